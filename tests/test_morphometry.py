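"""Centerline extraction, tracts, Frenet quantities, selection, planes."""

import numpy as np
import pandas as pd
import pytest

import aortaflow as af
from aortaflow import morphometry as mm
from aortaflow.morphometry import Polyline, TractSet, compute_features


def _helix(a: float, b: float, n: int, turns: float = 2.0) -> Polyline:
    t = np.linspace(0, 2 * np.pi * turns, n)
    return Polyline(np.column_stack([a * np.cos(t), a * np.sin(t), b * t]))


# ---------------------------------------------------------------------------
# centerline recovery
# ---------------------------------------------------------------------------

def test_circular_rings_recover_exact_radius(template_geometry):
    tree = af.centerlines_from_geometry(template_geometry)
    gt = template_geometry.centerline_tree
    np.testing.assert_allclose(tree.main.radii, gt.main.radii, atol=1e-6)
    np.testing.assert_allclose(tree.main.points, gt.main.points, atol=1e-6)


def test_elliptical_ring_radius_is_semi_minor(template_geometry):
    """Min-distance inscribed radius of an a/b ellipse is the semi-minor axis."""
    g = template_geometry
    ns = g.layout.n_samples
    pts = g.points.copy()
    ring = 5  # a straight ascending ring, lying in an x-y plane
    c = g.centerline_tree.main.points[ring]
    block = slice(ring * ns, (ring + 1) * ns)
    rel = pts[block] - c
    rel[:, 0] *= 1.5  # a = 1.5 r
    rel[:, 1] *= 0.8  # b = 0.8 r
    pts[block] = c + rel

    class Raw:
        pass

    raw = Raw()
    raw.points = pts
    raw.layout = g.layout
    tree = af.centerlines_from_geometry(raw)
    expected = 0.8 * g.centerline_tree.main.radii[ring]
    assert tree.main.radii[ring] == pytest.approx(expected, rel=0.01)


def test_missing_layout_fails():
    class Bare:
        points = np.zeros((10, 3))

    with pytest.raises(ValueError, match="layout"):
        af.centerlines_from_geometry(Bare())


# ---------------------------------------------------------------------------
# tracts
# ---------------------------------------------------------------------------

def test_seven_tracts_partition_the_total(template_geometry):
    ts = af.split_tracts(template_geometry.centerline_tree)
    assert set(ts.tracts) == set(mm.TRACT_NAMES)
    parts = ts["ascending"].length + ts["arch"].length + ts["descending"].length
    assert parts == pytest.approx(ts["total"].length, abs=1e-6)


def test_bovine_arch_boundary_at_shared_ostium(small_res):
    g = af.build_geometry(af.AortaParams(bovine_arch=True), small_res)
    ts = af.split_tracts(g.centerline_tree)
    assert ts.ostia_s["BCA"] == ts.ostia_s["LCCA"]
    # ascending/arch boundary sits at the shared ostium
    assert ts["ascending"].length == pytest.approx(ts.ostia_s["BCA"], abs=1e-9)


def test_out_of_order_ostia_fail(template_geometry):
    tree = template_geometry.centerline_tree
    bad = dict(tree.attach)
    bad["BCA"], bad["LSA"] = bad["LSA"], bad["BCA"]
    with pytest.raises(ValueError, match="out of order"):
        af.split_tracts(tree, ostia=bad)


# ---------------------------------------------------------------------------
# Frenet features
# ---------------------------------------------------------------------------

def test_straight_segment_features():
    t = np.linspace(0, 80, 60)
    line = Polyline(np.column_stack([t, 0.3 * t, np.zeros_like(t)]))
    f = compute_features(line)
    assert f.tortuosity == pytest.approx(1.0, abs=1e-12)
    assert abs(f.curvature_mean) < 1e-9
    assert abs(f.torsion_mean) < 1e-9


def test_circular_arc_curvature():
    th = np.linspace(0, np.pi / 2, 200)
    arc = Polyline(np.column_stack([25 * np.cos(th), 25 * np.sin(th), np.zeros_like(th)]))
    f = compute_features(arc)
    assert f.curvature_mean == pytest.approx(1 / 25.0, rel=0.01)
    assert f.torsion_mean == pytest.approx(0.0, abs=1e-9)


def test_helix_matches_closed_form():
    f = compute_features(_helix(10.0, 5.0, 200))
    assert f.curvature_mean == pytest.approx(10.0 / 125.0, rel=0.02)
    assert f.torsion_mean == pytest.approx(5.0 / 125.0, rel=0.02)


def test_frenet_estimates_converge_with_density():
    """Discretization error decreases at observed order >= 1 on the helix."""
    errs_k, errs_t = [], []
    for n in (200, 400, 800):
        f = compute_features(_helix(10.0, 5.0, n), smooth_window=1)
        errs_k.append(abs(f.curvature_mean - 0.08) / 0.08)
        errs_t.append(abs(f.torsion_mean - 0.04) / 0.04)
    for errs in (errs_k, errs_t):
        assert errs[0] / errs[1] > 1.5 and errs[1] / errs[2] > 1.5


def test_features_invariant_under_rigid_motion(template_geometry):
    ts = af.split_tracts(template_geometry.centerline_tree)
    tract = ts["arch"]
    # a rotation about an arbitrary axis plus a translation
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec([0.3, -1.1, 0.7]).as_matrix()
    moved = Polyline(tract.points @ R.T + np.array([12.0, -5.0, 40.0]), tract.radii)
    f0, f1 = compute_features(tract), compute_features(moved)
    for name in ("length", "tortuosity", "curvature_mean", "curvature_sd",
                 "torsion_sd", "radius_mean"):
        a, b = getattr(f0, name), getattr(f1, name)
        assert b == pytest.approx(a, rel=1e-6, abs=1e-12)
    assert abs(f1.torsion_mean - f0.torsion_mean) < 1e-6 * max(1.0, abs(f0.torsion_mean))


def test_tortuosity_at_least_one_everywhere(small_population, small_model):
    from aortaflow import ssm

    geoms = [*small_population, *ssm.augment_dataset(small_model, {0: (-3.0, 3.0)})]
    for g in geoms:
        ts = af.split_tracts(
            g.centerline_tree if g.params is not None
            else af.centerlines_from_geometry(g))
        for name in mm.TRACT_NAMES:
            assert compute_features(ts[name]).tortuosity >= 1.0


def test_degenerate_polyline_fails():
    pts = np.zeros((6, 3))
    pts[:, 0] = [0, 0, 0, 0, 0, 0]
    with pytest.raises(ValueError):
        compute_features(Polyline(pts + 1e-20))


# ---------------------------------------------------------------------------
# template comparison and selection
# ---------------------------------------------------------------------------

def _toy_table() -> pd.DataFrame:
    rows = []
    for label, scale in (("template", 1.0), ("m0_sd+2", 1.2), ("m1_sd-1", 0.9),
                         ("m11_sd+3", 5.0)):
        rows.append({"label": label, "tract": "total", "length": 100.0 * scale,
                     "tortuosity": 1.0 * scale, "radius_mean": 10.0, "radius_sd": 1.0,
                     "curvature_mean": 0.05, "curvature_sd": 0.01,
                     "torsion_mean": 0.01, "torsion_sd": 0.002})
    return pd.DataFrame(rows)


def test_percent_difference_against_template():
    out = mm.compare_to_template(_toy_table())
    tmpl = out[out.label == "template"]
    assert (tmpl[[c for c in out.columns if c.startswith("pct_") and
                  not c.endswith("_absolute")]].abs() < 1e-12).all().all()
    row = out[out.label == "m0_sd+2"].iloc[0]
    assert row["pct_length"] == pytest.approx(20.0)


def test_zero_template_value_reported_absolute():
    table = _toy_table()
    table.loc[table.label == "template", "torsion_mean"] = 0.0
    out = mm.compare_to_template(table)
    row = out[out.label == "m0_sd+2"].iloc[0]
    assert row["pct_torsion_mean_absolute"]
    assert row["pct_torsion_mean"] == pytest.approx(0.01)


def test_symmetric_sd_pair_has_near_zero_mean_length_deviation(small_model):
    from aortaflow import ssm

    geoms = ssm.augment_dataset(small_model, {0: (-2.0, 2.0)})
    tracts = {g.label: af.split_tracts(af.centerlines_from_geometry(g)) for g in geoms}
    table = mm.compare_to_template(mm.feature_table(tracts))
    rows = table[(table.tract == "total") & (table.label != "template")]
    assert abs(rows["pct_length"].mean()) < 5.0  # percentage points


def test_select_representatives_mode_limit_and_ranking():
    out = mm.compare_to_template(_toy_table())
    # m11 deviates most but sits beyond the mode limit
    sel = mm.select_representatives(out, k=2, mode_limit=10)
    assert sel == ["m0_sd+2", "m1_sd-1", "template"]
    sel1 = mm.select_representatives(out, k=1, mode_limit=10)
    assert sel1 == ["m0_sd+2", "template"]  # largest max-|%| deviation first
    with pytest.warns(UserWarning, match="eligible"):
        sel_all = mm.select_representatives(out, k=10, mode_limit=10)
    assert set(sel_all) == {"m0_sd+2", "m1_sd-1", "template"}


# ---------------------------------------------------------------------------
# result planes
# ---------------------------------------------------------------------------

def _straight_tractset() -> TractSet:
    def line(p0, d, L, n=50):
        t = np.linspace(0, L, n)
        pts = np.asarray(p0) + t[:, None] * np.asarray(d, dtype=float)
        return Polyline(pts, np.full(n, 10.0))

    tracts = {
        "total": line([0, 0, 0], [0, 0, 1], 300),
        "ascending": line([0, 0, 0], [0, 0, 1], 80),
        "arch": line([0, 0, 80], [0, 0, 1], 60),
        "descending": line([0, 0, 140], [0, 0, 1], 100),
        "BCA": line([0, 0, 80], [0, 1, 0], 30),
        "LCCA": line([0, 0, 100], [0, 1, 0], 30),
        "LSA": line([0, 0, 120], [0, 1, 0], 30),
    }
    return TractSet(tracts=tracts, ostia_s={"BCA": 80.0, "LCCA": 100.0, "LSA": 120.0})


def test_result_planes_on_straight_tracts():
    planes = {p.name: p for p in mm.define_result_planes(_straight_tractset())}
    assert set(planes) == {"pre-arch", "post-arch", "descending"}
    np.testing.assert_allclose(planes["post-arch"].origin, [0, 0, 150], atol=1e-9)
    np.testing.assert_allclose(planes["descending"].origin, [0, 0, 230], atol=1e-9)
    np.testing.assert_allclose(planes["pre-arch"].origin, [0, 0, 68], atol=1e-9)
    for p in planes.values():
        assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-9)


def test_result_plane_origins_lie_on_the_centerline(template_geometry):
    ts = af.split_tracts(template_geometry.centerline_tree)
    for p in mm.define_result_planes(ts):
        tract = ts["ascending" if p.name == "pre-arch" else "descending"]
        # distance from the origin to the nearest polyline segment
        a, b = tract.points[:-1], tract.points[1:]
        ab = b - a
        t = np.clip(np.einsum("ij,ij->i", p.origin - a, ab)
                    / np.einsum("ij,ij->i", ab, ab), 0, 1)
        d = np.linalg.norm(a + t[:, None] * ab - p.origin, axis=1).min()
        assert d < 1e-6
        assert np.linalg.norm(p.normal) == pytest.approx(1.0, abs=1e-9)
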