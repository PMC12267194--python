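"""Centerline morphometrics of the thoracic aorta.

Extracts centerline trees from corresponded ring-swept surfaces, splits them
into the seven characteristic tracts (total, ascending, arch, descending,
BCA, LCCA, LSA), computes per-tract morphometric quantities (length,
tortuosity, maximal-inscribed-sphere radius, curvature, torsion), compares
geometries against the population template, ranks shapes by morphological
deviation, and defines the three downstream result planes (pre-arch,
post-arch, descending).

Conventions
-----------
* All coordinates, arc lengths and radii are in millimetres; curvature and
  torsion in 1/mm.
* Tortuosity follows the length-over-chord definition and is therefore >= 1.
* Curvature and torsion are discrete Frenet estimates on a lightly smoothed
  polyline (moving average, window 5 by default); torsion is set to zero
  where curvature vanishes, since the osculating plane is undefined there.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

__all__ = [
    "Polyline",
    "CenterlineTree",
    "TractSet",
    "MorphoFeatures",
    "ResultPlane",
    "BRANCH_NAMES",
    "TRACT_NAMES",
    "FEATURE_COLUMNS",
    "centerlines_from_geometry",
    "split_tracts",
    "compute_features",
    "feature_table",
    "compare_to_template",
    "select_representatives",
    "define_result_planes",
]

BRANCH_NAMES = ("BCA", "LCCA", "LSA")
TRACT_NAMES = ("total", "ascending", "arch", "descending", "BCA", "LCCA", "LSA")

#: quantity columns of a feature table, in reporting order
FEATURE_COLUMNS = (
    "length",
    "tortuosity",
    "radius_mean",
    "radius_sd",
    "curvature_mean",
    "curvature_sd",
    "torsion_mean",
    "torsion_sd",
)

_CURVATURE_FLOOR = 1e-6  # 1/mm; below this torsion is reported as 0


@dataclass(frozen=True)
class Polyline:
    """Ordered 3D polyline with optional per-point inscribed radii (mm)."""

    points: np.ndarray  # (n, 3)
    radii: np.ndarray | None = None  # (n,)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("polyline needs an (n>=2, 3) point array")
        if not np.all(np.isfinite(pts)):
            raise ValueError("polyline contains non-finite coordinates")
        object.__setattr__(self, "points", pts)
        if self.radii is not None:
            r = np.asarray(self.radii, dtype=float)
            if r.shape != (pts.shape[0],):
                raise ValueError("radii must match the number of points")
            object.__setattr__(self, "radii", r)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def arclength(self) -> np.ndarray:
        """Cumulative arc length s (mm), s[0] = 0."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate(([0.0], np.cumsum(seg)))

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    @property
    def chord(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))

    @property
    def tortuosity(self) -> float:
        c = self.chord
        if c == 0.0:
            raise ValueError("degenerate polyline: coincident endpoints")
        ratio = self.length / c
        # length >= chord by the triangle inequality; absorb pure roundoff
        return 1.0 if 1.0 - 1e-9 < ratio < 1.0 else ratio

    def slice(self, i0: int, i1: int) -> "Polyline":
        """Contiguous sub-polyline over point indices [i0, i1]."""
        r = None if self.radii is None else self.radii[i0 : i1 + 1]
        return Polyline(self.points[i0 : i1 + 1], r)

    def point_at_s(self, s: float) -> np.ndarray:
        """Linear interpolation of the position at arc length s."""
        sa = self.arclength
        s = float(np.clip(s, sa[0], sa[-1]))
        x = np.array([np.interp(s, sa, self.points[:, k]) for k in range(3)])
        return x

    def tangent_at_s(self, s: float) -> np.ndarray:
        """Unit tangent at arc length s (central differences)."""
        sa = self.arclength
        grad = np.gradient(self.points, sa, axis=0)
        t = np.array([np.interp(s, sa, grad[:, k]) for k in range(3)])
        n = np.linalg.norm(t)
        if n == 0:
            raise ValueError("zero tangent on polyline")
        return t / n


@dataclass(frozen=True)
class CenterlineTree:
    """Centerline tree of one aorta.

    The tree is stored as one main polyline (aortic root -> descending
    outlet) plus three branch polylines whose first point coincides with the
    main polyline at the branch's attachment index, so the four root-to-outlet
    polylines share the root prefix point-for-point.
    """

    main: Polyline
    branches: Mapping[str, Polyline]
    attach: Mapping[str, int]  # branch name -> main point index of its ostium

    def __post_init__(self) -> None:
        for name in BRANCH_NAMES:
            if name not in self.branches or name not in self.attach:
                raise ValueError(f"centerline tree is missing branch {name}")
        sa = self.main.arclength
        if np.any(np.diff(sa) <= 0):
            raise ValueError("main centerline arc length is not strictly increasing")
        if self.main.radii is not None and np.any(self.main.radii <= 0):
            raise ValueError("non-positive inscribed radius on main centerline")
        for name, br in self.branches.items():
            i = self.attach[name]
            if not np.allclose(br.points[0], self.main.points[i], atol=1e-9):
                raise ValueError(f"branch {name} does not start at its attachment point")

    @property
    def ostia_s(self) -> dict[str, float]:
        sa = self.main.arclength
        return {name: float(sa[self.attach[name]]) for name in BRANCH_NAMES}

    def full_polyline(self, outlet: str) -> Polyline:
        """Root-to-outlet polyline for 'descending' or a branch name."""
        if outlet == "descending":
            return self.main
        br = self.branches[outlet]
        i = self.attach[outlet]
        pts = np.vstack([self.main.points[: i + 1], br.points[1:]])
        radii = None
        if self.main.radii is not None and br.radii is not None:
            radii = np.concatenate([self.main.radii[: i + 1], br.radii[1:]])
        return Polyline(pts, radii)


@dataclass(frozen=True)
class TractSet:
    """The seven characteristic tracts plus ostia bookkeeping."""

    tracts: Mapping[str, Polyline]
    ostia_s: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [n for n in TRACT_NAMES if n not in self.tracts]
        if missing:
            raise ValueError(f"tract set is missing {missing}")
        if len(self.tracts) != len(TRACT_NAMES):
            raise ValueError("tract set must contain exactly the seven tracts")

    def __getitem__(self, name: str) -> Polyline:
        return self.tracts[name]


@dataclass(frozen=True)
class MorphoFeatures:
    length: float  # mm
    tortuosity: float  # dimensionless, >= 1
    radius_mean: float | None  # mm
    radius_sd: float | None  # mm
    curvature_mean: float  # 1/mm
    curvature_sd: float  # 1/mm
    torsion_mean: float  # 1/mm, signed
    torsion_sd: float  # 1/mm

    def as_dict(self) -> dict[str, float]:
        d = {
            "length": self.length,
            "tortuosity": self.tortuosity,
            "curvature_mean": self.curvature_mean,
            "curvature_sd": self.curvature_sd,
            "torsion_mean": self.torsion_mean,
            "torsion_sd": self.torsion_sd,
        }
        d["radius_mean"] = np.nan if self.radius_mean is None else self.radius_mean
        d["radius_sd"] = np.nan if self.radius_sd is None else self.radius_sd
        return d


@dataclass(frozen=True)
class ResultPlane:
    """Cross-section plane on the centerline (origin + Frenet-tangent normal)."""

    name: str  # pre-arch | post-arch | descending
    origin: np.ndarray  # (3,), mm
    normal: np.ndarray  # (3,), unit

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ValueError("plane normal must be a unit vector")
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "normal", n)


# ---------------------------------------------------------------------------
# centerline extraction from corresponded ring-swept surfaces
# ---------------------------------------------------------------------------

def centerlines_from_geometry(geometry) -> CenterlineTree:
    """Recover the centerline tree of a ring-swept aorta surface.

    The centerline point of each ring is the centroid of the ring's surface
    samples; the inscribed-sphere radius at that point is the minimum distance
    from the centroid to the ring's samples (exact for circular rings, the
    semi-minor axis for elliptical ones). Branch polylines are assembled from
    the layout's topology and prefixed with the ostium point on the main
    centerline.

    Parameters
    ----------
    geometry
        Any object with ``points`` (n, 3) and a ring ``layout`` as produced by
        :mod:`aortaflow.population` (duck-typed).
    """
    layout = getattr(geometry, "layout", None)
    if layout is None:
        raise ValueError("geometry carries no ring layout metadata")
    pts = np.asarray(geometry.points, dtype=float)
    ns = layout.n_samples

    def _ring_block(start: int, count: int) -> tuple[np.ndarray, np.ndarray]:
        rings = pts[start : start + count * ns].reshape(count, ns, 3)
        centers = rings.mean(axis=1)
        radii = np.linalg.norm(rings - centers[:, None, :], axis=2).min(axis=1)
        return centers, radii

    main_centers, main_radii = _ring_block(0, layout.main_rings)
    main = Polyline(main_centers, main_radii)

    branches: dict[str, Polyline] = {}
    attach: dict[str, int] = {}
    for bl in layout.branches:
        centers, radii = _ring_block(bl.point_start, bl.ring_count)
        i = bl.attach_ring
        bpts = np.vstack([main_centers[i], centers])
        bradii = np.concatenate([[main_radii[i]], radii])
        branches[bl.name] = Polyline(bpts, bradii)
        attach[bl.name] = i
    return CenterlineTree(main=main, branches=branches, attach=attach)


def split_tracts(tree: CenterlineTree, ostia: Mapping[str, int] | None = None) -> TractSet:
    """Split a centerline tree into the seven characteristic tracts.

    ascending = root -> BCA ostium; arch = BCA -> LSA ostium; descending =
    LSA ostium -> outlet; each branch tract starts at its ostium; total =
    the whole main polyline. For a bovine arch the BCA and LCCA ostia
    coincide and the ascending/arch boundary sits at the shared ostium.

    Parameters
    ----------
    tree
        Centerline tree.
    ostia
        Optional override of the branch attachment indices on the main
        polyline; defaults to the tree's own attachments.
    """
    att = dict(tree.attach if ostia is None else ostia)
    i_bca, i_lcca, i_lsa = (att[n] for n in BRANCH_NAMES)
    if not (i_bca <= i_lcca <= i_lsa) or i_bca >= i_lsa:
        raise ValueError(
            f"ostia out of order along the arch: BCA@{i_bca}, LCCA@{i_lcca}, LSA@{i_lsa}"
        )
    main = tree.main
    tracts = {
        "total": main,
        "ascending": main.slice(0, i_bca),
        "arch": main.slice(i_bca, i_lsa),
        "descending": main.slice(i_lsa, main.n_points - 1),
        **{name: tree.branches[name] for name in BRANCH_NAMES},
    }
    sa = main.arclength
    ostia_s = {name: float(sa[att[name]]) for name in BRANCH_NAMES}
    return TractSet(tracts=tracts, ostia_s=ostia_s)


# ---------------------------------------------------------------------------
# discrete Frenet morphometrics
# ---------------------------------------------------------------------------

def _dedup(points: np.ndarray, radii: np.ndarray | None, tol: float = 1e-12):
    keep = np.concatenate(([True], np.linalg.norm(np.diff(points, axis=0), axis=1) > tol))
    return points[keep], (None if radii is None else radii[keep])


def compute_features(tract: Polyline, smooth_window: int = 5) -> MorphoFeatures:
    """Morphometric quantities of one tract polyline.

    Length is the polygonal arc length; tortuosity is length over endpoint
    chord. Curvature kappa = |r' x r''| / |r'|^3 and torsion
    tau = (r' x r'') . r''' / |r' x r''|^2 are evaluated with arc-length
    parameterized central differences on a moving-average smoothed copy of
    the polyline (smoothing affects curvature/torsion only). Means and SDs
    are taken over interior points; the inscribed radius statistics come from
    the raw per-point radii.
    """
    pts, radii = _dedup(np.asarray(tract.points, dtype=float),
                        None if tract.radii is None else np.asarray(tract.radii, dtype=float))
    if pts.shape[0] < 4:
        raise ValueError("tract has fewer than 4 distinct points; torsion needs third differences")
    clean = Polyline(pts, radii)

    if smooth_window and smooth_window > 1:
        sm = uniform_filter1d(pts, size=int(smooth_window), axis=0, mode="nearest")
    else:
        sm = pts
    s = Polyline(sm).arclength
    if np.any(np.diff(s) <= 0):
        raise ValueError("degenerate tract after smoothing")
    d1 = np.gradient(sm, s, axis=0)
    d2 = np.gradient(d1, s, axis=0)
    d3 = np.gradient(d2, s, axis=0)
    cross = np.cross(d1, d2)
    speed = np.linalg.norm(d1, axis=1)
    cross_norm = np.linalg.norm(cross, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = cross_norm / speed**3
        tau = np.einsum("ij,ij->i", cross, d3) / cross_norm**2
    kappa = np.nan_to_num(kappa, nan=0.0, posinf=0.0, neginf=0.0)
    tau = np.where(kappa < _CURVATURE_FLOOR, 0.0, np.nan_to_num(tau))

    # drop the endpoints, where the one-sided differences are low-order
    ntrim = 2 if pts.shape[0] >= 8 else 1
    interior = slice(ntrim, pts.shape[0] - ntrim)
    kin, tin = kappa[interior], tau[interior]

    if radii is not None:
        rin = radii[interior] if radii[interior].size else radii
        radius_mean, radius_sd = float(np.mean(rin)), float(np.std(rin))
    else:
        radius_mean = radius_sd = None

    return MorphoFeatures(
        length=clean.length,
        tortuosity=clean.tortuosity,
        radius_mean=radius_mean,
        radius_sd=radius_sd,
        curvature_mean=float(np.mean(kin)),
        curvature_sd=float(np.std(kin)),
        torsion_mean=float(np.mean(tin)),
        torsion_sd=float(np.std(tin)),
    )


# ---------------------------------------------------------------------------
# feature tables, template comparison, representative selection
# ---------------------------------------------------------------------------

def feature_table(tractsets: Mapping[str, TractSet], smooth_window: int = 5) -> pd.DataFrame:
    """One row per (geometry label, tract) with the morphometric quantities."""
    rows = []
    for label, ts in tractsets.items():
        for tract_name in TRACT_NAMES:
            feats = compute_features(ts[tract_name], smooth_window=smooth_window)
            rows.append({"label": label, "tract": tract_name, **feats.as_dict()})
    df = pd.DataFrame(rows)
    return df[["label", "tract", *FEATURE_COLUMNS]]


def compare_to_template(
    table: pd.DataFrame, template_label: str = "template", zero_tol: float = 1e-12
) -> pd.DataFrame:
    """Append percent-difference-from-template columns to a feature table.

    For each quantity q, pct_q = 100 * (q - q_template) / q_template, matched
    by tract. Where the template value is (numerically) zero the difference is
    reported absolute instead and flagged in ``pct_<q>_absolute``.
    """
    if template_label not in set(table["label"]):
        raise ValueError(f"template row '{template_label}' missing from table")
    tmpl = table[table["label"] == template_label].set_index("tract")
    out = table.copy()
    for q in FEATURE_COLUMNS:
        ref = out["tract"].map(tmpl[q])
        absolute = ref.abs() <= zero_tol
        with np.errstate(divide="ignore", invalid="ignore"):
            pct = 100.0 * (out[q] - ref) / ref
        out[f"pct_{q}"] = np.where(absolute, out[q] - ref, pct)
        out[f"pct_{q}_absolute"] = absolute.to_numpy()
    return out


def population_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Population mean/SD per (tract, quantity)."""
    return table.groupby("tract")[list(FEATURE_COLUMNS)].agg(["mean", "std"])


_MODE_LABEL = re.compile(r"^m(\d+)_sd([+-][0-9.]+)$")


def parse_mode_label(label: str) -> tuple[int, float] | None:
    """Parse a single-mode shape label 'm<k>_sd<+/-v>' -> (mode, sd)."""
    m = _MODE_LABEL.match(label)
    if m is None:
        return None
    return int(m.group(1)), float(m.group(2))


def select_representatives(
    table: pd.DataFrame,
    k: int = 20,
    mode_limit: int = 10,
    template_label: str = "template",
) -> list[str]:
    """Pick the k most morphologically deviant single-mode shapes.

    Eligible shapes are those generated from modes below ``mode_limit``;
    each is scored by its maximum absolute percent deviation from the
    template over all (tract, quantity) cells; the top k by score (ties
    broken by ascending label) are returned with the template appended.
    """
    if table.empty:
        raise ValueError("empty feature table")
    pct_cols = [f"pct_{q}" for q in FEATURE_COLUMNS if f"pct_{q}" in table.columns]
    if not pct_cols:
        raise ValueError("table carries no percent-deviation columns; run compare_to_template")
    scores: dict[str, float] = {}
    for label, grp in table.groupby("label"):
        parsed = parse_mode_label(str(label))
        if parsed is None or parsed[0] >= mode_limit:
            continue
        scores[str(label)] = float(np.nanmax(np.abs(grp[pct_cols].to_numpy())))
    ranked = sorted(scores, key=lambda lb: (-scores[lb], lb))
    if k > len(ranked):
        warnings.warn(
            f"requested {k} representatives but only {len(ranked)} eligible; returning all"
        )
    return ranked[:k] + [template_label]


# ---------------------------------------------------------------------------
# result planes
# ---------------------------------------------------------------------------

_PLANE_SPECS = (("pre-arch", "ascending", 0.85), ("post-arch", "descending", 0.10),
                ("descending", "descending", 0.90))


def define_result_planes(tracts: TractSet) -> list[ResultPlane]:
    """The three analysis planes: pre-arch at 85% of the ascending tract,
    post-arch at 10% and descending at 90% of the descending tract; the
    normal is the local Frenet tangent (central difference, normalized)."""
    planes = []
    for name, tract_name, frac in _PLANE_SPECS:
        tract = tracts[tract_name]
        if tract.n_points < 3:
            raise ValueError(f"tract {tract_name} too short to interpolate a plane")
        s = frac * tract.length
        planes.append(ResultPlane(name=name, origin=tract.point_at_s(s),
                                  normal=tract.tangent_at_s(s)))
    return planes
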