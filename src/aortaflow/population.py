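"""Synthetic, point-corresponded thoracic-aorta populations.

Every geometry is a swept-tube surface: an ascending segment, a circular-arc
arch with an optional out-of-plane sinusoidal perturbation, a descending
segment, and three supra-aortic branches (BCA, LCCA, LSA) attached at
arc-length fractions along the arch. Surfaces are built as circular rings
swept along the centerline with a rotation-minimizing frame and a linearly
tapering radius, using a fixed (ring, sample) layout shared by the whole
population — correspondence holds by construction, so PCA can be applied
directly and the true centerline is known for every subject.

Units: millimetres and radians throughout.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special, stats

from .morphometry import BRANCH_NAMES, CenterlineTree, Polyline, split_tracts

__all__ = [
    "AortaParams",
    "PopulationSpec",
    "Resolution",
    "RingLayout",
    "BranchLayout",
    "AortaGeometry",
    "build_geometry",
    "sample_population",
    "write_mesh",
    "write_centerline_csv",
    "write_population",
]


@dataclass(frozen=True)
class AortaParams:
    """Anatomical parameters of one synthetic thoracic aorta.

    Defaults describe an average adult thoracic aorta: total ascending tract
    (straight root segment plus the proximal quarter of the arch) near 90 mm,
    arch tract near 38 mm, descending tract near 124 mm, ascending lumen
    radius 16 mm tapering to ~11.7 mm distally, and supra-aortic branch radii
    of 6.3 / 3.4 / 5.3 mm for BCA / LCCA / LSA.
    """

    ascending_length: float = 65.0  # mm, straight segment below the arch
    arch_radius: float = 33.0  # mm, radius of the arch's guiding arc
    arch_angle: float = float(np.pi)  # rad, tangent turn of the arch
    descending_length: float = 85.0  # mm, straight segment after the arch
    root_radius: float = 16.0  # mm, lumen radius at the aortic root
    taper_ratio: float = 0.73  # distal/root lumen radius
    torsion_amplitude: float = 5.0  # mm, out-of-plane sinusoidal displacement
    branch_origin_u: tuple[float, float, float] = (0.25, 0.45, 0.62)  # arch fractions
    branch_radii: tuple[float, float, float] = (6.3, 3.4, 5.3)  # mm
    branch_lengths: tuple[float, float, float] = (35.0, 35.0, 35.0)  # mm
    bovine_arch: bool = False  # BCA and LCCA share an origin when True

    def validate(self) -> None:
        for name in ("ascending_length", "arch_radius", "descending_length",
                     "root_radius", "taper_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AortaParams.{name} must be positive")
        if self.torsion_amplitude < 0:
            raise ValueError("AortaParams.torsion_amplitude must be non-negative")
        if not (np.pi / 2 < self.arch_angle < 3 * np.pi / 2):
            raise ValueError("AortaParams.arch_angle must lie in (pi/2, 3pi/2)")
        u = self.branch_origin_u
        if len(u) != 3 or not all(0 < v < 1 for v in u):
            raise ValueError("AortaParams.branch_origin_u needs 3 values in (0, 1)")
        if not (u[0] < u[1] < u[2]):
            raise ValueError("AortaParams.branch_origin_u must be strictly increasing")
        for name in ("branch_radii", "branch_lengths"):
            vals = getattr(self, name)
            if len(vals) != 3 or any(v <= 0 for v in vals):
                raise ValueError(f"AortaParams.{name} needs 3 positive values")
        if any(r >= self.root_radius for r in self.branch_radii):
            raise ValueError("AortaParams.branch_radii must be smaller than root_radius")


#: scalar fields sampled per subject, with their default coefficient of variation
_DEFAULT_CV = {
    "ascending_length": 0.08,
    "arch_radius": 0.08,
    "arch_angle": 0.05,
    "descending_length": 0.08,
    "root_radius": 0.08,
    "taper_ratio": 0.05,
    "torsion_amplitude": 0.30,
    "branch_origin_u": 0.05,
    "branch_radii": 0.08,
    "branch_lengths": 0.08,
}


@dataclass(frozen=True)
class PopulationSpec:
    """Sampling specification for a synthetic cohort (default n = 19)."""

    n_subjects: int = 19
    means: AortaParams = field(default_factory=AortaParams)
    cv: dict = field(default_factory=dict)  # per-field CV overrides
    bovine_arch_probability: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("PopulationSpec.n_subjects must be >= 2")
        if not (0 <= self.bovine_arch_probability <= 1):
            raise ValueError("PopulationSpec.bovine_arch_probability must lie in [0, 1]")
        for k, v in self.cv.items():
            if k not in _DEFAULT_CV:
                raise ValueError(f"PopulationSpec.cv has unknown field '{k}'")
            if v < 0:
                raise ValueError(f"PopulationSpec.cv['{k}'] must be >= 0")
        self.means.validate()

    def field_cv(self, name: str) -> float:
        return float(self.cv.get(name, _DEFAULT_CV[name]))


@dataclass(frozen=True)
class Resolution:
    """Ring/sample counts of the swept surface.

    Defaults give (200 + 260 + 300 + 3 x 80) rings x 25 samples = 25,000
    surface points per geometry.
    """

    n_samples: int = 25
    ascending_rings: int = 200
    arch_rings: int = 260
    descending_rings: int = 300
    branch_rings: int = 80

    @property
    def main_rings(self) -> int:
        return self.ascending_rings + self.arch_rings + self.descending_rings

    @property
    def total_points(self) -> int:
        return (self.main_rings + 3 * self.branch_rings) * self.n_samples


@dataclass(frozen=True)
class BranchLayout:
    name: str
    point_start: int  # first point index of the branch's ring block
    ring_count: int
    attach_ring: int  # main-polyline ring index of the ostium


@dataclass(frozen=True)
class RingLayout:
    """Index map from flat point arrays to (ring, sample) locations.

    Identical for every geometry in a population, so the same point index
    always refers to the same parametric location.
    """

    n_samples: int
    main_rings: int
    segment_rings: tuple[int, int, int]  # ascending, arch, descending ring counts
    branches: tuple[BranchLayout, BranchLayout, BranchLayout]
    ostia_rings: dict  # branch name -> main ring index

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["branches"] = [dataclasses.asdict(b) for b in self.branches]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RingLayout":
        branches = tuple(BranchLayout(**b) for b in d["branches"])
        return cls(
            n_samples=d["n_samples"],
            main_rings=d["main_rings"],
            segment_rings=tuple(d["segment_rings"]),
            branches=branches,
            ostia_rings=dict(d["ostia_rings"]),
        )


@dataclass(frozen=True)
class AortaGeometry:
    """One corresponded aorta: surface points + layout + ground truth."""

    label: str
    points: np.ndarray  # (n_points, 3), ring-major
    layout: RingLayout
    centerline_tree: CenterlineTree
    ostia_landmarks: tuple[int, int, int]  # point indices of the three ostia
    params: AortaParams | None = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if not np.all(np.isfinite(pts)):
            raise ValueError(f"geometry '{self.label}' has non-finite coordinates")
        expected = (self.layout.main_rings + sum(b.ring_count for b in self.layout.branches)) \
            * self.layout.n_samples
        if pts.shape != (expected, 3):
            raise ValueError(
                f"geometry '{self.label}' point array {pts.shape} does not match layout "
                f"({expected} points)"
            )
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]


# ---------------------------------------------------------------------------
# sweep machinery
# ---------------------------------------------------------------------------

def _rotation_minimizing_frames(tangents: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transport normal/binormal fields along a tangent field."""
    t = tangents / np.linalg.norm(tangents, axis=1, keepdims=True)
    n = np.empty_like(t)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, t[0])) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n0 = ref - np.dot(ref, t[0]) * t[0]
    n[0] = n0 / np.linalg.norm(n0)
    for i in range(1, len(t)):
        v = n[i - 1] - np.dot(n[i - 1], t[i]) * t[i]
        nv = np.linalg.norm(v)
        if nv < 1e-12:  # near-degenerate transport; restart from reference
            v = ref - np.dot(ref, t[i]) * t[i]
            nv = np.linalg.norm(v)
        n[i] = v / nv
    b = np.cross(t, n)
    return n, b


def sweep_tube(centers: np.ndarray, radii: np.ndarray, n_samples: int) -> np.ndarray:
    """Sweep circular rings along a centerline; returns (n_rings*n_samples, 3).

    Ring samples are placed with a rotation-minimizing frame so that sample k
    of consecutive rings stays angularly aligned (no twist), which keeps the
    layout parametrically consistent across the population.
    """
    centers = np.asarray(centers, dtype=float)
    tangents = np.gradient(centers, axis=0)
    n, b = _rotation_minimizing_frames(tangents)
    phi = 2 * np.pi * np.arange(n_samples) / n_samples
    ring_dirs = (np.cos(phi)[None, :, None] * n[:, None, :]
                 + np.sin(phi)[None, :, None] * b[:, None, :])
    pts = centers[:, None, :] + np.asarray(radii)[:, None, None] * ring_dirs
    return pts.reshape(-1, 3)


def _main_centerline(params: AortaParams, res: Resolution) -> tuple[np.ndarray, np.ndarray]:
    """Main-vessel ring centers and per-ring taper radii."""
    L_asc, R, ang, L_desc = (params.ascending_length, params.arch_radius,
                             params.arch_angle, params.descending_length)
    # ascending: straight up from the origin (endpoint excluded; the arch starts there)
    z_asc = np.linspace(0.0, L_asc, res.ascending_rings, endpoint=False)
    asc = np.column_stack([np.zeros_like(z_asc), np.zeros_like(z_asc), z_asc])
    # arch: circular arc in the x-z plane, center at (R, 0, L_asc); tangent starts +z
    theta = np.linspace(0.0, ang, res.arch_rings, endpoint=False)
    arch = np.column_stack([
        R * (1.0 - np.cos(theta)),
        params.torsion_amplitude * np.sin(np.pi * theta / ang),
        L_asc + R * np.sin(theta),
    ])
    # descending: straight continuation along the arch's end tangent
    end = np.array([R * (1.0 - np.cos(ang)), 0.0, L_asc + R * np.sin(ang)])
    tangent = np.array([np.sin(ang), 0.0, np.cos(ang)])
    tvals = np.linspace(0.0, L_desc, res.descending_rings)
    desc = end[None, :] + tvals[:, None] * tangent[None, :]
    centers = np.vstack([asc, arch, desc])
    # linear taper from root radius to taper_ratio * root radius over arc length
    s = Polyline(centers).arclength
    radii = params.root_radius * (1.0 + (params.taper_ratio - 1.0) * s / s[-1])
    return centers, radii


def _branch_frames(params: AortaParams, res: Resolution):
    """Per-branch (attach ring, base point, unit direction) on the arch."""
    ang = params.arch_angle
    arch_center = np.array([params.arch_radius, 0.0, params.ascending_length])
    u = list(params.branch_origin_u)
    if params.bovine_arch:
        u[1] = u[0]  # LCCA shares the BCA origin
    rings, dirs = [], []
    tilts = (-0.15, 0.0, 0.15) if not params.bovine_arch else (-0.25, 0.25, 0.15)
    for i, (ui, tilt) in enumerate(zip(u, tilts)):
        ring = res.ascending_rings + int(round(ui * (res.arch_rings - 1)))
        theta = ui * ang
        # outward radial direction from the arc center (in-plane)
        p = np.array([params.arch_radius * (1 - np.cos(theta)),
                      params.torsion_amplitude * np.sin(np.pi * theta / ang),
                      params.ascending_length + params.arch_radius * np.sin(theta)])
        radial = p - arch_center
        radial[1] = 0.0
        radial /= np.linalg.norm(radial)
        tangent = np.array([np.sin(theta), 0.0, np.cos(theta)])
        d = radial + tilt * tangent
        d /= np.linalg.norm(d)
        rings.append(ring)
        dirs.append(d)
    if not params.bovine_arch and len({rings[0], rings[1], rings[2]}) < 3:
        raise ValueError("resolution too coarse to place three distinct ostia on the arch")
    if params.bovine_arch and rings[1] == rings[2]:
        raise ValueError("resolution too coarse to separate the shared trunk from the LSA")
    return rings, dirs


def build_geometry(
    params: AortaParams,
    resolution: Resolution | None = None,
    label: str = "subject",
) -> AortaGeometry:
    """Build one swept-tube aorta surface with known ground truth.

    The main vessel is ascending segment + circular-arc arch (out-of-plane
    sinusoid scaled by ``torsion_amplitude``) + descending segment; branches
    are straight tubes starting at the lumen surface above their ostium. The
    exact sweep centerline and taper radii are stored as the ground-truth
    centerline tree.
    """
    params.validate()
    res = resolution or Resolution()
    centers, radii = _main_centerline(params, res)
    rings, dirs = _branch_frames(params, res)

    points = [sweep_tube(centers, radii, res.n_samples)]
    branch_layouts = []
    branch_polylines: dict[str, Polyline] = {}
    attach: dict[str, int] = {}
    point_cursor = res.main_rings * res.n_samples
    for name, ring, d, br_r, br_len in zip(
        BRANCH_NAMES, rings, dirs, params.branch_radii, params.branch_lengths
    ):
        base = centers[ring] + d * radii[ring]  # start at the lumen surface
        t = np.linspace(0.0, br_len, res.branch_rings)
        bc = base[None, :] + t[:, None] * d[None, :]
        points.append(sweep_tube(bc, np.full(res.branch_rings, br_r), res.n_samples))
        branch_layouts.append(BranchLayout(name=name, point_start=point_cursor,
                                           ring_count=res.branch_rings, attach_ring=ring))
        bpts = np.vstack([centers[ring], bc])
        branch_polylines[name] = Polyline(bpts, np.concatenate([[radii[ring]],
                                                                np.full(res.branch_rings, br_r)]))
        attach[name] = ring
        point_cursor += res.branch_rings * res.n_samples

    layout = RingLayout(
        n_samples=res.n_samples,
        main_rings=res.main_rings,
        segment_rings=(res.ascending_rings, res.arch_rings, res.descending_rings),
        branches=tuple(branch_layouts),
        ostia_rings={name: r for name, r in zip(BRANCH_NAMES, rings)},
    )
    tree = CenterlineTree(main=Polyline(centers, radii), branches=branch_polylines,
                          attach=attach)
    landmarks = tuple(r * res.n_samples for r in rings)
    return AortaGeometry(label=label, points=np.vstack(points), layout=layout,
                         centerline_tree=tree, ostia_landmarks=landmarks, params=params)


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------

_PHI3 = stats.norm.cdf(3.0)


def _truncated_normal(rng: np.random.Generator, mean, cv: float, size=None):
    """Truncated-normal draw at +/- 3 CV around the mean (elementwise).

    Inverse-CDF sampling: u ~ U(Phi(-3), Phi(3)), x = mean + sd * Phi^-1(u).
    """
    mean = np.asarray(mean, dtype=float)
    u = rng.uniform(1.0 - _PHI3, _PHI3, size=size)  # drawn even at cv=0 for stream stability
    if cv == 0.0:
        return mean if size is None else np.broadcast_to(mean, np.shape(u)).copy()
    sd = cv * np.abs(mean)
    return mean + sd * special.ndtri(u)


def _sample_params(spec: PopulationSpec, rng: np.random.Generator) -> AortaParams:
    kwargs = {}
    for name in ("ascending_length", "arch_radius", "arch_angle", "descending_length",
                 "root_radius", "taper_ratio", "torsion_amplitude"):
        kwargs[name] = float(_truncated_normal(rng, getattr(spec.means, name),
                                               spec.field_cv(name)))
    for name in ("branch_origin_u", "branch_radii", "branch_lengths"):
        vals = _truncated_normal(rng, np.asarray(getattr(spec.means, name)),
                                 spec.field_cv(name), size=3)
        kwargs[name] = tuple(float(v) for v in np.atleast_1d(vals))
    kwargs["bovine_arch"] = bool(rng.random() < spec.bovine_arch_probability)
    params = AortaParams(**kwargs)
    try:
        params.validate()
    except ValueError as exc:
        raise ValueError(
            f"sampled parameters violate anatomy invariants ({exc}); "
            "reduce the offending field's CV"
        ) from exc
    return params


def sample_population(
    spec: PopulationSpec, resolution: Resolution | None = None
) -> list[AortaGeometry]:
    """Draw a mutually corresponded cohort of synthetic aortas.

    Per-field parameters follow truncated-normal distributions (+/- 3 CV) so
    every sampled anatomy satisfies its invariants without rejection loops;
    the bovine-arch variant is drawn with ``bovine_arch_probability``. The
    draw order is fixed, so a given seed reproduces the cohort bit-for-bit.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    res = resolution or Resolution()
    geometries = []
    width = max(2, len(str(spec.n_subjects - 1)))
    for i in range(spec.n_subjects):
        params = _sample_params(spec, rng)
        geometries.append(build_geometry(params, res, label=f"subject_{i:0{width}d}"))
    return geometries


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _surface_faces(layout: RingLayout) -> np.ndarray:
    """Triangle faces connecting consecutive rings within each tube block."""
    ns = layout.n_samples
    faces = []

    def _tube(ring_start_pt: int, n_rings: int) -> None:
        for r in range(n_rings - 1):
            a = ring_start_pt + r * ns
            b = a + ns
            for k in range(ns):
                k2 = (k + 1) % ns
                faces.append([a + k, b + k, b + k2])
                faces.append([a + k, b + k2, a + k2])

    _tube(0, layout.main_rings)
    for bl in layout.branches:
        _tube(bl.point_start, bl.ring_count)
    return np.asarray(faces, dtype=np.int64)


def write_mesh(geometry: AortaGeometry, path: str | Path) -> Path:
    """Export the surface as ASCII PLY or STL (by file extension).

    Open tube ends are capped with triangle fans (cap vertices are appended
    after the corresponded point set) so the exported surface is closed;
    inlet/outlet boundaries are recorded in the population manifest instead,
    since PLY/STL carry no boundary labels.
    """
    import trimesh

    path = Path(path)
    layout = geometry.layout
    ns = layout.n_samples
    verts = [geometry.points]
    faces = [_surface_faces(layout)]
    cursor = geometry.n_points

    def _cap(ring_start_pt: int, flip: bool) -> None:
        nonlocal cursor
        ring = geometry.points[ring_start_pt : ring_start_pt + ns]
        center = ring.mean(axis=0)
        verts.append(center[None, :])
        tri = []
        for k in range(ns):
            k2 = (k + 1) % ns
            f = [cursor, ring_start_pt + k, ring_start_pt + k2]
            tri.append(f[::-1] if flip else f)
        faces.append(np.asarray(tri, dtype=np.int64))
        cursor += 1

    _cap(0, flip=True)  # root
    _cap((layout.main_rings - 1) * ns, flip=False)  # descending outlet
    for bl in layout.branches:
        _cap(bl.point_start + (bl.ring_count - 1) * ns, flip=False)

    mesh = trimesh.Trimesh(vertices=np.vstack(verts), faces=np.vstack(faces), process=False)
    if path.suffix.lower() == ".ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    elif path.suffix.lower() == ".stl":
        path.write_text(trimesh.exchange.stl.export_stl_ascii(mesh))
    else:
        raise ValueError(f"unsupported mesh format '{path.suffix}' (use .ply or .stl)")
    return path


def write_centerline_csv(geometry: AortaGeometry, path: str | Path) -> Path:
    """Centerline export: branch_id, tract_id, point_index, s_mm, x/y/z_mm, r_inscribed_mm."""
    import pandas as pd

    tree = geometry.centerline_tree
    tracts = split_tracts(tree)
    i_bca = tree.attach["BCA"]
    i_lsa = tree.attach["LSA"]

    rows = []

    def _tract_of_main(i: int) -> str:
        if i <= i_bca:
            return "ascending"
        if i <= i_lsa:
            return "arch"
        return "descending"

    sa = tree.main.arclength
    for i in range(tree.main.n_points):
        x, y, z = tree.main.points[i]
        rows.append(("aorta", _tract_of_main(i), i, sa[i], x, y, z, tree.main.radii[i]))
    for name in BRANCH_NAMES:
        br = tree.branches[name]
        s0 = sa[tree.attach[name]]
        sb = br.arclength
        for i in range(br.n_points):
            x, y, z = br.points[i]
            rows.append((name, name, i, s0 + sb[i], x, y, z, br.radii[i]))
    df = pd.DataFrame(rows, columns=["branch_id", "tract_id", "point_index", "s_mm",
                                     "x_mm", "y_mm", "z_mm", "r_inscribed_mm"])
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def write_population(
    geometries: list[AortaGeometry],
    out_dir: str | Path,
    spec: PopulationSpec | None = None,
    mesh_format: str | None = "ply",
    centerlines: bool = True,
) -> Path:
    """Write meshes/centerlines plus a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for g in geometries:
        entry = {"label": g.label, "n_points": int(g.n_points),
                 "bovine_arch": bool(g.params.bovine_arch) if g.params else None,
                 "boundaries": ["root-inlet", "descending-outlet",
                                *[f"{b}-outlet" for b in BRANCH_NAMES]]}
        if mesh_format:
            entry["mesh"] = str(write_mesh(g, out_dir / f"{g.label}.{mesh_format}").name)
        if centerlines:
            entry["centerline"] = str(
                write_centerline_csv(g, out_dir / f"{g.label}_centerline.csv").name)
        entries.append(entry)
    manifest = {
        "n_geometries": len(geometries),
        "seed": None if spec is None else spec.seed,
        "spec": None if spec is None else {
            "n_subjects": spec.n_subjects,
            "bovine_arch_probability": spec.bovine_arch_probability,
            "means": dataclasses.asdict(spec.means),
            "cv": dict(spec.cv),
        },
        "geometries": entries,
    }
    path = out_dir / "population_manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path
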