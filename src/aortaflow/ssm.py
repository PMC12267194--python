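"""PCA statistical shape model on corresponded aorta point sets.

Shapes are flattened to rows of a shape matrix (3 x n_points values per
subject). The model holds the arithmetic mean shape, unit mode vectors and
eigenvalues of the sample covariance (divisor n - 1), obtained from the
singular value decomposition of the centered matrix. New shapes are
synthesized as

    x(c) = mean + sum_i c_i * sqrt(lambda_i) * phi_i

where c_i is the number of population standard deviations applied along
mode i. Dataset augmentation sweeps single modes over configurable SD
multipliers; the default scheme keeps a unit SD step for the first five
modes, the +/-3 SD extremes for modes 5-7 and only +3 SD for the later
modes, which together with the template yields 48 shapes on a 19-mode model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .morphometry import centerlines_from_geometry
from .population import AortaGeometry, RingLayout

__all__ = [
    "PCAModel",
    "AugmentScheme",
    "shape_matrix",
    "fit_pca",
    "generate_shape",
    "explained_variance",
    "augment_dataset",
    "default_augment_scheme",
    "format_sd_label",
    "save_model",
    "load_model",
]

_EIGVAL_TOL = 1e-10  # relative cutoff below which a mode is treated as null


def format_sd_label(mode: int, sd: float) -> str:
    """Canonical single-mode shape label, e.g. ``m0_sd-2`` or ``m12_sd+3``."""
    return f"m{mode}_sd{sd:+g}"


def shape_matrix(geometries: Sequence[AortaGeometry]) -> tuple[np.ndarray, list[str]]:
    """Stack geometries into an (n_subjects, 3*n_points) matrix + labels."""
    if len(geometries) < 2:
        raise ValueError("a shape matrix needs at least 2 subjects")
    n = geometries[0].n_points
    rows, labels = [], []
    for g in geometries:
        if g.n_points != n:
            raise ValueError(
                f"subject '{g.label}' has {g.n_points} points, expected {n}: "
                "population is not corresponded"
            )
        rows.append(g.points.reshape(-1))
        labels.append(g.label)
    return np.vstack(rows), labels


@dataclass(frozen=True)
class PCAModel:
    """Fitted shape model: mean, ordered eigenvalues (mm^2), unit modes."""

    mean_shape: np.ndarray  # (3*n_points,)
    eigenvalues: np.ndarray  # (n_modes,), non-increasing, >= 0
    modes: np.ndarray  # (n_modes, 3*n_points), orthonormal rows
    scores: np.ndarray  # (n_subjects, n_modes), training-shape projections
    labels: list[str]
    layout: RingLayout | None = None  # ring layout of the population, if known

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if np.any(ev < -1e-12) or np.any(np.diff(ev) > 1e-9 * max(ev[0], 1.0)):
            raise ValueError("eigenvalues must be non-negative and non-increasing")

    @property
    def n_modes(self) -> int:
        return int(self.eigenvalues.shape[0])

    @property
    def n_subjects(self) -> int:
        return int(self.scores.shape[0])

    def sd_scores(self, subject: int) -> np.ndarray:
        """Training-shape scores in SD units (zero where a mode is null)."""
        lam = self.eigenvalues
        out = np.zeros_like(lam)
        nz = lam > _EIGVAL_TOL * max(lam[0], 1.0)
        out[nz] = self.scores[subject, nz] / np.sqrt(lam[nz])
        return out


def fit_pca(
    shapes: np.ndarray | Sequence[AortaGeometry],
    labels: Sequence[str] | None = None,
    n_modes: int | None = None,
    layout: RingLayout | None = None,
) -> PCAModel:
    """Fit the shape model on corresponded shapes.

    Parameters
    ----------
    shapes
        Either a prebuilt (n_subjects, 3*n_points) matrix or a list of
        corresponded :class:`AortaGeometry`.
    n_modes
        Number of modes to retain. Default ``None`` keeps ``n_subjects - 1``
        (a centered PCA has at most that many non-trivial components); pass
        ``n_subjects`` to also keep the null last component when a
        fixed-size mode book is wanted.

    Mode signs are fixed so each mode's largest-magnitude loading is
    positive, removing the SVD sign ambiguity from generated-shape labels.
    """
    if not isinstance(shapes, np.ndarray):
        geometries = list(shapes)
        if layout is None and geometries:
            layout = geometries[0].layout
        shapes, inferred = shape_matrix(geometries)
        if labels is None:
            labels = inferred
    X = np.asarray(shapes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("shape matrix must be 2D with >= 2 rows")
    n = X.shape[0]
    if labels is None:
        labels = [f"subject_{i:02d}" for i in range(n)]
    if len(labels) != n:
        raise ValueError("labels length does not match the number of shapes")
    if n_modes is None:
        n_modes = n - 1
    if not (1 <= n_modes <= n):
        raise ValueError(f"n_modes must lie in [1, {n}]")

    mean = X.mean(axis=0)
    Xc = X - mean
    _, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = S**2 / (n - 1)
    modes = Vt
    # sign convention: largest-magnitude loading positive
    for i in range(modes.shape[0]):
        j = int(np.argmax(np.abs(modes[i])))
        if modes[i, j] < 0:
            modes[i] = -modes[i]
    modes = modes[:n_modes]
    eigenvalues = eigenvalues[:n_modes]
    scores = Xc @ modes.T
    return PCAModel(mean_shape=mean, eigenvalues=eigenvalues, modes=modes,
                    scores=scores, labels=list(labels), layout=layout)


def _to_geometry(model: PCAModel, flat: np.ndarray, label: str) -> AortaGeometry:
    points = flat.reshape(-1, 3)
    if model.layout is None:
        raise ValueError("model carries no ring layout; cannot rebuild a geometry")
    layout = model.layout
    landmarks = tuple(layout.ostia_rings[n] * layout.n_samples
                      for n in ("BCA", "LCCA", "LSA"))
    # ground-truth centerlines propagate by the ring-centroid rule
    class _Raw:
        pass

    raw = _Raw()
    raw.points = points
    raw.layout = layout
    tree = centerlines_from_geometry(raw)
    return AortaGeometry(label=label, points=points, layout=layout,
                         centerline_tree=tree, ostia_landmarks=landmarks, params=None)


def generate_shape(
    model: PCAModel, sd: Sequence[float], label: str | None = None
) -> AortaGeometry:
    """Synthesize a shape at the given per-mode SD multipliers.

    ``sd`` may be shorter than ``n_modes``; trailing modes are left at zero.
    The label defaults to the canonical encoding of the nonzero entries
    (``template`` when all are zero).
    """
    sd = np.asarray(sd, dtype=float)
    if sd.ndim != 1 or sd.shape[0] > model.n_modes:
        raise ValueError(f"sd vector length {sd.shape} exceeds n_modes={model.n_modes}")
    c = np.zeros(model.n_modes)
    c[: sd.shape[0]] = sd
    flat = model.mean_shape + (c * np.sqrt(model.eigenvalues)) @ model.modes
    if label is None:
        nz = np.nonzero(c)[0]
        label = "template" if nz.size == 0 else "_".join(
            format_sd_label(int(i), float(c[i])) for i in nz
        )
    return _to_geometry(model, flat, label)


def explained_variance(model: PCAModel, k: int) -> float:
    """Fraction of total variance carried by the first k modes."""
    if not (1 <= k <= model.n_modes):
        raise ValueError(f"k must lie in [1, {model.n_modes}]")
    total = float(np.sum(model.eigenvalues))
    if total == 0.0:
        raise ValueError("model has zero total variance")
    return float(np.sum(model.eigenvalues[:k]) / total)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

AugmentScheme = Mapping[int, Sequence[float]]


def default_augment_scheme(n_modes: int = 19) -> dict[int, tuple[float, ...]]:
    """Unit-step sweeps for early modes, extremes only for the later ones.

    modes 0-4 -> {-3,-2,-1,+1,+2,+3}; modes 5-7 -> {-3,+3}; modes 8+ -> {+3}.
    On 19 modes this yields 47 novel shapes (48 with the template).
    """
    scheme: dict[int, tuple[float, ...]] = {}
    for m in range(min(5, n_modes)):
        scheme[m] = (-3.0, -2.0, -1.0, 1.0, 2.0, 3.0)
    for m in range(5, min(8, n_modes)):
        scheme[m] = (-3.0, 3.0)
    for m in range(8, n_modes):
        scheme[m] = (3.0,)
    return scheme


def _validate_scheme(scheme: AugmentScheme, n_modes: int) -> None:
    for m, mults in scheme.items():
        if not (0 <= int(m) < n_modes):
            raise ValueError(f"scheme mode {m} outside the model's {n_modes} modes")
        if any(v == 0 for v in mults):
            raise ValueError(f"scheme mode {m} contains a zero SD multiplier")
        if len(set(mults)) != len(tuple(mults)):
            raise ValueError(f"scheme mode {m} contains duplicate SD multipliers")


def augment_dataset(
    model: PCAModel, scheme: AugmentScheme | None = None
) -> list[AortaGeometry]:
    """Single-mode SD sweep augmentation: template + one shape per
    (mode, multiplier) pair, in (mode, multiplier) order."""
    if model.n_modes == 0:
        raise ValueError("empty model")
    if scheme is None:
        scheme = default_augment_scheme(model.n_modes)
    _validate_scheme(scheme, model.n_modes)
    out = [generate_shape(model, np.zeros(model.n_modes), label="template")]
    for m in sorted(scheme):
        for mult in scheme[m]:
            c = np.zeros(model.n_modes)
            c[m] = mult
            out.append(generate_shape(model, c))
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_model(model: PCAModel, path: str | Path) -> Path:
    """Persist the model as <path>/model.json + <path>/arrays.npz."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "n_modes": model.n_modes,
        "n_subjects": model.n_subjects,
        "labels": model.labels,
        "layout": None if model.layout is None else model.layout.to_dict(),
    }
    (path / "model.json").write_text(json.dumps(meta, indent=2))
    np.savez(path / "arrays.npz", mean_shape=model.mean_shape,
             eigenvalues=model.eigenvalues, modes=model.modes, scores=model.scores)
    return path


def load_model(path: str | Path) -> PCAModel:
    path = Path(path)
    meta = json.loads((path / "model.json").read_text())
    arrays = np.load(path / "arrays.npz")
    layout = None if meta["layout"] is None else RingLayout.from_dict(meta["layout"])
    return PCAModel(mean_shape=arrays["mean_shape"], eigenvalues=arrays["eigenvalues"],
                    modes=arrays["modes"], scores=arrays["scores"],
                    labels=list(meta["labels"]), layout=layout)
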