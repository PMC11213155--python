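"""Per-subject morphological similarity networks (MSN).

An MSN is a 68x68 symmetric matrix whose entry (i, j) is the
Jensen-Shannon similarity estimate (JSSE) between the cortical-thickness
distributions of Desikan-Killiany regions i and j.  Nodes are regions;
edge weights quantify how alike two regions' thickness histograms are.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .atlas import DK_ROI_LABELS, N_ROIS, validate_roi_labels
from .divergence import DiscretePDF, GridSpec, estimate_pdf

__all__ = ["SubjectThickness", "MSNMatrix", "build_msn", "MSNTransformer"]


@dataclass
class SubjectThickness:
    """Vertex-wise cortical thickness values grouped by atlas region."""

    subject_id: str
    roi_values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        order = validate_roi_labels(self.roi_values.keys())
        values = {}
        for roi in order:
            v = np.asarray(self.roi_values[roi], dtype=float).ravel()
            if v.size == 0:
                raise ValueError(f"ROI {roi!r} has an empty thickness vector")
            if np.any(v <= 0):
                raise ValueError(f"ROI {roi!r} contains non-positive thickness values")
            values[roi] = v
        # store in canonical atlas order
        self.roi_values = values


@dataclass
class MSNMatrix:
    """68x68 symmetric JSSE similarity matrix for one subject."""

    subject_id: str
    values: np.ndarray = field(repr=False)
    roi_order: tuple[str, ...] = DK_ROI_LABELS

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.roi_order)
        if v.shape != (n, n):
            raise ValueError(f"expected a {n}x{n} matrix, got {v.shape}")
        if np.max(np.abs(v - v.T)) > 1e-12:
            raise ValueError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        off = v[~np.eye(n, dtype=bool)]
        if off.size and (off.min() < 0 or off.max() > 1):
            raise ValueError("off-diagonal similarities must lie in [0, 1]")
        self.values = v


def _pairwise_js(mass: np.ndarray) -> np.ndarray:
    """All-pairs base-2 Jensen-Shannon divergence between rows of *mass*.

    Vectorised equivalent of looping :func:`msnpipe.divergence.js_divergence`
    over row pairs (the loop form is kept as a test oracle).
    """
    p = mass[:, None, :]  # (n, 1, g)
    q = mass[None, :, :]  # (1, n, g)
    m = 0.5 * (p + q)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = p * np.log2(p / m)
    t = np.where(p > 0, t, 0.0)
    s = t.sum(axis=2)
    js = 0.5 * (s + s.T)  # adds KLD(Q||M): s transposed swaps the pair roles
    return np.clip(js, 0.0, 1.0)


def build_msn(subject: SubjectThickness, grid: GridSpec | None = None,
              bw_method: str | float = "silverman") -> MSNMatrix:
    """Build the morphological similarity network for one subject.

    Estimates one thickness PDF per region on the shared grid, scores all
    68*67/2 unordered region pairs with the JSSE, and returns the
    symmetric matrix with the (uninformative) self-similarity diagonal
    fixed to 1.
    """
    grid = grid or GridSpec()
    mass = np.empty((N_ROIS, grid.n_points))
    for i, roi in enumerate(DK_ROI_LABELS):
        mass[i] = estimate_pdf(subject.roi_values[roi], grid, bw_method).mass
    sim = 1.0 - _pairwise_js(mass)
    np.fill_diagonal(sim, 1.0)
    return MSNMatrix(subject.subject_id, sim)


class MSNTransformer(TransformerMixin, BaseEstimator):
    """Transform per-subject thickness samples into MSN matrices.

    A stateless scikit-learn transformer: ``transform`` maps a sequence of
    :class:`SubjectThickness` to an array of shape ``(n_subjects, 68, 68)``.

    Parameters
    ----------
    grid_lower, grid_upper : float
        Thickness grid bounds in mm.
    grid_points : int
        Number of grid points shared by all PDFs.
    bw_method : str or float
        KDE bandwidth rule (default Silverman's rule of thumb).
    """

    def __init__(self, grid_lower: float = 0.0, grid_upper: float = 6.0,
                 grid_points: int = 256, bw_method: str | float = "silverman"):
        self.grid_lower = grid_lower
        self.grid_upper = grid_upper
        self.grid_points = grid_points
        self.bw_method = bw_method

    def _grid(self) -> GridSpec:
        return GridSpec(self.grid_lower, self.grid_upper, self.grid_points)

    def fit(self, X: Sequence[SubjectThickness], y=None) -> "MSNTransformer":
        self._grid()  # validates parameters
        self.roi_order_ = DK_ROI_LABELS
        self.n_features_in_ = N_ROIS
        return self

    def transform(self, X: Sequence[SubjectThickness]) -> np.ndarray:
        grid = self._grid()
        return np.stack([build_msn(s, grid, self.bw_method).values for s in X])

    def transform_to_matrices(self, X: Sequence[SubjectThickness]) -> list[MSNMatrix]:
        """Like :meth:`transform` but keeps subject ids and labels."""
        grid = self._grid()
        return [build_msn(s, grid, self.bw_method) for s in X]
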