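"""Surface waviness and roughness metrology for tidemark heightmaps.

Two areal deviation indices are computed against a least-squares polynomial
reference surface SR(i, j):

    Sa = (1/MN) * sum_ij |s(i,j) - SR(i,j)|        (mean absolute deviation)
    Sq = sqrt((1/MN) * sum_ij (s(i,j) - SR(i,j))^2) (RMS deviation)

With a first-order reference (a tilted plane, absorbing specimen tilt) the
indices measure *waviness* (SWa, SWq) — the macroscopic undulation of the
interface.  With a fifth-order polynomial reference (which follows and
removes the waviness) they measure *roughness* (SRa, SRq) — the microscopic
texture.  Sa ≤ Sq always (power-mean inequality), and the order-5 residual
RMS can never exceed the order-1 residual RMS because its basis is a
superset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .geometry import SurfaceGrid

__all__ = [
    "ReferenceSurfaceFit",
    "SmoothnessPanel",
    "fit_reference_surface",
    "sa_index",
    "sq_index",
    "smoothness_panel",
    "pearson_report",
]


def _n_terms(order: int) -> int:
    return (order + 1) * (order + 2) // 2


def _design_matrix(x: np.ndarray, y: np.ndarray, order: int) -> np.ndarray:
    """All monomials x^a * y^b with a + b <= order, column-stacked.

    order 1 gives {1, x, y} (a tilted plane, the "poly11"-style fit);
    order 5 gives the 21 monomials of total degree <= 5 ("poly55"-style).
    """
    cols = [x**a * y**b for total in range(order + 1) for a in range(total + 1) for b in [total - a]]
    return np.column_stack(cols)


@dataclass
class ReferenceSurfaceFit:
    """Least-squares polynomial reference surface on a heightmap grid."""

    order: int
    coefficients: np.ndarray
    fitted: np.ndarray  # SR(i, j) on the input grid, µm

    @property
    def n_terms(self) -> int:
        return _n_terms(self.order)


def fit_reference_surface(s: SurfaceGrid, order: int, exclude_invalid: bool = False) -> ReferenceSurfaceFit:
    """Fit the order-1 or order-5 polynomial reference surface.

    Lateral coordinates are centred and scaled to [-1, 1] before building
    the Vandermonde matrix, for conditioning; fitted heights are returned on
    the original grid.  By default interpolated (crack/hole) nodes carry the
    same weight as detected ones; ``exclude_invalid`` drops them from the
    fit (the fitted surface still covers the whole grid).  Raises on a
    rank-deficient design (grid too small for the basis).
    """
    if order not in (1, 5):
        raise ValueError("reference surface order must be 1 (waviness) or 5 (roughness)")
    ny, nx = s.heights.shape
    if ny * nx < _n_terms(order):
        raise ValueError(f"grid has too few nodes for an order-{order} fit")
    yc, xc = s.lateral_coords()
    Y, X = np.meshgrid(yc, xc, indexing="ij")

    def scale(v):
        v = v - v.mean()
        m = np.abs(v).max()
        return v / m if m > 0 else v

    A = _design_matrix(scale(X).ravel(), scale(Y).ravel(), order)
    rows = s.valid_mask.ravel() if exclude_invalid else slice(None)
    coeffs, _, rank, _ = np.linalg.lstsq(A[rows], s.heights.ravel()[rows], rcond=None)
    if rank < A.shape[1]:
        raise ValueError(f"rank-deficient design for order-{order} fit (rank {rank} < {A.shape[1]})")
    fitted = (A @ coeffs).reshape(ny, nx)
    return ReferenceSurfaceFit(order=order, coefficients=coeffs, fitted=fitted)


def _deviations(s: SurfaceGrid, ref: ReferenceSurfaceFit) -> np.ndarray:
    if ref.fitted.shape != s.heights.shape:
        raise ValueError("reference fit shape does not match surface grid")
    return s.heights - ref.fitted


def sa_index(s: SurfaceGrid, ref: ReferenceSurfaceFit) -> float:
    """Mean absolute deviation from the reference surface, µm."""
    return float(np.mean(np.abs(_deviations(s, ref))))


def sq_index(s: SurfaceGrid, ref: ReferenceSurfaceFit) -> float:
    """Root-mean-square deviation from the reference surface, µm."""
    return float(np.sqrt(np.mean(_deviations(s, ref) ** 2)))


@dataclass
class SmoothnessPanel:
    """Per-disk smoothness indices, µm: waviness (order-1 reference) and
    roughness (order-5 reference), each as Sa and Sq."""

    swa: float
    swq: float
    sra: float
    srq: float

    def as_dict(self) -> dict[str, float]:
        return {"SWa": self.swa, "SWq": self.swq, "SRa": self.sra, "SRq": self.srq}


def smoothness_panel(s: SurfaceGrid) -> SmoothnessPanel:
    """SWa/SWq against the order-1 reference and SRa/SRq against the
    order-5 reference, for one surface."""
    ref1 = fit_reference_surface(s, 1)
    ref5 = fit_reference_surface(s, 5)
    return SmoothnessPanel(
        swa=sa_index(s, ref1),
        swq=sq_index(s, ref1),
        sra=sa_index(s, ref5),
        srq=sq_index(s, ref5),
    )


def pearson_report(x, y) -> tuple[float, float]:
    """Sample Pearson correlation and its two-sided p-value (Student t with
    n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1D sequences")
    if x.size < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
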