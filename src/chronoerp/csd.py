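"""Spherical-spline current source density (surface Laplacian) transform.

Scalp potentials recorded against any reference are interpolated with a
spherical spline of order ``m`` and the negative surface Laplacian of that
spline is evaluated at the electrode sites, yielding reference-free current
source density in µV/m².  The kernels are Legendre-polynomial series

.. math::

    g(x) = \\frac{1}{4\\pi} \\sum_{n\\ge 1} \\frac{2n+1}{(n(n+1))^m} P_n(x),
    \\qquad
    h(x) = \\frac{1}{4\\pi} \\sum_{n\\ge 1} \\frac{2n+1}{(n(n+1))^{m-1}} P_n(x),

with ``x`` the cosine of the angle between electrode positions.  A ridge
``lambda`` on the diagonal of G regularizes the fit; the constant term is
carried explicitly so the operator annihilates any added constant (reference
invariance).  Output is scaled by ``1 / head_radius**2`` to physical µV/m².

The defaults (m = 4, lambda = 1e-5, 50 Legendre terms, radius 8.75 cm) follow
the standard spherical-spline CSD literature.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from numpy.polynomial.legendre import legval

from .core import Epochs, Montage
from .preprocess import WrongStageError

__all__ = [
    "CsdParameters",
    "build_csd_matrix",
    "apply_csd",
    "identity_spatial_mode",
    "IDENTITY_UNITS_TAG",
]

IDENTITY_UNITS_TAG = "µV/m² (nominal)"


class SingularGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class CsdParameters:
    spline_order_m: int = 4
    regularization_lambda: float = 1e-5
    legendre_terms: int = 50
    head_radius_m: float = 0.0875
    #: output scaling convention: CSD = H @ c / head_radius_m**2 (µV -> µV/m²)
    scaling_note: str = "surface Laplacian scaled by 1/radius^2"

    def __post_init__(self):
        if self.spline_order_m < 2:
            raise ValueError("spline order m must be >= 2")
        if self.regularization_lambda < 0:
            raise ValueError("lambda must be non-negative")
        if self.legendre_terms < 20:
            raise ValueError("need at least 20 Legendre terms")


def _legendre_series(x: np.ndarray, weights: np.ndarray) -> np.ndarray:
    coeffs = np.zeros(weights.size + 1)
    coeffs[1:] = weights  # series starts at n = 1
    return legval(x, coeffs)


def spline_kernels(cosang: np.ndarray, params: CsdParameters) -> tuple:
    """Evaluate the g (interpolation) and h (Laplacian) kernels."""
    n = np.arange(1, params.legendre_terms + 1, dtype=float)
    common = (2 * n + 1) / (4 * np.pi)
    g = _legendre_series(cosang, common / (n * (n + 1)) ** params.spline_order_m)
    h = _legendre_series(cosang, common / (n * (n + 1)) ** (params.spline_order_m - 1))
    return g, h


def build_csd_matrix(montage: Montage, params: CsdParameters | None = None) -> np.ndarray:
    """Assemble the channels x channels CSD operator for a montage.

    The operator maps a potential vector (any reference) to current source
    density; rows sum to ~0, so adding a constant to all channels leaves the
    output unchanged.
    """
    if params is None:
        params = CsdParameters()
    pos = montage.positions
    cosang = np.clip(pos @ pos.T, -1.0, 1.0)
    if np.any(cosang[~np.eye(len(montage), dtype=bool)] > 1 - 1e-12):
        raise SingularGeometryError("duplicate electrode positions")
    G, H = spline_kernels(cosang, params)
    G = G + params.regularization_lambda * np.eye(len(montage))
    Ginv = np.linalg.inv(G)
    ones = np.ones(len(montage))
    # spline coefficients with explicit constant term:
    #   c = Ginv (v - c0), c0 = 1' Ginv v / 1' Ginv 1
    denom = ones @ Ginv @ ones
    P = Ginv - np.outer(Ginv @ ones, ones @ Ginv) / denom
    return (H @ P) / params.head_radius_m**2


def apply_csd(epochs: Epochs, matrix: np.ndarray) -> Epochs:
    """Apply a CSD operator sample-wise; units become µV/m²."""
    if "m²" in epochs.units_tag:
        raise WrongStageError("epochs are already current source density")
    if not (matrix.shape[0] == matrix.shape[1] == len(epochs.ch_names)):
        raise ValueError("CSD matrix does not match the epoch channel count")
    out = np.einsum("ij,tjs->tis", matrix, np.asarray(epochs.data, dtype=np.float64))
    return replace(epochs, data=out, units_tag="µV/m²")


def identity_spatial_mode(n_channels: int) -> np.ndarray:
    """Identity spatial operator (calibration mode).

    Leaves the data numerically unchanged while relabeling units as
    nominal µV/m², so generative component amplitudes can be recovered
    without spatial mixing.  Apply with :func:`apply_identity`.
    """
    return np.eye(n_channels)


def apply_identity(epochs: Epochs) -> Epochs:
    """Pass epochs through unchanged, tagged as nominal current density."""
    return replace(epochs, data=np.asarray(epochs.data, dtype=np.float64), units_tag=IDENTITY_UNITS_TAG)


def export_matrix(matrix: np.ndarray, montage: Montage) -> str:
    """Plain-text export of a spatial transform keyed to montage labels."""
    header = "\t".join(montage.labels)
    lines = [header]
    for lab, row in zip(montage.labels, matrix):
        lines.append(lab + "\t" + "\t".join(f"{v:.10e}" for v in row))
    return "\n".join(lines) + "\n"


def import_matrix(text: str, montage: Montage) -> np.ndarray:
    lines = [ln for ln in text.strip().splitlines() if ln.strip()]
    cols = lines[0].split("\t")
    if tuple(cols) != montage.labels:
        raise ValueError("matrix labels do not match the montage")
    rows = []
    for ln in lines[1:]:
        parts = ln.split("\t")
        rows.append([float(v) for v in parts[1:]])
    return np.asarray(rows)
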