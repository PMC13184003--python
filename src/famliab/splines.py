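"""Natural cubic spline basis for birth-year adjustment.

Construction mirrors R's ``splines::ns``: a cubic B-spline basis on
boundary knots at the data range and interior knots at equally spaced
quantiles, projected onto the subspace with zero second derivative at
(and linear extrapolation beyond) the boundaries, with the constant
column dropped.  ``df`` columns are returned; together with an intercept
the span contains all linear functions of x.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

__all__ = ["SplineBasis", "natural_cubic_spline_basis"]


@dataclass
class SplineBasis:
    basis: np.ndarray  # (n, df)
    interior_knots: np.ndarray
    boundary_knots: tuple
    _transform: np.ndarray = None  # (n_bspline, df) projection, for re-evaluation

    @property
    def df(self) -> int:
        return self.basis.shape[1]

    def evaluate(self, x) -> np.ndarray:
        """Evaluate the same basis at new points (linear beyond boundaries)."""
        return _evaluate(
            np.asarray(x, dtype=float),
            self.interior_knots,
            self.boundary_knots,
            self._transform,
        )


def _bspline_design(x, t, extrapolate_linear=True):
    """Cubic B-spline design matrix with first-order Taylor extension outside."""
    k = 3
    n_basis = len(t) - k - 1
    lo, hi = t[k], t[-k - 1]
    xc = np.clip(x, lo, hi)
    design = BSpline.design_matrix(xc, t, k).toarray()
    if extrapolate_linear:
        out_lo = x < lo
        out_hi = x > hi
        if out_lo.any() or out_hi.any():
            eye = np.eye(n_basis)
            for mask, b in ((out_lo, lo), (out_hi, hi)):
                if not mask.any():
                    continue
                val = BSpline.design_matrix(np.array([b]), t, k).toarray()[0]
                der = np.array(
                    [BSpline(t, eye[j], k).derivative()(b) for j in range(n_basis)]
                )
                design[mask] = val[None, :] + (x[mask] - b)[:, None] * der[None, :]
    return design


def _natural_transform(t, n_basis):
    """Null-space projection enforcing zero second derivative at both boundaries."""
    k = 3
    lo, hi = t[k], t[-k - 1]
    eye = np.eye(n_basis)
    d2 = np.array(
        [
            [BSpline(t, eye[j], k).derivative(2)(b) for j in range(n_basis)]
            for b in (lo, hi)
        ]
    )  # (2, n_basis)
    q, _ = np.linalg.qr(d2.T, mode="complete")
    return q[:, 2:]  # (n_basis, n_basis - 2)


def _evaluate(x, interior, boundary, transform):
    lo, hi = boundary
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    design = _bspline_design(x, t)
    full = design @ transform
    return full[:, 1:]  # drop the constant-spanning first column


def natural_cubic_spline_basis(x, df: int = 5) -> SplineBasis:
    """Natural cubic spline basis of ``x`` with ``df`` columns.

    Boundary knots at min/max of ``x``; ``df - 1`` interior knots at
    equally spaced quantiles.  Raises if ``x`` has fewer than ``df + 1``
    distinct values.
    """
    x = np.asarray(x, dtype=float)
    uniq = np.unique(x)
    if len(uniq) < df + 1:
        raise ValueError(
            f"need at least {df + 1} distinct values for df={df}, got {len(uniq)}"
        )
    lo, hi = float(uniq[0]), float(uniq[-1])
    probs = np.linspace(0, 1, df + 1)[1:-1]
    interior = np.quantile(x, probs)
    t = np.concatenate([[lo] * 4, interior, [hi] * 4])
    n_basis = len(t) - 4
    transform = _natural_transform(t, n_basis)
    basis = _evaluate(x, interior, (lo, hi), transform)
    return SplineBasis(
        basis=basis,
        interior_knots=interior,
        boundary_knots=(lo, hi),
        _transform=transform,
    )
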