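"""Penalized natural cubic regression spline smoother.

This is the nonlinear workhorse of the trend chain: a cubic regression
spline parameterized by its values at ``n_basis`` knots placed at quantiles
of the observed abscissa (the 'cr' basis of the GAM literature), penalized
by the integrated squared second derivative and with the smoothing parameter
chosen by generalized cross-validation (GCV).  Linear functions lie in the
null space of the penalty, so a noiseless straight line is reproduced
exactly at any smoothing level.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.linalg import cho_factor, cho_solve


def _gs_matrices(knots: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Green & Silverman band matrices for the natural-spline curvature.

    For knots t_1 < ... < t_k returns D ((k-2) x k) and B ((k-2) x (k-2))
    such that the second derivatives at the interior knots of the natural
    interpolating spline with knot values f are gamma = B^-1 D f, and the
    integrated squared second derivative is f' D' B^-1 D f.
    """
    h = np.diff(knots)
    k = len(knots)
    D = np.zeros((k - 2, k))
    B = np.zeros((k - 2, k - 2))
    for i in range(k - 2):
        D[i, i] = 1.0 / h[i]
        D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        D[i, i + 2] = 1.0 / h[i + 1]
        B[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < k - 2:
            B[i, i + 1] = h[i + 1] / 6.0
            B[i + 1, i] = h[i + 1] / 6.0
    return D, B


class NaturalCubicSmoother:
    """Penalized cubic regression spline with GCV-selected smoothing.

    Parameters
    ----------
    n_basis : int
        Basis dimension (number of knots); must be >= 3 and <= number of
        distinct abscissa values.
    lambdas : array-like, optional
        Candidate smoothing parameters (on the scale of the normalized
        penalty). Defaults to a wide logarithmic grid.

    Attributes
    ----------
    knots_ : ndarray of knot locations
    coef_ : ndarray of fitted values at the knots
    lambda_ : selected smoothing parameter (raw scale)
    edf_ : effective degrees of freedom of the selected fit
    gcv_ : GCV score of the selected fit
    """

    def __init__(self, n_basis: int, lambdas=None):
        if n_basis < 3:
            raise ValueError("n_basis must be at least 3")
        self.n_basis = int(n_basis)
        self.lambdas = lambdas

    def _design(self, x: np.ndarray) -> np.ndarray:
        # Column j is the natural cubic spline interpolating the j-th unit
        # vector at the knots, evaluated at x.
        basis = CubicSpline(self.knots_, np.eye(len(self.knots_)), axis=0, bc_type="natural")
        return basis(x)

    def fit(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.ndim != 1 or x.shape != y.shape:
            raise ValueError("x and y must be equal-length 1-D arrays")
        n = len(x)
        if self.n_basis > len(np.unique(x)):
            raise ValueError("n_basis exceeds the number of distinct x values")

        self.knots_ = np.quantile(np.unique(x), np.linspace(0.0, 1.0, self.n_basis))
        N = self._design(x)
        D, B = _gs_matrices(self.knots_)
        # Penalty K = D' B^-1 D; B is SPD and tiny, solve directly.
        K = D.T @ np.linalg.solve(B, D)
        self._penalty = K

        G = N.T @ N
        Nty = N.T @ y
        scale = np.trace(G) / max(np.trace(K), np.finfo(float).tiny)
        lam_grid = np.asarray(
            self.lambdas if self.lambdas is not None else np.logspace(-7.0, 9.0, 33)
        )

        best = None
        for lam_rel in lam_grid:
            lam = lam_rel * scale
            M = G + lam * K
            try:
                c, low = cho_factor(M)
            except np.linalg.LinAlgError:  # pragma: no cover - degenerate grid point
                continue
            f = cho_solve((c, low), Nty)
            edf = float(np.trace(cho_solve((c, low), G)))
            resid = y - N @ f
            rss = float(resid @ resid)
            denom = n - edf
            gcv = np.inf if denom <= 1e-8 else n * rss / denom**2
            if best is None or gcv < best[0] - 1e-15:
                best = (gcv, lam, f, edf)
        if best is None:
            raise np.linalg.LinAlgError("penalized spline fit failed on every grid point")

        self.gcv_, self.lambda_, self.coef_, self.edf_ = best
        self._spline = CubicSpline(self.knots_, self.coef_, bc_type="natural")
        self.fitted_ = self._spline(x)
        return self

    def predict(self, x) -> np.ndarray:
        return self._spline(np.asarray(x, dtype=float))

    def curvature_penalty(self, f=None) -> float:
        """Integrated squared second derivative of the spline with knot
        values ``f`` (defaults to the fitted coefficients)."""
        f = self.coef_ if f is None else np.asarray(f, dtype=float)
        return float(f @ self._penalty @ f)
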