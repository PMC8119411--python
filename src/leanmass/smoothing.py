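"""Penalized cubic regression spline basis in mixed-model form.

A cubic B-spline basis with a second-order difference penalty is
reparameterised so it can be fitted as part of a linear mixed model:

* a sum-to-zero constraint removes confounding with the intercept;
* the penalty's eigen-decomposition splits the constrained basis into an
  unpenalized null-space column (the linear trend, kept as a fixed
  effect) and penalized "wiggle" columns whose coefficients act as i.i.d.
  random effects — the smoothing parameter is then a variance ratio that
  REML estimates for free.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import BSpline

from .errors import ValidationError

__all__ = ["CubicSmooth"]


@dataclasses.dataclass
class CubicSmooth:
    """Frozen smooth-term design built from training covariate values."""

    knots: np.ndarray
    x_min: float
    x_max: float
    null_transform: np.ndarray  # k x 1: basis coefs of the unpenalized (linear) direction
    wiggle_transform: np.ndarray  # k x (k-2): basis coefs of penalized directions
    basis_dim: int

    @classmethod
    def from_data(cls, x: np.ndarray, basis_dim: int = 10) -> "CubicSmooth":
        if basis_dim < 4:
            raise ValidationError("smooth basis dimension must be >= 4 for a cubic basis")
        x = np.asarray(x, dtype=float)
        x_min, x_max = float(x.min()), float(x.max())
        if x_max <= x_min:
            raise ValidationError("smooth covariate is constant; no basis can be built")
        # Clamped knot vector, evenly spaced interior knots.
        interior = np.linspace(x_min, x_max, basis_dim - 2)[1:-1]
        knots = np.concatenate([[x_min] * 4, interior, [x_max] * 4])

        B = BSpline.design_matrix(x, knots, 3).toarray()
        # Second-order difference penalty on the basis coefficients.
        D = np.diff(np.eye(basis_dim), n=2, axis=0)
        S = D.T @ D

        # Sum-to-zero constraint: work in the null space of colsum(B).
        csum = B.sum(axis=0)[None, :]
        q, _ = np.linalg.qr(csum.T, mode="complete")
        Zc = q[:, 1:]  # k x (k-1)
        S_c = Zc.T @ S @ Zc

        eigval, eigvec = np.linalg.eigh(S_c)
        # One ~zero eigenvalue remains (the linear direction).
        null_mask = eigval < eigval.max() * 1e-10
        if null_mask.sum() != 1:
            raise ValidationError("unexpected penalty null space; check basis dimension")
        U0 = eigvec[:, null_mask]
        Up = eigvec[:, ~null_mask]
        lam = eigval[~null_mask]

        null_transform = Zc @ U0
        wiggle_transform = Zc @ (Up / np.sqrt(lam)[None, :])

        smooth = cls(
            knots=knots,
            x_min=x_min,
            x_max=x_max,
            null_transform=null_transform,
            wiggle_transform=wiggle_transform,
            basis_dim=basis_dim,
        )
        # Normalise sign/scale of the null column so it is increasing in x
        # with unit slope — makes its coefficient interpretable and stable.
        lin = smooth._raw(np.array([x_min, x_max])) @ null_transform
        slope = float(lin[1, 0] - lin[0, 0]) / (x_max - x_min)
        smooth.null_transform = null_transform / slope
        return smooth

    def _raw(self, x: np.ndarray) -> np.ndarray:
        x = np.clip(np.asarray(x, dtype=float), self.x_min, self.x_max)
        return BSpline.design_matrix(x, self.knots, 3, extrapolate=False).toarray()

    def design(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(null_column, wiggle_columns)`` evaluated at ``x``.

        Values outside the training range are clamped to its ends.
        """
        B = self._raw(x)
        return B @ self.null_transform, B @ self.wiggle_transform

    @property
    def n_wiggle(self) -> int:
        return self.wiggle_transform.shape[1]
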