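"""Spline bases and penalties for the penalized Gamma GAM.

Three smoother constructions, each exposing a raw (unconstrained) model
matrix plus one or more quadratic roughness penalties:

* :class:`CubicRegressionSpline` — cardinal natural cubic spline on
  quantile-placed knots, with the exact integrated-squared-second-derivative
  penalty (banded D/B construction).
* :class:`ThinPlateSpline` — 1-D low-rank thin plate regression spline via
  the eigen-approximation of the radial kernel |r|^3, null space {1, x}.
* :class:`TensorProduct` — row-wise tensor product of two marginal cubic
  regression splines with one marginal penalty per direction.
* :class:`RandomIntercept` — grouped indicator block with a ridge penalty,
  the usual random-effect-as-smooth representation.

Identifiability (sum-to-zero over the observed data) is absorbed by
reparametrizing each smooth block with the null space of its column-sum
constraint; the same linear map is stored and applied at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "CubicRegressionSpline",
    "ThinPlateSpline",
    "TensorProduct",
    "RandomIntercept",
    "sum_to_zero_nullspace",
    "penalty_nullspace_projector",
]


def sum_to_zero_nullspace(X: np.ndarray) -> np.ndarray:
    """Null-space basis Z of the constraint 1'X b = 0.

    Returns Z with shape (p, p-1) such that the reparametrized matrix X @ Z
    spans the subspace of fitted term values summing to zero over the data.
    """
    c = X.sum(axis=0, keepdims=True)
    # orthonormal null space via SVD of the 1 x p constraint row
    _, _, vt = np.linalg.svd(c, full_matrices=True)
    return vt[1:].T


def penalty_nullspace_projector(S: np.ndarray, rtol: float = 1e-7) -> np.ndarray | None:
    """Projector onto the (numerical) null space of a PSD penalty matrix.

    Used for the double-penalty shrinkage approach: the perfectly smooth
    component a roughness penalty cannot see gets its own ridge penalty so
    whole terms can shrink out of the model.  Returns None when the penalty
    is already full rank.
    """
    vals, vecs = np.linalg.eigh(S)
    tol = rtol * max(vals.max(), 1e-300)
    null = vecs[:, vals < tol]
    if null.shape[1] == 0:
        return None
    return null @ null.T


def _quantile_knots(x: np.ndarray, k: int) -> np.ndarray:
    ux = np.unique(x)
    if ux.size < k:
        raise ValueError(
            f"basis size {k} exceeds the {ux.size} distinct covariate values; "
            "use a smaller basis"
        )
    knots = np.quantile(ux, np.linspace(0.0, 1.0, k))
    # quantiles of ux are strictly increasing only if ux well spread; enforce
    if np.any(np.diff(knots) <= 0):
        idx = np.linspace(0, ux.size - 1, k).round().astype(int)
        knots = ux[idx]
    return knots


class CubicRegressionSpline:
    """Cardinal natural cubic regression spline on ``k`` knots.

    Coefficients are the function values at the knots; second derivatives
    at the knots follow from the natural-spline conditions via banded
    matrices B and D, giving the exact curvature penalty S = D' B^-1 D.
    """

    null_space_dimension = 2  # constants and linears are unpenalized

    def __init__(self, x: np.ndarray, k: int):
        x = np.asarray(x, dtype=float)
        self.knots = _quantile_knots(x, k)
        h = np.diff(self.knots)
        km2 = k - 2
        D = np.zeros((km2, k))
        B = np.zeros((km2, km2))
        for i in range(km2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            B[i, i] = (h[i] + h[i + 1]) / 3.0
            if i + 1 < km2:
                B[i, i + 1] = B[i + 1, i] = h[i + 1] / 6.0
        self._h = h
        binv_d = np.linalg.solve(B, D)
        # F maps knot values to knot second derivatives (natural: ends zero)
        self.F = np.vstack([np.zeros(k), binv_d, np.zeros(k)])
        self.S = D.T @ binv_d
        self.k = k

    def matrix(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        kn, h, F = self.knots, self._h, self.F
        j = np.clip(np.searchsorted(kn, x, side="right") - 1, 0, self.k - 2)
        xl, xr, hj = kn[j], kn[j + 1], h[j]
        am = (xr - x) / hj
        ap = (x - xl) / hj
        cm = ((xr - x) ** 3 / hj - hj * (xr - x)) / 6.0
        cp = ((x - xl) ** 3 / hj - hj * (x - xl)) / 6.0
        X = np.zeros((x.size, self.k))
        rows = np.arange(x.size)
        X[rows, j] += am
        X[rows, j + 1] += ap
        X += cm[:, None] * F[j] + cp[:, None] * F[j + 1]
        return X

    def penalties(self) -> list[np.ndarray]:
        return [self.S]


class ThinPlateSpline:
    """Low-rank 1-D thin plate regression spline (radial kernel |r|^3).

    The full-rank smoother over the unique covariate values is truncated to
    its ``k`` leading eigenvectors; coefficients are constrained so the
    radial part is orthogonal to the polynomial null space {1, x}, which is
    carried as two explicit columns (last two of the raw matrix).  The
    covariate is internally rescaled to [0, 1] so fits are invariant to
    affine changes of units.
    """

    null_space_dimension = 2

    def __init__(self, x: np.ndarray, k: int):
        x = np.asarray(x, dtype=float)
        self.x_min = float(x.min())
        self.x_rng = float(x.max() - x.min())
        if self.x_rng <= 0:
            raise ValueError("covariate is constant; cannot build a smooth")
        u = np.unique(self._scale(x))
        if u.size < k:
            raise ValueError(
                f"basis size {k} exceeds the {u.size} distinct covariate values; "
                "use a smaller basis"
            )
        self.centers = u
        E = self._kernel(u[:, None] - u[None, :])
        T = np.column_stack([np.ones_like(u), u])
        vals, vecs = np.linalg.eigh(E)
        order = np.argsort(np.abs(vals))[::-1][: k - 2 + 2]  # keep k of them
        Uk = vecs[:, order]
        lam = vals[order]
        C = T.T @ Uk  # 2 x k constraint on radial coefficients
        _, _, vt = np.linalg.svd(C, full_matrices=True)
        Z = vt[2:].T  # k x (k-2)
        self._UZ = Uk @ Z
        self.S_radial = (Z.T * lam) @ Z  # Z' diag(lam) Z
        self.k = k

    @staticmethod
    def _kernel(r: np.ndarray) -> np.ndarray:
        return np.abs(r) ** 3 / 12.0

    def _scale(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.x_min) / self.x_rng

    def matrix(self, x: np.ndarray) -> np.ndarray:
        u = self._scale(x)
        E = self._kernel(u[:, None] - self.centers[None, :])
        radial = E @ self._UZ
        return np.column_stack([radial, np.ones_like(u), u])

    def penalties(self) -> list[np.ndarray]:
        S = np.zeros((self.k, self.k))
        S[: self.k - 2, : self.k - 2] = self.S_radial
        return [S]


class TensorProduct:
    """Row-wise tensor product of two marginal cubic regression splines.

    Carries one curvature penalty per margin (S1 (x) I and I (x) S2), so the
    wiggliness in each direction gets its own smoothing parameter.
    """

    def __init__(self, x1: np.ndarray, x2: np.ndarray, k1: int = 4, k2: int = 4):
        self.m1 = CubicRegressionSpline(np.asarray(x1, float), k1)
        self.m2 = CubicRegressionSpline(np.asarray(x2, float), k2)
        self.k = k1 * k2

    def matrix(self, x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
        X1 = self.m1.matrix(np.asarray(x1, float))
        X2 = self.m2.matrix(np.asarray(x2, float))
        return (X1[:, :, None] * X2[:, None, :]).reshape(X1.shape[0], -1)

    def penalties(self) -> list[np.ndarray]:
        S1, S2 = self.m1.S, self.m2.S
        i1 = np.eye(self.m1.k)
        i2 = np.eye(self.m2.k)
        return [np.kron(S1, i2), np.kron(i1, S2)]


@dataclass
class RandomIntercept:
    """One indicator column per group with an identity (ridge) penalty."""

    levels: tuple[str, ...]

    @classmethod
    def from_values(cls, values) -> "RandomIntercept":
        return cls(levels=tuple(dict.fromkeys(str(v) for v in values)))

    @property
    def k(self) -> int:
        return len(self.levels)

    def matrix(self, values) -> np.ndarray:
        index = {lv: i for i, lv in enumerate(self.levels)}
        X = np.zeros((len(values), self.k))
        for row, v in enumerate(values):
            j = index.get(str(v))
            if j is not None:  # unseen levels predict at the population mean
                X[row, j] = 1.0
        return X

    def penalties(self) -> list[np.ndarray]:
        return [np.eye(self.k)]
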