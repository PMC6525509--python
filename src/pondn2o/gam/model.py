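"""Model structure for the N2O driver GAM.

The default specification mirrors the survey analysis: a Gamma response
with log link, univariate thin plate smooths (9 basis functions after the
identifiability constraint) of surface and deep dissolved-oxygen
saturation, sediment C:N, log chlorophyll-a, surface pH and log TDN:SRP, a
4x4 cubic-spline tensor product of sqrt(buoyancy frequency) and log(DIN)
capturing the stratification-nitrogen interaction, and a per-reservoir
random intercept.  All terms carry curvature penalties plus (optionally) a
null-space shrinkage penalty so that uninformative terms can be selected
out of the model entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .bases import (
    CubicRegressionSpline,
    RandomIntercept,
    TensorProduct,
    ThinPlateSpline,
    penalty_nullspace_projector,
    sum_to_zero_nullspace,
)

__all__ = [
    "SiteRecord",
    "SmoothTerm",
    "GamSpecification",
    "n2o_gam_specification",
    "transform_covariates",
    "screen_collinearity",
    "build_design",
    "GamDesign",
    "TermBlock",
    "PenaltyBlock",
]


@dataclass(frozen=True)
class SiteRecord:
    """Merged covariates + response for one reservoir (one GAM row)."""

    site_id: str
    n2o_nm: float
    surf_do: float
    deep_do: float
    sed_cn: float
    chla: float
    surf_ph: float
    n_to_p: float
    bf_max: float
    din: float

    def __post_init__(self) -> None:
        if self.n2o_nm <= 0:
            raise ValueError(f"site {self.site_id}: n2o must be > 0 (Gamma support)")
        for name in ("chla", "n_to_p", "din"):
            if getattr(self, name) <= 0:
                raise ValueError(
                    f"site {self.site_id}: {name} must be > 0 (log transform)"
                )
        if self.bf_max < 0:
            raise ValueError(f"site {self.site_id}: bf_max must be >= 0")


#: Raw-variable -> transformed design-column mapping for the survey model.
TRANSFORMS: dict[str, tuple[str, str]] = {
    "surf_do": ("surf_do", "identity"),
    "deep_do": ("deep_do", "identity"),
    "sed_cn": ("sed_cn", "identity"),
    "chla": ("log_chla", "log"),
    "surf_ph": ("surf_ph", "identity"),
    "n_to_p": ("log_np", "log"),
    "din": ("log_din", "log"),
    "bf_max": ("sqrt_bf", "sqrt"),
}


def records_to_frame(records: Sequence[SiteRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records])


def transform_covariates(records: Sequence[SiteRecord] | pd.DataFrame) -> pd.DataFrame:
    """Apply the survey transformations: natural log for chlorophyll-a,
    N:P and DIN; square root for buoyancy frequency; others untouched.

    Non-positive values in a log column raise, naming the site and field.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    out = pd.DataFrame(index=df.index)
    if "site_id" in df.columns:
        out["site_id"] = df["site_id"]
    if "n2o_nm" in df.columns:
        out["n2o_nm"] = df["n2o_nm"].astype(float)
    for raw, (col, kind) in TRANSFORMS.items():
        if raw not in df.columns:
            continue
        vals = df[raw].astype(float)
        if kind == "log":
            bad = vals <= 0
            if bad.any():
                site = (
                    df.loc[bad, "site_id"].iloc[0] if "site_id" in df.columns else "?"
                )
                raise ValueError(
                    f"site {site}: {raw} = {vals[bad].iloc[0]} not log-transformable"
                )
            out[col] = np.log(vals)
        elif kind == "sqrt":
            bad = vals < 0
            if bad.any():
                site = (
                    df.loc[bad, "site_id"].iloc[0] if "site_id" in df.columns else "?"
                )
                raise ValueError(f"site {site}: {raw} negative, not sqrt-transformable")
            out[col] = np.sqrt(vals)
        else:
            out[col] = vals
    return out


DEFAULT_PRIORITY = (
    "surf_do",
    "deep_do",
    "sed_cn",
    "log_chla",
    "surf_ph",
    "log_np",
    "sqrt_bf",
    "log_din",
)


def screen_collinearity(
    table: pd.DataFrame,
    threshold: float = 0.8,
    priority: Sequence[str] = DEFAULT_PRIORITY,
) -> tuple[list[str], pd.DataFrame]:
    """Pairwise Pearson screen of candidate predictors.

    Flags pairs with |r| >= threshold and drops the lower-priority member
    of each flagged pair (priority = order of ``priority``, unknown columns
    last).  Constant columns have undefined correlations; they are flagged
    and dropped.  Returns (retained columns, long-form report of all pairs
    with columns var_a, var_b, r, flagged).
    """
    cols = [c for c in table.columns if c not in ("site_id", "n2o_nm")]
    if len(cols) < 2 or len(table) < 3:
        raise ValueError("need >= 2 covariates and >= 3 rows to screen")
    rank = {c: i for i, c in enumerate(priority)}
    order = sorted(cols, key=lambda c: rank.get(c, len(priority)))
    rows = []
    dropped: set[str] = set()
    for c in cols:
        if table[c].astype(float).std(ddof=0) == 0:
            dropped.add(c)
            rows.append({"var_a": c, "var_b": c, "r": np.nan, "flagged": True})
    for i, a in enumerate(order):
        for b in order[i + 1 :]:
            va, vb = table[a].astype(float), table[b].astype(float)
            if a in dropped or b in dropped:
                r = np.nan
            else:
                r = float(np.corrcoef(va, vb)[0, 1])
            flagged = bool(np.isfinite(r) and abs(r) >= threshold)
            rows.append({"var_a": a, "var_b": b, "r": r, "flagged": flagged})
            if flagged and b not in dropped and a not in dropped:
                dropped.add(b)  # keep the higher-priority member
    retained = [c for c in order if c not in dropped]
    return retained, pd.DataFrame(rows)


@dataclass(frozen=True)
class SmoothTerm:
    """One smooth in the additive predictor."""

    name: str
    covariates: tuple[str, ...]
    kind: Literal["thin_plate", "cubic_regression", "tensor_product", "random_intercept"]
    basis_size: int = 9  # post-constraint dimension for 1-D smooths
    margin_sizes: tuple[int, int] = (4, 4)


@dataclass(frozen=True)
class GamSpecification:
    """Structure of the Gamma(log) additive model."""

    smooths: tuple[SmoothTerm, ...]
    double_penalty: bool = True
    family: str = "gamma"
    link: str = "log"

    def without_double_penalty(self) -> "GamSpecification":
        return replace(self, double_penalty=False)


def n2o_gam_specification(
    basis_size: int = 9,
    tensor_margins: tuple[int, int] = (4, 4),
    random_intercept: bool = True,
    double_penalty: bool = True,
) -> GamSpecification:
    """The survey model: six univariate smooths, one tensor interaction,
    and a per-reservoir random intercept."""
    terms = [
        SmoothTerm(f"s({c})", (c,), "thin_plate", basis_size)
        for c in ("surf_do", "deep_do", "sed_cn", "log_chla", "surf_ph", "log_np")
    ]
    terms.append(
        SmoothTerm(
            "te(sqrt_bf,log_din)",
            ("sqrt_bf", "log_din"),
            "tensor_product",
            margin_sizes=tensor_margins,
        )
    )
    if random_intercept:
        terms.append(SmoothTerm("ri(site_id)", ("site_id",), "random_intercept"))
    return GamSpecification(smooths=tuple(terms), double_penalty=double_penalty)


@dataclass
class PenaltyBlock:
    """A quadratic penalty acting on one term's coefficient block."""

    term: str
    sl: slice
    S: np.ndarray
    kind: Literal["range", "null", "ridge"]


@dataclass
class TermBlock:
    name: str
    sl: slice
    builder: object
    constraint: np.ndarray | None  # Z such that X_term = raw @ Z
    covariates: tuple[str, ...]
    kind: str
    hull: tuple[tuple[float, float], ...] = ()

    def design_matrix(self, table: pd.DataFrame | dict) -> np.ndarray:
        get = (lambda c: np.asarray(table[c])) if not isinstance(table, pd.DataFrame) else (
            lambda c: table[c].to_numpy()
        )
        if self.kind == "random_intercept":
            raw = self.builder.matrix(get(self.covariates[0]))
        elif self.kind == "tensor_product":
            raw = self.builder.matrix(
                np.asarray(get(self.covariates[0]), float),
                np.asarray(get(self.covariates[1]), float),
            )
        else:
            raw = self.builder.matrix(np.asarray(get(self.covariates[0]), float))
        return raw @ self.constraint if self.constraint is not None else raw


@dataclass
class GamDesign:
    """Assembled model matrix, penalties and bookkeeping for fitting."""

    X: np.ndarray
    y: np.ndarray
    terms: list[TermBlock]
    penalties: list[PenaltyBlock]
    spec: GamSpecification
    column_names: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def term(self, name: str) -> TermBlock:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"no term named {name!r}; have {[t.name for t in self.terms]}")


def _normalized(S: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(S, "fro")
    return S / nrm if nrm > 0 else S


def build_design(
    table: pd.DataFrame,
    spec: GamSpecification,
    response: str = "n2o_nm",
) -> GamDesign:
    """Build model matrices and penalty matrices for a transformed table.

    Every smooth block is reparametrized to satisfy the sum-to-zero
    identifiability constraint; with ``spec.double_penalty`` each smooth
    additionally receives a ridge penalty on the null space of its
    curvature penalty (the shrinkage/selection penalty).  Penalties are
    Frobenius-normalized so smoothing parameters are comparable.
    """
    y = table[response].to_numpy(dtype=float)
    if np.any(y <= 0):
        raise ValueError("response must be strictly positive for a Gamma fit")
    cols: list[np.ndarray] = [np.ones((len(table), 1))]
    names = ["intercept"]
    terms: list[TermBlock] = []
    penalties: list[PenaltyBlock] = []
    start = 1
    for term in spec.smooths:
        if term.kind == "random_intercept":
            builder = RandomIntercept.from_values(table[term.covariates[0]])
            raw = builder.matrix(list(table[term.covariates[0]]))
            Z = None
            pens = [("ridge", _normalized(builder.penalties()[0]))]
            hull: tuple[tuple[float, float], ...] = ()
        else:
            xs = [table[c].to_numpy(dtype=float) for c in term.covariates]
            if term.kind == "thin_plate":
                builder = ThinPlateSpline(xs[0], term.basis_size + 1)
            elif term.kind == "cubic_regression":
                builder = CubicRegressionSpline(xs[0], term.basis_size + 1)
            elif term.kind == "tensor_product":
                builder = TensorProduct(xs[0], xs[1], *term.margin_sizes)
            else:
                raise ValueError(f"unknown smooth kind {term.kind!r}")
            raw0 = (
                builder.matrix(*xs)
                if term.kind == "tensor_product"
                else builder.matrix(xs[0])
            )
            Z = sum_to_zero_nullspace(raw0)
            # rescale to unit column norms for numerical conditioning (the
            # eigen-scaled radial columns otherwise span many magnitudes)
            norms = np.linalg.norm(raw0 @ Z, axis=0)
            Z = Z / np.where(norms > 0, norms, 1.0)
            raw = raw0 @ Z
            pens = [
                ("range", _normalized(Z.T @ S @ Z)) for S in builder.penalties()
            ]
            if spec.double_penalty:
                total = sum(S for _, S in pens)
                proj = penalty_nullspace_projector(total)
                if proj is not None:
                    pens.append(("null", _normalized(proj)))
            hull = tuple((float(x.min()), float(x.max())) for x in xs)
        dim = raw.shape[1]
        sl = slice(start, start + dim)
        terms.append(
            TermBlock(
                name=term.name,
                sl=sl,
                builder=builder,
                constraint=Z,
                covariates=term.covariates,
                kind=term.kind,
                hull=hull,
            )
        )
        for kind, S in pens:
            penalties.append(PenaltyBlock(term=term.name, sl=sl, S=S, kind=kind))
        cols.append(raw)
        names.extend(f"{term.name}.{i}" for i in range(dim))
        start += dim
    X = np.hstack(cols)
    return GamDesign(
        X=X, y=y, terms=terms, penalties=penalties, spec=spec, column_names=names
    )
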