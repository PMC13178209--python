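"""Linear mixed models linking management to SOC metrics.

Each model regresses a transformed SOC metric on management fixed
effects with a random intercept per pedoclimatic zone, so that
management effects are estimated within zones rather than confounded by
them:

    y = Xβ + u_zone + ε,   u_zone ~ N(0, σ²_z),  ε ~ N(0, σ²)

Responses are variance-stabilised before fitting: stocks with log(1+x),
benchmark ratios with log(x), and the (sign-carrying) yearly change in
concentration with asinh(x).

Model reduction is stepwise backward elimination: the least significant
fixed term with p above the threshold is dropped (joint Wald test over
the term's columns; main effects are kept while any interaction or
higher-order term involving them remains) until all retained terms are
significant. The final model is judged against a random-intercept-only
null by a likelihood-ratio test on maximum-likelihood fits. Marginal
effect curves evaluate the fixed part over a grid of one variable with
the other covariates held at their means (continuous) or most frequent
level (categorical), back-transformed to the response scale with
delta-method confidence bands.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from patsy import build_design_matrices
from scipy import stats as sps

TRANSFORMS = {
    "none": (lambda x: x, lambda y: y),
    "log1p": (np.log1p, np.expm1),
    "log": (np.log, np.exp),
    "asinh": (np.arcsinh, np.sinh),
}

#: conventional transform per SOC metric
METRIC_TRANSFORM = {"stock": "log1p", "benchmark_ratio": "log", "delta_soc": "asinh"}


def transform_response(values, kind: str):
    """Apply the named variance-stabilising transform, checking domains."""
    if kind not in TRANSFORMS:
        raise ValueError(f"unknown transform {kind!r}; choose from {sorted(TRANSFORMS)}")
    v = np.asarray(values, dtype=float)
    if kind == "log":
        bad = np.sum(v[~np.isnan(v)] <= 0)
        if bad:
            raise ValueError(f"log transform requires positive values; {bad} violate")
    if kind == "log1p":
        bad = np.sum(v[~np.isnan(v)] <= -1)
        if bad:
            raise ValueError(f"log1p transform requires values > -1; {bad} violate")
    out = TRANSFORMS[kind][0](v)
    return out.item() if out.ndim == 0 else out


_IDENT = re.compile(r"[A-Za-z_][A-Za-z0-9_.]*")
_BUILTINS = {"C", "I", "np", "log", "log1p", "Treatment"}


def term_variables(term: str) -> frozenset[str]:
    """Data variables referenced by a formula term."""
    return frozenset(t for t in _IDENT.findall(term) if t not in _BUILTINS)


def _term_degree(term: str) -> int:
    return term.count(":") + (1 if "**" in term else 0)


def _protected(term: str, others: list[str]) -> bool:
    """Marginality: a term is protected while a higher-order term covers it."""
    tv, td = term_variables(term), _term_degree(term)
    return any(term_variables(o) >= tv and _term_degree(o) > td
               for o in others if o != term)


@dataclass(frozen=True)
class ModelSpec:
    """Response metric, transform, fixed-effect terms and grouping."""

    response: str
    fixed_terms: tuple[str, ...]
    transform: str = "none"
    group: str = "zone"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"unknown transform {self.transform!r}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class FitResult:
    """A fitted mixed model plus everything needed downstream."""

    spec: ModelSpec
    result: object                 # statsmodels MixedLMResults
    data: pd.DataFrame             # rows actually used (complete cases)
    reml: bool

    @property
    def terms(self) -> tuple[str, ...]:
        return self.spec.fixed_terms

    @property
    def fe_params(self) -> pd.Series:
        return self.result.fe_params

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def zone_var(self) -> float:
        return float(self.result.cov_re.iloc[0, 0])

    @property
    def resid_var(self) -> float:
        return float(self.result.scale)

    @property
    def n(self) -> int:
        return len(self.data)

    def cov_fe(self) -> np.ndarray:
        k = len(self.fe_params)
        return np.asarray(self.result.cov_params())[:k, :k]

    def term_pvalues(self) -> pd.Series:
        """Joint Wald p-value per fixed term (excluding the intercept)."""
        di = self.result.model.data.design_info
        names = list(self.result.params.index)
        k = len(names)
        out = {}
        for term, sl in di.term_name_slices.items():
            if term == "Intercept":
                continue
            rows = range(sl.start, sl.stop)
            r = np.zeros((len(list(rows)), k))
            for i, c in enumerate(range(sl.start, sl.stop)):
                r[i, c] = 1.0
            wt = self.result.wald_test(r, use_f=False, scalar=True)
            out[term] = float(wt.pvalue)
        return pd.Series(out)

    def summary_frame(self) -> pd.DataFrame:
        """Coefficients, SEs and Wald p-values of the fixed effects."""
        k = len(self.fe_params)
        return pd.DataFrame({
            "coef": self.fe_params,
            "se": self.result.bse.iloc[:k],
            "p": self.result.pvalues.iloc[:k],
        })


def _formula(spec: ModelSpec) -> str:
    rhs = " + ".join(spec.fixed_terms) if spec.fixed_terms else "1"
    return f"y_trans ~ {rhs}"


def _complete_cases(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    needed = {spec.response, spec.group}
    for t in spec.fixed_terms:
        needed |= term_variables(t)
    missing = needed - set(data.columns)
    if missing:
        raise KeyError(f"model references absent columns {sorted(missing)}")
    return data.dropna(subset=sorted(needed)).copy()


def fit_lmm(data: pd.DataFrame, spec: ModelSpec, reml: bool = True) -> FitResult:
    """Fit the random-intercept model for a spec.

    Complete cases only; requires at least two grouping levels and more
    observations than fixed-effect terms.
    """
    used = _complete_cases(data, spec)
    n_groups = used[spec.group].nunique()
    if n_groups < 2:
        raise ValueError(f"need >= 2 levels of {spec.group!r}, found {n_groups}")
    if len(used) <= len(spec.fixed_terms) + 2:
        raise ValueError("too few observations for the requested fixed effects")
    used["y_trans"] = transform_response(used[spec.response], spec.transform)
    model = smf.mixedlm(_formula(spec), used, groups=used[spec.group])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=reml)
    return FitResult(spec=spec, result=result, data=used, reml=reml)


def backward_eliminate(data: pd.DataFrame, spec: ModelSpec,
                       reml_final: bool = True) -> FitResult:
    """Stepwise backward elimination of non-significant fixed terms.

    Repeatedly drops the least significant term with p > alpha among
    the terms not protected by marginality, refitting each time (ML
    fits during elimination so fits stay comparable), and returns the
    final model refitted with REML for reporting.
    """
    terms = list(spec.fixed_terms)
    while terms:
        fit = fit_lmm(data, replace(spec, fixed_terms=tuple(terms)), reml=False)
        pvals = fit.term_pvalues()
        droppable = [t for t in terms if not _protected(t, terms)]
        cand = pvals[pvals.index.isin(droppable)]
        cand = cand[cand > spec.alpha]
        if cand.empty:
            break
        terms.remove(cand.idxmax())
    return fit_lmm(data, replace(spec, fixed_terms=tuple(terms)), reml=reml_final)


def lrt_vs_null(fit: FitResult) -> tuple[float, float]:
    """Likelihood-ratio test of the fixed effects against a null model.

    Refits both the final model and a random-intercept-only null with
    maximum likelihood on the same rows; returns (χ², p) with degrees
    of freedom equal to the number of fixed-effect columns dropped.
    """
    alt = fit if not fit.reml else fit_lmm(fit.data, fit.spec, reml=False)
    null_spec = replace(fit.spec, fixed_terms=())
    null = fit_lmm(fit.data, null_spec, reml=False)
    df = len(alt.fe_params) - len(null.fe_params)
    chi2 = max(0.0, 2.0 * (alt.llf - null.llf))
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return float(chi2), p


def marginal_effects(fit: FitResult, variable: str, grid=None,
                     by: str | None = None, ci: float = 0.95) -> pd.DataFrame:
    """Predicted response over a grid of one variable, original scale.

    Other continuous covariates are held at their means and categorical
    covariates at their most frequent level; the random intercept is
    set to zero. Predictions and delta-method confidence bounds are
    back-transformed with the inverse response transform (no smearing
    correction).
    """
    in_model = any(variable in term_variables(t) for t in fit.terms)
    if not in_model:
        raise ValueError(f"{variable!r} is not in the fitted model")
    used = fit.data
    if grid is None:
        grid = np.linspace(used[variable].min(), used[variable].max(), 25)
    grid = np.asarray(grid, dtype=float)

    covars = set().union(*(term_variables(t) for t in fit.terms)) if fit.terms else set()
    covars -= {variable}
    if by is not None:
        covars -= {by}
        levels = list(pd.unique(used[by]))
    else:
        levels = [None]

    frames = []
    for lev in levels:
        new = pd.DataFrame({variable: grid})
        for c in sorted(covars):
            col = used[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                new[c] = col.mode().iloc[0]
            else:
                new[c] = float(col.mean())
        if lev is not None:
            new[by] = lev
        frames.append(new)
    new = pd.concat(frames, ignore_index=True)

    di = fit.result.model.data.design_info
    (x,) = build_design_matrices([di], new)
    x = np.asarray(x)
    beta = fit.fe_params.to_numpy()
    pred_t = x @ beta
    var = np.einsum("ij,jk,ik->i", x, fit.cov_fe(), x)
    z = sps.norm.ppf(0.5 + ci / 2)
    se = np.sqrt(np.clip(var, 0, None))
    inv = TRANSFORMS[fit.spec.transform][1]
    out = new[[variable] + ([by] if by else [])].copy()
    out["predicted"] = inv(pred_t)
    out["ci_low"] = inv(pred_t - z * se)
    out["ci_high"] = inv(pred_t + z * se)
    return out
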