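"""Enrichment tests, simple correlations, and covariance (ANCOVA) models.

Three statistical surfaces used downstream of translatome quantification:

* hypergeometric enrichment of a trait within a gene subset, with the
  p-value defined as P(N > N_obs) - strictly greater (note: many tools
  use P(N >= N_obs); the strict convention is deliberate here);
* Pearson product-moment correlation with its two-sided t-test p-value;
* linear covariance models of a log response (ribosome occupancy,
  ribosome density, or protein level) on centered/reduced gene, mRNA and
  protein features plus a qualitative functional-category term, with
  stepwise AIC covariate selection and standardized coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "EnrichmentTest",
    "ModelSpec",
    "ModelFit",
    "hypergeometric_enrichment",
    "pearson_correlation",
    "default_model_spec",
    "fit_covariance_model",
    "protein_level_model",
]


@dataclass(frozen=True)
class EnrichmentTest:
    """A hypergeometric enrichment instance and its p-value."""

    n1: int        # subset size
    n2: int        # universe size
    m: int         # trait-positive genes in the universe
    n_obs: int     # trait-positive genes observed in the subset
    p_value: float


def hypergeometric_enrichment(n1: int, n2: int, m: int, n_obs: int) -> float:
    """P(N > n_obs) for N ~ Hypergeometric(universe n2, trait m, draws n1).

    The strict inequality means the most extreme attainable count
    (n_obs = min(n1, m)) has p-value exactly 0.
    """
    if not (0 <= m <= n2 and 0 <= n1 <= n2):
        raise ValueError("require 0 <= m <= n2 and 0 <= n1 <= n2")
    if not (max(0, n1 + m - n2) <= n_obs <= min(n1, m)):
        raise ValueError("n_obs outside the support of the hypergeometric law")
    return float(sps.hypergeom.sf(n_obs, n2, m, n1))


def pearson_correlation(x, y) -> tuple[float, float]:
    """Pearson r and its two-sided p-value.

    Requires equal-length finite samples of size >= 3 with nonzero
    variance on both axes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D samples of size >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class ModelSpec:
    """Covariate specification for a covariance model.

    ``quantitative`` maps feature column -> transform tag, "log" or
    "raw". Log is meant for strictly positive, right-skewed features;
    features that can be negative (chromosome position, GRAVY, folding
    energies) stay raw. Every quantitative covariate is then centered
    and reduced (mean 0, SD 1) so coefficients are comparable.
    ``qualitative`` columns enter as centered level indicators
    (deviation terms), each level individually selectable.
    """

    response: str
    quantitative: dict[str, str]
    qualitative: list[str] = field(default_factory=list)
    response_transform: str = "log"

    def __post_init__(self) -> None:
        for name, tag in self.quantitative.items():
            if tag not in ("log", "raw"):
                raise ValueError(f"covariate {name}: transform must be 'log' or 'raw'")
        if self.response_transform not in ("log", "raw"):
            raise ValueError("response_transform must be 'log' or 'raw'")


@dataclass
class ModelFit:
    """A selected-and-fitted covariance model."""

    response: str
    selected: list[str]
    coefficients: pd.Series
    p_values: pd.Series
    adj_r2: float
    r2: float
    aic: float
    aic_trace: list[tuple[str, float]]
    n_used: int
    n_dropped: int


#: Canonical covariate set for translatome responses.
_DEFAULT_QUANT = {
    "chrom_position": "raw",
    "mrna_concentration": "log",
    "mrna_half_life": "log",
    "cds_length_nt": "log",
    "aromaticity": "log",
    "gravy": "raw",
    "cai": "log",
    "dG_up": "raw",
    "dG_down": "raw",
}


def default_model_spec(response: str) -> ModelSpec:
    """The standard occupancy/density model: nine quantitative features
    plus the functional-category term."""
    return ModelSpec(
        response=response,
        quantitative=dict(_DEFAULT_QUANT),
        qualitative=["functional_category"],
    )


def _build_design(features: pd.DataFrame, response: pd.Series,
                  spec: ModelSpec) -> tuple[pd.DataFrame, np.ndarray, int]:
    cols = list(spec.quantitative) + list(spec.qualitative)
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"features table lacks columns: {missing}")
    df = features[cols].copy()
    df["__y"] = np.asarray(response, dtype=float)
    n_total = len(df)
    df = df.dropna()
    n_dropped = n_total - len(df)
    if len(df) < 20:
        raise ValueError("need >= 20 complete cases to fit a covariance model")
    y = df["__y"].to_numpy()
    if spec.response_transform == "log":
        if np.any(y <= 0):
            raise ValueError("response must be strictly positive for the log model")
        y = np.log(y)
    design = {}
    for name, tag in spec.quantitative.items():
        x = df[name].to_numpy(dtype=float)
        if tag == "log":
            if np.any(x <= 0):
                raise ValueError(f"covariate {name}: log transform requires "
                                 "strictly positive values")
            x = np.log(x)
        sd = x.std(ddof=0)
        if sd == 0:
            raise ValueError(f"covariate {name} is constant on complete cases")
        design[name] = (x - x.mean()) / sd
    for cat in spec.qualitative:
        levels = sorted(df[cat].astype(str).unique())
        for lev in levels:
            ind = (df[cat].astype(str) == lev).to_numpy(dtype=float)
            design[f"{cat}={lev}"] = ind - ind.mean()
    x_df = pd.DataFrame(design, index=df.index)
    _collinearity_check(x_df, list(spec.quantitative))
    return x_df, y, n_dropped


def _collinearity_check(design: pd.DataFrame, quant: list[str],
                        r_tol: float = 0.999) -> None:
    """Reject near-duplicate quantitative covariates, naming the pair."""
    for a, b in itertools.combinations(quant, 2):
        r = np.corrcoef(design[a], design[b])[0, 1]
        if abs(r) > r_tol:
            raise ValueError(
                f"collinear covariates: {a} and {b} (|r| = {abs(r):.6f})"
            )


def _aic(x: np.ndarray, y: np.ndarray) -> float:
    """AIC up to an additive constant: n*ln(RSS/n) + 2*(p + 2).

    p columns + intercept + error variance; matches statsmodels' OLS AIC
    up to the constant n*(ln(2*pi) + 1).
    """
    n = y.size
    xc = np.column_stack([np.ones(n), x]) if x.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(xc, y, rcond=None)
    rss = float(np.sum((y - xc @ beta) ** 2))
    # Relative floor: numerically perfect fits tie, so the parameter
    # penalty alone decides among them.
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = max(rss, 1e-20 * max(tss, 1e-300))
    return n * np.log(rss / n) + 2 * (xc.shape[1] + 1)


def _stepwise_aic(design: pd.DataFrame, y: np.ndarray,
                  trace: list[tuple[str, float]]) -> list[str]:
    """Bidirectional stepwise selection from the full model."""
    terms = list(design.columns)
    current = list(terms)
    current_aic = _aic(design[current].to_numpy(), y)
    trace.append(("start:full", current_aic))
    while True:
        best_move, best_aic = None, current_aic
        for t in current:
            cand = [c for c in current if c != t]
            a = _aic(design[cand].to_numpy(), y)
            if a < best_aic - 1e-10:
                best_move, best_aic = ("-" + t, a)
        for t in terms:
            if t in current:
                continue
            a = _aic(design[current + [t]].to_numpy(), y)
            if a < best_aic - 1e-10:
                best_move, best_aic = ("+" + t, a)
        if best_move is None:
            return current
        if best_move.startswith("-"):
            current.remove(best_move[1:])
        else:
            current.append(best_move[1:])
        current_aic = best_aic
        trace.append((best_move, current_aic))


def _exhaustive_aic(design: pd.DataFrame, y: np.ndarray,
                    trace: list[tuple[str, float]]) -> list[str]:
    terms = list(design.columns)
    if len(terms) > 12:
        raise ValueError("exhaustive search is limited to <= 12 covariates")
    best, best_aic = [], _aic(np.empty((y.size, 0)), y)
    for r in range(1, len(terms) + 1):
        for subset in itertools.combinations(terms, r):
            a = _aic(design[list(subset)].to_numpy(), y)
            if a < best_aic - 1e-10:
                best, best_aic = list(subset), a
    trace.append(("best-subset", best_aic))
    return best


def fit_covariance_model(
    features: pd.DataFrame,
    response: pd.Series | np.ndarray,
    spec: ModelSpec,
    selection: str = "stepwise",
) -> ModelFit:
    """Fit a log-response covariance model with AIC covariate selection.

    Quantitative covariates are transformed per the spec, centered and
    reduced; qualitative categories enter as centered level indicators.
    ``selection`` is ``"stepwise"`` (bidirectional from the full model,
    default), ``"exhaustive"`` (all subsets, <= 12 covariates) or
    ``"none"`` (keep the full model). Genes with missing values are
    dropped and counted. Coefficients, t-test p-values and adjusted R²
    come from the final ordinary-least-squares fit.
    """
    design, y, n_dropped = _build_design(features, response, spec)
    trace: list[tuple[str, float]] = []
    if selection == "stepwise":
        selected = _stepwise_aic(design, y, trace)
    elif selection == "exhaustive":
        selected = _exhaustive_aic(design, y, trace)
    elif selection == "none":
        selected = list(design.columns)
    else:
        raise ValueError("selection must be 'stepwise', 'exhaustive' or 'none'")
    x = sm.add_constant(design[selected], has_constant="add")
    fit = sm.OLS(y, x).fit()
    coef = fit.params.drop("const")
    pvals = fit.pvalues.drop("const")
    return ModelFit(
        response=spec.response,
        selected=list(coef.index),
        coefficients=coef,
        p_values=pvals,
        adj_r2=float(fit.rsquared_adj),
        r2=float(fit.rsquared),
        aic=float(fit.aic),
        aic_trace=trace,
        n_used=int(fit.nobs),
        n_dropped=n_dropped,
    )


def protein_level_model(
    features: pd.DataFrame,
    protein_level: pd.Series | np.ndarray,
    spec: ModelSpec | None = None,
    selection: str = "stepwise",
) -> tuple[ModelFit, ModelFit]:
    """Protein-level models without (I) and with (II) translatome covariates.

    Model II adds ribosome occupancy and ribosome density (both log,
    strictly positive) to the covariate pool; the ``features`` table must
    carry ``occupancy`` and ``density`` columns. Returns the pair
    (fit without, fit with) so their adjusted R² can be compared.
    """
    if spec is None:
        spec = default_model_spec("protein_level")
    fit_without = fit_covariance_model(features, protein_level, spec, selection)
    spec_with = ModelSpec(
        response=spec.response,
        quantitative={**spec.quantitative, "occupancy": "log", "density": "log"},
        qualitative=list(spec.qualitative),
        response_transform=spec.response_transform,
    )
    fit_with = fit_covariance_model(features, protein_level, spec_with, selection)
    return fit_without, fit_with
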