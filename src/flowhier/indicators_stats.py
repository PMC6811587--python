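"""Statistics linking Φ to per-city indicators.

Three explained-variance measures are reported per indicator, matching common
practice for mobility/indicator studies: the squared Pearson correlation
R_P² (linear), the squared Spearman rank correlation R_S² (monotone), and the
LOESS explained variance R_L² = 1 - RSS/TSS of a locally-linear tricube-
weighted fit of the indicator on Φ (flexible shape). Significance stars follow
the usual thresholds: * p < 0.05, ** p < 0.01, *** p < 0.001.

The multivariate stage quantifies how much variance Φ adds on top of
socio-economic covariates: three nested OLS fits (Φ only; covariates only;
covariates + Φ) give the gain R²_full - R²_covariates, which is non-negative
by construction for nested least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .exceptions import CollinearityError, FlowHierError, SampleSizeError

STAR_THRESHOLDS = (0.05, 0.01, 0.001)


@dataclass
class CorrelationResult:
    r2_pearson: float
    r2_spearman: float
    r2_loess: float            # raw; may be negative for pathological fits
    p_pearson: float
    p_spearman: float
    stars: int                 # from the Pearson regression p-value
    n_used: int
    n_dropped: int
    loess_span: float

    @property
    def r2_loess_clipped(self) -> float:
        return max(0.0, self.r2_loess)


@dataclass
class MultivariateGain:
    r2_phi_only: float
    r2_covariates_only: float
    r2_full: float
    gain: float
    n_used: int = 0
    covariates: list[str] = field(default_factory=list)


def _stars(p: float) -> int:
    return sum(p < t for t in STAR_THRESHOLDS)


def _complete(table: pd.DataFrame, cols: Sequence[str]) -> tuple[pd.DataFrame, int]:
    sub = table[list(cols)].apply(pd.to_numeric, errors="coerce")
    complete = sub.dropna()
    return complete, len(sub) - len(complete)


def correlate(table: pd.DataFrame, indicator: str, phi_column: str = "phi",
              loess_span: float = 0.75, loess_iterations: int = 0,
              permutations: int | None = None,
              seed: int | None = None) -> CorrelationResult:
    """Pearson, Spearman and LOESS explained variances of one indicator vs Φ.

    Complete-case analysis: rows with a missing value in either column are
    dropped and counted. ``permutations`` switches the p-values to an exact
    permutation test (seeded) for small samples.
    """
    for col in (phi_column, indicator):
        if col not in table.columns:
            raise FlowHierError(f"column {col!r} not in table")
    data, dropped = _complete(table, [phi_column, indicator])
    if len(data) < 4:
        raise SampleSizeError(
            f"need >= 4 complete (phi, {indicator}) pairs, have {len(data)}"
        )
    x = data[phi_column].to_numpy(float)
    y = data[indicator].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        raise FlowHierError("zero variance in phi or indicator column")

    if permutations:
        method = stats.PermutationMethod(
            n_resamples=permutations, random_state=np.random.default_rng(seed)
        )
        pear = stats.pearsonr(x, y, method=method)
        spear = stats.spearmanr(x, y)
        res = stats.permutation_test(
            (y,), lambda yy: stats.spearmanr(x, yy).statistic,
            permutation_type="pairings", n_resamples=permutations,
            random_state=np.random.default_rng(seed),
        )
        p_spear = float(res.pvalue)
    else:
        pear = stats.pearsonr(x, y)
        spear = stats.spearmanr(x, y)
        p_spear = float(spear.pvalue)

    fitted = lowess(y, x, frac=loess_span, it=loess_iterations,
                    return_sorted=False)
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(((y - fitted) ** 2).sum())
    r2_loess = 1.0 - rss / tss

    return CorrelationResult(
        r2_pearson=float(pear.statistic ** 2),
        r2_spearman=float(spear.statistic ** 2),
        r2_loess=r2_loess,
        p_pearson=float(pear.pvalue),
        p_spearman=p_spear,
        stars=_stars(float(pear.pvalue)),
        n_used=len(data),
        n_dropped=dropped,
        loess_span=loess_span,
    )


def _ols_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R² of an intercept-included least-squares fit."""
    design = np.column_stack([np.ones(len(y)), X]) if X.size else \
        np.ones((len(y), 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float((resid ** 2).sum()) / tss


def _check_rank(data: pd.DataFrame, cols: list[str]) -> None:
    X = np.column_stack([np.ones(len(data))] +
                        [data[c].to_numpy(float) for c in cols])
    if np.linalg.matrix_rank(X) == X.shape[1]:
        return
    offending = []
    kept = [np.ones(len(data))]
    for c in cols:
        candidate = np.column_stack(kept + [data[c].to_numpy(float)])
        if np.linalg.matrix_rank(candidate) < candidate.shape[1]:
            offending.append(c)
        else:
            kept.append(data[c].to_numpy(float))
    raise CollinearityError(
        f"design matrix is rank deficient; offending columns: {offending}",
        columns=offending,
    )


def multivariate_gain(table: pd.DataFrame, indicator: str,
                      covariates: Sequence[str],
                      phi_column: str = "phi") -> MultivariateGain:
    """Variance gained by adding Φ to a covariate-only OLS model.

    Fits three intercept-included OLS models of the indicator — on Φ alone,
    on the covariates alone, and on covariates plus Φ — and reports the four
    R² quantities. ``gain = r2_full - r2_covariates_only`` is >= 0.
    """
    covariates = list(covariates)
    cols = [phi_column, indicator, *covariates]
    for col in cols:
        if col not in table.columns:
            raise FlowHierError(f"column {col!r} not in table")
    data, dropped = _complete(table, cols)
    if len(data) < len(covariates) + 3:
        raise SampleSizeError(
            f"need >= {len(covariates) + 3} complete cases, have {len(data)}"
        )
    _check_rank(data, [phi_column, *covariates])

    y = data[indicator].to_numpy(float)
    phi = data[[phi_column]].to_numpy(float)
    cov = data[covariates].to_numpy(float) if covariates else \
        np.empty((len(data), 0))

    r2_phi = _ols_r2(y, phi)
    r2_cov = _ols_r2(y, cov)
    r2_full = _ols_r2(y, np.column_stack([cov, phi]))
    return MultivariateGain(
        r2_phi_only=r2_phi,
        r2_covariates_only=r2_cov,
        r2_full=r2_full,
        gain=r2_full - r2_cov,
        n_used=len(data),
        covariates=covariates,
    )


def rank_cities(table: pd.DataFrame, group_column: str | None = None,
                phi_column: str = "phi",
                city_column: str = "city") -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Rank cities by decreasing Φ (ties broken by city id) with per-group
    summaries of Φ and of rank.

    Returns ``(ranking, group_summary)``; the summary is ``None`` when no
    group column is given.
    """
    if table.empty:
        raise FlowHierError("cannot rank an empty table")
    ranking = table.sort_values(
        [phi_column, city_column], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    if group_column is None:
        return ranking, None
    grouped = ranking.groupby(group_column)
    summary = grouped.agg(
        mean_phi=(phi_column, "mean"),
        sd_phi=(phi_column, "std"),
        mean_rank=("rank", "mean"),
        sd_rank=("rank", "std"),
        n=(phi_column, "size"),
    ).reset_index()
    return ranking, summary
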