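"""Model fits and Tukey-adjusted pairwise contrasts for the drift statistics.

Three model families are used downstream:

* binomial GLM with logit link for the per-cue proportion of new responses,
* ordinary (gaussian) linear model for the per-cue KL divergence,
* gamma model with inverse link for the cosine similarity ratios, fit by
  generalized estimating equations with exchangeable within-cue correlation
  (the cue-level clustering that a random-intercept model would absorb).

Pairwise contrasts between factor levels are adjusted with the Tukey method
via the studentized range distribution (asymptotic df for the z-based
models, residual df for the gaussian one).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import DegenerateInputError

_ASYMPTOTIC_DF = 1e7  # effectively infinite df for z-based Tukey adjustment


@dataclass
class Contrast:
    """One pairwise comparison between two factor levels."""

    levels: tuple[str, str]
    estimate_link: float      # difference on the link scale
    estimate_response: float  # difference on the response scale
    se: float
    statistic: float
    p_adjusted: float


@dataclass
class ModelSummary:
    """Omnibus test plus Tukey-adjusted pairwise contrasts for one model."""

    family: str                 # binomial-logit | gaussian-identity | gamma-inverse
    statistic_name: str         # chi2 | F
    statistic: float
    df: tuple[float, ...]
    p_value: float
    contrasts: list[Contrast] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["contrasts"] = [asdict(c) for c in self.contrasts]
        return d


def tukey_adjust(t_stats: np.ndarray, n_levels: int, df: float) -> np.ndarray:
    """Tukey (studentized range) adjusted p-values for all-pairs contrasts."""
    q = np.abs(np.asarray(t_stats, dtype=float)) * np.sqrt(2.0)
    return stats.studentized_range.sf(q, n_levels, df)


def _pairwise(
    levels: list[str],
    eta: np.ndarray,
    cov: np.ndarray,
    inv_link,
    df: float,
) -> list[Contrast]:
    """All-pairs contrasts of per-level linear predictors ``eta``."""
    out = []
    k = len(levels)
    raw = []
    for i, j in combinations(range(k), 2):
        diff = eta[i] - eta[j]
        var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
        se = float(np.sqrt(var))
        stat = diff / se if se > 0 else np.inf
        raw.append((i, j, diff, se, stat))
    p_adj = tukey_adjust(np.array([r[4] for r in raw]), k, df)
    for (i, j, diff, se, stat), p in zip(raw, p_adj):
        out.append(
            Contrast(
                levels=(levels[i], levels[j]),
                estimate_link=float(diff),
                estimate_response=float(inv_link(eta[i]) - inv_link(eta[j])),
                se=se,
                statistic=float(stat),
                p_adjusted=float(p),
            )
        )
    return out


def _level_design(groups: pd.Series) -> tuple[list[str], np.ndarray]:
    """Cell-means design matrix (one indicator column per level)."""
    levels = sorted(groups.unique())
    if len(levels) < 2:
        raise DegenerateInputError(
            f"need at least 2 factor levels, got {levels}"
        )
    X = np.column_stack([(groups == lv).to_numpy(float) for lv in levels])
    return levels, X


def fit_binomial_groups(
    successes: pd.Series, totals: pd.Series, groups: pd.Series
) -> ModelSummary:
    """Binomial-logit GLM of per-unit (successes, totals) on a single factor.

    The omnibus test is the likelihood-ratio chi-square against the
    intercept-only model; contrasts are on the logit scale with the
    proportion-scale difference also reported.
    """
    levels, X = _level_design(groups)
    s = np.asarray(successes, dtype=float)
    t = np.asarray(totals, dtype=float)
    if s.sum() == 0 or (t - s).sum() == 0:
        # all-zero (or all-one) proportions: the logit is unbounded and the
        # factor carries no information, so the omnibus test is null
        return ModelSummary(
            family="binomial-logit", statistic_name="chi2",
            statistic=0.0, df=(float(len(levels) - 1),), p_value=1.0,
        )
    endog = np.column_stack([successes, totals - successes]).astype(float)
    full = sm.GLM(endog, X, family=sm.families.Binomial()).fit()
    null = sm.GLM(endog, np.ones((len(groups), 1)),
                  family=sm.families.Binomial()).fit()
    lr = 2.0 * (full.llf - null.llf)
    df = len(levels) - 1
    p = stats.chi2.sf(lr, df)
    inv_logit = lambda x: 1.0 / (1.0 + np.exp(-x))  # noqa: E731
    contrasts = _pairwise(
        levels, full.params, full.cov_params(), inv_logit, _ASYMPTOTIC_DF
    )
    return ModelSummary(
        family="binomial-logit",
        statistic_name="chi2",
        statistic=float(lr),
        df=(float(df),),
        p_value=float(p),
        contrasts=contrasts,
    )


def fit_gaussian_groups(values: pd.Series, groups: pd.Series) -> ModelSummary:
    """Ordinary linear model of a continuous response on a single factor.

    The omnibus test is the ANOVA F test; contrasts use the residual df.
    """
    levels, X = _level_design(groups)
    y = np.asarray(values, dtype=float)
    k = len(levels)
    n = len(y)
    if n <= k:
        raise DegenerateInputError("not enough observations for the F test")
    if np.ptp(y) == 0:
        # constant response: zero between- and within-group variance
        return ModelSummary(
            family="gaussian-identity", statistic_name="F",
            statistic=0.0, df=(float(k - 1), float(n - k)), p_value=1.0,
        )
    fit = sm.OLS(y, X).fit()
    # F for equality of all level means
    grand = sm.OLS(y, np.ones((n, 1))).fit()
    df1, df2 = k - 1, n - k
    F = ((grand.ssr - fit.ssr) / df1) / (fit.ssr / df2)
    p = stats.f.sf(F, df1, df2)
    contrasts = _pairwise(
        levels, fit.params, fit.cov_params(), lambda x: x, float(df2)
    )
    return ModelSummary(
        family="gaussian-identity",
        statistic_name="F",
        statistic=float(F),
        df=(float(df1), float(df2)),
        p_value=float(p),
        contrasts=contrasts,
    )


def fit_gamma_ratio_gee(
    ratios: pd.Series,
    cue_type: pd.Series,
    neighbor_type: pd.Series,
    cue: pd.Series,
) -> tuple[ModelSummary, dict[str, list[Contrast]]]:
    """Gamma/inverse-link model of similarity ratios with within-cue clustering.

    Fit by GEE with exchangeable working correlation over cues, with a full
    cue-type x neighbor-type cell-means parameterization.  The omnibus
    statistic is the Wald chi-square for the cue-type x neighbor-type
    interaction; per-neighbor-type pairwise cue-type contrasts are returned
    Tukey-adjusted.
    """
    y = np.asarray(ratios, dtype=float)
    if (y <= 0).any():
        raise DegenerateInputError("ratios must be strictly positive")
    ct_levels = sorted(cue_type.unique())
    nt_levels = sorted(neighbor_type.unique())
    if len(ct_levels) < 2 or len(nt_levels) < 2:
        raise DegenerateInputError(
            "need at least 2 cue types and 2 neighbor types"
        )
    if np.ptp(y) == 0:
        # constant response: no variation, hence no detectable interaction
        summary = ModelSummary(
            family="gamma-inverse", statistic_name="chi2",
            statistic=0.0,
            df=(float((len(ct_levels) - 1) * (len(nt_levels) - 1)),),
            p_value=1.0,
        )
        return summary, {}
    cells = [(a, b) for a in ct_levels for b in nt_levels]
    X = np.column_stack(
        [((cue_type == a) & (neighbor_type == b)).to_numpy(float)
         for a, b in cells]
    )
    with warnings.catch_warnings():
        # the inverse link can step outside the gamma domain during
        # iteration; statsmodels warns but the cell-means fit is safe
        warnings.simplefilter("ignore")
        fam = sm.families.Gamma(link=sm.families.links.InversePower())
        model = sm.GEE(
            y, X,
            groups=np.asarray(cue),
            family=fam,
            cov_struct=sm.cov_struct.Exchangeable(),
        )
        fit = model.fit()
    params = fit.params
    cov = fit.cov_params()

    # interaction: cell effects minus additive (row + column) structure;
    # contrast rows are double differences over a reference row/column
    rows = []
    for a in ct_levels[1:]:
        for b in nt_levels[1:]:
            c = np.zeros(len(cells))
            c[cells.index((a, b))] += 1
            c[cells.index((a, nt_levels[0]))] -= 1
            c[cells.index((ct_levels[0], b))] -= 1
            c[cells.index((ct_levels[0], nt_levels[0]))] += 1
            rows.append(c)
    C = np.array(rows)
    est = C @ params
    vcv = C @ cov @ C.T
    wald = float(est @ np.linalg.solve(vcv, est))
    df = C.shape[0]
    p = stats.chi2.sf(wald, df)

    inv = lambda x: 1.0 / x  # noqa: E731  (inverse link mean function)
    by_neighbor: dict[str, list[Contrast]] = {}
    for b in nt_levels:
        idx = [cells.index((a, b)) for a in ct_levels]
        by_neighbor[b] = _pairwise(
            ct_levels, params[idx], cov[np.ix_(idx, idx)], inv, _ASYMPTOTIC_DF
        )
    summary = ModelSummary(
        family="gamma-inverse",
        statistic_name="chi2",
        statistic=wald,
        df=(float(df),),
        p_value=float(p),
        contrasts=[c for cs in by_neighbor.values() for c in cs],
    )
    return summary, by_neighbor
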