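"""Per-cue drift statistics: new-response proportion and KL divergence.

A Covid-period response token is *new* when its type has zero Precovid
frequency for that cue; the proportion of new tokens among all Covid tokens
is the first drift statistic.  The second is the Kullback-Leibler divergence
(in nats) of the Covid response distribution from the Precovid one, computed
on the union support after additive smoothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _kl

from .data import FrequencyTable
from .errors import CueLookupError, UndefinedDistributionError
from .inference import ModelSummary, fit_binomial_groups, fit_gaussian_groups

DRIFT_COLUMNS = [
    "cue", "cue_type", "n_covid_tokens", "n_new_tokens",
    "proportion_new", "kl_nats",
]


def _period_counts(ft: FrequencyTable, cue: str) -> tuple[pd.Series, pd.Series]:
    for period in ("precovid", "covid"):
        if not ft.has(cue, period):
            raise CueLookupError(f"cue {cue!r} has no counts in period {period!r}")
    return ft.distribution(cue, "precovid"), ft.distribution(cue, "covid")


def new_response_proportion(
    ft: FrequencyTable, cue: str
) -> tuple[float, int, int]:
    """Token-level proportion of Covid responses whose type is new.

    Returns (proportion, n_new, n_total); every Covid response token counts
    as one Bernoulli trial, matching the binomial model downstream.
    """
    pre, cov = _period_counts(ft, cue)
    new_types = cov.index.difference(pre.index)
    n_new = int(cov.loc[new_types].sum())
    n_total = int(cov.sum())
    return n_new / n_total, n_new, n_total


def kl_divergence_cue(
    ft: FrequencyTable,
    cue: str,
    pseudocount: float = 0.5,
    direction: str = "covid_from_precovid",
) -> float:
    """KL divergence in nats between a cue's two response distributions.

    Computed over the union support of both periods after adding
    ``pseudocount`` to every cell (Jeffreys 0.5 by default; 0 is allowed and
    may return +inf).  The default direction is D(Covid || Precovid), the
    relative entropy of the Covid distribution with respect to Precovid.
    """
    pre, cov = _period_counts(ft, cue)
    if pre.sum() == 0 or cov.sum() == 0:
        raise UndefinedDistributionError(
            f"cue {cue!r}: zero tokens in one period"
        )
    support = pre.index.union(cov.index)
    p_pre = pre.reindex(support, fill_value=0).to_numpy(float) + pseudocount
    p_cov = cov.reindex(support, fill_value=0).to_numpy(float) + pseudocount
    if direction == "covid_from_precovid":
        p, q = p_cov, p_pre
    elif direction == "precovid_from_covid":
        p, q = p_pre, p_cov
    else:
        raise ValueError(f"unknown direction {direction!r}")
    # scipy normalizes and returns sum(p * ln(p/q)); inf when q has zeros
    # on p's support (possible only with pseudocount 0)
    return float(_kl(p, q))


def drift_table(
    ft: FrequencyTable,
    registry: pd.DataFrame,
    pseudocount: float = 0.5,
    include_types: tuple[str, ...] = ("control", "pandemic", "emotion", "routine"),
) -> pd.DataFrame:
    """One drift record per registry cue, ordered by cue token.

    Cues whose type is not in ``include_types`` (fillers by default) are
    skipped; errors for individual cues are re-raised naming the cue.
    """
    rows = []
    reg = registry[registry["cue_type"].isin(include_types)]
    for _, entry in reg.sort_values("cue").iterrows():
        cue = entry["cue"]
        try:
            prop, n_new, n_total = new_response_proportion(ft, cue)
            kl = kl_divergence_cue(ft, cue, pseudocount=pseudocount)
        except (CueLookupError, UndefinedDistributionError) as e:
            raise type(e)(f"cue {cue!r}: {e}") from e
        rows.append(
            {
                "cue": cue,
                "cue_type": entry["cue_type"],
                "n_covid_tokens": n_total,
                "n_new_tokens": n_new,
                "proportion_new": prop,
                "kl_nats": kl,
            }
        )
    return pd.DataFrame(rows, columns=DRIFT_COLUMNS)


def fit_drift_models(table: pd.DataFrame, response: str) -> ModelSummary:
    """Cue-type model for one drift statistic with Tukey pairwise contrasts.

    ``proportion_new`` is modeled as a binomial-logit GLM on the
    (n_new, n_total) token counts; ``kl_nats`` as an ordinary linear model.
    """
    if response == "proportion_new":
        return fit_binomial_groups(
            table["n_new_tokens"], table["n_covid_tokens"], table["cue_type"]
        )
    if response == "kl_nats":
        return fit_gaussian_groups(table["kl_nats"], table["cue_type"])
    raise ValueError(f"unknown response {response!r}")


@dataclass
class CueDriftRecord:
    """Convenience record mirroring one row of the drift table."""

    cue: str
    cue_type: str
    n_covid_tokens: int
    n_new_tokens: int
    proportion_new: float
    kl_nats: float

    def __post_init__(self):
        if not 0 <= self.n_new_tokens <= self.n_covid_tokens:
            raise ValueError("n_new_tokens outside [0, n_covid_tokens]")
        if self.kl_nats < 0 and not np.isnan(self.kl_nats):
            raise ValueError("kl_nats must be non-negative")
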