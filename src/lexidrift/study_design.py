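"""Design constants of the two-period COVID word-association study.

These numbers describe the study design this package models: the Covid-period
cue set by experimental type, the per-period participant quota, the
three-responses-per-trial task structure, and the demographic composition of
the two cohorts. The simulator draws its demographic marginals from here, and
the arithmetic helpers below derive the composite counts (total cues, cues
retained for analysis, implied response volume) that the design fixes.
"""

from __future__ import annotations

#: Number of cues presented during the Covid period, by experimental type.
COVID_CUE_COUNTS: dict[str, int] = {
    "control": 150,
    "pandemic": 107,
    "emotion": 119,
    "routine": 108,
    "filler": 180,
}

#: Target cues dropped because they were never presented Precovid.
CUES_REMOVED_MISSING_PRECOVID: dict[str, int] = {
    "emotion": 3,
    "pandemic": 8,
    "routine": 4,
}

#: Respondents retained per cue per period after quota sampling.
QUOTA_PER_PERIOD = 60
#: Responses requested per trial (R1, R2, R3).
RESPONSES_PER_TRIAL = 3

#: Cohort sizes after preprocessing.
PARTICIPANTS: dict[str, int] = {"precovid": 17_263, "covid": 4_181}

#: Demographic counts per cohort after preprocessing.
DEMOGRAPHIC_COUNTS: dict[str, dict[str, dict[str, int]]] = {
    "precovid": {
        "gender": {"female": 13_834, "male": 3_322, "X": 107},
        "native_language": {
            "Uruguay-Rioplatense": 10_894,
            "Argentina-Rioplatense": 6_231,
            "Argentina-Cordobés": 40,
            "Argentina-NOG": 17,
        },
        "education": {
            "none": 9,
            "primary": 232,
            "secondary": 6_285,
            "university": 9_063,
            "postgraduate": 1_674,
        },
    },
    "covid": {
        "gender": {"female": 3_287, "male": 846, "X": 48},
        "native_language": {
            "Uruguay-Rioplatense": 1_003,
            "Argentina-Rioplatense": 3_069,
            "Argentina-Cordobés": 48,
            "Argentina-NOG": 19,
        },
        "education": {
            "none": 5,
            "primary": 54,
            "secondary": 1_318,
            "university": 2_283,
            "postgraduate": 521,
        },
    },
}

#: Age mean and SD (years) per cohort.
AGE_MEAN_SD: dict[str, tuple[float, float]] = {
    "precovid": (37.0, 14.0),
    "covid": (40.0, 13.0),
}


def covid_cue_total() -> int:
    """Total number of cues presented during the Covid period."""
    return sum(COVID_CUE_COUNTS.values())


def analysis_cue_count() -> int:
    """Cues entering the drift analyses: target + control cues minus the
    target cues that were never presented Precovid (fillers are excluded)."""
    kept = sum(
        n for t, n in COVID_CUE_COUNTS.items() if t != "filler"
    )
    return kept - sum(CUES_REMOVED_MISSING_PRECOVID.values())


def implied_response_total() -> int:
    """Response volume implied by the quota design: every analysis cue seen
    by the quota of respondents in each of the two periods, three responses
    per trial."""
    return (
        analysis_cue_count() * 2 * QUOTA_PER_PERIOD * RESPONSES_PER_TRIAL
    )


def total_participants() -> int:
    """Participants across both cohorts after preprocessing."""
    return sum(PARTICIPANTS.values())


def demographic_percentages(period: str, field: str) -> dict[str, float]:
    """Percentage composition of one demographic field in one cohort,
    relative to the cohort size."""
    counts = DEMOGRAPHIC_COUNTS[period][field]
    n = PARTICIPANTS[period]
    return {k: 100.0 * v / n for k, v in counts.items()}


def demographic_probabilities(period: str, field: str) -> dict[str, float]:
    """Normalized sampling probabilities for one demographic field (the
    categories sum to 1; used by the synthetic-data generator)."""
    counts = DEMOGRAPHIC_COUNTS[period][field]
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}
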