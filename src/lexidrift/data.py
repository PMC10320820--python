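"""Data model and preprocessing for two-period word-association norms.

The central container is :class:`AssociationDataset`, holding three tables in
the style of the Small World of Words (SWOW) norms:

* ``participants`` — one row per participant with demographics and the
  collection period (``precovid`` / ``covid``),
* ``trials`` — one row per produced response (long form), where a response is
  either a normalized token or one of the sentinels ``NO_MORE`` / ``UNKNOWN``,
* ``registry`` — one row per cue with its experimental type
  (control / pandemic / emotion / routine / filler).

Preprocessing follows the SWOW conventions: token normalization and lexical
variant replacement, four participant-level exclusion rules, and per-cue
quota sampling with native-language priority.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    CueLookupError,
    IntegrityError,
    SchemaError,
)

# Internal sentinel markers; the on-disk strings are configurable.
NO_MORE = "<no_more>"
UNKNOWN = "<unknown>"
SENTINELS = frozenset({NO_MORE, UNKNOWN})

DEFAULT_SENTINEL_STRINGS = {
    "No more responses": NO_MORE,
    "Unknown word": UNKNOWN,
}

PERIODS = ("precovid", "covid")
POSITIONS = ("R1", "R2", "R3")
CUE_TYPES = ("control", "pandemic", "emotion", "routine", "filler")

DEMOGRAPHIC_COLUMNS = ("period", "gender", "age", "native_language", "education")

#: Native-language priority tiers used when trimming a cue to its quota:
#: Rioplatense speakers first, then the smaller Argentinean variants.
DEFAULT_LANGUAGE_PRIORITY: tuple[tuple[str, ...], ...] = (
    ("Uruguay-Rioplatense", "Argentina-Rioplatense"),
    ("Argentina-Cordobés", "Argentina-NOG"),
)


@dataclass(frozen=True)
class Lexicon:
    """A reference word list used by the in-lexicon exclusion rule."""

    words: frozenset[str]

    def __contains__(self, token: str) -> bool:
        return token in self.words

    def __len__(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class VariantMap:
    """Mapping from regional lexical variants to canonical forms.

    The mapping must be idempotent after one application: no canonical
    token may itself appear as a variant key.
    """

    mapping: Mapping[str, str]

    def __post_init__(self):
        bad = set(self.mapping.values()) & set(self.mapping.keys())
        if bad:
            raise ConfigurationError(
                f"variant map is not idempotent; canonical tokens also appear "
                f"as variants: {sorted(bad)}"
            )

    def apply(self, token: str) -> str:
        return self.mapping.get(token, token)


@dataclass(frozen=True)
class ExclusionThresholds:
    """Participant exclusion thresholds (all strict inequalities).

    A participant is removed when
    * more than ``sentence_frac`` of their responses are short sentences,
    * fewer than ``unique_frac`` of their responses are unique,
    * fewer than ``lexicon_frac`` of their responses appear in the lexicon,
    * more than ``unknown_frac`` of their presented cues were unknown.
    """

    sentence_frac: float = 0.30
    unique_frac: float = 0.80
    lexicon_frac: float = 0.60
    unknown_frac: float = 0.60
    #: minimum whitespace-separated token count for a response to count as
    #: a "short sentence"
    sentence_min_tokens: int = 3


@dataclass
class AssociationDataset:
    """Participants, trials and the cue registry for one or both periods."""

    participants: pd.DataFrame
    trials: pd.DataFrame
    registry: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        """Check referential integrity and trial-structure invariants."""
        pid = self.participants["participant_id"]
        if pid.duplicated().any():
            dups = pid[pid.duplicated()].unique()[:5]
            raise IntegrityError(f"duplicate participant ids: {list(dups)}")
        bad_period = set(self.participants["period"]) - set(PERIODS)
        if bad_period:
            raise IntegrityError(f"unknown periods: {sorted(bad_period)}")
        if not self.trials.empty:
            unknown_pid = set(self.trials["participant_id"]) - set(pid)
            if unknown_pid:
                raise IntegrityError(
                    f"trials reference unknown participants: "
                    f"{sorted(unknown_pid)[:5]}"
                )
            unknown_cue = set(self.trials["cue"]) - set(self.registry["cue"])
            if unknown_cue:
                raise IntegrityError(
                    f"trials reference unregistered cues: {sorted(unknown_cue)[:5]}"
                )
            key = self.trials[["participant_id", "cue", "position"]]
            if key.duplicated().any():
                raise IntegrityError(
                    "duplicate (participant, cue, position) trial rows"
                )
        if self.registry["cue"].duplicated().any():
            raise IntegrityError("duplicate cues in registry")

    # ------------------------------------------------------------------
    def period_of(self) -> pd.Series:
        """participant_id -> period lookup."""
        return self.participants.set_index("participant_id")["period"]

    def trials_with_period(self) -> pd.DataFrame:
        """Trials joined with each participant's collection period."""
        return self.trials.merge(
            self.participants[["participant_id", "period"]],
            on="participant_id",
            how="left",
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "AssociationDataset":
        return AssociationDataset(
            self.participants.copy(),
            self.trials.copy(),
            self.registry.copy(),
            list(self.provenance),
        )


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------

_WIDE_COLUMNS = [
    "participant_id", "period", "gender", "age", "native_language",
    "education", "cue", "R1", "R2", "R3",
]
_LONG_COLUMNS = [
    "participant_id", "period", "gender", "age", "native_language",
    "education", "cue", "position", "response",
]


def _check_columns(df: pd.DataFrame, required: Sequence[str]) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")


def _map_sentinels(s: pd.Series, sentinel_strings: Mapping[str, str]) -> pd.Series:
    return s.replace(dict(sentinel_strings))


def read_association_table(
    path: str | Path,
    dialect: str = "wide",
    sentinel_strings: Mapping[str, str] = DEFAULT_SENTINEL_STRINGS,
    registry: pd.DataFrame | None = None,
) -> AssociationDataset:
    """Read a tab-separated association table in wide or long dialect.

    The wide dialect has one row per (participant, cue) with R1/R2/R3
    columns; the long dialect one row per response with a ``position``
    column.  Empty response cells denote absent responses.  When no
    registry is supplied, one is inferred from the observed cues with cue
    type ``filler`` (analyses that need experimental types require an
    explicit registry).
    """
    if dialect not in ("wide", "long"):
        raise ConfigurationError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    _check_columns(df, _WIDE_COLUMNS if dialect == "wide" else _LONG_COLUMNS)

    participants = (
        df[["participant_id", *DEMOGRAPHIC_COLUMNS]]
        .drop_duplicates(subset="participant_id")
        .reset_index(drop=True)
    )
    participants["age"] = pd.to_numeric(
        participants["age"].replace("", np.nan), errors="coerce"
    ).astype("Int64")

    if dialect == "wide":
        long = df.melt(
            id_vars=["participant_id", "cue"],
            value_vars=["R1", "R2", "R3"],
            var_name="position",
            value_name="response",
        )
    else:
        long = df[["participant_id", "cue", "position", "response"]].copy()
    long = long[long["response"] != ""].reset_index(drop=True)
    long["response"] = _map_sentinels(long["response"], sentinel_strings)

    if long[["participant_id", "cue", "position"]].duplicated().any():
        raise IntegrityError("duplicate (participant, cue, position) rows in input")

    if registry is None:
        periods = (
            long.merge(participants[["participant_id", "period"]],
                       on="participant_id")
            .groupby("cue")["period"]
            .agg(lambda s: "|".join(sorted(set(s))))
        )
        registry = pd.DataFrame(
            {
                "cue": periods.index,
                "cue_type": "filler",
                "presented_in": periods.values,
            }
        ).reset_index(drop=True)

    ds = AssociationDataset(
        participants=participants,
        trials=long.sort_values(
            ["participant_id", "cue", "position"]
        ).reset_index(drop=True),
        registry=registry.reset_index(drop=True),
        provenance=[f"read {dialect} table from {path}"],
    )
    ds.validate()
    return ds


def write_association_table(
    ds: AssociationDataset,
    path: str | Path,
    sentinel_strings: Mapping[str, str] = DEFAULT_SENTINEL_STRINGS,
) -> None:
    """Serialize to the canonical long-dialect TSV (deterministic ordering)."""
    inverse = {v: k for k, v in sentinel_strings.items()}
    out = ds.trials.merge(
        ds.participants, on="participant_id", how="left"
    )[_LONG_COLUMNS].copy()
    out["response"] = out["response"].replace(inverse)
    out["age"] = out["age"].astype(object).where(out["age"].notna(), "")
    out = out.sort_values(["participant_id", "cue", "position"]).reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_lexicon(path: str | Path) -> Lexicon:
    """Read a one-token-per-line UTF-8 word list."""
    words = frozenset(
        line.strip()
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    )
    return Lexicon(words)


def read_variant_map(path: str | Path) -> VariantMap:
    """Read a two-column ``variant<TAB>canonical`` TSV."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["variant", "canonical"],
        dtype=str, keep_default_na=False, encoding="utf-8",
    )
    return VariantMap(dict(zip(df["variant"], df["canonical"])))


def read_cue_registry(path: str | Path) -> pd.DataFrame:
    """Read a cue registry TSV with columns cue, cue_type[, presented_in]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     encoding="utf-8")
    _check_columns(df, ["cue", "cue_type"])
    if "presented_in" not in df.columns:
        df["presented_in"] = "precovid|covid"
    bad = set(df["cue_type"]) - set(CUE_TYPES)
    if bad:
        raise SchemaError(f"unknown cue types in registry: {sorted(bad)}")
    return df


# ----------------------------------------------------------------------
# Normalization
# ----------------------------------------------------------------------

_TAG_RE = re.compile(r"<[^>]*>")
_QUOTE_CHARS = "\"'“”‘’«»"
_FINAL_PUNCT_RE = re.compile(r"[.,;:!?¡¿…]+$")
_WS_RE = re.compile(r"\s+")


def normalize_token(token: str, lowercase: bool = True) -> str:
    """Normalize one raw response string.

    Removes markup tags, surrounding quotes and final punctuation, collapses
    internal whitespace and (by default) lowercases. Sentinels pass through
    untouched. The function is idempotent.
    """
    if token in SENTINELS:
        return token
    t = _TAG_RE.sub(" ", token)
    # quote-stripping and final-punctuation removal can expose each other
    # (e.g. '"casa".'), so iterate to a fixpoint
    while True:
        prev = t
        t = t.strip().strip(_QUOTE_CHARS)
        t = _FINAL_PUNCT_RE.sub("", t)
        if t == prev:
            break
    t = _WS_RE.sub(" ", t).strip()
    if lowercase:
        t = t.lower()
    return t


def normalize_tokens(
    ds: AssociationDataset,
    variant_map: VariantMap | None = None,
    lowercase: bool = True,
) -> AssociationDataset:
    """Normalize every response token and apply the variant map once.

    Cue strings in trials and registry are normalized with the same rules
    (variant replacement applies to responses only, mirroring the treatment
    of regional response variants in SWOW norming).
    """
    out = ds.copy()
    raw = out.trials["response"]
    norm = raw.map(lambda t: normalize_token(t, lowercase=lowercase))
    if variant_map is not None:
        n_variant = int((norm.map(variant_map.apply) != norm).sum())
        norm = norm.map(variant_map.apply)
    else:
        n_variant = 0
    n_changed = int((norm != raw).sum())
    out.trials["response"] = norm
    out.trials["cue"] = out.trials["cue"].map(
        lambda t: normalize_token(t, lowercase=lowercase)
    )
    out.registry["cue"] = out.registry["cue"].map(
        lambda t: normalize_token(t, lowercase=lowercase)
    )
    out.log(
        f"normalize_tokens: {n_changed} tokens altered "
        f"({n_variant} by variant replacement)"
    )
    return out


# ----------------------------------------------------------------------
# Participant exclusion
# ----------------------------------------------------------------------

RULE_NAMES = ("sentences", "uniqueness", "lexicon", "unknown")


def _participant_rule_flags(
    trials: pd.DataFrame,
    lexicon: Lexicon | None,
    thr: ExclusionThresholds,
) -> dict[str, list[str]]:
    """Evaluate the four exclusion rules on one participant's trials."""
    responses = trials["response"]
    tokens = responses[~responses.isin(SENTINELS)]
    n_tok = len(tokens)
    violated: list[str] = []

    if n_tok > 0:
        n_sentence = int(
            (tokens.str.split().str.len() >= thr.sentence_min_tokens).sum()
        )
        if n_sentence / n_tok > thr.sentence_frac:
            violated.append("sentences")
        if tokens.nunique() / n_tok < thr.unique_frac:
            violated.append("uniqueness")
        if lexicon is not None:
            n_in = sum(t in lexicon for t in tokens)
            if n_in / n_tok < thr.lexicon_frac:
                violated.append("lexicon")

    presented = trials["cue"].nunique()
    if presented > 0:
        unknown_cues = trials.loc[trials["response"] == UNKNOWN, "cue"].nunique()
        if unknown_cues / presented > thr.unknown_frac:
            violated.append("unknown")
    return violated


def filter_participants(
    ds: AssociationDataset,
    lexicon: Lexicon | None = None,
    thresholds: ExclusionThresholds = ExclusionThresholds(),
) -> tuple[AssociationDataset, dict]:
    """Remove participants violating any of the four SWOW exclusion rules.

    Rules are evaluated on each participant's full response set; sentinels
    are excluded from the denominators of the sentence/uniqueness/lexicon
    rules, while the unknown-word rule is computed over presented cues.
    Returns the filtered dataset and a JSON-serializable report with per-rule
    counts and per-participant triggering rules.
    """
    if lexicon is not None and len(lexicon) == 0:
        raise ConfigurationError(
            "in-lexicon rule enabled with an empty lexicon"
        )
    per_participant: dict[str, list[str]] = {}
    for pid, grp in ds.trials.groupby("participant_id", sort=True):
        rules = _participant_rule_flags(grp, lexicon, thresholds)
        if rules:
            per_participant[pid] = rules

    excluded = set(per_participant)
    out = ds.copy()
    out.participants = out.participants[
        ~out.participants["participant_id"].isin(excluded)
    ].reset_index(drop=True)
    out.trials = out.trials[
        ~out.trials["participant_id"].isin(excluded)
    ].reset_index(drop=True)

    report = {
        "rule_counts": {
            rule: sum(rule in v for v in per_participant.values())
            for rule in RULE_NAMES
        },
        "per_participant": per_participant,
        "n_before": int(len(ds.participants)),
        "n_excluded": len(excluded),
        "n_after": int(len(out.participants)),
        "thresholds": {
            "sentence_frac": thresholds.sentence_frac,
            "unique_frac": thresholds.unique_frac,
            "lexicon_frac": thresholds.lexicon_frac,
            "unknown_frac": thresholds.unknown_frac,
            "sentence_min_tokens": thresholds.sentence_min_tokens,
        },
    }
    out.log(
        f"filter_participants: excluded {len(excluded)} of "
        f"{len(ds.participants)} participants"
    )
    return out, report


# ----------------------------------------------------------------------
# Quota sampling
# ----------------------------------------------------------------------

def select_participant_quota(
    ds: AssociationDataset,
    quota: int = 60,
    priority: Sequence[Sequence[str]] = DEFAULT_LANGUAGE_PRIORITY,
    seed: int = 0,
) -> AssociationDataset:
    """Trim each (cue, period) cell to ``quota`` respondents.

    Respondents are kept by native-language priority tier first; within the
    tier that straddles the quota boundary, a uniform random subset is drawn
    with the given seed.  Cells at or under quota are kept whole (no
    randomness is consumed); under-quota cells emit a warning.
    """
    if quota < 0:
        raise ConfigurationError(f"quota must be non-negative, got {quota}")

    tier_of: dict[str, int] = {}
    for i, group in enumerate(priority):
        for lang in group:
            tier_of[lang] = i
    n_tiers = len(priority)

    info = ds.participants.set_index("participant_id")
    rng = np.random.default_rng(seed)
    twp = ds.trials_with_period()
    drop_keys: list[tuple[str, str]] = []  # (participant_id, cue)
    short_cells: list[tuple[str, str, int]] = []

    for (cue, period), grp in sorted(
        twp.groupby(["cue", "period"], sort=True), key=lambda kv: kv[0]
    ):
        pids = sorted(grp["participant_id"].unique())
        if len(pids) < quota:
            short_cells.append((cue, period, len(pids)))
            continue
        if len(pids) == quota:
            continue
        tiers = np.array(
            [tier_of.get(info.at[p, "native_language"], n_tiers) for p in pids]
        )
        keep: list[str] = []
        for tier in range(n_tiers + 1):
            members = [p for p, t in zip(pids, tiers) if t == tier]
            room = quota - len(keep)
            if room <= 0:
                break
            if len(members) <= room:
                keep.extend(members)
            else:
                chosen = rng.choice(len(members), size=room, replace=False)
                keep.extend(members[i] for i in sorted(chosen))
        dropped = set(pids) - set(keep)
        drop_keys.extend((p, cue) for p in dropped)

    if short_cells:
        sample = ", ".join(
            f"{c}/{p}: {n}" for c, p, n in short_cells[:5]
        )
        warnings.warn(
            f"{len(short_cells)} (cue, period) cell(s) under quota {quota}; "
            f"keeping all respondents there (first few: {sample})",
            stacklevel=2,
        )
    out = ds.copy()
    if drop_keys:
        key = pd.MultiIndex.from_frame(out.trials[["participant_id", "cue"]])
        out.trials = out.trials[~key.isin(drop_keys)].reset_index(drop=True)
        remaining = set(out.trials["participant_id"])
        out.participants = out.participants[
            out.participants["participant_id"].isin(remaining)
        ].reset_index(drop=True)
    out.log(
        f"select_participant_quota: quota={quota}, seed={seed}, "
        f"dropped {len(drop_keys)} (participant, cue) cells"
    )
    return out


# ----------------------------------------------------------------------
# Period-dataset assembly and counting
# ----------------------------------------------------------------------

def assemble_period_datasets(
    full: AssociationDataset,
    target_cues: Iterable[str],
) -> tuple[AssociationDataset, AssociationDataset]:
    """Split into Precovid and Covid analysis sets.

    Both outputs share all trials for non-target cues (either period); for
    target cues each output keeps only its own period's trials. This mirrors
    the construction of period-specific semantic spaces that differ only in
    the responses to the words under study.
    """
    target = set(target_cues)
    missing = target - set(full.registry["cue"])
    if missing:
        raise CueLookupError(
            f"target cues absent from registry: {sorted(missing)}"
        )
    twp = full.trials_with_period()
    is_target = twp["cue"].isin(target)

    outs = []
    for period in PERIODS:
        mask = ~is_target | (twp["period"] == period)
        trials = full.trials[mask.values].reset_index(drop=True)
        pids = set(trials["participant_id"])
        sub = AssociationDataset(
            participants=full.participants[
                full.participants["participant_id"].isin(pids)
            ].reset_index(drop=True),
            trials=trials,
            registry=full.registry.copy(),
            provenance=list(full.provenance)
            + [f"assemble_period_datasets: period={period}, "
               f"{len(target)} target cues"],
        )
        outs.append(sub)
    return outs[0], outs[1]


@dataclass
class FrequencyTable:
    """Per-(cue, period) response counts over normalized tokens.

    ``counts`` has columns cue, response, period, count; sentinels never
    appear as responses.  ``token_totals`` is indexed by (cue, period).
    """

    counts: pd.DataFrame
    token_totals: pd.Series

    def distribution(self, cue: str, period: str) -> pd.Series:
        """Raw counts for one cue in one period (response -> count)."""
        sub = self.counts[
            (self.counts["cue"] == cue) & (self.counts["period"] == period)
        ]
        if sub.empty:
            raise CueLookupError(f"cue {cue!r} has no counts in period {period!r}")
        return sub.set_index("response")["count"]

    def has(self, cue: str, period: str) -> bool:
        return (cue, period) in self.token_totals.index

    def cues_in_both_periods(self) -> list[str]:
        by_cue = self.counts.groupby("cue")["period"].nunique()
        return sorted(by_cue.index[by_cue == 2])


def count_responses(
    ds: AssociationDataset,
    positions: Sequence[str] = POSITIONS,
) -> FrequencyTable:
    """Tabulate non-sentinel response tokens at the selected positions."""
    if not positions:
        raise ConfigurationError("positions must be a non-empty subset of R1-R3")
    bad = set(positions) - set(POSITIONS)
    if bad:
        raise ConfigurationError(f"unknown positions: {sorted(bad)}")
    twp = ds.trials_with_period()
    sub = twp[
        twp["position"].isin(positions) & ~twp["response"].isin(SENTINELS)
    ]
    counts = (
        sub.groupby(["cue", "response", "period"], sort=True)
        .size()
        .rename("count")
        .reset_index()
    )
    token_totals = counts.groupby(["cue", "period"])["count"].sum()
    return FrequencyTable(counts=counts, token_totals=token_totals)
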