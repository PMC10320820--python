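"""Synthetic two-period association datasets with known ground truth.

The generator emulates the statistical structure the analyses assume: each
cue has a sparse categorical response distribution theta supported on a
cue-specific subset of the vocabulary (drawn with most mass on tokens that
are themselves cues, mirroring how distinct cues evoke largely distinct
associates) with Dirichlet weights within that support; Precovid responses
are multinomial draws from theta, and Covid responses for
designated "shifted" cues come from the mixture (1 - delta) * theta +
delta * phi, where phi concentrates on a small set of pandemic-sense words
and delta in [0, 1] is the shift magnitude.  Trials produce three distinct
responses (successive sampling without replacement), participants carry
demographics sampled from the study's cohort marginals, and optional
contaminant participants violate exactly one named exclusion rule each.
Everything is driven by a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import study_design
from .data import NO_MORE, UNKNOWN, AssociationDataset
from .errors import ConfigurationError

RULES = ("sentences", "uniqueness", "lexicon", "unknown")


@dataclass
class SimConfig:
    """Study-condition parameters for the generator.

    Defaults mirror the modeled study: 100 analysis cues split over four
    types, 60 respondents per cue per period, three responses per trial,
    and a shift magnitude of 0.5 applied to the pandemic cues.
    """

    n_cues_per_type: Mapping[str, int] = field(
        default_factory=lambda: {
            "control": 25, "pandemic": 25, "emotion": 25, "routine": 25,
            "filler": 150,
        }
    )
    n_extra_responses: int = 500       # response-only tokens (never cues)
    pandemic_sense_size: int = 10      # sense words, added as filler cues
    participants_per_cue_period: int = 60
    responses_per_trial: int = 3
    cues_per_participant: int = 15
    support_size: int = 40             # distinct associates per cue
    dirichlet_concentration: float = 0.3  # within-support concentration
    noncue_weight: float = 0.18        # prior weight of response-only tokens
    sense_coherence: float = 0.45      # how strongly sense words inter-associate
    sense_decay: float = 0.6           # geometric profile of the new-sense
                                       # mixture (1.0 = uniform over sense words)
    shift_magnitude: float = 0.5
    shifted_types: tuple[str, ...] = ("pandemic",)
    unknown_rate: float = 0.02         # per-trial chance of an unknown cue
    no_more_rate: float = 0.10         # per-trial chance of stopping after R1
    contamination_rates: Mapping[str, float] = field(
        default_factory=lambda: {r: 0.0 for r in RULES}
    )
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.shift_magnitude <= 1.0:
            raise ConfigurationError("shift_magnitude must be in [0, 1]")
        if any(n <= 0 for n in self.n_cues_per_type.values()):
            raise ConfigurationError("cue counts must be positive")
        if self.responses_per_trial < 1:
            raise ConfigurationError("responses_per_trial must be positive")
        if self.participants_per_cue_period < 1:
            raise ConfigurationError("participants_per_cue_period must be positive")
        if self.support_size < self.responses_per_trial:
            raise ConfigurationError(
                "support_size must be at least responses_per_trial for "
                "without-replacement draws"
            )


@dataclass
class GroundTruth:
    """True generating quantities for one synthetic dataset."""

    cues: pd.DataFrame           # cue, cue_type, shifted, delta
    vocabulary: list[str]        # full response vocabulary, ordered
    sense_words: list[str]
    theta_precovid: dict[str, np.ndarray]
    theta_covid: dict[str, np.ndarray]


def _cue_tokens(cfg: SimConfig) -> tuple[list[str], dict[str, str], list[str]]:
    """Cue token list, cue -> type map, and the sense-word tokens."""
    prefixes = {"control": "ctl", "pandemic": "pan",
                "emotion": "emo", "routine": "rut", "filler": "fil"}
    cues, cue_type = [], {}
    for t in sorted(cfg.n_cues_per_type):
        for i in range(cfg.n_cues_per_type[t]):
            tok = f"{prefixes.get(t, t)}{i:03d}"
            cues.append(tok)
            cue_type[tok] = t
    sense = [f"sns{i:03d}" for i in range(cfg.pandemic_sense_size)]
    for tok in sense:
        cues.append(tok)
        cue_type[tok] = "filler"
    return cues, cue_type, sense


def _sample_demographics(rng: np.random.Generator, period: str) -> dict:
    row = {"period": period}
    for fld in ("gender", "native_language", "education"):
        probs = study_design.demographic_probabilities(period, fld)
        cats = sorted(probs)
        row[fld] = rng.choice(cats, p=[probs[c] for c in cats])
    mean, sd = study_design.AGE_MEAN_SD[period]
    row["age"] = int(np.clip(round(rng.normal(mean, sd)), 18, 90))
    return row


def _gumbel_topk(
    rng: np.random.Generator, theta: np.ndarray, n_trials: int, k: int
) -> np.ndarray:
    """Draw k distinct indices per trial, proportional to theta without
    replacement (Gumbel top-k trick), vectorized over trials."""
    with np.errstate(divide="ignore"):
        logits = np.log(theta)
    noise = rng.gumbel(size=(n_trials, theta.size))
    scores = logits[None, :] + noise
    top = np.argpartition(-scores, k - 1, axis=1)[:, :k]
    # order within each trial by descending score (R1 = highest)
    order = np.argsort(-np.take_along_axis(scores, top, axis=1), axis=1)
    return np.take_along_axis(top, order, axis=1)


def generate_dataset(cfg: SimConfig) -> tuple[AssociationDataset, GroundTruth]:
    """Generate a two-period dataset plus its ground truth (fully seeded)."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cues, cue_type, sense_words = _cue_tokens(cfg)
    extra = [f"rsp{i:03d}" for i in range(cfg.n_extra_responses)]
    vocab = cues + extra
    V = len(vocab)
    if V < cfg.responses_per_trial:
        raise ConfigurationError(
            "vocabulary too small for without-replacement response draws"
        )

    weights = np.array(
        [1.0] * len(cues) + [cfg.noncue_weight] * len(extra)
    )
    support_probs = weights / weights.sum()
    m = min(cfg.support_size, V)
    sense_idx = [vocab.index(w) for w in sense_words]
    phi = np.zeros(V)
    if sense_idx:
        # a few sense words dominate the new sense (geometric profile),
        # the way a handful of pandemic words dominated new responses
        w_sense = cfg.sense_decay ** np.arange(len(sense_idx))
        phi[sense_idx] = w_sense / w_sense.sum()

    theta_pre: dict[str, np.ndarray] = {}
    theta_cov: dict[str, np.ndarray] = {}
    truth_rows = []
    for c in cues:
        support = rng.choice(V, size=m, replace=False, p=support_probs)
        theta = np.zeros(V)
        theta[support] = rng.dirichlet(
            np.full(m, cfg.dirichlet_concentration)
        )
        if c in sense_words:
            # sense words form a coherent semantic field: their responses
            # concentrate on the other sense words (in both periods), so a
            # cue shifted toward the field acquires its profile via the walk
            peers = np.zeros(V)
            others = [i for i in sense_idx if vocab[i] != c]
            if others:
                peers[others] = 1.0 / len(others)
                theta = (
                    cfg.sense_coherence * peers
                    + (1.0 - cfg.sense_coherence) * theta
                )
        shifted = cue_type[c] in cfg.shifted_types
        delta = cfg.shift_magnitude if shifted else 0.0
        theta_pre[c] = theta
        theta_cov[c] = (1.0 - delta) * theta + delta * phi if shifted else theta
        truth_rows.append(
            {"cue": c, "cue_type": cue_type[c], "shifted": shifted,
             "delta": delta}
        )

    # participants answer blocks of cues; each (cue, period) cell gets
    # exactly participants_per_cue_period respondents.  Blocks interleave
    # cue types (as in the source task, where each participant saw only a
    # few target cues among controls and fillers) so that no participant
    # answers a run of same-type cues
    by_type: dict[str, list[str]] = {}
    for c in cues:
        by_type.setdefault(cue_type[c], []).append(c)
    interleaved: list[str] = []
    lists = [by_type[t] for t in sorted(by_type)]
    longest = max(len(lst) for lst in lists)
    for i in range(longest):
        for lst in lists:
            if i < len(lst):
                interleaved.append(lst[i])
    blocks = [
        interleaved[i:i + cfg.cues_per_participant]
        for i in range(0, len(interleaved), cfg.cues_per_participant)
    ]
    participants = []
    trial_frames = []
    k = cfg.responses_per_trial
    for period in ("precovid", "covid"):
        tag = "pre" if period == "precovid" else "cov"
        thetas = theta_pre if period == "precovid" else theta_cov
        for b, block in enumerate(blocks):
            pids = [
                f"{tag}_b{b:02d}_p{i:03d}"
                for i in range(cfg.participants_per_cue_period)
            ]
            for pid in pids:
                participants.append(
                    {"participant_id": pid, **_sample_demographics(rng, period)}
                )
            n = len(pids)
            for c in block:
                draws = _gumbel_topk(rng, thetas[c], n, k)
                unknown = rng.random(n) < cfg.unknown_rate
                stop_early = rng.random(n) < cfg.no_more_rate
                for i, pid in enumerate(pids):
                    if unknown[i]:
                        trial_frames.append((pid, c, "R1", UNKNOWN))
                        continue
                    trial_frames.append((pid, c, "R1", vocab[draws[i, 0]]))
                    if stop_early[i] and k > 1:
                        trial_frames.append((pid, c, "R2", NO_MORE))
                        if k > 2:
                            trial_frames.append((pid, c, "R3", NO_MORE))
                    else:
                        for j in range(1, k):
                            trial_frames.append(
                                (pid, c, f"R{j + 1}", vocab[draws[i, j]])
                            )

    registry = pd.DataFrame(
        {
            "cue": cues,
            "cue_type": [cue_type[c] for c in cues],
            "presented_in": "precovid|covid",
        }
    ).sort_values("cue").reset_index(drop=True)
    ds = AssociationDataset(
        participants=pd.DataFrame(participants)[
            ["participant_id", "period", "gender", "age",
             "native_language", "education"]
        ],
        trials=pd.DataFrame(
            trial_frames, columns=["participant_id", "cue", "position", "response"]
        ),
        registry=registry,
        provenance=[f"generate_dataset(seed={cfg.seed}, "
                    f"delta={cfg.shift_magnitude})"],
    )
    truth = GroundTruth(
        cues=pd.DataFrame(truth_rows),
        vocabulary=vocab,
        sense_words=sense_words,
        theta_precovid=theta_pre,
        theta_covid=theta_cov,
    )
    if any(r > 0 for r in cfg.contamination_rates.values()):
        ds, _ = inject_violators(ds, cfg.contamination_rates, seed=cfg.seed + 1)
    return ds, truth


# ----------------------------------------------------------------------
# Contaminant participants
# ----------------------------------------------------------------------

def inject_violators(
    ds: AssociationDataset,
    rates: Mapping[str, float],
    seed: int = 0,
) -> tuple[AssociationDataset, dict[str, str]]:
    """Add participants engineered to violate exactly one exclusion rule each.

    ``rates`` maps rule names (sentences / uniqueness / lexicon / unknown)
    to fractions of the current participant count; returns the augmented
    dataset and a participant_id -> intended-rule labeling.  Violators use
    in-vocabulary tokens everywhere except where the targeted rule requires
    otherwise, so no other rule is tripped.
    """
    bad = set(rates) - set(RULES)
    if bad:
        raise ConfigurationError(f"unknown exclusion rules: {sorted(bad)}")
    rng = np.random.default_rng(seed)
    n_base = len(ds.participants)
    reg_cues = sorted(ds.registry["cue"])
    if len(reg_cues) < 5:
        raise ConfigurationError("need at least 5 registry cues to inject violators")
    vocab_tokens = sorted(
        set(ds.trials.loc[~ds.trials["response"].isin((NO_MORE, UNKNOWN)),
                          "response"])
        | set(reg_cues)
    )

    out = ds.copy()
    labels: dict[str, str] = {}
    new_participants = []
    new_trials = []
    counter = 0
    for rule in RULES:
        n_inject = int(round(rates.get(rule, 0.0) * n_base))
        for _ in range(n_inject):
            pid = f"viol_{rule}_{counter:04d}"
            counter += 1
            labels[pid] = rule
            period = "covid" if counter % 2 == 0 else "precovid"
            new_participants.append(
                {"participant_id": pid, **_sample_demographics(rng, period)}
            )
            clean = list(
                rng.choice(vocab_tokens, size=12, replace=False)
            )
            cues4 = reg_cues[:4]
            if rule == "sentences":
                # 4 of 12 responses are >=3-token strings (33% > 30%);
                # 8 in-vocabulary tokens keep the lexicon rule at 66% >= 60%
                resp = [
                    f"frase larga {counter} {idx}" if idx % 3 == 0 else clean[idx]
                    for idx in range(12)
                ]
            elif rule == "uniqueness":
                resp = [clean[0]] * 12
            elif rule == "lexicon":
                # 6 of 12 responses are out-of-lexicon gibberish (50% < 60%)
                resp = [
                    f"zzq{counter}x{idx}" if idx < 6 else clean[idx]
                    for idx in range(12)
                ]
            else:  # unknown: 4 of 5 presented cues unknown (80% > 60%)
                cues5 = reg_cues[:5]
                for c in cues5[:4]:
                    new_trials.append((pid, c, "R1", UNKNOWN))
                for j, pos in enumerate(("R1", "R2", "R3")):
                    new_trials.append((pid, cues5[4], pos, clean[j]))
                continue
            it = iter(resp)
            for c in cues4:
                for pos in ("R1", "R2", "R3"):
                    new_trials.append((pid, c, pos, next(it)))

    if new_participants:
        out.participants = pd.concat(
            [out.participants, pd.DataFrame(new_participants)[
                out.participants.columns]],
            ignore_index=True,
        )
        out.trials = pd.concat(
            [out.trials, pd.DataFrame(
                new_trials,
                columns=["participant_id", "cue", "position", "response"])],
            ignore_index=True,
        )
        out.log(f"inject_violators: added {len(new_participants)} contaminants")
    return out, labels
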