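"""Sense ratings and the similarity-matched permutation test for sense shift.

A sense of a polysemous cue is anchored by two paradigm words; the cue's
rating for that sense is the sum of its cosine similarities to the two
anchors.  A directional sense shift is the Covid-minus-Precovid difference
in that rating.  Its significance is assessed against a matched null: the
same shift recomputed for random paradigm pairs whose within-pair cosine is
within a tolerance (default +-0.05) of the anchor pair's, so that the null
pairs are as geometrically "tight" as the real sense anchors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, CueLookupError, ShortfallError
from .semspace import SimilarityMatrix


@dataclass(frozen=True)
class SenseAnchor:
    """A named sense anchored by an ordered pair of paradigm words."""

    label: str
    paradigm: tuple[str, str]

    def __post_init__(self):
        if self.paradigm[0] == self.paradigm[1]:
            raise ConfigurationError("paradigm words must be distinct")


@dataclass
class ShiftTest:
    """Result of one matched-permutation sense-shift test."""

    cue: str
    anchor: SenseAnchor
    observed_shift: float
    null_shifts: np.ndarray
    p_value: float
    tolerance: float
    seed: int

    def to_dict(self, include_null: bool = True) -> dict:
        d = {
            "cue": self.cue,
            "sense_label": self.anchor.label,
            "paradigm": list(self.anchor.paradigm),
            "observed_shift": self.observed_shift,
            "p_value": self.p_value,
            "n_perm": int(len(self.null_shifts)),
            "tolerance": self.tolerance,
            "seed": self.seed,
        }
        if include_null:
            d["null_shifts"] = [float(x) for x in self.null_shifts]
        return d


def sense_rating(sim: SimilarityMatrix, cue: str, anchor: SenseAnchor) -> float:
    """Sum of the cue's similarities to the sense's two paradigm words."""
    w1, w2 = anchor.paradigm
    for w in (cue, w1, w2):
        if w not in sim:
            raise CueLookupError(f"word {w!r} not in vocabulary")
    return sim.sim(cue, w1) + sim.sim(cue, w2)


def sense_shift(
    sim_pre: SimilarityMatrix,
    sim_cov: SimilarityMatrix,
    cue: str,
    anchor: SenseAnchor,
) -> float:
    """Covid-minus-Precovid change in the cue's rating for one sense."""
    return sense_rating(sim_cov, cue, anchor) - sense_rating(sim_pre, cue, anchor)


def sample_matched_pairs(
    sim: SimilarityMatrix,
    anchor: SenseAnchor,
    n_perm: int = 1000,
    tol: float = 0.05,
    seed: int = 0,
    exclude: frozenset[str] | set[str] = frozenset(),
) -> list[tuple[str, str]]:
    """Random paradigm pairs similarity-matched to the anchor pair.

    Candidates are all unordered vocabulary pairs (minus excluded words)
    whose cosine lies within ``tol`` of the anchor pair's cosine; ``n_perm``
    of them are drawn uniformly without replacement with the given seed.
    Raises :class:`ShortfallError` when fewer than ``n_perm`` are eligible.
    """
    a1, a2 = anchor.paradigm
    target = sim.sim(a1, a2)
    excluded = set(exclude) | {a1, a2}
    position = {w: i for i, w in enumerate(sim.vocabulary)}
    words = [w for w in sim.vocabulary if w not in excluded]
    idx = np.array([position[w] for w in words])
    vals = sim.values[np.ix_(idx, idx)]
    iu = np.triu_indices(len(words), k=1)
    ok = np.abs(vals[iu] - target) <= tol
    eligible = np.flatnonzero(ok)
    if len(eligible) < n_perm:
        raise ShortfallError(len(eligible), n_perm)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(eligible, size=n_perm, replace=False)
    return [(words[iu[0][c]], words[iu[1][c]]) for c in chosen]


def permutation_test(
    sim_pre: SimilarityMatrix,
    sim_cov: SimilarityMatrix,
    cue: str,
    anchor: SenseAnchor,
    n_perm: int = 1000,
    tol: float = 0.05,
    seed: int = 0,
) -> ShiftTest:
    """One-sided matched permutation test for a directional sense shift.

    Pair eligibility is matched on the Precovid similarity matrix.  The
    p-value uses the add-one estimator (1 + #{null >= observed}) /
    (1 + n_perm), so it is never exactly zero.
    """
    observed = sense_shift(sim_pre, sim_cov, cue, anchor)
    pairs = sample_matched_pairs(
        sim_pre, anchor, n_perm=n_perm, tol=tol, seed=seed,
        exclude={cue, *anchor.paradigm},
    )
    null = np.array(
        [
            sense_shift(
                sim_pre, sim_cov, cue,
                SenseAnchor(label="null", paradigm=pair),
            )
            for pair in pairs
        ]
    )
    p = (1.0 + int((null >= observed).sum())) / (1.0 + n_perm)
    return ShiftTest(
        cue=cue,
        anchor=anchor,
        observed_shift=float(observed),
        null_shifts=null,
        p_value=float(p),
        tolerance=tol,
        seed=seed,
    )


def sense_shift_contrast(
    sim_pre: SimilarityMatrix,
    sim_cov: SimilarityMatrix,
    cue: str,
    new_sense: SenseAnchor,
    old_sense: SenseAnchor,
) -> float:
    """Two-sense contrast variant: (shift toward the new sense) minus
    (shift toward the old sense)."""
    return sense_shift(sim_pre, sim_cov, cue, new_sense) - sense_shift(
        sim_pre, sim_cov, cue, old_sense
    )


def read_anchors(path: str | Path) -> pd.DataFrame:
    """Read a sense-anchor TSV with columns cue, sense_label,
    paradigm_word_1, paradigm_word_2[, predicted_direction]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False,
                     encoding="utf-8")
    required = ["cue", "sense_label", "paradigm_word_1", "paradigm_word_2"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"anchor file missing column(s): {missing}")
    return df


def write_shift_tests(tests: list[ShiftTest], tsv_path, json_path=None) -> None:
    """Serialize shift tests as a summary TSV and a full-audit JSON."""
    rows = [t.to_dict(include_null=False) for t in tests]
    pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        payload = [t.to_dict(include_null=True) for t in tests]
        Path(json_path).write_text(json.dumps(payload, indent=1))
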