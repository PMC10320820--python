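"""Data model: readers, normalization, exclusion rules, quota, assembly."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lexidrift as lx
from lexidrift.data import (
    NO_MORE,
    UNKNOWN,
    count_responses,
)
from lexidrift.errors import (
    ConfigurationError,
    CueLookupError,
    IntegrityError,
    SchemaError,
)


# ----------------------------------------------------------------------
# Token normalization
# ----------------------------------------------------------------------

@pytest.mark.parametrize("raw,expected", [
    ("Casa", "casa"),
    ("  dos   palabras ", "dos palabras"),
    ('"casa"', "casa"),
    ("casa.", "casa"),
    ('"casa".', "casa"),      # interleaved quotes/punctuation to a fixpoint
    ("casa!?", "casa"),
    ("<b>negrita</b>", "negrita"),
    ("año", "año"),
])
def test_normalize_token_cases(raw, expected):
    assert lx.normalize_token(raw) == expected


def test_normalize_token_keeps_sentinels():
    assert lx.normalize_token(NO_MORE) == NO_MORE
    assert lx.normalize_token(UNKNOWN) == UNKNOWN


@given(st.text(max_size=40))
@settings(max_examples=200, deadline=None)
def test_normalize_token_idempotent(s):
    once = lx.normalize_token(s)
    assert lx.normalize_token(once) == once


def test_variant_map_must_be_idempotent():
    with pytest.raises(ConfigurationError):
        lx.VariantMap({"a": "b", "b": "c"})  # canonical 'b' is also a key
    vm = lx.VariantMap({"perrito": "perro"})
    assert vm.apply("perrito") == "perro"
    assert vm.apply("gato") == "gato"


def test_normalize_tokens_applies_variants_to_responses_only(tiny_wide_tsv):
    ds = lx.read_association_table(tiny_wide_tsv)
    vm = lx.VariantMap({"casa": "hogar"})  # 'casa' is also a cue
    out = lx.normalize_tokens(ds, vm)
    assert set(out.trials["cue"]) == {"casa", "sol"}  # cues untouched
    assert "casa" not in set(out.trials["response"])


# ----------------------------------------------------------------------
# Readers / writers
# ----------------------------------------------------------------------

def test_read_wide_table(tiny_wide_tsv):
    ds = lx.read_association_table(tiny_wide_tsv)
    assert len(ds.participants) == 3
    # blank cells are dropped, sentinel strings are mapped
    p1_sol = ds.trials[(ds.trials["participant_id"] == "p1")
                       & (ds.trials["cue"] == "sol")]
    assert list(p1_sol["response"]) == ["luna", NO_MORE]
    p3_sol = ds.trials[(ds.trials["participant_id"] == "p3")
                       & (ds.trials["cue"] == "sol")]
    assert list(p3_sol["response"]) == [UNKNOWN]
    # inferred registry covers the observed cues as fillers
    assert sorted(ds.registry["cue"]) == ["casa", "sol"]
    assert set(ds.registry["cue_type"]) == {"filler"}


def test_missing_column_raises(tmp_path):
    path = tmp_path / "bad.tsv"
    pd.DataFrame({"participant_id": ["p"], "cue": ["c"]}).to_csv(
        path, sep="\t", index=False
    )
    with pytest.raises(SchemaError, match="missing"):
        lx.read_association_table(path)


def test_duplicate_trial_rows_raise(tmp_path):
    df = pd.DataFrame([
        ("p1", "precovid", "female", "30", "Uruguay-Rioplatense",
         "university", "casa", "R1", "hogar"),
        ("p1", "precovid", "female", "30", "Uruguay-Rioplatense",
         "university", "casa", "R1", "techo"),
    ], columns=["participant_id", "period", "gender", "age",
                "native_language", "education", "cue", "position",
                "response"])
    path = tmp_path / "dup.tsv"
    df.to_csv(path, sep="\t", index=False)
    with pytest.raises(IntegrityError, match="duplicate"):
        lx.read_association_table(path, dialect="long")


def test_round_trip_is_byte_identical(tiny_wide_tsv, tmp_path):
    ds = lx.read_association_table(tiny_wide_tsv)
    p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
    lx.write_association_table(ds, p1)
    ds2 = lx.read_association_table(p1, dialect="long")
    lx.write_association_table(ds2, p2)
    assert p1.read_bytes() == p2.read_bytes()
    pd.testing.assert_frame_equal(ds.trials, ds2.trials)


# ----------------------------------------------------------------------
# Exclusion rules (strict inequalities at the thresholds)
# ----------------------------------------------------------------------

def _one_participant(responses, cues=None, period="precovid"):
    """Dataset with a single participant giving the listed R1 responses."""
    cues = cues or [f"cue{i:02d}" for i in range(len(responses))]
    trials = pd.DataFrame({
        "participant_id": "p0", "cue": cues, "position": "R1",
        "response": responses,
    })
    participants = pd.DataFrame([{
        "participant_id": "p0", "period": period, "gender": "female",
        "age": 30, "native_language": "Uruguay-Rioplatense",
        "education": "university",
    }])
    registry = pd.DataFrame({
        "cue": sorted(set(cues)), "cue_type": "filler",
        "presented_in": period,
    })
    ds = lx.AssociationDataset(participants, trials, registry, [])
    ds.validate()
    return ds


WORDS = [f"palabra{i}" for i in range(10)]
LEX = lx.Lexicon(frozenset(WORDS))


def _rules(ds, lexicon=LEX):
    _, report = lx.filter_participants(ds, lexicon)
    return report["per_participant"].get("p0", [])


def test_sentence_rule_strictly_greater():
    sentence = "una frase larga"
    # 3 of 10 = 30%: not excluded (rule needs > 30%)
    ds = _one_participant([sentence] * 3 + WORDS[:7])
    assert "sentences" not in _rules(ds)
    # 4 of 10 = 40%: excluded
    ds = _one_participant([sentence + f" {i}" for i in range(4)] + WORDS[:6])
    assert "sentences" in _rules(ds)


def test_uniqueness_rule_strictly_less():
    # 8 unique of 10 = 80%: kept (rule needs < 80%)
    ds = _one_participant(WORDS[:8] + WORDS[:2])
    assert "uniqueness" not in _rules(ds)
    # 7 unique of 10 = 70%: excluded
    ds = _one_participant(WORDS[:7] + WORDS[:3])
    assert "uniqueness" in _rules(ds)


def test_lexicon_rule_strictly_less():
    oov = [f"zzq{i}" for i in range(10)]
    # 6 of 10 in lexicon = 60%: kept (rule needs < 60%)
    ds = _one_participant(WORDS[:6] + oov[:4])
    assert "lexicon" not in _rules(ds)
    # 5 of 10 = 50%: excluded
    ds = _one_participant(WORDS[:5] + oov[:5])
    assert "lexicon" in _rules(ds)


def test_unknown_rule_over_presented_cues():
    # 3 of 5 cues unknown = 60%: kept (rule needs > 60%)
    ds = _one_participant([UNKNOWN] * 3 + WORDS[:2])
    assert "unknown" not in _rules(ds)
    # 4 of 5 = 80%: excluded
    ds = _one_participant([UNKNOWN] * 4 + WORDS[:1])
    assert "unknown" in _rules(ds)


def test_sentinels_leave_rule_denominators():
    # 5 real tokens, all unique, plus 5 no-more sentinels: kept
    ds = _one_participant(WORDS[:5] + [NO_MORE] * 5)
    assert _rules(ds) == []


def test_empty_lexicon_is_a_configuration_error():
    ds = _one_participant(WORDS[:5])
    with pytest.raises(ConfigurationError):
        lx.filter_participants(ds, lx.Lexicon(frozenset()))


def test_no_lexicon_disables_lexicon_rule():
    oov = [f"zzq{i}" for i in range(10)]
    ds = _one_participant(oov)
    assert _rules(ds, lexicon=None) == []


# ----------------------------------------------------------------------
# Quota sampling
# ----------------------------------------------------------------------

def _quota_dataset(n_by_lang, cue="casa", period="covid"):
    rows, parts = [], []
    i = 0
    for lang, n in n_by_lang.items():
        for _ in range(n):
            pid = f"p{i:03d}"
            i += 1
            parts.append({
                "participant_id": pid, "period": period, "gender": "female",
                "age": 30, "native_language": lang, "education": "university",
            })
            rows.append({"participant_id": pid, "cue": cue,
                         "position": "R1", "response": f"resp{i:03d}"})
    registry = pd.DataFrame({"cue": [cue], "cue_type": "control",
                             "presented_in": period})
    ds = lx.AssociationDataset(pd.DataFrame(parts), pd.DataFrame(rows),
                               registry, [])
    ds.validate()
    return ds


def test_quota_prefers_rioplatense_tier():
    ds = _quota_dataset({"Uruguay-Rioplatense": 40,
                         "Argentina-Rioplatense": 15,
                         "Argentina-Cordobés": 30})
    out = lx.select_participant_quota(ds, quota=60, seed=0)
    langs = out.participants["native_language"].value_counts()
    # the whole first tier is kept; the second tier fills the remainder
    assert langs["Uruguay-Rioplatense"] == 40
    assert langs["Argentina-Rioplatense"] == 15
    assert langs["Argentina-Cordobés"] == 5
    assert len(out.participants) == 60


def test_quota_is_deterministic_and_seed_sensitive():
    ds = _quota_dataset({"Uruguay-Rioplatense": 100})
    a = lx.select_participant_quota(ds, quota=60, seed=1)
    b = lx.select_participant_quota(ds, quota=60, seed=1)
    c = lx.select_participant_quota(ds, quota=60, seed=2)
    assert list(a.participants["participant_id"]) == \
        list(b.participants["participant_id"])
    assert list(a.participants["participant_id"]) != \
        list(c.participants["participant_id"])


def test_quota_no_randomness_at_or_under_quota():
    ds = _quota_dataset({"Uruguay-Rioplatense": 60})
    out = lx.select_participant_quota(ds, quota=60, seed=0)
    assert len(out.participants) == 60
    ds_small = _quota_dataset({"Uruguay-Rioplatense": 10})
    with pytest.warns(UserWarning, match="under quota"):
        out = lx.select_participant_quota(ds_small, quota=60, seed=0)
    assert len(out.participants) == 10


# ----------------------------------------------------------------------
# Period assembly and counting
# ----------------------------------------------------------------------

def test_assemble_period_datasets_restricts_target_cues(small_sim):
    ds, truth = small_sim
    targets = sorted(truth.cues["cue"])
    pre, cov = lx.assemble_period_datasets(ds, targets)
    assert set(pre.participants["period"]) == {"precovid"}
    assert set(cov.participants["period"]) == {"covid"}
    # target cues appear in both halves, restricted to their own period
    assert set(targets) <= set(pre.trials["cue"])
    assert set(targets) <= set(cov.trials["cue"])


def test_assemble_unregistered_cue_raises(small_sim):
    ds, _ = small_sim
    with pytest.raises(CueLookupError):
        lx.assemble_period_datasets(ds, ["palabra-inexistente"])


def test_count_responses_positions_subset(tiny_wide_tsv):
    ds = lx.read_association_table(tiny_wide_tsv)
    ft_all = count_responses(ds)
    ft_r1 = count_responses(ds, positions=("R1",))
    # R1 only: one token per (participant, cue) trial, sentinels excluded
    assert ft_r1.token_totals[("casa", "precovid")] == 2
    assert ft_all.token_totals[("casa", "precovid")] == 6
    assert NO_MORE not in set(ft_all.counts["response"])
    assert UNKNOWN not in set(ft_all.counts["response"])
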