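"""Shared fixtures: tiny hand-built datasets and seeded simulated ones."""

from __future__ import annotations

import pandas as pd
import pytest

import lexidrift as lx
from lexidrift.simulate import SimConfig, generate_dataset

TARGET_TYPES = ("control", "pandemic", "emotion", "routine")


def small_sim_config(**overrides) -> SimConfig:
    """A reduced-scale generator configuration for fast structural tests."""
    kwargs = dict(
        n_cues_per_type={
            "control": 6, "pandemic": 6, "emotion": 6, "routine": 6,
            "filler": 12,
        },
        n_extra_responses=120,
        pandemic_sense_size=6,
        participants_per_cue_period=20,
        cues_per_participant=6,
        support_size=20,
        seed=0,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def build_spaces(ds, alpha=0.75):
    """Period semantic spaces for a dataset's target cues."""
    targets = sorted(
        ds.registry.loc[ds.registry["cue_type"].isin(TARGET_TYPES), "cue"]
    )
    pre_ds, cov_ds = lx.assemble_period_datasets(ds, targets)
    _, sim_pre = lx.build_semantic_space(pre_ds, alpha=alpha, period="precovid")
    _, sim_cov = lx.build_semantic_space(cov_ds, alpha=alpha, period="covid")
    return sim_pre, sim_cov


def mirror_periods(ds):
    """Clone every Precovid participant into an identical Covid twin.

    The result has byte-identical response data in both periods, the
    degenerate case in which every drift measure must be exactly zero.
    """
    pre_ids = set(
        ds.participants.loc[ds.participants["period"] == "precovid",
                            "participant_id"]
    )
    parts = ds.participants[
        ds.participants["participant_id"].isin(pre_ids)
    ].reset_index(drop=True)
    trials = ds.trials[
        ds.trials["participant_id"].isin(pre_ids)
    ].reset_index(drop=True)

    twin_parts = parts.copy()
    twin_parts["participant_id"] = "c_" + twin_parts["participant_id"]
    twin_parts["period"] = "covid"
    twin_trials = trials.copy()
    twin_trials["participant_id"] = "c_" + twin_trials["participant_id"]

    registry = ds.registry.copy()
    registry["presented_in"] = "both"
    out = lx.AssociationDataset(
        participants=pd.concat([parts, twin_parts], ignore_index=True),
        trials=pd.concat([trials, twin_trials], ignore_index=True),
        registry=registry,
        provenance=["mirrored precovid into covid"],
    )
    out.validate()
    return out


@pytest.fixture(scope="session")
def default_sim():
    """One study-scale simulated dataset at the generator defaults."""
    return generate_dataset(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_spaces(default_sim):
    ds, _ = default_sim
    return build_spaces(ds)


@pytest.fixture(scope="session")
def small_sim():
    return generate_dataset(small_sim_config())


@pytest.fixture()
def tiny_wide_tsv(tmp_path):
    """A 3-participant wide-format table exercising sentinels and periods."""
    rows = [
        # pid, period, gender, age, lang, edu, cue, R1, R2, R3
        ("p1", "precovid", "female", "30", "Uruguay-Rioplatense",
         "university", "casa", "hogar", "puerta", "techo"),
        ("p1", "precovid", "female", "30", "Uruguay-Rioplatense",
         "university", "sol", "luna", "No more responses", ""),
        ("p2", "precovid", "male", "45", "Argentina-Rioplatense",
         "secondary", "casa", "hogar", "familia", "ladrillo"),
        ("p3", "covid", "X", "", "Argentina-Cordobés",
         "postgraduate", "casa", "encierro", "hogar", "cuarentena"),
        ("p3", "covid", "X", "", "Argentina-Cordobés",
         "postgraduate", "sol", "Unknown word", "", ""),
    ]
    df = pd.DataFrame(
        rows,
        columns=["participant_id", "period", "gender", "age",
                 "native_language", "education", "cue", "R1", "R2", "R3"],
    )
    path = tmp_path / "tiny.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path
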