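"""End-to-end orchestration of the drift-analysis stages.

Stages run in order preprocess -> drift -> semspace -> senseshift; each
writes its tabular/JSON artifacts under the configured output directory and
contributes counts to a run manifest that suffices to reproduce the run
(config hash, seed, package version, per-stage row counts).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .data import (
    AssociationDataset,
    ExclusionThresholds,
    assemble_period_datasets,
    count_responses,
    filter_participants,
    normalize_tokens,
    read_association_table,
    read_cue_registry,
    read_lexicon,
    read_variant_map,
    select_participant_quota,
    write_association_table,
)
from .drift import drift_table, fit_drift_models
from .semspace import (
    build_semantic_space,
    fit_ratio_model,
    neighbor_ratio_table,
)
from .senseshift import SenseAnchor, permutation_test, read_anchors, write_shift_tests

STAGES = ("preprocess", "drift", "semspace", "senseshift")


def _sniff_dialect(path) -> str:
    """Choose the table dialect from the header: a ``position`` column
    marks the long format, R1/R2/R3 columns the wide one."""
    header = pd.read_csv(path, sep="\t", nrows=0).columns
    return "long" if "position" in header else "wide"


def _target_cues(registry: pd.DataFrame) -> list[str]:
    return sorted(
        registry.loc[
            registry["cue_type"].isin(
                ("control", "pandemic", "emotion", "routine")
            ),
            "cue",
        ]
    )


def run_pipeline(
    cfg: PipelineConfig,
    stages: tuple[str, ...] = STAGES,
    dataset: AssociationDataset | None = None,
) -> dict:
    """Run the requested stages and return the run manifest.

    A dataset may be passed directly (e.g., from the simulator); otherwise
    it is read from ``cfg.data_path``.  Artifacts land under
    ``cfg.output_dir``; input files are never modified.
    """
    cfg.validate()
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": cfg.to_dict(),
        "config_digest": cfg.digest(),
        "version": __version__,
        "python": platform.python_version(),
        "stages": {},
        "status": "running",
    }

    def _write_manifest():
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    try:
        if dataset is None:
            registry = (
                read_cue_registry(cfg.registry_path)
                if cfg.registry_path else None
            )
            dialect = (
                _sniff_dialect(cfg.data_path)
                if cfg.data_dialect == "auto" else cfg.data_dialect
            )
            dataset = read_association_table(
                cfg.data_path, dialect=dialect, registry=registry
            )
        ds = dataset

        if "preprocess" in stages:
            vm = (read_variant_map(cfg.variant_map_path)
                  if cfg.variant_map_path else None)
            lex = read_lexicon(cfg.lexicon_path) if cfg.lexicon_path else None
            ds = normalize_tokens(ds, vm)
            thresholds = ExclusionThresholds(
                sentence_frac=cfg.sentence_frac,
                unique_frac=cfg.unique_frac,
                lexicon_frac=cfg.lexicon_frac,
                unknown_frac=cfg.unknown_frac,
            )
            ds, report = filter_participants(ds, lex, thresholds)
            ds = select_participant_quota(ds, quota=cfg.quota, seed=cfg.seed)
            write_association_table(ds, out / "preprocessed.tsv")
            (out / "exclusion_report.json").write_text(
                json.dumps(report, indent=1)
            )
            manifest["stages"]["preprocess"] = {
                "n_participants": int(len(ds.participants)),
                "n_trials": int(len(ds.trials)),
                "n_excluded": report["n_excluded"],
            }
            _write_manifest()

        ft = count_responses(ds, positions=cfg.positions)

        if "drift" in stages:
            table = drift_table(ft, ds.registry, pseudocount=cfg.pseudocount)
            table.to_csv(out / "drift_table.tsv", sep="\t", index=False)
            models = {}
            if table["cue_type"].nunique() >= 2:
                for resp in ("proportion_new", "kl_nats"):
                    models[resp] = fit_drift_models(table, resp).to_dict()
            (out / "drift_models.json").write_text(json.dumps(models, indent=1))
            manifest["stages"]["drift"] = {"n_cues": int(len(table))}
            _write_manifest()

        sim_pre = sim_cov = None
        if "semspace" in stages or "senseshift" in stages:
            targets = _target_cues(ds.registry)
            pre_ds, cov_ds = assemble_period_datasets(ds, targets)
            _, sim_pre = build_semantic_space(
                pre_ds, alpha=cfg.alpha, positions=cfg.positions,
                marginal=cfg.ppmi_marginal, period="precovid",
            )
            _, sim_cov = build_semantic_space(
                cov_ds, alpha=cfg.alpha, positions=cfg.positions,
                marginal=cfg.ppmi_marginal, period="covid",
            )

        if "semspace" in stages:
            ratios = neighbor_ratio_table(
                sim_pre, sim_cov, ds.registry, k=cfg.k_neighbors
            )
            ratios.to_csv(out / "neighbor_ratios.tsv", sep="\t", index=False)
            model = {}
            if (ratios["cue_type"].nunique() >= 2
                    and ratios["category"].nunique() >= 2):
                model = fit_ratio_model(ratios).to_dict()
            (out / "ratio_model.json").write_text(json.dumps(model, indent=1))
            manifest["stages"]["semspace"] = {
                "n_cue_neighbor_pairs": int(len(ratios)),
                "vocab_precovid": len(sim_pre.vocabulary),
                "vocab_covid": len(sim_cov.vocabulary),
            }
            _write_manifest()

        if "senseshift" in stages:
            if not cfg.anchors_path:
                raise ValueError("senseshift stage requires anchors_path")
            anchors = read_anchors(cfg.anchors_path)
            tests = []
            for _, row in anchors.iterrows():
                anchor = SenseAnchor(
                    label=row["sense_label"],
                    paradigm=(row["paradigm_word_1"], row["paradigm_word_2"]),
                )
                tests.append(
                    permutation_test(
                        sim_pre, sim_cov, row["cue"], anchor,
                        n_perm=cfg.n_perm, tol=cfg.tol, seed=cfg.seed,
                    )
                )
            write_shift_tests(
                tests, out / "sense_shifts.tsv", out / "sense_shifts.json"
            )
            manifest["stages"]["senseshift"] = {"n_tests": len(tests)}
            _write_manifest()

        manifest["status"] = "ok"
    except Exception as e:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(e).__name__}: {e}"
        _write_manifest()
        raise
    _write_manifest()
    return manifest
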