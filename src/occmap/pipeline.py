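"""End-to-end orchestration: validate -> match -> CV -> permutation -> map -> report.

A run is configured by a single mapping (usually a YAML file): either paths
to a stats directory + metadata table, or a synthetic cohort specification.
Every artifact is a TSV/JSON text file in the output directory, and the run
manifest records the configuration, seeds, grids and per-fold chosen
parameters, so a run is re-derivable from manifest + inputs alone.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .evaluation import (
    CVResult,
    MatchedPartition,
    OptGrid,
    match_pairs,
    roc_auc,
    run_occ_cv,
    subgroup_auc,
)
from .inference import (
    PermutationPlan,
    auc_permutation_test,
    make_region_report,
    preimage_significance,
    region_report_text,
)
from .synthetic import CohortConfig, EffectSpec, simulate_cohort

log = logging.getLogger("occmap")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str, produced: list[str]):
        super().__init__(f"stage {stage!r} failed: {message}; artifacts so far: {produced}")
        self.stage = stage
        self.produced = produced


@dataclass
class RunConfig:
    """One full analysis run: inputs, strata, mode, permutations, outputs."""

    output_dir: str = "occmap-run"
    stats_dir: str | None = None
    meta: str | None = None
    synthetic: dict[str, Any] | None = None
    effects: dict[str, Any] | None = None
    stratum: str = "pooled"
    target_class: str = "case"
    optimize: bool = False
    nu: float = 0.1
    gamma: float | str = "heuristic"
    n_permutations: int = 200
    alpha: float = 0.05
    seed: int = 0
    preimage_restarts: int = 2

    def __post_init__(self) -> None:
        has_files = self.stats_dir is not None or self.meta is not None
        if has_files and self.synthetic is not None:
            raise ValueError("give either input paths or a synthetic config, not both")
        if has_files and (self.stats_dir is None or self.meta is None):
            raise ValueError("both stats_dir and meta are required for file input")
        if not has_files and self.synthetic is None:
            raise ValueError("either input paths or a synthetic config is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text())
        return cls(**payload)


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        cohort_cfg = CohortConfig(**{**config.synthetic, "seed": config.synthetic.get("seed", config.seed)})
        effects = EffectSpec(**config.effects) if config.effects else EffectSpec()
        features, subjects = simulate_cohort(cohort_cfg, effects)
    else:
        features, subjects = mio.read_cohort(config.stats_dir)
        if Path(config.meta) != mio.subject_table_path(config.stats_dir):
            subjects = mio.read_subject_table(config.meta)
            features = features.loc[subjects.index]
    return features, subjects


def _write_partition(partition: MatchedPartition, path: Path) -> None:
    rows = [
        {"unit": j, "cases": ",".join(u.cases), "controls": ",".join(u.controls)}
        for j, u in enumerate(partition.units)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_cv(cv: CVResult, subjects: pd.DataFrame, path: Path) -> None:
    frame = pd.DataFrame(
        {
            "score": cv.scores,
            "group": subjects.loc[cv.scores.index, "group"],
            "nviq": subjects.loc[cv.scores.index, "nviq"],
        }
    )
    frame.index.name = "subject"
    frame.to_csv(path, sep="\t")


def run_full_analysis(config: RunConfig) -> dict[str, Any]:
    """Run the complete analysis; returns the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    produced: list[str] = []
    manifest: dict[str, Any] = {
        "config": {k: v for k, v in asdict(config).items()},
        "grids": {
            "gamma_coarse": OptGrid().gamma_coarse.tolist(),
            "nu_coarse": OptGrid().nu_coarse.tolist(),
            "nu_fine": OptGrid().nu_fine.tolist(),
        },
        "stages": {},
    }

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            log.info("stage %s: start", name)
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage inventory
                raise PipelineError(name, str(exc), produced) from exc
            manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
            log.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)
            return result

        return deco

    @stage("load")
    def _inputs():
        return _load_inputs(config)

    features, subjects = _inputs

    @stage("match")
    def _partition():
        partition = match_pairs(subjects, config.stratum)
        path = out / "partition.tsv"
        _write_partition(partition, path)
        produced.append(str(path))
        return partition

    partition = _partition
    stratum_ids = partition.subjects
    feats = features.loc[stratum_ids]
    subj = subjects.loc[stratum_ids]

    @stage("cv")
    def _cv():
        cv = run_occ_cv(
            feats, subj, partition,
            target_class=config.target_class, optimize=config.optimize,
            nu=config.nu, gamma=config.gamma,
        )
        path = out / "cv_scores.tsv"
        _write_cv(cv, subj, path)
        produced.append(str(path))
        manifest["fold_params"] = cv.fold_params
        return cv

    cv = _cv

    @stage("auc")
    def _auc():
        auc, _ = roc_auc(cv.scores, cv.labels)
        aucs = {"overall": auc}
        for name, pred in (
            ("nviq_lt_70", lambda r: r["nviq"] < 70),
            ("nviq_ge_70", lambda r: r["nviq"] >= 70),
        ):
            try:
                aucs[name] = subgroup_auc(cv, subj, pred)
            except Exception:
                aucs[name] = None
        path = out / "auc.json"
        path.write_text(json.dumps(aucs, indent=2))
        produced.append(str(path))
        return aucs

    aucs = _auc
    manifest["auc"] = aucs

    plan = PermutationPlan(n_permutations=config.n_permutations, seed=config.seed, alpha=config.alpha)

    @stage("auc_permutation")
    def _perm():
        checkpoint = out / "null_auc.tsv"
        completed: list[float] = []

        def progress(b: int, val: float) -> None:
            # checkpoint completed permutations every 100 so long runs are inspectable
            completed.append(float(val))
            if (b + 1) % 100 == 0:
                pd.Series(completed, name="auc").to_csv(
                    checkpoint, sep="\t", index_label="permutation"
                )

        res = auc_permutation_test(
            feats, subj, partition, plan, observed=cv, progress=progress,
            target_class=config.target_class, optimize=config.optimize,
            nu=config.nu, gamma=config.gamma,
        )
        pd.Series(res.null_aucs, name="auc").to_csv(checkpoint, sep="\t", index_label="permutation")
        produced.append(str(checkpoint))
        return res

    perm = _perm
    manifest["auc_permutation"] = {
        "observed_auc": perm.observed_auc,
        "p_value": perm.p_value,
        "p_value_add_one": perm.p_value_add_one,
        "n_permutations": perm.n_permutations,
    }

    @stage("preimage_map")
    def _map():
        sig = preimage_significance(
            feats, subj, partition, plan,
            target_class=config.target_class, nu=config.nu, gamma=config.gamma,
            n_restarts=config.preimage_restarts,
        )
        path = out / "significance_map.tsv"
        sig.table.to_csv(path, sep="\t")
        produced.append(str(path))
        return sig

    sig = _map
    manifest["preimage_map"] = {
        "n_significant": int(sig.table["significant"].sum()),
        "gamma": sig.gamma,
        "nu": sig.nu,
        "n_failed_permutations": sig.n_failed_permutations,
    }

    @stage("report")
    def _report():
        report = make_region_report(sig, feature_index=features.attrs.get("feature_index"))
        tsv = out / "region_report.tsv"
        txt = out / "region_report.txt"
        report.to_csv(tsv, sep="\t")
        txt.write_text(region_report_text(report))
        produced.extend([str(tsv), str(txt)])
        return report

    _ = _report
    manifest["artifacts"] = produced
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
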