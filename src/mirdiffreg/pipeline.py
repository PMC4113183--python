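"""End-to-end orchestration: simulate/load -> edit -> annotate -> quantify
-> QC -> regulation statistics, under a single validated configuration.

Every run directory contains the stage TSV outputs, the verbatim config,
a log file and ``manifest.json`` with row/pool counts at each stage.
Differential-regulation tables are produced twice when pools are excluded
(all pools, and with exclusions) so both analyses can be presented side by
side. Identical config + seed gives identical outputs.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import io as _io
from . import preprocess, quantify, qc, stats
from .annotate import ReferenceLibrary, annotate_matrix
from .design import PoolDesign
from .simulate import (
    OutlierPool,
    SpikeIn,
    SyntheticConfig,
    emit_fastq,
    generate_counts,
    generate_sequences,
)

log = logging.getLogger("mirdiffreg")


@dataclass
class LibrarySpec:
    path: str
    name: str | None = None
    mismatch_budget: int = 0


@dataclass
class RunConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "run"
    seed: int = 0
    # input: exactly one of simulate / counts_path / fastq
    simulate: SyntheticConfig | None = None
    emit_reads: bool = False
    counts_path: str | None = None
    fastq: dict[str, str] | None = None
    adapter: str | None = None
    libraries: list[LibrarySpec] = field(default_factory=list)
    design: PoolDesign = field(default_factory=PoolDesign)
    rpm_mode: str = quantify.MODE_READS_LEVEL
    rpm_threshold: float = quantify.RPM_THRESHOLD
    min_pools: int = quantify.MIN_POOLS
    exclude_pools: list[str] = field(default_factory=list)
    auto_exclude: bool = False
    metric: str = stats.METRIC_SUBTRACTION
    alpha: float = 0.05
    permutation_runs: int = 0
    permutation_mode: str = "estimates"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        design = PoolDesign(**raw.pop("design", {})) if "design" in raw else PoolDesign()
        sim_cfg = None
        if "simulate" in raw:
            sim_raw = dict(raw.pop("simulate") or {})
            spikes = tuple(SpikeIn(**s) for s in sim_raw.pop("spike_ins", []))
            outlier = sim_raw.pop("outlier", None)
            sim_cfg = SyntheticConfig(
                design=design,
                spike_ins=spikes,
                outlier=OutlierPool(**outlier) if outlier else None,
                **sim_raw,
            )
        libs = [LibrarySpec(**l) for l in raw.pop("libraries", [])]
        return cls(simulate=sim_cfg, libraries=libs, design=design, **raw)

    def validate(self) -> None:
        sources = [self.simulate is not None, self.counts_path is not None, self.fastq is not None]
        if sum(sources) != 1:
            raise ValueError("exactly one of simulate / counts_path / fastq must be set")
        if self.fastq is not None and not self.adapter:
            raise ValueError("fastq input requires an adapter sequence")
        if self.min_pools > len(self.design.pools):
            raise ValueError(
                f"min_pools={self.min_pools} exceeds the {len(self.design.pools)} design pools"
            )
        if self.rpm_mode not in (quantify.MODE_READS_LEVEL, quantify.MODE_WITHIN_LIBRARY):
            raise ValueError(f"unknown rpm_mode {self.rpm_mode!r}")
        if self.metric not in (stats.METRIC_SUBTRACTION, stats.METRIC_LOG2):
            raise ValueError(f"unknown metric {self.metric!r}")
        for pool in self.exclude_pools:
            self.design.group_of(pool)  # raises on unknown pool
        if self.simulate is not None:
            self.simulate.validate()


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    if not any(isinstance(h, logging.StreamHandler) and not isinstance(h, logging.FileHandler)
               for h in log.handlers):
        log.addHandler(logging.StreamHandler())


def _significant(table: pd.DataFrame, alpha: float) -> int:
    return int((table["q_fdr"] <= alpha).sum())


def run(config: RunConfig) -> Path:
    """Execute all configured stages; returns the run directory."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    (outdir / "config.yaml").write_text(yaml.safe_dump(_config_dict(config), sort_keys=False))
    manifest: dict[str, Any] = {"stages": {}}
    design = config.design

    stage = "input"
    try:
        # ------------------------------------------------ input / simulate
        if config.simulate is not None:
            counts, truth = generate_counts(config.simulate)
            truth.to_json(outdir / "ground_truth.json")
            _io.write_matrix(counts, outdir / "counts.tsv", mode="raw")
            log.info("simulated %d elements x %d pools", *counts.shape)
            if config.emit_reads:
                seqs = generate_sequences(config.simulate.n_elements, config.simulate.seed)
                fastq_dir = outdir / "reads"
                emit_fastq(counts, seqs, config.simulate.adapter, fastq_dir,
                           seed=config.simulate.seed)
                stage = "preprocess"
                counts, edit_stats = preprocess.preprocess_fastq(
                    {p: fastq_dir / f"{p}.fastq" for p in counts.columns},
                    config.simulate.adapter,
                )
                manifest["stages"]["preprocess"] = {
                    p: dataclasses.asdict(s) for p, s in edit_stats.items()
                }
                _io.write_matrix(counts, outdir / "collapsed.tsv", mode="raw")
        elif config.fastq is not None:
            stage = "preprocess"
            counts, edit_stats = preprocess.preprocess_fastq(config.fastq, config.adapter)
            manifest["stages"]["preprocess"] = {
                p: dataclasses.asdict(s) for p, s in edit_stats.items()
            }
            _io.write_matrix(counts, outdir / "collapsed.tsv", mode="raw")
        else:
            counts, _ = _io.read_matrix(config.counts_path)
        manifest["stages"]["input"] = {"rows": int(counts.shape[0]), "pools": int(counts.shape[1])}

        # ------------------------------------------------ annotate
        library_of = None
        if config.libraries:
            stage = "annotate"
            libs = [
                ReferenceLibrary.from_fasta(
                    spec.path, rank=i + 1, name=spec.name, mismatch_budget=spec.mismatch_budget
                )
                for i, spec in enumerate(config.libraries)
            ]
            result = annotate_matrix(counts, libs)
            result.annotations.to_csv(outdir / "annotations.tsv", sep="\t")
            _io.write_matrix(result.identifier_matrix, outdir / "identifier_counts.tsv", mode="raw")
            manifest["stages"]["annotate"] = {
                "assigned_sequences": int(result.annotations["identifier"].notna().sum()),
                "unassigned_sequences": int(result.annotations["identifier"].isna().sum()),
                "identifiers": int(result.identifier_matrix.shape[0]),
            }
            if config.rpm_mode == quantify.MODE_WITHIN_LIBRARY:
                counts = result.identifier_matrix
                library_of = result.library_of
            log.info("annotated: %s", manifest["stages"]["annotate"])

        # ------------------------------------------------ quantify
        stage = "quantify"
        rpm = quantify.to_rpm(counts, config.rpm_mode, library_of)
        _io.write_matrix(rpm, outdir / "rpm.tsv", mode=f"rpm_{config.rpm_mode}")
        filtered = quantify.abundance_filter(rpm, config.rpm_threshold, config.min_pools)
        _io.write_matrix(filtered, outdir / "rpm_filtered.tsv", mode=f"rpm_{config.rpm_mode}")
        manifest["stages"]["quantify"] = {
            "rows_before_filter": int(rpm.shape[0]),
            "rows_after_filter": int(filtered.shape[0]),
            "rpm_threshold": config.rpm_threshold,
            "min_pools": config.min_pools,
        }
        log.info("abundance filter kept %d / %d rows", filtered.shape[0], rpm.shape[0])

        # ------------------------------------------------ qc
        stage = "qc"
        report = qc.consistency_report(filtered, design)
        report.evidence.to_csv(outdir / "qc_report.tsv", sep="\t")
        report.correlations.to_csv(outdir / "qc_correlations.tsv", sep="\t")
        (outdir / "dendrogram.nwk").write_text(report.newick() + "\n")
        manifest["stages"]["qc"] = {
            "group_cv": {k: round(float(v), 4) for k, v in report.group_cv.items()},
            "flagged_pools": report.flagged,
        }
        excluded = list(config.exclude_pools)
        if config.auto_exclude:
            excluded += [p for p in report.flagged if p not in excluded]
        manifest["stages"]["qc"]["excluded_pools"] = excluded
        log.info("qc flags: %s; excluding: %s", report.flagged, excluded)

        # ------------------------------------------------ statistics
        stage = "stats"
        variants = {"all_pools": filtered}
        if excluded:
            variants["excluded"] = qc.exclude_pools(filtered, excluded)
        stats_manifest: dict[str, Any] = {}
        for label, mat in variants.items():
            for line in design.lines:
                t = stats.snl_reg_test(mat, design, line, alpha=config.alpha)
                t.to_csv(outdir / f"snl_reg_{line}_{label}.tsv", sep="\t")
                stats_manifest[f"snl_reg_{line}_{label}"] = {
                    "tested": int(t["p_one_tailed"].notna().sum()),
                    "significant_q": _significant(t, config.alpha),
                    "fdr_limit": t.attrs["fdr_limit"],
                }
            d = stats.diff_reg_table(
                mat, design, metric=config.metric, alpha=config.alpha,
                permutation_runs=config.permutation_runs,
                permutation_mode=config.permutation_mode, seed=config.seed,
            )
            d.to_csv(outdir / f"diff_reg_{label}.tsv", sep="\t")
            stats.volcano_frame(d).to_csv(outdir / f"volcano_{label}.tsv", sep="\t")
            stats_manifest[f"diff_reg_{label}"] = {
                "tested": int(d["t_p_two_tailed"].notna().sum()),
                "significant_q": _significant(d, config.alpha),
                "fdr_limit": d.attrs["fdr_limit"],
            }
        b = stats.baseline_compare(filtered, design, alpha=config.alpha)
        b.to_csv(outdir / "baseline_sham_vs_sham.tsv", sep="\t")
        stats_manifest["baseline"] = {"significant_q": _significant(b, config.alpha)}
        manifest["stages"]["stats"] = stats_manifest
    except Exception as exc:
        log.exception("stage %r failed", stage)
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed") from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    log.info("run complete: %s", outdir)
    return outdir


def _config_dict(config: RunConfig) -> dict[str, Any]:
    d = dataclasses.asdict(config)
    d["design"] = dataclasses.asdict(config.design)
    return d
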