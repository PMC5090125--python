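"""End-to-end orchestration: config validation, stage running, reporting.

``run_pipeline`` chains site scanning, per-sample quantification, matrix
assembly, group-difference filtering, differential testing, methylation
load, ordination and clustering, writing every intermediate table plus a
run manifest and a one-row summary of headline numbers.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from msreseq import __version__
from msreseq import cluster as clustermod
from msreseq import diff as diffmod
from msreseq import load as loadmod
from msreseq import ordination as ordmod
from msreseq import quantify as quantmod
from msreseq.quantify import MethylationMatrix, QuantConfig
from msreseq.reference import load_genome, read_sites_bed, scan_motif_sites, write_sites_bed

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    manifest: str
    alignments: Dict[str, str]  # sample id -> SAM/BAM path
    outdir: str
    fasta: Optional[str] = None
    sites: Optional[str] = None  # precomputed sites BED (else scan fasta)
    regions: Optional[str] = None
    classes: Optional[str] = None
    # quantification
    delta: int = 2
    window: int = 500
    read_length: int = 71
    min_lambda: float = 10.0
    min_calibration_sites: int = 50
    span_correction: bool = True
    # filtering / testing
    min_diff: float = 10.0
    alpha_fdr: float = 0.05
    count_scale: float = 1.0
    prior_weight: float = 10.0
    # ordination / clustering
    metric: str = "bray-curtis"
    nmds_starts: int = 20
    n_perm: int = 9999
    top_sites: int = 60
    n_boot: int = 1000
    promoter_width: int = 3000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fasta is None and self.sites is None:
            raise ValueError("config must provide 'fasta' or 'sites'")
        if not self.alignments:
            raise ValueError("config must map at least one sample to alignments")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def quant_config(self) -> QuantConfig:
        return QuantConfig(
            delta=self.delta,
            window=self.window,
            read_length=self.read_length,
            min_lambda=self.min_lambda,
            min_calibration_sites=self.min_calibration_sites,
            span_correction=self.span_correction,
        )


def _sha256(path: Union[str, Path]) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as handle:
        for block in iter(lambda: handle.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def histogram_pct_met(matrix: MethylationMatrix, bin_width: float = 2.0
                      ) -> pd.DataFrame:
    """Per-sample binned %MET frequency table (M-channel rows only)."""
    m = matrix.m_channel()
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    records = {}
    for sample in m.columns:
        counts, _ = np.histogram(m[sample].to_numpy(), bins=edges)
        records[sample] = counts
    out = pd.DataFrame(records)
    for sample in m.columns:
        total = max(int(out[sample].sum()), 1)
        out[f"{sample}_density"] = out[sample] / total
    out.insert(0, "bin_low", edges[:-1])
    out.insert(1, "bin_high", edges[1:])
    return out


def _run_stage(name: str, outdir: Path, func):
    t0 = time.time()
    try:
        result = func()
    except Exception as exc:
        (outdir / "FAILED").write_text(f"{name}: {exc}\n")
        raise PipelineError(name, str(exc)) from exc
    logger.info("stage %-10s done in %.1fs", name, time.time() - t0)
    return result


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage and assemble the report directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for path in [config.manifest, *config.alignments.values()]:
        if not Path(path).exists():
            raise FileNotFoundError(f"input does not exist: {path}")

    manifest = quantmod.read_manifest(config.manifest)
    qc = config.quant_config()
    summary: Dict[str, object] = {}

    def stage_sites():
        if config.sites:
            sites = read_sites_bed(config.sites)
        else:
            sites = scan_motif_sites(load_genome(config.fasta))
        write_sites_bed(sites, outdir / "sites.bed")
        return sites

    sites = _run_stage("sites", outdir, stage_sites)
    summary["n_sites_scanned"] = len(sites)

    def stage_quantify():
        metrics = {}
        for sample, sam in config.alignments.items():
            metrics[sample] = quantmod.quantify_sample(sam, sites, qc)
        return metrics

    metrics = _run_stage("quantify", outdir, stage_quantify)

    def stage_matrix():
        matrix = quantmod.build_matrix(metrics, manifest)
        matrix.to_tsv(outdir / "matrix.tsv")
        histogram_pct_met(matrix).to_csv(
            outdir / "histogram.tsv", sep="\t", index=False
        )
        return matrix

    matrix = _run_stage("matrix", outdir, stage_matrix)
    summary["n_sites_scored"] = matrix.m_channel().shape[0]

    def stage_filter():
        filtered = quantmod.filter_by_group_difference(matrix, config.min_diff)
        filtered.to_tsv(outdir / "matrix.filtered.tsv")
        return filtered

    filtered = _run_stage("filter", outdir, stage_filter)
    summary["n_rows_after_filter"] = filtered.data.shape[0]

    def stage_diff():
        table = diffmod.differential_table(
            filtered, alpha_fdr=config.alpha_fdr, scale=config.count_scale,
            prior_weight=config.prior_weight,
        )
        diffmod.write_diff_table(table, outdir / "diff.tsv")
        return table

    diff_table = _run_stage("diff", outdir, stage_diff)
    summary["n_significant"] = diff_table.attrs["n_significant"]
    summary["n_up"] = diff_table.attrs["n_up"]
    summary["n_down"] = diff_table.attrs["n_down"]

    if config.regions:
        def stage_load():
            classes = (
                loadmod.read_class_map(config.classes) if config.classes else None
            )
            regions = loadmod.read_regions_bed(config.regions, classes=classes)
            results = loadmod.per_region_loads(matrix, regions)
            pd.DataFrame(
                {
                    "region_id": [r.region_id for r in results],
                    "delta_ml": [round(r.delta_ml, 3) for r in results],
                    "n_sites": [r.n_sites for r in results],
                }
            ).to_csv(outdir / "ml.tsv", sep="\t", index=False)
            loadmod.aggregate_domains(matrix, regions).to_csv(
                outdir / "ml.domains.tsv", sep="\t", index=False,
                float_format="%.3f",
            )
            return results

        results = _run_stage("load", outdir, stage_load)
        if results:
            values = [r.delta_ml for r in results]
            summary["delta_ml_min"] = round(min(values), 3)
            summary["delta_ml_max"] = round(max(values), 3)

    def stage_ordinate():
        dist = ordmod.distance_matrix(filtered, metric=config.metric)
        dist.to_csv(outdir / "distances.tsv", sep="\t", float_format="%.6f")
        result = ordmod.nmds(
            dist, n_starts=config.nmds_starts, seed=config.seed
        )
        coords = pd.DataFrame(
            result.coordinates, index=result.sample_ids,
            columns=[f"axis{i+1}" for i in range(result.coordinates.shape[1])],
        )
        coords.index.name = "sample"
        coords.to_csv(outdir / "ordination.tsv", sep="\t", float_format="%.6f")
        ellipse_rows = []
        idx = {s: i for i, s in enumerate(result.sample_ids)}
        for group, members in sorted(filtered.group_samples().items()):
            ell = ordmod.confidence_ellipse(
                result.coordinates, [idx[s] for s in members], group=group
            )
            ellipse_rows.append(
                {
                    "group": group,
                    "center_x": round(float(ell.center[0]), 6),
                    "center_y": round(float(ell.center[1]), 6),
                    "semi_major": round(ell.semi_axes[0], 6),
                    "semi_minor": round(ell.semi_axes[1], 6),
                    "rotation_rad": round(ell.rotation, 6),
                    "level": ell.level,
                }
            )
        pd.DataFrame(ellipse_rows).to_csv(
            outdir / "ellipses.tsv", sep="\t", index=False
        )
        p_value, statistic, exhaustive = ordmod.permutation_group_test(
            dist, filtered.groups, n_perm=config.n_perm, seed=config.seed
        )
        ranking = ordmod.site_discrimination_ranking(
            filtered, result.coordinates
        )
        ranking.to_csv(
            outdir / "site_ranking.tsv", sep="\t", index=False,
            float_format="%.6f",
        )
        return result, p_value, statistic, exhaustive, ranking

    ord_result, p_value, statistic, exhaustive, ranking = _run_stage(
        "ordinate", outdir, stage_ordinate
    )
    summary["nmds_stress"] = round(ord_result.stress, 6)
    summary["permutation_p"] = round(p_value, 6)
    summary["permutation_statistic"] = round(statistic, 6)
    summary["permutation_exhaustive"] = exhaustive

    def stage_cluster():
        top_ids = ranking["site_id"].head(config.top_sites)
        profiles = filtered.data.loc[top_ids]
        tree = clustermod.bootstrap_branch_support(
            profiles, n_boot=config.n_boot, seed=config.seed
        )
        (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        clustermod.bipartition_table(tree).to_csv(
            outdir / "bipartitions.tsv", sep="\t", index=False,
            float_format="%.1f",
        )
        return tree

    _run_stage("cluster", outdir, stage_cluster)

    pd.DataFrame([summary]).to_csv(outdir / "summary.tsv", sep="\t", index=False)

    inputs = {"manifest": config.manifest, **{
        f"alignments.{s}": p for s, p in config.alignments.items()
    }}
    for key in ("fasta", "sites", "regions", "classes"):
        value = getattr(config, key)
        if value:
            inputs[key] = value
    run_manifest = {
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "seed": config.seed,
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(run_manifest, indent=2, sort_keys=True) + "\n"
    )
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return outdir
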