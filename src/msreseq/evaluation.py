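"""Ground-truth evaluation harness for the simulated acceptance checks.

Builds seeded cohorts, runs the real pipeline stages on them, and measures
recovery/calibration/discrimination statistics against the planted truth.
Used by the acceptance test suite and the acceptance report script.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from msreseq import ordination as ordmod
from msreseq.diff import differential_table
from msreseq.pipeline import histogram_pct_met
from msreseq.quantify import (
    MethylationMatrix,
    QuantConfig,
    SiteMetrics,
    build_matrix,
    filter_by_group_difference,
    quantify_sample,
    read_manifest,
)
from msreseq.simulate import (
    CohortResult,
    SimConfig,
    assign_methylation,
    generate_genome,
    simulate_cohort,
    simulate_library,
)

#: cohort used for parameter recovery, differential power and discrimination
ACCEPTANCE_SIM = dict(
    genome_length=1_250_000,
    n_sites=2000,
    mean_coverage=100.0,
    digestion_efficiency=0.98,
    n_diff_sites=100,
    effect_size=0.3,
)


@dataclass
class EvaluatedCohort:
    cohort: CohortResult
    metrics: Dict[str, List[SiteMetrics]]
    matrix: MethylationMatrix
    quant_config: QuantConfig


def build_evaluated_cohort(seed: int, workdir: Path,
                           sim_overrides: Optional[dict] = None,
                           quant_config: Optional[QuantConfig] = None
                           ) -> EvaluatedCohort:
    """Simulate a cohort and quantify every library with the real pipeline."""
    params = dict(ACCEPTANCE_SIM)
    if sim_overrides:
        params.update(sim_overrides)
    config = SimConfig(seed=seed, **params)
    cohort = simulate_cohort(config, Path(workdir))
    qc = quant_config or QuantConfig()
    manifest = read_manifest(cohort.manifest_path)
    metrics = {
        lib.sample_id: quantify_sample(lib.sam_path, cohort.truth.sites, qc)
        for lib in cohort.libraries
    }
    matrix = build_matrix(metrics, manifest)
    return EvaluatedCohort(cohort, metrics, matrix, qc)


def planted_site_ids(cohort: CohortResult) -> set:
    """Bare (channel-less) ids of sites carrying a planted effect."""
    truth = cohort.truth
    return {
        truth.sites[i].site_id[2:]
        for i in range(truth.n_sites)
        if truth.diff_flags[i]
    }


# ---------------------------------------------------------------------------
# criterion: parameter recovery


def parameter_recovery_rmse(ev: EvaluatedCohort, min_lambda: float = 50.0
                            ) -> Tuple[float, int]:
    """RMSE between pct_met and 100*f, pooled over samples, lambda-filtered."""
    truth = ev.cohort.truth
    errors = []
    for lib in ev.cohort.libraries:
        f = truth.f_by_group[lib.group]
        for i, sm in enumerate(ev.metrics[lib.sample_id]):
            if sm.low_coverage or sm.local_lambda < min_lambda:
                continue
            errors.append(sm.pct_met - 100.0 * f[i])
    arr = np.asarray(errors)
    return float(np.sqrt(np.mean(arr ** 2))), int(arr.size)


# ---------------------------------------------------------------------------
# criterion: repeatability (duplicate libraries, CV vs coverage)


def repeatability_cv(seed: int, workdir: Path,
                     coverages: Sequence[int] = (15, 30, 60),
                     n_sites: int = 500) -> Dict[int, float]:
    """Median per-site CV (%) of pct_met across duplicate libraries."""
    workdir = Path(workdir)
    config = SimConfig(
        genome_length=int(n_sites * 640 + 2_000),
        n_sites=n_sites,
        mean_coverage=max(coverages),
        seed=seed,
    )
    genome, sites = generate_genome(config)
    truth = assign_methylation(config, sites)
    qc = QuantConfig()
    out: Dict[int, float] = {}
    for cov in coverages:
        cfg = dataclasses.replace(config, mean_coverage=float(cov))
        values = []
        for rep in ("rep1", "rep2"):
            lib = simulate_library(genome, truth, f"{rep}.{cov}x", "A", cfg,
                                   workdir / f"cov{cov}")
            metrics = quantify_sample(lib.sam_path, sites, qc)
            values.append(np.array([m.pct_met for m in metrics]))
        x = np.vstack(values)
        mean = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        ok = ~np.isnan(mean) & (mean > 1.0)
        cv = 100.0 * sd[ok] / mean[ok]
        out[cov] = float(np.median(cv))
    return out


# ---------------------------------------------------------------------------
# criterion: differential testing calibration and power


def null_rejection_rate(seed: int, n_sites: int = 2000, mu: float = 70.0,
                        alpha: float = 0.05) -> float:
    """Type-I rate of the exact-test chain on null Poisson counts."""
    rng = np.random.default_rng(seed)
    counts = rng.poisson(mu, size=(n_sites, 6)).astype(float)
    index = [f"M.chr1.{i + 1:010d}" for i in range(n_sites)]
    data = pd.DataFrame(counts, index=index,
                        columns=[f"s{j}" for j in range(6)])
    mm = MethylationMatrix(
        data, {f"s{j}": ("A" if j < 3 else "B") for j in range(6)}
    )
    table = differential_table(mm, scale=1.0)
    return float((table["p_std"] < alpha).mean())


def differential_power(ev: EvaluatedCohort, alpha: float = 0.05,
                       min_diff: float = 10.0) -> Dict[str, float]:
    """Recall of planted sites and empirical FDR at the BH threshold."""
    filtered = filter_by_group_difference(ev.matrix, min_diff)
    table = differential_table(filtered, alpha_fdr=alpha)
    planted = planted_site_ids(ev.cohort)
    sig_sites = {
        sid[2:] for sid in table.loc[table["p_fdr"] < alpha, "site_id"]
    }
    recall = len(planted & sig_sites) / len(planted) if planted else float("nan")
    fdr = (len(sig_sites - planted) / len(sig_sites)) if sig_sites else 0.0
    return {"recall": recall, "empirical_fdr": fdr,
            "n_called": len(sig_sites), "n_planted": len(planted)}


# ---------------------------------------------------------------------------
# criterion: end-to-end discrimination


def discrimination_summary(ev: EvaluatedCohort, seed: int,
                           min_diff: float = 10.0,
                           top_n: int = 40) -> Dict[str, float]:
    filtered = filter_by_group_difference(ev.matrix, min_diff)
    dist = ordmod.distance_matrix(filtered)
    result = ordmod.nmds(dist, seed=seed)
    coords = result.coordinates
    idx = {s: i for i, s in enumerate(result.sample_ids)}
    by_group = filtered.group_samples()
    centroids = {
        g: coords[[idx[s] for s in ss]].mean(axis=0)
        for g, ss in by_group.items()
    }
    (g1, c1), (g2, c2) = sorted(centroids.items())
    between = float(np.linalg.norm(c1 - c2))
    max_within = float(max(
        np.linalg.norm(coords[idx[s]] - centroids[g])
        for g, ss in by_group.items()
        for s in ss
    ))
    p_value, statistic, exhaustive = ordmod.permutation_group_test(
        dist, filtered.groups, seed=seed
    )
    ranked = ordmod.site_discrimination_ranking(filtered, coords)
    planted = planted_site_ids(ev.cohort)
    top = ranked.head(top_n)["site_id"]
    top_planted = float(np.mean([sid[2:] in planted for sid in top]))
    return {
        "stress": result.stress,
        "between_centroid_distance": between,
        "max_within_group_spread": max_within,
        "permutation_p": p_value,
        "permutation_exhaustive": exhaustive,
        "top_rank_planted_fraction": top_planted,
    }


# ---------------------------------------------------------------------------
# criterion: simulator reproduces the bimodal score distribution


def histogram_modes(matrix: MethylationMatrix, antimode: float = 77.5
                    ) -> Dict[str, float]:
    """Locations of the two %MET modes and the high-mode mass fraction."""
    hist = histogram_pct_met(matrix, bin_width=2.5)
    pooled = hist[matrix.samples].sum(axis=1).to_numpy().astype(float)
    centers = (hist["bin_low"] + hist["bin_high"]).to_numpy() / 2.0
    # light smoothing stabilises the argmax under sampling noise
    kernel = np.array([1.0, 2.0, 1.0]) / 4.0
    smooth = np.convolve(pooled, kernel, mode="same")
    hi_zone = centers > antimode
    lo_zone = (centers > 30) & (centers <= antimode)
    mode_high = float(centers[hi_zone][np.argmax(smooth[hi_zone])])
    mode_low = float(centers[lo_zone][np.argmax(smooth[lo_zone])])
    values = matrix.m_channel().to_numpy()
    high_mass = float(np.mean(values > 80.0))
    return {
        "mode_high": mode_high,
        "mode_low": mode_low,
        "high_mode_mass_fraction": high_mass,
        "n_values": int(values.size),
    }
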