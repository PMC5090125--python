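"""Per-site methylation quantification from aligned MSRE-seq reads.

Two independent read-evidence channels are reconstructed per recognition
site: spanning coverage (reads crossing the intact motif; proportional to
the fully methylated fraction) and excess read termini at the cut boundary
(digest ends; proportional to the fully unmethylated fraction).  Both are
normalised by a trough-masked local coverage baseline, and the terminus
channel is calibrated per sample against the shearing background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import pysam

from msreseq.reference import GenomicSite

# ---------------------------------------------------------------------------
# configuration and records


@dataclass
class QuantConfig:
    """Tuning constants of the evidence model (all config-exposed)."""

    delta: int = 2  # end-match tolerance around the cut boundary (bp)
    window: int = 500  # local-coverage half-width (bp)
    read_length: int = 71
    min_lambda: float = 10.0  # minimum local coverage to score a site
    calib_threshold: float = 0.5  # max spanning ratio of calibration sites
    min_calibration_sites: int = 50
    span_correction: bool = True  # correct m for spanning-geometry loss

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise ValueError("delta must be >= 0")
        if self.window <= self.read_length:
            raise ValueError("window must exceed read_length")


@dataclass
class SiteCounts:
    """Raw per-site read evidence for one sample."""

    site: GenomicSite
    end_count: int  # E: read termini within delta of the cut boundary
    span_count: int  # S: reads fully spanning the motif, no terminus near cut
    local_lambda: float  # trough-masked median per-base coverage
    background: float  # expected shear termini in the end window


@dataclass
class SiteMetrics:
    """Derived M/U methylation metrics for one site in one sample.

    ``m_metric`` (spanning-coverage ratio) and ``u_metric`` (calibrated
    excess-end ratio) come from disjoint read sets; their consistency is a
    checkable property.  ``pct_met`` is 100x the inverse-variance
    combination of the two channels, which is the reported methylation
    score (the end channel carries several-fold more evidence per unit
    coverage than the spanning channel).
    """

    site: GenomicSite
    m_metric: float  # in [0, 1]; spanning estimate of the methylated fraction
    u_metric: float  # >= 0;   end-count estimate of the unmethylated fraction
    pct_met: float  # 100 * combined methylated-fraction estimate
    low_coverage: bool = False
    local_lambda: float = 0.0


@dataclass
class QCSummary:
    n_total: int
    n_retained: int

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_total if self.n_total else 0.0


# ---------------------------------------------------------------------------
# FASTQ quality-control filter


def read_confidence(quality: str) -> float:
    """1 minus the mean per-base error probability of a Phred+33 string."""
    q = np.frombuffer(quality.encode(), dtype=np.uint8).astype(float) - 33.0
    return 1.0 - float(np.mean(10.0 ** (-q / 10.0)))


def qc_filter(fastq_in: Union[str, Path], fastq_out: Union[str, Path],
              min_confidence: float = 0.97) -> QCSummary:
    """Retain reads whose mean-error read confidence exceeds ``min_confidence``.

    Confidence is ``1 - mean(10^(-Q/10))`` over the read's bases.  Retained
    records are written verbatim to ``fastq_out``.
    """
    n_total = n_kept = 0
    cache: Dict[str, bool] = {}
    with pysam.FastxFile(str(fastq_in)) as fq, open(fastq_out, "w") as out:
        for idx, rec in enumerate(fq):
            if rec.quality is None or not rec.sequence:
                raise ValueError(f"malformed FASTQ record at index {idx}")
            n_total += 1
            keep = cache.get(rec.quality)
            if keep is None:
                keep = read_confidence(rec.quality) > min_confidence
                if len(cache) < 4096:
                    cache[rec.quality] = keep
            if keep:
                n_kept += 1
                out.write(f"@{rec.name}\n{rec.sequence}\n+\n{rec.quality}\n")
    return QCSummary(n_total=n_total, n_retained=n_kept)


# ---------------------------------------------------------------------------
# alignment handling


@dataclass
class AlignmentSet:
    """Coordinate-sorted ungapped alignments of one sample, as flat arrays."""

    chrom_lengths: Dict[str, int]
    by_chrom: Dict[str, Dict[str, np.ndarray]] = field(default_factory=dict)
    # per chrom: {"start": int64[], "end": int64[], "reverse": bool[]}

    @property
    def n_reads(self) -> int:
        return sum(v["start"].size for v in self.by_chrom.values())


def load_alignments(sam_path: Union[str, Path]) -> AlignmentSet:
    """Read a coordinate-sorted SAM/BAM into arrays; errors if unsorted."""
    starts: Dict[str, List[int]] = {}
    ends: Dict[str, List[int]] = {}
    revs: Dict[str, List[bool]] = {}
    with pysam.AlignmentFile(str(sam_path), check_sq=True) as af:
        chrom_lengths = dict(zip(af.references, af.lengths))
        last: Dict[str, int] = {}
        for rec in af.fetch(until_eof=True):
            if rec.is_unmapped:
                continue
            chrom = rec.reference_name
            s = rec.reference_start
            if s < last.get(chrom, -1):
                raise ValueError(f"alignments not coordinate-sorted in {sam_path}")
            last[chrom] = s
            starts.setdefault(chrom, []).append(s)
            ends.setdefault(chrom, []).append(rec.reference_end)
            revs.setdefault(chrom, []).append(rec.is_reverse)
    aln = AlignmentSet(chrom_lengths=chrom_lengths)
    for chrom in starts:
        aln.by_chrom[chrom] = {
            "start": np.asarray(starts[chrom], dtype=np.int64),
            "end": np.asarray(ends[chrom], dtype=np.int64),
            "reverse": np.asarray(revs[chrom], dtype=bool),
        }
    return aln


def _merged_windows(sites: Sequence[GenomicSite], radius: int
                    ) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    out: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(
            (max(0, s.motif_start - radius), s.motif_end + radius)
        )
    for chrom, wins in by_chrom.items():
        wins.sort()
        merged = [list(wins[0])]
        for lo, hi in wins[1:]:
            if lo <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        arr = np.asarray(merged, dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def isolate_target_reads(alignments: AlignmentSet, sites: Sequence[GenomicSite],
                         radius: Optional[int] = None,
                         config: Optional[QuantConfig] = None) -> AlignmentSet:
    """Keep alignments overlapping any site window ``[start-radius, end+radius)``."""
    if radius is None:
        radius = (config or QuantConfig()).window
    windows = _merged_windows(sites, radius)
    out = AlignmentSet(chrom_lengths=alignments.chrom_lengths)
    for chrom, arrs in alignments.by_chrom.items():
        if chrom not in windows:
            continue
        w_lo, w_hi = windows[chrom]
        idx = np.searchsorted(w_lo, arrs["end"], side="right") - 1
        valid = idx >= 0
        keep = np.zeros(arrs["start"].size, dtype=bool)
        keep[valid] = arrs["start"][valid] < w_hi[idx[valid]]
        out.by_chrom[chrom] = {k: v[keep] for k, v in arrs.items()}
    return out


# ---------------------------------------------------------------------------
# evidence tabulation


def depth_track(alignments: AlignmentSet, chrom: str) -> np.ndarray:
    """Per-base read depth over one chromosome."""
    g = alignments.chrom_lengths[chrom]
    arrs = alignments.by_chrom.get(chrom)
    if arrs is None or arrs["start"].size == 0:
        return np.zeros(g, dtype=np.int64)
    delta = np.bincount(arrs["start"], minlength=g + 1)
    delta -= np.bincount(np.minimum(arrs["end"], g), minlength=g + 1)
    return np.cumsum(delta)[:g]


def _cut_mask(sites: Sequence[GenomicSite], chrom: str, g: int, L: int) -> np.ndarray:
    """Positions within ``L`` of any cut boundary (digestion troughs)."""
    mask = np.zeros(g, dtype=bool)
    for s in sites:
        if s.chrom != chrom:
            continue
        mask[max(0, s.cut_coord - L):min(g, s.cut_coord + L)] = True
    return mask


def local_coverage(depth: np.ndarray, site: GenomicSite, config: QuantConfig,
                   cut_mask: Optional[np.ndarray] = None) -> float:
    """Median depth in the site window, excluding digestion-trough positions."""
    g = depth.size
    lo = max(0, site.motif_start - config.window)
    hi = min(g, site.motif_end + config.window)
    window = depth[lo:hi]
    if cut_mask is not None:
        window = window[~cut_mask[lo:hi]]
    if window.size == 0:
        return 0.0
    return float(np.median(window))


def shear_background(lam: float, config: QuantConfig) -> float:
    """Expected random-shear termini within the cut-boundary end window."""
    return 2.0 * (2 * config.delta + 1) * lam / config.read_length


def spanning_geometry_factor(read_length: int, delta: int) -> float:
    """Fraction of per-base coverage that can register as motif-spanning.

    Enumerates, for a motif at [0, 4) with cut boundary 1, the read
    placements (by strand) that fully span the motif without leaving a
    terminus within ``delta`` of the cut.
    """
    L = read_length
    cut = 1
    fwd = sum(
        1 for p in range(4 - L, 1) if abs(p - cut) > delta
    )
    rev = sum(
        1 for e in range(4, L + 1) if abs(e - cut) > delta
    )
    return (fwd + rev) / (2.0 * L)


def tabulate_site_evidence(alignments: AlignmentSet, sites: Sequence[GenomicSite],
                           config: Optional[QuantConfig] = None) -> List[SiteCounts]:
    """Count cut-end and spanning evidence for every site.

    For each site, ``E`` counts fragment termini (5' start of forward reads,
    3' end of reverse reads) within ``delta`` of the cut boundary, and ``S``
    counts reads whose aligned span contains the whole motif and whose
    terminus is not within ``delta`` of the cut.  A read contributes to at
    most one of the two per site.
    """
    config = config or QuantConfig()
    out: List[SiteCounts] = []
    sites_by_chrom: Dict[str, List[GenomicSite]] = {}
    for s in sites:
        sites_by_chrom.setdefault(s.chrom, []).append(s)

    for chrom, chrom_sites in sites_by_chrom.items():
        arrs = alignments.by_chrom.get(chrom)
        g = alignments.chrom_lengths.get(chrom, 0)
        if arrs is None or arrs["start"].size == 0:
            for s in chrom_sites:
                out.append(SiteCounts(s, 0, 0, 0.0, 0.0))
            continue
        starts, ends, rev = arrs["start"], arrs["end"], arrs["reverse"]
        termini = np.where(rev, ends, starts)
        termini_sorted = np.sort(termini)
        depth = depth_track(alignments, chrom)
        mask = _cut_mask(chrom_sites, chrom, g, config.read_length)
        max_len = int(np.max(ends - starts))

        for s in chrom_sites:
            cut = s.cut_coord
            e_count = int(
                np.searchsorted(termini_sorted, cut + config.delta, side="right")
                - np.searchsorted(termini_sorted, cut - config.delta, side="left")
            )
            # candidate spanning reads: start in [motif_end - max_len, motif_start]
            lo = np.searchsorted(starts, s.motif_end - max_len, side="left")
            hi = np.searchsorted(starts, s.motif_start, side="right")
            cand_end = ends[lo:hi]
            cand_term = termini[lo:hi]
            spans = cand_end >= s.motif_end
            near_cut = np.abs(cand_term - cut) <= config.delta
            s_count = int(np.count_nonzero(spans & ~near_cut))
            lam = local_coverage(depth, s, config, mask)
            out.append(
                SiteCounts(s, e_count, s_count, lam, shear_background(lam, config))
            )
    # restore input site order
    order = {id(s): i for i, s in enumerate(sites)}
    out.sort(key=lambda c: order[id(c.site)])
    return out


# ---------------------------------------------------------------------------
# calibration and metrics


def _gamma(config: QuantConfig) -> float:
    if config.span_correction:
        return spanning_geometry_factor(config.read_length, config.delta)
    return 1.0


def estimate_end_capture(counts: Sequence[SiteCounts],
                         config: Optional[QuantConfig] = None) -> float:
    """Per-sample end-capture factor placing E on the coverage scale.

    Estimated in aggregate over all adequately covered sites as
    ``sum(E - b) / sum(lam * (1 - m))`` with ``m`` the (unbiased) spanning
    ratio; aggregation avoids the selection bias a per-site ratio over
    low-``m`` sites would incur.  Calibration still requires a minimum
    number of majority-unmethylated sites (spanning ratio below
    ``calib_threshold``), which carry the end-channel signal.
    """
    config = config or QuantConfig()
    gamma = _gamma(config)
    excess = 0.0
    unmeth_cov = 0.0
    n_signal = 0
    for c in counts:
        if c.local_lambda < config.min_lambda:
            continue
        m = min(c.span_count / (c.local_lambda * gamma), 1.0)
        excess += c.end_count - c.background
        unmeth_cov += c.local_lambda * (1.0 - m)
        if m < config.calib_threshold:
            n_signal += 1
    if n_signal < config.min_calibration_sites:
        raise ValueError(
            f"only {n_signal} calibration sites (need "
            f">={config.min_calibration_sites}); provide a larger or less "
            f"methylated input"
        )
    if unmeth_cov <= 0:
        raise ValueError("no unmethylated coverage to calibrate against")
    return max(float(excess / unmeth_cov), 1e-9)


def compute_metrics(counts: SiteCounts, kappa: float,
                    config: Optional[QuantConfig] = None) -> SiteMetrics:
    """Derive the M/U metrics and %MET for one site.

    %MET is 100x the inverse-variance weighted combination of the spanning
    estimate (``m``) and the end-channel estimate (``1 - u``), using
    Poisson plug-in variances for the two counts.
    """
    config = config or QuantConfig()
    if counts.local_lambda < config.min_lambda:
        return SiteMetrics(counts.site, math.nan, math.nan, math.nan,
                           low_coverage=True, local_lambda=counts.local_lambda)
    lam = counts.local_lambda
    gamma = _gamma(config)
    m = float(np.clip(counts.span_count / (lam * gamma), 0.0, 1.0))
    u = float(np.clip((counts.end_count - counts.background) / (kappa * lam),
                      0.0, 1.5))
    var_m = max(counts.span_count, 1.0) / (lam * gamma) ** 2
    var_u = max(counts.end_count, 1.0) / (kappa * lam) ** 2
    m_from_u = float(np.clip(1.0 - u, 0.0, 1.0))
    combined = (m / var_m + m_from_u / var_u) / (1.0 / var_m + 1.0 / var_u)
    combined = float(np.clip(combined, 0.0, 1.0))
    return SiteMetrics(counts.site, m, u, 100.0 * combined,
                       local_lambda=counts.local_lambda)


def quantify_sample(sam_path: Union[str, Path], sites: Sequence[GenomicSite],
                    config: Optional[QuantConfig] = None,
                    kappa: Optional[float] = None) -> List[SiteMetrics]:
    """Full per-sample chain: load, isolate, tabulate, calibrate, score."""
    config = config or QuantConfig()
    aln = load_alignments(sam_path)
    aln = isolate_target_reads(aln, sites, config.window, config)
    counts = tabulate_site_evidence(aln, sites, config)
    if kappa is None:
        kappa = estimate_end_capture(counts, config)
    return [compute_metrics(c, kappa, config) for c in counts]


# ---------------------------------------------------------------------------
# matrix assembly


@dataclass
class MethylationMatrix:
    """Sites-by-samples table of M- and U-channel scores on the % scale."""

    data: pd.DataFrame  # index: site_id (M.* and U.* rows); columns: samples
    groups: Dict[str, str]  # sample -> group label

    @property
    def samples(self) -> List[str]:
        return list(self.data.columns)

    def group_samples(self) -> Dict[str, List[str]]:
        by_group: Dict[str, List[str]] = {}
        for sample, group in self.groups.items():
            by_group.setdefault(group, []).append(sample)
        return by_group

    def m_channel(self) -> pd.DataFrame:
        return self.data.loc[self.data.index.str.startswith("M.")]

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.data.copy()
        out.index.name = "site_id"
        out.to_csv(path, sep="\t", float_format="%.3f")

    @classmethod
    def from_tsv(cls, path: Union[str, Path],
                 groups: Dict[str, str]) -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", index_col="site_id")
        return cls(data=df, groups={s: groups[s] for s in df.columns})


def read_manifest(path: Union[str, Path]) -> Dict[str, str]:
    """Sample -> group map from a two-column TSV (header ``sample\\tgroup``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample", "group"}.issubset(df.columns):
        raise ValueError("manifest must have 'sample' and 'group' columns")
    return dict(zip(df["sample"], df["group"]))


def build_matrix(metrics_by_sample: Dict[str, List[SiteMetrics]],
                 manifest: Dict[str, str]) -> MethylationMatrix:
    """Assemble the complete-case M/U matrix with group labels attached.

    Sites flagged low-coverage in any sample are dropped entirely (both
    channels).  Rows are sorted lexicographically by id, i.e. by
    (channel, chrom, position).
    """
    if len(metrics_by_sample) < 2:
        raise ValueError("need at least 2 samples")
    missing = set(manifest) - set(metrics_by_sample)
    if missing:
        raise ValueError(f"manifest samples absent from inputs: {sorted(missing)}")
    samples = [s for s in manifest if s in metrics_by_sample]

    bad_sites: set = set()
    for sample in samples:
        for sm in metrics_by_sample[sample]:
            if sm.low_coverage:
                bad_sites.add(sm.site.site_id)

    rows: Dict[str, Dict[str, float]] = {}
    for sample in samples:
        for sm in metrics_by_sample[sample]:
            mid = sm.site.site_id
            if mid in bad_sites:
                continue
            uid = "U" + mid[1:]
            rows.setdefault(mid, {})[sample] = sm.pct_met
            rows.setdefault(uid, {})[sample] = 100.0 * sm.u_metric
    df = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    df = df.sort_index()
    return MethylationMatrix(data=df, groups={s: manifest[s] for s in samples})


def filter_by_group_difference(matrix: MethylationMatrix,
                               min_diff: float = 10.0) -> MethylationMatrix:
    """Retain rows whose two group means differ by strictly more than ``min_diff``."""
    by_group = matrix.group_samples()
    if len(by_group) != 2:
        raise ValueError(f"expected exactly 2 groups, got {sorted(by_group)}")
    (g1, s1), (g2, s2) = sorted(by_group.items())
    if not s1 or not s2:
        raise ValueError("each group needs at least one sample")
    diff = (matrix.data[s1].mean(axis=1) - matrix.data[s2].mean(axis=1)).abs()
    kept = matrix.data.loc[diff > min_diff]
    return MethylationMatrix(data=kept, groups=dict(matrix.groups))
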