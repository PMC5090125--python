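"""Seeded MSRE-seq read simulator with planted ground truth.

Models a methyl-sensitive digest of a synthetic genome: each genome copy
is cut at every recognition site with probability ``(1 - f) * d`` (``f``
the methylated fraction of copies, ``d`` the digestion efficiency),
sheared into log-normally sized fragments, and sequenced with fixed-length
single-end reads taken from a uniformly chosen fragment end.  Output is
FASTQ plus coordinate-sorted SAM with exact (error-free) alignments, and
TSV truth tables recording every planted methylation fraction.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from msreseq.reference import GenomicSite, scan_motif_sites

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimConfig:
    """Parameters of the simulated genome, methylome and libraries."""

    genome_length: int = 200_000
    n_sites: int = 200
    read_length: int = 71
    fragment_median: int = 300
    fragment_sigma: float = 0.35
    mean_coverage: float = 30.0
    digestion_efficiency: float = 0.98
    # two-component Beta mixture of baseline methylation fractions
    weight_high: float = 1.0 / 3.0
    mode_high: float = 0.90
    conc_high: float = 150.0
    mode_low: float = 0.60
    conc_low: float = 35.0
    n_per_group: int = 3
    n_diff_sites: int = 0
    effect_size: float = 0.0
    min_fragment: Optional[int] = None
    max_fragment: Optional[int] = None
    base_quality: int = 35
    low_quality_fraction: float = 0.0
    low_quality_q: int = 10
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.digestion_efficiency <= 1.0:
            raise ValueError("digestion_efficiency must be in [0, 1]")
        for name in ("weight_high", "mode_high", "mode_low"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.read_length > self.fragment_median:
            raise ValueError("read_length must not exceed fragment_median")
        if self.effect_size < 0 or self.effect_size > 1:
            raise ValueError("effect_size must be in [0, 1]")

    @property
    def weight_low(self) -> float:
        return 1.0 - self.weight_high


@dataclass
class SimTruth:
    """Planted methylation fractions and differential flags."""

    sites: List[GenomicSite]
    f_by_group: Dict[str, np.ndarray]  # per group: fraction methylated per site
    diff_flags: np.ndarray  # bool per site
    effects: np.ndarray  # signed f_B - f_A per site

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class LibraryResult:
    sample_id: str
    group: str
    fastq_path: Path
    sam_path: Path
    counts_path: Path
    n_reads: int
    n_copies: int


@dataclass
class CohortResult:
    config: SimConfig
    genome_path: Path
    sites_path: Path
    truth_path: Path
    manifest_path: Path
    truth: SimTruth
    libraries: List[LibraryResult] = field(default_factory=list)


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    return np.random.default_rng([seed, zlib.crc32(sample_id.encode())])


def generate_genome(config: SimConfig, rng: Optional[np.random.Generator] = None
                    ) -> Tuple[Dict[str, str], List[GenomicSite]]:
    """Random ACGT genome with exactly ``n_sites`` planted CCGG motifs.

    Motifs are at least ``2 * fragment_median`` apart; accidental motifs in
    the background are mutated away so a scan recovers exactly the planted
    set.  Deterministic under ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 0xFA57A])
    g, n = config.genome_length, config.n_sites
    if g < 10 * config.fragment_median:
        raise ValueError("genome_length must be at least 10x fragment_median")
    spacing = 2 * config.fragment_median
    margin = config.fragment_median
    if n > 0:
        step = (g - 2 * margin - 4) // n
        if step < spacing:
            raise ValueError(
                f"cannot place {n} sites at least {spacing} bp apart in "
                f"{g} bp; reduce n_sites or enlarge the genome"
            )
        jitter = rng.integers(0, step - spacing + 1, size=n)
        positions = margin + np.arange(n) * step + jitter
    else:
        positions = np.array([], dtype=int)

    bases = np.frombuffer(b"ACGT", dtype="S1")
    seq = rng.choice(bases, size=g).tobytes().decode()
    seq_arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    planted = set(int(p) for p in positions)
    motif = np.frombuffer(b"CCGG", dtype="S1")
    for p in positions:
        seq_arr[p:p + 4] = motif

    # mutate away any occurrence that is not a planted site
    protected = np.zeros(g, dtype=bool)
    for p in positions:
        protected[p:p + 4] = True
    for _ in range(100):
        text = seq_arr.tobytes().decode()
        extra = [
            m for m in _find_all(text, "CCGG") if m not in planted
        ]
        if not extra:
            break
        for pos in extra:
            for off in range(4):
                idx = pos + off
                if not protected[idx]:
                    current = seq_arr[idx]
                    choices = [b for b in (b"A", b"C", b"G", b"T") if b != current]
                    seq_arr[idx] = rng.choice(np.array(choices, dtype="S1"))
                    break
    else:  # pragma: no cover - rejection loop virtually always terminates
        raise RuntimeError("failed to sanitise background motifs")

    genome = {config.chrom: seq_arr.tobytes().decode()}
    sites = scan_motif_sites(genome)
    assert len(sites) == n, "construction guarantee violated"
    return genome, sites


def _find_all(text: str, motif: str) -> List[int]:
    out, start = [], 0
    while True:
        i = text.find(motif, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def _mixture_beta_params(mode: float, conc: float) -> Tuple[float, float]:
    # Beta parameterised by mode and concentration (alpha + beta = conc)
    alpha = mode * (conc - 2.0) + 1.0
    beta = (1.0 - mode) * (conc - 2.0) + 1.0
    return alpha, beta


def assign_methylation(config: SimConfig, sites: Sequence[GenomicSite],
                       rng: Optional[np.random.Generator] = None) -> SimTruth:
    """Draw baseline per-site methylated fractions and plant group effects.

    Baseline ``f`` comes from a two-component Beta mixture (sharp mode at
    ``mode_high`` with weight ``weight_high``, broad mode at ``mode_low``
    with the remaining weight).  ``n_diff_sites`` random sites receive an
    exact ``effect_size`` shift in group B, with the sign chosen so the
    shifted value stays inside [0, 1].
    """
    if not sites:
        raise ValueError("sites must be nonempty")
    n = len(sites)
    if config.n_diff_sites > n:
        raise ValueError("n_diff_sites exceeds number of sites")
    if rng is None:
        rng = np.random.default_rng([config.seed, 0x7A07])

    high = rng.random(n) < config.weight_high
    a_hi, b_hi = _mixture_beta_params(config.mode_high, config.conc_high)
    a_lo, b_lo = _mixture_beta_params(config.mode_low, config.conc_low)
    f = np.where(high, rng.beta(a_hi, b_hi, size=n), rng.beta(a_lo, b_lo, size=n))
    f = np.clip(f, 0.0, 1.0)

    flags = np.zeros(n, dtype=bool)
    effects = np.zeros(n)
    if config.n_diff_sites > 0 and config.effect_size > 0:
        chosen = rng.choice(n, size=config.n_diff_sites, replace=False)
        flags[chosen] = True
        signs = rng.choice([-1.0, 1.0], size=config.n_diff_sites)
        for i, idx in enumerate(chosen):
            s = signs[i]
            if f[idx] + s * config.effect_size > 1.0 or f[idx] + s * config.effect_size < 0.0:
                s = -s
            if f[idx] + s * config.effect_size > 1.0 or f[idx] + s * config.effect_size < 0.0:
                # site too central for either sign at this effect size; pull
                # baseline to the nearest feasible value
                f[idx] = min(max(f[idx], config.effect_size), 1.0)
                s = -1.0
            effects[idx] = s * config.effect_size

    f_a = f
    f_b = np.clip(f + effects, 0.0, 1.0)
    return SimTruth(
        sites=list(sites),
        f_by_group={"A": f_a, "B": f_b},
        diff_flags=flags,
        effects=f_b - f_a,
    )


def _shear_points(rng: np.random.Generator, length: int, median: int,
                  sigma: float) -> np.ndarray:
    """Renewal process of log-normal fragment lengths across ``length`` bp."""
    mu = math.log(median)
    est = int(length / median * 1.5) + 16
    pieces = []
    total = 0.0
    while total < length:
        lens = rng.lognormal(mu, sigma, size=est)
        pieces.append(lens)
        total += lens.sum()
    cuts = np.cumsum(np.concatenate(pieces)).astype(np.int64)
    return cuts[(cuts > 0) & (cuts < length)]


def simulate_library(genome: Dict[str, str], truth: SimTruth, sample_id: str,
                     group: str, config: SimConfig, outdir: Path) -> LibraryResult:
    """Simulate one sequencing library and write FASTQ, SAM and truth counts.

    Deterministic under ``(config.seed, sample_id)``.
    """
    if config.mean_coverage <= 0:
        raise ValueError("mean_coverage must be positive")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _sample_rng(config.seed, sample_id)

    chrom = config.chrom
    seq = genome[chrom]
    g = len(seq)
    L = config.read_length
    f = truth.f_by_group[group]
    d = config.digestion_efficiency
    cut_coords = np.array([s.cut_coord for s in truth.sites], dtype=np.int64)
    p_cut = (1.0 - f) * d
    min_frag = max(L, config.min_fragment or 0)
    max_frag = config.max_fragment or np.iinfo(np.int64).max

    n_target = int(math.ceil(config.mean_coverage * g / L))
    pos_chunks: List[np.ndarray] = []
    rev_chunks: List[np.ndarray] = []
    cut_events = np.zeros(truth.n_sites, dtype=np.int64)
    n_reads = 0
    n_copies = 0
    while n_reads < n_target:
        n_copies += 1
        cut_mask = rng.random(truth.n_sites) < p_cut
        cut_events += cut_mask
        shear = _shear_points(rng, g, config.fragment_median, config.fragment_sigma)
        breaks = np.unique(np.concatenate(
            [np.array([0, g], dtype=np.int64), shear, cut_coords[cut_mask]]
        ))
        starts, ends = breaks[:-1], breaks[1:]
        lens = ends - starts
        keep = (lens >= min_frag) & (lens <= max_frag)
        starts, ends = starts[keep], ends[keep]
        right_end = rng.integers(0, 2, size=starts.size).astype(bool)
        pos = np.where(right_end, ends - L, starts)
        pos_chunks.append(pos)
        rev_chunks.append(right_end)
        n_reads += pos.size

    pos = np.concatenate(pos_chunks)
    rev = np.concatenate(rev_chunks)
    order = np.argsort(pos, kind="stable")
    pos, rev = pos[order], rev[order]

    low_q = (
        rng.random(pos.size) < config.low_quality_fraction
        if config.low_quality_fraction > 0
        else np.zeros(pos.size, dtype=bool)
    )
    qual_hi = chr(config.base_quality + 33) * L
    qual_lo = chr(config.low_quality_q + 33) * L

    fastq_path = outdir / f"{sample_id}.fastq"
    sam_path = outdir / f"{sample_id}.sam"
    counts_path = outdir / f"{sample_id}.truecounts.tsv"

    chunk = 200_000
    with open(fastq_path, "w") as fq, open(sam_path, "w") as sam:
        sam.write("@HD\tVN:1.6\tSO:coordinate\n")
        sam.write(f"@SQ\tSN:{chrom}\tLN:{g}\n")
        sam.write(f"@RG\tID:{sample_id}\tSM:{sample_id}\n")
        for lo in range(0, pos.size, chunk):
            hi = min(lo + chunk, pos.size)
            fq_lines, sam_lines = [], []
            for i in range(lo, hi):
                p = int(pos[i])
                ref_seq = seq[p:p + L]
                qual = qual_lo if low_q[i] else qual_hi
                name = f"{sample_id}:{i}"
                if rev[i]:
                    fq_lines.append(f"@{name}\n{revcomp(ref_seq)}\n+\n{qual}\n")
                    sam_lines.append(
                        f"{name}\t16\t{chrom}\t{p + 1}\t60\t{L}M\t*\t0\t0\t"
                        f"{ref_seq}\t{qual}\n"
                    )
                else:
                    fq_lines.append(f"@{name}\n{ref_seq}\n+\n{qual}\n")
                    sam_lines.append(
                        f"{name}\t0\t{chrom}\t{p + 1}\t60\t{L}M\t*\t0\t0\t"
                        f"{ref_seq}\t{qual}\n"
                    )
            fq.write("".join(fq_lines))
            sam.write("".join(sam_lines))

    with open(counts_path, "w") as out:
        out.write("site_id\tf_true\tcut_events\tn_copies\n")
        for i, site in enumerate(truth.sites):
            out.write(
                f"{site.site_id}\t{f[i]:.6f}\t{cut_events[i]}\t{n_copies}\n"
            )

    return LibraryResult(
        sample_id=sample_id,
        group=group,
        fastq_path=fastq_path,
        sam_path=sam_path,
        counts_path=counts_path,
        n_reads=int(pos.size),
        n_copies=n_copies,
    )


def write_genome_fasta(genome: Dict[str, str], path: Path, width: int = 80) -> None:
    with open(path, "w") as out:
        for chrom, seq in genome.items():
            out.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                out.write(seq[i:i + width] + "\n")


def write_truth_table(truth: SimTruth, path: Path) -> None:
    with open(path, "w") as out:
        out.write("site_id\tchrom\tcpg_pos\tf_groupA\tf_groupB\tis_diff\teffect\n")
        fa, fb = truth.f_by_group["A"], truth.f_by_group["B"]
        for i, site in enumerate(truth.sites):
            out.write(
                f"{site.site_id}\t{site.chrom}\t{site.cpg_pos}\t"
                f"{fa[i]:.6f}\t{fb[i]:.6f}\t{int(truth.diff_flags[i])}\t"
                f"{truth.effects[i]:.6f}\n"
            )


def simulate_cohort(config: SimConfig, outdir: Path) -> CohortResult:
    """Simulate a two-group cohort: genome, methylome, and all libraries."""
    if config.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome, sites = generate_genome(config)
    truth = assign_methylation(config, sites)

    genome_path = outdir / "genome.fa"
    write_genome_fasta(genome, genome_path)
    from msreseq.reference import write_sites_bed

    sites_path = outdir / "sites.bed"
    write_sites_bed(sites, sites_path)
    truth_path = outdir / "truth.tsv"
    write_truth_table(truth, truth_path)

    manifest_path = outdir / "manifest.tsv"
    libraries: List[LibraryResult] = []
    with open(manifest_path, "w") as mf:
        mf.write("sample\tgroup\n")
        for group in ("A", "B"):
            for k in range(1, config.n_per_group + 1):
                sample_id = f"{group}{k}"
                lib = simulate_library(genome, truth, sample_id, group, config, outdir)
                libraries.append(lib)
                mf.write(f"{sample_id}\t{group}\n")

    return CohortResult(
        config=config,
        genome_path=genome_path,
        sites_path=sites_path,
        truth_path=truth_path,
        manifest_path=manifest_path,
        truth=truth,
        libraries=libraries,
    )
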