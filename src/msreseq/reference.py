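"""Reference-genome indexing for methyl-sensitive restriction sites.

Scans a genome for a 4-base recognition motif (HpaII ``CCGG`` by default),
records the top-strand cut boundary and internal CpG position for each
occurrence, and writes standard BED interval files.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, List, Union

from Bio import SeqIO

DEFAULT_MOTIF = "CCGG"

#: offset of the top-strand cut within the motif (HpaII cuts C^CGG)
CUT_OFFSET = 1
#: offset of the internal CpG cytosine within the motif
CPG_OFFSET = 1


@dataclass(frozen=True)
class GenomicSite:
    """One recognition locus of the restriction motif.

    Coordinates are 0-based.  ``cut_coord`` is the boundary coordinate of
    the top-strand cut, i.e. the index of the first base of the right-hand
    cut product.  ``cpg_pos`` is the internal CpG cytosine.
    """

    chrom: str
    motif_start: int
    cut_coord: int
    cpg_pos: int
    site_id: str

    @property
    def motif_end(self) -> int:
        return self.motif_start + 4


GenomeLike = Union[str, Path, Dict[str, str]]


def load_genome(source: GenomeLike) -> Dict[str, str]:
    """Return ``{chrom: sequence}`` from a FASTA path (plain or gzip) or dict."""
    if isinstance(source, dict):
        return source
    path = Path(source)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as handle:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(handle, "fasta")}


def make_site_id(chrom: str, pos: int, channel: str) -> str:
    """Site identifier ``{channel}.{chrom}.{1-based pos, zero-padded to 10}``.

    ``pos`` is the 0-based coordinate of the internal CpG cytosine.
    """
    if channel not in ("M", "U"):
        raise ValueError(f"channel must be 'M' or 'U', got {channel!r}")
    if pos < 0:
        raise ValueError("pos must be >= 0")
    return f"{channel}.{chrom}.{pos + 1:010d}"


def parse_site_id(site_id: str) -> tuple:
    """Inverse of :func:`make_site_id`: returns (channel, chrom, 0-based pos)."""
    parts = site_id.split(".")
    channel, pos_str = parts[0], parts[-1]
    chrom = ".".join(parts[1:-1])
    return channel, chrom, int(pos_str) - 1


def scan_motif_sites(genome: GenomeLike, motif: str = DEFAULT_MOTIF) -> List[GenomicSite]:
    """Find every exact occurrence of ``motif`` on the forward strand.

    Matching is case-insensitive; any occurrence containing ``N`` (or any
    non-ACGT letter) is excluded.  ``motif`` must be unambiguous ACGT.
    Sites are returned sorted by ``(chrom, motif_start)`` in the input
    chromosome order.
    """
    if set(motif.upper()) - set("ACGT"):
        raise ValueError(f"motif must contain only ACGT, got {motif!r}")
    seqs = load_genome(genome)
    pattern = re.compile(f"(?={re.escape(motif.upper())})")
    sites: List[GenomicSite] = []
    for chrom, seq in seqs.items():
        upper = seq.upper()
        for match in pattern.finditer(upper):
            start = match.start()
            cpg = start + CPG_OFFSET
            sites.append(
                GenomicSite(
                    chrom=chrom,
                    motif_start=start,
                    cut_coord=start + CUT_OFFSET,
                    cpg_pos=cpg,
                    site_id=make_site_id(chrom, cpg, "M"),
                )
            )
    return sites


def count_cpg(genome: GenomeLike) -> int:
    """Count forward-strand ``CG`` dinucleotides, case-insensitive, N-free."""
    seqs = load_genome(genome)
    total = 0
    for seq in seqs.values():
        total += seq.upper().count("CG")
    return total


def write_sites_bed(sites: Iterable[GenomicSite], path: Union[str, Path]) -> None:
    """Write sites as BED6 (half-open, 0-based) with the M-channel id as name."""
    with open(path, "w") as out:
        for site in sites:
            out.write(
                f"{site.chrom}\t{site.motif_start}\t{site.motif_end}\t"
                f"{site.site_id}\t0\t+\n"
            )


def read_sites_bed(path: Union[str, Path]) -> List[GenomicSite]:
    """Read sites back from a BED file written by :func:`write_sites_bed`."""
    sites: List[GenomicSite] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start = fields[0], int(fields[1])
            cpg = start + CPG_OFFSET
            sites.append(
                GenomicSite(
                    chrom=chrom,
                    motif_start=start,
                    cut_coord=start + CUT_OFFSET,
                    cpg_pos=cpg,
                    site_id=make_site_id(chrom, cpg, "M"),
                )
            )
    return sites
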