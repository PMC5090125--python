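"""Methylation-load aggregation over regions, genes, domains and classes.

The differential methylation load of a region is the signed sum, over the
M-channel CpG sites it contains, of the difference in group-mean %MET
(reference group minus comparison group); positive values mean higher
methylation in the reference group.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from msreseq.quantify import MethylationMatrix
from msreseq.reference import parse_site_id

REGION_KINDS = ("gene", "promoter3kb", "exon", "intron", "cpg_island", "custom")


@dataclass(frozen=True)
class RegionAnnotation:
    """One annotated genomic interval (0-based half-open)."""

    region_id: str
    chrom: str
    start: int
    end: int
    kind: str = "gene"
    gene_id: Optional[str] = None
    strand: Optional[str] = None
    functional_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"region {self.region_id}: start must be < end")
        if self.kind not in REGION_KINDS:
            raise ValueError(f"region {self.region_id}: unknown kind {self.kind!r}")


@dataclass
class MLResult:
    """Differential methylation load of one region."""

    region_id: str
    delta_ml: float  # percentage-point units, reference minus comparison
    n_sites: int


def read_regions_bed(path: Union[str, Path], kind: str = "gene",
                     classes: Optional[Dict[str, str]] = None
                     ) -> List[RegionAnnotation]:
    """Read regions from BED (3-6 columns, optional 7th kind / 8th gene id)."""
    regions: List[RegionAnnotation] = []
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"{f[0]}:{f[1]}-{f[2]}"
            strand = f[5] if len(f) > 5 and f[5] in "+-" else None
            rkind = f[6] if len(f) > 6 else kind
            gene = f[7] if len(f) > 7 else name
            fclass = classes.get(gene) if classes else None
            regions.append(
                RegionAnnotation(
                    region_id=name, chrom=f[0], start=int(f[1]), end=int(f[2]),
                    kind=rkind, gene_id=gene, strand=strand,
                    functional_class=fclass,
                )
            )
    return regions


def read_class_map(path: Union[str, Path]) -> Dict[str, str]:
    """Gene -> functional-class map from a two-column TSV (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.iloc[0, 0] in ("gene", "gene_id"):
        df = df.iloc[1:]
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def derive_promoters(genes: Sequence[RegionAnnotation],
                     width: int = 3000) -> List[RegionAnnotation]:
    """Upstream promoter intervals (on the annotated strand when present)."""
    out = []
    for g in genes:
        if g.strand == "-":
            start, end = g.end, g.end + width
        else:
            start, end = max(0, g.start - width), g.start
        if start >= end:
            continue
        out.append(
            RegionAnnotation(
                region_id=f"{g.region_id}:promoter", chrom=g.chrom,
                start=start, end=end, kind="promoter3kb", gene_id=g.gene_id,
                strand=g.strand, functional_class=g.functional_class,
            )
        )
    return out


def _site_table(matrix: MethylationMatrix) -> pd.DataFrame:
    """M-channel per-site group means with parsed coordinates."""
    by_group = matrix.group_samples()
    ordered: List[str] = []
    for sample in matrix.groups:
        if matrix.groups[sample] not in ordered:
            ordered.append(matrix.groups[sample])
    if len(ordered) != 2:
        raise ValueError(f"expected exactly 2 groups, got {ordered}")
    g1, g2 = ordered
    m = matrix.m_channel()
    parsed = [parse_site_id(i) for i in m.index]
    return pd.DataFrame(
        {
            "chrom": [p[1] for p in parsed],
            "pos": [p[2] for p in parsed],
            "mean_ref": m[by_group[g1]].mean(axis=1).to_numpy(),
            "mean_cmp": m[by_group[g2]].mean(axis=1).to_numpy(),
        },
        index=m.index,
    )


def delta_ml(matrix: MethylationMatrix, region: RegionAnnotation,
             site_table: Optional[pd.DataFrame] = None) -> MLResult:
    """Signed sum of per-site group-mean %MET differences within the region.

    The reference group is the first group in manifest order; positive
    values mean higher methylation in the reference group.
    """
    st = site_table if site_table is not None else _site_table(matrix)
    mask = (
        (st["chrom"] == region.chrom)
        & (st["pos"] >= region.start)
        & (st["pos"] < region.end)
    )
    sub = st.loc[mask]
    if sub.empty:
        return MLResult(region.region_id, 0.0, 0)
    dml = float((sub["mean_ref"] - sub["mean_cmp"]).sum())
    return MLResult(region.region_id, dml, int(mask.sum()))


def per_region_loads(matrix: MethylationMatrix,
                     regions: Sequence[RegionAnnotation]) -> List[MLResult]:
    st = _site_table(matrix)
    return [delta_ml(matrix, r, st) for r in regions]


def aggregate_domains(matrix: MethylationMatrix,
                      regions: Sequence[RegionAnnotation]) -> pd.DataFrame:
    """Mean +/- SE of per-gene delta-ML by (functional class, domain kind).

    Genes contributing no sites to a domain are excluded from that cell.
    Genes without a class mapping fall into class ``"unannotated"``.
    """
    st = _site_table(matrix)
    records = []
    for region in regions:
        res = delta_ml(matrix, region, st)
        if res.n_sites == 0:
            continue
        records.append(
            {
                "functional_class": region.functional_class or "unannotated",
                "kind": region.kind,
                "gene_id": region.gene_id or region.region_id,
                "delta_ml": res.delta_ml,
            }
        )
    if not records:
        return pd.DataFrame(
            columns=["functional_class", "kind", "mean_delta_ml", "se", "n_genes"]
        )
    df = pd.DataFrame(records)
    # a gene's domain load is the sum over its intervals of that kind
    per_gene = (
        df.groupby(["functional_class", "kind", "gene_id"])["delta_ml"]
        .sum()
        .reset_index()
    )
    agg = (
        per_gene.groupby(["functional_class", "kind"])["delta_ml"]
        .agg(
            mean_delta_ml="mean",
            se=lambda x: float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) > 1 else 0.0,
            n_genes="count",
        )
        .reset_index()
    )
    return agg


def rank_genes_by_load(results: Sequence[MLResult], direction: str,
                       top_n: int) -> pd.DataFrame:
    """Rank per-gene loads; ``hypo-in-group2`` puts the most positive first.

    Positive delta-ML = reference group more methylated = comparison group
    (group 2) hypomethylated.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    if direction not in ("hypo-in-group2", "hyper-in-group2"):
        raise ValueError(f"unknown direction {direction!r}")
    df = pd.DataFrame(
        {
            "region_id": [r.region_id for r in results],
            "delta_ml": [r.delta_ml for r in results],
            "n_sites": [r.n_sites for r in results],
        }
    )
    ascending = direction == "hyper-in-group2"
    df = df.sort_values(
        ["delta_ml", "region_id"], ascending=[ascending, True], kind="stable"
    )
    return df.head(top_n).reset_index(drop=True)
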