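import numpy as np
import pytest

from msreseq.quantify import (
    AlignmentSet,
    QuantConfig,
    build_matrix,
    quantify_sample,
    read_manifest,
)
from msreseq.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def quant_config():
    # small cohorts have few majority-unmethylated sites; relax the floor
    return QuantConfig(min_calibration_sites=20)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Strong-effect 3v3 cohort: 200 sites, 60x, 20 planted at delta-f 0.3."""
    cfg = SimConfig(
        genome_length=150_000,
        n_sites=200,
        mean_coverage=60,
        n_diff_sites=20,
        effect_size=0.3,
        seed=7,
    )
    return simulate_cohort(cfg, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def cohort_matrix(small_cohort, quant_config):
    manifest = read_manifest(small_cohort.manifest_path)
    metrics = {
        lib.sample_id: quantify_sample(
            lib.sam_path, small_cohort.truth.sites, quant_config
        )
        for lib in small_cohort.libraries
    }
    return build_matrix(metrics, manifest)


def make_alignments(reads, chrom="chr1", chrom_length=10_000):
    """AlignmentSet from (start, length, is_reverse) triples (sorted by start)."""
    reads = sorted(reads)
    aln = AlignmentSet(chrom_lengths={chrom: chrom_length})
    aln.by_chrom[chrom] = {
        "start": np.array([r[0] for r in reads], dtype=np.int64),
        "end": np.array([r[0] + r[1] for r in reads], dtype=np.int64),
        "reverse": np.array([bool(r[2]) for r in reads]),
    }
    return aln
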