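import numpy as np
import pandas as pd
import pytest

from msreseq.quantify import (
    MethylationMatrix,
    QuantConfig,
    SiteCounts,
    SiteMetrics,
    build_matrix,
    compute_metrics,
    depth_track,
    estimate_end_capture,
    filter_by_group_difference,
    isolate_target_reads,
    local_coverage,
    qc_filter,
    quantify_sample,
    read_confidence,
    shear_background,
    spanning_geometry_factor,
    tabulate_site_evidence,
)
from msreseq.reference import GenomicSite, make_site_id

from conftest import make_alignments


def _site(motif_start, chrom="chr1"):
    return GenomicSite(
        chrom, motif_start, motif_start + 1, motif_start + 1,
        make_site_id(chrom, motif_start + 1, "M"),
    )


def _write_fastq(path, records):
    with open(path, "w") as out:
        for name, seq, qual in records:
            out.write(f"@{name}\n{seq}\n+\n{qual}\n")


class TestQcFilter:
    def test_q40_retained(self, tmp_path):
        fin, fout = tmp_path / "in.fq", tmp_path / "out.fq"
        _write_fastq(fin, [("r1", "ACGT" * 10, chr(40 + 33) * 40)])
        summary = qc_filter(fin, fout)
        assert summary.n_retained == 1

    def test_q10_removed(self, tmp_path):
        fin, fout = tmp_path / "in.fq", tmp_path / "out.fq"
        _write_fastq(fin, [("r1", "ACGT" * 10, chr(10 + 33) * 40)])
        summary = qc_filter(fin, fout)
        assert summary.n_retained == 0
        assert fout.read_text() == ""

    def test_mixed_quality_boundary(self, tmp_path):
        # half Q40 (err 1e-4), half Q13 (err ~0.05): confidence ~0.975 > 0.97
        qual = chr(40 + 33) * 20 + chr(13 + 33) * 20
        expected = 1.0 - (20 * 1e-4 + 20 * 10 ** (-1.3)) / 40
        assert read_confidence(qual) == pytest.approx(expected)
        assert expected > 0.97
        fin, fout = tmp_path / "in.fq", tmp_path / "out.fq"
        _write_fastq(fin, [("r1", "A" * 40, qual)])
        assert qc_filter(fin, fout).n_retained == 1

    def test_summary_fraction(self, tmp_path):
        fin, fout = tmp_path / "in.fq", tmp_path / "out.fq"
        _write_fastq(
            fin,
            [("r1", "AAAA", "IIII"), ("r2", "AAAA", "++++"), ("r3", "AAAA", "IIII")],
        )
        summary = qc_filter(fin, fout)
        assert summary.n_total == 3
        assert summary.retained_fraction == pytest.approx(2 / 3)

    def test_low_quality_injection_filtered(self, tmp_path):
        import dataclasses

        from msreseq.simulate import (
            SimConfig,
            assign_methylation,
            generate_genome,
            simulate_library,
        )

        cfg = SimConfig(genome_length=10_000, n_sites=8, mean_coverage=10,
                        low_quality_fraction=0.3, seed=3)
        genome, sites = generate_genome(cfg)
        truth = assign_methylation(cfg, sites)
        lib = simulate_library(genome, truth, "lq", "A", cfg, tmp_path)
        summary = qc_filter(lib.fastq_path, tmp_path / "kept.fq")
        assert 0.6 < summary.retained_fraction < 0.8


class TestIsolateTargetReads:
    def test_far_read_dropped(self):
        aln = make_alignments([(5000, 71, False)], chrom_length=20_000)
        out = isolate_target_reads(aln, [_site(100)], radius=500)
        assert out.n_reads == 0

    def test_overlapping_read_retained(self):
        aln = make_alignments([(90, 71, False)])
        out = isolate_target_reads(aln, [_site(100)], radius=0)
        assert out.n_reads == 1

    def test_radius_zero_strict(self):
        aln = make_alignments([(90, 71, False), (200, 71, False)])
        out = isolate_target_reads(aln, [_site(100)], radius=0)
        assert out.n_reads == 1  # only the read covering the motif


class TestTabulateSiteEvidence:
    def test_read_starting_at_cut(self):
        site = _site(100)  # cut boundary at 101
        aln = make_alignments([(101, 71, False)])
        counts = tabulate_site_evidence(aln, [site])
        assert counts[0].end_count == 1
        assert counts[0].span_count == 0

    def test_reverse_read_ending_at_cut(self):
        site = _site(100)
        aln = make_alignments([(30, 71, True)])  # ends at 101
        counts = tabulate_site_evidence(aln, [site])
        assert counts[0].end_count == 1
        assert counts[0].span_count == 0

    def test_spanning_read(self):
        site = _site(100)
        aln = make_alignments([(60, 71, False)])  # covers 60..131
        counts = tabulate_site_evidence(aln, [site])
        assert counts[0].end_count == 0
        assert counts[0].span_count == 1

    def test_no_reads_is_flagged_not_error(self):
        aln = make_alignments([], chrom_length=1000)
        counts = tabulate_site_evidence(aln, [_site(100)])
        assert counts[0].end_count == 0 and counts[0].span_count == 0
        assert counts[0].local_lambda == 0.0

    def test_brute_force_equivalence(self, quant_config):
        rng = np.random.default_rng(42)
        sites = [_site(p) for p in (300, 500, 900)]
        reads = [
            (int(rng.integers(200, 1000)), 71, bool(rng.integers(0, 2)))
            for _ in range(100)
        ]
        aln = make_alignments(reads, chrom_length=2000)
        counts = tabulate_site_evidence(aln, sites, quant_config)
        delta = quant_config.delta
        for sc, site in zip(counts, sites):
            e = s = 0
            for start, length, rev in sorted(reads):
                end = start + length
                term = end if rev else start
                if abs(term - site.cut_coord) <= delta:
                    e += 1
                elif start <= site.motif_start and end >= site.motif_end:
                    s += 1
            assert sc.end_count == e
            assert sc.span_count == s


class TestLocalCoverage:
    def test_uniform_depth(self):
        depth = np.full(3000, 50)
        cfg = QuantConfig()
        assert local_coverage(depth, _site(1500), cfg) == 50

    def test_trough_excluded(self):
        cfg = QuantConfig()
        site = _site(1500)
        depth = np.full(3000, 50)
        lo, hi = site.cut_coord - cfg.read_length, site.cut_coord + cfg.read_length
        depth[lo:hi] = 5  # digestion trough
        mask = np.zeros(3000, dtype=bool)
        mask[lo:hi] = True
        assert local_coverage(depth, site, cfg, mask) == 50

    def test_two_site_mask_union(self):
        cfg = QuantConfig(window=200, read_length=71)
        s1, s2 = _site(1000), _site(1100)
        depth = np.arange(3000, dtype=float)
        mask = np.zeros(3000, dtype=bool)
        for s in (s1, s2):
            mask[s.cut_coord - 71:s.cut_coord + 71] = True
        # independent oracle: direct median over unmasked window positions
        lo, hi = 1000 - 200, 1004 + 200
        keep = [i for i in range(lo, hi) if not mask[i]]
        assert local_coverage(depth, s1, cfg, mask) == np.median(depth[keep])

    def test_fully_masked_window(self):
        cfg = QuantConfig(window=100, read_length=71)
        depth = np.full(3000, 50)
        mask = np.ones(3000, dtype=bool)
        assert local_coverage(depth, _site(1500), cfg, mask) == 0.0


class TestEndCapture:
    def _exact_counts(self, kappa0, fs, lam=100.0):
        cfg = QuantConfig(span_correction=False)
        counts = []
        for i, f in enumerate(fs):
            site = _site(1000 * (i + 1))
            b = shear_background(lam, cfg)
            counts.append(
                SiteCounts(site, int(round(b + kappa0 * lam * (1 - f))),
                           int(round(lam * f)), lam, b)
            )
        return cfg, counts

    def test_plugin_identity(self):
        fs = np.linspace(0.0, 0.9, 60)
        cfg, counts = self._exact_counts(4.0, fs)
        cfg = QuantConfig(span_correction=False, min_calibration_sites=10)
        kappa = estimate_end_capture(counts, cfg)
        assert kappa == pytest.approx(4.0, rel=0.01)

    def test_all_methylated_errors(self):
        cfg, counts = self._exact_counts(4.0, np.ones(60))
        with pytest.raises(ValueError):
            estimate_end_capture(counts, cfg)

    def test_too_few_sites_errors(self):
        cfg, counts = self._exact_counts(4.0, np.linspace(0, 0.4, 10))
        with pytest.raises(ValueError):
            estimate_end_capture(counts, cfg)

    def test_stable_across_duplicate_libraries(self, small_cohort, quant_config):
        import dataclasses

        from msreseq.quantify import (
            isolate_target_reads,
            load_alignments,
        )
        from msreseq.simulate import simulate_library

        cfg = small_cohort.config
        genome = {
            cfg.chrom: "".join(
                line.strip()
                for line in open(small_cohort.genome_path)
                if not line.startswith(">")
            )
        }
        kappas = []
        for sample in ("k1", "k2"):
            lib = simulate_library(
                genome, small_cohort.truth, sample, "A", cfg,
                small_cohort.genome_path.parent / "dups",
            )
            aln = load_alignments(lib.sam_path)
            counts = tabulate_site_evidence(
                isolate_target_reads(aln, small_cohort.truth.sites,
                                     quant_config.window),
                small_cohort.truth.sites,
                quant_config,
            )
            kappas.append(estimate_end_capture(counts, quant_config))
        assert abs(kappas[0] - kappas[1]) / kappas[0] < 0.1


class TestComputeMetrics:
    def test_fully_methylated_limit(self):
        cfg = QuantConfig(span_correction=False)
        lam = 100.0
        b = shear_background(lam, cfg)
        sc = SiteCounts(_site(500), int(round(b)), int(lam), lam, b)
        sm = compute_metrics(sc, kappa=4.0, config=cfg)
        assert sm.m_metric == pytest.approx(1.0)
        assert sm.u_metric == pytest.approx(0.0)
        assert sm.pct_met == pytest.approx(100.0)

    def test_fully_unmethylated_limit(self):
        cfg = QuantConfig(span_correction=False)
        lam = 100.0
        b = shear_background(lam, cfg)
        sc = SiteCounts(_site(500), int(round(b + 4.0 * lam)), 0, lam, b)
        sm = compute_metrics(sc, kappa=4.0, config=cfg)
        assert sm.m_metric == pytest.approx(0.0)
        assert sm.u_metric == pytest.approx(1.0, rel=1e-3)
        assert sm.pct_met == pytest.approx(0.0, abs=0.1)

    def test_low_coverage_flagged(self):
        cfg = QuantConfig()
        sc = SiteCounts(_site(500), 0, 0, 2.0, 0.1)
        sm = compute_metrics(sc, kappa=4.0, config=cfg)
        assert sm.low_coverage
        assert np.isnan(sm.pct_met)

    def test_geometry_factor_enumeration(self):
        # L=71, delta=2: 66 eligible forward starts + 68 reverse ends of 142
        assert spanning_geometry_factor(71, 2) == pytest.approx(134 / 142)


class TestSimulationRecovery:
    def test_channel_consistency_and_accuracy(self, small_cohort, cohort_matrix,
                                              quant_config):
        metrics = quantify_sample(
            small_cohort.libraries[0].sam_path, small_cohort.truth.sites,
            quant_config,
        )
        m = np.array([x.m_metric for x in metrics])
        u = np.array([x.u_metric for x in metrics])
        pct = np.array([x.pct_met for x in metrics])
        f = small_cohort.truth.f_by_group["A"]
        ok = ~np.isnan(m)
        total = m[ok] + u[ok]
        assert np.mean((total > 0.8) & (total < 1.2)) >= 0.85
        rmse = np.sqrt(np.mean((pct[ok] - 100 * f[ok]) ** 2))
        assert rmse < 6  # 60x; acceptance asserts <5 at 100x

    def test_monotonicity_in_planted_f(self, tmp_path, quant_config):
        import dataclasses

        from msreseq.simulate import (
            SimConfig,
            assign_methylation,
            generate_genome,
            simulate_library,
        )

        cfg = SimConfig(genome_length=60_000, n_sites=60, mean_coverage=50,
                        digestion_efficiency=1.0, seed=21)
        genome, sites = generate_genome(cfg)
        truth = assign_methylation(cfg, sites)
        mean_m, mean_u = [], []
        qcfg = QuantConfig(min_calibration_sites=5)
        for f in (0.0, 0.25, 0.5, 0.75, 1.0):
            truth.f_by_group["A"] = np.full(len(sites), f)
            lib = simulate_library(genome, truth, f"f{f}", "A", cfg,
                                   tmp_path / f"f{f}")
            metrics_list = []
            from msreseq.quantify import (
                load_alignments,
                tabulate_site_evidence,
            )

            aln = load_alignments(lib.sam_path)
            counts = tabulate_site_evidence(aln, sites, qcfg)
            # kappa from the f=0 run is reused (high-f runs cannot calibrate)
            if f == 0.0:
                kappa = estimate_end_capture(counts, qcfg)
            metrics_list = [compute_metrics(c, kappa, qcfg) for c in counts]
            mean_m.append(np.nanmean([x.m_metric for x in metrics_list]))
            mean_u.append(np.nanmean([x.u_metric for x in metrics_list]))
        assert np.all(np.diff(mean_m) > 0)
        assert np.all(np.diff(mean_u) < 0)


def _metrics_row(site, pct, u=0.2, flagged=False):
    if flagged:
        return SiteMetrics(site, np.nan, np.nan, np.nan, low_coverage=True)
    return SiteMetrics(site, pct / 100, u, pct)


class TestBuildMatrix:
    def test_shapes(self):
        sites = [_site(100), _site(800), _site(1600)]
        metrics = {
            "s1": [_metrics_row(s, 50.0) for s in sites],
            "s2": [_metrics_row(s, 60.0) for s in sites],
        }
        mm = build_matrix(metrics, {"s1": "A", "s2": "B"})
        assert mm.data.shape == (6, 2)

    def test_complete_case_drop(self):
        sites = [_site(100), _site(800)]
        metrics = {
            "s1": [_metrics_row(sites[0], 50.0), _metrics_row(sites[1], 70.0)],
            "s2": [_metrics_row(sites[0], 55.0),
                   _metrics_row(sites[1], 0, flagged=True)],
        }
        mm = build_matrix(metrics, {"s1": "A", "s2": "B"})
        assert mm.data.shape == (2, 2)
        assert all(i.endswith("0000000102") for i in mm.data.index)

    def test_rows_sorted_lexicographically(self, cohort_matrix):
        ids = list(cohort_matrix.data.index)
        assert ids == sorted(ids)
        n = len(ids)
        assert all(i.startswith("M.") for i in ids[: n // 2])
        assert all(i.startswith("U.") for i in ids[n // 2:])

    def test_manifest_sample_missing_errors(self):
        sites = [_site(100)]
        metrics = {"s1": [_metrics_row(sites[0], 50.0)],
                   "s2": [_metrics_row(sites[0], 50.0)]}
        with pytest.raises(ValueError):
            build_matrix(metrics, {"s1": "A", "s2": "B", "s3": "B"})

    def test_tsv_roundtrip(self, cohort_matrix, tmp_path):
        path = tmp_path / "matrix.tsv"
        cohort_matrix.to_tsv(path)
        back = MethylationMatrix.from_tsv(path, cohort_matrix.groups)
        assert list(back.data.columns) == list(cohort_matrix.data.columns)
        np.testing.assert_allclose(
            back.data.to_numpy(), cohort_matrix.data.to_numpy(), atol=5e-4
        )


class TestGroupDifferenceFilter:
    def _matrix(self, mean_a, mean_b):
        data = pd.DataFrame(
            {
                "a1": [mean_a], "a2": [mean_a],
                "b1": [mean_b], "b2": [mean_b],
            },
            index=["M.chr1.0000000102"],
        )
        return MethylationMatrix(
            data, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"}
        )

    def test_retained(self):
        assert len(filter_by_group_difference(self._matrix(80, 65)).data) == 1

    def test_dropped(self):
        assert len(filter_by_group_difference(self._matrix(80, 75)).data) == 0

    def test_boundary_strict(self):
        assert len(filter_by_group_difference(self._matrix(80, 70)).data) == 0

    def test_empty_group_errors(self):
        data = pd.DataFrame({"a1": [50.0], "a2": [60.0]},
                            index=["M.chr1.0000000102"])
        mm = MethylationMatrix(data, {"a1": "A", "a2": "A"})
        with pytest.raises(ValueError):
            filter_by_group_difference(mm)
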