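import numpy as np
import pytest
from scipy import stats

from peakscape.core import (
    AnnotationRecord,
    AnnotationSet,
    GenomeModel,
    hit_flags,
    read_fasta,
    read_gff,
    read_peaks,
    read_track,
    total_bases,
)
from peakscape.expression import load_expression_table
from peakscape.profiles import gc_track
from peakscape.simulate import (
    SimulationConfig,
    generate_expression,
    simulate,
    subunit_replicate_peaks,
    write_bundle,
)
from conftest import SMALL_SIM


class TestConfigValidation:
    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(frac_active_promoters_bound=1.5)

    def test_chrom_length_vs_peak_width(self):
        with pytest.raises(ValueError):
            SimulationConfig(chrom_length=1_000, peak_width_mean=400)


class TestDeterminism:
    def test_same_seed_identical_bundle(self):
        cfg = SimulationConfig(**SMALL_SIM)
        a = simulate(cfg, seed=11)
        b = simulate(cfg, seed=11)
        assert a.sequences == b.sequences
        assert a.expression.equals(b.expression)
        assert a.tf_sets == b.tf_sets
        for complex_name in a.true_peaks:
            assert a.true_peaks[complex_name].peaks == b.true_peaks[complex_name].peaks
            for subunit in a.chip_tracks[complex_name]:
                for ta, tb in zip(
                    a.chip_tracks[complex_name][subunit], b.chip_tracks[complex_name][subunit]
                ):
                    for c in ta.data:
                        assert np.array_equal(ta.data[c], tb.data[c])

    def test_different_seed_differs(self):
        cfg = SimulationConfig(**SMALL_SIM)
        a = simulate(cfg, seed=1)
        b = simulate(cfg, seed=2)
        assert a.sequences != b.sequences


class TestSequence:
    def test_background_gc_fraction(self, small_bundle):
        seq = "".join(small_bundle.sequences.values())
        gc = sum(1 for ch in seq if ch in "GC") / len(seq)
        # peaks elevate GC slightly above background; allow for that margin
        n = len(seq)
        sd = np.sqrt(0.36 * 0.64 / n)
        assert abs(gc - small_bundle.config.gc_background) < 0.02

    def test_gc_elevated_at_summits_recomputed_from_sequence(self):
        cfg = SimulationConfig(
            **{**SMALL_SIM, "gc_background": 0.5, "gc_at_peaks": 0.7, "motif_plant_prob": 0.0}
        )
        b = simulate(cfg, seed=3)
        at_summit, at_flank = [], []
        for ps in b.true_peaks.values():
            for p in ps:
                vals = gc_track(b.sequences[p.chrom], 15)
                at_summit.append(vals[p.summit])
                flank_pos = p.summit - 600
                if flank_pos > 14:
                    at_flank.append(vals[flank_pos])
        assert np.mean(at_summit) == pytest.approx(0.7, abs=0.05)
        assert np.mean(at_flank) == pytest.approx(0.5, abs=0.05)

    def test_planted_motif_present_in_sequence(self, small_bundle):
        motif = small_bundle.config.motif_consensus
        for iv in small_bundle.planted_motifs:
            assert small_bundle.sequences[iv.chrom][iv.start : iv.end] == motif


class TestTruePeaks:
    def test_x_bias_concentrates_idc_on_x(self):
        cfg = SimulationConfig(
            n_chroms=3,
            chrom_length=50_000,
            n_genes_per_chrom=10,
            n_trnas_per_chrom=2,
            n_ncrnas_per_chrom=2,
            frac_active_promoters_bound=0.0,
            trna_bound_prob=0.0,
            n_enhancers_per_complex=80,
            x_bias=50.0,
        )
        fracs = []
        for seed in range(4):
            b = simulate(cfg, seed=seed)
            fracs.append(np.mean([p.chrom == "chrX" for p in b.true_peaks["condensin_IDC"]]))
        assert np.mean(fracs) > 0.9

    def test_condensin_ii_unbiased(self, small_bundle):
        frac_x = np.mean([p.chrom == "chrX" for p in small_bundle.true_peaks["condensin_II"]])
        assert frac_x < 0.7

    def test_frac_active_promoters_recovered(self):
        cfg = SimulationConfig(
            n_chroms=4,
            chrom_length=80_000,
            n_genes_per_chrom=40,
            n_trnas_per_chrom=2,
            n_ncrnas_per_chrom=2,
            frac_active_promoters_bound=0.2,
            x_bias=1.0,
            expression_shift=0.0,
            n_enhancers_per_complex=5,
        )
        fracs = []
        for seed in range(5):
            b = simulate(cfg, seed=seed)
            expr = dict(zip(b.expression["gene"], b.expression["median"]))
            genes = [r for r in b.annotations if r.cls == "gene"]
            cutoff = np.quantile([expr[g.name] for g in genes], 0.75)
            top = [g for g in genes if expr[g.name] >= cutoff]
            summits = {
                (p.chrom, p.summit)
                for p in b.true_peaks["condensin_II"]
            }
            n_bound = sum(
                any(c == g.chrom and abs(s - g.tss) <= 1_000 for c, s in summits) for g in top
            )
            fracs.append(n_bound / len(top))
        assert np.mean(fracs) == pytest.approx(0.2, abs=0.08)


class TestTracks:
    def test_null_enrichment_indistinguishable_from_input(self):
        cfg = SimulationConfig(
            **{**SMALL_SIM, "enrichment_height": 0.0, "replicate_noise": 0.0}
        )
        b = simulate(cfg, seed=5)
        chip = b.chip_tracks["condensin_II"]["iiSub1"][0].data["chr1"]
        inp = b.input_tracks["condensin_II"].data["chr1"]
        _, p = stats.ks_2samp(chip[:5_000], inp[:5_000])
        assert p > 0.01

    def test_peaks_visible_in_chip_not_input(self, small_bundle):
        b = small_bundle
        p = b.true_peaks["condensin_II"].peaks[0]
        chip = b.chip_tracks["condensin_II"]["iiSub1"][0].data[p.chrom]
        inp = b.input_tracks["condensin_II"].data[p.chrom]
        assert chip[p.summit] > inp[p.summit] + 3 * np.sqrt(b.config.background_rate)

    def test_replicate_dropout_bounded_to_minority(self):
        cfg = SimulationConfig(**{**SMALL_SIM, "replicate_dropout": 0.5})
        b = simulate(cfg, seed=9)
        for complex_name, ps in b.true_peaks.items():
            for subunit in b.chip_tracks[complex_name]:
                _, reps = subunit_replicate_peaks(b, complex_name, subunit)
                for i in range(len(ps)):
                    present = sum(
                        1
                        for r in range(cfg.n_replicates)
                        if (subunit, r, i) not in b.dropped[complex_name]
                    )
                    assert present * 2 > cfg.n_replicates  # strict majority retained


class TestExpression:
    def _gene_set(self, n):
        genome = GenomeModel({"chrI": (n + 2) * 1_000})
        recs = [
            AnnotationRecord("chrI", (i + 1) * 1_000, (i + 1) * 1_000 + 500, "+", "gene", f"g{i}")
            for i in range(n)
        ]
        return AnnotationSet(recs)

    def test_zero_shift_null_rho(self, rng):
        cfg = SimulationConfig(expression_shift=0.0)
        ann = self._gene_set(2_000)
        strength = {f"g{i}": float(rng.random()) for i in range(2_000)}
        df = generate_expression(cfg, ann, set(), set(), np.random.default_rng(0),
                                 binding_strength=strength)
        rho, _ = stats.spearmanr(
            [strength[g] for g in df["gene"]], df["median"]
        )
        assert abs(rho) < 0.1

    def test_positive_shift_positive_rho(self):
        cfg = SimulationConfig(expression_shift=1.5)
        ann = self._gene_set(500)
        bound = {f"g{i}" for i in range(0, 500, 3)}
        df = generate_expression(cfg, ann, bound, set(df_active := {f"g{i}" for i in range(500)}),
                                 np.random.default_rng(1))
        flags = [1.0 if g in bound else 0.0 for g in df["gene"]]
        rho, _ = stats.spearmanr(flags, df["median"])
        assert rho > 0.2

    def test_copula_recovers_target_rho(self, rng):
        cfg = SimulationConfig(expression_target_spearman=0.3)
        ann = self._gene_set(2_000)
        rhos = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            strength = {f"g{i}": float(r.random()) for i in range(2_000)}
            df = generate_expression(cfg, ann, set(), set(), r, binding_strength=strength)
            rho, _ = stats.spearmanr([strength[g] for g in df["gene"]], df["median"])
            rhos.append(rho)
        assert np.mean(rhos) == pytest.approx(0.3, abs=0.05)

    def test_median_column_is_replicate_median(self, small_bundle):
        df = small_bundle.expression
        reps = [c for c in df.columns if c.startswith("rep")]
        assert np.allclose(df["median"], df[reps].median(axis=1))


class TestTfSets:
    def test_planted_overlap_rate_recovered(self, small_bundle):
        b = small_bundle
        truth = [p.interval for ps in b.true_peaks.values() for p in ps]
        for name, sites in b.tf_sets.items():
            measured = hit_flags(sites, truth).mean()
            n = len(sites)
            se = np.sqrt(0.6 * 0.4 / n)
            # measured rate = planted rate + chance hits of the random remainder
            assert measured >= b.tf_truth_overlap[name] - 1e-9
            assert measured == pytest.approx(0.6, abs=3 * se + 0.15)

    def test_rate_zero_at_random_expectation(self):
        cfg = SimulationConfig(**{**SMALL_SIM, "tf_overlap_rate": 0.0})
        b = simulate(cfg, seed=13)
        truth = [p.interval for ps in b.true_peaks.values() for p in ps]
        genome_len = sum(b.genome.chrom_lengths.values())
        p_chance = (total_bases(truth) + len(truth) * 250) / genome_len
        for sites in b.tf_sets.values():
            measured = hit_flags(sites, truth).mean()
            se = np.sqrt(max(p_chance * (1 - p_chance), 1e-4) / len(sites))
            assert measured < p_chance + 4 * se + 0.05

    def test_hot_regions_covered_by_k_tfs(self, small_bundle):
        b = small_bundle
        k = b.config.hot_k
        for hot in b.hot_regions[:10]:
            mid = (hot.start + hot.end) // 2
            n_cover = sum(
                any(iv.chrom == hot.chrom and iv.start <= mid < iv.end for iv in sites)
                for sites in b.tf_sets.values()
            )
            assert n_cover >= k


class TestEmittedFiles:
    def test_bundle_reparses_through_core_readers(self, small_bundle, tmp_path):
        paths = write_bundle(small_bundle, tmp_path)
        genome = small_bundle.genome
        seqs = read_fasta(paths["fasta"])
        assert seqs == small_bundle.sequences
        ann = read_gff(paths["annotations"], genome=genome)
        assert len(ann) == len(small_bundle.annotations)
        track = read_track(paths["chip/condensin_II/iiSub1/rep1"], genome)
        orig = small_bundle.chip_tracks["condensin_II"]["iiSub1"][0]
        for c in genome.chrom_names:
            assert np.array_equal(track.data[c], orig.data[c])
        ps = read_peaks(paths["truth/condensin_II"], genome=genome)
        assert [(p.chrom, p.start, p.end, p.summit) for p in ps] == [
            (p.chrom, p.start, p.end, p.summit) for p in small_bundle.true_peaks["condensin_II"]
        ]
        expr = load_expression_table(paths["expression"])
        assert len(expr) == len(small_bundle.expression)

    def test_truth_files_alongside_data(self, small_bundle, tmp_path):
        paths = write_bundle(small_bundle, tmp_path / "x")
        for key in ("truth_json", "truth/condensin_IDC", "motifs", "hot"):
            assert key in paths
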