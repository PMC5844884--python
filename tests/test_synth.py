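"""The synthetic-data generator: determinism, planted-truth contracts."""

import numpy as np
import pandas as pd
import pytest

from enhancerkit.genome import GenomeLayout
from enhancerkit.intervals import build_tss_index, Interval, is_distal
from enhancerkit.synth import (
    PlantedTruth,
    default_layout,
    generate_annotation,
    plant_truth,
    simulate_chip,
    simulate_cohort,
    simulate_expression,
    simulate_sequences,
)


def small_layout():
    return GenomeLayout({"chr1": 5_000_000})


class TestAnnotation:
    def test_zero_genes_rejected(self):
        with pytest.raises(ValueError):
            generate_annotation(0, small_layout(), seed=1)

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            generate_annotation(10_000, small_layout(), seed=1)

    def test_deterministic_for_fixed_seed(self):
        a = generate_annotation(50, small_layout(), seed=1)
        b = generate_annotation(50, small_layout(), seed=1)
        assert a == b
        c = generate_annotation(50, small_layout(), seed=2)
        assert a != c

    def test_tss_separation_brute_force(self):
        genes = generate_annotation(50, small_layout(), seed=1)
        tss = [g.tss for g in genes]
        min_d = min(
            abs(a - b) for i, a in enumerate(tss) for b in tss[i + 1 :]
        )
        assert min_d >= 20_000

    def test_tss_is_five_prime_exon_boundary(self):
        for g in generate_annotation(50, small_layout(), seed=3):
            if g.strand == "+":
                assert g.tss == g.exons[0][0]
            else:
                assert g.tss == g.exons[-1][1]


class TestPlantedTruth:
    def _truth(self, seed=1):
        layout = default_layout(120)
        genes = generate_annotation(120, layout, seed)
        truth = plant_truth(
            genes, layout, seed, n_per_state=20, n_up=15, n_down=15, n_undetected=5
        )
        return layout, genes, truth

    def test_every_enhancer_is_distal(self):
        layout, genes, truth = self._truth()
        index = build_tss_index(genes)
        for iv in truth.enhancer_regions():
            assert is_distal(iv, index, 2000)

    def test_down_promoters_carry_miz1(self):
        _, _, truth = self._truth()
        down = truth.promoter_class[truth.promoter_class == "myc_down"].index
        assert (truth.rate_ratio[down] == 0.5).all()
        up = truth.promoter_class[truth.promoter_class == "myc_up"].index
        assert (truth.rate_ratio[up] == 8.0).all()

    def test_too_few_genes_rejected(self):
        layout = default_layout(50)
        genes = generate_annotation(50, layout, 1)
        with pytest.raises(ValueError):
            plant_truth(genes, layout, 1, n_per_state=20)

    def test_json_round_trip(self):
        _, _, truth = self._truth()
        back = PlantedTruth.from_dict(truth.to_dict())
        pd.testing.assert_frame_equal(truth.enhancers, back.enhancers)
        pd.testing.assert_series_equal(
            truth.promoter_class, back.promoter_class, check_names=False
        )
        pd.testing.assert_frame_equal(truth.expr_log2fc, back.expr_log2fc)
        assert truth.signature == back.signature


class TestSimulateChip:
    def _setup(self, seed=2):
        layout = default_layout(120)
        genes = generate_annotation(120, layout, seed)
        truth = plant_truth(
            genes, layout, seed, n_per_state=20, n_up=15, n_down=15, n_undetected=5
        )
        return layout, genes, truth

    def test_fold_below_one_rejected(self):
        layout, genes, truth = self._setup()
        bad = {"H3K4me1": {"inactive": {"WT": 0.5}}}
        with pytest.raises(ValueError):
            simulate_chip(genes, truth, layout, fold_map=bad, seed=1)

    def test_null_fold_map_gives_flat_mean(self):
        layout, genes, truth = self._setup()
        flat = {"H3K4me1": {"inactive": {"WT": 1.0}}}
        sim = simulate_chip(
            genes, truth, layout, depth=None, background_rate=2.0,
            fold_map=flat, seed=7,
        )
        track = sim.tracks[("H3K4me1", "WT")]
        regions = truth.enhancer_regions("inactive")
        vals = np.concatenate(
            [track.counts[iv.chromosome][iv.start // 100 : iv.end // 100] for iv in regions]
        )
        se = np.sqrt(2.0 / len(vals))
        assert abs(vals.mean() - 2.0) <= 3 * se

    def test_planted_mean_matches_poisson_rate(self):
        layout, genes, truth = self._setup()
        fm = {"H3K4me1": {"inactive": {"WT": 8.0}}}
        sim = simulate_chip(
            genes, truth, layout, depth=None, background_rate=2.0,
            fold_map=fm, seed=7,
        )
        track = sim.tracks[("H3K4me1", "WT")]
        vals = np.concatenate(
            [
                track.counts[iv.chromosome][iv.start // 100 : iv.end // 100]
                for iv in truth.enhancer_regions("inactive")
            ]
        )
        # 20 regions x 20 bins = 400 bins at rate 16
        se = np.sqrt(16.0 / len(vals))
        assert abs(vals.mean() - 16.0) <= 3 * se

    def test_depth_scaling_and_library_within_one_percent(self):
        layout, genes, truth = self._setup()
        sim = simulate_chip(genes, truth, layout, depth=1_000_000, seed=3)
        for track in sim.tracks.values():
            assert abs(track.library_size - 1_000_000) / 1_000_000 <= 0.01

    def test_same_seed_identical_counts(self):
        layout, genes, truth = self._setup()
        a = simulate_chip(genes, truth, layout, seed=5)
        b = simulate_chip(genes, truth, layout, seed=5)
        for key in a.tracks:
            for chrom in a.tracks[key].counts:
                assert np.array_equal(
                    a.tracks[key].counts[chrom], b.tracks[key].counts[chrom]
                )


class TestSimulateExpression:
    def _setup(self):
        layout = default_layout(120)
        genes = generate_annotation(120, layout, 4)
        truth = plant_truth(
            genes, layout, 4, n_per_state=20, n_up=15, n_down=15, n_undetected=5
        )
        return genes, truth

    def test_zero_noise_replicates_identical(self):
        genes, truth = self._setup()
        mat = simulate_expression(genes, truth, noise_sd=0.0, seed=1)
        for cond in ("WT", "MYC", "M2"):
            cols = mat.samples_of(cond)
            base = mat.intensities[cols[0]]
            for c in cols[1:]:
                pd.testing.assert_series_equal(
                    mat.intensities[c], base, check_names=False
                )

    def test_noiseless_fold_recovery_exact(self):
        genes, truth = self._setup()
        mat = simulate_expression(genes, truth, noise_sd=0.0, seed=1)
        up = truth.promoter_class[truth.promoter_class == "myc_up"].index[0]
        wt = mat.intensities.loc[up, mat.samples_of("WT")].mean()
        myc = mat.intensities.loc[up, mat.samples_of("MYC")].mean()
        assert myc / wt == pytest.approx(4.0, rel=1e-12)

    def test_noisy_fold_within_three_se(self):
        genes, truth = self._setup()
        noise_sd = 0.25
        mat = simulate_expression(genes, truth, noise_sd=noise_sd, seed=3)
        up = list(truth.promoter_class[truth.promoter_class == "myc_up"].index)
        l2 = np.log2(mat.intensities)
        diffs = (
            l2.loc[up, mat.samples_of("MYC")].mean(axis=1)
            - l2.loc[up, mat.samples_of("WT")].mean(axis=1)
        )
        se = noise_sd * np.sqrt(2 / 3) / np.sqrt(len(up))
        assert abs(diffs.mean() - 2.0) <= 3 * se

    def test_undetected_genes_have_high_detection_p(self):
        genes, truth = self._setup()
        mat = simulate_expression(genes, truth, seed=1)
        assert (mat.detection_p.loc[truth.undetected] > 0.05).all().all()
        detected = mat.detection_p.drop(index=truth.undetected)
        assert (detected <= 0.05).all().all()

    def test_negative_noise_rejected(self):
        genes, truth = self._setup()
        with pytest.raises(ValueError):
            simulate_expression(genes, truth, noise_sd=-0.1)


class TestSimulateSequences:
    def test_motif_planted_at_enhancer_centers(self):
        layout = default_layout(120)
        genes = generate_annotation(120, layout, 5)
        truth = plant_truth(
            genes, layout, 5, n_per_state=20, n_up=15, n_down=15, n_undetected=5
        )
        seqs = simulate_sequences(layout, truth, seed=5)
        planted = truth.enhancers[truth.enhancers["motif"] == 1]
        for row in planted.itertuples(index=False):
            mid = (row.start + row.end) // 2
            window = seqs[row.chromosome][mid - 20 : mid + 20]
            assert "GGCATGTGCC" in window

    def test_deterministic(self):
        layout = GenomeLayout({"chr1": 200_000})
        genes = generate_annotation(5, layout, 1)
        truth = plant_truth(
            genes, layout, 1, n_per_state=1, n_up=1, n_down=0, n_undetected=0
        )
        assert simulate_sequences(layout, truth, seed=9) == simulate_sequences(
            layout, truth, seed=9
        )


class TestSimulateCohort:
    def test_no_censoring_all_events(self):
        sim = simulate_cohort(["gA", "gB"], n_patients=50, censor_fraction=0.0, seed=1)
        assert (sim.cohort.meta["event"] == 1).all()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_cohort([], n_patients=10)
        with pytest.raises(ValueError):
            simulate_cohort(["g"], hazard_ratio=0.0)
        with pytest.raises(ValueError):
            simulate_cohort(["g"], censor_fraction=1.0)

    def test_high_group_has_shorter_event_times(self):
        sim = simulate_cohort(
            [f"g{i}" for i in range(20)],
            n_patients=400,
            hazard_ratio=3.0,
            censor_fraction=0.0,
            seed=2,
        )
        meta = sim.cohort.meta
        hi = meta.loc[sim.true_group == "High", "time"]
        lo = meta.loc[sim.true_group == "Low", "time"]
        assert hi.median() < lo.median()

    def test_hazard_ratio_one_type_one_error(self):
        from enhancerkit.survival import logrank

        rejections = 0
        n_rep = 200
        for seed in range(n_rep):
            sim = simulate_cohort(
                ["g0", "g1", "g2"], n_patients=80, hazard_ratio=1.0,
                censor_fraction=0.2, seed=seed,
            )
            meta = sim.cohort.meta
            hi = meta[sim.true_group == "High"]
            lo = meta[sim.true_group == "Low"]
            if len(hi) and len(lo):
                out = logrank(hi["time"], hi["event"], lo["time"], lo["event"])
                rejections += out["p_value"] < 0.05
        rate = rejections / n_rep
        se = np.sqrt(0.05 * 0.95 / n_rep)
        assert abs(rate - 0.05) <= 3 * se
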