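"""Expression preprocessing, fold-change calls, GSEA, binned correlation."""

import numpy as np
import pandas as pd
import pytest
from itertools import combinations

from enhancerkit.expression import (
    binned_binding_correlation,
    detection_filter,
    enrichment_score,
    fold_change_calls,
    gsea_preranked,
    quantile_normalize,
)

from .oracles import gsea_es_enumeration


class TestQuantileNormalize:
    def test_identical_columns_fixed_point(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_hand_computed_two_by_two(self):
        df = pd.DataFrame([[1.0, 3.0], [5.0, 7.0]], columns=["s1", "s2"])
        out = quantile_normalize(df)
        assert out["s1"].tolist() == [2.0, 6.0]
        assert out["s2"].tolist() == [2.0, 6.0]

    def test_sorted_columns_identical_after(self, rng):
        df = pd.DataFrame(rng.normal(size=(200, 5)), columns=list("abcde"))
        out = quantile_normalize(df)
        ref = np.sort(out["a"].to_numpy())
        for c in "bcde":
            assert np.allclose(np.sort(out[c].to_numpy()), ref)
        assert np.allclose(out.mean(axis=0), out.mean(axis=0).iloc[0])

    def test_ties_get_mean_of_spanned_reference(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 10.0], "b": [2.0, 4.0, 6.0]})
        out = quantile_normalize(df)
        ref = np.sort(df.to_numpy(), axis=0).mean(axis=1)
        assert out["a"].iloc[0] == pytest.approx((ref[0] + ref[1]) / 2)
        assert out["a"].iloc[0] == out["a"].iloc[1]

    def test_single_column_rejected(self):
        with pytest.raises(ValueError):
            quantile_normalize(pd.DataFrame({"a": [1.0, 2.0]}))


class TestDetectionFilter:
    def _tables(self, p):
        p = pd.DataFrame(p, columns=["s1", "s2", "s3"])
        m = pd.DataFrame(
            np.ones_like(p.to_numpy()), index=p.index, columns=p.columns
        )
        return m, p

    def test_single_detected_sample_keeps_gene(self):
        m, p = self._tables([[0.04, 0.5, 0.5]])
        assert len(detection_filter(m, p)) == 1

    def test_undetected_everywhere_removed(self):
        m, p = self._tables([[0.06, 0.06, 0.06]])
        assert len(detection_filter(m, p)) == 0

    def test_matches_row_scan_oracle(self, rng):
        p = pd.DataFrame(rng.uniform(0, 0.1, size=(500, 4)))
        m = pd.DataFrame(rng.normal(size=(500, 4)))
        out = detection_filter(m, p)
        expected = [i for i in range(500) if any(p.iloc[i] <= 0.05)]
        assert list(out.index) == expected

    def test_misaligned_tables_rejected(self):
        m, p = self._tables([[0.01, 0.01, 0.01]])
        with pytest.raises(ValueError):
            detection_filter(m, p.rename(columns={"s1": "x"}))


class TestFoldChangeCalls:
    def _matrix(self, a_vals, b_vals):
        data = {f"A_{i}": [v] for i, v in enumerate(a_vals)}
        data.update({f"B_{i}": [v] for i, v in enumerate(b_vals)})
        df = pd.DataFrame(data, index=["g"])
        cond = pd.Series(
            {c: ("A" if c.startswith("A") else "B") for c in df.columns}
        )
        return df, cond

    def test_flooring_neutralizes_sub_unit_intensities(self):
        df, cond = self._matrix([0.2, 0.2], [0.5, 0.5])
        out = fold_change_calls(df, "A", "B", cond)
        assert out.loc["g", "fold_change"] == 1.0
        assert out.loc["g", "call"] == "unchanged"

    def test_twofold_boundary_inclusive(self):
        df, cond = self._matrix([10.0, 10.0], [20.0, 20.0])
        out = fold_change_calls(df, "A", "B", cond)
        assert out.loc["g", "call"] == "up"
        df, cond = self._matrix([20.0, 20.0], [10.0, 10.0])
        assert fold_change_calls(df, "A", "B", cond).loc["g", "call"] == "down"

    def test_noiseless_planted_folds_recovered(self):
        rng = np.random.default_rng(3)
        folds = rng.choice([4.0, 1.0, 0.25], size=500)
        base = rng.uniform(10, 100, size=500)
        cols = {f"A_{i}": base for i in range(3)}
        cols.update({f"B_{i}": base * folds for i in range(3)})
        df = pd.DataFrame(cols, index=[f"g{i}" for i in range(500)])
        cond = pd.Series({c: c[0] for c in df.columns})
        out = fold_change_calls(df, "A", "B", cond)
        expected = np.select([folds == 4.0, folds == 0.25], ["up", "down"], "unchanged")
        assert (out["call"].to_numpy() == expected).all()

    def test_unknown_condition_rejected(self):
        df, cond = self._matrix([1.0, 1.0], [2.0, 2.0])
        with pytest.raises(KeyError):
            fold_change_calls(df, "A", "Z", cond)


class TestGSEA:
    def test_top_ranked_set_reaches_maximal_es(self):
        stats = pd.Series(np.arange(10, 0, -1, dtype=float), index=list("abcdefghij"))
        es = enrichment_score(stats, {"a", "b"}, weight=0.0)
        # direct running-sum enumeration: +1/2 at each of the top 2 hits
        assert es == pytest.approx(1.0)

    def test_es_matches_enumeration_for_all_placements(self):
        n = 12
        rng = np.random.default_rng(17)
        vals = np.sort(rng.normal(1.0, 2.0, size=n))[::-1]  # asymmetric, distinct
        stats = pd.Series(vals, index=[f"g{i}" for i in range(n)])
        genes = list(stats.index)
        for k in (1, 2, 3):
            for combo in combinations(range(n), k):
                members = {genes[i] for i in combo}
                in_set = np.array([g in members for g in genes])
                best_pos, best_neg = gsea_es_enumeration(stats.to_numpy(), in_set, 1.0)
                expected = best_pos if best_pos >= -best_neg else best_neg
                got = enrichment_score(stats, members, weight=1.0)
                if abs(best_pos + best_neg) > 1e-9:
                    assert got == pytest.approx(expected, abs=1e-12)
                else:  # exact tie: the sign is ambiguous, the magnitude is not
                    assert abs(got) == pytest.approx(best_pos, abs=1e-12)

    def test_planted_extreme_set_attains_minimal_p(self):
        rng = np.random.default_rng(5)
        stats = pd.Series(
            rng.normal(size=1000), index=[f"g{i}" for i in range(1000)]
        )
        top = list(stats.sort_values(ascending=False).index[:20])
        stats[top] += 50
        res = gsea_preranked(stats, top, n_perm=999, seed=1)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.es > 0.9

    def test_null_permutation_mean_near_zero(self):
        rng = np.random.default_rng(6)
        stats = pd.Series(
            rng.normal(size=200), index=[f"g{i}" for i in range(200)]
        )
        ps = []
        for seed in range(30):
            members = list(rng.choice(stats.index, 15, replace=False))
            res = gsea_preranked(stats, members, n_perm=200, seed=seed)
            ps.append(res.p_value)
        assert 0.05 < np.mean(ps) < 0.95

    def test_degenerate_sets_rejected(self):
        stats = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        with pytest.raises(ValueError):
            gsea_preranked(stats, [], n_perm=100)
        with pytest.raises(ValueError):
            gsea_preranked(stats, list("abc"), n_perm=100)


class TestBinnedCorrelation:
    def test_constant_binding_flagged_degenerate(self):
        fc = pd.Series(np.arange(30, dtype=float), index=[f"g{i}" for i in range(30)])
        flat = pd.Series(1.0, index=fc.index)
        out = binned_binding_correlation(fc, flat)
        assert out.degenerate and np.isnan(out.r_bins)

    def test_identity_gives_perfect_correlation(self):
        fc = pd.Series(np.arange(30, dtype=float), index=[f"g{i}" for i in range(30)])
        out = binned_binding_correlation(fc, fc.copy())
        assert out.r_bins == pytest.approx(1.0)

    def test_matches_brute_force_and_sharpens_correlation(self):
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 300
            log2fc = rng.normal(0, 1.5, n)
            binding = 0.8 * log2fc + rng.normal(0, 1.5, n)
            fc = pd.Series(log2fc, index=[f"g{i:03d}" for i in range(n)])
            db = pd.Series(binding, index=fc.index)
            out = binned_binding_correlation(fc, db)
            # brute-force recomputation
            order = sorted(fc.index, key=lambda g: (-fc[g], g))
            bins = [order[i * 10 : (i + 1) * 10] for i in range(n // 10)]
            mfc = np.array([fc[b].mean() for b in bins])
            mdb = np.array([db[b].mean() for b in bins])
            r = np.corrcoef(mfc, mdb)[0, 1]
            assert out.r_bins == pytest.approx(r, abs=1e-12)
            if out.r_bins > out.r_genes:
                wins += 1
        assert wins >= 19

    def test_too_few_genes_rejected(self):
        fc = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError):
            binned_binding_correlation(fc, fc)
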