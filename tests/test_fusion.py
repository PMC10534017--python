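"""Feature fusion: normalization, oversampling, multicollinearity reduction,
block assembly."""

import numpy as np
import pandas as pd
import pytest

from mfcrad.fusion import (
    FeatureTable,
    FusionConfig,
    assemble_feature_blocks,
    gaussian_oversample,
    multicollinearity_reduce,
    zscore_normalize,
)

from _oracles import exhaustive_reduction


def random_table(rng, n=20, p=6, prefix="f"):
    return pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"{prefix}{j}" for j in range(p)],
        index=[f"pt{i}" for i in range(n)],
    )


class TestZScore:
    def test_training_columns_standardized(self, rng):
        df = random_table(rng)
        norm, _, _ = zscore_normalize(df)
        np.testing.assert_allclose(norm.mean(), 0.0, atol=1e-9)
        np.testing.assert_allclose(norm.std(ddof=0), 1.0, atol=1e-9)

    def test_constant_feature_zeroed_and_flagged(self, rng):
        df = random_table(rng)
        df["f0"] = 3.14
        norm, _, stats = zscore_normalize(df)
        assert stats.zero_variance == ["f0"]
        assert (norm["f0"] == 0.0).all()

    def test_held_out_row_at_train_mean_maps_to_zero(self, rng):
        df = random_table(rng)
        held = pd.DataFrame([df.mean()], index=["new"])
        _, applied, _ = zscore_normalize(df, held)
        np.testing.assert_allclose(applied.loc["new"], 0.0, atol=1e-9)

    def test_empty_training_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            zscore_normalize(pd.DataFrame())


class TestGaussianOversample:
    def test_zero_noise_gives_exact_duplicates(self, rng):
        df = random_table(rng, n=6)
        labels = np.array([0, 0, 0, 0, 1, 1])
        cfg = FusionConfig(oversample_multiplicity=3, oversample_noise_sd=0.0, balance_classes=False)
        aug, aug_labels = gaussian_oversample(df, labels, cfg, rng=rng)
        assert len(aug) == 18
        np.testing.assert_array_equal(aug.iloc[:6].to_numpy(), df.to_numpy())
        assert aug_labels.sum() == 6

    def test_multiplicity_count_without_balancing(self, rng):
        df = random_table(rng, n=7)
        labels = np.array([0, 1, 0, 1, 0, 1, 0])
        cfg = FusionConfig(oversample_multiplicity=4, balance_classes=False)
        aug, _ = gaussian_oversample(df, labels, cfg, rng=rng)
        assert len(aug) == 28

    def test_balancing_reaches_class_parity(self, rng):
        df = random_table(rng, n=10)
        labels = np.array([1, 1] + [0] * 8)
        cfg = FusionConfig(oversample_multiplicity=2, balance_classes=True)
        _, aug_labels = gaussian_oversample(df, labels, cfg, rng=rng)
        assert (aug_labels == 1).sum() == (aug_labels == 0).sum()

    def test_noise_mean_obeys_clt_bound(self, rng):
        """10k noisy replicates of one row recover it within 3 sigma/sqrt(n)."""
        df = random_table(rng, n=4)
        labels = np.array([0, 0, 1, 1])
        frac = 0.05
        cfg = FusionConfig(
            oversample_multiplicity=10_000 // 4, oversample_noise_sd=frac, balance_classes=False
        )
        aug, _ = gaussian_oversample(df, labels, cfg, rng=rng)
        sd = df.std(ddof=0)
        row0 = aug.loc["pt0"]
        bound = 3 * sd * frac / np.sqrt(len(row0))
        assert (np.abs(row0.mean() - df.loc["pt0"]) < bound + 1e-12).all()


class TestMulticollinearityReduce:
    def test_identical_columns_keep_exactly_one(self, rng):
        df = random_table(rng, p=3)
        df["f1"] = df["f0"]
        labels = (rng.uniform(size=len(df)) < 0.5).astype(int)
        labels[:2] = [0, 1]
        kept, subsets = multicollinearity_reduce(df, labels)
        assert len([k for k in kept if k in ("f0", "f1")]) == 1
        assert "f2" in kept

    def test_near_duplicate_plus_independent(self, rng):
        df = pd.DataFrame(
            {
                "A": rng.normal(size=40),
            }
        )
        df["B"] = df["A"] + rng.normal(scale=0.01, size=40)
        df["C"] = rng.normal(size=40)
        labels = np.array([0, 1] * 20)
        kept, subsets = multicollinearity_reduce(df, labels)
        assert "C" in kept
        assert len(kept) == 2
        rep = next(k for k in kept if k != "C")
        assert set(subsets[rep]) == {"A", "B"}

    def test_uncorrelated_table_keeps_everything(self, rng):
        df = random_table(rng, n=50)
        labels = np.array([0, 1] * 25)
        kept, _ = multicollinearity_reduce(df, labels)
        assert kept == list(df.columns)

    def test_constant_feature_kept_and_isolated(self, rng):
        df = random_table(rng, p=3)
        df["f1"] = 0.0
        labels = np.array([0, 1] * 10)
        kept, subsets = multicollinearity_reduce(df, labels)
        assert "f1" in kept
        assert subsets["f1"] == ["f1"]

    def test_idempotence(self, rng):
        df = random_table(rng, n=30, p=8)
        df["f1"] = df["f0"] * 2 + rng.normal(scale=1e-3, size=30)
        labels = np.array([0, 1] * 15)
        kept1, _ = multicollinearity_reduce(df, labels)
        kept2, _ = multicollinearity_reduce(df[kept1], labels)
        assert kept1 == kept2

    def test_kept_count_monotone_in_threshold(self, rng):
        df = random_table(rng, n=25, p=10)
        for j in range(5):
            df[f"f{j+5}"] = df[f"f{j}"] + rng.normal(scale=0.05 * (j + 1), size=25)
        labels = np.array([0, 1] * 12 + [0])
        sizes = []
        for thr in (0.999, 0.95, 0.8, 0.5):
            kept, _ = multicollinearity_reduce(df, labels, FusionConfig(corr_threshold=thr))
            sizes.append(len(kept))
        assert sizes == sorted(sizes, reverse=True)

    def test_matches_exhaustive_enumeration(self, rng):
        """Component grouping + smallest-p representative vs brute force."""
        from mfcrad.fusion import _univariate_pvalues

        cfg = FusionConfig()
        for _ in range(30):
            n, p = 24, 10
            X = rng.normal(size=(n, p))
            # plant a few correlated clusters
            for j in range(1, p, 3):
                X[:, j] = X[:, j - 1] + rng.normal(scale=0.02, size=n)
            labels = rng.permutation([0, 1] * (n // 2))
            df = pd.DataFrame(X, columns=[f"f{j}" for j in range(p)])
            kept, _ = multicollinearity_reduce(df, labels, cfg)
            pv = _univariate_pvalues(X, labels, cfg.univariate_test)
            expected = exhaustive_reduction(X, labels, cfg.corr_threshold, pv)
            assert [df.columns[i] for i in expected] == kept


class TestAssemble:
    def make_blocks(self, rng, n=5, sbrt=False):
        ids = [f"pt{i}" for i in range(n)]
        hand = pd.DataFrame(rng.normal(size=(n, 105)),
                            columns=[f"h{j}" for j in range(105)], index=ids)
        deep = pd.DataFrame(rng.normal(size=(n, 512)),
                            columns=[f"d{j}" for j in range(512)], index=ids)
        ncl = 6 if sbrt else 4
        clin = pd.DataFrame(rng.normal(size=(n, ncl)),
                            columns=[f"c{j}" for j in range(ncl)], index=ids)
        return hand, deep, clin

    def test_surgery_block_widths(self, rng):
        table = assemble_feature_blocks(*self.make_blocks(rng))
        assert table.df.shape[1] == 105 + 512 + 4 == 621
        assert [table.block_of[c] for c in table.df.columns[:105]] == ["handcrafted"] * 105

    def test_sbrt_block_widths(self, rng):
        table = assemble_feature_blocks(*self.make_blocks(rng, sbrt=True))
        assert table.df.shape[1] == 623

    def test_row_order_permutation_is_canonicalized(self, rng):
        hand, deep, clin = self.make_blocks(rng)
        t1 = assemble_feature_blocks(hand, deep, clin)
        t2 = assemble_feature_blocks(hand.iloc[::-1], deep.sample(frac=1, random_state=0), clin)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_id_mismatch_names_offenders(self, rng):
        hand, deep, clin = self.make_blocks(rng)
        deep = deep.drop(index="pt3")
        with pytest.raises(ValueError, match="pt3"):
            assemble_feature_blocks(hand, deep, clin)

    def test_duplicate_columns_rejected(self, rng):
        df = pd.DataFrame(np.ones((2, 2)), columns=["a", "a"], index=["x", "y"])
        with pytest.raises(ValueError, match="duplicate"):
            FeatureTable(df, {"a": "handcrafted"})


class TestCohortReduce:
    def test_prunes_duplicates_table_wide(self, rng):
        from mfcrad.fusion import cohort_reduce

        df = random_table(rng, n=30, p=5)
        df["f1"] = df["f0"]
        labels = pd.Series(np.array([0, 1] * 15), index=df.index)
        table = FeatureTable(df, {c: "handcrafted" for c in df.columns})
        reduced = cohort_reduce(table, labels)
        assert reduced.df.shape[1] == 4
        assert len([c for c in reduced.df.columns if c in ("f0", "f1")]) == 1
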