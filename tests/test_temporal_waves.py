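"""Master-set construction, temporal filters, z-scoring, wave clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sewaves.io_formats import CoverageMap, GenomicInterval
from sewaves.synthetic_data import (
    CLASS_TEMPLATES,
    DYNAMIC_CLASSES,
    SAMPLES,
    SimulationConfig,
    simulate_class_profiles,
)
from sewaves.temporal_waves import (
    WaveConfig,
    build_master_set,
    classify_condition_invariant,
    classify_profiles,
    classify_stable,
    cluster_waves,
    label_waves,
    partition_summary,
    quantify_profiles,
    zscore_profile,
)


def _iv(chrom, start, end):
    return GenomicInterval(chrom, start, end)


class TestMasterSet:
    def test_overlap_merge_and_membership(self):
        master, membership = build_master_set(
            {"s1": [_iv("chr1", 0, 1000)], "s2": [_iv("chr1", 500, 1500)]}
        )
        assert [iv for _, iv in master] == [_iv("chr1", 0, 1500)]
        se_id = master[0][0]
        assert set(membership[se_id]) == {"s1", "s2"}

    def test_disjoint_sets_keep_every_interval(self):
        master, _ = build_master_set(
            {"s1": [_iv("chr1", 0, 100)], "s2": [_iv("chr1", 5000, 5100)],
             "s3": [_iv("chr2", 0, 100)]}
        )
        assert len(master) == 3

    def test_identical_interval_in_many_samples_merges_once(self):
        sets = {f"s{i}": [_iv("chr1", 10, 500)] for i in range(8)}
        master, membership = build_master_set(sets)
        assert len(master) == 1
        assert len(membership[master[0][0]]) == 8

    def test_matches_brute_force_union(self):
        rng = np.random.default_rng(4)
        sets = {}
        all_ivs = []
        for s in range(4):
            ivs = []
            for _ in range(50):
                start = int(rng.integers(0, 100_000))
                iv = _iv("chr1", start, start + int(rng.integers(100, 5000)))
                ivs.append(iv)
                all_ivs.append(iv)
            sets[f"s{s}"] = ivs
        master, _ = build_master_set(sets)
        # brute-force any-overlap union via a base-pair occupancy vector
        occ = np.zeros(200_000, dtype=bool)
        for iv in all_ivs:
            occ[iv.start : iv.end] = True
        edges = np.flatnonzero(np.diff(occ.astype(int)))
        n_blocks = (len(edges) + (1 if occ[0] else 0) + (1 if occ[-1] else 0)) // 2
        assert len(master) == n_blocks


class TestQuantify:
    def test_uniform_coverage_rpm(self):
        cov = CoverageMap.from_records([("chr1", 0, 10_000, 1.0)])
        master = [("se1", _iv("chr1", 0, 10_000))]
        df = quantify_profiles(master, {"s": cov}, {"s": 1e7})
        assert df.loc["se1", "s"] == pytest.approx(1000.0)

    def test_zero_coverage_and_missing_sample(self):
        cov = CoverageMap.from_records([("chr1", 0, 10, 1.0)])
        master = [("se1", _iv("chr2", 0, 100))]
        df = quantify_profiles(master, {"s": cov}, {"s": 1e7})
        assert df.loc["se1", "s"] == 0.0
        with pytest.raises(ValueError, match="missing"):
            quantify_profiles(master, {"s": cov}, {"other": 1e7})


class TestFilters:
    def test_stable_cv_examples(self):
        assert classify_stable([100, 110, 90, 100], 0.30)  # CV ~ 0.082
        assert classify_stable([7, 7, 7], 0.30)
        assert not classify_stable([100, 200, 300], 0.30)  # CV = 0.5
        assert classify_stable([0, 0, 0], 0.30)  # flat zero

    def test_condition_invariant_examples(self):
        assert classify_condition_invariant([100, 300, 500], [110, 290, 480], 200)
        assert not classify_condition_invariant([100, 600, 900], [100, 110, 120], 200)
        assert classify_condition_invariant([5, 6, 7], [5, 6, 7], 200)
        with pytest.raises(ValueError):
            classify_condition_invariant([1, 2], [1, 2, 3], 200)

    def test_zscore_examples_and_moments(self):
        np.testing.assert_allclose(
            zscore_profile([1, 2, 3]), [-1.2247, 0, 1.2247], atol=1e-4
        )
        np.testing.assert_array_equal(zscore_profile([5, 5, 5, 5]), np.zeros(4))
        rng = np.random.default_rng(0)
        for _ in range(20):
            z = zscore_profile(rng.normal(size=10))
            assert z.mean() == pytest.approx(0, abs=1e-12)
            assert z.std(ddof=0) == pytest.approx(1)


class TestClustering:
    def _cfg(self, **kw):
        kw.setdefault("k", 4)
        kw.setdefault("seed", 17)
        return WaveConfig(**kw)

    def test_separable_one_hot_centroids(self):
        rows = np.repeat(np.eye(4), 10, axis=0)
        labels, centroids, elbow = cluster_waves(
            pd.DataFrame(rows), self._cfg()
        )
        assert len(set(labels)) == 4
        # zero within-cluster scatter in the separable case
        assert elbow.loc[elbow["k"] == 4, "wcss"].iloc[0] == pytest.approx(0)

    def test_duplicated_rows_get_identical_labels(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=(20, 4))
        dup = np.vstack([base, base])
        labels, _, _ = cluster_waves(pd.DataFrame(dup), self._cfg(k=3))
        assert list(labels[:20]) == list(labels[20:])

    def test_reproducible_under_fixed_seed(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(100, 4)))
        a = cluster_waves(X, self._cfg(seed=5))
        b = cluster_waves(X, self._cfg(seed=5))
        assert list(a[0]) == list(b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_fewer_rows_than_k_errors(self):
        with pytest.raises(ValueError):
            cluster_waves(pd.DataFrame(np.zeros((3, 4))), self._cfg(k=4))


class TestWaveLabels:
    def test_argmax_labelling(self):
        centroids = np.array(
            [
                [1.3, -0.2, -0.5, -0.6],  # baseline-peaked -> lost
                [-0.5, 1.4, -0.4, -0.5],
                [-0.6, -0.4, 1.5, -0.5],  # day-4 peaked
                [-0.5, -0.5, -0.4, 1.4],
            ]
        )
        assert label_waves(centroids) == {
            0: "lost", 1: "wave_2d", 2: "wave_4d", 3: "wave_8d"
        }

    def test_shared_argmax_merges_labels(self):
        centroids = np.array(
            [
                [1.3, -0.2, -0.5, -0.6],
                [1.1, -0.1, -0.4, -0.6],  # second baseline-peaked centroid
                [-0.5, 1.4, -0.4, -0.5],
                [-0.6, -0.4, 1.5, -0.5],
                [-0.5, -0.5, -0.4, 1.4],
            ]
        )
        mapping = label_waves(centroids)
        assert mapping[0] == mapping[1] == "lost"
        assert len(set(mapping.values())) == 4


class TestClassifyProfiles:
    def _profiles_from_templates(self, counts):
        rows, idx = [], []
        i = 0
        for cls, n in counts.items():
            for _ in range(n):
                i += 1
                rows.append(CLASS_TEMPLATES[cls])
                idx.append(f"se_{i}")
        return pd.DataFrame(rows, index=idx, columns=list(SAMPLES))

    def test_partition_and_wave_recovery_on_templates(self):
        counts = {"stable": 10, "condition_invariant": 8, "lost": 9,
                  "wave_2d": 7, "wave_4d": 9, "wave_8d": 6}
        profiles = self._profiles_from_templates(counts)
        out = classify_profiles(profiles, WaveConfig(k=4, seed=1))
        summary = partition_summary(out)
        assert summary["n_total"] == sum(counts.values())
        assert summary["n_stable"] == counts["stable"]
        assert summary["n_invariant"] == counts["condition_invariant"]
        for wave in DYNAMIC_CLASSES:
            assert summary[f"n_{wave}"] == counts[wave]

    def test_filter_order_stable_wins_over_invariant(self):
        # flat profile is both low-CV and low-condition-difference;
        # the stable filter runs first so it is classified stable
        profiles = pd.DataFrame(
            [[400, 400, 400, 400, 400, 400]] * 6, columns=list(SAMPLES),
            index=[f"se_{i}" for i in range(6)],
        )
        out = classify_profiles(profiles, WaveConfig(k=5, seed=0))
        assert (out["class_label"] == "stable").all()

    def test_noisy_recovery_at_five_percent_dispersion(self):
        """At 5% count noise, class + wave recovery stays >= 95%."""
        cfg = SimulationConfig(dispersion=0.05)
        profiles, labels = simulate_class_profiles(
            cfg, seed=13, classes=("stable", "condition_invariant") + DYNAMIC_CLASSES
        )
        out = classify_profiles(profiles, WaveConfig(k=4, seed=13))
        predicted = np.where(
            out["class_label"] == "dynamic", out["wave_label"], out["class_label"]
        )
        accuracy = (predicted == labels.to_numpy()).mean()
        assert accuracy >= 0.95

    def test_stable_and_dynamic_filter_realism(self):
        """>= 99% of stable SEs pass and dynamic SEs fail the CV filter
        at 5% count noise."""
        cfg = SimulationConfig(dispersion=0.05)
        profiles, labels = simulate_class_profiles(
            cfg, seed=29, classes=("stable",) + DYNAMIC_CLASSES
        )
        wcfg = WaveConfig()
        atra = profiles[list(wcfg.zscore_samples)].to_numpy()
        passed = np.array([classify_stable(v, wcfg.stable_cv_max) for v in atra])
        stable_mask = (labels == "stable").to_numpy()
        assert passed[stable_mask].mean() >= 0.99
        assert (~passed[~stable_mask]).mean() >= 0.99

    def test_partition_bookkeeping_when_removing_one_dynamic(self):
        counts = {"stable": 6, "condition_invariant": 6, "lost": 8,
                  "wave_2d": 8, "wave_4d": 8, "wave_8d": 8}
        profiles = self._profiles_from_templates(counts)
        full = partition_summary(classify_profiles(profiles, WaveConfig(k=4, seed=2)))
        lost_id = profiles.index[counts["stable"] + counts["condition_invariant"]]
        reduced = partition_summary(
            classify_profiles(profiles.drop(index=lost_id), WaveConfig(k=4, seed=2))
        )
        assert reduced["n_total"] == full["n_total"] - 1
        assert reduced["n_dynamic"] == full["n_dynamic"] - 1
        assert reduced["n_lost"] == full["n_lost"] - 1
        for key in ("n_stable", "n_invariant", "n_wave_2d", "n_wave_4d", "n_wave_8d"):
            assert reduced[key] == full[key]

    def test_row_permutation_invariance_up_to_relabelling(self):
        cfg = SimulationConfig(dispersion=0.05)
        profiles, _ = simulate_class_profiles(cfg, seed=3)
        out = classify_profiles(profiles, WaveConfig(k=4, seed=3))
        perm = profiles.sample(frac=1.0, random_state=0)
        out_perm = classify_profiles(perm, WaveConfig(k=4, seed=3))
        joined = out["wave_label"].to_frame("a").join(out_perm["wave_label"].rename("b"))
        dyn = joined[(joined["a"] != "none") | (joined["b"] != "none")]
        assert adjusted_rand_score(dyn["a"], dyn["b"]) == pytest.approx(1.0)
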