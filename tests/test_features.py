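"""Metagene profiles, MSG selection, relative distance, permutation tests."""

import numpy as np
import pandas as pd
import pytest

from jsdscan.features import (
    count_ctypes_by_feature,
    csd_lsd_test,
    metagene_profile,
    msg_fraction_track,
    msg_te_proximity_test,
    relative_distance,
    select_msgs,
)
from jsdscan.simulate import simulate_annotations, simulate_binned_signal


def feature_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "id",
                                       "category"])


def sites_frame(pos, jsd, chrom="c"):
    return pd.DataFrame({"chrom": chrom, "pos": np.asarray(pos, dtype=np.int64),
                         "met": 0.5, "jsd": np.asarray(jsd, dtype=float)})


class TestMetageneProfile:
    def test_constant_signal(self):
        sites = sites_frame(np.arange(0, 20000, 13), 0.4)
        feats = feature_frame([("c", 5000, 8000, "+", "g1", "gene"),
                               ("c", 11000, 15000, "-", "g2", "gene")])
        prof = metagene_profile(sites, feats)
        assert np.allclose(prof.values[~np.isnan(prof.values)], 0.4)
        assert len(prof.upstream) == 40 and len(prof.body) == 60

    def test_strand_mirror_symmetry(self):
        rng = np.random.default_rng(1)
        pos = np.arange(0, 10000, 7)
        sites = sites_frame(pos, rng.random(len(pos)))
        plus = feature_frame([("c", 4000, 6000, "+", "g", "gene")])
        minus = feature_frame([("c", 4000, 6000, "-", "g", "gene")])
        p1 = metagene_profile(sites, plus).values
        p2 = metagene_profile(sites, minus).values
        np.testing.assert_allclose(p1, p2[::-1], atol=1e-12)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pos = np.sort(rng.choice(50000, 2000, replace=False))
        sites = sites_frame(pos, rng.random(len(pos)))
        feats = feature_frame([
            ("c", int(s), int(s + rng.integers(500, 4000)), "+", f"g{i}", "gene")
            for i, s in enumerate(rng.choice(40000, 10, replace=False) + 2500)
        ])
        prof = metagene_profile(sites, feats, flank_width=2000, flank_bin=50,
                                body_bins=60)
        # brute force: accumulate every (feature, site) pair independently
        total = 40 + 60 + 40
        sums = np.zeros(total)
        counts = np.zeros(total)
        p = sites["pos"].to_numpy()
        v = sites["jsd"].to_numpy()
        for _, f in feats.iterrows():
            for pi, vi in zip(p, v):
                if f["start"] - 2000 <= pi < f["start"]:
                    b = (pi - (f["start"] - 2000)) // 50
                elif f["start"] <= pi < f["end"]:
                    rel = (pi - f["start"]) / (f["end"] - f["start"])
                    b = 40 + min(int(rel * 60), 59)
                elif f["end"] <= pi < f["end"] + 2000:
                    b = 100 + (pi - f["end"]) // 50
                else:
                    continue
                sums[b] += vi
                counts[b] += 1
        expected = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        np.testing.assert_allclose(prof.values, expected, atol=1e-12)

    def test_feature_order_and_duplication_invariance(self):
        rng = np.random.default_rng(3)
        pos = np.arange(0, 30000, 11)
        sites = sites_frame(pos, rng.random(len(pos)))
        feats = feature_frame([("c", 5000, 7000, "+", "a", "g"),
                               ("c", 15000, 20000, "-", "b", "g")])
        p1 = metagene_profile(sites, feats).values
        p2 = metagene_profile(sites, feats.iloc[::-1]).values
        np.testing.assert_allclose(p1, p2, atol=1e-12)
        # duplicating the site stream leaves every mean unchanged
        doubled = pd.concat([sites, sites], ignore_index=True).sort_values("pos")
        p3 = metagene_profile(doubled, feats).values
        np.testing.assert_allclose(p1, p3, atol=1e-12)

    def test_short_feature_warns(self):
        sites = sites_frame([5, 10], [0.1, 0.2])
        feats = feature_frame([("c", 0, 30, "+", "tiny", "gene")])
        with pytest.warns(UserWarning, match="shorter"):
            metagene_profile(sites, feats, flank_width=100, flank_bin=50)

    def test_empty_features_rejected(self):
        with pytest.raises(ValueError):
            metagene_profile(sites_frame([1], [0.1]), feature_frame([]))


class TestMsgSelection:
    def _counts(self, msc, total):
        other = total - msc
        return pd.DataFrame({
            "LMC": other, "HMC": 0, "MMC": 0, "MSC": msc, "total": total,
        }, index=[f"g{i}" for i in range(len(msc))])

    def test_five_nonzero_of_hundred(self):
        msc = np.zeros(100, dtype=int)
        msc[[3, 10, 44, 70, 99]] = 5
        counts = self._counts(msc, np.full(100, 20))
        assert select_msgs(counts, min_sites=5) == {"g3", "g10", "g44", "g70", "g99"}

    def test_all_equal_proportions_empty(self):
        counts = self._counts(np.full(50, 2), np.full(50, 10))
        with pytest.warns(UserWarning):
            assert select_msgs(counts) == set()

    def test_min_sites_excludes_sparse_genes(self):
        counts = self._counts(np.array([5, 5, 0, 0]), np.array([10, 2, 10, 10]))
        got = select_msgs(counts, min_sites=5)
        assert got == {"g0"}  # g1 is sparse, filtered before ranking

    def test_size_bounded_by_quantile_plus_ties(self):
        rng = np.random.default_rng(0)
        msc = rng.integers(0, 10, 200)
        counts = self._counts(msc, np.full(200, 10))
        got = select_msgs(counts, min_sites=5)
        prop = msc / 10
        ties = (prop == np.quantile(prop, 0.95)).sum()
        assert len(got) <= int(np.ceil(0.05 * 200)) + ties

    def test_count_ctypes_by_feature(self):
        sites = pd.DataFrame({"chrom": "c", "pos": [5, 15, 25, 35],
                              "ctype": ["MSC", "LMC", "MSC", "HMC"]})
        feats = feature_frame([("c", 0, 20, "+", "a", "g"),
                               ("c", 20, 40, "+", "b", "g")])
        counts = count_ctypes_by_feature(sites, feats)
        assert counts.loc["a", "MSC"] == 1 and counts.loc["a", "total"] == 2
        assert counts.loc["b", "HMC"] == 1 and counts.loc["b", "total"] == 2


class TestMsgTrack:
    def test_fraction(self):
        genes = feature_frame([("c", i * 10, i * 10 + 5, "+", f"g{i}", "g")
                               for i in range(10)])
        track = msg_fraction_track({"g0", "g5"}, genes, bin_width=100)
        assert track["value"].iloc[0] == pytest.approx(0.2)
        assert track["n_genes"].iloc[0] == 10

    def test_no_msgs_zero_track(self):
        genes = feature_frame([("c", 0, 5, "+", "g0", "g")])
        track = msg_fraction_track(set(), genes, bin_width=10)
        assert (track["value"].dropna() == 0).all()

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        starts = np.sort(rng.choice(10000, 50, replace=False))
        genes = feature_frame([("c", int(s), int(s) + 10, "+", f"g{i}", "g")
                               for i, s in enumerate(starts)])
        msgs = set(rng.choice(genes["id"], 8, replace=False))
        track = msg_fraction_track(msgs, genes, bin_width=1000)
        for _, row in track.iterrows():
            inside = genes[(genes["start"] >= row["start"])
                           & (genes["start"] < row["end"])]
            if len(inside):
                assert row["value"] == pytest.approx(
                    inside["id"].isin(msgs).mean())
            else:
                assert np.isnan(row["value"])

    def test_unknown_id_raises(self):
        genes = feature_frame([("c", 0, 5, "+", "g0", "g")])
        with pytest.raises(KeyError):
            msg_fraction_track({"nope"}, genes, bin_width=10)


class TestRelativeDistance:
    def _refs(self, mids, chrom="c", half=5):
        return feature_frame([(chrom, m - half, m + half, "+", f"r{i}", "ref")
                              for i, m in enumerate(mids)])

    def test_coincident_midpoints_all_zero(self):
        refs = self._refs([100, 200, 300])
        res = relative_distance(refs, refs)
        assert np.all(res.distances == 0)
        assert res.frequencies[0] == pytest.approx(1.0)

    def test_midway_queries_all_half(self):
        refs = self._refs(np.arange(100, 1100, 100))
        queries = self._refs(np.arange(150, 1050, 100))
        res = relative_distance(queries, refs)
        assert np.all(res.distances == 0.5)
        assert res.frequencies[-1] == pytest.approx(1.0)

    def test_frequencies_sum_to_one(self):
        rng = np.random.default_rng(1)
        refs = self._refs(np.sort(rng.choice(100000, 50, replace=False)))
        queries = self._refs(np.sort(rng.choice(100000, 200, replace=False)))
        res = relative_distance(queries, refs)
        assert res.frequencies.sum() == pytest.approx(1.0)
        assert res.n_used + res.n_skipped == 200

    def test_sparse_chromosome_skipped(self):
        refs = self._refs([100], chrom="lonely")
        queries = self._refs([150], chrom="lonely")
        res = relative_distance(queries, refs)
        assert res.n_used == 0 and res.n_skipped == 1


class TestCsdLsdTest:
    def test_constant_signal_null(self):
        signs = np.array([-1, -1, 1, 1] * 10)
        res = csd_lsd_test(np.full(40, 0.3), signs, n_permutations=200, rng=0)
        assert res.observed == 0.0
        assert res.p_raw > 0.9

    def test_planted_shift_detected(self):
        ann = simulate_annotations(10_000_000, n_genes=100, seed=1)
        assert len(ann.segmentation) == 200
        values = simulate_binned_signal(ann.segmentation, shift=0.05,
                                        noise_sd=0.05, seed=2)
        res = csd_lsd_test(values, ann.segmentation["sign"].to_numpy(),
                           n_permutations=1000, rng=3)
        assert res.p_raw < 0.01
        assert res.observed > 0

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(5)
        values = rng.random(60)
        signs = np.resize([-1, 1], 60)
        r1 = csd_lsd_test(values, signs, n_permutations=300, rng=42)
        r2 = csd_lsd_test(values, signs, n_permutations=300, rng=42)
        assert r1.p_raw == r2.p_raw
        np.testing.assert_array_equal(r1.null_values, r2.null_values)

    def test_smoothed_p_bounds(self):
        rng = np.random.default_rng(6)
        res = csd_lsd_test(rng.random(40), np.resize([-1, 1], 40),
                           n_permutations=99, rng=0)
        assert 0 < res.p_smoothed <= 1
        assert res.p_smoothed >= res.p_raw
        assert 0 <= res.p_raw <= 1

    def test_single_sign_rejected(self):
        with pytest.raises(ValueError, match="both"):
            csd_lsd_test(np.ones(10), np.ones(10))

    def test_nan_bins_dropped(self):
        values = np.array([0.1, np.nan, 0.2, 0.3])
        signs = np.array([-1, -1, 1, 1])
        res = csd_lsd_test(values, signs, n_permutations=50, rng=0)
        assert res.meta["n_csd_bins"] == 1


class TestMsgTeProximity:
    def test_everyone_near_te(self):
        genes = feature_frame([("c", i * 10000, i * 10000 + 1000, "+", f"g{i}", "g")
                               for i in range(20)])
        tes = feature_frame([("c", i * 10000 + 1500, i * 10000 + 1900, "+",
                              f"t{i}", "TE") for i in range(20)])
        res = msg_te_proximity_test({"g0", "g1"}, genes, tes, n_draws=200, rng=0)
        assert res.observed == 1.0
        assert res.p_raw == 1.0

    def test_no_tes_degenerate(self):
        genes = feature_frame([("c", 0, 100, "+", "g0", "g"),
                               ("c", 10000, 10100, "+", "g1", "g")])
        res = msg_te_proximity_test({"g0"}, genes, feature_frame([]),
                                    n_draws=100, rng=0)
        assert res.observed == 0.0
        assert res.p_raw == 1.0

    def test_planted_enrichment(self):
        ann = simulate_annotations(5_000_000, n_genes=500, n_tes=200,
                                   msg_fraction=0.1, near_prob_msg=0.8,
                                   near_prob_bg=0.2, seed=4)
        res = msg_te_proximity_test(ann.msgs, ann.genes, ann.tes,
                                    n_draws=10000, rng=5)
        assert res.p_raw < 0.001
        assert res.observed > res.meta["background_near_fraction"]

    def test_msg_not_in_background_rejected(self):
        genes = feature_frame([("c", 0, 100, "+", "g0", "g")])
        with pytest.raises(ValueError, match="background"):
            msg_te_proximity_test({"zzz"}, genes, feature_frame([]))

    def test_reproducible_given_seed(self):
        genes = feature_frame([("c", i * 5000, i * 5000 + 500, "+", f"g{i}", "g")
                               for i in range(30)])
        tes = feature_frame([("c", 1200, 1400, "+", "t0", "TE"),
                             ("c", 51200, 51400, "+", "t1", "TE")])
        r1 = msg_te_proximity_test({"g0", "g5"}, genes, tes, n_draws=500, rng=9)
        r2 = msg_te_proximity_test({"g0", "g5"}, genes, tes, n_draws=500, rng=9)
        assert r1.p_raw == r2.p_raw
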