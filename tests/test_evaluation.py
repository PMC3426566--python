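import numpy as np
import pytest

from gtenet.evaluation import (
    ROCResult,
    hub_analysis,
    motif_audit,
    performance,
    ppc,
    roc,
    state_range_analysis,
    state_ranges,
    topology_report,
)
from gtenet.fluorescence import FluorescenceRecording
from gtenet.inference import EstimatorSpec, ScoreMatrix, rank_and_threshold
from gtenet.topology import DirectedNetwork, full_clustering, randomize_full


def net_from(A, positions=None):
    return DirectedNetwork(np.asarray(A, dtype=bool), positions, {})


def random_scores_net(N, p, seed):
    rng = np.random.default_rng(seed)
    A = rng.random((N, N)) < p
    np.fill_diagonal(A, False)
    vals = rng.random((N, N))
    np.fill_diagonal(vals, np.nan)
    return ScoreMatrix(vals, EstimatorSpec(), 0), net_from(A)


class TestROC:
    def test_truth_indicator_scores_are_perfect(self):
        rng = np.random.default_rng(0)
        A = rng.random((20, 20)) < 0.2
        np.fill_diagonal(A, False)
        sm = ScoreMatrix(A.astype(float), EstimatorSpec(), 0)
        r = roc(sm, net_from(A))
        assert r.tp_at_10fp == pytest.approx(1.0)
        assert r.fpr[0] == 0 and r.tpr[-1] == 1

    def test_monotone_curve(self):
        sm, net = random_scores_net(40, 0.15, 3)
        r = roc(sm, net)
        assert np.all(np.diff(r.fpr) >= 0)
        assert np.all(np.diff(r.tpr) >= 0)

    def test_random_scores_near_diagonal(self):
        vals = [roc(*random_scores_net(40, 0.15, s)).tp_at_10fp for s in range(40)]
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 0.10) < 3 * se + 0.01

    def test_invariant_under_increasing_transform(self):
        sm, net = random_scores_net(30, 0.2, 9)
        r1 = roc(sm, net)
        sm2 = ScoreMatrix(np.exp(3 * sm.values), sm.spec, 0)
        r2 = roc(sm2, net)
        assert np.allclose(r1.fpr, r2.fpr)
        assert np.allclose(r1.tpr, r2.tpr)


class TestPerformance:
    def test_perfect_and_diagonal(self):
        perfect = ROCResult(np.array([0.0, 0.0, 1.0]), np.array([0.0, 1.0, 1.0]), 1.0)
        assert performance(perfect) == 1.0
        diag = ROCResult(np.linspace(0, 1, 11), np.linspace(0, 1, 11), 0.1)
        assert performance(diag) == pytest.approx(0.10)

    def test_hand_built_interpolation(self):
        r = ROCResult(np.array([0.0, 0.05, 0.2, 1.0]),
                      np.array([0.0, 0.4, 0.7, 1.0]), np.nan)
        # linear interpolation between (0.05, 0.4) and (0.2, 0.7)
        assert performance(r, 0.10) == pytest.approx(0.4 + 0.3 * (0.05 / 0.15))


class TestPPC:
    def test_all_true_gives_unity(self):
        A = np.zeros((5, 5), dtype=bool)
        A[0, 1] = A[1, 2] = True
        vals = np.where(A, 2.0, 1.0).astype(float)
        np.fill_diagonal(vals, np.nan)
        res = ppc(ScoreMatrix(vals, EstimatorSpec(), 0), net_from(A))
        assert np.all(res.tfr[:2] == 1.0)

    def test_balanced_tp_fp_is_zero(self):
        # first two retained links: one true, one false -> TFR = 0 at TFS = 2
        A = np.zeros((4, 4), dtype=bool)
        A[0, 1] = True
        vals = np.full((4, 4), 0.1)
        vals[0, 1] = 0.9
        vals[1, 0] = 0.8
        np.fill_diagonal(vals, np.nan)
        res = ppc(ScoreMatrix(vals, EstimatorSpec(), 0), net_from(A))
        assert res.tfr[1] == 0.0

    def test_identity_tfr_times_tfs(self):
        sm, net = random_scores_net(25, 0.2, 4)
        res = ppc(sm, net)
        assert np.allclose(res.tfr * res.tfs, res.n_tp - res.n_fp)
        assert np.all(np.diff(res.tfs) == 1)

    def test_hand_counted_small_case(self):
        A = np.zeros((4, 4), dtype=bool)
        A[0, 1] = A[0, 2] = A[2, 3] = True
        order_scores = {(0, 1): 12, (2, 3): 11, (1, 0): 10, (0, 2): 9, (3, 1): 8}
        vals = np.zeros((4, 4))
        for (i, j), s in order_scores.items():
            vals[i, j] = s
        np.fill_diagonal(vals, np.nan)
        res = ppc(ScoreMatrix(vals, EstimatorSpec(), 0), net_from(A))
        # cumulative TP: 1,2,2,3,3 ; FP: 0,0,1,1,2
        assert np.allclose(res.n_tp[:5], [1, 2, 2, 3, 3])
        assert np.allclose(res.n_fp[:5], [0, 0, 1, 1, 2])


class TestTopologyReport:
    def test_identical_networks_identical_stats(self, small_net):
        frame = topology_report(small_net, [small_net], labels=["a", "b"])
        s = frame.attrs["summary"]
        assert s["mean_clustering"].iloc[0] == s["mean_clustering"].iloc[1]

    def test_er_vs_full_randomization_indistinguishable(self):
        rng = np.random.default_rng(2)
        A = rng.random((60, 60)) < 0.15
        np.fill_diagonal(A, False)
        er = net_from(A, rng.random((60, 2)))
        refs = [randomize_full(er, seed=s) for s in range(60)]
        frame = topology_report(er, refs)
        pct = frame.attrs["summary"].attrs["cc_percentile"]
        assert 1.0 < pct < 99.0

    def test_clustered_network_stands_out(self, small_net):
        refs = [randomize_full(small_net, seed=s) for s in range(60)]
        frame = topology_report(small_net, refs)
        assert frame.attrs["summary"].attrs["cc_percentile"] > 99.0


class TestMotifAudit:
    def test_perfect_reconstruction(self, small_net):
        audit = motif_audit(small_net, small_net)
        assert audit["bidir_recovered"] == 1.0
        assert audit["unidir_recovered"] == 1.0
        assert audit["unidir_reverse_spurious"] == 0.0
        assert audit["shared_source_spurious"] == 0.0
        assert audit["chain_shortcut_spurious"] == 0.0

    def test_crafted_six_node_example(self):
        # truth: 0<->1 reciprocal; 2->3 unidirectional; 4->0, 4->5 shared
        # source (no 0-5 link); chain 2->3 ... and 3->4 making 2->4 a
        # potential shortcut
        A = np.zeros((6, 6), dtype=bool)
        A[0, 1] = A[1, 0] = True
        A[2, 3] = True
        A[3, 4] = True
        A[4, 0] = A[4, 5] = True
        # reconstruction: keeps 0->1 only from the pair; keeps 2->3 and
        # adds its reverse 3->2; adds spurious lateral 0->5 and shortcut 2->4
        R = np.zeros((6, 6), dtype=bool)
        R[0, 1] = True
        R[2, 3] = R[3, 2] = True
        R[0, 5] = True
        R[2, 4] = True
        audit = motif_audit(net_from(R), net_from(A))
        assert audit["n_bidir_pairs"] == 1
        assert audit["bidir_recovered"] == 0.0  # only one direction kept
        # unidirectional truth links: 2->3, 3->4, 4->0, 4->5 -> one kept
        assert audit["unidir_recovered"] == pytest.approx(0.25)
        # the kept unidirectional link 2->3 has its reverse inferred
        assert audit["unidir_reverse_spurious"] == 1.0
        # shared-source pairs without true lateral: (0,5) via source 4,
        # (1, ...)? only (0,5); the reconstruction adds 0->5
        assert audit["n_shared_source_pairs"] == 1
        assert audit["shared_source_spurious"] == 1.0
        # chains: 2->3->4 (no true 2->4): shortcut added; also 3->4->0
        # (no true 3->0): not added; 3->4->5 (no 3->5): not added;
        # 4->0->1 (no 4->1): not added; others involve existing links
        assert audit["chain_shortcut_spurious"] == pytest.approx(
            audit["n_chain_pairs"] and 1.0 / audit["n_chain_pairs"])


class TestStateRanges:
    def test_counts_partition_frames(self, bursting_recording):
        _, _, rec = bursting_recording
        res = state_range_analysis(rec, None, n_ranges=7)
        assert res["counts"].sum() == rec.n_frames - 1
        assert len(res["scores"]) == 7

    def test_equal_samples_mode(self, bursting_recording):
        _, _, rec = bursting_recording
        res = state_range_analysis(rec, None, n_ranges=4, equal_samples=True, seed=3)
        n_min = res["counts"].min()
        spec = EstimatorSpec()
        # every range scored from the same number of retained tuples
        for sm in res["scores"]:
            assert abs(sm.n_samples - n_min) <= spec.order


class TestHubAnalysis:
    def test_advanced_group_has_negative_lag(self):
        rng = np.random.default_rng(8)
        T, N, shift = 6000, 40, 3
        group = np.arange(10)
        # population-wide bursts: smooth bumps at random frames
        base = np.zeros(T)
        for t0 in rng.integers(50, T - 50, 60):
            base[t0:t0 + 10] += np.hanning(10)
        data = np.zeros((T, N))
        for i in range(N):
            sig = np.roll(base, -shift) if i in group else base
            data[:, i] = np.cumsum(sig * 0.05) * 0.001 + sig + rng.normal(0, 0.05, T)
        rec = FluorescenceRecording(data, 0.02)
        # scores whose incoming sums single out the group as hubs, with the
        # retained in-links confined to the group (so hub neighborhoods
        # stay inside it)
        vals = rng.random((N, N)) * 0.01
        vals[np.ix_(group, group)] += 1.0
        np.fill_diagonal(vals, np.nan)
        sm = ScoreMatrix(vals, EstimatorSpec(), 1000)
        n_group_links = len(group) * (len(group) - 1)
        report = hub_analysis(rec, [sm], [(0.0, 1.0)], n_hubs=10, max_lag=10,
                              top_fraction=n_group_links / (N * (N - 1)), seed=0)
        res = report.results[0]
        assert set(res.hubs) == set(group)
        assert res.fit_ok
        assert res.peak_lag == pytest.approx(-shift, abs=0.5)

    def test_whole_population_group_zero_lag(self):
        rng = np.random.default_rng(9)
        T, N = 4000, 20
        base = np.zeros(T)
        for t0 in rng.integers(50, T - 50, 40):
            base[t0:t0 + 8] += np.hanning(8)
        data = base[:, None] + rng.normal(0, 0.05, (T, N))
        rec = FluorescenceRecording(data, 0.02)
        vals = rng.random((N, N))
        np.fill_diagonal(vals, np.nan)
        sm = ScoreMatrix(vals, EstimatorSpec(), 1000)
        report = hub_analysis(rec, [sm], [(0.0, 1.0)], n_hubs=N, max_lag=8, seed=0)
        assert report.results[0].peak_lag == pytest.approx(0.0, abs=0.5)
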