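"""NMF fitting, consensus rank selection, null shuffling and projection."""

import numpy as np
import pytest
from scipy.optimize import nnls

from facedyn import decomposition as dec
from facedyn import io_preprocess as iop
from facedyn import synthetic as syn


def _exact_rank_matrix(rng, n=200, a=12, k=3):
    T = rng.random((n, k))
    S = rng.random((k, a))
    return T @ S


class TestNMFFit:
    def test_exact_rank_data_fit_tightly(self, rng):
        X = _exact_rank_matrix(rng)
        m = dec.nmf_fit(X, 3, seed=0, max_iter=5000, tol=1e-10)
        rel_rss = m.objective_trace[-1] / np.linalg.norm(X) ** 2
        assert rel_rss < 1e-4

    @pytest.mark.parametrize("seed", range(10))
    def test_objective_trace_non_increasing(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((60, 8))
        m = dec.nmf_fit(X, 3, seed=seed, max_iter=200)
        diffs = np.diff(m.objective_trace)
        assert np.all(diffs <= 1e-9 * np.maximum(m.objective_trace[:-1], 1))

    def test_factors_nonnegative(self, rng):
        m = dec.nmf_fit(rng.random((50, 6)), 2, seed=1)
        assert np.all(m.S >= 0) and np.all(m.T >= 0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            dec.nmf_fit(np.array([[1.0, -0.1]]), 1)

    def test_scale_invariance_of_reconstruction(self, rng):
        m = dec.nmf_fit(rng.random((30, 5)), 2, seed=2)
        d = np.array([2.0, 0.5])
        rescaled = dec.NMFModel(k=2, S=(1 / d)[:, None] * m.S, T=m.T * d,
                                objective_trace=m.objective_trace,
                                seed=m.seed, n_iter=m.n_iter)
        assert np.allclose(dec.reconstruct(m), dec.reconstruct(rescaled))

    def test_matches_reference_nmf_solver(self, rng):
        """Independent cross-check against sklearn's multiplicative solver."""
        from sklearn.decomposition import NMF

        X = rng.random((80, 10)) + 0.1
        ours = dec.nmf_fit(X, 3, seed=0, max_iter=3000, tol=1e-9)
        ref = NMF(n_components=3, solver="mu", init="random", random_state=0,
                  max_iter=3000, tol=1e-9).fit(X)
        rss_ref = ref.reconstruction_err_ ** 2
        assert ours.objective_trace[-1] <= rss_ref * 1.05


class TestReconstruct:
    def test_zero_temporal_weights(self, rng):
        m = dec.nmf_fit(rng.random((20, 4)), 2, seed=0)
        m.T = np.zeros_like(m.T)
        assert np.allclose(dec.reconstruct(m), 0)

    def test_exact_rank_reconstruction_vs_svd(self, rng):
        X = _exact_rank_matrix(rng, n=150, a=10, k=2)
        m = dec.nmf_fit(X, 2, seed=3, max_iter=5000, tol=1e-12)
        err = np.abs(X - dec.reconstruct(m)).max()
        assert err < 1e-3 * np.ptp(X)
        # SVD oracle: the best rank-2 error is 0 here
        sv = np.linalg.svd(X, compute_uv=False)
        assert sv[2] < 1e-10 * sv[0]

    def test_evar_in_unit_interval(self, rng):
        X = rng.random((40, 6))
        m = dec.nmf_fit(X, 2, seed=1)
        assert 0.0 <= dec.explained_variance(X, m) <= 1.0


class TestConsensus:
    def test_block_structured_data_perfectly_stable(self):
        gt = syn.make_ground_truth(3, 12, 60, seed=0, noise_sd=0.0)
        trials = syn.make_dataset(gt, 2, 1, seed=0, n_frames=60,
                                  conditions=("expression_only",))
        M = iop.stack_trials(iop.preprocess_trials(trials, n_bins=60), 60)
        sil, coph = dec.consensus_metrics(M, 3, n_runs=6, seed=1)
        assert coph == pytest.approx(1.0)
        assert sil > 0.9

    def test_noise_less_stable_than_structure(self):
        """Paired comparison of cophenetic coefficients over seeds."""
        deltas = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            gt = syn.make_ground_truth(3, 12, 40, seed=seed, noise_sd=0.0)
            trials = syn.make_dataset(gt, 2, 1, seed=seed, n_frames=40,
                                      conditions=("expression_only",))
            M = iop.stack_trials(iop.preprocess_trials(trials, n_bins=40), 40)
            _, coph_structured = dec.consensus_metrics(M, 3, n_runs=6,
                                                       seed=seed)
            noise = rng.random(M.M.shape)
            _, coph_noise = dec.consensus_metrics(noise, 3, n_runs=6,
                                                  seed=seed)
            deltas.append(coph_structured - coph_noise)
        assert np.mean(deltas) > 0.02

    def test_k1_silhouette_is_missing(self, rng):
        sil, coph = dec.consensus_metrics(rng.random((40, 6)), 1, n_runs=3)
        assert np.isnan(sil)
        assert np.isfinite(coph)


class TestBlockShuffle:
    def test_full_block_is_identity(self, rng):
        X = rng.random((30, 4))
        st = iop.StackedMatrix(X.copy(), ["a", "b", "c"], 10)
        out = dec.block_shuffle(st, 10, seed=0)
        assert np.allclose(out.M, X)

    def test_value_multiset_preserved(self, rng):
        X = rng.random((40, 3))
        st = iop.StackedMatrix(X.copy(), ["a", "b"], 20)
        out = dec.block_shuffle(st, 5, seed=1)
        for t0 in (0, 20):
            for j in range(3):
                assert np.allclose(np.sort(out.M[t0:t0 + 20, j]),
                                   np.sort(X[t0:t0 + 20, j]))

    def test_autocorrelation_drops_on_smooth_data(self):
        def lag1(M):
            acs = []
            for j in range(M.shape[1]):
                x = M[:, j] - M[:, j].mean()
                if x.std() == 0:
                    continue
                acs.append(abs(np.corrcoef(x[:-1], x[1:])[0, 1]))
            return np.mean(acs)

        drops = []
        for seed in range(20):
            gt = syn.make_ground_truth(2, 6, 50, seed=seed)
            t = syn.simulate_trial(gt, "happy", "expression_only",
                                   n_frames=50, seed=seed)
            st = iop.stack_trials([t], 50)
            shuf = dec.block_shuffle(st, 5, seed=seed)
            drops.append(lag1(st.M) - lag1(shuf.M))
        assert np.mean(drops) > 0

    def test_invalid_block_len(self, rng):
        st = iop.StackedMatrix(rng.random((10, 2)), ["a"], 10)
        with pytest.raises(ValueError):
            dec.block_shuffle(st, 0)


class TestSelectK:
    def test_recovers_planted_rank_three(self, stacked_train):
        rep = dec.select_k(stacked_train, range(2, 7), n_runs=8, n_null=3,
                           seed=0)
        assert rep.chosen_k == 3
        rss = rep.table.sort_values("k")["rss"].to_numpy()
        assert np.all(np.diff(rss) <= 1e-6 * rss[:-1])

    def test_recovers_planted_rank_two(self):
        gt = syn.make_ground_truth(2, 12, 100, seed=3)
        trials = syn.make_dataset(gt, 3, 1, seed=3,
                                  conditions=("expression_only",))
        M = iop.stack_trials(iop.preprocess_trials(trials), 100)
        rep = dec.select_k(M, range(2, 6), n_runs=8, n_null=3, seed=3)
        assert rep.chosen_k == 2

    def test_pure_noise_has_no_evar_excess(self, rng):
        X = rng.random((600, 10))
        st = iop.StackedMatrix(X, [f"t{i}" for i in range(6)], 100)
        rep = dec.select_k(st, range(2, 5), n_runs=4, n_null=4, seed=0)
        null_evar = rep.null_table.groupby("k")["evar"].mean()
        excess = rep.table.set_index("k")["evar"] - null_evar
        assert np.all(np.abs(excess.to_numpy()) < 0.05)


class TestProject:
    def test_projection_rss_not_worse_than_joint_fit(self, stacked_train):
        m = dec.nmf_fit(stacked_train, 3, seed=0)
        W = dec.project(m, stacked_train)
        rss_proj = np.linalg.norm(stacked_train.M - W @ m.S) ** 2
        assert rss_proj <= m.objective_trace[-1] + 1e-6

    def test_rowwise_nnls_optimality(self, rng):
        """Each projected row matches an independent NNLS solve."""
        m = dec.nmf_fit(rng.random((30, 8)), 3, seed=1)
        X_new = rng.random((5, 8))
        W = dec.project(m, X_new)
        for i in range(5):
            w_ref, _ = nnls(m.S.T, X_new[i])
            assert np.allclose(W[i], w_ref, atol=1e-10)

    def test_zero_row_gets_zero_weights(self, rng):
        m = dec.nmf_fit(rng.random((30, 8)), 3, seed=1)
        W = dec.project(m, np.zeros((2, 8)))
        assert np.allclose(W, 0)

    def test_scaled_basis_row_concentrates_weight(self):
        S = np.array([[1.0, 0, 0, 0.05], [0, 1.0, 0.05, 0],
                      [0.05, 0, 1.0, 0]])
        m = dec.NMFModel(k=3, S=S, T=np.zeros((1, 3)),
                         objective_trace=np.zeros(1), seed=0, n_iter=0)
        W = dec.project(m, 4.0 * S[1][None, :])
        assert W[0, 1] == pytest.approx(4.0, rel=0.05)
        assert W[0, [0, 2]].max() < 0.2

    def test_channel_mismatch_rejected(self, rng):
        m = dec.nmf_fit(rng.random((10, 6)), 2, seed=0)
        with pytest.raises(ValueError, match="channel"):
            dec.project(m, rng.random((3, 5)))


class TestTrajectories:
    def test_single_trial_identity(self, rng):
        X = rng.random((10, 4)) + 0.1
        st = iop.stack_trials(
            [iop.AUTrial("t0", "s", "angry", "expression_only", 1, X)], 10)
        m = dec.nmf_fit(st, 2, seed=0)
        per_trial, _ = dec.trajectories(m.T, st)
        assert np.allclose(per_trial["t0"], m.T)

    def test_incomplete_index_rejected(self, rng, stacked_train):
        with pytest.raises(IndexError):
            dec.trajectories(rng.random((7, 3)), stacked_train)

    def test_component_loadings_recovered_noise_free(self):
        """After greedy matching, fitted S correlates >= 0.9 with truth."""
        gt = syn.make_ground_truth(3, 18, 100, seed=6, noise_sd=0.0)
        trials = syn.make_dataset(gt, 3, 1, seed=6,
                                  conditions=("expression_only",))
        M = iop.stack_trials(iop.preprocess_trials(trials), 100)
        m = dec.nmf_fit(M, 3, seed=0, max_iter=4000, tol=1e-9)
        corr = np.corrcoef(np.vstack([gt.S_true, m.S]))[:3, 3:]
        taken, mins = set(), []
        for i in np.argsort(-corr.max(axis=1)):
            j = int(np.argmax([corr[i, j] if j not in taken else -2
                               for j in range(3)]))
            taken.add(j)
            mins.append(corr[i, j])
        assert min(mins) >= 0.9

    def test_unimodal_base_recovered_unimodal(self):
        from facedyn.io_preprocess import smooth_moving_average

        gt = syn.make_ground_truth(1, 8, 100, seed=5, noise_sd=0.0)
        trials = syn.make_dataset(gt, 2, 1, seed=5,
                                  conditions=("expression_only",))
        M = iop.stack_trials(iop.preprocess_trials(trials), 100)
        m = dec.nmf_fit(M, 1, seed=0, max_iter=4000)
        per_trial, _ = dec.trajectories(m.T, M)
        traj = next(iter(per_trial.values()))
        sm = smooth_moving_average(traj[:, 0], 5)
        interior_max = np.sum(np.diff(np.sign(np.diff(sm))) < 0)
        assert interior_max == 1
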