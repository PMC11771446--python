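"""Model: closed-form loss pieces, gradients, training contracts."""

import copy

import numpy as np
import pandas as pd
import pytest
import scipy.stats

import termvae as tv
from termvae.model import (
    _batch_grads,
    _normalize_log1p,
    _one_hot,
    build_mask,
    group_lasso_penalty,
    kl_divergence,
    l1_penalty,
    nb_log_likelihood,
)


class TestKlDivergence:
    def test_prior_equals_posterior_is_zero(self):
        assert kl_divergence(np.zeros(5), np.zeros(5)) == 0.0

    def test_unit_mean_closed_form(self):
        assert kl_divergence(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_matches_monte_carlo_estimate(self):
        """KL equals E_q[log q - log p] estimated by sampling (1% at 1e6)."""
        rng = np.random.default_rng(0)
        mu = rng.normal(0, 1, size=3)
        logvar = rng.normal(0, 0.5, size=3)
        sd = np.exp(0.5 * logvar)
        z = mu + sd * rng.standard_normal((1_000_000, 3))
        log_q = scipy.stats.norm.logpdf(z, mu, sd).sum(axis=1)
        log_p = scipy.stats.norm.logpdf(z).sum(axis=1)
        mc = (log_q - log_p).mean()
        assert kl_divergence(mu, logvar) == pytest.approx(mc, rel=0.01)


class TestNbLogLikelihood:
    def test_zero_count_unit_mean_unit_theta(self):
        assert nb_log_likelihood(np.array([0]), 1.0, 1.0) == pytest.approx(np.log(0.5))

    def test_poisson_limit(self):
        x = np.arange(6)
        mean = np.full(6, 2.3)
        nb = np.array(
            [nb_log_likelihood(np.array([xi]), 2.3, 1e6) for xi in x]
        )
        pois = scipy.stats.poisson.logpmf(x, mean)
        assert np.abs(nb - pois).max() < 1e-3

    def test_matches_scipy_per_gene_sum(self):
        rng = np.random.default_rng(1)
        x = rng.poisson(3, size=40)
        mean = rng.uniform(0.5, 6.0, size=40)
        theta = rng.uniform(0.5, 4.0, size=40)
        expected = scipy.stats.nbinom.logpmf(
            x, theta, theta / (theta + mean)
        ).sum()
        assert nb_log_likelihood(x, mean, theta) == pytest.approx(expected)

    def test_non_integer_counts_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            nb_log_likelihood(np.array([0.5]), 1.0, 1.0)


class TestPenalties:
    def test_group_lasso_closed_form(self):
        W = np.array([[3.0], [4.0]])
        assert group_lasso_penalty(W, np.array([2])) == pytest.approx(np.sqrt(2) * 5)

    def test_group_lasso_zero_and_additive(self):
        assert group_lasso_penalty(np.zeros((4, 3))) == 0.0
        W = np.array([[3.0, 1.0], [4.0, 0.0]])
        dims = np.array([2, 1])
        total = group_lasso_penalty(W, dims)
        parts = group_lasso_penalty(W[:, :1], dims[:1]) + group_lasso_penalty(
            W[:, 1:], dims[1:]
        )
        assert total == pytest.approx(parts)

    def test_l1_value_and_homogeneity(self):
        W = np.array([[0.5], [-0.25]])
        assert l1_penalty(W) == pytest.approx(0.75)
        assert l1_penalty(3.0 * W) == pytest.approx(3.0 * 0.75)
        assert l1_penalty(np.zeros((2, 2))) == 0.0


class TestGradients:
    def test_backward_matches_finite_differences(self):
        """Analytic gradients of the differentiable objective (NB
        reconstruction + weighted KL) agree with central differences."""
        rng = np.random.default_rng(0)
        n, G, K, H, T = 5, 7, 2, 6, 3
        cfg = tv.ModelConfig(
            n_hidden=H, n_encoder_layers=2, alpha_group=0.0, alpha_l1=0.0,
            use_attention=True, seed=0,
        )
        mask = (rng.random((G, T)) < 0.5).astype(float)
        mask[0, :] = 1  # avoid empty columns
        x = rng.poisson(2.0, size=(n, G)).astype(float)
        cond = rng.integers(0, K, size=n)
        xin = np.concatenate([_normalize_log1p(x, cfg.target_sum), _one_hot(cond, K)], axis=1)
        lib = np.maximum(x.sum(axis=1), 1.0)
        params = {
            "enc_W_0": rng.normal(0, 0.3, (G + K, H)),
            "enc_b_0": rng.normal(0, 0.1, H),
            "enc_W_1": rng.normal(0, 0.3, (H, H)),
            "enc_b_1": rng.normal(0, 0.1, H),
            "W_mu": rng.normal(0, 0.3, (H, T)),
            "b_mu": rng.normal(0, 0.1, T),
            "W_lv": rng.normal(0, 0.1, (H, T)),
            "b_lv": rng.normal(0, 0.1, T),
            "W_gate": rng.normal(0, 0.3, (H, T)),
            "b_gate": rng.normal(0, 0.1, T),
            "W_dec": rng.normal(0, 0.3, (G, T)) * mask,
            "W_soft": rng.normal(0, 0.1, (G, T)) * (1 - mask),
            "b_gene": rng.normal(0, 0.2, G),
            "B_cond": rng.normal(0, 0.2, (K, G)),
            "log_theta": rng.normal(0, 0.2, G),
        }
        eps_noise = rng.standard_normal((n, T))
        dims = mask.sum(axis=0)
        kl_w = 0.01
        cond_oh = _one_hot(cond, K)

        _, grads = _batch_grads(
            params, cfg, mask, x, xin, cond_oh, lib, eps_noise, kl_w, dims
        )

        def objective(p):
            tot, _ = _batch_grads(
                p, cfg, mask, x, xin, cond_oh, lib, eps_noise, kl_w, dims
            )
            return tot

        h = 1e-6
        rng_probe = np.random.default_rng(99)
        for name in ["enc_W_0", "W_mu", "W_lv", "W_gate", "W_dec", "W_soft",
                     "b_gene", "B_cond", "log_theta", "enc_b_1"]:
            if name == "W_dec":  # gradient is projected onto the mask support
                allowed = np.flatnonzero(mask)
            elif name == "W_soft":
                allowed = np.flatnonzero(1 - mask)
            else:
                allowed = np.arange(params[name].size)
            flat_idx = allowed[rng_probe.integers(0, len(allowed), size=4)]
            for fi in flat_idx:
                idx = np.unravel_index(fi, params[name].shape)
                p_plus = {k: v.copy() for k, v in params.items()}
                p_minus = {k: v.copy() for k, v in params.items()}
                p_plus[name][idx] += h
                p_minus[name][idx] -= h
                fd = (objective(p_plus) - objective(p_minus)) / (2 * h)
                assert grads[name][idx] == pytest.approx(fd, rel=2e-3, abs=1e-6), name


class TestEncodeDecode:
    def test_encode_shapes_and_determinism(self, tiny_state, tiny_problem):
        _, dataset, _ = tiny_problem
        x = dataset.dense()[:3]
        conds = list(dataset.conditions[:3])
        mu1, lv1 = tv.encode(tiny_state, x, conds)
        mu2, lv2 = tv.encode(tiny_state, x, conds)
        assert mu1.shape == (3, tiny_state.latent_dim)
        assert np.array_equal(mu1, mu2) and np.array_equal(lv1, lv2)

    def test_identical_cells_identical_posteriors(self, tiny_state, tiny_problem):
        _, dataset, _ = tiny_problem
        x = np.vstack([dataset.dense()[0], dataset.dense()[0]])
        mu, lv = tv.encode(tiny_state, x, [dataset.conditions.iloc[0]] * 2)
        assert np.array_equal(mu[0], mu[1]) and np.array_equal(lv[0], lv[1])

    def test_unknown_condition_rejected(self, tiny_state, tiny_problem):
        _, dataset, _ = tiny_problem
        with pytest.raises(KeyError, match="unknown condition"):
            tv.encode(tiny_state, dataset.dense()[:1], ["mars"])

    def test_gate_is_half_with_zero_parameters(self, tiny_state):
        state = copy.deepcopy(tiny_state)
        state.params["W_gate"][:] = 0.0
        state.params["b_gate"][:] = 0.0
        g = tv.attention_gate(state, np.random.default_rng(0).normal(size=(4, state.config.n_hidden)))
        assert np.allclose(g, 0.5)

    def test_gate_bounded_in_unit_interval(self, tiny_state):
        h = np.random.default_rng(1).normal(0, 5, size=(20, tiny_state.config.n_hidden))
        g = tv.attention_gate(tiny_state, h)
        assert ((g > 0) & (g < 1)).all()

    def test_decode_mask_restricts_response(self, tiny_state):
        T = tiny_state.latent_dim
        z0, z1 = np.zeros(T), np.zeros(T)
        z1[0] = 1.5
        state = copy.deepcopy(tiny_state)
        state.params["W_soft"][:] = 0.0
        cond = state.condition_labels[0]
        base = tv.decode(state, z0, cond, 100.0)
        bumped = tv.decode(state, z1, cond, 100.0)
        changed = ~np.isclose(base, bumped)
        assert changed.any()
        assert not changed[state.mask[:, 0] == 0].any()

    def test_decode_zero_latent_gives_offset_baseline(self, tiny_state):
        cond = tiny_state.condition_labels[0]
        mean = tv.decode(tiny_state, np.zeros(tiny_state.latent_dim), cond, 1.0)
        expected = np.exp(
            np.clip(
                tiny_state.params["b_gene"] + tiny_state.params["B_cond"][0],
                -30.0, 15.0,
            )
        )
        assert np.allclose(mean, expected)

    def test_decode_linear_in_library(self, tiny_state):
        rng = np.random.default_rng(2)
        z = rng.normal(0, 0.5, tiny_state.latent_dim)
        cond = tiny_state.condition_labels[0]
        assert np.allclose(
            tv.decode(tiny_state, z, cond, 200.0),
            2.0 * tv.decode(tiny_state, z, cond, 100.0),
        )


class TestLoss:
    def test_zero_weights_reduce_to_reconstruction(self, tiny_problem):
        termset, dataset, _ = tiny_problem
        cfg = tv.ModelConfig(
            n_hidden=16, n_encoder_layers=1, alpha_kl=0.0, alpha_group=0.0,
            alpha_l1=0.0, max_epochs=2, batch_size=32, seed=0,
        )
        state = tv.train(dataset, termset, cfg)
        total, comp = tv.loss(
            dataset.dense()[:20], list(dataset.conditions[:20]), state
        )
        assert total == pytest.approx(comp["reconstruction"])

    def test_kl_contribution_linear_in_weight(self, tiny_state, tiny_problem):
        _, dataset, _ = tiny_problem
        x = dataset.dense()[:20]
        conds = list(dataset.conditions[:20])
        _, c1 = tv.loss(x, conds, tiny_state, kl_weight=0.01)
        _, c2 = tv.loss(x, conds, tiny_state, kl_weight=0.02)
        assert c2["kl_weighted"] == pytest.approx(2 * c1["kl_weighted"])
        assert c1["kl"] == pytest.approx(c2["kl"])

    def test_components_finite(self, tiny_state, tiny_problem):
        _, dataset, _ = tiny_problem
        total, comp = tv.loss(
            dataset.dense()[:10], list(dataset.conditions[:10]), tiny_state
        )
        assert np.isfinite(total)
        assert all(np.isfinite(v) for v in comp.values())
        assert comp["kl"] >= 0 and comp["group_lasso"] >= 0 and comp["l1"] >= 0


class TestTraining:
    def test_seed_determinism_identical_parameters(self, tiny_problem):
        termset, dataset, _ = tiny_problem
        cfg = tv.ModelConfig(
            n_hidden=16, n_encoder_layers=2, max_epochs=8, patience=8,
            batch_size=32, seed=123,
        )
        s1 = tv.train(dataset, termset, cfg)
        s2 = tv.train(dataset, termset, copy.deepcopy(cfg))
        for k in s1.params:
            assert np.abs(s1.params[k] - s2.params[k]).max() <= 1e-6, k
        assert s1.history["train_total"].tolist() == s2.history["train_total"].tolist()

    def test_loss_decreases_over_training(self, bench_state):
        hist = bench_state.history["train_total"]
        assert hist.tail(5).mean() < hist.head(5).mean()

    def test_latent_dim_must_match_terms(self, tiny_problem):
        termset, dataset, _ = tiny_problem
        cfg = tv.ModelConfig(n_hidden=8, n_encoder_layers=1, max_epochs=1, seed=0)
        small = tv.TermSet(termset.terms[:2])
        state = tv.train(dataset, small, cfg)
        assert state.latent_dim == 2  # latent follows the termset, by construction

    def test_empty_mask_column_is_an_error(self, tiny_problem):
        termset, dataset, _ = tiny_problem
        orphan = tv.Term("ORPHAN", "", ("NOT_A_GENE",))
        bad = tv.TermSet(termset.terms + (orphan,))
        with pytest.raises(ValueError, match="align_terms"):
            build_mask(bad, dataset.genes)

    def test_pruning_monotone_in_group_weight(self, tiny_problem):
        """Stronger group lasso deactivates at least as many terms."""
        termset, dataset, _ = tiny_problem
        counts = []
        for ag in (0.0, 0.95, 50.0):
            cfg = tv.ModelConfig(
                n_hidden=16, n_encoder_layers=2, max_epochs=10, patience=10,
                batch_size=32, alpha_group=ag, seed=5,
            )
            state = tv.train(dataset, termset, cfg)
            counts.append(len(tv.inactive_terms(state)))
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] >= 0.8 * len(termset)

    def test_attention_off_matches_gate_free_scores(self, tiny_problem):
        """With the gate disabled, influence scores equal plain posterior
        means — the gate layer is a true identity path when off."""
        termset, dataset, _ = tiny_problem
        cfg = tv.ModelConfig(
            n_hidden=16, n_encoder_layers=2, max_epochs=6, patience=6,
            batch_size=32, use_attention=False, seed=4,
        )
        state = tv.train(dataset, termset, cfg)
        scores = tv.influence_scores(state, dataset)
        mu, _ = tv.encode(state, dataset.dense(), list(dataset.conditions))
        assert np.array_equal(scores.scores, mu)


class TestInactiveTerms:
    def test_threshold_extremes(self, tiny_state):
        assert tv.inactive_terms(tiny_state, threshold=0.0) == []
        assert tv.inactive_terms(tiny_state, threshold=np.inf) == tiny_state.term_ids

    def test_hand_built_zero_column_detected(self, tiny_state):
        state = copy.deepcopy(tiny_state)
        state.params["W_dec"][:, 2] = 0.0
        state.params["W_soft"][:, 2] = 0.0
        assert state.term_ids[2] in tv.inactive_terms(state, threshold=1e-6)


class TestCheckpoint:
    def test_round_trip_preserves_behaviour(self, tiny_state, tiny_problem, tmp_path):
        _, dataset, _ = tiny_problem
        tv.save_model(tiny_state, tmp_path / "ckpt")
        back = tv.load_model(tmp_path / "ckpt")
        assert back.term_ids == tiny_state.term_ids
        assert back.gene_ids == tiny_state.gene_ids
        s1 = tv.influence_scores(tiny_state, dataset)
        s2 = tv.influence_scores(back, dataset)
        assert np.array_equal(s1.scores, s2.scores)
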