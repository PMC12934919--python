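"""Mask plans, decoders, losses, training determinism, and learning sanity."""

import numpy as np
import pytest

import tosgkit as tk
from tosgkit._autodiff import Tensor
from tosgkit.data import TosgError, TosgTopology
from tosgkit.encoder import encode_text
from tosgkit.pretrain import (
    MaskPlan,
    PretrainConfig,
    PretrainState,
    degree_loss,
    edge_logit,
    edge_loss,
    edge_loss_from_logits,
    evaluate_reconstruction,
    propagate,
    sample_edge_mask,
    sample_negative_edges,
    save_checkpoint,
    load_checkpoint,
    score_edge,
    total_loss,
    train,
)


@pytest.fixture(scope="module")
def world(tiny_world):
    _, cat, topo, coh = tiny_world
    text = encode_text(cat, width=8)
    return cat, topo, coh, text


def make_state(cat, text, seed=0, zero_init=False, **kw):
    cfg = PretrainConfig(d_prime=8, d=4, batch_size=4, seed=seed, **kw)
    return PretrainState(config=cfg, catalog=cat, text=text, zero_init=zero_init)


class TestMask:
    def test_p_zero_nothing_masked(self, world):
        _, topo, _, _ = world
        plan = sample_edge_mask(topo, 0.0, 1)
        assert plan.masked == [] and set(plan.visible) == set(topo.ppi_edges)

    def test_p_one_everything_masked(self, world):
        _, topo, _, _ = world
        plan = sample_edge_mask(topo, 1.0, 1)
        assert plan.visible == [] and set(plan.masked) == set(topo.ppi_edges)

    def test_partition_invariant(self, world):
        _, topo, _, _ = world
        plan = sample_edge_mask(topo, 0.3, 5)
        assert set(plan.masked) | set(plan.visible) == set(topo.ppi_edges)
        assert not set(plan.masked) & set(plan.visible)

    def test_binomial_mean_over_seeds(self):
        edges = [(f"p{i}", f"p{i + 500}") for i in range(1000)]
        topo = TosgTopology(internal_edges=[], ppi_edges=edges)
        counts = [len(sample_edge_mask(topo, 0.1, s).masked) for s in range(500)]
        se = np.sqrt(1000 * 0.1 * 0.9 / 500)
        assert abs(np.mean(counts) - 100) < 3 * se

    def test_invalid_ratio(self, world):
        _, topo, _, _ = world
        with pytest.raises(TosgError):
            sample_edge_mask(topo, 1.5, 0)


class TestPropagate:
    def test_zero_init_gives_zero_embeddings(self, world):
        cat, topo, coh, text = world
        state = make_state(cat, text, zero_init=True)
        h = propagate(state, coh.features[:3], topo)
        assert np.all(h.data == 0)

    def test_no_ppi_edges_plan_independent(self, world):
        cat, _, coh, text = world
        topo0 = TosgTopology(
            internal_edges=[(t, p) for t, p in
                            zip(cat.transcript_ids, [cat.protein_ids[0]] * 12)],
            ppi_edges=[],
        )
        state = make_state(cat, text)
        plan_a = MaskPlan(ratio=0.0, seed=0, masked=[], visible=[])
        h1 = propagate(state, coh.features[:2], topo0, plan_a)
        h2 = propagate(state, coh.features[:2], topo0, None)
        assert np.allclose(h1.data, h2.data)

    def test_matches_hand_computed_aggregation(self, world):
        """Single global layer on a 6-node graph equals the manual mean pass."""
        cat, topo, coh, text = world
        state = make_state(cat, text, n_global_layers=1)
        h = propagate(state, coh.features[:1], topo, None)
        # manual recomputation
        import scipy.sparse as sp

        idx = cat.index_of()
        m = cat.size
        fused = state.fusion.fuse(state.omic.encode(coh.features[:1]), state.text).data
        A_in = np.zeros((m, m))
        for t, p in topo.internal_edges:
            A_in[idx[p], idx[t]] = 1
        A_in = A_in / np.maximum(A_in.sum(1, keepdims=True), 1)
        z = fused @ state.internal_self.W.data + state.internal_self.b.data \
            + (A_in @ fused[0]) @ state.internal_nbr.W.data + state.internal_nbr.b.data
        z = np.maximum(z, 0)
        z = np.maximum(z @ state.perceptron.W.data + state.perceptron.b.data, 0)
        A_g = np.zeros((m, m))
        for a, b in topo.ppi_edges:
            A_g[idx[a], idx[b]] = A_g[idx[b], idx[a]] = 1
        A_g = A_g / np.maximum(A_g.sum(1, keepdims=True), 1)
        ln = state.global_layers[0]
        z = (A_g @ z[0]) @ ln.W.data + ln.b.data
        norm = 1.0 / np.sqrt((z * z).sum(-1, keepdims=True) + 1e-8)
        assert np.allclose(h.data, z * norm, atol=1e-10)

    def test_foreign_edge_rejected(self, world):
        cat, topo, coh, text = world
        state = make_state(cat, text)
        bad = TosgTopology(internal_edges=topo.internal_edges,
                           ppi_edges=[("zzz1", "zzz2")])
        with pytest.raises(TosgError):
            propagate(state, coh.features[:1], bad)


class TestEdgeScore:
    def test_zero_decoder_scores_half(self, world):
        cat, _, _, text = world
        state = make_state(cat, text, zero_init=True)
        h = Tensor(np.random.default_rng(0).standard_normal((2, 3, 4)))
        s = score_edge(state, h, h)
        assert np.allclose(s.data, 0.5)

    def test_symmetry_exact(self, world):
        cat, _, _, text = world
        state = make_state(cat, text)
        rng = np.random.default_rng(1)
        hi = Tensor(rng.standard_normal((2, 5, 4)))
        hj = Tensor(rng.standard_normal((2, 5, 4)))
        assert np.array_equal(
            score_edge(state, hi, hj).data, score_edge(state, hj, hi).data
        )

    def test_matches_composition_oracle(self, world):
        cat, _, _, text = world
        state = make_state(cat, text)
        rng = np.random.default_rng(2)
        hi, hj = rng.standard_normal((2, 3, 4)), rng.standard_normal((2, 3, 4))
        z = np.maximum((hi * hj) @ state.edge_hidden.W.data + state.edge_hidden.b.data, 0)
        want = 1 / (1 + np.exp(-(z @ state.edge_out.W.data + state.edge_out.b.data)))
        got = score_edge(state, Tensor(hi), Tensor(hj)).data
        assert np.allclose(got, want[..., 0])

    def test_width_mismatch(self, world):
        cat, _, _, text = world
        state = make_state(cat, text)
        with pytest.raises(TosgError):
            score_edge(state, Tensor(np.zeros((1, 2, 7))), Tensor(np.zeros((1, 2, 7))))


class TestLosses:
    def test_uninformative_scores_give_two_log_two(self):
        s = Tensor(np.full(10, 0.5))
        assert float(edge_loss(s, s).data) == pytest.approx(2 * np.log(2))

    def test_perfect_scores_vanish_at_clip(self):
        pos = Tensor(np.ones(5))
        neg = Tensor(np.zeros(5))
        assert float(edge_loss(pos, neg).data) == pytest.approx(0.0, abs=1e-6)

    def test_matches_hand_computed_bce(self, rng):
        p = rng.uniform(0.1, 0.9, 10)
        n = rng.uniform(0.1, 0.9, 10)
        want = -(np.mean(np.log(p)) + np.mean(np.log(1 - n)))
        assert float(edge_loss(Tensor(p), Tensor(n)).data) == pytest.approx(want)

    def test_logit_form_agrees_with_probability_form(self, rng):
        z_pos = rng.normal(0, 2, 20)
        z_neg = rng.normal(0, 2, 20)
        a = edge_loss_from_logits(Tensor(z_pos), Tensor(z_neg))
        sig = lambda z: 1 / (1 + np.exp(-z))
        b = edge_loss(Tensor(sig(z_pos)), Tensor(sig(z_neg)))
        assert float(a.data) == pytest.approx(float(b.data))

    def test_empty_sets_rejected(self):
        with pytest.raises(TosgError):
            edge_loss(Tensor(np.array([])), Tensor(np.array([0.5])))

    def test_degree_loss_zero_at_exact_prediction(self, world):
        cat, topo, coh, text = world
        state = make_state(cat, text)
        # overwrite the degree decoder to output exact degrees via bias probing
        idx = cat.index_of()
        deg = np.zeros(cat.size)
        for a, b in topo.ppi_edges:
            deg[idx[a]] += 1
            deg[idx[b]] += 1
        h = Tensor(np.zeros((2, cat.size, 4)))
        state.deg_hidden.W.data[:] = 0
        state.deg_hidden.b.data[:] = 0
        state.deg_out.W.data[:] = 0
        # with h = 0 and zeroed weights the prediction equals the output bias;
        # a per-node exact fit needs node-dependent output, so test the
        # documented arithmetic instead: prediction off by +1 -> loss 1
        state.deg_out.b.data[:] = 1.0
        loss = degree_loss(state, h, TosgTopology(internal_edges=[], ppi_edges=[]))
        assert float(loss.data) == pytest.approx(1.0)

    def test_degree_loss_matches_mse_oracle(self, world, rng):
        cat, topo, coh, text = world
        state = make_state(cat, text)
        h = Tensor(rng.standard_normal((3, cat.size, 4)))
        idx = cat.index_of()
        deg = np.zeros(cat.size)
        for a, b in topo.ppi_edges:
            deg[idx[a]] += 1
            deg[idx[b]] += 1
        z = np.maximum(h.data @ state.deg_hidden.W.data + state.deg_hidden.b.data, 0)
        pred = (z @ state.deg_out.W.data + state.deg_out.b.data)[..., 0]
        want = np.mean((pred - deg) ** 2)
        assert float(degree_loss(state, h, topo).data) == pytest.approx(want)

    def test_total_loss_weighted_sum(self):
        out = total_loss(Tensor(np.array(1.0)), Tensor(np.array(0.5)), 1.0, 1.0)
        assert float(out.data) == pytest.approx(1.5)
        with pytest.raises(TosgError):
            total_loss(Tensor(np.array(1.0)), Tensor(np.array(0.5)), 0.0, 1.0)


class TestNegativeSampling:
    def test_never_collides_with_true_edges(self, world):
        cat, topo, _, _ = world
        rng = np.random.default_rng(0)
        existing = set(topo.ppi_edges)
        for _ in range(20):
            negs = sample_negative_edges(topo, cat, 5, rng)
            assert not (set(negs) & existing)
            assert all(a != b for a, b in negs)


class TestTraining:
    def test_zero_learning_rate_freezes_parameters(self, world):
        cat, topo, coh, text = world
        state = make_state(cat, text, learning_rate=0.0)
        before = {k: p.data.copy() for k, p in state.params.items()}
        plan = sample_edge_mask(topo, 0.2, 0)
        trace = train(state, coh, topo, plan, 3)
        assert len(trace) == 3
        assert all(np.array_equal(before[k], p.data)
                   for k, p in state.params.items())

    def test_same_seed_identical_final_parameters(self, world):
        cat, topo, coh, text = world
        plan = sample_edge_mask(topo, 0.2, 0)
        finals = []
        for _ in range(2):
            state = make_state(cat, text, seed=3)
            train(state, coh, topo, plan, 5)
            finals.append({k: p.data.copy() for k, p in state.params.items()})
        assert all(np.array_equal(finals[0][k], finals[1][k]) for k in finals[0])

    def test_smoothed_loss_trace_decreases(self):
        spec = tk.SyntheticSpec(
            n_transcripts=40, n_proteins=40, n_communities=2, n_samples=30,
            intra_edge_prob=0.4, inter_edge_prob=0.05, seed=9,
        )
        cat = tk.make_catalog(spec)
        topo = tk.make_ppi(spec, cat)
        coh = tk.make_cohort(spec, topo, cat)
        text = encode_text(cat, width=16)
        cfg = PretrainConfig(d_prime=16, d=8, batch_size=8, seed=9)
        state = PretrainState(config=cfg, catalog=cat, text=text)
        plan = sample_edge_mask(topo, 0.1, 9)
        trace = np.array(train(state, coh, topo, plan, 200))
        win = 25
        smoothed = np.convolve(trace, np.ones(win) / win, mode="valid")
        drop = smoothed[0] - smoothed[-1]
        assert drop > 0
        # monotone up to minibatch noise, small relative to the total drop
        increments = np.diff(smoothed)
        assert increments.max() < 0.05 * drop

    def test_checkpoint_round_trip(self, world, tmp_path):
        cat, topo, coh, text = world
        state = make_state(cat, text, seed=5)
        plan = sample_edge_mask(topo, 0.2, 5)
        train(state, coh, topo, plan, 3)
        save_checkpoint(state, tmp_path / "ckpt.npz")
        back = load_checkpoint(tmp_path / "ckpt.npz", cat)
        h1 = propagate(state, coh.features[:2], topo)
        h2 = propagate(back, coh.features[:2], topo)
        assert np.allclose(h1.data, h2.data)


class TestEvaluate:
    def test_perfect_scores_give_perfect_metrics(self, world, monkeypatch):
        cat, topo, coh, text = world
        state = make_state(cat, text)
        plan = sample_edge_mask(topo, 0.3, 1)
        masked = set(plan.masked)
        import tosgkit.pretrain as P

        def fake_scores(state_, h, pairs):
            vals = np.array([[1.0 if p in masked else 0.0 for p in pairs]])
            return Tensor(vals)

        monkeypatch.setattr(P, "_pair_scores", fake_scores)
        rate, auc = evaluate_reconstruction(state, coh, topo, plan, seed=0)
        assert rate == 1.0 and auc == 1.0

    def test_random_scores_give_chance_auc(self, world, monkeypatch):
        cat, topo, coh, text = world
        state = make_state(cat, text)
        plan = sample_edge_mask(topo, 0.3, 1)
        import tosgkit.pretrain as P

        aucs = []
        for seed in range(200):
            g = np.random.default_rng(seed)

            def fake_scores(state_, h, pairs, g=g):
                return Tensor(g.random((1, len(pairs))))

            monkeypatch.setattr(P, "_pair_scores", fake_scores)
            _, auc = evaluate_reconstruction(state, coh, topo, plan, seed=seed)
            aucs.append(auc)
        n_pos = len(plan.masked)
        se = np.std(aucs, ddof=1) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se

    def test_empty_masked_set_rejected(self, world):
        cat, topo, coh, text = world
        state = make_state(cat, text)
        plan = sample_edge_mask(topo, 0.0, 1)
        with pytest.raises(TosgError):
            evaluate_reconstruction(state, coh, topo, plan)


class TestLearningSanity:
    def test_training_beats_untrained_baseline(self):
        """Held-out masked-edge AUC improves by >= 0.2 after training."""
        wins = 0
        n_runs = 20
        for seed in range(n_runs):
            spec = tk.SyntheticSpec(
                n_transcripts=60, n_proteins=60, n_communities=2, n_samples=20,
                intra_edge_prob=0.5, inter_edge_prob=0.02, seed=seed,
            )
            cat = tk.make_catalog(spec)
            topo = tk.make_ppi(spec, cat)
            coh = tk.make_cohort(spec, topo, cat)
            text = encode_text(cat, width=16)
            cfg = PretrainConfig(d_prime=16, d=8, batch_size=4, seed=seed)
            state = PretrainState(config=cfg, catalog=cat, text=text)
            plan = sample_edge_mask(topo, 0.2, seed)
            _, auc_before = evaluate_reconstruction(state, coh, topo, plan, seed=seed)
            train(state, coh, topo, plan, 300)
            _, auc_after = evaluate_reconstruction(state, coh, topo, plan, seed=seed)
            if auc_after - auc_before >= 0.2:
                wins += 1
        assert wins >= 0.95 * n_runs
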