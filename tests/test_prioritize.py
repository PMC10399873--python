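import numpy as np
import pandas as pd
import pytest

from cnvprior.features import FeatureKey, FeatureMatrix
from cnvprior.prioritize import (
    ClassifierHead,
    auc_rank,
    finetune,
    gene_scores,
    rank_genes,
)
from cnvprior.vae import (
    ArchitectureSpec,
    TrainConfig,
    VAEParams,
    init_params,
    load_checkpoint,
    plan_architecture,
    save_checkpoint,
)


class TestAucRank:
    def test_perfect_separation(self):
        assert auc_rank([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert auc_rank([5, 5, 5, 5], [0, 1, 0, 1]) == 0.5

    def test_matches_exhaustive_pairwise_count(self):
        rng = np.random.default_rng(9)
        scores = rng.integers(0, 8, size=20).astype(float)  # many ties
        labels = rng.integers(0, 2, size=20)
        if labels.sum() in (0, 20):
            labels[0] = 1 - labels[0]
        wins = ties = 0
        cases = scores[labels == 1]
        controls = scores[labels == 0]
        for sc in cases:
            for sn in controls:
                wins += sc > sn
                ties += sc == sn
        expected = (wins + 0.5 * ties) / (len(cases) * len(controls))
        assert auc_rank(scores, labels) == pytest.approx(expected)

    def test_single_class_is_fatal(self):
        with pytest.raises(ValueError):
            auc_rank([1.0, 2.0], [1, 1])


def linear_vae(enc_W, W_mu, head_w, head_b=0.0):
    """Assemble a linear-activation encoder with given weight chain."""
    I = enc_W[0].shape[0] if enc_W else W_mu.shape[0]
    hidden = tuple(w.shape[1] for w in enc_W)
    latent = W_mu.shape[1]
    arch = ArchitectureSpec(
        input_dim=I, hidden_sizes=hidden, latent_dim=latent,
        activation="linear", dropout_rate=0.0,
    )
    rng = np.random.default_rng(0)
    params = VAEParams(
        arch=arch,
        enc_W=[w.astype(float) for w in enc_W],
        enc_b=[rng.normal(size=w.shape[1]) for w in enc_W],
        W_mu=W_mu.astype(float),
        b_mu=rng.normal(size=latent),
        W_lv=np.zeros((enc_W[-1].shape[1] if enc_W else I, latent)),
        b_lv=np.zeros(latent),
        dec_W=[np.zeros((latent, I))],
        dec_b=[np.zeros(latent), np.zeros(I)][-1:],
    )
    return params, ClassifierHead(weights=np.asarray(head_w, float), bias=head_b)


class TestGeneScores:
    def test_single_linear_layer_returns_weight_vector(self):
        v = np.array([[0.3], [-1.2], [2.0], [0.0]])
        params, head = linear_vae([], v, [1.0])
        assert np.allclose(gene_scores(params, head), v.ravel())

    def test_identity_chain_returns_head_vector(self):
        I = 3
        params, head = linear_vae([np.eye(3)], np.eye(3), [0.5, -1.0, 2.0])
        assert np.allclose(gene_scores(params, head), [0.5, -1.0, 2.0])

    def test_linear_in_head_weights(self):
        rng = np.random.default_rng(2)
        params, head = linear_vae(
            [rng.normal(size=(6, 3))], rng.normal(size=(3, 2)), rng.normal(size=2)
        )
        s1 = gene_scores(params, head)
        head2 = ClassifierHead(weights=3.0 * head.weights, bias=head.bias)
        assert np.allclose(gene_scores(params, head2), 3.0 * s1)

    def test_equals_input_jacobian_of_linear_network(self):
        # oracle: forward evaluation of the pre-sigmoid logit at basis
        # vectors (exact Jacobian for a linear-activation network)
        rng = np.random.default_rng(4)
        I = 12
        params, head = linear_vae(
            [rng.normal(size=(I, 5)), rng.normal(size=(5, 3))],
            rng.normal(size=(3, 2)),
            rng.normal(size=2),
            head_b=0.7,
        )
        from cnvprior.vae import encode

        def logit(x):
            _, _, mu, _ = encode(params, x[None, :])
            return float((mu @ head.weights)[0] + head.bias)

        base = logit(np.zeros(I))
        jac = np.array([logit(np.eye(I)[i]) - base for i in range(I)])
        assert np.allclose(gene_scores(params, head), jac, atol=1e-8)

    def test_shape_mismatch_is_fatal(self):
        params, _ = linear_vae([], np.zeros((4, 2)), [1.0, 1.0])
        with pytest.raises(ValueError):
            gene_scores(params, ClassifierHead(weights=np.ones(3), bias=0.0))


def make_counts(rows):
    return pd.DataFrame(rows, columns=["gene_id", "dosage", "case_ov", "control_ov"])


class TestRankGenes:
    def test_sorted_by_score_descending(self):
        counts = make_counts(
            [("A", "del", 5, 1), ("B", "del", 5, 1), ("C", "del", 5, 1)]
        )
        res = rank_genes(np.array([2.0, 1.0, 3.0]), counts, np.array([0.1, 0.1, 0.1]))
        assert [r.key.gene_id for r in res] == ["C", "A", "B"]
        assert [r.rank for r in res] == [1, 2, 3]

    def test_control_dominated_feature_excluded_with_reason(self):
        counts = make_counts(
            [("A", "del", 5, 1), ("B", "del", 2, 5), ("C", "del", 5, 1)]
        )
        res = rank_genes(np.array([2.0, 1.0, 3.0]), counts, np.array([0.1, 0.1, 0.1]))
        by_gene = {r.key.gene_id: r for r in res}
        assert by_gene["B"].excluded and "control" in by_gene["B"].reason
        assert by_gene["B"].rank is None
        assert (by_gene["C"].rank, by_gene["A"].rank) == (1, 2)

    def test_zero_overlap_excluded(self):
        counts = make_counts([("A", "del", 0, 0), ("B", "del", 3, 1)])
        res = rank_genes(np.array([5.0, 1.0]), counts, np.array([1.0, 0.5]))
        by_gene = {r.key.gene_id: r for r in res}
        assert by_gene["A"].excluded and by_gene["B"].rank == 1

    def test_score_ties_break_by_fisher_p(self):
        counts = make_counts([("A", "del", 5, 1), ("B", "del", 5, 1)])
        res = rank_genes(np.array([1.0, 1.0]), counts, np.array([0.2, 0.01]))
        assert [r.key.gene_id for r in res] == ["B", "A"]

    def test_deterministic_given_inputs(self):
        rng = np.random.default_rng(0)
        counts = make_counts(
            [(f"G{i}", "del", int(rng.integers(1, 9)), 0) for i in range(30)]
        )
        scores = rng.choice([1.0, 2.0], size=30)
        fisher = rng.choice([0.1, 0.5], size=30)
        r1 = rank_genes(scores, counts, fisher)
        r2 = rank_genes(scores, counts, fisher)
        assert [(r.key, r.rank) for r in r1] == [(r.key, r.rank) for r in r2]


def separable_matrix(seed=0, n=200, p=40):
    rng = np.random.default_rng(seed)
    y = np.repeat([0, 1], n // 2)
    X = np.clip(rng.random((n, p)) * 0.3, 0, 1)
    X[:, 0] = y * 0.9 + 0.05  # perfectly separable coordinate
    ids = [f"s{i}" for i in range(n)]
    keys = [FeatureKey(f"G{j}", "del") for j in range(p)]
    return FeatureMatrix(X=X, y=y, sample_ids=ids, feature_keys=keys, scaling="unit_interval")


class TestFinetune:
    def test_separable_data_reaches_high_accuracy(self):
        fm = separable_matrix(seed=1)
        params = init_params(plan_architecture(fm.n_features), np.random.default_rng(1))
        _, _, m = finetune(params, fm, TrainConfig(seed=2, max_epochs=200, early_stop_patience=80))
        assert m["accuracy"] >= 0.95

    def test_label_shuffled_data_auc_near_half(self):
        aucs = []
        for seed in range(5):
            fm = separable_matrix(seed=seed)
            rng = np.random.default_rng(100 + seed)
            fm.y = rng.permutation(fm.y)
            params = init_params(plan_architecture(fm.n_features), rng)
            _, _, m = finetune(
                params, fm, TrainConfig(seed=seed, max_epochs=60, early_stop_patience=60)
            )
            aucs.append(m["auc"])
        assert 0.35 <= float(np.mean(aucs)) <= 0.65

    def test_joint_fits_training_data_at_least_as_well_as_frozen(self):
        fm = separable_matrix(seed=3)
        params = init_params(plan_architecture(fm.n_features), np.random.default_rng(3))
        cfg = TrainConfig(seed=4, max_epochs=200, early_stop_patience=200)
        _, _, m_joint = finetune(params, fm, cfg, mode="joint")
        _, _, m_frozen = finetune(params, fm, cfg, mode="frozen")
        assert min(m_joint["train_loss"]) <= min(m_frozen["train_loss"]) + 1e-6

    def test_single_class_labels_fatal(self):
        fm = separable_matrix()
        fm.y = np.ones_like(fm.y)
        params = init_params(plan_architecture(fm.n_features), np.random.default_rng(0))
        with pytest.raises(ValueError):
            finetune(params, fm, TrainConfig(seed=0, max_epochs=5))

    def test_feature_count_mismatch_fatal(self):
        fm = separable_matrix()
        params = init_params(plan_architecture(fm.n_features + 3), np.random.default_rng(0))
        with pytest.raises(ValueError):
            finetune(params, fm, TrainConfig(seed=0, max_epochs=5))


def test_scores_from_reloaded_checkpoint_are_bit_exact(tmp_path, benchmark_runs):
    run = benchmark_runs[0]
    params = run.params
    head = ClassifierHead(weights=np.full(params.arch.latent_dim, 0.7), bias=-0.2)
    path = tmp_path / "m.ckpt"
    save_checkpoint(path, params, head={"head_w": head.weights, "head_b": np.array([head.bias])})
    params2, _, head_arrays = load_checkpoint(path)
    head2 = ClassifierHead(weights=head_arrays["head_w"], bias=float(head_arrays["head_b"][0]))
    assert np.array_equal(gene_scores(params, head), gene_scores(params2, head2))


def test_planted_features_rank_in_top_decile_by_magnitude(benchmark_runs):
    """Planted risk features land in the top |score| decile in >= 4/5 runs."""
    hits = 0
    for run in benchmark_runs:
        n = len(run.scores)
        decile = max(1, n // 10)
        order = np.argsort(-np.abs(run.scores))
        top = {run.matrix.feature_keys[j] for j in order[:decile]}
        planted = {
            FeatureKey(g, d) for g, d in zip(run.truth["gene"], run.truth["status"])
        }
        if len(planted & top) >= len(planted) * 0.8:
            hits += 1
    assert hits >= 4
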