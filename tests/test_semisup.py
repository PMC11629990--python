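import numpy as np
import pytest

from annogcd import (
    Role,
    UNLABELED,
    combined_loss,
    consensus_label,
    encode,
    fit_occ_bank,
    label_loss,
    mse_loss,
    train_semisup,
)
from annogcd.semisup import OCCBank, Provenance, loss_weights


class _FixedOCC:
    """Stub one-class classifier with a predetermined accept decision."""

    def __init__(self, accept):
        self.accept = accept

    def decision_function(self, Z):
        return np.full(len(Z), 1.0 if self.accept else -1.0)


def _stub_bank(accept_vector):
    return OCCBank(classifiers=[_FixedOCC(a) for a in accept_vector],
                   train_sizes=[2] * len(accept_vector), nu=0.05)


# ---------------------------------------------------------------------------
# Loss functions
# ---------------------------------------------------------------------------

class TestLosses:
    @pytest.mark.parametrize(
        "X, X_hat, expected",
        [
            ([[1.0, 2.0]], [[1.0, 2.0]], 0.0),
            ([[1.0, 2.0]], [[0.0, 0.0]], 5.0),            # 1^2 + 2^2
            ([[1.0, 0.0], [0.0, 1.0]], [[0.0, 0.0], [0.0, 0.0]], 1.0),
        ],
    )
    def test_mse_reference_values(self, X, X_hat, expected):
        assert mse_loss(np.array(X), np.array(X_hat)) == pytest.approx(expected)

    def test_mse_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros((2, 3)), np.zeros((3, 2)))

    @pytest.mark.parametrize(
        "onehot, pred, expected",
        [
            ([[1, 0]], [[1.0, 0.0]], 0.0),
            ([[1, 0]], [[0.5, 0.5]], np.log(2)),
            ([[0, 1, 0, 0]], [[0.25] * 4], np.log(4)),
        ],
    )
    def test_label_loss_reference_values(self, onehot, pred, expected):
        assert label_loss(np.array(onehot, float), np.array(pred)) == pytest.approx(
            expected, abs=1e-9
        )

    def test_combined_loss_and_weight_parameterization(self):
        assert combined_loss(2.0, 3.0, (1.0, 1.0)) == 5.0
        assert combined_loss(2.0, 0.0, (0.7, 1.0)) == pytest.approx(1.4)
        assert loss_weights(0.0, 0.0) == (1.0, 1.0)


# ---------------------------------------------------------------------------
# Joint training
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def model(small_split):
    return train_semisup(small_split, epochs=150, seed=7)


@pytest.fixture(scope="module")
def latent_classes():
    rng = np.random.default_rng(0)
    cents = np.array([[0.0] * 8, [12.0] + [0.0] * 7, [0.0, 12.0] + [0.0] * 6])
    Z = np.concatenate([c + rng.normal(size=(60, 8)) for c in cents])
    labels = np.repeat([0, 1, 2], 60)
    return Z, labels


class TestTrainSemisup:
    def test_loss_decreases(self, model):
        assert model.loss_history[-1] < model.loss_history[0]

    def test_predictor_beats_chance_on_unlabeled_known(self, model, small_split):
        mask = small_split.mask(Role.UNLABELED_KNOWN)
        probs = model.predict_proba(small_split.dataset.features[mask])
        pred = probs.argmax(axis=1)
        truth = small_split.true_label_indices()[mask]
        assert np.mean(pred == truth) > 1.0 / small_split.n_known

    def test_predictor_rows_on_simplex(self, model, small_split):
        probs = model.predict_proba(small_split.dataset.features[:20])
        assert np.all(probs >= 0)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)

    def test_training_is_deterministic(self, small_split):
        a = train_semisup(small_split, epochs=30, seed=3)
        b = train_semisup(small_split, epochs=30, seed=3)
        assert a.loss_history[-1] == pytest.approx(b.loss_history[-1], abs=1e-12)

    def test_no_predictor_freezes_label_weight(self, small_split):
        model = train_semisup(small_split, epochs=30, seed=3, use_predictor=False)
        assert model.weights[1] == 0.0
        assert model.predictor is None

    def test_latent_predictor_input_variant_trains(self, small_split):
        model = train_semisup(small_split, epochs=30, seed=3,
                              predictor_input="latent")
        assert model.loss_history[-1] < model.loss_history[0]

    def test_encode_decode_consistent_with_training_log(self, model, small_split):
        X = small_split.dataset.features
        Z = encode(model, X)
        X_hat = model.decoder.forward(Z.Z)
        assert mse_loss(X, X_hat) <= model.mse_history[-1] * 1.05 + 1e-9


class TestEncode:
    def test_empty_input(self, small_split):
        model = train_semisup(small_split, epochs=5, seed=0)
        out = encode(model, np.zeros((0, small_split.dataset.n_features)))
        assert out.Z.shape == (0, model.latent_dim)

    def test_duplicate_rows_get_identical_codes(self, small_split):
        model = train_semisup(small_split, epochs=5, seed=0)
        x = small_split.dataset.features[0]
        out = encode(model, np.stack([x, x]))
        np.testing.assert_array_equal(out.Z[0], out.Z[1])

    def test_dimension_mismatch(self, small_split):
        model = train_semisup(small_split, epochs=5, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            encode(model, np.zeros((3, small_split.dataset.n_features + 1)))


# ---------------------------------------------------------------------------
# One-class classifier bank
# ---------------------------------------------------------------------------

class TestOCCBank:
    def test_nu_property_on_training_rows(self, latent_classes):
        Z, labels = latent_classes
        nu = 0.05
        bank = fit_occ_bank(Z, labels, K=3, nu=nu)
        accept = bank.accepts(Z)
        for k in range(3):
            inlier_frac = np.mean(accept[labels == k, k])
            assert inlier_frac >= 1 - nu - 0.05

    def test_far_field_point_rejected_by_all(self, latent_classes):
        Z, labels = latent_classes
        bank = fit_occ_bank(Z, labels, K=3)
        far = np.full((1, 8), 100.0 * Z.std())
        assert not bank.accepts(far).any()

    def test_single_class_bank(self, latent_classes):
        Z, labels = latent_classes
        bank = fit_occ_bank(Z[labels == 0], labels[labels == 0], K=1)
        assert bank.K == 1

    def test_undersized_class_raises_naming_it(self, latent_classes):
        Z, labels = latent_classes
        with pytest.raises(ValueError, match="class 1"):
            fit_occ_bank(Z[labels == 0], np.zeros(60, int), K=2)


# ---------------------------------------------------------------------------
# Consensus labelling
# ---------------------------------------------------------------------------

class TestConsensusLabel:
    def _labeled_pool(self):
        # 14 labeled cells of class 0 near origin, 6 of class 1 further out
        rng = np.random.default_rng(5)
        Z0 = rng.normal(scale=0.1, size=(14, 2))
        Z1 = np.array([3.0, 0.0]) + rng.normal(scale=0.1, size=(6, 2))
        return np.concatenate([Z0, Z1]), np.repeat([0, 1], [14, 6])

    def test_single_acceptance_assigns_that_class(self):
        Zl, labels = self._labeled_pool()
        bank = _stub_bank([False, True, False])
        labels3 = np.repeat([0, 1, 2], [8, 8, 4])
        state = consensus_label(bank, np.zeros((1, 2)), Zl, labels3, N=5)
        assert state.labels[0] == 1
        assert state.provenance[0] == int(Provenance.OCC_SINGLE)

    def test_multiple_acceptance_resolved_by_neighbor_majority(self):
        Zl, labels = self._labeled_pool()
        bank = _stub_bank([True, True])
        state = consensus_label(bank, np.zeros((1, 2)), Zl, labels, N=20)
        # neighbors: 14 votes for class 0 vs 6 for class 1
        assert state.labels[0] == 0
        assert state.provenance[0] == int(Provenance.OCC_CONSENSUS)

    def test_no_acceptance_stays_unlabeled(self):
        Zl, labels = self._labeled_pool()
        bank = _stub_bank([False, False])
        state = consensus_label(bank, np.zeros((1, 2)), Zl, labels, N=5)
        assert state.labels[0] == UNLABELED
        assert state.provenance[0] == int(Provenance.UNLABELED)

    def test_vote_restricted_to_accepting_classes(self):
        Zl, labels = self._labeled_pool()
        # classes 1 and 2 accept; neighbors are mostly class 0 which must be
        # excluded from the restricted vote
        bank = _stub_bank([False, True, True])
        labels3 = labels.copy()
        labels3[14:17] = 1
        labels3[17:] = 2
        probe = np.array([[3.0, 0.0]])
        state = consensus_label(bank, probe, Zl, labels3, N=20)
        assert state.labels[0] in (1, 2)

    def test_monotone_votes(self):
        # adding votes for the winning class never flips the winner
        Zl = np.concatenate([np.zeros((6, 2)), np.ones((4, 2))])
        bank = _stub_bank([True, True])
        for extra in range(3):
            labels = np.repeat([0, 1], [6 + 0, 4])
            labels[:6] = 0
            state = consensus_label(bank, np.zeros((1, 2)), Zl, labels, N=10)
            assert state.labels[0] == 0

    def test_never_emits_novel_ids(self, small_split):
        model = train_semisup(small_split, epochs=60, seed=1)
        X = small_split.dataset.features
        lab = small_split.mask(Role.LABELED_KNOWN)
        Z = encode(model, X).Z
        bank = fit_occ_bank(Z[lab], small_split.label[lab], small_split.n_known)
        state = consensus_label(bank, Z[~lab], Z[lab], small_split.label[lab])
        assert state.labels.max() < small_split.n_known

    def test_empty_labeled_set_raises(self):
        bank = _stub_bank([True])
        with pytest.raises(ValueError):
            consensus_label(bank, np.zeros((1, 2)), np.zeros((0, 2)),
                            np.zeros(0, int))


class TestBlockRecoveryInvariant:
    def test_known_recovered_and_novel_rejected_at_high_separation(self):
        """At >=6x separation the block should label >=90% of unlabeled
        known-type cells correctly and leave >=80% of novel-type cells
        unlabeled.

        Balanced types are used so every one-class classifier trains on a
        few hundred codes; with only tens of training codes the rejection
        rate is dominated by small-sample geometry rather than nu.
        """
        from annogcd import SynthConfig, make_split, reduce_pca, simulate_cells

        ds = reduce_pca(simulate_cells(SynthConfig(
            n_types=4, n_cells=1500, n_genes=60, separation=8.0,
            gini_target=0.0, seed=31)), 32)
        split = make_split(ds, known_frac=0.5, labeled_frac=0.7, seed=31)
        model = train_semisup(split, epochs=150, seed=7)
        X = split.dataset.features
        lab = split.mask(Role.LABELED_KNOWN)
        Z = encode(model, X).Z
        bank = fit_occ_bank(Z[lab], split.label[lab], split.n_known)
        pool = split.unlabeled_mask
        state = consensus_label(bank, Z[pool], Z[lab], split.label[lab])
        truth = split.true_label_indices()[pool]
        roles = split.role[pool]
        uk = roles == int(Role.UNLABELED_KNOWN)
        un = roles == int(Role.UNLABELED_NOVEL)
        assert np.mean(state.labels[uk] == truth[uk]) >= 0.90
        assert np.mean(state.labels[un] == UNLABELED) >= 0.80
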