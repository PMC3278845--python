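"""Network training, prediction, early stopping and cross-validation."""

import numpy as np
import pytest

from dinucpred.features import EncodingConfig, FeatureMatrix, assemble_features
from dinucpred.model import (
    Hyper,
    MLPModel,
    cross_validate,
    predict,
    train_classwise,
    train_with_early_stopping,
)
from dinucpred.simgen import SimConfig, make_complex

RULE = {"K": "AA", "R": "CC", "H": "GG", "W": "UU",
        "F": "AC", "Y": "CG", "M": "GU", "L": "UA"}
ONEHOT = EncodingConfig(neighbours_per_side=0, use_sparse=True,
                        use_pssm=False, use_gac=False)


def _rk_dataset(n_proteins, length, seed, n_out=1):
    """One-hot proteins with target 1 iff the residue is R or K."""
    rng = np.random.default_rng(seed)
    entries = []
    for p in range(n_proteins):
        seq = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
        fm = assemble_features(seq, None, ONEHOT, protein_id=f"p{p}")
        t = np.array([[1.0 if a in "RK" else 0.0] * n_out for a in seq])
        entries.append((fm, t))
    return entries


def _rule_dataset(n_complexes=10, seed=0):
    cfg = SimConfig(seed=seed, n_complexes=n_complexes, rna_length=(26, 30),
                    identity_rule=RULE)
    entries = []
    for i in range(n_complexes):
        sim = make_complex(cfg, i)
        fm = assemble_features(sim.protein_sequence, None, ONEHOT,
                               protein_id=sim.profile.protein_id)
        entries.append((fm, sim.profile))
    return entries


class TestForwardPass:
    def test_zero_weight_model_outputs_half(self):
        model = MLPModel(3, 2, 4, np.zeros((3, 2)), np.zeros(2),
                         np.zeros((2, 4)), np.zeros(4))
        fm = FeatureMatrix("x", np.ones((5, 3)))
        np.testing.assert_allclose(predict(model, fm).scores, 0.5)

    def test_matches_hand_computed_closed_form(self):
        w1 = np.array([[0.5, -0.3], [0.2, 0.8]])
        b1 = np.array([0.1, -0.2])
        w2 = np.array([[1.0], [-1.5]])
        b2 = np.array([0.3])
        model = MLPModel(2, 2, 1, w1, b1, w2, b2)
        x = np.array([0.7, -0.4])

        def sig(z):
            return 1.0 / (1.0 + np.exp(-z))

        h = sig(w1.T @ x + b1)
        expected = sig(w2.T @ h + b2)
        got = model.forward(x)[0]
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_outputs_in_open_unit_interval(self):
        rng = np.random.default_rng(0)
        model = MLPModel(4, 3, 2, rng.normal(size=(4, 3)), rng.normal(size=3),
                         rng.normal(size=(3, 2)), rng.normal(size=2))
        scores = model.forward(rng.normal(size=(20, 4)))
        assert ((scores > 0) & (scores < 1)).all()

    def test_dimension_mismatch_raises(self):
        model = MLPModel(4, 2, 1, np.zeros((4, 2)), np.zeros(2),
                         np.zeros((2, 1)), np.zeros(1))
        with pytest.raises(ValueError, match="expects 4"):
            predict(model, FeatureMatrix("x", np.ones((3, 5))))


class TestTraining:
    def test_separable_rule_is_learned(self):
        entries = _rk_dataset(8, 40, seed=1)
        model = train_with_early_stopping(
            entries[:6], entries[6:],
            Hyper(seed=0, max_epochs=300, learning_rate=0.2, patience=25),
        )
        from dinucpred.evaluate import roc_auc

        X = np.vstack([fm.rows for fm, _ in entries[:6]])
        T = np.vstack([t for _, t in entries[:6]])
        auc = roc_auc(model.forward(X)[:, 0], T[:, 0].astype(int)).auc
        assert auc >= 0.99

    def test_all_zero_targets_converge_low(self):
        rng = np.random.default_rng(2)
        entries = [
            (FeatureMatrix(f"p{i}", rng.uniform(size=(30, 10))), np.zeros((30, 1)))
            for i in range(4)
        ]
        model = train_with_early_stopping(entries[:3], entries[3:],
                                          Hyper(seed=0, max_epochs=100))
        assert model.forward(entries[0][0].rows).max() < 0.1

    def test_same_seed_gives_identical_weights(self):
        entries = _rk_dataset(6, 20, seed=3)
        h = Hyper(seed=7, max_epochs=30)
        m1 = train_with_early_stopping(entries[:4], entries[4:], h)
        m2 = train_with_early_stopping(entries[:4], entries[4:], h)
        assert m1.to_json() == m2.to_json()

    def test_empty_train_set_raises(self):
        entries = _rk_dataset(2, 10, seed=0)
        with pytest.raises(ValueError, match="empty"):
            train_with_early_stopping([], entries, Hyper())

    def test_nan_features_rejected_with_location(self):
        fm = FeatureMatrix("badprot", np.array([[0.1, np.nan]]))
        with pytest.raises(ValueError, match="badprot"):
            train_with_early_stopping([(fm, np.zeros((1, 1)))],
                                      [(fm, np.zeros((1, 1)))], Hyper())

    def test_early_stopping_returns_best_stop_epoch(self):
        """Retained weights never have worse stop error than any epoch seen."""
        entries = _rk_dataset(6, 25, seed=4)
        model = train_with_early_stopping(entries[:4], entries[4:],
                                          Hyper(seed=1, max_epochs=60))
        Xs = np.vstack([fm.rows for fm, _ in entries[4:]])
        Ts = np.vstack([t for _, t in entries[4:]])
        final_err = float(np.mean((model.forward(Xs) - Ts) ** 2))
        assert final_err == pytest.approx(model.train_meta["stop_error"], rel=1e-9)
        assert model.train_meta["stopping_epoch"] <= model.train_meta["epochs_run"]


class TestCrossValidation:
    def test_every_protein_tested_exactly_once(self):
        entries = _rk_dataset(10, 15, seed=5)
        res = cross_validate(entries, Hyper(seed=0, max_epochs=5))
        assert set(res.predictions) == {fm.protein_id for fm, _ in entries}
        # folds partition the protein set
        assert sorted(res.plan.fold_assignment.values()) == sorted(
            [i % 5 for i in range(10)]
        )

    def test_no_leakage_between_roles(self):
        entries = _rk_dataset(10, 15, seed=6)
        res = cross_validate(entries, Hyper(seed=0, max_epochs=5))
        for cycle in res.plan.cycles:
            assert cycle["test"] not in cycle["train"]
            assert cycle["stop"] not in cycle["train"]
            assert cycle["test"] != cycle["stop"]

    def test_too_few_proteins_raises(self):
        entries = _rk_dataset(4, 10, seed=7)
        with pytest.raises(ValueError, match="at least 5"):
            cross_validate(entries, Hyper())

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_rule_recovered_out_of_fold(self, seed):
        """Deterministic residue-identity rule gives macro AUC >= 0.90."""
        entries = _rule_dataset(n_complexes=10, seed=seed)
        res = cross_validate(entries,
                             Hyper(seed=seed, learning_rate=0.2, patience=25,
                                   max_epochs=300))
        assert res.macro_auc >= 0.90

    def test_label_permutation_gives_chance_auc(self):
        """Permuted targets drive per-class AUC to the 0.4-0.6 chance band
        (averaged over 5 permutation seeds)."""
        from dinucpred.structure_io import ContactProfile

        entries = _rule_dataset(n_complexes=20, seed=3)
        T = np.vstack([e[1].matrix for e in entries])
        per_seed = []
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            P = T[rng.permutation(len(T))]
            off, permuted = 0, []
            for fm, prof in entries:
                permuted.append(
                    (fm, ContactProfile(prof.protein_id, P[off : off + len(fm)]))
                )
                off += len(fm)
            res = cross_validate(permuted, Hyper(seed=s))
            per_seed.append(res.auc_per_class)
        mean_auc = np.nanmean(np.array(per_seed), axis=0)
        assert np.nanmin(mean_auc) >= 0.40
        assert np.nanmax(mean_auc) <= 0.60


class TestClasswise:
    def _labelled(self, n=12):
        entries = _rk_dataset(n, 12, seed=8)
        labels = {
            fm.protein_id: ["viral", "mRNA"][i % 2]
            for i, (fm, _) in enumerate(entries)
        }
        return entries, labels

    def test_two_classes_give_two_reports(self):
        entries, labels = self._labelled(12)
        out = train_classwise(entries, labels, Hyper(seed=0, max_epochs=3))
        assert set(out) == {"viral", "mRNA"}
        for res in out.values():
            assert res.meta["functional_class"] in labels.values()

    def test_small_class_skipped_with_warning(self):
        entries, labels = self._labelled(12)
        for i, (fm, _) in enumerate(entries[:3]):
            labels[fm.protein_id] = "tRNA"
        with pytest.warns(UserWarning, match="tRNA"):
            out = train_classwise(entries, labels, Hyper(seed=0, max_epochs=3))
        assert "tRNA" not in out

    def test_unknown_class_label_raises(self):
        entries, labels = self._labelled(6)
        labels[entries[0][0].protein_id] = "snRNA"
        with pytest.raises(ValueError, match="snRNA"):
            train_classwise(entries, labels, Hyper())

    def test_per_class_hyper_recorded(self):
        entries, labels = self._labelled(12)
        override = {"viral": Hyper(seed=0, n_hidden=4, max_epochs=3)}
        out = train_classwise(entries, labels, Hyper(seed=0, max_epochs=3),
                              per_class_hyper=override)
        assert out["viral"].meta["hyper"]["n_hidden"] == 4
        assert out["mRNA"].meta["hyper"]["n_hidden"] == 10
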