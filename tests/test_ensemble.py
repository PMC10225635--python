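import numpy as np
import pytest

from grf3d.ensemble import (EnsembleEstimate, SplitPlan, Split,
                            make_split_plans, member_dispersion, run_loso)
from grf3d.estimators import TrainConfig
from grf3d.preprocess import preprocess_trial
from grf3d.simulate import GeneratorConfig, simulate_cohort
from grf3d.types import EstimateSource


class TestSplitPlans:
    def test_twelve_subjects_default_geometry(self):
        ids = [f"S{i:02d}" for i in range(12)]
        plans = make_split_plans(ids, seed=0)
        assert len(plans) == 12
        for plan in plans:
            assert len(plan.splits) == 7
            seen = set()
            for s in plan.splits:
                assert len(s.validation) == 4
                assert len(s.training) == 7
                assert plan.test_subject not in s.validation + s.training
                assert not set(s.validation) & set(s.training)
                assert set(s.validation) | set(s.training) == set(ids) - {plan.test_subject}
                seen.add(frozenset(s.validation))
            assert len(seen) == 7  # pairwise distinct

    def test_deterministic(self):
        ids = [f"S{i}" for i in range(9)]
        a = make_split_plans(ids, seed=5)
        b = make_split_plans(ids, seed=5)
        assert a == b
        c = make_split_plans(ids, seed=6)
        assert a != c

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            make_split_plans(["a", "b", "c", "d", "e"], seed=0)
        # six subjects leave only C(5,4)=5 < 7 distinct validation sets
        with pytest.raises(ValueError, match="distinct"):
            make_split_plans([f"s{i}" for i in range(6)], seed=0)

    def test_leaked_test_subject_rejected(self):
        with pytest.raises(ValueError, match="leaked"):
            SplitPlan("A", [Split(validation=("A", "B"), training=("C",))], 0)


class TestDispersion:
    def test_identical_members(self):
        members = np.tile(np.linspace(0, 1, 50)[None, :, None], (3, 1, 3))
        est = EnsembleEstimate(members, 240.0, EstimateSource.DIRECT)
        d = member_dispersion(est)
        assert np.allclose(d["sd"], 0)
        np.testing.assert_array_equal(d["min"], d["max"])
        np.testing.assert_allclose(d["min"], est.mean, rtol=1e-12)

    def test_hand_example_n_minus_one_denominator(self):
        members = np.zeros((2, 1, 3))
        members[1] = 2.0
        d = member_dispersion(EnsembleEstimate(members, 240.0, "direct"))
        assert d["sd"][0, 0] == pytest.approx(np.sqrt(2.0))
        assert d["min"][0, 0] == 0 and d["max"][0, 0] == 2

    def test_single_member_rejected(self):
        est = EnsembleEstimate(np.zeros((1, 5, 3)), 240.0, "direct")
        with pytest.raises(ValueError, match="two members"):
            member_dispersion(est)


class TestEnsembleIdentities:
    def test_mean_of_members(self):
        members = np.array([[[1.0, 1, 1], [2, 2, 2]], [[3.0, 3, 3], [4, 4, 4]]])
        est = EnsembleEstimate(members, 240.0, "direct")
        np.testing.assert_allclose(est.mean, [[2, 2, 2], [3, 3, 3]])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        members = rng.standard_normal((7, 100, 3))
        a = EnsembleEstimate(members, 240.0, "direct")
        b = EnsembleEstimate(members[::-1].copy(), 240.0, "direct")
        np.testing.assert_allclose(a.mean, b.mean)

    def test_jensen_inequality_random_members(self):
        rng = np.random.default_rng(1)
        truth = rng.standard_normal((200, 3))
        members = truth[None] + rng.standard_normal((7, 200, 3))
        est = EnsembleEstimate(members, 240.0, "direct")
        mse_ens = ((est.mean - truth) ** 2).mean()
        mse_members = ((members - truth[None]) ** 2).mean(axis=(1, 2))
        assert mse_ens <= mse_members.mean() + 1e-12


@pytest.fixture(scope="module")
def tiny_loso():
    """A minimal but real LOSO run: 7 subjects, one short trial each."""
    cfg = GeneratorConfig(n_subjects=7, velocities_kmh=(12.0,),
                          sf_conditions=("preferred",), duration_s=10.0, seed=21)
    pairs = simulate_cohort(cfg)
    trials = [preprocess_trial(t, n_strides=6)[0] for t, _ in pairs]
    tcfg = TrainConfig(epochs=8, patience_epochs=100, batch_size=250, seed=2)
    result = run_loso(trials, "direct", tcfg)
    return trials, result


class TestRunLoso:
    def test_member_count(self, tiny_loso):
        trials, result = tiny_loso
        assert len(result.members) == 7
        assert all(len(m) == 7 for m in result.members.values())

    def test_loso_hygiene_in_manifest(self, tiny_loso):
        _, result = tiny_loso
        for entry in result.manifest["plans"]:
            test = entry["test_subject"]
            for sp in entry["splits"]:
                assert test not in sp["validation"]
                assert test not in sp["training"]

    def test_jensen_on_real_run(self, tiny_loso):
        """Ensemble MSE never exceeds the mean member MSE (exact identity)."""
        trials, result = tiny_loso
        by_id = {t.subject.subject_id: t for t in trials}
        for subj, ests in result.estimates.items():
            t = by_id[subj]
            a, b = t.stride_window
            truth = t.force.grf[a:b] / t.subject.bodyweight_n
            for ens in ests:
                mse_ens = ((ens.mean - truth) ** 2).mean()
                mse_mem = ((ens.members - truth[None]) ** 2).mean(axis=(1, 2))
                assert mse_ens <= mse_mem.mean() + 1e-12

    def test_hybrid_weakly_dominates_direct_validation_loss(self, tiny_loso):
        """Where the physical model is near-valid, giving the network the
        physical estimate as an input does not hurt: hybrid validation loss
        stays within 5% of the direct model's (same splits, same seeds)."""
        trials, direct = tiny_loso
        tcfg = TrainConfig(epochs=30, patience_epochs=100, batch_size=250, seed=2)
        d = run_loso(trials, "direct", tcfg)
        h = run_loso(trials, "hybrid", tcfg)
        dv = np.mean([m.best_val_loss for ms in d.members.values() for m in ms])
        hv = np.mean([m.best_val_loss for ms in h.members.values() for m in ms])
        assert hv <= 1.05 * dv

    def test_determinism(self, tiny_loso):
        trials, result = tiny_loso
        tcfg = TrainConfig(epochs=8, patience_epochs=100, batch_size=250, seed=2)
        again = run_loso(trials, "direct", tcfg)
        s = sorted(result.estimates)[0]
        np.testing.assert_array_equal(result.estimates[s][0].members,
                                      again.estimates[s][0].members)
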