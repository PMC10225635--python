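"""Leave-one-subject-out cross-validation and ensemble construction.

For every held-out subject, seven networks are trained on randomly drawn,
pairwise-distinct splits of the remaining subjects into four validation
subjects and the rest for training. Each member predicts every trial of
the held-out subject; the ensemble estimate is the arithmetic mean over
the members, and member dispersion (sd, min, max per sample) quantifies
ensemble agreement, which is typically widest near the force peaks.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .estimators import (TrainConfig, TrainedEstimator, build_features,
                         predict, train_members)
from .io import trial_dirname
from .physical import PhysicalParams
from .types import EstimateSource, GrfEstimate, Trial

N_MEMBERS_DEFAULT = 7
N_VAL_DEFAULT = 4


@dataclass(frozen=True)
class Split:
    validation: Tuple[str, ...]
    training: Tuple[str, ...]


@dataclass
class SplitPlan:
    test_subject: str
    splits: List[Split]
    seed: int

    def __post_init__(self) -> None:
        seen = set()
        for s in self.splits:
            if self.test_subject in s.validation or self.test_subject in s.training:
                raise ValueError("test subject leaked into a split")
            if set(s.validation) & set(s.training):
                raise ValueError("validation and training sets overlap")
            key = frozenset(s.validation)
            if key in seen:
                raise ValueError("duplicate split in plan")
            seen.add(key)


@dataclass
class EnsembleEstimate:
    """Member predictions and their aggregate for one trial."""

    members: np.ndarray          # (n_members, n_samples, 3), BW
    rate_hz: float
    kind: EstimateSource
    trial_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.members.ndim != 3 or self.members.shape[2] != 3:
            raise ValueError("members must have shape (M, n, 3)")

    @property
    def n_members(self) -> int:
        return self.members.shape[0]

    @property
    def mean(self) -> np.ndarray:
        return self.members.mean(axis=0)

    def as_estimate(self) -> GrfEstimate:
        return GrfEstimate(self.mean, EstimateSource.ENSEMBLE, self.rate_hz)


def member_dispersion(est: EnsembleEstimate) -> Dict[str, np.ndarray]:
    """Per-sample member sd (n−1 denominator), min and max, per axis."""
    if est.n_members < 2:
        raise ValueError("dispersion requires at least two members")
    return {
        "sd": est.members.std(axis=0, ddof=1),
        "min": est.members.min(axis=0),
        "max": est.members.max(axis=0),
    }


def make_split_plans(subject_ids: Sequence[str],
                     n_splits: int = N_MEMBERS_DEFAULT,
                     n_val: int = N_VAL_DEFAULT,
                     seed: int = 0) -> List[SplitPlan]:
    """One plan per subject: ``n_splits`` pairwise-distinct random splits of
    the remaining subjects into ``n_val`` validation and the rest training.

    Deterministic given the seed; duplicate draws are rejection-sampled.
    """
    ids = sorted(set(subject_ids))
    if len(ids) != len(list(subject_ids)):
        raise ValueError("duplicate subject ids")
    if len(ids) < n_val + 2:
        raise ValueError(f"need at least {n_val + 2} subjects, got {len(ids)}")
    if comb(len(ids) - 1, n_val) < n_splits:
        raise ValueError(f"cannot draw {n_splits} distinct splits: only "
                         f"{comb(len(ids) - 1, n_val)} validation sets exist")
    rng = np.random.default_rng(seed)
    plans = []
    for test in ids:
        rest = [s for s in ids if s != test]
        seen = set()
        splits = []
        while len(splits) < n_splits:
            val = tuple(sorted(rng.choice(rest, size=n_val, replace=False)))
            if val in seen:
                continue
            seen.add(val)
            train = tuple(s for s in rest if s not in val)
            splits.append(Split(validation=val, training=train))
        plans.append(SplitPlan(test_subject=test, splits=splits, seed=seed))
    return plans


@dataclass
class LosoResult:
    """Outputs of one LOSO run for one model kind."""

    kind: EstimateSource
    estimates: Dict[str, List[EnsembleEstimate]]   # test subject -> per trial
    members: Dict[str, List[TrainedEstimator]]     # test subject -> 7 members
    manifest: dict


def _pool_rows(trials: List[Trial], kind, w: int,
               params: PhysicalParams) -> Tuple[np.ndarray, np.ndarray, Dict[str, np.ndarray]]:
    """Stack feature/target rows of all trials; map subject -> row indices."""
    Xs, Ys, owners = [], [], []
    for t in trials:
        X, Y = build_features(t, kind, w=w, params=params)
        if Y is None:
            raise ValueError("all cohort trials need measured force for LOSO")
        Xs.append(X)
        Ys.append(Y)
        owners.append(np.full(X.shape[0], t.subject.subject_id, dtype=object))
    X = np.vstack(Xs)
    Y = np.vstack(Ys)
    owner = np.concatenate(owners)
    by_subject = {s: np.flatnonzero(owner == s) for s in np.unique(owner)}
    return X, Y, by_subject


def run_loso(trials: List[Trial], kind, train_cfg: TrainConfig,
             plans: Optional[List[SplitPlan]] = None, w: int = 0,
             physical_params: PhysicalParams = PhysicalParams(),
             ) -> LosoResult:
    """Train and apply the full LOSO ensemble for one model kind.

    Every subject needs at least one preprocessed (synchronized + windowed)
    trial. A member that fails to train aborts the run: silent short
    ensembles are not allowed.
    """
    kind = EstimateSource(kind)
    subjects = sorted({t.subject.subject_id for t in trials})
    if plans is None:
        plans = make_split_plans(subjects, seed=train_cfg.seed)
    X, Y, rows_by_subject = _pool_rows(trials, kind, w, physical_params)
    trials_by_subject: Dict[str, List[Trial]] = {}
    for t in trials:
        trials_by_subject.setdefault(t.subject.subject_id, []).append(t)

    estimates: Dict[str, List[EnsembleEstimate]] = {}
    members_out: Dict[str, List[TrainedEstimator]] = {}
    manifest = {"kind": kind.value, "seed": train_cfg.seed, "w": w,
                "n_members": None, "plans": [], "members": {}}
    for pi, plan in enumerate(plans):
        test = plan.test_subject
        if test not in trials_by_subject:
            raise ValueError(f"no trials for planned test subject {test}")
        train_idx = [np.concatenate([rows_by_subject[s] for s in sp.training])
                     for sp in plan.splits]
        val_idx = [np.concatenate([rows_by_subject[s] for s in sp.validation])
                   for sp in plan.splits]
        cfg_m = TrainConfig(**{**train_cfg.__dict__,
                               "seed": train_cfg.seed + 1000 * (pi + 1)})
        members = train_members(X, Y, train_idx, val_idx, cfg_m, kind=kind)
        members_out[test] = members
        per_trial = []
        for t in trials_by_subject[test]:
            Xt, _ = build_features(t, kind, w=w, params=physical_params)
            preds = np.stack([predict(mb, Xt, rate_hz=t.rate_hz).values
                              for mb in members])
            per_trial.append(EnsembleEstimate(preds, t.rate_hz, kind,
                                              trial_id=trial_dirname(t)))
        estimates[test] = per_trial
        manifest["plans"].append({
            "test_subject": test,
            "splits": [{"validation": list(sp.validation),
                        "training": list(sp.training)} for sp in plan.splits],
        })
        manifest["members"][test] = [
            {"best_epoch": mb.best_epoch, "best_val_loss": mb.best_val_loss,
             "epochs_run": len(mb.history["val_loss"]), "seed": cfg_m.seed}
            for mb in members
        ]
    manifest["n_members"] = len(plans[0].splits)
    return LosoResult(kind=kind, estimates=estimates, members=members_out,
                      manifest=manifest)
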