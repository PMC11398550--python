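"""Training, cross-validation, hyperparameter search, and model comparison.

Optimization follows the published recipe: Adam with learning rate starting at
0.01 and decaying by a factor of 0.95 every 20 optimizer steps, plus early
stopping on a held-out validation split.  Cohorts here are small, so the
default batch is the full training set, making steps and epochs coincide.

Targets are z-scored on the training split before optimization and predictions
are mapped back to the original scale.  Adam's per-coordinate step size is
bounded by the learning rate, so under the geometric decay schedule the total
parameter travel is bounded by roughly lr0 * decay_every / (1 - decay) ≈ 4;
standardizing the 0–100 scores puts the solution within reach of the schedule.
This is a harness choice (configurable via ``standardize_targets``) and does
not alter the loss definition itself.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, TrainingError
from .metrics import compute_metrics
from .model import (HyperParams, LEGNetParams, calibrated_init, forward_batch,
                    init_params, load_checkpoint, loss_and_grads,
                    save_checkpoint, zeros_like_params)


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer and early-stopping settings (defaults per the method)."""

    learning_rate: float = 0.01
    decay_factor: float = 0.95
    decay_every: int = 20
    max_epochs: int = 300
    patience: int = 20
    min_epochs: int = 0  # early stopping cannot trigger before this epoch
    batch_size: Optional[int] = None  # None = full batch
    val_fraction: float = 0.1
    standardize_targets: bool = True
    standardize_inputs: bool = True
    init_scale: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ContractError("learning_rate must be > 0")
        if not (0 < self.decay_factor <= 1):
            raise ContractError("decay_factor must be in (0, 1]")
        if self.patience < 1:
            raise ContractError("patience must be >= 1")


def learning_rate_at(step: int, tc: TrainConfig) -> float:
    """lr(step) = lr0 * decay^floor(step / decay_every)."""
    return tc.learning_rate * tc.decay_factor ** (step // tc.decay_every)


def _cohort_arrays(cohort):
    """Accept a Cohort object or an (X, p, y) triple of arrays."""
    if hasattr(cohort, "connectivity"):
        return (np.asarray(cohort.connectivity, dtype=float),
                np.asarray(cohort.spared, dtype=float),
                np.asarray(cohort.scores, dtype=float))
    X, p, y = cohort
    return np.asarray(X, dtype=float), np.asarray(p, dtype=float), np.asarray(y, dtype=float)


@dataclass
class TrainedModel:
    """A fitted LEGNet: parameters plus the input/target-scale transforms.

    ``feature_mu``/``feature_sigma`` hold the entrywise connectivity
    standardization fitted on the training subjects (None when disabled);
    ``target_mu``/``target_sigma`` map standardized predictions back to the
    0–100 score scale.
    """

    params: LEGNetParams
    hp: HyperParams
    target_mu: float = 0.0
    target_sigma: float = 1.0
    feature_mu: Optional[np.ndarray] = None
    feature_sigma: Optional[np.ndarray] = None

    def _transform(self, X):
        if self.feature_mu is None:
            return X
        return (np.asarray(X, dtype=float) - self.feature_mu) / self.feature_sigma

    def predict(self, X, p):
        yhat, _ = forward_batch(self._transform(X), p, self.params, self.hp)
        return self.target_mu + self.target_sigma * yhat

    def assignment_scores(self, X, p):
        _, S = forward_batch(self._transform(X), p, self.params, self.hp)
        return S

    def save(self, path):
        meta = {"target_mu": self.target_mu, "target_sigma": self.target_sigma}
        if self.feature_mu is not None:
            meta["feature_mu"] = self.feature_mu.tolist()
            meta["feature_sigma"] = self.feature_sigma.tolist()
        save_checkpoint(path, self.params, self.hp, metadata=meta)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        params, hp, meta = load_checkpoint(path)
        fmu = meta.get("feature_mu")
        fsd = meta.get("feature_sigma")
        return cls(params=params, hp=hp,
                   target_mu=float(meta.get("target_mu", 0.0)),
                   target_sigma=float(meta.get("target_sigma", 1.0)),
                   feature_mu=None if fmu is None else np.array(fmu),
                   feature_sigma=None if fsd is None else np.array(fsd))


class _Adam:
    """Plain Adam over a LEGNetParams pytree."""

    def __init__(self, params: LEGNetParams, beta1=0.9, beta2=0.999, eps=1e-8):
        self.m = zeros_like_params(params)
        self.v = zeros_like_params(params)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0

    def step(self, params: LEGNetParams, grads: LEGNetParams, lr: float) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for name, gval in grads.arrays().items():
            m = getattr(self.m, name)
            v = getattr(self.v, name)
            m *= b1
            m += (1 - b1) * gval
            v *= b2
            v += (1 - b2) * gval ** 2
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            arr = getattr(params, name)
            arr -= lr * mhat / (np.sqrt(vhat) + self.eps)


def train(cohort, hp: HyperParams, tc: TrainConfig,
          init: Optional[LEGNetParams] = None):
    """Fit LEGNet on a cohort; returns (TrainedModel, history).

    ``init`` seeds the parameters (e.g. a pretrained checkpoint); otherwise a
    fresh random initialization is drawn from ``tc.seed``.  Early stopping
    monitors the validation MSE (a seeded 10% split of the training subjects)
    and the parameters achieving the best validation loss are restored.
    """
    X, p, y = _cohort_arrays(cohort)
    M, N = len(y), X.shape[1]
    if M < 1:
        raise ContractError("empty cohort")
    rng = np.random.default_rng(tc.seed)

    # validation split for early stopping
    n_val = int(round(tc.val_fraction * M)) if M >= 4 else 0
    perm = rng.permutation(M)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, ptr, ytr = X[tr_idx], p[tr_idx], y[tr_idx]
    Xval, pval, yval = X[val_idx], p[val_idx], y[val_idx]

    feat_mu = feat_sd = None
    if tc.standardize_inputs:
        feat_mu = Xtr.mean(axis=0)
        feat_sd = np.maximum(Xtr.std(axis=0), 1e-6)
        Xtr = (Xtr - feat_mu) / feat_sd
        if n_val:
            Xval = (Xval - feat_mu) / feat_sd

    if tc.standardize_targets:
        mu = float(ytr.mean())
        sigma = float(max(ytr.std(), 1e-8))
    else:
        mu, sigma = 0.0, 1.0
    ytr_s = (ytr - mu) / sigma
    yval_s = (yval - mu) / sigma

    if init is not None:
        params = init.copy()
    else:
        params = calibrated_init(Xtr, ptr, hp, seed=tc.seed, scale=tc.init_scale)
    params.validate_shapes(N, hp)
    opt = _Adam(params)
    history = {"train_loss": [], "val_loss": [], "lr": []}
    best_val = np.inf
    best_params = params.copy()
    stale = 0
    step = 0
    batch = tc.batch_size or len(tr_idx)

    for epoch in range(tc.max_epochs):
        order = rng.permutation(len(tr_idx)) if batch < len(tr_idx) else np.arange(len(tr_idx))
        epoch_losses = []
        for start in range(0, len(tr_idx), batch):
            sel = order[start:start + batch]
            lr = learning_rate_at(step, tc)
            value, grads = loss_and_grads(Xtr[sel], ptr[sel], ytr_s[sel], params, hp)
            if not np.isfinite(value):
                raise TrainingError(f"non-finite loss at epoch {epoch}", history)
            opt.step(params, grads, lr)
            step += 1
            epoch_losses.append(value)
            history["lr"].append(lr)
        history["train_loss"].append(float(np.mean(epoch_losses)))

        if n_val > 0:
            yhat_val, _ = forward_batch(Xval, pval, params, hp)
            val = float(np.mean((np.atleast_1d(yhat_val) - yval_s) ** 2))
        else:
            val = history["train_loss"][-1]
        history["val_loss"].append(val)
        if val < best_val - 1e-12:
            best_val = val
            best_params = params.copy()
            stale = 0
        else:
            stale += 1
            if stale >= tc.patience and epoch + 1 >= tc.min_epochs:
                break

    model = TrainedModel(params=best_params, hp=hp, target_mu=mu, target_sigma=sigma,
                         feature_mu=feat_mu, feature_sigma=feat_sd)
    return model, history


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CVPlan:
    """Repeated k-fold assignment, a pure function of (n_subjects, seed)."""

    n_folds: int = 10
    n_repeats: int = 1
    seed: int = 0

    def assignments(self, n_subjects: int) -> np.ndarray:
        """(n_repeats, n_subjects) array of fold ids in 0..n_folds-1."""
        if n_subjects < self.n_folds:
            raise ContractError(
                f"{n_subjects} subjects cannot fill {self.n_folds} folds")
        rng = np.random.default_rng(self.seed)
        out = np.empty((self.n_repeats, n_subjects), dtype=int)
        for rep in range(self.n_repeats):
            perm = rng.permutation(n_subjects)
            folds = np.array_split(perm, self.n_folds)
            for f, idx in enumerate(folds):
                out[rep, idx] = f
        return out


def kfold_cv(cohort, hp: HyperParams, tc: TrainConfig, plan: CVPlan,
             init: Optional[LEGNetParams] = None,
             collect_scores: bool = False):
    """Repeated k-fold cross-validation.

    Returns a DataFrame with one row per repeat × fold (rmse, mae, r2,
    pearson) — and, when ``collect_scores`` is set, a second value: the
    (n_repeats, M, N, k) array of test-time subgraph assignment scores.
    """
    X, p, y = _cohort_arrays(cohort)
    M = len(y)
    assign = plan.assignments(M)
    rows = []
    scores = None
    for rep in range(plan.n_repeats):
        for f in range(plan.n_folds):
            test = assign[rep] == f
            tr = ~test
            fold_tc = replace(tc, seed=tc.seed + 1000 * rep + f)
            model, _ = train((X[tr], p[tr], y[tr]), hp, fold_tc, init=init)
            yhat = np.atleast_1d(model.predict(X[test], p[test]))
            m = compute_metrics(y[test], yhat)
            rows.append({"repeat": rep, "fold": f, "n_test": int(test.sum()),
                         "rmse": m.rmse, "mae": m.mae, "r2": m.r2,
                         "pearson": m.pearson})
            if collect_scores:
                if scores is None:
                    k = hp.k
                    scores = np.zeros((plan.n_repeats, M, X.shape[1], k))
                scores[rep, test] = model.assignment_scores(X[test], p[test])
    table = pd.DataFrame(rows)
    return (table, scores) if collect_scores else table


def summarize_cv(table: pd.DataFrame) -> pd.DataFrame:
    """Mean ± sd per metric.

    With several repeats the sd is taken over repeat means (each repeat first
    averaged over folds); with one repeat it falls back to the sd over folds.
    """
    metrics_cols = ["rmse", "mae", "r2", "pearson"]
    per_rep = table.groupby("repeat")[metrics_cols].mean()
    if len(per_rep) > 1:
        mean, sd = per_rep.mean(), per_rep.std(ddof=1)
    else:
        mean, sd = table[metrics_cols].mean(), table[metrics_cols].std(ddof=1)
    return pd.DataFrame({"mean": mean, "sd": sd})


# ---------------------------------------------------------------------------
# two-stage grid search


def _default_evaluator(cohort, tc: TrainConfig, plan: CVPlan) -> Callable[[HyperParams], float]:
    def evaluate(hp: HyperParams) -> float:
        table = kfold_cv(cohort, hp, tc, plan)
        return float((table["rmse"] ** 2).mean())  # CV mean validation MSE
    return evaluate


def grid_search(cohort, tc: TrainConfig,
                search_widths: Sequence[str] = ("k", "d0", "d1", "d2", "d3"),
                coarse: Sequence[int] = (2, 4, 8, 16, 32, 64),
                lambdas: Sequence[float] = tuple(np.logspace(-4, 0, 9)),
                base_hp: HyperParams = HyperParams(),
                plan: Optional[CVPlan] = None,
                evaluator: Optional[Callable[[HyperParams], float]] = None,
                fine_span: int = 2):
    """Two-stage grid search over widths/k and the ridge weight.

    Stage 1 sweeps each searched width over the coarse powers of two
    (2..64); stage 2 refines within ±``fine_span`` of the stage-1 winner.
    λ is swept over a log grid spanning [1e-4, 1] in both stages.  Scores come
    from ``evaluator`` (default: CV mean validation MSE on ``cohort``); the
    arg-min configuration and the full score table are returned.
    """
    if not search_widths and not len(lambdas):
        raise ContractError("empty search space")
    evaluator = evaluator or _default_evaluator(cohort, tc, plan or CVPlan(n_folds=3))

    def sweep(candidates_per_param, stage):
        rows = []
        names = list(candidates_per_param)
        for combo in itertools.product(*(candidates_per_param[n] for n in names)):
            hp = replace(base_hp, **dict(zip(names, combo)))
            rows.append({"stage": stage, **hp.to_dict(), "score": evaluator(hp)})
        return pd.DataFrame(rows)

    space1 = {name: list(coarse) for name in search_widths}
    space1["lam"] = list(lambdas)
    t1 = sweep(space1, "coarse")
    best1 = t1.loc[t1["score"].idxmin()]

    space2 = {}
    for name in search_widths:
        center = int(best1[name])
        space2[name] = sorted({max(1, center + d) for d in range(-fine_span, fine_span + 1)})
    space2["lam"] = [float(best1["lam"])]
    t2 = sweep(space2, "fine")
    table = pd.concat([t1, t2], ignore_index=True)
    best = table.loc[table["score"].idxmin()]
    best_hp = replace(base_hp, **{n: int(best[n]) for n in search_widths},
                      lam=float(best["lam"]))
    return best_hp, table


# ---------------------------------------------------------------------------
# pretrain → fine-tune protocol


def pretrain_finetune(pretrain_cohort, target_cohort, hp: HyperParams,
                      tc: TrainConfig, plan: CVPlan):
    """Compare CV on the target cohort with and without pretrained initialization.

    Trains once on ``pretrain_cohort``, then runs ``kfold_cv`` on
    ``target_cohort`` twice — initialized from the pretrained parameters
    versus from scratch.  Returns (table with a ``condition`` column,
    pretrained TrainedModel).
    """
    Xp, _, _ = _cohort_arrays(pretrain_cohort)
    Xt, _, _ = _cohort_arrays(target_cohort)
    if Xp.shape[1] != Xt.shape[1]:
        raise ContractError("pretrain and target cohorts disagree on N")
    pretrained, _ = train(pretrain_cohort, hp, tc)
    t_pre = kfold_cv(target_cohort, hp, tc, plan, init=pretrained.params)
    t_scr = kfold_cv(target_cohort, hp, tc, plan, init=None)
    t_pre["condition"] = "pretrained"
    t_scr["condition"] = "scratch"
    return pd.concat([t_pre, t_scr], ignore_index=True), pretrained
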