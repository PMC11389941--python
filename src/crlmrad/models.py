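"""Survival models: random survival forest and a compact neural Cox model.

Two risk models are fit on patient-level feature vectors with
right-censored outcomes:

* **Random survival forest (RSF)** — bootstrap ensemble of survival trees
  split by the log-rank statistic; a patient's risk is the ensemble-mean
  cumulative hazard summed over the event-time grid.  Backed by
  scikit-survival's ``RandomSurvivalForest``.
* **Neural Cox model ("DeepSurv-44")** — a small multilayer perceptron,
  two blocks of [linear(4) -> batch-normalization -> ReLU -> dropout(0.1)]
  followed by a linear output, trained full-batch with Adam to minimize
  the Breslow-tie negative Cox partial log-likelihood.  Training stops at
  the lowest validation loss (an internal 15% split of the training
  data); the weight snapshot at that epoch is returned.  Implemented in
  NumPy: the cohorts involved are small and full-batch training keeps
  the partial-likelihood risk sets intact (mini-batching would truncate
  them).

Both models freeze train-set standardization constants and their input
catalog, so holdout scoring is deterministic and name-checked.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coxutils import cox_partial_loss
from .errors import EstimationError, ScoringError

logger = logging.getLogger(__name__)

__all__ = [
    "cox_partial_loss",
    "NeuralSurvConfig",
    "NeuralCoxModel",
    "fit_neural_surv",
    "RSFModel",
    "fit_rsf",
    "predict_risk",
    "attach_crs",
]


@dataclass(frozen=True)
class NeuralSurvConfig:
    """Hyperparameters of the neural Cox model.

    Defaults follow the compact two-block backbone: 4-node layers,
    0.1 dropout, Adam at learning rate 1e-5.  At that conservative rate
    Adam's per-epoch parameter displacement is of order the learning rate,
    so convergence needs a large epoch budget (default 100k) with
    early-stopping patience 20,000 epochs on the validation loss (long
    enough to ride out the batch-norm running-statistics transient); see
    the methods note.
    """

    block_widths: tuple[int, ...] = (4, 4)
    dropout: float = 0.1
    learning_rate: float = 1e-5
    max_epochs: int = 100_000
    patience: int = 20_000
    val_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if any(w < 1 for w in self.block_widths):
            raise ValueError("block widths must be >= 1")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.learning_rate < 0:
            raise ValueError("learning rate must be >= 0")
        if not 0 < self.val_fraction < 1:
            raise ValueError("val_fraction must be in (0, 1)")


def _check_features(X, catalog):
    if isinstance(X, pd.DataFrame):
        missing = [c for c in catalog if c not in X.columns]
        if missing:
            raise ScoringError(f"features missing for scoring: {missing}")
        arr = X[list(catalog)].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        if arr.shape[1] != len(catalog):
            raise ScoringError(
                f"expected {len(catalog)} features, got {arr.shape[1]}"
            )
    if arr.size == 0:
        raise ScoringError("empty feature row")
    if not np.all(np.isfinite(arr)):
        raise ScoringError("non-finite feature values")
    return arr


class NeuralCoxModel:
    """Trained neural Cox risk model (inference mode: dropout off, running BN stats)."""

    def __init__(self, params, bn_stats, mu, sd, catalog, config, history):
        self.params = params
        self.bn_stats = bn_stats  # per block: (running_mean, running_var)
        self.mu = mu
        self.sd = sd
        self.catalog = tuple(catalog)
        self.config = config
        self.history = history

    def predict_risk(self, X) -> np.ndarray:
        arr = _check_features(X, self.catalog)
        h = (arr - self.mu) / self.sd
        for b, _ in enumerate(self.config.block_widths):
            W, bias, gamma, beta = (self.params[f"W{b}"], self.params[f"b{b}"],
                                    self.params[f"g{b}"], self.params[f"be{b}"])
            z = h @ W + bias
            rm, rv = self.bn_stats[b]
            zn = (z - rm) / np.sqrt(rv + 1e-5)
            h = np.maximum(gamma * zn + beta, 0.0)
        out = h @ self.params["Wout"] + self.params["bout"]
        return out.ravel()

    def parameter_count(self) -> int:
        """Trainable affine parameters (linear weights + biases, BN scale/shift excluded)."""
        n_blocks = len(self.config.block_widths)
        keys = [f"W{b}" for b in range(n_blocks)] + [f"b{b}" for b in range(n_blocks)]
        keys += ["Wout", "bout"]
        return sum(self.params[k].size for k in keys)


def _init_params(rng, d_in, widths):
    params = {}
    prev = d_in
    for b, w in enumerate(widths):
        params[f"W{b}"] = rng.normal(0, np.sqrt(2.0 / prev), size=(prev, w))
        params[f"b{b}"] = np.zeros(w)
        params[f"g{b}"] = np.ones(w)
        params[f"be{b}"] = np.zeros(w)
        prev = w
    params["Wout"] = rng.normal(0, np.sqrt(1.0 / prev), size=(prev, 1))
    params["bout"] = np.zeros(1)
    return params


def _forward_train(params, X, widths, dropout, rng, bn_running, momentum=0.01):
    """Training-mode forward pass; returns scores and a cache for backprop."""
    cache = {"inputs": [], "z": [], "zn": [], "bn": [], "drop": [], "act": []}
    h = X
    for b, _ in enumerate(widths):
        W, bias, gamma = params[f"W{b}"], params[f"b{b}"], params[f"g{b}"]
        beta = params[f"be{b}"]
        z = h @ W + bias
        bmean = z.mean(axis=0)
        bvar = z.var(axis=0)
        rm, rv = bn_running[b]
        bn_running[b] = ((1 - momentum) * rm + momentum * bmean,
                         (1 - momentum) * rv + momentum * bvar)
        zn = (z - bmean) / np.sqrt(bvar + 1e-5)
        a_pre = gamma * zn + beta
        act = np.maximum(a_pre, 0.0)
        if dropout > 0:
            keep = (rng.random(act.shape) >= dropout) / (1 - dropout)
        else:
            keep = np.ones_like(act)
        cache["inputs"].append(h)
        cache["z"].append(z)
        cache["zn"].append(zn)
        cache["bn"].append((bmean, bvar))
        cache["act"].append(a_pre)
        cache["drop"].append(keep)
        h = act * keep
        cache.setdefault("h_out", []).append(h)
    scores = h @ params["Wout"] + params["bout"]
    cache["last_h"] = h
    return scores.ravel(), cache


def _cox_loss_grad(scores, time, event):
    """Gradient of the event-averaged Breslow negative log partial likelihood."""
    n = len(scores)
    order = np.argsort(-time, kind="stable")
    s = scores[order]
    t = time[order]
    e = event[order]
    smax = s.max()
    w = np.exp(s - smax)
    cumw = np.cumsum(w)
    idx = np.searchsorted(-t, -t, side="right") - 1
    # gradient: for each subject j, sum over events i with t_i <= t_j of w_j / S0_i
    inv_s0 = np.where(e, 1.0 / cumw[idx], 0.0)
    # subject j (position pj) belongs to risk set of event i iff pi >= ... in this
    # decreasing-time ordering subject at position p is in risk set of events at
    # positions q >= first index of the tie group containing... we need events i
    # with position qi such that risk set (0..idx_i) includes p, i.e. idx_i >= p
    csum = np.cumsum(inv_s0[::-1])[::-1]  # sum of 1/S0 over events at positions >= p
    # but events at positions q in [p, last tie of p] have idx_q >= p always since
    # idx_q >= q >= p; events before p (q < p) have idx_q <= idx_p... need care:
    # idx_q is the last index of q's tie group; for q < p with t_q == t_p,
    # idx_q >= p, so those events also include p. Handle by using tie-group starts.
    start = np.searchsorted(-t, -t, side="left")
    grad_s = csum[start] * w - e.astype(float)
    n_events = int(e.sum())
    grad = np.zeros(n)
    grad[order] = grad_s / n_events
    return grad


def _backward(params, cache, dscores, widths, dropout):
    grads = {}
    h = cache["last_h"]
    dscores = dscores[:, None]
    grads["Wout"] = h.T @ dscores
    grads["bout"] = dscores.sum(axis=0)
    dh = dscores @ params["Wout"].T
    for b in reversed(range(len(widths))):
        keep = cache["drop"][b]
        a_pre = cache["act"][b]
        dh = dh * keep
        dh = dh * (a_pre > 0)
        zn = cache["zn"][b]
        gamma = params[f"g{b}"]
        grads[f"g{b}"] = (dh * zn).sum(axis=0)
        grads[f"be{b}"] = dh.sum(axis=0)
        dzn = dh * gamma
        bmean, bvar = cache["bn"][b]
        z = cache["z"][b]
        m = z.shape[0]
        inv_std = 1.0 / np.sqrt(bvar + 1e-5)
        dvar = (dzn * (z - bmean) * -0.5 * inv_std**3).sum(axis=0)
        dmean = (-dzn * inv_std).sum(axis=0) + dvar * (-2.0 * (z - bmean)).mean(axis=0)
        dz = dzn * inv_std + dvar * 2.0 * (z - bmean) / m + dmean / m
        x_in = cache["inputs"][b]
        grads[f"W{b}"] = x_in.T @ dz
        grads[f"b{b}"] = dz.sum(axis=0)
        dh = dz @ params[f"W{b}"].T
    return grads


def fit_neural_surv(
    features,
    time,
    event,
    config: NeuralSurvConfig = NeuralSurvConfig(),
) -> NeuralCoxModel:
    """Train the neural Cox model; returns the snapshot at minimum validation loss.

    Inputs are standardized with train-split statistics (frozen for later
    scoring).  The validation split is ``val_fraction`` of the rows; splits
    whose fit or validation portion is eventless are redrawn a bounded
    number of times before failing.  A fit whose validation loss never
    improves on the initialization (a pathological split/init draw on a
    small validation set) is retried with a derived seed, up to three
    attempts (logged); the last attempt is returned regardless.
    """
    if isinstance(features, pd.DataFrame):
        catalog = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        catalog = tuple(f"x{i}" for i in range(X.shape[1]))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if not event.any():
        raise EstimationError("cannot train with zero events")
    for attempt in range(3):
        model = _fit_neural_once(X, time, event, config, catalog, attempt)
        if model.history["best_epoch"] > 0 or config.learning_rate == 0.0:
            return model
        logger.warning(
            "validation loss never improved on initialization (attempt %d); "
            "redrawing validation split and init", attempt + 1,
        )
    return model


def _fit_neural_once(X, time, event, config, catalog, attempt):
    n, d = X.shape
    rng = np.random.default_rng([config.seed, attempt])
    n_val = max(1, int(round(config.val_fraction * n)))
    for _ in range(50):
        perm = rng.permutation(n)
        val_idx, fit_idx = perm[:n_val], perm[n_val:]
        if event[val_idx].any() and event[fit_idx].any():
            break
    else:
        raise EstimationError("could not draw a validation split containing events")

    mu = X[fit_idx].mean(axis=0)
    sd = X[fit_idx].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    Xf, Xv = Xs[fit_idx], Xs[val_idx]
    tf_, tv = time[fit_idx], time[val_idx]
    ef, ev = event[fit_idx], event[val_idx]

    widths = config.block_widths
    params = _init_params(rng, d, widths)
    bn_running = [(np.zeros(w), np.ones(w)) for w in widths]
    mstate = {k: np.zeros_like(v) for k, v in params.items()}
    vstate = {k: np.zeros_like(v) for k, v in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8

    def eval_loss(p, stats, Xe, te, ee):
        h = Xe
        for b, _ in enumerate(widths):
            z = h @ p[f"W{b}"] + p[f"b{b}"]
            rm, rv = stats[b]
            zn = (z - rm) / np.sqrt(rv + 1e-5)
            h = np.maximum(p[f"g{b}"] * zn + p[f"be{b}"], 0.0)
        s = (h @ p["Wout"] + p["bout"]).ravel()
        return cox_partial_loss(s, te, ee)

    best = {k: v.copy() for k, v in params.items()}
    best_stats = [tuple(a.copy() for a in s) for s in bn_running]
    best_loss = np.inf
    best_epoch = 0
    history = {"train_loss": [], "val_loss": []}
    for epoch in range(config.max_epochs):
        scores, cache = _forward_train(params, Xf, widths, config.dropout, rng, bn_running)
        dscores = _cox_loss_grad(scores, tf_, ef)
        grads = _backward(params, cache, dscores, widths, config.dropout)
        t_adam = epoch + 1
        for k in params:
            g = grads[k]
            mstate[k] = beta1 * mstate[k] + (1 - beta1) * g
            vstate[k] = beta2 * vstate[k] + (1 - beta2) * g * g
            mhat = mstate[k] / (1 - beta1**t_adam)
            vhat = vstate[k] / (1 - beta2**t_adam)
            params[k] = params[k] - config.learning_rate * mhat / (np.sqrt(vhat) + eps)
        if epoch % 10 == 0 or epoch == config.max_epochs - 1:
            vl = eval_loss(params, bn_running, Xv, tv, ev)
            history["val_loss"].append((epoch, vl))
            history["train_loss"].append(
                (epoch, eval_loss(params, bn_running, Xf, tf_, ef))
            )
            if vl < best_loss - 1e-9:
                best_loss = vl
                best_epoch = epoch
                best = {k: v.copy() for k, v in params.items()}
                best_stats = [tuple(a.copy() for a in s) for s in bn_running]
            elif epoch - best_epoch > config.patience:
                break
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_loss)
    history["best_train_loss"] = float(eval_loss(best, best_stats, Xf, tf_, ef))
    return NeuralCoxModel(best, best_stats, mu, sd, catalog, config, history)


class RSFModel:
    """Random survival forest wrapper carrying its input catalog and seed."""

    def __init__(self, forest, catalog, seed):
        self.forest = forest
        self.catalog = tuple(catalog)
        self.seed = seed

    def predict_risk(self, X) -> np.ndarray:
        arr = _check_features(X, self.catalog)
        return self.forest.predict(arr)


def fit_rsf(
    features,
    time,
    event,
    *,
    n_trees: int = 200,
    min_leaf: int = 5,
    seed: int = 0,
) -> RSFModel:
    """Fit a random survival forest (log-rank splits, sqrt-d feature sampling).

    Risk scores are the ensemble-mean Nelson-Aalen cumulative hazard summed
    over the training event-time grid (scikit-survival's ``predict``).
    """
    from sksurv.ensemble import RandomSurvivalForest

    if isinstance(features, pd.DataFrame):
        catalog = tuple(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.atleast_2d(np.asarray(features, dtype=float))
        catalog = tuple(f"x{i}" for i in range(X.shape[1]))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    if not event.any():
        raise EstimationError("cannot train with zero events")
    if min_leaf > len(time):
        raise ValueError("min_leaf exceeds the sample size")
    from sksurv.util import Surv

    y = Surv.from_arrays(event=event, time=time)
    forest = RandomSurvivalForest(
        n_estimators=n_trees,
        min_samples_leaf=min_leaf,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return RSFModel(forest, catalog, seed)


def predict_risk(model, features) -> np.ndarray:
    """Per-patient risk scores (higher = higher predicted hazard)."""
    return model.predict_risk(features)


def save_model(model, path) -> None:
    """Serialize a fitted survival model to a versioned bundle.

    Writes ``<path>`` (joblib) plus a JSON manifest next to it carrying the
    model kind, input catalog, seed and package version, so a scored table
    can always be traced back to its model.
    """
    import json
    from pathlib import Path

    import joblib

    from . import __version__

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    joblib.dump(model, path)
    kind = "rsf" if isinstance(model, RSFModel) else "deepsurv"
    manifest = {
        "kind": kind,
        "catalog": list(model.catalog),
        "seed": getattr(model, "seed", getattr(getattr(model, "config", None), "seed", None)),
        "version": __version__,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=2))


def load_model(path):
    """Load a survival model bundle written by :func:`save_model`."""
    import joblib

    return joblib.load(path)


def attach_crs(features: pd.DataFrame, crs, *, encoding: str = "dichotomous") -> pd.DataFrame:
    """Append a CRS column to a patient-level feature table.

    ``crs`` maps patient index -> 'low'/'high' (dichotomous encoding, 0/1)
    or -> integer score 0-5 (``encoding='raw'``).  Missing patients raise.
    """
    crs = pd.Series(crs)
    missing = [i for i in features.index if i not in crs.index]
    if missing:
        raise ScoringError(f"CRS missing for patients: {missing}")
    aligned = crs.reindex(features.index)
    if encoding == "dichotomous":
        col = aligned.map({"low": 0.0, "high": 1.0})
        if col.isna().any():
            raise ValueError("dichotomous encoding expects 'low'/'high' labels")
    elif encoding == "raw":
        col = aligned.astype(float)
        if ((col < 0) | (col > 5)).any():
            raise ValueError("raw CRS must lie in [0, 5]")
    else:
        raise ValueError(f"unknown CRS encoding {encoding!r}")
    out = features.copy()
    out["crs"] = col
    return out
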