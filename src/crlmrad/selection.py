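"""Feature-selection cascade and the radiomics signature.

The signature pipeline, run on the training partition only, is:

1. **MRMR** (minimum-redundancy maximum-relevance, difference criterion)
   ranks features against the event indicator and keeps the top ``k=50``.
   Relevance and redundancy are mutual information over quartile-
   discretized features.
2. **Univariate Cox filter**: a one-covariate proportional-hazards model
   per feature (Newton iteration, Breslow ties); only features whose
   training concordance index exceeds 0.53 survive.
3. **Lasso-Cox**: an L1-penalized Cox model over a decreasing penalty
   path; the penalty is chosen by 5-fold cross-validated partial
   likelihood; non-zero coefficients form the signature (reported on the
   original feature scale; features are standardized internally).

:func:`repeated_signature` reruns the cascade on 100 random 85% subsets
of the training set, records per-feature selection counts, and forms a
consensus signature from features selected in at least half the runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mutual_info_score

from .coxutils import cox_partial_loss, newton_cox_fit
from .errors import EstimationError, ScoringError
from .evaluate import concordance_index

logger = logging.getLogger(__name__)

__all__ = [
    "Signature",
    "SelectionTrace",
    "mrmr_select",
    "univariate_cox_filter",
    "lasso_cox",
    "repeated_signature",
    "signature_score",
    "run_cascade",
]


@dataclass(frozen=True)
class Signature:
    """A linear prognostic signature: named features with Cox coefficients."""

    terms: tuple[tuple[str, float], ...]
    provenance: dict = field(default_factory=dict, compare=False)

    def __post_init__(self):
        for name, coef in self.terms:
            if not np.isfinite(coef) or coef == 0.0:
                raise ValueError(f"signature coefficient for {name!r} must be finite and non-zero")

    @property
    def features(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.terms)

    def to_dict(self) -> dict[str, float]:
        return dict(self.terms)


@dataclass
class SelectionTrace:
    """Per-run selected features/coefficients and cross-run selection counts."""

    runs: pd.DataFrame  # columns: run, feature, coefficient
    n_runs: int

    @property
    def selection_counts(self) -> pd.Series:
        counts = self.runs.groupby("feature")["coefficient"].size().sort_values(ascending=False)
        if (counts > self.n_runs).any():  # defensive: a feature enters a run at most once
            raise AssertionError("selection count exceeds number of runs")
        return counts


def _quartile_bins(x: np.ndarray) -> np.ndarray:
    """Discretize a feature into (up to) 4 quantile bins; constants map to one bin."""
    edges = np.unique(np.quantile(x, [0.25, 0.5, 0.75]))
    return np.searchsorted(edges, x, side="left")


def mrmr_select(features: pd.DataFrame, target: np.ndarray, k: int) -> list[str]:
    """Greedy MRMR ranking (difference criterion) of length <= k.

    Relevance = MI(feature-quartiles, target); redundancy = mean MI with the
    already-selected set.  The first pick is the maximum-relevance feature;
    ties are broken by input column order.  Constant columns have zero
    relevance and are never picked while any feature has positive relevance.
    """
    if features.shape[1] < 2:
        raise ValueError("MRMR needs at least 2 candidate features")
    target = np.asarray(target)
    if len(target) != len(features):
        raise ValueError("target must be defined for every row")
    cols = list(features.columns)
    binned = {c: _quartile_bins(features[c].to_numpy(dtype=float)) for c in cols}
    relevance = {c: mutual_info_score(binned[c], target) for c in cols}
    selected: list[str] = []
    remaining = list(cols)
    red_sum = {c: 0.0 for c in cols}
    while remaining and len(selected) < k:
        if selected:
            scores = [relevance[c] - red_sum[c] / len(selected) for c in remaining]
        else:
            scores = [relevance[c] for c in remaining]
        best = remaining[int(np.argmax(scores))]  # argmax keeps first on ties
        selected.append(best)
        remaining.remove(best)
        for c in remaining:
            red_sum[c] += mutual_info_score(binned[c], binned[best])
    return selected


def univariate_cox_filter(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    threshold: float = 0.53,
) -> list[str]:
    """Keep features whose univariate Cox risk score has training C-index > threshold.

    One-covariate fits use Newton iteration with Breslow ties.  Features
    whose fit does not converge (e.g. perfect separation) are dropped with
    a warning rather than aborting the cascade.
    """
    event = np.asarray(event).astype(bool)
    if not event.any():
        raise EstimationError("univariate Cox filter needs at least one event")
    survivors = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            continue  # constant feature: no risk ordering
        xs = (x - x.mean()) / x.std()
        try:
            beta = newton_cox_fit(xs[:, None], time, event)
        except EstimationError as exc:
            warnings.warn(f"univariate Cox fit failed for {name!r} ({exc}); feature dropped")
            continue
        cidx = concordance_index(beta[0] * xs, time, event)
        if cidx > threshold:
            survivors.append(name)
    return survivors


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd, mu, sd


def _sksurv_y(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    return np.array(
        list(zip(np.asarray(event).astype(bool), np.asarray(time, dtype=float))),
        dtype=[("event", "?"), ("time", "<f8")],
    )


def lasso_cox(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    *,
    alphas: np.ndarray | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> Signature:
    """L1-penalized Cox signature with the penalty chosen by 5-fold CV.

    Features are standardized internally; returned coefficients are on the
    original feature scale.  ``alphas`` overrides the automatic penalty
    path; a path of a single value skips cross-validation.  An explicit
    penalty of 0 dispatches to the unpenalized Newton fit.  A penalty large
    enough to zero every coefficient yields an empty signature.
    """
    from sksurv.linear_model import CoxnetSurvivalAnalysis

    event = np.asarray(event).astype(bool)
    time = np.asarray(time, dtype=float)
    if not event.any():
        raise EstimationError("Lasso-Cox requires at least one event")
    names = list(features.columns)
    X = features.to_numpy(dtype=float)
    Xs, mu, sd = _standardize(X)

    if alphas is not None:
        alphas = np.sort(np.asarray(alphas, dtype=float))[::-1]
        if alphas[-1] == 0.0:
            beta_std = newton_cox_fit(Xs, time, event)
            coefs = beta_std / sd
            terms = tuple((n, float(c)) for n, c in zip(names, coefs) if c != 0.0)
            return Signature(terms, provenance={"penalty": 0.0, "solver": "newton"})

    model = CoxnetSurvivalAnalysis(
        l1_ratio=1.0, alphas=alphas, n_alphas=50, normalize=False, fit_baseline_model=False
    )
    y = _sksurv_y(time, event)
    try:
        model.fit(Xs, y)
    except Exception as exc:
        raise EstimationError(f"Lasso-Cox path fit failed: {exc}") from exc
    path = np.asarray(model.alphas_)

    if len(path) == 1:
        best_alpha = float(path[0])
    else:
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(time))
        folds = np.array_split(order, cv_folds)
        cv_loss = np.zeros(len(path))
        cv_valid = np.ones(len(path), dtype=bool)
        for fold in folds:
            test = np.zeros(len(time), dtype=bool)
            test[fold] = True
            if not event[~test].any() or not event[test].any():
                continue
            sub = CoxnetSurvivalAnalysis(
                l1_ratio=1.0, alphas=path, normalize=False, fit_baseline_model=False
            )
            try:
                sub.fit(Xs[~test], _sksurv_y(time[~test], event[~test]))
            except Exception:
                continue
            for ai, a in enumerate(path):
                try:
                    scores = sub.predict(Xs[test], alpha=a)
                    cv_loss[ai] += cox_partial_loss(scores, time[test], event[test])
                except Exception:
                    cv_valid[ai] = False
        cv_loss[~cv_valid] = np.inf
        best_alpha = float(path[int(np.argmin(cv_loss))])

    beta_std = model.coef_[:, np.argmin(np.abs(path - best_alpha))]
    coefs = beta_std / sd
    terms = tuple((n, float(c)) for n, c in zip(names, coefs) if c != 0.0)
    return Signature(
        terms,
        provenance={"penalty": best_alpha, "cv_folds": cv_folds, "seed": seed,
                    "path": path.tolist()},
    )


def signature_score(signature: Signature, features) -> float | np.ndarray:
    """Linear signature score: sum of coefficient x feature value.

    ``features`` may be a mapping, a pandas Series (one patient) or a
    DataFrame (one row per patient).  Missing features raise
    :class:`ScoringError` naming the offender.
    """
    if isinstance(features, pd.DataFrame):
        missing = [n for n in signature.features if n not in features.columns]
        if missing:
            raise ScoringError(f"features missing for scoring: {missing}")
        score = np.zeros(len(features))
        for name, coef in signature.terms:
            score = score + coef * features[name].to_numpy(dtype=float)
        return score
    get = features.get if hasattr(features, "get") else None
    total = 0.0
    for name, coef in signature.terms:
        val = get(name) if get is not None else None
        if val is None or (isinstance(val, float) and np.isnan(val)):
            raise ScoringError(f"feature {name!r} missing for scoring")
        total += coef * float(val)
    return total


def run_cascade(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    *,
    k: int = 50,
    cox_threshold: float = 0.53,
    seed: int = 0,
) -> tuple[Signature, list[str]]:
    """One full selection cascade: MRMR -> univariate Cox filter -> Lasso-Cox.

    Returns the signature and the list of features surviving the filter
    (the candidate set handed to the survival models).
    """
    ranked = mrmr_select(features, np.asarray(event).astype(int), k)
    surviving = univariate_cox_filter(features[ranked], time, event, cox_threshold)
    if not surviving:
        return Signature(()), []
    if len(surviving) == 1:
        # the L1 path needs >= 2 columns; a single survivor gets an unpenalized fit
        sig = lasso_cox(features[surviving], time, event, alphas=np.array([0.0]))
        return sig, surviving
    sig = lasso_cox(features[surviving], time, event, seed=seed)
    return sig, surviving


def repeated_signature(
    features: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    *,
    n_runs: int = 100,
    subsample: float = 0.85,
    k: int = 50,
    cox_threshold: float = 0.53,
    consensus_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[SelectionTrace, Signature]:
    """Repeat the cascade on random ``subsample`` fractions of the training set.

    Accepts the *training partition only* — the holdout never reaches this
    function.  Subsamples with zero events are redrawn (logged).  The
    consensus signature averages each feature's coefficient over the runs
    where it was selected, keeping features selected in at least
    ``consensus_fraction`` of runs.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    n = len(features)
    m = int(round(subsample * n))
    rng = np.random.default_rng(seed)
    rows = []
    for run in range(n_runs):
        for attempt in range(100):
            idx = rng.choice(n, size=m, replace=False)
            if event[idx].any():
                break
            logger.info("run %d: eventless subsample redrawn (attempt %d)", run, attempt + 1)
        else:
            raise EstimationError("could not draw a subsample containing events")
        sig, _ = run_cascade(
            features.iloc[idx], time[idx], event[idx],
            k=k, cox_threshold=cox_threshold, seed=int(rng.integers(2**31)),
        )
        for name, coef in sig.terms:
            rows.append({"run": run, "feature": name, "coefficient": coef})
    trace = SelectionTrace(
        runs=pd.DataFrame(rows, columns=["run", "feature", "coefficient"]), n_runs=n_runs
    )
    counts = trace.selection_counts
    keep = counts[counts >= consensus_fraction * n_runs].index
    terms = []
    for name in keep:
        coef = trace.runs.loc[trace.runs["feature"] == name, "coefficient"].mean()
        if coef != 0.0 and np.isfinite(coef):
            terms.append((name, float(coef)))
    consensus = Signature(
        tuple(terms),
        provenance={
            "n_runs": n_runs, "subsample": subsample, "seed": seed,
            "consensus_fraction": consensus_fraction,
            "selection_counts": counts.to_dict(),
        },
    )
    return trace, consensus
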