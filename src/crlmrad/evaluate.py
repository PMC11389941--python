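"""Splitting, metrics, two-stage classification and the repeated-split experiment.

Survival performance is Harrell's concordance index: over pairs that are
comparable under right censoring (the earlier time is an event), the
fraction in which the higher risk score belongs to the earlier event,
with half credit for score ties.  Classification performance is ROC AUC
after landmark dichotomization of the outcome (recurrence by 18 months
for TTR, death by 36 months for DSS); patients censored before the
horizon have indeterminate status and are excluded.  Confidence
intervals are percentile bootstrap (default 2,000 resamples).

:func:`run_experiment` orchestrates the full design: one stratified 15%
holdout, then per training subsample (85%, repeated) the selection
cascade, survival model fits with and without the clinical risk score,
holdout scoring, and metric aggregation across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, UndefinedMetricError

logger = logging.getLogger(__name__)

__all__ = [
    "SplitPlan",
    "EvalReport",
    "stratified_holdout",
    "concordance_index",
    "dichotomize_outcome",
    "fit_score_classifier",
    "fit_direct_classifier",
    "roc_auc",
    "bootstrap_ci",
    "run_experiment",
    "ExperimentConfig",
]


@dataclass(frozen=True)
class SplitPlan:
    """Reproducible holdout + repeated training-subsample indices."""

    holdout_idx: np.ndarray
    train_idx: np.ndarray
    run_subsamples: tuple[np.ndarray, ...]
    seed: int

    def __post_init__(self):
        hold = set(self.holdout_idx.tolist())
        if hold & set(self.train_idx.tolist()):
            raise AssertionError("holdout and training indices overlap")
        for r, sub in enumerate(self.run_subsamples):
            if hold & set(sub.tolist()):
                raise AssertionError(f"holdout indices leak into run {r} subsample")


def stratified_holdout(
    event: np.ndarray,
    fraction: float = 0.15,
    seed: int = 0,
    *,
    n_runs: int = 0,
    subsample: float = 0.85,
) -> SplitPlan:
    """Draw a holdout of ``round(fraction * n)`` patients, stratified on the event flag.

    Stratification keeps the holdout event ratio within 1/holdout_size of
    the cohort's.  When ``n_runs > 0`` the plan also carries that many
    random ``subsample`` fractions of the training remainder (eventless
    subsamples redrawn).
    """
    event = np.asarray(event).astype(bool)
    n = len(event)
    n_hold = int(round(fraction * n))
    if n_hold < 1 or n_hold >= n:
        raise ValueError("holdout fraction leaves an empty partition")
    if event.sum() < 2 or (~event).sum() < 2:
        raise EstimationError("too few events/censored records to stratify")
    rng = np.random.default_rng(seed)
    # proportional allocation per stratum, remainder to the larger stratum
    idx_event = np.where(event)[0]
    idx_cens = np.where(~event)[0]
    n_hold_event = int(round(n_hold * len(idx_event) / n))
    n_hold_event = min(max(n_hold_event, 1), n_hold - 1)
    hold = np.concatenate(
        [
            rng.choice(idx_event, size=n_hold_event, replace=False),
            rng.choice(idx_cens, size=n_hold - n_hold_event, replace=False),
        ]
    )
    hold = np.sort(hold)
    train = np.setdiff1d(np.arange(n), hold)
    subs = []
    m = int(round(subsample * len(train)))
    for _ in range(n_runs):
        for _attempt in range(100):
            s = np.sort(rng.choice(train, size=m, replace=False))
            if event[s].any():
                break
        else:
            raise EstimationError("could not draw a subsample containing events")
        subs.append(s)
    return SplitPlan(hold, train, tuple(subs), seed)


def concordance_index(scores, time, event) -> float:
    """Harrell's censoring-aware concordance index.

    A pair (i, j) is comparable iff the strictly earlier time is an event.
    Concordant = the earlier-event subject has the strictly higher score;
    score ties earn half credit.  Raises when no pair is comparable.
    """
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    ti = time[:, None]
    tj = time[None, :]
    comparable = (ti < tj) & event[:, None]  # i is the earlier event
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise UndefinedMetricError("no comparable pairs for the concordance index")
    si = scores[:, None]
    sj = scores[None, :]
    concordant = float(((si > sj) & comparable).sum())
    tied = float(((si == sj) & comparable).sum())
    return (concordant + 0.5 * tied) / n_comp


def dichotomize_outcome(time, event, horizon_months: float) -> np.ndarray:
    """Landmark labels: 1 = event by the horizon, 0 = event-free beyond it, -1 = excluded.

    A subject is positive iff the event occurred at time <= horizon,
    negative iff followed (event-free) strictly beyond the horizon, and
    excluded (indeterminate) when censored at or before it.
    """
    if not horizon_months > 0:
        raise ValueError("horizon must be positive")
    time = np.asarray(time, dtype=float)
    event = np.asarray(event).astype(bool)
    labels = np.full(len(time), -1, dtype=int)
    labels[event & (time <= horizon_months)] = 1
    labels[time > horizon_months] = 0
    return labels


def fit_score_classifier(scores: np.ndarray, labels: np.ndarray, crs: np.ndarray | None = None):
    """Logistic classifier on a survival risk score, optionally with CRS (1-2 inputs)."""
    from sklearn.linear_model import LogisticRegression

    X = np.asarray(scores, dtype=float)[:, None]
    if crs is not None:
        X = np.column_stack([X, np.asarray(crs, dtype=float)])
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise EstimationError("classifier fitting requires both classes")
    clf = LogisticRegression(C=1e6, max_iter=5000)  # effectively unpenalized ML
    clf.fit(X, labels)
    return clf


def fit_direct_classifier(
    features: pd.DataFrame, labels: np.ndarray, kind: str = "logistic", seed: int = 0
):
    """Baseline classifier straight on the cascade-selected feature columns."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise EstimationError("classifier fitting requires both classes")
    if kind == "logistic":
        from sklearn.linear_model import LogisticRegression

        clf = LogisticRegression(C=1e6, max_iter=5000)
    elif kind == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        clf = RandomForestClassifier(n_estimators=200, random_state=seed)
    else:
        raise ValueError(f"unknown classifier kind {kind!r}")
    clf.fit(np.asarray(features, dtype=float), labels)
    return clf


def roc_auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney rank statistic (ties get half credit)."""
    from sklearn.metrics import roc_auc_score

    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise UndefinedMetricError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def bootstrap_ci(
    metric_fn,
    data: tuple[np.ndarray, ...],
    n_boot: int = 2000,
    level: float = 0.95,
    seed: int = 0,
    max_redraw_factor: int = 10,
) -> tuple[float, float]:
    """Percentile bootstrap interval for ``metric_fn(*resampled data)``.

    ``data`` is a tuple of equal-length arrays resampled jointly (paired
    bootstrap).  Resamples on which the metric is undefined are redrawn and
    counted, up to ``max_redraw_factor * n_boot`` draws in total.
    """
    n = len(data[0])
    if n < 2:
        raise ValueError("bootstrap requires >= 2 records")
    rng = np.random.default_rng(seed)
    stats = []
    draws = 0
    limit = max_redraw_factor * n_boot
    while len(stats) < n_boot:
        if draws >= limit:
            raise UndefinedMetricError(
                f"metric undefined on too many bootstrap resamples ({draws} draws)"
            )
        idx = rng.integers(0, n, size=n)
        draws += 1
        try:
            stats.append(metric_fn(*(np.asarray(a)[idx] for a in data)))
        except UndefinedMetricError:
            continue
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# the repeated-split experiment


@dataclass(frozen=True)
class ExperimentConfig:
    """Design of the repeated-split evaluation experiment."""

    strategies: tuple[str, ...] = ("largest_only",)
    outcomes: tuple[str, ...] = ("ttr", "dss")
    models: tuple[str, ...] = ("rsf", "deepsurv")
    with_crs: tuple[bool, ...] = (False, True)
    n_runs: int = 100
    subsample: float = 0.85
    holdout_fraction: float = 0.15
    horizons: dict = field(default_factory=lambda: {"ttr": 18.0, "dss": 36.0})
    mrmr_k: int = 50
    cox_threshold: float = 0.53
    n_boot: int = 2000
    consensus_fraction: float = 0.5
    direct_classifiers: tuple[str, ...] = ()
    rsf_trees: int = 200
    rsf_min_leaf: int = 5
    neural_config: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class EvalReport:
    """Long-format metric table with bootstrap confidence bounds.

    One row per (outcome, strategy, model, crs flag, metric): the point
    estimate is the mean over runs; the CI is a percentile bootstrap over
    the per-run holdout metric values.  ``table`` additionally records
    ``n_runs`` (completed runs) and ``n_boot``.
    """

    table: pd.DataFrame
    per_run: pd.DataFrame
    config: ExperimentConfig

    def to_csv(self, path):
        self.table.to_csv(path, index=False)

    def to_json(self, path):
        self.table.to_json(path, orient="records", indent=2)


def _cohort_arrays(bundles, outcome):
    time = np.array([getattr(b, outcome).time for b in bundles])
    event = np.array([getattr(b, outcome).event for b in bundles])
    return time, event


def _crs_series(bundles):
    from .aggregation import dichotomize_crs, fong_crs

    return pd.Series(
        {b.patient_id: dichotomize_crs(fong_crs(b.profile)) for b in bundles}
    )


def run_experiment(bundles, config: ExperimentConfig = ExperimentConfig()) -> EvalReport:
    """Run the full repeated-split evaluation on a cohort.

    Per outcome: one stratified holdout; per run, the selection cascade is
    fit on the run's training subsample, survival models are fit on the
    surviving features (with and without CRS), and the holdout is scored.
    Metrics: holdout C-index per survival model, holdout AUC of the logistic
    classifier on the signature score and on each survival model's score
    (with/without CRS), plus optional direct-feature baselines.  Failed
    cells are recorded as NaN with the error logged, not fatal.
    """
    from .aggregation import aggregate_cohort

    rng = np.random.default_rng(config.seed)
    crs = _crs_series(bundles)
    agg_tables = {s: aggregate_cohort(bundles, s) for s in config.strategies}

    rows = []
    for outcome in config.outcomes:
        time, event = _cohort_arrays(bundles, outcome)
        horizon = config.horizons[outcome]
        plan = stratified_holdout(
            event,
            config.holdout_fraction,
            seed=int(rng.integers(2**31)),
            n_runs=config.n_runs,
            subsample=config.subsample,
        )
        hold = plan.holdout_idx
        hold_labels = dichotomize_outcome(time[hold], event[hold], horizon)
        for strategy, table in agg_tables.items():
            for run, sub in enumerate(plan.run_subsamples):
                # leakage audit: training subsamples never touch the holdout
                assert not set(sub.tolist()) & set(hold.tolist())
                run_seed = int(rng.integers(2**31))
                try:
                    rows.extend(
                        _run_one(
                            table, crs, time, event, sub, hold, hold_labels,
                            outcome, strategy, run, run_seed, horizon, config,
                        )
                    )
                except (EstimationError, UndefinedMetricError) as exc:
                    logger.warning(
                        "run %d (%s/%s) failed: %s", run, outcome, strategy, exc
                    )
                    rows.append(
                        {
                            "outcome": outcome, "strategy": strategy, "model": "all",
                            "crs": False, "metric": "error", "run": run,
                            "value": np.nan, "note": str(exc),
                        }
                    )
    per_run = pd.DataFrame(rows)
    table = _summarize(per_run, config)
    return EvalReport(table=table, per_run=per_run, config=config)


def _run_one(table, crs, time, event, sub, hold, hold_labels,
             outcome, strategy, run, run_seed, horizon, config):
    from .models import NeuralSurvConfig, attach_crs, fit_neural_surv, fit_rsf
    from .selection import run_cascade, signature_score

    out = []
    feats_train = table.iloc[sub]
    feats_hold = table.iloc[hold]
    crs01 = crs.map({"low": 0.0, "high": 1.0}).reindex(table.index).to_numpy(dtype=float)
    t_tr, e_tr = time[sub], event[sub]
    t_ho, e_ho = time[hold], event[hold]

    sig, surviving = run_cascade(
        feats_train, t_tr, e_tr,
        k=config.mrmr_k, cox_threshold=config.cox_threshold, seed=run_seed,
    )
    if not surviving:
        raise EstimationError("selection cascade retained no features")

    def emit(model, crs_flag, metric, value):
        out.append(
            {
                "outcome": outcome, "strategy": strategy, "model": model,
                "crs": crs_flag, "metric": metric, "run": run,
                "value": value, "note": "",
            }
        )

    # signature score (with the classification stage)
    sig_tr = signature_score(sig, feats_train) if sig.terms else np.zeros(len(sub))
    sig_ho = signature_score(sig, feats_hold) if sig.terms else np.zeros(len(hold))
    try:
        emit("signature", False, "cindex", concordance_index(sig_ho, t_ho, e_ho))
    except UndefinedMetricError:
        emit("signature", False, "cindex", np.nan)
    for sig_crs_flag in config.with_crs:
        _classify(emit, "signature", np.asarray(sig_tr), np.asarray(sig_ho), crs01,
                  sub, hold, time, event, hold_labels, horizon,
                  crs_in_classifier=sig_crs_flag)

    # survival models on the surviving feature set
    X_tr_base = feats_train[surviving]
    X_ho_base = feats_hold[surviving]
    for crs_flag in config.with_crs:
        if crs_flag:
            X_tr = attach_crs(X_tr_base, crs)
            X_ho = attach_crs(X_ho_base, crs)
        else:
            X_tr, X_ho = X_tr_base, X_ho_base
        for model_name in config.models:
            if model_name == "rsf":
                model = fit_rsf(
                    X_tr, t_tr, e_tr,
                    n_trees=config.rsf_trees, min_leaf=config.rsf_min_leaf,
                    seed=run_seed,
                )
            elif model_name == "deepsurv":
                ncfg = NeuralSurvConfig(**{**config.neural_config, "seed": run_seed})
                model = fit_neural_surv(X_tr, t_tr, e_tr, ncfg)
            else:
                raise ValueError(f"unknown survival model {model_name!r}")
            risk_tr = model.predict_risk(X_tr)
            risk_ho = model.predict_risk(X_ho)
            label = model_name
            try:
                emit(label, crs_flag, "cindex", concordance_index(risk_ho, t_ho, e_ho))
            except UndefinedMetricError:
                emit(label, crs_flag, "cindex", np.nan)
            _classify(emit, label, risk_tr, risk_ho, crs01, sub, hold,
                      time, event, hold_labels, horizon, crs_in_classifier=crs_flag)

    # direct-feature baselines
    for kind in config.direct_classifiers:
        tr_labels = dichotomize_outcome(time[sub], event[sub], horizon)
        tr_ok = tr_labels >= 0
        ho_ok = hold_labels >= 0
        if len(np.unique(tr_labels[tr_ok])) < 2 or len(np.unique(hold_labels[ho_ok])) < 2:
            emit(f"direct_{kind}", False, "auc", np.nan)
            continue
        clf = fit_direct_classifier(X_tr_base.iloc[tr_ok], tr_labels[tr_ok],
                                    kind=kind, seed=run_seed)
        proba = clf.predict_proba(np.asarray(X_ho_base.iloc[ho_ok], dtype=float))[:, 1]
        emit(f"direct_{kind}", False, "auc", roc_auc(proba, hold_labels[ho_ok]))
    return out


def _classify(emit, model_label, score_tr, score_ho, crs01, sub, hold,
              time, event, hold_labels, horizon, crs_in_classifier=False):
    """Second-stage logistic classification of landmark labels from risk scores.

    Fits on the run's training subsample (landmark-labelled at the same
    horizon as the holdout) and reports holdout AUC, with and without the
    dichotomized CRS as a second classifier input.
    """
    tr_labels = dichotomize_outcome(time[sub], event[sub], horizon)
    tr_ok = tr_labels >= 0
    ho_ok = hold_labels >= 0
    if (
        len(np.unique(tr_labels[tr_ok])) < 2
        or len(np.unique(hold_labels[ho_ok])) < 2
    ):
        emit(model_label, crs_in_classifier, "auc", np.nan)
        return
    crs_tr = crs01[sub][tr_ok]
    crs_ho = crs01[hold][ho_ok]
    try:
        if crs_in_classifier:
            clf = fit_score_classifier(score_tr[tr_ok], tr_labels[tr_ok], crs=crs_tr)
            X_ho = np.column_stack([score_ho[ho_ok], crs_ho])
        else:
            clf = fit_score_classifier(score_tr[tr_ok], tr_labels[tr_ok])
            X_ho = score_ho[ho_ok][:, None]
        proba = clf.predict_proba(X_ho)[:, 1]
        emit(model_label, crs_in_classifier, "auc", roc_auc(proba, hold_labels[ho_ok]))
    except (EstimationError, UndefinedMetricError) as exc:
        logger.debug("classification failed for %s: %s", model_label, exc)
        emit(model_label, crs_in_classifier, "auc", np.nan)


def _summarize(per_run: pd.DataFrame, config: ExperimentConfig) -> pd.DataFrame:
    """Aggregate per-run metrics into the long-format report with bootstrap CIs."""
    rows = []
    metrics = per_run[per_run["metric"] != "error"]
    for keys, grp in metrics.groupby(["outcome", "strategy", "model", "crs", "metric"]):
        vals = grp["value"].to_numpy(dtype=float)
        ok = np.isfinite(vals)
        n_ok = int(ok.sum())
        if n_ok == 0:
            point, lo, hi = np.nan, np.nan, np.nan
        elif n_ok == 1 or np.ptp(vals[ok]) == 0:
            point = float(np.mean(vals[ok]))
            lo = hi = point
        else:
            point = float(np.mean(vals[ok]))
            lo, hi = bootstrap_ci(
                lambda v: float(np.mean(v)), (vals[ok],),
                n_boot=config.n_boot, seed=config.seed,
            )
        rows.append(
            dict(
                zip(["outcome", "strategy", "model", "crs", "metric"], keys),
                estimate=point, ci_lo=lo, ci_hi=hi,
                n_runs=n_ok, n_boot=config.n_boot,
            )
        )
    return pd.DataFrame(rows)
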