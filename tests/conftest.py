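"""Shared fixtures: small synthetic cohorts and survival toy data."""

import numpy as np
import pandas as pd
import pytest

from crlmrad.synthetic import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120-patient cohort with 30 features, 3 informative (seed-fixed)."""
    cfg = SyntheticConfig(n_patients=120, n_features=30, seed=11)
    return generate_cohort(cfg), cfg


@pytest.fixture(scope="session")
def survival_frame():
    """200-row feature table with a planted 2-feature hazard signal."""
    rng = np.random.default_rng(7)
    n = 200
    X = pd.DataFrame(
        rng.standard_normal((n, 10)), columns=[f"f{i}" for i in range(10)]
    )
    lp = 0.8 * X["f0"].to_numpy() - 0.8 * X["f1"].to_numpy()
    latent = rng.exponential(1.0 / (0.06 * np.exp(lp)))
    censor = np.minimum(rng.exponential(1.0 / 0.03, n), 84.0)
    time = np.minimum(latent, censor)
    event = latent <= censor
    return X, time, event


def brute_force_cindex(scores, time, event):
    """Exhaustive pair-enumeration Harrell C (test oracle)."""
    num = den = 0.0
    n = len(scores)
    for i in range(n):
        for j in range(n):
            if time[i] < time[j] and event[i]:
                den += 1
                if scores[i] > scores[j]:
                    num += 1
                elif scores[i] == scores[j]:
                    num += 0.5
    if den == 0:
        raise ZeroDivisionError
    return num / den


def brute_force_auc(scores, labels):
    """Exhaustive positive/negative pair counting (test oracle)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    num = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                num += 1
            elif p == q:
                num += 0.5
    return num / (len(pos) * len(neg))


def brute_force_cox_loss(scores, time, event):
    """Explicit risk-set evaluation of the Breslow partial likelihood (oracle)."""
    import math

    total = 0.0
    n_events = 0
    for i in range(len(scores)):
        if not event[i]:
            continue
        n_events += 1
        risk = sum(math.exp(scores[j]) for j in range(len(scores)) if time[j] >= time[i])
        total += math.log(risk) - scores[i]
    return total / n_events
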