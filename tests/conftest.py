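"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (O(n·m) pair loops, exhaustive
threshold scans) and are kept separate from the package implementations
they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from glycoscreen.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A ~2000-subject synthetic cohort with its truth sidecar."""
    cfg = default_config(n=2000, seed=42)
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort with no missingness or self-report (for metric-level tests)."""
    import dataclasses

    cfg = dataclasses.replace(
        default_config(n=2000, seed=42),
        missing_hba1c_rate=0.0,
        missing_fpg_rate=0.0,
        missing_pg2h_rate=0.0,
        self_reported_diabetes_rate=0.0,
    )
    return generate_cohort(cfg)


def brute_auc(scores, disease, weights=None) -> float:
    """Pair-counting AUC: P(diseased outscores non-diseased), ties half."""
    s = np.asarray(scores, float)
    d = np.asarray(disease, bool)
    w = np.ones_like(s) if weights is None else np.asarray(weights, float)
    num = den = 0.0
    for i in np.flatnonzero(d):
        for j in np.flatnonzero(~d):
            psi = 1.0 if s[i] > s[j] else (0.5 if s[i] == s[j] else 0.0)
            num += w[i] * w[j] * psi
            den += w[i] * w[j]
    return num / den


def brute_roc_points(scores, disease, weights=None):
    """Operating points by exhaustive threshold enumeration (>= positivity).

    Returns {threshold: (tpr, fpr)} over all distinct scores.
    """
    s = np.asarray(scores, float)
    d = np.asarray(disease, bool)
    w = np.ones_like(s) if weights is None else np.asarray(weights, float)
    out = {}
    for t in np.unique(s):
        pos = s >= t
        out[float(t)] = (
            w[pos & d].sum() / w[d].sum(),
            w[pos & ~d].sum() / w[~d].sum(),
        )
    return out


def brute_delong(scores_a, scores_b, disease):
    """Placement-value DeLong test via explicit pair loops.

    Returns (auc_a, auc_b, var_diff, chi_square).
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    d = np.asarray(disease, bool)
    X = np.flatnonzero(d)
    Y = np.flatnonzero(~d)
    m, n = len(X), len(Y)

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    stats = []
    for s in (a, b):
        v10 = np.array([np.mean([psi(s[i], s[j]) for j in Y]) for i in X])
        v01 = np.array([np.mean([psi(s[i], s[j]) for i in X]) for j in Y])
        stats.append((v10, v01, v10.mean()))
    (v10a, v01a, auc_a), (v10b, v01b, auc_b) = stats
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    chi = (auc_a - auc_b) ** 2 / var if var > 0 else 0.0
    return auc_a, auc_b, var, chi
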