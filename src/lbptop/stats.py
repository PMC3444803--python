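"""Permutation-test and McNemar significance tests for classifiers.

The permutation test asks whether a classifier has learned real structure:
the full cross-validated pipeline is re-run on k datasets whose labels have
been randomly permuted, and

    p = (#{randomized error <= observed error} + 1) / (k + 1)

so the smallest attainable p is 1/(k+1) (1/101 at the default k = 100).
McNemar's test compares two classifiers evaluated on the same subjects
through their discordant predictions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar


@dataclass
class PermutationResult:
    p_value: float
    k: int
    observed_error: float
    randomized_errors: np.ndarray


def permutation_test(pipeline, X, y, k: int = 100, seed: int = 0) -> PermutationResult:
    """Permutation p-value for a cross-validated pipeline.

    ``pipeline(X, y)`` must run the full (deterministic) evaluation and
    return an object with an ``error`` attribute or a bare error float; the
    same CV plan must be used for the observed and randomized runs.  Labels
    are permuted (class balance preserved), not resampled.  Ties count as
    "randomized error <= observed", per the formula above.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    y = np.asarray(y)

    def _error(res):
        return float(getattr(res, "error", res))

    observed = _error(pipeline(X, y))
    rng = np.random.default_rng(seed)
    randomized = np.empty(k)
    for i in range(k):
        randomized[i] = _error(pipeline(X, y[rng.permutation(len(y))]))
    p = (int(np.sum(randomized <= observed)) + 1) / (k + 1)
    return PermutationResult(p_value=p, k=k, observed_error=observed,
                             randomized_errors=randomized)


@dataclass
class McNemarResult:
    p_value: float
    b: int  # a correct, b wrong
    c: int  # a wrong, b correct
    statistic: float
    exact: bool


def mcnemar_test(preds_a, preds_b, truth) -> McNemarResult:
    """McNemar's test on two prediction vectors over the same subjects.

    Only discordant counts matter: b = #(a right, b wrong), c = #(a wrong,
    b right).  The p-value is the exact two-sided binomial when b + c < 25,
    else the continuity-corrected chi-square on 1 df.  The reported
    ``statistic`` is always the corrected chi-square value
    (|b-c|-1)^2/(b+c), the usual summary of the discordance asymmetry.
    """
    preds_a, preds_b, truth = (np.asarray(v) for v in (preds_a, preds_b, truth))
    if not (len(preds_a) == len(preds_b) == len(truth)):
        raise ValueError("prediction and truth vectors must have equal length")
    a_ok, b_ok = preds_a == truth, preds_b == truth
    b = int(np.sum(a_ok & ~b_ok))
    c = int(np.sum(~a_ok & b_ok))
    if b + c == 0:
        return McNemarResult(p_value=1.0, b=0, c=0, statistic=0.0, exact=True)
    table = [[0, b], [c, 0]]
    exact = b + c < 25
    statistic = (abs(b - c) - 1) ** 2 / (b + c)
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return McNemarResult(p_value=float(res.pvalue), b=b, c=c,
                         statistic=statistic, exact=exact)
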