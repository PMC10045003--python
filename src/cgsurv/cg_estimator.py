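"""Copula-graphic and Kaplan-Meier survival estimators.

The copula-graphic (CG) estimator recovers a survival function S(t) from
right-censored data when the survival time T and the censoring time U are
dependent, with their dependence described by an assumed Archimedean
copula with generator ``phi_alpha``.  With at-risk counts ``Y(t_i)`` at
the event times of a sample of size n, the estimate is

    S_CG(t) = phi_inv( sum_{events t_i <= t} [ phi((Y(t_i) - 1) / n)
                                               - phi(Y(t_i) / n) ] ).

Under the independence generator ``phi(t) = -log t`` the sum telescopes
into the Kaplan-Meier product-limit estimator, so KM is the exact special
case of CG under independent censoring; with no censoring at all the sum
telescopes to ``phi(#survivors / n)`` and the curve is the empirical
survivor function for every generator.

Tied event times are processed sequentially, decrementing the at-risk
count by one per event; events precede censorings at the same time (the
product-limit convention), so same-time censored subjects stay in the
risk set for those events.  This is the unique tie rule under which the
alpha -> 0 limit reproduces KM exactly with ties present.
"""

from __future__ import annotations

import numpy as np

from .copulas import ArchimedeanCopula
from .survival_data import CensoredSample, StepSurvival

__all__ = ["cg_estimate", "km_estimate"]


def _event_terms(copula: ArchimedeanCopula, n: int) -> np.ndarray:
    """Generator-space increments by sorted position.

    ``terms[i] = phi((n-i-1)/n) - phi((n-i)/n)`` for the subject at sorted
    position i (0-based, events first at ties): with sequential decrement
    the at-risk count at position i is exactly n - i.  The last position
    carries phi(0) = inf, which drives the curve to exactly 0.
    """
    grid = np.asarray(copula.generator(np.arange(n + 1) / n))
    idx = n - 1 - np.arange(n)
    return grid[idx] - grid[idx + 1]


def _curve_arrays(
    time: np.ndarray,
    status: np.ndarray,
    copula: ArchimedeanCopula,
    terms: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Knots and values of the CG curve, as bare arrays.

    ``terms`` may be precomputed by :func:`_event_terms` (one allocation
    per (copula, group size), reused across permutations).
    """
    n = time.size
    order = np.lexsort((-status, time))
    t_sorted = time[order]
    ev = np.flatnonzero(status[order] == 1)
    if ev.size == 0:
        return np.empty(0), np.empty(0)
    if terms is None:
        terms = _event_terms(copula, n)
    values = np.asarray(copula.generator_inverse(np.cumsum(terms[ev])))
    knots = t_sorted[ev]
    keep = np.r_[knots[1:] != knots[:-1], True]  # last event of each tie group
    return knots[keep], np.minimum.accumulate(values[keep])


def cg_estimate(sample: CensoredSample, copula: ArchimedeanCopula) -> StepSurvival:
    """Copula-graphic survival estimate under an assumed copula.

    Jumps occur only at event times; censoring times only shrink the risk
    set.  If the at-risk count after an event reaches zero the curve is
    exactly 0 from that time on.

    Parameters
    ----------
    sample
        Right-censored sample (need not be sorted).
    copula
        Assumed dependence between survival and censoring; the
        independence copula yields the Kaplan-Meier estimate exactly.
    """
    if len(sample) == 0:
        raise ValueError("cannot estimate a survival curve from an empty sample")
    knots, values = _curve_arrays(sample.time, sample.status, copula)
    return StepSurvival(knots=knots, values=values)


def km_estimate(sample: CensoredSample) -> StepSurvival:
    """Kaplan-Meier product-limit estimate.

    Equals ``cg_estimate(sample, independence)`` exactly: the product over
    sequential single-event factors (1 - 1/Y) collapses to the standard
    (1 - d/Y) tie factor.
    """
    if len(sample) == 0:
        raise ValueError("cannot estimate a survival curve from an empty sample")
    srt = sample.sorted_by_time()
    n = len(srt)
    knots: list[float] = []
    values: list[float] = []
    surv = 1.0
    at_risk = n
    i = 0
    while i < n:
        t = srt.time[i]
        j = i
        while j < n and srt.time[j] == t:
            j += 1
        d = int(srt.status[i:j].sum())
        if d:
            # sequential single-event form, matching the CG convention
            for k in range(d):
                surv *= 1.0 - 1.0 / (at_risk - k)
            knots.append(float(t))
            values.append(surv)
        at_risk -= j - i
        i = j
    return StepSurvival(knots=np.asarray(knots), values=np.asarray(values))
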