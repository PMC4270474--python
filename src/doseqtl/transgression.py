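"""Resampling test for transgressive segregation.

Segregant phenotypes more extreme than either parent indicate alleles of
opposing effect hidden in the parents.  The statistic counts segregants
more than k pooled parental standard deviations above the high-parent
mean or below the low-parent mean.  The null model pools all parent
replicates and segregant values; each resample redraws null parents
(matching the original replicate counts) and null segregants with
replacement from the pool and recomputes the count.  The empirical
p-value uses the add-one convention p = (1 + #{null >= observed}) / (R + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateParentsError, InsufficientDataError

__all__ = ["TransgressionResult", "transgression_test", "transgression_count"]


@dataclass(frozen=True)
class TransgressionResult:
    """Observed transgression counts and resampling p-value."""

    n_above_high: int
    n_below_low: int
    n_segregants: int
    p_value: float
    resamples: int
    k_sd: float
    seed: int

    @property
    def count(self) -> int:
        return self.n_above_high + self.n_below_low


def _counts(parent_a, parent_b, segregants, k_sd):
    mean_a, mean_b = parent_a.mean(), parent_b.mean()
    pooled_var = (parent_a.var(ddof=1) + parent_b.var(ddof=1)) / 2.0
    sd = np.sqrt(pooled_var)
    high = max(mean_a, mean_b) + k_sd * sd
    low = min(mean_a, mean_b) - k_sd * sd
    return int((segregants > high).sum()), int((segregants < low).sum()), sd


def transgression_count(parent_a, parent_b, segregants, k_sd: float = 2.0):
    """(above, below) transgressive counts at k pooled-SD bounds."""
    a = np.asarray(parent_a, dtype=float)
    b = np.asarray(parent_b, dtype=float)
    s = np.asarray(segregants, dtype=float)
    above, below, _ = _counts(a, b, s, float(k_sd))
    return above, below


def transgression_test(
    parent_a_reps,
    parent_b_reps,
    segregant_values,
    k_sd: float = 2.0,
    resamples: int = 10_000,
    seed: int = 0,
    chunk: int = 2000,
) -> TransgressionResult:
    """Transgression count with a pooled-null resampling p-value."""
    a = np.asarray(parent_a_reps, dtype=float)
    b = np.asarray(parent_b_reps, dtype=float)
    s = np.asarray(segregant_values, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError("need >= 2 replicates per parent")
    if len(s) < 10:
        raise InsufficientDataError("need >= 10 segregants")
    above, below, sd = _counts(a, b, s, float(k_sd))
    if sd == 0:
        raise DegenerateParentsError("pooled parental variance is zero")
    observed = above + below

    pool = np.concatenate([a, b, s])
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 808]))
    R = int(resamples)
    exceed = 0
    for start in range(0, R, chunk):
        m = min(chunk, R - start)
        na = rng.choice(pool, size=(m, len(a)), replace=True)
        nb = rng.choice(pool, size=(m, len(b)), replace=True)
        ns = rng.choice(pool, size=(m, len(s)), replace=True)
        mean_a = na.mean(axis=1)
        mean_b = nb.mean(axis=1)
        pooled_sd = np.sqrt((na.var(axis=1, ddof=1) + nb.var(axis=1, ddof=1)) / 2.0)
        high = np.maximum(mean_a, mean_b) + k_sd * pooled_sd
        low = np.minimum(mean_a, mean_b) - k_sd * pooled_sd
        counts = (ns > high[:, None]).sum(axis=1) + (ns < low[:, None]).sum(axis=1)
        exceed += int((counts >= observed).sum())
    p = (1.0 + exceed) / (R + 1.0)
    return TransgressionResult(
        n_above_high=above,
        n_below_low=below,
        n_segregants=len(s),
        p_value=float(p),
        resamples=R,
        k_sd=float(k_sd),
        seed=int(seed),
    )
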