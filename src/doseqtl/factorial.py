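"""Factorial ANOVA of allele-replacement growth data.

Three biallelic gene factors (SWH1, MKT1, IRA2) are crossed with the
genetic background (BY or RM): 2^3 allele combinations in each background,
16 strains in all.  Fits use ordinary least squares with treatment
(reference-level) coding; the reference levels are MKT1 = RM, IRA2 = BY,
SWH1 = BY and background = BY, so coefficient labels read MKT1(BY),
IRA2(RM), SWH1(RM), BG(RM) and their products up to the highest-order
term.  Tukey-HSD pairwise comparisons use the studentized-range
distribution with the one-way pooled error (Tukey-Kramer SE for unequal
group sizes).
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import studentized_range

from .errors import AliasingError, InsufficientDataError, InvalidParameterError

__all__ = [
    "GENES",
    "REFERENCE_LEVELS",
    "fit_factorial_model",
    "tukey_hsd",
    "simulate_factorial_dataset",
    "rm_background_means",
]

GENES = ("MKT1", "IRA2", "SWH1")

#: Treatment-coding reference level per factor; the coefficient is named
#: after the non-reference allele, e.g. reference MKT1=RM -> term MKT1(BY).
REFERENCE_LEVELS = {"MKT1": "RM", "IRA2": "BY", "SWH1": "BY", "background": "BY"}

_LEVELS = ("BY", "RM")


def _indicator(series: pd.Series, factor: str) -> np.ndarray:
    """0/1 column: 1 when the allele is the non-reference level."""
    ref = REFERENCE_LEVELS[factor]
    vals = set(series.unique())
    if not vals <= set(_LEVELS):
        raise InvalidParameterError(f"{factor} levels must be BY/RM, got {vals}")
    return (series != ref).to_numpy(dtype=float)


def _term_label(factor: str) -> str:
    other = "BY" if REFERENCE_LEVELS[factor] == "RM" else "RM"
    return "BG(RM)" if factor == "background" else f"{factor}({other})"


def fit_factorial_model(
    data: pd.DataFrame,
    within_background: str | None = None,
    response: str = "growth",
) -> pd.DataFrame:
    """Full-factorial OLS coefficient table (term, estimate, se, t, p).

    With ``within_background`` the data are filtered to one background and
    the model is the saturated 2^3 factorial over the three genes.  Without
    it, background enters as a fourth two-level factor with all
    interactions (the pooled, background-crossed model).
    """
    df = data
    if within_background is not None:
        if within_background not in _LEVELS:
            raise InvalidParameterError("background must be 'BY' or 'RM'")
        df = df[df["background"] == within_background]
    if df.empty:
        raise InsufficientDataError("no records after background filtering")
    factors = list(GENES) + ([] if within_background else ["background"])

    # every factorial cell must be populated, else the term is inestimable
    observed = set(map(tuple, df[factors].itertuples(index=False)))
    for cell in product(_LEVELS, repeat=len(factors)):
        if cell not in observed:
            missing = ", ".join(f"{f}={v}" for f, v in zip(factors, cell))
            raise AliasingError(f"empty design cell ({missing}) aliases its terms")

    cols = {f: _indicator(df[f], f) for f in factors}
    names = ["(Intercept)"]
    X = [np.ones(len(df))]
    for order in range(1, len(factors) + 1):
        for combo in combinations(factors, order):
            col = np.ones(len(df))
            for f in combo:
                col = col * cols[f]
            X.append(col)
            names.append(":".join(_term_label(f) for f in combo))
    fit = sm.OLS(df[response].to_numpy(dtype=float), np.column_stack(X)).fit()
    return pd.DataFrame(
        {
            "term": names,
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )


def fitted_cell_means(coef_table: pd.DataFrame, factors: Sequence[str] = GENES) -> pd.DataFrame:
    """Reconstruct cell means from a saturated coefficient table."""
    est = dict(zip(coef_table["term"], coef_table["estimate"]))
    rows = []
    for cell in product(_LEVELS, repeat=len(factors)):
        mean = est["(Intercept)"]
        active = {
            _term_label(f)
            for f, v in zip(factors, cell)
            if v != REFERENCE_LEVELS[f]
        }
        for term, value in est.items():
            parts = set(term.split(":"))
            if term != "(Intercept)" and parts <= active:
                mean += value
        rows.append(dict(zip(factors, cell), fitted_mean=mean))
    return pd.DataFrame(rows)


def tukey_hsd(
    data: pd.DataFrame,
    grouping: str | Sequence[str],
    response: str = "growth",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise group comparisons with studentized-range adjustment.

    Groups are the observed combinations of ``grouping`` columns (joined
    with ':').  Adjusted p-values and simultaneous confidence intervals use
    q = |diff| / SE with SE = sqrt(MSE/2 * (1/n_i + 1/n_j)).
    """
    cols = [grouping] if isinstance(grouping, str) else list(grouping)
    labels = data[cols].astype(str).agg(":".join, axis=1)
    y = data[response].to_numpy(dtype=float)
    groups = labels.unique()
    k = len(groups)
    if k < 2:
        raise InsufficientDataError("need >= 2 groups to compare")
    stats = {}
    for g in groups:
        v = y[labels == g]
        if len(v) < 2:
            raise InsufficientDataError(f"group {g} has < 2 replicates")
        stats[g] = (len(v), v.mean(), v.var(ddof=1))
    N = sum(n for n, _, _ in stats.values())
    dof = N - k
    mse = sum((n - 1) * var for n, _, var in stats.values()) / dof
    rows = []
    qcrit = studentized_range.ppf(1 - alpha, k, dof)
    for g1, g2 in combinations(groups, 2):
        n1, m1, _ = stats[g1]
        n2, m2, _ = stats[g2]
        diff = m2 - m1
        se = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
        if se == 0:
            padj, lo, hi = (1.0, 0.0, 0.0) if diff == 0 else (0.0, diff, diff)
        else:
            q = abs(diff) / se
            padj = float(studentized_range.sf(q, k, dof))
            lo, hi = diff - qcrit * se, diff + qcrit * se
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "diff": diff,
                "se": se,
                "p_adj": min(1.0, padj),
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows)


def rm_background_means(
    background: str, mkt1: str, ira2: str, swh1: str
) -> float:
    """Cell-mean surface emulating the engineered-strain growth pattern.

    In the RM background the MKT1(BY):SWH1(RM) product dominates, with
    smaller MKT1(BY):IRA2(RM) and IRA2(RM):SWH1(RM) interactions; in the
    BY background effects are additive and interactions absent.
    """
    m = 1.0 if mkt1 == "BY" else 0.0
    i = 1.0 if ira2 == "RM" else 0.0
    s = 1.0 if swh1 == "RM" else 0.0
    if background == "RM":
        return (
            0.40 - 0.12 * m - 0.32 * i - 0.28 * s
            + 0.25 * m * i + 0.77 * m * s + 0.27 * i * s + 0.08 * m * i * s
        )
    return 0.80 + 0.05 * m + 0.04 * i + 0.10 * s



def simulate_factorial_dataset(
    mean_fn: Callable[[str, str, str, str], float] = rm_background_means,
    n_replicates: int = 36,
    noise_sd: float = 0.18,  # replicate SD implied by coefficient SEs at r = 36
    seed: int = 0,
    backgrounds: Sequence[str] = _LEVELS,
) -> pd.DataFrame:
    """Replicated 2^3 x background factorial growth dataset.

    ``mean_fn(background, mkt1, ira2, swh1)`` gives each cell's mean;
    replicate noise is i.i.d. normal and growth is clamped at zero.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 909]))
    rows = []
    for bg in backgrounds:
        for mkt1, ira2, swh1 in product(_LEVELS, repeat=3):
            mu = mean_fn(bg, mkt1, ira2, swh1)
            noise = rng.normal(0.0, noise_sd, size=n_replicates) if noise_sd else 0.0
            growth = np.clip(mu + noise, 0.0, None)
            for r in range(1, n_replicates + 1):
                rows.append(
                    {
                        "background": bg,
                        "MKT1": mkt1,
                        "IRA2": ira2,
                        "SWH1": swh1,
                        "replicate": r,
                        "growth": float(growth[r - 1]) if noise_sd else float(mu),
                    }
                )
    return pd.DataFrame(rows)
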