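"""Signed QTL effect sizes, additive models, and pairwise epistasis scans.

Effect sizes come from regressing the segregant phenotype on the +/-1
allele code, so for balanced complete data the slope equals
(mean_BY - mean_RM) / 2 and a positive value means BY-allele carriers
grow better.  The joint additive model reports total R^2 and a
drop-one-locus table; the interaction scan tests every unordered pair of
detected loci with a product term, Bonferroni-corrects over the pairs
tested, and reports the extra variance explained (delta_var) when all
significant interaction terms join the additive model.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import f as f_dist

from .errors import (
    CollinearityError,
    DegenerateLocusError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "EffectEstimate",
    "AdditiveModelFit",
    "InteractionScanResult",
    "locus_effect_size",
    "additive_model",
    "interaction_scan",
]


@dataclass(frozen=True)
class EffectEstimate:
    """Signed additive effect of one locus at one dose."""

    locus: str
    effect: float  # phenotype units per allele unit; > 0 favours BY
    se: float
    dose: float | None = None


@dataclass(frozen=True)
class AdditiveModelFit:
    """Joint additive fit over detected loci."""

    r_squared: float
    coefficients: pd.Series  # indexed by locus label, plus "intercept"
    drop_one: pd.DataFrame  # locus, delta_r2, f_stat, p_value
    n: int


@dataclass(frozen=True)
class InteractionScanResult:
    """All-pairs epistasis scan over detected loci."""

    pairs: pd.DataFrame  # locus_i, locus_j, gamma, raw_p, corrected_p, significant
    n_pairs: int
    r2_additive: float
    r2_with_interactions: float

    @property
    def n_significant(self) -> int:
        return int(self.pairs["significant"].sum())

    @property
    def delta_var(self) -> float:
        """Extra variance fraction from significant interaction terms (>= 0)."""
        return max(0.0, self.r2_with_interactions - self.r2_additive)


def _align(phenotype, design: pd.DataFrame | np.ndarray):
    if isinstance(design, pd.DataFrame):
        names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = [f"locus{j + 1}" for j in range(X.shape[1])]
    if isinstance(phenotype, pd.Series):
        y = phenotype.to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    if len(y) != X.shape[0]:
        raise InvalidParameterError("phenotype and locus matrix must align by strain")
    return y, X, names


def locus_effect_size(
    phenotype, genotype_column, locus: str = "locus", dose: float | None = None
) -> EffectEstimate:
    """OLS slope of phenotype on one +/-1 allele code, with its SE."""
    y, X, _ = _align(phenotype, np.asarray(genotype_column, dtype=float))
    g = X[:, 0]
    if np.ptp(g) == 0:
        raise DegenerateLocusError(f"locus {locus} is monomorphic")
    n = len(y)
    gc = g - g.mean()
    sxx = float(gc @ gc)
    b = float(gc @ (y - y.mean())) / sxx
    resid = y - y.mean() - b * gc
    dof = n - 2
    se = float(np.sqrt((resid @ resid) / dof / sxx)) if dof > 0 else np.nan
    return EffectEstimate(locus=locus, effect=b, se=se, dose=dose)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name the offending columns: perfectly correlated pairs first
        bad: list[str] = []
        C = np.corrcoef(X, rowvar=False)
        for i, j in combinations(range(X.shape[1]), 2):
            if abs(C[i, j]) > 1 - 1e-12:
                bad += [names[i], names[j]]
        raise CollinearityError(sorted(set(bad)) or names)


def additive_model(phenotype, peak_genotypes) -> AdditiveModelFit:
    """Joint OLS of phenotype on all detected-locus columns.

    Reports total R^2 and, per locus, the R^2 decrease and partial F-test
    p-value when that locus is removed from the model.
    """
    y, X, names = _align(phenotype, peak_genotypes)
    if X.shape[1] < 1:
        raise InsufficientDataError("need >= 1 locus")
    for j, name in enumerate(names):
        if np.ptp(X[:, j]) == 0:
            raise DegenerateLocusError(f"locus {name} is monomorphic")
    _check_rank(X, names)
    n, p = X.shape
    Xc = sm.add_constant(X)
    full = sm.OLS(y, Xc).fit()
    rss_full = float(full.ssr)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = float(full.rsquared) if tss > 0 else 0.0
    rows = []
    for j, name in enumerate(names):
        Xr = sm.add_constant(np.delete(X, j, axis=1))
        red = sm.OLS(y, Xr).fit()
        rss_red = float(red.ssr)
        dof = n - p - 1
        f = (rss_red - rss_full) / (rss_full / dof) if rss_full > 0 else np.inf
        pval = float(f_dist.sf(f, 1, dof)) if np.isfinite(f) else 0.0
        rows.append(
            {
                "locus": name,
                "delta_r2": max(0.0, (rss_red - rss_full) / tss) if tss > 0 else 0.0,
                "f_stat": f,
                "p_value": pval,
            }
        )
    coefs = pd.Series(full.params, index=["intercept"] + names)
    return AdditiveModelFit(
        r_squared=r2, coefficients=coefs, drop_one=pd.DataFrame(rows), n=n
    )


def interaction_scan(
    phenotype, peak_genotypes, corrected_alpha: float = 0.005
) -> InteractionScanResult:
    """Test every unordered locus pair for epistasis.

    Each pair (i, j) is fit as y ~ g_i + g_j + g_i*g_j; the raw p-value is
    the partial F-test (equivalently squared-t test) of the product term.
    Bonferroni correction multiplies by the number of pairs tested.
    delta_var compares the all-loci additive model with the same model
    plus every significant product term.
    """
    y, X, names = _align(phenotype, peak_genotypes)
    if X.shape[1] < 2:
        raise InsufficientDataError("need >= 2 loci for an interaction scan")
    _check_rank(X, names)
    n = len(y)
    pairs = list(combinations(range(X.shape[1]), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        prod = X[:, i] * X[:, j]
        D = sm.add_constant(np.column_stack([X[:, i], X[:, j], prod]))
        if np.linalg.matrix_rank(D) < D.shape[1]:
            gamma, raw = np.nan, 1.0  # product aliased with main effects
        else:
            fit = sm.OLS(y, D).fit()
            gamma = float(fit.params[3])
            raw = float(fit.pvalues[3])
            scale = float(np.std(y)) + 1e-30
            if abs(gamma) < 1e-10 * scale:  # numerically zero coefficient
                gamma, raw = 0.0, 1.0
            elif not np.isfinite(raw):  # zero-residual fit, exact interaction
                raw = 0.0
        corrected = min(1.0, raw * m)
        rows.append(
            {
                "locus_i": names[i],
                "locus_j": names[j],
                "gamma": gamma,
                "raw_p": raw,
                "corrected_p": corrected,
                "significant": corrected < corrected_alpha,
            }
        )
    table = pd.DataFrame(rows)
    r2_add = additive_model(y, pd.DataFrame(X, columns=names)).r_squared
    sig = table[table["significant"]]
    if len(sig):
        name_idx = {nm: k for k, nm in enumerate(names)}
        extra = np.column_stack(
            [
                X[:, name_idx[a]] * X[:, name_idx[b]]
                for a, b in zip(sig["locus_i"], sig["locus_j"])
            ]
        )
        Xfull = np.column_stack([X, extra])
        fit = sm.OLS(y, sm.add_constant(Xfull)).fit()
        r2_full = float(fit.rsquared)
    else:
        r2_full = r2_add
    return InteractionScanResult(
        pairs=table, n_pairs=m, r2_additive=r2_add,
        r2_with_interactions=max(r2_full, r2_add),
    )
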