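"""Broad- and narrow-sense heritability.

Broad-sense H^2 comes from replicate agreement via one-way random-effects
expected mean squares: sigma^2_G = (MS_strain - MS_error) / r_bar with
r_bar the harmonic-mean replicate count, clamped at zero, and
H^2 = sigma^2_G / (sigma^2_G + sigma^2_error).

Narrow-sense h^2 comes from the additive mixed model y = mu + u + e with
u ~ N(0, sigma^2_A K), where K = G G' / M is the marker-based relatedness
matrix rescaled to unit mean diagonal.  The variance ratio is estimated
by maximizing the restricted likelihood over h^2 in [0, 1] using the
eigendecomposition of K (the EMMA device: one decomposition, then each
candidate h^2 costs O(n)).  Uncertainty for both estimators is a seeded
bootstrap over strains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .errors import (
    InsufficientDataError,
    InsufficientReplicationError,
    NumericalConditioningError,
)
from .simulate import GenotypeMatrix

__all__ = [
    "HeritabilityEstimate",
    "broad_sense_heritability",
    "narrow_sense_heritability",
    "kinship",
    "reml_h2",
]


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Point estimate (clamped to [0, 1]) with bootstrap SE and method tag."""

    estimate: float
    se: float
    method: str  # "broad" | "narrow"
    dose: float | None = None
    n_strains: int = 0
    sigma2_g: float = np.nan
    sigma2_e: float = np.nan

    def __post_init__(self):
        object.__setattr__(self, "estimate", float(np.clip(self.estimate, 0.0, 1.0)))


def _h2_from_summaries(n_i: np.ndarray, mean_i: np.ndarray, ss_i: np.ndarray):
    """H^2 from per-strain replicate count, mean and within-strain SS."""
    k = len(n_i)
    N = n_i.sum()
    grand = float((n_i * mean_i).sum() / N)
    ms_strain = float((n_i * (mean_i - grand) ** 2).sum() / (k - 1))
    ms_error = float(ss_i.sum() / (N - k))
    r_bar = k / (1.0 / n_i).sum()  # harmonic-mean replicate count
    sigma2_g = max(0.0, (ms_strain - ms_error) / r_bar)
    denom = sigma2_g + ms_error
    h2 = sigma2_g / denom if denom > 0 else 0.0
    return h2, sigma2_g, ms_error


def broad_sense_heritability(
    records: pd.DataFrame,
    dose: float | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
    min_strains: int = 30,
) -> HeritabilityEstimate:
    """H^2 from a replicated phenotype table at one dose."""
    tab = records
    if dose is not None:
        tab = tab[tab["dose_uM"] == float(dose)]
    if tab.empty:
        raise InsufficientDataError("no records at the requested dose")
    g = tab.groupby("strain")["radius"]
    n_i = g.size().to_numpy(dtype=float)
    if (n_i >= 2).sum() < min_strains:
        raise InsufficientReplicationError(
            f"need >= 2 replicates for >= {min_strains} strains"
        )
    keep = n_i >= 2
    mean_i = g.mean().to_numpy(dtype=float)[keep]
    ss_i = (g.var(ddof=1) * (g.size() - 1)).to_numpy(dtype=float)[keep]
    n_i = n_i[keep]
    h2, s2g, s2e = _h2_from_summaries(n_i, mean_i, ss_i)
    se = np.nan
    if n_bootstrap > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 606]))
        k = len(n_i)
        draws = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, k, size=k)
            draws[b] = _h2_from_summaries(n_i[idx], mean_i[idx], ss_i[idx])[0]
        se = float(draws.std(ddof=1))
    return HeritabilityEstimate(
        estimate=h2, se=se, method="broad", dose=dose,
        n_strains=len(n_i), sigma2_g=s2g, sigma2_e=s2e,
    )


def kinship(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """Marker-based relatedness K = G G' / M, rescaled to unit mean diagonal."""
    G = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    G = G.astype(float)
    K = G @ G.T / G.shape[1]
    d = np.mean(np.diag(K))
    if d <= 0:
        raise NumericalConditioningError("kinship diagonal is not positive")
    return K / d


def _reml_loglik(h2: float, d: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> float:
    lam = h2 * d + (1.0 - h2)
    lam = np.maximum(lam, 1e-10)
    w = 1.0 / lam
    sxx = float(w @ (xstar**2))
    mu = float(w @ (xstar * ystar)) / sxx
    r = ystar - mu * xstar
    n = len(d)
    sigma2 = float(w @ r**2) / (n - 1)
    return -0.5 * (
        (n - 1) * (np.log(sigma2) + 1.0) + float(np.log(lam).sum()) + np.log(sxx)
    )


def reml_h2(K_eigvals: np.ndarray, K_eigvecs: np.ndarray, y: np.ndarray):
    """Restricted-likelihood h^2 on a precomputed kinship eigendecomposition.

    Grid search on h^2 in [0, 1] (step 0.01) followed by bounded
    refinement around the best grid point.  Returns (h2, sigma2_total).
    """
    ystar = K_eigvecs.T @ y
    xstar = K_eigvecs.T @ np.ones_like(y)
    d = K_eigvals
    grid = np.linspace(0.0, 0.999, 101)
    ll = np.array([_reml_loglik(h, d, ystar, xstar) for h in grid])
    best = int(np.argmax(ll))
    lo = grid[max(0, best - 1)]
    hi = grid[min(len(grid) - 1, best + 1)]
    res = minimize_scalar(
        lambda h: -_reml_loglik(h, d, ystar, xstar),
        bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-6},
    )
    h2 = float(np.clip(res.x, 0.0, 1.0))
    lam = np.maximum(h2 * d + (1 - h2), 1e-10)
    w = 1.0 / lam
    mu = float(w @ (xstar * ystar)) / float(w @ xstar**2)
    sigma2_t = float(w @ (ystar - mu * xstar) ** 2) / (len(d) - 1)
    return h2, sigma2_t


def narrow_sense_heritability(
    genotypes: GenotypeMatrix,
    phenotype,
    dose: float | None = None,
    n_bootstrap: int = 200,
    seed: int = 0,
    _eig: tuple[np.ndarray, np.ndarray] | None = None,
) -> HeritabilityEstimate:
    """h^2 = sigma^2_A / (sigma^2_A + sigma^2_e) from genome-wide kinship REML.

    ``_eig`` lets callers reuse a precomputed eigendecomposition of the
    kinship matrix when scanning many phenotypes on one panel.
    """
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(genotypes.strains).to_numpy(dtype=float)
    else:
        y = np.asarray(phenotype, dtype=float)
    n = len(y)
    if n < 100:
        raise InsufficientDataError("need >= 100 strains for kinship REML")
    if genotypes.n_markers < 50:
        raise InsufficientDataError("need >= 50 markers for kinship REML")
    if _eig is None:
        K = kinship(genotypes)
        d, U = np.linalg.eigh(K)
        if d.min() < -1e-8 * max(1.0, d.max()):
            raise NumericalConditioningError("kinship matrix is not PSD")
        d = np.clip(d, 0.0, None)
    else:
        d, U = _eig
    h2, sigma2_t = reml_h2(d, U, y)
    se = np.nan
    if n_bootstrap > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 707]))
        G = genotypes.codes.astype(float)
        draws = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, size=n)
            Kb = kinship(G[idx])
            db, Ub = np.linalg.eigh(Kb)
            draws[b] = reml_h2(np.clip(db, 0, None), Ub, y[idx])[0]
        se = float(draws.std(ddof=1))
    return HeritabilityEstimate(
        estimate=h2, se=se, method="narrow", dose=dose,
        n_strains=n, sigma2_g=h2 * sigma2_t, sigma2_e=(1 - h2) * sigma2_t,
    )
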