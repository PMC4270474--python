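"""Single-marker LOD scans, permutation significance, and peak calling.

For a fully informative biallelic marker coded +/-1, Haley-Knott
regression reduces to ordinary least squares of the phenotype on the
marker code, and the LOD score is

    LOD_j = (n/2) * log10(RSS_0 / RSS_j) = -(n/2) * log10(1 - R^2_j)

where RSS_0 is the intercept-only residual sum of squares.  With missing
genotype entries the defining Haley-Knott device applies: the regression
covariate becomes the expected allele code given the nearest flanking
genotyped markers under Haldane transition probabilities.

The non-parametric scan converts the tie-corrected two-group
Kruskal-Wallis statistic H to the LOD scale via the Wilks correspondence
2 ln(LR) ~ chi^2: LOD = H / (2 ln 10).

Genome-wide significance is the empirical (1 - alpha) quantile of the
maximum LOD over permutations of the phenotype vector.  Peaks are local
maxima above max(cutoff, permutation threshold); their support interval
is the range of markers within ``lod_drop`` (default 1.5) of the peak,
truncated at chromosome ends.  Two same-chromosome maxima are distinct
peaks only when separated by a valley at least ``lod_drop`` below the
lower maximum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import InsufficientDataError, InvalidParameterError, ShapeMismatchError
from .simulate import GenotypeMatrix, MarkerMap, haldane_r

__all__ = [
    "ScanConfig",
    "ScanResult",
    "QTLPeak",
    "hk_lod_scan",
    "np_lod_scan",
    "permutation_threshold",
    "call_peaks",
    "expected_genotype_codes",
]

LN10 = np.log(10.0)


@dataclass(frozen=True)
class ScanConfig:
    """Scan-wide settings: call cutoff, permutations, alpha, drop width."""

    lod_cutoff: float = 3.0
    n_permutations: int = 1000
    alpha: float = 0.05
    lod_drop: float = 1.5
    seed: int = 0
    lod_cap: float = 50.0  # reported LOD for numerically perfect fits

    def __post_init__(self):
        if self.lod_cutoff <= 0:
            raise InvalidParameterError("lod_cutoff must be > 0")
        if self.n_permutations < 100:
            raise InvalidParameterError("n_permutations must be >= 100")
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.lod_drop <= 0:
            raise InvalidParameterError("lod_drop must be > 0")


@dataclass(frozen=True)
class ScanResult:
    """Per-marker LOD profile aligned to a marker map."""

    lod: np.ndarray
    markers: MarkerMap
    method: str  # "hk" | "np"
    dose: float | None = None
    monomorphic: np.ndarray = field(default=None)  # bool mask, LOD forced to 0
    capped: np.ndarray = field(default=None)  # bool mask, perfect-fit cap applied
    constant_phenotype: bool = False

    def __post_init__(self):
        lod = np.asarray(self.lod, dtype=float)
        if len(lod) != len(self.markers):
            raise ShapeMismatchError("LOD vector must align with the marker map")
        if np.any(lod < 0):
            raise InvalidParameterError("LOD scores must be >= 0")
        object.__setattr__(self, "lod", lod)
        for name in ("monomorphic", "capped"):
            mask = getattr(self, name)
            mask = np.zeros(len(lod), bool) if mask is None else np.asarray(mask, bool)
            object.__setattr__(self, name, mask)

    def to_frame(self) -> pd.DataFrame:
        df = self.markers.to_frame()
        df["lod"] = self.lod
        return df


@dataclass(frozen=True)
class QTLPeak:
    """A called locus: peak marker plus its LOD-drop support interval."""

    chromosome: str
    marker: str
    position_cM: float
    lod: float
    ci_left_cM: float
    ci_right_cM: float
    dose: float | None = None

    def __post_init__(self):
        if not (self.ci_left_cM <= self.position_cM <= self.ci_right_cM):
            raise InvalidParameterError("interval must contain the peak position")

    def contains(self, chromosome: str, position_cM: float) -> bool:
        return (
            chromosome == self.chromosome
            and self.ci_left_cM <= position_cM <= self.ci_right_cM
        )


def _phenotype_vector(genotypes: GenotypeMatrix, phenotype) -> np.ndarray:
    if isinstance(phenotype, pd.Series):
        y = phenotype.reindex(genotypes.strains).to_numpy(dtype=float)
        if np.isnan(y).any():
            missing = [s for s, v in zip(genotypes.strains, y) if np.isnan(v)]
            raise ShapeMismatchError(
                f"phenotype missing for strains: {missing[:5]}"
            )
        return y
    y = np.asarray(phenotype, dtype=float)
    if len(y) != genotypes.n_strains:
        raise ShapeMismatchError("phenotype length must equal number of strains")
    return y


def expected_genotype_codes(
    codes: np.ndarray, marker_map: MarkerMap
) -> np.ndarray:
    """Impute missing (NaN) allele codes as conditional expectations.

    For a missing entry, the expectation of the +/-1 code is computed given
    the nearest non-missing flanking markers on the same chromosome, using
    Haldane transition probabilities.  With one informative flank at
    distance d the expectation is g_flank * (1 - 2r(d)); with two flanks
    the two-sided Markov conditional is used; with none it is 0.
    """
    G = np.asarray(codes, dtype=float).copy()
    if not np.isnan(G).any():
        return G
    for sl in marker_map.chromosome_slices().values():
        pos = marker_map.position_cM[sl]
        block = G[:, sl]
        rows, cols = np.nonzero(np.isnan(block))
        for i, j in zip(rows, cols):
            row = block[i]
            left = next((k for k in range(j - 1, -1, -1) if not np.isnan(row[k])), None)
            right = next((k for k in range(j + 1, len(row)) if not np.isnan(row[k])), None)
            if left is None and right is None:
                block[i, j] = 0.0
            elif right is None:
                r = haldane_r(pos[j] - pos[left])
                block[i, j] = row[left] * (1 - 2 * r)
            elif left is None:
                r = haldane_r(pos[right] - pos[j])
                block[i, j] = row[right] * (1 - 2 * r)
            else:
                rl = haldane_r(pos[j] - pos[left])
                rr = haldane_r(pos[right] - pos[j])
                a, b = row[left], row[right]
                # P(g = +1 | flanks) via the two-step transition product
                p_same_l = 1 - rl if a > 0 else rl
                p_same_r = 1 - rr if b > 0 else rr
                num = p_same_l * p_same_r
                den = num + (1 - p_same_l) * (1 - p_same_r)
                block[i, j] = 2 * num / den - 1
        G[:, sl] = block
    return G


def _lod_from_r2(r2: np.ndarray, n: int, cap: float) -> tuple[np.ndarray, np.ndarray]:
    # The cap only guards numerically perfect fits (R^2 -> 1, LOD -> inf);
    # large finite LODs from strong QTL on big panels are reported exactly.
    r2 = np.clip(r2, 0.0, 1.0)
    with np.errstate(divide="ignore"):
        lod = -(n / 2.0) * np.log10(1.0 - r2)
    capped = ~np.isfinite(lod)
    lod[capped] = cap
    return np.maximum(lod, 0.0), capped


def hk_lod_scan(
    genotypes: GenotypeMatrix,
    phenotype,
    dose: float | None = None,
    lod_cap: float = 50.0,
) -> ScanResult:
    """Haley-Knott regression LOD profile over all markers.

    Exact marker regression for complete +/-1 genotypes; NaN entries in a
    float code matrix are first replaced by their flanking-marker
    expectations (see :func:`expected_genotype_codes`).
    """
    y = _phenotype_vector(genotypes, phenotype)
    n = len(y)
    if n < 8:
        raise InsufficientDataError("need >= 8 strains for a scan")
    G = genotypes.codes.astype(float)
    yc = y - y.mean()
    ss_y = float(yc @ yc)
    if ss_y == 0.0:
        return ScanResult(
            lod=np.zeros(genotypes.n_markers), markers=genotypes.markers,
            method="hk", dose=dose, constant_phenotype=True,
        )
    Gc = G - G.mean(axis=0)
    ss_g = np.einsum("ij,ij->j", Gc, Gc)
    mono = ss_g <= 0
    cross = yc @ Gc
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(mono, 0.0, cross**2 / np.where(mono, 1.0, ss_g) / ss_y)
    lod, capped = _lod_from_r2(r2, n, lod_cap)
    lod[mono] = 0.0
    return ScanResult(
        lod=lod, markers=genotypes.markers, method="hk", dose=dose,
        monomorphic=mono, capped=capped & ~mono,
    )


def _kw_lod(G: np.ndarray, ranks: np.ndarray, tie_term: float) -> np.ndarray:
    """Vectorized two-group Kruskal-Wallis H on precomputed ranks -> LOD."""
    n = len(ranks)
    plus = G > 0
    n1 = plus.sum(axis=0).astype(float)
    n2 = n - n1
    mono = (n1 == 0) | (n2 == 0)
    r1 = ranks @ plus
    r2 = ranks.sum() - r1
    with np.errstate(invalid="ignore", divide="ignore"):
        h = (12.0 / (n * (n + 1))) * (
            r1**2 / np.where(n1 == 0, 1.0, n1) + r2**2 / np.where(n2 == 0, 1.0, n2)
        ) - 3.0 * (n + 1)
    if tie_term < 1.0:  # tie correction divides H by 1 - sum(t^3 - t)/(N^3 - N)
        h = h / tie_term
    h = np.where(mono, 0.0, np.maximum(h, 0.0))
    return h / (2.0 * LN10), mono


def np_lod_scan(
    genotypes: GenotypeMatrix, phenotype, dose: float | None = None
) -> ScanResult:
    """Rank-based (Kruskal-Wallis) LOD profile; monotone-transform invariant."""
    y = _phenotype_vector(genotypes, phenotype)
    n = len(y)
    if n < 8:
        raise InsufficientDataError("need >= 8 strains for a scan")
    if np.ptp(y) == 0:
        return ScanResult(
            lod=np.zeros(genotypes.n_markers), markers=genotypes.markers,
            method="np", dose=dose, constant_phenotype=True,
        )
    ranks = rankdata(y)
    _, counts = np.unique(y, return_counts=True)
    tie_term = 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))
    lod, mono = _kw_lod(genotypes.codes.astype(float), ranks, tie_term)
    lod[mono] = 0.0
    return ScanResult(
        lod=lod, markers=genotypes.markers, method="np", dose=dose,
        monomorphic=mono,
    )


def permutation_threshold(
    genotypes: GenotypeMatrix,
    phenotype,
    config: ScanConfig,
    method: str = "hk",
    return_maxima: bool = False,
):
    """Genome-wide LOD threshold from phenotype permutations.

    The phenotype vector is permuted against the genotype rows
    ``config.n_permutations`` times; the threshold is the empirical
    (1 - alpha) quantile of the per-permutation maximum LOD.
    """
    y = _phenotype_vector(genotypes, phenotype)
    n = len(y)
    if n < 8:
        raise InsufficientDataError("need >= 8 strains for a scan")
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 505]))
    P = config.n_permutations
    G = genotypes.codes.astype(float)
    Gc = G - G.mean(axis=0)
    ss_g = np.einsum("ij,ij->j", Gc, Gc)
    ok = ss_g > 0
    if method == "hk":
        yc = y - y.mean()
        ss_y = float(yc @ yc)
        if ss_y == 0.0:
            maxima = np.zeros(P)
        else:
            Y = rng.permuted(np.tile(yc, (P, 1)), axis=1).T  # (n, P)
            C = Gc[:, ok].T @ Y  # (m_ok, P)
            r2 = C**2 / ss_g[ok, None] / ss_y
            lod, _ = _lod_from_r2(r2, n, config.lod_cap)
            maxima = lod.max(axis=0)
    elif method == "np":
        ranks = rankdata(y)
        _, counts = np.unique(y, return_counts=True)
        tie_term = 1.0 - float(((counts**3 - counts).sum()) / (n**3 - n))
        if tie_term <= 0:
            maxima = np.zeros(P)
        else:
            R = rng.permuted(np.tile(ranks, (P, 1)), axis=1)  # (P, n)
            plus = G[:, ok] > 0
            n1 = plus.sum(axis=0).astype(float)
            n2 = n - n1
            r1 = R @ plus  # (P, m_ok)
            r2sum = ranks.sum() - r1
            h = (12.0 / (n * (n + 1))) * (r1**2 / n1 + r2sum**2 / n2) - 3.0 * (n + 1)
            h = np.maximum(h / tie_term, 0.0)
            maxima = (h / (2.0 * LN10)).max(axis=1)
    else:
        raise InvalidParameterError(f"unknown scan method: {method!r}")
    thr = float(np.quantile(maxima, 1.0 - config.alpha))
    return (thr, maxima) if return_maxima else thr


def _interval(
    lod: np.ndarray, pos: np.ndarray, peak: int, drop: float,
    lo: int, hi: int,
) -> tuple[float, float]:
    """LOD-drop support interval: the range of markers within ``drop`` of
    the peak, searched inside [lo, hi].  Isolated one-marker dips below the
    floor are bridged (the interval is a range, not a contiguous run), the
    behaviour of standard linkage-mapping interval routines; the search
    segment is bounded by the valleys separating this peak from other
    accepted peaks, and by the chromosome ends."""
    floor = lod[peak] - drop
    inside = np.flatnonzero(lod[lo : hi + 1] >= floor) + lo
    left = int(inside.min()) if len(inside) else peak
    right = int(inside.max()) if len(inside) else peak
    return float(pos[left]), float(pos[right])


def call_peaks(
    scan: ScanResult,
    threshold: float = 0.0,
    config: ScanConfig | None = None,
) -> list[QTLPeak]:
    """Call QTL peaks from a LOD profile.

    The effective calling threshold is max(config.lod_cutoff, threshold),
    i.e. the stricter of the fixed cutoff and the permutation threshold.
    """
    config = config or ScanConfig()
    thr = max(config.lod_cutoff, float(threshold))
    peaks: list[QTLPeak] = []
    mm = scan.markers
    for chrom, sl in mm.chromosome_slices().items():
        lod = scan.lod[sl]
        pos = mm.position_cM[sl]
        names = mm.marker[sl]
        # local maxima above threshold (plateaus: keep first index)
        cand = [
            i for i in range(len(lod))
            if lod[i] >= thr
            and (i == 0 or lod[i] > lod[i - 1])
            and (i == len(lod) - 1 or lod[i] >= lod[i + 1])
        ]
        cand.sort(key=lambda i: -lod[i])
        accepted: list[int] = []
        for i in cand:
            distinct = True
            for j in accepted:
                lo, hi = sorted((i, j))
                valley = lod[lo : hi + 1].min()
                if min(lod[i], lod[j]) - valley < config.lod_drop:
                    distinct = False  # merged into the stronger peak
                    break
            if distinct:
                accepted.append(i)
        accepted.sort()
        # segment each peak's interval search at the deepest point of the
        # valley separating it from its accepted neighbours
        bounds = []
        for k, i in enumerate(accepted):
            lo = 0 if k == 0 else accepted[k - 1] + int(
                np.argmin(lod[accepted[k - 1] : i + 1])
            )
            hi = len(lod) - 1 if k == len(accepted) - 1 else i + int(
                np.argmin(lod[i : accepted[k + 1] + 1])
            )
            bounds.append((lo, hi))
        for (lo, hi), i in zip(bounds, accepted):
            left, right = _interval(lod, pos, i, config.lod_drop, lo, hi)
            peaks.append(
                QTLPeak(
                    chromosome=chrom,
                    marker=str(names[i]),
                    position_cM=float(pos[i]),
                    lod=float(lod[i]),
                    ci_left_cM=left,
                    ci_right_cM=right,
                    dose=scan.dose,
                )
            )
    return peaks


def peaks_to_frame(peaks: list[QTLPeak]) -> pd.DataFrame:
    """Tabular view of called peaks."""
    return pd.DataFrame(
        [
            {
                "chromosome": p.chromosome,
                "peak_marker": p.marker,
                "peak_cM": p.position_cM,
                "lod": p.lod,
                "ci_left_cM": p.ci_left_cM,
                "ci_right_cM": p.ci_right_cM,
                "dose_uM": p.dose,
            }
            for p in peaks
        ],
        columns=[
            "chromosome", "peak_marker", "peak_cM", "lod",
            "ci_left_cM", "ci_right_cM", "dose_uM",
        ],
    )
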