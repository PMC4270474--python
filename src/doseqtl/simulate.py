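"""Synthetic biparental cross generator.

Emulates a panel of haploid segregants from a cross between two inbred
yeast parents (BY and RM), genotyped on a dense marker grid and phenotyped
for colony growth across a drug dose series.  Genotypes are coded +1 for
the BY allele and -1 for the RM allele.  Recombination follows the Haldane
(no-interference) map function, r = (1 - exp(-2d/100)) / 2 for an
inter-marker distance of d centiMorgans.

The phenotype model for strain i at dose D is

    y_i = mu(D) + sum_k beta_k(D) * g[i, q_k]
               + sum_(k,l) gamma_kl(D) * g[i, q_k] * g[i, q_l]
               + s_i,                       s_i ~ N(0, sigma_s^2)

with each replicate measurement adding independent N(0, sigma_e^2) noise,
and radii clamped at zero after noise (colonies cannot have negative
size; at high doses many strains legitimately do not grow).  The
strain-level effect s_i is drawn once per strain at each dose and shared
across that strain's replicates and layouts: it models dose-specific
non-additive genetic variance, and is the device that makes broad-sense
heritability exceed narrow-sense heritability.  A positive beta means
BY-allele carriers grow better.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidParameterError, ShapeMismatchError

__all__ = [
    "MarkerMap",
    "GenotypeMatrix",
    "AdditiveQTL",
    "EpistaticPair",
    "QTLArchitecture",
    "PHENOTYPE_COLUMNS",
    "make_marker_map",
    "simulate_genotypes",
    "strain_genetic_values",
    "simulate_phenotypes",
    "simulate_parent_panel",
    "haldane_r",
    "yeast_chromosome_names",
    "study_architecture",
]

#: Column schema of every long-format phenotype table in the package.
PHENOTYPE_COLUMNS = ("strain", "dose_uM", "replicate", "layout", "radius")

_ROMAN = [
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII",
    "IX", "X", "XI", "XII", "XIII", "XIV", "XV", "XVI",
]


def yeast_chromosome_names(n: int) -> list[str]:
    """Roman-numeral chromosome labels ("chrI", "chrII", ...)."""
    if n <= len(_ROMAN):
        return [f"chr{r}" for r in _ROMAN[:n]]
    return [f"chr{i + 1}" for i in range(n)]


def haldane_r(d_cM: np.ndarray | float) -> np.ndarray | float:
    """Haldane recombination fraction for a genetic distance in cM."""
    return (1.0 - np.exp(-2.0 * np.asarray(d_cM, dtype=float) / 100.0)) / 2.0


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker grid: chromosome label and cM position per marker."""

    chromosome: np.ndarray  # str array, one label per marker
    position_cM: np.ndarray  # float array, non-decreasing within chromosome
    marker: np.ndarray  # unique marker identifiers

    def __post_init__(self):
        chrom = np.asarray(self.chromosome, dtype=object)
        pos = np.asarray(self.position_cM, dtype=float)
        mk = np.asarray(self.marker, dtype=object)
        if not (len(chrom) == len(pos) == len(mk)):
            raise ShapeMismatchError("marker map fields must have equal length")
        if len(set(mk)) != len(mk):
            raise InvalidParameterError("marker identifiers must be unique")
        if np.any(pos < 0):
            raise InvalidParameterError("marker positions must be non-negative")
        for c in pd.unique(chrom):
            p = pos[chrom == c]
            if np.any(np.diff(p) < 0):
                raise InvalidParameterError(
                    f"positions must be non-decreasing within chromosome {c}"
                )
        object.__setattr__(self, "chromosome", chrom)
        object.__setattr__(self, "position_cM", pos)
        object.__setattr__(self, "marker", mk)

    def __len__(self) -> int:
        return len(self.marker)

    @property
    def n_markers(self) -> int:
        return len(self.marker)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in map order (first occurrence)."""
        return list(pd.unique(self.chromosome))

    def chromosome_slices(self) -> dict[str, slice]:
        """Contiguous index slice of each chromosome's markers."""
        out: dict[str, slice] = {}
        for c in self.chromosomes():
            idx = np.flatnonzero(self.chromosome == c)
            out[c] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker,
                "chromosome": self.chromosome,
                "position_cM": self.position_cM,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MarkerMap":
        return cls(
            chromosome=df["chromosome"].to_numpy(dtype=object),
            position_cM=df["position_cM"].to_numpy(dtype=float),
            marker=df["marker"].to_numpy(dtype=object),
        )


@dataclass(frozen=True)
class GenotypeMatrix:
    """Segregants x markers allele codes (+1 = BY, -1 = RM)."""

    codes: np.ndarray  # (n_strains, n_markers) int8
    markers: MarkerMap
    strains: np.ndarray  # strain identifiers

    def __post_init__(self):
        codes = np.asarray(self.codes)
        strains = np.asarray(self.strains, dtype=object)
        if codes.ndim != 2:
            raise ShapeMismatchError("genotype codes must be a 2-D matrix")
        if codes.shape[1] != len(self.markers):
            raise ShapeMismatchError(
                f"{codes.shape[1]} genotype columns vs {len(self.markers)} map markers"
            )
        if codes.shape[0] != len(strains):
            raise ShapeMismatchError("one strain identifier per genotype row required")
        if not np.isin(codes, (-1, 1)).all():
            raise InvalidParameterError("genotype codes must be +1 or -1")
        object.__setattr__(self, "codes", codes.astype(np.int8, copy=False))
        object.__setattr__(self, "strains", strains)

    @property
    def n_strains(self) -> int:
        return self.codes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.codes.shape[1]

    def column(self, j: int) -> np.ndarray:
        return self.codes[:, j].astype(float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=self.markers.marker)
        df.insert(0, "strain", self.strains)
        return df


@dataclass(frozen=True)
class AdditiveQTL:
    """A single additive locus with a per-dose effect beta (phenotype units)."""

    marker_index: int
    beta: Mapping[float, float]  # dose (uM) -> effect; absent dose -> 0

    def effect(self, dose: float) -> float:
        return float(self.beta.get(float(dose), 0.0))


@dataclass(frozen=True)
class EpistaticPair:
    """A pairwise interaction with a per-dose effect gamma."""

    marker_i: int
    marker_j: int
    gamma: Mapping[float, float]

    def effect(self, dose: float) -> float:
        return float(self.gamma.get(float(dose), 0.0))


@dataclass(frozen=True)
class QTLArchitecture:
    """Generative truth for a simulated panel.

    Parameters
    ----------
    additive : additive loci with dose-resolved effects beta.
    epistatic : locus pairs with dose-resolved interaction effects gamma.
    strain_sd : sigma_s, SD of the strain-level non-additive effect
        (shared across replicates/layouts/doses; source of H2 > h2).
    replicate_sd : sigma_e, SD of per-measurement noise.
    baseline : dose -> mu, the mean radius of a strain with no QTL effects.
    """

    additive: tuple[AdditiveQTL, ...] = ()
    epistatic: tuple[EpistaticPair, ...] = ()
    strain_sd: float = 0.0
    replicate_sd: float = 0.0
    baseline: Mapping[float, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.strain_sd < 0 or self.replicate_sd < 0:
            raise InvalidParameterError("variance components must be >= 0")
        object.__setattr__(self, "additive", tuple(self.additive))
        object.__setattr__(self, "epistatic", tuple(self.epistatic))

    def validate_for(self, n_markers: int) -> None:
        idx = [q.marker_index for q in self.additive]
        idx += [m for p in self.epistatic for m in (p.marker_i, p.marker_j)]
        if any(j < 0 or j >= n_markers for j in idx):
            raise ShapeMismatchError(
                f"architecture references marker outside 0..{n_markers - 1}"
            )

    def baseline_at(self, dose: float) -> float:
        return float(self.baseline.get(float(dose), 0.0))

    def doses(self) -> list[float]:
        d: set[float] = set(map(float, self.baseline))
        for q in self.additive:
            d.update(map(float, q.beta))
        for p in self.epistatic:
            d.update(map(float, p.gamma))
        return sorted(d)


def make_marker_map(
    chromosome_lengths_cM: Sequence[float],
    spacing_cM: float,
    chromosome_names: Sequence[str] | None = None,
) -> MarkerMap:
    """Regular marker grid: 0, spacing, 2*spacing, ... plus the chromosome end.

    Chromosome ends always carry a marker so that peak support intervals can
    truncate naturally at the end of a chromosome.
    """
    if len(chromosome_lengths_cM) < 1:
        raise InvalidParameterError("need at least one chromosome")
    if spacing_cM <= 0:
        raise InvalidParameterError("spacing_cM must be positive")
    if any(L < 0 for L in chromosome_lengths_cM):
        raise InvalidParameterError("chromosome lengths must be non-negative")
    names = (
        list(chromosome_names)
        if chromosome_names is not None
        else yeast_chromosome_names(len(chromosome_lengths_cM))
    )
    if len(names) != len(chromosome_lengths_cM):
        raise InvalidParameterError("one name per chromosome required")

    chrom, pos, marker = [], [], []
    for name, L in zip(names, chromosome_lengths_cM):
        grid = list(np.arange(0.0, float(L) + 1e-12, float(spacing_cM)))
        if not grid or grid[-1] < float(L) - 1e-9:
            grid.append(float(L))
        for i, p in enumerate(grid):
            chrom.append(name)
            pos.append(p)
            marker.append(f"{name}_m{i + 1:03d}")
    return MarkerMap(
        chromosome=np.array(chrom, dtype=object),
        position_cM=np.array(pos, dtype=float),
        marker=np.array(marker, dtype=object),
    )


def simulate_genotypes(
    marker_map: MarkerMap, n_segregants: int, seed: int
) -> GenotypeMatrix:
    """Draw haploid segregant genotypes under the Haldane model.

    Per chromosome the first marker is +1/-1 with probability 1/2; each
    subsequent marker switches allele with the Haldane recombination
    fraction for the inter-marker distance.  Chromosomes are independent.
    """
    if len(marker_map) == 0:
        raise InvalidParameterError("marker map is empty")
    if n_segregants < 1:
        raise InvalidParameterError("n_segregants must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 101]))
    n = int(n_segregants)
    codes = np.empty((n, len(marker_map)), dtype=np.int8)
    for sl in marker_map.chromosome_slices().values():
        pos = marker_map.position_cM[sl]
        m = len(pos)
        first = rng.choice(np.array([1, -1], dtype=np.int8), size=n)
        if m == 1:
            codes[:, sl] = first[:, None]
            continue
        r = haldane_r(np.diff(pos))  # (m-1,)
        switch = rng.random((n, m - 1)) < r  # True -> allele flips
        steps = np.where(switch, -1, 1).astype(np.int8)
        block = np.empty((n, m), dtype=np.int8)
        block[:, 0] = first
        block[:, 1:] = first[:, None] * np.cumprod(steps, axis=1, dtype=np.int8)
        codes[:, sl] = block
    strains = np.array([f"seg{i + 1:04d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(codes=codes, markers=marker_map, strains=strains)


def strain_genetic_values(
    genotypes: GenotypeMatrix | np.ndarray,
    architecture: QTLArchitecture,
    dose: float,
) -> np.ndarray:
    """Deterministic genetic value mu + additive + epistatic terms per strain."""
    codes = genotypes.codes if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    architecture.validate_for(codes.shape[1])
    g = codes.astype(float)
    y = np.full(g.shape[0], architecture.baseline_at(dose))
    for q in architecture.additive:
        b = q.effect(dose)
        if b:
            y += b * g[:, q.marker_index]
    for p in architecture.epistatic:
        c = p.effect(dose)
        if c:
            y += c * g[:, p.marker_i] * g[:, p.marker_j]
    return y


def _strain_effects(n: int, sigma_s: float, seed: int, dose: float) -> np.ndarray:
    # Dedicated stream keyed by (seed, dose): the non-additive effect is
    # shared across replicates and layouts of a strain at one dose, but is
    # redrawn across doses — it models dose-specific non-additive genetic
    # variance, which control-plate normalization therefore cannot remove.
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 202, int(round(float(dose) * 1000))])
    )
    return rng.normal(0.0, sigma_s, size=n) if sigma_s > 0 else np.zeros(n)


def _replicate_table(
    strains: np.ndarray,
    strain_values: np.ndarray,
    dose: float,
    n_replicates: int,
    sigma_e: float,
    seed: int,
    layouts: Sequence[str],
    layout_offsets: Mapping[str, float] | None,
) -> pd.DataFrame:
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 303, int(round(float(dose) * 1000))])
    )
    offs = dict(layout_offsets or {})
    n = len(strains)
    recs = []
    for rep in range(1, n_replicates + 1):
        layout = layouts[(rep - 1) % len(layouts)]
        noise = rng.normal(0.0, sigma_e, size=n) if sigma_e > 0 else np.zeros(n)
        radius = strain_values + offs.get(layout, 0.0) + noise
        radius = np.clip(radius, 0.0, None)  # no-growth colonies floor at 0
        recs.append(
            pd.DataFrame(
                {
                    "strain": strains,
                    "dose_uM": float(dose),
                    "replicate": rep,
                    "layout": layout,
                    "radius": radius,
                }
            )
        )
    return pd.concat(recs, ignore_index=True)


def simulate_phenotypes(
    genotypes: GenotypeMatrix,
    architecture: QTLArchitecture,
    dose: float,
    n_replicates: int,
    seed: int,
    layouts: Sequence[str] = ("A", "B"),
    layout_offsets: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Long-format phenotype table (strain, dose_uM, replicate, layout, radius).

    Replicates are assigned alternately to the layout configurations;
    ``layout_offsets`` adds a fixed position-effect shift per layout, which
    the control-plate normalization is designed to remove.
    """
    architecture.validate_for(genotypes.n_markers)
    values = strain_genetic_values(genotypes, architecture, dose)
    values = values + _strain_effects(
        genotypes.n_strains, architecture.strain_sd, seed, dose
    )
    return _replicate_table(
        genotypes.strains, values, dose, n_replicates,
        architecture.replicate_sd, seed, layouts, layout_offsets,
    )


def simulate_parent_panel(
    architecture: QTLArchitecture,
    dose: float,
    n_replicates: int,
    seed: int,
    n_markers: int | None = None,
    layouts: Sequence[str] = ("A", "B"),
    layout_offsets: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Replicate measurements of the two parents under the same model.

    The BY parent is the all-(+1) genotype and RM the all-(-1) genotype, so
    the parent gap at a dose is 2*|sum of beta| while segregants can stack
    alleles of opposing sign and exceed both parents (transgression).
    """
    if n_markers is None:
        idx = [q.marker_index for q in architecture.additive]
        idx += [m for p in architecture.epistatic for m in (p.marker_i, p.marker_j)]
        n_markers = (max(idx) + 1) if idx else 1
    codes = np.vstack(
        [np.ones(n_markers, dtype=np.int8), -np.ones(n_markers, dtype=np.int8)]
    )
    values = strain_genetic_values(codes, architecture, dose)
    # Parents get strain-level effects from a parent-specific stream.
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), 404, int(round(float(dose) * 1000))])
    )
    if architecture.strain_sd > 0:
        values = values + rng.normal(0.0, architecture.strain_sd, size=2)
    return _replicate_table(
        np.array(["BY", "RM"], dtype=object), values, dose, n_replicates,
        architecture.replicate_sd, seed + 1_000_003, layouts, layout_offsets,
    )


def _nearest_marker(marker_map: MarkerMap, chromosome: str, pos_cM: float) -> int:
    sl = marker_map.chromosome_slices()[chromosome]
    pos = marker_map.position_cM[sl]
    return int(sl.start + np.argmin(np.abs(pos - pos_cM)))


def study_architecture(marker_map: MarkerMap) -> QTLArchitecture:
    """Default architecture emulating the haloperidol study panel.

    Nine additive loci with dose-dependent effects: a large-effect locus on
    chromosome I active across the dose series (RM allele beneficial, so
    beta < 0), loci on chromosomes VII, XII and XIII active only at the two
    lower doses, and loci on chromosomes XIV and XV whose effects manifest
    primarily at the higher doses.  Three epistatic pairs among the
    chromosome I/XIV/XV loci act at 160-200 uM.  A strain-level effect
    (sigma_s) creates broad-sense heritability in excess of narrow-sense.
    Radii are in arbitrary scanner units; baselines shrink with dose.
    """
    D = (40.0, 80.0, 120.0, 160.0, 200.0)
    chroms = marker_map.chromosomes()

    def chrom_for(preferred: str, fallback_rank: int) -> str:
        return preferred if preferred in chroms else chroms[fallback_rank % len(chroms)]

    def locus(chrom: str, frac: float, rank: int) -> int:
        c = chrom_for(chrom, rank)
        sl = marker_map.chromosome_slices()[c]
        pos = marker_map.position_cM[sl]
        target = pos[0] + frac * (pos[-1] - pos[0])
        return _nearest_marker(marker_map, c, target)

    q = {
        "I": locus("chrI", 0.7, 0),
        "V": locus("chrV", 0.4, 4),
        "VII": locus("chrVII", 0.5, 6),
        "VIII": locus("chrVIII", 0.3, 7),
        "XI": locus("chrXI", 0.6, 10),
        "XII": locus("chrXII", 0.5, 11),
        "XIII": locus("chrXIII", 0.4, 12),
        "XIV": locus("chrXIV", 0.5, 13),
        "XV": locus("chrXV", 0.5, 14),
    }
    additive = (
        AdditiveQTL(q["I"], dict(zip(D, (-0.50, -0.55, -0.50, -0.40, -0.15)))),
        AdditiveQTL(q["V"], dict(zip(D, (-0.16, -0.18, -0.20, -0.15, -0.05)))),
        AdditiveQTL(q["VII"], {40.0: 0.24, 80.0: 0.18}),  # low-dose only
        AdditiveQTL(q["VIII"], dict(zip(D, (0.18, 0.16, 0.14, 0.10, 0.0)))),
        AdditiveQTL(q["XI"], dict(zip(D, (0.16, 0.16, 0.13, 0.10, 0.0)))),
        AdditiveQTL(q["XII"], {40.0: -0.18, 80.0: -0.15}),  # low-dose only
        AdditiveQTL(q["XIII"], {40.0: 0.20, 80.0: 0.16}),  # low-dose only
        AdditiveQTL(q["XIV"], {120.0: 0.20, 160.0: 0.30, 200.0: 0.25}),  # high-dose
        AdditiveQTL(q["XV"], {120.0: -0.15, 160.0: -0.28, 200.0: -0.22}),  # high-dose
    )
    # mixed-sign interaction effects: same-sign parental allele products
    # then largely cancel, so epistasis widens the segregant distribution
    # without lifting both parents (the transgression substrate at 200 uM)
    epistatic = (
        EpistaticPair(q["I"], q["XIV"], {40.0: 0.10, 80.0: 0.08, 160.0: 0.18, 200.0: 0.12}),
        EpistaticPair(q["I"], q["XV"], {40.0: -0.08, 160.0: -0.15, 200.0: -0.10}),
        EpistaticPair(q["XIV"], q["XV"], {160.0: 0.12, 200.0: 0.10}),
    )
    baseline = {0.0: 5.0, 40.0: 4.0, 80.0: 3.2, 120.0: 2.4, 160.0: 1.6, 200.0: 0.15}
    return QTLArchitecture(
        additive=additive,
        epistatic=epistatic,
        strain_sd=0.35,
        replicate_sd=0.35,
        baseline=baseline,
    )
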