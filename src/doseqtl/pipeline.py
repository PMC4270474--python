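"""End-to-end pipeline: simulate (or load) -> normalize -> scan -> report.

A single :class:`PipelineConfig` holds the study constants (dose series,
scan settings, resample counts, seed); :func:`run_pipeline` executes
normalization, both LOD scans, the permutation threshold, peak calling,
effect sizes, the additive and interaction models, heritability and the
transgression test for every dose, and returns one result bundle.  With
an output directory every artifact is written as headered TSV annotated
with the effective-config hash, so identical configs give identical
bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .effects import additive_model, interaction_scan, locus_effect_size
from .errors import InvalidParameterError, MissingDoseError
from .heritability import (
    broad_sense_heritability,
    kinship,
    narrow_sense_heritability,
)
from .phenotype import normalize_records, normalize_to_control
from .scan import ScanConfig, call_peaks, hk_lod_scan, np_lod_scan, permutation_threshold, peaks_to_frame
from .simulate import (
    GenotypeMatrix,
    QTLArchitecture,
    make_marker_map,
    simulate_genotypes,
    simulate_parent_panel,
    simulate_phenotypes,
    study_architecture,
)
from .transgression import transgression_test

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

log = logging.getLogger("doseqtl")


@dataclass(frozen=True)
class PipelineConfig:
    """Study constants and resampling settings for one pipeline run."""

    doses: tuple[float, ...] = (40.0, 80.0, 120.0, 160.0, 200.0)
    n_segregants: int = 1008
    n_replicates: int = 4  # 2 replicates x 2 layout configurations
    n_parent_replicates: int = 48
    chromosome_lengths_cM: tuple[float, ...] = (100.0,) * 16
    marker_spacing_cM: float = 2.0
    lod_cutoff: float = 3.0
    n_permutations: int = 1000
    alpha: float = 0.05
    lod_drop: float = 1.5
    interaction_alpha: float = 0.005
    broad_bootstrap: int = 1000
    narrow_bootstrap: int = 0
    transgression_k_sd: float = 2.0
    transgression_resamples: int = 10_000
    seed: int = 0
    out_dir: str | None = None
    quiet: bool = False

    def __post_init__(self):
        doses = tuple(float(d) for d in self.doses)
        if len(set(doses)) != len(doses) or any(d < 0 for d in doses):
            raise InvalidParameterError("doses must be unique and non-negative")
        object.__setattr__(self, "doses", doses)
        for name in (
            "n_segregants", "n_replicates", "n_parent_replicates",
            "n_permutations", "transgression_resamples",
        ):
            if getattr(self, name) < 1:
                raise InvalidParameterError(f"{name} must be positive")

    def scan_config(self) -> ScanConfig:
        return ScanConfig(
            lod_cutoff=self.lod_cutoff,
            n_permutations=self.n_permutations,
            alpha=self.alpha,
            lod_drop=self.lod_drop,
            seed=self.seed,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path, **overrides) -> "PipelineConfig":
        payload = json.loads(Path(path).read_text())
        payload.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("doses", "chromosome_lengths_cM"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class DoseResult:
    """All per-dose artifacts of one pipeline pass."""

    dose: float
    phenotype: pd.Series  # normalized per-strain values
    hk_scan: object
    np_scan: object
    threshold: float
    peaks: list
    effects: pd.DataFrame
    additive_fit: object
    interactions: object
    broad_h2: object
    narrow_h2: object
    transgression: object


@dataclass
class PipelineResult:
    config: PipelineConfig
    genotypes: GenotypeMatrix
    architecture: QTLArchitecture | None
    per_dose: dict[float, DoseResult]
    union_loci: pd.DataFrame  # loci detected at any dose
    truth_comparison: pd.DataFrame | None
    config_hash: str


def _union_loci(per_dose_peaks: dict[float, list]) -> pd.DataFrame:
    """Distinct loci across doses: same-chromosome peaks whose support
    intervals overlap are one locus; the strongest peak names it."""
    rows = []
    for dose, peaks in per_dose_peaks.items():
        for p in peaks:
            rows.append(
                {
                    "chromosome": p.chromosome, "marker": p.marker,
                    "position_cM": p.position_cM, "lod": p.lod,
                    "ci_left_cM": p.ci_left_cM, "ci_right_cM": p.ci_right_cM,
                    "dose_uM": dose,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["chromosome", "marker", "position_cM", "lod",
                     "ci_left_cM", "ci_right_cM", "n_doses"]
        )
    df = pd.DataFrame(rows).sort_values("lod", ascending=False)
    loci: list[dict] = []
    for _, r in df.iterrows():
        merged = False
        for loc in loci:
            if (
                loc["chromosome"] == r["chromosome"]
                and r["ci_left_cM"] <= loc["ci_right_cM"]
                and r["ci_right_cM"] >= loc["ci_left_cM"]
            ):
                loc["ci_left_cM"] = min(loc["ci_left_cM"], r["ci_left_cM"])
                loc["ci_right_cM"] = max(loc["ci_right_cM"], r["ci_right_cM"])
                loc["n_doses"] += 1
                merged = True
                break
        if not merged:
            loci.append(
                {
                    "chromosome": r["chromosome"], "marker": r["marker"],
                    "position_cM": r["position_cM"], "lod": r["lod"],
                    "ci_left_cM": r["ci_left_cM"], "ci_right_cM": r["ci_right_cM"],
                    "n_doses": 1,
                }
            )
    return pd.DataFrame(loci).sort_values(
        ["chromosome", "position_cM"], ignore_index=True
    )


def _truth_table(
    architecture: QTLArchitecture,
    genotypes: GenotypeMatrix,
    per_dose_peaks: dict[float, list],
) -> pd.DataFrame:
    mm = genotypes.markers
    rows = []
    for q in architecture.additive:
        chrom = str(mm.chromosome[q.marker_index])
        pos = float(mm.position_cM[q.marker_index])
        for dose, beta in sorted(q.beta.items()):
            if beta == 0:
                continue
            covered = any(
                p.contains(chrom, pos) for p in per_dose_peaks.get(float(dose), [])
            )
            rows.append(
                {
                    "marker": str(mm.marker[q.marker_index]),
                    "chromosome": chrom,
                    "position_cM": pos,
                    "dose_uM": float(dose),
                    "beta_true": beta,
                    "covered": covered,
                }
            )
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    genotypes: GenotypeMatrix | None = None,
    architecture: QTLArchitecture | None = None,
    drug_tables: dict[float, pd.DataFrame] | None = None,
    control_table: pd.DataFrame | None = None,
    parent_tables: dict[float, pd.DataFrame] | None = None,
) -> PipelineResult:
    """Run the full per-dose analysis; simulate inputs that are not given.

    In pure simulation mode (no tables supplied) the panel, the control
    plates and the parent panels are generated from ``architecture``
    (default: the study-emulating architecture) under ``config.seed``.
    """
    t0 = time.time()
    if not config.quiet:
        logging.basicConfig(level=logging.INFO, format="%(message)s")
    simulated = drug_tables is None
    if genotypes is None:
        mm = make_marker_map(config.chromosome_lengths_cM, config.marker_spacing_cM)
        genotypes = simulate_genotypes(mm, config.n_segregants, config.seed)
        log.info("simulated %d segregants x %d markers", genotypes.n_strains, genotypes.n_markers)
    if simulated:
        architecture = architecture or study_architecture(genotypes.markers)
        drug_tables = {
            d: simulate_phenotypes(genotypes, architecture, d, config.n_replicates, config.seed)
            for d in config.doses
        }
        control_table = simulate_phenotypes(
            genotypes, architecture, 0.0, config.n_replicates, config.seed
        )
        parent_tables = {
            d: simulate_parent_panel(
                architecture, d, config.n_parent_replicates, config.seed,
                n_markers=genotypes.n_markers,
            )
            for d in config.doses
        }
    if control_table is None:
        raise MissingDoseError("a dose-0 control table is required")
    missing = [d for d in config.doses if d not in drug_tables]
    if missing:
        raise MissingDoseError(f"doses absent from phenotype data: {missing}")

    scan_cfg = config.scan_config()
    K = kinship(genotypes)
    eigvals, eigvecs = np.linalg.eigh(K)
    eig = (np.clip(eigvals, 0.0, None), eigvecs)

    # pass 1: scans and peaks per dose
    per_dose_peaks: dict[float, list] = {}
    norm: dict[float, pd.Series] = {}
    scans: dict[float, tuple] = {}
    for d in config.doses:
        t = time.time()
        y = normalize_to_control(drug_tables[d], control_table)
        hk = hk_lod_scan(genotypes, y, dose=d)
        npr = np_lod_scan(genotypes, y, dose=d)
        thr = permutation_threshold(genotypes, y, scan_cfg)
        peaks = call_peaks(hk, threshold=thr, config=scan_cfg)
        norm[d], scans[d], per_dose_peaks[d] = y, (hk, npr, thr), peaks
        log.info(
            "dose %g uM: %d peaks (threshold %.2f) in %.1fs",
            d, len(peaks), max(config.lod_cutoff, thr), time.time() - t,
        )

    union = _union_loci(per_dose_peaks)
    marker_idx = {m: j for j, m in enumerate(genotypes.markers.marker)}

    per_dose: dict[float, DoseResult] = {}
    for d in config.doses:
        y = norm[d]
        hk, npr, thr = scans[d]
        loci = list(union["marker"]) if len(union) else []
        cols = {m: genotypes.column(marker_idx[m]) for m in loci}
        eff = pd.DataFrame(
            [
                dataclasses.asdict(locus_effect_size(y.to_numpy(), cols[m], locus=m, dose=d))
                for m in loci
            ]
        )
        design = pd.DataFrame(cols, index=genotypes.strains) if loci else None
        add_fit = additive_model(y.to_numpy(), design) if loci else None
        inter = (
            interaction_scan(y.to_numpy(), design, corrected_alpha=config.interaction_alpha)
            if len(loci) >= 2
            else None
        )
        rec = normalize_records(drug_tables[d], control_table)
        broad = broad_sense_heritability(
            rec.assign(radius=rec["residual"]),
            n_bootstrap=config.broad_bootstrap,
            seed=config.seed,
        )
        narrow = narrow_sense_heritability(
            genotypes, y, dose=d, n_bootstrap=config.narrow_bootstrap,
            seed=config.seed, _eig=eig,
        )
        par = parent_tables.get(d) if parent_tables else None
        trans = None
        if par is not None:
            trans = transgression_test(
                par[par["strain"] == "BY"]["radius"].to_numpy(),
                par[par["strain"] == "RM"]["radius"].to_numpy(),
                drug_tables[d].groupby("strain")["radius"].mean().to_numpy(),
                k_sd=config.transgression_k_sd,
                resamples=config.transgression_resamples,
                seed=config.seed,
            )
        per_dose[d] = DoseResult(
            dose=d, phenotype=y, hk_scan=hk, np_scan=npr, threshold=thr,
            peaks=per_dose_peaks[d], effects=eff, additive_fit=add_fit,
            interactions=inter, broad_h2=broad, narrow_h2=narrow,
            transgression=trans,
        )

    truth = (
        _truth_table(architecture, genotypes, per_dose_peaks)
        if (simulated and architecture is not None)
        else None
    )
    result = PipelineResult(
        config=config, genotypes=genotypes, architecture=architecture,
        per_dose=per_dose, union_loci=union, truth_comparison=truth,
        config_hash=config.hash(),
    )
    if config.out_dir:
        _write_bundle(result, Path(config.out_dir))
    log.info("pipeline finished in %.1fs", time.time() - t0)
    return result


def _write_bundle(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    meta = {"config": cfg.to_dict(), "config_hash": result.config_hash, "seed": cfg.seed}
    (out / "config.json").write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    dio.write_genotypes(
        result.genotypes, out / "genotypes.tsv", map_path=out / "marker_map.tsv"
    )
    if result.architecture is not None:
        dio.write_architecture(result.architecture, out / "architecture.json", seed=cfg.seed)
    summary_rows = []
    for d, res in result.per_dose.items():
        tag = f"{d:g}uM"
        dio.write_table(res.hk_scan.to_frame(), out / f"scan_hk_{tag}.tsv")
        dio.write_table(res.np_scan.to_frame(), out / f"scan_np_{tag}.tsv")
        dio.write_table(peaks_to_frame(res.peaks), out / f"peaks_{tag}.tsv")
        if len(res.effects):
            dio.write_table(res.effects, out / f"effects_{tag}.tsv")
        if res.interactions is not None:
            dio.write_table(res.interactions.pairs, out / f"interactions_{tag}.tsv")
        summary_rows.append(
            {
                "dose_uM": d,
                "n_peaks": len(res.peaks),
                "perm_threshold": res.threshold,
                "r2_additive": res.additive_fit.r_squared if res.additive_fit else np.nan,
                "n_sig_pairs": res.interactions.n_significant if res.interactions else 0,
                "delta_var": res.interactions.delta_var if res.interactions else np.nan,
                "H2": res.broad_h2.estimate,
                "H2_se": res.broad_h2.se,
                "h2": res.narrow_h2.estimate,
                "H2_minus_h2": res.broad_h2.estimate - res.narrow_h2.estimate,
                "transgression_count": res.transgression.count if res.transgression else np.nan,
                "transgression_p": res.transgression.p_value if res.transgression else np.nan,
                "config_hash": result.config_hash,
            }
        )
    dio.write_table(pd.DataFrame(summary_rows), out / "summary.tsv")
    if result.union_loci is not None:
        dio.write_table(result.union_loci, out / "loci_union.tsv")
    if result.truth_comparison is not None:
        dio.write_table(result.truth_comparison, out / "truth_vs_called.tsv")
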