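"""Tab-separated file formats for every pipeline artifact.

All matrices and tables are plain headered TSV so outputs diff cleanly;
a JSON sidecar records simulation truth (architecture and seed) for
recovery tests.  Genotype files accept the +1/-1, 1/-1 and BY/RM coding
dialects; anything else is rejected with the offending line number.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError
from .simulate import (
    AdditiveQTL,
    EpistaticPair,
    GenotypeMatrix,
    MarkerMap,
    QTLArchitecture,
)

__all__ = [
    "write_marker_map",
    "read_marker_map",
    "write_genotypes",
    "read_genotypes",
    "write_phenotypes",
    "read_phenotypes",
    "write_table",
    "read_growth_curve",
    "write_architecture",
    "read_architecture",
]

_ALLELE_TOKENS = {"1": 1, "+1": 1, "-1": -1, "BY": 1, "RM": -1}


def write_marker_map(marker_map: MarkerMap, path) -> None:
    marker_map.to_frame().to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> MarkerMap:
    df = pd.read_csv(path, sep="\t")
    required = {"marker", "chromosome", "position_cM"}
    if not required <= set(df.columns):
        raise ParseError(f"marker map must have columns {sorted(required)}")
    return MarkerMap.from_frame(df)


def write_genotypes(genotypes: GenotypeMatrix, path, map_path=None) -> None:
    """Strains x markers TSV; optionally write the map sidecar as well."""
    genotypes.to_frame().to_csv(path, sep="\t", index=False)
    if map_path is not None:
        write_marker_map(genotypes.markers, map_path)


def read_genotypes(path, map_path) -> GenotypeMatrix:
    """Read a genotype TSV plus its marker-map sidecar.

    Allele tokens may be +1/-1, 1/-1 or BY/RM; unknown tokens raise a
    :class:`ParseError` carrying the 1-based line number.
    """
    marker_map = read_marker_map(map_path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "strain" not in df.columns:
        raise ParseError("genotype file must have a 'strain' first column")
    markers = [c for c in df.columns if c != "strain"]
    if markers != list(marker_map.marker):
        if sorted(markers) == sorted(marker_map.marker):
            df = df[["strain"] + list(marker_map.marker)]
            markers = list(marker_map.marker)
        else:
            raise ParseError("genotype columns do not match the marker map")
    if len(set(markers)) != len(markers):
        raise ParseError("duplicate marker identifiers in genotype header")
    arr = np.char.strip(df[markers].to_numpy(dtype="U8"))
    plus = (arr == "1") | (arr == "+1") | (arr == "BY")
    minus = (arr == "-1") | (arr == "RM")
    bad = ~(plus | minus)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        # +2 for the header line and 1-based numbering
        raise ParseError(f"unknown allele token {arr[i, j]!r}", line=int(i) + 2)
    codes = np.where(plus, 1, -1).astype(np.int8)
    return GenotypeMatrix(
        codes=codes,
        markers=marker_map,
        strains=df["strain"].to_numpy(dtype=object),
    )


def write_phenotypes(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t", index=False)


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"strain", "dose_uM", "replicate", "layout", "radius"}
    if not required <= set(df.columns):
        raise ParseError(f"phenotype table must have columns {sorted(required)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Generic headered-TSV writer for reports."""
    df.to_csv(path, sep="\t", index=False)


def read_growth_curve(path) -> tuple[np.ndarray, np.ndarray]:
    """Two-column TSV (time_hr, od600) -> (time, od) arrays."""
    df = pd.read_csv(path, sep="\t")
    if not {"time_hr", "od600"} <= set(df.columns):
        raise ParseError("growth curve needs columns time_hr, od600")
    return df["time_hr"].to_numpy(dtype=float), df["od600"].to_numpy(dtype=float)


def _arch_to_dict(arch: QTLArchitecture) -> dict:
    return {
        "additive": [
            {"marker_index": q.marker_index, "beta": {str(k): v for k, v in q.beta.items()}}
            for q in arch.additive
        ],
        "epistatic": [
            {
                "marker_i": p.marker_i,
                "marker_j": p.marker_j,
                "gamma": {str(k): v for k, v in p.gamma.items()},
            }
            for p in arch.epistatic
        ],
        "strain_sd": arch.strain_sd,
        "replicate_sd": arch.replicate_sd,
        "baseline": {str(k): v for k, v in arch.baseline.items()},
    }


def write_architecture(arch: QTLArchitecture, path, seed: int | None = None) -> None:
    """JSON sidecar with the generative truth (and seed) of a simulation."""
    payload = _arch_to_dict(arch)
    if seed is not None:
        payload["seed"] = int(seed)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def read_architecture(path) -> tuple[QTLArchitecture, int | None]:
    payload = json.loads(Path(path).read_text())
    arch = QTLArchitecture(
        additive=tuple(
            AdditiveQTL(q["marker_index"], {float(k): v for k, v in q["beta"].items()})
            for q in payload["additive"]
        ),
        epistatic=tuple(
            EpistaticPair(
                p["marker_i"], p["marker_j"],
                {float(k): v for k, v in p["gamma"].items()},
            )
            for p in payload["epistatic"]
        ),
        strain_sd=payload["strain_sd"],
        replicate_sd=payload["replicate_sd"],
        baseline={float(k): v for k, v in payload["baseline"].items()},
    )
    return arch, payload.get("seed")
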