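"""Minimal LOD-profile figure writer."""

from __future__ import annotations

import numpy as np

from .scan import QTLPeak, ScanResult

__all__ = ["plot_lod_profile"]


def plot_lod_profile(
    scan: ScanResult,
    peaks: list[QTLPeak] | None = None,
    threshold: float | None = None,
    path=None,
):
    """Genome-wide LOD profile with chromosome boundaries and peak intervals.

    Returns the matplotlib figure; saves it when ``path`` is given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3))
    mm = scan.markers
    offset = 0.0
    ticks, labels = [], []
    offsets: dict[str, float] = {}
    for chrom, sl in mm.chromosome_slices().items():
        pos = mm.position_cM[sl] + offset
        ax.plot(pos, scan.lod[sl], lw=0.8, color="#1f4e79")
        ticks.append(pos.mean())
        labels.append(chrom.replace("chr", ""))
        offsets[chrom] = offset
        offset = pos[-1] + 5.0
        ax.axvline(offset - 2.5, color="0.85", lw=0.5)
    if threshold is not None:
        ax.axhline(threshold, color="firebrick", ls="--", lw=0.8)
    for p in peaks or []:
        base = offsets[p.chromosome]
        ax.axvspan(base + p.ci_left_cM, base + p.ci_right_cM, color="#9ecae1", alpha=0.4)
    ax.set_xticks(ticks)
    ax.set_xticklabels(labels, fontsize=7)
    ax.set_ylabel("LOD")
    ax.set_ylim(bottom=0)
    title = f"{scan.method.upper()} scan"
    if scan.dose is not None:
        title += f", {scan.dose:g} µM"
    ax.set_title(title, fontsize=9)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
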