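"""Normalize phenotypes and run a genome-wide LOD scan with peak calling.

Drug-plate radii are regressed on same-strain control radii per plate
layout; the residuals are scanned marker-by-marker with Haley-Knott
regression, genome-wide significance comes from 1000 phenotype
permutations, and peaks get 1.5-LOD drop support intervals.
"""

import doseqtl as dq
from doseqtl.scan import peaks_to_frame

mm = dq.make_marker_map([100.0] * 16, 2.0)
gm = dq.simulate_genotypes(mm, 1008, seed=1)
arch = dq.study_architecture(mm)
dose = 160.0

drug = dq.simulate_phenotypes(gm, arch, dose, n_replicates=4, seed=1)
ctrl = dq.simulate_phenotypes(gm, arch, 0.0, n_replicates=4, seed=1)
y = dq.normalize_to_control(drug, ctrl)

cfg = dq.ScanConfig(lod_cutoff=3.0, n_permutations=1000, alpha=0.05, seed=1)
scan = dq.hk_lod_scan(gm, y, dose=dose)
threshold = dq.permutation_threshold(gm, y, cfg)
peaks = dq.call_peaks(scan, threshold=threshold, config=cfg)

print(f"dose {dose:g} uM: permutation threshold {threshold:.2f} "
      f"(call cutoff max(3, threshold))")
print(peaks_to_frame(peaks).to_string(index=False))
# Each row is a called QTL: the LOD maximum and the interval of markers
# within 1.5 LOD of it. The chrI locus (RM allele beneficial, beta < 0)
# dominates; chrXIV/chrXV appear because their effects are high-dose.
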