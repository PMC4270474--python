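"""Simulate a BY x RM segregant panel with a dose-dependent QTL architecture.

Builds the default 16-chromosome marker grid, draws 1008 haploid
segregants under the Haldane recombination model, and generates replicated
colony-radius measurements at a drug dose and on drug-free control plates.
"""

import doseqtl as dq

mm = dq.make_marker_map([100.0] * 16, spacing_cM=2.0)
gm = dq.simulate_genotypes(mm, n_segregants=1008, seed=1)
arch = dq.study_architecture(mm)

drug = dq.simulate_phenotypes(gm, arch, dose=160.0, n_replicates=4, seed=1)
ctrl = dq.simulate_phenotypes(gm, arch, dose=0.0, n_replicates=4, seed=1)
parents = dq.simulate_parent_panel(arch, dose=160.0, n_replicates=48, seed=1,
                                   n_markers=gm.n_markers)

print(f"markers: {gm.n_markers} on {len(mm.chromosomes())} chromosomes")
print(f"segregants: {gm.n_strains}, BY-allele frequency "
      f"{(gm.codes == 1).mean():.3f}")
print(f"planted QTL: {len(arch.additive)} additive, "
      f"{len(arch.epistatic)} epistatic pairs")
summary = dq.summarize_replicates(drug)
print(f"radius at 160 uM: mean {summary['mean'].mean():.2f}, "
      f"between-strain SD {summary['mean'].std():.2f}")
pm = parents.groupby("strain")["radius"].mean()
print(f"parents at 160 uM: BY {pm['BY']:.2f}, RM {pm['RM']:.2f}")
# The +1/-1 allele coding is balanced by Mendelian segregation; the two
# parents sit close together while segregants spread far wider - the
# transgression substrate created by alleles of opposing effect.
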