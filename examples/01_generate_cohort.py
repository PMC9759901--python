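"""Generate a seeded synthetic case/control cohort with planted triplets.

Builds a small two-group cohort (5 vs 5 samples) with three planted
DMR -> miRNA -> target-mRNA chains, writes it to disk, and prints the
ground truth.  Every downstream example loads or regenerates this cohort.
"""

import methmirnet as mm

cfg = mm.SynthConfig(seed=11, n_mirnas=20, n_mrnas=60, n_triplets=3,
                     coverage_mean=50)
bundle = mm.generate_cohort(cfg)
manifest = mm.write_bundle(bundle, "example_cohort")

print(f"samples: {list(bundle.samples['sample_id'])}")
print(f"CpG sites: {len(bundle.cpg)}, miRNAs: {len(bundle.mirna_counts)}, "
      f"mRNAs: {len(bundle.mrna_counts)}")
print("planted triplets (promoter DMR, miRNA, target, signs):")
for t in bundle.truth.triplets:
    print(f"  {t.dmr_chrom}:{t.dmr_start}-{t.dmr_end}  {t.mirna_id} "
          f"({t.meth_direction} promoter -> {t.mirna_direction} miRNA) "
          f"-> {t.mrna_id} ({t.mrna_direction})")
# Each planted chain is sign-consistent: a hypomethylated promoter
# releases its miRNA (up in cases), which represses its target (down).
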