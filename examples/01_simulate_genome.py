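"""Build a small synthetic chromosome with a planted satellite array and a
planted CRM-like retroelement, then read the truth records back.

The simulator is the test bed for every downstream stage: each feature's
coordinates and realized mutation load are recorded, so detector output can
be scored against construction truth.
"""

from hopcen import syndata, te_annotator

monomer = syndata.random_monomer(seed=1, length=284)
ltr = syndata.random_monomer(seed=2, length=600)
internal = te_annotator.synthetic_internal_sequence(
    te_annotator.CANONICAL_DOMAIN_ORDER, seed=3)

chrom = syndata.ChromSpec(
    "chr1", length=60_000, centromere_center=30_000,
    satellite_plants=(
        syndata.ArrayPlant("SynCEN", monomer, copies=40,
                           per_base_mutation=0.02, start=24_000),),
    element_plants=(
        syndata.ElementPlant("crm1", ltr, internal, start=40_000,
                             target_divergence=0.012, tsd="ACGTA",
                             pbs_motif="TGGTATCAGAGCGGGC"),),
)
genome = syndata.simulate_genome(syndata.GenomeSpec((chrom,), seed=7))

print(f"chromosome length: {len(genome.sequences['chr1'])} bp")
a = genome.arrays[0]
print(f"satellite array {a.family_id}: [{a.start}, {a.end}) "
      f"{a.copies} x {a.monomer_length} bp, "
      f"realized divergence {a.realized_divergence:.4f}")
e = genome.elements[0]
print(f"element {e.element_id}: [{e.start}, {e.end}) "
      f"LTRs {e.ltr5} / {e.ltr3}, TSD {e.tsd}, "
      f"realized LTR divergence {e.realized_divergence:.4f}")
print("The realized divergences are the ground truth the monomer estimator"
      " and the insertion-age estimator are scored against.")
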