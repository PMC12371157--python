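"""Characterize a satellite array: monomer length by periodicity, internal
subunit structure, and similarity between two satellite consensi."""

from hopcen import satellite_tools, syndata

# a 284-bp monomer whose 3' end carries three copies of a 39-bp subunit
subunit = syndata.random_monomer(seed=1, length=39)
monomer = syndata.random_monomer(seed=2, length=284 - 3 * 39) + subunit * 3

plant = syndata.ArrayPlant("SynCEN", monomer, copies=40,
                           per_base_mutation=0.02, start=500)
genome = syndata.simulate_genome(syndata.GenomeSpec(
    (syndata.ChromSpec("c", 13_000, satellite_plants=(plant,)),), seed=3))
array = genome.sequences["c"][500:500 + 284 * 40]

est = satellite_tools.estimate_monomer_length(array, min_period=10,
                                              max_period=500)
print(f"estimated monomer: {est.period} bp "
      f"(peak match fraction {est.match_fraction:.2f}, "
      f"prominence {est.confidence:.2f})")
print(f"copy estimate: {satellite_tools.estimate_copies(len(array), est.period)}")

subs = satellite_tools.detect_subunits(monomer, min_len=20)
for ann in subs:
    print(f"internal subunit: {ann.subunit_length} bp x "
          f"{ann.copies_per_monomer} at offsets {ann.positions}")

other = syndata.random_monomer(seed=9, length=323)
sim = satellite_tools.consensus_similarity(monomer, other)
print(f"similarity to an unrelated 323-bp consensus: "
      f"{sim.identity_pct:.1f}% (best over strands and rotations)")
print("\nThe estimator recovers the planted 284-bp period and the 39-bp"
      " 3'-terminal subunit; unrelated satellite consensi align at roughly"
      " 50-60% identity, the background for tandem-repeat comparisons.")
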