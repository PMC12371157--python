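"""Run the whole analysis end to end on the bundled two-chromosome demo:
chrA carries a type 1 centromere (major satellite + CRM elements only),
chrB additionally carries an accessory satellite array (type 2)."""

from hopcen import centromere_profile as cp

config = cp.demo_config("scratch/demo_report", seed=1)
report = cp.run_pipeline(config)

print("repeat enrichment (ChIP/input):")
print(report["enrichment"].to_string(index=False))

print("\ncentromere typing:")
for name, prof in report["profiles"].items():
    comp = {fam: bp for fam, bp in sorted(prof.bp_per_family.items())}
    print(f"  {name}: {prof.centromere_type}  composition (bp) {comp}"
          + (f"  accessory: {prof.accessory_families}"
             if prof.accessory_families else ""))

print(f"\nintact elements found: {len(report['elements'])}")
print("summit placement within element substructure:")
print(report["summit_categories"].to_string())
print(f"\nreport bundle written to {report['out_dir']}/")
print("\nchrB is called type 2 because its accessory satellite occupies"
      " >= 2% of the domain; all planted elements are recovered with their"
      " autonomy classes and ages.")
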