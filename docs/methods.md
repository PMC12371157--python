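# Methods

This note documents the models, parameter choices and numerical decisions
behind each stage, what the synthetic data does and does not emulate, and
the known limitations.

## Synthetic genomes and reads (`syndata`)

Background sequence is i.i.d. with a configurable GC fraction (default
0.41) and carries no repeat structure, so any repeat called outside a
planted feature is a false positive by construction. Satellite arrays are
planted as `copies × monomer` with independent per-base substitutions;
the realized mutation count is recorded in the truth output. Retroelements
are emitted as `TSD + 5′LTR + PBS + internal + 3′LTR + TSD`; the target
LTR–LTR divergence is split evenly across the two copies (both drift from
the ancestral sequence, which is also what the dating model assumes), and
the realized divergence is the recorded Hamming fraction between the two
emitted copies. Mutations are substitutions only by default — an indel
rate exists but defaults to 0, because LTR insertion dating assumes
substitution-dominated decay. One global seed spawns independent
per-chromosome streams (`numpy.random.SeedSequence`), so outputs are
byte-reproducible and adding a chromosome does not perturb the others.

Reads are single-end, sampled by start position: uniform for the input
channel, piecewise-constant for ChIP with relative weight `chip_fold`
inside `centromere_center ± halfwidth` and 1 elsewhere. Read count per
channel is `depth × genome_length / read_length`. There is no sequencing
error model, no insert-size model and no quality model (FASTQ output uses
a constant quality). Consequently, passing tests demonstrate correctness
of the algorithms under clean, substitution-only data; they do not
demonstrate robustness to indels, sequencing error, nested insertions or
assembly artifacts present in real data.

Fold-enrichment and depth are nowhere published for this assay; the
defaults (fold 20, depth 20×) are fixture choices in the simulator, not
empirical claims.

## Repeat enrichment (`enrichment`)

Hit counting is alignment-free: a read is assigned to the repeat sharing
the most canonical *k*-mers (k = 21), provided the count reaches
`min_fraction` of the read's k-mer positions; ties go to the
lexicographically smallest repeat id; each read counts toward at most one
repeat. Canonical k-mers make the assay strandless. The default
`min_fraction = 0.5` is a conservative filter appropriate for reads that
match a consensus nearly exactly; for reads carrying ~2% substitutions two
well-spaced mutations already destroy more than half the 21-mers of a
100-bp read, so analyses in that regime should lower the threshold (the
oracle-equivalence tests use `min_fraction = 0.1`, which still rejects
random background by a wide margin — a background read shares essentially
zero 21-mers with a consensus).

The normalized ratio divides each channel's per-repeat hits by that
channel's total read count; it is scale-invariant in the totals. When the
input channel has zero hits the ratio is reported as *undefined* rather
than infinite, and undefined records rank last.

A note on magnitudes at desk scale: the attainable normalized ratio is
bounded by `fold / E[weight]`, where the mean ChIP weight over the genome
grows with the fraction of the genome inside the enriched interval. On a
400-kb demo chromosome with an 80-kb interval at fold 20 the ceiling is
≈ 4, which is why the demo flags candidates at ratio ≥ 3 rather than ≥ 10;
on a real multi-Gb genome the same statistic reaches the tens.

## Summit and domain calling (`domain_caller`)

Reads are binned by start position (default 10 kb). The per-bin score is a
pseudocounted, depth-normalized log2 ratio, boxcar-smoothed over 5 bins;
the summit is the midpoint of the max-score bin, leftmost on ties, with
equal-score secondary peaks reported in diagnostics. Degenerate inputs are
flagged rather than guessed at: an all-zero ChIP track yields *no
enrichment* and no summit; a perfectly flat profile yields bin 0 plus a
*flat profile* flag. The score is antisymmetric under swapping the
channels when totals are equal.

A caveat that matters for recovery experiments: when the true enriched
interval is much wider than a bin, its smoothed profile has a plateau and
the argmax within the plateau is decided by sampling noise — the summit is
then defined only up to the plateau width. Recovery tests therefore plant
an interval matched to the smoothing extent (halfwidth 25 kb = 5 bins,
centered on a bin midpoint), which makes the smoothed peak a triangle with
a unique apex. Bin size 10 kb, pseudocount 1 and smoothing 5 bins are
defaults chosen for 100–150-bp reads at ≥ 10×; all are arguments.

The centromeric domain is deliberately not adaptive: a fixed ± 3 Mbp
window around the summit, clipped at chromosome ends and flagged when
clipped. Morphology cut-offs (1.7, 3.0 on the long/short arm ratio) are
the classical cytogenetic bands and are exposed as parameters.

## Satellite analysis (`satellite_tools`)

Periodicity uses the shifted-match profile rather than an FFT: exact,
explainable, and robust in the few-percent mutation regime; the profile
value at the true period is ≈ (1−m)² for per-base mutation m. The smallest
period reaching 80% of the peak's prominence over the background median is
returned; larger significant periods (integer harmonics) are reported as
such. A peak prominence below 0.10 yields *no period* — on i.i.d.
sequence the profile is flat near 0.25 with fluctuations well below that
threshold.

Percent identity everywhere is matches / alignment columns (gaps count
against identity) under affine-gap alignment with match +1, mismatch −1,
gap open −2, gap extend −0.5. Heatmap windows default to 5 kb / 2 kb
steps; sparse tilings (step > window) are allowed but flagged.

Subunit detection self-compares the monomer at every shift in
`[min_len, max_len]` and looks for runs matching at ≥ 80%; run edges are
trimmed where the local 8-bp identity drops below 0.9, because chance
matches in the flanking sequence otherwise extend a run past the true
boundary (reported offsets can still be off by one base when the adjacent
flank base matches by chance). When the repeated block tiles ≥ 90% of the
monomer, the monomer is flagged as itself tandem and the shift is proposed
as the true monomer length.

Consensus similarity searches both strands and all cyclic rotations of the
second sequence (coarse stride 4, then ±3 refinement) because tandem-array
consensi have arbitrary phase.

## LTR element annotation (`te_annotator`)

Detection is a from-scratch seeded self-comparison. Exact 15-mers shared
by two positions 1–25 kb apart are collected as anchors, clustered on a
common offset band (±16 bp, valid because indels are not modelled), and
chained; block boundaries are refined by X-drop extension (match +1,
mismatch −2, drop 12). A candidate survives if the two blocks are 100–3000
bp, align at ≥ 85% identity, and pass a self-repeat screen: a block (plus
up to 600 bp of following context) containing a sustained internal
self-match of ≥ 100 bp at ≥ 80% is rejected, which removes both satellite
array segments masquerading as repeat pairs and composite blocks spanning
two near-identical whole elements.

TSD search goes beyond checking the X-drop boundaries: every 4–6-bp exact
direct repeat within a boundary jitter window is scored by
`TSD length + Δ`, where Δ is the LTR-pair alignment change (match +1,
mismatch −2) implied by moving the boundaries to fit that TSD. This lets a
true TSD several bases inside an overshot boundary win, because the
overshoot region scores poorly as LTR sequence. When a chance flank match
makes the t−1/t/t+1 interpretations exactly equally likely, the tie goes
to the TSD length nearest 5 bp — the characteristic chromoviral TSD — then
to the smaller boundary shift. Candidates without any TSD are kept but
flagged.

Conflicts are resolved globally by weighted interval scheduling
(maximum-weight set of non-overlapping candidates; an exact TSD adds a
bonus), not greedily: two genuine elements then always beat one composite
pairing that would block both. A candidate whose putative internal region
wholly contains a TSD-validated candidate is vetoed outright (nested
insertions are out of scope, so the compact interpretation wins). Solo
LTRs are reported separately: matches of a found element's LTR elsewhere
in the sequence, outside any element span.

PBS detection scans a 30-bp window 3′ of the 5′ LTR for the best catalog
motif with ≤ 1 mismatch. Protein domains are called by sliding each
amino-acid consensus profile ungapped along all six translation frames;
presence requires ≥ 55% identity (planted consensi score 1.0, random
translations stay below ~0.3 for 50-aa profiles). The bundled PBS motifs
and domain profiles are synthetic stand-ins — the published versions exist
only as figure graphics — with the structure (six domains, four dominant
PBS motifs, PBS4 most frequent among nonautonomous copies) preserved.

Insertion age: the two LTRs are globally aligned; d is the mismatch
fraction over non-gap columns; the divergence correction defaults to
Kimura 2-parameter (transitions/transversions counted on the alignment),
with Jukes–Cantor and raw available; age = K / (2r) at
r = 6.1 × 10⁻⁹ substitutions/site/year, reported in years and Ma. Pairs
aligning below 60% identity are flagged unreliable and left undated.
Saturated corrections (log argument ≤ 0) return infinity rather than a
number.

The PBS summary computes the detection percentage jointly over all
elements (detected / total), which is the reading of the published
80.9% figure that reproduces it (543/671), and reports the share of
PBS-bearing elements in the four most frequent motif groups.

## Composition and typing (`centromere_profile`)

Masking approximates RepeatMasker's adjudication: per family and strand,
exact 13-mer seeds nominate candidate regions, tiled edlib alignments of
the consensus produce scored hits (identity × length), and hits claim
still-uncovered territory in descending score order (ties to the
lexicographically smaller family), keeping only fragments ≥ 30 bp at
≥ 70% identity. The procedure is deterministic and idempotent. Composition
is reported as bp per family per domain, with fractions derived at report
time.

The type-2 rule — any accessory satellite at ≥ 2% of domain bp, inclusive
— is this package's quantitative operationalization of a qualitative
distinction (centromeres built from the two major repeats alone versus
those additionally carrying chromosome-specific arrays); the threshold is
an exposed parameter. Summit assignment uses half-open intervals with
precedence coding > ltr as a safety rule; domains never overlap LTRs in
well-formed elements.

`run_pipeline` chains all stages from a config (dict or YAML) and writes a
plain-text report bundle (enrichment table, domain BED, morphology,
satellite monomers, element table, age histogram, composition, summit
table, run log). It drives the synthetic generator; for external
assemblies and mapped reads the per-stage APIs are the interface, since
read mapping itself is outside this package's scope. Reruns with the same
config and seed are byte-identical; the demo (two 400-kb chromosomes, one
type 1 and one type 2 centromere, six elements, ~10 s on one CPU) is the
end-to-end fixture.

## Problem sizes used in tests

The suite runs at desk scale by design: 2-Mb chromosomes at 10× for summit
recovery (20 seeds), a 10-Mb chromosome at 10× for the 6-Mbp domain check,
20-element cohorts (~150 kb) for structure recovery, 30-kb repeat-free
backgrounds (20 seeds) for false-positive control, and ≤ 500 reads for
oracle-equivalence checks. These sizes exercise every code path; genome-
scale claims (multi-Gb assemblies, hundreds of elements per centromere)
are represented by the same statistics at smaller n, not reproduced.

## Known limitations

- No indel handling in element boundary refinement (offset bands assume
  substitution-only divergence); real degraded elements would need gapped
  chaining.
- Boundary placement at zero divergence is ambiguous by ±1 bp whenever a
  flank base chance-matches its partner; the TSD-anchored scoring removes
  most, but not provably all, of these cases.
- LTRs that internally contain two or more tandem copies of a satellite
  monomer would trip the self-repeat screen; single embedded copies (the
  common case for CRM LTRs carrying centromeric repeat fragments) are
  unaffected.
- The masker reports one best hit per tile and does not split co-optimal
  overlaps between families; sub-30-bp fragments are never masked.
- No paired-end, quality, or sequencing-error modelling; no polyploidy or
  heterozygosity.
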