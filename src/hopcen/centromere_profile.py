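"""Centromeric-domain composition profiling and the end-to-end pipeline.

``mask_domain`` is a RepeatMasker-style pass over a domain sequence:
seeded local alignments of every library consensus (both strands) are
tiled greedily by descending score into non-overlapping intervals, giving
bp-per-family composition.  ``classify_centromere_type`` separates the two
centromere organizations seen in hop: type 1 centromeres built from the
two major repeats only (the centromeric satellite plus the centrophilic
CRM retroelement), and type 2 centromeres additionally carrying
chromosome-specific accessory satellite arrays.  ``assign_summits`` places
CENH3 summits into element substructure (LTR / coding / spacer).
``run_pipeline`` chains every stage on a config and writes a plain-text
report bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import edlib
import numpy as np
import pandas as pd

from . import domain_caller, enrichment, satellite_tools, syndata, te_annotator
from ._align import revcomp
from .enrichment import RepeatConsensus
from .io import write_bed, write_fasta
from .te_annotator import LTRElement

DEFAULT_MIN_MASK_LEN = 30
DEFAULT_MIN_MASK_IDENTITY = 0.70
DEFAULT_TYPE2_FRACTION = 0.02


@dataclass
class MaskedInterval:
    family_id: str
    start: int
    end: int
    strand: str
    identity_pct: float


@dataclass
class CompositionProfile:
    chromosome: str
    domain_start: int
    domain_end: int
    bp_per_family: dict[str, int]
    unassigned_bp: int
    intervals: list[MaskedInterval] = field(default_factory=list)
    centromere_type: str = ""
    accessory_families: list[str] = field(default_factory=list)

    @property
    def domain_length(self) -> int:
        return self.domain_end - self.domain_start

    def fraction(self, family_id: str) -> float:
        return self.bp_per_family.get(family_id, 0) / self.domain_length


@dataclass
class SummitAssignment:
    summit: int
    category: str                # ltr | coding | spacer | outside_element
    element_id: str | None


# ---------------------------------------------------------------------------
# Masking


def _seed_regions(domain: str, consensus: str, k: int = 13) -> list[tuple[int, int]]:
    """Merged candidate regions of the domain sharing exact k-mers with the
    consensus (one strand)."""
    kmers = {consensus[i:i + k] for i in range(len(consensus) - k + 1)}
    hits = [i for i in range(len(domain) - k + 1) if domain[i:i + k] in kmers]
    if not hits:
        return []
    pad = len(consensus)
    regions = []
    start = prev = hits[0]
    for h in hits[1:]:
        if h - prev > pad:
            regions.append((max(0, start - pad // 2), min(len(domain), prev + k + pad // 2)))
            start = h
        prev = h
    regions.append((max(0, start - pad // 2), min(len(domain), prev + k + pad // 2)))
    return regions


def _family_hits(domain: str, family: RepeatConsensus, min_identity: float,
                 min_len: int) -> list[MaskedInterval]:
    hits = []
    clen = len(family.sequence)
    for strand, cons in (("+", family.sequence), ("-", revcomp(family.sequence))):
        for r0, r1 in _seed_regions(domain, cons):
            step = max(clen // 2, min_len)
            window = 2 * clen
            pos = r0
            while pos < r1:
                target = domain[pos:pos + window]
                if len(target) < min_len:
                    break
                res = edlib.align(cons, target, mode="HW", task="locations")
                if res["editDistance"] >= 0:
                    ident = 1.0 - res["editDistance"] / clen
                    if ident >= min_identity:
                        a, b = res["locations"][0]
                        b += 1
                        if b - a >= min_len:
                            hits.append(MaskedInterval(
                                family_id=family.id, start=pos + a,
                                end=pos + b, strand=strand,
                                identity_pct=100.0 * ident))
                pos += step
    return hits


def mask_domain(domain_sequence: str, library: list[RepeatConsensus],
                min_len: int = DEFAULT_MIN_MASK_LEN,
                min_identity: float = DEFAULT_MIN_MASK_IDENTITY,
                chromosome: str = "", domain_start: int = 0
                ) -> CompositionProfile:
    """Greedy non-overlapping repeat masking of a domain sequence.

    Candidate local alignments from every family are sorted by descending
    score (identity x length, ties to the lexicographically smaller family
    id) and claim whatever part of the domain is still uncovered; a
    candidate surviving only as fragments shorter than ``min_len`` is
    dropped.  Coordinates in the output are domain-relative plus
    ``domain_start``.
    """
    domain = domain_sequence.upper()
    n = len(domain)
    all_hits: list[MaskedInterval] = []
    for family in library:
        all_hits.extend(_family_hits(domain, family, min_identity, min_len))
    all_hits.sort(key=lambda h: (-(h.identity_pct / 100.0) * (h.end - h.start),
                                 h.family_id, h.start))
    covered = np.zeros(n, dtype=bool)
    accepted: list[MaskedInterval] = []
    for hit in all_hits:
        span = ~covered[hit.start:hit.end]
        if not span.any():
            continue
        # claim uncovered runs of the candidate interval, each >= min_len
        idx = np.flatnonzero(span)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_starts = np.concatenate(([0], breaks + 1))
        run_ends = np.concatenate((breaks, [len(idx) - 1]))
        for rs, re_ in zip(run_starts, run_ends):
            a, b = hit.start + idx[rs], hit.start + idx[re_] + 1
            if b - a >= min_len:
                covered[a:b] = True
                accepted.append(MaskedInterval(hit.family_id, a, b, hit.strand,
                                               hit.identity_pct))
    accepted.sort(key=lambda h: h.start)
    bp: dict[str, int] = {}
    for h in accepted:
        bp[h.family_id] = bp.get(h.family_id, 0) + int(h.end - h.start)
    for h in accepted:
        h.start += domain_start
        h.end += domain_start
    return CompositionProfile(
        chromosome=chromosome, domain_start=domain_start,
        domain_end=domain_start + n, bp_per_family=bp,
        unassigned_bp=int((~covered).sum()), intervals=accepted)


# ---------------------------------------------------------------------------
# Centromere typing


def classify_centromere_type(profile: CompositionProfile,
                             accessory_families: list[str],
                             min_fraction: float = DEFAULT_TYPE2_FRACTION
                             ) -> str:
    """Type 2 when any accessory satellite family occupies >= ``min_fraction``
    of the domain (inclusive); type 1 otherwise.  Triggering families are
    recorded on the profile."""
    triggers = [fam for fam in accessory_families
                if profile.fraction(fam) >= min_fraction]
    profile.accessory_families = triggers
    profile.centromere_type = "type2" if triggers else "type1"
    return profile.centromere_type


# ---------------------------------------------------------------------------
# Summit assignment


def assign_summits(summits: list[tuple[str, int]] | list[int],
                   elements: list[LTRElement],
                   domain_positions: dict[str, dict[str, int]] | None = None
                   ) -> tuple[list[SummitAssignment], pd.Series]:
    """Assign each summit to element substructure.

    Categories (half-open intervals): inside a protein-domain interval ->
    coding; inside either LTR -> ltr; inside the element but neither ->
    spacer; otherwise outside_element.  Precedence coding > ltr.  Per-element
    coding intervals come from ``domain_positions`` as
    {element_id: {domain: internal_offset}}; each domain interval spans the
    encoded profile length.
    """
    if summits and isinstance(summits[0], tuple):
        points = [s for _, s in summits]
    else:
        points = list(summits)
    profiles = te_annotator.load_domain_profiles()
    assignments = []
    for summit in points:
        category, eid = "outside_element", None
        for el in elements:
            if not el.start <= summit < el.end:
                continue
            eid = el.element_id
            coding = False
            offsets = (domain_positions or {}).get(el.element_id, {})
            for dom, off in offsets.items():
                a = el.internal[0] + off
                b = a + 3 * len(profiles.get(dom, ""))
                if a <= summit < b:
                    coding = True
                    break
            if coding:
                category = "coding"
            elif (el.ltr5[0] <= summit < el.ltr5[1]
                  or el.ltr3[0] <= summit < el.ltr3[1]):
                category = "ltr"
            else:
                category = "spacer"
            break
        assignments.append(SummitAssignment(summit, category, eid))
    freq = pd.Series([a.category for a in assignments],
                     dtype="object").value_counts()
    freq = freq.reindex(["spacer", "ltr", "coding", "outside_element"],
                        fill_value=0)
    return assignments, freq


# ---------------------------------------------------------------------------
# Pipeline


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    pass


REQUIRED_CONFIG_KEYS = ("library", "out_dir")


def run_pipeline(config: dict | str | Path) -> dict:
    """Run every stage end to end and write a plain-text report bundle.

    ``config`` is a mapping (or path to a YAML file) with keys:

    * ``simulate``: syndata GenomeSpec/ReadSimSpec parameters (see
      :func:`demo_config`), or ``genome``/``chip_reads``/``input_reads``
      FASTA paths;
    * ``library``: repeat library FASTA path or list of RepeatConsensus;
    * ``out_dir``: report directory;
    * optional ``seed``, ``bin_size``, ``min_ratio``, ``accessory_families``,
      ``major_families``.

    Any stage failure aborts with the stage name and the offending input.
    Identical config and seed give byte-identical TSV outputs.
    """
    import yaml

    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    for key in REQUIRED_CONFIG_KEYS:
        if key not in config:
            raise ConfigError(f"config missing required key: {key!r}")
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    log: list[str] = [f"hopcen pipeline | seed={seed}"]
    report: dict = {"out_dir": out_dir}

    def stage(name):
        log.append(f"stage: {name}")

    try:
        stage("syndata")
        if "simulate" in config:
            genome, chip, inp = _simulate_from_config(config["simulate"], seed)
            genome.write(out_dir, "genome")
        else:
            from .io import read_fasta
            genome = syndata.SimulatedGenome(
                spec=syndata.GenomeSpec(chromosomes=(), seed=seed),
                sequences=read_fasta(config["genome"]), arrays=[], elements=[])
            chip = inp = None
    except ConfigError:
        raise
    except Exception as exc:
        raise StageError(f"stage syndata failed: {exc}") from exc

    library = config["library"]
    if not isinstance(library, list):
        try:
            library = enrichment.load_library(library)
        except Exception as exc:
            raise StageError(f"stage enrichment failed on library input: {exc}") from exc

    try:
        stage("enrichment")
        chip_hits, chip_total = enrichment.count_hits(
            chip.sequences(genome), library)
        input_hits, input_total = enrichment.count_hits(
            inp.sequences(genome), library)
        records = enrichment.build_hit_records(chip_hits, input_hits,
                                               chip_total, input_total)
        ranked = enrichment.rank_candidates(records,
                                            config.get("min_ratio", 10.0))
        table = enrichment.enrichment_table(ranked, library)
        table.to_csv(out_dir / "enrichment_table.tsv", sep="\t", index=False)
        report["enrichment"] = table
    except Exception as exc:
        raise StageError(f"stage enrichment failed: {exc}") from exc

    try:
        stage("domain_caller")
        bin_size = int(config.get("bin_size", 10_000))
        tracks = domain_caller.bin_coverage(chip.positions(), inp.positions(),
                                            genome.lengths, bin_size)
        domains, morphology_rows = {}, []
        for name, track in tracks.items():
            call = domain_caller.call_summit(track)
            if call.summit is None:
                raise StageError(f"no enrichment on chromosome {name}")
            dom = domain_caller.extract_domain(call.summit, genome.lengths[name],
                                               chromosome=name,
                                               enrichment_score=call.enrichment_score)
            domains[name] = dom
            m = domain_caller.classify_morphology(call.summit,
                                                  genome.lengths[name], name)
            morphology_rows.append({
                "chromosome": name, "p_arm": m.p_arm, "q_arm": m.q_arm,
                "arm_ratio": round(m.arm_ratio, 3), "class": m.morphology_class})
        write_bed([(d.chromosome, d.domain_start, d.domain_end, "centromere",
                    round(d.enrichment_score, 3), "+")
                   for d in domains.values()], out_dir / "domains.bed")
        pd.DataFrame(morphology_rows).to_csv(out_dir / "morphology.tsv",
                                             sep="\t", index=False)
        report["domains"] = domains
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage domain_caller failed: {exc}") from exc

    try:
        stage("satellite_tools")
        sat_rows = []
        for fam in library:
            if fam.repeat_class != "satellite":
                continue
            est = satellite_tools.estimate_monomer_length(
                fam.sequence * 6, min_period=10,
                max_period=min(500, len(fam.sequence) * 2))
            sat_rows.append({"family": fam.id,
                             "library_monomer": fam.monomer_length,
                             "estimated_monomer": est.period,
                             "confidence": round(est.confidence, 3)})
        pd.DataFrame(sat_rows).to_csv(out_dir / "satellite_monomers.tsv",
                                      sep="\t", index=False)
    except Exception as exc:
        raise StageError(f"stage satellite_tools failed: {exc}") from exc

    try:
        stage("te_annotator")
        all_elements, age_values = [], []
        for name, dom in domains.items():
            seq = genome.sequences[name][dom.domain_start:dom.domain_end]
            elements, _ = te_annotator.find_ltr_elements(seq, chromosome=name)
            te_annotator.annotate_elements(seq, elements)
            for el in elements:
                el.start += dom.domain_start
                el.end += dom.domain_start
                el.ltr5 = (el.ltr5[0] + dom.domain_start, el.ltr5[1] + dom.domain_start)
                el.ltr3 = (el.ltr3[0] + dom.domain_start, el.ltr3[1] + dom.domain_start)
                if not math.isnan(el.age_years):
                    age_values.append(el.age_years / 1e6)
            all_elements.extend(elements)
        te_annotator.elements_to_frame(all_elements).to_csv(
            out_dir / "elements.tsv", sep="\t", index=False)
        edges = np.arange(0, 10.5, 0.5)
        hist, _ = np.histogram(age_values, bins=edges)
        pd.DataFrame({"age_ma_low": edges[:-1], "age_ma_high": edges[1:],
                      "count": hist}).to_csv(out_dir / "age_histogram.tsv",
                                             sep="\t", index=False)
        report["elements"] = all_elements
    except Exception as exc:
        raise StageError(f"stage te_annotator failed: {exc}") from exc

    try:
        stage("centromere_profile")
        major = config.get("major_families", [])
        accessory = config.get("accessory_families",
                               [f.id for f in library
                                if f.repeat_class == "satellite"
                                and f.id not in major])
        comp_rows, profiles = [], {}
        for name, dom in domains.items():
            seq = genome.sequences[name][dom.domain_start:dom.domain_end]
            prof = mask_domain(seq, library, chromosome=name,
                               domain_start=dom.domain_start)
            classify_centromere_type(prof, accessory)
            profiles[name] = prof
            for fam in sorted(set(list(prof.bp_per_family) + [f.id for f in library])):
                comp_rows.append({
                    "chromosome": name, "family": fam,
                    "bp": prof.bp_per_family.get(fam, 0),
                    "fraction": round(prof.fraction(fam), 4),
                    "centromere_type": prof.centromere_type})
        pd.DataFrame(comp_rows).to_csv(out_dir / "composition.tsv", sep="\t",
                                       index=False)
        summit_points = [(d.chromosome, d.summit) for d in domains.values()]
        assignments, freq = assign_summits(
            summit_points, report.get("elements", []))
        pd.DataFrame([{"summit": a.summit, "category": a.category,
                       "element": a.element_id or ""} for a in assignments]
                     ).to_csv(out_dir / "summits.tsv", sep="\t", index=False)
        report["profiles"] = profiles
        report["summit_categories"] = freq
    except Exception as exc:
        raise StageError(f"stage centromere_profile failed: {exc}") from exc

    import hopcen

    log.append(f"hopcen version: {hopcen.__version__}")
    log.append(f"parameters: bin_size={config.get('bin_size', 10_000)} "
               f"min_ratio={config.get('min_ratio', 10.0)}")
    (out_dir / "run_log.txt").write_text("\n".join(log) + "\n")
    return report


def _simulate_from_config(sim: dict, seed: int):
    chroms = []
    for c in sim["chromosomes"]:
        sat = tuple(syndata.ArrayPlant(**p) for p in c.get("satellite_plants", []))
        els = tuple(syndata.ElementPlant(**p) for p in c.get("element_plants", []))
        chroms.append(syndata.ChromSpec(
            name=c["name"], length=c["length"],
            centromere_center=c.get("centromere_center"),
            satellite_plants=sat, element_plants=els))
    gspec = syndata.GenomeSpec(chromosomes=tuple(chroms), seed=seed,
                               gc_background=sim.get("gc_background", 0.41))
    genome = syndata.simulate_genome(gspec)
    rspec = syndata.ReadSimSpec(
        read_length=sim.get("read_length", 100),
        input_depth=sim.get("depth", 8.0),
        chip_fold=sim.get("chip_fold", 20.0),
        chip_interval_halfwidth=sim.get("chip_interval_halfwidth", 50_000),
        seed=seed + 1)
    chip, inp = syndata.simulate_reads(genome, rspec)
    return genome, chip, inp


# ---------------------------------------------------------------------------
# Bundled demo: one type 1 and one type 2 centromere


def demo_monomers(seed: int = 7) -> dict[str, str]:
    """Synthetic stand-in monomers with the canonical lengths (the published
    consensi are not printed): CEN 284 bp, accessory satellites 323/320/324 bp,
    pericentromeric 120 bp."""
    lengths = {"SynCEN": 284, "Syn293": 323, "Syn85": 320, "Syn40": 324,
               "SynTR120": 120}
    return {name: syndata.random_monomer(seed + i, ln)
            for i, (name, ln) in enumerate(lengths.items())}


def demo_config(out_dir: str | Path, seed: int = 1) -> dict:
    """A two-chromosome demo: chrA has a type 1 centromere (major satellite +
    CRM-like elements only); chrB additionally carries an accessory satellite
    array (type 2)."""
    mono = demo_monomers()
    ltr = syndata.random_monomer(seed + 100, 600)
    crm_internal = te_annotator.synthetic_internal_sequence(
        ("GAG", "PRO", "CHD"), seed=seed + 201)
    catalog = te_annotator.load_pbs_catalog()
    pbs = dict(catalog.motifs)

    def elements(prefix, center, seed0):
        # distinct spacer randomness per copy and irregular spacing, as in a
        # real insertion landscape
        specs = [("a1", te_annotator.CANONICAL_DOMAIN_ORDER, "PBS1", 0.004, 6_200),
                 ("n1", ("GAG", "PRO", "CHD"), "PBS4", 0.002, 8_700),
                 ("n2", ("GAG", "PRO", "CHD"), "PBS4", 0.006, 7_400)]
        plants, pos = [], center - 40_000
        for i, (name, domains, motif, div, gap) in enumerate(specs):
            internal = te_annotator.synthetic_internal_sequence(
                domains, seed=seed0 + i)
            plants.append(dict(
                element_id=f"{prefix}_{name}", ltr_seq=ltr,
                internal_seq=internal, start=pos, target_divergence=div,
                tsd="ACGTA", pbs_motif=pbs[motif],
                autonomy=("autonomous" if len(domains) == 6
                          else "nonautonomous_dominant")))
            pos += len(internal) + 2 * 600 + 2 * 5 + len(pbs[motif]) + gap
        return plants

    chromosomes = [
        {"name": "chrA", "length": 400_000, "centromere_center": 200_000,
         "satellite_plants": [
             dict(family_id="SynCEN", monomer=mono["SynCEN"], copies=60,
                  per_base_mutation=0.02, start=190_000)],
         "element_plants": elements("A", 250_000, seed + 300)},
        {"name": "chrB", "length": 400_000, "centromere_center": 120_000,
         "satellite_plants": [
             dict(family_id="SynCEN", monomer=mono["SynCEN"], copies=40,
                  per_base_mutation=0.02, start=112_000),
             dict(family_id="Syn293", monomer=mono["Syn293"], copies=80,
                  per_base_mutation=0.02, start=126_000)],
         "element_plants": elements("B", 195_000, seed + 310)},
    ]
    library = [RepeatConsensus("SynCEN", "satellite", mono["SynCEN"], 284),
               RepeatConsensus("Syn293", "satellite", mono["Syn293"], 323),
               RepeatConsensus("SynCRM1", "TE", ltr + crm_internal[:800],
                               "variable")]
    return {
        "simulate": {"chromosomes": chromosomes, "read_length": 100,
                     "depth": 8.0, "chip_fold": 20.0,
                     "chip_interval_halfwidth": 40_000},
        "library": library,
        "min_ratio": 3.0,   # at demo scale the enriched interval is a large
                            # genome fraction, which dilutes attainable ratios
        "major_families": ["SynCEN", "SynCRM1"],
        "accessory_families": ["Syn293", "Syn85", "Syn40", "SynTR120"],
        "seed": seed,
        "out_dir": str(out_dir),
    }
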