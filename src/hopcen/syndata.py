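"""Synthetic genomes, truth annotations and ChIP/input read sets.

The simulator emulates the data regime the downstream analysis assumes:
monocentric chromosomes with a single CENH3-enriched interval, tandem
satellite arrays planted with a chosen monomer, copy number and per-base
substitution rate, and CRM-like LTR retroelements planted with a chosen
LTR-LTR divergence, target-site duplication (TSD) and primer binding site
(PBS).  Reads are sampled alignment-free: input uniformly over the genome,
ChIP with a constant fold weight inside the centromeric interval.

Background sequence is i.i.d. with a specified GC content and carries no
repeat structure, so any repeat the downstream detectors report outside a
planted feature is a false positive by construction.  Mutations are
substitutions only by default (an indel rate exists but defaults to 0):
LTR insertion-age dating assumes substitution-dominated decay.
Everything is reproducible from one integer seed; per-chromosome random
streams are spawned deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from ._align import revcomp
from .io import gff3_line, write_bed, write_fasta, write_fastq, write_gff3

BASES = np.frombuffer(b"ACGT", dtype="S1")


# ---------------------------------------------------------------------------
# Specs


@dataclass(frozen=True)
class ArrayPlant:
    """A tandem satellite array to plant: ``copies`` repeats of ``monomer``,
    each base substituted independently with probability ``per_base_mutation``."""

    family_id: str
    monomer: str
    copies: int
    per_base_mutation: float = 0.0
    start: int = 0

    def __post_init__(self):
        if self.copies < 1:
            raise ValueError(f"ArrayPlant {self.family_id}: copies must be >= 1")
        if not 0.0 <= self.per_base_mutation < 1.0:
            raise ValueError(f"ArrayPlant {self.family_id}: bad mutation rate")

    @property
    def length(self) -> int:
        return self.copies * len(self.monomer)


@dataclass(frozen=True)
class ElementPlant:
    """An LTR retroelement to plant.

    Emitted structure: TSD + 5'LTR + PBS + internal + 3'LTR + TSD.
    ``target_divergence`` substitutions/site are applied to the 3' LTR copy;
    the realized divergence (mismatches / LTR length) is recorded in truth.
    """

    element_id: str
    ltr_seq: str
    internal_seq: str
    start: int = 0
    target_divergence: float = 0.0
    tsd: str = "ACGTA"
    pbs_motif: str = ""
    autonomy: str = "autonomous"

    def __post_init__(self):
        if not 4 <= len(self.tsd) <= 6:
            raise ValueError(f"ElementPlant {self.element_id}: TSD must be 4-6 bp")
        if self.autonomy not in {"autonomous", "nonautonomous_dominant",
                                 "nonautonomous_minor"}:
            raise ValueError(f"ElementPlant {self.element_id}: bad autonomy class")

    @property
    def length(self) -> int:
        return (2 * len(self.tsd) + 2 * len(self.ltr_seq) + len(self.pbs_motif)
                + len(self.internal_seq))


@dataclass(frozen=True)
class ChromSpec:
    name: str
    length: int
    centromere_center: int | None = None
    satellite_plants: tuple[ArrayPlant, ...] = ()
    element_plants: tuple[ElementPlant, ...] = ()


@dataclass(frozen=True)
class GenomeSpec:
    chromosomes: tuple[ChromSpec, ...]
    seed: int = 0
    gc_background: float = 0.41


@dataclass(frozen=True)
class ReadSimSpec:
    read_length: int = 150
    input_depth: float = 20.0
    chip_fold: float = 20.0
    chip_interval_halfwidth: int = 50_000
    seed: int = 0


# ---------------------------------------------------------------------------
# Truth records


@dataclass(frozen=True)
class ArrayTruth:
    chromosome: str
    family_id: str
    start: int
    end: int
    copies: int
    monomer_length: int
    mutations: int
    realized_divergence: float


@dataclass(frozen=True)
class ElementTruth:
    chromosome: str
    element_id: str
    start: int          # element span including TSDs
    end: int
    tsd: str
    ltr5: tuple[int, int]
    ltr3: tuple[int, int]
    pbs: tuple[int, int] | None
    internal: tuple[int, int]
    autonomy: str
    pbs_motif: str
    target_divergence: float
    realized_divergence: float


@dataclass
class SimulatedGenome:
    spec: GenomeSpec
    sequences: dict[str, str]
    arrays: list[ArrayTruth]
    elements: list[ElementTruth]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def centromere_centers(self) -> dict[str, int]:
        return {c.name: c.centromere_center for c in self.spec.chromosomes
                if c.centromere_center is not None}

    def write(self, out_dir: str | Path, prefix: str = "genome") -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.sequences, out / f"{prefix}.fasta")
        write_bed(
            [(a.chromosome, a.start, a.end, a.family_id, a.copies, "+")
             for a in self.arrays],
            out / f"{prefix}_arrays.bed")
        lines = []
        for el in self.elements:
            parent = f"ID={el.element_id}"
            lines.append(gff3_line(el.chromosome, "syndata", "LTR_retrotransposon",
                                   el.start, el.end, attributes=parent))
            t = len(el.tsd)
            children = [
                ("target_site_duplication", el.start, el.start + t),
                ("long_terminal_repeat", *el.ltr5),
                ("long_terminal_repeat", *el.ltr3),
                ("repeat_region", *el.internal),
                ("target_site_duplication", el.end - t, el.end),
            ]
            if el.pbs is not None:
                children.insert(2, ("primer_binding_site", *el.pbs))
            for i, (ftype, s, e) in enumerate(children):
                lines.append(gff3_line(el.chromosome, "syndata", ftype, s, e,
                                       attributes=f"ID={el.element_id}.{i};Parent={el.element_id}"))
        write_gff3(lines, out / f"{prefix}_elements.gff3")


# ---------------------------------------------------------------------------
# Genome simulation


def random_sequence(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> tuple[str, int]:
    """Substitute each base independently with probability ``rate``."""
    if rate <= 0:
        return seq, 0
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.size) < rate
    n = int(hit.sum())
    if n:
        # shift each hit base by 1-3 positions in ACGT order: always a change
        idx = np.searchsorted(BASES, arr[hit])
        arr[hit] = BASES[(idx + rng.integers(1, 4, size=n)) % 4]
    return arr.tobytes().decode(), n


def _build_array(rng, plant: ArrayPlant) -> tuple[str, int]:
    seq, n = _mutate(rng, plant.monomer.upper() * plant.copies, plant.per_base_mutation)
    return seq, n


def _build_element(rng, plant: ElementPlant) -> tuple[str, dict, float]:
    # both LTR copies drift from the ancestral sequence: half the target
    # divergence applied to each (coincident double hits are rare and are
    # reflected in the realized divergence recorded in truth)
    base = plant.ltr_seq.upper()
    ltr5, _ = _mutate(rng, base, plant.target_divergence / 2)
    ltr3, _ = _mutate(rng, base, plant.target_divergence / 2)
    n_mut = sum(1 for a, b in zip(ltr5, ltr3) if a != b)
    realized = n_mut / len(base)
    t, L, pb = len(plant.tsd), len(ltr5), len(plant.pbs_motif)
    seq = (plant.tsd.upper() + ltr5 + plant.pbs_motif.upper()
           + plant.internal_seq.upper() + ltr3 + plant.tsd.upper())
    layout = {
        "ltr5": (t, t + L),
        "pbs": (t + L, t + L + pb) if pb else None,
        "internal": (t + L + pb, t + L + pb + len(plant.internal_seq)),
        "ltr3": (len(seq) - t - L, len(seq) - t),
    }
    return seq, layout, realized


def simulate_genome(spec: GenomeSpec) -> SimulatedGenome:
    """Emit chromosome sequences plus truth records for every plant.

    Plants overwrite the i.i.d. background in place, so chromosome length is
    exactly ``ChromSpec.length``.  Overlapping or out-of-range plants are
    rejected with a message naming the offending features.  The same seed
    always yields byte-identical output.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(len(spec.chromosomes))
    sequences: dict[str, str] = {}
    arrays: list[ArrayTruth] = []
    elements: list[ElementTruth] = []
    for chrom, stream in zip(spec.chromosomes, streams):
        rng = np.random.default_rng(stream)
        plants = list(chrom.satellite_plants) + list(chrom.element_plants)
        spans = []
        for p in plants:
            name = getattr(p, "family_id", None) or p.element_id
            if p.start < 0 or p.start + p.length > chrom.length:
                raise ValueError(
                    f"{chrom.name}: plant {name} [{p.start}, {p.start + p.length})"
                    f" outside [0, {chrom.length})")
            spans.append((p.start, p.start + p.length, name))
        spans.sort()
        for (s1, e1, n1), (s2, e2, n2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"{chrom.name}: plants {n1} and {n2} overlap")

        seq = np.frombuffer(random_sequence(rng, chrom.length,
                                            spec.gc_background).encode(),
                            dtype="S1").copy()
        for plant in chrom.satellite_plants:
            built, n_mut = _build_array(rng, plant)
            seq[plant.start:plant.start + len(built)] = \
                np.frombuffer(built.encode(), dtype="S1")
            arrays.append(ArrayTruth(
                chromosome=chrom.name, family_id=plant.family_id,
                start=plant.start, end=plant.start + len(built),
                copies=plant.copies, monomer_length=len(plant.monomer),
                mutations=n_mut,
                realized_divergence=n_mut / len(built)))
        for plant in chrom.element_plants:
            built, layout, realized = _build_element(rng, plant)
            seq[plant.start:plant.start + len(built)] = \
                np.frombuffer(built.encode(), dtype="S1")
            off = plant.start
            shift = lambda iv: (iv[0] + off, iv[1] + off) if iv else None
            elements.append(ElementTruth(
                chromosome=chrom.name, element_id=plant.element_id,
                start=off, end=off + len(built), tsd=plant.tsd.upper(),
                ltr5=shift(layout["ltr5"]), ltr3=shift(layout["ltr3"]),
                pbs=shift(layout["pbs"]), internal=shift(layout["internal"]),
                autonomy=plant.autonomy, pbs_motif=plant.pbs_motif.upper(),
                target_divergence=plant.target_divergence,
                realized_divergence=realized))
        sequences[chrom.name] = seq.tobytes().decode()
    return SimulatedGenome(spec=spec, sequences=sequences,
                           arrays=arrays, elements=elements)


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class ReadSet:
    """Sampled read positions; sequences are materialized on demand."""

    channel: str
    chromosomes: list[str]
    chrom_index: np.ndarray   # per-read index into ``chromosomes``
    starts: np.ndarray
    strands: np.ndarray       # bool, True = reverse
    read_length: int

    def __len__(self) -> int:
        return len(self.starts)

    def positions(self):
        """Yield (chromosome, start) per read."""
        for ci, s in zip(self.chrom_index, self.starts):
            yield self.chromosomes[ci], int(s)

    def sequences(self, genome: SimulatedGenome | dict):
        seqs = genome.sequences if isinstance(genome, SimulatedGenome) else genome
        rl = self.read_length
        for i, (ci, s, rev) in enumerate(zip(self.chrom_index, self.starts,
                                             self.strands)):
            frag = seqs[self.chromosomes[ci]][s:s + rl]
            yield revcomp(frag) if rev else frag

    def named_sequences(self, genome):
        for i, seq in enumerate(self.sequences(genome)):
            yield f"{self.channel}_{i}", seq

    def write_fasta(self, genome, path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.named_sequences(genome):
                fh.write(f">{name}\n{seq}\n")

    def write_fastq(self, genome, path) -> None:
        write_fastq(self.named_sequences(genome), path)


def _sample_channel(rng, channel, lengths, centers, spec, fold) -> ReadSet:
    chroms = list(lengths)
    rl = spec.read_length
    total = sum(lengths.values())
    n_reads = int(round(spec.input_depth * total / rl))

    # per-chromosome piecewise-constant start weights
    segments = []   # (chrom_idx, seg_start, seg_len, weight)
    for ci, name in enumerate(chroms):
        span = lengths[name] - rl + 1
        if span <= 0:
            raise ValueError(f"read_length {rl} exceeds chromosome {name}")
        center = centers.get(name) if fold > 1 else None
        if center is None:
            segments.append((ci, 0, span, 1.0))
        else:
            a = max(0, center - spec.chip_interval_halfwidth)
            b = min(span, center + spec.chip_interval_halfwidth)
            if a > 0:
                segments.append((ci, 0, a, 1.0))
            segments.append((ci, a, b - a, fold))
            if b < span:
                segments.append((ci, b, span - b, 1.0))
    seg_mass = np.array([ln * w for _, _, ln, w in segments], dtype=float)
    seg_choice = rng.choice(len(segments), size=n_reads, p=seg_mass / seg_mass.sum())
    offsets = rng.random(n_reads)
    starts = np.empty(n_reads, dtype=np.int64)
    chrom_index = np.empty(n_reads, dtype=np.int32)
    for si, (ci, s0, ln, _) in enumerate(segments):
        mask = seg_choice == si
        starts[mask] = s0 + np.floor(offsets[mask] * ln).astype(np.int64)
        chrom_index[mask] = ci
    strands = rng.random(n_reads) < 0.5
    return ReadSet(channel=channel, chromosomes=chroms, chrom_index=chrom_index,
                   starts=starts, strands=strands, read_length=rl)


def simulate_reads(genome: SimulatedGenome, spec: ReadSimSpec
                   ) -> tuple[ReadSet, ReadSet]:
    """Sample (chip, input) read sets.

    Input starts are uniform over each chromosome; ChIP starts carry relative
    weight ``chip_fold`` inside [centromere_center +/- halfwidth] and 1
    elsewhere.  Reads never extend past chromosome ends.  Expected read count
    per channel is input_depth * genome_length / read_length.
    """
    if spec.chip_fold < 1:
        raise ValueError("chip_fold must be >= 1")
    lengths = genome.lengths
    centers = genome.centromere_centers()
    chip_rng, input_rng = (np.random.default_rng(s)
                           for s in np.random.SeedSequence(spec.seed).spawn(2))
    chip = _sample_channel(chip_rng, "chip", lengths, centers, spec, spec.chip_fold)
    inp = _sample_channel(input_rng, "input", lengths, centers, spec, 1.0)
    return chip, inp


# ---------------------------------------------------------------------------
# Convenience constructors used across examples and tests


def random_monomer(seed: int, length: int, gc: float = 0.41) -> str:
    return random_sequence(np.random.default_rng(seed), length, gc)
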