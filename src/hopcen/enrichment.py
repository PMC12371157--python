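"""ChIP/input repeat-enrichment scoring against a repeat consensus library.

Each read is assigned to at most one library repeat by canonical k-mer
sharing (alignment-free, strandless), and per-repeat hit counts are turned
into a library-size-normalized ChIP/input ratio:

    normalized_ratio = (chip_hits / chip_total) / (input_hits / input_total)

Repeats with a ratio well above 1 are CENH3-associated candidates.
"""

from __future__ import annotations

import math
from collections.abc import Iterable
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._align import revcomp
from .io import read_fasta

DEFAULT_K = 21
DEFAULT_MIN_FRACTION = 0.5
UNDEFINED_FLAG = "undefined (no input hits)"


@dataclass(frozen=True)
class RepeatConsensus:
    id: str
    repeat_class: str              # "satellite" | "TE"
    sequence: str
    monomer_length: int | str = "variable"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"repeat {self.id}: empty consensus sequence")


@dataclass
class HitRecord:
    repeat_id: str
    chip_hits: int
    input_hits: int
    chip_total: int
    input_total: int
    normalized_ratio: float = math.nan
    flag: str = ""
    is_candidate: bool = False


def load_library(path: str | Path) -> list[RepeatConsensus]:
    """Read a library FASTA whose headers carry ``class=`` and ``monomer=`` tokens."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = dict(t.split("=", 1) for t in rec.description.split()[1:]
                      if "=" in t)
        monomer = tokens.get("monomer", "variable")
        out.append(RepeatConsensus(
            id=rec.id,
            repeat_class=tokens.get("class", "satellite"),
            sequence=str(rec.seq).upper(),
            monomer_length=int(monomer) if monomer != "variable" else monomer))
    _check_unique(out)
    return out


def _check_unique(library: Iterable[RepeatConsensus]) -> None:
    seen = set()
    for rep in library:
        if rep.id in seen:
            raise ValueError(f"duplicate repeat id in library: {rep.id}")
        seen.add(rep.id)


def canonical_kmers(seq: str, k: int) -> set[str]:
    rc = revcomp(seq)
    n = len(seq)
    return {min(seq[i:i + k], rc[n - i - k:n - i]) for i in range(n - k + 1)}


def assign_reads(reads: Iterable[str], library: list[RepeatConsensus],
                 k: int = DEFAULT_K, min_fraction: float = DEFAULT_MIN_FRACTION):
    """Yield the assigned repeat id (or None) per read.

    A read is assigned to the repeat sharing the largest number of canonical
    k-mers with it, provided that number is at least ``min_fraction`` of the
    read's k-mer positions; ties go to the lexicographically smallest repeat
    id.  Each read is assigned to at most one repeat.
    """
    if not library:
        raise ValueError("library is empty")
    _check_unique(library)
    order = sorted(range(len(library)), key=lambda i: library[i].id)
    kmer_to_repeats: dict[str, list[int]] = {}
    for rank, li in enumerate(order):
        for kmer in canonical_kmers(library[li].sequence, k):
            kmer_to_repeats.setdefault(kmer, []).append(rank)
    ids_by_rank = [library[li].id for li in order]
    for read in reads:
        n_pos = len(read) - k + 1
        if n_pos <= 0:
            yield None
            continue
        rc = revcomp(read)
        n = len(read)
        scores: dict[int, int] = {}
        for i in range(n_pos):
            kmer = min(read[i:i + k], rc[n - i - k:n - i])
            owners = kmer_to_repeats.get(kmer)
            if owners:
                for rank in owners:
                    scores[rank] = scores.get(rank, 0) + 1
        if not scores:
            yield None
            continue
        # max score, tie -> smallest rank == lexicographically smallest id
        best_rank = min(scores, key=lambda r: (-scores[r], r))
        yield (ids_by_rank[best_rank]
               if scores[best_rank] >= min_fraction * n_pos else None)


def count_hits(reads: Iterable[str], library: list[RepeatConsensus],
               k: int = DEFAULT_K, min_fraction: float = DEFAULT_MIN_FRACTION
               ) -> tuple[dict[str, int], int]:
    """Per-repeat hit counts from :func:`assign_reads`.

    Returns ({repeat_id: hits}, total reads examined); the totals are the
    channel library sizes used for ratio normalization.
    """
    hits = {rep.id: 0 for rep in library}
    total = 0
    for assigned in assign_reads(reads, library, k, min_fraction):
        total += 1
        if assigned is not None:
            hits[assigned] += 1
    return hits, total


def normalized_ratio(chip_hits: int, input_hits: int,
                     chip_total: int, input_total: int) -> float:
    """Library-size-normalized ChIP/input ratio; NaN when input_hits == 0."""
    if min(chip_hits, input_hits, chip_total, input_total) < 0:
        raise ValueError("counts must be non-negative")
    if chip_total <= 0 or input_total <= 0:
        raise ValueError("library totals must be positive")
    if input_hits == 0:
        return math.nan
    return (chip_hits / chip_total) / (input_hits / input_total)


def build_hit_records(chip_hits: dict[str, int], input_hits: dict[str, int],
                      chip_total: int, input_total: int) -> list[HitRecord]:
    records = []
    for repeat_id in chip_hits:
        c, i = chip_hits[repeat_id], input_hits.get(repeat_id, 0)
        ratio = normalized_ratio(c, i, chip_total, input_total)
        records.append(HitRecord(
            repeat_id=repeat_id, chip_hits=c, input_hits=i,
            chip_total=chip_total, input_total=input_total,
            normalized_ratio=ratio,
            flag=UNDEFINED_FLAG if math.isnan(ratio) else ""))
    return records


def rank_candidates(records: list[HitRecord], min_ratio: float = 10.0
                    ) -> list[HitRecord]:
    """Stable sort by normalized ratio descending; undefined ratios last.

    Records with ratio >= ``min_ratio`` are flagged as centromeric candidates.
    """
    defined = [r for r in records if not math.isnan(r.normalized_ratio)]
    undefined = [r for r in records if math.isnan(r.normalized_ratio)]
    ranked = sorted(defined, key=lambda r: -r.normalized_ratio) + undefined
    for r in ranked:
        r.is_candidate = (not math.isnan(r.normalized_ratio)
                          and r.normalized_ratio >= min_ratio)
    return ranked


def enrichment_table(records: list[HitRecord],
                     library: list[RepeatConsensus] | None = None
                     ) -> pd.DataFrame:
    """Tabulate records with the familiar column order (one row per repeat)."""
    meta = {rep.id: rep for rep in library or []}
    rows = []
    for r in records:
        rep = meta.get(r.repeat_id)
        rows.append({
            "repeat": r.repeat_id,
            "monomer_length": rep.monomer_length if rep else "",
            "chip_hits": r.chip_hits,
            "input_hits": r.input_hits,
            "normalized_ratio": (round(r.normalized_ratio, 2)
                                 if not math.isnan(r.normalized_ratio) else r.flag),
            "annotation": rep.repeat_class if rep else "",
        })
    return pd.DataFrame(rows)
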