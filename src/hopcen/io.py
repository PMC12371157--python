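"""Plain-text genomic I/O: FASTA (via Biopython), BED, bedGraph and GFF3 writers.

Coordinates are 0-based half-open internally; GFF3 output converts to
1-based closed on the way out.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path,
                descriptions: Mapping[str, str] | None = None) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description=(descriptions or {}).get(name, ""))
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fastq(reads: Iterable[tuple[str, str]], path: str | Path,
                quality_char: str = "I") -> None:
    """Write (name, sequence) reads as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{quality_char * len(seq)}\n")


def write_bed(intervals: Iterable[tuple], path: str | Path) -> None:
    """Write BED lines; each interval is (chrom, start, end[, name[, score[, strand]]])."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write("\t".join(str(x) for x in iv) + "\n")


def write_bedgraph(chrom: str, bin_size: int, counts, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(counts):
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{c}\n")


def gff3_line(chrom: str, source: str, feature_type: str, start0: int, end0: int,
              score: str = ".", strand: str = "+", attributes: str = ".") -> str:
    """Format one GFF3 line from 0-based half-open coordinates."""
    return f"{chrom}\t{source}\t{feature_type}\t{start0 + 1}\t{end0}\t{score}\t{strand}\t.\t{attributes}"


def write_gff3(lines: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in lines:
            fh.write(line + "\n")
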