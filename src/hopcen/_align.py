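"""Shared pairwise-alignment helpers.

Identity is defined as matches / alignment columns (gaps count against
identity), computed from an affine-gap global or local alignment with
match +1, mismatch -1, gap open -2, gap extend -0.5.
"""

from __future__ import annotations

from functools import lru_cache

from Bio import Align

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -2.0
    aligner.extend_gap_score = -0.5
    return aligner


def _column_pairs(alignment):
    """Yield (a_char, b_char) per alignment column; '-' marks a gap."""
    a, b = alignment.sequences
    prev_a = prev_b = None
    for (ia, ja), (ib, jb) in zip(*alignment.aligned):
        if prev_a is not None:
            for x in range(prev_a, ia):
                yield a[x], "-"
            for x in range(prev_b, ib):
                yield "-", b[x]
        for x, y in zip(range(ia, ja), range(ib, jb)):
            yield a[x], b[y]
        prev_a, prev_b = ja, jb


def align_stats(a: str, b: str, mode: str = "global") -> dict:
    """Best affine alignment of a vs b; returns match/mismatch/gap tallies.

    Keys: matches, mismatches, gaps, columns, transitions, transversions,
    identity_pct, score.  Transitions/transversions are counted over
    non-gap columns only.
    """
    a = a.upper()
    b = b.upper()
    if not a or not b:
        raise ValueError("cannot align empty sequence")
    alignment = _aligner(mode).align(a, b)[0]
    matches = mismatches = gaps = transitions = transversions = 0
    for x, y in _column_pairs(alignment):
        if x == "-" or y == "-":
            gaps += 1
        elif x == y:
            matches += 1
        else:
            mismatches += 1
            if {x, y} <= PURINES or {x, y} <= PYRIMIDINES:
                transitions += 1
            else:
                transversions += 1
    columns = matches + mismatches + gaps
    return {
        "matches": matches,
        "mismatches": mismatches,
        "gaps": gaps,
        "columns": columns,
        "transitions": transitions,
        "transversions": transversions,
        "identity_pct": 100.0 * matches / columns if columns else 0.0,
        "score": alignment.score,
    }


def global_identity(a: str, b: str) -> float:
    """Percent identity of the best global alignment (single orientation)."""
    return align_stats(a, b)["identity_pct"]


def best_strand_identity(a: str, b: str) -> tuple[float, str]:
    """Global percent identity, trying b on both strands; returns (pct, strand)."""
    fwd = global_identity(a, b)
    rev = global_identity(a, revcomp(b))
    return (fwd, "+") if fwd >= rev else (rev, "-")


def local_alignment(a: str, b: str):
    """Best affine local alignment of b within/against a (Biopython object)."""
    return _aligner("local").align(a.upper(), b.upper())[0]
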