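"""Satellite array characterization.

Four capabilities:

* monomer-length estimation from the shifted-match periodicity profile of
  an array (exact and explainable at the few-percent mutation regime
  satellite arrays show; harmonics are reported, the smallest significant
  period is returned);
* windowed pairwise-identity matrices (the classic tandem-repeat heatmap);
* detection of internally repeated subunits within a monomer consensus by
  self-comparison (e.g. a 39-bp block repeated three or four times at the
  3' end of a 284-bp centromeric monomer);
* inter-family consensus similarity with cyclic-rotation search, because
  tandem-repeat consensi have arbitrary phase.

Percent identity throughout is matches / alignment columns under the
affine-gap scoring defined in :mod:`hopcen._align`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import best_strand_identity, global_identity, revcomp


@dataclass
class MonomerEstimate:
    period: int | None
    confidence: float            # peak match-fraction minus background median
    match_fraction: float
    harmonics: list[int] = field(default_factory=list)
    profile: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class IdentityMatrix:
    window: int
    step: int
    starts: list[int]
    values: np.ndarray           # percent identity, symmetric, diag 100
    flags: list[str] = field(default_factory=list)

    def to_records(self):
        for i in range(len(self.starts)):
            for j in range(len(self.starts)):
                yield self.starts[i], self.starts[j], float(self.values[i, j])


@dataclass
class SubunitAnnotation:
    subunit_length: int
    positions: list[int]         # offsets within the monomer
    copies_per_monomer: int
    identity_pct: float
    flags: list[str] = field(default_factory=list)
    candidate_true_monomer: int | None = None


@dataclass
class ConsensusSimilarity:
    identity_pct: float
    rotation: int                # applied to the second sequence
    strand: str
    columns: int


# ---------------------------------------------------------------------------
# Monomer length


def _shift_profile(seq: str, periods: np.ndarray) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype="S1")
    out = np.empty(len(periods))
    for idx, p in enumerate(periods):
        out[idx] = np.mean(arr[:-p] == arr[p:])
    return out


def estimate_monomer_length(sequence: str, min_period: int = 10,
                            max_period: int = 500,
                            min_prominence: float = 0.10) -> MonomerEstimate:
    """Estimate the tandem-repeat period of ``sequence``.

    The score of a candidate period p is the fraction of positions i with
    sequence[i] == sequence[i + p].  The smallest period whose score rises
    most of the way (80%) from the background median to the peak is
    returned; larger such periods (typically integer multiples) are
    reported as harmonics.  When the peak's prominence over the background
    median is below ``min_prominence`` the array is declared aperiodic.
    """
    n = len(sequence)
    if n < 3 * min_period:
        raise ValueError("sequence shorter than 3 x min_period")
    max_period = min(max_period, n // 3)
    periods = np.arange(min_period, max_period + 1)
    profile = _shift_profile(sequence, periods)
    background = float(np.median(profile))
    peak = float(profile.max())
    prominence = peak - background
    if prominence < min_prominence:
        return MonomerEstimate(period=None, confidence=prominence,
                               match_fraction=peak, profile=profile,
                               flags=["no period"])
    significant = periods[profile >= background + 0.8 * prominence]
    period = int(significant[0])
    harmonics = [int(p) for p in significant[1:]]
    return MonomerEstimate(period=period, confidence=prominence,
                           match_fraction=float(profile[period - min_period]),
                           harmonics=harmonics, profile=profile)


def estimate_copies(array_length: int, monomer_length: int) -> int:
    return array_length // monomer_length


# ---------------------------------------------------------------------------
# Identity heatmap


def pairwise_identity(a: str, b: str, both_strands: bool = True) -> float:
    """Percent identity of the best global alignment (optionally both strands)."""
    if both_strands:
        return best_strand_identity(a, b)[0]
    return global_identity(a, b)


def identity_heatmap(sequence: str, window: int = 5000, step: int = 2000
                     ) -> IdentityMatrix:
    """Global-alignment percent identity for every pair of tiled windows."""
    if window > len(sequence):
        raise ValueError("window larger than sequence")
    flags = ["sparse tiling (step > window)"] if step > window else []
    starts = list(range(0, len(sequence) - window + 1, step))
    chunks = [sequence[s:s + window] for s in starts]
    k = len(starts)
    values = np.full((k, k), 100.0)
    for i in range(k):
        for j in range(i + 1, k):
            ident = pairwise_identity(chunks[i], chunks[j])
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(window=window, step=step, starts=starts,
                          values=values, flags=flags)


def heatmap_to_tsv(matrix: IdentityMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write("window_i\twindow_j\tidentity_pct\n")
        for i, j, v in matrix.to_records():
            fh.write(f"{i}\t{j}\t{v:.2f}\n")


def plot_heatmap(matrix: IdentityMatrix, path) -> None:
    """Optional image output (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(matrix.values, vmin=0, vmax=100, cmap="viridis",
                   origin="lower")
    fig.colorbar(im, ax=ax, label="% identity")
    ax.set_xlabel("window")
    ax.set_ylabel("window")
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Subunit detection


def _qualifying_runs(match: np.ndarray, min_len: int, min_identity: float):
    """Maximal intervals of ``match`` whose sliding min_len-window identity
    stays >= min_identity; yields (start, end)."""
    if len(match) < min_len:
        return
    kernel = np.ones(min_len)
    window_id = np.convolve(match.astype(float), kernel, mode="valid") / min_len
    good = window_id >= min_identity
    i = 0
    while i < len(good):
        if good[i]:
            j = i
            while j < len(good) and good[j]:
                j += 1
            yield i, j - 1 + min_len     # window span in match coordinates
            i = j
        else:
            i += 1


def detect_subunits(monomer_consensus: str, min_len: int = 20,
                    max_len: int | None = None,
                    min_identity: float = 0.80) -> list[SubunitAnnotation]:
    """Find internally repeated blocks of a monomer by self-comparison.

    Compares the monomer against itself at every shift in
    [min_len, max_len]; a run of >= min_len positions matching at
    >= ``min_identity`` at shift s marks a block of length s repeated in
    tandem.  The smallest such shift defines the subunit family.  When the
    repeated block tiles (nearly) the whole monomer, the monomer is flagged
    as itself tandem and the shift is proposed as the true monomer length.
    """
    seq = np.frombuffer(monomer_consensus.upper().encode(), dtype="S1")
    n = len(seq)
    if n <= 2 * min_len:
        raise ValueError("monomer too short for subunit search")
    max_len = max_len or n // 2
    for shift in range(min_len, max_len + 1):
        match = seq[:-shift] == seq[shift:]
        best = None
        for a, b in _qualifying_runs(match, min_len, min_identity):
            if best is None or (b - a) > (best[1] - best[0]):
                best = (a, b)
        if best is None:
            continue
        a, b = best
        # trim run edges: chance matches in flanking sequence can extend a
        # qualifying run past the true subunit boundary
        while a < b - 8 and np.mean(match[a:a + 8]) < 0.9:
            a += 1
        while b > a + 8 and np.mean(match[b - 8:b]) < 0.9:
            b -= 1
        if (b - a) < min_len:
            continue
        copies = (b - a) // shift + 1
        if copies < 2:
            continue
        positions = [a + i * shift for i in range(copies)]
        ident = 100.0 * float(np.mean(match[a:b]))
        ann = SubunitAnnotation(subunit_length=shift, positions=positions,
                                copies_per_monomer=copies, identity_pct=ident)
        span = b - a + shift
        if span >= 0.9 * n:
            ann.flags.append("monomer is itself tandem")
            ann.candidate_true_monomer = shift
        return [ann]
    return []


# ---------------------------------------------------------------------------
# Consensus similarity


def _rotate(seq: str, r: int) -> str:
    r %= len(seq)
    return seq[r:] + seq[:r]


def consensus_similarity(a: str, b: str, coarse_stride: int = 4
                         ) -> ConsensusSimilarity:
    """Best global identity of two monomer consensi over both strands and
    all cyclic rotations of ``b`` (coarse stride-4 scan, then +/-3 refinement)."""
    if not a or not b:
        raise ValueError("empty consensus")
    candidates = {"+": b, "-": revcomp(b)}
    best = None
    for strand, bs in candidates.items():
        coarse = []
        for r in range(0, len(bs), coarse_stride):
            ident = global_identity(a, _rotate(bs, r))
            coarse.append((ident, r))
        coarse.sort(reverse=True)
        _, r0 = coarse[0]
        for r in range(r0 - coarse_stride + 1, r0 + coarse_stride):
            ident = global_identity(a, _rotate(bs, r))
            cand = (ident, strand, r % len(bs))
            if best is None or cand[0] > best[0]:
                best = cand
    ident, strand, rotation = best
    columns = max(len(a), len(b))
    return ConsensusSimilarity(identity_pct=ident, rotation=rotation,
                               strand=strand, columns=columns)
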