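import numpy as np
import pytest

from hopcen import syndata, te_annotator


@pytest.fixture(scope="session")
def pbs_catalog():
    return te_annotator.load_pbs_catalog()


@pytest.fixture(scope="session")
def domain_profiles():
    return te_annotator.load_domain_profiles()


@pytest.fixture(scope="session")
def pbs_seqs(pbs_catalog):
    return dict(pbs_catalog.motifs)


def make_element_cohort(n_elements: int, seed: int, divergence: float = 0.02,
                        ltr_len: int = 500, pbs_motifs=None, embed: str = "",
                        tsd: str = "ACGTA", gap: int = 2500):
    """Build a chromosome spec planting ``n_elements`` CRM-like elements with
    per-element LTR sequences (a diverged family), plus its genome."""
    rng = np.random.default_rng(seed)
    plants = []
    pos = 3000
    for i in range(n_elements):
        ltr = syndata.random_sequence(rng, ltr_len)
        if embed:
            mid = (ltr_len - len(embed)) // 2
            ltr = ltr[:mid] + embed + ltr[mid + len(embed):]
        internal = te_annotator.synthetic_internal_sequence(
            ("GAG", "PRO", "CHD"), seed=seed * 1000 + i)
        motif = ""
        if pbs_motifs is not None:
            motif = pbs_motifs[i] or ""
        plants.append(syndata.ElementPlant(
            element_id=f"el{i}", ltr_seq=ltr, internal_seq=internal,
            start=pos, target_divergence=divergence, tsd=tsd,
            pbs_motif=motif))
        pos += plants[-1].length + gap + int(rng.integers(0, 2000))
    chrom = syndata.ChromSpec("cohort", pos + 3000,
                              element_plants=tuple(plants))
    genome = syndata.simulate_genome(
        syndata.GenomeSpec((chrom,), seed=seed))
    return genome
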