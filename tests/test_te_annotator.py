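"""Structural LTR-element detection, annotation and insertion dating."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopcen import syndata, te_annotator as te
from hopcen._align import revcomp
from conftest import make_element_cohort

RATE = 6.1e-9


def _single_element_genome(seed=11, divergence=0.0, tsd="ACGTA",
                           pbs="TGGTATCAGAGCGGGC", length=40_000, start=5000):
    ltr = syndata.random_monomer(seed + 1, 600)
    internal = te.synthetic_internal_sequence(te.CANONICAL_DOMAIN_ORDER,
                                              seed=seed + 2)
    plant = syndata.ElementPlant("el1", ltr, internal, start=start,
                                 target_divergence=divergence, tsd=tsd,
                                 pbs_motif=pbs)
    return syndata.simulate_genome(syndata.GenomeSpec(
        (syndata.ChromSpec("c1", length, element_plants=(plant,)),),
        seed=seed))


class TestFindElements:
    def test_repeat_free_background_yields_no_elements(self):
        for seed in range(20):
            g = syndata.simulate_genome(syndata.GenomeSpec(
                (syndata.ChromSpec("c", 30_000),), seed=seed))
            elements, solos = te.find_ltr_elements(g.sequences["c"])
            assert elements == [] and solos == []

    def test_planted_element_recovered_exactly(self):
        g = _single_element_genome(seed=11)
        truth = g.elements[0]
        elements, _ = te.find_ltr_elements(g.sequences["c1"], "c1")
        assert len(elements) == 1
        el = elements[0]
        assert (el.start, el.end) == (truth.start, truth.end)
        assert el.ltr5 == truth.ltr5 and el.ltr3 == truth.ltr3
        assert el.tsd == "ACGTA"

    def test_planted_solo_ltr_reported_separately(self):
        ltr = syndata.random_monomer(2, 600)
        internal = te.synthetic_internal_sequence(("GAG", "PRO", "CHD"),
                                                  seed=3)
        element = syndata.ElementPlant("el1", ltr, internal, start=3000,
                                       tsd="ACGTA")
        solo = syndata.ArrayPlant("solo", ltr, 1, start=20_000)
        g = syndata.simulate_genome(syndata.GenomeSpec(
            (syndata.ChromSpec("c", 30_000, satellite_plants=(solo,),
                               element_plants=(element,)),), seed=9))
        elements, solos = te.find_ltr_elements(g.sequences["c"])
        assert len(elements) == 1
        assert elements[0].end <= 20_000            # solo not in element list
        assert len(solos) == 1
        assert abs(solos[0].start - 20_000) <= 2
        assert abs(solos[0].end - 20_600) <= 2

    def test_satellite_array_not_called_as_element(self):
        mono = syndata.random_monomer(4, 284)
        plant = syndata.ArrayPlant("cen", mono, 40, 0.02, start=5000)
        g = syndata.simulate_genome(syndata.GenomeSpec(
            (syndata.ChromSpec("c", 30_000, satellite_plants=(plant,)),),
            seed=5))
        elements, _ = te.find_ltr_elements(g.sequences["c"])
        assert elements == []

    def test_cohort_recovery_with_tight_boundaries(self):
        """>= 95% of 20 planted elements found with <= 5 bp boundary error
        at divergence <= 0.05; every call matches a planted element."""
        genome = make_element_cohort(20, seed=17, divergence=0.03)
        truth = [(t.start, t.end) for t in genome.elements]
        elements, _ = te.find_ltr_elements(genome.sequences["cohort"])
        good = 0
        for el in elements:
            err = min(abs(ts - el.start) + abs(te_ - el.end)
                      for ts, te_ in truth)
            good += err <= 5
        assert len(elements) == 20
        assert good >= 19


class TestPBS:
    def test_planted_motif_detected(self, pbs_catalog, pbs_seqs):
        g = _single_element_genome(pbs=pbs_seqs["PBS4"])
        elements, _ = te.find_ltr_elements(g.sequences["c1"], "c1")
        assert te.detect_pbs(g.sequences["c1"], elements[0],
                             pbs_catalog) == "PBS4"

    def test_single_substitution_tolerated(self, pbs_catalog, pbs_seqs):
        motif = pbs_seqs["PBS2"]
        mutated = "A" + motif[1:] if motif[0] != "A" else "C" + motif[1:]
        g = _single_element_genome(pbs=mutated)
        elements, _ = te.find_ltr_elements(g.sequences["c1"], "c1")
        assert te.detect_pbs(g.sequences["c1"], elements[0],
                             pbs_catalog) == "PBS2"

    def test_absent_motif_gives_none_and_cohort_fraction_matches(self,
                                                                 pbs_catalog,
                                                                 pbs_seqs):
        motifs = [pbs_seqs["PBS4"], None, pbs_seqs["PBS1"], None,
                  pbs_seqs["PBS4"], pbs_seqs["PBS3"], None, pbs_seqs["PBS4"]]
        genome = make_element_cohort(8, seed=23, divergence=0.0,
                                     pbs_motifs=motifs)
        elements, _ = te.find_ltr_elements(genome.sequences["cohort"])
        assert len(elements) == 8
        calls = [te.detect_pbs(genome.sequences["cohort"], el, pbs_catalog)
                 for el in sorted(elements, key=lambda e: e.start)]
        detected = sum(c is not None for c in calls)
        assert detected == sum(m is not None for m in motifs)

    def test_missing_five_prime_ltr_rejected(self, pbs_catalog):
        el = te.LTRElement("c", 0, 100, None, (50, 100))
        with pytest.raises(ValueError):
            te.detect_pbs("A" * 200, el, pbs_catalog)


class TestDomains:
    def test_autonomous_internal_has_all_six_in_order(self, domain_profiles):
        internal = te.synthetic_internal_sequence(te.CANONICAL_DOMAIN_ORDER,
                                                  seed=31)
        scan = te.scan_domains(internal, domain_profiles)
        assert scan.domains_present == frozenset(te.CANONICAL_DOMAIN_ORDER)
        assert scan.ordered() == list(te.CANONICAL_DOMAIN_ORDER)
        assert "non-canonical domain order" not in scan.flags

    def test_deleted_domains_absent(self, domain_profiles):
        internal = te.synthetic_internal_sequence(("GAG", "PRO", "CHD"),
                                                  seed=32)
        scan = te.scan_domains(internal, domain_profiles)
        assert scan.domains_present == frozenset({"GAG", "PRO", "CHD"})

    def test_random_internal_has_no_domains(self, domain_profiles):
        for seed in range(20):
            seq = syndata.random_monomer(seed + 60, 2000)
            scan = te.scan_domains(seq, domain_profiles)
            assert scan.domains_present == frozenset()

    def test_short_internal_flagged(self, domain_profiles):
        scan = te.scan_domains("ACGT" * 20, domain_profiles)
        assert scan.domains_present == frozenset()
        assert "too short" in scan.flags


class TestAutonomy:
    @pytest.mark.parametrize("present,expected", [
        ({"GAG", "PRO", "RT", "RH", "INT", "CHD"}, "autonomous"),
        ({"GAG", "PRO", "CHD"}, "nonautonomous_dominant"),
        ({"PRO", "CHD"}, "nonautonomous_minor"),
        ({"GAG", "PRO", "RT", "RH", "CHD"}, "unclassified"),
    ])
    def test_classification_rule(self, present, expected):
        assert te.classify_autonomy(present) == expected

    @settings(max_examples=64, deadline=None, derandomize=True)
    @given(st.sets(st.sampled_from(te.CANONICAL_DOMAIN_ORDER)))
    def test_every_domain_set_gets_exactly_one_class(self, present):
        cls = te.classify_autonomy(present)
        assert cls in {"autonomous", "nonautonomous_dominant",
                       "nonautonomous_minor", "unclassified"}

    def test_unknown_domain_rejected(self):
        with pytest.raises(ValueError):
            te.classify_autonomy({"GAG", "XYZ"})


class TestInsertionAge:
    def test_identical_ltrs_age_zero(self):
        seq = syndata.random_monomer(41, 1000)
        est = te.estimate_insertion_age(seq, seq)
        assert est.K == pytest.approx(0.0) and est.age_years == 0.0

    def test_age_formula_at_printed_divergence(self):
        """K = 0.0122 at 6.1e-9 subs/site/yr dates to exactly 1.0 Ma."""
        n, subs = 5000, 61                    # 61/5000 = 0.0122 exactly
        a = syndata.random_monomer(42, n)
        b = list(a)
        rng = np.random.default_rng(43)
        for i in rng.choice(n, size=subs, replace=False):
            b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[b[i]]
        est = te.estimate_insertion_age(a, "".join(b),
                                        te.AgeModel(correction="raw"))
        assert est.K == pytest.approx(0.0122)
        assert est.age_ma == pytest.approx(1.0)   # 0.0122 / (2 * 6.1e-9) yr

    def test_planted_divergence_recovered_within_fifteen_percent(self):
        ltr = syndata.random_monomer(44, 2000)
        plant = syndata.ElementPlant("e", ltr, syndata.random_monomer(45, 600),
                                     start=1000, target_divergence=0.006)
        g = syndata.simulate_genome(syndata.GenomeSpec(
            (syndata.ChromSpec("c", 10_000, element_plants=(plant,)),),
            seed=46))
        t = g.elements[0]
        seq = g.sequences["c"]
        est = te.estimate_insertion_age(seq[t.ltr5[0]:t.ltr5[1]],
                                        seq[t.ltr3[0]:t.ltr3[1]])
        expected = 0.006 / (2 * RATE)
        assert est.age_years == pytest.approx(expected, rel=0.15)

    def test_low_identity_pair_withheld(self):
        a = syndata.random_monomer(47, 500)
        b = syndata.random_monomer(48, 500)
        est = te.estimate_insertion_age(a, b)
        assert "unreliable pair" in est.flags and est.age_years is None

    def test_age_monotone_in_divergence_and_rate(self):
        base = syndata.random_monomer(49, 2000)
        rng = np.random.default_rng(50)
        ages = []
        for n_sub in (5, 20, 60, 120):
            b = list(base)
            for i in rng.choice(2000, size=n_sub, replace=False):
                b[i] = "ACGT"[(("ACGT".index(b[i])) + 1) % 4]
            est = te.estimate_insertion_age(base, "".join(b))
            ages.append(est.age_years)
        assert ages == sorted(ages)
        # halving the rate doubles the age
        half = te.estimate_insertion_age(base, "".join(b),
                                         te.AgeModel(rate=RATE / 2))
        assert half.age_years == pytest.approx(2 * ages[-1])

    def test_correction_ordering_on_random_pairs(self):
        """kimura2p >= jukes_cantor >= raw for the same alignment."""
        rng = np.random.default_rng(51)
        for trial in range(100):
            n = int(rng.integers(200, 800))
            a = syndata.random_monomer(1000 + trial, n)
            b = list(a)
            d = rng.uniform(0.01, 0.3)
            for i in range(n):
                if rng.random() < d:
                    b[i] = "ACGT"[int(rng.integers(0, 4))]
            b = "".join(b)
            ks = {c: te.estimate_insertion_age(a, b, te.AgeModel(correction=c)).K
                  for c in ("raw", "jukes_cantor", "kimura2p")}
            assert ks["kimura2p"] >= ks["jukes_cantor"] - 1e-12
            assert ks["jukes_cantor"] >= ks["raw"] - 1e-12

    def test_short_ltrs_rejected(self):
        with pytest.raises(ValueError):
            te.estimate_insertion_age("ACGT" * 10, "ACGT" * 10)


class TestPBSSummary:
    def _stub(self, autonomy, pbs):
        return te.LTRElement("c", 0, 100, (0, 10), (90, 100),
                             autonomy=autonomy, pbs=pbs)

    def test_printed_cohort_percentages(self):
        """169 + 374 PBS-bearing of 189 + 482 elements -> 80.9% detection;
        449 of 543 in the four dominant motifs -> 82.7%."""
        elements = []
        top4 = {"PBS4": 200, "PBS1": 100, "PBS2": 80, "PBS3": 69}   # 449
        rare = {"PBS5": 50, "PBS6": 44}                             # 94
        motifs = [m for m, k in {**top4, **rare}.items() for _ in range(k)]
        assert len(motifs) == 543
        for i in range(169):
            elements.append(self._stub("autonomous", motifs[i]))
        for i in range(169, 543):
            elements.append(self._stub("nonautonomous_dominant", motifs[i]))
        elements += [self._stub("autonomous", None)] * (189 - 169)
        elements += [self._stub("nonautonomous_dominant", None)] * (482 - 374)
        summary = te.summarize_pbs_groups(elements)
        assert summary.total_elements == 671
        assert summary.detected == 543
        assert summary.detection_pct == 80.9
        assert summary.top4_count == 449
        assert summary.top4_pct == 82.7

    def test_zero_detected(self):
        elements = [self._stub("autonomous", None)] * 5
        summary = te.summarize_pbs_groups(elements)
        assert summary.detection_pct == 0.0

    def test_empty_cohort(self):
        assert te.summarize_pbs_groups([]).total_elements == 0


class TestRepeatInLTR:
    def test_embedded_repeat_found_in_both_ltrs(self):
        cen = syndata.random_monomer(61, 150)
        genome = make_element_cohort(1, seed=62, divergence=0.0, embed=cen)
        seq = genome.sequences["cohort"]
        elements, _ = te.find_ltr_elements(seq)
        hits = te.locate_repeat_in_ltr(seq, elements[0], cen)
        assert {h[0] for h in hits} == {"ltr5", "ltr3"}
        truth = genome.elements[0]
        mid = truth.ltr5[0] + (500 - 150) // 2
        hit5 = next(h for h in hits if h[0] == "ltr5")
        assert abs(hit5[1] - mid) <= 2

    def test_absent_repeat_gives_no_hits(self):
        genome = make_element_cohort(1, seed=63, divergence=0.0)
        seq = genome.sequences["cohort"]
        elements, _ = te.find_ltr_elements(seq)
        hits = te.locate_repeat_in_ltr(seq, elements[0],
                                       syndata.random_monomer(64, 150))
        assert hits == []

    def test_cohort_carrier_fraction_recovered(self):
        """17 of 18 planted carriers -> 94.4%, recovered within 2 points."""
        cen = syndata.random_monomer(65, 150)
        carriers = make_element_cohort(17, seed=66, divergence=0.01,
                                       embed=cen)
        non = make_element_cohort(1, seed=67, divergence=0.01)
        hit_lists = []
        for genome in (carriers, non):
            seq = genome.sequences["cohort"]
            elements, _ = te.find_ltr_elements(seq)
            for el in elements:
                hit_lists.append(te.locate_repeat_in_ltr(seq, el, cen))
        assert len(hit_lists) == 18
        frac = te.repeat_fraction(hit_lists)
        assert abs(100 * frac - 94.4) <= 2.0
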