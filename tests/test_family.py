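import itertools

import numpy as np
import pytest

from xhap import (
    FamilySpec,
    call_male_haplotypes,
    classify_crossover,
    draw_fathers,
    draw_mother,
    family_report,
    infer_paternal,
    phase_maternal,
    simulate_adults,
    simulate_family,
    study_scenario,
    truth_report,
)
from xhap.core import (
    DiploidGenotype,
    FamilyDataset,
    Locus,
    MarkerPanel,
    SampleRecord,
    XHaplotype,
)
from xhap.family import FamilyInference, MaternalPhase, PhasingError


def _phase(h1, h2, panel):
    het = tuple(i for i in range(len(h1)) if h1[i] != h2[i])
    return MaternalPhase(
        h1=XHaplotype(h1, label="H1"),
        h2=XHaplotype(h2, label="H2"),
        heterozygous_loci=het,
        locus_names=panel.names,
        scaffolds=tuple(l.scaffold for l in panel.loci),
        support=(0, 0),
    )


def _female(sid, pairs):
    return SampleRecord(sid, "female", "F", "FAM", DiploidGenotype(tuple(pairs)), stage="larva")


def _male_larva(sid, hap, subclutch=None):
    return SampleRecord(
        "" + sid, "male", "F", "FAM", DiploidGenotype(tuple((a,) for a in hap)),
        stage="larva", subclutch=subclutch,
    )


@pytest.fixture(scope="module")
def two_locus_panel():
    return MarkerPanel(
        (
            Locus("A", "49", 10, "TAA", frozenset({144, 147})),
            Locus("B", "49", 20, "TTCA", frozenset({295, 298, 299, 300})),
        )
    )


class TestPhaseMaternal:
    def test_n_hm_per_scaffold(self, panel):
        rng = np.random.default_rng(0)
        mother = draw_mother(panel, rng, {"49": 2, "61": 4})
        fathers = draw_fathers(panel, 3, rng)
        fam = simulate_family(FamilySpec(n_fathers=3, n_larvae=80), mother, fathers, panel, rng=rng)
        phase = phase_maternal(fam, panel)
        assert phase.n_hm == {"49": 2, "61": 4}
        assert phase.n_hm_pair == (2, 4)

    def test_fully_homozygous_mother_trivial_phase(self, panel):
        hap = tuple(sorted(l.alleles)[0] for l in panel.loci)
        mother = SampleRecord(
            "mo", "female", "F", "FAM", DiploidGenotype(tuple((a, a) for a in hap)),
            family="FAM",
        )
        larvae = [_male_larva(f"l{i}", hap) for i in range(4)]
        phase = phase_maternal(FamilyDataset(mother=mother, larvae=larvae), panel)
        assert phase.h1.alleles == phase.h2.alleles == hap
        assert phase.heterozygous_loci == ()

    def test_phase_recovered_from_simulated_family(self, family_with_truth, panel):
        fam, mother, _ = family_with_truth
        phase = phase_maternal(fam, panel)
        assert {phase.h1.alleles, phase.h2.alleles} == {
            mother[0].alleles,
            mother[1].alleles,
        }

    def test_support_counts_zero_recombination(self, panel):
        rng = np.random.default_rng(1)
        mother = draw_mother(panel, rng, {"49": 1, "61": 1})
        fathers = draw_fathers(panel, 2, rng)
        spec = FamilySpec(n_fathers=2, n_larvae=100,
                          recomb_fraction=[0.0] * (len(panel) - 1))
        fam = simulate_family(spec, mother, fathers, panel, rng=rng)
        phase = phase_maternal(fam, panel)
        assert sum(phase.support) == len(fam.male_larvae())

    def test_requires_male_larvae(self, panel):
        rng = np.random.default_rng(2)
        mother = draw_mother(panel, rng)
        fathers = draw_fathers(panel, 2, rng)
        spec = FamilySpec(n_fathers=2, n_larvae=20, sex_ratio_female=1.0)
        fam = simulate_family(spec, mother, fathers, panel, rng=rng)
        with pytest.raises(ValueError, match="male larva"):
            phase_maternal(fam, panel)

    def test_unexplainable_males_raise_phasing_error(self, two_locus_panel):
        mother = SampleRecord(
            "mo", "female", "F", "FAM",
            DiploidGenotype(((144, 147), (295, 298))), family="FAM",
        )
        alien = _male_larva("l1", (144, 300))  # 300 not maternal
        with pytest.raises(PhasingError):
            phase_maternal(FamilyDataset(mother=mother, larvae=[alien]), two_locus_panel)


class TestClassifyCrossover:
    def test_parental(self, family_with_truth, panel):
        fam, mother, _ = family_with_truth
        phase = phase_maternal(fam, panel)
        cls = classify_crossover(phase.h1, phase)
        assert cls.kind == "parental" and cls.n_crossovers == 0 and cls.intervals == ()

    def test_single_switch_is_sco_with_middle_interval(self, panel):
        # mother heterozygous at all six polymorphic loci
        poly = [i for i, l in enumerate(panel.loci) if len(l.alleles) >= 2]
        h1 = [sorted(l.alleles)[0] for l in panel.loci]
        h2 = list(h1)
        for i in poly:
            h2[i] = sorted(panel.loci[i].alleles)[1]
        phase = _phase(tuple(h1), tuple(h2), panel)
        observed = list(h1)
        for i in poly[3:]:
            observed[i] = h2[i]
        cls = classify_crossover(tuple(observed), phase)
        assert cls.kind == "SCO" and cls.n_crossovers == 1
        assert cls.intervals == ((panel.names[poly[2]], panel.names[poly[3]]),)

    def test_inconsistent_allele_flagged_never_reclassified(self, two_locus_panel):
        phase = _phase((144, 295), (147, 298), two_locus_panel)
        cls = classify_crossover((144, 300), phase)
        assert cls.kind == "inconsistent" and cls.n_crossovers is None
        assert cls.inconsistent_loci == ("B",)

    @pytest.mark.parametrize("n_loci", [4, 7, 10])
    def test_minimal_switches_match_exhaustive_oracle(self, n_loci):
        """Minimal switch count equals the brute-force minimum over all
        2^m origin assignments consistent with the allele matches."""
        loci = tuple(
            Locus(f"L{i}", "s", 10 * (i + 1), "AAA", frozenset({100, 103}))
            for i in range(n_loci)
        )
        panel = MarkerPanel(loci)
        h1 = tuple([100] * n_loci)
        h2 = tuple([103] * n_loci)
        phase = _phase(h1, h2, panel)
        rng = np.random.default_rng(n_loci)
        for _ in range(120):
            labels = rng.integers(0, 2, size=n_loci)
            missing = rng.random(n_loci) < 0.2
            observed = tuple(
                None if m else (h1[i] if l == 0 else h2[i])
                for i, (l, m) in enumerate(zip(labels, missing))
            )
            cls = classify_crossover(observed, phase)
            best = min(
                sum(1 for a, b in zip(v, v[1:]) if a != b)
                for v in itertools.product((0, 1), repeat=n_loci)
                if all(
                    observed[i] is None or v[i] == labels[i] for i in range(n_loci)
                )
            )
            assert cls.n_crossovers == best


class TestInferPaternal:
    def test_unique_via_single_gamete(self, two_locus_panel):
        phase = _phase((144, 295), (147, 298), two_locus_panel)
        larva = _female("f1", [(144, 147), (295, 300)])
        a = infer_paternal(larva, phase)
        assert a.status == "unique"
        assert a.paternal.alleles == (147, 300)
        assert a.n_crossovers == 0

    def test_symmetric_genotype_is_ambiguous(self, two_locus_panel):
        phase = _phase((144, 295), (147, 298), two_locus_panel)
        larva = _female("f1", [(144, 147), (295, 298)])
        a = infer_paternal(larva, phase)
        assert a.status == "ambiguous"
        assert set(a.candidates) == {(144, 295), (147, 298)}

    def test_homozygous_everywhere_forces_unique(self, two_locus_panel):
        phase = _phase((144, 295), (147, 298), two_locus_panel)
        larva = _female("f1", [(144, 144), (295, 295)])
        a = infer_paternal(larva, phase)
        assert a.status == "unique" and a.paternal.alleles == (144, 295)

    def test_non_maternal_genotype_is_inconsistent(self, two_locus_panel):
        phase = _phase((144, 295), (147, 298), two_locus_panel)
        larva = _female("f1", [(144, 147), (299, 300)])
        a = infer_paternal(larva, phase)
        assert a.status == "inconsistent" and a.paternal is None

    def test_margin_demotes_recombination_confounded_calls(self, panel):
        """A paternal vector that is also reachable as a one-crossover
        maternal gamete is not called unique under margin=1."""
        poly = [i for i, l in enumerate(panel.loci) if len(l.alleles) >= 2]
        h1 = [sorted(l.alleles)[0] for l in panel.loci]
        h2 = list(h1)
        for i in poly:
            h2[i] = sorted(panel.loci[i].alleles)[1]
        phase = _phase(tuple(h1), tuple(h2), panel)
        # father's haplotype = SCO mosaic of the maternal pair
        father = list(h1)
        for i in poly[3:]:
            father[i] = h2[i]
        larva = _female("f1", list(zip(h1, father)))
        assert infer_paternal(larva, phase, margin=0).status == "unique"
        assert infer_paternal(larva, phase, margin=1).status == "ambiguous"

    def test_monotonicity_in_budget(self, family_with_truth, panel):
        """Raising the crossover budget never decreases the number of
        larvae with a consistent explanation."""
        fam, _, _ = family_with_truth
        phase = phase_maternal(fam, panel)
        counts = []
        for budget in (0, 1, 2):
            ok = sum(
                infer_paternal(f, phase, budget=budget).status != "inconsistent"
                for f in fam.female_larvae()
            )
            counts.append(ok)
        assert counts[0] <= counts[1] <= counts[2]


class TestFamilyReport:
    def test_statuses_partition_female_larvae(self, family_with_truth, panel):
        fam, _, _ = family_with_truth
        report = family_report(fam, panel, permutations=19)
        statuses = [a.status for a in report.assignments]
        assert len(statuses) == report.n_female_larvae
        assert set(statuses) <= {"unique", "ambiguous", "inconsistent"}

    def test_single_father_dominant_share(self, panel):
        rng = np.random.default_rng(4)
        mother = draw_mother(panel, rng, {"49": 2, "61": 2})
        fathers = draw_fathers(panel, 1, rng)
        fam = simulate_family(
            FamilySpec(n_fathers=1, n_larvae=80), mother, fathers, panel, rng=rng
        )
        report = family_report(fam, panel, permutations=19)
        assert report.n_fathers_min == 1
        assert report.dominant_share == 1.0

    def test_identical_subclutch_columns_give_zero_chi2(self, two_locus_panel):
        # homozygous mother: the maternal gamete is fixed, so every female
        # larva's paternal haplotype is read off directly
        mother = SampleRecord(
            "mo", "female", "F", "FAM",
            DiploidGenotype(((144, 144), (295, 295))), family="FAM",
        )
        larvae = [_male_larva("m1", (144, 295), "S1")]
        fathers = [(147, 299), (147, 300)]
        k = 0
        for sub in ("S1", "S2"):  # identical father composition per sub-clutch
            for pat in fathers:
                for _ in range(3):
                    k += 1
                    larvae.append(
                        SampleRecord(
                            f"f{k}", "female", "F", "FAM",
                            DiploidGenotype(((144, pat[0]), (295, pat[1]))),
                            stage="larva", subclutch=sub,
                        )
                    )
        fam = FamilyDataset(mother=mother, larvae=larvae)
        report = family_report(fam, two_locus_panel, permutations=99)
        assert report.n_fathers_min == 2
        assert report.subclutch_chi2 == pytest.approx(0.0)
        assert report.subclutch_p == 1.0

    def test_maternal_class_frequencies_use_both_denominators(self, family_with_truth, panel):
        fam, _, _ = family_with_truth
        report = family_report(fam, panel, permutations=19)
        for kind, vec, count, f_all, f_males in report.maternal_classes:
            assert f_all == pytest.approx(count / report.n_larvae)
            assert f_males == pytest.approx(count / report.n_male_larvae)

    def test_novel_paternal_derivations(self, panel, family_with_truth):
        fam, _, fathers = family_with_truth
        adults = simulate_adults(study_scenario(seed=11))
        catalogue = call_male_haplotypes(adults, panel)
        report = family_report(fam, panel, adult_catalogue=catalogue, permutations=19)
        known = set(catalogue.vectors)
        for vec, derivation in report.novel_paternal:
            assert vec not in known
            if derivation is not None:
                kind, sources, k = derivation
                assert kind in ("SCO", "DCO") and k in (1, 2)
                assert all(lab in catalogue.naming for lab in sources)

    def test_count_bounds_bracket_unique_counts(self, family_with_truth, panel):
        fam, _, _ = family_with_truth
        report = family_report(fam, panel, permutations=19)
        ambiguous = [a for a in report.assignments if a.status == "ambiguous"]
        for vec, (lo, hi) in report.paternal_count_bounds.items():
            assert lo == report.paternal_counts.get(vec, 0)
            extra = sum(1 for a in ambiguous if vec in a.candidates)
            assert hi == lo + extra


class TestModelWrapper:
    def test_results_delegate_and_summary(self, family_with_truth, panel):
        fam, _, _ = family_with_truth
        res = FamilyInference(fam, panel, permutations=19).fit()
        assert res.n_fathers_min == res.report.n_fathers_min
        text = res.summary()
        assert "Minimum number of fathers" in text
        assert "Maternal phase" in text
        frame = res.assignments_frame()
        assert len(frame) == res.n_female_larvae
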