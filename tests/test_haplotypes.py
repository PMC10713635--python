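import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from xhap import (
    SimScenario,
    call_male_haplotypes,
    cut_groups,
    dissimilarity,
    enumerate_potential,
    nj_tree,
    potential_haplotypes,
    regional_frequencies,
    simulate_adults,
    spectrum,
)
from xhap.core import DiploidGenotype, Locus, MarkerPanel, SampleRecord, XHaplotype
from xhap.haplotypes import DissimilarityMatrix, HaplotypeCatalogue


def _panel_with_sizes(sizes):
    loci = tuple(
        Locus(f"L{i}", "s", 10 * (i + 1), "AAA", frozenset(100 + 3 * j for j in range(k)))
        for i, k in enumerate(sizes)
    )
    return MarkerPanel(loci)


def _male(sid, hap, locality="L1", region="R1"):
    return SampleRecord(sid, "male", locality, region, DiploidGenotype(tuple((a,) for a in hap)))


class TestEnumeration:
    def test_study_panel_has_192_potential_haplotypes(self, panel):
        assert enumerate_potential(panel) == 192

    def test_monomorphic_panel_counts_one(self):
        assert enumerate_potential(_panel_with_sizes([1, 1, 1])) == 1

    def test_two_by_three_matches_explicit_enumeration(self):
        p = _panel_with_sizes([2, 3])
        haps = potential_haplotypes(p)
        assert enumerate_potential(p) == len(haps) == 6
        assert len({h.alleles for h in haps}) == 6

    @given(st.lists(st.integers(min_value=1, max_value=4), min_size=2, max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_count_equals_cartesian_product_length(self, sizes):
        p = _panel_with_sizes(sizes)
        assert enumerate_potential(p) == len(potential_haplotypes(p, cap=10_000))


class TestCalling:
    def test_pool_bounded_catalogue(self, panel):
        sc = SimScenario(panel=panel, pool_size=36, seed=9)
        records = simulate_adults(sc)
        cat = call_male_haplotypes(records, panel)
        assert len(cat) <= 36
        assert sum(c for _, c, _ in cat.entries) == cat.n_males
        assert cat.n_males == sum(r.sex == "male" for r in records)

    def test_all_identical_males(self, panel):
        hap = tuple(sorted(l.alleles)[0] for l in panel.loci)
        cat = call_male_haplotypes([_male(f"m{i}", hap) for i in range(5)], panel)
        assert len(cat) == 1
        assert cat.entries[0][1:] == (5, 1.0)

    def test_single_male(self, panel):
        hap = tuple(sorted(l.alleles)[0] for l in panel.loci)
        cat = call_male_haplotypes([_male("m0", hap)], panel)
        assert len(cat) == 1 and cat.entries[0][1] == 1

    def test_counts_invariant_to_record_order(self, panel, adults):
        rng = np.random.default_rng(1)
        shuffled = list(adults)
        rng.shuffle(shuffled)
        a = call_male_haplotypes(adults, panel)
        b = call_male_haplotypes(shuffled, panel)
        assert [(h.label, h.alleles, c) for h, c, _ in a.entries] == [
            (h.label, h.alleles, c) for h, c, _ in b.entries
        ]

    def test_labels_descending_count_ties_lexicographic(self, panel):
        base = tuple(sorted(l.alleles)[0] for l in panel.loci)
        alt = list(base)
        alt[0] = sorted(panel.loci[0].alleles)[1]
        males = [_male("a", base), _male("b", tuple(alt)), _male("c", base)]
        cat = call_male_haplotypes(males, panel)
        assert cat.entries[0][0].label == "Xhap_01" and cat.entries[0][1] == 2
        assert cat.entries[1][0].label == "Xhap_02"

    def test_missing_polymorphic_locus_excludes_male(self, panel):
        hap = list(sorted(l.alleles)[0] for l in panel.loci)
        good = _male("g", tuple(hap))
        hap_missing = list(hap)
        hap_missing[0] = None  # Ld6102 is polymorphic
        bad = SampleRecord(
            "b", "male", "L1", "R1",
            DiploidGenotype(tuple((a,) if a is not None else None for a in hap_missing)),
        )
        cat = call_male_haplotypes([good, bad], panel)
        assert cat.n_males == 1 and cat.excluded == ["b"]

    def test_two_allele_male_raises(self, panel):
        pairs = [(sorted(l.alleles)[0],) for l in panel.loci]
        pairs[0] = tuple(sorted(panel.loci[0].alleles)[:2])
        rec = SampleRecord("m", "male", "L1", "R1", DiploidGenotype(tuple(pairs)))
        with pytest.raises(ValueError, match="two alleles"):
            call_male_haplotypes([rec], panel)


class TestSpectrum:
    def _catalogue_with_counts(self, panel, counts):
        haps = potential_haplotypes(panel)
        males = []
        k = 0
        for i, c in enumerate(counts):
            for _ in range(c):
                males.append(_male(f"m{k}", haps[i].alleles))
                k += 1
        return call_male_haplotypes(males, panel)

    def test_planted_counts_match_arithmetic_oracle(self, panel):
        counts = [50, 40, 30] + [5] * 8 + [1] * 9  # n = 169 males
        cat = self._catalogue_with_counts(panel, counts)
        s = spectrum(cat)
        n = sum(counts)
        assert s.shares_percent() == (
            round(100 * 120 / n, 1),
            round(100 * 40 / n, 1),
            round(100 * 9 / n, 1),
        ) == (71.0, 23.7, 5.3)

    def test_all_singletons(self, panel):
        cat = self._catalogue_with_counts(panel, [1] * 7)
        s = spectrum(cat)
        assert s.share_singleton == 1.0 and not s.common and not s.mid

    def test_classes_partition_catalogue(self, panel, adults):
        cat = call_male_haplotypes(adults, panel)
        s = spectrum(cat)
        assert sorted(s.common + s.mid + s.singleton) == sorted(cat.naming)
        assert s.share_common + s.share_mid + s.share_singleton == pytest.approx(1.0)


class TestDissimilarity:
    def test_identical_haplotypes_zero(self, panel):
        hap = tuple(sorted(l.alleles)[0] for l in panel.loci)
        m = dissimilarity(
            HaplotypeCatalogue(
                entries=[
                    (XHaplotype(hap, label="a"), 1, 0.5),
                    (XHaplotype(hap, label="b"), 1, 0.5),
                ],
                n_males=2,
                locus_names=panel.names,
            ),
            panel,
        )
        assert m.values[0, 1] == 0.0

    def test_one_of_six_polymorphic_loci(self, panel):
        h1 = list(sorted(l.alleles)[0] for l in panel.loci)
        h2 = list(h1)
        idx = panel.index("Ld6105")
        h2[idx] = sorted(panel.loci[idx].alleles)[1]
        cat = HaplotypeCatalogue(
            entries=[
                (XHaplotype(tuple(h1), label="a"), 1, 0.5),
                (XHaplotype(tuple(h2), label="b"), 1, 0.5),
            ],
            n_males=2,
            locus_names=panel.names,
        )
        m = dissimilarity(cat, panel)
        assert m.values[0, 1] == pytest.approx(1 / 6)

    def test_matrix_properties(self, panel, adults):
        m = dissimilarity(call_male_haplotypes(adults, panel), panel)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)
        assert m.values.min() >= 0 and m.values.max() <= 1


class TestNeighbourJoining:
    @staticmethod
    def _additive_matrix(topology_split, internal=0.3, external=(0.1, 0.15, 0.2, 0.25)):
        """4-taxon additive distances for the quartet split given as a
        frozenset pair, e.g. {('a','b'),('c','d')}."""
        labels = ("a", "b", "c", "d")
        d = np.zeros((4, 4))
        (p1, p2) = topology_split
        ext = dict(zip(labels, external))
        for i, x in enumerate(labels):
            for j, y in enumerate(labels):
                if i == j:
                    continue
                same = {x, y} == set(p1) or {x, y} == set(p2)
                d[i, j] = ext[x] + ext[y] + (0 if same else internal)
        return DissimilarityMatrix(labels=labels, values=d)

    @staticmethod
    def _score(matrix, split):
        """Least-squares fit of a quartet topology via the four-point
        condition: the correct split minimises the large sum mismatch."""
        lab = list(matrix.labels)
        d = matrix.values
        (x1, x2), (y1, y2) = split
        i, j, k, l = lab.index(x1), lab.index(x2), lab.index(y1), lab.index(y2)
        return d[i, j] + d[k, l]

    @pytest.mark.parametrize(
        "split",
        [
            (("a", "b"), ("c", "d")),
            (("a", "c"), ("b", "d")),
            (("a", "d"), ("b", "c")),
        ],
    )
    def test_recovers_generating_quartet(self, split):
        m = self._additive_matrix(split)
        # brute-force oracle: the generating split has the smallest
        # within-pair distance sum among the three quartets
        splits = [
            (("a", "b"), ("c", "d")),
            (("a", "c"), ("b", "d")),
            (("a", "d"), ("b", "c")),
        ]
        best = min(splits, key=lambda s: self._score(m, s))
        assert set(map(frozenset, best)) == set(map(frozenset, split))
        tree = nj_tree(m)
        # NJ on an additive matrix joins the generating cherry first
        import dendropy

        t = dendropy.Tree.get(data=tree.as_string(schema="newick"), schema="newick")
        for node in t.preorder_node_iter():
            leaves = {l.taxon.label for l in node.leaf_iter()}
            if len(leaves) == 2:
                assert leaves in (set(split[0]), set(split[1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scikit_bio_topology(self, seed):
        """Independent cross-check against scikit-bio's neighbour joining
        on tie-free distance matrices (with tied distances the joined pair
        is implementation-defined, so topologies may legitimately differ)."""
        import io

        import dendropy
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(seed)
        n = 12
        pts = rng.random((n, 5))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
        labels = tuple(f"t{i}" for i in range(n))
        ours = nj_tree(DissimilarityMatrix(labels=labels, values=d))
        theirs = skbio_nj(DistanceMatrix(d, ids=list(labels)))
        buf = io.StringIO()
        theirs.write(buf)
        tns = dendropy.TaxonNamespace()
        t1 = dendropy.Tree.get(data=ours.as_string(schema="newick"), schema="newick",
                               taxon_namespace=tns)
        t2 = dendropy.Tree.get(data=buf.getvalue(), schema="newick",
                               taxon_namespace=tns)
        t1.encode_bipartitions()
        t2.encode_bipartitions()
        rf = dendropy.calculate.treecompare.symmetric_difference(t1, t2)
        assert rf == 0

    def test_fewer_than_three_taxa_rejected(self):
        m = DissimilarityMatrix(labels=("a", "b"), values=np.array([[0, 1.0], [1.0, 0]]))
        with pytest.raises(ValueError, match="at least 3"):
            nj_tree(m)

    def test_asymmetric_matrix_rejected(self):
        v = np.array([[0, 1, 2], [1.5, 0, 1], [2, 1, 0]], dtype=float)
        with pytest.raises(ValueError, match="symmetric"):
            nj_tree(DissimilarityMatrix(labels=("a", "b", "c"), values=v))


class TestRegionalFrequencies:
    def test_single_region_equals_catalogue(self, panel):
        sc = SimScenario(panel=panel, n_localities=3, n_regions=1, seed=3)
        records = simulate_adults(sc)
        cat = call_male_haplotypes(records, panel)
        table = regional_frequencies(records, cat, panel)
        freqs = dict(zip(table["label"], table["frequency"]))
        for hap, _, f in cat.entries:
            assert freqs[hap.label] == pytest.approx(f)

    def test_one_male_region(self, panel):
        hap = tuple(sorted(l.alleles)[0] for l in panel.loci)
        records = [_male("m0", hap, locality="Lx", region="West")]
        cat = call_male_haplotypes(records, panel)
        table = regional_frequencies(records, cat, panel)
        assert len(table) == 1 and table.iloc[0]["frequency"] == 1.0

    def test_frequencies_sum_to_one_per_region(self, panel, adults):
        cat = call_male_haplotypes(adults, panel)
        table = regional_frequencies(adults, cat, panel)
        sums = table.groupby("region")["frequency"].sum()
        assert np.allclose(sums, 1.0)

    def test_planted_cline_is_monotone_across_regions(self, panel):
        sc = SimScenario(
            panel=panel,
            n_localities=12,
            adults_per_locality=80,
            n_regions=4,
            pool_size=6,
            cline=(0, 3.0, 0.0),  # pool haplotype 0 fades west -> east
            seed=13,
        )
        records = simulate_adults(sc)
        cat = call_male_haplotypes(records, panel)
        table = regional_frequencies(records, cat, panel)
        # the most frequent haplotype overall is the planted one
        label = cat.entries[0][0].label
        sub = table[table["label"] == label].set_index("region")["frequency"]
        freqs = [sub.get(f"R{g}", 0.0) for g in range(1, 5)]
        assert all(a >= b for a, b in zip(freqs, freqs[1:]))


def test_cut_groups_threshold(panel, adults):
    cat = call_male_haplotypes(adults, panel)
    m = dissimilarity(cat, panel)
    groups_fine = cut_groups(m, height=1e-9)
    groups_coarse = cut_groups(m, height=1.01)
    assert len(set(groups_fine.values())) == len(m.labels)
    assert len(set(groups_coarse.values())) == 1
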