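"""Haplotype enumeration, calling and frequency analysis in hemizygous
males, plus dissimilarity-based neighbour-joining grouping and regional
frequency tables.

In an X0 system every male's multilocus genotype is one X-haplotype, so a
male sample directly exposes the haplotype spectrum of the population.
"Polymorphic" is always decided on the *working* allele set (panel
definition extended by observed alleles), never hard-coded.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Optional

import dendropy
import numpy as np
import pandas as pd

from .core import MALE, MarkerPanel, SampleRecord, XHaplotype, validate_male_hemizygosity

log = logging.getLogger("xhap")

__all__ = [
    "HaplotypeCatalogue",
    "FrequencySpectrum",
    "DissimilarityMatrix",
    "working_allele_sets",
    "enumerate_potential",
    "potential_haplotypes",
    "call_male_haplotypes",
    "spectrum",
    "dissimilarity",
    "nj_tree",
    "regional_frequencies",
    "cut_groups",
]


@dataclass
class HaplotypeCatalogue:
    """Distinct male haplotypes with counts and frequencies.

    Entries are ordered by descending count (ties broken lexicographically
    by allele vector) and labelled ``Xhap_01``, ``Xhap_02``, ...
    """

    entries: list  # [(XHaplotype, count, frequency)]
    n_males: int
    locus_names: tuple
    excluded: list = None  # sample_ids dropped for missing polymorphic calls

    def __post_init__(self):
        if self.excluded is None:
            self.excluded = []

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def naming(self) -> dict:
        return {hap.label: hap for hap, _, _ in self.entries}

    @property
    def vectors(self) -> dict:
        """Mapping allele vector -> label."""
        return {hap.alleles: hap.label for hap, _, _ in self.entries}

    def counts(self) -> dict:
        return {hap.label: c for hap, c, _ in self.entries}


@dataclass
class FrequencySpectrum:
    """Haplotype frequency classes: common (count > 10), mid (2-10 copies)
    and singletons, with the share of males carried by each class."""

    common: list
    mid: list
    singleton: list
    share_common: float
    share_mid: float
    share_singleton: float

    def shares_percent(self, ndigits: int = 1) -> tuple:
        return (
            round(100 * self.share_common, ndigits),
            round(100 * self.share_mid, ndigits),
            round(100 * self.share_singleton, ndigits),
        )


@dataclass
class DissimilarityMatrix:
    labels: tuple
    values: np.ndarray  # symmetric, zero diagonal, entries in [0, 1]


def working_allele_sets(panel: MarkerPanel, records: Iterable[SampleRecord]) -> list:
    """Panel allele sets extended by every allele observed in ``records``."""
    sets = [set(l.alleles) for l in panel.loci]
    for rec in records:
        for i, pair in enumerate(rec.calls.pairs):
            if pair is not None:
                sets[i].update(pair)
    return [frozenset(s) for s in sets]


def enumerate_potential(
    panel: MarkerPanel, working_alleles: Optional[list] = None
) -> int:
    """Number of potential haplotypes: the product of allele-set sizes over
    polymorphic loci.  With no polymorphic loci the count is 1 (flagged)."""
    sets = working_alleles if working_alleles is not None else [l.alleles for l in panel.loci]
    poly = panel.polymorphic_indices(sets)
    if not poly:
        log.warning("no polymorphic loci: potential haplotype count is trivially 1")
        return 1
    count = 1
    for i in poly:
        count *= len(sets[i])
    return count


def potential_haplotypes(
    panel: MarkerPanel, working_alleles: Optional[list] = None, cap: int = 10_000
) -> list:
    """Explicit enumeration (lexicographic in panel order, alleles
    ascending) of all potential haplotypes; monomorphic loci carry their
    single allele.  Refuses to enumerate beyond ``cap`` combinations."""
    sets = working_alleles if working_alleles is not None else [l.alleles for l in panel.loci]
    count = enumerate_potential(panel, sets)
    if count > cap:
        raise ValueError(f"{count} combinations exceed enumeration cap {cap}")
    choices = [sorted(s) for s in sets]
    return [XHaplotype(v) for v in itertools.product(*choices)]


def call_male_haplotypes(
    records: Iterable[SampleRecord], panel: MarkerPanel
) -> HaplotypeCatalogue:
    """Collapse male records into a haplotype catalogue.

    Males with a missing call at any polymorphic locus are excluded (and
    listed in ``catalogue.excluded``); a missing call at a monomorphic
    locus is imputed to the locus's single working allele.  Raises on any
    male with two distinct alleles at a locus.
    """
    males = [r for r in records if r.sex == MALE]
    bad = validate_male_hemizygosity(males)
    if bad:
        raise ValueError(f"males with two alleles at a locus: {bad[:5]}{'...' if len(bad) > 5 else ''}")
    sets = working_allele_sets(panel, males)
    poly = set(panel.polymorphic_indices(sets))
    counts: dict = {}
    excluded = []
    n_included = 0
    for rec in males:
        hap = list(rec.haplotype())
        ok = True
        for i, a in enumerate(hap):
            if a is None:
                if i in poly:
                    ok = False
                    break
                hap[i] = next(iter(sets[i]))
        if not ok:
            excluded.append(rec.sample_id)
            continue
        n_included += 1
        counts[tuple(hap)] = counts.get(tuple(hap), 0) + 1
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = [
        (XHaplotype(vec, label=f"Xhap_{i + 1:02d}"), c, c / n_included)
        for i, (vec, c) in enumerate(ordered)
    ]
    if excluded:
        log.warning("excluded %d males with missing polymorphic calls", len(excluded))
    return HaplotypeCatalogue(
        entries=entries, n_males=n_included, locus_names=panel.names, excluded=excluded
    )


def spectrum(catalogue: HaplotypeCatalogue) -> FrequencySpectrum:
    """Partition the catalogue into count classes {>10, 2-10, 1} and report
    the share of males carried by each class."""
    if not catalogue.entries:
        raise ValueError("empty catalogue")
    common, mid, singleton = [], [], []
    males = {"common": 0, "mid": 0, "singleton": 0}
    for hap, c, _ in catalogue.entries:
        if c > 10:
            common.append(hap.label)
            males["common"] += c
        elif c >= 2:
            mid.append(hap.label)
            males["mid"] += c
        else:
            singleton.append(hap.label)
            males["singleton"] += c
    n = catalogue.n_males
    return FrequencySpectrum(
        common=common,
        mid=mid,
        singleton=singleton,
        share_common=males["common"] / n,
        share_mid=males["mid"] / n,
        share_singleton=males["singleton"] / n,
    )


def dissimilarity(
    catalogue: HaplotypeCatalogue, panel: Optional[MarkerPanel] = None
) -> DissimilarityMatrix:
    """Simple-matching dissimilarity between catalogue haplotypes over
    polymorphic loci: (# mismatching loci) / (# jointly non-missing loci).

    When a panel is given, "polymorphic" is decided on the panel's working
    allele sets; otherwise on the columns that vary within the catalogue.
    """
    vecs = [hap.alleles for hap, _, _ in catalogue.entries]
    labels = tuple(hap.label for hap, _, _ in catalogue.entries)
    arr = np.asarray(vecs)
    if panel is not None:
        idx = [panel.names.index(n) for n in catalogue.locus_names]
        sets = [panel.loci[i].alleles | set(arr[:, j]) for j, i in enumerate(idx)]
        poly = [j for j, s in enumerate(sets) if len(s) >= 2]
    else:
        poly = [j for j in range(arr.shape[1]) if len(set(arr[:, j])) >= 2]
    if not poly:
        raise ValueError("no polymorphic loci to compare")
    sub = arr[:, poly]
    mism = (sub[:, None, :] != sub[None, :, :]).sum(axis=2)
    values = mism / len(poly)
    return DissimilarityMatrix(labels=labels, values=values.astype(float))


def nj_tree(matrix: DissimilarityMatrix) -> dendropy.Tree:
    """Unweighted neighbour joining on a dissimilarity matrix.

    Classic agglomeration: at each step the pair minimising
    Q(i,j) = (n-2) d(i,j) - r_i - r_j is joined, the lowest-index pair
    first on ties (deterministic output).  Negative branch lengths are
    clamped to 0 with a log notice.  Returns an unrooted dendropy tree
    whose seed node is the final trifurcation.
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise ValueError("neighbour joining needs at least 3 taxa")
    D = np.asarray(matrix.values, dtype=float)
    if D.shape != (n, n) or not np.allclose(D, D.T):
        raise ValueError("dissimilarity matrix must be square and symmetric")

    tns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=tns)
    nodes = []
    for lab in labels:
        nd = dendropy.Node()
        nd.taxon = tns.get_taxon(lab)
        nodes.append(nd)
    active = list(range(n))
    D = D.copy()
    clamped = 0

    def _set_edge(child, length):
        nonlocal clamped
        if length < 0:
            clamped += 1
            length = 0.0
        child.edge.length = float(length)

    while len(active) > 3:
        m = len(active)
        r = {i: sum(D[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * D[i, j] - r[i] - r[j]
                if best_q is None or q < best_q:  # strict: lowest-index pair wins ties
                    best_q = q
                    best = (i, j)
        i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        _set_edge(nodes[i], li)
        _set_edge(nodes[j], lj)
        # distances from the new node to the remaining taxa
        newD = np.zeros(D.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            newD[k] = 0.5 * (D[i, k] + D[j, k] - D[i, j])
        D = np.pad(D, ((0, 1), (0, 1)))
        u = D.shape[0] - 1
        D[u, :-1] = newD[:-1]
        D[:-1, u] = newD[:-1]
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    a, b, c = active
    root = dendropy.Node()
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    for k, lk in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[k])
        _set_edge(nodes[k], lk)
    if clamped:
        log.info("clamped %d negative branch lengths to 0", clamped)
    tree.seed_node = root
    tree.is_rooted = False
    return tree


def regional_frequencies(
    records: Iterable[SampleRecord], catalogue: HaplotypeCatalogue, panel: MarkerPanel
) -> pd.DataFrame:
    """Per-region haplotype frequencies among males (long format:
    region, label, count, frequency; frequencies sum to 1 per region).
    Male vectors absent from the catalogue are reported as ``other``."""
    vectors = catalogue.vectors
    rows: dict = {}
    totals: dict = {}
    sets = working_allele_sets(panel, [r for r in records if r.sex == MALE])
    poly = set(panel.polymorphic_indices(sets))
    for rec in records:
        if rec.sex != MALE:
            continue
        hap = list(rec.haplotype())
        skip = False
        for i, a in enumerate(hap):
            if a is None:
                if i in poly:
                    skip = True
                    break
                hap[i] = next(iter(sets[i]))
        if skip:
            continue
        label = vectors.get(tuple(hap), "other")
        rows[(rec.region, label)] = rows.get((rec.region, label), 0) + 1
        totals[rec.region] = totals.get(rec.region, 0) + 1
    out = [
        {"region": reg, "label": lab, "count": c, "frequency": c / totals[reg]}
        for (reg, lab), c in sorted(rows.items())
    ]
    return pd.DataFrame(out, columns=["region", "label", "count", "frequency"])


def cut_groups(matrix: DissimilarityMatrix, height: float) -> dict:
    """Descriptive single-linkage grouping of haplotypes at a dissimilarity
    threshold (the tree-cut utility for delimiting haplotype groups)."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(matrix.values, checks=False), method="single")
    assignment = fcluster(Z, t=height, criterion="distance")
    return {lab: int(g) for lab, g in zip(matrix.labels, assignment)}
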