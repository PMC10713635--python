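"""Maternal phasing, crossover classification and paternity deconvolution
in single-female families.

The logic rests on X0 inheritance: a male larva carries exactly his
mother's transmitted X, so male larvae expose the two maternal haplotypes
(and their recombinants) directly; a female larva carries one maternal
gamete plus her father's X, so subtracting the maternal gamete from her
diploid genotype yields the paternal haplotype.  Minimal-crossover
parsimony is the explanation criterion throughout: an observed gamete is
attributed the fewest origin switches (along loci ordered by chromosome
position) compatible with the allele matches, and ties in the paternal
reconstruction are reported as ambiguity, never broken silently.

The number of distinct paternal haplotypes is a *minimum* bound on the
number of fathers (two fathers sharing a haplotype are indistinguishable).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import FEMALE, MALE, FamilyDataset, MarkerPanel, SampleRecord, XHaplotype

log = logging.getLogger("xhap")

__all__ = [
    "PhasingError",
    "MaternalPhase",
    "CrossoverClassification",
    "PaternalAssignment",
    "FamilyReport",
    "phase_maternal",
    "classify_crossover",
    "infer_paternal",
    "family_report",
    "FamilyInference",
    "FamilyInferenceResults",
]

KIND_BY_COUNT = {0: "parental", 1: "SCO", 2: "DCO"}


class PhasingError(RuntimeError):
    """No phasing of the mother's genotype explains any male larva within
    the crossover budget."""


@dataclass
class MaternalPhase:
    """The mother's two X haplotypes as resolved from her male larvae."""

    h1: XHaplotype
    h2: XHaplotype
    heterozygous_loci: tuple  # panel indices where h1 != h2, position order
    locus_names: tuple
    scaffolds: tuple
    support: tuple  # male larvae matching (h1 exactly, h2 exactly)
    n_zero_crossover: int = 0
    total_crossovers: int = 0

    @property
    def n_hm(self) -> dict:
        """Heterozygous-locus count per scaffold (ascending scaffold id)."""
        out: dict = {}
        for i in self.heterozygous_loci:
            out[self.scaffolds[i]] = out.get(self.scaffolds[i], 0) + 1
        return {k: out.get(k, 0) for k in sorted(set(self.scaffolds))}

    @property
    def n_hm_pair(self) -> tuple:
        return tuple(self.n_hm.values())

    def informative_names(self) -> tuple:
        return tuple(self.locus_names[i] for i in self.heterozygous_loci)


@dataclass
class CrossoverClassification:
    """Parsimony classification of one observed maternal gamete."""

    kind: str  # parental | SCO | DCO | complex | inconsistent
    n_crossovers: Optional[int]
    origins: tuple  # per informative locus: 'H1' | 'H2' | None (missing)
    intervals: tuple  # (left locus name, right locus name) per switch
    inconsistent_loci: tuple = ()


@dataclass
class PaternalAssignment:
    """Reconstruction of the paternal X from one female larva."""

    larva_id: str
    status: str  # unique | ambiguous | inconsistent
    n_crossovers: Optional[int]  # crossovers in the minimal maternal-gamete explanation
    paternal: Optional[XHaplotype]  # set when unique
    candidates: tuple  # all minimal-explanation paternal vectors
    maternal_origins: tuple = ()  # origin labels of one minimal explanation


@dataclass
class FamilyReport:
    family_id: str
    phase: MaternalPhase
    n_larvae: int
    n_male_larvae: int
    n_female_larvae: int
    maternal_classes: list  # (kind, vector, count, freq_all, freq_males)
    maternal_kind_counts: dict
    assignments: list  # PaternalAssignment per female larva
    paternal_counts: dict  # vector -> unique-status count
    paternal_count_bounds: dict  # vector -> (min, max) counts incl. ambiguity
    n_fathers_min: int
    dominant_share: float
    subclutch_table: Optional[pd.DataFrame]
    subclutch_chi2: float
    subclutch_p: float
    novel_paternal: list  # (vector, derivation | None) absent from adult catalogue
    notes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# maternal phasing


def _explain_gamete(observed, h1, h2, het_idx, mother_pairs):
    """Origin labels and minimal switch count of an observed (male-larva)
    haplotype against a candidate phase.

    Returns (labels, n_switches, inconsistent_locus_indices); labels are 0/1
    per informative locus, None where the observation is missing.  A locus
    whose allele matches neither haplotype — informative or not — marks the
    observation inconsistent.
    """
    inconsistent = []
    # non-informative loci must carry the (single) maternal allele
    for i, pair in enumerate(mother_pairs):
        if pair is None or i in het_idx:
            continue
        a = observed[i]
        if a is not None and a != pair[0] and a != pair[-1]:
            inconsistent.append(i)
    labels = []
    for i in het_idx:
        a = observed[i]
        if a is None:
            labels.append(None)
        elif a == h1[i]:
            labels.append(0)
        elif a == h2[i]:
            labels.append(1)
        else:
            inconsistent.append(i)
            labels.append(None)
    seen = [l for l in labels if l is not None]
    switches = sum(1 for x, y in zip(seen, seen[1:]) if x != y)
    return labels, switches, sorted(inconsistent)


def phase_maternal(
    family: FamilyDataset, panel: MarkerPanel, budget: int = 2
) -> MaternalPhase:
    """Resolve the mother's two haplotypes from her male larvae.

    All phasings of the mother's genotype are scored; the winner maximises
    the number of male larvae explained with zero crossovers, then
    minimises the total crossovers over all (consistent) male larvae, with
    a lexicographic tie-break on the H1 vector.  Raises
    :class:`PhasingError` when no phasing explains any male larva within
    ``budget`` crossovers.
    """
    mother_pairs = family.mother.calls.pairs
    males = family.male_larvae()
    if not males:
        raise ValueError("maternal phasing requires at least one male larva")
    het_idx = tuple(
        i for i, p in enumerate(mother_pairs) if p is not None and len(set(p)) == 2
    )
    male_haps = [m.haplotype() for m in males]

    if not het_idx:
        log.warning(
            "mother %s is homozygous at all loci: trivial phase, recombination undetectable",
            family.mother.sample_id,
        )
        hap = tuple(p[0] if p is not None else None for p in mother_pairs)
        n_ok = sum(
            1
            for obs in male_haps
            if not _explain_gamete(obs, hap, hap, (), mother_pairs)[2]
        )
        return MaternalPhase(
            h1=XHaplotype(hap, label="H1"),
            h2=XHaplotype(hap, label="H2"),
            heterozygous_loci=(),
            locus_names=panel.names,
            scaffolds=tuple(l.scaffold for l in panel.loci),
            support=(n_ok, n_ok),
        )

    base = [p[0] if p is not None else None for p in mother_pairs]
    best = None
    # fix the first heterozygous locus to break the (H1, H2) symmetry
    for combo in itertools.product((0, 1), repeat=len(het_idx) - 1):
        h1 = list(base)
        h2 = list(base)
        for j, i in enumerate(het_idx):
            pick = 0 if j == 0 else combo[j - 1]
            h1[i] = mother_pairs[i][pick]
            h2[i] = mother_pairs[i][1 - pick]
        n_zero = 0
        total = 0
        n_explained = 0
        for obs in male_haps:
            labels, k, bad = _explain_gamete(obs, h1, h2, het_idx, mother_pairs)
            if bad or k > budget:
                continue
            n_explained += 1
            total += k
            if k == 0:
                n_zero += 1
        score = (-n_zero, total, tuple(h1))
        if best is None or score < best[0]:
            best = (score, tuple(h1), tuple(h2), n_zero, total, n_explained)

    _, h1, h2, n_zero, total, n_explained = best
    if n_explained == 0:
        raise PhasingError(
            f"no phasing of mother {family.mother.sample_id} explains any male "
            f"larva within {budget} crossovers"
        )
    support_h1 = 0
    support_h2 = 0
    for obs in male_haps:
        labels, k, bad = _explain_gamete(obs, h1, h2, het_idx, mother_pairs)
        if bad or k != 0:
            continue
        seen = {l for l in labels if l is not None}
        if seen == {0}:
            support_h1 += 1
        elif seen == {1}:
            support_h2 += 1
    return MaternalPhase(
        h1=XHaplotype(h1, label="H1"),
        h2=XHaplotype(h2, label="H2"),
        heterozygous_loci=het_idx,
        locus_names=panel.names,
        scaffolds=tuple(l.scaffold for l in panel.loci),
        support=(support_h1, support_h2),
        n_zero_crossover=n_zero,
        total_crossovers=total,
    )


# ---------------------------------------------------------------------------
# crossover classification


def classify_crossover(observed, phase: MaternalPhase) -> CrossoverClassification:
    """Classify an observed maternal gamete by minimal origin switches.

    ``observed`` is an :class:`XHaplotype` or an allele tuple (``None`` =
    missing).  Any locus matching neither maternal haplotype yields
    ``kind='inconsistent'`` (possible mutation or non-maternal origin;
    never silently reclassified).
    """
    alleles = observed.alleles if isinstance(observed, XHaplotype) else tuple(observed)
    het_idx = phase.heterozygous_loci
    mother_pairs = tuple(
        (phase.h1.alleles[i], phase.h2.alleles[i]) for i in range(len(phase.h1))
    )
    labels, switches, bad = _explain_gamete(
        alleles, phase.h1.alleles, phase.h2.alleles, het_idx, mother_pairs
    )
    origins = tuple(
        None if l is None else ("H1" if l == 0 else "H2") for l in labels
    )
    if bad:
        return CrossoverClassification(
            kind="inconsistent",
            n_crossovers=None,
            origins=origins,
            intervals=(),
            inconsistent_loci=tuple(phase.locus_names[i] for i in bad),
        )
    names = phase.informative_names()
    observed_pos = [(j, l) for j, l in enumerate(labels) if l is not None]
    intervals = tuple(
        (names[a], names[b])
        for (a, la), (b, lb) in zip(observed_pos, observed_pos[1:])
        if la != lb
    )
    kind = KIND_BY_COUNT.get(switches, "complex")
    return CrossoverClassification(
        kind=kind, n_crossovers=switches, origins=origins, intervals=intervals
    )


# ---------------------------------------------------------------------------
# paternal inference


def _origin_vectors(m: int, budget: int):
    """All 0/1 origin vectors of length m with at most ``budget`` switches."""
    if m == 0:
        yield ()
        return
    for v in itertools.product((0, 1), repeat=m):
        if sum(1 for a, b in zip(v, v[1:]) if a != b) <= budget:
            yield v


def infer_paternal(
    larva: SampleRecord, phase: MaternalPhase, budget: int = 2, margin: int = 0
) -> PaternalAssignment:
    """Deconvolve the paternal haplotype from a female larva's genotype.

    Enumerates every maternal gamete derivable from (H1, H2) with at most
    ``budget`` crossovers; a gamete is consistent when each locus genotype
    contains the gamete allele, and the paternal allele is then the other
    member of the pair.  Among consistent explanations only the minimal
    crossover count is kept; the status is ``unique`` if all minimal
    explanations agree on the paternal vector, ``ambiguous`` otherwise,
    and ``inconsistent`` if no explanation exists within budget (possible
    mutation or non-maternal origin; reported, never reclassified).

    ``margin > 0`` makes the uniqueness call conservative: the status is
    ``unique`` only when every explanation within ``margin`` extra
    crossovers of the minimum also agrees.  With rare but non-negligible
    recombination a one-crossover alternative is not decisively less
    plausible than the minimal one, so father *counting* uses margin 1 to
    avoid inventing fathers from recombinant maternal gametes; the
    reported paternal vector and crossover count always come from the
    minimal explanations.
    """
    if larva.sex != FEMALE:
        raise ValueError("paternal inference is defined for female larvae only")
    pairs = larva.calls.pairs
    het_idx = phase.heterozygous_loci
    h1, h2 = phase.h1.alleles, phase.h2.alleles
    n = len(h1)
    explanations = []  # (k, paternal vector, origins)
    for origins in _origin_vectors(len(het_idx), budget):
        k = sum(1 for a, b in zip(origins, origins[1:]) if a != b)
        gamete = list(h1)
        for j, i in enumerate(het_idx):
            gamete[i] = h1[i] if origins[j] == 0 else h2[i]
        paternal = []
        ok = True
        for i in range(n):
            pair = pairs[i]
            g = gamete[i]
            if pair is None or g is None:
                paternal.append(None)
                continue
            if pair[0] == g:
                paternal.append(pair[-1])
            elif pair[-1] == g:
                paternal.append(pair[0])
            else:
                ok = False
                break
        if ok:
            explanations.append((k, tuple(paternal), origins))
    if not explanations:
        return PaternalAssignment(
            larva_id=larva.sample_id,
            status="inconsistent",
            n_crossovers=None,
            paternal=None,
            candidates=(),
        )
    kmin = min(e[0] for e in explanations)
    minimal = [e for e in explanations if e[0] == kmin]
    vectors = sorted({e[1] for e in minimal}, key=lambda v: tuple(-1 if a is None else a for a in v))
    within_margin = {e[1] for e in explanations if e[0] <= kmin + margin}
    origins0 = tuple("H1" if o == 0 else "H2" for o in minimal[0][2])
    if len(vectors) == 1 and len(within_margin) == 1:
        return PaternalAssignment(
            larva_id=larva.sample_id,
            status="unique",
            n_crossovers=kmin,
            paternal=XHaplotype(vectors[0]),
            candidates=tuple(vectors),
            maternal_origins=origins0,
        )
    return PaternalAssignment(
        larva_id=larva.sample_id,
        status="ambiguous",
        n_crossovers=kmin,
        paternal=None,
        candidates=tuple(vectors),
        maternal_origins=origins0,
    )


# ---------------------------------------------------------------------------
# family report


def _mosaic_min_switches(vector, a, b, order):
    """Minimal switches expressing ``vector`` as a mosaic of vectors a and b
    over the locus indices in ``order``; None when infeasible."""
    labels = []
    for i in order:
        va, vb, v = a[i], b[i], vector[i]
        if va == vb:
            if v != va:
                return None
            continue
        if v == va:
            labels.append(0)
        elif v == vb:
            labels.append(1)
        else:
            return None
    return sum(1 for x, y in zip(labels, labels[1:]) if x != y)


def _derive_novel(vector, catalogue, panel):
    """Minimal SCO/DCO derivation of a paternal vector from catalogue
    haplotypes; returns (kind, (source labels), k) or None."""
    order = [panel.names.index(n) for n in catalogue.locus_names]
    entries = [(hap.label, hap.alleles) for hap, _, _ in catalogue.entries]
    best = None
    for (la, va), (lb, vb) in itertools.combinations(entries, 2):
        k = _mosaic_min_switches(vector, va, vb, range(len(vector)))
        if k is None or k == 0 or k > 2:
            continue
        if best is None or k < best[2]:
            best = (KIND_BY_COUNT[k], (la, lb), k)
            if k == 1:
                break
    return best


def _chi2_stat(table: np.ndarray) -> float:
    table = np.asarray(table, dtype=float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    total = table.sum()
    if total == 0:
        return 0.0
    expected = rows @ cols / total
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def family_report(
    family: FamilyDataset,
    panel: MarkerPanel,
    budget: int = 2,
    adult_catalogue=None,
    permutations: int = 999,
    seed: int = 0,
    margin: int = 1,
) -> FamilyReport:
    """Full per-family analysis: maternal phase, recombinant classes with
    both frequency denominators (all larvae / male larvae), paternal
    catalogue with ambiguity-adjusted count bounds, minimum father count
    and dominant share, sub-clutch homogeneity (chi-square with a
    permutation p-value), and derivations of paternal haplotypes absent
    from the adult catalogue."""
    notes = []
    phase = phase_maternal(family, panel, budget=budget)
    males = family.male_larvae()
    females = family.female_larvae()

    # maternal side: classify male-larva gametes
    kind_counts: dict = {}
    class_counts: dict = {}
    for m in males:
        cls = classify_crossover(m.haplotype(), phase)
        kind_counts[cls.kind] = kind_counts.get(cls.kind, 0) + 1
        key = (cls.kind, m.haplotype())
        class_counts[key] = class_counts.get(key, 0) + 1
    n_all = len(family.larvae)
    n_males = len(males)
    maternal_classes = [
        (kind, vec, c, c / n_all, c / n_males if n_males else float("nan"))
        for (kind, vec), c in sorted(class_counts.items(), key=lambda kv: (-kv[1], kv[0]))
        if kind not in ("complex", "inconsistent")  # excluded from frequency lines
    ]

    # paternal side
    assignments = [infer_paternal(f, phase, budget=budget, margin=margin) for f in females]
    if not females:
        notes.append("no female larvae: paternal sections empty")
    unique = [a for a in assignments if a.status == "unique"]
    ambiguous = [a for a in assignments if a.status == "ambiguous"]
    paternal_counts: dict = {}
    for a in unique:
        v = a.paternal.alleles
        paternal_counts[v] = paternal_counts.get(v, 0) + 1
    bounds = {v: [c, c] for v, c in paternal_counts.items()}
    for a in ambiguous:
        for v in a.candidates:
            bounds.setdefault(v, [0, 0])[1] += 1
    paternal_count_bounds = {v: tuple(mm) for v, mm in bounds.items()}
    n_fathers_min = len(paternal_counts)
    total_unique = sum(paternal_counts.values())
    dominant_share = max(paternal_counts.values()) / total_unique if total_unique else 0.0

    # sub-clutch homogeneity among unique-status assignments
    sub_of = {f.sample_id: f.subclutch for f in females}
    labels = sorted(paternal_counts, key=lambda v: -paternal_counts[v])
    label_idx = {v: i for i, v in enumerate(labels)}
    subclutches = sorted({sub_of[a.larva_id] for a in unique if sub_of[a.larva_id]})
    if labels and len(subclutches) >= 2:
        sub_idx = {s: j for j, s in enumerate(subclutches)}
        table = np.zeros((len(labels), len(subclutches)), dtype=int)
        rows_units = []
        for a in unique:
            s = sub_of[a.larva_id]
            if s is None:
                continue
            table[label_idx[a.paternal.alleles], sub_idx[s]] += 1
            rows_units.append((label_idx[a.paternal.alleles], sub_idx[s]))
        stat = _chi2_stat(table)
        rng = np.random.default_rng(seed)
        fathers_arr = np.array([r[0] for r in rows_units])
        subs_arr = np.array([r[1] for r in rows_units])
        b = 0
        for _ in range(permutations):
            perm = rng.permutation(subs_arr)
            t = np.zeros_like(table)
            np.add.at(t, (fathers_arr, perm), 1)
            if _chi2_stat(t) >= stat - 1e-12:
                b += 1
        pval = (b + 1) / (permutations + 1)
        sub_df = pd.DataFrame(
            table,
            index=[f"P{i + 1:02d}" for i in range(len(labels))],
            columns=subclutches,
        )
    else:
        stat, pval, sub_df = 0.0, 1.0, None

    # paternal haplotypes absent from the adult catalogue
    novel = []
    if adult_catalogue is not None:
        known = set(adult_catalogue.vectors)
        for v in paternal_counts:
            if v not in known:
                novel.append((v, _derive_novel(v, adult_catalogue, panel)))

    return FamilyReport(
        family_id=family.mother.family or family.mother.sample_id,
        phase=phase,
        n_larvae=n_all,
        n_male_larvae=n_males,
        n_female_larvae=len(females),
        maternal_classes=maternal_classes,
        maternal_kind_counts=kind_counts,
        assignments=assignments,
        paternal_counts=paternal_counts,
        paternal_count_bounds=paternal_count_bounds,
        n_fathers_min=n_fathers_min,
        dominant_share=dominant_share,
        subclutch_table=sub_df,
        subclutch_chi2=stat,
        subclutch_p=pval,
        novel_paternal=novel,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# model-style wrapper


class FamilyInference:
    """Model object for one single-female family.

    Parameters mirror :func:`family_report`; :meth:`fit` runs the full
    procedure and returns a :class:`FamilyInferenceResults`.
    """

    def __init__(
        self,
        family: FamilyDataset,
        panel: MarkerPanel,
        budget: int = 2,
        adult_catalogue=None,
        permutations: int = 999,
        seed: int = 0,
        margin: int = 1,
    ):
        self.family = family
        self.panel = panel
        self.budget = budget
        self.adult_catalogue = adult_catalogue
        self.permutations = permutations
        self.seed = seed
        self.margin = margin

    def fit(self) -> "FamilyInferenceResults":
        report = family_report(
            self.family,
            self.panel,
            budget=self.budget,
            adult_catalogue=self.adult_catalogue,
            permutations=self.permutations,
            seed=self.seed,
            margin=self.margin,
        )
        return FamilyInferenceResults(self, report)


class FamilyInferenceResults:
    """Fitted family analysis; exposes the report fields and a summary."""

    def __init__(self, model: FamilyInference, report: FamilyReport):
        self.model = model
        self.report = report

    def __getattr__(self, name):
        return getattr(self.report, name)

    def assignments_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.report.assignments:
            rows.append(
                {
                    "larva_id": a.larva_id,
                    "status": a.status,
                    "n_crossovers": a.n_crossovers,
                    "paternal": "/".join(map(str, a.paternal.alleles)) if a.paternal else "",
                }
            )
        return pd.DataFrame(rows, columns=["larva_id", "status", "n_crossovers", "paternal"])

    def summary(self) -> str:
        r = self.report
        ph = r.phase
        lines = [
            f"Family {r.family_id}: {r.n_larvae} larvae "
            f"({r.n_male_larvae} male, {r.n_female_larvae} female)",
            f"Maternal phase H1 = {'/'.join(map(str, ph.h1.alleles))}",
            f"               H2 = {'/'.join(map(str, ph.h2.alleles))}",
            f"Heterozygous loci (N_hm by scaffold): {ph.n_hm}",
            f"Exact-match support (H1, H2): {ph.support}",
            "Maternal gamete kinds: "
            + ", ".join(f"{k}={v}" for k, v in sorted(r.maternal_kind_counts.items())),
            f"Minimum number of fathers: {r.n_fathers_min} "
            f"(dominant share {r.dominant_share:.3f})",
            f"Sub-clutch homogeneity: chi2 = {r.subclutch_chi2:.3f}, "
            f"permutation p = {r.subclutch_p:.4f}",
        ]
        if r.novel_paternal:
            lines.append(f"Paternal haplotypes absent from adult catalogue: {len(r.novel_paternal)}")
        for note in r.notes:
            lines.append(f"note: {note}")
        return "\n".join(lines)
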