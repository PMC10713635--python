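"""Domain types and validation for X-linked microsatellite haplotype analysis.

The organism is assumed to have X0 sex determination: females are XX, males
carry a single, maternally inherited X.  A male's multilocus genotype at
X-linked loci therefore *is* his X-haplotype, and two alleles at any locus in
a male indicate a data error (or a mislocalised marker).

Allele identity is the integer amplicon length in base pairs as sized by
capillary electrophoresis; sequence differences between equal-length alleles
are not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "Locus",
    "MarkerPanel",
    "XHaplotype",
    "DiploidGenotype",
    "SampleRecord",
    "FamilyDataset",
    "validate_panel",
    "validate_male_hemizygosity",
]

MALE = "male"
FEMALE = "female"
ADULT = "adult"
LARVA = "larva"


@dataclass(frozen=True)
class Locus:
    """One microsatellite marker on the X chromosome.

    Parameters
    ----------
    name : str
        Marker identifier, unique within a panel.
    scaffold : str
        Assembly scaffold the marker was designed from; used only for
        per-scaffold summaries (e.g. counts of heterozygous maternal loci).
    position_bp : int
        1-based chromosome-X coordinate of the locus.
    motif : str
        Repeat motif (panel convention: 3-6 bp motifs).
    alleles : frozenset[int]
        Known allele lengths (bp).  Treated as configuration: observed
        alleles absent from this set extend the *working* allele set with a
        logged notice rather than being rejected.
    """

    name: str
    scaffold: str
    position_bp: int
    motif: str
    alleles: frozenset

    def __post_init__(self):
        object.__setattr__(self, "alleles", frozenset(int(a) for a in self.alleles))


@dataclass(frozen=True)
class MarkerPanel:
    """Ordered collection of X-linked loci; the coordinate system for
    haplotypes and crossover classification.

    Loci are expected in ascending chromosome position.  Use
    :func:`validate_panel` to check invariants; :meth:`sorted_by_position`
    builds a conforming panel from unordered loci.
    """

    loci: tuple

    def __post_init__(self):
        object.__setattr__(self, "loci", tuple(self.loci))

    @classmethod
    def sorted_by_position(cls, loci: Iterable[Locus]) -> "MarkerPanel":
        return cls(tuple(sorted(loci, key=lambda l: l.position_bp)))

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci)

    @property
    def names(self) -> tuple:
        return tuple(l.name for l in self.loci)

    @property
    def positions(self) -> tuple:
        return tuple(l.position_bp for l in self.loci)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def locus(self, name: str) -> Locus:
        return self.loci[self.index(name)]

    def polymorphic_indices(self, working_alleles: Optional[Sequence[frozenset]] = None) -> tuple:
        """Indices of loci with >= 2 alleles in the working allele set.

        ``working_alleles``, when given, is one allele set per locus
        (panel alleles possibly extended by observed ones).
        """
        sets = working_alleles if working_alleles is not None else [l.alleles for l in self.loci]
        return tuple(i for i, s in enumerate(sets) if len(s) >= 2)

    def with_extra_alleles(self, extra: dict) -> "MarkerPanel":
        """Return a panel whose allele sets are extended by ``extra``
        (mapping locus name -> iterable of alleles)."""
        loci = []
        for l in self.loci:
            add = extra.get(l.name)
            loci.append(replace(l, alleles=l.alleles | frozenset(add)) if add else l)
        return MarkerPanel(tuple(loci))


@dataclass(frozen=True)
class XHaplotype:
    """An ordered vector of allele lengths, one per panel locus."""

    alleles: tuple
    label: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(
            self,
            "alleles",
            tuple(int(a) if a is not None else None for a in self.alleles),
        )

    def __len__(self) -> int:
        return len(self.alleles)


@dataclass(frozen=True)
class DiploidGenotype:
    """Per-locus unordered allele pairs; ``None`` marks a missing locus.

    Each entry is a sorted tuple: ``(a,)`` for a hemizygous male call,
    ``(a, b)`` (a <= b, a may equal b) for a diploid call.
    """

    pairs: tuple

    def __post_init__(self):
        norm = []
        for p in self.pairs:
            if p is None:
                norm.append(None)
            else:
                norm.append(tuple(sorted(int(a) for a in p)))
        object.__setattr__(self, "pairs", tuple(norm))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SampleRecord:
    """One genotyped individual with its sampling metadata."""

    sample_id: str
    sex: str
    locality: str
    region: str
    calls: DiploidGenotype
    family: Optional[str] = None
    stage: str = ADULT
    subclutch: Optional[str] = None

    def is_male(self) -> bool:
        return self.sex == MALE

    def haplotype(self) -> tuple:
        """Male multilocus call as a haplotype vector (``None`` for missing
        loci).  Only meaningful for hemizygous males."""
        return tuple(p[0] if p else None for p in self.calls.pairs)


@dataclass
class FamilyDataset:
    """A single-female family: the mother plus her genotyped larvae."""

    mother: SampleRecord
    larvae: list
    truth: Optional[list] = field(default=None, repr=False)

    def male_larvae(self) -> list:
        return [l for l in self.larvae if l.sex == MALE]

    def female_larvae(self) -> list:
        return [l for l in self.larvae if l.sex == FEMALE]


def validate_panel(panel: MarkerPanel) -> list:
    """Check panel invariants; returns human-readable violations (empty
    list when the panel is valid).  Pure: never raises on bad content."""
    violations = []
    names = [l.name for l in panel.loci]
    seen = set()
    for n in names:
        if n in seen:
            violations.append(f"duplicate locus name: {n}")
        seen.add(n)
    if len(panel.loci) < 2:
        violations.append("panel must contain at least 2 loci")
    for l in panel.loci:
        if not l.alleles:
            violations.append(f"{l.name}: empty allele set")
        elif any(a <= 0 for a in l.alleles):
            violations.append(f"{l.name}: non-positive allele length")
        if not (3 <= len(l.motif) <= 6):
            violations.append(f"{l.name}: motif length {len(l.motif)} outside 3-6")
        if l.position_bp < 1:
            violations.append(f"{l.name}: position_bp must be >= 1")
    # one violation per inverted pair (i < j in list order, position_i >= position_j)
    for i, a in enumerate(panel.loci):
        for b in panel.loci[i + 1 :]:
            if a.position_bp >= b.position_bp:
                violations.append(
                    f"positions not strictly increasing: {a.name} ({a.position_bp}) "
                    f">= {b.name} ({b.position_bp})"
                )
    return violations


def validate_male_hemizygosity(records: Iterable[SampleRecord]) -> list:
    """List every (sample_id, locus index) cell where a male carries two
    distinct alleles.  Empty list for clean data."""
    offending = []
    for rec in records:
        if rec.sex != MALE:
            continue
        for i, pair in enumerate(rec.calls.pairs):
            if pair is not None and len(set(pair)) > 1:
                offending.append((rec.sample_id, i))
    return offending
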