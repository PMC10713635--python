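"""Forward simulator of polyandrous X0 reproduction.

Generates (a) adult population samples — hemizygous males drawn as *linked*
haplotype vectors from a skewed haplotype pool, diploid females — and (b)
single-female families in which each larva receives one maternal gamete
(subject to per-interval crossovers between the mother's two X haplotypes)
and, if female, one paternal haplotype drawn according to sperm-use shares
with a single dominant father.

The defaults emulate the field design the package targets: a 10-locus
X-linked panel with 6 polymorphic loci (allele-set sizes 2, 4, 2, 2, 2, 3,
hence 192 potential haplotypes), 14 localities x 30 adults with a
female-biased sex ratio (0.55), and five families of 75-253 larvae sired by
3-13 fathers, the dominant one exceeding a 50% share, with rare
inter-locus recombination (roughly 4% of maternal gametes carrying at
least one crossover across the panel).

Every larva's true maternal gamete, crossover intervals and father index
are retained as a hidden-truth table for parameter-recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ADULT,
    FEMALE,
    LARVA,
    MALE,
    DiploidGenotype,
    FamilyDataset,
    Locus,
    MarkerPanel,
    SampleRecord,
    XHaplotype,
)

__all__ = [
    "default_panel",
    "default_allele_freqs",
    "FamilySpec",
    "SimScenario",
    "study_scenario",
    "build_haplotype_pool",
    "simulate_adults",
    "draw_mother",
    "draw_fathers",
    "simulate_family",
    "truth_report",
]


def default_panel() -> MarkerPanel:
    """The default 10-locus X-chromosome panel (positions in bp on the X;
    two source scaffolds).  Six loci are polymorphic with allele-set sizes
    2, 4, 2, 2, 2 and 3; four are monomorphic."""
    loci = [
        Locus("Ld6102", "61", 52_524_306, "ACTC", frozenset({244, 252})),
        Locus("Ld6105", "61", 52_598_946, "TGG", frozenset({208, 211})),
        Locus("Ld6106", "61", 52_659_499, "ATT", frozenset({236, 242})),
        Locus("Ld6109", "61", 52_841_444, "CTTAC", frozenset({309, 314, 319})),
        Locus("Ld6110", "61", 52_845_079, "TAT", frozenset({232})),
        Locus("Ld6111", "61", 52_920_157, "TAT", frozenset({174})),
        Locus("Ld4901", "49", 56_217_757, "TAA", frozenset({144, 147})),
        Locus("Ld4903", "49", 56_256_738, "AAC", frozenset({214})),
        Locus("Ld4905", "49", 56_323_276, "TTCA", frozenset({295, 298, 299, 300})),
        Locus("Ld4908", "49", 56_350_983, "AAT", frozenset({155})),
    ]
    return MarkerPanel.sorted_by_position(loci)


def default_allele_freqs(panel: MarkerPanel) -> list:
    """Skewed per-locus allele frequencies (major allele dominant), giving
    modest diversity comparable to a low-polymorphism microsatellite panel.

    Returns one dict ``{allele: freq}`` per panel locus, alleles in
    ascending length order.
    """
    shapes = {1: (1.0,), 2: (0.75, 0.25), 3: (0.60, 0.30, 0.10), 4: (0.55, 0.25, 0.12, 0.08)}
    freqs = []
    for locus in panel.loci:
        alleles = sorted(locus.alleles)
        freqs.append(dict(zip(alleles, shapes[len(alleles)])))
    return freqs


@dataclass
class FamilySpec:
    """Specification of one simulated single-female family.

    ``father_weights`` are sperm-use shares; the default gives the dominant
    (last) male a share of 0.55 and splits the remainder equally, mirroring
    last-male precedence.  ``recomb_fraction`` holds one crossover
    probability per adjacent-locus interval; the default of 0.005 per
    interval yields ~4-5% of maternal gametes carrying a crossover over a
    10-locus panel.
    """

    n_fathers: int = 8
    n_larvae: int = 200
    n_subclutches: int = 4
    father_weights: Optional[Sequence[float]] = None
    recomb_fraction: Optional[Sequence[float]] = None
    sex_ratio_female: float = 0.55
    dominant_share: float = 0.55
    subclutch_father_heterogeneity: float = 0.0  # >0 skews father shares per sub-clutch

    def weights(self) -> np.ndarray:
        if self.father_weights is not None:
            w = np.asarray(self.father_weights, dtype=float)
        elif self.n_fathers == 1:
            w = np.array([1.0])
        else:
            rest = (1.0 - self.dominant_share) / (self.n_fathers - 1)
            w = np.array([rest] * (self.n_fathers - 1) + [self.dominant_share])
        if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9 or len(w) != self.n_fathers:
            raise ValueError("father_weights must be non-negative and sum to 1")
        return w

    def interval_rates(self, n_loci: int) -> np.ndarray:
        if self.recomb_fraction is None:
            r = np.full(n_loci - 1, 0.005)
        else:
            r = np.asarray(self.recomb_fraction, dtype=float)
        if len(r) != n_loci - 1 or (r < 0).any() or (r > 0.5).any():
            raise ValueError("recomb_fraction must have length n_loci-1 with values in [0, 0.5]")
        return r


@dataclass
class SimScenario:
    """A population-sampling scenario for :func:`simulate_adults`."""

    panel: MarkerPanel
    allele_freqs: Optional[list] = None  # per-locus {allele: freq}
    n_localities: int = 14
    adults_per_locality: int = 30
    n_regions: int = 6
    sex_ratio_female: float = 0.55
    pool_size: int = 36
    pool_decay: float = 0.85  # geometric decay of pool haplotype weights
    linked_pool: bool = True  # False: independent per-locus draws (null mode)
    cline: Optional[tuple] = None  # (pool index, west weight factor, east weight factor)
    families: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.allele_freqs is None:
            self.allele_freqs = default_allele_freqs(self.panel)
        for f in self.allele_freqs:
            total = sum(f.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"allele frequencies must sum to 1, got {total}")
        if self.adults_per_locality < 1:
            raise ValueError("adults_per_locality must be >= 1")


def study_scenario(seed: int = 0) -> SimScenario:
    """The default end-to-end scenario: 14 localities x 30 adults in 6
    regions, plus five families (75-253 larvae, 6-13 fathers each)."""
    panel = default_panel()
    families = [
        FamilySpec(n_fathers=6, n_larvae=127, n_subclutches=3),
        FamilySpec(n_fathers=13, n_larvae=253, n_subclutches=8),
        FamilySpec(n_fathers=9, n_larvae=206, n_subclutches=5),
        FamilySpec(n_fathers=8, n_larvae=205, n_subclutches=4),
        FamilySpec(n_fathers=6, n_larvae=75, n_subclutches=2),
    ]
    return SimScenario(panel=panel, families=families, seed=seed)


# ---------------------------------------------------------------------------
# adults


def _draw_vector(freqs: list, rng: np.random.Generator) -> tuple:
    out = []
    for f in freqs:
        alleles = sorted(f)
        p = np.array([f[a] for a in alleles])
        out.append(int(rng.choice(alleles, p=p)))
    return tuple(out)


def build_haplotype_pool(scenario: SimScenario, rng: np.random.Generator):
    """Draw a pool of distinct haplotype vectors locus-wise from the
    scenario's allele frequencies and attach geometrically decaying weights
    (few common haplotypes, many rare ones)."""
    seen = []
    attempts = 0
    cap = 10_000
    while len(seen) < scenario.pool_size and attempts < cap:
        v = _draw_vector(scenario.allele_freqs, rng)
        attempts += 1
        if v not in seen:
            seen.append(v)
    weights = scenario.pool_decay ** np.arange(len(seen))
    weights /= weights.sum()
    return seen, weights


def _locality_weights(scenario: SimScenario, base: np.ndarray, i: int) -> np.ndarray:
    if scenario.cline is None:
        return base
    idx, west, east = scenario.cline
    t = i / max(scenario.n_localities - 1, 1)
    w = base.copy()
    w[idx] *= west * (1 - t) + east * t
    return w / w.sum()


def simulate_adults(scenario: SimScenario, rng: Optional[np.random.Generator] = None) -> list:
    """Simulate the adult field collection: per locality, adults sexed with
    P(female) = ``sex_ratio_female``; males carry one pool haplotype,
    females two (or fully independent per-locus draws when
    ``linked_pool=False``)."""
    rng = np.random.default_rng(scenario.seed) if rng is None else rng
    pool, weights = build_haplotype_pool(scenario, rng)
    pool_arr = np.arange(len(pool))
    records = []
    serial = 0
    for i in range(scenario.n_localities):
        region = f"R{i * scenario.n_regions // scenario.n_localities + 1}"
        locality = f"L{i + 1:02d}"
        w = _locality_weights(scenario, weights, i)
        for _ in range(scenario.adults_per_locality):
            serial += 1
            female = rng.random() < scenario.sex_ratio_female
            if scenario.linked_pool:
                if female:
                    h1 = pool[int(rng.choice(pool_arr, p=w))]
                    h2 = pool[int(rng.choice(pool_arr, p=w))]
                    pairs = tuple((a, b) for a, b in zip(h1, h2))
                else:
                    h = pool[int(rng.choice(pool_arr, p=w))]
                    pairs = tuple((a,) for a in h)
            else:
                if female:
                    h1 = _draw_vector(scenario.allele_freqs, rng)
                    h2 = _draw_vector(scenario.allele_freqs, rng)
                    pairs = tuple((a, b) for a, b in zip(h1, h2))
                else:
                    pairs = tuple((a,) for a in _draw_vector(scenario.allele_freqs, rng))
            records.append(
                SampleRecord(
                    sample_id=f"A{serial:04d}",
                    sex=FEMALE if female else MALE,
                    locality=locality,
                    region=region,
                    stage=ADULT,
                    calls=DiploidGenotype(pairs),
                )
            )
    return records


# ---------------------------------------------------------------------------
# families


def draw_mother(
    panel: MarkerPanel,
    rng: np.random.Generator,
    n_het_by_scaffold: Optional[dict] = None,
    allele_freqs: Optional[list] = None,
) -> tuple:
    """Draw a mother's two phased haplotypes with a configurable number of
    heterozygous loci per scaffold (default: 2 on each scaffold, where
    possible).  Returns ``(H1, H2)`` as :class:`XHaplotype`."""
    if allele_freqs is None:
        allele_freqs = default_allele_freqs(panel)
    if n_het_by_scaffold is None:
        n_het_by_scaffold = {}
        for sc in {l.scaffold for l in panel.loci}:
            n_het_by_scaffold[sc] = 2
    h1 = list(_draw_vector(allele_freqs, rng))
    h2 = list(h1)
    for scaffold, n_het in n_het_by_scaffold.items():
        candidates = [
            i
            for i, l in enumerate(panel.loci)
            if l.scaffold == scaffold and len(allele_freqs[i]) >= 2
        ]
        if n_het > len(candidates):
            raise ValueError(
                f"scaffold {scaffold}: requested {n_het} heterozygous loci, "
                f"only {len(candidates)} polymorphic loci available"
            )
        chosen = rng.choice(candidates, size=n_het, replace=False) if n_het else []
        for i in chosen:
            others = [a for a in sorted(allele_freqs[i]) if a != h1[i]]
            h2[i] = int(rng.choice(others))
    return XHaplotype(tuple(h1), label="H1"), XHaplotype(tuple(h2), label="H2")


def draw_fathers(
    panel: MarkerPanel,
    n_fathers: int,
    rng: np.random.Generator,
    allele_freqs: Optional[list] = None,
    distinct: bool = True,
) -> list:
    """Draw paternal haplotypes locus-wise; with ``distinct=True`` vectors
    are resampled until all differ (the detectable-polyandry regime)."""
    if allele_freqs is None:
        allele_freqs = default_allele_freqs(panel)
    fathers = []
    attempts = 0
    while len(fathers) < n_fathers:
        v = _draw_vector(allele_freqs, rng)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError("could not draw enough distinct father haplotypes")
        if distinct and any(v == f.alleles for f in fathers):
            continue
        fathers.append(XHaplotype(v, label=f"F{len(fathers) + 1}"))
    return fathers


def _gamete(h1, h2, start: int, switches: np.ndarray) -> tuple:
    """Maternal gamete given a starting haplotype (0 = H1) and per-interval
    switch indicators."""
    origin = start
    out = [h1.alleles[0] if origin == 0 else h2.alleles[0]]
    for i, s in enumerate(switches):
        if s:
            origin = 1 - origin
        out.append(h1.alleles[i + 1] if origin == 0 else h2.alleles[i + 1])
    return tuple(out)


def simulate_family(
    spec: FamilySpec,
    mother: tuple,
    fathers: list,
    panel: MarkerPanel,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    family_id: str = "FAM1",
    max_crossovers: Optional[int] = None,
) -> FamilyDataset:
    """Simulate one clutch.

    Each larva draws a maternal gamete: one of the mother's two haplotypes
    with independent per-interval Bernoulli crossovers (no interference).
    Females additionally draw a father by sperm-use share and receive his
    haplotype unchanged (a male transmits his single X without meiotic
    partner).  Males carry the maternal gamete only.  ``max_crossovers``
    optionally rejects gametes exceeding a hard crossover cap.

    The hidden truth (per larva: true start haplotype, crossover intervals,
    father index, sex) is stored on the returned dataset.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    h1, h2 = mother
    if len(h1) != len(panel) or len(h2) != len(panel):
        raise ValueError("mother haplotypes must match panel size")
    if len(fathers) != spec.n_fathers:
        raise ValueError("expected exactly n_fathers paternal haplotypes")
    rates = spec.interval_rates(len(panel))
    weights = spec.weights()

    mother_rec = SampleRecord(
        sample_id=f"{family_id}_mother",
        sex=FEMALE,
        locality=family_id,
        region="FAM",
        family=family_id,
        stage=ADULT,
        calls=DiploidGenotype(tuple((a, b) for a, b in zip(h1.alleles, h2.alleles))),
    )

    larvae = []
    truth = []
    for j in range(spec.n_larvae):
        while True:
            start = int(rng.integers(2))
            switches = rng.random(len(rates)) < rates
            if max_crossovers is None or switches.sum() <= max_crossovers:
                break
        gamete = _gamete(h1, h2, start, switches)
        intervals = tuple(int(i) for i in np.nonzero(switches)[0])
        female = rng.random() < spec.sex_ratio_female
        subclutch = f"S{j * spec.n_subclutches // spec.n_larvae + 1}"
        if female:
            father_idx = int(rng.choice(len(weights), p=weights))
            pat = fathers[father_idx].alleles
            pairs = tuple((g, p) for g, p in zip(gamete, pat))
        else:
            father_idx = None
            pairs = tuple((g,) for g in gamete)
        sample_id = f"{family_id}_L{j + 1:04d}"
        larvae.append(
            SampleRecord(
                sample_id=sample_id,
                sex=FEMALE if female else MALE,
                locality=family_id,
                region="FAM",
                family=family_id,
                stage=LARVA,
                subclutch=subclutch,
                calls=DiploidGenotype(pairs),
            )
        )
        n_co = len(intervals)
        truth.append(
            {
                "sample_id": sample_id,
                "sex": FEMALE if female else MALE,
                "start": "H1" if start == 0 else "H2",
                "label": ("H1" if start == 0 else "H2") if n_co == 0 else "recombinant",
                "intervals": intervals,
                "n_crossovers": n_co,
                "father_index": father_idx,
                "subclutch": subclutch,
            }
        )
    return FamilyDataset(mother=mother_rec, larvae=larvae, truth=truth)


def truth_report(dataset: FamilyDataset) -> pd.DataFrame:
    """Hidden-truth table of a simulated family (one row per larva)."""
    if dataset.truth is None:
        raise ValueError("truth_report requires a dataset produced by simulate_family")
    return pd.DataFrame(dataset.truth)
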