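"""Diversity descriptors, hierarchical AMOVA with permutation tests, and
allele-frequency bookkeeping for haploid (male) and diploid (female)
partitions of an X-linked data set.

Copy counting is X-aware throughout: a male contributes one allele copy
per locus, a female two.  Heterozygosity-style statistics (Ho, He, PIC, F)
are defined only for the diploid (female) partition; for males the haploid
diversity h = 1 - sum(p^2) takes their place, mirroring the reduced
descriptor range available for hemizygous samples.

AMOVA follows the classic sums-of-squared-pairwise-distances construction
with nested moment equations; fixation components are variance ratios
(Phi for the haploid distance model, F for the diploid codominant model)
and p-values come from permuting units at the appropriate level,
p = (b + 1) / (B + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import FEMALE, MALE, MarkerPanel, SampleRecord

log = logging.getLogger("xhap")

__all__ = [
    "AlleleFrequencies",
    "allele_frequencies",
    "DiversitySummary",
    "diversity",
    "Amova",
    "AmovaResults",
    "amova",
]


# ---------------------------------------------------------------------------
# allele frequencies


@dataclass
class AlleleFrequencies:
    """Per (cell, locus) allele frequency vectors with copy counts.

    ``freqs[(cell, locus)]`` maps allele -> frequency; ``copies`` holds the
    number of allele copies counted (1 per male, 2 per female).  Cells with
    no data at a locus are listed in ``empty_cells``.
    """

    partition: str
    cells: tuple
    freqs: dict
    copies: dict
    empty_cells: list


def _cell_of(rec: SampleRecord, partition: str) -> str:
    if partition == "pooled":
        return "all"
    if partition == "sex":
        return rec.sex
    if partition == "locality":
        return rec.locality
    if partition == "region":
        return rec.region
    raise ValueError(f"unknown partition {partition!r}")


def allele_frequencies(
    records: Iterable[SampleRecord], panel: MarkerPanel, partition: str = "pooled"
) -> AlleleFrequencies:
    """Tally allele frequencies per partition cell and locus (males one
    copy, females two)."""
    counts: dict = {}
    cells = []
    for rec in records:
        cell = _cell_of(rec, partition)
        if cell not in cells:
            cells.append(cell)
        for i, pair in enumerate(rec.calls.pairs):
            if pair is None:
                continue
            key = (cell, panel.names[i])
            d = counts.setdefault(key, {})
            copies = (pair[0],) if rec.sex == MALE else (pair[0], pair[-1])
            for a in copies:
                d[a] = d.get(a, 0) + 1
    freqs = {}
    copies = {}
    empty = []
    for cell in cells:
        for name in panel.names:
            key = (cell, name)
            if key not in counts:
                empty.append(key)
                continue
            n = sum(counts[key].values())
            freqs[key] = {a: c / n for a, c in sorted(counts[key].items())}
            copies[key] = n
    return AlleleFrequencies(
        partition=partition, cells=tuple(cells), freqs=freqs, copies=copies, empty_cells=empty
    )


# ---------------------------------------------------------------------------
# diversity descriptors


def _closed_forms(p: np.ndarray) -> dict:
    """Ne, I, h/He and PIC from an allele-frequency vector."""
    sum_p2 = float((p**2).sum())
    ne = 1.0 / sum_p2
    shannon = float(-(p[p > 0] * np.log(p[p > 0])).sum())
    he = 1.0 - sum_p2
    # PIC = 1 - sum p_i^2 - sum_{i<j} 2 p_i^2 p_j^2
    cross = float(np.sum(np.outer(p**2, p**2)) - np.sum(p**4)) / 2.0
    pic = 1.0 - sum_p2 - 2.0 * cross
    return {"Ne": ne, "I": shannon, "He": he, "PIC": pic}


@dataclass
class DiversitySummary:
    """Long-format diversity table plus aggregation helpers.

    One row per (sex, cell, locus) with Na, Ne, I, h (= He for diploids),
    Ho, He, PIC and F = 1 - Ho/He.  Ho/He/PIC/F are NaN for the haploid
    (male) partition and for monomorphic loci, mirroring the descriptor
    range actually defined in each case.
    """

    table: pd.DataFrame
    unbiased: bool = False

    _stat_cols = ["Na", "Ne", "I", "h", "Ho", "He", "PIC", "F"]

    def by_locus(self, sex: str) -> pd.DataFrame:
        """Mean +/- SD of each descriptor across cells, per locus."""
        sub = self.table[self.table["sex"] == sex]
        return sub.groupby("locus", sort=False)[self._stat_cols].agg(["mean", "std"])

    def by_population(self, sex: str) -> pd.DataFrame:
        sub = self.table[self.table["sex"] == sex]
        agg = sub.groupby("cell", sort=False)[self._stat_cols].agg(["mean", "std"])
        poly = sub.assign(poly=sub["Na"] >= 2).groupby("cell", sort=False)["poly"].mean() * 100
        agg[("P_pct", "")] = poly
        return agg


def diversity(
    records: Iterable[SampleRecord],
    panel: MarkerPanel,
    partition: str = "locality",
    unbiased: bool = False,
) -> DiversitySummary:
    """Per-cell, per-locus diversity descriptors, separately for the male
    (haploid) and female (diploid) partitions.

    ``unbiased=True`` applies the small-sample n/(n-1) correction to
    He/h (off by default; the plain 1 - sum p^2 matches the conventional
    spreadsheet output this mirrors).
    """
    records = list(records)
    rows = []
    for sex in (MALE, FEMALE):
        subset = [r for r in records if r.sex == sex]
        if not subset:
            continue
        af = allele_frequencies(subset, panel, partition)
        for cell in af.cells:
            cell_recs = [r for r in subset if _cell_of(r, partition) == cell]
            for i, name in enumerate(panel.names):
                key = (cell, name)
                if key not in af.freqs:
                    continue
                p = np.array(list(af.freqs[key].values()))
                n = af.copies[key]
                cf = _closed_forms(p)
                he = cf["He"]
                if unbiased and n > 1:
                    he = he * n / (n - 1)
                na = len(p)
                row = {
                    "sex": sex,
                    "cell": cell,
                    "locus": name,
                    "Na": na,
                    "Ne": cf["Ne"] if na > 1 else 1.0,
                    "I": cf["I"],
                    "h": he,
                    "n_copies": n,
                }
                if sex == FEMALE:
                    typed = [
                        r.calls.pairs[i]
                        for r in cell_recs
                        if r.calls.pairs[i] is not None
                    ]
                    ho = (
                        sum(1 for pair in typed if len(set(pair)) == 2) / len(typed)
                        if typed
                        else np.nan
                    )
                    row["Ho"] = ho if na > 1 else np.nan
                    row["He"] = he if na > 1 else np.nan
                    row["PIC"] = cf["PIC"] if na > 1 else np.nan
                    row["F"] = (1.0 - ho / he) if na > 1 and he > 0 else np.nan
                else:
                    row["Ho"] = np.nan
                    row["He"] = np.nan
                    row["PIC"] = np.nan
                    row["F"] = np.nan
                rows.append(row)
    cols = ["sex", "cell", "locus", "Na", "Ne", "I", "h", "Ho", "He", "PIC", "F", "n_copies"]
    return DiversitySummary(table=pd.DataFrame(rows, columns=cols), unbiased=unbiased)


# ---------------------------------------------------------------------------
# AMOVA


def _block_sum(D2: np.ndarray, idx: np.ndarray) -> float:
    return float(D2[np.ix_(idx, idx)].sum())


def _two_level_components(D2, pop_idx, region_of_pop, n_regions):
    """Nested AMOVA moments on unit-level squared distances.

    ``pop_idx``: list of index arrays (one per population); units are the
    rows/cols of D2.  Returns (rows, components) where components are
    (sigma_a among regions, sigma_b among pops, sigma_c within pops);
    sigma_a is None for a single region.
    """
    N = D2.shape[0]
    P = len(pop_idx)
    G = n_regions
    ss_total = D2.sum() / (2 * N)
    pop_blocks = [_block_sum(D2, idx) for idx in pop_idx]
    n_p = np.array([len(idx) for idx in pop_idx], dtype=float)
    ss_wp = sum(b / (2 * n) for b, n in zip(pop_blocks, n_p))
    region_members = [
        np.concatenate([pop_idx[p] for p in range(P) if region_of_pop[p] == g])
        for g in range(G)
    ]
    N_g = np.array([len(m) for m in region_members], dtype=float)
    ss_region_tot = sum(_block_sum(D2, m) / (2 * n) for m, n in zip(region_members, N_g))

    sigma_c = None
    rows = []
    if G > 1:
        ss_ar = ss_total - ss_region_tot
        ss_ap = ss_region_tot - ss_wp
        df_ar, df_ap, df_wp = G - 1, P - G, N - P
        ms_ar = ss_ar / df_ar
        ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
        ms_wp = ss_wp / df_wp
        sum_np2_over_Ng = sum(
            sum(n_p[p] ** 2 for p in range(P) if region_of_pop[p] == g) / N_g[g]
            for g in range(G)
        )
        n_coef = (N - sum_np2_over_Ng) / (P - G) if P > G else np.nan
        n1 = (sum_np2_over_Ng - (n_p**2).sum() / N) / (G - 1)
        n2 = (N - (N_g**2).sum() / N) / (G - 1)
        sigma_c = ms_wp
        sigma_b = (ms_ap - sigma_c) / n_coef if P > G else np.nan
        sigma_a = (ms_ar - sigma_c - n1 * sigma_b) / n2
        rows = [
            ("Among regions", df_ar, ss_ar, ms_ar, sigma_a),
            ("Among sub-populations", df_ap, ss_ap, ms_ap, sigma_b),
            ("Within sub-populations", df_wp, ss_wp, ms_wp, sigma_c),
        ]
        return rows, (sigma_a, sigma_b, sigma_c)
    # single level: among / within populations
    ss_ap = ss_total - ss_wp
    df_ap, df_wp = P - 1, N - P
    ms_ap = ss_ap / df_ap
    ms_wp = ss_wp / df_wp
    n0 = (N - (n_p**2).sum() / N) / (P - 1)
    sigma_c = ms_wp
    sigma_b = (ms_ap - sigma_c) / n0
    rows = [
        ("Among sub-populations", df_ap, ss_ap, ms_ap, sigma_b),
        ("Within sub-populations", df_wp, ss_wp, ms_wp, sigma_c),
    ]
    return rows, (None, sigma_b, sigma_c)


def _phi_stats(components) -> dict:
    sigma_a, sigma_b, sigma_c = components
    out = {}
    if sigma_a is None:
        tot = sigma_b + sigma_c
        out["Phi_PT"] = sigma_b / tot if tot != 0 else np.nan
        return out
    tot = sigma_a + sigma_b + sigma_c
    out["Phi_RT"] = sigma_a / tot if tot != 0 else np.nan
    out["Phi_PR"] = sigma_b / (sigma_b + sigma_c) if (sigma_b + sigma_c) != 0 else np.nan
    out["Phi_PT"] = (sigma_a + sigma_b) / tot if tot != 0 else np.nan
    return out


def _individual_components(D2, ind_idx, pop_of_ind, region_of_pop, pop_idx_copies, n_regions):
    """Four-level nested moments for the diploid model: copies within
    individuals within populations within regions.  Every individual
    carries exactly two copies."""
    N = D2.shape[0]  # allele copies
    I = len(ind_idx)
    P = len(pop_idx_copies)
    G = n_regions
    ss_total = D2.sum() / (2 * N)
    ss_wi = sum(_block_sum(D2, idx) / (2 * 2) for idx in ind_idx)
    pop_blocks = [_block_sum(D2, idx) for idx in pop_idx_copies]
    n_p = np.array([len(idx) for idx in pop_idx_copies], dtype=float)
    ss_pop_tot = sum(b / (2 * n) for b, n in zip(pop_blocks, n_p))
    ss_ai = ss_pop_tot - ss_wi
    region_members = [
        np.concatenate([pop_idx_copies[p] for p in range(P) if region_of_pop[p] == g])
        for g in range(G)
    ]
    N_g = np.array([len(m) for m in region_members], dtype=float)
    ss_region_tot = sum(_block_sum(D2, m) / (2 * n) for m, n in zip(region_members, N_g))
    ss_ap = ss_region_tot - ss_pop_tot
    ss_ar = ss_total - ss_region_tot

    df_wi = N - I
    df_ai = I - P
    df_ap = P - G
    df_ar = G - 1
    ms_wi = ss_wi / df_wi
    ms_ai = ss_ai / df_ai
    sigma_d = ms_wi
    sigma_c = (ms_ai - sigma_d) / 2.0  # two copies per individual
    sum_np2_over_Ng = sum(
        sum(n_p[p] ** 2 for p in range(P) if region_of_pop[p] == g) / N_g[g]
        for g in range(G)
    )
    if G > 1:
        ms_ap = ss_ap / df_ap if df_ap > 0 else np.nan
        ms_ar = ss_ar / df_ar
        n_coef = (N - sum_np2_over_Ng) / (P - G) if P > G else np.nan
        n1 = (sum_np2_over_Ng - (n_p**2).sum() / N) / (G - 1)
        n2 = (N - (N_g**2).sum() / N) / (G - 1)
        sigma_b = (ms_ap - sigma_d - 2 * sigma_c) / n_coef if P > G else np.nan
        sigma_a = (ms_ar - sigma_d - 2 * sigma_c - n1 * sigma_b) / n2
        rows = [
            ("Among regions", df_ar, ss_ar, ms_ar, sigma_a),
            ("Among sub-populations", df_ap, ss_ap, ms_ap, sigma_b),
            ("Among individuals", df_ai, ss_ai, ms_ai, sigma_c),
            ("Within individuals", df_wi, ss_wi, ms_wi, sigma_d),
        ]
        return rows, (sigma_a, sigma_b, sigma_c, sigma_d)
    n0 = (N - (n_p**2).sum() / N) / (P - 1)
    ms_ap = (ss_total - ss_pop_tot) / (P - 1)
    sigma_b = (ms_ap - sigma_d - 2 * sigma_c) / n0
    rows = [
        ("Among sub-populations", P - 1, ss_total - ss_pop_tot, ms_ap, sigma_b),
        ("Among individuals", df_ai, ss_ai, ms_ai, sigma_c),
        ("Within individuals", df_wi, ss_wi, ms_wi, sigma_d),
    ]
    return rows, (None, sigma_b, sigma_c, sigma_d)


def _f_stats(components) -> dict:
    sigma_a, sigma_b, sigma_c, sigma_d = components
    out = {}
    if sigma_a is None:
        tot = sigma_b + sigma_c + sigma_d
        out["F_ST"] = sigma_b / tot if tot != 0 else np.nan
        out["F_IS"] = sigma_c / (sigma_c + sigma_d) if (sigma_c + sigma_d) != 0 else np.nan
        out["F_IT"] = (sigma_b + sigma_c) / tot if tot != 0 else np.nan
        return out
    tot = sigma_a + sigma_b + sigma_c + sigma_d
    out["F_RT"] = sigma_a / tot if tot != 0 else np.nan
    out["F_SR"] = (
        sigma_b / (sigma_b + sigma_c + sigma_d)
        if (sigma_b + sigma_c + sigma_d) != 0
        else np.nan
    )
    out["F_ST"] = (sigma_a + sigma_b) / tot if tot != 0 else np.nan
    out["F_IS"] = sigma_c / (sigma_c + sigma_d) if (sigma_c + sigma_d) != 0 else np.nan
    out["F_IT"] = (sigma_a + sigma_b + sigma_c) / tot if tot != 0 else np.nan
    return out


class Amova:
    """Hierarchical analysis of molecular variance.

    Parameters
    ----------
    records, panel
        Genotyped individuals and the marker panel.  The haploid model
        uses male records (allele-mismatch distances between haplotypes);
        the diploid codominant model uses female records, decomposed into
        allele copies with an among-/within-individual level.
    hierarchy
        ``("region", "locality")`` for a regional design or
        ``("locality",)`` for a flat one-level design.
    permutations, seed
        Permutation-test settings; p = (b + 1) / (B + 1).

    Records with a missing call at any panel locus are dropped (with a log
    notice) so that every pairwise distance spans the same loci.
    """

    def __init__(
        self,
        records: Iterable[SampleRecord],
        panel: MarkerPanel,
        hierarchy: tuple = ("region", "locality"),
        model: str = "haploid",
        permutations: int = 999,
        seed: int = 0,
    ):
        if model not in ("haploid", "diploid"):
            raise ValueError("model must be 'haploid' or 'diploid'")
        if len(hierarchy) not in (1, 2):
            raise ValueError("hierarchy must name 1 or 2 levels")
        self.panel = panel
        self.hierarchy = tuple(hierarchy)
        self.model = model
        self.permutations = permutations
        self.seed = seed
        sex = MALE if model == "haploid" else FEMALE
        kept, dropped = [], 0
        for r in records:
            if r.sex != sex:
                continue
            if any(p is None for p in r.calls.pairs):
                dropped += 1
                continue
            kept.append(r)
        if dropped:
            log.warning("AMOVA: dropped %d %s records with missing calls", dropped, sex)
        if not kept:
            raise ValueError(f"no complete {sex} records for the {model} model")
        # canonical unit order makes permutation p-values invariant to the
        # row order of the input table
        kept.sort(key=lambda r: r.sample_id)
        self.records = kept

    # -- construction of unit-level distance and grouping -------------------

    def _layout(self):
        recs = self.records
        pop_attr = self.hierarchy[-1]
        pops = sorted({getattr(r, pop_attr) for r in recs})
        pop_of_rec = np.array([pops.index(getattr(r, pop_attr)) for r in recs])
        if len(self.hierarchy) == 2:
            reg_attr = self.hierarchy[0]
            pop_region = {}
            for r in recs:
                pop_region[getattr(r, pop_attr)] = getattr(r, reg_attr)
            regions = sorted(set(pop_region.values()))
            region_of_pop = np.array([regions.index(pop_region[p]) for p in pops])
            n_regions = len(regions)
        else:
            region_of_pop = np.zeros(len(pops), dtype=int)
            n_regions = 1
        return pops, pop_of_rec, region_of_pop, n_regions

    def _distances(self):
        if self.model == "haploid":
            X = np.array([r.haplotype() for r in self.records])
            D2 = (X[:, None, :] != X[None, :, :]).sum(axis=2).astype(float)
            return D2, None
        # diploid: two copies per individual, per-locus allele mismatch
        copy_a = np.array([[p[0] for p in r.calls.pairs] for r in self.records])
        copy_b = np.array([[p[-1] for p in r.calls.pairs] for r in self.records])
        X = np.empty((2 * len(self.records), copy_a.shape[1]), dtype=copy_a.dtype)
        X[0::2] = copy_a
        X[1::2] = copy_b
        D2 = (X[:, None, :] != X[None, :, :]).sum(axis=2).astype(float)
        return D2, X

    def fit(self) -> "AmovaResults":
        pops, pop_of_rec, region_of_pop, n_regions = self._layout()
        P = len(pops)
        if P < 2:
            raise ValueError("AMOVA needs at least 2 sub-populations")
        D2, _ = self._distances()
        rng = np.random.default_rng(self.seed)
        B = self.permutations

        if self.model == "haploid":
            pop_idx = [np.nonzero(pop_of_rec == p)[0] for p in range(P)]
            rows, comps = _two_level_components(D2, pop_idx, region_of_pop, n_regions)
            stats = _phi_stats(comps)
            pvals = self._phi_pvalues(D2, pop_of_rec, region_of_pop, n_regions, rng, B)
        else:
            n = len(self.records)
            ind_idx = [np.array([2 * i, 2 * i + 1]) for i in range(n)]
            pop_idx_copies = [
                np.nonzero(np.repeat(pop_of_rec, 2) == p)[0] for p in range(P)
            ]
            rows, comps = _individual_components(
                D2, ind_idx, pop_of_rec, region_of_pop, pop_idx_copies, n_regions
            )
            stats = _f_stats(comps)
            pvals = self._f_pvalues(D2, pop_of_rec, region_of_pop, n_regions, rng, B)

        return AmovaResults(self, pops, rows, comps, stats, pvals)

    # -- permutation machinery ---------------------------------------------

    @staticmethod
    def _perm_within_regions(rng, pop_of_rec, region_of_pop):
        """Permute unit positions within each region (for Phi_PR / F_SR)."""
        perm = np.arange(len(pop_of_rec))
        region_of_rec = region_of_pop[pop_of_rec]
        for g in np.unique(region_of_rec):
            members = np.nonzero(region_of_rec == g)[0]
            perm[members] = rng.permutation(members)
        return perm

    def _phi_pvalues(self, D2, pop_of_rec, region_of_pop, n_regions, rng, B):
        P = len(np.unique(pop_of_rec))
        pop_idx = [np.nonzero(pop_of_rec == p)[0] for p in range(P)]
        _, comps_obs = _two_level_components(D2, pop_idx, region_of_pop, n_regions)
        obs = _phi_stats(comps_obs)
        counts = {k: 0 for k in obs}
        for _ in range(B):
            # Phi_PT: units permuted among populations anywhere
            perm = rng.permutation(D2.shape[0])
            idx = [perm[ix] for ix in pop_idx]
            _, c = _two_level_components(D2, idx, region_of_pop, n_regions)
            if _phi_stats(c)["Phi_PT"] >= obs["Phi_PT"] - 1e-12:
                counts["Phi_PT"] += 1
            if n_regions > 1:
                # Phi_PR: units permuted among populations within regions
                perm = self._perm_within_regions(rng, pop_of_rec, region_of_pop)
                idx = [perm[ix] for ix in pop_idx]
                _, c = _two_level_components(D2, idx, region_of_pop, n_regions)
                if _phi_stats(c)["Phi_PR"] >= obs["Phi_PR"] - 1e-12:
                    counts["Phi_PR"] += 1
                # Phi_RT: whole populations permuted among regions
                reg_perm = region_of_pop[rng.permutation(len(region_of_pop))]
                _, c = _two_level_components(D2, pop_idx, reg_perm, n_regions)
                if _phi_stats(c)["Phi_RT"] >= obs["Phi_RT"] - 1e-12:
                    counts["Phi_RT"] += 1
        return {k: (counts[k] + 1) / (B + 1) for k in counts if k in obs}

    def _f_pvalues(self, D2, pop_of_rec, region_of_pop, n_regions, rng, B):
        n = len(pop_of_rec)
        P = len(np.unique(pop_of_rec))
        ind_idx = [np.array([2 * i, 2 * i + 1]) for i in range(n)]

        def components(ind_order, copy_pairs=None):
            """Recompute with individuals placed into populations by
            ``ind_order`` (a permutation of individuals), or with explicit
            per-individual copy pairs."""
            pairs = copy_pairs if copy_pairs is not None else ind_idx
            reordered = [pairs[i] for i in ind_order]
            pop_idx_copies = [
                np.concatenate([reordered[i] for i in np.nonzero(pop_of_rec == p)[0]])
                for p in range(P)
            ]
            return _individual_components(
                D2, reordered, pop_of_rec, region_of_pop, pop_idx_copies, n_regions
            )[1]

        obs = _f_stats(components(np.arange(n)))
        counts = {k: 0 for k in obs}
        copies_flat = np.arange(2 * n)
        for _ in range(B):
            # F_ST: individuals among populations anywhere
            perm = rng.permutation(n)
            s = _f_stats(components(perm))
            if s["F_ST"] >= obs["F_ST"] - 1e-12:
                counts["F_ST"] += 1
            # F_IS: copies among individuals within populations
            perm_c = np.arange(2 * n)
            region_of_rec = region_of_pop[pop_of_rec]
            for p in range(P):
                members = np.nonzero(np.repeat(pop_of_rec, 2) == p)[0]
                perm_c[members] = rng.permutation(members)
            pairs = [perm_c[ix] for ix in ind_idx]
            s = _f_stats(components(np.arange(n), copy_pairs=pairs))
            if s["F_IS"] >= obs["F_IS"] - 1e-12:
                counts["F_IS"] += 1
            # F_IT: copies among individuals anywhere
            perm_c = rng.permutation(copies_flat)
            pairs = [perm_c[ix] for ix in ind_idx]
            s = _f_stats(components(np.arange(n), copy_pairs=pairs))
            if s["F_IT"] >= obs["F_IT"] - 1e-12:
                counts["F_IT"] += 1
            if n_regions > 1:
                # F_SR: individuals among populations within regions
                perm = self._perm_within_regions(rng, pop_of_rec, region_of_pop)
                s = _f_stats(components(perm))
                if s["F_SR"] >= obs["F_SR"] - 1e-12:
                    counts["F_SR"] += 1
                # F_RT: populations among regions
                reg_perm = region_of_pop[rng.permutation(len(region_of_pop))]
                pop_idx_copies = [
                    np.concatenate([ind_idx[i] for i in np.nonzero(pop_of_rec == p)[0]])
                    for p in range(P)
                ]
                c = _individual_components(
                    D2, ind_idx, pop_of_rec, reg_perm, pop_idx_copies, n_regions
                )[1]
                if _f_stats(c)["F_RT"] >= obs["F_RT"] - 1e-12:
                    counts["F_RT"] += 1
        return {k: (counts[k] + 1) / (B + 1) for k in counts}


class AmovaResults:
    """Fitted AMOVA: variance decomposition rows, fixation components and
    permutation p-values."""

    def __init__(self, model: Amova, pops, rows, components, stats, p_values):
        self.model = model
        self.pops = pops
        self.components = components
        self.stats = stats
        self.p_values = p_values
        recs = []
        sigmas = [r[4] for r in rows]
        trunc = [max(s, 0.0) if s == s else np.nan for s in sigmas]  # NaN-safe
        total_var = np.nansum(trunc)
        for (source, df, ss, ms, sigma), tr in zip(rows, trunc):
            recs.append(
                {
                    "source": source,
                    "df": df,
                    "SS": ss,
                    "MS": ms,
                    "variance": sigma,
                    "percent": 100 * tr / total_var if total_var > 0 else np.nan,
                }
            )
        total_row = {
            "source": "Total",
            "df": sum(r["df"] for r in recs),
            "SS": sum(r["SS"] for r in recs),
            "MS": np.nan,
            "variance": np.nansum(sigmas),
            "percent": 100.0,
        }
        self.table = pd.DataFrame(recs + [total_row])

    def summary(self) -> str:
        lines = [
            f"AMOVA ({self.model.model} model, {len(self.pops)} sub-populations, "
            f"{self.model.permutations} permutations)",
            self.table.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
            "Fixation components:",
        ]
        for k, v in self.stats.items():
            p = self.p_values.get(k)
            lines.append(f"  {k} = {v:.4f}" + (f"  (p = {p:.4f})" if p is not None else ""))
        return "\n".join(lines)


def amova(
    records: Iterable[SampleRecord],
    panel: MarkerPanel,
    hierarchy: tuple = ("region", "locality"),
    model: str = "haploid",
    permutations: int = 999,
    seed: int = 0,
) -> AmovaResults:
    """Functional wrapper around :class:`Amova`."""
    return Amova(records, panel, hierarchy, model, permutations, seed).fit()
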