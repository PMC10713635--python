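"""Readers and writers for the marker panel, genotype tables, haplotype
catalogues and trees, plus the flat-text run configuration.

File dialects (all plain CSV with a header row):

* panel:      ``locus,scaffold,position_bp,motif,alleles`` with ``alleles``
  a semicolon-joined list of integer fragment lengths.
* genotypes:  ``sample_id,sex,locality,region,family,stage,subclutch`` then
  two columns per panel locus, ``<locus>.1`` and ``<locus>.2``.  Males leave
  ``.2`` empty (hemizygous); a fully empty pair is a missing call.
* catalogue:  ``label``, one allele column per locus, ``count,frequency``.

The missing-allele sentinel in files is the empty string; in memory it is
``None``.  All writers are deterministic (stable row and field order).
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Optional

from .core import (
    DiploidGenotype,
    Locus,
    MarkerPanel,
    SampleRecord,
    XHaplotype,
    validate_panel,
)

log = logging.getLogger("xhap")

__all__ = [
    "RunConfig",
    "read_config",
    "write_config",
    "read_panel",
    "write_panel",
    "read_genotypes",
    "write_genotypes",
    "read_catalogue",
    "write_catalogue",
    "write_tree",
]

META_COLUMNS = ["sample_id", "sex", "locality", "region", "family", "stage", "subclutch"]
SEXES = {"male", "female"}


@dataclass
class RunConfig:
    """Run-level knobs shared across pipeline stages.

    ``permutations`` drives all permutation tests (p = (b+1)/(B+1));
    ``crossover_budget`` caps the crossovers allowed when explaining a
    larval genotype; the TPM parameters configure the bottleneck test's
    two-phase microsatellite mutation model (fraction of strict one-step
    mutations, and the variance of multi-step changes).
    """

    seed: int = 0
    permutations: int = 999
    crossover_budget: int = 2
    tpm_smm_proportion: float = 0.95
    tpm_variance: float = 12.0
    bottleneck_replicates: int = 200

    def __post_init__(self):
        if self.permutations < 1:
            raise ValueError("permutations must be >= 1")
        if not (0.0 <= self.tpm_smm_proportion <= 1.0):
            raise ValueError("tpm_smm_proportion must be in [0, 1]")
        if self.crossover_budget not in (0, 1, 2):
            raise ValueError("crossover_budget must be 0, 1 or 2")


def read_config(path) -> RunConfig:
    """Parse a flat ``key = value`` text file into a :class:`RunConfig`.

    Unknown keys raise; missing keys take defaults.  ``#`` starts a comment.
    """
    fields = {f: t for f, t in RunConfig.__annotations__.items()}
    kwargs = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (s.strip() for s in line.split("=", 1))
        if key not in fields:
            raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
        caster = int if fields[key] is int or fields[key] == "int" else float
        kwargs[key] = caster(value)
    return RunConfig(**kwargs)


def write_config(config: RunConfig, path) -> None:
    lines = [f"{k} = {v}" for k, v in asdict(config).items()]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# marker panel


def read_panel(path) -> MarkerPanel:
    """Read a panel CSV; rows are sorted by chromosome position (unsorted
    input is sorted, not rejected).  The returned panel passes
    :func:`~xhap.core.validate_panel`."""
    loci = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"locus", "scaffold", "position_bp", "motif", "alleles"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: panel header must contain {sorted(required)}")
        for lineno, row in enumerate(reader, start=2):
            try:
                allele_field = (row["alleles"] or "").strip()
                if not allele_field:
                    raise ValueError("empty alleles field")
                alleles = frozenset(int(a) for a in allele_field.split(";"))
                loci.append(
                    Locus(
                        name=row["locus"].strip(),
                        scaffold=row["scaffold"].strip(),
                        position_bp=int(row["position_bp"]),
                        motif=row["motif"].strip(),
                        alleles=alleles,
                    )
                )
            except (KeyError, ValueError, TypeError) as exc:
                raise ValueError(f"{path}: line {lineno}: malformed panel row ({exc})") from exc
    panel = MarkerPanel.sorted_by_position(loci)
    violations = validate_panel(panel)
    if violations:
        raise ValueError(f"{path}: invalid panel: " + "; ".join(violations))
    return panel


def write_panel(panel: MarkerPanel, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["locus", "scaffold", "position_bp", "motif", "alleles"])
        for l in panel.loci:
            writer.writerow(
                [l.name, l.scaffold, l.position_bp, l.motif, ";".join(str(a) for a in sorted(l.alleles))]
            )


# ---------------------------------------------------------------------------
# genotype tables


def genotype_columns(panel: MarkerPanel) -> list:
    cols = list(META_COLUMNS)
    for name in panel.names:
        cols += [f"{name}.1", f"{name}.2"]
    return cols


def read_genotypes(path, panel: MarkerPanel, return_report: bool = False):
    """Read a genotype CSV into :class:`~xhap.core.SampleRecord` objects.

    Alleles absent from the panel definition are *not* dropped: they are
    collected into a report (mapping locus name -> set of novel alleles)
    and logged, extending the working allele set downstream.
    """
    records = []
    unknown: dict = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        expected = genotype_columns(panel)
        if reader.fieldnames is None or list(reader.fieldnames) != expected:
            raise ValueError(
                f"{path}: genotype header mismatch; expected columns {expected}"
            )
        for lineno, row in enumerate(reader, start=2):
            sex = row["sex"].strip()
            if sex not in SEXES:
                raise ValueError(f"{path}: line {lineno}: unknown sex code {sex!r}")
            pairs = []
            for locus in panel.loci:
                a1 = row[f"{locus.name}.1"].strip()
                a2 = row[f"{locus.name}.2"].strip()
                if not a1 and not a2:
                    pairs.append(None)
                    continue
                try:
                    alleles = tuple(int(a) for a in (a1, a2) if a)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: line {lineno}: bad allele at {locus.name}"
                    ) from exc
                for a in alleles:
                    if a not in locus.alleles:
                        unknown.setdefault(locus.name, set()).add(a)
                pairs.append(alleles)
            records.append(
                SampleRecord(
                    sample_id=row["sample_id"].strip(),
                    sex=sex,
                    locality=row["locality"].strip(),
                    region=row["region"].strip(),
                    family=row["family"].strip() or None,
                    stage=row["stage"].strip() or "adult",
                    subclutch=row["subclutch"].strip() or None,
                    calls=DiploidGenotype(tuple(pairs)),
                )
            )
    if unknown:
        log.warning(
            "alleles not in panel definition (working allele set extended): %s",
            {k: sorted(v) for k, v in sorted(unknown.items())},
        )
    if return_report:
        return records, unknown
    return records


def write_genotypes(records: Iterable[SampleRecord], panel: MarkerPanel, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(genotype_columns(panel))
        for rec in records:
            row = [
                rec.sample_id,
                rec.sex,
                rec.locality,
                rec.region,
                rec.family or "",
                rec.stage,
                rec.subclutch or "",
            ]
            for pair in rec.calls.pairs:
                if pair is None:
                    row += ["", ""]
                elif len(pair) == 1:
                    row += [str(pair[0]), ""]
                else:
                    row += [str(pair[0]), str(pair[1])]
            writer.writerow(row)


# ---------------------------------------------------------------------------
# haplotype catalogue


def write_catalogue(catalogue, path) -> None:
    """Write a :class:`~xhap.haplotypes.HaplotypeCatalogue` as CSV with one
    allele column per locus plus count and frequency."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", *catalogue.locus_names, "count", "frequency"])
        for hap, count, freq in catalogue.entries:
            writer.writerow([hap.label, *hap.alleles, count, repr(freq)])


def read_catalogue(path, panel: MarkerPanel):
    from .haplotypes import HaplotypeCatalogue

    entries = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        locus_names = tuple(header[1:-2])
        for row in reader:
            label = row[0]
            alleles = tuple(int(a) for a in row[1 : 1 + len(locus_names)])
            count = int(row[-2])
            freq = float(row[-1])
            entries.append((XHaplotype(alleles, label=label), count, freq))
    n_males = sum(c for _, c, _ in entries)
    return HaplotypeCatalogue(entries=entries, n_males=n_males, locus_names=locus_names)


# ---------------------------------------------------------------------------
# trees


def write_tree(tree, path: Optional[str] = None) -> str:
    """Serialise a dendropy tree to newick (branch lengths with 6
    significant digits); returns the string and optionally writes it."""
    newick = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        real_value_format_specifier=".6g",
    )
    if path is not None:
        Path(path).write_text(newick)
    return newick
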