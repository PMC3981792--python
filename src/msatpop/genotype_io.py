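"""Reading, validation and unit conversion of microsatellite genotype tables.

Genotypes are recorded as amplicon sizes in base pairs.  A cell holds one to
four allele sizes separated by ``/`` (``"187"``, ``"114/149"``), or ``NA`` for
a failed amplification.  Because fragment sizing cannot report allele dosage,
a single size may mean one or two copies in a diploid: dosage handling is a
downstream choice (see :func:`expand_dosage`).

Allele sizes convert to repeat counts through a per-locus anchor (the size and
repeat count of a reference strain) and the motif length.  The conversion is
affine and may yield fractional repeat counts when an indel outside the repeat
array shifted the amplicon size; fractional counts are kept, not rounded, so
that such alleles stay visible to downstream distance computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LocusDefinition",
    "GenotypeTable",
    "MISSING",
    "SUBSTRATE_CATEGORIES",
    "PLOIDY_CLASSES",
    "parse_cell",
    "format_cell",
    "read_genotype_table",
    "write_genotype_table",
    "read_metadata",
    "read_locus_definitions",
    "write_locus_definitions",
    "size_to_repeats",
    "repeats_to_size",
    "to_repeat_table",
    "expand_dosage",
    "ploidy_class",
    "default_loci",
]

#: Sentinel for a missing genotype: the empty tuple.
MISSING: tuple = ()

#: Substrate categories used for grouping strains.
SUBSTRATE_CATEGORIES = ("nature", "grape/wine", "bioprocess", "clinical", "unknown")

PLOIDY_CLASSES = (
    "homozygous_all_loci",
    "two_alleles_max",
    "three_alleles_one_locus",
    "complex",
)

MAX_ALLELES_PER_CELL = 4


class GenotypeParseError(ValueError):
    """Raised when a genotype cell cannot be parsed or validated."""


@dataclass(frozen=True)
class LocusDefinition:
    """A microsatellite locus: motif length plus a size/repeat-count anchor.

    The anchor (``ref_size``, ``ref_repeats``) is the allele of a reference
    strain whose repeat number is known, enabling size -> repeat conversion.
    """

    name: str
    motif_length: int
    ref_size: float
    ref_repeats: float
    size_range: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.motif_length < 1:
            raise ValueError(f"{self.name}: motif_length must be >= 1")
        if self.size_range is not None:
            lo, hi = self.size_range
            if not (lo <= self.ref_size <= hi):
                raise ValueError(
                    f"{self.name}: ref_size {self.ref_size} outside size_range {self.size_range}"
                )


@dataclass
class GenotypeTable:
    """Strains x loci matrix of allele multisets plus per-strain metadata.

    ``cells`` is a pandas DataFrame (index = strain, columns = locus names)
    whose entries are sorted tuples of allele values; the empty tuple means
    missing.  ``unit`` records whether values are amplicon sizes in bp
    (``"bp"``) or repeat counts (``"repeats"``).
    """

    cells: pd.DataFrame
    loci: list[LocusDefinition]
    metadata: pd.DataFrame | None = None
    unit: str = "bp"

    def __post_init__(self) -> None:
        if self.cells.index.has_duplicates:
            dups = self.cells.index[self.cells.index.duplicated()].tolist()
            raise GenotypeParseError(f"duplicate strain identifiers: {dups}")
        locus_names = [l.name for l in self.loci]
        if list(self.cells.columns) != locus_names:
            raise ValueError("cells columns must match loci definitions in order")

    @property
    def strains(self) -> list[str]:
        return list(self.cells.index)

    @property
    def locus_names(self) -> list[str]:
        return list(self.cells.columns)

    def locus(self, name: str) -> LocusDefinition:
        for l in self.loci:
            if l.name == name:
                return l
        raise KeyError(name)

    def subset(self, strains: Sequence[str]) -> "GenotypeTable":
        meta = self.metadata.loc[list(strains)] if self.metadata is not None else None
        return GenotypeTable(self.cells.loc[list(strains)].copy(), list(self.loci), meta, self.unit)

    def n_strains(self) -> int:
        return len(self.cells.index)


def parse_cell(text: object, where: str = "") -> tuple:
    """Parse one genotype cell: ``"187"``, ``"114/149"``, or ``"NA"``.

    Duplicate sizes within a cell are collapsed (``"187/187"`` == ``"187"``):
    the file format cannot encode copy number, so homozygotes may legally be
    written either way.
    """
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return MISSING
    s = str(text).strip()
    if s == "" or s.upper() in ("NA", "NAN"):
        return MISSING
    alleles = []
    for tok in s.split("/"):
        tok = tok.strip()
        try:
            val = float(tok)
        except ValueError:
            raise GenotypeParseError(f"malformed cell {s!r}{where}: non-numeric token {tok!r}")
        if val <= 0:
            raise GenotypeParseError(f"malformed cell {s!r}{where}: non-positive allele size")
        alleles.append(int(val) if val == int(val) else val)
    out = tuple(sorted(set(alleles)))
    if len(out) > MAX_ALLELES_PER_CELL:
        raise GenotypeParseError(f"cell {s!r}{where}: more than {MAX_ALLELES_PER_CELL} alleles")
    return out


def format_cell(alleles: tuple) -> str:
    if not alleles:
        return "NA"
    return "/".join(f"{a:g}" for a in alleles)


def _read_delimited(path: Path) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path, index_col=0, dtype=str)
    sep = "\t" if suffix in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str)


def read_genotype_table(
    path: str | Path,
    locus_defs: Sequence[LocusDefinition],
    metadata: pd.DataFrame | None = None,
) -> GenotypeTable:
    """Read a genotype table (CSV/TSV/spreadsheet) against locus definitions.

    The file must have a strain-identifier first column and one column per
    locus named in ``locus_defs`` (extra columns are ignored with a warning).
    """
    path = Path(path)
    raw = _read_delimited(path)
    raw.index = raw.index.astype(str)
    if raw.index.duplicated().any():
        dups = sorted(set(raw.index[raw.index.duplicated()]))
        raise GenotypeParseError(f"{path}: duplicate strain identifiers: {dups}")
    names = [l.name for l in locus_defs]
    missing_cols = [n for n in names if n not in raw.columns]
    if missing_cols:
        raise GenotypeParseError(f"{path}: missing locus columns {missing_cols}")
    extra = [c for c in raw.columns if c not in names]
    if extra:
        warnings.warn(f"{path}: ignoring columns {extra}")
    cells = pd.DataFrame(index=raw.index, columns=names, dtype=object)
    for strain in raw.index:
        for name in names:
            where = f" (strain {strain}, locus {name})"
            cells.at[strain, name] = parse_cell(raw.at[strain, name], where)
    return GenotypeTable(cells, list(locus_defs), metadata=metadata, unit="bp")


def write_genotype_table(table: GenotypeTable, path: str | Path) -> None:
    """Write the canonical slash-separated genotype file (CSV or TSV)."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    out = table.cells.map(format_cell)
    out.index.name = "strain"
    out.to_csv(path, sep=sep)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read strain metadata: columns strain, substrate, continent, country."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    meta = pd.read_csv(path, sep=sep, dtype=str).set_index("strain")
    meta.index = meta.index.astype(str)
    if "substrate" in meta.columns:
        bad = sorted(set(meta["substrate"].dropna()) - set(SUBSTRATE_CATEGORIES))
        if bad:
            warnings.warn(f"unmapped substrate labels {bad}; expected {SUBSTRATE_CATEGORIES}")
    return meta


def read_locus_definitions(path: str | Path) -> list[LocusDefinition]:
    """Read per-locus motif_length / ref_size / ref_repeats from YAML."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    loci = []
    for name, d in cfg.items():
        rng = tuple(d["size_range"]) if "size_range" in d else None
        loci.append(
            LocusDefinition(
                name=name,
                motif_length=int(d["motif_length"]),
                ref_size=float(d["ref_size"]),
                ref_repeats=float(d["ref_repeats"]),
                size_range=rng,
            )
        )
    return loci


def write_locus_definitions(loci: Sequence[LocusDefinition], path: str | Path) -> None:
    cfg = {}
    for l in loci:
        d = {
            "motif_length": l.motif_length,
            "ref_size": l.ref_size,
            "ref_repeats": l.ref_repeats,
        }
        if l.size_range is not None:
            d["size_range"] = list(l.size_range)
        cfg[l.name] = d
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def size_to_repeats(size: float, locus: LocusDefinition) -> float:
    """Convert an amplicon size (bp) to a repeat count via the locus anchor.

    ``repeats = ref_repeats + (size - ref_size) / motif_length``.  Fractional
    results are legal and indicate an indel outside the repeat array.
    """
    if size <= 0:
        raise ValueError("allele size must be positive")
    return locus.ref_repeats + (size - locus.ref_size) / locus.motif_length


def repeats_to_size(repeats: float, locus: LocusDefinition) -> float:
    return locus.ref_size + (repeats - locus.ref_repeats) * locus.motif_length


def to_repeat_table(table: GenotypeTable) -> GenotypeTable:
    """Convert a bp-sized table to repeat counts; counts the fractional cells."""
    if table.unit == "repeats":
        return table
    cells = pd.DataFrame(index=table.cells.index, columns=table.cells.columns, dtype=object)
    n_fractional = 0
    for locus in table.loci:
        for strain in table.cells.index:
            g = table.cells.at[strain, locus.name]
            reps = tuple(sorted(size_to_repeats(a, locus) for a in g))
            if any(abs(r - round(r)) > 1e-9 for r in reps):
                n_fractional += 1
            cells.at[strain, locus.name] = reps
    out = GenotypeTable(cells, list(table.loci), metadata=table.metadata, unit="repeats")
    out.n_fractional_cells = n_fractional  # type: ignore[attr-defined]
    return out


def expand_dosage(genotype: tuple, ploidy: int = 2) -> tuple:
    """Expand a single-allele cell to the implied homozygote dosage.

    Fragment analysis reports one peak for a homozygote, so under a diploid
    model a 1-allele cell is interpreted as two copies.  Cells that already
    hold >= 2 alleles are left as written (their dosage is unknowable).
    """
    if len(genotype) == 1 and ploidy >= 2:
        return genotype * ploidy
    return genotype


def ploidy_class(table: GenotypeTable) -> pd.Series:
    """Classify each strain's genome structure from allele counts per locus.

    Missing loci are ignored.  Classes partition the strains:
    ``homozygous_all_loci`` (every scored locus single-allele),
    ``two_alleles_max`` (at least one heterozygous locus, none above 2),
    ``three_alleles_one_locus`` (exactly one locus with 3 alleles, none with 4),
    ``complex`` (anything beyond that: >=4 alleles, or >=2 multi-allele loci).
    """
    out = {}
    for strain in table.cells.index:
        cards = [len(g) for g in table.cells.loc[strain] if len(g) > 0]
        if not cards or max(cards) <= 1:
            cls = "homozygous_all_loci"
        elif max(cards) <= 2:
            cls = "two_alleles_max"
        elif max(cards) == 3 and sum(c >= 3 for c in cards) == 1:
            cls = "three_alleles_one_locus"
        else:
            cls = "complex"
        out[strain] = cls
    return pd.Series(out, name="ploidy_class")


def default_loci() -> list[LocusDefinition]:
    """The eight-marker T. delbrueckii panel (motifs 2-4 bp, CLIB 230 anchors)."""
    spec = [
        # name, motif_length, ref_size, ref_repeats, size range
        ("TD1A", 3, 187, 10, (161, 269)),
        ("TD1B", 2, 149, 20, (114, 179)),
        ("TD1C", 3, 357, 11, (327, 379)),
        ("TD2A", 3, 276, 13, (250, 314)),
        ("TD5A", 2, 146, 20, (116, 146)),
        ("TD6A", 3, 298, 16, (249, 321)),
        ("TD7A", 4, 252, 7, (231, 263)),
        ("TD8A", 3, 156, 18, (133, 245)),
    ]
    return [
        LocusDefinition(name=n, motif_length=m, ref_size=s, ref_repeats=r, size_range=rng)
        for n, m, s, r, rng in spec
    ]
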