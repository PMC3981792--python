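"""Bruvo's genetic distance for microsatellite genotypes of any ploidy.

For two alleles whose repeat counts differ by ``x`` the distance is
``1 - 2**(-|x|)``: a geometric decay that mirrors the stepwise mutation
process, where a single-repeat change is far more likely than a multi-repeat
one.  A genotype-level distance is the minimum, over all one-to-one
assignments of alleles, of the mean allele distance.  Genotypes of unequal
cardinality are reconciled by one of three conventions:

* ``infinity`` — pad the smaller genotype with virtual alleles infinitely far
  from everything (allele distance 1).  Parameter-free; the default.
* ``genome_addition`` — assume the smaller genotype lost copies of its own
  alleles: average the distance over all ways of re-adding them.
* ``genome_loss`` — assume the smaller genotype descends from the larger one:
  the virtual alleles are drawn from the larger genotype's alleles, averaged
  over all choices.
* ``addition_loss_average`` — mean of the addition and loss models.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .genotype_io import GenotypeTable, expand_dosage

__all__ = [
    "BruvoOptions",
    "DistanceMatrix",
    "PLOIDY_MODELS",
    "allele_distance",
    "genotype_distance",
    "distance_matrix",
    "per_locus_distance_matrices",
]

PLOIDY_MODELS = ("infinity", "genome_addition", "genome_loss", "addition_loss_average")


@dataclass(frozen=True)
class BruvoOptions:
    """Options for genotype-level Bruvo distances.

    ``ploidy`` is the assumed base ploidy: single-allele cells are expanded to
    that dosage before comparison (a diploid homozygote counts twice).
    """

    unequal_ploidy_model: str = "infinity"
    ploidy: int = 2

    def __post_init__(self) -> None:
        if self.unequal_ploidy_model not in PLOIDY_MODELS:
            raise ValueError(f"unknown unequal-ploidy model {self.unequal_ploidy_model!r}")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with strain labels."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("matrix diagonal is not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "strain"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))

    def write_phylip(self, path: str | Path) -> None:
        """Square PHYLIP format (label padded to 10 characters)."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for lab, row in zip(self.labels, self.values):
                safe = lab.replace(" ", "_")[:10].ljust(10)
                fh.write(safe + "  " + "  ".join(f"{x:.6f}" for x in row) + "\n")


def allele_distance(x: float) -> float:
    """Bruvo distance between two alleles differing by ``x`` repeat units."""
    return 1.0 - 2.0 ** (-abs(x))


def _assignment_distance(g1: Sequence[float], g2: Sequence[float]) -> float:
    """Min over one-to-one allele assignments of the mean allele distance.

    Requires equal cardinality; solved as a linear assignment problem.
    """
    a = np.asarray(g1, dtype=float)
    b = np.asarray(g2, dtype=float)
    cost = 1.0 - 2.0 ** (-np.abs(a[:, None] - b[None, :]))
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].sum() / len(a))


def genotype_distance(
    g1: tuple,
    g2: tuple,
    opts: BruvoOptions | None = None,
) -> float:
    """Bruvo distance between two genotypes given as repeat-count multisets.

    Multisets are compared exactly as given; dosage expansion of homozygotes
    (a design choice tied to the assumed base ploidy) happens upstream in
    :func:`per_locus_distance_matrices`.  Either genotype missing (empty)
    returns ``nan`` so that matrix assembly can average over the loci that
    are present.
    """
    opts = opts or BruvoOptions()
    if len(g1) == 0 or len(g2) == 0:
        return float("nan")
    if len(g1) == len(g2):
        return _assignment_distance(g1, g2)
    small, large = (g1, g2) if len(g1) < len(g2) else (g2, g1)
    k = len(large) - len(small)
    model = opts.unequal_ploidy_model
    if model == "infinity":
        # Virtual alleles at distance 1 from everything: they contribute k
        # to the assignment total regardless of pairing.
        a = np.asarray(small, dtype=float)
        b = np.asarray(large, dtype=float)
        cost = 1.0 - 2.0 ** (-np.abs(a[:, None] - b[None, :]))
        pad = np.ones((k, len(large)))
        full = np.vstack([cost, pad])
        rows, cols = linear_sum_assignment(full)
        return float(full[rows, cols].sum() / len(large))
    if model == "genome_addition":
        return _imputed_mean(small, large, donors=small, k=k)
    if model == "genome_loss":
        return _imputed_mean(small, large, donors=large, k=k)
    if model == "addition_loss_average":
        add = _imputed_mean(small, large, donors=small, k=k)
        loss = _imputed_mean(small, large, donors=large, k=k)
        return 0.5 * (add + loss)
    raise AssertionError("unreachable")


def _imputed_mean(small, large, donors, k: int) -> float:
    """Average assignment distance over all ways of padding ``small`` with
    ``k`` alleles chosen (with replacement) from ``donors``."""
    total = 0.0
    count = 0
    for extra in combinations_with_replacement(sorted(set(donors)), k):
        total += _assignment_distance(tuple(small) + extra, large)
        count += 1
    return total / count


def per_locus_distance_matrices(
    table: GenotypeTable,
    opts: BruvoOptions | None = None,
) -> np.ndarray:
    """Stack of per-locus pairwise distance matrices, shape (L, n, n).

    Entries are ``nan`` where either strain is missing at the locus.  Genotype
    pair distances are memoised per locus, which matters for highly inbred
    tables where few distinct genotypes exist.
    """
    if table.unit != "repeats":
        raise ValueError("distance computation requires a repeat-count table")
    opts = opts or BruvoOptions()
    n = table.n_strains()
    loci = table.locus_names
    out = np.full((len(loci), n, n), np.nan)
    for li, locus in enumerate(loci):
        col = [expand_dosage(g, opts.ploidy) for g in table.cells[locus]]
        cache: dict[tuple, float] = {}
        m = out[li]
        for i in range(n):
            m[i, i] = 0.0 if len(col[i]) else np.nan
            for j in range(i + 1, n):
                gi, gj = col[i], col[j]
                if len(gi) == 0 or len(gj) == 0:
                    continue
                key = (gi, gj) if gi <= gj else (gj, gi)
                d = cache.get(key)
                if d is None:
                    d = genotype_distance(gi, gj, opts)
                    cache[key] = d
                m[i, j] = m[j, i] = d
    return out


def distance_matrix(
    table: GenotypeTable,
    opts: BruvoOptions | None = None,
) -> DistanceMatrix:
    """Pairwise Bruvo distances, averaged over loci scored in both strains.

    Raises if some strain pair shares no scored locus (pairwise deletion
    would leave the entry undefined).
    """
    if table.n_strains() < 2:
        raise ValueError("need at least 2 strains")
    per_locus = per_locus_distance_matrices(table, opts)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(per_locus, axis=0)
    counts = np.sum(~np.isnan(per_locus), axis=0)
    np.fill_diagonal(counts, 1)
    np.fill_diagonal(mean, 0.0)
    if np.any(counts == 0):
        i, j = np.argwhere(counts == 0)[0]
        labels = table.strains
        raise ValueError(
            f"strains {labels[i]!r} and {labels[j]!r} share no scored locus"
        )
    return DistanceMatrix(table.strains, mean)
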