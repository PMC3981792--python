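"""Per-locus population statistics: Ho, HWE tests, F-statistics, AMOVA.

Observed heterozygosity and allele counts are computed on all strains; the
diploid estimators (Hardy–Weinberg tests and Weir–Cockerham F-statistics)
use only diploid-compatible strains (<= 2 alleles at every locus), with
single-allele cells counted as dosage-2 homozygotes.

F-statistics follow the Weir–Cockerham variance-component estimator: for each
allele the variance of its frequency is split into components a (among
populations), b (among individuals within populations) and c (within
individuals), summed over alleles per locus:

    F_ST = sum(a) / sum(a + b + c)
    F_IT = 1 - sum(c) / sum(a + b + c)
    F_IS = 1 - sum(c) / sum(b + c)

AMOVA partitions the squared pairwise distances (here: Bruvo distances) into
among- and within-group variance components, with significance assessed by
permuting group labels across strains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bruvo import DistanceMatrix
from .genotype_io import GenotypeTable, expand_dosage, ploidy_class

__all__ = [
    "LocusStats",
    "FStatsResult",
    "AmovaResult",
    "observed_heterozygosity",
    "count_alleles",
    "hwe_test",
    "weir_cockerham",
    "amova",
    "locus_summary",
    "diploid_compatible_strains",
]


@dataclass
class LocusStats:
    locus: str
    Ho: float
    n_alleles: int
    allele_size_range: tuple[float, float]
    hwe_chi2: float = float("nan")
    hwe_df: int = 0
    hwe_p: float = float("nan")


@dataclass
class FStatsResult:
    grouping: str
    per_locus: pd.DataFrame  # index locus, columns F_IT, F_ST, F_IS
    components: pd.DataFrame  # index locus, columns a, b, c (summed over alleles)
    overall: dict = field(default_factory=dict)  # multilocus F's (components summed)


@dataclass
class AmovaResult:
    grouping: str
    ss_among: float
    ss_within: float
    df_among: int
    df_within: int
    sigma2_among: float
    sigma2_within: float
    percent_among: float
    p_value: float
    n_permutations: int
    negative_component: bool = False


def diploid_compatible_strains(table: GenotypeTable) -> list[str]:
    """Strains with at most two alleles at every scored locus."""
    cls = ploidy_class(table)
    return [s for s in table.strains if cls[s] in ("homozygous_all_loci", "two_alleles_max")]


def observed_heterozygosity(table: GenotypeTable, locus: str) -> float:
    """Fraction of scored strains carrying >= 2 distinct alleles at ``locus``.

    Strains with > 2 alleles count as heterozygous; all-missing loci are
    undefined (nan, with a warning).
    """
    col = table.cells[locus]
    scored = [g for g in col if len(g) > 0]
    if not scored:
        warnings.warn(f"locus {locus}: no scored strains, Ho undefined")
        return float("nan")
    return sum(len(g) >= 2 for g in scored) / len(scored)


def count_alleles(table: GenotypeTable, locus: str) -> tuple[int, tuple[float, float]]:
    """Number of distinct allele values and their (min, max) range."""
    values = sorted({a for g in table.cells[locus] for a in g})
    if not values:
        return 0, (float("nan"), float("nan"))
    return len(values), (values[0], values[-1])


def _diploid_genotypes(table: GenotypeTable, locus: str) -> list[tuple]:
    """Dosage-2 genotypes at a locus for diploid-compatible strains."""
    keep = set(diploid_compatible_strains(table))
    out = []
    for strain in table.strains:
        if strain not in keep:
            continue
        g = table.cells.at[strain, locus]
        if len(g) == 0:
            continue
        out.append(expand_dosage(g, 2))
    return out


def hwe_test(
    table: GenotypeTable,
    locus: str,
    n_mc: int = 0,
    seed: int | None = None,
) -> tuple[float, int, float]:
    """Chi-square goodness-of-fit of genotype counts to Hardy–Weinberg.

    Returns ``(chi2, df, p)`` with ``df = k(k-1)/2`` for ``k`` alleles.  When
    ``n_mc > 0`` the p-value is instead estimated by Monte Carlo: alleles are
    shuffled among individuals ``n_mc`` times and the chi-square statistic is
    recomputed, giving an exact-style test that is robust to sparse genotype
    cells (common for microsatellites).
    """
    genotypes = _diploid_genotypes(table, locus)
    if not genotypes:
        raise ValueError(f"locus {locus}: no diploid-compatible data")
    alleles = sorted({a for g in genotypes for a in g})
    k = len(alleles)
    if k == 1:
        warnings.warn(f"locus {locus}: monomorphic, HWE test undefined")
        return float("nan"), 0, float("nan")
    index = {a: i for i, a in enumerate(alleles)}
    pairs = np.array([[index[g[0]], index[g[1]]] for g in genotypes])

    def chi2_of(pairs_arr: np.ndarray) -> float:
        n = len(pairs_arr)
        lo = np.minimum(pairs_arr[:, 0], pairs_arr[:, 1])
        hi = np.maximum(pairs_arr[:, 0], pairs_arr[:, 1])
        obs = np.zeros((k, k))
        np.add.at(obs, (lo, hi), 1)
        freqs = np.bincount(pairs_arr.ravel(), minlength=k) / (2 * n)
        exp = np.zeros((k, k))
        for i in range(k):
            exp[i, i] = n * freqs[i] ** 2
            for j in range(i + 1, k):
                exp[i, j] = 2 * n * freqs[i] * freqs[j]
        mask = exp > 0
        return float(((obs[mask] - exp[mask]) ** 2 / exp[mask]).sum())

    chi2 = chi2_of(pairs)
    df = k * (k - 1) // 2
    if n_mc > 0:
        rng = np.random.default_rng(seed)
        pool = pairs.ravel().copy()
        hits = 0
        for _ in range(n_mc):
            rng.shuffle(pool)
            if chi2_of(pool.reshape(-1, 2)) >= chi2 - 1e-12:
                hits += 1
        p = (1 + hits) / (n_mc + 1)
    else:
        from scipy.stats import chi2 as chi2_dist

        p = float(chi2_dist.sf(chi2, df))
    return chi2, df, p


def weir_cockerham(table: GenotypeTable, grouping: pd.Series) -> FStatsResult:
    """Weir–Cockerham F-statistics per locus under a diploid model.

    ``grouping`` maps strain -> population label.  Strains with > 2 alleles at
    any locus are excluded (diploid estimator); at each locus, strains missing
    there are dropped and populations left with no data are ignored.
    Monomorphic loci yield nan with a warning.
    """
    keep = [s for s in diploid_compatible_strains(table) if s in grouping.index]
    rows = {}
    comps = {}
    for locus in table.locus_names:
        data = []  # (pop, allele1, allele2)
        for strain in keep:
            g = table.cells.at[strain, locus]
            if len(g) == 0:
                continue
            a1, a2 = expand_dosage(g, 2)
            data.append((grouping[strain], a1, a2))
        pops = sorted({p for p, _, _ in data})
        alleles = sorted({a for _, a1, a2 in data for a in (a1, a2)})
        if len(alleles) < 2 or len(pops) < 2:
            warnings.warn(f"locus {locus}: monomorphic or single-group, F undefined")
            rows[locus] = (np.nan, np.nan, np.nan)
            comps[locus] = (np.nan, np.nan, np.nan)
            continue
        r = len(pops)
        n_i = np.array([sum(1 for p, _, _ in data if p == pop) for pop in pops], float)
        nbar = n_i.mean()
        nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
        A = B = C = 0.0
        for allele in alleles:
            p_i = np.array(
                [
                    sum((a1 == allele) + (a2 == allele) for p, a1, a2 in data if p == pop)
                    / (2 * n)
                    for pop, n in zip(pops, n_i)
                ]
            )
            h_i = np.array(
                [
                    sum(
                        ((a1 == allele) != (a2 == allele))
                        for p, a1, a2 in data
                        if p == pop
                    )
                    / n
                    for pop, n in zip(pops, n_i)
                ]
            )
            pbar = (n_i * p_i).sum() / (r * nbar)
            s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
            hbar = (n_i * h_i).sum() / (r * nbar)
            a = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c = hbar / 2
            A, B, C = A + a, B + b, C + c
        tot = A + B + C
        f_st = A / tot if tot != 0 else np.nan
        f_it = 1 - C / tot if tot != 0 else np.nan
        f_is = 1 - C / (B + C) if (B + C) != 0 else np.nan
        rows[locus] = (f_it, f_st, f_is)
        comps[locus] = (A, B, C)
    per_locus = pd.DataFrame.from_dict(rows, orient="index", columns=["F_IT", "F_ST", "F_IS"])
    components = pd.DataFrame.from_dict(comps, orient="index", columns=["a", "b", "c"])
    valid = components.dropna()
    overall = {}
    if len(valid):
        A, B, C = valid["a"].sum(), valid["b"].sum(), valid["c"].sum()
        tot = A + B + C
        overall = {
            "F_ST": A / tot if tot else np.nan,
            "F_IT": 1 - C / tot if tot else np.nan,
            "F_IS": 1 - C / (B + C) if (B + C) else np.nan,
        }
    name = grouping.name or "grouping"
    return FStatsResult(grouping=name, per_locus=per_locus, components=components, overall=overall)


def _ss_within(d2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss


def amova(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 1000,
    seed: int | None = None,
) -> AmovaResult:
    """One-level AMOVA on a distance matrix with a permutation test.

    Sums of squares come from squared pairwise distances; the among-group
    variance component uses the standard moments equations with unequal group
    sizes.  The p-value is ``(1 + #{permuted sigma2_a >= observed}) /
    (n_perm + 1)`` over random relabellings of strains.
    """
    labels = np.array([groups[lab] for lab in dm.labels])
    uniq, counts = np.unique(labels, return_counts=True)
    if np.any(counts == 0):
        raise ValueError("empty group")
    if len(uniq) == 1:
        # no among-group level: all variance is within
        d2 = dm.values**2
        N = len(labels)
        ssw = d2.sum() / (2 * N)
        return AmovaResult(
            grouping=groups.name or "grouping",
            ss_among=0.0, ss_within=ssw, df_among=0, df_within=N - 1,
            sigma2_among=0.0, sigma2_within=ssw / (N - 1),
            percent_among=0.0, p_value=1.0, n_permutations=0,
        )
    d2 = dm.values**2
    N = len(labels)
    g = len(uniq)
    ss_total = d2.sum() / (2 * N)
    ss_within = _ss_within(d2, labels, uniq)
    ss_among = ss_total - ss_within
    df_among = g - 1
    df_within = N - g
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within
    n0 = (N - (counts**2).sum() / N) / (g - 1)
    sigma2_w = ms_within
    sigma2_a = (ms_among - ms_within) / n0
    negative = sigma2_a < 0
    denom = sigma2_a + sigma2_w
    percent = 100.0 * sigma2_a / denom if denom > 0 else float("nan")

    rng = np.random.default_rng(seed)
    hits = 0
    perm = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm)
        ssw = _ss_within(d2, perm, uniq)
        msa = (ss_total - ssw) / df_among
        msw = ssw / df_within
        if (msa - msw) / n0 >= sigma2_a - 1e-12:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return AmovaResult(
        grouping=groups.name or "grouping",
        ss_among=ss_among,
        ss_within=ss_within,
        df_among=df_among,
        df_within=df_within,
        sigma2_among=sigma2_a,
        sigma2_within=sigma2_w,
        percent_among=percent,
        p_value=p,
        n_permutations=n_perm,
        negative_component=bool(negative),
    )


def locus_summary(
    table: GenotypeTable,
    grouping: pd.Series | None = None,
    hwe_mc: int = 0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-locus report: allele counts, size ranges, Ho, HWE, F-statistics.

    HWE p-values are reported raw and Bonferroni-adjusted across loci.
    """
    records = []
    for locus in table.locus_names:
        n_alleles, size_range = count_alleles(table, locus)
        ho = observed_heterozygosity(table, locus)
        try:
            chi2, df, p = hwe_test(table, locus, n_mc=hwe_mc, seed=seed)
        except ValueError:
            chi2, df, p = np.nan, 0, np.nan
        records.append(
            {
                "locus": locus,
                "n_alleles": n_alleles,
                "size_min": size_range[0],
                "size_max": size_range[1],
                "Ho": ho,
                "hwe_chi2": chi2,
                "hwe_df": df,
                "hwe_p": p,
            }
        )
    df_out = pd.DataFrame(records).set_index("locus")
    L = len(df_out)
    df_out["hwe_p_bonferroni"] = np.minimum(df_out["hwe_p"] * L, 1.0)
    if grouping is not None:
        fst = weir_cockerham(table, grouping)
        df_out = df_out.join(fst.per_locus)
    return df_out
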