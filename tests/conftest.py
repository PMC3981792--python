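"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive quantities by brute force (exhaustive
enumeration, flat loops) so that the vectorised/optimised library code is
checked against an implementation that shares none of its structure.
"""

from __future__ import annotations

from itertools import combinations_with_replacement, permutations

import numpy as np
import pandas as pd
import pytest

from msatpop.genotype_io import GenotypeTable, LocusDefinition, default_loci
from msatpop.simulate import SimulationConfig, simulate_population_split


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def bruvo_allele(x: float) -> float:
    return 1.0 - 2.0 ** (-abs(x))


def bruvo_oracle(g1: tuple, g2: tuple, model: str = "infinity") -> float:
    """Exhaustive-enumeration Bruvo genotype distance (cardinality <= 4).

    Equal cardinality: min over all permutations of the mean allele distance.
    ``infinity``: pad the smaller side with virtual alleles at distance 1 to
    everything.  Addition/loss: average the equal-cardinality oracle over all
    paddings drawn from the donor genotype.
    """
    VIRT = object()

    def equal_k(a, b):
        best = np.inf
        for perm in permutations(range(len(b))):
            tot = 0.0
            for i, j in enumerate(perm):
                if a[i] is VIRT or b[j] is VIRT:
                    tot += 1.0
                else:
                    tot += bruvo_allele(a[i] - b[j])
            best = min(best, tot / len(b))
        return best

    if len(g1) == len(g2):
        return equal_k(list(g1), list(g2))
    small, large = (list(g1), list(g2)) if len(g1) < len(g2) else (list(g2), list(g1))
    k = len(large) - len(small)
    if model == "infinity":
        return equal_k(small + [VIRT] * k, large)
    donors = {"genome_addition": small, "genome_loss": large}
    if model == "addition_loss_average":
        return 0.5 * (
            bruvo_oracle(tuple(small), tuple(large), "genome_addition")
            + bruvo_oracle(tuple(small), tuple(large), "genome_loss")
        )
    vals = [
        equal_k(small + list(extra), large)
        for extra in combinations_with_replacement(sorted(set(donors[model])), k)
    ]
    return float(np.mean(vals))


def amova_sigma2_among_oracle(d: np.ndarray, labels: list) -> float:
    """Flat-loop AMOVA among-group variance component."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d[i, j] ** 2
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        s = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                s += d[idx[a], idx[b]] ** 2
        ss_within += s / len(idx)
    ss_among = ss_total - ss_within
    sizes = [labels.count(g) for g in groups]
    gN = len(groups)
    n0 = (n - sum(s**2 for s in sizes) / n) / (gN - 1)
    ms_among = ss_among / (gN - 1)
    ms_within = ss_within / (n - gN)
    return (ms_among - ms_within) / n0


def delta_mu_oracle(cellsA: list, cellsB: list) -> float:
    """Flat-loop (deltamu)^2 for one locus: lists of allele tuples per group."""

    def copies(cells):
        out = []
        for g in cells:
            if len(g) == 0:
                continue
            alleles = list(g) * 2 if len(g) == 1 else list(g)
            out.extend(alleles)
        return out

    ca, cb = copies(cellsA), copies(cellsB)
    return (float(np.mean(ca)) - float(np.mean(cb))) ** 2


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_table(cells: dict, loci=None, metadata=None, unit="repeats") -> GenotypeTable:
    """Build a GenotypeTable from {strain: {locus: tuple}} by hand."""
    frame = pd.DataFrame.from_dict(cells, orient="index")
    if loci is None:
        loci = [
            LocusDefinition(name, 2, 100, 10) for name in frame.columns
        ]
    frame = frame[[l.name for l in loci]]
    return GenotypeTable(frame, list(loci), metadata=metadata, unit=unit)


@pytest.fixture(scope="session")
def sim_default():
    """One simulated dataset at the default study-like conditions."""
    return simulate_population_split(SimulationConfig(seed=101))


@pytest.fixture(scope="session")
def sim_two_pops():
    """Two strongly diverged demes for clustering/recovery checks."""
    cfg = SimulationConfig(
        n_pops=2, split_time=1200, pop_size=100, sample_size=30, seed=202
    )
    return simulate_population_split(cfg)


@pytest.fixture(scope="session")
def generic_loci():
    def factory(L: int, motif: int = 2, ref_repeats: int = 20):
        return tuple(
            LocusDefinition(f"L{i:02d}", motif, 100 + motif * ref_repeats, ref_repeats)
            for i in range(L)
        )

    return factory
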