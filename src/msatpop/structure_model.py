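"""Bayesian no-admixture clustering of diploid genotypes by Gibbs sampling.

Each strain's whole genome is assumed to descend from exactly one of ``K``
ancestral populations.  Population allele frequencies at each locus carry a
symmetric Dirichlet(lambda) prior.  The sampler alternates:

(a) draw allele frequencies per population/locus from
    Dirichlet(lambda + allele counts of currently assigned strains);
(b) draw each strain's population label with probability proportional to its
    diploid genotype likelihood under each population's frequencies
    (homozygote ``p^2``, heterozygote ``2 p q``; missing loci skipped).

Averaged assignment indicators over the recorded iterations give the
posterior membership probabilities.  The model-choice score per K is the
standard harmonic-style deviance estimate of the log evidence: mean recorded
log-likelihood minus half its variance.  Non-convergence is not detected;
users should compare independent seeds.  Label switching within a chain is
rare under strong structure but possible; across chains, use
:func:`align_posteriors`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable, expand_dosage
from .popstats import diploid_compatible_strains

__all__ = [
    "StructureConfig",
    "AssignmentPosterior",
    "select_diploid_subset",
    "diploid_loglik",
    "gibbs_no_admixture",
    "sweep_K",
    "align_posteriors",
    "assignment_accuracy",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StructureConfig:
    """Chain settings.  The classic defaults (10000 burn-in, 1000 recorded)
    record a short window; longer recording is advisable for stable evidence
    estimates and a warning is issued below 1000 recorded iterations."""

    K: int = 2
    burn_in: int = 10000
    reps: int = 1000
    allele_freq_prior: float = 1.0  # Dirichlet concentration lambda
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.burn_in < 0 or self.reps < 1:
            raise ValueError("burn_in >= 0 and reps >= 1 required")
        if self.allele_freq_prior <= 0:
            raise ValueError("allele_freq_prior must be > 0")


@dataclass
class AssignmentPosterior:
    posterior: pd.DataFrame  # strains x K membership probabilities
    log_evidence: float
    mean_loglik: float
    var_loglik: float
    config: StructureConfig

    def hard_labels(self) -> pd.Series:
        return self.posterior.idxmax(axis=1)


def select_diploid_subset(table: GenotypeTable) -> tuple[GenotypeTable, list[str]]:
    """Drop strains with >= 3 alleles at any locus; return (subset, removed)."""
    keep = diploid_compatible_strains(table)
    removed = [s for s in table.strains if s not in set(keep)]
    if removed:
        logger.info("select_diploid_subset: removed %d strains: %s", len(removed), removed)
    return table.subset(keep), removed


def _encode(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray, list[np.ndarray], int]:
    """Integer-code alleles per locus; returns (a1, a2, codes, max_alleles).

    a1/a2 are (N, L) arrays of allele codes (-1 = missing); homozygotes carry
    the same code twice (dosage 2).
    """
    N, L = table.n_strains(), len(table.locus_names)
    a1 = np.full((N, L), -1, dtype=np.int64)
    a2 = np.full((N, L), -1, dtype=np.int64)
    codes = []
    for li, locus in enumerate(table.locus_names):
        col = list(table.cells[locus])
        alleles = sorted({a for g in col for a in g})
        index = {a: i for i, a in enumerate(alleles)}
        codes.append(np.array(alleles))
        for i, g in enumerate(col):
            if len(g) == 0:
                continue
            if len(g) > 2:
                raise ValueError("gibbs_no_admixture requires a diploid-compatible table")
            x, y = expand_dosage(g, 2)
            a1[i, li] = index[x]
            a2[i, li] = index[y]
    amax = max((len(c) for c in codes), default=1)
    return a1, a2, codes, amax


def diploid_loglik(
    a1: np.ndarray,
    a2: np.ndarray,
    logP: np.ndarray,
) -> np.ndarray:
    """Log-likelihood of each strain under each population's frequencies.

    ``a1``/``a2`` are (N, L) allele codes (-1 missing, homozygotes repeated);
    ``logP`` is (K, L, A) log allele frequencies.  Homozygotes contribute
    ``2 log p``, heterozygotes ``log 2 + log p + log q``; missing loci are
    skipped.  Returns (N, K).
    """
    N, L = a1.shape
    K = logP.shape[0]
    valid = a1 >= 0
    het = valid & (a1 != a2)
    loglik = np.zeros((N, K))
    for li in range(L):
        ok = valid[:, li]
        if not ok.any():
            continue
        lp = logP[:, li, :]
        contrib = lp[:, a1[ok, li]] + lp[:, a2[ok, li]]
        contrib = contrib + (np.log(2.0) * het[ok, li])[None, :]
        loglik[ok] += contrib.T
    return loglik


def gibbs_no_admixture(table: GenotypeTable, cfg: StructureConfig) -> AssignmentPosterior:
    """Run one Gibbs chain; see module docstring for the model."""
    strains = table.strains
    N, L = len(strains), len(table.locus_names)
    K = cfg.K
    if K > N:
        raise ValueError(f"K={K} exceeds number of strains ({N})")
    if cfg.reps < 1000:
        warnings.warn(
            f"only {cfg.reps} recorded iterations; evidence estimates are noisy"
        )
    a1, a2, codes, amax = _encode(table)
    valid = a1 >= 0  # (N, L) scored mask

    rng = np.random.default_rng(cfg.seed)
    z = rng.integers(K, size=N)
    indicators = np.zeros((N, K))
    logliks = np.empty(cfg.reps)

    # per-locus "allele present" mask so padded slots never get probability
    pad_mask = np.zeros((L, amax), dtype=bool)
    for li, c in enumerate(codes):
        pad_mask[li, : len(c)] = True

    lam = cfg.allele_freq_prior
    rows = np.arange(N)
    for it in range(cfg.burn_in + cfg.reps):
        # (a) allele frequencies | assignments
        counts = np.zeros((K, L, amax))
        for arr in (a1, a2):
            flat_k = np.repeat(z, L)[valid.ravel()]
            flat_l = np.tile(np.arange(L), N)[valid.ravel()]
            flat_a = arr[valid]
            np.add.at(counts, (flat_k, flat_l, flat_a), 1.0)
        gam = rng.gamma(lam + counts)
        gam[:, ~pad_mask] = 0.0
        P = gam / gam.sum(axis=2, keepdims=True)
        logP = np.log(np.where(P > 0, P, 1.0))

        # (b) labels | frequencies
        loglik = diploid_loglik(a1, a2, logP)
        g = loglik + rng.gumbel(size=(N, K))
        z = np.argmax(g, axis=1)

        if it >= cfg.burn_in:
            rec = it - cfg.burn_in
            indicators[rows, z] += 1.0
            logliks[rec] = loglik[rows, z].sum()

    posterior = pd.DataFrame(
        indicators / cfg.reps, index=strains, columns=[f"pop{k}" for k in range(K)]
    )
    mean_ll = float(np.mean(logliks))
    var_ll = float(np.var(logliks))
    return AssignmentPosterior(
        posterior=posterior,
        log_evidence=mean_ll - 0.5 * var_ll,
        mean_loglik=mean_ll,
        var_loglik=var_ll,
        config=cfg,
    )


def sweep_K(
    table: GenotypeTable,
    K_range: range | list[int],
    cfg: StructureConfig | None = None,
) -> dict[int, AssignmentPosterior]:
    """Run independent chains over a range of K; report the score profile.

    Each K gets a seed derived deterministically from the base seed.  The
    choice of K is left to the user (the evidence profile is reported, not
    thresholded).
    """
    Ks = list(K_range)
    if not Ks:
        raise ValueError("K_range is empty")
    cfg = cfg or StructureConfig()
    base = np.random.SeedSequence(cfg.seed)
    children = base.spawn(len(Ks))
    out = {}
    for K, ss in zip(Ks, children):
        seed = int(ss.generate_state(1)[0] % (2**31))
        kcfg = StructureConfig(
            K=K,
            burn_in=cfg.burn_in,
            reps=cfg.reps,
            allele_freq_prior=cfg.allele_freq_prior,
            seed=seed,
        )
        out[K] = gibbs_no_admixture(table, kcfg)
    return out


def align_posteriors(p: pd.DataFrame, reference: pd.DataFrame) -> pd.DataFrame:
    """Resolve label switching: greedily permute columns of ``p`` to best
    match ``reference`` (maximum column-correlation assignment)."""
    if p.shape != reference.shape:
        raise ValueError("posterior shapes differ")
    K = p.shape[1]
    cost = np.zeros((K, K))
    pv = p.to_numpy()
    rv = reference.to_numpy()
    for i in range(K):
        for j in range(K):
            cost[i, j] = -float(np.dot(pv[:, i], rv[:, j]))
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(cost)
    order = np.empty(K, dtype=int)
    order[cols] = rows
    aligned = pv[:, order]
    return pd.DataFrame(aligned, index=p.index, columns=reference.columns)


def assignment_accuracy(posterior: pd.DataFrame, truth: dict[str, int]) -> float:
    """Fraction of strains whose modal cluster matches the true label, after
    resolving label switching by the best cluster-to-label permutation."""
    from scipy.optimize import linear_sum_assignment

    strains = list(posterior.index)
    hard = posterior.to_numpy().argmax(axis=1)
    true = np.array([truth[s] for s in strains])
    K = posterior.shape[1]
    T = int(true.max()) + 1
    m = max(K, T)
    conf = np.zeros((m, m))
    for h, t in zip(hard, true):
        conf[h, t] += 1
    rows, cols = linear_sum_assignment(-conf)
    return float(conf[rows, cols].sum() / len(strains))
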