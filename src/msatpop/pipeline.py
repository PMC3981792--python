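"""End-to-end orchestration: genotypes -> distances -> trees/clustering/stats.

``run_full_pipeline`` executes the complete analysis graph on one dataset and
writes every intermediate product plus a manifest (input hashes, config echo,
per-stage seeds) so any output is reproducible from the manifest alone.

Stage seeds are expanded from the single global seed with
``numpy.random.SeedSequence(seed).spawn()`` in a fixed order (tree bootstrap,
structure sweep, AMOVA, divergence), so each stage can be rerun independently
with its recorded seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bruvo import BruvoOptions, distance_matrix
from .divergence import DivergenceConfig, divergence_report
from .genotype_io import (
    GenotypeTable,
    default_loci,
    ploidy_class,
    read_genotype_table,
    read_locus_definitions,
    read_metadata,
    to_repeat_table,
    write_genotype_table,
)
from .popstats import amova, locus_summary
from .structure_model import StructureConfig, select_diploid_subset, sweep_K
from .trees import DEFAULT_SCALES, multiscale_bootstrap, write_newick

__all__ = ["PipelineConfig", "run_full_pipeline"]

logger = logging.getLogger(__name__)

_STAGES = ("convert", "distance", "tree", "structure", "stats", "amova", "divergence")


@dataclass
class PipelineConfig:
    genotypes: str
    metadata: str | None = None
    locus_definitions: str | None = None  # None -> the default 8-locus panel
    out_dir: str = "msatpop_out"
    seed: int = 0
    bruvo_model: str = "infinity"
    ploidy: int = 2
    tree_scales: tuple[float, ...] = DEFAULT_SCALES
    tree_n_boot: int = 1000
    structure_K: tuple[int, ...] = tuple(range(3, 21))
    structure_burn_in: int = 10000
    structure_reps: int = 1000
    amova_groupings: tuple[str, ...] = ("substrate", "continent")
    hwe_mc: int = 1000
    divergence_pairs: tuple[tuple[str, str], ...] = ()  # pairs of grouping values
    divergence_grouping: str = "substrate"
    mutation_rate: float = 1e-5
    generations_per_year: float = 100.0
    divergence_n_boot: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("tree_scales", "structure_K", "amova_groupings"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "divergence_pairs" in raw:
            raw["divergence_pairs"] = tuple(tuple(p) for p in raw["divergence_pairs"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_full_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk).

    Any stage failure aborts with :class:`StageError` naming the stage;
    outputs of completed stages are left in place.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(cfg.seed).spawn(4)
    stage_seeds = {
        name: int(ss.generate_state(1)[0] % (2**31))
        for name, ss in zip(("tree", "structure", "amova", "divergence"), seeds)
    }
    manifest: dict = {
        "msatpop_version": __version__,
        "seed": cfg.seed,
        "stage_seeds": stage_seeds,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cfg).items()},
        "inputs": {},
        "outputs": {},
    }

    def record(stage: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, []).append(str(path))

    # ---- load inputs -------------------------------------------------------
    loci = (
        read_locus_definitions(cfg.locus_definitions)
        if cfg.locus_definitions
        else default_loci()
    )
    meta = read_metadata(cfg.metadata) if cfg.metadata else None
    for label, p in (("genotypes", cfg.genotypes), ("metadata", cfg.metadata),
                     ("locus_definitions", cfg.locus_definitions)):
        if p:
            manifest["inputs"][label] = {"path": str(p), "sha256": _sha256(Path(p))}
    table = read_genotype_table(cfg.genotypes, loci, metadata=meta)

    # validate groupings before any computation
    if meta is not None:
        for grouping in cfg.amova_groupings:
            if grouping not in meta.columns:
                raise StageError(
                    "amova", KeyError(f"grouping column {grouping!r} absent from metadata")
                )
    elif cfg.amova_groupings:
        raise StageError("amova", ValueError("AMOVA groupings requested but no metadata given"))

    # ---- convert -----------------------------------------------------------
    try:
        reps = to_repeat_table(table)
        classes = ploidy_class(table)
        p = out / "repeats.csv"
        write_genotype_table(reps, p)
        record("convert", p)
        p = out / "ploidy_classes.tsv"
        classes.to_csv(p, sep="\t")
        record("convert", p)
    except StageError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise StageError("convert", e) from e

    # ---- distance ----------------------------------------------------------
    try:
        opts = BruvoOptions(unequal_ploidy_model=cfg.bruvo_model, ploidy=cfg.ploidy)
        dm = distance_matrix(reps, opts)
        p = out / "bruvo_distance.tsv"
        dm.write_tsv(p)
        record("distance", p)
        p = out / "bruvo_distance.phylip"
        dm.write_phylip(p)
        record("distance", p)
    except StageError:
        raise
    except Exception as e:
        raise StageError("distance", e) from e

    # ---- tree + AU support -------------------------------------------------
    try:
        tree, fits = multiscale_bootstrap(
            reps, scales=cfg.tree_scales, n_boot=cfg.tree_n_boot,
            seed=stage_seeds["tree"], opts=opts,
        )
        support = {cl: fit.au_p for cl, fit in fits.items()}
        p = out / "nj_tree.nwk"
        p.write_text(write_newick(tree, support) + "\n")
        record("tree", p)
        rows = [
            {
                "cluster": ";".join(sorted(cl)),
                "au": fit.au_p,
                "bp": fit.bp,
                "v": fit.v,
                "c": fit.c,
                "degenerate": fit.degenerate,
            }
            for cl, fit in fits.items()
        ]
        p = out / "tree_support.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        record("tree", p)
    except StageError:
        raise
    except Exception as e:
        raise StageError("tree", e) from e

    # ---- structure sweep ---------------------------------------------------
    try:
        diploid, removed = select_diploid_subset(reps)
        scfg = StructureConfig(
            K=min(cfg.structure_K),
            burn_in=cfg.structure_burn_in,
            reps=cfg.structure_reps,
            seed=stage_seeds["structure"],
        )
        sweep = sweep_K(diploid, list(cfg.structure_K), scfg)
        profile = {str(K): r.log_evidence for K, r in sweep.items()}
        best_K = max(sweep, key=lambda K: sweep[K].log_evidence)
        p = out / "structure_posterior.tsv"
        sweep[best_K].posterior.to_csv(p, sep="\t")
        record("structure", p)
        p = out / "structure_summary.json"
        p.write_text(
            json.dumps(
                {
                    "removed_non_diploid": removed,
                    "evidence_profile": profile,
                    "best_K_by_evidence": best_K,
                    "seed": stage_seeds["structure"],
                    "burn_in": cfg.structure_burn_in,
                    "reps": cfg.structure_reps,
                },
                indent=2,
            )
        )
        record("structure", p)
    except StageError:
        raise
    except Exception as e:
        raise StageError("structure", e) from e

    # ---- per-locus stats ---------------------------------------------------
    try:
        grouping = None
        if meta is not None and "substrate" in meta.columns:
            grouping = meta["substrate"]
            grouping.name = "substrate"
        stats = locus_summary(table, grouping=grouping, hwe_mc=cfg.hwe_mc, seed=stage_seeds["amova"])
        p = out / "locus_stats.tsv"
        stats.to_csv(p, sep="\t")
        record("stats", p)
    except StageError:
        raise
    except Exception as e:
        raise StageError("stats", e) from e

    # ---- AMOVA per grouping ------------------------------------------------
    try:
        amova_out = {}
        for gi, grouping_name in enumerate(cfg.amova_groupings):
            labels = meta[grouping_name]
            labels.name = grouping_name
            keep = [s for s in dm.labels if pd.notna(labels.get(s))]
            sub = [dm.labels.index(s) for s in keep]
            sub_dm = type(dm)(keep, dm.values[np.ix_(sub, sub)])
            res = amova(sub_dm, labels, n_perm=1000, seed=stage_seeds["amova"] + gi)
            amova_out[grouping_name] = {
                "percent_among": res.percent_among,
                "sigma2_among": res.sigma2_among,
                "sigma2_within": res.sigma2_within,
                "p_value": res.p_value,
                "n_permutations": res.n_permutations,
                "negative_component": res.negative_component,
            }
        p = out / "amova.json"
        p.write_text(json.dumps(amova_out, indent=2))
        record("amova", p)
    except StageError:
        raise
    except Exception as e:
        raise StageError("amova", e) from e

    # ---- divergence dating -------------------------------------------------
    try:
        div_out = []
        dcfg = DivergenceConfig(
            mutation_rate=cfg.mutation_rate,
            generations_per_year=cfg.generations_per_year,
            n_boot=cfg.divergence_n_boot,
            seed=stage_seeds["divergence"],
        )
        if cfg.divergence_pairs and meta is not None:
            labels = meta[cfg.divergence_grouping]
            for a, b in cfg.divergence_pairs:
                sa = [s for s in reps.strains if labels.get(s) == a]
                sb = [s for s in reps.strains if labels.get(s) == b]
                res = divergence_report(reps.subset(sa), reps.subset(sb), dcfg, pair=(a, b))
                div_out.append(res.to_dict())
        p = out / "divergence.json"
        p.write_text(json.dumps(div_out, indent=2))
        record("divergence", p)
    except StageError:
        raise
    except Exception as e:
        raise StageError("divergence", e) from e

    p = out / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2))
    return manifest
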