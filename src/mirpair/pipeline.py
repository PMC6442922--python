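"""Orchestration: configuration, per-stage seeding, and the end-to-end run.

A single global seed is expanded into independent per-stage substreams
(via :class:`numpy.random.SeedSequence`) so any stage can be rerun in
isolation with identical results.  Every stage writes its tables under
the run directory and the run closes with a JSON manifest recording
versions, seeds, thresholds and SHA-256 digests of all inputs/outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .candidates import select_candidates
from .de import run_de
from .errors import ValidationError
from .network import assemble_network, inverse_pair, write_graphml
from .overlap import permutation_overlap_test
from .simulate import SimParams, simulate_paired_counts, simulate_target_tables, \
    simulate_universe_pair
from .targets import filter_predicted, merge_validated, targets_by_direction

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "stage_seed", "run_all"]

STAGES = ("simulate", "de", "select", "targets", "overlap", "integrate")


@dataclass
class PipelineConfig:
    """Paths, thresholds and seeds for one pipeline run.

    Path fields may be None when the synthetic stage generates them.
    """

    counts: str | None = None
    sample_sheet: str | None = None
    predicted_targets: str | None = None
    validated_targets: str | None = None
    gene_de: str | None = None          # gene-level directions for integration
    set_b_gmt: str | None = None        # comparison gene set (species B)
    universe_a: str | None = None
    universe_b: str | None = None
    orthologs: str | None = None

    fdr: float = 0.05
    fold: float = 1.3
    delta: float = 0.15
    pct: float = 0.2
    contextpp: float = -0.15
    n_perm: int = 10_000
    p_convention: str = "plus_one"
    seed: int = 0
    simulate: bool = True
    sim_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValidationError("fdr threshold must lie in (0, 1)")
        if self.fold < 1:
            raise ValidationError("fold threshold must be >= 1")
        if self.delta < 0:
            raise ValidationError("delta threshold must be non-negative")
        if self.n_perm < 1:
            raise ValidationError("n_perm must be >= 1")
        if self.p_convention not in ("plus_one", "raw"):
            raise ValidationError(f"unknown p-value convention {self.p_convention!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig, run_dir) -> Path:
    """Execute simulate (optional) -> de -> select -> targets -> overlap ->
    integrate, writing every intermediate table and a JSON manifest.

    Returns the run directory.  A stage failure aborts with the failing
    stage named; outputs of completed stages are retained.
    """
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            "fdr": config.fdr, "fold": config.fold, "delta": config.delta,
            "pct": config.pct, "contextpp": config.contextpp,
        },
        "n_perm": config.n_perm,
        "p_convention": config.p_convention,
        "stages": [],
        "digests": {},
    }
    current = "setup"
    try:
        # ---- simulate ---------------------------------------------------
        if config.simulate:
            current = "simulate"
            sim_seed = stage_seed(config.seed, "simulate")
            params = SimParams(seed=sim_seed, **config.sim_params)
            counts, sheet, truth = simulate_paired_counts(params)
            predicted, validated = simulate_target_tables(
                params.n_mirnas, n_genes=5000, seed=sim_seed + 1
            )
            pair = simulate_universe_pair(seed=sim_seed + 2)
            io.write_counts_tsv(counts, run_dir / "counts.tsv")
            io.write_sample_sheet(sheet, run_dir / "sample_sheet.csv")
            io.write_targets_tsv(predicted, run_dir / "predicted_targets.tsv")
            io.write_targets_tsv(validated, run_dir / "validated_targets.tsv")
            io.write_gmt({"set_b": set(pair.set_b)}, run_dir / "set_b.gmt")
            (run_dir / "universe_a.txt").write_text("\n".join(pair.universe_a) + "\n")
            (run_dir / "universe_b.txt").write_text("\n".join(pair.universe_b) + "\n")
            io.write_orthologs(pair.ortholog_map, run_dir / "orthologs.tsv")
            with open(run_dir / "sim_truth.json", "w") as fh:
                json.dump(
                    {
                        "de_ids": list(truth.de_ids),
                        "true_interaction_lfc": truth.true_interaction_lfc,
                        "true_size_factors": truth.true_size_factors,
                        "planted_overlap": pair.planted_overlap,
                    },
                    fh, indent=1,
                )
            manifest["stages"].append("simulate")
            universe_a, universe_b = list(pair.universe_a), list(pair.universe_b)
            omap = pair.ortholog_map
            set_b = set(pair.set_b)
        else:
            counts = io.read_counts_tsv(config.counts)
            sheet = io.read_sample_sheet(config.sample_sheet)
            predicted = io.read_targets_tsv(config.predicted_targets)
            validated = io.read_targets_tsv(config.validated_targets)
            universe_a = Path(config.universe_a).read_text().split()
            universe_b = Path(config.universe_b).read_text().split()
            omap = io.read_orthologs(config.orthologs)
            set_b = set.union(*io.read_gmt(config.set_b_gmt).values())
            manifest["stages"].append("load")

        # ---- differential expression ------------------------------------
        current = "de"
        de = run_de(counts, sheet, fdr_threshold=config.fdr)
        de.to_csv(run_dir / "de_results.tsv", sep="\t")
        manifest["stages"].append("de")

        # ---- candidate selection ----------------------------------------
        current = "select"
        cands = select_candidates(de, fdr=config.fdr, fold=config.fold, delta=config.delta)
        pd.DataFrame(
            [(m, "up") for m in sorted(cands.up)] + [(m, "down") for m in sorted(cands.down)],
            columns=["mirna_id", "direction"],
        ).to_csv(run_dir / "candidates.tsv", sep="\t", index=False)
        manifest["stages"].append("select")

        # ---- target filtering -------------------------------------------
        current = "targets"
        kept = filter_predicted(predicted)
        merged = merge_validated(kept, validated)
        io.write_targets_tsv(merged, run_dir / "targets_filtered.tsv")
        by_dir = targets_by_direction(cands, merged)
        io.write_gmt(
            {f"targets_{d}": genes for d, genes in by_dir.items() if genes},
            run_dir / "targets_by_direction.gmt",
        )
        manifest["stages"].append("targets")

        # ---- overlap test -----------------------------------------------
        current = "overlap"
        # species-A set: a seeded draw standing in for the cross-species
        # comparison set when the synthetic universes are in play
        rng = np.random.default_rng(stage_seed(config.seed, "overlap"))
        set_a = set(rng.choice(universe_a, size=min(100, len(universe_a)), replace=False))
        res = permutation_overlap_test(
            set_a, set_b, universe_a, universe_b, omap,
            n_perm=config.n_perm,
            seed=stage_seed(config.seed, "overlap"),
            p_convention=config.p_convention,
        )
        pd.DataFrame([{
            "observed_overlap": res.observed_overlap,
            "p_value": res.p_value,
            "n_perm": res.n_perm,
            "null_mean": res.null_mean,
            "null_sd": res.null_sd,
            "p_convention": res.p_convention,
        }]).to_csv(run_dir / "overlap.tsv", sep="\t", index=False)
        manifest["stages"].append("overlap")

        # ---- integration -------------------------------------------------
        current = "integrate"
        if config.gene_de is not None:
            gene_de = pd.read_csv(config.gene_de, sep="\t")
        else:
            # synthetic stand-in: random directions over the targeted genes
            rng = np.random.default_rng(stage_seed(config.seed, "integrate"))
            genes = sorted(set(merged["gene_id"]))
            gene_de = pd.DataFrame(
                {"gene": genes, "direction": rng.choice(["up", "down"], size=len(genes))}
            )
        edges = inverse_pair(cands, gene_de, merged)
        nodes, edge_table = assemble_network(edges)
        edge_table.to_csv(run_dir / "network_edges.tsv", sep="\t", index=False)
        nodes.to_csv(run_dir / "network_nodes.tsv", sep="\t", index=False)
        write_graphml(nodes, edge_table, run_dir / "network.graphml")
        manifest["stages"].append("integrate")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {current!r} failed: {exc}") from exc

    for p in sorted(run_dir.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["digests"][p.name] = _sha256(p)
    with open(run_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return run_dir
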