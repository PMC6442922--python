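#!/usr/bin/env python
"""Inverse-regulation pairing and regulatory-network export.

Pairs candidate miRNAs with target genes that moved in the opposite
direction in a matched gene-level comparison (miRNA binding represses
its target), then exports the de-duplicated node/edge tables as TSV and
GraphML.  The gene-level directions here are a synthetic stand-in drawn
over the filtered target genes, since the simulated dataset has no
companion mRNA study.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mirpair import assemble_network, inverse_pair, io
from mirpair.candidates import CandidateSets
from mirpair.network import write_graphml

SEED = 20_260_107
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"


def main() -> None:
    cand_df = pd.read_csv(OUT / "candidates.tsv", sep="\t")
    cands = CandidateSets(
        up=frozenset(cand_df.loc[cand_df["direction"] == "up", "mirna_id"]),
        down=frozenset(cand_df.loc[cand_df["direction"] == "down", "mirna_id"]),
    )
    merged = io.read_targets_tsv(OUT / "targets_filtered.tsv")

    # synthetic gene-level directions over the targeted genes
    rng = np.random.default_rng(SEED)
    genes = sorted(set(merged["gene_id"]))
    gene_de = pd.DataFrame(
        {"gene": genes, "direction": rng.choice(["up", "down"], size=len(genes))}
    )
    gene_de.to_csv(OUT / "gene_directions_synthetic.tsv", sep="\t", index=False)

    edges = inverse_pair(cands, gene_de, merged)
    nodes, edge_table = assemble_network(edges)
    edge_table.to_csv(OUT / "network_edges.tsv", sep="\t", index=False)
    nodes.to_csv(OUT / "network_nodes.tsv", sep="\t", index=False)
    write_graphml(nodes, edge_table, OUT / "network.graphml")

    n_mirna = (nodes["kind"] == "mirna").sum()
    print(f"{len(edge_table)} repression edges from {n_mirna} candidate miRNAs "
          f"to {len(nodes) - n_mirna} inversely regulated genes")
    print(f"wrote {OUT / 'network_edges.tsv'}, network_nodes.tsv, network.graphml")


if __name__ == "__main__":
    main()
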