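"""Assembly of a putative regulatory network from expression findings.

Pairs candidate miRNAs with inversely regulated genes through the target
map (a miRNA that rose should have fallen targets and vice versa, since
miRNA binding represses the target), then merges user-supplied
TF-miRNA / TF-gene layers into de-duplicated node and edge tables
exportable as TSV and GraphML.  The TF layer is data, not computation:
which regulators enter the network is a curation decision upstream of
this module.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .candidates import CandidateSets
from .errors import ValidationError

log = logging.getLogger(__name__)

__all__ = ["RegEdge", "inverse_pair", "assemble_network", "write_graphml", "read_graphml"]

EDGE_COLUMNS = ["source", "target", "source_kind", "interaction", "evidence",
                "direction_consistent"]


@dataclass(frozen=True)
class RegEdge:
    """One directed regulatory edge."""

    source: str
    target: str
    source_kind: str  # mirna | tf
    interaction: str  # represses | activates | regulates
    evidence: str     # predicted | validated | literature
    direction_consistent: bool = True


def inverse_pair(
    candidates: CandidateSets,
    gene_de: pd.DataFrame,
    target_set: pd.DataFrame,
) -> list[RegEdge]:
    """Emit a repression edge m -> g for every targeted, inversely regulated pair.

    ``gene_de`` carries columns ``gene`` and ``direction`` (up/down) from
    a matched gene-expression comparison; ``target_set`` is a filtered
    target table with ``mirna_id``/``gene_id``/``source`` columns.  An
    edge appears iff (m, g) is in the target table and the miRNA and gene
    moved in opposite directions.
    """
    if not set(gene_de["direction"]) <= {"up", "down"}:
        raise ValidationError("gene directions must be 'up' or 'down'")
    gene_dir = dict(zip(gene_de["gene"].astype(str).str.upper(), gene_de["direction"]))

    edges: list[RegEdge] = []
    n_unmatched = 0
    for row in target_set.itertuples(index=False):
        m, g = row.mirna_id, str(row.gene_id).upper()
        if m not in candidates.all_ids or g not in gene_dir:
            n_unmatched += 1
            continue
        if candidates.direction_of(m) != gene_dir[g]:
            evidence = "validated" if row.source in ("validated", "both") else "predicted"
            edges.append(RegEdge(source=m, target=g, source_kind="mirna",
                                 interaction="represses", evidence=evidence))
    if n_unmatched:
        log.info("%d target records had no matching candidate miRNA or DE gene", n_unmatched)
    return edges


def _edges_frame(edges) -> pd.DataFrame:
    if isinstance(edges, pd.DataFrame):
        df = edges.copy()
    else:
        df = pd.DataFrame([e.__dict__ for e in edges])
    if len(df) == 0:
        return pd.DataFrame(columns=EDGE_COLUMNS)
    missing = set(EDGE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"edge table missing columns: {sorted(missing)}")
    return df[EDGE_COLUMNS]


def assemble_network(
    mirna_gene_edges,
    tf_mirna_edges=None,
    tf_gene_edges=None,
    declared_nodes: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge edge layers into de-duplicated node and edge tables.

    Duplicate edges (same source, target, interaction) collapse to one
    with evidence strings concatenated by ``+``.  If ``declared_nodes``
    (columns ``node``, ``kind``) is given, every edge endpoint must be
    declared; dangling endpoints raise a validation error listing them.
    Returns ``(nodes, edges)``.
    """
    frames = [_edges_frame(e) for e in (mirna_gene_edges, tf_mirna_edges, tf_gene_edges)
              if e is not None]
    edges = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=EDGE_COLUMNS)

    if len(edges):
        edges = (
            edges.groupby(["source", "target", "interaction"], as_index=False)
            .agg(
                source_kind=("source_kind", "first"),
                evidence=("evidence", lambda s: "+".join(sorted(set(s)))),
                direction_consistent=("direction_consistent", "all"),
            )
        )[EDGE_COLUMNS]

    node_kind: dict[str, str] = {}
    for row in edges.itertuples(index=False):
        node_kind.setdefault(row.source, row.source_kind)
        node_kind.setdefault(row.target, "gene")
    if declared_nodes is not None:
        declared = set(declared_nodes["node"])
        dangling = sorted(set(node_kind) - declared)
        if dangling:
            raise ValidationError(f"edges reference undeclared nodes: {dangling}")
        node_kind = dict(zip(declared_nodes["node"], declared_nodes["kind"]))
    nodes = pd.DataFrame(
        sorted(node_kind.items()), columns=["node", "kind"]
    )
    return nodes, edges.sort_values(["source", "target"]).reset_index(drop=True)


def write_graphml(nodes: pd.DataFrame, edges: pd.DataFrame, path) -> None:
    """Export the network as GraphML."""
    g = nx.DiGraph()
    for row in nodes.itertuples(index=False):
        g.add_node(row.node, kind=row.kind)
    for row in edges.itertuples(index=False):
        g.add_edge(
            row.source,
            row.target,
            source_kind=row.source_kind,
            interaction=row.interaction,
            evidence=row.evidence,
            direction_consistent=bool(row.direction_consistent),
        )
    nx.write_graphml(g, path)


def read_graphml(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a GraphML network back into (nodes, edges) tables."""
    g = nx.read_graphml(path)
    nodes = pd.DataFrame(
        sorted((n, d.get("kind", "gene")) for n, d in g.nodes(data=True)),
        columns=["node", "kind"],
    )
    edges = pd.DataFrame(
        [
            {
                "source": u,
                "target": v,
                "source_kind": d.get("source_kind"),
                "interaction": d.get("interaction"),
                "evidence": d.get("evidence"),
                "direction_consistent": bool(d.get("direction_consistent", True)),
            }
            for u, v, d in g.edges(data=True)
        ],
        columns=EDGE_COLUMNS,
    )
    return nodes, edges.sort_values(["source", "target"]).reset_index(drop=True)
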