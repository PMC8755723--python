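"""Gene-sharing networks across genomes from all-vs-all alignment hits.

Genes of a genome set are compared all-vs-all (BLAST tabular input); each hit
is scored with the coverage-times-identity similarity
``alignment_length * identity / query_length`` (capped at 1), an undirected
edge joins two genes when either directed score reaches the threshold, and
connected components of the resulting graph are the gene families. Families
restricted to one or two genomes are the gene-loss / horizontal-transfer
candidates exported for downstream phylogenetic screening.

"identity" here is the fractional percent identity of the alignment — the
only reading under which the score is a coverage-weighted identity in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import pandas as pd

OUTFMT6_COLUMNS = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)

SIMILARITY_THRESHOLDS = (0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass(frozen=True)
class GeneHit:
    query_id: str
    subject_id: str
    identity: float            # fraction in [0, 1]
    alignment_length: int      # aa
    query_length: int          # aa
    e_value: float


def similarity(hit: GeneHit) -> float:
    """Coverage-x-identity similarity: alignment_length * identity / query_length,
    capped at 1."""
    if hit.query_length <= 0:
        raise ValueError("query_length must be positive")
    if not 0 <= hit.identity <= 1:
        raise ValueError("identity must be a fraction in [0, 1]")
    return min(1.0, hit.alignment_length * hit.identity / hit.query_length)


def read_outfmt6(path_or_df, query_lengths: Mapping[str, int] | pd.Series) -> list[GeneHit]:
    """Parse BLAST tabular (outfmt 6) hits; pident is a percent there."""
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df
    else:
        df = pd.read_csv(path_or_df, sep="\t", header=None,
                         names=list(OUTFMT6_COLUMNS))
    ql = pd.Series(dict(query_lengths))
    hits = []
    for row in df.itertuples():
        if row.qseqid not in ql.index:
            raise ValueError(f"no query length for gene {row.qseqid}")
        hits.append(GeneHit(
            query_id=str(row.qseqid), subject_id=str(row.sseqid),
            identity=float(row.pident) / 100.0,
            alignment_length=int(row.length),
            query_length=int(ql[row.qseqid]), e_value=float(row.evalue),
        ))
    return hits


def build_network(
    hits: list[GeneHit],
    threshold: float = 0.4,
    e_cutoff: float = 1e-5,
    mode: str = "max",
    genes: list[str] | None = None,
) -> nx.Graph:
    """Undirected gene-sharing graph at one similarity threshold.

    An edge joins q and s when the max (default) or min of the two directed
    similarities reaches ``threshold``; hits above ``e_cutoff`` and self-hits
    are ignored. ``genes`` may list additional genes to include as isolated
    nodes (so singleton families are reported).
    """
    if mode not in ("max", "min"):
        raise ValueError("mode must be 'max' or 'min'")
    graph = nx.Graph()
    if genes:
        graph.add_nodes_from(genes)
    directed: dict[tuple[str, str], float] = {}
    for h in hits:
        graph.add_node(h.query_id)
        graph.add_node(h.subject_id)
        if h.e_value > e_cutoff or h.query_id == h.subject_id:
            continue
        key = (h.query_id, h.subject_id)
        score = similarity(h)
        directed[key] = max(directed.get(key, 0.0), score)
    seen = set()
    for (q, s), sc in directed.items():
        pair = frozenset((q, s))
        if pair in seen:
            continue
        seen.add(pair)
        rev = directed.get((s, q))
        if mode == "max":
            combined = sc if rev is None else max(sc, rev)
        else:
            combined = min(sc, rev) if rev is not None else sc
        if combined >= threshold:
            graph.add_edge(q, s, similarity=combined)
    return graph


def gene_families(graph: nx.Graph) -> list[set[str]]:
    """Connected components, sorted for determinism (largest first)."""
    comps = [set(c) for c in nx.connected_components(graph)]
    return sorted(comps, key=lambda c: (-len(c), sorted(c)))


def rare_genes(
    families: list[set[str]],
    gene_to_genome: Mapping[str, str],
    max_genomes: int = 2,
) -> pd.DataFrame:
    """Families whose genes span at most ``max_genomes`` distinct genomes —
    gene-loss / horizontal-transfer candidates."""
    rows = []
    for fid, fam in enumerate(families):
        genomes = set()
        for gene in fam:
            if gene not in gene_to_genome:
                raise ValueError(f"gene {gene} has no genome mapping")
            genomes.add(gene_to_genome[gene])
        if len(genomes) <= max_genomes:
            rows.append({
                "family_id": fid,
                "n_genomes": len(genomes),
                "genomes": ",".join(sorted(genomes)),
                "genes": ",".join(sorted(fam)),
            })
    return pd.DataFrame(rows, columns=["family_id", "n_genomes", "genomes", "genes"])


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [{"gene_a": a, "gene_b": b, "similarity": d.get("similarity")}
            for a, b, d in sorted(graph.edges(data=True))]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity"]).to_csv(
        path, sep="\t", index=False)
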