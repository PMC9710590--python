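"""Disease-centric bipartite networks of top-scoring genes and functions.

For a chosen disease, the network connects its highest-|z| genes (default
15) and most-similar functions (default 20) by edges whose gene–function
z-score passes a threshold (default |z| > 3) *and* whose sign is consistent
with the signs of the adjacent gene and function nodes — a positive gene
and a negative function can only be joined by a negative-score edge. Node
signs record whether the gene/function is positively or anti-correlated
with the disease. Edges are annotated with provenance: "known" if the
gene–function association is present in the curated matrix Y, "inferred"
if it is purely predicted; genes carry a flag for known association with
the disease itself.

Function candidates are de-redundified: ontology ancestors of higher-ranked
retained functions are dropped (keeping specific terms over general ones),
and within each context bundle (functions sharing the same cell-type or
tissue context) only the top scorer survives.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .function_space import FunctionEmbeddings, ScoreMatrix
from .knowledge_model import AssociationMatrix, FunctionTerm, Ontology

logger = logging.getLogger(__name__)

DEFAULT_N_GENES = 15
DEFAULT_N_FUNCTIONS = 20
DEFAULT_Z_CUT = 3.0


@dataclass
class DiseaseNetwork:
    disease: str
    gene_nodes: list[tuple[str, int, bool]]       # (id, sign, known_assoc)
    function_nodes: list[tuple[str, int]]         # (id, sign)
    edges: list[tuple[str, str, float, str]]      # (gene, function, z, prov)
    z_cut: float = DEFAULT_Z_CUT

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for gene, sign, known in self.gene_nodes:
            g.add_node(f"gene:{gene}", kind="gene", sign=sign, known=known)
        for func, sign in self.function_nodes:
            g.add_node(f"func:{func}", kind="function", sign=sign)
        for gene, func, z, prov in self.edges:
            g.add_edge(f"gene:{gene}", f"func:{func}", z=z, provenance=prov)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)

    def to_json(self) -> str:
        return json.dumps({
            "disease": self.disease,
            "z_cut": self.z_cut,
            "genes": [{"id": g, "sign": s, "known": k}
                      for g, s, k in self.gene_nodes],
            "functions": [{"id": f, "sign": s}
                          for f, s in self.function_nodes],
            "edges": [{"gene": g, "function": f, "z": z, "provenance": p}
                      for g, f, z, p in self.edges],
        }, indent=2)


def top_disease_genes(
    disease: str, S: ScoreMatrix, n_genes: int = DEFAULT_N_GENES
) -> list[tuple[str, int]]:
    """Genes ranked by |z| against the disease, with their score signs.
    Ties broken lexicographically by gene id."""
    if S.zscores is None:
        raise ValueError("score matrix has no z-scores; run score_zscores")
    j = S.functions.index(disease)
    z = S.zscores[:, j]
    order = sorted(range(len(S.genes)), key=lambda i: (-abs(z[i]), S.genes[i]))
    return [(S.genes[i], 1 if z[i] > 0 else -1) for i in order[:n_genes]]


def top_disease_functions(
    disease: str,
    F: FunctionEmbeddings,
    terms: dict[str, FunctionTerm],
    ont: Ontology,
    n_functions: int = DEFAULT_N_FUNCTIONS,
) -> list[tuple[str, int]]:
    """Functions ranked by |cosine similarity| to the disease vector, after
    redundancy pruning.

    The disease itself and its ontology ancestors are excluded. Scanning in
    descending |similarity|: a candidate is skipped if it is an ontology
    ancestor of an already retained function (prefer specific terms), or if
    its context bundle already has a retained member.
    """
    d_vec = F.vector(disease)
    sims = F.P_norm @ d_vec
    excluded = {disease} | ont.ancestors(disease)
    candidates = [
        (f, float(sims[i])) for i, f in enumerate(F.functions)
        if f not in excluded and not F.degenerate[i]
    ]
    candidates.sort(key=lambda t: (-abs(t[1]), t[0]))

    retained: list[tuple[str, int]] = []
    retained_ids: set[str] = set()
    used_contexts: set[str] = set()
    for f, sim in candidates:
        if len(retained) >= n_functions:
            break
        if ont.descendants(f) & retained_ids:
            continue  # f is an ancestor of a retained, more specific term
        ctx = terms.get(f, FunctionTerm(f)).context
        if ctx is not None:
            if ctx in used_contexts:
                continue
            used_contexts.add(ctx)
        retained.append((f, 1 if sim > 0 else -1))
        retained_ids.add(f)
    return retained


def build_network(
    disease: str,
    genes: list[tuple[str, int]],
    functions: list[tuple[str, int]],
    S: ScoreMatrix,
    Y: AssociationMatrix,
    z_cut: float = DEFAULT_Z_CUT,
) -> DiseaseNetwork:
    """Assemble the bipartite network.

    Edge (i, j) is included iff |z_ij| > z_cut and
    sign(z_ij) = sign(gene i) * sign(function j). Provenance is "known" when
    Y_ij != 0, "inferred" otherwise. Gene nodes are flagged when they have a
    known (curated) association with the disease column of Y.
    """
    if S.zscores is None:
        raise ValueError("score matrix has no z-scores; run score_zscores")
    disease_col = (Y.column(disease) if disease in Y.functions
                   else np.zeros(len(Y.genes), dtype=int))
    gene_nodes = [
        (g, s, bool(disease_col[Y.gene_index(g)] != 0)) for g, s in genes
    ]
    edges = []
    for g, gs, _known in gene_nodes:
        i = S.genes.index(g)
        for f, fs in functions:
            j = S.functions.index(f)
            z = float(S.zscores[i, j])
            if abs(z) > z_cut and np.sign(z) == gs * fs:
                yij = Y.matrix[Y.gene_index(g), Y.function_index(f)] \
                    if f in Y.functions else 0
                prov = "known" if yij != 0 else "inferred"
                edges.append((g, f, z, prov))
    return DiseaseNetwork(
        disease=disease,
        gene_nodes=gene_nodes,
        function_nodes=list(functions),
        edges=sorted(edges),
        z_cut=z_cut,
    )
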