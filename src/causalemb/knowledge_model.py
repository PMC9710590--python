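"""Domain model for signed causal knowledge graphs.

The central objects are a signed bipartite *expression* graph (regulators —
genes or drugs — connected to expression-regulated target genes by +1/-1
edges), a signed gene–function association matrix, and a function ontology
whose parents inherit the causal gene associations of their descendants.

Edge signs encode the consensus direction of effect curated from the
literature: +1 for activation (the regulator increases the target or
function), -1 for inhibition. The absence of an edge encodes "no known
effect" (0); a stored edge never carries sign 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from graphlib import CycleError, TopologicalSorter
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import sparse

logger = logging.getLogger(__name__)

VALID_SIGNS = (-1, 1)


@dataclass(frozen=True)
class Entity:
    """A regulator node of the expression graph: a gene or a drug."""

    id: str
    kind: str = "gene"  # "gene" or "drug"
    name: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("gene", "drug"):
            raise ValueError(f"unknown entity kind {self.kind!r}")


@dataclass(frozen=True)
class SignedEdge:
    """A signed causal relationship source -> target, sign in {-1, +1}."""

    source: str
    target: str
    sign: int

    def __post_init__(self) -> None:
        if self.sign not in VALID_SIGNS:
            raise ValueError(f"edge sign must be -1 or +1, got {self.sign}")


@dataclass(frozen=True)
class FunctionTerm:
    """A biological function or disease term.

    Many terms have the compositional form "<process> of <context>"
    (e.g. "Proliferation of T lymphocytes"); for those both ``process``
    and ``context`` are set.
    """

    id: str
    name: str = ""
    process: str | None = None
    context: str | None = None
    category: str | None = None
    is_disease: bool = False

    def __post_init__(self) -> None:
        if (self.process is None) != (self.context is None):
            raise ValueError(
                f"function {self.id}: process and context must both be "
                "present or both absent"
            )


class Ontology:
    """A DAG of function terms given by (child, parent) edges.

    Parents inherit causal gene associations (and their signs) from their
    descendants; see :func:`propagate_ontology`.
    """

    def __init__(self, parent_edges: Iterable[tuple[str, str]] = ()):
        self.parent_edges: set[tuple[str, str]] = set(parent_edges)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        ts = TopologicalSorter()
        for child, parent in self.parent_edges:
            ts.add(parent, child)  # parent depends on child
        try:
            ts.prepare()
        except CycleError as exc:
            raise ValueError(f"ontology contains a cycle: {exc.args}") from exc

    def parents(self, term: str) -> set[str]:
        return {p for c, p in self.parent_edges if c == term}

    def children(self, term: str) -> set[str]:
        return {c for c, p in self.parent_edges if p == term}

    def ancestors(self, term: str) -> set[str]:
        out: set[str] = set()
        frontier = self.parents(term)
        while frontier:
            out |= frontier
            frontier = set().union(*(self.parents(t) for t in frontier)) - out
        return out

    def descendants(self, term: str) -> set[str]:
        out: set[str] = set()
        frontier = self.children(term)
        while frontier:
            out |= frontier
            frontier = set().union(*(self.children(t) for t in frontier)) - out
        return out

    def leaves(self, terms: Iterable[str]) -> list[str]:
        """Terms from ``terms`` that have no children in the ontology."""
        parents_with_children = {p for _, p in self.parent_edges}
        return [t for t in terms if t not in parents_with_children]

    def topological_order(self) -> list[str]:
        """Children before parents."""
        ts = TopologicalSorter()
        nodes = {t for e in self.parent_edges for t in e}
        for n in nodes:
            ts.add(n)
        for child, parent in self.parent_edges:
            ts.add(parent, child)
        return list(ts.static_order())


class CausalGraph:
    """Signed bipartite expression graph G.

    Regulators (rows) are connected to expression-regulated target genes
    (columns) by signed edges. ``sign_matrix`` is the sparse N x M matrix of
    edge signs s_ij in {-1, 0, +1}; N_i = sum_j |s_ij| is the number of
    targets regulated by regulator i. Regulators and targets may overlap as
    gene ids but occupy distinct index spaces.
    """

    def __init__(
        self,
        regulators: Sequence[str],
        targets: Sequence[str],
        edges: Iterable[SignedEdge],
        entities: Mapping[str, Entity] | None = None,
    ):
        self.regulators = list(regulators)
        self.targets = list(targets)
        self.edges: list[SignedEdge] = sorted(
            edges, key=lambda e: (e.source, e.target)
        )
        self.entities = dict(entities) if entities else {
            r: Entity(r) for r in self.regulators
        }
        self._reg_index = {r: i for i, r in enumerate(self.regulators)}
        self._tgt_index = {t: j for j, t in enumerate(self.targets)}
        if len(self._reg_index) != len(self.regulators):
            raise ValueError("duplicate regulator ids")
        if len(self._tgt_index) != len(self.targets):
            raise ValueError("duplicate target ids")
        for e in self.edges:
            if e.source not in self._reg_index:
                raise ValueError(f"edge source {e.source!r} not a regulator")
            if e.target not in self._tgt_index:
                raise ValueError(f"edge target {e.target!r} not a target")
        seen = set()
        for e in self.edges:
            key = (e.source, e.target)
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)

    @property
    def n_regulators(self) -> int:
        return len(self.regulators)

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def sign_matrix(self) -> sparse.csr_matrix:
        """Sparse N x M matrix of edge signs s_ij."""
        if not self.edges:
            return sparse.csr_matrix(
                (self.n_regulators, self.n_targets), dtype=np.int8
            )
        rows = [self._reg_index[e.source] for e in self.edges]
        cols = [self._tgt_index[e.target] for e in self.edges]
        data = [e.sign for e in self.edges]
        return sparse.csr_matrix(
            (data, (rows, cols)),
            shape=(self.n_regulators, self.n_targets),
            dtype=np.int8,
        )

    def out_degrees(self) -> np.ndarray:
        """N_i = sum_j |s_ij| per regulator."""
        return np.asarray(
            abs(self.sign_matrix()).sum(axis=1)
        ).ravel().astype(int)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for r in self.regulators:
            ent = self.entities.get(r, Entity(r))
            g.add_node(f"reg:{r}", side="regulator", kind=ent.kind)
        for t in self.targets:
            g.add_node(f"tgt:{t}", side="target")
        for e in self.edges:
            g.add_edge(f"reg:{e.source}", f"tgt:{e.target}", sign=e.sign)
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


@dataclass
class AssociationMatrix:
    """Signed gene–function matrix Y with Y_ij in {-1, 0, +1}.

    Y_ij is the curated causal effect of gene i on function j: +1 activation,
    -1 inhibition, 0 no known effect. Stored sparse, genes as rows.
    """

    genes: list[str]
    functions: list[str]
    matrix: sparse.csr_matrix  # N x J, dtype int8
    terms: dict[str, FunctionTerm] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.matrix = sparse.csr_matrix(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.genes), len(self.functions)):
            raise ValueError("matrix shape does not match gene/function lists")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._func_index = {f: j for j, f in enumerate(self.functions)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_functions(self) -> int:
        return len(self.functions)

    def column(self, function_id: str) -> np.ndarray:
        j = self._func_index[function_id]
        return np.asarray(self.matrix[:, j].todense()).ravel()

    def gene_index(self, gene_id: str) -> int:
        return self._gene_index[gene_id]

    def function_index(self, function_id: str) -> int:
        return self._func_index[function_id]

    def copy(self) -> "AssociationMatrix":
        return AssociationMatrix(
            list(self.genes), list(self.functions), self.matrix.copy(),
            dict(self.terms),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _parse_sign(value, where: str) -> int:
    try:
        s = int(value)
    except (TypeError, ValueError):
        raise ValueError(f"malformed sign {value!r} at {where}") from None
    if s not in VALID_SIGNS:
        raise ValueError(f"sign must be -1 or +1 at {where}, got {s}")
    return s


def load_expression_edges(path, min_targets: int = 0,
                          kinds: Mapping[str, str] | None = None) -> CausalGraph:
    """Read a signed expression edge list (TSV: source, target, sign).

    Duplicate (source, target) rows with conflicting signs are dropped with a
    logged warning (the stored sign is a literature consensus; without
    per-finding counts no consensus can be formed, so the conservative choice
    is "no edge"). Regulators left with fewer than ``max(1, min_targets)``
    targets are removed. Orderings are lexicographic so the derived matrices
    are reproducible.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        raise ValueError(f"empty edge file: {path}")
    required = {"source", "target", "sign"}
    if not required.issubset(df.columns):
        raise ValueError(f"edge file must have columns {sorted(required)}")

    signs: dict[tuple[str, str], int] = {}
    conflicted: set[tuple[str, str]] = set()
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        s = _parse_sign(row.sign, f"{path}:{line_no}")
        key = (str(row.source), str(row.target))
        if key in signs and signs[key] != s:
            conflicted.add(key)
        signs.setdefault(key, s)
    for key in conflicted:
        del signs[key]
        logger.warning("conflicting signs for edge %s -> %s; edge dropped",
                       key[0], key[1])

    edges = [SignedEdge(src, tgt, sg) for (src, tgt), sg in signs.items()]
    threshold = max(1, min_targets)
    counts: dict[str, int] = {}
    for e in edges:
        counts[e.source] = counts.get(e.source, 0) + 1
    kept = {r for r, c in counts.items() if c >= threshold}
    dropped = set(counts) - kept
    if dropped:
        logger.info("dropped %d regulators with fewer than %d targets",
                    len(dropped), threshold)
    edges = [e for e in edges if e.source in kept]
    regulators = sorted(kept)
    targets = sorted({e.target for e in edges})
    entities = {
        r: Entity(r, kind=(kinds or {}).get(r, "gene")) for r in regulators
    }
    return CausalGraph(regulators, targets, edges, entities)


def write_expression_edges(graph: CausalGraph, path) -> None:
    """Write the graph's edge set as the TSV dialect read by
    :func:`load_expression_edges` (round-trips exactly)."""
    df = pd.DataFrame(
        [(e.source, e.target, e.sign) for e in graph.edges],
        columns=["source", "target", "sign"],
    )
    df.to_csv(path, sep="\t", index=False)


def load_function_associations(
    path, genes: Sequence[str],
    terms: Mapping[str, FunctionTerm] | None = None,
) -> AssociationMatrix:
    """Read signed gene–function associations (TSV: gene, function, sign),
    restricted to the supplied gene list. Unknown genes are dropped with a
    logged count."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    gene_list = sorted(genes)
    gene_index = {g: i for i, g in enumerate(gene_list)}
    if df.empty:
        return AssociationMatrix(gene_list, [], sparse.csr_matrix(
            (len(gene_list), 0), dtype=np.int8))
    required = {"gene", "function", "sign"}
    if not required.issubset(df.columns):
        raise ValueError(f"association file must have columns {sorted(required)}")

    functions = sorted(df["function"].astype(str).unique())
    func_index = {f: j for j, f in enumerate(functions)}
    rows, cols, data = [], [], []
    n_dropped = 0
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        s = _parse_sign(row.sign, f"{path}:{line_no}")
        g = str(row.gene)
        if g not in gene_index:
            n_dropped += 1
            continue
        rows.append(gene_index[g])
        cols.append(func_index[str(row.function)])
        data.append(s)
    if n_dropped:
        logger.info("dropped %d associations with unknown genes", n_dropped)
    mat = sparse.csr_matrix(
        (data, (rows, cols)), shape=(len(gene_list), len(functions)),
        dtype=np.int8,
    )
    term_map = {f: (terms or {}).get(f, FunctionTerm(f)) for f in functions}
    return AssociationMatrix(gene_list, functions, mat, term_map)


def write_function_associations(Y: AssociationMatrix, path) -> None:
    coo = Y.matrix.tocoo()
    df = pd.DataFrame({
        "gene": [Y.genes[i] for i in coo.row],
        "function": [Y.functions[j] for j in coo.col],
        "sign": coo.data.astype(int),
    }).sort_values(["gene", "function"])
    df.to_csv(path, sep="\t", index=False)


def load_ontology(path) -> Ontology:
    """Read a function hierarchy as a two-column TSV (child, parent)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"child", "parent"}.issubset(df.columns):
        raise ValueError("ontology file must have columns child, parent")
    return Ontology((str(r.child), str(r.parent))
                    for r in df.itertuples(index=False))


def load_function_metadata(path) -> dict[str, FunctionTerm]:
    """Read function/disease metadata (TSV: id, name, process, context,
    category, is_disease)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out = {}
    for row in df.itertuples(index=False):
        def opt(v):
            return None if pd.isna(v) or v == "" else str(v)
        out[str(row.id)] = FunctionTerm(
            id=str(row.id),
            name=opt(getattr(row, "name", None)) or "",
            process=opt(getattr(row, "process", None)),
            context=opt(getattr(row, "context", None)),
            category=opt(getattr(row, "category", None)),
            is_disease=str(getattr(row, "is_disease", "False")).lower()
            in ("1", "true", "yes"),
        )
    return out


# ---------------------------------------------------------------------------
# Ontology propagation
# ---------------------------------------------------------------------------

def propagate_ontology(
    Y: AssociationMatrix, ont: Ontology,
    excluded_roots: set[str] | frozenset[str] = frozenset(),
) -> AssociationMatrix:
    """Propagate gene associations up the function hierarchy.

    Each parent term (unless listed in ``excluded_roots`` — very general
    terms that should not inherit) receives, for every gene without a direct
    curated entry, the consensus sign over its descendants' entries. If the
    descendants disagree in sign the parent entry stays 0: without
    per-finding counts a majority cannot be established, so disagreement
    conservatively encodes "no consistent effect". Direct curated entries of
    the parent are kept as they are (they already encode a literature
    consensus), which also makes the operation idempotent. Leaves are
    unchanged.
    """
    dense = np.asarray(Y.matrix.todense(), dtype=np.int8)
    func_index = {f: j for j, f in enumerate(Y.functions)}
    order = [t for t in ont.topological_order() if t in func_index]
    out = dense.copy().astype(np.int16)
    for term in order:  # children first, so grandparents see merged values
        if term in excluded_roots:
            continue
        kids = [func_index[c] for c in ont.children(term) if c in func_index]
        if not kids:
            continue
        j = func_index[term]
        stack = out[:, kids]
        has_pos = (stack > 0).any(axis=1)
        has_neg = (stack < 0).any(axis=1)
        inherited = np.where(has_pos & ~has_neg, 1,
                             np.where(has_neg & ~has_pos, -1, 0))
        out[:, j] = np.where(out[:, j] != 0, out[:, j], inherited)
    return AssociationMatrix(
        list(Y.genes), list(Y.functions),
        sparse.csr_matrix(out.astype(np.int8)), dict(Y.terms),
    )
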