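"""Gene Ontology handling: OBO parsing, annotation propagation, IC.

Only ``is_a`` and ``part_of`` edges are used (the CAFA convention).
Information content is computed in bits from annotation frequencies in a
training set; the conditional IC used by the Smin metric shares the same
log base (configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx

NAMESPACES = {
    "molecular_function": "MF",
    "biological_process": "BP",
    "cellular_component": "CC",
}

_KEPT_RELATIONS = {"is_a", "part_of"}


@dataclass
class GoDag:
    """Directed acyclic ontology; edges point child -> parent."""

    graph: nx.DiGraph  # nodes carry 'namespace' and 'name'

    @property
    def terms(self) -> set[str]:
        return set(self.graph.nodes)

    def namespace(self, term: str) -> str:
        return self.graph.nodes[term]["namespace"]

    def parents(self, term: str) -> set[str]:
        return set(self.graph.successors(term))

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable via child->parent edges, excluding `term`."""
        return nx.descendants(self.graph, term)

    def roots(self) -> dict[str, str]:
        """Namespace -> root term (no outgoing parent edges)."""
        out: dict[str, str] = {}
        for node in self.graph.nodes:
            if self.graph.out_degree(node) == 0:
                out[self.namespace(node)] = node
        return out

    def terms_in_namespace(self, namespace: str) -> set[str]:
        return {t for t in self.graph.nodes if self.namespace(t) == namespace}


@dataclass(frozen=True)
class TermIndex:
    """Ordered term vocabulary defining label-vector positions."""

    namespace: str
    terms: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("duplicate terms in index")

    def __len__(self) -> int:
        return len(self.terms)

    def position(self, term: str) -> int:
        return self.terms.index(term)

    @classmethod
    def from_terms(cls, namespace: str, terms) -> "TermIndex":
        return cls(namespace=namespace, terms=tuple(sorted(terms)))


@dataclass
class IcTable:
    """Per-term marginal probability, marginal IC and conditional IC (bits)."""

    probability: dict[str, float] = field(default_factory=dict)
    ic: dict[str, float] = field(default_factory=dict)
    conditional_ic: dict[str, float] = field(default_factory=dict)
    count: dict[str, int] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.ic

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("term\tcount\tP\tIC_bits\tcondIC_bits\n")
            for term in sorted(self.ic):
                fh.write(f"{term}\t{self.count[term]}\t{self.probability[term]:.10g}"
                         f"\t{self.ic[term]:.10g}\t{self.conditional_ic[term]:.10g}\n")

    @classmethod
    def read_tsv(cls, path) -> "IcTable":
        table = cls()
        with open(path) as fh:
            next(fh)
            for line in fh:
                term, count, p, ic, cic = line.rstrip("\n").split("\t")
                table.count[term] = int(count)
                table.probability[term] = float(p)
                table.ic[term] = float(ic)
                table.conditional_ic[term] = float(cic)
        return table


def parse_obo(path) -> GoDag:
    """Parse an OBO file into a GoDag, dropping obsolete terms.

    Raises on cycles, naming one offending cycle.
    """
    graph = nx.DiGraph()
    edges: list[tuple[str, str]] = []
    stanza: dict | None = None

    def flush(st):
        if st is None or st.get("obsolete") or "id" not in st:
            return
        graph.add_node(st["id"],
                       name=st.get("name", ""),
                       namespace=NAMESPACES.get(st.get("namespace", ""),
                                                st.get("namespace", "")))
        for parent in st.get("parents", []):
            edges.append((st["id"], parent))

    in_term = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if line == "[Term]":
                flush(stanza)
                stanza, in_term = {"parents": []}, True
                continue
            if line.startswith("[") and line.endswith("]"):
                flush(stanza)
                stanza, in_term = None, False
                continue
            if not in_term or stanza is None or ":" not in line:
                continue
            key, _, value = line.partition(":")
            value = value.strip()
            if key == "id":
                stanza["id"] = value
            elif key == "name":
                stanza["name"] = value
            elif key == "namespace":
                stanza["namespace"] = value
            elif key == "is_obsolete" and value.startswith("true"):
                stanza["obsolete"] = True
            elif key == "is_a":
                stanza["parents"].append(value.split("!")[0].strip())
            elif key == "relationship":
                parts = value.split("!")[0].split()
                if len(parts) == 2 and parts[0] in _KEPT_RELATIONS:
                    stanza["parents"].append(parts[1])
    flush(stanza)

    for child, parent in edges:
        if parent in graph:  # parent may be obsolete/foreign
            graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise ValueError(f"ontology contains a cycle: {cycle}")
    return GoDag(graph)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

AnnotationSet = dict[str, set[str]]


def read_annotations(path) -> AnnotationSet:
    """TSV with lines `protein_id<TAB>GO:NNNNNNN`."""
    annotations: AnnotationSet = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            protein, term = line.split("\t")[:2]
            annotations.setdefault(protein, set()).add(term)
    return annotations


def write_annotations(annotations: AnnotationSet, path) -> None:
    with open(path, "w") as fh:
        for protein in sorted(annotations):
            for term in sorted(annotations[protein]):
                fh.write(f"{protein}\t{term}\n")


def propagate(annotations: AnnotationSet, dag: GoDag) -> AnnotationSet:
    """Close each protein's term set under the ancestor relation."""
    unknown = {t for terms in annotations.values() for t in terms} - dag.terms
    if unknown:
        raise ValueError(f"unknown terms in annotations: {sorted(unknown)}")
    ancestor_cache: dict[str, set[str]] = {}
    out: AnnotationSet = {}
    for protein, terms in annotations.items():
        closed = set(terms)
        for term in terms:
            if term not in ancestor_cache:
                ancestor_cache[term] = dag.ancestors(term)
            closed |= ancestor_cache[term]
        out[protein] = closed
    return out


def compute_ic(annotations: AnnotationSet, dag: GoDag,
               log_base: float = 2.0) -> IcTable:
    """IC table from propagated training annotations over n proteins.

    P(term) = count/n; IC = -log_b P. The conditional IC divides a term's
    count by the number of proteins co-annotated with *all* of its parents
    (roots fall back to their marginal IC); terms whose parent count is
    zero are excluded.
    """
    n = len(annotations)
    if n < 1:
        raise ValueError("need at least one annotated protein")
    counts: dict[str, int] = {}
    for terms in annotations.values():
        for t in terms:
            counts[t] = counts.get(t, 0) + 1

    table = IcTable()
    log = lambda x: math.log(x, log_base)
    for term, count in counts.items():
        p = count / n
        table.count[term] = count
        table.probability[term] = p
        table.ic[term] = -log(p)
        parents = dag.parents(term) if term in dag.terms else set()
        parents = {p_ for p_ in parents if p_ in counts}
        if not parents:
            table.conditional_ic[term] = table.ic[term]
            continue
        parent_count = sum(1 for terms in annotations.values()
                           if parents <= terms)
        if parent_count == 0:
            # unreachable after propagation, kept as a guard
            continue
        table.conditional_ic[term] = -log(count / parent_count)
    return table


def ic_category(ic: float) -> str:
    """Bucket an IC value; boundaries 5 and 10 go to the lower bucket."""
    if ic < 0:
        raise ValueError(f"IC must be non-negative, got {ic}")
    if ic <= 5:
        return "IC<5"
    if ic <= 10:
        return "5<IC<10"
    return "IC>10"


def label_matrix(annotations: AnnotationSet, index: TermIndex,
                 protein_ids: list[str]):
    """Binary n x C label matrix for the given proteins and term order."""
    import numpy as np

    positions = {t: i for i, t in enumerate(index.terms)}
    Y = np.zeros((len(protein_ids), len(index)))
    for row, pid in enumerate(protein_ids):
        for term in annotations.get(pid, ()):  # terms outside index ignored
            col = positions.get(term)
            if col is not None:
                Y[row, col] = 1.0
    return Y


def evaluation_vocabulary(annotations: AnnotationSet, dag: GoDag,
                          namespace: str) -> TermIndex:
    """Terms with >= 1 positive training protein in the namespace."""
    seen: set[str] = set()
    ns_terms = dag.terms_in_namespace(namespace)
    for terms in annotations.values():
        seen |= terms & ns_terms
    return TermIndex.from_terms(namespace, seen)
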