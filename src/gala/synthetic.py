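"""Deterministic two-domain synthetic benchmark.

Generates contact-map protein graphs in two domains whose length,
long-range contact density and residue composition distributions differ
(a controlled covariate shift), a small GO-like DAG, and labels planted
through 3-mer sequence motifs: a leaf term is active iff its motif occurs
in the sequence, and annotations are closed upward. Coordinates lie on a
perturbed helix so structure-based code paths (contact maps, PDB
round-trips) can be exercised on synthetic proteins too.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .graph_build import ProteinGraph, build_features
from .ontology import AnnotationSet, GoDag, TermIndex, propagate

#: letters available to synthetic sequences (standard amino acids)
RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticSpec:
    seed: int = 17
    n_mid_terms: int = 4
    n_leaf_terms: int = 10
    source_length: tuple[int, int] = (40, 80)
    target_length: tuple[int, int] = (80, 150)
    p_contact_source: float = 0.05
    p_contact_target: float = 0.15
    motif_length: int = 3
    label_noise: float = 0.0
    #: letters motifs are drawn from; frequent in both domains so planted
    #: labels occur on either side of the shift
    motif_letters: str = "ACDEFG"
    #: composition weights (motif letters vs the rest, per domain); the
    #: gap between domains controls how strong the composition shift is
    source_motif_weight: float = 12.0
    target_motif_weight: float = 9.0
    source_other_weight: float = 1.0
    target_other_weight: float = 2.0

    def lengths(self, domain: str) -> tuple[int, int]:
        return self.source_length if domain == "source" else self.target_length

    def contact_probability(self, domain: str) -> float:
        return (self.p_contact_source if domain == "source"
                else self.p_contact_target)

    def composition(self, domain: str) -> np.ndarray:
        """Residue sampling probabilities for one domain."""
        source = domain == "source"
        motif_w = self.source_motif_weight if source else self.target_motif_weight
        other_w = self.source_other_weight if source else self.target_other_weight
        weights = np.array([motif_w if aa in self.motif_letters else other_w
                            for aa in RESIDUES])
        return weights / weights.sum()


ROOT_TERM = "GO:1000000"


def make_go_dag(spec: SyntheticSpec) -> tuple[GoDag, TermIndex]:
    """Toy rooted DAG: 1 root, mid-level terms, leaves (some diamonds)."""
    graph = nx.DiGraph()
    graph.add_node(ROOT_TERM, namespace="MF", name="root")
    mids = [f"GO:100000{i + 1}" for i in range(spec.n_mid_terms)]
    for mid in mids:
        graph.add_node(mid, namespace="MF", name="mid")
        graph.add_edge(mid, ROOT_TERM)
    leaves = [f"GO:10000{10 + i}" for i in range(spec.n_leaf_terms)]
    for i, leaf in enumerate(leaves):
        graph.add_node(leaf, namespace="MF", name="leaf")
        graph.add_edge(leaf, mids[i % len(mids)])
        if i % 2 == 0:  # diamond: every other leaf gets a second parent
            graph.add_edge(leaf, mids[(i + 1) % len(mids)])
    dag = GoDag(graph)
    index = TermIndex.from_terms("MF", dag.terms)
    return dag, index


def motif_table(spec: SyntheticSpec) -> dict[str, str]:
    """Leaf term -> planted 3-mer motif (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed + 1)
    leaves = [f"GO:10000{10 + i}" for i in range(spec.n_leaf_terms)]
    motifs: dict[str, str] = {}
    used: set[str] = set()
    for leaf in leaves:
        while True:
            motif = "".join(rng.choice(list(spec.motif_letters),
                                       size=spec.motif_length))
            if motif not in used:
                used.add(motif)
                motifs[leaf] = motif
                break
    return motifs


def helix_coords(n: int, rng: np.random.Generator) -> np.ndarray:
    """Cα positions on an ideal alpha-helix plus small Gaussian noise."""
    i = np.arange(n)
    theta = np.deg2rad(100.0) * i
    coords = np.stack([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * i],
                      axis=1)
    return coords + rng.normal(scale=0.15, size=(n, 3))


def _sample_graph(pid: str, spec: SyntheticSpec, domain: str,
                  rng: np.random.Generator) -> ProteinGraph:
    lo, hi = spec.lengths(domain)
    n = int(rng.integers(lo, hi + 1))
    seq = "".join(rng.choice(list(RESIDUES), size=n,
                             p=spec.composition(domain)))
    adj = np.zeros((n, n), dtype=np.int8)
    idx = np.arange(n - 1)
    adj[idx, idx + 1] = adj[idx + 1, idx] = 1  # backbone chain
    p = spec.contact_probability(domain)
    upper = np.triu(rng.random((n, n)) < p, k=2)
    adj = np.maximum(adj, (upper | upper.T).astype(np.int8))
    return ProteinGraph(id=pid, sequence=seq, adjacency=adj,
                        features=build_features(seq),
                        coords=helix_coords(n, rng))


def _labels_for(sequence: str, motifs: dict[str, str],
                noise: float, rng: np.random.Generator) -> set[str]:
    active = {leaf for leaf, motif in motifs.items() if motif in sequence}
    if noise > 0:
        flipped = set()
        for leaf in motifs:
            present = leaf in active
            if rng.random() < noise:
                present = not present
            if present:
                flipped.add(leaf)
        active = flipped
    return active


def make_domain(spec: SyntheticSpec, domain: str, n_proteins: int,
                seed_offset: int = 0, require_labeled: bool = False,
                max_retries: int = 200
                ) -> tuple[list[ProteinGraph], AnnotationSet]:
    """Generate one domain; annotations are propagated to ancestors.

    With ``require_labeled`` each protein is resampled (bounded retries)
    until at least one leaf motif occurs, for labeled splits.
    """
    if domain not in ("source", "target"):
        raise ValueError(f"unknown domain {domain!r}")
    dag, _ = make_go_dag(spec)
    motifs = motif_table(spec)
    domain_code = {"source": 0, "target": 1}[domain]
    rng = np.random.default_rng((spec.seed, domain_code, seed_offset))
    graphs: list[ProteinGraph] = []
    annotations: AnnotationSet = {}
    for i in range(n_proteins):
        pid = f"{domain[0].upper()}{seed_offset}_{i:05d}"
        for _ in range(max_retries):
            graph = _sample_graph(pid, spec, domain, rng)
            leaves = _labels_for(graph.sequence, motifs, spec.label_noise, rng)
            if leaves or not require_labeled:
                break
        else:
            raise RuntimeError(f"could not sample a labeled protein ({pid})")
        graphs.append(graph)
        if leaves:
            annotations[pid] = leaves
    return graphs, propagate(annotations, dag)


def make_fixture() -> dict:
    """Tiny frozen instance: 8 graphs (4 per domain), 15-term DAG, seed 17.

    Regeneration is byte-identical; used by gradient and oracle tests.
    """
    spec = SyntheticSpec(seed=17)
    dag, index = make_go_dag(spec)
    source, source_ann = make_domain(spec, "source", 4, require_labeled=True)
    target, target_ann = make_domain(spec, "target", 4, require_labeled=True)
    return {
        "spec": spec,
        "dag": dag,
        "index": index,
        "motifs": motif_table(spec),
        "source_graphs": source,
        "source_annotations": source_ann,
        "target_graphs": target,
        "target_annotations": target_ann,
    }


def fixture_checksum(fixture: dict) -> str:
    """Stable digest of everything the fixture generates."""
    import hashlib

    h = hashlib.sha256()
    for graph in fixture["source_graphs"] + fixture["target_graphs"]:
        h.update(graph.id.encode())
        h.update(graph.sequence.encode())
        h.update(np.ascontiguousarray(graph.adjacency).tobytes())
        h.update(np.round(graph.coords, 6).tobytes())
    for ann in (fixture["source_annotations"], fixture["target_annotations"]):
        for pid in sorted(ann):
            h.update(pid.encode())
            h.update(",".join(sorted(ann[pid])).encode())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# serialisation of a generated benchmark (all plain text)
# ---------------------------------------------------------------------------

def write_obo(dag: GoDag, path) -> None:
    ns_long = {"MF": "molecular_function", "BP": "biological_process",
               "CC": "cellular_component"}
    with open(path, "w") as fh:
        fh.write("format-version: 1.2\n\n")
        for term in sorted(dag.terms):
            fh.write("[Term]\n")
            fh.write(f"id: {term}\n")
            fh.write(f"name: {dag.graph.nodes[term].get('name', term)}\n")
            ns = dag.namespace(term)
            fh.write(f"namespace: {ns_long.get(ns, ns)}\n")
            for parent in sorted(dag.parents(term)):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def write_fasta(graphs: list[ProteinGraph], path) -> None:
    with open(path, "w") as fh:
        for graph in graphs:
            fh.write(f">{graph.id}\n{graph.sequence}\n")


def write_ca_pdb(graph: ProteinGraph, path, chain: str = "A") -> None:
    """Minimal Cα-only PDB for one synthetic protein."""
    from Bio.Data.IUPACData import protein_letters_1to3

    if graph.coords is None:
        raise ValueError(f"{graph.id}: no coordinates to write")
    with open(path, "w") as fh:
        for i, (aa, xyz) in enumerate(zip(graph.sequence, graph.coords)):
            resname = protein_letters_1to3.get(aa.upper(), "Unk").upper()
            resseq = graph.residue_numbers[i]
            fh.write(
                f"ATOM  {i + 1:5d}  CA  {resname:>3s} {chain}{resseq:4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {'C':>2s}\n")
        fh.write("END\n")
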