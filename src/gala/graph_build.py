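"""Protein graph construction: contact maps, residue features, PDB input.

A protein is modelled as a residue graph whose edges connect residue pairs
with Cα-Cα distance strictly below a threshold (10 Å by default). Node
features are a one-hot residue encoding, optionally concatenated with an
externally supplied per-residue embedding matrix.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

#: Fixed residue alphabet: the 20 standard amino acids followed by
#: selenocysteine (U), pyrrolysine (O), the ambiguity codes B and Z, and
#: the catch-all X. Any symbol outside this set is encoded as X.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYUOBZX"
ALPHABET_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

DEFAULT_CONTACT_THRESHOLD = 10.0  # Å


@dataclass
class ProteinGraph:
    """One protein: sequence, contact adjacency, node features, coordinates.

    The adjacency is binary, symmetric, with a zero diagonal; self-loops
    are added only inside the GCN normalisation.
    """

    id: str
    sequence: str
    adjacency: np.ndarray
    features: np.ndarray
    coords: np.ndarray | None = None
    residue_numbers: list[int] = field(default_factory=list)

    def __post_init__(self):
        self.validate()
        if not self.residue_numbers:
            self.residue_numbers = list(range(1, len(self.sequence) + 1))

    def __len__(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ValueError(f"{self.id}: empty sequence")
        if self.adjacency.shape != (n, n):
            raise ValueError(
                f"{self.id}: adjacency shape {self.adjacency.shape} != ({n}, {n})")
        if not np.array_equal(self.adjacency, self.adjacency.T):
            raise ValueError(f"{self.id}: adjacency is not symmetric")
        if np.any(np.diag(self.adjacency) != 0):
            raise ValueError(f"{self.id}: adjacency diagonal must be zero")
        if not np.isin(self.adjacency, (0, 1)).all():
            raise ValueError(f"{self.id}: adjacency must be binary")
        if self.features.shape[0] != n:
            raise ValueError(
                f"{self.id}: features rows {self.features.shape[0]} != |V|={n}")
        if self.coords is not None and self.coords.shape != (n, 3):
            raise ValueError(
                f"{self.id}: coords shape {self.coords.shape} != ({n}, 3)")


def build_contact_map(coords: np.ndarray,
                      threshold: float = DEFAULT_CONTACT_THRESHOLD) -> np.ndarray:
    """Binary contact map: (i, j) = 1 iff i != j and d(i, j) < threshold."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValueError(f"coords must be |V|x3, got {coords.shape}")
    if coords.shape[0] < 1:
        raise ValueError("need at least one residue")
    bad = np.where(~np.isfinite(coords).all(axis=1))[0]
    if bad.size:
        raise ValueError(f"non-finite coordinates at residue index {bad[0]}")
    if coords.shape[0] == 1:
        return np.zeros((1, 1), dtype=np.int8)
    adj = (squareform(pdist(coords)) < threshold).astype(np.int8)
    np.fill_diagonal(adj, 0)
    return adj


def one_hot_encode(sequence: str) -> np.ndarray:
    """|V| x 25 one-hot residue encoding; unknown symbols map to X."""
    if not sequence:
        raise ValueError("empty sequence")
    x_col = ALPHABET_INDEX["X"]
    idx = np.array([ALPHABET_INDEX.get(aa, x_col) for aa in sequence.upper()])
    out = np.zeros((len(sequence), len(ALPHABET)))
    out[np.arange(len(sequence)), idx] = 1.0
    return out


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode` on the fixed alphabet."""
    return "".join(ALPHABET[i] for i in np.asarray(matrix).argmax(axis=1))


def build_features(sequence: str, embeddings: np.ndarray | None = None) -> np.ndarray:
    """One-hot block, optionally followed by an external embedding block."""
    onehot = one_hot_encode(sequence)
    if embeddings is None:
        return onehot
    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.shape[0] != len(sequence):
        raise ValueError(
            f"embedding rows ({embeddings.shape[0]}) != sequence length "
            f"({len(sequence)})")
    return np.concatenate([onehot, embeddings], axis=1)


def pseudo_embeddings(sequence: str, dim: int = 32, seed: int = 0) -> np.ndarray:
    """Deterministic stand-in for an external language-model embedding.

    Each row depends only on (symbol, position, seed) via a hash, so the
    provider is reproducible across processes without model weights.
    """
    rows = []
    for pos, aa in enumerate(sequence):
        digest = hashlib.sha256(f"{seed}:{pos}:{aa}".encode()).digest()
        rng = np.random.default_rng(int.from_bytes(digest[:8], "little"))
        rows.append(rng.standard_normal(dim))
    return np.asarray(rows)


def read_structure(path, chain: str) -> tuple[str, np.ndarray, list[int]]:
    """Extract (sequence, Cα coords, author residue numbers) for one chain.

    First model only; residues without a Cα atom are skipped with a
    warning; for disordered atoms the highest-occupancy altloc is used.
    Sequence comes from ATOM records so it always co-indexes coords.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.Polypeptide import protein_letters_3to1_extended

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = PDBParser(QUIET=True).get_structure("s", str(path))
    model = next(structure.get_models())
    chains = {c.id for c in model}
    if chain not in chains:
        raise ValueError(
            f"chain {chain!r} not found in {path}; available: {sorted(chains)}")
    seq, coords, numbers = [], [], []
    for residue in model[chain]:
        if residue.id[0] != " ":  # skip heteroatoms/water
            continue
        if "CA" not in residue:
            logger.warning("residue %s %s lacks a CA atom; skipped",
                           residue.get_resname(), residue.id[1])
            continue
        ca = residue["CA"]
        if ca.is_disordered():
            ca = max(ca.disordered_get_list(), key=lambda a: a.get_occupancy())
        seq.append(protein_letters_3to1_extended.get(residue.get_resname(), "X"))
        coords.append(ca.get_coord())
        numbers.append(residue.id[1])
    if not coords:
        raise ValueError(f"no CA atoms found for chain {chain!r} in {path}")
    return "".join(seq), np.asarray(coords, dtype=float), numbers


def graph_from_structure(path, chain: str, protein_id: str | None = None,
                         threshold: float = DEFAULT_CONTACT_THRESHOLD,
                         embeddings: np.ndarray | None = None) -> ProteinGraph:
    """Read a PDB chain and assemble the full ProteinGraph."""
    seq, coords, numbers = read_structure(path, chain)
    return ProteinGraph(
        id=protein_id or f"{path}_{chain}",
        sequence=seq,
        adjacency=build_contact_map(coords, threshold),
        features=build_features(seq, embeddings),
        coords=coords,
        residue_numbers=numbers,
    )


# ---------------------------------------------------------------------------
# on-disk container: one .npz per protein, shape-checked on load
# ---------------------------------------------------------------------------

def save_graph(graph: ProteinGraph, path) -> None:
    arrays = {
        "sequence": np.array(graph.sequence),
        "adjacency": graph.adjacency,
        "features": graph.features,
        "residue_numbers": np.array(graph.residue_numbers),
        "id": np.array(graph.id),
    }
    if graph.coords is not None:
        arrays["coords"] = graph.coords
    np.savez(path, **arrays)


def load_graph(path) -> ProteinGraph:
    with np.load(path, allow_pickle=False) as z:
        return ProteinGraph(
            id=str(z["id"]),
            sequence=str(z["sequence"]),
            adjacency=z["adjacency"],
            features=z["features"],
            coords=z["coords"] if "coords" in z else None,
            residue_numbers=[int(x) for x in z["residue_numbers"]],
        )
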