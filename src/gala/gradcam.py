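"""Residue-level attribution of a predicted term via Grad-CAM.

The feature map is the final GCN layer output F (L x D); the gradient of
the term's pre-sigmoid logit w.r.t. F weights the map, and the ReLU of
the channel-mean product gives a raw per-residue contribution which is
min-max normalized to [0, 100] per profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .graph_build import ProteinGraph
from .network import GalaModel
from .ontology import TermIndex


@dataclass
class CamProfile:
    protein_id: str
    term_id: str
    scores: np.ndarray      # length L, each in [0, 100]
    raw: np.ndarray         # pre-normalization values
    residue_numbers: list[int]
    sequence: str

    def __post_init__(self):
        if np.any(self.scores < 0) or np.any(self.scores > 100):
            raise ValueError("normalized CAM scores must lie in [0, 100]")


def normalize_cam(raw: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 100]; an all-constant profile maps to 0."""
    raw = np.asarray(raw, dtype=float)
    span = raw.max() - raw.min()
    if span == 0:
        return np.zeros_like(raw)
    return np.clip(100.0 * (raw - raw.min()) / span, 0.0, 100.0)


def cam_profile(model: GalaModel, graph: ProteinGraph, term: str,
                index: TermIndex) -> CamProfile:
    """Grad-CAM profile of one term on one protein."""
    if term not in index.terms:
        raise ValueError(f"unknown term {term!r} for this model")
    class_idx = index.position(term)
    model.dropout_rng = None
    out = model.forward_one(graph)
    logit = out["logits"][class_idx]
    model.zero_grad()
    logit.backward()
    F = out["H"].data                      # L x D feature map
    W = out["H"].grad                      # d logit / d F
    raw = np.maximum((W * F).mean(axis=1), 0.0)
    return CamProfile(protein_id=graph.id, term_id=term,
                      scores=normalize_cam(raw), raw=raw,
                      residue_numbers=list(graph.residue_numbers),
                      sequence=graph.sequence)


def cam_to_pdb(profile: CamProfile, structure_path, out_path,
               chain: str = "A") -> None:
    """Copy a PDB file with B-factors replaced by the CAM scores.

    Scores are assigned per residue (all atoms of a residue share one
    value), matched by order of appearance of the chain's residues.
    """
    residue_scores: dict[tuple, float] = {}
    order: list[tuple] = []
    with open(structure_path) as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith(("ATOM", "HETATM")) and line[21] == chain:
            key = (line[22:27], line[17:20])  # resseq+icode, resname
            if key not in residue_scores:
                order.append(key)
                residue_scores[key] = np.nan
    if len(order) != len(profile.scores):
        raise ValueError(
            f"profile length {len(profile.scores)} != {len(order)} residues "
            f"in chain {chain} of {structure_path}")
    for key, score in zip(order, profile.scores):
        residue_scores[key] = score
    with open(out_path, "w") as fh:
        for line in lines:
            if line.startswith(("ATOM", "HETATM")) and line[21] == chain:
                key = (line[22:27], line[17:20])
                score = residue_scores[key]
                line = f"{line[:60]}{score:6.2f}{line[66:]}"
                if not line.endswith("\n"):
                    line += "\n"
            fh.write(line)


def write_cam_tsv(profile: CamProfile, path) -> None:
    """TSV: residue_index (0-based), author residue number, symbol, score."""
    with open(path, "w") as fh:
        fh.write("residue_index\tauthor_residue_number\tsymbol\tcam_score\n")
        for i, (num, aa, score) in enumerate(
                zip(profile.residue_numbers, profile.sequence, profile.scores)):
            fh.write(f"{i}\t{num}\t{aa}\t{score:.4f}\n")


def cam_site_auc(profile: CamProfile | np.ndarray,
                 site_indices: list[int]) -> float:
    """ROC-AUC of CAM scores ranking site vs non-site residues (ties 0.5)."""
    scores = profile.scores if isinstance(profile, CamProfile) else \
        np.asarray(profile, dtype=float)
    sites = set(int(i) for i in site_indices)
    n = len(scores)
    if not sites or not sites < set(range(n)):
        raise ValueError("site set must be a non-empty proper subset of residues")
    if any(i < 0 or i >= n for i in sites):
        raise ValueError("site index out of range")
    from scipy.stats import rankdata

    ranks = rankdata(scores)  # average ranks handle ties
    pos = np.array(sorted(sites))
    n_pos = len(pos)
    n_neg = n - n_pos
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))
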