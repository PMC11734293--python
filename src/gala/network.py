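"""Differentiable model: GCN encoder, meta-node graph transformer,
attention pooling, classifier, label projector and domain discriminator.

The architecture, per graph:

1. an N-layer GCN with symmetric normalisation produces residue
   embeddings H (|V| x D);
2. K learnable meta-node queries per head attend over keys/values that
   are themselves single GCN layers of H, giving Gamma (K x D) per head;
3. head outputs are concatenated and merged back to K x D by an MLP;
4. an attention-pooling readout with a learnable query collapses the K
   meta-nodes into the graph embedding z (dim D);
5. a linear classifier + sigmoid maps z to per-term probabilities.

A 2-layer MLP projects label vectors into the z space (contrastive
alignment) and a 2-layer MLP discriminator consumes a frozen randomized
multilinear map of (z, y_hat) for adversarial domain alignment.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .autodiff import Tensor, concat, grad_reverse, softmax
from .graph_build import ProteinGraph

EPS = 1e-7


@dataclass
class ModelConfig:
    n_features: int = 25
    n_classes: int = 15
    gcn_layers: int = 2        # N
    hidden_dim: int = 128      # D
    meta_nodes: int = 8        # K
    heads: int = 4             # h
    multilinear_dim: int = 512 # d
    temperature: float = 0.1   # tau
    dropout: float = 0.2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_features", "n_classes", "gcn_layers", "hidden_dim",
                     "meta_nodes", "heads", "multilinear_dim"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class GalaModel:
    """All learnable parameters plus the frozen random projection matrices.

    ``R_z`` and ``R_y`` are sampled exactly once at construction from the
    standard normal (unit variance, symmetric) and are never updated; they
    are serialized together with the parameters.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        D, K, h, d, C = (config.hidden_dim, config.meta_nodes, config.heads,
                         config.multilinear_dim, config.n_classes)
        F = config.n_features
        p: dict[str, Tensor] = {}

        dims = [F] + [D] * config.gcn_layers
        for l in range(config.gcn_layers):
            p[f"gcn_W{l}"] = self._param(_glorot(rng, dims[l], dims[l + 1]))
        # per-head meta-node queries; key/value GCN layers shared across heads
        for head in range(h):
            p[f"queries_{head}"] = self._param(rng.standard_normal((K, D)) * 0.1)
        p["key_gcn_W"] = self._param(_glorot(rng, D, D))
        p["value_gcn_W"] = self._param(_glorot(rng, D, D))
        # merge MLP: K x (h*D) -> K x D, one hidden ReLU layer
        p["merge_W1"] = self._param(_glorot(rng, h * D, D))
        p["merge_b1"] = self._param(np.zeros(D))
        p["merge_W2"] = self._param(_glorot(rng, D, D))
        p["merge_b2"] = self._param(np.zeros(D))
        # attention pooling
        p["pool_q"] = self._param(rng.standard_normal(D) * 0.1)
        p["pool_K"] = self._param(_glorot(rng, D, D))
        p["pool_V"] = self._param(_glorot(rng, D, D))
        # classifier G
        p["cls_W"] = self._param(_glorot(rng, D, C))
        p["cls_b"] = self._param(np.zeros(C))
        # label projector P: C -> D -> D
        p["proj_W1"] = self._param(_glorot(rng, C, D))
        p["proj_b1"] = self._param(np.zeros(D))
        p["proj_W2"] = self._param(_glorot(rng, D, D))
        p["proj_b2"] = self._param(np.zeros(D))
        # discriminator: d -> D -> 1
        p["disc_W1"] = self._param(_glorot(rng, d, D))
        p["disc_b1"] = self._param(np.zeros(D))
        p["disc_W2"] = self._param(_glorot(rng, D, 1))
        p["disc_b2"] = self._param(np.zeros(1))
        self.params = p
        # frozen random matrices for the multilinear map
        self.R_z = rng.standard_normal((d, D))
        self.R_y = rng.standard_normal((d, C))
        # dropout is active only while a training loop installs an rng here
        self.dropout_rng: np.random.Generator | None = None

    @staticmethod
    def _param(value: np.ndarray) -> Tensor:
        return Tensor(value, requires_grad=True)

    # ------------------------------------------------------------ param views
    def discriminator_params(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if k.startswith("disc_")}

    def main_params(self) -> dict[str, Tensor]:
        return {k: v for k, v in self.params.items() if not k.startswith("disc_")}

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.zero_grad()

    # -------------------------------------------------------------- forward
    def gcn_forward(self, X, A: np.ndarray) -> Tensor:
        """N-layer GCN: H^{l+1} = ReLU(D~^{-1/2} A~ D~^{-1/2} H^l W^l)."""
        X = X if isinstance(X, Tensor) else Tensor(X)
        if X.shape[0] != A.shape[0]:
            raise ValueError(f"feature rows {X.shape} vs adjacency {A.shape}")
        if X.shape[1] != self.config.n_features:
            raise ValueError(
                f"feature dim {X.shape[1]} != model n_features "
                f"{self.config.n_features}")
        A_hat = Tensor(_normalized_adjacency(A))
        H = X
        for l in range(self.config.gcn_layers):
            H = (A_hat @ (H @ self.params[f"gcn_W{l}"])).relu()
            if (self.dropout_rng is not None and self.config.dropout > 0
                    and l < self.config.gcn_layers - 1):
                keep = 1.0 - self.config.dropout
                mask = self.dropout_rng.random(H.shape) < keep
                H = H * Tensor(mask / keep)
        return H

    def _single_gcn(self, H: Tensor, A_hat: Tensor, weight: Tensor) -> Tensor:
        return (A_hat @ (H @ weight)).relu()

    def meta_node_attention(self, H: Tensor, A: np.ndarray, head: int) -> Tensor:
        """Gamma = softmax(Q K^T / sqrt(D)) V with GCN-derived keys/values."""
        A_hat = Tensor(_normalized_adjacency(A))
        keys = self._single_gcn(H, A_hat, self.params["key_gcn_W"])
        values = self._single_gcn(H, A_hat, self.params["value_gcn_W"])
        Q = self.params[f"queries_{head}"]
        scores = (Q @ keys.T) / np.sqrt(self.config.hidden_dim)
        return softmax(scores, axis=-1) @ values

    def multihead_merge(self, gammas: list[Tensor]) -> Tensor:
        if len(gammas) != self.config.heads:
            raise ValueError(
                f"got {len(gammas)} heads, expected {self.config.heads}")
        shapes = {g.shape for g in gammas}
        if len(shapes) != 1:
            raise ValueError(f"head shape mismatch: {shapes}")
        cat = concat(gammas, axis=-1)
        hidden = (cat @ self.params["merge_W1"] + self.params["merge_b1"]).relu()
        return hidden @ self.params["merge_W2"] + self.params["merge_b2"]

    def attention_pool(self, U: Tensor) -> Tensor:
        """z = softmax(q^P (U K^P)^T / sqrt(D)) U V^P, softmax over meta-nodes."""
        keys = U @ self.params["pool_K"]
        scores = (self.params["pool_q"] @ keys.T) / np.sqrt(self.config.hidden_dim)
        weights = softmax(scores, axis=-1)
        return weights @ (U @ self.params["pool_V"])

    def classify(self, z: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (probabilities, pre-sigmoid logits)."""
        logits = z @ self.params["cls_W"] + self.params["cls_b"]
        return logits.sigmoid().clip(EPS, 1.0 - EPS), logits

    def embed_labels(self, y: np.ndarray) -> Tensor:
        """2-layer MLP projecting a binary label vector into z space."""
        y = np.asarray(y, dtype=float)
        if not np.isin(y, (0.0, 1.0)).all():
            raise ValueError("label vector must be binary")
        hidden = (Tensor(y) @ self.params["proj_W1"] + self.params["proj_b1"]).relu()
        return hidden @ self.params["proj_W2"] + self.params["proj_b2"]

    def multilinear_map(self, z: Tensor, y_hat: Tensor) -> Tensor:
        """T(z, y) = (R_z z) * (R_y y) / sqrt(d), elementwise product."""
        d = self.config.multilinear_dim
        return (Tensor(self.R_z) @ z) * (Tensor(self.R_y) @ y_hat) / np.sqrt(d)

    def discriminate(self, t: Tensor) -> Tensor:
        """Domain probability in (eps, 1-eps)."""
        hidden = (t @ self.params["disc_W1"] + self.params["disc_b1"]).relu()
        out = hidden @ self.params["disc_W2"] + self.params["disc_b2"]
        return out.sigmoid().clip(EPS, 1.0 - EPS)

    def forward_one(self, graph: ProteinGraph,
                    reverse_grad: float | None = None
                    ) -> dict[str, Tensor]:
        """Full forward pass for one graph.

        Returns z, y_hat, logits, the final GCN feature map H (retained
        for Grad-CAM), and — when `reverse_grad` is set — the
        discriminator output on the gradient-reversed multilinear map.
        """
        if len(graph) == 0:
            raise ValueError(f"{graph.id}: empty graph")
        H = self.gcn_forward(graph.features, graph.adjacency)
        gammas = [self.meta_node_attention(H, graph.adjacency, head)
                  for head in range(self.config.heads)]
        U = self.multihead_merge(gammas)
        z = self.attention_pool(U)
        y_hat, logits = self.classify(z)
        out = {"z": z, "y_hat": y_hat, "logits": logits, "H": H}
        if reverse_grad is not None:
            t = self.multilinear_map(z, y_hat)
            out["domain_prob"] = self.discriminate(grad_reverse(t, reverse_grad))
        return out

    def forward(self, graphs: list[ProteinGraph],
                reverse_grad: float | None = None) -> list[dict[str, Tensor]]:
        """Batch forward: graphs are disjoint, so per-graph evaluation is
        exact (no cross-graph edges or attention by construction)."""
        if not graphs:
            raise ValueError("empty batch")
        return [self.forward_one(g, reverse_grad) for g in graphs]

    # ---------------------------------------------------------- persistence
    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        arrays["R_z"], arrays["R_y"] = self.R_z, self.R_y
        arrays["_config_json"] = np.array(json.dumps(asdict(self.config)))
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "GalaModel":
        with np.load(path, allow_pickle=False) as z:
            config = ModelConfig(**json.loads(str(z["_config_json"])))
            model = cls(config)
            for k in model.params:
                model.params[k].data = z[k].copy()
            model.R_z, model.R_y = z["R_z"].copy(), z["R_y"].copy()
        return model


def _normalized_adjacency(A: np.ndarray) -> np.ndarray:
    """D~^{-1/2} (A + I) D~^{-1/2} with D~ the degree matrix of A + I."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got {A.shape}")
    A_tilde = A + np.eye(A.shape[0])
    inv_sqrt_deg = 1.0 / np.sqrt(A_tilde.sum(axis=1))
    return A_tilde * inv_sqrt_deg[:, None] * inv_sqrt_deg[None, :]
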