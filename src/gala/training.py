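"""Domain-adversarial training loop.

Each step samples M labeled source graphs and M unlabeled target graphs.
The classifier stack is trained by Adam on the total loss; the domain
discriminator is trained by momentum SGD on the adversarial term, while a
gradient-reversal contract at its input makes the encoder maximize the
same term. Ablation flags switch the adversarial and label-alignment
branches off independently (the M2/M3/M4/M5 configurations).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

from . import cafa_metrics, losses
from .autodiff import Tensor, stack
from .graph_build import ProteinGraph
from .network import GalaModel, ModelConfig


@dataclass
class TrainConfig:
    batch_size: int = 16              # M graphs per domain per step
    epochs: int = 50
    lr_main: float = 1e-4             # Adam, encoder/classifier/projector
    lr_disc: float = 0.03             # SGD for the domain discriminator
    disc_momentum: float = 0.9
    grl_lambda: float = 1.0
    #: "constant" uses grl_lambda at every step; "ramp" scales it by the
    #: standard warm-up 2/(1+exp(-10 p)) - 1 over training progress p,
    #: letting the classifier settle before the adversarial game starts
    grl_schedule: str = "constant"
    seed: int = 0
    use_adversarial: bool = True      # "adv" ablation flag
    use_label_alignment: bool = True  # "cl" ablation flag
    patience: int = 10                # early stopping on validation Fmax
    namespace: str = "MF"
    log_path: str | None = None

    def __post_init__(self):
        if self.use_label_alignment and self.batch_size < 2:
            raise ValueError("label alignment needs batch_size >= 2")


@dataclass
class TrainedState:
    model: GalaModel
    config: TrainConfig
    history: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_fmax: float = 0.0


class Adam:
    def __init__(self, params: dict[str, Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params, self.lr, self.betas, self.eps = params, lr, betas, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class MomentumSGD:
    def __init__(self, params: dict[str, Tensor], lr: float, momentum: float):
        self.params, self.lr, self.momentum = params, lr, momentum
        self.velocity = {k: np.zeros_like(v.data) for k, v in params.items()}

    def step(self) -> None:
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.velocity[k] = self.momentum * self.velocity[k] + p.grad
            p.data -= self.lr * self.velocity[k]


def training_step(model: GalaModel,
                  source_graphs: list[ProteinGraph], source_Y: np.ndarray,
                  target_graphs: list[ProteinGraph],
                  config: TrainConfig,
                  main_opt: Adam, disc_opt: MomentumSGD,
                  progress: float = 1.0) -> losses.LossBreakdown:
    """One optimization step over an M+M mini-batch; returns the breakdown.

    `progress` in [0, 1] drives the optional gradient-reversal warm-up.
    """
    adv = config.use_adversarial
    lam = config.grl_lambda
    if config.grl_schedule == "ramp":
        lam *= 2.0 / (1.0 + np.exp(-10.0 * progress)) - 1.0
    reverse = lam if adv else None
    src_out = model.forward(source_graphs, reverse_grad=reverse)
    y_hat = stack([o["y_hat"] for o in src_out])
    l_sup = losses.supervised_bce(y_hat, source_Y)

    if adv:
        tgt_out = model.forward(target_graphs, reverse_grad=reverse)
        src_w = [losses.entropy_weight(o["y_hat"].detach()).item()
                 for o in src_out]
        tgt_w = [losses.entropy_weight(o["y_hat"].detach()).item()
                 for o in tgt_out]
        l_adv = losses.adversarial_loss(
            [o["domain_prob"] for o in src_out], src_w,
            [o["domain_prob"] for o in tgt_out], tgt_w)
    else:
        l_adv = Tensor(0.0)

    if config.use_label_alignment:
        b = [model.embed_labels(source_Y[i]) for i in range(len(source_graphs))]
        l_con = losses.alignment_loss([o["z"] for o in src_out], b,
                                      model.config.temperature)
    else:
        l_con = Tensor(0.0)

    total = losses.total_loss(l_sup, l_adv, l_con)
    if not np.isfinite(total.data):
        raise FloatingPointError(
            f"NaN/inf loss: sup={l_sup.item()} adv={l_adv.item()} "
            f"con={l_con.item()}")
    model.zero_grad()
    total.backward()
    main_opt.step()
    if adv:
        disc_opt.step()
    return losses.LossBreakdown(l_sup.item(), l_adv.item(), l_con.item())


def train(model: GalaModel,
          source_graphs: list[ProteinGraph], source_Y: np.ndarray,
          target_graphs: list[ProteinGraph],
          config: TrainConfig,
          val_graphs: list[ProteinGraph] | None = None,
          val_Y: np.ndarray | None = None) -> TrainedState:
    """Full training run with per-epoch validation Fmax and early stopping.

    Target labels are never read. One epoch is a pass over the source set;
    the target iterator cycles independently.
    """
    if not source_graphs:
        raise ValueError("empty source set")
    if config.use_adversarial and not target_graphs:
        raise ValueError("empty target set with adversarial training enabled")
    rng = np.random.default_rng(config.seed)
    main_opt = Adam(model.main_params(), config.lr_main)
    disc_opt = MomentumSGD(model.discriminator_params(), config.lr_disc,
                           config.disc_momentum)
    state = TrainedState(model=model, config=config)
    best_params: dict[str, np.ndarray] | None = None
    stale = 0
    m = config.batch_size
    n_src = len(source_graphs)
    target_order: list[int] = []
    log_fh = open(config.log_path, "w") if config.log_path else None
    step = 0
    try:
        for epoch in range(config.epochs):
            model.dropout_rng = rng
            order = rng.permutation(n_src)
            epoch_losses: list[losses.LossBreakdown] = []
            for start in range(0, n_src, m):
                src_idx = order[start:start + m]
                if config.use_label_alignment and len(src_idx) < 2:
                    continue  # contrastive term needs >= 2 samples
                while len(target_order) < len(src_idx):
                    target_order.extend(
                        rng.permutation(len(target_graphs)).tolist()
                        if target_graphs else [])
                    if not target_graphs:
                        break
                tgt_idx, target_order = (target_order[:len(src_idx)],
                                         target_order[len(src_idx):])
                total_steps = max(1, config.epochs * ((n_src + m - 1) // m))
                breakdown = training_step(
                    model,
                    [source_graphs[i] for i in src_idx], source_Y[src_idx],
                    [target_graphs[j] for j in tgt_idx],
                    config, main_opt, disc_opt,
                    progress=step / total_steps)
                epoch_losses.append(breakdown)
                if log_fh:
                    log_fh.write(json.dumps(
                        {"step": step, "epoch": epoch,
                         "l_sup": breakdown.l_sup, "l_adv": breakdown.l_adv,
                         "l_con": breakdown.l_con,
                         "l_total": breakdown.l_total}) + "\n")
                step += 1
            model.dropout_rng = None
            record = {
                "epoch": epoch,
                "l_sup": float(np.mean([b.l_sup for b in epoch_losses])),
                "l_adv": float(np.mean([b.l_adv for b in epoch_losses])),
                "l_con": float(np.mean([b.l_con for b in epoch_losses])),
            }
            if val_graphs is not None and val_Y is not None:
                P = predict(model, val_graphs)
                keep = val_Y.sum(axis=1) > 0
                f, _ = cafa_metrics.fmax(P[keep], val_Y[keep])
                record["val_fmax"] = f
                if f > state.best_val_fmax:
                    state.best_val_fmax, state.best_epoch = f, epoch
                    best_params = {k: v.data.copy()
                                   for k, v in model.params.items()}
                    stale = 0
                else:
                    stale += 1
            state.history.append(record)
            if stale > config.patience:
                break
    finally:
        model.dropout_rng = None
        if log_fh:
            log_fh.close()
    if best_params is not None:
        for k, v in best_params.items():
            model.params[k].data = v
    return state


def predict(model: GalaModel, graphs: list[ProteinGraph]) -> np.ndarray:
    """Deterministic n x C score matrix in [0, 1]."""
    if not graphs:
        return np.zeros((0, model.config.n_classes))
    model.dropout_rng = None
    outs = model.forward(graphs)
    return np.stack([o["y_hat"].data for o in outs])


def fit(source_graphs: list[ProteinGraph], source_Y: np.ndarray,
        target_graphs: list[ProteinGraph],
        model_config: ModelConfig, train_config: TrainConfig,
        val_graphs: list[ProteinGraph] | None = None,
        val_Y: np.ndarray | None = None) -> TrainedState:
    """Construct a model (seeded from the train config) and train it."""
    model_config = dataclasses.replace(model_config, seed=train_config.seed)
    model = GalaModel(model_config)
    return train(model, source_graphs, source_Y, target_graphs,
                 train_config, val_graphs, val_Y)
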