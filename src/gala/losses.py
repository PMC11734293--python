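"""Training objectives: supervised BCE, entropy-weighted adversarial loss,
and contrastive label-embedding alignment. All losses use natural log and
clip probabilities to [1e-7, 1 - 1e-7] before any logarithm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack, tensor

EPS = 1e-7


@dataclass
class LossBreakdown:
    l_sup: float
    l_adv: float
    l_con: float

    @property
    def l_total(self) -> float:
        return self.l_sup + self.l_adv + self.l_con


def supervised_bce(y_hat, y) -> Tensor:
    """Mean binary cross-entropy over all M x C protein-term pairs."""
    y_hat = tensor(y_hat)
    y = np.asarray(y.data if isinstance(y, Tensor) else y, dtype=float)
    if y_hat.shape != y.shape:
        raise ValueError(f"shape mismatch: {y_hat.shape} vs {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("ground truth must be binary")
    p = y_hat.clip(EPS, 1.0 - EPS)
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    return -ll.mean()


def entropy_weight(y_hat) -> Tensor:
    """w = 1 + exp(-H), H = mean per-class binary entropy of the prediction.

    Confident (low-entropy) samples get weight near 2, uncertain ones near
    1 + exp(-ln 2) at p = 0.5 per class.
    """
    p = tensor(y_hat).clip(EPS, 1.0 - EPS)
    entropy = -(p * p.log() + (1.0 - p) * (1.0 - p).log()).mean()
    return 1.0 + (-entropy).exp()


def adversarial_loss(source_domain_probs: list[Tensor],
                     source_weights: list[float],
                     target_domain_probs: list[Tensor],
                     target_weights: list[float]) -> Tensor:
    """Entropy-weighted domain BCE.

    `*_domain_probs` are discriminator outputs D(T(z, y_hat)) per sample;
    the weights are w(H(y_hat)) computed on detached predictions. The
    discriminator should output high for source, low for target.
    """
    if len(source_domain_probs) != len(target_domain_probs):
        raise ValueError(
            f"batch-size mismatch: {len(source_domain_probs)} source vs "
            f"{len(target_domain_probs)} target")
    m = len(source_domain_probs)
    terms = []
    for prob, w in zip(source_domain_probs, source_weights):
        terms.append(-w * prob.clip(EPS, 1.0 - EPS).log())
    for prob, w in zip(target_domain_probs, target_weights):
        terms.append(-w * (1.0 - prob).clip(EPS, 1.0 - EPS).log())
    return stack([t.reshape(()) for t in terms]).sum() / m


def cosine_similarity(a: Tensor, b: Tensor) -> Tensor:
    na = (a * a).sum() ** 0.5
    nb = (b * b).sum() ** 0.5
    if na.item() == 0.0 or nb.item() == 0.0:
        raise ValueError("zero-norm vector in cosine similarity")
    return (a @ b) / (na * nb)


def alignment_loss(z_batch: list[Tensor], b_batch: list[Tensor],
                   temperature: float,
                   include_positive_in_denominator: bool = False) -> Tensor:
    """Contrastive alignment of graph embeddings with label embeddings.

    L = -(1/M) sum_i log( exp(s_ii/tau) / sum_{j != i} exp(s_ij/tau) )
    with s_ij the cosine similarity of z_i and b_j. As printed the
    positive pair is excluded from the denominator, so the loss can be
    negative; `include_positive_in_denominator` switches to the standard
    InfoNCE form.
    """
    m = len(z_batch)
    if m < 2:
        raise ValueError("alignment loss needs a batch of at least 2")
    if len(b_batch) != m:
        raise ValueError(f"batch-size mismatch: {m} vs {len(b_batch)}")
    sims = [[cosine_similarity(z_batch[i], b_batch[j]) / temperature
             for j in range(m)] for i in range(m)]
    terms = []
    for i in range(m):
        denom_idx = range(m) if include_positive_in_denominator else \
            [j for j in range(m) if j != i]
        # log-sum-exp over the denominator terms
        row = stack([sims[i][j] for j in denom_idx])
        shift = Tensor(row.data.max())
        lse = shift + ((row - shift).exp().sum()).log()
        terms.append(sims[i][i] - lse)
    return -stack(terms).mean()


def total_loss(l_sup: Tensor, l_adv: Tensor, l_con: Tensor) -> Tensor:
    """Unweighted sum of the three objectives."""
    for name, part in (("l_sup", l_sup), ("l_adv", l_adv), ("l_con", l_con)):
        if not np.isfinite(np.asarray(part.data)).all():
            raise ValueError(f"non-finite loss component: {name}")
    return l_sup + l_adv + l_con
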