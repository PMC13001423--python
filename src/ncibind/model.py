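"""Interaction-supervised cross-attention model for binding prediction.

Frozen encoders provide token embeddings ``P`` (n residues x h) and ``D``
(m ligand atoms x h). Six h x h projections produce queries, keys and values
for each side; multi-head attention with H = 8 heads (one per non-covalent
interaction type plus two "overall" heads) computes bidirectional
cross-attention and self-attention per head:

    A_pd = softmax(Q_p K_d^T / sqrt(h_t)),   A_dp = softmax(Q_d K_p^T / sqrt(h_t))
    P* = 1/2 (P_sa + A_pd V_d),              D* = 1/2 (D_sa + A_dp V_p)

Head outputs are concatenated and projected, mean-pooled, concatenated into
a pair vector F = [D_bar, P_bar], and a small MLP emits the binding
probability. The joint objective mixes binary cross-entropy on the label
with a weighted KL divergence aligning each supervised head's attention
(renormalized to a distribution over residue-atom pairs) with the
ground-truth interaction map of its type:

    L = (1 - lambda) L_cls + lambda L_att,     lambda = 0.3 by default.

Supervision is symmetric over directions: the loss is computed on A_dp and
on the transpose of A_pd and averaged. Pairs without interaction maps (and
heads whose ground-truth map is all-zero) fall back to the classification
loss alone.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from typing import Optional, Sequence

import numpy as np

from .annotate import InteractionMapSet
from .autodiff import Adam, Tensor, concat, relu, sigmoid, softmax
from .encoders import EmbeddingBatch
from .rules import INTERACTION_TYPES

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig", "AttentionStack", "InteractionModel",
    "bce_loss", "attention_alignment_loss", "total_loss",
    "predict_sites_and_types", "train",
    "HEAD_NAMES", "N_HEADS",
]

N_HEADS = 8
HEAD_NAMES: tuple[str, ...] = INTERACTION_TYPES + ("overall_0", "overall_1")
OVERALL_HEADS = ("overall_0", "overall_1")

PROB_EPS = 1e-12  # clamp for log terms in the losses
DIST_FLOOR = 1e-12  # floor for normalized attention distributions


@dataclass
class ModelConfig:
    """Hyperparameters of the interaction module and training loop."""

    h: int = 64                    # hidden dimension (divisible by n_heads)
    n_heads: int = N_HEADS
    d_out: int = 64                # fused token dimension after output projection
    mlp_hidden: tuple[int, int] = (64, 32)
    lambda_att: float = 0.3        # mixing weight of the attention loss
    supervise_overall: bool = True # overall heads supervised by the overall map
    lr: float = 3e-3
    epochs: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.lambda_att <= 1.0:
            raise ValueError("lambda must lie in [0, 1]")
        if self.h % self.n_heads != 0:
            raise ValueError(f"h={self.h} must be divisible by n_heads={self.n_heads}")

    @property
    def head_dim(self) -> int:
        return self.h // self.n_heads

    def supervised_heads(self) -> tuple[str, ...]:
        return HEAD_NAMES if self.supervise_overall else INTERACTION_TYPES


@dataclass
class AttentionStack:
    """Per-head cross-attention maps in both directions (row-stochastic)."""

    A_pd: dict[str, Tensor]  # head -> (n, m)
    A_dp: dict[str, Tensor]  # head -> (m, n)

    def head_names(self) -> tuple[str, ...]:
        return tuple(self.A_dp.keys())


class InteractionModel:
    """Trainable interaction module + classifier over frozen embeddings."""

    PARAM_NAMES = ("Wqd", "Wkd", "Wvd", "Wqp", "Wkp", "Wvp", "Wpo", "Wdo")

    def __init__(self, config: ModelConfig, rng: Optional[np.random.Generator] = None):
        self.config = config
        rng = rng or np.random.default_rng(config.seed)
        h, d = config.h, config.d_out
        scale = 1.0 / math.sqrt(h)
        self.params: dict[str, Tensor] = {}
        for name in ("Wqd", "Wkd", "Wvd", "Wqp", "Wkp", "Wvp"):
            self.params[name] = Tensor(rng.standard_normal((h, h)) * scale, requires_grad=True)
        self.params["Wpo"] = Tensor(rng.standard_normal((h, d)) * scale, requires_grad=True)
        self.params["Wdo"] = Tensor(rng.standard_normal((h, d)) * scale, requires_grad=True)
        w1, w2 = config.mlp_hidden
        sizes = [(2 * d, w1), (w1, w2), (w2, 1)]
        for k, (a, b) in enumerate(sizes, start=1):
            self.params[f"M{k}"] = Tensor(rng.standard_normal((a, b)) / math.sqrt(a), requires_grad=True)
            self.params[f"b{k}"] = Tensor(np.zeros(b), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- forward ---------------------------------------------------------
    def interaction_forward(self, E: EmbeddingBatch) -> tuple[AttentionStack, Tensor, Tensor]:
        """Multi-head bidirectional attention; returns the attention stack and
        the fused token sequences P* (n, d) and D* (m, d)."""
        cfg = self.config
        if E.h != cfg.h:
            raise ValueError(f"embedding dim {E.h} != model h {cfg.h}")
        P, D = Tensor(E.P), Tensor(E.D)
        p = self.params
        Qp, Kp, Vp = P @ p["Wqp"], P @ p["Wkp"], P @ p["Wvp"]
        Qd, Kd, Vd = D @ p["Wqd"], D @ p["Wkd"], D @ p["Wvd"]
        ht = cfg.head_dim
        inv = 1.0 / math.sqrt(ht)
        A_pd, A_dp = {}, {}
        P_heads, D_heads = [], []
        for k, head in enumerate(HEAD_NAMES[: cfg.n_heads]):
            sl = slice(k * ht, (k + 1) * ht)
            Qp_t, Kp_t, Vp_t = Qp[:, sl], Kp[:, sl], Vp[:, sl]
            Qd_t, Kd_t, Vd_t = Qd[:, sl], Kd[:, sl], Vd[:, sl]
            a_pd = softmax(Qp_t @ Kd_t.T * inv, axis=-1)      # (n, m)
            a_dp = softmax(Qd_t @ Kp_t.T * inv, axis=-1)      # (m, n)
            P_sa = softmax(Qp_t @ Kp_t.T * inv, axis=-1) @ Vp_t
            D_sa = softmax(Qd_t @ Kd_t.T * inv, axis=-1) @ Vd_t
            P_heads.append((P_sa + a_pd @ Vd_t) * 0.5)
            D_heads.append((D_sa + a_dp @ Vp_t) * 0.5)
            A_pd[head], A_dp[head] = a_pd, a_dp
        P_star = concat(P_heads, axis=-1) @ p["Wpo"]
        D_star = concat(D_heads, axis=-1) @ p["Wdo"]
        return AttentionStack(A_pd, A_dp), P_star, D_star

    def classify(self, P_star: Tensor, D_star: Tensor) -> Tensor:
        """Mean-pool both token sequences, concatenate to F = [D_bar, P_bar],
        and run the sigmoid-terminated MLP head."""
        P_bar = P_star.mean(axis=0, keepdims=True)
        D_bar = D_star.mean(axis=0, keepdims=True)
        F = concat([D_bar, P_bar], axis=-1)
        p = self.params
        hline = relu(F @ p["M1"] + p["b1"])
        hline = relu(hline @ p["M2"] + p["b2"])
        return sigmoid(hline @ p["M3"] + p["b3"])[0, 0]

    def forward(self, E: EmbeddingBatch) -> tuple[AttentionStack, Tensor]:
        stack, P_star, D_star = self.interaction_forward(E)
        return stack, self.classify(P_star, D_star)

    def predict(self, E: EmbeddingBatch) -> dict:
        stack, prob = self.forward(E)
        scores, type_maps = predict_sites_and_types(stack)
        return {"p": prob.item(), "residue_scores": scores, "type_maps": type_maps}

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {k: v.data for k, v in self.params.items()}
        np.savez(path, __config__=json.dumps(asdict(self.config)), **arrays)

    @classmethod
    def load(cls, path) -> "InteractionModel":
        with np.load(path, allow_pickle=False) as z:
            cfg_d = json.loads(str(z["__config__"]))
            cfg_d["mlp_hidden"] = tuple(cfg_d["mlp_hidden"])
            model = cls(ModelConfig(**cfg_d))
            for k in model.params:
                model.params[k] = Tensor(z[k], requires_grad=True)
        return model

    def checksum(self) -> str:
        import hashlib

        hsh = hashlib.sha256()
        for k in sorted(self.params):
            hsh.update(k.encode())
            hsh.update(np.ascontiguousarray(self.params[k].data).tobytes())
        return hsh.hexdigest()


# ---------------------------------------------------------------------------
# losses

def bce_loss(p: Tensor, y: int) -> Tensor:
    """Binary cross-entropy -[y log p + (1-y) log(1-p)], clamp-protected."""
    pc = p.clamp_min(PROB_EPS)
    qc = (1.0 - p).clamp_min(PROB_EPS)
    return -(float(y) * pc.log() + (1.0 - float(y)) * qc.log())


def _kl_term(weight: np.ndarray, true_dist: np.ndarray, pred: Tensor) -> Tensor:
    """sum_ij w_ij * T_ij * log(T_ij / pred_ij), with 0 log 0 := 0."""
    mask = true_dist > 0
    const = float(np.sum(weight[mask] * true_dist[mask] * np.log(true_dist[mask])))
    cross = (Tensor(weight * true_dist) * pred.clamp_min(DIST_FLOOR).log()).sum()
    return const - cross


def attention_alignment_loss(
    stack: AttentionStack,
    maps: InteractionMapSet,
    supervised: Sequence[str] = HEAD_NAMES,
    warn_on_empty: bool = True,
) -> Optional[Tensor]:
    """Weighted KL divergence between supervised attention heads and the
    ground-truth interaction maps, averaged over heads and both attention
    directions. Returns None when no supervised head has a nonzero map."""
    terms: list[Tensor] = []
    for head in supervised:
        A_raw = maps.overall if head in OVERALL_HEADS else maps.maps[head]
        total = A_raw.sum()
        if total <= 0:
            if warn_on_empty:
                logger.warning("head %s skipped: all-zero ground-truth map", head)
            continue
        true_dist = A_raw / total           # distribution over (i, j)
        weight = np.log1p(A_raw)
        a_dp = stack.A_dp[head]
        a_pd_t = stack.A_pd[head].T
        direction_terms = []
        for pred in (a_dp, a_pd_t):        # both (m, n)
            pred_dist = pred / pred.sum()
            direction_terms.append(_kl_term(weight, true_dist, pred_dist))
        terms.append((direction_terms[0] + direction_terms[1]) / 2.0)
    if not terms:
        return None
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out / float(len(terms))


def total_loss(l_cls: Tensor, l_att: Optional[Tensor], lam: float) -> Tensor:
    """Convex combination (1 - lambda) L_cls + lambda L_att; falls back to
    L_cls alone when no attention supervision is available."""
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must lie in [0, 1]")
    if l_att is None:
        return l_cls
    return (1.0 - lam) * l_cls + lam * l_att


# ---------------------------------------------------------------------------
# site / type readout

def predict_sites_and_types(stack: AttentionStack) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Residue scores and per-type score maps from a forward pass.

    The per-type map for each typed head is its ligand->protein attention
    A_dp (m, n). The residue score of position j is the maximum over ligand
    atoms of the mean of the two overall heads' A_dp. Downstream rankings
    break ties toward the lower residue index.
    """
    type_maps = {t: stack.A_dp[t].data.copy() for t in INTERACTION_TYPES if t in stack.A_dp}
    overall = [stack.A_dp[hd].data for hd in OVERALL_HEADS if hd in stack.A_dp]
    if overall:
        mean_map = np.mean(overall, axis=0)
    else:  # typed-only stacks: fall back to the mean of typed heads
        mean_map = np.mean(list(type_maps.values()), axis=0)
    scores = mean_map.max(axis=0)
    return scores, type_maps


# ---------------------------------------------------------------------------
# training

def train(
    dataset: Sequence[dict],
    config: Optional[ModelConfig] = None,
    model: Optional[InteractionModel] = None,
) -> tuple[InteractionModel, list[float]]:
    """Fit the interaction module and classifier on a dataset of samples.

    Each sample is a dict with keys ``P`` (n, h), ``D`` (m, h), ``y`` in
    {0, 1} and optionally ``maps`` (an :class:`InteractionMapSet`). Only the
    projection and MLP parameters are updated; embeddings enter the graph as
    constants (frozen-encoder contract). Returns the model and the per-epoch
    mean loss history. Fully determined by the config seed.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    config = config or ModelConfig()
    rng = np.random.default_rng(config.seed)
    if model is None:
        model = InteractionModel(config, rng=rng)
    opt = Adam(model.parameters(), lr=config.lr)
    supervised = config.supervised_heads()
    history: list[float] = []
    for _epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        epoch_loss = 0.0
        for idx in order:
            sample = dataset[idx]
            E = EmbeddingBatch(P=sample["P"], D=sample["D"])
            stack, prob = model.forward(E)
            l_cls = bce_loss(prob, sample["y"])
            l_att = None
            if config.lambda_att > 0 and sample.get("maps") is not None:
                # sparse corpora routinely leave typed heads without truth;
                # the skip is expected here, not an anomaly worth warning on
                l_att = attention_alignment_loss(stack, sample["maps"], supervised,
                                                 warn_on_empty=False)
            loss = total_loss(l_cls, l_att, config.lambda_att)
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
        history.append(epoch_loss / len(dataset))
    return model, history
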