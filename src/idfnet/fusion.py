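"""Dual-stage dynamic routing, cross-modal attention fusion, classifier head
and the composite training loss.

The fusion stage works on the three modality embeddings f_E, f_C, f_H:

1. **Pre-modality reliability gate** — a learned scalar gate
   ``g_m = sigmoid(w_m . f_m + b_m)`` attenuates each embedding before any
   cross-modal interaction: ``f~_m = g_m * f_m``.
2. **Entropy-regularized dynamic routing** — softmax routing weights
   ``g_i = softmax_i(W_i . f~_i + b_i)`` computed from the gated embeddings.
   The routing entropy ``H = -sum_i g_i log g_i`` enters the loss as a bonus
   (see below), discouraging collapse onto a single modality.
3. **Cross-modal attention fusion** — the routed tokens (unit-normalized
   embeddings scaled by ``g_i * g_m``) form a 3-token sequence processed by
   bidirectional multi-head attention; the attended tokens are summed and
   linearly projected to ``d_fused`` (paper-scale 1024 -> 2048; desk default
   32 -> 64).  The projection is weight-shared across modalities on purpose:
   with no slot-specific map downstream, the gate/routing scaling is the
   only channel that sets a modality's contribution, which keeps the routing
   weights identifiable (a concat + slot projection can silently renormalize
   any token).  A weighted-sum path (``sum_i g_i f~_i`` then projection) is
   the routing-only ablation configuration, and a plain concatenation path
   serves as the static no-fusion baseline.
4. **Classifier head** — ``d_fused -> d_hidden -> 1`` with ReLU, dropout
   (p = 0.3, training only) and a sigmoid malignancy probability.

Composite loss: ``L_total = L_BCE + lambda * L_ent + beta * L_L2`` with
``lambda = 0.01`` and ``beta = 0.001`` by default.  ``L_ent`` is ``-H``
(mean routing entropy with a *negative* sign) so that minimizing the total
loss maximizes entropy: an entropy bonus is the only sign choice consistent
with the stated purpose of preventing modality collapse.  The literal
"+H" penalty variant is available via ``entropy_sign='literal'`` for
comparison experiments.  ``L_L2`` is the mean squared
encoder/fusion weight (the classifier head is excluded by default,
configurable).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import preprocess
from .autograd import Tensor, concatenate, no_grad
from .encoders import CTEncoder, EncoderConfig, EndoscopyEncoder, HistologyEncoder
from .layers import Dropout, Linear, Module, MultiHeadAttention, concat_tokens
from .synthdata import MODALITIES

LOG_FLOOR = 1e-12

FUSION_MODES = ("attention", "weighted_sum", "concat")


# --------------------------------------------------------------------------
# functional building blocks (numpy; used directly in tests and analyses)
# --------------------------------------------------------------------------


def pre_modality_gate(f_m: np.ndarray, w_m: np.ndarray, b_m: float):
    """Sigmoid reliability gate: returns (g_m, g_m * f_m)."""
    f = np.atleast_2d(np.asarray(f_m, dtype=float))
    logit = f @ np.asarray(w_m, dtype=float) + b_m
    g = 1.0 / (1.0 + np.exp(-logit))
    return g, g[:, None] * f if g.ndim == 1 else g * f


def dynamic_route(gated_embeddings, weights, biases) -> np.ndarray:
    """Softmax routing over per-modality logits W_i . f_i + b_i.

    ``gated_embeddings``: sequence of (N, D) arrays (one per modality).
    Computed with max subtraction so huge logits cannot overflow.
    """
    logits = np.stack(
        [
            np.atleast_2d(np.asarray(f, dtype=float)) @ np.asarray(w, dtype=float) + b
            for f, w, b in zip(gated_embeddings, weights, biases)
        ],
        axis=-1,
    )
    logits = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    return e / e.sum(axis=-1, keepdims=True)


def routing_entropy(weights) -> np.ndarray:
    """Shannon entropy -sum g log g of routing weights, with 0 log 0 = 0."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("routing weights must lie in [0, 1]")
    terms = np.where(w > 0, w * np.log(np.maximum(w, LOG_FLOOR)), 0.0)
    return -terms.sum(axis=-1)


def weighted_sum_fuse(gated_embeddings, routing_weights) -> np.ndarray:
    """Convex combination sum_m g_m f~_m (the routing-only fusion path)."""
    embs = np.stack([np.atleast_2d(np.asarray(f, dtype=float)) for f in gated_embeddings], axis=1)
    w = np.asarray(routing_weights, dtype=float)
    if np.any(w < 0) or not np.allclose(w.sum(axis=-1), 1.0, atol=1e-6):
        raise ValueError("routing weights must lie on the simplex")
    return (w[..., None] * embs).sum(axis=1)


# --------------------------------------------------------------------------
# records
# --------------------------------------------------------------------------


@dataclass
class GateState:
    """Per-case gate diagnostics recorded during a forward pass."""

    reliability_gates: np.ndarray  # (N, 3) in modality order E, C, H
    routing_weights: np.ndarray  # (N, 3), rows on the simplex
    entropy: np.ndarray  # (N,)


@dataclass
class PredictionRecord:
    probability: np.ndarray  # (N,)
    logit: np.ndarray  # (N,)
    fused: np.ndarray  # (N, d_fused)
    gate_state: GateState
    embeddings: dict  # modality -> (N, d_latent)


@dataclass
class LossBreakdown:
    total: float
    bce: float
    entropy_term: float
    l2: float
    lam: float
    beta: float


# --------------------------------------------------------------------------
# model configuration
# --------------------------------------------------------------------------


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Desk-scale defaults; the paper-scale preset uses d_latent=1024,
    d_fused=2048, heads=8 with large pretrained backbones.
    """

    image_size: int = 64
    d_latent: int = 32
    d_fused: int = 64
    n_heads: int = 4
    dropout: float = 0.3
    lam: float = 0.01
    beta: float = 0.001
    fusion_mode: str = "attention"
    entropy_sign: str = "bonus"  # 'bonus' (-H, default) or 'literal' (+H)
    l2_include_head: bool = False
    backbone_endoscopy: str = "tiny_cnn"
    backbone_ct: str = "tiny_cnn"
    backbone_histology: str = "tiny_cnn"
    cnn_width: int = 8
    seed: int = 42

    def __post_init__(self):
        if self.fusion_mode not in FUSION_MODES:
            raise ValueError(f"fusion_mode must be one of {FUSION_MODES}")
        if self.entropy_sign not in ("bonus", "literal"):
            raise ValueError("entropy_sign must be 'bonus' or 'literal'")
        if self.lam < 0 or self.beta < 0:
            raise ValueError("loss coefficients must be non-negative")
        if self.d_latent % self.n_heads:
            raise ValueError(
                f"head count {self.n_heads} must divide d_latent {self.d_latent}"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


# --------------------------------------------------------------------------
# the model
# --------------------------------------------------------------------------


class IDFNet(Module):
    """Trimodal fusion classifier: encoders -> gates -> routing -> fusion ->
    classifier.  See module docstring for the dataflow."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        d = config.d_latent
        self.encoder_E = EndoscopyEncoder(
            EncoderConfig("E", config.backbone_endoscopy, d, width=config.cnn_width),
            rng,
            config.image_size,
        )
        self.encoder_C = CTEncoder(
            EncoderConfig(
                "C", config.backbone_ct, d, pooling="global_average", width=config.cnn_width
            ),
            rng,
            config.image_size,
        )
        self.encoder_H = HistologyEncoder(
            EncoderConfig(
                "H", config.backbone_histology, d, pooling="attention", width=config.cnn_width
            ),
            rng,
            config.image_size,
        )
        # stage 1: per-modality sigmoid reliability gates
        self.gate_E = Linear(d, 1, rng)
        self.gate_C = Linear(d, 1, rng)
        self.gate_H = Linear(d, 1, rng)
        # stage 2: softmax routing over gated embeddings
        self.route_E = Linear(d, 1, rng)
        self.route_C = Linear(d, 1, rng)
        self.route_H = Linear(d, 1, rng)
        # fusion paths
        self.attention = MultiHeadAttention(d, config.n_heads, rng)
        self.fuse_attention = Linear(d, config.d_fused, rng)
        self.fuse_weighted = Linear(d, config.d_fused, rng)
        self.fuse_concat = Linear(3 * d, config.d_fused, rng)
        # classifier head
        d_hidden = max(config.d_fused // 4, 8)
        self.head1 = Linear(config.d_fused, d_hidden, rng)
        self.head_dropout = Dropout(config.dropout)
        self.head_dropout.reseed(config.seed + 1)
        self.head2 = Linear(d_hidden, 1, rng)
        # per-channel normalization statistics, fit on training data
        self.norm_stats: dict = _default_norm_stats()
        # gating warmup blend: 0 -> tokens enter fusion unscaled (encoders
        # bootstrap), 1 -> full gate/routing scaling (the trained model);
        # the training loop ramps this during the first epochs
        self.gate_blend: float = 1.0
        # Platt calibration of the output probability, fitted on validation
        # data after checkpoint selection: p = sigmoid(a * logit + b).
        # Monotone (a > 0), so rankings and AUC are unchanged.
        self.calib_scale: float = 1.0
        self.calib_bias: float = 0.0

    # -------------------------------------------------------- preprocessing
    def fit_preprocessing(self, cases: list):
        """Estimate per-channel z-score statistics from training cases."""
        endo = np.stack([c.endoscopy for c in cases]).astype(float) / 255.0
        histo = np.stack([c.histology for c in cases]).astype(float) / 255.0
        self.norm_stats = {
            "endo_mean": endo.mean(axis=(0, 1, 2)),
            "endo_std": np.maximum(endo.std(axis=(0, 1, 2)), 1e-6),
            "histo_mean": histo.mean(axis=(0, 1, 2, 3)),
            "histo_std": np.maximum(histo.std(axis=(0, 1, 2, 3)), 1e-6),
        }

    def batch_inputs(self, cases: list) -> dict:
        """Raw cases -> normalized float input tensors.

        Endoscopy and histology are scaled to [0, 1] then z-scored with the
        fitted per-channel statistics; CT is HU-clipped to [-150, 350] and
        linearly scaled to [0, 1].
        """
        s = self.norm_stats
        endo = np.stack([c.endoscopy for c in cases]).astype(float) / 255.0
        endo = (endo - s["endo_mean"]) / s["endo_std"]
        endo = endo.transpose(0, 3, 1, 2)  # NHWC -> NCHW
        ct = preprocess.clip_and_scale_hu(np.stack([c.ct for c in cases]).astype(float))
        histo = np.stack([c.histology for c in cases]).astype(float) / 255.0
        histo = (histo - s["histo_mean"]) / s["histo_std"]
        histo = histo.transpose(0, 1, 4, 2, 3)  # N,p,H,W,C -> N,p,C,H,W
        return {"endoscopy": Tensor(endo), "ct": Tensor(ct), "histology": Tensor(histo)}

    # --------------------------------------------------------------- forward
    def encode(self, inputs: dict) -> dict:
        return {
            "endoscopy": self.encoder_E(inputs["endoscopy"]),
            "ct": self.encoder_C(inputs["ct"]),
            "histology": self.encoder_H(inputs["histology"]),
        }

    def forward_tensors(self, inputs: dict):
        """Full pipeline on input tensors; returns the internal Tensors
        needed for loss/backward plus a detached :class:`PredictionRecord`."""
        emb = self.encode(inputs)
        f = [emb[m] for m in MODALITIES]
        N = f[0].shape[0]

        gates = [self.gate_E, self.gate_C, self.gate_H]
        g_m = [gate(fm).sigmoid() for gate, fm in zip(gates, f)]  # each (N,1)

        f_tilde = [gm * fm for gm, fm in zip(g_m, f)]

        routers = [self.route_E, self.route_C, self.route_H]
        logits = concatenate([r(ft) for r, ft in zip(routers, f_tilde)], axis=1)  # (N,3)
        g_i = logits.softmax(axis=-1)
        ent = -(g_i * (g_i + LOG_FLOOR).log()).sum(axis=-1)  # (N,)

        a = self.gate_blend
        # Tokens entering fusion are unit-normalized, then scaled by the
        # gate/routing product: every modality offers content of identical
        # magnitude, so the learned gates are the only channel that sets a
        # modality's contribution (keeping the routing weights identifiable).
        # The warmup blend (1-a) + a*g keeps encoder gradients alive before
        # the gates differentiate (a = 1 after warmup).
        def scaled_token(i):
            fi = f[i]
            norm = ((fi * fi).sum(axis=1, keepdims=True) + 1e-8) ** 0.5
            unit = fi * norm ** -1.0
            scale = g_i[:, i].reshape(N, 1) * g_m[i]
            return ((1.0 - a) + a * scale) * unit

        mode = self.config.fusion_mode
        if mode == "attention":
            routed = [scaled_token(i) for i in range(3)]
            tokens = concat_tokens(routed)  # (N,3,D)
            attended = self.attention(tokens)  # (N,3,D)
            # the attended tokens are summed and projected through a single
            # weight-shared map: with no slot-specific projection downstream,
            # the gate/routing scaling at the attention input is the only
            # channel that sets each modality's contribution
            fused = self.fuse_attention(attended.sum(axis=1))
        elif mode == "weighted_sum":
            mix = None
            for i in range(3):
                term = scaled_token(i)
                mix = term if mix is None else mix + term
            fused = self.fuse_weighted(mix)
        else:  # concat baseline: static fusion of raw embeddings
            fused = self.fuse_concat(concatenate(f, axis=1))

        h = self.head_dropout(self.head1(fused).relu())
        logit = self.head2(h).reshape(N)
        prob = logit.sigmoid()
        calibrated = 1.0 / (
            1.0 + np.exp(-(self.calib_scale * logit.data + self.calib_bias))
        )

        record = PredictionRecord(
            probability=calibrated,
            logit=logit.data.copy(),
            fused=fused.data.copy(),
            gate_state=GateState(
                reliability_gates=np.concatenate([g.data for g in g_m], axis=1),
                routing_weights=g_i.data.copy(),
                entropy=ent.data.copy(),
            ),
            embeddings={m: emb[m].data.copy() for m in MODALITIES},
        )
        return {"prob": prob, "logit": logit, "entropy": ent, "record": record}

    def forward(self, cases: list) -> PredictionRecord:
        """Convenience full pass from raw cases (records gate diagnostics)."""
        return self.forward_tensors(self.batch_inputs(cases))["record"]

    def predict(self, cases: list, batch_size: int = 64) -> PredictionRecord:
        """Inference pass in eval mode (dropout off, no tape)."""
        was_training = self.training
        self.set_training(False)
        try:
            records = []
            with no_grad():
                for start in range(0, len(cases), batch_size):
                    records.append(self.forward(cases[start : start + batch_size]))
            out = _concat_records(records)
        finally:
            self.set_training(was_training)
        return out

    def encoder_parameters(self) -> list:
        """Backbone parameters (excluded from optimizer weight decay:
        decaying an encoder that receives no task gradient collapses its
        output to a constant, which hides unreliable inputs from the gates;
        encoders are regularized through the explicit L2 loss term)."""
        params = []
        for m in (self.encoder_E, self.encoder_C, self.encoder_H):
            params.extend(m.parameters())
        return params

    # ------------------------------------------------------------------ loss
    def regularized_parameters(self) -> list:
        """Parameters entering the L2 term: encoders + fusion stage
        (classifier head excluded unless configured otherwise)."""
        mods = [
            self.encoder_E,
            self.encoder_C,
            self.encoder_H,
            self.gate_E,
            self.gate_C,
            self.gate_H,
            self.route_E,
            self.route_C,
            self.route_H,
            self.attention,
            self.fuse_attention,
            self.fuse_weighted,
            self.fuse_concat,
        ]
        params = []
        for m in mods:
            params.extend(m.parameters())
        if self.config.l2_include_head:
            params.extend(self.head1.parameters())
            params.extend(self.head2.parameters())
        return params


def total_loss(
    prob: Tensor,
    labels,
    entropy: Tensor,
    regularized_params: list,
    lam: float,
    beta: float,
    entropy_sign: str = "bonus",
    logit: Tensor | None = None,
):
    """Composite loss L_total = L_BCE + lam * L_ent + beta * L_L2.

    ``L_ent`` defaults to the *negative* mean routing entropy (an entropy
    bonus: minimizing the total maximizes entropy); ``entropy_sign='literal'``
    uses +H instead.  When the pre-sigmoid ``logit`` is supplied the BCE is
    computed in logit space (numerically stable softplus form, identical in
    value); otherwise from the clipped probabilities.  Returns
    (scalar Tensor, LossBreakdown).
    """
    y = np.asarray(labels, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be binary 0/1")
    if logit is not None:
        # softplus(x) - y*x = -[y log p + (1-y) log(1-p)] for p = sigmoid(x)
        x = logit
        abs_x = x.relu() + (-x).relu()
        softplus = x.relu() + (1.0 + (-abs_x).exp()).log()
        bce = (softplus - Tensor(y) * x).mean()
    else:
        p = prob.clip(LOG_FLOOR, 1.0 - LOG_FLOOR)
        bce = -(Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()).mean()
    mean_ent = entropy.mean()
    ent_term = mean_ent if entropy_sign == "literal" else -mean_ent
    # mean squared parameter ("mild" weight regularization at any width;
    # a raw sum would dominate the loss as soon as the model grows)
    l2 = None
    n_params = 0
    for param in regularized_params:
        sq = (param * param).sum()
        l2 = sq if l2 is None else l2 + sq
        n_params += param.size
    l2 = Tensor(0.0) if l2 is None else l2 * (1.0 / n_params)
    total = bce + lam * ent_term + beta * l2
    breakdown = LossBreakdown(
        total=float(total.data),
        bce=float(bce.data),
        entropy_term=float(ent_term.data),
        l2=float(l2.data),
        lam=lam,
        beta=beta,
    )
    return total, breakdown


def _concat_records(records: list) -> PredictionRecord:
    if len(records) == 1:
        return records[0]
    return PredictionRecord(
        probability=np.concatenate([r.probability for r in records]),
        logit=np.concatenate([r.logit for r in records]),
        fused=np.concatenate([r.fused for r in records]),
        gate_state=GateState(
            reliability_gates=np.concatenate([r.gate_state.reliability_gates for r in records]),
            routing_weights=np.concatenate([r.gate_state.routing_weights for r in records]),
            entropy=np.concatenate([r.gate_state.entropy for r in records]),
        ),
        embeddings={
            m: np.concatenate([r.embeddings[m] for r in records]) for m in MODALITIES
        },
    )


def _default_norm_stats() -> dict:
    return {
        "endo_mean": np.full(3, 0.5),
        "endo_std": np.full(3, 0.25),
        "histo_mean": np.full(3, 0.5),
        "histo_std": np.full(3, 0.25),
    }


# --------------------------------------------------------------------------
# checkpointing
# --------------------------------------------------------------------------


def save_checkpoint(model: IDFNet, path):
    """Save model weights + config + preprocessing stats as a ``.npz``."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(asdict(model.config)).encode(), dtype=np.uint8
    )
    for k, v in model.norm_stats.items():
        state[f"__norm__{k}"] = np.asarray(v)
    state["__gate_blend__"] = np.asarray(model.gate_blend)
    state["__calibration__"] = np.asarray([model.calib_scale, model.calib_bias])
    np.savez(path, **state)


def load_checkpoint(path) -> IDFNet:
    with np.load(path) as data:
        cfg = ModelConfig(**json.loads(bytes(data["__config__"].tobytes()).decode()))
        model = IDFNet(cfg)
        model.norm_stats = {
            k[len("__norm__") :]: data[k] for k in data.files if k.startswith("__norm__")
        }
        if "__gate_blend__" in data.files:
            model.gate_blend = float(data["__gate_blend__"])
        if "__calibration__" in data.files:
            model.calib_scale, model.calib_bias = (
                float(v) for v in data["__calibration__"]
            )
        model.load_state_dict(
            {k: data[k] for k in data.files if not k.startswith("__")}
        )
    return model
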