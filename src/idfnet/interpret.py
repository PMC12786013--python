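"""Quantitative interpretability: Grad-CAM++ spatial saliency per modality,
saliency-vs-lesion-mask IoU, and exact per-modality Shapley attribution.

Shapley attribution treats the three modalities as players in a cooperative
game whose value function is the model's malignancy probability with the
modalities outside the coalition replaced by the zero-input used in the
missing-modality protocol.  With only 3 players the 2^3 = 8 coalition
values are enumerated exactly, so the attribution satisfies the efficiency,
null-player and symmetry axioms to machine precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .encoders import TinyCNN, TinyViT
from .fusion import IDFNet, GateState
from .synthdata import MODALITIES, TrimodalCase
from .training import simulate_missing

logger = logging.getLogger(__name__)


@dataclass
class SaliencyMap:
    modality: str
    map: np.ndarray  # (H, W) or (k, H, W), values in [0, 1]
    target_layer: str
    threshold: float = 0.5


@dataclass
class AttributionProfile:
    phi: dict  # modality -> Shapley value
    baseline: float  # v(empty coalition)
    full: float  # v(all three modalities)


@dataclass
class ExplanationBundle:
    case_id: str
    probability: float
    saliency: dict  # modality -> SaliencyMap
    iou: dict  # modality -> float (only where a non-empty mask exists)
    attribution: AttributionProfile
    gate_state: GateState


# --------------------------------------------------------------------------
# Grad-CAM++
# --------------------------------------------------------------------------


def _grad_cam_pp_from_activation(activation: np.ndarray, gradient: np.ndarray, out_shape):
    """Grad-CAM++ closed form on one activation map (C, h, w) with its
    gradient; returns the upsampled, min-max-normalized saliency map."""
    A, G = activation, gradient
    g2, g3 = G * G, G * G * G
    sum_ag3 = (A * g3).sum(axis=(1, 2), keepdims=True)
    denom = 2.0 * g2 + sum_ag3
    alpha = np.where(np.abs(denom) > 1e-12, g2 / np.where(denom == 0, 1.0, denom), 0.0)
    weights = (alpha * np.maximum(G, 0.0)).sum(axis=(1, 2))  # (C,)
    cam = np.maximum((weights[:, None, None] * A).sum(axis=0), 0.0)
    cam = resize(cam, out_shape, order=1, anti_aliasing=False)
    cam = np.maximum(cam, 0.0)
    peak = cam.max()
    if peak <= 0:
        logger.warning("zero-gradient Grad-CAM++ map; returning all zeros")
        return np.zeros(out_shape)
    return cam / peak


DEFAULT_TARGET_LAYER = "conv2"


def _target_activation(model: IDFNet, modality: str, target_layer: str | None):
    encoder = {
        "endoscopy": model.encoder_E,
        "ct": model.encoder_C,
        "histology": model.encoder_H,
    }[modality]
    backbone = encoder.backbone
    if isinstance(backbone, TinyCNN):
        layer = target_layer or DEFAULT_TARGET_LAYER
        if layer not in backbone.feature_maps:
            raise ValueError(
                f"unknown target layer {layer!r}; available: {sorted(backbone.feature_maps)}"
            )
        return backbone.feature_maps[layer], layer
    if isinstance(backbone, TinyViT):
        return backbone.last_token_grid, "token_grid"
    raise ValueError(f"no saliency target layer for backbone {type(backbone).__name__}")


def grad_cam_pp(
    model: IDFNet, case: TrimodalCase, modality: str, target_layer: str | None = None
) -> SaliencyMap:
    """Grad-CAM++ saliency for one modality of one case.

    Gradients of the pre-sigmoid malignancy logit are taken at a
    convolutional feature map (CNN backbones; default the middle block,
    whose spatial resolution still resolves lesion-scale structure — the
    deepest block's grid is coarser than the thinnest planted lesions) or
    at the final patch-token grid reshaped to a spatial map (transformer
    backbones).  The map is upsampled to input resolution and min-max
    normalized; a degenerate zero-gradient case yields an all-zero map
    with a warning.
    """
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    was_training = model.training
    model.set_training(False)
    try:
        model.zero_grad()
        out = model.forward_tensors(model.batch_inputs([case]))
        act_tensor, layer_name = _target_activation(model, modality, target_layer)
        out["logit"].backward(np.ones(1))
        acts = act_tensor.data
        grads = act_tensor.grad
        if grads is None:
            grads = np.zeros_like(acts)
    finally:
        model.set_training(was_training)

    size = case.endoscopy.shape[0]
    # acts: (n_planes, C, h, w) where planes are CT slices / histology patches
    maps = np.stack(
        [
            _grad_cam_pp_from_activation(acts[i], grads[i], (size, size))
            for i in range(acts.shape[0])
        ]
    )
    sal = maps[0] if maps.shape[0] == 1 else maps
    return SaliencyMap(modality=modality, map=sal, target_layer=layer_name)


def saliency_iou(saliency: np.ndarray, mask: np.ndarray, threshold: float = 0.5) -> float:
    """IoU between the thresholded saliency map and a binary lesion mask.

    Both-empty is defined as IoU = 1.0 (with a warning): a map that marks
    nothing on a lesion-free image is a perfect match.
    """
    s = np.asarray(saliency, dtype=float)
    m = np.asarray(mask).astype(bool)
    if s.shape != m.shape:
        raise ValueError(f"shape mismatch: saliency {s.shape} vs mask {m.shape}")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    binary = s >= threshold
    union = (binary | m).sum()
    if union == 0:
        logger.warning("both saliency and mask empty; IoU defined as 1.0")
        return 1.0
    return float((binary & m).sum() / union)


# --------------------------------------------------------------------------
# exact Shapley attribution over the 3-modality coalition lattice
# --------------------------------------------------------------------------


def exact_shapley(value: dict, players: tuple = MODALITIES) -> dict:
    """Exact Shapley values from a complete coalition-value table.

    ``value`` maps ``frozenset`` coalitions (all 2^n of them) to floats.
    """
    n = len(players)
    phi = {}
    for m in players:
        others = [p for p in players if p != m]
        total = 0.0
        for bits in range(2 ** (n - 1)):
            S = frozenset(p for i, p in enumerate(others) if bits >> i & 1)
            w = math.factorial(len(S)) * math.factorial(n - len(S) - 1) / math.factorial(n)
            total += w * (value[S | {m}] - value[S])
        phi[m] = total
    return phi


def shapley_permutation_estimate(
    value_fn, players: tuple = MODALITIES, n_permutations: int = 200, seed: int = 0
) -> dict:
    """Monte-Carlo Shapley estimate by sampling player orderings; converges
    to the exact enumeration and serves as its independent cross-check."""
    rng = np.random.default_rng(seed)
    players = tuple(players)
    phi = {p: 0.0 for p in players}
    order = list(players)
    for _ in range(n_permutations):
        rng.shuffle(order)
        S: frozenset = frozenset()
        v_prev = value_fn(S)
        for p in order:
            S = S | {p}
            v_new = value_fn(S)
            phi[p] += v_new - v_prev
            v_prev = v_new
    return {p: v / n_permutations for p, v in phi.items()}


def coalition_values(model: IDFNet, case: TrimodalCase) -> dict:
    """Model probability for every modality coalition, absent modalities
    replaced by the zero-input of the missing-modality protocol."""
    values = {}
    for bits in range(8):
        S = frozenset(m for i, m in enumerate(MODALITIES) if bits >> i & 1)
        c = case
        for m in MODALITIES:
            if m not in S:
                c = simulate_missing(c, m)
        values[S] = float(model.predict([c]).probability[0])
    return values


def modality_shapley(model: IDFNet, case: TrimodalCase) -> AttributionProfile:
    """Exact per-modality Shapley attribution of the malignancy probability."""
    values = coalition_values(model, case)
    phi = exact_shapley(values)
    return AttributionProfile(
        phi=phi,
        baseline=values[frozenset()],
        full=values[frozenset(MODALITIES)],
    )


# --------------------------------------------------------------------------
# full per-case explanation
# --------------------------------------------------------------------------


def explain_case(
    model: IDFNet, case: TrimodalCase, iou_threshold: float = 0.5
) -> ExplanationBundle:
    """Saliency maps for all three modalities, IoU against any non-empty
    lesion masks, exact Shapley attribution, and the gate diagnostics."""
    record = model.predict([case])
    saliency = {m: grad_cam_pp(model, case, m) for m in MODALITIES}
    iou = {}
    for m in MODALITIES:
        mask = case.masks.get(m)
        if mask is None or not np.any(mask):
            continue
        sal = saliency[m].map
        msk = np.asarray(mask)
        if sal.ndim == 2 and msk.ndim == 3 and msk.shape[0] == 1:
            msk = msk[0]
        iou[m] = saliency_iou(sal, msk, iou_threshold)
        saliency[m].threshold = iou_threshold
    return ExplanationBundle(
        case_id=case.case_id,
        probability=float(record.probability[0]),
        saliency=saliency,
        iou=iou,
        attribution=modality_shapley(model, case),
        gate_state=record.gate_state,
    )
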