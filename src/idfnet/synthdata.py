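"""Seeded synthetic trimodal imaging cases with known ground truth.

Each case carries three modality renderings of one latent benign/malignant
label, pixel-accurate lesion masks, and a planted per-modality *reliability*
in [0, 1] that blends the clean rendering with pure noise.  The cues are
deliberately simple geometric/textural primitives so that very small
encoders can learn them quickly on a CPU:

* **endoscopy** — RGB mucosa-like background; malignant cases carry a
  textured elliptical protrusion (polyp-like).
* **ct** — Hounsfield-unit bowel-wall ring phantom; malignant cases carry a
  locally thickened wall segment.  Pixel values live on the HU scale
  [-1000, 1000] so downstream HU clipping is exercised for real.
* **histology** — eosin-like background with scattered nuclear dots;
  malignant cases carry a region of strongly elevated nuclear density.

Reliability ``r`` mixes ``image = r * clean + (1 - r) * noise`` where the
noise is clipped Gaussian mixing iid pixels with a smooth low-frequency
component (structured acquisition artifacts), so ``r = 0`` carries no label
information at all and ``r = 1`` is the clean rendering.

Independently of reliability, every malignant rendering draws a per-case,
per-modality *visibility* factor scaling the lesion cue's contrast, and
with probability ``miss_rate`` a modality misses the lesion almost entirely
(visibility near zero).  This emulates the clinical fact that no single
modality shows every tumour clearly: each modality alone is an imperfect
classifier (single-modality AUC around 0.9 at the defaults), the misses are
independent across modalities, and fusing the three genuinely helps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

logger = logging.getLogger(__name__)

MODALITIES = ("endoscopy", "ct", "histology")

HU_RANGE = (-1000.0, 1000.0)

_KNOWN_COLUMNS = {
    "case_id",
    "patient_id",
    "label",
    "endo_path",
    "ct_path",
    "histo_path",
    "endo_mask_path",
    "ct_mask_path",
    "histo_mask_path",
    "present_endo",
    "present_ct",
    "present_histo",
    "reliability_endo",
    "reliability_ct",
    "reliability_histo",
}


def _check_reliability(value):
    """Accept a float or a (lo, hi) sampling range; return normalized form."""
    if np.isscalar(value):
        v = float(value)
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"reliability must be in [0, 1], got {v}")
        return v
    lo, hi = (float(v) for v in value)
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"reliability range must satisfy 0 <= lo <= hi <= 1, got ({lo}, {hi})")
    return (lo, hi)


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic trimodal dataset.

    ``reliability`` may be a single float, a (lo, hi) uniform sampling
    range, or a per-modality dict of either.
    """

    n_cases: int
    class_balance: float = 0.5
    image_size: int = 64
    reliability: object = 1.0
    cases_per_patient: int = 1
    seed: int = 0
    n_ct_slices: int = 1
    n_histology_patches: int = 1
    visibility: tuple = (0.6, 1.0)  # per-case per-modality lesion contrast
    # chance a modality barely shows the lesion (scalar, or per-modality
    # dict emulating different detection sensitivities)
    miss_rate: object = 0.12

    def __post_init__(self):
        if self.n_cases < 2:
            raise ValueError(f"n_cases must be >= 2, got {self.n_cases}")
        if not 0.0 <= self.class_balance <= 1.0:
            raise ValueError(f"class_balance must be in [0, 1], got {self.class_balance}")
        if self.image_size < 16:
            raise ValueError(f"image_size must be >= 16, got {self.image_size}")
        if self.cases_per_patient < 1:
            raise ValueError("cases_per_patient must be a positive integer")
        if self.n_cases < self.cases_per_patient:
            raise ValueError(
                f"n_cases ({self.n_cases}) must be >= cases_per_patient ({self.cases_per_patient})"
            )
        if self.n_ct_slices < 1 or self.n_histology_patches < 1:
            raise ValueError("slice/patch counts must be positive")
        lo, hi = self.visibility
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("visibility must be a (lo, hi) range inside [0, 1]")
        if isinstance(self.miss_rate, dict):
            unknown = set(self.miss_rate) - set(MODALITIES)
            if unknown:
                raise ValueError(f"unknown modalities in miss_rate: {sorted(unknown)}")
            self.miss_rate = {m: float(self.miss_rate.get(m, 0.12)) for m in MODALITIES}
        else:
            self.miss_rate = {m: float(self.miss_rate) for m in MODALITIES}
        for m, q in self.miss_rate.items():
            if not 0.0 <= q < 1.0:
                raise ValueError(f"miss_rate for {m} must lie in [0, 1)")
        self.reliability = self._normalize_reliability(self.reliability)

    @staticmethod
    def _normalize_reliability(rel) -> dict:
        if isinstance(rel, dict):
            unknown = set(rel) - set(MODALITIES)
            if unknown:
                raise ValueError(f"unknown modalities in reliability spec: {sorted(unknown)}")
            return {m: _check_reliability(rel.get(m, 1.0)) for m in MODALITIES}
        v = _check_reliability(rel)
        return {m: v for m in MODALITIES}

    def sample_reliability(self, rng: np.random.Generator) -> dict:
        out = {}
        for m in MODALITIES:
            v = self.reliability[m]
            out[m] = float(rng.uniform(*v)) if isinstance(v, tuple) else v
        return out


@dataclass
class TrimodalCase:
    """One patient case: three modality image stacks plus ground truth."""

    case_id: str
    patient_id: str
    label: int
    endoscopy: np.ndarray  # (H, W, 3) uint8
    ct: np.ndarray  # (k, H, W) int16 on the HU scale
    histology: np.ndarray  # (p, H, W, 3) uint8
    masks: dict = field(default_factory=dict)  # modality -> bool array
    present: dict = field(default_factory=lambda: {m: True for m in MODALITIES})
    reliability: dict = field(default_factory=lambda: {m: 1.0 for m in MODALITIES})

    def copy(self) -> "TrimodalCase":
        return TrimodalCase(
            case_id=self.case_id,
            patient_id=self.patient_id,
            label=self.label,
            endoscopy=self.endoscopy.copy(),
            ct=self.ct.copy(),
            histology=self.histology.copy(),
            masks={k: v.copy() for k, v in self.masks.items()},
            present=dict(self.present),
            reliability=dict(self.reliability),
        )


@dataclass
class TrimodalDataset:
    cases: list
    manifest: pd.DataFrame
    spec: SyntheticSpec | None = None

    def __len__(self):
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)

    def labels(self) -> np.ndarray:
        return np.array([c.label for c in self.cases], dtype=int)

    def subset(self, indices) -> "TrimodalDataset":
        cases = [self.cases[i] for i in indices]
        manifest = self.manifest.iloc[list(indices)].reset_index(drop=True)
        return TrimodalDataset(cases, manifest, self.spec)


# --------------------------------------------------------------------------
# rendering primitives
# --------------------------------------------------------------------------


def _smooth_noise(rng, size, sigma, amplitude):
    from scipy.ndimage import gaussian_filter

    n = gaussian_filter(rng.standard_normal((size, size)), sigma)
    scale = n.std()
    return amplitude * n / (scale + 1e-12)


def _ellipse_mask(size, center, axes, rng) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    theta = rng.uniform(0, np.pi)
    dy, dx = yy - center[0], xx - center[1]
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return (u / axes[0]) ** 2 + (v / axes[1]) ** 2 <= 1.0


def _render_endoscopy(size, label, rng, visibility=1.0):
    base = np.array([0.78, 0.47, 0.42])
    img = np.empty((size, size, 3))
    shading = _smooth_noise(rng, size, size / 8.0, 0.08)
    for c in range(3):
        img[..., c] = base[c] + shading + _smooth_noise(rng, size, 2.0, 0.03)
    mask = np.zeros((size, size), dtype=bool)
    if label == 1:
        center = rng.uniform(0.3 * size, 0.7 * size, size=2)
        axes = rng.uniform(0.14 * size, 0.22 * size, size=2)
        mask = _ellipse_mask(size, center, axes, rng)
        texture = _smooth_noise(rng, size, 1.0, 0.18)
        lesion = np.stack(
            [0.55 + texture, 0.25 + texture, 0.30 + 0.5 * texture], axis=-1
        )
        v = visibility
        img[mask] = (1.0 - v) * img[mask] + v * lesion[mask]
    return np.clip(img, 0, 1), mask


def _render_ct_slice(size, label, rng, visibility=1.0):
    yy, xx = np.mgrid[0:size, 0:size]
    center = (size / 2.0 + rng.uniform(-0.04, 0.04) * size,
              size / 2.0 + rng.uniform(-0.04, 0.04) * size)
    r = np.hypot(yy - center[0], xx - center[1])
    R = 0.30 * size * rng.uniform(0.9, 1.1)
    wall = 0.06 * size
    img = 30.0 + 12.0 * rng.standard_normal((size, size))  # soft tissue
    img[r < R - wall] = -80.0 + 12.0 * rng.standard_normal(((r < R - wall).sum(),))  # lumen
    ring = (r >= R - wall) & (r <= R)
    img[ring] = 90.0 + 10.0 * rng.standard_normal((ring.sum(),))
    mask = np.zeros((size, size), dtype=bool)
    if label == 1:
        phi = np.arctan2(yy - center[0], xx - center[1])
        phi0 = rng.uniform(-np.pi, np.pi)
        span = np.deg2rad(rng.uniform(110, 160))
        dphi = np.angle(np.exp(1j * (phi - phi0)))
        sector = np.abs(dphi) <= span / 2.0
        thick = (r >= R - 3.0 * wall) & (r <= R + wall) & sector & (r <= 0.48 * size)
        # contrast-enhancing tumour segment: brighter than the normal wall
        img[thick] = (1.0 - visibility) * img[thick] + visibility * (
            160.0 + 12.0 * rng.standard_normal((thick.sum(),))
        )
        mask = thick
    return np.clip(img, *HU_RANGE), mask


def _stamp_dots(img, size, n_dots, region_mask, rng):
    """Stamp dark nuclear dots whose centres fall inside ``region_mask``."""
    ys, xs = np.nonzero(region_mask)
    if len(ys) == 0 or n_dots == 0:
        return
    idx = rng.integers(0, len(ys), size=n_dots)
    yy, xx = np.mgrid[0:size, 0:size]
    color = np.array([0.36, 0.20, 0.52])
    for y0, x0 in zip(ys[idx], xs[idx]):
        rad = rng.uniform(0.9, 1.8)
        disk = (yy - y0) ** 2 + (xx - x0) ** 2 <= rad ** 2
        img[disk] = color + rng.normal(0, 0.02, size=3)


def _render_histology(size, label, rng, visibility=1.0):
    base = np.array([0.93, 0.76, 0.86])
    img = np.empty((size, size, 3))
    for c in range(3):
        img[..., c] = base[c] + _smooth_noise(rng, size, 3.0, 0.03)
    area = size * size
    everywhere = np.ones((size, size), dtype=bool)
    _stamp_dots(img, size, int(0.010 * area), everywhere, rng)
    mask = np.zeros((size, size), dtype=bool)
    if label == 1:
        center = rng.uniform(0.3 * size, 0.7 * size, size=2)
        axes = rng.uniform(0.14 * size, 0.24 * size, size=2)
        mask = _ellipse_mask(size, center, axes, rng)
        _stamp_dots(img, size, int(visibility * 0.13 * mask.sum()), mask, rng)
    return np.clip(img, 0, 1), mask


def _noise_field(rng, shape):
    """Unit-variance noise mixing iid pixels with a smooth low-frequency
    component (structured acquisition artifacts), so unreliable images vary
    coherently from case to case instead of averaging out under pooling."""
    from scipy.ndimage import gaussian_filter

    white = rng.standard_normal(shape)
    spatial = shape[:2] if len(shape) >= 2 else shape
    sigma = [max(s / 8.0, 1.0) for s in spatial] + [0] * (len(shape) - len(spatial))
    smooth = gaussian_filter(rng.standard_normal(shape), sigma)
    smooth = smooth / (smooth.std() + 1e-12)
    return 0.5 * white + 0.5 * smooth


def _blend_unit(clean, r, rng):
    noise = np.clip(0.5 + 0.25 * _noise_field(rng, clean.shape), 0.0, 1.0)
    return r * clean + (1.0 - r) * noise


def _blend_hu(clean, r, rng):
    noise = np.clip(100.0 + 400.0 * _noise_field(rng, clean.shape), *HU_RANGE)
    return r * clean + (1.0 - r) * noise


# --------------------------------------------------------------------------
# case / dataset generation
# --------------------------------------------------------------------------


def generate_case(
    spec: SyntheticSpec,
    label: int,
    reliability_triplet,
    rng: np.random.Generator,
    case_id: str = "case0",
    patient_id: str = "pt0",
) -> TrimodalCase:
    """Render one trimodal case with the given label and reliabilities."""
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    if isinstance(reliability_triplet, dict):
        rel = {m: float(reliability_triplet[m]) for m in MODALITIES}
    else:
        rel = dict(zip(MODALITIES, (float(v) for v in reliability_triplet)))
    for m, v in rel.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"reliability for {m} must be in [0, 1], got {v}")

    size = spec.image_size
    vis_lo, vis_hi = spec.visibility
    vis = {}
    for m in MODALITIES:
        missed = rng.random() < spec.miss_rate[m]
        vis[m] = float(rng.uniform(0.0, 0.1)) if missed else float(rng.uniform(vis_lo, vis_hi))

    endo_clean, endo_mask = _render_endoscopy(size, label, rng, vis["endoscopy"])
    endo = _blend_unit(endo_clean, rel["endoscopy"], rng)
    endo_u8 = np.round(endo * 255).astype(np.uint8)

    ct_slices, ct_masks = [], []
    for _ in range(spec.n_ct_slices):
        sl, m = _render_ct_slice(size, label, rng, vis["ct"])
        sl = _blend_hu(sl, rel["ct"], rng)
        ct_slices.append(np.round(sl).astype(np.int16))
        ct_masks.append(m)
    ct = np.stack(ct_slices)
    ct_mask = np.stack(ct_masks)

    h_patches, h_masks = [], []
    for _ in range(spec.n_histology_patches):
        patch, m = _render_histology(size, label, rng, vis["histology"])
        patch = _blend_unit(patch, rel["histology"], rng)
        h_patches.append(np.round(patch * 255).astype(np.uint8))
        h_masks.append(m)
    histo = np.stack(h_patches)
    histo_mask = np.stack(h_masks)

    return TrimodalCase(
        case_id=case_id,
        patient_id=patient_id,
        label=int(label),
        endoscopy=endo_u8,
        ct=ct,
        histology=histo,
        masks={"endoscopy": endo_mask, "ct": ct_mask, "histology": histo_mask},
        reliability=rel,
    )


def _patient_blocks(n_cases: int, cases_per_patient: int, n_malignant: int):
    """Group cases into patients so no patient straddles the class boundary."""
    blocks = []
    for label, total in ((1, n_malignant), (0, n_cases - n_malignant)):
        remaining = total
        while remaining > 0:
            size = min(cases_per_patient, remaining)
            blocks.append((label, size))
            remaining -= size
    return blocks


def generate_dataset(spec: SyntheticSpec) -> TrimodalDataset:
    """Generate ``spec.n_cases`` seeded trimodal cases plus a manifest."""
    rng = np.random.default_rng(spec.seed)
    n_malignant = int(round(spec.class_balance * spec.n_cases))
    blocks = _patient_blocks(spec.n_cases, spec.cases_per_patient, n_malignant)
    # shuffle patient order so folds/splits see mixed labels
    order = rng.permutation(len(blocks))

    cases = []
    rows = []
    case_idx = 0
    for patient_idx, block_i in enumerate(order):
        label, size = blocks[block_i]
        patient_id = f"pt{patient_idx:04d}"
        for _ in range(size):
            case_id = f"case{case_idx:05d}"
            rel = spec.sample_reliability(rng)
            case = generate_case(spec, label, rel, rng, case_id=case_id, patient_id=patient_id)
            cases.append(case)
            rows.append(
                {
                    "case_id": case_id,
                    "patient_id": patient_id,
                    "label": label,
                    "endo_path": f"images/{case_id}_endo.png",
                    "ct_path": ";".join(
                        f"images/{case_id}_ct{s}.png" for s in range(spec.n_ct_slices)
                    ),
                    "histo_path": ";".join(
                        f"images/{case_id}_histo{p}.png"
                        for p in range(spec.n_histology_patches)
                    ),
                    "endo_mask_path": f"masks/{case_id}_endo.png" if label else "",
                    "ct_mask_path": ";".join(
                        f"masks/{case_id}_ct{s}.png" for s in range(spec.n_ct_slices)
                    )
                    if label
                    else "",
                    "histo_mask_path": ";".join(
                        f"masks/{case_id}_histo{p}.png"
                        for p in range(spec.n_histology_patches)
                    )
                    if label
                    else "",
                    "present_endo": True,
                    "present_ct": True,
                    "present_histo": True,
                    "reliability_endo": rel["endoscopy"],
                    "reliability_ct": rel["ct"],
                    "reliability_histo": rel["histology"],
                }
            )
            case_idx += 1
    manifest = pd.DataFrame(rows)
    return TrimodalDataset(cases, manifest, spec)


# --------------------------------------------------------------------------
# PNG + CSV round trip
# --------------------------------------------------------------------------


def _write_png_rgb(arr: np.ndarray, path: Path):
    Image.fromarray(arr, mode="RGB").save(path)


def _write_png_hu(arr: np.ndarray, path: Path):
    # store HU + 1000 as 16-bit grayscale: lossless for integer HU in [-1000, 1000]
    Image.fromarray((arr.astype(np.int32) + 1000).astype(np.uint16)).save(path)


def _write_png_mask(arr: np.ndarray, path: Path):
    Image.fromarray((arr.astype(np.uint8)) * 255, mode="L").save(path)


def _read_png(path: Path, case_id: str) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"file {path} referenced by manifest for case {case_id} is missing")
    return np.asarray(Image.open(path))


def write_dataset(dataset: TrimodalDataset, out_dir) -> Path:
    """Write cases as PNGs plus a CSV manifest under ``out_dir``."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for case, (_, row) in zip(dataset.cases, dataset.manifest.iterrows()):
        _write_png_rgb(case.endoscopy, out / row["endo_path"])
        for s, p in enumerate(row["ct_path"].split(";")):
            _write_png_hu(case.ct[s], out / p)
        for s, p in enumerate(row["histo_path"].split(";")):
            _write_png_rgb(case.histology[s], out / p)
        if row["endo_mask_path"]:
            _write_png_mask(case.masks["endoscopy"], out / row["endo_mask_path"])
        if row["ct_mask_path"]:
            for s, p in enumerate(row["ct_mask_path"].split(";")):
                _write_png_mask(case.masks["ct"][s], out / p)
        if row["histo_mask_path"]:
            for s, p in enumerate(row["histo_mask_path"].split(";")):
                _write_png_mask(case.masks["histology"][s], out / p)
    dataset.manifest.to_csv(out / "manifest.csv", index=False)
    return out


def read_dataset(path) -> TrimodalDataset:
    """Read a dataset written by :func:`write_dataset`.

    Unknown manifest columns are ignored with a logged warning; missing mask
    files for benign cases are treated as empty masks; missing image files
    raise an error naming the case.
    """
    root = Path(path)
    manifest_path = root / "manifest.csv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.csv under {root}")
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    unknown = set(manifest.columns) - _KNOWN_COLUMNS
    if unknown:
        logger.warning("ignoring unknown manifest columns: %s", sorted(unknown))
        manifest = manifest.drop(columns=sorted(unknown))

    cases = []
    for _, row in manifest.iterrows():
        cid = row["case_id"]
        endo = _read_png(root / row["endo_path"], cid).astype(np.uint8)
        ct = np.stack(
            [
                _read_png(root / p, cid).astype(np.int32) - 1000
                for p in row["ct_path"].split(";")
            ]
        ).astype(np.int16)
        histo = np.stack(
            [_read_png(root / p, cid).astype(np.uint8) for p in row["histo_path"].split(";")]
        )
        size = endo.shape[0]

        def read_mask(col, shape):
            spec_paths = str(row.get(col, "") or "")
            if not spec_paths:
                return np.zeros(shape, dtype=bool)
            planes = []
            for p in spec_paths.split(";"):
                fp = root / p
                if not fp.exists():
                    planes.append(np.zeros(shape[-2:], dtype=bool))
                else:
                    planes.append(np.asarray(Image.open(fp)) > 127)
            out = np.stack(planes)
            return out[0] if len(shape) == 2 else out

        masks = {
            "endoscopy": read_mask("endo_mask_path", (size, size)),
            "ct": read_mask("ct_mask_path", ct.shape),
            "histology": read_mask("histo_mask_path", histo.shape[:3]),
        }
        def as_bool(v):
            return str(v).strip().lower() in ("true", "1", "1.0", "yes")

        present = {
            "endoscopy": as_bool(row.get("present_endo", True)),
            "ct": as_bool(row.get("present_ct", True)),
            "histology": as_bool(row.get("present_histo", True)),
        }
        rel = {
            "endoscopy": float(row.get("reliability_endo", 1.0)),
            "ct": float(row.get("reliability_ct", 1.0)),
            "histology": float(row.get("reliability_histo", 1.0)),
        }
        cases.append(
            TrimodalCase(
                case_id=cid,
                patient_id=row["patient_id"],
                label=int(row["label"]),
                endoscopy=endo,
                ct=ct,
                histology=histo,
                masks=masks,
                present=present,
                reliability=rel,
            )
        )
    return TrimodalDataset(cases, manifest)
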