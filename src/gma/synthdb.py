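"""Synthetic hand-over-texture database generator.

Emulates a supervised-evaluation image set: procedural hand-shaped
foregrounds (palm ellipse plus five finger capsules, seeded pose
jitter) filled with a skin-tone model, composited over procedural
texture backgrounds from 17 named families.  Each composite is
illumination-equalized (histogram equalization of the YCbCr Y channel
only) and opened with a disk structuring element of radius 5 pixels to
fade the hand/background boundary.  Every image ships with its exact
binary ground-truth mask, so the construction doubles as ground truth.

The generator is fully deterministic from (config, master seed).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import color, exposure, morphology

from .errors import ContractError, ParameterError

log = logging.getLogger(__name__)

#: the 17 background texture families (headline-table order)
TEXTURE_FAMILIES = (
    "carpets",
    "paper",
    "stones",
    "fabric",
    "parquet",
    "tiles",
    "glass",
    "pavement",
    "tree",
    "grass",
    "skin_and_fur",
    "wall",
    "mud",
    "sky",
    "wood",
    "objects",
    "soil",
)

#: radius (pixels) of the disk structuring element for boundary fading
OPENING_RADIUS = 5


# ---------------------------------------------------------------------------
# hand silhouettes


def make_hand_mask(height: int, width: int, pose_seed: int) -> np.ndarray:
    """Hand-like binary silhouette: palm ellipse plus five finger
    capsules with seeded jitter in lengths, spread and global pose.

    The silhouette is a single connected component occupying 15-50% of
    the frame.
    """
    if height < 64 or width < 64:
        raise ParameterError("frame must be at least 64x64 for the hand template")
    rng = np.random.default_rng(pose_seed)
    unit = min(height, width)
    theta = np.deg2rad(rng.uniform(-25.0, 25.0))
    center = np.array(
        [
            height / 2 + rng.uniform(-0.06, 0.06) * unit,
            width / 2 + rng.uniform(-0.06, 0.06) * unit,
        ]
    )
    palm_rx = 0.155 * unit * rng.uniform(0.9, 1.1)  # col semi-axis
    palm_ry = 0.185 * unit * rng.uniform(0.9, 1.1)  # row semi-axis
    # finger parameters in the canonical (un-rotated) frame: angles
    # measured from "up" (negative row direction)
    finger_angles = np.deg2rad(
        np.array([-32.0, -12.0, 6.0, 25.0]) + rng.uniform(-5.0, 5.0, size=4)
    )
    finger_lengths = unit * np.array([0.30, 0.38, 0.41, 0.33]) * rng.uniform(
        0.85, 1.1, size=4
    )
    finger_radius = 0.040 * unit * rng.uniform(0.9, 1.1)
    thumb_angle = np.deg2rad(68.0 + rng.uniform(-6.0, 6.0))
    thumb_length = 0.26 * unit * rng.uniform(0.85, 1.1)
    thumb_radius = finger_radius * 1.15

    rr, cc = np.mgrid[0:height, 0:width].astype(float)
    dr = rr - center[0]
    dc = cc - center[1]
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    # rotate into the canonical frame
    ur = cos_t * dr + sin_t * dc
    uc = -sin_t * dr + cos_t * dc

    scale = 1.0
    for _ in range(12):
        mask = _rasterize_hand(
            ur,
            uc,
            palm_rx * scale,
            palm_ry * scale,
            finger_angles,
            finger_lengths * scale,
            finger_radius * scale,
            thumb_angle,
            thumb_length * scale,
            thumb_radius * scale,
        )
        frac = mask.mean()
        if 0.15 <= frac <= 0.50:
            break
        scale *= 1.12 if frac < 0.15 else 0.9
    else:
        raise ParameterError("could not fit hand template into the frame")

    # safety: clipping at the frame edge cannot split the silhouette, but
    # keep the guarantee explicit
    lab, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    return mask.astype(np.uint8)


def _rasterize_hand(
    ur,
    uc,
    palm_rx,
    palm_ry,
    finger_angles,
    finger_lengths,
    finger_radius,
    thumb_angle,
    thumb_length,
    thumb_radius,
) -> np.ndarray:
    mask = (uc / palm_rx) ** 2 + (ur / palm_ry) ** 2 <= 1.0
    for ang, length in zip(finger_angles, finger_lengths):
        base = np.array([-0.85 * palm_ry * np.cos(ang), 0.9 * palm_rx * np.sin(ang)])
        tip = base + length * np.array([-np.cos(ang), np.sin(ang)])
        mask |= _capsule(ur, uc, base, tip, finger_radius)
    base = np.array([0.1 * palm_ry, 0.85 * palm_rx * np.sign(np.sin(thumb_angle))])
    tip = base + thumb_length * np.array([-np.cos(thumb_angle), np.sin(thumb_angle)])
    mask |= _capsule(ur, uc, base, tip, thumb_radius)
    return mask


def _capsule(ur, uc, p0, p1, radius) -> np.ndarray:
    """Points within ``radius`` of the segment p0-p1 ((row, col) coords)."""
    d = p1 - p0
    len2 = float(d @ d)
    if len2 == 0:
        t = np.zeros_like(ur)
    else:
        t = np.clip(((ur - p0[0]) * d[0] + (uc - p0[1]) * d[1]) / len2, 0.0, 1.0)
    dr = ur - (p0[0] + t * d[0])
    dc = uc - (p0[1] + t * d[1])
    return dr * dr + dc * dc <= radius * radius


# ---------------------------------------------------------------------------
# skin fill and ground truth from blue backgrounds


def make_skin(height: int, width: int, seed: int) -> np.ndarray:
    """Skin-tone RGB fill: warm base colour plus correlated
    low-frequency shading, per-seed tone jitter."""
    rng = np.random.default_rng(seed)
    base = np.array([0.85, 0.58, 0.47]) + rng.uniform(-0.02, 0.02, size=3)
    shade = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), sigma=min(height, width) / 8
    )
    shade = 0.025 * shade / max(shade.std(), 1e-9)
    img = base[None, None, :] * (1.0 + shade[..., None])
    fine = 0.005 * rng.standard_normal((height, width, 3))
    return np.clip(img + fine, 0.0, 1.0)


def threshold_ground_truth(blue_bg_image: np.ndarray) -> np.ndarray:
    """Hand mask from a photo on a predominantly blue background.

    Thresholds the CIELAB b* channel (blue backgrounds sit far negative,
    skin positive) at the Otsu point and keeps the largest connected
    component, holes filled.  Returns an all-zero mask with a warning if
    no foreground separates.
    """
    arr = np.asarray(blue_bg_image)
    if arr.dtype == np.uint8:
        arr = arr.astype(float) / 255.0
    b_star = color.rgb2lab(arr)[..., 2]
    if float(b_star.max() - b_star.min()) < 5.0:
        warnings.warn("no foreground found: b* channel is flat", stacklevel=2)
        return np.zeros(b_star.shape, dtype=np.uint8)
    from skimage.filters import threshold_otsu

    mask = b_star > threshold_otsu(b_star)
    if not mask.any() or mask.all():
        warnings.warn("no foreground found after thresholding", stacklevel=2)
        return np.zeros(b_star.shape, dtype=np.uint8)
    lab, n = ndimage.label(mask)
    sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
    mask = lab == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask).astype(np.uint8)


# ---------------------------------------------------------------------------
# procedural textures

# per-family recipe: two palette colours, pattern kind and feature scale.
# "skin_and_fur" and "soil" deliberately overlap skin chromaticity (the
# hard cases); most others keep their green-red balance away from skin.
_RECIPES: dict[str, dict] = {
    "carpets": dict(c0=(0.20, 0.42, 0.40), c1=(0.28, 0.52, 0.50), kind="noise", scale=6),
    "paper": dict(c0=(0.84, 0.84, 0.79), c1=(0.76, 0.77, 0.73), kind="noise", scale=20),
    "stones": dict(c0=(0.48, 0.49, 0.50), c1=(0.64, 0.65, 0.65), kind="blotch", scale=10),
    "fabric": dict(c0=(0.25, 0.45, 0.42), c1=(0.35, 0.55, 0.50), kind="stripes", scale=7),
    "parquet": dict(c0=(0.55, 0.52, 0.30), c1=(0.66, 0.63, 0.40), kind="planks", scale=24),
    "tiles": dict(c0=(0.70, 0.74, 0.71), c1=(0.52, 0.58, 0.56), kind="grid", scale=28),
    "glass": dict(c0=(0.55, 0.74, 0.77), c1=(0.68, 0.84, 0.86), kind="noise", scale=14),
    "pavement": dict(c0=(0.50, 0.51, 0.52), c1=(0.40, 0.42, 0.44), kind="blotch", scale=16),
    "tree": dict(c0=(0.26, 0.40, 0.20), c1=(0.40, 0.50, 0.28), kind="blotch", scale=12),
    "grass": dict(c0=(0.25, 0.48, 0.20), c1=(0.38, 0.60, 0.28), kind="stripes", scale=4),
    "skin_and_fur": dict(c0=(0.76, 0.58, 0.46), c1=(0.64, 0.47, 0.36), kind="noise", scale=9),
    "wall": dict(c0=(0.83, 0.82, 0.77), c1=(0.75, 0.75, 0.71), kind="noise", scale=16),
    "mud": dict(c0=(0.36, 0.33, 0.20), c1=(0.28, 0.26, 0.17), kind="blotch", scale=9),
    "sky": dict(c0=(0.55, 0.72, 0.80), c1=(0.68, 0.81, 0.86), kind="noise", scale=30),
    "wood": dict(c0=(0.52, 0.48, 0.26), c1=(0.62, 0.58, 0.34), kind="planks", scale=10),
    "objects": dict(c0=(0.36, 0.50, 0.38), c1=(0.56, 0.58, 0.40), kind="blotch", scale=14),
    "soil": dict(c0=(0.50, 0.40, 0.27), c1=(0.42, 0.34, 0.23), kind="blotch", scale=8),
}
assert set(_RECIPES) == set(TEXTURE_FAMILIES)


def _value_noise(rng, height, width, feature_scale) -> np.ndarray:
    """Smoothed standardized noise field in roughly [-1, 1]."""
    f = ndimage.gaussian_filter(
        rng.standard_normal((height, width)), sigma=feature_scale
    )
    return f / max(f.std(), 1e-9)


def make_texture(family: str, height: int, width: int, seed: int) -> np.ndarray:
    """Procedural RGB texture (float in [0, 1]) with seeded per-family
    geometry; statistics are stationary across the frame."""
    if family not in _RECIPES:
        raise ParameterError(
            f"unknown texture family {family!r}; choose one of {TEXTURE_FAMILIES}"
        )
    r = _RECIPES[family]
    rng = np.random.default_rng(seed)
    c0 = np.asarray(r["c0"])
    c1 = np.asarray(r["c1"])
    s = r["scale"]
    rr, cc = np.mgrid[0:height, 0:width].astype(float)
    if r["kind"] == "noise":
        t = 0.5 + 0.5 * np.tanh(_value_noise(rng, height, width, s))
    elif r["kind"] == "blotch":
        t = (_value_noise(rng, height, width, s) > rng.uniform(-0.3, 0.3)).astype(float)
        t = ndimage.gaussian_filter(t, sigma=1.5)
    elif r["kind"] == "stripes":
        ang = rng.uniform(0, np.pi)
        phase = rng.uniform(0, 2 * np.pi)
        wave = np.sin(2 * np.pi * (rr * np.cos(ang) + cc * np.sin(ang)) / s + phase)
        t = 0.5 + 0.5 * wave
    elif r["kind"] == "grid":
        off = rng.uniform(0, s, size=2)
        t = (((rr + off[0]) % s < s - 2) & ((cc + off[1]) % s < s - 2)).astype(float)
    elif r["kind"] == "planks":
        off = rng.uniform(0, s)
        grain = 0.5 + 0.5 * np.sin(2 * np.pi * cc / rng.uniform(3, 6))
        board = ((rr + off) % s < s - 2).astype(float)
        t = 0.6 * board + 0.4 * grain
    else:  # pragma: no cover
        raise ParameterError(f"bad recipe kind {r['kind']!r}")
    img = c0[None, None, :] + t[..., None] * (c1 - c0)[None, None, :]
    img = img + 0.012 * rng.standard_normal((height, width, 3))
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# compositing


def equalize_illumination(rgb: np.ndarray) -> np.ndarray:
    """Histogram-equalize the YCbCr luma channel only; chroma passes
    through untouched (up to transform round-off).

    The equalized Y is clamped per pixel into the gamut-feasible range
    implied by its (Cb, Cr): clipping the reconstructed RGB instead
    would silently shift the chroma of saturated pixels.
    """
    ycbcr = color.rgb2ycbcr(rgb)
    y = ycbcr[..., 0]  # nominal range [16, 235]
    y_eq = exposure.equalize_hist(y) * (235.0 - 16.0) + 16.0
    # rgb is affine in Y at fixed chroma: rgb(Y) = base + Y * slope with
    # a positive slope shared by all channels and pixels
    probe = np.zeros((1, 2, 3))
    probe[0, :, 0] = (0.0, 1.0)
    probe[0, :, 1:] = ycbcr[0, 0, 1:]
    pr = color.ycbcr2rgb(probe)[0]
    slope = float(pr[1, 0] - pr[0, 0])
    zero = ycbcr.copy()
    zero[..., 0] = 0.0
    base = color.ycbcr2rgb(zero)
    y_lo = ((0.0 - base) / slope).max(axis=-1)
    y_hi = ((1.0 - base) / slope).min(axis=-1)
    out = ycbcr.copy()
    out[..., 0] = np.clip(y_eq, y_lo, y_hi)
    return np.clip(color.ycbcr2rgb(out), 0.0, 1.0)


def composite(
    hand_rgb: np.ndarray, hand_mask: np.ndarray, texture_rgb: np.ndarray
) -> np.ndarray:
    """Overlay hand pixels on the texture, equalize illumination (Y),
    and fade the boundary with a channel-wise disk-5 opening."""
    hand_rgb = np.asarray(hand_rgb, dtype=float)
    texture_rgb = np.asarray(texture_rgb, dtype=float)
    hand_mask = np.asarray(hand_mask).astype(bool)
    if hand_rgb.shape != texture_rgb.shape or hand_mask.shape != hand_rgb.shape[:2]:
        raise ContractError("hand, mask and texture sizes must match")
    img = np.where(hand_mask[..., None], hand_rgb, texture_rgb)
    img = equalize_illumination(img)
    footprint = morphology.disk(OPENING_RADIUS)
    out = np.stack(
        [morphology.opening(img[..., ch], footprint) for ch in range(3)], axis=-1
    )
    return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# database generation


@dataclass
class DbConfig:
    """Counts and geometry of a generated database.  Record count is the
    product of the five counts."""

    n_subjects: int = 1
    hands_per_subject: int = 2
    acquisitions_per_hand: int = 1
    images_per_acquisition: int = 5
    n_textures: int = 17
    height: int = 150
    width: int = 200
    seed: int = 0
    out_dir: str = "gma_db"

    def __post_init__(self) -> None:
        for name in (
            "n_subjects",
            "hands_per_subject",
            "acquisitions_per_hand",
            "images_per_acquisition",
            "n_textures",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.n_textures > len(TEXTURE_FAMILIES):
            raise ParameterError(
                f"at most {len(TEXTURE_FAMILIES)} texture families available"
            )

    @property
    def n_records(self) -> int:
        return (
            self.n_subjects
            * self.hands_per_subject
            * self.acquisitions_per_hand
            * self.images_per_acquisition
            * self.n_textures
        )


@dataclass
class CompositeRecord:
    image_path: str
    mask_path: str
    texture_family: str
    subject: int
    hand: int
    acquisition: int
    image_index: int
    texture_index: int
    seed: int


@dataclass
class DbManifest:
    """Records of generated composites plus the config that made them."""

    config: DbConfig
    records: list[CompositeRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records])

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        path.with_suffix(".config.json").write_text(json.dumps(asdict(self.config)))

    @classmethod
    def load(cls, path: str | Path) -> "DbManifest":
        path = Path(path)
        df = pd.read_csv(path)
        cfg_path = path.with_suffix(".config.json")
        config = (
            DbConfig(**json.loads(cfg_path.read_text()))
            if cfg_path.exists()
            else DbConfig()
        )
        records = [
            CompositeRecord(**{k: row[k] for k in CompositeRecord.__dataclass_fields__})
            for row in df.to_dict("records")
        ]
        return cls(config=config, records=records)


def _mix_seed(master: int, salt: int, index: int) -> int:
    """Deterministic 63-bit per-record seed (splitmix64-style)."""
    with np.errstate(over="ignore"):
        x = np.uint64(master) * np.uint64(0x9E3779B97F4A7C15)
        x ^= np.uint64(salt) * np.uint64(0xBF58476D1CE4E5B9)
        x = (x + np.uint64(index)) * np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
        x *= np.uint64(0xD6E8FEB86659FD93)
        x ^= x >> np.uint64(29)
    return int(x & np.uint64(0x7FFFFFFFFFFFFFFF))


_POSE_SALT = 101
_TEXTURE_SALT = 202
_SKIN_SALT = 303


def iter_index_tuples(config: DbConfig) -> Iterator[tuple[int, int, int, int, int]]:
    for subj in range(config.n_subjects):
        for hand in range(config.hands_per_subject):
            for acq in range(config.acquisitions_per_hand):
                for img in range(config.images_per_acquisition):
                    for tex in range(config.n_textures):
                        yield subj, hand, acq, img, tex


def render_record(config: DbConfig, record: CompositeRecord) -> tuple[np.ndarray, np.ndarray]:
    """(composite RGB float image, binary mask) for one manifest record."""
    h, w = config.height, config.width
    pose_index = (
        (record.subject * config.hands_per_subject + record.hand)
        * config.acquisitions_per_hand
        + record.acquisition
    ) * config.images_per_acquisition + record.image_index
    mask = make_hand_mask(h, w, _mix_seed(config.seed, _POSE_SALT, pose_index))
    skin = make_skin(h, w, _mix_seed(config.seed, _SKIN_SALT, pose_index))
    texture = make_texture(record.texture_family, h, w, record.seed)
    return composite(skin, mask, texture), mask


def generate_database(
    config: DbConfig,
    manifest_only: bool = False,
    out_dir: Optional[str | Path] = None,
) -> DbManifest:
    """Generate the composite database (or just its manifest).

    Record count equals the product of the five config counts; all seeds
    derive deterministically from the master seed.
    """
    base = Path(out_dir if out_dir is not None else config.out_dir)
    records: list[CompositeRecord] = []
    for idx, (subj, hand, acq, img, tex) in enumerate(iter_index_tuples(config)):
        family = TEXTURE_FAMILIES[tex]
        stem = f"s{subj:03d}_h{hand}_a{acq:02d}_i{img}_{family}"
        records.append(
            CompositeRecord(
                image_path=str(base / "images" / f"{stem}.png"),
                mask_path=str(base / "masks" / f"{stem}.png"),
                texture_family=family,
                subject=subj,
                hand=hand,
                acquisition=acq,
                image_index=img,
                texture_index=tex,
                seed=_mix_seed(config.seed, _TEXTURE_SALT, idx),
            )
        )
    manifest = DbManifest(config=config, records=records)
    if manifest_only:
        return manifest
    (base / "images").mkdir(parents=True, exist_ok=True)
    (base / "masks").mkdir(parents=True, exist_ok=True)
    for record in records:
        image, mask = render_record(config, record)
        iio.imwrite(record.image_path, (image * 255).round().astype(np.uint8))
        iio.imwrite(record.mask_path, (mask * 255).astype(np.uint8))
    manifest.save(base / "manifest.csv")
    return manifest
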