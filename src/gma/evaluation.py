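"""Supervised segmentation evaluation: F-measure against ground truth.

The rate definitions follow the source convention literally:
``P = tp / (tp + fn)`` and ``R = tp / (tp + fp)`` — note these names are
swapped relative to the usual precision/recall convention.  The
F-measure ``F = 2RP / (R + P)`` is the harmonic mean and therefore
identical under either naming.  Degenerate denominators (tp = 0) yield
0 by convention.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ContractError
from .synthdb import CompositeRecord, DbConfig, DbManifest, render_record

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts with hand as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass(frozen=True)
class EvalRecord:
    image_id: str
    texture_family: str
    precision: float
    recall: float
    f: float


def confusion(pred_mask: np.ndarray, truth_mask: np.ndarray) -> ConfusionCounts:
    """Pixelwise confusion counts between binary masks of equal shape."""
    pred = np.asarray(pred_mask).astype(bool)
    truth = np.asarray(truth_mask).astype(bool)
    if pred.shape != truth.shape:
        raise ContractError(
            f"mask shapes differ: {pred.shape} vs {truth.shape}"
        )
    tp = int(np.count_nonzero(pred & truth))
    fn = int(np.count_nonzero(~pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    tn = int(np.count_nonzero(~pred & ~truth))
    return ConfusionCounts(tp, fn, fp, tn)


def f_measure(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(P, R, F) from confusion counts; 1 is a perfect segmentation,
    0 a total failure."""
    tp, fn, fp = counts.tp, counts.fn, counts.fp
    if tp == 0:
        if fn or fp:
            log.debug("tp=0: returning F=0 by convention")
        return 0.0, 0.0, 0.0
    p = tp / (tp + fn)
    r = tp / (tp + fp)
    return p, r, 2.0 * r * p / (r + p)


#: a segmenter maps (rgb image, manifest record) -> binary mask
Segmenter = Callable[[np.ndarray, CompositeRecord], np.ndarray]


def gma_segmenter(params=None) -> Segmenter:
    from .aggregation import AggregationParams, run_multiscale

    params = params or AggregationParams()

    def seg(image: np.ndarray, record: CompositeRecord) -> np.ndarray:
        return run_multiscale(image, params).mask

    return seg


def oracle_segmenter() -> Segmenter:
    """Returns the ground-truth mask itself (the F = 1 upper bound)."""

    def seg(image: np.ndarray, record: CompositeRecord) -> np.ndarray:
        return _read_mask(record.mask_path)

    return seg


def external_segmenter(pred_dir: str | Path) -> Segmenter:
    """Reads pre-computed masks (e.g., from a third-party method) named
    like the ground-truth mask files from ``pred_dir``."""
    pred_dir = Path(pred_dir)

    def seg(image: np.ndarray, record: CompositeRecord) -> np.ndarray:
        return _read_mask(pred_dir / Path(record.mask_path).name)

    return seg


def _read_mask(path: str | Path) -> np.ndarray:
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def _load_pair(
    manifest: DbManifest, record: CompositeRecord
) -> tuple[np.ndarray, np.ndarray]:
    img_path = Path(record.image_path)
    mask_path = Path(record.mask_path)
    if img_path.exists() and mask_path.exists():
        image = iio.imread(img_path)
        if image.ndim == 3 and image.shape[2] == 4:
            image = image[..., :3]
        return image, _read_mask(mask_path)
    # rasters not on disk (manifest-only databases): render on the fly
    image, mask = render_record(manifest.config, record)
    return (image * 255).round().astype(np.uint8), mask


def evaluate_record(
    manifest: DbManifest, record: CompositeRecord, segmenter: Segmenter
) -> EvalRecord:
    image, truth = _load_pair(manifest, record)
    pred = segmenter(image, record)
    p, r, f = f_measure(confusion(pred, truth))
    return EvalRecord(
        image_id=Path(record.image_path).stem,
        texture_family=record.texture_family,
        precision=p,
        recall=r,
        f=f,
    )


def batch_evaluate(
    manifest: DbManifest,
    segmenter: Segmenter,
    out_csv: Optional[str | Path] = None,
    render_missing: bool = True,
) -> pd.DataFrame:
    """Run the segmenter over every manifest record and report mean F
    (in %, one decimal) with its standard deviation and standard error
    per texture family, plus a global row.

    Missing/broken records are skipped with a warning and counted in the
    ``skipped`` column.  Set ``render_missing=False`` to skip (rather
    than re-render) records whose rasters are absent.
    """
    rows: list[EvalRecord] = []
    skipped: dict[str, int] = {}
    for record in manifest.records:
        if not render_missing and not Path(record.image_path).exists():
            warnings.warn(f"missing {record.image_path}: skipped", stacklevel=2)
            skipped[record.texture_family] = skipped.get(record.texture_family, 0) + 1
            continue
        try:
            rows.append(evaluate_record(manifest, record, segmenter))
        except (OSError, FileNotFoundError) as exc:
            warnings.warn(f"{record.image_path}: {exc}; skipped", stacklevel=2)
            skipped[record.texture_family] = skipped.get(record.texture_family, 0) + 1
    per_image = pd.DataFrame([r.__dict__ for r in rows])
    if out_csv is not None:
        per_image.to_csv(Path(out_csv).with_suffix(".images.csv"), index=False)
    if per_image.empty:
        table = pd.DataFrame(
            columns=["texture", "n", "mean_f_pct", "std_f_pct", "sem_f_pct", "skipped"]
        )
    else:
        grouped = per_image.groupby("texture_family")["f"]
        table = pd.DataFrame(
            {
                "texture": grouped.mean().index,
                "n": grouped.count().values,
                "mean_f_pct": (grouped.mean() * 100).round(1).values,
                "std_f_pct": (grouped.std(ddof=0) * 100).round(1).values,
                "sem_f_pct": (
                    grouped.std(ddof=0) / np.sqrt(grouped.count()) * 100
                ).round(1).values,
            }
        )
        table["skipped"] = table["texture"].map(skipped).fillna(0).astype(int)
        all_f = per_image["f"]
        table = pd.concat(
            [
                table,
                pd.DataFrame(
                    [
                        {
                            "texture": "ALL",
                            "n": len(all_f),
                            "mean_f_pct": round(all_f.mean() * 100, 1),
                            "std_f_pct": round(all_f.std(ddof=0) * 100, 1),
                            "sem_f_pct": round(
                                all_f.std(ddof=0) / np.sqrt(len(all_f)) * 100, 1
                            ),
                            "skipped": sum(skipped.values()),
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
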