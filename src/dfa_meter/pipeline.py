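"""End-to-end orchestration: splitting, measurement, and evaluation.

The flow mirrors the measurement protocol: split the dataset 7:3 into a
training pool and a test set, split the pool 9:1 into training and
validation sets, train the segmentation model selecting the lowest
validation loss, then for each test image predict the mask, extract the two
centers, and compute the signed disc-fovea angle.  Evaluation emits the
three summary tables (DFA error; per-class IoU/PA with MIoU/MPA; disc and
macula center errors DO/DM) plus a per-image metrics table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dfa import compute_dfa, dfa_error
from .geometry import MissingClassError, extract_centers
from .metrics import center_error, confusion_counts, iou_pa, summarize
from .training import predict_mask, preprocess_masks

__all__ = [
    "SplitSpec",
    "MeasurementRecord",
    "split_dataset",
    "measure_image",
    "measure_mask",
    "evaluate",
    "EvaluationReport",
]


@dataclass(frozen=True)
class SplitSpec:
    """Train/test 7:3 and train/validation 9:1 split ratios with a seed."""

    train_test_ratio: tuple = (7, 3)
    train_val_ratio: tuple = (9, 1)
    seed: int = 0

    def __post_init__(self):
        for ratio in (self.train_test_ratio, self.train_val_ratio):
            if len(ratio) != 2 or ratio[0] <= 0 or ratio[1] <= 0:
                raise ValueError(f"split ratio must be two positive numbers, got {ratio}")


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive id partitions (train_pool = train + validation)."""

    train_pool: tuple
    test: tuple
    train: tuple
    validation: tuple


def split_dataset(ids, spec: SplitSpec = SplitSpec()) -> DatasetSplit:
    """Shuffle ids and split by the floor rule.

    ``len(train_pool) = floor(N * a / (a+b))`` for train:test ratio a:b, the
    rest is the test set; the pool then splits 9:1 the same way into train
    and validation.  With N = 682 this yields 477/205 and then 429/48.
    """
    ids = list(ids)
    if not ids:
        raise ValueError("cannot split an empty id list")
    order = np.random.default_rng(spec.seed).permutation(len(ids))
    shuffled = [ids[i] for i in order]
    a, b = spec.train_test_ratio
    n_pool = int(len(ids) * a / (a + b))
    pool, test = shuffled[:n_pool], shuffled[n_pool:]
    c, d = spec.train_val_ratio
    n_train = int(len(pool) * c / (c + d))
    train, validation = pool[:n_train], pool[n_train:]
    return DatasetSplit(
        train_pool=tuple(pool),
        test=tuple(test),
        train=tuple(train),
        validation=tuple(validation),
    )


@dataclass(frozen=True)
class MeasurementRecord:
    """One image's automatic DFA measurement.

    ``status`` is 'ok' or 'unmeasurable' (a class was missing from the
    predicted mask).  ``dfa_error_deg`` is present iff the measurement
    succeeded and a ground-truth angle is known.
    """

    image_id: object
    status: str
    ox: float | None = None
    oy: float | None = None
    mx: float | None = None
    my: float | None = None
    dfa_pred_deg: float | None = None
    dfa_true_deg: float | None = None
    dfa_error_deg: float | None = None
    detail: str = ""

    def to_row(self) -> dict:
        return {
            "id": self.image_id,
            "status": self.status,
            "ox": None if self.ox is None else round(self.ox, 4),
            "oy": None if self.oy is None else round(self.oy, 4),
            "mx": None if self.mx is None else round(self.mx, 4),
            "my": None if self.my is None else round(self.my, 4),
            "dfa_pred_deg": None
            if self.dfa_pred_deg is None
            else round(self.dfa_pred_deg, 4),
            "dfa_true_deg": None
            if self.dfa_true_deg is None
            else round(self.dfa_true_deg, 4),
            "dfa_error_deg": None
            if self.dfa_error_deg is None
            else round(self.dfa_error_deg, 4),
            "detail": self.detail,
        }


def _upscale_mask(mask: np.ndarray, height: int, width: int) -> np.ndarray:
    """Nearest-neighbor upscale of a label mask to native resolution."""
    if mask.shape == (height, width):
        return mask
    rows = (np.arange(height) * mask.shape[0] / height).astype(int)
    cols = (np.arange(width) * mask.shape[1] / width).astype(int)
    return mask[np.ix_(rows, cols)]


def measure_mask(
    mask: np.ndarray,
    image_id=None,
    true_dfa: float | None = None,
    method: str = "circle",
) -> MeasurementRecord:
    """Geometry + angle stages on an already-predicted (or reference) mask."""
    try:
        centers = extract_centers(mask, method=method)
    except MissingClassError as exc:
        return MeasurementRecord(
            image_id=image_id,
            status="unmeasurable",
            dfa_true_deg=true_dfa,
            detail=str(exc),
        )
    result = compute_dfa((centers.ox, centers.oy), (centers.mx, centers.my))
    err = None if true_dfa is None else dfa_error(result.angle, true_dfa)
    return MeasurementRecord(
        image_id=image_id,
        status="ok",
        ox=centers.ox,
        oy=centers.oy,
        mx=centers.mx,
        my=centers.my,
        dfa_pred_deg=result.angle,
        dfa_true_deg=true_dfa,
        dfa_error_deg=err,
    )


def measure_image(
    image: np.ndarray,
    model,
    method: str = "circle",
    image_id=None,
    true_dfa: float | None = None,
    native_resolution: bool = True,
) -> MeasurementRecord:
    """Predict the mask for one image and measure its disc-fovea angle.

    With ``native_resolution`` (default) the predicted mask is upscaled
    nearest-neighbor to the image's own resolution before center extraction,
    so centers and center errors are reported in native pixels.
    """
    mask = predict_mask(model, image)
    if native_resolution:
        mask = _upscale_mask(mask, image.shape[0], image.shape[1])
    return measure_mask(mask, image_id=image_id, true_dfa=true_dfa, method=method)


@dataclass
class EvaluationReport:
    """Per-image metrics plus the three summary tables.

    ``dfa_table``, ``seg_table`` and ``center_table`` mirror the layout of
    the protocol's result tables: min/max/average DFA error (degrees),
    per-class IoU/PA with MIoU/MPA (%), and min/max/average DO/DM (pixels).
    """

    per_image: pd.DataFrame
    dfa_table: pd.DataFrame
    seg_table: pd.DataFrame
    center_table: pd.DataFrame
    n_unmeasurable: int = 0


def evaluate(
    images: np.ndarray,
    masks: np.ndarray,
    manifest: pd.DataFrame,
    model=None,
    method: str = "circle",
    native_resolution: bool = True,
    model_name: str = "model",
) -> EvaluationReport:
    """Evaluate a model (or the ground-truth masks) on a test set.

    Parameters
    ----------
    images, masks : arrays of test images (n, H, W, 3) and reference masks.
    manifest : DataFrame with columns id, disc_x, disc_y, fovea_x, fovea_y,
        true_dfa_deg aligned with ``images``.
    model : trained segmentation model; ``None`` feeds the reference masks
        through the geometric stages (oracle run isolating rasterization
        error).
    native_resolution : compute centers/DO/DM at the images' own resolution.

    Unmeasurable images are excluded from the angle and center summaries and
    counted in ``n_unmeasurable``; segmentation metrics are averaged
    per-image over all images.
    """
    if len(manifest) == 0:
        raise ValueError("empty evaluation manifest")
    rows = []
    dfa_errors, do_list, dm_list = [], [], []
    iou_acc, pa_acc = [], []
    n_unmeasurable = 0
    for i, (_, rec) in enumerate(manifest.iterrows()):
        truth_mask = np.asarray(masks[i])
        true_dfa = float(rec["true_dfa_deg"])
        if model is None:
            pred_mask = truth_mask
        else:
            pred_mask = predict_mask(model, images[i])
            if native_resolution:
                pred_mask = _upscale_mask(
                    pred_mask, truth_mask.shape[0], truth_mask.shape[1]
                )
            else:
                truth_mask = preprocess_masks(
                    truth_mask, model.config.input_size
                )[0]
        seg = iou_pa(confusion_counts(pred_mask, truth_mask))
        iou_acc.append(seg.iou)
        pa_acc.append(seg.pa)
        meas = measure_mask(
            pred_mask, image_id=rec["id"], true_dfa=true_dfa, method=method
        )
        row = meas.to_row()
        row.update(
            iou_bg=seg.iou[0], iou_disc=seg.iou[1], iou_macula=seg.iou[2],
            pa_bg=seg.pa[0], pa_disc=seg.pa[1], pa_macula=seg.pa[2],
        )
        if meas.status == "ok":
            scale_x = truth_mask.shape[1] / pred_mask.shape[1]
            do = center_error((rec["disc_x"], rec["disc_y"]), (meas.ox, meas.oy))
            dm = center_error((rec["fovea_x"], rec["fovea_y"]), (meas.mx, meas.my))
            dfa_errors.append(meas.dfa_error_deg)
            do_list.append(do)
            dm_list.append(dm)
            row.update(do_px=round(do, 4), dm_px=round(dm, 4))
        else:
            n_unmeasurable += 1
            row.update(do_px=None, dm_px=None)
        rows.append(row)

    per_image = pd.DataFrame(rows)

    def _mmtable(values, label):
        lo, hi, mean = summarize(values)
        return pd.DataFrame(
            {label: [lo, hi, mean]}, index=["Min", "Max", "Average"]
        )

    dfa_table = (
        _mmtable(dfa_errors, model_name)
        if dfa_errors
        else pd.DataFrame({model_name: []}, index=pd.Index([]))
    )
    iou_mean = np.mean(iou_acc, axis=0) * 100.0
    pa_mean = np.mean(pa_acc, axis=0) * 100.0
    seg_table = pd.DataFrame(
        {
            "IoU": np.append(iou_mean, iou_mean.mean()),
            "PA": np.append(pa_mean, pa_mean.mean()),
        },
        index=["Background", "Optic disc", "Macular", "Average (MIoU/MPA)"],
    )
    if do_list:
        center_table = pd.DataFrame(
            {
                "DO": summarize(do_list),
                "DM": summarize(dm_list),
            },
            index=["Min", "Max", "Average"],
        )
    else:
        center_table = pd.DataFrame({"DO": [], "DM": []})
    return EvaluationReport(
        per_image=per_image,
        dfa_table=dfa_table,
        seg_table=seg_table,
        center_table=center_table,
        n_unmeasurable=n_unmeasurable,
    )
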