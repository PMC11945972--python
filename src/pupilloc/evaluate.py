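"""Localization metrics and the blur-stratified benchmark harness.

Error is the Euclidean distance (px) between the located and true pupil
centers; a localization counts as correct when that error is within 1 % of
the pixel count of the image's long side (annotation tolerance), and
accuracy is the fraction of correct images.  The benchmark runs the locate
pipeline over a ground-truthed manifest, stratifies by defocus level, and
reports per-level mean error and accuracy.

Conventions: a no-detection counts as incorrect, its error is recorded as
NaN and excluded from mean-error aggregation but kept in the accuracy
denominator.
"""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AppConfig
from .errors import EmptyEvaluation
from .io import load_gray_image
from .moments import locate_pupil

logger = logging.getLogger(__name__)


@dataclass
class EvalRecord:
    filename: str
    status: str  # "ok" | "no_pupil_found" | "read_error"
    xc: float
    yc: float
    x0: float
    y0: float
    error: float  # px; NaN when not located
    correct: bool
    level: float  # blur level tag (defocus z in cm)


@dataclass
class BenchmarkReport:
    levels: list[dict] = field(default_factory=list)
    overall: dict = field(default_factory=dict)
    records: list[EvalRecord] = field(default_factory=list)
    n_failed_reads: int = 0

    def to_json_dict(self) -> dict:
        return {"levels": self.levels, "overall": self.overall}

    def save_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json_dict(), fh, indent=2)

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def localization_error(pred: tuple[float, float], truth: tuple[float, float]) -> float:
    """Euclidean distance in pixels between predicted and true centers."""
    return math.hypot(pred[0] - truth[0], pred[1] - truth[1])


def is_correct(error: float, img_w: int, img_h: int) -> bool:
    """Correct when the error is within 1 % of the long side, inclusive.
    NaN errors (no detection) are never correct."""
    if math.isnan(error):
        return False
    return error <= 0.01 * max(img_w, img_h)


def accuracy(records: list[EvalRecord]) -> float:
    """Fraction of correctly located images."""
    if not records:
        raise EmptyEvaluation("accuracy over zero records")
    return sum(r.correct for r in records) / len(records)


def _aggregate(records: list[EvalRecord], n_failed: int) -> BenchmarkReport:
    if not records:
        raise EmptyEvaluation("benchmark over zero records")
    report = BenchmarkReport(records=records, n_failed_reads=n_failed)
    frame = report.records_frame()
    for level, grp in frame.groupby("level", sort=True):
        errs = grp["error"].dropna()
        report.levels.append(
            {
                "z_cm": float(level),
                "n": int(len(grp)),
                "mean_error_px": float(errs.mean()) if len(errs) else math.nan,
                "accuracy": float(grp["correct"].mean()),
            }
        )
    all_errs = frame["error"].dropna()
    report.overall = {
        "n": int(len(frame)),
        "mean_error_px": float(all_errs.mean()) if len(all_errs) else math.nan,
        "accuracy": float(frame["correct"].mean()),
        "n_failed_reads": n_failed,
    }
    return report


def evaluate_predictions(
    predictions: pd.DataFrame,
    manifest: pd.DataFrame,
    img_w: int = 640,
    img_h: int = 480,
) -> BenchmarkReport:
    """Score an existing predictions table (filename, status, xc, yc)
    against a ground-truth manifest, joined on filename."""
    missing = set(manifest["filename"]) - set(predictions["filename"])
    if missing:
        raise KeyError(f"predictions missing for: {sorted(missing)}")
    merged = manifest.merge(predictions, on="filename", how="left")
    records = []
    for row in merged.itertuples():
        ok = row.status == "ok"
        err = (
            localization_error((row.xc, row.yc), (row.x0, row.y0))
            if ok
            else math.nan
        )
        level = getattr(row, "defocus_z_cm", math.nan)
        records.append(
            EvalRecord(
                filename=row.filename,
                status=row.status,
                xc=row.xc if ok else math.nan,
                yc=row.yc if ok else math.nan,
                x0=row.x0,
                y0=row.y0,
                error=err,
                correct=is_correct(err, img_w, img_h),
                level=float(level) if not pd.isna(level) else math.nan,
            )
        )
    return _aggregate(records, n_failed=0)


def run_benchmark(
    manifest: pd.DataFrame | str | Path,
    image_dir: str | Path | None = None,
    cfg: AppConfig | None = None,
) -> BenchmarkReport:
    """Locate the pupil on every manifest image and aggregate metrics.

    *manifest* may be a DataFrame or a path to the manifest CSV (in which
    case images are resolved relative to the CSV's directory unless
    *image_dir* is given).  Unreadable images are logged, marked failed and
    counted as incorrect.
    """
    cfg = cfg or AppConfig()
    if not isinstance(manifest, pd.DataFrame):
        path = Path(manifest)
        if image_dir is None:
            image_dir = path.parent
        manifest = pd.read_csv(path)
    if len(manifest) == 0:
        raise EmptyEvaluation("empty manifest")
    image_dir = Path(image_dir) if image_dir is not None else Path(".")
    records = []
    n_failed = 0
    for row in manifest.itertuples():
        level = float(getattr(row, "defocus_z_cm", math.nan))
        try:
            img = load_gray_image(image_dir / row.filename)
        except (OSError, ValueError) as exc:
            logger.warning("failed to read %s: %s", row.filename, exc)
            n_failed += 1
            records.append(
                EvalRecord(
                    filename=row.filename, status="read_error",
                    xc=math.nan, yc=math.nan, x0=row.x0, y0=row.y0,
                    error=math.nan, correct=False, level=level,
                )
            )
            continue
        t0 = time.perf_counter()
        res = locate_pupil(img, cfg)
        dt = time.perf_counter() - t0
        logger.debug("%s located in %.1f ms", row.filename, 1e3 * dt)
        err = (
            localization_error((res.xc, res.yc), (row.x0, row.y0))
            if res.status == "ok"
            else math.nan
        )
        h, w = img.shape
        records.append(
            EvalRecord(
                filename=row.filename, status=res.status,
                xc=res.xc, yc=res.yc, x0=row.x0, y0=row.y0,
                error=err, correct=is_correct(err, w, h), level=level,
            )
        )
    return _aggregate(records, n_failed=n_failed)
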