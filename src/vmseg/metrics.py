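"""Evaluation metrics: Dice, non-perfusion index, Spearman, Bland-Altman.

All pixel counting excludes eliminated pixels: a region that was cropped
out of the image is not evaluable, so it contributes neither to the
confusion counts behind the Dice coefficient nor to the NPI denominator.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .imgio import EliminationMask, SegmentationMask, _check_same_shape

__all__ = [
    "ConfusionCounts",
    "EvalRecord",
    "confusion",
    "dice",
    "npi",
    "spearman",
    "bland_altman",
    "evaluate_pair",
    "evaluation_table",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Per-pixel confusion counts over the evaluable (non-eliminated) region."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class EvalRecord:
    """One image's evaluation: Dice plus estimated and ground-truth NPI."""

    image_id: str
    dice: float
    npi_estimated: float
    npi_ground_truth: float
    area_nonperfusion: int
    area_total: int
    area_eliminated: int


def confusion(
    pred: SegmentationMask,
    truth: SegmentationMask,
    elim: EliminationMask | None = None,
) -> ConfusionCounts:
    """Confusion counts between predicted and reference masks, restricted
    to pixels outside the elimination mask."""
    _check_same_shape(pred.nonperfusion, truth.nonperfusion, "pred vs truth")
    if elim is None:
        elim = EliminationMask.empty(pred.shape)
    _check_same_shape(pred.nonperfusion, elim.excluded, "pred vs elim")
    ok = ~elim.excluded
    p = pred.nonperfusion[ok]
    t = truth.nonperfusion[ok]
    return ConfusionCounts(
        TP=int(np.sum(p & t)),
        FP=int(np.sum(p & ~t)),
        FN=int(np.sum(~p & t)),
        TN=int(np.sum(~p & ~t)),
    )


def dice(counts: ConfusionCounts) -> float:
    """Dice coefficient 2*TP / (2*TP + FP + FN).

    Both masks empty (TP = FP = FN = 0) returns 1.0: perfect agreement
    on the absence of non-perfusion.
    """
    denom = 2 * counts.TP + counts.FP + counts.FN
    if denom == 0:
        return 1.0
    return 2.0 * counts.TP / denom


def npi(area_np: int, area_total: int, area_elim: int = 0) -> float:
    """Non-perfusion index: Area_nonperfusion / (Area_total - Area_eliminated)."""
    denom = area_total - area_elim
    if denom <= 0:
        raise ZeroDivisionError("NPI undefined: eliminated area covers the frame")
    if area_np < 0 or area_np > denom:
        raise ValueError("area_nonperfusion must lie in [0, analyzable area]")
    return area_np / denom


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (midranks for ties, t-approximation p-value)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for a constant series")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def bland_altman(a, b, ids=None) -> tuple[float, float, float, list]:
    """Bland-Altman agreement between paired series.

    Differences d = a - b; limits of agreement are mean(d) +/- 1.96*sd(d)
    with the sample (n-1) standard deviation.  Returns
    ``(mean_diff, loa_low, loa_high, outlier_ids)`` where outliers are the
    points whose difference falls strictly outside the limits.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must have equal length")
    if a.size < 3:
        raise ValueError("need at least 3 observations")
    if ids is None:
        ids = list(range(a.size))
    d = a - b
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    lo, hi = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    outliers = [ids[i] for i in range(d.size) if d[i] < lo or d[i] > hi]
    return mean_diff, lo, hi, outliers


# ---------------------------------------------------------------------------
# Batch evaluation
# ---------------------------------------------------------------------------

def evaluate_pair(
    image_id: str,
    pred: SegmentationMask,
    truth: SegmentationMask,
    elim: EliminationMask | None = None,
) -> EvalRecord:
    """Dice + estimated/ground-truth NPI for one predicted/reference pair."""
    if elim is None:
        elim = EliminationMask.empty(pred.shape)
    counts = confusion(pred, truth, elim)
    area_total = int(np.prod(pred.shape))
    area_elim = elim.area
    return EvalRecord(
        image_id=image_id,
        dice=dice(counts),
        npi_estimated=npi(int(np.sum(pred.nonperfusion & ~elim.excluded)),
                          area_total, area_elim),
        npi_ground_truth=npi(int(np.sum(truth.nonperfusion & ~elim.excluded)),
                             area_total, area_elim),
        area_nonperfusion=pred.area,
        area_total=area_total,
        area_eliminated=area_elim,
    )


def evaluation_table(records: list[EvalRecord]) -> pd.DataFrame:
    """Per-image evaluation CSV layout plus a mean +/- sd summary row."""
    if not records:
        raise ValueError("no evaluation records")
    df = pd.DataFrame([vars(r) for r in records])
    summary = {
        "image_id": "mean±sd",
        "dice": df["dice"].mean(),
        "npi_estimated": df["npi_estimated"].mean(),
        "npi_ground_truth": df["npi_ground_truth"].mean(),
        "area_nonperfusion": df["area_nonperfusion"].mean(),
        "area_total": df["area_total"].mean(),
        "area_eliminated": df["area_eliminated"].mean(),
    }
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
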