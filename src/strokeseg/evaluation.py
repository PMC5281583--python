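"""Agreement metrics and the semi-automated threshold baseline.

Metrics: Dice overlap, lesion volume (mm³), and the intraclass correlation
coefficient for absolute agreement between two measurement methods
(two-way model, single measures — McGraw & Wong ICC(A,1)).

The baseline mirrors the observer workflow: a group-level threshold (mean
plus two standard deviations of per-animal contralateral ROI means), a
strict high-intensity threshold mask, and an optional exclusion mask that
stands in for the observer's manual removal of confounding regions
(ventricles and other non-infarct high-T2 structures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg

from .volume import ScalarVolume

__all__ = [
    "AgreementReport",
    "dice_index",
    "lesion_volume",
    "icc_absolute_agreement",
    "roi_mean",
    "contralateral_threshold",
    "threshold_mask",
    "semi_automated_segment",
    "evaluate_pair",
    "evaluate_batch",
]

log = logging.getLogger(__name__)


def dice_index(r1: np.ndarray, r2: np.ndarray) -> float:
    """Dice overlap ``2|R1 ∩ R2| / (|R1| + |R2|)`` in [0, 1].

    Two empty masks are in perfect (vacuous) agreement: returns 1.0.
    """
    r1 = np.asarray(r1, dtype=bool)
    r2 = np.asarray(r2, dtype=bool)
    if r1.shape != r2.shape:
        raise ValueError("mask shapes differ")
    denom = int(r1.sum()) + int(r2.sum())
    if denom == 0:
        log.info("dice_index: both masks empty; returning 1.0 by convention")
        return 1.0
    return 2.0 * int((r1 & r2).sum()) / denom


def lesion_volume(mask: np.ndarray, spacing: Sequence[float]) -> float:
    """Voxel count times voxel volume, in mm³."""
    spacing = tuple(float(s) for s in spacing)
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    return float(np.asarray(mask, dtype=bool).sum()) * float(np.prod(spacing))


def icc_absolute_agreement(ratings: np.ndarray) -> float:
    """ICC(A,1): two-way, absolute agreement, single measures.

    ``ratings`` is a ``(n_cases, 2)`` array — typically the observer-mean
    volume and the automated volume per case.
    """
    ratings = np.asarray(ratings, dtype=np.float64)
    if ratings.ndim != 2 or ratings.shape[1] != 2:
        raise ValueError("ratings must have shape (n_cases, 2)")
    n = ratings.shape[0]
    if n < 3:
        raise ValueError("need at least 3 cases")
    if np.allclose(ratings, ratings.ravel()[0]):
        raise ValueError("degenerate-ratings: zero total variance")
    frame = pd.DataFrame(
        {
            "case": np.repeat(np.arange(n), 2),
            "rater": np.tile([0, 1], n),
            "score": ratings.ravel(),
        }
    )
    table = pg.intraclass_corr(
        data=frame, targets="case", raters="rater", ratings="score"
    ).set_index("Type")
    label = "ICC(A,1)" if "ICC(A,1)" in table.index else "ICC2"
    return float(table.loc[label, "ICC"])


def roi_mean(t2: ScalarVolume, roi: np.ndarray) -> float:
    """Average T2 (ms) within a region of interest."""
    roi = np.asarray(roi, dtype=bool)
    if not roi.any():
        raise ValueError("empty ROI")
    return float(t2.values[roi].mean())


def contralateral_threshold(roi_means: Sequence[float]) -> float:
    """Group threshold: mean + 2 * sample sd of per-animal ROI means (ms).

    Each entry of ``roi_means`` is one animal's average T2 inside a
    contralateral-hemisphere ROI (see :func:`roi_mean`); the threshold is
    shared by all animals of the group.
    """
    v = np.asarray(list(roi_means), dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 per-animal ROI means")
    return float(v.mean() + 2.0 * v.std(ddof=1))


def threshold_mask(
    t2: ScalarVolume, threshold: float, domain: Optional[np.ndarray] = None
) -> np.ndarray:
    """Strictly-above-threshold mask, optionally restricted to ``domain``."""
    mask = t2.values > threshold
    if domain is not None:
        mask = mask & np.asarray(domain, dtype=bool)
    return mask


def semi_automated_segment(
    t2: ScalarVolume,
    threshold: float,
    domain: Optional[np.ndarray] = None,
    exclusion: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Threshold-based baseline lesion mask.

    ``exclusion`` stands in for the observer's manual removal of
    confounding high-T2 regions (ventricles, periventricular structures).
    """
    mask = threshold_mask(t2, threshold, domain)
    if exclusion is not None:
        mask = mask & ~np.asarray(exclusion, dtype=bool)
    return mask


@dataclass
class AgreementReport:
    """Per-case and group-level agreement between two methods."""

    case_ids: list
    dice: list[float]
    volumes_1: list[float]
    volumes_2: list[float]
    abs_volume_diff: list[float]
    icc: Optional[float] = None

    def summary(self) -> dict:
        dice = np.asarray(self.dice)
        dvol = np.asarray(self.abs_volume_diff)
        return {
            "n_cases": len(self.case_ids),
            "dice_mean": float(dice.mean()),
            "dice_sd": float(dice.std(ddof=1)) if dice.size > 1 else 0.0,
            "abs_volume_diff_mean_mm3": float(dvol.mean()),
            "abs_volume_diff_sd_mm3": float(dvol.std(ddof=1)) if dvol.size > 1 else 0.0,
            "icc": self.icc,
        }


def evaluate_pair(
    pred: np.ndarray, ref: np.ndarray, spacing: Sequence[float]
) -> dict[str, float]:
    """Dice and volumes for one pair of masks."""
    v1 = lesion_volume(pred, spacing)
    v2 = lesion_volume(ref, spacing)
    return {
        "dice": dice_index(pred, ref),
        "volume_pred_mm3": v1,
        "volume_ref_mm3": v2,
        "abs_volume_diff_mm3": abs(v1 - v2),
    }


def evaluate_batch(
    cases: Sequence[tuple[object, np.ndarray, np.ndarray, Sequence[float]]],
) -> AgreementReport:
    """Agreement over a batch of ``(case_id, pred, ref, spacing)`` tuples.

    The ICC is computed on the two volume columns when there are at least
    three cases with non-degenerate variance.
    """
    ids, dice, v1s, v2s, dv = [], [], [], [], []
    for case_id, pred, ref, spacing in cases:
        r = evaluate_pair(pred, ref, spacing)
        ids.append(case_id)
        dice.append(r["dice"])
        v1s.append(r["volume_pred_mm3"])
        v2s.append(r["volume_ref_mm3"])
        dv.append(r["abs_volume_diff_mm3"])
    icc = None
    if len(ids) >= 3:
        try:
            icc = icc_absolute_agreement(np.column_stack([v1s, v2s]))
        except ValueError:
            icc = None
    return AgreementReport(
        case_ids=ids, dice=dice, volumes_1=v1s, volumes_2=v2s,
        abs_volume_diff=dv, icc=icc,
    )
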