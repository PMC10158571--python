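"""Leave-one-out inter-subject correlation (ISC).

For each participant, fROI, and condition: the fROI-mean BOLD time course is
extracted starting 6 s after stimulus onset (skipping the initial hemodynamic
rise), z-scored, and correlated (Pearson) with the average of the remaining
participants' z-scored time courses.  Correlations are Fisher-transformed
(arctanh) before any statistical testing.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_CLIP = 1.0 - 1e-7


def zscore(x: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sd 1 (population sd); error on zero variance."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        raise ValueError("cannot z-score a zero-variance series")
    return (x - x.mean()) / sd


@dataclass
class ConditionTimecourse:
    """One participant's z-scored fROI-mean series for one condition."""

    subject: int
    froi: str
    network: str
    condition: str
    condition_type: str
    series: np.ndarray


def extract_condition_timecourse(
    clean: np.ndarray,
    froi_voxels: Sequence[int],
    tr: float,
    onset_s: float = 0.0,
    offset_s: Optional[float] = None,
    trim_s: float = 6.0,
    min_frames: int = 10,
    **labels,
) -> ConditionTimecourse:
    """fROI-mean time course, trimmed and z-scored.

    Frames run from ``onset + ceil(trim/tr)`` (6 s after stimulus onset by
    default) to the stimulus offset (exclusive; end of run if ``offset_s`` is
    None).  The average is across the fROI's voxels, then z-scored.
    """
    voxels = np.asarray(list(froi_voxels))
    if voxels.size == 0:
        raise ValueError("empty fROI")
    n_frames = clean.shape[1]
    start = int(round(onset_s / tr)) + math.ceil(trim_s / tr)
    stop = n_frames if offset_s is None else int(round(offset_s / tr))
    if stop - start < min_frames:
        raise ValueError(
            f"condition {labels.get('condition', '?')!r}: trimmed window "
            f"[{start}, {stop}) has fewer than {min_frames} frames"
        )
    series = zscore(clean[voxels, start:stop].mean(axis=0))
    return ConditionTimecourse(
        subject=labels.get("subject", 0),
        froi=labels.get("froi", "froi"),
        network=labels.get("network", "network"),
        condition=labels.get("condition", "condition"),
        condition_type=labels.get("condition_type", ""),
        series=series,
    )


def loo_isc(series: np.ndarray) -> np.ndarray:
    """Leave-one-out ISC: r_i = Pearson(row i, mean of the other rows).

    ``series`` is subject × frame; rows should already be z-scored (the
    correlation itself is scale-invariant, so this is a convention, not a
    requirement for correctness).  Subjects whose own series or whose
    leave-one-out average has zero variance get NaN (logged).
    """
    Z = np.asarray(series, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 2:
        raise ValueError("need a subject × frame matrix with >= 2 subjects")
    n = Z.shape[0]
    total = Z.sum(axis=0)
    r = np.empty(n)
    for i in range(n):
        others = (total - Z[i]) / (n - 1)
        xi, yi = Z[i], others
        sx, sy = xi.std(), yi.std()
        if sx == 0 or sy == 0:
            logger.warning("zero-variance series for subject %d; ISC undefined", i)
            r[i] = np.nan
            continue
        r[i] = np.dot(xi - xi.mean(), yi - yi.mean()) / (len(xi) * sx * sy)
    return r


def fisher_z(r) -> np.ndarray:
    """Fisher transform arctanh(r), clipping |r| at 1 − 1e−7 so that r = ±1
    maps to a finite value (≈ ±8.4)."""
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) > 1.0 + 1e-12):
        raise ValueError("correlation outside [-1, 1]")
    out = np.arctanh(np.clip(arr, -_CLIP, _CLIP))
    return out if arr.shape else float(out)


def isc_table(timecourses: Iterable[ConditionTimecourse]) -> pd.DataFrame:
    """Long-format ISC table from per-subject condition time courses.

    Groups by (fROI, condition), computes the leave-one-out ISC within each
    group, Fisher-transforms, and returns one row per (participant, fROI,
    condition) with network/condition-type labels and per-condition N.
    """
    groups: Dict[Tuple[str, str], List[ConditionTimecourse]] = {}
    for tc in timecourses:
        groups.setdefault((tc.froi, tc.condition), []).append(tc)
    rows = []
    for (froi, condition), tcs in groups.items():
        lengths = {len(t.series) for t in tcs}
        if len(lengths) != 1:
            raise ValueError(f"unequal series lengths for ({froi}, {condition})")
        Z = np.vstack([t.series for t in tcs])
        r = loo_isc(Z)
        z = fisher_z(r)
        for t, ri, zi in zip(tcs, r, z):
            rows.append(
                {
                    "participant": t.subject,
                    "network": t.network,
                    "froi": froi,
                    "condition": condition,
                    "condition_type": t.condition_type,
                    "n_frames": len(t.series),
                    "n_subjects": len(tcs),
                    "r": ri,
                    "z": zi,
                }
            )
    return pd.DataFrame(rows)


def network_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Average Fisher-z across a network's fROIs within participant and
    condition — the network-level summary used for plots and descriptives."""
    return (
        table.groupby(["participant", "network", "condition", "condition_type"], as_index=False)
        .agg(z=("z", "mean"), n_frois=("froi", "nunique"))
    )
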