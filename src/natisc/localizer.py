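"""Localizer GLM, contrast maps, and subject-specific fROI definition.

A short controlled block-design task (e.g., sentences > nonwords, false
belief > false photo) is modeled voxel-wise with an ordinary-least-squares
GLM: one canonical-HRF-convolved boxcar per condition plus its first temporal
derivative, an intercept, and discrete-cosine drift terms equivalent to a
200 s high-pass.  The resulting contrast map is intersected with a group
parcel and the top 10% of gray-matter voxels by contrast effect become that
subject's functional region of interest (fROI) — the top-n% rule guarantees
every subject gets an fROI of the same size.  Subjects with fewer than 100
suprathreshold voxels (p < 0.001 uncorrected) across a network's parcels are
excluded, and voxels claimed by fROIs of two different networks are removed
from both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Canonical HRF

def double_gamma_hrf(
    tr: float,
    duration: float = 32.0,
    oversampling: int = 16,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_disp: float = 1.0,
    undershoot_disp: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled at ``tr``.

    Peak at ~6 s, undershoot at ~16 s, peak:undershoot amplitude ratio 6:1,
    normalized to unit sum so that a sustained boxcar plateaus at 1.
    """
    dt = tr / oversampling
    t = np.arange(0, duration, dt)
    h = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp) - stats.gamma.pdf(
        t, undershoot_delay / undershoot_disp, scale=undershoot_disp
    ) / ratio
    h = h[::oversampling]
    return h / h.sum()


@dataclass
class LocalizerDesign:
    """Block design of a localizer run."""

    blocks: List[Tuple[float, float, str]]  # (onset s, duration s, condition)
    n_frames: int
    tr: float
    contrast: Dict[str, float]  # condition -> weight (difference contrasts sum to 0)

    def validate(self) -> None:
        run_len = self.n_frames * self.tr
        ordered = sorted(self.blocks)
        for onset, dur, cond in ordered:
            if onset < 0 or dur <= 0 or onset + dur > run_len:
                raise ValueError(f"block {(onset, dur, cond)} outside run of {run_len} s")
        for (o1, d1, c1), (o2, d2, c2) in zip(ordered, ordered[1:]):
            if o1 + d1 > o2:
                raise ValueError(f"blocks overlap: {(o1, d1, c1)} and {(o2, d2, c2)}")
        weights = np.array(list(self.contrast.values()))
        if (weights > 0).any() and (weights < 0).any() and abs(weights.sum()) > 1e-12:
            raise ValueError("difference contrast weights must sum to 0")

    @property
    def conditions(self) -> List[str]:
        return sorted({c for _, _, c in self.blocks})


def make_default_localizer_design(
    n_frames: int = 160,
    tr: float = 2.0,
    block_s: float = 16.0,
    conditions: Tuple[str, str] = ("task", "control"),
) -> LocalizerDesign:
    """Alternating-block two-condition design with fixation at both ends."""
    run_len = n_frames * tr
    blocks: List[Tuple[float, float, str]] = []
    onset, i = 16.0, 0
    while onset + block_s <= run_len - 16.0:
        blocks.append((onset, block_s, conditions[i % 2]))
        onset += block_s
        i += 1
    return LocalizerDesign(blocks, n_frames, tr, {conditions[0]: 1.0, conditions[1]: -1.0})


def hrf_convolved_boxcars(design: LocalizerDesign, oversampling: int = 16) -> Dict[str, np.ndarray]:
    """HRF-convolved boxcar regressor per condition, sampled at frame times."""
    dt = design.tr / oversampling
    n_hi = design.n_frames * oversampling
    t_hi = np.arange(n_hi) * dt
    hrf_hi = _hrf_highres(design.tr, oversampling)
    out: Dict[str, np.ndarray] = {}
    for cond in design.conditions:
        box = np.zeros(n_hi)
        for onset, dur, c in design.blocks:
            if c == cond:
                box[(t_hi >= onset) & (t_hi < onset + dur)] = 1.0
        conv = np.convolve(box, hrf_hi)[:n_hi]
        out[cond] = conv[::oversampling]
    return out


def _hrf_highres(tr: float, oversampling: int, duration: float = 32.0) -> np.ndarray:
    dt = tr / oversampling
    t = np.arange(0, duration, dt)
    h = stats.gamma.pdf(t, 6.0, scale=1.0) - stats.gamma.pdf(t, 16.0, scale=1.0) / 6.0
    return h / h.sum()


def dct_drift_basis(n_frames: int, tr: float, cutoff_s: float = 200.0) -> np.ndarray:
    """Discrete-cosine drift columns for a high-pass at ``1/cutoff_s`` Hz."""
    order = int(np.floor(2.0 * n_frames * tr / cutoff_s))
    t = np.arange(n_frames)
    cols = [np.cos(np.pi * k * (2 * t + 1) / (2 * n_frames)) for k in range(1, order + 1)]
    return np.column_stack(cols) if cols else np.empty((n_frames, 0))


def build_design_matrix(
    design: LocalizerDesign,
    highpass_s: Optional[float] = 200.0,
) -> pd.DataFrame:
    """Frame × regressor design: per condition an HRF-convolved boxcar and its
    first temporal derivative, plus intercept and cosine drift columns."""
    design.validate()
    regs = hrf_convolved_boxcars(design)
    if not regs:
        raise ValueError("design has no blocks")
    for cond in design.contrast:
        if cond not in regs:
            raise ValueError(f"contrast condition {cond!r} has no blocks in the design")
    cols: Dict[str, np.ndarray] = {}
    for cond, x in regs.items():
        cols[cond] = x
        d = np.diff(x, prepend=x[:1])
        d[0] = 0.0
        cols[f"{cond}_derivative"] = d
    cols["intercept"] = np.ones(design.n_frames)
    if highpass_s is not None:
        drift = dct_drift_basis(design.n_frames, design.tr, highpass_s)
        for k in range(drift.shape[1]):
            cols[f"drift_{k + 1}"] = drift[:, k]
    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# GLM and contrast maps

@dataclass
class ContrastMap:
    """Per-voxel contrast effects and t-statistics for one subject."""

    effect: np.ndarray  # (n_voxels,)
    t: np.ndarray  # (n_voxels,)
    df: float  # residual degrees of freedom
    subject: int = 0
    name: str = "contrast"


def fit_glm_contrast(
    run: np.ndarray,
    design_matrix: pd.DataFrame,
    contrast: Mapping[str, float],
    subject: int = 0,
    name: str = "contrast",
) -> ContrastMap:
    """Voxel-wise OLS fit and linear contrast of the condition effects.

    ``contrast`` maps condition-column names to weights; all other columns
    (derivatives, intercept, drift) get weight 0.  t = effect / SE(effect)
    with the per-voxel residual variance estimate.
    """
    X = design_matrix.to_numpy(dtype=float)
    n_frames, p = X.shape
    if run.shape[1] != n_frames:
        raise ValueError("run and design matrix frame counts differ")
    if n_frames <= p:
        raise ValueError(f"fewer frames ({n_frames}) than regressors ({p})")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError("design matrix is rank deficient")
    c = np.zeros(p)
    for cond, w in contrast.items():
        if cond not in design_matrix.columns:
            raise ValueError(f"contrast names unknown column {cond!r}")
        c[design_matrix.columns.get_loc(cond)] = w

    pinv = np.linalg.pinv(X)
    beta = run @ pinv.T  # voxels × p
    resid = run - beta @ X.T
    df = n_frames - p
    sigma2 = (resid**2).sum(axis=1) / df
    effect = beta @ c
    cvar = c @ np.linalg.inv(X.T @ X) @ c
    se = np.sqrt(np.maximum(sigma2 * cvar, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, effect / se, 0.0)
    return ContrastMap(effect=effect, t=t, df=float(df), subject=subject, name=name)


# ---------------------------------------------------------------------------
# fROI definition

@dataclass(frozen=True)
class FROI:
    """A subject-specific functional region of interest inside one parcel."""

    subject: int
    parcel: str
    network: str
    voxels: Tuple[int, ...]  # sorted voxel indices

    @property
    def size(self) -> int:
        return len(self.voxels)


def define_froi(
    cmap: ContrastMap,
    parcel: np.ndarray,
    gm_mask: Optional[np.ndarray] = None,
    fraction: float = 0.10,
    parcel_name: str = "parcel",
    network: str = "network",
) -> FROI:
    """Top-``fraction`` voxels of the parcel by contrast effect.

    The candidate set is parcel ∩ gray matter; ``ceil(fraction * n)`` voxels
    (at least 1) with the highest contrast values are kept.  Ties at the
    threshold break deterministically by ascending voxel index.
    """
    parcel = np.asarray(parcel)
    if parcel.size == 0:
        raise ValueError("empty parcel")
    if gm_mask is not None:
        parcel = np.intersect1d(parcel, np.asarray(gm_mask))
        if parcel.size == 0:
            raise ValueError("parcel contains no gray-matter voxels")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n_keep = max(1, math.ceil(fraction * parcel.size))
    values = cmap.effect[parcel]
    # lexsort: primary key descending effect, secondary ascending voxel index
    order = np.lexsort((parcel, -values))
    chosen = np.sort(parcel[order[:n_keep]])
    return FROI(cmap.subject, parcel_name, network, tuple(int(v) for v in chosen))


def qc_subject(
    cmap: ContrastMap,
    network_masks: Sequence[np.ndarray],
    p_thresh: float = 0.001,
    min_voxels: int = 100,
) -> Tuple[bool, int]:
    """Localizer quality check: count suprathreshold voxels within the union
    of a network's parcels and fail subjects with fewer than ``min_voxels``.

    Suprathreshold means one-sided p < ``p_thresh`` for a positive contrast,
    i.e. t above the upper ``p_thresh`` quantile of the Student-t with the
    GLM's residual df.
    """
    union = np.unique(np.concatenate([np.asarray(m) for m in network_masks]))
    t_thresh = stats.t.isf(p_thresh, cmap.df)
    count = int((cmap.t[union] > t_thresh).sum())
    return count >= min_voxels, count


def exclude_overlap(frois: Iterable[FROI]) -> Tuple[List[FROI], pd.DataFrame]:
    """Remove voxels claimed by fROIs of two or more networks within a subject.

    Returns the pruned fROIs (order preserved) and a per-subject,
    per-network-pair overlap report with counts and percentages relative to
    each member fROI's size.
    """
    frois = list(frois)
    report_rows = []
    # voxels to remove, per subject: those appearing in >= 2 distinct networks
    by_subject: Dict[int, List[FROI]] = {}
    for f in frois:
        by_subject.setdefault(f.subject, []).append(f)
    removal: Dict[int, set] = {}
    for subj, group in by_subject.items():
        vox_networks: Dict[int, set] = {}
        for f in group:
            for v in f.voxels:
                vox_networks.setdefault(v, set()).add(f.network)
        removal[subj] = {v for v, nets in vox_networks.items() if len(nets) >= 2}
        for i, f1 in enumerate(group):
            for f2 in group[i + 1 :]:
                if f1.network == f2.network:
                    continue
                shared = set(f1.voxels) & set(f2.voxels)
                report_rows.append(
                    {
                        "subject": subj,
                        "froi_1": f1.parcel,
                        "froi_2": f2.parcel,
                        "network_1": f1.network,
                        "network_2": f2.network,
                        "n_overlap": len(shared),
                        "pct_of_froi_1": 100.0 * len(shared) / max(f1.size, 1),
                        "pct_of_froi_2": 100.0 * len(shared) / max(f2.size, 1),
                    }
                )
    pruned = [
        FROI(
            f.subject,
            f.parcel,
            f.network,
            tuple(v for v in f.voxels if v not in removal.get(f.subject, set())),
        )
        for f in frois
    ]
    return pruned, pd.DataFrame(report_rows)
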