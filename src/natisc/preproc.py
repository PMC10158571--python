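"""Temporal denoising of naturalistic runs.

The stream mirrors standard component-based nuisance correction: temporal
principal components and mean signals of the white-matter and CSF
compartments, the six rigid-body motion parameters with their first temporal
derivatives, and spike regressors for outlier frames are regressed out of
every voxel's time course; the residuals are then band-pass filtered to
0.008–0.09 Hz.  Outlier frames are flagged where the scan-to-scan change in
the global signal exceeds 5 standard deviations or framewise displacement
exceeds 0.9 mm.

Outlier frames are regressed out (spike columns), not deleted: deletion would
desynchronize subjects, which inter-subject correlation cannot tolerate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .synthetic import MOTION_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_BAND = (0.008, 0.09)

#: radius (mm) of the sphere used to convert rotations (radians) to mm of
#: displacement in the framewise-displacement computation
FD_ROTATION_RADIUS_MM = 50.0


def motion_with_derivatives(motion: pd.DataFrame) -> np.ndarray:
    """Frame × 12 matrix: the 6 rigid-body parameters and their first
    temporal differences (first frame's derivative set to 0)."""
    params = motion[MOTION_COLUMNS].to_numpy(dtype=float)
    deriv = np.diff(params, axis=0, prepend=params[:1])
    deriv[0] = 0.0
    return np.hstack([params, deriv])


def extract_noise_pcs(
    run: np.ndarray,
    compartment: np.ndarray,
    k: int = 5,
) -> Tuple[np.ndarray, np.ndarray]:
    """Top-k temporal principal components and mean signal of a compartment.

    Parameters
    ----------
    run : voxel × time matrix.
    compartment : voxel indices of the noise ROI (WM or CSF).
    k : number of components (default 5).

    Returns
    -------
    pcs : frame × k matrix, columns orthonormal over frames (unit L2 norm).
    mean_series : across-voxel average of the raw compartment signal.

    Components are computed after per-voxel mean removal only (no variance
    normalization).  If the compartment's rank is below ``k``, the available
    components are returned and a warning logged.
    """
    compartment = np.asarray(compartment)
    if compartment.size == 0:
        raise ValueError("compartment mask is empty")
    X = run[compartment].astype(float)  # voxels × time
    mean_series = X.mean(axis=0)
    Xc = X - X.mean(axis=1, keepdims=True)
    # temporal PCs = right singular vectors of the voxel × time matrix
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    tol = max(Xc.shape) * np.finfo(float).eps * (s[0] if s.size else 0.0)
    rank = int((s > tol).sum())
    if rank < k:
        logger.warning("compartment rank %d < requested k=%d; returning %d PCs", rank, k, rank)
    k_eff = min(k, rank)
    return vt[:k_eff].T.copy(), mean_series


def framewise_displacement(motion: pd.DataFrame) -> np.ndarray:
    """Scalar framewise displacement per frame: sum of absolute differences of
    the three translations (mm) plus the three rotations converted to arc
    length on a 50 mm sphere.  Frame 0 has FD 0."""
    params = motion[MOTION_COLUMNS].to_numpy(dtype=float)
    d = np.abs(np.diff(params, axis=0, prepend=params[:1]))
    d[0] = 0.0
    return d[:, :3].sum(axis=1) + FD_ROTATION_RADIUS_MM * d[:, 3:].sum(axis=1)


def detect_outlier_frames(
    global_signal: np.ndarray,
    motion: pd.DataFrame,
    z_thresh: float = 5.0,
    motion_thresh: float = 0.9,
) -> np.ndarray:
    """Flag frames with a global-signal jump above ``z_thresh`` standard
    deviations or framewise displacement above ``motion_thresh`` mm.

    The scan-to-scan global signal difference is z-scored across frames; the
    first frame is never flagged by either delta criterion.
    """
    global_signal = np.asarray(global_signal, dtype=float)
    if len(global_signal) != len(motion):
        raise ValueError("global signal and motion table must share frame count")
    dg = np.diff(global_signal, prepend=global_signal[:1])
    dg[0] = 0.0
    sd = dg[1:].std()
    z = np.zeros_like(dg)
    if sd > 0:
        z[1:] = (dg[1:] - dg[1:].mean()) / sd
    fd = framewise_displacement(motion)
    flags = (np.abs(z) > z_thresh) | (fd > motion_thresh)
    flags[0] = False
    return flags


@dataclass
class NuisanceSet:
    """All nuisance regressors for one run."""

    motion: np.ndarray  # frame × 12 (6 params + derivatives)
    noise_pcs: Dict[str, np.ndarray] = field(default_factory=dict)  # compartment -> frame × k
    noise_means: Dict[str, np.ndarray] = field(default_factory=dict)  # compartment -> frame
    outlier_frames: Optional[np.ndarray] = None  # boolean per frame
    detrend_order: int = 2  # polynomial detrending columns (0 disables)

    def design_matrix(self, n_frames: int) -> Tuple[np.ndarray, List[str]]:
        """Assemble intercept + nuisance columns + one spike column per outlier."""
        cols: List[np.ndarray] = [np.ones(n_frames)]
        names: List[str] = ["intercept"]
        t = np.linspace(-1.0, 1.0, n_frames)
        for d in range(1, self.detrend_order + 1):
            cols.append(t**d)
            names.append(f"trend_{d}")
        if self.motion is not None:
            for j in range(self.motion.shape[1]):
                cols.append(self.motion[:, j])
                names.append(f"motion_{j}")
        for comp, pcs in self.noise_pcs.items():
            for j in range(pcs.shape[1]):
                cols.append(pcs[:, j])
                names.append(f"{comp}_pc{j + 1}")
        for comp, mean in self.noise_means.items():
            cols.append(mean)
            names.append(f"{comp}_mean")
        if self.outlier_frames is not None:
            for t in np.flatnonzero(self.outlier_frames):
                spike = np.zeros(n_frames)
                spike[t] = 1.0
                cols.append(spike)
                names.append(f"spike_{t}")
        return np.column_stack(cols), names


def build_nuisance_set(
    run: np.ndarray,
    motion: pd.DataFrame,
    wm: np.ndarray,
    csf: np.ndarray,
    gm: Optional[np.ndarray] = None,
    k: int = 5,
    z_thresh: float = 5.0,
    motion_thresh: float = 0.9,
) -> NuisanceSet:
    """Standard nuisance set for one run: 12 motion columns, 5 PCs + mean per
    noise compartment, and outlier spikes from the gray-matter global signal."""
    pcs: Dict[str, np.ndarray] = {}
    means: Dict[str, np.ndarray] = {}
    for name, idx in (("wm", wm), ("csf", csf)):
        if idx is not None and len(idx) > 0:
            pcs[name], means[name] = extract_noise_pcs(run, idx, k=k)
    gsig = run[gm].mean(axis=0) if gm is not None and len(gm) else run.mean(axis=0)
    outliers = detect_outlier_frames(gsig, motion, z_thresh, motion_thresh)
    return NuisanceSet(
        motion=motion_with_derivatives(motion),
        noise_pcs=pcs,
        noise_means=means,
        outlier_frames=outliers,
    )


def _drop_collinear(D: np.ndarray, names: List[str]) -> Tuple[np.ndarray, List[str]]:
    """Greedy Gram-Schmidt rank filter: keep columns that add rank."""
    keep: List[int] = []
    basis = np.zeros((D.shape[0], 0))
    for j in range(D.shape[1]):
        col = D[:, j]
        if basis.shape[1]:
            col = col - basis @ (basis.T @ col)
        norm = np.linalg.norm(col)
        if norm > 1e-10 * max(1.0, np.linalg.norm(D[:, j])):
            keep.append(j)
            basis = np.hstack([basis, (col / norm)[:, None]])
    dropped = [names[j] for j in range(D.shape[1]) if j not in keep]
    if dropped:
        logger.info("dropping collinear nuisance columns: %s", dropped)
    return D[:, keep], [names[j] for j in keep]


def regress_nuisance(run: np.ndarray, nuisance: NuisanceSet) -> np.ndarray:
    """Project every voxel's series orthogonally to the nuisance design.

    Returns the least-squares residual matrix (voxel × time).  Collinear
    design columns are dropped (and logged) before projection.
    """
    n_frames = run.shape[1]
    D, names = nuisance.design_matrix(n_frames)
    D, names = _drop_collinear(D, names)
    Q, _ = np.linalg.qr(D)
    resid = run - (run @ Q) @ Q.T
    return resid


def bandpass(
    run: np.ndarray,
    tr: float,
    band: Tuple[float, float] = DEFAULT_BAND,
    method: str = "butter",
) -> np.ndarray:
    """Zero-phase band-pass filter along the time axis.

    ``method="butter"`` (default) uses a forward–backward 2nd-order Butterworth
    filter; ``method="fft"`` uses a hard spectral mask.  Both realizations are
    zero-phase; the Butterworth has smooth roll-off, the mask is ideal.
    """
    low, high = band
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low < high < nyquist):
        raise ValueError(f"band {band!r} outside (0, Nyquist={nyquist})")
    x = np.atleast_2d(np.asarray(run, dtype=float))
    if method == "butter":
        sos = sp_signal.butter(2, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
        out = sp_signal.sosfiltfilt(sos, x - x.mean(axis=-1, keepdims=True), axis=-1)
    elif method == "fft":
        n = x.shape[-1]
        freqs = np.fft.rfftfreq(n, d=tr)
        spec = np.fft.rfft(x, axis=-1)
        spec[..., ~((freqs >= low) & (freqs <= high))] = 0.0
        out = np.fft.irfft(spec, n=n, axis=-1)
    else:
        raise ValueError(f"unknown bandpass method {method!r}")
    return out.reshape(np.shape(run))


@dataclass
class CleanRun:
    """Denoised run with provenance."""

    data: np.ndarray  # voxel × time residuals
    tr: float
    band: Optional[Tuple[float, float]]
    n_regressors: int
    filter_method: str


def clean_run(
    run: np.ndarray,
    nuisance: NuisanceSet,
    tr: float,
    band: Optional[Tuple[float, float]] = DEFAULT_BAND,
    filter_method: str = "butter",
) -> CleanRun:
    """Full temporal-denoising stream: nuisance regression then band-pass.

    Pass ``band=None`` to skip filtering (the robustness variant: conclusions
    should not depend on the band-pass step).
    """
    resid = regress_nuisance(run, nuisance)
    if band is not None:
        resid = bandpass(resid, tr, band, method=filter_method)
    D, names = nuisance.design_matrix(run.shape[1])
    return CleanRun(resid, tr, band, len(names), filter_method if band else "none")
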