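"""Multi-subject synthetic BOLD generator with known planted structure.

Generative model for a naturalistic run.  Every gray-matter voxel ``v`` of
subject ``i`` lying in a parcel of network ``n`` follows

    y_v,i(t) = a(n, c) * sigma_shared * s(t)          stimulus-locked signal
             + sigma_subject * g_i(t)                 subject-global noise
             + sigma_voxel * e_v,i(t)                 voxel noise
             + nuisance_v,i(t)                        drift, motion, compartments

where ``s(t)`` is a single band-limited shared signal per condition (common to
all subjects — this is what inter-subject correlation measures), ``g_i`` is
white noise shared across all of subject *i*'s gray-matter voxels but
independent across subjects (it inflates within-subject correlations, never
ISC), and ``a(n, c)`` is the planted coupling of network ``n`` to condition
``c``.  Gray-matter voxels outside any parcel carry no stimulus-locked signal.
White-matter and CSF voxels carry compartment-wide signals plus voxel noise;
the compartment signals also leak into gray matter so that component-based
nuisance removal has something real to remove.

Everything is a pure function of ``(config, seed)``; ground truth (shared
signals, couplings, nuisance sources) is stored on the dataset so downstream
stages can be verified against it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .config import Condition, SimulationConfig

MOTION_COLUMNS = ["trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z"]

# tissue codes in the flat label array
GM, WM, CSF = 1, 2, 3


def _derive_seed(master: int, *tokens) -> np.random.SeedSequence:
    """Deterministic child seed from a master seed and string/int tokens."""
    digest = hashlib.sha256(("|".join(map(str, tokens))).encode()).digest()
    extra = int.from_bytes(digest[:8], "little")
    return np.random.SeedSequence(entropy=(int(master) & 0x7FFFFFFF, extra))


def make_shared_signal(
    n_timepoints: int,
    tr: float,
    passband: Tuple[float, float],
    seed,
) -> np.ndarray:
    """Band-limited unit-variance shared signal.

    White Gaussian noise is spectrally masked to the passband and standardized
    (mean 0, sd 1).  Because the series is exactly band-limited by
    construction, it passes through any band-pass filter covering the same
    band essentially unchanged — the planted signal survives preprocessing.
    """
    low, high = passband
    nyquist = 1.0 / (2.0 * tr)
    if not (0 < low < high < nyquist):
        raise ValueError(f"degenerate passband {passband!r} for tr={tr}")
    if n_timepoints < 8:
        raise ValueError("need at least 8 timepoints")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n_timepoints)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    mask = (freqs >= low) & (freqs <= high)
    if not mask.any():
        raise ValueError(f"passband {passband!r} contains no DFT bin at T={n_timepoints}")
    spec[~mask] = 0.0
    series = np.fft.irfft(spec, n=n_timepoints)
    series -= series.mean()
    sd = series.std()
    if sd == 0:
        raise ValueError("degenerate shared signal (zero variance)")
    return series / sd


def expected_isc(a: float, sigma_s: float, sigma_n: float, n_subjects: int) -> float:
    """Large-T expectation of the leave-one-out ISC.

    For ``y_i = a*s + n_i`` with independent noise of sd ``sigma_n`` per
    subject, the correlation of subject *i* with the average of the other
    ``N-1`` subjects converges (T → ∞) to

        a^2 σs^2 / sqrt( (a^2 σs^2 + σn^2) (a^2 σs^2 + σn^2/(N−1)) ).

    When the series being correlated is a parcel mean over ``m`` voxels, the
    effective noise variance is ``sigma_subject^2 + sigma_voxel^2 / m``
    (subject-global noise does not average out across a subject's voxels).
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if sigma_s < 0 or sigma_n < 0:
        raise ValueError("standard deviations must be >= 0")
    sig2 = (a * sigma_s) ** 2
    noise2 = sigma_n**2
    if sig2 + noise2 == 0:
        raise ValueError("signal and noise cannot both be zero")
    if sig2 == 0:
        return 0.0
    denom = np.sqrt((sig2 + noise2) * (sig2 + noise2 / (n_subjects - 1)))
    return float(sig2 / denom)


@dataclass
class BrainLayout:
    """Flat voxel layout: tissue labels and parcel index sets on a 3D grid."""

    grid_shape: Tuple[int, int, int]
    tissue: np.ndarray  # (n_voxels,) codes GM/WM/CSF
    parcels: Dict[str, np.ndarray]  # parcel name -> sorted voxel indices
    parcel_network: Dict[str, str]  # parcel name -> network name

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.grid_shape))

    @property
    def gm(self) -> np.ndarray:
        return np.flatnonzero(self.tissue == GM)

    @property
    def wm(self) -> np.ndarray:
        return np.flatnonzero(self.tissue == WM)

    @property
    def csf(self) -> np.ndarray:
        return np.flatnonzero(self.tissue == CSF)

    def network_parcels(self, network: str) -> Dict[str, np.ndarray]:
        return {p: v for p, v in self.parcels.items() if self.parcel_network[p] == network}

    def network_mask(self, network: str) -> np.ndarray:
        idx = [v for p, v in self.parcels.items() if self.parcel_network[p] == network]
        return np.unique(np.concatenate(idx))


def make_layout(config: SimulationConfig) -> BrainLayout:
    """Partition the grid into GM (55%) / WM (30%) / CSF (15%) slabs and place
    equally sized parcels at the start of gray matter.

    Spatial realism is not the point; shared flat indexing across subjects is.
    """
    n_vox = int(np.prod(config.grid_shape))
    tissue = np.full(n_vox, GM, dtype=np.int8)
    n_gm = int(round(0.55 * n_vox))
    n_wm = int(round(0.30 * n_vox))
    tissue[n_gm : n_gm + n_wm] = WM
    tissue[n_gm + n_wm :] = CSF
    parcels: Dict[str, np.ndarray] = {}
    parcel_network: Dict[str, str] = {}
    cursor = 0
    for net in config.networks:
        for j in range(net.n_parcels):
            name = f"{net.name}_p{j + 1}"
            idx = np.arange(cursor, cursor + net.voxels_per_parcel)
            if idx[-1] >= n_gm:
                raise ValueError("parcels exceed gray-matter compartment")
            parcels[name] = idx
            parcel_network[name] = net.name
            cursor += net.voxels_per_parcel
    return BrainLayout(config.grid_shape, tissue, parcels, parcel_network)


@dataclass
class GroundTruth:
    """Planted quantities stored with a synthetic run."""

    shared_signal: np.ndarray  # (T,)
    coupling: Dict[str, float]  # network -> a for this condition
    subject_noise: List[np.ndarray] = field(default_factory=list)  # per subject (T,)
    nuisance_sources: List[Dict[str, np.ndarray]] = field(default_factory=list)
    localizer_effects: Optional[np.ndarray] = None  # (n_voxels,) for localizer runs


@dataclass
class MultiSubjectRun:
    """One condition's synthetic data for all subjects.

    ``bold[i]`` is the voxel × time matrix of subject ``i``; motion tables are
    per subject (6 parameters, BIDS-style column names).
    """

    condition: Condition
    config: SimulationConfig
    layout: BrainLayout
    bold: List[np.ndarray]
    motion: List[pd.DataFrame]
    ground_truth: GroundTruth

    @property
    def n_subjects(self) -> int:
        return len(self.bold)


def _simulate_motion(n_timepoints: int, rng: np.random.Generator) -> pd.DataFrame:
    """Slow random-walk head motion: translations in mm, rotations in radians."""
    steps = rng.normal(0.0, [0.02] * 3 + [0.0004] * 3, size=(n_timepoints, 6))
    params = np.cumsum(steps, axis=0)
    return pd.DataFrame(params, columns=MOTION_COLUMNS)


def _motion_artifact(motion: pd.DataFrame) -> np.ndarray:
    """A standardized motion-locked artifact source, linear in the framewise
    parameter derivatives (the leading-order form of motion contamination)."""
    d = np.diff(motion.to_numpy(), axis=0, prepend=motion.to_numpy()[:1])
    d[0] = 0.0
    src = d[:, :3].sum(axis=1) + 50.0 * d[:, 3:].sum(axis=1)
    src = src - src.mean()
    sd = src.std()
    return src / sd if sd > 0 else src


def _standardized_drift(n_timepoints: int, rng: np.random.Generator) -> np.ndarray:
    """Random slow polynomial drift, standardized to unit variance."""
    t = np.linspace(-1.0, 1.0, n_timepoints)
    drift = rng.normal() * t + rng.normal() * (t**2 - np.mean(t**2))
    drift = drift - drift.mean()
    sd = drift.std()
    if sd == 0:  # both coefficients ~0: fall back to linear trend
        drift = t - t.mean()
        sd = drift.std()
    return drift / sd


def simulate_naturalistic_run(
    config: SimulationConfig,
    condition: str,
    layout: Optional[BrainLayout] = None,
) -> MultiSubjectRun:
    """Simulate one naturalistic condition for all subjects (see module docstring)."""
    cond = config.condition(condition)  # KeyError for unknown condition
    if layout is None:
        layout = make_layout(config)
    T = config.n_timepoints
    n_vox = layout.n_voxels

    shared = make_shared_signal(
        T, config.tr, config.passband, _derive_seed(config.seed, "shared", cond.name)
    )
    coupling = {net.name: config.coupling[(net.name, cond.name)] for net in config.networks}

    gm_idx = layout.gm
    wm_idx, csf_idx = layout.wm, layout.csf
    # fixed (subject-independent) voxel loadings for nuisance sources
    load_rng = np.random.default_rng(_derive_seed(config.seed, "loadings", cond.name))
    drift_load = load_rng.uniform(0.5, 1.5, size=n_vox)
    motion_load = load_rng.uniform(0.5, 1.5, size=n_vox)
    wm_leak = load_rng.uniform(0.2, 1.0, size=n_vox)
    csf_leak = load_rng.uniform(0.2, 1.0, size=n_vox)
    # compartment-internal loadings: physiological signal dominates WM/CSF
    wm_internal = load_rng.uniform(0.5, 1.5, size=n_vox)
    csf_internal = load_rng.uniform(0.5, 1.5, size=n_vox)

    truth = GroundTruth(shared_signal=shared, coupling=coupling)
    bold_all: List[np.ndarray] = []
    motion_all: List[pd.DataFrame] = []

    amp = config.sigma_shared  # nuisance amplitudes are specified relative to this
    for i in range(config.n_subjects):
        rng = np.random.default_rng(_derive_seed(config.seed, "subject", cond.name, i))
        g = rng.standard_normal(T)
        y = config.sigma_voxel * rng.standard_normal((n_vox, T))
        y[gm_idx] += config.sigma_subject * g

        for net in config.networks:
            a = coupling[net.name]
            if a == 0.0:
                continue
            for pname, vidx in layout.network_parcels(net.name).items():
                y[vidx] += a * config.sigma_shared * shared

        motion = _simulate_motion(T, rng)
        sources: Dict[str, np.ndarray] = {}
        if config.drift_amplitude > 0:
            drift = _standardized_drift(T, rng)
            y += config.drift_amplitude * amp * np.outer(drift_load, drift)
            sources["drift"] = drift
        if config.motion_amplitude > 0:
            art = _motion_artifact(motion)
            y += config.motion_amplitude * amp * np.outer(motion_load, art)
            sources["motion_artifact"] = art
        if config.noise_roi_amplitude > 0:
            wm_sig = rng.standard_normal(T)
            csf_sig = rng.standard_normal(T)
            y[wm_idx] += amp * np.outer(wm_internal[wm_idx], wm_sig)
            y[csf_idx] += amp * np.outer(csf_internal[csf_idx], csf_sig)
            # physiological leakage of compartment signals into gray matter
            y[gm_idx] += 0.5 * config.noise_roi_amplitude * amp * np.outer(wm_leak[gm_idx], wm_sig)
            y[gm_idx] += 0.5 * config.noise_roi_amplitude * amp * np.outer(csf_leak[gm_idx], csf_sig)
            sources["wm_signal"] = wm_sig
            sources["csf_signal"] = csf_sig

        truth.subject_noise.append(g)
        truth.nuisance_sources.append(sources)
        bold_all.append(y)
        motion_all.append(motion)

    return MultiSubjectRun(cond, config, layout, bold_all, motion_all, truth)


# ---------------------------------------------------------------------------
# Localizer runs


def simulate_localizer_run(
    config: SimulationConfig,
    design,  # LocalizerDesign; imported lazily to avoid a cycle
    effect_map: np.ndarray,
    subject: int = 0,
    noise_sd: float = 1.0,
    layout: Optional[BrainLayout] = None,
):
    """Simulate a single subject's block-design localizer run.

    Each voxel's series is ``effect * x(t) + noise`` where ``x`` is the
    HRF-convolved boxcar *difference* between the design's two conditions
    (first contrast-positive condition minus first contrast-negative one).
    Ground-truth effects are returned alongside the run.
    """
    from .localizer import hrf_convolved_boxcars

    if layout is None:
        layout = make_layout(config)
    n_vox = layout.n_voxels
    effect_map = np.asarray(effect_map, dtype=float)
    if effect_map.shape != (n_vox,):
        raise ValueError(f"effect map must cover all {n_vox} voxels")
    design.validate()

    regs = hrf_convolved_boxcars(design)
    pos = [c for c, w in design.contrast.items() if w > 0]
    neg = [c for c, w in design.contrast.items() if w < 0]
    if not pos or not neg:
        raise ValueError("localizer design needs a difference contrast")
    x = regs[pos[0]] - regs[neg[0]]

    rng = np.random.default_rng(_derive_seed(config.seed, "localizer", subject))
    y = np.outer(effect_map, x) + noise_sd * rng.standard_normal((n_vox, design.n_frames))
    truth = GroundTruth(
        shared_signal=x, coupling={}, localizer_effects=effect_map.copy()
    )
    return y, design, truth
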