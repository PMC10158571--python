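"""End-to-end orchestration: simulate → denoise → fROIs → ISC table → inference.

These functions wire the stage modules together for simulation studies; every
stage can equally be driven by hand on real (or file-backed) data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .isc import ConditionTimecourse, extract_condition_timecourse, isc_table
from .localizer import (
    FROI,
    define_froi,
    exclude_overlap,
    fit_glm_contrast,
    build_design_matrix,
    make_default_localizer_design,
    qc_subject,
)
from .null_inference import group_null_table
from .preproc import build_nuisance_set, clean_run
from .synthetic import (
    BrainLayout,
    MultiSubjectRun,
    make_layout,
    simulate_localizer_run,
    simulate_naturalistic_run,
)

logger = logging.getLogger(__name__)


def preprocess_run(run: MultiSubjectRun, band=(0.008, 0.09), filter_method="butter") -> List[np.ndarray]:
    """Temporal denoising of every subject's data in a multi-subject run."""
    layout = run.layout
    out = []
    for i in range(run.n_subjects):
        nuis = build_nuisance_set(
            run.bold[i], run.motion[i], wm=layout.wm, csf=layout.csf, gm=layout.gm
        )
        out.append(clean_run(run.bold[i], nuis, run.config.tr, band, filter_method).data)
    return out


def parcel_frois(layout: BrainLayout, n_subjects: int) -> List[FROI]:
    """Use the parcels themselves as fROIs (the anatomical-ROI route, which
    bypasses localizer-based definition)."""
    return [
        FROI(subject=i, parcel=p, network=layout.parcel_network[p], voxels=tuple(int(v) for v in vox))
        for i in range(n_subjects)
        for p, vox in layout.parcels.items()
    ]


def localizer_frois(
    config: SimulationConfig,
    layout: BrainLayout,
    effect: float = 3.0,
    noise_sd: float = 1.0,
    fraction: float = 0.10,
    remove_overlap: bool = True,
    qc_min_voxels: int = 100,
) -> Tuple[List[FROI], pd.DataFrame]:
    """Localizer-based fROIs for every subject.

    Simulates one localizer run per subject and network with the planted
    effect inside the network's parcels, fits the GLM, and takes the top
    ``fraction`` of each parcel by contrast effect.  Returns the fROIs (after
    cross-network overlap removal) and a QC table (subject, network,
    suprathreshold count, pass).
    """
    design = make_default_localizer_design(config.n_timepoints, config.tr)
    X = build_design_matrix(design)
    frois: List[FROI] = []
    qc_rows = []
    for net in config.networks:
        net_parcels = layout.network_parcels(net.name)
        effect_map = np.zeros(layout.n_voxels)
        for vox in net_parcels.values():
            effect_map[vox] = effect
        for i in range(config.n_subjects):
            run, _, _ = simulate_localizer_run(
                config, design, effect_map, subject=i, noise_sd=noise_sd, layout=layout
            )
            cmap = fit_glm_contrast(run, X, design.contrast, subject=i, name=net.name)
            ok, count = qc_subject(cmap, list(net_parcels.values()), min_voxels=qc_min_voxels)
            qc_rows.append({"subject": i, "network": net.name, "n_supra": count, "passed": ok})
            for pname, vox in net_parcels.items():
                frois.append(
                    define_froi(cmap, vox, gm_mask=layout.gm, fraction=fraction,
                                parcel_name=pname, network=net.name)
                )
    if remove_overlap:
        frois, _ = exclude_overlap(frois)
    return frois, pd.DataFrame(qc_rows)


def condition_timecourses(
    clean: Sequence[np.ndarray],
    frois: Sequence[FROI],
    run: MultiSubjectRun,
    trim_s: float = 6.0,
) -> List[ConditionTimecourse]:
    """Trimmed, z-scored fROI-mean time courses for all subjects of one run."""
    tcs = []
    for f in frois:
        tcs.append(
            extract_condition_timecourse(
                clean[f.subject],
                f.voxels,
                tr=run.config.tr,
                trim_s=trim_s,
                subject=f.subject,
                froi=f.parcel,
                network=f.network,
                condition=run.condition.name,
                condition_type=run.condition.ctype,
            )
        )
    return tcs


@dataclass
class StudyResult:
    """Everything the downstream statistics consume."""

    table: pd.DataFrame  # long ISC table
    timecourses: Dict[Tuple[str, str], np.ndarray]  # (froi, condition) -> subj × frame
    layout: BrainLayout
    qc: Optional[pd.DataFrame] = None


def run_study(
    config: SimulationConfig,
    conditions: Optional[Sequence[str]] = None,
    preprocess: bool = True,
    froi_source: str = "parcel",
    band=(0.008, 0.09),
    trim_s: float = 6.0,
) -> StudyResult:
    """Simulate the study and produce the long ISC table.

    ``froi_source`` is ``"parcel"`` (parcels as anatomical ROIs) or
    ``"localizer"`` (subject-specific top-10% fROIs from simulated localizer
    runs).  ``preprocess`` toggles nuisance regression + band-pass; with the
    generator's nuisance amplitudes at zero it can be skipped for speed
    without changing the generative signal model.
    """
    layout = make_layout(config)
    if conditions is None:
        conditions = [c.name for c in config.conditions]
    qc = None
    if froi_source == "parcel":
        frois = parcel_frois(layout, config.n_subjects)
    elif froi_source == "localizer":
        frois, qc = localizer_frois(config, layout)
    else:
        raise ValueError(f"unknown froi_source {froi_source!r}")

    all_tcs: List[ConditionTimecourse] = []
    for cond in conditions:
        run = simulate_naturalistic_run(config, cond, layout)
        clean = preprocess_run(run, band=band) if preprocess else run.bold
        all_tcs.extend(condition_timecourses(clean, frois, run, trim_s=trim_s))
        del run, clean

    table = isc_table(all_tcs)
    cells: Dict[Tuple[str, str], np.ndarray] = {}
    for (froi, cond), group in _group_timecourses(all_tcs).items():
        cells[(froi, cond)] = np.vstack([t.series for t in group])
    return StudyResult(table=table, timecourses=cells, layout=layout, qc=qc)


def _group_timecourses(tcs: Sequence[ConditionTimecourse]):
    groups: Dict[Tuple[str, str], List[ConditionTimecourse]] = {}
    for t in tcs:
        groups.setdefault((t.froi, t.condition), []).append(t)
    return groups


def surrogate_inference(
    study: StudyResult,
    n_sim: int = 1000,
    seed: int = 0,
    q: float = 0.05,
) -> pd.DataFrame:
    """Phase-randomization group tests for every (fROI, condition) cell of a
    study, FDR-corrected."""
    out = group_null_table(study.timecourses, n_sim=n_sim, seed=seed, q=q)
    nets = {f: n for f, n in zip(study.table["froi"], study.table["network"])}
    out["network"] = out["froi"].map(nets)
    return out
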