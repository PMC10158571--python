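"""File-backed interchange: NIfTI runs and masks, TSV tables, ground-truth JSON.

Synthetic datasets can be written to (and read back from) the on-disk layout
a neuroimaging pipeline expects: per-subject 4D BOLD NIfTI, 3D parcel and
tissue masks, BIDS-style motion and events TSVs, and a JSON sidecar holding
the generator's ground truth.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .localizer import LocalizerDesign
from .synthetic import BrainLayout, MultiSubjectRun

_AFFINE = np.diag([2.0, 2.0, 2.0, 1.0])  # 2 mm isotropic, like the analysis grid


def _to_4d(flat: np.ndarray, grid_shape: Tuple[int, int, int]) -> np.ndarray:
    return flat.reshape(*grid_shape, flat.shape[-1])


def write_run_nifti(path, bold: np.ndarray, grid_shape: Tuple[int, int, int], tr: float) -> None:
    """Write a voxel × time matrix as a 4D NIfTI with the TR in the header."""
    img = nib.Nifti1Image(_to_4d(bold, grid_shape).astype(np.float32), _AFFINE)
    img.header.set_zooms((2.0, 2.0, 2.0, tr))
    nib.save(img, str(path))


def read_run_nifti(path) -> Tuple[np.ndarray, float]:
    """Read a 4D NIfTI back into a voxel × time matrix (flat C-order indexing)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    tr = float(img.header.get_zooms()[3])
    return data.reshape(-1, data.shape[-1]), tr


def write_mask_nifti(path, indices: np.ndarray, grid_shape: Tuple[int, int, int]) -> None:
    vol = np.zeros(int(np.prod(grid_shape)), dtype=np.uint8)
    vol[np.asarray(indices)] = 1
    nib.save(nib.Nifti1Image(vol.reshape(grid_shape), _AFFINE), str(path))


def read_mask_nifti(path) -> np.ndarray:
    data = np.asarray(nib.load(str(path)).dataobj)
    return np.flatnonzero(data.reshape(-1) > 0)


def write_events_tsv(path, design: LocalizerDesign) -> None:
    rows = [{"onset": o, "duration": d, "condition": c} for o, d, c in design.blocks]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_events_tsv(path, n_frames: int, tr: float, contrast: Dict[str, float]) -> LocalizerDesign:
    df = pd.read_csv(path, sep="\t")
    blocks = [(float(r.onset), float(r.duration), str(r.condition)) for r in df.itertuples()]
    return LocalizerDesign(blocks, n_frames, tr, contrast)


def write_dataset(run: MultiSubjectRun, outdir) -> Path:
    """Write one multi-subject run to disk.

    Layout::

        outdir/
          sub-XX_task-<condition>_bold.nii.gz
          sub-XX_motion.tsv
          masks/parcel-<name>_mask.nii.gz, tissue-{gm,wm,csf}_mask.nii.gz
          ground_truth.json
    """
    outdir = Path(outdir)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    layout = run.layout
    cfg = run.config
    for i in range(run.n_subjects):
        stem = f"sub-{i:02d}"
        write_run_nifti(
            outdir / f"{stem}_task-{run.condition.name}_bold.nii.gz",
            run.bold[i], layout.grid_shape, cfg.tr,
        )
        run.motion[i].to_csv(outdir / f"{stem}_motion.tsv", sep="\t", index=False)
    for pname, vox in layout.parcels.items():
        write_mask_nifti(outdir / "masks" / f"parcel-{pname}_mask.nii.gz", vox, layout.grid_shape)
    for tname, vox in (("gm", layout.gm), ("wm", layout.wm), ("csf", layout.csf)):
        write_mask_nifti(outdir / "masks" / f"tissue-{tname}_mask.nii.gz", vox, layout.grid_shape)
    truth = {
        "condition": run.condition.name,
        "condition_type": run.condition.ctype,
        "seed": cfg.seed,
        "tr": cfg.tr,
        "coupling": run.ground_truth.coupling,
        "sigma_shared": cfg.sigma_shared,
        "sigma_subject": cfg.sigma_subject,
        "sigma_voxel": cfg.sigma_voxel,
        "shared_signal": run.ground_truth.shared_signal.tolist(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return outdir


def write_isc_tsv(table: pd.DataFrame, path) -> None:
    """Long-format ISC table as TSV (participant, network, froi, condition,
    condition_type, n_frames, r, z)."""
    table.to_csv(path, sep="\t", index=False)


def read_isc_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
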