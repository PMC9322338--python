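"""Reading and writing the package's on-disk formats.

Configs are JSON or YAML documents (YAML is a superset of JSON here);
time courses travel as CSV with a JSON metadata sidecar; image series are
written as one NIfTI volume per metabolite plus a JSON ground-truth ledger
and a CSV manifest.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field

from . import __version__
from .sim_core import (
    AcquisitionScheme,
    InputFunction,
    KineticParams,
    METABOLITES,
    PoolTimecourse,
)
from .synthetic_data import DynamicImageSeries

__all__ = [
    "SimConfig",
    "load_sim_config",
    "timecourse_to_frame",
    "write_timecourse",
    "read_timecourse",
    "write_series",
]


class SimConfig(BaseModel):
    """One simulation run: kinetics + scheme + pyruvate supply."""

    kinetics: KineticParams = Field(default_factory=KineticParams)
    scheme: AcquisitionScheme = Field(default_factory=AcquisitionScheme)
    input: InputFunction = Field(default_factory=InputFunction)


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a JSON/YAML simulation config."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return SimConfig.model_validate(doc or {})


def timecourse_to_frame(tc: PoolTimecourse) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "time_s": tc.times,
            "Mz_P": tc.Mz_P, "Mz_L": tc.Mz_L, "Mz_B": tc.Mz_B,
            "sig_P": tc.sig_P, "sig_L": tc.sig_L, "sig_B": tc.sig_B,
        }
    )


def write_timecourse(tc: PoolTimecourse, path: str | Path) -> None:
    """CSV with columns time_s, Mz_*, sig_* and a JSON sidecar echoing the
    generating configuration and package version."""
    path = Path(path)
    timecourse_to_frame(tc).to_csv(path, index=False)
    meta = {"package": "hp13c", "version": __version__}
    if tc.params is not None:
        meta["kinetics"] = tc.params.model_dump()
    if tc.scheme is not None:
        meta["scheme"] = tc.scheme.model_dump()
    if tc.input_fn is not None:
        meta["input"] = tc.input_fn.model_dump()
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(meta, sort_keys=True, indent=2)
    )


def read_timecourse(path: str | Path) -> pd.DataFrame:
    """Read a delimited time-course table (columns time_s, sig_P, sig_L,
    sig_B at minimum)."""
    df = pd.read_csv(path)
    missing = {"time_s", "sig_P", "sig_L", "sig_B"} - set(df.columns)
    if missing:
        raise ValueError(f"time-course table lacks columns: {sorted(missing)}")
    return df


def write_series(series: DynamicImageSeries, out_dir: str | Path) -> list[Path]:
    """Write one arm as NIfTI per metabolite + ground truth + manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vox = series.geometry["voxel_mm"]
    affine = np.diag([vox, vox, series.geometry["slice_mm"], 1.0])
    written = []
    rows = []
    for m, name in enumerate(METABOLITES):
        img = nib.Nifti1Image(series.voxels[:, :, :, m, :].astype(np.float32), affine)
        img.header.set_xyzt_units("mm", "sec")
        fname = out_dir / f"{series.subject_id}_{series.arm}_{name}.nii"
        nib.save(img, fname)
        written.append(fname)
        rows.append(dict(subject=series.subject_id, arm=series.arm,
                         metabolite=name, file=fname.name))
    ledger = out_dir / f"{series.subject_id}_{series.arm}_truth.json"
    ledger.write_text(json.dumps(
        {"ground_truth": series.ground_truth,
         "times_s": series.times.tolist(),
         "scheme": series.scheme.model_dump(),
         "geometry": series.geometry},
        sort_keys=True, indent=2))
    written.append(ledger)
    manifest = out_dir / "manifest.csv"
    df = pd.DataFrame(rows)
    if manifest.exists():
        df = pd.concat([pd.read_csv(manifest), df], ignore_index=True)
    df.to_csv(manifest, index=False)
    written.append(manifest)
    return written
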