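"""Delimited-text I/O for gated polar maps, cohort tables and reports.

All formats are plain CSV with headers.  Gated polar maps are stored
long-form, one row per (ring, angle, frame) sample: ring 0 is the apex,
angle index 0 the anterior wall increasing anterior -> septal ->
inferior -> lateral as viewed from the apex, frames 0-based within one
R-R cycle.  One file per patient.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .perfusion import SegmentProfile
from .phase import GatedPolarSamples, PolarGeometry
from .stats import PatientRecord, records_to_frame

GATED_COLUMNS = ["ring", "angle", "frame", "counts"]


def write_gated_counts(path, gated: GatedPolarSamples) -> None:
    """Write one patient's gated polar map as `ring,angle,frame,counts`."""
    g = gated.geometry
    rings, angles, frames = np.meshgrid(
        np.arange(g.n_rings), np.arange(g.n_angles), np.arange(g.n_frames), indexing="ij"
    )
    pd.DataFrame({
        "ring": rings.ravel(),
        "angle": angles.ravel(),
        "frame": frames.ravel(),
        "counts": gated.counts.ravel(),
    }).to_csv(path, index=False)


def read_gated_counts(path) -> GatedPolarSamples:
    """Read a gated polar map written by :func:`write_gated_counts`.

    The geometry is inferred from the index ranges; the grid must be
    complete (every ring/angle/frame combination present exactly once).
    """
    df = pd.read_csv(path)
    missing = [c for c in GATED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    n_rings = int(df["ring"].max()) + 1
    n_angles = int(df["angle"].max()) + 1
    n_frames = int(df["frame"].max()) + 1
    geometry = PolarGeometry(n_rings=n_rings, n_angles=n_angles, n_frames=n_frames)
    if len(df) != n_rings * n_angles * n_frames:
        raise ValueError(f"{path}: incomplete polar grid")
    counts = np.zeros((n_rings, n_angles, n_frames))
    counts[df["ring"], df["angle"], df["frame"]] = df["counts"]
    return GatedPolarSamples(geometry=geometry, counts=counts)


def write_cohort(path, records: Sequence[PatientRecord]) -> None:
    """Write the cohort table, one row per patient, derived labels included."""
    records_to_frame(records).to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    """Read a cohort table; derives response labels if absent."""
    from .stats import label_response, label_super_response

    df = pd.read_csv(path)
    if "response" not in df.columns:
        df["response"] = [
            int(label_response(b, f))
            for b, f in zip(df["lvef_baseline_pct"], df["lvef_6mo_pct"])
        ]
    if "super_response" not in df.columns:
        df["super_response"] = [
            int(label_super_response(b, f))
            for b, f in zip(df["lvef_baseline_pct"], df["lvef_6mo_pct"])
        ]
    return df


def write_segment_profile(path, profile: SegmentProfile) -> None:
    """Write `segment,mean_phase_deg,scar_pct,n_samples`."""
    pd.DataFrame({
        "segment": profile.segment_ids,
        "mean_phase_deg": profile.mean_phase_deg,
        "scar_pct": profile.scar_pct,
        "n_samples": profile.sample_count,
    }).to_csv(path, index=False)


def list_gated_files(input_dir) -> list[Path]:
    """Deterministically ordered gated polar-map files in a directory."""
    return sorted(Path(input_dir).glob("*.csv"))
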