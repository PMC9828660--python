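"""Scan-archive persistence and raster visualization.

An archive is a directory of plain-text files:

- ``manifest.yaml`` — acquisition metadata (rates, counts, pixel spacing,
  stimulus onset sample, optional seed/provenance), units in the key names;
- ``sweeps.csv`` — long-format sweep samples
  (``position_index, sweep_index, sample_index, amplitude_uV``);
- ``track.csv`` — per-position needle tip and three landmark coordinates;
- ``truth.csv`` — optional per-position generator ground truth.

Reads and writes round-trip exactly (floats serialized at full repr
precision).
"""
from __future__ import annotations

import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

from .analysis import CorrectedTrack, MUPMeasurement
from .records import NeedleTrack, ScanRecording
from .synth import ScanGroundTruth

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402  (backend must be set first)

log = logging.getLogger("muscan")

__all__ = [
    "REQUIRED_MANIFEST_FIELDS",
    "write_scan_archive",
    "read_scan_archive",
    "read_ground_truth",
    "plot_scan_raster",
]

REQUIRED_MANIFEST_FIELDS = (
    "sampling_rate_hz",
    "stim_rate_hz",
    "sweeps_per_position",
    "n_positions",
    "pixel_spacing_mm",
    "stim_onset_index",
)

_TRACK_COLUMNS = [
    "position_index",
    "needle_x", "needle_y",
    "lm1_x", "lm1_y", "lm2_x", "lm2_y", "lm3_x", "lm3_y",
]


def write_scan_archive(
    path: str | Path,
    recording: ScanRecording,
    track: NeedleTrack,
    stim_rate_hz: float = 2.0,
    seed: int | None = None,
    truth: ScanGroundTruth | None = None,
    provenance: str = "muscan synthetic generator",
) -> Path:
    """Write a scan archive directory; returns its path."""
    if recording.n_positions != track.n_positions:
        raise ValueError("recording and track position counts differ")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    manifest = {
        "sampling_rate_hz": float(recording.sampling_rate_hz),
        "stim_rate_hz": float(stim_rate_hz),
        "sweeps_per_position": int(recording.sweeps_per_position),
        "n_positions": int(recording.n_positions),
        "n_samples": int(recording.n_samples),
        "pixel_spacing_mm": float(track.pixel_spacing_mm),
        "stim_onset_index": int(recording.stim_onset_index),
        "provenance": provenance,
    }
    if seed is not None:
        manifest["seed"] = int(seed)
    if truth is not None:
        manifest["true_territory_extent_mm"] = float(truth.true_territory_extent_mm)
    (path / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))

    p, s, n = recording.sweeps.shape
    idx = pd.MultiIndex.from_product(
        [range(p), range(s), range(n)],
        names=["position_index", "sweep_index", "sample_index"],
    )
    sweeps_df = pd.DataFrame(
        {"amplitude_uV": recording.sweeps.ravel()}, index=idx
    ).reset_index()
    # %.17g round-trips IEEE doubles exactly
    sweeps_df.to_csv(path / "sweeps.csv", index=False, float_format="%.17g")

    track_df = pd.DataFrame(
        np.column_stack(
            [np.arange(p), track.needle_xy, track.landmarks_xy.reshape(p, 6)]
        ),
        columns=_TRACK_COLUMNS,
    )
    track_df["position_index"] = track_df["position_index"].astype(int)
    track_df.to_csv(path / "track.csv", index=False, float_format="%.17g")

    if truth is not None:
        truth_df = pd.DataFrame(
            {
                "position_index": np.arange(p),
                "position_mm": truth.true_positions_mm,
                "amplitude_uV": truth.true_amplitude_uV,
                "latency_ms": truth.true_latency_ms,
                "duration_ms": truth.true_duration_ms,
                "cannula": truth.cannula_positions.astype(int),
                "n_fired": truth.fired_flags.sum(axis=1),
            }
        )
        truth_df.to_csv(path / "truth.csv", index=False, float_format="%.17g")
    log.info("wrote scan archive to %s (%d positions, %d sweeps each)", path, p, s)
    return path


def _read_csv(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise FileNotFoundError(f"archive file missing: {path}")
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing column(s) {missing}")
    bad = df[required].isna()
    if bad.any().any():
        line = int(bad.any(axis=1).idxmax()) + 2  # 1-based, after header
        raise ValueError(f"{path}: malformed or missing value at line {line}")
    return df


def read_scan_archive(path: str | Path) -> tuple[ScanRecording, NeedleTrack, dict]:
    """Read a scan archive; returns (recording, track, manifest)."""
    path = Path(path)
    manifest_path = path / "manifest.yaml"
    if not manifest_path.exists():
        raise FileNotFoundError(f"archive manifest missing: {manifest_path}")
    manifest = yaml.safe_load(manifest_path.read_text())
    if not isinstance(manifest, dict):
        raise ValueError(f"{manifest_path}: manifest is not a mapping")
    for fieldname in REQUIRED_MANIFEST_FIELDS:
        if fieldname not in manifest:
            raise ValueError(f"{manifest_path}: missing required field {fieldname!r}")

    p = int(manifest["n_positions"])
    s = int(manifest["sweeps_per_position"])

    sweeps_df = _read_csv(
        path / "sweeps.csv",
        ["position_index", "sweep_index", "sample_index", "amplitude_uV"],
    )
    n = int(sweeps_df["sample_index"].max()) + 1
    if len(sweeps_df) != p * s * n:
        raise ValueError(
            f"{path / 'sweeps.csv'}: expected {p * s * n} rows "
            f"({p} positions x {s} sweeps x {n} samples), found {len(sweeps_df)}"
        )
    sweeps_df = sweeps_df.sort_values(["position_index", "sweep_index", "sample_index"])
    sweeps = sweeps_df["amplitude_uV"].to_numpy().reshape(p, s, n)

    track_df = _read_csv(path / "track.csv", _TRACK_COLUMNS)
    if sorted(track_df["position_index"]) != list(range(p)):
        raise ValueError(
            f"{path / 'track.csv'}: position indices do not match the "
            f"{p} positions declared in the manifest"
        )
    track_df = track_df.sort_values("position_index")
    track = NeedleTrack(
        needle_xy=track_df[["needle_x", "needle_y"]].to_numpy(),
        landmarks_xy=track_df[
            ["lm1_x", "lm1_y", "lm2_x", "lm2_y", "lm3_x", "lm3_y"]
        ].to_numpy().reshape(p, 3, 2),
        pixel_spacing_mm=float(manifest["pixel_spacing_mm"]),
    )
    recording = ScanRecording(
        sweeps=sweeps,
        sampling_rate_hz=float(manifest["sampling_rate_hz"]),
        stim_onset_index=int(manifest["stim_onset_index"]),
    )
    return recording, track, manifest


def read_ground_truth(path: str | Path) -> pd.DataFrame:
    """Per-position generator ground truth, if the archive stored it."""
    return _read_csv(
        Path(path) / "truth.csv",
        ["position_index", "position_mm", "amplitude_uV"],
    )


def plot_scan_raster(
    recording: ScanRecording,
    corrected: CorrectedTrack | None = None,
    measurements: list[MUPMeasurement] | None = None,
    out_path: str | Path | None = None,
    average: bool = False,
) -> "plt.Figure":
    """Stacked stimulus-locked traces, one group per needle position.

    The y origin is the deepest needle position; each position's traces are
    offset by its distance (mm, along the corrected track when available)
    from that origin, so the vertical axis reads as withdrawn distance.
    Stimulus time is x = 0. Valid positions are drawn in color, invalid in
    gray; ``average=True`` plots the per-position mean trace instead of all
    sweeps overlaid.
    """
    if recording.n_positions == 0:
        raise ValueError("empty recording")
    if corrected is not None:
        xy = corrected.corrected_xy
        # distance from the deepest (first) position along the track, in mm
        offsets_mm = (
            np.linalg.norm(xy - xy[0], axis=1) * corrected.pixel_spacing_mm
        )
    else:
        offsets_mm = np.arange(recording.n_positions, dtype=float)
    t_ms = recording.time_ms()

    peak = np.abs(recording.sweeps).max() or 1.0
    spacing = np.diff(np.sort(offsets_mm))
    gain = 0.45 * (spacing[spacing > 0].min() if (spacing > 0).any() else 1.0) / peak

    fig, ax = plt.subplots(figsize=(7, 6))
    order = np.argsort(offsets_mm)
    for p in order:
        valid = measurements[p].valid if measurements is not None else True
        color = "C0" if valid else "0.6"
        traces = recording.sweeps[p]
        if average:
            traces = traces.mean(axis=0, keepdims=True)
        for trace in traces:
            ax.plot(t_ms, offsets_mm[p] + gain * trace, color=color, lw=0.5, alpha=0.8)
    ax.axvline(0.0, color="k", lw=0.8, ls=":")
    ax.set_xlabel("time after stimulus (ms)")
    ax.set_ylabel("withdrawn distance from deepest position (mm)")
    ax.set_title("stimulus-locked sweeps by needle position")
    if out_path is not None:
        fig.savefig(out_path, dpi=150)
        log.info("wrote raster plot to %s", out_path)
    return fig
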