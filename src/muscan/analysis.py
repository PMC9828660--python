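"""Measurement pipeline for scanning-EMG transects.

Converts raw scan archives into drift-corrected motor-unit territory
measurements in four stages:

1. *Drift correction* — the mean frame-to-frame displacement of three
   fascial-plane landmarks estimates probe drift / tissue distortion; its
   cumulative sum is subtracted from the raw needle-tip coordinates,
   anchoring the corrected track at the first (deepest) position.
2. *MUP detection* — each stimulus-locked sweep at a position is classified
   fired or flat by its peak-to-peak amplitude inside the response window
   (stimulus artifact blanked). A position holds a valid motor-unit
   potential when enough sweeps fired with synchronous onset latencies and
   the amplitude exceeds the 50 uV validity rule used in scanning EMG.
3. *Territory extent* — the Euclidean distance between the corrected needle
   positions of the outermost valid traces.
4. *Summaries* — per-transect maxima (amplitude = maximum peak-to-peak at
   any valid position, duration = longest at any valid position, latency =
   earliest onset) and cohort-level statistics.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import NeedleTrack, ScanRecording

__all__ = [
    "CorrectedTrack",
    "DetectionConfig",
    "MUPMeasurement",
    "ExtentResult",
    "TransectSummary",
    "correct_needle_positions",
    "detect_mup",
    "territory_extent",
    "transect_summary",
    "analyze_scan",
    "summaries_to_frame",
    "summarize_cohort",
]


# --------------------------------------------------------------------------
# drift correction
# --------------------------------------------------------------------------

@dataclass
class CorrectedTrack:
    """Needle track after landmark-based drift compensation."""

    corrected_xy: np.ndarray  # (n_positions, 2) pixels
    delta_landmark_px: np.ndarray  # (n_positions - 1, 2) mean landmark step
    cumulative_drift_px: np.ndarray  # (n_positions, 2)
    pixel_spacing_mm: float

    @property
    def n_positions(self) -> int:
        return self.corrected_xy.shape[0]

    def corrected_mm(self) -> np.ndarray:
        return self.corrected_xy * self.pixel_spacing_mm

    def step_sizes_mm(self) -> np.ndarray:
        """Realized distances between consecutive corrected positions."""
        d = np.diff(self.corrected_xy, axis=0)
        return np.linalg.norm(d, axis=1) * self.pixel_spacing_mm


def correct_needle_positions(track: NeedleTrack) -> CorrectedTrack:
    """Compensate needle coordinates for probe drift and tissue distortion.

    Per step, the drift estimate is the mean over the three landmarks of
    their coordinate change between consecutive positions; the corrected
    needle position subtracts the *accumulated* drift from the raw
    coordinate, anchored at the first position. With static landmarks the
    corrected track equals the raw one, and adding a common translation to
    the needle and all landmarks at any step leaves the corrected track
    unchanged.
    """
    if track.n_positions < 2:
        raise ValueError("drift correction needs at least 2 positions")
    delta = np.diff(track.landmarks_xy, axis=0).mean(axis=1)  # (P-1, 2)
    cum = np.vstack([np.zeros(2), np.cumsum(delta, axis=0)])
    return CorrectedTrack(
        corrected_xy=track.needle_xy - cum,
        delta_landmark_px=delta,
        cumulative_drift_px=cum,
        pixel_spacing_mm=track.pixel_spacing_mm,
    )


# --------------------------------------------------------------------------
# MUP detection
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionConfig:
    """Rules replacing the manual marking of valid traces.

    ``threshold_uv`` is the scanning-EMG validity rule (peak-to-peak above
    50 uV); a position further needs ``min_fired`` firing sweeps whose
    onset latencies agree within ``latency_sd_tol_ms`` (synchronicity). The
    onset threshold is ``onset_k`` baseline SDs with an absolute floor so
    the rule remains defined on noise-free records.
    """

    threshold_uv: float = 50.0
    min_fired: int = 3
    latency_sd_tol_ms: float = 1.0
    response_window_ms: tuple[float, float] = (2.0, 100.0)
    blank_ms: float = 1.0
    onset_k: float = 3.0
    onset_floor_uv: float = 2.0
    min_consecutive: int = 5

    def __post_init__(self) -> None:
        if self.threshold_uv <= 0 or self.min_fired < 1:
            raise ValueError("threshold must be positive, min_fired >= 1")
        lo, hi = self.response_window_ms
        if not 0 <= lo < hi:
            raise ValueError("response window must be an increasing pair of ms >= 0")


@dataclass
class MUPMeasurement:
    """Per-position detection outcome."""

    valid: bool
    peak_to_peak_uV: float
    onset_latency_ms: float
    duration_ms: float
    fired_sweep_flags: np.ndarray = field(repr=False)
    n_fired: int = 0


def _onset_end(
    dev: np.ndarray, min_consecutive: int
) -> tuple[int, int] | None:
    """First index of the first run and last index of the last run of at
    least ``min_consecutive`` consecutive True samples; None if no run."""
    if not dev.any():
        return None
    padded = np.concatenate([[False], dev, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, stops = edges[::2], edges[1::2]
    long_enough = (stops - starts) >= min_consecutive
    if not long_enough.any():
        return None
    starts, stops = starts[long_enough], stops[long_enough]
    return int(starts[0]), int(stops[-1] - 1)


def detect_mup(
    sweeps: np.ndarray,
    sampling_rate_hz: float,
    stim_onset_index: int,
    config: DetectionConfig | None = None,
) -> MUPMeasurement:
    """Classify the sweeps at one needle position and measure the MUP.

    Each sweep is fired when its peak-to-peak amplitude inside the response
    window (first ``blank_ms`` after the stimulus excluded) exceeds the
    validity threshold. A fired sweep's onset is the first run of at least
    ``min_consecutive`` samples deviating from the pre-stimulus baseline by
    more than ``max(onset_k * baseline_SD, onset_floor_uv)``; its end is the
    last sample of the last such run. The position-level amplitude is the
    maximum over fired sweeps; latency and duration are medians over fired
    sweeps. All-flat input is a normal outcome (``valid=False``), not an
    error.
    """
    if config is None:
        config = DetectionConfig()
    sweeps = np.atleast_2d(np.asarray(sweeps, dtype=float))
    if sweeps.shape[0] < 1 or sweeps.shape[1] <= stim_onset_index:
        raise ValueError("need at least one sweep extending past the stimulus")
    fs = sampling_rate_hz

    def ms_to_idx(ms: float) -> int:
        return stim_onset_index + int(round(ms * fs / 1000.0))

    w0, w1 = (min(ms_to_idx(m), sweeps.shape[1]) for m in config.response_window_ms)
    blank_end = ms_to_idx(config.blank_ms)
    search0 = max(blank_end, stim_onset_index)

    n_sweeps = sweeps.shape[0]
    fired = np.zeros(n_sweeps, dtype=bool)
    p2p = np.zeros(n_sweeps)
    latency = np.full(n_sweeps, np.nan)
    duration = np.full(n_sweeps, np.nan)

    for s in range(n_sweeps):
        window = sweeps[s, w0:w1]
        p2p[s] = window.max() - window.min() if window.size else 0.0
        if p2p[s] <= config.threshold_uv:
            continue
        fired[s] = True
        baseline = sweeps[s, :stim_onset_index]
        bmean = baseline.mean() if baseline.size else 0.0
        bsd = baseline.std() if baseline.size else 0.0
        thr = max(config.onset_k * bsd, config.onset_floor_uv)
        dev = np.abs(sweeps[s, search0:] - bmean) > thr
        run = _onset_end(dev, config.min_consecutive)
        if run is None:
            continue
        onset, end = (search0 + i for i in run)
        latency[s] = (onset - stim_onset_index) * 1000.0 / fs
        duration[s] = (end - onset + 1) * 1000.0 / fs

    n_fired = int(fired.sum())
    have_onsets = fired & ~np.isnan(latency)
    synchronous = (
        have_onsets.sum() >= config.min_fired
        and float(np.std(latency[have_onsets])) <= config.latency_sd_tol_ms
    )
    valid = n_fired >= config.min_fired and synchronous
    return MUPMeasurement(
        valid=valid,
        peak_to_peak_uV=float(p2p[fired].max()) if n_fired else float(p2p.max()),
        onset_latency_ms=float(np.median(latency[have_onsets])) if have_onsets.any() else np.nan,
        duration_ms=float(np.median(duration[have_onsets])) if have_onsets.any() else np.nan,
        fired_sweep_flags=fired,
        n_fired=n_fired,
    )


# --------------------------------------------------------------------------
# territory extent and summaries
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ExtentResult:
    extent_mm: float
    boundary_indices: tuple[int, int] | None
    single_position: bool  # <= 1 valid position: extent reported as 0


def territory_extent(
    corrected: CorrectedTrack, measurements: list[MUPMeasurement]
) -> ExtentResult:
    """Distance between the outermost valid traces along the corrected track.

    The spatial extent of the motor unit is the Euclidean distance in mm
    between the corrected needle positions of the first and last positions
    holding a valid MUP. With one or zero valid positions the extent is 0
    and flagged rather than failing: sparse hand-stepped transects of small
    units legitimately produce such scans.
    """
    if corrected.n_positions == 0 or len(measurements) == 0:
        raise ValueError("empty scan")
    if corrected.n_positions != len(measurements):
        raise ValueError("track and measurement lengths differ")
    valid_idx = [i for i, m in enumerate(measurements) if m.valid]
    if len(valid_idx) <= 1:
        idx = (valid_idx[0], valid_idx[0]) if valid_idx else None
        return ExtentResult(extent_mm=0.0, boundary_indices=idx, single_position=True)
    i, j = valid_idx[0], valid_idx[-1]
    d = np.linalg.norm(corrected.corrected_xy[j] - corrected.corrected_xy[i])
    return ExtentResult(
        extent_mm=float(d * corrected.pixel_spacing_mm),
        boundary_indices=(i, j),
        single_position=False,
    )


@dataclass
class TransectSummary:
    """Per-recording summary mirroring the per-scan report columns."""

    territory_extent_mm: float
    n_positions_in_mu: int
    max_amplitude_uV: float
    longest_duration_ms: float
    earliest_latency_ms: float
    step_sizes_mm: np.ndarray = field(repr=False)
    single_position: bool = False
    empty: bool = False  # no valid position anywhere in the scan


def transect_summary(
    corrected: CorrectedTrack, measurements: list[MUPMeasurement]
) -> TransectSummary:
    """Summarize one transect: maximum peak-to-peak amplitude at any valid
    position, longest duration at any valid position, earliest onset
    latency, territory extent, and realized step sizes."""
    ext = territory_extent(corrected, measurements)
    valid = [m for m in measurements if m.valid]
    steps = corrected.step_sizes_mm()
    if not valid:
        return TransectSummary(
            territory_extent_mm=0.0,
            n_positions_in_mu=0,
            max_amplitude_uV=np.nan,
            longest_duration_ms=np.nan,
            earliest_latency_ms=np.nan,
            step_sizes_mm=steps,
            single_position=True,
            empty=True,
        )
    return TransectSummary(
        territory_extent_mm=ext.extent_mm,
        n_positions_in_mu=len(valid),
        max_amplitude_uV=max(m.peak_to_peak_uV for m in valid),
        longest_duration_ms=float(np.nanmax([m.duration_ms for m in valid])),
        earliest_latency_ms=float(np.nanmin([m.onset_latency_ms for m in valid])),
        step_sizes_mm=steps,
        single_position=ext.single_position,
    )


def analyze_scan(
    recording: ScanRecording,
    track: NeedleTrack,
    config: DetectionConfig | None = None,
) -> tuple[CorrectedTrack, list[MUPMeasurement], TransectSummary]:
    """Full pipeline for one scan archive: drift correction, per-position
    detection, transect summary."""
    if recording.n_positions != track.n_positions:
        raise ValueError(
            f"recording has {recording.n_positions} positions but track has "
            f"{track.n_positions}"
        )
    corrected = correct_needle_positions(track)
    measurements = [
        detect_mup(
            recording.sweeps[p],
            recording.sampling_rate_hz,
            recording.stim_onset_index,
            config,
        )
        for p in range(recording.n_positions)
    ]
    return corrected, measurements, transect_summary(corrected, measurements)


# --------------------------------------------------------------------------
# cohort statistics
# --------------------------------------------------------------------------

def summaries_to_frame(rows: list[TransectSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "transect_length_mm": [r.territory_extent_mm for r in rows],
            "n_positions": [r.n_positions_in_mu for r in rows],
            "max_amplitude_uV": [r.max_amplitude_uV for r in rows],
            "mup_duration_ms": [r.longest_duration_ms for r in rows],
            "onset_latency_ms": [r.earliest_latency_ms for r in rows],
            "mean_step_mm": [
                float(np.mean(r.step_sizes_mm)) if len(r.step_sizes_mm) else np.nan
                for r in rows
            ],
        }
    )


def _parse_mmss(value: str) -> float:
    minutes, seconds = value.split(":")
    return 60.0 * int(minutes) + float(seconds)


def _format_mmss(seconds: float) -> str:
    whole = int(seconds // 60)
    return f"{whole:02d}:{int(seconds - 60 * whole):02d}"


def summarize_cohort(rows: pd.DataFrame | list[TransectSummary]) -> dict:
    """Cohort statistics over per-transect rows.

    Numeric columns are averaged; position counts additionally get a
    median (scan counts are small and skewed); ``experiment_duration``
    given as mm:ss strings is averaged on seconds and reported back as
    mm:ss. Values are full precision — round to each column's printed
    precision for standardized comparison. A single row summarizes to
    itself.
    """
    if isinstance(rows, list):
        if len(rows) == 0:
            raise ValueError("empty cohort")
        rows = summaries_to_frame(rows)
    if len(rows) == 0:
        raise ValueError("empty cohort")
    out: dict = {"n_recordings": int(len(rows))}
    for col in rows.columns:
        if col == "id":
            continue
        if col == "experiment_duration":
            secs = rows[col].map(_parse_mmss)
            out["mean_experiment_duration"] = _format_mmss(float(secs.mean()))
            continue
        series = pd.to_numeric(rows[col], errors="coerce")
        out[f"mean_{col}"] = float(series.mean())
        if col in ("n_positions", "transect_steps"):
            out[f"median_{col}"] = float(series.median())
    return out
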