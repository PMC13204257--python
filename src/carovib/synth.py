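"""Synthetic bilateral cohorts of carotid vibration recordings.

The clinical signal this emulates is the skin-surface acceleration produced by
carotid blood flow: every cardiac cycle launches a low-frequency (< 20 Hz)
systolic pulse, and a narrowed or dissected lumen adds a turbulence burst whose
energy sits higher in the band (roughly 20-40 Hz) and grows with lesion
severity.  Each simulated carotid side therefore receives

* a beat-locked train of exponentially damped sinusoids near 8-15 Hz,
* a severity-scaled burst of band-limited Gaussian noise gated over the
  systolic interval of each beat,
* broadband sensor noise and a sub-0.5 Hz baseline drift,

with beat-to-beat jitter in timing and amplitude, per-patient physiology
(heart rate, pulse frequency) shared across that patient's recordings, and two
sensor positions per side differing by a small multiplicative gain.

Severity is a number in [0, 1]; a side is labelled pathological when severity
is at or above :data:`SEVERITY_LABEL_CUT` (the synthetic analogue of the >=50 %
stenosis decision threshold).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal
from scipy.io import wavfile

SEVERITY_LABEL_CUT = 0.5
SIDES = ("L", "R")


@dataclass(frozen=True)
class CohortConfig:
    """Generation parameters for one synthetic cohort.

    ``severity_range`` applies to pathological sides only; non-pathological
    sides draw severity uniformly below the label cut.  ``fast=True`` generates
    directly at ``fs_raw / 10`` (2.4 kHz by default) so the decimation stage is
    skipped downstream; the manifest records the flag.
    """

    n_patients: int = 60
    prevalence_side: float = 0.30
    severity_range: tuple[float, float] = (0.5, 1.0)
    heart_rate_bpm: tuple[float, float] = (70.0, 10.0)  # mean, SD across patients
    duration_s: float = 60.0
    fs_raw: float = 24000.0
    pulse_center_freq_hz: tuple[float, float] = (8.0, 15.0)
    turbulence_band_hz: tuple[float, float] = (20.0, 40.0)
    turbulence_gain: float = 0.8
    # per-side phenotype diversity: the burst band shifts by U(-j, +j) Hz,
    # emulating stenosis-like (lower) vs dissection-like (broader/higher) bruits
    turbulence_band_jitter_hz: float = 6.0
    # convex dose-response: burst amplitude ~ severity**exponent, so
    # lower-stenosis sides show little mid-band elevation
    severity_exponent: float = 2.0
    noise_sd: float = 0.08
    # sensor coupling and skin properties vary between placements: the
    # realized noise SD is noise_sd times U(lo, hi) per recording
    noise_level_jitter: tuple[float, float] = (0.5, 1.5)
    drift_amp: float = 0.3
    positions_per_side: int = 2
    position_gain_jitter: float = 0.15
    beat_jitter_frac: float = 0.04
    pulse_decay_s: float = 0.06
    # inter-patient waveform morphology: relative 2nd-harmonic amplitude and
    # multiplicative jitter on the pulse ring-down time
    harmonic_amp_range: tuple[float, float] = (0.0, 1.0)
    pulse_decay_jitter: tuple[float, float] = (0.66, 1.5)
    burst_window_s: tuple[float, float] = (0.03, 0.25)  # offset, length after beat
    seed: int = 0
    fast: bool = False

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients: must be >= 1")
        if not 0.0 <= self.prevalence_side <= 1.0:
            raise ValueError("prevalence_side: must lie in [0, 1]")
        lo, hi = self.severity_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("severity_range: must be an interval within [0, 1]")
        if hi < SEVERITY_LABEL_CUT:
            raise ValueError(
                "severity_range: upper end below the label cut "
                f"{SEVERITY_LABEL_CUT}; pathological sides would be unlabellable"
            )
        if self.duration_s <= 0:
            raise ValueError("duration_s: must be positive")
        if self.fs_raw <= 0:
            raise ValueError("fs_raw: must be positive")
        b_lo, b_hi = self.turbulence_band_hz
        if not (0.0 < b_lo < b_hi < self.fs_effective / 2):
            raise ValueError("turbulence_band_hz: must lie within (0, fs/2)")
        if self.positions_per_side < 1:
            raise ValueError("positions_per_side: must be >= 1")
        if self.heart_rate_bpm[0] <= 0:
            raise ValueError("heart_rate_bpm: mean must be positive")

    @property
    def fs_effective(self) -> float:
        """Sampling rate the samples are actually generated at."""
        return self.fs_raw / 10.0 if self.fast else self.fs_raw


@dataclass(frozen=True)
class GroundTruth:
    patient_id: str
    side: str  # "L" or "R"
    severity: float

    @property
    def label(self) -> int:
        return int(self.severity >= SEVERITY_LABEL_CUT)


@dataclass(frozen=True)
class Physiology:
    """Per-patient physiological parameters shared by all of a patient's recordings.

    Real carotid pulses are non-sinusoidal and vary in waveform across
    subjects: ``harmonic_amp`` sets the relative strength of the second
    harmonic of the pulse oscillation and ``pulse_decay_s`` the ring-down time
    of the systolic transient, both drawn once per patient.
    """

    heart_rate_bpm: float
    pulse_freq_hz: float
    harmonic_amp: float = 0.3
    pulse_decay_s: float = 0.06


@dataclass
class Recording:
    samples: np.ndarray
    fs: float
    patient_id: str
    side: str
    position: int
    truth: GroundTruth

    @property
    def group_key(self) -> str:
        return f"{self.patient_id}:{self.side}"


def _substream(master_seed: int, *tokens) -> np.random.Generator:
    """Independent RNG stream keyed by content, not by insertion order."""
    h = hashlib.blake2b("|".join(str(t) for t in tokens).encode(), digest_size=16)
    words = np.frombuffer(h.digest(), dtype=np.uint32)
    return np.random.default_rng([int(master_seed) & 0x7FFFFFFF, *map(int, words)])


def _draw_physiology(config: CohortConfig, patient_id: str) -> Physiology:
    rng = _substream(config.seed, "phys", patient_id)
    hr_mean, hr_sd = config.heart_rate_bpm
    hr = float(np.clip(rng.normal(hr_mean, hr_sd), 40.0, 140.0))
    f_lo, f_hi = config.pulse_center_freq_hz
    return Physiology(
        heart_rate_bpm=hr,
        pulse_freq_hz=float(rng.uniform(f_lo, f_hi)),
        harmonic_amp=float(rng.uniform(*config.harmonic_amp_range)),
        pulse_decay_s=float(rng.uniform(*config.pulse_decay_jitter) * config.pulse_decay_s),
    )


def _draw_severity(config: CohortConfig, patient_id: str, side: str) -> GroundTruth:
    rng = _substream(config.seed, "truth", patient_id, side)
    pathological = rng.uniform() < config.prevalence_side
    lo, hi = config.severity_range
    if pathological:
        sev = float(rng.uniform(max(lo, SEVERITY_LABEL_CUT), hi))
    else:
        sev = float(rng.uniform(0.0, SEVERITY_LABEL_CUT * 0.999))
    return GroundTruth(patient_id=patient_id, side=side, severity=sev)


def generate_recording(
    truth: GroundTruth,
    phys: Physiology,
    position: int,
    config: CohortConfig,
    seed: int | None = None,
) -> Recording:
    """Synthesise one carotid-side recording at one sensor position.

    The additive model is

    ``x(t) = sum_beats pulse(t) + severity * gain * sum_beats burst(t)
             + white noise + drift``

    where each pulse is an exponentially damped sinusoid at the patient's pulse
    frequency and each burst is band-pass-filtered Gaussian noise gated by a
    Hann window over the systolic interval.
    """
    if not 0.0 <= truth.severity <= 1.0:
        raise ValueError("severity: must lie in [0, 1]")
    master = config.seed if seed is None else seed
    rng = _substream(master, "rec", truth.patient_id, truth.side, position)

    fs = config.fs_effective
    n = int(round(config.duration_s * fs))
    t = np.arange(n) / fs

    # --- beat times: mean RR interval with per-beat jitter -------------------
    rr = 60.0 / phys.heart_rate_bpm
    n_beats = int(np.ceil(config.duration_s / rr)) + 2
    intervals = rr * (1.0 + config.beat_jitter_frac * rng.standard_normal(n_beats))
    beat_times = np.cumsum(np.clip(intervals, 0.3 * rr, 2.0 * rr)) - intervals[0]
    beat_times = beat_times[beat_times < config.duration_s]
    beat_idx = np.round(beat_times * fs).astype(int)
    beat_idx = beat_idx[beat_idx < n]

    # --- systolic pulse train: impulse train (*) damped sinusoid kernel ------
    amps = 1.0 + 0.1 * rng.standard_normal(beat_idx.size)
    impulses = np.zeros(n)
    np.add.at(impulses, beat_idx, amps)
    tau = phys.pulse_decay_s
    k_len = int(round(8.0 * tau * fs))
    tk = np.arange(k_len) / fs
    kernel = np.exp(-tk / tau) * (
        np.sin(2 * np.pi * phys.pulse_freq_hz * tk)
        + phys.harmonic_amp * np.sin(4 * np.pi * phys.pulse_freq_hz * tk)
    )
    pulses = signal.fftconvolve(impulses, kernel)[:n]

    # --- turbulence bursts: gated band-limited noise --------------------------
    x = pulses
    if truth.severity > 0 and config.turbulence_gain > 0:
        band_rng = _substream(master, "phenotype", truth.patient_id, truth.side)
        # dissection-like sides (broader, higher bruit band) are the minority
        # phenotype; stenotic bruits sit at or below the nominal band
        if band_rng.uniform() < 0.25:
            shift = float(band_rng.uniform(0.0, 1.0)) * config.turbulence_band_jitter_hz
        else:
            shift = -float(band_rng.uniform(0.0, 1.0)) * config.turbulence_band_jitter_hz
        lo = max(config.turbulence_band_hz[0] + shift, 5.0)
        hi = min(config.turbulence_band_hz[1] + shift, 0.45 * fs)
        # steep shaping keeps the burst confined to its band (little skirt
        # leakage above the upper edge)
        sos = signal.butter(4, (lo, hi), btype="bandpass", fs=fs, output="sos")
        band_noise = signal.sosfilt(sos, rng.standard_normal(n))
        band_noise /= max(np.std(band_noise), 1e-12)
        off_s, len_s = config.burst_window_s
        w_len = int(round(len_s * fs))
        window = np.hanning(w_len)
        gate = np.zeros(n)
        off = int(round(off_s * fs))
        for b0, a in zip(beat_idx, amps):
            s = b0 + off
            e = min(s + w_len, n)
            if s < n:
                gate[s:e] += a * window[: e - s]
        dose = truth.severity**config.severity_exponent
        x = x + dose * config.turbulence_gain * gate * band_noise

    # --- sensor noise and slow baseline drift --------------------------------
    if config.noise_sd > 0:
        level = config.noise_sd * float(rng.uniform(*config.noise_level_jitter))
        x = x + level * rng.standard_normal(n)
    if config.drift_amp > 0:
        f1, f2 = rng.uniform(0.05, 0.4, size=2)
        p1, p2 = rng.uniform(0, 2 * np.pi, size=2)
        x = x + config.drift_amp * (np.sin(2 * np.pi * f1 * t + p1) + 0.5 * np.sin(2 * np.pi * f2 * t + p2))

    # --- sensor reposition gain ----------------------------------------------
    if position != 1 and config.position_gain_jitter > 0:
        gain_rng = _substream(master, "gain", truth.patient_id, truth.side, position)
        x = x * float(np.exp(config.position_gain_jitter * gain_rng.standard_normal()))

    return Recording(
        samples=x.astype(np.float64),
        fs=fs,
        patient_id=truth.patient_id,
        side=truth.side,
        position=position,
        truth=truth,
    )


def generate_cohort(config: CohortConfig) -> tuple[list[Recording], pd.DataFrame]:
    """Generate ``n_patients x 2 sides x positions_per_side`` recordings.

    Deterministic given ``config.seed``; every recording draws from an RNG
    substream keyed by (patient, side, position) so the result does not depend
    on generation order.
    """
    config.validate()
    recordings: list[Recording] = []
    truth_rows = []
    for i in range(config.n_patients):
        pid = f"P{i:04d}"
        phys = _draw_physiology(config, pid)
        for side in SIDES:
            truth = _draw_severity(config, pid, side)
            truth_rows.append(
                {
                    "patient_id": pid,
                    "side": side,
                    "severity": truth.severity,
                    "label": truth.label,
                }
            )
            for position in range(1, config.positions_per_side + 1):
                recordings.append(generate_recording(truth, phys, position, config))
    truth_table = pd.DataFrame(truth_rows)
    return recordings, truth_table


def write_cohort(
    recordings: Sequence[Recording],
    truth: pd.DataFrame,
    out_dir: str | Path,
    config: CohortConfig | None = None,
) -> Path:
    """Write one float32 WAV per recording plus metadata CSV and manifest JSON.

    Returns the manifest path.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    files = []
    for rec in recordings:
        fname = f"{rec.patient_id}_{rec.side}_pos{rec.position}.wav"
        try:
            wavfile.write(out_dir / fname, int(round(rec.fs)), rec.samples.astype(np.float32))
        except OSError as exc:  # pragma: no cover - I/O failure path
            raise OSError(f"failed writing {out_dir / fname}: {exc}") from exc
        meta_rows.append(
            {
                "patient_id": rec.patient_id,
                "side": rec.side,
                "position": rec.position,
                "severity": rec.truth.severity,
                "label": rec.truth.label,
                "filename": fname,
            }
        )
        files.append(fname)
    meta = pd.DataFrame(meta_rows)
    meta.to_csv(out_dir / "metadata.csv", index=False)
    truth.to_csv(out_dir / "ground_truth.csv", index=False)
    manifest = {
        "format": "carovib-cohort/1",
        "n_recordings": len(files),
        "files": files,
        "metadata_csv": "metadata.csv",
        "ground_truth_csv": "ground_truth.csv",
        "fast": bool(config.fast) if config is not None else bool(recordings and recordings[0].fs < 10000),
        "fs_hz": float(recordings[0].fs) if recordings else None,
        "config": config_to_dict(config) if config is not None else None,
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest_path


def read_cohort(cohort_dir: str | Path) -> tuple[list[Recording], pd.DataFrame]:
    """Load a cohort written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    manifest = json.loads((cohort_dir / "manifest.json").read_text())
    meta = pd.read_csv(cohort_dir / manifest["metadata_csv"])
    truth = pd.read_csv(cohort_dir / manifest["ground_truth_csv"])
    recordings = []
    for row in meta.itertuples(index=False):
        fs, samples = wavfile.read(cohort_dir / row.filename)
        truth_obj = GroundTruth(patient_id=row.patient_id, side=row.side, severity=float(row.severity))
        recordings.append(
            Recording(
                samples=np.asarray(samples, dtype=np.float64),
                fs=float(fs),
                patient_id=row.patient_id,
                side=row.side,
                position=int(row.position),
                truth=truth_obj,
            )
        )
    return recordings, truth


def config_to_dict(config: CohortConfig) -> dict:
    return dataclasses.asdict(config)
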