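"""Synthetic single-lead ECG records with known beat labels.

The generator produces WFDB-like records for exercising the full pipeline
without any database download: a periodic train of beats built from Gaussian
bumps (P, Q, R, S, T), low-frequency sinusoidal baseline wander, additive
Gaussian noise, class-dependent RR timing and a configurable four-class
imbalance (defaults mirror the MIT-BIH inter-patient benchmark: ~89.5% N,
2.8% SVEB, 6.9% VEB, 0.8% F).

Class signatures
----------------
* N — full P-QRS-T morphology, regular timing.
* SVEB — near-normal QRS with an attenuated P wave; its defining feature is
  timing: the preceding RR interval is shortened by a prematurity factor
  (< 1) and followed by a compensatory pause, so the RR features carry most
  of the discriminative signal, as for real atrial premature beats.
* VEB — wide, bizarre QRS (broad R, deep slurred S), no P wave, inverted T.
* F — an equal-weight superposition of the N and VEB morphologies, i.e. a
  fusion beat genuinely intermediate between the two and hence the hardest
  minority class, mirroring the real data's F class.

These are stylized beats, not a physiological ODE model; see the project
methods note for what that does and does not let tests demonstrate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .mitdb_io import AAMIClass, EcgRecord

__all__ = [
    "SyntheticConfig",
    "generate_record",
    "generate_patients",
    "write_record",
    "CLASS_SYMBOLS",
    "MIN_BEATS",
]

#: One canonical MIT-BIH symbol per AAMI class.
CLASS_SYMBOLS = {AAMIClass.N: "N", AAMIClass.SVEB: "A", AAMIClass.VEB: "V", AAMIClass.F: "F"}

#: Minimum beats per record: the local-RR feature looks back 10 intervals.
MIN_BEATS = 12

# Beat morphology templates: (offset_s from R, gaussian sigma_s, amplitude_mV)
_N_COMPONENTS = (
    (-0.200, 0.025, 0.15),   # P
    (-0.030, 0.010, -0.10),  # Q
    (0.000, 0.012, 1.00),    # R
    (0.030, 0.010, -0.25),   # S
    (0.220, 0.030, 0.30),    # T
)
_SVEB_COMPONENTS = (
    (-0.160, 0.020, 0.05),   # attenuated P (ectopic atrial focus)
    (-0.030, 0.010, -0.10),
    (0.000, 0.012, 1.00),
    (0.030, 0.010, -0.25),
    (0.220, 0.030, 0.30),
)
_VEB_COMPONENTS = (
    (0.000, 0.035, 0.95),    # broad R
    (0.055, 0.030, -0.55),   # deep slurred S
    (0.185, 0.028, -0.20),   # discordant (inverted) T
)
_F_COMPONENTS = tuple(
    (off, sig, 0.5 * amp) for off, sig, amp in _N_COMPONENTS
) + tuple((off, sig, 0.5 * amp) for off, sig, amp in _VEB_COMPONENTS)

_CLASS_COMPONENTS = {
    AAMIClass.N: _N_COMPONENTS,
    AAMIClass.SVEB: _SVEB_COMPONENTS,
    AAMIClass.VEB: _VEB_COMPONENTS,
    AAMIClass.F: _F_COMPONENTS,
}

#: Margin (s) kept free of beat centers at each record edge so every beat's
#: waveform (and its 200-sample segment) fits inside the record.
_EDGE_START_S = 0.40
_EDGE_END_S = 0.45


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults emulate the MIT-BIH study conditions."""

    sampling_rate_hz: float = 360.0
    duration_s: float = 60.0
    class_proportions: tuple[float, float, float, float] = (0.895, 0.028, 0.069, 0.008)
    mean_rr_s: float = 0.8
    rr_jitter_sd_s: float = 0.04
    wander_amplitude: float = 0.20
    wander_period_s: float = 3.0
    noise_sd: float = 0.02
    seed: int = 0
    #: Factor (< 1) shortening the RR interval that precedes an SVEB beat.
    sveb_prematurity: float = 0.65
    #: Per-record scaling of beat amplitudes (inter-patient variation knob).
    amplitude_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0 or self.duration_s <= 0 or self.mean_rr_s <= 0:
            raise ValueError("sampling_rate_hz, duration_s and mean_rr_s must be > 0")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (4,) or np.any(props < 0):
            raise ValueError("class_proportions must be 4 nonnegative numbers")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class_proportions must sum to 1 (got {props.sum():.12f})"
            )
        if self.rr_jitter_sd_s < 0 or self.wander_amplitude < 0 or self.noise_sd < 0:
            raise ValueError("rr_jitter_sd_s, wander_amplitude, noise_sd must be >= 0")
        if self.wander_period_s <= 0.6:
            raise ValueError(
                "wander_period_s must exceed 0.6 s so the wander survives the "
                "600-ms median filter"
            )
        if not 0 < self.sveb_prematurity < 1:
            raise ValueError("sveb_prematurity must be in (0, 1)")


def _schedule_beats(
    config: SyntheticConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw beat times (s) and classes; SVEB beats arrive early and are
    followed by a compensatory pause."""
    props = np.asarray(config.class_proportions, dtype=float)
    times: list[float] = []
    classes: list[int] = []
    t = _EDGE_START_S
    cls = int(rng.choice(4, p=props))
    limit = config.duration_s - _EDGE_END_S
    while t <= limit:
        times.append(t)
        classes.append(cls)
        nxt = int(rng.choice(4, p=props))
        interval = config.mean_rr_s + rng.normal(0.0, config.rr_jitter_sd_s)
        interval = max(0.4 * config.mean_rr_s, interval)
        if nxt == AAMIClass.SVEB:
            interval = min(interval, config.mean_rr_s) * config.sveb_prematurity
        elif cls == AAMIClass.SVEB:
            interval *= 2.0 - config.sveb_prematurity  # compensatory pause
        t += interval
        cls = nxt
    return np.asarray(times), np.asarray(classes, dtype=int)


def generate_record(config: SyntheticConfig) -> EcgRecord:
    """Synthesize one record; fully reproducible from ``config.seed``.

    Raises if the duration cannot hold at least 12 beats (the local-RR
    feature needs 10 prior intervals).
    """
    if config.duration_s / config.mean_rr_s < MIN_BEATS + 1:
        raise ValueError(
            f"duration {config.duration_s} s holds fewer than the minimum "
            f"{MIN_BEATS} beats at mean RR {config.mean_rr_s} s"
        )
    rng = np.random.default_rng(config.seed)
    fs = config.sampling_rate_hz
    n = int(round(config.duration_s * fs))
    t_axis = np.arange(n) / fs

    beat_times, beat_classes = _schedule_beats(config, rng)
    signal = np.zeros(n)
    half = int(0.5 * fs)  # beat support: +/- 0.5 s around R
    for bt, bc in zip(beat_times, beat_classes):
        center = int(round(bt * fs))
        lo, hi = max(0, center - half), min(n, center + half)
        tt = t_axis[lo:hi] - bt
        for off, sig, amp in _CLASS_COMPONENTS[AAMIClass(bc)]:
            signal[lo:hi] += (
                config.amplitude_scale * amp * np.exp(-0.5 * ((tt - off) / sig) ** 2)
            )

    if config.wander_amplitude > 0:
        ph1, ph2 = rng.uniform(0, 2 * np.pi, size=2)
        signal += config.wander_amplitude * (
            0.7 * np.sin(2 * np.pi * t_axis / config.wander_period_s + ph1)
            + 0.3 * np.sin(2 * np.pi * t_axis / (1.55 * config.wander_period_s) + ph2)
        )
    if config.noise_sd > 0:
        signal += rng.normal(0.0, config.noise_sd, size=n)

    annotations = [
        (int(round(bt * fs)), CLASS_SYMBOLS[AAMIClass(bc)])
        for bt, bc in zip(beat_times, beat_classes)
    ]
    return EcgRecord(f"syn{config.seed:08d}", fs, signal, annotations)


def generate_patients(
    n_records: int, base_config: SyntheticConfig, seed: int | None = None
) -> list[EcgRecord]:
    """Generate ``n_records`` records with inter-patient variation.

    Each record gets its own child seed plus a patient-specific resting rate
    (mean RR scaled by U(0.85, 1.15)) and beat amplitude (scaled by
    U(0.85, 1.15)), so records drawn here behave like distinct patients for
    inter-patient train/test splits.
    """
    rng = np.random.default_rng(base_config.seed if seed is None else seed)
    records = []
    for _ in range(n_records):
        child = replace(
            base_config,
            seed=int(rng.integers(2**31 - 1)),
            mean_rr_s=base_config.mean_rr_s * rng.uniform(0.85, 1.15),
            amplitude_scale=base_config.amplitude_scale * rng.uniform(0.85, 1.15),
        )
        records.append(generate_record(child))
    return records


def write_record(record: EcgRecord, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the plain-text dialect: ``<id>.csv`` and ``<id>.ann.json``.

    The CSV holds one amplitude per line with a leading comment carrying the
    sampling rate; the JSON is a list of ``{"sample": int, "symbol": str}``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    csv_path = out_dir / f"{record.record_id}.csv"
    ann_path = out_dir / f"{record.record_id}.ann.json"
    lines = [f"# sampling_rate_hz={record.sampling_rate_hz:g}"]
    lines.extend(f"{v:.6f}" for v in record.signal)
    csv_path.write_text("\n".join(lines) + "\n")
    ann_path.write_text(
        json.dumps(
            [{"sample": int(s), "symbol": sym} for s, sym in record.annotations]
        )
    )
    return csv_path, ann_path
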