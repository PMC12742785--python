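"""Synthetic fNIRS cohort generator.

Emulates a 15-channel prefrontal montage sampled at 8 Hz through one
block-design cycle (rest 30 s / preparation 30 s / rest 10 s / play 60 s /
rest 30 s = 160 s).  Each channel carries a task-evoked hemodynamic
response (block design convolved with a canonical double-gamma kernel),
a slow linear drift, physiological oscillations (cardiac ~1 Hz,
respiratory ~0.3 Hz, Mayer waves ~0.1 Hz) with per-channel phase jitter,
and white measurement noise.

A group-by-task effect can be planted in configurable channels: short
Gaussian transients plus white-noise variance inflation restricted to the
play block.  The effect deliberately perturbs *dynamics* rather than mean
level, because the downstream autoencoder is trained on z-scored
score-task windows and is therefore blind to amplitude offsets.

Every output is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma

from .io import CohortManifest, Recording, save_manifest, write_wide_csv


class ConfigError(ValueError):
    """A generator configuration violates its invariants."""


@dataclass(frozen=True)
class TaskTiming:
    """Durations (s) of the five blocks of one experimental cycle."""

    rest1_s: float = 30.0
    prep_s: float = 30.0
    rest2_s: float = 10.0
    play_s: float = 60.0
    rest3_s: float = 30.0

    def __post_init__(self) -> None:
        for name in ("rest1_s", "prep_s", "rest2_s", "play_s", "rest3_s"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    @property
    def total_s(self) -> float:
        return self.rest1_s + self.prep_s + self.rest2_s + self.play_s + self.rest3_s


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise model: white noise + linear drift + physiological sinusoids.

    ``osc_components`` is a list of (frequency Hz, amplitude) pairs; defaults
    are the three standard fNIRS physiological bands.  ``osc_phase_jitter``
    (radians) is the half-width of the uniform per-channel phase draw.
    """

    white_sd: float = 0.3
    drift_coeff: float = 0.002  # amplitude units per second
    osc_components: tuple = ((1.0, 0.10), (0.3, 0.15), (0.1, 0.20))
    osc_phase_jitter: float = float(np.pi)

    def validate(self, rate_hz: float) -> None:
        if self.white_sd < 0:
            raise ConfigError("white_sd must be >= 0")
        for freq, amp in self.osc_components:
            if amp < 0:
                raise ConfigError("oscillation amplitudes must be >= 0")
            if freq >= rate_hz / 2:
                raise ConfigError(f"oscillation at {freq} Hz violates Nyquist for rate {rate_hz} Hz")


@dataclass(frozen=True)
class EffectSpec:
    """Plantable group-by-task effect, confined to the play block.

    burst_rate: expected transient count per play block (Poisson).
    burst_amp_sd: transient amplitude in units of white_sd.
    variance_inflation: multiplicative factor on white-noise variance in
    target channels during play.
    """

    target_channels: tuple = (1, 15)
    burst_rate: float = 5.0
    burst_amp_sd: float = 10.0
    burst_width_s: float = 1.0
    variance_inflation: float = 2.0

    def __post_init__(self) -> None:
        if self.burst_rate < 0:
            raise ConfigError("burst_rate must be >= 0")
        if self.variance_inflation < 1:
            raise ConfigError("variance_inflation must be >= 1")

    def is_null(self) -> bool:
        return self.burst_rate == 0 and self.variance_inflation == 1


@dataclass(frozen=True)
class CohortConfig:
    """Cohort layout: group A ("pianist", n=16) vs group B ("non_pianist", n=6)."""

    n_group_a: int = 16
    n_group_b: int = 6
    rate_hz: float = 8.0
    n_channels: int = 15
    timing: TaskTiming = field(default_factory=TaskTiming)
    noise: NoiseParams = field(default_factory=NoiseParams)
    effect: EffectSpec = field(default_factory=EffectSpec)
    seed: int = 0
    repeat_cycles: int = 1
    gain_sigma: float = 0.2  # lognormal sd of per-subject channel gains
    inject_group_b: bool = False

    def __post_init__(self) -> None:
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ConfigError("group sizes must be >= 1")
        if self.rate_hz <= 0:
            raise ConfigError("rate_hz must be > 0")
        if self.n_channels < 1:
            raise ConfigError("n_channels must be >= 1")
        if self.repeat_cycles < 1:
            raise ConfigError("repeat_cycles must be >= 1")
        bad = [c for c in self.effect.target_channels if not 1 <= c <= self.n_channels]
        if bad:
            raise ConfigError(f"effect target channels {bad} outside 1..{self.n_channels}")
        self.noise.validate(self.rate_hz)


@dataclass
class CohortData:
    recordings: list
    manifest: CohortManifest
    config: CohortConfig

    def get(self, subject_id: str, task: str) -> Recording:
        for rec in self.recordings:
            if rec.subject_id == subject_id and rec.task == task:
                return rec
        raise KeyError((subject_id, task))


def make_block_design(timing: TaskTiming, rate_hz: float) -> np.ndarray:
    """0/1 indicator over one cycle; 1 exactly on the play interval.

    The play interval [rest1+prep+rest2, rest1+prep+rest2+play) is half-open
    in seconds, mapped to 0-based samples.
    """
    if rate_hz <= 0:
        raise ConfigError("rate_hz must be > 0")
    n = int(round(timing.total_s * rate_hz))
    onset = int(round((timing.rest1_s + timing.prep_s + timing.rest2_s) * rate_hz))
    offset = int(round((timing.rest1_s + timing.prep_s + timing.rest2_s + timing.play_s) * rate_hz))
    design = np.zeros(n)
    design[onset:offset] = 1.0
    return design


def double_gamma_kernel(
    rate_hz: float,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    undershoot_ratio: float = 1.0 / 6.0,
    length_s: float = 32.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic impulse response, sampled at rate_hz.

    Gamma shapes are peak_s+1 and undershoot_s+1 with unit scale, so the
    positive lobe peaks at peak_s and the undershoot at undershoot_s.
    """
    t = np.arange(int(round(length_s * rate_hz))) / rate_hz
    kernel = _gamma.pdf(t, a=peak_s + 1.0) - undershoot_ratio * _gamma.pdf(t, a=undershoot_s + 1.0)
    return kernel


def hemodynamic_response(design: np.ndarray, rate_hz: float, **hrf_params) -> np.ndarray:
    """Convolve a 0/1 design with the double-gamma kernel (dt-scaled).

    The 1/rate scaling makes the discrete convolution approximate the
    continuous one, so the response amplitude is rate-independent.
    """
    design = np.asarray(design, dtype=float)
    if design.size and not np.all(np.isin(design, (0.0, 1.0))):
        raise ValueError("design must be a 0/1 indicator")
    kernel = double_gamma_kernel(rate_hz, **hrf_params)
    out = np.convolve(design, kernel)[: len(design)] / rate_hz
    return out


def simulate_recording(
    config: CohortConfig,
    group: str,
    task: str,
    subject_seed: int,
) -> Recording:
    """One subject x task recording: evoked response + drift + oscillations + noise.

    Channel gains are drawn once per subject (shared across tasks via a
    task-independent stream); noise streams differ per task.
    """
    timing, noise = config.timing, config.noise
    design = np.tile(make_block_design(timing, config.rate_hz), config.repeat_cycles)
    evoked = hemodynamic_response(design, config.rate_hz)
    n = len(design)
    t = np.arange(n) / config.rate_hz
    C = config.n_channels

    gain_rng = np.random.default_rng([int(subject_seed), 0])
    gains = np.exp(gain_rng.normal(0.0, config.gain_sigma, size=C))

    task_code = {"score": 1, "improv": 2}.get(task, 3)
    rng = np.random.default_rng([int(subject_seed), task_code])
    data = np.empty((n, C))
    for c in range(C):
        x = gains[c] * evoked + noise.drift_coeff * t
        for freq, amp in noise.osc_components:
            phase = rng.uniform(-noise.osc_phase_jitter, noise.osc_phase_jitter)
            x = x + amp * np.sin(2 * np.pi * freq * t + phase)
        x = x + rng.normal(0.0, noise.white_sd, size=n) if noise.white_sd > 0 else x
        data[:, c] = x
    return Recording(
        subject_id=f"S{subject_seed}",
        group=group,
        task=task,
        rate_hz=config.rate_hz,
        data=data,
        channel_ids=list(range(1, C + 1)),
    )


def inject_channel_effect(
    recording: Recording,
    effect: EffectSpec,
    design: np.ndarray,
    seed: int,
    white_sd: float = 1.0,
) -> Recording:
    """Plant play-block transients + variance inflation in the target channels.

    Poisson-count Gaussian bumps (width ~1 s) of amplitude burst_amp_sd x
    white_sd are added inside the play block, and white-noise variance there
    is multiplied by variance_inflation.  Non-target channels are returned
    bit-identical.  ``white_sd`` is the amplitude unit (the cohort's
    white-noise sd).
    """
    design = np.asarray(design, dtype=float)
    if len(design) != recording.n_samples:
        raise ValueError(
            f"design length {len(design)} != recording length {recording.n_samples}"
        )
    for ch in effect.target_channels:
        if ch not in recording.channel_ids:
            raise KeyError(f"unknown channel id {ch}")
    if effect.is_null():
        return recording.with_data(recording.data.copy())

    sd = white_sd
    rng = np.random.default_rng([int(seed), 7])
    play = np.flatnonzero(design > 0)
    rate = recording.rate_hz
    t = np.arange(recording.n_samples) / rate
    data = recording.data.copy()
    n_blocks = max(1, _count_blocks(design))
    for ch in effect.target_channels:
        col = recording.channel_index(ch)
        if play.size:
            n_events = rng.poisson(effect.burst_rate * n_blocks)
            centers = rng.choice(play, size=n_events, replace=True) if n_events else []
            width = effect.burst_width_s / 2.0  # Gaussian sigma; FWHM ~ 1.2 s
            for idx in centers:
                sign = rng.choice((-1.0, 1.0))
                bump = sign * effect.burst_amp_sd * sd * np.exp(
                    -0.5 * ((t - t[idx]) / width) ** 2
                )
                data[:, col] += bump
            if effect.variance_inflation > 1:
                extra_sd = sd * np.sqrt(effect.variance_inflation - 1.0)
                data[play, col] += rng.normal(0.0, extra_sd, size=play.size)
    return recording.with_data(data)


def _count_blocks(design: np.ndarray) -> int:
    d = np.asarray(design) > 0
    return int(np.sum(d[1:] & ~d[:-1]) + (1 if d.size and d[0] else 0))


def simulate_cohort(config: CohortConfig) -> CohortData:
    """Generate the full labeled cohort: one score + one improv recording per subject.

    Score recordings are never injected.  Improv recordings of group A
    ("pianist") receive the effect; group B only when ``inject_group_b``.
    """
    seed_rng = np.random.default_rng(config.seed)
    n_total = config.n_group_a + config.n_group_b
    subject_seeds = seed_rng.integers(0, 2**31 - 1, size=n_total)
    design = np.tile(make_block_design(config.timing, config.rate_hz), config.repeat_cycles)

    recordings = []
    rows = []
    for i in range(n_total):
        in_a = i < config.n_group_a
        group = "pianist" if in_a else "non_pianist"
        sid = f"{'P' if in_a else 'N'}{(i if in_a else i - config.n_group_a) + 1:02d}"
        sseed = int(subject_seeds[i])
        for task in ("score", "improv"):
            rec = simulate_recording(config, group, task, sseed)
            rec.subject_id = sid
            if task == "improv" and (in_a or config.inject_group_b):
                rec = inject_channel_effect(
                    rec, config.effect, design, sseed, white_sd=config.noise.white_sd
                )
            recordings.append(rec)
            rows.append({"subject_id": sid, "group": group, "task": task, "file": "", "seed": sseed})
    manifest = CohortManifest(pd.DataFrame(rows))
    return CohortData(recordings=recordings, manifest=manifest, config=config)


def write_cohort(cohort: CohortData, outdir: str | Path) -> Path:
    """Write each recording as wide CSV plus a manifest CSV referencing them."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table = cohort.manifest.table.copy()
    for i, rec in enumerate(cohort.recordings):
        fname = f"{rec.subject_id}_{rec.task}.csv"
        write_wide_csv(rec, outdir / fname)
        table.loc[i, "file"] = fname
    manifest = CohortManifest(table)
    save_manifest(manifest, outdir / "manifest.csv")
    return outdir / "manifest.csv"
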