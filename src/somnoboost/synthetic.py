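"""Seeded synthetic EEG: Markov hypnograms + stage-dependent spectral content.

The generator emulates the features of overnight single-channel EEG that the
staging pipeline exploits, without claiming physiological realism:

* 100 Hz sampling and 30-s epoch-aligned stage labels over {W, N1, N2, SWS, REM};
* stage-dependent band content — α/β1 in wake, θ in N1, σ spindle bursts plus
  K-complex pulses in N2, large δ in SWS, θ/β2 in REM — on a 1/f background;
* Markov stage persistence (sticky diagonal), so that ±1-epoch feature
  shifting carries real information;
* subject age metadata (drawn uniformly from 20–60 years).

Two presets: ``easy`` (well-separated band amplitudes) and ``hard`` (smaller
stage contrasts, more background noise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .edf_io import Hypnogram, Recording, write_edf
from .stages import EPOCH_SECONDS, STAGES

__all__ = [
    "StageSpectralProfile",
    "MarkovHypnogramSpec",
    "DEFAULT_PROFILES",
    "HARD_PROFILES",
    "DEFAULT_TRANSITIONS",
    "simulate_hypnogram",
    "simulate_recording",
    "simulate_subject",
    "make_fixture",
]

#: Analysis-band centre frequencies used for the synthetic oscillations (Hz).
_BAND_CENTRES = {
    "delta": 1.5,
    "theta": 6.0,
    "alpha": 10.0,
    "sigma": 13.5,
    "beta1": 17.0,
    "beta2": 25.0,
    "gamma1": 35.0,
    "gamma2": 44.0,
}


@dataclass(frozen=True)
class StageSpectralProfile:
    """Band-amplitude map (µV) plus transient content for one stage."""

    amplitudes: dict  # band name -> sinusoid amplitude, µV
    pink_scale: float = 5.0  # 1/f background RMS, µV
    pink_exponent: float = 1.0
    spindles_per_epoch: int = 0  # 1-s 13.5 Hz bursts
    spindle_amplitude: float = 0.0
    kcomplex_per_epoch: int = 0  # 0.7 Hz biphasic pulses
    kcomplex_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.amplitudes.values()):
            raise ValueError("band amplitudes must be non-negative")
        if not self.amplitudes and self.pink_scale == 0:
            raise ValueError("at least one band amplitude must be positive")


DEFAULT_PROFILES: dict[str, StageSpectralProfile] = {
    "W": StageSpectralProfile({"alpha": 20.0, "beta1": 10.0}),
    "N1": StageSpectralProfile({"theta": 15.0}),
    "N2": StageSpectralProfile(
        {"theta": 8.0},
        spindles_per_epoch=2,
        spindle_amplitude=15.0,
        kcomplex_per_epoch=1,
        kcomplex_amplitude=40.0,
    ),
    "SWS": StageSpectralProfile({"delta": 40.0}),
    "REM": StageSpectralProfile({"theta": 10.0, "beta2": 8.0}),
}

#: Harder preset: 40 % of the stage-specific amplitudes, doubled background.
HARD_PROFILES: dict[str, StageSpectralProfile] = {
    stage: StageSpectralProfile(
        {b: 0.4 * a for b, a in p.amplitudes.items()},
        pink_scale=2 * p.pink_scale,
        pink_exponent=p.pink_exponent,
        spindles_per_epoch=p.spindles_per_epoch,
        spindle_amplitude=0.4 * p.spindle_amplitude,
        kcomplex_per_epoch=p.kcomplex_per_epoch,
        kcomplex_amplitude=0.4 * p.kcomplex_amplitude,
    )
    for stage, p in DEFAULT_PROFILES.items()
}

#: Sticky stage-transition matrix (rows/cols in W,N1,N2,SWS,REM order).
DEFAULT_TRANSITIONS = np.array(
    [
        #  W     N1     N2    SWS    REM
        [0.88, 0.09, 0.01, 0.00, 0.02],  # W
        [0.04, 0.80, 0.12, 0.00, 0.04],  # N1
        [0.01, 0.04, 0.85, 0.06, 0.04],  # N2
        [0.00, 0.01, 0.09, 0.88, 0.02],  # SWS
        [0.02, 0.04, 0.04, 0.00, 0.90],  # REM
    ]
)


@dataclass
class MarkovHypnogramSpec:
    transitions: np.ndarray = field(default_factory=lambda: DEFAULT_TRANSITIONS.copy())
    initial: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0, 0]))
    n_epochs: int = 400
    seed: int = 0

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if self.transitions.shape != (5, 5) or np.abs(
            self.transitions.sum(axis=1) - 1
        ).max() > 1e-9 or (self.transitions < 0).any():
            raise ValueError("transition matrix must be 5×5 row-stochastic")
        if abs(self.initial.sum() - 1) > 1e-9 or (self.initial < 0).any():
            raise ValueError("initial distribution must be a probability vector")


def simulate_hypnogram(spec: MarkovHypnogramSpec) -> Hypnogram:
    """Seeded Markov-chain stage sequence."""
    rng = np.random.default_rng(spec.seed)
    states = np.empty(spec.n_epochs, dtype=int)
    states[0] = rng.choice(5, p=spec.initial)
    for t in range(1, spec.n_epochs):
        states[t] = rng.choice(5, p=spec.transitions[states[t - 1]])
    return Hypnogram([STAGES[s] for s in states])


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """FFT-shaped 1/f^exponent noise, unit RMS."""
    white = rng.standard_normal(n)
    spectrum = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    freqs[0] = freqs[1]
    spectrum *= freqs ** (-exponent / 2)
    x = np.fft.irfft(spectrum, n)
    return x / x.std()


def _epoch_signal(
    profile: StageSpectralProfile, rate: float, rng: np.random.Generator
) -> np.ndarray:
    n = int(round(rate * EPOCH_SECONDS))
    t = np.arange(n) / rate
    x = np.zeros(n)
    for band, amp in profile.amplitudes.items():
        if amp <= 0:
            continue
        centre = _BAND_CENTRES[band]
        freq = centre * (1 + rng.uniform(-0.06, 0.06))
        x += amp * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
    for _ in range(profile.spindles_per_epoch):
        start = rng.integers(0, n - int(rate))
        width = int(rate)  # 1-s burst
        window = np.hanning(width)
        tt = np.arange(width) / rate
        burst = profile.spindle_amplitude * window * np.sin(
            2 * np.pi * 13.5 * tt + rng.uniform(0, 2 * np.pi)
        )
        x[start : start + width] += burst
    for _ in range(profile.kcomplex_per_epoch):
        width = int(round(rate / 0.7))  # one 0.7 Hz cycle
        start = rng.integers(0, n - width)
        tt = np.arange(width) / rate
        pulse = profile.kcomplex_amplitude * np.sin(2 * np.pi * 0.7 * tt)
        x[start : start + width] += pulse * np.hanning(width)
    if profile.pink_scale > 0:
        x += profile.pink_scale * _pink_noise(n, profile.pink_exponent, rng)
    return x


def simulate_recording(
    hypnogram: Hypnogram,
    profiles: dict[str, StageSpectralProfile] | None = None,
    rate: float = 100.0,
    seed: int = 0,
    age: float = 30.0,
    sex: str = "U",
    rec_id: str = "synthetic",
) -> Recording:
    """Stage-conditional synthetic EEG matched to the hypnogram, 3000 samples/epoch."""
    profiles = profiles or DEFAULT_PROFILES
    missing = set(hypnogram.stages) - set(profiles)
    if missing:
        raise ValueError(f"no spectral profile for stages {sorted(missing)}")
    rng = np.random.default_rng(seed)
    pieces = [_epoch_signal(profiles[stage], rate, rng) for stage in hypnogram.stages]
    return Recording(
        samples=np.concatenate(pieces),
        rate=rate,
        age=age,
        sex=sex,
        id=rec_id,
    )


def simulate_subject(
    n_epochs: int,
    preset: str = "easy",
    seed: int = 0,
    rec_id: str = "synthetic",
) -> tuple[Recording, Hypnogram]:
    """One subject: seeded hypnogram + matched recording + age metadata."""
    profiles = {"easy": DEFAULT_PROFILES, "hard": HARD_PROFILES}.get(preset)
    if profiles is None:
        raise ValueError(f"unknown preset {preset!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA9E]))
    age = float(rng.integers(20, 61))
    sex = "F" if rng.integers(2) else "M"
    hyp = simulate_hypnogram(
        MarkovHypnogramSpec(n_epochs=n_epochs, seed=seed)
    )
    rec = simulate_recording(
        hyp, profiles, seed=seed + 1, age=age, sex=sex, rec_id=rec_id
    )
    return rec, hyp


def make_fixture(
    n_subjects: int,
    epochs_per_subject: int,
    preset: str = "easy",
    seed: int = 0,
    out_dir: str | Path = ".",
) -> Path:
    """Write paired signal/hypnogram EDF files plus a JSON manifest.

    Returns the manifest path; the manifest lists every file, the per-subject
    seeds and the generator parameters, and is byte-identical for equal seeds.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for s in range(n_subjects):
        subj_seed = seed * 1000 + s
        rec_id = f"SYN{s:02d}"
        rec, hyp = simulate_subject(
            epochs_per_subject, preset=preset, seed=subj_seed, rec_id=rec_id
        )
        psg, hyp_path = write_edf(rec, hyp, out_dir / rec_id)
        entries.append(
            {
                "id": rec_id,
                "psg": psg.name,
                "hypnogram": hyp_path.name,
                "seed": subj_seed,
                "age": rec.age,
                "sex": rec.sex,
                "epochs": epochs_per_subject,
            }
        )
    manifest = {
        "preset": preset,
        "seed": seed,
        "n_subjects": n_subjects,
        "epochs_per_subject": epochs_per_subject,
        "subjects": entries,
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
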