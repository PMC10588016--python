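"""Synthetic labeled ECG generator for three rhythm classes.

A template-based model: each beat is a sum of five Gaussian bumps (P, Q, R,
S, T) placed at cumulative RR intervals drawn from a truncated normal
distribution.  The three presets emulate the gross rhythm features that
separate the target classes —

* **NSR** (normal sinus rhythm): regular 75 bpm, full-amplitude beats.
* **ARR** (arrhythmia): highly variable RR intervals plus occasional
  ectopic beats (wide QRS, 1.3x amplitude, absent P wave).
* **CHF** (congestive heart failure): fast (100 bpm), metronomically regular
  rhythm with reduced QRS amplitude.

Additive white noise and sinusoidal baseline wander (respiratory-band
drift) complete the signal.  Everything is deterministic given the seed.
This generator targets class separability for pipeline testing, not
physiological realism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import ECGRecord

__all__ = ["RhythmSpec", "PRESETS", "generate_record", "generate_dataset", "BEAT_WAVES"]

# Per-wave morphology defaults: (time offset from R peak [s], Gaussian width
# [s], amplitude [mV]).  Amplitudes are pre qrs_amplitude_scale.
BEAT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (-0.20, 0.025, 0.15),
    "Q": (-0.03, 0.010, -0.12),
    "R": (0.00, 0.012, 1.00),
    "S": (0.03, 0.010, -0.25),
    "T": (0.25, 0.055, 0.35),
}

# Ectopic beat: QRS width x2.5, amplitude x1.3, P wave removed.
ECTOPIC_WIDTH_FACTOR = 2.5
ECTOPIC_AMP_FACTOR = 1.3

RR_FLOOR = 0.2  # s; truncation of the RR distribution


@dataclass(frozen=True)
class RhythmSpec:
    """Generative parameters for one rhythm class.

    rr_mean/rr_sd parameterize the (truncated) normal RR-interval
    distribution in seconds; ectopic_rate is the per-beat probability of an
    ectopic replacement; qrs_amplitude_scale multiplies the Q, R and S bump
    amplitudes; noise_sd is additive white noise in millivolts; the baseline
    wander is a sinusoid of the given amplitude (mV) and frequency (Hz).
    """

    class_label: str
    rr_mean: float
    rr_sd: float
    ectopic_rate: float = 0.0
    qrs_amplitude_scale: float = 1.0
    noise_sd: float = 0.05
    baseline_wander_amp: float = 0.1
    baseline_wander_freq: float = 0.25

    def __post_init__(self) -> None:
        if self.rr_mean <= 0:
            raise ValueError(f"rr_mean must be positive, got {self.rr_mean}")
        if self.rr_sd < 0:
            raise ValueError(f"rr_sd must be nonnegative, got {self.rr_sd}")
        if not 0 <= self.ectopic_rate <= 1:
            raise ValueError(f"ectopic_rate must be in [0, 1], got {self.ectopic_rate}")


PRESETS: dict[str, RhythmSpec] = {
    "NSR": RhythmSpec("NSR", rr_mean=0.8, rr_sd=0.03, ectopic_rate=0.0),
    "ARR": RhythmSpec("ARR", rr_mean=0.8, rr_sd=0.18, ectopic_rate=0.10),
    "CHF": RhythmSpec("CHF", rr_mean=0.6, rr_sd=0.005, ectopic_rate=0.0, qrs_amplitude_scale=0.6),
}


def _beat_waves(spec: RhythmSpec, ectopic: bool) -> list[tuple[float, float, float]]:
    waves = []
    for name, (off, width, amp) in BEAT_WAVES.items():
        if name in ("Q", "R", "S"):
            amp *= spec.qrs_amplitude_scale
            if ectopic:
                width *= ECTOPIC_WIDTH_FACTOR
                amp *= ECTOPIC_AMP_FACTOR
        elif name == "P" and ectopic:
            continue
        waves.append((off, width, amp))
    return waves


def generate_record(
    spec: RhythmSpec,
    n_samples: int,
    sampling_rate: float = 128.0,
    seed: int = 0,
    record_id: str = "",
    include_noise: bool = True,
) -> ECGRecord:
    """Generate one synthetic single-channel ECG record.

    Beats are placed at cumulative RR intervals drawn from
    Normal(rr_mean, rr_sd) truncated below at 0.2 s; with probability
    ``ectopic_rate`` a beat uses the ectopic template.  White noise and
    baseline wander are added unless ``include_noise`` is False (the
    noiseless track has identical beat placement for the same seed, which
    peak-finding tests rely on).

    Raises if ``n_samples`` cannot hold at least one mean RR interval.
    """
    duration = n_samples / sampling_rate
    if duration < spec.rr_mean:
        raise ValueError(
            f"n_samples={n_samples} at {sampling_rate} Hz spans {duration:.3f} s, "
            f"shorter than one mean RR interval ({spec.rr_mean} s)"
        )
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / sampling_rate

    # beat placement first so the clean/noisy tracks share it at equal seed
    beat_times = []
    ectopics = []
    now = float(rng.uniform(0.0, spec.rr_mean))
    while now < duration + 0.5:  # overshoot so partial edge beats render
        beat_times.append(now)
        ectopics.append(bool(rng.random() < spec.ectopic_rate))
        now += max(float(rng.normal(spec.rr_mean, spec.rr_sd)), RR_FLOOR)

    x = np.zeros(n_samples)
    for bt, ect in zip(beat_times, ectopics):
        for off, width, amp in _beat_waves(spec, ect):
            x += amp * np.exp(-0.5 * ((t - bt - off) / width) ** 2)

    if include_noise:
        x = x + spec.baseline_wander_amp * np.sin(
            2.0 * np.pi * spec.baseline_wander_freq * t + rng.uniform(0, 2 * np.pi)
        )
        x = x + rng.normal(0.0, spec.noise_sd, n_samples)

    return ECGRecord(
        samples=x,
        sampling_rate=sampling_rate,
        record_id=record_id or f"{spec.class_label.lower()}-{seed}",
        label=spec.class_label,
    )


def generate_dataset(
    n_records_per_class: int,
    n_samples: int,
    sampling_rate: float = 128.0,
    seed: int = 0,
    presets: dict[str, RhythmSpec] | None = None,
) -> list[ECGRecord]:
    """Generate a balanced labeled dataset across the rhythm-class presets.

    Per-record seeds are derived reproducibly from the master seed, so two
    calls with equal arguments return identical datasets.
    """
    if n_records_per_class < 1:
        raise ValueError(f"n_records_per_class must be >= 1, got {n_records_per_class}")
    presets = presets or PRESETS
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(presets) * n_records_per_class)
    records = []
    i = 0
    for label in presets:
        spec = presets[label]
        for j in range(n_records_per_class):
            child_seed = int(children[i].generate_state(1)[0] % (2**31))
            records.append(
                generate_record(
                    spec,
                    n_samples,
                    sampling_rate,
                    seed=child_seed,
                    record_id=f"{label}{j:03d}",
                )
            )
            i += 1
    return records
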