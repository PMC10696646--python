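"""Synthetic annotated ECG records.

Beats are modelled as sums of Gaussian bumps (P/QRS/T surrogates) laid
down at stochastic RR intervals, with additive Gaussian noise and a
sinusoidal baseline-wander term.  This is deliberately *not* a
physiological ECG model: its purpose is to give every other module —
window extraction, image conversion, classifier training, the streaming
detector — fully reproducible inputs with controllable, well-separated
beat morphologies and exactly known R-peak positions.

Two presets are provided: ``"N"``, a narrow tall QRS with P and T
waves, and ``"V"``, a wide large ventricular-like complex without a P
wave.  Their rendered shapes correlate weakly (< 0.9), which guarantees
the two classes are separable by amplitude/width features alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .ecg_io import BeatAnnotation, CLASS_LABELS, EcgRecord
from .ecg_io import write_record as _write_wfdb

__all__ = [
    "BeatTemplate", "SynthesisConfig", "TEMPLATES",
    "render_beat", "generate_record", "write_record",
]


@dataclass(frozen=True)
class BeatTemplate:
    """One beat morphology: Gaussian components over a fixed duration.

    ``waves`` are ``(amplitude, center_s, width_s)`` triples; amplitude
    is in the record's (arbitrary, mV-like) units, center and width
    (Gaussian sigma) in seconds from beat onset.
    """

    label: str
    waves: tuple[tuple[float, float, float], ...]
    duration: float = 0.6

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("template duration must be positive")
        if not self.waves:
            raise ValueError("template needs at least one component wave")
        if self.label not in CLASS_LABELS:
            raise ValueError(f"label {self.label!r} outside the vocabulary")


#: Built-in morphologies.  "N": P wave, narrow tall QRS, T wave.
#: "V": wide high-amplitude complex, no P wave, discordant T.
TEMPLATES: dict[str, BeatTemplate] = {
    "N": BeatTemplate(
        label="N",
        waves=((0.12, 0.15, 0.02),    # P
               (-0.10, 0.275, 0.008), # Q
               (1.00, 0.30, 0.012),   # R
               (-0.18, 0.325, 0.009), # S
               (0.30, 0.47, 0.040)),  # T
    ),
    "V": BeatTemplate(
        label="V",
        waves=((1.15, 0.30, 0.055),   # broad ventricular complex
               (-0.45, 0.47, 0.050)), # discordant T
    ),
}


def render_beat(template: BeatTemplate, fs: float) -> tuple[np.ndarray, int]:
    """Sample a template at ``fs``; returns ``(samples, peak_index)``.

    ``peak_index`` is the argmax of the absolute rendered amplitude and
    is where the beat annotation is placed.
    """
    t = np.arange(int(round(template.duration * fs))) / fs
    y = np.zeros_like(t)
    for amp, center, width in template.waves:
        y += amp * np.exp(-0.5 * ((t - center) / width) ** 2)
    peak = int(np.argmax(np.abs(y))) if y.any() else int(len(y) // 2)
    return y, peak


@dataclass
class SynthesisConfig:
    """Knobs for one synthetic record.

    ``classes`` cycles deterministically unless ``class_probs`` is
    given, in which case each beat's label is drawn i.i.d.  Amplitude
    units are arbitrary; defaults put the QRS at 1.0 against noise of
    sd 0.03 and slow baseline wander of amplitude 0.1.
    """

    fs: float = 360.0
    duration: float = 30.0
    classes: tuple[str, ...] = ("N",)
    class_probs: tuple[float, ...] | None = None
    rr_mean: float = 0.8
    rr_sd: float = 0.05
    noise_sd: float = 0.03
    wander_amplitude: float = 0.1
    wander_frequency: float = 0.33
    seed: int = 0
    record_id: str = "synth"
    n_channels: int = 1
    templates: dict[str, BeatTemplate] = field(default_factory=lambda: dict(TEMPLATES))

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.class_probs is not None:
            if len(self.class_probs) != len(self.classes):
                raise ValueError("class_probs must match classes in length")
            if abs(sum(self.class_probs) - 1.0) > 1e-9:
                raise ValueError("class_probs must sum to 1")


def generate_record(config: SynthesisConfig) -> EcgRecord:
    """Build a fully annotated synthetic record from ``config``.

    Beats are placed at truncated-normal RR intervals (clipped below at
    0.25 s); one annotation is written per beat at the peak of its clean
    rendering, before noise is added.  Identical configs (including
    seed) produce byte-identical records.
    """
    rng = np.random.default_rng(config.seed)
    n_total = int(round(config.duration * config.fs))
    rendered = {c: render_beat(config.templates[c], config.fs)
                for c in config.classes}
    min_len = min(len(y) for y, _ in rendered.values())
    if n_total < min_len:
        raise ValueError(
            f"record of {config.duration} s is too short for a single beat"
        )
    signal = np.zeros(n_total)
    annotations: list[BeatAnnotation] = []
    cursor = int(round(0.1 * config.fs))
    beat_i = 0
    while True:
        if config.class_probs is not None:
            label = str(rng.choice(list(config.classes), p=list(config.class_probs)))
        else:
            label = config.classes[beat_i % len(config.classes)]
        y, peak = rendered[label]
        if cursor + len(y) > n_total:
            break
        signal[cursor : cursor + len(y)] += y
        annotations.append(BeatAnnotation(cursor + peak, label))
        rr = max(float(rng.normal(config.rr_mean, config.rr_sd)), 0.25)
        cursor += int(round(rr * config.fs))
        beat_i += 1
    t = np.arange(n_total) / config.fs
    signal = (signal
              + config.wander_amplitude
              * np.sin(2 * np.pi * config.wander_frequency * t)
              + rng.normal(0.0, config.noise_sd, n_total))
    channels = [signal]
    names = ["MLII"]
    for ch in range(1, config.n_channels):
        # crude secondary lead: attenuated copy with its own noise
        channels.append(0.5 * signal + rng.normal(0.0, config.noise_sd, n_total))
        names.append(f"V{ch}")
    return EcgRecord(
        record_id=config.record_id,
        signal=np.vstack(channels),
        fs=config.fs,
        channel_names=names,
        annotations=annotations,
        raw_symbols=[a.symbol for a in annotations],
    )


def write_record(
    record: EcgRecord,
    directory: str | Path,
    *,
    fmt: str = "16",
    gain: float = 200.0,
) -> Path:
    """Write a record as WFDB-dialect files readable by ``ecg_io.read_record``.

    Amplitudes are quantized at ``gain`` ADC units per physical unit, so
    the round-trip error is at most ``0.5 / gain``.
    """
    return _write_wfdb(record, directory, fmt=fmt, gain=gain)
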