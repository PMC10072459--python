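"""Synthetic labelled heartbeat generator.

Generates class-separable, R-centered beats as sums of Gaussian bumps
emulating gross P/QRS/T morphology, so the whole
segmentation→compression→classification pipeline can be exercised at desk
scale without downloading an ECG database.  The four default classes mirror
the morphology that separates the AAMI super-classes:

* ``N`` — narrow QRS, normal P and T waves;
* ``S`` — narrow QRS with a premature ectopic bump before the complex and an
  attenuated T (supraventricular-ectopy-like);
* ``V`` — wide, tall QRS with no P wave and a discordant (negative) T
  (ventricular-ectopy-like);
* ``F`` — intermediate fused morphology.

This is a statistical stand-in, not a physiological simulator: it reproduces
class-distinct fixed-length morphology with controllable jitter and noise, and
nothing about rhythm, heart-rate variability or inter-patient variation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import BeatDataset
from .preprocessing import normalize_beats

__all__ = ["GaussianBump", "SyntheticBeatSpec", "generate_beat", "generate_dataset", "template_waveform"]


@dataclass(frozen=True)
class GaussianBump:
    """One Gaussian component: center offset from the window center (samples),
    width (standard deviation, samples) and amplitude (arbitrary units)."""

    center: float
    width: float
    amplitude: float


def _default_templates() -> dict[str, tuple[GaussianBump, ...]]:
    return {
        "N": (
            GaussianBump(-50.0, 8.0, 0.15),   # P
            GaussianBump(0.0, 4.0, 1.00),     # narrow QRS
            GaussianBump(55.0, 18.0, 0.30),   # T
        ),
        "S": (
            GaussianBump(-32.0, 6.0, 0.28),   # premature ectopic P'
            GaussianBump(0.0, 4.0, 0.95),
            GaussianBump(50.0, 16.0, 0.12),   # attenuated T
        ),
        "V": (
            GaussianBump(0.0, 14.0, 1.20),    # wide tall QRS
            GaussianBump(60.0, 20.0, -0.35),  # discordant T
        ),
        "F": (
            GaussianBump(-50.0, 8.0, 0.08),
            GaussianBump(0.0, 9.0, 1.10),     # fused, intermediate width
            GaussianBump(55.0, 18.0, 0.20),
        ),
    }


@dataclass
class SyntheticBeatSpec:
    """Parameters of the synthetic beat population.

    ``jitter_sd`` shifts a whole beat's bump train relative to the window
    center (samples), emulating imperfect R centering; ``amplitude_sd`` is a
    relative per-bump amplitude scatter; ``noise_sd`` is additive white noise
    in template amplitude units.
    """

    beat_length: int = 260
    class_templates: dict[str, tuple[GaussianBump, ...]] = field(default_factory=_default_templates)
    jitter_sd: float = 2.0
    amplitude_sd: float = 0.05
    noise_sd: float = 0.03
    seed: int = 0

    @property
    def class_names(self) -> list[str]:
        return list(self.class_templates)

    @property
    def n_classes(self) -> int:
        return len(self.class_templates)

    def __post_init__(self) -> None:
        max_width = max(
            bump.width for bumps in self.class_templates.values() for bump in bumps
        )
        if self.beat_length < 2 * max_width:
            raise ValueError(
                f"beat_length {self.beat_length} shorter than twice the widest bump ({max_width})"
            )


def template_waveform(spec: SyntheticBeatSpec, class_name: str) -> np.ndarray:
    """The deterministic (noise-free, jitter-free) class template."""
    t = np.arange(spec.beat_length) - spec.beat_length / 2.0
    wave = np.zeros(spec.beat_length)
    for bump in spec.class_templates[class_name]:
        wave += bump.amplitude * np.exp(-0.5 * ((t - bump.center) / bump.width) ** 2)
    return wave


def generate_beat(
    spec: SyntheticBeatSpec, class_id: int | str, rng: np.random.Generator
) -> np.ndarray:
    """Draw one raw (unnormalized) beat of the given class.

    ``class_id`` may be a class name or an index into ``spec.class_names``.
    """
    if isinstance(class_id, (int, np.integer)):
        if not 0 <= class_id < spec.n_classes:
            raise IndexError(f"class_id {class_id} out of range [0, {spec.n_classes})")
        class_name = spec.class_names[class_id]
    else:
        class_name = str(class_id)
        if class_name not in spec.class_templates:
            raise IndexError(f"unknown class {class_name!r}")
    t = np.arange(spec.beat_length) - spec.beat_length / 2.0
    shift = rng.normal(0.0, spec.jitter_sd) if spec.jitter_sd > 0 else 0.0
    wave = np.zeros(spec.beat_length)
    for bump in spec.class_templates[class_name]:
        scale = 1.0 + (rng.normal(0.0, spec.amplitude_sd) if spec.amplitude_sd > 0 else 0.0)
        wave += (
            bump.amplitude
            * scale
            * np.exp(-0.5 * ((t - bump.center - shift) / bump.width) ** 2)
        )
    if spec.noise_sd > 0:
        wave += rng.normal(0.0, spec.noise_sd, size=spec.beat_length)
    return wave


def generate_dataset(
    spec: SyntheticBeatSpec, n_per_class: int, normalize: bool = True
) -> BeatDataset:
    """Generate a balanced labelled dataset of ``n_per_class`` beats per class.

    Beats are min-max normalized to [0, 1] (the same normalization the
    preprocessing stage applies to recorded beats) unless ``normalize`` is
    False.  The draw is a pure function of ``spec`` (including its seed).
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    rng = np.random.default_rng(spec.seed)
    beats = np.empty((spec.n_classes * n_per_class, spec.beat_length))
    labels = np.empty(spec.n_classes * n_per_class, dtype=object)
    row = 0
    for class_name in spec.class_names:
        for _ in range(n_per_class):
            beats[row] = generate_beat(spec, class_name, rng)
            labels[row] = class_name
            row += 1
    if normalize:
        beats = normalize_beats(beats)
    return BeatDataset(beats, labels.astype(str), spec.beat_length, spec.class_names)
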