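"""Synthetic five-class EEG generator in the Bonn record shape.

Each class recipe encodes only the qualitative electrophysiology that
separates the Bonn classes, so that pipeline behaviour — not biology — is
what the test suite asserts:

    A  pink-noise background + moderate posterior alpha (8–13 Hz), eyes open
    B  same background with stronger alpha and added low-frequency (theta)
       power, emulating eye closure
    C  A-like background + sparse biphasic interictal spikes (~0.7 events/s)
    D  A-like background + denser, larger spikes (~1.0 events/s,
       epileptogenic zone)
    E  high-amplitude rhythmic 3–7 Hz spike-wave discharge dominating the
       record (ictal)

Defaults mirror the Bonn corpus geometry: 100 records per class, 4,096
samples per record, 173.61 Hz, amplitudes quantised to integer µV to stay
in the file dialect (``integer_quantize=False`` keeps floats for numeric
tests).  Every record is deterministic in (seed, class, record index).

``hard_mode`` shrinks the ictal rhythm to the in-band noise floor and
matches the ictal background to the eyes-open background; it exists to
demonstrate that classification accuracy degrades monotonically with
effect size.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bonn import CLASS_LABELS, DEFAULT_FS, EEGRecord, ClassSet


@dataclass
class ClassRecipe:
    """Spectral recipe for one class (amplitudes in µV)."""

    noise_scale: float = 30.0
    osc_band: tuple[float, float] = (8.0, 13.0)  # Hz
    osc_amp: float = 0.0
    low_band: tuple[float, float] = (4.0, 7.0)  # Hz
    low_amp: float = 0.0
    spike_rate: float = 0.0  # events/s
    spike_amp: float = 0.0
    ictal_band: tuple[float, float] = (3.0, 7.0)  # Hz
    ictal_amp: float = 0.0


def _default_recipes() -> dict[str, ClassRecipe]:
    return {
        "A": ClassRecipe(noise_scale=30.0, osc_amp=40.0),
        "B": ClassRecipe(noise_scale=30.0, osc_amp=60.0, low_amp=30.0),
        "C": ClassRecipe(noise_scale=30.0, osc_amp=20.0, spike_rate=0.7, spike_amp=150.0),
        "D": ClassRecipe(noise_scale=30.0, osc_amp=20.0, spike_rate=1.0, spike_amp=180.0),
        "E": ClassRecipe(noise_scale=40.0, ictal_amp=300.0),
    }


@dataclass
class SynthConfig:
    fs: float = DEFAULT_FS
    record_len: int = 4096
    n_records_per_class: int = 100
    seed: int = 0
    integer_quantize: bool = True
    recipes: dict[str, ClassRecipe] = field(default_factory=_default_recipes)

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.record_len < 1 or self.n_records_per_class < 1:
            raise ValueError("fs, record_len and n_records_per_class must be positive")
        for label, r in self.recipes.items():
            for band in (r.osc_band, r.low_band, r.ictal_band):
                if not (0 < band[0] < band[1] < self.fs / 2):
                    raise ValueError(f"class {label}: band {band} outside (0, fs/2)")
            for amp in (r.noise_scale, r.osc_amp, r.low_amp, r.spike_amp, r.ictal_amp):
                if amp < 0:
                    raise ValueError(f"class {label}: negative amplitude")

    def to_dict(self) -> dict:
        return asdict(self)


def hard_mode(seed: int = 0, ictal_scale: float = 0.05, **overrides) -> SynthConfig:
    """Reduced-effect-size conditions for the monotonicity check.

    The ictal class keeps only a faint spike-wave rhythm (default 5% of the
    standard amplitude, which puts the rhythm's line power at about the
    pink-noise power already present in its 3–7 Hz band) and otherwise
    shares the eyes-open background (noise scale and alpha oscillation), so
    the classes genuinely overlap and classification accuracy must drop
    below the default conditions.
    """
    cfg = SynthConfig(seed=seed, **overrides)
    a = cfg.recipes["A"]
    e = cfg.recipes["E"]
    e.ictal_amp *= ictal_scale
    e.noise_scale = a.noise_scale
    e.osc_band = a.osc_band
    e.osc_amp = a.osc_amp
    return cfg


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance 1/f noise, band-limited to 0.5 Hz .. Nyquist."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spectrum = (
        rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)
    )
    shaping = np.zeros_like(freqs)
    nz = freqs >= 0.5
    shaping[nz] = freqs[nz] ** -0.5
    x = np.fft.irfft(spectrum * shaping, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _oscillation(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """A slowly amplitude-modulated sinusoid at a random in-band frequency."""
    f = rng.uniform(*band)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    envelope = 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.05, 0.2) * t + rng.uniform(0, 2 * np.pi))
    return envelope * np.sin(2 * np.pi * f * t + phase)


def _spike_kernel(fs: float) -> np.ndarray:
    """Biphasic transient: derivative-of-Gaussian, ~60 ms wide."""
    width = int(round(0.06 * fs))
    t = np.linspace(-3, 3, 2 * width + 1)
    k = -t * np.exp(-(t**2) / 2)
    return k / np.max(np.abs(k))


def _spike_train(
    rng: np.random.Generator, n: int, fs: float, rate: float, amp: float
) -> np.ndarray:
    out = np.zeros(n)
    n_events = rng.poisson(rate * n / fs)
    kernel = _spike_kernel(fs)
    half = kernel.size // 2
    for _ in range(n_events):
        pos = rng.integers(half, n - half)
        polarity = 1.0 if rng.random() < 0.8 else -1.0
        scale = amp * rng.uniform(0.7, 1.3) * polarity
        out[pos - half : pos + half + 1] += scale * kernel
    return out


def _spike_wave(
    rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]
) -> np.ndarray:
    """Rhythmic non-sinusoidal spike-wave at a random in-band frequency."""
    f = rng.uniform(*band)
    phase = rng.uniform(0, 2 * np.pi)
    t = np.arange(n) / fs
    base = np.sin(2 * np.pi * f * t + phase)
    # sharpen the positive phase into a spike, keep a slow wave beneath
    sharp = np.sign(base) * np.abs(base) ** 3
    wave = 0.6 * base + 0.4 * sharp
    envelope = 1.0 + 0.2 * np.sin(2 * np.pi * rng.uniform(0.05, 0.15) * t)
    return envelope * wave


def _record_rng(config: SynthConfig, class_label: str, index: int) -> np.random.Generator:
    class_idx = CLASS_LABELS.index(class_label)
    ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(class_idx, index))
    return np.random.default_rng(ss)


def generate_record(
    class_label: str, config: SynthConfig | None = None, record_index: int = 0
) -> EEGRecord:
    """One synthetic record, deterministic in (seed, class, index)."""
    if config is None:
        config = SynthConfig()
    if class_label not in CLASS_LABELS:
        raise ValueError(f"unknown class {class_label!r}; valid: {CLASS_LABELS}")
    recipe = config.recipes[class_label]
    rng = _record_rng(config, class_label, record_index)
    n, fs = config.record_len, config.fs
    x = recipe.noise_scale * _pink_noise(rng, n, fs)
    if recipe.osc_amp > 0:
        x += recipe.osc_amp * _oscillation(rng, n, fs, recipe.osc_band)
    if recipe.low_amp > 0:
        x += recipe.low_amp * _oscillation(rng, n, fs, recipe.low_band)
    if recipe.spike_rate > 0 and recipe.spike_amp > 0:
        x += _spike_train(rng, n, fs, recipe.spike_rate, recipe.spike_amp)
    if recipe.ictal_amp > 0:
        x += recipe.ictal_amp * _spike_wave(rng, n, fs, recipe.ictal_band)
    if config.integer_quantize:
        x = np.rint(x)
    return EEGRecord(
        samples=x,
        fs=fs,
        class_label=class_label,
        record_id=f"{class_label}{record_index:03d}",
    )


def generate_classes(config: SynthConfig | None = None) -> dict[str, ClassSet]:
    """All five synthetic classes, in memory."""
    if config is None:
        config = SynthConfig()
    return {
        label: ClassSet(
            label=label,
            records=[
                generate_record(label, config, i)
                for i in range(config.n_records_per_class)
            ],
        )
        for label in CLASS_LABELS
    }


def generate_dataset(
    config: SynthConfig | None = None,
    root: str | Path = "synthetic_bonn",
    force: bool = False,
) -> Path:
    """Write a Bonn-dialect directory tree plus a JSON manifest.

    Layout: ``<root>/<class>/<class><index>.txt``.  Refuses to write into
    an existing non-empty directory unless ``force`` is set.
    """
    from .bonn import write_record  # local import to keep module load light

    if config is None:
        config = SynthConfig()
    root = Path(root)
    if root.exists() and any(root.iterdir()) and not force:
        raise FileExistsError(
            f"{root} exists and is not empty; pass force=True to overwrite"
        )
    for label in CLASS_LABELS:
        (root / label).mkdir(parents=True, exist_ok=True)
        for i in range(config.n_records_per_class):
            rec = generate_record(label, config, i)
            write_record(
                rec,
                root / label / f"{rec.record_id}.txt",
                precise=not config.integer_quantize,
            )
    manifest = {"generator": "ictalnet.synth", "config": config.to_dict()}
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return root
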