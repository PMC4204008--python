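"""Stage-labelled synthetic single-channel EEG.

Each sleep stage gets a target magnitude spectrum on the 0.5 Hz bin grid
(0.5-50 Hz): a 1/f background plus Gaussian bumps, shaped so the
features that drive the detector separate REM from the other stages by
construction:

* REM — band power concentrated at the 8-16 Hz band edges: a bump just
  above 8 Hz, suppressed 9-15 Hz activity, and a rise near 15 Hz. This
  yields a low SEF50, a high SEF95 and hence the largest SEFd, with the
  lowest in-band absolute power.
* Wake — a strong alpha peak near 10 Hz (high band power, narrow SEF
  spread).
* N1 — theta activity with residual low-alpha; moderate band power.
* N2 — a 12-14 Hz spindle-band elevation.
* N3 — delta dominance (0.5-4 Hz) with little 8-16 Hz structure.

Signals are synthesised as sums of bin-aligned sinusoids with uniform
random phases and per-epoch amplitude jitter, plus a small white noise
floor. Bin alignment with the 512-point analysis FFT makes the
template-to-spectrum mapping near-exact, so tight oracles are possible.
The amplitude values are artifact parameters chosen to satisfy the
ordering constraints above, not claims about real EEG microvolt levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import BandConfig, EpochFeatures
from .io import EEGRecord, Hypnogram
from .preprocessing import EPOCH_SECONDS, TARGET_FS

__all__ = ["StageTemplate", "default_templates", "synthesize_epoch",
           "synthesize_recording", "analytic_sef", "analytic_sefd",
           "labelled_feature_sample"]

#: Bin grid shared by all templates: 0.5-50 Hz in 0.5 Hz steps.
TEMPLATE_FREQS = np.arange(0.5, 50.0 + 0.25, 0.5)


@dataclass
class StageTemplate:
    """Target magnitude per 0.5 Hz bin for one sleep stage."""

    stage: str
    bin_amplitudes: np.ndarray
    background_exponent: float
    jitter: float = 0.1

    def __post_init__(self) -> None:
        self.bin_amplitudes = np.asarray(self.bin_amplitudes,
                                         dtype=np.float64)
        if self.bin_amplitudes.shape != TEMPLATE_FREQS.shape:
            raise ValueError("bin_amplitudes must cover the 0.5-50 Hz grid")
        if np.any(self.bin_amplitudes < 0):
            raise ValueError("amplitudes must be non-negative")
        if not 0 <= self.jitter < 1:
            raise ValueError("jitter must be a proportion in [0, 1)")

    def band_power(self, band: BandConfig | None = None) -> float:
        """Total template power (Σ amp²) inside the analysis band."""
        if band is None:
            band = BandConfig()
        m = (TEMPLATE_FREQS >= band.f1) & (TEMPLATE_FREQS <= band.f2)
        return float((self.bin_amplitudes[m] ** 2).sum())


def _shape(bg_amp, exponent, bumps, band_scale=None):
    """Build bin amplitudes: 1/f background + Gaussian bumps (+ band dip)."""
    f = TEMPLATE_FREQS
    amp = bg_amp * f ** (-exponent)
    if band_scale is not None:
        lo, hi, scale = band_scale
        amp = np.where((f >= lo) & (f <= hi), amp * scale, amp)
    for center, sd, height in bumps:
        amp = amp + height * np.exp(-0.5 * ((f - center) / sd) ** 2)
    return amp


def default_templates() -> dict[str, StageTemplate]:
    """The five stage templates used throughout testing and examples."""
    specs = {
        "W": dict(bg=25.0, exp=1.0, bumps=[(10.0, 1.0, 12.0)]),
        "N1": dict(bg=22.0, exp=1.1,
                   bumps=[(5.5, 1.2, 9.0), (9.5, 0.9, 9.0)]),
        "N2": dict(bg=22.0, exp=1.1,
                   bumps=[(13.0, 0.7, 14.0), (10.0, 0.8, 5.0)]),
        "N3": dict(bg=40.0, exp=1.4,
                   bumps=[(1.5, 1.0, 45.0), (9.0, 0.6, 12.0)]),
        "REM": dict(bg=14.0, exp=1.0,
                    bumps=[(8.1, 0.3, 9.0), (15.5, 0.35, 6.5)],
                    dip=(9.0, 15.0, 0.2)),
    }
    out = {}
    for stage, p in specs.items():
        amp = _shape(p["bg"], p["exp"], p["bumps"], p.get("dip"))
        out[stage] = StageTemplate(stage=stage, bin_amplitudes=amp,
                                   background_exponent=p["exp"])
    return out


def analytic_sef(template: StageTemplate, fraction: float,
                 band: BandConfig | None = None) -> float:
    """SEF of the template's own bin power (no signal synthesis)."""
    if band is None:
        band = BandConfig()
    m = (TEMPLATE_FREQS >= band.f1) & (TEMPLATE_FREQS <= band.f2)
    power = template.bin_amplitudes[m] ** 2
    cum = np.cumsum(power)
    idx = int(np.searchsorted(cum, fraction * cum[-1] * (1 - 1e-12)))
    return float(TEMPLATE_FREQS[m][idx])


def analytic_sefd(template: StageTemplate,
                  band: BandConfig | None = None) -> float:
    """SEF95 − SEF50 of the template itself, Hz."""
    return (analytic_sef(template, 0.95, band)
            - analytic_sef(template, 0.50, band))


def synthesize_epoch(template: StageTemplate, seed) -> np.ndarray:
    """One 30-s epoch (7680 samples at 256 Hz) drawn from a template.

    Sum of bin-aligned sinusoids with jittered amplitudes and uniform
    random phases, plus a small white-noise floor. Deterministic for a
    fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = EPOCH_SECONDS * TARGET_FS
    t = np.arange(n) / TARGET_FS
    amps = template.bin_amplitudes * (
        1.0 + template.jitter * rng.standard_normal(len(TEMPLATE_FREQS)))
    amps = np.clip(amps, 0.0, None)
    phases = rng.uniform(0.0, 2.0 * np.pi, len(TEMPLATE_FREQS))
    x = np.sum(amps[:, None]
               * np.cos(2.0 * np.pi * TEMPLATE_FREQS[:, None] * t[None, :]
                        + phases[:, None]), axis=0)
    x += 0.05 * rng.standard_normal(n)
    return x


def synthesize_recording(stage_sequence, templates=None,
                         seed=0) -> tuple[EEGRecord, Hypnogram]:
    """A full labelled recording: concatenated stage-templated epochs.

    ``stage_sequence`` is a Hypnogram or an iterable of stage labels.
    Per-epoch randomness is spawned from the single seed, so recordings
    are reproducible and epochs are statistically independent.
    """
    if templates is None:
        templates = default_templates()
    if isinstance(stage_sequence, Hypnogram):
        stages = stage_sequence.stages
    else:
        stages = tuple(stage_sequence)
    if not stages:
        raise ValueError("stage sequence must be non-empty")
    missing = sorted({s for s in stages} - set(templates))
    if missing:
        raise ValueError(f"no template for stages: {missing}")
    child_seeds = np.random.SeedSequence(seed).spawn(len(stages))
    samples = np.concatenate([
        synthesize_epoch(templates[s], cs) for s, cs in
        zip(stages, child_seeds)])
    record = EEGRecord(samples=samples, fs=float(TARGET_FS),
                       channel="synthetic")
    return record, Hypnogram(stages, float(EPOCH_SECONDS))


#: Per-stage bout-length ranges in 30-s epochs, reflecting typical sleep
#: architecture: REM periods and N2/N3 stretches last many minutes while
#: N1 is transitional and brief.
BOUT_EPOCHS = {"W": (4, 20), "N1": (2, 8), "N2": (10, 40),
               "N3": (10, 30), "REM": (16, 48)}


def sample_hypnogram(n_epochs: int, seed=0, base_probs=None,
                     ensure_stages=None) -> Hypnogram:
    """Draw a stage sequence with sleep-architecture-like bouts.

    The sequence is built bout by bout: a stage is drawn from
    ``base_probs`` (defaults roughly matching overnight stage
    proportions: W 15%, N1 10%, N2 35%, N3 20%, REM 20%, never repeating
    the previous stage) and held for a uniformly drawn number of epochs
    from :data:`BOUT_EPOCHS`. Multi-minute bouts keep the 9-point SEFd
    smoother operating within stage runs, as it does on real
    hypnograms. ``ensure_stages`` lists stages that must occur; the
    sequence is redrawn deterministically until they all do.
    """
    stages_order = ("W", "N1", "N2", "N3", "REM")
    if base_probs is None:
        base_probs = (0.15, 0.10, 0.35, 0.20, 0.20)
    base = np.asarray(base_probs, dtype=float)
    required = set(ensure_stages or ())
    for child in np.random.SeedSequence(seed).spawn(64):
        rng = np.random.default_rng(child)
        out: list[str] = []
        prev = None
        while len(out) < n_epochs:
            p = base.copy()
            if prev is not None:
                p[stages_order.index(prev)] = 0.0
                p /= p.sum()
            stage = stages_order[rng.choice(5, p=p)]
            lo, hi = BOUT_EPOCHS[stage]
            out.extend([stage] * int(rng.integers(lo, hi + 1)))
            prev = stage
        out = out[:n_epochs]
        if required <= set(out):
            return Hypnogram(tuple(out), float(EPOCH_SECONDS))
    raise ValueError(f"could not draw a sequence containing {required}")


def labelled_feature_sample(n_per_class: int = 200, boundary: float = 4.5,
                            separation: float = 1.2, sd: float = 0.45,
                            seed: int = 0):
    """Feature-level sample with a designed SEFd class boundary.

    REM and non-REM SEFd values are Gaussians of equal spread placed
    symmetrically about ``boundary`` (±separation/2), so the optimal
    separating threshold is the boundary itself. AP/RP follow the REM
    phenomenology (lower AP in REM, RP in a characteristic window).
    Returns (features, labels) for calibration studies.
    """
    rng = np.random.default_rng(seed)
    half = separation / 2.0
    sefd = np.concatenate([
        rng.normal(boundary - half, sd, n_per_class),
        rng.normal(boundary + half, sd, n_per_class)])
    labels = np.concatenate([np.zeros(n_per_class, dtype=bool),
                             np.ones(n_per_class, dtype=bool)])
    ap = np.where(labels, rng.normal(12.0, 1.5, 2 * n_per_class),
                  rng.normal(17.0, 2.0, 2 * n_per_class))
    rp = np.where(labels, rng.normal(-8.0, 1.0, 2 * n_per_class),
                  rng.normal(-12.0, 2.5, 2 * n_per_class))
    features = [EpochFeatures(sefd=float(d), ap=float(a), rp=float(r))
                for d, a, r in zip(sefd, ap, rp)]
    return features, labels
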