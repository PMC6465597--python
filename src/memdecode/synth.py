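"""Synthetic multi-subject epoch generator with a controlled representational
geometry.

Each stimulus image *i* contributes two prototype patterns: an early identity
pattern ``u_i`` shared in structure by both conditions (spherical normal,
scale ``sigma_id``), switched on at ``t_early``, and a later pattern
``v_i = c + r_i`` active only inside the effect window ``[t_on, t_off]``.
The residuals ``r_i`` are spherical normal with a *per-condition* scale
(``sigma_high`` or ``sigma_low``) around a centroid ``c`` shared by both
conditions, so high-memorability exemplars are more dispersed than
low-memorability ones without the two conditions being linearly separable in
expectation.  Trials add temporally smooth (AR(1)) Gaussian noise and a
per-subject multiplicative gain jitter.

The noise default is expressed at a 64-channel reference and rescaled by
``sqrt(n_channels / 64)`` so that the pattern-level signal-to-noise ratio —
which grows as the square root of the channel count for fixed per-channel
scales — is invariant to desk-scale reductions of the channel count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from .containers import EpochSet, ValidationError

#: per-channel noise SD at the 64-channel reference; calibrated so that
#: pairwise decoding sits in the realistic mid-range (identity epoch ~55%,
#: within-high window ~70%) rather than at ceiling, where accuracy
#: saturation would distort the representational geometry
#: (see docs/methods.md).
SIGMA_NOISE_REF = 12.0
_REFERENCE_CHANNELS = 64


@dataclass
class SynthConfig:
    """Free parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 15 subjects, 15 high- plus 15
    low-memorability images, 30 trials per image, epochs from -100 to 500 ms,
    early identity onset at 70 ms and a dispersion effect confined to
    149-228 ms.  Channel count and sampling rate default to desk scale
    (64 channels, 250 Hz); 306 channels / 1000 Hz reproduce the full-size
    geometry.
    """

    n_subjects: int = 15
    n_high: int = 15
    n_low: int = 15
    n_trials_per_image: int = 30
    n_channels: int = 64
    sampling_rate: float = 250.0
    tmin: float = -100.0
    tmax: float = 500.0
    t_early: float = 70.0
    t_on: float = 149.0
    t_off: float = 228.0
    sigma_high: float = 1.0
    sigma_low: float = 0.3
    sigma_id: float = 0.6
    sigma_noise: float | None = None      # None -> SIGMA_NOISE_REF * sqrt(S/64)
    envelope: str = "cosine"              # "cosine" (5 ms raised-cosine ramps) or "boxcar"
    ramp_ms: float = 5.0
    ar_coef: float = 0.9                  # AR(1) coefficient at 1 kHz equivalent
    gain_jitter: float = 0.1
    frontal_fraction: float = 0.125
    seed: int = 0

    @property
    def n_images(self) -> int:
        return self.n_high + self.n_low

    @property
    def times(self) -> np.ndarray:
        step = 1000.0 / self.sampling_rate
        n = int(round((self.tmax - self.tmin) / step)) + 1
        return self.tmin + step * np.arange(n)

    def resolved_sigma_noise(self) -> float:
        if self.sigma_noise is not None:
            return float(self.sigma_noise)
        return SIGMA_NOISE_REF * np.sqrt(self.n_channels / _REFERENCE_CHANNELS)

    def validate(self) -> "SynthConfig":
        if self.n_subjects < 1 or self.n_high < 1 or self.n_low < 1:
            raise ValidationError("n_subjects, n_high, n_low must be >= 1")
        if self.n_trials_per_image < 1 or self.n_channels < 1:
            raise ValidationError("n_trials_per_image and n_channels must be >= 1")
        if not (self.tmin < self.t_on < self.t_off <= self.tmax):
            raise ValidationError("effect window [t_on, t_off] must lie inside the epoch")
        if not (self.tmin <= self.t_early < self.tmax):
            raise ValidationError("t_early must lie inside the epoch")
        for name in ("sigma_high", "sigma_low", "sigma_id"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.sigma_high < self.sigma_low:
            raise ValidationError("sigma_high must be >= sigma_low")
        if self.resolved_sigma_noise() < 0:
            raise ValidationError("sigma_noise must be >= 0")
        if self.envelope not in ("cosine", "boxcar"):
            raise ValidationError("envelope must be 'cosine' or 'boxcar'")
        if not 0 <= self.ar_coef < 1:
            raise ValidationError("ar_coef must be in [0, 1)")
        return self

    def replace(self, **kw) -> "SynthConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def desk_scale(cls, **kw) -> "SynthConfig":
        """A reduced configuration for fast end-to-end runs.

        Fewer subjects/images/channels and a 100 Hz grid; the noise default's
        sqrt(S/64) scaling keeps the pattern-level SNR equal to the full-size
        configuration's.
        """
        base = dict(n_subjects=10, n_high=10, n_low=10, n_trials_per_image=20,
                    n_channels=24, sampling_rate=100.0)
        base.update(kw)
        return cls(**base)


@dataclass
class GroundTruth:
    """Prototype patterns exactly as drawn, for recovery tests."""

    u: np.ndarray             # (K, S) early identity prototypes
    v: np.ndarray             # (K, S) effect-window prototypes (= centroid + r)
    centroid: np.ndarray      # (S,)
    image_ids: np.ndarray     # (K,)
    condition_of: dict[int, str]
    t_on: float
    t_off: float
    sigma_high: float
    sigma_low: float
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "u": self.u.tolist(), "v": self.v.tolist(),
            "centroid": self.centroid.tolist(),
            "image_ids": self.image_ids.tolist(),
            "condition_of": {str(k): v for k, v in self.condition_of.items()},
            "t_on": self.t_on, "t_off": self.t_off,
            "sigma_high": self.sigma_high, "sigma_low": self.sigma_low,
            "seed": self.seed,
        }


def draw_prototypes(cfg: SynthConfig, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw per-image prototype patterns.

    Early prototypes are condition-independent (spherical normal, scale
    ``sigma_id``).  Window prototypes share one centroid with per-condition
    dispersion residuals drawn *on a sphere* of radius
    ``sigma_cond * sqrt(n_channels)`` (uniform random direction), so the
    expected squared within-condition pair distance is
    ``2 * n_channels * sigma_cond**2`` — the same second moment a spherical
    normal would give — while between-condition distances concentrate
    strictly between the two within-condition distributions.  The
    fixed-radius construction keeps the categorical (linearly separable)
    hypothesis RDM rank-uncorrelated with the true geometry; with Gaussian
    radii the broad within-high distance distribution overlaps the between
    distribution asymmetrically and induces a small spurious positive
    categorical correlation.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    K, S = cfg.n_images, cfg.n_channels
    image_ids = np.arange(1, K + 1)
    condition_of = {int(i): ("high" if k < cfg.n_high else "low")
                    for k, i in enumerate(image_ids)}
    u = cfg.sigma_id * rng.standard_normal((K, S))
    centroid = cfg.sigma_id * rng.standard_normal(S)
    scales = np.asarray([cfg.sigma_high if condition_of[int(i)] == "high" else cfg.sigma_low
                         for i in image_ids])
    directions = rng.standard_normal((K, S))
    directions /= np.maximum(np.linalg.norm(directions, axis=1, keepdims=True), 1e-300)
    v = centroid[None, :] + (scales * np.sqrt(S))[:, None] * directions
    return GroundTruth(u=u, v=v, centroid=centroid, image_ids=image_ids,
                       condition_of=condition_of, t_on=cfg.t_on, t_off=cfg.t_off,
                       sigma_high=cfg.sigma_high, sigma_low=cfg.sigma_low,
                       seed=cfg.seed)


def _ramp_up(t: np.ndarray, t0: float, ramp: float) -> np.ndarray:
    """Raised-cosine step from 0 (t < t0) to 1 (t > t0 + ramp)."""
    if ramp <= 0:
        return (t >= t0).astype(float)
    x = np.clip((t - t0) / ramp, 0.0, 1.0)
    return 0.5 * (1.0 - np.cos(np.pi * x))


def envelopes(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    """Temporal envelopes (g_early, g_window) on the epoch's time grid.

    ``g_early`` rises at ``t_early`` and stays on; ``g_window`` is supported
    only on ``[t_on, t_off]`` with raised-cosine edges (or a boxcar).
    """
    t = cfg.times
    ramp = cfg.ramp_ms if cfg.envelope == "cosine" else 0.0
    ramp_w = min(ramp, (cfg.t_off - cfg.t_on) / 2.0)
    g_early = _ramp_up(t, cfg.t_early, ramp)
    g_window = _ramp_up(t, cfg.t_on, ramp_w) * (1.0 - _ramp_up(t, cfg.t_off - ramp_w, ramp_w))
    g_window[(t < cfg.t_on) | (t > cfg.t_off)] = 0.0
    return g_early, g_window


def ar1_noise(rng: np.random.Generator, shape: tuple, phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) Gaussian noise along the last axis, marginal SD sigma."""
    if sigma == 0:
        return np.zeros(shape)
    if phi == 0:
        return sigma * rng.standard_normal(shape)
    n_burn = min(500, int(np.ceil(np.log(1e-8) / np.log(phi))))
    ext = shape[:-1] + (shape[-1] + n_burn,)
    w = rng.standard_normal(ext)
    y = lfilter([np.sqrt(1.0 - phi ** 2)], [1.0, -phi], w, axis=-1)
    return sigma * y[..., n_burn:]


def _channel_layout(cfg: SynthConfig) -> tuple[np.ndarray, np.ndarray]:
    S = cfg.n_channels
    n_front = max(1, int(round(cfg.frontal_fraction * S)))
    names = np.asarray([f"MEG{k:03d}" for k in range(1, S + 1)], dtype=object)
    groups = np.asarray(["frontal"] * n_front + ["sensor"] * (S - n_front), dtype=object)
    return names, groups


def simulate_subject(cfg: SynthConfig, truth: GroundTruth,
                     subject_seed, subject_id: str = "") -> EpochSet:
    """Simulate one subject's epochs from the shared cohort prototypes.

    Each trial of image *i* is
    ``gain * (g_early(t) u_i + g_window(t) v_i) + noise(t)`` with a
    per-subject gain drawn once, so subjects are exchangeable but not
    identical.
    """
    cfg.validate()
    rng = np.random.default_rng(subject_seed)
    t = cfg.times
    g_early, g_window = envelopes(cfg)
    phi = cfg.ar_coef ** (1000.0 / cfg.sampling_rate)
    gain = max(0.2, 1.0 + cfg.gain_jitter * rng.standard_normal())

    K, S, T = cfg.n_images, cfg.n_channels, t.size
    n_tr = cfg.n_trials_per_image
    # (K, S, T) per-image signal
    signal = gain * (truth.u[:, :, None] * g_early[None, None, :]
                     + truth.v[:, :, None] * g_window[None, None, :])
    data = np.repeat(signal, n_tr, axis=0)
    data += ar1_noise(rng, (K * n_tr, S, T), phi, cfg.resolved_sigma_noise())

    image_id = np.repeat(truth.image_ids, n_tr)
    condition = np.asarray([truth.condition_of[int(i)] for i in image_id], dtype=object)
    names, groups = _channel_layout(cfg)
    return EpochSet(
        data=data, times=t, image_id=image_id, condition=condition,
        channel_names=names, channel_group=groups,
        sampling_rate=cfg.sampling_rate, subject_id=subject_id,
    ).validate()


def cohort_seeds(cfg: SynthConfig) -> tuple[np.random.SeedSequence, list[np.random.SeedSequence]]:
    """Deterministic (prototype_seed, per-subject seeds) from cfg.seed."""
    root = np.random.SeedSequence(cfg.seed)
    children = root.spawn(cfg.n_subjects + 1)
    return children[0], children[1:]


def simulate_cohort(cfg: SynthConfig) -> tuple[list[EpochSet], GroundTruth]:
    """Simulate all subjects; identical cfg (incl. seed) gives identical output."""
    cfg.validate()
    proto_ss, subject_ss = cohort_seeds(cfg)
    truth = draw_prototypes(cfg, np.random.default_rng(proto_ss))
    subjects = [
        simulate_subject(cfg, truth, ss, subject_id=f"sub-{k + 1:02d}")
        for k, ss in enumerate(subject_ss)
    ]
    return subjects, truth


def inject_blinks(epochs: EpochSet, rng: np.random.Generator,
                  fraction: float = 0.1, amplitude: float = 50.0,
                  width_ms: float = 60.0) -> tuple[EpochSet, np.ndarray, np.ndarray]:
    """Add a spatially fixed blink-like transient to a random subset of trials.

    The spatial pattern loads mostly on frontal channels; the temporal shape
    is a Gaussian bump at a random latency per affected trial.  Returns the
    contaminated epochs, the affected trial indices, and the unit spatial
    pattern (for residual checks in tests).
    """
    front = epochs.channel_indices("frontal")
    pattern = np.zeros(epochs.n_channels)
    pattern[front] = 1.0
    other = np.setdiff1d(np.arange(epochs.n_channels), front)
    pattern[other] = 0.1 * rng.standard_normal(other.size)
    pattern /= np.linalg.norm(pattern)

    n_bad = max(1, int(round(fraction * epochs.n_trials)))
    bad = rng.choice(epochs.n_trials, size=n_bad, replace=False)
    data = epochs.data.copy()
    t = epochs.times
    for tr in bad:
        center = rng.uniform(t[0] + width_ms, t[-1] - width_ms)
        bump = amplitude * np.exp(-0.5 * ((t - center) / (width_ms / 4.0)) ** 2)
        data[tr] += pattern[:, None] * bump[None, :]
    return epochs.copy(data=data), np.sort(bad), pattern
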