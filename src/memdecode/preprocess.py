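"""Epoch-domain preprocessing: baseline removal, zero-phase low-pass
filtering, amplitude-based trial rejection, and PCA-based blink projection.

The canonical chain order is baseline -> lowpass -> reject -> blinks (see
:func:`preprocess_chain`); each step is also usable standalone.  All steps
preserve trial labels of surviving trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, find_peaks, sosfiltfilt

from .containers import EpochSet, ValidationError


@dataclass
class PreprocParams:
    baseline: tuple[float, float] = (-100.0, 0.0)
    lowpass_hz: float = 20.0
    amp_threshold: float | dict = 6000.0      # scalar, or {channel_group: value}
    blink_z: float = 4.0
    blink_halfwidth_ms: float = 200.0
    blink_var_fraction: float = 0.9
    blink_max_components: int = 2


def baseline_correct(epochs: EpochSet, window: tuple[float, float] = (-100.0, 0.0)) -> EpochSet:
    """Subtract the per-trial, per-channel mean over the baseline window."""
    epochs.validate()
    lo, hi = window
    mask = (epochs.times >= lo) & (epochs.times <= hi)
    if not mask.any():
        raise ValidationError(f"baseline window {window} contains no samples")
    mean = epochs.data[:, :, mask].mean(axis=2, keepdims=True)
    return epochs.copy(data=epochs.data - mean)


def lowpass(epochs: EpochSet, cutoff: float = 20.0, order: int = 4) -> EpochSet:
    """Zero-phase low-pass (Butterworth applied forward-backward)."""
    epochs.validate()
    nyq = epochs.sampling_rate / 2.0
    if not 0 < cutoff < nyq:
        raise ValidationError(f"cutoff must lie in (0, Nyquist={nyq:g}) Hz")
    sos = butter(order, cutoff / nyq, btype="low", output="sos")
    return epochs.copy(data=sosfiltfilt(sos, epochs.data, axis=2))


def reject_amplitude(epochs: EpochSet,
                     threshold: float | dict = 6000.0) -> tuple[EpochSet, np.ndarray]:
    """Drop trials whose max absolute amplitude exceeds the threshold.

    ``threshold`` may be a scalar applied to all channels or a mapping
    ``channel_group -> value`` (e.g. separate magnetometer/gradiometer
    limits); a trial is bad if it exceeds the limit in any group.
    """
    epochs.validate()
    if isinstance(threshold, dict):
        bad = np.zeros(epochs.n_trials, dtype=bool)
        for group, th in threshold.items():
            if th <= 0:
                raise ValidationError("amplitude threshold must be > 0")
            idx = epochs.channel_indices(group)
            bad |= np.abs(epochs.data[:, idx, :]).max(axis=(1, 2)) > th
    else:
        if threshold <= 0:
            raise ValidationError("amplitude threshold must be > 0")
        bad = np.abs(epochs.data).max(axis=(1, 2)) > threshold
    rejected = np.flatnonzero(bad)
    if rejected.size == epochs.n_trials:
        raise ValidationError(
            "all trials exceed the amplitude threshold; review the threshold value"
        )
    keep = ~bad
    clean = epochs.copy(
        data=epochs.data[keep],
        image_id=epochs.image_id[keep],
        condition=epochs.condition[keep],
    )
    return clean, rejected


def _detect_blink_events(epochs: EpochSet, z_threshold: float) -> list[tuple[int, int]]:
    """(trial, sample) peaks of the frontal-channel RMS z-score."""
    front = epochs.channel_indices("frontal")
    rms = np.sqrt((epochs.data[:, front, :] ** 2).mean(axis=1))   # (trials, times)
    z = (rms - rms.mean()) / (rms.std() or 1.0)
    events = []
    for tr in range(epochs.n_trials):
        peaks, _ = find_peaks(z[tr], height=z_threshold)
        events.extend((tr, int(p)) for p in peaks)
    return events


def remove_blinks(epochs: EpochSet,
                  params: PreprocParams | None = None,
                  components: np.ndarray | None = None) -> tuple[EpochSet, dict]:
    """Detect blink transients on frontal channels and project them out.

    Peri-event segments are pooled across trials, their principal spatial
    components computed, and components up to ``blink_var_fraction`` of the
    pooled variance (capped at ``blink_max_components``) removed from all
    data by orthogonal projection.  Pass ``components`` (channels x k, as
    returned in the report) to reuse previously detected components instead
    of re-detecting; the projection is idempotent under reuse.
    """
    epochs.validate()
    if params is None:
        params = PreprocParams()
    epochs.channel_indices("frontal")   # raises if absent
    if components is None:
        events = _detect_blink_events(epochs, params.blink_z)
    else:
        events = []
    report: dict = {"n_events": len(events), "n_components": 0,
                    "variance_fraction_removed": 0.0, "components": None,
                    "warnings": []}
    if components is None and not events:
        report["warnings"].append("no blink events detected; data unchanged")
        return epochs.copy(), report

    if components is None:
        half = int(round(params.blink_halfwidth_ms * epochs.sampling_rate / 1000.0))
        segs = []
        for tr, p in events:
            lo, hi = max(0, p - half), min(epochs.n_times, p + half + 1)
            seg = epochs.data[tr, :, lo:hi]
            segs.append(seg - seg.mean(axis=1, keepdims=True))
        pooled = np.concatenate(segs, axis=1)             # (channels, samples)
        U, s, _ = np.linalg.svd(pooled, full_matrices=False)
        var = s ** 2 / np.sum(s ** 2)
        k = int(np.searchsorted(np.cumsum(var), params.blink_var_fraction) + 1)
        k = max(1, min(k, params.blink_max_components, U.shape[1]))
        V = U[:, :k]                                      # (channels, k)
        report["variance_fraction_removed"] = float(var[:k].sum())
    else:
        V = np.asarray(components, dtype=np.float64)
        if V.ndim != 2 or V.shape[0] != epochs.n_channels:
            raise ValidationError("components must be (n_channels, k)")
        k = V.shape[1]

    shape = epochs.data.shape
    flat = epochs.data.transpose(1, 0, 2).reshape(shape[1], -1)
    clean = flat - V @ (V.T @ flat)
    clean = clean.reshape(shape[1], shape[0], shape[2]).transpose(1, 0, 2)
    report.update(n_components=k, components=V)
    return epochs.copy(data=clean), report


def preprocess_chain(epochs: EpochSet,
                     params: PreprocParams | None = None) -> tuple[EpochSet, dict]:
    """Run baseline -> lowpass -> amplitude rejection -> blink removal."""
    if params is None:
        params = PreprocParams()
    out = baseline_correct(epochs, params.baseline)
    out = lowpass(out, params.lowpass_hz)
    out, rejected = reject_amplitude(out, params.amp_threshold)
    out, blink_report = remove_blinks(out, params)
    report = {
        "n_trials_in": epochs.n_trials,
        "n_trials_rejected": int(rejected.size),
        "rejected_trials": rejected.tolist(),
        "fraction_rejected": float(rejected.size / epochs.n_trials),
        "blink": blink_report,
    }
    return out, report
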