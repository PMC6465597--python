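"""Core data containers shared by all pipeline stages.

The containers are plain dataclasses wrapping NumPy arrays.  Each carries an
explicit time axis in milliseconds relative to stimulus onset and validates
its own structural invariants via :meth:`validate`; operations call
``validate`` on entry so a malformed object fails early with a message naming
the violated invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

CONDITIONS = ("high", "low")


class ValidationError(ValueError):
    """An object violates one of its declared structural invariants."""


class FormatError(ValueError):
    """An on-disk container is missing or malformed."""


def _as_float_array(x, name: str, ndim: int) -> np.ndarray:
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != ndim:
        raise ValidationError(f"{name} must be {ndim}-dimensional, got {arr.ndim}")
    return arr


def check_time_axis(times: np.ndarray, sampling_rate: float, rtol: float = 1e-6) -> None:
    """Times must be strictly increasing with constant step 1000/sampling_rate ms."""
    if times.ndim != 1 or times.size < 2:
        raise ValidationError("times must be a 1-D array with at least 2 samples")
    steps = np.diff(times)
    if np.any(steps <= 0):
        raise ValidationError("times must be strictly increasing")
    expected = 1000.0 / sampling_rate
    if not np.allclose(steps, expected, rtol=rtol, atol=1e-9):
        raise ValidationError(
            "times must have constant step equal to 1000/sampling_rate ms "
            f"(expected {expected:g} ms)"
        )


@dataclass
class EpochSet:
    """Labelled single-trial data: trials x channels x time.

    Parameters
    ----------
    data
        Array ``(n_trials, n_channels, n_times)``.  Units are arbitrary
        (fT for magnetometer sensors, dimensionless for synthetic/source data).
    times
        Time axis in ms relative to stimulus onset; uniform step.
    image_id
        Per-trial integer stimulus identity (1..K).
    condition
        Per-trial condition label, one of ``("high", "low")``.  The condition
        is a function of ``image_id``: an image never changes condition.
    channel_names, channel_group
        Per-channel name and group label (e.g. ``"sensor"``, ``"frontal"``,
        ``"ROI:pericalcarine_L"``).
    sampling_rate
        Sampling rate in Hz.
    subject_id
        Free-form subject identifier.
    """

    data: np.ndarray
    times: np.ndarray
    image_id: np.ndarray
    condition: np.ndarray
    channel_names: np.ndarray
    channel_group: np.ndarray
    sampling_rate: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = _as_float_array(self.data, "data", 3)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.image_id = np.asarray(self.image_id, dtype=np.int64)
        self.condition = np.asarray(self.condition, dtype=object)
        self.channel_names = np.asarray(self.channel_names, dtype=object)
        self.channel_group = np.asarray(self.channel_group, dtype=object)

    # -- basic shape accessors -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def validate(self) -> "EpochSet":
        n_tr, n_ch, n_t = self.data.shape
        if n_tr < 1:
            raise ValidationError("EpochSet must contain at least one trial")
        if self.times.shape != (n_t,):
            raise ValidationError("times length must match data's time axis")
        check_time_axis(self.times, self.sampling_rate)
        for name, arr, n in (
            ("image_id", self.image_id, n_tr),
            ("condition", self.condition, n_tr),
            ("channel_names", self.channel_names, n_ch),
            ("channel_group", self.channel_group, n_ch),
        ):
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length {n}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("all data values must be finite")
        bad = set(self.condition) - set(CONDITIONS)
        if bad:
            raise ValidationError(f"condition labels must be in {CONDITIONS}, got {bad}")
        # condition must be a function of image_id
        seen: dict[int, str] = {}
        for img, cond in zip(self.image_id, self.condition):
            if seen.setdefault(int(img), str(cond)) != str(cond):
                raise ValidationError(
                    f"image {img} appears in more than one condition "
                    "(condition must be a function of image_id)"
                )
        return self

    def condition_of(self) -> dict[int, str]:
        """Mapping image_id -> condition label."""
        out: dict[int, str] = {}
        for img, cond in zip(self.image_id, self.condition):
            out[int(img)] = str(cond)
        return out

    def channel_indices(self, group: str | None) -> np.ndarray:
        """Indices of channels in ``group`` (all channels if ``group`` is None)."""
        if group is None:
            return np.arange(self.n_channels)
        idx = np.flatnonzero(np.asarray([g == group for g in self.channel_group]))
        if idx.size == 0:
            raise ValidationError(f"no channels with channel_group {group!r}")
        return idx

    def copy(self, **updates) -> "EpochSet":
        new = replace(self, **updates)
        if "data" not in updates:
            new.data = self.data.copy()
        return new


@dataclass
class PseudoTrialSet:
    """Pseudo-trials of one image: averages of disjoint random trial groups."""

    data: np.ndarray          # (n_pseudo, n_channels, n_times)
    times: np.ndarray
    image_id: int
    group_size: int
    members: np.ndarray       # (n_pseudo, group_size) original trial indices
    repetition: int = 0
    seed: int | None = None

    @property
    def n_pseudo(self) -> int:
        return self.data.shape[0]

    def validate(self) -> "PseudoTrialSet":
        if self.data.ndim != 3:
            raise ValidationError("pseudo-trial data must be 3-D")
        if self.members.shape != (self.n_pseudo, self.group_size):
            raise ValidationError("members must be (n_pseudo, group_size)")
        flat = self.members.ravel()
        if len(set(flat.tolist())) != flat.size:
            raise ValidationError("pseudo-trial groups must be disjoint")
        return self


@dataclass
class RDMSeries:
    """Time-resolved representational dissimilarity matrices.

    ``values[t, i, j]`` is the cross-validated pairwise decoding accuracy in
    percent for images ``image_ids[i]`` vs ``image_ids[j]`` at time
    ``times[t]``; each K x K slice is symmetric with a zero diagonal.
    """

    values: np.ndarray        # (n_times, K, K), percent
    times: np.ndarray
    image_ids: np.ndarray     # (K,)
    condition_of: dict[int, str]
    subject_id: str = ""

    @property
    def n_images(self) -> int:
        return self.values.shape[1]

    def validate(self) -> "RDMSeries":
        v = self.values
        if v.ndim != 3 or v.shape[1] != v.shape[2]:
            raise ValidationError("values must be (n_times, K, K)")
        if self.times.shape != (v.shape[0],):
            raise ValidationError("times length must match values")
        if self.image_ids.shape != (v.shape[1],):
            raise ValidationError("image_ids length must match K")
        if not np.all(np.isfinite(v)):
            raise ValidationError("RDM entries must be finite")
        if not np.allclose(v, np.swapaxes(v, 1, 2), atol=1e-9):
            raise ValidationError("each RDM slice must be symmetric")
        if not np.allclose(np.diagonal(v, axis1=1, axis2=2), 0.0, atol=1e-9):
            raise ValidationError("RDM diagonals must be zero")
        if v.min() < -1e-9 or v.max() > 100 + 1e-9:
            raise ValidationError("RDM entries must lie in [0, 100]")
        missing = [int(i) for i in self.image_ids if int(i) not in self.condition_of]
        if missing:
            raise ValidationError(f"condition_of missing images {missing}")
        return self

    def pair_indices(self, condition: str | None = None) -> list[tuple[int, int]]:
        """Index pairs (i < j); optionally only pairs within one condition."""
        K = self.n_images
        pairs = []
        for i in range(K):
            for j in range(i + 1, K):
                if condition is not None:
                    ci = self.condition_of[int(self.image_ids[i])]
                    cj = self.condition_of[int(self.image_ids[j])]
                    if not (ci == condition and cj == condition):
                        continue
                pairs.append((i, j))
        return pairs


@dataclass
class ModelRDM:
    """Hypothesis dissimilarity matrix with an inclusion mask."""

    values: np.ndarray        # (K, K)
    mask: np.ndarray          # (K, K) bool; True = entry enters the correlation
    image_ids: np.ndarray
    name: str = ""

    def validate(self) -> "ModelRDM":
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValidationError("model RDM must be square")
        if not np.allclose(v, v.T):
            raise ValidationError("model RDM must be symmetric")
        if self.mask.shape != v.shape:
            raise ValidationError("mask shape must match values")
        if np.any(np.diagonal(self.mask)):
            raise ValidationError("diagonal must be excluded by the mask")
        return self


@dataclass
class DecodingTimeCourse:
    """A per-subject 1-D accuracy (or correlation) time course."""

    accuracy: np.ndarray      # (n_times,), percent (or rho for model tags)
    times: np.ndarray
    tag: str                  # "high" | "low" | "difference" | "model_correlation"
    subject_id: str = ""


@dataclass
class TempGenMatrix:
    """Train-time x test-time decoding accuracy matrix."""

    accuracy: np.ndarray      # (n_train_times, n_test_times), percent
    times: np.ndarray
    tag: str = ""
    subject_id: str = ""
    image_pair: tuple[int, int] | None = None


@dataclass
class ClusterResult:
    """Supra-threshold clusters with sizes and permutation p-values."""

    clusters: list            # list of index arrays (1-D) or (rows, cols) tuples (2-D)
    sizes: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray   # bool map over the tested axis/axes
    params: dict = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        alpha = self.params.get("alpha", 0.05)
        return int(np.sum(self.p_values <= alpha))

    def significant_clusters(self) -> list:
        alpha = self.params.get("alpha", 0.05)
        return [c for c, p in zip(self.clusters, self.p_values) if p <= alpha]

    def extents_ms(self, times: np.ndarray) -> list[tuple[float, float]]:
        """(onset_ms, offset_ms) of each cluster (1-D clusters only)."""
        out = []
        for c in self.clusters:
            idx = np.asarray(c[0] if isinstance(c, tuple) else c)
            out.append((float(times[idx.min()]), float(times[idx.max()])))
        return out


@dataclass
class BehavioralCounts:
    """Signal-detection outcome counts for one subject."""

    hits: int
    misses: int
    false_alarms: int
    correct_rejections: int

    def validate(self) -> "BehavioralCounts":
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValidationError(f"{name} must be a non-negative integer")
        if self.hits + self.misses == 0:
            raise ValidationError("hits + misses must be > 0")
        if self.false_alarms + self.correct_rejections == 0:
            raise ValidationError("false_alarms + correct_rejections must be > 0")
        return self
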