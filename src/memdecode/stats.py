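"""Nonparametric group-level inference.

Cluster-size permutation tests (sign-flip null, max-cluster-size statistic)
for 1-D time courses and 2-D temporal-generalization matrices, bootstrap
confidence intervals for peak latency, the exact Wilcoxon signed-rank test,
and signal-detection d'.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

from .containers import ClusterResult, BehavioralCounts, ValidationError


@dataclass
class StatParams:
    n_perm: int = 1000
    cdt: float = 0.05            # cluster-defining threshold (pointwise p)
    alpha: float = 0.05          # corrected cluster threshold
    tail: str = "greater"        # "greater", "less", or "two-sided"
    n_boot: int = 1000
    ci: float = 95.0
    seed: int = 0

    def validate(self) -> "StatParams":
        if not (0 < self.cdt < 1 and 0 < self.alpha < 1):
            raise ValidationError("cdt and alpha must lie in (0, 1)")
        if self.n_perm < 100 or self.n_boot < 100:
            raise ValidationError("n_perm and n_boot must be >= 100")
        if self.tail not in ("greater", "less", "two-sided"):
            raise ValidationError("tail must be greater, less, or two-sided")
        return self


def _t_stat(dev: np.ndarray) -> np.ndarray:
    """One-sample t across axis 0 (subjects).

    Zero-variance points map to 0 for zero mean and +-inf otherwise (a
    constant nonzero deviation is infinitely reliable).
    """
    n = dev.shape[0]
    m = dev.mean(axis=0)
    sd = dev.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, m / (sd / np.sqrt(n)), np.sign(m) * np.inf)
    return np.where(np.isnan(t), 0.0, t)


def _perm_t(dev2d: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t-statistics for all sign-flip permutations at once.

    dev2d: (n_subjects, n_points); flips: (n_perm, n_subjects).
    Uses the flip-invariance of per-subject squared deviations.
    """
    n = dev2d.shape[0]
    m = flips @ dev2d / n
    ss = (dev2d ** 2).sum(axis=0)
    var = np.maximum(ss - n * m ** 2, 0.0) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 1e-300, m / np.sqrt(var / n), np.sign(m) * np.inf)
    return np.where(np.isnan(t), 0.0, t)


def _sign_flips(n_subjects: int, n_perm: int,
                rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Random sign-flip matrix, or the exhaustive set if it is smaller."""
    if n_perm >= 2 ** n_subjects:
        warnings.warn(
            f"n_perm={n_perm} exceeds the 2^{n_subjects} distinct sign flips; "
            "using the exhaustive set", UserWarning)
        bits = np.arange(2 ** n_subjects)
        flips = 1.0 - 2.0 * ((bits[:, None] >> np.arange(n_subjects)) & 1)
        return flips, True
    return rng.choice([-1.0, 1.0], size=(n_perm, n_subjects)), False


def _max_run_lengths(mask: np.ndarray) -> np.ndarray:
    """Longest run of True per row of a 2-D boolean array (vectorized)."""
    x = mask.astype(np.int64)
    cs = np.cumsum(x, axis=1)
    anchor = np.where(~mask, cs, 0)
    run = cs - np.maximum.accumulate(anchor, axis=1)
    return run.max(axis=1)


def _threshold(df: int, cdt: float, tail: str) -> float:
    p = cdt / 2 if tail == "two-sided" else cdt
    return float(t_dist.ppf(1.0 - p, df))


def _signed_masks(t: np.ndarray, crit: float, tail: str) -> list[np.ndarray]:
    if tail == "greater":
        return [t > crit]
    if tail == "less":
        return [-t > crit]
    return [t > crit, -t > crit]


def cluster_test_1d(samples: np.ndarray, chance: float,
                    params: StatParams | None = None,
                    rng: np.random.Generator | None = None) -> ClusterResult:
    """Cluster-size permutation test on subject x time accuracy curves.

    Pointwise one-sample t-statistics against ``chance`` are thresholded at
    the cluster-defining p, contiguous supra-threshold runs form clusters,
    and each observed cluster's size (time-point count) is compared with the
    null distribution of the *maximum* cluster size over whole-series
    sign-flips of the subject deviations.  p = (1 + #{perm max >= size}) /
    (n_perm + 1); with exhaustive flips the raw proportion is used.
    """
    params = (params or StatParams()).validate()
    dev = np.asarray(samples, dtype=np.float64) - chance
    if dev.ndim != 2:
        raise ValidationError("samples must be (n_subjects, n_times)")
    n_sub, n_t = dev.shape
    if n_sub < 6:
        raise ValidationError("cluster test requires at least 6 subjects")
    if not np.all(np.isfinite(dev)):
        raise ValidationError("samples must be finite")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    crit = _threshold(n_sub - 1, params.cdt, params.tail)

    t_obs = _t_stat(dev)
    clusters, sizes = [], []
    for mask in _signed_masks(t_obs, crit, params.tail):
        lab, n_lab = ndimage.label(mask)
        for k in range(1, n_lab + 1):
            idx = np.flatnonzero(lab == k)
            clusters.append(idx)
            sizes.append(idx.size)
    sizes = np.asarray(sizes, dtype=np.int64)

    flips, exhaustive = _sign_flips(n_sub, params.n_perm, rng)
    t_perm = _perm_t(dev, flips)
    null_max = np.zeros(flips.shape[0], dtype=np.int64)
    for mask in _signed_masks(t_perm, crit, params.tail):
        null_max = np.maximum(null_max, _max_run_lengths(mask))

    if exhaustive:
        p = np.asarray([(null_max >= s).mean() for s in sizes])
    else:
        p = np.asarray([(1 + (null_max >= s).sum()) / (flips.shape[0] + 1) for s in sizes])
    significant = np.zeros(n_t, dtype=bool)
    for idx, pv in zip(clusters, p):
        if pv <= params.alpha:
            significant[idx] = True
    return ClusterResult(
        clusters=clusters, sizes=sizes, p_values=p, significant=significant,
        params={"n_perm": int(flips.shape[0]), "cdt": params.cdt,
                "alpha": params.alpha, "tail": params.tail, "chance": chance,
                "statistic": "one-sample t, sign-flip max cluster size",
                "exhaustive": exhaustive, "threshold": crit},
    )


_STRUCTURE_4 = np.asarray([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


def _components_2d(mask: np.ndarray) -> tuple[list, np.ndarray]:
    lab, n_lab = ndimage.label(mask, structure=_STRUCTURE_4)
    comps, sizes = [], []
    for k in range(1, n_lab + 1):
        rows, cols = np.nonzero(lab == k)
        comps.append((rows, cols))
        sizes.append(rows.size)
    return comps, np.asarray(sizes, dtype=np.int64)


def cluster_test_2d(samples: np.ndarray, chance: float,
                    params: StatParams | None = None,
                    rng: np.random.Generator | None = None) -> ClusterResult:
    """As :func:`cluster_test_1d`, with 4-connected 2-D components."""
    params = (params or StatParams()).validate()
    dev = np.asarray(samples, dtype=np.float64) - chance
    if dev.ndim != 3:
        raise ValidationError("samples must be (n_subjects, n_train, n_test)")
    n_sub = dev.shape[0]
    if n_sub < 6:
        raise ValidationError("cluster test requires at least 6 subjects")
    if not np.all(np.isfinite(dev)):
        raise ValidationError("samples must be finite")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    shape2d = dev.shape[1:]
    crit = _threshold(n_sub - 1, params.cdt, params.tail)

    t_obs = _t_stat(dev)
    clusters, sizes = [], []
    for mask in _signed_masks(t_obs, crit, params.tail):
        comps, sz = _components_2d(mask)
        clusters.extend(comps)
        sizes.extend(sz.tolist())
    sizes = np.asarray(sizes, dtype=np.int64)

    flips, exhaustive = _sign_flips(n_sub, params.n_perm, rng)
    flat = dev.reshape(n_sub, -1)
    t_perm = _perm_t(flat, flips).reshape(flips.shape[0], *shape2d)
    null_max = np.zeros(flips.shape[0], dtype=np.int64)
    for i in range(flips.shape[0]):
        for mask in _signed_masks(t_perm[i], crit, params.tail):
            _, sz = _components_2d(mask)
            if sz.size:
                null_max[i] = max(null_max[i], int(sz.max()))

    if exhaustive:
        p = np.asarray([(null_max >= s).mean() for s in sizes])
    else:
        p = np.asarray([(1 + (null_max >= s).sum()) / (flips.shape[0] + 1) for s in sizes])
    significant = np.zeros(shape2d, dtype=bool)
    for (rows, cols), pv in zip(clusters, p):
        if pv <= params.alpha:
            significant[rows, cols] = True
    return ClusterResult(
        clusters=clusters, sizes=sizes, p_values=p, significant=significant,
        params={"n_perm": int(flips.shape[0]), "cdt": params.cdt,
                "alpha": params.alpha, "tail": params.tail, "chance": chance,
                "statistic": "one-sample t, sign-flip max 4-connected cluster size",
                "exhaustive": exhaustive, "threshold": crit},
    )


def bootstrap_peak_latency(samples: np.ndarray, times: np.ndarray,
                           params: StatParams | None = None,
                           rng: np.random.Generator | None = None
                           ) -> tuple[float, float, float, np.ndarray]:
    """Peak latency of the group-mean curve with a bootstrap CI.

    Subjects are resampled with replacement ``n_boot`` times; each
    resample's mean curve contributes its argmax latency to the empirical
    distribution whose percentiles bound the CI.  Returns
    ``(peak_ms, ci_low_ms, ci_high_ms, bootstrap_peaks_ms)``.  Flat curves
    take the earliest maximum.
    """
    params = (params or StatParams()).validate()
    samples = np.asarray(samples, dtype=np.float64)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValidationError("samples must be (n_subjects >= 2, n_times)")
    if samples.shape[1] != len(times):
        raise ValidationError("times length must match samples")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n_sub = samples.shape[0]
    peak = float(times[int(np.argmax(samples.mean(axis=0)))])
    draws = rng.integers(0, n_sub, size=(params.n_boot, n_sub))
    boot_means = samples[draws].mean(axis=1)
    boot_peaks = times[np.argmax(boot_means, axis=1)]
    lo, hi = np.percentile(boot_peaks, [(100 - params.ci) / 2, 100 - (100 - params.ci) / 2])
    return peak, float(lo), float(hi), boot_peaks


def dprime(counts: BehavioralCounts) -> float:
    """Signal-detection sensitivity d' = z(hit rate) - z(false-alarm rate).

    Rates are clipped to [1/(2n), 1 - 1/(2n)] per response class so that
    perfect (or zero) rates stay finite; negative d' is representable.
    """
    counts.validate()
    n_sig = counts.hits + counts.misses
    n_noise = counts.false_alarms + counts.correct_rejections
    h = np.clip(counts.hits / n_sig, 1 / (2 * n_sig), 1 - 1 / (2 * n_sig))
    fa = np.clip(counts.false_alarms / n_noise, 1 / (2 * n_noise), 1 - 1 / (2 * n_noise))
    return float(norm.ppf(h) - norm.ppf(fa))


def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Exact two-sided p by dynamic programming over the sign-flip null.

    Average ranks are doubled to integers; the distribution of the doubled
    positive-rank sum W over all 2^n sign assignments is built by
    convolution (exact in float64 for n <= 25).
    """
    r2 = np.rint(2 * rankdata(np.abs(d))).astype(np.int64)
    w_obs = int(r2[d > 0].sum())
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[:total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    p_low = dist[: w_obs + 1].sum()
    p_high = dist[w_obs:].sum()
    return float(min(1.0, 2.0 * min(p_low, p_high)))


def signed_rank(values: np.ndarray, null_value: float = 0.0,
                exact_max_n: int = 25) -> float:
    """Two-sided Wilcoxon signed-rank p-value against ``null_value``.

    Zero differences are dropped; ties get average ranks.  The exact
    sign-flip distribution is enumerated for n <= ``exact_max_n``, a normal
    approximation with tie correction is used beyond.  All-zero differences
    give p = 1 with a warning.
    """
    d = np.asarray(values, dtype=np.float64) - null_value
    d = d[d != 0]
    n = d.size
    if n == 0:
        warnings.warn("all differences are zero; p = 1", UserWarning)
        return 1.0
    if n <= exact_max_n:
        return _exact_signed_rank_p(d)
    r = rankdata(np.abs(d))
    w = r[d > 0].sum()
    mu = n * (n + 1) / 4
    _, tie_counts = np.unique(r, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24 - (tie_counts ** 3 - tie_counts).sum() / 48
    z = (w - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * norm.sf(abs(z))))
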