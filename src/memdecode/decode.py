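"""Time-resolved pairwise decoding.

For every pair of images and every time point, a linear SVM (libsvm backend,
C = 1) is trained on pseudo-trials (averages of ``g`` randomly grouped
trials) and evaluated with a paired leave-one-out schedule: fold *k* holds
out pseudo-trial *k* of each image and trains on the remaining ``2(N-1)``
pattern vectors.  Feature vectors are the raw channel values at a single
time point; no scaling or dimensionality reduction is applied.  Accuracies
averaged over repetitions populate the time-resolved RDM.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .containers import (
    DecodingTimeCourse,
    EpochSet,
    PseudoTrialSet,
    RDMSeries,
    TempGenMatrix,
    ValidationError,
)

# The public SVC estimator spends ~100x the libsvm solve time on input
# validation, which is prohibitive at ~10^6 tiny fits per analysis; use the
# low-level libsvm binding directly, falling back to SVC if it moves.
try:  # pragma: no cover - import plumbing
    from sklearn.svm import _libsvm as _libsvm

    _libsvm.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except Exception:  # pragma: no cover
    from sklearn.svm import SVC

    _HAVE_LIBSVM = False


def fit_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0) -> tuple[np.ndarray, float]:
    """Fit a linear C-SVM; return (w, b) with decision ``x @ w + b``.

    ``y`` holds labels 0.0 (class A) and 1.0 (class B); a decision value
    >= 0 classifies as A, so exact ties break deterministically toward A.
    """
    if _HAVE_LIBSVM:
        _, SV, _, dual, intercept, *_ = _libsvm.fit(
            np.ascontiguousarray(X, dtype=np.float64),
            np.ascontiguousarray(y, dtype=np.float64),
            svm_type=0, kernel="linear", C=C,
        )
        return dual[0] @ SV, float(intercept[0])
    clf = SVC(kernel="linear", C=C).fit(X, y)  # decision > 0 -> classes_[1] = 1.0 = B
    return -clf.coef_[0], float(-clf.intercept_[0])


@dataclass
class DecodeParams:
    """Knobs of the decoding stage."""

    group_size: int = 5          # trials per pseudo-trial
    n_repetitions: int = 100     # independent re-draws of the subaveraging
    C: float = 1.0               # SVM regularization
    channel_group: str | None = None   # None = all channels; else ROI/group name
    seed: int = 0

    def validate(self) -> "DecodeParams":
        if self.group_size < 1:
            raise ValidationError("group_size must be >= 1")
        if self.n_repetitions < 1:
            raise ValidationError("n_repetitions must be >= 1")
        if self.C <= 0:
            raise ValidationError("C must be > 0")
        return self


def subaverage(epochs: EpochSet, image_id: int, g: int,
               rng: np.random.Generator, repetition: int = 0) -> PseudoTrialSet:
    """Randomly partition one image's trials into groups of ``g`` and average.

    ``floor(n/g)`` pseudo-trials result; remainder trials are discarded at
    random (the partition is drawn from a uniform random permutation).
    """
    idx = np.flatnonzero(epochs.image_id == image_id)
    if idx.size == 0:
        raise ValidationError(f"no trials with image_id {image_id}")
    n_groups = idx.size // g
    if n_groups < 1:
        raise ValidationError(
            f"image {image_id} has {idx.size} trials, fewer than group size {g}"
        )
    perm = rng.permutation(idx)[: n_groups * g]
    members = perm.reshape(n_groups, g)
    data = epochs.data[members].mean(axis=1)
    return PseudoTrialSet(
        data=data, times=epochs.times, image_id=int(image_id), group_size=g,
        members=members, repetition=repetition,
    ).validate()


def _stacked(pseudo: PseudoTrialSet, ch_idx: np.ndarray | None) -> np.ndarray:
    """Pseudo-trial data as a (T, N, S) C-contiguous stack."""
    d = pseudo.data if ch_idx is None else pseudo.data[:, ch_idx, :]
    return np.ascontiguousarray(d.transpose(2, 0, 1))


def _fit_fold_classifiers(Pa: np.ndarray, Pb: np.ndarray, C: float) -> tuple[np.ndarray, np.ndarray]:
    """Train the paired leave-one-out classifiers at every time point.

    Pa, Pb: (T, N, S).  Returns ws (T, N, S) and bs (T, N): the classifier of
    fold k at time t is trained on all pseudo-trials except index k of each
    class (class A = first argument, labelled 0).
    """
    T, N, S = Pa.shape
    if N < 2:
        raise ValidationError("need at least 2 pseudo-trials per image")
    ws = np.empty((T, N, S))
    bs = np.empty((T, N))
    y = np.concatenate([np.zeros(N - 1), np.ones(N - 1)])
    keep = [np.r_[0:k, k + 1:N] for k in range(N)]
    Xtr = np.empty((2 * (N - 1), S))
    for t in range(T):
        At, Bt = Pa[t], Pb[t]
        for k in range(N):
            Xtr[: N - 1] = At[keep[k]]
            Xtr[N - 1:] = Bt[keep[k]]
            w, b = fit_linear_svm(Xtr, y, C)
            ws[t, k] = w
            bs[t, k] = b
    return ws, bs


def _diag_accuracy(Pa: np.ndarray, Pb: np.ndarray,
                   ws: np.ndarray, bs: np.ndarray) -> np.ndarray:
    """% correct of each fold's held-out pair, at the training time point."""
    da = np.einsum("tns,tns->tn", Pa, ws) + bs
    db = np.einsum("tns,tns->tn", Pb, ws) + bs
    N = Pa.shape[1]
    return 100.0 * ((da >= 0).sum(axis=1) + (db < 0).sum(axis=1)) / (2.0 * N)


def _check_pair(pseudoA: PseudoTrialSet, pseudoB: PseudoTrialSet) -> None:
    if pseudoA.n_pseudo != pseudoB.n_pseudo:
        raise ValidationError("images must have the same pseudo-trial count")
    if not np.array_equal(pseudoA.times, pseudoB.times):
        raise ValidationError("pseudo-trial sets must share the time axis")


def pair_decode_timecourse(pseudoA: PseudoTrialSet, pseudoB: PseudoTrialSet,
                           params: DecodeParams | None = None,
                           ch_idx: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out pairwise decoding accuracy (%) at every time point."""
    params = (params or DecodeParams()).validate()
    _check_pair(pseudoA, pseudoB)
    Pa, Pb = _stacked(pseudoA, ch_idx), _stacked(pseudoB, ch_idx)
    ws, bs = _fit_fold_classifiers(Pa, Pb, params.C)
    return _diag_accuracy(Pa, Pb, ws, bs)


def temporal_generalization(pseudoA: PseudoTrialSet, pseudoB: PseudoTrialSet,
                            params: DecodeParams | None = None,
                            ch_idx: np.ndarray | None = None,
                            subject_id: str = "", tag: str = "") -> TempGenMatrix:
    """Train at each time point, test the same held-out folds at all others.

    The diagonal reuses the classifiers of :func:`pair_decode_timecourse`
    (identical fold schedule), so it equals the 1-D time course bit for bit
    under the same pseudo-trials.
    """
    params = (params or DecodeParams()).validate()
    _check_pair(pseudoA, pseudoB)
    Pa, Pb = _stacked(pseudoA, ch_idx), _stacked(pseudoB, ch_idx)
    ws, bs = _fit_fold_classifiers(Pa, Pb, params.C)
    T, N, _ = Pa.shape
    acc = np.empty((T, T))
    for t in range(T):
        # held-out pseudo-trial k evaluated at every test time t'
        da = np.einsum("uns,ns->un", Pa, ws[t]) + bs[t][None, :]
        db = np.einsum("uns,ns->un", Pb, ws[t]) + bs[t][None, :]
        acc[t] = 100.0 * ((da >= 0).sum(axis=1) + (db < 0).sum(axis=1)) / (2.0 * N)
    return TempGenMatrix(accuracy=acc, times=pseudoA.times, tag=tag,
                         subject_id=subject_id,
                         image_pair=(pseudoA.image_id, pseudoB.image_id))


def repetition_seeds(seed: int, n_repetitions: int) -> list[np.random.SeedSequence]:
    """Deterministic child seeds, one per subaveraging repetition."""
    return np.random.SeedSequence(seed).spawn(n_repetitions)


def _draw_pseudotrials(epochs: EpochSet, image_ids: np.ndarray, g: int,
                       rng: np.random.Generator, repetition: int) -> dict[int, PseudoTrialSet]:
    pseudos = {int(i): subaverage(epochs, int(i), g, rng, repetition) for i in image_ids}
    n_common = min(p.n_pseudo for p in pseudos.values())
    for i, p in pseudos.items():
        if p.n_pseudo > n_common:
            pseudos[i] = PseudoTrialSet(
                data=p.data[:n_common], times=p.times, image_id=p.image_id,
                group_size=p.group_size, members=p.members[:n_common],
                repetition=p.repetition, seed=p.seed,
            )
    return pseudos


def rdm_one_repetition(epochs: EpochSet, params: DecodeParams,
                       seed) -> np.ndarray:
    """One repetition's (n_times, K, K) RDM from a fresh random subaveraging."""
    rng = np.random.default_rng(seed)
    image_ids = np.unique(epochs.image_id)
    ch_idx = epochs.channel_indices(params.channel_group)
    pseudos = _draw_pseudotrials(epochs, image_ids, params.group_size, rng, 0)
    stacks = {i: _stacked(p, ch_idx) for i, p in pseudos.items()}
    K = image_ids.size
    rdm = np.zeros((epochs.n_times, K, K))
    for a, b in combinations(range(K), 2):
        Pa, Pb = stacks[int(image_ids[a])], stacks[int(image_ids[b])]
        ws, bs = _fit_fold_classifiers(Pa, Pb, params.C)
        acc = _diag_accuracy(Pa, Pb, ws, bs)
        rdm[:, a, b] = acc
        rdm[:, b, a] = acc
    return rdm


def build_rdm_series(epochs: EpochSet, params: DecodeParams | None = None) -> RDMSeries:
    """Average pairwise decoding RDMs over ``n_repetitions`` subaveragings."""
    params = (params or DecodeParams()).validate()
    epochs.validate()
    image_ids = np.unique(epochs.image_id)
    counts = np.asarray([(epochs.image_id == i).sum() for i in image_ids])
    if counts.min() < params.group_size:
        raise ValidationError("every image needs at least group_size trials")
    seeds = repetition_seeds(params.seed, params.n_repetitions)
    acc = np.zeros((epochs.n_times, image_ids.size, image_ids.size))
    for s in seeds:
        acc += rdm_one_repetition(epochs, params, s)
    acc /= params.n_repetitions
    return RDMSeries(
        values=acc, times=epochs.times, image_ids=image_ids,
        condition_of=epochs.condition_of(), subject_id=epochs.subject_id,
    ).validate()


def condition_mean_timecourses(rdm: RDMSeries) -> dict[str, DecodingTimeCourse]:
    """Mean decoding within each condition plus their difference (high - low).

    Between-condition pairs contribute to neither mean.
    """
    rdm.validate()
    out = {}
    for cond in ("high", "low"):
        pairs = rdm.pair_indices(cond)
        if len(pairs) < 1:
            raise ValidationError(f"condition {cond!r} needs at least 2 images")
        ii = np.asarray([p[0] for p in pairs])
        jj = np.asarray([p[1] for p in pairs])
        out[cond] = DecodingTimeCourse(
            accuracy=rdm.values[:, ii, jj].mean(axis=1),
            times=rdm.times, tag=cond, subject_id=rdm.subject_id,
        )
    out["difference"] = DecodingTimeCourse(
        accuracy=out["high"].accuracy - out["low"].accuracy,
        times=rdm.times, tag="difference", subject_id=rdm.subject_id,
    )
    return out


def subject_tempgen(epochs: EpochSet, params: DecodeParams | None = None,
                    seed=None) -> list[TempGenMatrix]:
    """Temporal-generalization matrices for every image pair of one subject.

    One subaveraging draw (repetitions are prohibitive in T^2); pass ``seed``
    to override the params seed.
    """
    params = (params or DecodeParams()).validate()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    image_ids = np.unique(epochs.image_id)
    ch_idx = epochs.channel_indices(params.channel_group)
    pseudos = _draw_pseudotrials(epochs, image_ids, params.group_size, rng, 0)
    cond = epochs.condition_of()
    out = []
    for a, b in combinations([int(i) for i in image_ids], 2):
        tag = cond[a] if cond[a] == cond[b] else "between"
        out.append(temporal_generalization(pseudos[a], pseudos[b], params,
                                           ch_idx=ch_idx,
                                           subject_id=epochs.subject_id, tag=tag))
    return out


def condition_mean_tempgen(matrices: list[TempGenMatrix],
                           condition_of: dict[int, str]) -> dict[str, TempGenMatrix]:
    """Average per-pair matrices within condition (per subject), then across
    subjects.  Between-condition pairs are excluded."""
    if not matrices:
        raise ValidationError("no matrices supplied")
    out = {}
    for cond in ("high", "low"):
        per_subject: dict[str, list[np.ndarray]] = {}
        for m in matrices:
            if m.image_pair is None:
                raise ValidationError("matrices must carry image_pair labels")
            a, b = m.image_pair
            if condition_of[int(a)] == cond and condition_of[int(b)] == cond:
                per_subject.setdefault(m.subject_id, []).append(m.accuracy)
        if not per_subject:
            raise ValidationError(f"no within-{cond} pair matrices supplied")
        subj_means = [np.mean(v, axis=0) for v in per_subject.values()]
        out[cond] = TempGenMatrix(
            accuracy=np.mean(subj_means, axis=0), times=matrices[0].times,
            tag=cond, subject_id="group",
        )
    return out
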