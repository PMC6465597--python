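"""Representational similarity analysis against hypothesis geometries.

Two hypothesis RDMs are provided: a *categorical* geometry (the two
conditions are linearly separable clusters) and a *dispersion* geometry
(high-memorability exemplars spread out around the same centroid the
low-memorability exemplars cluster tightly around).  Measured RDMs are
compared with a model by Spearman rank correlation over the masked
off-diagonal entries, per time point and per subject; being rank-based, the
comparison is invariant to any monotone transform of the measured
dissimilarities and to the specific within/between values chosen for the
models as long as their ordering is preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .containers import ModelRDM, RDMSeries, ValidationError


def _check_conditions(condition_of: dict[int, str]) -> tuple[np.ndarray, np.ndarray]:
    image_ids = np.asarray(sorted(condition_of), dtype=np.int64)
    conds = np.asarray([condition_of[int(i)] for i in image_ids], dtype=object)
    for cond in ("high", "low"):
        if (conds == cond).sum() < 2:
            raise ValidationError(f"condition {cond!r} needs at least 2 images")
    return image_ids, conds


def categorical_model(condition_of: dict[int, str]) -> ModelRDM:
    """Linearly separable clusters: between-condition 1, within-condition 0."""
    image_ids, conds = _check_conditions(condition_of)
    between = conds[:, None] != conds[None, :]
    values = between.astype(float)
    mask = ~np.eye(image_ids.size, dtype=bool)
    return ModelRDM(values=values, mask=mask, image_ids=image_ids,
                    name="categorical").validate()


def dispersion_model(condition_of: dict[int, str],
                     include_between: bool = True) -> ModelRDM:
    """Dispersion geometry: within-high 1, within-low 0, between 0.5.

    With a shared centroid the expected between-condition distance lies
    between the two within-condition distances, hence the intermediate 0.5
    coding.  ``include_between=False`` masks between-condition pairs out of
    the correlation instead.
    """
    image_ids, conds = _check_conditions(condition_of)
    high = conds == "high"
    values = np.full((image_ids.size,) * 2, 0.5)
    values[np.ix_(high, high)] = 1.0
    values[np.ix_(~high, ~high)] = 0.0
    np.fill_diagonal(values, 0.0)
    mask = ~np.eye(image_ids.size, dtype=bool)
    if not include_between:
        mask &= ~(high[:, None] ^ high[None, :])
    return ModelRDM(values=values, mask=mask, image_ids=image_ids,
                    name="dispersion" if include_between else "dispersion_masked").validate()


@dataclass
class RsaResult:
    """Per-time-point model correlation for one subject (or stacked group)."""

    rho: np.ndarray           # (n_times,) or (n_subjects, n_times)
    times: np.ndarray
    model_name: str
    subject_id: str = ""
    n_zero_variance: int = 0  # time points where rho was set to 0 (flat RDM)


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman rank correlation with average ranks for ties."""
    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return np.nan
    return float((rx * ry).sum() / denom)


def rsa_correlate(rdm: RDMSeries, model: ModelRDM) -> RsaResult:
    """Spearman correlation of the measured RDM with a model, per time point.

    Entries are the masked lower-triangle dissimilarities.  Time points where
    either vector has zero variance yield rho = 0 and are counted in
    ``n_zero_variance``.
    """
    rdm.validate()
    model.validate()
    if not np.array_equal(np.sort(rdm.image_ids), np.sort(model.image_ids)):
        raise ValidationError("RDM and model must cover the same images")
    order = np.argsort(rdm.image_ids)
    morder = np.argsort(model.image_ids)
    tri = np.tril(np.ones(rdm.n_images, dtype=bool), k=-1)
    sel = model.mask[np.ix_(morder, morder)] & tri
    mvec = model.values[np.ix_(morder, morder)][sel]
    rho = np.empty(rdm.times.size)
    n_flat = 0
    values = rdm.values[:, order][:, :, order]
    for t in range(rdm.times.size):
        r = spearman_rho(values[t][sel], mvec)
        if np.isnan(r):
            r, n_flat = 0.0, n_flat + 1
        rho[t] = r
    return RsaResult(rho=rho, times=rdm.times, model_name=model.name,
                     subject_id=rdm.subject_id, n_zero_variance=n_flat)


def cohort_rsa(rdms: list[RDMSeries], model: ModelRDM) -> RsaResult:
    """Stack per-subject rho curves into an (n_subjects, n_times) result."""
    results = [rsa_correlate(r, model) for r in rdms]
    return RsaResult(
        rho=np.stack([r.rho for r in results]),
        times=results[0].times, model_name=model.name, subject_id="group",
        n_zero_variance=sum(r.n_zero_variance for r in results),
    )


def mds_embed(dissimilarity: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Classical (Torgerson) MDS of a symmetric zero-diagonal dissimilarity.

    Double-centers the squared dissimilarities and returns the top spectral
    coordinates, centered at the origin.  Axes with non-positive eigenvalues
    come back as zeros.
    """
    D = np.asarray(dissimilarity, dtype=np.float64)
    K = D.shape[0]
    if D.ndim != 2 or D.shape != (K, K):
        raise ValidationError("dissimilarity must be a square matrix")
    if K < 3:
        raise ValidationError("MDS needs at least 3 items")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValidationError("dissimilarity must be symmetric with zero diagonal")
    J = np.eye(K) - np.ones((K, K)) / K
    B = -0.5 * J @ (D ** 2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1][:n_components]
    coords = np.zeros((K, n_components))
    for a, k in enumerate(order):
        if eigval[k] > 0:
            coords[:, a] = eigvec[:, k] * np.sqrt(eigval[k])
    return coords
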