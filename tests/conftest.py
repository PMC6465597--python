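import numpy as np
import pytest

from memdecode.containers import EpochSet
from memdecode.decode import DecodeParams, build_rdm_series, condition_mean_timecourses
from memdecode.rsa import categorical_model, cohort_rsa, dispersion_model
from memdecode.stats import StatParams, cluster_test_1d
from memdecode.synth import SynthConfig, simulate_cohort


def make_epochs(n_trials=8, n_channels=3, n_times=10, sampling_rate=1000.0,
                tmin=-2.0, seed=0, n_images=2, subject_id="toy") -> EpochSet:
    """Small deterministic EpochSet; first channel is 'frontal'."""
    rng = np.random.default_rng(seed)
    times = tmin + np.arange(n_times) * (1000.0 / sampling_rate)
    image_id = np.arange(n_trials) % n_images + 1
    condition = np.asarray(
        ["high" if i <= (n_images + 1) // 2 else "low" for i in image_id], dtype=object)
    return EpochSet(
        data=rng.standard_normal((n_trials, n_channels, n_times)),
        times=times,
        image_id=image_id,
        condition=condition,
        channel_names=np.asarray([f"ch{i}" for i in range(n_channels)], dtype=object),
        channel_group=np.asarray(
            ["frontal"] + ["sensor"] * (n_channels - 1), dtype=object),
        sampling_rate=sampling_rate,
        subject_id=subject_id,
    ).validate()


@pytest.fixture
def tiny_epochs() -> EpochSet:
    return make_epochs()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# Shared cohort-recovery computation: 20 independent synthetic cohorts at desk
# scale, decoded and tested once, then examined by the geometry-contrast and
# difference-window recovery tests.
# ---------------------------------------------------------------------------

N_RECOVERY_COHORTS = 20
RECOVERY_SEED_BASE = 5000


def _analyze_cohort(seed: int) -> dict:
    cfg = SynthConfig.desk_scale(seed=seed)
    st = StatParams(n_perm=500, cdt=0.05, alpha=0.05, tail="greater", seed=seed + 1)
    subjects, truth = simulate_cohort(cfg)
    rdms, diffs = [], []
    for k, ep in enumerate(subjects):
        rdm = build_rdm_series(
            ep, DecodeParams(group_size=5, n_repetitions=1, seed=seed * 101 + k))
        rdms.append(rdm)
        diffs.append(condition_mean_timecourses(rdm)["difference"].accuracy)
    times = rdms[0].times
    cond = rdms[0].condition_of

    def _sig_extents(result):
        return [(float(times[c.min()]), float(times[c.max()]))
                for c, p in zip(result.clusters, result.p_values) if p <= st.alpha]

    return {
        "t_on": cfg.t_on,
        "t_off": cfg.t_off,
        "dispersion": _sig_extents(
            cluster_test_1d(cohort_rsa(rdms, dispersion_model(cond)).rho, 0.0, st)),
        "categorical": _sig_extents(
            cluster_test_1d(cohort_rsa(rdms, categorical_model(cond)).rho, 0.0, st)),
        "difference": _sig_extents(
            cluster_test_1d(np.stack(diffs), 0.0, st)),
    }


@pytest.fixture(scope="session")
def recovery_cohorts() -> list[dict]:
    return [_analyze_cohort(RECOVERY_SEED_BASE + c) for c in range(N_RECOVERY_COHORTS)]
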