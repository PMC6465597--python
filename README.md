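# memdecode

Time-resolved multivariate decoding and representational similarity
analysis (RSA) for epoched multichannel recordings — the analysis family
used to ask *when* a stimulus property (here: image memorability) becomes
explicit in neural population activity, and *what shape* the underlying
representational geometry has.

The package is aimed at cognitive-neuroimaging researchers who want a
tested, reproducible implementation of this pipeline, together with a
synthetic-cohort generator whose ground truth makes the pipeline's
sensitivity and error rates measurable.

## What it computes

Given epochs `X ∈ ℝ^{trials × channels × time}` labelled with image
identity `i ∈ 1..K` and condition (high/low memorability):

1. **Pairwise decoding RDMs.**  Trials are sub-averaged in random groups
   of *g* = 5 into pseudo-trials.  For every image pair (i, j) and time
   point *t*, a linear SVM (libsvm, C = 1) on the raw channel vectors at
   *t* is scored with paired leave-one-out cross-validation; accuracies,
   averaged over R sub-averaging repetitions, fill a K×K representational
   dissimilarity matrix per time point.
2. **Condition means.**  Decoding averaged within high pairs, within low
   pairs, and their difference — the difference time course is the
   memorability signal.
3. **RSA.**  Spearman rank correlation ρ(t) of the measured RDM with two
   hypothesis geometries: *categorical* (conditions form linearly separable
   clusters) and *dispersion* (high-memorability exemplars spread around
   the same centroid that low-memorability exemplars cluster tightly
   about).  Classical MDS embeddings visualize the geometry.
4. **Temporal generalization.**  Classifiers trained at *t* tested at all
   *t′*; the matrix distinguishes sustained from dynamically evolving
   codes.
5. **Inference.**  Cluster-size permutation tests (sign-flip null, max
   cluster size, cluster-defining p = 0.05, corrected p = 0.05) for 1-D
   curves and 2-D matrices; bootstrap CIs for peak latency; exact Wilcoxon
   signed-rank tests; signal-detection d′ for behavioral counts.

The synthetic generator simulates cohorts with an early image-identity
signal shared by both conditions plus a condition-specific dispersion
difference confined to a configurable latency window (default
149–228 ms), so recovery of both the *timing* and the *geometry* can be
checked against ground truth.  See `docs/methods.md` for the model and
all numerical choices.

## Worked example

```python
import numpy as np
from memdecode import (SynthConfig, simulate_cohort, DecodeParams,
                       build_rdm_series, condition_mean_timecourses,
                       dispersion_model, categorical_model, cohort_rsa,
                       cluster_test_1d, StatParams, bootstrap_peak_latency)

cfg = SynthConfig.desk_scale(seed=7)        # 10 subjects, 10+10 images, 24 ch, 100 Hz
subjects, truth = simulate_cohort(cfg)
rdms = [build_rdm_series(ep, DecodeParams(group_size=5, n_repetitions=1, seed=k))
        for k, ep in enumerate(subjects)]
courses = [condition_mean_timecourses(r) for r in rdms]
times = rdms[0].times

high = np.stack([c["high"].accuracy for c in courses])
diff = np.stack([c["difference"].accuracy for c in courses])
st = StatParams(n_perm=500, seed=0)
res = cluster_test_1d(diff, 0.0, st)
peak, lo, hi, _ = bootstrap_peak_latency(high, times, st)
disp = cluster_test_1d(cohort_rsa(rdms, dispersion_model(rdms[0].condition_of)).rho, 0.0, st)
```

Output (printed from the run above):

```
high peak accuracy 71.7% at 170 ms (bootstrap 95% CI 160-200 ms)
high-low difference cluster(s): [(160.0, 220.0)]
dispersion-model rho cluster(s): [(160.0, 230.0)]
categorical-model rho cluster(s): []
```

Reading: within-high decoding peaks at 170 ms; the high−low difference is
significant from 160 to 220 ms, recovering the injected 149–228 ms effect
window (onset resolution is one 10 ms sample); the dispersion geometry —
but not the categorical one — explains the measured RDMs inside that
window, reproducing the qualitative contrast the pipeline is designed to
detect.

The same analyses run from the shell:

```bash
memdecode simulate --config synth.yaml --out cohort/
memdecode preprocess --in cohort/sub-01.h5 --out clean/sub-01.h5
memdecode decode --in clean/sub-01.h5 --out rdm/sub-01.csv
memdecode rsa --rdm rdm/*.csv --model dispersion --out rho.csv
memdecode run --config pipeline.yaml      # full pipeline + report
```

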