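"""End-to-end orchestration: simulate -> preprocess -> decode -> RSA ->
temporal generalization -> statistics -> report.

``run_pipeline`` executes the requested analyses on a synthetic cohort and
writes a deterministic directory of epochs containers, RDM tables,
time-course tables, cluster JSONs, MDS coordinates, figures and a
machine-readable ``summary.json``; every output records the seed and
parameters that produced it.  Seeds are derived hierarchically
(global -> subject -> repetition -> permutation) so any stage can be re-run
in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import decode, preprocess, rsa, stats, synth
from .containers import ValidationError
from .io import write_epochs, write_json, write_rdm_series, write_timecourse_table

DEFAULT_ANALYSES = ("rdm", "condition_means", "rsa_categorical", "rsa_dispersion")
KNOWN_ANALYSES = DEFAULT_ANALYSES + ("tempgen",)   # plus "roi:<group>"


@dataclass
class PipelineConfig:
    synth: synth.SynthConfig = field(default_factory=synth.SynthConfig.desk_scale)
    preproc: preprocess.PreprocParams = field(default_factory=preprocess.PreprocParams)
    decode: decode.DecodeParams = field(default_factory=decode.DecodeParams)
    stats: stats.StatParams = field(default_factory=stats.StatParams)
    analyses: tuple = DEFAULT_ANALYSES
    out_dir: str = "memdecode_out"
    seed: int = 0
    run_preprocess: bool = True
    make_figures: bool = False

    def validate(self) -> "PipelineConfig":
        self.synth.validate()
        self.decode.validate()
        self.stats.validate()
        for a in self.analyses:
            if a not in KNOWN_ANALYSES and not a.startswith("roi:"):
                raise ValidationError(f"unknown analysis {a!r}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        for key, factory in (("synth", synth.SynthConfig),
                             ("preproc", preprocess.PreprocParams),
                             ("decode", decode.DecodeParams),
                             ("stats", stats.StatParams)):
            if key in raw:
                section = dict(raw.pop(key))
                for name in ("baseline",):
                    if name in section and isinstance(section[name], list):
                        section[name] = tuple(section[name])
                kw[key] = factory(**section)
        if "analyses" in raw:
            raw["analyses"] = tuple(raw["analyses"])
        kw.update(raw)
        return cls(**kw).validate()

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["analyses"] = list(self.analyses)
        return d


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0])


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all requested analyses; return the summary dict (also on disk)."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "config": config.to_dict(), "analyses": {}}

    root = np.random.SeedSequence(config.seed)
    ss_synth, ss_decode, ss_stats = root.spawn(3)

    # -- simulate ------------------------------------------------------------
    cohort_cfg = config.synth.replace(seed=_seed_int(ss_synth) % (2 ** 31))
    subjects, truth = synth.simulate_cohort(cohort_cfg)
    write_json(truth.to_dict(), out / "ground_truth.json")
    epoch_dir = out / "epochs"
    epoch_dir.mkdir(exist_ok=True)
    for ep in subjects:
        write_epochs(ep, epoch_dir / f"{ep.subject_id}.h5", overwrite=True)

    # -- preprocess ----------------------------------------------------------
    if config.run_preprocess:
        cleaned = []
        reports = {}
        for ep in subjects:
            clean, rep = preprocess.preprocess_chain(ep, config.preproc)
            cleaned.append(clean)
            reports[ep.subject_id] = rep
        subjects = cleaned
        write_json(reports, out / "preprocess_report.json")

    condition_of = subjects[0].condition_of()
    times = subjects[0].times
    st = config.stats
    stat_rng = np.random.default_rng(ss_stats)

    def _cluster_summary(result, times):
        return {
            "cluster_extents_ms": result.extents_ms(times),
            "cluster_sizes": result.sizes.tolist(),
            "p_values": result.p_values.tolist(),
            "significant_extents_ms": [
                e for e, p in zip(result.extents_ms(times), result.p_values)
                if p <= result.params["alpha"]],
            "params": result.params,
        }

    # -- decode (sensors and any requested ROI channel sets) ------------------
    decode_sets = [("sensors", None)]
    decode_sets += [(a, a.split(":", 1)[1]) for a in config.analyses if a.startswith("roi:")]
    rdm_needed = any(a in config.analyses for a in
                     ("rdm", "condition_means", "rsa_categorical", "rsa_dispersion")) \
        or any(a.startswith("roi:") for a in config.analyses)

    rdms_by_set: dict[str, list] = {}
    if rdm_needed:
        subj_seeds = ss_decode.spawn(len(subjects))
        for label, group in decode_sets:
            if label != "sensors" and label not in config.analyses:
                continue
            dparams = dataclasses.replace(config.decode, channel_group=group)
            rdm_dir = out / ("rdm" if label == "sensors" else f"rdm_{group}")
            rdm_dir.mkdir(exist_ok=True)
            rdms = []
            for ep, ss in zip(subjects, subj_seeds):
                p = dataclasses.replace(dparams, seed=_seed_int(ss) % (2 ** 31))
                rdm = decode.build_rdm_series(ep, p)
                write_rdm_series(rdm, rdm_dir / f"{ep.subject_id}.csv")
                rdms.append(rdm)
            rdms_by_set[label] = rdms

    # -- condition means + difference cluster test + peak latency -------------
    for label, rdms in rdms_by_set.items():
        if label == "sensors" and "condition_means" not in config.analyses:
            continue
        courses = [decode.condition_mean_timecourses(r) for r in rdms]
        tc_path = out / (f"timecourses_{label}.csv")
        write_timecourse_table(
            [c[tag] for c in courses for tag in ("high", "low", "difference")],
            tc_path, meta={"seed": config.seed, "channel_set": label})
        entry: dict = {}
        for tag, chance, tail in (("high", 50.0, "greater"),
                                  ("low", 50.0, "greater"),
                                  ("difference", 0.0, "greater")):
            mat = np.stack([c[tag].accuracy for c in courses])
            res = stats.cluster_test_1d(mat, chance,
                                        dataclasses.replace(st, tail=tail),
                                        rng=stat_rng)
            entry[tag] = _cluster_summary(res, times)
            if tag in ("high", "low"):
                peak, lo, hi, _ = stats.bootstrap_peak_latency(mat, times, st, rng=stat_rng)
                entry[tag]["peak_latency_ms"] = {"peak": peak, "ci": [lo, hi]}
        key = "condition_means" if label == "sensors" else label
        summary["analyses"][key] = entry
        write_json(entry, out / f"clusters_{label}.json")

    # -- RSA -----------------------------------------------------------------
    rsa_models = []
    if "rsa_categorical" in config.analyses:
        rsa_models.append(rsa.categorical_model(condition_of))
    if "rsa_dispersion" in config.analyses:
        rsa_models.append(rsa.dispersion_model(condition_of))
    for model in rsa_models:
        group = rsa.cohort_rsa(rdms_by_set["sensors"], model)
        res = stats.cluster_test_1d(group.rho, 0.0,
                                    dataclasses.replace(st, tail="greater"),
                                    rng=stat_rng)
        entry = _cluster_summary(res, times)
        entry["mean_rho"] = group.rho.mean(axis=0).tolist()
        entry["n_zero_variance"] = group.n_zero_variance
        summary["analyses"][f"rsa_{model.name}"] = entry
        write_json(entry, out / f"rsa_{model.name}.json")
        np.savetxt(out / f"rho_{model.name}.csv",
                   np.column_stack([times, group.rho.T]), delimiter=",",
                   header="time_ms," + ",".join(r.subject_id for r in rdms_by_set["sensors"]),
                   comments="")

    # -- MDS of the grand-average RDM inside the effect window ----------------
    if rdms_by_set.get("sensors"):
        win = (times >= config.synth.t_on) & (times <= config.synth.t_off)
        grand = np.mean([r.values for r in rdms_by_set["sensors"]], axis=0)
        coords = rsa.mds_embed(grand[win].mean(axis=0))
        np.savetxt(out / "mds_window.csv", coords, delimiter=",",
                   header="dim1,dim2", comments="")
        summary["analyses"]["mds"] = {"window_ms": [config.synth.t_on, config.synth.t_off]}

    # -- temporal generalization ----------------------------------------------
    if "tempgen" in config.analyses:
        tg_seeds = ss_decode.spawn(len(subjects) + 1000)[len(subjects):]
        mats = []
        for ep, ss in zip(subjects, tg_seeds):
            mats.extend(decode.subject_tempgen(ep, config.decode, seed=ss))
        entry = {}
        for cond in ("high", "low"):
            per_subj = {}
            for m in mats:
                a, b = m.image_pair
                if condition_of[int(a)] == cond and condition_of[int(b)] == cond:
                    per_subj.setdefault(m.subject_id, []).append(m.accuracy)
            stackmat = np.stack([np.mean(v, axis=0) for v in per_subj.values()])
            res = stats.cluster_test_2d(stackmat, 50.0,
                                        dataclasses.replace(st, tail="greater"),
                                        rng=stat_rng)
            np.savetxt(out / f"tempgen_{cond}.csv", stackmat.mean(axis=0),
                       delimiter=",")
            entry[cond] = {
                "n_significant_clusters": int(res.n_significant),
                "significant_fraction": float(res.significant.mean()),
                "cluster_sizes": res.sizes.tolist(),
                "p_values": res.p_values.tolist(),
                "params": res.params,
            }
        summary["analyses"]["tempgen"] = entry
        write_json(entry, out / "tempgen_clusters.json")

    if config.make_figures:
        _make_figures(summary, rdms_by_set, times, out)

    write_json(summary, out / "summary.json")
    (out / "report.md").write_text(make_report(summary))
    return summary


def _make_figures(summary, rdms_by_set, times, out: Path) -> None:  # pragma: no cover
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if "condition_means" in summary["analyses"] and rdms_by_set.get("sensors"):
        fig, ax = plt.subplots()
        courses = [decode.condition_mean_timecourses(r) for r in rdms_by_set["sensors"]]
        for tag, color in (("high", "tab:red"), ("low", "tab:blue")):
            mean = np.mean([c[tag].accuracy for c in courses], axis=0)
            ax.plot(times, mean, color=color, label=tag)
        ax.axhline(50, color="gray", lw=0.5)
        ax.set(xlabel="time (ms)", ylabel="pairwise decoding (%)")
        ax.legend()
        fig.savefig(out / "condition_means.png", dpi=120)
        plt.close(fig)


def make_report(summary: dict) -> str:
    """Render the machine-readable summary as a short Markdown report."""
    lines = ["# memdecode pipeline report", "",
             f"seed: {summary.get('seed')}", ""]
    requested = summary.get("config", {}).get("analyses", [])
    analyses = summary.get("analyses", {})
    for name in requested:
        key = {"rsa_categorical": "rsa_categorical",
               "rsa_dispersion": "rsa_dispersion"}.get(name, name)
        if name == "rdm":
            lines += ["## rdm", "", "Per-subject RDM tables written under rdm/.", ""]
            continue
        entry = analyses.get(key)
        if entry is None:
            lines += [f"## {name}", "", "skipped (no outputs)", ""]
            continue
        lines += [f"## {name}", ""]
        for tag, val in entry.items():
            if isinstance(val, dict) and "significant_extents_ms" in val:
                ext = val["significant_extents_ms"]
                desc = ", ".join(f"{a:.0f}-{b:.0f} ms" for a, b in ext) or "none"
                lines.append(f"- {tag}: significant clusters: {desc}")
                if "peak_latency_ms" in val:
                    pk = val["peak_latency_ms"]
                    lines.append(
                        f"  peak latency {pk['peak']:.0f} ms "
                        f"(CI {pk['ci'][0]:.0f}-{pk['ci'][1]:.0f} ms)")
            elif tag == "significant_extents_ms":
                desc = ", ".join(f"{a:.0f}-{b:.0f} ms" for a, b in val) or "none"
                lines.append(f"- significant clusters: {desc}")
            elif tag in ("n_zero_variance",):
                lines.append(f"- flat-RDM time points: {val}")
            elif isinstance(val, dict) and "n_significant_clusters" in val:
                lines.append(f"- {tag}: {val['n_significant_clusters']} significant "
                             f"cluster(s), {100 * val['significant_fraction']:.1f}% "
                             "of the matrix significant")
        lines.append("")
    return "\n".join(lines)
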