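"""End-to-end orchestration: simulate -> decompose -> cluster-test -> correlate.

Stages communicate through files in the run directory so the expensive
permutation stage can be re-run with different correction parameters without
re-simulating.  Every output records the seed and a hash of the full
configuration; a run is deterministic given its seed.

Layout of a run directory::

    run/
      provenance.json          seed, config hash, package versions
      config.json              the fully-resolved RunConfig
      behavior/<subject>.tsv   behavioral logs (one row per trial)
      behavior_summary.tsv     per-block and pooled behavioral measures
      clinical.tsv             per-subject clinical table
      epochs/<roi>_<lock>.npz  epoch sets (+ .meta.tsv sidecars)
      tf/<roi>_<lock>.npz      dB time-frequency arrays
      cluster/<roi>_<lock>/    t/diff/mask CSVs, cluster table, run metadata
      correlations.tsv         age-adjusted EEG-clinical correlations (+ FDR)
      report.txt               human-readable summary
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cluster as cl
from . import spectral as sp
from . import synth as sy
from . import task as tk
from .clinical import behavior_clinical_corr, correlate_eeg_clinical, fdr_adjust

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "RunConfig", "run_pipeline", "validate_suite",
           "stage_simulate", "stage_decompose", "stage_cluster", "stage_correlate"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Time-frequency and statistics parameters."""

    fmin: float = 3.0
    fmax: float = 50.0
    df: float = 0.5
    cycles: tuple[float, float] = (3.0, 10.0)
    decim: int = 5
    n_perm: int = 1000
    pixel_alpha: float = 0.05
    alpha: float = 0.05
    n_rois: int = 3
    locks: tuple[str, ...] = (sy.MOTION_ONSET,)
    stats_window_motion: tuple[float, float] = (0.0, 300.0)
    stats_window_stop: tuple[float, float] = (0.0, 500.0)

    def stats_window(self, lock: str) -> tuple[float, float]:
        return (self.stats_window_motion if lock == sy.MOTION_ONSET
                else self.stats_window_stop)


def _default_effects() -> tuple[sy.ERSPEffect, ...]:
    # gamma ERD around motion onset in both groups, deeper in the CTD group
    shared = sy.ERSPEffect("RSFG", (30.0, 50.0), (-100.0, 300.0), -2.5,
                           lock=sy.MOTION_ONSET, group="both")
    extra = sy.ERSPEffect("RSFG", (30.0, 50.0), (-100.0, 300.0), -2.5,
                          lock=sy.MOTION_ONSET, group="CTD")
    return (shared, extra)


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a pipeline run."""

    seed: int = 0
    n_ctd: int = 8
    n_hc: int = 7
    task: tk.TaskConfig = field(default_factory=tk.TaskConfig)
    subject_ctd: tk.SubjectModel = field(default_factory=tk.SubjectModel)
    subject_hc: tk.SubjectModel = field(
        default_factory=lambda: tk.SubjectModel(go_mu=793.0))
    eeg: sy.EEGGenConfig = field(
        default_factory=lambda: sy.EEGGenConfig(rois=("RSFG",),
                                                effects=_default_effects()))
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    linkage: sy.LinkageSpec | None = field(
        default_factory=lambda: sy.LinkageSpec(effect_index=1,
                                               target_partial_r=0.66,
                                               delta_sd=1.5))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "task" in d:
            d["task"] = tk.TaskConfig(**_tupled(d["task"], ("go_window",)))
        for key in ("subject_ctd", "subject_hc"):
            if key in d:
                d[key] = tk.SubjectModel(**d[key])
        if "eeg" in d:
            e = dict(d["eeg"])
            e["oscillators"] = tuple(sy.Oscillator(**o) for o in e.get("oscillators", []))
            e["effects"] = tuple(
                sy.ERSPEffect(**_tupled(f, ("band", "window"))) for f in e.get("effects", []))
            d["eeg"] = sy.EEGGenConfig(**_tupled(
                e, ("rois", "epoch_span_motion", "epoch_span_stop")))
        if "analysis" in d:
            d["analysis"] = AnalysisConfig(**_tupled(
                d["analysis"],
                ("cycles", "locks", "stats_window_motion", "stats_window_stop")))
        if d.get("linkage") is not None:
            d["linkage"] = sy.LinkageSpec(**d["linkage"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls.from_dict(data)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _tupled(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and d[k] is not None and not isinstance(d[k], (int, float, str)):
            d[k] = tuple(tuple(v) if isinstance(v, list) else v for v in d[k]) \
                if any(isinstance(v, list) for v in d[k]) else tuple(d[k])
    return d


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _provenance(cfg: RunConfig) -> dict:
    import scipy
    return {"seed": cfg.seed, "config_hash": cfg.config_hash(),
            "numpy": np.__version__, "scipy": scipy.__version__,
            "pandas": pd.__version__}


def stage_simulate(cfg: RunConfig, outdir: Path) -> sy.Cohort:
    """Simulate the cohort and write behavioral, clinical and epoch files."""
    t0 = time.time()
    outdir = Path(outdir)
    (outdir / "behavior").mkdir(parents=True, exist_ok=True)
    (outdir / "epochs").mkdir(exist_ok=True)
    cohort = sy.build_cohort(
        cfg.n_ctd, cfg.n_hc, cfg.eeg, cfg.task, cfg.subject_ctd, cfg.subject_hc,
        seed=cfg.seed, linkage=cfg.linkage, locks=cfg.analysis.locks)
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    for subject, trials in cohort.trials.items():
        tk.write_behavior_tsv(trials, outdir / "behavior" / f"{subject}.tsv",
                              metadata={**meta, "subject": subject})
    cohort.clinical.to_csv(outdir / "clinical.tsv", sep="\t", index=False)
    cohort.behavior.to_csv(outdir / "behavior_summary.tsv", sep="\t", index=False)
    for (roi, lock), es in cohort.epochs.items():
        es.save(outdir / "epochs" / f"{roi}_{lock}.npz")
        logger.info("simulate: %s %s -> %d epochs", roi, lock, es.n_trials)
    logger.info("simulate stage done in %.1f s", time.time() - t0)
    return cohort


def _save_tf(tf: sp.TFArray, path: Path) -> None:
    np.savez(path, power=tf.power, freqs=tf.freqs, times=tf.times,
             edge_valid=tf.edge_valid, units=tf.units,
             lock_event=tf.lock_event,
             baseline=tf.baseline if tf.baseline is not None else np.zeros(0))
    tf.meta.to_csv(str(path) + ".meta.tsv", sep="\t", index=False)


def _load_tf(path: Path) -> sp.TFArray:
    npz = np.load(path)
    meta = pd.read_csv(str(path) + ".meta.tsv", sep="\t")
    base = npz["baseline"]
    return sp.TFArray(power=npz["power"], freqs=npz["freqs"], times=npz["times"],
                      edge_valid=npz["edge_valid"], meta=meta,
                      lock_event=str(npz["lock_event"]), units=str(npz["units"]),
                      baseline=base if base.size else None)


def stage_decompose(cfg: RunConfig, outdir: Path) -> dict:
    """Wavelet decomposition + dB normalization of every saved epoch set."""
    t0 = time.time()
    outdir = Path(outdir)
    (outdir / "tf").mkdir(exist_ok=True)
    a = cfg.analysis
    family = sp.build_wavelets(a.fmin, a.fmax, a.df, cfg.eeg.fs, cycles=a.cycles)
    tfs = {}
    for path in sorted((outdir / "epochs").glob("*.npz")):
        es = sy.EpochSet.load(path.with_suffix(""))
        tf = sp.tf_power(es, family, decim=a.decim)
        base = sp.baseline_power(es, family)
        tf_db = sp.db_normalize(tf, base)
        key = (es.roi, es.lock_event)
        tfs[key] = tf_db
        _save_tf(tf_db, outdir / "tf" / path.name)
        logger.info("decompose: %s %s -> %s", es.roi, es.lock_event,
                    tf_db.power.shape)
    logger.info("decompose stage done in %.1f s", time.time() - t0)
    return tfs


def stage_cluster(cfg: RunConfig, outdir: Path, tfs: dict | None = None) -> dict:
    """Permutation cluster test per (ROI, lock event)."""
    t0 = time.time()
    outdir = Path(outdir)
    a = cfg.analysis
    if tfs is None:
        tfs = {}
        for path in sorted((outdir / "tf").glob("*.npz")):
            tf = _load_tf(path)
            roi = path.stem.split("_")[0]
            tfs[(roi, tf.lock_event)] = tf
    results = {}
    for (roi, lock), tf in tfs.items():
        w = a.stats_window(lock)
        tf.require_valid(*w)
        tfc = tf.crop(*w)
        master = cl.MasterArray.from_tf(tfc, groups=("CTD", "HC"))
        res = cl.cluster_permutation_test(
            master, n_perm=a.n_perm, seed=cfg.seed, pixel_alpha=a.pixel_alpha,
            n_rois=a.n_rois, alpha=a.alpha)
        res.export(outdir / "cluster" / f"{roi}_{lock}", seed=cfg.seed)
        results[(roi, lock)] = res
        logger.info("cluster: %s %s -> %d clusters, %d significant",
                    roi, lock, len(res.masses), res.n_significant)
    logger.info("cluster stage done in %.1f s", time.time() - t0)
    return results


def stage_correlate(
    cfg: RunConfig, outdir: Path,
    tfs: dict | None = None, results: dict | None = None,
) -> pd.DataFrame | None:
    """Cluster-masked power extraction + age-adjusted clinical correlations.

    Runs only for (ROI, lock) analyses with at least one significant
    cluster; returns None (and notes it in the report) when there is none.
    """
    outdir = Path(outdir)
    clinical = pd.read_csv(outdir / "clinical.tsv", sep="\t")
    behavior = pd.read_csv(outdir / "behavior_summary.tsv", sep="\t")
    if tfs is None:
        tfs = {}
        for path in sorted((outdir / "tf").glob("*.npz")):
            tf = _load_tf(path)
            tfs[(path.stem.split("_")[0], tf.lock_event)] = tf
    if results is None:
        masks = {}
        for key in tfs:
            cdir = outdir / "cluster" / f"{key[0]}_{key[1]}"
            if (cdir / "significant_mask.csv").exists():
                masks[key] = np.loadtxt(cdir / "significant_mask.csv",
                                        delimiter=",", ndmin=2).astype(bool)
    else:
        masks = {k: r.significant_mask for k, r in results.items()}
    rows = []
    for (roi, lock), mask in masks.items():
        if not mask.any():
            continue
        tf = tfs[(roi, lock)].crop(*cfg.analysis.stats_window(lock))
        ctd_subjects = clinical.loc[clinical.diagnosis == "CTD", "subject"]
        maps, ids = [], []
        for s in ctd_subjects:
            sel = (tf.meta["subject"] == s).to_numpy()
            if sel.any():
                maps.append(sp.ersp_map(tf, sel))
                ids.append(s)
        extracted = pd.Series(
            cl.extract_masked_power(np.stack(maps), mask),
            index=ids, name="cluster_db")
        for c in correlate_eeg_clinical(extracted, clinical):
            rows.append({"roi": roi, "lock": lock, "pair": c.pair, "n": c.n,
                         "r": c.r, "p": c.p, "p_fdr": c.p_fdr})
    ssrt = (behavior[behavior.block_label == "overall"]
            .set_index("subject")["ssrt"])
    try:
        b = behavior_clinical_corr(ssrt, clinical)
        rows.append({"roi": "", "lock": "behavior", "pair": b.pair, "n": b.n,
                     "r": b.r, "p": b.p, "p_fdr": np.nan})
    except ValueError as exc:
        logger.info("behavioral correlation skipped: %s", exc)
    if not rows:
        return None
    out = pd.DataFrame(rows)
    out.to_csv(outdir / "correlations.tsv", sep="\t", index=False)
    return out


def run_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run all stages and write a report bundle; returns a summary dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2, default=str))
    (outdir / "provenance.json").write_text(
        json.dumps(_provenance(cfg), indent=2))
    cohort = stage_simulate(cfg, outdir)
    tfs = stage_decompose(cfg, outdir)
    results = stage_cluster(cfg, outdir, tfs)
    corr = stage_correlate(cfg, outdir, tfs, results)

    lines = [f"seed {cfg.seed}  config {cfg.config_hash()}"]
    overall = cohort.behavior[cohort.behavior.block_label == "overall"]
    lines.append(f"subjects: {cfg.n_ctd} CTD + {cfg.n_hc} HC; "
                 f"mean P(inhibit) {overall.p_inhibit.mean():.3f}; "
                 f"mean SSRT {overall.ssrt.mean():.1f} ms")
    any_sig = False
    for (roi, lock), res in results.items():
        lines.append(f"{roi} {lock}: {len(res.masses)} clusters, "
                     f"{res.n_significant} significant "
                     f"(mass threshold {res.mass_threshold:.1f} at "
                     f"{res.percentile} pct)")
        any_sig |= res.n_significant > 0
    if not any_sig:
        lines.append("no significant clusters; correlation stage skipped")
    elif corr is not None:
        for _, r in corr.iterrows():
            lines.append(f"corr {r['pair']} ({r['roi']} {r['lock']}): "
                         f"r={r['r']:.2f} p={r['p']:.3f} p_fdr={r['p_fdr']}")
    report = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(report)
    logger.info("pipeline report:\n%s", report)
    return {"cohort": cohort, "tfs": tfs, "cluster": results,
            "correlations": corr, "report": report}


# ---------------------------------------------------------------------------
# validation suite (reduced-scale calibration checks)
# ---------------------------------------------------------------------------

def _null_master(rng, shape=(30, 50), n_per_group=40) -> cl.MasterArray:
    f, t = shape
    n = 2 * n_per_group
    power = rng.standard_normal((f, t, n))
    labels = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    return cl.MasterArray(power, labels, np.arange(f, dtype=float),
                          np.arange(t, dtype=float), groups=("A", "B"))


def type1_error_rate(
    n_datasets: int = 500,
    n_perm: int = 500,
    shape=(30, 50),
    n_per_group: int = 40,
    n_rois: int = 3,
    seed: int = 0,
) -> float:
    """Monte-Carlo familywise false-positive rate of the cluster test on
    exchangeable null data (nominal alpha/n_rois per analysis)."""
    hits = 0
    for d in range(n_datasets):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 909, d]))
        master = _null_master(rng, shape, n_per_group)
        res = cl.cluster_permutation_test(
            master, n_perm=n_perm, seed=int(seed) + d, n_rois=n_rois)
        hits += res.n_significant > 0
    return hits / n_datasets


def staircase_p_inhibit(n_sessions: int = 200, seed: int = 1,
                        subject: tk.SubjectModel | None = None) -> float:
    """Grand-mean probability of stop success over simulated sessions."""
    subject = subject or tk.SubjectModel()
    cfg = tk.TaskConfig()
    vals = []
    for s in range(n_sessions):
        trials = tk.run_session(cfg, subject, seed=int(seed) + s,
                                include_practice=False)
        vals.append(tk.summarize_behavior(trials).overall["p_inhibit"])
    return float(np.mean(vals))


def ssrt_recovery(n_sessions: int = 200, seed: int = 1,
                  subject: tk.SubjectModel | None = None) -> float:
    """Mean means-method SSRT over simulated sessions."""
    subject = subject or tk.SubjectModel()
    cfg = tk.TaskConfig()
    vals = []
    for s in range(n_sessions):
        trials = tk.run_session(cfg, subject, seed=int(seed) + s,
                                include_practice=False)
        vals.append(tk.summarize_behavior(trials).overall["ssrt"])
    return float(np.mean(vals))


def effect_mass_curve(deltas=(0.0, -3.0, -6.0, -10.0), seed: int = 0,
                      shape=(30, 50), n_per_group: int = 40,
                      region=(slice(5, 15), slice(10, 30))) -> list[float]:
    """Largest observed cluster mass vs injected group offset (array-level
    injection, fixed noise seed): power should grow with |delta|."""
    masses = []
    for delta in deltas:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 111]))
        master = _null_master(rng, shape, n_per_group)
        master.power[region[0], region[1], :n_per_group] += delta
        _, tmap = cl.observed_stats(master)
        thr = cl.pixel_t_threshold(n_per_group, n_per_group)
        labels, n = cl.find_clusters(np.abs(tmap) > thr)
        m = cl.cluster_masses(labels, tmap, n)
        masses.append(float(m.max()) if n else 0.0)
    return masses


def delta_recovery(delta_db: float = -10.0, n_trials: int = 100,
                   seed: int = 0) -> float:
    """Generate trials with a known gamma-band effect and recover its size
    with the leakage-corrected estimator (group-difference route)."""
    eff = sy.ERSPEffect("RSFG", (30.0, 50.0), (0.0, 300.0), delta_db,
                        group="A")
    cfg = sy.EEGGenConfig(rois=("RSFG",), oscillators=(), effects=(eff,))
    family = sp.build_wavelets(fs=cfg.fs)
    ep_a = sy.synthesize_epochs(cfg, n_trials, group="A", seed=int(seed))
    ep_b = sy.synthesize_epochs(cfg, n_trials, group="B", seed=int(seed) + 1)
    tf_a = sp.tf_power(ep_a, family, decim=5)
    tf_b = sp.tf_power(ep_b, family, decim=5)
    return sp.recover_effect_db(tf_a, family, eff.band, eff.window,
                                tf_b=tf_b,
                                psd=lambda f: sy.model_psd(cfg, f))


def validate_suite(
    seed: int = 0,
    n_type1_datasets: int = 100,
    n_perm: int = 200,
    n_sessions: int = 200,
    n_recovery_trials: int = 100,
    outpath=None,
) -> dict:
    """Reduced-scale calibration report: type-I rate, power monotonicity,
    staircase equilibrium, SSRT recovery and injected-effect recovery, each
    with a pass flag at its stated tolerance."""
    report = {}
    p = staircase_p_inhibit(n_sessions, seed=seed + 1)
    report["staircase_p_inhibit"] = {"value": p, "band": [0.47, 0.53],
                                     "pass": 0.47 <= p <= 0.53}
    s = ssrt_recovery(n_sessions, seed=seed + 1)
    report["ssrt_recovery_ms"] = {"value": s, "band": [235.0, 265.0],
                                  "pass": 235.0 <= s <= 265.0}
    t1 = type1_error_rate(n_type1_datasets, n_perm, seed=seed)
    report["type1_familywise_rate"] = {"value": t1, "band": [0.007, 0.027],
                                       "pass": 0.007 <= t1 <= 0.027}
    curve = effect_mass_curve(seed=seed)
    mono = all(b >= a for a, b in zip(curve, curve[1:]))
    report["power_mass_curve"] = {"value": curve, "pass": mono}
    rec = delta_recovery(-10.0, n_recovery_trials, seed=seed)
    report["delta_db_recovery"] = {"value": rec, "target": -10.0,
                                   "pass": abs(rec + 10.0) <= 1.0}
    report["all_pass"] = all(v["pass"] for v in report.values()
                             if isinstance(v, dict))
    if outpath is not None:
        Path(outpath).write_text(json.dumps(report, indent=2))
    return report
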