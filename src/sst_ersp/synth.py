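"""Synthetic ROI source time series with controlled oscillatory effects.

Generates what the recording/pre-processing/source-modeling chain of a real
experiment would deliver: clean single-trial current-source-density traces for
the three right-frontal regions of interest (RSFG, RMFG, RIFG) at 1000 Hz,
composed of 1/f-like Gaussian background activity, optional band-limited
oscillators, and injected event-locked ERD/ERS effects of known size.

An :class:`ERSPEffect` multiplies the amplitude envelope of its frequency band
by ``10**(delta_db/20)`` inside its time window (so wavelet *power* changes by
``delta_db``), with cosine on/off ramps placed outside the nominal window so
the in-window gain is exact.  Because the gain is applied to the band-passed
component of the composite signal, the injected dB change is exact in
expectation regardless of the background spectrum.

The module also generates clinical score tables and cohorts in which a chosen
effect size is drawn per subject with a prescribed age-adjusted correlation to
a clinical scale, enabling recovery tests of the power-vs-severity analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .task import (
    GO,
    STOP,
    SubjectModel,
    TaskConfig,
    TrialRecord,
    run_session,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Oscillator",
    "ERSPEffect",
    "EEGGenConfig",
    "EpochSet",
    "ContinuousSession",
    "simulate_session_eeg",
    "synthesize_trial",
    "make_epochs",
    "synthesize_epochs",
    "model_psd",
    "generate_clinical_table",
    "draw_linked_clinical",
    "build_cohort",
    "Cohort",
    "LinkageSpec",
]

MOTION_ONSET = "motion_onset"
STOP_SIGNAL = "stop_signal"

#: minimum frequency for the 1/f amplitude law (avoids the DC singularity)
_F_CLAMP = 1.0


@dataclass(frozen=True)
class Oscillator:
    """Band-limited background oscillation (e.g. an alpha bump)."""

    center: float  # Hz
    bandwidth: float  # Hz (full width)
    amplitude: float  # RMS, source units


@dataclass(frozen=True)
class ERSPEffect:
    """Band-limited power change locked to a task event.

    ``delta_db`` is the power change in dB (negative = ERD).  ``window`` is in
    ms relative to ``lock`` (motion_onset or stop_signal).  ``group`` limits
    the effect to one cohort group ("A"/"B" or a diagnosis label) or "both".
    """

    roi: str
    band: tuple[float, float]  # Hz
    window: tuple[float, float]  # ms relative to lock event
    delta_db: float
    lock: str = MOTION_ONSET
    group: str = "both"
    ramp_ms: float = 50.0

    def __post_init__(self) -> None:
        f1, f2 = self.band
        if not (0 < f1 < f2):
            raise ValueError("band must satisfy 0 < f1 < f2")
        if not np.isfinite(self.delta_db):
            raise ValueError("delta_db must be finite")
        if self.lock not in (MOTION_ONSET, STOP_SIGNAL):
            raise ValueError(f"unknown lock event {self.lock!r}")

    def applies_to(self, group: str) -> bool:
        return self.group in ("both", group)


@dataclass(frozen=True)
class EEGGenConfig:
    """Parameters of the ROI source-signal generator."""

    fs: float = 1000.0
    rois: tuple[str, ...] = ("RSFG", "RMFG", "RIFG")
    background_exponent: float = 1.0  # power ~ 1/f**chi
    background_rms: float = 1.0
    oscillators: tuple[Oscillator, ...] = (Oscillator(10.0, 4.0, 0.5),)
    effects: tuple[ERSPEffect, ...] = ()
    epoch_span_motion: tuple[float, float] = (-500.0, 1000.0)
    epoch_span_stop: tuple[float, float] = (-500.0, 800.0)
    baseline_ms: float = 200.0
    baseline_pad_ms: float = 500.0
    post_motion_pad_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.fs <= 100:
            raise ValueError("fs too low for 3-50 Hz analysis")
        for eff in self.effects:
            if eff.band[1] >= self.fs / 2:
                raise ValueError("effect band exceeds Nyquist")


@dataclass
class EpochSet:
    """Per-ROI trials x time matrix cut around a lock event.

    ``baseline`` holds the last ``baseline_ms`` of the fixation screen of the
    same trials; ``baseline_padded`` the same segment with ``baseline_pad_ms``
    of surrounding context on each side, so that wavelet power estimated on
    the central segment is free of convolution edge artifacts.
    """

    roi: str
    data: np.ndarray  # (n_trials, n_samples)
    times: np.ndarray  # ms relative to lock event
    lock_event: str
    fs: float
    baseline: np.ndarray  # (n_trials, n_baseline_samples)
    baseline_padded: np.ndarray
    baseline_pad_ms: float
    meta: pd.DataFrame  # one row per trial, aligned with data rows

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.meta):
            raise ValueError("metadata rows must align with data rows")
        dt = np.diff(self.times)
        if len(dt) and not np.allclose(dt, 1000.0 / self.fs):
            raise ValueError("time axis must be uniform at 1/fs")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def subset(self, idx) -> "EpochSet":
        """Row subset/permutation; data and metadata move together."""
        idx = np.asarray(idx)
        return EpochSet(
            roi=self.roi,
            data=self.data[idx],
            times=self.times,
            lock_event=self.lock_event,
            fs=self.fs,
            baseline=self.baseline[idx],
            baseline_padded=self.baseline_padded[idx],
            baseline_pad_ms=self.baseline_pad_ms,
            meta=self.meta.iloc[idx].reset_index(drop=True),
        )

    def save(self, path) -> None:
        """Array container (.npz) + TSV metadata sidecar."""
        path = str(path)
        if path.endswith(".npz"):
            path = path[:-4]
        np.savez(
            path + ".npz",
            data=self.data,
            times=self.times,
            baseline=self.baseline,
            baseline_padded=self.baseline_padded,
            fs=self.fs,
            baseline_pad_ms=self.baseline_pad_ms,
            roi=self.roi,
            lock_event=self.lock_event,
        )
        self.meta.to_csv(path + ".meta.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "EpochSet":
        path = str(path)
        if path.endswith(".npz"):
            path = path[:-4]
        npz = np.load(path + ".npz")
        meta = pd.read_csv(path + ".meta.tsv", sep="\t")
        return cls(
            roi=str(npz["roi"]),
            data=npz["data"],
            times=npz["times"],
            lock_event=str(npz["lock_event"]),
            fs=float(npz["fs"]),
            baseline=npz["baseline"],
            baseline_padded=npz["baseline_padded"],
            baseline_pad_ms=float(npz["baseline_pad_ms"]),
            meta=meta,
        )


@dataclass
class ContinuousSession:
    """Continuous per-trial traces for one subject (one matrix per ROI)."""

    data: dict[str, np.ndarray]  # roi -> (n_trials, n_samples)
    fs: float
    times: np.ndarray  # ms from trial start
    events: pd.DataFrame  # motion_onset_ms, stop_ms (NaN on go), trial metadata
    cfg: EEGGenConfig
    task_cfg: TaskConfig


# ---------------------------------------------------------------------------
# noise synthesis primitives
# ---------------------------------------------------------------------------

def _filtered_noise(
    rng: np.random.Generator, n: int, fs: float, gain: np.ndarray, rms: float
) -> np.ndarray:
    """Gaussian noise shaped by an amplitude gain over rfft frequencies,
    scaled analytically (not empirically) to the requested RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white) * gain
    x = np.fft.irfft(spec, n=n)
    # expected variance of the filtered unit-white noise (Parseval with
    # Hermitian duplication of the interior rfft bins)
    w = np.full(gain.shape, 2.0)
    w[0] = 1.0
    if n % 2 == 0:
        w[-1] = 1.0
    exp_var = float(np.sum(w * gain**2)) / n
    if exp_var <= 0:
        return np.zeros(n)
    return x * (rms / np.sqrt(exp_var))


def _background_gain(freqs: np.ndarray, exponent: float) -> np.ndarray:
    f_eff = np.maximum(freqs, _F_CLAMP)
    gain = f_eff ** (-exponent / 2.0)
    gain[freqs == 0] = 0.0
    return gain


def _oscillator_gain(freqs: np.ndarray, osc: Oscillator) -> np.ndarray:
    """Raised-cosine band mask (10% transition on each edge)."""
    f1 = osc.center - osc.bandwidth / 2
    f2 = osc.center + osc.bandwidth / 2
    trans = max(0.1 * osc.bandwidth, 0.25)
    gain = np.zeros_like(freqs)
    core = (freqs >= f1) & (freqs <= f2)
    gain[core] = 1.0
    lo = (freqs >= f1 - trans) & (freqs < f1)
    gain[lo] = 0.5 * (1 + np.cos(np.pi * (f1 - freqs[lo]) / trans))
    hi = (freqs > f2) & (freqs <= f2 + trans)
    gain[hi] = 0.5 * (1 + np.cos(np.pi * (freqs[hi] - f2) / trans))
    return gain


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Brick-wall FFT band-pass (exact on the trial's DFT grid)."""
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(len(x), 1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    return np.fft.irfft(spec * mask, n=len(x))


def _gain_profile(
    n: int, fs: float, w0_ms: float, w1_ms: float, delta_db: float, ramp_ms: float
) -> np.ndarray:
    """Amplitude gain over time: 10**(delta/20) inside [w0, w1], cosine ramps
    of ``ramp_ms`` immediately outside, 1 elsewhere."""
    g_full = 10.0 ** (delta_db / 20.0)
    t = np.arange(n) * 1000.0 / fs
    g = np.ones(n)
    inside = (t >= w0_ms) & (t <= w1_ms)
    g[inside] = g_full
    if ramp_ms > 0:
        up = (t >= w0_ms - ramp_ms) & (t < w0_ms)
        frac = (t[up] - (w0_ms - ramp_ms)) / ramp_ms
        g[up] = 1 + (g_full - 1) * 0.5 * (1 - np.cos(np.pi * frac))
        dn = (t > w1_ms) & (t <= w1_ms + ramp_ms)
        frac = (t[dn] - w1_ms) / ramp_ms
        g[dn] = g_full + (1 - g_full) * 0.5 * (1 - np.cos(np.pi * frac))
    return g


def model_psd(cfg: EEGGenConfig, freqs: np.ndarray) -> np.ndarray:
    """Model power spectral density of the *baseline* (no-effect) signal,
    in source-units**2 per Hz up to a common constant.

    Used by the leakage-corrected effect-recovery estimator; relative shape
    and the relative weight of background vs oscillators are what matter.
    """
    freqs = np.asarray(freqs, dtype=float)
    nyq_grid = np.linspace(0, cfg.fs / 2, 4097)
    out = np.zeros_like(freqs)

    def add_component(gain_fn, rms):
        g2_grid = gain_fn(nyq_grid) ** 2
        total = np.trapezoid(g2_grid, nyq_grid)
        if total > 0:
            out[:] += rms**2 * gain_fn(freqs) ** 2 / total

    add_component(lambda f: _background_gain(f, cfg.background_exponent),
                  cfg.background_rms)
    for osc in cfg.oscillators:
        add_component(lambda f, o=osc: _oscillator_gain(f, o), osc.amplitude)
    return out


# ---------------------------------------------------------------------------
# trial synthesis
# ---------------------------------------------------------------------------

def _trial_events(task_cfg: TaskConfig, trial: TrialRecord | None) -> dict:
    motion_onset = task_cfg.fixation_duration + task_cfg.pre_motion_delay
    stop_ms = np.nan
    if trial is not None and trial.trial_type == STOP and trial.ssd is not None:
        stop_ms = motion_onset + trial.ssd
    return {"motion_onset_ms": motion_onset, "stop_ms": stop_ms}


def _synth_one(
    cfg: EEGGenConfig,
    task_cfg: TaskConfig,
    events: dict,
    group: str,
    roi: str,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / cfg.fs)
    x = _filtered_noise(rng, n, cfg.fs,
                        _background_gain(freqs, cfg.background_exponent),
                        cfg.background_rms)
    for osc in cfg.oscillators:
        if osc.amplitude > 0:
            x = x + _filtered_noise(rng, n, cfg.fs, _oscillator_gain(freqs, osc),
                                    osc.amplitude)
    for eff in cfg.effects:
        if eff.roi != roi or not eff.applies_to(group):
            continue
        if eff.lock == STOP_SIGNAL:
            if not np.isfinite(events["stop_ms"]):
                continue
            anchor = events["stop_ms"]
        else:
            anchor = events["motion_onset_ms"]
        w0, w1 = anchor + eff.window[0], anchor + eff.window[1]
        total_ms = n * 1000.0 / cfg.fs
        if w0 - eff.ramp_ms < 0 or w1 + eff.ramp_ms > total_ms:
            raise ValueError(
                f"effect window [{w0}, {w1}] ms (+ramps) outside trial span "
                f"[0, {total_ms}] ms"
            )
        band_part = _bandpass(x, cfg.fs, eff.band)
        g = _gain_profile(n, cfg.fs, w0, w1, eff.delta_db, eff.ramp_ms)
        x = x + (g - 1.0) * band_part
    return x


def _trial_length_samples(cfg: EEGGenConfig, task_cfg: TaskConfig) -> int:
    total_ms = (task_cfg.fixation_duration + task_cfg.pre_motion_delay
                + task_cfg.motion_duration + cfg.post_motion_pad_ms)
    return int(round(total_ms * cfg.fs / 1000.0))


def synthesize_trial(
    cfg: EEGGenConfig,
    trial: TrialRecord | None,
    task_cfg: TaskConfig,
    group: str,
    seed,
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """One continuous trial (fixation through motion end + pad) per ROI.

    Returns ``(times_ms, {roi: signal})``; deterministic for a given seed.
    """
    n = _trial_length_samples(cfg, task_cfg)
    events = _trial_events(task_cfg, trial)
    out = {}
    for r, roi in enumerate(cfg.rois):
        rng = np.random.default_rng(np.random.SeedSequence([*np.atleast_1d(seed).tolist(), r]))
        out[roi] = _synth_one(cfg, task_cfg, events, group, roi, rng, n)
    times = np.arange(n) * 1000.0 / cfg.fs
    return times, out


def simulate_session_eeg(
    cfg: EEGGenConfig,
    task_cfg: TaskConfig,
    trials: Sequence[TrialRecord],
    group: str,
    seed: int,
    subject: str = "S01",
) -> ContinuousSession:
    """Per-trial ROI traces for the main trials of one behavioral session."""
    main = [t for t in trials if t.is_main]
    n = _trial_length_samples(cfg, task_cfg)
    data = {roi: np.empty((len(main), n)) for roi in cfg.rois}
    rows = []
    for i, tr in enumerate(main):
        _, sigs = synthesize_trial(cfg, tr, task_cfg, group, [int(seed), 303, i])
        for roi in cfg.rois:
            data[roi][i] = sigs[roi]
        ev = _trial_events(task_cfg, tr)
        rows.append({
            "subject": subject, "group": group, "block": tr.block,
            "trial": tr.trial, "trial_type": tr.trial_type,
            "ssd": tr.ssd if tr.ssd is not None else np.nan,
            "outcome": tr.outcome, **ev,
        })
    times = np.arange(n) * 1000.0 / cfg.fs
    return ContinuousSession(data=data, fs=cfg.fs, times=times,
                             events=pd.DataFrame(rows), cfg=cfg, task_cfg=task_cfg)


def make_epochs(
    session: ContinuousSession,
    roi: str,
    lock_event: str,
    span: tuple[float, float] | None = None,
) -> EpochSet:
    """Cut epochs around a lock event, attaching each trial's fixation
    baseline (stop-locked sets contain only stop trials; trials without the
    lock event are skipped with a log entry)."""
    cfg = session.cfg
    if span is None:
        span = cfg.epoch_span_motion if lock_event == MOTION_ONSET else cfg.epoch_span_stop
    fs = session.fs
    sig = session.data[roi]
    n_total = sig.shape[1]
    nsp = int(round((span[1] - span[0]) * fs / 1000.0))
    nb = int(round(cfg.baseline_ms * fs / 1000.0))
    npad = int(round(cfg.baseline_pad_ms * fs / 1000.0))
    fix_end = int(round(session.task_cfg.fixation_duration * fs / 1000.0))
    b0, b1 = fix_end - nb, fix_end
    pb0, pb1 = b0 - npad, b1 + npad
    if pb0 < 0 or pb1 > n_total:
        raise ValueError("padded baseline segment outside generated samples")

    rows, dat, base, base_pad = [], [], [], []
    for i, ev in session.events.iterrows():
        anchor_ms = ev["motion_onset_ms"] if lock_event == MOTION_ONSET else ev["stop_ms"]
        if not np.isfinite(anchor_ms):
            logger.info("trial %s has no %s event; skipped", i, lock_event)
            continue
        a = int(round(anchor_ms * fs / 1000.0))
        s0 = a + int(round(span[0] * fs / 1000.0))
        s1 = s0 + nsp
        if s0 < 0 or s1 > n_total:
            raise ValueError(
                f"epoch span {span} around {lock_event} at {anchor_ms} ms "
                f"exceeds generated samples"
            )
        dat.append(sig[i, s0:s1])
        base.append(sig[i, b0:b1])
        base_pad.append(sig[i, pb0:pb1])
        rows.append(ev)
    times = np.arange(nsp) * 1000.0 / fs + span[0]
    return EpochSet(
        roi=roi,
        data=np.asarray(dat),
        times=times,
        lock_event=lock_event,
        fs=fs,
        baseline=np.asarray(base),
        baseline_padded=np.asarray(base_pad),
        baseline_pad_ms=cfg.baseline_pad_ms,
        meta=pd.DataFrame(rows).reset_index(drop=True),
    )


def synthesize_epochs(
    cfg: EEGGenConfig,
    n_trials: int,
    group: str = "A",
    roi: str | None = None,
    lock_event: str = MOTION_ONSET,
    span: tuple[float, float] | None = None,
    seed: int = 0,
    task_cfg: TaskConfig | None = None,
    subject: str = "S01",
) -> EpochSet:
    """Convenience generator of motion-locked epochs without a behavioral
    session (all trials are treated as go trials) — the workhorse of the
    statistical calibration and recovery simulations."""
    task_cfg = task_cfg or TaskConfig()
    roi = roi or cfg.rois[0]
    n = _trial_length_samples(cfg, task_cfg)
    data = {r: np.empty((n_trials, n)) for r in cfg.rois}
    rows = []
    for i in range(n_trials):
        _, sigs = synthesize_trial(cfg, None, task_cfg, group, [int(seed), 404, i])
        for r in cfg.rois:
            data[r][i] = sigs[r]
        rows.append({"subject": subject, "group": group, "block": 1, "trial": i + 1,
                     "trial_type": GO, "ssd": np.nan, "outcome": "go_success",
                     **_trial_events(task_cfg, None)})
    times = np.arange(n) * 1000.0 / cfg.fs
    session = ContinuousSession(data=data, fs=cfg.fs, times=times,
                                events=pd.DataFrame(rows), cfg=cfg, task_cfg=task_cfg)
    return make_epochs(session, roi, lock_event, span)


# ---------------------------------------------------------------------------
# clinical table + cohort
# ---------------------------------------------------------------------------

def generate_clinical_table(
    n_ctd: int,
    n_hc: int,
    seed: int,
    ygtss: tuple[float, float] = (23.0, 9.3),
    puts: tuple[float, float] = (22.0, 5.9),
    cybocs: tuple[float, float] = (8.6, 9.9),
    dupaul: tuple[float, float] = (17.3, 10.8),
    age_range: tuple[int, int] = (10, 17),
    p_female: float = 0.33,
) -> pd.DataFrame:
    """Synthetic per-subject clinical table.

    CTD scale scores are normal draws (clipped to valid ranges) centered on
    the cohort summary statistics; healthy controls get zero tic/urge scores
    and low comorbidity scores.  PUTS item 10 (self-rated tic
    suppressibility, 1-4) is drawn independently unless linked elsewhere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 505]))
    rows = []
    for i in range(n_ctd + n_hc):
        is_ctd = i < n_ctd
        diag = "CTD" if is_ctd else "HC"
        row = {
            "subject": f"{diag}{i + 1:02d}" if is_ctd else f"HC{i - n_ctd + 1:02d}",
            "diagnosis": diag,
            "age": int(rng.integers(age_range[0], age_range[1] + 1)),
            "sex": "F" if rng.random() < p_female else "M",
        }
        if is_ctd:
            row["ygtss_total_tic"] = float(np.clip(rng.normal(*ygtss), 0, 50))
            row["puts_total"] = float(np.clip(rng.normal(*puts), 9, 44))
            row["puts_item10"] = int(rng.integers(1, 5))
            row["cybocs"] = float(np.clip(rng.normal(*cybocs), 0, 40))
            row["dupaul_adhd"] = float(np.clip(rng.normal(*dupaul), 0, 54))
        else:
            row.update(ygtss_total_tic=0.0, puts_total=9.0, puts_item10=4,
                       cybocs=float(np.clip(rng.normal(1, 2), 0, 40)),
                       dupaul_adhd=float(np.clip(rng.normal(6, 5), 0, 54)))
        rows.append(row)
    return pd.DataFrame(rows)


def draw_linked_clinical(
    n: int,
    target_partial_r: float,
    seed,
    delta_mu: float = -4.0,
    delta_sd: float = 2.0,
    score_mu: float = 23.0,
    score_sd: float = 9.3,
    age_range: tuple[int, int] = (10, 17),
    age_loading: float = 0.3,
) -> pd.DataFrame:
    """Per-subject (age, effect size, clinical score) with a built-in
    age-adjusted (partial) correlation between effect size and score.

    Both variables load on standardized age with weight ``age_loading``;
    their age-independent residuals are bivariate normal with correlation
    ``target_partial_r``, so the population partial correlation given age
    equals the target exactly.
    """
    if not -1.0 <= target_partial_r <= 1.0:
        raise ValueError("|target partial correlation| must be <= 1")
    if n < 2:
        raise ValueError("need n >= 2 subjects")
    rng = np.random.default_rng(np.random.SeedSequence(
        [*np.atleast_1d(seed).tolist(), 606]))
    age = rng.integers(age_range[0], age_range[1] + 1, size=n).astype(float)
    age_z = (age - np.mean(age_range)) / (np.ptp(age_range) / np.sqrt(12))
    r = target_partial_r
    cov = np.array([[1.0, r], [r, 1.0]])
    eps = rng.multivariate_normal([0, 0], cov, size=n)
    a = age_loading
    x = delta_mu + delta_sd * (a * age_z + np.sqrt(1 - a**2) * eps[:, 0])
    y = score_mu + score_sd * (a * age_z + np.sqrt(1 - a**2) * eps[:, 1])
    return pd.DataFrame({"age": age.astype(int), "delta_db": x,
                         "ygtss_total_tic": y})


@dataclass(frozen=True)
class LinkageSpec:
    """Links a per-subject effect size to a clinical scale (CTD group)."""

    effect_index: int
    target_partial_r: float
    delta_sd: float = 2.0
    scale: str = "ygtss_total_tic"


@dataclass
class Cohort:
    """Simulated two-group cohort: epochs pooled across subjects per
    (ROI, lock event), plus behavior and a clinical table."""

    epochs: dict[tuple[str, str], EpochSet]
    clinical: pd.DataFrame
    behavior: pd.DataFrame  # per subject per block summary rows
    true_delta_db: pd.Series  # per CTD subject, linked effect size (NaN if unlinked)
    trials: dict[str, list[TrialRecord]] = field(default_factory=dict)


def _concat_epochs(parts: list[EpochSet]) -> EpochSet:
    first = parts[0]
    return EpochSet(
        roi=first.roi,
        data=np.concatenate([p.data for p in parts]),
        times=first.times,
        lock_event=first.lock_event,
        fs=first.fs,
        baseline=np.concatenate([p.baseline for p in parts]),
        baseline_padded=np.concatenate([p.baseline_padded for p in parts]),
        baseline_pad_ms=first.baseline_pad_ms,
        meta=pd.concat([p.meta for p in parts], ignore_index=True),
    )


def build_cohort(
    n_a: int,
    n_b: int,
    cfg: EEGGenConfig,
    task_cfg: TaskConfig | None = None,
    subject_a: SubjectModel | None = None,
    subject_b: SubjectModel | None = None,
    seed: int = 0,
    linkage: LinkageSpec | None = None,
    group_names: tuple[str, str] = ("CTD", "HC"),
    locks: tuple[str, ...] = (MOTION_ONSET, STOP_SIGNAL),
) -> Cohort:
    """Simulate a full two-group cohort: one behavioral session + per-trial
    ROI EEG + one clinical row per subject.

    With ``linkage``, the chosen effect's ``delta_db`` is drawn per CTD
    subject with the requested age-adjusted correlation to the clinical
    scale, enabling end-to-end recovery of the power-vs-severity analysis.
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("need at least 2 subjects per group")
    task_cfg = task_cfg or TaskConfig()
    subject_a = subject_a or SubjectModel()
    subject_b = subject_b or SubjectModel()
    name_a, name_b = group_names

    clinical = generate_clinical_table(n_a, n_b, seed)
    deltas = pd.Series(np.nan, index=clinical.subject)
    if linkage is not None:
        base_eff = cfg.effects[linkage.effect_index]
        linked = draw_linked_clinical(
            n_a, linkage.target_partial_r, [int(seed), 1], delta_mu=base_eff.delta_db,
            delta_sd=linkage.delta_sd)
        ctd_idx = clinical.index[clinical.diagnosis == "CTD"]
        clinical.loc[ctd_idx, "age"] = linked["age"].to_numpy()
        clinical.loc[ctd_idx, linkage.scale] = linked[linkage.scale].to_numpy()
        deltas.iloc[: n_a] = linked["delta_db"].to_numpy()

    parts: dict[tuple[str, str], list[EpochSet]] = {}
    behavior_rows = []
    all_trials: dict[str, list[TrialRecord]] = {}
    from .task import summarize_behavior  # local import to avoid cycle at top

    for s, row in clinical.iterrows():
        group = name_a if row.diagnosis == "CTD" else name_b
        model = subject_a if group == name_a else subject_b
        trials = run_session(task_cfg, model, seed=int(seed) * 1000 + s)
        all_trials[row.subject] = trials
        summ = summarize_behavior(trials).table
        summ = summ.assign(subject=row.subject, group=group)
        behavior_rows.append(summ.reset_index(names="block_label"))

        sub_cfg = cfg
        if linkage is not None and group == name_a:
            effects = list(cfg.effects)
            effects[linkage.effect_index] = replace(
                effects[linkage.effect_index], delta_db=float(deltas.loc[row.subject]))
            sub_cfg = replace(cfg, effects=tuple(effects))
        session = simulate_session_eeg(sub_cfg, task_cfg, trials, group,
                                       seed=int(seed) * 1000 + s, subject=row.subject)
        for roi in cfg.rois:
            for lock in locks:
                parts.setdefault((roi, lock), []).append(
                    make_epochs(session, roi, lock))
    epochs = {k: _concat_epochs(v) for k, v in parts.items()}
    return Cohort(
        epochs=epochs,
        clinical=clinical,
        behavior=pd.concat(behavior_rows, ignore_index=True),
        true_delta_db=deltas,
        trials=all_trials,
    )
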