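"""Synthetic cohort generator with exported ground truth.

Simulates a two-group cohort (Parkinson disease vs healthy control) whose
tapping logs, phonation audio and syllable-train audio carry a known,
severity- and time-frame-dependent statistical structure:

* inter-tap intervals are lognormal with a per-frame SD that rises linearly
  over the five time frames, faster for more severe disease;
* sustained vowels carry injected local jitter, local shimmer and a loudness
  drift, each linear in time frame with a slope coupled to the UPDRS part
  III motor score;
* syllable trains have inter-onset intervals whose SD grows with frame and
  severity.

Every generated trial is reproducible from (master seed, subject id, task,
trial index); the generating parameters (the "truth") are exported so that
downstream estimators can be scored against them.

The numeric anchors (group means/SDs of each feature, and the coefficients
of the severity models) sit in ``GROUP_ANCHORS`` and ``SEVERITY_MODELS``.
Between-subject and within-subject variance components are derived once
from those anchors under the convention that printed feature SDs describe
observation-level spread while group tests act on per-subject means.

Besides the signal-level synthesizers, ``simulate_feature_table`` draws
long-format feature records directly from the same generating model. This
feature-level path is what makes large replication studies (type-I error,
CI coverage, sign recovery at hundreds of cohorts) tractable; the
signal-level paths are validated separately by the estimator-recovery
suites.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .taps import SIDES, TapEvent, TapTrial, write_tap_csv
from .voice import Waveform, write_wav

SCENARIOS = ("paper_like", "null_interaction", "custom")

#: anchor cohort size behind all derived variance components
_ANCHOR_N = 20
_UPDRS_MEAN, _UPDRS_SD = 22.10, 10.64
_AGE_PD = (68.30, 6.30)
_AGE_CTRL = (33.55, 7.85)
_HY_LEVELS = (1.5, 2.0, 2.5, 3.0)
_HY_PROBS = (0.20, 0.25, 0.35, 0.20)

#: (task, feature) -> (ctrl_mean, ctrl_sd, pd_mean, pd_sd, |t|) group anchors
GROUP_ANCHORS: dict[tuple[str, str], tuple[float, float, float, float, float]] = {
    ("tapping", "total_taps"): (199.263, 32.600, 76.250, 35.932, 22.678),
    ("tapping", "mean_variability"): (0.0288, 0.0101, 0.158, 0.144, 8.017),
    ("a", "loudness"): (1.573, 0.735, 2.051, 0.844, 4.514),
    ("a", "jitter"): (0.0074, 0.00521, 0.0151, 0.0174, 4.647),
    ("a", "jitter_cv"): (1.930, 1.583, 3.181, 1.959, 5.180),
    ("a", "shimmer"): (0.477, 0.196, 0.578, 0.332, 2.692),
    ("a", "shimmer_cv"): (0.737, 0.303, 0.971, 0.337, 5.446),
    ("i", "loudness"): (1.082, 0.503, 1.302, 0.519, 3.225),
    ("i", "jitter"): (0.0071, 0.00583, 0.0103, 0.0105, 2.773),
    ("i", "jitter_cv"): (2.011, 1.960, 3.673, 2.420, 5.608),
    ("i", "shimmer"): (0.402, 0.190, 0.417, 0.246, 0.497),
    ("i", "shimmer_cv"): (0.766, 0.352, 1.071, 0.452, 5.577),
    ("dadada", "repeat_count"): (40.067, 4.623, 36.225, 5.329, 5.791),
    ("dadada", "interval_sd"): (1.931, 0.874, 3.705, 2.755, 6.325),
    ("pataka", "repeat_count"): (41.010, 7.011, 37.442, 5.475, 4.089),
    ("pataka", "interval_sd"): (4.970, 10.808, 5.087, 3.938, 0.101),
}

#: number of replicate series per subject entering a subject mean
_N_SERIES = {"tapping": 4, "a": 6, "i": 6, "dadada": 6, "pataka": 6}

#: within-PD severity models, value ~ b0 + b_tf*tf + b_u*u + b_int*u*tf,
#: tf coded 1..5, UPDRS III uncentered; se_int anchors the residual scale;
#: ctrl_means give the control trajectory (scalar = flat)
SEVERITY_MODELS: dict[tuple[str, str], dict] = {
    ("tapping", "interval_sd"): dict(
        b0=0.0290, b_tf=0.0112, b_u=0.00291, b_int=-0.000376, se_int=0.000262,
        ctrl_means=(0.0238, 0.0238, 0.0258, 0.0284, 0.0323),
        anchor=("tapping", "mean_variability"),
    ),
    ("a", "loudness"): dict(
        b0=2.319, b_tf=0.0825, b_u=0.00123, b_int=-0.00830, se_int=0.00238,
        ctrl_means=1.573, anchor=("a", "loudness"),
    ),
    ("a", "jitter"): dict(
        b0=0.00929, b_tf=-0.000456, b_u=-0.000111, b_int=0.000106, se_int=0.0000412,
        ctrl_means=0.0074, anchor=("a", "jitter"),
    ),
    ("a", "shimmer"): dict(
        b0=0.395, b_tf=-0.0183, b_u=-0.000815, b_int=0.00338, se_int=0.000989,
        ctrl_means=0.477, anchor=("a", "shimmer"),
    ),
    ("i", "loudness"): dict(
        b0=1.341, b_tf=0.0787, b_u=0.00238, b_int=-0.00492, se_int=0.00145,
        ctrl_means=1.082, anchor=("i", "loudness"),
    ),
    ("i", "jitter"): dict(
        b0=0.0112, b_tf=-0.00232, b_u=-0.000357, b_int=0.000196, se_int=0.0000351,
        ctrl_means=0.0071, anchor=("i", "jitter"),
    ),
    ("i", "shimmer"): dict(
        b0=0.393, b_tf=-0.0470, b_u=-0.00823, b_int=0.00498, se_int=0.000829,
        ctrl_means=0.402, anchor=("i", "shimmer"),
    ),
    ("dadada", "interval_sd"): dict(
        b0=1.474, b_tf=-0.0433, b_u=0.0462, b_int=0.00307, se_int=0.00542,
        ctrl_means=1.931, anchor=("dadada", "interval_sd"),
    ),
    ("pataka", "interval_sd"): dict(
        b0=0.424, b_tf=0.724, b_u=0.0961, b_int=-0.0194, se_int=0.00916,
        ctrl_means=4.970, anchor=("pataka", "interval_sd"),
    ),
}

#: fixed harmonic recipes standing in for two-resonance vowel shaping
VOWEL_HARMONICS = {
    "a": np.array([1.0, 0.35, 0.45, 0.30, 0.15, 0.08]),
    "i": np.array([1.0, 0.12, 0.06, 0.05, 0.30, 0.12]),
}

#: nominal inter-onset intervals (s) yielding the anchor repeat counts in 5 s
DDK_IOI = {
    ("dadada", "control"): 5.0 / 40.067,
    ("dadada", "PD"): 5.0 / 36.225,
    ("pataka", "control"): 5.0 / 41.010,
    ("pataka", "PD"): 5.0 / 37.442,
}

#: printed DDK interval variability is read as units of 10 ms -> seconds
DDK_SD_UNIT = 0.01
#: printed shimmer is on a dB-like scale; small-perturbation relative factor
SHIMMER_DB_TO_REL = 0.115

_TF = np.arange(1, 6, dtype=float)
_VAR_TF = 2.0  # population variance of codes 1..5
_VAR_U = _UPDRS_SD**2

TAP_INTERVAL_MEAN = {"control": 0.25, "PD": 0.55}
DUPLICATE_FRACTION = 0.02


@dataclass(frozen=True)
class SubjectProfile:
    subject_id: str
    group: str  # "PD" | "control"
    age: float
    sex: str  # "F" | "M"
    updrs3: int | None = None
    hy: float | None = None

    def __post_init__(self) -> None:
        if self.group == "PD":
            if self.updrs3 is None or self.hy is None:
                raise ValueError("PD subjects need updrs3 and hy")
            if not (0 <= self.updrs3 <= 132):
                raise ValueError("updrs3 outside [0, 132]")
        elif self.group == "control":
            if self.updrs3 is not None or self.hy is not None:
                raise ValueError("controls carry no severity scores")
        else:
            raise ValueError(f"unknown group {self.group!r}")


@dataclass
class SimulationTruth:
    """Generating parameters for one simulated cohort.

    ``models`` holds the resolved per-feature fixed effects (beta_int is 0
    exactly under the null scenario) and variance components; ``subjects``
    the per-subject signal-level parameters (tap_sigma0, tap_tf_slope,
    jitter0/shimmer0/loudness0 and their frame slopes, random intercepts);
    ``trial_truth`` collects per-trial ground truth (clean tap times, true
    period/amplitude sequences, true onset lists) as trials are synthesised.
    """

    seed: int
    scenario: str
    models: dict[str, dict]
    subjects: dict[str, dict]
    trial_truth: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "seed": self.seed,
            "scenario": self.scenario,
            "models": self.models,
            "subjects": self.subjects,
            "trial_truth": self.trial_truth,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationTruth":
        doc = json.loads(Path(path).read_text())
        return cls(
            seed=doc["seed"],
            scenario=doc["scenario"],
            models=doc["models"],
            subjects=doc["subjects"],
            trial_truth=doc.get("trial_truth", {}),
        )


def _key(task: str, feature: str) -> str:
    return f"{task}.{feature}"


def _substream(seed: int, *tags) -> np.random.Generator:
    """Deterministic per-trial RNG: master seed + hashed string tags."""
    ents = [int(seed) & 0x7FFFFFFF]
    for t in tags:
        ents.append(zlib.crc32(str(t).encode()))
    return np.random.default_rng(np.random.SeedSequence(ents))


def _subject_mean_sd(delta: float, t_abs: float) -> float:
    """Between-subject SD of subject means implied by a printed pooled t."""
    return delta * np.sqrt(_ANCHOR_N / 2.0) / t_abs


def _anchor_components(task: str, feature: str, m_obs: int) -> dict:
    """Split a printed (mean, SD, t) anchor into variance components.

    Printed SDs are taken as observation-level spread; the printed t as the
    test on per-subject means of ``m_obs`` observations. Returns pooled
    sigma_b (between subjects), sigma_w (within), and per-group scale
    factors proportional to the printed group SDs.
    """
    cm, csd, pm, psd, t_abs = GROUP_ANCHORS[(task, feature)]
    delta = abs(pm - cm)
    sd_tot2 = (csd**2 + psd**2) / 2.0
    s_sm2 = _subject_mean_sd(delta, t_abs) ** 2
    sigma_b2 = max(0.0, (s_sm2 - sd_tot2 / m_obs) / (1.0 - 1.0 / m_obs))
    sigma_w2 = max(sd_tot2 - sigma_b2, 1e-12)
    scale = np.sqrt(sd_tot2)
    return dict(
        ctrl_mean=cm,
        pd_mean=pm,
        sigma_b=float(np.sqrt(sigma_b2)),
        sigma_w=float(np.sqrt(sigma_w2)),
        ctrl_scale=float(csd / scale),
        pd_scale=float(psd / scale),
    )


def _resolve_models(scenario: str, overrides: Mapping | None = None) -> dict[str, dict]:
    """Fixed effects + variance components per feature for a scenario."""
    models: dict[str, dict] = {}
    for (task, feature), m in SEVERITY_MODELS.items():
        n_series = _N_SERIES[task]
        n_obs = _ANCHOR_N * n_series * 5
        # residual scale in PD units: the printed interaction SE anchors it
        sigma_e = m["se_int"] * np.sqrt(n_obs * _VAR_TF * _VAR_U)
        comp = _anchor_components(*m["anchor"], m_obs=n_series * 5)
        # express the pooled between-subject SD in PD units as well, so the
        # PD group carries scale 1 and controls a proportional reduction
        psd_rel = comp["pd_scale"]
        sigma_b = float(max(comp["sigma_b"] * psd_rel, 1e-6))
        ctrl_rel = comp["ctrl_scale"] / psd_rel
        b0, b_tf, b_u, b_int = m["b0"], m["b_tf"], m["b_u"], m["b_int"]
        if scenario == "null_interaction":
            # keep the average-severity trajectory, remove all u-dependence
            b0 = b0 + b_u * _UPDRS_MEAN
            b_tf = b_tf + b_int * _UPDRS_MEAN
            b_u = 0.0
            b_int = 0.0
        ctrl = m["ctrl_means"]
        ctrl_means = list(ctrl) if isinstance(ctrl, tuple) else [float(ctrl)] * 5
        models[_key(task, feature)] = dict(
            task=task,
            feature=feature,
            tf_resolved=True,
            b0=float(b0),
            b_tf=float(b_tf),
            b_u=float(b_u),
            b_int=float(b_int),
            sigma_e=float(sigma_e),
            sigma_b=sigma_b,
            ctrl_means=ctrl_means,
            ctrl_scale=float(ctrl_rel),
            pd_scale=1.0,
        )
    # whole-trial anchored features (no time-frame structure)
    for (task, feature), anc in GROUP_ANCHORS.items():
        if (task, feature) in SEVERITY_MODELS or feature == "mean_variability":
            continue
        comp = _anchor_components(task, feature, m_obs=_N_SERIES[task])
        models[_key(task, feature)] = dict(
            task=task,
            feature=feature,
            tf_resolved=False,
            ctrl_mean=comp["ctrl_mean"],
            pd_mean=comp["pd_mean"],
            sigma_b=comp["sigma_b"],
            sigma_w=comp["sigma_w"],
            ctrl_scale=comp["ctrl_scale"],
            pd_scale=comp["pd_scale"],
            b_int=0.0,
        )
    if overrides:
        for k, v in overrides.items():
            models[k].update(v)
    return models


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(x, lo, hi))


def _subject_params(profile: SubjectProfile, models: dict, scenario: str,
                    rng: np.random.Generator) -> dict:
    """Signal-level generating parameters for one subject."""
    pd_group = profile.group == "PD"
    u = float(profile.updrs3) if pd_group else 0.0

    # random intercepts, one per feature model
    b = {}
    for k, m in models.items():
        scale = m["pd_scale"] if pd_group else m["ctrl_scale"]
        b[k] = float(rng.normal(0.0, m["sigma_b"] * scale))

    f0 = float(rng.uniform(170.0, 220.0) if profile.sex == "F"
               else rng.uniform(150.0, 185.0))

    # tapping: lognormal interval mean, per-frame SD = sigma0 + slope*(k-1)
    if pd_group:
        mu = TAP_INTERVAL_MEAN["PD"]
        if scenario == "null_interaction":
            sigma0 = max(0.0290 + 0.00291 * _UPDRS_MEAN + rng.normal(0, 0.03), 0.01)
            slope = 0.005 + 0.00025 * _UPDRS_MEAN
        else:
            sigma0 = max(0.0290 + 0.00291 * u + rng.normal(0, 0.03), 0.01)
            slope = max(0.005 + 0.00025 * u, 0.0)
    else:
        mu = TAP_INTERVAL_MEAN["control"]
        sigma0 = max(rng.normal(0.0238, 0.008), 0.006)
        slope = 0.0021

    def _traj(task: str, feature: str, unit: float = 1.0,
              floor: float = 1e-4) -> tuple[float, float]:
        """(level at TF1, per-frame slope) for this subject."""
        m = models[_key(task, feature)]
        if pd_group:
            lvl = m["b0"] + m["b_tf"] + m["b_u"] * u + m["b_int"] * u + b[_key(task, feature)]
            slp = m["b_tf"] + m["b_int"] * u
        else:
            lvl = m["ctrl_means"][0] + b[_key(task, feature)]
            slp = 0.0
        return max(lvl * unit, floor), slp * unit

    vowels = {}
    for v in ("a", "i"):
        j0, js = _traj(v, "jitter", floor=5e-4)
        s0, ss = _traj(v, "shimmer", unit=SHIMMER_DB_TO_REL, floor=2e-3)
        l0, ls = _traj(v, "loudness", floor=0.3)
        vowels[v] = dict(jitter0=j0, jitter_slope=js, shimmer0=s0,
                         shimmer_slope=ss, loudness0=l0, loudness_slope=ls)

    ddk = {}
    for task in ("dadada", "pataka"):
        ioi = DDK_IOI[(task, profile.group)] + float(rng.normal(0, 0.004))
        sd0, sds = _traj(task, "interval_sd", unit=DDK_SD_UNIT, floor=1e-4)
        ddk[task] = dict(ioi=float(ioi), sd0=sd0, sd_slope=sds)

    return dict(
        group=profile.group,
        updrs3=profile.updrs3,
        f0=f0,
        tap=dict(interval_mean=float(mu), tap_sigma0=float(sigma0),
                 tap_tf_slope=float(slope)),
        vowels=vowels,
        ddk=ddk,
        b=b,
    )


def sample_cohort(
    n_pd: int,
    n_control: int,
    scenario: str = "paper_like",
    seed: int = 0,
    overrides: Mapping | None = None,
) -> tuple[list[SubjectProfile], SimulationTruth]:
    """Draw subject profiles and the full generating truth for a cohort.

    PD severity (UPDRS part III) is normal with mean 22.10, SD 10.64,
    truncated to [5, 60]; ages are group-specific normals; the Hoehn & Yahr
    stage is drawn from the anchor distribution. Under ``null_interaction``
    every feature's severity coupling (main and interaction) is exactly 0.
    """
    if n_pd < 1 or n_control < 1:
        raise ValueError("group sizes must be >= 1")
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    models = _resolve_models(scenario, overrides)
    profiles: list[SubjectProfile] = []
    subjects: dict[str, dict] = {}
    rng = _substream(seed, "cohort")
    for i in range(n_pd):
        sid = f"pd{i + 1:03d}"
        updrs = int(round(_truncated_normal(rng, _UPDRS_MEAN, _UPDRS_SD, 5, 60)))
        prof = SubjectProfile(
            subject_id=sid,
            group="PD",
            age=_truncated_normal(rng, *_AGE_PD, 40, 90),
            sex="F" if rng.random() < 0.85 else "M",
            updrs3=updrs,
            hy=float(rng.choice(_HY_LEVELS, p=_HY_PROBS)),
        )
        profiles.append(prof)
        subjects[sid] = _subject_params(prof, models, scenario, _substream(seed, sid))
    for i in range(n_control):
        sid = f"hc{i + 1:03d}"
        prof = SubjectProfile(
            subject_id=sid,
            group="control",
            age=_truncated_normal(rng, *_AGE_CTRL, 20, 80),
            sex="F" if rng.random() < 0.5 else "M",
        )
        profiles.append(prof)
        subjects[sid] = _subject_params(prof, models, scenario, _substream(seed, sid))
    truth = SimulationTruth(seed=seed, scenario=scenario, models=models,
                            subjects=subjects)
    return profiles, truth


# ---------------------------------------------------------------------------
# signal-level synthesis


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    s2 = np.log1p((sd / mean) ** 2)
    return np.log(mean) - s2 / 2.0, np.sqrt(s2)


def simulate_tap_trial(
    profile: SubjectProfile,
    truth: SimulationTruth,
    hand: str = "right",
    session: int = 1,
    duration: float = 20.0,
    duplicate_fraction: float = DUPLICATE_FRACTION,
) -> TapTrial:
    """Alternating tap log over 20 s with frame-dependent interval spread.

    Intervals are lognormal; the SD within frame k is
    ``tap_sigma0 + tap_tf_slope * (k - 1)``. A small fraction of events
    duplicates the previous side (same-button double hits) to exercise the
    alternation filter; the clean event list is recorded in the truth.
    """
    if hand not in SIDES:
        raise ValueError(f"hand must be one of {SIDES}")
    sp = truth.subjects[profile.subject_id]["tap"]
    rng = _substream(truth.seed, profile.subject_id, f"tap_{hand}", session)
    frame_len = duration / 5.0
    times = [float(rng.uniform(0.0, 0.05))]
    while True:
        k = min(int(times[-1] / frame_len), 4)
        sd_k = sp["tap_sigma0"] + sp["tap_tf_slope"] * k
        mu, sig = _lognormal_params(sp["interval_mean"], sd_k)
        dt = float(rng.lognormal(mu, sig))
        t_next = times[-1] + dt
        if t_next > duration:
            break
        times.append(t_next)
    sides = [SIDES[i % 2] for i in range(len(times))]

    events: list[TapEvent] = []
    clean_times: list[float] = []
    for i, (t, s) in enumerate(zip(times, sides)):
        events.append(TapEvent(t, s))
        clean_times.append(t)
        nxt = times[i + 1] if i + 1 < len(times) else duration
        if duplicate_fraction > 0 and rng.random() < duplicate_fraction:
            t_dup = t + 0.3 * (nxt - t)
            if t_dup < min(nxt, duration):
                events.append(TapEvent(float(t_dup), s))
    truth.trial_truth[f"{profile.subject_id}/tap_{hand}/{session}"] = {
        "clean_times": clean_times,
        "n_events": len(events),
    }
    return TapTrial(subject_id=profile.subject_id, hand=hand, session=session,
                    events=events, duration=duration)


def _render_cycles(
    periods: np.ndarray,
    amps: np.ndarray,
    harmonics: np.ndarray,
    rate: int,
    duration: float,
) -> np.ndarray:
    """Render a harmonic waveform from exact cycle periods and amplitudes.

    Phase runs 0..1 within each cycle, so every harmonic crosses zero at the
    cycle boundaries and the true period sequence is exactly `periods`.
    """
    starts = np.concatenate([[0.0], np.cumsum(periods)])
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    ci = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(periods) - 1)
    phase = (t - starts[ci]) / periods[ci]
    x = np.zeros(n)
    for h, a_h in enumerate(harmonics, start=1):
        x += a_h * np.sin(2 * np.pi * h * phase)
    return amps[ci] * x


def synthesize_phonation(
    profile: SubjectProfile,
    truth: SimulationTruth,
    vowel: str = "a",
    trial_index: int = 1,
    sample_rate: int = 16000,
    duration: float = 10.0,
    snr_db: float = 30.0,
    jitter_override: float | None = None,
    shimmer_override: float | None = None,
    zero_drift: bool = False,
) -> Waveform:
    """10 s sustained vowel with injected jitter, shimmer and loudness drift.

    Within frame k (1..5) the local jitter target is
    ``jitter0 + jitter_slope * (k - 1)`` (clipped at 0), analogously for
    shimmer; the amplitude envelope follows the loudness trajectory mapped
    through the inverse of the ``energy**0.3`` compression. True period and
    cycle-amplitude sequences are recorded in the truth.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    if vowel not in VOWEL_HARMONICS:
        raise ValueError(f"vowel must be one of {tuple(VOWEL_HARMONICS)}")
    sub = truth.subjects[profile.subject_id]
    vp = dict(sub["vowels"][vowel])
    if jitter_override is not None:
        vp["jitter0"], vp["jitter_slope"] = jitter_override, 0.0
    if shimmer_override is not None:
        vp["shimmer0"], vp["shimmer_slope"] = shimmer_override, 0.0
    if zero_drift:
        vp["jitter_slope"] = vp["shimmer_slope"] = vp["loudness_slope"] = 0.0
    rng = _substream(truth.seed, profile.subject_id, f"phon_{vowel}", trial_index)

    f0 = sub["f0"]
    t0 = 1.0 / f0
    frame_len = duration / 5.0
    n_cycles = int(np.ceil(duration / t0)) + 2
    # frame of each cycle by its nominal start time
    k = np.minimum((np.arange(n_cycles) * t0 / frame_len).astype(int), 4)
    j_target = np.maximum(vp["jitter0"] + vp["jitter_slope"] * k, 0.0)
    s_target = np.maximum(vp["shimmer0"] + vp["shimmer_slope"] * k, 0.0)
    # Gaussian period scatter giving E|dT|/T = target
    sig_j = j_target * np.sqrt(np.pi) / 2.0
    sig_s = s_target * np.sqrt(np.pi) / 2.0
    periods = t0 * (1.0 + sig_j * rng.standard_normal(n_cycles))
    periods = np.maximum(periods, 0.2 * t0)

    loud = np.maximum(vp["loudness0"] + vp["loudness_slope"] * k, 0.05)
    base_amp = 0.25 * (loud / loud[0]) ** (1.0 / 0.6)
    amps = base_amp * (1.0 + sig_s * rng.standard_normal(n_cycles))
    amps = np.maximum(amps, 0.01 * base_amp)

    x = _render_cycles(periods, amps, VOWEL_HARMONICS[vowel], sample_rate, duration)
    if np.isfinite(snr_db):
        noise_sd = float(np.sqrt(np.mean(x**2))) / (10 ** (snr_db / 20.0))
        x = x + rng.normal(0.0, noise_sd, len(x))
    peak = np.max(np.abs(x))
    if peak > 0.97:
        x = x * (0.97 / peak)

    n_used = int(np.searchsorted(np.cumsum(periods), duration)) + 1
    truth.trial_truth[f"{profile.subject_id}/{vowel}/{trial_index}"] = {
        "periods": periods[:n_used].tolist(),
        "amplitudes": amps[:n_used].tolist(),
        "frames": (k[:n_used] + 1).tolist(),
        "f0": f0,
    }
    return Waveform(samples=x, rate=sample_rate, task=vowel)


def _syllable_burst(rate: int, f0: float, dur: float = 0.12,
                    attack: float = 0.005, decay: float = 0.025) -> np.ndarray:
    """One voiced burst: sharp attack, exponential decay."""
    n = int(round(dur * rate))
    t = np.arange(n) / rate
    env = np.minimum(t / attack, 1.0) * np.exp(-np.maximum(t - attack, 0.0) / decay)
    carrier = (np.sin(2 * np.pi * f0 * t)
               + 0.5 * np.sin(2 * np.pi * 2 * f0 * t)
               + 0.25 * np.sin(2 * np.pi * 3 * f0 * t))
    return env * carrier / 1.75


def synthesize_syllable_train(
    profile: SubjectProfile,
    truth: SimulationTruth,
    task: str = "dadada",
    trial_index: int = 1,
    sample_rate: int = 16000,
    duration: float = 5.0,
    snr_db: float = 20.0,
    ioi_override: float | None = None,
    sd_override: float | None = None,
) -> Waveform:
    """5 s train of decaying voiced bursts with controlled interval spread.

    Inter-onset intervals are ``ioi + N(0, sd_k)`` with the SD linear in the
    frame of the interval start; intervals are floored at 90 ms. True onset
    times go into the truth.
    """
    if sample_rate < 8000:
        raise ValueError("sample_rate must be >= 8000 Hz")
    if task not in DDK_IOI and task not in ("dadada", "pataka"):
        raise ValueError("task must be dadada or pataka")
    sub = truth.subjects[profile.subject_id]
    dp = dict(sub["ddk"][task])
    if ioi_override is not None:
        dp["ioi"] = ioi_override
    if sd_override is not None:
        dp["sd0"], dp["sd_slope"] = sd_override, 0.0
    rng = _substream(truth.seed, profile.subject_id, f"ddk_{task}", trial_index)

    frame_len = duration / 5.0
    onsets = [0.05]
    while True:
        k = min(int(onsets[-1] / frame_len), 4)
        sd_k = max(dp["sd0"] + dp["sd_slope"] * k, 0.0)
        gap = dp["ioi"] + (float(rng.normal(0.0, sd_k)) if sd_k > 0 else 0.0)
        t_next = onsets[-1] + max(gap, 0.09)
        # a burst needs room for its attack to exist in the recording
        if t_next >= duration - 0.03:
            break
        onsets.append(t_next)

    n = int(round(duration * sample_rate))
    x = np.zeros(n)
    burst = _syllable_burst(sample_rate, sub["f0"])
    for t in onsets:
        i0 = int(round(t * sample_rate))
        seg = burst[: max(0, min(len(burst), n - i0))]
        x[i0 : i0 + len(seg)] += 0.6 * seg
    if np.isfinite(snr_db):
        noise_sd = float(np.sqrt(np.mean(x**2))) / (10 ** (snr_db / 20.0))
        x = x + rng.normal(0.0, noise_sd, n)
    peak = np.max(np.abs(x))
    if peak > 0.97:
        x = x * (0.97 / peak)
    truth.trial_truth[f"{profile.subject_id}/{task}/{trial_index}"] = {
        "onsets": [float(t) for t in onsets],
    }
    return Waveform(samples=x, rate=sample_rate, task=task)


# ---------------------------------------------------------------------------
# feature-level simulation (fast path for replication studies)


def simulate_feature_table(
    profiles: Sequence[SubjectProfile],
    truth: SimulationTruth,
    n_sessions: int = 2,
    n_trials: int = 3,
    tasks: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Draw long-format feature records directly from the generating model.

    Every (subject, series, frame) cell of a frame-resolved feature is
    ``fixed-effect trajectory + subject intercept + N(0, sigma_e)``; whole-
    trial features are ``group mean + subject intercept + N(0, sigma_w)``.
    Derived whole-trial aggregates (mean_variability, per-trial jitter /
    shimmer / loudness means) are computed from the simulated frame values
    exactly as the extraction pipeline computes them from signals.
    """
    sel = set(tasks) if tasks is not None else None
    rows: list[dict] = []
    for prof in profiles:
        sid = prof.subject_id
        sub = truth.subjects[sid]
        is_pd = prof.group == "PD"
        u = float(prof.updrs3) if is_pd else 0.0
        rng = _substream(truth.seed, sid, "features")
        base = dict(subject_id=sid, group=prof.group,
                    updrs3=prof.updrs3 if is_pd else np.nan)
        for key, m in truth.models.items():
            task, feature = m["task"], m["feature"]
            if sel is not None and task not in sel:
                continue
            n_series = (n_sessions * 2 if task == "tapping"
                        else n_sessions * n_trials)
            scale = m["pd_scale"] if is_pd else m["ctrl_scale"]
            b_i = sub["b"][key]
            if m["tf_resolved"]:
                if is_pd:
                    mean_k = (m["b0"] + m["b_tf"] * _TF + m["b_u"] * u
                              + m["b_int"] * u * _TF)
                else:
                    mean_k = np.asarray(m["ctrl_means"], dtype=float)
                sig = m["sigma_e"] * scale
                for s in range(1, n_series + 1):
                    vals = mean_k + b_i + rng.normal(0.0, sig, 5)
                    for k in range(1, 6):
                        rows.append(dict(base, task=task, trial=f"r{s}",
                                         tf=k, feature=feature,
                                         value=float(vals[k - 1])))
                    if feature == "interval_sd" and task == "tapping":
                        rows.append(dict(base, task=task, trial=f"r{s}", tf=0,
                                         feature="mean_variability",
                                         value=float(vals.mean())))
                    elif task in ("a", "i"):
                        rows.append(dict(base, task=task, trial=f"r{s}", tf=0,
                                         feature=feature,
                                         value=float(vals.mean())))
                    elif feature == "interval_sd":
                        rows.append(dict(base, task=task, trial=f"r{s}", tf=0,
                                         feature=feature,
                                         value=float(vals.mean())))
            else:
                mean = m["pd_mean"] if is_pd else m["ctrl_mean"]
                sig = m["sigma_w"] * scale
                for s in range(1, n_series + 1):
                    rows.append(dict(base, task=task, trial=f"r{s}", tf=0,
                                     feature=feature,
                                     value=float(mean + b_i + rng.normal(0.0, sig))))
    df = pd.DataFrame(rows)
    cols = ["subject_id", "group", "updrs3", "task", "trial", "tf", "feature", "value"]
    return df[cols]


# ---------------------------------------------------------------------------
# cohort writer


def cohort_frame(profiles: Sequence[SubjectProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(subject_id=p.subject_id, group=p.group, age=round(p.age, 1),
                 sex=p.sex, updrs3=p.updrs3, hy=p.hy)
            for p in profiles
        ]
    )


def write_cohort(
    out_dir: str | Path,
    profiles: Sequence[SubjectProfile],
    truth: SimulationTruth,
    n_sessions: int = 2,
    n_trials: int = 3,
    sample_rate: int = 16000,
    write_audio: bool = True,
) -> Path:
    """Materialise a cohort: cohort.csv, truth.json, taps/*.csv, audio/*.wav."""
    out = Path(out_dir)
    (out / "taps").mkdir(parents=True, exist_ok=True)
    if write_audio:
        (out / "audio").mkdir(parents=True, exist_ok=True)
    for prof in profiles:
        for session in range(1, n_sessions + 1):
            for hand in SIDES:
                trial = simulate_tap_trial(prof, truth, hand=hand, session=session)
                write_tap_csv(trial, out / "taps" / f"{prof.subject_id}_{hand}_{session}.csv")
        if write_audio:
            for session in range(1, n_sessions + 1):
                for rep in range(1, n_trials + 1):
                    idx = (session - 1) * n_trials + rep
                    for vowel in ("a", "i"):
                        w = synthesize_phonation(prof, truth, vowel=vowel,
                                                 trial_index=idx,
                                                 sample_rate=sample_rate)
                        write_wav(w, out / "audio" / f"{prof.subject_id}_{vowel}_{idx}.wav")
                    for task in ("dadada", "pataka"):
                        w = synthesize_syllable_train(prof, truth, task=task,
                                                      trial_index=idx,
                                                      sample_rate=sample_rate)
                        write_wav(w, out / "audio" / f"{prof.subject_id}_{task}_{idx}.wav")
    cohort_frame(profiles).to_csv(out / "cohort.csv", index=False)
    truth.to_json(out / "truth.json")
    return out
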