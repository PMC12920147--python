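"""Synthetic multimodal PSG cohorts with known ground truth.

A hidden five-state Markov chain at 30-s resolution (the annotation
granularity) drives all four modalities of each synthetic recording:

* BAS (EEG/EOG): a mixture of band-limited oscillations whose per-band
  amplitudes depend on the hidden stage, with a distinct dominant band per
  stage (Wake-beta, N1-theta, N2-sigma, N3-delta, REM-alpha);
* ECG: a pulse train whose beat-to-beat interval tracks a stage-dependent
  heart rate;
* EMG: broadband noise whose level falls from Wake to REM atonia;
* RESP: a slow breathing oscillation whose envelope collapses during
  injected apnea events occurring at the patient's AHI rate, plus a
  continuous envelope irregularity that grows with AHI severity.

Channels within a modality are noisy copies of the modality source signal.
Survival outcomes follow an exponential proportional-hazards model
lambda_0 * exp(beta' z) on a per-patient latent risk vector z whose first
component is the (standardized log-) AHI, so apnea severity is predictive
of the coupled condition by construction. Censoring is uniform on
[0, follow-up horizon] for a configurable fraction of patients.

Everything is deterministic given (seed, patient_seed).
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .labels import STAGES, SurvivalLabelSet
from .preprocess import CHANNEL_CAPS, Channel, MODALITIES, RawRecording, assign_modalities

EPOCH_SECONDS = 30.0

#: default native sampling rates (Hz) per modality; deliberately
#: heterogeneous so both resampling paths are exercised.
DEFAULT_RATES = {"BAS": 256.0, "ECG": 200.0, "EMG": 256.0, "RESP": 64.0}

DEFAULT_CHANNEL_COUNTS = {"BAS": 4, "ECG": 1, "EMG": 2, "RESP": 3}

_CHANNEL_NAMES = {
    "BAS": ["C3", "C4", "O1", "O2", "F3", "F4", "E1", "E2", "Cz", "Oz"],
    "ECG": ["ECG", "ECG2"],
    "EMG": ["CHIN1", "CHIN2", "LLEG", "RLEG"],
    "RESP": ["THOR", "ABD", "FLOW", "NASAL", "SPO2", "PLETH", "SNORE"],
}

# stage-conditional generator tables, indexed by STAGES order
# (Wake, N1, N2, N3, REM)
BAS_BAND_FREQS = np.array([2.0, 6.0, 10.0, 14.0, 22.0])  # delta..beta, Hz
BAS_BAND_AMPS = np.array([
    [0.20, 0.30, 0.50, 0.20, 1.00],  # Wake: beta-dominant
    [0.40, 1.00, 0.30, 0.20, 0.20],  # N1: theta-dominant
    [0.60, 0.40, 0.20, 1.00, 0.10],  # N2: sigma-dominant (spindle band)
    [1.20, 0.40, 0.15, 0.20, 0.05],  # N3: delta-dominant
    [0.30, 0.50, 1.00, 0.15, 0.30],  # REM: alpha-dominant (synthetic cue)
])
#: index of the designated dominant band per stage (testable contract)
BAS_DOMINANT_BAND = np.argmax(BAS_BAND_AMPS, axis=1)

ECG_STAGE_BPM = np.array([72.0, 66.0, 60.0, 55.0, 76.0])
EMG_STAGE_SD = np.array([1.20, 0.70, 0.50, 0.40, 0.15])

RESP_BREATH_HZ = 0.25
APNEA_MIN_S, APNEA_MAX_S = 10.0, 20.0
APNEA_DEPTH = 0.1  # envelope multiplier during an event

#: AHI ~ lognormal(log(10), 0.8): clinic-like median 10/h with a heavy tail
AHI_LOG_MEDIAN = float(np.log(10.0))
AHI_LOG_SIGMA = 0.8


def default_transition_matrix() -> np.ndarray:
    """Row-stochastic 30-s stage transition matrix with realistic persistence."""
    return np.array([
        [0.90, 0.08, 0.02, 0.00, 0.00],  # Wake
        [0.05, 0.70, 0.23, 0.01, 0.01],  # N1
        [0.02, 0.05, 0.80, 0.08, 0.05],  # N2
        [0.01, 0.02, 0.12, 0.83, 0.02],  # N3
        [0.02, 0.05, 0.08, 0.00, 0.85],  # REM
    ])


@dataclass
class SimConfig:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 16
    duration_hours: float = 1.0
    stage_transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    modality_channel_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_COUNTS))
    native_rates: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    hazard_coefficients: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {"coupled": (1.0, 0.5), "unrelated": (0.0, 0.0)})
    baseline_hazard: float = 5e-4  # events/day
    censor_rate: float = 0.3
    follow_up_days: float = 3650.0
    noise_sd: float = 0.3
    demo_coupling: float = 0.0  # correlation knob between age and latent risk
    seed: int = 0

    def __post_init__(self):
        m = np.asarray(self.stage_transition_matrix, dtype=float)
        if m.shape != (5, 5) or np.any(m < 0):
            raise ValueError("stage_transition_matrix must be a nonnegative 5x5 matrix")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("stage_transition_matrix rows must sum to 1")
        self.stage_transition_matrix = m
        if self.duration_hours <= 0:
            raise ValueError("duration_hours must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if not 0.0 <= self.censor_rate <= 1.0:
            raise ValueError("censor_rate must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for mod, cnt in self.modality_channel_counts.items():
            if mod not in MODALITIES:
                raise ValueError(f"unknown modality {mod}")
            if not 0 <= cnt <= CHANNEL_CAPS[mod]:
                raise ValueError(
                    f"{mod}: channel count {cnt} outside [0, {CHANNEL_CAPS[mod]}]")
        dims = {len(b) for b in self.hazard_coefficients.values()}
        if len(dims) > 1:
            raise ValueError("all hazard coefficient vectors must share a dimension")
        self.z_dim = dims.pop() if dims else 2


@dataclass
class SimRecording:
    """One synthetic recording with its ground-truth annotations.

    ``recording`` may be None when a cohort was simulated with
    ``keep_signals=False``; the signals are regenerated deterministically
    via :func:`cohort_recording` when needed.
    """

    recording: RawRecording | None
    stages: np.ndarray  # (n_epochs,) int indices into STAGES
    ahi: float  # drawn events/hour
    n_apnea_events: int  # events actually injected
    apnea_intervals: list[tuple[float, float]]
    patient_seed: int = 0

    @property
    def stage_labels(self) -> list[str]:
        return [STAGES[s] for s in self.stages]


@dataclass
class SimCohort:
    config: SimConfig
    recordings: list[SimRecording]
    covariates: pd.DataFrame  # patient_id, age, sex, ahi
    z: np.ndarray  # (n, z_dim) latent risk
    survival: SurvivalLabelSet

    @property
    def patient_ids(self) -> list[str]:
        return list(self.covariates["patient_id"])


# ---------------------------------------------------------------------------
# recording-level simulation
# ---------------------------------------------------------------------------


def _simulate_stages(rng: np.random.Generator, transition: np.ndarray,
                     n_epochs: int) -> np.ndarray:
    states = np.empty(n_epochs, dtype=np.int64)
    state = 0  # start awake
    for e in range(n_epochs):
        states[e] = state
        state = rng.choice(5, p=transition[state])
    return states


def _bas_source(rng, t, stage_per_sample):
    phases = rng.uniform(0, 2 * np.pi, size=len(BAS_BAND_FREQS))
    amps = BAS_BAND_AMPS[stage_per_sample]  # (n, bands)
    waves = np.sin(2 * np.pi * BAS_BAND_FREQS[None, :] * t[:, None] + phases[None, :])
    return (amps * waves).sum(axis=1) + 0.05 * rng.standard_normal(len(t))


def _ecg_source(rng, t, rate, stages, duration_s):
    sig = np.zeros(len(t))
    beat = 0.0
    width = 0.04
    half = int(round(3 * width * rate))
    kernel_t = (np.arange(2 * half + 1) - half) / rate
    kernel = np.exp(-0.5 * (kernel_t / width) ** 2)
    while beat < duration_s:
        stage = stages[min(int(beat // EPOCH_SECONDS), len(stages) - 1)]
        idx = int(round(beat * rate))
        lo = max(0, idx - half)
        hi = min(len(sig), idx + half + 1)
        sig[lo:hi] += kernel[lo - (idx - half) : hi - (idx - half)]
        ibi = 60.0 / ECG_STAGE_BPM[stage]
        beat += ibi * (1.0 + 0.04 * rng.standard_normal())
    return sig


def _resp_source(rng, t, ahi, duration_s):
    """Breathing oscillation with AHI-dependent irregularity and apnea drops."""
    phase = rng.uniform(0, 2 * np.pi)
    base = np.sin(2 * np.pi * RESP_BREATH_HZ * t + phase)
    sev = min(ahi / 30.0, 1.5)
    slow = (np.sin(2 * np.pi * 0.015 * t + rng.uniform(0, 2 * np.pi))
            + 0.6 * np.sin(2 * np.pi * 0.037 * t + rng.uniform(0, 2 * np.pi)))
    envelope = 1.0 + 0.35 * sev * slow
    n_events = int(round(ahi * duration_s / 3600.0))
    intervals = []
    for _ in range(n_events):
        dur = rng.uniform(APNEA_MIN_S, APNEA_MAX_S)
        start = rng.uniform(0, max(duration_s - dur, 0.0))
        intervals.append((start, start + dur))
        mask = (t >= start) & (t < start + dur)
        envelope[mask] *= APNEA_DEPTH
    return envelope * base, n_events, intervals


def simulate_recording(config: SimConfig, patient_seed: int,
                       ahi: float | None = None) -> SimRecording:
    """Generate one multichannel recording plus its stage annotations.

    All modalities are driven by the same hidden stage sequence. Channels
    within a modality are noisy copies of the modality source at
    ``noise_sd``. Deterministic given (config.seed, patient_seed).
    """
    rng = np.random.default_rng([config.seed, patient_seed])
    duration_s = config.duration_hours * 3600.0
    n_epochs = int(round(duration_s / EPOCH_SECONDS))
    if n_epochs < 1:
        raise ValueError("recording shorter than one 30-s epoch")
    stages = _simulate_stages(rng, config.stage_transition_matrix, n_epochs)
    if ahi is None:
        ahi = float(np.exp(AHI_LOG_MEDIAN + AHI_LOG_SIGMA * rng.standard_normal()))

    channels: list[Channel] = []
    n_apnea, intervals = 0, []
    for mod in MODALITIES:
        cnt = config.modality_channel_counts.get(mod, 0)
        if cnt == 0:
            continue
        rate = config.native_rates[mod]
        n = int(round(duration_s * rate))
        t = np.arange(n) / rate
        stage_per_sample = stages[np.minimum(
            (t // EPOCH_SECONDS).astype(np.int64), n_epochs - 1)]
        if mod == "BAS":
            source = _bas_source(rng, t, stage_per_sample)
        elif mod == "ECG":
            source = _ecg_source(rng, t, rate, stages, duration_s)
        elif mod == "EMG":
            source = EMG_STAGE_SD[stage_per_sample] * rng.standard_normal(n)
        else:  # RESP
            source, n_apnea, intervals = _resp_source(rng, t, ahi, duration_s)
        for c in range(cnt):
            sig = source + config.noise_sd * rng.standard_normal(n)
            channels.append(Channel(
                label=_CHANNEL_NAMES[mod][c], signal=sig, rate=rate))
    rec = RawRecording(
        channels=channels,
        patient_id=f"P{patient_seed:05d}",
        start_time=datetime.datetime(2000, 1, 1, 22, 0, 0),
    )
    assign_modalities(rec)
    return SimRecording(rec, stages, ahi, n_apnea, intervals,
                        patient_seed=patient_seed)


# ---------------------------------------------------------------------------
# survival simulation
# ---------------------------------------------------------------------------


def simulate_survival(config: SimConfig, z: np.ndarray,
                      patient_ids: list[str] | None = None) -> SurvivalLabelSet:
    """Exponential proportional-hazards outcomes on latent risk z.

    Event times are Exp(lambda_0 * exp(beta' z)) per condition; a
    ``censor_rate`` fraction of patients receives an independent uniform
    censoring time on [0, follow_up_days]. delta = 1 iff the event precedes
    censoring; conditions are independent given z.
    """
    z = np.atleast_2d(np.asarray(z, dtype=float))
    n = z.shape[0]
    if z.shape[1] != config.z_dim:
        raise ValueError(
            f"z has dimension {z.shape[1]}, hazard coefficients expect {config.z_dim}")
    if config.baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    rng = np.random.default_rng([config.seed, 7_919])
    ids = patient_ids or [f"P{i:05d}" for i in range(n)]
    conditions = list(config.hazard_coefficients)
    time = np.empty((n, len(conditions)))
    event = np.empty((n, len(conditions)), dtype=np.int8)
    censored = rng.random(n) < config.censor_rate
    c_time = np.where(censored, rng.uniform(0, config.follow_up_days, n), np.inf)
    for j, cond in enumerate(conditions):
        beta = np.asarray(config.hazard_coefficients[cond], dtype=float)
        rate = config.baseline_hazard * np.exp(z @ beta)
        t_event = rng.exponential(1.0 / rate)
        event[:, j] = (t_event <= c_time).astype(np.int8)
        time[:, j] = np.minimum(t_event, c_time)
    return SurvivalLabelSet(patient_ids=ids, conditions=conditions,
                            time=time, event=event)


# ---------------------------------------------------------------------------
# cohort-level composition
# ---------------------------------------------------------------------------


def simulate_cohort(config: SimConfig, keep_signals: bool = True) -> SimCohort:
    """Full cohort: recordings, stages, AHI, covariates, latent z, survival.

    The first component of z is the standardized log-AHI, so any condition
    with a nonzero first hazard coefficient is predictable from apnea
    severity visible in the respiratory channels.

    With ``keep_signals=False`` the raw channel arrays are released after
    each patient (annotations, AHI and outcomes are kept); use
    :func:`cohort_recording` to regenerate any patient's signals
    bit-identically on demand. This keeps large cohorts within memory.
    """
    if config.n_patients <= 1:
        raise ValueError("a cohort needs at least 2 patients")
    cohort_rng = np.random.default_rng([config.seed, 104_729])
    recordings = []
    z = np.zeros((config.n_patients, config.z_dim))
    ages = np.empty(config.n_patients)
    sexes = np.empty(config.n_patients, dtype=np.int64)
    ahis = np.empty(config.n_patients)
    for i in range(config.n_patients):
        sim = simulate_recording(config, patient_seed=i)
        if not keep_signals:
            sim.recording = None
        recordings.append(sim)
        ahis[i] = sim.ahi
        z[i, 0] = (np.log(sim.ahi) - AHI_LOG_MEDIAN) / AHI_LOG_SIGMA
        if config.z_dim > 1:
            z[i, 1:] = cohort_rng.standard_normal(config.z_dim - 1)
        eps = cohort_rng.standard_normal()
        rho = config.demo_coupling
        ages[i] = np.clip(55 + 12 * (rho * z[i, 0] + np.sqrt(1 - rho**2) * eps), 18, 90)
        sexes[i] = cohort_rng.integers(0, 2)
    ids = [f"P{r.patient_seed:05d}" for r in recordings]
    survival = simulate_survival(config, z, patient_ids=ids)
    if np.any(survival.time <= 0):
        raise AssertionError("survival times must be positive")
    covariates = pd.DataFrame(
        {"patient_id": ids, "age": ages, "sex": sexes, "ahi": ahis})
    return SimCohort(config, recordings, covariates, z, survival)


# ---------------------------------------------------------------------------
# on-disk representation (round-trips with the preprocess readers)
# ---------------------------------------------------------------------------


def write_cohort(cohort: SimCohort, outdir: str | Path) -> Path:
    """Write EDFs, stage CSVs, covariates, survival labels and the config."""
    from .preprocess import write_recording_edf

    outdir = Path(outdir)
    (outdir / "edf").mkdir(parents=True, exist_ok=True)
    (outdir / "stages").mkdir(exist_ok=True)
    for sim in cohort.recordings:
        pid = sim.recording.patient_id
        write_recording_edf(outdir / "edf" / f"{pid}.edf", sim.recording)
        onsets = np.arange(len(sim.stages)) * EPOCH_SECONDS
        pd.DataFrame({
            "epoch_index": np.arange(len(sim.stages)),
            "onset_s": onsets,
            "label": sim.stage_labels,
        }).to_csv(outdir / "stages" / f"{pid}.csv", index=False)
    cohort.covariates.to_csv(outdir / "covariates.csv", index=False)
    cohort.survival.frame().to_csv(outdir / "survival.csv", index=False)
    cfg = cohort.config
    with open(outdir / "config.txt", "w") as fh:
        fh.write(f"n_patients: {cfg.n_patients}\n")
        fh.write(f"duration_hours: {cfg.duration_hours}\n")
        fh.write(f"baseline_hazard: {cfg.baseline_hazard}\n")
        fh.write(f"censor_rate: {cfg.censor_rate}\n")
        fh.write(f"noise_sd: {cfg.noise_sd}\n")
        fh.write(f"seed: {cfg.seed}\n")
    return outdir


def cohort_recording(cohort: SimCohort, index: int) -> RawRecording:
    """The raw recording for one cohort member, regenerated if released."""
    sim = cohort.recordings[index]
    if sim.recording is not None:
        return sim.recording
    regen = simulate_recording(cohort.config, patient_seed=sim.patient_seed)
    return regen.recording
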