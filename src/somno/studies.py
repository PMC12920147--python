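"""Desk-scale reference studies: the package's end-to-end experiments.

Two studies exercise the whole pipeline on synthetic cohorts:

* **Pretraining study** — 16 patients x 1 h, single-channel modalities;
  200 LOO-CL steps at batch 32 must drive the loss well below its random-
  initialization value (~ln 32) and make within-batch cross-modal top-1
  retrieval beat chance by a wide margin.
* **Survival study** — 1,500 patients x 5 min (one pretraining context
  window per recording) at the generator's default channel counts. The
  frozen pretrained encoder embeds every recording; a linear Cox head on
  the concatenated per-modality embeddings plus age/sex is trained on half
  the cohort and evaluated on the other half. The condition whose hazard
  is coupled to apnea severity must show a bootstrap C-index interval
  excluding 0.5; the null condition's interval must not.

Problem sizes are fixed study conditions chosen for a single-CPU desk
budget; see the methods note for rationale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .encoder import SleepEncoder, desk_config
from .heads import fit_survival_head, predict_survival_scores
from .labels import SurvivalLabelSet
from .metrics import BootstrapResult, bootstrap_ci, harrell_c_index
from .preprocess import MODALITIES, tokenize_recording
from .pretrain import build_windows, pretrain_loop, retrieval_top1
from .synthetic import SimConfig, cohort_recording, simulate_cohort

PRETRAIN_STEPS = 200
PRETRAIN_BATCH = 32
SURVIVAL_N = 1500
SURVIVAL_DURATION_H = 1.0 / 12.0  # one 5-min context window per recording


@dataclass
class PretrainStudyResult:
    encoder: SleepEncoder
    initial_loss: float
    final_loss: float
    retrieval_top1: float
    retrieval_chance: float
    loss_trace: list[float] = field(default_factory=list)


def pretraining_study(seed: int = 0, steps: int = PRETRAIN_STEPS,
                      batch_size: int = PRETRAIN_BATCH) -> PretrainStudyResult:
    """Contrastive pretraining on a 16-patient, 1-h synthetic corpus."""
    cfg = SimConfig(n_patients=16, duration_hours=1.0,
                    modality_channel_counts={"BAS": 1, "ECG": 1,
                                             "EMG": 1, "RESP": 1},
                    seed=seed * 13 + 1)
    cohort = simulate_cohort(cfg)
    token_arrays = [tokenize_recording(r.recording) for r in cohort.recordings]
    result = pretrain_loop(token_arrays, desk_config(seed=seed),
                           steps=steps, batch_size=batch_size, seed=seed)
    windows = build_windows(token_arrays)
    rng = np.random.default_rng([seed, 555])
    accs = [retrieval_top1(result.encoder, windows,
                           rng.choice(windows.n_windows, batch_size,
                                      replace=False))
            for _ in range(4)]
    return PretrainStudyResult(
        encoder=result.encoder,
        initial_loss=result.loss_trace[0],
        final_loss=float(np.mean(result.loss_trace[-10:])),
        retrieval_top1=float(np.mean(accs)),
        retrieval_chance=1.0 / batch_size,
        loss_trace=result.loss_trace,
    )


@dataclass
class SurvivalStudyResult:
    c_index: dict[str, BootstrapResult]
    c_true_predictor: float
    n_train: int
    n_eval: int
    n_events_eval: dict[str, int]


def survival_study(encoder: SleepEncoder, seed: int = 0,
                   n_patients: int = SURVIVAL_N,
                   duration_hours: float = SURVIVAL_DURATION_H,
                   n_boot: int = 1000) -> SurvivalStudyResult:
    """Frozen-encoder disease-risk discrimination on a synthetic cohort.

    Recordings are generated, tokenized, embedded and released one at a
    time, so cohort size is not memory-bound.
    """
    cfg = SimConfig(n_patients=n_patients, duration_hours=duration_hours,
                    seed=seed * 17 + 3)
    cohort = simulate_cohort(cfg, keep_signals=False)
    feats = np.empty((n_patients, 128 * len(MODALITIES)), dtype=np.float32)
    for i in range(n_patients):
        rec = cohort_recording(cohort, i)
        emb = encoder.embed_recording(tokenize_recording(rec))
        feats[i] = np.concatenate([emb.pooled[m] for m in MODALITIES])

    rng = np.random.default_rng([seed, 777])
    idx = rng.permutation(n_patients)
    tr, te = idx[: n_patients // 2], idx[n_patients // 2 :]
    age = cohort.covariates["age"].to_numpy(dtype=float)
    age_z = (age - age[tr].mean()) / age[tr].std()
    sex = cohort.covariates["sex"].to_numpy(dtype=float)
    lab = cohort.survival

    def subset(ix):
        return SurvivalLabelSet([lab.patient_ids[i] for i in ix],
                                lab.conditions, lab.time[ix], lab.event[ix])

    fit = fit_survival_head(feats[tr], subset(tr), age_z[tr], sex[tr],
                            epochs=40, lr=1e-2, batch_size=32, seed=seed,
                            weight_decay=1e-4)
    scores = predict_survival_scores(fit.model, feats[te], age_z[te], sex[te])

    results: dict[str, BootstrapResult] = {}
    events = {}
    te_labels = subset(te)
    for j, cond in enumerate(lab.conditions):
        t, e, _ = te_labels.column(cond)
        results[cond] = bootstrap_ci(harrell_c_index, (scores[:, j], e, t),
                                     n_boot=n_boot, seed=seed + 1)
        events[cond] = int((e == 1).sum())
    t_all, e_all, _ = lab.column("coupled")
    beta = np.asarray(cfg.hazard_coefficients["coupled"])
    c_true = harrell_c_index(cohort.z @ beta, e_all, t_all)
    return SurvivalStudyResult(results, float(c_true), len(tr), len(te), events)
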