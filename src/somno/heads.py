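"""Fine-tuning on frozen embeddings: modality fusion, sequence head, and
task outputs (multilabel Cox survival, sleep staging, apnea severity,
sex and age).

The survival objective is the negative log partial likelihood

    L = -(1/N_e) Σ_i δ_i ( h_i - log Σ_{j: t_j >= t_i} exp(h_j) )

with N_e the number of events; ties are handled with the Breslow
convention (risk sets are inclusive, t_j >= t_i). The multilabel extension
computes the loss independently per condition and sums; with cohort-scale
data the loss is evaluated in batches of 32 patients sorted by time in
descending order, which restricts each risk set to the batch.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._autograd import Tensor, concatenate, no_grad
from .labels import STAGES, SurvivalLabelSet

TOKEN_DIM = 128
LSTM_HIDDEN = 64
FUSION_HEADS = 4  # fine-tuning uses four pooling heads


# ---------------------------------------------------------------------------
# CoxPH losses
# ---------------------------------------------------------------------------


def coxph_loss(scores: Tensor, event, time) -> Tensor:
    """Negative log Cox partial likelihood (Breslow ties), 1/N_e scaled.

    Computed with the descending-time sort + cumulative log-sum-exp scheme;
    returns an exact zero (no gradient) when the batch has no events.
    """
    event = np.asarray(event).astype(bool)
    time = np.asarray(time, dtype=float)
    if np.any(time < 0):
        raise ValueError("survival times must be nonnegative")
    n = len(time)
    if n < 2:
        raise ValueError("CoxPH loss needs at least 2 patients")
    n_events = int(event.sum())
    if n_events == 0:
        return Tensor(0.0)
    order = np.argsort(-time, kind="mergesort")  # descending time
    h = scores[order]
    t_sorted = time[order]
    d_sorted = event[order]
    # prefix logsumexp over patients with t >= current; extend each tie
    # group so risk sets are inclusive (Breslow)
    m = float(h.data.max())
    csum = _cumsum((h - Tensor(m)).exp())  # (n,) prefix sums in sorted order
    # index of the last member of each tie group
    last_of_group = np.empty(n, dtype=int)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and t_sorted[j + 1] == t_sorted[i]:
            j += 1
        last_of_group[i : j + 1] = j
        i = j + 1
    log_risk = csum[last_of_group].log() + Tensor(m)
    ev_idx = np.where(d_sorted)[0]
    contrib = h[ev_idx] - log_risk[ev_idx]
    return -contrib.sum() * (1.0 / n_events)


def _cumsum(x: Tensor) -> Tensor:
    data = np.cumsum(x.data)

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.cumsum(g[::-1])[::-1].copy())

    return Tensor._make(data, (x,), backward)


def coxph_loss_reference(scores: np.ndarray, event, time) -> float:
    """O(n^2) brute-force partial likelihood (Breslow), the test oracle."""
    h = np.asarray(scores, dtype=np.float64)
    event = np.asarray(event).astype(bool)
    time = np.asarray(time, dtype=float)
    ne = int(event.sum())
    if ne == 0:
        return 0.0
    total = 0.0
    for i in range(len(h)):
        if not event[i]:
            continue
        risk = h[time >= time[i]]
        total += h[i] - np.log(np.exp(risk).sum())
    return float(-total / ne)


def multilabel_coxph_loss(scores: Tensor, labels: SurvivalLabelSet,
                          batch_size: int | None = None,
                          permutation: np.ndarray | None = None) -> Tensor:
    """Sum of per-condition CoxPH losses, optionally batch-restricted.

    With ``batch_size`` set, patients are partitioned into consecutive
    minibatches of that size (after the optional ``permutation``); each
    batch's per-label losses — risk sets restricted to the batch, patients
    sorted by time in descending order inside :func:`coxph_loss` for the
    cumulative computation — are summed over labels, and the batch losses
    are averaged. ``batch_size=None`` evaluates the exact full-cohort sum.
    Conditions with zero in-scope events contribute zero. Excluded
    (prevalent) patients are left out of the corresponding condition's
    loss.
    """
    n, L = scores.data.shape
    if L != len(labels.conditions):
        raise ValueError(
            f"scores have {L} columns, labels {len(labels.conditions)} conditions")
    if n != labels.n_patients:
        raise ValueError("scores and labels disagree on patient count")

    def one_span(idx: np.ndarray) -> Tensor:
        parts = []
        for j in range(L):
            ev = labels.event[idx, j]
            keep = ev >= 0
            if keep.sum() < 2 or (ev == 1).sum() == 0:
                continue
            sub = idx[keep]
            parts.append(coxph_loss(scores[sub, j], labels.event[sub, j],
                                    labels.time[sub, j]))
        if not parts:
            return Tensor(0.0)
        out = parts[0]
        for p in parts[1:]:
            out = out + p
        return out

    if batch_size is None or batch_size >= n:
        return one_span(np.arange(n))
    order = np.arange(n) if permutation is None else np.asarray(permutation)
    batch_losses = []
    for lo in range(0, n, batch_size):
        idx = order[lo : lo + batch_size]
        if len(idx) < 2:
            continue
        batch_losses.append(one_span(idx))
    total = batch_losses[0]
    for b in batch_losses[1:]:
        total = total + b
    return total * (1.0 / len(batch_losses))


# ---------------------------------------------------------------------------
# architecture heads
# ---------------------------------------------------------------------------


class ModalityFusion(_nn.Module):
    """Attention pooling across the modality axis per token.

    One transformer-encoder layer (four heads) contextualizes the (up to
    four) modality embeddings of each 5-s token, followed by a masked mean;
    output is invariant to modality order and to absent-modality content.
    """

    def __init__(self, rng, ffn_width: int = 2048, dropout: float = 0.3):
        super().__init__()
        self.layer = _nn.TransformerEncoderLayer(
            rng, TOKEN_DIM, FUSION_HEADS, ffn_width, dropout)

    def forward(self, x: Tensor, modality_mask: np.ndarray) -> Tensor:
        """x (B', M, D), mask (B', M) -> (B', D)."""
        if not modality_mask.any(axis=1).all():
            raise ValueError("a token with zero present modalities cannot be fused")
        h = self.layer(x, key_padding_mask=modality_mask)
        m = modality_mask.astype(h.data.dtype)
        w = m / m.sum(axis=1, keepdims=True)
        return (h * Tensor(w[:, :, None])).sum(axis=1)


def fuse_modalities(fusion: ModalityFusion, patient: "PatientTensor") -> Tensor:
    """(M, S, 128) with modality mask -> (S, 128)."""
    emb = patient.embeddings  # (M, S, D)
    m, s, d = emb.shape
    pres = patient.modality_mask
    if not pres.any():
        raise ValueError("patient has no present modality")
    x = Tensor(np.ascontiguousarray(emb.transpose(1, 0, 2)))  # (S, M, D)
    mask = np.repeat(pres[None, :], s, axis=0)
    return fusion(x, mask)


@dataclass
class PatientTensor:
    """Standardized per-patient input to the fine-tuning heads."""

    embeddings: np.ndarray  # (M, S, 128); absent modalities zero
    modality_mask: np.ndarray  # (M,)
    token_mask: np.ndarray  # (S,)
    age_z: float = 0.0
    sex: int = 0
    patient_id: str = ""

    def __post_init__(self):
        if self.embeddings.ndim != 3 or self.embeddings.shape[2] != TOKEN_DIM:
            raise ValueError("embeddings must be (M, S, 128)")


class SequenceHead(_nn.Module):
    """Two-layer bidirectional LSTM (hidden 64 -> 128 per token) plus
    masked temporal mean pooling over valid timesteps.

    Padded tokens form a suffix (context standardization pads at the end),
    so the recurrence runs over the valid prefix only; per-token outputs at
    padded positions are zero and never influence the pooled state.
    """

    def __init__(self, rng):
        super().__init__()
        self.lstm = _nn.BiLSTM(rng, TOKEN_DIM, LSTM_HIDDEN, n_layers=2)

    def forward(self, fused: Tensor, token_mask: np.ndarray) -> tuple[Tensor, Tensor]:
        s, d = fused.data.shape
        n_valid = int(token_mask.sum())
        if n_valid == 0:
            raise ValueError("sequence head needs at least one valid token")
        if not token_mask[:n_valid].all():
            raise ValueError("token mask must be a valid prefix (padding is a suffix)")
        states = self.lstm(fused[:n_valid, :].reshape(1, n_valid, d))[0]
        pooled = states.mean(axis=0)
        if n_valid < s:
            pad = Tensor(np.zeros((s - n_valid, states.data.shape[1]),
                                  dtype=states.data.dtype))
            states = concatenate([states, pad], axis=0)
        return states, pooled


class SurvivalHead(_nn.Module):
    """Linear map from pooled state (+ age, sex) to per-condition log-hazards."""

    def __init__(self, rng, n_conditions: int, in_dim: int = TOKEN_DIM,
                 demographics: bool = True):
        super().__init__()
        self.demographics = demographics
        self.linear = _nn.Linear(rng, in_dim + (2 if demographics else 0),
                                 n_conditions)

    def forward(self, pooled: Tensor, age_z=None, sex=None) -> Tensor:
        if self.demographics:
            if age_z is None or sex is None:
                raise ValueError("demographics-enabled head requires age and sex")
            demo = Tensor(np.stack([np.atleast_1d(age_z),
                                    np.atleast_1d(sex)], axis=-1)
                          .astype(pooled.data.dtype))
            if pooled.data.ndim == 1:
                pooled = pooled.reshape(1, -1)
            x = concatenate([pooled, demo], axis=-1)
        else:
            x = pooled if pooled.data.ndim == 2 else pooled.reshape(1, -1)
        return self.linear(x)


class StagingHead(_nn.Module):
    """Per-token linear classifier over the five sleep stages."""

    def __init__(self, rng, in_dim: int = TOKEN_DIM):
        super().__init__()
        self.linear = _nn.Linear(rng, in_dim, len(STAGES))

    def forward(self, states: Tensor) -> Tensor:
        if states.data.ndim < 2:
            raise ValueError("staging head needs per-token states")
        return self.linear(states)


class PooledClassifierHead(_nn.Module):
    """Linear head on the pooled state (apnea severity: 4 logits;
    sex: 1 logit; age: 1 regression output)."""

    def __init__(self, rng, n_out: int, in_dim: int = TOKEN_DIM):
        super().__init__()
        self.linear = _nn.Linear(rng, in_dim, n_out)

    def forward(self, pooled: Tensor) -> Tensor:
        if pooled.data.ndim == 1:
            pooled = pooled.reshape(1, -1)
        return self.linear(pooled)


class DemographicsMLP(_nn.Module):
    """Demographics-only baseline: shallow MLP 4 -> 128 -> out."""

    def __init__(self, rng, n_out: int, n_in: int = 4):
        super().__init__()
        self.fc1 = _nn.Linear(rng, n_in, 128)
        self.fc2 = _nn.Linear(rng, 128, n_out)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


def cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy over rows; targets are integer class indices."""
    n = logits.data.shape[0]
    log_z = logits.logsumexp(axis=-1)
    idx = (np.arange(n), np.asarray(targets, dtype=int))
    return (log_z - logits[idx]).mean()


def mae_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    diff = pred.reshape(-1) - Tensor(np.asarray(target, dtype=float))
    return ((diff * diff + Tensor(1e-12)) ** 0.5).mean()


# ---------------------------------------------------------------------------
# training helpers on frozen embeddings
# ---------------------------------------------------------------------------


def encoder_checksum(encoder) -> str:
    """Digest of all encoder weights; fine-tuning must never change it."""
    h = hashlib.sha256()
    for k in sorted(encoder.state_dict()):
        h.update(k.encode())
        h.update(np.ascontiguousarray(encoder.state_dict()[k]).tobytes())
    return h.hexdigest()


@dataclass
class TrainResult:
    model: _nn.Module
    loss_trace: list[float] = field(default_factory=list)


def fit_survival_head(features: np.ndarray, labels: SurvivalLabelSet,
                      age_z: np.ndarray | None = None,
                      sex: np.ndarray | None = None,
                      demographics: bool = True,
                      epochs: int = 30, lr: float = 1e-2,
                      batch_size: int | None = 32,
                      seed: int = 0,
                      weight_decay: float = 0.0) -> TrainResult:
    """Train a linear multilabel Cox head on fixed per-patient features.

    ``features``: (n, d) pooled representations (frozen-encoder outputs or,
    for recovery studies, the true latent risk). The head minimizes the
    batch-restricted multilabel CoxPH loss with Adam.
    """
    n, d = features.shape
    rng = np.random.default_rng([seed, 31])
    head = SurvivalHead(rng, len(labels.conditions), in_dim=d,
                        demographics=demographics)
    opt = _nn.Adam(head.parameters(), lr=lr)
    x = features.astype(np.float32)
    trace = []
    for _ in range(epochs):
        if demographics:
            scores = head(Tensor(x), age_z, sex)
        else:
            scores = head(Tensor(x))
        perm = rng.permutation(n) if batch_size else None
        loss = multilabel_coxph_loss(scores, labels, batch_size=batch_size,
                                     permutation=perm)
        if weight_decay:
            loss = loss + Tensor(weight_decay) * (head.linear.weight ** 2).sum()
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append(float(loss.data))
    return TrainResult(head, trace)


def predict_survival_scores(head: SurvivalHead, features: np.ndarray,
                            age_z=None, sex=None) -> np.ndarray:
    with no_grad():
        if head.demographics:
            return head(Tensor(features.astype(np.float32)), age_z, sex).data
        return head(Tensor(features.astype(np.float32))).data
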