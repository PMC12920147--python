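"""Leave-one-out contrastive (LOO-CL) pretraining.

For each sample k and modality i in a batch of N samples, the target is the
leave-one-out representation x̄_k^{-i}: the mean of the *other* present
modalities' pooled embeddings. The loss for the (i, k) term is

    L_{i,k} = -log  exp(sim(x_k^i, x̄_k^{-i}) / τ)
                    ------------------------------------
                    Σ_{m=1..N} exp(sim(x_k^i, x̄_m^{-i}) / τ)

with sim = cosine similarity on unit-normalized vectors and temperature τ.
The reported loss is the mean of L_{i,k} over all contributing (i, k):
a modality missing for a sample is excluded both as a query and from other
modalities' leave-one-out means. Only the modality-as-query direction is
used, matching the definition; a symmetrized variant is not implemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._autograd import Tensor, concatenate, no_grad
from .encoder import EncoderConfig, SleepEncoder
from .preprocess import MODALITIES, TOKEN_LEN, TokenArray

_EPS = 1e-12


def loo_average(embeddings: np.ndarray, presence: np.ndarray,
                modality_index: int, sample_index: int) -> np.ndarray:
    """x̄_k^{-i}: mean of sample k's embeddings over present modalities != i."""
    emb = np.asarray(embeddings, dtype=float)
    pres = np.asarray(presence, dtype=bool)
    others = [m for m in range(emb.shape[1])
              if m != modality_index and pres[sample_index, m]]
    if not others:
        raise ValueError(
            f"sample {sample_index}: no other modality present; the sample "
            f"cannot contribute to modality {modality_index}'s loss")
    return emb[sample_index, others].mean(axis=0)


def _normalize(x: Tensor, axis: int = -1) -> Tensor:
    norm = ((x * x).sum(axis=axis, keepdims=True) + Tensor(_EPS)) ** 0.5
    return x / norm


def loo_cl_loss(embeddings: Tensor, presence: np.ndarray | None = None,
                tau: float = 0.1) -> Tensor:
    """Mean LOO-CL loss over contributing (modality, sample) terms.

    ``embeddings``: (N, M, D) pooled modality embeddings. ``presence``:
    (N, M) booleans; absent modalities are excluded as queries and from
    leave-one-out means. Differentiable; raises for tau <= 0 or N < 2.
    """
    if tau <= 0:
        raise ValueError("temperature tau must be positive")
    n, m, d = embeddings.data.shape
    if n < 2:
        raise ValueError("a contrastive batch needs at least 2 samples")
    if presence is None:
        presence = np.ones((n, m), dtype=bool)
    presence = np.asarray(presence, dtype=bool)
    pres_f = presence.astype(embeddings.data.dtype)
    counts = presence.sum(axis=1)  # present modalities per sample

    emb = embeddings * Tensor(pres_f[:, :, None])
    total = emb.sum(axis=1)  # (N, D)

    losses = []
    inv_tau = 1.0 / tau
    for i in range(m):
        others = counts - presence[:, i]  # per-sample count excluding i
        target_ok = others >= 1
        query_ok = presence[:, i] & target_ok
        if not query_ok.any():
            continue
        denom = np.maximum(others, 1).astype(embeddings.data.dtype)
        loo = (total - emb[:, i, :]) * Tensor((1.0 / denom)[:, None])  # (N, D)
        q = _normalize(embeddings[:, i, :])
        t = _normalize(loo)
        sims = (q @ t.swapaxes(0, 1)) * inv_tau  # (N queries, N targets)
        # targets with no constituent modality carry no meaning; exclude
        # them from every query's denominator
        col_invalid = ~target_ok
        if col_invalid.any():
            sims = sims.masked_fill(
                np.broadcast_to(col_invalid[None, :], sims.data.shape), -1e30)
        log_denom = sims.logsumexp(axis=1)  # (N,)
        diag = (q * t).sum(axis=1) * inv_tau
        term = log_denom - diag
        losses.append(term[np.where(query_ok)[0]])
    if not losses:
        raise ValueError("no (modality, sample) term has a contrastive target")
    all_terms = concatenate(losses, axis=0)
    return all_terms.mean()


def loo_cl_loss_reference(embeddings: np.ndarray,
                          presence: np.ndarray | None = None,
                          tau: float = 0.1) -> float:
    """Independent scalar implementation of the same definition.

    Plain double loops over samples and modalities; used as the oracle the
    vectorized loss is checked against.
    """
    emb = np.asarray(embeddings, dtype=np.float64)
    n, m, _ = emb.shape
    if presence is None:
        presence = np.ones((n, m), dtype=bool)

    def cos(a, b):
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b) + _EPS))

    terms = []
    for i in range(m):
        for k in range(n):
            if not presence[k, i]:
                continue
            try:
                target_k = loo_average(emb, presence, i, k)
            except ValueError:
                continue
            num = np.exp(cos(emb[k, i], target_k) / tau)
            den = 0.0
            for m2 in range(n):
                try:
                    target_m = loo_average(emb, presence, i, m2)
                except ValueError:
                    continue
                den += np.exp(cos(emb[k, i], target_m) / tau)
            terms.append(-np.log(num / den))
    if not terms:
        raise ValueError("no contributing terms")
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


@dataclass
class PretrainWindows:
    """Non-overlapping 5-min windows pooled across a token-array corpus."""

    tokens: dict[str, np.ndarray]  # modality -> (W, C, 60, 640)
    window_ids: list[tuple[str, int]]  # (patient_id, window index)

    @property
    def n_windows(self) -> int:
        return len(self.window_ids)


def build_windows(token_arrays: list[TokenArray],
                  window_tokens: int = 60) -> PretrainWindows:
    """Cut each recording into full non-overlapping context windows."""
    mods = set()
    for ta in token_arrays:
        mods.update(ta.modalities)
    mods = [m for m in MODALITIES if m in mods]
    if len(mods) < 2:
        raise ValueError("contrastive pretraining needs >= 2 modalities")
    per_mod: dict[str, list[np.ndarray]] = {m: [] for m in mods}
    ids = []
    for ta in token_arrays:
        n_win = ta.n_tokens // window_tokens
        for w in range(n_win):
            lo = w * window_tokens
            if not ta.token_mask[lo : lo + window_tokens].all():
                continue
            ids.append((ta.patient_id, w))
            for mod in mods:
                if ta.present(mod):
                    per_mod[mod].append(
                        ta.data[mod][:, lo : lo + window_tokens, :])
                else:
                    per_mod[mod].append(None)
    if not ids:
        raise ValueError("corpus contains no full context window")
    stacked = {}
    for mod in mods:
        chunks = per_mod[mod]
        c_max = max(c.shape[0] for c in chunks if c is not None)
        arr = np.zeros((len(ids), c_max, window_tokens, TOKEN_LEN), dtype=np.float32)
        for i, c in enumerate(chunks):
            if c is not None:
                arr[i, : c.shape[0]] = c
        stacked[mod] = arr
    return PretrainWindows(stacked, ids)


@dataclass
class PretrainResult:
    encoder: SleepEncoder
    loss_trace: list[float] = field(default_factory=list)
    tau: float = 0.1

    @property
    def initial_loss(self) -> float:
        return self.loss_trace[0]

    @property
    def final_loss(self) -> float:
        return float(np.mean(self.loss_trace[-10:]))


def batch_modality_embeddings(encoder: SleepEncoder,
                              windows: PretrainWindows,
                              idx: np.ndarray) -> tuple[Tensor, np.ndarray]:
    """Pooled (B, M, 128) embeddings for the selected windows."""
    embs = []
    presence = []
    for mod in MODALITIES:
        if mod not in windows.tokens:
            continue
        tokens = windows.tokens[mod][idx]
        emb = encoder.encode_tokens(Tensor(tokens), mod)
        seq = encoder.pool_channels(emb, mod)
        seq = encoder.temporal_context(seq)
        embs.append(encoder.pool_time(seq))
        presence.append(np.ones(len(idx), dtype=bool))
    stacked = _nn.concatenate(
        [e.reshape(e.data.shape[0], 1, e.data.shape[1]) for e in embs], axis=1)
    return stacked, np.stack(presence, axis=1)


def pretrain_loop(token_arrays: list[TokenArray],
                  config: EncoderConfig | None = None,
                  steps: int = 200,
                  batch_size: int = 32,
                  lr: float = 1e-3,
                  tau: float = 0.1,
                  seed: int = 0,
                  grad_clip: float = 1.0,
                  log_every: int = 1) -> PretrainResult:
    """Adam-optimized LOO-CL pretraining on 5-min windows.

    Windows are shuffled each epoch under ``seed``; one optimizer step per
    batch with gradient-norm clipping. The loss trace records every step.
    """
    windows = build_windows(token_arrays)
    encoder = SleepEncoder(config)
    encoder.train()
    opt = _nn.Adam(encoder.parameters(), lr=lr)
    rng = np.random.default_rng(seed)
    trace: list[float] = []
    order = np.array([], dtype=int)
    pos = 0
    for step in range(steps):
        if pos + batch_size > len(order):
            order = rng.permutation(windows.n_windows)
            pos = 0
        idx = order[pos : pos + batch_size]
        pos += batch_size
        emb, presence = batch_modality_embeddings(encoder, windows, idx)
        loss = loo_cl_loss(emb, presence, tau=tau)
        opt.zero_grad()
        loss.backward()
        _nn.clip_grad_norm(encoder.parameters(), grad_clip)
        opt.step()
        trace.append(float(loss.data))
    return PretrainResult(encoder, trace, tau)


def retrieval_top1(encoder: SleepEncoder, windows: PretrainWindows,
                   idx: np.ndarray, tau: float = 0.1) -> float:
    """Cross-modal top-1 retrieval within a batch.

    For every (query modality, sample), the positive is the sample's own
    leave-one-out target; retrieval succeeds when that target has the
    highest similarity among all batch targets. Chance is 1/len(idx).
    """
    was_training = encoder.training
    encoder.eval()
    try:
        with no_grad():
            emb, presence = batch_modality_embeddings(encoder, windows, idx)
    finally:
        encoder.train(was_training)
    e = emb.data
    n, m, d = e.shape
    hits, total = 0, 0
    for i in range(m):
        mask = presence[:, i]
        others = presence.sum(axis=1) - presence[:, i]
        loo = (e * presence[:, :, None]).sum(axis=1) - e[:, i, :]
        loo = loo / np.maximum(others, 1)[:, None]
        q = e[:, i, :] / (np.linalg.norm(e[:, i, :], axis=1, keepdims=True) + _EPS)
        t = loo / (np.linalg.norm(loo, axis=1, keepdims=True) + _EPS)
        sims = q @ t.T
        sims[:, others < 1] = -np.inf
        pred = sims.argmax(axis=1)
        ok = mask & (others >= 1)
        hits += int((pred[ok] == np.where(ok)[0]).sum())
        total += int(ok.sum())
    return hits / total if total else float("nan")
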