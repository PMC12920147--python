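"""Signal preprocessing: heterogeneous raw PSG recordings to token arrays.

The pipeline is fixed: resample each channel to 128 Hz (zero-phase 4th-order
Butterworth anti-aliasing before downsampling, linear interpolation when
upsampling), z-score per channel over the whole recording, group channels
into the four modalities with per-modality caps, and segment into
non-overlapping 5-s tokens of 640 samples. A 9-h context standardization
(crop/zero-pad to 6,480 tokens) is applied before fine-tuning.
"""

from __future__ import annotations

import datetime
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from ._edf import EdfSignal, read_edf as _read_edf_file

TARGET_RATE = 128.0
TOKEN_LEN = 640  # samples per 5-s token at 128 Hz
TOKEN_SECONDS = TOKEN_LEN / TARGET_RATE
MODALITIES = ("BAS", "ECG", "EMG", "RESP")
CHANNEL_CAPS = {"BAS": 10, "ECG": 2, "EMG": 4, "RESP": 7}
TOKENS_PER_HOUR = int(3600 * TARGET_RATE / TOKEN_LEN)  # 720
CONTEXT_HOURS = 9.0
CONTEXT_TOKENS = int(CONTEXT_HOURS * TOKENS_PER_HOUR)  # 6480

# Canonical channel-alias table: alias -> (modality, canonical_rank).
# Rank fixes the deterministic within-modality order used for cap truncation.
_DEFAULT_ALIASES: list[tuple[str, str, int]] = [
    ("F3", "BAS", 0), ("F4", "BAS", 1), ("C3", "BAS", 2), ("C4", "BAS", 3),
    ("CZ", "BAS", 4), ("O1", "BAS", 5), ("O2", "BAS", 6), ("OZ", "BAS", 7),
    ("E1", "BAS", 8), ("E2", "BAS", 9), ("F7", "BAS", 10), ("F8", "BAS", 11),
    ("EOG-L", "BAS", 12), ("EOG-R", "BAS", 13),
    ("ECG", "ECG", 0), ("ECG2", "ECG", 1), ("ECG-II", "ECG", 2),
    ("CHIN1", "EMG", 0), ("CHIN2", "EMG", 1), ("LLEG", "EMG", 2),
    ("RLEG", "EMG", 3), ("EMG", "EMG", 4),
    ("THOR", "RESP", 0), ("ABD", "RESP", 1), ("FLOW", "RESP", 2),
    ("NASAL", "RESP", 3), ("SPO2", "RESP", 4), ("PLETH", "RESP", 5),
    ("SNORE", "RESP", 6),
]


def default_alias_table() -> pd.DataFrame:
    """Channel alias table as (alias, modality, canonical_rank) rows."""
    return pd.DataFrame(_DEFAULT_ALIASES, columns=["alias", "modality", "canonical_rank"])


def load_alias_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"alias", "modality", "canonical_rank"}
    if not required.issubset(df.columns):
        raise ValueError(f"alias table must have columns {sorted(required)}")
    return df


def _alias_lookup(table: pd.DataFrame) -> dict[str, tuple[str, int]]:
    return {
        str(r.alias).upper(): (str(r.modality), int(r.canonical_rank))
        for r in table.itertuples()
    }


@dataclass
class Channel:
    label: str
    signal: np.ndarray
    rate: float
    modality: str | None = None
    canonical_rank: int = 10_000


@dataclass
class RawRecording:
    """Per-channel signals with native rates and modality assignments."""

    channels: list[Channel]
    patient_id: str
    start_time: datetime.datetime = datetime.datetime(2000, 1, 1)

    def __post_init__(self):
        for ch in self.channels:
            if ch.rate <= 0:
                raise ValueError(f"channel {ch.label}: rate must be positive")

    def duration_hours(self) -> float:
        return max(len(c.signal) / c.rate for c in self.channels) / 3600.0


@dataclass
class TokenArray:
    """Per-modality (C x S x 640) token tensors with validity masks.

    ``token_mask`` is shared across modalities (S is aligned); masked-out
    tokens are zero. Absent modalities have C = 0 and ``present`` False.
    """

    data: dict[str, np.ndarray]
    channel_labels: dict[str, list[str]]
    token_mask: np.ndarray
    patient_id: str = ""
    channel_masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.channel_masks:
            self.channel_masks = {
                m: np.ones(self.data[m].shape[0], dtype=bool) for m in self.data
            }

    @property
    def n_tokens(self) -> int:
        return len(self.token_mask)

    def present(self, modality: str) -> bool:
        return modality in self.data and self.data[modality].shape[0] > 0

    @property
    def modalities(self) -> list[str]:
        return [m for m in MODALITIES if self.present(m)]


# ---------------------------------------------------------------------------
# core operations
# ---------------------------------------------------------------------------


def resample_to_common_rate(signal: np.ndarray, rate: float,
                            target: float = TARGET_RATE,
                            label: str = "") -> np.ndarray:
    """Resample one channel to the common 128-Hz grid.

    Downsampling first applies a zero-phase fourth-order low-pass Butterworth
    filter with cutoff 0.9 x target Nyquist, then interpolates onto the new
    grid; upsampling uses plain linear interpolation. Output length is
    ``round(len(signal) * target / rate)``.
    """
    if rate <= 0:
        raise ValueError(f"channel {label!r}: sampling rate must be positive")
    signal = np.asarray(signal, dtype=np.float64)
    if not np.all(np.isfinite(signal)):
        raise ValueError(f"channel {label!r}: non-finite samples")
    n = len(signal)
    m = int(round(n * target / rate))
    if rate == target:
        return signal.copy()
    if rate > target:
        cutoff = 0.9 * (target / 2.0)
        b, a = butter(4, cutoff / (rate / 2.0), btype="low")
        padlen = 3 * (max(len(a), len(b)) - 1)
        if n <= padlen:
            raise ValueError(
                f"channel {label!r}: {n} samples is shorter than the "
                f"anti-aliasing filter warm-up ({padlen + 1} samples)"
            )
        signal = filtfilt(b, a, signal)
    t_old = np.arange(n) / rate
    t_new = np.arange(m) / target
    return np.interp(t_new, t_old, signal)


def standardize(signal: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Z-score to zero mean, unit variance; constant signals map to zeros."""
    signal = np.asarray(signal, dtype=np.float64)
    if signal.size == 0:
        raise ValueError("cannot standardize an empty signal")
    if signal.size < 2:
        raise ValueError("standardization requires at least 2 samples")
    mu = signal.mean()
    sd = signal.std()
    if sd < eps:
        return np.zeros_like(signal)
    return (signal - mu) / sd


def group_modalities(recording: RawRecording,
                     caps: dict[str, int] | None = None) -> dict[str, list[Channel]]:
    """Group channels by modality in canonical order, truncated at the caps."""
    caps = caps or CHANNEL_CAPS
    known = [c for c in recording.channels if c.modality in MODALITIES]
    if not known:
        raise ValueError(
            f"recording {recording.patient_id}: no channel has a known modality"
        )
    dropped = [c.label for c in recording.channels if c.modality not in MODALITIES]
    if dropped:
        warnings.warn(f"dropping channels with unknown modality: {dropped}")
    groups: dict[str, list[Channel]] = {m: [] for m in MODALITIES}
    for ch in known:
        groups[ch.modality].append(ch)
    for m in MODALITIES:
        groups[m].sort(key=lambda c: (c.canonical_rank, c.label))
        groups[m] = groups[m][: caps[m]]
    return groups


def segment_tokens(signal: np.ndarray, token_len: int = TOKEN_LEN) -> np.ndarray:
    """Split a 128-Hz signal into non-overlapping (S x 640) tokens.

    The trailing remainder shorter than one token is dropped. Signals
    shorter than one token yield S = 0 with a warning.
    """
    signal = np.asarray(signal, dtype=np.float64)
    s = len(signal) // token_len
    if s == 0:
        warnings.warn(f"signal of {len(signal)} samples yields zero tokens")
        return np.empty((0, token_len))
    return signal[: s * token_len].reshape(s, token_len)


def tokenize_recording(recording: RawRecording,
                       alias_table: pd.DataFrame | None = None,
                       caps: dict[str, int] | None = None) -> TokenArray:
    """Full pipeline: resample -> standardize -> group -> segment.

    The order is contractual: z-scoring uses whole-recording statistics after
    resampling, and segmentation happens last so every token is drawn from
    the standardized signal.
    """
    if alias_table is not None:
        assign_modalities(recording, alias_table)
    groups = group_modalities(recording, caps)
    per_mod_tokens: dict[str, list[np.ndarray]] = {}
    labels: dict[str, list[str]] = {}
    s_values = []
    for m in MODALITIES:
        toks = []
        labs = []
        for ch in groups[m]:
            x = resample_to_common_rate(ch.signal, ch.rate, label=ch.label)
            x = standardize(x)
            t = segment_tokens(x)
            toks.append(t)
            labs.append(ch.label)
        if toks:
            s_min = min(t.shape[0] for t in toks)
            s_values.append(s_min)
        per_mod_tokens[m] = toks
        labels[m] = labs
    if not s_values:
        raise ValueError("no tokenizable channels")
    s_common = min(s_values)
    data = {}
    for m in MODALITIES:
        toks = per_mod_tokens[m]
        if toks:
            data[m] = np.stack([t[:s_common] for t in toks], axis=0)
        else:
            data[m] = np.empty((0, s_common, TOKEN_LEN))
    return TokenArray(
        data=data,
        channel_labels=labels,
        token_mask=np.ones(s_common, dtype=bool),
        patient_id=recording.patient_id,
    )


def standardize_context(tokens: TokenArray,
                        target_hours: float = CONTEXT_HOURS) -> TokenArray:
    """Crop or zero-pad the token axis to the standardized context length.

    Longer recordings keep their initial segment; shorter ones are padded
    with zero tokens whose token-mask entries are False.
    """
    target_s = int(round(target_hours * TOKENS_PER_HOUR))
    s = tokens.n_tokens
    data = {}
    for m, arr in tokens.data.items():
        c = arr.shape[0]
        if s >= target_s:
            data[m] = arr[:, :target_s, :].copy()
        else:
            out = np.zeros((c, target_s, TOKEN_LEN), dtype=arr.dtype)
            out[:, :s, :] = arr
            data[m] = out
    if s >= target_s:
        mask = tokens.token_mask[:target_s].copy()
    else:
        mask = np.zeros(target_s, dtype=bool)
        mask[:s] = tokens.token_mask
    return TokenArray(
        data=data,
        channel_labels={m: list(v) for m, v in tokens.channel_labels.items()},
        token_mask=mask,
        patient_id=tokens.patient_id,
        channel_masks={m: v.copy() for m, v in tokens.channel_masks.items()},
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def assign_modalities(recording: RawRecording,
                      alias_table: pd.DataFrame | None = None) -> RawRecording:
    """Assign modality and canonical rank to channels via the alias table."""
    lookup = _alias_lookup(alias_table if alias_table is not None else default_alias_table())
    for ch in recording.channels:
        key = ch.label.upper().strip()
        if key in lookup:
            ch.modality, ch.canonical_rank = lookup[key]
    return recording


def read_recording_edf(path: str | Path,
                       alias_table: pd.DataFrame | None = None,
                       patient_id: str | None = None) -> RawRecording:
    """Read one EDF file into a RawRecording with modality assignment."""
    signals, start = _read_edf_file(path)
    channels = [Channel(s.label, s.data, s.rate) for s in signals]
    rec = RawRecording(
        channels=channels,
        patient_id=patient_id or Path(path).stem,
        start_time=start,
    )
    return assign_modalities(rec, alias_table)


def write_recording_edf(path: str | Path, recording: RawRecording) -> None:
    from ._edf import write_edf

    sigs = [EdfSignal(c.label, c.signal, c.rate) for c in recording.channels]
    write_edf(path, sigs, start=recording.start_time, patient_id=recording.patient_id)
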