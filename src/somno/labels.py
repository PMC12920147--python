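"""Supervised targets: phecode survival labels, AHI severity, stage tokens.

Disease labels are derived from ICD event tables via a user-supplied
ICD-to-phecode mapping. A phecode's timestamp is the earliest of its mapped
ICD dates per patient; a patient is a positive (incident) case for a
condition only when that first instance falls more than seven days after
the sleep study, patients with earlier instances are excluded for that
condition (prevalent disease), and conditions below a prevalence threshold
are dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

STAGES = ("Wake", "N1", "N2", "N3", "REM")
STAGE_TO_INDEX = {s: i for i, s in enumerate(STAGES)}

#: Rechtschaffen & Kales and shorthand names mapped onto the AASM scheme;
#: R&K stages 3 and 4 merge into N3.
_STAGE_SYNONYMS = {
    "WAKE": "Wake", "W": "Wake", "0": "Wake",
    "N1": "N1", "1": "N1", "S1": "N1",
    "N2": "N2", "2": "N2", "S2": "N2",
    "N3": "N3", "3": "N3", "S3": "N3", "4": "N3", "S4": "N3", "N4": "N3",
    "REM": "REM", "R": "REM", "5": "REM",
}

TOKENS_PER_EPOCH = 6  # 30-s epochs over 5-s tokens

APNEA_CLASSES = ("none", "mild", "moderate", "severe")


def normalize_stage(label: str) -> str:
    key = str(label).strip().upper()
    if key not in _STAGE_SYNONYMS:
        raise ValueError(f"unrecognized sleep-stage label {label!r}")
    return _STAGE_SYNONYMS[key]


@dataclass
class SurvivalLabelSet:
    """Per patient x condition event indicators and times (days).

    ``event`` entries: 1 event, 0 censored, -1 excluded for that condition
    (prevalent disease). ``time`` is days from the sleep study to the event
    (event == 1) or to censoring (event == 0).
    """

    patient_ids: list[str]
    conditions: list[str]
    time: np.ndarray  # (n, L) float days
    event: np.ndarray  # (n, L) int8

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=np.int8)
        n, L = len(self.patient_ids), len(self.conditions)
        if self.time.shape != (n, L) or self.event.shape != (n, L):
            raise ValueError("time/event shape must be (n_patients, n_conditions)")
        valid = self.event >= 0
        if np.any(self.time[valid] <= 0):
            raise ValueError("retained survival times must be positive")

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def n_events(self, condition: str) -> int:
        j = self.conditions.index(condition)
        return int((self.event[:, j] == 1).sum())

    def column(self, condition: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(time, event, included_mask) for one condition."""
        j = self.conditions.index(condition)
        inc = self.event[:, j] >= 0
        return self.time[:, j], self.event[:, j], inc

    def frame(self) -> pd.DataFrame:
        rows = []
        for j, cond in enumerate(self.conditions):
            for i, pid in enumerate(self.patient_ids):
                if self.event[i, j] >= 0:
                    rows.append((pid, cond, int(self.event[i, j]), float(self.time[i, j])))
        return pd.DataFrame(rows, columns=["patient_id", "condition", "delta", "t_days"])

    def subset(self, conditions: list[str]) -> "SurvivalLabelSet":
        idx = [self.conditions.index(c) for c in conditions]
        return SurvivalLabelSet(self.patient_ids, list(conditions),
                                self.time[:, idx], self.event[:, idx])


# ---------------------------------------------------------------------------
# phecode mapping and survival label derivation
# ---------------------------------------------------------------------------


def map_icd_to_phecode(events: pd.DataFrame, mapping: pd.DataFrame) -> pd.DataFrame:
    """Map ICD events to phecode events with earliest-timestamp collapsing.

    ``events``: columns (patient_id, icd_code, icd_version, date);
    ``mapping``: columns (icd_code, icd_version, phecode). Unmapped codes
    are dropped with a warning, never fabricated. Returns one row per
    (patient_id, phecode) carrying the earliest mapped date.
    """
    for col in ("patient_id", "icd_code", "icd_version", "date"):
        if col not in events.columns:
            raise ValueError(f"events table lacks column {col!r}")
    for col in ("icd_code", "icd_version", "phecode"):
        if col not in mapping.columns:
            raise ValueError(f"mapping table lacks column {col!r}")
    if len(mapping) == 0:
        warnings.warn("empty ICD-to-phecode mapping: no phecode events produced")
        return pd.DataFrame(columns=["patient_id", "phecode", "date"])
    ev = events.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    merged = ev.merge(mapping[["icd_code", "icd_version", "phecode"]],
                      on=["icd_code", "icd_version"], how="left")
    unmapped = merged["phecode"].isna()
    if unmapped.any():
        codes = sorted(merged.loc[unmapped, "icd_code"].unique())
        warnings.warn(f"{int(unmapped.sum())} events with unmapped ICD codes "
                      f"dropped: {codes[:10]}")
    mapped = merged.loc[~unmapped]
    out = (mapped.groupby(["patient_id", "phecode"], as_index=False)["date"].min())
    return out


def derive_survival_labels(phecode_events: pd.DataFrame,
                           psg_dates: pd.DataFrame,
                           last_contact: pd.DataFrame,
                           min_days: float = 7.0,
                           prevalent: str = "exclude") -> SurvivalLabelSet:
    """Incident-disease survival labels from phecode events.

    A patient is a positive case for a phecode when the first instance
    occurs strictly more than ``min_days`` days after the sleep study
    (t = event - PSG days). Patients whose first instance falls at or
    before ``min_days`` (including before the study) carry prevalent
    disease: with ``prevalent='exclude'`` they are excluded for that
    condition, with ``prevalent='censor'`` they are treated as censored at
    last contact. Everyone else is censored at last contact.

    ``psg_dates`` and ``last_contact``: columns (patient_id, date).
    """
    if prevalent not in ("exclude", "censor"):
        raise ValueError("prevalent must be 'exclude' or 'censor'")
    psg = {r.patient_id: pd.Timestamp(r.date) for r in psg_dates.itertuples()}
    last = {r.patient_id: pd.Timestamp(r.date) for r in last_contact.itertuples()}
    for pid in psg:
        if pid not in last:
            raise ValueError(f"patient {pid} lacks a last-contact date")
        if psg[pid] >= last[pid]:
            raise ValueError(f"patient {pid}: PSG date not before last contact")
    patient_ids = sorted(psg)
    conditions = sorted(phecode_events["phecode"].unique()) if len(phecode_events) else []
    n, L = len(patient_ids), len(conditions)
    time = np.zeros((n, L))
    event = np.zeros((n, L), dtype=np.int8)
    first = {}
    if L:
        pe = phecode_events.copy()
        pe["date"] = pd.to_datetime(pe["date"])
        grp = pe.groupby(["patient_id", "phecode"])["date"].min()
        first = grp.to_dict()
    for i, pid in enumerate(patient_ids):
        censor_days = (last[pid] - psg[pid]).days
        for j, cond in enumerate(conditions):
            key = (pid, cond)
            if key in first:
                if first[key] > last[pid]:
                    raise ValueError(
                        f"patient {pid}: event for {cond} after last contact")
                days = (first[key] - psg[pid]).days
                if days > min_days:
                    event[i, j] = 1
                    time[i, j] = days
                elif prevalent == "exclude":
                    event[i, j] = -1
                    time[i, j] = np.nan
                else:
                    event[i, j] = 0
                    time[i, j] = censor_days
            else:
                event[i, j] = 0
                time[i, j] = censor_days
    lab = SurvivalLabelSet(patient_ids, conditions, np.where(event >= 0, time, 1.0),
                           event)
    # the >7-day guard is a hard invariant of every generated label set
    assert all(lab.time[lab.event == 1] > min_days), "label leakage: event <= min_days"
    return lab


def prevalence_filter(labels: SurvivalLabelSet,
                      threshold: float = 0.015) -> list[str]:
    """Conditions whose positive fraction reaches the threshold.

    Prevalence is computed among patients included for the condition.
    Intended to run on the training split only; persist the returned list
    for reuse at evaluation time.
    """
    if labels.n_patients == 0:
        raise ValueError("empty cohort")
    retained = []
    for cond in labels.conditions:
        _, ev, inc = labels.column(cond)
        denom = int(inc.sum())
        if denom and (ev == 1).sum() / denom >= threshold:
            retained.append(cond)
    return retained


# ---------------------------------------------------------------------------
# apnea severity and stage expansion
# ---------------------------------------------------------------------------


def ahi_to_class(ahi: float) -> tuple[str, int]:
    """AHI -> (severity class, presence flag).

    Bins: none (AHI < 5), mild (5 <= AHI < 15), moderate (15 <= AHI < 30),
    severe (AHI >= 30); presence = 1 for moderate or severe.
    """
    if ahi < 0:
        raise ValueError("AHI must be nonnegative")
    if ahi < 5:
        cls = "none"
    elif ahi < 15:
        cls = "mild"
    elif ahi < 30:
        cls = "moderate"
    else:
        cls = "severe"
    return cls, int(cls in ("moderate", "severe"))


def expand_stage_labels(epoch_labels, n_tokens: int | None = None) -> np.ndarray:
    """Expand 30-s epoch labels to 5-s token labels (six tokens per epoch).

    Stage names are normalized first (R&K 3/4 -> N3). When ``n_tokens``
    exceeds the expansion, trailing tokens inherit the last epoch's label;
    a shorter ``n_tokens`` truncates. Missing epochs are rejected.
    """
    labels = list(epoch_labels)
    if len(labels) == 0:
        raise ValueError("no epoch labels")
    if any(lab is None or (isinstance(lab, float) and np.isnan(lab)) for lab in labels):
        raise ValueError("gap in epoch labels")
    norm = [normalize_stage(lab) for lab in labels]
    idx = np.repeat([STAGE_TO_INDEX[s] for s in norm], TOKENS_PER_EPOCH)
    if n_tokens is not None:
        if n_tokens > len(idx):
            idx = np.concatenate([idx, np.full(n_tokens - len(idx), idx[-1])])
        else:
            idx = idx[:n_tokens]
    return idx
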