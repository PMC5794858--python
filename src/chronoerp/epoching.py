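"""Trial classification and the three segmentation schemes.

Responses in the 1200-ms time-production task are classified from reaction
time (ms after stimulus onset): early ``[400, 1000)``, correct
``[1000, 1400]``, late ``(1400, 2000]``, miss otherwise (including no
response within 3000 ms).  The shared boundaries are resolved half-open so
every reaction time maps to exactly one category.

Three epochings feed the ERP components:

* stimulus-locked, ``[-2000, 3000]`` ms, baseline ``[-200, 0]`` pre-stimulus
  (P1/N1);
* response-relocked from the stimulus epochs, ``[-2000, 1000]`` ms around the
  response, keeping the pre-stimulus baseline (CNV);
* response-locked cut from the continuous record, ``[-200, 1500]`` ms,
  baseline ``[-200, 0]`` pre-response (feedback complex / FRN).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ContinuousRecording, Epochs, TrialCategory, ms_to_samples, window_indices

logger = logging.getLogger(__name__)

__all__ = [
    "ClassificationBoundaries",
    "SegmentationScheme",
    "STIMULUS_SCHEME",
    "CNV_SCHEME",
    "FEEDBACK_SCHEME",
    "classify_trial",
    "segment_stimulus",
    "relock_to_response",
    "segment_feedback",
    "trial_table",
]


@dataclass(frozen=True)
class ClassificationBoundaries:
    """Category boundaries in ms; see module docstring for the conventions."""

    early_min: float = 400.0
    correct_min: float = 1000.0
    correct_max: float = 1400.0
    late_max: float = 2000.0
    response_deadline: float = 3000.0

    def __post_init__(self):
        if not (self.early_min < self.correct_min < self.correct_max < self.late_max):
            raise ValueError("classification boundaries must be ordered")


@dataclass(frozen=True)
class SegmentationScheme:
    lock: str  # "stimulus" | "response"
    window_ms: tuple
    baseline_ms: tuple | None  # None: inherit the stimulus baseline (relock)

    def __post_init__(self):
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("segmentation window start must precede end")


STIMULUS_SCHEME = SegmentationScheme("stimulus", (-2000.0, 3000.0), (-200.0, 0.0))
CNV_SCHEME = SegmentationScheme("response", (-2000.0, 1000.0), None)
FEEDBACK_SCHEME = SegmentationScheme("response", (-200.0, 1500.0), (-200.0, 0.0))


def classify_trial(rt_ms: float | None, bounds: ClassificationBoundaries | None = None) -> TrialCategory:
    """Map a reaction time (or None = no response) to its trial category."""
    if bounds is None:
        bounds = ClassificationBoundaries()
    if rt_ms is None or (isinstance(rt_ms, float) and np.isnan(rt_ms)):
        return TrialCategory.MISS
    if rt_ms < 0:
        raise ValueError("reaction time cannot be negative")
    if bounds.correct_min <= rt_ms <= bounds.correct_max:
        return TrialCategory.CORRECT
    if bounds.early_min <= rt_ms < bounds.correct_min:
        return TrialCategory.EARLY
    if bounds.correct_max < rt_ms <= bounds.late_max:
        return TrialCategory.LATE
    return TrialCategory.MISS


def _trial_rts(rec: ContinuousRecording) -> dict:
    """trial_index -> reaction time in ms (from paired stimulus/response events)."""
    stim = {ev.trial_index: ev.onset_sample for ev in rec.events_of("stimulus")}
    rts = {}
    for ev in rec.events_of("response"):
        if ev.trial_index in stim:
            rts[ev.trial_index] = (ev.onset_sample - stim[ev.trial_index]) * 1000.0 / rec.rate
    return rts


def _times_axis(window_ms, rate) -> tuple:
    i0 = ms_to_samples(window_ms[0], rate)
    i1 = ms_to_samples(window_ms[1], rate)
    times = np.arange(i0, i1 + 1) * (1000.0 / rate)
    return i0, i1, times


def _cut(rec, lock_samples, window_ms):
    """Cut epochs around lock samples, dropping those exceeding the record."""
    i0, i1, times = _times_axis(window_ms, rec.rate)
    n = rec.n_samples
    keep, slabs = [], []
    for k, s in enumerate(lock_samples):
        lo, hi = s + i0, s + i1
        if lo < 0 or hi >= n:
            logger.warning("epoch around sample %d exceeds recording bounds; trial dropped", s)
            keep.append(False)
            continue
        keep.append(True)
        slabs.append(rec.data[:, lo : hi + 1])
    data = np.stack(slabs) if slabs else np.empty((0, rec.data.shape[0], times.size))
    return np.asarray(keep, bool), data, times


def segment_stimulus(
    rec: ContinuousRecording,
    scheme: SegmentationScheme = STIMULUS_SCHEME,
    bounds: ClassificationBoundaries | None = None,
) -> Epochs:
    """Stimulus-locked epochs with pre-stimulus baseline correction."""
    stim_events = sorted(rec.events_of("stimulus"), key=lambda e: e.trial_index)
    rts = _trial_rts(rec)
    keep, data, times = _cut(rec, [ev.onset_sample for ev in stim_events], scheme.window_ms)
    rows = []
    for ev, k in zip(stim_events, keep):
        if not k:
            continue
        rt = rts.get(ev.trial_index, None)
        cat = classify_trial(rt, bounds)
        rows.append({"trial_index": ev.trial_index, "rt_ms": np.nan if rt is None else rt,
                     "category": cat.value, "kept": True})
    meta = pd.DataFrame(rows, columns=["trial_index", "rt_ms", "category", "kept"])
    epochs = Epochs(
        data=data, times_ms=times, lock="stimulus", rate=rec.rate,
        ch_names=rec.montage.labels, trial_meta=meta, baseline_applied=False, units_tag="µV",
    )
    if scheme.baseline_ms is not None:
        sl = window_indices(epochs.lock_index(), scheme.baseline_ms, rec.rate)
        epochs.data = epochs.data - epochs.data[:, :, sl].mean(axis=2, keepdims=True)
        epochs.baseline_applied = True
    return epochs


def relock_to_response(stim_epochs: Epochs, scheme: SegmentationScheme = CNV_SCHEME) -> Epochs:
    """Re-window stimulus epochs around each trial's response (CNV epochs).

    The pre-stimulus baseline is preserved — no re-baselining — so slow
    preparatory activity is measured against a fixed resting level.  Trials
    without a response (misses) are excluded.
    """
    if not stim_epochs.baseline_applied:
        raise ValueError("relocking requires baseline-corrected stimulus epochs")
    if scheme.baseline_ms is not None:
        raise ValueError("the relocked scheme must inherit the stimulus baseline")
    rate = stim_epochs.rate
    i0 = ms_to_samples(scheme.window_ms[0], rate)
    i1 = ms_to_samples(scheme.window_ms[1], rate)
    times = np.arange(i0, i1 + 1) * (1000.0 / rate)
    L = stim_epochs.lock_index()
    n_samp = stim_epochs.data.shape[2]

    slabs, rows = [], []
    for t in range(stim_epochs.n_trials):
        meta = stim_epochs.trial_meta.iloc[t]
        rt = meta["rt_ms"]
        if not np.isfinite(rt) or meta["category"] == TrialCategory.MISS.value:
            continue
        r = L + ms_to_samples(rt, rate)
        lo, hi = r + i0, r + i1
        if lo < 0 or hi >= n_samp:
            logger.warning("relocked window for trial %s exceeds the stimulus epoch; dropped",
                           meta["trial_index"])
            continue
        slabs.append(stim_epochs.data[t, :, lo : hi + 1])
        rows.append(meta)
    data = np.stack(slabs) if slabs else np.empty((0, len(stim_epochs.ch_names), times.size))
    meta = pd.DataFrame(rows).reset_index(drop=True)
    return Epochs(
        data=data, times_ms=times, lock="response", rate=rate,
        ch_names=stim_epochs.ch_names, trial_meta=meta,
        baseline_applied=True, units_tag=stim_epochs.units_tag,
    )


def segment_feedback(
    rec: ContinuousRecording,
    scheme: SegmentationScheme = FEEDBACK_SCHEME,
    bounds: ClassificationBoundaries | None = None,
) -> Epochs:
    """Response-locked feedback epochs cut from the continuous record.

    Condition labels pool early and late responses into "error"; misses have
    no response event and are therefore absent.
    """
    resp_events = sorted(rec.events_of("response"), key=lambda e: e.trial_index)
    rts = _trial_rts(rec)
    keep, data, times = _cut(rec, [ev.onset_sample for ev in resp_events], scheme.window_ms)
    rows = []
    for ev, k in zip(resp_events, keep):
        if not k:
            continue
        rt = rts.get(ev.trial_index, None)
        cat = classify_trial(rt, bounds)
        if cat == TrialCategory.MISS:
            continue  # out-of-range key presses are not analyzed further
        rows.append({
            "trial_index": ev.trial_index, "rt_ms": rt, "category": cat.value,
            "condition": "correct" if cat == TrialCategory.CORRECT else "error",
            "kept": True,
        })
    # misses dropped after cutting: re-align data to surviving rows
    if rows:
        ok_idx = [i for i, (ev, k) in enumerate(zip(resp_events, keep)) if k]
        trial_ids = {r["trial_index"] for r in rows}
        sel = [j for j, i in enumerate(ok_idx) if resp_events[i].trial_index in trial_ids]
        data = data[sel]
    meta = pd.DataFrame(rows, columns=["trial_index", "rt_ms", "category", "condition", "kept"])
    epochs = Epochs(
        data=data, times_ms=times, lock="response", rate=rec.rate,
        ch_names=rec.montage.labels, trial_meta=meta, baseline_applied=False, units_tag="µV",
    )
    if scheme.baseline_ms is not None and epochs.n_trials:
        sl = window_indices(epochs.lock_index(), scheme.baseline_ms, rec.rate)
        epochs.data = epochs.data - epochs.data[:, :, sl].mean(axis=2, keepdims=True)
    epochs.baseline_applied = True
    return epochs


def trial_table(stim_epochs: Epochs, feedback_epochs: Epochs | None = None) -> pd.DataFrame:
    """Per-trial export table (trial, rt_ms, category, kept flags)."""
    t = stim_epochs.trial_meta[["trial_index", "rt_ms", "category", "kept"]].rename(
        columns={"kept": "kept_stimulus"}
    )
    if feedback_epochs is not None and len(feedback_epochs.trial_meta):
        f = feedback_epochs.trial_meta[["trial_index", "kept"]].rename(columns={"kept": "kept_feedback"})
        t = t.merge(f, on="trial_index", how="left")
        t["kept_feedback"] = t["kept_feedback"].astype("boolean")
    return t
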