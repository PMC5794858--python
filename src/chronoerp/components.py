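"""ERP component quantification.

* P1 / N1: windowed mean over four posterior-lateral electrodes
  (P7/P8/P9/P10), window keyed to group (controls vs patients).
* CNV: mean amplitude in four pre-response windows at Cz, per accuracy
  condition (correct vs error = early + late pooled).
* FRN: peak-to-peak amplitude of the two negative post-response deflections
  at FCz per feedback condition, and the correct-minus-error difference.
* A selection-validation procedure testing each electrode's window mean
  against the average of all remaining electrodes (Bonferroni threshold).

"Mean peak amplitude" is implemented as the windowed mean of the
trial-average waveform; the windows are narrow, and a literal per-trial peak
search would be biased by noise.  The FRN peak is the minimum of the
condition-average waveform within its 10-ms window (earliest sample on ties).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import Epochs, window_indices

logger = logging.getLogger(__name__)

__all__ = [
    "ComponentWindows",
    "window_mean",
    "extract_cnv",
    "extract_frn",
    "extract_p1_n1",
    "validate_selection",
    "CNV_WINDOWS",
    "FRN_PEAK_WINDOWS",
    "P1_WINDOWS",
    "N1_WINDOWS",
]

PARIETAL = ("P7", "P8", "P9", "P10")

CNV_WINDOWS = {
    "w1": (-825.0, -775.0),
    "w2": (-625.0, -525.0),
    "w3": (-225.0, -175.0),
    "w4": (-50.0, 0.0),
}

#: FRN peak windows in ms post-response, keyed by group.
FRN_PEAK_WINDOWS = {
    "control": ((200.0, 210.0), (300.0, 310.0)),
    "ADD": ((200.0, 210.0), (300.0, 310.0)),
    "ADHD-C": ((225.0, 235.0), (320.0, 330.0)),
}

P1_WINDOWS = {"control": (115.0, 140.0), "ADD": (125.0, 150.0), "ADHD-C": (125.0, 150.0)}
N1_WINDOWS = {"control": (185.0, 205.0), "ADD": (195.0, 215.0), "ADHD-C": (195.0, 215.0)}


@dataclass(frozen=True)
class ComponentWindows:
    """All component windows; defaults are the published analysis windows."""

    cnv: dict = field(default_factory=lambda: dict(CNV_WINDOWS))
    frn_peaks: dict = field(default_factory=lambda: dict(FRN_PEAK_WINDOWS))
    p1: dict = field(default_factory=lambda: dict(P1_WINDOWS))
    n1: dict = field(default_factory=lambda: dict(N1_WINDOWS))
    cnv_electrode: str = "Cz"
    frn_electrode: str = "FCz"
    p1n1_electrodes: tuple = PARIETAL


def _require_csd(epochs: Epochs):
    if "m²" not in epochs.units_tag:
        raise ValueError("component quantification expects CSD (or identity-mode) epochs")


def _kept(epochs: Epochs) -> np.ndarray:
    return epochs.trial_meta["kept"].to_numpy(bool)


def _condition_mask(epochs: Epochs, condition: str | None) -> np.ndarray:
    mask = _kept(epochs)
    if condition is None:
        return mask
    meta = epochs.trial_meta
    if "condition" in meta:
        cond = meta["condition"].to_numpy()
    else:
        cond = np.where(meta["category"].to_numpy() == "correct", "correct", "error")
    return mask & (cond == condition)


def average_waveform(epochs: Epochs, condition: str | None = None) -> np.ndarray | None:
    """Trial-average waveform (channels x samples) over kept trials of a condition."""
    mask = _condition_mask(epochs, condition)
    if not mask.any():
        return None
    return np.asarray(epochs.data[mask], dtype=np.float64).mean(axis=0)


def window_mean(
    epochs: Epochs,
    electrodes,
    window_ms,
    condition: str | None = None,
) -> float:
    """Windowed mean amplitude of the condition-average ERP over electrodes.

    Returns NaN (with a logged warning) when the condition has no kept trial.
    """
    _require_csd(epochs)
    erp = average_waveform(epochs, condition)
    if erp is None:
        logger.warning("no kept trials for condition %r; value is missing", condition)
        return float("nan")
    if isinstance(electrodes, str):
        electrodes = (electrodes,)
    ch = [epochs.channel(e) for e in electrodes]
    sl = window_indices(epochs.lock_index(), window_ms, epochs.rate)
    return float(erp[ch, sl].mean())


def extract_cnv(
    relocked_epochs: Epochs,
    windows: ComponentWindows | None = None,
) -> pd.DataFrame:
    """CNV window means at Cz per accuracy condition.

    Returns a tidy frame with columns condition, window, value (µV/m²).
    """
    w = windows or ComponentWindows()
    rows = []
    for condition in ("correct", "error"):
        for name, win in w.cnv.items():
            rows.append({
                "condition": condition,
                "window": name,
                "value": window_mean(relocked_epochs, w.cnv_electrode, win, condition),
            })
    return pd.DataFrame(rows)


def extract_frn(
    feedback_epochs: Epochs,
    group: str,
    windows: ComponentWindows | None = None,
) -> dict:
    """FRN peak-to-peak per condition and their correct-minus-error difference.

    Peak-to-peak is the value at the second negative peak minus the value at
    the first, each located as the minimum of the condition-average FCz
    waveform within the group's 10-ms peak window.
    """
    w = windows or ComponentWindows()
    _require_csd(feedback_epochs)
    win1, win2 = w.frn_peaks[group]
    ch = feedback_epochs.channel(w.frn_electrode)
    L = feedback_epochs.lock_index()
    out = {}
    for condition in ("correct", "error"):
        erp = average_waveform(feedback_epochs, condition)
        if erp is None:
            logger.warning("no kept %s-feedback trials; FRN value missing", condition)
            out[f"p2p_{condition}"] = float("nan")
            continue
        peaks = []
        for win in (win1, win2):
            seg = erp[ch, window_indices(L, win, feedback_epochs.rate)]
            peaks.append(float(seg.min()))  # argmin ties -> earliest via min()
        out[f"p2p_{condition}"] = peaks[1] - peaks[0]
    out["frn_difference"] = out["p2p_correct"] - out["p2p_error"]
    return out


def extract_p1_n1(
    stim_epochs: Epochs,
    group: str,
    windows: ComponentWindows | None = None,
) -> dict:
    """P1 and N1 amplitudes: parietal-electrode mean per accuracy condition."""
    w = windows or ComponentWindows()
    out = {}
    for comp, wins in (("p1", w.p1), ("n1", w.n1)):
        for condition in ("correct", "error"):
            out[f"{comp}_{condition}"] = window_mean(
                stim_epochs, w.p1n1_electrodes, wins[group], condition
            )
    return out


def validate_selection(
    subject_epochs: list,
    window_ms,
    expected_polarity: str,
    condition: str | None = None,
    alpha: float = 0.0007,
) -> list:
    """Electrode/window validation across subjects.

    For every electrode, the per-subject window mean at that electrode is
    compared against the per-subject mean over all other electrodes with a
    paired two-tailed t-test.  An electrode is selected iff p < ``alpha``
    (the published Bonferroni-corrected threshold) *and* its amplitude is
    larger in the expected direction (``"negative"`` for N-components,
    ``"positive"`` for P-components).

    Parameters
    ----------
    subject_epochs : list of Epochs
        One (CSD-stage) epochs object per subject, identical montages.
    """
    if expected_polarity not in ("negative", "positive"):
        raise ValueError("expected_polarity must be 'negative' or 'positive'")
    if len(subject_epochs) < 2:
        raise ValueError("validation needs at least 2 subjects")
    ch_names = subject_epochs[0].ch_names
    per_subject = []
    for ep in subject_epochs:
        _require_csd(ep)
        erp = average_waveform(ep, condition)
        if erp is None:
            continue
        sl = window_indices(ep.lock_index(), window_ms, ep.rate)
        per_subject.append(erp[:, sl].mean(axis=1))
    vals = np.asarray(per_subject)  # subjects x electrodes
    n_ch = vals.shape[1]
    selected = []
    for e in range(n_ch):
        others = vals[:, [c for c in range(n_ch) if c != e]].mean(axis=1)
        t, p = sps.ttest_rel(vals[:, e], others)
        direction = vals[:, e].mean() - others.mean()
        if p < alpha and (direction < 0 if expected_polarity == "negative" else direction > 0):
            selected.append(ch_names[e])
    return selected


def subject_component_table(
    subject_id: str,
    group: str,
    stim_epochs: Epochs,
    relocked_epochs: Epochs,
    feedback_epochs: Epochs,
    windows: ComponentWindows | None = None,
) -> pd.DataFrame:
    """Tidy per-subject component table: one row per condition x component."""
    w = windows or ComponentWindows()
    rows = []
    cnv = extract_cnv(relocked_epochs, w)
    for _, r in cnv.iterrows():
        rows.append((r["condition"], f"cnv_{r['window']}", r["value"]))
    frn = extract_frn(feedback_epochs, group, w)
    rows.append(("correct", "frn_p2p", frn["p2p_correct"]))
    rows.append(("error", "frn_p2p", frn["p2p_error"]))
    rows.append(("difference", "frn_difference", frn["frn_difference"]))
    pn = extract_p1_n1(stim_epochs, group, w)
    for comp in ("p1", "n1"):
        for condition in ("correct", "error"):
            rows.append((condition, comp, pn[f"{comp}_{condition}"]))
    df = pd.DataFrame(rows, columns=["condition", "component", "value"])
    df.insert(0, "group", group)
    df.insert(0, "subject", subject_id)
    return df
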