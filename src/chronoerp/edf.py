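"""Minimal EDF+ writer and an MNE-backed reader for continuous recordings.

The writer produces standard EDF+C files: 16-bit signals (physical range
±1000 µV) plus an "EDF Annotations" channel carrying the stimulus /
response / feedback markers as time-stamped annotation lists with
descriptions of the form ``"<kind>/<trial_index>"``.  Files are written at
run time as exchange artifacts; reading goes through :mod:`mne` so external
EDF(+) recordings can enter the pipeline the same way.
"""

from __future__ import annotations

import math

import numpy as np

from .core import ContinuousRecording, Event, Montage

__all__ = ["write_edf", "read_edf"]

_PHYS_MIN, _PHYS_MAX = -1000.0, 1000.0
_DIG_MIN, _DIG_MAX = -32768, 32767


def _pad(text: str, width: int) -> bytes:
    b = str(text).encode("ascii")[:width]
    return b + b" " * (width - len(b))


def _annotation_records(rec: ContinuousRecording, n_records: int) -> list:
    tals = [b"" for _ in range(n_records)]
    for ev in sorted(rec.events, key=lambda e: e.onset_sample):
        onset = ev.onset_sample / rec.rate
        r = min(int(onset), n_records - 1)
        tals[r] += f"+{onset:.4f}\x15{0:.4f}\x14{ev.kind}/{ev.trial_index}\x14\x00".encode("ascii")
    out = []
    for r, tal in enumerate(tals):
        out.append(f"+{float(r):.4f}\x14\x14\x00".encode("ascii") + tal)
    return out


def write_edf(path, rec: ContinuousRecording, patient_id: str = "X", recording_id: str = "X"):
    """Write a recording (µV) as EDF+C; the last partial second is zero-padded."""
    if rec.rate != int(rec.rate):
        raise ValueError("EDF writer requires an integer sampling rate")
    rate = int(rec.rate)
    n_ch = rec.data.shape[0]
    n_records = math.ceil(rec.n_samples / rate)
    ann = _annotation_records(rec, n_records)
    ann_bytes = max(120, max(len(a) for a in ann))
    ann_samples = (ann_bytes + 1) // 2 + 1

    n_signals = n_ch + 1
    header_bytes = 256 * (n_signals + 1)
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad(patient_id, 80))
        f.write(_pad(recording_id, 80))
        f.write(_pad("01.01.00", 8))
        f.write(_pad("00.00.00", 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("EDF+C", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad("1", 8))  # record duration, seconds
        f.write(_pad(str(n_signals), 4))

        labels = list(rec.montage.labels) + ["EDF Annotations"]
        for lab in labels:
            f.write(_pad(lab, 16))
        for _ in range(n_signals):
            f.write(_pad("AgAgCl electrode", 80))
        for i in range(n_signals):
            f.write(_pad("uV" if i < n_ch else "", 8))
        for i in range(n_signals):
            f.write(_pad(f"{_PHYS_MIN:g}" if i < n_ch else "-1", 8))
        for i in range(n_signals):
            f.write(_pad(f"{_PHYS_MAX:g}" if i < n_ch else "1", 8))
        for i in range(n_signals):
            f.write(_pad(str(_DIG_MIN), 8))
        for i in range(n_signals):
            f.write(_pad(str(_DIG_MAX), 8))
        for _ in range(n_signals):
            f.write(_pad("", 80))
        for i in range(n_signals):
            f.write(_pad(str(rate if i < n_ch else ann_samples), 8))
        for _ in range(n_signals):
            f.write(_pad("", 32))

        gain = (_DIG_MAX - _DIG_MIN) / (_PHYS_MAX - _PHYS_MIN)
        for r in range(n_records):
            sl = np.zeros((n_ch, rate), dtype=np.float64)
            chunk = rec.data[:, r * rate : (r + 1) * rate]
            sl[:, : chunk.shape[1]] = chunk
            dig = np.clip(np.round((sl - _PHYS_MIN) * gain + _DIG_MIN), _DIG_MIN, _DIG_MAX)
            f.write(dig.astype("<i2").tobytes())
            a = ann[r] + b"\x00" * (2 * ann_samples - len(ann[r]))
            f.write(a[: 2 * ann_samples])


def read_edf(path, montage: Montage | None = None) -> ContinuousRecording:
    """Read an EDF(+) file (via MNE) into a ContinuousRecording in µV.

    Annotations with descriptions ``"<kind>/<trial_index>"`` become events;
    other annotations are ignored.  If no montage is given, a generated
    equidistant layout of matching size is attached (positions are then
    nominal, which is fine for identity-spatial-mode analyses).
    """
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    rate = float(raw.info["sfreq"])
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if "/" not in desc:
            continue
        kind, _, idx = desc.partition("/")
        if kind not in ("stimulus", "response", "feedback"):
            continue
        events.append(Event(int(round(onset * rate)), kind, int(idx)))
    if montage is None:
        from .core import make_equidistant_montage

        montage = make_equidistant_montage(max(16, data.shape[0]))
        if data.shape[0] != len(montage):
            raise ValueError("cannot build a default montage for this channel count")
        # keep recorded labels where they match the generated required set
        montage = Montage(labels=tuple(raw.ch_names), positions=montage.positions)
    return ContinuousRecording(data=data, rate=rate, events=events, montage=montage)
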