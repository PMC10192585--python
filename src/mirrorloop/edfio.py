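"""Disk interchange: 16-bit EDF recordings, events TSV, ground-truth JSON.

The writer emits classic EDF (one data record per second, int16 samples,
physical units microvolts).  Only the subset of the format needed for the
simulate -> preprocess contract is implemented; the reader refuses files
with per-signal sampling rates that differ across channels.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EventSchedule, RawRecording
from .montage import standard_montage


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | Path, raw: RawRecording) -> None:
    """Write a recording as classic EDF, int16, microvolts."""
    path = Path(path)
    sfreq = raw.sfreq
    if abs(sfreq - round(sfreq)) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    spr = int(round(sfreq))  # samples per 1 s record
    nch = raw.n_channels
    n_rec = int(np.ceil(raw.n_samples / spr))
    data = np.zeros((nch, n_rec * spr))
    data[:, : raw.n_samples] = raw.data

    pmax = float(np.max(np.abs(data)))
    pmax = max(pmax * 1.01, 1.0)
    # the header stores the range as text: scale against the stored value
    pmax = float(f"{pmax:.6g}"[:8])
    pmin = -pmax
    scale = 32767.0 / pmax
    digital = np.clip(np.round(data * scale), -32767, 32767).astype("<i2")

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate X X X X", 80))
        fh.write(_pad("01.01.00", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (nch + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_rec), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(nch), 4))
        names = raw.montage.channel_names
        for name in names:
            fh.write(_pad(f"EEG {name}", 16))
        for _ in names:
            fh.write(_pad("AgAgCl electrode", 80))
        for _ in names:
            fh.write(_pad("uV", 8))
        for _ in names:
            fh.write(_pad(f"{pmin:.6g}"[:8], 8))
        for _ in names:
            fh.write(_pad(f"{pmax:.6g}"[:8], 8))
        for _ in names:
            fh.write(_pad("-32767", 8))
        for _ in names:
            fh.write(_pad("32767", 8))
        for _ in names:
            fh.write(_pad("", 80))
        for _ in names:
            fh.write(_pad(str(spr), 8))
        for _ in names:
            fh.write(_pad("", 32))
        # data records: all samples of ch0, then ch1, ... per record
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> RawRecording:
    """Read back an EDF file written by :func:`write_edf`."""
    path = Path(path)
    with open(path, "rb") as fh:
        hdr = fh.read(256)
        n_rec = int(hdr[236:244].decode().strip())
        rec_dur = float(hdr[244:252].decode().strip())
        nch = int(hdr[252:256].decode().strip())
        sig = fh.read(256 * nch)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * nch
            return [sig[base + i * width : base + (i + 1) * width].decode().strip()
                    for i in range(nch)]

        labels = [lb.removeprefix("EEG ").strip() for lb in fields(0, 16)]
        pmin = np.array([float(v) for v in fields(16 + 80 + 8, 8)])
        pmax = np.array([float(v) for v in fields(16 + 80 + 8 + 8, 8)])
        dmin = np.array([float(v) for v in fields(16 + 80 + 8 + 16, 8)])
        dmax = np.array([float(v) for v in fields(16 + 80 + 8 + 24, 8)])
        spr = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]
        if len(set(spr)) != 1:
            raise ValueError("mixed per-channel sampling rates are unsupported")
        spr0 = spr[0]
        raw16 = np.frombuffer(fh.read(n_rec * nch * spr0 * 2), dtype="<i2")

    raw16 = raw16.reshape(n_rec, nch, spr0)
    data = raw16.transpose(1, 0, 2).reshape(nch, n_rec * spr0).astype(float)
    gain = (pmax - pmin) / (dmax - dmin)
    data = (data - dmin[:, None]) * gain[:, None] + pmin[:, None]
    montage = standard_montage(labels)
    return RawRecording(data, spr0 / rec_dur, montage)


def write_events_tsv(path: str | Path, schedule: EventSchedule) -> None:
    schedule.events.to_csv(path, sep="\t", index=False, na_rep="n/a")


def read_events_tsv(path: str | Path) -> EventSchedule:
    df = pd.read_csv(path, sep="\t", na_values=["n/a"])
    df["finger"] = df["finger"].astype("Int64")
    df["trial_index"] = df["trial_index"].astype("Int64")
    df["is_target"] = df["is_target"].astype("boolean")
    return EventSchedule(df)


def write_ground_truth(path: str | Path, truth: dict) -> None:
    Path(path).write_text(json.dumps(truth, indent=1))


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def save_subject(out_dir: str | Path, sub) -> None:
    """Persist one subject: EDF + events TSV per session + truth sidecar."""
    out_dir = Path(out_dir) / sub.subject_id
    out_dir.mkdir(parents=True, exist_ok=True)
    for session, raw in sub.recordings.items():
        write_edf(out_dir / f"{session}.edf", raw)
        write_events_tsv(out_dir / f"{session}_events.tsv", sub.schedules[session])
    write_ground_truth(out_dir / "ground_truth.json", sub.ground_truth)


def load_subject(sub_dir: str | Path):
    """Load a subject directory back into a :class:`SubjectData`."""
    from .simulate import SubjectData

    sub_dir = Path(sub_dir)
    recordings, schedules = {}, {}
    for edf in sorted(sub_dir.glob("*.edf")):
        session = edf.stem
        recordings[session] = read_edf(edf)
        schedules[session] = read_events_tsv(sub_dir / f"{session}_events.tsv")
    truth = read_ground_truth(sub_dir / "ground_truth.json")
    return SubjectData(sub_dir.name, recordings, schedules, truth)
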