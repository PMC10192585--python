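"""HDF5 persistence for derived objects.

Layouts
-------
Epochs file::

    /data      (epochs, channels, times) float64, microvolts
    /times     (times,) seconds
    /metadata  table of per-epoch labels (fixed-width strings / ints)
    attrs: sfreq, ch_names, baseline_interval (optional)

CSP model file::

    /filters      (components, channels)
    /patterns     (channels, components)
    /eigenvalues  (components,)
    attrs: band_name, band_hz, selected, candidates

ERD/S time-courses are tabular and exported as long-format TSV instead
(subject, condition, band, time, db).
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Epochs
from .csp import CSP, BandSpec


def save_epochs(path: str | Path, epochs: Epochs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data, compression="gzip",
                         compression_opts=1)
        f.create_dataset("times", data=epochs.times)
        f.attrs["sfreq"] = epochs.sfreq
        f.attrs["ch_names"] = list(epochs.ch_names)
        if epochs.baseline_interval is not None:
            f.attrs["baseline_interval"] = list(epochs.baseline_interval)
        md = f.create_group("metadata")
        for col in epochs.metadata.columns:
            values = epochs.metadata[col]
            if values.dtype == object or str(values.dtype).startswith(
                    ("string", "category")):
                data = values.astype(str).to_numpy(dtype="S32")
            elif str(values.dtype) == "boolean":
                data = values.fillna(False).to_numpy(dtype="i8")
            elif str(values.dtype) == "Int64":
                data = values.fillna(-1).to_numpy(dtype="i8")
            else:
                data = values.to_numpy()
            md.create_dataset(col, data=data)


def load_epochs(path: str | Path) -> Epochs:
    with h5py.File(path, "r") as f:
        data = f["data"][()]
        times = f["times"][()]
        sfreq = float(f.attrs["sfreq"])
        ch_names = tuple(str(c) for c in f.attrs["ch_names"])
        baseline = f.attrs.get("baseline_interval")
        cols = {}
        for col, ds in f["metadata"].items():
            values = ds[()]
            if values.dtype.kind == "S":
                values = np.array([v.decode() for v in values])
                values = np.where(values == "None", None, values)
            cols[col] = values
        md = pd.DataFrame(cols)
    return Epochs(data, times, sfreq, md, ch_names,
                  tuple(baseline) if baseline is not None else None)


def save_csp(path: str | Path, model: CSP, band: BandSpec | None = None) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("filters", data=model.filters_)
        f.create_dataset("patterns", data=model.patterns_)
        f.create_dataset("eigenvalues", data=model.eigenvalues_)
        f.attrs["selected"] = list(model.selected_)
        f.attrs["candidates"] = list(model.candidates_)
        if band is not None:
            f.attrs["band_name"] = band.name
            f.attrs["band_hz"] = list(band.range_hz)


def load_csp(path: str | Path) -> tuple[CSP, BandSpec | None]:
    model = CSP()
    with h5py.File(path, "r") as f:
        model.filters_ = f["filters"][()]
        model.patterns_ = f["patterns"][()]
        model.eigenvalues_ = f["eigenvalues"][()]
        model.selected_ = [int(i) for i in f.attrs["selected"]]
        model.candidates_ = [int(i) for i in f.attrs["candidates"]]
        band = None
        if "band_name" in f.attrs:
            lo, hi = f.attrs["band_hz"]
            band = BandSpec(str(f.attrs["band_name"]), (float(lo), float(hi)))
    return model, band


def patterns_to_tsv(path: str | Path, model: CSP, ch_names) -> None:
    """Export pattern topographies (one column per retained component)."""
    cols = {"channel": list(ch_names)}
    for i in model.selected_:
        cols[f"csp{i}"] = model.patterns_[:, i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def erds_to_tsv(path: str | Path, rows: list[dict]) -> None:
    """Long-format ERD/S export: subject, condition, band, time, db."""
    frames = []
    for row in rows:
        frames.append(pd.DataFrame({
            "subject": row["subject"], "condition": row["condition"],
            "band": row["band"], "time": row["times"], "db": row["values"],
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
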