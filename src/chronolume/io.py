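"""File dialects: TSV readers/writers, TOML configs, raw signal matrices.

All TSVs are UTF-8, tab-delimited, '.' decimal separator; times are decimal
hours.  Epoch signal matrices are stored as raw little-endian float32 with a
JSON sidecar describing the geometry; EDF reading is available when mne is
installed.
"""

from __future__ import annotations

import dataclasses
import json
import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from .eeg import EpochSpectra
from .synth import (ActivitySimConfig, ActivityTrace, EEGSimConfig, ERGTrace,
                    Hypnogram, LightInterval, LightSchedule, SpectralPeak,
                    StateTemplate)


# ---------------------------------------------------------------------------
# Light schedules
# ---------------------------------------------------------------------------

def write_schedule_tsv(schedule: LightSchedule, path) -> None:
    df = pd.DataFrame([{"start_h": iv.start_h, "end_h": iv.end_h,
                        "state": iv.state, "intensity_cdm2": iv.intensity_cdm2}
                       for iv in schedule.intervals])
    df.to_csv(path, sep="\t", index=False)


def read_schedule_tsv(path) -> LightSchedule:
    df = pd.read_csv(path, sep="\t")
    return LightSchedule(tuple(
        LightInterval(float(r.start_h), float(r.end_h), str(r.state),
                      float(r.intensity_cdm2))
        for r in df.itertuples()))


# ---------------------------------------------------------------------------
# Activity traces
# ---------------------------------------------------------------------------

def write_activity_tsv(trace: ActivityTrace, path) -> None:
    df = pd.DataFrame({"t_start_h": trace.bin_starts_h(),
                       "counts": trace.counts})
    df.to_csv(path, sep="\t", index=False)


def read_activity_tsv(path) -> ActivityTrace:
    df = pd.read_csv(path, sep="\t")
    t = df["t_start_h"].to_numpy(dtype=float)
    if t.size > 1:
        bin_seconds = float(np.median(np.diff(t))) * 3600.0
    else:
        bin_seconds = 300.0
    return ActivityTrace(counts=df["counts"].to_numpy(dtype=np.int64),
                         bin_seconds=round(bin_seconds, 6),
                         start_time_h=float(t[0]))


# ---------------------------------------------------------------------------
# Hypnograms
# ---------------------------------------------------------------------------

def write_hypnogram_tsv(h: Hypnogram, path) -> None:
    df = pd.DataFrame({"epoch_index": np.arange(h.n_epochs),
                       "state": h.states})
    df.to_csv(path, sep="\t", index=False)
    meta = {"epoch_seconds": h.epoch_seconds, "start_time_h": h.start_time_h}
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True))


def read_hypnogram_tsv(path, epoch_seconds: float | None = None,
                       start_time_h: float | None = None) -> Hypnogram:
    df = pd.read_csv(path, sep="\t")
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return Hypnogram(
        states=df["state"].to_numpy(dtype="U4"),
        epoch_seconds=(epoch_seconds if epoch_seconds is not None
                       else float(meta.get("epoch_seconds", 4.0))),
        start_time_h=(start_time_h if start_time_h is not None
                      else float(meta.get("start_time_h", 0.0))))


# ---------------------------------------------------------------------------
# Epoch spectra
# ---------------------------------------------------------------------------

def write_spectra_tsv(spectra: EpochSpectra, path) -> None:
    cols = [f"{f:.2f}" for f in spectra.freqs_hz]
    df = pd.DataFrame(spectra.power, columns=cols)
    df.insert(0, "epoch_index", np.arange(spectra.n_epochs))
    df.to_csv(path, sep="\t", index=False)


def read_spectra_tsv(path, epoch_seconds: float = 4.0,
                     start_time_h: float = 0.0) -> EpochSpectra:
    df = pd.read_csv(path, sep="\t")
    freq_cols = [c for c in df.columns if c != "epoch_index"]
    freqs = np.array([float(c) for c in freq_cols])
    return EpochSpectra(freqs_hz=freqs,
                        power=df[freq_cols].to_numpy(dtype=float),
                        epoch_seconds=epoch_seconds,
                        start_time_h=start_time_h)


# ---------------------------------------------------------------------------
# Epoch signal matrices (raw float32 + JSON sidecar) and EDF
# ---------------------------------------------------------------------------

def write_signal_matrix(signals: np.ndarray, sampling_hz: float,
                        epoch_seconds: float, path) -> None:
    x = np.ascontiguousarray(signals, dtype="<f4")
    x.tofile(path)
    sidecar = {"sampling_hz": sampling_hz, "epoch_seconds": epoch_seconds,
               "n_epochs": int(x.shape[0]), "dtype": "<f4"}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, sort_keys=True))


def read_signal_matrix(path) -> tuple[np.ndarray, float, float]:
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    n_epochs = int(sidecar["n_epochs"])
    fs = float(sidecar["sampling_hz"])
    es = float(sidecar["epoch_seconds"])
    flat = np.fromfile(path, dtype=sidecar.get("dtype", "<f4"))
    return flat.reshape(n_epochs, -1).astype(float), fs, es


def read_edf_epochs(path, epoch_seconds: float = 4.0,
                    channel: int = 0) -> tuple[np.ndarray, float]:
    """Read one EDF channel and reshape into consecutive epochs (requires
    mne); trailing samples that do not fill an epoch are dropped."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    fs = float(raw.info["sfreq"])
    data = raw.get_data()[channel] * 1e6  # volts -> microvolts
    n_samp = int(round(fs * epoch_seconds))
    n_epochs = data.size // n_samp
    return data[:n_epochs * n_samp].reshape(n_epochs, n_samp), fs


# ---------------------------------------------------------------------------
# ERG traces
# ---------------------------------------------------------------------------

def write_erg_tsv(trace: ERGTrace, path) -> None:
    df = pd.DataFrame({"time_ms": trace.time_ms,
                       "voltage_uV": trace.voltage_uV})
    df.to_csv(path, sep="\t", index=False)
    Path(str(path) + ".json").write_text(
        json.dumps({"stim_time_ms": trace.stim_time_ms}, sort_keys=True))


def read_erg_tsv(path, stim_time_ms: float | None = None) -> ERGTrace:
    df = pd.read_csv(path, sep="\t")
    if stim_time_ms is None:
        meta_path = Path(str(path) + ".json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        stim_time_ms = float(meta.get("stim_time_ms", 0.0))
    return ERGTrace(time_ms=df["time_ms"].to_numpy(dtype=float),
                    voltage_uV=df["voltage_uV"].to_numpy(dtype=float),
                    stim_time_ms=stim_time_ms)


# ---------------------------------------------------------------------------
# TOML configs
# ---------------------------------------------------------------------------

def load_activity_config(path) -> ActivitySimConfig:
    """ActivitySimConfig from a TOML file (table ``[activity]`` or root),
    field names mirroring the dataclass."""
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    table = doc.get("activity", doc)
    names = {f.name for f in dataclasses.fields(ActivitySimConfig)}
    return ActivitySimConfig(**{k: v for k, v in table.items() if k in names})


def load_eeg_config(path) -> EEGSimConfig:
    """EEGSimConfig from a TOML file (table ``[eeg]`` or root).

    ``state_templates`` is a table of ``{noise_uV, slope, peaks}`` per state
    with peaks as ``[center_hz, width_hz, amplitude_uV]`` triples;
    ``transition_matrices`` a table of 4x4 row lists per light state.
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    table = doc.get("eeg", doc)
    kwargs = {}
    for key in ("sampling_hz", "epoch_seconds", "tpf_light_hz",
                "tpf_dark_hz", "seed"):
        if key in table:
            kwargs[key] = table[key]
    if "state_templates" in table:
        kwargs["state_templates"] = {
            st: StateTemplate(
                noise_uV=float(t["noise_uV"]), slope=float(t["slope"]),
                peaks=tuple(SpectralPeak(*map(float, pk))
                            for pk in t.get("peaks", [])))
            for st, t in table["state_templates"].items()}
    if "transition_matrices" in table:
        kwargs["transition_matrices"] = {
            k: np.asarray(v, dtype=float)
            for k, v in table["transition_matrices"].items()}
    return EEGSimConfig(**kwargs)
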