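"""Plain-text readers and writers for experiments, spectra and series.

A simulated experiment is written as a directory of columnar text files
(one per FID: index, real, imaginary) plus a YAML metadata file with the
acquisition parameters, delays, start times and reference flags. Processed
spectra are two-column text (ppm, intensity) with a JSON provenance sidecar.
Recovery series travel as TSV.

A best-effort adapter for the Bruker TopSpin 1D layout (binary ``fid`` +
``acqus`` parameter file) is included for re-analysis of instrument data; it
covers the common int32/float64 single-FID case only and is untested against
vendor data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .processing import Fid, Spectrum
from .recovery import RecoverySeries

__all__ = [
    "write_experiment",
    "read_experiment",
    "write_spectrum",
    "read_spectrum",
    "write_series",
    "read_series",
    "read_bruker",
]

SERIES_COLUMNS = ["peak_id", "tau_ms", "intensity", "error",
                  "start_time_min", "is_reference"]


def write_experiment(fids: list[Fid], outdir: str | Path) -> Path:
    """Write one experiment: fid_000.txt ... plus experiment.yaml."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, fid in enumerate(fids):
        name = f"fid_{i:03d}.txt"
        data = np.column_stack([np.arange(len(fid)),
                                fid.points.real, fid.points.imag])
        np.savetxt(outdir / name, data, fmt="%d %.10e %.10e",
                   header="index real imag")
        entries.append({"file": name, "dwell_s": fid.dwell,
                        **{k: v for k, v in fid.meta.items()}})
    with open(outdir / "experiment.yaml", "w") as fh:
        yaml.safe_dump({"fids": entries}, fh, sort_keys=False)
    return outdir


def read_experiment(indir: str | Path) -> list[Fid]:
    indir = Path(indir)
    with open(indir / "experiment.yaml") as fh:
        meta = yaml.safe_load(fh)
    fids = []
    for entry in meta["fids"]:
        raw = np.loadtxt(indir / entry["file"])
        points = raw[:, 1] + 1j * raw[:, 2]
        info = {k: v for k, v in entry.items() if k not in ("file", "dwell_s")}
        fids.append(Fid(points=points, dwell=entry["dwell_s"], meta=info,
                        provenance=("read",)))
    return fids


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Two-column text (ppm, intensity) with a .json provenance sidecar."""
    path = Path(path)
    np.savetxt(path, np.column_stack([spectrum.ppm, spectrum.intensities]),
               fmt="%.6f %.10e", header="ppm intensity")
    sidecar = path.with_suffix(path.suffix + ".json")
    with open(sidecar, "w") as fh:
        json.dump({"provenance": list(spectrum.provenance),
                   "meta": {k: v for k, v in spectrum.meta.items()}}, fh,
                  indent=1, default=str)
    return path


def read_spectrum(path: str | Path) -> Spectrum:
    path = Path(path)
    raw = np.loadtxt(path)
    meta, provenance = {}, ()
    sidecar = path.with_suffix(path.suffix + ".json")
    if sidecar.exists():
        with open(sidecar) as fh:
            extra = json.load(fh)
        meta = extra.get("meta", {})
        provenance = tuple(extra.get("provenance", ()))
    return Spectrum(intensities=raw[:, 1], ppm=raw[:, 0], meta=meta,
                    provenance=provenance)


def write_series(series: dict[str, RecoverySeries] | list[RecoverySeries],
                 path: str | Path) -> Path:
    """Recovery series as TSV with one row per (peak, delay)."""
    if isinstance(series, dict):
        series = list(series.values())
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    frame.to_csv(path, sep="\t", index=False, columns=SERIES_COLUMNS)
    return Path(path)


def read_series(path: str | Path) -> dict[str, RecoverySeries]:
    frame = pd.read_csv(path, sep="\t")
    out = {}
    for pid, grp in frame.groupby("peak_id", sort=False):
        out[pid] = RecoverySeries.from_arrays(
            peak_id=pid, tau=grp["tau_ms"], intensity=grp["intensity"],
            error=grp["error"], start_time=grp["start_time_min"],
            is_reference=grp["is_reference"])
    return out


def _parse_acqus(path: Path) -> dict:
    """Minimal JCAMP-DX parameter parse: ##$KEY= value lines only."""
    params = {}
    for line in path.read_text(errors="replace").splitlines():
        if line.startswith("##$") and "=" in line:
            key, _, val = line[3:].partition("=")
            params[key.strip()] = val.strip()
    return params


def read_bruker(dataset_dir: str | Path) -> Fid:
    """Best-effort reader for a Bruker TopSpin 1D dataset directory.

    Expects ``fid`` and ``acqus`` in ``dataset_dir``; honours TD (total real
    points), SW_h (spectral width, Hz), SFO1 (carrier frequency, MHz), O1
    (carrier offset, Hz), BYTORDA (endianness) and DTYPA (0 = int32,
    2 = float64). Digital-filter group delay is not corrected.
    """
    dataset_dir = Path(dataset_dir)
    acqus = _parse_acqus(dataset_dir / "acqus")
    td = int(float(acqus["TD"]))
    sw_hz = float(acqus["SW_h"])
    sfo1 = float(acqus["SFO1"])
    o1 = float(acqus.get("O1", 0.0))
    byteorder = "<" if acqus.get("BYTORDA", "0") == "0" else ">"
    dtype = np.dtype(f"{byteorder}f8") if acqus.get("DTYPA", "0") == "2" \
        else np.dtype(f"{byteorder}i4")
    raw = np.fromfile(dataset_dir / "fid", dtype=dtype)[:td].astype(float)
    points = raw[0::2] + 1j * raw[1::2]
    return Fid(points=points, dwell=1.0 / sw_hz,
               meta={"spectrometer_freq": sfo1, "carrier": o1 / sfo1,
                     "spectral_width": sw_hz / sfo1},
               provenance=("read-bruker",))
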