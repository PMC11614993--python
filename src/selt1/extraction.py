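"""Peak intensity extraction at frozen chemical shifts, noise and SNR.

The chemical shift of each peak maximum is located once, on the spectrum of
the first recovery delay, and then frozen: every later spectrum is read at
that same grid point (nearest point, no interpolation). This is robust at
the low signal-to-noise typical of in-cell spectra, where per-spectrum peak
picking would chase noise. The per-point standard error follows
I / (2*SNR) with the SINO-style convention SNR = peak / (2*rms noise),
under which the error reduces exactly to the rms noise of the spectrum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .processing import Spectrum

__all__ = [
    "PeakWindow",
    "PeakTable",
    "DEFAULT_NOISE_REGION",
    "locate_peaks",
    "rms_noise",
    "snr",
    "intensity_error",
    "extract_series",
]

# Empty region of the 1H imino spectrum used for noise estimation (ppm).
DEFAULT_NOISE_REGION: tuple[float, float] = (15.0, 16.0)


@dataclass(frozen=True)
class PeakWindow:
    """Search window for one peak, used only on the first spectrum."""

    peak_id: str
    lo: float  # ppm
    hi: float  # ppm

    def __post_init__(self):
        if self.lo >= self.hi:
            raise ValueError("window must satisfy lo < hi")


@dataclass(frozen=True)
class PeakTable:
    """Frozen chemical shifts per peak after locating on the first spectrum."""

    peaks: tuple  # of (peak_id, fixed_shift, locatable)

    def shifts(self) -> dict[str, float]:
        return {pid: s for pid, s, ok in self.peaks if ok}

    def __len__(self):
        return len(self.peaks)


def _check_region(spectrum: Spectrum, lo: float, hi: float, what: str):
    if lo < spectrum.ppm.min() - 1e-9 or hi > spectrum.ppm.max() + 1e-9:
        raise ValueError(f"{what} [{lo}, {hi}] ppm outside spectrum axis "
                         f"[{spectrum.ppm.min():.2f}, {spectrum.ppm.max():.2f}]")


def locate_peaks(first_spectrum: Spectrum, windows: list[PeakWindow],
                 noise_floor: float = 0.0) -> PeakTable:
    """Fix each peak's shift at the |intensity| extremum in its window.

    A window whose extremum does not rise above ``noise_floor`` (or that is
    perfectly flat) is flagged unlocatable rather than silently picked.
    Windows must not overlap.
    """
    ws = sorted(windows, key=lambda w: w.lo)
    for a, b in zip(ws, ws[1:]):
        if a.hi > b.lo:
            raise ValueError(f"windows {a.peak_id} and {b.peak_id} overlap")
    rows = []
    for w in windows:
        _check_region(first_spectrum, w.lo, w.hi, f"window {w.peak_id}")
        mask = (first_spectrum.ppm >= w.lo) & (first_spectrum.ppm <= w.hi)
        sub = np.abs(first_spectrum.intensities[mask])
        axis = first_spectrum.ppm[mask]
        peak = sub.max()
        locatable = bool(peak > noise_floor and peak > sub.min())
        shift = float(axis[np.argmax(sub)]) if locatable else math.nan
        rows.append((w.peak_id, shift, locatable))
    return PeakTable(tuple(rows))


def rms_noise(spectrum: Spectrum,
              region: tuple[float, float] = DEFAULT_NOISE_REGION) -> float:
    """Standard deviation of a peak-free region, mean-subtracted first.

    Subtracting the region mean makes the estimate insensitive to a constant
    baseline offset, which would otherwise inflate it.
    """
    lo, hi = region
    _check_region(spectrum, lo, hi, "noise region")
    vals = spectrum.slice(lo, hi)
    if vals.size < 16:
        raise ValueError(f"noise region has {vals.size} points, need >= 16")
    return float(np.std(vals - vals.mean(), ddof=1))


def snr(spectrum: Spectrum, shift: float,
        region: tuple[float, float] = DEFAULT_NOISE_REGION) -> float:
    """SINO-style signal-to-noise: intensity at ``shift`` / (2 * rms noise)."""
    noise = rms_noise(spectrum, region)
    signal = spectrum.intensity_at(shift)
    if noise == 0:
        return math.inf
    return signal / (2.0 * noise)


def intensity_error(intensity: float, snr_value: float) -> float:
    """Standard error I / (2*SNR); equals the rms noise under the SINO
    convention used here."""
    if snr_value <= 0:
        raise ValueError("SNR must be > 0")
    return intensity / (2.0 * snr_value)


def extract_series(spectra: list[Spectrum], peak_table: PeakTable,
                   region: tuple[float, float] = DEFAULT_NOISE_REGION):
    """One recovery series per locatable peak from a set of spectra.

    All spectra must share the ppm axis. Intensities are read at the frozen
    shift's nearest grid point; each point carries the error rms-noise-based
    standard error of its own spectrum, the recovery delay, the wall-clock
    start time and the reference flag from the FID metadata. Also reports a
    shift-drift diagnostic: the per-spectrum |argmax| position near each
    frozen shift (within +-0.2 ppm) minus the frozen shift - peaks whose
    maxima wander are fit-failure candidates, but are never re-picked.

    Returns a dict ``peak_id -> RecoverySeries``.
    """
    from .recovery import RecoveryPoint, RecoverySeries

    if not spectra:
        raise ValueError("no spectra supplied")
    axis0 = spectra[0].ppm
    for s in spectra[1:]:
        if s.ppm.shape != axis0.shape or not np.allclose(s.ppm, axis0):
            raise ValueError("all spectra must share the same ppm axis")
    out: dict[str, RecoverySeries] = {}
    for pid, shift, ok in peak_table.peaks:
        if not ok:
            continue
        points = []
        drifts = []
        for s in spectra:
            noise = rms_noise(s, region)
            inten = s.intensity_at(shift)
            err = noise if noise > 0 else 1.0
            meta = s.meta
            points.append(RecoveryPoint(
                tau=float(meta["tau_ms"]),
                intensity=inten,
                error=err,
                start_time=float(meta.get("start_time_min", 0.0)),
                is_reference=bool(meta.get("is_reference", False)),
            ))
            near = (s.ppm >= shift - 0.2) & (s.ppm <= shift + 0.2)
            local = np.abs(s.intensities[near])
            drifts.append(float(s.ppm[near][np.argmax(local)] - shift))
        out[pid] = RecoverySeries(peak_id=pid, points=tuple(points),
                                  shift_drift=tuple(drifts))
    return out
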