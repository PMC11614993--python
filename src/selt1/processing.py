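"""FID -> spectrum processing: truncation, apodization, linear prediction, FT.

Three named recipes mirror the alternative processing routes used to check
that the fitted relaxation times are insensitive to processing choices:

``lb1_trunc``
    1 Hz exponential line broadening, FID truncated to 512 complex points.
``lb1_trunc_lp``
    as above plus forward linear prediction (16 coefficients, 8192 points).
``lb15_full``
    15 Hz line broadening, no truncation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Fid",
    "Spectrum",
    "ProcessingRecipe",
    "RECIPES",
    "truncate",
    "apodize_exponential",
    "linear_predict",
    "to_spectrum",
    "run_recipe",
]


@dataclass(frozen=True)
class Fid:
    """Complex time-domain record with acquisition metadata.

    ``meta`` must carry ``spectrometer_freq`` (MHz) and ``carrier`` (ppm) for
    the Fourier step, and usually carries ``tau_ms``, ``start_time_min`` and
    ``is_reference`` for the recovery analysis. ``provenance`` is the ordered
    record of processing steps applied so far.
    """

    points: np.ndarray
    dwell: float  # s
    meta: dict = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=complex)
        object.__setattr__(self, "points", pts)
        if self.dwell <= 0:
            raise ValueError("dwell must be > 0")
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("FID must be a 1-D array of length >= 2")

    def __len__(self) -> int:
        return self.points.size

    def _step(self, points: np.ndarray, tag: str) -> "Fid":
        return Fid(points, self.dwell, dict(self.meta), self.provenance + (tag,))


@dataclass(frozen=True)
class Spectrum:
    """Real 1D spectrum on a strictly decreasing ppm axis."""

    intensities: np.ndarray
    ppm: np.ndarray
    meta: dict = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def __post_init__(self):
        ints = np.asarray(self.intensities, float)
        ppm = np.asarray(self.ppm, float)
        object.__setattr__(self, "intensities", ints)
        object.__setattr__(self, "ppm", ppm)
        if ints.shape != ppm.shape:
            raise ValueError("intensities and ppm axis must have equal length")
        if np.any(np.diff(ppm) >= 0):
            raise ValueError("ppm axis must be strictly decreasing")

    def index_of(self, shift: float) -> int:
        """Index of the grid point nearest to ``shift`` (ppm)."""
        return int(np.argmin(np.abs(self.ppm - shift)))

    def intensity_at(self, shift: float) -> float:
        """Intensity at the nearest grid point, no interpolation."""
        return float(self.intensities[self.index_of(shift)])

    def slice(self, lo: float, hi: float) -> np.ndarray:
        """Intensities with lo <= ppm <= hi."""
        mask = (self.ppm >= min(lo, hi)) & (self.ppm <= max(lo, hi))
        return self.intensities[mask]


@dataclass(frozen=True)
class ProcessingRecipe:
    """Parameters of one processing route.

    lb: exponential line broadening in Hz; td_eff: effective time-domain size
    after truncation (None = no truncation); lp_coefficients / lp_output:
    forward linear prediction (0 coefficients = off); zero_fill: final
    transform size (None = next power of two >= 2x effective length).
    """

    name: str
    lb: float = 0.0
    td_eff: int | None = None
    lp_coefficients: int = 0
    lp_output: int = 0
    zero_fill: int | None = None

    def __post_init__(self):
        if self.lb < 0:
            raise ValueError("line broadening must be >= 0")
        if self.lp_coefficients and self.lp_output < 1:
            raise ValueError("lp_output required when prediction is active")


RECIPES: dict[str, ProcessingRecipe] = {
    "lb1_trunc": ProcessingRecipe("lb1_trunc", lb=1.0, td_eff=512),
    "lb1_trunc_lp": ProcessingRecipe(
        "lb1_trunc_lp", lb=1.0, td_eff=512, lp_coefficients=16, lp_output=8192
    ),
    "lb15_full": ProcessingRecipe("lb15_full", lb=15.0),
}


def truncate(fid: Fid, td_eff: int) -> Fid:
    """Keep the first ``td_eff`` complex points."""
    if not 2 <= td_eff <= len(fid):
        raise ValueError(f"td_eff must be in [2, {len(fid)}], got {td_eff}")
    return fid._step(fid.points[:td_eff], f"truncate({td_eff})")


def apodize_exponential(fid: Fid, lb: float) -> Fid:
    """Exponential window (EM): point k scaled by exp(-pi*lb*k*dwell)."""
    if lb < 0:
        raise ValueError("line broadening must be >= 0")
    if lb == 0:
        return fid._step(fid.points, "em(0)")
    t = np.arange(len(fid)) * fid.dwell
    return fid._step(fid.points * np.exp(-np.pi * lb * t), f"em({lb})")


def _reflect_unstable_roots(coeffs: np.ndarray) -> np.ndarray:
    """Move prediction-polynomial roots outside the unit circle inside.

    Forward prediction with any root of magnitude > 1 diverges; reflecting a
    root r to 1/conj(r) keeps the modelled frequencies but makes the
    extrapolated components decay. No-op for stable coefficient sets.
    """
    poly = np.concatenate(([1.0 + 0j], -coeffs))
    roots = np.roots(poly)
    bad = np.abs(roots) > 1.0
    if not bad.any():
        return coeffs
    roots[bad] = 1.0 / np.conj(roots[bad])
    newpoly = np.poly(roots)
    return -newpoly[1:] / newpoly[0]


def linear_predict(fid: Fid, n_coefficients: int = 16, n_output: int = 8192) -> Fid:
    """Forward autoregressive extrapolation of a truncated FID.

    Coefficients are estimated by least squares on the existing points
    (minimum-norm solution when the data contain fewer modes than
    coefficients); unstable roots are reflected inside the unit circle before
    extrapolating. Existing points are returned unchanged. A rank-deficient
    or non-finite estimation falls back to zero-filling to ``n_output``.
    """
    n = len(fid)
    if not 1 <= n_coefficients < n:
        raise ValueError("need length > n_coefficients >= 1")
    if n_output < n:
        raise ValueError("n_output must be >= current length")
    x = fid.points
    m = n_coefficients
    out = np.zeros(n_output, dtype=complex)
    out[:n] = x
    if not np.any(x):
        return fid._step(out, f"lp({m},{n_output})")
    # rows: x[k-1], ..., x[k-m] predicting x[k]
    rows = np.lib.stride_tricks.sliding_window_view(x, m)[:-1][:, ::-1]
    try:
        coeffs, *_ = np.linalg.lstsq(rows, x[m:], rcond=None)
        coeffs = _reflect_unstable_roots(coeffs)
    except np.linalg.LinAlgError:
        coeffs = None
    if coeffs is None or not np.all(np.isfinite(coeffs)):
        return fid._step(out, f"lp-failed-zerofill({n_output})")
    for k in range(n, n_output):
        out[k] = np.dot(coeffs, out[k - 1: k - 1 - m: -1])
    return fid._step(out, f"lp({m},{n_output})")


def _default_zero_fill(n: int) -> int:
    return 1 << int(np.ceil(np.log2(2 * n)))


def to_spectrum(fid: Fid, zero_fill: int | None = None) -> Spectrum:
    """Fourier transform to a real spectrum on a descending ppm axis.

    The first point is halved before the transform (standard half-dwell
    correction, removes the flat baseline offset of a discrete Lorentzian),
    the FID is zero-filled to ``zero_fill`` points, and the real part is
    returned with zero-order phase 0 - the convention under which a
    resonance simulated with positive amplitude gives a positive absorptive
    peak. The axis is ``carrier + f/spectrometer_freq`` in ppm, descending.
    """
    sfo = fid.meta.get("spectrometer_freq")
    carrier = fid.meta.get("carrier")
    if sfo is None or carrier is None:
        raise ValueError("FID metadata must carry spectrometer_freq and carrier")
    n = len(fid)
    nfft = _default_zero_fill(n) if zero_fill is None else int(zero_fill)
    if nfft < n:
        raise ValueError("zero_fill must be >= FID length")
    pts = fid.points.copy()
    pts[0] *= 0.5
    freq = np.fft.fftshift(np.fft.fft(pts, n=nfft))
    hz = np.fft.fftshift(np.fft.fftfreq(nfft, d=fid.dwell))
    ppm = carrier + hz / sfo
    # descending axis (NMR display convention)
    return Spectrum(
        intensities=freq.real[::-1],
        ppm=ppm[::-1],
        meta=dict(fid.meta),
        provenance=fid.provenance + (f"ft({nfft})",),
    )


def run_recipe(fid: Fid, recipe: ProcessingRecipe | str = "lb1_trunc") -> Spectrum:
    """Apply a full recipe: truncate -> linear predict -> apodize -> FT."""
    if isinstance(recipe, str):
        try:
            recipe = RECIPES[recipe]
        except KeyError:
            raise ValueError(
                f"unknown recipe {recipe!r}; choose from {sorted(RECIPES)}"
            ) from None
    out = fid
    if recipe.td_eff is not None:
        out = truncate(out, recipe.td_eff)
    if recipe.lp_coefficients:
        out = linear_predict(out, recipe.lp_coefficients, recipe.lp_output)
    out = apodize_exponential(out, recipe.lb)
    return to_spectrum(out, recipe.zero_fill)
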