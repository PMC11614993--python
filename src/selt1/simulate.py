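"""Synthetic 1D imino FIDs and inversion-recovery experiment series.

The forward model is the one the analysis pipeline assumes: a handful of
Lorentzian imino resonances (10-15 ppm) whose integrated amplitude at recovery
delay tau follows the mono-exponential inversion-recovery law

    I(tau) = A + D * exp(-tau / selT1)

with A the equilibrium amplitude, D the inversion coefficient (-2A for a
perfect inversion), and selT1 the selective longitudinal relaxation time.
White Gaussian noise is added independently to the real and imaginary
channels, and a multiplicative linear drift in wall-clock time emulates
sample deterioration (cell death) over the course of a measurement session.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .processing import Fid

__all__ = [
    "ResonanceSpec",
    "AcquisitionConfig",
    "DelaySchedule",
    "DriftModel",
    "simulate_fid",
    "simulate_experiment",
    "simulate_recovery_points",
    "resonance_preset",
    "delay_schedule_preset",
    "calibrate_noise_sigma",
    "SELT1_IN_VITRO",
    "SELT1_IN_CELL",
    "SELT1_RATIO_PRINTED",
]


# Fitted selective T1 values (ms, standard error) for the dsA2 imino peaks:
# buffered in vitro sample and the global in-cell fit over the first technical
# replicate of three biological replicates. Peaks that are resolved in vitro
# merge into composite peaks in the broadened in-cell spectra.
SELT1_IN_VITRO: dict[str, tuple[float, float]] = {
    "T8": (331.0, 8.0),
    "T9": (328.0, 6.0),
    "G20": (294.0, 12.0),
    "G6": (286.0, 10.0),
    "G11": (108.0, 2.0),
    "T4/T22": (253.0, 5.0),
    "T18": (224.0, 3.0),
}

SELT1_IN_CELL: dict[str, tuple[float, float]] = {
    "T8": (49.0, 13.0),
    "T9": (45.0, 17.0),
    "G20/G6": (101.0, 18.0),
    "G11": (24.0, 2.0),
    "T4/T22/T18": (84.0, 10.0),
}

# Published one-decimal in vitro / in-cell ratios for reference.
SELT1_RATIO_PRINTED: dict[str, float] = {
    "T8": 6.8,
    "T9": 7.2,
    "G20/G6": 2.9,
    "G11": 4.5,
    "T4/T22": 3.1,
    "T18": 2.8,
}


@dataclass(frozen=True)
class ResonanceSpec:
    """One imino resonance of the recovery model.

    Parameters
    ----------
    peak_id : str
        Label, e.g. ``"T4/T22/T18"``.
    shift : float
        Chemical shift in ppm.
    linewidth : float
        Lorentzian full width at half maximum in Hz, must be positive.
    A : float
        Equilibrium amplitude (arbitrary units); the peak amplitude at
        tau -> infinity.
    D : float
        Inversion coefficient, same units; -2A for perfect inversion, so the
        amplitude at tau = 0 is A + D = -A.
    selt1 : float
        Selective longitudinal relaxation time in ms, must be positive.
    """

    peak_id: str
    shift: float
    linewidth: float
    A: float
    selt1: float
    D: float | None = None

    def __post_init__(self):
        if self.linewidth <= 0:
            raise ValueError(f"linewidth must be > 0, got {self.linewidth}")
        if self.selt1 <= 0:
            raise ValueError(f"selT1 must be > 0, got {self.selt1}")
        if self.D is None:
            object.__setattr__(self, "D", -2.0 * self.A)

    def amplitude(self, tau_ms: float) -> float:
        """Recovery-law amplitude A + D*exp(-tau/selT1) at delay tau (ms)."""
        return self.A + self.D * math.exp(-tau_ms / self.selt1)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition parameters of the simulated 1D experiment.

    Defaults correspond to a 600.16 MHz 1H spectrometer with a 22.04 ppm
    spectral window centred on the imino region.
    """

    spectrometer_freq: float = 600.16  # MHz
    spectral_width: float = 22.04      # ppm
    carrier: float = 13.5              # ppm
    n_points: int = 2048               # complex time-domain points
    noise_sigma: float = 0.0           # per-point Gaussian sd, each channel
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 2 or self.n_points % 2:
            raise ValueError("n_points must be even and >= 2")
        if self.spectral_width <= 0:
            raise ValueError("spectral_width must be > 0")

    @property
    def sw_hz(self) -> float:
        return self.spectral_width * self.spectrometer_freq

    @property
    def dwell(self) -> float:
        """Sampling interval in s."""
        return 1.0 / self.sw_hz

    @property
    def acquisition_time(self) -> float:
        """Duration of the sampled FID in s."""
        return self.n_points * self.dwell


@dataclass(frozen=True)
class DelaySchedule:
    """Ordered recovery delays with reference flags and wall-clock starts.

    Repeated short "reference" delays (0.320 ms in the published schedules)
    bracket the series and are what the deterioration correction fits.
    """

    delays: tuple[float, ...]
    is_reference: tuple[bool, ...]
    start_times: tuple[float, ...]  # min

    def __post_init__(self):
        n = len(self.delays)
        if len(self.is_reference) != n or len(self.start_times) != n:
            raise ValueError("delays, is_reference, start_times must align")
        if any(d <= 0 for d in self.delays):
            raise ValueError("all delays must be > 0")
        if sum(self.is_reference) < 2:
            raise ValueError("need >= 2 reference entries for drift fitting")
        if any(b <= a for a, b in zip(self.start_times, self.start_times[1:])):
            raise ValueError("start_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.delays)


@dataclass(frozen=True)
class DriftModel:
    """Multiplicative linear intensity drift over wall-clock time.

    factor(t) = 1 + relative_slope * (t - reference_time); every amplitude is
    scaled by this factor. Models proportional signal loss from cell death /
    sample deterioration. The factor must stay positive over the schedule.
    """

    relative_slope: float = 0.0   # 1/min
    reference_time: float = 0.0   # min

    def factor(self, t_min):
        return 1.0 + self.relative_slope * (np.asarray(t_min, float) - self.reference_time)


NO_DRIFT = DriftModel()

# Saturation recovery per scan (acquisition 310 ms + D1 658.5 ms) and scan
# count used to derive wall-clock start times of the schedule presets.
_BASE_RECOVERY_MS = 968.5
_N_SCANS = 1024

_SCHEDULE_DELAYS = {
    # long schedule: three technical replicates per biological replicate
    "long9": (0.320, 150.0, 300.0, 600.0, 1200.0, 0.320, 225.0, 450.0, 900.0),
    # short schedule: fourth preparation, samples the early recovery
    "short9": (0.320, 15.0, 50.0, 250.0, 900.0, 0.320, 7.5, 75.0, 4.0),
}


def delay_schedule_preset(name: str) -> DelaySchedule:
    """Published nine-delay schedules ``"long9"`` and ``"short9"``.

    Start times are cumulative scan-time estimates: each delay's experiment
    lasts n_scans * (base recovery + tau).
    """
    try:
        delays = _SCHEDULE_DELAYS[name]
    except KeyError:
        raise ValueError(
            f"unknown schedule {name!r}; choose from {sorted(_SCHEDULE_DELAYS)}"
        ) from None
    starts = []
    t = 0.0
    for tau in delays:
        starts.append(t)
        t += _N_SCANS * (_BASE_RECOVERY_MS + tau) / 1000.0 / 60.0  # min
    refs = tuple(tau == 0.320 for tau in delays)
    return DelaySchedule(delays, refs, tuple(starts))


# Representative imino chemical shifts / linewidths / amplitudes for the
# dsA2 duplex (synthetic placement; only the T4/T22/T18 composite at 13.4 ppm
# is anchored by the published spectra). In-cell peaks are broadened and the
# near-degenerate resonances merge.
_PRESETS = {
    "in_vitro": [
        # (peak_id, shift ppm, lw Hz, A)
        ("T8", 13.95, 8.0, 1.0),
        ("T9", 13.70, 8.0, 0.8),
        ("T4/T22", 13.45, 8.0, 2.0),
        ("T18", 13.25, 8.0, 1.0),
        ("G20", 12.90, 8.0, 1.0),
        ("G6", 12.65, 8.0, 1.0),
        ("G11", 12.15, 8.0, 1.0),
    ],
    "in_cell": [
        ("T8", 13.95, 25.0, 1.0),
        ("T9", 13.70, 25.0, 0.8),
        ("T4/T22/T18", 13.40, 25.0, 3.0),
        ("G20/G6", 12.80, 25.0, 1.6),
        ("G11", 12.15, 25.0, 1.0),
    ],
}


def resonance_preset(name: str) -> list[ResonanceSpec]:
    """Named resonance bundles ``"in_vitro"`` and ``"in_cell"``.

    selT1 values are the fitted values of the corresponding condition
    (global in-cell fit for ``"in_cell"``); D defaults to -2A.
    """
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    table = SELT1_IN_VITRO if name == "in_vitro" else SELT1_IN_CELL
    return [
        ResonanceSpec(peak_id=pid, shift=shift, linewidth=lw, A=a, selt1=table[pid][0])
        for pid, shift, lw, a in _PRESETS[name]
    ]


def _fid_meta(acq: AcquisitionConfig, tau: float, start_time: float,
              is_reference: bool) -> dict:
    return {
        "tau_ms": tau,
        "start_time_min": start_time,
        "is_reference": is_reference,
        "spectrometer_freq": acq.spectrometer_freq,
        "spectral_width": acq.spectral_width,
        "carrier": acq.carrier,
    }


def simulate_fid(
    resonances: list[ResonanceSpec],
    acq: AcquisitionConfig,
    tau: float,
    drift: DriftModel = NO_DRIFT,
    start_time: float = 0.0,
    is_reference: bool = False,
    rng: np.random.Generator | None = None,
) -> Fid:
    """Simulate one complex FID at recovery delay ``tau`` (ms).

    Each resonance contributes ``amp * exp(2j*pi*dnu*t - pi*lw*t)`` where
    ``amp = (A + D*exp(-tau/selT1)) * drift_factor`` and ``dnu`` is the offset
    from the carrier in Hz; iid Gaussian noise of sd ``acq.noise_sigma`` is
    added to the real and imaginary parts independently.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0 ms, got {tau}")
    if not resonances:
        raise ValueError("resonance list must not be empty")
    fac = float(drift.factor(start_time))
    if fac <= 0:
        raise ValueError("drift factor must stay positive over the schedule")
    t = np.arange(acq.n_points) * acq.dwell
    points = np.zeros(acq.n_points, dtype=complex)
    for res in resonances:
        amp = res.amplitude(tau) * fac
        dnu = (res.shift - acq.carrier) * acq.spectrometer_freq  # Hz
        points += amp * np.exp((2j * np.pi * dnu - np.pi * res.linewidth) * t)
    if acq.noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(acq.seed)
        noise = rng.normal(scale=acq.noise_sigma, size=(2, acq.n_points))
        points = points + noise[0] + 1j * noise[1]
    return Fid(points=points, dwell=acq.dwell,
               meta=_fid_meta(acq, tau, start_time, is_reference),
               provenance=("simulate",))


def simulate_experiment(
    resonances: list[ResonanceSpec],
    acq: AcquisitionConfig,
    schedule: DelaySchedule,
    drift: DriftModel = NO_DRIFT,
) -> list[Fid]:
    """Simulate one technical replicate: one FID per scheduled delay.

    Deterministic under a fixed ``acq.seed``; noise is drawn from a single
    seeded generator in schedule order.
    """
    rng = np.random.default_rng(acq.seed)
    return [
        simulate_fid(resonances, acq, tau, drift, t0, ref, rng=rng)
        for tau, ref, t0 in zip(schedule.delays, schedule.is_reference,
                                schedule.start_times)
    ]


def simulate_recovery_points(
    resonance: ResonanceSpec,
    schedule: DelaySchedule,
    snr: float = 10.0,
    drift: DriftModel = NO_DRIFT,
    rng: np.random.Generator | None = None,
):
    """Intensity-level simulation of one recovery series for one peak.

    Bypasses the FID/spectrum stage: intensities follow the recovery law with
    multiplicative drift plus Gaussian noise of sd ``A / (2*snr)`` (the noise
    level at which the equilibrium peak has the given SINO-style SNR). Returns
    arrays ``(tau, intensity, error, start_time, is_reference)`` ready for
    :class:`selt1.recovery.RecoverySeries`. ``snr=inf`` gives noiseless data.
    """
    tau = np.asarray(schedule.delays, float)
    t0 = np.asarray(schedule.start_times, float)
    ideal = (resonance.A + resonance.D * np.exp(-tau / resonance.selt1))
    ideal = ideal * drift.factor(t0)
    sigma = abs(resonance.A) / (2.0 * snr) if np.isfinite(snr) else 0.0
    if sigma > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        intensity = ideal + rng.normal(scale=sigma, size=ideal.size)
        error = np.full_like(ideal, sigma)
    else:
        intensity = ideal.copy()
        error = np.ones_like(ideal)
    return tau, intensity, error, t0, np.asarray(schedule.is_reference, bool)


def calibrate_noise_sigma(
    resonances: list[ResonanceSpec],
    acq: AcquisitionConfig,
    target_snr: float,
    recipe=None,
    peak_id: str | None = None,
    n_realizations: int = 8,
    seed: int = 0,
) -> float:
    """Time-domain noise sd giving a target spectrum SNR for a preset.

    The target is the SINO-style SNR (peak / (2 * rms noise), noise region
    15-16 ppm) of the chosen peak at equilibrium (tau >> selT1), under the
    given processing recipe (default ``"lb1_trunc"``). The spectral rms per
    unit time-domain sigma is measured empirically on noise-only FIDs, which
    keeps the calibration valid for any recipe including linear prediction.
    """
    from .extraction import rms_noise
    from .processing import RECIPES, run_recipe

    if target_snr <= 0:
        raise ValueError("target_snr must be > 0")
    if recipe is None:
        recipe = RECIPES["lb1_trunc"]
    if peak_id is None:
        res = max(resonances, key=lambda r: abs(r.A))
    else:
        res = next(r for r in resonances if r.peak_id == peak_id)
    quiet = replace(acq, noise_sigma=0.0)
    tau_eq = 50.0 * max(r.selt1 for r in resonances)
    spec = run_recipe(simulate_fid(resonances, quiet, tau_eq), recipe)
    peak_height = spec.intensity_at(res.shift)
    rng = np.random.default_rng(seed)
    zero = [ResonanceSpec("zero", acq.carrier, 1.0, 0.0, 1.0)]
    noisy = replace(acq, noise_sigma=1.0)
    rms = np.mean([
        rms_noise(run_recipe(simulate_fid(zero, noisy, 1.0, rng=rng), recipe))
        for _ in range(n_realizations)
    ])
    return peak_height / (2.0 * target_snr * rms)
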