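"""Mono-exponential inversion-recovery fitting with shared-parameter variants.

The model is I(tau) = A + D*exp(-tau/selT1): A is the equilibrium intensity,
D the coefficient correcting for imperfect inversion (-2A for a perfect
inversion), selT1 the selective longitudinal relaxation time. Fits are
weighted nonlinear least squares (weights 1/error^2 by default).

The module follows the statsmodels convention: a model object is built from
data and ``fit()`` returns a results object carrying estimates, standard
errors, covariance, diagnostics and ``summary()``.

* :class:`InversionRecovery` - one recovery series, three free parameters.
* :class:`GlobalInversionRecovery` - several series (technical or biological
  replicates) sharing one selT1, with per-series A and D.

Sample deterioration over the hours-long measurement is tracked by the
repeated short reference delay interleaved in the schedule: a straight line
fitted through the reference intensities versus wall-clock time
(:func:`fit_drift`) gives a multiplicative correction factor
(:func:`correct_deterioration`) applied before fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import lmfit
import numpy as np
import pandas as pd

__all__ = [
    "RecoveryPoint",
    "RecoverySeries",
    "DriftFit",
    "fit_drift",
    "correct_deterioration",
    "renormalize_replicates",
    "InversionRecovery",
    "GlobalInversionRecovery",
    "InversionRecoveryResults",
    "GlobalInversionRecoveryResults",
    "fit_recovery",
    "fit_recovery_global",
    "normalize",
    "ratio_table",
]


@dataclass(frozen=True)
class RecoveryPoint:
    """One (tau, intensity) observation of a recovery curve."""

    tau: float               # ms
    intensity: float         # amplitude units
    error: float = 1.0       # standard error, same units
    start_time: float = 0.0  # wall-clock start of this delay's experiment, min
    is_reference: bool = False

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be > 0 ms")
        if self.error <= 0:
            raise ValueError("error must be > 0")


@dataclass(frozen=True)
class RecoverySeries:
    """Recovery curve of one peak: points plus replicate labels.

    ``shift_drift`` is the per-spectrum diagnostic from extraction (observed
    local peak maximum minus the frozen shift, ppm); it is reported, never
    acted on.
    """

    peak_id: str
    points: tuple
    replicate_id: tuple = ("bio1", "tech1")
    shift_drift: tuple = ()

    def __post_init__(self):
        if not self.points:
            raise ValueError("series must contain at least one point")

    def __len__(self):
        return len(self.points)

    @property
    def tau(self) -> np.ndarray:
        return np.array([p.tau for p in self.points])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p.intensity for p in self.points])

    @property
    def error(self) -> np.ndarray:
        return np.array([p.error for p in self.points])

    @property
    def start_time(self) -> np.ndarray:
        return np.array([p.start_time for p in self.points])

    @property
    def is_reference(self) -> np.ndarray:
        return np.array([p.is_reference for p in self.points])

    def scaled(self, factor: float) -> "RecoverySeries":
        """Series with every intensity and error multiplied by ``factor``."""
        pts = tuple(replace(p, intensity=p.intensity * factor,
                            error=p.error * abs(factor)) for p in self.points)
        return replace(self, points=pts)

    @classmethod
    def from_arrays(cls, peak_id, tau, intensity, error=None, start_time=None,
                    is_reference=None, replicate_id=("bio1", "tech1")):
        tau = np.asarray(tau, float)
        intensity = np.asarray(intensity, float)
        error = np.ones_like(tau) if error is None else np.asarray(error, float)
        start_time = np.zeros_like(tau) if start_time is None else np.asarray(start_time, float)
        if start_time is not None and np.ndim(start_time) == 0:
            start_time = np.full_like(tau, float(start_time))
        is_reference = (np.zeros(tau.size, bool) if is_reference is None
                        else np.asarray(is_reference, bool))
        pts = tuple(RecoveryPoint(t, i, e, s, bool(r)) for t, i, e, s, r in
                    zip(tau, intensity, error, start_time, is_reference))
        return cls(peak_id=peak_id, points=pts, replicate_id=tuple(replicate_id))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "peak_id": self.peak_id,
            "tau_ms": self.tau,
            "intensity": self.intensity,
            "error": self.error,
            "start_time_min": self.start_time,
            "is_reference": self.is_reference,
        })


# ---------------------------------------------------------------------------
# deterioration (drift) correction


@dataclass(frozen=True)
class DriftFit:
    """Straight line through the reference-delay intensities vs time.

    ``intercept`` is the fitted reference intensity at the first reference
    start time ``t0``; ``slope`` is in intensity units per minute and
    ``relative_slope`` = slope / intercept (1/min).
    """

    slope: float
    slope_se: float
    intercept: float
    t0: float

    @property
    def relative_slope(self) -> float:
        return self.slope / self.intercept

    def value(self, t_min):
        return self.intercept + self.slope * (np.asarray(t_min, float) - self.t0)

    def factor(self, t_min):
        """Correction factor, normalized to 1 at the first reference time."""
        return self.value(t_min) / self.intercept


def fit_drift(series: RecoverySeries) -> DriftFit:
    """Ordinary least-squares line through the reference points only."""
    mask = series.is_reference
    if mask.sum() < 2:
        raise ValueError("need >= 2 reference points to fit deterioration")
    t = series.start_time[mask]
    y = series.intensity[mask]
    t0 = t[0]
    slope, intercept = np.polyfit(t - t0, y, 1)
    if t.size > 2:
        resid = y - (intercept + slope * (t - t0))
        s2 = resid @ resid / (t.size - 2)
        sxx = np.sum((t - t.mean()) ** 2)
        slope_se = math.sqrt(s2 / sxx)
    else:
        slope_se = math.nan
    return DriftFit(slope=float(slope), slope_se=slope_se,
                    intercept=float(intercept), t0=float(t0))


def correct_deterioration(series: RecoverySeries, drift: DriftFit | None = None,
                          mode: str = "multiplicative") -> RecoverySeries:
    """Remove the fitted linear deterioration from a series.

    ``multiplicative`` (default) divides each intensity and error by the
    drift factor at that point's start time - appropriate when cell loss
    scales all signal proportionally. ``additive`` subtracts the line's
    departure from its initial value instead.
    """
    if drift is None:
        drift = fit_drift(series)
    fac = drift.factor(series.start_time)
    if np.any(fac <= 0):
        raise ValueError("drift factor must stay positive over the schedule")
    if mode == "multiplicative":
        pts = tuple(replace(p, intensity=p.intensity / f, error=p.error / f)
                    for p, f in zip(series.points, fac))
    elif mode == "additive":
        delta = drift.value(series.start_time) - drift.intercept
        pts = tuple(replace(p, intensity=p.intensity - d)
                    for p, d in zip(series.points, delta))
    else:
        raise ValueError("mode must be 'multiplicative' or 'additive'")
    return replace(series, points=pts)


def renormalize_replicates(series_list: list[RecoverySeries]) -> list[RecoverySeries]:
    """Put technical replicates on a common scale via the remeasured
    reference delay: each series is scaled by (first reference intensity of
    the first series) / (its own first reference intensity)."""
    if not series_list:
        return []

    def first_ref(s: RecoverySeries) -> float:
        mask = s.is_reference
        if not mask.any():
            raise ValueError(f"series {s.replicate_id} has no reference point")
        return float(s.intensity[mask][0])

    base = first_ref(series_list[0])
    return [s.scaled(base / first_ref(s)) for s in series_list]


# ---------------------------------------------------------------------------
# model fitting


def _recovery_model(tau, selt1, A, D):
    return A + D * np.exp(-tau / selt1)


def _initial_guess(tau, y):
    """Starting values: A from the largest delay, D from the smallest,
    selT1 from the delay where the remaining departure from A is closest to
    |D|/e (median delay as fallback)."""
    a0 = y[np.argmax(tau)]
    d0 = y[np.argmin(tau)] - a0
    if d0 == 0:
        d0 = -2.0 * a0 if a0 != 0 else -1.0
    target = abs(d0) / math.e
    dep = np.abs(y - a0)
    order = np.argsort(np.abs(dep - target))
    t10 = tau[order[0]]
    if not np.isfinite(t10) or t10 <= 0:
        t10 = float(np.median(tau))
    return float(t10), float(a0), float(d0)


_T1_MIN = 1e-9


def _fit_status(minres, selt1, selt1_se):
    if not minres.success:
        return "failed", f"optimizer did not converge: {minres.message}"
    if selt1 <= 10 * _T1_MIN:
        return "failed", "selT1 collapsed to its lower bound"
    if selt1_se is None or not np.isfinite(selt1_se):
        return "failed", "covariance could not be estimated"
    if selt1_se / selt1 > 1.0:
        return "failed", "relative standard error of selT1 exceeds 100%"
    return "ok", "converged"


class InversionRecovery:
    """Inversion-recovery model I(tau) = A + D*exp(-tau/selT1) for one series.

    Parameters
    ----------
    series : RecoverySeries
        Observed recovery curve; needs at least four non-reference points
        for the three-parameter fit.
    weighted : bool
        Weight residuals by 1/error (default); unweighted otherwise.

    Examples
    --------
    >>> series = RecoverySeries.from_arrays("T4/T22/T18", [1, 50, 150, 600],
    ...                                     [-0.9, 0.1, 0.7, 1.0])
    >>> res = InversionRecovery(series).fit()
    >>> res.selt1  # doctest: +SKIP
    """

    def __init__(self, series: RecoverySeries, weighted: bool = True):
        if (~series.is_reference).sum() < 4:
            raise ValueError("need >= 4 non-reference points for a "
                             "3-parameter fit")
        self.series = series
        self.weighted = weighted

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, peak_id: str | None = None,
                       weighted: bool = True) -> "InversionRecovery":
        """Build from a series table (columns tau_ms, intensity, error,
        start_time_min, is_reference, peak_id)."""
        if peak_id is not None:
            df = df[df["peak_id"] == peak_id]
        if df.empty:
            raise ValueError(f"no rows for peak {peak_id!r}")
        series = RecoverySeries.from_arrays(
            peak_id=df["peak_id"].iloc[0] if "peak_id" in df else "peak",
            tau=df["tau_ms"], intensity=df["intensity"],
            error=df.get("error"), start_time=df.get("start_time_min"),
            is_reference=df.get("is_reference"),
        )
        return cls(series, weighted=weighted)

    def _weights(self):
        return 1.0 / self.series.error if self.weighted else np.ones(len(self.series))

    def fit(self) -> "InversionRecoveryResults":
        tau, y = self.series.tau, self.series.intensity
        w = self._weights()
        t10, a0, d0 = _initial_guess(tau, y)
        params = lmfit.Parameters()
        params.add("selt1", value=t10, min=_T1_MIN)
        params.add("A", value=a0)
        params.add("D", value=d0)

        def residual(p):
            return (_recovery_model(tau, p["selt1"], p["A"], p["D"]) - y) * w

        # with known per-point errors the weighted-NLS covariance is used as
        # is; without them it is scaled by the reduced chi-square
        minres = lmfit.minimize(residual, params, scale_covar=not self.weighted)
        return InversionRecoveryResults(self, minres)


class _ResultsBase:
    """Shared covariance/uncertainty plumbing for fit results."""

    def __init__(self, model, minres):
        self.model = model
        self.minres = minres
        names = list(minres.params)
        self.param_names = names
        self.params = pd.Series({k: minres.params[k].value for k in names})
        self.bse = pd.Series(
            {k: (minres.params[k].stderr if minres.params[k].stderr is not None
                 else math.nan) for k in names})
        if getattr(minres, "covar", None) is not None:
            var_names = list(minres.var_names)
            cov = pd.DataFrame(minres.covar, index=var_names, columns=var_names)
        else:
            cov = pd.DataFrame(np.nan, index=names, columns=names)
        self.cov_params = cov
        self.redchi = minres.redchi
        self.nfev = minres.nfev
        self.status, self.message = _fit_status(
            minres, self.params["selt1"], self.bse["selt1"])

    @property
    def selt1(self) -> float:
        """Fitted selective T1 in ms."""
        return float(self.params["selt1"])

    @property
    def selt1_se(self) -> float:
        return float(self.bse["selt1"])

    @property
    def ok(self) -> bool:
        return self.status == "ok"


class InversionRecoveryResults(_ResultsBase):
    """Fit results for one series: selT1, A, D with standard errors."""

    @property
    def A(self) -> float:
        return float(self.params["A"])

    @property
    def D(self) -> float:
        return float(self.params["D"])

    def predict(self, tau) -> np.ndarray:
        return _recovery_model(np.asarray(tau, float), self.selt1, self.A, self.D)

    @property
    def normalized_points(self) -> pd.DataFrame:
        """Intensities divided by the fitted equilibrium amplitude A, so the
        curve tends to 1 at large delay (and to -1 at tau=0 for a perfect
        inversion)."""
        return normalize(self)

    def summary(self) -> str:
        s = self.model.series
        lines = [
            "Inversion recovery fit: I(tau) = A + D*exp(-tau/selT1)",
            f"peak: {s.peak_id}   replicate: {s.replicate_id}   "
            f"n={len(s)}   weighted={self.model.weighted}",
            f"status: {self.status} ({self.message})   "
            f"red. chi2 = {self.redchi:.4g}",
            "-" * 58,
            f"{'param':>8} {'value':>14} {'std err':>12}",
        ]
        for k in self.param_names:
            lines.append(f"{k:>8} {self.params[k]:>14.6g} {self.bse[k]:>12.3g}")
        lines.append("-" * 58)
        lines.append(f"selT1 = {self.selt1:.1f} +/- {self.selt1_se:.1f} ms")
        return "\n".join(lines)

    def plot(self, ax=None, normalized: bool = False):
        """Recovery curve with data points and the fitted model."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        s = self.model.series
        scale = self.A if normalized else 1.0
        grid = np.linspace(min(s.tau), max(s.tau), 300)
        ax.errorbar(s.tau, s.intensity / scale, yerr=s.error / abs(scale),
                    fmt="o", label="data")
        ax.plot(grid, self.predict(grid) / scale, "-",
                label=f"selT1 = {self.selt1:.0f} ms")
        ax.set_xlabel("recovery delay tau (ms)")
        ax.set_ylabel("I / A" if normalized else "intensity")
        ax.set_title(s.peak_id)
        ax.legend()
        return ax


class GlobalInversionRecovery:
    """Several recovery series of one peak sharing a single selT1.

    Per-series equilibrium amplitudes A_i and inversion coefficients D_i stay
    free; only the relaxation time is shared. With a single series the fit
    reduces to :class:`InversionRecovery`.
    """

    def __init__(self, series_list: list[RecoverySeries], weighted: bool = True,
                 renormalize: bool = False):
        if not series_list:
            raise ValueError("need at least one series")
        ids = {s.peak_id for s in series_list}
        if len(ids) > 1:
            raise ValueError(f"series mix different peaks: {sorted(ids)}")
        for s in series_list:
            if (~s.is_reference).sum() < 4:
                raise ValueError("every series needs >= 4 non-reference points")
        if renormalize:
            series_list = renormalize_replicates(series_list)
        self.series_list = list(series_list)
        self.weighted = weighted

    def fit(self) -> "GlobalInversionRecoveryResults":
        params = lmfit.Parameters()
        guesses = [_initial_guess(s.tau, s.intensity) for s in self.series_list]
        t10 = float(np.median([g[0] for g in guesses]))
        params.add("selt1", value=t10, min=_T1_MIN)
        for i, (_, a0, d0) in enumerate(guesses):
            params.add(f"A_{i}", value=a0)
            params.add(f"D_{i}", value=d0)
        data = [(s.tau, s.intensity,
                 1.0 / s.error if self.weighted else np.ones(len(s)))
                for s in self.series_list]

        def residual(p):
            parts = [
                (_recovery_model(tau, p["selt1"], p[f"A_{i}"], p[f"D_{i}"]) - y) * w
                for i, (tau, y, w) in enumerate(data)
            ]
            return np.concatenate(parts)

        minres = lmfit.minimize(residual, params, scale_covar=not self.weighted)
        return GlobalInversionRecoveryResults(self, minres)


class GlobalInversionRecoveryResults(_ResultsBase):
    """Shared-selT1 fit results: one selT1, per-series A and D."""

    @property
    def per_series(self) -> pd.DataFrame:
        rows = []
        for i, s in enumerate(self.model.series_list):
            rows.append({
                "replicate_id": "/".join(s.replicate_id),
                "A": self.params[f"A_{i}"], "A_se": self.bse[f"A_{i}"],
                "D": self.params[f"D_{i}"], "D_se": self.bse[f"D_{i}"],
            })
        return pd.DataFrame(rows)

    def predict(self, tau, i: int = 0) -> np.ndarray:
        return _recovery_model(np.asarray(tau, float), self.selt1,
                               self.params[f"A_{i}"], self.params[f"D_{i}"])

    def summary(self) -> str:
        peak = self.model.series_list[0].peak_id
        lines = [
            "Global inversion recovery fit (shared selT1)",
            f"peak: {peak}   series: {len(self.model.series_list)}   "
            f"weighted={self.model.weighted}",
            f"status: {self.status} ({self.message})   "
            f"red. chi2 = {self.redchi:.4g}",
            "-" * 58,
            f"shared selT1 = {self.selt1:.1f} +/- {self.selt1_se:.1f} ms",
            self.per_series.to_string(index=False),
        ]
        return "\n".join(lines)


def fit_recovery(series: RecoverySeries, weighted: bool = True) -> InversionRecoveryResults:
    """Fit one series; convenience wrapper around :class:`InversionRecovery`."""
    return InversionRecovery(series, weighted=weighted).fit()


def fit_recovery_global(series_list: list[RecoverySeries], weighted: bool = True,
                        renormalize: bool = False) -> GlobalInversionRecoveryResults:
    """Fit several series with one shared selT1."""
    return GlobalInversionRecovery(series_list, weighted=weighted,
                                   renormalize=renormalize).fit()


def normalize(results: InversionRecoveryResults) -> pd.DataFrame:
    """Series points normalized by the fitted equilibrium amplitude A."""
    if results.A == 0:
        raise ValueError("cannot normalize: fitted A is zero")
    s = results.model.series
    a = results.A
    return pd.DataFrame({
        "tau_ms": s.tau,
        "normalized_intensity": s.intensity / a,
        "normalized_error": s.error / abs(a),
    })


def _as_value_se(entry) -> tuple[float, float]:
    if isinstance(entry, _ResultsBase):
        return entry.selt1, entry.selt1_se
    value, se = entry
    return float(value), float(se)


def _match_in_cell(peak: str, in_cell_keys) -> str | None:
    """Match an in vitro peak label to its (possibly composite) in-cell peak:
    exact label first, then the composite whose '/'-components contain it."""
    if peak in in_cell_keys:
        return peak
    parts = set(peak.split("/"))
    for key in in_cell_keys:
        if parts <= set(key.split("/")):
            return key
    return None


def ratio_table(in_vitro: dict, in_cell: dict) -> pd.DataFrame:
    """Per-peak in vitro / in-cell selT1 ratios with propagated uncertainty.

    Values may be fit results or ``(value, se)`` pairs. Ratios are computed
    from the unrounded values and additionally reported rounded to one
    decimal; first-order error propagation combines the two relative SEs.
    Peaks without an in-cell counterpart are skipped with a warning.
    """
    rows = []
    for peak, entry in in_vitro.items():
        key = _match_in_cell(peak, in_cell.keys())
        if key is None:
            warnings.warn(f"no in-cell counterpart for peak {peak!r}; skipped")
            continue
        v, v_se = _as_value_se(entry)
        c, c_se = _as_value_se(in_cell[key])
        ratio = v / c
        ratio_se = ratio * math.hypot(v_se / v, c_se / c)
        rows.append({
            "peak_id": peak, "in_cell_peak": key,
            "selt1_in_vitro": v, "se_in_vitro": v_se,
            "selt1_in_cell": c, "se_in_cell": c_se,
            "ratio": ratio, "ratio_se": ratio_se,
            "ratio_1dp": round(ratio, 1),
        })
    return pd.DataFrame(rows)
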