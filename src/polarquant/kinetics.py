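"""GTPase assay kinetics.

Converts raw plate-reader readouts into specific GTPase activities
(GTP hydrolyzed per enzyme molecule per hour) for two assay formats:

* the continuous regenerative coupled assay, where each GTP hydrolyzed
  consumes one NADH (read as an A340 decrease, epsilon_340 = 6220 M^-1 cm^-1),
  and
* the malachite-green endpoint assay, where released inorganic phosphate
  is read at A590 against a Pi standard curve.

Fold stimulations and GAP titration curves (hyperbolic saturation fits)
are derived from the recovered rates.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "AbsorbanceTrace",
    "AssayContext",
    "TurnoverEstimate",
    "RateFit",
    "StandardCurve",
    "TitrationSeries",
    "TitrationFit",
    "fit_linear_rate",
    "trace_to_turnover",
    "estimate_turnover",
    "malachite_standard_fit",
    "endpoint_to_turnover",
    "fold_stimulation",
    "titration_analysis",
    "load_traces",
]

#: A340 below which the coupled assay is considered NADH-depleted; points at
#: or below this level are dropped from rate fits.
SATURATION_A340 = 0.05


@dataclass(frozen=True)
class AbsorbanceTrace:
    """One plate-reader time series (seconds, absorbance at 340 nm)."""

    times: np.ndarray
    a340: np.ndarray
    condition: str = ""
    replicate: int = 0

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        a340 = np.asarray(self.a340, dtype=float)
        if times.ndim != 1 or times.shape != a340.shape:
            raise ValueError("times and a340 must be 1-D arrays of equal length")
        if len(times) >= 2 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "a340", a340)


@dataclass(frozen=True)
class AssayContext:
    """Conversion constants for one assay setup.

    enzyme_conc_uM
        GTPase concentration in the reaction (µM).
    epsilon_340
        NADH extinction coefficient at 340 nm (M^-1 cm^-1).
    path_length_cm
        Effective optical path length; for a 96-well plate this depends on
        the well volume, hence configurable.
    background_condition
        Label of the no-enzyme control traces used for background
        subtraction, if any.
    """

    enzyme_conc_uM: float
    epsilon_340: float = 6220.0
    path_length_cm: float = 0.5
    background_condition: str | None = None

    def __post_init__(self):
        if self.enzyme_conc_uM <= 0 or self.epsilon_340 <= 0 or self.path_length_cm <= 0:
            raise ValueError("enzyme_conc_uM, epsilon_340 and path_length_cm must be positive")


@dataclass(frozen=True)
class TurnoverEstimate:
    """Specific activity in GTP per enzyme molecule per hour."""

    rate: float
    se: float = float("nan")
    n_replicates: int = 1
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass(frozen=True)
class RateFit:
    """OLS slope of an absorbance trace (absorbance per second)."""

    slope: float
    stderr: float
    n_points: int
    truncated: bool = False


@dataclass(frozen=True)
class StandardCurve:
    slope: float          # A590 per µM Pi
    intercept: float      # A590 of the blank
    r_squared: float
    a590_max: float       # highest standard absorbance (extrapolation bound)


@dataclass(frozen=True)
class TitrationSeries:
    """Activities (percent of a reference condition) vs titrant concentration."""

    concentrations_uM: np.ndarray
    activities: np.ndarray
    reference_label: str = ""

    def __post_init__(self):
        conc = np.asarray(self.concentrations_uM, dtype=float)
        act = np.asarray(self.activities, dtype=float)
        if conc.shape != act.shape or conc.ndim != 1:
            raise ValueError("concentrations and activities must be 1-D and equal length")
        if np.any(conc < 0) or (len(conc) >= 2 and not np.all(np.diff(conc) > 0)):
            raise ValueError("concentrations must be >= 0 and strictly increasing")
        object.__setattr__(self, "concentrations_uM", conc)
        object.__setattr__(self, "activities", act)


@dataclass(frozen=True)
class TitrationFit:
    a_max: float
    k: float
    a_0: float
    saturation_conc_uM: float | None
    flags: tuple[str, ...] = ()

    @property
    def plateau(self) -> float:
        return self.a_0 + self.a_max

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.a_0 + self.a_max * x / (self.k + x)


def fit_linear_rate(trace: AbsorbanceTrace, window: tuple[float, float] | None = None) -> RateFit:
    """OLS slope of A340 vs time over ``window`` (default: the full trace).

    If the trace reaches NADH depletion (A340 <= 0.05) the window is
    truncated just before the first depleted point.
    """
    times, a340 = trace.times, trace.a340
    if window is not None:
        keep = (times >= window[0]) & (times <= window[1])
        times, a340 = times[keep], a340[keep]
    truncated = False
    depleted = np.nonzero(a340 <= SATURATION_A340)[0]
    if depleted.size:
        times, a340 = times[: depleted[0]], a340[: depleted[0]]
        truncated = True
    if len(times) < 3:
        raise ValueError("rate fit requires at least 3 points in the window")
    res = stats.linregress(times, a340)
    return RateFit(slope=float(res.slope), stderr=float(res.stderr),
                   n_points=len(times), truncated=truncated)


def trace_to_turnover(slope, context: AssayContext, background_slope=0.0) -> TurnoverEstimate:
    """Convert an A340/s slope into GTP hydrolyzed per enzyme per hour.

    The net NADH oxidation rate is ``background_slope - slope`` (both slopes
    are negative for declining traces); division by epsilon*l gives M/s of
    NADH == GTP, which is scaled to per-hour and normalized by the enzyme
    concentration. A background steeper than the sample clamps the rate at 0.
    """
    s = slope.slope if isinstance(slope, RateFit) else float(slope)
    b = background_slope.slope if isinstance(background_slope, RateFit) else float(background_slope)
    net = b - s  # A340/s consumed by the GTPase reaction
    flags: tuple[str, ...] = ()
    if net < 0:
        net = 0.0
        flags = ("background_exceeds_sample",)
    rate_M_per_s = net / (context.epsilon_340 * context.path_length_cm)
    rate = rate_M_per_s * 3600.0 / (context.enzyme_conc_uM * 1e-6)
    return TurnoverEstimate(rate=rate, flags=flags)


def estimate_turnover(traces, context: AssayContext, background_traces=None,
                      window=None) -> TurnoverEstimate:
    """Replicate-averaged turnover from coupled-assay traces.

    ``background_traces`` (the no-enzyme control) are fitted and averaged to a
    single background slope subtracted from every replicate.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces supplied")
    bg_slope = 0.0
    if background_traces:
        bg_slope = float(np.mean([fit_linear_rate(t, window).slope for t in background_traces]))
    rates = []
    flags: set[str] = set()
    for t in traces:
        est = trace_to_turnover(fit_linear_rate(t, window), context, bg_slope)
        rates.append(est.rate)
        flags.update(est.flags)
    rates = np.asarray(rates)
    n = len(rates)
    se = float(rates.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
    return TurnoverEstimate(rate=float(rates.mean()), se=se, n_replicates=n,
                            flags=tuple(sorted(flags)))


def malachite_standard_fit(concs_uM, a590) -> StandardCurve:
    """OLS standard curve A590 vs [Pi] from >= 3 standards including a blank."""
    concs = np.asarray(concs_uM, dtype=float)
    a590 = np.asarray(a590, dtype=float)
    if concs.shape != a590.shape or concs.ndim != 1:
        raise ValueError("standards must be 1-D and equal length")
    if len(concs) < 3:
        raise ValueError("standard curve requires at least 3 standards")
    res = stats.linregress(concs, a590)
    if res.slope <= 0:
        raise ValueError("non-positive standard-curve slope")
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue**2), a590_max=float(a590.max()))


def endpoint_to_turnover(a590: float, curve: StandardCurve, context: AssayContext,
                         incubation_h: float = 1.0) -> TurnoverEstimate:
    """Released Pi from the standard curve, normalized per enzyme per hour."""
    if incubation_h <= 0:
        raise ValueError("incubation_h must be positive")
    flags: tuple[str, ...] = ()
    if a590 > curve.a590_max:
        flags = ("above_standard_range",)
    pi_uM = (a590 - curve.intercept) / curve.slope
    rate = pi_uM / context.enzyme_conc_uM / incubation_h
    return TurnoverEstimate(rate=float(rate), flags=flags)


def fold_stimulation(rate_condition, rate_reference) -> float:
    """Ratio of two specific activities (e.g. +GAP over intrinsic)."""
    a = rate_condition.rate if isinstance(rate_condition, TurnoverEstimate) else float(rate_condition)
    b = rate_reference.rate if isinstance(rate_reference, TurnoverEstimate) else float(rate_reference)
    if b <= 0:
        raise ValueError("reference rate must be positive")
    return a / b


def titration_analysis(series: TitrationSeries, saturation_fraction: float = 0.95) -> TitrationFit:
    """Hyperbolic saturation fit activity(x) = A0 + Amax*x/(K+x).

    The saturation concentration is the smallest *tested* concentration whose
    fitted activity reaches ``saturation_fraction`` of the fitted plateau
    (A0 + Amax); ``None`` when no tested concentration reaches it. A series
    with an overall decreasing trend violates the model and is flagged
    without fitting.
    """
    x, y = series.concentrations_uM, series.activities
    if len(x) < 4:
        raise ValueError("titration fit requires at least 4 concentrations")
    trend = np.polyfit(x, y, 1)[0]
    if trend < 0:
        return TitrationFit(a_max=float("nan"), k=float("nan"), a_0=float("nan"),
                            saturation_conc_uM=None, flags=("non_hyperbolic",))

    def hyperbola(x, a_max, k, a_0):
        return a_0 + a_max * x / (k + x)

    a0_guess = float(y[x == x.min()].mean())
    amax_guess = max(float(y.max() - a0_guess), 1e-6)
    k_guess = max(float(np.median(x[x > 0])) if np.any(x > 0) else 1.0, 1e-6)
    popt, _ = optimize.curve_fit(
        hyperbola, x, y, p0=[amax_guess, k_guess, a0_guess],
        bounds=([0.0, 1e-12, -np.inf], [np.inf, np.inf, np.inf]), maxfev=20000)
    a_max, k, a_0 = (float(v) for v in popt)
    plateau = a_0 + a_max
    fitted = hyperbola(x, a_max, k, a_0)
    reached = x[fitted >= saturation_fraction * plateau]
    flags: tuple[str, ...] = ()
    sat = float(reached.min()) if reached.size else None
    if sat is None:
        flags = ("saturation_not_reached",)
    return TitrationFit(a_max=a_max, k=k, a_0=a_0, saturation_conc_uM=sat, flags=flags)


def load_traces(path) -> list[AbsorbanceTrace]:
    """Read long-format TSV (condition, replicate, time_s, a340) into traces."""
    df = pd.read_csv(path, sep="\t")
    required = {"condition", "replicate", "time_s", "a340"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace TSV must contain columns {sorted(required)}")
    traces = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_s")
        traces.append(AbsorbanceTrace(times=grp["time_s"].to_numpy(),
                                      a340=grp["a340"].to_numpy(),
                                      condition=str(cond), replicate=int(rep)))
    return traces
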