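"""Quantify proteoliposome transport assays from ratiometric dye traces.

The assay: proteoliposomes loaded with a ratiometric indicator (Fura-2 for
divalent metals, BCECF for pH) are voltage-clamped with K⁺ gradients plus
valinomycin (ΔΨ from the Nernst equation), substrate is added, and the two
excitation channels are read over time. Quantification proceeds:

* Fura-2 340/380 ratio → free metal via the standard ratiometric
  (Grynkiewicz-form) relation  [M] = Kd·β·(R−Rmin)/(Rmax−R)  for metals with a
  known dye Kd (Cd²⁺); for strongly quenching metals (Mn²⁺, Co²⁺) the fraction
  of fluorescence quenched, normalised to the maximum quenching after
  ionomycin, estimates relative import.
* BCECF 450/490 ratio → internal pH via the ratiometric Henderson–Hasselbalch
  form  pH = pKa + log10((R−Rmin)/(Rmax−R)); the pH change, together with the
  known internal buffer and dye totals, yields net proton import from the
  change in protonated buffer+dye.
* Initial rates (OLS slope over a short window after addition) across a
  substrate titration are fitted to v = Vmax·S/(KM+S) by nonlinear least
  squares, optionally excluding anomalous high-substrate points.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

GAS_CONSTANT = 8.314462618  # J / (mol K)
FARADAY = 96485.33212  # C / mol

#: assay defaults: 0.5 mM MOPS inside, 150 µM BCECF, standard pKa values
DEFAULT_BUFFER_CONC_MM = 0.5
DEFAULT_DYE_CONC_UM = 150.0
DEFAULT_BUFFER_PKA = 7.20  # MOPS at 25 °C
DEFAULT_BCECF_PKA = 6.98


@dataclass
class FluorescenceTrace:
    """Two-channel fluorescence time course with named event timestamps."""

    time: np.ndarray
    channels: dict[str, np.ndarray]
    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if len(self.channels) != 2:
            raise ValueError("a ratiometric trace needs exactly two channels")
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        for name, series in self.channels.items():
            if series.shape != self.time.shape:
                raise ValueError(f"channel {name!r} length does not match time")

    @property
    def channel_names(self) -> tuple[str, str]:
        return tuple(self.channels)  # type: ignore[return-value]

    def ratio(self, numerator: str, denominator: str) -> np.ndarray:
        den = self.channels[denominator]
        if np.any(den <= 0):
            raise ValueError(f"channel {denominator!r} has non-positive intensities")
        return self.channels[numerator] / den

    def window_mask(self, start: float, end: float) -> np.ndarray:
        return (self.time >= start) & (self.time <= end)


@dataclass
class FuraCalibration:
    """Fura-2 ratiometric constants: [M] = Kd·beta·(R−Rmin)/(Rmax−R).

    Kd in µM (dye–metal, must be supplied per metal — there is no universal
    default); beta is the free/bound 380 nm intensity ratio.
    """

    Kd: float
    Rmin: float
    Rmax: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.Kd <= 0 or self.beta <= 0:
            raise ValueError("Kd and beta must be positive")
        if not self.Rmin < self.Rmax:
            raise ValueError("require Rmin < Rmax")


@dataclass
class BcecfCalibration:
    """BCECF ratiometric constants; ``ratio_increases_with_pH`` declares the
    instrument's channel-ratio orientation."""

    pKa_dye: float = DEFAULT_BCECF_PKA
    Rmin: float = 0.0
    Rmax: float = 1.0
    ratio_increases_with_pH: bool = True

    def __post_init__(self) -> None:
        if not self.Rmin < self.Rmax:
            raise ValueError("require Rmin < Rmax")


@dataclass
class AssayConditions:
    K_in: float = 120.0  # mM
    K_out: float = 120.0  # mM
    temperature: float = 298.15  # K
    buffer_conc: float = DEFAULT_BUFFER_CONC_MM  # mM total internal buffer
    buffer_pKa: float = DEFAULT_BUFFER_PKA
    dye_conc: float = DEFAULT_DYE_CONC_UM  # µM total internal dye
    dye_pKa: float = DEFAULT_BCECF_PKA

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")
        for name in ("K_in", "K_out", "buffer_conc", "dye_conc"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be ≥ 0")


@dataclass
class RateEstimate:
    slope: float  # units per second
    stderr: float
    n_points: int
    window: tuple[float, float]


@dataclass
class KineticsFit:
    KM: float
    KM_se: float
    Vmax: float
    Vmax_se: float
    residuals: np.ndarray
    excluded: list[int] = field(default_factory=list)

    def predict(self, S: np.ndarray) -> np.ndarray:
        S = np.asarray(S, dtype=float)
        return self.Vmax * S / (self.KM + S)


def nernst_potential(cond: AssayConditions) -> float:
    """Equilibrium K⁺ potential ΔΨ = (RT/F)·ln([K]out/[K]in) in mV (inside-relative).

    Negative when K_out < K_in, the configuration used to drive cation uptake.
    """
    if cond.K_in <= 0 or cond.K_out <= 0:
        raise ValueError("K_in and K_out must be positive to define a Nernst potential")
    return (
        1000.0
        * GAS_CONSTANT
        * cond.temperature
        / FARADAY
        * np.log(cond.K_out / cond.K_in)
    )


def fura2_concentration(ratio: float | np.ndarray, calib: FuraCalibration) -> float | np.ndarray:
    """Free metal (µM) from a Fura-2 340/380 ratio.

    Ratios below Rmin are clamped to zero (with a warning); a ratio at or
    above Rmax means dye saturation and raises.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any(r >= calib.Rmax):
        raise ValueError("ratio at or above Rmax: dye saturated, concentration undefined")
    below = r < calib.Rmin
    if np.any(below):
        warnings.warn("ratio below Rmin; clamping concentration to 0", stacklevel=2)
        r = np.where(below, calib.Rmin, r)
    conc = calib.Kd * calib.beta * (r - calib.Rmin) / (calib.Rmax - r)
    return float(conc) if np.isscalar(ratio) else conc


def fura2_ratio(concentration: float | np.ndarray, calib: FuraCalibration) -> float | np.ndarray:
    """Inverse of :func:`fura2_concentration` (used by the trace simulator)."""
    y = np.asarray(concentration, dtype=float) / (calib.Kd * calib.beta)
    r = (calib.Rmin + calib.Rmax * y) / (1.0 + y)
    return float(r) if np.isscalar(concentration) else r


def quench_fraction(
    trace: FluorescenceTrace,
    t: float | np.ndarray,
    baseline_window: tuple[float, float],
    ionomycin_plateau: tuple[float, float],
) -> float | np.ndarray:
    """Normalised Fura-2 quench at time t, in [0, 1].

    q(t) = mean over both channels of (1 − F(t)/F_baseline), divided by the
    same quantity averaged over the ionomycin plateau (maximum quenching).
    Values outside [0, 1] are clipped with a warning.
    """
    base_mask = trace.window_mask(*baseline_window)
    plat_mask = trace.window_mask(*ionomycin_plateau)
    if not base_mask.any():
        raise ValueError("baseline window contains no samples")
    if not plat_mask.any():
        raise ValueError("ionomycin plateau window contains no samples")

    per_channel = []
    plateau_per_channel = []
    for series in trace.channels.values():
        f0 = series[base_mask].mean()
        if f0 <= 0:
            raise ValueError("zero or negative baseline fluorescence")
        ft = np.interp(np.atleast_1d(t), trace.time, series)
        per_channel.append(1.0 - ft / f0)
        plateau_per_channel.append(1.0 - series[plat_mask].mean() / f0)
    q_raw = np.mean(per_channel, axis=0)
    q_max = float(np.mean(plateau_per_channel))
    if q_max <= 0:
        raise ValueError("no quenching observed in the ionomycin plateau")
    q = q_raw / q_max
    if np.any((q < -1e-9) | (q > 1 + 1e-9)):
        warnings.warn("quench fraction outside [0, 1]; clipping", stacklevel=2)
    q = np.clip(q, 0.0, 1.0)
    return float(q[0]) if np.isscalar(t) else q


def bcecf_pH(ratio: float | np.ndarray, calib: BcecfCalibration) -> float | np.ndarray:
    """Internal pH from a BCECF 450/490 ratio (ratiometric Henderson–Hasselbalch).

    pH = pKa + log10((R−Rmin)/(Rmax−R)) when the ratio rises with pH; the
    orientation flag flips the argument for instruments where it falls.
    """
    r = np.asarray(ratio, dtype=float)
    if np.any((r <= calib.Rmin) | (r >= calib.Rmax)):
        raise ValueError("ratio outside the open interval (Rmin, Rmax)")
    x = (r - calib.Rmin) / (calib.Rmax - r)
    if not calib.ratio_increases_with_pH:
        x = 1.0 / x
    ph = calib.pKa_dye + np.log10(x)
    return float(ph) if np.isscalar(ratio) else ph


def bcecf_ratio(pH: float | np.ndarray, calib: BcecfCalibration) -> float | np.ndarray:
    """Inverse of :func:`bcecf_pH` (used by the trace simulator)."""
    x = 10.0 ** (np.asarray(pH, dtype=float) - calib.pKa_dye)
    if not calib.ratio_increases_with_pH:
        x = 1.0 / x
    r = (calib.Rmin + calib.Rmax * x) / (1.0 + x)
    return float(r) if np.isscalar(pH) else r


def protonated_amount(total: float, pKa: float, pH: float) -> float:
    """Protonated fraction of a monoprotic species: total / (1 + 10^(pH − pKa))."""
    return total / (1.0 + 10.0 ** (pH - pKa))


def net_proton_import(pH_start: float, pH_end: float, cond: AssayConditions) -> float:
    """Net protons imported (µM, internal volume) for an internal pH change.

    Every imported proton is absorbed by buffer or dye, so the net import is
    the summed increase in protonated buffer + dye between the two pH values
    (Henderson–Hasselbalch bookkeeping). Positive for acidification.
    """
    buffer_uM = cond.buffer_conc * 1000.0
    total = 0.0
    for conc, pka in ((buffer_uM, cond.buffer_pKa), (cond.dye_conc, cond.dye_pKa)):
        total += protonated_amount(conc, pka, pH_end) - protonated_amount(conc, pka, pH_start)
    return total


def initial_rate(
    time: np.ndarray,
    series: np.ndarray,
    t0: float,
    window: float = 30.0,
) -> RateEstimate:
    """OLS slope of ``series`` over (t0, t0 + window], with standard error."""
    time = np.asarray(time, dtype=float)
    series = np.asarray(series, dtype=float)
    mask = (time > t0) & (time <= t0 + window)
    if mask.sum() < 3:
        raise ValueError(
            f"need ≥3 points in ({t0}, {t0 + window}] for a rate, got {int(mask.sum())}"
        )
    t, y = time[mask], series[mask]
    if np.allclose(y, y[0]):
        return RateEstimate(0.0, 0.0, int(mask.sum()), (t0, t0 + window))
    res = stats.linregress(t, y)
    stderr = 0.0 if np.isnan(res.stderr) else float(res.stderr)
    return RateEstimate(float(res.slope), stderr, int(mask.sum()), (t0, t0 + window))


def fit_michaelis_menten(
    S: np.ndarray,
    v: np.ndarray,
    exclude: list[int] | None = None,
) -> KineticsFit:
    """Nonlinear least-squares fit of v = Vmax·S/(KM + S).

    ``exclude`` lists indices (into S) left out of the fit but recorded in the
    result — the standard treatment of anomalous high-substrate points (e.g.
    substrate inhibition at high [Cd²⁺]). Raises on non-convergence or a
    non-positive parameter estimate.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(v, dtype=float)
    if S.shape != v.shape:
        raise ValueError("S and v must have equal lengths")
    exclude = sorted(set(exclude or []))
    keep = np.ones(len(S), dtype=bool)
    for i in exclude:
        keep[i] = False
    S_fit, v_fit = S[keep], v[keep]
    if len(np.unique(S_fit)) < 3:
        raise ValueError("need ≥3 distinct substrate concentrations after exclusion")

    def model(s, vmax, km):
        return vmax * s / (km + s)

    vmax0 = max(float(v_fit.max()), 1e-12)
    half = vmax0 / 2.0
    km0 = float(np.interp(half, np.sort(v_fit), np.sort(S_fit))) or float(np.median(S_fit))
    try:
        popt, pcov = optimize.curve_fit(
            model,
            S_fit,
            v_fit,
            p0=[vmax0, max(km0, 1e-6)],
            bounds=([0.0, 0.0], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"Michaelis–Menten fit did not converge: {exc}") from exc
    vmax, km = popt
    if vmax <= 0 or km <= 0:
        raise ValueError(f"non-positive parameter estimate (Vmax={vmax}, KM={km})")
    perr = np.sqrt(np.diag(pcov))
    residuals = v_fit - model(S_fit, *popt)
    return KineticsFit(
        KM=float(km),
        KM_se=float(perr[1]),
        Vmax=float(vmax),
        Vmax_se=float(perr[0]),
        residuals=residuals,
        excluded=exclude,
    )


def read_trace_csv(path, time_col: str = "time_s") -> FluorescenceTrace:
    """Read a trace table: column ``time_s`` plus exactly two channel columns.

    Event timestamps may be supplied in companion columns named
    ``event_<name>`` holding a single timestamp, or set afterwards on the
    returned object.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if time_col not in df.columns:
        raise ValueError(f"{path}: missing required column {time_col!r}")
    events = {}
    channel_cols = []
    for col in df.columns:
        if col == time_col:
            continue
        if col.startswith("event_"):
            events[col[len("event_") :]] = float(df[col].dropna().iloc[0])
        else:
            channel_cols.append(col)
    if len(channel_cols) != 2:
        raise ValueError(f"{path}: expected exactly 2 channel columns, got {channel_cols}")
    return FluorescenceTrace(
        time=df[time_col].to_numpy(),
        channels={c: df[c].to_numpy() for c in channel_cols},
        events=events,
    )
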