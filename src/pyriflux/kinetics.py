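"""Enzyme-inhibition and thermal-shift analysis.

Dose-response curves are fitted with the three-parameter inhibition equation

    V = Vmax / (1 + (I / IC50)^h)

where I is the inhibitor concentration (uM), IC50 the half-maximal
inhibitory concentration and h the Hill-type slope.  For a competitive
inhibitor the apparent IC50 grows with substrate concentration S as
IC50 = Ki (1 + S/Km) (Cheng-Prusoff), while an uncompetitive inhibitor shows
the opposite trend, IC50 = Ki (1 + Km/S).  The direction of the IC50 shift
across substrate levels therefore classifies the inhibition mode.

Thermal-shift (nanoDSF) melt curves report the 350/330 nm fluorescence ratio
versus temperature; the melting temperature Tm is the transition midpoint,
extracted either as the argmax of the smoothed first derivative or as the
midpoint of a fitted two-state Boltzmann sigmoid with linear baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares
from scipy.signal import savgol_filter

__all__ = [
    "AssayTable",
    "DoseResponseFit",
    "InhibitionModeCall",
    "MeltCurve",
    "fit_dose_response",
    "cheng_prusoff_ki",
    "predicted_ic50_curve",
    "classify_inhibition_mode",
    "fit_melting_temperature",
    "delta_tm",
    "read_assay_csv",
    "write_assay_csv",
    "read_melt_csv",
    "write_melt_csv",
]


@dataclass(frozen=True)
class AssayTable:
    """Activity measurements at one substrate concentration.

    inhibitor_uM and activity are parallel arrays; substrate_uM is the fixed
    substrate concentration of the series.
    """

    substrate_uM: float
    inhibitor_uM: np.ndarray
    activity: np.ndarray
    replicate: str = "r1"

    def __post_init__(self):
        I = np.asarray(self.inhibitor_uM, dtype=float)
        V = np.asarray(self.activity, dtype=float)
        if I.shape != V.shape or I.ndim != 1:
            raise ValueError("inhibitor_uM and activity must be parallel 1-D arrays")
        if self.substrate_uM <= 0:
            raise ValueError("substrate concentration must be positive")
        if (I < 0).any():
            raise ValueError("inhibitor concentrations must be >= 0")
        if not np.isfinite(V).all():
            raise ValueError("activities must be finite")
        object.__setattr__(self, "inhibitor_uM", I)
        object.__setattr__(self, "activity", V)


@dataclass(frozen=True)
class DoseResponseFit:
    Vmax: float
    IC50: float
    h: float
    residual_ss: float
    converged: bool
    message: str = ""

    def predict(self, I) -> np.ndarray:
        I = np.asarray(I, dtype=float)
        return _hill(I, self.Vmax, self.IC50, self.h)


@dataclass(frozen=True)
class InhibitionModeCall:
    mode: str  # competitive | uncompetitive | indeterminate
    ic50_by_substrate: tuple[tuple[float, float], ...]
    fold_shift: float
    Ki: float | None = None
    Km_used: float | None = None


@dataclass(frozen=True)
class MeltCurve:
    """350/330 nm fluorescence ratio vs temperature (ascending, >= 10 points)."""

    temperature_C: np.ndarray
    ratio: np.ndarray
    label: str = ""

    def __post_init__(self):
        T = np.asarray(self.temperature_C, dtype=float)
        R = np.asarray(self.ratio, dtype=float)
        if T.shape != R.shape or T.ndim != 1:
            raise ValueError("temperature and ratio must be parallel 1-D arrays")
        if T.size < 10:
            raise ValueError("melt curve needs at least 10 points")
        if not (np.diff(T) > 0).all():
            raise ValueError("temperatures must be strictly increasing")
        object.__setattr__(self, "temperature_C", T)
        object.__setattr__(self, "ratio", R)


# ---------------------------------------------------------------------------
# Dose-response fitting
# ---------------------------------------------------------------------------


def _hill(I, Vmax, IC50, h):
    I = np.asarray(I, dtype=float)
    out = np.full_like(I, float(Vmax))
    pos = I > 0
    out[pos] = Vmax / (1.0 + (I[pos] / IC50) ** h)
    return out


def fit_dose_response(table: AssayTable, init: tuple[float, float, float] | None = None
                      ) -> DoseResponseFit:
    """Nonlinear least-squares fit of V = Vmax / (1 + (I/IC50)^h).

    The fit is parameterized in (Vmax, log10 IC50, log h) so IC50 and h stay
    positive; it is initialized from the interpolated half-maximal crossing
    on log-concentration.  I = 0 rows anchor Vmax (the model evaluates to
    Vmax there) but play no role on the log-concentration axis.
    """
    I, V = table.inhibitor_uM, table.activity
    if np.unique(I[I > 0]).size < 5:
        raise ValueError("need >= 5 distinct positive inhibitor concentrations")
    order = np.argsort(I)
    Is, Vs = I[order], V[order]
    top = float(np.mean(Vs[: max(1, len(Vs) // 4)])) if init is None else init[0]
    if top <= 0:
        top = max(float(np.max(V)), 1e-12)
    # flat/non-monotone guard: require a clear downward transition
    span = float(np.max(V) - np.min(V))
    if span < 0.05 * max(abs(float(np.max(V))), 1e-12):
        return DoseResponseFit(top, math.nan, math.nan, math.nan, False,
                               "flat data: no inhibition transition")
    if init is None:
        half = top / 2.0
        below = np.nonzero(Vs <= half)[0]
        if below.size and below[0] > 0:
            j = below[0]
            x0, x1 = np.log10(max(Is[j - 1], 1e-12)), np.log10(Is[j])
            y0, y1 = Vs[j - 1], Vs[j]
            frac = (y0 - half) / (y0 - y1) if y0 != y1 else 0.5
            ic50_0 = 10 ** (x0 + frac * (x1 - x0))
        else:
            ic50_0 = float(np.median(Is[Is > 0]))
        init = (top, ic50_0, 1.0)

    def residuals(p):
        Vmax, lIC50, lh = p
        return _hill(I, Vmax, 10.0 ** lIC50, math.exp(lh)) - V

    p0 = np.array([init[0], math.log10(max(init[1], 1e-12)), math.log(max(init[2], 1e-6))])
    res = least_squares(residuals, p0, method="lm", max_nfev=5000)
    Vmax, IC50, h = res.x[0], 10.0 ** res.x[1], math.exp(res.x[2])
    ss = float(np.sum(res.fun ** 2))
    ok = bool(res.success) and Vmax > 0 and np.isfinite(IC50) and 1e-6 < h < 1e3
    # reject fits whose IC50 landed far outside the measured range
    pos = I[I > 0]
    if ok and not (pos.min() / 1e3 <= IC50 <= pos.max() * 1e3):
        ok = False
    return DoseResponseFit(float(Vmax), float(IC50), float(h), ss, ok,
                           "" if ok else "fit did not converge to a plausible optimum")


# ---------------------------------------------------------------------------
# Cheng-Prusoff relations and mode classification
# ---------------------------------------------------------------------------


def cheng_prusoff_ki(ic50: float, S: float, Km: float) -> float:
    """Ki = IC50 / (1 + S/Km) for a competitive inhibitor.

    S = 0 is allowed (no substrate competition; Ki = IC50).
    """
    if ic50 <= 0 or Km <= 0:
        raise ValueError("IC50 and Km must be positive")
    if S < 0:
        raise ValueError("substrate concentration must be >= 0")
    return ic50 / (1.0 + S / Km)


def predicted_ic50_curve(
    Ki: float, Km: float, mode: str, S_list: Sequence[float]
) -> list[tuple[float, float]]:
    """Apparent IC50 as a function of substrate concentration.

    competitive:   IC50 = Ki (1 + S/Km)   (increases with S)
    uncompetitive: IC50 = Ki (1 + Km/S)   (decreases with S)
    """
    if Ki <= 0 or Km <= 0:
        raise ValueError("Ki and Km must be positive")
    if mode == "competitive":
        return [(float(S), Ki * (1.0 + S / Km)) for S in S_list]
    if mode == "uncompetitive":
        if any(S <= 0 for S in S_list):
            raise ValueError("uncompetitive IC50 diverges at S = 0; S must be > 0")
        return [(float(S), Ki * (1.0 + Km / S)) for S in S_list]
    raise ValueError(f"unknown inhibition mode {mode!r}")


def classify_inhibition_mode(
    ic50_by_substrate: Sequence[tuple[float, float]],
    rel_tol: float = 0.25,
    Km: float | None = None,
) -> InhibitionModeCall:
    """Call the inhibition mode from the IC50 trend across substrate levels.

    The fold shift IC50(S_high)/IC50(S_low) above 1 + rel_tol calls
    competitive, below 1/(1 + rel_tol) uncompetitive, anything in the dead
    band indeterminate.  For a competitive call with Km supplied, Ki is the
    mean of the per-point Cheng-Prusoff values.
    """
    pts = sorted((float(S), float(ic50)) for S, ic50 in ic50_by_substrate)
    if len(pts) < 2:
        raise ValueError("need IC50s at >= 2 substrate levels")
    S_vals = [S for S, _ in pts]
    if len(set(S_vals)) != len(S_vals):
        raise ValueError("duplicated substrate levels")
    fold = pts[-1][1] / pts[0][1]
    if fold > 1.0 + rel_tol:
        mode = "competitive"
    elif fold < 1.0 / (1.0 + rel_tol):
        mode = "uncompetitive"
    else:
        mode = "indeterminate"
    ki = None
    if mode == "competitive" and Km is not None:
        ki = float(np.mean([cheng_prusoff_ki(ic50, S, Km) for S, ic50 in pts]))
    return InhibitionModeCall(mode, tuple(pts), float(fold), ki,
                              Km if ki is not None else None)


# ---------------------------------------------------------------------------
# Melt curves
# ---------------------------------------------------------------------------


def _boltzmann(T, bl, ml, bu, mu, Tm, slope):
    frac = 1.0 / (1.0 + np.exp((Tm - T) / slope))
    return (bl + ml * T) + ((bu + mu * T) - (bl + ml * T)) * frac


def fit_melting_temperature(curve: MeltCurve, method: str = "derivative") -> float:
    """Melting temperature from a 350/330 ratio melt curve.

    derivative: Tm is the argmax of the Savitzky-Golay smoothed first
    derivative of ratio vs temperature, refined by parabolic interpolation
    around the peak.  boltzmann: Tm is the midpoint of a two-state sigmoid
    with linear pre-/post-transition baselines, initialized from the
    derivative estimate.  Raises on curves without a detectable transition.
    """
    T, R = curve.temperature_C, curve.ratio
    dT = float(np.mean(np.diff(T)))
    # smooth over a ~2.5 degC span (at least 5 points) before differentiating
    window = max(5, int(round(2.5 / dT)) | 1)
    window = min(window, len(T) if len(T) % 2 == 1 else len(T) - 1)
    deriv = savgol_filter(R, window_length=window, polyorder=2, deriv=1, delta=dT)
    peak = int(np.argmax(deriv))
    # a transition shows as a derivative peak well above the typical level;
    # a flat or purely linear curve has a near-constant derivative instead
    baseline = float(np.median(np.abs(deriv)))
    interior = 0 < peak < len(T) - 1
    if not interior or deriv[peak] <= 0 or deriv[peak] < 3.0 * baseline:
        raise ValueError("no transition detected in melt curve")
    # refine the peak as the vertex of a local quadratic over ~+-2 degC
    half = max(1, int(round(2.0 / dT)))
    lo_i, hi_i = max(0, peak - half), min(len(T), peak + half + 1)
    coeffs = np.polyfit(T[lo_i:hi_i], deriv[lo_i:hi_i], 2)
    if coeffs[0] < 0:
        vertex = -coeffs[1] / (2.0 * coeffs[0])
        tm_deriv = float(np.clip(vertex, T[lo_i], T[hi_i - 1]))
    else:
        tm_deriv = float(T[peak])
    if method == "derivative":
        return tm_deriv
    if method != "boltzmann":
        raise ValueError(f"unknown Tm method {method!r}")
    lo, hi = float(np.min(R)), float(np.max(R))
    p0 = [lo, 0.0, hi, 0.0, tm_deriv, max(dT, 0.5)]
    popt, _ = curve_fit(_boltzmann, T, R, p0=p0, maxfev=20000)
    tm = float(popt[4])
    if not (T[0] <= tm <= T[-1]):
        raise ValueError("Boltzmann fit placed Tm outside the measured range")
    return tm


def delta_tm(tm_holo: float, tm_apo: float) -> float:
    """Ligand-induced melting-temperature shift (positive = stabilization)."""
    if not (np.isfinite(tm_holo) and np.isfinite(tm_apo)):
        raise ValueError("Tm values must be finite")
    return float(tm_holo - tm_apo)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------


def write_assay_csv(tables: Sequence[AssayTable], path) -> None:
    rows = []
    for t in tables:
        for i, v in zip(t.inhibitor_uM, t.activity):
            rows.append({"substrate_uM": t.substrate_uM, "inhibitor_uM": i,
                         "activity": v, "replicate": t.replicate})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assay_csv(path) -> list[AssayTable]:
    df = pd.read_csv(path)
    need = {"substrate_uM", "inhibitor_uM", "activity"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: assay CSV needs columns {sorted(need)}")
    if "replicate" not in df.columns:
        df["replicate"] = "r1"
    out = []
    for (S, rep), grp in df.groupby(["substrate_uM", "replicate"], sort=True):
        out.append(AssayTable(float(S), grp["inhibitor_uM"].to_numpy(),
                              grp["activity"].to_numpy(), replicate=str(rep)))
    return out


def write_melt_csv(curve: MeltCurve, path) -> None:
    pd.DataFrame({"temperature_C": curve.temperature_C,
                  "ratio_350_330": curve.ratio}).to_csv(path, index=False)


def read_melt_csv(path, label: str = "") -> MeltCurve:
    df = pd.read_csv(path)
    need = {"temperature_C", "ratio_350_330"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: melt CSV needs columns {sorted(need)}")
    return MeltCurve(df["temperature_C"].to_numpy(), df["ratio_350_330"].to_numpy(),
                     label=label)
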