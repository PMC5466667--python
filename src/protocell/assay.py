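"""Dye-leakage permeability pipeline.

Fits solute-release traces from encapsulated-fluorophore assays, converts
release rates to permeability and trans-membrane diffusion coefficients
under a monodisperse spherical-vesicle geometry, maps lipid molar ratios to
membrane surface fractions via head areas, and interpolates the resulting
(composition, permeability) points with the unique exact-matching
polynomial, yielding the multiplier curve consumed by the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .physics import PermeabilityCurve

__all__ = [
    "ReleaseTrace",
    "AssayGeometry",
    "FitResult",
    "FitError",
    "fit_release_rate",
    "permeability_from_rate",
    "molar_to_surface_fraction",
    "fit_permeability_curve",
]


class FitError(RuntimeError):
    """A release-trace fit failed; carries diagnostics."""

    def __init__(self, message: str, diagnostics: Optional[dict] = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


@dataclass
class ReleaseTrace:
    """Timestamped fraction-released measurements for one composition."""

    times: np.ndarray  # min
    fraction_released: np.ndarray
    composition: str = ""
    temperature: float = 45.0  # Celsius

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fraction_released = np.asarray(self.fraction_released, dtype=float)
        if self.times.shape != self.fraction_released.shape:
            raise ValueError("times and fractions must have the same shape")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.fraction_released < 0) | (self.fraction_released > 1)):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass(frozen=True)
class AssayGeometry:
    """Vesicle geometry assumed for permeability conversion (nm)."""

    radius: float = 200.0
    thickness: float = 3.0

    def __post_init__(self) -> None:
        if not self.radius > self.thickness > 0:
            raise ValueError("need radius > thickness > 0")


@dataclass
class FitResult:
    """Fitted release rate with goodness-of-fit diagnostics."""

    k: float  # 1/min
    method: str
    r_squared: float
    residuals: np.ndarray
    f_inf: float = 1.0
    n_points: int = 0


def _r_squared(y: np.ndarray, y_hat: np.ndarray) -> float:
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0


EARLY_LINEAR_THRESHOLD = 0.3
PLATEAU_FREE_FINF = 0.9


def fit_release_rate(trace: ReleaseTrace, method: str = "exponential") -> FitResult:
    """Fit the release rate k (1/min) of a trace.

    ``exponential``: least squares on F(t) = F_inf (1 - exp(-k t)), with
    F_inf fixed to 1 (perfect sink, complete release) unless the trace ends
    on a plateau below 0.9, in which case F_inf is freed.  ``early_linear``:
    ordinary least squares over the points with F < 0.3; the slope estimates
    k since F ~ k t in that regime.
    """
    t, f = trace.times, trace.fraction_released
    if t.size < 4:
        raise FitError("need at least 4 points")
    if np.allclose(f, f[0]):
        raise FitError("degenerate trace: all fractions equal", {"value": float(f[0])})

    if method == "exponential":
        try:
            popt, _ = curve_fit(
                lambda tt, k: 1.0 - np.exp(-k * tt),
                t,
                f,
                p0=[_initial_k(t, f)],
                maxfev=10_000,
            )
        except RuntimeError as exc:
            raise FitError(f"exponential fit did not converge: {exc}") from exc
        k, f_inf = float(popt[0]), 1.0
        sse_fixed = float(np.sum((f - (1.0 - np.exp(-k * t))) ** 2))
        # a genuinely incomplete release (plateau below 0.9) is refit with a
        # free amplitude, kept only when it clearly beats the sink model
        if f[-1] < PLATEAU_FREE_FINF and _looks_plateaued(t, f):
            try:
                popt2, _ = curve_fit(
                    lambda tt, kk, finf: finf * (1.0 - np.exp(-kk * tt)),
                    t,
                    f,
                    p0=[k, max(f[-1], 0.1)],
                    maxfev=10_000,
                )
                k2, finf2 = float(popt2[0]), float(popt2[1])
                sse_free = float(np.sum((f - finf2 * (1.0 - np.exp(-k2 * t))) ** 2))
                if sse_free < 0.5 * sse_fixed and 0.05 < finf2 < 1.1 and k2 > 0:
                    k, f_inf = k2, finf2
            except RuntimeError:
                pass
        y_hat = f_inf * (1.0 - np.exp(-k * t))
        res = FitResult(
            k=k,
            method="exponential",
            r_squared=_r_squared(f, y_hat),
            residuals=f - y_hat,
            f_inf=f_inf,
            n_points=t.size,
        )
    elif method == "early_linear":
        mask = f < EARLY_LINEAR_THRESHOLD
        if mask.sum() < 2:
            raise FitError("fewer than 2 points in the early-linear window (F < 0.3)")
        lr = linregress(t[mask], f[mask])
        k = float(lr.slope)
        y_hat = lr.intercept + k * t[mask]
        res = FitResult(
            k=k,
            method="early_linear",
            r_squared=float(lr.rvalue**2),
            residuals=f[mask] - y_hat,
            n_points=int(mask.sum()),
        )
    else:
        raise ValueError(f"unknown method {method!r}")

    if not res.k > 0:
        raise FitError(
            f"non-positive fitted rate k={res.k:.3g}",
            {"r_squared": res.r_squared, "method": res.method},
        )
    return res


def _initial_k(t: np.ndarray, f: np.ndarray) -> float:
    mask = (f > 0) & (f < 0.95)
    if mask.sum() >= 2:
        with np.errstate(divide="ignore"):
            slopes = -np.log(1.0 - f[mask]) / np.where(t[mask] > 0, t[mask], np.inf)
        valid = slopes[np.isfinite(slopes) & (slopes > 0)]
        if valid.size:
            return float(np.median(valid))
    return 0.01


def _looks_plateaued(t: np.ndarray, f: np.ndarray, window: int = 3, tol: float = 0.02) -> bool:
    if t.size < window + 1:
        return False
    return float(np.ptp(f[-window:])) < tol


def permeability_from_rate(
    k: float, geom: AssayGeometry = AssayGeometry(), k_unit: str = "1/min"
) -> tuple[float, float]:
    """Convert a release rate to (P, D).

    For a sphere the efflux rate constant is k = P S / V = 3 P / r, so
    P = k r / 3 (m/s) and the trans-membrane diffusion rate D = P lambda
    (m^2/s).
    """
    if not k > 0:
        raise ValueError("release rate must be positive")
    per_second = {"1/min": 1.0 / 60.0, "1/h": 1.0 / 3600.0, "1/s": 1.0}
    try:
        k_s = k * per_second[k_unit]
    except KeyError:
        raise ValueError(f"unknown rate unit {k_unit!r}") from None
    p = k_s * (geom.radius * 1e-9) / 3.0
    return p, p * geom.thickness * 1e-9


def molar_to_surface_fraction(x_derivative: float, alpha_l: float, alpha_d: float) -> float:
    """Surface fraction of the derivative lipid from its molar fraction.

    chi = x a_d / (x a_d + (1 - x) a_l); strictly increasing, chi(0)=0,
    chi(1)=1.  Head areas in any common unit.
    """
    if not 0.0 <= x_derivative <= 1.0:
        raise ValueError("molar fraction must lie in [0, 1]")
    if alpha_l <= 0 or alpha_d <= 0:
        raise ValueError("head areas must be positive")
    num = x_derivative * alpha_d
    return num / (num + (1.0 - x_derivative) * alpha_l)


def fit_permeability_curve(points: Sequence[tuple[float, float]]) -> PermeabilityCurve:
    """Exact-matching polynomial through (chi, permeability-like value) points.

    Values are normalized to multiplier form f(chi) = value / value(chi=0),
    so the curve plugs directly into the simulator's permeability model.
    Requires at least three distinct compositions spanning chi = 0 and 1.
    """
    pts = sorted((float(x), float(v)) for x, v in points)
    xs = [p[0] for p in pts]
    if len(set(xs)) != len(xs):
        raise ValueError("duplicate chi values")
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    v0 = dict(pts).get(0.0)
    if v0 is None or v0 <= 0:
        raise ValueError("need a positive reference value at chi = 0")
    return PermeabilityCurve([(x, v / v0) for x, v in pts])


def traces_from_dataframe(df: pd.DataFrame) -> list[ReleaseTrace]:
    """Group a tidy (time_min, fraction_released, composition, replicate) table."""
    traces = []
    for (comp, _rep), grp in df.groupby(["composition", "replicate"], sort=True):
        grp = grp.sort_values("time_min")
        traces.append(
            ReleaseTrace(
                times=grp["time_min"].to_numpy(),
                fraction_released=grp["fraction_released"].to_numpy(),
                composition=str(comp),
            )
        )
    return traces
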