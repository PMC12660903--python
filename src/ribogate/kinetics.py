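"""Splicing kinetics models: the sequential two-step scheme and Michaelis-Menten.

Self-splicing proceeds through two consecutive first-order steps,

    precursor --k1--> intermediate --k2--> linear intron,

whose closed-form populations (starting from pure precursor, p0) are

    P(t) = p0 exp(-k1 t)
    I(t) = p0 k1/(k2 - k1) (exp(-k1 t) - exp(-k2 t))       (k1 != k2)
    I(t) = p0 k1 t exp(-k1 t)                               (k1 == k2 limit)
    L(t) = p0 - P(t) - I(t)

Rate constants are in min^-1 and populations are fractions of total signal.
The spliced-exon-reopening (SER) assay is analysed with initial slopes of the
response curves followed by a direct nonlinear Michaelis-Menten fit,
v = vmax * S / (KM + S); the Lineweaver-Burk reciprocal-space line fit is
co-reported for comparison only, as is traditional.

Fitting uses lmfit (Levenberg-Marquardt with multi-start over a log-spaced
rate grid to avoid the k1 <-> k2 exchange ambiguity of sequential schemes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np

__all__ = [
    "TwoStepParams",
    "MichaelisMentenParams",
    "TimeCourse",
    "FitError",
    "two_step_populations",
    "fit_two_step",
    "initial_slope",
    "fit_michaelis_menten",
    "relative_activity",
]


class FitError(RuntimeError):
    """Raised when a kinetic fit fails to converge or is ill-posed."""


@dataclass
class TwoStepParams:
    """Rate constants of the two sequential splicing steps, in min^-1."""

    k1: float
    k2: float
    p0: float = 1.0
    k1_stderr: Optional[float] = None
    k2_stderr: Optional[float] = None
    exchange_ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.k1 <= 0 or self.k2 <= 0 or self.p0 <= 0:
            raise ValueError("k1, k2 and p0 must be positive")


@dataclass
class MichaelisMentenParams:
    """vmax (nmol L^-1 min^-1) and KM (nmol L^-1)."""

    vmax: float
    km: float
    vmax_stderr: Optional[float] = None
    km_stderr: Optional[float] = None
    lineweaver_burk: Optional[tuple[float, float]] = None  # (vmax, km) from 1/v vs 1/S

    def __post_init__(self) -> None:
        if self.vmax <= 0 or self.km <= 0:
            raise ValueError("vmax and km must be positive")

    def rate(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s, float)
        return self.vmax * s / (self.km + s)


@dataclass
class TimeCourse:
    """Observed species fractions over time (minutes)."""

    times: np.ndarray
    precursor: Optional[np.ndarray] = None
    intermediate: Optional[np.ndarray] = None
    product: Optional[np.ndarray] = None
    sigma: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        for name in ("precursor", "intermediate", "product", "sigma"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, float)
                if v.shape != self.times.shape:
                    raise ValueError(f"{name} length does not match times")
                setattr(self, name, v)

    @property
    def observed_species(self) -> list[str]:
        return [n for n in ("precursor", "intermediate", "product")
                if getattr(self, n) is not None]


def two_step_populations(
    p: TwoStepParams, t: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form (P, I, L) populations of the sequential scheme at times t."""
    t = np.asarray(t, float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    k1, k2, p0 = p.k1, p.k2, p.p0
    prec = p0 * np.exp(-k1 * t)
    # continuous limit at k1 == k2; switch when the difference is numerically tiny
    if abs(k2 - k1) <= 1e-12 * max(k1, k2):
        inter = p0 * k1 * t * np.exp(-k1 * t)
    else:
        inter = p0 * k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    lin = p0 - prec - inter
    return prec, inter, lin


def _two_step_residuals(params: lmfit.Parameters, tc: TimeCourse) -> np.ndarray:
    p = TwoStepParams(params["k1"].value, params["k2"].value, params["p0"].value)
    prec, inter, lin = two_step_populations(p, tc.times)
    model = {"precursor": prec, "intermediate": inter, "product": lin}
    resid = []
    for name in tc.observed_species:
        r = model[name] - getattr(tc, name)
        if tc.sigma is not None:
            r = r / tc.sigma
        resid.append(r)
    return np.concatenate(resid)


def fit_two_step(
    tc: TimeCourse,
    p0_fixed: Optional[float] = 1.0,
    n_starts: int = 5,
) -> TwoStepParams:
    """Nonlinear least-squares fit of (k1, k2) to all observed species at once.

    Multi-start over a log-spaced rate grid guards against the local minima
    of the exchange-symmetric product-only likelihood. Standard errors come
    from the fit covariance. When only the product is observed, the returned
    pair is reported with k1 = first step by convention and flagged
    exchange-ambiguous.
    """
    if len(tc.times) < 4:
        raise FitError("need >= 4 time points")
    species = tc.observed_species
    if not species:
        raise FitError("no observed species in time course")

    t_span = tc.times[-1] - tc.times[0]
    k_grid = np.logspace(np.log10(0.1 / t_span), np.log10(50.0 / t_span), n_starts)
    best = None
    for ka in k_grid:
        for kb in k_grid:
            params = lmfit.Parameters()
            params.add("k1", value=ka, min=1e-8)
            params.add("k2", value=kb, min=1e-8)
            if p0_fixed is None:
                params.add("p0", value=1.0, min=1e-6)
            else:
                params.add("p0", value=p0_fixed, vary=False)
            try:
                res = lmfit.minimize(_two_step_residuals, params, args=(tc,), method="leastsq")
            except Exception:
                continue
            if best is None or res.chisqr < best.chisqr - 1e-12:
                best = res
    if best is None:
        raise FitError("two-step fit did not converge from any start")
    k1 = best.params["k1"].value
    k2 = best.params["k2"].value
    ambiguous = species == ["product"]
    return TwoStepParams(
        k1=k1,
        k2=k2,
        p0=best.params["p0"].value,
        k1_stderr=best.params["k1"].stderr,
        k2_stderr=best.params["k2"].stderr,
        exchange_ambiguous=ambiguous,
    )


def initial_slope(
    times: Sequence[float],
    signal: Sequence[float],
    n_points: int = 10,
    blank: float = 0.0,
) -> float:
    """Ordinary least-squares slope over the first ``n_points`` samples.

    ``blank`` is subtracted from the signal first (blank-well correction).
    """
    times = np.asarray(times, float)
    signal = np.asarray(signal, float) - blank
    if len(times) < n_points or len(signal) < n_points:
        raise ValueError(f"need >= {n_points} points, got {len(times)}")
    t = times[:n_points]
    y = signal[:n_points]
    slope, _ = np.polyfit(t, y, 1)
    return float(slope)


def fit_michaelis_menten(
    substrate: Sequence[float], rates: Sequence[float]
) -> MichaelisMentenParams:
    """Direct nonlinear Michaelis-Menten fit with a Lineweaver-Burk cross-check.

    The nonlinear fit of v = vmax S / (KM + S) is primary; the reciprocal-
    space linear fit (1/v = 1/vmax + (KM/vmax)/S, zero-rate points excluded)
    is attached for comparison only.
    """
    s = np.asarray(substrate, float)
    v = np.asarray(rates, float)
    if len(np.unique(s)) < 3:
        raise FitError("need >= 3 distinct substrate concentrations")
    if np.all(v <= 0):
        raise FitError("all rates are zero; nothing to fit")

    params = lmfit.Parameters()
    params.add("vmax", value=float(v.max()) or 1.0, min=1e-12)
    params.add("km", value=float(np.median(s[s > 0])) or 1.0, min=1e-12)

    def resid(p):
        return p["vmax"].value * s / (p["km"].value + s) - v

    res = lmfit.minimize(resid, params, method="leastsq")
    if not res.success:
        raise FitError(f"Michaelis-Menten fit failed: {res.message}")

    lb = None
    mask = (s > 0) & (v > 0)
    if mask.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / s[mask], 1.0 / v[mask], 1)
        if intercept > 0:
            lb = (1.0 / intercept, slope / intercept)

    return MichaelisMentenParams(
        vmax=res.params["vmax"].value,
        km=res.params["km"].value,
        vmax_stderr=res.params["vmax"].stderr,
        km_stderr=res.params["km"].stderr,
        lineweaver_burk=lb,
    )


def relative_activity(mutant: dict[str, float], wildtype: dict[str, float]) -> dict[str, dict[str, float]]:
    """Mutant parameters as percentages of wild type.

    Returns, per shared parameter name, the exact percentage and the
    nearest-integer percent used for reporting.
    """
    out: dict[str, dict[str, float]] = {}
    for name, wt in wildtype.items():
        if name not in mutant:
            continue
        if wt <= 0:
            raise ValueError(f"wild-type {name} must be positive")
        pct = 100.0 * mutant[name] / wt
        out[name] = {"percent": pct, "percent_rounded": float(round(pct))}
    if not out:
        raise ValueError("no shared parameters between mutant and wild type")
    return out
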