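"""Binding and polymerization-kinetics computations.

Two curve models sit at the core of this module, both exposed as
sklearn-style estimators and as thin fitting functions:

* the tight-binding (ligand-depletion) quadratic, which gives the bound
  fraction of a receptor R titrated with ligand L when neither species is in
  large excess::

      [LR]/[R] = (L + R + K_D - sqrt((L + R + K_D)^2 - 4 L R)) / (2 R)

  used to extract the dissociation constant K_D of dimeric
  nucleation-promoting-factor constructs for Arp2/3 complex from supernatant
  depletion assays; and

* the saturation (hyperbolic) activation curve relating the maximum
  polymerization rate (MPR) of a pyrene actin assay to activator
  concentration::

      Y = Ymax * [Las17] / (K_1/2 + [Las17]) + Yo

Concentration units are micromolar for binding and nanomolar for titrations,
following the conventions of the assays; rates are nM actin / s.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator, RegressorMixin

__all__ = [
    "BindingMeasurement",
    "BindingFit",
    "PolymerizationTrace",
    "TitrationFit",
    "ActivityComparison",
    "TightBindingModel",
    "ActivationTitrationModel",
    "fraction_bound",
    "quadratic_fraction",
    "fit_kd",
    "equilibration_time",
    "convert_rfu_to_polymer",
    "max_polymerization_rate",
    "fit_mpr_titration",
    "percent_activity",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class BindingMeasurement:
    """One point of a supernatant-depletion titration (concentrations in uM)."""

    ligand_total: float
    receptor_total: float
    supernatant: float
    fraction_bound: float

    def __post_init__(self) -> None:
        if self.ligand_total < 0 or self.receptor_total < 0 or self.supernatant < 0:
            raise ValueError("concentrations must be >= 0")
        if not 0 <= self.fraction_bound <= 1:
            raise ValueError("fraction_bound must lie in [0, 1]")


@dataclass
class BindingFit:
    """Result of a quadratic tight-binding fit (receptor fixed)."""

    kd: float
    receptor_total: float
    kd_stderr: float
    residuals: np.ndarray
    at_bound: bool = False


@dataclass
class PolymerizationTrace:
    """A pyrene actin polymerization time course."""

    time: np.ndarray
    fluorescence: np.ndarray
    polymer: np.ndarray | None = None  # nM, after conversion

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape:
            raise ValueError("time and fluorescence must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class TitrationFit:
    """Saturation fit of MPR versus activator concentration (nM)."""

    ymax: float
    k_half: float
    y0: float
    concentrations: np.ndarray = field(default_factory=lambda: np.empty(0))
    rates: np.ndarray = field(default_factory=lambda: np.empty(0))
    k_half_identifiable: bool = True


@dataclass
class ActivityComparison:
    """Percent activity of a mutant relative to wild type at matched activator."""

    mpr_mutant: float
    mpr_wt: float
    mpr_actin: float
    percent: float


# ---------------------------------------------------------------------------
# elementary computations


def fraction_bound(receptor_total: float, supernatant: float) -> float:
    """Bound fraction from total receptor and its free supernatant concentration.

    F_b = (theta0 - supernatant) / theta0, clipped to [0, 1]; theta0 is the
    total receptor concentration.
    """
    if receptor_total <= 0:
        raise ValueError("receptor_total must be > 0")
    if supernatant < 0:
        raise ValueError("supernatant must be >= 0")
    return float(np.clip((receptor_total - supernatant) / receptor_total, 0.0, 1.0))


def quadratic_fraction(L, R: float, kd: float):
    """Bound receptor fraction [LR]/[R] under ligand depletion.

    Valid for total concentrations L, R and dissociation constant ``kd``
    (all in the same units, >= 0; R > 0). Continuous in every argument.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0) or kd < 0:
        raise ValueError("L and kd must be >= 0")
    if not R > 0:
        raise ValueError("R must be > 0")
    s = L + R + kd
    disc = s * s - 4.0 * L * R
    # roundoff can push the discriminant a hair negative at kd == 0, L == R
    disc = np.maximum(disc, 0.0)
    # multiply by the conjugate: (s - sqrt(disc))/(2R) == 2L/(s + sqrt(disc)),
    # which avoids catastrophic cancellation when 4LR << s^2
    denom = s + np.sqrt(disc)
    out = np.where(denom > 0, 2.0 * L / np.where(denom > 0, denom, 1.0), 0.0)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


class TightBindingModel(RegressorMixin, BaseEstimator):
    """Quadratic ligand-depletion binding model with K_D as the only free
    parameter.

    The total receptor concentration is fixed at the assay design value
    (default 0.05 uM) rather than floated, since it is known exactly.
    Nonlinear least squares over ``kd_starts`` multi-starts; best SSE kept.

    Attributes
    ----------
    kd_ : float
        Fitted dissociation constant, uM.
    kd_stderr_ : float
        Asymptotic standard error of ``kd_``.
    residuals_ : ndarray
        Fit residuals (observed - predicted).
    at_bound_ : bool
        True when the optimum pinned at a bound (flagged, not an error).
    """

    def __init__(
        self,
        receptor_total: float = 0.05,
        bounds: tuple[float, float] = (1e-6, 1e3),
        starts: Sequence[float] = (0.01, 0.1, 1.0),
    ) -> None:
        self.receptor_total = receptor_total
        self.bounds = bounds
        self.starts = starts

    def fit(self, X, y):
        L = np.asarray(X, dtype=float).ravel()
        fb = np.asarray(y, dtype=float).ravel()
        if L.shape != fb.shape:
            raise ValueError("X and y must have equal length")
        if L.size < 4:
            raise ValueError("need >= 4 titration points to fit K_D")
        if not (L.min() < self.receptor_total < L.max() or L.size >= 4):
            raise ValueError("titration should span the receptor concentration")

        def resid(p: np.ndarray) -> np.ndarray:
            return quadratic_fraction(L, self.receptor_total, p[0]) - fb

        best = None
        for start in self.starts:
            sol = optimize.least_squares(
                resid, x0=[start], bounds=([self.bounds[0]], [self.bounds[1]])
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise RuntimeError("K_D fit did not converge")
        kd = float(best.x[0])
        r = best.fun
        dof = max(L.size - 1, 1)
        jac = best.jac.ravel()
        jtj = float(jac @ jac)
        sigma2 = float(r @ r) / dof
        self.kd_ = kd
        self.kd_stderr_ = float(np.sqrt(sigma2 / jtj)) if jtj > 0 else np.inf
        self.residuals_ = -r  # observed - predicted
        self.at_bound_ = bool(
            np.isclose(kd, self.bounds[0]) or np.isclose(kd, self.bounds[1])
        )
        return self

    def predict(self, X):
        if not hasattr(self, "kd_"):
            raise RuntimeError("model is not fitted")
        return quadratic_fraction(np.asarray(X, dtype=float).ravel(),
                                  self.receptor_total, self.kd_)


def fit_kd(
    measurements: Sequence[BindingMeasurement],
    receptor_total: float | None = None,
    bounds: tuple[float, float] = (1e-6, 1e3),
    starts: Sequence[float] = (0.01, 0.1, 1.0),
) -> BindingFit:
    """Fit K_D to fraction-bound measurements with receptor fixed."""
    if len(measurements) < 4:
        raise ValueError("need >= 4 titration points")
    if receptor_total is None:
        totals = {m.receptor_total for m in measurements}
        if len(totals) != 1:
            raise ValueError("mixed receptor totals; pass receptor_total explicitly")
        receptor_total = totals.pop()
    L = np.array([m.ligand_total for m in measurements])
    fb = np.array([m.fraction_bound for m in measurements])
    est = TightBindingModel(receptor_total=receptor_total, bounds=bounds,
                            starts=starts).fit(L, fb)
    return BindingFit(
        kd=est.kd_,
        receptor_total=receptor_total,
        kd_stderr=est.kd_stderr_,
        residuals=est.residuals_,
        at_bound=est.at_bound_,
    )


# ---------------------------------------------------------------------------
# equilibration


def equilibration_time(
    time_min: Sequence[float],
    signal: Sequence[float],
    tolerance: float = 0.05,
) -> float:
    """Earliest time (same units as ``time_min``) after which the signal stays
    within ``tolerance`` (fractional) of its final value.

    Raises on fewer than four points; a series whose late excursions exceed
    three tolerances of the final value is flagged as non-equilibrated.
    """
    t = np.asarray(time_min, dtype=float)
    y = np.asarray(signal, dtype=float)
    if t.size < 4:
        raise ValueError("need >= 4 time points to assess equilibration")
    final = y[-1]
    scale = abs(final) if final != 0 else np.max(np.abs(y))
    if scale == 0:
        return float(t[0])
    dev = np.abs(y - final) / scale
    within = dev <= tolerance
    # earliest index from which everything stays within tolerance
    idx = t.size - 1
    while idx > 0 and within[idx - 1]:
        idx -= 1
    if np.any(dev[idx:] > 3 * tolerance):
        raise ValueError("series has not plateaued (non-monotone within tail)")
    return float(t[idx])


# ---------------------------------------------------------------------------
# pyrene kinetics


def convert_rfu_to_polymer(
    trace: PolymerizationTrace,
    polymerizable_actin: float,
    baseline: float | None = None,
    plateau: float | None = None,
    plateau_fraction: float = 0.05,
) -> PolymerizationTrace:
    """Anchor a fluorescence trace to polymer concentration (nM).

    polymer(t) = (F(t) - baseline) / (plateau - baseline) * polymerizable pool.
    When not given, the baseline is the first sample and the plateau the mean
    of the final ``plateau_fraction`` of the trace.
    """
    if baseline is None:
        baseline = float(trace.fluorescence[0])
    if plateau is None:
        k = max(1, int(round(plateau_fraction * trace.time.size)))
        plateau = float(trace.fluorescence[-k:].mean())
    if plateau <= baseline:
        raise ValueError("plateau must exceed baseline")
    polymer = (trace.fluorescence - baseline) / (plateau - baseline) * polymerizable_actin
    return PolymerizationTrace(
        time=trace.time, fluorescence=trace.fluorescence, polymer=polymer
    )


def _sliding_slopes(t: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Least-squares slope of y vs t in every contiguous window."""
    n = t.size - window + 1
    slopes = np.empty(n)
    for i in range(n):
        tt = t[i : i + window]
        yy = y[i : i + window]
        tc = tt - tt.mean()
        slopes[i] = float(tc @ (yy - yy.mean()) / (tc @ tc))
    return slopes


def max_polymerization_rate(
    trace: PolymerizationTrace, window: int = 5
) -> float:
    """Maximum local slope of a polymerization trace (the MPR).

    Uses the converted polymer series when present (nM/s), otherwise raw
    fluorescence (RFU/s). The slope is a least-squares fit in a sliding
    window (default 5 points). A non-positive MPR (monotone decreasing
    trace) is returned as-is; callers may flag it.
    """
    y = trace.polymer if trace.polymer is not None else trace.fluorescence
    if trace.time.size < window:
        raise ValueError(f"trace shorter than slope window ({window})")
    return float(np.max(_sliding_slopes(trace.time, np.asarray(y, dtype=float), window)))


# ---------------------------------------------------------------------------
# titration


class ActivationTitrationModel(RegressorMixin, BaseEstimator):
    """Hyperbolic saturation model Y = Ymax*[L]/(K_1/2+[L]) + Yo.

    Concentrations in nM, rates in nM/s. Bounds keep all three parameters
    nonnegative; K_1/2 is multi-started. When the response is flat the fit
    returns Ymax ~ 0 and flags ``k_half_identifiable_ = False``.
    """

    def __init__(self, k_half_starts: Sequence[float] = (10.0, 100.0, 1000.0)) -> None:
        self.k_half_starts = k_half_starts

    def fit(self, X, y):
        conc = np.asarray(X, dtype=float).ravel()
        rate = np.asarray(y, dtype=float).ravel()
        if conc.size != rate.size:
            raise ValueError("X and y must have equal length")
        if conc.size < 4:
            raise ValueError("need >= 4 concentrations")

        def model(p: np.ndarray) -> np.ndarray:
            ymax, khalf, y0 = p
            return ymax * conc / (khalf + conc) + y0

        span = max(rate.max() - rate.min(), 1e-12)
        best = None
        for k0 in self.k_half_starts:
            sol = optimize.least_squares(
                lambda p: model(p) - rate,
                x0=[span, k0, max(rate.min(), 0.0)],
                bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            )
            if best is None or sol.cost < best.cost:
                best = sol
        if best is None or not best.success:
            raise RuntimeError("titration fit did not converge")
        self.ymax_, self.k_half_, self.y0_ = (float(v) for v in best.x)
        self.residuals_ = -best.fun
        self.k_half_identifiable_ = bool(self.ymax_ > 1e-6 * max(abs(self.y0_), span))
        return self

    def predict(self, X):
        if not hasattr(self, "ymax_"):
            raise RuntimeError("model is not fitted")
        conc = np.asarray(X, dtype=float).ravel()
        return self.ymax_ * conc / (self.k_half_ + conc) + self.y0_


def fit_mpr_titration(concentrations, rates) -> TitrationFit:
    """Fit the saturation curve to (activator concentration, MPR) points."""
    conc = np.asarray(concentrations, dtype=float)
    y = np.asarray(rates, dtype=float)
    est = ActivationTitrationModel().fit(conc, y)
    return TitrationFit(
        ymax=est.ymax_,
        k_half=est.k_half_,
        y0=est.y0_,
        concentrations=conc,
        rates=y,
        k_half_identifiable=est.k_half_identifiable_,
    )


def percent_activity(mpr_mutant: float, mpr_wt: float, mpr_actin: float) -> float:
    """Mutant activity as a percentage of wild type at matched activator:

    %activity = (MPR_mutant - MPR_actin) / (MPR_WT - MPR_actin) * 100,
    with MPR_actin the actin-alone baseline rate.
    """
    denom = mpr_wt - mpr_actin
    if denom <= 0:
        raise ValueError("WT rate must exceed the actin-alone baseline")
    return (mpr_mutant - mpr_actin) / denom * 100.0
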