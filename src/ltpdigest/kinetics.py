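"""Digestion kinetics from densitometry time courses.

Band intensities (normalised to the undigested control) are modelled as
first-order decay I(t) = I0·exp(-K·t).  A two-tailed Student's t-test between
the control and final-time replicates gates fitting: bands indistinguishable
from the control are called resistant and reported with infinite half-life
rather than forced through a decay fit.  Transient intermediates (fragments
that accumulate then decay) follow the consecutive first-order model
B(t) = A·k_form/(k_deg-k_form)·(exp(-k_form·t) - exp(-k_deg·t)), which
reduces to rising saturation A·(1-exp(-k_form·t)) as k_deg -> 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .core import DigestionCondition

LN2 = math.log(2.0)


@dataclass
class TimeCourse:
    """Densitometry series for one band under one condition."""

    time_min: np.ndarray
    intensity: np.ndarray  # fractions of the undigested control band
    replicate: np.ndarray | None = None
    band: str = "parent"  # parent | fragment_7kDa | other
    condition: DigestionCondition | None = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.time_min.shape != self.intensity.shape:
            raise ValueError("time and intensity shapes differ")
        if (self.time_min < 0).any():
            raise ValueError("negative times")
        if (self.intensity < 0).any():
            raise ValueError("negative intensities")


@dataclass
class DecayFit:
    K: float  # min^-1
    I0: float
    stderr_K: float
    rse: float  # residual standard error sqrt(SSE/(n-2))
    t_half: float  # min; inf when resistant or K == 0
    resistant: bool = False
    p_value: float | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.K < 0:
            raise ValueError("rate constant must be >= 0")


@dataclass
class TransientFit:
    k_form: float  # min^-1
    k_deg: float  # min^-1
    amplitude: float
    classification: str  # rising | transient
    peak_time_min: float | None
    rse: float


def resistance_test(
    iu_intensities,
    final_intensities,
    alpha: float = 0.05,
    welch: bool = False,
) -> tuple[float, bool]:
    """Two-tailed two-sample t-test of control vs final-time band intensity.

    resistant = (p >= alpha): the band is statistically indistinguishable from
    the undigested control, so the series is excluded from decay fitting.
    Classic equal-variance Student's test by default; Welch by flag.
    """
    a = np.asarray(iu_intensities, dtype=float)
    b = np.asarray(final_intensities, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("resistance test needs >= 2 replicates per group")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    if np.isnan(p):  # zero variance in both groups and equal means
        p = 1.0
    return float(p), bool(p >= alpha)


def _loglinear_init(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Initial (I0, K) from ordinary regression of log intensity on time."""
    pos = y > 0
    if pos.sum() < 2:
        return float(y.max(initial=1.0)), 0.01
    slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
    return float(np.exp(intercept)), float(max(-slope, 1e-6))


def fit_decay(
    tc: TimeCourse, max_iter: int = 500, weighting: str = "signal"
) -> DecayFit:
    """Fit I(t) = I0·exp(-K·t) by Levenberg-Marquardt damped least squares.

    Densitometry errors scale with band intensity, so by default the fit is
    iteratively reweighted with standard deviation proportional to the model
    value (floored at 1e-6·I0 only to avoid division by zero);
    ``weighting="none"`` gives the plain unweighted fit.  On noiseless data
    both recover (I0, K) exactly.
    """
    if weighting not in ("signal", "none"):
        raise ValueError(f"unknown weighting {weighting!r}")
    t, y = tc.time_min, tc.intensity
    if len(np.unique(t)) < 3:
        raise ValueError("decay fit needs >= 3 distinct time points")
    if not np.any(y > 0):
        raise ValueError("all intensities are zero")
    if np.ptp(y) == 0:
        # constant series: the decay model degenerates to K = 0
        return DecayFit(
            K=0.0, I0=float(y[0]), stderr_K=float("nan"), rse=0.0,
            t_half=float("inf"), degenerate=True,
        )

    def model(tt, i0, k):
        return i0 * np.exp(-k * tt)

    i0_0, k_0 = _loglinear_init(t, y)
    popt = np.array([i0_0, k_0])
    n_rounds = 3 if weighting == "signal" else 1
    try:
        for _ in range(n_rounds):
            sigma = None
            if weighting == "signal":
                pred = model(t, *popt)
                sigma = np.maximum(pred, 1e-6 * abs(popt[0]))
            popt, pcov = optimize.curve_fit(
                model, t, y, p0=popt, sigma=sigma, method="lm",
                maxfev=max_iter * 10, xtol=1e-12, ftol=1e-12,
            )
    except RuntimeError as exc:
        raise RuntimeError(f"decay fit did not converge: {exc}") from exc
    i0, k = popt
    if k < 0:
        k = 0.0
    resid = y - model(t, i0, k)
    n = len(y)
    rse = math.sqrt(float(resid @ resid) / (n - 2)) if n > 2 else float("nan")
    stderr_k = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else float("nan")
    return DecayFit(
        K=float(k), I0=float(i0), stderr_K=stderr_k, rse=rse,
        t_half=half_life(float(k)),
    )


def half_life(K: float) -> float:
    """First-order half-life ln(2)/K in minutes; infinity when K == 0."""
    if K < 0:
        raise ValueError("rate constant must be >= 0")
    if K == 0:
        return float("inf")
    return LN2 / K


def transient_model(t, amplitude, k_form, k_deg):
    """Intermediate concentration in consecutive first-order reactions.

    B(t) = A·k_form/(k_deg-k_form)·(exp(-k_form·t) - exp(-k_deg·t)); the
    analytic limit A·k·t·exp(-k·t) is used when the two rates coincide.
    """
    t = np.asarray(t, dtype=float)
    if abs(k_deg - k_form) < 1e-12 * max(abs(k_form), 1.0):
        return amplitude * k_form * t * np.exp(-k_form * t)
    return (
        amplitude
        * k_form
        / (k_deg - k_form)
        * (np.exp(-k_form * t) - np.exp(-k_deg * t))
    )


def rising_model(t, amplitude, k_form):
    """Saturating accumulation A·(1-exp(-k·t)): the k_deg -> 0 limit."""
    return amplitude * (1.0 - np.exp(-k_form * np.asarray(t, dtype=float)))


def fit_transient(tc: TimeCourse, max_iter: int = 500) -> TransientFit:
    """Fit the consecutive-reaction model to a fragment time course.

    When the fitted degradation rate is indistinguishable from zero (below
    1e-6 min^-1 or within two standard errors of zero) the model reduces to
    rising saturation and the fragment is classified "rising", reporting
    k_form as its rate constant; otherwise "transient" with the peak time
    ln(k_form/k_deg)/(k_form-k_deg).
    """
    t, y = tc.time_min, tc.intensity
    if len(np.unique(t)) < 4:
        raise ValueError("transient fit needs >= 4 distinct time points")

    # deterministic initialisation from the observed peak
    i_peak = int(np.argmax(y))
    t_peak = max(float(t[i_peak]), float(np.min(t[t > 0], initial=1.0)))
    k0 = 1.0 / t_peak
    a0 = float(np.max(y)) * math.e  # A·k·t·exp(-kt) peaks at A/e when k1=k2

    def run(modelfn, p0):
        popt, pcov = optimize.curve_fit(
            modelfn, t, y, p0=p0, method="lm",
            maxfev=max_iter * 10, xtol=1e-12, ftol=1e-12,
        )
        resid = y - modelfn(t, *popt)
        dof = max(len(y) - len(popt), 1)
        return popt, pcov, math.sqrt(float(resid @ resid) / dof)

    try:
        popt, pcov, rse = run(transient_model, [a0, k0 * 1.5, k0 * 0.5])
    except RuntimeError:
        popt = None
    reduce_to_rising = popt is None
    if popt is not None:
        amp, k_form, k_deg = popt
        se_kdeg = (
            float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("inf")
        )
        if k_deg < 1e-6 or k_deg < 2 * se_kdeg or k_form <= 0:
            reduce_to_rising = True

    if reduce_to_rising:
        try:
            (amp, k_form), _, rse = run(
                rising_model, [float(np.max(y)) or 1.0, k0]
            )
        except RuntimeError as exc:
            raise RuntimeError(f"transient fit did not converge: {exc}") from exc
        return TransientFit(
            k_form=float(abs(k_form)), k_deg=0.0, amplitude=float(amp),
            classification="rising", peak_time_min=None, rse=rse,
        )

    if k_form < 0 or k_deg < 0:
        raise RuntimeError("transient fit converged to negative rates")
    if abs(k_form - k_deg) < 1e-12:
        peak = 1.0 / k_form
    else:
        peak = math.log(k_form / k_deg) / (k_form - k_deg)
    return TransientFit(
        k_form=float(k_form), k_deg=float(k_deg), amplitude=float(amp),
        classification="transient", peak_time_min=float(peak), rse=rse,
    )


def fold_change_half_life(fit_a: DecayFit, fit_b: DecayFit) -> float:
    """Ratio t½(a)/t½(b); infinite numerators propagate to infinity."""
    if math.isinf(fit_a.t_half):
        return float("inf")
    return fit_a.t_half / fit_b.t_half
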