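"""Inhibition-ELISA analysis: four-parameter logistic fits and IC50 reporting.

The inhibition curve records absorbance (A450) against the concentration of
competing antigen.  The four-parameter logistic (4PL) model

    y = d + (a - d) / (1 + (x / c)^b)

has upper asymptote ``a`` (uninhibited signal), lower asymptote ``d``,
Hill slope ``b`` and inflection ``c``.  IC50 is reported as ``c`` — the
concentration at the midpoint between the asymptotes — and is censored to
"< min tested" / "> max tested" whenever the estimate falls outside the
assayed concentration range, since the data cannot localise it there.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize


@dataclass
class InhibitionCurve:
    """One patient/sample inhibition series (concentrations in µg/mL)."""

    concentration: np.ndarray
    response: np.ndarray  # A450
    patient_id: str = ""
    sample: str = "intact"  # intact | digest | digest+bile

    def __post_init__(self) -> None:
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentration.shape != self.response.shape:
            raise ValueError("concentration and response shapes differ")
        if (self.concentration <= 0).any():
            raise ValueError(
                "concentrations must be > 0 (keep the buffer control separate)"
            )
        if (self.response < 0).any():
            raise ValueError("negative responses")


@dataclass(frozen=True)
class IC50:
    """A point estimate or a censored bound on IC50 (µg/mL)."""

    value: float
    censor: str = ""  # "" | "<" | ">"
    approximate: bool = False

    def __str__(self) -> str:
        prefix = self.censor or ("~ " if self.approximate else "")
        return f"{prefix}{self.value:g}"

    @property
    def is_censored(self) -> bool:
        return bool(self.censor)


@dataclass
class FourPLFit:
    a: float  # upper asymptote
    d: float  # lower asymptote
    b: float  # slope
    c: float  # inflection concentration
    ic50: IC50
    rse: float
    stderr_c: float


def four_pl(x, a, d, b, log_c):
    """4PL response; the inflection is parametrised on the log scale (c > 0)."""
    return d + (a - d) / (1.0 + (np.asarray(x, dtype=float) / np.exp(log_c)) ** b)


def fit_4pl(curve: InhibitionCurve, flag_rel_stderr: float = 0.5) -> FourPLFit:
    """Least-squares 4PL fit with censored IC50 reporting.

    Initialisation is deterministic: a = max response, d = min response,
    b = 1, c = geometric mid-concentration.  Fits whose relative standard
    error on c exceeds ``flag_rel_stderr`` are flagged approximate ("~").
    """
    x, y = curve.concentration, curve.response
    if len(x) < 5:
        raise ValueError("4PL fit needs >= 5 concentration points")
    log_c0 = float(np.mean(np.log(x)))
    p0 = [float(np.max(y)), float(np.min(y)), 1.0, log_c0]
    try:
        popt, pcov = optimize.curve_fit(
            four_pl, x, y, p0=p0, method="lm", maxfev=20000,
            xtol=1e-12, ftol=1e-12,
        )
    except RuntimeError as exc:
        raise RuntimeError(f"4PL fit did not converge: {exc}") from exc
    a, d, b, log_c = popt
    if a < d:  # canonicalise so a is the upper asymptote
        a, d, b = d, a, -b
    c = float(np.exp(log_c))
    resid = y - four_pl(x, *popt)
    dof = max(len(y) - 4, 1)
    rse = math.sqrt(float(resid @ resid) / dof)
    se_logc = float(np.sqrt(pcov[3, 3])) if np.isfinite(pcov[3, 3]) else float("inf")
    stderr_c = c * se_logc  # delta method on the log-scale parameter

    cmin, cmax = float(np.min(x)), float(np.max(x))
    if c < cmin:
        ic50 = IC50(cmin, censor="<")
    elif c > cmax:
        ic50 = IC50(cmax, censor=">")
    else:
        ic50 = IC50(c, approximate=(se_logc > flag_rel_stderr))
    return FourPLFit(
        a=float(a), d=float(d), b=float(b), c=c,
        ic50=ic50, rse=rse, stderr_c=stderr_c,
    )


def ic50_fold_change(reference: FourPLFit, test: FourPLFit) -> IC50:
    """test IC50 / reference IC50, propagating censored bounds.

    A censored-low reference ("< x") or censored-high test ("> y") yields a
    lower bound "> y/x"; the converse yields an upper bound.
    """
    ref, tst = reference.ic50, test.ic50
    ratio = tst.value / ref.value
    if ref.censor == "<" or tst.censor == ">":
        return IC50(ratio, censor=">")
    if ref.censor == ">" or tst.censor == "<":
        return IC50(ratio, censor="<")
    return IC50(ratio, approximate=ref.approximate or tst.approximate)
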