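"""Phosphorescence lifetime oximetry: decays -> pO2 -> SO2 -> OEF.

Oxygen quenches the phosphorescence of an intravascular probe, so the
photon-decay lifetime shortens as pO2 rises (arteries decay faster than
veins).  The chain implemented here:

1. fit each averaged photon-decay histogram with a single exponential
   a·exp(-t/tau) + b by nonlinear least squares;
2. convert tau to pO2 (mmHg) with a calibration from independent oxygen
   titrations — either Stern-Volmer parameters (1/tau = 1/tau0 + kq·pO2)
   or a monotone (tau, pO2) lookup table;
3. convert pO2 to hemoglobin saturation SO2 with a Hill curve
   SO2 = pO2^h / (p50^h + pO2^h);
4. pair mean arterial and venous saturations into the oxygen extraction
   fraction OEF = (Sa - Sv)/Sa.

Hill parameters are configuration: the defaults are literature values
for mouse hemoglobin, not measured by this pipeline, and every output
records the parameters used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .linescan import profile_fwhm

__all__ = [
    "PhosphorescenceDecay",
    "SternVolmerCalibration",
    "TableCalibration",
    "HillParameters",
    "LifetimeFit",
    "fit_lifetime",
    "lifetime_to_po2",
    "po2_to_so2",
    "oef",
    "vessel_diameter_manual",
]


class NoDecayError(ValueError):
    """Raised when a histogram shows no detectable exponential decay."""


@dataclass
class PhosphorescenceDecay:
    """Averaged photon-decay histogram over the collection window."""

    t_us: np.ndarray
    counts: np.ndarray
    n_sweeps: int = 1

    def __post_init__(self) -> None:
        self.t_us = np.asarray(self.t_us, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.t_us.shape != self.counts.shape:
            raise ValueError("time grid and counts must match")
        if np.any(np.diff(self.t_us) <= 0):
            raise ValueError("time grid must be increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class LifetimeFit:
    tau_us: float
    amplitude: float
    background: float
    r_squared: float


@dataclass(frozen=True)
class SternVolmerCalibration:
    """1/tau = 1/tau0 + kq * pO2 with tau0 the zero-oxygen lifetime."""

    tau0_us: float
    kq_per_mmHg_us: float

    def po2(self, tau_us: float) -> float:
        if tau_us <= 0:
            raise ValueError("lifetime must be positive")
        if tau_us > self.tau0_us:
            warnings.warn(
                "lifetime exceeds the zero-oxygen lifetime; clamping pO2 to 0"
            )
            return 0.0
        return (1.0 / tau_us - 1.0 / self.tau0_us) / self.kq_per_mmHg_us

    def tau(self, po2_mmHg: float) -> float:
        return 1.0 / (1.0 / self.tau0_us + self.kq_per_mmHg_us * po2_mmHg)


@dataclass
class TableCalibration:
    """Monotone (tau, pO2) lookup from an oxygen-titration experiment."""

    tau_us: np.ndarray
    po2_mmHg: np.ndarray

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau_us, dtype=float)
        po2 = np.asarray(self.po2_mmHg, dtype=float)
        order = np.argsort(tau)
        tau, po2 = tau[order], po2[order]
        if np.any(np.diff(tau) <= 0) or np.any(np.diff(po2) >= 0):
            raise ValueError("table must be strictly monotone (tau up, pO2 down)")
        self.tau_us, self.po2_mmHg = tau, po2

    def po2(self, tau_us: float) -> float:
        if tau_us < self.tau_us[0]:
            raise ValueError("lifetime below the calibrated range")
        if tau_us > self.tau_us[-1]:
            warnings.warn(
                "lifetime above the calibrated range; clamping pO2 to "
                "the table minimum"
            )
            return float(self.po2_mmHg[-1])
        return float(np.interp(tau_us, self.tau_us, self.po2_mmHg))

    def tau(self, po2_mmHg: float) -> float:
        # invert on the pO2-sorted view
        order = np.argsort(self.po2_mmHg)
        return float(
            np.interp(po2_mmHg, self.po2_mmHg[order], self.tau_us[order])
        )


@dataclass(frozen=True)
class HillParameters:
    """Hemoglobin O2 affinity: half-saturation p50 (mmHg), cooperativity h.

    Defaults are literature values for mouse hemoglobin (not measured by
    this pipeline); record them with any SO2/OEF you report.
    """

    p50_mmHg: float = 40.2
    h: float = 2.59
    source: str = "literature default (mouse hemoglobin)"


def fit_lifetime(decay: PhosphorescenceDecay) -> LifetimeFit:
    """Single-exponential lifetime by nonlinear least squares.

    Model a·exp(-t/tau) + b; initialized from a log-linear regression of
    the background-subtracted counts.  Raises :class:`NoDecayError`
    when the histogram carries no decaying component.
    """
    t, y = decay.t_us, decay.counts
    if t.size < 10:
        raise ValueError("need at least 10 samples")
    span = t[-1] - t[0]
    tail = y[-max(3, y.size // 10):]
    b0 = float(tail.mean())
    a0 = float(y[: max(3, y.size // 20)].mean() - b0)
    # an amplitude within the tail's noise band is no decay at all
    if a0 <= 3.0 * float(tail.std()) or y.max() == y.min():
        raise NoDecayError("histogram shows no decay above background")
    pos = y - b0 > a0 * 1e-3
    if pos.sum() < 3:
        raise NoDecayError("too few samples above background")
    slope = np.polyfit(t[pos], np.log(y[pos] - b0), 1)[0]
    if slope >= 0:
        raise NoDecayError("counts do not decrease with time")
    tau0 = min(-1.0 / slope, span)

    def model(t, a, tau, b):
        return a * np.exp(-t / tau) + b

    popt, _ = curve_fit(
        model, t, y, p0=(a0, tau0, b0),
        bounds=([0, 1e-6, 0], [np.inf, 100 * span, np.inf]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=10000,
    )
    a, tau, b = popt
    resid = y - model(t, *popt)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot else 0.0
    if span < tau:
        warnings.warn("collection window shorter than the fitted lifetime")
    return LifetimeFit(
        tau_us=float(tau), amplitude=float(a), background=float(b),
        r_squared=r2,
    )


def lifetime_to_po2(tau_us: float, calibration) -> float:
    """Convert a lifetime to pO2 (mmHg) through the calibration object."""
    return calibration.po2(tau_us)


def po2_to_so2(po2_mmHg, hill: HillParameters = HillParameters()):
    """Hemoglobin saturation from pO2 via the Hill equation."""
    po2 = np.asarray(po2_mmHg, dtype=float)
    if np.any(po2 < 0):
        raise ValueError("pO2 must be non-negative")
    if hill.p50_mmHg <= 0 or hill.h <= 0:
        raise ValueError("Hill parameters must be positive")
    ratio = (po2 / hill.p50_mmHg) ** hill.h
    out = ratio / (1.0 + ratio)
    return float(out) if np.isscalar(po2_mmHg) else out


def oef(mean_arterial_so2: float, mean_venous_so2: float) -> float:
    """Oxygen extraction fraction (Sa - Sv)/Sa from paired saturations."""
    sa, sv = float(mean_arterial_so2), float(mean_venous_so2)
    if not 0 < sa <= 1:
        raise ValueError("arterial SO2 must be in (0, 1]")
    if sv < 0:
        raise ValueError("venous SO2 must be >= 0")
    if sv > sa:
        warnings.warn("venous SO2 exceeds arterial: nonphysical pairing")
    return (sa - sv) / sa


def vessel_diameter_manual(profiles, pixel_size_um: float) -> float:
    """Vessel diameter as the mean FWHM of transversal intensity lines.

    ``profiles`` is a sequence of 1-D intensity profiles drawn across
    the vessel axis (five lines in the standard protocol).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile line")
    widths = [profile_fwhm(p, pixel_size_um) for p in profiles]
    return float(np.mean(widths))
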