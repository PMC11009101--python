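"""Effective-PSF model and the angular emission law for circular sampling.

In MINSTED localization the STED donut shrinks the region from which
detected fluorescence can originate to an effective point-spread function
(E-PSF), modeled here as an isotropic 2D Gaussian with standard deviation
``sigma_e``.  The E-PSF is scanned on a circle of radius ``r`` around the
current position estimate; upon each photon detection the circle center is
shifted by a fraction ``alpha`` of the radius toward the point of emission.

Because the beams circle much faster than photons are detected (125 kHz
circling versus <=62 kHz count rates), each detection samples the whole
circle: the emission angle ``beta`` follows the normalized restriction of
the Gaussian E-PSF to the circle.  For an emitter at distance ``d`` from
the circle center this restriction is a von Mises law with mean direction
pointing at the emitter and concentration ``kappa = r * d / sigma_e**2``.

Units: nanometers and seconds throughout; angles in radians, measured from
the +x axis, counterclockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0e

__all__ = [
    "FWHM_FACTOR",
    "EPSF",
    "ScanConfig",
    "emission_probability",
    "vonmises_params",
    "angular_emission_density",
    "sample_emission_angle",
]

#: FWHM of a Gaussian in units of its standard deviation: 2*sqrt(2*ln 2).
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class EPSF:
    """Gaussian effective point-spread function.

    Parameters
    ----------
    sigma_e : float
        Standard deviation of the Gaussian E-PSF in nm.  The full width at
        half maximum follows as ``fwhm = 2*sqrt(2*ln 2) * sigma_e``.
    """

    sigma_e: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sigma_e) and self.sigma_e > 0):
            raise ValueError(f"sigma_e must be positive and finite, got {self.sigma_e}")

    @property
    def fwhm(self) -> float:
        """Full width at half maximum of the E-PSF in nm."""
        return FWHM_FACTOR * self.sigma_e

    @classmethod
    def from_fwhm(cls, fwhm: float) -> "EPSF":
        """Construct from the FWHM instead of the standard deviation."""
        return cls(sigma_e=fwhm / FWHM_FACTOR)


@dataclass(frozen=True)
class ScanConfig:
    """Parameters of the circular MINSTED sampling scheme.

    Parameters
    ----------
    radius : float
        Circling radius r in nm.  The standard operating point sets the
        circle diameter equal to the E-PSF FWHM (``2 r = fwhm``).
    alpha : float
        Update fraction: each detection shifts the circle center by
        ``alpha * radius`` toward the detection point.  Dimensionless,
        strictly between 0 and 1.
    rate : float
        Mean photon detection rate k in counts per second.
    circling_freq : float
        Beam circling frequency in Hz.  Must exceed the detection rate so
        that each photon samples the whole circle.
    termination_window : float
        Termination time T_t in seconds: a localization stops once fewer
        than 16 photons arrive within a trailing window of this length.
    power_label : str
        Free-text STED-power metadata; not used computationally.
    """

    radius: float
    alpha: float
    rate: float
    circling_freq: float = 125e3
    termination_window: float = 5e-3
    power_label: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if not (self.radius > 0):
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not (self.rate > 0):
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not (self.termination_window > 0):
            raise ValueError("termination_window must be positive")
        if not (self.circling_freq > self.rate):
            raise ValueError(
                "circling_freq must exceed the detection rate; the angular "
                "emission law assumes each photon samples the whole circle"
            )

    @classmethod
    def matched(cls, epsf: EPSF, rate: float, alpha: float = 0.15, **kwargs) -> "ScanConfig":
        """Standard configuration with circle diameter matching the FWHM."""
        return cls(radius=epsf.fwhm / 2.0, alpha=alpha, rate=rate, **kwargs)


def emission_probability(offset, epsf: EPSF):
    """Unnormalized emission weight at a beam-emitter offset.

    Evaluates ``exp(-|offset|^2 / (2 sigma_e^2))``, the Gaussian E-PSF
    weight in (0, 1] for the given 2-vector offset (nm).  Broadcasts over
    leading axes of an ``(..., 2)`` array.
    """
    offset = np.asarray(offset, dtype=float)
    if offset.shape[-1] != 2:
        raise ValueError("offset must be a 2-vector (or array of 2-vectors)")
    if not np.all(np.isfinite(offset)):
        raise ValueError("offset must be finite")
    sq = np.sum(offset**2, axis=-1)
    return np.exp(-sq / (2.0 * epsf.sigma_e**2))


def vonmises_params(center_to_emitter, r: float, epsf: EPSF):
    """Mean direction and concentration of the angular emission law.

    For an emitter displaced by ``center_to_emitter`` (nm) from the circle
    center, the emission angle is von Mises distributed with mean direction
    ``mu = atan2(dy, dx)`` and concentration ``kappa = r * d / sigma_e**2``.
    """
    if r <= 0:
        raise ValueError("r must be positive")
    v = np.asarray(center_to_emitter, dtype=float)
    if v.shape != (2,) or not np.all(np.isfinite(v)):
        raise ValueError("center_to_emitter must be a finite 2-vector")
    d = math.hypot(v[0], v[1])
    mu = math.atan2(v[1], v[0]) if d > 0 else 0.0
    kappa = r * d / epsf.sigma_e**2
    return mu, kappa


def angular_emission_density(beta, center_to_emitter, r: float, epsf: EPSF):
    """Normalized density of the emission angle beta over [0, 2*pi).

    The density is proportional to ``exp(-|e - c(beta)|^2 / (2 sigma_e^2))``
    with ``c(beta)`` the point on the sampling circle, which reduces to the
    von Mises density ``exp(kappa cos(beta - mu)) / (2 pi I0(kappa))``.
    Evaluated with exponentially scaled Bessel functions for stability at
    large concentration.
    """
    mu, kappa = vonmises_params(center_to_emitter, r, epsf)
    beta = np.asarray(beta, dtype=float)
    # exp(kappa*(cos(b-mu)-1)) / (2*pi*i0e(kappa)) is stable for any kappa
    return np.exp(kappa * (np.cos(beta - mu) - 1.0)) / (2.0 * math.pi * i0e(kappa))


def sample_emission_angle(center_to_emitter, r: float, epsf: EPSF, rng: np.random.Generator, size=None):
    """Draw emission angles beta in [0, 2*pi) from the angular law.

    Reproducible for a fixed seeded ``numpy.random.Generator``.
    """
    mu, kappa = vonmises_params(center_to_emitter, r, epsf)
    beta = rng.vonmises(mu, kappa, size=size)
    return np.mod(beta, 2.0 * math.pi)
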