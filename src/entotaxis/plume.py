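"""Advection-diffusion encounter-rate model of a pulsed odor plume.

A point source at ``r0`` releases odor particles at rate ``E`` into a mean
wind of speed ``W``; particles diffuse with effective diffusivity ``D`` and
survive for a mean lifetime ``tau``.  The expected detection rate of a
searcher with sensor size ``a`` at position ``r`` is

    R(r | r0) = (a E / d) * exp(-d / lambda) * exp(s W / (2 D))

with d = |r - r0| (clamped below by a), s the signed downwind displacement
of the searcher from the candidate source, and decay length

    lambda = sqrt(D tau / (1 + W^2 tau / (4 D))).

All quantities are SI (metres, seconds).  With W = 0 the rate is isotropic
and lambda collapses to sqrt(D tau); increasing wind shortens lambda but
slows the decay on the downwind side (as long as W/2D < 1/lambda), which is
where a plume actually extends.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PlumeParameters", "effective_lambda", "encounter_rate"]


def effective_lambda(D: float, tau: float, W: float) -> float:
    """Decay length lambda = sqrt(D*tau / (1 + W^2*tau/(4*D))) in metres.

    Raises ``ValueError`` for non-positive diffusivity or lifetime.
    """
    if D <= 0 or tau <= 0:
        raise ValueError(f"D and tau must be positive (got D={D}, tau={tau})")
    if W < 0:
        raise ValueError("wind speed W must be non-negative")
    return float(np.sqrt(D * tau / (1.0 + W * W * tau / (4.0 * D))))


@dataclass(frozen=True)
class PlumeParameters:
    """Parameters of the encounter-rate model.

    Attributes
    ----------
    a : float
        Searcher sensor size (m); also the lower clamp on source distance.
    E : float
        Source emission rate (treated as a given scalar).
    tau : float
        Mean odor-particle lifetime (s).
    D : float
        Effective diffusivity (m^2/s).
    W : float
        Mean wind speed (m/s).
    wind_axis : (2,) array
        Unit vector of the downwind direction in arena coordinates.
    r0 : (2,) array
        Source location (m).
    """

    a: float = 0.010
    E: float = 1.0
    tau: float = 6.3
    D: float = 0.057
    W: float = 0.6
    wind_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0]))
    r0: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        if self.a <= 0 or self.E <= 0:
            raise ValueError("a and E must be positive")
        # effective_lambda validates D, tau, W
        effective_lambda(self.D, self.tau, self.W)
        axis = np.asarray(self.wind_axis, dtype=float)
        norm = float(np.linalg.norm(axis))
        if not np.isclose(norm, 1.0, rtol=1e-9, atol=1e-12):
            if norm == 0:
                raise ValueError("wind_axis must be a non-zero vector")
            axis = axis / norm
        object.__setattr__(self, "wind_axis", axis)
        object.__setattr__(self, "r0",
                           np.asarray(self.r0, dtype=float).reshape(2))

    @property
    def lambda_(self) -> float:
        """Derived decay length (m)."""
        return effective_lambda(self.D, self.tau, self.W)

    def replace(self, **kw) -> "PlumeParameters":
        from dataclasses import replace
        return replace(self, **kw)


def encounter_rate(r: np.ndarray, p: PlumeParameters,
                   r0: np.ndarray | None = None) -> np.ndarray:
    """Expected odor-encounter rate R(r | r0) in 1/s.

    Parameters
    ----------
    r : (..., 2) array
        Searcher position(s), metres.
    p : PlumeParameters
    r0 : (..., 2) array, optional
        Candidate source location(s), metres; defaults to ``p.r0``.
        Broadcasts against ``r``, so a (n_cells, 1, 2) grid against a
        (n_times, 2) trajectory yields an (n_cells, n_times) rate matrix.

    The distance is clamped to ``d >= a`` so the rate stays finite at the
    source; the exponential advection factor uses the signed downwind
    displacement of the searcher from the source.
    """
    r = np.asarray(r, dtype=float)
    src = p.r0 if r0 is None else np.asarray(r0, dtype=float)
    delta = r - src
    d = np.linalg.norm(delta, axis=-1)
    d = np.maximum(d, p.a)
    s = delta @ p.wind_axis  # signed downwind displacement
    lam = p.lambda_
    return (p.a * p.E / d) * np.exp(-d / lam) * np.exp(s * p.W / (2.0 * p.D))
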