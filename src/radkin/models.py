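"""Candidate kinetic laws for radical-decay absorbance traces.

Two families are implemented as pure functions of time:

* **Parallel first-order (FO1/FO2/FO3)** — the absorbance is a sum of one to
  three exponential channels plus an offset,
  ``y(t) = y0 + sum_i Ar_i * exp(-t / tau_i)``, interpreted as independent
  first-order quenching pathways with rate constants ``1/tau_i``.

* **Second-order (SO)** — a single bimolecular step AH + r -> P where both
  the radical (Ar) and the antioxidant pool (AAH) are consumed.  For unequal
  initial levels the radical trace follows the closed form

  ``Ar(t) = Ar0 * d * exp(-k*t*d) / (AAH0 - Ar0 * exp(-k*t*d))``,
  ``d = AAH0 - Ar0``,

  which collapses to the textbook ``Ar0 / (1 + k*t*Ar0)`` when the initial
  levels coincide.  ``k`` is expressed per absorbance unit per second
  because the model is fitted on absorbance directly; conversion to a
  concentration scale via a calibration line is a separate, optional step.

``integrate_so`` integrates the underlying ODE system numerically and is
kept as an independent oracle for the closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core import ValidationError

__all__ = ["FOParams", "SOParams", "fo_model", "so_model", "so_antioxidant", "integrate_so"]

#: Relative threshold below which |AAH0 - Ar0| is treated as zero and the
#: equal-concentration closed form is used (avoids catastrophic cancellation).
EPS_DEGENERATE = 1e-9


@dataclass(frozen=True)
class FOParams:
    """Parameters of a 1-3 component parallel first-order decay.

    ``amplitudes[i]`` [AU] and ``time_constants[i]`` [s] describe channel i;
    canonical ordering is fastest channel first (time constants ascending).
    ``y0`` is the absorbance remaining after infinite time.
    """

    amplitudes: tuple[float, ...]
    time_constants: tuple[float, ...]
    y0: float

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in np.atleast_1d(self.amplitudes))
        taus = tuple(float(t) for t in np.atleast_1d(self.time_constants))
        object.__setattr__(self, "amplitudes", amps)
        object.__setattr__(self, "time_constants", taus)
        if len(amps) != len(taus):
            raise ValidationError("amplitudes and time_constants lengths differ")
        if not 1 <= len(amps) <= 3:
            raise ValidationError("order must be 1, 2 or 3")
        if not all(np.isfinite(a) for a in amps):
            raise ValidationError("amplitudes must be finite")
        if not all(np.isfinite(t) and t > 0 for t in taus):
            raise ValidationError("time constants must be finite and > 0")
        if not np.isfinite(self.y0):
            raise ValidationError("y0 must be finite")

    @property
    def order(self) -> int:
        return len(self.amplitudes)

    @property
    def rate_constants(self) -> tuple[float, ...]:
        """Per-channel first-order rate constants 1/tau_i [1/s]."""
        return tuple(1.0 / t for t in self.time_constants)

    def canonical(self) -> "FOParams":
        """Components sorted fastest first (time constants ascending)."""
        idx = np.argsort(self.time_constants, kind="stable")
        return FOParams(
            tuple(self.amplitudes[i] for i in idx),
            tuple(self.time_constants[i] for i in idx),
            self.y0,
        )


@dataclass(frozen=True)
class SOParams:
    """Parameters of the bimolecular quenching step AH + r -> P.

    ``k`` [1/(AU s)] is the second-order rate constant on the absorbance
    scale, ``ar0`` [AU] the initial radical absorbance and ``aah0`` [AU] the
    initial antioxidant level in absorbance-equivalent units.
    """

    k: float
    ar0: float
    aah0: float

    def __post_init__(self) -> None:
        for name, v in (("k", self.k), ("ar0", self.ar0), ("aah0", self.aah0)):
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be finite and > 0, got {v}")


def _check_times(t) -> np.ndarray:
    arr = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValidationError("time must be finite")
    if np.any(arr < 0):
        raise ValidationError("time must be >= 0")
    return arr


def fo_model(t, p: FOParams):
    """Evaluate the parallel first-order model ``y0 + sum_i Ar_i e^{-t/tau_i}``."""
    arr = _check_times(t)
    y = np.full_like(arr, p.y0, dtype=float)
    for a, tau in zip(p.amplitudes, p.time_constants):
        y += a * np.exp(-arr / tau)
    return float(y) if np.isscalar(t) else y


def so_model(t, p: SOParams):
    """Radical absorbance under second-order quenching with unequal initial levels.

    Strictly decreasing in t; ``so_model(0, p) == p.ar0`` exactly and the
    long-time limit is ``max(0, ar0 - aah0)`` (radical excess survives).
    The degenerate case ``aah0 == ar0`` uses the equal-concentration form
    ``ar0 / (1 + k t ar0)``.
    """
    arr = _check_times(t)
    k, ar0, aah0 = p.k, p.ar0, p.aah0
    d = aah0 - ar0
    if abs(d) <= EPS_DEGENERATE * max(ar0, aah0):
        y = ar0 / (1.0 + k * arr * ar0)
    elif d > 0:
        # antioxidant excess: decay of the exponential keeps E in (0, 1]
        e = np.exp(-k * arr * d)
        y = ar0 * d * e / (aah0 - ar0 * e)
    else:
        # radical excess: rearranged to keep the exponent non-positive
        m = -d
        y = ar0 * m / (ar0 - aah0 * np.exp(-k * arr * m))
    return float(y) if np.isscalar(t) else y


def so_antioxidant(t, p: SOParams, stoichiometry: float = 1.0):
    """Antioxidant level over time under the bimolecular step.

    With the default 1:1 stoichiometry the antioxidant consumed equals the
    radical consumed: ``AAH(t) = aah0 - (ar0 - Ar(t))``.  A stoichiometric
    factor n > 1 (n radicals quenched per antioxidant, as reported for
    polyphenols reacting with galvinoxyl) divides the consumption by n.
    """
    if not (np.isfinite(stoichiometry) and stoichiometry > 0):
        raise ValidationError(f"stoichiometry must be > 0, got {stoichiometry}")
    ar = so_model(t, p)
    return p.aah0 - (p.ar0 - ar) / stoichiometry


def integrate_so(p: SOParams, grid) -> np.ndarray:
    """Numerically integrate dAr/dt = dAAH/dt = -k*Ar*AAH on a time grid.

    Independent oracle for :func:`so_model`; adaptive Runge-Kutta with
    relative tolerance well below 1e-9.  The grid must be strictly
    increasing and start at 0.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValidationError("grid must be a non-empty 1-D sequence")
    if grid[0] != 0 or np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be strictly increasing from 0")
    if grid.size == 1:
        return np.array([p.ar0])

    def rhs(_t, y):
        rate = -p.k * y[0] * y[1]
        return [rate, rate]

    sol = solve_ivp(
        rhs,
        (0.0, float(grid[-1])),
        [p.ar0, p.aah0],
        t_eval=grid,
        method="DOP853",
        rtol=1e-12,
        atol=1e-300,  # effectively pure relative control; Ar never hits 0

    )
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[0]
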