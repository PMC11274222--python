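"""Shared domain types and assay arithmetic for radical-quenching kinetics.

The central object is the :class:`KineticTrace`: a single absorbance-time
series recorded while a stable chromogenic radical (DPPH· at 517 nm or
galvinoxyl at 428 nm) is quenched by antioxidants in solution.  This module
also carries the empirical calibration line that maps absorbance to a
concentration-equivalent scale, the percent-remaining transform used to
report radical survival, the dilution-scheme metadata of the assay design,
and a small elemental-composition utility (H/C and N/C ratios from CHN
combustion percentages).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Radical",
    "Source",
    "KineticTrace",
    "CalibrationCurve",
    "SampleSpec",
    "ElementalComposition",
    "ElementalRatios",
    "RadkinError",
    "ValidationError",
    "InvalidReferenceError",
    "InvalidCalibrationError",
    "DegenerateDesignError",
    "WAVELENGTH_NM",
    "A0_REFERENCE",
    "DPPH_CALIBRATION",
    "GLV_CALIBRATION",
    "percent_remaining",
    "trace_to_percent",
    "absorbance_to_concentration",
    "concentration_to_absorbance",
    "fit_calibration",
    "elemental_ratios",
    "read_trace",
    "write_trace",
    "read_calibration",
    "write_calibration",
]


class RadkinError(Exception):
    """Base class for all package errors."""


class ValidationError(RadkinError, ValueError):
    """An input violates a documented precondition."""


class InvalidReferenceError(ValidationError):
    """The reference absorbance A0 is non-positive or non-finite."""


class InvalidCalibrationError(ValidationError):
    """A calibration curve has a non-positive slope."""


class DegenerateDesignError(ValidationError):
    """A calibration design has no spread in concentration."""


class Radical(str, Enum):
    """The stable radical probe being monitored."""

    DPPH = "DPPH"
    GLV = "GLV"


class Source(str, Enum):
    """Plant material the infusion was brewed from."""

    FLOWER = "FLOWER"
    FRUIT = "FRUIT"


#: Monitoring wavelength of each radical's absorbance maximum [nm].
WAVELENGTH_NM = {Radical.DPPH: 517.0, Radical.GLV: 428.0}

#: Assay initial absorbance of the pure radical solution [AU].
A0_REFERENCE = {Radical.DPPH: 1.1219, Radical.GLV: 1.1720}

#: Acronym fragment used in sample identifiers (K/O + tag + dilution level).
ACRONYM_TAG = {Radical.DPPH: "DPPH", Radical.GLV: "GL"}

#: Acronym prefix per plant source (K = flower, O = fruit).
SOURCE_PREFIX = {Source.FLOWER: "K", Source.FRUIT: "O"}

# Atomic masses for molar-basis elemental ratios [g/mol].
_ATOMIC_MASS = {"H": 1.008, "C": 12.011, "N": 14.007}


@dataclass(frozen=True)
class KineticTrace:
    """One absorbance-time series of a radical-quenching run.

    Parameters
    ----------
    times
        Sampling times in seconds, strictly increasing, all >= 0.
    absorbance
        Absorbance readings [AU], same length as ``times`` (>= 3 points).
    radical
        Which radical probe was monitored.
    sample_id
        Sample acronym, e.g. ``KDPPH1.0`` (flower, DPPH, 1.0e-3 g/mL
        dilution) or ``OGL2.5``.
    a0_reference
        Initial absorbance of the pure radical solution used to normalise
        percent-remaining.  Defaults to the radical's assay constant
        (1.1219 AU for DPPH, 1.1720 AU for galvinoxyl).
    wavelength
        Monitoring wavelength [nm]; defaults to, and must match, the
        radical's standard wavelength (517 nm DPPH, 428 nm galvinoxyl).
    """

    times: np.ndarray
    absorbance: np.ndarray
    radical: Radical
    sample_id: str = ""
    a0_reference: float | None = None
    wavelength: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.ndim != 1 or a.ndim != 1:
            raise ValidationError("times and absorbance must be 1-D")
        if t.shape != a.shape:
            raise ValidationError(
                f"times ({t.size}) and absorbance ({a.size}) lengths differ"
            )
        if t.size < 3:
            raise ValidationError("a kinetic trace needs at least 3 points")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(a)):
            raise ValidationError("times and absorbance must be finite")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing and >= 0")
        radical = Radical(self.radical)
        object.__setattr__(self, "radical", radical)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)
        if self.a0_reference is None:
            object.__setattr__(self, "a0_reference", A0_REFERENCE[radical])
        elif not (np.isfinite(self.a0_reference) and self.a0_reference > 0):
            raise InvalidReferenceError(
                f"a0_reference must be finite and > 0, got {self.a0_reference}"
            )
        if self.wavelength is None:
            object.__setattr__(self, "wavelength", WAVELENGTH_NM[radical])
        elif self.wavelength != WAVELENGTH_NM[radical]:
            raise ValidationError(
                f"wavelength {self.wavelength} nm inconsistent with "
                f"{radical.value} ({WAVELENGTH_NM[radical]} nm)"
            )

    def __len__(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class CalibrationCurve:
    """Empirical linear absorbance-concentration relation y = slope*x + intercept.

    The concentration axis x is carried in the opaque unit in which the
    standard series was prepared; the package never converts it.
    """

    radical: Radical
    slope: float
    intercept: float
    r_squared: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "radical", Radical(self.radical))
        if not (np.isfinite(self.slope) and self.slope > 0):
            raise InvalidCalibrationError(f"slope must be > 0, got {self.slope}")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError(f"r_squared must be in [0, 1], got {self.r_squared}")


#: Published calibration line for DPPH (absorbance vs concentration).
DPPH_CALIBRATION = CalibrationCurve(Radical.DPPH, 8.6885, 0.0315, 0.9994)

#: Published calibration line for galvinoxyl.
GLV_CALIBRATION = CalibrationCurve(Radical.GLV, 18.465, 0.0471, 0.9972)


@dataclass(frozen=True)
class SampleSpec:
    """One row of the assay dilution scheme.

    An infusion aliquot (``infusion_volume_ml``, equal in mL to the dilution
    level in 1e-3 g/mL) is made up to 10 mL with water; 0.5 mL of that
    dilution is mixed with 3.0 mL of radical solution for the kinetic run.
    """

    source: Source
    dilution_level: float  # units of 1e-3 g/mL; one of 1.0, 1.5, 2.0, 2.5
    infusion_volume_ml: float | None = None
    water_volume_ml: float | None = None
    radical_solution_ml: float = 3.0
    aliquot_ml: float = 0.5

    DILUTION_LEVELS = (1.0, 1.5, 2.0, 2.5)

    def __post_init__(self) -> None:
        object.__setattr__(self, "source", Source(self.source))
        if not any(
            np.isclose(self.dilution_level, lvl) for lvl in self.DILUTION_LEVELS
        ):
            raise ValidationError(
                f"dilution_level must be one of {self.DILUTION_LEVELS} "
                f"(x1e-3 g/mL), got {self.dilution_level}"
            )
        if self.infusion_volume_ml is None:
            object.__setattr__(self, "infusion_volume_ml", self.dilution_level)
        if self.water_volume_ml is None:
            object.__setattr__(self, "water_volume_ml", 10.0 - self.infusion_volume_ml)
        if not np.isclose(self.infusion_volume_ml + self.water_volume_ml, 10.0):
            raise ValidationError("infusion + water volumes must total 10.0 mL")
        if self.radical_solution_ml != 3.0 or self.aliquot_ml != 0.5:
            raise ValidationError(
                "assay fixes 3.0 mL radical solution and a 0.5 mL aliquot"
            )

    def acronym(self, radical: Radical) -> str:
        """Sample identifier, e.g. ``KDPPH1.0`` or ``OGL2.5``."""
        radical = Radical(radical)
        return (
            f"{SOURCE_PREFIX[self.source]}{ACRONYM_TAG[radical]}"
            f"{self.dilution_level:.1f}"
        )


@dataclass(frozen=True)
class ElementalComposition:
    """CHN combustion result as mass percentages of the dry material."""

    pct_c: float
    pct_h: float
    pct_n: float

    def __post_init__(self) -> None:
        for name, v in (("pct_c", self.pct_c), ("pct_h", self.pct_h), ("pct_n", self.pct_n)):
            if not (np.isfinite(v) and 0.0 <= v <= 100.0):
                raise ValidationError(f"{name} must be in [0, 100], got {v}")
        if self.pct_c + self.pct_h + self.pct_n > 100.0 + 1e-9:
            raise ValidationError("C + H + N mass percentages exceed 100%")


@dataclass(frozen=True)
class ElementalRatios:
    """H/C and N/C ratios on mass and molar bases."""

    h_over_c_mass: float
    n_over_c_mass: float
    h_over_c_molar: float
    n_over_c_molar: float


def percent_remaining(a_t, a_0: float):
    """Percent of radical remaining: ``100 * a_t / a_0``.

    ``a_t`` may be a scalar or array of absorbances at time t; ``a_0`` is the
    initial absorbance of the radical solution.  Values above 100% are legal
    (instrument noise on early points) and are deliberately not clamped.
    """
    if not np.isfinite(a_0):
        raise InvalidReferenceError(f"a_0 must be finite, got {a_0}")
    if a_0 <= 0:
        raise InvalidReferenceError(f"a_0 must be > 0, got {a_0}")
    a = np.asarray(a_t, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValidationError("a_t must be finite")
    if np.any(a < 0):
        raise ValidationError("a_t must be >= 0")
    out = 100.0 * a / a_0
    return float(out) if np.isscalar(a_t) else out


def trace_to_percent(trace: KineticTrace) -> np.ndarray:
    """Pointwise percent-remaining of a trace against its ``a0_reference``.

    Returns an array of shape (n, 2) with columns (time [s], R%).
    """
    pct = percent_remaining(trace.absorbance, trace.a0_reference)
    return np.column_stack([trace.times, pct])


def absorbance_to_concentration(a, cal: CalibrationCurve):
    """Invert the calibration line: ``x = (a - intercept) / slope``.

    May return negative values for absorbances below the intercept; clamping
    is left to the caller.
    """
    if cal.slope <= 0:
        raise InvalidCalibrationError(f"slope must be > 0, got {cal.slope}")
    out = (np.asarray(a, dtype=float) - cal.intercept) / cal.slope
    return float(out) if np.isscalar(a) else out


def concentration_to_absorbance(x, cal: CalibrationCurve):
    """Forward calibration line ``y = slope*x + intercept``."""
    out = cal.slope * np.asarray(x, dtype=float) + cal.intercept
    return float(out) if np.isscalar(x) else out


def fit_calibration(
    points: Iterable[tuple[float, float]], radical: Radical
) -> CalibrationCurve:
    """Ordinary least-squares calibration line from (concentration, AU) pairs.

    Requires at least 3 points with at least 2 distinct concentrations.
    ``r_squared`` is the coefficient of determination of the fit.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValidationError("need >= 3 (concentration, absorbance) points")
    x, y = pts[:, 0], pts[:, 1]
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("calibration points must be finite")
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all concentrations identical")
    # closed-form OLS; avoids linregress's NaN r-value on zero-variance y
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    slope = np.sum((x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (slope * x + intercept)
    tss = np.sum((y - ym) ** 2)
    r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 0.0
    return CalibrationCurve(radical, float(slope), float(intercept), float(np.clip(r2, 0.0, 1.0)))


def elemental_ratios(comp: ElementalComposition) -> ElementalRatios:
    """H/C and N/C ratios of a CHN composition, on mass and molar bases.

    The mass basis divides the raw percentages; the molar basis divides each
    percentage by the element's atomic mass first (H 1.008, C 12.011,
    N 14.007 g/mol).
    """
    if comp.pct_c <= 0:
        raise ValidationError(f"pct_c must be > 0, got {comp.pct_c}")
    mol_c = comp.pct_c / _ATOMIC_MASS["C"]
    mol_h = comp.pct_h / _ATOMIC_MASS["H"]
    mol_n = comp.pct_n / _ATOMIC_MASS["N"]
    return ElementalRatios(
        h_over_c_mass=comp.pct_h / comp.pct_c,
        n_over_c_mass=comp.pct_n / comp.pct_c,
        h_over_c_molar=mol_h / mol_c,
        n_over_c_molar=mol_n / mol_c,
    )


# ---------------------------------------------------------------------------
# File I/O: trace CSV + JSON sidecar, calibration JSON
# ---------------------------------------------------------------------------

def write_trace(trace: KineticTrace, csv_path: str | Path) -> Path:
    """Write a trace as ``time_s,absorbance`` CSV plus a ``.meta.json`` sidecar."""
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": trace.times, "absorbance": trace.absorbance}).to_csv(
        csv_path, index=False
    )
    meta = {
        "radical": trace.radical.value,
        "wavelength": trace.wavelength,
        "sample_id": trace.sample_id,
        "a0_reference": trace.a0_reference,
    }
    sidecar = csv_path.with_suffix(".meta.json")
    sidecar.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return csv_path


def read_trace(csv_path: str | Path) -> KineticTrace:
    """Read a trace CSV and its ``.meta.json`` sidecar."""
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    if not {"time_s", "absorbance"} <= set(df.columns):
        raise ValidationError(f"{csv_path} lacks time_s/absorbance columns")
    sidecar = csv_path.with_suffix(".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        raise ValidationError(f"missing metadata sidecar {sidecar}")
    return KineticTrace(
        times=df["time_s"].to_numpy(float),
        absorbance=df["absorbance"].to_numpy(float),
        radical=Radical(meta["radical"]),
        sample_id=meta.get("sample_id", csv_path.stem),
        a0_reference=meta.get("a0_reference"),
        wavelength=meta.get("wavelength"),
    )


def write_calibration(cal: CalibrationCurve, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "radical": cal.radical.value,
        "slope": cal.slope,
        "intercept": cal.intercept,
        "r_squared": cal.r_squared,
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_calibration(path: str | Path) -> CalibrationCurve:
    d = json.loads(Path(path).read_text())
    return CalibrationCurve(
        Radical(d["radical"]), d["slope"], d["intercept"], d.get("r_squared", 1.0)
    )
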