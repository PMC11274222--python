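"""Synthetic absorbance-time traces with known ground truth.

The real assay traces were never deposited, so every pipeline stage is
exercised on simulated data: a ground-truth kinetic law (multi-exponential
or second-order) evaluated on the assay's sampling grid (1000 s at 1 s
intervals) with additive homoscedastic Gaussian instrument noise.  The
default study layout reproduces the dilution scheme of the assay: two plant
sources (flower/fruit) x four dilution levels x two radicals = 16 cells,
with the antioxidant level proportional to the dilution level and flower
rate constants faster than fruit by one (DPPH) or three (galvinoxyl) orders
of magnitude — the qualitative structure the assay reported, encoded as
simulator defaults rather than asserted truths about the real infusions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .core import (
    A0_REFERENCE,
    ACRONYM_TAG,
    SOURCE_PREFIX,
    CalibrationCurve,
    KineticTrace,
    Radical,
    SampleSpec,
    Source,
    ValidationError,
    write_trace,
)
from .models import FOParams, SOParams, fo_model, so_model

__all__ = [
    "SimulationConfig",
    "StudyDesign",
    "SimulatedStudy",
    "simulate_trace",
    "simulate_study",
    "simulate_calibration",
]

#: Default additive instrument noise, typical UV-Vis repeatability [AU].
DEFAULT_NOISE_SIGMA = 0.005

#: Default second-order rate constants [1/(AU s)] per (source, radical).
#: Flower is 10x fruit for DPPH and 1000x for galvinoxyl; within flowers
#: galvinoxyl is quenched faster than DPPH, within fruits the reverse.
DEFAULT_K = {
    (Source.FLOWER, Radical.DPPH): 0.01,
    (Source.FRUIT, Radical.DPPH): 0.001,
    (Source.FLOWER, Radical.GLV): 0.03,
    (Source.FRUIT, Radical.GLV): 3.0e-5,
}

#: Default proportionality aah0 = coeff * dilution_level [AU per 1e-3 g/mL].
DEFAULT_AAH0_COEFF = {Source.FLOWER: 0.35, Source.FRUIT: 0.30}


@dataclass(frozen=True)
class SimulationConfig:
    """Ground truth, sampling grid and noise for one simulated trace."""

    truth_model: str  # "FO1" | "FO2" | "FO3" | "SO"
    truth_params: FOParams | SOParams
    duration: float = 1000.0
    dt: float = 1.0
    noise_sigma: float = DEFAULT_NOISE_SIGMA
    seed: int = 0
    radical: Radical = Radical.DPPH
    sample_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "radical", Radical(self.radical))
        if self.truth_model not in ("FO1", "FO2", "FO3", "SO"):
            raise ValidationError(f"unknown truth model {self.truth_model!r}")
        expected = SOParams if self.truth_model == "SO" else FOParams
        if not isinstance(self.truth_params, expected):
            raise ValidationError(
                f"{self.truth_model} truth requires {expected.__name__} parameters"
            )
        if self.duration <= 0 or self.dt <= 0 or self.duration / self.dt < 9:
            raise ValidationError("duration/dt must yield at least 10 points")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.duration / self.dt)) + 1
        return np.arange(n) * self.dt


@dataclass(frozen=True)
class StudyDesign:
    """Full-factorial simulated study mirroring the assay dilution scheme.

    16 cells: {flower, fruit} x {1.0, 1.5, 2.0, 2.5}e-3 g/mL x {DPPH, Glv}.
    Within each (source, radical) cell the ground-truth antioxidant level is
    proportional to the dilution level (``aah0 = coeff * level``), so more
    concentrated infusions quench more radical — the dose ordering the assay
    observed.
    """

    sources: tuple[Source, ...] = (Source.FLOWER, Source.FRUIT)
    dilution_levels: tuple[float, ...] = SampleSpec.DILUTION_LEVELS
    radicals: tuple[Radical, ...] = (Radical.DPPH, Radical.GLV)
    k_by_cell: Mapping[tuple[Source, Radical], float] = field(
        default_factory=lambda: dict(DEFAULT_K)
    )
    aah0_coeff: Mapping[Source, float] = field(
        default_factory=lambda: dict(DEFAULT_AAH0_COEFF)
    )
    duration: float = 1000.0
    dt: float = 1.0
    noise_sigma: float = DEFAULT_NOISE_SIGMA

    def cells(self) -> list[tuple[Source, Radical, float]]:
        return [
            (s, r, lvl)
            for s in self.sources
            for r in self.radicals
            for lvl in self.dilution_levels
        ]

    def truth_for(self, source: Source, radical: Radical, level: float) -> SOParams:
        return SOParams(
            k=self.k_by_cell[(source, radical)],
            ar0=A0_REFERENCE[radical],
            aah0=self.aah0_coeff[source] * level,
        )


@dataclass(frozen=True)
class SimulatedStudy:
    """Traces plus the ground-truth manifest needed for recovery scoring."""

    traces: tuple[KineticTrace, ...]
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        """Write trace CSVs + sidecars and ``manifest.json`` to a directory."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for trace in self.traces:
            write_trace(trace, out_dir / f"{trace.sample_id}.csv")
        manifest_path = out_dir / "manifest.json"
        manifest_path.write_text(json.dumps(self.manifest, indent=2, sort_keys=True) + "\n")
        return out_dir


def simulate_trace(cfg: SimulationConfig) -> KineticTrace:
    """Ground-truth model on the sampling grid plus seeded Gaussian noise.

    Deterministic for a fixed config and seed; with ``noise_sigma = 0`` the
    output equals the model evaluated on the grid exactly.
    """
    grid = cfg.grid
    if cfg.truth_model == "SO":
        clean = so_model(grid, cfg.truth_params)
    else:
        clean = fo_model(grid, cfg.truth_params)
    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        clean = clean + rng.normal(0.0, cfg.noise_sigma, size=grid.size)
    return KineticTrace(
        times=grid,
        absorbance=clean,
        radical=cfg.radical,
        sample_id=cfg.sample_id or f"SIM{cfg.radical.value}",
        a0_reference=A0_REFERENCE[cfg.radical],
    )


def simulate_study(design: StudyDesign, seed: int = 0) -> SimulatedStudy:
    """Simulate the full 2 x 4 x 2 study with second-order ground truth.

    Per-cell seeds are derived deterministically from ``seed``.  The
    manifest maps each sample acronym to its generating parameters.
    """
    traces: list[KineticTrace] = []
    manifest: dict = {}
    for i, (source, radical, level) in enumerate(design.cells()):
        truth = design.truth_for(source, radical, level)
        sample_id = f"{SOURCE_PREFIX[source]}{ACRONYM_TAG[radical]}{level:.1f}"
        cell_seed = (int(seed) * 10007 + i) % (2**31)
        cfg = SimulationConfig(
            truth_model="SO",
            truth_params=truth,
            duration=design.duration,
            dt=design.dt,
            noise_sigma=design.noise_sigma,
            seed=cell_seed,
            radical=radical,
            sample_id=sample_id,
        )
        traces.append(simulate_trace(cfg))
        manifest[sample_id] = {
            "model": "SO",
            "k": truth.k,
            "ar0": truth.ar0,
            "aah0": truth.aah0,
            "source": source.value,
            "radical": radical.value,
            "dilution_level": level,
            "noise_sigma": design.noise_sigma,
            "seed": cell_seed,
        }
    return SimulatedStudy(traces=tuple(traces), manifest=manifest)


def simulate_calibration(
    cal: CalibrationCurve,
    concentrations,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Noisy standard-series points on a calibration line (fixture generator)."""
    x = np.asarray(concentrations, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 concentrations")
    if noise_sigma < 0:
        raise ValidationError("noise_sigma must be >= 0")
    y = cal.slope * x + cal.intercept
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sigma, size=x.size)
    return list(zip(x.tolist(), y.tolist()))
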