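"""Synthetic GC-MS peak-area generator for the three experimental designs.

Stands in for the instrument: expected fiber concentrations come from the
equilibrium model, and a peak area is

    area = response_factor * C_f * exp(eps),   eps ~ Normal(0, sigma^2)

with ``sigma = sqrt(ln(1 + CV^2))`` so that the lognormal factor has exactly
the requested coefficient of variation.  Noise is independent per peak by
default; compounds measured from the same vial nevertheless share their
standard's area, as on a real chromatogram.  Everything is driven by one
seeded generator, so the same seed reproduces the run table bit for bit.

Three designs are supported:

* ``calibration_series`` — analytes spiked at 0-2 mg/L over nine levels,
  internal standards at 10 mg/L isolated in the ampoule (four-phase,
  short extraction);
* ``cd_dose_experiment`` — analytes at 1 mg/L with cyclodextrin doses in the
  sample and the standards safe in the ampoule;
* ``three_phase_cd_experiment`` — the conventional design with the standards
  co-dissolved in the sample, where the CD binds analyte and standard alike
  and the relative peak areas come out unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from math import log, sqrt
from typing import Mapping

import numpy as np
import pandas as pd

from .benchmark import CALIBRATION_LEVELS_MG_PER_L, retention_benchmark
from .core_model import (CDSpecies, CompoundParams, Spike, VialConfig,
                         solve_closed_system, solve_with_cd)
from .defaults import (ANALYTE_CONC_MG_PER_L, ISTD_CONC_MG_PER_L, default_cd,
                       default_compounds, default_vial, standard_for)
from .inference import fit_binding_constant
from .quantification import RUN_TABLE_COLUMNS
from .units import mass_conc_to_molar

__all__ = [
    "ExperimentDesign",
    "generate_peak_areas",
    "default_binding_constants",
    "lognormal_sigma",
]

DESIGN_KINDS = ("calibration_series", "cd_dose_experiment",
                "three_phase_cd_experiment")


def lognormal_sigma(cv: float) -> float:
    """Log-scale sigma giving a lognormal factor the coefficient of variation ``cv``."""
    if cv < 0:
        raise ValueError(f"CV must be >= 0, got {cv}")
    return sqrt(log(1.0 + cv * cv))


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of one simulated experiment.

    ``cv`` is the multiplicative noise level of a single peak area (e.g.
    0.03 for 3%); ``response_factor`` converts fiber concentration (mol/L)
    to counts and cancels out of every relative peak area.
    """

    kind: str
    levels_mg_per_L: tuple[float, ...] = CALIBRATION_LEVELS_MG_PER_L
    cds: tuple[str, ...] = ("alpha", "beta", "gamma")
    doses_g_per_L: tuple[float, ...] = (5.0, 25.0)
    analytes: tuple[str, ...] | None = None
    replicates: int = 3
    cv: float = 0.03
    response_factor: float = 1e8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in DESIGN_KINDS:
            raise ValueError(f"unknown design kind {self.kind!r}; "
                             f"expected one of {DESIGN_KINDS}")
        if self.replicates < 1:
            raise ValueError(f"replicates must be >= 1, got {self.replicates}")
        if self.cv < 0:
            raise ValueError(f"cv must be >= 0, got {self.cv}")
        if self.response_factor <= 0:
            raise ValueError("response_factor must be > 0")


def _analyte_names(design: ExperimentDesign,
                   compounds: Mapping[str, CompoundParams]) -> list[str]:
    if design.analytes is not None:
        unknown = [a for a in design.analytes if a not in compounds]
        if unknown:
            raise ValueError(f"unknown analytes {unknown}; "
                             f"known: {sorted(compounds)}")
        return list(design.analytes)
    if design.kind in ("calibration_series", "three_phase_cd_experiment"):
        # The compounds with their own labelled isotopologue: the calibration
        # and conventional three-phase assays cover only those, and the
        # three-phase null result (RPA unchanged by CD) requires the analyte
        # and its normalizing standard to share binding constants.
        return [p.isotopologue_of for p in compounds.values()
                if p.isotopologue_of is not None]
    return [n for n, p in compounds.items() if p.isotopologue_of is None]


def _noise(rng: np.random.Generator, sigma: float, n: int) -> np.ndarray:
    return np.exp(rng.normal(0.0, sigma, n)) if sigma > 0 else np.ones(n)


def _vial_rows(rng, design, vial_id, treatment, cd_name, dose, analytes,
               expected_cf: Mapping[str, float], replicate) -> list[dict]:
    sigma = lognormal_sigma(design.cv)
    names = list(expected_cf)
    areas = dict(zip(names, design.response_factor
                     * np.array([expected_cf[n] for n in names])
                     * _noise(rng, sigma, len(names))))
    rows = []
    for analyte in analytes:
        rows.append(dict(
            vial_id=vial_id, treatment=treatment, cd=cd_name,
            dose_g_per_L=dose, compound=analyte, replicate=replicate,
            area_analyte=areas[analyte],
            area_standard=areas[standard_for(analyte)],
        ))
    return rows


def generate_peak_areas(design: ExperimentDesign,
                        compounds: Mapping[str, CompoundParams] | None = None,
                        vial: VialConfig | None = None,
                        ) -> tuple[pd.DataFrame, dict]:
    """Simulate a run table for ``design``; returns (RunTable, metadata).

    ``compounds`` defaults to the bundled phenols with benchmark-derived
    binding constants (for CD designs) and must contain an internal standard
    for every analyte.  The metadata dictionary records the seed, the design,
    the solver mode, and the true binding constants used.
    """
    vial = vial or default_vial()
    if compounds is None:
        needs_kb = design.kind != "calibration_series"
        compounds = default_compounds(
            kb=default_binding_constants() if needs_kb else None)
    analytes = _analyte_names(design, compounds)
    istds = sorted({standard_for(a) for a in analytes})
    rng = np.random.default_rng(design.seed)
    rows: list[dict] = []

    if design.kind == "calibration_series":
        mode = "four_phase_short_extraction"
        istd_spikes = [
            Spike(compounds[i],
                  mass_conc_to_molar(ISTD_CONC_MG_PER_L, compounds[i].molar_mass),
                  phase="istd") for i in istds]
        for level in design.levels_mg_per_L:
            spikes = [Spike(compounds[a],
                            mass_conc_to_molar(level, compounds[a].molar_mass))
                      for a in analytes] + istd_spikes
            state = solve_closed_system(spikes, vial, mode)
            cf = {n: state.c_f(n) for n in state.table.index}
            for rep in range(1, design.replicates + 1):
                rows += _vial_rows(rng, design, f"cal-{level:g}-r{rep}",
                                   "calibration", None, 0.0, analytes, cf, rep)
                rows[-len(analytes):] = [dict(r, level_mg_per_L=level)
                                         for r in rows[-len(analytes):]]
    else:
        three_phase = design.kind == "three_phase_cd_experiment"
        mode = "three_phase" if three_phase else "four_phase_short_extraction"
        istd_phase = "sample" if three_phase else "istd"
        spikes = [Spike(compounds[a],
                        mass_conc_to_molar(ANALYTE_CONC_MG_PER_L,
                                           compounds[a].molar_mass))
                  for a in analytes] + [
            Spike(compounds[i],
                  mass_conc_to_molar(ISTD_CONC_MG_PER_L, compounds[i].molar_mass),
                  phase=istd_phase) for i in istds]
        treatments = [("control", None, 0.0)] + [
            (f"{cd}_{dose:g}", cd, dose)
            for cd in design.cds for dose in design.doses_g_per_L]
        for treatment, cd_name, dose in treatments:
            if cd_name is None:
                state = solve_closed_system(spikes, vial, mode)
            else:
                state = solve_with_cd(spikes, default_cd(cd_name, dose), vial, mode)
            cf = {n: state.c_f(n) for n in state.table.index}
            for rep in range(1, design.replicates + 1):
                rows += _vial_rows(rng, design, f"{treatment}-r{rep}", treatment,
                                   cd_name, dose, analytes, cf, rep)

    table = pd.DataFrame(rows)
    for col in RUN_TABLE_COLUMNS:
        if col not in table.columns:
            table[col] = None
    metadata = dict(
        seed=design.seed, kind=design.kind, mode=mode, cv=design.cv,
        replicates=design.replicates, response_factor=design.response_factor,
        analytes=analytes, internal_standards=istds,
        binding_constants={f"{n}:{cd}": k
                           for n, p in compounds.items()
                           for cd, k in dict(p.kb).items()},
        vial=dict(v_total=vial.v_total, v_sample=vial.v_sample,
                  v_istd=vial.v_istd, v_fiber=vial.v_fiber),
    )
    return table, metadata


@lru_cache(maxsize=1)
def _default_kb_cached() -> tuple[tuple[tuple[str, str], float], ...]:
    bench = retention_benchmark()
    rows = bench[(bench["dose_g_per_L"] == 25.0)]
    out = []
    for _, row in rows.iterrows():
        pct = float(row["percent_printed"])
        if pct >= 100.0:
            warnings.warn(
                f"{row['compound']}/{row['cd']}: benchmark retention {pct}% "
                ">= 100%; assigning K_b = 0", stacklevel=2)
            kb = 0.0
        else:
            kb = fit_binding_constant(pct, 25.0, row["compound"], row["cd"]).kb
        out.append(((row["compound"], row["cd"]), kb))
    return tuple(out)


def default_binding_constants() -> dict[tuple[str, str], float]:
    """Apparent K_b (L/mol) per (compound, CD), derived from the benchmark.

    Each constant is the unique value for which the four-phase model at
    25 g/L reproduces the bundled benchmark's printed percent-of-control;
    the derivation is a round-trip of :func:`cdspme.inference.fit_binding_constant`.
    """
    return dict(_default_kb_cached())
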