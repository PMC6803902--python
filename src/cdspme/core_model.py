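"""Multi-phase partition equilibria for headspace SPME with cyclodextrin binding.

The physical system is a sealed headspace vial containing up to four phases:

* the liquid sample (model wine spiked with volatile phenols), volume ``V_s``;
* the headspace gas, volume ``V_h``;
* the SPME fiber coating, volume ``V_f``;
* optionally a second liquid phase — a glass ampoule holding the internal
  standard solution — volume ``V_i``.

At equilibrium each compound distributes across the phases it can reach
according to dimensionless partition constants:

* ``K1 = C_s / C_h``  (sample liquid / gas),
* ``K2 = C_h / C_f``  (gas / fiber coating; small K2 means strong uptake),
* ``K3 = C_h / C_i``  (gas / ampoule liquid; for an ampoule matrix identical
  to the sample, K3 = 1/K1 so that C_i = C_s at equilibrium).

Mass conservation for a compound spiked into the sample at ``C_0`` reads

    C_0 V_s = C_s V_s + C_h V_h + C_f V_f            (three phases)
    C_0 V_s = C_s V_s + C_i V_i + C_h V_h + C_f V_f  (four phases)

Substituting the partition constants gives the closed form

    C_h = C_0 V_s / (K1 V_s + V_h + V_f / K2 [+ V_i / K3]).

Cyclodextrins (CDs) dissolved in the sample act as a non-volatile 1:1
host–guest sink: with free host concentration ``h``, a compound with binding
constant ``K_b`` (L/mol) carries an extra sample-phase term ``K1 V_s K_b h``
in the denominator, and the complexed concentration is ``C_x = K_b h C_s``.
The free host is the unique root of the host mass balance, found by bracketed
root-finding on [0, total host].

Three solver modes mirror the experimental designs:

* ``three_phase`` — the internal standard is co-dissolved with the sample
  (conventional HS-SPME): the two liquids are merged and the CD can bind the
  standard too.
* ``four_phase_equilibrium`` — all four phases fully equilibrate, including
  transfer between the two liquids through the gas phase.
* ``four_phase_short_extraction`` — the extraction is short enough that
  cross-liquid transfer is negligible (C_i V_i = 0 for sample compounds, and
  symmetrically C_s V_s = 0 for ampoule compounds); this is the working
  assumption of the four-phase method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .units import molar_mass_from_formula

__all__ = [
    "MODES",
    "CompoundParams",
    "VialConfig",
    "CDSpecies",
    "Spike",
    "EquilibriumState",
    "phase_ratio",
    "headspace_fraction",
    "solve_closed_system",
    "solve_with_cd",
]

MODES = ("three_phase", "four_phase_equilibrium", "four_phase_short_extraction")

#: Relative mass-balance tolerance guaranteed by the closed-form solvers.
CLOSED_FORM_RESIDUAL = 1e-12


@dataclass(frozen=True)
class CompoundParams:
    """Partition and binding parameters for one volatile compound.

    ``k1``/``k2``/``k3`` are the dimensionless partition constants defined in
    the module docstring; ``kb`` maps a cyclodextrin name to the 1:1 binding
    constant in L/mol.  ``k3=None`` resolves to ``1/k1`` (ampoule matrix
    identical to the sample matrix).  ``quant_ions`` is GC-MS metadata only.
    """

    name: str
    molar_mass: float
    k1: float
    k2: float = 1e-3
    k3: float | None = None
    kb: Mapping[str, float] = field(default_factory=dict)
    isotopologue_of: str | None = None
    quant_ions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be > 0")
        if self.k1 <= 0 or self.k2 <= 0:
            raise ValueError(f"{self.name}: K1 and K2 must be > 0")
        if self.k3 is not None and self.k3 <= 0:
            raise ValueError(f"{self.name}: K3 must be > 0 when given")
        for cd_name, value in dict(self.kb).items():
            if value < 0:
                raise ValueError(f"{self.name}: K_b for {cd_name!r} must be >= 0")

    @property
    def k3_resolved(self) -> float:
        return self.k3 if self.k3 is not None else 1.0 / self.k1

    def binding_constant(self, cd_name: str | None) -> float:
        if cd_name is None:
            return 0.0
        return float(dict(self.kb).get(cd_name, 0.0))

    def with_binding(self, cd_name: str, kb: float) -> "CompoundParams":
        new_kb = dict(self.kb)
        new_kb[cd_name] = kb
        return replace(self, kb=new_kb)

    @classmethod
    def from_formula(cls, name: str, formula: str, k1: float, **kwargs) -> "CompoundParams":
        return cls(name=name, molar_mass=molar_mass_from_formula(formula), k1=k1, **kwargs)

    @classmethod
    def isotopologue(cls, parent: "CompoundParams", name: str, molar_mass: float,
                     **overrides) -> "CompoundParams":
        """A labelled isotopologue inheriting the parent's K1/K2/K3/K_b."""
        base = dict(
            k1=parent.k1, k2=parent.k2, k3=parent.k3, kb=dict(parent.kb),
            isotopologue_of=parent.name,
        )
        base.update(overrides)
        return cls(name=name, molar_mass=molar_mass, **base)


@dataclass(frozen=True)
class VialConfig:
    """Geometry of the headspace vial in mL.

    The ampoule's glass wall volume is treated as zero; the headspace is
    whatever the sample and ampoule liquids leave free.
    """

    v_total: float = 20.0
    v_sample: float = 6.0
    v_istd: float = 0.5
    v_fiber: float = 6.6e-4

    def __post_init__(self) -> None:
        for label, v in (("v_total", self.v_total), ("v_sample", self.v_sample),
                         ("v_istd", self.v_istd), ("v_fiber", self.v_fiber)):
            if v < 0:
                raise ValueError(f"{label} must be >= 0, got {v}")
        if self.v_headspace <= 0:
            raise ValueError(
                f"headspace volume must be positive, got {self.v_headspace} mL "
                f"(v_total={self.v_total}, v_sample={self.v_sample}, v_istd={self.v_istd})"
            )

    @property
    def v_headspace(self) -> float:
        return self.v_total - self.v_sample - self.v_istd

    @property
    def beta_sample(self) -> float:
        return phase_ratio(self.v_headspace, self.v_sample)

    @property
    def beta_istd(self) -> float:
        return phase_ratio(self.v_headspace, self.v_istd)


@dataclass(frozen=True)
class CDSpecies:
    """A cyclodextrin dissolved in the sample phase at ``dose`` g/L."""

    name: str
    molar_mass: float
    dose: float

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise ValueError(f"{self.name}: molar_mass must be > 0")
        if self.dose < 0:
            raise ValueError(f"{self.name}: dose must be >= 0 g/L, got {self.dose}")

    @property
    def total_molar(self) -> float:
        """Total host concentration in mol/L of the CD-bearing liquid."""
        return self.dose / self.molar_mass


@dataclass(frozen=True)
class Spike:
    """A compound placed in one phase at an initial concentration (mol/L)."""

    params: CompoundParams
    c0: float
    phase: str = "sample"

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise ValueError(f"{self.params.name}: initial concentration must be >= 0")
        if self.phase not in ("sample", "istd"):
            raise ValueError(f"{self.params.name}: phase must be 'sample' or 'istd'")


@dataclass(frozen=True)
class EquilibriumState:
    """Equilibrium concentrations for every compound, plus the host balance.

    ``table`` is indexed by compound name with columns ``c0``,
    ``initial_phase``, ``c_s``, ``c_h``, ``c_i``, ``c_f``, ``c_x`` (all
    mol/L) and ``residual`` (relative mass-balance error).  ``free_host`` and
    ``total_host`` are mol/L in the CD-bearing liquid.
    """

    table: pd.DataFrame
    mode: str
    free_host: float = 0.0
    total_host: float = 0.0
    cd_name: str | None = None

    def __getitem__(self, compound: str) -> pd.Series:
        return self.table.loc[compound]

    def c_h(self, compound: str) -> float:
        return float(self.table.loc[compound, "c_h"])

    def c_f(self, compound: str) -> float:
        return float(self.table.loc[compound, "c_f"])

    @property
    def max_residual(self) -> float:
        return float(self.table["residual"].abs().max())


def phase_ratio(headspace_volume: float, liquid_volume: float) -> float:
    """Phase ratio β = V_headspace / V_liquid (dimensionless)."""
    if liquid_volume <= 0:
        raise ValueError(f"liquid volume must be > 0, got {liquid_volume}")
    if headspace_volume < 0:
        raise ValueError(f"headspace volume must be >= 0, got {headspace_volume}")
    return headspace_volume / liquid_volume


def headspace_fraction(c0: float, k: float, beta: float) -> float:
    """Equilibrium headspace concentration C_h = C_0 / (K + β).

    The two-phase (liquid/gas) limit: a compound at C_0 in a liquid with
    liquid/gas partition constant K under a headspace with phase ratio β.
    """
    if k < 0:
        raise ValueError(f"K must be >= 0, got {k}")
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    if k + beta == 0:
        raise ValueError("K + beta must be positive")
    return c0 / (k + beta)


def _phase_volumes(vial: VialConfig, mode: str) -> tuple[float, float]:
    """(effective sample volume, ampoule volume) for the given mode."""
    if mode == "three_phase":
        # ISTD co-dissolved: the two liquids are one phase.
        return vial.v_sample + vial.v_istd, 0.0
    return vial.v_sample, vial.v_istd


def _denominator(params: CompoundParams, spike_phase: str, vial: VialConfig,
                 mode: str, kb_h: float) -> tuple[float, bool, bool]:
    """Closed-form denominator and phase accessibility for one compound.

    Returns ``(D, sample_access, istd_access)`` where ``C_h = n0 / D`` and the
    booleans say whether the compound reaches the sample / ampoule liquid.
    """
    v_s, v_i = _phase_volumes(vial, mode)
    fiber = vial.v_fiber / params.k2
    if mode == "three_phase":
        return params.k1 * v_s * (1.0 + kb_h) + vial.v_headspace + fiber, True, False
    if mode == "four_phase_equilibrium":
        d = (params.k1 * v_s * (1.0 + kb_h) + vial.v_headspace + fiber
             + v_i / params.k3_resolved)
        return d, True, v_i > 0
    if mode == "four_phase_short_extraction":
        if spike_phase == "sample":
            return params.k1 * v_s * (1.0 + kb_h) + vial.v_headspace + fiber, True, False
        if v_i <= 0:
            raise ValueError(
                f"{params.name} is spiked into the ampoule but v_istd is 0")
        return v_i / params.k3_resolved + vial.v_headspace + fiber, False, True
    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def _assemble_state(spikes: Sequence[Spike], vial: VialConfig, mode: str,
                    cd: CDSpecies | None, h: float) -> EquilibriumState:
    v_s, v_i = _phase_volumes(vial, mode)
    rows = {}
    for spike in spikes:
        p = spike.params
        kb = p.binding_constant(cd.name) if cd is not None else 0.0
        v0 = v_s if (spike.phase == "sample" or mode == "three_phase") else v_i
        n0 = spike.c0 * v0
        d, sample_access, istd_access = _denominator(p, spike.phase, vial, mode, kb * h)
        c_h = n0 / d if d > 0 else 0.0
        c_s = p.k1 * c_h if sample_access else 0.0
        c_x = kb * h * c_s
        c_i = c_h / p.k3_resolved if istd_access else 0.0
        c_f = c_h / p.k2
        total = (c_s + c_x) * v_s + c_h * vial.v_headspace + c_i * v_i + c_f * vial.v_fiber
        residual = (n0 - total) / n0 if n0 > 0 else 0.0
        rows[p.name] = dict(
            c0=spike.c0, initial_phase=spike.phase, c_s=c_s, c_h=c_h,
            c_i=c_i, c_f=c_f, c_x=c_x, residual=residual,
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    return EquilibriumState(
        table=table, mode=mode, free_host=h,
        total_host=cd.total_molar if cd is not None else 0.0,
        cd_name=cd.name if cd is not None else None,
    )


def solve_closed_system(spikes: Sequence[Spike], vial: VialConfig,
                        mode: str = "four_phase_short_extraction") -> EquilibriumState:
    """Equilibrium distribution with no cyclodextrin present (linear closed form)."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    return _assemble_state(spikes, vial, mode, cd=None, h=0.0)


def solve_with_cd(spikes: Sequence[Spike], cd: CDSpecies, vial: VialConfig,
                  mode: str = "four_phase_short_extraction") -> EquilibriumState:
    """Equilibrium distribution with 1:1 cyclodextrin complexation in the sample.

    For a trial free-host concentration ``h`` every compound's distribution is
    the linear closed form with the extra sample-phase sink ``K_b h``; the
    host mass balance ``h + Σ K_b h C_s(h) = total host`` is strictly
    increasing in ``h``, so its root is found by bracketed root-finding on
    [0, total host] to machine precision.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    h_total = cd.total_molar
    if h_total == 0 or all(s.params.binding_constant(cd.name) == 0 for s in spikes):
        return _assemble_state(spikes, vial, mode, cd=cd, h=h_total)

    v_s, _ = _phase_volumes(vial, mode)

    def bound_host(h: float) -> float:
        total = 0.0
        for spike in spikes:
            p = spike.params
            kb = p.binding_constant(cd.name)
            if kb == 0:
                continue
            v0 = v_s if (spike.phase == "sample" or mode == "three_phase") else \
                vial.v_istd
            d, sample_access, _ = _denominator(p, spike.phase, vial, mode, kb * h)
            if not sample_access:
                continue
            c_h = spike.c0 * v0 / d
            total += kb * h * p.k1 * c_h
        return total

    def host_balance(h: float) -> float:
        return h + bound_host(h) - h_total

    # host_balance(0) = -h_total < 0 and host_balance(h_total) >= 0, so the
    # root is always bracketed.
    h = brentq(host_balance, 0.0, h_total, xtol=1e-300, rtol=4 * np.finfo(float).eps,
               maxiter=200)
    if not math.isfinite(h) or h < 0:
        raise RuntimeError(
            f"free-host solve failed: h={h}, total host={h_total} mol/L")
    return _assemble_state(spikes, vial, mode, cd=cd, h=h)
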