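"""Default compounds, cyclodextrins and vial geometry for the model-wine system.

Encodes the standard experimental setup: a 20-mL headspace vial with 6 mL of
model wine (12% v/v aqueous ethanol, 5 g/L tartaric acid, pH 3.5) spiked with
eight volatile phenols at 1 mg/L, a 2-mL glass ampoule holding 0.5 mL of
internal-standard solution (three deuterated isotopologues at 10 mg/L each),
and a SPME fiber sampling the headspace at 35 °C.

The liquid/gas partition constant defaults to the literature water/air value
for guaiacol at ambient temperature, K1 = 2.2e4, uniformly across phenols
(compound-specific constants are rarely tabulated for model wine and the
retention percentages are insensitive to K1 because the K1·V_s term dominates
the mass balance either way).  The gas/fiber constant K2 = 1e-3 (the fiber
coating enriches a thousand-fold over the gas phase) keeps fiber depletion of
the analyte below 0.001% of the total — quantification reads concentrations
off the fiber without perturbing the equilibrium.  Binding constants are not
part of these defaults; :func:`cdspme.synthetic_data.default_binding_constants`
derives them from the bundled benchmark.
"""

from __future__ import annotations

from .core_model import CDSpecies, CompoundParams, VialConfig
from .units import molar_mass_from_formula

__all__ = [
    "DEFAULT_K1",
    "DEFAULT_K2",
    "ISTD_CONC_MG_PER_L",
    "ANALYTE_CONC_MG_PER_L",
    "default_vial",
    "default_compounds",
    "default_cd",
    "CD_FORMULAS",
    "standard_for",
]

DEFAULT_K1 = 2.2e4
DEFAULT_K2 = 1e-3

#: Spiking levels of the standard retention experiment.
ANALYTE_CONC_MG_PER_L = 1.0
ISTD_CONC_MG_PER_L = 10.0

# name -> (formula, SIM ions; quantifier last)
_PHENOL_TABLE = {
    "guaiacol": ("C7H8O2", (109, 124)),
    "4-methylguaiacol": ("C8H10O2", (123, 138)),
    "4-ethylphenol": ("C8H10O", (77, 122)),
    "4-ethylguaiacol": ("C9H12O2", (122, 137, 152)),
    "o-cresol": ("C7H8O", (77, 90, 108)),
    "m-cresol": ("C7H8O", (79, 108)),
    "p-cresol": ("C7H8O", (77, 107)),
    "eugenol": ("C10H12O2", (149, 164)),
}

# labelled standard -> (parent, formula, SIM ions)
_ISTD_TABLE = {
    "d3-guaiacol": ("guaiacol", "C7H5D3O2", (109, 127)),
    "d3-4-methylguaiacol": ("4-methylguaiacol", "C8H7D3O2", (126, 141)),
    "d4-4-ethylphenol": ("4-ethylphenol", "C8H6D4O", (77, 126)),
}

CD_FORMULAS = {"alpha": "C36H60O30", "beta": "C42H70O35", "gamma": "C48H80O40"}


def default_vial() -> VialConfig:
    """20-mL vial, 6 mL sample, 0.5 mL ampoule, nominal 0.66 µL fiber coating."""
    return VialConfig(v_total=20.0, v_sample=6.0, v_istd=0.5, v_fiber=6.6e-4)


def default_compounds(kb: dict | None = None) -> dict[str, CompoundParams]:
    """The eight phenols plus three isotopologues, keyed by name.

    ``kb`` optionally maps ``(compound, cd_name) -> K_b`` (L/mol); analytes
    get their entries and isotopologues inherit the parent's, reflecting the
    assumption that deuteration does not change cavity affinity.
    """
    kb = kb or {}
    out: dict[str, CompoundParams] = {}
    for name, (formula, ions) in _PHENOL_TABLE.items():
        compound_kb = {cd: k for (c, cd), k in kb.items() if c == name}
        out[name] = CompoundParams.from_formula(
            name, formula, k1=DEFAULT_K1, k2=DEFAULT_K2, kb=compound_kb,
            quant_ions=ions)
    for name, (parent, formula, ions) in _ISTD_TABLE.items():
        out[name] = CompoundParams.isotopologue(
            out[parent], name, molar_mass_from_formula(formula), quant_ions=ions)
    return out


def default_cd(name: str, dose: float) -> CDSpecies:
    """An α/β/γ-cyclodextrin at ``dose`` g/L, molar mass from its formula."""
    if name not in CD_FORMULAS:
        raise ValueError(
            f"unknown cyclodextrin {name!r}; known: {sorted(CD_FORMULAS)}")
    return CDSpecies(name=name, molar_mass=molar_mass_from_formula(CD_FORMULAS[name]),
                     dose=dose)


def standard_for(compound: str) -> str:
    """The internal standard used to normalize ``compound``.

    Guaiacol, 4-methylguaiacol and 4-ethylphenol have their own labelled
    isotopologues; every other phenol is normalized against d3-guaiacol.
    """
    for istd, (parent, _, _) in _ISTD_TABLE.items():
        if parent == compound:
            return istd
    if compound in _PHENOL_TABLE:
        return "d3-guaiacol"
    raise ValueError(f"unknown compound {compound!r}; known: {sorted(_PHENOL_TABLE)}")
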