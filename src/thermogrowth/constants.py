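"""Physical constants and reference parameter values.

The reference values collected here are posterior means from a published
hierarchical fit of the thermodynamic growth model to a large literature
compilation of intrinsic growth rates (230 strains spanning all three
domains of life).  They serve two purposes: as defaults for the synthetic
data generator, so that simulated datasets resemble real compilations, and
as plug-in parameter values for the derived thermodynamic summaries.
"""

from __future__ import annotations

#: Gas constant, J/(K·mol).
R = 8.314

#: Universal protein-unfolding parameters shared by all strains
#: (per mol amino-acid residue; temperatures in K).
UNIVERSAL_REFERENCE = {
    "dH_star": 4874.0,   # enthalpy change at the enthalpy convergence temperature, J/mol-residue
    "dS_star": 17.0,     # entropy change at the entropy convergence temperature, J/(K·mol-residue)
    "T_H": 375.5,        # convergence temperature for enthalpy, K
    "T_S": 390.9,        # convergence temperature for entropy, K
}

#: Thermal-group mean parameters of the rate-limiting enzyme:
#: enthalpy of activation (J/mol), heat-capacity change on denaturation
#: (J/(K·mol-residue)), and number of amino-acid residues.
GROUP_REFERENCE = {
    "psychrophile":     {"dH_act": 48600.0, "dCp": 49.7, "n": 388.0},
    "mesophile":        {"dH_act": 75300.0, "dCp": 59.9, "n": 422.0},
    "ascomycota":       {"dH_act": 39700.0, "dCp": 61.7, "n": 340.0},
    "thermophile":      {"dH_act": 71300.0, "dCp": 71.4, "n": 180.0},
    "hyperthermophile": {"dH_act": 96000.0, "dCp": 96.9, "n": 101.0},
}

#: Canonical ordering of the five thermal groups, cold to hot.
GROUP_ORDER = [
    "psychrophile",
    "mesophile",
    "ascomycota",
    "thermophile",
    "hyperthermophile",
]

#: Coefficients (slope, intercept) of the linear map from the per-residue
#: heat-capacity change (J/(K·mol-residue)) to the average number of
#: non-polar hydrogen atoms per residue.  The relationship between
#: unfolding heat capacity and apolar hydration is taken as linear;
#: these defaults are calibrated against published derived values for the
#: five thermal groups and may be overridden in configuration.
NH_COEFFICIENTS = (0.08876705, -0.02705792)

#: Thermal-group classification thresholds on the stability temperature
#: T* (K): psychrophile/mesophile, mesophile/thermophile and
#: thermophile/hyperthermophile boundaries.  Ties go to the colder group.
THERMAL_THRESHOLDS = (285.0, 300.0, 316.0)
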