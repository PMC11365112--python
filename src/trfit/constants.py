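"""Per-peptide scenario constants for the W-viscosin study system.

Two provenance classes are distinguished throughout:

``"table"``
    Quantities taken from the published per-peptide fit table of the study
    system (fixed dissociation constant Kd in uM, limiting anisotropies in
    buffer and membrane, limiting relaxation levels in buffer and membrane).

``"invented"``
    Quantities the study does not tabulate (fluorescence lifetimes and
    amplitudes, relaxation pre-exponential C, spectral band width, rotational
    parameters, quenching constants). These are plausible defaults chosen once
    for the synthetic generator and flagged so that downstream provenance
    maps can distinguish anchored from assumed values.
"""

from __future__ import annotations

# Published per-peptide endpoint values.
# Kd in uM; r_inf dimensionless; nu_inf in cm^-1 (table prints 10^3 cm^-1).
TABLE_ENDPOINTS: dict[str, dict[str, float]] = {
    "L1W": {"Kd": 23.0, "r_inf_aq": 0.019, "r_inf_m": 0.061,
            "nu_inf_aq": 28640.0, "nu_inf_m": 29170.0},
    "L5W": {"Kd": 17.0, "r_inf_aq": 0.005, "r_inf_m": 0.070,
            "nu_inf_aq": 28450.0, "nu_inf_m": 28900.0},
    "L7W": {"Kd": 18.0, "r_inf_aq": 0.010, "r_inf_m": 0.086,
            "nu_inf_aq": 28440.0, "nu_inf_m": 29210.0},
    "V4W": {"Kd": 23.0, "r_inf_aq": 0.005, "r_inf_m": 0.080,
            "nu_inf_aq": 28700.0, "nu_inf_m": 29590.0},
}

# Peptides handled by the generator that have no tabulated endpoint row:
# the non-fluorogenic parent lipopeptide and the water-exposed Trp reference.
EXTRA_PEPTIDES: dict[str, dict[str, float]] = {
    "viscosin": {"Kd": 20.0, "r_inf_aq": 0.010, "r_inf_m": 0.070,
                 "nu_inf_aq": 28500.0, "nu_inf_m": 29200.0},
    "NATA": {"Kd": 20.0, "r_inf_aq": 0.000, "r_inf_m": 0.000,
             "nu_inf_aq": 28300.0, "nu_inf_m": 28300.0},
}

# Invented generator defaults shared by all peptides.
INVENTED_DEFAULTS: dict[str, object] = {
    # Tri-exponential Trp decay (ns); amplitudes relative.
    "lifetimes": (0.6, 1.8, 4.5),
    "amplitudes": (0.3, 0.4, 0.3),
    # Anisotropy decay: amplitude B, rotational correlation time phi (ns).
    "B_aq": 0.15, "phi_aq": 0.35,
    "B_m": 0.12, "phi_m": 1.5,
    "G": 1.1,
    # Dipolar relaxation: detectable amplitude C (cm^-1) and relaxation
    # times (ns) in buffer and in the membrane.
    "C_aq": 800.0, "t_relax_aq": 1.0,
    "C_m": 500.0, "t_relax_m": 2.0,
    # Gaussian emission-band width (cm^-1 std. dev.; FWHM ~ 3.3e3 cm^-1).
    "spectral_width_sigma": 1400.0,
    # Apparent collisional quenching constant (ns^-1 M^-1 scale).
    "kq": 2.0,
    # Two-fraction ("water recruitment") relaxation defaults.
    "hetero_fraction": 0.0,
    "t_relax_slow": 10.0,
}

# Peptide-specific overrides of the invented defaults: the deeply inserted
# Trp4 relaxes on the ~10 ns water-recruitment timescale in the membrane.
INVENTED_OVERRIDES: dict[str, dict[str, object]] = {
    "V4W": {"t_relax_m": 10.0, "hetero_fraction": 0.5, "t_relax_slow": 10.0,
            "C_m": 1200.0},
}

PEPTIDE_IDS = tuple(TABLE_ENDPOINTS) + tuple(EXTRA_PEPTIDES)
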