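"""Shared numerical constants.

All LP feasibility checks, flux-inclusion cutoffs and stoichiometric
residual tests in the package use the single tolerance below so that
"numerically zero" means the same thing everywhere.
"""

#: LP feasibility / optimality tolerance and nonzero-flux reporting cutoff.
FLUX_TOLERANCE: float = 1e-6

#: Default magnitude for unconstrained flux bounds (mmol·gDW⁻¹·h⁻¹).
DEFAULT_BOUND: float = 1000.0

#: Default maximal uptake rate assigned to media metabolites when a media
#: file lists metabolite ids without rates (mmol·gDW⁻¹·h⁻¹).
DEFAULT_UPTAKE: float = 10.0

#: Reserved id of the growth objective reaction.
BIOMASS_ID: str = "biomass"
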