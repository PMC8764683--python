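"""Validating the equilibrium solution with patch-scale dynamics.

Simulates logistic growth on sub-cell patches hit by Poisson trawl events
and compares long-run mean abundance with the closed-form equilibrium
evaluated at the converted cell-scale recovery R = r d / (-ln(1 - d)).
"""

from benthicstatus import dynamics
from benthicstatus.core import grid_recovery_from_gear_scale

table = dynamics.equilibrium_vs_simulation(
    d_values=[0.05, 0.1, 0.2, 0.3],
    F_values=[0.25, 0.5, 1.0, 2.0],
    r=0.5,
    n_patches=20,
    years=200.0,
    seed=1234,
)
print(table.round(4).to_string(index=False))
print(f"\nmax |simulated - analytic| = {table['abs_error'].max():.4f}")

# implied cell-scale recovery from the simulated equilibria
sub = table[table.d == 0.2]
R_hat = dynamics.estimate_effective_R(
    sub["F"].to_numpy(), sub["simulated"].to_numpy(), d=0.2
)
print(
    f"implied R at d=0.2: {R_hat:.4f} vs conversion formula "
    f"{grid_recovery_from_gear_scale(0.5, 0.2):.4f}"
)
print(
    "\nAgreement confirms that the equilibrium model with the gear-to-grid\n"
    "recovery conversion reproduces explicit patch dynamics under random\n"
    "within-cell trawl placement."
)
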