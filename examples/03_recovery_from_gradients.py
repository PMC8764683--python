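"""Recovery rates estimated from synthetic trawling-gradient studies.

Fits the through-origin mixed model of log10 relative abundance on the
depletion-weighted intensity dF, with sediment fractions modifying the
slope, then converts the slope to an annual recovery rate of the
untrawled community via R = dF0 / (1 - 10^(b dF0)) at dF0 -> 0.
"""

from benthicstatus import recovery, synth
from benthicstatus.habitat import default_depletion_table

d_table = default_depletion_table()
spec = synth.SynthStudySpec(seed=4)
records = synth.gen_gradient_studies(spec, d_table)
print(f"{len(records)} records from {records['study_id'].nunique()} gradient studies")

slope = recovery.fit_gradient_model(records, d_table)
b_mid = slope.slope_at(1 / 3, 1 / 3, 1 / 3)
print(f"fitted slope at the simplex centroid: b = {b_mid:.3f}")
print(
    f"  each unit of dF decreases abundance by "
    f"{100 * recovery.percent_decrease_per_unit_dF(b_mid):.1f}%"
)

print("\nrecovery rate R (/y) along the gravel -> mud gradient:")
print("  composition        fitted (lcl)      true")
for label, comp in [
    ("pure gravel", (1.0, 0.0, 0.0)),
    ("pure sand  ", (0.0, 1.0, 0.0)),
    ("pure mud   ", (0.0, 0.0, 1.0)),
]:
    r_mean, r_lcl, _ = recovery.recovery_with_cls(slope, *comp)
    r_true = recovery.recovery_from_slope(spec.true_slope.slope_at(*comp))
    print(f"  {label}   {r_mean:.3f} ({r_lcl:.3f})     {r_true:.3f}")
print(
    "\nSlower recovery in gravel reflects the longer-lived communities of\n"
    "stable coarse sediments; the lower confidence limit is the\n"
    "precautionary rate used for the status lower band."
)
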