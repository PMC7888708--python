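"""Birth-length vs extension (BL/E) analysis: diagnose the size-control mode.

The BL/E slope is -1 for a perfect sizer (all deviation corrected in one
cycle), 0 for an adder (fixed increment), positive for a timer under
exponential growth. Fits are on raw records; 0.5-µm cohorts are for display.
"""

from sizehom import (
    adder_preset,
    fit_ble,
    simulate_lineages,
    sizer_preset,
    timer_preset,
)

for preset, seed in [(sizer_preset, 4), (adder_preset, 5), (timer_preset, 6)]:
    records = simulate_lineages(preset(n_founders=130, seed=seed))
    fit = fit_ble(records)
    print(
        f"{fit.strain:10s} n={fit.n:4d}  slope={fit.slope:+.3f} "
        f"(SE {fit.slope_se:.3f})  R²={fit.r_squared:.2f}  -> {fit.mode_label}"
    )

# Cohort table of the last fit (timer): mean extension per 0.5 µm birth bin.
print("\ntimer cohorts (display aid):")
print(fit.cohorts.query("n >= 10").round(2).to_string(index=False))
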