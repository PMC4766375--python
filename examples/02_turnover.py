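"""From a proliferation-label count to a population-turnover estimate.

19 of 1000 microglia double-positive after a 1-day label pulse gives a
proliferation index of 1.9%/day; accumulated linearly over 4 weeks this
means ~53% of the population proliferates — and if total numbers are
stable, an equal fraction must die (compensatory turnover).
"""

from plaquesholl import summarize_turnover

summary = summarize_turnover(
    n_double_positive=19,
    n_total=1000,
    label_window_days=1.0,
    extrapolation_days=28.0,
    population_fold_change=1.0,  # stable population over the 4 weeks
)
print(f"proliferation index      : {summary.pi:.1%} per day")
print(f"cumulative over 28 days  : {summary.cumulative_fraction:.0%}"
      f"{' (capped)' if summary.cumulative_capped else ''}")
print(f"implied death fraction   : {summary.implied_death_fraction:.0%}")
print("\nWith a stable population, every birth must be balanced by a death:")
print("the same 53% of the starting population is lost over the window.")
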