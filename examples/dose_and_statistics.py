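"""UV radiant-exposure arithmetic and control-normalized group comparison.

Converts the photoaging exposure schedule (0.45 mW/cm² UVA, 2 h daily, one
week) into daily and cumulative radiant exposure, then compares a mock
treated group against controls the way volumetric metrics are compared:
normalize every sample to the control mean, two-tailed t-test.
"""

import numpy as np

import skinquant as sq

dose = sq.radiant_exposure(sq.ExposureSchedule(
    irradiance_mw_cm2=0.45, hours_per_day=2.0, days=7,
    irradiance_tolerance_mw_cm2=0.15,
))
print(f"daily dose : {dose.daily_j_cm2:.2f} J/cm^2")
print(f"total dose : {dose.total_j_cm2:.2f} J/cm^2 over 7 days")
lo, hi = dose.daily_interval_j_cm2
print(f"meter tolerance band: {lo:.2f}-{hi:.2f} J/cm^2 per day")

# mock per-sample integrated-intensity readouts (arbitrary units)
rng = np.random.default_rng(0)
control = rng.normal(100.0, 10.0, 6)
treated = rng.normal(52.0, 9.0, 6)  # ~50% adiposity loss

norm_treated = sq.normalize_to_control(treated, control)
res = sq.compare_groups(sq.normalize_to_control(control, control), norm_treated)
print(f"\ntreated / control fold change: {norm_treated.mean():.2f}")
print(f"t = {res.statistic:.2f}, p = {res.p_value:.2e} {res.significance}")
print("fold change < 1 with p below 0.05 marks a significant loss vs. control")
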