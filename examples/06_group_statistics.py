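"""The statistics hygiene layer: outliers, normality gating, aggregation.

Values more than 3 interquartile ranges outside [Q1, Q3] are removed, each
group is Kolmogorov-Smirnov-tested for normality at alpha 0.05, and the
test family (parametric vs rank-based) is chosen accordingly. Cell-level
tables can be averaged up to session or animal level first.
"""

import numpy as np
import pandas as pd

from hippotune import aggregate, choose_and_run_test, remove_extreme_outliers

rng = np.random.default_rng(2)

values = np.r_[rng.normal(1.0, 0.3, 50), [25.0, np.nan]]
kept, n_removed = remove_extreme_outliers(values)
print(f"outlier removal: kept {len(kept)} of {np.isfinite(values).sum()} "
      f"finite values, removed {n_removed} beyond the 3-IQR fence")

gaussian = [rng.normal(0, 1, 80), rng.normal(0.6, 1, 80)]
rep = choose_and_run_test(gaussian, variable="si_familiar_vs_novel")
print(f"gaussian groups -> {rep.test_used}: stat {rep.statistic:.2f}, "
      f"p {rep.p_value:.1e} (normality p {min(rep.normality_p):.2f})")

skewed = [rng.lognormal(0, 1.5, 80), rng.lognormal(0.4, 1.5, 80)]
rep = choose_and_run_test(skewed, variable="transient_rate")
print(f"skewed groups   -> {rep.test_used}: stat {rep.statistic:.2f}, "
      f"p {rep.p_value:.1e} (normality gate routed to ranks)")

cells = pd.DataFrame({
    "session_id": np.repeat([f"s{i}" for i in range(4)], 5),
    "animal_id": np.repeat(["m1", "m1", "m2", "m2"], 5),
    "value": rng.normal(1.0, 0.5, 20),
})
by_session = aggregate(cells, "session")
print(f"aggregation: {len(cells)} cells -> {len(by_session)} sessions "
      f"(group sizes {by_session['n'].tolist()}); session means become the "
      "units for downstream tests")
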