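"""Split-plot ANOVA and Duncan letters on a simulated genotype trial.

A balanced 3-block x 3-environment x 8-genotype trial of ISVAD of grain
area is simulated with a real genotype effect; the split-plot ANOVA tests
environment against the main-plot (block x environment) error and genotype
against the residual, then Duncan's multiple range test letters the
environment means.
"""

import itertools

import numpy as np
import pandas as pd

from spikegrain import anova_split_plot, dmrt

rng = np.random.default_rng(3)
env_effect = {"C": 0.3, "D": 0.0, "L": -0.1}
rows = []
for b, (e, ee), g in itertools.product(
        range(3), env_effect.items(), range(8)):
    rows.append(dict(block=f"b{b}", environment=e, genotype=f"g{g}",
                    value=2.9 + ee + 0.15 * g + rng.normal(0, 0.15)))
table = pd.DataFrame(rows)

anova = anova_split_plot(table)
print(anova.round(4))

res = dmrt(table.groupby("environment")["value"].mean().to_dict(),
           n_per_group=24, mse=anova.at["main_plot_error", "MS"],
           df_error=int(anova.at["main_plot_error", "df"]))
print("\nenvironment means with Duncan letters (p < 0.05):")
for name, row in res.groups.iterrows():
    print(f"  {name}: {row['mean']:.3f} {row['letters']}")
# environments sharing no letter differ significantly in mean ISVAD.
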