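"""Percent change under stress and the heat susceptibility index.

Works directly from trait means: the published circularity/roundness means
under control, terminal drought and late sowing reproduce the printed
percent decreases, and HSI compares a genotype's relative loss with the
trial-wide depression.
"""

from spikegrain import (heat_susceptibility_index, mean_depression,
                        percent_change, round_half_up)

means = {  # trait -> (control, drought, late-sown)
    "circularity": (0.72, 0.69, 0.71),
    "roundness": (0.48, 0.44, 0.45),
}
for trait, (c, d, l) in means.items():
    print(f"{trait}: -{round_half_up(percent_change(c, d))}% under drought, "
          f"-{round_half_up(percent_change(c, l))}% under late sowing")
# expected: circularity -4.2% / -1.4%, roundness -8.3% / -6.3%

# HSI of single-grain weight for two hypothetical genotypes
depression = mean_depression(stress_means=[0.039], control_means=[0.045])
stable = heat_susceptibility_index(0.037, 0.038, depression)
sensitive = heat_susceptibility_index(0.025, 0.051, depression)
print(f"trial depression D = {depression:.3f}")
print(f"HSI stable genotype    = {stable:.2f}  (< 1: better than average)")
print(f"HSI sensitive genotype = {sensitive:.2f}  (> 1: worse than average)")
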