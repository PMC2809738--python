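"""Train one reduced network and measure its whisker-direction map.

Trains a sheet on half-plane stimuli at the headline noise level
(kappa = 3), measures the feed-forward direction map, scores every
supra-barrel against the somatotopic pinwheel template, and writes the map
as CSV and PNG next to this script.
"""

import numpy as np

import barrelmap as bm
from barrelmap.analysis import map_to_csv, plot_direction_map
from barrelmap.experiments import classify_fractions, train_network

arch = bm.Architecture(supra_size=13)
net = train_network(
    bm.StimulusConfig(kappa=3.0), arch, seed=7, n_patterns=1500,
)
dmap = net.maps[1500]
scores = bm.score_all_supra_barrels(dmap)
fractions = classify_fractions(scores)

print(f"supra-barrels scored          : {fractions['n']}")
print(f"counter-clockwise (somatotopic): {fractions['ccw_somatotopic']:.2f}")
print(f"clockwise (inverted)           : {fractions['cw_inverted']:.2f}")
print(f"not pinwheels                  : {fractions['non_pinwheel']:.2f}")
corrs = [s.corr for s in scores if s is not None]
print(f"mean |pinwheelness|            : {np.mean(np.abs(corrs)):.3f}")
print("Each supra-barrel map is compared to the ideal atan2 pinwheel; "
      "|r| above the classification threshold (0.33) counts as a pinwheel, "
      "and positive r means somatotopically correct rotation.")

map_to_csv(dmap, "direction_map.csv")
plot_direction_map(dmap, path="direction_map.png")
print("wrote direction_map.csv and direction_map.png "
      "(hue = preferred direction, saturation = selectivity)")
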