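# barrelmap

Self-organization of whisker deflection-direction maps in rat barrel cortex.

Rat primary somatosensory cortex contains one "barrel" per large facial
whisker, and tetrode recordings have shown that the layer-2/3 territory above
a barrel (the *supra-barrel*) holds a pinwheel map of the direction in which
that whisker is deflected, aligned with the layout of the surrounding
barrels: deflecting whisker A toward neighbouring whisker B most strongly
activates the part of supra-barrel A nearest supra-barrel B. `barrelmap`
implements a LISSOM-style self-organizing model of how such somatotopically
aligned pinwheels can develop from tactile experience alone, for
computational neuroscientists studying input-driven cortical map formation.

The model: a tactile stimulus is a half plane sweeping a 5x5 whisker grid;
swept whiskers are deflected in directions drawn from a Von Mises
distribution centred on the stimulus movement direction θ_s with
concentration κ, so κ controls how strongly the *combination* of deflected
whiskers predicts each whisker's deflection *direction*. Each whisker drives
a barrel of 25 units with fixed, randomly assigned preferred directions
(rectified-cosine tuning). A recurrent cortical sheet (one supra-barrel of
neurons per whisker) computes afferent drive s_j = Σ_u χ_u A_uj, settles for
9 steps through η_j = σ(s_j + γ_E Σ E_kj η_k − γ_I Σ I_kj η_k) with a
piecewise-linear σ, and then updates afferent and lateral-inhibitory weights
by Hebbian learning with divisive normalization,
w'_kj = (w_kj + α η_k η_j) / Σ_field (w + α η η). Maps are read out
feed-forward and scored per supra-barrel by the Fisher–Lee angular-angular
correlation against the ideal pinwheel template atan2(y, x) ("pinwheelness").

## A worked example

```python
import barrelmap as bm
from barrelmap.experiments import train_network, classify_fractions

arch = bm.Architecture(supra_size=13)          # 65x65 sheet, reduced scale
net  = train_network(bm.StimulusConfig(kappa=3.0), arch,
                     seed=7, n_patterns=1500)
scores = bm.score_all_supra_barrels(net.maps[1500])
print(classify_fractions(scores))
```

Running `python examples/03_train_and_map.py` (the same computation plus map
export) prints:

```
supra-barrels scored          : 25
counter-clockwise (somatotopic): 0.04
clockwise (inverted)           : 0.00
not pinwheels                  : 0.96
mean |pinwheelness|            : 0.080
wrote direction_map.csv and direction_map.png (hue = preferred direction, saturation = selectivity)
```

`ccw_somatotopic` is the fraction of the 25 supra-barrels whose map
correlates with the somatotopic pinwheel template above the classification
threshold 0.33 with counter-clockwise (correct) rotation; `cw_inverted`
counts inverted pinwheels; `pinwheel_any` counts both. Single short runs
like this one are noisy: somatotopic alignment emerges slowly and, in this
implementation, pinwheel fractions saturate well below the fractions the
modelled experiments aim for — see the known-limitations discussion in
`docs/methods.md` for the analysis of why (the positional resolution of the
flat lateral-inhibition window limits how precisely activity bubbles track
the stimulus boundary within a supra-barrel). The `examples/`
directory holds one short script per capability: stimulus statistics,
leading-edge migration of activity bubbles, training and map measurement,
condition campaigns, and the simulated whisker-trimming and
anti-correlated-whisker experiments. Long campaigns can also be run from the
shell: `barrelmap run --condition kappa_sweep --scale reduced --seed 42
--out out/`.

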