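# irtuning

Analysis toolkit for the functional evolution of olfactory **Ionotropic
receptors (Irs)** — the acid-sensing chemoreceptors of drosophilid antennal
coeloconic sensilla. It is written for sensory neuroscientists and molecular
evolutionists who record odor-evoked spikes from single sensilla (or express
receptor variants in a decoder neuron) and want to trace how amino-acid
substitutions reshaped a receptor's odor tuning.

The pipeline has four quantitative stages:

1. **Spike quantification.** The response of a sensillum to a 500 ms odor
   pulse is `2 × (N_stim − N_base)` spikes/s, where `N_stim` counts spikes in
   a 500 ms window starting at odor delivery (valve opening + 200 ms air-path
   delay) and `N_base` counts a 500 ms window 2 s earlier. Responses are
   solvent-corrected per sensillum, then either max-normalized or z-scored
   across the odor panel (C1–C6, the linear carboxylic acids with 1–6
   carbons).
2. **Tuning space.** PCA of the z-scored tuning profiles. PC1 captures the
   C2 ↔ C4 trade-off that separates acetic-acid sensors from butyric-acid
   sensors; its projection is the scalar phenotype
   `s_i = (x_i − x̄) · w₁`, oriented so larger values mean more C4-tuned.
3. **Ancestral phenotypes.** Fitch small parsimony (with Hartigan's
   multifurcation generalization) on a rooted species tree with C2/C4 tip
   states: the minimum number of tuning switches and one optimal ancestral
   labeling.
4. **Evolutionary landscape.** Between two alleles differing at *n* sites,
   all 2ⁿ genotypes and *n*! mutation-addition paths are enumerated. Each
   hypercube edge is tested for a significant increase in mean PC1
   (Shapiro-gated Welch-t / Wilcoxon, Bonferroni-corrected); each
   single+single and single+double mutation pair is tested for **epistasis**
   with a bootstrap additivity null: 1000 sums of randomly drawn
   per-sensillum effects of the two groups, recentered on the initial
   genotype's mean, compared with the observed combined genotype by Wilcoxon
   rank-sum.

A seeded synthetic-data module generates Poisson spike trains, full-hypercube
response panels with programmable additive effects and interaction terms, and
the ten-species fixture phylogeny, so every stage is testable end to end with
known ground truth.

## Worked example

Simulate a three-substitution landscape (T289S, Q536K, F538L — the pocket
substitutions that convert a C2 sensor into a C4 sensor) and analyze it:

```sh
irtuning simulate  --out sim  --seed 42
irtuning landscape --table sim/panel.csv --mutations T289S,Q536K,F538L \
                   --out land --seed 42 --phenotype odor:C4
irtuning parsimony --out pars.json
```

which logs

```
INFO irtuning: wrote sim/panel.csv (80 rows)            # 8 genotypes × 10 sensilla
INFO irtuning: 12/12 solid steps, 0 epistatic pair(s)
INFO irtuning: minimum number of tuning switches: 2
```

All 12 hypercube edges are "solid" (each substitution significantly raises
the C4 response, so every one of the 3! = 6 mutational paths is accessible),
and no pair is called epistatic — correct, because the default simulation is
purely additive in spikes/s. `land/landscape_genotypes.csv` holds the
per-genotype phenotype means ± SEM, e.g.

```
genotype,n,pc1_mean,pc1_sem
F538L,10,35.54724051963666,1.3534781406736258
Q536K,10,29.75246223096405,0.7810718600838766
"Q536K,F538L",10,53.15929425382863,1.2975945419890942
```

The parsimony stage reports that the ten-species tuning pattern (C2 sensors:
D. melanogaster, simulans, yakuba, erecta, ananassae, pseudoobscura; C4
sensors: D. sechellia, willistoni, mojavensis, virilis) requires a minimum of
**two** tuning switches — a C4→C2 gain on the branch to the
melanogaster/obscura-group ancestor and a C2→C4 reversion on the
D. sechellia branch — so the ancestral drosophilid receptor is reconstructed
as a C4 sensor.

Note on phenotype modes: `--phenotype pc1` (the default) scores each
sensillum by the PC1 projection of its *z-scored* profile, the standard
readout for real recordings. Because per-row z-scoring is nonlinear, effects
that are additive in spikes/s are not additive on that scale; use
`--phenotype odor:C4` or `pc1_raw` when additivity in firing rate is the
question (see `docs/methods.md`).

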