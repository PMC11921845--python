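# clpnet

Cross-lagged panel networks for symptom-level comorbidity analysis.

`clpnet` is for researchers who study how the symptoms of two co-occurring
disorders — the canonical case being posttraumatic stress and depression in
trauma-exposed children and adolescents — drive each other over time. Given
two waves of item-level ordinal scores (0–3) on the two instruments, the
package estimates a **directed symptom network**, quantifies which symptoms
**bridge** the two disorders, checks how **stable** those conclusions are
under resampling, finds the **communities** the symptoms actually form
(rather than the ones the diagnostic manual assigns), and measures how well
all of this **replicates** across independent samples.

## The model

For each item $j$, the wave-2 score is regressed on *all* $p$ wave-1 scores
with a LASSO penalty chosen per node by 10-fold cross-validation:

$$ y^{(2)}_j = \textstyle\sum_i a_{ij}\, y^{(1)}_i + \varepsilon_j . $$

The coefficient matrix $A$ is the cross-lagged panel network (CLPN):
$a_{jj}$ is the autoregressive self-loop, $a_{ij}$ the directed cross-lagged
edge $i \to j$ controlling for every other wave-1 symptom. On top of the
fitted network the package computes expected influence
$\mathrm{EI}(j) = \sum_{i \ne j} (a_{ij} + a_{ji})$, its restriction to
cross-disorder edges (bridge expected influence, BEI), and flags **bridge
symptoms** as nodes whose z-scored BEI exceeds 1 in every sample. Stability
comes from a nonparametric edge bootstrap (percentile CIs) and the
case-dropping correlation-stability (CS) coefficient; communities come from
bootstrapped exploratory graph analysis (EBIC graphical lasso + walktrap);
replicability metrics compare edge lists, replicated-edge counts, and
centralities between samples. Because raw clinical panels are rarely
shareable, a first-class synthetic-data module generates two-wave ordinal
panels from a known directed ground truth so every stage is testable end to
end. See `docs/methods.md` for the full model account.

## Worked example

```python
import clpnet

catalog = clpnet.default_catalog()          # 33 items: 15 PTSD + 18 depression
truth = clpnet.make_ground_truth(catalog, seed=7)
panels = [
    clpnet.simulate_panel(truth, clpnet.SimulationConfig(n=n, seed=s))
    for n, s in ((600, 1), (400, 2))        # two samples, one shared truth
]
nets = [
    clpnet.CrossLaggedPanelModel.from_panel(ds, communities=truth.communities).fit(seed=0)
    for ds in panels
]
print(nets[0].summary())
tables = [clpnet.centrality_table(net) for net in nets]
print(tables[0].sort_values("BEI_z", ascending=False).head(3).round(2))
print("bridge symptoms:", clpnet.identify_bridges(tables))
print(clpnet.compare_networks(nets[0], nets[1]).summary())
```

prints

```
Cross-lagged panel network
==========================
nodes:                 33
penalty rule:          cv (10-fold CV, seed 0)
autoregressive edges:  31 (mean 0.089)
cross-lagged nonzero:  280 of 1056 (mean 0.024)

      EI   BEI  BEI_z  bridge
C2  1.29  1.00   2.40    True
C5  1.13  0.86   1.92    True
C1  0.95  0.78   1.65    True

bridge symptoms: ['C1', 'C2', 'C5', 'C6', 'D5']

Network replicability
=====================
edge-list Pearson r:     0.423 [0.373, 0.472], t = 15.17 (m = 1056 edge pairs)
replicated edges:        104 same-sign (122 by presence)
  share of network A:    0.371 (of 280 nonzero)
  share of network B:    0.344 (of 302 nonzero)
BEI Pearson r:           0.859 [0.732, 0.929]
top-3 BEI overlap:       1/3 (A: ['C2', 'C5', 'C1'], B: ['C6', 'C2', 'D5'])
```

Reading this: the self-loops dominate the cross-lagged edges (means 0.089
vs 0.024 on the standardized scale), as they should in a two-wave panel.
Five of the six dysphoria items designated as bridges in the generating
truth (C1 *loss of interest*, C2 *future foreshortening*, C5 *memory
difficulty*, C6 *detachment*, D5 *irritable behavior*) clear the
normalized-BEI > 1 bar in **both** samples at these modest sample sizes.
Edge-by-edge agreement between the two samples is moderate (r = 0.42; 104
edges replicate with matching sign) while the bridge-centrality profile
replicates well (BEI r = 0.86) — global structure travels across samples
more reliably than individual edges, and both improve with n.

The same analysis runs from the shell:

```bash
clpnet init-config -o config.yaml   # edit sample sizes, B, seeds ...
clpnet all -c config.yaml -o run/   # simulate -> ... -> compare, cached stages
```

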