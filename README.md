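# paleodiv

Lineage diversity and dental topographic disparity through time, for
fossil-inclusive macroevolutionary analysis.

Paleogene mammal faunas — for instance the endemic rodents and primates of
Afro-Arabia — are known mostly from dated fossil teeth placed on time-scaled
phylogenies. `paleodiv` provides the full chain of analyses such a dataset
supports:

* **Lineage-through-time (LTT) with fossil tips.** On a time-scaled tree the
  number of lineages at age *t* is the number of edges whose interval contains
  *t*; fossil terminals make the curve drop, exposing extinction pulses. Peak
  to trough loss is `(max N in peak window − min N in trough window) / max N`.
* **A tip-age-preserving null.** Random rooted binary labeled topologies with
  the observed tip ages and root age, with internal-node ages drawn uniformly
  subject to age validity. The null distribution of percent lineage loss says
  how much loss the tip-age spectrum forces *regardless* of phylogenetic
  structure.
* **Dental topographic metrics (DTMs)** on triangulated crown meshes in
  occlusal orientation:
  * relief index `RFI = ln(√A₃D / √A₂D)` (3-D crown area over 2-D outline area),
  * orientation patch count rotated (`OPCR`): mean over eight 5.625°
    rotations of the number of edge-connected, ≥3-face patches sharing one of
    eight normal-azimuth bins,
  * `ariaDNE`: robust Dirichlet normal energy (Gaussian-weighted local PCA,
    bandwidth ε = 0.1 on the unit-area mesh).
* **Morphospace.** Species-mean `{ariaDNE, ln OPCR, RFI}` → correlation-matrix
  PCA; PC1–PC2 is the working morphospace.
* **Multi-regime multivariate Brownian motion.** Clades are painted onto the
  tree; every set partition of the clade tags is a candidate model (4 clades →
  15 paintings; × 3 rate-matrix constraints for bivariate data → 45 versions).
  Likelihoods come from Gaussian pruning with the root profiled out; models
  are compared by AICc (n = tips), and ancestral states are GLS conditional
  expectations under the winning model(s).
* **Time-slice disparity.** Linear interpolation of node values where edges
  cross a 0.5 Myr age grid yields an edge × slice table; per slice the PC1–PC2
  cloud is summarized by SoV (sum of variances), SoR (sum of ranges), SR2DHA
  (√ of convex-hull area), MST (minimum-spanning-tree length), centroids and
  centroid paths; per-clade SR2DHA/MST series can be summed (sumSR2DHA,
  sumMST).
* **A synthetic-data generator** (fossilized birth–death trees with
  programmable extinction pulses, per-regime BM traits with known truth, and
  parametric tooth crowns with controllable cusp number/relief/sharpness) so
  every stage is testable without external data.

## Worked example

```python
import paleodiv as pv

cfg = pv.SimulationConfig(seed=2, pulse_age=33.0, pulse_fraction=0.6,
                          min_tips=200, max_tips=450)
tree = pv.simulate_fbd_tree(cfg, max_retries=2000)
observed = pv.percent_lineage_loss(pv.ltt_continuous(tree))

ens = pv.build_null_ensemble(tree.tip_ages(), tree.root_age,
                             n_trees=200, seed=0, keep_trees=False)
null = pv.null_loss_distribution(ens)
print(f"observed {100*observed:.1f}% vs null mean {100*null['mean']:.1f}%")
```

prints (from `examples/ltt_and_null.py`):

```
simulated tree: 364 tips, 264 fossil, root 76.16 Ma
observed peak-to-trough loss: 75.0%
null (tip ages preserved, topology random): mean 12.4%, 97.5% quantile 17.0%
```

The simulated tree carries a programmed extinction pulse at 33 Ma, so its
peak-to-trough loss far exceeds anything the tip-age spectrum alone produces:
extinction signal, not sampling artifact. The other scripts in `examples/`
walk through the dental metrics, regime model selection, disparity series,
and the resumable pipeline driver (`run_pipeline` / the `paleodiv` CLI).

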