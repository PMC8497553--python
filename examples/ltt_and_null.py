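"""Lineage diversity through time, and how much loss a random tree requires.

Simulates a fossil birth-death tree with an extinction pulse at 33 Ma, plots
its lineage-through-time curve against a tip-age-preserving null ensemble,
and prints the observed vs null peak-to-trough lineage loss.
"""

import paleodiv as pv

cfg = pv.SimulationConfig(seed=2, pulse_age=33.0, pulse_fraction=0.6, min_tips=200, max_tips=450)
tree = pv.simulate_fbd_tree(cfg, max_retries=2000)
print(f"simulated tree: {tree.n_tips} tips, {len(tree.fossil_tips())} fossil, "
      f"root {tree.root_age:.2f} Ma")

series = pv.ltt_continuous(tree)
observed = pv.percent_lineage_loss(series)  # default: late-Eocene peak vs Oligocene trough windows

ens = pv.build_null_ensemble(tree.tip_ages(), tree.root_age, n_trees=200, seed=0, keep_trees=False)
null = pv.null_loss_distribution(ens)

print(f"observed peak-to-trough loss: {100 * observed:.1f}%")
print(f"null (tip ages preserved, topology random): mean {100 * null['mean']:.1f}%, "
      f"97.5% quantile {100 * null['quantiles'][0.975]:.1f}%")
print("-> a loss far above the null quantile cannot be a sampling artifact; it reflects")
print("   the tree's phylogenetic structure (few ghost lineages spanning the gap).")
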