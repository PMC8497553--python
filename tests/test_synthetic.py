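"""Generators: FBD trees, BM traits, parametric tooth crowns."""

import numpy as np
import pytest

from paleodiv import (
    RegimePainting,
    SimulationConfig,
    generate_tooth_mesh,
    simulate_bm_traits,
    simulate_fbd_tree,
    tag_clades,
)


def test_pure_birth_all_tips_extant():
    cfg = SimulationConfig(seed=0, birth_rate=0.1, death_rate=0.0, fossil_rate=0.0, root_age=30.0)
    tree = simulate_fbd_tree(cfg)
    assert len(tree.fossil_tips()) == 0
    assert all(nd.age == 0.0 for nd in tree.tips())
    assert tree.root_age == 30.0


def test_fossil_count_tracks_poisson_expectation():
    """Observed fossil-tip count scales with recovery rate (Poisson thinning).

    With death but no recovery no fossils appear; doubling the recovery rate
    roughly doubles sampled extinct terminals over replicates.
    """
    def mean_fossils(psi, n=60):
        tot = 0
        for s in range(n):
            cfg = SimulationConfig(
                seed=s, birth_rate=0.15, death_rate=0.1, fossil_rate=psi, root_age=40.0
            )
            tot += len(simulate_fbd_tree(cfg, max_retries=3000).fossil_tips())
        return tot / n

    assert mean_fossils(0.0) == 0.0
    lo, hi = mean_fossils(0.05), mean_fossils(0.2)
    assert hi > 2 * lo > 0


def test_pulse_removes_crossing_lineages():
    cfg = SimulationConfig(
        seed=3, pulse_age=20.0, pulse_fraction=1.0, pulse_fossilization=1.0,
        birth_rate=0.15, death_rate=0.05, fossil_rate=0.05, root_age=40.0, min_tips=10,
    )
    tree = simulate_fbd_tree(cfg, max_retries=3000)
    # no edge spans the pulse: every lineage alive at 20 Ma was killed there
    for pid, cid in tree.edges():
        assert not (tree.nodes[pid].age > 20.0 > tree.nodes[cid].age + 1e-12)
    assert len(tree.extant_tips()) == 0 or all(
        tree.nodes[pid].age <= 20.0 for pid, cid in tree.edges() if tree.nodes[cid].age == 0
    )


def test_seeded_tree_determinism():
    cfg = SimulationConfig(seed=12, min_tips=5)
    assert simulate_fbd_tree(cfg).to_newick() == simulate_fbd_tree(cfg).to_newick()


def test_tag_clades_partitions_tips():
    tree = simulate_fbd_tree(SimulationConfig(seed=5, min_tips=40, max_tips=200), max_retries=2000)
    tag_clades(tree, ["w", "x", "y", "z"])
    tip_tags = [tree.clade_tags.get(nd.id) for nd in tree.tips()]
    assert None not in tip_tags
    assert set(tip_tags) == {"w", "x", "y", "z"}


# ---------------------------------------------------------------------------
# BM traits


def _tagged_tree(seed=1):
    tree = simulate_fbd_tree(SimulationConfig(seed=seed, min_tips=30, max_tips=200), max_retries=2000)
    return tag_clades(tree, ["a", "b"])


def test_zero_rate_keeps_root_state():
    tree = _tagged_tree()
    painting = RegimePainting(groups=(frozenset(["a", "b"]),))
    vals = simulate_bm_traits(tree, painting, [np.array([[0.0]])], [3.14], seed=0)
    assert np.allclose(vals.to_numpy(), 3.14)


def test_non_psd_rate_rejected():
    tree = _tagged_tree()
    painting = RegimePainting(groups=(frozenset(["a", "b"]),))
    with pytest.raises(ValueError, match="semi-definite"):
        simulate_bm_traits(tree, painting, [np.array([[1.0, 2.0], [2.0, 1.0]])], [0.0, 0.0])


def test_tip_variance_grows_linearly_with_depth():
    """BM variance law: Var(tip - root) = rate * depth."""
    tree = _tagged_tree(seed=9)
    painting = RegimePainting(groups=(frozenset(["a", "b"]),))
    rate = 0.07
    tips = tree.tips()
    depths = np.array([tree.root_age - nd.age for nd in tips])
    sq = np.zeros(len(tips))
    n_rep = 150
    for r in range(n_rep):
        vals = simulate_bm_traits(tree, painting, [np.array([[rate]])], [0.0], seed=r)
        y = vals.loc[[nd.id for nd in tips], "trait1"].to_numpy()
        sq += y**2
    emp_var = sq / n_rep
    slope = np.linalg.lstsq(depths[:, None], emp_var, rcond=None)[0][0]
    assert slope == pytest.approx(rate, rel=0.15)


def test_sister_tips_covary_more_than_distant_tips():
    tree = _tagged_tree(seed=2)
    painting = RegimePainting(groups=(frozenset(["a", "b"]),))
    # find a cherry and a cross-clade pair
    cherry = None
    for nd in tree.nodes:
        if nd.children and all(tree.nodes[c].is_tip for c in nd.children):
            cherry = nd.children
            break
    tips = tree.tips()
    left = tree.subtree_tip_ids(tree.nodes[tree.root].children[0])
    right = tree.subtree_tip_ids(tree.nodes[tree.root].children[1])
    far_pair = (left[0], right[0])
    prod_near, prod_far = 0.0, 0.0
    n_rep = 200
    for r in range(n_rep):
        vals = simulate_bm_traits(tree, painting, [np.array([[0.05]])], [0.0], seed=1000 + r)
        prod_near += vals.loc[cherry[0], "trait1"] * vals.loc[cherry[1], "trait1"]
        prod_far += vals.loc[far_pair[0], "trait1"] * vals.loc[far_pair[1], "trait1"]
    assert prod_near / n_rep > prod_far / n_rep


# ---------------------------------------------------------------------------
# tooth meshes


def test_flat_disc_has_zero_relief():
    from paleodiv.dtm import compute_rfi

    disc = generate_tooth_mesh(n_cusps=0, relief=0.0, face_count=1000)
    assert compute_rfi(disc) == pytest.approx(0.0, abs=1e-9)


def test_mesh_face_budget_respected():
    for target in (600, 2000, 8000):
        mesh = generate_tooth_mesh(n_cusps=4, relief=1.0, face_count=target)
        assert abs(len(mesh.faces) - target) / target < 0.35


def test_mesh_determinism_without_noise():
    a = generate_tooth_mesh(n_cusps=4, relief=1.0, seed=1, face_count=800)
    b = generate_tooth_mesh(n_cusps=4, relief=1.0, seed=99, face_count=800)
    assert np.array_equal(a.vertices, b.vertices)
    assert np.array_equal(a.faces, b.faces)


def test_mesh_noise_is_seeded():
    a = generate_tooth_mesh(n_cusps=4, relief=1.0, noise_sd=0.01, seed=1, face_count=800)
    b = generate_tooth_mesh(n_cusps=4, relief=1.0, noise_sd=0.01, seed=1, face_count=800)
    c = generate_tooth_mesh(n_cusps=4, relief=1.0, noise_sd=0.01, seed=2, face_count=800)
    assert np.array_equal(a.vertices, b.vertices)
    assert not np.array_equal(a.vertices, c.vertices)


def test_metric_orderings_across_parameter_sweep():
    """Rank correlations across the synthetic crown family: OPCR tracks cusp
    count, RFI tracks relief, ariaDNE tracks sharpness (each monotone over a
    5-level sweep)."""
    from scipy.stats import spearmanr

    from paleodiv.dtm import compute_ariadne, compute_opcr, compute_rfi

    cusps = [1, 2, 3, 4, 5]
    opcr = [compute_opcr(generate_tooth_mesh(n_cusps=k, relief=1.2, face_count=1500)) for k in cusps]
    assert spearmanr(cusps, opcr).statistic == pytest.approx(1.0)

    reliefs = [0.2, 0.6, 1.0, 1.5, 2.0]
    rfi = [compute_rfi(generate_tooth_mesh(n_cusps=4, relief=h, face_count=1500)) for h in reliefs]
    assert spearmanr(reliefs, rfi).statistic == pytest.approx(1.0)

    sharps = [0.6, 0.9, 1.2, 1.6, 2.0]
    dne = [
        compute_ariadne(generate_tooth_mesh(n_cusps=4, relief=1.2, sharpness=s, face_count=1500))
        for s in sharps
    ]
    assert spearmanr(sharps, dne).statistic == pytest.approx(1.0)
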