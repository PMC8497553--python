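"""Multi-regime BM fitting, AICc selection, and ancestral reconstruction."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import paleodiv.bm_asr as ba
from paleodiv import (
    RegimePainting,
    SimulationConfig,
    enumerate_regime_paintings,
    estimate_ancestral_states,
    fit_mvbm,
    parse_tree,
    select_model,
    simulate_bm_traits,
    simulate_fbd_tree,
    tag_clades,
)


def single_regime(*tags):
    return RegimePainting(groups=(frozenset(tags or ["a"]),))


def dense_profiled_loglik(tree, traits, rates, painting):
    """Independent oracle: explicit (n*p x n*p) covariance + scipy MVN."""
    regimes = ba.edge_regimes(tree, painting)
    tips = tree.tips()
    Y = traits.loc[[nd.label for nd in tips]].to_numpy(dtype=float)
    p = Y.shape[1]
    V = ba.dense_tip_covariance(tree, rates, regimes)
    X = np.kron(np.ones((len(tips), 1)), np.eye(p))
    Vi = np.linalg.inv(V)
    root = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ Y.ravel())
    return multivariate_normal.logpdf(Y.ravel(), mean=X @ root, cov=V), root


# ---------------------------------------------------------------------------
# painting enumeration


def test_painting_counts_for_four_clades():
    clades = ["anomaluroid", "anthropoid", "hystricognath", "strepsirrhine"]
    paintings = enumerate_regime_paintings(clades)
    assert len(paintings) == 15
    by_size = {k: sum(p.n_regimes == k for p in paintings) for k in range(1, 5)}
    assert by_size == {1: 1, 2: 7, 3: 6, 4: 1}
    # crossed with the three bivariate constraints: 45 versions
    assert len(paintings) * 3 == 45


def test_single_clade_single_painting():
    paintings = enumerate_regime_paintings(["a"])
    assert len(paintings) == 1
    assert paintings[0].n_regimes == 1


def test_untagged_edges_map_to_regime_zero():
    p = RegimePainting(groups=(frozenset(["a"]), frozenset(["b"])))
    assert p.regime_of(None) == 0
    assert p.regime_of("b") == 1
    with pytest.raises(KeyError):
        p.regime_of("zzz")


# ---------------------------------------------------------------------------
# likelihood


def test_star_tree_closed_form_mle():
    """Single regime, single trait, star-like tree with equal tip depths:
    the MLE root is the tip mean and the rate the mean squared deviation
    over depth."""
    # balanced tree with all internal nodes at the root age minus epsilon is
    # numerically a star; build an exact 4-tip balanced tree of depth T and
    # tiny internal stems
    T, eps = 10.0, 1e-6
    nwk = f"((A:{T - eps},B:{T - eps}):{eps},(C:{T - eps},D:{T - eps}):{eps});"
    tree = parse_tree(nwk, root_age=T)
    y = pd.DataFrame({"trait1": [1.0, 3.0, 2.0, 6.0]}, index=list("ABCD"))
    fit = fit_mvbm(tree, y, single_regime(), "equal", n_restarts=2, seed=0)
    ybar = y.trait1.mean()
    sigma2 = np.mean((y.trait1 - ybar) ** 2) / T
    assert fit.root_state[0] == pytest.approx(ybar, abs=1e-3)
    assert fit.rates[0][0, 0] == pytest.approx(sigma2, rel=1e-2)


@pytest.mark.parametrize("p,constraint", [(1, "equal"), (2, "unconstrained"), (2, "diagonal"), (2, "equal")])
def test_pruning_equals_dense_oracle(fossil_trees, p, constraint):
    """Pruning log-likelihood equals the dense-covariance MVN oracle on all
    small fixture trees, for 1- and 2-regime paintings."""
    rng = np.random.default_rng(0)
    small = [t for t in fossil_trees if t.n_tips <= 8] or [fossil_trees[0].prune_to(
        [nd.label for nd in fossil_trees[0].tips()[:6]])]
    for tree in small:
        tag_clades(tree, ["a", "b"])
        for painting in enumerate_regime_paintings(["a", "b"]):
            if constraint == "unconstrained" and p == 2:
                rates = []
                for _ in range(painting.n_regimes):
                    L = np.array([[0.6, 0.0], [rng.uniform(-0.3, 0.3), 0.4]])
                    rates.append(L @ L.T)
            elif p == 2:
                rates = [np.diag(rng.uniform(0.1, 1.0, size=2)) for _ in range(painting.n_regimes)]
            else:
                rates = [np.array([[rng.uniform(0.05, 0.5)]]) for _ in range(painting.n_regimes)]
            traits = simulate_bm_traits(tree, painting, rates, np.zeros(p), seed=1)
            tips = tree.tips()
            Y = traits.loc[[nd.id for nd in tips]].to_numpy()
            tip_rows = {nd.id: i for i, nd in enumerate(tips)}
            regimes = ba.edge_regimes(tree, painting)
            ll, root = ba._prune_loglik(tree, Y, tip_rows, rates, regimes)
            tdf = traits.loc[[nd.id for nd in tips]]
            tdf.index = [nd.label for nd in tips]
            oracle_ll, oracle_root = dense_profiled_loglik(tree, tdf, rates, painting)
            assert abs(ll - oracle_ll) < 1e-6
            assert root == pytest.approx(oracle_root, abs=1e-8)


def test_parameter_counts_and_aicc():
    tree = parse_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);", root_age=2)
    tag_clades(tree, ["a", "b"])
    y = pd.DataFrame(
        {"t1": [0.1, 0.4, -0.2, 0.8], "t2": [1.0, 0.2, 0.5, -0.1]}, index=list("ABCD")
    )
    p = single_regime("a", "b")
    k_unc = fit_mvbm(tree, y, p, "unconstrained", seed=0).k
    k_diag = fit_mvbm(tree, y, p, "diagonal", seed=0).k
    k_eq = fit_mvbm(tree, y, p, "equal", seed=0).k
    assert k_unc == 3 + 2 and k_diag == 2 + 2 and k_eq == 1 + 2
    assert k_eq < k_unc


def test_aicc_approaches_aic_for_large_n():
    # 2k(k+1)/(n-k-1) -> 0 as n -> infinity
    k = 5
    small = ba._aicc(-100.0, k, 30)
    huge = ba._aicc(-100.0, k, 10**6)
    aic = -2 * -100.0 + 2 * k
    assert abs(huge - aic) < 1e-3
    assert small > huge


# ---------------------------------------------------------------------------
# selection


def test_select_single_candidate_returns_itself():
    tree = parse_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);", root_age=2)
    y = pd.DataFrame({"t": [0.0, 1.0, 0.5, 0.2]}, index=list("ABCD"))
    fit = fit_mvbm(tree, y, single_regime(), "equal", seed=0)
    sel = select_model([fit])
    assert sel.best is fit and sel.near_ties == [fit]


def test_equal_loglik_ties_favor_fewer_parameters():
    a = ba.BMModelFit(single_regime(), "equal", [np.eye(1)], np.zeros(1), -10.0, 2,
                      ba._aicc(-10.0, 2, 50), 50, ["t"])
    b = ba.BMModelFit(single_regime(), "unconstrained", [np.eye(1)], np.zeros(1), -10.0, 5,
                      ba._aicc(-10.0, 5, 50), 50, ["t"])
    assert select_model([b, a]).best is a


def test_two_regime_recovery_under_rate_contrast():
    """10x rate contrast between two painted clades: AICc should prefer the
    generating 2-regime painting in most seeded replicates."""
    wins = 0
    n_seeds = 8
    for seed in range(n_seeds):
        tree = simulate_fbd_tree(
            SimulationConfig(seed=300 + seed, min_tips=80, max_tips=170), max_retries=2000
        )
        tag_clades(tree, ["a", "b"])
        paintings = enumerate_regime_paintings(["a", "b"])
        gen = [p for p in paintings if p.n_regimes == 2][0]
        vals = simulate_bm_traits(tree, gen, [np.array([[0.01]]), np.array([[0.1]])], [0.0], seed=seed)
        tips = tree.tips()
        Y = vals.loc[[nd.id for nd in tips]]
        Y.index = [nd.label for nd in tips]
        fits = [fit_mvbm(tree, Y, p, "equal", n_restarts=2, seed=seed) for p in paintings]
        wins += select_model(fits).best.painting.n_regimes == 2
    assert wins >= int(0.8 * n_seeds)


# ---------------------------------------------------------------------------
# ancestral states


def test_identical_tip_values_reconstruct_everywhere():
    tree = parse_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);", root_age=2)
    y = pd.DataFrame({"t": [2.5] * 4}, index=list("ABCD"))
    fit = fit_mvbm(tree, y, single_regime(), "equal", seed=0)
    asr = estimate_ancestral_states(tree, y, fit)
    assert np.allclose(asr.estimates.to_numpy(), 2.5, atol=1e-4)


def test_symmetric_two_tip_root_is_midpoint():
    tree = parse_tree("(A:5,B:5);", root_age=5)
    y = pd.DataFrame({"t": [1.0, 3.0]}, index=["A", "B"])
    fit = fit_mvbm(tree, y, single_regime(), "equal", seed=0)
    asr = estimate_ancestral_states(tree, y, fit)
    assert asr.estimates.loc[tree.root, "t"] == pytest.approx(2.0, abs=1e-6)
    assert asr.estimates.loc[tree.root, "t"] == pytest.approx(fit.root_state[0], abs=1e-9)


def test_asr_recovery_on_simulated_bm():
    tree = simulate_fbd_tree(
        SimulationConfig(seed=7, min_tips=190, max_tips=260), max_retries=2000
    )
    tag_clades(tree, ["a", "b"])
    p1 = single_regime("a", "b")
    vals = simulate_bm_traits(tree, p1, [np.array([[0.04]])], [0.0], seed=3)
    tips = tree.tips()
    Y = vals.loc[[nd.id for nd in tips]]
    Y.index = [nd.label for nd in tips]
    fit = fit_mvbm(tree, Y, p1, "equal", seed=0)
    asr = estimate_ancestral_states(tree, Y, fit)
    truth = vals.loc[asr.estimates.index].to_numpy().ravel()
    est = asr.estimates.to_numpy().ravel()
    assert np.corrcoef(truth, est)[0, 1] > 0.8
    slope = np.polyfit(truth, est, 1)[0]
    assert 0.8 <= slope <= 1.2


def test_asr_averages_over_near_tied_models():
    tree = parse_tree("((A:1,B:1):1,(C:1.5,D:1.5):0.5);", root_age=2)
    tag_clades(tree, ["a", "b"])
    y = pd.DataFrame({"t": [0.3, 0.9, -0.2, 0.6]}, index=list("ABCD"))
    fits = [
        fit_mvbm(tree, y, p, "equal", seed=0)
        for p in enumerate_regime_paintings(["a", "b"])
    ]
    single = estimate_ancestral_states(tree, y, fits[0]).estimates
    averaged = estimate_ancestral_states(tree, y, fits).estimates
    manual = np.mean(
        [estimate_ancestral_states(tree, y, f).estimates.to_numpy() for f in fits], axis=0
    )
    assert averaged.to_numpy() == pytest.approx(manual)
    assert averaged.shape == single.shape
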