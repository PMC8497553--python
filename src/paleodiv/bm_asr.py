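"""Multi-regime multivariate Brownian motion: fitting, AICc selection, ASR.

Model
-----
Traits evolve along the time-scaled tree as (multivariate) Brownian motion.
Each edge belongs to a *regime* r with its own rate matrix ``R_r`` (trait
variance per Myr, covariance where the constraint allows), so the covariance
between two tips is the per-regime shared path length from the root weighted
by the regime rate matrices.  Regimes are painted onto edges through clade
tags; the model space is the set of all partitions of the clade tags
(4 clades -> 15 paintings), optionally crossed with three rate-matrix
constraints for bivariate data:

* ``unconstrained`` — full symmetric PSD rate matrix per regime;
* ``diagonal``      — independent per-trait rates, no covariance;
* ``equal``         — one shared rate for all traits, no covariance.

The likelihood is computed by Gaussian belief propagation over the tree
(pruning), with the root state profiled out analytically; the root MLE is the
GLS estimate.  Model choice uses AICc with ``n`` = number of tips.  Ancestral
states are the conditional expectations of internal-node values given the
tips under the fitted Gaussian model (a GLS reconstruction), averaged over
the replicate-selected models when replicates disagree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .tree import TimeScaledTree

__all__ = [
    "RegimePainting",
    "enumerate_regime_paintings",
    "CONSTRAINTS",
    "BMModelFit",
    "fit_mvbm",
    "select_model",
    "repeat_model_selection",
    "ASRResult",
    "estimate_ancestral_states",
]

CONSTRAINTS = ("unconstrained", "diagonal", "equal")

_LOG2PI = np.log(2.0 * np.pi)


# ---------------------------------------------------------------------------
# regime paintings


@dataclass(frozen=True)
class RegimePainting:
    """Partition of clade tags into rate regimes.

    ``groups[i]`` is the set of clade tags sharing regime ``i``.  Edges whose
    clade tag is missing (stem/backbone branches) are assigned regime 0 —
    a documented default, since a BM fit needs a total painting while clade
    tags only cover the named clades.
    """

    groups: tuple[frozenset, ...]

    @property
    def n_regimes(self) -> int:
        return len(self.groups)

    def regime_of(self, tag: Optional[str]) -> int:
        if tag is None:
            return 0
        for i, g in enumerate(self.groups):
            if tag in g:
                return i
        raise KeyError(f"clade tag {tag!r} not covered by painting {self}")

    def __str__(self) -> str:
        return " | ".join("+".join(sorted(g)) for g in self.groups)


def enumerate_regime_paintings(clades: Sequence[str]) -> list[RegimePainting]:
    """All set partitions of the clade tags (Bell number of them).

    4 clades -> 15 paintings: one 1-regime, seven 2-regime, six 3-regime,
    one 4-regime.
    """
    clades = sorted(set(clades))
    if not clades:
        raise ValueError("need at least one clade tag")

    def partitions(items: list) -> list[list[list]]:
        if not items:
            return [[]]
        first, rest = items[0], items[1:]
        out = []
        for part in partitions(rest):
            for i in range(len(part)):
                out.append(part[:i] + [[first] + part[i]] + part[i + 1 :])
            out.append([[first]] + part)
        return out

    result = []
    for part in partitions(clades):
        groups = tuple(sorted((frozenset(g) for g in part), key=lambda g: sorted(g)))
        result.append(RegimePainting(groups=groups))
    result.sort(key=lambda p: (p.n_regimes, str(p)))
    return result


def edge_regimes(tree: TimeScaledTree, painting: RegimePainting) -> dict[int, int]:
    """Regime index per edge, keyed by child node id."""
    return {c: painting.regime_of(tree.clade_tags.get(c)) for _, c in tree.edges()}


# ---------------------------------------------------------------------------
# likelihood (pruning / belief propagation)


def _prune_loglik(
    tree: TimeScaledTree,
    Y: np.ndarray,
    tip_rows: dict[int, int],
    rates: Sequence[np.ndarray],
    regimes: dict[int, int],
) -> tuple[float, np.ndarray]:
    """Profiled log-likelihood and root-state MLE by Gaussian pruning.

    ``Y`` is tips x p (rows indexed via ``tip_rows``: node id -> row).
    Messages carry (mean, covariance) of the subtree-conditional Gaussian;
    combining two children contributes the density of their mean difference.
    """
    p = Y.shape[1]
    mu: dict[int, np.ndarray] = {}
    V: dict[int, np.ndarray] = {}
    ll = 0.0
    for nd in tree.postorder():
        if nd.is_tip:
            mu[nd.id] = Y[tip_rows[nd.id]]
            V[nd.id] = np.zeros((p, p))
            continue
        c1, c2 = nd.children
        t1 = nd.age - tree.nodes[c1].age
        t2 = nd.age - tree.nodes[c2].age
        A = V.pop(c1) + t1 * rates[regimes[c1]]
        B = V.pop(c2) + t2 * rates[regimes[c2]]
        S = A + B
        if p == 1:
            s = S[0, 0]
            if s <= 0:
                s = 1e-12
            d = mu[c1][0] - mu[c2][0]
            ll += -0.5 * (_LOG2PI + np.log(s) + d * d / s)
            g = A[0, 0] / s
            V[nd.id] = np.array([[A[0, 0] - A[0, 0] * g]])
            mu[nd.id] = mu[c1] + (mu[c2] - mu[c1]) * g
        else:
            sign, logdet = np.linalg.slogdet(S)
            if sign <= 0:
                S = S + 1e-12 * np.eye(p)
                sign, logdet = np.linalg.slogdet(S)
            Sinv = np.linalg.inv(S)
            d = mu[c1] - mu[c2]
            ll += -0.5 * (p * _LOG2PI + logdet + d @ Sinv @ d)
            G = A @ Sinv
            V[nd.id] = A - G @ A
            mu[nd.id] = mu[c1] + G @ (mu[c2] - mu[c1])
        mu.pop(c1), mu.pop(c2)
    Vr = V[tree.root]
    if p == 1:
        ll += -0.5 * (_LOG2PI + np.log(max(Vr[0, 0], 1e-300)))
    else:
        sign, logdet = np.linalg.slogdet(Vr + 0.0)
        if sign <= 0:
            logdet = np.log(1e-300)
        ll += -0.5 * (p * _LOG2PI + logdet)
    return float(ll), mu[tree.root]


# ---------------------------------------------------------------------------
# rate-matrix parameterization


def _n_rate_params(p: int, constraint: str) -> int:
    if p == 1:
        return 1
    return {"unconstrained": p * (p + 1) // 2, "diagonal": p, "equal": 1}[constraint]


def _theta_to_rates(theta: np.ndarray, p: int, n_regimes: int, constraint: str) -> list[np.ndarray]:
    per = _n_rate_params(p, constraint)
    rates = []
    for r in range(n_regimes):
        t = np.clip(theta[r * per : (r + 1) * per], -40.0, 40.0)
        if p == 1:
            R = np.array([[np.exp(t[0])]])
        elif constraint == "equal":
            R = np.exp(t[0]) * np.eye(p)
        elif constraint == "diagonal":
            R = np.diag(np.exp(t))
        else:  # Cholesky: log-diagonal + free off-diagonal
            L = np.zeros((p, p))
            k = 0
            for i in range(p):
                for j in range(i + 1):
                    L[i, j] = np.exp(t[k]) if i == j else t[k]
                    k += 1
            R = L @ L.T
        rates.append(R)
    return rates


def _rates_to_theta(rates: Sequence[np.ndarray], constraint: str) -> np.ndarray:
    p = rates[0].shape[0]
    out = []
    for R in rates:
        if p == 1:
            out.append(np.log(max(R[0, 0], 1e-12)))
        elif constraint == "equal":
            out.append(np.log(max(np.trace(R) / p, 1e-12)))
        elif constraint == "diagonal":
            out.extend(np.log(np.maximum(np.diag(R), 1e-12)))
        else:
            L = np.linalg.cholesky(R + 1e-12 * np.eye(p))
            for i in range(p):
                for j in range(i + 1):
                    out.append(np.log(max(L[i, j], 1e-12)) if i == j else L[i, j])
    return np.array(out)


# ---------------------------------------------------------------------------
# fitting


@dataclass
class BMModelFit:
    painting: RegimePainting
    constraint: str
    rates: list[np.ndarray]  # per-regime p x p rate matrices (variance / Myr)
    root_state: np.ndarray  # p-vector
    loglik: float
    k: int  # free parameters (rate params + root states)
    aicc: float
    n_tips: int
    trait_names: list[str]
    converged: bool = True
    seed: Optional[int] = None

    def summary_row(self) -> dict:
        return {
            "painting": str(self.painting),
            "n_regimes": self.painting.n_regimes,
            "constraint": self.constraint,
            "k": self.k,
            "loglik": self.loglik,
            "aicc": self.aicc,
            "converged": self.converged,
        }


def _aicc(loglik: float, k: int, n: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _align_traits(tree: TimeScaledTree, traits: pd.DataFrame) -> tuple[np.ndarray, dict[int, int]]:
    tips = tree.tips()
    labels = [nd.label or str(nd.id) for nd in tips]
    missing = set(labels) - set(traits.index)
    if missing:
        raise ValueError(f"traits missing for tips: {sorted(missing)[:5]} ...")
    Y = traits.loc[labels].to_numpy(dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    tip_rows = {nd.id: i for i, nd in enumerate(tips)}
    return Y, tip_rows


def fit_mvbm(
    tree: TimeScaledTree,
    traits: pd.DataFrame,
    painting: RegimePainting,
    constraint: str = "unconstrained",
    n_restarts: int = 1,
    seed: int = 0,
) -> BMModelFit:
    """Maximum-likelihood multi-regime BM fit.

    ``traits`` is a tips x p DataFrame (p = 1 or 2) indexed by tip label.
    Rate matrices are parameterized through Cholesky factors (log-diagonal),
    so every proposal is PSD by construction; the root state is profiled out
    of the likelihood (its MLE is the GLS root estimate).  ``n_restarts``
    dispersed random initializations guard against local optima; the best is
    kept and non-convergence of the winning run is flagged, not hidden.
    """
    if constraint not in CONSTRAINTS:
        raise ValueError(f"unknown constraint {constraint!r}")
    Y, tip_rows = _align_traits(tree, traits)
    p = Y.shape[1]
    if p not in (1, 2):
        raise ValueError("1 or 2 trait columns supported")
    regimes = edge_regimes(tree, painting)
    n_regimes = painting.n_regimes
    per = _n_rate_params(p, constraint)
    rng = np.random.default_rng(seed)

    # empirical starting rate: trait variance over mean root-to-tip time
    depths = np.array([tree.root_age - nd.age for nd in tree.tips()])
    base_rate = max(np.mean(np.var(Y, axis=0, ddof=1)) / max(depths.mean(), 1e-9), 1e-8)
    base = np.full(per * n_regimes, np.log(base_rate))
    if p > 1 and constraint == "unconstrained":
        # off-diagonal Cholesky entries start at 0
        mask = np.tile([True, False, True], n_regimes)
        base = np.where(mask, np.log(np.sqrt(base_rate)), 0.0)
    elif p > 1 and constraint == "diagonal":
        base = np.full(per * n_regimes, np.log(base_rate))

    def nll(theta: np.ndarray) -> float:
        rates = _theta_to_rates(theta, p, n_regimes, constraint)
        ll, _ = _prune_loglik(tree, Y, tip_rows, rates, regimes)
        return -ll if np.isfinite(ll) else 1e12

    best = None
    for i in range(max(1, n_restarts)):
        x0 = base if i == 0 else base + rng.normal(0, 1.0, size=base.size)
        res = minimize(nll, x0, method="L-BFGS-B")
        if best is None or res.fun < best.fun:
            best = res
    rates = _theta_to_rates(best.x, p, n_regimes, constraint)
    ll, root = _prune_loglik(tree, Y, tip_rows, rates, regimes)
    k = per * n_regimes + p
    n = len(tip_rows)
    return BMModelFit(
        painting=painting,
        constraint=constraint,
        rates=rates,
        root_state=root,
        loglik=ll,
        k=k,
        aicc=_aicc(ll, k, n),
        n_tips=n,
        trait_names=list(traits.columns),
        converged=bool(best.success),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# model selection


@dataclass
class ModelSelection:
    best: BMModelFit
    near_ties: list[BMModelFit]  # fits with delta-AICc < 2, best included
    table: pd.DataFrame


def select_model(fits: Sequence[BMModelFit], delta_aicc: float = 2.0) -> ModelSelection:
    """Minimum-AICc model; near-ties (delta-AICc < 2) reported as a set."""
    if not fits:
        raise ValueError("no fits to select from")
    # ties on AICc broken toward fewer parameters
    ordered = sorted(fits, key=lambda f: (f.aicc, f.k))
    best = ordered[0]
    ties = [f for f in ordered if f.aicc - best.aicc < delta_aicc]
    table = pd.DataFrame([f.summary_row() for f in ordered])
    table["delta_aicc"] = table["aicc"] - best.aicc
    return ModelSelection(best=best, near_ties=ties, table=table)


def repeat_model_selection(
    tree: TimeScaledTree,
    traits: pd.DataFrame,
    paintings: Sequence[RegimePainting],
    constraints: Sequence[str] = ("unconstrained",),
    replicates: int = 10,
    n_restarts: int = 2,
    seed: int = 0,
) -> tuple[list[BMModelFit], pd.DataFrame]:
    """Replicated model test: rerun the whole suite and tally AICc winners.

    Each replicate refits the whole candidate suite from fresh dispersed
    starting points and records its AICc winner; replicates can disagree when
    the optimizer lands in different optima.  Returns the per-replicate
    winners and the last replicate's comparison table.
    """
    winners = []
    table = None
    ss = np.random.SeedSequence(seed).spawn(replicates)
    p = traits.shape[1] if traits.ndim == 2 else 1
    for rep, child in enumerate(ss):
        rep_seed = int(child.generate_state(1)[0] % (2**31))
        fits = []
        for painting in paintings:
            for constraint in constraints if p > 1 else ("equal",):
                fits.append(
                    fit_mvbm(
                        tree,
                        traits,
                        painting,
                        constraint,
                        n_restarts=n_restarts,
                        seed=rep_seed,
                    )
                )
        sel = select_model(fits)
        winners.append(sel.best)
        table = sel.table
    return winners, table


# ---------------------------------------------------------------------------
# ancestral states


@dataclass
class ASRResult:
    """Per-internal-node trait estimates (conditional means given tips)."""

    estimates: pd.DataFrame  # internal node id x traits
    fits: list[BMModelFit] = field(default_factory=list)
    replicates: int = 1


def _regime_path_lengths(
    tree: TimeScaledTree, regimes: dict[int, int], n_regimes: int
) -> dict[int, np.ndarray]:
    """Per-node vector of root-to-node path length spent in each regime."""
    L: dict[int, np.ndarray] = {tree.root: np.zeros(n_regimes)}
    for nd in tree.preorder():
        if nd.id == tree.root:
            continue
        vec = L[nd.parent].copy()
        vec[regimes[nd.id]] += tree.nodes[nd.parent].age - nd.age
        L[nd.id] = vec
    return L


def _ancestor_sets(tree: TimeScaledTree) -> dict[int, list[int]]:
    anc: dict[int, list[int]] = {tree.root: [tree.root]}
    for nd in tree.preorder():
        if nd.id == tree.root:
            continue
        anc[nd.id] = anc[nd.parent] + [nd.id]
    return anc


def _mrca_matrix(tree: TimeScaledTree, left: Sequence[int], right: Sequence[int]) -> np.ndarray:
    anc = _ancestor_sets(tree)
    anc_sets = {nid: set(path) for nid, path in anc.items()}
    out = np.empty((len(left), len(right)), dtype=int)
    for i, u in enumerate(left):
        path_u = anc[u]
        for j, v in enumerate(right):
            sv = anc_sets[v]
            m = tree.root
            for a in path_u:
                if a in sv:
                    m = a
                else:
                    break
            out[i, j] = m
    return out


def dense_tip_covariance(
    tree: TimeScaledTree, fit_rates: Sequence[np.ndarray], regimes: dict[int, int]
) -> np.ndarray:
    """Explicit (n*p x n*p) tip covariance: sum_r kron(C_r, R_r).

    ``C_r[i, j]`` is the root-to-MRCA path length of tips i, j spent in
    regime r.  Tip order matches ``tree.tips()``; the flattened trait vector
    is tip-major.
    """
    n_regimes = len(fit_rates)
    L = _regime_path_lengths(tree, regimes, n_regimes)
    tips = [nd.id for nd in tree.tips()]
    mrca = _mrca_matrix(tree, tips, tips)
    p = fit_rates[0].shape[0]
    V = np.zeros((len(tips) * p, len(tips) * p))
    for r in range(n_regimes):
        C = np.array([[L[mrca[i, j]][r] for j in range(len(tips))] for i in range(len(tips))])
        V += np.kron(C, fit_rates[r])
    return V


def estimate_ancestral_states(
    tree: TimeScaledTree,
    traits: pd.DataFrame,
    fits: BMModelFit | Sequence[BMModelFit],
    replicates: int = 1,
) -> ASRResult:
    """GLS ancestral reconstruction under fitted BM model(s).

    For each fit, internal-node values are the conditional expectation of the
    joint Gaussian given the tips: ``E[z | y] = mu_z + Cov(z, y) V_yy^{-1}
    (y - mu_y)`` built from per-regime shared-path matrices.  When several
    fits are supplied (near-tied models, or replicate rounds), node estimates
    are their arithmetic mean.  The root estimate under a single fit equals
    that fit's root state.
    """
    if isinstance(fits, BMModelFit):
        fits = [fits]
    fits = list(fits)
    Y, tip_rows = _align_traits(tree, traits)
    p = Y.shape[1]
    tips = [nd.id for nd in tree.tips()]
    internals = [nd.id for nd in tree.nodes if not nd.is_tip]
    per_fit = []
    for fit in fits:
        regimes = edge_regimes(tree, fit.painting)
        n_regimes = fit.painting.n_regimes
        L = _regime_path_lengths(tree, regimes, n_regimes)
        Vyy = dense_tip_covariance(tree, fit.rates, regimes)
        mrca_zy = _mrca_matrix(tree, internals, tips)
        Czy = np.zeros((len(internals) * p, len(tips) * p))
        for r in range(n_regimes):
            C = np.array(
                [[L[mrca_zy[i, j]][r] for j in range(len(tips))] for i in range(len(internals))]
            )
            Czy += np.kron(C, fit.rates[r])
        resid = (Y - fit.root_state[None, :]).ravel()
        sol = np.linalg.solve(Vyy + 1e-10 * np.eye(Vyy.shape[0]), resid)
        z = np.tile(fit.root_state, len(internals)) + Czy @ sol
        per_fit.append(z.reshape(len(internals), p))
    est = np.mean(per_fit, axis=0)
    df = pd.DataFrame(est, index=pd.Index(internals, name="node_id"), columns=fits[0].trait_names)
    return ASRResult(estimates=df, fits=fits, replicates=len(fits))
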