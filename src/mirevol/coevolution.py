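"""Correlated evolution of binary phylogenetic profiles.

Two presence/absence traits are modelled as a continuous-time Markov chain
on the paired state space {00, 01, 10, 11} (simultaneous double
transitions forbidden). The independent model has 4 rates (gain/loss per
trait); the dependent model has 8 (each single-trait transition rate may
depend on the state of the other trait). Both are fitted by maximum
likelihood with Felsenstein pruning, and association is measured by
LR = 2 (lnL_dep - lnL_ind), asymptotically chi-square with 4 df under
independence (rate-boundary effects inflate the tail slightly).

State index convention: ``2 * trait_a + trait_b``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.optimize import minimize
from scipy.stats import chi2

from .io_formats import ProfileMatrix, SpeciesTree

__all__ = [
    "CtmcModel",
    "AssociationResult",
    "build_rate_matrix",
    "stationary_distribution",
    "pruning_loglik",
    "fit_model",
    "simulate_pair",
    "screen_pairs",
]

RATE_BOUNDS = (1e-6, 100.0)

# dependent-model rate order: each entry (from_state, to_state)
DEPENDENT_TRANSITIONS = [
    (0, 1), (0, 2),  # from 00: gain B, gain A
    (1, 0), (1, 3),  # from 01: loss B, gain A
    (2, 0), (2, 3),  # from 10: loss A, gain B
    (3, 1), (3, 2),  # from 11: loss A, loss B
]


@dataclass(frozen=True)
class CtmcModel:
    """Model kind and its rate vector layout.

    independent: rates = (gain_a, loss_a, gain_b, loss_b).
    dependent: rates follow :data:`DEPENDENT_TRANSITIONS`.
    """

    kind: str

    def __post_init__(self):
        if self.kind not in ("independent", "dependent"):
            raise ValueError("kind must be independent|dependent")

    @property
    def n_rates(self) -> int:
        return 4 if self.kind == "independent" else 8

    def independent_to_dependent(self, rates: np.ndarray) -> np.ndarray:
        """Embed independent rates in the dependent parameterisation."""
        ga, la, gb, lb = rates
        return np.array([gb, ga, lb, ga, la, gb, la, lb])


def build_rate_matrix(model: CtmcModel, rates) -> np.ndarray:
    """4x4 generator; rows sum to zero, double transitions are zero."""
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (model.n_rates,):
        raise ValueError(f"{model.kind} model needs {model.n_rates} rates")
    if (rates < 0).any():
        raise ValueError("rates must be >= 0")
    if model.kind == "independent":
        rates = model.independent_to_dependent(rates)
    Q = np.zeros((4, 4))
    for r, (i, j) in zip(rates, DEPENDENT_TRANSITIONS):
        Q[i, j] = r
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Solve pi Q = 0, sum(pi) = 1 (least squares; always well-posed here)."""
    A = np.vstack([Q.T, np.ones(4)])
    b = np.array([0.0, 0.0, 0.0, 0.0, 1.0])
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def _leaf_states(profile_a: dict, profile_b: dict, tree: SpeciesTree) -> dict:
    out = {}
    for leaf in tree.leaves:
        a = int(profile_a[leaf.label])
        b = int(profile_b[leaf.label])
        if a not in (0, 1) or b not in (0, 1):
            raise ValueError("profiles must be binary")
        out[leaf.id] = 2 * a + b
    return out


def pruning_loglik(
    profile_a: dict,
    profile_b: dict,
    tree: SpeciesTree,
    model: CtmcModel,
    rates,
    root="stationary",
) -> float:
    """Felsenstein pruning log-likelihood of a trait pair on the tree.

    ``root`` is the root state distribution: the chain's stationary
    distribution (default), ``"uniform"``, or an explicit length-4
    probability vector. Zero-length branches are collapsed (identity
    transition) with a warning.
    """
    Q = build_rate_matrix(model, rates)
    states = _leaf_states(profile_a, profile_b, tree)
    if len({s for s in states.values()}) == 1 and len(states) > 1:
        warnings.warn("all leaves share one paired state; likelihood is "
                      "degenerate in the rates", stacklevel=2)
    P_cache: dict[float, np.ndarray] = {}

    def P(t: float) -> np.ndarray:
        if t not in P_cache:
            if t == 0.0:
                warnings.warn("zero-length branch collapsed", stacklevel=2)
                P_cache[t] = np.eye(4)
            else:
                P_cache[t] = expm(Q * t)
        return P_cache[t]

    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            v = np.zeros(4)
            v[states[node.id]] = 1.0
        else:
            v = np.ones(4)
            for cid in node.children:
                child = tree.nodes[cid]
                v = v * (P(child.length) @ partial[cid])
        partial[node.id] = v
    if isinstance(root, str):
        if root == "stationary":
            pi = stationary_distribution(Q)
        elif root == "uniform":
            pi = np.full(4, 0.25)
        else:
            raise ValueError("root must be stationary|uniform|vector")
    else:
        pi = np.asarray(root, dtype=float)
        if pi.shape != (4,) or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("root vector must be a length-4 distribution")
    lik = float(pi @ partial[tree.root])
    if lik <= 0.0:
        return -np.inf
    return float(np.log(lik))


# ---------------------------------------------------------------------------
# Two-state closed form (fast path for the independent model)
# ---------------------------------------------------------------------------


def _loglik_2state(profile: dict, tree: SpeciesTree, gain: float,
                   loss: float, root: str) -> float:
    tot = gain + loss
    pi1 = gain / tot
    P_cache: dict[float, np.ndarray] = {}

    def P(t: float) -> np.ndarray:
        if t not in P_cache:
            e = np.exp(-tot * t)
            P_cache[t] = np.array(
                [
                    [1 - pi1 + pi1 * e, pi1 * (1 - e)],
                    [(1 - pi1) * (1 - e), pi1 + (1 - pi1) * e],
                ]
            )
        return P_cache[t]

    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            v = np.zeros(2)
            v[int(profile[node.label])] = 1.0
        else:
            v = np.ones(2)
            for cid in node.children:
                v = v * (P(tree.nodes[cid].length) @ partial[cid])
        partial[node.id] = v
    pi = np.array([1 - pi1, pi1]) if root == "stationary" else np.full(2, 0.5)
    lik = float(pi @ partial[tree.root])
    return float(np.log(lik)) if lik > 0 else -np.inf


def _fit_2state(profile: dict, tree: SpeciesTree, n_restarts: int,
                rng: np.random.Generator, root: str) -> tuple[np.ndarray, float]:
    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def neg(theta):
        g, l = np.exp(theta)
        return -_loglik_2state(profile, tree, g, l, root)

    best = None
    starts = [np.log([1.0, 1.0])] + [
        rng.uniform(np.log(0.01), np.log(10.0), size=2)
        for _ in range(max(n_restarts - 1, 0))
    ]
    for x0 in starts:
        res = minimize(neg, x0, method="L-BFGS-B",
                       bounds=[(lo, hi)] * 2)
        if best is None or res.fun < best.fun:
            best = res
    return np.exp(best.x), -float(best.fun)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    model: CtmcModel
    rates: np.ndarray
    loglik: float
    converged: bool
    n_restarts: int


def fit_model(
    profile_a: dict,
    profile_b: dict,
    tree: SpeciesTree,
    kind: str,
    n_restarts: int = 5,
    seed: int = 0,
    root: str = "stationary",
) -> FitResult:
    """Bounded multi-start maximum likelihood for one trait pair.

    The independent model factorises into two 2-state chains, each fitted
    by closed-form transition probabilities; the dependent model is fitted
    on the 4-state chain, seeded both from random starts and from the
    embedded independent optimum (which guarantees lnL_dep >= lnL_ind up
    to optimizer tolerance).
    """
    rng = np.random.default_rng(seed)
    model = CtmcModel(kind)
    ind = CtmcModel("independent")
    ra, lla = _fit_2state(profile_a, tree, n_restarts, rng, root)
    rb, llb = _fit_2state(profile_b, tree, n_restarts, rng, root)
    ind_rates = np.array([ra[0], ra[1], rb[0], rb[1]])
    if kind == "independent":
        return FitResult(ind, ind_rates, lla + llb, True, n_restarts)

    lo, hi = np.log(RATE_BOUNDS[0]), np.log(RATE_BOUNDS[1])

    def neg(theta):
        return -pruning_loglik(profile_a, profile_b, tree, model,
                               np.exp(theta), root=root)

    starts = [np.log(np.clip(ind.independent_to_dependent(ind_rates),
                             *RATE_BOUNDS))]
    starts += [rng.uniform(np.log(0.01), np.log(10.0), size=8)
               for _ in range(max(n_restarts - 1, 0))]
    best, any_success = None, False
    for x0 in starts:
        res = minimize(neg, x0, method="L-BFGS-B", bounds=[(lo, hi)] * 8)
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    return FitResult(model, np.exp(best.x), -float(best.fun),
                     any_success, n_restarts)


def simulate_pair(
    tree: SpeciesTree,
    model: CtmcModel,
    rates,
    rng: np.random.Generator,
    root: str = "stationary",
) -> tuple[dict, dict]:
    """Sample one trait pair by evolving the 4-state chain down the tree."""
    Q = build_rate_matrix(model, rates)
    pi = stationary_distribution(Q) if root == "stationary" else np.full(4, 0.25)
    P_cache: dict[float, np.ndarray] = {}
    state = {tree.root: int(rng.choice(4, p=pi))}
    for node in tree.preorder():
        if node.id == tree.root:
            continue
        t = node.length
        if t not in P_cache:
            P_cache[t] = expm(Q * t) if t > 0 else np.eye(4)
        row = np.clip(P_cache[t][state[node.parent]], 0, None)
        row = row / row.sum()
        state[node.id] = int(rng.choice(4, p=row))
    pa, pb = {}, {}
    for leaf in tree.leaves:
        s = state[leaf.id]
        pa[leaf.label] = s // 2
        pb[leaf.label] = s % 2
    return pa, pb


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    pair: tuple[str, str]
    lnl_independent: float
    lnl_dependent: float
    lr: float
    n_present_a: int
    n_present_b: int
    passed_filter: bool
    degenerate: bool = False
    significant: bool = False


def screen_pairs(
    matrix_a: ProfileMatrix,
    matrix_b: ProfileMatrix | None,
    tree: SpeciesTree,
    min_present: int = 5,
    min_absent: int = 5,
    lr_threshold: float | None = None,
    bonferroni: bool = False,
    n_restarts: int = 5,
    seed: int = 0,
    max_pairs: int | None = None,
) -> list[AssociationResult]:
    """Test all filtered profile pairs and rank them by likelihood ratio.

    Pairs with fewer than ``min_present`` presences or ``min_absent``
    absences in either trait are reported unfitted (``passed_filter`` is
    False): associations driven by a handful of species are uninformative.
    ``matrix_b=None`` screens within ``matrix_a``. Significance defaults
    to the chi-square(4 df) 0.999 quantile on LR, Bonferroni-adjusted on
    request.
    """
    a = matrix_a.to_presence().data
    within = matrix_b is None
    b = a if within else matrix_b.to_presence().data
    nsp = a.shape[1]

    def ok(row) -> bool:
        s = int(row.sum())
        return s >= min_present and (nsp - s) >= min_absent

    pairs = []
    for i, fa in enumerate(a.index):
        for fb in (a.index[i + 1 :] if within else b.index):
            pairs.append((fa, fb))
    if max_pairs is not None and len(pairs) > max_pairs:
        raise ValueError(f"{len(pairs)} pairs exceed max_pairs={max_pairs}")
    results: list[AssociationResult] = []
    tested = 0
    for fa, fb in pairs:
        ra, rb = a.loc[fa], b.loc[fb]
        res = AssociationResult(
            pair=(fa, fb),
            lnl_independent=np.nan,
            lnl_dependent=np.nan,
            lr=np.nan,
            n_present_a=int(ra.sum()),
            n_present_b=int(rb.sum()),
            passed_filter=bool(ok(ra) and ok(rb)),
        )
        if res.passed_filter:
            pa, pb = dict(ra), dict(rb)
            fit_i = fit_model(pa, pb, tree, "independent",
                              n_restarts=n_restarts, seed=seed)
            fit_d = fit_model(pa, pb, tree, "dependent",
                              n_restarts=n_restarts, seed=seed)
            res.lnl_independent = fit_i.loglik
            res.lnl_dependent = fit_d.loglik
            res.lr = 2.0 * (fit_d.loglik - fit_i.loglik)
            res.degenerate = bool((ra == rb).all() or (ra == 1 - rb).all())
            tested += 1
        results.append(res)
    if lr_threshold is None:
        q = 0.999
        lr_threshold = float(chi2.ppf(q, df=4))
    if bonferroni and tested > 0:
        lr_threshold = float(chi2.ppf(1.0 - 0.001 / tested, df=4))
    for res in results:
        if res.passed_filter and np.isfinite(res.lr):
            res.significant = bool(res.lr > lr_threshold)
    results.sort(
        key=lambda r: (-(r.lr if np.isfinite(r.lr) else -np.inf), r.pair)
    )
    return results


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = [
        {
            "trait_a": r.pair[0],
            "trait_b": r.pair[1],
            "lnL_independent": r.lnl_independent,
            "lnL_dependent": r.lnl_dependent,
            "likelihood_ratio": r.lr,
            "n_present_a": r.n_present_a,
            "n_present_b": r.n_present_b,
            "passed_filter": r.passed_filter,
            "degenerate": r.degenerate,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
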