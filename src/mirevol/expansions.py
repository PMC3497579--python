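"""Birth-death analysis of family copy-number evolution.

Family sizes evolve along the tree under a linear birth-death process in
which every gene duplicates and dies at the same rate lambda (events per
gene per unit branch length). The transition probability has the closed
form

    P(c | s, t) = sum_{j=0}^{min(s,c)} C(s,j) C(s+c-j-1, s-1)
                  alpha^(s+c-2j) (1-2*alpha)^j,   alpha = lt/(1+lt)

for a parent of size s >= 1; size 0 is absorbing. A single global lambda
is fitted by maximum likelihood (pruning over internal sizes, uniform
root-size prior), and per-family expansion p-values are conditional
Monte-Carlo: the observed family log-likelihood is ranked against
likelihoods of families simulated under the fitted model. The null
distribution depends only on (tree, lambda, prior), so one simulated
sample serves every family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

from .io_formats import ProfileMatrix, SpeciesTree
from .synthetic_data import simulate_family_sizes

__all__ = [
    "bd_transition",
    "transition_matrix",
    "root_present_families",
    "fit_lambda",
    "family_loglik",
    "expansion_pvalue",
    "expansion_report",
]

MAX_SIZE_DEFAULT = 100


def bd_transition(s: int, c: int, t: float, lam: float) -> float:
    """P(child size = c | parent size = s) under the single-rate model.

    Rejects s = 0: an extinct lineage cannot regenerate (absorbing state,
    handled internally by the pruning recursion, not by this public form).
    For lam*t <= 1 every term of the closed form is non-negative and the
    sum is evaluated directly; beyond that the alternating terms cancel
    catastrophically in floating point, so the probability is taken from
    the matrix exponential of the (truncated) birth-death generator.
    """
    if s < 1:
        raise ValueError("parent size must be >= 1 (size 0 is absorbing)")
    if c < 0 or t < 0 or lam < 0:
        raise ValueError("need c >= 0, t >= 0, lambda >= 0")
    if lam * t == 0:
        return 1.0 if c == s else 0.0
    if lam * t <= 1.0:
        alpha = lam * t / (1.0 + lam * t)
        x = 1.0 - 2.0 * alpha
        total = 0.0
        for j in range(min(s, c) + 1):
            logmag = (
                _log_comb(s, j)
                + _log_comb(s + c - j - 1, s - 1)
                + (s + c - 2 * j) * np.log(alpha)
            )
            if j > 0:
                if x == 0.0:
                    continue
                logmag += j * np.log(x)
            total += np.exp(logmag)
        return min(max(total, 0.0), 1.0)
    smax = min(int(2 * (s + c + 5) + 10 * lam * t), 1000)
    return float(_bd_expm(t, lam, smax)[s, c])


def _bd_expm(t: float, lam: float, smax: int) -> np.ndarray:
    """expm of the linear birth-death generator truncated at smax.

    Rates s -> s+1 and s -> s-1 are both lam*s; the truncation drops
    births above smax, so rows near the cap lose a little mass upward.
    """
    from scipy.linalg import expm as _expm

    sizes = np.arange(smax + 1, dtype=float)
    Q = np.zeros((smax + 1, smax + 1))
    Q[np.arange(1, smax + 1), np.arange(smax)] = lam * sizes[1:]
    Q[np.arange(smax), np.arange(1, smax + 1)] = lam * sizes[:-1]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    P = _expm(Q * t)
    return np.clip(P, 0.0, 1.0)


def _log_comb(n: int, k: int) -> float:
    if k < 0 or k > n:
        return -np.inf
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def transition_matrix(t: float, lam: float, smax: int) -> np.ndarray:
    """(smax+1) x (smax+1) matrix M[s, c] = P(c | s, t); row 0 absorbing.

    Rows are the closed form truncated at c = smax (no renormalisation);
    choose smax comfortably above the largest observed size.
    """
    M = np.zeros((smax + 1, smax + 1))
    M[0, 0] = 1.0
    if lam * t == 0:
        M[np.arange(smax + 1), np.arange(smax + 1)] = 1.0
        return M
    if lam * t > 1.0:
        # alternating closed-form terms cancel in floating point here;
        # use the generator exponential instead (slightly lossy at the cap)
        P = _bd_expm(t, lam, smax)
        P[0] = 0.0
        P[0, 0] = 1.0
        return P
    alpha = lam * t / (1.0 + lam * t)
    x = 1.0 - 2.0 * alpha
    s = np.arange(1, smax + 1)[:, None]  # parents
    c = np.arange(0, smax + 1)[None, :]
    out = np.zeros((smax, smax + 1))
    log_alpha = np.log(alpha)
    log_ax = np.log(abs(x)) if x != 0.0 else None
    sign_x = np.sign(x)
    for j in range(smax + 1):
        valid = (j <= s) & (j <= c)
        if not valid.any():
            break
        n2 = s + c - j - 1
        k2 = s - 1
        logmag = (
            _log_comb_arr(np.broadcast_to(s, valid.shape), j)
            + _log_comb_arr(n2, np.broadcast_to(k2, valid.shape))
            + (s + c - 2 * j) * log_alpha
        )
        if j == 0:
            term = np.exp(logmag)
        else:
            if log_ax is None:
                continue
            term = (sign_x ** j) * np.exp(logmag + j * log_ax)
        out += np.where(valid, term, 0.0)
    M[1:, :] = np.clip(out, 0.0, None)
    return M


def _log_comb_arr(n: np.ndarray, k) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    with np.errstate(invalid="ignore"):
        res = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
    bad = (k < 0) | (k > n) | (n < 0)
    return np.where(bad, -np.inf, res)


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------


def root_present_families(
    counts: ProfileMatrix, tree: SpeciesTree
) -> list[str]:
    """Families whose presence MRCA is the (sub)tree root.

    The birth-death model requires root presence; under Dollo the inferred
    root size is >= 1 exactly when the MRCA of presence leaves is the root.
    """
    keep = []
    data = counts.data
    for fam in data.index:
        present = [sp for sp in data.columns if data.loc[fam, sp] > 0]
        if present and tree.mrca(present) == tree.root:
            keep.append(fam)
    return keep


def _branch_matrices(tree: SpeciesTree, lam: float,
                     smax: int) -> dict[int, np.ndarray]:
    by_length: dict[float, np.ndarray] = {}
    out = {}
    for node in tree.nodes:
        if node.id == tree.root:
            continue
        if node.length not in by_length:
            by_length[node.length] = transition_matrix(node.length, lam, smax)
        out[node.id] = by_length[node.length]
    return out


def family_loglik(
    observed: dict[str, int],
    tree: SpeciesTree,
    lam: float,
    smax: int,
    root_max: int,
    matrices: dict[int, np.ndarray] | None = None,
) -> float:
    """Log-likelihood of one family's leaf sizes by pruning over sizes.

    The root size carries a uniform prior over 1..root_max.
    """
    if matrices is None:
        matrices = _branch_matrices(tree, lam, smax)
    partial: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            v = np.zeros(smax + 1)
            obs = observed[node.label]
            if obs > smax:
                raise ValueError(
                    f"size {obs} exceeds the cap {smax}; raise max_size"
                )
            v[obs] = 1.0
            partial[node.id] = v
        else:
            v = np.ones(smax + 1)
            for cid in node.children:
                v = v * (matrices[cid] @ partial[cid])
            partial[node.id] = v
    root_v = partial[tree.root][1 : root_max + 1]
    lik = root_v.mean()
    if lik <= 0.0:
        return -np.inf
    return float(np.log(lik))


def fit_lambda(
    counts: ProfileMatrix,
    tree: SpeciesTree,
    max_size: int = MAX_SIZE_DEFAULT,
    lam_bounds: tuple[float, float] = (0.0, 10.0),
    root_max: int | None = None,
) -> tuple[float, pd.Series]:
    """ML estimate of the global birth-death rate over root-present families.

    ``root_max`` caps the uniform root-size prior (default: the largest
    observed size). Returns (lambda_hat, per-family log-likelihoods at
    lambda_hat).
    """
    counts.check_against_tree(tree)
    fams = root_present_families(counts, tree)
    if not fams:
        raise ValueError("no root-present families to fit")
    if sum(n.length for n in tree.nodes) <= 0:
        raise ValueError("tree has zero total branch length")
    data = counts.data.loc[fams]
    max_obs = int(data.to_numpy().max())
    if max_obs > max_size:
        raise ValueError(
            f"largest family size {max_obs} exceeds max_size={max_size}"
        )
    prior_max = root_max if root_max is not None else max_obs
    smax = min(max_size, max(2 * max(max_obs, prior_max) + 10, 20))
    observations = [dict(data.loc[fam]) for fam in fams]

    def neg_total(lam: float) -> float:
        matrices = _branch_matrices(tree, lam, smax)
        total = 0.0
        for obs in observations:
            total += family_loglik(obs, tree, lam, smax, prior_max, matrices)
        return -total

    res = minimize_scalar(neg_total, bounds=lam_bounds, method="bounded",
                          options={"xatol": 1e-5})
    lam_hat = float(res.x)
    # snap to the boundary when the optimum is flat at zero
    if neg_total(0.0) <= res.fun:
        lam_hat = 0.0
    matrices = _branch_matrices(tree, lam_hat, smax)
    logliks = pd.Series(
        {
            fam: family_loglik(obs, tree, lam_hat, smax, prior_max, matrices)
            for fam, obs in zip(fams, observations)
        }
    )
    return lam_hat, logliks


# ---------------------------------------------------------------------------
# Expansion p-values
# ---------------------------------------------------------------------------


def _viterbi_sizes(observed: dict[str, int], tree: SpeciesTree,
                   matrices: dict[int, np.ndarray], smax: int,
                   root_max: int) -> dict[int, int]:
    """Most probable internal size assignment (max-product pass)."""
    best: dict[int, np.ndarray] = {}
    choice: dict[int, np.ndarray] = {}
    logM = {nid: np.log(np.clip(m, 1e-300, None)) for nid, m in matrices.items()}
    for node in tree.postorder():
        if node.is_leaf:
            v = np.full(smax + 1, -np.inf)
            v[observed[node.label]] = 0.0
            best[node.id] = v
        else:
            v = np.zeros(smax + 1)
            for cid in node.children:
                scores = logM[cid] + best[cid][None, :]
                choice[cid] = np.argmax(scores, axis=1)
                v = v + np.max(scores, axis=1)
            best[node.id] = v
    sizes: dict[int, int] = {}
    root_scores = best[tree.root].copy()
    root_scores[0] = -np.inf
    root_scores[root_max + 1 :] = -np.inf
    sizes[tree.root] = int(np.argmax(root_scores))
    for node in tree.preorder():
        if node.id == tree.root:
            continue
        sizes[node.id] = int(choice[node.id][sizes[node.parent]])
    return sizes


def flag_branch(observed: dict[str, int], tree: SpeciesTree, lam: float,
                smax: int, root_max: int) -> int:
    """Branch (child node id) with the least probable size transition."""
    matrices = _branch_matrices(tree, lam, smax)
    sizes = _viterbi_sizes(observed, tree, matrices, smax, root_max)
    worst, worst_lp = None, np.inf
    for node in tree.nodes:
        if node.id == tree.root:
            continue
        ps, cs = sizes[node.parent], sizes[node.id]
        p = matrices[node.id][ps, cs]
        lp = np.log(max(p, 1e-300))
        if lp < worst_lp:
            worst, worst_lp = node.id, lp
    return worst


def expansion_pvalue(
    observed: dict[str, int],
    tree: SpeciesTree,
    lam_hat: float,
    n_sim: int = 1000,
    seed: int = 0,
    max_size: int = MAX_SIZE_DEFAULT,
    root_max: int | None = None,
    null_logliks: np.ndarray | None = None,
) -> tuple[float, int]:
    """Conditional Monte-Carlo p-value for one family, plus flagged branch.

    p = fraction of families simulated under lambda_hat whose log-likelihood
    is <= the observed family's (add-one corrected). Pass ``null_logliks``
    to reuse a shared null sample.
    """
    if n_sim < 1 and null_logliks is None:
        raise ValueError("n_sim must be >= 1")
    max_obs = max(observed.values())
    if root_max is None:
        root_max = max(max_obs, 1)
    smax = min(max_size, max(2 * max(max_obs, root_max) + 10, 20))
    if null_logliks is None:
        null_logliks = simulate_null_logliks(
            tree, lam_hat, root_max, n_sim, seed, smax
        )
    obs_ll = family_loglik(observed, tree, lam_hat, smax, root_max)
    p = (1.0 + np.sum(null_logliks <= obs_ll)) / (len(null_logliks) + 1.0)
    branch = flag_branch(observed, tree, lam_hat, smax, root_max)
    return float(p), branch


def simulate_null_logliks(
    tree: SpeciesTree,
    lam: float,
    root_max: int,
    n_sim: int,
    seed: int,
    smax: int,
) -> np.ndarray:
    """Log-likelihoods of families simulated under the fitted model.

    Null families are conditioned exactly like the observed ones: draws
    that fail the root-presence criterion (presence MRCA below the root)
    are discarded and re-sampled, because the analysis only ever tests
    families passing that filter.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    matrices = _branch_matrices(tree, lam, smax)
    out: list[float] = []
    guard = 0
    while len(out) < n_sim:
        batch = max(n_sim - len(out), 16)
        root_sizes = {
            f"null{guard}_{i}": int(rng.integers(1, root_max + 1))
            for i in range(batch)
        }
        sim_counts, _ = simulate_family_sizes(
            tree, lam, root_sizes, seed=int(rng.integers(2**31))
        )
        keep = set(root_present_families(sim_counts, tree))
        for fam in sim_counts.data.index:
            if fam not in keep or len(out) >= n_sim:
                continue
            obs = dict(sim_counts.data.loc[fam])
            if max(obs.values()) > smax:
                out.append(-np.inf)  # more extreme than anything observable
                continue
            out.append(family_loglik(obs, tree, lam, smax, root_max,
                                     matrices))
        guard += 1
        if guard > 1000:
            raise RuntimeError("null simulation cannot satisfy the "
                               "root-presence condition")
    return np.asarray(out)


def expansion_report(
    counts: ProfileMatrix,
    tree: SpeciesTree,
    n_sim: int = 1000,
    seed: int = 0,
    max_size: int = MAX_SIZE_DEFAULT,
    p_threshold: float = 0.01,
    root_max: int | None = None,
) -> pd.DataFrame:
    """Fit lambda on root-present families and test each for fast change.

    One shared Monte-Carlo null sample (the null law of the family
    log-likelihood depends only on tree and lambda-hat) serves all
    families. Returns a table sorted by p-value.
    """
    lam_hat, logliks = fit_lambda(counts, tree, max_size=max_size,
                                  root_max=root_max)
    fams = list(logliks.index)
    data = counts.data.loc[fams]
    max_obs = int(data.to_numpy().max())
    if root_max is None:
        root_max = max(max_obs, 1)
    smax = min(max_size, max(2 * max(max_obs, root_max) + 10, 20))
    null = simulate_null_logliks(tree, lam_hat, root_max, n_sim, seed, smax)
    rows = []
    for fam in fams:
        obs = dict(data.loc[fam])
        obs_ll = logliks[fam]
        p = (1.0 + np.sum(null <= obs_ll)) / (len(null) + 1.0)
        branch = flag_branch(obs, tree, lam_hat, smax, root_max)
        rows.append(
            {
                "family": fam,
                "lambda_hat": lam_hat,
                "loglik": obs_ll,
                "p_value": float(p),
                "flagged_branch": branch,
                "significant": bool(p < p_threshold),
            }
        )
    return (
        pd.DataFrame(rows)
        .set_index("family")
        .sort_values(["p_value", "loglik"])
    )
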