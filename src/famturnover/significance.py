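"""Acceleration tests for gene families and branches, with a simulated null.

Three layers of testing, mirroring a CAFE-style workflow:

* per-family Monte-Carlo p-values: how unlikely is a family's tip profile
  under the fitted global birth-death model, judged by ranking its
  log-likelihood among profiles simulated from the model (root sizes drawn
  from each family's conditional root-size posterior);
* per-branch exact tail tests on single transitions given maximum-likelihood
  ancestral states;
* a likelihood-ratio test between nested rate models whose null distribution
  is built by simulation (fit both models to datasets simulated under the
  fitted null), replacing any asymptotic chi-square assumption.

Monte-Carlo p-values use the (1 + k) / (1 + n) estimator.  Because count data
produce heavily tied log-likelihoods, ties are broken by a seeded uniform rank
draw by default, which makes null p-values exactly uniform on the achievable
grid; a strict conservative mode (ties counted as at-least-as-extreme) is
available via ``tie_break='conservative'``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .bd_likelihood import (
    ErrorModel,
    FitResult,
    RateModel,
    _branch_matrices,
    _tip_partials,
    fit_model,
    observation_matrix,
    table_log_likelihood,
)
from .phylo_io import Chronogram, FamilyCountTable

__all__ = [
    "LrtResult",
    "ml_ancestral_states",
    "family_pvalues",
    "branch_pvalues",
    "simulate_null_lrt",
    "adjust_pvalues",
]

_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# Multiple-testing corrections
# ---------------------------------------------------------------------------

_METHODS = {
    "bonferroni": "bonferroni",
    "holm": "holm",
    "sidak": "sidak",
    "bh": "fdr_bh",
}


def adjust_pvalues(pvals, method: str = "bh") -> np.ndarray:
    """Adjusted p-values (clamped to [0, 1]); BH is step-up monotone."""
    if method not in _METHODS:
        raise ValueError(f"unknown correction {method!r}; choose from {sorted(_METHODS)}")
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # sidak emits log1p(-1) at p = 1
        adj = multipletests(p, method=_METHODS[method])[1]
    return np.clip(adj, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Maximum-likelihood ancestral states
# ---------------------------------------------------------------------------


def ml_ancestral_states(
    profile,
    tree: Chronogram,
    model: RateModel,
    error: ErrorModel | None = None,
    S: int | None = None,
) -> np.ndarray:
    """Jointly most likely ancestral copy numbers (max-product over the tree).

    Returns a per-node-index state array; ties resolve to the smaller state.
    """
    prof = dict(profile)
    counts = np.array([[int(prof[sp]) for sp in tree.tip_labels]], dtype=np.int64)
    if S is None:
        S = int(counts.max()) + 10
    mats = _branch_matrices(tree, model, S)
    tipp = _tip_partials(counts, tree, error, S)
    up: dict[int, np.ndarray] = {}
    for n in tree.postorder():
        if tree.is_tip(n):
            up[n] = tipp[n][0]
        else:
            u = np.ones(S + 1)
            for ch in tree.children[n]:
                u = u * np.max(mats[ch] * up[ch][None, :], axis=1)
            m = u.max()
            up[n] = u / (m if m > 0 else 1.0)
    states = np.zeros(tree.n_nodes, dtype=np.int64)
    states[tree.root] = 1 + int(np.argmax(up[tree.root][1:]))
    for n in tree.preorder():
        if n == tree.root:
            continue
        sp = states[tree.parent[n]]
        states[n] = int(np.argmax(mats[n][sp] * up[n]))
    return states


# ---------------------------------------------------------------------------
# Per-branch exact tail tests
# ---------------------------------------------------------------------------


def branch_pvalues(
    profile,
    tree: Chronogram,
    fitted: FitResult,
) -> pd.Series:
    """Probability-ordered exact tail p per branch for one family.

    For each branch, sums the probabilities of all child states no more
    probable than the realised one given the parent's ML state (two-tailed by
    probability ordering).
    """
    model = fitted.model
    error = fitted.error if not fitted.error.is_zero else None
    S = fitted.S
    states = ml_ancestral_states(profile, tree, model, error, S=S)
    mats = _branch_matrices(tree, model, S)
    out = {}
    for n in range(tree.n_nodes):
        if n == tree.root:
            continue
        row = mats[n][states[tree.parent[n]]]
        row = row / row.sum()
        p_obs = row[states[n]]
        out[tree.labels[n]] = float(row[row <= p_obs * (1.0 + 1e-12)].sum())
    return pd.Series(out, name="branch_p")


# ---------------------------------------------------------------------------
# Model-based simulation of tip profiles
# ---------------------------------------------------------------------------


def _sample_profiles(
    tree: Chronogram,
    model: RateModel,
    root_sizes: np.ndarray,
    S: int,
    rng: np.random.Generator,
    error: ErrorModel | None = None,
) -> np.ndarray:
    """Sample (N, n_tips) count profiles by drawing transitions down the tree."""
    mats = _branch_matrices(tree, model, S)
    cums = {n: np.cumsum(m, axis=1) for n, m in mats.items()}
    N = len(root_sizes)
    state = np.empty((tree.n_nodes, N), dtype=np.int64)
    state[tree.root] = np.clip(root_sizes, 0, S)
    for n in tree.preorder():
        if n == tree.root:
            continue
        rows = cums[n][state[tree.parent[n]]]
        u = rng.random(N)
        state[n] = np.minimum((rows < u[:, None]).sum(axis=1), S)
    tips = tree.tip_indices
    out = state[tips].T.copy()
    if error is not None and not error.is_zero:
        for col, node in enumerate(tips):
            eps = error.eps_for(tree.labels[node])
            if eps == 0:
                continue
            E = observation_matrix(S, eps)
            ec = np.cumsum(E, axis=1)
            rows = ec[out[:, col]]
            u = rng.random(N)
            out[:, col] = np.minimum((rows < u[:, None]).sum(axis=1), S)
    return out


# ---------------------------------------------------------------------------
# Per-family Monte-Carlo p-values
# ---------------------------------------------------------------------------


def _root_posteriors(counts, tree, model, error, S) -> np.ndarray:
    """Per-family root-size posterior over sizes 1..S (rows sum to 1)."""
    mats = _branch_matrices(tree, model, S)
    partial = _tip_partials(counts, tree, error, S)
    # replicate the pruning pass but keep the root partial vector
    for n in tree.postorder():
        if tree.is_tip(n):
            continue
        msgs = [partial.pop(ch) @ mats[ch].T for ch in tree.children[n]]
        p = msgs[0] * msgs[1]
        m = p.max(axis=1)
        partial[n] = p / np.where(m > 0, m, 1.0)[:, None]
    rootp = partial[tree.root][:, 1:]
    tot = rootp.sum(axis=1, keepdims=True)
    return rootp / np.where(tot > 0, tot, 1.0)


def family_pvalues(
    table: FamilyCountTable,
    tree: Chronogram,
    fitted: FitResult,
    n_mc: int = 1000,
    seed: int = 0,
    tie_break: str = "random",
    chunk: int = 100_000,
) -> pd.Series:
    """Monte-Carlo p-value per family under the fitted global model.

    For each family, ``n_mc`` profiles are simulated with root sizes drawn
    from that family's conditional root-size posterior; the p-value is
    ``(1 + k) / (1 + n_mc)`` where ``k`` is the observed log-likelihood's
    lower rank among the simulated ones.
    """
    if n_mc < 10:
        raise ValueError("n_mc must be at least 10")
    if n_mc < 100:
        import warnings

        warnings.warn("n_mc < 100 gives very coarse p-values", stacklevel=2)
    if tie_break not in ("random", "conservative"):
        raise ValueError(f"unknown tie_break {tie_break!r}")

    rng = np.random.default_rng(seed)
    model = fitted.model
    error = fitted.error if not fitted.error.is_zero else None
    S = fitted.S
    counts = table.df[tree.tip_labels].to_numpy()
    F = counts.shape[0]

    post = _root_posteriors(counts, tree, model, error, S)  # (F, S)
    cum = np.cumsum(post, axis=1)
    u = rng.random((F, n_mc))
    roots = 1 + (cum[:, None, :] < u[:, :, None]).sum(axis=2)  # (F, n_mc)
    roots = np.minimum(roots.reshape(-1), S)

    sims = _sample_profiles(tree, model, roots, S, rng, error)
    # redraw unobservable (all-zero) simulated profiles
    for _ in range(50):
        zero = sims.sum(axis=1) == 0
        if not zero.any():
            break
        sims[zero] = _sample_profiles(
            tree, model, roots[zero], S, rng, error
        )
    zero = sims.sum(axis=1) == 0

    sim_ll = np.empty(sims.shape[0])
    for lo in range(0, sims.shape[0], chunk):
        hi = min(lo + chunk, sims.shape[0])
        block = sims[lo:hi]
        ok = block.sum(axis=1) > 0
        vals = np.full(hi - lo, -np.inf)
        if ok.any():
            vals[ok] = table_log_likelihood(
                block[ok], tree, model, error, S=S,
                condition_on_survival=fitted.condition_on_survival,
            )
        sim_ll[lo:hi] = vals
    sim_ll[zero] = -np.inf
    sim_ll = sim_ll.reshape(F, n_mc)

    obs_ll = table_log_likelihood(
        counts, tree, model, error, S=S,
        condition_on_survival=fitted.condition_on_survival,
    )

    diff = sim_ll - obs_ll[:, None]
    less = (diff < -_TIE_TOL).sum(axis=1)
    ties = (np.abs(diff) <= _TIE_TOL).sum(axis=1)
    if tie_break == "conservative":
        k = less + ties
    else:
        k = less + rng.integers(0, ties + 1)
    p = (1.0 + k) / (1.0 + n_mc)
    return pd.Series(p, index=table.df.index, name="family_p")


# ---------------------------------------------------------------------------
# Simulation-based likelihood-ratio null
# ---------------------------------------------------------------------------


@dataclass
class LrtResult:
    """Null sample of 2*Delta-lnL and its empirical critical value."""

    sample: np.ndarray
    critical_value: float
    alpha: float
    n_sims: int
    n_families: int
    seed: int

    def pvalue(self, observed: float) -> float:
        s = np.maximum(self.sample, 0.0)
        return float((1 + (s >= observed).sum()) / (1 + len(s)))


def _embed_start(null_model: RateModel, alt_spec: RateModel) -> RateModel:
    """Alt-model start whose per-branch rates equal the fitted null's."""
    lams = np.empty(alt_spec.n_classes)
    mus = np.empty(alt_spec.n_classes)
    for k in range(alt_spec.n_classes):
        sel = alt_spec.branch_class == k
        sel[alt_spec.tree.root] = False
        if sel.any():
            nk = int(null_model.branch_class[sel][0])
        else:
            nk = 0
        lams[k] = null_model.lams[nk]
        mus[k] = null_model.mus[nk]
    return alt_spec.with_rates(lams, mus if not alt_spec.tied else lams)


def simulate_null_lrt(
    tree: Chronogram,
    fitted_null: FitResult,
    alt_spec: RateModel,
    n_sims: int = 1000,
    n_families: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    root_dist: str | tuple = "prior",
) -> LrtResult:
    """Null distribution of 2*Delta-lnL between nested rate models.

    Datasets of ``n_families`` are simulated under the fitted null model
    (root sizes from the fitting root prior by default), both models are
    refit to each (warm-started from the generating rates), and the empirical
    ``1 - alpha`` quantile of the clipped 2*Delta-lnL sample is returned as
    the critical value.
    """
    null_model = fitted_null.model
    if not null_model.nests_within(alt_spec):
        raise ValueError("alternative model does not nest the null")
    S = fitted_null.S
    error = fitted_null.error if not fitted_null.error.is_zero else None
    rng = np.random.default_rng(seed)
    tip_labels = tree.tip_labels

    stats = np.empty(n_sims)
    for i in range(n_sims):
        if root_dist == "prior":
            roots = rng.integers(1, S + 1, size=n_families)
        else:
            kind, param = root_dist
            if kind != "geometric":
                raise ValueError(f"unsupported root_dist {root_dist!r}")
            roots = np.minimum(rng.geometric(1.0 / param, size=n_families), S)
        sims = _sample_profiles(tree, null_model, roots, S, rng, error)
        sims = sims[sims.sum(axis=1) > 0]
        tb = FamilyCountTable(
            pd.DataFrame(
                sims,
                index=pd.Index([f"s{j}" for j in range(len(sims))], name="family_id"),
                columns=tip_labels,
            )
        )
        f0 = fit_model(
            tb, tree, null_model, error, n_restarts=1, seed=int(rng.integers(2**31)),
            S=S, condition_on_survival=fitted_null.condition_on_survival,
            start=null_model,
        )
        f1 = fit_model(
            tb, tree, alt_spec, error, n_restarts=1, seed=int(rng.integers(2**31)),
            S=S, condition_on_survival=fitted_null.condition_on_survival,
            start=_embed_start(f0.model, alt_spec),
        )
        stats[i] = 2.0 * (f0.neg_log_likelihood - f1.neg_log_likelihood)

    clipped = np.sort(np.maximum(stats, 0.0))
    idx = int(np.ceil((1.0 - alpha) * n_sims)) - 1
    crit = float(clipped[max(idx, 0)])
    return LrtResult(
        sample=stats,
        critical_value=crit,
        alpha=alpha,
        n_sims=n_sims,
        n_families=n_families,
        seed=seed,
    )
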