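"""Birth-death likelihood machinery for gene-family size evolution.

Family sizes evolve along each branch as a linear birth-death process: each
gene copy independently duplicates at rate lambda and is lost at rate mu (per
gene per million years); size 0 is absorbing (a family never re-originates).
The transition probability uses the classical closed form in terms of the
extinction coefficient alpha and growth coefficient beta,

    alpha = mu (e-1) / (lam e - mu),  beta = lam (e-1) / (lam e - mu),
    e = exp((lam-mu) t),

with alpha = beta = lam t / (1 + lam t) in the critical case lam = mu.  The
offspring distribution of one copy is P(0) = alpha and a geometric tail, and
the s-copy transition is the survivor-sum convolution

    P(c|s) = sum_j C(s,j) alpha^(s-j) (1-alpha)^j C(c-1,j-1) (1-beta)^j beta^(c-j)

evaluated in log space.

Observed tip counts may deviate from the truth through a +/-1 annotation-error
channel with per-species rate eps (``P(obs=true)=1-eps``, ``eps/2`` to either
neighbour, the inadmissible -1 mass at true=0 reflected onto obs=0).  Model
fitting maximizes the pruning likelihood over ancestral sizes 0..S under a
uniform root prior on sizes 1..S, with Nelder-Mead restarts in log-rate space,
and the annotation-error rate is estimated by a grid-then-refine profile
likelihood search in the spirit of CAFE's caferror procedure.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.special import gammaln, logsumexp, xlogy

from .phylo_io import Chronogram, FamilyCountTable

logger = logging.getLogger(__name__)

__all__ = [
    "ErrorModel",
    "RateModel",
    "FitResult",
    "transition_probability",
    "transition_matrix",
    "observation_probability",
    "observation_matrix",
    "family_log_likelihood",
    "table_log_likelihood",
    "fit_model",
    "estimate_error",
    "default_state_cap",
]

#: extra headroom above the maximum observed count when truncating the
#: ancestral state space
STATE_CAP_EXTRA = 10

#: |lam - mu| * t below which the critical-case formula is used
CRITICAL_SWITCH = 1e-8

#: top of the caferror-style epsilon search grid
ERROR_GRID_TOP = 0.4126


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------


def _alpha_beta(lam: float, mu: float, t: float) -> tuple[float, float]:
    if t <= 0:
        raise ValueError(f"branch duration must be positive (got {t})")
    if lam < 0 or mu < 0:
        raise ValueError("rates must be non-negative")
    if abs(lam - mu) * t < CRITICAL_SWITCH:
        a = lam * t / (1.0 + lam * t)
        return a, a
    e = math.exp((lam - mu) * t)
    denom = lam * e - mu
    alpha = mu * (e - 1.0) / denom
    beta = lam * (e - 1.0) / denom
    return alpha, beta


def _logchoose(n: np.ndarray, k: int) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    out = gammaln(n + 1) - gammaln(k + 1.0) - gammaln(n - k + 1)
    return np.where(n >= k, out, -np.inf)


_TENSOR_CACHE: dict[int, tuple] = {}


def _survivor_tensors(S: int) -> tuple:
    """Precomputed log-binomial tensors for the survivor-sum, keyed by S.

    Axes: parent size s = 1..S, child size c = 1..S, surviving lineages
    j = 1..S.  ``base[s,c,j]`` holds log C(s,j) + log C(c-1,j-1) (-inf where
    j exceeds s or c); ``ea``/``eb`` hold the alpha/beta exponents s-j and
    c-j clipped at 0 (invalid cells are already -inf in ``base``).
    """
    if S not in _TENSOR_CACHE:
        s = np.arange(1, S + 1)
        j = np.arange(1, S + 1)
        lcs = np.stack([_logchoose(s, int(k)) for k in j], axis=1)  # (S, S)
        lcc = np.stack([_logchoose(s - 1, int(k) - 1) for k in j], axis=1)
        with np.errstate(over="ignore"):
            bc = np.exp(lcs[:, None, :] + lcc[None, :, :])  # (s, c, j)
        bc[~np.isfinite(bc)] = 0.0  # unreachable for supported S
        ea = np.maximum(s[:, None] - j[None, :], 0)  # (s, j)
        eb = ea  # (c, j): same grid
        _TENSOR_CACHE[S] = (bc, ea, eb, j)
    return _TENSOR_CACHE[S]


def transition_matrix(S: int, lam: float, mu: float, t: float) -> np.ndarray:
    """(S+1)x(S+1) matrix ``P[s, c]`` of birth-death transition probabilities.

    Rows sum to 1 up to truncation at ``S``; state 0 is absorbing.
    """
    alpha, beta = _alpha_beta(lam, mu, t)
    P = np.zeros((S + 1, S + 1))
    P[0, 0] = 1.0
    if S == 0:
        return P
    s = np.arange(1, S + 1)
    P[1:, 0] = alpha ** s.astype(float)
    bc, ea, eb, j = _survivor_tensors(S)
    pow_a = alpha ** np.arange(S)  # alpha^0..alpha^(S-1); 0^0 = 1
    pow_b = beta ** np.arange(S)
    pj = ((1.0 - alpha) * (1.0 - beta)) ** j
    A2 = pow_a[ea] * pj[None, :]  # (s, j)
    B2 = pow_b[eb]  # (c, j)
    P[1:, 1:] = np.einsum("scj,sj,cj->sc", bc, A2, B2, optimize=True)
    return P


def transition_probability(s: int, c: int, lam: float, mu: float, t: float) -> float:
    """P(child size = c | parent size = s) for one branch of duration ``t``."""
    if s < 0 or c < 0:
        raise ValueError("sizes must be non-negative")
    if s == 0:
        _alpha_beta(lam, mu, t)  # still validate rates and t
        return 1.0 if c == 0 else 0.0
    S = max(s, c)
    return float(transition_matrix(S, lam, mu, t)[s, c])


# ---------------------------------------------------------------------------
# Annotation-error channel
# ---------------------------------------------------------------------------


def observation_probability(true_count: int, obs_count: int, eps: float) -> float:
    """P(observed count | true count) under the +/-1 error channel."""
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"error rate must be in [0, 1) (got {eps})")
    if true_count < 0 or obs_count < 0:
        raise ValueError("counts must be non-negative")
    if true_count == 0:
        if obs_count == 0:
            return 1.0 - eps / 2.0
        if obs_count == 1:
            return eps / 2.0
        return 0.0
    if obs_count == true_count:
        return 1.0 - eps
    if abs(obs_count - true_count) == 1:
        return eps / 2.0
    return 0.0


def observation_matrix(S: int, eps: float) -> np.ndarray:
    """(S+1)x(S+1) channel matrix ``E[true, obs]``.

    The column space is truncated at ``S``; mass that would land on obs = S+1
    is folded onto obs = S so rows still sum to 1.
    """
    if not 0.0 <= eps < 1.0:
        raise ValueError(f"error rate must be in [0, 1) (got {eps})")
    E = np.zeros((S + 1, S + 1))
    E[0, 0] = 1.0 - eps / 2.0
    if S >= 1:
        E[0, 1] = eps / 2.0
        idx = np.arange(1, S + 1)
        E[idx, idx] = 1.0 - eps
        E[idx, idx - 1] = eps / 2.0
        E[idx[:-1], idx[:-1] + 1] = eps / 2.0
        E[S, S] += eps / 2.0  # truncation fold
    else:
        E[0, 0] = 1.0
    return E


@dataclass
class ErrorModel:
    """Per-species annotation-error rates (scalar = shared global rate)."""

    eps: float | dict[str, float] = 0.0

    def eps_for(self, species: str) -> float:
        if isinstance(self.eps, dict):
            if species not in self.eps:
                raise KeyError(f"no error rate for species {species!r}")
            return float(self.eps[species])
        return float(self.eps)

    @property
    def is_zero(self) -> bool:
        if isinstance(self.eps, dict):
            return all(v == 0 for v in self.eps.values())
        return self.eps == 0


# ---------------------------------------------------------------------------
# Rate models over branch classes
# ---------------------------------------------------------------------------


@dataclass
class RateModel:
    """Branch-classed birth-death rates on a chronogram.

    ``branch_class[i]`` gives the rate class of the branch above node ``i``
    (the root entry is ignored).  Under ``tied=True`` a single turnover rate
    per class is used for both gain and loss (lambda = mu).
    """

    tree: Chronogram
    branch_class: np.ndarray
    lams: np.ndarray
    mus: np.ndarray
    tied: bool = True
    class_names: list[str] = field(default_factory=lambda: ["global"])

    def __post_init__(self) -> None:
        self.branch_class = np.asarray(self.branch_class, dtype=np.int64)
        self.lams = np.asarray(self.lams, dtype=float)
        self.mus = np.asarray(self.mus, dtype=float)
        if (self.lams < 0).any() or (self.mus < 0).any():
            raise ValueError("rates must be non-negative")
        if self.branch_class.max(initial=0) >= len(self.lams):
            raise ValueError("branch class without a rate")
        if self.tied and not np.array_equal(self.lams, self.mus):
            raise ValueError("tied model requires lambda = mu")

    @classmethod
    def single(cls, tree: Chronogram, lam: float = 1e-3, mu: float | None = None,
               tied: bool | None = None) -> "RateModel":
        if mu is None:
            mu = lam
            tied = True if tied is None else tied
        else:
            tied = (lam == mu) if tied is None else tied
        return cls(
            tree=tree,
            branch_class=np.zeros(tree.n_nodes, dtype=np.int64),
            lams=np.array([lam]),
            mus=np.array([mu]),
            tied=tied,
            class_names=["global"],
        )

    @classmethod
    def from_clades(cls, tree: Chronogram, clades: dict[str, list[str]],
                    tied: bool = True, lam: float = 1e-3,
                    mu: float | None = None) -> "RateModel":
        """Background class 0 plus one class per named clade.

        Each clade (given as a tip-label list) claims its MRCA's stem branch
        and every branch inside the clade; later entries override earlier
        ones, so nested specs are allowed.
        """
        bc = np.zeros(tree.n_nodes, dtype=np.int64)
        names = ["background"]
        for k, (name, tips) in enumerate(clades.items(), start=1):
            for i in tree.clade_node_indices(tips):
                bc[i] = k
            names.append(name)
        n = len(names)
        if mu is None:
            mu = lam
        if tied and lam != mu:
            raise ValueError("tied model requires lambda = mu")
        return cls(tree=tree, branch_class=bc, lams=np.full(n, lam),
                   mus=np.full(n, mu), tied=tied, class_names=names)

    @property
    def n_classes(self) -> int:
        return len(self.lams)

    @property
    def n_params(self) -> int:
        return self.n_classes if self.tied else 2 * self.n_classes

    def with_rates(self, lams, mus=None) -> "RateModel":
        lams = np.asarray(lams, dtype=float)
        mus = lams.copy() if mus is None else np.asarray(mus, dtype=float)
        return RateModel(self.tree, self.branch_class, lams, mus,
                         tied=self.tied, class_names=list(self.class_names))

    def nests_within(self, alt: "RateModel") -> bool:
        """True if this model is a special case of ``alt``.

        ``alt`` must partition branches at least as finely and may free
        lambda/mu where this model ties them.
        """
        if alt.tree != self.tree:
            return False
        if self.tied is False and alt.tied is True:
            return False
        for k in range(alt.n_classes):
            sel = (alt.branch_class == k)
            sel[alt.tree.root] = False
            if sel.any() and len(np.unique(self.branch_class[sel])) > 1:
                return False
        return True

    def rates_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lambda": self.lams, "mu": self.mus},
            index=pd.Index(self.class_names, name="rate_class"),
        )


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------


def default_state_cap(counts: np.ndarray) -> int:
    return int(np.max(counts)) + STATE_CAP_EXTRA


def _branch_matrices(tree: Chronogram, model: RateModel, S: int) -> dict[int, np.ndarray]:
    mats: dict[int, np.ndarray] = {}
    cache: dict[tuple, np.ndarray] = {}
    for i in range(tree.n_nodes):
        if i == tree.root:
            continue
        k = int(model.branch_class[i])
        key = (k, float(tree.blen[i]))
        if key not in cache:
            cache[key] = transition_matrix(S, model.lams[k], model.mus[k], tree.blen[i])
        mats[i] = cache[key]
    return mats


def _tip_partials(counts: np.ndarray, tree: Chronogram, error: ErrorModel | None,
                  S: int) -> dict[int, np.ndarray]:
    """Per-tip conditional likelihood arrays of shape (F, S+1)."""
    F = counts.shape[0]
    tips = tree.tip_indices
    partials: dict[int, np.ndarray] = {}
    for col, node in enumerate(tips):
        obs = counts[:, col]
        eps = error.eps_for(tree.labels[node]) if error is not None else 0.0
        if eps == 0.0:
            p = np.zeros((F, S + 1))
            p[np.arange(F), obs] = 1.0
        else:
            E = observation_matrix(S, eps)
            p = E[:, obs].T.copy()
        partials[node] = p
    return partials


def _prune(counts: np.ndarray, tree: Chronogram, mats: dict[int, np.ndarray],
           error: ErrorModel | None, S: int,
           root_prior: str | tuple = "uniform") -> np.ndarray:
    """Log-likelihood per row of ``counts`` (families x tips, tree tip order)."""
    F = counts.shape[0]
    partial = _tip_partials(counts, tree, error, S)
    logscale = np.zeros(F)
    for n in tree.postorder():
        if tree.is_tip(n):
            continue
        msgs = []
        for ch in tree.children[n]:
            msgs.append(partial.pop(ch) @ mats[ch].T)
        p = msgs[0] * msgs[1]
        m = p.max(axis=1)
        safe = np.where(m > 0, m, 1.0)
        logscale += np.where(m > 0, np.log(safe), -np.inf)
        partial[n] = p / safe[:, None]
    rootp = partial[tree.root]
    if root_prior == "uniform":
        L = rootp[:, 1:].mean(axis=1)
    elif isinstance(root_prior, tuple) and root_prior[0] == "point":
        L = rootp[:, int(root_prior[1])]
    else:
        raise ValueError(f"unknown root prior {root_prior!r}")
    with np.errstate(divide="ignore"):
        return np.log(L) + logscale


def _log_p_unobserved(tree: Chronogram, mats, error: ErrorModel | None,
                      S: int) -> float:
    """log P(all tips observed as zero) under the uniform 1..S root prior."""
    zero = np.zeros((1, len(tree.tip_indices)), dtype=np.int64)
    return float(_prune(zero, tree, mats, error, S)[0])


def table_log_likelihood(
    table: FamilyCountTable | np.ndarray,
    tree: Chronogram,
    rate_model: RateModel,
    error_model: ErrorModel | None = None,
    S: int | None = None,
    condition_on_survival: bool = False,
    root_prior: str | tuple = "uniform",
) -> np.ndarray:
    """Per-family log-likelihoods via post-order pruning.

    ``table`` may be a :class:`FamilyCountTable` or a (families x tips) array
    in ``tree.tip_labels`` order.  With ``condition_on_survival`` each family
    likelihood is divided by the probability that a family is observed at all
    (not zero at every tip), correcting the ascertainment of observable
    families.
    """
    if isinstance(table, FamilyCountTable):
        counts = table.df[tree.tip_labels].to_numpy()
    else:
        counts = np.asarray(table, dtype=np.int64)
        if counts.ndim == 1:
            counts = counts[None, :]
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("all-zero profile: family not observed at any tip")
    if S is None:
        S = default_state_cap(counts)
    if counts.max() > S:
        raise ValueError(
            f"state cap S={S} is below the maximum observed count "
            f"{counts.max()}; increase S"
        )
    mats = _branch_matrices(tree, rate_model, S)
    ll = _prune(counts, tree, mats, error_model, S, root_prior=root_prior)
    if condition_on_survival:
        lp0 = _log_p_unobserved(tree, mats, error_model, S)
        ll = ll - math.log1p(-math.exp(min(lp0, -1e-12)))
    return ll


def family_log_likelihood(
    profile,
    tree: Chronogram,
    rate_model: RateModel,
    error_model: ErrorModel | None = None,
    S: int | None = None,
    root_prior: str | tuple = "uniform",
) -> float:
    """Log-likelihood of one family's tip profile (mapping species -> count)."""
    prof = dict(profile)
    counts = np.array([[int(prof[sp]) for sp in tree.tip_labels]], dtype=np.int64)
    if S is None:
        S = default_state_cap(counts)
        if isinstance(root_prior, tuple) and root_prior[0] == "point":
            S = max(S, int(root_prior[1]) + STATE_CAP_EXTRA)
    return float(
        table_log_likelihood(counts, tree, rate_model, error_model, S=S,
                             root_prior=root_prior)[0]
    )


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass
class FitResult:
    """Outcome of a model fit: rates, error model, likelihood, diagnostics."""

    model: RateModel
    error: ErrorModel
    neg_log_likelihood: float
    per_family_ll: pd.Series
    restart_nlls: list[float]
    converged: bool
    S: int
    condition_on_survival: bool = True
    name: str = ""

    @property
    def n_params(self) -> int:
        return self.model.n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params + 2.0 * self.neg_log_likelihood

    def report(self) -> dict:
        eps = self.error.eps
        return {
            "model": self.name or ("tied" if self.model.tied else "free"),
            "classes": list(self.model.class_names),
            "lambda": [float(x) for x in self.model.lams],
            "mu": [float(x) for x in self.model.mus],
            "epsilon": eps if not isinstance(eps, dict)
            else {k: float(v) for k, v in eps.items()},
            "neg_log_likelihood": float(self.neg_log_likelihood),
            "aic": float(self.aic),
            "n_params": self.n_params,
            "converged": bool(self.converged),
            "restart_nlls": [float(x) for x in self.restart_nlls],
        }


def _pack(model: RateModel) -> np.ndarray:
    if model.tied:
        return np.log(np.maximum(model.lams, 1e-9))
    return np.log(np.maximum(np.concatenate([model.lams, model.mus]), 1e-9))


def _unpack(theta: np.ndarray, template: RateModel) -> RateModel:
    r = np.exp(np.clip(theta, np.log(1e-9), np.log(10.0)))
    k = template.n_classes
    if template.tied:
        return template.with_rates(r[:k], r[:k])
    return template.with_rates(r[:k], r[k:])


def _moments_start(counts: np.ndarray, depth: float) -> float:
    m = counts.mean(axis=1)
    v = counts.var(axis=1)
    r0 = float(np.median(v / (2.0 * np.maximum(m, 0.5) * depth)))
    return float(np.clip(r0, 1e-5, 0.05))


def fit_model(
    table: FamilyCountTable,
    tree: Chronogram,
    model_spec: RateModel,
    error_model: ErrorModel | None = None,
    n_restarts: int = 5,
    seed: int = 0,
    S: int | None = None,
    condition_on_survival: bool = True,
    start: RateModel | None = None,
    name: str = "",
) -> FitResult:
    """Maximize the summed family log-likelihood over the model's rates.

    Derivative-free Nelder-Mead search in log-rate space with ``n_restarts``
    jittered starts around a method-of-moments estimate (or ``start``); the
    fit is flagged converged when the two best restarts agree in -lnL within
    1e-4 (a single restart is reported as converged).
    """
    counts = table.df[tree.tip_labels].to_numpy()
    if (counts.sum(axis=1) == 0).any():
        raise ValueError("table contains all-zero families; filter them first")
    if S is None:
        S = default_state_cap(counts)
    rng = np.random.default_rng(seed)

    if start is not None:
        theta0 = _pack(start)
    else:
        r0 = _moments_start(counts, tree.depth)
        base = model_spec.with_rates(
            np.full(model_spec.n_classes, r0), np.full(model_spec.n_classes, r0)
        )
        theta0 = _pack(base)

    def objective(theta: np.ndarray) -> float:
        m = _unpack(theta, model_spec)
        ll = table_log_likelihood(
            counts, tree, m, error_model, S=S,
            condition_on_survival=condition_on_survival,
        )
        return -float(ll.sum())

    results = []
    for r in range(n_restarts):
        th = theta0.copy()
        if r > 0:
            th = th + rng.uniform(np.log(0.5), np.log(1.5), size=th.shape)
        res = minimize(
            objective, th, method="Nelder-Mead",
            options={"xatol": 1e-3, "fatol": 1e-4,
                     "maxfev": 300 * len(th) + 200},
        )
        results.append(res)
    nlls = sorted(float(r.fun) for r in results)
    best = min(results, key=lambda r: r.fun)
    converged = len(nlls) < 2 or (nlls[1] - nlls[0]) < 1e-4
    if not converged:
        logger.warning("restarts disagree: best -lnL %s vs %s", nlls[0], nlls[1])
    fitted = _unpack(best.x, model_spec)
    per_fam = table_log_likelihood(
        counts, tree, fitted, error_model, S=S,
        condition_on_survival=condition_on_survival,
    )
    return FitResult(
        model=fitted,
        error=error_model if error_model is not None else ErrorModel(0.0),
        neg_log_likelihood=float(best.fun),
        per_family_ll=pd.Series(per_fam, index=table.df.index),
        restart_nlls=[float(r.fun) for r in results],
        converged=converged,
        S=S,
        condition_on_survival=condition_on_survival,
        name=name,
    )


# ---------------------------------------------------------------------------
# Annotation-error estimation (caferror-style profile likelihood)
# ---------------------------------------------------------------------------


def _error_grid() -> list[float]:
    return [0.0] + [ERROR_GRID_TOP * 2.0 ** (-k) for k in range(6, -1, -1)]


def estimate_error(
    table: FamilyCountTable,
    tree: Chronogram,
    model_spec: RateModel,
    scope: str = "global",
    seed: int = 0,
    n_restarts: int = 2,
    max_cycles: int = 3,
    condition_on_survival: bool = True,
) -> tuple[ErrorModel, FitResult]:
    """Estimate annotation-error rates by profile likelihood.

    ``scope='global'``: one shared eps searched on a log-spaced grid
    (0 and 0.4126 * 2^-k) then refined by a bounded scalar search around the
    best grid point, jointly refitting rates at every candidate.
    ``scope='per_species'``: starting from the global optimum, species are
    cycled, each eps optimized on the grid with the others held fixed, until
    no eps changes by more than 1e-3.

    The returned fit is never worse than the eps = 0 fit (0 is on the grid).
    """
    if scope not in ("global", "per_species"):
        raise ValueError(f"unknown scope {scope!r}")
    species = tree.tip_labels
    missing = set(species) - set(table.species)
    if missing:
        raise ValueError(f"table missing species: {sorted(missing)}")

    cache: dict[tuple, FitResult] = {}
    warm: dict[str, RateModel] = {}

    def fit_at(eps_model: ErrorModel, key: tuple) -> FitResult:
        if key in cache:
            return cache[key]
        res = fit_model(
            table, tree, model_spec, eps_model, n_restarts=n_restarts,
            seed=seed, condition_on_survival=condition_on_survival,
            start=warm.get("best"),
        )
        warm.setdefault("best", res.model)
        if res.neg_log_likelihood <= min(
            (c.neg_log_likelihood for c in cache.values()), default=np.inf
        ):
            warm["best"] = res.model
        cache[key] = res
        return res

    # ---- global stage ----
    grid = _error_grid()
    for e in grid:
        fit_at(ErrorModel(e), ("g", round(e, 6)))
    best_e = min(grid, key=lambda e: cache[("g", round(e, 6))].neg_log_likelihood)
    i = grid.index(best_e)
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if hi > lo:
        minimize_scalar(
            lambda e: fit_at(ErrorModel(float(e)), ("g", round(float(e), 6))
                             ).neg_log_likelihood,
            bounds=(lo, hi), method="bounded",
            options={"xatol": 2e-3, "maxiter": 8},
        )
    gkey = min((k for k in cache if k[0] == "g"),
               key=lambda k: cache[k].neg_log_likelihood)
    gbest = float(gkey[1])
    if scope == "global":
        res = cache[gkey]
        return ErrorModel(gbest), res

    # ---- per-species stage ----
    eps = {sp: gbest for sp in species}
    key0 = ("s",) + tuple(sorted(eps.items()))
    fit_at(ErrorModel(dict(eps)), key0)
    for _ in range(max_cycles):
        max_change = 0.0
        for sp in species:
            best_val, best_nll = eps[sp], np.inf
            for e in grid:
                trial = dict(eps)
                trial[sp] = e
                k = ("s",) + tuple(sorted(trial.items()))
                nll = fit_at(ErrorModel(trial), k).neg_log_likelihood
                if nll < best_nll:
                    best_nll, best_val = nll, e
            max_change = max(max_change, abs(best_val - eps[sp]))
            eps[sp] = best_val
        if max_change <= 1e-3:
            break
    final_key = ("s",) + tuple(sorted(eps.items()))
    res = fit_at(ErrorModel(dict(eps)), final_key)
    return ErrorModel(dict(eps)), res
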