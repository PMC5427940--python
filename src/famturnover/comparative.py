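"""Trait-turnover correlation, raw and phylogenetically corrected.

Phylogenetic independent contrasts (PIC) follow Felsenstein's pruning scheme:
at each internal node of a binary tree the contrast between the two daughter
values is standardized by the square root of their summed (corrected) branch
lengths, the nodal value is the branch-length-weighted average of the
daughters, and the node's own branch is extended by b_i b_j / (b_i + b_j).
Under Brownian motion the n_tips - 1 standardized contrasts are i.i.d.
normal, so correlation between two contrasted traits is computed through the
origin with n - 1 degrees of freedom.  Raw associations use Spearman's rank
correlation with a seeded permutation p-value (appropriate at small n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .phylo_io import Chronogram

__all__ = [
    "ContrastSet",
    "CorrelationResult",
    "pic_contrasts",
    "correlate",
    "impute_cvalue",
]


@dataclass
class ContrastSet:
    """Standardized contrasts and nodal estimates from one PIC pass."""

    contrasts: pd.Series  # indexed by internal-node label
    node_values: pd.Series  # phylogenetically weighted nodal trait estimates
    corrected_lengths: pd.Series  # per-node corrected branch lengths


def pic_contrasts(tree: Chronogram, trait) -> ContrastSet:
    """Felsenstein's independent contrasts for one tip trait.

    ``trait`` is a mapping/Series of species -> value covering every tip.
    Contrast sign follows the tree's stored child order (contrasts are only
    defined up to sign).
    """
    tr = dict(trait) if not isinstance(trait, pd.Series) else trait.to_dict()
    missing = set(tree.tip_labels) - set(tr)
    if missing:
        raise ValueError(f"missing trait value for species: {sorted(missing)}")
    x = np.zeros(tree.n_nodes)
    v = np.zeros(tree.n_nodes)  # corrected branch length above each node
    contrasts = {}
    for n in tree.postorder():
        if tree.is_tip(n):
            val = float(tr[tree.labels[n]])
            if not np.isfinite(val):
                raise ValueError(
                    f"non-finite trait value for species {tree.labels[n]!r}"
                )
            x[n] = val
            v[n] = tree.blen[n]
        else:
            i, j = tree.children[n]
            contrasts[tree.labels[n]] = (x[i] - x[j]) / np.sqrt(v[i] + v[j])
            w = 1.0 / v[i] + 1.0 / v[j]
            x[n] = (x[i] / v[i] + x[j] / v[j]) / w
            v[n] = tree.blen[n] + v[i] * v[j] / (v[i] + v[j])
    internal = [tree.labels[n] for n in tree.postorder() if not tree.is_tip(n)]
    return ContrastSet(
        contrasts=pd.Series({k: contrasts[k] for k in internal}, name="contrast"),
        node_values=pd.Series({lab: x[tree.index(lab)] for lab in internal}),
        corrected_lengths=pd.Series(
            {tree.labels[n]: v[n] for n in range(tree.n_nodes)}
        ),
    )


@dataclass
class CorrelationResult:
    method: str
    use_pic: bool
    estimate: float
    p: float
    n: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "use_pic": self.use_pic,
            "estimate": float(self.estimate),
            "p": float(self.p),
            "n": int(self.n),
            "seed": self.seed,
        }


def _align(x, y, tree: Chronogram | None):
    if isinstance(x, pd.Series) and isinstance(y, pd.Series):
        common = x.index.intersection(y.index)
        if tree is not None:
            common = pd.Index(tree.tip_labels).intersection(common)
        return x.loc[common].to_numpy(float), y.loc[common].to_numpy(float), common
    return np.asarray(x, float), np.asarray(y, float), None


def correlate(
    x,
    y,
    method: str = "spearman",
    use_pic: bool = False,
    tree: Chronogram | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> CorrelationResult:
    """Correlation between two tip traits.

    Raw mode: Spearman (average-rank ties) or Pearson with a two-sided
    seeded permutation p-value.  PIC mode (requires ``tree`` and
    Series-like inputs keyed by species): both traits are contrasted on the
    same tree and the Pearson correlation through the origin is tested with
    a t statistic on n_contrasts - 1 degrees of freedom.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown method {method!r}")
    if use_pic:
        if tree is None:
            raise ValueError("PIC mode requires a tree")
        cx = pic_contrasts(tree, x).contrasts
        cy = pic_contrasts(tree, y).contrasts
        u = cx.to_numpy()
        w = cy.loc[cx.index].to_numpy()
        n = len(u)
        if n < 4:
            raise ValueError("need at least 4 contrasts")
        denom = np.sqrt((u**2).sum() * (w**2).sum())
        r = float((u * w).sum() / denom) if denom > 0 else 0.0
        df = n - 1
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * np.sqrt(df / (1.0 - r**2))
            p = 2.0 * float(stats.t.sf(abs(t), df))
        return CorrelationResult("pearson_through_origin", True, r, p, n)

    xv, yv, _ = _align(x, y, tree)
    n = len(xv)
    if n < 4:
        raise ValueError("need at least 4 paired observations")
    if len(yv) != n:
        raise ValueError("x and y must have equal length")

    def est(a, b) -> float:
        if method == "spearman":
            return float(stats.spearmanr(a, b).statistic)
        return float(stats.pearsonr(a, b).statistic)

    r = est(xv, yv)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        rp = est(xv, rng.permutation(yv))
        if abs(rp) >= abs(r) - 1e-12:
            hits += 1
    p = (1.0 + hits) / (1.0 + n_perm)
    return CorrelationResult(method, False, r, p, n, seed=seed)


def impute_cvalue(species: str, cvalue_db: pd.Series) -> tuple[float, str]:
    """Genome-size (C-value) lookup with genus-average imputation.

    Returns ``(value, flag)`` where flag is ``"direct"`` when the species has
    its own entry and ``"genus_mean"`` when the value is the arithmetic mean
    over congeners (genus = first underscore-delimited token of the label).
    """
    if species in cvalue_db.index:
        return float(cvalue_db.loc[species]), "direct"
    genus = species.split("_")[0]
    congeners = [sp for sp in cvalue_db.index if sp.split("_")[0] == genus]
    if not congeners:
        raise KeyError(
            f"no congeners of {species!r} (genus {genus!r}) in the C-value "
            "database; supply a value manually"
        )
    return float(cvalue_db.loc[congeners].mean()), "genus_mean"
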