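"""Parsimony mapping of gene gains, duplications and losses onto a species tree.

Each gene family is summarized as a copy-count profile over the tips.  The
family's origin is fixed to the MRCA of the species where it is observed
(hierarchical-orthologous-group semantics: the group is born at its defining
taxonomic level), and ancestral copy numbers inside the origin subtree are
reconstructed by Wagner parsimony — minimum total |copy-number change| — via
Sankoff dynamic programming with linear per-copy cost, so a duplication and a
loss are weighted equally.

Tie-breaking is deterministic: among minimum-cost states at a node, the state
closest to the parent's chosen state wins, then the smaller count; at the
origin the smallest minimum-cost state >= 1 wins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phylo_io import Chronogram, FamilyCountTable

__all__ = [
    "AncestralStateMap",
    "infer_family_origin",
    "ancestral_counts",
    "summarize_branch_events",
    "filter_lineage_presence",
    "filter_root_presence",
]

EVENT_COLUMNS = [
    "families_gained",
    "families_lost",
    "duplication_events",
    "loss_events",
    "expanded",
    "contracted",
]


@dataclass
class AncestralStateMap:
    """Reconstructed per-node copy numbers for one family."""

    family_id: str
    tree: Chronogram
    states: np.ndarray  # per node index, non-negative int
    origin: int  # node index where the family first exists
    cost: int  # minimum total |change| within the origin subtree

    def state_of(self, label: str) -> int:
        return int(self.states[self.tree.index(label)])


def _profile_array(profile, tree: Chronogram) -> np.ndarray:
    """Per-tip-index counts from a mapping/Series keyed by species label."""
    counts = np.zeros(tree.n_nodes, dtype=np.int64)
    seen = set()
    for sp, v in dict(profile).items():
        counts[tree.index(sp)] = int(v)
        seen.add(sp)
    missing = set(tree.tip_labels) - seen
    if missing:
        raise ValueError(f"profile missing species: {sorted(missing)}")
    return counts


def infer_family_origin(profile, tree: Chronogram) -> int:
    """MRCA node index of all species with a nonzero count."""
    counts = _profile_array(profile, tree)
    present = [tree.labels[i] for i in tree.tip_indices if counts[i] > 0]
    if not present:
        raise ValueError("family not observed in any species (all-zero profile)")
    return tree.mrca(present)


def ancestral_counts(profile, tree: Chronogram, family_id: str = "") -> AncestralStateMap:
    """Wagner-parsimony ancestral copy numbers for one family.

    Counts are fixed to 0 outside the origin subtree and the origin state is
    constrained to be >= 1.
    """
    counts = _profile_array(profile, tree)
    origin = infer_family_origin(profile, tree)

    smax = int(counts.max()) + 1
    states = np.arange(smax + 1)
    inf = np.iinfo(np.int64).max // 4

    # subtree membership
    in_sub = np.zeros(tree.n_nodes, dtype=bool)
    stack = [origin]
    while stack:
        n = stack.pop()
        in_sub[n] = True
        stack.extend(tree.children[n])

    # bottom-up Sankoff over the origin subtree
    cost = {}
    for n in tree.postorder():
        if not in_sub[n]:
            continue
        if tree.is_tip(n):
            c = np.full(smax + 1, inf, dtype=np.int64)
            c[counts[n]] = 0
        else:
            c = np.zeros(smax + 1, dtype=np.int64)
            for ch in tree.children[n]:
                child_cost = cost[ch]
                # min over s' of |s - s'| + child_cost[s']
                c = c + np.min(
                    np.abs(states[:, None] - states[None, :]) + child_cost[None, :],
                    axis=1,
                )
        cost[n] = c

    # origin state: smallest minimum-cost state >= 1
    oc = cost[origin][1:]
    best = int(np.min(oc))
    chosen = int(np.argmin(oc)) + 1  # argmin returns first (smallest) minimizer

    assign = np.zeros(tree.n_nodes, dtype=np.int64)
    assign[origin] = chosen
    # top-down: closest-to-parent tie-break, then smaller state
    order = [n for n in tree.preorder() if in_sub[n] and n != origin]
    for n in order:
        sp = assign[tree.parent[n]]
        tot = np.abs(sp - states) + cost[n]
        m = tot.min()
        cand = states[tot == m]
        d = np.abs(cand - sp)
        cand = cand[d == d.min()]
        assign[n] = int(cand.min())

    return AncestralStateMap(
        family_id=family_id, tree=tree, states=assign, origin=origin, cost=best
    )


def summarize_branch_events(
    maps, tree: Chronogram | None = None
) -> pd.DataFrame:
    """Aggregate per-branch event tallies over a collection of families.

    Rows are indexed by the branch's child-node label (the root row can only
    receive ``families_gained``, for families originating at the root).
    Columns: families_gained, families_lost, duplication_events, loss_events,
    expanded, contracted.
    """
    maps = list(maps)
    if tree is None:
        if not maps:
            raise ValueError("empty family set and no tree given")
        tree = maps[0].tree
    for m in maps:
        if m.tree is not tree and m.tree != tree:
            raise ValueError("ancestral state maps come from different trees")

    tally = np.zeros((tree.n_nodes, len(EVENT_COLUMNS)), dtype=np.int64)
    col = {name: k for k, name in enumerate(EVENT_COLUMNS)}
    for m in maps:
        tally[m.origin, col["families_gained"]] += 1
        stack = list(tree.children[m.origin])
        while stack:
            n = stack.pop()
            stack.extend(tree.children[n])
            par = m.states[tree.parent[n]]
            ch = m.states[n]
            d = int(ch) - int(par)
            if d > 0:
                tally[n, col["duplication_events"]] += d
                tally[n, col["expanded"]] += 1
            elif d < 0:
                tally[n, col["loss_events"]] += -d
                tally[n, col["contracted"]] += 1
                if ch == 0 and par > 0:
                    tally[n, col["families_lost"]] += 1
    return pd.DataFrame(tally, index=pd.Index(tree.labels, name="branch_child_node"),
                        columns=EVENT_COLUMNS)


def filter_lineage_presence(
    table: FamilyCountTable,
    tree: Chronogram,
    absent_clade,
    required_clades,
    min_present: int,
) -> list[str]:
    """Families absent from one clade but present in several others.

    Returns family ids with zero counts at every tip of ``absent_clade`` and
    a nonzero count in at least ``min_present`` of the ``required_clades``
    (a clade counts as present if any of its tips has a nonzero count).
    Clades are given as lists of tip labels (or a single tip label).
    """
    if min_present > len(required_clades):
        raise ValueError(
            f"min_present={min_present} exceeds the number of required clades "
            f"({len(required_clades)})"
        )

    def tips_of(clade) -> list[str]:
        if isinstance(clade, str):
            clade = [clade]
        return sorted(tree.tipset(tree.mrca(clade)))

    absent_tips = tips_of(absent_clade)
    req_tips = [tips_of(c) for c in required_clades]

    vals = table.df
    absent_ok = (vals[absent_tips].to_numpy() == 0).all(axis=1)
    present_n = np.zeros(len(vals), dtype=int)
    for tips in req_tips:
        present_n += (vals[tips].to_numpy() > 0).any(axis=1)
    keep = absent_ok & (present_n >= min_present)
    return [f for f, k in zip(table.families, keep) if k]


def filter_root_presence(table: FamilyCountTable, tree: Chronogram) -> list[str]:
    """Families inferred present at the tree root (origin MRCA = root).

    Mirrors restricting a model fit to families with at least one gene at the
    focal root of the phylogeny.
    """
    keep = []
    for fam in table.families:
        prof = table.profile(fam)
        if prof.sum() == 0:
            continue
        if infer_family_origin(prof, tree) == tree.root:
            keep.append(fam)
    return keep
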