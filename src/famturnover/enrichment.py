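"""Term enrichment of expanding/contracting family sets by Fisher's exact test.

The test is one-sided over-representation: for a term annotated on K of the N
population families and k of the n study families, the p-value is the upper
hypergeometric tail P(X >= k), X ~ Hypergeom(N, K, n).  The population
follows the parental-node convention: all families reconstructed as present
(copy number >= 1) at the parent of the branch under test.  Terms absent from
the population are skipped rather than reported at p = 1; the multiple-testing
burden m is the number of terms actually tested.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .event_mapping import AncestralStateMap
from .phylo_io import Chronogram
from .significance import adjust_pvalues

__all__ = [
    "define_population",
    "changed_families",
    "fisher_enrichment",
]


def define_population(
    branch: str,
    state_maps: dict[str, AncestralStateMap] | list[AncestralStateMap],
    tree: Chronogram | None = None,
) -> set[str]:
    """Families present at the parent node of the tested branch.

    ``branch`` names the branch by its child node.  For the root "branch"
    (no parent) the population is every family present at the root.
    """
    maps = (
        list(state_maps.values()) if isinstance(state_maps, dict) else list(state_maps)
    )
    if not maps:
        return set()
    tree = tree or maps[0].tree
    child = tree.index(branch)
    node = tree.parent[child] if child != tree.root else tree.root
    return {m.family_id for m in maps if m.states[node] >= 1}


def changed_families(
    branch: str,
    state_maps: dict[str, AncestralStateMap] | list[AncestralStateMap],
    tree: Chronogram | None = None,
) -> tuple[set[str], set[str]]:
    """(expanded, contracted) family sets on the branch to node ``branch``."""
    maps = (
        list(state_maps.values()) if isinstance(state_maps, dict) else list(state_maps)
    )
    if not maps:
        return set(), set()
    tree = tree or maps[0].tree
    child = tree.index(branch)
    if child == tree.root:
        raise ValueError("the root has no branch above it")
    parent = tree.parent[child]
    exp, con = set(), set()
    for m in maps:
        d = int(m.states[child]) - int(m.states[parent])
        if d > 0:
            exp.add(m.family_id)
        elif d < 0:
            con.add(m.family_id)
    return exp, con


def fisher_enrichment(
    study_set,
    population_set,
    term_map: dict[str, set[str]],
) -> pd.DataFrame:
    """One-sided over-representation test for every term seen in the population.

    Returns a DataFrame (index: term) with columns ``k`` (study count), ``n``
    (study size), ``K`` (population count), ``N`` (population size),
    ``p_raw`` and Bonferroni/Holm/Sidak-adjusted columns, sorted by ``p_raw``.
    """
    study = set(study_set)
    population = set(population_set)
    if not study <= population:
        raise ValueError("study set must be a subset of the population set")
    N = len(population)
    n = len(study)
    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for fam in population:
        for term in term_map.get(fam, ()):  # families without terms contribute nothing
            term_pop[term] = term_pop.get(term, 0) + 1
            if fam in study:
                term_study[term] = term_study.get(term, 0) + 1
    terms = sorted(term_pop)
    rows = []
    for term in terms:
        K = term_pop[term]
        k = term_study.get(term, 0)
        # upper tail P(X >= k)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append((term, k, n, K, N, min(p, 1.0)))
    df = pd.DataFrame(
        rows, columns=["term", "k", "n", "K", "N", "p_raw"]
    ).set_index("term")
    if len(df):
        for meth in ("bonferroni", "holm", "sidak"):
            df[f"p_{meth}"] = adjust_pvalues(df["p_raw"].to_numpy(), meth)
        df = df.sort_values("p_raw", kind="stable")
    else:
        for meth in ("bonferroni", "holm", "sidak"):
            df[f"p_{meth}"] = []
    return df
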