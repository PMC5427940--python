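import numpy as np
import pytest

from famturnover import (
    FamilyCountTable,
    RateModel,
    fit_model,
    laurasiatheria_tree,
    parse_chronogram,
    simulate_count_table,
)


@pytest.fixture(scope="session")
def fixture_tree():
    return laurasiatheria_tree()


@pytest.fixture(scope="session")
def three_tip_tree():
    return parse_chronogram("((A:1.0,B:1.0):1.0,C:2.0);")


def random_ultrametric_newick(rng: np.random.Generator, n_tips: int,
                              depth: float = 10.0) -> str:
    """Random binary ultrametric tree with distinct split times."""
    labels = [f"t{i}" for i in range(n_tips)]

    def build(labs, top):
        # returns "<subtree>:<branch length>" for a node whose parent
        # sits at time `top`
        if len(labs) == 1:
            return f"{labs[0]}:{depth - top:.9g}"
        split = rng.uniform(top + 0.05 * (depth - top), depth - 0.01)
        k = int(rng.integers(1, len(labs)))
        return (f"({build(labs[:k], split)},{build(labs[k:], split)})"
                f":{split - top:.9g}")

    s = build(labels, 0.0)
    return s[: s.rfind(":")] + ";"  # strip the root's branch length


def drop_unobserved(table: FamilyCountTable) -> FamilyCountTable:
    keep = table.values.sum(axis=1) > 0
    return FamilyCountTable(table.df.loc[keep])


@pytest.fixture(scope="session")
def null_study(fixture_tree):
    """2,000 families simulated under a tied global rate, plus its refit.

    Shared by the significance-calibration and recovery-adjacent tests.
    """
    truth = RateModel.single(fixture_tree, 0.0008)
    table, events, node_counts = simulate_count_table(
        fixture_tree, truth, 2000, root_dist=("geometric", 2.0), seed=11
    )
    observed = drop_unobserved(table)
    fit = fit_model(observed, fixture_tree, RateModel.single(fixture_tree),
                    n_restarts=2, seed=2)
    return {"table": observed, "fit": fit, "truth": truth,
            "events": events, "node_counts": node_counts}
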