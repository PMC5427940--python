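"""Input/output for dated species trees, gene-family count tables, traits and terms.

The central container is :class:`Chronogram`, an array-backed rooted binary
ultrametric tree with branch lengths in million years (My).  Newick parsing is
delegated to dendropy; the parsed tree is converted into flat parent/child
index arrays so that the likelihood and parsimony machinery elsewhere in the
package can run vectorized post-order sweeps.

Conventions
-----------
* Tip labels are species names; whitespace inside labels is normalized to
  underscores on ingestion (``"R. aegyptiacus"`` becomes ``"R._aegyptiacus"``)
  so labels match across count/trait/term tables.
* Trees must be strictly binary and ultrametric (relative tolerance 1e-6);
  polytomies and non-ultrametric trees are rejected rather than repaired.
* Count tables are TSV with a ``family_id`` first column and one column per
  species; trait tables are ``species<TAB>value`` with a header; term tables
  are header-less ``family_id<TAB>term1,term2,...``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Chronogram",
    "FamilyCountTable",
    "ChronogramError",
    "NewickParseError",
    "LAURASIATHERIA_NEWICK",
    "LAURASIATHERIA_CLADES",
    "parse_chronogram",
    "laurasiatheria_tree",
    "read_count_table",
    "write_count_table",
    "read_annotation_tables",
    "read_trait_table",
    "write_trait_table",
    "read_term_map",
    "write_term_map",
]

ULTRAMETRIC_RTOL = 1e-6

#: The 18-taxon dated laurasiatherian species tree used throughout as the
#: default fixture: eight bats (three Old World fruit bats, five
#: yangochiropterans), four carnivores, one perissodactyl and five
#: cetartiodactyls, with integer branch lengths in My and a root at 80 My
#: (the Scrotifera MRCA).
LAURASIATHERIA_NEWICK = (
    "(((R._aegyptiacus:24,(P._alecto:12,P._vampyrus:12):12):42,"
    "(M._natalensis:45,(E._fuscus:25,(M._davidii:14,"
    "(M._lucifugus:9,M._brandtii:9):5):11):20):21):14,"
    "((F._catus:55,(C._l._familiaris:46,(M._p._furo:40,A._melanoleuca:40):6):9):24,"
    "(E._caballus:78,(V._pacos:65,(S._scrofa:64,(T._truncatus:56,"
    "(O._aries:26,B._taurus:26):30):8):1):13):1):1);"
)

#: Named clades of the fixture tree (tip-label lists), used to build
#: multi-rate-class models and lineage-presence filters.
LAURASIATHERIA_CLADES: dict[str, list[str]] = {
    "bats": [
        "R._aegyptiacus", "P._alecto", "P._vampyrus", "M._natalensis",
        "E._fuscus", "M._davidii", "M._lucifugus", "M._brandtii",
    ],
    "owf": ["R._aegyptiacus", "P._alecto", "P._vampyrus"],
    "yango": [
        "M._natalensis", "E._fuscus", "M._davidii", "M._lucifugus", "M._brandtii",
    ],
    "carnivora": ["F._catus", "C._l._familiaris", "M._p._furo", "A._melanoleuca"],
    "perissodactyla": ["E._caballus"],
    "cetartiodactyla": [
        "V._pacos", "S._scrofa", "T._truncatus", "O._aries", "B._taurus",
    ],
}


class ChronogramError(ValueError):
    """A tree violates the chronogram contract (binary, dated, ultrametric)."""


class NewickParseError(ChronogramError):
    """Malformed Newick input."""


class Chronogram:
    """Rooted, strictly binary, ultrametric tree with branch lengths in My.

    Nodes are indexed 0..n_nodes-1 in preorder (root = 0).  ``parent[i]`` is
    the parent index (-1 for the root) and ``blen[i]`` the length of the
    branch above node ``i`` (0.0 for the root).
    """

    def __init__(self, labels: list[str], parent: np.ndarray, blen: np.ndarray):
        self.labels = list(labels)
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        n = len(self.labels)
        if not (len(self.parent) == len(self.blen) == n):
            raise ChronogramError("labels/parent/blen length mismatch")
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i, p in enumerate(self.parent):
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise ChronogramError("tree must have exactly one root")
        self.root = roots[0]
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self._index) != n:
            raise ChronogramError("node labels must be unique")
        self._tipsets: list[frozenset[str]] | None = None
        self._validate()

    # -- construction/validation ------------------------------------------

    def _validate(self) -> None:
        for i in range(self.n_nodes):
            nc = len(self.children[i])
            if nc not in (0, 2):
                raise ChronogramError(
                    f"tree must be strictly binary; node {self.labels[i]!r} "
                    f"has {nc} children (polytomy or unifurcation)"
                )
        for i in range(self.n_nodes):
            if i != self.root and not self.blen[i] > 0:
                raise ChronogramError(
                    f"branch above node {self.labels[i]!r} must have length > 0 "
                    f"(got {self.blen[i]})"
                )
        for i in self.tip_indices:
            if not self.labels[i]:
                raise ChronogramError("tip labels must be non-empty")
        depths = self.node_depths()
        tip_d = depths[self.tip_indices]
        dmax = tip_d.max()
        if dmax > 0 and (dmax - tip_d.min()) > ULTRAMETRIC_RTOL * dmax:
            worst = self.tip_indices[int(np.argmin(tip_d))]
            raise ChronogramError(
                f"tree is not ultrametric: tip {self.labels[worst]!r} has "
                f"root-to-tip depth {tip_d.min():g} vs maximum {dmax:g}"
            )

    # -- basic queries -----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    @property
    def tip_indices(self) -> np.ndarray:
        return np.array([i for i in range(self.n_nodes) if not self.children[i]])

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_tips(self) -> int:
        return len(self.tip_indices)

    def index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r} on the tree") from None

    def is_tip(self, i: int) -> bool:
        return not self.children[i]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            n = stack.pop()
            order.append(n)
            stack.extend(self.children[n])
        order.reverse()
        return order

    def preorder(self) -> list[int]:
        return list(reversed(self.postorder()))

    def node_depths(self) -> np.ndarray:
        """Root-to-node path length for every node."""
        d = np.zeros(self.n_nodes)
        for i in self.preorder():
            if i != self.root:
                d[i] = d[self.parent[i]] + self.blen[i]
        return d

    @property
    def depth(self) -> float:
        """Root-to-tip height of the (ultrametric) tree in My."""
        return float(self.node_depths()[self.tip_indices].max())

    def tipset(self, i: int) -> frozenset[str]:
        """Set of tip labels in the subtree rooted at node ``i``."""
        if self._tipsets is None:
            ts: list[frozenset[str] | None] = [None] * self.n_nodes
            for n in self.postorder():
                if self.is_tip(n):
                    ts[n] = frozenset([self.labels[n]])
                else:
                    acc: frozenset[str] = frozenset()
                    for c in self.children[n]:
                        acc = acc | ts[c]  # type: ignore[operator]
                    ts[n] = acc
            self._tipsets = ts  # type: ignore[assignment]
        return self._tipsets[i]  # type: ignore[return-value]

    def mrca(self, tip_labels) -> int:
        """Index of the most recent common ancestor of the given tips."""
        want = set(tip_labels)
        if not want:
            raise ValueError("mrca of an empty tip set is undefined")
        unknown = want - set(self.tip_labels)
        if unknown:
            raise KeyError(f"tips not on tree: {sorted(unknown)}")
        best = self.root
        # smallest subtree containing all wanted tips
        for i in self.postorder():
            if want <= self.tipset(i) and len(self.tipset(i)) < len(self.tipset(best)):
                best = i
        return best

    def clade_node_indices(self, tip_labels) -> list[int]:
        """All node indices within the clade spanned by ``tip_labels``
        (the MRCA and every descendant, including the MRCA itself so that the
        clade's stem branch is part of the clade)."""
        m = self.mrca(tip_labels)
        out = []
        stack = [m]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(self.children[n])
        return out

    # -- serialization -----------------------------------------------------

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if self.is_tip(i):
                core = self.labels[i]
            else:
                core = "(" + ",".join(render(c) for c in self.children[i]) + ")"
                if not self.labels[i].startswith("_node"):
                    core += self.labels[i]
            if i == self.root:
                return core
            return f"{core}:{self.blen[i]:.12g}"

        return render(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Chronogram {self.n_tips} tips, depth {self.depth:g} My>"

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Chronogram)
            and self.labels == other.labels
            and np.array_equal(self.parent, other.parent)
            and np.allclose(self.blen, other.blen, rtol=0, atol=1e-9)
        )

    def __hash__(self):
        return hash((tuple(self.labels), self.parent.tobytes()))


def _normalize_label(label: str) -> str:
    return "_".join(label.split())


def parse_chronogram(newick_text: str) -> Chronogram:
    """Parse a Newick string into a validated :class:`Chronogram`.

    Raises :class:`NewickParseError` for malformed input (the message names
    the offending position where dendropy reports one) and
    :class:`ChronogramError` for trees violating the chronogram contract.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick_text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error classes
        pos = ""
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        if line is not None:
            pos = f" at line {line}, column {col}"
        raise NewickParseError(f"malformed Newick{pos}: {exc}") from exc

    labels: list[str] = []
    parent: list[int] = []
    blen: list[float] = []
    index: dict[int, int] = {}
    auto = 0
    for node in dtree.preorder_node_iter():
        i = len(labels)
        index[id(node)] = i
        if node.is_leaf():
            if node.taxon is None or not (node.taxon.label or "").strip():
                raise ChronogramError("tip with empty label")
            lab = _normalize_label(node.taxon.label)
        else:
            lab = _normalize_label(node.label) if node.label else f"_node{auto}"
            auto += 1
        labels.append(lab)
        if node.parent_node is None:
            parent.append(-1)
            blen.append(0.0)
        else:
            parent.append(index[id(node.parent_node)])
            if node.edge.length is None:
                raise ChronogramError(
                    f"branch above node {lab!r} is missing a branch length"
                )
            blen.append(float(node.edge.length))
    return Chronogram(labels, np.array(parent), np.array(blen))


def laurasiatheria_tree() -> Chronogram:
    """The packaged 18-taxon laurasiatherian chronogram (depth 80 My)."""
    return parse_chronogram(LAURASIATHERIA_NEWICK)


# ---------------------------------------------------------------------------
# Family count tables
# ---------------------------------------------------------------------------


@dataclass
class FamilyCountTable:
    """Integer copy-count matrix, families x species.

    ``df`` is indexed by family id with one integer column per species.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        if self.df.index.has_duplicates:
            dup = self.df.index[self.df.index.duplicated()][0]
            raise ValueError(f"duplicate family id {dup!r}")
        if self.df.columns.has_duplicates:
            raise ValueError("duplicate species column")
        vals = self.df.to_numpy()
        if not np.issubdtype(vals.dtype, np.integer):
            raise ValueError("counts must be integers")
        if (vals < 0).any():
            r, c = np.argwhere(vals < 0)[0]
            raise ValueError(
                f"negative count at family {self.df.index[r]!r}, "
                f"species {self.df.columns[c]!r}"
            )

    @property
    def families(self) -> list[str]:
        return list(self.df.index)

    @property
    def species(self) -> list[str]:
        return list(self.df.columns)

    @property
    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def validate_against(self, tree: Chronogram) -> None:
        extra = set(self.species) - set(tree.tip_labels)
        if extra:
            raise ValueError(f"species not on tree: {sorted(extra)}")
        missing = set(tree.tip_labels) - set(self.species)
        if missing:
            raise ValueError(f"tree tips missing from table: {sorted(missing)}")
        if (self.values.sum(axis=1) == 0).any():
            bad = self.df.index[self.values.sum(axis=1) == 0][0]
            raise ValueError(f"family {bad!r} has no nonzero counts")

    def profile(self, family: str) -> pd.Series:
        return self.df.loc[family]


def read_count_table(path, tree: Chronogram | None = None) -> FamilyCountTable:
    """Read a TSV count table (``family_id<TAB>sp1<TAB>sp2...`` with header)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        for i, raw in enumerate(df[col]):
            try:
                v = int(str(raw))
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {raw!r} at family {df.index[i]!r}, "
                    f"species {col!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"negative count at family {df.index[i]!r}, species {col!r}"
                )
            mat[i, j] = v
    table = FamilyCountTable(pd.DataFrame(mat, index=df.index, columns=df.columns))
    if tree is not None:
        table.validate_against(tree)
    return table


def write_count_table(table: FamilyCountTable, path) -> None:
    table.df.to_csv(path, sep="\t", index_label="family_id")


# ---------------------------------------------------------------------------
# Trait and term tables
# ---------------------------------------------------------------------------


def read_trait_table(path) -> pd.Series:
    """Read a ``species<TAB>value`` TSV (header required) into a float Series."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] != 2:
        raise ValueError("trait table must have exactly two columns")
    species = df.iloc[:, 0].astype(str)
    if species.duplicated().any():
        dup = species[species.duplicated()].iloc[0]
        raise ValueError(f"duplicate species row {dup!r} in trait table")
    try:
        values = df.iloc[:, 1].astype(float)
    except ValueError as exc:
        raise ValueError(f"unparseable trait value: {exc}") from None
    if not np.isfinite(values).all():
        bad = species[~np.isfinite(values)].iloc[0]
        raise ValueError(f"non-finite trait value for species {bad!r}")
    s = pd.Series(values.to_numpy(), index=pd.Index(species, name="species"))
    s.name = df.columns[1]
    return s


def write_trait_table(trait: pd.Series, path, value_name: str | None = None) -> None:
    name = value_name or trait.name or "value"
    df = pd.DataFrame({"species": trait.index, name: trait.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def read_term_map(path) -> dict[str, set[str]]:
    """Read a header-less ``family_id<TAB>term1,term2,...`` TSV."""
    out: dict[str, set[str]] = {}
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
    else:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    for ln in lines:
        if not ln.strip():
            continue
        parts = ln.split("\t")
        fam = parts[0]
        terms = set()
        if len(parts) > 1 and parts[1].strip():
            terms = {t.strip() for t in parts[1].split(",") if t.strip()}
        if fam in out:
            out[fam] |= terms
        else:
            out[fam] = terms
    return out


def write_term_map(term_map: dict[str, set[str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for fam in term_map:
            fh.write(f"{fam}\t{','.join(sorted(term_map[fam]))}\n")


def read_annotation_tables(
    trait_path, term_path, table: FamilyCountTable | None = None
):
    """Read trait and term tables together.

    Term-map families absent from ``table`` are kept but logged; they are
    ignored downstream.
    """
    trait = read_trait_table(trait_path)
    terms = read_term_map(term_path)
    if table is not None:
        extra = set(terms) - set(table.families)
        if extra:
            logger.warning(
                "%d term-map families are not in the count table (ignored)",
                len(extra),
            )
    return trait, terms
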