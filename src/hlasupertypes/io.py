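"""Readers and writers for affinity tables, amino-acid index tables and annotated trees.

The in-memory containers are thin wrappers around :class:`pandas.DataFrame`:
an :class:`AffinityMatrix` holds alleles x peptides IC50 values in nM plus a
locus label (DR/DQ/DP) per allele; an :class:`IndexTable` holds K
physicochemical indices x 20 standard amino acids.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

STANDARD_AAS = tuple("ACDEFGHIKLMNPQRSTVWY")

#: allele-name prefix -> locus, for the beta-chain gene names used throughout
LOCUS_PREFIXES = {"DRB": "DR", "DQB": "DQ", "DPB": "DP"}

#: the 15 beta-chain positions forming the linear binding motif
DEFAULT_BETA_POSITIONS = (9, 11, 13, 28, 30, 37, 47, 57, 60, 61, 67, 70, 71, 74, 78)


class ParseError(ValueError):
    """A malformed input file (non-numeric cell, empty table, bad layout)."""


def infer_locus(allele_id: str) -> str:
    """Locus (DR/DQ/DP) from an allele name such as ``DRB1*0101``.

    Raises ``KeyError`` when the name does not start with a known beta-chain
    gene prefix.
    """
    for prefix, locus in LOCUS_PREFIXES.items():
        if allele_id.upper().startswith(prefix):
            return locus
    raise KeyError(f"cannot infer locus from allele name {allele_id!r}; "
                   f"known prefixes: {sorted(LOCUS_PREFIXES)}")


@dataclass
class AffinityMatrix:
    """Alleles x peptides IC50 values (nM), with per-allele locus labels.

    ``values`` is indexed by allele id (rows) and peptide id (columns);
    missing measurements are NaN, never zero.
    """

    values: pd.DataFrame
    locus_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("allele and peptide ids must be unique")
        present = self.values.to_numpy(dtype=float)
        if np.any(present[~np.isnan(present)] <= 0):
            raise ValueError("IC50 values must be strictly positive where present")
        missing = set(self.values.index) - set(self.locus_of)
        if missing:
            raise ValueError(f"locus_of missing for alleles: {sorted(missing)}")

    @property
    def allele_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class IndexTable:
    """K amino-acid indices x 20 standard amino acids.

    ``values`` is indexed by index id (rows) with one column per amino acid.
    ``standardized`` records whether each index was scaled to mean 0 / sd 1
    across the 20 amino acids (the default on load, so that Euclidean
    distances between encodings are not dominated by index units).
    """

    values: pd.DataFrame
    standardized: bool = True

    def __post_init__(self) -> None:
        missing = set(STANDARD_AAS) - set(self.values.columns)
        if missing:
            raise ValueError(f"index table lacks amino acids: {sorted(missing)}")
        if self.values[list(STANDARD_AAS)].isna().any().any():
            bad = self.values.index[self.values[list(STANDARD_AAS)].isna().any(axis=1)]
            raise ValueError(f"missing cells in indices: {list(bad)}")
        self.values = self.values[list(STANDARD_AAS)].astype(float)

    @property
    def index_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_indices(self) -> int:
        return len(self.values)

    def lookup(self, index_id: str, aa: str) -> float:
        return float(self.values.at[index_id, aa])


def _looks_like_alleles(labels) -> bool:
    hits = sum(1 for s in labels if re.match(r"^(DRB|DQB|DPB)", str(s).upper()))
    return hits >= max(1, len(labels) // 2)


def read_affinity_table(path, locus_map: Mapping[str, str] | str | Path | None = None,
                        orientation: str = "auto") -> AffinityMatrix:
    """Read a CSV/TSV IC50 table into an :class:`AffinityMatrix`.

    Parameters
    ----------
    path
        Delimited text file; first column holds row ids, first row column ids.
        The delimiter is sniffed (tab if any tab appears in the header line).
    locus_map
        Optional mapping allele -> locus, or path to a two-column TSV of the
        same; by default loci are inferred from allele-name prefixes.
    orientation
        ``"alleles-rows"``, ``"alleles-cols"`` or ``"auto"`` (detect which
        axis carries allele-like names; rows win a tie).
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty affinity table")
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.empty:
        raise ParseError(f"{path}: no data rows")

    if orientation == "auto":
        if _looks_like_alleles(df.index):
            pass
        elif _looks_like_alleles(df.columns):
            df = df.T
        # else keep rows-as-alleles; locus resolution below will complain
    elif orientation == "alleles-cols":
        df = df.T
    elif orientation != "alleles-rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna() & (df.astype(str).apply(lambda c: c.str.strip()) != "")
    if bad.any().any():
        r = bad.index[bad.any(axis=1)][0]
        c = bad.columns[bad.loc[r]][0]
        raise ParseError(f"{path}: non-numeric cell at row {r!r}, column {c!r}: "
                         f"{df.at[r, c]!r}")

    if locus_map is None:
        locus_of = {a: infer_locus(str(a)) for a in numeric.index}
    elif isinstance(locus_map, (str, Path)):
        lm = pd.read_csv(locus_map, sep=None, engine="python", header=None,
                         names=["allele", "locus"])
        locus_of = dict(zip(lm["allele"].astype(str), lm["locus"].astype(str)))
    else:
        locus_of = dict(locus_map)
    locus_of = {str(a): locus_of[str(a)] for a in numeric.index}
    numeric.index = numeric.index.astype(str)
    numeric.columns = numeric.columns.astype(str)
    return AffinityMatrix(values=numeric, locus_of=locus_of)


def _read_bundled(name: str) -> str:
    return resources.files("hlasupertypes.data").joinpath(name).read_text()


def load_beta_positions() -> tuple[int, ...]:
    """The bundled 15 beta-chain motif positions."""
    return tuple(int(x) for x in _read_bundled("beta_positions.txt").split())


def load_index_table(name_or_path: str | Path = "hqi24-like",
                     standardize: bool = True) -> IndexTable:
    """Load an amino-acid index table.

    ``"hqi24-like"`` loads the bundled 24-index stand-in fixture (four
    well-known scales plus twenty synthetic indices; see the file header).
    Any other value is treated as a path to a TSV with an ``index`` column
    followed by one column per amino acid. Each index is standardized to
    mean 0, sd 1 over the 20 amino acids unless ``standardize=False``.
    """
    if str(name_or_path) == "hqi24-like":
        from io import StringIO
        df = pd.read_csv(StringIO(_read_bundled("hqi24_standin.tsv")),
                         sep="\t", comment="#", index_col=0)
    else:
        df = pd.read_csv(name_or_path, sep="\t", comment="#", index_col=0)
    table = IndexTable(values=df, standardized=False)
    if standardize:
        v = table.values
        table = IndexTable(
            values=v.sub(v.mean(axis=1), axis=0).div(v.std(axis=1, ddof=0), axis=0),
            standardized=True)
    return table


# ---------------------------------------------------------------------------
# Annotated Newick serialization
# ---------------------------------------------------------------------------

_ANNOT_KEYS = ("au", "bp", "v", "c", "se_au")


def _node_label(node) -> str:
    ann = node.annotation
    missing = [k for k in ("au", "bp") if ann.get(k) is None]
    if missing:
        raise ValueError(f"internal edge over {sorted(node.leaves)} lacks "
                         f"annotations: {missing}")
    return "&".join(f"{k}={ann.get(k):.6g}" for k in _ANNOT_KEYS
                    if ann.get(k) is not None)


def write_annotated_newick(tree, path) -> None:
    """Serialize an annotated dendrogram as Newick.

    AU/BP (and the fitted v, c, se) ride as internal-node labels of the form
    ``au=0.97&bp=0.93&...``; branch lengths encode merge heights. Every
    internal non-root edge must carry AU and BP annotations.
    """

    def render(node, parent_height) -> str:
        blen = (max(parent_height - node.height, 0.0)
                if parent_height is not None else 0.0)
        if node.is_leaf:
            return f"{node.leaves[0]}:{blen:.6g}"
        children = ",".join(render(ch, node.height) for ch in node.children)
        label = f"'{_node_label(node)}'" if parent_height is not None else ""
        tail = f":{blen:.6g}" if parent_height is not None else ""
        return f"({children}){label}{tail}"

    root = tree.root
    Path(path).write_text(render(root, None) + ";\n")


@dataclass
class _ReadNode:
    leaves: tuple[str, ...]
    height: float
    children: list = field(default_factory=list)
    annotation: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ReadTree:
    """Topology + annotations recovered from an annotated Newick file."""
    root: _ReadNode

    def internal_nodes(self):
        out = []

        def walk(n):
            if not n.is_leaf:
                out.append(n)
                for c in n.children:
                    walk(c)
        walk(self.root)
        return out

    def clades(self) -> dict[frozenset, dict]:
        return {frozenset(n.leaves): dict(n.annotation)
                for n in self.internal_nodes()}


def read_annotated_newick(path) -> ReadTree:
    """Parse a Newick file written by :func:`write_annotated_newick`."""
    import dendropy

    dtree = dendropy.Tree.get(path=str(path), schema="newick",
                              suppress_internal_node_taxa=True)

    def convert(dnode, height_above) -> _ReadNode:
        blen = dnode.edge.length or 0.0
        if dnode.is_leaf():
            return _ReadNode(leaves=(dnode.taxon.label.replace(" ", "_"),),
                             height=0.0)
        children = [convert(c, None) for c in dnode.child_nodes()]
        height = max((_subtree_height(c) for c in children), default=0.0)
        node = _ReadNode(
            leaves=tuple(sorted(l for c in children for l in c.leaves)),
            height=height, children=children)
        label = dnode.taxon.label if dnode.taxon else dnode.label
        if label:
            for part in str(label).replace(" ", "_").split("&"):
                if "=" in part:
                    k, _, val = part.partition("=")
                    node.annotation[k] = float(val)
        return node

    def _subtree_height(n: _ReadNode) -> float:
        return n.height

    # recover heights from branch lengths (leaf depth 0, ultrametric writer)
    def set_heights(dnode) -> float:
        if dnode.is_leaf():
            return 0.0
        return max(set_heights(c) + (c.edge.length or 0.0)
                   for c in dnode.child_nodes())

    root = convert(dtree.seed_node, None)

    def fix(dnode, rnode):
        if dnode.is_leaf():
            rnode.height = 0.0
            return
        rnode.height = set_heights(dnode)
        for dc, rc in zip(dnode.child_nodes(), rnode.children):
            fix(dc, rc)

    fix(dtree.seed_node, root)
    return ReadTree(root=root)
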