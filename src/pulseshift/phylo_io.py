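"""Trees, expression tables, and the steps that turn relative-abundance
data into per-toxin continuous trait vectors.

The analysis operates on a rooted, ultrametric, time-calibrated phylogeny
(branch lengths in millions of years) and a species x toxin-family table of
relative expression fractions, possibly with several replicate transcriptomes
per species.  Before any model fitting the table is (i) filtered to toxin
families detected in a minimum fraction of species, (ii) reduced to species
means scaled by the average within-species variance, and (iii) aligned with
the tree by pruning both to their shared species.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: relative tolerance on tip-height spread when checking ultrametricity
ULTRAMETRIC_RTOL = 1e-6


class TimeTree:
    """Rooted ultrametric phylogeny with branch lengths in time units.

    Nodes carry integer ids ``0 .. n_nodes-1`` assigned in preorder, with the
    root at id 0.  ``parent[i]`` is the parent id (-1 for the root) and
    ``lengths[i]`` the length of the branch subtending node ``i`` (0 for the
    root).  Polytomies are preserved as-is.

    Invariants enforced at construction: exactly one root, all non-root
    branch lengths strictly positive, unique tip labels, and all tip depths
    equal within ``ULTRAMETRIC_RTOL`` relative tolerance.
    """

    def __init__(self, parent, lengths, labels, *, check=True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.lengths = np.asarray(lengths, dtype=float)
        self.labels = list(labels)
        n = self.parent.shape[0]
        if not (self.lengths.shape[0] == n and len(self.labels) == n):
            raise ValueError("parent, lengths and labels must have equal length")
        self.children: list[list[int]] = [[] for _ in range(n)]
        roots = []
        for i in range(n):
            p = int(self.parent[i])
            if p < 0:
                roots.append(i)
            else:
                self.children[p].append(i)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        # preorder / postorder traversals (iterative; trees can be deep)
        pre, post, stack = [], [], [self.root]
        while stack:
            v = stack.pop()
            pre.append(v)
            stack.extend(reversed(self.children[v]))
        seen = [False] * n
        stack = [self.root]
        while stack:
            v = stack[-1]
            if seen[v]:
                stack.pop()
                post.append(v)
            else:
                seen[v] = True
                stack.extend(reversed(self.children[v]))
        self.preorder = np.array(pre, dtype=np.int64)
        self.postorder = np.array(post, dtype=np.int64)
        # node depths: time from root to node
        self.node_depths = np.zeros(n)
        for v in pre:
            p = int(self.parent[v])
            if p >= 0:
                self.node_depths[v] = self.node_depths[p] + self.lengths[v]
        if check:
            self._validate()

    # ------------------------------------------------------------------
    def _validate(self):
        nonroot = np.arange(self.n_nodes) != self.root
        if np.any(~np.isfinite(self.lengths[nonroot])):
            bad = int(np.flatnonzero(nonroot & ~np.isfinite(self.lengths))[0])
            raise ValueError(f"missing branch length at node {self._name(bad)}")
        if np.any(self.lengths[nonroot] <= 0):
            bad = int(np.flatnonzero(nonroot & (self.lengths <= 0))[0])
            raise ValueError(
                f"non-positive branch length at node {self._name(bad)}"
            )
        tips = self.tip_indices
        labels = [self.labels[i] for i in tips]
        if any(l is None or l == "" for l in labels):
            raise ValueError("all tips must be labelled")
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate tip labels: {dupes}")
        depths = self.node_depths[tips]
        spread = float(depths.max() - depths.min())
        if spread > ULTRAMETRIC_RTOL * max(depths.max(), 1.0):
            raise ValueError(
                f"tree is not ultrametric: tip-height spread {spread:.6g} "
                f"exceeds tolerance {ULTRAMETRIC_RTOL:g} (relative to depth "
                f"{depths.max():.6g})"
            )

    def _name(self, i: int) -> str:
        if self.labels[i]:
            return repr(self.labels[i])
        below = [self.labels[j] for j in self.descendant_tips(i)]
        return f"(internal node above {below[:3]})"

    # ------------------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.parent.shape[0]

    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def n_tips(self) -> int:
        return int(self.is_tip.sum())

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def depth(self) -> float:
        """Root-to-tip depth (time units)."""
        return float(self.node_depths[self.tip_indices].max())

    @property
    def node_heights(self) -> np.ndarray:
        """Time before present of every node (tips ~ 0, root = depth)."""
        return self.depth - self.node_depths

    @property
    def total_branch_length(self) -> float:
        return float(self.lengths.sum())

    def descendant_tips(self, node: int) -> list[int]:
        out, stack = [], [node]
        while stack:
            v = stack.pop()
            if self.is_tip[v]:
                out.append(v)
            stack.extend(self.children[v])
        return out

    def mrca(self, labels) -> int:
        """Most recent common ancestor of the given tip labels."""
        want = set(labels)
        idx = [i for i in self.tip_indices if self.labels[i] in want]
        if len(idx) != len(want):
            missing = want - set(self.tip_labels)
            raise KeyError(f"tips not in tree: {sorted(missing)}")
        paths = []
        for i in idx:
            path = []
            v = i
            while v != -1:
                path.append(v)
                v = int(self.parent[v])
            paths.append(set(path))
        common = set.intersection(*paths)
        return max(common, key=lambda v: self.node_depths[v])

    def clade_nodes(self, labels) -> np.ndarray:
        """All node ids in the crown clade spanned by the given tips
        (the MRCA and everything below it)."""
        m = self.mrca(labels)
        out, stack = [], [m]
        while stack:
            v = stack.pop()
            out.append(v)
            stack.extend(self.children[v])
        return np.array(sorted(out), dtype=np.int64)

    def with_lengths(self, new_lengths) -> "TimeTree":
        """Copy of the tree with replaced branch lengths (no ultrametricity
        or positivity re-check: used by model-specific branch rescalings)."""
        return TimeTree(self.parent, new_lengths, self.labels, check=False)

    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "TimeTree":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        labels: list[str | None] = [None] * len(nodes)
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                if nd.edge.length is None:
                    name = (
                        nd.taxon.label
                        if nd.taxon is not None
                        else (nd.label or f"internal node #{i}")
                    )
                    raise ValueError(f"missing branch length at node {name!r}")
                lengths[i] = float(nd.edge.length)
            if nd.taxon is not None:
                labels[i] = nd.taxon.label
            elif nd.label:
                labels[i] = nd.label
        return cls(parent, lengths, labels)

    @classmethod
    def from_newick(cls, source) -> "TimeTree":
        """Parse a Newick tree from a path, file object or string."""
        if hasattr(source, "read"):
            data = source.read()
        elif isinstance(source, (str, os.PathLike)) and os.path.exists(source):
            with open(source) as fh:
                data = fh.read()
        else:
            data = str(source)
        from dendropy.dataio.newickreader import NewickReader

        try:
            dtree = dendropy.Tree.get(
                data=data, schema="newick", preserve_underscores=True
            )
        except NewickReader.NewickReaderDuplicateTaxonError as exc:
            raise ValueError(f"duplicate tip labels: {exc}") from None
        return cls.from_dendropy(dtree)

    def to_newick(self, comments: dict[int, str] | None = None) -> str:
        """Serialize to Newick; ``comments`` maps node id -> bracket comment
        (e.g. ``"&rate=0.52"``) appended after the branch length."""

        def fmt(v: int) -> str:
            lab = self.labels[v] or ""
            if any(c in lab for c in " (),:;[]'"):
                lab = "'" + lab.replace("'", "''") + "'"
            if self.children[v]:
                inner = ",".join(fmt(c) for c in self.children[v])
                s = f"({inner}){lab}"
            else:
                s = lab
            if v != self.root:
                s += f":{self.lengths[v]:.10g}"
                if comments and v in comments:
                    s += f"[{comments[v]}]"
            return s

        return fmt(self.root) + ";"

    # ------------------------------------------------------------------
    def prune_to_tips(self, keep_labels) -> "TimeTree":
        """Prune to the given tips, collapsing degree-2 internal nodes by
        summing branch lengths.  The root is retained even if it is left
        with a single child, so root-to-tip depth is unchanged."""
        keep = set(keep_labels)
        missing = keep - set(self.tip_labels)
        if missing:
            raise KeyError(f"tips not in tree: {sorted(missing)}")

        new_parent: list[int] = []
        new_lengths: list[float] = []
        new_labels: list[str | None] = []

        def add(parent_id: int, length: float, label) -> int:
            new_parent.append(parent_id)
            new_lengths.append(length)
            new_labels.append(label)
            return len(new_parent) - 1

        def build(v: int, parent_id: int, acc_len: float):
            if self.is_tip[v]:
                if self.labels[v] in keep:
                    add(parent_id, acc_len + self.lengths[v], self.labels[v])
                return
            live = [
                c
                for c in self.children[v]
                if any(self.labels[t] in keep for t in self.descendant_tips(c))
            ]
            if v == self.root:
                me = add(parent_id, 0.0, self.labels[v])
                for c in live:
                    build(c, me, 0.0)
            elif len(live) >= 2:
                me = add(parent_id, acc_len + self.lengths[v], self.labels[v])
                for c in live:
                    build(c, me, 0.0)
            else:  # degree-2 pass-through: extend the running branch
                build(live[0], parent_id, acc_len + self.lengths[v])

        build(self.root, -1, 0.0)
        return TimeTree(new_parent, new_lengths, new_labels)


def read_newick(path) -> TimeTree:
    """Read and validate a time tree from a Newick file (or string)."""
    return TimeTree.from_newick(path)


# ----------------------------------------------------------------------
# expression tables


@dataclass
class ExpressionTable:
    """Species x toxin-family table of relative expression fractions.

    ``values`` has one row per replicate transcriptome (index = species
    label, repeated for replicate rows) and one column per toxin family.
    """

    values: pd.DataFrame

    def __post_init__(self):
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("expression values must be finite")
        if np.any(arr < 0):
            raise ValueError("expression values must be non-negative")
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("toxin labels must be unique")

    @property
    def species(self) -> list[str]:
        seen, out = set(), []
        for s in self.values.index:
            if s not in seen:
                seen.add(s)
                out.append(s)
        return out

    @property
    def toxin_families(self) -> list[str]:
        return list(self.values.columns)

    def n_replicates(self, species: str) -> int:
        return int((self.values.index == species).sum())


def read_expression_table(path, delimiter: str | None = None) -> ExpressionTable:
    """Read a delimited expression table (first column species, header of
    toxin labels).  Repeated species labels become replicates; empty / NA
    cells are recorded as 0 (toxin not detected in that transcriptome)."""
    if hasattr(path, "read"):
        path = io.StringIO(path.read())
    raw = pd.read_csv(
        path,
        sep=delimiter,
        engine="python" if delimiter is None else "c",
        index_col=0,
        dtype=str,
        keep_default_na=False,
    )
    na_tokens = {"", "NA", "NaN", "nan", "N/A", "na"}
    num = pd.DataFrame(index=raw.index.astype(str), columns=raw.columns, dtype=float)
    for col in raw.columns:
        for row_pos, cell in enumerate(raw[col]):
            cell = str(cell).strip()
            if cell in na_tokens:
                num.iloc[row_pos, num.columns.get_loc(col)] = 0.0
                continue
            try:
                num.iloc[row_pos, num.columns.get_loc(col)] = float(cell)
            except ValueError:
                raise ValueError(
                    f"non-numeric cell {cell!r} at row "
                    f"{raw.index[row_pos]!r}, column {col!r}"
                ) from None
    return ExpressionTable(num)


def presence_filter(table: ExpressionTable, min_fraction: float = 0.5) -> ExpressionTable:
    """Retain toxin columns detected (>0 in any replicate) in at least
    ``min_fraction`` of species; column order is preserved."""
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    species = table.species
    present = table.values.groupby(level=0, sort=False).max() > 0
    frac = present.loc[species].sum(axis=0) / len(species)
    keep = [c for c in table.toxin_families if frac[c] >= min_fraction - 1e-12]
    if not keep:
        listing = ", ".join(f"{c}: {frac[c]:.3f}" for c in table.toxin_families)
        raise ValueError(
            f"presence filter at {min_fraction} removed every toxin "
            f"(per-toxin presence fractions: {listing})"
        )
    return ExpressionTable(table.values[keep])


# ----------------------------------------------------------------------
# scaled trait vectors


@dataclass
class ScaledTraitVector:
    """One scalar (dimensionless) trait value per species for one toxin.

    ``scaling_constant`` is the average within-species variance whose square
    root divided the species means (1.0 when no replicate information was
    available or usable).
    """

    species: list[str]
    values: np.ndarray
    toxin: str = ""
    scaling_constant: float = 1.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.species) != self.values.shape[0]:
            raise ValueError("species and values must have equal length")
        if len(set(self.species)) != len(self.species):
            raise ValueError("species labels must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trait values must be finite")
        if not self.scaling_constant > 0:
            raise ValueError("scaling_constant must be positive")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.species, name=self.toxin)

    def __contains__(self, label) -> bool:
        return label in set(self.species)

    def subset(self, labels) -> "ScaledTraitVector":
        s = self.as_series()
        return ScaledTraitVector(
            list(labels), s.loc[list(labels)].to_numpy(), self.toxin, self.scaling_constant
        )

    def to_tsv(self, path):
        self.as_series().to_csv(path, sep="\t", header=False)

    @classmethod
    def from_tsv(cls, path, toxin: str = "") -> "ScaledTraitVector":
        s = pd.read_csv(path, sep="\t", header=None, index_col=0)[1]
        return cls(list(s.index.astype(str)), s.to_numpy(dtype=float), toxin)


_TRANSFORMS = {
    "none": lambda x: x,
    "log": lambda x: np.log(x + 1e-6),
    "logit": lambda x: np.log((x + 1e-6) / (1 - x + 1e-6)),
}


def scale_by_within_species_variance(
    table: ExpressionTable,
    toxin: str,
    *,
    divisor: str = "sd",
    transform: str = "none",
) -> ScaledTraitVector:
    """Species means across replicates, standardized by the average
    within-species variance.

    The mean within-species sample variance (n-1 denominator, over species
    with >= 2 replicates) is computed; species means are divided by its
    square root (``divisor="sd"``, the default, yielding SD-like units) or by
    the variance itself (``divisor="variance"``).  With no replicates, or a
    zero average variance, the divisor falls back to 1 with a warning.
    """
    if toxin not in table.toxin_families:
        raise KeyError(f"toxin {toxin!r} not in table")
    if divisor not in ("sd", "variance"):
        raise ValueError("divisor must be 'sd' or 'variance'")
    col = _TRANSFORMS[transform](table.values[toxin].astype(float))
    groups = col.groupby(level=0, sort=False)
    means = groups.mean()
    sizes = groups.size()
    with_reps = sizes[sizes >= 2].index
    if len(with_reps) == 0:
        logger.warning(
            "no species has replicate measurements for %s; values pass "
            "through unscaled",
            toxin,
        )
        const, div = 1.0, 1.0
    else:
        avg_var = float(groups.var(ddof=1).loc[with_reps].mean())
        if avg_var <= 0:
            logger.warning(
                "average within-species variance for %s is zero; falling "
                "back to divisor 1",
                toxin,
            )
            const, div = 1.0, 1.0
        else:
            const = avg_var
            div = np.sqrt(avg_var) if divisor == "sd" else avg_var
    species = table.species
    return ScaledTraitVector(
        species,
        (means.loc[species] / div).to_numpy(),
        toxin,
        const,
    )


def prune_to_overlap(
    tree: TimeTree, trait: ScaledTraitVector
) -> tuple[TimeTree, ScaledTraitVector]:
    """Restrict tree and trait vector to their shared species (>= 3)."""
    shared = [l for l in tree.tip_labels if l in trait]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} species shared between tree and trait "
            "vector; at least 3 required"
        )
    pruned = tree.prune_to_tips(shared)
    return pruned, trait.subset(pruned.tip_labels)
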