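"""Trees and tip tables: array-backed phylogenies, Newick and TSV I/O, pruning.

The in-memory :class:`Phylogeny` is a flat array structure (parent pointers,
child pointers, edge lengths) designed for fast likelihood kernels.  Tips
occupy node ids ``0 .. n_tips-1``; internal nodes follow; ``postorder`` lists
every node with children before parents, ending at the root.  Newick parsing
and writing are delegated to dendropy; polytomies are resolved into
zero-length bifurcations deterministically (left-fold in input child order),
which leaves every likelihood in this package unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

UNKNOWN = -1  #: sentinel for an unknown tip state

__all__ = [
    "Phylogeny",
    "TipStateTable",
    "TipValueTable",
    "read_newick",
    "write_newick",
    "prune_to_taxa",
    "validate_ultrametric",
    "normalize_name",
    "UNKNOWN",
]


def normalize_name(name: str) -> str:
    """Normalize a species name for matching: strip, spaces -> underscores."""
    return "_".join(str(name).strip().split())


class TreeError(ValueError):
    """Raised for malformed trees or tree/table mismatches."""


@dataclass
class Phylogeny:
    """Rooted bifurcating phylogeny with branch lengths.

    ``lengths[v]`` is the length of the edge above node ``v`` (0.0 at the
    root).  ``child1``/``child2`` are -1 for tips.
    """

    parent: np.ndarray
    child1: np.ndarray
    child2: np.ndarray
    lengths: np.ndarray
    labels: list
    n_tips: int
    root: int
    postorder: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.postorder is None:
            self.postorder = self._compute_postorder()
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _compute_postorder(self) -> np.ndarray:
        order = []
        stack = [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done or self.child1[v] < 0:
                order.append(v)
            else:
                stack.append((v, True))
                stack.append((int(self.child2[v]), False))
                stack.append((int(self.child1[v]), False))
        return np.asarray(order, dtype=np.int64)

    def _validate(self):
        n = self.n_nodes
        if n != 2 * self.n_tips - 1:
            raise TreeError(
                f"binary tree with {self.n_tips} tips must have "
                f"{2 * self.n_tips - 1} nodes, got {n}"
            )
        if np.any(self.lengths < 0):
            raise TreeError("negative branch lengths are not allowed")
        if (self.parent == -1).sum() != 1 or self.parent[self.root] != -1:
            raise TreeError("tree must have exactly one root")
        seen = set()
        for lab in self.tip_labels:
            if lab in seen:
                raise TreeError(f"duplicate tip label {lab!r}")
            seen.add(lab)

    # -- basic queries ---------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def tip_labels(self) -> list:
        return self.labels[: self.n_tips]

    def is_tip(self, v: int) -> bool:
        return v < self.n_tips

    def depths(self) -> np.ndarray:
        """Root-to-node path lengths (time from the root)."""
        d = np.zeros(self.n_nodes)
        for v in self.postorder[::-1]:
            p = self.parent[v]
            if p >= 0:
                d[v] = d[p] + self.lengths[v]
        return d

    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def total_length(self) -> float:
        return float(self.lengths.sum())

    def tip_index(self) -> dict:
        return {lab: i for i, lab in enumerate(self.tip_labels)}

    def mrca_matrix(self) -> np.ndarray:
        """n_tips x n_tips matrix of root-to-MRCA path lengths.

        This is the Brownian-motion covariance structure (up to sigma^2) and
        the basis for patristic distances.
        """
        n = self.n_tips
        depth = self.depths()
        C = np.zeros((n, n))
        tipsets: dict[int, np.ndarray] = {}
        for v in self.postorder:
            if self.is_tip(v):
                tipsets[v] = np.asarray([v])
                C[v, v] = depth[v]
            else:
                a = tipsets.pop(int(self.child1[v]))
                b = tipsets.pop(int(self.child2[v]))
                C[np.ix_(a, b)] = depth[v]
                C[np.ix_(b, a)] = depth[v]
                tipsets[v] = np.concatenate([a, b])
        return C

    def patristic_distances(self) -> np.ndarray:
        C = self.mrca_matrix()
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2.0 * C

    # -- Newick ----------------------------------------------------------------

    def to_newick(self, precision: int = 12) -> str:
        parts = [""] * self.n_nodes
        fmt = f"%.{precision}g"
        for v in self.postorder:
            if self.is_tip(v):
                node = self.labels[v]
            else:
                node = f"({parts[self.child1[v]]},{parts[self.child2[v]]})"
            if v == self.root:
                parts[v] = node
            else:
                parts[v] = node + ":" + (fmt % self.lengths[v])
        return parts[self.root] + ";"


class _Builder:
    """Accumulates nodes during tree construction; tips first, then internals."""

    def __init__(self):
        self.tip_labels = []
        self.tip_lengths = []
        # internal nodes: (child_ids, length); ids: tips >= 0, internals < 0
        self.internals = []

    def add_tip(self, label: str, length: float) -> int:
        self.tip_labels.append(label)
        self.tip_lengths.append(length)
        return len(self.tip_labels) - 1

    def add_internal(self, children: list, length: float) -> int:
        # binarize by left-fold with zero-length edges (deterministic)
        while len(children) > 2:
            sub = self.add_internal(children[:2], 0.0)
            children = [sub] + children[2:]
        if len(children) != 2:
            raise TreeError("internal node must have >= 2 children")
        self.internals.append((tuple(children), length))
        return -len(self.internals)  # negative placeholder id

    def build(self, root_id: int) -> Phylogeny:
        n_tips = len(self.tip_labels)
        if n_tips < 2:
            raise TreeError("a phylogeny needs at least 2 tips")
        n_nodes = n_tips + len(self.internals)
        parent = np.full(n_nodes, -1, dtype=np.int64)
        child1 = np.full(n_nodes, -1, dtype=np.int64)
        child2 = np.full(n_nodes, -1, dtype=np.int64)
        lengths = np.zeros(n_nodes)
        lengths[:n_tips] = self.tip_lengths

        def real(i: int) -> int:
            return i if i >= 0 else n_tips + (-i - 1)

        for k, (children, length) in enumerate(self.internals):
            v = n_tips + k
            lengths[v] = length
            c1, c2 = (real(c) for c in children)
            child1[v], child2[v] = c1, c2
            parent[c1] = v
            parent[c2] = v
        root = real(root_id)
        lengths[root] = 0.0
        labels = list(self.tip_labels) + [""] * len(self.internals)
        return Phylogeny(parent, child1, child2, lengths, labels, n_tips, root)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Branch lengths are required on every edge except the root edge.
    Polytomies are resolved into zero-length bifurcations (left-fold in input
    order).  Raises on duplicate tip labels or missing lengths.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"malformed Newick: {exc}") from exc

    b = _Builder()

    def convert(node) -> int:
        length = node.edge.length
        children = node.child_nodes()
        if not children:
            if node.taxon is None or not node.taxon.label:
                raise TreeError("unlabeled tip in Newick input")
            if length is None:
                raise TreeError(f"missing branch length above tip {node.taxon.label!r}")
            return b.add_tip(normalize_name(node.taxon.label), float(length))
        if length is None:
            if node.parent_node is not None:
                raise TreeError("missing branch length on an internal edge")
            length = 0.0
        while len(children) == 1:  # suppress unifurcations
            child = children[0]
            extra = child.edge.length
            if extra is None and child.child_nodes():
                raise TreeError("missing branch length on an internal edge")
            length += float(extra or 0.0)
            children = child.child_nodes()
            if not children:
                if child.taxon is None or not child.taxon.label:
                    raise TreeError("unlabeled tip in Newick input")
                return b.add_tip(normalize_name(child.taxon.label), float(length))
        return b.add_internal([convert(c) for c in children], float(length))

    root_id = convert(dtree.seed_node)
    if root_id >= 0:
        raise TreeError("Newick input describes a single tip, not a tree")
    return b.build(root_id)


def write_newick(tree: Phylogeny, path=None, precision: int = 12):
    """Serialize to Newick; returns the string, optionally also writing a file."""
    s = tree.to_newick(precision=precision)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(s + "\n")
    return s


def prune_to_taxa(tree: Phylogeny, keep) -> Phylogeny:
    """Induced subtree on ``keep`` tips; preserves all patristic distances.

    Degree-2 nodes created by the pruning are suppressed with their edge
    lengths summed.  The pruned root's stem is discarded.
    """
    keep = {normalize_name(k) for k in keep}
    if not keep:
        raise TreeError("keep set is empty")
    have = set(tree.tip_labels)
    missing = keep - have
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)[:5]}")
    if len(keep) < 2:
        raise TreeError("cannot prune to fewer than 2 tips")

    b = _Builder()
    # bottom-up reduction: each node maps to (builder_id, stem_length) or None
    res: dict[int, tuple] = {}
    for v in tree.postorder:
        if tree.is_tip(v):
            if tree.labels[v] in keep:
                res[v] = ("tip", tree.labels[v], tree.lengths[v])
        else:
            kids = [res.pop(c) for c in (int(tree.child1[v]), int(tree.child2[v])) if c in res]
            if not kids:
                continue
            if len(kids) == 1:
                kind, payload, stem = kids[0]
                res[v] = (kind, payload, stem + tree.lengths[v])
            else:
                ids = []
                for kind, payload, stem in kids:
                    if kind == "tip":
                        ids.append(b.add_tip(payload, stem))
                    else:
                        ids.append(b.add_internal(payload, stem))
                res[v] = ("internal", ids, tree.lengths[v])
    kind, payload, _stem = res[tree.root]
    assert kind == "internal"  # guaranteed by len(keep) >= 2
    root_id = b.add_internal(payload, 0.0)
    return b.build(root_id)


def validate_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6):
    """Check that all root-to-tip distances agree within ``rel_tol`` of their mean.

    Returns ``(ok, max_relative_deviation)``.
    """
    d = tree.depths()[: tree.n_tips]
    mean = d.mean()
    if mean <= 0:
        return False, np.inf
    dev = float(np.abs(d - mean).max() / mean)
    return dev <= rel_tol, dev


# -- tip tables ---------------------------------------------------------------


@dataclass
class TipStateTable:
    """Species -> binary state (0 = GSD, 1 = TSD, UNKNOWN = -1).

    ``alt_state`` carries an alternative assignment (mixed/equivocal taxa
    reclassified); it defaults to ``state`` where no alternative is given.
    """

    species: list
    state: np.ndarray
    alt_state: np.ndarray = None

    def __post_init__(self):
        self.species = [normalize_name(s) for s in self.species]
        self.state = np.asarray(self.state, dtype=np.int8)
        if self.alt_state is None:
            self.alt_state = self.state.copy()
        self.alt_state = np.asarray(self.alt_state, dtype=np.int8)
        for arr in (self.state, self.alt_state):
            bad = ~np.isin(arr, [0, 1, UNKNOWN])
            if bad.any():
                raise ValueError("states must be 0, 1 or unknown (-1)")
        if len(self.species) != len(self.state) or len(self.state) != len(self.alt_state):
            raise ValueError("species/state/alt_state length mismatch")

    @classmethod
    def from_dict(cls, mapping: dict, alt: dict | None = None) -> "TipStateTable":
        species = list(mapping)
        state = [mapping[s] for s in species]
        alt_state = None
        if alt:
            alt_state = [alt.get(s, mapping[s]) for s in species]
        return cls(species, state, alt_state)

    def known_species(self, use_alt: bool = False) -> list:
        st = self.alt_state if use_alt else self.state
        return [s for s, x in zip(self.species, st) if x != UNKNOWN]

    def states_for(
        self, tree: Phylogeny, use_alt: bool = False, allow_unknown: bool = False
    ) -> np.ndarray:
        """States aligned to tree tip ids; raises if any tip is missing, or
        (unless ``allow_unknown``) has an unknown state."""
        st = self.alt_state if use_alt else self.state
        lookup = dict(zip(self.species, st))
        out = np.empty(tree.n_tips, dtype=np.int8)
        for i, lab in enumerate(tree.tip_labels):
            if lab not in lookup:
                raise ValueError(f"no state for tip {lab!r}")
            if lookup[lab] == UNKNOWN and not allow_unknown:
                raise ValueError(f"unknown state for tip {lab!r}; prune first")
            out[i] = lookup[lab]
        return out

    def to_frame(self) -> pd.DataFrame:
        def enc(x):
            return "unknown" if x == UNKNOWN else int(x)

        return pd.DataFrame(
            {
                "species": self.species,
                "state": [enc(x) for x in self.state],
                "alt_state": [enc(x) for x in self.alt_state],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "TipStateTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if "species" not in df or "state" not in df:
            raise ValueError("state table needs 'species' and 'state' columns")

        def dec(x):
            if pd.isna(x) or str(x).lower() in {"unknown", "na", "?", ""}:
                return UNKNOWN
            return int(x)

        state = [dec(x) for x in df["state"]]
        alt = [dec(x) for x in df["alt_state"]] if "alt_state" in df else None
        return cls(list(df["species"]), state, alt)


@dataclass
class TipValueTable:
    """Species -> strictly positive value (lifespan in years, or clade richness)."""

    species: list
    value: np.ndarray

    def __post_init__(self):
        self.species = [normalize_name(s) for s in self.species]
        self.value = np.asarray(self.value, dtype=float)
        if len(self.species) != len(self.value):
            raise ValueError("species/value length mismatch")
        if not np.all(self.value > 0):
            raise ValueError("values must be strictly positive")

    @classmethod
    def from_dict(cls, mapping: dict) -> "TipValueTable":
        species = list(mapping)
        return cls(species, [mapping[s] for s in species])

    def values_for(self, tree: Phylogeny, log: bool = False) -> np.ndarray:
        lookup = dict(zip(self.species, self.value))
        out = np.empty(tree.n_tips)
        for i, lab in enumerate(tree.tip_labels):
            if lab not in lookup:
                raise ValueError(f"no value for tip {lab!r}")
            out[i] = lookup[lab]
        return np.log(out) if log else out

    def require_integral(self) -> None:
        if not np.allclose(self.value, np.round(self.value)):
            raise ValueError("richness counts must be integers")

    def to_tsv(self, path, column: str = "value") -> None:
        pd.DataFrame({"species": self.species, column: self.value}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def read_tsv(cls, path) -> "TipValueTable":
        df = pd.read_csv(path, sep="\t")
        if "species" not in df.columns:
            raise ValueError("value table needs a 'species' column")
        value_col = [c for c in df.columns if c != "species"][0]
        return cls(list(df["species"].astype(str)), df[value_col].to_numpy())
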