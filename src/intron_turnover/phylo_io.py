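"""Readers, writers and validated in-memory structures for the pipeline's formats.

Three structures flow through every analysis here:

* :class:`Phylogeny` — a rooted tree whose branch lengths are measured in
  expected nucleotide substitutions per site, so that gain/loss rates fitted
  on it come out *relative to the substitution rate* (mu = 1 means "as fast
  as nucleotide substitution").
* :class:`PhyleticPattern` — presence (1) / absence (0) of a character
  (the intron, or the homing endonuclease gene within it) across taxa.
* :class:`Alignment` — an aligned set of nucleotide sequences; gaps are kept
  distinct from ambiguity codes so downstream consumers can decide whether a
  gap is missing data or a scoreable difference.

Newick parsing is delegated to dendropy; patterns are plain tab-separated
tables (columns ``taxon``, then one 0/1/NA column per character) so they can
be diffed and edited by hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class PhyloIOError(ValueError):
    """Raised on malformed input (trees, patterns, alignments)."""


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    """Node of a rooted phylogeny.

    ``length`` is the length of the branch *above* the node (toward the
    root), in expected substitutions per site; it is 0.0 for the root.
    """

    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label: str | None = None, length: float = 0.0):
        self.label = label
        self.length = float(length)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<TreeNode {self.label!r} {kind} t={self.length:g}>"


class Phylogeny:
    """Rooted tree with branch lengths; polytomies allowed.

    Invariants (checked in :meth:`validate`): a single root, unique non-empty
    leaf labels, and finite non-negative branch lengths on every non-root
    node. Zero-length branches are legal (the transition matrix across them
    is the identity).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self.validate()

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            for child in reversed(node.children):
                stack.append(child)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def node_ids(self) -> dict[TreeNode, str]:
        """Stable identifiers: leaf label for leaves, existing label or
        ``node<i>`` (preorder index) for internal nodes."""
        ids: dict[TreeNode, str] = {}
        for i, node in enumerate(self.preorder()):
            if node.is_leaf:
                ids[node] = node.label
            else:
                ids[node] = node.label if node.label else f"node{i}"
        return ids

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.root.parent is not None:
            raise PhyloIOError("root must not have a parent")
        seen: set[int] = set()
        labels: set[str] = set()
        n_leaves = 0
        for node in self.postorder():
            if id(node) in seen:
                raise PhyloIOError("tree contains a cycle or shared node")
            seen.add(id(node))
            if node.is_leaf:
                n_leaves += 1
                if not node.label:
                    raise PhyloIOError("leaf with empty label")
                if node.label in labels:
                    raise PhyloIOError(f"duplicate leaf label {node.label!r}")
                labels.add(node.label)
            if node.parent is not None:
                if not np.isfinite(node.length):
                    raise PhyloIOError(
                        f"non-finite branch length on node {node.label!r}")
                if node.length < 0:
                    raise PhyloIOError(
                        f"negative branch length {node.length} on node "
                        f"{node.label!r}")
            for child in node.children:
                if child.parent is not node:
                    raise PhyloIOError("inconsistent parent pointer")
        if n_leaves < 1:
            raise PhyloIOError("tree has no leaves")

    def copy(self) -> "Phylogeny":
        def clone(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for child in node.children:
                new.add_child(clone(child))
            return new

        return Phylogeny(clone(self.root))


def _from_dendropy(dnode: dendropy.Node, default_length: float | None) -> TreeNode:
    if dnode.is_leaf():
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
    else:
        label = dnode.label
    length = dnode.edge.length
    if length is None:
        length = 0.0 if dnode.parent_node is None else default_length
        if length is None:
            raise PhyloIOError(
                f"missing branch length above node {label!r}; branch lengths "
                "are required (rates are measured per substitution) — pass "
                "default_branch_length to assign one explicitly")
    node = TreeNode(label, float(length))
    for dchild in dnode.child_nodes():
        node.add_child(_from_dendropy(dchild, default_length))
    return node


def parse_newick(text: str, default_branch_length: float | None = None) -> Phylogeny:
    """Parse a single rooted Newick statement into a :class:`Phylogeny`.

    Branch lengths are required; a tree with missing lengths is rejected
    unless ``default_branch_length`` supplies an explicit substitute.
    Underscores in labels are preserved verbatim.
    """
    text = text.strip()
    if not text.endswith(";"):
        raise PhyloIOError("Newick statement must end with ';'")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise PhyloIOError(f"Newick parse error: {exc}") from exc
    root = _from_dendropy(dtree.seed_node, default_branch_length)
    root.length = 0.0
    return Phylogeny(root)


def read_newick(path: str | Path, **kwargs) -> Phylogeny:
    return parse_newick(Path(path).read_text(), **kwargs)


def _format_length(t: float) -> str:
    s = repr(float(t))
    return s[:-2] if s.endswith(".0") else s


def write_newick(tree: Phylogeny) -> str:
    """Serialize a Phylogeny; ``parse_newick`` of the output reproduces the
    topology, labels and branch lengths exactly (lengths printed with repr
    precision)."""

    def render(node: TreeNode) -> str:
        if node.is_leaf:
            core = node.label
        else:
            inner = ",".join(render(c) for c in node.children)
            core = f"({inner}){node.label or ''}"
        if node.parent is None:
            return core
        return f"{core}:{_format_length(node.length)}"

    return render(tree.root) + ";"


def save_newick(tree: Phylogeny, path: str | Path) -> None:
    Path(path).write_text(write_newick(tree) + "\n")


def prune_to_taxa(tree: Phylogeny, taxa: set[str]) -> Phylogeny:
    """Restrict a tree to a leaf subset.

    Removed leaves take their branches with them; internal nodes left with
    a single child are spliced out with branch lengths merged, so path
    lengths among the kept taxa are preserved. Used to carry an analysis
    from the full taxon set to a character defined only on a subset (the
    HEG exists only within intron-containing taxa).
    """
    keep = set(taxa)
    missing = keep - set(tree.leaf_labels())
    if missing:
        raise PhyloIOError(f"taxa not in tree: {sorted(missing)}")
    if len(keep) < 2:
        raise PhyloIOError("pruned tree needs at least 2 taxa")
    tree = tree.copy()
    changed = True
    while changed:
        changed = False
        for node in list(tree.postorder()):
            if node.is_leaf:
                if node.label not in keep and node.parent is not None:
                    node.parent.children.remove(node)
                    node.parent = None
                    changed = True
                continue
            if not node.children:
                if node.parent is not None:
                    node.parent.children.remove(node)
                    node.parent = None
                    changed = True
            elif len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                if node.parent is None:
                    child.length = 0.0
                    child.parent = None
                    tree.root = child
                else:
                    idx = node.parent.children.index(node)
                    node.parent.children[idx] = child
                    child.parent = node.parent
                changed = True
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# Phyletic patterns
# ---------------------------------------------------------------------------

@dataclass
class PhyleticPattern:
    """Presence/absence states of one character across taxa."""

    character: str
    states: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, state in self.states.items():
            if state not in (0, 1):
                raise PhyloIOError(
                    f"non-binary state {state!r} for taxon {taxon!r} in "
                    f"character {self.character!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def __getitem__(self, taxon: str) -> int:
        return self.states[taxon]

    def validate_against(self, tree: Phylogeny) -> None:
        tree_taxa = set(tree.leaf_labels())
        pattern_taxa = set(self.states)
        missing = tree_taxa - pattern_taxa
        extra = pattern_taxa - tree_taxa
        if missing or extra:
            parts = []
            if missing:
                parts.append(f"taxa in tree but not pattern: {sorted(missing)}")
            if extra:
                parts.append(f"taxa in pattern but not tree: {sorted(extra)}")
            raise PhyloIOError("; ".join(parts))


def pattern_summary(pattern: PhyleticPattern) -> dict[str, int]:
    """Counts of taxa / present / absent; present + absent == taxa."""
    n_present = sum(pattern.states.values())
    n = len(pattern)
    return {"n_taxa": n, "n_present": n_present, "n_absent": n - n_present}


def read_pattern(path: str | Path, character: str) -> PhyleticPattern:
    """Read one 0/1 character from a tab-separated pattern table.

    The table has a ``taxon`` column plus one column per character; cells are
    0, 1 or NA. NA rows are excluded from the returned pattern (used for the
    HEG character, which is only defined on intron-containing taxa).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "taxon" not in df.columns:
        raise PhyloIOError(f"pattern file {path} lacks a 'taxon' column")
    if character not in df.columns:
        raise PhyloIOError(
            f"unknown character {character!r}; available: "
            f"{[c for c in df.columns if c != 'taxon']}")
    if df["taxon"].duplicated().any():
        dups = df.loc[df["taxon"].duplicated(), "taxon"].tolist()
        raise PhyloIOError(f"duplicated taxa in pattern file: {dups}")
    states: dict[str, int] = {}
    for taxon, cell in zip(df["taxon"], df[character]):
        if pd.isna(cell) or str(cell).strip().upper() == "NA":
            continue
        cell = str(cell).strip()
        if cell not in ("0", "1"):
            raise PhyloIOError(
                f"non-binary cell {cell!r} for taxon {taxon!r}, "
                f"character {character!r}")
        states[str(taxon)] = int(cell)
    return PhyleticPattern(character=character, states=states)


def write_pattern(patterns: Sequence[PhyleticPattern], path: str | Path) -> None:
    """Write characters side by side; taxa missing a character get NA."""
    taxa: list[str] = []
    for p in patterns:
        for t in p.taxa:
            if t not in taxa:
                taxa.append(t)
    df = pd.DataFrame({"taxon": taxa})
    for p in patterns:
        df[p.character] = [
            str(p.states[t]) if t in p.states else "NA" for t in taxa
        ]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

_CANONICAL = set("ACGT-")

# integer codes used throughout: A..T nucleotides, 4 gap, 5 ambiguity/missing
NUC_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "-": 4}
GAP_CODE = 4
MISSING_CODE = 5


@dataclass
class Alignment:
    """Equal-length aligned sequences over {A,C,G,T,-}; anything else is
    normalized to 'N' and treated as missing data."""

    labels: list[str]
    sequences: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise PhyloIOError("labels/sequences length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise PhyloIOError("duplicate sequence labels")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            offender = {
                lab: len(s) for lab, s in zip(self.labels, self.sequences)
            }
            raise PhyloIOError(f"ragged alignment, lengths by record: {offender}")
        if self.sequences and len(self.sequences[0]) < 1:
            raise PhyloIOError("alignment length must be >= 1")
        normalized = []
        for s in self.sequences:
            s = s.upper()
            s = "".join(c if c in _CANONICAL else "N" for c in s)
            normalized.append(s)
        self.sequences = normalized

    @property
    def n_taxa(self) -> int:
        return len(self.labels)

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def row(self, label: str) -> str:
        try:
            return self.sequences[self.labels.index(label)]
        except ValueError:
            raise PhyloIOError(f"unknown sequence label {label!r}") from None

    def codes(self) -> np.ndarray:
        """(n_taxa, n_columns) int8 matrix: A,C,G,T -> 0..3, '-' -> 4,
        ambiguity/'N' -> 5."""
        out = np.full((self.n_taxa, self.n_columns), MISSING_CODE, dtype=np.int8)
        table = np.full(128, MISSING_CODE, dtype=np.int8)
        for ch, code in NUC_CODES.items():
            table[ord(ch)] = code
        for i, s in enumerate(self.sequences):
            out[i] = table[np.frombuffer(s.encode(), dtype=np.uint8)]
        return out

    def replace_row(self, label: str, sequence: str) -> "Alignment":
        seqs = list(self.sequences)
        seqs[self.labels.index(label)] = sequence
        return Alignment(labels=list(self.labels), sequences=seqs)


def read_alignment(path: str | Path) -> Alignment:
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise PhyloIOError(f"alignment {path} has fewer than 2 records")
    return Alignment(
        labels=[r.id for r in records],
        sequences=[str(r.seq) for r in records],
    )


def write_alignment(aln: Alignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(s), id=lab, description="")
        for lab, s in zip(aln.labels, aln.sequences)
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta_sequence(path: str | Path) -> tuple[str, str]:
    """Read a single-record FASTA (label, sequence) — used for the packaged
    endonuclease recognition-site fixture."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise PhyloIOError(f"{path} must contain exactly one record")
    return records[0].id, str(records[0].seq).upper()
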