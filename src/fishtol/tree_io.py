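"""Newick I/O for rooted time trees and the structured tip-label convention.

Trees are chronograms: branch lengths in millions of years (Myr), internal
nodes optionally labelled with bootstrap support percentages. The dialect
follows the convention of large fish phylogenies: an internal-node label
that parses as a number in (1, 100] is a bootstrap support value; any other
label is kept as a clade-name annotation. Support values printed on the
0-1 scale are rejected rather than rescaled, so a tree written with
fractional supports fails loudly instead of being silently misread.

Tip labels follow the ``Family_Genus_species_Code`` convention; see
:func:`parse_tip_label`.

Parsing and serialisation are delegated to :mod:`dendropy`; this module
adds the dialect rules, validation and a light :class:`Phylogeny` wrapper.
"""

from __future__ import annotations

import io
from collections import Counter
from typing import Iterable, NamedTuple, Optional

import dendropy

from .exceptions import (
    MalformedLabelError,
    NewickParseError,
    TreeValidationError,
)

__all__ = [
    "Phylogeny",
    "TipAnnotation",
    "parse_newick",
    "read_newick",
    "write_newick",
    "parse_tip_label",
]


class TipAnnotation(NamedTuple):
    """Family/genus/species/specimen-code parsed from a tip label."""

    family: str
    genus: str
    species: str
    code: str


def parse_tip_label(label: str) -> TipAnnotation:
    """Split an underscore-delimited ``Family_Genus_species_Code`` tip label.

    The first three tokens are family, genus and species; any remaining
    tokens are re-joined (with underscores) into the specimen code, which
    may be empty for three-token labels.

    >>> parse_tip_label("Percidae_Perca_fluviatilis_X123")
    TipAnnotation(family='Percidae', genus='Perca', species='fluviatilis', code='X123')
    """
    tokens = label.split("_")
    if len(tokens) < 3 or any(t == "" for t in tokens[:3]):
        raise MalformedLabelError(
            f"tip label {label!r} does not follow Family_Genus_species_Code "
            "(need at least three non-empty underscore-delimited tokens)"
        )
    family, genus, species = tokens[:3]
    if not family[0].isupper():
        raise MalformedLabelError(
            f"tip label {label!r}: family token {family!r} must be capitalized"
        )
    return TipAnnotation(family, genus, species, "_".join(tokens[3:]))


def _classify_internal_label(label):
    """Map an internal-node label to ``(support, clade_name)`` per the dialect."""
    if label is None or label == "":
        return None, None
    try:
        value = float(label)
    except ValueError:
        return None, label
    if 0.0 <= value <= 1.0:
        raise TreeValidationError(
            f"internal-node label {label!r} looks like support on the 0-1 "
            "scale; this reader accepts percentages only (rescale upstream)"
        )
    if 1.0 < value <= 100.0:
        return value, None
    return None, label


def _format_support(value: float) -> str:
    return str(int(value)) if float(value).is_integer() else f"{value:g}"


class Phylogeny:
    """A rooted chronogram wrapped around a :class:`dendropy.Tree`.

    Leaves carry their label on ``node.label``; internal nodes carry an
    optional ``node.support`` (percentage) and an optional clade-name
    annotation on ``node.label``. Child order is preserved from input and
    is meaningful downstream (classification ordering).
    """

    def __init__(self, tree: dendropy.Tree, validate: bool = True):
        self.tree = tree
        self._invalidate_caches()
        if validate:
            self.validate()

    # ------------------------------------------------------------------
    # construction / serialisation
    # ------------------------------------------------------------------
    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        return parse_newick(text)

    def to_newick(self, precision: int = 6) -> str:
        return write_newick(self, precision=precision)

    def copy(self) -> "Phylogeny":
        clone = dendropy.Tree(self.tree)  # deep-copies nodes and attributes
        return Phylogeny(clone, validate=False)

    # ------------------------------------------------------------------
    # basic structure
    # ------------------------------------------------------------------
    @property
    def root(self):
        return self.tree.seed_node

    def nodes(self):
        return self.tree.preorder_node_iter()

    def leaf_nodes(self):
        return [nd for nd in self.tree.leaf_node_iter()]

    @property
    def leaf_labels(self):
        return [nd.label for nd in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def _invalidate_caches(self):
        self._leafsets = None
        self._leaf_index = None
        self._depths = None
        self._preorder_index = None

    # ------------------------------------------------------------------
    # cached indices
    # ------------------------------------------------------------------
    def leafset(self, node) -> frozenset:
        """Frozenset of leaf labels under ``node`` (cached for the tree)."""
        if self._leafsets is None:
            sets = {}
            for nd in self.tree.postorder_node_iter():
                if nd.is_leaf():
                    sets[nd] = frozenset((nd.label,))
                else:
                    sets[nd] = frozenset().union(
                        *(sets[ch] for ch in nd.child_nodes())
                    )
            self._leafsets = sets
        return self._leafsets[node]

    def leaf_node(self, label: str):
        if self._leaf_index is None:
            self._leaf_index = {nd.label: nd for nd in self.tree.leaf_node_iter()}
        try:
            return self._leaf_index[label]
        except KeyError:
            raise KeyError(f"leaf label {label!r} not in tree") from None

    def depths(self) -> dict:
        """Node depth (sum of branch lengths from the root; root depth 0)."""
        if self._depths is None:
            d = {self.root: 0.0}
            for nd in self.tree.preorder_node_iter():
                if nd is self.root:
                    continue
                length = nd.edge.length
                if length is None:
                    raise TreeValidationError(
                        "tree has missing branch lengths; depths undefined"
                    )
                d[nd] = d[nd.parent_node] + length
            self._depths = d
        return self._depths

    def preorder_index(self) -> dict:
        """Node -> rank in a depth-first preorder traversal (stored child order)."""
        if self._preorder_index is None:
            self._preorder_index = {
                nd: i for i, nd in enumerate(self.tree.preorder_node_iter())
            }
        return self._preorder_index

    def mrca(self, labels: Iterable[str]):
        """Most recent common ancestor of the given tip labels."""
        labels = frozenset(labels)
        if not labels:
            raise ValueError("mrca of an empty tip set is undefined")
        if self._leaf_index is None:
            self._leaf_index = {nd.label: nd for nd in self.tree.leaf_node_iter()}
        missing = sorted(lbl for lbl in labels if lbl not in self._leaf_index)
        if missing:
            raise KeyError(f"tips not in tree: {missing}")
        node = self.leaf_node(next(iter(labels)))
        while not labels <= self.leafset(node):
            node = node.parent_node
        return node

    def find_clade(self, name: str):
        """Internal node whose clade-name annotation equals ``name`` (or None)."""
        for nd in self.tree.preorder_internal_node_iter():
            if nd.label == name:
                return nd
        return None

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def validate(self):
        labels = [nd.label for nd in self.tree.leaf_node_iter()]
        dupes = sorted(lbl for lbl, k in Counter(labels).items() if k > 1)
        if dupes:
            raise TreeValidationError(f"duplicate leaf labels: {dupes}")
        if any(lbl is None or lbl == "" for lbl in labels):
            raise TreeValidationError("every leaf must carry a non-empty label")
        for nd in self.tree.preorder_node_iter():
            if nd is not self.root and nd.parent_node is None:
                raise TreeValidationError("non-root node without a parent")
            if nd.edge.length is not None and nd.edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length {nd.edge.length} at {nd.label!r}"
                )
            support = getattr(nd, "support", None)
            if support is not None and not (0.0 <= support <= 100.0):
                raise TreeValidationError(
                    f"support {support} outside [0, 100] at {nd.label!r}"
                )
        return self

    # ------------------------------------------------------------------
    # comparison helpers (used heavily in tests)
    # ------------------------------------------------------------------
    def canonical_form(self, length_decimals: int = 9):
        """Nested tuples with children sorted by smallest leaf label.

        Insensitive to child order; suitable for equality checks between a
        tree and its re-parsed serialisation.
        """

        def rec(nd):
            length = (
                None
                if nd.edge.length is None
                else round(nd.edge.length, length_decimals)
            )
            support = getattr(nd, "support", None)
            if nd.is_leaf():
                return (nd.label, length)
            children = sorted(
                (rec(ch) for ch in nd.child_nodes()),
                key=lambda sub: min(self._canon_leaves(sub)),
            )
            return (nd.label, support, length, tuple(children))

        return rec(self.root)

    @staticmethod
    def _canon_leaves(sub):
        if len(sub) == 2:  # leaf tuple
            return [sub[0]]
        out = []
        for ch in sub[3]:
            out.extend(Phylogeny._canon_leaves(ch))
        return out

    def __repr__(self):
        return f"<Phylogeny with {self.n_leaves} leaves>"


def _check_balanced(text: str):
    """Report the character offset of the first unbalanced parenthesis."""
    depth = 0
    in_quote = False
    for i, ch in enumerate(text):
        if ch == "'":
            in_quote = not in_quote
        elif not in_quote:
            if ch == "(":
                depth += 1
            elif ch == ")":
                depth -= 1
                if depth < 0:
                    raise NewickParseError("unbalanced ')'", offset=i)
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' in newick statement", offset=len(text)
        )


def parse_newick(text: str) -> Phylogeny:
    """Parse a single rooted newick statement into a :class:`Phylogeny`.

    Internal-node labels that parse as numbers in (1, 100] become support
    values; other internal labels are retained as clade names. Unquoted
    underscores are preserved verbatim (tip labels rely on them).
    """
    text = text.strip()
    if not text.endswith(";"):
        raise NewickParseError("newick statement must end with ';'", offset=len(text))
    _check_balanced(text)
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
        )
    except Exception as exc:  # dendropy raises several reader error types
        raise NewickParseError(f"could not parse newick: {exc}") from exc

    for nd in tree.preorder_node_iter():
        if nd.is_leaf():
            nd.support = None
        else:
            nd.support, nd.label = _classify_internal_label(nd.label)
    return Phylogeny(tree)


def read_newick(path) -> Phylogeny:
    """Read a newick file (UTF-8) containing a single tree."""
    with io.open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: Phylogeny, precision: int = 6) -> str:
    """Serialise to newick; supports are emitted as internal-node labels.

    An internal node cannot carry both a support value and a clade name in
    this dialect; when both are present the support wins (matching how the
    source trees print them).
    """
    clone = tree.copy()
    for nd in clone.tree.preorder_node_iter():
        if nd.is_leaf():
            continue
        support = getattr(nd, "support", None)
        if support is not None:
            nd.label = _format_support(support)
    text = clone.tree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_leaf_node_labels=False,
        unquoted_underscores=True,
        preserve_spaces=True,
        real_value_format_specifier=f".{precision}f",
    ).strip()
    return text
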