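"""Render a validated taxonomy as a ranked classification document.

Presentation follows the conventions of modern ranked fish
classifications: supra-familial taxa appear in phylogenetic order — the
order in which their crown (MRCA) nodes are first reached by a
depth-first preorder traversal of the tree in stored child order — while
families are listed alphabetically inside their order or suborder block.
Incertae sedis families attach directly to a series and are rendered as a
grouped block under it; unexamined families are collected into a
"Not examined:" line per block. Bootstrap support percentages are printed
in parentheses after supra-familial names when available; provisional
names are quoted; non-monophyletic families carry an inline note.

Two serialisations are produced: an indented UTF-8 text document and a
flat TSV that round-trips through :func:`fishtol.taxonomy_model.load_taxonomy`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import pandas as pd

from .clade_validation import MonophylyReport
from .exceptions import TaxonomyError
from .taxonomy_model import Taxon, Taxonomy, write_taxonomy
from .tree_io import Phylogeny, parse_tip_label

__all__ = [
    "ClassificationDocument",
    "phylogenetic_order",
    "render_classification",
    "counts_summary",
]

INDENT = "  "  # two spaces per rank depth


# ----------------------------------------------------------------------
# ordering
# ----------------------------------------------------------------------
def _taxon_tipsets(tree: Phylogeny, taxonomy: Taxonomy) -> Dict[str, frozenset]:
    tips_by_family: Dict[str, set] = {}
    for label in tree.leaf_labels:
        tips_by_family.setdefault(parse_tip_label(label).family, set()).add(label)
    out = {}
    for taxon in taxonomy:
        fams = taxonomy.families_under(taxon)
        out[taxon.name] = frozenset().union(
            *(tips_by_family.get(f.name, set()) for f in fams)
        ) if fams else frozenset()
    return out


def _order_siblings(siblings: List[Taxon], sort_key, kind: str) -> List[Taxon]:
    """Order sampled siblings by ``sort_key``; insert unsampled after anchors."""
    sampled = [t for t in siblings if sort_key(t) is not None]
    unsampled = [t for t in siblings if sort_key(t) is None]
    ordered = sorted(sampled, key=sort_key)
    pending = list(unsampled)
    while pending:
        progressed = False
        for t in list(pending):
            if t.anchor is None:
                raise TaxonomyError(
                    f"{kind} {t.name!r} is unsampled and declares no anchor "
                    "sibling; cannot place it in phylogenetic order"
                )
            names = [o.name for o in ordered]
            if t.anchor in names:
                ordered.insert(names.index(t.anchor) + 1, t)
                pending.remove(t)
                progressed = True
        if not progressed:
            raise TaxonomyError(
                f"could not place unsampled taxa {[t.name for t in pending]}: "
                "anchors missing from their sibling set"
            )
    return ordered


def phylogenetic_order(
    tree: Phylogeny,
    taxonomy: Taxonomy,
    report: Optional[MonophylyReport] = None,
) -> List[Taxon]:
    """Depth-first document order over the taxonomy.

    Supra-familial siblings sort by the preorder index of their MRCA node
    (ties — a polytomy where two taxa attach to the same node — break by
    older crown age, then name); unsampled supra-familial taxa slot in
    after their declared anchor sibling. Family children are emitted
    first within a block, alphabetically.
    """
    tipsets = _taxon_tipsets(tree, taxonomy)
    preorder = tree.preorder_index()
    depths = tree.depths()

    def sort_key(taxon: Taxon):
        tips = tipsets.get(taxon.name, frozenset())
        if not tips:
            return None
        node = (
            tree.mrca(tips) if len(tips) > 1 else tree.leaf_node(next(iter(tips)))
        )
        return (preorder[node], depths[node], taxon.name)

    ordered: List[Taxon] = []

    def emit(taxon: Taxon):
        ordered.append(taxon)
        children = taxonomy.children(taxon.name)
        families = sorted(
            (t for t in children if t.rank == "family"), key=lambda t: t.name
        )
        supra = [t for t in children if t.rank != "family"]
        for fam in families:
            ordered.append(fam)
        for child in _order_siblings(supra, sort_key, "taxon"):
            emit(child)

    for root in _order_siblings(taxonomy.roots(), sort_key, "root taxon"):
        emit(root)
    return ordered


# ----------------------------------------------------------------------
# document
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class ClassificationEntry:
    taxon: Taxon
    depth: int
    support: Optional[float]
    status: Optional[str]


class ClassificationDocument:
    def __init__(self, entries, counts, taxonomy):
        self.entries: List[ClassificationEntry] = list(entries)
        self.counts: dict = counts
        self._taxonomy = taxonomy

    # -- text ----------------------------------------------------------
    def text(self) -> str:
        # rows: (text, taxon name or None, parent name, is_family, depth)
        rows: List[tuple] = []
        not_examined: Dict[str, List[str]] = {}
        for entry in self.entries:
            t = entry.taxon
            if t.rank == "family" and t.has("not_examined"):
                not_examined.setdefault(t.parent or "", []).append(
                    self._family_label(t, entry)
                )
                continue
            rows.extend(self._render_entry(entry))
        # a block's "Not examined:" line follows its last examined family,
        # or the block header when every family in it is unexamined
        for parent, names in not_examined.items():
            fam_idx = [
                i for i, r in enumerate(rows) if r[2] == parent and r[3]
            ]
            if fam_idx:
                at = fam_idx[-1]
                depth = rows[at][4]
            else:
                head_idx = [i for i, r in enumerate(rows) if r[1] == parent]
                if not head_idx:
                    continue  # parent itself not rendered (filtered view)
                at = head_idx[0]
                depth = rows[at][4] + 1
            line = f"{INDENT * depth}Not examined: {', '.join(sorted(names))}"
            rows.insert(at + 1, (line, None, parent, False, depth))
        return "\n".join(r[0] for r in rows) + "\n"

    def _family_label(self, t: Taxon, entry=None) -> str:
        name = f'"{t.name}"' if t.has("provisional") else t.name
        notes = []
        status = entry.status if entry is not None else None
        if status == "non_monophyletic" or t.has("non_monophyletic_declared"):
            notes.append("not monophyletic in our tree")
        if notes:
            name += f" ({'; '.join(notes)})"
        return name

    def _render_entry(self, entry: ClassificationEntry):
        t = entry.taxon
        indent = INDENT * entry.depth
        if t.rank == "family":
            line = f"{indent}{self._family_label(t, entry)}"
            return [(line, t.name, t.parent, True, entry.depth)]
        label = f"{t.rank.capitalize()} {t.name}"
        if entry.support is not None:
            label += f" ({entry.support:g}%)"
        if t.has("sedis_mutabilis"):
            label += " (sedis mutabilis)"
        rows = [(f"{indent}{label}", t.name, t.parent, False, entry.depth)]
        fams = [
            c for c in self._taxonomy.children(t.name)
            if c.rank == "family" and c.has("incertae_sedis")
        ]
        if t.rank == "series" and fams:
            rows.append(
                (
                    f"{indent}{INDENT}Order-level incertae sedis in {t.name}",
                    None,
                    t.name,
                    False,
                    entry.depth + 1,
                )
            )
        return rows

    # -- tables --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        ordered = Taxonomy([e.taxon for e in self.entries], validate=False)
        return write_taxonomy(ordered)

    def to_taxonomy(self) -> Taxonomy:
        return Taxonomy([e.taxon for e in self.entries])

    def counts_json(self) -> str:
        return json.dumps(self.counts, indent=2)


def counts_summary(
    taxonomy: Taxonomy,
    report: Optional[MonophylyReport] = None,
) -> dict:
    """Headline counters for a classification.

    With a monophyly report, examined/non-monophyletic counts come from the
    tree (a family is examined iff it has sampled tips); without one they
    fall back on the ``not_examined`` and ``non_monophyletic_declared``
    status flags.
    """
    fams = taxonomy.families()
    if report is not None:
        examined = sum(
            1 for f in fams if report.by_name[f.name].n_tips_sampled > 0
        )
        non_mono = sum(
            1
            for f in fams
            if report.by_name[f.name].status == "non_monophyletic"
        )
    else:
        examined = sum(1 for f in fams if not f.has("not_examined"))
        non_mono = sum(1 for f in fams if f.has("non_monophyletic_declared"))
    incertae = sum(1 for f in fams if f.has("incertae_sedis"))
    return {
        "orders": len(taxonomy.at_rank("order")),
        "suborders": len(taxonomy.at_rank("suborder")),
        "series_count": len(taxonomy.at_rank("series")),
        "families_total": len(fams),
        "families_examined": examined,
        "families_unexamined": len(fams) - examined,
        "families_non_monophyletic": non_mono,
        "incertae_sedis_families": incertae,
        "provisional_families": sum(1 for f in fams if f.has("provisional")),
    }


def render_classification(
    taxonomy: Taxonomy,
    tree: Optional[Phylogeny] = None,
    report: Optional[MonophylyReport] = None,
) -> ClassificationDocument:
    """Build the ordered, annotated classification document.

    Without a tree the taxonomy's own row order stands in for phylogenetic
    order (children still grouped under parents); with a tree, supra-
    familial taxa follow the branching order of the tree.
    """
    if tree is not None:
        ordered = phylogenetic_order(tree, taxonomy, report)
    else:
        ordered = []

        def emit(taxon):
            ordered.append(taxon)
            children = taxonomy.children(taxon.name)
            fams = sorted(
                (t for t in children if t.rank == "family"), key=lambda t: t.name
            )
            supra = sorted(
                (t for t in children if t.rank != "family"), key=lambda t: t.row
            )
            ordered.extend(fams)
            for child in supra:
                emit(child)

        for root in sorted(taxonomy.roots(), key=lambda t: t.row):
            emit(root)

    depth_of: Dict[str, int] = {}
    entries = []
    for taxon in ordered:
        depth = 0 if taxon.parent is None else depth_of[taxon.parent] + 1
        depth_of[taxon.name] = depth
        record = report.by_name.get(taxon.name) if report is not None else None
        support = record.mrca_support if record is not None else None
        status = record.status if record is not None else None
        if taxon.rank == "family":
            support = None  # support is rendered only at supra-familial ranks
        entries.append(ClassificationEntry(taxon, depth, support, status))
    counts = counts_summary(taxonomy, report)
    return ClassificationDocument(entries, counts, taxonomy)
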