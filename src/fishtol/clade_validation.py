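"""Monophyly assessment and the bootstrap endorsement rule.

A named taxon is *monophyletic* when the most recent common ancestor
(MRCA) of its sampled tips contains exactly those tips; any foreign leaf
under the MRCA is an *intruder*. Order-level and supraordinal taxa are
endorsed when their MRCA carries bootstrap support strictly above 90%, or
— at lower or missing support — when they are flagged ``corroborated``
(consistently recovered by independent studies). Families are exempt from
endorsement; they are only flagged monophyletic or not.

Taxon tip sets derive from the tip-label convention: a family's tips are
the leaves whose parsed family equals its name, and a higher taxon's tips
are the union over its descendant families. Leaves whose family is not in
the taxonomy (e.g. outgroups) are excluded from all unions and reported
separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import pandas as pd

from .taxonomy_model import Taxonomy, Taxon, RANK_INDEX
from .tree_io import Phylogeny, parse_tip_label

__all__ = [
    "SUPPORT_THRESHOLD",
    "TaxonRecord",
    "MonophylyReport",
    "assess_monophyly",
    "support_at_mrca",
    "endorse_taxon",
    "validate_all",
]

#: endorsement needs support strictly above this percentage
SUPPORT_THRESHOLD = 90.0

_SUPRAFAMILIAL = tuple(r for r in RANK_INDEX if r != "family")


def assess_monophyly(tree: Phylogeny, taxon_tips: Iterable[str]):
    """Classify a tip set as monophyletic / non_monophyletic / monotypic / unsampled.

    Returns ``(status, intruders)`` where the intruders are the foreign
    leaves under the tip set's MRCA, sorted lexicographically.
    """
    tips = frozenset(taxon_tips)
    if not tips:
        return "unsampled", []
    if len(tips) == 1:
        return "monotypic", []
    mrca = tree.mrca(tips)
    intruders = sorted(tree.leafset(mrca) - tips)
    return ("monophyletic" if not intruders else "non_monophyletic"), intruders


def support_at_mrca(tree: Phylogeny, taxon_tips: Iterable[str]) -> Optional[float]:
    """Bootstrap support stored at the MRCA of the tips; None if unlabeled."""
    tips = frozenset(taxon_tips)
    if len(tips) < 2:
        raise ValueError("support_at_mrca needs at least two tips")
    return getattr(tree.mrca(tips), "support", None)


def endorse_taxon(status: str, support: Optional[float], flags: Iterable[str]) -> str:
    """Apply the endorsement rule to one supra-familial taxon.

    monophyletic with support > 90 -> ``endorsed``; monophyletic with lower
    or missing support, or non-monophyletic, -> ``endorsed_by_corroboration``
    when flagged ``corroborated`` and ``not_endorsed`` otherwise.
    Monotypic and unsampled taxa carry no testable clade: ``not_applicable``.
    """
    flags = frozenset(flags)
    if status in ("monotypic", "unsampled"):
        return "not_applicable"
    if status == "monophyletic":
        if support is not None and support > SUPPORT_THRESHOLD:
            return "endorsed"
        return "endorsed_by_corroboration" if "corroborated" in flags else "not_endorsed"
    # non-monophyletic: tolerated only when corroborated elsewhere and the
    # incongruence is not strongly supported here
    return "endorsed_by_corroboration" if "corroborated" in flags else "not_endorsed"


@dataclass(frozen=True)
class TaxonRecord:
    name: str
    rank: str
    n_tips_sampled: int
    status: str
    mrca_support: Optional[float]
    intruders: Tuple[str, ...]
    endorsement: str


class MonophylyReport:
    """Per-taxon monophyly records plus the summary counters."""

    def __init__(self, records, outgroup_tips, taxonomy: Taxonomy):
        self.records: List[TaxonRecord] = list(records)
        self.by_name: Dict[str, TaxonRecord] = {r.name: r for r in self.records}
        self.outgroup_tips: Tuple[str, ...] = tuple(sorted(outgroup_tips))
        self._taxonomy = taxonomy

    def __iter__(self):
        return iter(self.records)

    def families(self) -> List[TaxonRecord]:
        return [r for r in self.records if r.rank == "family"]

    def non_monophyletic_families(self) -> List[str]:
        return [r.name for r in self.families() if r.status == "non_monophyletic"]

    def incertae_sedis_by_series(self) -> Dict[str, List[str]]:
        grouped: Dict[str, List[str]] = {}
        for fam in self._taxonomy.families():
            if fam.has("incertae_sedis") and fam.parent is not None:
                parent = self._taxonomy.get(fam.parent)
                if parent.rank == "series":
                    grouped.setdefault(parent.name, []).append(fam.name)
        return {k: sorted(v) for k, v in sorted(grouped.items())}

    @property
    def summary(self) -> dict:
        fams = self.families()
        count = lambda s: sum(1 for r in fams if r.status == s)
        return {
            "families_total": len(fams),
            "families_sampled": sum(1 for r in fams if r.n_tips_sampled > 0),
            "families_non_monophyletic": count("non_monophyletic"),
            "families_monotypic": count("monotypic"),
            "families_unsampled": count("unsampled"),
            "incertae_sedis_by_series": self.incertae_sedis_by_series(),
            "outgroup_tips": list(self.outgroup_tips),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "name": r.name,
                    "rank": r.rank,
                    "n_tips_sampled": r.n_tips_sampled,
                    "status": r.status,
                    "mrca_support": "" if r.mrca_support is None else r.mrca_support,
                    "intruders": ";".join(r.intruders),
                    "endorsement": r.endorsement,
                }
                for r in self.records
            ]
        )

    def summary_json(self, **kwargs) -> str:
        return json.dumps(self.summary, indent=2, **kwargs)


def _family_tip_map(tree: Phylogeny):
    tips_by_family: Dict[str, set] = {}
    for label in tree.leaf_labels:
        fam = parse_tip_label(label).family
        tips_by_family.setdefault(fam, set()).add(label)
    return tips_by_family


def validate_all(
    tree: Phylogeny,
    taxonomy: Taxonomy,
    unknown_families: str = "warn",
) -> MonophylyReport:
    """Assess every taxon in the taxonomy against the tree.

    A family's tips are the leaves carrying its name; a higher taxon's tips
    are the union over its descendant families. Leaves whose family is not
    in the taxonomy are excluded from every union and reported in
    ``outgroup_tips`` (``unknown_families`` may be "warn", "error" or
    "ignore").
    """
    tips_by_family = _family_tip_map(tree)
    known = {t.name for t in taxonomy.families()}
    foreign_families = sorted(set(tips_by_family) - known)
    outgroup_tips = sorted(
        tip for fam in foreign_families for tip in tips_by_family[fam]
    )
    if foreign_families:
        msg = (
            f"{len(foreign_families)} tip families absent from the taxonomy "
            f"(treated as outgroups): {foreign_families[:10]}"
        )
        if unknown_families == "error":
            raise ValueError(msg)
        if unknown_families == "warn":
            warnings.warn(msg, stacklevel=2)

    records = []
    for taxon in taxonomy:
        fams = taxonomy.families_under(taxon)
        tips = frozenset().union(
            *(tips_by_family.get(f.name, set()) for f in fams)
        ) if fams else frozenset()
        status, intruders = assess_monophyly(tree, tips)
        support = (
            support_at_mrca(tree, tips)
            if status in ("monophyletic", "non_monophyletic")
            else None
        )
        endorsement = (
            "not_applicable"
            if taxon.rank == "family"
            else endorse_taxon(status, support, taxon.flags)
        )
        records.append(
            TaxonRecord(
                name=taxon.name,
                rank=taxon.rank,
                n_tips_sampled=len(tips),
                status=status,
                mrca_support=support,
                intruders=tuple(intruders),
                endorsement=endorsement,
            )
        )
    return MonophylyReport(records, outgroup_tips, taxonomy)
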