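"""Ranked Linnean taxonomy (megaclass -> family) with status flags.

The rank vocabulary is frozen to the 21 ranks used in modern ranked fish
classifications, from megaclass down to family, including the cohort-level
ranks (megacohort > supercohort > cohort > subcohort > infracohort) and the
section/subsection, division/subdivision and series/subseries levels that
sit between subsection and superorder. Unknown ranks are rejected rather
than coerced.

Status flags:

``provisional``
    The name awaits formal description; it is printed in quotation marks.
    The loader strips the quotes and sets this flag.
``incertae_sedis``
    A family of uncertain ordinal placement, attached directly to a series.
``not_examined``
    A family not sampled in the phylogeny; listed for completeness.
``corroborated``
    The clade is consistently recovered by independent studies — an input
    assertion standing in for a literature survey, used by the endorsement
    rule when bootstrap support alone is insufficient.
``sedis_mutabilis``
    The taxon's position among its siblings is explicitly unresolved.
``non_monophyletic_declared``
    The source classification itself flags the taxon as non-monophyletic.

Rank-ending conventions (order "-iformes", suborder "-oidei", infraorder
"-ales", division "-pterygii") are data, not code: :class:`RankRule`
objects with per-name exemptions, checkable via
:func:`check_rank_endings`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from typing import Iterable, List, Optional, Sequence, Tuple

import pandas as pd

from .exceptions import TaxonomyError

__all__ = [
    "RANKS",
    "FLAGS",
    "Taxon",
    "Taxonomy",
    "RankRule",
    "DEFAULT_RANK_RULES",
    "RankViolation",
    "load_taxonomy",
    "write_taxonomy",
    "check_rank_endings",
    "load_rank_rules",
]

RANKS: Tuple[str, ...] = (
    "megaclass",
    "superclass",
    "class",
    "subclass",
    "infraclass",
    "megacohort",
    "supercohort",
    "cohort",
    "subcohort",
    "infracohort",
    "section",
    "subsection",
    "division",
    "subdivision",
    "series",
    "subseries",
    "superorder",
    "order",
    "suborder",
    "infraorder",
    "family",
)
RANK_INDEX = {r: i for i, r in enumerate(RANKS)}

FLAGS = frozenset(
    {
        "provisional",
        "incertae_sedis",
        "not_examined",
        "corroborated",
        "sedis_mutabilis",
        "non_monophyletic_declared",
    }
)

_QUOTES = "\"“”"


@dataclass(frozen=True)
class Taxon:
    name: str
    rank: str
    parent: Optional[str] = None
    flags: frozenset = frozenset()
    anchor: Optional[str] = None  # sibling after which an unsampled taxon sorts
    row: int = -1  # source row, used as a deterministic tiebreak

    def has(self, flag: str) -> bool:
        return flag in self.flags


@dataclass(frozen=True)
class RankRule:
    rank: str
    suffixes: Tuple[str, ...]
    exempt: Tuple[str, ...] = ()

    def __post_init__(self):
        if not self.suffixes:
            raise TaxonomyError(f"rank rule for {self.rank!r} needs suffixes")

    def accepts(self, name: str) -> bool:
        if name in self.exempt:
            return True
        return any(name.endswith(s.lstrip("-")) for s in self.suffixes)


#: the endings the source classification enforces; series, cohort and
#: supercohort names carry no uniform suffix and are deliberately unruled.
DEFAULT_RANK_RULES: Tuple[RankRule, ...] = (
    RankRule("order", ("-iformes",)),
    RankRule("suborder", ("-oidei",), exempt=("Zeiodei",)),
    RankRule("infraorder", ("-ales",)),
    RankRule("division", ("-pterygii",)),
)


@dataclass(frozen=True)
class RankViolation:
    taxon: Taxon
    expected_suffixes: Tuple[str, ...]


class Taxonomy:
    """An ordered collection of :class:`Taxon` rows forming a ranked forest."""

    def __init__(self, taxa: Sequence[Taxon], validate: bool = True):
        self.taxa: List[Taxon] = list(taxa)
        self._by_key = {}
        self._by_name = {}
        for t in self.taxa:
            key = (t.name, t.rank)
            if key in self._by_key:
                raise TaxonomyError(f"duplicate taxon {t.name!r} at rank {t.rank!r}")
            self._by_key[key] = t
            self._by_name.setdefault(t.name, []).append(t)
        self._children = {}
        for t in self.taxa:
            if t.parent is not None:
                self._children.setdefault(t.parent, []).append(t)
        if validate:
            self.validate()

    # -- access --------------------------------------------------------
    def __iter__(self):
        return iter(self.taxa)

    def __len__(self):
        return len(self.taxa)

    def __contains__(self, name):
        return name in self._by_name

    def __eq__(self, other):
        if not isinstance(other, Taxonomy):
            return NotImplemented
        strip = lambda t: (t.name, t.rank, t.parent, t.flags, t.anchor)
        return sorted(map(strip, self.taxa)) == sorted(map(strip, other.taxa))

    def get(self, name: str, rank: Optional[str] = None) -> Taxon:
        if rank is not None:
            return self._by_key[(name, rank)]
        hits = self._by_name.get(name, [])
        if not hits:
            raise KeyError(f"no taxon named {name!r}")
        if len(hits) > 1:
            raise TaxonomyError(
                f"taxon name {name!r} is ambiguous across ranks "
                f"{[t.rank for t in hits]}; pass rank="
            )
        return hits[0]

    def children(self, name: str) -> List[Taxon]:
        return list(self._children.get(name, []))

    def roots(self) -> List[Taxon]:
        return [t for t in self.taxa if t.parent is None]

    def ancestors(self, taxon: Taxon):
        seen = set()
        t = taxon
        while t.parent is not None:
            if t.parent in seen:
                raise TaxonomyError(f"parent cycle through {t.parent!r}")
            seen.add(t.parent)
            t = self.get(t.parent)
            yield t

    def descendants(self, name: str):
        stack = self.children(name)
        while stack:
            t = stack.pop(0)
            yield t
            stack.extend(self.children(t.name))

    def families(self) -> List[Taxon]:
        return [t for t in self.taxa if t.rank == "family"]

    def families_under(self, taxon: Taxon) -> List[Taxon]:
        if taxon.rank == "family":
            return [taxon]
        return [t for t in self.descendants(taxon.name) if t.rank == "family"]

    def at_rank(self, rank: str) -> List[Taxon]:
        return [t for t in self.taxa if t.rank == rank]

    # -- invariants ----------------------------------------------------
    def validate(self):
        for t in self.taxa:
            if t.rank not in RANK_INDEX:
                raise TaxonomyError(f"unknown rank {t.rank!r} for taxon {t.name!r}")
            bad = t.flags - FLAGS
            if bad:
                raise TaxonomyError(f"unknown flags {sorted(bad)} on {t.name!r}")
            if any(q in t.name for q in _QUOTES):
                raise TaxonomyError(
                    f"taxon name {t.name!r} stored with quotation marks; "
                    "strip them and set the provisional flag"
                )
            if t.parent is not None:
                if t.parent not in self._by_name:
                    raise TaxonomyError(
                        f"taxon {t.name!r} references missing parent {t.parent!r}"
                    )
                parent = self.get(t.parent)
                if RANK_INDEX[parent.rank] > RANK_INDEX[t.rank]:
                    raise TaxonomyError(
                        f"parent {parent.name!r} ({parent.rank}) does not outrank "
                        f"{t.name!r} ({t.rank})"
                    )
        for t in self.taxa:
            list(self.ancestors(t))  # raises on cycles
        for fam in self.families():
            ranks = {a.rank for a in self.ancestors(fam)}
            if "order" in ranks:
                continue
            if fam.has("incertae_sedis") and "series" in ranks:
                continue
            raise TaxonomyError(
                f"family {fam.name!r} has no order ancestor and is not an "
                "incertae sedis family under a series"
            )
        return self


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------
def _strip_quotes(name: str):
    stripped = name.strip().strip(_QUOTES)
    return stripped, stripped != name.strip()


def load_taxonomy(source) -> Taxonomy:
    """Load a ranked TSV (columns name, rank, parent, flags[, anchor]).

    Quoted names mark provisional taxa: the quotes are stripped and the
    ``provisional`` flag is set. Flags are semicolon- or comma-separated.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(
            source, sep="\t", dtype=str, keep_default_na=False,
            quoting=csv.QUOTE_NONE,
        )
    required = {"name", "rank", "parent", "flags"}
    if not required <= set(df.columns):
        raise TaxonomyError(
            f"taxonomy table needs columns {sorted(required)}; got {list(df.columns)}"
        )
    taxa = []
    for i, row in enumerate(df.itertuples(index=False)):
        rank = row.rank.strip().lower()
        if rank not in RANK_INDEX:
            raise TaxonomyError(f"unknown rank {row.rank!r} at row {i + 2}")
        name, quoted = _strip_quotes(row.name)
        if not name:
            raise TaxonomyError(f"empty taxon name at row {i + 2}")
        flags = {
            f.strip()
            for f in row.flags.replace(",", ";").split(";")
            if f.strip()
        }
        if quoted:
            flags.add("provisional")
        parent, _ = _strip_quotes(row.parent)
        anchor = getattr(row, "anchor", "").strip() or None
        taxa.append(
            Taxon(
                name=name,
                rank=rank,
                parent=parent or None,
                flags=frozenset(flags),
                anchor=anchor,
                row=i,
            )
        )
    return Taxonomy(taxa)


def write_taxonomy(taxonomy: Taxonomy, path=None) -> pd.DataFrame:
    """Serialise back to the TSV schema (provisional names re-quoted)."""
    rows = []
    for t in taxonomy:
        flags = sorted(t.flags - {"provisional"})
        name = f'"{t.name}"' if t.has("provisional") else t.name
        rows.append(
            {
                "name": name,
                "rank": t.rank,
                "parent": t.parent or "",
                "flags": ";".join(flags),
                "anchor": t.anchor or "",
            }
        )
    df = pd.DataFrame(rows, columns=["name", "rank", "parent", "flags", "anchor"])
    if path is not None:
        df.to_csv(path, sep="\t", index=False, quoting=csv.QUOTE_NONE)
    return df


# ----------------------------------------------------------------------
# rank-ending lint
# ----------------------------------------------------------------------
def check_rank_endings(
    taxonomy: Taxonomy,
    rules: Iterable[RankRule] = DEFAULT_RANK_RULES,
) -> List[RankViolation]:
    """List taxa whose names break their rank's suffix convention.

    Violations come back in taxonomy row order; exempt names are skipped.
    """
    by_rank = {}
    for rule in rules:
        by_rank.setdefault(rule.rank, []).append(rule)
    violations = []
    for t in taxonomy:
        for rule in by_rank.get(t.rank, []):
            if not rule.accepts(t.name):
                violations.append(RankViolation(t, rule.suffixes))
    return violations


def load_rank_rules(path) -> Tuple[RankRule, ...]:
    """Read rules from a TSV with columns rank, suffixes[, exempt]."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    rules = []
    for row in df.itertuples(index=False):
        rules.append(
            RankRule(
                rank=row.rank.strip().lower(),
                suffixes=tuple(s for s in row.suffixes.split(";") if s),
                exempt=tuple(
                    e for e in getattr(row, "exempt", "").split(";") if e
                ),
            )
        )
    return tuple(rules)
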