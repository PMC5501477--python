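"""Time-scaling donor subtrees and grafting them into a calibrated backbone.

The assembly model: a calibrated, ultrametric backbone chronogram carries a
small number of placeholder clades; each placeholder is replaced by a
densely sampled donor subtree that was inferred independently. Donors are
first made ultrametric (:func:`smooth_to_ultrametric`), rescaled so their
crown age matches a secondary calibration (:func:`rescale_to_age`), and
attached so the composite tree stays ultrametric (:func:`graft_clade`):
the donor's stem branch absorbs the difference between the backbone parent
node's age and the calibrated crown age.

Smoothing here is a deterministic recursive mean-path smoother, not a
penalized-likelihood optimisation: each node's age is the child-averaged
mean of its remaining root-to-leaf path lengths, scaled into the interval
below its parent's age. It is exact on already-ultrametric input
(idempotent), preserves topology, and recovers true node ages as
branch-rate noise shrinks. A different smoother can be swapped in through
the ``smoother`` hook on :func:`graft_all`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence, Tuple, Union

import pandas as pd

from .exceptions import (
    FishtolError,
    GraftError,
    LabelCollisionError,
    NegativeStemError,
    NonMonophyleticAttachmentError,
    TreeValidationError,
)
from .tree_io import Phylogeny

__all__ = [
    "CalibrationEntry",
    "CalibrationTable",
    "load_calibrations",
    "check_ultrametric",
    "smooth_to_ultrametric",
    "rescale_to_age",
    "graft_clade",
    "graft_all",
    "node_ages",
]

#: tolerance used for the ultrametricity preconditions of rescale/graft
ULTRAMETRIC_RTOL = 1e-9

CladeSelector = Union[str, Iterable[str]]


# ----------------------------------------------------------------------
# calibrations
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class CalibrationEntry:
    """A secondary calibration: a backbone clade and its crown age in Ma."""

    clade_name: str
    crown_age_ma: Optional[float] = None  # None -> take age from the backbone
    tips: Tuple[str, ...] = ()

    def __post_init__(self):
        if self.crown_age_ma is not None and self.crown_age_ma <= 0:
            raise FishtolError(
                f"calibration {self.clade_name!r}: crown age must be positive"
            )

    def selector(self) -> CladeSelector:
        return tuple(self.tips) if self.tips else self.clade_name


@dataclass
class CalibrationTable:
    entries: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)

    def get(self, clade_name: str) -> CalibrationEntry:
        for e in self.entries:
            if e.clade_name == clade_name:
                return e
        raise KeyError(clade_name)


def load_calibrations(path) -> CalibrationTable:
    """Read a calibration TSV with columns clade_name, tips, crown_age_ma.

    ``tips`` is an optional semicolon-separated tip list; when present it
    overrides clade-name lookup on the backbone. An empty ``crown_age_ma``
    means "use the backbone's own crown age".
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"clade_name", "crown_age_ma"}
    if not required <= set(df.columns):
        raise FishtolError(
            f"calibration table needs columns {sorted(required)}; got {list(df.columns)}"
        )
    entries = []
    for _, row in df.iterrows():
        tips = tuple(
            t for t in str(row.get("tips", "")).split(";") if t
        )
        age = row["crown_age_ma"].strip()
        entries.append(
            CalibrationEntry(
                clade_name=row["clade_name"],
                crown_age_ma=float(age) if age else None,
                tips=tips,
            )
        )
    return CalibrationTable(entries)


# ----------------------------------------------------------------------
# ultrametricity
# ----------------------------------------------------------------------
def check_ultrametric(tree: Phylogeny, rel_tol: float = ULTRAMETRIC_RTOL):
    """Test leaf-depth equality.

    Returns ``(is_ultrametric, max_deviation)`` where the deviation is the
    largest absolute difference between a leaf depth and the mean leaf
    depth (in Myr); the tree passes iff that deviation is at most
    ``rel_tol`` times the mean depth.
    """
    depths = tree.depths()
    leaf_depths = [depths[nd] for nd in tree.leaf_nodes()]
    mean = sum(leaf_depths) / len(leaf_depths)
    deviation = max((abs(d - mean) for d in leaf_depths), default=0.0)
    return deviation <= rel_tol * mean if mean > 0 else deviation == 0.0, deviation


def node_ages(tree: Phylogeny) -> dict:
    """Node -> age in Myr, with the present at 0 (ultrametric trees only)."""
    ok, dev = check_ultrametric(tree, rel_tol=1e-6)
    if not ok:
        raise TreeValidationError(
            f"node ages are only defined for ultrametric trees "
            f"(max leaf-depth deviation {dev:g} Myr)"
        )
    depths = tree.depths()
    height = max(depths[nd] for nd in tree.leaf_nodes())
    return {nd: height - d for nd, d in depths.items()}


def _mean_paths(tree: Phylogeny) -> dict:
    """Child-averaged mean remaining root-to-leaf path length per node."""
    mp = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            mp[nd] = 0.0
        else:
            children = nd.child_nodes()
            mp[nd] = sum(
                (ch.edge.length or 0.0) + mp[ch] for ch in children
            ) / len(children)
    return mp


def smooth_to_ultrametric(tree: Phylogeny) -> Phylogeny:
    """Deterministic recursive mean-path smoothing to an ultrametric tree.

    The root height is set to the child-averaged mean root-to-leaf path of
    the input; each internal node is then placed, root to leaf, at the
    fraction of its parent's age given by its own mean remaining path over
    the mean path through its stem branch. Ages therefore decrease
    monotonically (strictly, except across zero-length branches), topology
    is untouched, and an already-ultrametric tree is a fixed point.
    """
    if tree.n_leaves < 2:
        raise TreeValidationError("smoothing needs a tree with at least two leaves")
    for nd in tree.nodes():
        if nd is not tree.root and nd.edge.length is None:
            raise TreeValidationError("smoothing requires branch lengths everywhere")

    out = tree.copy()
    mp = _mean_paths(out)
    age = {out.root: mp[out.root]}
    for nd in out.tree.preorder_node_iter():
        if nd is out.root:
            continue
        if nd.is_leaf():
            age[nd] = 0.0
        else:
            total = mp[nd] + (nd.edge.length or 0.0)
            age[nd] = age[nd.parent_node] * (mp[nd] / total) if total > 0 else age[nd.parent_node]
    for nd in out.tree.preorder_node_iter():
        if nd is out.root:
            continue
        nd.edge.length = age[nd.parent_node] - age[nd]
    out._invalidate_caches()
    return out


def rescale_to_age(tree: Phylogeny, target_crown_age: float) -> Phylogeny:
    """Multiply every branch length so the root (crown) height hits the target."""
    if target_crown_age <= 0:
        raise FishtolError("target crown age must be positive")
    ok, dev = check_ultrametric(tree)
    if not ok:
        raise TreeValidationError(
            f"rescale_to_age needs an ultrametric tree (deviation {dev:g} Myr); "
            "run smooth_to_ultrametric first"
        )
    depths = tree.depths()
    height = max(depths[nd] for nd in tree.leaf_nodes())
    if height == 0:
        raise TreeValidationError("cannot rescale a tree of zero height")
    factor = target_crown_age / height
    out = tree.copy()
    for nd in out.tree.preorder_node_iter():
        if nd.edge.length is not None:
            nd.edge.length *= factor
    out._invalidate_caches()
    return out


# ----------------------------------------------------------------------
# grafting
# ----------------------------------------------------------------------
def _resolve_selector(backbone: Phylogeny, selector: CladeSelector):
    """Return (crown node, selected tip set) for a name or explicit tip set."""
    if isinstance(selector, str):
        node = backbone.find_clade(selector)
        if node is None:
            raise GraftError(f"no backbone clade named {selector!r}")
        return node, backbone.leafset(node)
    tips = frozenset(selector)
    if len(tips) < 2:
        raise GraftError("a clade selector must cover at least two backbone tips")
    node = backbone.mrca(tips)
    return node, tips


def graft_clade(
    backbone: Phylogeny,
    selector: CladeSelector,
    donor: Phylogeny,
    crown_age: Optional[float] = None,
    force: bool = False,
    squeeze: bool = False,
) -> Phylogeny:
    """Replace a backbone clade by a donor subtree, preserving ultrametricity.

    Parameters
    ----------
    selector : clade name or tip set identifying the backbone crown node.
    crown_age : Ma; ``None`` keeps the backbone's own age for that crown.
    force : attach at the MRCA even if the selected tips are not
        monophyletic; displaced tips are removed and reported via a warning.
    squeeze : when the calibrated crown age reaches the parent node's age,
        compress the donor to 0.99x the parent age instead of failing.

    The donor is rescaled so its crown age equals ``crown_age`` and the
    stem branch is set to ``parent age - crown age``; every node age
    outside the replaced clade is untouched.
    """
    node, tips = _resolve_selector(backbone, selector)
    clade_leaves = backbone.leafset(node)
    if clade_leaves != tips:
        displaced = sorted(clade_leaves - tips)
        if not force:
            raise NonMonophyleticAttachmentError(
                f"selector tips are not monophyletic in the backbone; the MRCA "
                f"also contains {displaced} (pass force=True to attach anyway)",
                displaced=displaced,
            )
        warnings.warn(
            f"grafting at a non-monophyletic attachment; displaced tips removed: "
            f"{displaced}",
            stacklevel=2,
        )
    if node is backbone.root:
        raise GraftError("cannot graft over the backbone root")

    ok, dev = check_ultrametric(donor)
    if not ok:
        raise TreeValidationError(
            f"donor is not ultrametric (deviation {dev:g} Myr); smooth it first"
        )

    ages = node_ages(backbone)
    parent_age = ages[node.parent_node]
    if crown_age is None:
        crown_age = ages[node]
    if crown_age >= parent_age:
        if not squeeze:
            name = selector if isinstance(selector, str) else "<tip set>"
            raise NegativeStemError(
                f"crown age {crown_age:g} Ma >= parent node age {parent_age:g} Ma "
                f"for clade {name}; pass squeeze=True to compress the donor"
            )
        warnings.warn(
            f"crown age {crown_age:g} >= parent age {parent_age:g}; "
            f"squeezing donor to {0.99 * parent_age:g} Ma",
            stacklevel=2,
        )
        crown_age = 0.99 * parent_age

    outside = frozenset(backbone.leafset(backbone.root)) - clade_leaves
    collisions = sorted(outside & frozenset(donor.leaf_labels))
    if collisions:
        raise LabelCollisionError(
            f"donor tips collide with backbone tips outside the replaced clade: "
            f"{collisions}"
        )

    scaled = rescale_to_age(donor, crown_age)

    out = backbone.copy()
    # locate the crown node in the copy by preorder position
    index = backbone.preorder_index()[node]
    target = list(out.tree.preorder_node_iter())[index]
    parent = target.parent_node
    position = parent.child_nodes().index(target)
    parent.remove_child(target)
    graft_root = scaled.root
    graft_root.edge.length = parent_age - crown_age
    if getattr(graft_root, "support", None) is None:
        graft_root.support = getattr(node, "support", None)
    parent.insert_child(position, graft_root)
    out._invalidate_caches()
    return Phylogeny(out.tree)


def graft_all(
    backbone: Phylogeny,
    donors: dict,
    calibrations: CalibrationTable,
    smoother: Callable[[Phylogeny], Phylogeny] = smooth_to_ultrametric,
    squeeze: bool = False,
) -> Phylogeny:
    """Smooth and graft several donors (``{clade_name: Phylogeny}``) in turn."""
    tree = backbone
    for entry in calibrations:
        donor = donors[entry.clade_name]
        ok, _ = check_ultrametric(donor)
        if not ok:
            donor = smoother(donor)
        tree = graft_clade(
            tree,
            entry.selector(),
            donor,
            crown_age=entry.crown_age_ma,
            squeeze=squeeze,
        )
    return tree
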