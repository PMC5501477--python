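"""Seeded generators for backbones, donor subtrees and planted taxonomies.

Every pipeline stage is testable without any external files: the
generators produce (i) ultrametric pure-birth (Yule) backbone chronograms
with integer bootstrap labels, (ii) donor chronograms whose branch lengths
carry independent lognormal rate noise (so they are non-ultrametric for
sigma > 0, with the noise-free node ages recorded as truth), and (iii)
ranked taxonomies planted over a tree by partitioning its leaves into
contiguous clades, with a known set of non-monophyletic families (created
by swapping tip labels between neighbouring families — a taxonomy-vs-tree
conflict, which is how real non-monophyly manifests to this pipeline) and
a known set of incertae sedis families re-parented to their series.

Everything is deterministic under (parameters, seed): the same seed gives
bit-identical newick and TSV output. Pure birth is used rather than
birth-death; extinction adds nothing that these pipeline tests need.

:func:`simulate_study` bundles the stages at the scale of a ~2000-tip
composite tree assembled from a backbone plus four dense donor clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import dendropy
import numpy as np

from .chronogram_ops import (
    CalibrationEntry,
    CalibrationTable,
    graft_all,
    node_ages,
)
from .exceptions import FishtolError
from .taxonomy_model import Taxon, Taxonomy
from .tree_io import Phylogeny

__all__ = [
    "simulate_backbone",
    "simulate_donor",
    "plant_taxonomy",
    "PlantedTruth",
    "SyntheticTruth",
    "simulate_study",
]


# ----------------------------------------------------------------------
# Yule trees
# ----------------------------------------------------------------------
def _yule_topology(n_tips: int, rng: np.random.Generator):
    """Crown Yule tree: returns (children, birth_time) maps over int node ids."""
    # node 0 is the crown; lineages split at exponential waiting times
    children: Dict[int, List[int]] = {0: []}
    birth: Dict[int, float] = {0: 0.0}
    next_id = 1
    active: List[int] = []
    for _ in range(2):
        children[0].append(next_id)
        children[next_id] = []
        birth[next_id] = 0.0
        active.append(next_id)
        next_id += 1
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        split = active.pop(int(rng.integers(k)))
        for _ in range(2):
            children[split].append(next_id)
            children[next_id] = []
            birth[next_id] = t
            active.append(next_id)
            next_id += 1
    present = t + rng.exponential(1.0 / n_tips)
    return children, birth, present


def _build_phylogeny(
    children,
    birth,
    present: float,
    root_age: float,
    rng: np.random.Generator,
    support_range: Tuple[int, int],
    label_prefix: str,
) -> Phylogeny:
    scale = root_age / present
    lo, hi = support_range
    if not (2 <= lo <= hi <= 100):
        raise FishtolError("support_range must satisfy 2 <= lo <= hi <= 100")
    leaf_counter = [0]

    def build(idx: int) -> dendropy.Node:
        # a node's edge spans from its birth (its parent's split) to its
        # own event: its split time for internal nodes, the present for leaves
        nd = dendropy.Node()
        if children[idx]:
            split_time = birth[children[idx][0]]
            nd.edge.length = (split_time - birth[idx]) * scale
            nd.support = float(rng.integers(lo, hi + 1))
            nd.label = None
            for ch in children[idx]:
                nd.add_child(build(ch))
        else:
            nd.support = None
            leaf_counter[0] += 1
            nd.label = f"{label_prefix}{leaf_counter[0]:04d}"
            nd.edge.length = (present - birth[idx]) * scale
        return nd

    root = build(0)
    root.edge.length = None
    tree = dendropy.Tree(seed_node=root)
    return Phylogeny(tree)


def simulate_backbone(
    n_tips: int,
    birth_rate: float = 1.0,
    root_age: float = 425.0,
    support_range: Tuple[int, int] = (50, 100),
    seed: int = 0,
    label_prefix: str = "T",
) -> Phylogeny:
    """Ultrametric pure-birth chronogram conditioned on ``n_tips``.

    The tree is scaled so the crown (root) age equals ``root_age`` Ma —
    the birth rate therefore only shapes relative node depths through the
    Yule process and is kept at 1/Myr by default. Internal nodes carry
    integer bootstrap supports drawn uniformly from ``support_range``.
    """
    if n_tips < 2:
        raise FishtolError("a backbone needs at least two tips")
    if root_age <= 0 or birth_rate <= 0:
        raise FishtolError("root_age and birth_rate must be positive")
    rng = np.random.default_rng(seed)
    children, birth, present = _yule_topology(n_tips, rng)
    # birth_rate rescales time uniformly; the subsequent root_age scaling
    # makes it a no-op, but keep it for dimensional honesty
    present /= birth_rate
    birth = {k: v / birth_rate for k, v in birth.items()}
    return _build_phylogeny(
        children, birth, present, root_age, rng, support_range, label_prefix
    )


def simulate_donor(
    n_tips: int,
    crown_age: float,
    rate_noise_sigma: float = 0.0,
    seed: int = 0,
    support_range: Tuple[int, int] = (50, 100),
    label_prefix: str = "D",
):
    """Donor chronogram with multiplicative lognormal branch-rate noise.

    Returns ``(tree, true_ages)`` where ``true_ages`` maps each clade's
    frozenset of leaf labels to its noise-free age in Ma. With sigma = 0
    the tree is exactly ultrametric with crown age ``crown_age``.
    """
    if rate_noise_sigma < 0:
        raise FishtolError("rate_noise_sigma must be >= 0")
    tree = simulate_backbone(
        n_tips,
        root_age=crown_age,
        support_range=support_range,
        seed=seed,
        label_prefix=label_prefix,
    )
    ages = node_ages(tree)
    true_ages = {tree.leafset(nd): age for nd, age in ages.items()}
    if rate_noise_sigma > 0:
        rng = np.random.default_rng((seed, 1))
        for nd in tree.tree.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= rng.lognormal(0.0, rate_noise_sigma)
        tree._invalidate_caches()
    return tree, true_ages


# ----------------------------------------------------------------------
# planted taxonomies
# ----------------------------------------------------------------------
def _split_frontier(tree: Phylogeny, frontier, k: int):
    """Refine a list of disjoint clade nodes to exactly ``k`` by splitting
    the largest (ties: first in preorder) until the count is reached."""
    pre = tree.preorder_index()
    frontier = list(frontier)
    while len(frontier) < k:
        splittable = [nd for nd in frontier if not nd.is_leaf()]
        if not splittable:
            raise FishtolError(
                f"cannot split {len(frontier)} clades into {k}: out of internal nodes"
            )
        target = max(splittable, key=lambda nd: (len(tree.leafset(nd)), -pre[nd]))
        at = frontier.index(target)
        frontier[at : at + 1] = target.child_nodes()
    return frontier


@dataclass
class PlantedTruth:
    """Ground truth recorded while planting a taxonomy over a tree."""

    seed: int
    tree: Phylogeny  # relabeled copy of the input tree
    nonmono_families: frozenset
    incertae_families: frozenset
    clade_supports: Dict[str, Optional[float]]
    n_series: int
    n_orders: int
    n_suborders: int
    n_families: int


def plant_taxonomy(
    tree: Phylogeny,
    n_families: int,
    k_nonmono: int = 0,
    m_incertae: int = 0,
    seed: int = 0,
    n_orders: Optional[int] = None,
    n_suborders: Optional[int] = None,
    n_series: Optional[int] = None,
) -> Tuple[Taxonomy, PlantedTruth]:
    """Partition a tree's leaves into a ranked taxonomy with known truth.

    Leaves are partitioned into ``n_families`` contiguous clades (nested
    inside suborder/order/series clades) and relabeled
    ``FamilyNNN_GenusNNN_spJ_CXXXXX``. ``k_nonmono`` families then each
    swap one tip label with a neighbouring family in the same suborder —
    both members of each swap are recorded as non-monophyletic truth.
    ``m_incertae`` further families are re-parented from their order to
    the enclosing series and flagged ``incertae_sedis``.
    """
    n_leaves = tree.n_leaves
    if n_families > n_leaves // 2:
        raise FishtolError("n_families must be at most half the number of leaves")
    if k_nonmono >= n_families:
        raise FishtolError("k_nonmono must be smaller than n_families")
    if n_orders is None:
        n_orders = max(1, n_families // 5)
    if n_suborders is None:
        n_suborders = max(n_orders, n_families // 3)
    if n_series is None:
        n_series = max(1, n_orders // 6)
    if not (1 <= n_series <= n_orders <= n_suborders <= n_families):
        raise FishtolError(
            "need 1 <= n_series <= n_orders <= n_suborders <= n_families"
        )
    rng = np.random.default_rng(seed)

    work = tree.copy()
    series_f = _split_frontier(work, [work.root], n_series)
    order_f = _split_frontier(work, series_f, n_orders)
    suborder_f = _split_frontier(work, order_f, n_suborders)
    family_f = _split_frontier(work, suborder_f, n_families)

    def enclosing(coarse, fine):
        """fine node index -> coarse node index, by clade containment."""
        out = []
        for nd in fine:
            leaves = work.leafset(nd)
            for j, up in enumerate(coarse):
                if leaves <= work.leafset(up):
                    out.append(j)
                    break
        return out

    fam_to_sub = enclosing(suborder_f, family_f)
    sub_to_ord = enclosing(order_f, suborder_f)
    ord_to_ser = enclosing(series_f, order_f)

    # relabel leaves family by family, in tree order
    code = [0]
    fam_leaves: List[List] = []
    for fi, nd in enumerate(family_f, start=1):
        leaves = [nd] if nd.is_leaf() else list(nd.leaf_iter())
        for j, leaf in enumerate(leaves, start=1):
            code[0] += 1
            leaf.label = f"Family{fi:03d}_Genus{fi:03d}_sp{j}_C{code[0]:05d}"
        fam_leaves.append(leaves)
    work._invalidate_caches()

    fam_name = lambda i: f"Family{i:03d}"
    sub_name = lambda i: f"Suborder{i:03d}oidei"
    ord_name = lambda i: f"Order{i:03d}iformes"
    ser_name = lambda i: f"Series{i:03d}aria"
    root_name = "Synthopterygii"

    # plant non-monophyly by swapping one tip between neighbouring
    # same-suborder families; keep the swapped pairs disjoint
    # pair eligible (>= 2 tips) families within each suborder; each planted
    # swap exchanges one tip label between the two members of a pair, making
    # both non-monophyletic while leaving the suborder's tip set intact
    pairs = []
    for s in range(n_suborders):
        eligible = [
            i for i in range(n_families)
            if fam_to_sub[i] == s and len(fam_leaves[i]) >= 2
        ]
        pairs.extend(zip(eligible[0::2], eligible[1::2]))
    if len(pairs) < k_nonmono:
        raise FishtolError(
            f"could only plant {len(pairs)} of {k_nonmono} requested "
            "non-monophyletic families; use more families or a larger tree"
        )
    chosen = (
        sorted(
            int(j) for j in rng.choice(len(pairs), size=k_nonmono, replace=False)
        )
        if k_nonmono
        else []
    )
    used: set = set()
    nonmono = set()
    for j in chosen:
        a_i, b_i = pairs[j]
        used.update({a_i, b_i})
        a = fam_leaves[a_i][-1]
        b = fam_leaves[b_i][0]
        a.label, b.label = b.label, a.label
        nonmono.update({fam_name(a_i + 1), fam_name(b_i + 1)})
    work._invalidate_caches()

    # incertae sedis: re-parent families untouched by the swaps, without
    # ever emptying an order of its last family
    fam_to_ord = [sub_to_ord[s] for s in fam_to_sub]
    per_order = {o: fam_to_ord.count(o) for o in set(fam_to_ord)}
    per_suborder = {s: fam_to_sub.count(s) for s in set(fam_to_sub)}
    free = [i for i in range(n_families) if i not in used]
    rng.shuffle(free)
    incertae_idx: set = set()
    for i in free:
        if len(incertae_idx) == m_incertae:
            break
        if per_order[fam_to_ord[i]] > 1 and per_suborder[fam_to_sub[i]] > 1:
            incertae_idx.add(i)
            per_order[fam_to_ord[i]] -= 1
            per_suborder[fam_to_sub[i]] -= 1
    if len(incertae_idx) < m_incertae:
        raise FishtolError(
            f"could only plant {len(incertae_idx)} of {m_incertae} requested "
            "incertae sedis families without emptying an order"
        )

    taxa = [Taxon(root_name, "division", None)]
    for si in range(n_series):
        taxa.append(Taxon(ser_name(si + 1), "series", root_name))
    for oi in range(n_orders):
        taxa.append(Taxon(ord_name(oi + 1), "order", ser_name(ord_to_ser[oi] + 1)))
    for bi in range(n_suborders):
        taxa.append(
            Taxon(sub_name(bi + 1), "suborder", ord_name(sub_to_ord[bi] + 1))
        )
    for fi in range(n_families):
        if fi in incertae_idx:
            series = ord_to_ser[sub_to_ord[fam_to_sub[fi]]]
            taxa.append(
                Taxon(
                    fam_name(fi + 1),
                    "family",
                    ser_name(series + 1),
                    frozenset({"incertae_sedis"}),
                )
            )
        else:
            taxa.append(
                Taxon(fam_name(fi + 1), "family", sub_name(fam_to_sub[fi] + 1))
            )
    taxonomy = Taxonomy(
        [Taxon(t.name, t.rank, t.parent, t.flags, t.anchor, i)
         for i, t in enumerate(taxa)]
    )

    supports: Dict[str, Optional[float]] = {}
    for names, frontier in (
        ([ser_name(i + 1) for i in range(n_series)], series_f),
        ([ord_name(i + 1) for i in range(n_orders)], order_f),
        ([sub_name(i + 1) for i in range(n_suborders)], suborder_f),
    ):
        for name, nd in zip(names, frontier):
            supports[name] = getattr(nd, "support", None) if not nd.is_leaf() else None
    for fi, nd in enumerate(family_f):
        if fam_name(fi + 1) not in nonmono and not nd.is_leaf():
            supports[fam_name(fi + 1)] = getattr(nd, "support", None)

    truth = PlantedTruth(
        seed=seed,
        tree=work,
        nonmono_families=frozenset(nonmono),
        incertae_families=frozenset(fam_name(i + 1) for i in incertae_idx),
        clade_supports=supports,
        n_series=n_series,
        n_orders=n_orders,
        n_suborders=n_suborders,
        n_families=n_families,
    )
    return taxonomy, truth


# ----------------------------------------------------------------------
# study-scale bundle
# ----------------------------------------------------------------------
@dataclass
class SyntheticTruth:
    """Full synthetic study bundle: inputs, grafted tree and planted truth."""

    seed: int
    backbone: Phylogeny
    backbone_ages: Dict[frozenset, float]
    donors: Dict[str, Phylogeny]
    donor_true_ages: Dict[str, Dict[frozenset, float]]
    calibrations: CalibrationTable
    grafted: Phylogeny
    taxonomy: Taxonomy
    tree: Phylogeny  # grafted + relabeled, what validation runs on
    nonmono_families: frozenset
    incertae_families: frozenset
    clade_supports: Dict[str, Optional[float]]


def _pick_disjoint_clades(
    tree: Phylogeny, n_clades: int, size_range: Tuple[int, int]
):
    """Deterministically pick disjoint clades with sizes in the given range."""
    lo, hi = size_range
    pre = tree.preorder_index()
    chosen: List = []
    taken: set = set()
    for nd in sorted(pre, key=pre.get):
        if nd.is_leaf() or nd is tree.root:
            continue
        leaves = tree.leafset(nd)
        if lo <= len(leaves) <= hi and not (leaves & taken):
            chosen.append(nd)
            taken |= leaves
            if len(chosen) == n_clades:
                return chosen
    raise FishtolError(
        f"could not find {n_clades} disjoint clades of {lo}-{hi} tips; "
        "increase the backbone size"
    )


def simulate_study(
    seed: int = 0,
    n_backbone: int = 600,
    donor_sizes: Sequence[int] = (450, 400, 350, 300),
    placeholder_size_range: Tuple[int, int] = (15, 45),
    root_age: float = 425.0,
    rate_noise_sigma: float = 0.1,
    n_families: int = 180,
    n_orders: int = 40,
    n_suborders: int = 60,
    n_series: int = 9,
    k_nonmono: int = 12,
    m_incertae: int = 30,
) -> SyntheticTruth:
    """End-to-end synthetic study at the scale of a ~2000-tip time tree.

    A calibrated backbone is simulated, four placeholder clades are chosen
    and named, rate-noisy donors are simulated at the placeholders' crown
    ages, smoothed, grafted, and a ranked taxonomy with planted truth is
    laid over the composite tree.
    """
    rng = np.random.default_rng(seed)
    sub = lambda: int(rng.integers(0, 2**31))

    backbone = simulate_backbone(
        n_backbone, root_age=root_age, seed=sub(), label_prefix="B"
    )
    clades = _pick_disjoint_clades(backbone, len(donor_sizes), placeholder_size_range)
    ages = node_ages(backbone)
    entries = []
    donors: Dict[str, Phylogeny] = {}
    donor_truth: Dict[str, Dict[frozenset, float]] = {}
    for i, (nd, size) in enumerate(zip(clades, donor_sizes)):
        name = f"DonorClade{i + 1}"
        nd.label = name
        nd.support = None
        crown = ages[nd]
        donor, true_ages = simulate_donor(
            size,
            crown_age=crown,
            rate_noise_sigma=rate_noise_sigma,
            seed=sub(),
            label_prefix=f"G{i + 1}x",
        )
        donors[name] = donor
        donor_truth[name] = true_ages
        entries.append(CalibrationEntry(name, crown_age_ma=crown))
    backbone._invalidate_caches()
    calibrations = CalibrationTable(entries)

    grafted = graft_all(backbone, donors, calibrations)
    taxonomy, planted = plant_taxonomy(
        grafted,
        n_families=n_families,
        k_nonmono=k_nonmono,
        m_incertae=m_incertae,
        seed=sub(),
        n_orders=n_orders,
        n_suborders=n_suborders,
        n_series=n_series,
    )
    backbone_ages = {backbone.leafset(nd): a for nd, a in ages.items()}
    return SyntheticTruth(
        seed=seed,
        backbone=backbone,
        backbone_ages=backbone_ages,
        donors=donors,
        donor_true_ages=donor_truth,
        calibrations=calibrations,
        grafted=grafted,
        taxonomy=taxonomy,
        tree=planted.tree,
        nonmono_families=planted.nonmono_families,
        incertae_families=planted.incertae_families,
        clade_supports=planted.clade_supports,
    )
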