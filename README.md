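# fishtol

Tools for assembling large time-calibrated fish phylogenies from
independently dated subtrees, and for validating and rendering a ranked
Linnean classification (megaclass → family) against the resulting tree.

Modern classifications of bony fishes rest on composite chronograms: a
calibrated backbone tree carries the deep structure, while taxonomically
dense clades (cypriniforms, otophysans, percomorphs, ...) come from
separate studies and are *grafted* in after being time-scaled to secondary
crown-age calibrations. The classification laid over such a tree must then
be audited: which named taxa are monophyletic, which carry enough
bootstrap support to be endorsed, which families sit *incertae sedis*, and
how should the ranked list be printed. `fishtol` implements that whole
pipeline for systematists and tool builders, together with a seeded
synthetic-data generator so every stage is testable without any external
data files.

## The operations at the core

**Grafting.** Given an ultrametric backbone with node ages `a(v)`, a clade
selector resolving to a crown node `c` with parent `p`, a donor chronogram
`D`, and a secondary calibration `t` (the donor's crown age in Ma), the
donor is rescaled by `t / h(D)` (with `h(D)` its crown height), replaces
the backbone clade below `c`, and receives the stem branch
`a(p) − t`, so the composite tree remains ultrametric. A calibration of
`t ≥ a(p)` is a hard error (no silent age compression) unless `squeeze`
compresses the donor to `0.99·a(p)`.

**Rate smoothing.** Donor trees arrive non-ultrametric (branch lengths
carry rate noise). `smooth_to_ultrametric` is a deterministic recursive
mean-path smoother: the root height is the child-averaged mean
root-to-leaf path, and each internal node is placed at the fraction
`m(v) / (m(v) + b(v))` of its parent's age, where `m(v)` is the node's
mean remaining path and `b(v)` its stem branch. It is idempotent, exact on
ultrametric input, and recovers true node ages as rate noise → 0.

**Monophyly and endorsement.** A taxon's tips are derived from the
`Family_Genus_species_Code` tip-label convention (a family's tips are the
leaves carrying its name; higher taxa take unions over their families). A
taxon is monophyletic iff the MRCA of its tips contains exactly those
tips; foreign leaves under the MRCA are reported as intruders. Order-level
and supraordinal taxa are endorsed when MRCA bootstrap support is
strictly greater than 90%, or by corroboration (an input flag standing for
consistent recovery in independent studies) when support is lower or
missing.

**Classification rendering.** The ranked list is printed in phylogenetic
order down to the subordinal rank — the order in which the taxa's crown
nodes are first reached by a preorder traversal of the tree — with
families listed alphabetically inside each block, incertae sedis families
grouped under their series, unexamined families collected into
"Not examined:" lines, provisional names quoted, and support percentages
in parentheses.

## Worked example

```python
from fishtol.synthetic_data import simulate_study
from fishtol.clade_validation import validate_all
from fishtol.classification_writer import render_classification

bundle = simulate_study(
    seed=3, n_backbone=80, donor_sizes=(30, 25),
    placeholder_size_range=(5, 15), n_families=20, n_orders=6,
    n_suborders=8, n_series=2, k_nonmono=2, m_incertae=2,
)
report = validate_all(bundle.tree, bundle.taxonomy)
doc = render_classification(bundle.taxonomy, bundle.tree, report)
print(doc.counts_json())
print(sorted(report.non_monophyletic_families()))
```

This simulates an 80-tip backbone, grafts two rate-noisy donor clades
(30 and 25 tips) at their backbone crown ages after smoothing, lays a
20-family taxonomy over the 114-tip composite tree with two planted
label-swap conflicts and two incertae sedis families, and validates it:

```
{
  "orders": 6,
  "suborders": 8,
  "series_count": 2,
  "families_total": 20,
  "families_examined": 20,
  "families_unexamined": 0,
  "families_non_monophyletic": 4,
  "incertae_sedis_families": 2,
  "provisional_families": 0
}
['Family004', 'Family005', 'Family017', 'Family018']
```

Each planted swap makes *both* families of the pair non-monophyletic,
hence four flagged families from two swaps — and they are exactly the
generator's recorded truth (`bundle.nonmono_families`). The rendered
document starts:

```
Division Synthopterygii (99%)
  Series Series001aria (89%)
    Order-level incertae sedis in Series001aria
    Family009
    Order Order001iformes
      Suborder Suborder001oidei
        Family001
```

The same pipeline is available from a shell: `fishtol simulate`,
`fishtol graft`, `fishtol lint`, `fishtol validate`, `fishtol classify`
(see `fishtol --help`).

## The reference classification

The package ships a ranked classification of bony fishes
(`fishtol.load_reference_classification()`): the complete suprafamilial
hierarchy — 72 orders across 21 ranks from megaclass to infraorder — plus
every family with a special status (the 30 order-level incertae sedis
percomorph families of Carangaria, Ovalentaria and Eupercaria; the five
provisional quoted families) and exemplar family lists. It doubles as the
default fixture for the rank-ending lint rules (order `-iformes`,
suborder `-oidei`, infraorder `-ales`, division `-pterygii`).

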