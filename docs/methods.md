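# Methods

This note documents the models, conventions and numerical choices behind
`fishtol`, and what the synthetic-data experiments do and do not show.

## Tree dialect

Chronograms are rooted newick trees with branch lengths in millions of
years. Internal-node labels are overloaded in the source material: an
internal label that parses as a number in (1, 100] is read as a bootstrap
support percentage; any other label is kept as a clade-name annotation.
Labels in [0, 1] are rejected outright rather than rescaled — a tree
printed on the 0–1 support scale should fail loudly, because silently
multiplying by 100 would corrupt the >90% endorsement rule. Absent
support is represented as absent (`None`), never as 0; several major
clades in real composite trees legitimately carry no support value.

Tip labels follow `Family_Genus_species_Code`: the first three
underscore-delimited tokens are family, genus and species; everything
after the third token is re-joined into the specimen code, so codes may
themselves contain underscores. Unquoted underscores are never converted
to spaces (the convention depends on them); quoted labels with spaces are
supported and re-quoted on write. Branch lengths are written with 6
decimals by default (configurable; 17 decimals reproduces a double
exactly at these magnitudes).

## Grafting model

The composite tree is assembled by replacing placeholder clades in a
calibrated ultrametric backbone with densely sampled donor chronograms:

1. the donor is made ultrametric (below) if it is not already;
2. it is linearly rescaled so its crown age equals the secondary
   calibration (default: the backbone's own crown age for that clade);
3. the backbone clade below the selected crown node is removed, the donor
   root takes its place at the same child position, and the stem branch
   is set to (parent node age − crown age).

Node ages outside the replaced clade are untouched (their root-to-node
path sums are bit-identical before and after). A calibration at or above
the parent node's age raises a negative-stem error; the `squeeze` option
instead compresses the donor to 0.99× the parent age and warns. Selector
tips that are not monophyletic in the backbone raise an error listing the
displaced tips; `force` attaches at the MRCA, removing and reporting
them. The grafted crown node keeps the donor's root support when present,
otherwise it inherits the backbone's.

Ultrametricity is judged by leaf depths: the tree passes at relative
tolerance `rtol` iff the largest |leaf depth − mean leaf depth| is at
most `rtol ×` mean depth. Preconditions use `rtol = 1e-9`; simulated and
smoothed trees meet this with two orders of magnitude to spare (their
deviation is pure float round-off, ~1e-13 at a root age of 425 Ma).

## Mean-path smoothing

Penalized-likelihood smoothing requires a clock model and a smoothing
parameter, and different settings give different chronograms. To keep the
time-scaling step fully reproducible, donor trees are smoothed with a
deterministic recursive mean-path rule instead:

- the mean remaining path `m(v)` is 0 at leaves and, at an internal node,
  the plain average over children `c` of `b(c) + m(c)`, where `b` is the
  branch length (children weighted equally, not by tip count);
- the root age is `m(root)`;
- descending from the root, each internal node is placed at
  `age(parent) × m(v) / (m(v) + b(v))` — its subtree height as a fraction
  of the path through its stem, scaled into the interval below its
  parent.

Consequences, all exercised by tests: already-ultrametric trees are fixed
points (so the procedure is idempotent); ages decrease strictly from root
to leaf except across zero-length branches, where parent and child ages
coincide; topology and tip set are untouched; and as multiplicative
branch-rate noise shrinks, recovered node ages converge to the truth
(the node-age RMSE across 100 simulated donors per noise level rises
monotonically through σ = 0, 0.05, 0.1, 0.3 and is exactly 0 at σ = 0
after rescaling). The smoothing step is exposed as a strategy hook on
`graft_all`, so a penalized-likelihood smoother can be substituted
without touching the grafting code.

## Taxonomy model

The rank vocabulary is frozen to the 21 ranks used in modern ranked fish
classifications: megaclass, superclass, class, subclass, infraclass,
megacohort, supercohort, cohort, subcohort, infracohort, section,
subsection, division, subdivision, series, subseries, superorder, order,
suborder, infraorder, family. The cohort ranks nest megacohort >
supercohort > cohort > subcohort > infracohort, matching their actual use
(e.g. a supercohort containing cohorts). Unknown ranks are rejected, not
coerced.

Every family must have an order among its ancestors, or carry the
`incertae_sedis` flag and attach to a series — the two placements the
source classifications actually use. Provisional names are stored
unquoted with the `provisional` flag; the loader strips straight and
curly quotation marks and sets the flag, and the writer re-quotes them,
so the TSV round-trips exactly.

Rank-ending conventions are data, not code: `RankRule` records with
per-name exemptions. The default ruleset enforces order `-iformes`,
suborder `-oidei`, infraorder `-ales` and division `-pterygii`; series,
cohort and supercohort names carry no uniform suffix and are unruled.
`Zeiodei` is exempt from the suborder rule: it is the one suborder in the
reference classification formed without the full `-oidei` ending.

The `corroborated` flag encodes "consistently recovered by independent
studies" as a per-taxon input assertion. Surveying the literature (or
running topology tests for "incongruence not strongly rejected") is out
of scope for this package, so the flag is taken at face value.

## Monophyly and endorsement

A family's tip set is the set of leaves whose parsed family equals its
name; a higher taxon's tip set is the union over its descendant families.
Leaves whose family does not appear in the taxonomy (outgroups) are
excluded from every union and reported separately — they still count as
intruders where they fall inside a taxon's MRCA. Statuses: `unsampled`
(no tips), `monotypic` (one tip; no testable clade), `monophyletic`,
`non_monophyletic` (with intruders sorted lexicographically for
determinism).

Endorsement applies to supra-familial taxa only; families are flagged but
never endorsed. The support threshold is strict: support must exceed 90
(90.0 exactly does not endorse on support alone). Non-monophyletic taxa
can still be endorsed by corroboration — composite trees sometimes
contradict a well-established order with negligible support, and the
classification keeps such orders. Monotypic and unsampled taxa return
`not_applicable`.

## Classification rendering

Supra-familial taxa print in phylogenetic order: siblings sort by the
preorder index of their crown (MRCA) node under the tree's stored child
order. The tree is used as stored — no ladderization is applied, and the
writer emits children in input order, so the rendering is a pure function
of the inputs. When two sibling taxa attach to the same node (a
polytomy), the older crown age wins, then the name. Unsampled
supra-familial taxa cannot be placed by the tree and must declare an
anchor — the sibling after which they sort; a missing anchor is an error
rather than a silent guess. Families print alphabetically inside their
parent block, before any supra-familial siblings (the layout used for
incertae sedis families directly under a series). Unexamined families
collapse into a "Not examined:" line at the end of their block's family
list. Indentation is two spaces per taxonomy depth.

Counts: `families_examined` comes from sampled tips when a monophyly
report is supplied, and falls back on the `not_examined` flag for
taxonomies rendered without a tree (the shipped reference classification
is counted this way). `families_total = examined + unexamined` holds by
construction.

## Synthetic data

The generators emulate the structure of a composite fish time tree and
its classification, not its biology:

- **Backbones** are pure-birth (Yule) trees conditioned on the tip count
  and rescaled to the crown age (default 425 Ma, a deep root age typical
  of bony-fish-wide chronograms). Extinction is omitted deliberately: the
  pipeline consumes only the ultrametric shape, which birth–death
  modelling would not change qualitatively. Internal nodes carry integer
  bootstrap supports drawn uniformly (default 50–100; the lower bound
  must exceed 1 so that written labels cannot collide with the rejected
  0–1 support scale). No support correlation is modelled.
- **Donors** are Yule chronograms whose branches are multiplied by
  independent lognormal(0, σ) factors (default σ = 0.1, mild rate noise;
  σ = 0 yields the exact chronogram). True node ages are recorded per
  clade for recovery experiments.
- **Taxonomies** are planted by refining the tree into nested frontiers
  of series ⊃ orders ⊃ suborders ⊃ families (largest-clade-first
  splitting), then relabelling leaves `FamilyNNN_GenusNNN_spJ_CXXXXX`.
  Non-monophyly is planted by swapping one tip label between two
  same-suborder families with at least two tips each — a taxonomy-vs-tree
  conflict, which is how real non-monophyly presents to this pipeline —
  and both members of each swapped pair are recorded as truth. Incertae
  sedis families are re-parented to their series, never emptying an order
  or suborder.
- **`simulate_study`** composes the stages at study scale: a 600-tip
  backbone, four placeholder clades of 15–45 tips, donors of 450, 400,
  350 and 300 tips grafted at the placeholders' backbone crown ages
  (≈1990 tips total), and a planted taxonomy with 180 families, 60
  suborders, 40 orders, 9 series, 12 swap pairs and 30 incertae sedis
  families. One full run (simulate → graft → validate → render) takes
  under a second, and output is byte-identical under a fixed seed.

What passing these tests shows: the pipeline's bookkeeping (tip
conservation, ultrametricity, age calibration, planted-truth recovery,
deterministic rendering) is correct at realistic scale. What it does not
show: anything about inference quality on real data — the generator
plants clean, label-driven conflicts, whereas real non-monophyly comes
with alignment error, rogue taxa and correlated support, none of which
are modelled.

## The reference classification fixture

`src/fishtol/data/bony_fish_classification.tsv` is a ranked
classification of bony fishes covering the complete suprafamilial
hierarchy (72 orders, 76 printed suborders, 11 series of which 9 are
percomorph) plus all families carrying a special status — the 30
order-level incertae sedis percomorph families split 7/9/14 across
Carangaria, Ovalentaria and Eupercaria (three of the Eupercaria set also
unexamined), and the five provisional quoted families — together with
exemplar family lists for several orders. Family rows are deliberately
not exhaustive: the full 514-family table exists only in spreadsheet
form and is not distributed here. The optional integration tests accept
that spreadsheet (or a TSV conversion) under `./supplementary/` and skip
cleanly when it is absent.

## Known limitations

- The mean-path smoother is a reproducible stand-in for rate smoothing,
  not an estimator of rate variation; heavily autocorrelated rates will
  bias its interior ages even though the crown age is always exact after
  rescaling.
- Clade selectors assume unique tip labels and resolve named clades by
  internal-node annotations; there is no fuzzy taxon matching.
- The endorsement rule consumes one support value per node; trees with
  multiple support measures (e.g. posterior + bootstrap) must be reduced
  to one before parsing.
- NEXUS, phyloXML and reticulate (extended-newick) inputs are out of
  scope.
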