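"""Phylogenetic ordering, rendering and the counts summary."""

import io

import pandas as pd
import pytest

from fishtol.classification_writer import (
    counts_summary,
    phylogenetic_order,
    render_classification,
)
from fishtol.clade_validation import validate_all
from fishtol.exceptions import TaxonomyError
from fishtol.synthetic_data import plant_taxonomy, simulate_backbone
from fishtol.taxonomy_model import Taxon, Taxonomy, load_taxonomy
from fishtol.tree_io import parse_newick


def tax(rows):
    return Taxonomy(
        [Taxon(n, r, p or None, frozenset(f.split(";")) - {""}, a or None, i)
         for i, (n, r, p, f, a) in enumerate(rows)]
    )


@pytest.fixture
def two_order_tree():
    return parse_newick(
        "((Aidae_Ga_s1_c1:1,Aidae_Ga_s2_c2:1)90:2,"
        "((Bidae_Gb_s1_c3:1,Bidae_Gb_s2_c4:1)85:1,"
        "(Cidae_Gc_s1_c5:1,Cidae_Gc_s2_c6:1)80:1)95:1);"
    )


@pytest.fixture
def two_order_taxonomy():
    return tax([
        ("Xiformes", "order", "", "", ""),
        ("Aidae", "family", "Xiformes", "", ""),
        ("Yiformes", "order", "", "", ""),
        ("Bidae", "family", "Yiformes", "", ""),
        ("Cidae", "family", "Yiformes", "", ""),
    ])


class TestPhylogeneticOrder:
    def test_branching_order_of_orders(self, two_order_tree, two_order_taxonomy):
        ordered = [t.name for t in phylogenetic_order(two_order_tree, two_order_taxonomy)]
        assert ordered.index("Xiformes") < ordered.index("Yiformes")

    def test_families_alphabetical_within_block(self):
        tree = parse_newick(
            "((Zeidae_G_s_1:1,(Parazenidae_G_s_2:1,Zeniontidae_G_s_3:1):1):1,Out_G_s_4:2);"
        )
        taxonomy = tax([
            ("Zeiformes", "order", "", "", ""),
            ("Zeioidei", "suborder", "Zeiformes", "", ""),
            ("Zeidae", "family", "Zeioidei", "", ""),
            ("Parazenidae", "family", "Zeioidei", "", ""),
            ("Zeniontidae", "family", "Zeioidei", "", ""),
        ])
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # "Out" tip is an outgroup
            ordered = [t.name for t in phylogenetic_order(tree, taxonomy)]
        assert ordered == [
            "Zeiformes", "Zeioidei", "Parazenidae", "Zeidae", "Zeniontidae"
        ]

    def test_single_order_matches_row_order(self):
        tree = parse_newick("((Aidae_G_s_1:1,Aidae_G_s_2:1):1,Bidae_G_s_3:2);")
        taxonomy = tax([
            ("Xiformes", "order", "", "", ""),
            ("Aidae", "family", "Xiformes", "", ""),
            ("Bidae", "family", "Xiformes", "", ""),
        ])
        ordered = [t.name for t in phylogenetic_order(tree, taxonomy)]
        assert ordered == ["Xiformes", "Aidae", "Bidae"]

    def test_unsampled_taxon_inserted_after_anchor(self, two_order_tree):
        taxonomy = tax([
            ("Xiformes", "order", "", "", ""),
            ("Aidae", "family", "Xiformes", "", ""),
            ("Ghostiformes", "order", "", "", "Xiformes"),
            ("Ghostidae", "family", "Ghostiformes", "not_examined", ""),
            ("Yiformes", "order", "", "", ""),
            ("Bidae", "family", "Yiformes", "", ""),
            ("Cidae", "family", "Yiformes", "", ""),
        ])
        ordered = [t.name for t in phylogenetic_order(two_order_tree, taxonomy)]
        assert ordered.index("Ghostiformes") == ordered.index("Xiformes") + 2

    def test_unsampled_without_anchor_errors(self, two_order_tree):
        taxonomy = tax([
            ("Xiformes", "order", "", "", ""),
            ("Aidae", "family", "Xiformes", "", ""),
            ("Ghostiformes", "order", "", "", ""),
            ("Ghostidae", "family", "Ghostiformes", "not_examined", ""),
        ])
        with pytest.raises(TaxonomyError, match="anchor"):
            phylogenetic_order(two_order_tree, taxonomy)


class TestRendering:
    def test_support_and_notes_in_text(self, two_order_tree, two_order_taxonomy):
        report = validate_all(two_order_tree, two_order_taxonomy)
        doc = render_classification(two_order_taxonomy, two_order_tree, report)
        text = doc.text()
        assert "Order Xiformes (90%)" in text
        assert "Order Yiformes (95%)" in text

    def test_provisional_family_quoted(self):
        taxonomy = tax([
            ("Xiformes", "order", "", "", ""),
            ("Cyclopsettidae", "family", "Xiformes", "provisional", ""),
        ])
        doc = render_classification(taxonomy)
        assert '"Cyclopsettidae"' in doc.text()

    def test_non_monophyletic_note_rendered(self):
        tree = parse_newick(
            "((Aidae_G_s_1:1,Bidae_G_s_2:1):1,(Aidae_G_s_3:1,Bidae_G_s_4:1):1);"
        )
        taxonomy = tax([
            ("Xiformes", "order", "", "", ""),
            ("Aidae", "family", "Xiformes", "", ""),
            ("Bidae", "family", "Xiformes", "", ""),
        ])
        report = validate_all(tree, taxonomy)
        doc = render_classification(taxonomy, tree, report)
        assert "Aidae (not monophyletic in our tree)" in doc.text()

    def test_not_examined_collected_per_block(self):
        taxonomy = tax([
            ("Xiformes", "order", "", "", ""),
            ("Aidae", "family", "Xiformes", "", ""),
            ("Midae", "family", "Xiformes", "not_examined", ""),
            ("Zidae", "family", "Xiformes", "not_examined", ""),
        ])
        text = render_classification(taxonomy).text()
        assert "Not examined: Midae, Zidae" in text
        assert "\n  Midae" not in text

    def test_incertae_sedis_header_under_series(self, reference_taxonomy):
        text = render_classification(reference_taxonomy).text()
        assert "Order-level incertae sedis in Carangaria" in text
        assert "Order-level incertae sedis in Ovalentaria" in text
        assert "Order-level incertae sedis in Eupercaria" in text

    def test_render_load_round_trip(self, reference_taxonomy):
        doc = render_classification(reference_taxonomy)
        buf = io.StringIO()
        doc.to_frame().to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        assert load_taxonomy(buf) == reference_taxonomy

    def test_parent_precedes_child_everywhere(self, reference_taxonomy):
        doc = render_classification(reference_taxonomy)
        seen = set()
        for e in doc.entries:
            if e.taxon.parent is not None:
                assert e.taxon.parent in seen
            seen.add(e.taxon.name)

    def test_deterministic_output(self):
        tree = simulate_backbone(60, seed=41)
        taxonomy, truth = plant_taxonomy(tree, n_families=10, k_nonmono=2, seed=41)
        outs = []
        for _ in range(2):
            report = validate_all(truth.tree, taxonomy)
            outs.append(render_classification(taxonomy, truth.tree, report).text())
        assert outs[0] == outs[1]


class TestCounts:
    def test_empty_taxonomy_all_zero(self):
        counts = counts_summary(Taxonomy([]))
        assert all(v == 0 for v in counts.values())

    def test_planted_counts_recovered(self):
        tree = simulate_backbone(80, seed=42)
        taxonomy, truth = plant_taxonomy(
            tree, n_families=12, m_incertae=2, seed=42,
            n_orders=4, n_suborders=6, n_series=2,
        )
        report = validate_all(truth.tree, taxonomy)
        counts = counts_summary(taxonomy, report)
        assert counts["orders"] == 4
        assert counts["suborders"] == 6
        assert counts["series_count"] == 2
        assert counts["families_total"] == 12
        assert counts["incertae_sedis_families"] == 2

    def test_counts_identities(self, reference_taxonomy):
        counts = counts_summary(reference_taxonomy)
        assert (
            counts["families_total"]
            == counts["families_examined"] + counts["families_unexamined"]
        )
        assert counts["incertae_sedis_families"] <= counts["families_total"]
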