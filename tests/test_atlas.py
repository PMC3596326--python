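"""Pathway atlas: fixture golden values, accumulation, recruitment, painting."""

import networkx as nx
import pytest

import foldchron as fc
from foldchron.atlas import RECRUIT_INTER, RECRUIT_INTRA, RECRUIT_UNIQUE, ec_matches


class TestPurineFixture:
    def test_golden_age_values(self, purine):
        ages, _ = purine
        expected = {
            "c.37.1.12": 0.0,
            "c.37.1.20": 0.004,
            "c.94.1.1": 0.033,
            "c.23.16.1": 0.057,
            "c.37.1.10": 0.057,
            "c.30.1.1": 0.061,
            "d.142.1.2": 0.061,
            "c.61.1.1": 0.069,
            "c.37.1.1": 0.073,
            "a.127.1.1": 0.094,
            "d.143.1.1": 0.188,
        }
        assert {f: ages[f] for f in ages.families()} == expected

    def test_pathway_labels(self, purine):
        _, net = purine
        shares = {
            ff: frozenset().union(*(s.pathways for s in net.steps_with_family(ff)))
            for ff in net.families()
        }
        assert shares["c.23.16.1"] == {"INT", "BIO"}
        assert shares["c.30.1.1"] == {"INT", "BIO"}
        assert shares["d.142.1.2"] == {"INT", "BIO"}
        assert shares["c.61.1.1"] == {"CAT", "BIO"}
        assert shares["a.127.1.1"] == {"INT", "BIO"}
        assert shares["c.37.1.1"] == {"INT"}
        assert shares["d.143.1.1"] == {"BIO"}
        assert shares["c.37.1.12"] == {"INT"}
        assert shares["c.37.1.20"] == {"INT"}


class TestFirstAppearance:
    def test_pathway_order_on_fixture(self, purine):
        ages, net = purine
        int_nd = fc.pathway_first_appearance(net, ages, "INT")
        bio_nd = fc.pathway_first_appearance(net, ages, "BIO")
        cat_nd = fc.pathway_first_appearance(net, ages, "CAT")
        assert (int_nd, bio_nd, cat_nd) == (0.0, 0.057, 0.069)
        assert int_nd < bio_nd < cat_nd

    def test_unknown_pathway_rejected(self, purine):
        ages, net = purine
        with pytest.raises(ValueError):
            fc.pathway_first_appearance(net, ages, "NOSUCH")

    def test_missing_age_rejected(self, purine):
        _, net = purine
        sparse = fc.AgeTable({"c.23.16.1": 0.057})
        with pytest.raises(KeyError):
            fc.pathway_first_appearance(net, sparse, "BIO")


class TestAccumulation:
    def test_counts_on_fixture_bio(self, purine):
        ages, net = purine
        curve = fc.accumulation_curve(net, ages, "BIO")
        at_006 = max(c for nd, c in curve if nd <= 0.06)
        assert at_006 == 1  # only the amidotransferase family is that old
        assert curve[-1][1] == len(net.pathway_families("BIO"))
        counts = [c for _, c in curve]
        assert counts == sorted(counts)

    def test_first_and_completion_bracket_curve(self, purine):
        ages, net = purine
        curve = fc.accumulation_curve(net, ages, "BIO")
        assert curve[0][0] == fc.pathway_first_appearance(net, ages, "BIO")
        assert curve[-1][0] == fc.pathway_completion(net, ages, "BIO")

    def test_empty_network_gives_empty_curve(self):
        net = fc.EnzymeNetwork([])
        assert fc.accumulation_curve(net, fc.AgeTable({}), "BIO") == []


class TestRecruitment:
    def test_fixture_classes(self, purine):
        ages, net = purine
        events = {e.ff: e for e in fc.classify_recruitment(net, ages)}
        assert events["c.61.1.1"].recruitment_class == RECRUIT_INTER
        assert events["c.61.1.1"].pathways_sharing == {"CAT", "BIO"}
        assert events["d.143.1.1"].recruitment_class == RECRUIT_UNIQUE
        assert events["c.37.1.1"].recruitment_class == RECRUIT_INTRA
        assert len(events) == len(net.families())

    def test_sorted_by_age(self, purine):
        ages, net = purine
        nds = [e.nd for e in fc.classify_recruitment(net, ages)]
        assert nds == sorted(nds)

    def test_single_step_family_is_unique(self):
        net = fc.EnzymeNetwork.from_records(
            [{"step_id": "s1", "ec": "1.1.1.1", "pathways": "X", "families": "a.1.1.1"}]
        )
        events = fc.classify_recruitment(net, fc.AgeTable({"a.1.1.1": 0.5}))
        assert events[0].recruitment_class == RECRUIT_UNIQUE


class TestTimeline:
    def test_fixture_fold_clock(self, purine):
        ages, net = purine
        tl = fc.build_timeline(net, ages, fc.FOLD_CLOCK, pathways=["INT", "BIO", "CAT"])
        assert round(tl["INT"].first_age_gy, 1) == 3.8
        assert tl["BIO"].completion_nd == 0.188
        assert tl["BIO"].first_nd <= tl["BIO"].completion_nd

    def test_constant_clock(self, purine):
        ages, net = purine
        flat = fc.MolecularClock(slope=0.0, intercept=5.0)
        tl = fc.build_timeline(net, ages, flat)
        assert all(t.first_age_gy == 5.0 and t.completion_age_gy == 5.0 for t in tl.values())


class TestPainting:
    def test_color_ramp_endpoints_and_midpoint(self):
        assert fc.age_color(0.0) == "#ff0000"
        assert fc.age_color(1.0) == "#0000ff"
        assert fc.age_color(0.5) == "#800080"  # 128/0/127 rounded midpoint

    def test_painted_graph_attributes(self, purine):
        ages, net = purine
        g = fc.paint_network(net, ages)
        assert isinstance(g, nx.Graph)
        node = g.nodes["fgam_synthetase"]
        assert node["nd"] == 0.057
        assert node["color"] == fc.age_color(0.057)
        assert "c.23.16.1=0.057" in node["families"]
        dot = fc.to_dot(g)
        assert dot.startswith("graph") and "fgam_synthetase" in dot

    def test_multi_domain_enzyme_uses_minimum_age(self, purine):
        ages, net = purine
        g = fc.paint_network(net, ages)
        # AIR carboxylase carries both biotin-carboxylase families (0.061)
        assert g.nodes["air_carboxylase"]["nd"] == 0.061


class TestECMatching:
    @pytest.mark.parametrize(
        "pattern,ec,match",
        [
            ("6.3.4.-", "6.3.4.18", True),
            ("6.3.4.-", "6.3.5.2", False),
            ("2.4.2.8", "2.4.2.8", True),
            ("2.4.2.8", "2.4.2.7", False),
            ("-.-.-.-", "1.2.3.4", True),
        ],
    )
    def test_wildcards(self, pattern, ec, match):
        assert ec_matches(pattern, ec) is match

    def test_malformed_ec_rejected(self):
        with pytest.raises(ValueError, match="EC"):
            fc.Step("s", "1.2.3", frozenset({"X"}), frozenset({"a.1.1.1"}))
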