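"""Domain types, validation diagnostics, and file dialect round-trips."""

import math

import numpy as np
import pytest

from cophylo import (
    CostScheme,
    RegionSpec,
    Tanglegram,
    TanglegramError,
    TimeZoneSpec,
    Tree,
    simulate_tanglegram,
    validate,
    write_tanglegram,
)
from cophylo.io import ParseError, parse_nexus, parse_tabular, read_tanglegram

MINIMAL_NEXUS = """#NEXUS
BEGIN TREES;
    TREE HOST = (h1,h2)H1;
    TREE PARASITE = (p1,p2)P1;
END;
BEGIN COPHYLOGENY;
    ASSOCIATE p1 : h1;
    ASSOCIATE p2 : h2;
END;
"""


class TestTree:
    def test_basic_structure(self):
        t = Tree({"r": ("a", "b"), "a": ("x", "y")}, root="r")
        assert t.n_tips == 3 and t.m == 2
        assert t.mrca("x", "b") == "r"
        assert t.is_ancestor("a", "y") and not t.is_ancestor("b", "y")
        assert t.depth("y") == 2

    def test_two_parents_rejected(self):
        with pytest.raises(TanglegramError, match="two parents"):
            Tree({"r": ("a", "b"), "a": ("b", "c")}, root="r")

    def test_disconnected_rejected(self):
        with pytest.raises(TanglegramError):
            Tree({"r": ("a", "b"), "z": ("x", "y")}, root="r")


class TestValidate:
    def test_well_formed_instance_has_no_diagnostics(self):
        hist = simulate_tanglegram(6, np.random.default_rng(1))
        assert validate(hist.tanglegram) == []

    def test_every_simulator_output_validates(self):
        for seed in range(20):
            hist = simulate_tanglegram(5, np.random.default_rng(100 + seed))
            assert validate(hist.tanglegram) == []

    def test_polytomy_reported(self):
        host = Tree({"r": ("a", "b", "c")}, root="r")
        para = Tree({"R": ("p", "q")}, root="R")
        tg = Tanglegram(host, para, {"p": "a", "q": "b"})
        diags = validate(tg)
        assert len(diags) == 1 and "r" in diags[0] and "3 children" in diags[0]

    def test_zone_contradicting_ancestry_reported(self):
        host = Tree({"r": ("a", "b"), "a": ("x", "y")}, root="r")
        para = Tree({"R": ("p", "q")}, root="R")
        tg = Tanglegram(
            host,
            para,
            {"p": "x", "q": "b"},
            zones=TimeZoneSpec({"r": (5, 9), "a": (1, 2)}, {}),
        )
        diags = validate(tg)
        assert len(diags) == 1 and "ends (2) before parent" in diags[0]

    def test_missing_association_and_unknown_host_reported(self):
        host = Tree({"r": ("a", "b")}, root="r")
        para = Tree({"R": ("p", "q")}, root="R")
        tg = Tanglegram(host, para, {"p": "nowhere"})
        diags = validate(tg)
        assert any("'q' has no host association" in d for d in diags)
        assert any("'nowhere'" in d for d in diags)

    def test_negative_cost_rejected(self):
        with pytest.raises(TanglegramError, match="non-negative"):
            CostScheme(loss_cost=-1)


class TestNexusDialect:
    def test_minimal_file(self):
        tg = parse_nexus(MINIMAL_NEXUS)
        assert tg.host.m == 1 and tg.parasite.m == 1
        assert tg.tip_mapping == {"p1": "h1", "p2": "h2"}
        # omitted blocks get defaults
        assert tg.costs == CostScheme()
        assert tg.zones is None and tg.regions is None
        assert tg.switch_distance_bound is None

    def test_unknown_host_label_named_in_error(self):
        bad = MINIMAL_NEXUS.replace("ASSOCIATE p2 : h2;", "ASSOCIATE p2 : h9;")
        with pytest.raises(ParseError, match="h9"):
            parse_nexus(bad)

    def test_polytomy_named_in_error(self):
        bad = MINIMAL_NEXUS.replace("(h1,h2)H1", "(h1,h2,h3)H1")
        with pytest.raises(ParseError, match="'H1' has 3 children"):
            parse_nexus(bad)

    def test_malformed_newick_rejected(self):
        bad = MINIMAL_NEXUS.replace("(h1,h2)H1", "((h1,h2)H1")
        with pytest.raises(ParseError, match="Newick"):
            parse_nexus(bad)

    def test_missing_associations_rejected(self):
        bad = "\n".join(
            ln for ln in MINIMAL_NEXUS.splitlines() if "ASSOCIATE" not in ln
        )
        with pytest.raises(ParseError, match="association"):
            parse_nexus(bad)

    def test_optional_blocks_parsed(self):
        tg = parse_nexus(
            MINIMAL_NEXUS.rstrip()[: -len("END;")]
            + "    COSTS 0 1 inf 2;\n"
            + "    ZONE host H1 1 3;\n"
            + "    ZONE parasite P1 2 4;\n"
            + "    REGION H1 r1;\n    REGION h1 r1;\n    REGION h2 r2;\n"
            + "    REGIONCOST r1 r1 1;\n    REGIONCOST r1 r2 2;\n"
            + "    REGIONCOST r2 r1 2;\n    REGIONCOST r2 r2 1;\n"
            + "    SWITCHDISTANCE 2;\nEND;\n"
        )
        assert math.isinf(tg.costs.switch_cost)
        assert tg.zones.host_zones == {"H1": (1, 3)}
        assert tg.zones.parasite_zones == {"P1": (2, 4)}
        assert tg.regions.vertex_region["h2"] == "r2"
        assert tg.regions.cost("r1", "r2") == 2
        assert tg.switch_distance_bound == 2


class TestTabularDialect:
    def test_empty_association_section_rejected(self):
        text = "HOSTTREE\nr\ta\nr\tb\nPARASITETREE\nR\tp\nR\tq\nASSOCIATIONS\n"
        with pytest.raises(ParseError, match="ASSOCIATIONS"):
            parse_tabular(text)

    def test_comments_and_whitespace_tolerated(self):
        text = (
            "# a tiny instance\nHOSTTREE\nr\ta\nr\tb\n"
            "PARASITETREE\nR\tp\nR\tq\n"
            "ASSOCIATIONS\np\ta  # on host a\nq\tb\n"
        )
        tg = parse_tabular(text)
        assert tg.host.root == "r" and tg.tip_mapping["p"] == "a"


def _random_instance(seed: int) -> Tanglegram:
    hist = simulate_tanglegram(6, np.random.default_rng(seed))
    tg = hist.tanglegram
    if seed % 3 == 0:
        tg.zones = TimeZoneSpec(
            {tg.host.internal[0]: (1, 3)}, {tg.parasite.internal[0]: (2, 5)}
        )
    if seed % 4 == 0:
        regs = {v: ("r1" if i % 2 else "r2") for i, v in enumerate(tg.host.vertices)}
        tg.regions = RegionSpec(
            regs,
            {(a, b): (1.5 if a != b else 1.0) for a in ("r1", "r2") for b in ("r1", "r2")},
        )
        tg.switch_distance_bound = 3
    return tg


@pytest.mark.parametrize("dialect", ["nexus", "tabular"])
def test_round_trip_on_simulated_instances(dialect):
    """parse(write(tg)) reproduces the instance for 100 simulated
    tanglegrams, including zones, regions and the distance bound."""
    for seed in range(100):
        tg = _random_instance(1000 + seed)
        back = read_tanglegram(write_tanglegram(tg, dialect))
        assert back.host == tg.host and back.parasite == tg.parasite
        assert back.tip_mapping == tg.tip_mapping
        assert back.costs == tg.costs
        assert back.zones == tg.zones
        assert back.regions == tg.regions
        assert back.switch_distance_bound == tg.switch_distance_bound


def test_dialect_sniffing():
    tg = _random_instance(1)
    assert read_tanglegram(write_tanglegram(tg, "nexus")).host == tg.host
    assert read_tanglegram(write_tanglegram(tg, "tabular")).host == tg.host
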