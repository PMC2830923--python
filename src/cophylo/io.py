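"""Readers and writers for tanglegram files.

Two dialects are supported.

**Nexus dialect** — a standard ``#NEXUS`` file with a TREES block naming
the two trees HOST and PARASITE (Newick; internal vertices may carry
labels, which zones and regions refer to) and a COPHYLOGENY block::

    #NEXUS
    BEGIN TREES;
        TREE HOST = ((h1,h2)H2,h3)H1;
        TREE PARASITE = (p1,p2)P1;
    END;
    BEGIN COPHYLOGENY;
        ASSOCIATE p1 : h1;
        ASSOCIATE p2 : h3;
        COSTS 0 1 1 2;
        ZONE host H2 1 3;
        ZONE parasite P1 2 3;
        REGION H1 mainland;
        REGIONCOST mainland island 2.5;
        SWITCHDISTANCE 2;
    END;

**Tabular dialect** — a line-oriented format with ``HOSTTREE`` and
``PARASITETREE`` sections (tab-separated parent/child edge lists, root
inferred), an ``ASSOCIATIONS`` section (parasite-tip, host-tip pairs),
and the same optional keys (``COSTS``, ``ZONE``, ``REGION``,
``REGIONCOST``, ``SWITCHDISTANCE``); ``#`` starts a comment.

Costs accept ``inf`` to forbid an event.  Unlabelled internal Newick
vertices receive deterministic generated labels, so writing and
re-parsing is structure- and label-stable.
"""

from __future__ import annotations

import math
import re
from typing import Optional

import dendropy

from .model import (
    CostScheme,
    RegionSpec,
    Tanglegram,
    TanglegramError,
    TimeZoneSpec,
    Tree,
)

__all__ = ["ParseError", "parse_nexus", "parse_tabular", "write_tanglegram", "read_tanglegram"]


class ParseError(TanglegramError):
    """Raised when an input file cannot be interpreted."""


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|+-]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _tree_to_newick(tree: Tree) -> str:
    def rec(v: str) -> str:
        if tree.is_tip(v):
            return _quote(v)
        inner = ",".join(rec(c) for c in tree.children[v])
        return f"({inner}){_quote(v)}"

    return rec(tree.root) + ";"


def _tree_from_newick(newick: str, autolabel_prefix: str) -> Tree:
    try:
        dtree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error types
        raise ParseError(f"malformed Newick: {exc}") from exc

    used: set[str] = set()
    for nd in dtree.preorder_node_iter():
        name = nd.taxon.label if nd.taxon is not None else nd.label
        if name:
            used.add(name)
    counter = 0

    def name_of(nd) -> str:
        nonlocal counter
        name = nd.taxon.label if nd.taxon is not None else nd.label
        if name:
            return name
        while True:
            counter += 1
            cand = f"{autolabel_prefix}{counter}"
            if cand not in used:
                used.add(cand)
                nd.label = cand
                return cand

    children: dict[str, tuple[str, ...]] = {}

    def build(nd) -> str:
        label = name_of(nd)
        kids = nd.child_nodes()
        if kids:
            if len(kids) != 2:
                raise ParseError(
                    f"vertex {label!r} has {len(kids)} children; trees must be "
                    f"strictly bifurcating (polytomies are not supported)"
                )
            children[label] = tuple(build(c) for c in kids)
        return label

    root = build(dtree.seed_node)
    try:
        return Tree(children, root=root)
    except TanglegramError as exc:
        raise ParseError(str(exc)) from exc


# ---------------------------------------------------------------------------
# shared key-line handling for the optional blocks
# ---------------------------------------------------------------------------


def _parse_float(tok: str) -> float:
    if tok.lower() in ("inf", "+inf", "infinity"):
        return math.inf
    try:
        return float(tok)
    except ValueError as exc:
        raise ParseError(f"expected a number, got {tok!r}") from exc


class _OptionalBlocks:
    def __init__(self) -> None:
        self.costs: Optional[CostScheme] = None
        self.host_zones: dict[str, tuple[int, int]] = {}
        self.parasite_zones: dict[str, tuple[int, int]] = {}
        self.vertex_region: dict[str, str] = {}
        self.pair_costs: dict[tuple[str, str], float] = {}
        self.switch_distance: Optional[int] = None

    def feed(self, key: str, args: list[str]) -> bool:
        key = key.upper()
        if key == "COSTS":
            if len(args) != 4:
                raise ParseError("COSTS needs 4 values: cosp dup switch loss")
            c, d, s, l = (_parse_float(a) for a in args)
            self.costs = CostScheme(c, d, s, l)
            return True
        if key == "ZONE":
            if len(args) != 4:
                raise ParseError("ZONE needs: <host|parasite> <vertex> <lo> <hi>")
            which, vertex, lo, hi = args
            try:
                rng = (int(lo), int(hi))
            except ValueError as exc:
                raise ParseError(f"ZONE bounds must be integers: {lo!r} {hi!r}") from exc
            if which.lower() == "host":
                self.host_zones[vertex] = rng
            elif which.lower() == "parasite":
                self.parasite_zones[vertex] = rng
            else:
                raise ParseError(f"ZONE tree must be 'host' or 'parasite', got {which!r}")
            return True
        if key == "REGION":
            if len(args) != 2:
                raise ParseError("REGION needs: <host-vertex> <region-id>")
            self.vertex_region[args[0]] = args[1]
            return True
        if key == "REGIONCOST":
            if len(args) != 3:
                raise ParseError("REGIONCOST needs: <from> <to> <cost>")
            self.pair_costs[(args[0], args[1])] = _parse_float(args[2])
            return True
        if key == "SWITCHDISTANCE":
            if len(args) != 1:
                raise ParseError("SWITCHDISTANCE needs one integer")
            try:
                self.switch_distance = int(args[0])
            except ValueError as exc:
                raise ParseError(f"SWITCHDISTANCE must be an integer: {args[0]!r}") from exc
            return True
        return False

    def assemble(
        self, host: Tree, parasite: Tree, mapping: dict[str, str]
    ) -> Tanglegram:
        zones = None
        if self.host_zones or self.parasite_zones:
            zones = TimeZoneSpec(dict(self.host_zones), dict(self.parasite_zones))
        regions = None
        if self.vertex_region or self.pair_costs:
            regions = RegionSpec(dict(self.vertex_region), dict(self.pair_costs))
        tg = Tanglegram(
            host=host,
            parasite=parasite,
            tip_mapping=mapping,
            costs=self.costs or CostScheme(),
            zones=zones,
            regions=regions,
            switch_distance_bound=self.switch_distance,
        )
        try:
            tg.require_valid()
        except TanglegramError as exc:
            raise ParseError(str(exc)) from exc
        return tg


# ---------------------------------------------------------------------------
# Nexus dialect
# ---------------------------------------------------------------------------


def parse_nexus(text: str) -> Tanglegram:
    """Parse the Nexus dialect into a validated tanglegram."""
    stripped = text.strip()
    if not stripped.upper().startswith("#NEXUS"):
        raise ParseError("not a Nexus file (missing #NEXUS header)")
    body = stripped[len("#NEXUS"):]
    # drop bracketed Nexus comments
    body = re.sub(r"\[[^\]]*\]", "", body)
    statements = [s.strip() for s in body.split(";") if s.strip()]

    trees: dict[str, Tree] = {}
    mapping: dict[str, str] = {}
    blocks = _OptionalBlocks()
    current_block = None
    for st in statements:
        words = st.split()
        key = words[0].upper()
        if key == "BEGIN":
            if len(words) != 2:
                raise ParseError(f"malformed BEGIN statement: {st!r}")
            current_block = words[1].upper()
            continue
        if key in ("END", "ENDBLOCK"):
            current_block = None
            continue
        if current_block == "TREES" and key == "TREE":
            m = re.match(r"(?is)^TREE\s+(\S+)\s*=\s*(.+)$", st)
            if not m:
                raise ParseError(f"malformed TREE statement: {st!r}")
            name = m.group(1).upper()
            if name not in ("HOST", "PARASITE"):
                raise ParseError(f"tree must be named HOST or PARASITE, got {name!r}")
            prefix = "HN" if name == "HOST" else "PN"
            trees[name] = _tree_from_newick(m.group(2) + ";", prefix)
            continue
        if current_block == "COPHYLOGENY":
            if key == "ASSOCIATE":
                m = re.match(r"^ASSOCIATE\s+(\S+)\s*:\s*(\S+)$", st, re.IGNORECASE)
                if not m:
                    raise ParseError(f"malformed ASSOCIATE statement: {st!r}")
                mapping[m.group(1)] = m.group(2)
                continue
            if blocks.feed(key, words[1:]):
                continue
            raise ParseError(f"unknown COPHYLOGENY statement: {st!r}")
        if current_block in (None, "TREES", "COPHYLOGENY"):
            continue  # tolerate unrelated blocks/statements
    if "HOST" not in trees or "PARASITE" not in trees:
        raise ParseError("file must define TREE HOST and TREE PARASITE")
    if not mapping:
        raise ParseError("file defines no tip associations (ASSOCIATE lines)")
    return blocks.assemble(trees["HOST"], trees["PARASITE"], mapping)


# ---------------------------------------------------------------------------
# tabular dialect
# ---------------------------------------------------------------------------


def _tree_from_edges(edges: list[tuple[str, str]], which: str) -> Tree:
    if not edges:
        raise ParseError(f"{which} section lists no edges")
    children: dict[str, list[str]] = {}
    child_set = set()
    for parent, child in edges:
        children.setdefault(parent, []).append(child)
        if child in child_set:
            raise ParseError(f"{which}: vertex {child!r} listed with two parents")
        child_set.add(child)
    roots = [v for v in children if v not in child_set]
    if len(roots) != 1:
        raise ParseError(f"{which}: expected one root, found {len(roots)}")
    for v, cs in children.items():
        if len(cs) != 2:
            raise ParseError(
                f"{which}: vertex {v!r} has {len(cs)} children; trees must be "
                f"strictly bifurcating (polytomies are not supported)"
            )
    try:
        return Tree({v: tuple(cs) for v, cs in children.items()}, root=roots[0])
    except TanglegramError as exc:
        raise ParseError(f"{which}: {exc}") from exc


def parse_tabular(text: str) -> Tanglegram:
    """Parse the line-oriented tabular dialect into a validated tanglegram."""
    host_edges: list[tuple[str, str]] = []
    para_edges: list[tuple[str, str]] = []
    mapping: dict[str, str] = {}
    blocks = _OptionalBlocks()
    section = None
    saw_assoc_section = False
    for raw in text.splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        upper = line.upper()
        if upper in ("HOSTTREE", "PARASITETREE", "ASSOCIATIONS"):
            section = upper
            saw_assoc_section = saw_assoc_section or section == "ASSOCIATIONS"
            continue
        fields = line.split("\t") if "\t" in line else line.split()
        if blocks.feed(fields[0], fields[1:]):
            section = None
            continue
        if section == "HOSTTREE" or section == "PARASITETREE":
            if len(fields) != 2:
                raise ParseError(f"{section}: expected 'parent<TAB>child', got {line!r}")
            (host_edges if section == "HOSTTREE" else para_edges).append(
                (fields[0], fields[1])
            )
        elif section == "ASSOCIATIONS":
            if len(fields) != 2:
                raise ParseError(
                    f"ASSOCIATIONS: expected 'parasite-tip<TAB>host-tip', got {line!r}"
                )
            mapping[fields[0]] = fields[1]
        else:
            raise ParseError(f"line outside any section: {line!r}")
    host = _tree_from_edges(host_edges, "HOSTTREE")
    parasite = _tree_from_edges(para_edges, "PARASITETREE")
    if not mapping:
        raise ParseError("ASSOCIATIONS section is missing or empty")
    return blocks.assemble(host, parasite, mapping)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def _fmt_cost(x: float) -> str:
    if math.isinf(x):
        return "inf"
    return f"{x:g}"


def _optional_lines(tg: Tanglegram, sep: str) -> list[str]:
    c = tg.costs
    out = [
        "COSTS"
        + sep
        + sep.join(
            _fmt_cost(x)
            for x in (c.cospeciation_cost, c.duplication_cost, c.switch_cost, c.loss_cost)
        )
    ]
    if tg.zones is not None:
        for v, (lo, hi) in sorted(tg.zones.host_zones.items()):
            out.append(f"ZONE{sep}host{sep}{v}{sep}{lo}{sep}{hi}")
        for v, (lo, hi) in sorted(tg.zones.parasite_zones.items()):
            out.append(f"ZONE{sep}parasite{sep}{v}{sep}{lo}{sep}{hi}")
    if tg.regions is not None:
        for v, r in sorted(tg.regions.vertex_region.items()):
            out.append(f"REGION{sep}{v}{sep}{r}")
        for (r1, r2), cost in sorted(tg.regions.pair_costs.items()):
            out.append(f"REGIONCOST{sep}{r1}{sep}{r2}{sep}{_fmt_cost(cost)}")
    if tg.switch_distance_bound is not None:
        out.append(f"SWITCHDISTANCE{sep}{tg.switch_distance_bound}")
    return out


def write_tanglegram(tg: Tanglegram, dialect: str = "nexus") -> str:
    """Serialize a tanglegram; the output re-parses to an equal instance."""
    if dialect == "nexus":
        lines = [
            "#NEXUS",
            "BEGIN TREES;",
            f"    TREE HOST = {_tree_to_newick(tg.host)}",
            f"    TREE PARASITE = {_tree_to_newick(tg.parasite)}",
            "END;",
            "BEGIN COPHYLOGENY;",
        ]
        for p, h in sorted(tg.tip_mapping.items()):
            lines.append(f"    ASSOCIATE {p} : {h};")
        lines.extend(f"    {ln};" for ln in _optional_lines(tg, " "))
        lines.append("END;")
        return "\n".join(lines) + "\n"
    if dialect == "tabular":
        lines = ["HOSTTREE"]
        lines += [f"{u}\t{v}" for u, v in tg.host.edges()]
        lines.append("PARASITETREE")
        lines += [f"{u}\t{v}" for u, v in tg.parasite.edges()]
        lines.append("ASSOCIATIONS")
        lines += [f"{p}\t{h}" for p, h in sorted(tg.tip_mapping.items())]
        lines.extend(_optional_lines(tg, "\t"))
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown dialect {dialect!r} (use 'nexus' or 'tabular')")


def read_tanglegram(text: str, dialect: Optional[str] = None) -> Tanglegram:
    """Parse either dialect; sniffs the format when ``dialect`` is None."""
    if dialect is None:
        dialect = "nexus" if text.lstrip().upper().startswith("#NEXUS") else "tabular"
    if dialect == "nexus":
        return parse_nexus(text)
    if dialect == "tabular":
        return parse_tabular(text)
    raise ValueError(f"unknown dialect {dialect!r} (use 'nexus' or 'tabular')")
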