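"""Branched, mixed and homotypic ubiquitin chain architectures.

A polyubiquitin chain is a rooted tree: each node is one Ub moiety, each
edge an (iso)peptide bond from the C-terminal G76 of a *distal* Ub to an
attachment site (one of the seven lysines or the M1 amine) of a *proximal*
Ub.  The root is the proximal-most moiety (the one whose C terminus is free
or anchored to a substrate/resin).  This module provides the tree types, a
parser/formatter for an ASCII chain notation, enumeration of branched
trimer topologies, topology classification and in-silico cleavage.

Notation dialect
----------------
``chain := arms? "Ub" mods? ( "-[" sites "]" "Ub" mods? )*`` read distal to
proximal, left to right.  A parenthesised list before a ``-[sites]`` gives
the distal arms of the following unit, e.g. ``(Ub)2-[48,63]Ub`` is a
branched trimer with two monoUb arms on K48 and K63 of the root.  Unit
modifications go in braces: ``Ub{K48R,K63R}``, ``Ub{1-72}``, ``Ub{AVI}``,
``Ub{15N}``.  Compact homotypic forms ``48Ub3`` (K48-linked trimer) and
prefix repetitions ``63(Ub-[48]Ub)2`` are accepted, as are the unicode
superscript renderings commonly used in print (``^48^Ub_3``,
``(Ub)_2–^48,63^Ub``) on a best-effort basis.
"""

from __future__ import annotations

import itertools
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AttachmentSite",
    "UbUnit",
    "LinkageEdge",
    "ChainArchitecture",
    "NotationError",
    "ArchitectureError",
    "parse_architecture",
    "format_architecture",
    "compact_alias",
    "enumerate_branched_trimers",
    "classify_topology",
    "simulate_cleavage",
    "linkage_composition",
]


class AttachmentSite(IntEnum):
    """Ub-Ub attachment sites, ordered M1 < K6 < ... < K63 by residue number."""

    M1 = 1
    K6 = 6
    K11 = 11
    K27 = 27
    K29 = 29
    K33 = 33
    K48 = 48
    K63 = 63

    @property
    def label(self) -> str:
        """Numeric label used in chain notation ('1' for M1, '48' for K48...)."""
        return str(int(self))

    @classmethod
    def from_label(cls, label: str) -> "AttachmentSite":
        txt = label.strip().upper().lstrip("KM")
        try:
            return cls(int(txt))
        except (ValueError, KeyError) as exc:
            raise ArchitectureError(f"unknown attachment site {label!r}") from exc


ALL_SITES: tuple[AttachmentSite, ...] = tuple(AttachmentSite)
LYSINE_SITES: tuple[AttachmentSite, ...] = tuple(s for s in AttachmentSite if s is not AttachmentSite.M1)


class NotationError(ValueError):
    """Syntax error in chain notation; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class ArchitectureError(ValueError):
    """Semantic error: the described chain is chemically inadmissible."""


@dataclass(frozen=True)
class UbUnit:
    """One Ub moiety and its sequence variant.

    Parameters
    ----------
    id
        Opaque identifier, unique within an architecture.
    substitutions
        Lysine sites knocked out by K->R swaps (removes the site from
        availability for a proximal attachment).
    c_term
        Last residue retained; 76 is the full-length protein.  A truncated
        unit lacks G76 and therefore cannot be the distal end of an edge.
    tags
        Appended sequence tags by name (e.g. ``AVI``); sequences are
        resolved by the mass engine.
    isotope
        ``natural`` or ``15N`` (uniform metabolic labeling).
    """

    id: str
    substitutions: frozenset[AttachmentSite] = frozenset()
    c_term: int = 76
    tags: tuple[str, ...] = ()
    isotope: str = "natural"

    def __post_init__(self):
        if not 1 <= self.c_term <= 76:
            raise ArchitectureError(f"c_term must be in 1..76, got {self.c_term}")
        if AttachmentSite.M1 in self.substitutions:
            raise ArchitectureError("M1 is the N-terminal amine and cannot be substituted away")
        if self.isotope not in ("natural", "15N"):
            raise ArchitectureError(f"unknown isotope state {self.isotope!r}")
        for s in self.substitutions:
            if int(s) > self.c_term:
                raise ArchitectureError(f"substituted site {s.name} lies beyond the 1-{self.c_term} truncation")

    @property
    def available_sites(self) -> frozenset[AttachmentSite]:
        """Sites usable as the proximal end of an edge on this unit."""
        return frozenset(s for s in ALL_SITES if s not in self.substitutions and int(s) <= self.c_term)

    @property
    def has_free_g76(self) -> bool:
        """True when the C terminus ends at G76 so the unit can be ligated distally."""
        return self.c_term == 76

    @property
    def variant_key(self) -> tuple:
        """Identity of the sequence variant, independent of the unit id."""
        return (tuple(sorted(self.substitutions)), self.c_term, tuple(self.tags), self.isotope)

    def is_wild_type(self) -> bool:
        return self.variant_key == ((), 76, (), "natural")


@dataclass(frozen=True)
class LinkageEdge:
    """An isopeptide (or, for M1, peptide) bond between two units."""

    distal: str
    proximal: str
    site: AttachmentSite


class ChainArchitecture:
    """Rooted tree of :class:`UbUnit` with site-labeled edges.

    Invariants enforced on construction: edges form a tree over the units,
    there is exactly one root, ``(proximal, site)`` pairs are unique, the
    site is available on the proximal unit, and every distal unit carries a
    free G76.
    """

    def __init__(self, units: Iterable[UbUnit], edges: Iterable[LinkageEdge]):
        units = tuple(units)
        edges = tuple(edges)
        by_id = {u.id: u for u in units}
        if len(by_id) != len(units):
            raise ArchitectureError("duplicate unit ids")
        seen_prox: set[tuple[str, AttachmentSite]] = set()
        seen_distal: set[str] = set()
        for e in edges:
            if e.distal not in by_id or e.proximal not in by_id:
                raise ArchitectureError(f"edge references unknown unit: {e}")
            if e.distal == e.proximal:
                raise ArchitectureError("self-linkage is not a tree edge")
            key = (e.proximal, e.site)
            if key in seen_prox:
                raise ArchitectureError(f"duplicate attachment at {e.proximal}:{e.site.name}")
            seen_prox.add(key)
            if e.site not in by_id[e.proximal].available_sites:
                raise ArchitectureError(f"site {e.site.name} is not available on unit {e.proximal}")
            if not by_id[e.distal].has_free_g76:
                raise ArchitectureError(f"unit {e.distal} is C-terminally truncated and cannot be distal")
            if e.distal in seen_distal:
                raise ArchitectureError(f"unit {e.distal} is the distal end of more than one edge")
            seen_distal.add(e.distal)
        roots = [u.id for u in units if u.id not in seen_distal]
        if len(units) == 0:
            raise ArchitectureError("architecture needs at least one unit")
        if len(roots) != 1:
            raise ArchitectureError(f"expected exactly one root, found {len(roots)}")
        if len(edges) != len(units) - 1:
            raise ArchitectureError("edges do not form a spanning tree")
        # connectivity: walk down from the root
        children: dict[str, list[LinkageEdge]] = {u.id: [] for u in units}
        for e in edges:
            children[e.proximal].append(e)
        reached = set()
        stack = [roots[0]]
        while stack:
            uid = stack.pop()
            reached.add(uid)
            stack.extend(e.distal for e in children[uid])
        if len(reached) != len(units):
            raise ArchitectureError("architecture is not connected")
        self._units = by_id
        self._edges = edges
        self._root = roots[0]
        self._children = {uid: tuple(sorted(es, key=lambda e: e.site)) for uid, es in children.items()}

    # -- accessors ---------------------------------------------------------
    @property
    def units(self) -> tuple[UbUnit, ...]:
        return tuple(self._units[uid] for uid in sorted(self._units))

    @property
    def edges(self) -> tuple[LinkageEdge, ...]:
        return self._edges

    @property
    def root(self) -> UbUnit:
        return self._units[self._root]

    def unit(self, uid: str) -> UbUnit:
        return self._units[uid]

    def children(self, uid: str) -> tuple[LinkageEdge, ...]:
        """Distal arms of a unit, sorted by attachment site."""
        return self._children[uid]

    def __len__(self) -> int:
        return len(self._units)

    def __repr__(self) -> str:
        return f"ChainArchitecture({format_architecture(self)!r})"

    def __eq__(self, other) -> bool:
        return isinstance(other, ChainArchitecture) and self.is_isomorphic(other)

    def __hash__(self) -> int:
        return hash(format_architecture(self))

    def is_isomorphic(self, other: "ChainArchitecture") -> bool:
        """Equality up to unit-id relabeling.

        Children are keyed by attachment site and sites are unique per
        unit, so the canonical notation is a complete tree invariant.
        """
        return format_architecture(self) == format_architecture(other)

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "units": [
                {
                    "id": u.id,
                    "substitutions": [s.name for s in sorted(u.substitutions)],
                    "c_term": u.c_term,
                    "tags": list(u.tags),
                    "isotope": u.isotope,
                }
                for u in self.units
            ],
            "edges": [
                {"distal": e.distal, "proximal": e.proximal, "site": e.site.name}
                for e in self._edges
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "ChainArchitecture":
        units = [
            UbUnit(
                id=u["id"],
                substitutions=frozenset(AttachmentSite.from_label(s) for s in u.get("substitutions", ())),
                c_term=u.get("c_term", 76),
                tags=tuple(u.get("tags", ())),
                isotope=u.get("isotope", "natural"),
            )
            for u in data["units"]
        ]
        edges = [
            LinkageEdge(e["distal"], e["proximal"], AttachmentSite.from_label(e["site"]))
            for e in data["edges"]
        ]
        return cls(units, edges)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "ChainArchitecture":
        return cls.from_dict(json.loads(text))


def mono(unit: UbUnit | None = None) -> ChainArchitecture:
    """A single free Ub."""
    return ChainArchitecture([unit or UbUnit("u1")], [])


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_KNOWN_TAGS = ("AVI", "HIS", "SPY")


@dataclass(frozen=True)
class _UnitSpec:
    substitutions: frozenset[AttachmentSite] = frozenset()
    c_term: int = 76
    tags: tuple[str, ...] = ()
    isotope: str = "natural"


@dataclass
class _Node:
    spec: _UnitSpec
    arms: list[tuple[AttachmentSite, "_Node"]] = field(default_factory=list)

    def clone(self) -> "_Node":
        return _Node(self.spec, [(s, n.clone()) for s, n in self.arms])


def _normalize(notation: str) -> str:
    """Fold the unicode/superscript print rendering into the ASCII dialect."""
    s = re.sub(r"\s+", "", notation)
    s = s.replace("–", "-").replace("—", "-").replace("−", "-")
    if "^" in s or "_" in s:
        # square brackets in print are grouping brackets, not site lists
        s = s.replace("[", "(").replace("]", ")")
        s = s.replace("*biotin", "")
        # subscript repeat counts: (Ub)_2_ -> (Ub)2 ; Ub_3_ -> Ub3
        s = re.sub(r"_(\d+)_?", r"\1", s)
        # unit modifications: Ub^K48R,K63R^ -> Ub{K48R,K63R}
        s = re.sub(r"(?<=Ub)\^([^^]+)\^", lambda m: "{" + m.group(1) + "}", s)
        # linkage superscripts after a dash: -^48,63^ -> -[48,63]
        s = re.sub(r"-\^([\dKM,]+)\^", r"-[\1]", s)
        # homotypic / repetition prefixes: ^48^Ub3, ^63^( -> 48Ub3, 63(
        s = re.sub(r"\^([\dKM]+)\^(?=\(|Ub)", r"\1", s)
        if "^" in s or "_" in s:
            raise NotationError(f"could not interpret superscript notation in {notation!r}")
    return s


class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    # -- low level ---------------------------------------------------------
    def peek(self, lit: str) -> bool:
        return self.text.startswith(lit, self.pos)

    def expect(self, lit: str) -> None:
        if not self.peek(lit):
            raise NotationError(f"expected {lit!r}", self.pos)
        self.pos += len(lit)

    def eat_int(self) -> int | None:
        m = re.match(r"\d+", self.text[self.pos:])
        if not m:
            return None
        self.pos += m.end()
        return int(m.group())

    def at_end(self) -> bool:
        return self.pos >= len(self.text)

    def expect_end(self) -> None:
        if not self.at_end():
            raise NotationError(f"unexpected trailing text {self.text[self.pos:]!r}", self.pos)

    # -- grammar -----------------------------------------------------------
    def parse_chain(self) -> _Node:
        node = self._compact()
        if node is not None:
            return node
        pending: list[_Node] = []
        if self.peek("Ub"):
            pending = [_Node(self.parse_unit())]
        elif self.peek("("):
            pending = self.parse_arm_list()
        else:
            raise NotationError("expected 'Ub' or '('", self.pos)
        while self.peek("-["):
            sites = self.parse_sites()
            spec = self.parse_unit()
            if len(sites) != len(pending):
                raise NotationError(
                    f"site list {[s.label for s in sites]} does not match "
                    f"{len(pending)} distal group(s)", self.pos)
            node = _Node(spec, list(zip(sites, pending)))
            _check_node(node)
            pending = [node]
            if self.peek("("):
                pending += self.parse_arm_list()
        if len(pending) != 1:
            raise NotationError("distal arms lack a '-[sites]' attachment", self.pos)
        return pending[0]

    def _compact(self) -> _Node | None:
        """``48Ub3`` and ``63(chain)2`` prefix-repetition forms."""
        m = re.match(r"(\d+)(?=\(|Ub)", self.text[self.pos:])
        if not m:
            return None
        site = AttachmentSite.from_label(m.group(1))
        self.pos += m.end()
        if self.peek("("):
            self.expect("(")
            inner = self.parse_chain()
            self.expect(")")
        else:
            inner = _Node(self.parse_unit())
        n = self.eat_int()
        if n is None or n < 1:
            raise NotationError("repetition count required after compact form", self.pos)
        copies = [inner.clone() for _ in range(n)]
        for distal, proximal in zip(copies, copies[1:]):
            head = _spine_head(proximal)
            if any(s == site for s, _ in head.arms):
                raise NotationError(f"site {site.label} already occupied in repetition", self.pos)
            head.arms.append((site, distal))
            _check_node(head)
        return copies[-1]

    def parse_arm_list(self) -> list[_Node]:
        arms: list[_Node] = []
        while self.peek("("):
            self.expect("(")
            chain = self.parse_chain()
            self.expect(")")
            count = self.eat_int() or 1
            arms.extend(chain.clone() for _ in range(count))
        return arms

    def parse_sites(self) -> list[AttachmentSite]:
        self.expect("-[")
        sites = []
        while True:
            m = re.match(r"[KM]?\d+", self.text[self.pos:])
            if not m:
                raise NotationError("expected site label", self.pos)
            sites.append(AttachmentSite.from_label(m.group()))
            self.pos += m.end()
            if self.peek(","):
                self.expect(",")
            else:
                break
        self.expect("]")
        return sites

    def parse_unit(self) -> _UnitSpec:
        self.expect("Ub")
        if not self.peek("{"):
            return _UnitSpec()
        self.expect("{")
        subs: set[AttachmentSite] = set()
        c_term = 76
        tags: list[str] = []
        isotope = "natural"
        while True:
            m = re.match(r"[^,}]+", self.text[self.pos:])
            if not m:
                raise NotationError("empty modification", self.pos)
            tok = m.group()
            self.pos += m.end()
            if tok == "15N":
                isotope = "15N"
            elif re.fullmatch(r"K\d+R", tok):
                subs.add(AttachmentSite.from_label(tok[1:-1]))
            elif re.fullmatch(r"1-\d+(-\w+)?", tok):
                parts = tok.split("-")
                c_term = int(parts[1])
                if len(parts) == 3:
                    tags.append(parts[2].upper())
            elif tok.upper() in _KNOWN_TAGS:
                tags.append(tok.upper())
            else:
                raise NotationError(f"unknown modification {tok!r}", self.pos - len(tok))
            if self.peek(","):
                self.expect(",")
            else:
                break
        self.expect("}")
        try:
            return _UnitSpec(frozenset(subs), c_term, tuple(tags), isotope)
        except ArchitectureError as exc:
            raise NotationError(str(exc), self.pos) from exc


def _spine_head(node: _Node) -> _Node:
    """Distal-most unit along an unbranched spine (for prefix repetitions)."""
    while node.arms:
        if len(node.arms) > 1:
            raise NotationError("prefix repetition requires an unbranched chain")
        node = node.arms[0][1]
    return node


def _check_node(node: _Node) -> None:
    sites = [s for s, _ in node.arms]
    dup = [s for s, c in Counter(sites).items() if c > 1]
    if dup:
        raise ArchitectureError(f"duplicate attachment site {dup[0].label} on one unit")
    for s, child in node.arms:
        if s in node.spec.substitutions or int(s) > node.spec.c_term:
            raise ArchitectureError(f"site {s.label} is not available on the modified unit")
        if child.spec.c_term != 76:
            raise ArchitectureError("a C-terminally truncated unit cannot form a distal arm")


def parse_architecture(notation: str) -> ChainArchitecture:
    """Parse chain notation into a validated :class:`ChainArchitecture`.

    Raises :class:`NotationError` for syntax problems (with position) and
    :class:`ArchitectureError` for chemically inadmissible chains.
    """
    parser = _Parser(_normalize(notation))
    tree = parser.parse_chain()
    parser.expect_end()
    units: list[UbUnit] = []
    edges: list[LinkageEdge] = []

    def build(node: _Node) -> str:
        uid = f"u{len(units) + 1}"
        units.append(UbUnit(uid, node.spec.substitutions, node.spec.c_term, node.spec.tags, node.spec.isotope))
        for site, child in sorted(node.arms, key=lambda sc: sc[0]):
            cid = build(child)
            edges.append(LinkageEdge(cid, uid, site))
        return uid

    build(tree)
    return ChainArchitecture(units, edges)


# ---------------------------------------------------------------------------
# Formatting
# ---------------------------------------------------------------------------

def _unit_str(u: UbUnit) -> str:
    mods: list[str] = [f"K{int(s)}R" for s in sorted(u.substitutions)]
    if u.c_term < 76:
        mods.append(f"1-{u.c_term}")
    mods.extend(u.tags)
    if u.isotope == "15N":
        mods.append("15N")
    return "Ub" + ("{" + ",".join(mods) + "}" if mods else "")


def format_architecture(arch: ChainArchitecture) -> str:
    """Canonical notation: identical architectures (up to unit-id relabeling)
    format identically, and ``parse(format(x))`` is isomorphic to ``x``."""

    def fmt(uid: str) -> str:
        unit = arch.unit(uid)
        kids = arch.children(uid)
        if not kids:
            return _unit_str(unit)
        if len(kids) == 1:
            e = kids[0]
            return f"{fmt(e.distal)}-[{e.site.label}]{_unit_str(unit)}"
        arm_strs = [fmt(e.distal) for e in kids]
        parts: list[str] = []
        for s, grp in itertools.groupby(arm_strs):
            k = len(list(grp))
            parts.append(f"({s})" + (str(k) if k > 1 else ""))
        sites = ",".join(e.site.label for e in kids)
        return "".join(parts) + f"-[{sites}]{_unit_str(unit)}"

    return fmt(arch.root.id)


def compact_alias(arch: ChainArchitecture) -> str | None:
    """Short homotypic alias such as ``48Ub3``, or ``Ub`` for monoUb.

    Returns None for branched/mixed chains or chains with modified units.
    """
    if any(not u.is_wild_type() for u in arch.units):
        return None
    if len(arch) == 1:
        return "Ub"
    labels = {e.site for e in arch.edges}
    if classify_topology(arch) == "homotypic_unbranched" and len(labels) == 1:
        return f"{labels.pop().label}Ub{len(arch)}"
    return None


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def enumerate_branched_trimers(sites: Sequence[AttachmentSite]) -> list[ChainArchitecture]:
    """All branched trimers: two monoUb arms on distinct sites of one root.

    One architecture per unordered pair of distinct sites; the count is
    C(len(sites), 2).  Deterministic canonical (site-sorted) order.
    """
    sites = [s if isinstance(s, AttachmentSite) else AttachmentSite.from_label(str(s)) for s in sites]
    if len(set(sites)) != len(sites):
        raise ArchitectureError("duplicate site labels")
    out = []
    for a, b in itertools.combinations(sorted(sites), 2):
        out.append(parse_architecture(f"(Ub)2-[{a.label},{b.label}]Ub"))
    return out


def classify_topology(arch: ChainArchitecture) -> str:
    """``mono`` | ``homotypic_unbranched`` | ``mixed_unbranched`` | ``branched``."""
    if len(arch) == 1:
        return "mono"
    if any(len(arch.children(u.id)) >= 2 for u in arch.units):
        return "branched"
    labels = {e.site for e in arch.edges}
    return "homotypic_unbranched" if len(labels) == 1 else "mixed_unbranched"


def simulate_cleavage(arch: ChainArchitecture, cut_edges: Iterable[LinkageEdge]) -> list[ChainArchitecture]:
    """Connected components after hydrolyzing ``cut_edges``.

    Cleavage of an isopeptide bond restores the distal unit's free C
    terminus and the proximal unit's free attachment site, so each
    component is itself a valid architecture; the unit multiset is
    conserved and ``len(result) == len(cut_edges) + 1``.
    """
    cut = set(cut_edges)
    unknown = cut - set(arch.edges)
    if unknown:
        raise ArchitectureError(f"unknown edge(s): {sorted(unknown, key=str)}")
    keep = [e for e in arch.edges if e not in cut]
    adj: dict[str, list[str]] = {u.id: [] for u in arch.units}
    for e in keep:
        adj[e.distal].append(e.proximal)
        adj[e.proximal].append(e.distal)
    comp_of: dict[str, int] = {}
    comps: list[list[str]] = []
    for u in arch.units:
        if u.id in comp_of:
            continue
        stack, members = [u.id], []
        comp_of[u.id] = len(comps)
        while stack:
            v = stack.pop()
            members.append(v)
            for w in adj[v]:
                if w not in comp_of:
                    comp_of[w] = len(comps)
                    stack.append(w)
        comps.append(members)
    out = []
    for members in comps:
        mset = set(members)
        out.append(ChainArchitecture(
            [arch.unit(m) for m in sorted(mset)],
            [e for e in keep if e.distal in mset],
        ))
    out.sort(key=format_architecture)
    return out


def linkage_composition(arch: ChainArchitecture) -> dict[AttachmentSite, int]:
    """Edge count per site label; values sum to ``len(arch) - 1``."""
    return dict(sorted(Counter(e.site for e in arch.edges).items()))
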