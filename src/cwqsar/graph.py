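"""Hydrogen-suppressed molecular graph and its attribute-key invariants.

The SMILES grammar supported here covers organic-subset atoms (B, C, N, O,
P, S, F, Cl, Br, I and their aromatic lower-case forms), bracket atoms,
single/double/triple bonds, branches, and ring closures (digits and %NN).
Explicit hydrogens are dropped from the graph.  Bond orders are ignored
for adjacency: an edge is an edge, aromatic or not.

Invariants rendered as 12-character attribute keys:

* ``EC0`` — vertex degree ("EC0-" + element padded to 4 + degree).
* ``EC1`` — first-order Morgan extended connectivity, i.e. the sum of the
  degrees of a vertex's neighbours.
* ``C5``/``C6`` — counts of 5-/6-membered rings in a minimum cycle basis
  of the skeleton, clipped to one digit ("C5......n...").
* ``NNC`` — a per-vertex neighbourhood code, disabled by default.  The
  convention used here is the counts of neighbours of degree 1, 2 and >=3
  (each clipped at 9): "NNC-" + element + three digits.  It exists so that
  NNC-style report rows can be rendered; it is this package's own
  convention and is never used in validated descriptors by default.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .attributes import KEY_WIDTH, SmilesParseError, tokenize_raw

__all__ = ["HeavySkeleton", "parse_skeleton", "ec0", "ec1", "ring_counts", "nnc"]

_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "Cl", "Br", "I"}
_AROMATIC = {"b", "c", "n", "o", "p", "s"}
_BOND_SYMBOLS = {"-", "=", "#", "/", "\\"}

_BRACKET_RE = re.compile(
    r"^(?P<isotope>\d+)?(?P<element>[A-Z][a-z]?|[a-z])(?P<chiral>@{1,2})?"
    r"(?P<hcount>H\d*)?(?P<charge>[+-]\d*|[+]+|[-]+)?$"
)


@dataclass
class HeavySkeleton:
    """Heavy-atom graph: element symbols, aromatic flags, edge set."""

    elements: list[str]
    aromatic: list[bool]
    edges: set[tuple[int, int]]

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)

    def degrees(self) -> list[int]:
        deg = [0] * self.n_atoms
        for u, v in self.edges:
            deg[u] += 1
            deg[v] += 1
        return deg

    def neighbors(self, i: int) -> list[int]:
        out = []
        for u, v in self.edges:
            if u == i:
                out.append(v)
            elif v == i:
                out.append(u)
        return out

    def to_networkx(self) -> "nx.Graph":
        g = nx.Graph()
        g.add_nodes_from(range(self.n_atoms))
        g.add_edges_from(self.edges)
        return g


def parse_skeleton(smiles: str) -> HeavySkeleton:
    """Parse a SMILES string into a hydrogen-suppressed heavy-atom graph.

    Raises :class:`SmilesParseError` for unmatched ring closures or
    unsupported constructs (named in the message).
    """
    tokens = tokenize_raw(smiles)
    elements: list[str] = []
    aromatic: list[bool] = []
    edges: set[tuple[int, int]] = set()
    prev: int | None = None
    branch_stack: list[int | None] = []
    open_rings: dict[str, int] = {}

    def add_atom(element: str, is_aromatic: bool) -> None:
        nonlocal prev
        elements.append(element)
        aromatic.append(is_aromatic)
        idx = len(elements) - 1
        if prev is not None:
            edges.add((min(prev, idx), max(prev, idx)))
        prev = idx

    i = 0
    n = len(tokens)
    while i < n:
        tok = tokens[i]
        if tok == "[":
            # collect tokens until ']'
            j = i + 1
            content = ""
            while j < n and tokens[j] != "]":
                content += tokens[j]
                j += 1
            if j >= n:
                raise SmilesParseError(f"unclosed bracket atom in {smiles!r}")
            m = _BRACKET_RE.match(content)
            if not m:
                raise SmilesParseError(
                    f"unsupported bracket atom [{content}] in {smiles!r}"
                )
            elem = m.group("element")
            if elem == "H":
                # explicit hydrogen vertex: excluded from the heavy graph;
                # it terminates a branch, so the previous atom is kept.
                pass
            elif elem.lower() == elem:
                add_atom(elem.capitalize(), True)
            else:
                add_atom(elem, False)
            i = j + 1
        elif tok in _ORGANIC:
            add_atom(tok, False)
            i += 1
        elif tok in _AROMATIC:
            add_atom(tok.capitalize(), True)
            i += 1
        elif tok == "(":
            branch_stack.append(prev)
            i += 1
        elif tok == ")":
            if not branch_stack:
                raise SmilesParseError(f"unmatched ')' in {smiles!r}")
            prev = branch_stack.pop()
            i += 1
        elif tok in _BOND_SYMBOLS or tok == ":":
            # bond order/aromaticity markers do not change adjacency
            i += 1
        elif tok.isdigit() or tok.startswith("%"):
            label = tok.lstrip("%")
            if prev is None:
                raise SmilesParseError(
                    f"ring closure {tok!r} before any atom in {smiles!r}"
                )
            if label in open_rings:
                other = open_rings.pop(label)
                if other != prev:
                    edges.add((min(other, prev), max(other, prev)))
            else:
                open_rings[label] = prev
            i += 1
        elif tok in ("@", "@@", ".", "]"):
            if tok == "]":
                raise SmilesParseError(f"unmatched ']' in {smiles!r}")
            if tok == ".":
                prev = None
            i += 1
        else:
            raise SmilesParseError(
                f"unsupported SMILES feature {tok!r} in {smiles!r}"
            )
    if open_rings:
        raise SmilesParseError(
            f"unmatched ring closure(s) {sorted(open_rings)} in {smiles!r}"
        )
    if not elements:
        raise SmilesParseError(f"no heavy atoms in {smiles!r}")
    return HeavySkeleton(elements, aromatic, edges)


def _render(tag: str, element: str | None, value: str) -> str:
    body = tag + (element.ljust(4, ".") if element is not None else "......")
    key = (body + value).ljust(KEY_WIDTH, ".")
    if len(key) != KEY_WIDTH:
        raise ValueError(f"invariant key overflow: {key!r}")
    return key


def ec0(skeleton: HeavySkeleton) -> Counter[str]:
    """Vertex-degree keys, one per heavy atom (multiplicities accumulate)."""
    counts: Counter[str] = Counter()
    for elem, deg in zip(skeleton.elements, skeleton.degrees()):
        counts[_render("EC0-", elem, str(deg))] += 1
    return counts


def ec1(skeleton: HeavySkeleton) -> Counter[str]:
    """First-order Morgan extended connectivity keys (neighbour-degree sums)."""
    deg = skeleton.degrees()
    counts: Counter[str] = Counter()
    for i, elem in enumerate(skeleton.elements):
        value = sum(deg[j] for j in skeleton.neighbors(i))
        counts[_render("EC1-", elem, str(value))] += 1
    return counts


def ring_counts(skeleton: HeavySkeleton) -> Counter[str]:
    """C5/C6 ring-code keys from a minimum cycle basis of the skeleton."""
    basis = nx.minimum_cycle_basis(skeleton.to_networkx())
    n5 = min(sum(1 for cyc in basis if len(cyc) == 5), 9)
    n6 = min(sum(1 for cyc in basis if len(cyc) == 6), 9)
    return Counter({_render("C5", None, str(n5)): 1, _render("C6", None, str(n6)): 1})


def nnc(skeleton: HeavySkeleton) -> Counter[str]:
    """Neighbourhood codes (this package's convention; see module docstring)."""
    deg = skeleton.degrees()
    counts: Counter[str] = Counter()
    for i, elem in enumerate(skeleton.elements):
        nbr = [deg[j] for j in skeleton.neighbors(i)]
        d1 = min(sum(1 for d in nbr if d == 1), 9)
        d2 = min(sum(1 for d in nbr if d == 2), 9)
        d3 = min(sum(1 for d in nbr if d >= 3), 9)
        counts[_render("NNC-", elem, f"{d1}{d2}{d3}")] += 1
    return counts
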