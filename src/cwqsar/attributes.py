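"""SMILES attribute extraction.

A SMILES string is treated as a stream of tokens ("SMILES atoms"): single
characters, or the few multi-character symbols that cannot be split
(two-letter element symbols such as 'Cl'/'Br', the stereo marker '@@', and
ring closures of the form '%NN').  From the token stream two families of
*local* attributes are formed — Sk (single tokens) and SSk (adjacent token
pairs) — and four families of *global* attributes describing the whole
molecule: BOND (bond symbols present), NOSP (N/O/S/P present), HALO
(halogens present) and PAIR (co-occurring feature pairs).

Every attribute is rendered as a fixed-width 12-character key so that
weight tables from different models can be compared attribute by attribute.
Closing parentheses are canonicalized to '(' before any attribute is
formed, so a branch boundary is a single symbol regardless of direction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

__all__ = [
    "SmilesParseError",
    "KEY_WIDTH",
    "tokenize",
    "tokenize_raw",
    "render_local",
    "extract_local",
    "encode_globals",
    "extract_attributes",
    "normalize_key",
    "SMILES_FAMILIES",
    "EC_FAMILIES",
    "RING_FAMILIES",
    "ALL_FAMILIES",
]

KEY_WIDTH = 12

# Families understood by extract_attributes.  SK/SSK are the local SMILES
# attributes; BOND/NOSP/HALO/PAIR the global ones; EC0/EC1/C5/C6/NNC are
# graph invariants computed from the hydrogen-suppressed skeleton.
SMILES_FAMILIES = frozenset({"SK", "SSK", "BOND", "NOSP", "HALO", "PAIR"})
EC_FAMILIES = frozenset({"SK", "SSK", "EC0", "EC1"})
RING_FAMILIES = frozenset({"SK", "SSK", "C5", "C6"})
ALL_FAMILIES = SMILES_FAMILIES | frozenset({"EC0", "EC1", "C5", "C6", "NNC"})

_TWO_CHAR = ("Cl", "Br", "@@")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be tokenized or parsed."""


def _check_text(smiles: str) -> str:
    if not isinstance(smiles, str) or not smiles:
        raise SmilesParseError("empty SMILES string")
    if any(ch.isspace() for ch in smiles):
        raise SmilesParseError(f"whitespace inside SMILES: {smiles!r}")
    if smiles.count("(") != smiles.count(")"):
        raise SmilesParseError(
            f"unbalanced parentheses in {smiles!r}: "
            f"{smiles.count('(')} '(' vs {smiles.count(')')} ')'"
        )
    return smiles


def tokenize_raw(smiles: str) -> list[str]:
    """Tokenize without canonicalization: ')' is kept as ')'.

    Greedy longest match: 'Cl', 'Br', '@@' and '%NN' are single tokens;
    everything else is one character.  Joining the result reproduces the
    input exactly.
    """
    _check_text(smiles)
    tokens: list[str] = []
    i = 0
    n = len(smiles)
    while i < n:
        two = smiles[i : i + 2]
        if two in _TWO_CHAR:
            tokens.append(two)
            i += 2
        elif smiles[i] == "%":
            digits = smiles[i + 1 : i + 3]
            if len(digits) != 2 or not digits.isdigit():
                raise SmilesParseError(
                    f"'%' at position {i} not followed by two digits in {smiles!r}"
                )
            tokens.append(smiles[i : i + 3])
            i += 3
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


def tokenize(smiles: str) -> list[str]:
    """Tokenize a SMILES string into canonical tokens (')' becomes '(')."""
    return ["(" if t == ")" else t for t in tokenize_raw(smiles)]


def render_local(token_a: str, token_b: Optional[str] = None) -> str:
    """Render one token (Sk) or a token pair (SSk) as a 12-character key.

    An Sk key is the token left-justified with '.' padding.  An SSk key
    holds two 4-character '.'-padded token fields followed by four '.';
    the token that sorts *higher* in ASCII order occupies the first field,
    so render_local(a, b) == render_local(b, a).
    """
    if len(token_a) > 4 or (token_b is not None and len(token_b) > 4):
        raise ValueError("token longer than 4 characters")
    if token_b is None:
        return token_a.ljust(KEY_WIDTH, ".")
    hi, lo = (token_a, token_b) if token_a >= token_b else (token_b, token_a)
    return hi.ljust(4, ".") + lo.ljust(4, ".") + "...."


def extract_local(tokens: Sequence[str]) -> Counter[str]:
    """Sk and SSk attribute multiset of a canonical token stream."""
    counts: Counter[str] = Counter()
    for tok in tokens:
        counts[render_local(tok)] += 1
    for a, b in zip(tokens, tokens[1:]):
        counts[render_local(a, b)] += 1
    return counts


# Feature alphabet for the global attributes, in canonical order.  B2/B3
# stand for a double/triple bond anywhere in the molecule, ST for a stereo
# marker ('@' or '@@').
_FEATURE_ORDER = ("F", "Cl", "Br", "I", "N", "O", "S", "P", "B2", "B3", "ST")

_ELEMENT_FEATURES = {
    "N": "N", "n": "N",
    "O": "O", "o": "O",
    "S": "S", "s": "S",
    "P": "P", "p": "P",
    "F": "F",
    "Cl": "Cl",
    "Br": "Br",
    "I": "I",
}


def _present_features(tokens: Sequence[str]) -> list[str]:
    present: set[str] = set()
    for tok in tokens:
        if tok in _ELEMENT_FEATURES:
            present.add(_ELEMENT_FEATURES[tok])
        elif tok == "=":
            present.add("B2")
        elif tok == "#":
            present.add("B3")
        elif tok in ("@", "@@"):
            present.add("ST")
    return [f for f in _FEATURE_ORDER if f in present]


def _flags(present: Iterable[str], order: Sequence[str]) -> str:
    p = set(present)
    return "".join("1" if f in p else "0" for f in order)


def render_pair(feature_a: str, feature_b: str) -> str:
    """PAIR key: '++++', first feature '-'-padded to 4, second '='-padded."""
    ia, ib = _FEATURE_ORDER.index(feature_a), _FEATURE_ORDER.index(feature_b)
    first, second = (feature_a, feature_b) if ia <= ib else (feature_b, feature_a)
    return "++++" + first.ljust(4, "-") + second.ljust(4, "=")


def encode_globals(tokens: Sequence[str]) -> Counter[str]:
    """Global BOND/NOSP/HALO/PAIR keys for one molecule (multiplicity 1 each).

    BOND flags, in order: '=' present, '#' present, '@'/'@@' present, then
    five unused '0' positions.  NOSP flags N, O, S, P; HALO flags F, Cl,
    Br, I (each followed by four '0').  One PAIR key is emitted for every
    unordered pair of distinct present features.
    """
    present = _present_features(tokens)
    counts: Counter[str] = Counter()
    counts["BOND" + _flags(present, ("B2", "B3", "ST")) + "00000"] = 1
    counts["NOSP" + _flags(present, ("N", "O", "S", "P")) + "0000"] = 1
    counts["HALO" + _flags(present, ("F", "Cl", "Br", "I")) + "0000"] = 1
    for a, b in combinations(present, 2):
        counts[render_pair(a, b)] = 1
    return counts


def normalize_key(key: str) -> str:
    """Canonicalize an attribute key read from an external table.

    Accepts the alternative PAIR paddings found in printed tables ('.'
    fill for the first feature field) and upper-case halogen spellings
    ('CL', 'BR'); pads short keys to 12 characters with '.'.
    """
    key = key.rstrip()
    if len(key) < KEY_WIDTH:
        key = key.ljust(KEY_WIDTH, ".")
    if len(key) != KEY_WIDTH:
        raise ValueError(f"attribute key {key!r} is not {KEY_WIDTH} characters")
    if key.startswith("++++"):
        f1 = key[4:8].rstrip("-.").strip()
        f2 = key[8:12].rstrip("=").strip()
        fixup = {"CL": "Cl", "BR": "Br"}
        f1 = fixup.get(f1, f1)
        f2 = fixup.get(f2, f2)
        if f1 not in _FEATURE_ORDER or f2 not in _FEATURE_ORDER:
            raise ValueError(f"unknown PAIR features in key {key!r}")
        return render_pair(f1, f2)
    return key


@dataclass(frozen=True)
class DescriptorConfig:
    """Descriptor definition: rarity threshold T, epoch count N, families.

    ``threshold`` (T) is the minimum number of distinct training molecules
    an attribute must occur in to receive a correlation weight; rarer
    attributes are blocked (weight fixed at 0).  ``epochs`` (N) is the
    number of Monte Carlo optimization epochs.  ``families`` selects which
    attribute families enter the descriptor sum.
    """

    threshold: int = 1
    epochs: int = 10
    families: frozenset[str] = field(default_factory=lambda: SMILES_FAMILIES)

    def __post_init__(self) -> None:
        if self.threshold < 1:
            raise ValueError("threshold T must be >= 1")
        if self.epochs < 0:
            raise ValueError("epoch count N must be >= 0")
        unknown = set(self.families) - ALL_FAMILIES
        if unknown:
            raise ValueError(f"unknown attribute families: {sorted(unknown)}")


def extract_attributes(
    smiles: str, config: DescriptorConfig | None = None
) -> Counter[str]:
    """Full attribute multiset of one SMILES under a descriptor config.

    Local and global SMILES attributes are always computed from the token
    stream; graph-invariant families (EC0, EC1, C5, C6, NNC) additionally
    parse the hydrogen-suppressed skeleton.  Deterministic for a fixed
    input and config.
    """
    if config is None:
        config = DescriptorConfig()
    fams = config.families
    tokens = tokenize(smiles)
    counts: Counter[str] = Counter()
    if "SK" in fams or "SSK" in fams:
        local = extract_local(tokens)
        if "SK" in fams and "SSK" in fams:
            counts.update(local)
        else:
            keep_pairs = "SSK" in fams
            for key, c in local.items():
                # An SSk key has a non-'.' second field; tokens are <= 3
                # chars so an Sk key never reaches positions 5-8.
                is_pair = key[4:8].strip(".") != ""
                if is_pair == keep_pairs:
                    counts[key] += c
    if fams & {"BOND", "NOSP", "HALO", "PAIR"}:
        for key, c in encode_globals(tokens).items():
            family = key[:4] if not key.startswith("++++") else "PAIR"
            if family in fams:
                counts[key] = c
    if fams & {"EC0", "EC1", "C5", "C6", "NNC"}:
        from . import graph

        skeleton = graph.parse_skeleton(smiles)
        if "EC0" in fams:
            counts.update(graph.ec0(skeleton))
        if "EC1" in fams:
            counts.update(graph.ec1(skeleton))
        if fams & {"C5", "C6"}:
            for key, c in graph.ring_counts(skeleton).items():
                if key[:2] in fams:
                    counts[key] = c
        if "NNC" in fams:
            counts.update(graph.nnc(skeleton))
    return counts
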