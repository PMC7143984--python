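"""Synthetic SMILES datasets with a planted correlation-weight endpoint.

The generator emits small organic-looking SMILES from a closed grammar —
chains, branches, 5-/6-membered rings (aliphatic or aromatic), double and
triple bonds, terminal halogens — restricted by construction to exactly
the syntax the tokenizer and graph parser support, so every generated
string is parseable.

An endpoint is planted as a noisy linear function of the descriptor under
a hidden weight table:

    endpoint_i = intercept + slope * DCW(attrs_i; true_weights) + eps_i,
    eps ~ Normal(0, noise_sd)

which mirrors the structure the one-variable correlation-weight model
assumes, so parameter recovery is a meaningful end-to-end check.  The
default harness generates n=250 molecules with noise_sd set to 5% of the
standard deviation of the noiseless signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .attributes import DescriptorConfig, extract_attributes
from .descriptor import CorrelationWeightTable
from .io import Dataset

__all__ = [
    "GrammarSpec",
    "PlantedModel",
    "generate_molecules",
    "plant_weights",
    "simulate_endpoint",
    "make_dataset",
    "make_splits",
]


@dataclass(frozen=True)
class GrammarSpec:
    """Closed SMILES grammar for the generator.

    Probabilities are per-opportunity; ``max_chain`` bounds the backbone
    length (atoms).  Halogens from the alphabet appear only terminally.
    """

    atoms: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br")
    max_chain: int = 12
    p_branch: float = 0.3
    p_ring: float = 0.25
    p_double: float = 0.15
    p_triple: float = 0.03
    p_aromatic_ring: float = 0.4

    def __post_init__(self) -> None:
        for name in ("p_branch", "p_ring", "p_double", "p_triple", "p_aromatic_ring"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.max_chain < 2:
            raise ValueError("max_chain must be >= 2")


_HALOGENS = ("F", "Cl", "Br", "I")


def _backbone_atom(rng: np.random.Generator, g: GrammarSpec) -> str:
    pool = [a for a in g.atoms if a not in _HALOGENS]
    # bias toward carbon backbones
    weights = np.array([3.0 if a == "C" else 1.0 for a in pool])
    return pool[int(rng.choice(len(pool), p=weights / weights.sum()))]


def _terminal_atom(rng: np.random.Generator, g: GrammarSpec) -> str:
    return g.atoms[int(rng.integers(len(g.atoms)))]


def _ring(rng: np.random.Generator, g: GrammarSpec, digit: int) -> str:
    label = str(digit) if digit <= 9 else f"%{digit:02d}"
    size = 6 if rng.random() < 0.5 else 5
    if size == 6 and rng.random() < g.p_aromatic_ring:
        return f"c{label}ccccc{label}"
    atoms = [_backbone_atom(rng, g) for _ in range(size)]
    return atoms[0] + label + "".join(atoms[1:-1]) + atoms[-1] + label


def _bond(rng: np.random.Generator, g: GrammarSpec) -> str:
    u = rng.random()
    if u < g.p_triple:
        return "#"
    if u < g.p_triple + g.p_double:
        return "="
    return ""


def _chain(
    rng: np.random.Generator, g: GrammarSpec, length: int, depth: int, ring_ids: list
) -> str:
    parts: list[str] = []
    for pos in range(length):
        if pos > 0:
            parts.append(_bond(rng, g))
        if depth == 0 and rng.random() < g.p_ring:
            ring_ids.append(len(ring_ids) + 1)
            parts.append(_ring(rng, g, ring_ids[-1]))
        else:
            parts.append(_backbone_atom(rng, g))
        if depth < 2 and pos < length - 1 and rng.random() < g.p_branch:
            if rng.random() < 0.4:
                parts.append("(" + _terminal_atom(rng, g) + ")")
            else:
                sub_len = int(rng.integers(1, 4))
                parts.append(
                    "(" + _chain(rng, g, sub_len, depth + 1, ring_ids) + ")"
                )
    # terminal halogen
    if rng.random() < 0.2:
        halo = [a for a in g.atoms if a in _HALOGENS]
        if halo:
            parts.append(halo[int(rng.integers(len(halo)))])
    return "".join(parts)


def generate_molecules(
    n: int, grammar: GrammarSpec | None = None, seed: int = 0
) -> list[str]:
    """Generate n syntactically valid SMILES strings, seed-deterministic."""
    if n < 1:
        raise ValueError("n must be >= 1")
    g = grammar or GrammarSpec()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        length = int(rng.integers(2, g.max_chain + 1))
        out.append(_chain(rng, g, length, 0, []))
    return out


@dataclass
class PlantedModel:
    """Hidden truth behind a synthetic dataset."""

    true_weights: CorrelationWeightTable
    intercept: float = 0.0
    slope: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.slope == 0:
            raise ValueError("slope must be non-zero")


def plant_weights(
    molecules: Sequence[str],
    dconf: DescriptorConfig | None = None,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> PlantedModel:
    """Draw uniform(−1, 1) true weights over the observed attribute universe."""
    if not molecules:
        raise ValueError("empty molecule list")
    dconf = dconf or DescriptorConfig()
    keys: set[str] = set()
    for s in molecules:
        keys |= set(extract_attributes(s, dconf))
    rng = np.random.default_rng(seed)
    ordered = sorted(keys)
    weights = {k: float(w) for k, w in zip(ordered, rng.uniform(-1, 1, len(ordered)))}
    return PlantedModel(
        CorrelationWeightTable(weights), intercept=0.0, slope=1.0, noise_sd=noise_sd
    )


def simulate_endpoint(
    molecules: Sequence[str],
    planted: PlantedModel,
    seed: int = 0,
    dconf: DescriptorConfig | None = None,
) -> Dataset:
    """Endpoint = intercept + slope·DCW(true weights) + Gaussian noise."""
    dconf = dconf or DescriptorConfig()
    signal = np.array(
        [planted.true_weights.dcw(extract_attributes(s, dconf)) for s in molecules]
    )
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, planted.noise_sd, len(molecules))
        if planted.noise_sd > 0
        else np.zeros(len(molecules))
    )
    y = planted.intercept + planted.slope * signal + noise
    ids = [f"mol{i+1}" for i in range(len(molecules))]
    return Dataset(ids, list(molecules), y)


def make_dataset(
    n: int = 250,
    seed: int = 7,
    noise_frac: float = 0.05,
    grammar: GrammarSpec | None = None,
    dconf: DescriptorConfig | None = None,
) -> tuple[Dataset, PlantedModel]:
    """Default harness: n molecules, noise_sd = noise_frac · sd(signal).

    Sub-seeds for generation, weight planting and noise are derived from
    ``seed`` (kept below 2^31).
    """
    dconf = dconf or DescriptorConfig()
    base = int(seed) % (2**31 - 10)
    molecules = generate_molecules(n, grammar, seed=base)
    planted = plant_weights(molecules, dconf, seed=base + 1)
    signal = np.array(
        [planted.true_weights.dcw(extract_attributes(s, dconf)) for s in molecules]
    )
    planted.noise_sd = float(noise_frac) * float(signal.std())
    dataset = simulate_endpoint(molecules, planted, seed=base + 2, dconf=dconf)
    return dataset, planted


def make_splits(
    dataset: Dataset,
    scheme: str = "random",
    fractions: Sequence[float] = (0.8, 0.2),
    seed: int = 0,
    set_names: Sequence[str] | None = None,
) -> dict[str, str]:
    """Assign molecules to training/validation(/calibration) sets.

    ``random`` is a seeded shuffle; ``striped`` sorts by endpoint and
    deals round-robin in proportion to the fractions, emulating a
    "rational" split whose sets share the endpoint distribution (the
    seed is accepted but unused for striped).
    """
    fractions = list(fractions)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if set_names is None:
        set_names = (
            ("training", "validation")
            if len(fractions) == 2
            else ("training", "calibration", "validation")
        )
    if len(set_names) != len(fractions):
        raise ValueError("one fraction per set name required")
    n = len(dataset)
    counts = [int(round(f * n)) for f in fractions]
    counts[0] += n - sum(counts)
    if any(c < 1 for c in counts):
        raise ValueError(f"fractions {fractions} leave an empty set for n={n}")

    if scheme == "random":
        rng = np.random.default_rng(seed)
        order = rng.permutation(n)
    elif scheme == "striped":
        order = np.argsort(dataset.endpoints, kind="stable")
    else:
        raise ValueError(f"unknown split scheme {scheme!r}")

    assignment: dict[str, str] = {}
    if scheme == "random":
        bounds = np.cumsum([0] + counts)
        for k, name in enumerate(set_names):
            for idx in order[bounds[k] : bounds[k + 1]]:
                assignment[dataset.ids[int(idx)]] = name
    else:
        # proportional striping over the endpoint-sorted order
        assigned = [0] * len(set_names)
        targets = [c / n for c in counts]
        for i, idx in enumerate(order):
            deficits = [
                targets[k] * (i + 1) - assigned[k] for k in range(len(set_names))
            ]
            k = int(np.argmax(deficits))
            assignment[dataset.ids[int(idx)]] = set_names[k]
            assigned[k] += 1
    return assignment
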