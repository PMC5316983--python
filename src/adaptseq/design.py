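"""Amplicon architecture of the staggered ssODN profiling library.

A library molecule is a 35-nt random region flanked by two fixed
primer-binding sites.  On the sequenced (forward) strand a read runs

    [stagger pad, 0-3 nt][variable region, 35 nt][constant anchor, 20 nt]
    [i7 index][P7 adapter ...]

The stagger pads (+1/+2/+3 variants) exist so that the low-diversity
constant region does not hit the sequencer in the same cycle for every
cluster.  The 20-nt constant anchor is the reverse-primer binding site and
is what defines a *valid* read: a read is valid iff the anchor is found,
within a small substitution tolerance, at an offset implying one of the
configured stagger lengths.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "FORWARD_PRIMER",
    "REVERSE_PRIMER",
    "P5_ADAPTER",
    "P7_ADAPTER",
    "LibraryDesign",
    "default_design",
    "make_index_set",
    "hamming",
]

DNA_ALPHABET = "ACGT"

#: 15-nt forward (5') primer-binding constant region.
FORWARD_PRIMER = "TCGTCGGCAGCGTCA"
#: 20-nt reverse primer-binding constant region; the demultiplexing anchor.
REVERSE_PRIMER = "CTAGCATGACTGCAGTACGT"
#: Flow-cell adapters contributed by the one-step index PCR primers.
P5_ADAPTER = "AATGATACGGCGACCACCGAGATCTAAC"
P7_ADAPTER = "CAAGCAGAAGACGGCATACGGAT"


def hamming(a: str, b: str) -> int:
    """Substitution distance between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: length mismatch ({len(a)} vs {len(b)})")
    return sum(x != y for x, y in zip(a, b))


def _check_dna(name: str, seq: str) -> None:
    if not seq or any(c not in DNA_ALPHABET for c in seq):
        raise ValueError(f"{name} must be a non-empty string over A/C/G/T, got {seq!r}")


@dataclass(frozen=True)
class LibraryDesign:
    """Printed amplicon design: primers, variable slot, staggers, indices.

    ``i7_indices`` maps sample_id -> index sequence; every index within one
    set must stay unique at the configured mismatch radius so that a read
    one substitution away from an index can still be assigned unambiguously.
    """

    forward_primer: str = FORWARD_PRIMER
    reverse_primer: str = REVERSE_PRIMER
    variable_length: int = 35
    stagger_offsets: frozenset[int] = frozenset({0, 1, 2, 3})
    i7_indices: dict[str, str] = field(default_factory=dict)
    i5_indices: dict[str, str] = field(default_factory=dict)
    p5_adapter: str = P5_ADAPTER
    p7_adapter: str = P7_ADAPTER
    index_mismatch_radius: int = 1

    def __post_init__(self) -> None:
        _check_dna("forward_primer", self.forward_primer)
        _check_dna("reverse_primer", self.reverse_primer)
        _check_dna("p5_adapter", self.p5_adapter)
        _check_dna("p7_adapter", self.p7_adapter)
        if self.variable_length <= 0:
            raise ValueError("variable_length must be positive")
        offsets = frozenset(int(o) for o in self.stagger_offsets)
        if not offsets or min(offsets) < 0:
            raise ValueError("stagger_offsets must be non-negative integers")
        object.__setattr__(self, "stagger_offsets", offsets)
        for pool in (self.i7_indices, self.i5_indices):
            self._validate_index_set(pool)

    def _validate_index_set(self, pool: dict[str, str]) -> None:
        items = list(pool.items())
        for _, idx in items:
            _check_dna("index", idx)
        lengths = {len(idx) for _, idx in items}
        if len(lengths) > 1:
            raise ValueError("all indices in one set must share a length")
        # uniqueness at the mismatch radius: min pairwise distance must exceed
        # 2*radius or assignment within the radius can be ambiguous
        for (sa, a), (sb, b) in itertools.combinations(items, 2):
            if hamming(a, b) <= 2 * self.index_mismatch_radius:
                raise ValueError(
                    f"indices for {sa!r} and {sb!r} collide at mismatch radius "
                    f"{self.index_mismatch_radius}: {a} vs {b}"
                )

    @property
    def anchor(self) -> str:
        """The constant region used for valid-read detection."""
        return self.reverse_primer

    @property
    def index_length(self) -> int:
        if not self.i7_indices:
            raise ValueError("design carries no i7 indices")
        return len(next(iter(self.i7_indices.values())))

    def min_read_length(self) -> int:
        """Shortest read that can hold pad + variable + anchor + index."""
        pad = max(self.stagger_offsets)
        idx = self.index_length if self.i7_indices else 0
        return pad + self.variable_length + len(self.anchor) + idx

    def with_indices(self, i7_indices: dict[str, str]) -> "LibraryDesign":
        return replace(self, i7_indices=dict(i7_indices))


def make_index_set(
    sample_ids: list[str],
    length: int = 8,
    min_distance: int = 3,
    seed: int = 7,
) -> dict[str, str]:
    """Greedy random i7 index set with pairwise Hamming >= ``min_distance``.

    min_distance 3 keeps single-mismatch demultiplexing unambiguous.
    """
    rng = np.random.default_rng(seed)
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < len(sample_ids):
        cand = "".join(rng.choice(list(DNA_ALPHABET), size=length))
        if all(hamming(cand, c) >= min_distance for c in chosen):
            chosen.append(cand)
        attempts += 1
        if attempts > 100_000:
            raise RuntimeError(
                f"could not place {len(sample_ids)} indices of length {length} "
                f"at distance {min_distance}"
            )
    return dict(zip(sample_ids, chosen))


def default_design(
    sample_ids: list[str] | None = None, index_seed: int = 7
) -> LibraryDesign:
    """The printed amplicon design: published primers/adapters, a 35-nt
    variable region and stagger offsets {0,1,2,3}.  Optionally attach a
    generated i7 index set for the given samples.  Deterministic."""
    design = LibraryDesign()
    if sample_ids:
        design = design.with_indices(make_index_set(sample_ids, seed=index_seed))
    return design
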