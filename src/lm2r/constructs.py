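"""Domain types for RNA constructs, helices, and mutant design.

Positions in the public API are 1-based, inclusive, *biological* numbering:
a :class:`Construct` carries a ``numbering_offset`` so that flanking
reference hairpins and primer tails can live outside the biologically
numbered region of interest (their labels may be zero or negative).
Internally sequences are ordinary 0-based Python strings; conversion
happens only at the attribute boundary.

Mutant design follows the conventions used for compensatory-rescue
(M2R) experiments: a *quartet* interrogates one candidate base pair with
the wild type, each single mutant, and the double mutant that restores
Watson-Crick pairing; a *lock* mutant swaps two consecutive base pairs
of a helix to the alternative Watson-Crick pairs, stabilizing the helix
while keeping it formable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

RNA_ALPHABET = frozenset("ACGU")

WC_COMPLEMENT = {"A": "U", "U": "A", "G": "C", "C": "G"}

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE_PAIRS = {("G", "U"), ("U", "G")}


def is_watson_crick(a: str, b: str) -> bool:
    return (a, b) in _WC_PAIRS


def can_pair(a: str, b: str) -> bool:
    """True for Watson-Crick (A-U, G-C) and wobble (G-U) combinations."""
    return (a, b) in _WC_PAIRS or (a, b) in _WOBBLE_PAIRS


class MutationError(ValueError):
    """A mutation specification conflicts with the construct sequence."""


@dataclass(frozen=True)
class Construct:
    """An RNA construct with biological numbering and reference annotations.

    Parameters
    ----------
    name:
        Identifier for the construct.
    sequence:
        RNA sequence over {A, C, G, U}, uppercase.
    numbering_offset:
        Biological label of the first nucleotide minus one; biological
        position ``p`` maps to 0-based index ``p - 1 - numbering_offset``.
    probed_region:
        Half-open ``(start, stop)`` interval of biological positions used
        in profile comparisons. Defaults to the whole sequence.
    reference_loops:
        Two position tuples (5' and 3' reference hairpin loops, e.g. the
        GAGUA pentaloops) used for normalization and attenuation
        correction. May be empty for constructs without flanking hairpins.
    """

    name: str
    sequence: str
    numbering_offset: int = 0
    probed_region: tuple[int, int] | None = None
    reference_loops: tuple[tuple[int, ...], tuple[int, ...]] = ((), ())

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence of {self.name!r} contains non-RNA symbols: {sorted(bad)}"
            )
        if self.probed_region is None:
            object.__setattr__(
                self, "probed_region", (self.first_position, self.last_position + 1)
            )
        start, stop = self.probed_region
        if not (self.first_position <= start < stop <= self.last_position + 1):
            raise ValueError(
                f"probed_region {self.probed_region} outside sequence bounds "
                f"[{self.first_position}, {self.last_position}]"
            )
        probed = set(range(start, stop))
        for loop in self.reference_loops:
            overlap = probed & set(loop)
            if overlap:
                raise ValueError(
                    f"reference loop positions {sorted(overlap)} overlap the probed region"
                )

    # -- numbering ---------------------------------------------------------

    @property
    def first_position(self) -> int:
        return 1 + self.numbering_offset

    @property
    def last_position(self) -> int:
        return len(self.sequence) + self.numbering_offset

    def index(self, position: int) -> int:
        """0-based sequence index of a biological position."""
        idx = position - 1 - self.numbering_offset
        if not 0 <= idx < len(self.sequence):
            raise IndexError(
                f"position {position} outside construct {self.name!r} "
                f"[{self.first_position}, {self.last_position}]"
            )
        return idx

    def base_at(self, position: int) -> str:
        return self.sequence[self.index(position)]

    def positions(self) -> range:
        return range(self.first_position, self.last_position + 1)

    def probed_positions(self) -> range:
        start, stop = self.probed_region
        return range(start, stop)


@dataclass(frozen=True, order=True)
class BasePair:
    """A candidate base pair (i, j), i < j, in biological numbering."""

    i: int
    j: int

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError(f"base pair requires i < j, got ({self.i}, {self.j})")

    def bases(self, construct: Construct) -> tuple[str, str]:
        return construct.base_at(self.i), construct.base_at(self.j)

    def is_paired_in(self, construct: Construct) -> bool:
        return can_pair(*self.bases(construct))


@dataclass(frozen=True)
class Helix:
    """An ordered run of stacked base pairs, e.g. P1 or P4B.

    Pairs must be consecutive and nested: i ascending by one, j
    descending by one.
    """

    name: str
    pairs: tuple[BasePair, ...]

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError(f"helix {self.name!r} must contain at least one pair")
        object.__setattr__(self, "pairs", tuple(self.pairs))
        for prev, nxt in zip(self.pairs, self.pairs[1:]):
            if nxt.i != prev.i + 1 or nxt.j != prev.j - 1:
                raise ValueError(
                    f"helix {self.name!r} pairs must be stacked: "
                    f"({prev.i},{prev.j}) followed by ({nxt.i},{nxt.j})"
                )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_bp(self) -> int:
        return len(self.pairs)

    @property
    def span(self) -> tuple[int, int]:
        return self.pairs[0].i, self.pairs[0].j


@dataclass(frozen=True)
class Substitution:
    position: int
    wt_base: str
    new_base: str

    def __post_init__(self) -> None:
        for b in (self.wt_base, self.new_base):
            if b not in RNA_ALPHABET:
                raise ValueError(f"invalid base {b!r}")
        if self.wt_base == self.new_base:
            raise ValueError(f"substitution at {self.position} does not change the base")

    @property
    def label(self) -> str:
        return f"{self.wt_base}{self.position}{self.new_base}"


@dataclass(frozen=True)
class MutantSpec:
    """A set of point substitutions with a canonical hyphen-joined label."""

    substitutions: tuple[Substitution, ...] = ()

    def __post_init__(self) -> None:
        subs = tuple(sorted(self.substitutions, key=lambda s: s.position))
        positions = [s.position for s in subs]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate substitution positions in {positions}")
        object.__setattr__(self, "substitutions", subs)

    @property
    def label(self) -> str:
        if not self.substitutions:
            return "WT"
        return "-".join(s.label for s in self.substitutions)

    @property
    def positions(self) -> tuple[int, ...]:
        return tuple(s.position for s in self.substitutions)

    def __add__(self, other: "MutantSpec") -> "MutantSpec":
        return MutantSpec(self.substitutions + other.substitutions)

    @classmethod
    def from_label(cls, label: str) -> "MutantSpec":
        """Parse a label like ``"A19U-U77A"`` (or ``"WT"``) back to a spec.

        Positions may be negative (nucleotides upstream of the
        biologically numbered region, e.g. in a flanking hairpin).
        """
        import re

        label = label.strip()
        if label in ("", "WT", "wt"):
            return cls(())
        token_re = r"[ACGU]-?\d+[ACGU]"
        if not re.fullmatch(f"{token_re}(-{token_re})*", label):
            raise ValueError(f"cannot parse mutant label {label!r}")
        subs = []
        for token in re.findall(token_re, label):
            subs.append(Substitution(int(token[1:-1]), token[0], token[-1]))
        return cls(tuple(subs))


def apply_mutations(construct: Construct, spec: MutantSpec) -> Construct:
    """Apply a mutant specification, checking wild-type bases first.

    The returned construct differs from the input at exactly the
    substituted positions; its name is suffixed with the mutant label.
    """
    seq = list(construct.sequence)
    for sub in spec.substitutions:
        idx = construct.index(sub.position)
        found = seq[idx]
        if found != sub.wt_base:
            raise MutationError(
                f"substitution {sub.label}: construct {construct.name!r} holds "
                f"{found!r} at position {sub.position}, expected {sub.wt_base!r}"
            )
        seq[idx] = sub.new_base
    name = construct.name if not spec.substitutions else f"{construct.name}:{spec.label}"
    return Construct(
        name=name,
        sequence="".join(seq),
        numbering_offset=construct.numbering_offset,
        probed_region=construct.probed_region,
        reference_loops=construct.reference_loops,
    )


def design_compensatory_quartet(
    construct: Construct, pair: BasePair
) -> tuple[MutantSpec, MutantSpec, MutantSpec]:
    """Design the (mutA, mutB, mutAB) specs interrogating one base pair.

    Each side of a Watson-Crick pair is flipped to its own complement
    (A<->U, G<->C): either single mutation abolishes pairing while the
    double mutation restores a Watson-Crick pair with strands swapped.
    For a G-U wobble the G is flipped to C (purine -> pyrimidine) and the
    U to G, so the double mutant forms a C-G Watson-Crick pair.
    """
    a, b = pair.bases(construct)
    if not can_pair(a, b):
        raise MutationError(
            f"positions ({pair.i}, {pair.j}) hold {a}-{b}, not a pairable combination"
        )
    if (a, b) in _WOBBLE_PAIRS:
        if a == "G":  # G(i)-U(j) -> C(i)-G(j)
            new_a, new_b = "C", "G"
        else:  # U(i)-G(j) -> G(i)-C(j)
            new_a, new_b = "G", "C"
    else:
        new_a, new_b = WC_COMPLEMENT[a], WC_COMPLEMENT[b]
    if not is_watson_crick(new_a, new_b):
        raise MutationError(
            f"designed double mutant {new_a}-{new_b} at ({pair.i}, {pair.j}) is not Watson-Crick"
        )
    mut_a = MutantSpec((Substitution(pair.i, a, new_a),))
    mut_b = MutantSpec((Substitution(pair.j, b, new_b),))
    return mut_a, mut_b, mut_a + mut_b


_TRANSVERSION_PAIR = {
    ("A", "U"): ("C", "G"),
    ("U", "A"): ("G", "C"),
    ("G", "C"): ("U", "A"),
    ("C", "G"): ("A", "U"),
}


def design_double_pair_lock(
    construct: Construct,
    helix: Helix,
    start_index: int = 0,
    style: str = "swap",
) -> MutantSpec:
    """Design a helix lock: two consecutive pairs switched to alternative
    Watson-Crick pairs.

    ``style="swap"`` (default) swaps the strands of each pair
    (A-U -> U-A, G-C -> C-G), the convention behind lock mutants such as
    lock-P1 (A19U-U20A-A76U-U77A). ``style="transversion"`` substitutes
    the other Watson-Crick pair class at both positions
    (A-U -> C-G, G-C -> U-A).
    """
    if start_index < 0 or start_index + 2 > len(helix.pairs):
        raise ValueError(
            f"helix {helix.name!r} has no two consecutive pairs at start_index {start_index}"
        )
    subs: list[Substitution] = []
    for pair in helix.pairs[start_index : start_index + 2]:
        a, b = pair.bases(construct)
        if not is_watson_crick(a, b):
            raise MutationError(
                f"lock design requires Watson-Crick pairs; ({pair.i},{pair.j}) holds {a}-{b}"
            )
        if style == "swap":
            new_a, new_b = b, a
        elif style == "transversion":
            new_a, new_b = _TRANSVERSION_PAIR[(a, b)]
        else:
            raise ValueError(f"unknown lock style {style!r}")
        subs.append(Substitution(pair.i, a, new_a))
        subs.append(Substitution(pair.j, b, new_b))
    return MutantSpec(tuple(subs))


def helix_from_span(name: str, i: int, j: int, n_bp: int) -> Helix:
    """Convenience constructor: an ``n_bp``-long helix whose outermost pair
    is (i, j)."""
    return Helix(name, tuple(BasePair(i + k, j - k) for k in range(n_bp)))
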