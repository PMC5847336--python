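"""Rescue-factor metric for compensatory-mutagenesis quartets.

A quartet of reactivity profiles (wild type, the two single mutants of a
candidate base pair, and the compensatory double mutant) is summarized
by a single rescue factor

    rescue = 1 - RMSD(WT, AB) / max(RMSD(WT, A), RMSD(WT, B))

where RMSD is the root-mean-square difference between two profiles over
the probed nucleotides. A factor of 1 means the double mutant restores
the wild-type profile exactly (full rescue); 0 means the double mutant
is as disrupted as the worse single mutant (no rescue); intermediate
values indicate partial rescue, the signature of a base pair present in
only part of the structural ensemble. Values below 0 (double mutant more
disrupted than either single) are retained, not clipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .constructs import BasePair, Helix
from .profiles_io import ReactivityProfile

logger = logging.getLogger(__name__)

#: Default category thresholds (no / partial / full rescue).
DEFAULT_THRESHOLDS = (0.2, 0.7)


class UninformativeQuartetError(ValueError):
    """Neither single mutant perturbs the profile: the rescue factor's
    denominator vanishes and the quartet carries no information."""


def profile_rmsd(
    a: ReactivityProfile | np.ndarray,
    b: ReactivityProfile | np.ndarray,
    positions: Sequence[int] | None = None,
) -> float:
    """Root-mean-square difference between two profiles.

    With :class:`ReactivityProfile` inputs, ``positions`` selects the
    biological positions compared (default: all positions of ``a``,
    which must be covered by ``b``). Plain arrays are compared
    elementwise.
    """
    if isinstance(a, ReactivityProfile):
        pos = list(positions) if positions is not None else a.positions.tolist()
        if not pos:
            raise ValueError("empty position set for RMSD")
        va = a.value_at(pos)
        vb = b.value_at(pos)
    else:
        va = np.asarray(a, float)
        vb = np.asarray(b, float)
        if positions is not None:
            va = va[np.asarray(positions)]
            vb = vb[np.asarray(positions)]
        if va.size == 0:
            raise ValueError("empty position set for RMSD")
        if va.shape != vb.shape:
            raise ValueError(f"profile shapes differ: {va.shape} vs {vb.shape}")
    return float(np.sqrt(np.mean((va - vb) ** 2)))


@dataclass(frozen=True)
class Quartet:
    """The four profiles interrogating one candidate base pair."""

    pair: BasePair
    wt: ReactivityProfile
    mut_a: ReactivityProfile
    mut_b: ReactivityProfile
    mut_ab: ReactivityProfile
    comparison_positions: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        shared = set(self.wt.positions.tolist())
        for prof in (self.mut_a, self.mut_b, self.mut_ab):
            shared &= set(prof.positions.tolist())
        if self.comparison_positions is None:
            object.__setattr__(self, "comparison_positions", tuple(sorted(shared)))
        missing = set(self.comparison_positions) - shared
        if missing:
            raise ValueError(
                f"comparison positions {sorted(missing)} not shared by all four profiles"
            )
        if not self.comparison_positions:
            raise ValueError("quartet has no shared comparison positions")

    def profiles(self) -> tuple[ReactivityProfile, ...]:
        return self.wt, self.mut_a, self.mut_b, self.mut_ab


def rescue_factor(
    q: Quartet,
    exclude_mutation_window: int | None = None,
    zero_tol: float = 1e-12,
) -> float:
    """Rescue factor of a quartet (unclipped; <= 1 by construction).

    By default the comparison spans all shared probed nucleotides,
    including the mutated positions themselves. Setting
    ``exclude_mutation_window=w`` drops positions within ``w`` of either
    mutated nucleotide before comparing.

    Raises
    ------
    UninformativeQuartetError
        If neither single mutant differs from the wild type on the
        comparison positions.
    """
    positions = list(q.comparison_positions)
    if exclude_mutation_window is not None:
        w = exclude_mutation_window
        excluded = {
            p
            for center in (q.pair.i, q.pair.j)
            for p in range(center - w, center + w + 1)
        }
        positions = [p for p in positions if p not in excluded]
        if not positions:
            raise ValueError("mutation-window exclusion removed every comparison position")
    rmsd_a = profile_rmsd(q.wt, q.mut_a, positions)
    rmsd_b = profile_rmsd(q.wt, q.mut_b, positions)
    denom = max(rmsd_a, rmsd_b)
    if denom <= zero_tol:
        raise UninformativeQuartetError(
            f"pair ({q.pair.i}, {q.pair.j}): neither single mutant perturbs the profile "
            f"(max single-mutant RMSD {denom:g})"
        )
    rmsd_ab = profile_rmsd(q.wt, q.mut_ab, positions)
    return 1.0 - rmsd_ab / denom


@dataclass(frozen=True)
class HelixRescueResult:
    """Per-pair rescue factors of a helix and their arithmetic mean."""

    helix: Helix
    per_pair_factors: dict[BasePair, float]
    skipped: tuple[BasePair, ...] = ()

    def __post_init__(self) -> None:
        if not self.per_pair_factors:
            raise ValueError(f"helix {self.helix.name!r}: no informative quartets")

    @property
    def mean_factor(self) -> float:
        return float(np.mean(list(self.per_pair_factors.values())))

    @property
    def n_pairs(self) -> int:
        return len(self.per_pair_factors)


def helix_rescue(
    helix: Helix,
    quartets: Mapping[BasePair, Quartet] | Sequence[Quartet],
    exclude_mutation_window: int | None = None,
) -> HelixRescueResult:
    """Aggregate per-pair rescue factors over a helix.

    Quartets flagged uninformative (flat single-mutant response) are
    skipped with a warning rather than poisoning the mean.
    """
    if not isinstance(quartets, Mapping):
        quartets = {q.pair: q for q in quartets}
    if not quartets:
        raise ValueError(f"helix {helix.name!r}: no quartets supplied")
    factors: dict[BasePair, float] = {}
    skipped: list[BasePair] = []
    for pair, q in quartets.items():
        try:
            factors[pair] = rescue_factor(q, exclude_mutation_window)
        except UninformativeQuartetError as exc:
            logger.warning("helix %s: skipping uninformative quartet: %s", helix.name, exc)
            skipped.append(pair)
    return HelixRescueResult(helix=helix, per_pair_factors=factors, skipped=tuple(skipped))


def classify_rescue(
    factor: float, thresholds: tuple[float, float] = DEFAULT_THRESHOLDS
) -> str:
    """Classify a rescue factor as ``"no"``, ``"partial"`` or ``"full"``.

    Thresholds default to (0.2, 0.7); they are qualitative reporting
    conveniences, not part of the quantitative inference chain.
    """
    t_low, t_high = thresholds
    if not 0 < t_low < t_high < 1:
        raise ValueError(f"thresholds must satisfy 0 < low < high < 1, got {thresholds}")
    if factor < t_low:
        return "no"
    if factor >= t_high:
        return "full"
    return "partial"
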