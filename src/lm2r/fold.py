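"""Secondary-structure partition-function backends.

Base-pair probability (BPP) matrices drive the in-silico
mutate-map-rescue simulations. Two backends are provided behind one
interface:

* :class:`ReferenceBackend` — a self-contained McCaskill-style dynamic
  program over a minimal additive base-pair energy model (G-C, A-U and
  G-U pair energies, minimum hairpin loop of 3). It has no external
  dependencies and is exactly verifiable against brute-force Boltzmann
  enumeration for short sequences.
* :class:`ViennaBackend` — the ViennaRNA (RNAlib) equilibrium partition
  function with Turner energies, the production choice for realistic
  calibration runs.

:func:`enumerate_bpp` enumerates every secondary structure of a short
sequence and Boltzmann-averages the pair indicators under the same
simple energy model; it is the independent oracle for the reference
backend, not a backend itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator

import numpy as np

from .constructs import can_pair

#: Gas constant in kcal/(mol*K).
_R = 0.0019872


@dataclass(frozen=True)
class PairEnergyModel:
    """Additive per-pair energy model (kcal/mol) with a hairpin-loop floor.

    Stabilities follow the usual ordering G-C < A-U < G-U; defaults are
    round numbers chosen for a well-conditioned toy ensemble, not fitted
    nearest-neighbor parameters.
    """

    gc: float = -3.0
    au: float = -2.0
    gu: float = -1.0
    min_hairpin: int = 3
    temperature: float = 37.0

    @property
    def rt(self) -> float:
        return _R * (self.temperature + 273.15)

    def pair_energy(self, a: str, b: str) -> float | None:
        key = frozenset((a, b))
        if key == frozenset("GC"):
            return self.gc
        if key == frozenset("AU"):
            return self.au
        if key == frozenset("GU"):
            return self.gu
        return None

    def boltzmann_weight(self, a: str, b: str) -> float:
        e = self.pair_energy(a, b)
        return 0.0 if e is None else float(np.exp(-e / self.rt))


@dataclass(frozen=True)
class BasePairProbabilityMatrix:
    """Symmetric matrix of equilibrium base-pairing probabilities.

    ``p[i, j]`` is the probability (0-based indices) that nucleotides i
    and j are paired with each other; row sums never exceed 1 because a
    nucleotide pairs with at most one partner in any structure.
    """

    sequence_ref: str
    sequence: str
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        n = len(self.sequence)
        if p.shape != (n, n):
            raise ValueError(f"BPP matrix shape {p.shape} does not match sequence length {n}")
        if not np.allclose(p, p.T, atol=1e-12):
            raise ValueError("BPP matrix must be symmetric")
        if p.min() < -1e-12 or p.max() > 1 + 1e-9:
            raise ValueError("BPP entries must lie in [0, 1]")
        if (p.sum(axis=1) > 1 + 1e-6).any():
            raise ValueError("BPP row sums exceed 1")
        object.__setattr__(self, "p", p)

    def __len__(self) -> int:
        return len(self.sequence)

    def pair_probability(self, i: int, j: int) -> float:
        """Probability of the pair at 1-based positions (i, j)."""
        return float(self.p[i - 1, j - 1])

    def unpaired_probability(self) -> np.ndarray:
        """Per-position probability of being unpaired, in [0, 1]."""
        return np.clip(1.0 - self.p.sum(axis=1), 0.0, 1.0)


class FoldBackend:
    """Contract: deterministic map from a sequence to its BPP matrix."""

    name: str = "abstract"
    temperature: float = 37.0

    def fold(self, sequence: str, name: str = "seq") -> BasePairProbabilityMatrix:
        raise NotImplementedError

    def __repr__(self) -> str:
        return f"<{type(self).__name__} T={self.temperature:g}C>"


def _pair_weight_matrix(sequence: str, model: PairEnergyModel) -> np.ndarray:
    n = len(sequence)
    q = np.zeros((n, n))
    for i in range(n):
        for j in range(i + model.min_hairpin + 1, n):
            q[i, j] = model.boltzmann_weight(sequence[i], sequence[j])
    return q


class ReferenceBackend(FoldBackend):
    """Bundled McCaskill inside-outside partition function.

    Runs the classic O(n^3) inside recursion and an O(n^4) outside
    recursion restricted to pairable cells, with a uniform per-nucleotide
    rescaling factor to keep partition functions in floating-point range.
    Intended for tests, fixtures and moderate lengths (couple hundred nt);
    use :class:`ViennaBackend` for production calibration runs.
    """

    name = "reference"

    def __init__(self, model: PairEnergyModel | None = None, scale: float = 2.0):
        self.model = model or PairEnergyModel()
        self.temperature = self.model.temperature
        self._scale = scale

    def fold(self, sequence: str, name: str = "seq") -> BasePairProbabilityMatrix:
        sequence = sequence.upper().replace("T", "U")
        n = len(sequence)
        if n < 2:
            raise ValueError("sequence too short to fold")
        inv_s = 1.0 / self._scale
        q = _pair_weight_matrix(sequence, self.model) * inv_s * inv_s

        # Inside: Z[i, j] = partition function of segment i..j (scaled by
        # s^-(j-i+1)); Z over empty segments is 1. Padded by one row/col so
        # Z[i+1, k-1] is well-formed at segment edges.
        Z = np.zeros((n + 1, n + 1))
        for i in range(n + 1):
            for j in range(i):  # empty segments
                Z[i, j] = 1.0
        for i in range(n):
            Z[i, i] = inv_s
        for span in range(2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span - 1
                total = Z[i + 1, j] * inv_s
                ks = np.nonzero(q[i, i + 1 : j + 1])[0] + i + 1
                if ks.size:
                    inner = Z[i + 1, ks - 1]
                    outer = np.array([Z[k + 1, j] for k in ks])
                    total += float(np.dot(q[i, ks] * inner, outer))
                Z[i, j] = total

        def zin(a: int, b: int) -> float:
            if b < a:
                return 1.0
            return Z[a, b]

        # Outside: zhat[i, j] = exterior partition function given (i, j)
        # paired, excluding the pair's own weight. Processed by decreasing
        # span so enclosing cells are ready.
        pairable = [(i, j) for i in range(n) for j in range(i + 1, n) if q[i, j] > 0]
        pairable.sort(key=lambda ij: ij[1] - ij[0], reverse=True)
        zhat = np.zeros((n, n))
        qh = np.zeros((n, n))  # q * zhat, the recurring product
        for i, j in pairable:
            total = zin(0, i - 1) * zin(j + 1, n - 1)
            if i > 0 and j < n - 1:
                block = qh[0:i, j + 1 : n]
                if block.any():
                    left = np.array([zin(k + 1, i - 1) for k in range(i)])
                    right = np.array([zin(j + 1, l - 1) for l in range(j + 1, n)])
                    total += float(left @ block @ right)
            zhat[i, j] = total
            qh[i, j] = q[i, j] * total

        z_total = Z[0, n - 1]
        p = np.zeros((n, n))
        for i, j in pairable:
            p[i, j] = q[i, j] * zin(i + 1, j - 1) * zhat[i, j] / z_total
        p = p + p.T
        return BasePairProbabilityMatrix(sequence_ref=name, sequence=sequence, p=p)


class ViennaBackend(FoldBackend):
    """ViennaRNA equilibrium base-pair probabilities (Turner energies)."""

    name = "vienna"

    def __init__(self, temperature: float = 37.0):
        self.temperature = temperature

    def fold(self, sequence: str, name: str = "seq") -> BasePairProbabilityMatrix:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise RuntimeError(
                "ViennaRNA Python bindings not available; use ReferenceBackend"
            ) from exc
        sequence = sequence.upper().replace("T", "U")
        md = RNA.md()
        md.temperature = self.temperature
        fc = RNA.fold_compound(sequence, md)
        _, mfe = fc.mfe()
        fc.exp_params_rescale(mfe)
        fc.pf()
        upper = np.array(fc.bpp())[1:, 1:]  # drop 1-based padding
        p = upper + upper.T
        return BasePairProbabilityMatrix(sequence_ref=name, sequence=sequence, p=p)


def get_backend(name: str, temperature: float = 37.0) -> FoldBackend:
    if name == "reference":
        return ReferenceBackend(PairEnergyModel(temperature=temperature))
    if name == "vienna":
        return ViennaBackend(temperature=temperature)
    raise ValueError(f"unknown fold backend {name!r}")


# ---------------------------------------------------------------------------
# Brute-force Boltzmann enumeration (independent oracle)
# ---------------------------------------------------------------------------


def enumerate_structures(
    sequence: str, model: PairEnergyModel | None = None
) -> Iterator[tuple[frozenset[tuple[int, int]], float]]:
    """Yield every secondary structure (as a set of 0-based pairs) with its
    Boltzmann weight under the simple pair-energy model.

    Enumeration is exhaustive and exponential; intended for sequences of
    a couple dozen nucleotides at most.
    """
    model = model or PairEnergyModel()
    n = len(sequence)
    weights = _pair_weight_matrix(sequence, model)

    def recurse(i: int, j: int) -> list[tuple[tuple[tuple[int, int], ...], float]]:
        # all structures of segment i..j as (pairs, weight)
        if j - i < model.min_hairpin + 1:
            return [((), 1.0)]
        out = list(recurse(i + 1, j))  # i unpaired
        for k in range(i + model.min_hairpin + 1, j + 1):
            w = weights[i, k]
            if w == 0.0:
                continue
            for inner_pairs, inner_w in recurse(i + 1, k - 1):
                for outer_pairs, outer_w in recurse(k + 1, j):
                    out.append((((i, k),) + inner_pairs + outer_pairs, w * inner_w * outer_w))
        return out

    for pairs, weight in recurse(0, n - 1):
        yield frozenset(pairs), weight


def enumerate_bpp(
    sequence: str, model: PairEnergyModel | None = None, name: str = "seq"
) -> BasePairProbabilityMatrix:
    """Exact BPP matrix by exhaustive structure enumeration."""
    sequence = sequence.upper().replace("T", "U")
    n = len(sequence)
    z = 0.0
    acc = np.zeros((n, n))
    for pairs, weight in enumerate_structures(sequence, model):
        z += weight
        for i, j in pairs:
            acc[i, j] += weight
    p = acc / z
    p = p + p.T
    return BasePairProbabilityMatrix(sequence_ref=name, sequence=sequence, p=p)
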