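"""Ground-truth synthetic fixtures: toy structural ensembles, reactivity
quartets, calibration tables, and the bundled riboswitch construct.

A :class:`ToyEnsemble` is a mixture of explicit secondary structures
(dot-bracket) over one sequence with known mixture weights — the ground
truth that every downstream stage is tested against. Reactivity is
generated as the weighted probability-unpaired indicator plus additive
Gaussian noise, mimicking a normalized chemical-mapping profile.

Mutant response is structure-aware: a mutation breaks every structure in
which a mutated nucleotide is paired with a now-incompatible partner,
and broken structures rearrange to the most populated surviving
structure (preferring ones without the probed pair). This reproduces the
partial-rescue phenomenology: a compensatory double mutant restores
structures carrying the probed pair but rearranges competing structures
that used the same nucleotides elsewhere.

The calibration-fixture family is a three-state motif — a target helix
X:Y, a decoy register Y:Z sharing the Y strand, and an open state — so
the rescue factor interpolates smoothly between 0 (helix absent) and 1
(helix always present) as the true helix frequency varies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import CALIBRATION_COLUMNS, CalibrationSample
from .constructs import (
    BasePair,
    Construct,
    Helix,
    MutantSpec,
    WC_COMPLEMENT,
    apply_mutations,
    can_pair,
    design_compensatory_quartet,
)
from .profiles_io import RdatFile, ReactivityProfile
from .rescue import HelixRescueResult, Quartet, helix_rescue

DEFAULT_NOISE_SD = 0.1


def dotbracket_pairs(structure: str, first_position: int = 1) -> frozenset[tuple[int, int]]:
    """Base pairs (biological positions) of a dot-bracket string."""
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for k, ch in enumerate(structure):
        if ch == "(":
            stack.append(k)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at column {k} in {structure!r}")
            i = stack.pop()
            pairs.add((i + first_position, k + first_position))
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket symbol {ch!r}")
    if stack:
        raise ValueError(f"unbalanced '(' in {structure!r}")
    return frozenset(pairs)


@dataclass(frozen=True)
class ToyEnsemble:
    """A discrete structural ensemble with known mixture weights."""

    construct: Construct
    structures: tuple[str, ...]
    weights: tuple[float, ...]
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.structures) != len(self.weights):
            raise ValueError("one weight per structure required")
        w = np.asarray(self.weights, float)
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {w.sum()}")
        n = len(self.construct.sequence)
        for db in self.structures:
            if len(db) != n:
                raise ValueError(f"structure length {len(db)} != sequence length {n}")
            for i, j in dotbracket_pairs(db, self.construct.first_position):
                a, b = self.construct.base_at(i), self.construct.base_at(j)
                if not can_pair(a, b):
                    raise ValueError(
                        f"structure pairs unpairable bases {a}{i}-{b}{j} in {db!r}"
                    )
        object.__setattr__(self, "structures", tuple(self.structures))
        object.__setattr__(self, "weights", tuple(float(x) for x in w))

    @property
    def pair_sets(self) -> tuple[frozenset[tuple[int, int]], ...]:
        fp = self.construct.first_position
        return tuple(dotbracket_pairs(db, fp) for db in self.structures)

    def unpaired_indicators(self) -> np.ndarray:
        """(n_structures, n_positions) binary matrix: 1 where unpaired."""
        n = len(self.construct.sequence)
        fp = self.construct.first_position
        out = np.ones((len(self.structures), n))
        for k, pairs in enumerate(self.pair_sets):
            for i, j in pairs:
                out[k, i - fp] = 0.0
                out[k, j - fp] = 0.0
        return out

    def frequency_of(self, item: BasePair | Helix) -> float:
        """True ensemble frequency of a base pair or a whole helix."""
        pairs = (
            {(item.i, item.j)}
            if isinstance(item, BasePair)
            else {(p.i, p.j) for p in item.pairs}
        )
        return float(
            sum(w for w, ps in zip(self.weights, self.pair_sets) if pairs <= ps)
        )

    def conditioned_on(self, item: BasePair | Helix) -> "ToyEnsemble":
        """Ensemble locked on a helix: weight renormalized onto structures
        containing it (others kept at weight zero so they remain probeable)."""
        pairs = (
            {(item.i, item.j)}
            if isinstance(item, BasePair)
            else {(p.i, p.j) for p in item.pairs}
        )
        mask = np.array([pairs <= ps for ps in self.pair_sets])
        w = np.asarray(self.weights, float) * mask
        if w.sum() <= 0:
            raise ValueError("cannot condition on an element absent from the ensemble")
        return replace(self, weights=tuple(w / w.sum()))


def ensemble_profile(
    ensemble: ToyEnsemble,
    weights: Sequence[float] | None = None,
    mutant_label: str = "WT",
    rng: np.random.Generator | None = None,
) -> ReactivityProfile:
    """Simulated reactivity: weighted unpaired fraction plus noise, >= 0."""
    if rng is None:
        rng = np.random.default_rng(ensemble.seed)
    w = np.asarray(weights if weights is not None else ensemble.weights, float)
    clean = w @ ensemble.unpaired_indicators()
    noise = rng.normal(0.0, ensemble.noise_sd, size=clean.shape) if ensemble.noise_sd > 0 else 0.0
    values = np.clip(clean + noise, 0.0, None)
    return ReactivityProfile(
        construct_ref=ensemble.construct.name,
        mutant_label=mutant_label,
        positions=np.array(list(ensemble.construct.positions())),
        values=values,
        modifier="synthetic",
    )


def _mutant_weights(
    ensemble: ToyEnsemble,
    spec: MutantSpec,
    probed_pair: BasePair,
    response_model: str = "rearrange",
) -> np.ndarray:
    """Redistribute ensemble weight after a mutation.

    A structure breaks when any mutated position is paired to a partner
    it can no longer form a Watson-Crick/G-U pair with (partner bases are
    evaluated after the same mutation). Broken weight rearranges to
    intact structures — the most populated one under ``"rearrange"``,
    spread evenly under ``"uniform"`` — preferring structures without the
    probed pair, since the probed positions were just perturbed. If no
    structure survives, the weight melts into an open (fully unpaired)
    pseudo-structure appended as a final component.
    """
    mutant = apply_mutations(ensemble.construct, spec)
    probed = (probed_pair.i, probed_pair.j)
    pair_sets = ensemble.pair_sets
    broken = np.zeros(len(pair_sets), dtype=bool)
    for k, pairs in enumerate(pair_sets):
        for i, j in pairs:
            if i in spec.positions or j in spec.positions:
                if not can_pair(mutant.base_at(i), mutant.base_at(j)):
                    broken[k] = True
                    break
    w = np.asarray(ensemble.weights, float)
    out = np.append(w * ~broken, 0.0)  # final slot: open pseudo-structure
    lost = float(w[broken].sum())
    if lost > 0:
        intact = [k for k in range(len(pair_sets)) if not broken[k]]
        without_pair = [k for k in intact if probed not in pair_sets[k]]
        targets = without_pair or intact
        if not targets:
            out[-1] += lost
        elif response_model == "rearrange":
            best = max(targets, key=lambda k: (w[k], -k))
            out[best] += lost
        elif response_model == "uniform":
            out[np.array(targets)] += lost / len(targets)
        else:
            raise ValueError(f"unknown response model {response_model!r}")
    return out


@dataclass(frozen=True)
class QuartetFixture:
    """A synthetic quartet with its ground truth attached."""

    quartet: Quartet
    true_frequency: float
    specs: tuple[MutantSpec, MutantSpec, MutantSpec]


def make_quartet_fixture(
    ensemble: ToyEnsemble,
    pair: BasePair,
    response_model: str = "rearrange",
    rng: np.random.Generator | None = None,
) -> QuartetFixture:
    """Generate the four profiles interrogating one base pair of a toy
    ensemble, with the true pair frequency recorded alongside.

    The pair must be carried by at least one structure of the ensemble
    (possibly at weight zero, e.g. after locking a mutually exclusive
    helix).
    """
    probed = (pair.i, pair.j)
    if not any(probed in ps for ps in ensemble.pair_sets):
        raise ValueError(
            f"pair ({pair.i}, {pair.j}) is absent from every structure of the ensemble"
        )
    if rng is None:
        rng = np.random.default_rng(ensemble.seed)
    mut_a, mut_b, mut_ab = design_compensatory_quartet(ensemble.construct, pair)
    indicators = np.vstack(
        [ensemble.unpaired_indicators(), np.ones(len(ensemble.construct.sequence))]
    )
    wt_w = np.append(np.asarray(ensemble.weights, float), 0.0)
    profiles = {}
    for label, spec, weights in (
        ("WT", None, wt_w),
        (mut_a.label, mut_a, _mutant_weights(ensemble, mut_a, pair, response_model)),
        (mut_b.label, mut_b, _mutant_weights(ensemble, mut_b, pair, response_model)),
        (mut_ab.label, mut_ab, _mutant_weights(ensemble, mut_ab, pair, response_model)),
    ):
        clean = weights @ indicators
        noise = (
            rng.normal(0.0, ensemble.noise_sd, size=clean.shape)
            if ensemble.noise_sd > 0
            else 0.0
        )
        profiles[label] = ReactivityProfile(
            construct_ref=ensemble.construct.name,
            mutant_label=label,
            positions=np.array(list(ensemble.construct.positions())),
            values=np.clip(clean + noise, 0.0, None),
            modifier="synthetic",
        )
    quartet = Quartet(
        pair=pair,
        wt=profiles["WT"],
        mut_a=profiles[mut_a.label],
        mut_b=profiles[mut_b.label],
        mut_ab=profiles[mut_ab.label],
    )
    return QuartetFixture(
        quartet=quartet,
        true_frequency=ensemble.frequency_of(pair),
        specs=(mut_a, mut_b, mut_ab),
    )


def helix_quartets(
    ensemble: ToyEnsemble,
    helix: Helix,
    response_model: str = "rearrange",
    rng: np.random.Generator | None = None,
) -> dict[BasePair, Quartet]:
    """One quartet fixture per base pair of a helix."""
    if rng is None:
        rng = np.random.default_rng(ensemble.seed)
    return {
        pair: make_quartet_fixture(ensemble, pair, response_model, rng=rng).quartet
        for pair in helix.pairs
    }


def observe_helix(
    ensemble: ToyEnsemble, helix: Helix, rng: np.random.Generator | None = None
) -> HelixRescueResult:
    """Simulated M2R experiment: rescue factors for every pair of a helix."""
    return helix_rescue(helix, helix_quartets(ensemble, helix, rng=rng))


# ---------------------------------------------------------------------------
# Toy-ensemble families
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGU"))


def _random_strand(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _revcomp(s: str) -> str:
    return "".join(WC_COMPLEMENT[c] for c in reversed(s))


def three_state_ensemble(
    n_bp: int,
    frequency: float,
    decoy_share: float = 0.7,
    loop: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[ToyEnsemble, Helix]:
    """The calibration motif: target helix X:Y, decoy Y:Z, open state.

    The target helix (``n_bp`` pairs) forms with probability
    ``frequency``; the remaining weight splits between a decoy structure
    that sequesters the Y strand elsewhere (share ``decoy_share``) and a
    fully open state. Because Y is shared, single and double mutants on
    the target pair also perturb the decoy, producing the partial-rescue
    signature at intermediate frequencies.
    """
    if not 0.0 <= frequency <= 1.0:
        raise ValueError("frequency must be in [0, 1]")
    rng = np.random.default_rng(seed)
    x = _random_strand(rng, n_bp)
    y = _revcomp(x)
    z = _revcomp(y)
    seq = x + "A" * loop + y + "A" * loop + z
    n = len(seq)
    s_open = "." * n
    s1 = "(" * n_bp + "." * loop + ")" * n_bp + "." * (loop + n_bp)
    s2 = "." * (n_bp + loop) + "(" * n_bp + "." * loop + ")" * n_bp
    construct = Construct(name=f"toy{seed}", sequence=seq)
    w1 = frequency
    w2 = decoy_share * (1 - frequency)
    w3 = (1 - decoy_share) * (1 - frequency)
    ensemble = ToyEnsemble(
        construct=construct,
        structures=(s1, s2, s_open),
        weights=(w1, w2, w3),
        noise_sd=noise_sd,
        seed=seed,
    )
    helix = Helix("target", tuple(BasePair(i + 1, n_bp + loop + n_bp - i) for i in range(n_bp)))
    return ensemble, helix


def anticorrelated_ensemble(
    n_bp: int = 4,
    f1: float = 0.5,
    f2: float = 0.35,
    loop: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[ToyEnsemble, Helix, Helix]:
    """Two mutually exclusive helices sharing the Y strand (true g = 0).

    Helix 1 (X:Y) and helix 2 (Y:Z) can never co-occur; their true
    frequencies are ``f1`` and ``f2`` with the rest of the weight open.
    """
    ensemble, h1 = three_state_ensemble(
        n_bp, f1, decoy_share=f2 / (1 - f1), loop=loop, noise_sd=noise_sd, seed=seed
    )
    n = len(ensemble.construct.sequence)
    h2 = Helix(
        "decoy",
        tuple(BasePair(n_bp + loop + 1 + k, n - k) for k in range(n_bp)),
    )
    return ensemble, h1, h2


def correlated_ensemble(
    n_bp: int = 4,
    f1: float = 0.5,
    f2: float = 0.5,
    g: float = 1.0,
    decoy_share: float = 0.7,
    loop: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[ToyEnsemble, Helix, Helix]:
    """Two helix modules with a prescribed true correlation value g.

    Each module is a three-state motif (target, decoy, open) on its own
    nucleotides. The joint distribution over the 3x3 state combinations
    preserves the marginal frequencies ``f1`` and ``f2`` while setting
    the joint target-target weight to ``g * f1 * f2``: g = 1 gives the
    product (independent) ensemble, g < 1 partial mutual exclusion. The
    requested g must keep all nine weights non-negative.
    """
    rng = np.random.default_rng(seed)
    modules = []
    for freq in (f1, f2):
        x = _random_strand(rng, n_bp)
        y = _revcomp(x)
        z = _revcomp(y)
        seq = x + "A" * loop + y + "A" * loop + z + "A" * loop
        target = "(" * n_bp + "." * loop + ")" * n_bp + "." * (loop + n_bp + loop)
        decoy = "." * (n_bp + loop) + "(" * n_bp + "." * loop + ")" * n_bp + "." * loop
        opened = "." * len(seq)
        w = np.array([freq, decoy_share * (1 - freq), (1 - decoy_share) * (1 - freq)])
        modules.append((seq, (target, decoy, opened), w))
    (seq1, dbs1, m1), (seq2, dbs2, m2) = modules
    # rank-one tilt preserving both marginals; a and b sum to zero
    delta = (g - 1.0) * f1 * f2
    a = np.array([1.0, -m1[1] / (1 - f1), -m1[2] / (1 - f1)])
    b = np.array([1.0, -m2[1] / (1 - f2), -m2[2] / (1 - f2)])
    joint = np.outer(m1, m2) + delta * np.outer(a, b)
    if joint.min() < -1e-12:
        raise ValueError(f"correlation g={g} infeasible for marginals ({f1}, {f2})")
    joint = np.clip(joint, 0.0, None)
    joint /= joint.sum()
    off = len(seq1)
    structures = [db1 + db2 for db1 in dbs1 for db2 in dbs2]
    weights = tuple(joint.ravel())
    construct = Construct(name=f"duo{seed}", sequence=seq1 + seq2)
    ensemble = ToyEnsemble(
        construct=construct,
        structures=tuple(structures),
        weights=weights,
        noise_sd=noise_sd,
        seed=seed,
    )
    h1 = Helix("mod1", tuple(BasePair(1 + k, 2 * n_bp + loop - k) for k in range(n_bp)))
    h2 = Helix(
        "mod2", tuple(BasePair(off + 1 + k, off + 2 * n_bp + loop - k) for k in range(n_bp))
    )
    return ensemble, h1, h2


def independent_ensemble(
    n_bp: int = 4,
    f1: float = 0.5,
    f2: float = 0.5,
    decoy_share: float = 0.7,
    loop: int = 4,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int = 0,
) -> tuple[ToyEnsemble, Helix, Helix]:
    """Two structurally independent helix modules (true g = 1)."""
    return correlated_ensemble(
        n_bp, f1, f2, g=1.0, decoy_share=decoy_share, loop=loop,
        noise_sd=noise_sd, seed=seed,
    )


def make_calibration_fixture(
    n_helices: int = 150,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
    n_bp_range: tuple[int, int] = (3, 6),
) -> pd.DataFrame:
    """Deterministic toy calibration table with known true frequencies.

    ``n_helices`` three-state ensembles are generated with true helix
    frequencies sweeping 0.05-0.95 (with seeded jitter), base-pair counts
    cycling over ``n_bp_range``, and per-pair quartets evaluated through
    the rescue metric. The ``frequency`` column holds the *true* mixture
    weight, so the table doubles as its own ground-truth map.
    """
    if n_helices < 1:
        raise ValueError("n_helices must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = n_bp_range
    rows = []
    grid = np.linspace(0.05, 0.95, 19)
    for k in range(n_helices):
        freq = float(np.clip(grid[k % len(grid)] + rng.uniform(-0.02, 0.02), 0.02, 0.98))
        n_bp = lo + k % (hi - lo + 1)
        decoy_share = float(rng.uniform(0.5, 0.9))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        ensemble, helix = three_state_ensemble(
            n_bp, freq, decoy_share=decoy_share, noise_sd=noise_sd, seed=sub_seed
        )
        result = observe_helix(ensemble, helix)
        rows.append(
            CalibrationSample(
                family=f"toy{k}",
                helix_i=helix.pairs[0].i,
                helix_j=helix.pairs[0].j,
                n_bp=n_bp,
                rescue_factor=result.mean_factor,
                frequency=freq,
            )
        )
    df = pd.DataFrame([asdict(r) for r in rows], columns=CALIBRATION_COLUMNS)
    df.attrs["provenance"] = {
        "backend": "toy-ensembles",
        "seed": seed,
        "noise_sd": noise_sd,
        "n_helices": n_helices,
    }
    return df


def random_rna_sequences(
    n: int,
    length_range: tuple[int, int] = (100, 250),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Seeded uniform-random RNA sequences standing in for a family
    screen (synthetic substitute for a curated alignment database)."""
    rng = np.random.default_rng(seed)
    out = []
    for k in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        out.append((f"rand{k:03d}", _random_strand(rng, length)))
    return out


# ---------------------------------------------------------------------------
# Bundled probed construct
# ---------------------------------------------------------------------------


def quartet_to_rdat(fixture: QuartetFixture, construct: Construct, name: str | None = None) -> RdatFile:
    """Package a quartet fixture as an RDAT dataset (WT + three mutants)."""
    return RdatFile(
        name=name or construct.name,
        sequence=construct.sequence,
        offset=construct.numbering_offset,
        profiles=list(fixture.quartet.profiles()),
        comments=[f"synthetic quartet fixture; true frequency {fixture.true_frequency:g}"],
    )


def add_construct() -> tuple[Construct, dict[str, Helix], dict[str, str]]:
    """The bundled 198-nt adenine-riboswitch probed construct.

    Returns the construct (with GAGUA reference-loop annotations and
    riboswitch biological numbering), the helix registries implied by
    the published lock-mutant designs, and the printed lock/stabilizer
    mutant labels.
    """
    data = resources.files("lm2r.data")
    fasta = (data / "add_construct.fasta").read_text().splitlines()
    seq = "".join(line.strip() for line in fasta if not line.startswith(">"))
    meta = json.loads((data / "add_construct.json").read_text())
    construct = Construct(
        name=meta["name"],
        sequence=seq,
        numbering_offset=meta["numbering_offset"],
        probed_region=tuple(meta["probed_region"]),
        reference_loops=(
            tuple(meta["reference_loops"][0]),
            tuple(meta["reference_loops"][1]),
        ),
    )
    helices = {
        name: Helix(name, tuple(BasePair(i, j) for i, j in pairs))
        for name, pairs in meta["helices"].items()
    }
    return construct, helices, dict(meta["lock_mutants"])
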