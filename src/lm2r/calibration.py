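"""In-silico mutate-map-rescue simulation and calibration tables.

The quantitative link between an observed rescue factor and the
underlying helix frequency is established by simulation: candidate
helices are screened from the base-pair probability (BPP) matrix of each
calibration sequence, every base pair of each helix is subjected to an
in-silico compensatory quartet (wild type, two single mutants, double
mutant, all folded with the same backend), and the helix's mean
simulated rescue factor is recorded next to its mean BPP — the simulated
helix frequency. The resulting table of (base-pair count, rescue factor,
frequency) samples is the calibration prior used by
:mod:`lm2r.bayes`.

Simulated reactivity is the probability of being unpaired
(1 minus the BPP row sum): chemical probes acylate flexible, unpaired
nucleotides, and the probability-unpaired profile is the deterministic,
noise-free limit of such a measurement.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .constructs import (
    BasePair,
    Construct,
    Helix,
    apply_mutations,
    can_pair,
    design_compensatory_quartet,
)
from .fold import BasePairProbabilityMatrix, FoldBackend
from .profiles_io import ReactivityProfile
from .rescue import Quartet, UninformativeQuartetError, rescue_factor

logger = logging.getLogger(__name__)

DEFAULT_MIN_BPP = 0.01
DEFAULT_MIN_LEN = 3

CALIBRATION_COLUMNS = ["family", "helix_i", "helix_j", "n_bp", "rescue_factor", "frequency"]


def fold_bpp(sequence: str, backend: FoldBackend, name: str = "seq") -> BasePairProbabilityMatrix:
    """Fold a sequence into its BPP matrix, tagging failures with the id."""
    if len(sequence) < 10:
        raise ValueError(f"{name}: sequence too short to simulate ({len(sequence)} nt)")
    bad = set(sequence.upper()) - set("ACGU")
    if bad:
        raise ValueError(f"{name}: non-RNA symbols {sorted(bad)}")
    try:
        return backend.fold(sequence, name=name)
    except Exception as exc:
        raise RuntimeError(f"fold backend {backend.name!r} failed on {name!r}: {exc}") from exc


def simulate_reactivity(
    bpp: BasePairProbabilityMatrix, mutant_label: str = "WT"
) -> ReactivityProfile:
    """Noise-free simulated reactivity profile: probability unpaired."""
    values = bpp.unpaired_probability()
    return ReactivityProfile(
        construct_ref=bpp.sequence_ref,
        mutant_label=mutant_label,
        positions=np.arange(1, len(bpp) + 1),
        values=values,
        modifier="simulated",
    )


def screen_candidate_helices(
    bpp: BasePairProbabilityMatrix,
    min_bpp: float = DEFAULT_MIN_BPP,
    min_len: int = DEFAULT_MIN_LEN,
) -> list[Helix]:
    """Screen maximal stacked runs of probable base pairs.

    A cell (i, j) is a candidate if the bases can pair (Watson-Crick or
    G-U) and its BPP is at least ``min_bpp`` (default 1%). Candidates are
    grouped into maximal anti-diagonal runs — helices — and runs shorter
    than ``min_len`` (default 3 bp) are discarded. Positions are 1-based.
    """
    if not 0 < min_bpp < 1:
        raise ValueError(f"min_bpp must be in (0, 1), got {min_bpp}")
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    seq = bpp.sequence
    n = len(seq)
    candidate = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if bpp.p[i, j] >= min_bpp and can_pair(seq[i], seq[j]):
                candidate[i, j] = True
    helices: list[Helix] = []
    for i in range(n):
        for j in range(i + 1, n):
            if not candidate[i, j]:
                continue
            if i > 0 and j < n - 1 and candidate[i - 1, j + 1]:
                continue  # not the start of a run
            length = 1
            while (
                i + length < n
                and j - length >= 0
                and i + length < j - length
                and candidate[i + length, j - length]
            ):
                length += 1
            if length >= min_len:
                helices.append(
                    Helix(
                        name=f"{bpp.sequence_ref}:{i + 1}-{j + 1}x{length}",
                        pairs=tuple(BasePair(i + 1 + k, j + 1 - k) for k in range(length)),
                    )
                )
    return helices


@dataclass(frozen=True)
class SimulatedQuartet:
    """Outcome of one in-silico compensatory quartet."""

    pair: BasePair
    rescue_factor: float | None
    informative: bool
    wt_pair_probability: float

    @property
    def quartet_label(self) -> str:
        return f"({self.pair.i},{self.pair.j})"


def simulate_quartet(
    sequence: str,
    pair: BasePair,
    backend: FoldBackend,
    name: str = "seq",
    wt_bpp: BasePairProbabilityMatrix | None = None,
) -> SimulatedQuartet:
    """Simulate the compensatory quartet for one base pair.

    The quartet is designed with the standard complement-flip rule, all
    four variants are folded, probability-unpaired profiles are compared
    over the full sequence, and the rescue factor is returned. A quartet
    whose single mutants leave the simulated profile unchanged is flagged
    uninformative (``rescue_factor=None``).
    """
    construct = Construct(name=name, sequence=sequence.upper().replace("T", "U"))
    mut_a, mut_b, mut_ab = design_compensatory_quartet(construct, pair)
    if wt_bpp is None:
        wt_bpp = fold_bpp(construct.sequence, backend, name=name)
    profiles = {}
    for label, spec in (("wt", None), ("a", mut_a), ("b", mut_b), ("ab", mut_ab)):
        if spec is None:
            bpp = wt_bpp
        else:
            mutant = apply_mutations(construct, spec)
            bpp = fold_bpp(mutant.sequence, backend, name=mutant.name)
        profiles[label] = simulate_reactivity(bpp, "WT" if spec is None else spec.label)
    q = Quartet(
        pair=pair,
        wt=profiles["wt"],
        mut_a=profiles["a"],
        mut_b=profiles["b"],
        mut_ab=profiles["ab"],
    )
    wt_p = wt_bpp.pair_probability(pair.i, pair.j)
    try:
        factor = rescue_factor(q, zero_tol=1e-9)
    except UninformativeQuartetError:
        logger.info("%s pair (%d,%d): uninformative simulated quartet", name, pair.i, pair.j)
        return SimulatedQuartet(pair, None, False, wt_p)
    return SimulatedQuartet(pair, factor, True, wt_p)


@dataclass(frozen=True)
class CalibrationSample:
    """One simulated helix: mean rescue factor vs mean BPP (frequency)."""

    family: str
    helix_i: int
    helix_j: int
    n_bp: int
    rescue_factor: float
    frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency <= 1.0:
            raise ValueError(f"frequency {self.frequency} outside [0, 1]")
        if self.n_bp < 1:
            raise ValueError("n_bp must be >= 1")


def simulate_helix(
    sequence: str,
    helix: Helix,
    backend: FoldBackend,
    bpp: BasePairProbabilityMatrix | None = None,
    family: str = "seq",
) -> CalibrationSample | None:
    """Average simulated quartets over all base pairs of one helix."""
    if bpp is None:
        bpp = fold_bpp(sequence, backend, name=family)
    factors = []
    for pair in helix.pairs:
        sim = simulate_quartet(sequence, pair, backend, name=family, wt_bpp=bpp)
        if sim.informative:
            factors.append(sim.rescue_factor)
    if not factors:
        logger.warning("%s helix %s: all quartets uninformative", family, helix.name)
        return None
    freq = float(np.mean([bpp.pair_probability(p.i, p.j) for p in helix.pairs]))
    return CalibrationSample(
        family=family,
        helix_i=helix.pairs[0].i,
        helix_j=helix.pairs[0].j,
        n_bp=helix.n_bp,
        rescue_factor=float(np.mean(factors)),
        frequency=freq,
    )


def build_calibration(
    sequences: Iterable[tuple[str, str]],
    backend: FoldBackend,
    min_bpp: float = DEFAULT_MIN_BPP,
    min_len: int = DEFAULT_MIN_LEN,
    max_helices_per_sequence: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Build a calibration table from (id, sequence) pairs.

    For each sequence: fold, screen candidate helices (BPP >= ``min_bpp``
    over runs of >= ``min_len`` Watson-Crick/G-U pairs), and simulate a
    compensatory quartet for every base pair of every screened helix.
    Per-sequence failures are logged and skipped so one pathological
    input cannot abort a long run. When ``max_helices_per_sequence`` is
    set, helices are subsampled with the seeded generator.

    Returns a DataFrame with columns ``family, helix_i, helix_j, n_bp,
    rescue_factor, frequency`` and run provenance in ``df.attrs``.
    """
    rng = np.random.default_rng(seed)
    rows: list[CalibrationSample] = []
    n_sequences = 0
    for name, seq in sequences:
        n_sequences += 1
        try:
            bpp = fold_bpp(seq, backend, name=name)
            helices = screen_candidate_helices(bpp, min_bpp=min_bpp, min_len=min_len)
            if max_helices_per_sequence is not None and len(helices) > max_helices_per_sequence:
                keep = rng.choice(len(helices), size=max_helices_per_sequence, replace=False)
                helices = [helices[k] for k in sorted(keep)]
            for helix in helices:
                sample = simulate_helix(seq, helix, backend, bpp=bpp, family=name)
                if sample is not None:
                    rows.append(sample)
        except Exception as exc:
            logger.warning("skipping sequence %r: %s", name, exc)
            continue
    if n_sequences == 0:
        raise ValueError("no calibration sequences supplied")
    df = pd.DataFrame([asdict(r) for r in rows], columns=CALIBRATION_COLUMNS)
    df.attrs["provenance"] = {
        "backend": backend.name,
        "temperature": backend.temperature,
        "min_bpp": min_bpp,
        "min_len": min_len,
        "seed": seed,
        "n_sequences": n_sequences,
    }
    return df


def read_fasta_sequences(path) -> list[tuple[str, str]]:
    """Load (id, RNA sequence) pairs from a FASTA file."""
    from Bio import SeqIO

    records = [
        (rec.id, str(rec.seq).upper().replace("T", "U"))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return records


def write_calibration(df: pd.DataFrame, path) -> None:
    """Serialize a calibration table as TSV plus a JSON provenance sidecar."""
    df.to_csv(path, sep="\t", index=False)
    prov = dict(df.attrs.get("provenance", {}))
    prov["table_sha256"] = hashlib.sha256(
        df.to_csv(sep="\t", index=False).encode()
    ).hexdigest()
    with open(str(path) + ".json", "w") as fh:
        json.dump(prov, fh, indent=2)


def read_calibration(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CALIBRATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"calibration table {path} missing columns {sorted(missing)}")
    return df
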