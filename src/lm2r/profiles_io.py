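"""Reactivity profiles, RDAT file I/O, and profile-level cleaning.

The RDAT flat-file format of the RNA Mapping Database stores one
chemical-mapping dataset per file: a sequence, an offset, per-row
annotations (``mutation:A19U``, ``modifier:1M7`` ...) and tab-delimited
``REACTIVITY`` rows. Only the tab-delimited 0.2+ dialect is supported.

Cleaning operations mirror standard capillary-electrophoresis pipelines
at the profile level: normalization against GAGUA reference hairpin
loops, 5'->3' signal-attenuation correction anchored at the two
reference loops, and background (no-modification) subtraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .constructs import Construct, MutantSpec

logger = logging.getLogger(__name__)


class RdatParseError(ValueError):
    """Raised on a malformed RDAT file; carries the offending line number."""


@dataclass(frozen=True)
class ReactivityProfile:
    """Per-nucleotide reactivities of one construct variant.

    ``positions`` are biological positions aligned with ``values``;
    ``errors`` are optional one-sigma uncertainties of the same length.
    """

    construct_ref: str
    mutant_label: str
    positions: np.ndarray
    values: np.ndarray
    errors: np.ndarray | None = None
    modifier: str = "1M7"

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", np.asarray(self.positions, dtype=int))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.errors is not None:
            object.__setattr__(self, "errors", np.asarray(self.errors, dtype=float))
        if self.values.shape != self.positions.shape:
            raise ValueError(
                f"profile {self.mutant_label!r}: {len(self.values)} values for "
                f"{len(self.positions)} positions"
            )
        if self.errors is not None and self.errors.shape != self.values.shape:
            raise ValueError(f"profile {self.mutant_label!r}: error-length mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"profile {self.mutant_label!r}: non-finite reactivities")

    def __len__(self) -> int:
        return len(self.values)

    def value_at(self, positions: Sequence[int]) -> np.ndarray:
        """Values at the requested biological positions (all must be present)."""
        idx = self._indices(positions)
        return self.values[idx]

    def _indices(self, positions: Sequence[int]) -> np.ndarray:
        lookup = {p: k for k, p in enumerate(self.positions.tolist())}
        try:
            return np.array([lookup[p] for p in positions], dtype=int)
        except KeyError as exc:
            raise KeyError(
                f"position {exc.args[0]} not covered by profile {self.mutant_label!r}"
            ) from None

    def restrict(self, positions: Sequence[int]) -> "ReactivityProfile":
        idx = self._indices(positions)
        return replace(
            self,
            positions=self.positions[idx],
            values=self.values[idx],
            errors=None if self.errors is None else self.errors[idx],
        )

    def with_values(self, values: np.ndarray, errors: np.ndarray | None = None) -> "ReactivityProfile":
        return replace(self, values=np.asarray(values, float), errors=errors)

    @property
    def mutant_spec(self) -> MutantSpec:
        return MutantSpec.from_label(self.mutant_label)


@dataclass
class RdatFile:
    """In-memory image of one RDAT dataset."""

    name: str
    sequence: str
    offset: int
    profiles: list[ReactivityProfile]
    structure: str | None = None
    version: str = "0.34"
    annotations: dict[str, list[str]] = field(default_factory=dict)
    comments: list[str] = field(default_factory=list)

    @property
    def seqpos(self) -> np.ndarray:
        if self.profiles:
            return self.profiles[0].positions
        return np.arange(1, len(self.sequence) + 1) + self.offset


def _parse_annotations(tokens: Iterable[str]) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for tok in tokens:
        tok = tok.strip()
        if not tok:
            continue
        key, _, value = tok.partition(":")
        out.setdefault(key, []).append(value)
    return out


def _mutant_label(annotations: dict[str, list[str]]) -> str:
    muts = [m for m in annotations.get("mutation", []) if m not in ("WT", "wt", "")]
    if not muts:
        return "WT"
    # canonical order via MutantSpec round trip
    return MutantSpec.from_label("-".join(muts)).label


def read_rdat(path) -> RdatFile:
    """Parse a tab-delimited RDAT file into profiles.

    One :class:`ReactivityProfile` is produced per ``REACTIVITY`` row;
    per-row ``mutation:`` annotations are folded into a canonical mutant
    label and ``modifier:`` annotations (file-level or per-row) set the
    probe chemistry.
    """
    name = ""
    sequence = ""
    structure: str | None = None
    offset = 0
    version = "0.34"
    seqpos: np.ndarray | None = None
    comments: list[str] = []
    global_annotations: dict[str, list[str]] = {}
    row_annotations: dict[int, dict[str, list[str]]] = {}
    reactivities: dict[int, np.ndarray] = {}
    errors: dict[int, np.ndarray] = {}

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            tag, *rest = line.split("\t")
            tag = tag.strip()
            try:
                if tag in ("RDAT_VERSION", "VERSION"):
                    version = rest[0].strip()
                elif tag == "NAME":
                    name = rest[0].strip()
                elif tag == "SEQUENCE":
                    sequence = rest[0].strip().upper().replace("T", "U")
                elif tag == "STRUCTURE":
                    structure = rest[0].strip()
                elif tag == "OFFSET":
                    offset = int(rest[0])
                elif tag == "SEQPOS":
                    toks = [t for t in rest if t.strip()]
                    seqpos = np.array(
                        [int("".join(c for c in t if c in "-0123456789")) for t in toks]
                    )
                elif tag == "COMMENT":
                    comments.append("\t".join(rest))
                elif tag == "ANNOTATION":
                    global_annotations.update(_parse_annotations(rest))
                elif tag.startswith(("ANNOTATION_DATA:", "DATA_ANNOTATION:")):
                    idx = int(tag.split(":", 1)[1])
                    row_annotations[idx] = _parse_annotations(rest)
                elif tag.startswith("REACTIVITY_ERROR:"):
                    idx = int(tag.split(":", 1)[1])
                    errors[idx] = np.array([float(t) for t in rest if t.strip()])
                elif tag.startswith("REACTIVITY:"):
                    idx = int(tag.split(":", 1)[1])
                    reactivities[idx] = np.array([float(t) for t in rest if t.strip()])
                # unknown tags are preserved as comments
                else:
                    comments.append(line)
            except (ValueError, IndexError) as exc:
                raise RdatParseError(f"{path}:{lineno}: cannot parse {tag!r} line: {exc}") from exc

    if not sequence:
        raise RdatParseError(f"{path}: no SEQUENCE block found")
    if seqpos is None:
        seqpos = np.arange(1, len(sequence) + 1) + offset

    profiles: list[ReactivityProfile] = []
    for idx in sorted(reactivities):
        values = reactivities[idx]
        if len(values) != len(seqpos):
            raise RdatParseError(
                f"{path}: REACTIVITY:{idx} has {len(values)} values but SEQPOS lists "
                f"{len(seqpos)} positions"
            )
        ann = dict(global_annotations)
        ann.update(row_annotations.get(idx, {}))
        err = errors.get(idx)
        if err is not None and len(err) != len(seqpos):
            raise RdatParseError(f"{path}: REACTIVITY_ERROR:{idx} length mismatch")
        profiles.append(
            ReactivityProfile(
                construct_ref=name or "rdat",
                mutant_label=_mutant_label(ann),
                positions=seqpos.copy(),
                values=values,
                errors=err,
                modifier=ann.get("modifier", ["1M7"])[0] or "1M7",
            )
        )
    logger.info("read %d profiles from %s", len(profiles), path)
    return RdatFile(
        name=name or "rdat",
        sequence=sequence,
        offset=offset,
        profiles=profiles,
        structure=structure,
        version=version,
        annotations=global_annotations,
        comments=comments,
    )


def write_rdat(rdat: RdatFile, path) -> None:
    """Write an RDAT file; reactivity values round-trip bit-exact."""
    lines: list[str] = [f"RDAT_VERSION\t{rdat.version}", f"NAME\t{rdat.name}"]
    lines.append(f"SEQUENCE\t{rdat.sequence}")
    if rdat.structure:
        lines.append(f"STRUCTURE\t{rdat.structure}")
    lines.append(f"OFFSET\t{rdat.offset}")
    seqpos = rdat.seqpos
    lines.append("SEQPOS\t" + "\t".join(str(int(p)) for p in seqpos))
    for comment in rdat.comments:
        lines.append(f"COMMENT\t{comment}")
    if rdat.annotations:
        toks = [f"{k}:{v}" for k, vals in rdat.annotations.items() for v in vals]
        lines.append("ANNOTATION\t" + "\t".join(toks))
    for n, prof in enumerate(rdat.profiles, start=1):
        if not np.array_equal(prof.positions, seqpos):
            raise ValueError(
                f"profile {prof.mutant_label!r} positions differ from file SEQPOS"
            )
        ann = [f"mutation:{s.label}" for s in prof.mutant_spec.substitutions] or ["mutation:WT"]
        ann.append(f"modifier:{prof.modifier}")
        lines.append(f"ANNOTATION_DATA:{n}\t" + "\t".join(ann))
        lines.append(f"REACTIVITY:{n}\t" + "\t".join(repr(float(v)) for v in prof.values))
        if prof.errors is not None:
            lines.append(
                f"REACTIVITY_ERROR:{n}\t" + "\t".join(repr(float(v)) for v in prof.errors)
            )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    logger.info("wrote %d profiles to %s", len(rdat.profiles), path)


def _loop_positions(
    construct: Construct, modifier_mask: dict[str, Sequence[int]] | None, modifier: str
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Reference-loop positions, optionally restricted per modifier.

    Some probes react with only a subset of the GAGUA loop; the mask maps
    a modifier name to the loop positions that respond to it.
    """
    five, three = construct.reference_loops
    if modifier_mask and modifier in modifier_mask:
        allowed = set(modifier_mask[modifier])
        five = tuple(p for p in five if p in allowed)
        three = tuple(p for p in three if p in allowed)
    return five, three


def normalize_profile(
    raw: ReactivityProfile,
    construct: Construct,
    modifier_mask: dict[str, Sequence[int]] | None = None,
) -> ReactivityProfile:
    """Scale a profile so the mean reactivity over the reference loops is 1.

    A single common factor is applied to all values (and errors), so the
    operation is idempotent.
    """
    five, three = _loop_positions(construct, modifier_mask, raw.modifier)
    loop = tuple(five) + tuple(three)
    if not loop:
        raise ValueError(f"construct {construct.name!r} has no reference-loop positions")
    mean = float(np.mean(raw.value_at(loop)))
    if mean <= 0:
        raise ValueError(
            f"profile {raw.mutant_label!r}: non-positive reference-loop mean {mean:g}"
        )
    return raw.with_values(
        raw.values / mean, None if raw.errors is None else raw.errors / mean
    )


def correct_attenuation(
    raw: ReactivityProfile,
    construct: Construct,
    modifier_mask: dict[str, Sequence[int]] | None = None,
) -> ReactivityProfile:
    """Correct 5'->3' signal attenuation against the two reference loops.

    Reverse-transcription drop-off attenuates signal geometrically along
    the transcript, so the correction factor is an exponential in
    position, anchored so the geometric-mean intensity of the 3' loop is
    raised to that of the 5' loop. Equal loop intensities leave the
    profile unchanged.
    """
    five, three = _loop_positions(construct, modifier_mask, raw.modifier)
    if not five or not three:
        raise ValueError(
            f"attenuation correction needs both reference loops on {construct.name!r}"
        )
    v5 = raw.value_at(five)
    v3 = raw.value_at(three)
    if np.any(v5 <= 0) or np.any(v3 <= 0):
        raise ValueError(
            f"profile {raw.mutant_label!r}: reference-loop reactivities must be positive "
            "for attenuation correction"
        )
    m5 = float(np.exp(np.mean(np.log(v5))))
    m3 = float(np.exp(np.mean(np.log(v3))))
    c5 = float(np.mean(five))
    c3 = float(np.mean(three))
    ratio = m3 / m5  # < 1 when 3' signal is attenuated
    t = (raw.positions - c5) / (c3 - c5)
    factor = ratio ** (-t)
    return raw.with_values(
        raw.values * factor, None if raw.errors is None else raw.errors * factor
    )


def subtract_background(
    signal: ReactivityProfile, nomod: ReactivityProfile
) -> ReactivityProfile:
    """Subtract a no-modification control, flooring at zero.

    Reactivities are physically non-negative; negative differences are
    clipped. Errors, when present on both profiles, add in quadrature.
    """
    if signal.construct_ref != nomod.construct_ref:
        raise ValueError(
            f"construct mismatch: {signal.construct_ref!r} vs {nomod.construct_ref!r}"
        )
    if not np.array_equal(signal.positions, nomod.positions):
        raise ValueError("signal and no-modification profiles cover different positions")
    values = np.maximum(signal.values - nomod.values, 0.0)
    errors = None
    if signal.errors is not None and nomod.errors is not None:
        errors = np.sqrt(signal.errors**2 + nomod.errors**2)
    return signal.with_values(values, errors)


def profiles_to_tsv(profiles: Sequence[ReactivityProfile], path) -> None:
    """Export profiles as a long-format TSV (construct, mutant, modifier,
    position, value, error)."""
    import pandas as pd

    rows = []
    for prof in profiles:
        err = prof.errors if prof.errors is not None else np.full(len(prof), np.nan)
        for p, v, e in zip(prof.positions, prof.values, err):
            rows.append((prof.construct_ref, prof.mutant_label, prof.modifier, int(p), v, e))
    pd.DataFrame(
        rows, columns=["construct", "mutant", "modifier", "position", "value", "error"]
    ).to_csv(path, sep="\t", index=False)
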