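"""Two-state linear decomposition of chemical-mapping profiles.

A lock mutant is validated by checking that the wild-type profile is a
two-state mixture of locked-state endpoint profiles: the fit finds the
fraction f minimizing RMSD(target, f*A + (1-f)*B) in closed form,
clamped to [0, 1]. Profiles from several probe chemistries can be
concatenated (after per-modifier normalization) to share a single f.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .profiles_io import ReactivityProfile
from .rescue import profile_rmsd


@dataclass(frozen=True)
class TwoStateFit:
    """Mixture weight of state A, fit residual, and endpoint references."""

    fraction: float
    residual_rmsd: float
    endpoint_a: str
    endpoint_b: str
    unconstrained_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction} outside [0, 1]")
        if self.residual_rmsd < 0:
            raise ValueError("residual must be non-negative")


def _as_values(
    prof: ReactivityProfile | np.ndarray | Sequence[float],
) -> tuple[np.ndarray, str]:
    if isinstance(prof, ReactivityProfile):
        return np.asarray(prof.values, float), prof.mutant_label
    return np.asarray(prof, float), "array"


def two_state_fit(
    target: ReactivityProfile | np.ndarray,
    state_a: ReactivityProfile | np.ndarray,
    state_b: ReactivityProfile | np.ndarray,
    degenerate_tol: float = 1e-12,
) -> TwoStateFit:
    """Closed-form constrained least squares of target onto two endpoints.

    The unconstrained optimum f* = <(t - B), (A - B)> / ||A - B||^2 is
    clamped to [0, 1]; both the clamped fraction and the raw optimum are
    reported, together with the RMSD residual at the clamped fraction.
    Identical endpoints make the decomposition degenerate and raise.
    """
    t, _ = _as_values(target)
    va, label_a = _as_values(state_a)
    vb, label_b = _as_values(state_b)
    if not (t.shape == va.shape == vb.shape):
        raise ValueError(
            f"profiles must share positions: shapes {t.shape}, {va.shape}, {vb.shape}"
        )
    diff = va - vb
    norm2 = float(diff @ diff)
    if norm2 <= degenerate_tol * len(diff):
        raise ValueError("endpoint profiles are identical; two-state fit is degenerate")
    f_raw = float((t - vb) @ diff / norm2)
    f = float(np.clip(f_raw, 0.0, 1.0))
    residual = profile_rmsd(t, f * va + (1 - f) * vb)
    return TwoStateFit(
        fraction=f,
        residual_rmsd=residual,
        endpoint_a=label_a,
        endpoint_b=label_b,
        unconstrained_fraction=f_raw,
    )


def two_state_fit_multi(
    targets: Sequence[ReactivityProfile | np.ndarray],
    states_a: Sequence[ReactivityProfile | np.ndarray],
    states_b: Sequence[ReactivityProfile | np.ndarray],
) -> TwoStateFit:
    """Shared-fraction fit across several modifiers.

    Per-modifier profiles are concatenated so that a single mixture
    fraction explains all chemistries simultaneously; inputs should
    already be normalized per modifier.
    """
    if not (len(targets) == len(states_a) == len(states_b) > 0):
        raise ValueError("need equal, non-empty profile lists per modifier")
    t = np.concatenate([_as_values(p)[0] for p in targets])
    a = np.concatenate([_as_values(p)[0] for p in states_a])
    b = np.concatenate([_as_values(p)[0] for p in states_b])
    labels_a = ",".join(_as_values(p)[1] for p in states_a)
    labels_b = ",".join(_as_values(p)[1] for p in states_b)
    fit = two_state_fit(t, a, b)
    return TwoStateFit(
        fraction=fit.fraction,
        residual_rmsd=fit.residual_rmsd,
        endpoint_a=labels_a,
        endpoint_b=labels_b,
        unconstrained_fraction=fit.unconstrained_fraction,
    )
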