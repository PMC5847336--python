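"""Simulation-calibrated posteriors over helix frequencies and
helix-helix correlation values.

The posterior over a helix frequency F given an observed mean rescue
factor is nonparametric: it is the empirical set of simulated helix
frequencies among calibration samples with the same base-pair count
whose simulated rescue factor falls in the same bin (default binwidth
0.05) as the observation. The median of these samples is the point
estimate; a boundary-reflected Gaussian kernel density estimate is used
for plotting and for combining experiments.

A correlation value g(h1, h2) = F(h1|h2) / F(h1) compares the frequency
of helix 1 conditional on helix 2 (measured by probing h1 in an
ensemble where h2 is locked) with its unconditional frequency:
g << 1 signals mutual exclusion (the conformational-selection, MWC
signature), g ~ 1 independence. Its posterior is built from ratios of
frequency-posterior samples, and two independent experiments probing
the same pair (the "flipped" designs) are combined by multiplying
kernel density estimates under a flat prior on g.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .rescue import HelixRescueResult

logger = logging.getLogger(__name__)

DEFAULT_BINWIDTH = 0.05
MIN_BIN_SAMPLES = 20
MAX_RATIO_SAMPLES = 10**6


class EmptyBinError(ValueError):
    """No calibration samples match the observation even after widening."""


def silverman_bandwidth(samples: np.ndarray) -> float:
    """Silverman's rule of thumb, guarded for degenerate samples."""
    samples = np.asarray(samples, float)
    n = len(samples)
    if n < 2:
        return 1e-3
    sd = float(np.std(samples, ddof=1))
    iqr = float(np.subtract(*np.percentile(samples, [75, 25])))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread <= 0:
        return 1e-3
    return 0.9 * spread * n ** (-0.2)


def reflected_kde(
    samples: np.ndarray,
    grid: np.ndarray,
    bandwidth: float | None = None,
    bandwidth_scale: float = 1.0,
    reflect_low: float | None = 0.0,
    reflect_high: float | None = None,
) -> np.ndarray:
    """Gaussian KDE with boundary reflection, normalized on the grid.

    Reflection at a bound folds the kernel mass that would leak past it
    back into the support, removing the usual KDE boundary bias for
    quantities bounded at 0 (correlations) or in [0, 1] (frequencies).
    """
    samples = np.asarray(samples, float)
    h = (bandwidth if bandwidth is not None else silverman_bandwidth(samples)) * bandwidth_scale
    h = max(h, 1e-6)
    points = [samples]
    if reflect_low is not None:
        points.append(2 * reflect_low - samples)
    if reflect_high is not None:
        points.append(2 * reflect_high - samples)
    pts = np.concatenate(points)
    dens = np.exp(-0.5 * ((grid[:, None] - pts[None, :]) / h) ** 2).sum(axis=1)
    dens /= len(samples) * h * np.sqrt(2 * np.pi)
    area = np.trapezoid(dens, grid)
    if area <= 0:
        raise ValueError("degenerate density (zero mass on grid)")
    return dens / area


@dataclass(frozen=True)
class FrequencyPosterior:
    """Sample-based posterior over a helix frequency in [0, 1]."""

    helix_ref: str
    samples: np.ndarray
    relaxations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, float)
        if samples.size == 0:
            raise ValueError(f"{self.helix_ref}: empty posterior sample set")
        if samples.min() < 0 or samples.max() > 1:
            raise ValueError(f"{self.helix_ref}: frequency samples outside [0, 1]")
        object.__setattr__(self, "samples", samples)

    @property
    def median(self) -> float:
        return float(np.median(self.samples))

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        lo = (1 - level) / 2
        return tuple(np.quantile(self.samples, [lo, 1 - lo]))

    def kde(self, grid: np.ndarray | None = None, bandwidth_scale: float = 1.0):
        if grid is None:
            grid = np.linspace(0.0, 1.0, 512)
        return grid, reflected_kde(
            self.samples, grid, bandwidth_scale=bandwidth_scale,
            reflect_low=0.0, reflect_high=1.0,
        )


@dataclass(frozen=True)
class CorrelationPosterior:
    """Sample-based posterior over a correlation value g >= 0.

    ``grid``/``density`` are set for combined posteriors, in which case
    they — not the drawn samples — define the posterior support.
    """

    pair_ref: tuple[str, str]
    samples: np.ndarray
    grid: np.ndarray | None = None
    density: np.ndarray | None = None

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, float)
        if samples.size == 0:
            raise ValueError(f"{self.pair_ref}: empty posterior sample set")
        if samples.min() < 0:
            raise ValueError(f"{self.pair_ref}: negative correlation samples")
        object.__setattr__(self, "samples", samples)

    @property
    def median(self) -> float:
        if self.density is not None:
            cdf = _cumtrapz(self.density, self.grid)
            return float(np.interp(0.5, cdf, self.grid))
        return float(np.median(self.samples))

    @property
    def support_above_1(self) -> float:
        return posterior_support(self, 1.0)

    def credible_bound(self, level: float = 0.95) -> float:
        """Upper bound g* with P(g <= g*) = level."""
        if self.density is not None:
            cdf = _cumtrapz(self.density, self.grid)
            return float(np.interp(level, cdf, self.grid))
        return float(np.quantile(self.samples, level))


def _bin_index(x: float | np.ndarray, binwidth: float) -> np.ndarray:
    return np.floor(np.asarray(x, float) / binwidth + 1e-9).astype(int)


def posterior_frequency(
    observed: HelixRescueResult | float,
    calibration: pd.DataFrame,
    binwidth: float = DEFAULT_BINWIDTH,
    n_bp: int | None = None,
    helix_ref: str | None = None,
    min_samples: int = MIN_BIN_SAMPLES,
) -> FrequencyPosterior:
    """Posterior over helix frequency given an observed rescue factor.

    Calibration samples are matched on exact base-pair count and on the
    rescue-factor bin of the observation. Starved cells are widened
    progressively — first +/-1 bin, then +/-1 base pair — with each
    relaxation recorded on the returned posterior; an observation outside
    the populated bin range is clamped to the nearest populated bin with
    a warning. An empty match after all widening raises
    :class:`EmptyBinError`.

    Parameters
    ----------
    observed:
        A :class:`HelixRescueResult` (mean factor and helix taken from
        it) or a bare rescue factor, in which case ``n_bp`` is required.
    """
    if isinstance(observed, HelixRescueResult):
        factor = observed.mean_factor
        n_bp = observed.helix.n_bp
        helix_ref = helix_ref or observed.helix.name
    else:
        factor = float(observed)
        if n_bp is None:
            raise ValueError("n_bp is required when passing a bare rescue factor")
        helix_ref = helix_ref or f"helix[{n_bp}bp]"
    if binwidth <= 0:
        raise ValueError("binwidth must be positive")
    if calibration.empty:
        raise ValueError("empty calibration table")

    calib_bins = _bin_index(calibration["rescue_factor"].to_numpy(), binwidth)
    obs_bin = int(_bin_index(factor, binwidth))
    relaxations: list[str] = []

    lo, hi = int(calib_bins.min()), int(calib_bins.max())
    if obs_bin < lo or obs_bin > hi:
        clamped = int(np.clip(obs_bin, lo, hi))
        logger.warning(
            "%s: observed rescue factor %.3f outside calibrated bin range; "
            "using nearest populated bin %d", helix_ref, factor, clamped,
        )
        relaxations.append(f"clamped_bin:{obs_bin}->{clamped}")
        obs_bin = clamped

    nbp_arr = calibration["n_bp"].to_numpy()
    freqs = calibration["frequency"].to_numpy()

    def matches(bin_slack: int, nbp_slack: int) -> np.ndarray:
        mask = (np.abs(calib_bins - obs_bin) <= bin_slack) & (
            np.abs(nbp_arr - n_bp) <= nbp_slack
        )
        return freqs[mask]

    stages = [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2)]
    samples = np.array([])
    for bin_slack, nbp_slack in stages:
        samples = matches(bin_slack, nbp_slack)
        if (bin_slack, nbp_slack) != (0, 0):
            relaxations.append(f"widened:bin+-{bin_slack},n_bp+-{nbp_slack}")
        if len(samples) >= min_samples:
            break
    if len(samples) == 0:
        raise EmptyBinError(
            f"{helix_ref}: no calibration samples with n_bp~{n_bp} near rescue-factor "
            f"bin {obs_bin} (binwidth {binwidth})"
        )
    if len(samples) < min_samples:
        logger.warning(
            "%s: only %d calibration samples after widening", helix_ref, len(samples)
        )
    for r in relaxations:
        logger.info("%s: calibration matching relaxed (%s)", helix_ref, r)
    return FrequencyPosterior(
        helix_ref=helix_ref, samples=np.sort(samples), relaxations=tuple(relaxations)
    )


def posterior_correlation(
    wt: FrequencyPosterior,
    locked: FrequencyPosterior,
    pair_ref: tuple[str, str] | None = None,
    max_samples: int = MAX_RATIO_SAMPLES,
    seed: int = 0,
    zero_tol: float = 1e-9,
) -> CorrelationPosterior:
    """Posterior over g = F(h1|h2) / F(h1) from two frequency posteriors.

    Every conditional-frequency sample (probing h1 with h2 locked) is
    divided by every unconditional sample; the full cross-product is
    subsampled with a seeded generator above ``max_samples``. Zero
    wild-type samples are excluded (logged); if all are zero the
    correlation is undefined.
    """
    wt_samples = wt.samples[wt.samples > zero_tol]
    n_dropped = len(wt.samples) - len(wt_samples)
    if n_dropped:
        logger.info("%s: excluded %d zero wild-type frequency samples", wt.helix_ref, n_dropped)
    if len(wt_samples) == 0:
        raise ValueError(
            f"{wt.helix_ref}: all wild-type frequency samples are zero; correlation undefined"
        )
    pair_ref = pair_ref or (locked.helix_ref, wt.helix_ref)
    n_total = len(locked.samples) * len(wt_samples)
    if n_total <= max_samples:
        ratios = (locked.samples[:, None] / wt_samples[None, :]).ravel()
    else:
        rng = np.random.default_rng(seed)
        idx_l = rng.integers(0, len(locked.samples), size=max_samples)
        idx_w = rng.integers(0, len(wt_samples), size=max_samples)
        ratios = locked.samples[idx_l] / wt_samples[idx_w]
    return CorrelationPosterior(pair_ref=pair_ref, samples=np.sort(ratios))


def _cumtrapz(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    out = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(x))])
    return out / out[-1]


def combine_posteriors(
    a: CorrelationPosterior,
    b: CorrelationPosterior,
    n_grid: int = 2048,
    n_samples: int = 20000,
    bandwidth_scale: float = 1.0,
    seed: int = 0,
) -> CorrelationPosterior:
    """Combine two posteriors on the same helix pair by density product.

    With a flat prior on g, the posterior given both (independent)
    experiments is proportional to the product of the two single-
    experiment densities. Densities are boundary-reflected Gaussian KDEs
    evaluated on a shared grid spanning [0, max(4, 99.5th percentile)];
    the product is renormalized by the trapezoid rule and representative
    samples are drawn from it by inverse-CDF with a seeded generator.
    Disjoint supports (vanishing product everywhere) raise, flagging
    mutually inconsistent experiments.
    """
    if set(a.pair_ref) != set(b.pair_ref):
        raise ValueError(f"cannot combine posteriors for {a.pair_ref} and {b.pair_ref}")
    pooled = np.concatenate([a.samples, b.samples])
    upper = max(4.0, float(np.percentile(pooled, 99.5)))
    grid = np.linspace(0.0, upper, n_grid)
    da = reflected_kde(a.samples, grid, bandwidth_scale=bandwidth_scale, reflect_low=0.0)
    db = reflected_kde(b.samples, grid, bandwidth_scale=bandwidth_scale, reflect_low=0.0)
    prod = da * db
    area = np.trapezoid(prod, grid)
    if area <= 1e-300:
        raise ValueError(
            f"posteriors for {a.pair_ref} have disjoint supports; experiments inconsistent"
        )
    density = prod / area
    cdf = _cumtrapz(density, grid)
    rng = np.random.default_rng(seed)
    u = rng.uniform(0, 1, size=n_samples)
    samples = np.interp(u, cdf, grid)
    return CorrelationPosterior(
        pair_ref=a.pair_ref, samples=np.sort(samples), grid=grid, density=density
    )


def posterior_support(post: CorrelationPosterior, threshold: float = 1.0) -> float:
    """Posterior mass strictly above ``threshold`` (default: g > 1, the
    non-anticorrelated regime)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if post.density is not None:
        mask = post.grid > threshold
        if not mask.any():
            return 0.0
        x = np.concatenate([[threshold], post.grid[mask]])
        y = np.concatenate(
            [[np.interp(threshold, post.grid, post.density)], post.density[mask]]
        )
        return float(min(1.0, np.trapezoid(y, x)))
    return float(np.mean(post.samples > threshold))
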