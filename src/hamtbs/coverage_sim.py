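"""Coverage-accuracy bootstrap: how deep must a CpG be sequenced?

Sequencing a library to a given depth is subsampling the template
population: the methylation estimate from ``c`` reads drawn from a pool of
``N`` fragments at true level ``p`` has a hypergeometric sampling
distribution.  This module reproduces that subsampling empirically — a
pool of 100,000 fragments per methylation level, 1000 bootstrap subsets
per (level, coverage) cell — and summarises the accuracy-per-cost
trade-off to recommend a minimum coverage cutoff.

The empirical SD of each cell is checked against the closed form

    SD(p, c) = 100 * sqrt( p(1-p)/c * (N-c)/(N-1) )  [percentage points]

(the hypergeometric SD with finite-population correction), which serves as
the analytic oracle in the test suite.  Under the fitted ``k/sqrt(c)``
decay of the summed SD, the relative accuracy gain per additional 100x
coverage is ``50/c`` regardless of ``k``, so a 5% marginal-gain threshold
puts the recommended cutoff at 1000x.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DiagnosticError, SamplingError

DEFAULT_POPULATION = 100_000
DEFAULT_N_BOOT = 1000
#: Coverage grid: 100, 200, then 200-steps to 2000, then 1000-steps to 5000.
DEFAULT_COVERAGES = (
    100, 200, 400, 600, 800, 1000, 1200, 1400, 1600, 1800, 2000, 3000, 4000, 5000,
)
#: Methylation levels 0-100% in 10-point steps (as fractions).
DEFAULT_LEVELS = tuple(i / 10 for i in range(11))
DEFAULT_MARGINAL_GAIN = 0.05


@dataclass(frozen=True)
class FragmentSet:
    """A finite fragment population at one methylation level."""

    level: float
    n_fragments: int = DEFAULT_POPULATION

    def __post_init__(self) -> None:
        if not 0.0 <= self.level <= 1.0:
            raise ConfigurationError(f"level outside [0, 1]: {self.level}")
        if self.n_fragments < 1:
            raise ConfigurationError("population must be positive")

    @property
    def n_meth(self) -> int:
        """Number of methylated ("C") fragments; the rest read "T"."""
        return round(self.level * self.n_fragments)


@dataclass
class SimGrid:
    """Bootstrap SD (percentage points) per (level, coverage) cell."""

    sd: pd.DataFrame  # index: level, columns: coverage
    n_fragments: int
    n_boot: int
    seed: int | None


@dataclass
class CostCurve:
    """Combined SD, its Monte-Carlo SE, and the cost proxy per coverage."""

    table: pd.DataFrame  # coverage, combined_sd, combined_se, cost
    n_boot: int


def hypergeometric_sd(p: float, c: int, n_fragments: int = DEFAULT_POPULATION) -> float:
    """Closed-form SD (pp) of a methylation estimate from ``c`` of ``N`` fragments."""
    if c < 1:
        return 0.0
    fpc = (n_fragments - c) / (n_fragments - 1)
    return 100.0 * float(np.sqrt(p * (1 - p) / c * fpc))


def subsample_sd(
    level: float,
    coverage: int,
    n_fragments: int = DEFAULT_POPULATION,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Bootstrap SD (pp) of the methylation estimate at one grid cell.

    Draws ``n_boot`` subsets of size ``coverage`` without replacement from
    a :class:`FragmentSet` and returns the sample SD (n-1 denominator) of
    the per-subset methylation estimates, on the percent scale.
    """
    fragments = FragmentSet(level, n_fragments)
    if coverage > n_fragments:
        raise SamplingError(
            f"coverage {coverage} exceeds population {n_fragments}"
        )
    if coverage < 1:
        raise SamplingError("coverage must be at least 1")
    if n_boot < 2:
        raise ConfigurationError("n_boot must be at least 2")
    if n_boot < 30:
        warnings.warn(f"n_boot={n_boot} gives a high-variance SD estimate")
    if rng is None:
        rng = np.random.default_rng(seed)
    draws = rng.hypergeometric(
        fragments.n_meth, n_fragments - fragments.n_meth, coverage, size=n_boot
    )
    estimates = draws / coverage
    return float(estimates.std(ddof=1)) * 100.0


def build_grid(
    levels: tuple[float, ...] = DEFAULT_LEVELS,
    coverages: tuple[int, ...] = DEFAULT_COVERAGES,
    n_fragments: int = DEFAULT_POPULATION,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int | None = None,
) -> SimGrid:
    """Fill the (level, coverage) SD table by per-cell bootstrap.

    Each cell uses an independent generator spawned deterministically from
    the master seed, so grids are reproducible and cell order immaterial.
    """
    if not levels or not coverages:
        raise ConfigurationError("levels and coverages must be non-empty")
    ss = np.random.SeedSequence(seed)
    children = iter(ss.spawn(len(levels) * len(coverages)))
    table = np.empty((len(levels), len(coverages)))
    for i, level in enumerate(levels):
        for j, cov in enumerate(coverages):
            rng = np.random.default_rng(next(children))
            table[i, j] = subsample_sd(
                level, cov, n_fragments=n_fragments, n_boot=n_boot, rng=rng
            )
    sd = pd.DataFrame(table, index=list(levels), columns=list(coverages))
    sd.index.name = "level"
    sd.columns.name = "coverage"
    return SimGrid(sd=sd, n_fragments=n_fragments, n_boot=n_boot, seed=seed)


def cost_curve(grid: SimGrid) -> CostCurve:
    """Combined SD per coverage and the accuracy-per-depth cost proxy.

    The combined SD sums the per-level SDs at each coverage; the cost is
    the combined SD divided by the coverage.  ``combined_se`` propagates
    the per-cell Monte-Carlo SE (``sd / sqrt(2(n_boot - 1))``) and is used
    as the noise scale for monotonicity diagnostics.
    """
    sd = grid.sd.sort_index(axis=1)
    combined = sd.sum(axis=0)
    cell_se = sd / np.sqrt(2 * (grid.n_boot - 1))
    combined_se = np.sqrt((cell_se**2).sum(axis=0))
    table = pd.DataFrame(
        {
            "coverage": combined.index.to_numpy(dtype=int),
            "combined_sd": combined.to_numpy(),
            "combined_se": combined_se.to_numpy(),
        }
    )
    table["cost"] = table["combined_sd"] / table["coverage"]
    return CostCurve(table=table.reset_index(drop=True), n_boot=grid.n_boot)


def recommend_cutoff(
    curve: CostCurve, marginal_gain: float = DEFAULT_MARGINAL_GAIN
) -> int:
    """Smallest grid coverage where extra depth buys little accuracy.

    The combined SD decays as ``k / sqrt(c)``; under that model the
    relative SD reduction per additional 100x coverage is ``50 / c``,
    independent of ``k``.  The recommendation is the smallest grid
    coverage with ``50 / c <= marginal_gain`` (5% by default, i.e. 1000x
    on the default grid).

    Raises :class:`DiagnosticError` when the curve is degenerate (no
    accuracy gradient, e.g. a single fully (un)methylated level) or
    increases beyond Monte-Carlo tolerance.
    """
    t = curve.table.sort_values("coverage").reset_index(drop=True)
    if len(t) < 3:
        raise ConfigurationError("need at least 3 grid coverages")
    if not 0 < marginal_gain < 1:
        raise ConfigurationError("marginal_gain must lie in (0, 1)")
    if t["combined_sd"].max() <= 1e-9:
        raise DiagnosticError(
            "combined SD is zero everywhere; no finite recommendation"
        )
    sd = t["combined_sd"].to_numpy()
    se = t["combined_se"].to_numpy()
    rises = sd[1:] - sd[:-1]
    tol = 3.0 * np.sqrt(se[1:] ** 2 + se[:-1] ** 2) + 1e-12
    if np.any(rises > tol):
        where = int(np.argmax(rises > tol))
        raise DiagnosticError(
            f"combined SD increases from coverage {t['coverage'][where]} to "
            f"{t['coverage'][where + 1]} beyond Monte-Carlo tolerance"
        )
    threshold = 50.0 / marginal_gain
    eligible = t.loc[t["coverage"] >= threshold, "coverage"]
    if eligible.empty:
        raise DiagnosticError(
            f"no grid coverage reaches the {marginal_gain:.0%} marginal-gain "
            "criterion; extend the grid"
        )
    return int(eligible.iloc[0])
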