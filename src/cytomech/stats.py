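"""Damage and viability statistics.

Membrane elements whose maximum principal strain exceeds a tensile
threshold (default 20%) are counted as damaged (DE).  The reduction of
damage under cyclic relative to static compression is expressed as

    percentage difference of DE = (1 - DE_cyclic / DE_static) * 100%

and compared against the cell death rate ND / T * 100% from live/dead
counts.  Correlations between filament angle and membrane strain use
Pearson's r with a Kolmogorov--Smirnov normality pre-check (recorded as a
flag, not a gate); group comparisons use Student's t-test for two groups
and one-way ANOVA for more, with significance tiers at 0.05 / 0.01 / 0.001.
No multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .synthetic import generate_viability_counts


class UndefinedRatioError(ZeroDivisionError):
    """Denominator count is zero."""


class UndefinedCorrelationError(ValueError):
    """A variable has zero variance; Pearson r is undefined."""


@dataclass
class DamageReport:
    DE_static: int
    DE_cyclic: int
    percentage_difference: float  # %
    strain_threshold: float = 0.20


@dataclass
class ViabilityRecord:
    ND: int
    T: int

    @property
    def death_rate(self) -> float:
        return cell_death_rate(self.ND, self.T)


@dataclass
class CorrelationResult:
    r: float
    p_value: float
    n: int
    normality_passed: tuple[bool, bool]


def damaged_elements(membrane_strains, threshold: float = 0.20) -> int:
    """Count membrane elements with max principal strain strictly above threshold.

    A value exactly equal to the threshold is not counted (strict
    inequality), making the boundary rule explicit and testable.
    """
    arr = np.asarray(list(membrane_strains), dtype=float)
    if arr.size == 0:
        raise ValueError("empty strain set")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite strains")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    return int(np.count_nonzero(arr > threshold))


def percentage_difference(DE_cyclic: int, DE_static: int) -> float:
    """(1 - DE_cyclic / DE_static) * 100; negative if cyclic exceeds static."""
    if DE_static == 0:
        raise UndefinedRatioError("DE_static is zero; ratio undefined")
    if DE_cyclic < 0 or DE_static < 0:
        raise ValueError("element counts must be non-negative")
    return (1.0 - DE_cyclic / DE_static) * 100.0


def cell_death_rate(ND: int, T: int) -> float:
    """Dead cells over total cells as a percentage: ND / T * 100."""
    if T < 1:
        raise ValueError("T must be >= 1")
    if ND < 0 or ND > T:
        raise ValueError("require 0 <= ND <= T")
    return ND / T * 100.0


def correlate(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with a Kolmogorov--Smirnov normality pre-check.

    Each variable is standardised and tested against the standard normal;
    the pass/fail flags are recorded but do not gate the correlation.
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.std(xa) == 0 or np.std(ya) == 0:
        raise UndefinedCorrelationError("a variable has zero variance")
    flags = []
    for v in (xa, ya):
        z = (v - v.mean()) / v.std(ddof=1)
        ks = sps.kstest(z, "norm")
        flags.append(bool(ks.pvalue > alpha))
    r, p = sps.pearsonr(xa, ya)
    return CorrelationResult(r=float(r), p_value=float(p), n=int(xa.size),
                             normality_passed=(flags[0], flags[1]))


def significance_tier(p: float) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001, ns otherwise."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def compare_groups(*groups):
    """Two groups -> Student's t-test; more -> one-way ANOVA.

    Returns a dict with the test name, statistic, p-value and the
    significance tier.
    """
    gs = [np.asarray(list(g), dtype=float) for g in groups]
    if len(gs) < 2:
        raise ValueError("need at least two groups")
    for g in gs:
        if g.size < 2:
            raise ValueError("each group needs at least two samples")
    if len(gs) == 2:
        res = sps.ttest_ind(gs[0], gs[1])
        name = "t-test"
    else:
        res = sps.f_oneway(*gs)
        name = "anova"
    p = float(res.pvalue)
    if np.isnan(p) and all(np.std(g) == 0 for g in gs) and \
            len({g.mean() for g in gs}) == 1:
        p = 1.0  # identical constant groups: no evidence of difference
    return {"test": name, "statistic": float(res.statistic), "p_value": p,
            "significance": significance_tier(p)}


def simulate_death_rate(avg_membrane_strain: float, T: int = 300,
                        baseline: float = 0.02, slope: float = 2.0,
                        seed: int = 0) -> ViabilityRecord:
    """Viability counts from a strain-driven death model.

    Death probability rises linearly with the average membrane strain
    (clipped to [0, 1]); dead counts are binomial draws, so replicate
    records carry realistic sampling noise.
    """
    p = float(np.clip(baseline + slope * avg_membrane_strain, 0.0, 1.0))
    nd, t = generate_viability_counts(p, T, seed=seed)
    return ViabilityRecord(ND=nd, T=t)
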