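"""Comparison statistics for paired PPA/GPE disturbance rates.

The comparison layer of the analysis: two-sided paired t-tests per ecozone
(alpha = 0.05, no multiple-testing correction by default, matching the
per-ecozone reporting convention; an optional Holm adjustment is available),
Pearson correlation of unit rates, a symmetric relative-difference index
bounded in [-200, 200], the fraction of units above an occurrence threshold,
latitude binning to the nearest degree, and a north/south mean split.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps

from .errors import (
    PairingError,
    PreconditionError,
    UndefinedCorrelationError,
    UndefinedStatisticError,
)

DEFAULT_ALPHA = 0.05
OCCURRENCE_THRESHOLD = 0.1  # % of area disturbed per year
LATITUDE_SPLIT_DEG = 55.0


@dataclass(frozen=True)
class ComparisonResult:
    ecozone: str
    agent: str
    n_pairs: int
    mean_ppa: float
    mean_gpe: float
    t_stat: float
    p_value: float
    significant: bool
    defined: bool


@dataclass(frozen=True)
class CorrelationResult:
    agent: str
    r: float
    n: int
    defined: bool = True


@dataclass(frozen=True)
class LatitudeSummary:
    bin_degree: int
    agent: str
    mean_ppa_rate: float
    mean_gpe_rate: float
    n_units: int


def paired_ttest(
    ppa_rates: Sequence[float],
    gpe_rates: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    ecozone: str = "",
    agent: str = "",
) -> ComparisonResult:
    """Classical two-sided paired t-test on per-unit rate pairs.

    d = ppa - gpe; t = mean(d) / (sd(d)/sqrt(n)) with n-1 degrees of
    freedom.  Zero-variance differences make the statistic undefined; such
    results carry ``defined = False`` and claim no significance.
    """
    ppa = np.asarray(ppa_rates, dtype=float)
    gpe = np.asarray(gpe_rates, dtype=float)
    if ppa.shape != gpe.shape:
        raise PairingError(f"length mismatch: {ppa.shape[0]} vs {gpe.shape[0]}")
    n = ppa.shape[0]
    if n < 2:
        raise PreconditionError("paired t-test requires at least 2 pairs")
    d = ppa - gpe
    # zero-variance differences up to float rounding (e.g. an exact constant
    # shift) make the statistic undefined rather than arbitrarily huge
    scale = max(1.0, float(np.max(np.abs(d))))
    if np.std(d, ddof=1) <= 1e-12 * scale:
        return ComparisonResult(
            ecozone, agent, n, float(ppa.mean()), float(gpe.mean()),
            float("nan"), float("nan"), significant=False, defined=False,
        )
    t_stat, p_value = sps.ttest_rel(ppa, gpe)
    return ComparisonResult(
        ecozone,
        agent,
        n,
        float(ppa.mean()),
        float(gpe.mean()),
        float(t_stat),
        float(p_value),
        significant=bool(p_value < alpha),
        defined=True,
    )


def pearson_r(x: Sequence[float], y: Sequence[float], agent: str = "") -> CorrelationResult:
    """Product-moment correlation between paired unit rates."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise PairingError(f"length mismatch: {x.shape[0]} vs {y.shape[0]}")
    if x.shape[0] < 2:
        raise PreconditionError("correlation requires at least 2 pairs")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedCorrelationError("zero variance in one of the vectors")
    r, _ = sps.pearsonr(x, y)
    return CorrelationResult(agent=agent, r=float(r), n=int(x.shape[0]))


def correlation_summary(x, y, agent: str = "") -> CorrelationResult:
    """Like :func:`pearson_r`, but a constant vector yields r = 0 with
    ``defined = False`` — no linear association is measurable."""
    try:
        return pearson_r(x, y, agent=agent)
    except UndefinedCorrelationError:
        return CorrelationResult(agent=agent, r=0.0, n=len(x), defined=False)


def relative_difference(ppa_d: float, gpe_d: float) -> float:
    """100 * (PPA_D - GPE_D) / mean(PPA_D, GPE_D); antisymmetric, in [-200, 200].

    Undefined (raises) when both rates are zero.
    """
    if ppa_d < 0 or gpe_d < 0:
        raise PreconditionError("rates must be non-negative")
    if ppa_d == 0.0 and gpe_d == 0.0:
        raise UndefinedStatisticError("relative difference undefined for two zero rates")
    denom = (ppa_d + gpe_d) / 2.0
    if denom == 0.0:
        # subnormal rates whose mean underflows: return the formula's limit
        return 200.0 if ppa_d > gpe_d else -200.0 if gpe_d > ppa_d else 0.0
    # clamp float rounding at the formula's exact extremes (one rate zero)
    return float(np.clip(100.0 * (ppa_d - gpe_d) / denom, -200.0, 200.0))


def pct_units_disturbed(
    rates: Sequence[float], threshold: float = OCCURRENCE_THRESHOLD
) -> float:
    """Percent of units with rate strictly above ``threshold`` (%/yr)."""
    rates = np.asarray(rates, dtype=float)
    if rates.size == 0:
        raise UndefinedStatisticError("no units")
    return 100.0 * float((rates > threshold).sum()) / rates.size


def round_half_away(x) -> np.ndarray:
    """Round to nearest integer, ties away from zero (np.round ties to even)."""
    x = np.asarray(x, dtype=float)
    return (np.sign(x) * np.floor(np.abs(x) + 0.5)).astype(int)


def bin_by_latitude(
    latitudes: Sequence[float],
    ppa_rates: Sequence[float],
    gpe_rates: Sequence[float],
    agent: str = "",
) -> List[LatitudeSummary]:
    """Unweighted mean PPA and GPE rates per integer-degree latitude bin."""
    lats = np.asarray(latitudes, dtype=float)
    ppa = np.asarray(ppa_rates, dtype=float)
    gpe = np.asarray(gpe_rates, dtype=float)
    bins = round_half_away(lats)
    out = []
    for b in sorted(set(int(v) for v in bins)):
        sel = bins == b
        out.append(
            LatitudeSummary(
                bin_degree=b,
                agent=agent,
                mean_ppa_rate=float(ppa[sel].mean()),
                mean_gpe_rate=float(gpe[sel].mean()),
                n_units=int(sel.sum()),
            )
        )
    return out


def split_by_latitude(
    latitudes: Sequence[float],
    rates: Sequence[float],
    threshold_deg: float = LATITUDE_SPLIT_DEG,
) -> Tuple[Optional[float], Optional[float]]:
    """Pooled unweighted mean rate below vs at-or-above a latitude threshold.

    Units exactly at the threshold count as "above".  An empty side yields
    None for that mean.
    """
    lats = np.asarray(latitudes, dtype=float)
    rates = np.asarray(rates, dtype=float)
    below = rates[lats < threshold_deg]
    above = rates[lats >= threshold_deg]
    mean_below = float(below.mean()) if below.size else None
    mean_above = float(above.mean()) if above.size else None
    return mean_below, mean_above


def holm_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional multiplicity control)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj
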