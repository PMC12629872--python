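"""Geometric-mean fluorescence intensity (GMFI) and expression-pattern metrics.

The GMFI of a gated population on one channel is exp(mean(ln intensity)) on
linear scale.  Stained-vs-FMO comparison and tail/top-heavy/bottom-heavy
pattern labels live here; significance testing belongs to cohort_stats.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .gating import PopulationCall
from .listmode_io import EventTable

__all__ = [
    "GMFIResult",
    "FMOComparison",
    "PatternMetrics",
    "InadequatePopulationError",
    "gmfi",
    "population_gmfi",
    "fmo_compare",
    "pattern_metrics",
]

#: default minimum events for a reportable population GMFI / pattern
MIN_EVENTS = 50
#: tolerated fraction of nonpositive intensities (dropped with a warning)
NONPOSITIVE_LIMIT = 0.01
#: |log-skewness| below which a fully shifted population counts as uniform
SKEW_UNIFORM = 0.5


class InadequatePopulationError(ValueError):
    """Population too small (or otherwise ineligible) for GMFI reporting."""


@dataclass(frozen=True)
class GMFIResult:
    population: str
    marker: str
    n: int
    gmfi: float
    log_gmfi: float


@dataclass(frozen=True)
class FMOComparison:
    stained: GMFIResult
    fmo: GMFIResult
    log_ratio: float
    above_background: bool


@dataclass(frozen=True)
class PatternMetrics:
    tail_fraction: float
    log_skewness: float
    label: str          # uniform | tail | top_heavy | bottom_heavy


def _clean_positive(values: np.ndarray, limit: float = NONPOSITIVE_LIMIT) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("no values")
    bad = values <= 0
    n_bad = int(bad.sum())
    if n_bad == values.size:
        raise ValueError("all values are nonpositive")
    frac = n_bad / values.size
    if frac > limit:
        raise ValueError(
            f"nonpositive fraction {frac:.3f} exceeds limit {limit:.3f}"
        )
    if n_bad:
        warnings.warn(
            f"dropping {n_bad} nonpositive value(s) ({frac:.2%}) before GMFI",
            stacklevel=3,
        )
        values = values[~bad]
    return values


def gmfi(values, nonpositive_limit: float = NONPOSITIVE_LIMIT) -> float:
    """Geometric mean of positive linear intensities: exp(mean(ln v)).

    Nonpositive values are dropped (with a warning) when they make up at
    most ``nonpositive_limit`` of the input, otherwise an error is raised.
    """
    v = _clean_positive(np.asarray(values, dtype=np.float64), nonpositive_limit)
    return float(np.exp(np.mean(np.log(v))))


def population_gmfi(
    table: EventTable,
    call: PopulationCall,
    marker: str = "CD9",
    min_events: int = MIN_EVENTS,
) -> GMFIResult:
    """GMFI of one marker over a gated population's member events.

    Refuses populations below the adequacy floor (default 50 events),
    mirroring clinical practice of not reporting under-sized populations.
    """
    if call.n < min_events or not call.evaluable:
        raise InadequatePopulationError(
            f"population {call.label!r} has {call.n} events "
            f"(< {min_events}); GMFI not reported"
        )
    values = table.marker(marker)[call.indices]
    g = gmfi(values)
    return GMFIResult(
        population=call.label,
        marker=marker,
        n=call.n,
        gmfi=g,
        log_gmfi=math.log(g),
    )


def fmo_compare(
    stained: GMFIResult, fmo: GMFIResult, margin: float = 0.0
) -> FMOComparison:
    """Stained vs FMO GMFI on one population/marker.

    ``above_background`` is true when the log-ratio exceeds ``margin``
    (default 0: any positive ratio counts).
    """
    if stained.population != fmo.population or stained.marker != fmo.marker:
        raise ValueError(
            f"mismatched comparison: {stained.population}/{stained.marker} vs "
            f"{fmo.population}/{fmo.marker}"
        )
    log_ratio = stained.log_gmfi - fmo.log_gmfi
    return FMOComparison(
        stained=stained,
        fmo=fmo,
        log_ratio=log_ratio,
        above_background=log_ratio > margin,
    )


def pattern_metrics(
    values,
    positivity_threshold: float,
    min_events: int = MIN_EVENTS,
    skew_cutoff: float = SKEW_UNIFORM,
) -> PatternMetrics:
    """Classify a population's expression pattern against a background threshold.

    tail_fraction is the share of events above the positivity threshold.
    Labels:

    - ``uniform``      — nearly all events on one side of the threshold with
      no pronounced log-skew (uniformly dim, or a whole-population shift);
    - ``tail``         — a distinct brighter subset (tail_fraction in
      [0.1, 0.5) with clear positive log-skew);
    - ``bottom_heavy`` — bulk dim with the distribution straddling the
      threshold (tail_fraction in [0.1, 0.5), no distinct subset);
    - ``top_heavy``    — majority of events above the threshold.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size < min_events:
        raise ValueError(f"need >= {min_events} values, got {values.size}")
    v = _clean_positive(values)
    tail_fraction = float(np.mean(v > positivity_threshold))
    log_skew = float(stats.skew(np.log(v)))
    if tail_fraction < 0.1:
        label = "uniform"
    elif tail_fraction >= 0.5:
        if tail_fraction > 0.9 and abs(log_skew) < skew_cutoff:
            label = "uniform"
        else:
            label = "top_heavy"
    else:
        label = "tail" if log_skew > skew_cutoff else "bottom_heavy"
    return PatternMetrics(
        tail_fraction=tail_fraction, log_skewness=log_skew, label=label
    )
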