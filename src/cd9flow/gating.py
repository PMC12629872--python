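"""Hierarchical gating of listmode events into analysis populations.

The gating tree mirrors routine leukemia immunophenotyping practice:

1. singlet gate  — drop events with elevated FSC_A/FSC_H ratio (doublets);
2. debris gate   — drop low-FSC particles;
3. primary gates on CD45 vs side scatter — lymphocytes (high CD45, low
   SSC), monocytes (high CD45, intermediate SSC), granulocytes (variable
   CD45, high SSC) and blasts (dim CD45, low SSC);
4. terminal sub-gates: CD34+/CD19- myeloid blasts (with immature-B
   exclusion via CD10/CD19/CD22/CD24), the granulocytic CD24-vs-CD10 split
   into promyelocytes / myelocytes / neutrophils, marker-refined monocytes,
   CD19+CD20+CD10- mature B cells, and CD10+CD19+CD38+ hematogones split
   into stages 1 and 2.

Myelocytes are gated but flagged for exclusion from downstream CD9
quantification because eosinophils (bright CD9) land in the same
CD24+/CD10- region.  CD9 is never consulted by any gate.

Qualitative descriptors ("dim", "high", "intermediate") are quantified as
configurable threshold defaults calibrated to the synthetic presets;
positivity thresholds default to a fixed value and are replaced by the 99th
percentile of an FMO control when one is supplied.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .listmode_io import EventTable

__all__ = [
    "GatingConfig",
    "Thresholds",
    "GateDef",
    "GatingTree",
    "PopulationCall",
    "GatingResult",
    "exclude_doublets",
    "exclude_debris",
    "calibrate_thresholds",
    "build_default_tree",
    "apply_gating",
    "split_hsc_cmp",
    "gate_sample",
]

#: terminal populations quantified downstream (myelocytes gated, excluded)
TERMINAL_LABELS: tuple[str, ...] = (
    "myeloid_blast", "promyelocyte", "myelocyte", "neutrophil", "monocyte",
    "mature_B", "hematogone1", "hematogone2",
)


@dataclass(frozen=True)
class GatingConfig:
    """Tunable gating parameters (linear intensity units unless noted)."""

    min_events: int = 50                   # adequacy floor for GMFI reporting
    hsc_eligibility_fraction: float = 0.30 # HSC share of CD34+/CD19- progenitors
    doublet_ratio_threshold: float = 1.4   # FSC_A / FSC_H
    debris_fsc_threshold: float = 20_000.0
    cd45_high: float = 25_000.0            # lymphocyte/monocyte CD45 floor
    cd45_dim_low: float = 1_500.0          # blast-gate CD45 floor
    ssc_low_max: float = 25_000.0          # low/intermediate SSC boundary
    ssc_high_min: float = 80_000.0         # intermediate/high SSC boundary
    positivity_default: float = 1_000.0    # per-marker +/- threshold fallback
    cd9_positivity_default: float = 2_000.0  # ~99th pct of blast CD9 background
    fmo_quantile: float = 0.99             # positivity from FMO background
    cd19_bright_factor: float = 10.0       # "bright" CD19 = factor x threshold
    cd34_negative_floor: float = 0.20      # CD34+ share triggering fallback

    def __post_init__(self) -> None:
        if self.min_events < 1:
            raise ValueError("min_events must be >= 1")
        if not (0.0 < self.hsc_eligibility_fraction < 1.0):
            raise ValueError("hsc_eligibility_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GatingConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path


@dataclass(frozen=True)
class Thresholds:
    """Resolved numeric gate boundaries for one sample."""

    positivity: dict[str, float]
    cd45_high: float
    cd45_dim_low: float
    ssc_low_max: float
    ssc_high_min: float
    fmo_derived: tuple[str, ...] = ()

    def positive(self, table: EventTable, marker: str) -> np.ndarray:
        return table.marker(marker) > self.positivity[marker]


_GATING_MARKERS = (
    "CD45", "CD10", "CD19", "CD20", "CD22", "CD24", "CD34", "CD38", "CD58",
)


def calibrate_thresholds(
    table: EventTable,
    fmo_table: EventTable | None = None,
    config: GatingConfig | None = None,
) -> Thresholds:
    """Resolve positivity and CD45/SSC boundaries for a sample.

    With an FMO control the CD9 positivity threshold is the
    ``fmo_quantile``-th CD9 percentile of the FMO's own gated myeloid-blast
    population (the FMO is gated identically — gating is CD9-blind — so the
    background is measured on the population actually being assessed); when
    the FMO blast population is inadequate, the whole FMO event cloud is
    used.  Only CD9 gains an FMO-derived threshold since the FMO omits only
    the CD9 stain; all other markers use the configured default.
    Deterministic for fixed inputs.
    """
    config = config or GatingConfig()
    positivity = {m: config.positivity_default for m in _GATING_MARKERS}
    # the analyte channel's fallback approximates the 99th percentile of the
    # dim (blast) background rather than lymphocyte autofluorescence
    positivity["CD9"] = config.cd9_positivity_default
    fmo_derived: tuple[str, ...] = ()
    if fmo_table is not None:
        cd9 = fmo_table.marker("CD9")
        if cd9.size:
            fmo_gated = apply_gating(fmo_table, config=config)
            blast = next(c for c in fmo_gated if c.label == "myeloid_blast")
            background = cd9[blast.indices] if blast.evaluable else cd9
            positivity["CD9"] = float(np.quantile(background, config.fmo_quantile))
            fmo_derived = ("CD9",)
    return Thresholds(
        positivity=positivity,
        cd45_high=config.cd45_high,
        cd45_dim_low=config.cd45_dim_low,
        ssc_low_max=config.ssc_low_max,
        ssc_high_min=config.ssc_high_min,
        fmo_derived=fmo_derived,
    )


# ---------------------------------------------------------------------------
# gate definitions
# ---------------------------------------------------------------------------

#: a condition is (marker, op, value) with op in {"<", "<=", ">", ">=", "between"}
Condition = tuple


@dataclass(frozen=True)
class GateDef:
    """Conjunction of threshold comparisons over marker values."""

    name: str
    conditions: tuple[Condition, ...]

    def mask(self, table: EventTable) -> np.ndarray:
        out = np.ones(table.n_events, dtype=bool)
        for marker, op, value in self.conditions:
            x = table.marker(marker)
            if op == "<":
                out &= x < value
            elif op == "<=":
                out &= x <= value
            elif op == ">":
                out &= x > value
            elif op == ">=":
                out &= x >= value
            elif op == "between":
                lo, hi = value
                out &= (x >= lo) & (x < hi)
            else:
                raise ValueError(f"unknown op {op!r} in gate {self.name}")
        return out

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GatingTree:
    """Primary CD45-vs-SSC gates plus the thresholds terminals rely on."""

    primary: dict[str, GateDef]
    thresholds: Thresholds

    def to_dict(self) -> dict:
        return {
            "primary": {k: g.to_dict() for k, g in self.primary.items()},
            "thresholds": asdict(self.thresholds),
        }


def build_default_tree(thresholds: Thresholds) -> GatingTree:
    t = thresholds
    primary = {
        "lymphocyte": GateDef(
            "lymphocyte",
            ((("CD45"), ">", t.cd45_high), (("SSC"), "<", t.ssc_low_max)),
        ),
        "monocyte": GateDef(
            "monocyte",
            ((("CD45"), ">", t.cd45_high),
             (("SSC"), "between", (t.ssc_low_max, t.ssc_high_min))),
        ),
        "granulocyte": GateDef("granulocyte", ((("SSC"), ">=", t.ssc_high_min),)),
        "blast": GateDef(
            "blast",
            ((("CD45"), "between", (t.cd45_dim_low, t.cd45_high)),
             (("SSC"), "<", t.ssc_low_max)),
        ),
    }
    return GatingTree(primary=primary, thresholds=t)


@dataclass(frozen=True)
class PopulationCall:
    """A gated population: label, member rows, adequacy flag, provenance."""

    label: str
    indices: np.ndarray
    evaluable: bool
    provenance: str

    @property
    def n(self) -> int:
        return len(self.indices)


def _call(
    label: str, mask_or_idx: np.ndarray, config: GatingConfig, provenance: str
) -> PopulationCall:
    idx = (
        np.flatnonzero(mask_or_idx)
        if mask_or_idx.dtype == bool
        else np.asarray(mask_or_idx)
    )
    return PopulationCall(
        label=label,
        indices=idx,
        evaluable=len(idx) >= config.min_events,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# exclusions
# ---------------------------------------------------------------------------

def exclude_doublets(
    table: EventTable, ratio_threshold: float | None = None
) -> tuple[EventTable, np.ndarray]:
    """Drop events whose FSC_A/FSC_H ratio exceeds the doublet threshold.

    Returns the surviving table (event order preserved) and the removed row
    indices of the input table.
    """
    thr = GatingConfig().doublet_ratio_threshold if ratio_threshold is None else ratio_threshold
    if table.n_events == 0:
        return table, np.array([], dtype=int)
    fsc_h = table.marker("FSC_H")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = table.marker("FSC_A") / fsc_h
    removed = np.flatnonzero(~(ratio < thr))
    keep = np.flatnonzero(ratio < thr)
    return table.subset(keep), removed


def exclude_debris(
    table: EventTable, fsc_threshold: float | None = None
) -> tuple[EventTable, np.ndarray]:
    """Drop low-forward-scatter particles (debris)."""
    thr = GatingConfig().debris_fsc_threshold if fsc_threshold is None else fsc_threshold
    if table.n_events == 0:
        return table, np.array([], dtype=int)
    fsc = table.marker("FSC_A")
    removed = np.flatnonzero(fsc < thr)
    return table.subset(np.flatnonzero(fsc >= thr)), removed


# ---------------------------------------------------------------------------
# terminal gating
# ---------------------------------------------------------------------------

def _b_lineage_mask(table: EventTable, t: Thresholds, config: GatingConfig) -> np.ndarray:
    """Events excluded from the myeloid-blast call as immature B cells.

    Isolated weak/partial CD19 is not sufficient: exclusion requires at
    least two B-lineage signals among CD10+, CD22+, CD24+ and bright CD19.
    """
    bright_cd19 = table.marker("CD19") > config.cd19_bright_factor * t.positivity["CD19"]
    score = (
        t.positive(table, "CD10").astype(int)
        + t.positive(table, "CD22").astype(int)
        + t.positive(table, "CD24").astype(int)
        + bright_cd19.astype(int)
    )
    return score >= 2


def apply_gating(
    table: EventTable,
    tree: GatingTree | None = None,
    config: GatingConfig | None = None,
) -> list[PopulationCall]:
    """Assign post-exclusion events to the terminal analysis populations.

    Returns calls for myeloid_blast, promyelocyte, myelocyte (flagged
    excluded-from-analysis in provenance), neutrophil, monocyte, mature_B,
    hematogone1 and hematogone2.  Terminal populations are pairwise
    disjoint.  CD9 is never read.
    """
    config = config or GatingConfig()
    if tree is None:
        tree = build_default_tree(calibrate_thresholds(table, config=config))
    t = tree.thresholds
    calls: list[PopulationCall] = []

    lymph = tree.primary["lymphocyte"].mask(table)
    mono_gate = tree.primary["monocyte"].mask(table)
    gran = tree.primary["granulocyte"].mask(table)
    blast_gate = tree.primary["blast"].mask(table)

    cd10 = t.positive(table, "CD10")
    cd19 = t.positive(table, "CD19")
    cd24 = t.positive(table, "CD24")
    cd22 = t.positive(table, "CD22")
    cd34 = t.positive(table, "CD34")
    cd38 = t.positive(table, "CD38")
    cd20 = t.positive(table, "CD20")

    # granulocyte gate: CD24 vs CD10 split
    calls.append(_call("promyelocyte", gran & ~cd24 & ~cd10, config,
                       "granulocyte>CD24-CD10-"))
    calls.append(_call("myelocyte", gran & cd24 & ~cd10, config,
                       "granulocyte>CD24+CD10- [excluded from CD9 analysis: "
                       "eosinophil coincidence]"))
    calls.append(_call("neutrophil", gran & cd24 & cd10, config,
                       "granulocyte>CD24+CD10+"))

    # monocyte gate refined to exclude granulocyte/lymphocyte spillover
    calls.append(_call("monocyte", mono_gate & ~cd10 & ~cd19 & ~cd22 & ~cd24,
                       config, "monocyte>CD10-CD19-CD22-CD24-"))

    # lymphocyte gate: mature B cells
    calls.append(_call("mature_B", lymph & cd19 & cd20 & ~cd10, config,
                       "lymphocyte>CD19+CD20+CD10-"))

    # blast gate: hematogones first (CD10+CD19+CD38+), staged by CD34 with a
    # CD10/CD19/CD45 linear-discriminant fallback for CD34-ambiguous events
    hg = blast_gate & cd10 & cd19 & cd38
    hg_idx = np.flatnonzero(hg)
    if hg_idx.size:
        cd34_pos_hg = cd34[hg_idx]
        lcd10 = np.log(np.maximum(table.marker("CD10")[hg_idx], 1e-9))
        lcd19 = np.log(np.maximum(table.marker("CD19")[hg_idx], 1e-9))
        lcd45 = np.log(np.maximum(table.marker("CD45")[hg_idx], 1e-9))
        # stage 1: brighter CD10, dimmer CD19/CD45, CD34 mostly present
        disc = lcd10 - lcd19 - lcd45  # larger => stage 1
        if cd34_pos_hg.any() and (~cd34_pos_hg).any():
            # linear-discriminant fallback for CD34-ambiguous events: the
            # boundary is the midpoint between the CD34+ and CD34- centroids
            boundary = 0.5 * (disc[cd34_pos_hg].mean() + disc[~cd34_pos_hg].mean())
        else:
            boundary = np.median(disc)
        stage1 = np.where(cd34_pos_hg, True, disc > boundary)
    else:
        stage1 = np.array([], dtype=bool)
    calls.append(_call("hematogone1", hg_idx[stage1], config,
                       "blast>CD10+CD19+CD38+>stage1"))
    calls.append(_call("hematogone2", hg_idx[~stage1], config,
                       "blast>CD10+CD19+CD38+>stage2"))

    # blast gate: myeloid blasts = CD34+, CD19-, non-B, non-hematogone
    b_excl = _b_lineage_mask(table, t, config)
    candidates = blast_gate & ~hg & ~b_excl
    cd34_blast = candidates & cd34 & ~cd19
    n_cand = int(candidates.sum())
    cd34_frac = cd34_blast.sum() / n_cand if n_cand else 0.0
    if n_cand and cd34_frac < config.cd34_negative_floor:
        # CD34-negative/subset-positive leukemia: take the whole dim-CD45
        # low-SSC non-B blast cloud
        calls.append(_call("myeloid_blast", candidates, config,
                           "blast>non-B [CD34-negative fallback]"))
    else:
        calls.append(_call("myeloid_blast", cd34_blast, config,
                           "blast>CD34+CD19-non-B"))

    return calls


def split_hsc_cmp(
    blast_call: PopulationCall,
    table: EventTable,
    config: GatingConfig | None = None,
    thresholds: Thresholds | None = None,
) -> tuple[PopulationCall, PopulationCall, bool]:
    """Partition the CD34+/CD19- myeloid-blast call by CD38.

    HSC = CD38 decreased-to-absent, CMP = CD38 positive.  Eligibility for
    the HSC-vs-CMP comparison requires the HSC share of the progenitors to
    strictly exceed the configured fraction (default 30%).
    """
    config = config or GatingConfig()
    thr = (
        thresholds.positivity["CD38"]
        if thresholds is not None
        else config.positivity_default
    )
    idx = blast_call.indices
    if idx.size == 0:
        empty = np.array([], dtype=int)
        return (
            _call("myeloid_blast_HSC", empty, config, blast_call.provenance + ">CD38dim"),
            _call("myeloid_blast_CMP", empty, config, blast_call.provenance + ">CD38+"),
            False,
        )
    cd38 = table.marker("CD38")[idx]
    hsc_idx = idx[cd38 <= thr]
    cmp_idx = idx[cd38 > thr]
    hsc = _call("myeloid_blast_HSC", hsc_idx, config, blast_call.provenance + ">CD38dim")
    cmp_ = _call("myeloid_blast_CMP", cmp_idx, config, blast_call.provenance + ">CD38+")
    eligible = hsc.n / blast_call.n > config.hsc_eligibility_fraction
    return hsc, cmp_, eligible


# ---------------------------------------------------------------------------
# one-call orchestration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GatingResult:
    """Terminal calls (indices into the ORIGINAL table) plus bookkeeping."""

    calls: dict[str, PopulationCall]
    hsc: PopulationCall
    cmp: PopulationCall
    hsc_cmp_eligible: bool
    removed_doublets: np.ndarray
    removed_debris: np.ndarray
    thresholds: Thresholds

    def event_labels(self, n_events: int) -> np.ndarray:
        """Per-original-event assignment ('ungated' where no terminal fired)."""
        out = np.full(n_events, "ungated", dtype=object)
        for call in self.calls.values():
            out[call.indices] = call.label
        out[self.removed_doublets] = "doublet"
        out[self.removed_debris] = "debris"
        return out


def gate_sample(
    table: EventTable,
    fmo_table: EventTable | None = None,
    config: GatingConfig | None = None,
) -> GatingResult:
    """Run exclusions, threshold calibration, gating and the HSC/CMP split.

    All returned indices refer to rows of the input table.
    """
    config = config or GatingConfig()
    singlets, removed_doublets = exclude_doublets(table, config.doublet_ratio_threshold)
    kept1 = np.setdiff1d(np.arange(table.n_events), removed_doublets, assume_unique=True)
    intact, removed_debris_local = exclude_debris(singlets, config.debris_fsc_threshold)
    removed_debris = kept1[removed_debris_local]
    kept = np.setdiff1d(kept1, removed_debris, assume_unique=True)

    thresholds = calibrate_thresholds(intact, fmo_table, config)
    tree = build_default_tree(thresholds)
    calls = {}
    for call in apply_gating(intact, tree, config):
        calls[call.label] = PopulationCall(
            label=call.label,
            indices=kept[call.indices],
            evaluable=call.evaluable,
            provenance=call.provenance,
        )
    hsc, cmp_, eligible = split_hsc_cmp(
        calls["myeloid_blast"], table, config, thresholds
    )
    return GatingResult(
        calls=calls,
        hsc=hsc,
        cmp=cmp_,
        hsc_cmp_eligible=eligible,
        removed_doublets=removed_doublets,
        removed_debris=removed_debris,
        thresholds=thresholds,
    )
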