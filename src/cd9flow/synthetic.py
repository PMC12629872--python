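"""Seeded synthetic bone-marrow / blood samples with ground-truth labels.

Each sample is a lognormal mixture over the hematopoietic populations that a
CD45-vs-side-scatter gating strategy resolves: myeloid blasts (split into
hematopoietic stem cells, HSC, and committed myeloid progenitors, CMP),
granulocytic precursors, neutrophils, eosinophils, monocytes, mature B
cells, stage-1/2 hematogones, other lymphocytes, and (for leukemic presets)
a dominant leukemic-blast population.  Every channel of every population is
drawn lognormal(mu, sigma) on linear fluorescence scale, with an optional
two-component "tail" mixture for populations that show a subset of brighter
expression.  Doublets are sums of two singlet events on area-like channels
with FSC_H inherited from the larger parent; debris sits at low FSC/SSC with
near-autofluorescence marker levels.

CD9 calibration targets come from published cohort GMFI ranges per
population and per AML subtype; those ranges are encoded below and presets
draw per-sample CD9 locations inside them.

Randomness discipline: each channel owns an independent child stream of the
sample seed, and event counts own their own stream.  An FMO variant (CD9
antibody omitted) therefore regenerates bit-identical values on every
channel except CD9, whose values come from the population's background
(autofluorescence) distribution instead.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .listmode_io import EventTable, PanelConfig

__all__ = [
    "CHANNELS",
    "FLUOR_MARKERS",
    "POPULATION_LABELS",
    "NORMAL_CD9_RANGES",
    "AML_CD9_RANGES",
    "AML_SUBTYPES",
    "MarkerModel",
    "PopulationSpec",
    "SampleSpec",
    "TruthLabels",
    "generate_sample",
    "make_fmo",
    "preset",
    "generate_cohort",
]

#: channel order of every generated sample
CHANNELS: tuple[str, ...] = (
    "FSC_A", "FSC_H", "SSC", "CD45", "CD9", "CD10", "CD19", "CD20", "CD22",
    "CD24", "CD34", "CD38", "CD58",
)
FLUOR_MARKERS: tuple[str, ...] = (
    "CD45", "CD9", "CD10", "CD19", "CD20", "CD22", "CD24", "CD34", "CD38", "CD58",
)

POPULATION_LABELS: tuple[str, ...] = (
    "myeloid_blast_HSC", "myeloid_blast_CMP", "promyelocyte", "myelocyte",
    "neutrophil", "monocyte", "mature_B", "hematogone1", "hematogone2",
    "eosinophil", "other_lymphocyte", "leukemic_blast",
)

#: published cohort CD9 GMFI ranges (linear units) for normal populations
NORMAL_CD9_RANGES: dict[str, tuple[float, float]] = {
    "myeloid_blast": (707.0, 4662.0),
    "promyelocyte": (1315.0, 5481.0),
    "neutrophil": (737.0, 24_800.0),
    "monocyte": (1357.0, 66_487.0),
    "hematogone1": (4245.0, 29_439.0),
    "hematogone2": (5287.0, 32_269.0),
    "mature_B": (392.0, 1921.0),
}

#: published cohort CD9 GMFI ranges for leukemic myeloid blasts by AML subtype
AML_CD9_RANGES: dict[str, tuple[float, float]] = {
    "TP53": (760.0, 2124.0),
    "CBFB_MYH11": (3520.0, 14_178.0),
    "RUNX1_RUNX1T1": (1084.0, 8794.0),
    "NOS": (912.0, 5064.0),
    "MDS_rel": (580.0, 7664.0),
    "APL": (6856.0, 35_903.0),
    "NPM1": (927.0, 7661.0),
    "KMT2Ar": (7852.0, 9624.0),
}
AML_SUBTYPES: tuple[str, ...] = tuple(AML_CD9_RANGES)

#: cohort-central CD9 geometric means used as preset centres
_CD9_CENTERS: dict[str, float] = {
    "myeloid_blast_CMP": 1550.0,   # HSC = ratio * CMP, blended blast GMFI ~1615
    "promyelocyte": 2095.0,
    "neutrophil": 1818.0,
    "monocyte": 5689.0,
    "mature_B": 700.0,
    "hematogone1": 13_129.0,
    "hematogone2": 14_755.0,
}

#: HSC/CMP CD9 geometric-mean ratio in normal marrow (HSC brighter)
_HSC_CMP_RATIO = 1.5
#: G-CSF blast CD9 fold change (treated vs untreated cohort geometric means)
_GCSF_FOLD = 1845.0 / 1578.0
#: infection scenario: log-units added to blast + maturing-myeloid CD9
_INFECTION_SHIFT = 0.7

_LN = math.log


@dataclass(frozen=True)
class MarkerModel:
    """Lognormal component for one marker: exp(N(mu, sigma)), optional tail.

    The tail re-draws a fraction ``tail_weight`` of events with the location
    shifted up by ``tail_shift`` natural-log units, emulating a brighter
    subset ("tail") of expression.
    """

    mu: float
    sigma: float
    tail_weight: float = 0.0
    tail_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not (0.0 <= self.tail_weight < 1.0):
            raise ValueError("tail_weight must be in [0, 1)")
        if self.tail_weight > 0 and self.tail_shift <= 0:
            raise ValueError("tail_shift must be > 0 when a tail is present")

    @property
    def geomean(self) -> float:
        """Expected geometric mean of the mixture (exp of mean log)."""
        return math.exp(self.mu + self.tail_weight * self.tail_shift)


@dataclass(frozen=True)
class PopulationSpec:
    """Generative description of one cell population."""

    label: str
    fraction: float
    markers: dict[str, MarkerModel]                 # unlisted -> autofluorescence
    fsc: MarkerModel = MarkerModel(_LN(100_000.0), 0.30)
    cd9_background: MarkerModel | None = None       # FMO / autofluorescence CD9

    def __post_init__(self) -> None:
        if self.label not in POPULATION_LABELS:
            raise ValueError(f"unknown population label {self.label!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must be in [0, 1]")


@dataclass(frozen=True)
class SampleSpec:
    """Everything needed to generate one synthetic sample deterministically."""

    sample_id: str
    populations: tuple[PopulationSpec, ...]
    n_events: int = 50_000
    doublet_fraction: float = 0.03
    debris_fraction: float = 0.04
    autofluorescence: MarkerModel = MarkerModel(_LN(300.0), 0.50)
    seed: int = 0
    fmo: bool = False
    scenario: str = "none"                          # none|gcsf|infection|aml:<subtype>
    specimen: str = "marrow"

    def __post_init__(self) -> None:
        if self.n_events < 0:
            raise ValueError("n_events must be >= 0")
        for f in (self.doublet_fraction, self.debris_fraction):
            if not (0.0 <= f < 1.0):
                raise ValueError("contamination fractions must be in [0, 1)")
        total = sum(p.fraction for p in self.populations)
        if self.populations and abs(total - 1.0) > 1e-9:
            raise ValueError(f"population fractions sum to {total}, not 1")


@dataclass(frozen=True)
class TruthLabels:
    """Per-event ground-truth labels (population, 'doublet' or 'debris')."""

    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.labels)

    def mask(self, *names: str) -> np.ndarray:
        return np.isin(self.labels, names)


# ---------------------------------------------------------------------------
# event synthesis
# ---------------------------------------------------------------------------

def _draw_marker(rng: np.random.Generator, model: MarkerModel, n: int) -> np.ndarray:
    logv = rng.normal(model.mu, model.sigma, size=n)
    if model.tail_weight > 0.0:
        in_tail = rng.random(n) < model.tail_weight
        logv = logv + model.tail_shift * in_tail
    return np.exp(logv)


def _population_model(
    pop: PopulationSpec, marker: str, autofluor: MarkerModel, fmo: bool
) -> MarkerModel:
    if marker == "CD9" and fmo:
        return pop.cd9_background or autofluor
    return pop.markers.get(marker, autofluor)


_DEBRIS_FSC = MarkerModel(_LN(5_000.0), 0.40)
_DEBRIS_SSC = MarkerModel(_LN(3_000.0), 0.40)
#: multiplicative FSC_A/FSC_H jitter for singlets (log-sd)
_FSC_RATIO_SD = 0.05


def _singlet_matrix(
    pops: list[PopulationSpec],
    counts: np.ndarray,
    channel_rngs: dict[str, np.random.Generator],
    spec: SampleSpec,
) -> np.ndarray:
    """Stack singlet events population-by-population, channel streams fixed."""
    n = int(counts.sum())
    out = np.empty((n, len(CHANNELS)), dtype=np.float64)
    ci = {ch: i for i, ch in enumerate(CHANNELS)}
    # FSC_H drives FSC_A; draw per population from the FSC_H stream
    row = 0
    for pop, k in zip(pops, counts):
        k = int(k)
        sl = slice(row, row + k)
        fsc_h = _draw_marker(channel_rngs["FSC_H"], pop.fsc, k)
        ratio = np.exp(channel_rngs["FSC_A"].normal(0.0, _FSC_RATIO_SD, size=k))
        out[sl, ci["FSC_H"]] = fsc_h
        out[sl, ci["FSC_A"]] = fsc_h * ratio
        ssc_model = pop.markers.get("SSC", MarkerModel(_LN(15_000.0), 0.30))
        out[sl, ci["SSC"]] = _draw_marker(channel_rngs["SSC"], ssc_model, k)
        for m in FLUOR_MARKERS:
            model = _population_model(pop, m, spec.autofluorescence, spec.fmo)
            out[sl, ci[m]] = _draw_marker(channel_rngs[m], model, k)
        row += k
    return out


def generate_sample(spec: SampleSpec) -> tuple[EventTable, TruthLabels]:
    """Generate one sample (events + ground-truth labels), bit-reproducible.

    Event counts per population are a multinomial draw at the spec fractions
    of the intact-singlet budget; doublets are pairwise sums on area-like
    channels; debris sits low on FSC/SSC.  Rows are shuffled so populations
    interleave as on a real acquisition.
    """
    if not spec.populations and spec.n_events > 0:
        raise ValueError("spec has no populations but n_events > 0")
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(3 + len(CHANNELS))
    counts_rng = np.random.default_rng(children[0])
    aux_rng = np.random.default_rng(children[1])
    perm_rng = np.random.default_rng(children[2])
    channel_rngs = {
        ch: np.random.default_rng(child)
        for ch, child in zip(CHANNELS, children[3:])
    }
    ci = {ch: i for i, ch in enumerate(CHANNELS)}

    n = spec.n_events
    if n == 0:
        table = _as_table(spec, np.empty((0, len(CHANNELS))))
        return table, TruthLabels(np.array([], dtype=object))

    kind_counts = counts_rng.multinomial(
        n,
        [
            spec.debris_fraction,
            spec.doublet_fraction,
            1.0 - spec.debris_fraction - spec.doublet_fraction,
        ],
    )
    n_debris, n_doublet, n_singlet = (int(x) for x in kind_counts)
    pops = list(spec.populations)
    fracs = np.array([p.fraction for p in pops])

    singlet_counts = counts_rng.multinomial(n_singlet, fracs)
    parent_counts = counts_rng.multinomial(2 * n_doublet, fracs)

    singlets = _singlet_matrix(pops, singlet_counts, channel_rngs, spec)
    parents = _singlet_matrix(pops, parent_counts, channel_rngs, spec)

    # doublets: area-like channels add; FSC_H follows the larger parent
    order = aux_rng.permutation(parents.shape[0])
    a, b = parents[order[:n_doublet]], parents[order[n_doublet : 2 * n_doublet]]
    doublets = a + b
    h = np.maximum(a[:, ci["FSC_H"]], b[:, ci["FSC_H"]])
    doublets[:, ci["FSC_H"]] = h * np.exp(aux_rng.normal(0.0, 0.03, size=n_doublet))

    debris = np.empty((n_debris, len(CHANNELS)))
    deb_h = _draw_marker(aux_rng, _DEBRIS_FSC, n_debris)
    debris[:, ci["FSC_H"]] = deb_h
    debris[:, ci["FSC_A"]] = deb_h * np.exp(
        aux_rng.normal(0.0, _FSC_RATIO_SD, size=n_debris)
    )
    debris[:, ci["SSC"]] = _draw_marker(aux_rng, _DEBRIS_SSC, n_debris)
    for m in FLUOR_MARKERS:
        debris[:, ci[m]] = _draw_marker(channel_rngs[m], spec.autofluorescence, n_debris)

    data = np.vstack([singlets, doublets, debris])
    labels = np.concatenate(
        [
            np.repeat([p.label for p in pops], singlet_counts),
            np.repeat("doublet", n_doublet),
            np.repeat("debris", n_debris),
        ]
    ).astype(object)

    perm = perm_rng.permutation(data.shape[0])
    return _as_table(spec, data[perm]), TruthLabels(labels[perm])


def _as_table(spec: SampleSpec, data: np.ndarray) -> EventTable:
    marker_map = PanelConfig().resolve(list(CHANNELS))
    tags = (spec.scenario,) if spec.scenario != "none" else ()
    if spec.fmo:
        tags = tags + ("fmo",)
    return EventTable(
        sample_id=spec.sample_id,
        data=data,
        channel_names=list(CHANNELS),
        marker_map=marker_map,
        specimen=spec.specimen,
        tags=tags,
    )


def make_fmo(spec: SampleSpec) -> SampleSpec:
    """FMO variant of a spec: identical except the CD9 stain is omitted.

    On generation every population's CD9 values come from its background
    (autofluorescence) distribution; all other channels are bit-identical.
    """
    if spec.fmo:
        raise ValueError("spec is already an FMO variant")
    return replace(spec, fmo=True, sample_id=spec.sample_id + "_fmo")


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _bg(level: float = 300.0, sigma: float = 0.50) -> MarkerModel:
    return MarkerModel(_LN(level), sigma)


def _pos(level: float, sigma: float = 0.35) -> MarkerModel:
    return MarkerModel(_LN(level), sigma)


#: non-CD9 marker layout per population (markers absent here draw
#: autofluorescence).  SSC/CD45 realise the CD45-vs-SSC topology: lymphoid
#: populations bright CD45 / low SSC, monocytes bright CD45 / intermediate
#: SSC, granulocytes variable CD45 / high SSC, blasts + hematogones dim
#: CD45 / low SSC.
_POP_MARKERS: dict[str, dict[str, MarkerModel]] = {
    "myeloid_blast_HSC": {
        "SSC": _pos(12_000.0, 0.30), "CD45": _pos(6_500.0, 0.30),
        "CD34": _pos(4_000.0, 0.35), "CD58": _pos(2_500.0),
    },
    "myeloid_blast_CMP": {
        "SSC": _pos(12_000.0, 0.30), "CD45": _pos(5_000.0, 0.30),
        "CD34": _pos(3_000.0, 0.35), "CD38": _pos(3_000.0, 0.40),
        "CD58": _pos(2_500.0),
    },
    "promyelocyte": {
        "SSC": _pos(160_000.0, 0.25), "CD45": MarkerModel(_LN(12_000.0), 0.45),
    },
    "myelocyte": {
        "SSC": _pos(140_000.0, 0.25), "CD45": MarkerModel(_LN(10_000.0), 0.45),
        "CD24": _pos(3_000.0),
    },
    "neutrophil": {
        "SSC": _pos(150_000.0, 0.25), "CD45": MarkerModel(_LN(18_000.0), 0.45),
        "CD10": _pos(3_000.0), "CD24": _pos(3_500.0),
    },
    "eosinophil": {
        "SSC": _pos(180_000.0, 0.25), "CD45": MarkerModel(_LN(15_000.0), 0.40),
        "CD24": _pos(2_500.0),
    },
    "monocyte": {
        "SSC": _pos(45_000.0, 0.22), "CD45": _pos(60_000.0, 0.30),
        "CD58": _pos(5_000.0),
    },
    "mature_B": {
        "SSC": _pos(10_000.0, 0.30), "CD45": _pos(60_000.0, 0.30),
        "CD19": _pos(5_000.0), "CD20": _pos(6_000.0), "CD58": _pos(3_000.0),
    },
    "other_lymphocyte": {
        "SSC": _pos(9_000.0, 0.30), "CD45": _pos(70_000.0, 0.30),
    },
    "hematogone1": {
        "SSC": _pos(11_000.0, 0.30), "CD45": _pos(3_500.0, 0.30),
        "CD10": _pos(6_000.0), "CD19": _pos(3_000.0), "CD38": _pos(6_000.0),
        "CD34": _pos(2_500.0),
    },
    "hematogone2": {
        "SSC": _pos(11_000.0, 0.30), "CD45": _pos(8_000.0, 0.30),
        "CD10": _pos(3_000.0), "CD19": _pos(6_000.0), "CD38": _pos(6_000.0),
    },
}

#: intact-singlet fractions of the normal-marrow preset
_NORMAL_FRACTIONS: dict[str, float] = {
    "myeloid_blast_HSC": 0.008,
    "myeloid_blast_CMP": 0.012,
    "promyelocyte": 0.030,
    "myelocyte": 0.080,
    "neutrophil": 0.480,
    "eosinophil": 0.020,
    "monocyte": 0.080,
    "mature_B": 0.050,
    "other_lymphocyte": 0.200,
    "hematogone1": 0.015,
    "hematogone2": 0.025,
}

#: intact-singlet fractions of AML presets (dominant leukemic blasts)
_AML_FRACTIONS: dict[str, float] = {
    "leukemic_blast": 0.550,
    "myeloid_blast_HSC": 0.002,
    "myeloid_blast_CMP": 0.003,
    "promyelocyte": 0.030,
    "myelocyte": 0.040,
    "neutrophil": 0.180,
    "eosinophil": 0.010,
    "monocyte": 0.050,
    "mature_B": 0.040,
    "other_lymphocyte": 0.095,
}

#: CD9 log-sd within a population
_CD9_SIGMA = 0.40
#: per-sample log-jitter applied to each population's CD9 location
_CD9_SAMPLE_JITTER = 0.20
#: FMO (background) CD9 geometric means: blasts vs mature B vs default
_CD9_BACKGROUND = {"blast": 619.0, "mature_B": 268.0, "default": 300.0}

PRESET_NAMES: tuple[str, ...] = (
    "normal_marrow", "normal_blood", "gcsf", "infection",
) + tuple(f"aml_{s}" for s in AML_SUBTYPES)


def _cd9_background_for(label: str) -> MarkerModel:
    if label in ("myeloid_blast_HSC", "myeloid_blast_CMP", "leukemic_blast"):
        return _bg(_CD9_BACKGROUND["blast"])
    if label == "mature_B":
        return _bg(_CD9_BACKGROUND["mature_B"])
    return _bg(_CD9_BACKGROUND["default"])


def _jittered_center(
    rng: np.random.Generator | None, center: float, bounds: tuple[float, float]
) -> float:
    """Per-sample CD9 location: lognormal jitter clipped inside the cohort range."""
    lo, hi = bounds
    if rng is None:
        return center
    mu = _LN(center) + rng.normal(0.0, _CD9_SAMPLE_JITTER)
    return float(np.exp(np.clip(mu, _LN(lo) + 0.1, _LN(hi) - 0.1)))


def _normal_cd9(rng: np.random.Generator | None) -> dict[str, MarkerModel]:
    """Per-population CD9 models for a normal sample (HSC = ratio x CMP)."""
    cd9: dict[str, MarkerModel] = {}
    cmp_center = _jittered_center(
        rng, _CD9_CENTERS["myeloid_blast_CMP"],
        (NORMAL_CD9_RANGES["myeloid_blast"][0] * 1.05,
         NORMAL_CD9_RANGES["myeloid_blast"][1] / (1.05 * _HSC_CMP_RATIO)),
    )
    cd9["myeloid_blast_CMP"] = MarkerModel(_LN(cmp_center), _CD9_SIGMA)
    cd9["myeloid_blast_HSC"] = MarkerModel(
        _LN(cmp_center * _HSC_CMP_RATIO), _CD9_SIGMA
    )
    for label in ("promyelocyte", "monocyte", "mature_B", "hematogone1", "hematogone2"):
        cd9[label] = MarkerModel(
            _LN(_jittered_center(rng, _CD9_CENTERS[label], NORMAL_CD9_RANGES[label])),
            _CD9_SIGMA,
        )
    # neutrophils: bottom-heavy, a brighter subset ("tail") of expression
    tail_w, tail_d = 0.20, 1.0
    pmn_center = _jittered_center(
        rng, _CD9_CENTERS["neutrophil"], NORMAL_CD9_RANGES["neutrophil"]
    )
    cd9["neutrophil"] = MarkerModel(
        _LN(pmn_center) - tail_w * tail_d, _CD9_SIGMA, tail_w, tail_d
    )
    cd9["myelocyte"] = MarkerModel(_LN(2_500.0), _CD9_SIGMA)
    cd9["eosinophil"] = MarkerModel(_LN(20_000.0), _CD9_SIGMA)  # bright CD9
    cd9["other_lymphocyte"] = MarkerModel(_LN(400.0), _CD9_SIGMA)
    return cd9


def _build_populations(
    fractions: dict[str, float],
    cd9: dict[str, MarkerModel],
    extra_markers: dict[str, dict[str, MarkerModel]] | None = None,
) -> tuple[PopulationSpec, ...]:
    pops = []
    for label, frac in fractions.items():
        markers = dict(_POP_MARKERS.get(label, {}))
        if extra_markers and label in extra_markers:
            markers.update(extra_markers[label])
        markers["CD9"] = cd9[label]
        pops.append(
            PopulationSpec(
                label=label,
                fraction=frac,
                markers=markers,
                cd9_background=_cd9_background_for(label),
            )
        )
    return tuple(pops)


def _shift(model: MarkerModel, delta: float) -> MarkerModel:
    return replace(model, mu=model.mu + delta)


def preset(
    name: str,
    *,
    n_events: int = 50_000,
    seed: int = 0,
    rng: np.random.Generator | None = None,
    sample_id: str | None = None,
) -> SampleSpec:
    """Build a SampleSpec for a named study condition.

    ``rng`` (if given) draws the per-sample CD9 locations inside the cohort
    calibration ranges; without it the cohort-central values are used.
    Known names: normal_marrow, normal_blood, gcsf, infection, and
    ``aml_<subtype>`` for subtypes TP53, CBFB_MYH11, RUNX1_RUNX1T1, NOS,
    MDS_rel, APL, NPM1, KMT2Ar.
    """
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r} (known: {', '.join(PRESET_NAMES)})")
    sample_id = sample_id or name
    specimen = "blood" if name in ("normal_blood", "gcsf") else "marrow"

    if name.startswith("aml_"):
        subtype = name[4:]
        lo, hi = AML_CD9_RANGES[subtype]
        if rng is None:
            blast_mu = 0.5 * (_LN(lo) + _LN(hi))
        else:
            blast_mu = rng.uniform(_LN(lo), _LN(hi))
        cd9 = _normal_cd9(rng)
        cd9["leukemic_blast"] = MarkerModel(blast_mu, _CD9_SIGMA)
        # APL blast equivalents are CD34-negative; other subtypes CD34+
        blast_markers: dict[str, MarkerModel] = {
            "SSC": _pos(15_000.0, 0.30),
            "CD45": _pos(5_000.0, 0.30),
            "CD38": _pos(3_000.0, 0.40),
            "CD58": _pos(2_500.0),
        }
        if subtype != "APL":
            blast_markers["CD34"] = _pos(3_500.0, 0.35)
        return SampleSpec(
            sample_id=sample_id,
            populations=_build_populations(
                _AML_FRACTIONS, cd9, {"leukemic_blast": blast_markers}
            ),
            n_events=n_events,
            seed=seed,
            scenario=f"aml:{subtype}",
            specimen="marrow",
        )

    cd9 = _normal_cd9(rng)
    scenario = "none"
    if name == "gcsf":
        scenario = "gcsf"
        for label in ("myeloid_blast_HSC", "myeloid_blast_CMP"):
            cd9[label] = _shift(cd9[label], _LN(_GCSF_FOLD))
    elif name == "infection":
        scenario = "infection"
        for label in (
            "myeloid_blast_HSC", "myeloid_blast_CMP", "promyelocyte",
            "myelocyte", "neutrophil", "monocyte",
        ):
            cd9[label] = _shift(cd9[label], _INFECTION_SHIFT)
        # mature B cells remain low
    return SampleSpec(
        sample_id=sample_id,
        populations=_build_populations(_NORMAL_FRACTIONS, cd9),
        n_events=n_events,
        seed=seed,
        scenario=scenario,
        specimen=specimen,
    )


def generate_cohort(
    n_samples: int,
    preset_name: str,
    master_seed: int = 0,
    *,
    n_events: int = 50_000,
    with_fmo: bool = False,
) -> list[tuple[EventTable, TruthLabels, dict]]:
    """Generate a reproducible cohort of one preset.

    Per-sample seeds (and the per-sample CD9 location draws) derive
    deterministically from ``master_seed``.  Each element carries a manifest
    row dict (sample_id, scenario, subtype, seed); with ``with_fmo`` the FMO
    companion table is appended to the row as ``fmo_table``.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    out = []
    for i, child in enumerate(ss.spawn(n_samples)):
        rng = np.random.default_rng(child)
        sample_seed = int(rng.integers(0, 2**31 - 1))
        spec = preset(
            preset_name,
            n_events=n_events,
            seed=sample_seed,
            rng=rng,
            sample_id=f"{preset_name}_{i:03d}",
        )
        table, truth = generate_sample(spec)
        row = {
            "sample_id": spec.sample_id,
            "scenario": spec.scenario,
            "subtype": spec.scenario[4:] if spec.scenario.startswith("aml:") else "",
            "seed": spec.seed,
            "specimen": spec.specimen,
        }
        if with_fmo:
            fmo_table, _ = generate_sample(make_fmo(spec))
            row["fmo_table"] = fmo_table
        out.append((table, truth, row))
    return out


def cohort_manifest(cohort: list[tuple[EventTable, TruthLabels, dict]]) -> pd.DataFrame:
    """Tidy manifest DataFrame for a generated cohort."""
    rows = [{k: v for k, v in row.items() if k != "fmo_table"} for _, _, row in cohort]
    return pd.DataFrame(rows)
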