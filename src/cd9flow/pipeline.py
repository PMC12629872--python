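"""End-to-end orchestration: simulate -> gate -> GMFI -> abnormality -> stats.

`run_sample` takes one event table (plus optional FMO companion) through
exclusions, gating, per-population CD9 GMFI, pattern metrics, the HSC/CMP
split and the abnormality call, logging every exclusion with its reason.
`run_cohort` aggregates samples into a tidy cohort table, runs the
statistics layer across blast groups, and (optionally) writes deterministic
CSV/JSON outputs with provenance (config hash, master seed, version).
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .abnormality import AbnormalityConfig, AbnormalityReport, assess
from .cohort_stats import (
    DegenerateStatisticsError,
    log_transform,
    oneway_anova,
    proportion_above_cutoff,
    tukey_pairwise,
)
from .expression import (
    GMFIResult,
    InadequatePopulationError,
    pattern_metrics,
    population_gmfi,
)
from .gating import GatingConfig, GatingResult, gate_sample
from .listmode_io import EventTable
from .synthetic import generate_cohort

__all__ = ["RunConfig", "SampleResult", "CohortResult", "run_sample", "run_cohort", "simulate"]

#: populations whose CD9 GMFI is reported (myelocytes gated but excluded)
REPORTED_POPULATIONS: tuple[str, ...] = (
    "myeloid_blast", "promyelocyte", "neutrophil", "monocyte", "mature_B",
    "hematogone1", "hematogone2",
)
_MATURING_MYELOID = ("promyelocyte", "neutrophil", "monocyte")


@dataclass(frozen=True)
class RunConfig:
    gating: GatingConfig = field(default_factory=GatingConfig)
    abnormality: AbnormalityConfig = field(default_factory=AbnormalityConfig)
    marker: str = "CD9"
    master_seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SampleResult:
    sample_id: str
    status: str                                  # ok | failed
    gmfis: dict[str, GMFIResult]
    excluded: dict[str, str]                     # population -> reason
    report: AbnormalityReport | None
    gating: GatingResult | None
    failure_reason: str = ""


def run_sample(
    table: EventTable,
    fmo_table: EventTable | None = None,
    config: RunConfig | None = None,
) -> SampleResult:
    """Full single-sample analysis; never raises on inadequate populations."""
    config = config or RunConfig()
    if table.n_events == 0:
        return SampleResult(
            sample_id=table.sample_id, status="failed", gmfis={}, excluded={},
            report=None, gating=None, failure_reason="empty sample (0 events)",
        )
    gating = gate_sample(table, fmo_table, config.gating)

    gmfis: dict[str, GMFIResult] = {}
    excluded: dict[str, str] = {
        "myelocyte": "excluded from CD9 analysis (eosinophil coincidence in "
        "the CD24+/CD10- region)"
    }
    for label in REPORTED_POPULATIONS:
        call = gating.calls[label]
        try:
            gmfis[label] = population_gmfi(
                table, call, config.marker, config.gating.min_events
            )
        except (InadequatePopulationError, ValueError) as exc:
            excluded[label] = str(exc)

    blast = gmfis.get("myeloid_blast")
    if blast is None:
        return SampleResult(
            sample_id=table.sample_id, status="failed", gmfis=gmfis,
            excluded=excluded, report=None, gating=gating,
            failure_reason="myeloid blast population not evaluable: "
            + excluded.get("myeloid_blast", "unknown"),
        )

    blast_values = table.marker(config.marker)[gating.calls["myeloid_blast"].indices]
    pattern = pattern_metrics(
        blast_values, gating.thresholds.positivity[config.marker]
    )

    hsc = cmp_ = None
    eligible = gating.hsc_cmp_eligible
    if eligible:
        try:
            hsc = population_gmfi(table, gating.hsc, config.marker,
                                  config.gating.min_events)
            cmp_ = population_gmfi(table, gating.cmp, config.marker,
                                   config.gating.min_events)
        except (InadequatePopulationError, ValueError) as exc:
            excluded["hsc_cmp"] = f"HSC/CMP comparison not reported: {exc}"
            hsc = cmp_ = None
            eligible = False
    else:
        excluded["hsc_cmp"] = (
            "HSC/CMP comparison ineligible (HSC share of CD34+/CD19- "
            "progenitors not > "
            f"{config.gating.hsc_eligibility_fraction:.0%})"
        )

    maturing = {k: gmfis[k] for k in _MATURING_MYELOID if k in gmfis}
    report = assess(
        blast, pattern, hsc, cmp_, eligible, maturing,
        config.abnormality, sample_id=table.sample_id,
    )
    return SampleResult(
        sample_id=table.sample_id, status="ok", gmfis=gmfis,
        excluded=excluded, report=report, gating=gating,
    )


@dataclass
class CohortResult:
    samples: list[SampleResult]
    cohort_table: pd.DataFrame          # sample_id, group, population, n, gmfi
    reports: pd.DataFrame
    tukey_matrix: pd.DataFrame | None
    anova_p: float | None
    percent_above_cutoff: int | None


def _blast_group(meta: dict) -> str:
    subtype = meta.get("subtype", "")
    return f"aml_{subtype}" if subtype else "normal_myeloid_blast"


def run_cohort(
    samples: list[tuple[EventTable, EventTable | None, dict]],
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
) -> CohortResult:
    """Analyse a cohort and (optionally) write deterministic outputs.

    ``samples`` are (table, fmo_table or None, manifest-row) triples.  The
    statistics layer compares blast groups (normal vs AML subtypes) with
    one-way ANOVA + Tukey pairwise tests on ln(GMFI) whenever at least two
    groups carry two or more samples, and reports the percentage of AML
    samples flagged by the GMFI cutoff.
    """
    if not samples:
        raise ValueError("empty cohort")
    config = config or RunConfig()
    results, rows, report_rows = [], [], []
    for table, fmo, meta in samples:
        res = run_sample(table, fmo, config)
        results.append(res)
        for label, g in res.gmfis.items():
            group = _blast_group(meta) if label == "myeloid_blast" else label
            rows.append(
                {
                    "sample_id": res.sample_id,
                    "group": group,
                    "population": label,
                    "n_events": g.n,
                    "gmfi": g.gmfi,
                    "specimen": meta.get("specimen", table.specimen),
                }
            )
        rep = res.report
        report_rows.append(
            {
                "sample_id": res.sample_id,
                "status": res.status,
                "blast_gmfi": rep.blast_gmfi if rep else np.nan,
                "cutoff_flag": rep.cutoff_flag if rep else False,
                "pattern": rep.pattern_label if rep else "",
                "orientation": rep.orientation if rep else "",
                "overall": rep.overall if rep else "failed",
                "rationale": rep.rationale if rep else res.failure_reason,
            }
        )
    if all(r.status == "failed" for r in results):
        raise ValueError("all samples failed")

    cohort_table = pd.DataFrame(rows)
    reports = pd.DataFrame(report_rows)

    blast_rows = cohort_table[cohort_table["population"] == "myeloid_blast"]
    groups = {
        g: log_transform(sub["gmfi"].to_numpy())
        for g, sub in blast_rows.groupby("group")
        if len(sub) >= 2
    }
    tukey = None
    anova_p = None
    if len(groups) >= 2:
        try:
            anova_p = oneway_anova(groups).p_value
            tukey = tukey_pairwise(groups)
        except DegenerateStatisticsError:
            pass

    aml_mask = [bool(meta.get("subtype")) for _, _, meta in samples]
    aml_flags = [
        bool(rep["cutoff_flag"])
        for rep, is_aml in zip(report_rows, aml_mask)
        if is_aml and rep["status"] == "ok"
    ]
    percent = proportion_above_cutoff(sum(aml_flags), len(aml_flags)) if aml_flags else None

    result = CohortResult(results, cohort_table, reports, tukey, anova_p, percent)
    if outdir is not None:
        _write_outputs(result, Path(outdir), config)
    return result


def _write_outputs(result: CohortResult, outdir: Path, config: RunConfig) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.cohort_table.to_csv(outdir / "cohort_table.csv", index=False,
                               float_format="%.8g")
    result.reports.to_csv(outdir / "reports.csv", index=False, float_format="%.8g")
    if result.tukey_matrix is not None:
        result.tukey_matrix.to_csv(outdir / "tukey_pairwise_p.csv",
                                   float_format="%.8g")
    provenance = {
        "tool": "cd9flow",
        "version": __version__,
        "config_hash": config.digest(),
        "master_seed": config.master_seed,
        "anova_p": result.anova_p,
        "percent_aml_above_cutoff": result.percent_above_cutoff,
    }
    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n"
    )


def simulate(
    preset_name: str,
    n_samples: int,
    master_seed: int,
    outdir: str | Path,
    *,
    n_events: int = 50_000,
    with_fmo: bool = False,
    format: str = "csv",
) -> pd.DataFrame:
    """Generate a cohort to disk (event files + manifest + truth labels)."""
    from .listmode_io import write_events

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(
        n_samples, preset_name, master_seed, n_events=n_events, with_fmo=with_fmo
    )
    manifest_rows = []
    for table, truth, meta in cohort:
        path = outdir / f"{meta['sample_id']}.{format}"
        write_events(table, path, format)
        pd.DataFrame({"label": truth.labels}).to_csv(
            outdir / f"{meta['sample_id']}_truth.csv", index=False
        )
        row = {k: v for k, v in meta.items() if k != "fmo_table"}
        row["path"] = path.name
        if with_fmo:
            fmo_path = outdir / f"{meta['sample_id']}_fmo.{format}"
            write_events(meta["fmo_table"], fmo_path, format)
            row["fmo_path"] = fmo_path.name
        manifest_rows.append(row)
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
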