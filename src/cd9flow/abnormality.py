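"""Normal-vs-aberrant calling for a sample's myeloid-blast CD9 findings.

Three signals feed the call:

1. magnitude — blast CD9 GMFI above a cutoff (default 6000, chosen above
   the highest GMFI seen in normal myeloid blasts, 4662);
2. pattern  — a whole-population shift above background (most of the
   population above the positivity threshold), as opposed to the subset
   ("tail") or uniformly dim expression normal blasts show;
3. orientation — normal marrow shows higher CD9 on the CD38-dim HSC subset
   than on the CD38+ committed myeloid progenitors; an inverted
   relationship is aberrant.

A caution rule downgrades magnitude/pattern elevation to ``indeterminate``
when the maturing myeloid compartments are globally upregulated (as seen
with infection/inflammation), since blast elevation is then uninterpretable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

from .expression import GMFIResult, PatternMetrics

__all__ = [
    "AbnormalityConfig",
    "AbnormalityReport",
    "cutoff_flag",
    "hsc_cmp_orientation",
    "assess",
]

#: cohort-central maturing-myeloid CD9 GMFIs used as global-upregulation
#: reference norms
DEFAULT_REFERENCE_NORMS: dict[str, float] = {
    "promyelocyte": 2095.0,
    "neutrophil": 1818.0,
    "monocyte": 5689.0,
}


@dataclass(frozen=True)
class AbnormalityConfig:
    cutoff: float = 6000.0
    whole_shift_tail_fraction: float = 0.9
    # fold over the reference norm that counts a maturing-myeloid population
    # as upregulated: above normal sample-to-sample spread (~1.2x), below
    # infection-scale upregulation (~2x)
    global_upregulation_fold: float = 1.5
    global_upregulation_min_pops: int = 2
    reference_norms: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REFERENCE_NORMS)
    )


@dataclass(frozen=True)
class AbnormalityReport:
    sample_id: str
    blast_gmfi: float
    cutoff: float
    cutoff_flag: bool
    pattern_label: str
    hsc_gmfi: float | None
    cmp_gmfi: float | None
    orientation: str        # normal_hsc_above | inverted | not_assessed
    overall: str            # normal | aberrant | indeterminate
    rationale: str


def cutoff_flag(blast_gmfi: float, cutoff: float = 6000.0) -> bool:
    """Strictly-greater-than comparison of the blast GMFI against the cutoff."""
    if blast_gmfi <= 0:
        raise ValueError("blast GMFI must be positive")
    return blast_gmfi > cutoff


def hsc_cmp_orientation(
    hsc_gmfi: float | None, cmp_gmfi: float | None, eligible: bool
) -> str:
    """Orientation of the HSC-vs-CMP CD9 relationship.

    ``normal_hsc_above`` when HSC > CMP, ``inverted`` when HSC < CMP,
    ``not_assessed`` when the sample is ineligible (HSC share too small).
    Exact ties are not evidence of inversion and report ``indeterminate``.
    """
    if not eligible:
        return "not_assessed"
    if hsc_gmfi is None or cmp_gmfi is None:
        raise ValueError("eligible sample requires both HSC and CMP GMFIs")
    if hsc_gmfi > cmp_gmfi:
        return "normal_hsc_above"
    if hsc_gmfi < cmp_gmfi:
        return "inverted"
    return "indeterminate"


def assess(
    blast: GMFIResult,
    pattern: PatternMetrics | None = None,
    hsc: GMFIResult | None = None,
    cmp: GMFIResult | None = None,
    eligible: bool = False,
    maturing: dict[str, GMFIResult] | None = None,
    config: AbnormalityConfig | None = None,
    sample_id: str = "",
) -> AbnormalityReport:
    """Combine cutoff, pattern and orientation signals into one call.

    ``aberrant`` when the cutoff fires, the HSC/CMP orientation is
    inverted, or the pattern is a whole-population shift; elevation-based
    flags are downgraded to ``indeterminate`` when enough maturing-myeloid
    populations exceed their reference norms by the configured fold
    (global-upregulation caution); otherwise ``normal``.  The rationale
    names every fired rule.
    """
    if blast is None:
        raise ValueError("blast GMFI result required")
    config = config or AbnormalityConfig()

    flag = cutoff_flag(blast.gmfi, config.cutoff)
    orientation = hsc_cmp_orientation(
        hsc.gmfi if hsc else None, cmp.gmfi if cmp else None, eligible
    )
    whole_shift = (
        pattern is not None
        and pattern.tail_fraction >= config.whole_shift_tail_fraction
        and pattern.label in ("top_heavy", "uniform")
    )

    elevated_pops = []
    if maturing:
        for label, result in maturing.items():
            norm = config.reference_norms.get(label)
            if norm is not None and result.gmfi > config.global_upregulation_fold * norm:
                elevated_pops.append(label)
    global_up = len(elevated_pops) >= config.global_upregulation_min_pops

    fired: list[str] = []
    if flag:
        fired.append(f"blast GMFI {blast.gmfi:.0f} > cutoff {config.cutoff:.0f}")
    if whole_shift:
        fired.append(
            f"whole-population shift above background "
            f"(tail fraction {pattern.tail_fraction:.2f})"
        )
    if orientation == "inverted":
        fired.append("HSC CD9 below CMP CD9 (inverted orientation)")

    if orientation == "inverted":
        overall = "aberrant"
    elif (flag or whole_shift) and global_up:
        overall = "indeterminate"
        fired.append(
            "caution: global myeloid CD9 upregulation in "
            + ", ".join(sorted(elevated_pops))
        )
    elif flag or whole_shift:
        overall = "aberrant"
    else:
        overall = "normal"
        fired.append("no abnormality rule fired")

    return AbnormalityReport(
        sample_id=sample_id or blast.population,
        blast_gmfi=blast.gmfi,
        cutoff=config.cutoff,
        cutoff_flag=flag,
        pattern_label=pattern.label if pattern else "not_assessed",
        hsc_gmfi=hsc.gmfi if hsc else None,
        cmp_gmfi=cmp.gmfi if cmp else None,
        orientation=orientation,
        overall=overall,
        rationale="; ".join(fired),
    )
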