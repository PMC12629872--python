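# Methods

## The measurement model

A flow-cytometry sample is an event table: one row per cell-sized particle,
one column per detector (forward scatter area/height, side scatter, and ten
antibody channels: CD9, CD10, CD19, CD20, CD22, CD24, CD34, CD38, CD58,
CD45).  All analysis happens on linear intensity units; log/logicle
transforms are a display concern and are deliberately out of scope.  The
statistic of interest is the geometric mean fluorescence intensity of a
gated population,

    GMFI = exp( (1/n) Σ ln xᵢ ),

which is scale-equivariant, bounded above by the arithmetic mean, and turns
multiplicative shifts of expression into additive shifts of ln GMFI — the
reason the cohort statistics operate on natural-log GMFIs.  Nonpositive
intensities (absent in the synthetic data, possible in instrument exports)
are dropped when they are at most 1% of a population (with a warning) and
are an error beyond that; this is a package convention, since clinical
software leaves the behaviour undocumented.

## Synthetic samples

No raw per-event data are publicly available for this problem, so the
generator is the package's test bed and calibration target, not a fixture.
Each population is a lognormal mixture component: every channel of every
population draws exp(N(μ, σ)), optionally with a two-component "tail"
(fraction w of events shifted up by δ log units) for populations that show
a brighter subset — neutrophils default to w = 0.2, δ = 1.0.  Lognormality
is the simplest family consistent with geometric-mean summaries; it is an
assumption, not an observation.

Topology and marker logic follow the gating vocabulary: lymphoid
populations are bright CD45 / low SSC, monocytes bright CD45 / intermediate
SSC, granulocytes variable CD45 / high SSC, blasts and hematogones dim
CD45 / low SSC.  "Positive" markers sit ≥ 1.5 natural-log units above the
~300-unit autofluorescence background so that threshold gates are learnable
from the data.  CD9 levels are calibrated so population geometric means fall
inside published cohort GMFI ranges (normal myeloid blasts 707–4662,
promyelocytes 1315–5481, neutrophils 737–24 800, monocytes 1357–66 487,
stage-1/2 hematogones 4245–29 439 / 5287–32 269, mature B cells 392–1921;
AML subtype ranges from TP53 760–2124 up to APL 6856–35 903).  Presets add a
per-sample lognormal jitter (σ = 0.2, clipped inside the range) around
cohort-central values; AML presets draw the blast CD9 location log-uniformly
across the subtype's range.  Within-population CD9 σ is 0.4 — a package
choice, since per-sample spreads are not published.  Normal presets set the
HSC CD9 geometric mean 1.5× the CMP value (and HSC slightly brighter CD34
and CD45); the G-CSF preset multiplies blast CD9 by 1845/1578 ≈ 1.17; the
infection preset adds +0.7 log units to blast and maturing-myeloid CD9
while mature B cells stay low.  FMO backgrounds are population-specific:
blasts 619, mature B cells 268, otherwise 300.

Contamination: doublets (default 3%) are sums of two singlet draws on
area-like channels with FSC_H inherited from the larger parent, so the
FSC_A/FSC_H ratio separates them; debris (default 4%) sits at low FSC/SSC
with autofluorescent markers.  Sample sizes default to 50 000 events — the
scale of a routine acquisition — and every event carries a ground-truth
label.

Randomness discipline: each channel owns an independent child stream of the
sample seed (counts, contamination and shuffling own their own streams), so
an FMO variant regenerates every non-CD9 channel bit-identically while CD9
comes from the background distribution.  Fixed seeds give bit-identical
samples.

What the generator does **not** emulate: spectral spillover/compensation,
acquisition drift, instrument-specific channel resolution, dead cells and
nonspecific antibody deposition, or continuous maturation gradients between
populations (components are well-separated clusters).  Passing tests
therefore demonstrate correctness of the pipeline's logic under the stated
generative model, not robustness to every artefact of real acquisitions —
on real data the threshold defaults below would need instrument-specific
recalibration.

## Gating

Doublets are removed at FSC_A/FSC_H > 1.4; debris at FSC_A < 20 000.
Primary gates quantify the qualitative descriptors with configurable
defaults: CD45 "high" > 25 000; blast-gate CD45 ∈ (1 500, 25 000]; SSC
low/intermediate boundary 25 000 and intermediate/high boundary 80 000.
Positivity defaults to 1 000 (≈ the 99th percentile of the ~300-unit
autofluorescence) for the gating markers.  The CD9 threshold is special:
with an FMO companion it is the 99th percentile of CD9 over the FMO's *own
gated myeloid-blast population* — gating is CD9-blind, so the FMO gates
identically, and measuring the background on the population actually being
assessed avoids the underestimate that the whole-cloud percentile produces
(the cloud is dominated by low-background neutrophils).  Without an FMO the
CD9 fallback is 2 000, the analogous percentile of the dim-blast
background.

Terminal rules: granulocytes split on CD24 vs CD10 (promyelocytes −/−,
myelocytes +/−, neutrophils +/+); myelocytes are gated but excluded from
CD9 analysis because eosinophils (bright CD9) are coincident in the
CD24+/CD10− region; monocytes are refined to CD10/CD19/CD22/CD24-negative;
mature B cells are lymphocyte-gate CD19+CD20+CD10−; hematogones are
blast-gate CD10+CD19+CD38+ events.  Hematogone stages use CD34 positivity
(stage 1 mostly CD34+) with a linear-discriminant fallback for
CD34-negative events: the score ln CD10 − ln CD19 − ln CD45 (stage 1 is
brighter CD10, dimmer CD19/CD45) is thresholded at the midpoint between
the CD34+ and CD34− centroids.  A median split was rejected because it
forces a fixed proportion into stage 1 regardless of the actual mixture.

Myeloid blasts are blast-gate CD34+/CD19− events that are not hematogones
and not B-excluded.  Isolated weak or partial CD19 never reassigns lineage:
exclusion as B-lineage requires at least two signals among CD10+, CD22+,
CD24+ and bright CD19 (> 10× threshold).  When fewer than 20% of the
candidate blast-gate events are CD34+, the sample is treated as a
CD34-negative/subset-positive leukemia and the whole dim-CD45/low-SSC non-B
cloud becomes the blast call, flagged in the call's provenance (the APL
preset exercises this path).  The HSC/CMP split thresholds CD38 at its
positivity value; the HSC-vs-CMP comparison requires the HSC share of the
CD34+/CD19− progenitors to strictly exceed 30%, and every reported GMFI
requires at least 50 events — both comparisons deliberately strict.

## Abnormality calling

Three signals combine into one call per sample:

- **cutoff** — blast GMFI strictly above 6000 (configurable; the default
  sits above the highest normal-blast GMFI of 4662 with margin);
- **pattern** — a whole-population shift above background, operationalised
  as tail fraction ≥ 0.9 with a top-heavy or uniform label.  Pattern labels
  themselves are operational definitions: uniform when < 10% (or > 90%
  with |log-skewness| < 0.5) of events exceed the positivity threshold;
  top-heavy at tail fraction ≥ 0.5; in the 10–50% band, "tail" when the
  log-skewness exceeds 0.5 (a distinct brighter subset) and "bottom-heavy"
  otherwise (a continuous distribution straddling the threshold) — the two
  descriptions are near-synonyms in practice and the skewness separates a
  discrete subset from a shoulder;
- **orientation** — inverted HSC-vs-CMP CD9 (HSC < CMP) is aberrant on its
  own; ties are reported as indeterminate orientation rather than
  inversion.

Elevation-based flags (cutoff, pattern) are downgraded to *indeterminate*
when ≥ 2 maturing-myeloid populations (promyelocytes, neutrophils,
monocytes) exceed 1.5× their reference norms — a fold chosen between
normal between-sample spread (≈ 1.2×) and infection-scale upregulation
(≈ 2×), so the infection preset lands on indeterminate while jittered
normals do not.  The combination logic (inversion ⇒ aberrant even under
global upregulation; any fired elevation rule ⇒ aberrant otherwise) is an
explicit package convention: the underlying observations do not prescribe a
formal combination rule, and every report's rationale string names the
rules that fired.

## Statistics

Tests run on ln GMFI.  The two-sample t test is pooled-variance by default
(preserving the exact F = t² identity with the one-way ANOVA at two
groups; Welch is available via `equal_var=False`).  Tukey post hoc
comparisons use the Tukey-Kramer studentized-range adjustment, valid for
the unbalanced group sizes typical of AML subtype cohorts, and adjusted p
values are never below the raw pairwise p.  Zero-variance or undersized
inputs raise `DegenerateStatisticsError` instead of returning degenerate p
values.  Cutoff proportions round half-up to integer percent.  Type-I
error of the paired t, pooled t and ANOVA is verified by seeded
2000-replicate null simulations (acceptance band 0.035–0.065 at α = .05).

## Problem sizes and determinism

The test suite and the acceptance script use 50 000-event samples (20 000
for some pipeline round-trips), cohorts of 8–20 samples, and 400–2000
simulation replicates for the statistical calibration checks — sizes chosen
to match routine acquisitions while keeping a full run in the low minutes
on one core.  All randomness flows from explicit seeds: cohort generation
spawns per-sample seed sequences from a master seed, and the CLI `run-all`
produces byte-identical CSVs under a fixed seed.

## Known limitations

- Gate boundaries are conventions calibrated to the synthetic presets, not
  transferable clinical coordinates.
- Stage-1/2 hematogone discrimination is heuristic; real maturation is a
  continuum.
- The abnormality combination rule and the global-upregulation fold are
  package conventions exposed in configuration, to be validated against
  real cohorts before clinical use.
- The cohort-statistics layer reproduces the *methods*, not any specific
  cohort's p values — those depend on unpublished per-patient data.
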