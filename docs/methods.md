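# Methods

This note documents the models implemented in pcfkit, the defaults and why
they were chosen, the numerical conventions, what the synthetic-data module
does and does not emulate, and known limitations.

## Conductivity from two-probe I/V sweeps

A sweep is modeled as Ohmic: I = G·V + I₀, fitted by ordinary least squares
over all points.  The current entering σ = (I·l)/(V·A) is taken from the
fitted line with the intercept removed (I = G·V_eval, V_eval = 0.1 V by
default), not from the nearest raw sample: this is robust to single-point
noise and identical to the raw reading for genuinely linear traces.  σ is
therefore G·l/A, computed in SI units (A/V, m, m²) and converted to S/cm
only for presentation.

The cross-section A is a per-strain model, never measured per filament:

| strain | per-fiber area (nm²) | PCF count |
|--------|----------------------|-----------|
| GS     | 850                  | fixed, 34 |
| RB     | 1100                 | fixed, 15 |
| Rat/Hou/Hou1 | 850            | 5·π·d (d = filament diameter, µm) |

A fixed count always wins over the diameter formula; the formula result is
rounded to the nearest integer, half away from zero (no convention is
published, and counts enter only multiplicatively, so the choice is
harmless).

Censoring: a filament is below the limit of detection when |G| < 1 pA/V
(strict inequality — a conductance exactly at the limit is detectable).
Censored filaments are excluded from every cohort statistic but reported in
`n_below_lod`; `n_total` counts both.  The percentage-below-LOD statistic
is deliberately left to the caller, because the published per-strain n
values appear to count only detectable replicates and the denominator is
therefore ambiguous.  Cohort dispersion is the sample standard deviation
(n−1), and box statistics follow the Tukey convention (quartiles, whiskers
at the most extreme data within 1.5×IQR, outliers beyond).

A degenerate sweep (constant voltage) is an error; a perfectly flat current
trace fits exactly, so its r² is reported as 1.

## STEM-EDX relative quantification

The quantification model is a single multiplicative sensitivity factor per
element (Cliff–Lorimer-style relative quantification):

    percentᵢ = 100 · cᵢ·fᵢ / Σⱼ cⱼ·fⱼ

Only ratios of factors matter; fitted factor sets are normalized so the
first element's factor is 1.  Factors are acquisition-dependent (beam
current, dwell time and map size all rescale raw counts), so they are
always supplied or fitted per region or batch — the package ships no global
defaults.  `fit_sensitivity_factors` inverts the model on a region with
known composition (fᵢ ∝ percentᵢ/cᵢ); composing the two operations is the
identity on any strictly positive row, which the test suite exercises on
random rows and on all published reference rows.

Printed reference rows sum to 100.0–100.1 after rounding; quantification
renormalizes to exactly 100, so recomputation from printed rows can differ
from printed values by one unit in the last digit.  Three such known
discrepancies exist in the published table itself (GS Ni mean prints 2.4
where the rounded rows give 2.5; RB Fe 10.9 vs 11.0; RB S:Fe 7.24 vs 7.25),
because the original averages were formed from unrounded values.  The
summaries here are computed from the printed rows and reproduce every other
printed average exactly.

Ratio averaging defaults to the mean of per-row ratios
(`ratio_mode="from_row_ratios"`), which is how the published average row
was formed; the ratio of mean percentages is available as
`"from_percents"` and can differ grossly when one row has a near-zero
denominator element.  Region records may carry their as-printed per-row
ratios; these take precedence over ratios recomputed from rounded percents.
Outlier exclusion is by explicit flag only — no numeric criterion is
published for the one excluded GS cross-section, and none is invented.
Presentation rounding is 1 decimal for percents, 2 for ratios; internal
arithmetic is unrounded.  The element panel defaults to S/Fe/Ni; Cu, Si and
Al signals (sample holder and detector artifacts) are excluded upstream by
panel selection, not modeled.

## Isotope-pattern verification

Relative counts are formed over an explicit, ordered isotope subset
(default ⁵⁸Ni, ⁶⁰Ni, ⁶²Ni) rather than "everything present", because
ToF-SIMS spectra contain interfering peaks.  Expected fractions are natural
abundances renormalized over the subset (e.g. ⁵⁸Ni: 68.08/97.94 = 0.6951).
The headline output is the observed-vs-expected fraction table; a Pearson
χ² with dof = k−1 is reported alongside, with a warning (not an error) when
an expected cell count is below 5, and no default p-value verdict — no
quantitative agreement criterion is published for the isotope check.  Note
that χ² is scale-invariant only for exactly proportional counts; otherwise
it grows linearly with total count, which the tests document.

## Morphometry

Shape models are assigned per strain from configuration (GS circular,
RB rectangular) and never inferred from data.  Percent differences are
rounded to a 10% step by default, matching the coarseness the dimension
averages support; unrounded values are always reported alongside.  Two
per-fiber area presets exist and every comparison states which it used:
the measured shapes (749.4 nm² for GS, 1116.1 nm² for RB) and the
conduction-model areas (850/1100 nm²).  The total-area comparison gives
RB ≈ 43% smaller than GS under the model preset and ≈ 34% smaller under
the measured preset; which preset underlies the published "approximately
40% smaller" is unstated, so both are emitted.  Vesicle summaries report
the IMAV fraction and per-class diameter mean ± sample std (std requires
n ≥ 2 per class).

## Heme-motif mining and conservation

The motif is strict C-x-x-C-H (the canonical heme-c attachment pattern);
wider spacings (C-x{n}-C-H) are available behind `MotifSpec` for
sensitivity analysis but off by default.  The residue X never matches an
anchor position (C or H) but is accepted as a wildcard.  The default
`non_overlapping` scan resumes after a match's last residue; the `all`
policy reports every matching window and is proven equal to brute-force
window enumeration by property test.

Classification: 0 hemes → none, 1 → monoheme, ≥2 → multiheme, exactly 5 →
pentaheme, split into sPHC/lPHC by sequence length.  The published split is
by predicted domain size without a printed cutoff, so the threshold here
(250 residues) is a documented, configurable estimate chosen to separate
the small variant (~180-residue cytochrome domain) from the large fused
variants several hundred residues long.

Conservation is by reciprocal best hits under Smith–Waterman local
alignment with affine gaps, computed through Bio.Align.PairwiseAligner and
verified against an independent quadratic Gotoh dynamic program in the
tests.  Scoring defaults: BLOSUM62, gap open 11, gap extend 1, with the
BLAST convention that a gap of length k costs 11 + k (realized as
open_gap_score −12 / extend_gap_score −1 in the aligner).  In the default
lenient mode X scores 0 against everything; strict mode rejects X.  The RBH
threshold is a raw score of 50, at which unrelated ~300-residue sequences
of natural composition essentially never pair (validated in tests); ties
for best hit are broken lexicographically and flagged rather than dropped.

The census counts reciprocal pairs where **both** members carry at least
one heme motif; pairs where exactly one member does are listed as
discordant.  The published figure of 11 conserved extracytoplasmic soluble
c-type cytochromes additionally depends on subcellular-localization
prediction (external tools) and the real genome assemblies; localization is
not re-implemented, so that count is reproducible only by supplying an
external localization label table, and is not a target of this package's
checks.

## Synthetic data

All generators are pure functions of their spec; the random source is
numpy's `default_rng` (PCG64) and the generator algorithm is recorded in
simulation metadata.  Defaults are the conditions of the measurements each
stage emulates:

* **I/V**: 21-point −1..1 V sweeps; gap uniform in 100–800 µm; true σ
  4.0 S/cm; 5% relative Gaussian current noise; censored filaments are
  generated at 0.1× the LOD conductance (not zero) to exercise the
  censoring boundary.
* **EDX**: 50 regions at 10⁴ total counts, Poisson per element, planted
  composition 24.9/72.7/2.4%; a zero-variance expectation mode exists in
  which counts are exact (non-integer) expectations so the planted
  composition round-trips bit-exactly.
* **Isotope**: multinomial draws at the renormalized Ni abundances
  (expectation mode available).
* **Vesicles**: Bernoulli IMAV labels at fraction 0.9, Normal diameters
  65.5 ± 4.6 nm (IMAV) and 68.9 ± 4.6 nm (CV), truncated at zero.
* **Proteomes**: the standard fixture plants 8 homolog pairs (heme counts
  5,5,5,4,2,1,3,0; lengths 180–600, including sPHC- and lPHC-sized
  pentahemes) plus 12 unrelated decoys, partner sequences derived by 10%
  i.i.d. point mutation.  Motif positions are masked from mutation and
  substitutions draw only non-C/non-H residues, so planted heme counts are
  invariant — a deliberate deviation from neutral evolution that keeps the
  planted truth exact.  Background and decoy residues are drawn from
  natural amino-acid frequencies (Robinson–Robinson) rather than uniformly:
  uniform sampling overrepresents rare high-self-score residues (W, C)
  about fivefold and inflates spurious local-alignment scores, which would
  misrepresent the score statistics the RBH threshold relies on.

What passing the synthetic tests does **not** show: real sweeps have
contact-resistance and drift effects beyond i.i.d. relative noise; real EDX
counts carry background, absorption and thickness effects the
sensitivity-factor model folds into its factors; real proteomes contain
paralogs, domain shuffling and compositional bias that make homology calls
harder than the planted fixture.  Recovery results on synthetic data
validate the estimators' correctness, not field performance.

## Problem sizes and numerical conventions

Test and acceptance runs use 200 sweeps (conductivity recovery), 50 EDX
regions, 500 vesicles, 1000 multinomial replicates for the χ² null-mean
check, 100 seeded 30-mer pairs for the alignment oracle, and the
8-homolog/12-decoy proteome fixture — sizes at which the stated recovery
bounds (2% on σ, 1 percentage point per element, 0.03 on the IMAV
fraction) hold with wide margin under the central limit theorem.  The full
suite runs in a few seconds.

Other conventions: invalid inputs raise typed exceptions
(`InvalidInputError`, `SchemaError`, `ConfigError`); undefined ratios
(zero denominator) are flagged `None` rather than raised; percent-sum
validation tolerates 0.2 to accommodate printed rounded rows; all tables
are UTF-8 with period decimals, thousands separators parsed leniently on
input and never emitted.

## Known limitations

* No instrument control, air-decay kinetics, or temperature dependence for
  conductivity; no spectral peak fitting, background subtraction or
  absolute (weight-percent) quantification for EDX; no mass calibration or
  peak integration for ToF-SIMS; no image segmentation for morphometry —
  inputs are already-reduced tables.
* Published raw Kα count columns are typographically ambiguous in the
  available rendering; they are used only for round-trip identities (which
  hold for any positive counts), never as numeric oracles.
* The sPHC/lPHC threshold and the RBH score threshold are defensible
  defaults, not published constants; both are configurable.
* Whether published conservation calls used one-way or reciprocal matches,
  and at what significance, is unstated; reciprocal best hits are the
  stricter, standard choice.
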