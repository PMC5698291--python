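# Methods

## Model

The trophic position of an individual consumer is

    TP = (δ15N_Glu − δ15N_Phe + β) / TDF + 1

with all isotope quantities in per mil (‰). Glutamic acid is a trophic
amino acid: transamination/deamination enriches its δ15N by TDF with every
trophic transfer. Phenylalanine is a source amino acid: its C–N bond is
neither formed nor cleaved during consumer metabolism, so it carries the
δ15N of the primary producers nearly unchanged. β is the Glu−Phe offset in
those producers; TDF is the per-step enrichment of the Glu−Phe difference.
TP is continuous: 1 = primary producer, 2 = strict herbivore, 3 = carnivore
on herbivores. TP is deliberately **not** clamped at 1 or 2 — measurement
noise and baseline misfit can legitimately produce values below the
herbivore floor (blood-feeders on C4-fed livestock plausibly sit near 1.8),
and clamping would bias species means.

### Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| TDF | 7.6 ± 1.2 | ‰ (1σ) | trophic discrimination factor for terrestrial consumers |
| β (marine/aquatic) | −3.4 ± 0.9 | ‰ (1σ) | producer Glu−Phe offset, aquatic systems |
| β (C4 terrestrial) | −0.4 ± 1.7 | ‰ (1σ) | producer offset, C4-plant food webs |
| β (C3 terrestrial) | +8.4 ± 1.6 | ‰ (1σ) | producer offset, C3-plant food webs |
| σ_Glu, σ_Phe | 0.5 | ‰ (1σ) | amino-acid δ15N measurement uncertainty, per sample, overridable per row |

All are configurable (YAML or per-call); the defaults are the literature
values for terrestrial vertebrate consumers.

## Baseline classification

β is chosen per individual from bulk hair isotopes with threshold rules,
applied in fixed order: marine if δ13C > −19 and δ15N > 12; else C4 if
δ13C > −15 and δ15N < 12; else C3. Inequalities are strict, exactly as the
rules are conventionally stated, so boundary values (δ13C = −19, δ15N = 12)
fail the specific rules and fall through to the C3 default. The two
specific rules cannot both fire (they demand δ15N on opposite sides of 12),
so the three rules partition the plane and classification is a total,
deterministic, idempotent function.

Real datasets cluster well inside these regions; inputs between the
clusters — δ13C in (−19, −15], or a C3 fall-through whose carbon or
nitrogen is not C3-like — get an **anomaly flag**. Flagged individuals are
still classified (the thresholds are approximate; rejecting would silently
drop data), but every flag is logged and recorded in the run manifest. No
"mixed" β interpolated from δ13C is computed: the classifier targets
consumers with specialized diets on well-separated food webs.

## Uncertainty propagation

Inputs (Glu, Phe, β, TDF) are treated as mutually independent Gaussians —
no covariances are available, and the 1σ notation of the source values
implies normality.

**First-order Taylor expansion** (the reported method): the mean is the
plug-in evaluation at the input means; with partial derivatives 1/TDF
(Glu, β), −1/TDF (Phe) and −(Glu−Phe+β)/TDF² (TDF),

    var(TP) = (σ_Glu² + σ_Phe² + σ_β²)/TDF² + (Glu−Phe+β)²·σ_TDF²/TDF⁴.

The linearization is exact in Glu, Phe and β and approximate only in TDF.
The second-order mean correction from TDF curvature,
(Glu−Phe+β)·σ_TDF²/TDF³, is computed and attached to every estimate as a
diagnostic but never added to the mean, so the reported value stays the
plain first-order (plug-in) mean.

**Monte-Carlo** (the independent check): 100 000 draws by default
(configurable, minimum 1000), TDF draws ≤ 0 rejected and redrawn with the
rejection count reported, seed mandatory. At the default parameter values
(σ_TDF/TDF ≈ 0.16) the Taylor sd sits ~9–10% below the Monte-Carlo sd —
the heavy right tail of 1/TDF — and within 2% once σ_TDF/TDF ≤ 0.05; with
σ_TDF = 0 both reduce to √(σ_Glu²+σ_Phe²+σ_β²)/TDF exactly. When the fully
degenerate case (all σ = 0) is requested, the Monte-Carlo path returns the
plug-in value with sd exactly 0 rather than the ~1e-16 floating-point
residue of summing a million identical draws.

In batch estimation each sample's Monte-Carlo stream is spawned from the
single base seed via `numpy.random.SeedSequence`, keyed by the sample's
rank in id order, so results are reproducible and independent of row order
in the input file.

## Species comparison

ANOVA and Tukey HSD run on the per-individual TP **point estimates**,
ignoring each estimate's propagated sd — this mirrors the standard
workflow in the field; a variance-weighted model is a non-goal. Species
with fewer than two estimates are excluded with a notice. Pairwise Tukey
p-values come from the studentized-range distribution
(`scipy.stats.tukey_hsd`); the compact letter display is a Piepho-style
insert-and-absorb: start with one group of all species, split any group
containing a significantly different pair, absorb subset groups, and
assign letters to groups ordered by descending mean (ties alphabetical),
so 'a' always marks the highest-TP group and output is deterministic. The
display is re-checked against the full significance matrix on every call.
Degenerate inputs: zero within-group variance with distinct means gives
F = ∞, p = 0 and pairwise significance by "means differ"; all-identical
data gives F = 0, p = 1 and one shared letter.

The TP-vs-bulk-δ15N regression is ordinary least squares with a two-sided
slope p-value. Exclusion is expressed by food-web **class** (marine by
default) rather than species name: marine-baseline individuals sit on a
basal δ15N unrelated to the terrestrial food webs, so including them
conflates baseline and trophic enrichment.

## Synthetic data generator

The generator inverts the TP equation. Per individual of a species at true
TP on food web class c:

- latent Phe ~ Normal(phe_base[c], baseline_phe_sd): baseline variation of
  the food web (default sd 1.5‰); an optional per-step Phe shift (default
  0) lets users probe violation of the source-amino-acid assumption;
- individual TDF_i ~ Normal(tdf_true, tdf_individual_sd) (defaults 7.6, 0);
- latent Glu = Phe_latent − β_c + TDF_i·(TP − 1);
- measured Glu and Phe = latent values plus **independent**
  Normal(0, sigma_meas) measurement errors (default 0.5‰). Independence
  matters: it is what the propagation model assumes, and it makes the
  sampling sd of estimated TP equal √2·σ_meas/TDF (≈ 0.0930 at defaults)
  rather than σ_meas/TDF;
- bulk (δ13C, δ15N) uniform on a per-class rectangle chosen strictly
  inside the classifier's region — so classification recovers the true
  class by construction — plus a 3.4‰-per-TP bulk δ15N enrichment
  (referenced to TP 2, clipped to the rectangle) that makes TP-vs-bulk
  regressions non-degenerate. The bulk values are geometric, not
  mechanistic: the pipeline only needs the classifier to see realistic
  inputs.

Everything derives from one mandatory seed; identical configs give
bit-identical datasets. The ground-truth table is a separate output so the
estimation pipeline cannot consume it by accident.

The ready-made nine-species community (`paperlike_config`) places guilds at
true TPs a field ecologist would expect — frugivore 2.0, nectarivore 2.3
(partly insectivorous), cattle-blood sanguivore on a C4 web 1.8, bird-blood
sanguivore 3.0, two insectivores 2.6, two carnivores 3.6, marine piscivore
3.5 — with 3 individuals per species (5 for the piscivore). The per-class
baseline Phe means (marine 5.0, C4 7.0, C3 4.0‰) keep simulated Phe and Glu
within ranges observed in natural hair (roughly 0–15‰ and 8–33‰).

### What the generator does not emulate

Real data add: covariance between Glu and Phe errors within a run,
non-Gaussian baseline variation (e.g. spatial denitrification/N-fixation
gradients under marine food webs), diet-quality-dependent TDF, bulk values
mechanistically coupled to diet, and bulk-only individuals (the generator
gives every individual AA values; bulk-only rows are exercised through
hand-built fixtures instead). Passing tests therefore demonstrate
correctness of the estimation machinery under the stated model, not
robustness to these violations.

## Numerical and design choices

- Problem sizes for validation: 10⁶ Monte-Carlo draws for
  propagation-equivalence checks, 1000 individuals for parameter-recovery
  and coverage checks, 1000 replicates for the ANOVA null calibration —
  large enough that the Monte-Carlo error on each checked quantity is well
  below its tolerance.
- CSV numerics are written at 6 decimal places; NaN/absent values as empty
  cells, which read back as absent. Read → write → read is the identity at
  that precision.
- Isotope values outside ±60‰ raise a warning, never an error: the bounds
  are plausibility heuristics, not physics.
- α = 0.05 default for Tukey letters, configurable.
- Bulk-value measurement σ (~0.1‰) is carried as metadata only; it does
  not enter TP propagation, which uses AA, β and TDF uncertainties.

## Limitations

- Only the two-amino-acid (Glu/Phe) estimator is implemented; weighted
  multi-AA estimators are out of scope.
- The classifier has no rule for intermediate δ13C (−19 to −15‰) because
  well-separated food webs do not produce such values; the anomaly flag
  records, rather than resolves, that gap.
- β uncertainty is propagated per individual; if many individuals share
  one baseline, their TP errors are correlated in reality but treated as
  independent downstream.
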