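# Methods

Statistical models, parameter defaults, numerical choices and limitations of
the `autoab` package. Module-level API details live in the docstrings; this
document explains *why* the defaults are what they are.

## 1. Weighted prevalence (`autoab.prevalence`)

### Model

Each antibody *j* is observed in *k* independent studies; study *i* reports
*x<sub>ij</sub>* reactive subjects out of *n<sub>ij</sub>*. Per-study
prevalence is the raw proportion *p<sub>ij</sub>* = *x<sub>ij</sub>*/*n<sub>ij</sub>*.
A random-effects model of the DerSimonian–Laird type pools the studies:

- *v<sub>ij</sub>* = *n<sub>ij</sub>* / (*p<sub>ij</sub>*(1 − *p<sub>ij</sub>*))
  — the inverse of the binomial sampling variance of *p<sub>ij</sub>*;
- p̄<sub>j</sub> = Σ<sub>i</sub> *v<sub>ij</sub> p<sub>ij</sub>* / Σ<sub>i</sub> *v<sub>ij</sub>* (fixed-effect mean);
- *Q<sub>j</sub>* = Σ<sub>i</sub> *v<sub>ij</sub>*(*p<sub>ij</sub>* − p̄<sub>j</sub>)² (Cochran's heterogeneity statistic);
- v̄ = Σ*v*/*k*, *s*² = (Σ*v*² − *k* v̄²)/(*k* − 1),
  *U* = (*k* − 1)(v̄ − *s*²/(*k* v̄));
- τ²<sub>j</sub> = (*Q<sub>j</sub>* − *k* + 1)/*U* if *Q<sub>j</sub>* > *k* − 1, else 0;
- p̂<sub>j</sub> = Σ *w<sub>ij</sub> p<sub>ij</sub>* / Σ *w<sub>ij</sub>*.

### The two weighting modes

The canonical random-effects weight is the inverse of the total variance of
a study estimate, *w* = (sampling variance + τ²)⁻¹ = (1/*v* + τ²)⁻¹. Because
*v* here denotes the *inverse* sampling variance, a literal reading of
"w = (v + τ²)⁻¹" instead adds τ² to the inverse variance. The two choices
coincide when τ² = 0 and diverge under heterogeneity. Both are implemented:

- `standard` (default): *w* = (1/*v* + τ²)⁻¹ — the usual DerSimonian–Laird
  weighting; heterogeneity shrinks large-study dominance.
- `paper_literal`: *w* = (*v* + τ²)⁻¹ — the literal printed formula, kept so
  results computed under that convention can be reproduced exactly.

Hand-computed oracles for both modes are frozen in the test suite
(`tests/test_prevalence.py`): for counts (5/50, 20/50) the standard mode
gives p̂ = 0.2450 with τ̂² ≈ 0.0417, the literal mode gives p̂ = 0.3181744.

### Boundary stabilization

At *p* ∈ {0, 1} the binomial variance is zero and *v* is undefined. The
variance term (only) is computed from stabilized counts *x*′ = *x* + 0.5,
*n*′ = *n* + 1; the prevalence itself stays the raw proportion. This keeps
every study usable without biasing the point estimates of interior studies.

### Calibration facts

Under true homogeneity, *Q* ~ χ²(*k* − 1) approximately, so the truncation
τ̂² = 0 fires whenever *Q* ≤ *k* − 1 — about 59% of the time at *k* = 5
under independent binomial sampling, and always when the studies report
identical prevalences. The estimator is slightly biased downward for
*p* < 0.5 (≈ 0.008 at *p* = 0.2, *n* = 50) because inverse-variance weights
favour extreme proportions; this is inherent to the printed formulas and is
bounded in the acceptance tests (|bias| < 0.02).

### Group comparisons

`group_compare` wraps the standard two-sample machinery: Welch's t-test
(unequal variances) between adjacent age groups (0–6, 6–12, 12–18, 18–51,
51–84 years), an equal-variance unpaired t-test between sexes, and a paired
t-test for matched prevalence designs. All p-values are two-sided; each
group needs at least 2 observations.

## 2. Concordance (`autoab.concordance`)

The phi coefficient of the subject-level 2×2 table for an antibody pair is
φ = (n₁₁n₀₀ − n₁₀n₀₁)/√(r₁r₀c₁c₀). φ is *undefined* (returned as `None`,
never coerced to 0) when any margin is zero — a never-reactive antibody
carries no concordance information. Studies are combined by Fisher's z:
z = atanh(φ), weighted by *n* − 3 (the inverse variance of z), back-
transformed with tanh. φ values of exactly ±1 are clipped to
±(1 − 10⁻¹²) before atanh to avoid infinities; the clip changes combined
values by less than 10⁻⁶. Studies with *n* < 4 are rejected (weight would
be non-positive). A pair is *reported* when the combined φ exceeds the
floor (default 0.6) **and** φ was defined in ≥ 2 studies — single-study
signals are never promoted.

## 3. Molecular mimicry (`autoab.mimicry`)

Pipeline stages, in order:

1. **Exact dedup** of viral protein sequences (first id kept).
2. **14-mer decomposition** of each viral protein with a 1-residue slide.
   14 is twice the 7-residue match threshold, so every shared 7-mer is seen
   by at least one window.
3. **Repeat filter**: any 14-mer containing a run of ≥ 3 identical residues
   is discarded whole.
4. **Low-complexity masking** of host proteins: windowed Shannon entropy
   (window 12, in bits); windows below the trigger cut 2.2 seed a masked
   region that extends over adjacent windows below the extension cut 2.5
   (a SEG-style two-threshold scheme). `X` residues are always masked;
   sequences shorter than one window are left unmasked.
5. **Exact ungapped matching**: a hash index of unmasked host 7-mers seeds
   diagonal extension in both directions; maximal runs of length ≥ 7 are
   reported. Two collapses keep the output non-redundant: matches whose
   host interval is contained in a longer match from the same
   (host, viral source) pair are dropped, and identical host intervals
   reached through overlapping 14-mer windows are reported once.
6. **Residue-level test**: the fraction of matched residues (union of match
   intervals over unmasked positions) in one protein set versus another is
   compared with Pearson's chi-square on the 2×2 contingency, without
   continuity correction — the convention that reproduces the published
   statistic for the 201/34,070 vs 5,801/2,026,890 contingency
   (p ≈ 6 × 10⁻²⁵).

The matcher is verified against a brute-force all-substring oracle on
randomized instances (small alphabet, threshold 4) in both the unit and
acceptance suites.

## 4. Sequence properties (`autoab.seqprops`)

All residue scales are vendored in `autoab.scales` with their literature
sources: Kyte–Doolittle hydropathy (GRAVY), Chou–Fasman turn propensity,
Emini surface accessibility, Karplus–Schulz flexibility, Parker
hydrophilicity. Secondary-structure fractions use the corrected residue
groupings (helix EMALK, turn NPGSD, sheet VIYFWLT) that current reference
implementations use. The isoelectric point solves Σ charges(pH) = 0 by
bisection on [0, 14] to |charge| < 10⁻⁴, with Bjellqvist pKa values and
residue-specific N/C-terminal adjustments; results agree with the reference
implementation to < 2 × 10⁻⁴ pH units.

Windowed profiles (Chou–Fasman turn w = 4, Emini w = 6, Karplus–Schulz
w = 7, Parker w = 7) aggregate by window mean, except Emini which uses the
published product form Π s / 0.37^w. Windows containing `X` yield NaN;
whole-protein summaries are the NaN-aware means of the profiles. Unknown
residues are excluded and the remaining composition renormalized for global
properties; `length` counts all residues.

## 5. Preranked enrichment (`autoab.enrichment`)

Proteins are ranked descending by a property (ties broken by id for
determinism). The weighted Kolmogorov–Smirnov running sum increments by
|metric|^w / N_R at set members (w = 1 by default) and decrements by
1/(N − N_H) at non-members; the enrichment score is the maximum-magnitude
signed deviation. Significance uses a **gene-set permutation** null
(random same-size sets, vectorized), appropriate when only one phenotype
exists per ranking. NES divides ES by the mean |null ES| of matching sign;
the nominal p is Laplace-corrected, p = (1 + #extreme)/(1 + #same-sign), so
it is never exactly 0. Results backed by fewer than 10 same-sign null
samples are flagged unstable. BH FDR is applied across the property family.
Null p-values are verified approximately uniform (KS test) in the
acceptance suite. At least 100 permutations are required.

## 6. Localization and organ specificity (`autoab.localization`)

Free-text localization terms map through a keyword vocabulary to three
flags (intracellular, cell membrane, secreted), whose non-empty
combinations form seven exclusive groups. Matching is case-insensitive with
keyword containment (so "Golgi apparatus" maps via "golgi"); unrecognized
terms are logged and ignored, and a protein with no mapped term stays
unannotated. Group proportions between a subset and the probed universe are
compared with a two-sided two-proportion z-test (pooled variance);
fractions are reported over annotated proteins, with the all-protein
denominator included alongside.

Organ specificity from an organ × gene TPM table: for each gene and organ,
fold change = (TPM + c)/(mean TPM of the other organs + c) with pseudocount
c = 0.01 (one-hundredth of a transcript per million — negligible against
expressed genes, but keeps zero backgrounds finite). Organs with
log2 FC > 3 (8-fold) are called specific; the log2 FC row is z-standardized
(population sd) for visualization. Tissue-level tables are averaged into
organs by arithmetic mean before scoring.

## 7. Synthetic generators (`autoab.synth`)

The generators exist to give every analysis a ground truth; their defaults
are the simulated study conditions, not tuning knobs.

- **Response matrices**: per antibody, each study's prevalence is drawn
  logit-normal around the true prevalence (default 0.2) with between-study
  sd 0.3 on the logit scale; subjects are independent Bernoulli. Defaults:
  5 studies × 50 subjects × 50 antibodies. Planted concordant pairs share
  one study-level marginal (mean of the two true logits plus a common
  random effect) and draw from the exact 2×2 joint with the target φ —
  without the shared marginal, drifted marginals would cap the attainable
  φ below the target (Fréchet bounds) and the plant would be infeasible.
- **Proteomes**: each reference peptide (29 peptides across 21 autoantigens;
  28 seven-mers and one eight-mer) is embedded once in its host protein
  (background length 200) and once in a viral protein (length 60).
  Backgrounds are uniform random without 3-runs; host and viral flanks of
  each plant are forced to differ so planted matches are maximal at exactly
  the peptide length. The whole instance is rejected and resampled if host
  and viral sets share any accidental 7-mer, or if a planted 7-mer occurs
  outside its plant — so the pipeline's output on this fixture is exactly
  the planted truth, for every seed.
- **TPM tables**: log-normal background (median 5 TPM, σ = 0.25 on the log
  scale) with planted genes set to fold change 16 over the mean of the
  other organs in one organ.
- **Annotations**: group frequencies realized exactly by largest-remainder
  allocation (deterministic), not sampled.

All generators are pure functions of their `SimulationConfig`; identical
seeds give identical outputs.

## 8. Pipeline (`autoab.pipeline`, `autoab.cli`)

Stages run in dependency order (prevalence → concordance → mimicry →
enrichment → localization → tissue) and communicate only through files;
the run manifest records SHA-256 hashes of all inputs, the parameter set
and every output path. A failure writes a `FAILED` marker naming the stage
and re-raises. Reports are written with 6 significant digits and
deterministic column order, so reruns are byte-identical.

## 9. Limitations

- Desk scale only: the printed large-scale results (the 77-antibody common
  set, the healthy-versus-disease frequency correlation, specific combined
  φ values) require the original deposited reactivity matrix and the real
  protein library; they are not recomputed here. The package verifies the
  *methods* on planted synthetic truth instead.
- The mimicry matcher is exact and ungapped by design; it does not model
  substitutions or gapped similarity.
- The localization vocabulary is keyword-based and intentionally small;
  terms outside it are ignored rather than guessed.
- NES magnitudes from gene-set permutation are not comparable to
  phenotype-permutation NES values; only sign and significance carry over.
- The prevalence estimator inherits the small-sample bias of
  inverse-variance weighting of proportions (bounded in the tests); a
  GLMM-based pooled estimate would remove it but would no longer match the
  printed formulas.
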