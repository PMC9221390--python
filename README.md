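# autoab

Meta-analysis toolkit for autoantibody profiles in healthy human serum.

Healthy individuals carry a repertoire of IgG autoantibodies — antibodies
that bind the body's own proteins without causing disease. Pooling binary
antibody × subject reactivity matrices from several independent serum
studies raises two statistical problems: studies differ in cohort size and
assay behaviour (between-study heterogeneity), and any claim that an
autoantigen resembles a viral protein, prefers a subcellular compartment,
or is expressed organ-specifically needs an explicit null. `autoab`
implements the full analysis chain:

- **Weighted prevalence** — a DerSimonian–Laird-style random-effects
  estimator pools per-study prevalences with a moment estimate of
  between-study variance, then calls the "common" autoantibody set at a
  prevalence threshold.
- **Concordance** — phi coefficients on subject-level 2×2 tables per
  antibody pair, combined across studies by Fisher-z weighting.
- **Molecular mimicry** — viral proteins are cut into 14-mer peptides,
  repeat-filtered and screened against low-complexity–masked host proteins
  (windowed Shannon-entropy masking) with an exact ungapped matcher; a
  residue-level chi-square compares match frequencies between protein sets.
- **Sequence properties and enrichment** — aromaticity, GRAVY, isoelectric
  point, secondary-structure fractions and windowed antigenicity profiles
  (Chou–Fasman turn, Emini, Karplus–Schulz, Parker), tested for rank
  enrichment with a from-scratch preranked GSEA (permutation null, NES,
  BH FDR).
- **Localization and tissue specificity** — keyword-based subcellular
  classification into seven accessibility groups with a two-proportion
  z-test, and per-gene organ specificity from TPM tables
  (log2 fold change of one organ against the mean of the rest).
- **Synthetic generators** — every input the pipeline consumes can be
  simulated with known ground truth (planted prevalences, planted
  concordant pairs, planted shared peptides, planted organ-specific genes),
  which is how the package tests itself end to end.

## Model

For antibody *j* observed in *k* studies with per-study prevalence
*p<sub>ij</sub>* = *x<sub>ij</sub>*/*n<sub>ij</sub>*:

- inverse sampling variance *v<sub>ij</sub>* = *n<sub>ij</sub>* / (*p<sub>ij</sub>*(1 − *p<sub>ij</sub>*)),
  with boundary counts stabilized as (*x* + 0.5)/(*n* + 1) for the variance
  term only;
- fixed-effect mean p̄ = Σ*v p* / Σ*v* and Cochran's *Q* = Σ*v*(*p* − p̄)²;
- between-study variance τ² = max(0, (*Q* − (*k* − 1)) / *U*) with
  *U* = (*k* − 1)(v̄ − *s*²/(*k* v̄));
- pooled estimate p̂ = Σ*w p* / Σ*w* with *w* = (1/*v* + τ²)⁻¹ (a
  `paper_literal` mode using *w* = (*v* + τ²)⁻¹ is also provided; see
  `docs/methods.md`).

## Worked example

```python
from autoab.synth import SimulationConfig, gen_response_matrices, gen_proteomes
from autoab.prevalence import StudyCount, weighted_prevalence
from autoab.mimicry import mimicry_screen

cfg = SimulationConfig(seed=1)           # 5 studies x 50 subjects x 50 antibodies
studies = gen_response_matrices(cfg)

counts = [StudyCount(*s.counts("AB0000"), study_id=s.study_id) for s in studies]
res = weighted_prevalence(counts)
print("per-study prevalences:", [f"{c.x}/{c.n}" for c in counts])
print(f"pooled prevalence p_hat = {res.p_hat:.4f}")
print(f"heterogeneity Q = {res.Q:.3f}, tau2 = {res.tau2:.4f}")

hosts, viral, truth = gen_proteomes(cfg)  # 29 peptides planted in 21 autoantigens
matches = mimicry_screen(hosts, viral, threshold=7)
print(f"\n{len(matches)} matches across {len({m.host_id for m in matches})} host proteins")
for m in matches[:3]:
    print(f"  {m.host_id:10s} {m.viral_source_id:10s} start={m.host_start:3d} len={m.length} {m.sequence}")
```

Output:

```
per-study prevalences: ['13/50', '6/50', '5/50', '11/50', '6/50']
pooled prevalence p_hat = 0.1530
heterogeneity Q = 6.788, tau2 = 0.0017

29 matches across 21 host proteins
  ADNP2      P16812     start= 63 len=7 LPVPPGG
  ADNP2      H9C1C1     start=129 len=7 SYFGLRT
  AHCY       F8WQQ3     start= 97 len=7 GKLNVKL
```

The same analyses run from the command line. `autoab synth` writes a full
synthetic input directory and `autoab run` executes the staged pipeline
(each stage communicates only through files and the run manifest records
input hashes and parameters):

```
$ autoab synth --seed 1 --out-dir inputs
$ autoab run --config pipeline.yaml
stages completed: prevalence, concordance, mimicry, enrichment, tissue

$ head -4 out/prevalence.tsv
antibody_id	k	p_hat	tau2	Q	p_study
AB0000	5	0.152976	0.00173072	6.78812	0.26;0.12;0.1;0.22;0.12
AB0001	5	0.179489	0.0119966	24.6221	0.18;0.2;0.16;0.36;0.04
AB0002	5	0.252184	0.00779566	12.967	0.16;0.32;0.3;0.14;0.38

$ head -4 out/matches.tsv
host_id	peptide_source	host_start	length	sequence
ADNP2	P16812	63	7	LPVPPGG
ADNP2	H9C1C1	129	7	SYFGLRT
AHCY	F8WQQ3	97	7	GKLNVKL
```

Individual stages are also exposed as subcommands: `autoab prevalence`,
`concordance`, `mimicry`, `props`, `gsea`, `localization`, `tissue`.

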