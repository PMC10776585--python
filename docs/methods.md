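# Methods

## The statistic and its rationale

At a biallelic locus with sex-stratified minor-allele counts $V_f, V_m$ and
total allele counts $A_f, A_m$, the female-to-male allele proportion ratio
is

$$R = \frac{(V_f + 1)/(A_f + 1)}{(V_m + 1)/(A_m + 1)}.$$

The pseudocounts are fixed, not a tunable prior: +1 on all four terms is
the only convention under which the worked example (18,736/104,056 female
vs 0/38,527 male) evaluates to 6937.5, and it gives $R$ the property that
matters scientifically — with zero male carriers, $R \approx
\frac{V_f+1}{A_f+1}(A_m+1)$ scales with the number of males genotyped
without a carrier, i.e. with the strength of the depletion evidence. An
exact bound follows: $R \le A_m + 1$ always.

On the non-pseudoautosomal X, males are hemizygous, so a variant lethal in
hemizygotes (and in homozygous females) survives only in heterozygous
females: $V_m = 0$, hom-female count 0, high $R$. The statistic is **not**
informative for dominant-effect variants (depleted in both sexes) and this
package deliberately does not model dominance.

`A_f = 104,056` in the worked example is read as total female *allele*
observations, not individuals; only that reading reproduces 6937.5.

## Threshold calibration

Pseudoautosomal variants are diploid in both sexes, hence form an
empirical null for $R$. `PAR_MAX` calibration sets the threshold to the
smallest integer strictly greater than the maximum PAR ratio (a raw-max
mode and an upper-quantile mode exist). Flagging is strict
(`ratio > threshold`) and restricted to non-PAR X by default: PAR variants
are never flagged, and autosomal flagging is opt-in since autosomal
discovery thresholds are not established. "Above" was chosen strict so
that "no PAR variant above 11" and "319 non-PAR variants above this
threshold" are simultaneously coherent statements about a threshold of 11.

Numerical choice: the PAR maximum and its integer ceiling are computed in
exact rational arithmetic (`fractions.Fraction`), because a PAR ratio that
is exactly integral (e.g. 3) rounds *down* in binary floating point
(2.999…96) and would otherwise yield a threshold one unit too low.

## Carrier profiles

From counts plus optional zygosity fields, each variant is categorised:
`ONLY_HET_FEMALES` (no male carriers, hom-female count known to be 0),
`NO_MALES` (no male carriers, zygosity unknown or hom females present),
`MALES_AND_HOM_FEMALES_RARE` (both male carrier frequency $V_m/A_m$ and
hom-female frequency hom$_f/(A_f/2)$ below a rarity fraction, default
1e-4, configurable — no published cutoff exists), `UNRESTRICTED`
otherwise, and `UNKNOWN` when no claim is possible (no carriers at all, or
male carriers present but zygosity unavailable).

## Annotation counting rules

Over the packaged tables of the 25 ClinVar-annotated high-ratio variants:

- **Benign-or-likely-benign** counts the classes Benign, Likely benign and
  the combined "Benign/likely benign" label. The packaged table recounts
  to 21/25 (three Uncertain-significance rows and one Conflicting row);
  narrative summaries elsewhere round this up, but the tally reported here
  is always the recount of the table.
- **QC failure** counts explicit "yes" in the independent genomes dataset:
  22/25 (one variant was not assessed, two passed).
- **OMIM link** counts only *specific* gene–phenotype links: 22/25 (two
  genes only putatively tied to pathology, one with no phenotypes noted).
- **Structural predictability** counts explicit effect calls (neutral /
  stabilizing / destabilizing): 6/25. "Unclear" calls — where the stated
  substitution could not be matched to an isoform — are excluded, as are
  variants with no single amino-acid change (intronic, synonymous, UTR,
  splice).
- **Regulatory evidence** is RegulomeDB rank stratum < 3 (any of 1a–1f,
  2a–2c) **or** score strictly > 0.5: 13/25. The rank comparison is on the
  integer stratum, so 2b with score 0.48 qualifies; the score comparison
  is strict, so 3a with score 0.5 does not.

## The simulator

Each simulated variant has frequency $p$ drawn from the configured
spectrum (default log-uniform on [1e-4, 0.2]; no published spectrum
exists, and log-uniform spreads mass across the rare-to-common range a
screened exome dataset spans). Genotypes follow Hardy–Weinberg; viability
selection acts exactly once, before ascertainment, emulating premature
death depleting an adult sequencing cohort — no age structure, no
multi-generation dynamics, no linkage. Defaults encode the interpretive
model for a male-lethal variant: carrier males survive with $w_m = 0$,
homozygous females $w_{f,hom} = 0$, heterozygous females $w_{f,het} = 1$.

Default cohort geometry: 10,000 genotyped per sex, 20% of variants
pseudoautosomal (always null, simulated with diploid males so $A_m = 2
\times$ male survivors, matching the count structure of real PAR data),
the remainder non-PAR X with hemizygous males; 10% of non-PAR variants
causal. An autosomal mode places diploid variants on chromosome 21 with
sex-specific carrier viability. All randomness flows through a single
`numpy.random.Generator` (PCG64, pinned in config metadata), so identical
configs are byte-identical across runs and platforms.

What the simulator does *not* emulate about real data: sequencing depth
and call-rate variation between sites, relatedness, population structure
and ancestry-specific frequencies, genotyping error correlated with sex
(the very artefact QC filters attribute high ratios to), and reference
bias. Passing calibration/power tests therefore show the statistic behaves
as designed under its own generative model, not that real-data thresholds
transfer across gnomAD releases.

## Operating characteristics and the study conditions used

- **Null calibration** (`analysis/03_null_calibration.py`, 10 seeds):
  10,000 no-effect variants per seed, frequencies log-uniform on
  [0.01, 0.2], 10,000 per sex. The mean log2 ratio stays within 3 standard
  errors of 0 and the PAR_MAX threshold wrongly flags no non-PAR variants
  (non-PAR specificity 1.0 ≥ 0.999 on every seed). The frequency floor for
  *this property* is 0.01 rather than the generator's 1e-4 default because
  the symmetric-null check is only meaningful when counts are informative:
  the pseudocount biases $E[\log_2 R]$ by about $-\log_2(e)/(4 n_m p)$
  under the 2:1 female:male allele-denominator structure, which is
  negligible for $n p \gg 1$ but dominates at $n p \sim 1$. Rare-variant
  ratios are individually noisy by construction; the screen's protection
  there is the allele-count filter (sex-combined minor allele count ≥ 5,
  inclusive, the gnomAD convention) plus the PAR null, which is drawn from
  the same count regime.
- **Power** (`analysis/04_power_analysis.py`): fully male-lethal variants
  with $p \ge 0.01$ and 10,000 genotyped per sex are flagged at threshold
  11 with sensitivity 1.0 across seeds (criterion ≥ 0.95); the expected
  ratio for such a variant is $\approx \frac{p}{1+p}(A_m + 1)$, e.g. ~99
  at $p = 0.01$, far above 11. The median causal ratio rises monotonically
  as $w_m$ falls.

Problem sizes (10,000 variants × 10 seeds; 2,000 × 5 for power) were
chosen to make the binomial Monte Carlo error of each property at least an
order of magnitude smaller than the property's margin.

## External-validation context (not recomputed here)

The screen's published operating point — 44,606 X-chromosome variants
passing the allele-count filter from 76,702 males / 64,754 females, an
empirical PAR threshold of 11, 319 flagged non-PAR variants, and
chromosome-21 ratio summaries (mean 1.5, SD 1.1, max 43.6 over 21,493
ratios) — is a property of a specific gnomAD release whose identity and
genome build are not recorded. These numbers validate the approach against
the external dataset; they cannot be recomputed from packaged inputs and
are not acceptance surfaces for this package.

## Known limitations

- No confidence intervals or shrinkage on $R$; the screen is purely
  empirical ranking plus an empirical threshold.
- Sample-SD (n−1) is used in ratio summaries; the convention is recorded
  in output metadata since published summaries do not state theirs.
- The `variant_io` layer does not lift over between genome builds and does
  not parse per-sample genotypes; PAR coordinates default to the standard
  Ensembl GRCh37/GRCh38 definitions (1-based, half-open) and are
  overridable via a YAML region map.
- Annotation inputs are static tables; no live ClinVar/OMIM/RegulomeDB
  queries.
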