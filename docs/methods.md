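# Methods

## Substitution channels and reference tables

A *signature channel* is a single-base substitution together with its
immediate flanking bases: `(ctx5, ref, alt, ctx3)`. Strand-resolved, there
are 4 × 3 × 16 = 192 channels; folding reverse complements together (so that
GGA→GAA counts as TCC→TTC) leaves the 96 channels with a pyrimidine
reference base. A mutational signature is a probability distribution over
the 192 channels (sum 1 ± 1e−6, validated at load). A 96-channel
pyrimidine-folded TSV is accepted and symmetrized with halved mass per
strand, with a warning, since several public signature releases are
strand-folded.

**Codon usage.** The bundled table is the standard Kazusa human codon-usage
table in per-mil units (rounded to 0.1 as published); the loader rescales
any consistent unit by the column total so frequencies sum to 1. After
rescaling, P(TCC)·P(GAG) = 7.0064e−4, within 3e−7 of the commonly quoted
7.0092e−4 (the residual is the rounding of the published per-mil values).

**Hydropathy.** The Kyte–Doolittle (1982) per-residue scale, in arbitrary
units (AU), positive = hydrophobic. Stop codons carry a configurable
hydropathy (default 0 AU): stop gain is a census quantity, not a
hydrophobicity one, and is reported separately.

**The bundled UV signature is synthetic.** Only one channel probability of
the strand-resolved UV signature is pinned by the literature
(TCC→TTC = 0.2887); no complete 192-channel table is redistributable here.
The bundled stand-in (`data/uv_signature_synthetic.tsv`, labelled synthetic
in file and header) fixes that channel exactly and distributes the
remaining mass by a frozen qualitative model of UV photochemistry: C→T at
5′-pyrimidine (dipyrimidine) contexts dominates, with 5′T > 5′C, a mild 3′
preference C > T > A > G, small C→A/C→G/T→C/T→A/T→G components, and a 5×
transcriptional strand bias against purine-reference (reciprocal-strand)
channels. The folded C→T share is 88%. Quantities that depend only on the
codon table and the scale (baseline exome hydropathy, worked-example
arithmetic) are exact; quantities that depend on the full signature
(per-dose delta, stop-codon gain) are qualitative under the stand-in and
will shift if a published signature table is supplied instead.

## In-silico mutagenesis

The coding genome is modelled as a probability distribution over the 4096
six-nucleotide stretches (two adjacent in-frame codons), initialized with
`mass(s) = P(codon1)·P(codon2)` from codon usage. Six bases are the minimum
that exposes a full flanking context for every position of one codon across
all reading frames.

One iteration applies, to every stretch, all 12 single-base substitutions
at its four interior positions (positions 1 and 6 lack an in-stretch
flanking base and are never mutated; 4096 × 12 = 49 152 transitions). The
signature probability of the corresponding channel acts as a
per-opportunity transition rate: mass `p(s)·q(s→m)` moves from `s` to the
mutant `m`, and unselected mass stays on `s`. This makes each iteration a
sparse stochastic-matrix multiplication — mass is conserved to 1e−9 over
100 iterations — and reproduces the single-iteration arithmetic of the
worked example exactly. At most one substitution per stretch per iteration
(no within-iteration compounding), and the rates are *not* renormalized per
stretch; a signature whose applicable rates sum above 1 for any stretch is
rejected as uninterpretable. One iteration corresponds to one arbitrary
dose unit of UV exposure.

*Reciprocal-strand mode* (off by default) additionally credits the
complement-strand channel of every substitution, modelling damage read off
either strand; the default matches the convention of counting the written
strand only, reflecting the known strand bias of UV lesions.

*Observables per iteration:* expected hydropathy `Σ p(s)·AU(s)` (AU of the
encoded dipeptide; stops contribute the configured stop value), its delta,
the per-slot amino-acid census (mass per residue, × 4096 for a
pseudo-count), and the stop-codon mass relative to iteration 0. The
per-stretch before/after AU-weighted values of iteration 1 feed a Wilcoxon
signed-rank test (scipy).

With the bundled tables, the baseline exome hydropathy is −0.7188 AU
(−0.7191 is the value implied by unrounded codon counts; the per-mil
rounding accounts for the 3e−4 gap) and one dose adds +0.097 AU. The drift
is strictly positive through roughly the first 38 doses and then saturates
as the chain approaches its stationary distribution — C→T opportunities
deplete and the small non-C→T channels pull back slightly (−0.18 AU from
the +0.79 AU peak by dose 100, still far above baseline at every dose).
Under a published UV signature with stronger C→T dominance the monotone
regime extends further; the headline 1- and 20-dose behaviour (positive
delta, stop-codon gain +31% after one dose and +451% after 20 with the
stand-in) is robust to the choice.

A reduced 5-nt mode (one codon plus one flanking base per side, flanks
priored by the codon-usage nucleotide marginal) reproduces the same
qualitative hydrophobicity increase and serves as a robustness check.

## UVMSE scoring

Input is a VCF v4.x or MAF plus an indexed FASTA. SNVs are kept;
equal-length MNVs (e.g. the UV-typical CC→TT tandem) are decomposed into
component SNVs; indels are dropped and counted; reference alleles are
verified against the FASTA and mismatches rejected. Filters follow the
common variant-quality convention: QUAL ≥ 50 and depth ≥ 100 are kept
(records lacking the annotation pass), with an optional BED (0-based
half-open) restriction to a panel footprint.

For each variant a 41-nt reference window (±20, clipped at contig ends) is
extracted. Counts are pooled over all of a sample's windows before the
enrichment ratio is taken — the score is a per-sample statistic, and
overlapping windows are counted in full. The *class* of a channel is its
strand-folded substitution type (C→A, C→G, C→T, T→A, T→C, T→G): for a C→T
channel, `Mut_b` counts the sample's C→T and G→A calls and `Con_b` the C
and G bases in those calls' windows, matching the definition of the
denominator as the same-substitution baseline. Motif counts (`Con_m`) scan
every 3-mer of the windows for the channel motif and its reverse
complement. Degenerate denominators (class never mutated, motif absent —
both common on small panels) yield `E_m = 0`, logged, which is conservative
for an enrichment score. UVMSE sums `p_m·E_m` over the 192 strand-resolved
channels; folded channel pairs share the same `E`, each contributing its
own `p_m`.

The engine is signature-agnostic: any loaded signature yields the analogous
MSE, so non-UV signatures can serve as specificity controls.

*Calibration:* under context-independent mutation placement the score is 1
in expectation (measured 1.00 ± 0.13 per 500-variant sample); it increases
with the fraction of signature-drawn variants and saturates above ~2.3 on
fully signature-drawn samples, because the class-internal normalization
absorbs part of the excess once nearly all mutations share the C→T class.
The *weighted UV load* multiplies the post-filter mutation count by the
score (both pre- and post-filter counts are logged).

## Neopeptide hydrophobicity

Transcripts are user-supplied in-frame CDSs (start codon required unless
flagged partial) with optional expression. An SNV at a CDS coordinate is
applied, both CDSs translated to the first stop; stop-gain truncates the
mutant peptide, stop-loss or frameshift products read through to the next
stop. The full-length delta is `AU(after) − AU(before)`. Neopeptides are
all 8/9/10-mers containing a changed residue, paired with same-coordinate
wild-type windows; starts are clipped at the termini (interior missense:
27 pairs; residue 1: 3), and for truncations the mutant-side window is
clipped at the new terminus so the pair's delta reflects the lost
residues. Per-pair deltas are summed (not averaged) per mutation, and
per-mutation deltas summed per sample. Expression weighting multiplies a
transcript's delta by its fraction of the sample's total expression
(linear; the simplest weighting consistent with "weighted by expression").
Per-sample deltas are correlated against the UVMSE-weighted load with OLS
(R², slope t-test) plus Spearman rank correlation.

## Cohort analysis

The cohort table carries per-patient UVMSE, TMB (mut/Mb), RECIST best
response, and right-censored PFS/OS. Responders are CR/PR. TMB bins: low
1–5 (values < 1 folded into low), intermediate 6–19, high ≥ 20; strata pool
low with intermediate, versus high. The dichotomization threshold defaults
to 0.7917 (the published immunotherapy-cohort cutoff, shipped as a
documented constant — cohort-dependent and not reproducible from synthetic
data; 1.642 is likewise recorded for whole-exome comparisons).
`roc_threshold` re-derives a cutoff on any cohort by maximizing Youden's J
over midpoints of adjacent distinct scores ("ROC curve method" does not
pin a unique rule; Youden's J is the standard choice and is documented as
such), with score ≥ threshold = UV high. Fisher's exact test gives the
two-sided p; the odds ratio is the cross-product with a log-OR normal 95%
CI (Haldane–Anscombe +0.5 on zero cells, flagged). Survival uses lifelines:
product-limit medians (undefined = "not reached") and the Mantel–Cox
log-rank test. Multivariate logistic/Cox modelling is intentionally out of
scope; the tidy table supports external fitting.

## Synthetic fixtures

The generators emulate the statistical structure the methods assume, not
real genomes: an iid reference with adjustable GC (default 0.41, human-like);
variants placed either at uniformly random positions (background) or at
positions whose 3-mer context matches a channel drawn from the signature,
on either strand, with mixing fraction `f`; QUAL/DP sampled above the
default filters so filter behaviour is tested explicitly; a transcriptome
of clean ATG…stop CDSs with log-normal expression; a cohort with ~30%
UV-high patients, log-normal TMB (median ≈ 6 mut/Mb, ~10% ≥ 20 — the
conventional low/intermediate/high split), a planted response-probability
and exponential-survival advantage for UV-high patients confined to the
low/intermediate-TMB stratum, and uniform censoring over 48 months.
Everything is a deterministic function of (parameters, seed).

Passing tests on these fixtures demonstrate internal consistency and
parameter recovery under the assumed model; they do not capture real-data
features such as non-iid genome composition, mutation clustering, panel
footprint bias, calling artifacts, or cohort confounding (tumor type,
therapy line), so published cohort-level constants (thresholds, R², mean
scores) are not reproduction targets.

## Numerical and scale choices

- Simulation problem sizes: 4096 stretches × 49 152 transitions as one
  sparse matrix; 100 iterations run in seconds. Synthetic scoring uses a
  20 kb reference and 500-variant samples; Monte-Carlo statements average
  5–20 seeds.
- The UVMSE-vs-f monotonicity is a property of the score's expectation;
  tests compare 5-seed means per f because single 500-variant draws
  overlap in the saturated regime.
- All coordinates are 1-based inclusive at the VCF/FASTA interface and
  0-based half-open for BED; conversions are centralized in the scoring
  module.
- Accumulation in double precision; per-channel breakdowns retained for
  inspection rather than rounded.

## Known limitations

- The bundled signature is a stand-in; absolute simulator deltas and score
  magnitudes shift under a published signature table (the pinned TCC→TTC
  probability, combinatorics, and all codon-table-only quantities do not).
- No nucleotide-excision-repair or genome-coordinate-aware simulation; the
  stretch model is reading-frame complete but positionally exchangeable.
- No MHC binding prediction, proteasomal processing, or NMD modelling; the
  8–10-mer enumeration is presentation-range bookkeeping only.
- TMB is accepted as an input column; the panel-to-exome extrapolation that
  produces it is vendor-specific and out of scope.
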