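# Methods

This note documents the models, parameter choices and known limitations of
`zwscreen`, in the package's own terms.

## The problem and the study design it assumes

The package targets the discovery of W-linked markers in a
female-heterogametic (ZW/ZZ) fish from pooled gonad RNA-seq: replicated
female and male pools (default 6 + 6 pools of 2 fish) are sequenced, reads
are assembled and counted per contig, and contigs transcribed in females
but absent from males are candidate W-linked markers. Everything upstream
of the count matrix — read QC, de novo assembly, mapping — is out of scope;
the inputs are a contig × pool count matrix with pool sex labels, library
sizes and contig lengths, plus contig sequences in FASTA.

## Synthetic-data generator

`simulate.py` draws a transcript universe with six classes (autosomal,
Z-linked, W-linked, female-biased, male-biased, contaminant) and a pooled
count matrix with the statistical structure the screen assumes:

- **Counts** are negative binomial with mean
  μ = base_rate × sex_multiplier × length × library_size and gene-wise
  dispersion φ (variance μ + φμ²), matching the NB assumption of the
  screen's posterior. φ is log-normal, default median 0.1 (log-mean
  ln 0.1, log-sd 0.5) — a typical bulk RNA-seq overdispersion scale.
  φ → 0 degrades to Poisson.
- **W-linked** transcripts have a structurally zero male multiplier: their
  male counts are exact zeros, not small numbers.
- **Sex-biased** classes use a favored-sex fold change (default 4).
- **Contaminants** (bacterial carry-over) are present in a random subset of
  pools irrespective of sex, so a female-only contaminant can arise by
  chance and exercise the exclusion-list path; identifying contaminants
  (a database lookup in practice) is an input, not a computation.
- **Library sizes** are log-normal around 10⁶ with CV 0.2. Per-pool depth
  variability is not dictated by the study design, so CV 0.2 — a typical
  spread for libraries sequenced together — is a free choice, fixed once.
- **Expression rates** are log-uniform over (10⁻⁷, 5·10⁻⁷) reads per bp
  per unit library size, so a W-linked transcript of ≥ 600 bp expects
  ≥ ~36 reads per female pool at nominal depth — comfortably inside the
  regime where the screen should reach full sensitivity.
- **Reproducibility**: every operation takes one integer seed; each
  transcript gets a child RNG stream keyed by its index, so outputs are
  bit-identical for a fixed seed and invariant to evaluation order.

What the generator does *not* emulate: read-level errors, assembly
artifacts (chimeras, fragmented contigs), mapping ambiguity, GC or length
bias, and correlated library composition effects. Passing tests therefore
demonstrate the statistical logic of the screen under its own model
assumptions, not robustness to the full messiness of real RNA-seq.

## Candidate screen

A contig is a final candidate iff all of: female-exclusive, length > 500 bp
(strictly: `min_length_bp` = 501), DE posterior ≥ 1 − 10⁻⁶, and not on the
exclusion list.

**Exclusivity** is defined on mapped counts — zero total male reads
(configurable via `max_male_reads_total`) and at least one female pool with
≥ 1 read (`min_female_pools_present` = 1, since a transcript can be
assembled from a single pool's reads).

**The DE posterior** replaces a black-box "likelihood of differential
expression" with a defined two-model comparison. Per contig: method-of-
moments dispersion φ̂ = max(0, (s² − m̄)/m̄²) on offset-scaled counts,
estimated within each sex and pooled with degrees-of-freedom weights (no
shrinkage across contigs — the simplest defensible choice, diverging from
empirical-Bayes tools that share information across genes); maximum-
likelihood rates under a shared-rate model M0 and a per-sex model M1
(1-D bounded optimization on log θ, started at the Poisson MLE Σy/Σo,
guarded never to fall below the likelihood at the start; an all-zero side
has the exact boundary solution θ = 0 with log-likelihood 0); model scores
penalized by (k/2)·ln(n_pools) (BIC); posterior = softmax of scores with
prior P(DE) = 0.05, in log-space. The posterior is symmetric under sex
relabeling and invariant to global library-size rescaling.

The threshold 1 − 10⁻⁶ operationalizes "posterior of 1" at 6-decimal
reporting precision. Under null simulations the criterion fires at ~0.02%
of contigs, far below the 5% prior — the BIC penalty plus the extreme
threshold make the screen conservative by construction.

**Assembly metrics** (N50; reference-gene coverage
(gene + average UTR length)/(contig length excluding N's)) are provided for
assembly evaluation workflows and validated against direct formula
evaluation.

## Primer engine

Defaults mirror conventional marker-PCR settings: Tm min/opt/max
59/60/61 °C, pair ΔTm ≤ 1 °C, max homopolymer 3, one-base 3′ G/C clamp,
product 480/500/520 bp, primer length 18–27 nt, 50 mM Na⁺, 500 nM oligo.

Tm uses the unified nearest-neighbor parameter set with initiation terms,
the two-state formula Tm(K) = ΔH/(ΔS + R·ln(C_T/4)) for non-self-
complementary oligos, and the logarithmic monovalent-salt correction.
Perfect-match values agree with Biopython's independent implementation of
the same table to < 0.01 °C. No claim of numeric agreement with any
particular primer-design program's Tm is made: the compatibility surface is
the constraint logic, not the Tm values.

**Mismatched duplexes** (species/allele-specific design) use a
destabilization floor rather than mismatch-parameterized NN tables: stacks
touching a mismatched position are zeroed, terminal initiation terms always
apply, and each mismatch costs +2 kcal/mol of ΔH. The penalty term is
load-bearing: stack removal alone can *raise* the two-state Tm when the
removed stack's ΔH/ΔS ratio (~338 K for TA) lies below the duplex's
pre-salt melting point, so zeroing by itself does not guarantee that a
mismatch destabilizes. With the penalty, off-target Tm strictly decreases
with each covered difference, which is the property the ΔTm ranking needs.
The +2 kcal/mol magnitude (≈ 2–4 °C per mismatch for a 20-mer) is a
deliberately mild, conservative figure; swapping in full mismatch NN tables
would be a drop-in refinement. Fully destabilized duplexes (ΔH ≥ 0) are
floored at 0 °C.

Pair enumeration is exhaustive over all windows within the length bounds;
feasible pairs are ranked by |Tm_f − 60| + |Tm_r − 60| + |product − 500|/100
with ties broken by leftmost forward start — fully deterministic. Product
size is the inclusive 5′-to-5′ span. Multiplex compatibility demands
pairwise product separation (default 40 bp) and a control product strictly
smaller than every candidate product.

## Species diagnostics

Ortholog pairs are aligned by Needleman–Wunsch with affine gaps (Gotoh;
match +2, mismatch −1, gap −12 − 2 per base), deterministic tie-breaking
(diagonal, then gap-in-B, then gap-in-A). DNA scoring is used even though
some alignment GUIs apply protein matrices to DNA; the gap weights echo
conventional settings. Scores are verified against exhaustive enumeration
on short pairs and cross-checked against Biopython's aligner.

Diagnostic primers are windows whose 3′-terminal base sits on a
discriminating site and which cover ≥ 2 (configurable) sites, gap-free in
both species; pairs are ranked by the smaller of the two primers' ΔTm,
descending. In-silico PCR scans both strands for binding sites with ≤ 2
internal mismatches and a mandatory 3′-terminal match (allele-specific PCR
logic; both configurable) and reports all productive forward/reverse-
complement site pairs with the inclusive 5′-to-5′ product span.
Annealing-temperature-dependent amplification efficiency is out of scope —
binding is sequence-rule-based only.

## Clock dating

p-distance (uncorrected) is rounded half-up to 4 decimals *before*
division by the fastest and slowest calibrated rates; times are rounded
half-up to 2 decimals. The pre-rounding convention matters: 6/396 bp gives
1.52%, and 0.0152/0.044 = 0.345 → 0.35 Myr, whereas the unrounded fraction
would print 0.34. The rounding rule is inferred from the standard worked
examples and fixed as half-up. No multiple-hit correction is applied;
corrected distances would be a config-gated extension.

## Validation reporting

Band presence maps deterministically to genotype (ZW iff band).
Discordant individuals (phenotypic female without band, or male with) are
annotated "putative sex reversal or W/Z recombination" and never
reassigned: PCR alone cannot distinguish a naturally feminized ZZ
neo-female from a W/Z recombinant. The packaged `replica_cohort()` is a
synthetic 115-individual stand-in for a typical two-population validation
panel (25 F + 19 M and 28 F + 42 M, plus one discordant female whose
population is deliberately unassigned); the per-individual genotyping table
it emulates is not published, so the fixture is labelled synthetic.

## Problem sizes used in the test suite and acceptance script

Simulation-based checks run at desk scale, chosen to keep Monte-Carlo
error well inside the asserted tolerances: 1,000-transcript screens with
6 + 6 pools; null calibration over 100 (tests) or 50 (acceptance script)
simulations of 100 contigs; diagnostic design over 10–20 simulated 1 kb
ortholog pairs at 5% divergence; cohort Monte-Carlo at 1,000 individuals ×
200 seeds. Dataset-scale quantities from real experiments (tens of
thousands of contigs, hundred-candidate lists) depend on external data and
are deliberately replaced by truth-recovery properties on simulations.

## Known limitations

- The DE posterior is a defined, conservative statistic analogous to — but
  not numerically equivalent to — empirical-Bayes NB tools; no equivalence
  with any specific tool's output is claimed.
- The mismatch Tm model ranks reliably but does not predict experimental
  mismatch Tm shifts quantitatively.
- The simulator's independence assumptions (no correlation between
  contigs, no composition effects) make the null calibration optimistic
  relative to real libraries.
- In-silico PCR ignores primer secondary structure, dimers and annealing
  kinetics.
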