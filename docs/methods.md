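# Methods

Definitions, modelling assumptions, default parameters, and limitations of
each `cagedit` module. Everything below describes what the code computes;
no empirical claims are made beyond what the implemented models and
simulations produce.

## Repeat-allele model (`repeat_model`)

An allele is a tuple of trinucleotide codons for the *HTT* exon-1 repeat
tract. Structure classes:

- **canonical** — an uninterrupted CAG run followed by exactly one CAA–CAG
  doublet; glutamine length = CAG + 2.
- **LOI** (loss of interruption) — pure CAG run, no doublet; glutamines =
  CAG.
- **DI** (duplicated interruption) — run followed by two consecutive
  CAA–CAG doublets; glutamines = CAG + 4.
- **custom** — anything else (e.g. the interrupted knock-in repeat of
  tandem CAG-CAA-CAG-CAA-CAA units).

`uninterrupted_cag_length` is the longest run of consecutive CAG codons —
the phenotype-relevant quantity. `glutamine_length` counts CAG and CAA
codons (both encode glutamine).

**Site numbering.** Conversion sites are positional: the maximal trailing
run of CAA–CAG doublets is stripped, and the remaining codons are numbered
1..m. This keeps site numbers stable across successive edits of the same
allele. `apply_conversion(allele, s)` requires the codon at site *s* to be
CAG; converting a site that is already CAA (or out of range) is an input
error. Converting the penultimate CAG of a canonical allele produces a DI
allele — the intended therapeutic outcome, since it removes two CAG from
the run while adding no or fewer glutamine changes.

**Effective CAG.** `effective_cag(allele, offsets)` returns the
uninterrupted CAG length plus a class-specific additive offset. Defaults
are +3 for LOI and −1 for DI — the values the offset estimator recovers
from its own simulated cohorts (below) and the convention used throughout
this package. Custom alleles require an explicit offset.

**Locus template.** The default template carries ~50 nt flanks with the
amplicon primer sites and named canonical alleles (16/17 CAG by default,
matching a heterozygous HEK293-like configuration). Templates are
YAML-configurable.

## Guide design (`guide_design`)

The repeat is periodic, so a 20-nt spacer can hybridize in many registers.
`enumerate_registers` scans both strands for all placements within a given
Hamming distance (bulges are not modelled). Editor profiles hold an
ordered list of PAM classes (e.g. NGG rank 1, NGN rank 2 for relaxed
variants) and an activity window expressed as distance from the PAM
(13–17 nt for BE4-class editors; spacer positions are counted 1..20 from
the 5' end, so this window covers spacer positions 4–8).

`window_cag_sites` maps a register's window onto sense-strand CAG sites:
only antisense-strand registers can produce CAG→CAA (the edited antisense
C must pair with the wobble G of a sense CAG codon); sense registers
return the empty set with a warning. Predictions are ranked by PAM rank,
then mismatch count, then PAM-distal mismatch preference.

Limitations: no deamination-efficiency model (the window is treated as
uniform), no bystander scoring beyond window membership, no off-target
genome search.

## Read QC (`amplicon_qc`)

Four filters, applied in order, with each removed pair attributed to the
first filter it fails:

1. mean base Phred < 20 on either mate (a mean of exactly 20 is kept);
2. mate discordance — merging requires a zero-mismatch overlap of ≥ 30 nt
   between R1 and the reverse-complement of R2;
3. fewer than 6 CAG trinucleotides in the merged sense sequence;
4. absence of the exact forward primer near the 5' end or the exact
   reverse-complemented reverse primer near the 3' end (30-nt search
   window).

The number of kept reads is invariant under filter order (each filter is a
pure predicate); only the attribution depends on the order. Exact-overlap
merging is deliberately strict: any sequencing error in the overlap
removes the pair, which trades yield for consensus purity.

## Conversion calling (`conversion_calling`)

Kept reads are decomposed into codons between two 12-nt flank anchors.
Reads are assigned to the nearest known allele by codon count; length
differences are classified as in-frame insertions/deletions (whole codons)
or frameshifts. With a heterozygous template whose alleles differ by one
codon (16/17), a single-codon indel of one allele is indistinguishable
from the other allele — an inherent ambiguity of length-based assignment,
which slightly deflates apparent indel rates in that configuration.

Per read, each repeat site is called CAG (reference), CAA (conversion), or
one of seven other single-base variants of CAG; the nine-type spectrum is
tallied presence-based over the leading CAG run. Per-site conversion
percentages use either all assigned reads (default) or only "eligible"
reads (clean, expected-length, CAG/CAA-only) as denominator. An
empty-vector baseline vector can be subtracted; differences are floored at
zero.

The duplicated-interruption fraction is the percent of reads whose tract
ends CAA-CAG-CAA-CAG. Allele-specific summaries compare per-replicate
conversion efficiencies between alleles with a Welch t-test (skipped, with
a warning, below two replicates).

## Onset model (`onset_model`)

Expected age at onset follows `E[onset] = α + exp(β − γ·CAG)`, or an
explicit lookup table for worked examples. `SIM_DEFAULT_COEFFS = (21.5,
9.56, 0.146)` are the simulation defaults used by this package's cohort
generator; they are curve parameters of the implemented model, not
estimates from any external dataset. `fit_onset_model` fits the three
coefficients by nonlinear least squares (requires ≥ 3 distinct CAG
values).

Class offsets are estimated by grid search: for integer offsets −10..10,
the residual sum of squares of `onset − E[CAG + offset]` is minimized;
ties break toward zero. `onset_delay` converts an in-silico edit into a
predicted onset difference via effective CAG before and after the edit.

Limitations: the offset grid is integer-valued; onset variance is treated
as homoscedastic; no censoring or cohort ascertainment model.

## Somatic instability (`instability`)

A fragment-analysis trace is a list of (repeat-size, height) peaks. Peaks
below 10% of the tallest peak are discarded; remaining heights are
normalized to fractions. The **expansion index** is `Σ f_i · Δ_i` over
peaks with positive repeat-unit gain Δ relative to the main allele, which
is anchored on the matched tail-DNA trace (falling back, with a warning,
to the trace's own modal peak). A symmetric contraction index is provided.

Treatment effects are estimated by OLS of the expansion index on treatment
(reference: PBS) with tail CAG, age, sex, and batch as covariates
(statsmodels; categorical covariates reference-coded, single-level
covariates dropped, rank-deficient designs rejected with the offending
columns named).

Limitations: peak calling itself (from raw electropherograms) is out of
scope — traces enter as peak tables; the 10% threshold is a convention,
exposed as a parameter.

## Simulators (`synthetic_data`)

All generators derive an independent named RNG stream from a single seed
(`numpy` `default_rng([stream_id, seed])`) and emit truth records.

- **Reads**: full-amplicon mate pairs over configured alleles with
  per-site conversion probabilities, non-CAA variant codons, whole-codon
  indels plus frameshifts (default per-read indel rate 0.10, emulating the
  apparent-indel background of repeat amplicon sequencing), per-base
  error, Gaussian Phred scores, and injected mate discordance.
- **Cohorts**: onsets drawn as `E[CAG + class offset] + N(0, σ)` with
  defaults σ = 6 y, 21 LOI and 69 DI carriers, CAG 40–50, offsets +3/−1.
- **Traces**: a modal peak plus a geometrically decaying expansion tail;
  the truth record carries the analytic expansion index of the noiseless
  trace after thresholding (the `drift` knob sets tail mass, not the index
  directly). Optional noise peaks stay below the threshold.

Simulation defaults describe the regimes the estimators are tested in;
they are not fitted to external data.
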