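# Methods

## Signal model

Chemical reduction converts dihydrouridine (D) into a species that
reverse transcription reads as C, so a D site appears in aligned
sequencing data as a T→C misincorporation. The package models the
observed mutation ratio at a reference uridine as a linear function of
the true modified fraction *x* of the transcript pool:

    y = A·x + b,      0 < A ≤ 1,  0 ≤ b ≤ 0.2

with slope *A* (read-through conversion efficiency) and intercept *b*
(background misincorporation of unmodified uridine) both specific to the
5-mer sequence context centered on the site. 256 such contexts exist.
Curves are fitted per motif by ordinary least squares from a defined
mixture series — probes carrying 0, 20, 40, 60, 80 and 100 % D in a fixed
35-nt scaffold whose flanks contain no uridine — and inverted at call
time, x̂ = (y − b)/A, clamped to [0, 1] with an explicit flag when
clamping fires (over-/under-shoot is measurement noise, not an error).
Depth-weighted least squares is available by flag; the default is
unweighted because probe depths are near-uniform in this design. When a
motif has no fitted curve the global mean curve (mean A, mean b over
available motifs) is used and the call flagged.

**Mutation ratio.** The default denominator is C + T (the conversion
semantics of three-letter aligners): r = n_C/(n_C + n_T). The assay does
produce few T→A/T→G events, so an `any_mismatch` mode
((depth − n_T)/depth) is offered; whether the original pipeline used
depth or C + T as denominator is not stated, so both are exposed and the
choice is recorded in output headers. Deletions are tallied but excluded
from depth and from either ratio — the signal of this chemistry is
misincorporation, not truncation or deletion. A ratio with an empty
denominator is undefined (flagged), never zero.

## Site calling

Both callers evaluate every reference-uridine site and report one record
per site with per-criterion pass flags, so filtering is auditable; a site
is *called* only if all applicable criteria pass. "Above"/"below" are
strict inequalities throughout. Replicates are pooled by count summation
for all ratio criteria; the mRNA t-test alone uses per-replicate ratios.

**ncRNA (tRNA-scale) criteria**, defaults in parentheses: (1) treated
ratio > 0.20 with mismatch count > 5; (2) Input1 and Input2 ratios each
< 0.15; (3) depth > 50 in treated and both inputs; (4) treated ratio
> 3× the motif's 0 %-D background; (5) > 3× the Input2 ratio; (6) not a
multi-U context; (7) uridine sites only (enforced structurally). Fold
denominators are floored at ε = 1e-4 so perfectly clean motifs or
zero-ratio inputs cannot divide by zero.

**mRNA criteria** against an in-vitro-transcribed (IVT) background:
site universe = uridines covered in both cellular and IVT libraries;
(1) cellular ratio > 0.20; (2) IVT ratio < 0.20; (3) two-sided t-test
between per-replicate cellular and IVT ratios p < 0.05 *and* cellular
ratio > 3× IVT; (4) no overlap with annotated tRNA intervals;
(5) cellular ratio > 2× motif background and > 2× Input2; (6) cellular
depth > 30; (7) not multi-U; (8) exact one-sided binomial test of the
mismatch count against the motif background rate, p < 0.05.

Design choices where the procedure was genuinely open:

- **Multi-U definition.** "Multi-U context" is read as an immediate
  uridine neighbor (UU dinucleotide) by default, since adjacent uridines
  are where mutation signal bleeds between sites during analysis; a
  stricter mode (any additional U in the 5-mer) is a flag.
- **t-test variant.** Welch (unequal variance) is the default; pooled
  Student is a flag. Note the power consequence under duplicate designs
  described in Limitations.
- **Fold-change conflict.** Where the flowchart description (2-fold over
  IVT) and the procedure text (3-fold) disagree, the procedure text wins
  as the default (`fold_over_ivt = 3.0`); both are configurable.
- **Binomial null.** The criterion names "the background", so the motif
  background rate is the default null; an IVT-ratio null is a flag.
  Multiple testing is off by default (matching the original procedure);
  Benjamini–Hochberg across tested sites is available and can only make
  the criterion stricter.
- **Input2 in criterion (5).** Read as the cellular Input2 library;
  flagged as an interpretation in the config docstring.
- **Single-replicate data.** Without ≥ 2 replicates per condition the
  t-test criterion cannot be evaluated; such sites are flagged
  provisional and are never called.
- **Missing data.** A site covered in treated but absent from an input
  is evaluated (for auditability) with missing-data flags and can never
  be called.

**Degenerate statistics.** Zero variance in both t-test groups gives
p = 1 for equal means, p = 0 otherwise; the same convention applies to
the paired test when all deltas are equal (detected with a 1e-12
tolerance to absorb float cancellation). These are flagged conventions,
not silent defaults.

## Dynamics and writer assignment

Stoichiometry is compared between conditions by pairing sites on
(reference, position) and applying a two-sided paired t-test to the
deltas. Writer assignment formalizes the knockdown readout: a site is
assigned to the dihydrouridine synthase whose depletion produces the
largest stoichiometry drop, provided that drop strictly exceeds an
absolute threshold (default 0.10); exact ties and sub-threshold drops
stay "unassigned", reflecting compensatory deposition among the DUS
enzymes rather than forcing a choice. The 0.10 threshold is a package
choice (the original heatmaps show but do not threshold their drops) and
is configurable.

## Synthetic data

The generator emulates the statistical structure the callers assume, not
raw reads: at each reference uridine the expected treated ratio is
clip(A·f + b, 0, 1) with (A, b) per motif (defaults A = 0.9, b = 0.05,
matching the high conversion and few-percent background of the probe
series); n_C ~ Binomial(N, y) with n_T = N − n_C; input and IVT libraries
use f = 0, inputs with *b* scaled by a configurable factor; depth is
fixed or Poisson. One integer seed drives per-condition/replicate
substreams, so identical configs are byte-identical. An optional uniform
miscall rate adds A/G calls; it is off by default because the assay's
background is dominated by the motif-level intercept.

What it does **not** emulate — and hence what passing tests do not show
about real data: alignment and mapping artifacts (multi-mapping in tRNA
families, indels), positional coverage bias, UMI/PCR duplication
structure, RT truncation, other uridine modifications that mutate in
inputs (acp³U confounds are handled by the input-ratio criterion, not
simulated), and correlated replicate noise.

## Problem sizes and seeds

The test suite and the acceptance script use simulation sizes chosen to
exercise every criterion with comfortable statistical margins: ~5,000
background uridines for ncRNA recovery (20 planted sites, depth 500,
duplicate treated libraries), ~10,000 for mRNA recovery (8 planted
sites at fractions 0.10–0.40, depth 200, duplicate cellular and IVT
libraries), 100–200 seeded series for calibration fit recovery, and
depth 1000 for stoichiometry RMSE. All randomness is seeded; the
acceptance script derives independent sub-seeds from its `--seed` flag.

## Known limitations

- **Analytic detection limit.** The published cutoffs impose a floor on
  callable stoichiometry under this signal model: ratio > 0.20 implies
  f > (0.20 − b)/A (≈ 0.17 at the default A = 0.9, b = 0.05), and the
  3-fold-over-IVT rule independently implies f > 2b/A. Minimizing over
  b, no site below f ≈ 0.15 can satisfy both regardless of motif, so
  the lowest-stoichiometry sites in the 0.10–0.40 regime are structurally
  uncallable and measured sensitivity there reflects the criteria, not
  the implementation.
- **Welch with duplicates.** With two replicates per group the
  Welch–Satterthwaite df is ≈ 1 (critical t = 12.7), so the t-test
  criterion rejects a noticeable share of genuinely strong sites; the
  pooled-Student flag (df = 2) is considerably more powerful for
  duplicate designs.
- Calibration is linear only; saturating response at extreme conversion
  is clamped, not modeled.
- Sprinzl-style canonical tRNA position labels are user-supplied
  annotation; the package groups by them but never infers them.
- The pileup path is for small text SAM fixtures, not production BAM
  throughput; production use starts from per-site count tables.
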