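# Methods

## The measurement being modelled

A pooled Y2H selection screen couples binding of a bait kinase to a
docking-site peptide (grafted into a reporter substrate fragment) to yeast
growth under histidine dropout. A library of 14-mer docking-site variants
competes in liquid culture; samples drawn at known cumulative population
doublings are amplicon-sequenced over the variable region, and each
member's abundance trajectory summarises how well it binds. The package
analyses that readout and, because the real sequencing data live in
external repositories, ships a generative stand-in with the same
statistical structure.

## Enrichment scores

Frequencies are computed per sample as
`F_ij = (c_ij + a) / Σ_i (c_ij + a)` with a uniform pseudocount `a = 0.5`
(configurable). For each member and replicate screen the package regresses
`y_t = ln(F_t / F_0)` on the doubling grid by ordinary least squares with a
free intercept, including the baseline point (0, 0) as data; the slope is
the enrichment score (ES). Conventions, and why:

* **Baseline zeros are exclusions, not imputations.** A member with a raw
  count of 0 at the baseline of a replicate gets a missing ES in that
  replicate: a slope anchored at an imputed baseline measures the
  pseudocount, not the member. The pseudocount only guards against zeros at
  later timepoints, where it perturbs the slope by O(a / depth).
* **Free intercept.** Sampling error in the baseline shifts every point of
  a member's trajectory by the same amount; a free intercept absorbs it
  instead of leaking it into the slope. The (0, 0) point is kept as an
  ordinary observation.
* **Natural log, doublings on the x-axis.** Under exponential growth
  `N_i(t) = N_i(0) e^{g_i t}`, ES = ln2 · (g_i − ḡ)/ḡ̃ in the small-spread
  limit, i.e. a relative fitness per population doubling. ES 0 means
  growing with the population; because frequencies sum to one, any screen
  with real enrichment also shows bulk depletion (negative mode of the ES
  distribution).

Replicate ES are averaged unweighted over the replicates where they are
defined (`n_replicates_used` recorded). Z-scores are computed per screen
(genotype × condition) over the replicate-averaged ES with the sample
(n−1) standard deviation; per-replicate Z is also emitted for
replicate-consistency filters. Screens whose ES are constant (degenerate)
get missing Z from the model fit; the standalone `zscores` operation raises
instead.

The per-member regression is the closed-form estimator, vectorised over
members; the test suite checks it against an independent general OLS
implementation to 1e-10.

## Hit calling and comparison

A hit has Z strictly greater than 3 (the boundary is excluded; a lenient
flag is available). Given a reference screen and two mutant screens:
lost = reference hits absent from both mutant hit sets; common = reference
hits shared with at least one mutant (the "both mutants" count is also
reported, since published overlap language is ambiguous between the two);
gained = hits in both mutants but not the reference. All seven Venn cells
are emitted. Only *hits* are categorized — a member that never clears the
hit threshold in the reference screen belongs to no category, which is the
denominator convention the end-to-end recovery checks use.

The relaxed membership takes the `ceil(p·N/100)` members with highest mean
ES (default p = 3), ties broken lexicographically by member id. The
differential ranking scores candidates by
`Δ = ES_ref − mean(ES_mut1, ES_mut2)` (a `max` alternative is exposed;
the choice of combining the two mutant screens is a declared convention,
not something the screen design forces).

## Synthetic screen generator

What it emulates, per member *i* and genotype:

* **Library**: 14-mers conforming to the design consensus
  `[R/K]-x(0,2)-[R/K]-x(3,5)-[ILV]-x-[FILMV]`; an exact fraction
  `frac_heptp` (default 0.05) additionally carries `I/L-x-x-R-R` starting
  within the first four positions (the CD-site element), with the
  remaining members rejection-sampled to exclude it. DNA is a fixed
  most-frequent-yeast-codon reverse translation, so libraries are
  byte-reproducible and peptide-level read matching is exercised by
  synonymous-variant reads.
* **Affinity**: reference-genotype dissociation constants are log-uniform —
  generic members over 1–100 µM, CD-element members over 0.1–100 µM (they
  carry a genuine docking element), and a rare fraction (2%) of generic
  members are strong *common* binders (0.05–1 µM) whose binding does not
  involve the CD site. In each mutant genotype, CD-element members have
  their Kd multiplied by a log-uniform fold loss from 3–40 (the published
  range for mutation-sensitive peptides); everything else keeps its
  affinity.
* **Fitness link**: occupancy-saturating, θ = C/(C + Kd) with bait scale
  C = 1 µM, and selective growth g = r0(1 + s·θ) with r0 = 0.5/h, s = 1.
  The saturating link is deliberate: very strong binders plateau, while a
  3–40-fold affinity loss in the transition region still separates
  genotypes. Nonselective growth is r0 for everyone.
* **Propagation and sampling**: deterministic exponential growth from equal
  starting abundance (an optional Poisson founding bottleneck models the
  transformation step); each requested cumulative doubling D on the default
  grid {0, 1.75, 3.5, 5.25, 7} is converted to a time by a monotone root
  solve of log2(total growth) = D; reads are multinomial at fixed depth
  (default 1e5), with an optional Dirichlet-multinomial overdispersion
  knob for PCR-jackpot-like noise. Replicates (default 3) share the truth
  and differ only in sampling substreams. FASTQ emission writes
  anchor5′ + insert + anchor3′ reads at constant quality, shuffled
  deterministically.

The Kd ranges were calibrated against the pipeline's own prescribed
operating points: at depth 1e5 with 3 replicates, the ES ranking must
resolve true growth rates (Spearman > 0.9), and the Z > 3 tail must select
roughly the top ~1–2% of members, matching the hit rate of real screens of
this design (~120 hits in ~12,000 members). Wider ranges (upper bound
1000 µM) leave the weak half of the library with growth differences below
sampling noise; floors below ~1 µM for the generic pool put too many
members on the occupancy plateau and destroy the rare-tail structure that
Z-score hit calling assumes.

What the generator does *not* model: yeast physiology (lag phase, reporter
enzymology, 3-AT dose-response), PCR amplification chemistry, sequencing
errors at the base level, library synthesis biases, or member cross-talk
(competition enters only through the shared population total). Passing
recovery tests therefore demonstrate correctness of the estimators under
the stated generative model, not robustness to every artifact of real
screens.

A structural note on hit fractions: because Z-scores are standardised
within a screen, no more than ~1/(1+9) of scored members can ever exceed
Z = 3 (one-sided Chebyshev); screens where a large fraction of the library
genuinely binds are outside the regime this hit rule — and the generator's
defaults — are built for.

## Read counting

Extraction takes the substring strictly between the first exact occurrence
of the 5′ anchor and the first subsequent exact occurrence of the 3′
anchor, forward strand only; no mismatch tolerance (exactness keeps counts
auditable; anchors are fixed construct sequence). Regions are matched to
the whitelist by exact DNA first, then by exact translated peptide —
tolerating synonymous artifacts without inventing an error model. Every
read increments exactly one member or one of four rejection reasons
(`no_anchor`, `bad_length`, `stop_or_ambiguous`, `not_in_whitelist`), so
matched + rejected = total per sample. Quality trimming, UMIs,
demultiplexing and paired-end reads are out of scope.

## Motif statistics

The motif grammar (`[XYZ]` classes, `x` wildcards, `x{m,n}` spacers, an
optional start window) is scanned by explicit enumeration of all spacer
combinations, shortest spacing first at each start — a regex with greedy or
lazy quantifiers does not enumerate alternative placements, and the
enumeration is what the brute-force oracle in the tests checks
placement-for-placement. The `I/L-x-x-R-R` window defaults to start
positions 1–4 ("near the N-terminus" made concrete and configurable); the
position-1 class is {I, L}, not {I, L, V}.

Positional overrepresentation uses exact binomial tails (no normal
approximation): for residue r at position j with foreground count k of n
and background frequency p₀, the overrepresentation p-value is P(X ≥ k)
and underrepresentation P(X ≤ k), X ~ Binomial(n, p₀); the logo height is
−log₁₀ p of the favoured tail, signed, exactly zero when k/n = p₀.
Significance is Bonferroni at α = 0.05 over 20·L tests, the convention of
published probability logos. The default background is the screened
library itself, position-specific — this corrects for the library's
built-in consensus bias, which a proteome background would not. The
14-mers are treated as pre-aligned fixed-length strings; no alignment is
performed. When a residue is absent from the background but present in the
foreground, the p-value is clamped to the smallest positive float with a
warning rather than reported as zero.

## Dose-response fitting

Rates are normalized as (raw − min)/(max − min) against no-competitor and
no-kinase controls. The 4PL is fit per replicate by least squares on the
log₁₀-concentration axis with all four parameters free (bottom can be
fixed for a 3PL); zero-concentration points inform only the normalization.
Initial values come from the data: plateaus from the extreme-concentration
quartiles, IC₅₀ from the half-maximal crossing, Hill slope 1. The reported
IC₅₀ is the mean of replicate IC₅₀s with a t-based 95% CI (matching how
triplicate kinase assays are conventionally summarised), rather than a
single-fit asymptotic CI. Fits that fail to converge, show no inhibition
(non-positive amplitude or Hill slope), or place the IC₅₀ outside the
tested range are flagged and reported, never dropped. Fold changes are
IC₅₀ ratios (mutant/reference) with a delta-method CI on the log scale;
when inputs come from printed summary tables, the implied standard error
is recovered from the published CI width. Mechanistic Ki extraction
(Cheng–Prusoff) is out of scope.

## Problem sizes and determinism

The shipped calibration and recovery analyses use 1,000-member libraries
at sequencing depth 1e5 with 3 replicates and 5 timepoints — large enough
for the distributional checks (null calibration, rank recovery, hit-set
recovery) to be stable across seeds, small enough to run in seconds. Every
stochastic stage draws from named substreams of a single seed
(`numpy.random.SeedSequence` spawn keys per stage, genotype, condition and
replicate), so libraries, count tables, FASTQ files and summaries are
reproducible byte-for-byte, and replicates are independent by
construction rather than by seed arithmetic.

## Known limitations

* Enrichment scores are plain OLS slopes: no shrinkage across members, no
  mixed-effects replicate model, no variance stabilisation. With few
  timepoints and low counts the per-replicate ES is noisy, and the
  replicate average is the only pooling performed.
* The hit rule inherits the fragility of screen-wide Z-scores: hit counts
  depend on the whole ES distribution, so screens with different depletion
  structure (e.g. a mutant that releases competition) shift each other's
  thresholds — the mechanism behind apparent "gained" interactors, which
  the relaxed top-percent membership is there to interrogate.
* The published per-screen ES/Z tables and raw reads live in external
  repositories (GEO); analyses that recompute the published headline
  numbers require downloading them and are not runnable from this
  repository alone.
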