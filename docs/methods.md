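# Methods

## Problem setting

DamID-seq reads out protein–DNA contact via adenine methylation of GATC
sites by a Dam-fusion protein, with a Dam-only sample controlling for
accessibility and amplification bias. After DpnI digestion the genome is
partitioned into GATC fragments — intervals between consecutive `GA^TC`
blunt cuts — whose lengths are roughly exponential (mean ≈ 1/rate of the
motif). All quantities in this package live on that fragment grid, with
0-based half-open coordinates internally and conversion only at I/O
boundaries (WIG is 1-based inclusive).

The cut coordinate is fixed at motif start + 2 (the DpnI blunt cut).
Any consistent convention shifts boundaries by ≤ 2 bp; one is fixed for
reproducibility. `N` bases never match the motif, and strand is ignored
throughout because GATC is palindromic and Dam methylation is
strand-symmetric. Chromosome-end flanks (bounded by only one cut) are
kept but flagged `end_flank` so users can exclude them.

Read assignment is strict containment: a read increments a fragment's
count only if it lies entirely inside the fragment; reads spanning a cut
site are discarded and tallied. This is the conservative
`intersection_strict` overlap rule; its accounting identity
(counted + discarded = input reads) is property-tested.

## Normalization

Per replicate, the binding intensity of fragment *i* is

    value_i = log2( (pc_i/N_pc * 1e6 + c) / (dam_i/N_dam * 1e6 + c) )

with library totals `N` (reads-per-million scaling) and pseudocount
`c = 0.5` RPM. RPM scaling makes values invariant to sequencing depth;
the pseudocount keeps all values finite. GC or mappability corrections
used by some DamID pipelines are deliberately omitted — they address
upstream biases outside this package's scope.

Replicate concordance: with `d_i = rep1_i - rep2_i`, fragment *i* is
excluded iff `|d_i - median(d)| > k * 1.4826 * MAD(d)`, default `k = 3`.
This is a robust z-score with one interpretable knob; it reproduces the
"highly discordant fragments excluded" behaviour without assuming a
particular noise model. Fragments with zero Dam-control counts in every
replicate are additionally masked as unobserved. Surviving fragments
carry the arithmetic mean of replicate values.

Note that RPM scaling shifts the whole profile by a constant that
depends on the genome-wide enrichment mixture (`-log2` of the mean
linear enrichment). Absolute emission means fitted from count data are
therefore shifted relative to the generative truth; state *labels* are
unaffected because the HMM refits its means.

## The heterogeneous HMM

Three states — depleted (0), intermediate (1), enriched (2), ordered and
relabelled ascending by emission mean — with Gaussian emissions
`N(mu_k, sigma_k)` in log2-ratio units. Because fragments are unevenly
spaced, the transition matrix depends on the physical distance `d`
between the midpoints of adjacent (unmasked) fragments:

    A(d)_jj = pi_j + (p0 - pi_j) * exp(-d / L)
    A(d)_jk = (1 - A(d)_jj) * pi_k / (1 - pi_j),  k != j

an exponential relaxation from a zero-distance self-transition `p0` to
the stationary distribution `pi` with decay length `L` (bases). `A(0)`
has diagonal `p0`; `A(inf)` rows equal `pi`; rows sum to 1 for every
`d ≥ 0` (property-tested). This kernel has the two features the
segmentation relies on — nearby fragments correlated, distant ones
independent — with only two extra parameters.

Fitting is Baum–Welch over per-chromosome chains (chromosomes are
independent; one parameter set is shared genome-wide; emission variances
are untied — both choices configurable in principle via the fit
interface). Per iteration:

* E-step: forward–backward in log space (numba-compiled kernels; no
  underflow on long chains);
* exact M-step for `mu`, `sigma` from the posterior weights, variance
  floored at 1e-3 (log2 units)^2 to prevent emission collapse;
* `pi` (occupancy candidate), `p0` and `log10 L` (bounded scalar
  searches, `p0` in (0,1), `L` in [1, 1e7] bp) updated by direct
  observed-likelihood ascent, each accepted only if the likelihood
  improves.

The combination makes the log-likelihood trace non-decreasing by
construction (the emission step by the EM inequality, the rest by
accept-if-better); the trace is asserted monotone in tests. Convergence:
relative log-likelihood change < 1e-6 (default) or 500 iterations.
Initialization is deterministic: `mu` at the 10th/50th/90th profile
percentiles, `sigma` at half the profile sd, uniform `pi`, `p0 = 0.9`,
`L` = median inter-fragment distance. Fits with two means closer than
1e-3 are flagged degenerate, not raised. Masked fragments are skipped
gap-aware: the distance between their unmasked neighbours is used, never
imputed.

Viterbi ties break toward the lower state index (conservative: favours
'depleted'). Decoding correctness is established against exhaustive
enumeration of all 3^n paths on chains of up to 10 fragments (1e-8
tolerance), and against an independent homogeneous-HMM implementation
(hmmlearn) in the constant-spacing special case where the heterogeneous
chain reduces to a homogeneous one.

## Transition calls and turnover

Fragments masked in either condition are dropped from the comparison
entirely (not treated as depleted). Full mode labels by rank:
gain iff rank(test) > rank(reference). Whether intermediate→enriched
counts as a gain in the full analysis is ambiguous in general; full mode
assumes yes, and the `enriched_only` mode covers the conservative
alternative (only transitions in and out of 'enriched' count).

Bound-state turnover pools intermediate and enriched as "bound":
`pct_lost` = loss-labelled share of reference-bound fragments;
`pct_de_novo` = share of test-bound fragments whose reference state was
depleted. The pooled denominator follows the usual summary of how many
bound states are lost or arise de novo between conditions.

## Regulatory integration

TSS windows span 2.5 kb upstream to 1.5 kb downstream, reflected on the
minus strand and clipped to chromosome bounds. The downstream bound is a
parameter (some analyses use +1 kb); the default follows the stated
regulatory-region definition. A fragment is transcription-associated
(taGATCf) for a gene iff it overlaps the window by at least one base —
no minimum-overlap requirement. Genes with multiple TSSs get one window
per TSS and are classified from the union of their taGATCf.

Region class: gain iff ≥ 1 gain and no loss among the gene's labelled
taGATCf; loss symmetric; mixed iff both present; no_change otherwise;
genes whose taGATCf all lack labels are excluded. Joined with DE
direction (retain adjusted p < 0.05, split by sign of log2FC):
(up, gain) → I, (down, gain) → II, (up, loss) → III, (down, loss) → IV,
(down, mixed) → m1, (up, mixed) → m2, anything with no_change → none.
The classifier is verified against brute-force enumeration of every
label multiset up to size 6.

## QC

Pearson correlations are computed over the jointly unmasked fragment
set; clustering is average linkage on `1 - r` (no linkage is canonical
for this application; average is the documented, configurable default),
exported as Newick. Lag-k autocorrelation is defined over *fragment
index* on consecutive unmasked fragments (neighbouring recovered GATC
sites, not base pairs), within chromosomes, pooled before the
correlation; whether to run it per replicate or on averaged profiles is
left to the caller (the pipeline reports it on averaged profiles).
State-specific fragment-size summaries report count, median and
quartiles per state plus full distributions.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the features the analysis depends on:

* uneven fragment lengths — random A/C/G/T background (spontaneous GATC
  at 4^-4 per base ≈ 3.9/kb) plus motifs planted as a Poisson process at
  `gatc_rate` (default 4/kb, about the genome-wide GATC frequency);
* a hidden state chain drawn from the same distance-dependent kernel the
  HMM fits, with `p0 = 1` (zero-distance neighbours always agree — the
  only choice for which L → inf collapses each chromosome to one state)
  and stationary distribution default uniform;
* per-fragment true enrichment `state_mean + N(0, state_sd)` (defaults
  −1.5/0/+1.5 and 0.5 log2 units, decay length 2 kb), shared across
  replicates because it is biological truth, not sequencing noise;
* overdispersed counts: gamma–Poisson (negative binomial, size =
  `dispersion`, default 20) with Dam mean `dam_mean_per_kb` (default
  150, a realistic DamID-seq depth of ~20–40 reads on a median
  fragment) times fragment length, and fusion mean scaled by
  `2^enrichment`; `dispersion = inf` recovers the Poisson limit;
* a DE table with exact `frac_up` / `frac_down` allocations of
  significant genes (adjusted p < 0.05) and TSSs placed at least one
  window-width from chromosome ends (clipping is tested separately);
* a second condition derived by re-assigning each same-state segment
  with probability `change_rate` (default 0.15), emulating loci-specific
  binding turnover rather than genome-wide reshuffling.

It does **not** simulate raw reads, sequencing error, mappability,
GC bias, or replicate batch effects. Passing the recovery tests
therefore shows the inference is correct when its model holds and robust
to count-level overdispersion — not that real tissue profiles meet those
assumptions.

Everything is deterministic given the seed; each operation draws from
its own derived stream so stages are independently reproducible.

## Problem sizes and numerical choices

Tests run the count-based pipeline on one 500 kb chromosome
(~3800 fragments, two replicates per condition) and the parameter
recovery fixture on 5000 fragments — sizes at which recovery statistics
are stable (state accuracy ~96% from counts, ~99% from model-true
emissions; fitted means within 0.03 of truth on the emission fixture).
The acceptance script uses a two-chromosome 1 Mb genome. Exhaustive
oracles cap chains at 10 fragments (3^10 paths). Log-space arithmetic is
used in all recursions; posteriors are renormalized per position;
correlation matrices are symmetrized against rounding before clustering.

## Known limitations

* The exponential-relaxation kernel is one concrete realization of a
  distance-aware chain; other decay laws would also satisfy the
  nearby-correlated / distant-independent requirements.
* The Gaussian emission model understates the heavy count noise of very
  short fragments (a few reads each); the discordance mask removes the
  worst cases but the residual misfit caps state accuracy from count
  data below the model-true ceiling.
* Normalization recovers relative, not absolute, enrichment (see the RPM
  shift note above).
* All inputs must share one genome assembly; no liftover is performed.
* Significance testing of transition enrichments is out of scope.
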