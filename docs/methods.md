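# Methods

## Generative model

A repeat family's copies (annotated intervals extended by a `flank` of
1000 bp, clipped at chromosome ends, overlapping extensions merged) are
concatenated into a *repeat genome* of `n` positions over `r` copies. Two
oppositely-oriented cores closer than twice the flank merge into a single
copy; this is deliberate — such a pair is one transcriptional unit forming an
RNA duplex, and hyper-editing of the duplex means A→G (forward state) or T→C
(reverse state) across the whole merged copy in plus-strand coordinates.

Latent structure, top down:

* `H_k ∈ {not_edited, edited_forward, edited_reverse}` per copy, prior
  `(0.90, 0.05, 0.05)`.
* `T_i ∈ {normal, snp, edited}` per position. `P(snp) = 0.01` everywhere in
  the repeat core; at a position licensed for editing (reference A in a
  forward-edited copy, reference T in a reverse-edited copy, core only)
  `P(edited) = 0.5` and `P(normal) = 0.49`; elsewhere `P(edited) = 0`.
* `G_i | T_i ~ Dirichlet(α_{T_i, ref_i})`, the three-component Dirichlet
  mixture over per-position base distributions.
* `X ~ Dirichlet(α_X · 1)`, `α_X = 1`; a read's copy of origin is drawn from
  `X`, its offset uniformly, indels with affine log-penalties
  (`gap_open = −9.2`, `gap_extend = −2.3` per extra base); read bases are
  independent draws from `G` at the aligned positions.

Conditioned on the profile, read bases are independent across positions.
Real hyper-editing is processive (the run-length analysis below measures
exactly that dependence), so this is a deliberate simplification; the
copy-level states `H` retain the key dependence that edits cluster within a
duplex.

## Dirichlet defaults and why

Each mixture component's Dirichlet encodes what that component is supposed to
generate:

* **normal** — only read error. `α = (997, 1, 1, 1)` with 997 on the
  reference base: exactly 1000 pseudo-observations of the 0.997/0.001
  error profile used throughout the read model.
* **snp** — an unknown alternate at an unknown frequency: flat
  `α = (1, 1, 1, 1)`.
* **edited** — editing level roughly uniform on (0, 1): one extra
  pseudo-observation on the reference and on the edited base,
  `α = (2, 1, 2, 1)` at reference A (G edited), `(1, 2, 1, 2)` at reference
  T (C edited).

The choice that matters is the *contrast* between normal and edited. The
asymptotic detection threshold is the editing level at which the edited
component's density first exceeds the normal component's at the empirical
base distribution; with the defaults above it sits near level 0.013, so the
detectability of a site is limited by coverage, not by the prior. A mildly
concentrated normal prior (e.g. 40 pseudo-counts) may look harmless but
raises that threshold to ~0.19 and silently caps sensitivity near 0.8 at any
depth. All values live in `PriorConfig`, serialize to a flat INI file, and
are overridable per run.

## Candidate alignments

Editing-compatible mismatches must not penalize placement, so matching runs
on a masked three-letter alphabet: A→G in read and genome (sense mask) or
T→C (antisense mask). Candidates are all placements with at most
`max_other_mm = 4` surviving mismatches per end (N counts as a mismatch);
hidden A→G / T→C differences are unlimited and recorded separately. Both
masks are tried per placement and the one leaving fewer non-editing
mismatches wins, so library strandedness is never assumed.

The internal matcher is seed-and-extend: `max_other_mm + 1` non-overlapping
seeds of length `⌊q/(max_other_mm+1)⌋` per orientation and mask, exact
k-mer lookup, then vectorized verification of every seeded offset. With
disjoint seeds the pigeonhole principle makes it complete for ungapped
placements (verified against an all-offsets scan in the tests); reads too
short for disjoint seeds fall back to a full scan. Gapped placements enter
through the SAM import path, where mismatch classes are recomputed against
the unmasked genome and records violating the 4-mismatch rule are dropped.

Ends pair on opposite strands, inward-oriented, same copy, insert length in
`[read length, 1500]`. A pair with placements but no consistent joint
placement contributes its ends as single-end candidates carrying a pairing
log-penalty (−9.2); per read, up to `max_candidates = 10000` candidates are
kept, by ascending non-editing mismatch count.

## EM

E-step: per read `j`, the posterior over its candidate set is
`P(a | R_j) ∝ h(a) · X_{k(a)} · ∏_t G_{a(t)}(R_j(t))`, normalized over
candidates only — the tractable approximation to the sum over all
alignments, justified because non-candidate placements carry ≥ 5 unexplained
mismatches and hence negligible mass. Minus-strand bases are complemented
into plus-strand coordinates before accumulating `U`. All candidate
probabilities are recomputed every step; no change-detection shortcut is
applied.

M-step, exact and layered: `X̂ = (α_X − 1 + V)/Σ(·)` (numerators clipped at
0); for each position and type, `Ĝ_T = (α_T − 1 + U_i)/Σ(·)` with numerators
clipped at 1e−10 so profile entries stay strictly positive; the type
objective is `log P(T|H) − log B(α_T) + (α_T − 1 + U_i)·log Ĝ_T`; each
copy's state maximizes its prior plus the summed best-type objectives, after
which types and profile rows are fixed by back-substitution. Ties break
toward `normal` / `not_edited`.

The tracked objective is the log posterior
`log P(θ) + Σ_j log Σ_a P(a, R_j | θ)` over the candidate support. Because
every M-step layer is an exact argmax, EM cannot decrease it; the driver
raises an internal error if it ever drops by more than 1e−6 (the tests
assert non-decrease within 1e−8 on randomized instances). Note the related
quantity `log_joint` in `repeat_model` — prior terms plus the
*expected* complete-data likelihood `U·log G + V·log X` — is the Q-function
form; it differs from the tracked posterior by the alignment-posterior
entropy and is exposed for algebraic checks rather than convergence.

Convergence: `|Δ objective| < tol` (default 1e−4) or `max_steps`. The
absolute tolerance is rarely the binding control at realistic read counts —
posterior sharpening produces a long shallow tail — so production runs bound
work with `max_steps` (50 in the shipped analyses; state assignments
stabilize within ~15 steps).

Initialization: every copy `not_edited`, profile at the per-position
Dirichlet *mean* of the normal component (strictly positive, so every
candidate starts finite), expression uniform. Restarts: for each hyper-edited
copy of the current best solution, a new initial condition resets that copy's
profile rows to the prior mean; EM re-runs, and the schedule continues while
a better optimum changes the hyper-edited set (at least one restart per
hyper-edited copy). Local maxima with identical edited sets within 1e−3
log-units are deduplicated. A copy hyper-edited in every retained maximum is
tiered `most_confident`; edited in the global maximum only, `confident`.

Mapping quality is `round(−10·log10(1 − posterior of best placement))`,
capped at 60. Per-read computations are independent and accumulated in fixed
key order, so results are order-independent and bit-reproducible.

## Simulators

The hypothetical family: one random 1 kb core copied 24 times, 12 per
orientation; 20 isolated copies each get 1 kb random flanks, and two
core+reverse-complement duplexes get 1 kb flanks; 200 bp random spacers keep
extended intervals of distinct copies from merging. Duplex 1 is edited
forward, duplex 2 reverse. Profiles: each editable position is edited with
probability 0.5 at a level `p ~ U(0.001, 0.997)` — edited base `p`,
reference `0.998 − p`, others 0.001; every other core position is a SNP with
probability 0.01 (same level scheme, alternate uniform); everything else,
flanks included, is reference 0.997 / error 0.001. Reads: 2×100 bp
inner-oriented pairs, insert `U[200, 500]`, fragment copy from the
expression weights (uniform by default), offset uniform, constant Q40;
50,000 pairs by default. The random-hyperediting design edits each supplied
copy with probability 0.3 in its transcription direction, over 20 pooled
replicates; a clone-style mode imposes levels from an external table. All
randomness descends from one master seed via `SeedSequence.spawn`.

What the simulator does *not* emulate: position-dependent error profiles,
quality-score variation, PCR duplicates, intra-molecule editing
correlation, or coverage heterogeneity beyond copy-level weights. Passing
tests therefore demonstrate correctness of the inference under the model's
own assumptions, not robustness to every artifact of real libraries.

## Pattern analyses

*Run hazard.* Per confidently placed read (MAP alignment, MQ ≥ 30, copy
called edited; strand-normalized so the edited base is G at reference A),
maximal stretches of consecutively edited adenosines are extracted; a run
ending at a non-A (or the read end) is censored, one ending at an unedited A
is observed. The discrete hazard
`P(len = n | len ≥ n) ≈ #(n, uncensored) / (#(n, uncensored) + #(> n))`
— censored runs of length exactly `n` in neither count — with Clopper–
Pearson 95% intervals. Using only MAP placements avoids double-counting
under alignment uncertainty.

*Context.* Mean editing level per three-letter context (centered or ending
at the edited adenosine), edge-truncated positions skipped; pairwise Welch
t-tests with Benjamini–Hochberg–Yekutieli FDR. Eligibility filters (e.g.
helix depth ≥ 25, implemented as distance along the sequence to the nearest
unpaired position) are supplied by the caller.

*Helices.* From dot-bracket or CT input, stacked base pairs are merged
across interior bulges of up to 2 unpaired bases on one or both sides; helix
length is the number of pairs. Editing is binned by helix length with
binomial CIs on the edited fraction and normal-approximation CIs on mean
level; bin boundaries are configurable (default edges 0/18/32/64, chosen so
the outer bins match the "< 18" and "> 64" summaries the analysis reports).

## Numerical and design notes

* Log-domain throughout; profile floors at ~1e−10 prevent −inf while leaving
  likelihood ratios of ~50 nats available to reject a placement.
* Exact worked values for the M-step formulas and the hazard estimator are
  locked in tests; the E-step, M-steps and state selection are additionally
  verified against independent loop-based brute-force implementations on
  100 randomized small instances (≤ 1.2 kb genomes) to 1e−8.
* The level-agreement slope is least squares through the origin over the
  union of predicted-or-true sites (absent side filled with 0).
* Shipped problem sizes: the accuracy tests run the hypothetical design at
  its full 50,000 pairs (the benchmark's defining condition — sensitivity is
  coverage-limited below that); the acceptance script measures the
  mapping-accuracy quantities at 15,000 pairs, where they are already at
  ceiling, and `max_steps = 50`.
* Expression is a per-copy weight; no correction for copy length is applied
  to the alignment prior, matching the model in which `X` is constant across
  positions of a copy.

## Limitations

* One family at a time; cross-family multi-mapping is resolved only through
  the flank sequence included in the repeat genome.
* The internal matcher is ungapped; indel-containing placements must come
  through the SAM import path.
* MAP inference only — no posterior sampling over `H`/`T`, so the confidence
  tiers derive from the restart schedule's local maxima, not a full
  posterior.
* Secondary structure is consumed, never predicted.
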