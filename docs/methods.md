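# Methods

## The model

The package treats a melody as the realization of a variable-order Markov
process over *relative* spectro-temporal tokens and asks what the
transition statistics of that process reveal about the musician who
produced it.  For a sequence of elements e_1, ..., e_N, the order-n
transition probability (TP) is the conditional probability

    P(e_{n+1} | e_n, ..., e_1),

estimated by relative frequency: windows of n+1 consecutive tokens are
tallied, and each context's continuation counts are normalized.  No
smoothing is applied — unobserved patterns are structural zeros, entering
the downstream matrices as 0 and the logit transform at the clamp value.
Higher orders are read as deeper sequential knowledge: an order-1 table
captures local expectancies, an order-6 table captures phrase-length
formulae.

Two information measures summarize a table.  The information content of an
observed transition is its surprisal, I = −log2 p bits.  The conditional
entropy of a piece's order-n table is

    H(B|A) = − Σ_i P(a_i) Σ_j P(b_j|a_i) log2 P(b_j|a_i),

with the context marginal P(a_i) taken as the empirical window frequency.
This plug-in form equals the mean surprisal over observed windows exactly
(the test suite asserts the identity to 1e-9).  No bias correction
(Miller–Madow etc.) is applied: entropies are compared across pieces of
similar length, where the plug-in bias is common mode.

## From a recording to tokens

1. **Skyline reduction.**  Polyphony is reduced to the highest-pitch line:
   grace notes are dropped, each slur group counts as one event (its first
   note), and at each distinct onset only the highest attacked pitch
   survives.  "Attacked" is the operative word: a held lower note does not
   suppress a later higher attack, and a new lower attack under a held
   higher note is kept as its own melodic event.  The attack-based rule is
   deterministic and is the standard skyline convention; sounding-duration
   alternatives would need a tie-break the data cannot supply.  After
   reduction only onsets and pitches are used — durations and rests play no
   further role.

2. **Relative encoding.**  Four window streams are derived at each order
   n = 1..6, overlapping with stride 1:

   * `pitch` — n+1 pitches re-zeroed to the window's first pitch
     (semitone offsets; transposition-invariant).
   * `rhythm` — n+1 inter-onset intervals (IOIs) as ratios to the
     window's first IOI (tempo-invariant).
   * `pitch_rhythm` — the pitch tokens of a `pitch` window paired with
     the ratios of the n IOIs it spans.  At order 1 the single IOI has no
     in-window reference, so it is expressed as a ratio to the crotchet
     (quarter note = 1 beat); this one token is therefore tempo-sensitive,
     a documented exception.
   * `rhythm_pitch` — the rhythm tokens of a `rhythm` window paired with
     the re-zeroed pitches of all n+2 notes it spans.

   Rhythm ratios are rounded to 3 decimals *after* division, so triplet
   values collide onto 0.333/0.667 regardless of how they were notated.
   Pattern strings are printed in the field's bracketed style, e.g.
   `[0, -1, -2] with [1, 0.5]`.

No key detection is performed: the relative encoding itself removes key
(and register) from the representation.

## Corpus statistics

**Aggregation.**  TPs are estimated per piece; a musician's distribution
is the pattern-wise *mean of per-piece TPs* over the union vocabulary
(absent = 0), not a pooled-count refit, so pieces contribute equally
regardless of length.  The mean of probabilities is deliberately left
unnormalized.  The top-5 patterns by mean TP (ties broken lexicographically
on the serialized pattern) define each musician's signature set.

**PCA.**  The aligned pieces x patterns TP matrix is analyzed through the
correlation matrix *among pieces*: pieces are the variables, patterns the
observations, so each piece receives a loading per component.  Components
with eigenvalue > 1 (Kaiser, valid because the decomposition is of a
correlation matrix) are retained and the first two interpreted.
Eigenvalues sum to the number of pieces; percentage variance sums to 100.
Component signs are fixed by making the dominant loading positive.  A
piece with a constant TP vector has no defined correlation and is reported
by id as degenerate input.

**Mixed ANOVA.**  Musician is the between-subject factor, transition
pattern the within-subject factor, pieces are subjects, and the dependent
variable is the logit TP, ln(p/(1−p)) with p clamped to [eps, 1−eps],
eps = 1e-6, so structural zeros stay finite.  The within-factor levels are
the union of the musicians' top-5 patterns evaluated on every piece, which
keeps the design balanced by construction.  Sphericity is assessed with
Mauchly's test; when violated (p < 0.05) the within main effect is
reported with Greenhouse–Geisser-corrected degrees of freedom and p-value.
Effect size is partial eta squared; post-hoc pairwise comparisons are
Bonferroni-corrected.  Computation is delegated to pingouin; the test
suite re-derives the sums of squares by hand on a balanced toy design and
requires agreement to 1e-9.

**Stepwise chronological regression.**  Within a musician, the
chronological index (1..K over the K pieces) is regressed on candidate
predictors — the per-piece TPs of the musician's top-5 patterns, or the
per-piece conditional entropies across orders — by bidirectional stepwise
OLS.  Removal drops any included predictor with p > 0.10.  Entry screens
all remaining candidates and admits the best one only if its p-value,
Bonferroni-adjusted for the number of candidates screened at that step,
is at most 0.05.  The adjustment is deliberate: with five noise
candidates and seven observations, unadjusted best-of-five entry at 0.05
would return a spurious model in about 23% of null datasets
(1 − 0.95^5); the adjusted rule keeps the null false-selection rate near
5% while a genuinely drifting TP — which typically enters with p < 0.01 —
is still recovered in well over 80% of replicates.  A candidate whose
entry would push any variance inflation factor to ≥ 2 or the model
condition index (largest/smallest singular value of the column-scaled,
intercept-included design matrix) to ≥ 20 is refused.  An empty final
model — "no significant regression equation" — is a valid result.

## The synthetic corpus generator

Real corpora of transcribed improvisations are not redistributable, so
validation rests on a generator that emulates the study design — three
musicians, seven chronologically ordered pieces each — with exactly known
statistics.

* **Pitch.**  Either an explicit order-g Markov chain over semitone
  intervals or a motif process (i.i.d. concatenation of fixed interval
  motifs).  Random chains are drawn with Dirichlet(3) rows blended 50/50
  with the uniform distribution and constrained to inversion symmetry
  P(−b|−ctx) = P(b|ctx).  The symmetry makes the melodic random walk
  exactly drift-free and the uniform blend bounds directional persistence
  — a melody in a tonal idiom holds a stable register rather than running
  away.  At the register boundary (MIDI 24..108) the conditional is
  restricted to inward steps, as a player at the edge of the instrument
  picks a playable note; the resulting distortion of the conditionals is
  proportional to the boundary-visit rate, a fraction of a percent at
  these settings.
* **Rhythm.**  IOIs drawn i.i.d. from a distribution over the metrical
  grid {1/4, 1/3, 1/2, 2/3, 1, 3/2, 2, 3} beats.  Onsets are accumulated
  as integer ticks at 30720 per quarter (2^11·3·5), so every token and
  every tempo scale on the grid {0.8, 0.9, 1.0, 1.1, 1.25} is exactly
  representable and MIDI output round-trips to float precision.
* **Decorations.**  Chords (extra pitches strictly below the melody note
  at the same onset), flagged grace notes, a per-piece transposition and a
  per-piece tempo scale.  Decorations are drawn from an RNG substream
  separate from the core pitch/rhythm stream, so toggling them never
  changes the clean truth line, and the skyline reduction of a decorated
  piece reproduces that line exactly.
* **Drift.**  Optionally one transition's probability moves linearly with
  the chronological index, the context's remaining mass rescaled
  proportionally — the simplest model of a gradually changing habit.
* **Ground truth.**  The generator exposes its exact tables, the
  stationary context distribution (power iteration to 1e-12), and the
  implied conditional entropy, against which pipeline estimates are
  checked.

The **hierarchy corpus** makes the central phenomenon testable: all three
musicians' motifs are permutations of one shared zero-sum interval
multiset (2, 2, −1, −3, 0), so the order-1 relative-pitch statistics (the
interval unigram) are identical across musicians while order-4 windows
trace musician-specific motifs, and the shared IOI distribution leaves no
musician signal in rhythm at any order.  The pipeline should therefore
find one dominant shared PCA component at order 1, clean musician
separation on components 1–2 at order 4 (silhouette on loadings), and no
separation for rhythm — which it does.

**What the generator does not emulate:** harmony and voice leading, swing
and expressive timing, rests as structural events, performer-specific
rhythm grammars (IOIs are i.i.d.), and transcription noise.  Passing tests
demonstrate that the pipeline recovers the statistics it is pointed at;
they do not certify musicological conclusions about real recordings.

## Problem sizes and numerical choices

Default study conditions are 3 musicians x 7 pieces; the hierarchy
experiments use 2,000-note pieces and the parameter-recovery experiments a
single 100,000-note piece, where the worst TP error over contexts with
stationary mass ≥ 0.01 is below 0.02 and the entropy error below 0.02
bits.  Drift/null stepwise experiments use 200 replicates at the TP level
(tp 0.20 + 0.04 per step vs. noise sd 0.03).  The unit-test suite runs the
same analyses at reduced sizes.  Other numerical conventions: logit clamp
eps = 1e-6; rhythm-token rounding to 3 decimals; per-context TP sums
asserted to 1e-9; vocabulary order and tie-breaks lexicographic on the
serialized pattern, making every stage deterministic across platforms;
0·log 0 := 0; windows containing a non-positive IOI (impossible for a
valid melody line) are skipped with a warning.

## Known limitations

* The conditional-entropy estimate is the uncorrected plug-in; comparisons
  across pieces of very different lengths inherit its length-dependent
  bias.
* The stepwise entry adjustment makes selection conservative when
  candidates are strongly correlated (the Bonferroni factor counts
  near-duplicates as independent tests).
* With seven observations per musician, regression models with more than
  two predictors are rarely identifiable; the VIF/CI gates make this
  explicit rather than fixing it.
* MIDI files carry no grace/slur annotation, so those must come from CSV
  note lists; MIDI ingest treats every note as a plain event.
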