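# Methods

This note documents the modelling decisions, defaults and numerical choices
behind `voicetp`, and what the synthetic-corpus tests do and do not
establish about real scores.

## Event extraction from scores

A "point in time" is every onset at which at least one non-grace note
begins.  The sounding set at that onset contains every non-grace pitch whose
(tie-merged) duration covers the onset, so notes sustained from earlier
attacks participate in the highest/lowest-pitch decision.  Consequences of
this rule:

* a chord is one event; duplicate simultaneous pitches (unisons across
  staves or doubled chord tones) count once;
* a tied chain is a single playable note anchored at the tie start — tied
  continuations create no onset (the `<tie>` sound elements are honoured;
  purely notational `<tied>` marks are ignored);
* grace notes are excluded entirely (they have no duration and no event);
* rests advance time but generate no events and never split a piece into
  segments — each file yields one sequence.  Phrase-boundary segmentation is
  deliberately not attempted; where a pianist lifts the hand is ambiguous
  and any rule would be arbitrary;
* a note re-attacked underneath a sustained higher note *does* create a new
  event (the sustained note simply participates in it).  This is one
  defensible reading of "playable at a given point in time"; the
  alternative (only counting changes of the extreme pitch) is not offered.

Consecutive equal pitches in an extracted line are retained: they encode
interval 0, which is real melodic information (tone repetition).

Mode labels (major/minor) come exclusively from the corpus manifest.  Key
signatures cannot distinguish a major key from its relative minor, so no
inference from score content is attempted.

Both MusicXML dialects (partwise/timewise) and `.mxl` archives are read.
Onsets are normalized to quarter-note units via each part's `<divisions>`,
using exact rational arithmetic, so parts with different division bases
align exactly.

## Interval encoding

Pitch sequences are re-expressed relative to a reference tone (+1 per
semitone up, −1 down) so that a pattern and any transposition of it share
one code; enharmonic spelling is ignored.  Two conventions are available:

* **window** (default): an order-*n* pattern is an (n+1)-tone window
  re-based on its first pitch; the context is the offsets of tones 2..n and
  the target the offset of tone n+1.  Order 0 is defined as the marginal of
  elementary intervals, because a single tone has no transposition-invariant
  code and an absolute-pitch order-0 would reintroduce the key effects the
  encoding exists to remove.  A corollary worth knowing: orders 0 and 1
  coincide under this convention (a one-tone context carries no invariant
  information), so their output tables are identical by construction.
* **chain**: events are elementary intervals d_t = p_{t+1} − p_t and order
  *n* conditions on the previous *n* intervals.  Orders separate cleanly
  here; the two conventions are interconvertible (an order-(n+1) window
  model carries exactly the information of an order-n chain model) and the
  choice is exposed as `encoding` configuration rather than hidden.

A line of L tones contributes max(0, L − max(n, 1)) window patterns; lines
too short for an order contribute nothing at that order (logged, and the
corresponding entropy cell is flagged missing rather than silently dropped).

## Estimation, pooling, entropy

Transitional probabilities are plug-in maximum-likelihood count ratios with
no smoothing or bias correction — any smoothing would change the entropies,
and the analysis only ever evaluates probabilities of observed transitions
(information content is undefined, not infinite, for unobserved patterns).

Multi-piece aggregation units (a sonata's movements; a key's preludes and
fugues) are pooled by **count pooling**: summing raw counts, equivalent to
averaging each piece's conditional distributions weighted by its context
frequencies.  This is the unique weighting that makes the pooled object the
empirical distribution of the concatenated unit.  An `explicit` mode
rescales pieces to caller-supplied weights first; the pooling mode is
recorded in the run log.

Conditional entropy is evaluated on the pooled distribution per (unit,
voice, order), with 0·log 0 = 0.  Entropies are exact bits (log base 2).

## PCA of TP distributions

The feature matrix has one column per (unit, voice) and one row per
transition type at a given order; cell values are conditional probabilities
(`value_kind="tp"`, default) with 0 for types a column never produced —
absence is informative.  The alternative `"ic"` uses information content
and must restrict rows to types observed in every column, since absence has
no surprisal; the choice is configurable because either reading of
"distributions of TPs (information content)" is defensible.

PCA is of the **column correlation matrix** (standardized variables), so
eigenvalues sum to the number of columns and variance shares are
eigenvalue/n_columns.  With 32 two-voice units that total is 64; with 24 it
is 48 — the signature by which this variant is identified.  Components with
eigenvalue > 1 are adopted; templates report 2 (multi-movement design) or 3
(key-paired design) components.  Loadings are eigenvectors scaled by the
square root of their eigenvalue (variable-component correlations, bounded
by 1); each component's sign is fixed to mean-positive, since eigenvector
sign is arbitrary and a deterministic rule makes reruns comparable.
Component reports classify each adopted component as `shared` (all loadings
above a floor, default 0), `voice-contrast` / `mode-contrast` (group mean
loadings differing in sign or by more than a margin, default 0.2, taking
the larger separation), or `mixed`.

## Correlation analyses

Pearson r between melody and bass entropies across units, per order —
pooled across units or split by mode — and between tonic-paired major/minor
units per voice.  The major↔minor pairing matches units sharing a tonic
(C major ↔ C minor); it is the only natural bijection over a full key
cycle, and an explicit pairing can be supplied instead.  p-values use the
exact two-sided t-transformation with df = n − 2 (for |r| = 1 the p-value
is reported as 0).  Strength bands on |r|: strong ≥ 0.7, moderate ≥ 0.4;
the additional weak ≥ 0.2 band is a package convention for completeness.
No multiple-testing correction is applied across orders; the per-test α
(default 0.05) is reported alongside each result.  Pairs with fewer than 3
complete observations are flagged not-computable, never silently skipped.

## Synthetic corpus generator

Each (unit, voice) sequence is driven by an order-n interval chain built
from three ingredients: a corpus-wide base matrix (rows Dirichlet), a
voice-level perturbation matrix (shared across units — systematic
melody/bass differences), and a smaller unit-level perturbation
(idiosyncrasy).  The mixed rows are then tempered, `row ∝ row^(1/τ)`, with
a per-unit temperature: τ → 0 approaches determinism (entropy → 0), τ > 1
flattens rows.  Temperature is the uncertainty knob because it moves
conditional entropy monotonically while preserving support.  The melody and
bass temperatures of a unit are log-normal, coupled by a Gaussian copula
with correlation ρ (`uncertainty_correlation`), which makes the cross-voice
entropy correlation controllable: the mapping from ρ to the realized
entropy correlation is monotone and close to (slightly below) the identity,
and is measured empirically in the tests rather than assumed exact.

Defaults (one reference condition, used throughout the test suite):

| parameter | default | rationale |
| --- | --- | --- |
| `interval_alphabet` | −6..+6 semitones | most melodic motion stays within a fifth; 13 states keep order-2 contexts estimable |
| `base_concentration` | 0.5 | spiky, music-like conditional rows |
| `voice_perturbation` | 0.15 | voice identity visible but base-dominated |
| `unit_noise_fraction` | 0.2 | units idiosyncratic without drowning the voice signal |
| `temperature_range` | (0.4, 2.5) | central 95% of the log-normal τ; pieces vary widely in uncertainty |
| `uncertainty_correlation` | 0.8 | focal coupled-uncertainty condition |
| `n_units`, `tones_per_voice` | 32, 5000 | corpus-sized recovery conditions |

Analytic conditional entropies come from the stationary distribution of the
context chain (closed form, eigen decomposition with a power-iteration
fallback; a chain with no clean stationary vector falls back to uniform
context weights with a warning).  Generated pitch lines are cumulative
interval sums; a chain whose analysis-side model is wanted at order n
should be analysed at chain order n or, equivalently, window order n + 1.

**Recovery-check conditions.**  Estimation-error checks (TP within 0.01,
entropy within 0.02 bits of truth at 50,000 tones) run on a stepwise
(−1, 0, +1) chain at neutral temperature: with 3 contexts each visited
roughly 17,000 times, those tolerances are meaningful.  On the 13-interval
default alphabet the same tolerances are mathematically out of reach at
that length (per-context sampling error alone exceeds them), so wider
alphabets are checked at the looser entropy tolerance only.  Correlation
recovery uses 100 corpora of 32 units × 5000 tones at ρ ∈ {0.8, 0}; PCA
structure uses 100 corpora of 16 units × 3000 tones at fixed τ = 1 (the
pure shared-base + voice-perturbation design).

**What the generator does not emulate** — and hence what passing tests do
not show about real scores: no rhythm, meter, harmony, phrase structure or
counterpoint; intervals are conditionally stationary with no mean
reversion, so long lines drift in register (real melodies do not), which is
also why MusicXML fixture writing is limited to short pieces; voices are
coupled only through shared distributions and temperatures, not through
harmonic constraints between simultaneous tones.  The tests establish that
the pipeline measures what it claims to measure on data satisfying its
assumptions, not that real corpora satisfy them.

## Numerical and reproducibility choices

* Exact rational onsets (`fractions.Fraction`); integer semitone pitches.
* 0·log 0 = 0 throughout; entropies clipped at 0 against −0.0.
* Feature-matrix rows ordered lexicographically by pattern text — an
  arbitrary but deterministic tie-break.
* Eigendecomposition via symmetric `eigh`; tiny negative eigenvalues from
  rank-deficient correlation matrices are clipped to 0.
* Fixture writing octave-shifts melody and bass independently (whole
  octaves preserve every interval statistic) to satisfy MIDI range and
  melody ≥ bass; infeasible spans raise an error suggesting shorter lines.
* All randomness flows from a single integer seed per corpus; pipeline
  outputs embed a config hash, print floats at 6 decimals, and are
  byte-identical across reruns.

## Known limitations

* Under the window convention, order-0 and order-1 tables are identical by
  construction; use the chain convention when the distinction matters.
* The MusicXML reader covers the score subset relevant to pitch-event
  extraction (notes, chords, ties, grace notes, rests, backup/forward,
  divisions, both dialects); repeats/voltas are not unrolled and
  notation-only features are ignored.
* Plug-in entropy is biased low at short lengths; no bias correction is
  applied, so per-unit entropies should be compared at similar sequence
  lengths (the pooled-unit design does this).
* PCA on probability vectors treats transition types as exchangeable
  observations; with very high orders the union of types grows and columns
  become sparse, making correlations — and hence components — noisier.
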