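# Methods

`signalchains` re-implements, as a tested pipeline, the structure measures and
statistical models used to study how combinatorial structure, compositional
structure, transmission fidelity and iconicity emerge in iterated learning of
binary signaling systems, together with a synthetic chain simulator so that
every stage runs — and is validated — without human data.

## The experimental design being modeled

A *meaning space* of 8 referents crosses three binary features: size
(small/large), shape (round/spiky) and brightness (light/dark); a meaning is
encoded as a 3-bit vector in that fixed order, with large/spiky/dark = 1. A
*signal* is a non-empty string over the binary alphabet `{0, 1}` (low/high
tone, or blue/orange circle). One learner's 8 test-phase productions form a
*language*; a production-time ambiguity filter forces the 8 signals of a
generation to be pairwise distinct. A *chain* is an ordered lineage: the
experimenter-seeded language at generation 0 (4 random signals of length 4 and
4 of length 6), then 10 learner generations, each trained on its predecessor's
output. Two conditions per experiment are compared (e.g. a short vs long
training criterion of 3 vs 5 correct per round).

The symbol labels are a pure convention ("0" = low tone): all metrics are
invariant under a global 0↔1 relabeling, and the tests check that.

## Combinatorial coefficient (CC)

Combinatorial structure — the reuse of meaningless sub-units across signals —
is measured in two steps.

**MDL compression.** Candidate units are all n-grams of length ≥ 2 occurring
in the current signals (including previously introduced unit names, so units
can nest). Substituting an n-gram by a fresh dictionary symbol changes the
total description length, counted as the symbols of all recoded signals plus,
per dictionary entry, name + delimiter + gram (a bigram entry costs 4). Each
round applies the substitution achieving the minimal description length if it
is a strict improvement, breaking ties toward the shorter gram and then
lexicographically; the loop stops at a fixed point. On
`{0010, 0100, 0011, 0101}` this finds the single unit `A = 01` and shortens
the description from 16 to 15 symbols (`{A:01, 0A0, A00, 0A1, AA}`). The
delimiter-inclusive entry cost is what makes that worked total come out at 15;
counting name + gram alone would give 14 and a different search behavior.
Note the trigram `010` ties at 15 here; the shorter-gram tie-break selects
`01`.

The greedy one-unit-per-round search is a hill climb, not a global optimum
over unit sets; on small inventories (≤ 4 signals of length ≤ 6) it provably
matches an exhaustive two-unit oracle in the test suite.

**Recombination index.** With `S` signals and, for each dictionary unit `u`,
`s_u` = the number of distinct signals whose recursive expansion uses `u`,

    CC = mean over units of (s_u − 1) / (S − 1),

0 for an empty dictionary, undefined (NaN) for S < 2. Counting through the
expansion (rather than the literal recoded strings) keeps the index in [0, 1]
when a unit is absorbed into a later unit's gram. This index is a declared
stand-in satisfying the verbal definition of the form recombination index;
absolute CC levels from the original human-data analyses are not expected to
be matched.

Because complementary grams (e.g. `01`/`10`) tie in the search, the
lexicographic tie-break is not relabel-equivariant; `combinatorial_coefficient`
therefore canonicalizes the labeling first (choosing the relabeling with the
lexicographically smallest sorted signal list), which makes CC exactly
relabel-invariant without touching the compression itself.

## Compositional structure: Mantel z

Compositionality — similar meanings receiving similar signals — is the
Pearson correlation `r` between the 28 pairwise length-normalized Levenshtein
distances (nLED: unit-cost edit distance divided by the longer length) among
signals and the 28 pairwise Hamming distances (0–3) among meanings,
standardized within its permutation distribution:

    z = (r_obs − mean(r_perm)) / sd(r_perm)

with permutations drawn uniformly with replacement from the 8! reassignments
of signals to meanings (default 1000; population-form sd; the observed
assignment is not forced into the null sample). Zero variance in either
distance vector is flagged as degenerate. An exact variant enumerates all
40,320 reassignments and serves as the oracle for the sampled test. Edit
distances are computed with `edlib`; the tests hold an independent
dynamic-programming oracle against it.

Calibration: the permutation z is approximately standard normal under the
null (measured mean ≈ 0, sd ≈ 1 over structureless languages), and the
two-sided exceedance rate at the conventional 1.96 threshold is close to the
nominal 5% (measured ≈ 4%). The one-sided rate at 1.96 is ≈ 2%, as expected
for a near-normal statistic — a point worth keeping in mind when reading
"z > 1.96" claims at the 5% level.

## Transmission metrics

* **Fidelity**: mean nLED between signals for the same meaning in consecutive
  generations; parent-relative values are missing (not zero) at generation 0.
* **Self-comprehension**: mean Hamming distance (raw 0..3 scale) between the
  target meaning and the meaning the learner selects for their own signal.
* **Iconicity**: mean signal length over the 4 small and the 4 large
  referents; the summary `len_diff = large − small` is positive when longer
  signals go with larger referents (the attested direction).

Within a chain the same permutation seed is reused for every generation's
Mantel test, so identical languages at different generations receive
bit-identical z.

## Growth-curve models

Each dependent variable is modeled over generations with fixed effects of
sum-coded condition (±1; alphabetically first level = +1, which puts `large`
at +1 for the size contrast), centered orthonormal polynomial generation
terms (linear + quadratic, computed by QR over the observed generation
vector, R `poly()`-style), and their interactions; random intercepts and
generation slopes by chain; for the item-level signal-length model
additionally a size contrast (size × condition × generation fixed structure)
and meaning-level variance components.

Fitting uses REML via statsmodels `MixedLM`. Two deliberate deviations from
an lme4-style analysis:

* **Normal-reference Wald tests** replace Satterthwaite degrees of freedom;
  the package's claims rest on sign/recovery properties, not df-exact
  p-values.
* **Crossed random effects** (chain and meaning) are not supported by
  `MixedLM`; meaning effects are approximated as variance components within
  chain.

On convergence failure the random structure is simplified stepwise —
quadratic slope dropped, then linear, then the meaning components — and the
level reached is recorded with the fit (`simplification_level`, 0 = full).
Within each level three optimizers are tried (L-BFGS, Powell, Nelder–Mead)
before simplifying. Degenerate zero-variance outcomes short-circuit to the
closed-form fit (intercept = the constant, all other coefficients 0), since
REML is undefined there.

## Synthetic chains

Human learners are replaced by a parametric noisy-copy/regenerate agent with
no claim of cognitive fidelity; it exists to give the metrics known ground
truth. Per meaning, with probability `p_comp` the signal is regenerated from
a fixed feature→bigram map (size chunk + shape chunk + brightness chunk, 6
symbols), otherwise the parent signal is copied; either way per-position
noise applies: substitution `p_flip`, insertion `p_ins`, deletion `p_del`,
with the deletion rate shifted by `iconicity_beta` (up for small referents,
down for large) to plant relative iconicity. Duplicates are resampled up to
`max_unique_retries`, then disambiguated by appending random symbols — the
simulator's stand-in for the experiment's forced retry. `p_comp_schedule`
lets the regeneration probability vary by generation (used to plant
rise-and-fall compositionality trajectories).

Training is simulated as alternating comprehension/production rounds of 8
trials; per-item recall starts at chance (1/8 for comprehension; a 0.01 floor
for production) and rises by `learn_rate` per exposure, credited at
presentation so an instant learner finishes in the minimal 16 trials. A round
with ≥ criterion (3 or 5) correct earns a star; two stars end training;
trials-to-criterion is the total trial count. Self-comprehension presents 4
random targets; the agent picks the target with its recall probability, else
one of 3 random distractors (mirroring the 4-candidate display).

Defaults are the study design (12 chains × 10 generations per condition,
short/long criteria 3/5) with noise chosen to produce fidelity typical of
human transmission of such signals (mean nLED in the 0.2–0.4 range):
`p_flip=0.12, p_ins=0.03, p_del=0.07` give mean nLED ≈ 0.20–0.25, and the
deletion excess makes signals shorten over generations, a regular feature of
transmission chains. `p_comp=0.1` and `iconicity_beta=0` by default (no
planted structure).

What the simulator does *not* emulate: modality (audio vs visual) and
temporal presentation mechanics, participant-level variation in learning
style, communicative or pedagogical pressure, and any cognitively motivated
chunking. Passing tests therefore show that the *measures and models recover
planted structure of the stated kinds and sizes* — not that human chains
would produce that structure.

## Numerical choices and problem sizes

* Mantel permutation count defaults to 1000; the exact 8! enumeration is
  vectorized and cheap (~ms), as is the sampled test.
* Tie-breaks in the MDL search: (description length, gram length, gram) —
  the last key is ours, for determinism; repeated runs are bit-identical.
* All randomness flows from integer seeds; experiments derive per-chain and
  per-generation child seeds from the master seed via `SeedSequence`, so an
  experiment is a pure function of its config.
* Validation suites run the planted-effect recovery at 100 simulated
  experiments (12 chains × 2 conditions × 10 generations each), the Mantel
  calibration at 500 structureless languages × 1000 permutations, and the
  sampled-vs-exact agreement at 20 languages × 5000 permutations — sizes at
  which the binomial/Monte-Carlo error of each check is well below its
  decision margin.

## Known limitations

* The recombination index is a documented stand-in; only its qualitative
  behavior (0 without reuse, 1 at full reuse, monotone in reuse) is asserted.
* The meaning-within-chain variance-component approximation understates the
  shrinkage a fully crossed meaning effect would give; coefficient signs and
  magnitudes on simulated data are unaffected in the recovery tests.
* The human-data point estimates (trials-to-criterion means, nLED means,
  Table-style coefficients) require the original participant data and are
  out of scope; the pipeline's correctness is instead established by exact
  worked examples, independent oracles, calibration, and planted-effect
  recovery.
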