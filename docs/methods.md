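# Methods

## The learning rule and its fixed point

Both simulations use the Widrow–Hoff delta rule on a two-layer network of
discrete cues and outcomes.  On each trial the activation of outcome *j*
is the sum of the weights from all present cues; present cues' weights to
*j* move by `η(1 − act(j))` when *j* occurred and `η(0 − act(j))` when it
did not; absent cues are untouched.  All deltas of a trial are computed
from the pre-trial matrix and applied simultaneously (the standard
convention; per-cell sequential updating would make the result depend on
an arbitrary cue order).  The learning rate is the rule's single
parameter, `η = 0.01` (dimensionless) everywhere.

Cues and outcomes are indexed up front from the complete event stream, so
negative evidence applies from trial one to every outcome the stream will
ever contain.  The alternative — growing the outcome set online — makes
early weights depend on the accidental order of first appearances and
drifts away from batch-style asymptotes; pre-indexing removes that
artifact.  The one deliberate exception is class-restricted training in
Simulation 2, where a learner's outcome index is exactly the outcome set
of its own (reduced) stream: that reduction *is* the manipulation.

Because the rule is the LMS rule, its small-η long-run weights from a zero
start are the minimum-norm least-squares solution of the
frequency-weighted regression of outcome indicators on cue indicators.
`asymptote_oracle` computes this by pseudoinverse and serves as the
independent oracle in the tests.  Two read-out subtleties matter when
comparing trained weights to the oracle at a fixed η:

* In convergent designs (noun features → marker; noun features → object)
  the cue patterns are linearly separable from their targets, per-trial
  residuals vanish, and the endpoint weights converge to the oracle
  (verified to max |Δ| < 0.02 after 20 epochs for the category task, and at
  the much longer noun-task timescale of several hundred epochs — more
  outcomes mean slower modes).
* In the divergent premarking design the learner cannot predict *which*
  class member follows the marker, per-trial residuals stay large, and the
  fixed-η iterate oscillates around the fixed point with an amplitude of a
  few hundredths.  The trailing-epoch *average* of the weights matches the
  oracle (< 0.02 after 20 epochs); the endpoint alone does not, at any
  budget.

`detect_asymptote` declares asymptote at the first trial whose trailing
window (default one 412-trial epoch) of per-trial maximum weight change
stays below a tolerance, optionally restricted to chosen outcome columns.

## The artificial language as synthetic data

The entire input is generated from the printed language: 32 nouns in four
classes, each class combining one distinct meaning feature (animal, plant,
or one of two "random object" classes sharing `D3meaning`) with a
three-feature stress-pattern set of one distinct and two shared features.
The sharing is the deliberate ambiguity structure: classes 2 and 4 have
identical form sets, classes 3 and 4 identical meaning sets, class 1 is
fully unambiguous.  Nouns are additionally represented as uniphones with
word-boundary marks, produced by a declared longest-match-first
grapheme→phone table (digraphs sh→ʃ, ng→ŋ, ch→x, ts→ts, all other letters
identity).  Phonetic fidelity is irrelevant — only cue identity and
overlap matter — and the table round-trips the whole lexicon, which the
integrity check enforces.  Stress is carried solely by the abstract
form features; per-syllable annotations and stem-length variation are not
modeled.  Concrete markers (ima/imo/ime/imi; ove/ira/agi/epo with their
carrier-phrase vowel alternation) and the unspecific markers of each
variant are stored for stimulus listings only; simulation events consume
the abstract identities marker1…marker4 plus an ever-present `constant`
cue that plays the role of a regression intercept and guarantees a minimum
of cue competition in the divergent condition.

Within every class the eight nouns follow the geometric per-epoch
frequencies 32/23/16/11/8/6/4/3 (sum 103; 412 trials per epoch).  The
default stream sampler shuffles this exact multiset per epoch and
concatenates epochs — matching the behavioral design and removing
frequency-realization variance; an i.i.d. frequency-weighted sampler is
available behind a flag.  The pseudorandomized behavioral order (first 112
tokens drawn only from the four highest-frequency nouns per class) is
implemented separately and is not used by the simulations.

What the generator does *not* emulate: acoustic variability, carrier
phrases and visual context, participant attention and memory limits, or
any between-participant variation.  Passing tests therefore show that the
order effects follow from the learning rule plus the language's
combinatorics — not that human listeners will show them at these
magnitudes.

## Simulation 1 — category structure

Premarking and postmarking learners consume the *same* noun-token stream
with roles swapped: `{marker_k, constant} → {meaning set ∪ form set ∪
uniphones ∪ object}` versus `{… ∪ constant} → {marker_k}`.  Training runs
1,600 trials (the category weights' asymptote regime), with a checkpoint
at the behavioral count of 412 trials.

Evaluation separates the two dimensions.  Postmarking: cue the learner
with one class's meaning or form set plus the constant and compare the
four markers' activations.  Premarking: cue with one marker plus the
constant and score each candidate feature set by the sum of its features'
activations (three candidate sets per dimension).  Accuracy is the mean of
binary rectified-Luce choices, which equalizes chance at ½ across the
3-vs-4-alternative asymmetry.  Binary choices whose two alternatives are
both correct for the cue — derived mechanically from the shared feature
sets, never hard-coded — are excluded.  ReLU is applied at the *set* level
after summing (a set is one choice object; rectifying its members
individually would let negative evidence inside a set vanish); a
feature-level switch exists for sensitivity analysis.  The headline
statistic per dimension is the postmarking-minus-premarking mean over the
four classes.

Expected mechanics, which the tests assert: on the form dimension the
convergent postmarking learner dissociates the shared features and leans
on the distinct ones (advantage ≈ +0.21); on the meaning dimension both
orders approach ceiling with a small premarking edge (≈ −0.02) because the
divergent learner tracks conditional probabilities, which are already
diagnostic there.  Early in divergent learning, feature *activations*
given marker + constant rise in frequency order (shared-by-three fastest,
distinct slowest).  Note the frequency ordering lives in the activations:
the marker-row weights alone order the other way around, because the
constant cue competes away more of the frequent features' predictive
value.

At the 412-trial checkpoint the postmarking read-outs are already settled
to within 0.01 of their asymptotic values and the premarking form
read-out to within 0.09; the premarking meaning cells are still drifting
(up to 0.16 below asymptote), so "relatively constant" holds everywhere
except the slowest divergent cells.

## Simulation 2 — levels of abstraction

Both conditions learn `{form set ∪ uniphones ∪ constant} → object`.  The
postmarking learner trains on the full 32-noun stream throughout.  The
premarking learner shares that full-set training for the first quarter of
the budget (marker–class associations must first exist before they can
reduce uncertainty) and then continues as four class learners, each a
*reduced network* initialized from the quarter-point weights of its
surviving columns and trained only on its class's trials, with negative
evidence confined to its own outcome index.  The continuations inherit the
shared weights rather than restarting, since the premise is one learner
whose premarkers narrow the candidate set; a fresh-learner switch exists
for sensitivity analysis.

Choice alternatives are each learner's own outcome index — the objects it
was actually discriminating.  This single convention produces all three
reported behaviors at once: veridical premarking class models compete over
their 8 within-class objects (chance 1/8) while postmarking competes over
all 32 (chance 1/32); at the 412-trial checkpoint the premarking condition
*is* still the full-set learner, so the difference is exactly zero; and in
outcome-shuffled baselines the class streams deliver all objects, the
"class" models index (almost) all 32, and the null difference centers on
zero rather than on the 1/8 − 1/32 gap that a fixed 8-vs-32 normalization
would force.

The budget is set by the stated stopping rule — frequent nouns' object
weights at asymptote — operationalized a priori as per-trial prediction
error within 5% of the unit ceiling across a full trailing epoch for the
frequency-32 object columns.  On the reference stream this is first
satisfied at ≈ 72.7 epochs; the default budget is 73 epochs (30,076
trials, first 7,519 shared).  The statistic is budget-sensitive on the way
there (it peaks near 0.29 around 8–16 epochs and decays as the full-set
learner catches up, toward ≈ 0.03 in the infinite limit), which is why the
stopping rule, not a round number, fixes the default.  At that point the
premarking-minus-postmarking mean over the 32 nouns is ≈ +0.10, the
correct-object probability rises with training frequency in both
conditions, and the advantage is absent at 412 trials.

## Randomization tests

Significance of the three mean differences is assessed by retraining both
models of a simulation on streams whose per-trial outcome *sets* were
permuted across trials (cue sets and trial order untouched; a label-level
shuffle exists behind a flag but can merge duplicate labels and is not the
default reading).  Each baseline recomputes the same statistic; p-values
use the add-one estimator `(b + 1)/(n + 1)`, so `p = 1/1001 ≈ .001` is the
floor at the default 1,000 baselines.  The form-dimension and
noun-learning tests are one-sided in their hypothesized directions; the
meaning-dimension test is two-sided, as it checks the absence of an
effect.  The two Simulation-1 statistics share one set of retrained
baseline pairs — the protocol is identical, only the statistic differs.
Under the null the baseline means sit where the marginal feature
frequencies put them (form ≈ −0.02 and meaning ≈ −0.04, both from the
premarking set-size/frequency asymmetry alone; Simulation 2 ≈ 0), and the
estimator's p-values are uniform on their grid, which a scaled-down
200-replication check (one-epoch streams, 99 baselines) verifies.

## Numerical and engineering choices

Dense float64 arithmetic; no saliences, schedules, or minibatching.  The
sequential inner loop is a numba kernel with a byte-identical pure-numpy
fallback (tested equal).  Degenerate Luce cases (all rectified activations
zero) fall back to the uniform choice, preserving the exact untrained
baselines of ½, 1/8 and 1/32; an evaluation whose every binary choice is
excluded raises instead of guessing.  Event streams serialize to the
tab-separated `Cues/Outcomes/Frequency` text format with `_`-joined
labels; the language itself ships as a canonical YAML listing.  All
randomness flows through explicit integer seeds, and identical
configurations reproduce byte-identical outputs.

## Known limitations

The within-class frequency profile, the feature geometry, and the 4-class
design are fixed by the language; the package does not parameterize
alternative category systems.  Simulation 2's headline magnitude depends
on the asymptote tolerance through the stopping rule (its sign and
significance do not).  The behavioral experiment that accompanies these
simulations — participants, eye-tracking, GAMM analyses — is out of scope,
and nothing here should be read as a fit to human data.
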