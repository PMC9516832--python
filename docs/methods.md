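# Methods

## The general model G

G is a character-level autoregressive language model over SMILES strings:
an embedding table, a stack of GRU layers, and a linear readout over the
vocabulary.  SMILES are tokenized strictly per character (two-letter
element symbols such as `Cl` become two tokens); three reserved special
tokens — pad, start, end — are added because autoregressive sampling needs
a start symbol and a stop criterion, and batching needs padding.  The
specials are multi-character strings, so they can never collide with a
SMILES character.  A regex-based multi-character token pattern ships in
`corpus.MULTI_CHAR_PATTERN` for users who want chemically atomic tokens,
but it is not the default.

Training is teacher-forced next-character prediction.  The loss reported
and minimised is the conventional per-token mean negative log-likelihood;
the standalone `cross_entropy` operation also exposes the variant with a
1/k prefactor (k = vocabulary size), which differs from the conventional
one only by a constant factor and therefore only rescales the learning
rate.  Probabilities inside logs are floored at 1e-12 so a zero predicted
probability can never produce an infinite loss.  Loss is masked over
padded positions.  Optimisation uses Adam.

Sampling draws one character at a time from `softmax(logits / T)` starting
at the start token and stopping at the end token or at `max_length`
characters (default 100, matching the corpus length cap).  Pad and start
logits are masked out at sampling time.  Temperature applies at generation
only; training always uses T = 1.  T below 1 sharpens the distribution
(raising validity, lowering uniqueness), T above 1 flattens it; the
package default is T = 0.50, a compromise between the two ends of that
trade-off.

### Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `recurrent_layers` × `hidden_units` | 3 × 512 | capacity of G (full scale); desk-scale experiments use 1 × 64 |
| `embedding_dim` | 128 | character embedding width (free choice; 32 at desk scale) |
| `learning_rate` | 5e-4 | Adam step size, used for G and CRLV |
| `temperature` | 0.50 | sampling softmax divisor |
| `max_length` | 100 | corpus length cap and sampling horizon, characters |
| `batch_size` | 64 | sequences per optimizer step |

The sequence-model core (`molbias.nn`) is a self-contained NumPy
implementation with analytic backpropagation through time, verified
against central finite differences in the test suite, and bit-reproducible
for a fixed seed.  All randomness flows through seeded
`numpy.random.Generator` streams: weight initialisation, per-epoch batch
shuffling, per-epoch probe sampling and episode sampling each draw from a
separate stream keyed by (seed, purpose, epoch), which is what makes the
"CRLV at d = 0 equals plain training bitwise" contract testable.

## CRLV — conditional reduction of the loss value

Each biassing epoch:

1. sample `n_probe` molecules (default 20) at the benchmark temperature
   and measure the desirable fraction d = (valid AND objective-satisfying) / n_probe;
2. run one ordinary teacher-forced pass over the general corpus with the
   backpropagated loss multiplied by `scale(d)`;
3. run the k-molecule best-epoch probe (k = 20) and keep the checkpoint
   only on strict improvement (ties keep the earlier epoch).

The default reduction rule is linear, `scale(d) = 1 − d`, which satisfies
the method's limit conditions: full general-training loss at d = 0,
nothing backpropagated at d = 1.  A step rule (`"step@TAU"`: full loss
below the threshold, negligible epsilon above) is available.  d is
estimated once per epoch, not per batch — 20 samples is the only probe
size the reference experiment states, and a per-batch estimate at that
size would just add noise.  Desirability inside CRLV requires validity as
well as the objective: an invalid string is never desirable
(`require_validity=False` exists for validity-free diagnostic objectives).
The probe uses the same temperature as the final benchmark so the
quantity being optimised is the quantity being evaluated.

A numerical subtlety: at `scale = 0` the optimizer step is *skipped*, not
fed zero gradients.  Adam carries momentum state; feeding it exact zeros
would still move the parameters, violating the contract that a fully
desirable model stays put.

Because the loss is the same one used to train G, CRLV's fine-tuning
degrades validity, novelty, uniqueness and diversity far less than
policy-gradient fine-tuning — the catastrophic-forgetting comparison is
the package's central claim and is asserted at desk scale in the test
suite.  At desk scale the mechanism is visible in its purest form: the
loss scale modulates only the *magnitude* of ordinary training updates,
so CRLV gains desirable yield through continued training (validity
recovery) plus the best-epoch ratchet, while REINFORCE gains through
directed but diversity-destroying reward maximisation.

## REINFORCE

Episodes are complete sampled SMILES; the terminal reward is broadcast to
every character position with no discounting and no baseline subtraction
(an optional moving-average baseline is config-gated off).  The update is
one Adam step on the batch mean of r · Σ_t log p(a_t | s_t).  Rewards
default to +1 / 0 / −0.1 for desirable / valid-but-undesirable / invalid;
the ordering `desirable > valid_undesirable ≥ invalid` is validated at
configuration time, and all three are pluggable because hand-engineered
reward tables are the least portable part of any policy-gradient setup.
Episodes are sampled at T = 1: REINFORCE's gradient estimator assumes
actions are drawn from the policy itself, and tempered sampling would
bias it.  The best-epoch probe, by contrast, uses the benchmark
temperature (0.50), mirroring CRLV.

## Objectives and descriptors

Descriptors come from RDKit: Crippen logP, molecular weight, Lipinski
H-bond donor/acceptor counts, strict rotatable-bond count, and SSSR ring
perception with a ring counted aromatic iff all its atoms are aromatic.
The four functional groups are SMARTS substructure matches (hydroxyl
`[OX2H][#6]`, ester `[CX3](=O)[OX2][#6]`, carboxylic acid
`[CX3](=O)[OX2H]`, primary amine `[NX3;H2]`), kept as visible module
constants.  All boundary comparisons are inclusive.

The R-value used by objective 2 has no universally fixed definition; it
is a pluggable descriptor slot whose shipped implementation — rotatable
bonds / heavy atoms — is a PLACEHOLDER on the right scale, replaceable
via `set_r_value_fn` and disableable via `require_r=False`.

Structural variance counts distinct characters of the
whitespace-stripped raw SMILES and divides by the global maximum length
(100).  Dividing by each molecule's own length instead destroys the
common reference scale (a long, symbol-rich string can score *lower* than
a short plain one); that variant is shipped only as an explicitly
non-canonical diagnostic.

## Evaluation funnel

Stages are strictly sequential and each fraction is relative to the
previous stage: validity (parse + sanitize), novelty (canonical form
absent from the training set), uniqueness (canonical deduplication, first
occurrence kept), desirability (objective predicate).  Internal diversity
is 1 − mean pairwise Tanimoto of 1024-bit radius-2 Morgan fingerprints
over the full n × n matrix including the diagonal — including the
diagonal makes the singleton case well defined (exactly 0) and matches
the power-mean formulation at p = 1.  Intersection percentages between
two generated sets are reported over the smaller deduplicated set, with
both set sizes and the raw overlap always emitted so any other
denominator convention can be recovered.

## The synthetic fixture corpus

`generate_fixture_corpus` assembles chemically valid SMILES from
parametric templates: short C/O/N chains, methyl branches, C=C units,
aromatic rings (benzene, pyridine, furan, pyrrole), aliphatic rings, and
simple functional-group tails (alcohol, amine, acid, ester, amide,
nitrile).  The `"simple"` template set places a ring in ~45 % of
molecules; `"ring-rich"` in all of them.  Every emitted string passes
RDKit sanitization, and generation is deterministic per seed.

What the fixture emulates: a homogeneous population of small drug-like
fragments with a ~17-character alphabet, enough for a small GRU to learn
grammar (ring closure, branch balancing, valence patterns) in under a
minute of CPU.  What it does not emulate: the scale (1.5 M molecules),
the ~72-character alphabet with bracket atoms, stereochemistry and salts,
and the long-tail structural diversity of a real screening library.
Passing tests therefore demonstrate the *mechanisms* — loss conditioning
preserves competence, policy gradients focus but collapse, temperature
trades validity against uniqueness — not production-scale metric values,
which the full-scale configuration exists for.

## Desk-scale study conditions

The test suite runs two seeded experiments on the 500-molecule fixture
corpus with a 1 × 64-unit G (seeds 101/202/303, benchmarks on 500 samples
at T = 0.50):

* **Comparative experiment** — G trained 60 epochs (validity ≈ 0.55,
  deliberately short of saturation), biased 50 epochs toward "at most one
  rotatable bond" (corpus frequency 0.32, but only ~1–2 % of G's output,
  so both methods have headroom) by CRLV (defaults) and by REINFORCE
  (lr 2e-4, 32 episodes/epoch).  Asserted: both best-epoch models beat
  the unbiased G's desirable count; CRLV retains uniqueness at least as
  well as RL; RL's final epoch never has more unique molecules than its
  best epoch; CRLV keeps ≥ half of G's validity and uniqueness.
* **CRLV-dynamics experiment** — G trained only 30 epochs (validity
  ≈ 0.15, large headroom), CRLV toward "no aromatic ring".  Asserted: the
  probed desirable fraction trends upward and the best-epoch model beats
  the unbiased G by a wide margin.

The REINFORCE learning rate is lower than CRLV's because policy-gradient
fine-tuning of a small generator collapses onto a handful of rewarded
molecules within a few epochs at 5e-4 — the focus-without-maximisation
failure mode the comparison exists to expose; 2e-4 lets the reward rise
for tens of epochs before the collapse, giving the best-epoch checkpoint
something to find.

## Numerical choices and degenerate inputs

* Softmax and log-softmax are max-shifted; sigmoid is computed by sign
  split; no exp overflow is possible for finite logits.
* Log probabilities are floored at 1e-12 in the standalone cross-entropy.
* Empty generated lists: validity returns 0 with a warning; internal
  diversity on an empty set is an explicit error (undefined), a singleton
  scores 0.
* Best-epoch tie-break: strictly-greater comparison, so ties keep the
  earlier checkpoint; with zero biassing epochs, final = best = input.
* Zero-weight update batches (CRLV at d = 1, REINFORCE with all-zero
  rewards) skip the optimizer step entirely (see above).
* Duplicate corpus lines are kept at ingest — deduplication is an
  evaluation concern, and silently dropping duplicates would change the
  empirical distribution the generator is supposed to learn.

## Known limitations

* The per-character tokenizer treats `Cl`/`Br` and bracket atoms as
  multiple tokens; the fixture corpus avoids them, real corpora will
  spend model capacity learning to close brackets.
* CRLV's loss scale modulates update magnitude only; it has no gradient
  pointing *toward* the objective, so in short runs its gains come from
  continued training plus checkpoint selection.  With a saturated
  generator and a rare objective it can plateau.
* REINFORCE here is the plain algorithm — no baseline, no entropy bonus,
  no trust region — because that is the comparison target; its run-to-run
  variance is correspondingly high.
* The R-value descriptor is a placeholder (see above).
* Novelty is canonical-form exact match; tautomer- or
  stereo-insensitive novelty is out of scope.
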