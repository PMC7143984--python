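# Methods

## The model

`cwqsar` fits one-variable QSAR/QSPR models built on *optimal descriptors
of correlation weights*.  A molecule's SMILES string is decomposed into a
multiset of attributes; each attribute `A_k` carries a real correlation
weight `CW(A_k)`; the descriptor is their sum

    DCW(T, N) = Σ_k CW(A_k)        (multiplicity respected)

and the endpoint model is the line

    endpoint = C0 + C1 · DCW(T, N)

with `C0`, `C1` from ordinary least squares on the training set.  `T`
(rarity threshold) is the minimum number of distinct training molecules
an attribute must occur in to receive a weight — rarer attributes are
*blocked* at weight 0 — and `N` is the number of Monte Carlo epochs spent
optimizing the weights.

### Attribute families

Local SMILES attributes: **Sk** (one token: a character, or 'Cl', 'Br',
'@@', '%NN') and **SSk** (adjacent token pairs).  Global SMILES
attributes: **BOND** (flags for '=', '#', '@'/'@@'), **NOSP** (flags for
N, O, S, P), **HALO** (flags for F, Cl, Br, I) and **PAIR** (one key per
unordered pair of co-present features from {F, Cl, Br, I, N, O, S, P,
double bond, triple bond, stereo marker}).  Graph invariants computed on
the hydrogen-suppressed heavy-atom skeleton: **EC0** (vertex degree),
**EC1** (first-order Morgan extended connectivity — sum of neighbour
degrees), **C5**/**C6** (counts of 5-/6-membered rings in a minimum
cycle basis), and an optional per-vertex neighbourhood code **NNC**
(counts of neighbours of degree 1, 2, ≥3; this is the package's own
documented convention, disabled by default and excluded from any
validated descriptor because the code's published semantics are not
available in full).

Every attribute renders as a fixed-width 12-character key so weight
tables from different models are comparable attribute-by-attribute.
Conventions adopted where printed tables are the only guide:

* ')' is canonicalized to '(' before any attribute is formed (a branch
  boundary is one symbol); the raw string is retained only for
  round-trip checks.
* SSk keys place the token with the higher ASCII ordering in the first
  4-character field, so the pair key is order-invariant.
* BOND flag order is '=', '#', '@'; '@@' sets the same flag as '@'.
* PAIR keys pad the first feature with '-' and the second with '=';
  the reader also accepts the '.'-padded and upper-case ('CL') dialects
  seen in some printed tables and normalizes them.
* Bracket atoms are tokenized character-by-character ('[', element,
  'H', charge signs and digits are separate tokens); aromatic lowercase
  atoms are distinct tokens from their uppercase forms; no implicit-H
  expansion.

The graph parser ignores bond order for adjacency (an edge is an edge),
suppresses explicit hydrogens, and resolves fused-ring ambiguity with a
minimum cycle basis (SSSR-equivalent).  Ring counts are clipped at 9 to
fit one key digit; EC1 values above 9 simply occupy more digit positions.

## Monte Carlo weight optimization

Weights start at 1.0 (or uniform(−1, 1) with `init_mode="uniform"`).
Each epoch visits every active attribute once in a freshly shuffled
order; for each visit one magnitude `u ~ Uniform(0, step_max]`
(default `step_max = 0.1`) is drawn and tried as `CW ± u`, one random
direction first, the opposite direction if the first is rejected.  A
move is kept only when the target strictly increases, so the per-epoch
trace is non-decreasing.  There is no annealing temperature; greedy
acceptance is the simplest scheme consistent with a Monte Carlo
coordinate search, and it makes run-to-run differences attributable to
the seed alone.

The default target is **|Pearson r|** between DCW and the endpoint over
the training set.  The magnitude — not the signed r — is the right
objective for a one-variable model because the calibration slope absorbs
the sign of the association; maximizing signed r would have to drag a
strongly anti-correlated initial descriptor through r = 0.  After the
search the weight table is canonicalized so that DCW correlates
*positively* with the endpoint (all weights are negated if needed, which
leaves |r| unchanged): a positive weight therefore always means a
promoter of endpoint increase and the slope C1 is non-negative, which is
what makes promoter-sign analysis across runs meaningful.  A degenerate
descriptor (zero variance) scores −1.

The optional `balance` target scores
`r_sub + r_cal − 0.1·|r_sub − r_cal|` with a user-supplied calibration
subset (three-set workflows).  Two-set training/validation mode is the
default.

All randomness flows from one `numpy` generator seeded per run; fitted
model files are bit-reproducible from (data, descriptor config,
optimizer config).  Model files are JSON with weights serialized via
`repr`, which round-trips IEEE doubles exactly.

Out-of-vocabulary attributes at prediction time contribute 0 to DCW and
increment a counter (`CorrelationWeightTable.oov_seen`) that serves as a
crude applicability-domain signal; no further domain analysis is done.

## Validation criteria

`cwqsar.stats` implements the standard external-validation battery:
Pearson r/r²; Lin's concordance correlation coefficient; the
through-origin slopes k = Σyỹ/Σỹ², k′ = Σyỹ/Σy² with the matching
determination coefficients r0², r0′² (each direction's through-origin
fit judged against that direction's centred variance); the external
predictivity family Q² (external mean), Q²F1 (training mean), Q²F2
(external mean — numerically equal to Q² here), Q²F3 (external PRESS per
compound over the training-set endpoint variance); Roy's rm² in both
regression directions (average and absolute gap); the index of ideality
of correlation (IIC); and the Golbraikh–Tropsha pass/fail flags
(defaults r² > 0.6, 0.85 ≤ k ≤ 1.15, (r²−r0²)/r² < 0.1,
|r0²−r0′²| < 0.3, all overridable).

Notes and choices:

* The training context needed by Q²F1/F3 stores the training mean,
  size, and *population* variance (SS/N).
* rm² defaults to the square-root form r²(1 − √|r² − r0²|) used in the
  validation literature; `sqrt_form=False` selects the literal
  no-square-root variant, and the two directional values are averaged
  (a printed minus sign in some sources is treated as a typo).  The
  sqrt form is non-Lipschitz at r² = r0², so exact cross-implementation
  agreement degrades to ~1e-9 there; the literal form is
  well-conditioned and is what the 1e-12 brute-force comparison in the
  test suite checks.
* A leave-one-out Q² for the one-variable line is provided
  (closed-form PRESS via leverages) alongside the external Q², since
  the plain "Q²" symbol is used both ways in the literature.
* Undefined statistics (zero variance, empty residual class where a
  mean is required) are reported as absent (`None`/`NA`), never as
  silent zeros.  The single deliberate exception is the IIC, which is
  *defined* as 0 when all residuals share one sign.

## Endpoint similarity via promoter stability

For one endpoint, several independent optimization runs (different
seeds; three runs is the conventional choice) are classified per
attribute: weight > 0 in every run → stable promoter of increase (+1);
weight < 0 in every run → stable promoter of decrease (−1); anything
else, including an attribute blocked in any run, → unstable (0).
Strict sign is used with no epsilon band.  Two endpoints' similarity is
the number of attributes with identical non-zero labels, dissimilarity
the number with opposite non-zero labels; missing attributes count as
unstable.  The similarity matrix's diagonal holds each endpoint's
stable-attribute count; the dissimilarity diagonal is 0 by construction.

For run-ensemble stability analysis `init_mode="uniform"` should be
used: with the all-ones init, attributes the search never needs to move
would stay positive in every run and the stability labels would carry no
information.

The split × run *consistency table* is the cohort-comparison variant
(e.g. models fitted separately for male and female animals over three
data splits × three runs): each cell is 1 iff the attribute's weight is
strictly positive in that (split, run) model, with row totals per cohort.
The bundled reference table's published grand totals disagree with the
sums of its own published row totals; the package computes grand totals
as row-total sums and the bundled file carries only the row-level data.

## Synthetic data

The generator emits SMILES from a closed grammar — backbone chains
(2–12 heavy atoms), branches (p = 0.3, depth ≤ 2), 5-/6-membered rings
(p = 0.25 per chain position, 6-rings aromatic with p = 0.4), double and
triple bonds (p = 0.15 / 0.03), atom alphabet C, N, O, S, F, Cl, Br with
halogens only in terminal positions and a carbon-biased backbone.  The
grammar is restricted by construction to what the tokenizer and graph
parser support, so generator–parser compatibility is an invariant rather
than a hope.

An endpoint is planted as
`endpoint = intercept + slope·DCW(true weights) + ε`, with true weights
drawn uniform(−1, 1) over the observed attribute universe and
ε ~ Normal(0, noise_sd); the default harness uses n = 250 molecules and
noise_sd = 0.05·sd(signal), with an 80/20 training/validation split.
Additive Gaussian noise on the endpoint scale is the natural emulation
of log-scale biochemical endpoints (lnR, pIC50).  Splits are either
seeded random shuffles or "striped": endpoint-sorted round-robin
dealing, which emulates a rational split whose sets share the endpoint
distribution.

What the generator does *not* emulate: chemically realistic molecule
distributions, valence constraints, stereochemistry beyond the '@'
token, or the composition of any specific experimental dataset.
Passing recovery tests therefore demonstrates that the pipeline can
find a planted linear signal in its own attribute space — a necessary
correctness property — not that comparable accuracy is attainable on
real endpoints.

## Problem sizes and numerical choices

The recovery check runs the default harness noiselessly at N = 50
epochs for three seeds and requires validation r² ≥ 0.95 (measured
0.986–0.990); at these sizes one optimization takes well under a second.
The split-sensitivity check fits ten random 80/20 splits of one n = 120
dataset at N = 10 and asserts a strictly positive spread of validation
R².  Statistics are compared against naive-loop reference
implementations at 1e-12 (literal rm² form; sqrt form at 1e-9, see
above).  OLS calibration refuses descriptors with zero variance;
optimization falls back to an intercept-only model (slope 0) only if the
final descriptor is degenerate.  Ties in the SSk ASCII ordering cannot
occur (equal tokens render identically); ring-digit labels are reused
per the SMILES standard and matched pairwise.

## Known limitations

* SMILES are treated syntactically: no valence checking, aromaticity
  perception, or canonicalization; equivalent SMILES spellings of one
  molecule produce different local attribute multisets by design (the
  descriptor is notation-sensitive, as is inherent to SMILES-attribute
  methods).
* The NNC convention here is a documented stand-in and must not be
  compared against published NNC values.
* Blocked/unknown attributes contribute 0 at prediction, so predictions
  far outside the training chemistry degrade silently except for the
  OOV counter.
* The Monte Carlo search is greedy and can stall on plateaus; epochs,
  step size and initialization are exposed for that reason.
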