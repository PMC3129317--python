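# Methods

This note records the models, conventions and numerical choices behind
habitevol, and what the synthetic-data tests do and do not demonstrate.

## Character coding and missing data

The life habit of a species is a single unordered categorical character:
1 cementing, 2 byssal attaching, 3 free-living, 4 recessing, 5 gliding,
6 nestling. Code 0 means "behaviour unknown" and is treated as missing
data throughout: a missing tip contributes an all-ones partial likelihood
(Mk) or a zero-cost full state set (parsimony), and 0 is never part of the
reconstructable state space. The state space of an analysis is the set of
codes actually observed among the tips (size *k*); whether an outgroup
taxon enters as its putative habit or as missing is decided by the
character file, not by the code.

Taxon names are matched exactly after trimming and collapsing internal
whitespace to underscores, which absorbs the main Newick dialect
difference. Trees are taken as rooted as written and never re-rooted;
polytomies are accepted natively rather than resolved, since the intended
inputs are consensus topologies.

## Mk1 likelihood and marginal reconstruction

The Mk1 model has one instantaneous rate *r* for every ordered state pair;
its transition probabilities have the closed form given in the README and
are used directly (no matrix exponentiation at run time; the matrix
exponential serves as an independent oracle in the tests). The root prior
is uniform 1/k over the observed state space — the conventional default
for a symmetric chain, where the stationary distribution is uniform.

Branch lengths of exactly zero (or absent) are clamped to
`min_branch_length = 1e-8` before likelihood work, because P(t) is singular
only at t = 0 and consensus trees routinely carry zero-length branches;
parsimony ignores branch lengths entirely. Partial likelihoods are rescaled
at every internal node (log accumulators), so ~100-tip trees are far from
underflow.

The rate is estimated once for the whole tree and character by bounded 1-D
maximum likelihood on [1e-8, 1e3/height]. The profile likelihood flattens
onto its saturation asymptote (#observed tips × ln 1/k) at large *r*, which
can strand a single golden-section search on the flat shoulder; the search
therefore first brackets the optimum with a 41-point log-spaced scan and
then refines locally. An invariant character has its maximum at r → 0 and
returns the lower bound with a warning.

Marginal (not joint) reconstruction is used because per-node probability
pies are marginal quantities: the inside (subtree) and outside
(rest-of-tree, prior included) partials are combined per node, normalised,
and checked for internal consistency (every node must reproduce the same
total log-likelihood to 1e-6 relative).

**Decision rule.** At each node, states whose log marginal likelihood lies
more than `lnl_threshold` (default 2.0) below the best state's are
rejected; a difference exactly equal to the threshold does *not* reject, so
ties at the boundary leave the node ambiguous. The rule is applied to the
log marginal likelihoods; applying it to normalised probabilities is
equivalent because the per-node normaliser cancels in differences.

## Parsimony

Unordered parsimony is implemented as unit-cost Sankoff in two passes over
the state space, which generalises Fitch to polytomies without inflating
scores. The reported per-node sets are exact MPR sets — states attained in
at least one most-parsimonious labeling — rather than a single
ACCTRAN/DELTRAN resolution, so reconstruction ambiguity is reported, not
hidden. Costs are kept in integer arithmetic (the "infinite" cost is
#nodes + 1), making the dynamic program exact.

## Transition enumeration

Ancestral-state sets are collapsed to single states before counting:

* `inherit_parent` (default): an ambiguous node adopts its parent's
  assigned state when that state is in its own set, adding no change on the
  connecting branch. This realises a minimal transition count among
  parent-propagating completions (asserted by exhaustive completion on
  small trees) and matches the "minimum number of transitions" reading of
  ancestral-state figures. An ambiguous root stays unassigned; descendants
  anchor at the first resolved node below it.
* `skip_branch`: ambiguous nodes stay unassigned and their branches are
  simply not counted.

One transition is recorded per branch with differently-assigned endpoints;
terminal branches count (single-species origins are real origins), and with
an ingroup restriction the branch subtending the ingroup's root is included
so a change at the family's origin is attributed to the family. Multiple
hits on one branch are invisible to any endpoint-based count — this is a
floor on the true number of changes, which is exactly how it is used.

## Origins, parallelism, convergence

Each transition record is one origin of its derived state; its ancestral
state is the state assigned to the parent node of that branch. Pairs of
origins of the same state are labelled parallel (equal ancestors) or
convergent (different ancestors); the per-state summary is `unique`,
`parallel`, `convergent`, or `both` for mixtures, since a state with three
or more origins can legitimately mix trajectories. Pairs were chosen as the
primitive precisely because per-state summaries lose that mixture
information. The "transitions sourced from habit *a*" count is a plain row
sum, including origins with no same-ancestor partner; a strict variant
(`include_singletons=False`) that requires a partner is provided because
the row-sum arithmetic counts one byssal-derived origin (recessing) that
has no parallel partner.

## Progenitor-bias test

Pearson's X² against a uniform expectation total/m with df = m − 1, no
continuity correction. Categories with zero observed transitions stay in
the category set (they contribute exp each); the six-category test on the
bundled study table gives X² = 37.000 with df = 5 and the merged-permanent
five-category test gives X² = 28.000 with df = 4. With a total of 17
events the chi-squared reference is an asymptotic approximation; the test
suite measures its type-I error at this scale by simulation (bounded
loosely, 3–8% at nominal 5%). An exact multinomial test is a documented
extension point, not implemented.

## Synthetic data

`simulate_yule_tree` draws a pure-birth tree: with *i* lineages alive the
next split waits Exp(λ·i) and a uniform lineage splits; the tree is
ultrametric with expected root-to-tip depth Σ_{i=2..n} 1/(λi), which the
tests check by Monte Carlo. `simulate_mk_character` runs the Gillespie
algorithm along each branch (leave rate (k−1)r, uniform choice among the
other states) and records *every* jump with its position, so the truth
available to tests is the full change history, not just endpoints; replay
of the history against the endpoint states is asserted on construction.

`make_study_like_dataset` emulates the study's conditions: 81 tips, six
states, a byssal-attaching root (the inferred ancestral condition), and a
rate calibrated on the realised tree so the expected number of changes is
17 (the observed transition count). Because the Gillespie event count is
Poisson with mean (k−1)·r·L for total tree length L, the calibration is
solved in closed form, r = 17/((k−1)·L), rather than by search. Defaults
follow those conditions and the simulation tests use them unchanged.

What the simulator does **not** emulate: extinction or fossil sampling,
trait-dependent diversification, rate variation among habits or lineages,
phylogenetic uncertainty (a single known tree is analysed), and the
taxonomically non-random sampling of a real dataset. Passing recovery tests
therefore show that the pipeline's inference machinery is correct and
well-calibrated under its own model, not that the model is adequate for any
particular empirical dataset.

## Known limitations and observed behaviour

* Single-character ML rate estimates on very small trees are poorly
  constrained and can saturate; toy analyses with a handful of tips may
  leave every node ambiguous (the pipeline then reports transitions as
  absent and marks the bias test skipped rather than failing).
* A fully resolved reconstruction is not guaranteed to reproduce the true
  simulated history. When the truth contains clustered homoplasy (e.g. two
  sibling lineages changing independently to the same state), the marginal
  reconstruction can confidently prefer a single earlier change — a more
  probable and more parsimonious history than the realised one. At the
  study-scale settings this affects a minority of fully-resolved replicates;
  it is a property of minimum-change ancestral inference itself, and the
  recovery tests document it rather than mask it.
* Asymmetric or ordered-state models, stochastic character mapping, and
  reconstruction over tree posteriors are out of scope.
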