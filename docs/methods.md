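# Methods

## Model

`clldbn` models a patient's course as a discrete-time, first-order Markov
process over a vector of categorical variables **X** = (X_1, …, X_n). A
dynamic Bayesian network is specified by two Bayesian networks over the
same variable catalog:

- the **prior network** B₀, a DAG over X^(0) giving the distribution at
  diagnosis (t = 0);
- the **transition network** B→, a conditional DAG over X^(t) given
  X^(t−1), in which each parent is tagged with a slice offset of −1
  (previous slice) or 0 (current slice).

The joint over an unrolled horizon 0..T factorises as

    P(X^(0:T)) = ∏_i P(X_i^(0) | π(X_i; B₀)) · ∏_{t=1..T} ∏_i P(X_i^(t) | π(X_i; B→)),

with π(·) the parent set and every conditional stored as an explicit CPT
(one probability vector per combination of parent states). The model is
time-invariant: the same transition CPTs apply at every step. Higher-order
temporal edges (offsets beyond −1) are rejected at parse time; the
two-slice template is a structural assumption, not a convenience.

The shipped networks use a slice of 6 months. The slice duration is
carried as document metadata and used only to label the time axis of
survival curves; inference itself is unit-free, which is why the
elicitation calculus below works in "unit periods" (1 unit period = 1
slice).

## Elicitation calculus

CPT entries for rare events usually come from literature statements over
long horizons. With `p` the probability over a horizon of `m` unit
periods, the per-`k`-period probability is computed as

- `rescale_probability` (default): `P_k = −(k/m)·ln(1−p)` — the cumulative
  hazard `−ln(1−p)` spread uniformly over the horizon. This linearized
  form is unbounded; outputs above 1 are clamped to 1 and an
  `ElicitationWarning` is recorded. It is undefined at `p = 1`.
- `rescale_probability_exact`: `P_k = 1−(1−p)^{k/m}` — the exact
  constant-hazard survival form, the identity at `k = m`. The two agree to
  first order in `p`; the worst-case gap over `k ≤ m` is `−ln(1−p) − p`
  (at `k = m`), e.g. 1.3e-3 at p = 0.05.

The worked conversion used throughout the package is 0.3 over 50 periods
(25 years of 6-month slices) → 0.00713 ≈ 0.007 per slice. Horizons are
deliberately expressed in unit periods rather than months so that the
caller states both numbers on the same clock.

Expert statements of the form "event E occurs r times more often in
stratum S" are applied with `odds_adjust`, by default on the odds scale
(`p ↦ rp / (rp + 1 − p)`): bounded, symmetric under `r ↔ 1/r`, with 0 and
1 as fixed points. The literature rarely states which scale such
multipliers live on; odds is this package's documented convention, and a
risk-ratio scale (`min(rp, 1)`) is available via `scale="risk"`.

## Exact inference

Queries are answered on the unrolled network by variable elimination:

1. **Intervention surgery.** Interventions replace CPTs *before* any
   message passing. An intervention names a variable, the slices it covers
   (`"all"` or a list), a transition-shaped replacement CPT and optionally
   a prior-shaped one for slice 0. Replacements must keep the declared
   parent set and pass the same row checks as any CPT — intervention means
   "this node behaves differently", not "rewire the graph".
2. **Relevance pruning.** For a query node X^(t) under evidence E, only
   the ancestral closure of {X^(t)} ∪ E contributes; barren descendants
   integrate to one and are dropped. This makes a T-slice survival
   trajectory cost roughly T small eliminations instead of T large ones.
3. **Elimination.** Factors are numpy arrays over (variable, slice) axes.
   The elimination order is greedy min-fill with a deterministic
   tie-break on (fill count, variable name, slice), so repeated runs take
   identical paths. Any intermediate factor above 5·10⁶ entries raises
   `IntractableError` — the engine refuses rather than silently
   approximates.
4. **Normalization.** The final factor is normalized; a total mass of zero
   raises `InconsistentEvidenceError` (typed, never NaNs).

Evidence is hard assignment per (variable, slice) and composes freely with
interventions: surgery first, conditioning second. Because the full
unrolled network is eliminated, queries at slice t are automatically
smoothed by any later-slice evidence.

`brute_force_marginals` answers the same queries by materialising the full
joint table (broadcast product of every CPT over the complete assignment
grid, capped at 10⁷ assignments) and summing axes. It shares no code path
with the elimination engine and exists as the test oracle;
`joint_probability` (a literal product of CPT lookups for one trajectory)
is a third, independent route used to check normalization.

## Shipped networks

Two networks are shipped as YAML documents generated from builder code
(`scripts/regenerate_networks.py`; tests assert the round-trip is
byte-identical, so code and documents cannot drift).

**HSN** (Health Status Network, 16 variables/slice) tracks prognosis, Rai
stage, transformation to aggressive disease, complications (infections,
autoimmune, other cancers), four cause-specific death indicators, ECOG
performance, and overall death/survival. Treatment is not represented
explicitly. **TEN** (Treatment Effect Network, 18 variables/slice) adds
the treatment pathway: a treat/watch-and-wait decision, the administered
line (none / alkylating agents / purine analogs / monoclonal antibodies),
its result (CR+PR / SD / PD / death), previous-line memory, and
treatment- and complication-specific mortality.

Provenance is tracked per CPT on two axes: `provenance` (`paper` — the
numbers are published expert values — vs `placeholder`) and `structure`
(`paper` — the parent set comes from a published table header or explicit
description — vs `inferred`). Paper-sourced content comprises: the HSN
*CLL stage* transition (18 rows), the HSN *Death from other cancers*
transition (the published worked elicitation: impossible without another
cancer, absorbing once dead, 0.007/slice otherwise), and the TEN
*Treatment result* transition (8 rows, including the absorbing rows for
dead patients). Everything else is placeholder; `cpt_coverage_report`
exposes the split machine-readably, and no placeholder number should be
read as a published value.

Placeholder choices worth knowing (all in the builder modules, all
flagged):

- Demographics at diagnosis: P(age ≤ 65) = 0.35 (median diagnosis age is
  around 70), P(female) = 0.37 (male:female incidence ≈ 1.7:1).
- Cause-specific hazards built with the rescaling calculus: death from
  infections 0.010/slice (≈40%/25 y), death after transformation
  0.173/slice (≈50%/2 y), death from complications in the TEN 0.018/slice
  (≈30%/10 y); treatment toxicity 0.010–0.015/slice by line; age-dependent
  background mortality 0.002–0.018/slice.
- Logical nodes are deterministic gates: overall *Death* is the OR of the
  cause-specific indicators, *Survival* its negation (HSN) or the AND of
  staying-alive conditions (TEN); *Previous treatment* copies last slice's
  *Treatment*. All cause-of-death indicators are absorbing, which is what
  makes P(Survival = yes) provably non-increasing — a property the tests
  check rather than a constraint the engine enforces.
- State order follows the printed CPT column order where a published table
  exists (e.g. HSN CLL stage as III–IV, I–II, 0) and the catalog order
  otherwise, so published rows transcribe without permutation. Stored
  probabilities are exact decimal literals as printed.

Initial-slice priors are nowhere published; all B₀ CPTs are placeholders.
The complete published structure exists only as diagrams that are not
machine-readable; parent sets not fixed by a table header or explicit
description are reconstructed from the running text and marked `inferred`.

### Scenario presets

Three presets for the TEN mirror the published patient groups:
`all_patients` (empty payload), `no_fatal_treatment_toxicity` (every row
of the *Death from treatment* CPT assigns 0 to "yes", prior and
transition, all slices) and `with_complications` (the *Complications* CPT
puts all mass on "yes" everywhere). With the placeholder CPT set the
group survival curves preserve the published qualitative ordering
(group 2 ≥ group 1 ≥ group 3 pointwise over 20 slices); the absolute
levels are *not* reproductions — they depend on the full unpublished CPT
set, so only the ordering is asserted.

## Forward sampling

`sample_trajectories` draws whole trajectories ancestrally (slice 0 from
B₀, then B→ slice by slice, each variable after its parents), vectorized
over trajectories. Randomness comes from counter-based Philox streams,
one stream per (variable, slice) step keyed by (seed, step index), with
exactly one uniform consumed per trajectory. Consequences: runs are
bitwise reproducible, and the first N trajectories of a larger run equal
the N-trajectory run (prefix stability), which keeps regression tests
cheap. Interventions are applied as CPT surgery with exactly the
inference semantics; hard evidence is deliberately unsupported (that
would require weighting — out of scope for prediction-only use).

`compare_mc_exact` reports, per (variable, slice, state), the empirical
frequency, the exact probability, and flags deviations beyond 4 binomial
standard errors `√(p(1−p)/N)` (plus a 1e-12 floor for degenerate rows).

## Curve comparison and pooling

Agreement between two survival curves is summarized as the mean absolute
difference at the five yearly points 12–60 months, in percentage points,
with linear interpolation from the 6-month grid; the metric is symmetric
and zero iff the curves agree at all five points. Multi-study trial
curves are pooled as the sample-size-weighted mean with a 95% normal
approximation CI computed from the pooled proportion at total n
(`p ± 1.96·√(p(1−p)/Σn)`), so a single study gets its binomial CI and the
band shrinks as 1/√n. How published trial bands were actually computed is
not stated anywhere we could encode; this is a documented convention, not
a reproduction. No registry or trial data is bundled — curves arrive as
`month,survival` CSVs.

## What the tests do and do not show

The test suite validates the *engine* (exact ≡ enumeration within 1e-9 on
200 random toy DBNs; sampler within 4σ of exact at N = 10⁵ on the shipped
TEN; normalization within 1e-8) and the *encoding* (published rows
reproduced exactly through inference; catalogs string-for-string; scenario
ordering and monotone survival). Problem sizes: random toy networks use
3–5 variables of 2–3 states over ≤3 slices so the enumeration oracle stays
exact and fast; Monte-Carlo checks use 10⁴–10⁵ trajectories over 10–20
slices. None of this validates the placeholder numbers against clinical
reality: with most CPTs placeholders, absolute survival levels are
illustrative, and real-data claims would require the original expert
tables plus registry curves supplied as CSVs.

## Known limitations

- Exact inference only; the interface cap raises a typed error on
  networks whose frontier grows too large, and no approximate fallback is
  provided.
- Transition CPTs are constant in time (time-invariance assumption);
  secular trends in therapy cannot be expressed except through
  slice-indexed interventions.
- Conditioning the sampler on evidence is unsupported (use the exact
  engine for posteriors).
- The treatment catalog is the classical chemo/immunotherapy triple; new
  agent classes would need new states and placeholder CPTs.
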