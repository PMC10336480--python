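# Methods

## The decision model

The engine treats guideline-conform therapy selection for upper
aerodigestive tract tumors as a lookup-and-filter procedure over a small
structured case file, with explicit escalation for everything the lookup
cannot responsibly cover.

**Stage classing.** TNM stages are grouped into three classes that key the
rule table: *early* = T1–T2 N0 M0, *locally advanced* = any other M0 stage
(T3/T4 or N ≥ 1), *metastatic* = M1. N2 subcategories (a/b/c) are distinct
stage tokens but class identically to bare N2. This three-way grouping is
the coarsest one that separates the packaged benchmark cases correctly; it
deliberately avoids committing to an AJCC edition's I–IVC numerals, which
the case file does not carry.

**Rule table.** `data/rules.json` maps (sublocation, early|locally_advanced)
to a set of candidate regimens. A regimen is an ordered modality list —
`[surgery, radiation]` is surgery with adjuvant radiation, a different
treatment from definitive radiation — except concurrent chemoradiation,
which is one treatment however it is spelled and is normalized to
`[radiation, chemotherapy]`. The table is data, not code: the ten benchmark
cases pin eleven of the sixteen cells directly or by implication, and the
remaining cells are completed by pattern (advanced non-nasopharyngeal sites
get {surgery→radiation, chemoradiation}; the nasopharynx, a
radiation/chemoradiation site, never offers surgery; early oral-cavity sites
mirror the anterior tongue's {surgery, radiation}). Pattern-completed cells
carry `"anchored": false` in the shipped file so a deploying team knows
exactly which entries to review against current guidelines before clinical
use. Metastatic disease has no entry anywhere: M1 always escalates.

**Decision procedure.** For a valid case: collect every applicable
escalation trigger in precedence order — relapse, metastatic (M1), and
no-feasible-option (the rule-table entry, filtered by the three feasibility
flags, is empty). Any trigger yields a face-to-face decision carrying the
full trigger list; the no-feasible-option check for M1 cases is evaluated
against the stage class the case would have without the metastasis, so an
M1 case whose local treatment is also infeasible reports both reasons.
Otherwise the filtered candidate set is returned as the options. The
procedure is pure and total on valid cases, and monotone in feasibility:
removing a feasible modality can only shrink the option set or convert it
into an escalation, never the reverse.

**Poor prognosis factors** are carried through the case file and into
reports but consume no rule: no published decision in the benchmark set
depends on them, so encoding any behavior would be invention. They remain
inert, documented input.

## Canonicalization and agreement

Decision strings use a small dialect: `or` separates alternatives, `+` and
`and` combine modalities into one regimen, `X ± Y` expands to the two
alternatives `X` and `X + Y`, and any capitalization/pluralization/dash
variant of "Face-to-face MDM" is the escalation marker. Canonical forms are
compared for exact equality — overlapping but unequal option sets count as
disagreement. This is the strict reading; a scorer giving partial credit for
a narrowed option set would only raise the observed agreement.

Cohen's κ is computed with each distinct canonical decision as one nominal
category: p_o is the fraction of equal pairs, p_e the chance agreement from
the two marginal distributions, κ = (p_o − p_e)/(1 − p_e). The degenerate
single-shared-category layout (p_e = 1) is defined as κ = 1 under perfect
agreement and is an error otherwise. Interpretation uses the Landis–Koch
bands (≤0 poor, then slight/fair/moderate/substantial in 0.2 steps, (0.8,1]
almost perfect). Weighted κ is deliberately out of scope: the decision
categories have no defensible ordering. Over the ten packaged benchmark
pairs the engine and the blinded expert agree on 7 cases with p_e = 0.20,
giving κ = 0.625 ("substantial") — the number `scripts/acceptance.py`
recomputes.

## Review workflow

The state machine is draft → pending → {validated | escalated}, plus
draft → escalated when the engine decision is already face-to-face;
validated and escalated are terminal. Only the five consultant roles vote;
a member may pick an engine option, propose an alternative regimen (which
becomes votable by the others), or request an in-person discussion. A
unanimous regimen validates; any split — including a single face-to-face
request, which makes unanimity on a regimen impossible — escalates with
reason `non_unanimous`. Re-voting before resolution replaces the earlier
vote, which minimizes deadlock; resolution is invariant to vote arrival
order because only the final multiset of choices matters.

The review window defaults to 15 days (matching a biweekly in-person
meeting cadence) and is configurable per submission. "Within 15 days" is
read inclusively: a case is overdue strictly after its deadline timestamp.
All timestamps are injected by the caller — the package never reads a wall
clock — so every workflow behavior is replayable in tests. Persistence is a
flat JSON state file per roster directory; a database is a deployment
concern, not part of the method.

## Synthetic case generator

`GeneratorConfig` draws valid draft cases from one explicit NumPy generator
(no global random state; identical seed ⇒ identical output). Defaults model
a plausible head-and-neck tumor-board caseload: sites uniform over the eight
sublocations, stage mix 45% early / 45% locally advanced / 10% metastatic,
each modality independently infeasible at 15%, relapse at 10%, and
histology tied to site (nasopharynx ⇒ UCNT, otherwise epidermoid
carcinoma). The generator emulates the *structure* of real case files, not
their epidemiology: real caseloads have correlated feasibility (a patient
unfit for surgery is often unfit for chemotherapy), site-dependent stage
distributions, and site frequencies that vary by region. Passing property
tests on generated cases therefore demonstrates the engine's structural
invariants (validity, monotonicity, totality, determinism), not clinical
performance on any real population.

## Numerical and interface choices

- κ is computed in double precision from integer marginal counts; the
  oracle-equivalence test requires agreement with an independent
  contingency-table computation to 1e−12.
- Option sets are mathematically unordered; rendering sorts regimens by
  (length, lexical modality order) for stable output.
- Problem sizes in the test suite — 1,000 generated cases for the
  monotonicity sweep, 200 random samples for the κ oracle check, 10,000
  random operation sequences for the workflow fuzzer — were chosen as the
  smallest sizes at which a violation of the respective invariant would be
  overwhelmingly likely to surface; all are deterministic (fixed seeds or
  derandomized hypothesis profiles).

## Known limitations

- The rule table covers eight sublocations of the upper aerodigestive
  tract; other head-and-neck sites (sinus, salivary glands, skin) are
  rejected at parse time rather than guessed at.
- Histology is carried in the rule-lookup signature but currently splits no
  cell; the nasopharynx/UCNT pathway is implied by the site. HPV status,
  performance status and dose/fractionation detail are out of scope.
- Unanchored rule cells are best-effort pattern completions and must be
  reviewed against current guidelines before any real-world use; the
  package is a decision-support research artifact, not a medical device.
- κ on ten items has wide sampling uncertainty; no confidence interval is
  reported because the benchmark set is fixed, not sampled.
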