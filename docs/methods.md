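# Methods

## The consolidation model

Each claim carries two anonymized identifiers: ID1, a digest of the insured
identifier + gender + birthdate, and ID2, a digest of the name + gender +
birthdate. Model every distinct value as a node of a bipartite graph with
node identity `(kind, value)` — an ID1 value and an ID2 value with equal
bytes are distinct nodes — and add one edge per claim joining its ID1 and
ID2 values. The virtual patient identifier (vPID) of a claim is the
connected component containing its nodes.

The single structural assumption is that **ID1 and ID2 rarely change at the
same time with no claim in between**. Under it, any sequence of life events
leaves a chain of co-occurrences: a claim before and a claim after an
insurance change share the unchanged ID2 node, and vice versa. The
assumption fails for simultaneous changes (e.g. marriage plus job change in
one gap between claims), which split a patient into two components, and it
is *over*-connected by values shared across patients (twins sharing an ID1,
garbage claims sharing a sentinel ID2), which merge distinct patients into
one component. These two error directions are exactly what the two
evaluation scores separate.

Components are computed with a disjoint-set forest (union by size, path
compression), near-linear in the number of claims; the result is identical
to any other connected-components computation, which the test suite checks
against a breadth-first-search oracle (networkx) on randomized instances.

### Canonical vPID values

The vPID value of a component is its members rendered as `1:<value>` /
`2:<value>`, sorted lexicographically, joined with `|`. This makes the value
a pure function of the merged set — independent of claim order — and
decodable back into its members. The `:`/`|` characters are therefore
reserved and rejected in identifier values at validation (the simulator
emits hex values, which cannot contain them). An optional digest flag
replaces the canonical string with its SHA-256 prefix (32 hex chars) when
compactness matters; the partition is unchanged. Component labels use the
lexicographically smallest member rendering, so all outputs are
deterministic without any seed.

Claims with neither identifier cannot participate in linkage; they receive a
per-claim fallback value `0:<claim_id>` so claim counts are conserved
end-to-end, and they are reported in a skip log.

## Evaluation scores

Ground truth assigns each claim to an anonymized unique citizen number. For
an identifier under evaluation, only claims that carry the identifier *and*
have a resolved citizen are scored (excluded counts are reported). With
`V(u)` the set of identifier values over citizen `u`'s scored claims and
`U(v)` the set of citizens carrying value `v`:

- **traceability** = fraction of citizens with `|V(u)| = 1`, computed as
  `1 − m/n` where `m` is the number of multi-value citizens and `n` the
  number of citizens with at least one scored claim;
- **identifiability** = fraction of citizens with `|U(v)| = 1` for every
  `v ∈ V(u)`.

Both are patient-level and all-or-nothing: one stray claim or one shared
value disqualifies the whole citizen. This is deliberately stricter than
pairwise precision/recall and makes the two failure directions orthogonal.
The denominator is citizens with at least one scored claim — a citizen with
no claims has no identifier values to consolidate, so including them would
be meaningless. Two theorems follow when every scored claim carries both
identifiers, because the vPID label is a coarsening of both raw labels:
consolidation can only raise traceability and only lower identifiability,
and the vPID cardinality is bounded by the smaller raw cardinality. The
package computes `m` by two independent code paths (set-based counting and a
pandas groupby) and asserts the `1 − m/n` identity exactly.

### Ground-truth resolution

Enrollment-history records bind a citizen number to an (id1, id2) pair over
a validity period of calendar months. A claim resolves to citizen `u` iff
exactly one citizen has an era containing the claim's service month whose
id1 equals the claim's id1 **or** whose id2 equals the claim's id2. The
OR-match tolerates a clerical error in one identifier; requiring a unique
citizen keeps the truth conservative — ambiguous claims (e.g. a twin-shared
ID1 where the other identifier matches nothing) are reported as unresolved
rather than guessed. On simulated worlds without clerical errors and without
twins the join reproduces the simulator's own truth table exactly; twins are
inherently ambiguous under any identifier-based join, which is why the
simulator's truth table (which records the emitting citizen directly) is the
reference, not the join.

All timing is at calendar-month granularity (`YYYY-MM`): claims in these
systems are monthly statements and enrollment periods are reported in
months, so days are not modeled.

## The synthetic claims world

No real claims or enrollment data can be redistributed, so the simulator
provides the ground-truth-bearing worlds everything is validated on. Per
citizen per month, change events fire first (updating the citizen's
surrogate state and closing the current enrollment era), then a Poisson
number of claims is stamped with the current ID1/ID2. Identifier values are
SHA-1 prefixes (16 hex chars) of the surrogate fields — a standard digest
playing the role of the production hashing, with the avalanche property that
any field change yields an unrelated value. No personal data is modeled at
any point.

Mechanisms, with per-citizen-month (events) or per-claim (noise)
probabilities:

| knob | mechanism | effect on vPID |
|---|---|---|
| `p_id1_change` | insurer change reissues the insured token | none (bridged by ID2) |
| `p_id2_change` | name change | none (bridged by ID1) |
| `p_simultaneous` | both tokens change in one month, no claim between | splits a patient: traceability ↓ |
| `p_clerical_id1/2` | one claim carries a one-off wrong value | none (the claim still co-occurs with a true value) |
| `twin_fraction` | fraction of citizens in same-sex twin pairs sharing insured token, gender, birthdate | merges the pair: identifiability ↓ |
| `p_garbage` | claim's ID2 replaced by the shared blank-name/zero-birthdate sentinel | merges strangers: identifiability ↓ |

Clerical errors are transient (one claim) rather than persistent: they stand
for typos on individual documents; a persistent misspelling is
indistinguishable from a name change and can be modeled as one. Events start
from the second month so every citizen's first era is observable. Identical
configurations (including the seed) produce byte-identical worlds; all
randomness flows through one seeded numpy generator in a fixed iteration
order.

### Presets and calibration

`clean` switches every mechanism off — the baseline on which the
consolidated identifier is provably perfect. `simultaneous`, `twins` and
`garbage` each enable exactly one failure mechanism so its signature on the
two scores can be observed in isolation. `churn` enables only the benign
churn that consolidation is designed to bridge.

`mie_like` and `gifu_like` combine all mechanisms at rates calibrated so a
citizen accumulates on average ≈1.2 ID1 values and ≈1.5 ID2 values over
36 months — the churn regime of real prefecture-scale claims data — with a
simultaneous-change rate of order 10⁻⁴ per citizen-month (≈0.5% of citizens
affected over the period) and, in `gifu_like` only, a garbage rate that
visibly pollutes identifiability (≈2% of citizens touched by the sentinel
blob). Under these rates the raw identifiers trace only ~80%/~59% of
citizens while the consolidated identifier traces ≥99% and condenses the
identifier cardinalities close to the true citizen count. The exact rate
values are package defaults chosen once from these instance-count targets;
the real-world joint distribution of life-event rates is unknown.

Default world sizes are 10,000 citizens × 36 months for presets (the
acceptance script's size) and 400–2,000 citizens in most tests — large
enough for every mechanism to appear many times per world while keeping a
full run of the suite to a few minutes.

### What the simulator does not emulate

Demographic realism (age pyramids, family structure beyond twin pairs),
diagnosis/procedure content, expenditure, insurer heterogeneity, seasonal
claim intensity, and persistent clerical variants. Passing tests therefore
demonstrate the algorithmic properties of consolidation and scoring — the
direction and rough magnitude of each trade-off under stated churn rates —
not the exact score values of any particular real dataset, whose event rates
and error structure are unobserved.

## Known limitations

- Simultaneous ID1+ID2 changes are unlinkable by construction; affected
  patients split into multiple vPIDs.
- Values shared across patients (twins, garbage sentinels) merge patients;
  a single garbage value can chain many patients into one component. The
  package reports the damage (`n_shared_values`, identifiability) but does
  not attempt preprocessing heuristics or learned disambiguation.
- Consolidation is batch, not incremental: adding claims can only merge
  components (never split), but vPID *values* of grown components change,
  so values are not stable across dataset releases — compare partitions, not
  strings.
- Only homogeneous claim-to-claim linkage is treated; linking across
  differently anonymized databases is out of scope.
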