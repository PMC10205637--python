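# vpid — virtual patient identifiers for anonymized insurance claims

Administrative claims databases that strip personal identifiers often carry
*anonymized* patient identifiers instead: in Japan's national claims database
each claim holds **ID1** (a hash of the insured identifier + gender +
birthdate) and **ID2** (a hash of the name + gender + birthdate). Both churn
with life events — ID1 when a citizen changes insurers (job changes), ID2 on
name changes (marriage) and name typos — so neither identifier alone can
collect all of a patient's claims for a longitudinal analysis.

This package implements the **virtual patient identifier (vPID)**: treat
every distinct ID1 and ID2 value as a node of a bipartite co-occurrence
graph, join the two values appearing on each claim, and take connected
components. Because only one of the two identifiers usually changes at a
time, the surviving identifier bridges each change, and one component — one
vPID — collects a patient's claims across churn. The canonical vPID value of
a component is the sorted concatenation of its members
(`1:<id1>` / `2:<id2>` joined by `|`), computed with a union-find
(disjoint-set forest) in near-linear time.

The package is aimed at researchers working with claims-like linked data who
need to (a) run this consolidation, (b) quantify what it buys and costs, and
(c) study its failure modes without access to private claims data. It ships:

- `vpid.claims_model` — claim / enrollment-history / ground-truth types,
  delimited-file readers and writers, and the claims-to-enrollment join that
  produces ground truth;
- `vpid.linkage` — the co-occurrence graph, union-find consolidation,
  canonical vPID derivation, and merge histograms;
- `vpid.metrics` — patient-level linkage-quality scores against ground
  truth: **traceability** (fraction of citizens all of whose claims carry a
  single identifier value, `1 − m/n` with `m` multi-value citizens out of
  `n`) and **identifiability** (fraction of citizens none of whose values is
  shared with another citizen), plus cardinalities and per-citizen instance
  counts;
- `vpid.simulate` — a seeded synthetic claims-world generator with ground
  truth, modelling insurance changes, name changes, simultaneous changes,
  one-off clerical errors, same-sex twins sharing an ID1, and garbage claims
  carrying a shared sentinel ID2;
- `vpid.cli` — a `vpid` command with `simulate`, `link`, `evaluate` and
  `histogram` subcommands.

## Worked example

Simulate a churn-calibrated world of 2,000 citizens over 36 months, run the
consolidation, and score all three identifiers against the simulator's
ground truth:

```sh
vpid simulate --preset mie_like --n-citizens 2000 --out demo
vpid link demo/claims.csv --out demo/vpid_map.csv --members demo/members.csv
vpid evaluate demo/claims.csv --truth demo/truth.csv \
    --vpid-map demo/vpid_map.csv --out demo/report.json
```

which prints:

```
                                                ID1           ID2          vPID
Number of instances                            2410          3051          2009
Identifiability score                         0.998         1.000         0.998
Traceability score                            0.813         0.591         0.995
Average instances per insured citizen         1.206         1.526         1.006
Citizens scored                                2000          2000          2000
```

Read this column-wise: the raw identifiers distinguish patients almost
perfectly (identifiability ≈ 1) but fail to collect all claims for 19% (ID1)
and 41% (ID2) of citizens, because a citizen accumulates 1.2 ID1 values and
1.5 ID2 values on average over three years. The consolidated vPID collapses
those 2,410 + 3,051 values into 2,009 — close to the 2,000 true citizens —
and traces 99.5% of citizens, giving up only the rare simultaneous-change
cases (which nothing co-occurrence-based can bridge) and a little
identifiability to twins who share an ID1.

`vpid histogram demo/members.csv --kind id1 --out demo/hist_id1.csv` then
reports how many ID1 values each vPID merged (here 18.2% of vPIDs merged
more than one — exactly the patients a raw ID1 would have lost).

Every command writes a `*.manifest.json` with the resolved parameters and
SHA-256 digests of its inputs, so runs are auditable; identical seeds give
byte-identical data files.

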