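# c13referee

Automatic peer review of assigned ¹³C-NMR data.

Published carbon-NMR tables are riddled with a small set of recurring
mistakes: digit-drop typos (132.2 ppm printed as 32.2 ppm), swapped or
rotated signal assignments, the same peak list published twice under two
different structures, and outright wrong structure proposals.  `c13referee`
is a desk-scale referee that catches these errors automatically, the way a
database-backed verification service does during manuscript review:

1. the structure proposal (MDL MOL/SDF, V2000) is formally checked
   (valences, charges, unspecified stereocenters);
2. every carbon's environment is encoded as a canonical spherical
   environment string (a HOSE code): sphere 1 lists the direct neighbors,
   sphere 2 their neighbors, and so on;
3. each carbon's shift is predicted as the mean shift
   δ̂ = (1/n) Σᵢ δᵢ of the n reference carbons sharing its deepest
   matching environment code, with the per-prediction n, standard
   deviation and sphere reported;
4. experimental signals are paired with symmetry-equivalence classes —
   the published assignment where given, otherwise a minimum-total-|Δδ|
   bipartite matching — and each deviation Δδ = δ_exp − δ̂ is classified
   **green** (|Δδ| < 5 ppm), **yellow** (5–10 ppm) or **red** (> 10 ppm);
   the compound-level mean absolute deviation Δδ_C and a gross-error flag
   (any |Δδ| > 20 ppm) summarize the verdict;
5. identical-structure and identical-pattern searches catch duplicated
   data; peak-list dereplication ranks a candidate collection by the mean
   |Δδ| under optimal pairing;
6. a structure generator modifies the topology exclusively at flagged
   positions (substituent relocation/swap, double-bond shift, heteroatom
   exchange) and re-ranks all alternatives — a better-ranked alternative
   is an automatic revision proposal.

Because curated literature shift collections are proprietary, the package
ships a synthetic stand-in: deterministic structure families (n-alkanes,
substituted benzenes, chromones, fused scaffolds) whose shifts come from a
versioned additive increment model, plus an error injector that reproduces
each error class with ground truth retained.

## Worked example

Inject a digit-drop typo into the Br-bearing carbon of 3-bromoanisole
(123.26 ppm published as 23.26 ppm) and referee the submission:

```python
from c13referee import build_index
from c13referee.fixtures import ErrorInjection, inject_errors, make_reference_set
from c13referee.workflow import WorkflowConfig, run_workflow, render_report

db = make_reference_set("benzenes", 30, seed=7)
target = next(i for i, r in enumerate(db) if r.name == "3-bromoanisole")
(entry,) = inject_errors(db, [ErrorInjection("digit-drop", seed=3,
                                             params={"record": target})])
(report,) = run_workflow([(entry.molecule, entry.peaklist)], db,
                         config=WorkflowConfig(min_contributors=1))
print(render_report(report))
```

prints

```
Compound: 3-bromoanisole
Identifier: COc1cccc(Br)c1
MW: 187.04 amu
Verdict: INCONSISTENT

class  atoms          exp(ppm)  pred(ppm)  |diff|  color  provenance
    1  9                 49.02      49.11     0.1  green  [assigned]
    2  5                131.12     131.12     0.0  green  [assigned]
    ...
    6  1                 23.26     123.26    99.0  red    [assigned]

Mean |delta| (ppm): 14.30   max: 100.00   gross error: YES
```

The corrupted carbon is flagged red with the ~100 ppm deviation shown
capped at 99; the gross-error flag marks the compound for re-inspection.
(No topological revision can explain a 100 ppm typo, so the revision table
offers only worse-or-similar alternatives — the defect is in the data, not
the structure.)

The same pipeline is available from the shell:

```bash
c13referee fixtures --family benzenes --size 30 --seed 7 --out data/
c13referee verify --sdf sub.sdf --peaks sub.tsv --db data/benzenes.sdf
c13referee dup-scan --sdf sub.sdf --peaks sub.tsv --db data/benzenes.sdf --tolerance 0.1
c13referee revise --sdf sub.sdf --peaks sub.tsv --db data/benzenes.sdf --level yellow
c13referee run --sdf sub.sdf --peaks sub.tsv --db data/benzenes.sdf --out reports/
```

## Scope

The referee is constitution-only: stereocenters are reported, not used.
¹H data, DEPT/multiplicity checks, C–F coupling analysis and web-scale
predicted-spectrum databases are out of scope.  See `docs/methods.md` for
the model details, parameter defaults and known limitations.
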