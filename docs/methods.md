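# Methods

## Data model and conventions

Residue coordinates are 1-based and inclusive on both ends everywhere in
the public API; no half-open conversion occurs anywhere. A domain instance
is one classified unit, possibly discontinuous; discontinuity is encoded in
its residue-range string (`1-111,177-409`), never as duplicate table rows.
Whether two same-family regions are one interrupted domain or two repeats
is therefore delegated to the input encoding: segments belong to one
instance iff they share a row, and the detector never merges separate rows
of the same family. Family IDs are dot-separated integer hierarchies
(X-group . H-group . T-group . F-group); both 4- and 5-field dialects are
accepted, with the X/H/T prefixes always the first 1/2/3 fields, and IDs
ending `.0.0` marking topology-only assignments. Topology-only families
participate fully in detection and profiling; `--exclude-unassigned` drops
them from profiles. Chain prefixes in range strings are accepted, checked
for consistency, and stripped; multi-chain domains are rejected, as the
analysis is framed per polypeptide. Domains of one protein that overlap in
residue space are input errors, rejected at load time (whole protein, with
a named reason); rejected rows never abort a run unless `--strict` is set.

## Insertion detection

For every domain with ≥ 2 segments, gaps are the stretches strictly
between consecutive segments, `(prev.end + 1, next.start − 1)`; a gap
qualifies when its length is at least `min_gap` (default 30 residues,
inclusive — 30 is the smallest size at which an intervening region could
plausibly be a folded domain rather than a long linker). A candidate
insert is any other domain whose segments *all* lie within one qualifying
gap; a discontinuous domain spanning two different gaps is not an event,
and neither is a domain straddling a gap boundary. Each candidate is
assigned exclusively to the smallest containing gap, breaking ties by
smaller gap start and then host uid. (For disjoint domain sets an exact
tie is provably impossible — two gaps containing the same insert are
strictly nested and the inner one is at least two residues smaller — but
the deterministic rule costs nothing and guards against future input
relaxations.) Event depth is defined recursively on the host relation,
which is a forest by construction; a cycle raises an internal-consistency
error. Host length is always A1 + A2 combined, never counting gap
residues. Relative insertion position is the fraction of host residues
strictly before the gap start, bucketed into thirds with half-open
intervals [0, ⅓), [⅓, ⅔), [⅔, 1]. Prevalence is reported over multidomain
proteins only; with zero multidomain proteins it is reported as 0 with an
explicit undefined flag.

## Family-level aggregation

Each event contributes one host tally and one insert tally, so summed host
counts, summed insert counts and the event count all agree (double-entry
conservation, asserted in tests). Role categories over families with
≥ `min_events` (default 10) total events are mutually exclusive:
host-consistent (zero insert events), insertion-consistent (zero host
events), versatile (both), with the remainder "insufficient". Families are
counted once each regardless of role; the alternative role-instance count
is exposed in the run report as a secondary statistic. Partnership records
are directional (host, insert) — an A1-B-A2 event is inherently ordered —
and the cross-H-group fraction compares the two families' H-group
prefixes. The host-diversity spectrum classifies insert families with
≥ 10 insert events by distinct host H-groups: 1 = specialist,
≥ 11 = generalist. Rankings sort by the role's event count with
lexicographic family-ID tie-breaks for determinism.

## Statistics

*Wilcoxon signed-rank* (paired host/insert sizes): zero differences are
dropped before ranking (Wilcoxon's original treatment) and absolute
differences receive average ranks. For n ≤ 25 the two-sided p comes from
the exact null distribution of W⁺, computed by dynamic-programming
convolution over the (possibly half-integer) doubled ranks — this remains
exact in the presence of ties, which is why the test is implemented
in-package rather than delegated. For larger n the normal approximation is
used with continuity correction and the tie-robust variance
Var(W⁺) = Σrᵢ²/4. An all-zero difference vector flags the test undefined
rather than raising. Tests cross-check the exact path against explicit 2ⁿ
sign enumeration and against scipy on tie-free cases, and check
exact-vs-approximate agreement at the n = 25 boundary.

*Fisher's exact test* (scipy) provides two-sided p-values for 2×2 tables;
a zero margin gives p = 1. *BH false-discovery control* (scipy) supplies
monotone, permutation-consistent q-values. Both are validated against
independent enumeration/hand computation in the tests.

*Enrichment.* Architecture-level enrichment compares host-role and
insert-role instance counts per architecture label against all other
labels, with log₂OR = log₂(((a+½)(d+½))/((b+½)(c+½))) (Haldane–Anscombe
pseudocount; positive = host-enriched) and classification at |log₂OR| >
0.5. X-group insert enrichment compares insert-role instances per X-group
against a supplied background universe of classified domain instances with
the same pseudocounted odds ratio (positive = insert-enriched),
significance at BH FDR < 0.05, and a `min_count` background-representation
filter (default 10). The pseudocounted odds-ratio form is this package's
choice of log-odds definition; printed enrichment values from other
pipelines using an unspecified variant may differ slightly in magnitude.

*Positions and correlation.* Position fractions use the thirds convention
above and must sum to 1 when events exist. Spearman correlation uses
average ranks; constant inputs flag the coefficient undefined.

## Termini geometry

The termini distance of a domain is the Euclidean distance between the Cα
atoms of its first and last residues — for discontinuous domains, the
first residue of the first segment and the last residue of the last
segment (a generalisation chosen here; standalone continuous domains are
unaffected). Coordinates are read from PDB or mmCIF via gemmi, one Cα per
residue, altlocs resolved by highest occupancy then first-seen; a missing
terminal Cα skips the domain with a recorded reason. Role comparisons
(insert vs background, host vs background) use Mann–Whitney U with
rank-biserial r = 1 − 2U/(n₁n₂), oriented so that the focal sample being
stochastically *smaller* gives positive r. Comparisons run overall and
within 50-residue size bins (50–99 … 450–499, 500+, plus a `<50`
catch-all), with bins under 5 observations per side flagged underpowered —
the size-binned control separates the termini effect from the inserts-are-
smaller confound. The background sample is a seeded random draw from
domains participating in no event.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale. Defaults are fixed study conditions, not tuning knobs:

| parameter | default | rationale |
|---|---|---|
| `n_proteins` | 500 | desk-scale dataset; tests scale it 150–5000 |
| `n_families` | 60 | enough families for ≥10-event profiles at these sizes |
| role propensities | 0.12 / 0.12 / 0.50 / 0.26 (host-only / insert-only / versatile / never-insert) | echoes the observed dominance of versatile families among active ones, plus a never-insert reservoir |
| `p_multidomain` | 0.476 | multidomain fraction of classified representatives |
| `p_insertion` | 0.20 | insertion prevalence among multidomain proteins |
| `p_nest`, `max_depth` | 0.15, 6 | single-level events dominate; deep nests rare but reachable |
| `p_multi_insert` | 0.05 | occasional side-by-side inserts in one gap |
| host / insert length means | 241.2 / 133.4 aa | observed family-level role means; log-normal with family-level location effects |
| termini medians | 14.3 / 29.8 Å (insert / background) | observed insert vs background medians; hosts draw from the background distribution |
| `linker` | 2 aa | short inter-segment linkers |
| `ca_spacing` | 3.8 Å | canonical Cα–Cα distance |

Proteins are linear chains of domains; with probability `p_insertion` one
chain domain (host-capable family) is split at a uniform interior point
around an insert subtree (insert-capable family), recursing with `p_nest`.
A nested insert that itself hosts a deeper insert is drawn from versatile
families only, since hosting by an insert-only family would contradict its
generated role. Insert lengths are truncated at 30 residues so every
generated gap (insert span + two linkers) meets the default threshold;
configurations violating `min_insert_length + 2·linker ≥ min_gap` are
rejected before generation. The grammar guarantees well-formedness — no
overlaps, no straddling inserts, inner containing gaps always smallest —
so on generated data the detector must reproduce ground truth *exactly*,
and any disagreement is a detector bug. Deliberately nasty inputs
(boundary gaps of min_gap−1/min_gap/min_gap+1, near-tie nested gaps,
side-by-side inserts, discontinuous and straddling inserts) are
hand-constructed with hand-derived truth in the adversarial fixture set.

Toy Cα traces are per-domain: residues laid on a circular arc with exact
3.8 Å consecutive spacing whose end-to-end chord equals the drawn termini
distance (solved by bracketed root-finding, clamped to the reachable
range), followed by a random rigid placement. They emulate only what the
termini analysis measures — chain connectivity and termini separation —
and none of the real features of folds (secondary structure, packing,
excluded volume). Passing termini tests therefore demonstrates the
statistical machinery and the geometric bookkeeping, not any structural
realism.

## Numerical and design choices

* All randomness flows through `numpy.random.Generator` seeded from
  explicit config/CLI seeds; identical seeds give byte-identical outputs.
* Floats in emitted tables are written with 6 significant digits; p-values
  are never truncated for display.
* The event-table schema is frozen (column order stable) with two optional
  architecture-label columns appended so architecture enrichment can run
  from the table alone; gap indices are reassigned on read from per-host
  gap-start order.
* Problem sizes in the test suite (150–5,000 proteins, 300 random oracle
  architectures per property run) were chosen so that the full suite
  completes in well under a minute while leaving each statistical check
  comfortable sampling margins.

## Known limitations

* Detection consumes domain *assignments*; it cannot discover insertions
  from raw coordinates or sequence, and inherits any boundary errors in
  the input classification.
* Circular permutations, multi-chain domains and confidence filtering of
  predicted structures are out of scope.
* The X-group enrichment background is whatever universe the caller
  supplies; with event-participating domains included in the background
  the enrichment is conservative.
* Termini distances are measured on whichever coordinates are supplied per
  domain; measuring a domain inside its parent structure versus as a
  standalone model is the caller's modelling decision.
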