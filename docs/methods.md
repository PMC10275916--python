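# Methods

## The model

A genome-scale metabolic network reconstruction is represented as a
constraint-based model: a stoichiometric matrix **S** (metabolites ×
reactions), flux bounds lb ≤ v ≤ ub (mmol·gDW⁻¹·h⁻¹), a biomass
pseudo-reaction as growth objective, and boolean gene–protein–reaction
(GPR) rules linking genes to reactions (OR = isozymes, AND = complexes).
Steady state is assumed throughout: S·v = 0. Models are COBRApy objects,
so the package's own analyses and the wider COBRApy toolbox operate on the
same in-memory artifact, and everything serializes as SBML Level 3 + FBC
v2.

## Database curation

Reactions in the universal pool are screened by exact element accounting:
formulas are parsed with a flat `Symbol[count]` grammar (no parenthesized
groups — ModelSEED-style formulas are flat; anything outside the grammar
is *undetermined*, never an error). Pseudo-element symbols such as `R`
that fit the grammar are treated as ordinary symbols that must cancel
across the reaction, which conservatively catches dangling generic
groups. A reaction is removed only when it is demonstrably unbalanced —
a nonzero element delta with all formulas parseable, or (with charge
checking on, the default) a nonzero charge delta with all charges known.
Undetermined reactions are retained and flagged in the audit report:
discarding them would gut real databases, where many cofactors carry `R`
groups or lack curated charges. Charge checking can be disabled
(`check_charge=False`) for databases whose charge annotations are
unreliable. Exchange and biomass pseudo-reactions and identity transports
(the same compound moving between compartments) are exempt — they are
unbalanced by construction. Curation is idempotent, and the exactness of
the filter is exercised on fixtures where specific reactions were
perturbed by +1 on one stoichiometric coefficient.

## Draft evidence

Alignment hits are filtered at e-value ≤ 1e-10 and bitscore ≥ 50 by
default — the thresholds are explicit, logged and flag-overridable, since
reasonable pipelines differ — keeping the best hit per (query, subject)
pair (a keep-all flag exists). Genes mapping to the same reaction are
combined with OR; AND relationships cannot be inferred from hit tables
(they carry no subunit structure) and are never invented. Under a defined
medium the draft also receives each media metabolite's exchange reaction
and, when the evidence provides no transporter, one reversible e↔c
transport — the minimal plumbing that makes the stated uptake physically
possible; under the complete medium it receives every database exchange.

## Gap-filling

The gap-fill LP extends the draft with every absent database reaction and
minimizes Σ wᵣ(vᵣ⁺ + vᵣ⁻) subject to S·v = 0, bounds, and
v_biomass ≥ g_min, with wᵣ = 1 for candidates and wᵣ = 0 for draft
reactions. Setting the gene weight to zero isolates the candidate-selection
objective — flux through reactions with genetic evidence is free, so no
evidenced reaction is ever penalized out of use; a strictly parsimonious
variant (gene weight 1e-4) additionally discourages wasteful draft flux
and is exposed as a flag. Defaults: g_min = 0.01 flux units (a growth
demand makes the LP well-posed; the exact floor is a convention, exposed
as `--min_growth`), adoption cutoff 1e-6 (coupled to the LP tolerance —
anything smaller is numerical noise). Absolute values are linearized
exactly by the nonnegative forward/reverse variable split. Among alternate
optima the solver's vertex is accepted as-is; correctness claims (and the
test oracles) therefore compare objective values, not reaction identity,
wherever alternates could exist. Additions are cumulative: step 2 never
removes a step-1 reaction, even one that is flux-free under the user
medium — removal would amount to a second, different curation criterion.
Infeasibility at g_min even with the whole database is a hard error naming
the medium, not a silent empty answer.

The solver path is optlang/GLPK throughout the package. The test suite
and the acceptance script re-derive every gap-fill optimum by exhaustive
candidate-subset enumeration — each subset checked with a feasibility LP
and a flux-minimization LP built directly from the stoichiometric arrays
and solved with scipy's HiGHS — an independent route to the same number.

## Analyses

- **FBA**: maximize v_biomass; infeasibility surfaces as a status flag,
  never a silent zero.
- **pFBA**: minimize Σ|v| holding v_biomass ≥ fraction·z\* (default
  fraction 1.0), via COBRApy's implementation of the same forward/reverse
  split.
- **Essentiality**: per gene, reactions whose GPR evaluates inactive under
  the knockout are constrained to zero; essential ⇔ knockout optimum
  < 1% of wild type (the conventional threshold, exposed as a parameter).
- **Flux sampling**: seeded hit-and-run over {S·v = 0, lb ≤ v ≤ ub}.
  Directions are drawn in the null space of S, a uniform point is taken on
  each feasible chord, with a 100-step warm-up and thinning of 10. The
  contract is determinism (one integer seed, bitwise-reproducible output)
  and feasibility (|S·v| ≤ 1e-6 per sample); statistical uniformity over
  the polytope is *not* asserted and should not be assumed for inference
  about flux-space geometry.

All tolerances derive from one named constant (1e-6).

## Fixtures: what they emulate, and what they do not

The fixture generator builds a linear catabolic pathway (exchange →
gene-annotated transporter → 1:1 conversion chain → biomass) with
closed-form FBA optimum uptake × yield, surrounded by balanced decoys
(disconnected, so provably never part of a minimal completion),
seeded-unbalanced reactions, an exchange-less extracellular orphan,
optionally a short/long bypass pair, and optionally a biomass cofactor
whose 2-reaction import is flux-cheaper than its 3-reaction synthesis —
under the complete medium gap-filling imports it, and the minimal medium
then forces the synthesis chain, giving known disjoint per-step
completions. Default sizes: pathway length 4, 5 decoys, 2 unbalanced
reactions, uptake 10 mmol·gDW⁻¹·h⁻¹ (a standard glucose-scale rate),
unit yield. Enumeration-checked instances keep candidate pools at ≤ 12
reactions so exhaustive subset search stays exact and fast.

These are stoichiometric toys: they exercise the algorithms' correctness
(LP optimality, exact curation, essentiality logic, determinism), not
their behavior on realistic biochemistry. Passing tests demonstrate that
the machinery computes what it claims on networks with known answers; they
say nothing about annotation quality, namespace coverage or biomass
realism on real genomes, which depend entirely on the database and mapping
files a user supplies.

## Degenerate inputs and edge behavior

Empty evidence yields a warning and a biomass+media-only draft (gap-filling
then reconstructs a full route from exchanges to biomass). A fully
determined flux space (all chords degenerate) makes the sampler return the
single feasible point n times. Malformed hit rows are skipped and counted;
an entirely unparseable hit table, a database whose curation leaves no
reactions, an SBML file without an objective, and a Type 1 input without an
external aligner on PATH are hard errors with instructive messages.

## Known limitations

- Gap-filled reactions carry no GPR by construction; they are hypotheses,
  flagged via `source=gapfilled` and per-step notes for audit.
- The gap-filler optimizes against one medium per step; simultaneous
  multi-media gap-filling is out of scope.
- Set-cardinality (MILP) gap-filling is deliberately not implemented; the
  method's premise is that flux parsimony, not reaction count, is the
  right objective.
- The Type 1 (FASTA) path only orchestrates an external aligner; without
  one, users supply hit tables directly.
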