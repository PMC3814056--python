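# Methods

This note documents the models and procedures implemented in `tisnet`, the
parameters that matter, the numerical choices, what the synthetic benchmarks
do and do not emulate, and the design decisions taken where the workflow
left genuine freedom.

## Constraint-based model and LP analyses

A metabolic model is a stoichiometric matrix S (metabolites × reactions),
finite flux bounds l ≤ v ≤ u (mmol·gDW⁻¹·h⁻¹ by convention; ±1000 denotes
"unconstrained"), a biomass objective reaction, and per-reaction GPR rules
(boolean AND/OR expressions over gene ids; AND = obligate complex, OR =
isozymes).  Steady state is S v = 0.  Exchange reactions are identified
structurally as single-metabolite boundary reactions; negative exchange flux
is uptake.

All analyses are linear programs solved with scipy's HiGHS backend:

- **FBA** maximizes biomass flux.  Infeasible or unbounded problems are
  reported as such in the result status, never as silent zeros.
- **FVA** minimizes and maximizes each reaction flux, optionally adding
  cᵀv ≥ fraction × (FBA optimum).  The default fraction for every analysis
  in this package is 0 (the whole bounded flux cone), so that knockout
  effects on secretion/uptake capacity are not masked by growth coupling;
  a `fraction` argument (and `--fraction` flag) exposes the
  growth-constrained reading.
- **Linear MOMA** minimizes the L1 distance Σ|vᵢ − v_wt,i| to a wild-type
  flux distribution subject to the knockout model's constraints, via split
  auxiliary variables dᵢ ≥ |vᵢ − v_wt,i|.  Only the linear variant is
  implemented; the reported growth is the biomass flux at the optimum (the
  distance is unique, the flux vector need not be).
- **Gene deletion** applies a knockout by evaluating each reaction's GPR
  with the deleted genes set false and zeroing the bounds of failed
  reactions, then evaluates growth by FBA or MOMA.  Verdicts: *lethal* if
  growth ratio ≤ 1e−3, *reduced* if < 0.95, else *nonlethal*.  Both
  thresholds are configurable; the defaults separate "numerically zero"
  from "meaningfully below wild type" on models whose wild-type growth is
  O(10).
- **Flux spans**: fᵢ = |v_max,i − v_min,i| per condition, ratio
  rᵢ = f_ko,i / f_wt,i.  Classes: type I (r > 2), type II (0 < r < 0.5),
  type III (f_ko = 0 < f_wt), otherwise *unchanged*.  When f_wt = 0 the
  ratio is undefined: f_ko = 0 is reported as r = 1 / *unchanged*, and
  f_ko > 0 as class *novel* with a missing ratio, rather than dividing by
  zero.

Numerics: LP feasibility tolerance is HiGHS's default (≤1e−9); fluxes with
magnitude < 1e−9 are clipped to exactly 0; a reaction counts as able to
carry flux if it reaches magnitude ≥ 1e−6.  Reported FBA solutions satisfy
S v = 0 within 1e−6 and bounds within 1e−9 (asserted in tests).

## Evidence integration and core sets

Protein evidence rows are (gene, cell type, IHC signal, summary score).  A
gene is protein-active if any cell type shows a positive IHC stain (weak,
moderate, strong) or a non-"none" summary score; cell types are pooled with
OR because the tissue is represented by several cell types jointly.
Transcript matrices are averaged within replicate groups; the activity
threshold is the 10th percentile (linear interpolation on the pooled
averaged values), and boundary values are kept.  Genes with transcript
evidence but no protein evidence must pass the same filter in an
independent validation dataset or are discarded.

Core sets are derived by GPR evaluation: CH contains reactions whose rule
is satisfiable using protein-supported genes alone, plus the biomass
objective; CM contains reactions satisfiable only with the weaker
(validated-transcript) evidence included.  Reactions with empty GPRs —
exchanges, spontaneous transport — join neither set and are free to prune;
the extraction step re-keeps the ones the core needs for mass balance.
This protein→CH / transcript-only→CM mapping mirrors the two-tier evidence
hierarchy; it is a package design choice (the tiers could be weighted
differently) and is therefore explicit and configurable at the call site.

## Tissue-model extraction

One pruning scan visits all non-CH reactions in a seed-determined random
permutation.  For candidate r, let B be {r} plus the reactions newly blocked
by removing r.  The removal is rolled back if (a) the biomass optimum falls
below 1e−6, (b) B contains a CH reaction, or (c) |B ∩ CM| >
eps_w · |B \ (CH ∪ CM)| with eps_w = 0.5 — i.e. pruning may sacrifice at
most one moderately-supported reaction per two unsupported ones it
eliminates.  Accepted removals delete all of B.

`mba_extract` aggregates n_runs scans (default 1000; analyses and tests in
this repository use 10–50, which is sufficient for the synthetic networks'
size) into inclusion frequencies.  The final reaction set is CH plus all
reactions with frequency ≥ 0.5; if biomass is infeasible, leftover reactions
are added back in descending frequency until it is, and any still-blocked
non-core reactions are then trimmed (removing a blocked reaction cannot
change the flux cone, so one pass suffices).  Final consistency deliberately
outranks frequency.  Sub-seeds are derived from the master seed by a
counter-based SeedSequence scheme, so runs are independent and the whole
extraction is reproducible bit for bit.

Blocked-reaction detection uses witness reuse: every optimal flux vector
certifies all reactions in its support as unblocked, and cached witnesses
whose support avoids the removed set carry over between candidate removals.
This reduces the per-scan LP count by roughly an order of magnitude without
changing any result.

## Biomarker prediction

For each disorder gene, wild-type and knockout FVA intervals of every
exchange reaction are compared.  The call is *elevated* if both endpoints
move up (beyond tol = 1e−6), *reduced* if both move down, *unchanged*
otherwise — including ambiguous widenings, which are deliberately not
called.  Currency metabolites (h, h2o, o2, co2, co, pi, ppi, nh4, na1, k,
cl, so4, hco3, fe2, fe3; configurable, compartment suffixes stripped before
matching) are excluded because ubiquitous species are useless as clinical
markers.  Disorders with several genes are evaluated per gene; a
disorder-level union view and distribution summaries (per-disorder
biomarker counts with cumulative fractions, and groups of disorders sharing
an identical metabolite/direction pattern) are also produced.  A gene whose
knockout leaves no feasible flux state is reported with a flag rather than
with fabricated intervals.

## Comparison, enrichment, DEG profiles, target search

Two models are compared by pair-different genes: genes present in exactly
one of them.  The gene–reaction topology is summarized by the bipartite
degree histogram and the least-squares slope of log(count) vs log(degree) —
a quick power-law check; maximum-likelihood exponent fitting is out of
scope.  Enrichment of a gene set against an annotation table uses the
upper-tail hypergeometric probability P(X ≥ k) with parameters (N, K, n)
and Benjamini–Hochberg adjustment across all tested terms (enriched iff
q < 0.01 by default).  The annotation is taken as given — no ontology-DAG
propagation.  DEG profiling knocks out each mapped gene (up- and
down-regulated alike; a bound-scaling mode is deliberately not the default)
and tallies type I/II/III reactions from the span-ratio profile.  The
target search ranks genes by the fraction of reactions whose alteration
class matches a reference gene's knockout profile; the fraction-of-matches
metric makes scores symmetric and equal to 1 exactly for identical
profiles.

## Synthetic benchmarks

The generator builds a "generic" network of linear core pathways from one
substrate exchange to a biomass precursor, plus decoy pathways that branch
off core intermediates and drain through their own exchanges.  Because
decoys only ever *consume* core metabolites, removing them can never block
the core — the extraction target provably exists.  Internal reactions get
fresh genes combined into AND/OR rules (1–2 genes by default).  Both the
generic and the planted models are verified flux-consistent and
biomass-feasible at generation time, and every planted biomarker direction
is verified with the package's own FVA-shift oracle before it enters the
ground truth.

Evidence tables mark exactly the planted genes at zero noise: protein rows
are positive for planted genes, the two expression datasets report planted
genes at high signal (200–1000) over a 3:1 background of low-signal
(1–10) filler genes that the 10th-percentile filter removes, and each
dataset has its own background probe set (emulating different array
platforms), so a background gene detected in one is never confirmed by the
other.  A false-negative rate demotes planted genes to transcript-only
evidence (exercising the validation path); a false-positive rate promotes
decoy genes to protein evidence.  Decoy genes are emitted as unprobed in
the transcript matrices: an empirical-percentile filter cannot exclude a
large block of uniformly low rows, and the generator's contract is that
zero noise recovers exactly the planted genes.

What the benchmarks do **not** emulate: realistic biochemistry
(metabolite identities, compartments beyond labels, cofactor coupling),
genome-scale size (presets cap at a few hundred reactions), correlated
probe-level noise, or literature-curated cores.  Passing them shows the
algorithms are implemented correctly, not that a particular real tissue
model is right.

Scale choices: recovery benchmarks use networks of ~60 reactions with
~25% decoy reactions (12 core paths of length 3–4, 6 decoy paths), 20
generator seeds and 50 scans per extraction — large enough that aggregation
matters, small enough for interactive runs.

## Pipeline

`run_pipeline` sequences evidence → core sets → extraction → essentiality
(FBA and MOMA) → biomarkers → comparison/enrichment → DEG profiles from one
validated YAML config; every paper-gap parameter (core-set rule inputs,
eps_w, FVA fraction, lethality thresholds, currency list, enrichment alpha)
surfaces there with the defaults stated above.  Outputs contain no
timestamps, so identical config + seed give byte-identical artifacts; the
manifest records versions, seeds, parameters and per-stage tallies.

## Known limitations

- Quadratic MOMA, parsimonious FBA, loopless FVA and flux sampling are not
  implemented.
- The SBML reader targets Level 3 + FBC v2 (with a notes-field fallback for
  gene associations and subsystems); legacy Level 2 quirks are out of scope.
- Compartments are carried as labels only; collapsing or localizing
  metabolites across compartments is left to the user.
- The extraction aggregation rule (frequency threshold + consistency
  rescue/trim) is one defensible choice among several (intersection, union,
  iterative re-scanning); it is isolated behind `mba_extract`'s parameters.
- Enrichment treats annotations as flat; genes outside the supplied
  universe are ignored.
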