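# Methods

This note documents the models, conventions and design choices behind
`microprot`, in the order the pipeline applies them.

## Spectral-count quantification

The quantification basis is the peptide-spectrum match (PSM) count per
protein after 1 % FDR protein inference; the pipeline consumes the
downstream table format (sample, peptide, candidate proteins, count) and
is agnostic to the search engine that produced it.

**Razor assignment.** The inference chain that produces these tables
resolves shared peptides to a single "razor" protein; the published
descriptions leave the exact rule open, so this package uses a greedy
majority-evidence rule chosen for determinism: unique-peptide counts are
tallied first, then shared rows are processed in input order and each
row's full count is assigned to the candidate with the largest
accumulated evidence (unique plus previously assigned shared), ties
broken by lexicographically smallest protein id. Total counts are
conserved exactly — an invariant the tests check against a brute-force
re-implementation. Contaminant entries (ids prefixed `contam_`) are
dropped before assignment, mirroring the convention of appending a
contaminant database to the search and then analysing only the
organism's proteome.

**Length normalization.** The quantification value is
q_p = razor-PSM_p / L_p (PSMs per residue), with L_p counting every
residue including ambiguous ones. Longer proteins generate more
detectable peptides, so dividing by length makes q_p proportional to
molar abundance under the simulator's sampling model, and component
*shares* of Σq additionally cancel any global scale (scale invariance is
a tested property). Proteins with zero assigned PSMs are omitted rather
than zero-filled, the usual spectral-counting convention; this avoids
spurious zeros propagating into ratios downstream.

## GO cellular-component collapse

The reference is the union of is_a/part_of descendant closures (root
included) of three roots: cellular anatomical entity (GO:0110165),
protein-containing complex (GO:0032991) and ribosome (GO:0005840).
Traversal uses only is_a and part_of edges; regulates-type relations are
ignored. Obsolete terms are skipped at parse time and a cycle over the
traversed relations is a hard error.

Per protein, the procedure is:

1. expand the CC annotations to ancestors-plus-self;
2. intersect with the reference;
3. if at least two matches remain and one is an ancestor of another,
   keep only the more specific term — interpreting the requirement that
   retained terms have no ontology relations among each other as
   "keep the deepest term of each lineage", which is deterministic and
   idempotent;
4. collapse each survivor: descendants of GO:0005840 → *ribosome*;
   other descendants of GO:0032991 → *protein containing complexes*;
   terms whose name contains "membrane" (case-insensitive) →
   *membrane*; anything else keeps its own term name. When step 2 finds
   no match at all, the expanded set itself is labelled by the same
   rules (this is where the membrane name-grouping mostly acts).

Choices worth flagging: unrelated reference matches that both survive
step 3 are all kept (the procedure can return several labels per
protein); a multi-label protein contributes its full q_p to each of its
labels, since summed "intensities of each term" admit no apportioning
rule; and the reference uses full descendant closures, with a
direct-children-only mode available behind a flag
(`ReferenceSet.build(..., direct_children_only=True)`).

Allocation sums q_p per label, reports the top 3 labels (lexicographic
tie-break), and the annotated fraction — the quant-weighted proportion
of proteins carrying at least one CC label. Annotation ids missing from
the ontology are skipped with a warning (the offline analogue of a
failed lookup); only a protein whose ids are all unknown is an error.

## Amino-acid profiles

raw_a = Σ_p q_p · count_{p,a} over the requested protein subset.
Two normalizations are provided: **count mode** (mol fraction,
raw_a/Σraw) and **mass mode** (g AA/g protein), which weights raw_a by
the average residue mass (monomer minus water) before normalizing. Mass
mode is the default because the reporting unit of interest for
nutrition is g AA/g protein; count mode is kept for sensitivity
analysis since the underlying product-of-quant-and-count formula is
count-based. The residue-mass table is a documented package constant
(Gly 57.0519, Ala 71.0788, … Trp 186.2132 Da).

Ambiguity handling: B, Z, U and X count toward protein length but are
excluded from composition vectors — length normalization stays faithful
without inventing amino-acid assignments. Initial Met is retained (no
N-terminal processing model), and fixed-modification chemistry such as
cysteine carbamidomethylation does not alter counts. Tryptophan is
retained even though the classical hydrolysate reference method destroys
it; bottom-up spectral counting is not hydrolysis-limited.

The relative-difference statistic is Δ_a = (f_{a,c} − f_{a,ribo}) /
f_{a,ribo} × 100 %, with amino acids of zero ribosomal fraction reported
as missing rather than infinite. The nutritional focus set is the 15
essential plus conditionally essential amino acids for humans (Arg, Cys,
Gln, Gly, His, Ile, Leu, Lys, Met, Phe, Pro, Thr, Trp, Tyr, Val),
restricted without renormalization by default.

## Growth, substrates and correlation analysis

**Observed growth rate.** μ_i = ln(OD_{i+1}/OD_i)/(t_{i+1}−t_i),
assigned to the interval midpoint, optionally 3-point smoothed. The
consecutive-pair estimator (rather than a whole-phase regression) was
chosen because composition is correlated against *time-resolved* growth
rate, requiring a per-sample value. It is exact on pure exponentials for
any sampling grid. Productivity is ΔCDW/Δt on the same midpoints.
Midpoint estimates are joined to composition samples by nearest time
within a 1 h tolerance — half of a typical 2 h sampling interval.

**COD.** Organic compounds are aggregated as chemical oxygen demand,
COD = Σ c_j·f_j, with factors from the oxygen-demand balance
C_cH_hO_oN_n + (c + h/4 − o/2 − 3n/4) O₂ → c CO₂ + … (nitrogen stays
reduced). Nominal integer atomic masses are used, matching the
stoichiometric convention of the COD literature (fructose: exactly
192/180 gCOD/g). Electron equivalents follow 1 eeq = 8 gCOD.

**Phase classification.** "Substrate limitation" is defined
conceptually — a substrate concentration that restricts the growth
rate — so the operational rule here is declared package policy: a point
is *limiting* when the residual limiting substrate has fallen to ≤10 %
of its initial value AND μ is below 90 % of the run's maximum, else
*abundant*; under dual limitation either substrate may trigger. Both
parameters are surfaced in the API and recorded with the output.

**Correlograms.** Pairwise Spearman ρ with mid-rank ties; two-sided
p-values via the t approximation t = ρ√((n−2)/(1−ρ²)); pairwise-complete
deletion for missing values (observables are measured on different
schedules); significance at α = 0.05 per pair with *no* multiplicity
correction — a 5 % significance level is the stated convention, and a
Benjamini–Hochberg option is available behind a flag. Constant variables
yield an undefined ρ with a warning. Strata: all data, substrate-
abundant, substrate-limiting, and per limitation type. The
implementation is rank-then-Pearson written directly, which lets
`scipy.stats.spearmanr` serve as an independent oracle in the tests.

**Linear fits.** Ordinary least squares with the textbook t-based
pointwise confidence band for the mean response (half-width
t·s·√(1/n + (x₀−x̄)²/Sxx)), minimal at x̄ and zero-width on exact lines;
coverage is verified by simulation in the tests.

## Flow cytometry

Channels follow the acquisition layout of a blue/red-laser instrument:
SYBR Green (and BODIPY) on BL1 (height and area), propidium iodide on
BL3, SYTO 62 on RL1.

**Singlets** are kept when the BL1-A/BL1-H ratio, normalized by the
population median ratio, lies in [0.7, 1.3]. The bounds are package
defaults (no published values exist for this step): wide enough for
lognormal acquisition noise on singlets, narrow enough to reject the
canonical doublet signature (summed area, maximum height + 10 % →
ratio ≈ 1.8). Doublets formed by two very unequal cells can still
mimic singlets — a real limitation of area/height gating that the
synthetic generator reproduces (~10 % of lognormal doublet pairs pass).

**Concentrations** are qualifying events (singlet-gated, stain-positive
on BL1) divided by the recorded volume (default 0.075 mL, i.e. 75 µL)
times the dilution factor. The SGPI panel splits qualifying events at
the PI threshold into intact (BL3 ≤ threshold) and damaged, with
intact + damaged = total holding exactly by construction.

**PHA/neutral-lipid gating** is a triple threshold applied in order —
low SSC-H, SYTO 62 (RL1) to select nucleic-acid-containing cells, then
a minor BODIPY (BL1) threshold — with per-stage retained counts logged.
The gate is monotone in every threshold (a tested property). Threshold
values are explicit parameters; an auto-threshold at the minimum-density
valley between the two largest KDE modes is provided for mixtures with
clear bimodality.

**Intensity summaries** are medians over gated events, reported in
arbitrary units under the documented assumption that stain intensity is
linear in content (nucleic acid for SYTO 62, PHA/neutral lipid for
BODIPY). Medians are robust to the heavy right tails of fluorescence
distributions and scale linearly, preserving the proxy interpretation.

## Synthetic-data generator

The generator produces every input with known ground truth. What it
emulates, and the defaults:

- **Allocation growth law.** φ_ribo(μ) = φ0 + k·μ with φ0 = 0.10 and
  k = 0.50 h. Over the simulated range μ ∈ [0.05, 0.35] h⁻¹ this puts
  the ribosomal share at 12.5–27.5 %, inside the band reported for
  fast-growing heterotrophs. The linear form is a stand-in: the
  functional link between allocation and rate is not specified by the
  study design this emulates, and only monotonicity is relied on. The
  non-ribosomal remainder is split in fixed proportions (cytoplasm 0.22,
  membrane 0.24, protein complexes 0.06, unannotated 0.48 of 1−φ),
  placing the annotated fraction near 60 %.
- **Proteome.** 40 proteins per component by default (tests use 20),
  lognormal lengths (median 250 residues, σ_log 0.3, minimum 50),
  residues drawn i.i.d. from per-component weight vectors: ribosomal
  proteins 1.6× enriched in Arg/Lys/Met/Val, cytoplasmic and membrane
  proteins 1.3× in Cys/Leu/Phe/Thr/Trp/Tyr — the documented direction of
  contrast between ribosomal and metabolic proteins. A toy CC ontology
  (11 terms, the three reference roots with ≥2 levels of is_a/part_of
  descendants) and one leaf annotation per annotated protein accompany
  the FASTA; "unannotated" proteins get no term.
- **PSM tables.** Expected counts are budget · s_p·L_p / Σ s_q·L_q with
  per-protein abundance s_p = share(component)/n_component, so length
  normalization is the exact inverse and shares are recovered to
  machine precision with noise off. The default budget is 50,000 PSMs
  per sample; Poisson sampling gives integer counts (the noise-off mode
  emits the exact, generally non-integer expectations — the one place
  the integer-count invariant of real tables is deliberately relaxed).
  A configurable fraction (default 10 %) of proteins donate a shared
  peptide carved as 20 % of their count, paired with a same-component
  partner holding at most 40 % of the donor's expectation, so razor
  evidence resolves the share back to the donor noise-free and
  misassignment under Poisson noise is component-neutral.
- **Batch growth.** Dual-Monod kinetics, μ = μmax·min(C/(K_C+C),
  N/(K_N+N)), with μmax 0.35 h⁻¹, K_C 0.02 gCOD/L, K_N 5·10⁻⁴ gN/L
  (ammonium affinity is high), yields 0.40 gCDW/gCOD and 8.0 gCDW/gN,
  C₀ 2.133 gCOD/L (2 g/L fructose) and X₀ 0.05 gCDW/L — a small
  fructose-fed batch. Initial nitrogen is set per scenario: 2× the
  carbon-matched amount (carbon limitation), 0.5× (nitrogen), exactly
  matched (dual). Integration is fixed-step RK4 (dt = 0.01 h, verified
  by step-halving to <0.1 % endpoint change) with non-negativity
  clipping; observations default to every 2 h up to 16 h. The
  ground-truth phase label is *abundant* while every limiting substrate
  exceeds 10× its half-saturation constant, i.e. while growth sits on
  the Monod plateau.
- **Composition observables.** Linear rules in μ: nucleic-acid signal
  40 + 300·μ A.U. (rising), protein 0.65 − 0.50·μ g/gCDW (falling),
  carbohydrate 0.05 + 0.20·μ, cell size 1.0 + 1.5·μ µm, neutral lipid
  20 + 60·μ A.U.; PHA signal jumps by +120 A.U. in the limiting phase
  of nitrogen-containing limitations (storage accumulation needs spare
  carbon). Multiplicative lognormal noise at 5 % CV per observable by
  default, mean-corrected so E[noisy] equals the truth.
- **Event tables.** 20,000 events per panel, lognormal channels;
  SGPI mixes intact/damaged at 25 % damaged (PI high vs low on BL3),
  the BODIPY panel mixes PHA-positive/negative at 30 % positive
  (well-separated BL1 modes), all with a SYTO 62-bright RL1 signal.
  Doublets (2 % default) sum area channels and take max height + 10 %.
  Metadata records 0.075 mL volume and dilution 1.

All randomness flows through `numpy` Generators seeded from the single
config seed plus a per-operation tag, so identical seed + config gives
byte-identical files and the operations are order-independent.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no peptide-level detectability or
ionization-efficiency bias (real spectral counts are not Poisson around
a length-proportional mean); i.i.d. residue sampling instead of real
sequence structure; a toy ontology instead of real GO breadth and
multi-annotation; noise that is independent across observables and
time, unlike drifting instruments; no spectral overlap or compensation
in cytometry; and a literal growth law where real allocation data are
scattered. Estimator correctness and internal consistency transfer to
real inputs; effect sizes and error rates do not.

## Problem sizes and runtime choices

The test and acceptance workloads are sized for quick, deterministic
runs on one CPU: proteomes of 100 proteins (5 components × 20), PSM
budgets of 50,000 with 20 Poisson replicates over a 7-point μ grid,
50 random DAGs of up to 500 terms for the closure oracle, 1,000 random
razor tables, 100 seeded batch simulations for the correlation-sign
check, and 20,000-event cytometry tables over 20 seeds. The whole suite
runs in well under a minute.

## Known limitations

- The razor rule is order-dependent for shared rows by design
  (deterministic given the table), which matches no specific published
  implementation; totals are conserved under any order.
- Multi-label proteins double-count quantification across labels, so
  label sums can exceed the annotated total; shares over single-label
  proteins remain additive.
- The observed-growth-rate estimator is noisy at low OD and near
  substrate depletion, where the interval mean deviates from the
  midpoint instantaneous rate; the 2 %-accuracy guarantee holds on the
  Monod plateau.
- KDE valley auto-thresholding requires clear bimodality and fails
  loudly otherwise; thresholds remain explicit parameters.
- Cell size enters as a provided covariate; no optical size estimation
  is attempted.
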