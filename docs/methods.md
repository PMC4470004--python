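# Methods

## Model and simulation semantics

A `MolecularModel` is a bipartite place/transition net. Species (places)
carry non-negative token concentrations and are typed gene, mRNA, protein,
miRNA, complex, compound, pseudo-object or siRNA; reactions (transitions)
are typed by biochemical process and reference reactants (consumed),
products (produced), enzymes (rate factors, never consumed) and inhibitor
annotations.

The speed of reaction *i* at step *t* is the mass-action product

    S = k · Π [reactant] · Π [enzyme] · Π (iKd / [I]) / eKd

with these conventions, pinned so the engine and its independent test
oracle agree bit-for-bit:

* absent enzymes contribute a factor of 1;
* an inhibitor whose concentration is 0 (or unresolvable) contributes a
  factor of 1, i.e. inhibition switches off smoothly with the dose;
* each inhibitor contributes the single factor `iKd/[I]` (one
  multiplication), and eKd divides once at the end; eKd is treated as 1
  when absent so the law degenerates to plain mass action;
* concentrations must be non-negative; a negative value aborts the run as
  an internal invariant violation.

One time step sweeps all reactions in lexicographic id order with
sequential in-place updates (reaction *i* sees reaction *i−1*'s effect).
This makes the result order-dependent, which is why the order is pinned:
two loads of the same model always simulate identically. A reaction fires
only when

    min [product] < min [reactant]   and   S < 0.75 · min [reactant]

For multi-reactant reactions both guard clauses use the limiting
(minimum-concentration) species; with one reactant this degenerates to the
single-species rule. For pure-source reactions (no consumed reactants,
e.g. transcription from a gene template) the guard driver is the limiting
enzyme: a transcript pool can then never exceed its gene's expression
level. Because firing subtracts S < 0.75·min[reactant] from every
reactant, concentrations can never go negative; in closed transfer subnets
token mass is conserved to float rounding.

Genes are transcription *templates* (listed under enzymes, not
reactants): gene species carry expression levels that must drive flux
continuously rather than be consumed.

**Steady state.** A run is steady at the first step t ≥ 5 with
|C_j,t − C_j,t−5| ≤ 0.001 for every species *j* (window and tolerance
configurable). The absolute value is used deliberately: a signed test
would only catch increases and miss slowly oscillating decline. A net with
nothing to fire is steady at exactly t = 5, the first step the lagged
comparison exists. Runs that exhaust `max_steps` (default 10 000) are
flagged `reached_steady = False`, never raised; downstream consumers use
the final state with a warning.

The steady criterion is an *absolute* flux threshold, and this is load
bearing for treatment effects: slowing a pathway's flux below the
tolerance ends accumulation earlier, so hallmark levels track flux rather
than only their eventual fixed point.

## Flux Comparative Analysis and scoring

FCA simulates the same initialized model twice: untreated, and with the
drug's inhibitor annotations applied (`apply_treatment` adds an inhibitor
entry with the target's iKd and the administered concentration to every
reaction whose enzyme list matches a drug target; matching is
case-insensitive on species id or display name with a phospho "P-" prefix
stripped; species, topology and kinetic parameters never change). Both
runs share every numeric setting, so a drug that matches nothing yields a
bit-identical trajectory and P = 1 exactly.

Per hallmark readout (a pseudo-object species, e.g. `proliferation`):

    P = readout level at treatment steady state / readout level at control steady state

P is undefined (flagged) when the control readout is 0. Both the steady
token count and the cumulative incident inflow of a readout are exposed
(`readout_value` / `readout_flux`); fold changes use the token count. The
model-based sensitivity score is `log10(P) + K`, K = 5.2 by default;
base 10 keeps the score commensurate with GI50's −log10 mol/L scale.
P < 1 classifies a responder; the boundary P = 1 (treatment changed
nothing) is pinned to non-responder for determinism.

The administered drug concentration is a free scalar in token units
(default 1.0) because clinically meaningful dosing does not translate into
token units; dose–response behavior (P non-increasing in [I]) is the
meaningful, tested property.

**Statistics.** Per-treatment agreement between model scores and
experimental scores uses Pearson r with the t-based two-sided p.
Aggregation over treatments uses the within-subject (Bland–Altman)
correlation: both variables are centered per treatment, pooled and
correlated, which removes per-treatment offsets — the tested invariance.
The difference between two aggregate correlations (same samples scored two
ways) is assessed by a seeded bootstrap over samples with a two-sided
percentile p-value, since no analytic test applies cleanly to pooled
within-treatment correlations. Group discrimination uses the rank
(Mann–Whitney) AUC with ties counting ½.

## The miR-add-on

The extension walks the model's gene array; a gene participates when its
id keys the miRT table *and* the model contains the gene's transcript
(identified as the mRNA-kind product of a transcription reaction the gene
drives) — binding needs a target mRNA, so genes without one are skipped
with a warning. Per new mature miRNA it creates a miRNA gene (nucleus), a
nuclear miRNA, a TF-regulated transcription reaction and a translocation
to the cytoplasm; per (miRNA, target-mRNA) pair a miRNA-binding reaction
(cytoplasmic miRNA + mRNA → silenced complex) and a decay of that complex.
Design choices:

* **One shared mature-miRNA pool per miRNA id.** Targets compete for a
  common pool — the biologically meaningful titration behavior — instead
  of per-target miRNA copies.
* **Silencing = sequestration + degradation.** The complex is never
  translated; its decay destroys the bound transcript (and turns the
  miRNA over with it), making silencing a *sustained* drain on the target
  mRNA. A strictly terminal complex was rejected: under the product guard
  it eventually blocks its own binding reaction, so steady-state silencing
  would be exactly zero.
* **TF signs.** Activating TFs (present in the model) join the
  transcription reaction as enzymes; repressing TFs become inhibitor
  annotations with a default iKd of 1 token unit, reusing the standard
  inhibition law rather than introducing negative rates.
* **Deterministic ids** (`miRgene:<mir>`, `miR:<mir>:nuc`,
  `miR:<mir>:cyt`, `cx:<mir>:<mRNA-id>`) make the extension reproducible
  byte-for-byte and idempotent: re-running on its own output adds
  nothing. miRNA ids are canonicalized (lower-case, `hsa-` stripped) to
  bridge the mixed `mir-223`/`miR-21` styles of curated tables.

### Kinetic defaults of created reactions

Published token-model kinetics are empirical and unprinted, so the
extension uses a configurable default k = 0.01 with clearance scaled
relative to production: translocation and target binding run at 2k and
the silenced complex decays at a fast absolute 0.5/step. The scaling is
not cosmetic: each downstream pool must equilibrate *strictly below* its
firing guard (nuclear miRNA below its gene, cytoplasmic miRNA below the
nuclear pool, complex below both binding substrates). A pool whose
equilibrium sits at or above its guard "hovers" — fires, overshoots,
blocks, refills — with an oscillation amplitude of one per-step flux
quantum, which typically exceeds the steady tolerance and prevents
convergence. The same reasoning gives TF-driven transcription an
enzymatic dissociation constant of 25 token units per activating TF
(sub-saturation): without it a TF at tens of tokens multiplies the speed
past the downstream clearance.

## Expression input

TMM normalization: per library, the scale factor is the precision-weighted
mean of per-feature log2 ratios (M) against a reference library after
double trimming — 30 % of M and 5 % of absolute intensity (A) from each
tail, features with a zero in either library excluded; weights are the
delta-method variances of M. The reference defaults to the library whose
upper-quartile count fraction is closest to the mean. Reported factors
are rescaled to geometric mean 1 (the conventional presentation); the
normalized matrix is counts per million of the effective library size
using each sample's *pairwise-to-reference* factor, so one sample's
normalized values never depend on an unrelated library's depth (rescaling
one library then changes only its own column).

Initialization is a total reset: every concentration is set to 0, then
gene species matched by Ensembl id receive their expression value and
miRNA-gene species matched by miRNA id likewise; unmatched ids on either
side are counted and logged, never fatal. Expression values are used
directly as token concentrations — no transform is applied because none
is defined for this model family; all concentrations are therefore only
meaningful relative to each other.

## Synthetic study generator

The generator emulates the *shape* of a real study — a curated signaling
model plus per-individual expression — not its content. The toy model is
a star of per-gene cascades gene → mRNA → protein (→ phospho-protein)
feeding a single `proliferation` pseudo-object:

* one **kinase** gene (the planted drug target) whose protein catalyzes
  all phosphorylations;
* **pathway** genes whose proteins reach the hallmark only through that
  phosphorylation (drug-sensitive route);
* **background** genes whose proteins activate the hallmark directly
  (drug-insensitive route);
* every protein also decays, and the hallmark decays quickly (0.5/step).

The two structural points that make treatment effects well-posed: the
protein decay *competes* with phosphorylation, so inhibiting the kinase
re-routes pathway tokens into decay instead of the hallmark (in a pure
chain, all tokens reach the hallmark at equilibrium regardless of speed,
and P would be 1); and the hallmark's fast decay makes its steady level
proportional to incoming flux, the quantity treatment perturbs. Cascade
constants (k_tx = 0.005, k_tl = 0.01, k_ph = 5·10⁻⁴, k_act = 0.005,
protein decay 0.02) keep per-step transfers small against pool sizes
(quasi-continuous dynamics) and every equilibrium strictly below its
firing guard, per the hover argument above; fixture extensions use
k = 0.002 for the same reason. Typical cohort simulations converge in
1 000–2 000 steps.

Cohorts plant responder structure: responders carry pathway/kinase gene
expression multiplied by `effect_size` (default 4) and
hallmark-repressing miRNA expression divided by it; all values get
multiplicative log-normal noise (sd 0.25 on the log scale — expression is
non-negative and right-skewed). Base levels are 10 (genes) and 8
(miRNAs) token units. With `effect_size = 1` the two groups are
exchangeable by construction, giving the null calibration. The generated
miRNAs always target pathway genes, so lowering them in responders
reinforces the drug-sensitive route. The planted drug binds the kinase
protein with iKd 0.1 nM, i.e. a 10-fold speed reduction at the default
administered concentration of 1 token unit.

What passing tests on these fixtures do **not** show: real transcriptome
scale (tens of genes, not thousands), realistic pathway crosstalk,
measurement error structure of RNA-seq, or clinical response labels —
separation results demonstrate that the machinery recovers structure it
can represent, not clinical accuracy.

## Numerical and policy choices

* Reaction order: lexicographic by id, sorted at load/extension time.
* Float formatting in XML: `repr` round-trip literals; serialization is
  canonical (sorted species/readouts, pinned reaction order), so
  write→read→write is a byte-level fixed point.
* The firing-rule oracle in the test suite is an independently written
  dict-based simulator; equivalence is asserted bit-for-bit, which pins
  the floating-point evaluation order above.
* P = 1 tie → non-responder; log base 10 in the score; steady test uses
  |Δ|. Each is an explicit determinism choice documented at the API.
* Degenerate inputs: zero-variance correlation inputs are flagged
  undefined rather than silently NaN; single-class AUC raises; a
  single-sample TMM warns and returns factor 1; treatments with fewer
  than 3 score pairs are skipped with a warning.

## Known limitations

* The discrete sequential-update semantics is not an ODE or stochastic
  (Gillespie) approximation; results are exactly reproducible but depend
  on the pinned reaction order and on concentration scales through the
  firing guards.
* Guard-boundary hovering can keep a model from formally reaching steady
  state; the engine reports this honestly (`reached_steady = False`) and
  the fixture kinetics are chosen to avoid it, but arbitrary user models
  may trigger it.
* Drug treatment is a single multiplicative factor per matched reaction —
  no PK/PD, no dose–time course; combinations beyond multiplicative
  inhibitor factors are out of scope.
* The miRNA extension models neither microprocessor steps (DROSHA/DGCR8)
  nor explicit RISC components, and partial translational repression is
  collapsed into full sequestration of the bound transcript.
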