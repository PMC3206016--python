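# Methods

This note documents the models implemented in `pdzlinker`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
data generators do and do not emulate.

## The additive pairwise scoring model

A PDZ domain is represented by a *profile*: its residues at a fixed set of
alignment columns (16 by default). A C-terminal peptide is represented by
its last five residues, positions p0 (C-terminal) to p-4. The model is a set
of *position pairs* `(d, o)` — domain profile position `d` coupled with
peptide offset `o ∈ {0, …, −4}` — and a *sub-score table*
`s(k, a, b)` giving the contribution of domain amino acid `a` meeting
peptide amino acid `b` at pair `k`. The prediction score is the plain sum of
the sub-scores over all pairs; a pair of sequences is classified as
interacting when the score reaches the cutoff, 0.5, inclusively. The
boundary is inclusive because 0.5 is described as the value *sufficient* for
a hit.

Assumptions baked into this model: contributions are additive and
independent across position pairs; residues upstream of p-4 and domain
residues outside the modelled positions carry no information; an alignment
gap at a modelled domain position contributes exactly 0 (consistent with the
treatment of never-observed combinations). Only binary (hit / no-hit)
operation is implemented; no affinity-weighted variant.

### Training

Sub-scores are estimated as pseudocounted log-odds of occurrence in
positives versus negatives:

    s(k, a, b) = log2[ (c⁺ + q)/(N⁺ + 400 q) ] − log2[ (c⁻ + q)/(N⁻ + 400 q) ]

with `q = 1` (Laplace), counts `c±` of the combination in each class and
per-pair class totals `N±`. Combinations observed fewer than
`min_observations` (default 1) times stay absent from the table and read as
exactly 0.0 — neutral. This estimator reproduces the positive / neutral /
negative semantics of the published sub-scores and the zero-for-unseen rule;
the exact Bayesian estimator used upstream of the original predictor is not
public, so absolute sub-score values from retraining are not expected to
match any distributed table, only their structure and sign semantics.
Defaults: pseudocount 1.0 (the minimal smoothing that keeps every log
finite), log base 2 (bit-scaled scores), `min_observations` 1 (the table
stores exactly what was observed).

### The default position-pair model

The published model couples 16 domain positions with 5 peptide positions
through 38 position pairs chosen from a single reference complex. The
concrete reference structure is not distributed with this package, so the
default pair model is derived by the package's own contact rule
(minimal-atom distance ≤ 5 Å) from a **synthetic** reference complex
(`simulate.reference_complex()`): 16 domain residues making 38 planted
sub-5-Å contacts across the p0..p-4 window, with p0 and p-2 touching the
most positions, as in real PDZ pockets. Deriving instead from a real
PDZ-peptide PDB file is a one-liner
(`derive_position_pair_model(read_complex(path, "A", "B"))`), and the pair
model is overridable everywhere.

## Benchmarking

Predictions are evaluated against three-way test data: positives,
motif-bearing negatives (experimentally established non-interactions whose
peptide still looks like a PDZ ligand — the hard class) and motif-less
negatives (motif disrupted — the easy class). Metrics are pair-level:
sensitivity `100·TP/(TP+FN)`, and FPR `100·FP/(FP+TN)` separately per
negative class, since conflating the two hides the informative hard-class
error. A metric whose denominator is zero is reported as absent, not as 0.
Stratification by training-ortholog membership takes an explicit id list;
orthology is a curation decision, not something this package infers.
Percentages are displayed to one decimal; raw counts are kept alongside.
Duplicate (domain, peptide) records with conflicting labels are rejected;
identical duplicates produce a warning.

## Proteome screening and the p0 filter

Because unseen combinations score 0, a proteome-wide scan accepts many
C-termini whose terminal residue never occurs in known PDZ ligands (training
pools contain essentially only V, L, I, F, C, A at p0). The screen therefore
reports per-domain hit counts both raw and after a p0 filter that keeps only
termini ending in {C, Y, F, L, I, M, V, W, A} — the residues observed at p0
in natural or artificial PDZ-binding peptides. Score histograms bin hits by
their score rounded half-even to two decimals (the rounded value is the bin
key; no fixed edges). Best-domain assignment credits, per protein, every
domain tied at the maximal score — the only order-independent reading of
"scored highest". Proteins shorter than five residues or with non-standard
residues in the terminal window are skipped and logged, never silently
scored.

## Contact selection from complex structures

Three residue-residue distance measures are implemented: Cα–Cα; mass-weighted
centroid distance over heavy atoms (hydrogens are absent from most crystal
structures, and an unweighted centroid would over-weight peripheral atoms);
and minimal atom distance over all atom pairs. Within one complex, the
distance of a residue pair is the arithmetic mean over all models (NMR
ensemble members or crystal copies supplied as models). A pair is a
*consensus* contact for a domain when its per-complex mean is at or below
the threshold **in every complex** of that domain. The underlying published
rule is grammatically ambiguous between this reading and a grand mean over
all complexes; the strict per-complex reading is the default and the grand
mean is available via `pooled=True`.

Residue correspondence across complexes uses author numbering by default,
with an optional per-complex map (e.g. alignment columns) for
heterogeneously numbered ensembles. Threshold sweeps evaluate Jaccard
similarity between the selected domain-residue set and a reference set over
a 0–40 Å grid in 0.5 Å steps (the published range; the step is a choice
balancing resolution against cost), for all three metrics; ties break toward
the smaller threshold, then the metric order (min_atom, c_alpha,
center_of_mass) — prefer the stricter, cheaper-to-interpret rule.

Deriving a position-pair model from a reference complex maps contacts to
(profile position, peptide offset) pairs; contacts to peptide residues
upstream of p-4 are reported separately and excluded from the model, since
the scoring window ends at p-4 (such upstream contacts are exactly the
structural argument for why the five-residue window is incomplete).

## Steady-state SPR analysis

Equilibrium responses are the mean of the sensorgram over a five-second
window at equilibrium (double referencing of raw sensorgrams is assumed done
upstream by instrument software). The titration is fitted with the 1:1
Langmuir isotherm `Req(C) = Rmax·C/(Kd+C)` by unweighted least squares over
the *total* analyte concentration — no ligand-depletion correction, matching
how steady-state SPR titrations are normally analysed. Initial values are
`Rmax₀ = max(Req)`, `Kd₀ = median(C>0)`; both parameters are bounded
positive. A fit is flagged unreliable when `Kd > Cmax` (the top injected
concentration bounds the weakest measurable interaction) or when the
fractional Kd standard error exceeds 50% — a numeric stand-in for the
qualitative "high χ², likely inaccurate" judgement; flagged fits keep their
values but should only be used for relative ranking.

Req is directly proportional to analyte molecular weight and to the amount
of immobilised ligand, so cross-surface comparison divides both out against
a reference surface `(MW_ref, level_ref)` supplied in config (default: the
first construct/surface). The proportionality constant itself is not
determined, so normalised values are defined up to the reference convention;
relative rankings are unaffected. Duplicate measurements (e.g. the
systematically duplicated 10 µM injections) are combined by arithmetic mean
before normalisation.

Score–signal association uses Pearson r over the pairs present in both
mappings, with a two-sided t-test p-value. The r computation uses the
unit-vector identity `r = 1 − |u−v|²/2` (sign-adjusted), which is stable
near |r| = 1 and returns exactly ±1.0 for (anti-)identical inputs; it agrees
with the textbook formula to ~1e-15 elsewhere.

## Synthetic data: what it emulates, what it does not

The generators plant a known truth behind every input so that recovery can
be scored exactly. Fixed choices (made once, for stated reasons):

* **Planted sub-score tables** are zero-inflated: two thirds of the
  combinations neutral (real trained tables had values for roughly one third
  of the 15 200-parameter space), the rest N(0, 0.5) — the scale of decisive
  single-position contributions (a single p-2 threonine contribution of 0.64
  can exceed the 0.5 cutoff alone).
* **Decision threshold** 0.5, the predictor's operating cutoff, so planted
  labels and classified hits live on the same scale.
* **Peptides** draw p0 from {V, L, I, F, C, A} with weight 0.9, mirroring
  training pools of confirmed binders; all other positions, and domain
  profiles, are uniform over the 20-letter alphabet.
* **Synthetic complexes** place peptide residues 20 Å apart with
  single-atom residues by default; each planted contact is realised exactly
  (within float32 coordinate precision), unlisted residue pairs are ≥ 20 Å
  apart, and options add multi-atom residues, displaced Cα atoms and decoy
  atoms to exercise the minimal-atom search.
* **Titrations** use nine concentrations spanning 0.12–30 µM with
  multiplicative Gaussian noise (default 3%), the design of the measured
  titration series.

What passing tests on these data do **not** show: real domain profiles are
phylogenetically correlated, not uniform; real training matrices are sparse
and biased rather than complete rectangles; real proteome C-termini have
strongly non-uniform composition; real complexes have side-chain packing,
not planted point contacts; real SPR noise has systematic (drift, bulk)
components. Conclusions about absolute predictive performance on biological
data cannot be drawn from the synthetic recovery rates.

### A note on sub-score recovery

On the 200 × 200 planted matrix with 5% label noise, the pseudocounted
log-odds estimator recovers the planted table only partially (Spearman ≈
0.4 over all observed combinations, ≈ 0.7 over combinations with
non-neutral planted values, sign agreement ≈ 76%, as recomputed by
`scripts/acceptance.py`). This is a property of the estimation problem, not
a bug: within one domain row, all 200 labels share the same profile, so the
37 other position pairs act as correlated — not independent — background,
and the effective sample size per (pair, amino acid, amino acid)
combination is far below the nominal count. Recovery improves with more
domains/peptides per combination and with sparser planted tables; sign
agreement is reported over combinations with non-neutral planted values,
since a planted value of exactly zero has no sign a continuous estimate
could match. The same limitation applies a fortiori to tables trained on
real interaction matrices of this size.

## Numerical and degenerate-input choices

* Scores and sub-score sums are IEEE double sums in fixed pair order; the
  vectorised generator accumulates in the same order, so recorded true
  scores equal scalar scores bit for bit.
* Score histogram keys round half-even (banker's rounding) on the decimal
  representation, avoiding float-binning artefacts like 0.515 → 0.52 vs 0.51
  depending on representation.
* Alternate locations in PDB files resolve to the highest-occupancy
  conformer; ties fall to the first encountered.
* The amino-acid alphabet is strictly the standard 20 letters; X/U/B are
  rejected at parse time (sub-score tables are indexed by this alphabet),
  and screens skip — with a logged warning — proteins whose terminal window
  contains anything else.
* Isotherm fitting requires at least three distinct non-zero concentrations;
  correlation requires at least three shared pairs and a non-constant input.
* An empty class in synthetic training data (e.g. a threshold below every
  planted score) raises a generation error rather than returning a
  degenerate dataset.

## Problem sizes

Default validation sizes were chosen so the full suite and the acceptance
script each run in seconds on one CPU: 50 × 100 pairs for the planted
separation check, 200 × 200 for sub-score recovery, 100 replicate
titrations for Kd recovery, 1000 random triples for the scoring oracle and
50 random residue pairs for the distance oracle. All sizes are plain
function arguments and scale up without code changes.

## Known limitations

* The default position-pair model comes from a synthetic reference complex;
  scores under it are structurally plausible but not comparable to scores
  from any distributed trained model.
* Absolute benchmark numbers on published test datasets require those
  datasets and the distributed trained table as inputs; the package ships
  the machinery, not the third-party data.
* No affinity-mode training, no ROC/AUC sweeps over cutoffs, no mmCIF
  input, no kinetic (on/off-rate) SPR analysis, and no homology modelling.
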