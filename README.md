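# pdzlinker

Prediction and evaluation of interactions between PDZ domains and the
C-termini of their partner proteins.

PDZ domains are ~90-residue protein-interaction modules that recognise short
linear motifs at the extreme C-terminus of target proteins (position p0 is
the terminal residue, p-1 the one upstream, and so on). `pdzlinker`
implements, as a tested and reusable library plus CLI, the computational
workflow needed to apply and scrutinise an additive pairwise interaction
predictor for such motifs:

* **Scoring model** — a (domain, peptide) pair is scored as the sum of
  sub-scores over a set of *position pairs* (by default 38 pairs coupling 16
  alignment-derived domain positions with peptide positions p0..p-4):

  `S(domain, peptide) = Σ_k  s_k( domain_residue(d_k), peptide_residue(o_k) )`

  Sub-scores are trained from labelled interaction / non-interaction data as
  pseudocounted log-odds; amino-acid combinations never seen in training
  contribute exactly 0 (neutral). A pair is called a hit when `S >= 0.5`.
* **Benchmarking** — sensitivity `100·TP/(TP+FN)` over positives and a false
  positive rate `100·FP/(FP+TN)` per negative class (motif-bearing and
  motif-less non-interactions), with stratification by training-ortholog
  membership.
* **Proteome screening** — every C-terminus of a proteome scored against
  every domain profile, with an additional p0 filter (accept only C-termini
  ending in C, Y, F, L, I, M, V, W or A), score histograms, best-domain
  assignment and promiscuity counts.
* **Structure contacts** — selection of peptide-contacting domain residues
  from PDZ-peptide complex structures under three distance measures (Cα,
  centre of mass, minimal atom distance), consensus across complexes and
  NMR models, threshold sweeps against a reference selection, and derivation
  of the default position-pair model from a reference complex.
* **Steady-state SPR** — equilibrium-window averaging, 1:1 Langmuir isotherm
  fits `Req(C) = Rmax·C/(Kd + C)` with reliability flags, molecular-weight /
  surface normalisation of Req, heat-map assembly and Pearson correlation of
  prediction scores with measured signals.
* **Synthetic data** — generators with planted ground truth for every input
  above (interaction matrices, proteomes, complexes, titrations), so the
  entire pipeline is exercisable offline.

## Worked example

Train a model on a synthetic interaction matrix with a planted generating
model, then score a C-terminal peptide:

```python
from pdzlinker import simulate as sim
from pdzlinker.model import PairwiseInteractionModel, PDZProfile

pair_model = sim.reference_pair_model()          # 38 pairs over 16 positions
planted = sim.PlantedModel(
    sim.plant_subscore_table(pair_model, seed=1), pair_model, label_noise=0.05
)
data = sim.simulate_training_data(planted, n_domains=50, n_peptides=100, seed=2)
profiles = {k: PDZProfile(k, v) for k, v in data.profiles.items()}
results = PairwiseInteractionModel(
    data.positives, data.negatives, profiles, pair_model
).fit()
print(results.summary())
res = results.score("SYND0000-1/1", "VMRLQSETSV")
print(f"{res.pdz_id}  {res.peptide[-5:]}  score={res.score:.3f}  hit={res.is_hit}")
```

which prints

```
Pairwise PDZ-peptide interaction model
==========================================
position pairs:        38
parameter space:       15200
trained sub-scores:    13091  (86.1% of space)
training positives:    1900
training negatives:    3100
decision cutoff:       0.5 (inclusive)
pseudocount:           1.0
log base:              2.0
largest |sub-scores|:
  pair 19 (domain pos 7, peptide p0): C/V = -4.752
  pair 24 (domain pos 9, peptide p-2): I/G = +4.065
  pair 28 (domain pos 11, peptide p-2): N/W = -4.038
  pair 11 (domain pos 4, peptide p0): T/L = +3.975
  pair 24 (domain pos 9, peptide p-2): Q/R = +3.928

SYND0000-1/1  SETSV  score=-16.985  hit=False
```

The summary reports the size of the model (38 position pairs, 20×20×38 =
15 200 trainable sub-scores), how much of that space the training data
actually covered, and the strongest learned contributions. The scored pair
sums its 38 sub-scores over the last five peptide residues only (`SETSV`
here); a score below the 0.5 cutoff is a predicted non-interaction.

The same operations are available from the shell:

```bash
pdzlinker simulate training --seed 3 --out simdata/
pdzlinker train --positives simdata/positives.tsv --negatives simdata/negatives.tsv \
    --profiles simdata/profiles.tsv --pair-model pairs.json --out table.tsv
pdzlinker screen --proteome proteome.fasta --profiles profiles.tsv \
    --pair-model pairs.json --table table.tsv --out hits.tsv
pdzlinker spr-fit titrations.tsv
```

## Layout

```
src/pdzlinker/
  io.py        # datasets, FASTA, PDB complexes
  model.py     # profiles, position pairs, sub-scores, training, scoring
  benchmark.py # sensitivity / FPR, stratification
  screen.py    # proteome-wide scans, p0 filter, histograms
  contacts.py  # residue distances, consensus contacts, threshold sweeps
  spr.py       # isotherm fits, normalisation, correlation, heat maps
  simulate.py  # synthetic-data generators with planted truth
  cli.py       # `pdzlinker` command group
docs/methods.md  # models, assumptions, parameter choices, limitations
```
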