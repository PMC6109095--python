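# Methods

This note documents the models, conventions and numerical choices behind
`navvar`, and what its synthetic-data experiments do and do not demonstrate.

## Protein topology

Nav1.5 (SCN5A isoform 1, 2016 residues) is modelled as an ordered list of
regions that tile positions 1..2016 exactly: N-terminus, four homologous
domains of six transmembrane segments (S1–S6) with their five intra-domain
loops each, three cytoplasmic inter-domain linkers (L12, L23, L34), and the
C-terminus. S4 of each domain is flagged voltage-sensing; the S5–S6 loop
("pore" linker) folds back into the membrane and is annotated extracellular.
Default boundaries follow public NCBI/UniProt-style annotation of the
channel and ship as an editable TSV (`data/scn5a_topology.tsv`) validated at
load (tiling, 4×6 segment census, three inter-domain linkers). Published
sources do not agree to the residue on segment boundaries, so the config is
explicitly a replaceable data asset: all downstream code reads only the
loaded topology.

Distances are residue counts along the chain, never spatial: the distance
from a position to a region class is 0 inside a matching region and
otherwise the count to the nearest boundary residue of the nearest matching
instance (adjacent residue = 1). Positions are 1-based inclusive on the
isoform-1 numbering; variants reported on isoform-2 (Q1077del) numbering are
shifted (+1 at positions ≥ 1077) at ingest.

## Missense enumeration

Each codon has nine single-nucleotide neighbours. Those encoding a different
residue — excluding stop-gains and synonymous changes, under the standard
nuclear genetic code — are the reachable missense substitutions. Two totals
are tracked: with duplicates (distinct nucleotide events) and unique
(distinct (position, target) pairs). All codons are treated as mutable,
including the first and last. Expected transition frequencies are the
with-duplicates counts normalised to sum to one; observed/expected ratios
divide observed transition proportions by these, with cells of zero expected
mass flagged as NaN rather than inflated. Internal stop codons in a supplied
CDS warn and are skipped, so toy fixtures need not be biologically complete.

## Amino-acid properties

Seven scalar tables ship as data: average residue mass (Da), percentage of
buried occurrences, van der Waals volume (Å³), polarity ranking (Grantham's
scale), net charge at physiological pH (D,E = −1; K,R = +1; H = 0),
hydropathy (Kyte–Doolittle) and α-helix propensity (Chou–Fasman). All
substitution deltas use the fixed sign convention new − old. The Grantham
matrix is generated from its defining formula — the weighted Euclidean
combination of side-chain composition, polarity and molecular volume with
weights 1.833, 0.1018 and 0.000399, mean-scaled to 100 — frozen as an
integer TSV and spot-checked against canonical published entries. The
Gonnet-250 log-odds matrix is taken from Biopython's substitution-matrix
collection. Data files are SHA-256 checksummed at load.

## Conservedness

The score of a reference position is the mean, over non-reference alignment
rows, of the Gonnet-250 score between the reference residue and the row's
residue in that column; a gap contributes a fixed penalty of one less than
the smallest matrix entry, so a gap always scores below any substitution.
This is one reasonable instantiation of "conservedness under a Gonnet-250
alignment"; the column score is deliberately pluggable (matrix and gap
penalty are arguments). Alignment construction is out of scope: the module
consumes aligned FASTA or Clustal files. No sequence weighting is applied.

## EP-report resolution

Each report records, per outcome (zero current, activation, inactivation
including recovery, late component), one of measured-and-affected,
measured-and-unaffected, or not-measured, plus experimental metadata and
optional midpoint shifts in mV. Resolution rules:

- **Majority vote** per outcome over measured reports only; equal non-zero
  counts exclude the variant from that problem (counted in an exclusion
  fraction); no measured report leaves the label unknown.
- **Changed/unchanged** is the disjunction: affected if any outcome is
  affected; a tie on any outcome (with nothing affected) excludes;
  unaffected requires at least one measured, unaffected outcome.
- **Preferred report** for quantitative data: filter to β₁-co-expressing
  recordings, then α-subunit 'b', then HEK cells — each filter applied only
  if it leaves at least one report — then the most recent year, with a final
  deterministic tie-break on study identifier.
- **Shift discretisation**: (−∞, −3) mV → neg, [−3, 3] → mid, (3, ∞) → pos,
  with the boundaries themselves in the middle bin.

## Classification protocol

Datasets are split 66.7%/33.3% stratified by label (stratification is a
package choice: these are small, imbalanced datasets). Hyperparameters are
chosen by stratified 10-fold cross-validation on the training split only,
maximising pooled out-of-fold MCC; folds reduce with a warning when the
smallest class is too small. The tuned model is refit on the full training
split and evaluated once on the untouched test split.

Metrics are implemented in-house and oracle-tested: binary MCC with the
return-0 convention for zero denominators, the Gorodkin multiclass
generalisation for three-bin problems, ROC area as the Mann–Whitney rank
statistic with half credit for ties (macro one-vs-rest averaging in the
multiclass case), and information gain in bits with Fayyad–Irani MDL
binning for numeric features (a feature with no accepted cut has one bin,
hence zero gain). The Zero-R baseline predicts the training majority class
(ties break to the lexicographically smallest label): its accuracy is the
majority prevalence, its AUC 0.5 and its MCC 0 by construction.

Classifier families delegate to scikit-learn, except Naive Bayes, which is
an in-house mixed implementation: categorical attributes get
Laplace-smoothed multinomial likelihoods (modelled natively rather than
one-hot encoded) and numeric attributes per-class Gaussians with a pooled
variance floor. Grids are deliberately small (documented in
`model.DEFAULT_GRIDS`, overridable per fit); the random-forest grid includes
class-weighted and shallow all-features variants because the tuning
objective is MCC on imbalanced data.

## Synthetic data generator

The generator emulates the statistical structure of the curated EP
literature: 243 variants with EP data, a 72%/28% changed/unchanged split,
74/243 variants with more than one report, 58% of multi-report variants
conflicting, and per-outcome missingness. Defaults derive from the
database's published category counts: truth base rates 0.123 (zero
current), 0.41 (activation), 0.65 (inactivation), 0.34 (late) with
measurement rates 1.0/0.80/0.90/0.55 reproduce the reported per-outcome
affected counts at n = 243.

Outcomes follow a per-outcome logistic model: logit of the base rate plus
log odds-multipliers for the position's region classes. A single global
intercept shift is calibrated by bisection so the *expected*
changed/unchanged fraction equals `p_changed` under any effect map, keeping
the headline imbalance a config-honoured invariant. Zero-current variants
have no measurable gating, so their other outcomes are not measured.
Default region effects encode the qualitative structure–function pattern of
the real data (zero current enriched in the pore loops; activation in S4
and the inter-domain linkers; inactivation in S4, S6, the linkers and the
C-terminus; late component in the C-terminus and linkers), with mild
position-sampling weights (S4 and L34 enriched). Metadata fields (cell
type, α-subunit, β₁) are sampled independently from marginals ordered as in
the real database; a joint distribution is not modelled. Conflicts flip one
measured gating outcome in one extra report of a multi-report variant;
midpoint shifts draw |N(10, 5)| mV with random sign for affected outcomes
and N(0, 1.5) for unaffected ones.

The reference coding sequence is synthetic (seeded random stop-free
codons), as is the homolog alignment used for conservedness in synthetic
runs; both are labelled synthetic in code. What passing tests on generated
data show is that the pipeline recovers structure *of the kind planted* —
region-driven odds, config-level marginals — at realistic sample sizes.
They do not show that real EP outcomes follow a logistic region model, nor
do they reproduce the literature's ascertainment biases (compatibility with
life, clinical reporting), which the generator deliberately omits.

## Recovery experiment

`recovery_experiment` runs the full pipeline (generate → resolve →
featurize → tune → evaluate) over replicate seeds and reports, per seed,
the CV-selected best method's test MCC and whether region type ranks in the
information-gain top 3. The strong-signal configuration applies activation
odds ×8 to the voltage-sensing segments *and* the inter-domain linkers —
mirroring the observed activation pattern, where S4 is the main contributor
and the domain linkers nearly as prone — so that the affected-region mass
(~1/3 of residues) makes recovery statistically meaningful at 243 variants.
The null configuration sets all multipliers to 1.

An honest caveat on sampling noise: the activation dataset at 243 variants
has ~165 usable rows, so the held-out test third has n ≈ 55 and any test
MCC carries a standard error near 1/√55 ≈ 0.13. Single-seed test MCCs
therefore scatter widely around the planted effect (the median across seeds
is the stable summary), and even under the null a sizeable minority of
seeds show |MCC| > 0.15. This is a property of the study conditions, not of
the implementation: an oracle classifier knowing the true effect regions
shows the same test-split scatter.

## Known limitations

- Region boundaries are annotation-approximate; swap in alternative
  configs for sensitivity analyses.
- The conservedness column score is an interpretation (mean pairwise
  Gonnet-250 vs. the reference); other column statistics are reasonable.
- The curated EP literature database is not redistributable, so all
  end-to-end numbers in tests and the acceptance script are computed on
  synthetic data or on the database's published category counts; headline
  classification metrics of the real data are not reproduced here.
- Nucleotide-level mutation biases (transition/transversion, CpG) are out
  of scope; expected transition frequencies assume unbiased changes.
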