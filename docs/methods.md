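# Methods

## The prediction problem

A liquid–liquid phase separation (LLPS) experiment combines one protein
and one RNA at given concentrations in a buffer with given salts, pH,
and temperature, and records the outcome morphology: *solute* (no
separation), *liquid*, *gel*, or *solid* condensates.  The package
models two questions over such per-experiment records:

* **Behavior**: will a given (protein, RNA, conditions) triple form
  liquid condensates?  Binary classification with solute as the
  negative class and liquid as the positive class; gel and solid
  records are excluded.
* **Conditions**: for a given protein–RNA pair, in which class of each
  experimental condition does LLPS occur?  Five linked multiclass
  problems solved with a classifier chain.

## Preprocessing

Concentrations are unified to µM (`M`, `mM`, `uM`, `nM` by SI factor;
`mg/mL` via the sequence-derived average molar mass, c[µM] = value ×
10⁶ / MW) and log10-transformed; zero concentrations cannot be
log-transformed and exclude the record.  Salt concentrations are
converted to ionic strength with the fully dissociated electrolyte
formula **I = ½ Σ cᵢ zᵢ²**, using a shipped table of common buffer
salts (NaCl, KCl, LiCl, MgCl₂, CaCl₂, ZnCl₂, Na₂SO₄, mono/dibasic
sodium and potassium phosphate, Tris·HCl treated as a 1:1 monovalent
electrolyte).  Only the listed salt species contribute; no
activity-coefficient or speciation corrections are applied, and records
with unsupported species are excluded with a reason.  Temperatures are
unified to °C, with the token "room temperature" defined as 25 °C and
Kelvin values offset by 273.15.  pH passes through untransformed.

Records enter the behavior model only if the morphology is solute or
liquid, no crowding agent or small molecule is present, both sequences
are at least 10 letters over their standard alphabets (T in RNA is
mapped to U with a logged warning; any other non-ACGU letter excludes
the record rather than being imputed), and all five conditions are
present and convertible.  Exclusion is always an explicit outcome with
a reason, never a silent drop.

## Features (29 + 97 + 5 = 131)

**Protein (29)** — computed with Biopython's ProteinAnalysis: the 20
amino-acid fractions, sequence length, average molecular weight,
aromaticity (fraction of F/W/Y), the Guruprasad dipeptide-weight
instability index, the isoelectric point (bisection on the net-charge
curve over pH ∈ [4.05, 12]; note the terminal residues carry their own
pKa values, so pI is sensitive to the first and last residue), GRAVY
(mean Kyte–Doolittle hydropathy), and the helix/turn/sheet
secondary-structure fractions (V,I,Y,F,W,L / N,P,G,S / E,M,A,L).

**RNA (97)** — 4 + 16 + 64 overlapping k-mer frequencies in
lexicographic ACGU order (each block sums to 1), plus 13 statistics of
the discrete-Fourier power spectrum of the purine-indicator signal
(A,G → 1; C,U → 0, mean-removed; unnormalized forward DFT; power
|X_f|² over f = 1..⌊n/2⌋, DC excluded): mean, median, max, min, peak
position (1-based argmax over the half-spectrum length), sample
standard deviation, 25/50/75th percentiles, amplitude, sample variance,
skewness, and excess kurtosis.  A constant spectrum (e.g. a
homopolymer) has skewness and kurtosis defined as 0 so every statistic
is finite.  The periodicity mapping and statistic set are this
package's canonical definition; feature registries are exported so the
inventory can be swapped.

**Conditions (5)** — log10 protein conc (µM), log10 RNA conc (µM),
ionic strength (mol/L), pH, temperature (°C), in that fixed order at
the end of the vector.

## Behavior model and evaluation protocol

Seven algorithms are registered (logistic regression, k-NN, SVM,
Gaussian naive Bayes, random forest, LightGBM, AdaBoost).  The four
non-tree algorithms consume the standardized design matrix (zero mean,
unit population variance, fitted on the training partition of each fold
only; zero-variance columns pass through); the tree ensembles consume
the raw matrix.

Evaluation is **repeated stratified group 10-fold cross-validation**:
the group key is the exact protein sequence, so no protein ever appears
on both sides of a split; folds are assigned by scikit-learn's
stratified group splitter (a greedy, label-balance-minimizing
assignment of whole groups), seeded per repeat.  Within each fold,
hyperparameters are selected by exhaustive grid search with inner
stratified (ungrouped) 5-fold CV on ROC-AUC, ties broken by grid order;
the winner is refitted on the whole training split.  ROC curves are
vertically averaged on a fixed 101-point FPR grid within each repeat
and then across repeats; the headline number is the mean of per-repeat
mean AUCs.  Impurity-based feature importances (tree models only) are
averaged within each repeat and then across repeats.  Default
hyperparameter grids are intentionally small and overridable (they are
a package choice, since no canonical search ranges are fixed):
regularization strength over 5 log-spaced values for LR, k ∈ {3,5,11},
SVM C ∈ {0.1,1,10}, tree counts {100,300}, AdaBoost {50,100} × learning
rate {0.5,1.0}.

A stricter grouped-inner-CV mode is deliberately not the default: the
inner loop is stratified-only, matching the outer/inner asymmetry of
the protocol this package implements.

## Condition model

Only liquid records are used.  Each condition value is binned with the
published class boundaries (pH 0–7.0–8.0–14; temperature 0–25–30–40 °C;
ionic strength 0–0.032–0.066–0.14–0.17–0.40 mol/L; protein conc
−1.64…2.7 and RNA conc −4.7…2.3 log µM in five classes).  The closure
convention is: first interval closed on both ends, later intervals
left-open/right-closed, so a value on a shared boundary belongs to the
lower class; out-of-range values clamp to the terminal class with a
logged warning.  Quantile re-fitting of the boundaries from training
data (order-statistic percentiles at 20/40/…/100%) is available as an
alternative to the fixed published boundaries.

The chain trains one AdaBoost classifier per condition in the fixed
order pH → temperature → protein conc → RNA conc → ionic strength, each
consuming the 126 sequence features plus the upstream targets: **true**
classes during training (teacher forcing), **predicted** hard labels at
prediction time (a flag switches to passing probability vectors).  The
base learner uses the library-default weak learners (depth-1 trees, 50
rounds).  Evaluation pools out-of-fold predictions from group 10-fold
CV into per-condition macro-averaged one-vs-rest ROC-AUCs (classes
absent from the pooled truth are skipped with a warning) and confusion
matrices.

## Phase diagrams

For one pair, each axis spans [min − 1.0, max + 1.0] of the pair's
observed log10 concentrations in 20 equally spaced points (endpoints
included), giving 400 grid predictions.  Non-swept conditions default
to the component-wise median of the pair's own records (an explicit
override is accepted; the choice is open because only "held constant"
is specified).  The diagram model is taken from the repeat with the
highest mean ROC-AUC (ties to the earliest), specifically the fold that
held the pair's protein group out of training; supplying a model whose
training manifest contains the pair's protein is an error, not a
warning.  Pair accuracy is the fraction of the pair's experimental
records whose predicted label matches the observed one.

## Synthetic data

The generator emits schema-complete records: sequence pools with
repeated use (Dirichlet-weighted, giving the realistic many-records-
per-protein group structure), protein lengths 10–500 and RNA lengths
10–200, conditions drawn over the published class spans (pH clipped
normal around 7; temperature 60% "room temperature" token, otherwise
uniform 0–40 °C; NaCl molarity uniform 0–0.4 M so ionic strength is the
molarity itself; log concentrations uniform over −1.64…2.7 and
−4.7…2.3), and concentrations re-expressed in a random unit (µM/mM/nM)
to exercise unit unification.  Labels follow a logistic rule on the
standardized planted covariates — ionic strength (−2.0), log protein
conc (+2.0), log RNA conc (+1.5), protein R/K fraction (+1.5), zero
intercept — with a noise temperature of 0.4 (Bernoulli draws from
sigmoid(z/τ); τ = 0 gives deterministic threshold labels) and an
optional label-flip rate.  These defaults were chosen once to give a
positive fraction near ½ and a planted signal strong enough to be
recoverable across protein groups, and are not tuned thereafter.  The
condition-dataset variant plants a chain-learnable dependency: the pH
class is the protein's aromaticity tercile (sequences get a per-protein
aromatic-composition bias so terciles are well separated) and the
ionic-strength class copies the pH class, with the other conditions
independent; a null mode makes all conditions independent of the
sequences.

What the generator does **not** emulate: biological sequence
composition (sequences are i.i.d. over their alphabets with simple
biases), correlated conditions, the real dataset's marginal
distributions, and gel/solid physics.  Passing tests therefore
demonstrate that the pipeline's plumbing, protocol, and statistics
behave correctly — not that the published real-data accuracy is
reproduced; that requires the curated external dataset.

## Problem sizes and determinism

Every source of randomness flows from a single integer seed (per-repeat
fold plans use seed + repeat).  The test suite and the acceptance
script run the protocol at deliberately modest sizes chosen as adequate
for the properties they check: leakage and null checks at n = 500,
planted-rule recovery at n = 2000 with a single SG10CV pass and fixed
default hyperparameters, chain evaluation at n = 400, and the
acceptance script's behavior run at n = 1500 with 3 repeats and a
two-point AdaBoost grid.  The library defaults remain the full protocol
(10 repeats, tuning on).

## Known limitations

* The exact published inventories of the 29 protein and 97 RNA features
  are not restated anywhere public; the sets here match the named
  descriptor families and the stated totals, and the registries are
  data-driven so they can be corrected.
* The supported-salt table is a superset guess over common LLPS buffer
  salts; buffer identity and pH titration are not converted to ions.
* Macro-ROC averaging and ROC-curve averaging use vertical
  interpolation on a fixed FPR grid — one of several defensible
  conventions.
* Probability calibration, gel/solid multiclass prediction, IDR- or
  peptide-composition feature variants, and chain-order search are out
  of scope.
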