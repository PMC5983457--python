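# Methods

## The modelling problem

A peptide's blood half-life *t* spans roughly 20 seconds to 24 hours in
curated experimental compilations. All modelling is done on *y* = log₂ *t*
(seconds), which linearizes the scale and makes errors interpretable: an
MAE of 1.5 means held-out predictions are off by a factor of ~2.8 in
half-life on average. Everything downstream — curation bounds, metrics,
predictions — lives on this scale; predictions are also back-transformed to
seconds (2^y) in reports.

## Curation

Records are kept when sequence length lies in [5, 50] residues and
half-life in [20, 86400] s. Both bounds are **inclusive**: removal is
defined as strictly outside the range. Duplicates are then removed keeping
the first occurrence; the key is the upper-cased sequence string, or the
SMILES string for sequence-less modified entries, so a natural peptide and
a differently modified variant of the same sequence are distinct records.
Curation is idempotent and reports per-filter removal counts. Sequence
entries with characters outside the 20 standard codes are rejected at read
time unless the row carries a SMILES (then flagged `is_modified`), because
all sequence encoders assume the standard alphabet.

## Feature encodings

Vector layout uses the fixed alphabetical residue order
`ACDEFGHIKLMNPQRSTVWY`. Compositions are reported in **percent** — AAC,
DPC and atom-fraction vectors each sum to 100 — so they are
length-invariant, which matters for a regressor trained on 5–50-mers.

*Atom composition* is fractional by default (counts available via
`mode="count"`). For natural peptides the molecular formula comes from a
free amino-acid formula table minus one water per peptide bond (free
termini, cysteine as free thiol, no charge); this is exact and avoids a
sequence→SMILES round trip. The SMILES route (`smiles_element_counts`)
exists for modified peptides: a small tokenizer handles the organic subset,
two-letter halogens, aromatic lowercase atoms, bracket atoms with explicit
hydrogen counts, branches and ring closures, and fills implicit hydrogens
from default valences (aromatic atoms charged one extra bond for the
delocalized system). The two routes agree exactly on generated peptide
SMILES, and the tokenizer is cross-checked against RDKit in the tests.

*Physicochemical panel*: length, monoisotopic mass (residue-mass sum plus
water), net charge at pH 7 with the coarse convention Asp/Glu −1, Lys/Arg
+1, His +0.1, mean Eisenberg consensus hydrophobicity, and percent
aromatic (F, W, Y), small (A, G, S, T, P, C, D, N), negative (D, E) and
positive (K, R) residues. The panel was chosen to cover the properties the
compositional analyses discuss — charge, size, aromaticity — since no
canonical panel is fixed by convention.

*Terminal profiles* take the five N- or C-terminal residues (well defined
after curation, minimum length 5) and one-hot encode each position over the
20 residues (100 dims, exactly five ones).

## Descriptor selection (CFS + best-first)

External chemical descriptors arrive as a PaDEL-dialect CSV (first column
`Name`). Cleaning drops any column with a missing marker ("", "NaN",
"Infinity", …) or zero variance and standardizes the rest to zero mean and
unit population variance. Selection maximizes the CFS merit

    merit(S) = k · r̄_cf / sqrt(k + k(k−1) · r̄_ff)

with r̄_cf the mean |Pearson r| of subset features against y and r̄_ff the
mean pairwise |Pearson r| within the subset — the continuous-target CFS
variant, appropriate for a regression response. For k = 1 the merit is
|r(feature, y)|. The search is forward best-first from the empty set: the
best open subset is expanded by every unused feature, the global best is
tracked, and the search stops after 5 consecutive non-improving expansions
(the cited selection tool's documented default). Ties in merit break to the
lower column index, so the result is deterministic for a given column
order. An exhaustive-subset oracle (`exhaustive_cfs`, ≤ 12 columns) bounds
the heuristic in tests. Selected descriptor *names* are never hard-coded:
selection is re-run on whatever table is supplied, because descriptor
availability depends on the external software version.

## Regression and evaluation

The primary learner is epsilon-SVR; `svr` and `smo_svr` are the same model
with two solver presets (shrinking on / off with a tighter tolerance),
mirroring the two SVR implementations such models are traditionally fit
with. Baselines: ordinary least squares (pseudo-inverse on singular
designs), uniform-weight k-NN, and a Gaussian process with RBF kernel plus
fitted white-noise term. All estimators sit behind a per-fold
standardization step fitted on training data only, so cross-validation
never leaks held-out statistics; whether the original models scaled
features is unknowable, and per-fold standardization is the defensible
default.

Evaluation uses Pearson R, MAE and RMSE on the log2-seconds training
scale. LOOCV predicts each sample from a model trained on the other N−1;
metrics are computed over all N held-out pairs. Hyperparameters are tuned
by grid search maximizing LOOCV R (ties: lower MAE, then lattice order).
The default lattice — SVR kernel ∈ {rbf, linear}, C ∈ 2^−5…2^7, γ ∈
2^−9…2^1, ε ∈ {0.01, 0.1, 0.5, 1}; k ∈ {1, 3, 5, 7} — is documented and
overridable; published results of this kind report only the achieved
maximum, so the lattice is a package choice. The independent check draws
five random 10% hold-out splits (test size = round(0.1 n)), trains on each
remainder, and reports per-repeat metrics and their arithmetic mean; the
split seed is mandatory and recorded.

## Design tools

Analog generation enumerates all 19·L single-point mutants in (position,
alphabet) order; protein scanning extracts all N−w+1 overlapping windows
(stride 1), with the window length restricted to the model validity range
[5, 50]. Coordinates in reports are 1-based inclusive, the convention
biologists expect. Batch prediction is the same code path as scoring a
candidate list. Ranking sorts by predicted log2 half-life with stable ties
(input order) in both directions.

## Synthetic data: what it does and does not establish

The generator draws lengths uniformly on [5, 50] and residues uniformly
over the 20 standard codes (or a supplied distribution), then sets

    y = intercept + Σ_a w(a) · AAC_a / 100 + N(0, noise_sd),

clipped to [log₂ 20, log₂ 86400]. Defaults: n = 200 peptides, intercept 10
(mid-range, ~17 min), noise sd 0.5 log2-seconds, and weights +12 for Ala
and Glu, −12 for Phe and Tyr — i.e. 3 log2-seconds per 25 composition
percent, the minimal structure matching the compositional findings on real
data (small/negatively charged residues stabilize, aromatics destabilize).
Clipping rather than rejection keeps n exact but slightly flattens the
extremes. Duplicate sequences are redrawn so the output passes curation
unchanged.

A green pipeline test on this world establishes that encoding, selection,
cross-validation and design machinery recover a planted compositional
signal at realistic noise (LOOCV R ≥ 0.9 at noise sd 0.5, degrading
monotonically as noise rises). It does **not** establish real-data
performance: real blood half-life compilations have correlated residue
usage, sequence-similarity clusters (up to 90% identity), position- and
motif-specific protease effects, and terminal modifications, none of which
the generator emulates. The published-scale numeric results can only be
reproduced with the original experimental tables, which are not
redistributable here.

## Numerical choices

- Pearson R is undefined (reported NaN / raised, not 0) for constant
  observations or zero-variance features.
- LOOCV metrics are invariant to sample order exactly for closed-form
  learners; for SVR only up to the solver tolerance (~1e−3), since libsvm's
  iterate depends weakly on data order.
- SVR hyperparameter grids over powers of 2; `gamma` defaults to sklearn's
  `scale` heuristic when unspecified.
- Dedup and encoding are case-insensitive (sequences upper-cased on entry).
- Merit comparisons in the best-first search use a 1e−12 improvement
  threshold to keep tie-breaking deterministic under floating-point noise.

## Known limitations

- Modified peptides are carried (SMILES, atom composition) but the design
  tools operate on natural sequences only.
- The SMILES reader counts atoms; it is not a general cheminformatics
  parser (no kekulization, no stereo semantics, no sanitization) — RDKit
  remains the tool of choice when full chemistry is needed.
- Chemical descriptors are ingested, never computed: producing them
  requires external software.
- The Gaussian-process and k-NN baselines are generic equivalents of the
  classical Weka learners, not bit-level reproductions.
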