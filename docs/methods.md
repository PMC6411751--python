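# Methods

## Feature space

Molecules are standardized before any computation: parse, keep the largest
organic fragment (salt/solvent stripping), neutralize charges where
chemically valid, canonicalize. The sequence is idempotent and structures
without a carbon atom are rejected. Stereochemistry is deliberately ignored
in featurization — antagonist panels in this chemical space mix enantiomers
whose activities differ only modestly, and circular fingerprints are
computed without chiral flags.

Features are sparse hashed circular (Morgan) environments of bond radius
0..r in unfolded (sparse-id) form. Unfolded ids avoid folding collisions,
which matters because the classifier estimates a frequency per feature;
r = 2 (ECFP4-equivalent) is the classifier default, r = 3
(ECFP6-equivalent) is used for diversity clustering. Six physicochemical
descriptors (AlogP, molecular weight, H-bond donors/acceptors, rotatable
bonds, fractional polar surface area) are discretized into B = 10
equal-frequency bins learned on the training set, with open-ended outer
bins; each molecule contributes exactly one indicator id per descriptor.
Descriptor ids live at 2^35 and above, disjoint from the 32-bit fingerprint
hashes. Fractional PSA is computed as topological PSA divided by the Labute
approximate surface area, clipped to [0, 1] — a purely 2D surrogate chosen
so the whole pipeline stays conformer-free.

Quantile cuts may coincide on skewed descriptors (e.g. integer counts);
duplicate cut points are collapsed, so a descriptor can occupy fewer than B
effective bins. Binning is a property of the molecules, not the labels, so
cross-validation procedures fit the scheme once per dataset and reuse it
across folds and permutations.

## Classifier

The Laplacian-corrected naive Bayes weight for feature *i* is
w_i = ln[((A_i + pK)/(T_i + K))/p] with K = 1/p, where A_i/T_i are active
and total training counts and p the base active rate. This form makes a
base-rate feature weigh exactly zero and shrinks rarely observed features
toward zero — the smoothing assumes most features carry no activity signal.
Features unseen in training contribute zero at prediction time. The raw
score is the weight sum; the normalized score divides by max(1, feature
count) to remove molecule-size dependence, so score distributions are
comparable across molecules (the normalization choice is recorded in the
serialized model).

Leave-one-out scores are exact: the held-out molecule's feature counts and
class totals are decremented rather than retraining naively, which is
algebraically identical (verified against a brute-force retrain oracle to
1e-12). In a degenerate fold whose remaining records are single-class, the
base rate is clipped to (0.5/T, 1 − 0.5/T) so the record is still scored.
Class means and standard deviations of the LOO normalized scores define the
two-Gaussian EstPGood transform, computed in log space (a logistic of the
log-density difference) so extreme scores saturate at 0/1 instead of
producing NaN. Standard deviations are floored at 1e-6 for degenerate
(zero-variance) training sets. The binary decision threshold is the
normalized-score cut minimizing total LOO misclassifications, ties resolved
toward the lowest cut.

## Validation

AUC uses the Mann–Whitney convention (tied active–inactive pairs credited
0.5). The label-randomization null permutes labels uniformly (class sizes
preserved), retrains, and computes the LOO AUC per repetition. Note a small
negative bias (~0.01–0.03 on an 83-compound panel) is intrinsic to exact
LOO under permutation: removing a held-out "active" lowers the weights of
its own features, anti-correlating score and label. Repeated stratified
k-fold shuffles each class independently, splits each into k equal bins by
floor division and drops the leftovers for that repetition (class size mod
k records — 3 of 58 actives and 0 of 25 inactives at k = 5); reshuffling
every repetition ensures no compound is systematically excluded. All
stochastic procedures are bit-reproducible from their seed.

## Screening, clustering, selection, novelty

Library compounds are ranked by the sum of the two models' EstPGood, ties
broken by id. The dual gate is strict: predicted active iff EstPGood > 0.9
under both models, predicted inactive iff < 0.1 under both. The gated set
is partitioned into max(1, round-half-up(N/5)) clusters: the first centroid
is the top-ranked compound, each next centroid maximizes its minimum
1 − Tanimoto distance (radius-3 fingerprints) to the chosen centroids (ties
to the lowest id), and every compound joins its nearest centroid (ties to
the lowest cluster id). This deterministic max-min partition stands in for
the proprietary partitioning component the original workflow used; with 138
gated compounds it yields 28 clusters where the original reported 27, so
the cluster count is overridable. Representative selection automates the
original manual criteria: per non-singleton cluster, the non-training
member with the highest mean EstPGood inside an optional molecular-weight
window; vendor availability is intentionally not modeled. Novelty is the
maximum Tanimoto similarity (radius-2 fingerprints) of each hit to any
training active, histogrammed in ten 0.1-wide bins with the top bin closed.

## Assay analytics

Percent-of-control: raw% = 100·I_test / mean(I_pre1, I_pre2), then
normalized by the sham (vehicle-only) percent, in that order; inhibition% =
100 − normalized%. A compound is inactive iff inhibition at 3 mM is ≤ 20%.
The Hill model I = Imax/(1 + (X/IC50)^n) is fit by nonlinear least squares
with all three parameters free and log-parameterized (positivity by
construction), initialized at Imax0 = max response, IC50_0 = geometric mean
of the tested concentrations, n0 = 1. Because percent-of-control data have
roughly constant coefficient of variation, the default weighting is
relative (sigma proportional to the response; an unweighted option is
provided). Standard errors are asymptotic, transformed from the log scale
by the delta method; on exact noise-free data the covariance is singular
and the SEs are undefined while the estimate itself is still returned with
converged = True. Fits whose IC50 falls outside the tested concentration
range are flagged (`within_tested_range = False`) — the typical signature
of no-inhibition data. The potent-subset (model B) gate takes converged
fits with IC50 strictly below 500 µM. The behavior response index is
RI = (S − C)/(S + C) over larvae scored outside the starting circle;
RI is undefined when no larvae are scored.

## Synthetic study conditions

The generators reproduce the shape of the study's inputs, not its exact
chemistry. The training panel (default 58 actives / 25 inactives) draws
actives from three motif-bearing chemotype grammars — substituted
phenols/catechols, cinnamate esters/cinnamaldehydes, and
cyclohexanol/terpenoid-like alcohols — echoing the chemotypes that dominate
known Orco antagonist panels, and inactives from motif-free scaffolds
(alkylbenzenes, anisoles, aliphatic esters/ketones/ethers/alcohols,
dialkyl-benzamides, nitriles, cyclohexanes). Potency correlates with
chemotype: log10 IC50 (µM) is drawn per compound around family offsets
(−0.8, 0, +0.8) from the panel location 3.0 with a within-family sd chosen
so the marginal sd is 0.8; clipped to 5 µM – 20 mM. Under these defaults
roughly a third of actives fall below the 500 µM potent-subset cutoff, and
the weak (cyclohexanol) actives sit nearest the decoys in fingerprint
space, so the all-actives model separates slightly less cleanly than the
potent-subset model — the qualitative behavior of real wide-potency-range
panels. `label_noise` flips labels independently at a given rate and is the
dial for degrading separability in tests.

The library generator (default 1280 compounds, 5% motif-bearing) emits
hidden ground truth to a separate table so pipeline code cannot consume
labels, and can spike the training records into the library to reproduce a
catalog containing previously tested compounds. Dose-response data are
generated from the Hill curve with multiplicative Gaussian noise (CV 5% by
default) on an 8-point half-log dilution series (1–3000 µM), truncated at
zero; behavior plates draw binomial exclusions then binomial side choices
for 50 larvae.

What the synthetic conditions do **not** emulate: real structure-activity
cliffs (the motif signal is cleaner than experimental SAR, so validation
AUCs on the surrogate panel run higher than on a real panel), assay-to-assay
rundown beyond the sham factor, correlated replicate structure within
oocytes, and any vapor-pressure/volatility physics. Passing tests therefore
demonstrate correctness of the statistical machinery and pipeline wiring,
not expected performance on experimental data.

## Problem sizes and determinism

Default demonstration sizes are the study's: 58/25 training, 1280 library.
Repeated procedures use 100 repetitions for the permutation null and
100–200 for k-fold summaries (the k-fold rep mean is stable to ~0.003 at
200 reps); cluster partitioning, gating and selection contain no hidden
randomness, so screen → gate → cluster → select is bit-identical across
runs. All generators and resampling procedures take explicit integer seeds.
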