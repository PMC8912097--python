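# Methods

`acpfuse` classifies short peptides (11–~200 residues, 20-letter alphabet)
as anticancer peptides (ACPs) or non-ACPs. It fuses two views of a peptide:
a 35-dimensional engineered feature vector fed to a dense branch, and the
raw residue sequence fed, via a learned embedding, to a bidirectional LSTM
branch. This note records the model, the conventions and defaults we pinned
where the problem left choices open, and what the shipped tests do and do
not demonstrate.

## Engineered features (35 dimensions)

**Pseudo amino acid composition (PAAC), 30 dims.** For a sequence
R₁…R_L, the first 20 components are the amino-acid frequencies f_u and the
last λ components carry sequence order:

    p_u = f_u / (Σf + w·Στ)                u = 1…20
    p_u = w·τ_{u−20} / (Σf + w·Στ)         u = 21…20+λ

with τ_k = (1/(L−k)) Σ_i J(R_i, R_{i+k}) and
J(a,b) = (1/3) Σ_q [Φ_q(b) − Φ_q(a)]² over three per-residue properties:
Kyte–Doolittle hydropathy, Hopp–Woods hydrophilicity, and side-chain mass.
Defaults λ = 10 and w = 0.05 (the conventional recommendations). All
20+λ components are non-negative and sum to 1 by construction; this
algebraic identity is property-tested. PAAC requires L > λ; shorter
sequences are a hard error rather than a silent λ reduction, because the
correlation factors are undefined there (benchmark ACP sets have minimum
length 11, so λ = 10 is always legal on real data).

*Scale normalization.* Each property table is standardized to mean 0,
SD 1 (population SD) across the 20 residues before computing J — the
standard convention in the PAAC literature; without it side-chain mass
(tens of Daltons) dominates the coupling. The tables are pluggable via
`PAACParams`; the shipped values are pinned in `acpfuse.tables` and
cross-checked against Biopython's copies in the tests.

**Length, Shannon entropy (2 dims).** Entropy is −Σ f_i log f_i in natural
log (the defining formula writes `log` without base; the choice only
rescales a feature that is z-scored downstream, and is pinned here for
reproducibility). Range [0, ln 20]; 0 iff homopolymer.

**Physicochemical properties (3 dims).** GRAVY is the mean Kyte–Doolittle
hydropathy. Molecular weight uses average (not monoisotopic) residue
masses plus 18.02 Da for the terminal water. Net charge at pH 10 uses
Henderson–Hasselbalch fractions: +1/(1+10^(pH−pKa)) per basic group
(N-terminus, K, R, H), −1/(1+10^(pKa−pH)) per acidic group (C-terminus,
D, E, C, Y), with an EMBOSS-style pKa table (C 8.5, D 3.9, E 4.1, H 6.5,
K 10.8, R 12.5, Y 10.1, N-term 8.6, C-term 3.6). The table is pluggable
via `ChargeParams`; the pH-10 feature is qualitatively robust to the table
choice, but pinning one makes results bit-reproducible. Net charge is
strictly decreasing in pH, which the tests exploit as an invariant.

## Sequence encoding and the network

Residues map to integers alphabetically (A→1 … Y→20); index 0 is reserved
for padding. Sequences are post-padded to `max_len` (default: longest
training sequence) and longer inference sequences are truncated with a
warning. The embedding table has 21 rows, 50 columns by default; row 0 is
pinned at zero and masked out of the recurrent pass, so padding neither
contributes to the representation nor receives gradient.

The LSTM follows the standard forget/input/output-gate cell
(c_t = f∘c_{t−1} + i∘g, h_t = o∘tanh c_t). Both directions read the valid
prefix of the sequence (the backward pass reads it reversed) and their
final hidden states are concatenated — the least lossy way to combine
directions absent a reason to prefer another. The dense branch applies
two ReLU layers (64→32) to the z-scored engineered features; branch
outputs are concatenated and passed through a 64→32→1 head with a
logistic output, the ACP probability.

Ablation modes mirror the feature study: `MS` (dense branch only), `AE`
(sequence branch only), `MS+AE` (both). Toggling the mode changes which
branches exist, never the feature order within a branch.

The network is implemented directly in numpy (embedding, masked LSTM,
dense layers, inverted dropout, Adam), with explicit reverse-mode
gradients. A finite-difference check over every parameter tensor of the
full fused graph guards the backward pass (relative error ≲ 1e-4 at
eps = 1e-6).

**Training.** Binary cross-entropy (the natural loss for a logistic score
thresholded at 0.5), Adam at 1e-3, batch size 32, up to 200 epochs with
early stopping on validation loss (patience 20, best-epoch weights
restored). Architecture defaults — 64 LSTM units per direction, dense
64→32, head 64→32→1, dropout 0.3 — are ordinary small-data settings and
are all `ModelConfig` knobs. The engineered features are z-scored with
training-set statistics frozen into the checkpoint (molecular weight is
~10³ while PAAC components are ~10⁻²). Runs are deterministic for a fixed
seed under single-threaded numpy; one `numpy.random.Generator` drives
initialization, and a second (derived from the same seed) drives shuffling
and dropout.

**Decision rule.** A peptide is called ACP iff its score strictly exceeds
the threshold (default 0.5); a score of exactly 0.5 is non-ACP. The
threshold is a predict/evaluate-time argument, not baked into the
checkpoint, since thresholding is a post-hoc decision layer.

## Evaluation conventions

Positive class is ACP. Accuracy, F1, recall, precision and MCC come from
the 2×2 confusion table by the standard formulas. A zero factor under the
MCC root (or an empty predicted/actual positive set for the other metrics)
yields 0 with a `degenerate` flag rather than an error, keeping batch
evaluation alive. ROC/AUC uses trapezoidal integration over all score
thresholds (equivalent to the Mann–Whitney statistic with tied scores
rank-averaged); the PR area uses the average-precision step convention,
which differs slightly from a trapezoidal PR integral — both delegated to
scikit-learn and verified against brute-force threshold-sweep oracles in
the tests. Tables report percentages at one decimal; underlying values
keep full precision.

## Synthetic benchmark

The generator plants a purely compositional class signal emulating what
separates real ACPs from decoys: positives up-weight K, R, L, W, I, F
(cationic/amphipathic enrichment, the profile visible in published ACP
validation sets), negatives up-weight D, E, G, S; lengths are uniform on
11–50 (the regime of the public benchmark sets; minimum 11 keeps λ = 10
legal). A `null_spec` control draws both classes from one uniform
composition. The profile was chosen qualitatively, once, as a test
scaffold — it is not a fitted or biological model.

What passing tests show: the feature math is correct, the planted
composition signal is learnable by every branch (validation accuracy
≥ 0.90 on 200+200 train / 50+50 validation), and no signal is invented
where none exists (null control stays within [0.35, 0.65]). What they do
not show: performance on real peptides. Real ACP discrimination involves
order-dependent structure (amphipathic periodicity, motifs) that the
generator does not emulate, so synthetic accuracies say nothing about
accuracy on laboratory data.

Desk-scale check sizes (the package's own choice for its test suite and
acceptance script): 250+250 generated peptides split 80/20 stratified,
max 40 epochs with patience 10, `max_len` 50.

## Reproducing published-scale results

The headline independent-test results of the reference hybrid model
(accuracy 89.6%, AUC 0.945 on the 82+82 test set) require the original
public ACPs250/ACPs82 FASTA datasets (available from their authors'
repository) and retraining; the exact original architecture beyond the
defaults above is not published, so this is an informational, non-gating
expectation: training on ACPs250 (80/20 split) and evaluating on ACPs82
with `MS+AE` defaults is expected to land within ±5 percentage points of
89.6% accuracy over 5 seeds (roughly 10–20 min on one CPU). What this
package reproduces exactly, with no downloads, are the metric values
implied by the published raw confusion counts and the 20-peptide
independent-set decision-rule outcome (one of ten true ACPs scored 0.4979
and is therefore called non-ACP; all ten non-ACPs called non-ACP).

## Known limitations

- Inference on sequences longer than `max_len` sees only the truncated
  prefix (a warning is logged).
- The charge model ignores local electrostatic environment and uses a
  single fixed pKa table.
- No redundancy reduction or homology-aware splitting is performed;
  supplied datasets are taken as-is.
- Single fixed train/validation split; no cross-validation orchestration.
- The model does not distinguish cancer types or predict activity values.
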