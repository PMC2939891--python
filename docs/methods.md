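# Methods

## Model

The package scores a peptide `S = S1...Sn` against an SH3 domain described
by position-specific energy matrices.  One matrix `M` (20 residues x 10
structural positions, FoldX-like arbitrary units, lower = tighter) gives the
additive energy under register (offset) `k`:

    E(S, k; M) = sum over i in 1..10 of M[S_{i-k}, i],   taken over
                 positions with 1 <= i - k <= n; uncovered positions add 0.

Offset 0 is the canonical mapping (P1, S1)...(P10, S10); offset -1 reads
(P1, S2)...(P10, S11).  The register search covers -4..4 by default.

A *binding state* is a set of conformations (e.g. MD snapshots) of one
peptide template.  Its energy is the mean of the `n_lowest` smallest
per-conformation energies, evaluated at a register shared by all
conformations of that template.  The prediction for a peptide is the
minimum of this quantity over candidate templates; candidates are all
templates (`min_energy`), the templates whose class matches the peptide's
canonical motif (`motif_class`, falling back to all templates for
motif-free or dual-motif peptides), or one fixed template.

All ties break deterministically: registers prefer |offset| small, then the
more negative offset; templates prefer the lowest id.  Runs are therefore
bit-reproducible, and the batch scorer is the same numeric kernel as the
single-peptide path (identical accumulation order), so batch and loop
results are identical.

Specificity profiles (PSFMs) are built from the `top_k` lowest-energy
members of a scored pool: each selected peptide deposits its residues at
the structural positions through its chosen register, uncovered positions
count as the placeholder symbol `X`, and columns are normalized.  Profiles
are compared by Frobenius distance (the `X` row is excluded by default,
since reference PWMs carry no placeholder mass).  The p-value of an
observed profile against a reference is the lower tail of a normal
distribution fitted to the distances between the reference and profiles of
uniform-random sequence sets of the same size; the normal-tail fit (rather
than an empirical quantile) lets genuinely extreme profiles be assigned
p-values far below 1/n_null, floored at 1e-100.

SPOT-array intensities (BLU) convert to pseudo-energies by
`E = -ln(BLU + pseudocount)` — the bound-complex count is assumed
proportional to intensity, kT is fixed to 1, and the default pseudocount 1
keeps `E(0) = 0`.  Evaluation reports Pearson correlation between predicted
and SPOT pseudo-energies (both axes are energies, so good predictions give
positive r) and the tie-corrected Mann-Whitney AROC on binder /non-binder
labels from the k strongest and k weakest spots.

## Key parameters

| parameter | default | meaning |
| --- | --- | --- |
| `n_lowest` | all (11) | conformations averaged into the binding energy |
| `offset_min..offset_max` | -4..4 | register search range |
| `template_selection` | `min_energy` | candidate-template policy |
| `conformation_mode` | `ensemble` | or `single:<id>` for one snapshot |
| `pseudocount` | 1.0 | BLU -> energy regularizer |
| `top_k` / pool size | 1000 / 10^5 | PSFM construction |
| `n_null` | 1000 | null profiles for the p-value fit |

Two optional behaviors are off by default and exposed for sensitivity
analysis only: `normalize_coverage` divides a register's energy by its
number of covered positions (registers with partial coverage otherwise
enjoy a small bias when matrix entries are mostly unfavorable — faithful
behavior keeps the raw sum and reports `n_assigned` per prediction), and
`per_conformation_offset` lets every snapshot optimize its own register
instead of sharing one per template (a register is treated as a property of
the binding mode, not of a thermal snapshot, which also makes the reported
alignment a single value).

## Synthetic data

The generator emulates the output of the structure-based pipeline at the
energy-matrix level, not the structures themselves — the simplest model
consistent with an energy calculation that is sensitive to small structural
variation:

* **Ground truth.**  Per class, a 20 x 10 matrix with N(0, 0.5^2)
  background and the canonical motif cells set to -2.0: class I
  (R and K at the anchor, P at anchor+3 and anchor+6), class II (P at the
  anchor and anchor+3, R and K at anchor+5).  The default anchor is
  structural position 3 for both classes, placing the motif interior to the
  groove as in real complexes (canonical registers sit at offsets -3..0);
  an edge anchor would let a one-residue register shift trade a motif cell
  for an uncovered position, a degenerate geometry.  The *sequence*
  generator's motif modes default to anchor 1; pair them with the truth by
  passing `anchor=3` explicitly.
* **Ensemble.**  Template t = class truth + fixed N(0, 0.4^2) per-entry
  perturbation; conformation c of template t adds independent N(0, 0.3^2)
  noise.  Default grid: 9 templates (3 class I, 6 class II) x 11
  conformations = 99 matrices, the production shape; the 2-5 ns / 300 ps
  sampling schedule labels 11 snapshots.
* **SPOT tables.**  `BLU = exp(-E_true) * LogNormal(0, 0.2^2)`, where
  `E_true` is the offset-0 additive score against the peptide's better
  class truth.  Multiplicative noise is chosen so the log conversion yields
  additive Gaussian noise on energies.  Zero-noise tables invert exactly
  under pseudocount 0.

The noise defaults are set so that prediction-vs-SPOT correlations land in
the realistic SPOT-study range (single-conformation and ensemble r roughly
0.6-0.8 on motif peptide sets) rather than in a trivially easy regime.
What passing tests on these fixtures show is that the scoring, selection
and profile machinery recovers planted structure under matrix-level
Gaussian noise; they do not exercise real structural error modes
(systematic force-field bias, register-dependent backbone strain,
correlated errors across residues), SPOT-array saturation, or peptides
longer than the modeled groove plus the register range.

## Numerical choices and degenerate inputs

* Energy-matrix text files store full `repr` precision, so write/read
  round-trips are bit-exact; PSFM files store 12 significant digits
  (round-trip error < 1e-12) and validate column normalization to 1e-9 on
  read.
* The n-lowest mean uses a sort; its equality with the minimum over all
  size-n conformation subsets is the brute-force oracle used in tests.
* A register that covers zero positions scores exactly 0 (the empty sum);
  empty sequences, unknown residues, incomplete template x conformation
  grids, constant inputs to Pearson, single-class AROC labels, zero-variance
  p-value nulls and all-`X` PSFM columns raise typed errors rather than
  propagating NaNs.
* `blu_to_energy` accepts pseudocount 0 for strictly positive intensities
  (needed to invert noiseless synthetic tables) and rejects `BLU +
  pseudocount <= 0`.
* Profile width mismatches are an error; register-shifted comparison is an
  explicit utility (`best_shift_distance`) rather than an implicit slide.

## Known limitations

* Additivity is assumed throughout; inter-residue coupling is out of scope.
* Energies are treated as an opaque lower-is-better scale; no absolute
  unit conversion or temperature dependence is modeled.
* The `motif_class` selection policy cannot beat the cross-class register
  degeneracy inherent to the shared PxxP spacing: under default noise a
  minimum-energy search sends roughly 5-10% of single-motif peptides to a
  template of the other class, matching the cross-class best templates
  observed in real SPOT data.
* The "best conformation" column of the evaluation report maximizes
  correlation against the observed data and is deliberately excluded from
  blind-prediction paths.
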