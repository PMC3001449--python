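# Methods

## The observation model

The unit of observation is one pairwise structure alignment between two
homologous domains of the same family. From the alignment we take three
quantities:

- **PNI** = 100·(1 − N_iden/N_algn), the percentage of aligned positions
  whose residues differ. N_algn is the number of aligned residue pairs and
  N_iden the number with identical residues.
- **SNG** = L·N_gap/N_algn with standard length L = 100 residues
  (`sng_standard_length`, configurable). N_gap counts *indel events*: each
  maximal internal run of unaligned residues, in either domain, is one
  gap, irrespective of its length. Terminal overhangs are alignment-extent
  artifacts, not indels, and are excluded by default
  (`count_terminal_gaps`).
- **RMSD**, the root-mean-square Cα deviation over the aligned pairs after
  least-squares rigid-body superposition. Reflections are excluded
  (proteins are chiral); the rotation comes from the Kabsch solution and
  the RMSD is recomputed from the rotated residuals, because the solver's
  reported residual loses precision to cancellation near zero.

Within a family, structural divergence is modelled as bilinear in the two
kinds of sequence divergence:

    RMSD_i = b0 + b1·PNI_i + b2·SNG_i + ε_i,   ε_i ~ N(0, σ²) i.i.d.

fitted by ordinary least squares. b1 is the structural substitution
sensitivity (SSS, Å per PNI percent), b2 the structural indel sensitivity
(SIDS, Å per SNG unit). Coefficient p-values use the two-sided t
distribution with n−3 degrees of freedom; the overall fit is tested with
the F statistic against the intercept-only model; the multiple correlation
coefficient R is reported as the nonnegative root of R² (the conventional
sign for a multiple correlation).

Assumptions worth stating: alignments within a family are treated as
independent observations although they share domains (the same
approximation every pairwise-alignment regression in this area makes);
RMSD measurement noise (resolution, crystallization conditions) is folded
into ε rather than modelled as errors-in-variables; and no
multiple-testing correction is applied across families.

## Model comparison

Four mean surfaces are fitted per family:

| model        | design columns              | k |
|--------------|-----------------------------|---|
| linear_pni   | PNI                         | 1 |
| bilinear     | PNI, SNG                    | 2 |
| paraboloid   | PNI, SNG, PNI², SNG²        | 4 |
| cubic_spline | ns(PNI, 4) + ns(SNG, 4)     | 8 |

Adjusted R² = 1 − (1 − R²)(n − 1)/(n − k − 1) with k the number of
independent variables. *Adequacy* of a smaller against a larger nested
model is the ratio of their adjusted R² values; 1 means the extra terms
buy nothing once penalized, and values above 1 are legitimate (the larger
model can lose on adjusted terms).

The spline surface is additive: a natural cubic spline in each predictor
with 4 degrees of freedom and interior knots at within-family quantiles.
The raw cubic-regression-spline basis spans the constant, so each block is
centered and rotated onto its non-constant column space (a sum-to-zero
identifiability constraint, as in mgcv) before joining the intercept;
k counts the resulting basis columns (8). A bivariate tensor-product
surface would be the natural alternative; the additive form was chosen as
the minimal, deterministic construction with a df directly comparable to
the paraboloid's.

Diagnostics: first-order partial correlations of each predictor with RMSD
given the other (p-values via the t transform with n−3 df), and the
variance inflation factor VIF = 1/(1 − r²(PNI, SNG)), flagged above 4.
Degenerate cases are defined rather than fatal: if the conditioning
variable explains RMSD exactly, the partial correlation of the other
predictor is 0 with p = 1; perfect PNI–SNG collinearity raises a singular
-fit error carrying the offending correlation, and cohort fitting falls
back to the PNI-only model for such families (e.g. gapless families with
zero SNG variance) with a recorded reason.

## Input handling

PDB text is parsed directly (fixed-column ATOM/SSBOND/EXPDTA/REMARK 2):
one entry per CA atom, altloc ' ' or 'A' only, highest-occupancy conformer
on duplicates, first MODEL only, selenomethionine accepted. Disulfide
bonds are counted from SSBOND records and a bond counts only when both
cysteines lie inside the domain range ("local" bonds); a geometric
fallback (SG–SG < 2.3 Å) exists behind `infer_disulfides` for headerless
files. Correspondences are 0-based positions into the ordered CA list
(not PDB numbering), strictly increasing in both columns. Tables are
UTF-8 TSV with a `# bisens-format: v1` tag and `.` for absent values;
floats are written with 8 significant digits so reruns are byte-identical.

Family selection applies, in order: NMR exclusion, mutant exclusion,
optional resolution cut (strictly better than the threshold, default use
case 2.2 Å), a minimum of 20 surviving structures, and a minimum of 10
accurate alignments — alignments whose P-score (the structure matcher's
−log p significance, consumed as input metadata, never computed here)
strictly exceeds 3. Cross-family SSS/SIDS comparisons use the subset with
R > 0.75 and both coefficient p-values < 0.01. Cohort quartiles use
linear interpolation between order statistics (type 7). The
disulfide-group comparison is a pooled-variance Student t test between
families with mean disulfide count ≥ 1.5 and < 1.5 (Welch behind a flag);
"mean disulfide count" is the mean over accurate pair records of the two
domains' averaged counts. "Gaps per unit length" is the mean of
N_gap/N_algn and "total indels" the sum of N_gap over accurate records.

## The synthetic-data generator

Table-level scenarios draw PNI uniform on `pni_range`, then quantize
through integer counts: N_algn uniform on 100–300, N_iden rounded from the
continuous PNI, N_gap rounded from the continuous SNG — so generated
tables obey exactly the arithmetic identities of tables computed from real
alignments, and RMSD is formed from the *quantized* predictors. A
noiseless scenario is therefore recovered exactly by the fit (used as a
machine-precision oracle).

SNG has a linear-in-PNI mean reaching `sng_rate` at the top of the PNI
range, emulating the empirical pattern that indels accumulate together
with substitutions; its total standard deviation is fixed at 0.2·sng_rate
and partitioned between the PNI-shared and independent components so that
corr(PNI, SNG) equals `pni_sng_coupling` — hence an implied VIF of
1/(1 − coupling²). Because quantization adds rounding variance
((L/N_algn)²/12), that amount is subtracted from the independent
component's budget; couplings so high that the budget clamps at zero
cannot be realized and the measured correlation falls short (not reachable
for the VIF range 1–10 at the default rates). Both SNG and RMSD are
truncated at zero; scenarios require b0 ≥ 0 and the acceptance-grade
scenarios keep b0 ≥ 3·noise_sd so the truncation essentially never binds
(bias well below 1%).

The built-in "benchmark" cohort has 73 families spanning 80–400
alignments, SSS 0.015–0.045 Å/% and SIDS 0.08–0.30 Å/unit, noise 0.15–0.30
Å, coupling 0.3–0.7; 10 disulfide-rich families (mean count 1.8–4.0) have
SSS halved, encoding the hypothesis that covalent cross-links constrain
the structural response to substitutions but not to indels (indels occur
on the protein surface, away from the cross-linked core). A homogeneous
52-family variant isolates that group effect (or, with `effect=0`, its
exact null) for calibration studies.

Coordinate-level toys are extended Cα traces (3.8 Å spacing) with exact
bookkeeping: specified substitutions, internal non-adjacent gap regions
(deletions from or insertions into the copy), isotropic Gaussian
positional noise and a uniformly random proper rigid motion. They emulate
the *statistics* the analysis consumes, not protein geometry: no secondary
structure, no excluded volume, no spatially correlated displacements.
Passing tests on them therefore validate the arithmetic and the
estimators, not the biological realism of any particular family; the
headline cohort numbers produced from synthetic families characterize the
method under its own model, not any deposited structure set.

All randomness flows from integer seeds through numpy's PCG64;
collections split seeds with `SeedSequence.spawn`, making every table
reproducible cross-platform. Pipeline reruns with the same configuration
and seed are byte-identical (verified in the test suite).

## Problem sizes and tolerances

The calibration studies run at sizes chosen to make their Monte-Carlo
error small against the bounds they check: CI coverage and bias over a
3×3×2 coefficient/noise grid with 200 replicates of n = 300 (coverage
bound [0.92, 0.98] against binomial s.e. ≈ 0.004; bias is pooled over the
σ = 0.1 cells, where the pooled relative-bias s.e. is ~0.2% against the 2%
bound — a per-cell reading at 200 replicates would test seed luck for the
smallest SIDS values); type-I error of the SIDS test over 1000 null
families; VIF targets {1, 2, 4, 10} at n = 2000 (sampling s.e. ≈ 4% at
VIF 10); p-value uniformity of the null disulfide-group test over 500
replicate cohorts (Kolmogorov–Smirnov) and its power over 100 replicates
with a 50% effect. Superposition is checked to 1e−9 Å under exact rigid
motions and to 1e−3 Å against a multistart numeric minimizer over
rotations; OLS agrees with an explicit normal-equations oracle to 1e−8
relative; gap counting is verified exhaustively against a run-enumeration
oracle over all correspondences between domains of length ≤ 8.

## Known limitations

- Ingested RMSD values from an external structure matcher may differ
  slightly from recomputed full-aligned-set superposition RMSD if the
  matcher trims a core; the package recomputes over all aligned pairs.
- The regression treats pairwise alignments as exchangeable; shared-domain
  correlation inflates effective significance in real families.
- Using an alternative structure-similarity response (e.g. a Z-score) is
  supported by passing it as the response column, but any sign convention
  (similarity scores decrease with divergence) is the caller's
  responsibility.
- The exponential PNI–RMSD model family and the structure matcher's own
  scoring are out of scope; P-scores and Z-scores are metadata.
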