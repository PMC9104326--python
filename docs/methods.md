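# Methods

## The problem and the predictors

A predicted structure assigns every residue a conformation and a
confidence score (pLDDT ∈ [0, 100], stored residue-wise in the B-factor
field). For intrinsically disordered regions the conformation is largely
arbitrary but the confidence is systematically low, so two families of
residue-wise disorder predictors can be read off a single model:

* **DSSPp** (naive structure rule). Assign 8-class secondary structure
  by the Kabsch–Sander criteria and call helices (H, G, I), strands
  (E, B) and hydrogen-bond-stabilised turns (T) ordered; bend (S) and
  loop (−) — the classes *not* defined by hydrogen bonding — disordered.
* **tpLD** (continuous): `score = 1 − pLDDT/100`, higher = more
  disordered.
* **pLDn** (binary): ordered iff pLDDT ≥ n. The threshold n is selected
  by maximising MCC over the integer grid 0..100 on pooled evaluated
  residues (pooling over proteins is the benchmarking convention for
  residue-level disorder assessment; a per-protein option exists).
  Ties resolve to the smallest n, which yields the most ordered calls at
  the margin; the tie-break only matters on separability plateaus.
  Combining dataset-specific optima uses the arithmetic mean with
  round-half-up — (76 + 68)/2 = 72 exactly, so the rounding rule matters
  only for user-supplied odd sums.

## Reference label sets

Two variants are built from 1-based inclusive interval tables:

* **annotation-only (“disprot”)**: residues inside any disorder interval
  are 1, all others 0, nothing masked. Unannotated-but-disordered
  residues therefore count as ordered; conclusions from this variant
  carry that caveat.
* **evidence-only (“disprot-pdb”)**: disorder annotations give 1 and win
  any conflict with structural coverage; covered-but-unannotated
  residues give 0; residues with neither source are masked and excluded
  from *every* metric, including threshold selection.

Proteins whose model length differs from the annotation length are
truncated to the shorter length with a logged warning (the conservative
choice); proteins with zero evaluated residues are dropped from pooled
metrics, with counts surfaced in the run manifest.

## Secondary-structure assignment

The classic 8-class alphabet {H, G, I, E, B, T, S, −} is computed from
backbone geometry:

* Amide hydrogens are constructed as
  `H = N_i + unit(C_{i−1} − O_{i−1}) × 1.0 Å`; prolines and chain-start
  residues donate no hydrogen.
* H-bond energy `E = 27.888·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)`
  kcal/mol; a bond is recorded iff E < −0.5. Distances are clamped below
  at 0.5 Å (malformed input only). Donor–acceptor pairs adjacent in
  sequence are excluded.
* n-turns (CO_i → NH_{i+n}, n = 3, 4, 5) give G/H/I helices, two
  consecutive n-turns being required to start a helix; parallel and
  antiparallel bridge patterns give B, bridges extended by a
  neighbouring bridge of the same type (ladders) give E; residues
  bracketed by an n-turn but in no helix get T; a CA pseudo-bond bend
  angle (CA_{i−2}, CA_i, CA_{i+2}) above 70° gives S.
* Priority on overlap: H > E > B > G > I > T > S > −. Chain breaks are
  declared where the peptide C–N distance exceeds 2.5 Å; chains shorter
  than 5 residues are assigned all '−' with a warning. β-bulges, PPII
  ('P') and solvent accessibility are deliberately out of scope; the
  8-class output predates the PPII extension because the downstream
  analyses only use helix/strand/turn/coil.

The 4-class reduction is H,G,I→H; E,B→E; T→T; S,−→C. The test suite
cross-checks the assignment against an independent reference
implementation (the mdtraj DSSP port) with a 95% per-residue agreement
floor — reference builds differ in ladder/bridge edge cases, which the
tolerance absorbs.

## Evaluation

Disordered (1) is the positive class everywhere; masked residues never
enter any statistic. ROC and precision–recall curves use scikit-learn;
the trapezoidal AUC equals pairwise concordance with ties counted ½ and
is verified against a brute-force concordance oracle in the tests and
acceptance script. MCC follows the standard conventions: 0 when a
denominator factor vanishes with both classes present, undefined
(`None`) on a single-class reference. Per-protein RMSD is
`sqrt(mean((v−w)²))` over evaluated residues; on binary vectors this is
the square root of the normalised Hamming distance, with an
uninformed-predictor baseline of √0.5 ≈ 0.707 on balanced vectors.
Disorder content is the evaluated-residue mean label; proteins bin into
highly disordered (> 0.90), highly ordered (< 0.10) and other, with
strict inequalities at the boundaries. Both cutoffs are configurable
(the source literature uses 0.90 and 0.95 in different places for the
upper cutoff; 0.90 is the default here). Bootstrap summaries resample
with replacement — 10,000 samples of size 60 at the protein level,
10,000 of size 500 at the residue level — and report the mean of
resample means and their standard deviation; a single seed makes them
exactly reproducible. Disorder-content histograms default to bin width
0.05 on [0, 1] (configurable).

## Confidence vs. local structure

pLDDT values are grouped by reduced class and by secondary-structure
codon (the triplet at a residue and its two neighbours; termini are
excluded rather than padded, and codons do not span chain breaks).
Distributions report mean, skewness, a Gaussian KDE (Scott's-rule
bandwidth, 512-point grid on [0, 100], no boundary reflection) and
optional bootstrap summaries; codons with fewer than 25 observations are
flagged low-support. Bimodality is operationalised as two KDE local
maxima separated by ≥ 10 pLDDT units. pLDnorm is per-segment min–max
normalisation (constant segments map to 0.5 with a warning);
propensity fits are ordinary least squares for the line model and
log–log least squares for the power law, with non-positive points
dropped.

## The synthetic generator

The generator defines the study conditions; its defaults are fixed:

| parameter | default | rationale |
|---|---|---|
| n_proteins | 150 | desk-scale stand-in for a several-hundred-target benchmark set |
| length_range | (60, 400) | typical single-domain to multi-domain spans |
| disorder_fraction | 0.3 | realistic cohort-level disorder content |
| mean_segment_length | 30 | IDRs occur in runs, not i.i.d. residues |
| plddt_ordered / plddt_disordered | (85, 10) / (45, 10) | well-separated but overlapping states (d′ = 4); midpoint 65 is the implied optimal threshold |
| smoothing_window | 5 | emulates spatial correlation of confidence along the chain |
| coverage_fraction_ordered / _disordered | 0.9 / 0.2 | experimental coverage is biased toward ordered regions |
| transient_helix_rate | 0.2 | fraction of disordered segments folded into low-confidence helices |
| confident_coil_rate | 0.1 | fraction of ordered runs assigned coil at high confidence |

Labels follow a two-state Markov chain whose exit rates reproduce the
stationary disorder fraction and mean segment length. Confidence is
drawn per state, clipped to [0, 100] and moving-average smoothed.
Secondary-structure strings fill ordered segments with helix/strand runs
joined by turn linkers and disordered segments with loop/bend; the
transient-helix and confident-coil knobs are the mechanism that makes
DSSPp and pLDn measurably different — with both at zero, DSSPp equals
the true labels by construction. Emulated external predictors draw
scores from the equal-variance binormal model (shift √2·Φ⁻¹(AUC) pushed
through the normal CDF), so their theoretical AUC is exact and
Φ(d′/√2) is the closed-form AUC of the confidence predictor on
unsmoothed profiles.

Backbones are built by sequential torsion (NeRF) placement from ideal
internal coordinates (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, ω =
180°); helices at φ = −57°, ψ = −47°, strands at φ = −139°, ψ = 135°,
coil torsions drawn from broad allowed basins with regeneration (up to
100 retries) when non-adjacent CA atoms come within 2 Å. Antiparallel
strand pairs place a flipped copy of an ideal strand by a deterministic
grid search over 180° flips and translations maximising the number of
inter-chain Kabsch–Sander H-bonds; the placement is cached per strand
length since ideal strand geometry is seed-independent.

What the generator does **not** emulate: real AlphaFold2 error modes
beyond the two knobs, side chains, sequence composition (everything is
polyalanine), UniProt-vs-model numbering offsets, or correlated
annotation errors. Passing tests therefore demonstrate the correctness
and calibration of the *pipeline*, not the published performance of any
real predictor on real data — those numbers require the real annotation
and structure sets, which can be supplied through the `io_formats`
readers.

## Problem sizes and acceptance checks

The acceptance script and tests use cohorts of 50–80 proteins of
150–300 residues (10⁴–2·10⁴ pooled residues), 100 random instances for
the AUC oracle, a 50-chain suite for geometry recovery, and
d′ ∈ {0.5, 1, 2, 4} for binormal calibration — sizes at which every
closed-form tolerance (±0.01 on the RMSD baseline, ±0.02 on AUC, ±1 on
threshold recovery) is comfortably resolved by the available sampling
noise. Threshold recovery uses a balanced (disorder_fraction 0.5)
cohort: with equal class priors and equal state variances the
MCC-optimal threshold coincides with the state midpoint, whereas a
perfectly separable cohort would leave the optimum ill-defined on a
plateau (the tie-break would then return the plateau's left edge).

## Known limitations

* The MCC threshold sweep pools residues across proteins; per-protein
  averaging gives slightly different optima on heterogeneous cohorts.
* The DSSP re-implementation omits β-bulges and sheet topology labels;
  agreement with reference builds is ≥ 95%, not 100%.
* Interval annotations are assumed to share the structure's author
  numbering; length mismatches are truncated and logged, never
  remapped.
* Multi-model (NMR-style) structure files are not supported; only the
  first model and first altloc are read.
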