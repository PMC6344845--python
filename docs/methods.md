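# Methods

## Model and procedure

The pipeline treats a domain family as a fixed coordinate system — the
ordered match states of its profile HMM — and each protein–ligand
co-complex structure containing the domain as one noisy observation of the
family's interaction interface.  The stages are:

1. **Structure ingestion** (`structio`).  PDB/mmCIF entries are reduced to
   heavy atoms (elements H and D removed); alternate locations keep the
   highest-occupancy conformer, ties resolved by file order; only the first
   model of a multi-model (NMR) entry is used, since aggregation is over
   entries, not conformers.  Waters are never ligands.  Non-polymer HETATM
   groups, nucleic-acid chains, and protein chains of ≤ 30 residues (bound
   peptides) are exposed as ligand instances.  When several chains in an
   entry share one sequence, the copy with the smallest any-atom distance to
   the ligand contributes; exact ties go to the lexicographically smaller
   chain id so results never depend on file order.
2. **Ligand typing** (`ligandtype`).  Nucleic chains are RNA if any residue
   carries an O2′ atom, else DNA; nucleotide atoms split into backbone
   (phosphate + sugar: P, OP1–OP3, O5′, C5′, C4′, O4′, C3′, O3′, C2′, O2′,
   C1′) and base (all other heavy atoms).  Compounds whose full name
   contains the standalone word "ion" (token-boundary match, so
   "methionine" does not qualify) are ions; everything else is a small
   molecule, additionally metabolite-like / drug-like if its fingerprint
   Tanimoto similarity to a reference set reaches 0.9.  Fingerprints are
   1024-bit linear-path (RDKit `RDKFingerprint`), configurable; the
   Tanimoto coefficient itself (|a∧b|/|a∨b|, 0 for two empty vectors) is
   computed in-package on plain bit vectors.
3. **Instance filtering** (`domhits`).  A structural instance enters the
   aggregation only if its bit score reaches the family's gathering
   threshold, it maps both terminal match states, it shows the modal
   residue at every mapped state with information content ≥ 4 bits, and it
   contains at least one annotated binding residue.  Information content is
   log₂ 20 − H(emission) against a uniform background, matching the reading
   that 4 bits corresponds to a ≈ 95 % point mass; a null-model-relative
   variant would be a configuration alternative.  Modal-residue ties fail
   the filter only when the observed residue matches none of the tied
   maxima.
4. **Scoring** (`bindfreq`).  Distances are minimum heavy side-chain-atom to
   heavy ligand-atom Euclidean distances; for nucleic ligand classes the
   ligand atoms are first restricted to the base or backbone subset.
   Binding frequency per state is the Henikoff-weighted contact fraction at
   3.6 Å.  The denominator counts only instances that map the state: a
   deleted state carries no evidence either way, and states mapped by no
   instance are reported absent rather than 0.
5. **Evaluation** (`evalcv`) and **transfer** (`transfer`), and
6. **Overlap significance** (`sitestats`), as described below.

## Parameters

| parameter | default | meaning |
|---|---|---|
| distance cutoff | 3.6 Å | residue–ligand contact; spans H-bonds (2.6–3.3 Å) and vdW contacts (2.8–4.1 Å), excludes water bridges |
| Tanimoto cutoff | 0.9 | metabolite/drug-likeness; lowering it can only grow the sets |
| max folds | 10 | cross-validation folds (fewer when fewer units) |
| min precision | 0.5 | confident-set admission |
| bootstrap resamples | 1000 | SE of each binding frequency |
| consistency repetitions | 10 | two-fold PCC averaging |
| identity threshold | 0.90 | single-linkage grouping for the stricter fold mode |
| min non-redundant instances | 3 | representable-NR admission |
| glycine mode | `ca_proxy` | see below |

All of these surface in the CLI and in `RunConfig`; none is hard-coded.

## Numerical and design choices

* **Glycine / missing side chains.**  The distance contract requires
  side-chain heavy atoms, which glycine lacks.  Default `ca_proxy` lets CA
  stand in; `exclude` returns a "no side chain" sentinel and the state is
  treated as unmapped for that instance.  Both behaviours are kept because
  neither is forced by the definition of the statistic.
* **Henikoff gaps.**  Gap characters neither define a residue type in a
  column nor receive a column score; a row's weight is the mean over its
  non-gap columns.  Deletions carry no emission evidence.
* **Bootstrap.**  Instances are resampled with replacement; Henikoff
  weights are recomputed inside each resample (a resample changes the
  redundancy structure, so fixed weights would understate variation); a
  fixed-weight mode exists as a flag.  The SE is the sample standard
  deviation (ddof 1) over resamples; states absent from a resample simply
  contribute no value for it.  At very small n the bootstrap SE is biased
  low — a 3-instance family whose three residues all touch the ligand has
  zero resampling spread even though the underlying frequency is uncertain —
  so size comparisons must average over replicate families (the acceptance
  checks do).
* **Precision–recall integration.**  Average precision (step integration)
  rather than trapezoids, avoiding optimistic interpolation between PR
  points; all pairs tied at a score cross each threshold together.  The
  choice is recorded in evaluation output metadata.
* **Per-fold vs pooled cross-validation.**  The default reports the mean of
  per-fold average precisions (fold-wise evaluation); pooling all held-out
  (instance, state) pairs into a single curve is available as a mode.  The
  returned curve's points are always the pooled curve, which is also what
  the confident threshold is read from.
* **Confident threshold.**  Among binding-frequency thresholds whose pooled
  cross-validated precision reaches the minimum, the one with maximal
  recall is chosen, ties resolved toward higher precision (equivalently the
  largest qualifying threshold at that recall): the most permissive
  defensible cutoff for transfer.
* **Poisson binomial.**  Exact PMF via iterative convolution, O(N²); exact
  enumeration is the test oracle up to N = 15.  Tail probabilities that
  underflow to 0 are reported as 1e-15.  The per-site success probability
  is the binding-site fraction of the whole host protein (binding residues
  / protein length); the alternative reading — a denominator restricted to
  some site neighbourhood — is not implemented.
* **Degenerate inputs.**  Constant distance vectors in the consistency
  split (correlation undefined) count as perfectly consistent when the two
  halves agree exactly and as 0 otherwise; repetitions sharing fewer than
  two states are skipped with a warning, and an all-skipped run is an
  error, not a silent number.

## What the synthetic generator emulates

`fixtures` plants a family with known truth: each instance is a single
chain of two-atom residue stubs (CA plus one side-chain atom) positioned
around a compact 3–8-atom pseudo-ligand so that the realized minimum
side-chain distance at each state equals a draw from a truncated normal —
below 3.6 Å at designated binding states, well above it elsewhere.
Coordinates are rounded to the three decimals PDB files carry and all
derived quantities (planted distances, annotations) are computed from the
rounded coordinates, so in-memory families and their on-disk form agree
exactly and regeneration is byte-identical per seed.  Sequences mutate from
a consensus at a configurable rate and avoid glycine so every stub has an
explicit side-chain atom (glycine handling is unit-tested on hand-built
residues instead).  Defaults describe a mid-sized family: 20 states, 10
instances, 5 binding states, contact distances 3.0 ± 0.25 Å vs 7.5 ± 0.25 Å,
15 % per-position mutation rate.

The generator makes no attempt at physical realism: no backbone geometry,
sterics, rotamers, B-factors, crystal contacts, missing density, or
chemically meaningful ligands.  Passing tests therefore demonstrate the
correctness of the aggregation, weighting, evaluation and testing
machinery on inputs with known answers — not predictive performance on
real structural data, which depends on data quality and coverage the
fixtures deliberately idealize.

The proteome generator draws interest sites independently over residues
with weight `enrichment` inside planted binding sites and 1 elsewhere;
`enrichment = 1` realizes exactly the null hypothesis of the overlap test.
Calibration is checked with 1000 sites per replicate so the discrete
Poisson-binomial tail is smooth enough for a Kolmogorov–Smirnov comparison
against the uniform; with few sites the tail p-value is super-uniform
purely through lattice effects, which is a discreteness property, not
miscalibration.

## Problem sizes

The shipped checks run at desk scale by design: families of 3–12 instances
with 20 match states, exhaustive oracles up to 2¹⁵ outcomes, 1000-resample
bootstraps averaged over 10–30 replicate families, and 500-replicate null
calibrations.  These sizes are where the exact oracles remain enumerable
and the planted truths remain exact.

## Known limitations

* Domain search is out of process: the package consumes hit tables with
  alignment coordinates and never runs HMMER itself.
* No structure superposition, symmetry-mate generation or assembly
  reconstruction; the asymmetric unit is taken as given.
* Cognate vs non-cognate binding is approximated only through
  metabolite/drug similarity labels; no 3D chemistry is considered.
* Odds ratios use no continuity correction and are undefined for tables
  with empty cells.
* No multiple-testing correction layer on overlap tests; callers comparing
  many site lists must correct externally.
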