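# Methods

## Model and assumptions

The package operationalizes the molecular-ruler hypothesis for Dicer-like
enzymes: the siRNA product length is set by the rigid-body geometry between
the PAZ domain's terminal-nucleotide-binding pockets and the RNase III
catalytic centers. Three assumptions follow:

1. **Sites are residue sets, centers are centroids.** A functional site
   (3′ pocket, 5′ pocket, RNase III A, RNase III B) is a small set of
   residues in author numbering. Its "center" is the unweighted mean of the
   selected atoms' coordinates. The default atom policy is Cα-only: side
   chains rotate freely between models of the same fold, so a Cα centroid
   is invariant to rotamer choice; an `all_heavy` policy exists for
   sensitivity checks and will generally shift centroids by fractions of an
   Å. Unresolved entries (``?`` in a site table — residues that could not
   be assigned in the ortholog alignment) are skipped and counted, never
   guessed.
2. **The ruler is a distance pair.** The caliper is measured as
   3′ pocket ↔ RNase III A and 5′ pocket ↔ RNase III B (the pairing used
   in the published distance table), summarized by the arithmetic mean.
   Euclidean distances are invariant under rigid motion, so the
   superposition frame cannot affect ruler values; superposition RMSDs are
   reported for conservation context only.
3. **Distance maps linearly to product length** over the narrow 18–24-nt
   window of interest.

## Calibration and parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `rise` | 2.0 | Å/nt | caliper pitch: distance change per nucleotide of product length |
| `L_ref` | 21 | nt | product length of the reference enzyme |
| `d_ref` | measured | Å | reference mean caliper distance (measured, not configured) |
| `relevance_threshold` | 0.5 | Å | caliper shifts strictly exceeding this are flagged biologically relevant |
| `n_replicates` | 3 | — | re-measurements per structure |
| `perturb_sigma` | 0.0 | Å | per-coordinate Gaussian noise applied per replicate |

The default anchored model predicts
`L = L_ref + round((d̄ − d_ref)/rise)` with ties rounded away from zero (no
real data sits on a tie; the convention is documented for completeness).
The default pitch of 2.0 Å/nt is the empirical inter-class spacing of the
ortholog data — the 20/21/22-nt classes sit roughly 2 Å apart, and an OLS
fit of length on mean distance across the five orthologs gives a slope of
0.490 nt/Å ≈ 1/(2.04 Å/nt) — and it is consistent with the rule of thumb
that ±1–2 Å corresponds to 1–2 nt. The crystallographic A-form rise
(2.81 Å/bp) is available via `rise=2.81`; both pitches give identical
length classes for the shipped data, because the class boundaries are not
tight at these distances. `fit_calibration` provides the second mode, an
ordinary least-squares line; the fitted model's anchor is set to the data
centroid (mean distance, rounded mean length) so the anchor-consistency
property `predict(d_ref) = L_ref` holds in both modes.

Predictions outside 18–24 nt are returned with an `in_range=False` flag
rather than raised: an absurd prediction is a finding about the input, not
a crash.

## Superposition

Cα atoms are paired across structures on identical (chain, author number)
by default, or through an explicit correspondence map; residues missing a
Cα in either partner are dropped symmetrically, and at least three pairs
are required. The optimal rigid transform is the SVD solution with
determinant correction (via `scipy.spatial.transform.Rotation.align_vectors`),
so the returned rotation is always proper (det = +1) even for
chirality-breaking inputs. A single full-correspondence fit is performed —
no outlier-rejection cycles. Domain-level RMSDs (e.g. helicase, PAZ,
RNase III spans read from a TSV) are evaluated **under the global
transform without refitting**, so they decompose the global fit; a refit
per domain would always read lower and would no longer be comparable
across domains.

## Residue correspondence between orthologs

Annotation transfer uses deterministic pairwise global alignment with
affine gaps (BLOSUM62; gap open −10, extend −1; a gap of length k costs
open + (k−1)·extend). `X` is scored as a flat −1 mismatch against
everything. Site entries aligned opposite a gap become unresolved; a
`strict` mode additionally drops entries whose target amino acid differs
from the reference's (off by default — pocket residues are genuinely
non-identical across these orthologs, e.g. a tyrosine replaced by an
arginine in the 3′ pocket). Catalytic DDxE/D motifs are never detected de
novo; sites always originate from an annotated reference table. Multiple
sequence alignment and phylogenetics are out of scope: orthology transfer
only needs pairwise correspondence, and a pairwise optimum is reproducible
without external tools.

## Synthetic structures

The generators provide ground-truth inputs in place of (non-redistributable)
homology models:

* **Caliper scaffolds** place the four site clusters so their Cα centroids
  sit at *exactly* the requested distances (cluster offsets are re-centered
  to make the centroid exact), add decoy residues for parser/selector bulk,
  then optionally add isotropic Gaussian coordinate noise and finally a
  seeded random rigid placement. The noise term is the simplest model of
  model-to-model variability (rotamer repacking, loop wobble); scaffolds
  are geometric stand-ins, not folded proteins.
* **Duplexes** are two antiparallel strands of one phosphate-proxy
  pseudo-atom per nucleotide on a regular helix (default rise 2.81 Å/bp,
  twist 32.7°/bp, radius 9 Å), numbered 5′→3′ per strand. They support
  end-geometry arithmetic — the axial extent is (n_bp − 1)·rise, and one
  extra base pair adds exactly one rise — not nucleotide chemistry; 2-nt
  3′ overhangs are not modeled.

What passing tests on these synthetics do **not** show: robustness to real
crystallographic pathologies (alternate conformations beyond simple altloc
policies, gaps at site residues, insertion-code-bearing numbering) or to
genuinely misfolded models. They do show that the measurement chain —
generation → PDB round-trip → site resolution → centroid → distance →
calibration — is exact to the PDB coordinate precision.

## Replicates

Replicates are re-measurements of optionally perturbed copies of each
structure (`perturb_sigma` per replicate, seeded from the pipeline seed).
With the default `perturb_sigma = 0` all replicates are identical and the
replicate SD is exactly 0, which the pipeline logs explicitly; replicate
spread is only meaningful when a perturbation scale is configured. The
replicate statistic is the sample SD (n−1 denominator, 0 for a single run).

## Numerical choices

* All arithmetic is in double precision; Å values are rounded only at
  serialization.
* Serialized Å values are first quantized to 10⁻³ Å — the PDB coordinate
  precision, below which a distance carries no information — then rounded
  to one decimal with ties toward zero. The tie rule matters exactly once
  in the shipped data (a mean of exactly 58.35 Å prints as 58.3, matching
  the published table); the quantization step keeps sub-precision noise
  from a PDB round-trip from flipping a displayed digit.
* A reported mean that disagrees with its own distance pair at one decimal
  raises a warning note, never an error: the recomputed value is reported,
  the configured one is not trusted. The shipped ortholog data contains one
  such row (recomputed 60.0 Å vs reported 59.8 Å for *T. castaneum*).
* Degenerate inputs fail loudly and specifically: empty structures, empty
  selections, fewer than 3 superposition pairs, all-identical calibration
  distances, sites with no resolved residue.
* The pipeline JSON report contains no timestamp, so a fixed seed yields a
  byte-identical report.

## Problem sizes

The test suite and acceptance script run on scaffolds of 66 residues (4×4
site residues + 50 decoys), alignment oracles on sequences of length ≤ 8
(exhaustive enumeration stays exact), 20 optimizer-oracle superposition
instances of 5–10 points, and 100–200-replicate Monte-Carlo checks — sizes
at which every oracle is exact or its sampling error is quantifiable, and
the whole suite runs in well under a minute of CPU.

## Known limitations

* PDB only; mmCIF, multi-model ensembles and assemblies are out of scope.
* Insertion codes are preserved through I/O but site tables address
  residues by (chain, number) only.
* The linear distance→length calibration is supported by five orthologs
  spanning ~4 Å; extrapolation far outside that window is unvalidated.
* Pocket shape, depth and electrostatics — also plausibly length- and
  efficiency-determining — are not computed here.
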