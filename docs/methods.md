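# Methods

This note documents the models, parameters and numerical choices behind the
package: a spacio-linear screen for local 3D similarity between protein
substructures (ligand-binding cavities and solvent-exposed surface patches),
with ligand pose transfer and score calibration on top.

## The alignment model

Two protein substructures A and B are compared without any sequence-order
or backbone assumption. The only information used is (i) interatomic
distances and (ii) per-atom chemistry. The pipeline:

1. **Neighborhoods.** Every heavy atom is the center of a neighborhood: its
   k nearest other heavy atoms of the same substructure, serialized as a
   linear sequence sorted by increasing distance from the center
   (k = 7 by default, configurable 7–11). Distance ties break
   lexicographically by atom id, so results are bit-reproducible.
2. **Atom annotation.** Each heavy atom carries a four-bit DABE key —
   hydrogen-bond **D**onor, **A**cceptor, **B**ulkiness,
   **E**lectropositivity — plus a reduced-alphabet amino-acid group.
   * Donor/acceptor flags come from a bundled per-residue template table
     (all 20 residues + backbone, e.g. Ser OG → donor and acceptor, Lys NZ
     → donor only); unknown residue/atom names fall back to an element
     heuristic with a logged warning.
   * An atom is bulky iff w_i³ + Σ_j w_j³ > 10 Å³ (strict), summed over
     its van der Waals contact neighbors (distance ≤ w_i + w_j + tolerance,
     tolerance 0 by default). Radii are a bundled Bondi-style table
     (C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, Se 1.90 Å, …); unknown
     elements raise instead of defaulting.
   * An atom is electropositive iff its own and all its contact neighbors'
     Pauling electronegativities are ≤ 2.5.
   Bulkiness and electropositivity are conformation-dependent; annotation
   must be re-run after coordinates change.
3. **Substitution score.** Aligning atom a (group g_a, key d_a) with atom b
   scores `W[g_a, g_b] + chem_weight · shared(d_a, d_b)` where
   `shared ∈ {0..4}` counts equal DABE positions and W is a 7×7 group
   weight matrix derived from PAM250: entries averaged within group pairs
   over the six groups {AGPST}, {C}, {DENQ}, {FWY}, {HKR}, {ILMV}, then
   affinely rescaled to [0, 4] to match the DABE range. The seventh
   (neutral) group holds hetero/unknown atoms; it scores half the smallest
   real self-weight against everything and the smallest real self-weight
   against itself, so every row of W stays diagonally dominant and a
   neutral atom can never outrank a same-group match. (A literal "matrix
   midpoint" neutral weight of 2.0 would violate diagonal dominance: four
   real self-weights fall below 2 after rescaling.)
4. **Sequence alignment.** All neighborhoods of A are globally aligned
   against all of B (Needleman–Wunsch with affine gaps, Gotoh recursion;
   a gap run of length L costs `gap_open + gap_extend·(L−1)`, defaults
   −4/−1). Traceback tie order is match > gap-in-B > gap-in-A.
5. **Evidence accumulation.** An alignment passes the quality gate when its
   score reaches `quality_gate_fraction` (default 0.9) of the smaller of
   the two self-alignment scores. Every matched atom pair of a passing
   alignment — plus the center pair itself, since the alignment is evidence
   for the center correspondence — accumulates the full alignment score.
   Pairs inside genuinely superimposable regions recur across many
   overlapping neighborhoods and accumulate far more evidence than chance
   pairs.
   *Why 0.9:* the gate is not stated by the method's description beyond
   "high-quality alignments". At 0.7, essentially every random neighborhood
   pair passes (most protein atoms are bulky carbons, so even mismatched
   columns score 4–6 of 8) and background evidence buries the recurrence
   signal (identity-pair recall 36/61 on a rigid-copy screen); at 0.9 the
   same screen recovers 61/61 while jittered-motif recall stays high. The
   value was fixed once against these construction-validated properties.
6. **Candidate selection.** The per-pair evidence distribution is split
   into background and outliers. Default rule: evidence above
   median + 2·1.4826·MAD, a scale-robust outlier cut that still works when
   the background is nearly constant; pairs matched in ≥ 3 passing
   alignments with at-least-median evidence are kept as well, because
   recurrence is the primary superimposability signal and on small clean
   inputs the table is mostly signal (an outlier cut alone would return
   nothing). Literal mean + c·SD, top-quantile and fixed-value policies
   are available in the config.
7. **Clustering.** Candidates are agglomerated under a hard geometric
   constraint: a merge is acceptable only if the Pearson correlation r
   between the interatomic-distance vectors of the merged group (all
   C(N,2) distances among matched atoms, A side vs B side) exceeds
   r_min = 0.85, and no atom may be used twice on either side.
   Each of the top 50 evidence-ranked candidates seeds a lineage that
   greedily accretes, one pair per step, the compatible pair maximizing
   the union correlation; accretion draws on the full evidence pool
   (capped at 500 pairs), so clusters expand beyond the initial
   candidates. The very first accretion has a single distance component
   per side (r undefined) and is accepted when the two distances agree
   within 1 Å. Because correlation degrades toward r_min as weaker pairs
   join, every step is snapshotted and each lineage reports its
   best-Ncorr5 state (≥ 4 pairs, the minimum for a meaningful r). A
   single-pass "merge until nothing exceeds 0.85" variant was measured to
   absorb decoys late and fragment planted motifs (14/20 planted pairs
   recovered vs 20/20 with snapshots) and was dropped.
8. **Scoring.** A 3D alignment of N pairs with correlation r scores
   Ncorr5 = N·r⁵. Published operating points: 25 (significant), 30
   (stringent comparisons), 35 (surface screens).

Known limitation: Pearson correlation of pooled distance vectors is
invariant to affine rescaling of the distances, so two internally rigid
motifs that sit far apart on both sides can merge into one high-r cluster
even when the two cross-distances are numerically very different. This is
inherent to the correlation criterion (which deliberately tolerates uniform
scaling); superpositions derived from such alignments are caught downstream
by the docking shift. When the two copies land at mutually inconsistent
separations the correlation collapses and the motifs stay separate.

## Extraction

* **Ligand cavity:** all whole residues with ≥ 1 heavy atom within 7 Å of
  any ligand heavy atom; kept only with ≥ 40 heavy atoms; the ligand's own
  atoms are never part of the cavity.
* **SASA:** Shrake–Rupley (via biotite) with a 1.4 Å probe, 960 points per
  sphere, package radii; computed per isolated chain — ligands and other
  chains do not occlude by default (configurable).
* **Surface patch:** the same whole-residue 7 Å shell around a single atom
  with SASA strictly above 2 Å². One patch per exposed atom; an optional
  residue-set deduplication switch exists but is off by default.
* SASA-annotated structures can be written with the per-atom area in the
  B-factor column of a separate chain 'X'.

## Pose transfer and FE-score

The Kabsch transform (scipy's `Rotation.align_vectors`, proper rotations
only) computed on an alignment's matched pairs carries the probe ligand
into the target frame. The pose is refined locally — receptor rigid —
either by an external AutoDock Vina ≥ 1.2 executable (`--local_only`,
minimal PDBQT writer, no torsion tree) or by the bundled stub optimizer:
Nelder–Mead over the 6 rigid degrees of freedom of a clash-penalized
contact potential (quadratic overlap penalty, Gaussian contact well,
harmonic tether to the initial pose so the refinement stays local). Stub
energies preserve the sign conventions and monotonicities of a docking
score but are **not** physical binding free energies.

FE-score = FE / (Shift + 0.1), with Shift the heavy-atom RMSD between
initial and optimized poses (centroid displacement available via config;
which one the original protocol used is not determinable). A docking with
FE-score strictly below −1.5 is classified a true positive. Large shifts
suppress significance by construction: they indicate the alignment-based
placement was unstable.

## Calibration and evaluation

Across a screen, maximal alignment scores behave like extreme values; the
background is modelled as Gumbel, F(x) = exp(−exp(−(x−μ)/β)). Moment
estimates β̂ = s·√6/π, μ̂ = x̄ − γβ̂ (γ Euler–Mascheroni); MLE optional.
On the double-log transform log(−log F̂) a Gumbel sample is a straight
line; significant alignments appear as a tail departure.

The knee detector fits the Gumbel by moments on the full sample (a rare
signal component barely moves the moments, whereas fitting a truncated
bulk biases the predicted tail) and scans score values above the 90 %
quantile for the smallest x whose observed exceedance count is more than
4 Poisson standard deviations above the predicted n·(1−F(x)), requiring
≥ 5 observations above x. A residual-SD rule on the double-log curve was
tried first and rejected: the variance of log(−log F̂) grows without bound
in the tail, so a mid-range residual SD triggers on every pure-Gumbel
sample. The implemented rule was validated on 30 seeds: no knee on pure
Gumbel(10,2) samples of 10⁵; knees inside [25, 30] on the same samples
plus 20 planted scores ≥ 30.

Screen evaluation: hits are results with alignment score strictly above
the threshold; a hit is a true positive iff FE-score < −1.5; ROC/AUC
(trapezoidal, scikit-learn) ranks all results by alignment score against
the TP labels.

## Synthetic data

The generators state the world the tests live in:

* `make_random_structure(n_residues, seed)` — a self-avoiding chain
  (Cα step 3.8 Å, non-successive Cα ≥ 4.2 Å, all-atom minimum separation
  1.2 Å) of idealized residues with full heavy-atom complements
  (~8.3 atoms/residue over the 20 standard types). Side-chain geometry is
  an idealized helical path from CB — the aligner consumes only distances
  and chemistry, so torsional realism is deliberately absent.
* `plant_shared_motif(a, b, motif_size, jitter_sigma, seed)` — copies a
  contiguous window of A's atoms into B under a random rigid transform
  plus per-atom Gaussian jitter, placed clash-free outside B's host
  atoms; returns the exact atom-pair ground truth.
  `shuffle_chemistry=True` permutes the copied atoms' chemical labels
  while keeping the geometry — a same-shape decoy.
* `make_toy_complex(pocket_residues, ligand_atoms, seed)` — a small
  ligand placed at van der Waals contact distance (≥ 3.5 Å) such that
  exactly the requested number of residues fall in its 7 Å shell.

What a green test does not establish: real cavities are larger (hundreds
of atoms), chemically biased, and solvated; jitter is not a model of
conformational change; the stub optimizer is not a force field. The
full-PDB screens, the published hit counts and TP rates, and
engine-grade FE-scores are out of scope for this repository and require
external databases plus AutoDock Vina.

On motif size and Ncorr5: a planted motif of 25 atoms can contribute at
most N = 25 pairs, and any jitter σ > 0 keeps r < 1, so the top score
N·r⁵ is strictly below 25 (observed 12.8–24.4 at σ = 0.3 Å across seeds
1–20, with mean planted-pair recovery 91.4 % and all 20 chemistry-shuffled
decoys below 25). Reaching the significance threshold 25 requires either
a larger motif (40 atoms at σ = 0.2 Å scores ≈ 38) or zero noise.

## Defaults worth knowing

| parameter | default | meaning |
|---|---|---|
| `k` | 7 | atoms per neighborhood sequence (7–11) |
| `gap_open`, `gap_extend` | −4, −1 | affine gap penalties |
| `quality_gate_fraction` | 0.9 | alignment gate vs self-score |
| `candidate_policy` | robust | median + 2·1.4826·MAD outlier cut |
| `r_min` | 0.85 | correlation floor for cluster merges |
| `min_cluster_pairs` | 4 | smallest emitted alignment |
| `cavity_radius` | 7 Å | residue-shell radius |
| `cavity_min_atoms` | 40 | smallest usable cavity |
| `sasa_min_area` | 2 Å² | surface-exposure cut (strict >) |
| `ncorr5_min` | 25 | significance threshold (30/35 stringent/surface) |
| `fe_threshold` | −1.5 | TP cut on the FE-score (strict <) |

All of these live in `SlamConfig` (YAML-serializable); every output table
embeds the resolved configuration as comment lines.
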