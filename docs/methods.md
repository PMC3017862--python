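# Methods

## The coevolution statistic

For an alignment of n sequences, every column k defines a *variability
vector* over the n(n−1)/2 sequence pairs: the BLOSUM substitution score of
the two residues a sequence pair shows at that column,

    θ_k(i,j) = B(a_ik, a_jk),

centered on the column's mean over defined pairs. A large centered value
means the pair (i, j) is unusually conservative at k, a negative value
unusually radical. Coevolution of two columns is scored as the Pearson
correlation of their vectors over the sequence pairs defined in both; two
columns whose substitution patterns rise and fall together across the same
sequence pairs get r near 1. Column pairs with r ≥ 0.4 (signed, by
default) are reported and grouped into connected components of the
position-pair graph ("correlated groups"). This is the pairwise
substitution-matrix branch of correlated-mutation methods; no parametric
significance model is attached to r — validation is by resampling against
independent data (below).

**Time correction.** Sequence pairs that diverged long ago accumulate
coincidental double substitutions. Optionally each centered θ_k(i,j) is
divided by the Poisson-corrected distance t_ij = −ln(1 − p_ij), where
p_ij is the proportion of differing residues over columns defined in both
sequences, and re-centered. Identical sequence pairs (t = 0) are dropped
from the vectors rather than floored — dividing by zero has no meaning and
a floor would give those pairs arbitrary weight. Pairs with p = 1 are
likewise dropped (the scalar API raises instead, since a caller asking for
one distance should hear that it is undefined). For inter-molecular
analysis t_ij is computed on the concatenation of the two paired rows: one
joint divergence per ortholog-pair row.

**Gap policy.** θ_k(i,j) is undefined when either residue is a gap;
correlations use the intersection of defined pairs; columns with gap
fraction above 0.1 are skipped entirely (configurable). A correlation is
only reported when the defined-pair overlap is at least max(10, half of
all sequence pairs) and both restrictions are non-constant — tiny overlaps
and degenerate columns otherwise produce spurious |r| = 1.

**Numerics.** The all-against-all correlation matrix is computed with
masked matrix products on per-column-centered data (pairwise-complete
observations). Centering bounds the summands, so the five-matmul
formulation agrees with a per-pair two-pass Pearson to ~1e−15 (checked
against `np.corrcoef` on random instances); variance below 1e−9 is treated
as constant. Detection is deterministic for fixed input.

**Intra vs inter.** Intra-molecular mode scans all column pairs of one
family alignment; inter-molecular mode scans only A-columns × B-columns of
a row-paired alignment (one row per ortholog pair, paired within species).
All threshold-passing pairs are retained and annotated with their group id
rather than filtering to multi-pair groups; a caller who wants only
recurrent groups can filter on the annotation.

## Dataset assembly

Candidates are assigned to their maximum-identity reference protein
("best hit"), with identity computed on aligned rows counting a gap
against a residue as a mismatch and ignoring gap–gap columns. Candidates
from whole-genome sources must additionally be the reference's best hit
within their species+source pool (bidirectional best hit) — for genome
sequences the sweep is assumed complete, so failing the reciprocal test
indicates the candidate is a paralog. Identity ties are broken toward the
lexicographically smaller reference id with a warning. Within each
species, same-reference sequences are collapsed by greedy centroid
clustering at 95% identity (members join the first cluster whose founder
they match at ≥ 0.95, in input order); this replaces an external
clustering tool whose exact behaviour is unspecified, preserving the
intent of removing within-species redundancy while keeping close paralogs
apart. One representative per cluster is kept with source priority
genome > interpro > blast, remaining ties resolved by a seeded random
choice. Thresholds are inclusive: identity ≥ 0.25 to the reference,
≥ 30 rows per analyzed dataset. Co-orthologs are paired per species by
full Cartesian product (2 × 2 orthologs → 4 row pairs), after clustering.

## Validation comparisons and nulls

All resampling p-values use the add-one convention
p = (1 + #{null ≥ observed}) / (1 + reps); p is never anti-conservative
and is bounded below by 1/(1+reps), matching "p < 0.001" reporting at
1000 replicates.

* **Distance enrichment.** Correlated pairs are mapped to structure
  residues (through the per-chain structure→reference mapping; unmapped
  pairs are dropped and counted) and the fraction within 15 Å and 10 Å is
  compared with the same fraction over all residue pairs of the structure.
  The null draws random residue-pair subsets of matching size. For
  homodimer-like structures the inter-chain lookup takes the minimum over
  the two chain assignments. Positions outside the mapped range are
  excluded, mirroring a structure that covers only part of the protein.
* **Pairing shuffle.** For inter-molecular results, B-rows are permuted
  against A-rows and the full detection re-run per replicate. The
  statistic is pluggable: detected-pair count, maximum inter-block
  correlation (continuous — the right choice for calibration studies,
  since the count null is nearly degenerate at realistic sizes), or any
  callable on the hit list.
* **Motif overlap.** Position-level coverages in reference coordinates:
  the fraction of motif positions hit by ≥ 1 correlated position, the
  fraction of correlated positions inside ≥ 1 motif, and their harmonic
  mean (F). *Consistent overlap* requires the two positions of a
  correlated pair to fall inside the two members of one complementary
  motif pair, molecule-matched. The null replaces each distinct position
  by a random position of the same protein — injectively, and consistently
  across all pairs sharing the position.
* **SNP overlap.** Exact-position matching of SNP residue positions
  against correlated positions, tabulated per class (synonymous /
  non-synonymous) and per analysis set (interacting / non-interacting);
  no tolerance window is applied.

## Conservation and entropy

Homologous positions are defined through a user-supplied master alignment
of the reference proteins — an explicit, auditable mapping rather than an
implicit one. A correlated pair (p, q) of protein X is *conserved* in Y
iff both positions map (neither falls on a gap in Y's master row) and the
mapped pair is correlated in Y; pairs with unmappable positions are
excluded from conserved-fraction summaries. Column entropy
S_k = −Σ_{j=1..20} P_jk ln P_jk is computed over amino-acid frequencies
with gaps excluded and the column renormalized (range 0 to ln 20 ≈ 3.0
nats). The entropy comparison contrasts, per (pair, other-protein) case,
the mean entropy of the two correlated positions with the mean entropy of
their homologous positions where no correlation was found; ties count as
"not higher". Inter-molecular *conserved groups* are mapped position
pairs recurring in more than one interaction pair.

## Helix periodicity

Helices are maximal runs of coil probability ≥ 0.5 with length ≥ 4
(probability tracks are inputs — any coiled-coil predictor can produce
them; interval calling from tracks is what this package owns). Pairs with
both positions inside one helix are binned by sequence separation
d = |i − j| in reference residue coordinates, pooled across proteins
(a per-protein option exists). On a helical face, contacts recur at
d ≈ 3, 4, 7 and avoid d = 2; the summary contrast is
Δ = pct(d=4) − pct(d=2). The null re-places stretches of the same number
and lengths uniformly at random, non-overlapping, within the analyzed
region; replicates in which no pair falls inside any stretch contribute a
neutral Δ = 0.

## The synthetic-data generator

The generator produces data with exactly the structure the analysis
assumes, so that recovering a planted signal is a meaningful test of the
statistic rather than of the simulator:

* **Star phylogeny.** Every sequence descends independently from one
  random ancestor. This removes shared-ancestry correlation — the main
  confounder of covariation analyses — so planted compensation is the
  only source of inter-column signal and false-positive rates are
  interpretable. A consequence is that the generator is *easier* than
  real data: passing recovery tests shows the statistic works when its
  assumptions hold, not that phylogenetic noise is handled (the method
  deliberately carries no tree correction).
* **Background process.** 20-state uniform-replacement substitution: per
  branch and site, at least one jump occurs with probability p_jump, and
  a jumped site is uniform over the alphabet. p_jump is solved in closed
  form so the expected pairwise proportion of differences p satisfies
  −ln(1 − p) = divergence_depth. Default depth 0.7 (≈ 50% pairwise
  differences) sits mid-range for families filtered at ≥ 25% identity;
  realized mean pairwise distance is within ±20% of target at the default
  sizes. Depths above −ln(1/20·19) (p ≥ 0.95) are unreachable and
  rejected. No indels are simulated, so alignment columns coincide with
  reference residue numbers. Default family size is 60 rows of 100
  columns — comfortably above the 30-row analysis minimum and the scale
  of the smaller real families.
* **Planted pairs.** A seeded alphabet bijection defines, for every state
  of the first column, exactly one compatible partner state (size-2
  joint-state sets — a charge-pair metaphor). Each sequence is *coupled*
  with probability q: its second residue is the compatible image of its
  first; otherwise the second column evolves as independent background.
  q = 0 is exactly background (verified); q = 0.9, the default, yields
  engine correlations ≈ 0.75–0.95 at the default depth — strong but not
  degenerate compensation.
* **Toy structure.** Chain A residues sit along a line at 6 Å spacing
  (CA + CB pseudo-atoms, ±0.3 Å jitter), chain B parallel at 30 Å;
  planted-pair partners are relocated next to their anchors within the
  contact distance (8 Å default). Sequence-distant non-planted pairs are
  therefore > 15 Å apart and enrichment of planted detections is
  guaranteed by construction. The structure is emitted as minimal PDB
  text so the real reader path is exercised.
* **Annotations.** With probability `fidelity`, motif pairs bracket
  planted pairs and non-synonymous SNPs avoid planted positions;
  otherwise both are placed at random. Coil tracks carry probability 0.8
  over declared helix regions and 0.1 elsewhere.

Everything is driven by one `numpy` Generator per entry point; outputs
are byte-identical for a fixed seed.

## Problem sizes used in the checks

The acceptance script and test suite run at desk scale: 20 simulation
seeds for recovery (60 rows × 100 columns, 5 intra + 3 inter planted
pairs at q = 0.9) and for interacting-vs-non-interacting discrimination
(40 rows × 40 + 40 columns, 3 planted inter pairs, 200-rep enrichment
nulls); null calibrations use 200–500 trials at 100 replicates each,
with 30-row, 25+25-column paired alignments for the pairing-shuffle null.
These sizes give binomial standard errors of ~0.01–0.015 on the reported
p ≤ 0.05 rates.

## Known limitations

* The published study percentages that depend on the original retrieved
  sequence set, the crystal structure mapping, externally predicted
  motifs and the SNP catalogue are not recomputable here; the package
  reproduces the *arithmetic* on the published counts and the *behaviour*
  of every procedure on generated data.
* No phylogenetic correction (clade removal, tree-aware nulls) is
  implemented; the statistic is tree-ignorant by design.
* The exact BLOSUM variant and gap policy of the original analysis are
  unrecorded; BLOSUM62 and the gap rules above are the package defaults
  and configurable.
* Greedy centroid clustering is order-dependent (input order is part of
  the contract); a different member order can change cluster boundaries
  near the 95% cutoff.
* `randomize_positions_pvalue` requires protein lengths at least as large
  as the number of distinct correlated positions per protein (the
  replacement map is injective).
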