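# corrmut

Correlated-mutation (coevolution) analysis for families of interacting
proteins, modelled on the analysis workflow used for the plant MADS-domain
transcription-factor network.

## The problem

When a deleterious substitution at one residue is compensated by a
substitution at another, the two positions accumulate **correlated
mutations** across a protein family. Such covarying position pairs tend to
be close in the 3D structure — within one protein, or across the interface
of an interacting pair. In a *family* of interacting proteins the signal
can additionally be checked for **conservation**: the same homologous
position pair detected as correlated in several family members (or in
several interacting pairs) is far more credible than a singleton hit, and
non-interacting pairs of family members provide a natural negative
control.

`corrmut` implements that full analysis as a reusable library + CLI:

1. **Dataset assembly** (`ortholog_assembly`) — best-hit ortholog
   assignment from pairwise sequence identity (bidirectional for
   whole-genome candidates), greedy 95%-identity redundancy clustering
   within species, representative selection (genome > interpro > blast),
   a 25% minimum-identity filter, a 30-row minimum per dataset, and
   per-species Cartesian pairing of co-orthologs for inter-molecular
   alignments.
2. **Coevolution statistic** (`caps_engine`) — for columns *k*, *l* of an
   alignment, score every sequence pair *(i, j)* with a BLOSUM62 entry
   θ_k(i,j) = B(a_ik, a_jk), center per column, optionally divide by the
   Poisson-corrected divergence time t_ij = −ln(1 − p_ij), and report the
   Pearson correlation r_kl of the two per-column vectors. Pairs with
   r ≥ 0.4 are correlated-mutation pairs; their graph's connected
   components are *correlated groups*.
3. **Validation** (`validation`) — distance enrichment within 15/10 Å
   against minimum heavy-atom distances from a PDB structure; overlap with
   predicted interaction-motif pairs (coverages, F-score, consistent
   overlap); overlap with synonymous / non-synonymous SNPs. Significance
   by resampling: random residue-pair subsets, re-detection after
   shuffling the row pairing, and consistent position randomization — all
   with add-one p-values.
4. **Conservation** (`conservation`) — homologous-position mapping through
   a master alignment, conserved / not-conserved calls, column entropy
   S_k = −Σ_j P_jk ln P_jk (nats, gaps excluded), entropy contrasts
   between conserved correlated positions and their quiet homologs, and
   recurring inter-molecular "conserved groups".
5. **Helix topology** (`helix_topology`) — coiled-coil helix calling from
   probability tracks (p ≥ 0.5, length ≥ 4), the within-helix separation
   histogram with the Δ = pct(i,i+4) − pct(i,i+2) periodicity contrast,
   a matched random-stretch null, and helix/domain contact tables.
6. **Synthetic data** (`synthetic_data`) — a star-phylogeny sequence
   simulator with planted compensatory column pairs of tunable strength
   *q*, interacting / non-interacting paired sets, a toy structure placing
   planted pairs in 3D contact, and motif/SNP/coil-track annotations, so
   the whole pipeline is testable without any downloads.

## Worked example

Simulate an interacting pair of 40-residue proteins for 50 species with
two planted inter-molecular compensatory pairs (8↔33 and 15↔10, q = 0.9),
detect inter-molecular correlated mutations with time correction, and test
their distance enrichment on a toy structure that places the planted
residues in contact:

```python
from corrmut.synthetic_data import (SimulationConfig, PlantedPair,
                                    simulate_paired_alignment, make_toy_structure)
from corrmut.caps_engine import detect_correlated_pairs
from corrmut.validation import distance_enrichment

planted = [PlantedPair(8, 33, "inter", q=0.9), PlantedPair(15, 10, "inter", q=0.9)]
cfg = SimulationConfig(seed=42, n_species=50, length=40, planted_pairs=planted)
pa = simulate_paired_alignment(cfg, interacting=True)
pairs = detect_correlated_pairs(pa, "inter", cutoff=0.4, time_correction=True)
for p in pairs:
    print(f"  {p.mol_a}:{p.col_a} -- {p.mol_b}:{p.col_b}   r = {p.r:.2f}   group {p.group_id}")
toy = make_toy_structure(cfg.length, planted, seed=42)
pos = [(("A", p.ref_a), ("B", p.ref_b)) for p in pairs]
for e in distance_enrichment(pos, toy.distances, mode="inter",
                             thresholds=[15.0, 10.0], reps=1000, seed=0):
    print(f"within {e.threshold:.0f} A: observed {100*e.observed_fraction:.0f}% "
          f"vs background {100*e.background_fraction:.1f}%  (p = {e.p_value:.3f})")
```

prints

```
  A:8 -- B:33   r = 0.90   group 0
  A:15 -- B:10   r = 0.77   group 1
within 15 A: observed 100% vs background 0.6%  (p = 0.001)
within 10 A: observed 100% vs background 0.4%  (p = 0.001)
```

Both planted pairs are recovered (and nothing else); 100% of the detected
residue pairs lie within 15 Å although only 0.6% of all inter-chain
residue pairs do, and no random subset of residue pairs of the same size
reaches that enrichment in 1000 draws (add-one p = 1/1001).

The same steps are available from the shell:

```bash
corrmut simulate --config sim.json --outdir fixtures/
corrmut caps --alignment fixtures/family.fasta --out pairs.tsv
corrmut validate-structure --pairs pairs.tsv --pdb fixtures/structure.pdb --out report.json
corrmut helix --track fixtures/tracks.tsv --pairs pairs.tsv --out helix.json
```

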