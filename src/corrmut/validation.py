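"""Validation of correlated-mutation results against independent data.

Three comparisons, each with a resampling null:

* **Structure**: are correlated residue pairs enriched at short distances
  (within 15 and 10 Å) relative to all residue pairs of the structure?
  Null: random residue-pair subsets of matching size.  A second, stronger
  null for inter-molecular results re-runs the whole detection after
  shuffling the row pairing of the two alignments.
* **Interaction motifs**: position-level overlap between correlated
  positions and predicted interaction motifs, summarized by the F-score
  (harmonic mean of the two coverages) and by "consistent overlap" of
  correlated pairs with complementary motif pairs.  Null: replace each
  correlated position by a random sequence position (consistently across
  all pairs sharing the position).
* **SNPs**: fraction of (non-)synonymous SNPs that land on a correlated
  position, tabulated separately for interacting and non-interacting
  analysis sets.

All p-values use the add-one convention p = (1 + #{null >= obs}) / (1 + reps),
which is never anti-conservative and bounds p below by 1/(1+reps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .caps_engine import CorrelatedPair, _detect_inter_raw
from .seqdata import (
    ContentError,
    MotifAnnotation,
    PairedAlignment,
    SNPRecord,
    StructureDistances,
)

Position = tuple[str, int]  # (protein, reference residue)
PositionPair = tuple[Position, Position]


# ---------------------------------------------------------------------------
# Resampling primitives
# ---------------------------------------------------------------------------

def add_one_pvalue(null: np.ndarray, observed: float) -> float:
    null = np.asarray(null, dtype=float)
    return float((1 + np.sum(null >= observed)) / (1 + null.size))


def random_subset_pvalue(
    background: Sequence[float] | np.ndarray,
    k: int,
    statistic: Callable[[np.ndarray], float],
    observed: float,
    reps: int = 1000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, np.ndarray]:
    """P-value from random size-k subsets of a background pool.

    Each replicate draws k elements without replacement and evaluates the
    statistic; p is the add-one fraction of replicates at or above the
    observed value.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(seed)
    pool = np.asarray(background, dtype=float)
    if k > pool.size:
        raise ContentError("subset size exceeds background size")
    null = np.empty(reps)
    for i in range(reps):
        null[i] = statistic(rng.choice(pool, size=k, replace=False))
    return add_one_pvalue(null, observed), null


# ---------------------------------------------------------------------------
# Structure-distance enrichment
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    threshold: float
    observed_fraction: float
    background_fraction: float
    p_value: float
    n_evaluated: int
    n_unmapped: int = 0


def _map_pairs_to_distances(
    cm_pairs: Sequence[CorrelatedPair] | Sequence[PositionPair],
    distances: StructureDistances,
    mode: str,
    chain: str | None,
    chain_pair: tuple[str, str] | None,
) -> tuple[list[float], int]:
    """Resolve correlated pairs (reference coordinates) to structure distances.

    Intra mode maps both residues onto one chain; inter mode maps the two
    residues onto the two chains, taking the minimum over the two chain
    assignments (for homodimer-like structures the assignment is arbitrary).
    Unmapped pairs are dropped and counted.
    """
    vals: list[float] = []
    unmapped = 0
    for p in cm_pairs:
        if isinstance(p, CorrelatedPair):
            ra, rb = p.ref_a, p.ref_b
        else:
            (_, ra), (_, rb) = p
        if ra is None or rb is None:
            unmapped += 1
            continue
        if mode == "intra":
            c = chain or distances.chains[0]
            si = distances.reference_to_structure(c, ra)
            sj = distances.reference_to_structure(c, rb)
            if si is None or sj is None:
                unmapped += 1
                continue
            vals.append(distances.distance(c, si, c, sj))
        else:
            ca, cb = chain_pair or tuple(distances.chains[:2])
            d_candidates = []
            for cx, cy in ((ca, cb), (cb, ca)):
                si = distances.reference_to_structure(cx, ra)
                sj = distances.reference_to_structure(cy, rb)
                if si is not None and sj is not None:
                    d_candidates.append(distances.distance(cx, si, cy, sj))
            if not d_candidates:
                unmapped += 1
                continue
            vals.append(min(d_candidates))
    return vals, unmapped


def distance_enrichment(
    cm_pairs: Sequence[CorrelatedPair] | Sequence[PositionPair],
    distances: StructureDistances,
    mode: str = "intra",
    thresholds: Sequence[float] = (15.0, 10.0),
    chain: str | None = None,
    chain_pair: tuple[str, str] | None = None,
    reps: int = 1000,
    seed: int | None = None,
) -> list[EnrichmentResult]:
    """Fraction of correlated residue pairs within each distance threshold,
    against the background of all residue pairs, with a random-subset p-value.
    """
    observed_d, unmapped = _map_pairs_to_distances(
        cm_pairs, distances, mode, chain, chain_pair
    )
    if not observed_d:
        raise ContentError("no correlated pairs could be mapped to the structure")
    if mode == "intra":
        c = chain or distances.chains[0]
        background = distances.pair_distances(c, c)
    else:
        ca, cb = chain_pair or tuple(distances.chains[:2])
        background = distances.pair_distances(ca, cb)
    observed_d = np.asarray(observed_d)
    results = []
    rng = np.random.default_rng(seed)
    for thr in thresholds:
        obs_frac = float(np.mean(observed_d <= thr))
        bg_frac = float(np.mean(background <= thr))
        stat = lambda sub, t=thr: float(np.mean(sub <= t))
        p, _ = random_subset_pvalue(
            background, observed_d.size, stat, obs_frac, reps=reps, rng=rng
        )
        results.append(
            EnrichmentResult(thr, obs_frac, bg_frac, p, observed_d.size, unmapped)
        )
    return results


def shuffle_pairing_null(
    paired: PairedAlignment,
    reps: int = 100,
    seed: int | None = None,
    cutoff: float = 0.4,
    time_correction: bool = True,
    statistic: str | Callable[[list], float] = "n_pairs",
    max_gap_frac: float = 0.1,
) -> tuple[float, np.ndarray, float]:
    """Null for inter-molecular signal: shuffle the row pairing and re-detect.

    Per replicate, B-rows are permuted against A-rows and the full
    inter-molecular detection is re-run.  ``statistic`` is evaluated on
    each detection outcome: "n_pairs" (count of threshold-passing pairs),
    "max_r" (maximum inter-column correlation; continuous, preferable for
    calibration), or a callable on the hit list.  Returns
    (observed, null distribution, add-one p).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    seqs_a = paired.sequences_a()
    seqs_b = paired.sequences_b()

    def evaluate(sb: list[str]) -> float:
        hits, block = _detect_inter_raw(
            seqs_a, sb, cutoff=cutoff, time_correction=time_correction,
            max_gap_frac=max_gap_frac,
        )
        if statistic == "n_pairs":
            return float(len(hits))
        if statistic == "max_r":
            finite = block[np.isfinite(block)]
            return float(finite.max()) if finite.size else -np.inf
        return float(statistic(hits))

    observed = evaluate(seqs_b)
    null = np.empty(reps)
    for i in range(reps):
        perm = rng.permutation(len(seqs_b))
        null[i] = evaluate([seqs_b[j] for j in perm])
    return observed, null, add_one_pvalue(null, observed)


# ---------------------------------------------------------------------------
# Motif overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    coverage_motif: float  # fraction of motif positions hit by >= 1 cm position
    coverage_cm: float  # fraction of cm positions inside >= 1 motif
    f_score: float
    n_motif_positions: int
    n_cm_positions: int
    p_value: float | None = None


def fscore(coverage_a: float, coverage_b: float) -> float:
    """Harmonic mean of two coverages; 0 when either coverage is 0."""
    if coverage_a <= 0 or coverage_b <= 0:
        return 0.0
    return 2 * coverage_a * coverage_b / (coverage_a + coverage_b)


def _overlap_counts(
    cm_positions: Iterable[Position], motifs: Sequence[MotifAnnotation]
) -> tuple[int, int, int, int]:
    cm_set = set(cm_positions)
    motif_positions = {
        (m.protein, pos) for m in motifs for pos in m.positions()
    }
    if not motif_positions:
        raise ContentError("empty motif set: coverages undefined")
    covered_motif = len(motif_positions & cm_set)
    covered_cm = sum(1 for p in cm_set if p in motif_positions)
    return covered_motif, len(motif_positions), covered_cm, len(cm_set)


def motif_overlap(
    cm_positions: Iterable[Position], motifs: Sequence[MotifAnnotation]
) -> OverlapResult:
    """Position-level overlap between correlated positions and motifs."""
    cm_mot, n_mot, cov_cm, n_cm = _overlap_counts(cm_positions, motifs)
    if n_cm == 0:
        raise ContentError("no correlated positions supplied")
    a = cm_mot / n_mot
    b = cov_cm / n_cm
    return OverlapResult(a, b, fscore(a, b), n_mot, n_cm)


def aggregate_motif_overlap(
    items: Sequence[tuple[Iterable[Position], Sequence[MotifAnnotation]]]
) -> OverlapResult:
    """Pool overlap counts over several analysis sets (interaction pairs)."""
    tm = tc = nm = nc = 0
    for cm_positions, motifs in items:
        cm_mot, n_mot, cov_cm, n_cm = _overlap_counts(cm_positions, motifs)
        tm += cm_mot
        nm += n_mot
        tc += cov_cm
        nc += n_cm
    if nm == 0 or nc == 0:
        raise ContentError("empty pooled overlap")
    a, b = tm / nm, tc / nc
    return OverlapResult(a, b, fscore(a, b), nm, nc)


def pair_motifs(motifs: Sequence[MotifAnnotation]) -> list[tuple[MotifAnnotation, MotifAnnotation]]:
    """Resolve partner links into unique complementary motif pairs."""
    by_id = {m.motif_id: m for m in motifs}
    pairs = []
    seen = set()
    for m in motifs:
        if m.partner_motif_id is None or m.motif_id in seen:
            continue
        partner = by_id.get(m.partner_motif_id)
        if partner is None:
            continue
        if partner.protein == m.protein:
            raise ContentError(
                f"motif pair {m.motif_id}/{partner.motif_id} spans a single molecule"
            )
        seen.update({m.motif_id, partner.motif_id})
        pairs.append((m, partner))
    return pairs


def consistent_overlap(
    cm_pairs: Sequence[tuple[str, PositionPair]],
    motifs: Sequence[MotifAnnotation],
) -> dict[tuple[str, str], set[str]]:
    """Interaction pairs in which each motif pair overlaps consistently.

    ``cm_pairs`` are (interaction_id, ((protein_a, pos_a), (protein_b, pos_b)))
    records.  A correlated pair is consistent with a motif pair when its two
    positions fall inside the two motifs respectively, molecule-matched.
    Returns motif-pair id -> set of interaction ids with >= 1 consistent pair.
    """
    out: dict[tuple[str, str], set[str]] = {}
    for ma, mb in pair_motifs(motifs):
        key = (ma.motif_id, mb.motif_id)
        out[key] = set()
        for interaction_id, ((pa, xa), (pb, xb)) in cm_pairs:
            direct = pa == ma.protein and xa in ma and pb == mb.protein and xb in mb
            swapped = pb == ma.protein and xb in ma and pa == mb.protein and xa in mb
            if direct or swapped:
                out[key].add(interaction_id)
    return out


def randomize_positions_pvalue(
    cm_pairs: Sequence[PositionPair],
    lengths: Mapping[str, int],
    motifs: Sequence[MotifAnnotation],
    reps: int = 1000,
    seed: int | None = None,
) -> tuple[float, float, np.ndarray]:
    """Null for motif overlap: replace each correlated position by a random one.

    The replacement map is a per-replicate injection (distinct positions map
    to distinct random positions within the same protein) applied
    consistently across all pairs sharing a position.  Returns
    (observed F, add-one p, null F distribution).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    positions = sorted({p for pair in cm_pairs for p in pair})
    observed = motif_overlap(positions, motifs).f_score
    by_protein: dict[str, list[Position]] = {}
    for p in positions:
        by_protein.setdefault(p[0], []).append(p)
    null = np.empty(reps)
    for i in range(reps):
        mapping: dict[Position, Position] = {}
        for protein, plist in by_protein.items():
            new = rng.choice(lengths[protein], size=len(plist), replace=False) + 1
            for old, pos in zip(plist, new):
                mapping[old] = (protein, int(pos))
        randomized = {mapping[p] for pair in cm_pairs for p in pair}
        null[i] = motif_overlap(sorted(randomized), motifs).f_score
    return observed, add_one_pvalue(null, observed), null


# ---------------------------------------------------------------------------
# SNP overlap
# ---------------------------------------------------------------------------

@dataclass
class SnpOverlapResult:
    """Per-class counts of SNPs on / off correlated-mutation positions."""

    counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    def fraction(self, snp_class: str) -> float | None:
        overlap, no_overlap = self.counts.get(snp_class, (0, 0))
        total = overlap + no_overlap
        return overlap / total if total else None


def snp_overlap(
    snps: Sequence[SNPRecord], cm_positions: Iterable[Position]
) -> SnpOverlapResult:
    """Count SNPs whose residue position is a correlated-mutation position.

    Overlap is exact-position matching in reference coordinates.
    """
    cm_set = set(cm_positions)
    result = SnpOverlapResult()
    for snp in snps:
        overlap, no_overlap = result.counts.get(snp.snp_class, (0, 0))
        if (snp.protein, snp.position) in cm_set:
            overlap += 1
        else:
            no_overlap += 1
        result.counts[snp.snp_class] = (overlap, no_overlap)
    return result
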