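"""Dataset assembly: best-hit orthology, redundancy clustering, filtering.

Reproduces the construction of ortholog families around a set of reference
(Arabidopsis) proteins: each candidate sequence is assigned to its
maximum-identity reference ("best hit"; bidirectionally confirmed for
whole-genome candidates), near-identical sequences within a species are
collapsed at 95% identity by greedy centroid clustering, one representative
per cluster is kept with source priority genome > interpro > blast, and
candidates below 25% identity to their reference are removed.  Families
and paired datasets enter downstream analysis only when at least 30 rows
survive.  Interacting-pair datasets take, per species, the full Cartesian
product of the co-orthologs of the two partners.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .seqdata import ContentError, pairwise_identity

logger = logging.getLogger(__name__)

SOURCE_PRIORITY = {"genome": 0, "interpro": 1, "blast": 2}


@dataclass(frozen=True)
class CandidateSeq:
    seq_id: str
    species: str
    source: str
    seq: str


@dataclass(frozen=True)
class BestHit:
    reference: str
    identity: float


@dataclass
class OrthologAssignment:
    """Map candidate seq_id -> best reference, with bidirectional flags."""

    hits: dict[str, BestHit]
    candidates: dict[str, CandidateSeq]
    bidirectional_ok: dict[str, bool] = field(default_factory=dict)

    def by_reference(self) -> dict[str, list[CandidateSeq]]:
        out: dict[str, list[CandidateSeq]] = {}
        for cid, hit in self.hits.items():
            out.setdefault(hit.reference, []).append(self.candidates[cid])
        return out


IdentityFn = Callable[[str, str], float]


def assign_best_hits(
    candidates: Sequence[CandidateSeq],
    references: Mapping[str, str],
    identity_fn: IdentityFn | None = None,
    bidirectional_sources: Iterable[str] = ("genome",),
) -> OrthologAssignment:
    """Assign each candidate to its maximum-identity reference.

    Candidates from ``bidirectional_sources`` are retained only if they are
    also the best hit of that reference within their species+source pool
    (bidirectional best hit).  Identity ties between references are broken
    toward the lexicographically smaller reference id, with a warning.
    """
    if not references:
        raise ContentError("empty reference set")
    ident = identity_fn or pairwise_identity
    bidirectional = set(bidirectional_sources)
    seen: set[str] = set()
    for c in candidates:
        if c.seq_id in seen:
            raise ContentError(f"duplicate candidate id {c.seq_id}")
        seen.add(c.seq_id)

    identities: dict[str, dict[str, float]] = {}
    hits: dict[str, BestHit] = {}
    for c in candidates:
        scores = {ref_id: ident(c.seq, ref_seq) for ref_id, ref_seq in references.items()}
        identities[c.seq_id] = scores
        best = max(scores.values())
        best_refs = sorted(r for r, s in scores.items() if s == best)
        if len(best_refs) > 1:
            warnings.warn(
                f"candidate {c.seq_id}: identity tie between {best_refs}; "
                f"assigned to {best_refs[0]}"
            )
        hits[c.seq_id] = BestHit(best_refs[0], best)

    bidirectional_ok: dict[str, bool] = {}
    kept: dict[str, BestHit] = {}
    cand_by_id = {c.seq_id: c for c in candidates}
    for c in candidates:
        hit = hits[c.seq_id]
        if c.source not in bidirectional:
            bidirectional_ok[c.seq_id] = True
            kept[c.seq_id] = hit
            continue
        pool = [
            o for o in candidates
            if o.species == c.species and o.source == c.source
        ]
        pool_scores = [(identities[o.seq_id][hit.reference], o.seq_id) for o in pool]
        best_score = max(s for s, _ in pool_scores)
        best_ids = sorted(sid for s, sid in pool_scores if s == best_score)
        ok = best_ids[0] == c.seq_id
        bidirectional_ok[c.seq_id] = ok
        if ok:
            kept[c.seq_id] = hit
        else:
            logger.info(
                "dropping %s: not the reciprocal best hit of %s in %s/%s",
                c.seq_id, hit.reference, c.species, c.source,
            )
    return OrthologAssignment(
        kept, {cid: cand_by_id[cid] for cid in kept}, bidirectional_ok
    )


def filter_min_identity(
    assignment: OrthologAssignment, threshold: float = 0.25
) -> OrthologAssignment:
    """Remove candidates with identity below the threshold (inclusive keep)."""
    kept = {cid: h for cid, h in assignment.hits.items() if h.identity >= threshold}
    return OrthologAssignment(
        kept,
        {cid: assignment.candidates[cid] for cid in kept},
        {cid: assignment.bidirectional_ok.get(cid, True) for cid in kept},
    )


def cluster_within_species(
    members: Sequence[CandidateSeq],
    identity_fn: IdentityFn | None = None,
    cutoff: float = 0.95,
) -> list[list[CandidateSeq]]:
    """Greedy centroid clustering of same-species, same-reference sequences.

    Members are processed in input order; each joins the first cluster whose
    centroid (founder) identity is >= cutoff, else founds a new cluster.
    """
    ident = identity_fn or pairwise_identity
    clusters: list[list[CandidateSeq]] = []
    for m in members:
        for cluster in clusters:
            if ident(m.seq, cluster[0].seq) >= cutoff:
                cluster.append(m)
                break
        else:
            clusters.append([m])
    return clusters


def select_representative(
    cluster: Sequence[CandidateSeq], rng: np.random.Generator
) -> CandidateSeq:
    """Pick a cluster representative: genome > interpro > blast, ties random."""
    if not cluster:
        raise ContentError("empty cluster")
    best = min(SOURCE_PRIORITY.get(m.source, 99) for m in cluster)
    top = [m for m in cluster if SOURCE_PRIORITY.get(m.source, 99) == best]
    return top[int(rng.integers(len(top)))]


def apply_min_rows(n_rows: int, minimum: int = 30) -> bool:
    """Keep/drop decision on dataset size (inclusive threshold)."""
    keep = n_rows >= minimum
    logger.info("min-rows check: %d rows, threshold %d -> %s",
                n_rows, minimum, "keep" if keep else "drop")
    return keep


def build_intermolecular_pairs(
    orthos_a_by_species: Mapping[str, Sequence[str]],
    orthos_b_by_species: Mapping[str, Sequence[str]],
) -> list[tuple[str, str, str]]:
    """Per-species Cartesian product of co-orthologs of two partners.

    Returns (species, a_id, b_id) triples; two co-orthologs on each side
    within one species yield 2 * 2 = 4 combinations.
    """
    pairs: list[tuple[str, str, str]] = []
    for species in sorted(set(orthos_a_by_species) & set(orthos_b_by_species)):
        for a in orthos_a_by_species[species]:
            for b in orthos_b_by_species[species]:
                pairs.append((species, a, b))
    return pairs


def assemble_family(
    candidates: Sequence[CandidateSeq],
    references: Mapping[str, str],
    identity_fn: IdentityFn | None = None,
    bidirectional_sources: Iterable[str] = ("genome",),
    min_identity: float = 0.25,
    cluster_cutoff: float = 0.95,
    seed: int = 0,
) -> dict[str, list[CandidateSeq]]:
    """Full assembly pipeline: best hits -> identity filter -> clustering ->
    representatives.  Returns retained candidates keyed by reference id.

    Deterministic for a fixed seed and fixed candidate order.
    """
    rng = np.random.default_rng(seed)
    assignment = assign_best_hits(
        candidates, references, identity_fn, bidirectional_sources
    )
    assignment = filter_min_identity(assignment, min_identity)
    result: dict[str, list[CandidateSeq]] = {ref: [] for ref in references}
    for ref_id, members in sorted(assignment.by_reference().items()):
        by_species: dict[str, list[CandidateSeq]] = {}
        for m in members:
            by_species.setdefault(m.species, []).append(m)
        for species in sorted(by_species):
            for cluster in cluster_within_species(
                by_species[species], identity_fn, cluster_cutoff
            ):
                result[ref_id].append(select_representative(cluster, rng))
    return result
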