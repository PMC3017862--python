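"""Conservation of correlated mutations across family members.

A correlated position pair found in protein X is "conserved" in protein Y
when the homologous positions (through a master alignment of the reference
proteins) form a correlated pair in Y as well.  For pairs that are not
conserved, column entropy distinguishes two explanations: the homologous
positions are themselves invariant (low entropy), or they vary but without
correlation.  The same recurrence idea applies inter-molecularly: position
pairs detected (via homology) in more than one interaction pair form
"conserved groups", counted separately for interacting and non-interacting
sets.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .seqdata import AMINO_ACIDS, GAP, ContentError, FamilyAlignment

Pair = tuple[int, int]  # reference-coordinate position pair within one protein


class HomologyMap:
    """Bijection between each protein's residues and master-alignment columns."""

    def __init__(self, master: Mapping[str, str]) -> None:
        lengths = {len(s) for s in master.values()}
        if len(lengths) > 1:
            raise ContentError("master alignment rows have unequal lengths")
        self.master = dict(master)
        self._res_to_col: dict[str, dict[int, int]] = {}
        self._col_to_res: dict[str, dict[int, int]] = {}
        for protein, seq in self.master.items():
            r2c: dict[int, int] = {}
            c2r: dict[int, int] = {}
            residue = 0
            for col, ch in enumerate(seq, start=1):
                if ch != GAP:
                    residue += 1
                    r2c[residue] = col
                    c2r[col] = residue
            self._res_to_col[protein] = r2c
            self._col_to_res[protein] = c2r

    @property
    def proteins(self) -> list[str]:
        return sorted(self.master)

    def residue_to_column(self, protein: str, residue: int) -> int:
        return self._res_to_col[protein][residue]

    def column_to_residue(self, protein: str, column: int) -> int | None:
        return self._col_to_res[protein].get(column)

    def map_position(self, src: str, residue: int, dst: str) -> int | None:
        """Homologous residue of ``src``:``residue`` in ``dst`` (None if gap)."""
        col = self._res_to_col[src].get(residue)
        if col is None:
            raise IndexError(f"residue {residue} out of range for {src}")
        return self._col_to_res[dst].get(col)


def build_homology_map(master: Mapping[str, str] | FamilyAlignment) -> HomologyMap:
    """Build the residue <-> master-column mapping from a master alignment."""
    if isinstance(master, FamilyAlignment):
        master = {r.seq_id: r.seq for r in master.rows}
    return HomologyMap(master)


@dataclass
class ConservationCall:
    """Conservation status of one correlated pair across the other proteins."""

    protein: str
    pair: Pair
    status: dict[str, str] = field(default_factory=dict)  # other protein -> status

    @property
    def conserved_in(self) -> list[str]:
        return sorted(p for p, s in self.status.items() if s == "conserved")

    @property
    def conserved_any(self) -> bool:
        return any(s == "conserved" for s in self.status.values())

    @property
    def mappable_proteins(self) -> list[str]:
        return sorted(p for p, s in self.status.items() if s != "unmappable")


def classify_conservation(
    cm_pairs_by_protein: Mapping[str, Iterable[Pair]],
    homology: HomologyMap,
) -> list[ConservationCall]:
    """Designate each correlated pair conserved / not-conserved / unmappable
    in every other analyzed protein.

    Pair (p, q) of X is conserved in Y iff both positions map through the
    master alignment and the mapped (unordered) pair is correlated in Y.
    """
    normalized = {
        prot: {tuple(sorted(p)) for p in pairs}
        for prot, pairs in cm_pairs_by_protein.items()
    }
    calls: list[ConservationCall] = []
    for protein in sorted(normalized):
        for pair in sorted(normalized[protein]):
            call = ConservationCall(protein, pair)
            for other in sorted(normalized):
                if other == protein:
                    continue
                mp = homology.map_position(protein, pair[0], other)
                mq = homology.map_position(protein, pair[1], other)
                if mp is None or mq is None:
                    call.status[other] = "unmappable"
                elif tuple(sorted((mp, mq))) in normalized[other]:
                    call.status[other] = "conserved"
                else:
                    call.status[other] = "not-conserved"
            calls.append(call)
    return calls


def conserved_fraction(calls: Sequence[ConservationCall]) -> float:
    """Fraction of correlated pairs conserved in at least one other protein.

    Pairs with no mappable homolog in any other protein are excluded.
    """
    eligible = [c for c in calls if c.mappable_proteins]
    if not eligible:
        raise ContentError("no pairs with mappable homologs")
    return sum(c.conserved_any for c in eligible) / len(eligible)


def column_entropy(alignment: FamilyAlignment | Sequence[str], column: int) -> float:
    """Shannon entropy S_k = -sum_j P_jk ln P_jk of an alignment column (nats).

    Frequencies are over the 20 amino acids only; gaps are excluded and the
    column is renormalized over its non-gap count.
    """
    rows = (
        alignment.sequences() if isinstance(alignment, FamilyAlignment) else alignment
    )
    residues = [r[column - 1].upper() for r in rows]
    counts = Counter(ch for ch in residues if ch in AMINO_ACIDS)
    total = sum(counts.values())
    if total == 0:
        raise ContentError(f"column {column} has no non-gap residues")
    return -sum((c / total) * math.log(c / total) for c in counts.values())


@dataclass
class EntropyComparison:
    """Entropy contrast between conserved correlated positions and their
    homologous positions where the correlation was not observed."""

    mean_correlated: float
    sd_correlated: float
    mean_homologous: float
    sd_homologous: float
    fraction_higher: float  # fraction of cases with strict entropy excess
    n_cases: int


def entropy_comparison(
    calls: Sequence[ConservationCall],
    alignments: Mapping[str, FamilyAlignment],
    homology: HomologyMap,
    which: str = "conserved",
) -> EntropyComparison:
    """Compare column entropy at correlated positions vs their homologs.

    ``which="conserved"`` analyzes pairs conserved in >= 1 other protein,
    taking as cases the proteins where the pair is *not* conserved (the
    homologous, non-correlated positions); ``which="non-conserved"``
    analyzes pairs conserved nowhere.  Each case contributes the mean
    entropy of the two positions on either side; ties count as not-higher.
    """
    ent_corr: list[float] = []
    ent_hom: list[float] = []
    higher = 0
    n_cases = 0
    for call in calls:
        if which == "conserved" and not call.conserved_any:
            continue
        if which == "non-conserved" and call.conserved_any:
            continue
        aln_x = alignments[call.protein]
        e_self = np.mean([
            column_entropy(aln_x, aln_x.reference_to_column(pos))
            for pos in call.pair
        ])
        for other, status in call.status.items():
            if status != "not-conserved":
                continue
            aln_y = alignments[other]
            mp = homology.map_position(call.protein, call.pair[0], other)
            mq = homology.map_position(call.protein, call.pair[1], other)
            if mp is None or mq is None:
                continue
            e_other = np.mean([
                column_entropy(aln_y, aln_y.reference_to_column(pos))
                for pos in (mp, mq)
            ])
            ent_corr.append(float(e_self))
            ent_hom.append(float(e_other))
            higher += e_self > e_other
            n_cases += 1
    if n_cases == 0:
        raise ContentError("no comparable cases")
    return EntropyComparison(
        float(np.mean(ent_corr)), float(np.std(ent_corr)),
        float(np.mean(ent_hom)), float(np.std(ent_hom)),
        higher / n_cases, n_cases,
    )


def identity_conservation_correlation(
    calls: Sequence[ConservationCall],
    identities: Mapping[tuple[str, str], float],
) -> float:
    """Spearman rank correlation between protein-pair sequence identity and
    the fraction of pairs conserved between the two proteins (a report
    field; no association is expected a priori)."""
    from scipy.stats import spearmanr

    frac: dict[tuple[str, str], list[int]] = {}
    for call in calls:
        for other, status in call.status.items():
            if status == "unmappable":
                continue
            key = tuple(sorted((call.protein, other)))
            frac.setdefault(key, []).append(1 if status == "conserved" else 0)
    keys = [k for k in frac if k in identities]
    if len(keys) < 3:
        raise ContentError("need at least 3 protein pairs")
    x = [identities[k] for k in keys]
    y = [float(np.mean(frac[k])) for k in keys]
    return float(spearmanr(x, y).statistic)


@dataclass
class ConservedGroup:
    """A position pair (in master coordinates) recurring across interaction
    pairs, with the interaction pairs it occurs in."""

    master_pair: tuple[int, int]
    interaction_pairs: list[tuple[str, str]]


def intermolecular_conserved_groups(
    cm_pairs_by_interaction: Mapping[tuple[str, str], Iterable[Pair]],
    homology: HomologyMap,
) -> list[ConservedGroup]:
    """Groups of inter-molecular correlated positions recurring in > 1
    interaction pair (both positions mapped to master coordinates).

    ``cm_pairs_by_interaction`` maps (protein_a, protein_b) to pairs of
    reference residues (pos_in_a, pos_in_b).
    """
    occurrences: dict[tuple[int, int], list[tuple[str, str]]] = {}
    for (prot_a, prot_b), pairs in cm_pairs_by_interaction.items():
        for pos_a, pos_b in pairs:
            col_a = homology.residue_to_column(prot_a, pos_a)
            col_b = homology.residue_to_column(prot_b, pos_b)
            key = tuple(sorted((col_a, col_b)))
            if (prot_a, prot_b) not in occurrences.setdefault(key, []):
                occurrences[key].append((prot_a, prot_b))
    return [
        ConservedGroup(key, sorted(ips))
        for key, ips in sorted(occurrences.items())
        if len(ips) > 1
    ]
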