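"""Site-coevolution statistic for multiple sequence alignments.

The statistic follows the substitution-matrix lineage of correlated-mutation
methods: for every alignment column, the variability seen by each pair of
sequences is scored with a BLOSUM substitution matrix; the resulting
per-column vectors (optionally normalized by the Poisson-corrected
divergence time of each sequence pair, which down-weights substitutions
that had long to accumulate by chance) are centered and compared between
columns with the Pearson correlation.  Column pairs whose correlation
exceeds a cutoff (0.4 by default) are reported as correlated-mutation
pairs, intra-molecularly (all column pairs of one alignment) or
inter-molecularly (columns of molecule A against columns of molecule B of
a row-paired alignment).  Threshold-passing pairs are grouped into
"correlated groups" -- connected components of the position-pair graph.

Gap policy (the alignments this method targets are gappy): a sequence-pair
entry is undefined at a column if either residue is a gap; correlations
use the intersection of defined pairs; columns whose gap fraction exceeds
``max_gap_frac`` are skipped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .seqdata import (
    GAP,
    ContentError,
    FamilyAlignment,
    PairedAlignment,
    encode_rows,
)

__all__ = [
    "blosum_matrix",
    "poisson_distance",
    "pairwise_poisson_distances",
    "SiteVariabilityVector",
    "site_variability_vector",
    "site_pair_correlation",
    "CorrelatedPair",
    "CorrelatedGroup",
    "detect_correlated_pairs",
    "correlation_matrix",
    "correlated_groups",
    "assign_groups",
]

_EPS_VAR = 1e-9


@lru_cache(maxsize=None)
def blosum_matrix(name: str = "BLOSUM62") -> np.ndarray:
    """20x20 substitution-score matrix over the canonical amino-acid order."""
    from Bio.Align import substitution_matrices

    from .seqdata import AMINO_ACIDS

    mat = substitution_matrices.load(name)
    out = np.empty((20, 20), dtype=float)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = mat[a, b]
    return out


def poisson_distance(row_a: str, row_b: str) -> float:
    """Poisson-corrected amino-acid distance t = -ln(1 - p).

    ``p`` is the fraction of differing residues over columns where both
    rows are non-gap.  ``p == 1`` (no shared residue) is outside the
    model's domain and raises.
    """
    enc = encode_rows([row_a, row_b])
    both = (enc[0] >= 0) & (enc[1] >= 0)
    n = int(both.sum())
    if n == 0:
        raise ContentError("no comparable columns between rows")
    p = float((enc[0][both] != enc[1][both]).sum()) / n
    if p >= 1.0:
        raise ContentError("proportion of differences is 1: distance undefined")
    return -np.log(1.0 - p)


def _pair_indices(n_rows: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n_rows, k=1)


def pairwise_poisson_distances(enc: np.ndarray) -> np.ndarray:
    """Vector of Poisson distances over sequence pairs (i<j order).

    Pairs with p = 1 or no comparable columns get NaN (dropped downstream).
    """
    ii, jj = _pair_indices(enc.shape[0])
    a = enc[ii]
    b = enc[jj]
    both = (a >= 0) & (b >= 0)
    n = both.sum(axis=1)
    diff = ((a != b) & both).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n > 0, diff / np.maximum(n, 1), np.nan)
        t = np.where(p < 1.0, -np.log1p(-np.where(p < 1.0, p, 0.0)), np.nan)
    return t


def _raw_theta(enc: np.ndarray, blosum: np.ndarray) -> np.ndarray:
    """(n_cols, n_pairs) matrix of BLOSUM scores; NaN where either is a gap."""
    ii, jj = _pair_indices(enc.shape[0])
    a = enc[ii]  # (P, L)
    b = enc[jj]
    valid = (a >= 0) & (b >= 0)
    theta = blosum[np.clip(a, 0, None), np.clip(b, 0, None)]
    theta[~valid] = np.nan
    return theta.T.copy()  # (L, P)


def _variability_matrix(
    enc: np.ndarray,
    time_correction: bool = False,
    blosum_name: str = "BLOSUM62",
    max_gap_frac: float = 0.1,
) -> np.ndarray:
    """Centered (optionally time-normalized) variability matrix.

    Rows are alignment columns, columns are sequence pairs (i<j order);
    NaN marks undefined entries.  Columns with gap fraction above
    ``max_gap_frac`` are entirely NaN.
    """
    theta = _raw_theta(enc, blosum_matrix(blosum_name))
    gap_frac = (enc < 0).mean(axis=0)
    theta[gap_frac > max_gap_frac, :] = np.nan
    theta = _center(theta)
    if time_correction:
        # center before normalizing so a constant column stays all-zero
        t = pairwise_poisson_distances(enc)
        t = np.where((t > 0) & np.isfinite(t), t, np.nan)
        theta = _center(theta / t[np.newaxis, :])
    return theta


def _center(theta: np.ndarray) -> np.ndarray:
    """Subtract the per-column mean over defined entries (NaN-safe, quiet)."""
    finite = np.isfinite(theta)
    counts = finite.sum(axis=1, keepdims=True)
    sums = np.where(finite, theta, 0.0).sum(axis=1, keepdims=True)
    means = sums / np.maximum(counts, 1)
    return theta - means


@dataclass
class SiteVariabilityVector:
    """Per-column variability over sequence pairs, centered on its mean."""

    column: int  # 1-based alignment column
    values: np.ndarray  # (n_pairs,) centered scores, NaN = undefined
    pair_index: tuple[np.ndarray, np.ndarray]  # (i, j) row indices per entry

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_defined(self) -> int:
        return int(self.defined.sum())


def site_variability_vector(
    rows: Sequence[str],
    column: int,
    time_correction: bool = False,
    blosum: str = "BLOSUM62",
    max_gap_frac: float = 1.0,
) -> SiteVariabilityVector:
    """Variability vector of one column (1-based) of an aligned row set."""
    enc = encode_rows(list(rows))
    if not (1 <= column <= enc.shape[1]):
        raise IndexError(f"column {column} out of range")
    V = _variability_matrix(
        enc, time_correction=time_correction, blosum_name=blosum,
        max_gap_frac=max_gap_frac,
    )
    return SiteVariabilityVector(column, V[column - 1], _pair_indices(enc.shape[0]))


def default_min_pairs(n_pairs_total: int) -> int:
    """Minimum defined-pair overlap required for a correlation."""
    return max(10, n_pairs_total // 2)


def site_pair_correlation(
    vec_a: SiteVariabilityVector,
    vec_b: SiteVariabilityVector,
    min_pairs: int | None = None,
) -> float | None:
    """Pearson correlation over the common defined pairs of two vectors.

    Returns ``None`` when the overlap is too small or either restriction
    is constant (the pair is skipped, not reported).
    """
    common = vec_a.defined & vec_b.defined
    n = int(common.sum())
    if min_pairs is None:
        min_pairs = default_min_pairs(len(vec_a.values))
    if n < max(2, min_pairs):
        return None
    x = vec_a.values[common]
    y = vec_b.values[common]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    r = np.corrcoef(x, y)[0, 1]
    return float(r)


def correlation_matrix(V: np.ndarray, min_pairs: int) -> tuple[np.ndarray, np.ndarray]:
    """All-against-all Pearson correlations of a variability matrix.

    Uses pairwise-complete observations (the intersection of defined
    sequence pairs per column pair).  Returns ``(R, N)`` where ``R`` is the
    (n_cols, n_cols) correlation matrix with NaN for skipped pairs and
    ``N`` the defined-overlap counts.
    """
    M = np.isfinite(V)
    X = np.where(M, V, 0.0)
    Mf = M.astype(float)
    N = Mf @ Mf.T
    Sx = X @ Mf.T
    Sxy = X @ X.T
    Sxx = (X * X) @ Mf.T
    cov = N * Sxy - Sx * Sx.T
    var_x = N * Sxx - Sx**2
    var_y = var_x.T
    with np.errstate(invalid="ignore", divide="ignore"):
        R = cov / np.sqrt(var_x * var_y)
    bad = (N < np.maximum(2, min_pairs)) | (var_x <= _EPS_VAR) | (var_y <= _EPS_VAR)
    R = np.where(bad, np.nan, R)
    return R, N


@dataclass
class CorrelatedPair:
    """A threshold-passing correlated position pair (intra or inter)."""

    mol_a: str
    col_a: int
    mol_b: str
    col_b: int
    r: float
    n_pairs: int
    mode: str  # "intra" | "inter"
    time_corrected: bool = False
    ref_a: int | None = None
    ref_b: int | None = None
    group_id: int | None = None

    def positions(self) -> tuple[tuple[str, int], tuple[str, int]]:
        return ((self.mol_a, self.col_a), (self.mol_b, self.col_b))


@dataclass
class CorrelatedGroup:
    """Connected component of the correlated position-pair graph."""

    group_id: int
    positions: frozenset
    pairs: list[CorrelatedPair] = field(default_factory=list)


def _select_pairs(R: np.ndarray, cutoff: float, use_abs: bool) -> np.ndarray:
    score = np.abs(R) if use_abs else R
    with np.errstate(invalid="ignore"):
        return np.isfinite(R) & (score >= cutoff)


def _detect_inter_raw(
    seqs_a: Sequence[str],
    seqs_b: Sequence[str],
    cutoff: float = 0.4,
    time_correction: bool = True,
    blosum: str = "BLOSUM62",
    max_gap_frac: float = 0.1,
    min_pairs: int | None = None,
) -> tuple[list[tuple[int, int, float, int]], np.ndarray]:
    """Inter-molecular detection on raw row lists.

    Divergence times are computed on the concatenation of the paired rows
    (one joint divergence per ortholog-pair row pair).  Returns the list of
    (col_a, col_b, r, n) hits (1-based columns within each molecule) and
    the full A-by-B correlation block.
    """
    la = len(seqs_a[0])
    joined = [a + b for a, b in zip(seqs_a, seqs_b)]
    enc = encode_rows(joined)
    n_pairs_total = enc.shape[0] * (enc.shape[0] - 1) // 2
    if min_pairs is None:
        min_pairs = default_min_pairs(n_pairs_total)
    V = _variability_matrix(
        enc, time_correction=time_correction, blosum_name=blosum,
        max_gap_frac=max_gap_frac,
    )
    R, N = correlation_matrix(V, min_pairs)
    block = R[:la, la:]
    n_block = N[:la, la:]
    hits = []
    sel = _select_pairs(block, cutoff, use_abs=False)
    for ia, ib in zip(*np.nonzero(sel)):
        hits.append((int(ia) + 1, int(ib) + 1, float(block[ia, ib]), int(n_block[ia, ib])))
    return hits, block


def detect_correlated_pairs(
    data: FamilyAlignment | PairedAlignment,
    mode: str | None = None,
    cutoff: float = 0.4,
    time_correction: bool = False,
    blosum: str = "BLOSUM62",
    max_gap_frac: float = 0.1,
    min_pairs: int | None = None,
    use_abs: bool = False,
    group: bool = True,
) -> list[CorrelatedPair]:
    """Scan an alignment (intra) or paired alignment (inter) for correlated
    position pairs with r >= cutoff.

    Deterministic for fixed input.  With ``group=True`` (default) pairs are
    annotated with the connected-component id of the position-pair graph.
    """
    if mode is None:
        mode = "inter" if isinstance(data, PairedAlignment) else "intra"
    pairs: list[CorrelatedPair] = []
    if mode == "intra":
        if not isinstance(data, FamilyAlignment):
            raise TypeError("intra mode requires a FamilyAlignment")
        enc = encode_rows(data.sequences())
        n_rows = enc.shape[0]
        n_pairs_total = n_rows * (n_rows - 1) // 2
        mp = default_min_pairs(n_pairs_total) if min_pairs is None else min_pairs
        V = _variability_matrix(
            enc, time_correction=time_correction, blosum_name=blosum,
            max_gap_frac=max_gap_frac,
        )
        R, N = correlation_matrix(V, mp)
        sel = _select_pairs(R, cutoff, use_abs)
        sel = np.triu(sel, k=1)
        mol = data.family_id
        for ia, ib in zip(*np.nonzero(sel)):
            pairs.append(
                CorrelatedPair(
                    mol, int(ia) + 1, mol, int(ib) + 1,
                    float(R[ia, ib]), int(N[ia, ib]), "intra", time_correction,
                    ref_a=data.column_to_reference(int(ia) + 1),
                    ref_b=data.column_to_reference(int(ib) + 1),
                )
            )
    elif mode == "inter":
        if not isinstance(data, PairedAlignment):
            raise TypeError("inter mode requires a PairedAlignment")
        if use_abs:
            raise NotImplementedError("absolute-value cutoff is intra-only")
        hits, _ = _detect_inter_raw(
            data.sequences_a(), data.sequences_b(), cutoff=cutoff,
            time_correction=time_correction, blosum=blosum,
            max_gap_frac=max_gap_frac, min_pairs=min_pairs,
        )
        mol_a, mol_b = data.family_ids
        for ca, cb, r, n in hits:
            pairs.append(
                CorrelatedPair(
                    mol_a, ca, mol_b, cb, r, n, "inter", time_correction,
                    ref_a=data.column_to_reference("A", ca),
                    ref_b=data.column_to_reference("B", cb),
                )
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if group:
        assign_groups(pairs)
    return pairs


def correlated_groups(pairs: Iterable[CorrelatedPair]) -> list[CorrelatedGroup]:
    """Connected components of the graph whose edges are correlated pairs."""
    g = nx.Graph()
    pair_list = list(pairs)
    for p in pair_list:
        g.add_edge((p.mol_a, p.col_a), (p.mol_b, p.col_b))
    groups: list[CorrelatedGroup] = []
    comps = sorted(nx.connected_components(g), key=lambda c: sorted(c))
    for gid, comp in enumerate(comps):
        members = [
            p for p in pair_list
            if (p.mol_a, p.col_a) in comp and (p.mol_b, p.col_b) in comp
        ]
        groups.append(CorrelatedGroup(gid, frozenset(comp), members))
    return groups


def assign_groups(pairs: list[CorrelatedPair]) -> list[CorrelatedGroup]:
    """Annotate pairs in-place with their connected-component group id."""
    groups = correlated_groups(pairs)
    for grp in groups:
        for p in grp.pairs:
            p.group_id = grp.group_id
    return groups
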