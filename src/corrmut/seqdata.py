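"""Domain types and I/O for alignment-based coevolution analysis.

The central objects are :class:`FamilyAlignment` (one ortholog family,
anchored to a reference sequence), :class:`PairedAlignment` (row-paired
alignments of two families, one row per ortholog pair, for inter-molecular
analysis), :class:`StructureDistances` (minimum heavy-atom distances per
residue pair, intra- and inter-chain), and light annotation records
(motifs, SNPs, coiled-coil probability tracks, helix intervals).

Conventions used throughout the package:

* alignment columns and residue numbers are 1-based;
* intervals are closed ``[start, end]``;
* the gap character is ``-``; any character outside the 20 standard amino
  acids is treated as a gap for scoring purposes;
* aligned FASTA headers follow the dialect ``seq_id|species|source`` with
  ``source`` one of ``interpro``, ``blast``, ``genome``, ``reference``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
SOURCES = ("interpro", "blast", "genome", "reference")


class FormatError(ValueError):
    """Malformed input file (ragged alignment, bad header, bad table)."""


class ContentError(ValueError):
    """Structurally valid input with invalid content (e.g. no reference row)."""


def encode_rows(rows: Sequence[str]) -> np.ndarray:
    """Encode aligned sequences as an int8 array; gaps/unknowns become -1."""
    if not rows:
        return np.empty((0, 0), dtype=np.int8)
    length = len(rows[0])
    out = np.full((len(rows), length), -1, dtype=np.int8)
    for r, seq in enumerate(rows):
        if len(seq) != length:
            raise FormatError("rows have unequal lengths")
        for c, ch in enumerate(seq.upper()):
            out[r, c] = AA_INDEX.get(ch, -1)
    return out


# ---------------------------------------------------------------------------
# Family alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentRow:
    seq_id: str
    species: str
    source: str
    seq: str

    def header(self) -> str:
        return f"{self.seq_id}|{self.species}|{self.source}"


@dataclass
class FamilyAlignment:
    """One subfamily's ortholog alignment anchored to a reference sequence."""

    family_id: str
    rows: list[AlignmentRow]
    reference_row: int

    def __post_init__(self) -> None:
        if not self.rows:
            raise ContentError("alignment has no rows")
        length = len(self.rows[0].seq)
        for row in self.rows:
            if len(row.seq) != length:
                raise FormatError(
                    f"ragged alignment: row {row.seq_id} has length "
                    f"{len(row.seq)} != {length}"
                )
        if not (0 <= self.reference_row < len(self.rows)):
            raise ContentError("reference_row index out of range")
        n_ref = sum(1 for r in self.rows if r.source == "reference")
        if n_ref != 1:
            raise ContentError(f"expected exactly one reference row, found {n_ref}")
        if self.rows[self.reference_row].source != "reference":
            raise ContentError("reference_row does not point at the reference")

    @property
    def length(self) -> int:
        return len(self.rows[0].seq)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def reference(self) -> AlignmentRow:
        return self.rows[self.reference_row]

    def sequences(self) -> list[str]:
        return [r.seq for r in self.rows]

    def column_to_reference(self, column: int) -> int | None:
        """Reference residue number at an alignment column (1-based).

        Returns ``None`` if the reference carries a gap at that column.
        """
        if not (1 <= column <= self.length):
            raise IndexError(f"column {column} out of range 1..{self.length}")
        ref = self.reference.seq
        if ref[column - 1] == GAP:
            return None
        return sum(1 for ch in ref[:column] if ch != GAP)

    def reference_to_column(self, residue: int) -> int:
        """Alignment column of a reference residue number (inverse mapping)."""
        ref = self.reference.seq
        count = 0
        for col, ch in enumerate(ref, start=1):
            if ch != GAP:
                count += 1
                if count == residue:
                    return col
        raise IndexError(f"reference residue {residue} out of range")

    @property
    def reference_length(self) -> int:
        return sum(1 for ch in self.reference.seq if ch != GAP)


def read_alignment(path: str | Path, family_id: str | None = None) -> FamilyAlignment:
    """Read an aligned FASTA with ``seq_id|species|source`` headers."""
    path = Path(path)
    rows: list[AlignmentRow] = []
    for record in SeqIO.parse(str(path), "fasta"):
        parts = record.id.split("|")
        if len(parts) != 3:
            raise FormatError(
                f"header {record.id!r} does not follow seq_id|species|source"
            )
        seq_id, species, source = parts
        if source not in SOURCES:
            raise FormatError(f"unknown source tag {source!r} in {record.id!r}")
        rows.append(AlignmentRow(seq_id, species, source, str(record.seq).upper()))
    if not rows:
        raise FormatError(f"no sequences in {path}")
    ref_rows = [i for i, r in enumerate(rows) if r.source == "reference"]
    if len(ref_rows) != 1:
        raise ContentError(
            f"{path}: expected exactly one reference row, found {len(ref_rows)}"
        )
    return FamilyAlignment(family_id or path.stem, rows, ref_rows[0])


def write_alignment(aln: FamilyAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(r.seq), id=r.header(), description="") for r in aln.rows
    ]
    SeqIO.write(records, str(path), "fasta")


def pairwise_identity(
    row_a: str, row_b: str, count_gap_gap: bool = False
) -> float:
    """Fraction of identical residues between two aligned rows.

    Gap-vs-residue columns count as non-identical; gap-vs-gap columns are
    excluded from the denominator unless ``count_gap_gap`` is set.
    """
    if len(row_a) != len(row_b):
        raise FormatError("rows have unequal lengths")
    same = 0
    denom = 0
    for a, b in zip(row_a.upper(), row_b.upper()):
        a_gap = a == GAP
        b_gap = b == GAP
        if a_gap and b_gap:
            if count_gap_gap:
                denom += 1
            continue
        denom += 1
        if not a_gap and not b_gap and a == b:
            same += 1
    if denom == 0:
        raise ContentError("identity undefined: no comparable columns")
    return same / denom


# ---------------------------------------------------------------------------
# Paired alignments
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedRow:
    seq_id_a: str
    seq_id_b: str
    species: str
    seq_a: str
    seq_b: str


@dataclass
class PairedAlignment:
    """Row-paired alignments of two families (one row per ortholog pair).

    Column namespaces of the two molecules are disjoint: positions are
    reported as ``(molecule, column)`` with molecule "A" or "B".  Optional
    aligned reference sequences allow mapping columns to reference residue
    numbers; without them columns are taken as residue numbers directly
    (valid for ungapped alignments).
    """

    family_ids: tuple[str, str]
    rows: list[PairedRow]
    interacting: bool = True
    reference_a: str | None = None
    reference_b: str | None = None

    def __post_init__(self) -> None:
        if not self.rows:
            raise ContentError("paired alignment has no rows")
        la = len(self.rows[0].seq_a)
        lb = len(self.rows[0].seq_b)
        for row in self.rows:
            if len(row.seq_a) != la or len(row.seq_b) != lb:
                raise FormatError("ragged paired alignment")
        if self.reference_a is not None and len(self.reference_a) != la:
            raise FormatError("reference_a length mismatch")
        if self.reference_b is not None and len(self.reference_b) != lb:
            raise FormatError("reference_b length mismatch")

    @property
    def length_a(self) -> int:
        return len(self.rows[0].seq_a)

    @property
    def length_b(self) -> int:
        return len(self.rows[0].seq_b)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def sequences_a(self) -> list[str]:
        return [r.seq_a for r in self.rows]

    def sequences_b(self) -> list[str]:
        return [r.seq_b for r in self.rows]

    def column_to_reference(self, molecule: str, column: int) -> int | None:
        ref = self.reference_a if molecule == "A" else self.reference_b
        length = self.length_a if molecule == "A" else self.length_b
        if not (1 <= column <= length):
            raise IndexError(f"column {column} out of range for molecule {molecule}")
        if ref is None:
            return column
        if ref[column - 1] == GAP:
            return None
        return sum(1 for ch in ref[:column] if ch != GAP)


# ---------------------------------------------------------------------------
# Structure distances
# ---------------------------------------------------------------------------

class StructureDistances:
    """Minimum heavy-atom distance per residue pair, intra- and inter-chain.

    Residues are addressed by (chain id, structure residue number).  An
    optional per-chain mapping translates structure residue numbers to
    reference-protein residue numbers (the analysis coordinate system).
    """

    def __init__(
        self,
        residues: dict[str, list[int]],
        matrices: dict[tuple[str, str], np.ndarray],
        mapping: dict[str, dict[int, int]] | None = None,
    ) -> None:
        self.residues = {c: list(r) for c, r in residues.items()}
        self._index = {
            c: {res: i for i, res in enumerate(r)} for c, r in self.residues.items()
        }
        self._mat: dict[tuple[str, str], np.ndarray] = {}
        for (ca, cb), mat in matrices.items():
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (len(self.residues[ca]), len(self.residues[cb])):
                raise ContentError("distance matrix shape mismatch")
            self._mat[(ca, cb)] = mat
        for chain in self.residues:
            if (chain, chain) in self._mat:
                m = self._mat[(chain, chain)]
                if not np.allclose(m, m.T):
                    raise ContentError("intra-chain distances not symmetric")
        self.mapping = mapping or {}
        for chain, mp in self.mapping.items():
            vals = list(mp.values())
            if len(vals) != len(set(vals)):
                raise ContentError(f"mapping for chain {chain} is not injective")

    @property
    def chains(self) -> list[str]:
        return sorted(self.residues)

    def _lookup(self, ca: str, cb: str) -> tuple[np.ndarray, bool]:
        if (ca, cb) in self._mat:
            return self._mat[(ca, cb)], False
        if (cb, ca) in self._mat:
            return self._mat[(cb, ca)], True
        raise KeyError(f"no distances for chain pair ({ca}, {cb})")

    def distance(self, chain_i: str, res_i: int, chain_j: str, res_j: int) -> float:
        mat, flipped = self._lookup(chain_i, chain_j)
        i = self._index[chain_i][res_i]
        j = self._index[chain_j][res_j]
        return float(mat[j, i] if flipped else mat[i, j])

    def pair_distances(self, chain_a: str, chain_b: str) -> np.ndarray:
        """Flat array of distances over unique residue pairs of a chain pair."""
        mat, _ = self._lookup(chain_a, chain_b)
        if chain_a == chain_b:
            iu = np.triu_indices(mat.shape[0], k=1)
            return mat[iu]
        return mat.ravel()

    # -- reference-coordinate access -------------------------------------
    def reference_to_structure(self, chain: str, ref_residue: int) -> int | None:
        mp = self.mapping.get(chain)
        if not mp:
            # identity mapping when none supplied
            return ref_residue if ref_residue in self._index[chain] else None
        inv = {v: k for k, v in mp.items()}
        return inv.get(ref_residue)

    def mapped_reference_residues(self, chain: str) -> list[int]:
        mp = self.mapping.get(chain)
        if not mp:
            return list(self.residues[chain])
        return sorted(mp.values())

    # -- serialisation ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        recs = []
        for (ca, cb), mat in self._mat.items():
            for i, ri in enumerate(self.residues[ca]):
                for j, rj in enumerate(self.residues[cb]):
                    if ca == cb and j <= i:
                        continue
                    recs.append((ca, ri, cb, rj, mat[i, j]))
        return pd.DataFrame(
            recs, columns=["chain_i", "res_i", "chain_j", "res_j", "distance"]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(
        cls, df: pd.DataFrame, mapping: dict[str, dict[int, int]] | None = None
    ) -> "StructureDistances":
        residues: dict[str, set[int]] = {}
        for _, row in df.iterrows():
            residues.setdefault(str(row.chain_i), set()).add(int(row.res_i))
            residues.setdefault(str(row.chain_j), set()).add(int(row.res_j))
        res_sorted = {c: sorted(s) for c, s in residues.items()}
        idx = {c: {r: i for i, r in enumerate(rs)} for c, rs in res_sorted.items()}
        mats: dict[tuple[str, str], np.ndarray] = {}
        for _, row in df.iterrows():
            ca, cb = str(row.chain_i), str(row.chain_j)
            key = (ca, cb) if (ca, cb) in mats or ca <= cb else (cb, ca)
            if key not in mats:
                mats[key] = np.full(
                    (len(res_sorted[key[0]]), len(res_sorted[key[1]])), np.nan
                )
            i = idx[key[0]][int(row.res_i if key == (ca, cb) else row.res_j)]
            j = idx[key[1]][int(row.res_j if key == (ca, cb) else row.res_i)]
            mats[key][i, j] = float(row.distance)
            if key[0] == key[1]:
                mats[key][j, i] = float(row.distance)
        for key, m in mats.items():
            if key[0] == key[1]:
                np.fill_diagonal(m, 0.0)
        return cls(res_sorted, mats, mapping)

    @classmethod
    def read_tsv(
        cls, path: str | Path, mapping: dict[str, dict[int, int]] | None = None
    ) -> "StructureDistances":
        return cls.from_frame(pd.read_csv(path, sep="\t"), mapping)


def min_heavy_atom_distances(
    pdb_path: str | Path,
    chain_ids: Sequence[str],
    mapping: dict[str, dict[int, int]] | None = None,
) -> StructureDistances:
    """Minimum heavy-atom distance for every residue pair of the given chains.

    Hydrogens are ignored; the first altloc of disordered atoms is used;
    insertion-coded residues and residues without heavy atoms are skipped
    with a warning.
    """
    from Bio.PDB import PDBParser
    from scipy.spatial.distance import cdist

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(pdb_path))
    model = next(structure.get_models())
    coords: dict[str, list[np.ndarray]] = {}
    residues: dict[str, list[int]] = {}
    for chain_id in chain_ids:
        if chain_id not in [c.id for c in model]:
            raise ContentError(f"chain {chain_id!r} not found in {pdb_path}")
        chain = model[chain_id]
        coords[chain_id] = []
        residues[chain_id] = []
        for res in chain:
            hetflag, resseq, icode = res.id
            if hetflag.strip():
                continue
            if icode.strip():
                warnings.warn(
                    f"skipping insertion-coded residue {resseq}{icode} "
                    f"in chain {chain_id}"
                )
                continue
            heavy = [
                a.coord for a in res.get_atoms() if a.element not in ("H", "D", "")
            ]
            if not heavy:
                warnings.warn(
                    f"residue {resseq} in chain {chain_id} has no heavy atoms"
                )
                continue
            coords[chain_id].append(np.asarray(heavy, dtype=float))
            residues[chain_id].append(resseq)

    def min_matrix(atoms_a: list[np.ndarray], atoms_b: list[np.ndarray]) -> np.ndarray:
        if not atoms_a or not atoms_b:
            return np.empty((len(atoms_a), len(atoms_b)))
        flat_a = np.concatenate(atoms_a)
        flat_b = np.concatenate(atoms_b)
        d = cdist(flat_a, flat_b)
        starts_a = np.cumsum([0] + [len(x) for x in atoms_a[:-1]])
        starts_b = np.cumsum([0] + [len(x) for x in atoms_b[:-1]])
        d = np.minimum.reduceat(d, starts_a, axis=0)
        d = np.minimum.reduceat(d, starts_b, axis=1)
        return d

    mats: dict[tuple[str, str], np.ndarray] = {}
    ids = list(chain_ids)
    for i, ca in enumerate(ids):
        for cb in ids[i:]:
            mats[(ca, cb)] = min_matrix(coords[ca], coords[cb])
    return StructureDistances(residues, mats, mapping)


# ---------------------------------------------------------------------------
# Annotation records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifAnnotation:
    """A predicted interaction motif: closed interval in reference coordinates."""

    motif_id: str
    protein: str
    start: int
    end: int
    partner_motif_id: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ContentError(f"motif {self.motif_id}: start > end")

    def positions(self) -> range:
        return range(self.start, self.end + 1)

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class SNPRecord:
    protein: str
    position: int
    snp_class: str  # "synonymous" | "non-synonymous"

    def __post_init__(self) -> None:
        if self.snp_class not in ("synonymous", "non-synonymous"):
            raise ContentError(f"unknown SNP class {self.snp_class!r}")


@dataclass(frozen=True)
class HelixInterval:
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ContentError("helix interval start > end")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class CoilTrack:
    """Per-residue coiled-coil probability track (1-based positions)."""

    protein: str
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.ndim != 1:
            raise ContentError("probability track must be 1-D")
        if np.any((self.probabilities < 0) | (self.probabilities > 1)):
            raise ContentError("coil probabilities must lie in [0, 1]")


def read_motifs(path: str | Path) -> list[MotifAnnotation]:
    df = pd.read_csv(path, sep="\t")
    motifs = [
        MotifAnnotation(
            str(r.motif_id),
            str(r.protein),
            int(r.start),
            int(r.end),
            None if pd.isna(r.partner_motif_id) else str(r.partner_motif_id),
        )
        for r in df.itertuples()
    ]
    by_id = {m.motif_id: m for m in motifs}
    for m in motifs:
        if m.partner_motif_id is not None:
            partner = by_id.get(m.partner_motif_id)
            if partner is not None and partner.partner_motif_id != m.motif_id:
                raise ContentError(
                    f"motif pairing not symmetric: {m.motif_id} / {m.partner_motif_id}"
                )
    return motifs


def write_motifs(motifs: Iterable[MotifAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            (m.motif_id, m.protein, m.start, m.end, m.partner_motif_id or "")
            for m in motifs
        ],
        columns=["motif_id", "protein", "start", "end", "partner_motif_id"],
    ).to_csv(path, sep="\t", index=False)


def read_snps(path: str | Path) -> list[SNPRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SNPRecord(str(r.protein), int(r.position), str(getattr(r, "snp_class")))
        for r in df.itertuples()
    ]


def write_snps(snps: Iterable[SNPRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(s.protein, s.position, s.snp_class) for s in snps],
        columns=["protein", "position", "snp_class"],
    ).to_csv(path, sep="\t", index=False)


def read_coil_tracks(path: str | Path) -> dict[str, CoilTrack]:
    df = pd.read_csv(path, sep="\t")
    tracks: dict[str, CoilTrack] = {}
    for protein, group in df.groupby("protein"):
        group = group.sort_values("position")
        positions = group["position"].to_numpy()
        if not np.array_equal(positions, np.arange(1, len(positions) + 1)):
            raise FormatError(f"track for {protein} is not contiguous from 1")
        tracks[str(protein)] = CoilTrack(str(protein), group["probability"].to_numpy())
    return tracks


def write_coil_tracks(tracks: Iterable[CoilTrack], path: str | Path) -> None:
    recs = []
    for t in tracks:
        for i, p in enumerate(t.probabilities, start=1):
            recs.append((t.protein, i, p))
    pd.DataFrame(recs, columns=["protein", "position", "probability"]).to_csv(
        path, sep="\t", index=False
    )
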