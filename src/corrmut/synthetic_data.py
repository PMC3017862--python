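"""Synthetic inputs with the statistical structure the analysis assumes.

The generator emulates the kind of data the pipeline consumes -- ortholog
family alignments, row-paired alignments of interacting / non-interacting
partners, a structure placing coevolving residues in 3D contact, and
motif/SNP/coiled-coil annotations -- with planted, tunable coevolution:

* Sequences descend from a random ancestor on a **star phylogeny**: every
  leaf evolves independently, so shared ancestry cannot masquerade as
  coevolution and planted signal is the only correlation source.
* Background columns follow a 20-state uniform-replacement (Jukes-Cantor
  style) substitution process whose per-branch jump probability is solved
  in closed form from the target mean pairwise Poisson-corrected distance.
* A **planted pair** couples two columns through a compatibility bijection
  of the alphabet (every state has exactly one compatible partner state, a
  charge-pair metaphor such as E/K <-> K/E).  Each sequence is "coupled"
  with probability ``q`` (the compensation strength): its second residue is
  the compatible partner of whatever the first residue did; with
  probability ``1 - q`` the second column evolves independently.  ``q = 1``
  is perfect compensation; ``q = 0`` is exactly background.

Alignments are gap-free (indel simulation is out of scope), so alignment
columns coincide with reference residue numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .seqdata import (
    AMINO_ACIDS,
    AlignmentRow,
    CoilTrack,
    ContentError,
    FamilyAlignment,
    MotifAnnotation,
    PairedAlignment,
    PairedRow,
    SNPRecord,
    StructureDistances,
)

_LEAF_SOURCES = ("interpro", "blast", "genome")


@dataclass(frozen=True)
class PlantedPair:
    """A coevolving column pair planted into the simulation."""

    pos1: int
    pos2: int  # for scope="inter", a column of molecule B
    scope: str = "intra"  # "intra" | "inter"
    q: float = 0.9  # compensation strength
    shared: bool = False  # plant into every family member
    family_index: int = 0  # family receiving a non-shared pair

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ContentError("compensation strength q must lie in [0, 1]")
        if self.scope not in ("intra", "inter"):
            raise ContentError(f"unknown scope {self.scope!r}")
        if self.scope == "intra" and self.pos1 == self.pos2:
            raise ContentError("planted positions must be distinct")


@dataclass
class SimulationConfig:
    """Study conditions for the generator.

    ``divergence_depth`` is the target mean pairwise Poisson-corrected
    distance between rows (0.7 ~ 50% pairwise differences, the mid-range
    of a 25-95% identity family).  ``n_species`` doubles as the row count:
    one ortholog per species on the star tree.
    """

    seed: int
    n_species: int = 60
    n_proteins: int = 2
    length: int = 100
    site_rate: float = 1.0
    divergence_depth: float = 0.7
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    n_interacting: int = 34
    n_noninteracting: int = 34

    def __post_init__(self) -> None:
        if self.site_rate == 0 and self.divergence_depth > 0:
            raise ContentError("site rate 0 cannot reach a nonzero divergence depth")
        for p in self.planted_pairs:
            if not (1 <= p.pos1 <= self.length and 1 <= p.pos2 <= self.length):
                raise ContentError("planted positions out of range")


def _branch_jump_probability(depth: float, site_rate: float = 1.0) -> float:
    """Per-branch, per-site probability of >= 1 substitution event.

    Solved so that the expected pairwise proportion of differences p
    between two leaves satisfies -ln(1 - p) = depth, under the 20-state
    uniform-replacement process (after the first jump the residue is
    uniform over the alphabet, hence differs from the partner with
    probability 19/20 given at least one jump on the joint path).
    """
    if depth < 0:
        raise ContentError("divergence depth must be >= 0")
    if depth == 0 or site_rate == 0:
        return 0.0
    p_diff = 1.0 - math.exp(-depth)
    arg = 1.0 - p_diff * 20.0 / 19.0
    if arg <= 0:
        raise ContentError(f"divergence depth {depth} is unreachable (p >= 0.95)")
    path = -math.log(arg)  # total jump intensity leaf-to-leaf
    return 1.0 - math.exp(-site_rate * path / 2.0)


def _species_name(i: int) -> str:
    return "A.thaliana" if i == 0 else f"species{i:03d}"


def _evolve(
    n_rows: int,
    length: int,
    p_jump: float,
    planted_cols: Sequence[tuple[int, int, float]],
    rng: np.random.Generator,
) -> np.ndarray:
    """Evolve one alignment; ``planted_cols`` holds (col1, col2, q) 0-based.

    Returns an (n_rows, length) array of amino-acid characters.
    """
    aa = np.array(list(AMINO_ACIDS))
    ancestor = rng.choice(20, size=length)
    jumped = rng.random((n_rows, length)) < p_jump
    random_states = rng.integers(0, 20, size=(n_rows, length))
    chars = np.where(jumped, random_states, ancestor[np.newaxis, :])
    for col1, col2, q in planted_cols:
        # compatibility is a seeded alphabet bijection: every state of the
        # first column has exactly one compatible partner state (size-2
        # joint-state sets, a charge-pair metaphor).  A row is "coupled"
        # with probability q: its second residue is the compatible partner
        # of whatever the first residue did; otherwise it evolves
        # independently like background.  q = 0 is exactly background.
        shift = 1 + int(rng.integers(19))
        anc2 = (ancestor[col1] + shift) % 20  # ancestrally compatible pair
        indep2 = np.where(jumped[:, col2], random_states[:, col2], anc2)
        coupled = rng.random(n_rows) < q
        chars[:, col2] = np.where(coupled, (chars[:, col1] + shift) % 20, indep2)
    return aa[chars]


def _rows_to_family(
    chars: np.ndarray, family_id: str, prefix: str
) -> FamilyAlignment:
    rows = []
    for i in range(chars.shape[0]):
        seq = "".join(chars[i])
        source = "reference" if i == 0 else _LEAF_SOURCES[(i - 1) % 3]
        rows.append(
            AlignmentRow(f"{prefix}{i:03d}", _species_name(i), source, seq)
        )
    return FamilyAlignment(family_id, rows, reference_row=0)


def simulate_family(
    config: SimulationConfig,
    family_id: str = "FAM0",
    rng: np.random.Generator | None = None,
) -> FamilyAlignment:
    """One ortholog family alignment with the configured intra planted pairs.

    Row 0 is the reference (Arabidopsis) sequence; the other rows are one
    putative ortholog per species.  Alignments are gap-free, so columns
    equal reference residue numbers.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p_jump = _branch_jump_probability(config.divergence_depth, config.site_rate)
    planted = [
        (p.pos1 - 1, p.pos2 - 1, p.q)
        for p in config.planted_pairs
        if p.scope == "intra"
    ]
    chars = _evolve(config.n_species, config.length, p_jump, planted, rng)
    return _rows_to_family(chars, family_id, prefix=f"{family_id}_")


def simulate_protein_set(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> list[FamilyAlignment]:
    """Alignments for ``n_proteins`` family members with shared planted pairs.

    Pairs with ``shared=True`` are planted into every family (at the same
    columns, so the trivial master alignment maps them onto each other);
    non-shared pairs go only into their ``family_index`` family.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p_jump = _branch_jump_probability(config.divergence_depth, config.site_rate)
    families = []
    for f in range(config.n_proteins):
        planted = [
            (p.pos1 - 1, p.pos2 - 1, p.q)
            for p in config.planted_pairs
            if p.scope == "intra" and (p.shared or p.family_index == f)
        ]
        chars = _evolve(config.n_species, config.length, p_jump, planted, rng)
        families.append(_rows_to_family(chars, f"FAM{f}", prefix=f"F{f}_"))
    return families


def simulate_paired_alignment(
    config: SimulationConfig,
    family_ids: tuple[str, str] = ("A", "B"),
    interacting: bool = True,
    rng: np.random.Generator | None = None,
) -> PairedAlignment:
    """A row-paired alignment of two molecules, one ortholog pair per species.

    Interacting pairs carry the configured inter-scope planted pairs;
    non-interacting pairs share the background process but carry none.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    p_jump = _branch_jump_probability(config.divergence_depth, config.site_rate)
    inter = [p for p in config.planted_pairs if p.scope == "inter"] if interacting else []
    # evolve the two molecules as one concatenated alignment so that an
    # inter planted pair is just a planted column pair spanning the halves
    planted = [
        (p.pos1 - 1, config.length + p.pos2 - 1, p.q) for p in inter
    ]
    chars = _evolve(config.n_species, 2 * config.length, p_jump, planted, rng)
    rows = []
    for i in range(config.n_species):
        seq = "".join(chars[i])
        rows.append(
            PairedRow(
                f"{family_ids[0]}_{i:03d}", f"{family_ids[1]}_{i:03d}",
                _species_name(i), seq[: config.length], seq[config.length:],
            )
        )
    return PairedAlignment(tuple(family_ids), rows, interacting=interacting)


def simulate_interaction_set(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[PairedAlignment], list[PairedAlignment]]:
    """Interacting and non-interacting paired-alignment sets.

    Both sets share the background process; only interacting pairs carry
    planted inter-molecular coevolution.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    interacting = [
        simulate_paired_alignment(
            config, (f"I{k}A", f"I{k}B"), interacting=True, rng=rng
        )
        for k in range(config.n_interacting)
    ]
    noninteracting = [
        simulate_paired_alignment(
            config, (f"N{k}A", f"N{k}B"), interacting=False, rng=rng
        )
        for k in range(config.n_noninteracting)
    ]
    return interacting, noninteracting


# ---------------------------------------------------------------------------
# Toy structure
# ---------------------------------------------------------------------------

@dataclass
class ToyStructure:
    """A minimal synthetic structure placing planted pairs in 3D contact."""

    coords: dict[str, np.ndarray]  # chain -> (n_res, 2, 3): CA and CB pseudo-atoms
    distances: StructureDistances
    pdb_text: str

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.pdb_text)


def _format_atom(serial: int, name: str, chain: str, resseq: int,
                 xyz: np.ndarray, element: str) -> str:
    return (
        f"ATOM  {serial:5d}  {name:<4s}ALA {chain}{resseq:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
        f"          {element:>2s}"
    )


def make_toy_structure(
    length: int,
    planted_pairs: Sequence[PlantedPair],
    contact_distance: float = 8.0,
    seed: int = 0,
    length_b: int | None = None,
) -> ToyStructure:
    """Synthetic backbone with planted-pair residues in contact.

    Chain A residues sit along a line at 6 Å spacing (so residues more
    than two apart in sequence are > 15 Å apart); a second chain B (built
    when any planted pair is inter-scope or ``length_b`` is given) runs
    parallel 30 Å away.  For each planted pair the second residue is
    relocated next to the first, within ``contact_distance``.  Each residue
    carries CA and CB pseudo-atoms; distances are minimum heavy-atom
    distances.  Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    two_chains = length_b is not None or any(p.scope == "inter" for p in planted_pairs)
    length_b = length_b if length_b is not None else (length if two_chains else 0)

    def chain_coords(n: int, y0: float) -> np.ndarray:
        ca = np.stack(
            [6.0 * np.arange(n), np.full(n, y0), np.zeros(n)], axis=1
        ) + rng.uniform(-0.3, 0.3, size=(n, 3))
        cb = ca + np.array([0.0, 0.0, 1.5])
        return np.stack([ca, cb], axis=1)

    coords = {"A": chain_coords(length, 0.0)}
    if two_chains:
        coords["B"] = chain_coords(length_b, 30.0)

    for k, p in enumerate(planted_pairs):
        offset = np.array([0.0, 0.6 * contact_distance, 2.5 * k])
        if p.scope == "intra":
            anchor = coords["A"][p.pos1 - 1, 0]
            coords["A"][p.pos2 - 1, 0] = anchor + offset
            coords["A"][p.pos2 - 1, 1] = anchor + offset + np.array([0, 0, 1.5])
        else:
            anchor = coords["A"][p.pos1 - 1, 0]
            coords["B"][p.pos2 - 1, 0] = anchor + offset
            coords["B"][p.pos2 - 1, 1] = anchor + offset + np.array([0, 0, 1.5])

    lines = []
    serial = 1
    for chain, arr in coords.items():
        for res in range(arr.shape[0]):
            for name, element, idx in (("CA", "C", 0), ("CB", "C", 1)):
                lines.append(
                    _format_atom(serial, name, chain, res + 1, arr[res, idx], element)
                )
                serial += 1
        lines.append("TER")
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"

    from scipy.spatial.distance import cdist

    residues = {c: list(range(1, arr.shape[0] + 1)) for c, arr in coords.items()}
    mats: dict[tuple[str, str], np.ndarray] = {}
    chains = sorted(coords)
    for i, ca in enumerate(chains):
        for cb in chains[i:]:
            flat_a = coords[ca].reshape(-1, 3)
            flat_b = coords[cb].reshape(-1, 3)
            d = cdist(flat_a, flat_b)
            n_a, n_b = coords[ca].shape[0], coords[cb].shape[0]
            d = d.reshape(n_a, 2, n_b, 2).min(axis=(1, 3))
            mats[(ca, cb)] = d
    distances = StructureDistances(residues, mats)
    return ToyStructure(coords, distances, pdb_text)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

@dataclass
class AnnotationBundle:
    motifs: list[MotifAnnotation]
    snps: list[SNPRecord]
    tracks: dict[str, CoilTrack]


def make_annotations(
    planted_pairs: Sequence[PlantedPair],
    length: int,
    fidelity: float = 1.0,
    seed: int = 0,
    proteins: tuple[str, str] = ("A", "B"),
    motif_halfwidth: int = 2,
    n_snps_per_class: int = 30,
    helix_regions: Sequence[tuple[int, int]] = ((10, 25), (40, 55)),
) -> AnnotationBundle:
    """Motif, SNP and coiled-coil annotations correlated with planted pairs.

    With probability ``fidelity`` a motif pair brackets a planted
    inter-molecular pair (else it is placed at random); non-synonymous
    SNPs avoid planted positions with probability ``fidelity``; coil
    tracks carry probability 0.8 runs over ``helix_regions`` and 0.1
    elsewhere.
    """
    if not (0.0 <= fidelity <= 1.0):
        raise ContentError("fidelity must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    prot_a, prot_b = proteins
    planted_positions = {
        prot_a: {p.pos1 for p in planted_pairs},
        prot_b: {p.pos2 for p in planted_pairs if p.scope == "inter"},
    }

    def interval_around(pos: int) -> tuple[int, int]:
        return max(1, pos - motif_halfwidth), min(length, pos + motif_halfwidth)

    def random_interval() -> tuple[int, int]:
        start = int(rng.integers(1, length - 2 * motif_halfwidth))
        return start, start + 2 * motif_halfwidth

    motifs: list[MotifAnnotation] = []
    inter_pairs = [p for p in planted_pairs if p.scope == "inter"]
    for k, p in enumerate(inter_pairs):
        faithful = rng.random() < fidelity
        sa, ea = interval_around(p.pos1) if faithful else random_interval()
        sb, eb = interval_around(p.pos2) if faithful else random_interval()
        motifs.append(MotifAnnotation(f"m{k}a", prot_a, sa, ea, f"m{k}b"))
        motifs.append(MotifAnnotation(f"m{k}b", prot_b, sb, eb, f"m{k}a"))

    snps: list[SNPRecord] = []
    for protein in proteins:
        avoid = planted_positions[protein]
        candidates = [p for p in range(1, length + 1) if p not in avoid]
        for _ in range(n_snps_per_class):
            if avoid and rng.random() < fidelity:
                pos = int(candidates[rng.integers(len(candidates))])
            else:
                pos = int(rng.integers(1, length + 1))
            snps.append(SNPRecord(protein, pos, "non-synonymous"))
        for _ in range(n_snps_per_class):
            snps.append(
                SNPRecord(protein, int(rng.integers(1, length + 1)), "synonymous")
            )

    probs = np.full(length, 0.1)
    for start, end in helix_regions:
        probs[start - 1 : end] = 0.8
    tracks = {p: CoilTrack(p, probs.copy()) for p in proteins}
    return AnnotationBundle(motifs, snps, tracks)
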