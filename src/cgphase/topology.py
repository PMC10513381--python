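"""Coarse-grained molecular topologies and initial coordinates.

One bead per amino acid (placed at the C-alpha position) or per nucleotide
(placed at the residue centroid). Topologies are plain dataclasses; masses
and charges come from the residue registry shipped with the package, with
the histidine charge depending on the force-field family requested.

Indices are 0-based internally; PDB serial numbers are 1-based on write.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser, PDBIO, StructureBuilder
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

_DATA_DIR = Path(__file__).parent / "data"

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
DNA_RESNAMES = {"DA": "A", "DC": "C", "DG": "G", "DT": "T"}
RNA_RESNAMES = {"A": "A", "C": "C", "G": "G", "U": "U",
                "RA": "A", "RC": "C", "RG": "G", "RU": "U"}
DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Default virtual C-alpha--C-alpha bond length, nm.
CA_SPACING = 0.38

# Ideal B-form helix used for de novo dsDNA coordinates (one bead per
# nucleotide at the residue centroid): rise per bp, twist per bp, helix
# radius and the azimuthal offset of the second strand.
BDNA_RISE = 0.34          # nm
BDNA_TWIST = 36.0         # degrees
BDNA_RADIUS = 0.9         # nm
BDNA_STRAND_PHASE = 154.0 # degrees


class TopologyError(ValueError):
    """Raised for invalid residues, missing atoms or malformed topologies."""


@dataclass(frozen=True)
class Bead:
    """One coarse-grained interaction site."""

    index: int
    name: str
    residue_code: str
    chain_id: str
    molecule_index: int
    mass: float    # amu
    charge: float  # e

    @property
    def bead_type(self) -> str:
        """Pair-table key: kind prefix + one-letter code, e.g. ``p:G``."""
        prefix = {"CA": "p", "DN": "d", "RN": "r"}.get(self.name, "p")
        return f"{prefix}:{self.residue_code}"


@dataclass(frozen=True)
class BondedTerm:
    """A bond (2 beads), angle (3), dihedral (4) or inter-strand fan bond (2)."""

    kind: str                     # bond | angle | dihedral | fan_bond
    bead_indices: tuple[int, ...]
    coefficient_key: str
    delta: Optional[int] = None   # fan_bond only

    def __post_init__(self):
        n_expected = {"bond": 2, "angle": 3, "dihedral": 4, "fan_bond": 2}
        if self.kind not in n_expected:
            raise TopologyError(f"unknown bonded term kind {self.kind!r}")
        if len(self.bead_indices) != n_expected[self.kind]:
            raise TopologyError(
                f"{self.kind} needs {n_expected[self.kind]} beads, "
                f"got {len(self.bead_indices)}")


@dataclass
class MoleculeTopology:
    """Beads plus bonded terms for a single molecule (possibly multi-chain)."""

    beads: list[Bead]
    bonded_terms: list[BondedTerm]
    sequence: str
    molecule_kind: str  # protein | dna | rna

    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    @property
    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    @property
    def bead_types(self) -> list[str]:
        return [b.bead_type for b in self.beads]

    def terms(self, kind: str) -> list[BondedTerm]:
        return [t for t in self.bonded_terms if t.kind == kind]

    def validate(self) -> None:
        idx = [b.index for b in self.beads]
        if idx != list(range(len(idx))):
            raise TopologyError("bead indices must be contiguous from 0")
        if any(b.mass <= 0 for b in self.beads):
            raise TopologyError("all bead masses must be positive")
        for t in self.bonded_terms:
            if any(i < 0 or i >= self.n_beads for i in t.bead_indices):
                raise TopologyError(f"bonded term {t} has out-of-range index")

    def __eq__(self, other) -> bool:
        if not isinstance(other, MoleculeTopology):
            return NotImplemented
        return (self.beads == other.beads
                and sorted(self.bonded_terms, key=_term_sort_key)
                == sorted(other.bonded_terms, key=_term_sort_key)
                and self.sequence == other.sequence
                and self.molecule_kind == other.molecule_kind)


def _term_sort_key(t: BondedTerm):
    return (t.kind, t.bead_indices, t.delta if t.delta is not None else 0)


@dataclass
class SystemTopology:
    """Molecules with copy counts, flattened into one global bead index space."""

    entries: list[tuple[MoleculeTopology, int]]
    bead_ranges: list[tuple[int, int]] = field(default_factory=list)
    n_total_beads: int = 0

    def __post_init__(self):
        if not self.bead_ranges:
            start = 0
            for mol, count in self.entries:
                if count < 1:
                    raise TopologyError("copy counts must be >= 1")
                for _ in range(count):
                    self.bead_ranges.append((start, start + mol.n_beads))
                    start += mol.n_beads
            self.n_total_beads = start
        # partition check
        pos = 0
        for lo, hi in self.bead_ranges:
            if lo != pos or hi <= lo:
                raise TopologyError("bead_ranges must partition [0, n_total_beads)")
            pos = hi
        if pos != self.n_total_beads:
            raise TopologyError("bead_ranges do not cover all beads")

    @property
    def n_molecules(self) -> int:
        return len(self.bead_ranges)

    def iter_copies(self) -> Iterator[tuple[MoleculeTopology, int, tuple[int, int]]]:
        i = 0
        for mol, count in self.entries:
            for _ in range(count):
                yield mol, i, self.bead_ranges[i]
                i += 1

    @property
    def masses(self) -> np.ndarray:
        return np.concatenate([mol.masses for mol, _, _ in self.iter_copies()])

    @property
    def charges(self) -> np.ndarray:
        return np.concatenate([mol.charges for mol, _, _ in self.iter_copies()])

    @property
    def bead_types(self) -> list[str]:
        out: list[str] = []
        for mol, _, _ in self.iter_copies():
            out.extend(mol.bead_types)
        return out

    @property
    def molecule_of_bead(self) -> np.ndarray:
        out = np.empty(self.n_total_beads, dtype=int)
        for _, i, (lo, hi) in self.iter_copies():
            out[lo:hi] = i
        return out

    def global_terms(self, kind: str) -> list[tuple[BondedTerm, tuple[int, ...]]]:
        """Bonded terms of one kind with bead indices shifted per copy."""
        out = []
        for mol, _, (lo, _) in self.iter_copies():
            for t in mol.terms(kind):
                out.append((t, tuple(i + lo for i in t.bead_indices)))
        return out

    @classmethod
    def single(cls, mol: MoleculeTopology) -> "SystemTopology":
        return cls(entries=[(mol, 1)])


# ---------------------------------------------------------------------------
# residue registry
# ---------------------------------------------------------------------------

def _load_registry() -> tuple[pd.DataFrame, pd.DataFrame]:
    aa = pd.read_csv(_DATA_DIR / "amino_acids.csv", comment="#").set_index("code")
    nt = pd.read_csv(_DATA_DIR / "nucleotides.csv", comment="#").set_index(["kind", "code"])
    return aa, nt


_AA_TABLE, _NT_TABLE = _load_registry()


def residue_mass_charge(code: str, kind: str, force_field_tag: str) -> tuple[float, float]:
    """Mass (amu) and charge (e) for one residue under a force-field family.

    The histidine charge differs between the MOFF and HPS families; all
    other residues share one charge set.
    """
    tag = force_field_tag.upper()
    if kind == "protein":
        if code not in _AA_TABLE.index:
            raise TopologyError(f"unknown amino-acid code {code!r}")
        row = _AA_TABLE.loc[code]
        col = "charge_moff_e" if tag.startswith("MOFF") else "charge_hps_e"
        return float(row["mass_amu"]), float(row[col])
    if kind in ("dna", "rna"):
        try:
            row = _NT_TABLE.loc[(kind, code)]
        except KeyError:
            raise TopologyError(f"unknown {kind} nucleotide code {code!r}") from None
        return float(row["mass_amu"]), float(row["charge_e"])
    raise TopologyError(f"unknown molecule kind {kind!r}")


def _bead_name(kind: str) -> str:
    return {"protein": "CA", "dna": "DN", "rna": "RN"}[kind]


def _make_bead(i: int, code: str, chain_id: str, kind: str, tag: str) -> Bead:
    mass, charge = residue_mass_charge(code, kind, tag)
    return Bead(index=i, name=_bead_name(kind), residue_code=code,
                chain_id=chain_id, molecule_index=0, mass=mass, charge=charge)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def chain_topology(sequence: str, force_field_tag: str = "HPS",
                   molecule_kind: str = "protein",
                   chain_id: str = "A") -> MoleculeTopology:
    """Linear single-chain topology with harmonic backbone bonds."""
    if not sequence:
        raise TopologyError("empty sequence")
    beads = [_make_bead(i, c, chain_id, molecule_kind, force_field_tag)
             for i, c in enumerate(sequence)]
    key = "mrg_bond" if molecule_kind == "dna" else "backbone"
    bonds = [BondedTerm("bond", (i, i + 1), key) for i in range(len(sequence) - 1)]
    top = MoleculeTopology(beads, bonds, sequence, molecule_kind)
    top.validate()
    return top


def build_straight_chain(sequence: str, spacing: float = CA_SPACING) -> np.ndarray:
    """Collinear coordinates along +z with exact consecutive spacing (nm)."""
    if not sequence:
        raise TopologyError("empty sequence")
    if spacing <= 0:
        raise TopologyError("spacing must be positive")
    for c in sequence:
        if c not in AA1_TO_3 and c not in "ACGTU":
            raise TopologyError(f"invalid residue code {c!r}")
    n = len(sequence)
    coords = np.zeros((n, 3))
    coords[:, 2] = spacing * np.arange(n)
    return coords


def wc_complement(sequence: str) -> str:
    try:
        return "".join(DNA_COMPLEMENT[c] for c in reversed(sequence))
    except KeyError as e:
        raise TopologyError(f"invalid DNA code {e.args[0]!r}") from None


def build_dsdna_topology(n_bp: int, sequence: Optional[str] = None,
                         fan_deltas: Sequence[int] = (-2, -1, 0, 1, 2),
                         ) -> MoleculeTopology:
    """Two antiparallel strands, one bead per nucleotide.

    Strand 1 occupies beads 0..n_bp-1 (5'->3'), strand 2 beads
    n_bp..2*n_bp-1 in its own 5'->3' order, so the Watson-Crick partner of
    strand-1 position i is strand-2 position n_bp-1-i. Intra-strand bonds
    and angles follow the MRG-CG description; inter-strand fan bonds
    connect nucleotide i with the beads at offsets delta from its WC
    partner, for every tabulated delta where the partner exists.
    """
    if n_bp < 1:
        raise TopologyError("n_bp must be >= 1")
    if sequence is None:
        sequence = ("ATGC" * ((n_bp + 3) // 4))[:n_bp]
    if len(sequence) != n_bp:
        raise TopologyError("sequence length must equal n_bp")
    seq2 = wc_complement(sequence)

    beads = []
    for i, c in enumerate(sequence):
        beads.append(_make_bead(i, c, "A", "dna", "MRG-CG"))
    for i, c in enumerate(seq2):
        beads.append(_make_bead(n_bp + i, c, "B", "dna", "MRG-CG"))

    terms: list[BondedTerm] = []
    for s0 in (0, n_bp):
        for i in range(n_bp - 1):
            terms.append(BondedTerm("bond", (s0 + i, s0 + i + 1), "mrg_bond"))
        for i in range(n_bp - 2):
            terms.append(BondedTerm("angle", (s0 + i, s0 + i + 1, s0 + i + 2),
                                    "mrg_angle"))
    for i in range(n_bp):
        p = n_bp - 1 - i  # WC partner position on strand 2
        for d in fan_deltas:
            j = p + d
            if 0 <= j < n_bp:
                terms.append(BondedTerm("fan_bond", (i, n_bp + j),
                                        f"fan_{d}", delta=d))

    top = MoleculeTopology(beads, terms, sequence + seq2, "dna")
    top.validate()
    return top


def ideal_dsdna_coordinates(n_bp: int) -> np.ndarray:
    """Ideal B-form helix coordinates matching :func:`build_dsdna_topology`."""
    if n_bp < 1:
        raise TopologyError("n_bp must be >= 1")
    i = np.arange(n_bp)
    theta1 = np.deg2rad(BDNA_TWIST * i)
    z = BDNA_RISE * i
    s1 = np.column_stack([BDNA_RADIUS * np.cos(theta1),
                          BDNA_RADIUS * np.sin(theta1), z])
    theta2 = theta1 + np.deg2rad(BDNA_STRAND_PHASE)
    s2_by_bp = np.column_stack([BDNA_RADIUS * np.cos(theta2),
                                BDNA_RADIUS * np.sin(theta2), z])
    # strand-2 beads are indexed 5'->3' along strand 2: position p pairs
    # with strand-1 position n_bp-1-p
    s2 = s2_by_bp[::-1]
    return np.vstack([s1, s2])


# ---------------------------------------------------------------------------
# PDB / FASTA io
# ---------------------------------------------------------------------------

def _classify_residue(resname: str) -> tuple[str, str]:
    resname = resname.strip().upper()
    if resname in AA3_TO_1:
        return "protein", AA3_TO_1[resname]
    if resname in DNA_RESNAMES:
        return "dna", DNA_RESNAMES[resname]
    if resname in RNA_RESNAMES:
        return "rna", RNA_RESNAMES[resname]
    raise TopologyError(f"unknown residue name {resname!r}")


def parse_cg_pdb(path, force_field_tag: str = "HPS",
                 ) -> tuple[MoleculeTopology, np.ndarray]:
    """Read one molecule from a PDB file, reducing to one bead per residue.

    Proteins are reduced to their C-alpha positions (an atomistic input
    must carry one CA per residue); nucleotides are reduced to the residue
    centroid. Coordinates are returned in nm (PDB stores Angstrom).
    Consecutive residues within a chain are bonded.
    """
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("cg", str(path))
    model = next(structure.get_models())

    beads: list[Bead] = []
    coords: list[np.ndarray] = []
    terms: list[BondedTerm] = []
    kinds: set[str] = set()
    sequence = []
    for chain in model:
        first_in_chain = True
        for residue in chain:
            if residue.id[0].strip():
                continue  # skip heteroatoms/waters
            kind, code = _classify_residue(residue.get_resname())
            kinds.add(kind)
            atoms = list(residue.get_atoms())
            if kind == "protein":
                ca = [a for a in atoms if a.get_name() == "CA"]
                if not ca:
                    raise TopologyError(
                        f"residue {residue.get_resname()} {residue.id[1]} "
                        f"in chain {chain.id} has no CA atom")
                pos = ca[0].get_coord()
            else:
                pos = np.mean([a.get_coord() for a in atoms], axis=0)
            i = len(beads)
            beads.append(_make_bead(i, code, chain.id, kind, force_field_tag))
            coords.append(np.asarray(pos, dtype=float) / 10.0)  # A -> nm
            sequence.append(code)
            if not first_in_chain:
                key = "mrg_bond" if kind == "dna" else "backbone"
                terms.append(BondedTerm("bond", (i - 1, i), key))
            first_in_chain = False

    if not beads:
        raise TopologyError(f"no residues found in {path}")
    if len(kinds) > 1:
        raise TopologyError("mixed molecule kinds in one PDB are not supported")
    top = MoleculeTopology(beads, terms, "".join(sequence), kinds.pop())
    top.validate()
    return top, np.array(coords)


def write_cg_pdb(topology: MoleculeTopology, coords: np.ndarray, path,
                 multi_model_coords: Optional[Sequence[np.ndarray]] = None) -> None:
    """Write a coarse-grained topology as (multi-model) PDB, serials 1-based."""
    frames = [coords] if multi_model_coords is None else list(multi_model_coords)
    builder = StructureBuilder.StructureBuilder()
    builder.init_structure("cg")
    for m, frame in enumerate(frames):
        frame = np.asarray(frame, dtype=float)
        if frame.shape != (topology.n_beads, 3):
            raise TopologyError("coordinate shape does not match topology")
        builder.init_model(m)
        current_chain = None
        resseq = 0
        for bead, pos in zip(topology.beads, frame):
            if bead.chain_id != current_chain:
                builder.init_chain(bead.chain_id)
                builder.init_seg("    ")
                current_chain = bead.chain_id
                resseq = 0
            resseq += 1
            if topology.molecule_kind == "protein":
                resname = AA1_TO_3[bead.residue_code]
            elif topology.molecule_kind == "dna":
                resname = "D" + bead.residue_code
            else:
                resname = bead.residue_code
            builder.init_residue(resname, " ", resseq, " ")
            builder.init_atom(bead.name, pos * 10.0, 0.0, 1.0, " ",
                              bead.name.center(4), element=bead.name[0])
    io = PDBIO()
    io.set_structure(builder.get_structure())
    io.save(str(path))


_CHAIN_CYCLE = string.ascii_uppercase + string.ascii_lowercase + string.digits


def flatten_system(system: SystemTopology) -> MoleculeTopology:
    """All copies of a system as one multi-chain molecule (for PDB export).

    Chain ids cycle through one-character PDB ids, one per molecule copy
    (per-copy chains of multi-chain molecules are merged).
    """
    beads: list[Bead] = []
    terms: list[BondedTerm] = []
    seq: list[str] = []
    for mol, ci, (lo, _) in system.iter_copies():
        cid = _CHAIN_CYCLE[ci % len(_CHAIN_CYCLE)]
        for b in mol.beads:
            beads.append(replace(b, index=lo + b.index, chain_id=cid,
                                 molecule_index=ci))
        for t in mol.bonded_terms:
            terms.append(BondedTerm(t.kind,
                                    tuple(i + lo for i in t.bead_indices),
                                    t.coefficient_key, t.delta))
        seq.append(mol.sequence)
    kind = system.entries[0][0].molecule_kind
    return MoleculeTopology(beads, terms, "".join(seq), kind)


def read_fasta_sequence(path) -> str:
    """First record of a FASTA file as a plain one-letter string."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


# ---------------------------------------------------------------------------
# replication
# ---------------------------------------------------------------------------

MAX_INSERTION_ATTEMPTS = 10_000


class InsertionError(RuntimeError):
    def __init__(self, placed: int, requested: int):
        self.placed = placed
        super().__init__(
            f"could not place copy {placed + 1} of {requested} after "
            f"{MAX_INSERTION_ATTEMPTS} attempts; box too crowded?")


def replicate_into_box(molecule: MoleculeTopology, coords: np.ndarray,
                       n_copies: int, box, min_dist: float, seed: int,
                       ) -> tuple[SystemTopology, np.ndarray]:
    """Insert rigid, randomly rotated copies at random positions.

    Every inter-copy bead pair is kept at least ``min_dist`` apart under
    the minimum-image convention; placement is deterministic for a given
    seed. ``box`` is anything with a ``lengths`` triple (see
    :class:`cgphase.energetics.Box`).
    """
    if min_dist <= 0:
        raise TopologyError("min_dist must be positive")
    lengths = np.asarray(box.lengths, dtype=float)
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    span = 2.0 * np.linalg.norm(centered, axis=1).max()
    if span > lengths.min():
        raise TopologyError("molecule does not fit in the box")
    rng = np.random.default_rng(seed)

    placed: list[np.ndarray] = []
    tree = None
    for copy in range(n_copies):
        for _ in range(MAX_INSERTION_ATTEMPTS):
            rot = Rotation.from_quat(_random_quaternion(rng))
            trial = centered @ rot.as_matrix().T + rng.uniform(0, lengths)
            wrapped = np.mod(trial, lengths)
            if tree is not None:
                if tree.query_ball_point(wrapped, min_dist, return_length=True).sum():
                    continue
            placed.append(trial)
            all_pts = np.mod(np.vstack(placed), lengths)
            tree = cKDTree(all_pts, boxsize=lengths)
            break
        else:
            raise InsertionError(copy, n_copies)
    system = SystemTopology(entries=[(molecule, n_copies)])
    return system, np.vstack(placed)


def _random_quaternion(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    return q / np.linalg.norm(q)
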