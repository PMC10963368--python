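"""Domain containers shared by every analysis stage.

Conventions
-----------
* Residue and codon indices are 1-based and inclusive everywhere.
  Residue *i* of a protein corresponds to codon *i* of its ORF.
* Coordinates are in Angstrom, energies in kcal/mol, times in ns,
  masses in Da.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

# Standard atomic masses (Da) for the elements that occur in protein
# heavy-atom models plus hydrogen.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
    "P": 30.974,
    "SE": 78.971,
}

HEAVY_ELEMENTS = frozenset(ATOMIC_MASSES) - {"H"}

SAMPLE_KINDS = ("translatome", "interactome")


@dataclass
class Atom:
    name: str
    element: str
    coord: np.ndarray  # shape (3,), Angstrom

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise ValidationError(
                f"atom {self.name}: coordinates must be 3 finite floats"
            )
        self.element = self.element.strip().upper()


@dataclass
class Residue:
    index: int  # 1-based author residue number
    name: str  # 3-letter code
    atoms: list[Atom] = field(default_factory=list)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def has_ca(self) -> bool:
        return self.atom("CA") is not None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self):
        idx = [r.index for r in self.residues]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValidationError(
                f"chain {self.chain_id}: residue indices must be strictly increasing"
            )

    def residue(self, index: int) -> Residue | None:
        for r in self.residues:
            if r.index == index:
                return r
        return None


class ComplexStructure:
    """A (possibly multi-chain) protein structure.

    Atom order is the file/build order: chains, then residues, then atoms.
    This flat order is shared with :class:`Trajectory` frames.
    """

    def __init__(self, chains: list[Chain]):
        ids = [c.chain_id for c in chains]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate chain ids")
        self.chains = chains

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise ValidationError(f"unknown chain id {chain_id!r}")

    @property
    def chain_ids(self) -> list[str]:
        return [c.chain_id for c in self.chains]

    def iter_atoms(self):
        """Yield (flat_index, chain, residue, atom) in canonical order."""
        i = 0
        for c in self.chains:
            for r in c.residues:
                for a in r.atoms:
                    yield i, c, r, a
                    i += 1

    @property
    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains for r in c.residues)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coord for _, _, _, a in self.iter_atoms()], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValidationError("coordinate array shape mismatch")
        for i, _, _, a in self.iter_atoms():
            a.coord = coords[i]

    @property
    def masses(self) -> np.ndarray:
        return np.array(
            [ATOMIC_MASSES.get(a.element, 12.011) for _, _, _, a in self.iter_atoms()]
        )

    def atom_index(self, chain_id: str, residue_index: int, atom_name: str) -> int:
        for i, c, r, a in self.iter_atoms():
            if c.chain_id == chain_id and r.index == residue_index and a.name == atom_name:
                return i
        raise ValidationError(
            f"atom {chain_id}/{residue_index}/{atom_name} not found"
        )

    def ca_map(self, chain_id: str) -> dict[int, np.ndarray]:
        """residue index -> Cα coordinate for one chain."""
        out = {}
        for c, r, a in (
            (c, r, a) for _, c, r, a in self.iter_atoms() if c.chain_id == chain_id
        ):
            if a.name == "CA":
                out[r.index] = a.coord
        return out

    def heavy_coords(self, chain_id: str) -> np.ndarray:
        pts = [
            a.coord
            for _, c, r, a in self.iter_atoms()
            if c.chain_id == chain_id and a.element in HEAVY_ELEMENTS
        ]
        return np.array(pts, dtype=float) if pts else np.empty((0, 3))


@dataclass
class Trajectory:
    """A conformational ensemble congruent with a reference structure."""

    reference: ComplexStructure
    frames: np.ndarray  # (n_frames, n_atoms, 3)
    frame_times: np.ndarray  # ns, strictly increasing
    masses: np.ndarray | None = None  # Da; defaults to element masses

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        n_atoms = self.reference.n_atoms
        if self.frames.ndim != 3 or self.frames.shape[1:] != (n_atoms, 3):
            raise ValidationError(
                f"frames must have shape (n_frames, {n_atoms}, 3), "
                f"got {self.frames.shape}"
            )
        if len(self.frame_times) != len(self.frames):
            raise ValidationError("frame_times length must equal frame count")
        if np.any(np.diff(self.frame_times) <= 0):
            raise ValidationError("frame_times must be strictly increasing")
        if self.masses is None:
            self.masses = self.reference.masses
        self.masses = np.asarray(self.masses, dtype=float)
        if self.masses.shape != (n_atoms,):
            raise ValidationError("masses length must equal atom count")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass
class FootprintProfile:
    """Per-codon ribosome-footprint read counts for one ORF/sample/replicate."""

    orf_id: str
    sample_kind: str  # "translatome" | "interactome"
    replicate_id: int
    counts: np.ndarray  # non-negative ints, length = ORF length in codons
    total_mapped_reads: int  # library size

    def __post_init__(self):
        if self.sample_kind not in SAMPLE_KINDS:
            raise ValidationError(
                f"sample_kind must be one of {SAMPLE_KINDS}, got {self.sample_kind!r}"
            )
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValidationError("counts must be a 1-D vector")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if self.total_mapped_reads < int(self.counts.sum()):
            raise ValidationError(
                "total_mapped_reads must be at least the sum of ORF counts"
            )

    @property
    def length(self) -> int:
        return len(self.counts)


@dataclass
class CoreRegionMap:
    """Residue correspondences between two subunits (external aligner output)."""

    pairs: list[tuple[int, int]]
    source_label: str = ""

    def __post_init__(self):
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValidationError("a residue index may appear at most once per side")
        if any(p[0] < 1 or p[1] < 1 for p in self.pairs):
            raise ValidationError("residue indices are 1-based (>= 1)")


class EnergyTable:
    """Per-residue interface energy contributions (ΔΔG, kcal/mol) with replicates.

    Rows are unique (chain_id, residue_index) pairs of one subunit;
    columns of ``replicates`` are independent production runs.
    """

    def __init__(
        self,
        residue_index: np.ndarray,
        replicates: np.ndarray,
        residue_name: list[str] | None = None,
        chain_id: str | list[str] = "A",
        subunit_label: str = "",
        orf_length: int | None = None,
    ):
        self.residue_index = np.asarray(residue_index, dtype=np.int64)
        self.replicates = np.atleast_2d(np.asarray(replicates, dtype=float))
        n = len(self.residue_index)
        if self.replicates.shape[0] != n:
            raise ValidationError("replicates must have one row per residue")
        if len(set(self.residue_index.tolist())) != n:
            raise ValidationError("duplicate residue indices")
        if np.any(self.residue_index < 1):
            raise ValidationError("residue indices are 1-based (>= 1)")
        self.residue_name = list(residue_name) if residue_name else ["UNK"] * n
        self.chain_id = (
            [chain_id] * n if isinstance(chain_id, str) else list(chain_id)
        )
        self.subunit_label = subunit_label
        self.orf_length = (
            int(orf_length)
            if orf_length is not None
            else int(self.residue_index.max(initial=0))
        )
        if n and self.residue_index.max() > self.orf_length:
            raise ValidationError("residue_index exceeds orf_length")
        # filled by interface_energetics.aggregate_replicates
        self.mean: np.ndarray | None = None
        self.sd: np.ndarray | None = None
        self.single_replicate_warning: bool = False

    @property
    def n_residues(self) -> int:
        return len(self.residue_index)

    @property
    def n_rep(self) -> int:
        return self.replicates.shape[1]

    def require_means(self) -> np.ndarray:
        if self.mean is None:
            raise ValidationError(
                "per-residue means not computed; call aggregate_replicates first"
            )
        return self.mean

    def mean_by_residue(self) -> dict[int, float]:
        means = self.require_means()
        return {int(i): float(m) for i, m in zip(self.residue_index, means)}
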