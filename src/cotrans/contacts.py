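"""Geometric interface, partner-contact, and hydrogen-bond determination
on static structures.

Two distinct contact criteria are kept separate on purpose:

* subunit–subunit interface residues: Cα within 4 Angstrom of a partner
  chain's Cα (inclusive),
* contacts against an arbitrary partner heavy-atom cloud (e.g. the
  ribosome surface): Cα within 4 Angstrom of any partner heavy atom.

Hydrogen bonds use a donor/acceptor-agnostic N/O heavy-atom distance
criterion (default 3.5 Angstrom); when the structure carries explicit
hydrogens a D-H...A angle minimum (default 120 degrees) is applied too.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import ComplexStructure
from .exceptions import ValidationError


def interface_residues(structure: ComplexStructure, chain_a: str, chain_b: str,
                       cutoff: float = 4.0) -> tuple[set[int], set[int]]:
    """Residues of each chain whose Cα lies within ``cutoff`` (inclusive)
    of any Cα of the other chain.  Returns ``(set_a, set_b)``."""
    ca_a = structure.ca_map(chain_a)
    ca_b = structure.ca_map(chain_b)
    if not ca_a or not ca_b:
        raise ValidationError("both chains need Cα atoms")
    res_a = list(ca_a)
    res_b = list(ca_b)
    xa = np.array([ca_a[r] for r in res_a])
    xb = np.array([ca_b[r] for r in res_b])
    tree_b = cKDTree(xb)
    pairs = tree_b.query_ball_point(xa, cutoff)
    set_a = {res_a[i] for i, hits in enumerate(pairs) if hits}
    set_b = {res_b[j] for hits in pairs for j in hits}
    return set_a, set_b


def contact_residues_heavy(structure: ComplexStructure, chain: str,
                           partner_atoms: np.ndarray,
                           cutoff: float = 4.0) -> set[int]:
    """Residues of ``chain`` whose Cα lies within ``cutoff`` (inclusive)
    of any coordinate in ``partner_atoms``.

    ``partner_atoms`` must be the partner's *heavy* atoms only; callers
    exclude hydrogens by element before passing coordinates in.
    """
    partner_atoms = np.asarray(partner_atoms, dtype=float)
    if partner_atoms.size == 0:
        raise ValidationError("empty partner atom set")
    ca = structure.ca_map(chain)
    if not ca:
        raise ValidationError(f"chain {chain!r} has no Cα atoms")
    tree = cKDTree(partner_atoms)
    return {
        res
        for res, xyz in ca.items()
        if tree.query_ball_point(xyz, cutoff)
    }


@dataclass
class HydrogenBond:
    donor_residue: int
    acceptor_residue: int
    donor_atom: str
    acceptor_atom: str
    distance: float  # heavy-atom N/O...N/O distance, Angstrom


def _polar_atoms(structure: ComplexStructure, chain_id: str,
                 residues: set[int]):
    """(residue, atom_name, coord, attached hydrogens) for N/O heavy atoms."""
    out = []
    chain = structure.chain(chain_id)
    for r in chain.residues:
        if r.index not in residues:
            continue
        hydrogens = [a.coord for a in r.atoms if a.element == "H"]
        for a in r.atoms:
            if a.element in ("N", "O"):
                out.append((r.index, a.name, a.coord, hydrogens))
    return out


def hydrogen_bonds(structure: ComplexStructure,
                   group_a: set[int], group_b: set[int],
                   chain_id: str = "A",
                   d_max: float = 3.5,
                   angle_min: float = 120.0) -> list[HydrogenBond]:
    """Hydrogen bonds between two residue groups of one chain.

    All N and O heavy atoms are treated as both donor- and
    acceptor-capable.  A bond is reported when the N/O...N/O distance is
    <= ``d_max``; if the donor residue carries explicit hydrogens, the
    best D-H...A angle must additionally be >= ``angle_min`` degrees
    (distance-only mode otherwise).  Bonds within a group, or of a
    residue with itself, are not reported.
    """
    atoms_a = _polar_atoms(structure, chain_id, set(group_a))
    atoms_b = _polar_atoms(structure, chain_id, set(group_b))
    bonds = []
    for res_a, name_a, xa, hyd_a in atoms_a:
        for res_b, name_b, xb, _ in atoms_b:
            if res_a == res_b:
                continue
            d = float(np.linalg.norm(xa - xb))
            if d > d_max:
                continue
            if hyd_a:
                angles = [_dha_angle(xa, h, xb) for h in hyd_a]
                if max(angles) < angle_min:
                    continue
            bonds.append(
                HydrogenBond(
                    donor_residue=res_a,
                    acceptor_residue=res_b,
                    donor_atom=name_a,
                    acceptor_atom=name_b,
                    distance=d,
                )
            )
    return bonds


def _dha_angle(donor: np.ndarray, hydrogen: np.ndarray,
               acceptor: np.ndarray) -> float:
    v1 = donor - hydrogen
    v2 = acceptor - hydrogen
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
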