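"""Readers and writers for the on-disk formats.

Formats
-------
* PDB v3.3 fixed-column coordinate files (single- and multi-model) via
  biotite; insertion codes are rejected as an unsupported dialect and
  altloc is resolved to the highest occupancy (ties keep the first listed).
* Footprint profile TSV: a header block of per-ORF declarations followed
  by sparse per-codon counts (see :func:`read_profiles`).
* Energy table CSV: one row per (chain, residue, replicate).
* Core-region map TSV: two 1-based residue-index columns.

All readers and writers round-trip at the declared precision (PDB
coordinates: 3 decimals).
"""

from __future__ import annotations

import io as _io

import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .datatypes import (
    Atom,
    Chain,
    ComplexStructure,
    CoreRegionMap,
    EnergyTable,
    FootprintProfile,
    Residue,
    Trajectory,
)
from .exceptions import (
    DuplicateKeyError,
    EmptyInputError,
    ParseError,
    SchemaError,
    UnsupportedDialectError,
    ValidationError,
)

# ---------------------------------------------------------------------------
# PDB structures
# ---------------------------------------------------------------------------


def _prevalidate_pdb(path) -> list[str]:
    """Scan raw PDB lines, enforcing the supported dialect.

    Returns the lines so the caller can hand them to biotite.
    Raises with 1-based line numbers so errors are actionable.
    """
    with open(path) as fh:
        lines = fh.readlines()
    n_coord = 0
    for lineno, line in enumerate(lines, start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        n_coord += 1
        stripped = line.rstrip("\n")
        if len(stripped) < 54:
            raise ParseError(
                f"line {lineno}: ATOM/HETATM record too short "
                f"({len(stripped)} columns, need 54 for coordinates)"
            )
        if stripped[26] != " ":
            raise UnsupportedDialectError(
                f"line {lineno}: insertion code {stripped[26]!r} not supported"
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(stripped[lo:hi])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: cannot parse {what} coordinate "
                    f"field {stripped[lo:hi]!r}"
                ) from None
    if n_coord == 0:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    return lines


def _atom_array_to_structure(arr) -> ComplexStructure:
    chains: list[Chain] = []
    cur_chain = None
    cur_res = None
    for i in range(arr.array_length()):
        cid = str(arr.chain_id[i])
        rid = int(arr.res_id[i])
        if cur_chain is None or cur_chain.chain_id != cid:
            cur_chain = Chain(cid, [])
            chains.append(cur_chain)
            cur_res = None
        if cur_res is None or cur_res.index != rid:
            cur_res = Residue(rid, str(arr.res_name[i]), [])
            cur_chain.residues.append(cur_res)
        elem = str(arr.element[i]) or str(arr.atom_name[i])[:1]
        cur_res.atoms.append(Atom(str(arr.atom_name[i]), elem, arr.coord[i]))
    # re-run the strictly-increasing residue check skipped during appends
    return ComplexStructure([Chain(c.chain_id, c.residues) for c in chains])


def read_structure(path, model: int = 1) -> ComplexStructure:
    """Read one model of a PDB file as a :class:`ComplexStructure`."""
    lines = _prevalidate_pdb(path)
    pdb = PDBFile.read(_io.StringIO("".join(lines)))
    try:
        arr = pdb.get_structure(model=model, altloc="occupancy")
    except Exception as exc:  # biotite-level failure -> our error type
        raise ParseError(f"{path}: {exc}") from exc
    return _atom_array_to_structure(arr)


def read_trajectory(path, frame_time_step_ns: float = 1.0) -> Trajectory:
    """Read a multi-model PDB as a trajectory.

    Model 1 provides the reference topology; frame times are synthesized
    on a uniform grid (``frame_time_step_ns`` apart) since PDB carries no
    time information.
    """
    lines = _prevalidate_pdb(path)
    pdb = PDBFile.read(_io.StringIO("".join(lines)))
    try:
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    reference = _atom_array_to_structure(stack[0])
    frames = np.asarray(stack.coord, dtype=float)
    times = frame_time_step_ns * np.arange(len(frames), dtype=float)
    return Trajectory(reference=reference, frames=frames, frame_times=times)


def _structure_to_atom_array(structure: ComplexStructure):
    import biotite.structure as struc

    n = structure.n_atoms
    arr = struc.AtomArray(n)
    for i, c, r, a in structure.iter_atoms():
        arr.chain_id[i] = c.chain_id
        arr.res_id[i] = r.index
        arr.res_name[i] = r.name
        arr.atom_name[i] = a.name
        arr.element[i] = a.element
        arr.coord[i] = a.coord
        arr.hetero[i] = False
    return arr


def write_structure(path, structure: ComplexStructure) -> None:
    pdb = PDBFile()
    pdb.set_structure(_structure_to_atom_array(structure))
    pdb.write(path)


def write_trajectory(path, traj: Trajectory) -> None:
    import biotite.structure as struc

    template = _structure_to_atom_array(traj.reference)
    stack = struc.from_template(template, traj.frames)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(path)


# ---------------------------------------------------------------------------
# Footprint profiles
# ---------------------------------------------------------------------------

_PROFILE_COLUMNS = ["orf_id", "sample_kind", "replicate_id", "codon_index", "count"]


def read_profiles(path) -> list[FootprintProfile]:
    """Read footprint profiles from the sparse per-codon TSV format.

    Layout::

        #orf_length<TAB><orf_id><TAB><L_codons>           (one per ORF, required)
        #library_size<TAB><orf_id><TAB><kind><TAB><rep><TAB><reads>  (optional)
        orf_id  sample_kind  replicate_id  codon_index  count
        ...data rows...

    Codons absent from the data rows are densified to zero.  A profile
    without a library-size declaration gets the sum of its own counts.
    """
    lengths: dict[str, int] = {}
    libsizes: dict[tuple[str, str, int], int] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split("\t")
                if parts[0] == "orf_length" and len(parts) == 3:
                    lengths[parts[1]] = int(parts[2])
                elif parts[0] == "library_size" and len(parts) == 5:
                    libsizes[(parts[1], parts[2], int(parts[3]))] = int(parts[4])
                else:
                    raise SchemaError(f"line {lineno}: unrecognized header {line!r}")
            else:
                data_lines.append(line)
    if not data_lines:
        raise EmptyInputError(f"{path}: no data rows")
    df = pd.read_csv(_io.StringIO("\n".join(data_lines)), sep="\t")
    missing = set(_PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        raise ValidationError(f"{path}: negative counts")
    profiles = []
    for (orf, kind, rep), grp in df.groupby(
        ["orf_id", "sample_kind", "replicate_id"], sort=True
    ):
        if orf not in lengths:
            raise SchemaError(f"{path}: no '#orf_length' declaration for ORF {orf!r}")
        L = lengths[orf]
        idx = grp["codon_index"].to_numpy()
        if idx.min() < 1 or idx.max() > L:
            raise ValidationError(
                f"{path}: codon_index outside [1, {L}] for ORF {orf!r}"
            )
        if len(np.unique(idx)) != len(idx):
            raise DuplicateKeyError(
                f"{path}: duplicate codon_index for {orf}/{kind}/{rep}"
            )
        counts = np.zeros(L, dtype=np.int64)
        counts[idx - 1] = grp["count"].to_numpy()
        total = libsizes.get((orf, str(kind), int(rep)), int(counts.sum()))
        profiles.append(
            FootprintProfile(
                orf_id=str(orf),
                sample_kind=str(kind),
                replicate_id=int(rep),
                counts=counts,
                total_mapped_reads=total,
            )
        )
    return profiles


def write_profiles(path, profiles: list[FootprintProfile]) -> None:
    lengths: dict[str, int] = {}
    for p in profiles:
        if lengths.setdefault(p.orf_id, p.length) != p.length:
            raise ValidationError(f"inconsistent lengths for ORF {p.orf_id!r}")
    with open(path, "w") as fh:
        for orf, L in sorted(lengths.items()):
            fh.write(f"#orf_length\t{orf}\t{L}\n")
        for p in profiles:
            fh.write(
                f"#library_size\t{p.orf_id}\t{p.sample_kind}"
                f"\t{p.replicate_id}\t{p.total_mapped_reads}\n"
            )
        fh.write("\t".join(_PROFILE_COLUMNS) + "\n")
        for p in profiles:
            nz = np.nonzero(p.counts)[0]
            for i in nz:
                fh.write(
                    f"{p.orf_id}\t{p.sample_kind}\t{p.replicate_id}"
                    f"\t{i + 1}\t{p.counts[i]}\n"
                )


# ---------------------------------------------------------------------------
# Energy tables
# ---------------------------------------------------------------------------

_ENERGY_COLUMNS = ["chain_id", "residue_index", "residue_name", "replicate_id",
                   "ddG_kcal_mol"]


def read_energy_table(path, subunit_label: str = "",
                      orf_length: int | None = None) -> EnergyTable:
    """Read a per-residue ΔΔG decomposition CSV into an :class:`EnergyTable`."""
    try:
        df = pd.read_csv(path)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(_ENERGY_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    if not pd.api.types.is_numeric_dtype(df["ddG_kcal_mol"]):
        bad = df[pd.to_numeric(df["ddG_kcal_mol"], errors="coerce").isna()]
        raise ParseError(
            f"{path}: non-numeric energies, e.g. "
            f"{bad['ddG_kcal_mol'].iloc[0]!r}"
        )
    key = ["chain_id", "residue_index", "replicate_id"]
    dup = df.duplicated(subset=key)
    if dup.any():
        first = df.loc[dup, key].iloc[0].tolist()
        raise DuplicateKeyError(f"{path}: duplicate (chain, residue, replicate) "
                                f"row, e.g. {first}")
    reps = sorted(df["replicate_id"].unique())
    pivot = df.pivot_table(
        index=["chain_id", "residue_index"],
        columns="replicate_id",
        values="ddG_kcal_mol",
    )
    if pivot.isna().any().any():
        bad = pivot[pivot.isna().any(axis=1)].index.tolist()
        raise ValidationError(
            f"{path}: non-uniform replicate coverage for residues {bad}"
        )
    pivot = pivot[reps].sort_index()
    names = (
        df.drop_duplicates(subset=["chain_id", "residue_index"])
        .set_index(["chain_id", "residue_index"])["residue_name"]
    )
    chain_ids = [str(c) for c, _ in pivot.index]
    res_idx = np.array([int(r) for _, r in pivot.index])
    res_names = [str(names.loc[k]) for k in pivot.index]
    return EnergyTable(
        residue_index=res_idx,
        replicates=pivot.to_numpy(),
        residue_name=res_names,
        chain_id=chain_ids,
        subunit_label=subunit_label,
        orf_length=orf_length,
    )


def write_energy_table(path, table: EnergyTable) -> None:
    rows = []
    for i in range(table.n_residues):
        for j in range(table.n_rep):
            rows.append(
                (
                    table.chain_id[i],
                    int(table.residue_index[i]),
                    table.residue_name[i],
                    j + 1,
                    table.replicates[i, j],
                )
            )
    pd.DataFrame(rows, columns=_ENERGY_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Core-region maps
# ---------------------------------------------------------------------------


def read_region_map(path, source_label: str | None = None) -> CoreRegionMap:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: need two residue-index columns")
    pairs = [
        (int(a), int(b)) for a, b in zip(df.iloc[:, 0], df.iloc[:, 1])
    ]
    return CoreRegionMap(pairs=pairs, source_label=source_label or str(path))


def write_region_map(path, region_map: CoreRegionMap) -> None:
    with open(path, "w") as fh:
        fh.write("residue_a\tresidue_b\n")
        for a, b in region_map.pairs:
            fh.write(f"{a}\t{b}\n")
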