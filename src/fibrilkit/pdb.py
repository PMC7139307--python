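"""Fixed-column PDB reading and writing.

Multi-model files (MODEL/ENDMDL blocks) are read as trajectories; single-model
files as structures.  Coordinates are converted between the PDB's angstroms
and the package-internal nanometres at this boundary.

Only the ATOM/HETATM/MODEL/ENDMDL/TER/END records are interpreted; everything
else is ignored.  Altloc conflicts keep the first conformer (with a warning);
insertion codes are rejected because fibril models do not use them.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np

from .structure import AtomRecord, Structure, Trajectory

__all__ = ["read_pdb", "write_pdb", "PDBParseError"]

A_PER_NM = 10.0


class PDBParseError(ValueError):
    """Raised for malformed fixed-column records (carries the line number)."""


def _parse_atom_line(line: str, lineno: int) -> tuple[AtomRecord, str]:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain_id = line[21].strip() or " "
        resid = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}")
    if icode:
        raise PDBParseError(f"line {lineno}: insertion codes are unsupported")
    if not element:
        # fall back on the atom-name convention used by PDB columns 13-14
        element = "".join(c for c in name if c.isalpha())[:1].upper()
    record = AtomRecord(
        serial=serial,
        name=name,
        element=element,
        residue_name=resname,
        residue_id=resid,
        chain_id=chain_id,
        position=(x / A_PER_NM, y / A_PER_NM, z / A_PER_NM),
        is_hetero=line.startswith("HETATM"),
    )
    return record, altloc


def read_pdb(path: str | Path, time_per_frame: float = 1.0):
    """Read a PDB file into a :class:`Structure` or :class:`Trajectory`.

    A file without MODEL records, or with exactly one, yields a Structure;
    a file with several MODEL blocks yields a Trajectory whose frames are the
    models in file order (``time_per_frame`` in ns applies to the result).

    Raises
    ------
    PDBParseError
        On malformed fixed-column records (message carries the line number)
        or when models disagree on atom count/identity.
    """
    path = Path(path)
    models: list[list[AtomRecord]] = []
    current: list[AtomRecord] = []
    seen_altloc: set[tuple[str, int, str]] = set()
    in_model = False
    any_model_kw = False
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("MODEL"):
                any_model_kw = True
                in_model = True
                current = []
                seen_altloc = set()
            elif line.startswith("ENDMDL"):
                in_model = False
                models.append(current)
                current = []
            elif line.startswith(("ATOM", "HETATM")):
                record, altloc = _parse_atom_line(line, lineno)
                if altloc:
                    key = (record.chain_id, record.residue_id, record.name)
                    if key in seen_altloc:
                        warnings.warn(
                            f"line {lineno}: alternate conformer for {key} "
                            "ignored; keeping the first"
                        )
                        continue
                    seen_altloc.add(key)
                current.append(record)
    if current:
        models.append(current)
    if not models or not any(models):
        raise PDBParseError(f"{path}: no ATOM/HETATM records found")
    models = [m for m in models if m]

    first = models[0]
    topology = Structure(first)
    if len(models) == 1 and not any_model_kw:
        return topology
    if len(models) == 1:
        # a single MODEL block still describes one structure
        return topology

    n = len(first)
    frames = np.empty((len(models), n, 3), dtype=float)
    ident = [(a.chain_id, a.residue_id, a.name) for a in first]
    for m, model in enumerate(models):
        if len(model) != n:
            raise PDBParseError(
                f"{path}: model {m + 1} has {len(model)} atoms, expected {n}"
            )
        for i, a in enumerate(model):
            if (a.chain_id, a.residue_id, a.name) != ident[i]:
                raise PDBParseError(
                    f"{path}: model {m + 1} atom {i + 1} identity mismatch"
                )
            frames[m, i] = a.position
    return Trajectory(topology, frames, time_per_frame=time_per_frame)


def _format_atom_line(a: AtomRecord, serial: int, pos_nm) -> str:
    record = "HETATM" if a.is_hetero else "ATOM  "
    if len(a.chain_id) != 1:
        raise ValueError(f"chain id {a.chain_id!r} not single-character")
    x, y, z = (c * A_PER_NM for c in pos_nm)
    for c in (x, y, z):
        if not (-999.999 <= c <= 9999.999):
            raise ValueError(
                f"coordinate {c:.3f} A overflows the PDB field width"
            )
    name = a.name
    # standard alignment: 1-3 char names start in column 14
    name_field = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record}{serial:>5d} {name_field}{'':1s}{a.residue_name:>3s} "
        f"{a.chain_id}{a.residue_id:>4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
        f"{a.element:>2s}\n"
    )


def _write_model(fh, structure: Structure, coords) -> None:
    serial = 0
    prev_chain = None
    for a, pos in zip(structure.atoms, coords):
        if prev_chain is not None and a.chain_id != prev_chain:
            fh.write("TER\n")
        prev_chain = a.chain_id
        serial += 1
        fh.write(_format_atom_line(a, serial, pos))
    fh.write("TER\n")


def write_pdb(obj, path: str | Path) -> None:
    """Write a Structure or Trajectory as a fixed-column PDB file.

    Trajectories are emitted as consecutive MODEL/ENDMDL blocks.  Coordinates
    that would overflow the 8.3 fixed field raise instead of being silently
    truncated.
    """
    path = Path(path)
    if isinstance(obj, Structure):
        if obj.n_atoms == 0:
            raise ValueError("nothing to write: structure has no atoms")
        with path.open("w") as fh:
            _write_model(fh, obj, obj.coords)
            fh.write("END\n")
        return
    if isinstance(obj, Trajectory):
        if obj.n_frames == 0 or obj.topology.n_atoms == 0:
            raise ValueError("nothing to write: empty trajectory")
        with path.open("w") as fh:
            for m in range(obj.n_frames):
                fh.write(f"MODEL {m + 1:>8d}\n")
                _write_model(fh, obj.topology, obj.frames[m])
                fh.write("ENDMDL\n")
            fh.write("END\n")
        return
    raise TypeError(f"cannot write object of type {type(obj).__name__}")
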