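"""In-memory model of fibril structures and trajectories.

A :class:`Structure` is an ordered list of atoms grouped into chains and
residues, with coordinates in nanometres.  A :class:`Trajectory` is a stack of
coordinate frames sharing one topology.  Atom subsets are addressed through
:class:`SelectionMask` objects produced by :func:`select`.

All coordinates are stored in **nm**; file readers and writers convert at the
boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRecord",
    "Structure",
    "Trajectory",
    "SelectionMask",
    "select",
    "ATOMIC_MASSES",
]

#: Standard atomic masses (g/mol) for the elements a fibril model can contain.
ATOMIC_MASSES = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "S": 32.06,
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom of a structure.

    Parameters
    ----------
    serial
        Atom serial number as written in the source file.
    name
        Atom name, e.g. ``"CA"``, ``"N"``, ``"C"``, ``"O"``.
    element
        Element symbol; must be non-empty.
    residue_name
        Three-letter residue name (``"GLY"``, ``"LIG"``, ...).
    residue_id
        Residue sequence number.  Fibril fixtures follow the amyloid-beta
        numbering convention (residues 11-42).
    chain_id
        Single-character chain identifier.
    position
        Cartesian position in nm.
    is_hetero
        True for HETATM records (ligand / non-polymer atoms).
    """

    serial: int
    name: str
    element: str
    residue_name: str
    residue_id: int
    chain_id: str
    position: tuple[float, float, float]
    is_hetero: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element symbol")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.serial}: non-finite position")


class Structure:
    """An ordered collection of atoms with a defined chain stacking order."""

    def __init__(
        self,
        atoms: Sequence[AtomRecord],
        chain_order: Sequence[str] | None = None,
    ) -> None:
        self.atoms: list[AtomRecord] = list(atoms)
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        if chain_order is None:
            chain_order = seen
        else:
            chain_order = list(chain_order)
            if set(chain_order) != set(seen):
                raise ValueError(
                    f"chain_order {chain_order} does not match chains present {seen}"
                )
        self.chain_order: list[str] = chain_order
        self._validate()
        self._coords = np.array([a.position for a in self.atoms], dtype=float)

    def _validate(self) -> None:
        keys = set()
        for a in self.atoms:
            k = (a.chain_id, a.residue_id, a.name)
            if k in keys:
                raise ValueError(f"duplicate atom {k}")
            keys.add(k)
        # residues must be contiguous runs within each chain
        seen_res: set[tuple[str, int]] = set()
        prev: tuple[str, int] | None = None
        for a in self.atoms:
            k = (a.chain_id, a.residue_id)
            if k != prev:
                if k in seen_res:
                    raise ValueError(f"residue {k} is not contiguous in atom order")
                seen_res.add(k)
                prev = k

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in nm."""
        return self._coords

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Return a copy of this structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise ValueError(f"expected shape {(self.n_atoms, 3)}, got {coords.shape}")
        atoms = [replace(a, position=tuple(c)) for a, c in zip(self.atoms, coords)]
        return Structure(atoms, chain_order=self.chain_order)

    def chain_indices(self, chain_id: str) -> np.ndarray:
        return np.array(
            [i for i, a in enumerate(self.atoms) if a.chain_id == chain_id], dtype=int
        )

    def residues(self) -> list[tuple[str, int, str]]:
        """Ordered unique residues as (chain_id, residue_id, residue_name)."""
        out: list[tuple[str, int, str]] = []
        prev = None
        for a in self.atoms:
            k = (a.chain_id, a.residue_id, a.residue_name)
            if (a.chain_id, a.residue_id) != prev:
                out.append(k)
                prev = (a.chain_id, a.residue_id)
        return out

    def masses(self) -> np.ndarray:
        try:
            return np.array([ATOMIC_MASSES[a.element] for a in self.atoms])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"no mass for element {exc}") from exc

    def __repr__(self) -> str:
        return (
            f"<Structure {self.n_atoms} atoms, "
            f"{len(self.chain_order)} chains {self.chain_order}>"
        )


class Trajectory:
    """Frames sharing one topology.

    ``frames`` is an (n_frames, n_atoms, 3) array in nm; ``time_per_frame``
    maps frame indices to simulated time in ns.
    """

    def __init__(
        self,
        topology: Structure,
        frames: np.ndarray,
        time_per_frame: float = 1.0,
    ) -> None:
        frames = np.asarray(frames, dtype=float)
        if frames.ndim != 3 or frames.shape[1:] != (topology.n_atoms, 3):
            raise ValueError(
                f"frames shape {frames.shape} incompatible with "
                f"{topology.n_atoms}-atom topology"
            )
        if time_per_frame <= 0:
            raise ValueError("time_per_frame must be > 0")
        self.topology = topology
        self.frames = frames
        self.time_per_frame = float(time_per_frame)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, index: int) -> Structure:
        return self.topology.with_coords(self.frames[index])

    def window_frames(self, window_ns: float) -> np.ndarray:
        """Frame indices covering the final ``window_ns`` nanoseconds.

        The window is ``round(window_ns / time_per_frame)`` trailing frames,
        clipped to at least one frame.
        """
        n = int(round(window_ns / self.time_per_frame))
        n = max(1, min(n, self.n_frames))
        return np.arange(self.n_frames - n, self.n_frames)

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.time_per_frame

    def __repr__(self) -> str:
        return (
            f"<Trajectory {self.n_frames} frames x {self.topology.n_atoms} atoms, "
            f"dt={self.time_per_frame} ns>"
        )


@dataclass(frozen=True)
class SelectionMask:
    """Strictly increasing atom indices into a topology, with provenance."""

    indices: tuple[int, ...]
    query: str = ""

    def __post_init__(self) -> None:
        idx = np.asarray(self.indices, dtype=int)
        if idx.size and np.any(np.diff(idx) <= 0):
            raise ValueError("selection indices must be strictly increasing")
        if idx.size and idx[0] < 0:
            raise ValueError("selection indices must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)

    def check_bounds(self, n_atoms: int) -> None:
        if self.indices and self.indices[-1] >= n_atoms:
            raise IndexError(
                f"selection index {self.indices[-1]} out of bounds for "
                f"{n_atoms} atoms"
            )


def select(
    structure: Structure,
    *,
    chains: Iterable[str] | None = None,
    residue_range: tuple[int, int] | None = None,
    names: Iterable[str] | None = None,
    heavy_only: bool = False,
    hetero: bool | None = None,
) -> SelectionMask:
    """Select atoms by chain, residue range, atom name, heaviness or HET flag.

    All criteria given are combined with AND.  An empty result is legal;
    downstream operations that require atoms reject empty masks themselves.

    Parameters
    ----------
    chains
        Chain identifiers to keep.
    residue_range
        Inclusive ``(low, high)`` residue-id range.
    names
        Atom names to keep (e.g. ``{"CA"}``).
    heavy_only
        Drop hydrogens.
    hetero
        If True keep only HETATM atoms, if False only polymer atoms,
        if None keep both.
    """
    chains_set = set(chains) if chains is not None else None
    names_set = set(names) if names is not None else None
    idx = []
    for i, a in enumerate(structure.atoms):
        if chains_set is not None and a.chain_id not in chains_set:
            continue
        if residue_range is not None and not (
            residue_range[0] <= a.residue_id <= residue_range[1]
        ):
            continue
        if names_set is not None and a.name not in names_set:
            continue
        if heavy_only and a.element == "H":
            continue
        if hetero is not None and a.is_hetero != hetero:
            continue
        idx.append(i)
    parts = []
    if chains_set is not None:
        parts.append(f"chains={sorted(chains_set)}")
    if residue_range is not None:
        parts.append(f"residues={residue_range[0]}-{residue_range[1]}")
    if names_set is not None:
        parts.append(f"names={sorted(names_set)}")
    if heavy_only:
        parts.append("heavy")
    if hetero is not None:
        parts.append(f"hetero={hetero}")
    return SelectionMask(tuple(idx), " and ".join(parts) or "all")
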