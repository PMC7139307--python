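"""Shrake-Rupley solvent-accessible surface area and inter-chain contact area.

The fibril-stability readout here is the interaction area between adjacent
chains of the stack: half the solvent-accessible area buried when two chains
are brought together,

    buried(A, B) = [sasa(A alone) + sasa(B alone) - sasa(A union B)] / 2.

Because "contact surface with a distance cut-off" admits a second reading, a
count of cross-chain heavy-atom pairs within the cutoff is computed alongside
the buried area, so either definition of chain-chain contact can be tracked.

SASA uses a deterministic Fibonacci-sphere quadrature: the accessible area of
an atom is the unoccluded fraction of points on its probe-expanded sphere
times the sphere area.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .structure import SelectionMask, Trajectory, select

__all__ = [
    "DEFAULT_RADII",
    "SasaResult",
    "InteractionAreaSeries",
    "sasa",
    "buried_area",
    "contact_pair_count",
    "interchain_area_series",
]

#: van der Waals radii in nm
DEFAULT_RADII = {"C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18, "H": 0.12}
DEFAULT_PROBE_NM = 0.14
DEFAULT_N_POINTS = 960


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic, nearly uniform unit-sphere point set."""
    k = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


_SPHERE_CACHE: dict[int, np.ndarray] = {}


def _sphere(n: int) -> np.ndarray:
    if n not in _SPHERE_CACHE:
        _SPHERE_CACHE[n] = _fibonacci_sphere(n)
    return _SPHERE_CACHE[n]


def _exposed_counts_numpy(coords, radii, sphere, indptr, indices) -> np.ndarray:
    n = coords.shape[0]
    counts = np.empty(n, dtype=np.int64)
    for i in range(n):
        nb = indices[indptr[i] : indptr[i + 1]]
        if nb.size == 0:
            counts[i] = sphere.shape[0]
            continue
        pts = coords[i] + radii[i] * sphere
        d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
        counts[i] = int((~(d2 < (radii[nb] ** 2)[None, :]).any(axis=1)).sum())
    return counts


try:  # pragma: no cover - exercised implicitly wherever numba is present
    from numba import njit

    @njit(cache=False)
    def _exposed_counts_numba(coords, radii, sphere, indptr, indices):
        n = coords.shape[0]
        npts = sphere.shape[0]
        counts = np.empty(n, dtype=np.int64)
        for i in range(n):
            exposed = 0
            for p in range(npts):
                px = coords[i, 0] + radii[i] * sphere[p, 0]
                py = coords[i, 1] + radii[i] * sphere[p, 1]
                pz = coords[i, 2] + radii[i] * sphere[p, 2]
                free = True
                for jj in range(indptr[i], indptr[i + 1]):
                    j = indices[jj]
                    dx = px - coords[j, 0]
                    dy = py - coords[j, 1]
                    dz = pz - coords[j, 2]
                    if dx * dx + dy * dy + dz * dz < radii[j] * radii[j]:
                        free = False
                        break
                if free:
                    exposed += 1
            counts[i] = exposed
        return counts

    _exposed_counts = _exposed_counts_numba
except ImportError:  # pragma: no cover
    _exposed_counts = _exposed_counts_numpy


@dataclass(frozen=True)
class SasaResult:
    """Per-atom and total accessible area in nm^2."""

    per_atom: np.ndarray
    probe_radius: float
    n_points: int

    @property
    def total(self) -> float:
        return float(self.per_atom.sum())


def _radii_for(elements, radii_table: dict[str, float]) -> np.ndarray:
    missing = sorted({e for e in elements if e not in radii_table})
    if missing:
        raise KeyError(f"no van der Waals radius for element(s): {missing}")
    return np.array([radii_table[e] for e in elements])


def sasa(
    coords: np.ndarray,
    elements,
    probe: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_N_POINTS,
    radii_table: dict[str, float] | None = None,
) -> SasaResult:
    """Shrake-Rupley accessible surface area of an atom group.

    Parameters
    ----------
    coords
        (n, 3) positions in nm.
    elements
        Element symbol per atom (radius lookup).
    probe
        Solvent probe radius in nm (water: 0.14).
    n_points
        Quadrature points per atom sphere (>= 60).
    """
    if n_points < 60:
        raise ValueError("n_points must be at least 60")
    if radii_table is None:
        radii_table = DEFAULT_RADII
    coords = np.ascontiguousarray(coords, dtype=float)
    n = coords.shape[0]
    radii = _radii_for(elements, radii_table) + probe
    sphere = _sphere(n_points)

    max_r = radii.max()
    tree = cKDTree(coords)
    pairs = tree.query_ball_point(coords, r=2.0 * max_r)
    # flatten neighbor lists (closest first, for early occlusion exits)
    indptr = np.zeros(n + 1, dtype=np.int64)
    chunks = []
    for i in range(n):
        nb = np.array([j for j in pairs[i] if j != i], dtype=np.int64)
        if nb.size:
            d = ((coords[nb] - coords[i]) ** 2).sum(axis=1)
            nb = nb[np.argsort(d, kind="stable")]
        chunks.append(nb)
        indptr[i + 1] = indptr[i] + nb.size
    indices = (
        np.concatenate(chunks) if chunks else np.empty(0, dtype=np.int64)
    ).astype(np.int64)

    counts = _exposed_counts(coords, radii, sphere, indptr, indices)
    areas = counts / n_points * 4.0 * np.pi * radii**2
    return SasaResult(per_atom=areas, probe_radius=probe, n_points=n_points)


def _group_indices(mask) -> np.ndarray:
    idx = mask.as_array() if isinstance(mask, SelectionMask) else np.asarray(mask, int)
    return idx


def buried_area(
    coords: np.ndarray,
    elements,
    mask_a,
    mask_b,
    probe: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_N_POINTS,
    radii_table: dict[str, float] | None = None,
) -> float:
    """Interface area buried between two disjoint atom groups, nm^2.

    Computed as half the accessible area lost on association; quadrature
    noise can push the value marginally negative, in which case it is clamped
    to zero with a warning.
    """
    ia = _group_indices(mask_a)
    ib = _group_indices(mask_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("buried_area requires two non-empty groups")
    if np.intersect1d(ia, ib).size:
        raise ValueError("atom groups overlap")
    coords = np.asarray(coords, dtype=float)
    elements = np.asarray(elements)
    args = dict(probe=probe, n_points=n_points, radii_table=radii_table)
    sa = sasa(coords[ia], elements[ia], **args).total
    sb = sasa(coords[ib], elements[ib], **args).total
    iab = np.concatenate([ia, ib])
    sab = sasa(coords[iab], elements[iab], **args).total
    value = 0.5 * (sa + sb - sab)
    if value < 0:
        if value < -1e-6:
            warnings.warn(
                f"buried area {value:.2e} nm^2 below zero (quadrature noise); clamped"
            )
        value = 0.0
    return value


def contact_pair_count(coords: np.ndarray, mask_a, mask_b, cutoff: float = 0.35) -> int:
    """Number of cross-group atom pairs within ``cutoff`` nm (strict <)."""
    ia = _group_indices(mask_a)
    ib = _group_indices(mask_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("contact_pair_count requires two non-empty groups")
    c = np.asarray(coords, dtype=float)
    return int((cdist(c[ia], c[ib]) < cutoff).sum())


@dataclass(frozen=True)
class InteractionAreaSeries:
    """Per-frame adjacent-chain interaction areas over an analysis window.

    ``per_pair`` has shape (n_frames, n_pairs) where pair k is the k-th
    consecutive chain pair in stacking order; ``totals`` is the per-frame sum.
    ``pair_contacts`` carries the companion cutoff-based metric (cross-chain
    heavy-atom pairs within the contact cutoff).
    """

    frame_indices: np.ndarray
    pairs: list[tuple[str, str]]
    per_pair: np.ndarray
    pair_contacts: np.ndarray
    contact_cutoff: float

    @property
    def totals(self) -> np.ndarray:
        return self.per_pair.sum(axis=1)

    @property
    def mean(self) -> float:
        return float(self.totals.mean())

    @property
    def sd(self) -> float:
        return float(self.totals.std())

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for k, f in enumerate(self.frame_indices):
            for p, (ci, cj) in enumerate(self.pairs):
                rows.append(
                    {
                        "frame": int(f),
                        "chain_i": ci,
                        "chain_j": cj,
                        "buried_area_nm2": self.per_pair[k, p],
                        "contact_pair_count": int(self.pair_contacts[k, p]),
                    }
                )
        return pd.DataFrame(rows)


def interchain_area_series(
    trajectory: Trajectory,
    chain_order: list[str] | None = None,
    window: np.ndarray | None = None,
    probe: float = DEFAULT_PROBE_NM,
    n_points: int = DEFAULT_N_POINTS,
    contact_cutoff: float = 0.35,
    radii_table: dict[str, float] | None = None,
) -> InteractionAreaSeries:
    """Buried area between consecutive chains of the stack, per frame.

    Heavy-atom cross-pair counts within ``contact_cutoff`` are recorded for
    the same pairs as a secondary contact metric.
    """
    top = trajectory.topology
    if chain_order is None:
        chain_order = [
            c
            for c in top.chain_order
            if any(not a.is_hetero for a in top.atoms if a.chain_id == c)
        ]
    if len(chain_order) < 2:
        raise ValueError("interaction area needs at least 2 chains")
    if window is None:
        window = np.arange(trajectory.n_frames)
    window = np.asarray(window, dtype=int)

    chain_masks = {
        c: select(top, chains=[c], hetero=False).as_array() for c in chain_order
    }
    heavy = {
        c: select(top, chains=[c], hetero=False, heavy_only=True).as_array()
        for c in chain_order
    }
    elements = np.array([a.element for a in top.atoms])
    pairs = [(chain_order[k], chain_order[k + 1]) for k in range(len(chain_order) - 1)]

    per_pair = np.zeros((window.size, len(pairs)))
    contacts = np.zeros((window.size, len(pairs)), dtype=int)
    args = dict(probe=probe, n_points=n_points, radii_table=radii_table)
    for k, f in enumerate(window):
        coords = trajectory.frames[f]
        solo = {
            c: sasa(coords[chain_masks[c]], elements[chain_masks[c]], **args).total
            for c in chain_order
        }
        for p, (ci, cj) in enumerate(pairs):
            union = np.concatenate([chain_masks[ci], chain_masks[cj]])
            s_ab = sasa(coords[union], elements[union], **args).total
            value = 0.5 * (solo[ci] + solo[cj] - s_ab)
            per_pair[k, p] = max(value, 0.0)
            contacts[k, p] = (
                cdist(coords[heavy[ci]], coords[heavy[cj]]) < contact_cutoff
            ).sum()
    return InteractionAreaSeries(
        frame_indices=window,
        pairs=pairs,
        per_pair=per_pair,
        pair_contacts=contacts,
        contact_cutoff=contact_cutoff,
    )
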