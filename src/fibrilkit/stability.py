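"""Fibril stability metrics: order parameter, ligand contacts, summary report.

The order parameter quantifies how well each chain keeps its internal
orientation relative to the starting structure.  For chain c and residue n,

    v(c, n; t) = unit(Ca_t(c, n) - CoM_t(c))

is the connecting vector from the chain's alpha-carbon centroid to the
residue's alpha carbon.  The per-frame order parameter is the mean over all
(c, n) of the dot product ``v(c, n; 0) . v(c, n; t)``: exactly 1 when every
chain retains its reference orientation, and decaying toward 0 as the fibril
loses structural order.  Frames are least-squares fitted onto the reference
on the alpha carbons by default, so rigid tumbling of the whole fibril does
not register as disorder.

Ligand binding is summarized as a per-residue contact probability: the
fraction of (bound) frames in which any chain's copy of a residue has a heavy
atom within the contact cutoff of the ligand.  Chains are not distinguished
— the fibril is a stack of identical chains, so only the residue identity is
informative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import kabsch_superpose, min_distance
from .secondary import beta_content
from .structure import SelectionMask, Structure, Trajectory, select
from .surface import InteractionAreaSeries, interchain_area_series

__all__ = [
    "OrderParameterResult",
    "ContactProbabilityMap",
    "StabilityReport",
    "order_parameter",
    "bound_frames",
    "residue_contact_probability",
    "summarize_complex",
]

DEFAULT_CONTACT_CUTOFF_NM = 0.35
DEFAULT_WINDOW_NS = 25.0


@dataclass(frozen=True)
class OrderParameterResult:
    """Per-frame order parameter and its window average."""

    per_frame: np.ndarray
    frame_indices: np.ndarray
    mean: float
    n_chains: int
    n_residues_per_chain: int
    reference_frame: int
    fitted: bool

    def __post_init__(self) -> None:
        if np.any(self.per_frame > 1 + 1e-9) or np.any(self.per_frame < -1 - 1e-9):
            raise ValueError("order parameter out of [-1, 1]")


@dataclass(frozen=True)
class ContactProbabilityMap:
    """Chain-agnostic residue -> contact probability mapping.

    Keys are (residue_id, residue_name); probabilities are fractions of the
    considered frames.  ``frames_considered`` reflects any bound-frame
    masking that was applied.
    """

    probabilities: dict[tuple[int, str], float]
    cutoff: float
    frames_considered: int

    def __post_init__(self) -> None:
        for key, p in self.probabilities.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of range for {key}: {p}")

    def top(self, k: int = 5) -> list[tuple[tuple[int, str], float]]:
        return sorted(self.probabilities.items(), key=lambda kv: -kv[1])[:k]

    def to_dataframe(self):
        import pandas as pd

        rows = [
            {"residue_id": rid, "residue_name": name, "probability": p}
            for (rid, name), p in sorted(self.probabilities.items())
        ]
        return pd.DataFrame(rows, columns=["residue_id", "residue_name", "probability"])


@dataclass(frozen=True)
class StabilityReport:
    """The per-complex stability triple plus the ligand contact map."""

    beta_mean: float
    beta_sd: float
    beta_per_frame: np.ndarray
    ordp: OrderParameterResult
    area: InteractionAreaSeries
    contacts: ContactProbabilityMap
    window_ns: float
    frame_indices: np.ndarray

    @property
    def beta_percent(self) -> float:
        return 100.0 * self.beta_mean

    def summary_row(self) -> dict:
        return {
            "beta_percent_mean": 100.0 * self.beta_mean,
            "beta_percent_sd": 100.0 * self.beta_sd,
            "ordp_mean": self.ordp.mean,
            "interchain_area_mean_nm2": self.area.mean,
            "interchain_area_sd_nm2": self.area.sd,
            "window_ns": self.window_ns,
            "frames_analyzed": int(len(self.frame_indices)),
            "bound_frames": self.contacts.frames_considered,
        }


def _chain_ca_layout(structure: Structure, ca_mask: SelectionMask | None):
    """Group alpha-carbon atom indices by polymer chain, checking uniformity."""
    if ca_mask is None:
        ca_mask = select(structure, names=["CA"], hetero=False)
    idx = ca_mask.as_array()
    if idx.size == 0:
        raise ValueError("no alpha carbons selected")
    by_chain: dict[str, list[int]] = {}
    for i in idx:
        a = structure.atoms[i]
        by_chain.setdefault(a.chain_id, []).append(i)
    counts = {c: len(v) for c, v in by_chain.items()}
    if len(set(counts.values())) != 1:
        raise ValueError(f"chains contribute unequal residue counts: {counts}")
    n_res = next(iter(counts.values()))
    if n_res < 2:
        raise ValueError("each chain needs at least 2 residues")
    chains = [c for c in structure.chain_order if c in by_chain]
    layout = np.array([by_chain[c] for c in chains], dtype=int)  # (n_chains, n_res)
    return layout, idx


def _unit_fan(coords: np.ndarray, layout: np.ndarray, com_mode: str, structure):
    """Unit connecting vectors (n_chains, n_res, 3) for one frame."""
    ca = coords[layout]  # (n_chains, n_res, 3)
    if com_mode == "chain":
        com = ca.mean(axis=1, keepdims=True)
        v = ca - com
    elif com_mode == "residue":
        # vector from the residue's own atom centroid to its alpha carbon
        v = np.empty_like(ca)
        for c in range(layout.shape[0]):
            for n in range(layout.shape[1]):
                a = structure.atoms[layout[c, n]]
                res_idx = [
                    i
                    for i, b in enumerate(structure.atoms)
                    if b.chain_id == a.chain_id and b.residue_id == a.residue_id
                ]
                v[c, n] = ca[c, n] - coords[res_idx].mean(axis=0)
    else:
        raise ValueError(f"unknown com_mode {com_mode!r}")
    norms = np.linalg.norm(v, axis=2, keepdims=True)
    if np.any(norms < 1e-12):
        raise ValueError("zero-length connecting vector")
    return v / norms


def order_parameter(
    trajectory: Trajectory,
    ca_mask: SelectionMask | None = None,
    reference_frame: int = 0,
    fit: bool = True,
    window: np.ndarray | None = None,
    com_mode: str = "chain",
) -> OrderParameterResult:
    """Orientation order parameter of the fibril relative to a reference frame.

    Parameters
    ----------
    trajectory
        Frames to score.
    ca_mask
        Alpha-carbon selection; defaults to all polymer CA atoms.  Every
        chain must contribute the same number of residues.
    reference_frame
        Frame index defining the reference vectors (default: first frame).
    fit
        Least-squares fit each frame's alpha carbons onto the reference
        before computing vectors, removing global rigid-body motion.
    window
        Frame indices to score and average over (default: all frames).
    com_mode
        "chain": vectors run from the chain's alpha-carbon centroid to each
        residue's alpha carbon (default).  "residue": vectors run from each
        residue's own atom centroid to its alpha carbon.
    """
    top = trajectory.topology
    layout, fit_idx = _chain_ca_layout(top, ca_mask)
    if not (0 <= reference_frame < trajectory.n_frames):
        raise IndexError(f"reference frame {reference_frame} out of range")
    if window is None:
        window = np.arange(trajectory.n_frames)
    window = np.asarray(window, dtype=int)
    if window.size == 0:
        raise ValueError("empty analysis window")

    ref_coords = trajectory.frames[reference_frame]
    v0 = _unit_fan(ref_coords, layout, com_mode, top)

    per_frame = np.empty(window.size)
    for k, f in enumerate(window):
        coords = trajectory.frames[f]
        if fit:
            transform, _ = kabsch_superpose(coords[fit_idx], ref_coords[fit_idx])
            coords = transform.apply(coords)
        vt = _unit_fan(coords, layout, com_mode, top)
        per_frame[k] = float((v0 * vt).sum(axis=2).mean())
    return OrderParameterResult(
        per_frame=per_frame,
        frame_indices=window,
        mean=float(per_frame.mean()),
        n_chains=layout.shape[0],
        n_residues_per_chain=layout.shape[1],
        reference_frame=reference_frame,
        fitted=fit,
    )


def bound_frames(
    trajectory: Trajectory,
    ligand_mask: SelectionMask,
    receptor_mask: SelectionMask,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    window: np.ndarray | None = None,
) -> np.ndarray:
    """Frame indices where the ligand touches the receptor (strict < cutoff)."""
    if len(ligand_mask) == 0:
        raise ValueError("ligand mask is empty")
    if len(receptor_mask) == 0:
        raise ValueError("receptor mask is empty")
    if window is None:
        window = np.arange(trajectory.n_frames)
    window = np.asarray(window, dtype=int)
    keep = [
        f
        for f in window
        if min_distance(trajectory.frames[f], ligand_mask, receptor_mask) < cutoff
    ]
    return np.asarray(keep, dtype=int)


def residue_contact_probability(
    trajectory: Trajectory,
    ligand_mask: SelectionMask,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    frame_mask: np.ndarray | None = None,
    heavy_only: bool = True,
) -> ContactProbabilityMap:
    """Contact probability per residue identity, aggregated over chains.

    A residue identity (residue_id, residue_name) is in contact in a frame
    iff any chain's copy has an atom within ``cutoff`` nm of any ligand atom
    (heavy atoms only by default).  Probability = contact frames divided by
    the considered frames (``frame_mask`` if given, else all frames).
    """
    if len(ligand_mask) == 0:
        raise ValueError("ligand mask is empty")
    if frame_mask is None:
        frame_mask = np.arange(trajectory.n_frames)
    frame_mask = np.asarray(frame_mask, dtype=int)
    if frame_mask.size == 0:
        raise ValueError("no bound frames to consider")

    top = trajectory.topology
    lig = ligand_mask.as_array()
    if heavy_only:
        lig = np.array([i for i in lig if top.atoms[i].element != "H"], dtype=int)
        if lig.size == 0:
            raise ValueError("ligand has no heavy atoms")

    # group receptor atom indices by chain-agnostic residue identity
    groups: dict[tuple[int, str], list[int]] = {}
    lig_set = set(int(i) for i in lig)
    for i, a in enumerate(top.atoms):
        if a.is_hetero or i in lig_set:
            continue
        if heavy_only and a.element == "H":
            continue
        groups.setdefault((a.residue_id, a.residue_name), []).append(i)

    counts = {key: 0 for key in groups}
    for f in frame_mask:
        coords = trajectory.frames[f]
        lig_coords = coords[lig]
        for key, atom_idx in groups.items():
            if cdist(coords[atom_idx], lig_coords).min() < cutoff:
                counts[key] += 1
    probs = {key: counts[key] / frame_mask.size for key in groups}
    return ContactProbabilityMap(
        probabilities=probs, cutoff=cutoff, frames_considered=int(frame_mask.size)
    )


def summarize_complex(
    trajectory: Trajectory,
    ligand_mask: SelectionMask | None = None,
    window_ns: float = DEFAULT_WINDOW_NS,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    ordp_fit: bool = True,
    ordp_com_mode: str = "chain",
    count_bridge: bool = True,
    sasa_probe: float = 0.14,
    sasa_points: int = 960,
    chain_order: list[str] | None = None,
) -> StabilityReport:
    """Compute the stability triple and contact map on one analysis window.

    The window is the trailing ``window_ns`` nanoseconds of the trajectory,
    resolved to ``round(window_ns / time_per_frame)`` frames; beta content,
    order parameter and inter-chain area all use exactly this frame set.  A
    ligand-free input yields a wild-type report with an empty contact map.
    Contact probabilities are computed over the window frames in which the
    ligand is bound (within the cutoff of the receptor).
    """
    n_window = int(round(window_ns / trajectory.time_per_frame))
    if n_window > trajectory.n_frames:
        raise ValueError(
            f"window of {n_window} frames longer than trajectory "
            f"({trajectory.n_frames} frames)"
        )
    window = trajectory.window_frames(window_ns)
    top = trajectory.topology

    fractions, beta_mean, beta_sd, _ = beta_content(
        trajectory, window=window, count_bridge=count_bridge
    )
    ordp = order_parameter(
        trajectory, fit=ordp_fit, window=window, com_mode=ordp_com_mode
    )
    area = interchain_area_series(
        trajectory,
        chain_order=chain_order,
        window=window,
        probe=sasa_probe,
        n_points=sasa_points,
        contact_cutoff=contact_cutoff,
    )

    if ligand_mask is not None and len(ligand_mask) > 0:
        receptor = select(top, hetero=False, heavy_only=True)
        bound = bound_frames(
            trajectory, ligand_mask, receptor, cutoff=contact_cutoff, window=window
        )
        if bound.size:
            contacts = residue_contact_probability(
                trajectory, ligand_mask, cutoff=contact_cutoff, frame_mask=bound
            )
        else:
            contacts = ContactProbabilityMap({}, contact_cutoff, 0)
    else:
        contacts = ContactProbabilityMap({}, contact_cutoff, 0)

    return StabilityReport(
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        beta_per_frame=fractions,
        ordp=ordp,
        area=area,
        contacts=contacts,
        window_ns=window_ns,
        frame_indices=window,
    )
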