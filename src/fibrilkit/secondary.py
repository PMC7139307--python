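"""Hydrogen-bond-based beta-strand assignment (Kabsch-Sander subset).

Implements the DSSP electrostatic hydrogen-bond model and the bridge/ladder
rules needed to assign extended-strand (E) and isolated-bridge (B) codes;
every other state is lumped into C, because the metric of interest is the
beta-sheet structure probability of a fibril, not a full secondary-structure
string.

Conventions follow the original method:

* amide hydrogens are placed at ``N + 0.10 nm * unit(C_prev - O_prev)``
  (chain-first residues and prolines have none);
* the bond energy, with distances in angstroms, is
  ``E = 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN)`` kcal/mol,
  clamped to -9.9 when any of the four distances drops below 0.5 A;
* ``Hbond(a, d)`` means the carbonyl of residue *a* accepts from the amide of
  residue *d*, and exists iff E < -0.5 kcal/mol;
* a donor keeps at most its two best-energy acceptors (no bifurcation beyond
  two);
* parallel bridge (i, j): [Hbond(i-1, j) and Hbond(j, i+1)] or
  [Hbond(j-1, i) and Hbond(i, j+1)];
  antiparallel bridge (i, j): [Hbond(i, j) and Hbond(j, i)] or
  [Hbond(i-1, j+1) and Hbond(j-1, i+1)];
* bridges chain into ladders along (i+1, j+1) for parallel and (i+1, j-1)
  for antiparallel steps; ladder members get E, isolated bridges B.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure import Structure, Trajectory

__all__ = [
    "SSAssignment",
    "BackboneTable",
    "place_amide_hydrogens",
    "hbond_energy",
    "assign_beta",
    "beta_content",
    "HBOND_ENERGY_CUTOFF",
]

A_PER_NM = 10.0
#: DSSP coupling constant q1*q2*332 (kcal/mol * A)
KS_CONST = 0.084 * 332.0
#: a hydrogen bond exists below this energy (kcal/mol)
HBOND_ENERGY_CUTOFF = -0.5
#: clash clamp: any of the four distances under 0.5 A
CLAMP_DISTANCE_A = 0.5
CLAMP_ENERGY = -9.9
#: N-H bond length used for hydrogen placement (nm)
NH_BOND_NM = 0.10


@dataclass(frozen=True)
class SSAssignment:
    """Per-frame, per-residue codes in {"E", "B", "C"}.

    ``codes`` has shape (n_frames, n_residues); ``residues`` lists the
    polymer residues as (chain_id, residue_id, residue_name) in topology
    order.
    """

    codes: np.ndarray
    residues: list[tuple[str, int, str]]

    def beta_fraction(self, count_bridge: bool = True) -> np.ndarray:
        """Per-frame fraction of residues in beta structure."""
        beta = self.codes == "E"
        if count_bridge:
            beta |= self.codes == "B"
        return beta.mean(axis=1)

    def to_dataframe(self):
        import pandas as pd

        frames, residues = np.meshgrid(
            np.arange(self.codes.shape[0]),
            np.arange(self.codes.shape[1]),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "frame": frames.ravel(),
                "chain": [self.residues[r][0] for r in residues.ravel()],
                "residue_id": [self.residues[r][1] for r in residues.ravel()],
                "code": self.codes.ravel(),
            }
        )


class BackboneTable:
    """Per-residue backbone atom indices of the polymer part of a topology.

    Missing backbone atoms disqualify a residue from the corresponding
    donor/acceptor role but never raise: such residues simply stay C.
    """

    def __init__(self, structure: Structure) -> None:
        residues = [
            r
            for r in structure.residues()
            if any(
                not a.is_hetero
                for a in structure.atoms
                if (a.chain_id, a.residue_id) == (r[0], r[1])
            )
        ]
        index = {(c, rid): k for k, (c, rid, _) in enumerate(residues)}
        n = len(residues)
        self.residues = residues
        self.n_residues = n
        self.idx_n = np.full(n, -1, dtype=int)
        self.idx_ca = np.full(n, -1, dtype=int)
        self.idx_c = np.full(n, -1, dtype=int)
        self.idx_o = np.full(n, -1, dtype=int)
        for i, a in enumerate(structure.atoms):
            if a.is_hetero:
                continue
            k = index.get((a.chain_id, a.residue_id))
            if k is None:
                continue
            if a.name == "N":
                self.idx_n[k] = i
            elif a.name == "CA":
                self.idx_ca[k] = i
            elif a.name == "C":
                self.idx_c[k] = i
            elif a.name == "O":
                self.idx_o[k] = i
        chain_ids = [r[0] for r in residues]
        self.chain_index = np.array(
            [structure.chain_order.index(c) for c in chain_ids], dtype=int
        )
        self.is_proline = np.array(
            [r[2].upper() == "PRO" for r in residues], dtype=bool
        )
        self.has_prev = np.zeros(n, dtype=bool)
        self.has_prev[1:] = self.chain_index[1:] == self.chain_index[:-1]
        self.has_next = np.zeros(n, dtype=bool)
        self.has_next[:-1] = self.chain_index[1:] == self.chain_index[:-1]

    def hydrogen_positions(self, coords: np.ndarray) -> np.ndarray:
        """(n_residues, 3) amide-H positions in nm; NaN where no H exists."""
        H = np.full((self.n_residues, 3), np.nan)
        ok = (
            self.has_prev
            & ~self.is_proline
            & (self.idx_n >= 0)
        )
        prev = np.arange(self.n_residues) - 1
        ok &= np.where(ok, self.idx_c[np.clip(prev, 0, None)] >= 0, False)
        ok &= np.where(ok, self.idx_o[np.clip(prev, 0, None)] >= 0, False)
        idx = np.flatnonzero(ok)
        if idx.size == 0:
            return H
        c_prev = coords[self.idx_c[idx - 1]]
        o_prev = coords[self.idx_o[idx - 1]]
        n_pos = coords[self.idx_n[idx]]
        d = c_prev - o_prev
        norm = np.linalg.norm(d, axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            H[idx] = n_pos + NH_BOND_NM * d / norm
        return H


def place_amide_hydrogens(structure: Structure) -> dict[tuple[str, int], np.ndarray]:
    """Amide hydrogen positions keyed by (chain_id, residue_id), in nm.

    Residues with no amide hydrogen (chain-first residues, prolines, or
    residues missing the needed backbone atoms) are absent from the mapping.
    """
    table = BackboneTable(structure)
    H = table.hydrogen_positions(structure.coords)
    out: dict[tuple[str, int], np.ndarray] = {}
    for k, (chain, rid, _name) in enumerate(table.residues):
        if np.all(np.isfinite(H[k])):
            out[(chain, rid)] = H[k]
    return out


def hbond_energy(donor_atoms: dict, acceptor_atoms: dict) -> float:
    """Kabsch-Sander electrostatic H-bond energy in kcal/mol.

    ``donor_atoms`` must provide ``"N"`` and ``"H"`` positions, and
    ``acceptor_atoms`` must provide ``"C"`` and ``"O"``, all in nm.  A bond
    exists iff the returned energy is below -0.5 kcal/mol.
    """
    try:
        n = np.asarray(donor_atoms["N"], dtype=float)
        h = np.asarray(donor_atoms["H"], dtype=float)
        c = np.asarray(acceptor_atoms["C"], dtype=float)
        o = np.asarray(acceptor_atoms["O"], dtype=float)
    except KeyError as exc:
        raise KeyError(f"missing backbone atom {exc} for H-bond energy") from exc
    r_on = np.linalg.norm(o - n) * A_PER_NM
    r_ch = np.linalg.norm(c - h) * A_PER_NM
    r_oh = np.linalg.norm(o - h) * A_PER_NM
    r_cn = np.linalg.norm(c - n) * A_PER_NM
    if min(r_on, r_ch, r_oh, r_cn) < CLAMP_DISTANCE_A:
        return CLAMP_ENERGY
    return float(KS_CONST * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn))


def _hbond_matrix(table: BackboneTable, coords: np.ndarray) -> np.ndarray:
    """Boolean matrix HB[a, d]: carbonyl of residue a accepts from amide of d."""
    n = table.n_residues
    H = table.hydrogen_positions(coords)
    donor_ok = np.all(np.isfinite(H), axis=1) & (table.idx_n >= 0)
    acceptor_ok = (table.idx_c >= 0) & (table.idx_o >= 0)
    if not donor_ok.any() or not acceptor_ok.any():
        return np.zeros((n, n), dtype=bool)

    di = np.flatnonzero(donor_ok)
    ai = np.flatnonzero(acceptor_ok)
    N = coords[table.idx_n[di]]
    Hd = H[di]
    C = coords[table.idx_c[ai]]
    O = coords[table.idx_o[ai]]

    def dist(X, Y):  # (a, d) pairwise distances in A
        return (
            np.sqrt(((X[:, None, :] - Y[None, :, :]) ** 2).sum(axis=2)) * A_PER_NM
        )

    r_on = dist(O, N)
    r_ch = dist(C, Hd)
    r_oh = dist(O, Hd)
    r_cn = dist(C, N)
    with np.errstate(divide="ignore"):
        E = KS_CONST * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)
    clash = np.minimum(np.minimum(r_on, r_ch), np.minimum(r_oh, r_cn)) < CLAMP_DISTANCE_A
    E = np.where(clash, CLAMP_ENERGY, E)

    # expand back to full residue indexing
    Efull = np.zeros((n, n))
    Efull[np.ix_(ai, di)] = E
    # exclude self and sequence-adjacent pairs within one chain
    res = np.arange(n)
    same_chain = table.chain_index[:, None] == table.chain_index[None, :]
    near = np.abs(res[:, None] - res[None, :]) < 2
    Efull[same_chain & near] = 0.0

    # no-bifurcation: each donor keeps its two best-energy acceptors
    bonded = Efull < HBOND_ENERGY_CUTOFF
    for d in np.flatnonzero(bonded.any(axis=0)):
        acceptors = np.flatnonzero(bonded[:, d])
        if acceptors.size > 2:
            keep = acceptors[np.argsort(Efull[acceptors, d])[:2]]
            drop = np.setdiff1d(acceptors, keep)
            bonded[drop, d] = False
    return bonded


def _shift_rows(M: np.ndarray, offset: int, valid: np.ndarray) -> np.ndarray:
    """S[i, :] = M[i + offset, :] where valid[i]; False elsewhere."""
    S = np.zeros_like(M)
    n = M.shape[0]
    if offset == -1:
        S[1:, :] = M[:-1, :]
    elif offset == 1:
        S[:-1, :] = M[1:, :]
    else:  # pragma: no cover
        raise ValueError(offset)
    S[~valid, :] = False
    return S


def _bridge_matrices(table: BackboneTable, HB: np.ndarray):
    """Boolean parallel / antiparallel bridge matrices over residue pairs."""
    n = table.n_residues
    res = np.arange(n)
    prev_ok = table.has_prev
    next_ok = table.has_next

    # helper matrices indexed [i, j]
    HB_ad = HB  # Hbond(i, j) == HB[i, j] (acceptor i, donor j)
    HB_da = HB.T  # Hbond with roles [donor i, acceptor j] -> HB[j, i]

    # Hbond(i-1, j): acceptor i-1, donor j
    hb_im1_j = _shift_rows(HB_ad, -1, prev_ok)
    # Hbond(j, i+1): acceptor j, donor i+1 -> as [i, j]: HB[j, i+1] = HB_da.T ...
    hb_j_ip1 = _shift_rows(HB_da, 1, next_ok)  # [i, j] = HB[j, i+1]
    # Hbond(j-1, i): acceptor j-1, donor i -> [i, j] = HB[j-1, i]
    hb_jm1_i = _shift_rows(HB_ad, -1, prev_ok).T
    # Hbond(i, j+1): acceptor i, donor j+1 -> [i, j] = HB[i, j+1]
    hb_i_jp1 = _shift_rows(HB_ad.T, 1, next_ok).T

    parallel = (hb_im1_j & hb_j_ip1) | (hb_jm1_i & hb_i_jp1)

    # antiparallel: [Hbond(i, j) and Hbond(j, i)] or
    #               [Hbond(i-1, j+1) and Hbond(j-1, i+1)]
    mutual = HB_ad & HB_ad.T
    hb_im1_jp1 = _shift_rows(_shift_rows(HB_ad, -1, prev_ok).T, 1, next_ok).T
    hb_jm1_ip1 = hb_im1_jp1.T
    antiparallel = mutual | (hb_im1_jp1 & hb_jm1_ip1)

    # a bridge needs non-overlapping stretches: different chains, or a
    # same-chain separation of at least 3 residues
    same_chain = table.chain_index[:, None] == table.chain_index[None, :]
    allowed = (~same_chain) | (np.abs(res[:, None] - res[None, :]) >= 3)
    parallel &= allowed
    antiparallel &= allowed
    np.fill_diagonal(parallel, False)
    np.fill_diagonal(antiparallel, False)
    return parallel, antiparallel


def _codes_from_bridges(table, parallel: np.ndarray, antiparallel: np.ndarray):
    n = parallel.shape[0]
    prev_ok = table.has_prev
    next_ok = table.has_next

    def neighbor(M: np.ndarray, di: int, dj: int) -> np.ndarray:
        """N[i, j] = M[i+di, j+dj] with chain-break masking."""
        rows = _shift_rows(M, di, next_ok if di == 1 else prev_ok)
        return _shift_rows(rows.T, dj, next_ok if dj == 1 else prev_ok).T

    in_par_ladder = parallel & (neighbor(parallel, 1, 1) | neighbor(parallel, -1, -1))
    in_anti_ladder = antiparallel & (
        neighbor(antiparallel, 1, -1) | neighbor(antiparallel, -1, 1)
    )
    in_ladder = in_par_ladder | in_anti_ladder
    any_bridge = parallel | antiparallel

    codes = np.full(n, "C", dtype="U1")
    bridge_res = any_bridge.any(axis=1) | any_bridge.any(axis=0)
    ladder_res = in_ladder.any(axis=1) | in_ladder.any(axis=0)
    codes[bridge_res] = "B"
    codes[ladder_res] = "E"
    return codes


def assign_beta(
    frame_coords: np.ndarray,
    structure: Structure,
    table: BackboneTable | None = None,
) -> np.ndarray:
    """Assign E/B/C codes to every polymer residue for one frame.

    ``frame_coords`` is the (n_atoms, 3) coordinate set of the frame in nm.
    Returns an array of one-character codes aligned with
    ``BackboneTable(structure).residues``.
    """
    if table is None:
        table = BackboneTable(structure)
    HB = _hbond_matrix(table, np.asarray(frame_coords, dtype=float))
    parallel, antiparallel = _bridge_matrices(table, HB)
    return _codes_from_bridges(table, parallel, antiparallel)


def beta_content(
    trajectory: Trajectory,
    window: np.ndarray | None = None,
    count_bridge: bool = True,
) -> tuple[np.ndarray, float, float, SSAssignment]:
    """Beta-structure fraction per frame plus the window mean and sd.

    Parameters
    ----------
    trajectory
        Frames to assign.
    window
        Frame indices to analyze (default: all frames).  Must be non-empty.
    count_bridge
        Count isolated-bridge (B) residues as beta in addition to E.

    Returns
    -------
    fractions, mean, sd, assignment
        ``fractions`` aligns with ``window``; ``sd`` is the population
        standard deviation over the window.
    """
    if window is None:
        window = np.arange(trajectory.n_frames)
    window = np.asarray(window, dtype=int)
    if window.size == 0:
        raise ValueError("empty analysis window")
    table = BackboneTable(trajectory.topology)
    codes = np.empty((window.size, table.n_residues), dtype="U1")
    for k, f in enumerate(window):
        codes[k] = assign_beta(trajectory.frames[f], trajectory.topology, table)
    assignment = SSAssignment(codes, table.residues)
    fractions = assignment.beta_fraction(count_bridge=count_bridge)
    return fractions, float(fractions.mean()), float(fractions.std()), assignment
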