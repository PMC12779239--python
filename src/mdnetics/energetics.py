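"""Interaction energetics: contact-gated residue-pairwise short-range
Coulomb/Lennard-Jones energies, group interaction energies, Shrake-Rupley
SASA with the gamma*SAS + b apolar solvation term, finite-difference PB
polar solvation, and MM/PBSA-style summaries with replica statistics.

Binding energies follow the end-state convention
``dE = E(complex) - (E(receptor) + E(ligand))`` term by term, under the
single-trajectory convention (component frames are the complex frames
restricted to each group, so bonded terms cancel). The internal energy
evaluated with the short-range cutoff only is reported as E_SR; the
full-range Coulomb/LJ term is a cutoff-free direct pair summation (within
the minimum image when a box is present), the desk-scale semantic
stand-in for Ewald reciprocal-space plus dispersion corrections.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import F_COULOMB
from .core import Selection, Topology, TrajectoryEnsemble
from .pb import PBSettings, polar_energy_fdpb

__all__ = [
    "NonbondedParams", "ApolarParams", "EnergySummary", "PairEnergyTable",
    "anyframe_contact_pairs", "pair_energy_series", "group_interaction_energy",
    "sasa_shrake_rupley", "apolar_energy", "mmpbsa_summary", "pb_radii",
]


@dataclass
class NonbondedParams:
    """Short-range nonbonded settings: Coulomb factor, cutoff (nm),
    Lorentz-Berthelot combination."""

    coulomb_factor: float = F_COULOMB
    cutoff: float = 1.2

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")


@dataclass
class ApolarParams:
    """Apolar solvation term E = gamma * SAS + b.

    gamma = 0.00542 * 4.184 * 100 kJ/(mol nm^2), b = 0.92 * 4.184 kJ/mol,
    probe radius 0.14 nm.
    """

    gamma: float = 0.00542 * 4.184 * 100.0   # 2.267728 kJ/(mol nm^2)
    b: float = 0.92 * 4.184                  # 3.84928 kJ/mol
    probe_radius: float = 0.14
    n_points: int = 960

    def __post_init__(self):
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


@dataclass
class PairEnergyTable:
    """Residue-pairwise short-range energies averaged over analysis frames
    then replicas; only contact-gated pairs are present."""

    table: pd.DataFrame                      # residue_a, residue_b, labels, coulomb, lj, total
    per_replica: list                        # replica -> DataFrame with same layout
    cutoff: float = None
    gate_cutoff: float = None


@dataclass
class EnergySummary:
    """MM/PBSA term table: per-replica means, replica-mean, and standard
    deviation of the mean for each energy component (kJ/mol)."""

    terms: pd.DataFrame                      # index: term; columns: mean, sem, n_snapshots
    per_replica: pd.DataFrame                # index: term; columns: replica means
    groups: tuple = None

    def delta(self, term: str) -> float:
        return float(self.terms.loc[term, "mean"])


def _check_parameters(topology: Topology):
    if not topology.parameters_assigned:
        raise ValueError(
            "topology has no nonbonded parameters assigned; load a parameter table first")


def _check_disjoint(group_a, group_b):
    a, b = np.asarray(group_a.indices), np.asarray(group_b.indices)
    if np.intersect1d(a, b).size:
        raise ValueError("groups overlap; energy components require disjoint groups")


# ---------------------------------------------------------------------------
# Contact gating
# ---------------------------------------------------------------------------

def anyframe_contact_pairs(traj: TrajectoryEnsemble, group_a: Selection,
                           group_b: Selection, cutoff: float = 0.6):
    """Residue pairs (a in A, b in B) with any interatomic distance <=
    ``cutoff`` (nm, inclusive) in at least one analysis frame of any
    replica. Deterministic ordering by (residue_a, residue_b)."""
    _check_disjoint(group_a, group_b)
    top = traj.topology
    ia, ib = group_a.indices, group_b.indices
    res_a = top.residue_indices[ia]
    res_b = top.residue_indices[ib]
    pairs = set()
    for rep in traj.replicas:
        coords = rep.coords[traj.analysis_mask(rep)]
        for f in range(coords.shape[0]):
            ta = cKDTree(coords[f, ia])
            tb = cKDTree(coords[f, ib])
            hits = ta.query_ball_tree(tb, r=cutoff)
            for ja, neigh in enumerate(hits):
                for jb in neigh:
                    pairs.add((int(res_a[ja]), int(res_b[jb])))
    return sorted(pairs)


# ---------------------------------------------------------------------------
# Pairwise nonbonded energies
# ---------------------------------------------------------------------------

def _min_image(diff: np.ndarray, box) -> np.ndarray:
    if box is not None:
        diff = diff - box * np.round(diff / box)
    return diff


def _atom_pair_energy(coords, idx_i, idx_j, top: Topology, params: NonbondedParams,
                      cutoff, box):
    """Summed Coulomb and LJ energy between two atom index sets for a
    (n_frames, n_atoms, 3) coordinate stack. Returns (coul, lj) arrays of
    length n_frames."""
    qi, qj = top.charges[idx_i], top.charges[idx_j]
    si, sj = top.lj_sigmas[idx_i], top.lj_sigmas[idx_j]
    ei, ej = top.lj_epsilons[idx_i], top.lj_epsilons[idx_j]
    sig = 0.5 * (si[:, None] + sj[None, :])
    eps = np.sqrt(ei[:, None] * ej[None, :])
    qq = qi[:, None] * qj[None, :]
    diff = coords[:, idx_i, None, :] - coords[:, None, idx_j, :]
    diff = _min_image(diff, box)
    r = np.sqrt((diff**2).sum(axis=3))
    with np.errstate(divide="ignore", invalid="ignore"):
        inv_r = 1.0 / r
        coul = params.coulomb_factor * qq[None] * inv_r
        sr6 = (sig[None] * inv_r) ** 6
        lj = 4.0 * eps[None] * (sr6 * sr6 - sr6)
    if np.isfinite(cutoff):
        within = r <= cutoff
        coul = np.where(within, coul, 0.0)
        lj = np.where(within, lj, 0.0)
    return coul.sum(axis=(1, 2)), lj.sum(axis=(1, 2))


def pair_energy_series(traj: TrajectoryEnsemble, pairs, params: NonbondedParams = None,
                       gate_cutoff: float = 0.6) -> PairEnergyTable:
    """Per-pair short-range Coulomb and LJ energies.

    For each gated residue pair, sums ``f q_i q_j / r`` and
    ``4 eps[(sig/r)^12 - (sig/r)^6]`` over atom pairs with r <= cutoff,
    per frame; averages over analysis frames, then reports the
    replica-mean alongside per-replica tables.
    """
    params = params or NonbondedParams()
    top = traj.topology
    _check_parameters(top)
    res_atoms = [np.asarray(r.atom_indices) for r in top.residues]
    per_replica_rows = [[] for _ in traj.replicas]
    for ri, rep in enumerate(traj.replicas):
        coords = rep.coords[traj.analysis_mask(rep)]
        for (a, b) in pairs:
            coul, lj = _atom_pair_energy(coords, res_atoms[a], res_atoms[b], top,
                                         params, params.cutoff, rep.box)
            per_replica_rows[ri].append((a, b, top.residue_label(a), top.residue_label(b),
                                         coul.mean(), lj.mean(), coul.mean() + lj.mean()))
    cols = ["residue_a", "residue_b", "label_a", "label_b", "coulomb", "lj", "total"]
    reps = [pd.DataFrame(rows, columns=cols) for rows in per_replica_rows]
    mean = reps[0].copy()
    for col in ("coulomb", "lj", "total"):
        mean[col] = np.mean([df[col].to_numpy() for df in reps], axis=0)
    return PairEnergyTable(table=mean, per_replica=reps, cutoff=params.cutoff,
                           gate_cutoff=gate_cutoff)


def group_interaction_energy(traj: TrajectoryEnsemble, group_a: Selection,
                             group_b: Selection, params: NonbondedParams = None,
                             cutoff: float = None):
    """Total inter-group nonbonded energy per analysis frame, per replica.

    Equals E_TOT - (E_A + E_B) under pairwise sums, since intra-group and
    bonded terms cancel in the difference. ``cutoff=None`` uses the
    short-range cutoff from ``params``; ``cutoff=np.inf`` gives the
    cutoff-free full-range sum. Returns a list of per-frame arrays
    (coulomb + LJ, kJ/mol), one per replica.
    """
    params = params or NonbondedParams()
    _check_parameters(traj.topology)
    _check_disjoint(group_a, group_b)
    cut = params.cutoff if cutoff is None else cutoff
    out = []
    for rep in traj.replicas:
        coords = rep.coords[traj.analysis_mask(rep)]
        coul, lj = _atom_pair_energy(coords, group_a.indices, group_b.indices,
                                     traj.topology, params, cut, rep.box)
        out.append(coul + lj)
    return out


# ---------------------------------------------------------------------------
# SASA (Shrake-Rupley) and apolar term
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden spiral)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * i
    return np.stack([np.sin(phi) * np.cos(theta),
                     np.sin(phi) * np.sin(theta),
                     np.cos(phi)], axis=1)


def _principal_frame(coords: np.ndarray) -> np.ndarray:
    """Molecule-intrinsic right-handed axes (columns). Orienting the test
    sphere in this frame makes the discretised SASA exactly invariant
    under rigid motions: the frame co-rotates with the molecule. Axis
    signs are fixed by the third coordinate moments, which also co-rotate."""
    X = coords - coords.mean(axis=0)
    C = X.T @ X
    _, V = np.linalg.eigh(C)
    V = V[:, ::-1]
    for k in range(2):
        third = np.sum((X @ V[:, k]) ** 3)
        if third < 0 or (third == 0 and V[np.argmax(np.abs(V[:, k])), k] < 0):
            V[:, k] = -V[:, k]
    V[:, 2] = np.cross(V[:, 0], V[:, 1])
    return V


def sasa_shrake_rupley(coords: np.ndarray, radii: np.ndarray, probe: float = 0.14,
                       n_points: int = 960):
    """Shrake-Rupley solvent-accessible surface area.

    ``coords`` (n,3) nm, ``radii`` per-atom vdW radii (nm). Test points are
    placed on each atom's probe-inflated sphere (oriented in the
    molecule's principal-axes frame, so rigid motions leave the result
    unchanged); the accessible fraction times the sphere area gives the
    per-atom SASA. Deterministic for a given ``n_points``. Returns
    (per_atom, total) in nm^2.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    if np.any(~np.isfinite(radii)) or np.any(radii <= 0):
        raise ValueError("every atom needs a positive radius")
    n = len(coords)
    inflated = radii + probe
    unit = _sphere_points(n_points) @ _principal_frame(coords).T
    tree = cKDTree(coords)
    per_atom = np.zeros(n)
    max_r = inflated.max()
    for i in range(n):
        pts = coords[i] + inflated[i] * unit
        neighbours = [j for j in tree.query_ball_point(coords[i], inflated[i] + max_r)
                      if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in neighbours:
            d2 = ((pts - coords[j]) ** 2).sum(axis=1)
            accessible &= d2 > inflated[j] ** 2
        per_atom[i] = accessible.mean() * 4.0 * np.pi * inflated[i] ** 2
    return per_atom, float(per_atom.sum())


def apolar_energy(sas: float, params: ApolarParams = None) -> float:
    """Apolar solvation energy gamma*SAS + b (kJ/mol), SAS in nm^2."""
    params = params or ApolarParams()
    if sas < 0:
        raise ValueError("SAS must be >= 0")
    return params.gamma * sas + params.b


def pb_radii(topology: Topology) -> np.ndarray:
    """Default PB/SASA atomic radii: the LJ energy-minimum radius
    sigma * 2^(1/6) / 2; atoms with sigma = 0 get 0.15 nm."""
    r = topology.lj_sigmas * 2.0 ** (1.0 / 6.0) / 2.0
    return np.where(r > 0, r, 0.15)


# ---------------------------------------------------------------------------
# MM/PBSA summary
# ---------------------------------------------------------------------------

def _strided(coords: np.ndarray, stride: int) -> np.ndarray:
    return coords[::stride]


def mmpbsa_summary(traj: TrajectoryEnsemble, group_a: Selection, group_b: Selection,
                   params: NonbondedParams = None, apolar_params: ApolarParams = None,
                   pb_settings: PBSettings = None, dense_stride: int = 1,
                   sparse_stride: int = 10, radii: np.ndarray = None,
                   include_polar: bool = True,
                   include_longrange: bool = True) -> EnergySummary:
    """End-state binding-energy decomposition with replica statistics.

    Terms (all as Delta = complex - receptor - ligand, kJ/mol):

    - ``E_SR``: inter-group Coulomb+LJ within the short-range cutoff,
      dense snapshot set.
    - ``E_Coul/LJ``: cutoff-free full-range inter-group sum (dense set).
    - ``E_solv-apolar``: gamma*SAS + b per end state (dense set).
    - ``E_solv-polar``: FD-PB reaction-field energy per end state (sparse
      snapshot set; the linearized solver is a validation-scale stand-in
      for production PB engines).

    Components use the single-trajectory convention: receptor/ligand frames
    are the complex frames restricted to each group. Per-replica means are
    averaged and their spread is reported as the standard deviation of the
    mean.
    """
    params = params or NonbondedParams()
    apolar_params = apolar_params or ApolarParams()
    pb_settings = pb_settings or PBSettings()
    top = traj.topology
    _check_parameters(top)
    _check_disjoint(group_a, group_b)
    if radii is None:
        radii = pb_radii(top)
    ia, ib = group_a.indices, group_b.indices
    all_idx = np.concatenate([ia, ib])

    term_rows = {}

    # dense terms
    sr_rep, full_rep, apolar_rep = [], [], []
    n_dense = []
    for rep in traj.replicas:
        coords = _strided(rep.coords[traj.analysis_mask(rep)], dense_stride)
        if coords.shape[0] < 2:
            raise ValueError("dense stride leaves fewer than 2 snapshots")
        n_dense.append(coords.shape[0])
        coul, lj = _atom_pair_energy(coords, ia, ib, top, params, params.cutoff, rep.box)
        sr_rep.append((coul + lj).mean())
        if include_longrange:
            coul_f, lj_f = _atom_pair_energy(coords, ia, ib, top, params, np.inf, rep.box)
            full_rep.append((coul_f + lj_f).mean())
        ap_vals = []
        for f in range(coords.shape[0]):
            _, sas_c = sasa_shrake_rupley(coords[f, all_idx], radii[all_idx],
                                          apolar_params.probe_radius, apolar_params.n_points)
            _, sas_a = sasa_shrake_rupley(coords[f, ia], radii[ia],
                                          apolar_params.probe_radius, apolar_params.n_points)
            _, sas_b = sasa_shrake_rupley(coords[f, ib], radii[ib],
                                          apolar_params.probe_radius, apolar_params.n_points)
            ap_vals.append(apolar_energy(sas_c, apolar_params)
                           - apolar_energy(sas_a, apolar_params)
                           - apolar_energy(sas_b, apolar_params))
        apolar_rep.append(float(np.mean(ap_vals)))
    term_rows["E_SR"] = (sr_rep, n_dense)
    if include_longrange:
        term_rows["E_Coul/LJ"] = (full_rep, n_dense)
    term_rows["E_solv-apolar"] = (apolar_rep, n_dense)

    if include_polar:
        polar_rep, n_sparse = [], []
        for rep in traj.replicas:
            coords = _strided(rep.coords[traj.analysis_mask(rep)], sparse_stride)
            if coords.shape[0] < 2:
                raise ValueError("sparse stride leaves fewer than 2 snapshots")
            n_sparse.append(coords.shape[0])
            vals = []
            for f in range(coords.shape[0]):
                e_c = polar_energy_fdpb(coords[f, all_idx], top.charges[all_idx],
                                        radii[all_idx], pb_settings)
                e_a = polar_energy_fdpb(coords[f, ia], top.charges[ia], radii[ia], pb_settings)
                e_b = polar_energy_fdpb(coords[f, ib], top.charges[ib], radii[ib], pb_settings)
                vals.append(e_c - e_a - e_b)
            polar_rep.append(float(np.mean(vals)))
        term_rows["E_solv-polar"] = (polar_rep, n_sparse)

    index, means, sems, snaps, rep_cols = [], [], [], [], []
    for term, (vals, counts) in term_rows.items():
        vals = np.asarray(vals, float)
        index.append(term)
        means.append(vals.mean())
        sems.append(vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0)
        snaps.append(int(np.mean(counts)))
        rep_cols.append(vals)
    terms = pd.DataFrame({"mean": means, "sem": sems, "n_snapshots": snaps}, index=index)
    per_replica = pd.DataFrame(
        np.array(rep_cols), index=index,
        columns=[f"replica_{i+1}" for i in range(traj.n_replicas)])
    return EnergySummary(terms=terms, per_replica=per_replica)
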