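"""Stability and flexibility metrics over trajectory ensembles.

RMSD after optimal (Kabsch) superposition, block-averaged RMSF, radius of
gyration, hydrogen-bond counts, and residue-pair distance series with
contact occupancy. All time averages respect the ensemble's
discard-equilibration window; replica aggregation is the mean of
per-replica values with the spread reported as the standard deviation of
the mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .core import Frame, Selection, Topology, TrajectoryEnsemble

__all__ = [
    "FlexibilityProfile", "DistanceSeries", "superpose_rmsd", "superpose_stack",
    "rmsf_blocked", "radius_of_gyration", "rg_series", "rmsd_series",
    "count_hbonds", "residue_pair_distances",
]


class DegenerateFitError(ValueError):
    """Fit selection has fewer than 3 non-collinear atoms."""


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF with per-block and per-replica detail (nm)."""

    residue_indices: np.ndarray
    rmsf: np.ndarray                    # mean over blocks and replicas
    rmsf_sem: np.ndarray                # sd of the mean over replicas
    per_replica: list                   # replica -> (n_blocks, n_residues)
    block_ns: float = None
    discard_ns: float = None
    selection: str = None


@dataclass
class DistanceSeries:
    """Per-frame residue-pair distances (nm) and threshold occupancy."""

    pair: tuple
    labels: tuple
    per_replica_distances: list
    threshold: float = None
    occupancy: float = None             # fraction of analysis frames <= threshold
    per_replica_occupancy: np.ndarray = None

    @property
    def distances(self) -> np.ndarray:
        return np.concatenate(self.per_replica_distances)


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def _check_fit_selection(coords):
    if coords.shape[0] < 3:
        raise DegenerateFitError("fit selection needs at least 3 atoms")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise DegenerateFitError("fit selection is collinear or degenerate")


def superpose_rmsd(frame: Frame, reference: Frame, fit: Selection,
                   measure: Selection = None):
    """Least-squares rigid superposition of ``frame`` onto ``reference``.

    The rotation/translation minimise the RMSD over the ``fit`` selection
    (Kabsch); the returned RMSD is evaluated on ``measure`` (defaults to
    ``fit``) after applying that transform.

    Returns ``(rotation_matrix, translation, rmsd_nm)`` such that
    ``x @ R.T + t`` maps frame coordinates onto the reference.
    """
    measure = fit if measure is None else measure
    x = frame.coordinates[fit.indices]
    y = reference.coordinates[fit.indices]
    _check_fit_selection(x)
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    rot, _ = Rotation.align_vectors(y - yc, x - xc)
    R = rot.as_matrix()
    t = yc - xc @ R.T
    moved = frame.coordinates[measure.indices] @ R.T + t
    delta = moved - reference.coordinates[measure.indices]
    rmsd = float(np.sqrt((delta**2).sum(axis=1).mean()))
    return R, t, rmsd


def superpose_stack(coords: np.ndarray, reference: np.ndarray,
                    fit_indices: np.ndarray) -> np.ndarray:
    """Superpose every frame of a (n_frames, n_atoms, 3) stack onto a
    reference structure, fitting on ``fit_indices``. Vectorised Kabsch."""
    import warnings as _warnings
    out = np.empty_like(coords)
    ref = reference[fit_indices]
    ref_c = ref - ref.mean(axis=0)
    ref_mean = ref.mean(axis=0)
    with _warnings.catch_warnings():
        # zero-variance stacks make the rotation ill-defined but harmless
        _warnings.filterwarnings("ignore", message="Optimal rotation is not")
        for f in range(coords.shape[0]):
            x = coords[f, fit_indices]
            x_mean = x.mean(axis=0)
            rot, _ = Rotation.align_vectors(ref_c, x - x_mean)
            R = rot.as_matrix()
            out[f] = (coords[f] - x_mean) @ R.T + ref_mean
    return out


def rmsd_series(traj: TrajectoryEnsemble, fit: Selection, measure: Selection = None,
                reference: Frame = None):
    """Per-replica RMSD time series (nm) against a reference structure
    (default: first frame of the first replica). Uses all frames so the
    equilibration transient remains visible."""
    measure = fit if measure is None else measure
    if reference is None:
        reference = traj.replicas[0].frame(0)
    series = []
    for rep in traj.replicas:
        vals = np.array([
            superpose_rmsd(rep.frame(i), reference, fit, measure)[2]
            for i in range(rep.n_frames)
        ])
        series.append(vals)
    return series


# ---------------------------------------------------------------------------
# Blocked RMSF
# ---------------------------------------------------------------------------

def rmsf_blocked(traj: TrajectoryEnsemble, selection: Selection,
                 block_ns: float = 100.0, fit: Selection = None,
                 n_fit_iterations: int = 2, superpose: bool = True) -> FlexibilityProfile:
    """Block-averaged per-residue RMSF.

    The post-discard span of each replica is cut into ``floor(span/block)``
    windows. Within each window the frames are iteratively superposed onto
    the window-mean structure (removing rigid-body drift), and
    RMSF_i = sqrt(<|r_i - <r_i>|^2>). The profile is the mean over windows,
    then over replicas; per-replica per-block values are retained.

    ``superpose=False`` skips the per-block rigid fit. Use it for ensembles
    sampled in a fixed laboratory frame (the synthetic harmonic wells):
    a least-squares fit necessarily absorbs fluctuation variance into the
    removed rigid modes, preferentially from high-amplitude atoms at the
    periphery, which biases those RMSF values low when there is no actual
    rigid-body drift to remove.
    """
    fit = selection if fit is None else fit
    block_ps = block_ns * 1000.0
    sel_idx = selection.indices
    fit_idx = fit.indices
    per_replica = []
    for rep in traj.replicas:
        mask = traj.analysis_mask(rep)
        times = rep.times[mask]
        coords = rep.coords[mask]
        if len(times) == 0:
            raise ValueError("no analysis frames after discard window")
        span = times[-1] - times[0] + (times[1] - times[0] if len(times) > 1 else 0.0)
        n_blocks = int(span // block_ps)
        if n_blocks < 1:
            raise ValueError(
                f"analysis span {span / 1000.0:g} ns shorter than one block ({block_ns:g} ns)")
        t0 = times[0]
        block_rmsf = []
        for b in range(n_blocks):
            sel = (times - t0 >= b * block_ps) & (times - t0 < (b + 1) * block_ps)
            if b == n_blocks - 1:  # absorb rounding stragglers into last block
                sel = (times - t0 >= b * block_ps)
            blk = coords[sel]
            if blk.shape[0] < 2:
                continue
            fitted = blk
            if superpose:
                for _ in range(n_fit_iterations):
                    mean_structure = fitted.mean(axis=0)
                    fitted = superpose_stack(fitted, mean_structure, fit_idx)
            mean_structure = fitted.mean(axis=0)
            disp2 = ((fitted[:, sel_idx] - mean_structure[sel_idx]) ** 2).sum(axis=2)
            block_rmsf.append(np.sqrt(disp2.mean(axis=0)))
        per_replica.append(np.array(block_rmsf))
    replica_means = np.array([br.mean(axis=0) for br in per_replica])
    rmsf = replica_means.mean(axis=0)
    if len(replica_means) > 1:
        sem = replica_means.std(axis=0, ddof=1) / np.sqrt(len(replica_means))
    else:
        sem = np.zeros_like(rmsf)
    res_idx = traj.topology.residue_indices[sel_idx]
    return FlexibilityProfile(
        residue_indices=res_idx, rmsf=rmsf, rmsf_sem=sem, per_replica=per_replica,
        block_ns=block_ns, discard_ns=traj.discard_ps / 1000.0)


# ---------------------------------------------------------------------------
# Radius of gyration
# ---------------------------------------------------------------------------

def radius_of_gyration(frame: Frame, topology: Topology, selection: Selection) -> float:
    """Mass-weighted radius of gyration (nm) about the centre of mass."""
    idx = selection.indices
    if idx.size == 0:
        raise ValueError("empty selection")
    m = topology.masses[idx]
    total = m.sum()
    if total <= 0:
        raise ValueError("zero total mass in selection")
    x = frame.coordinates[idx]
    com = (m[:, None] * x).sum(axis=0) / total
    r2 = ((x - com) ** 2).sum(axis=1)
    return float(np.sqrt((m * r2).sum() / total))


def rg_series(traj: TrajectoryEnsemble, selection: Selection):
    """Per-replica Rg time series over all frames."""
    out = []
    for rep in traj.replicas:
        out.append(np.array([
            radius_of_gyration(rep.frame(i), traj.topology, selection)
            for i in range(rep.n_frames)]))
    return out


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def count_hbonds(frame: Frame, topology: Topology, donors, acceptors: Selection,
                 d_max: float = 0.35, angle_max: float = 30.0) -> int:
    """Count hydrogen bonds under the geometric criterion
    D...A <= d_max (nm) and H-D...A angle <= angle_max (degrees);
    both thresholds inclusive.

    ``donors`` is a sequence of ``(donor_index, hydrogen_index)`` pairs --
    the bonded hydrogen must be recorded explicitly.
    """
    coords = frame.coordinates
    acc_idx = acceptors.indices
    count = 0
    for pair in donors:
        try:
            d_i, h_i = pair
        except (TypeError, ValueError):
            raise ValueError(
                f"donor entry {pair!r} must be a (donor, hydrogen) index pair; "
                "a donor without a recorded hydrogen cannot be evaluated") from None
        d = coords[d_i]
        h = coords[h_i]
        for a_i in acc_idx:
            if a_i == d_i or a_i == h_i:
                continue
            a = coords[a_i]
            da = a - d
            dist = np.linalg.norm(da)
            if dist > d_max or dist == 0:
                continue
            dh = h - d
            cosang = np.dot(dh, da) / (np.linalg.norm(dh) * dist)
            angle = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if angle <= angle_max:
                count += 1
    return count


def hbond_series(traj: TrajectoryEnsemble, donors, acceptors: Selection,
                 d_max: float = 0.35, angle_max: float = 30.0):
    out = []
    for rep in traj.replicas:
        out.append(np.array([
            count_hbonds(rep.frame(i), traj.topology, donors, acceptors, d_max, angle_max)
            for i in range(rep.n_frames)]))
    return out


# ---------------------------------------------------------------------------
# Residue-pair distances and occupancy
# ---------------------------------------------------------------------------

def residue_pair_distances(traj: TrajectoryEnsemble, residue_a: int, residue_b: int,
                           mode: str = "min-heavy", atoms: tuple = None,
                           threshold: float = None) -> DistanceSeries:
    """Per-frame distance between two residues over the analysis window.

    ``mode='min-heavy'`` uses the minimum heavy-atom distance;
    ``mode='named'`` uses the single distance between ``atoms=(name_a,
    name_b)``. Occupancy is the fraction of analysis frames (pooled across
    replicas via the per-replica mean) with distance <= threshold.
    """
    top = traj.topology
    res_a, res_b = top.residues[residue_a], top.residues[residue_b]
    if mode == "min-heavy":
        idx_a = [i for i in res_a.atom_indices if top.atoms[i].is_heavy]
        idx_b = [i for i in res_b.atom_indices if top.atoms[i].is_heavy]
        if not idx_a or not idx_b:
            raise ValueError("residue without heavy atoms")
    elif mode == "named":
        if atoms is None:
            raise ValueError("mode='named' requires atoms=(name_a, name_b)")
        name_a, name_b = atoms
        idx_a = [i for i in res_a.atom_indices if top.atoms[i].name == name_a]
        idx_b = [i for i in res_b.atom_indices if top.atoms[i].name == name_b]
        if not idx_a:
            raise ValueError(f"atom {name_a!r} not found in residue {res_a.label}")
        if not idx_b:
            raise ValueError(f"atom {name_b!r} not found in residue {res_b.label}")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    idx_a, idx_b = np.asarray(idx_a), np.asarray(idx_b)

    per_replica = []
    occupancies = []
    for rep in traj.replicas:
        coords = rep.coords[traj.analysis_mask(rep)]
        diff = coords[:, idx_a, None, :] - coords[:, None, idx_b, :]
        dist = np.sqrt((diff**2).sum(axis=3)).reshape(coords.shape[0], -1).min(axis=1)
        per_replica.append(dist)
        if threshold is not None:
            occupancies.append(float((dist <= threshold).mean()))
    occ_arr = np.array(occupancies) if threshold is not None else None
    return DistanceSeries(
        pair=(residue_a, residue_b),
        labels=(res_a.label, res_b.label),
        per_replica_distances=per_replica,
        threshold=threshold,
        occupancy=float(occ_arr.mean()) if occ_arr is not None else None,
        per_replica_occupancy=occ_arr,
    )
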