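"""Synthetic trajectory ensembles, toy complexes, and work sets with
planted, analytically known structure.

Every generator is a pure function of its spec plus seed. The generators do
not attempt physically realistic protein geometry; they guarantee the
statistical and geometric properties the downstream analyses measure:
controllable per-residue fluctuation amplitudes, planted inter-residue
correlations, planted contact geometry, interface electrostatics, and
Gaussian forward/backward work distributions satisfying the Crooks
fluctuation relation in distribution.

Beads carry one residue per bead so residue-level and atom-level analyses
coincide on synthetic systems. Frames are i.i.d. draws by default; an
optional AR(1) parameter introduces time correlation to stress-test block
averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import KB, DEFAULT_TEMPERATURE
from .core import AtomRecord, Frame, Replica, Topology, TrajectoryEnsemble

__all__ = [
    "SpecError", "GaussianEnsembleSpec", "ToyComplexSpec", "WorkSetSpec",
    "gen_gaussian_ensemble", "gen_harmonic_wells", "gen_toy_complex",
    "gen_planted_path", "gen_work_sets",
]


class SpecError(ValueError):
    """Invalid generator specification."""


def _bead_topology(positions, names=None, chain_ids=None, charges=None,
                   sigmas=None, epsilons=None, masses=None, groups=None,
                   residue_name="BEA"):
    n = len(positions)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    sigmas = np.full(n, 0.3) if sigmas is None else np.asarray(sigmas, float)
    epsilons = np.zeros(n) if epsilons is None else np.asarray(epsilons, float)
    masses = np.full(n, 100.0) if masses is None else np.asarray(masses, float)
    atoms = [
        AtomRecord(
            index=i,
            name=(names[i] if names is not None else "CA"),
            element="C", mass=float(masses[i]), charge=float(charges[i]),
            lj_sigma=float(sigmas[i]), lj_epsilon=float(epsilons[i]),
            residue_index=i, residue_name=residue_name,
            chain_id=(chain_ids[i] if chain_ids is not None else "A"),
        )
        for i in range(n)
    ]
    top = Topology(atoms, groups=groups)
    top.parameters_assigned = True
    top.group_charges = {k: float(charges[v].sum()) for k, v in top.groups.items()}
    return top


def _ar1_colour(rng_draws: np.ndarray, phi: float) -> np.ndarray:
    """Turn i.i.d. standard-normal draws into a stationary AR(1) series
    with the same marginal variance."""
    if phi == 0.0:
        return rng_draws
    out = np.empty_like(rng_draws)
    out[0] = rng_draws[0]
    scale = np.sqrt(1.0 - phi * phi)
    for t in range(1, len(rng_draws)):
        out[t] = phi * out[t - 1] + scale * rng_draws[t]
    return out


# ---------------------------------------------------------------------------
# Gaussian ensembles with planted correlations
# ---------------------------------------------------------------------------

@dataclass
class GaussianEnsembleSpec:
    """Bead chain fluctuating as a multivariate normal with planted
    pairwise correlations (same rho in each Cartesian dimension)."""

    n_residues: int
    sd: object = 0.1                       # scalar or per-residue, nm
    correlations: list = field(default_factory=list)  # (i, j, rho)
    spacing: float = 0.4                   # reference bead spacing, nm
    n_frames: int = 1000
    n_replicas: int = 1
    seed: int = 0
    ar1: float = 0.0

    def sd_array(self) -> np.ndarray:
        s = np.broadcast_to(np.asarray(self.sd, float), (self.n_residues,)).copy()
        if np.any(s <= 0):
            raise SpecError("per-residue sd must be > 0")
        return s

    def covariance(self) -> np.ndarray:
        """Per-dimension covariance over residues (nm^2)."""
        s = self.sd_array()
        cov = np.diag(s * s)
        for (i, j, rho) in self.correlations:
            if not -1.0 < rho < 1.0:
                raise SpecError(f"|rho| must be < 1, got {rho} for pair ({i},{j})")
            cov[i, j] = cov[j, i] = rho * s[i] * s[j]
        eigmin = np.linalg.eigvalsh(cov).min()
        if eigmin <= 0:
            raise SpecError(f"requested covariance is not positive definite (min eig {eigmin:g})")
        return cov


def gen_gaussian_ensemble(spec: GaussianEnsembleSpec) -> TrajectoryEnsemble:
    """Frames drawn i.i.d. from N(reference, planted covariance), each
    Cartesian dimension independent with the same residue-level covariance."""
    cov = spec.covariance()
    L = np.linalg.cholesky(cov)
    ref = np.zeros((spec.n_residues, 3))
    ref[:, 0] = np.arange(spec.n_residues) * spec.spacing
    rng = np.random.default_rng(spec.seed)
    replicas = []
    for _ in range(spec.n_replicas):
        # (n_frames, n_residues, 3): correlate residues within each dimension
        z = rng.standard_normal((spec.n_frames, spec.n_residues, 3))
        if spec.ar1:
            z = _ar1_colour(z, spec.ar1)
        disp = np.einsum("ij,fjd->fid", L, z)
        coords = ref[None] + disp
        replicas.append(Replica(coords, np.arange(spec.n_frames, dtype=float)))
    ens = TrajectoryEnsemble(_bead_topology(ref), replicas)
    ens.planted_covariance = cov
    return ens


# ---------------------------------------------------------------------------
# Harmonic wells (closed-form oracle for RMSF and Schlitter entropy)
# ---------------------------------------------------------------------------

def gen_harmonic_wells(n_residues: int, force_constants, T: float = DEFAULT_TEMPERATURE,
                       n_frames: int = 5000, seed: int = 0, spacing: float = 1.0,
                       mass: float = 100.0, ar1: float = 0.0) -> TrajectoryEnsemble:
    """Independent isotropic harmonic wells at temperature T.

    Each bead's displacement per Cartesian dimension is Normal(0, kB*T/k_i),
    so RMSF_i = sqrt(3 kB T / k_i) and the Cartesian covariance is diagonal
    with kB*T/k_i per coordinate; that analytic covariance is attached as
    ``analytic_covariance`` (per-coordinate, 3N x 3N diagonal given as the
    per-dof variance vector) for use as an entropy/RMSF oracle.
    """
    k = np.broadcast_to(np.asarray(force_constants, float), (n_residues,)).copy()
    if np.any(k <= 0):
        raise SpecError("force constants must be > 0")
    if T <= 0:
        raise SpecError("temperature must be > 0 (zero-variance wells are degenerate)")
    var = KB * T / k                       # nm^2 per dimension
    ref = np.zeros((n_residues, 3))
    ref[:, 0] = np.arange(n_residues) * spacing
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n_frames, n_residues, 3))
    if ar1:
        z = _ar1_colour(z, ar1)
    coords = ref[None] + z * np.sqrt(var)[None, :, None]
    top = _bead_topology(ref, masses=np.full(n_residues, mass))
    ens = TrajectoryEnsemble(top, [Replica(coords, np.arange(n_frames, dtype=float))])
    ens.analytic_variance_per_dof = np.repeat(var, 3)  # nm^2, per Cartesian dof
    ens.well_constants = k
    ens.temperature = T
    return ens


# ---------------------------------------------------------------------------
# Two-group toy complex (receptor/ligand) with optional point mutant
# ---------------------------------------------------------------------------

@dataclass
class ToyComplexSpec:
    """Receptor/ligand bead complex with interface electrostatics.

    ``mutant_charges``/``mutant_positions`` describe a variant differing
    from the parent in exactly the declared beads (index -> new value);
    the engineered/parental pair of an affinity-maturation study is the
    use case this emulates.
    """

    receptor_positions: np.ndarray
    ligand_positions: np.ndarray
    receptor_charges: np.ndarray = None
    ligand_charges: np.ndarray = None
    lj_sigma: float = 0.3
    lj_epsilon: float = 0.0
    jitter_sd: float = 0.0                 # thermal jitter, nm
    n_frames: int = 100
    n_replicas: int = 1
    seed: int = 0
    mutant_charges: dict = None            # bead index (global) -> charge
    mutant_positions: dict = None          # bead index (global) -> (x, y, z)

    def _assemble(self, variant: str):
        rpos = np.asarray(self.receptor_positions, float)
        lpos = np.asarray(self.ligand_positions, float)
        pos = np.vstack([rpos, lpos])
        n_r, n_l = len(rpos), len(lpos)
        q = np.concatenate([
            np.zeros(n_r) if self.receptor_charges is None else np.asarray(self.receptor_charges, float),
            np.zeros(n_l) if self.ligand_charges is None else np.asarray(self.ligand_charges, float),
        ])
        if variant == "mutant":
            for i, qi in (self.mutant_charges or {}).items():
                q[i] = qi
            for i, xi in (self.mutant_positions or {}).items():
                pos[i] = np.asarray(xi, float)
        return pos, q, n_r, n_l


def gen_toy_complex(spec: ToyComplexSpec):
    """Build parent (and mutant, if declared) systems.

    Returns a dict ``variant -> (Topology, TrajectoryEnsemble)``; the two
    variants share topology shape and random stream, so frame-wise
    differences come only from the declared mutation.
    """
    variants = ["parent"]
    if spec.mutant_charges or spec.mutant_positions:
        variants.append("mutant")
    out = {}
    for variant in variants:
        pos, q, n_r, n_l = spec._assemble(variant)
        from scipy.spatial.distance import pdist
        if len(pos) > 1 and pdist(pos).min() < 0.05:
            raise SpecError("overlapping beads (r < 0.05 nm) give singular energies")
        groups = {"receptor": np.arange(n_r), "ligand": np.arange(n_r, n_r + n_l)}
        chain_ids = ["R"] * n_r + ["L"] * n_l
        top = _bead_topology(pos, chain_ids=chain_ids, charges=q,
                             sigmas=np.full(len(pos), spec.lj_sigma),
                             epsilons=np.full(len(pos), spec.lj_epsilon),
                             groups=groups)
        rng = np.random.default_rng(spec.seed)  # same stream for both variants
        replicas = []
        for _ in range(spec.n_replicas):
            jitter = (rng.standard_normal((spec.n_frames, len(pos), 3)) * spec.jitter_sd
                      if spec.jitter_sd > 0 else np.zeros((spec.n_frames, len(pos), 3)))
            coords = pos[None] + jitter
            replicas.append(Replica(coords, np.arange(spec.n_frames, dtype=float)))
        out[variant] = (top, TrajectoryEnsemble(top, replicas))
    return out


# ---------------------------------------------------------------------------
# Planted allosteric path
# ---------------------------------------------------------------------------

def gen_planted_path(n_residues: int, path, rho_on: float, rho_off: float,
                     n_frames: int = 5000, seed: int = 0, jitter_sd: float = 0.02,
                     contact_distance: float = 0.4, n_replicas: int = 1):
    """Bead system whose correlation/contact structure plants a known
    shortest allosteric path.

    Geometry: consecutive path residues are laid along x at
    ``contact_distance`` spacing (pairwise in contact); the remaining
    residues are placed as bridge beads near the path segments, each in
    contact with the two flanking path nodes, providing decoy routes.
    Correlations come from an explicit linear-Gaussian model (positive
    definite by construction): path-node displacements form a Markov chain
    with adjacent correlation exactly ``rho_on`` (non-adjacent path pairs
    then correlate as rho_on^k, but lie outside contact range and are
    filtered by the contact map); each bridge bead mixes its two anchors so
    its correlation with each anchor is exactly ``rho_off``. With
    rho_on > rho_off the minimum -log10(r) route from path[0] to path[-1]
    is the planted chain.
    """
    path = list(path)
    if rho_off > rho_on:
        raise SpecError("rho_off must not exceed rho_on")
    if not (-1.0 < rho_off <= rho_on < 1.0):
        raise SpecError("correlations must satisfy -1 < rho_off <= rho_on < 1")
    if len(path) < 2 or len(set(path)) != len(path):
        raise SpecError("path must list at least two distinct residues")
    if any(p < 0 or p >= n_residues for p in path):
        raise SpecError("path residue out of range")

    positions = np.zeros((n_residues, 3))
    for rank, res in enumerate(path):
        positions[res] = (rank * contact_distance, 0.0, 0.0)
    off_path = [r for r in range(n_residues) if r not in path]
    n_segments = len(path) - 1
    bridge_edges = []  # (off residue, path rank a, path rank b)
    for slot, res in enumerate(off_path):
        seg = slot % n_segments
        layer = slot // n_segments + 1
        mid = (positions[path[seg]] + positions[path[seg + 1]]) / 2.0
        # layer-1 bridges sit at contact_distance from both flanking path
        # nodes (decoy routes); higher layers are pushed out of contact
        dy = np.sqrt(max(contact_distance**2 - (contact_distance / 2.0) ** 2, 1e-12))
        positions[res] = mid + (0.0, dy * layer, 0.3 * (layer - 1))
        bridge_edges.append((res, seg, seg + 1))

    # verify planted geometry satisfies the contact rule by construction
    for a, b in zip(path[:-1], path[1:]):
        if np.linalg.norm(positions[a] - positions[b]) > 0.5 - 4 * jitter_sd:
            raise SpecError("path not geometrically realizable under the contact rule")

    # bridge mixing coefficients: x_bridge = c*(x_a + x_b) + d*noise with
    # unit variance and corr(bridge, anchor) = rho_off
    c = rho_off / (1.0 + rho_on)
    d2 = 1.0 - 2.0 * c * c * (1.0 + rho_on)
    if d2 < 0:
        raise SpecError("rho_off too large for the bridge construction")
    d = np.sqrt(d2)

    rng = np.random.default_rng(seed)
    replicas = []
    for _ in range(n_replicas):
        xp = np.empty((n_frames, len(path), 3))
        xp[:, 0] = rng.standard_normal((n_frames, 3))
        innov = np.sqrt(1.0 - rho_on * rho_on)
        for rank in range(1, len(path)):
            xp[:, rank] = rho_on * xp[:, rank - 1] + innov * rng.standard_normal((n_frames, 3))
        disp = np.empty((n_frames, n_residues, 3))
        for rank, res in enumerate(path):
            disp[:, res] = xp[:, rank]
        for res, ra, rb in bridge_edges:
            disp[:, res] = c * (xp[:, ra] + xp[:, rb]) + d * rng.standard_normal((n_frames, 3))
        replicas.append(Replica(positions[None] + jitter_sd * disp,
                                np.arange(n_frames, dtype=float)))
    top = _bead_topology(positions)
    ens = TrajectoryEnsemble(top, replicas)
    ens.planted_path = path
    return top, ens


# ---------------------------------------------------------------------------
# Crooks-consistent Gaussian work sets
# ---------------------------------------------------------------------------

@dataclass
class WorkSetSpec:
    """Forward/backward nonequilibrium work ensembles for a transformation
    with known free-energy difference.

    Gaussian work distributions satisfying the Crooks relation exactly:
    W_f ~ N(dG + beta sigma^2/2, sigma^2), W_b ~ N(-dG + beta sigma^2/2,
    sigma^2), with beta = 1/(kB T). Backward works use the
    work-done-on-the-system sign convention for the reverse transformation.
    """

    delta_g: float                 # kJ/mol
    sigma: float                   # kJ/mol
    T: float = DEFAULT_TEMPERATURE
    n_forward: int = 300
    n_backward: int = 300
    seed: int = 0

    def __post_init__(self):
        if self.sigma <= 0:
            raise SpecError("work sd must be > 0")
        if self.n_forward < 2 or self.n_backward < 2:
            raise SpecError("need at least 2 works per direction")


def gen_work_sets(spec: WorkSetSpec):
    """Draw (forward_works, backward_works) in kJ/mol."""
    beta = 1.0 / (KB * spec.T)
    dissip = beta * spec.sigma**2 / 2.0
    rng = np.random.default_rng(spec.seed)
    forward = spec.delta_g + dissip + spec.sigma * rng.standard_normal(spec.n_forward)
    backward = -spec.delta_g + dissip + spec.sigma * rng.standard_normal(spec.n_backward)
    return forward, backward
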