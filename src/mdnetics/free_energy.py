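"""Configurational entropy and work-based free-energy estimation.

Schlitter's formula gives a quasi-harmonic upper bound on the
configurational entropy from the mass-weighted Cartesian covariance of the
fluctuations:

    S = (kB/2) ln det[ 1 + (kB T e^2 / hbar^2) M^(1/2) C M^(1/2) ]

computed via eigenvalues for numerical stability (e is Euler's number).
Binding-entropy differences combine per-system entropies through the
cycle -T ddS_b = -T [ dS_b(sys1) - dS_b(sys2) ] with
dS_b = S(complex) - sum S(parts).

Relative binding free energies come from forward/backward nonequilibrium
work ensembles via the Bennett acceptance ratio (self-consistent solution
of the Bennett equation) or the Crooks Gaussian intersection, combined
through the thermodynamic cycle ddG_b = dG_mut(complex) - dG_mut(isolated).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .constants import (AMU_KG, AVOGADRO, DEFAULT_TEMPERATURE, HBAR_SI, KB,
                        KB_SI, NM_M)
from .core import Selection, TrajectoryEnsemble
from .flexibility import superpose_stack

__all__ = [
    "EntropyResult", "WorkSet", "FreeEnergyCycle", "schlitter_entropy",
    "schlitter_from_covariance", "quantum_harmonic_entropy", "entropy_cycle",
    "bar_delta_g", "ddg_cycle", "read_work_table", "write_work_table",
]


@dataclass
class EntropyResult:
    """Schlitter entropy estimate.

    ``S`` kJ/mol/K, ``minus_TS`` kJ/mol; ``eigenvalues`` are the mass-
    weighted covariance spectrum (amu nm^2) retained as a conditioning
    diagnostic; ``n_samples`` flags thin sampling (< 3N frames warrants
    caution).
    """

    S: float
    T: float
    minus_TS: float
    eigenvalues: np.ndarray = None
    n_samples: int = None
    selection: str = None


@dataclass
class WorkSet:
    """Direction-labelled work values (kJ/mol) at one temperature."""

    forward: np.ndarray
    backward: np.ndarray
    T: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.forward = np.asarray(self.forward, float)
        self.backward = np.asarray(self.backward, float)
        if len(self.forward) < 2 or len(self.backward) < 2:
            raise ValueError("need at least 2 work values per direction")


@dataclass
class FreeEnergyCycle:
    """Two alchemical legs combined into a relative binding free energy."""

    dg_complex: float
    dg_complex_err: float
    dg_isolated: float
    dg_isolated_err: float
    method: str = "BAR"

    @property
    def ddg(self) -> float:
        return self.dg_complex - self.dg_isolated

    @property
    def ddg_err(self) -> float:
        return float(np.hypot(self.dg_complex_err, self.dg_isolated_err))


# ---------------------------------------------------------------------------
# Schlitter entropy
# ---------------------------------------------------------------------------

#: dimensionless prefactor alpha such that the Schlitter argument is
#: 1 + alpha * T * m[amu] * lambda[nm^2], with
#: alpha = kB_SI e^2 amu nm^2 / hbar^2 (per kelvin)
_SCHLITTER_ALPHA = KB_SI * np.e**2 * AMU_KG * NM_M**2 / HBAR_SI**2


def schlitter_from_covariance(covariance: np.ndarray, masses_per_dof: np.ndarray,
                              T: float = DEFAULT_TEMPERATURE) -> EntropyResult:
    """Schlitter entropy from a Cartesian covariance (nm^2) and per-dof
    masses (amu)."""
    covariance = np.asarray(covariance, float)
    m_sqrt = np.sqrt(np.asarray(masses_per_dof, float))
    mw = covariance * np.outer(m_sqrt, m_sqrt)       # amu nm^2
    eig = np.linalg.eigvalsh((mw + mw.T) / 2.0)
    tol = -1e-8 * max(eig.max(), 1.0)
    if eig.min() < tol:
        raise ValueError(f"covariance not positive semidefinite (min eig {eig.min():g})")
    eig = np.clip(eig, 0.0, None)
    S = 0.5 * KB * np.sum(np.log1p(_SCHLITTER_ALPHA * T * eig))
    return EntropyResult(S=float(S), T=T, minus_TS=float(-T * S), eigenvalues=eig)


def schlitter_entropy(traj: TrajectoryEnsemble, selection: Selection,
                      T: float = DEFAULT_TEMPERATURE, superpose: bool = True,
                      pool_replicas: bool = False) -> EntropyResult:
    """Schlitter entropy of the selected atoms over the analysis window.

    Frames are superposed to the ensemble mean (removing rigid-body
    motion) before the covariance is accumulated. By default the entropy
    is computed per replica and averaged; ``pool_replicas`` pools all
    frames into one covariance instead.
    """
    idx = selection.indices
    masses_per_dof = np.repeat(traj.topology.masses[idx], 3)
    stacks = []
    for rep in traj.replicas:
        coords = rep.coords[traj.analysis_mask(rep)]
        if superpose:
            for _ in range(2):
                mean_structure = coords.mean(axis=0)
                coords = superpose_stack(coords, mean_structure, idx)
        stacks.append(coords[:, idx].reshape(coords.shape[0], -1))
    if pool_replicas:
        stacks = [np.concatenate(stacks)]
    results = []
    for flat in stacks:
        dev = flat - flat.mean(axis=0)
        cov = dev.T @ dev / len(flat)
        res = schlitter_from_covariance(cov, masses_per_dof, T)
        res.n_samples = len(flat)
        results.append(res)
    S = float(np.mean([r.S for r in results]))
    out = EntropyResult(S=S, T=T, minus_TS=float(-T * S),
                        eigenvalues=results[0].eigenvalues,
                        n_samples=sum(r.n_samples for r in results))
    if out.n_samples < 3 * len(idx):
        import warnings
        warnings.warn(
            f"only {out.n_samples} frames for {3 * len(idx)} degrees of freedom; "
            "entropy estimate is likely unconverged", stacklevel=2)
    return out


def quantum_harmonic_entropy(covariance_eigenvalues: np.ndarray,
                             T: float = DEFAULT_TEMPERATURE) -> float:
    """Quantum harmonic-oscillator entropy (kJ/mol/K) from the same
    mass-weighted covariance spectrum (amu nm^2) the Schlitter formula
    uses; Schlitter upper-bounds this mode-by-mode."""
    eig = np.asarray(covariance_eigenvalues, float)
    eig = eig[eig > 0]
    # classical quasi-harmonic frequencies: alpha_i = hbar / sqrt(kB T m lam)
    alpha = HBAR_SI / np.sqrt(KB_SI * T * eig * AMU_KG * NM_M**2)
    with np.errstate(over="ignore"):
        s = alpha / np.expm1(alpha) - np.log(-np.expm1(-alpha))
    return float(KB * np.sum(np.where(np.isfinite(s), s, 0.0)))


def entropy_cycle(s_complex_1: float, s_parts_1, s_complex_2: float, s_parts_2,
                  T: float = DEFAULT_TEMPERATURE) -> float:
    """Binding-entropy double difference -T ddS_b (kJ/mol).

    ``s_parts_*`` are iterables of component entropies (kJ/mol/K);
    dS_b = S(complex) - sum(S(parts)); the sign convention makes a more
    ordered complex in system 1 a positive (unfavourable) penalty.
    """
    ds1 = s_complex_1 - float(np.sum(s_parts_1))
    ds2 = s_complex_2 - float(np.sum(s_parts_2))
    return -T * (ds1 - ds2)


# ---------------------------------------------------------------------------
# BAR / CGI estimators
# ---------------------------------------------------------------------------

def _fermi(x):
    return 1.0 / (1.0 + np.exp(np.clip(x, -500, 500)))


def _bar_point_estimate(wf: np.ndarray, wb: np.ndarray, T: float) -> float:
    """Self-consistent Bennett acceptance ratio estimate (kJ/mol).

    Solves sum_f fermi(beta(M + W_f - dG)) = sum_b fermi(beta(M - W_b + dG))
    with M = kB T ln(n_f / n_b); ``wb`` holds works of the reverse
    transformation in its own direction, so -wb samples the forward work
    under the end state.
    """
    beta = 1.0 / (KB * T)
    nf, nb = len(wf), len(wb)
    M = np.log(nf / nb) / beta

    def implicit(dg):
        lhs = _fermi(beta * (M + wf - dg)).sum()
        rhs = _fermi(beta * (-M + wb + dg)).sum()
        return lhs - rhs

    lo = min(wf.min(), -wb.max()) - 50.0 / beta
    hi = max(wf.max(), -wb.min()) + 50.0 / beta
    flo, fhi = implicit(lo), implicit(hi)
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    if flo * fhi > 0:  # degenerate overlap; fall back to midpoint convention
        return 0.5 * (np.mean(wf) - np.mean(wb))
    return brentq(implicit, lo, hi, xtol=1e-10)


def _cgi_point_estimate(wf: np.ndarray, wb: np.ndarray) -> float:
    """Crooks Gaussian intersection: dG is the crossing point of the
    forward work density and the negated-backward work density."""
    m1, s1 = np.mean(wf), np.std(wf, ddof=1)
    m2, s2 = np.mean(-wb), np.std(wb, ddof=1)
    if np.isclose(s1, s2, rtol=1e-6, atol=1e-12):
        return 0.5 * (m1 + m2)
    a = 1.0 / s1**2 - 1.0 / s2**2
    b = -2.0 * (m1 / s1**2 - m2 / s2**2)
    c = m1**2 / s1**2 - m2**2 / s2**2 - 2.0 * np.log(s2 / s1)
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return 0.5 * (m1 + m2)
    roots = np.array([(-b - np.sqrt(disc)) / (2 * a), (-b + np.sqrt(disc)) / (2 * a)])
    # the physical intersection lies between the two means
    lo, hi = min(m1, m2), max(m1, m2)
    inside = roots[(roots >= lo) & (roots <= hi)]
    if len(inside):
        return float(inside[0])
    return float(roots[np.argmin(np.abs(roots - 0.5 * (m1 + m2)))])


def bar_delta_g(work_set: WorkSet, method: str = "BAR", n_bootstrap: int = 100,
                bootstrap_seed: int = 0):
    """Free-energy difference from forward/backward work ensembles.

    Returns ``(dG, uncertainty)`` in kJ/mol; the uncertainty is the
    standard deviation of seeded bootstrap resamples. A result computed
    from non-overlapping work distributions carries an ``overlap_warning``
    attribute on the returned dG (exposed via the third tuple element).
    """
    wf, wb = work_set.forward, work_set.backward
    if method.upper() == "BAR":
        estimate = _bar_point_estimate(wf, wb, work_set.T)
    elif method.upper() == "CGI":
        estimate = _cgi_point_estimate(wf, wb)
    else:
        raise ValueError(f"unknown method {method!r}; use 'BAR' or 'CGI'")

    rng = np.random.default_rng(bootstrap_seed)
    boots = []
    for _ in range(n_bootstrap):
        bf = rng.choice(wf, size=len(wf), replace=True)
        bb = rng.choice(wb, size=len(wb), replace=True)
        try:
            if method.upper() == "BAR":
                boots.append(_bar_point_estimate(bf, bb, work_set.T))
            else:
                boots.append(_cgi_point_estimate(bf, bb))
        except (ValueError, RuntimeError):  # pragma: no cover
            continue
    err = float(np.std(boots, ddof=1)) if len(boots) > 1 else 0.0

    # overlap diagnostic: forward and negated-backward ranges must touch
    overlap = min(wf.max(), (-wb).max()) - max(wf.min(), (-wb).min())
    if overlap < 0:
        import warnings
        warnings.warn("forward and backward work distributions do not overlap; "
                      "the estimate is unreliable", stacklevel=2)
    return float(estimate), err


def ddg_cycle(dg_complex, dg_isolated, method: str = "BAR") -> FreeEnergyCycle:
    """Combine two alchemical legs (each a ``(dG, err)`` pair) into the
    relative binding free energy ddG_b = dG(complex) - dG(isolated),
    uncertainties propagated in quadrature."""
    if dg_complex is None or dg_isolated is None:
        raise ValueError("both cycle legs are required")
    (dgc, ec), (dgi, ei) = dg_complex, dg_isolated
    return FreeEnergyCycle(dg_complex=float(dgc), dg_complex_err=float(ec),
                           dg_isolated=float(dgi), dg_isolated_err=float(ei),
                           method=method)


# ---------------------------------------------------------------------------
# Work table I/O
# ---------------------------------------------------------------------------

def read_work_table(path, T: float = DEFAULT_TEMPERATURE) -> WorkSet:
    """Two-column delimited file: direction (forward|backward), work kJ/mol."""
    import pandas as pd
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    fwd = df.loc[df["direction"].str.lower() == "forward", "work"].to_numpy(float)
    bwd = df.loc[df["direction"].str.lower() == "backward", "work"].to_numpy(float)
    return WorkSet(forward=fwd, backward=bwd, T=T)


def write_work_table(path, work_set: WorkSet) -> None:
    import pandas as pd
    rows = [("forward", w) for w in work_set.forward] + \
           [("backward", w) for w in work_set.backward]
    pd.DataFrame(rows, columns=["direction", "work"]).to_csv(path, index=False)
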