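"""Condensate and polymer observables.

Covers the slab-simulation analysis chain -- protein-contact clustering,
cluster-centered density profiles along z, coexistence densities, and the
critical-point fit rho_H - rho_L = A (Tc - T)^beta with the 3D-Ising
exponent beta = 0.325 held fixed -- plus radius of gyration and the
bond-vector-correlation estimate of polymer persistence length.

Densities are mass densities in mg/mL. Molecules are made whole
(unwrapped by bond-walking) before any center-of-mass or Rg computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
from scipy.optimize import least_squares

from .units import AMU_PER_NM3_TO_MG_PER_ML
from .energetics import Box

ISING_BETA = 0.325


class AnalysisError(ValueError):
    pass


@dataclass
class DensityProfile:
    """Frame-averaged mass density along z, mg/mL."""

    bin_centers: np.ndarray  # nm, relative to the (centered) box middle
    density: np.ndarray      # mg/mL
    bin_width: float
    n_frames: int
    box: Box

    def total_mass(self) -> float:
        """Sum of density * bin volume, amu (mass-conservation check)."""
        lx, ly, _ = self.box.lengths
        bin_volume = lx * ly * self.bin_width
        return float(self.density.sum() * bin_volume / AMU_PER_NM3_TO_MG_PER_ML)


@dataclass
class CoexistencePoint:
    temperature: float  # K
    rho_dilute: float   # mg/mL
    rho_dense: float    # mg/mL

    def __post_init__(self):
        if self.rho_dilute < 0 or self.rho_dense < 0:
            raise AnalysisError("densities must be non-negative")


@dataclass
class CriticalFit:
    Tc: float
    A: float
    beta: float
    residuals: np.ndarray
    points: list[CoexistencePoint] = field(default_factory=list)

    def rho_diff(self, T: np.ndarray) -> np.ndarray:
        return self.A * np.maximum(self.Tc - np.asarray(T), 0.0) ** self.beta


@dataclass
class PersistenceFit:
    mean_bond_length: float       # nm
    separations: np.ndarray       # n values
    correlation: np.ndarray       # C(n)
    lp: float                     # nm; inf for a rigid chain
    fit_range: tuple[int, int]
    slope: float = 0.0


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def unwrap_molecule(mol_topology, coords: np.ndarray, box: Box) -> np.ndarray:
    """Make a molecule whole by walking its bond graph across images."""
    n = mol_topology.n_beads
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for t in mol_topology.terms("bond"):
        i, j = t.bead_indices
        adj[i].append(j)
        adj[j].append(i)
    out = coords.copy()
    visited = np.zeros(n, dtype=bool)
    for root in range(n):
        if visited[root]:
            continue
        visited[root] = True
        stack = [root]
        while stack:
            i = stack.pop()
            for j in adj[i]:
                if not visited[j]:
                    visited[j] = True
                    out[j] = out[i] + box.minimum_image(coords[j] - coords[i])
                    stack.append(j)
    return out


def radius_of_gyration(coordinates: np.ndarray,
                       masses: Optional[np.ndarray] = None) -> float:
    """Mass-weighted radius of gyration, nm.

    Pass whole-molecule (unwrapped) coordinates for multi-chain species.
    """
    coordinates = np.asarray(coordinates, dtype=float)
    if coordinates.ndim != 2 or len(coordinates) == 0:
        raise AnalysisError("empty selection")
    if masses is None:
        masses = np.ones(len(coordinates))
    masses = np.asarray(masses, dtype=float)
    if np.any(masses <= 0):
        raise AnalysisError("masses must be positive")
    com = np.average(coordinates, axis=0, weights=masses)
    sq = np.sum((coordinates - com) ** 2, axis=1)
    return float(np.sqrt(np.average(sq, weights=masses)))


def molecule_centers_of_mass(positions: np.ndarray, system_topology,
                             box: Box) -> np.ndarray:
    """Per-molecule-copy COM from unwrapped coordinates, (n_mol, 3)."""
    coms = np.empty((system_topology.n_molecules, 3))
    for mol, i, (lo, hi) in system_topology.iter_copies():
        if hi - lo == 1:
            coms[i] = positions[lo]
            continue
        whole = unwrap_molecule(mol, positions[lo:hi], box)
        coms[i] = np.average(whole, axis=0, weights=mol.masses)
    return coms


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def identify_largest_cluster(positions: np.ndarray, system_topology,
                             box: Box, cutoff: float = 5.0) -> list[int]:
    """Largest connected component of the molecule-contact network.

    Molecules (one copy = one node, i.e. a pre-assembled dimer counts as
    one monomer) are in contact when their center-of-mass minimum-image
    distance is below ``cutoff``. Ties are broken toward the component
    containing the lowest molecule index. Returns sorted molecule indices.
    """
    if cutoff <= 0:
        raise AnalysisError("cutoff must be positive")
    coms = molecule_centers_of_mass(positions, system_topology, box)
    n = len(coms)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if all(box.periodic) and cutoff < min(box.lengths) / 2.0:
        from scipy.spatial import cKDTree
        L = box.lengths_array
        wrapped = np.minimum(np.mod(coms, L), L * (1 - 1e-12))
        pairs = cKDTree(wrapped, boxsize=L).query_pairs(cutoff,
                                                        output_type="ndarray")
        g.add_edges_from(map(tuple, pairs))
    else:
        d = coms[:, None, :] - coms[None, :, :]
        d = box.minimum_image(d.reshape(-1, 3)).reshape(n, n, 3)
        dist = np.linalg.norm(d, axis=2)
        ii, jj = np.where(np.triu(dist < cutoff, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    comps = sorted(nx.connected_components(g),
                   key=lambda c: (-len(c), min(c)))
    return sorted(comps[0])


# ---------------------------------------------------------------------------
# density profiles and coexistence
# ---------------------------------------------------------------------------

def _circular_mean_z(z: np.ndarray, weights: np.ndarray, lz: float) -> float:
    """Periodic-aware weighted mean of z coordinates."""
    ang = z / lz * 2.0 * np.pi
    s = np.average(np.sin(ang), weights=weights)
    c = np.average(np.cos(ang), weights=weights)
    return float(np.arctan2(s, c) / (2.0 * np.pi) * lz % lz)


def density_profile(frames: Sequence[np.ndarray], system_topology, box: Box,
                    bin_width: float = 1.0, center_on_cluster: bool = True,
                    cluster_cutoff: float = 5.0) -> DensityProfile:
    """Mass density along the elongated (z) axis, averaged over frames.

    With ``center_on_cluster`` each frame is translated so the largest
    cluster's center of mass sits at z = 0 (the box middle) before
    binning; the operation is idempotent. ``frames`` is any sequence of
    position arrays (e.g. a TrajectoryHandle's positions, typically the
    second half of a production run).
    """
    if bin_width <= 0:
        raise AnalysisError("bin_width must be positive")
    lz = box.lengths[2]
    n_bins = max(1, int(round(lz / bin_width)))
    bw = lz / n_bins
    masses = system_topology.masses
    total = np.zeros(n_bins)
    n_frames = 0
    for pos in frames:
        z = pos[:, 2].copy()
        if center_on_cluster:
            cluster = identify_largest_cluster(pos, system_topology, box,
                                               cluster_cutoff)
            coms = molecule_centers_of_mass(pos, system_topology, box)
            w = np.array([masses[lo:hi].sum() for _, i, (lo, hi)
                          in system_topology.iter_copies()])
            zc = _circular_mean_z(coms[cluster, 2], w[cluster], lz)
            z = z - zc + lz / 2.0
        z = np.mod(z, lz)
        hist, _ = np.histogram(z, bins=n_bins, range=(0.0, lz), weights=masses)
        total += hist
        n_frames += 1
    if n_frames == 0:
        raise AnalysisError("no frames given")
    lx, ly, _ = box.lengths
    density = total / n_frames / (lx * ly * bw) * AMU_PER_NM3_TO_MG_PER_ML
    centers = (np.arange(n_bins) + 0.5) * bw - lz / 2.0
    return DensityProfile(bin_centers=centers, density=density, bin_width=bw,
                          n_frames=n_frames, box=box)


def coexistence_densities(profile: DensityProfile, temperature: float,
                          dense_halfwidth: float = 5.0,
                          dilute_min_z: float = 50.0) -> CoexistencePoint:
    """Dense/dilute densities from windows of a centered slab profile.

    rho_H is the mean density over |z| < dense_halfwidth (5 nm for the
    HPS protocol, 10 nm for MOFF), rho_L over |z| > dilute_min_z.
    """
    lz = profile.box.lengths[2]
    if not (0 < dense_halfwidth < dilute_min_z < lz / 2.0):
        raise AnalysisError(
            "need 0 < dense_halfwidth < dilute_min_z < half the z extent")
    z = profile.bin_centers
    dense = np.abs(z) < dense_halfwidth
    dilute = np.abs(z) > dilute_min_z
    if not dense.any() or not dilute.any():
        raise AnalysisError("empty density window")
    return CoexistencePoint(temperature=temperature,
                            rho_dilute=float(profile.density[dilute].mean()),
                            rho_dense=float(profile.density[dense].mean()))


HPS_WINDOWS = {"dense_halfwidth": 5.0, "dilute_min_z": 50.0}
MOFF_WINDOWS = {"dense_halfwidth": 10.0, "dilute_min_z": 50.0}


# ---------------------------------------------------------------------------
# critical-point fit
# ---------------------------------------------------------------------------

def fit_critical_point(points: Sequence[CoexistencePoint],
                       beta: float = ISING_BETA) -> CriticalFit:
    """Least-squares fit of rho_H - rho_L = A (Tc - T)^beta, beta fixed.

    Only points with rho_H > rho_L (phase-separated) enter the fit;
    at least two distinct temperatures are required. Initial guesses:
    Tc = max T + 20 K, A from the coldest point.
    """
    pts = [p for p in points if p.rho_dense > p.rho_dilute]
    if len(pts) < 2:
        raise AnalysisError("need >= 2 phase-separated coexistence points")
    T = np.array([p.temperature for p in pts])
    drho = np.array([p.rho_dense - p.rho_dilute for p in pts])
    if np.ptp(T) == 0:
        raise AnalysisError("degenerate points: all at the same temperature")
    t_max = T.max()
    t_cold = T.min()
    tc0 = t_max + 20.0
    a0 = drho[np.argmin(T)] / (tc0 - t_cold) ** beta

    def resid(p):
        a, tc = p
        dt = np.maximum(tc - T, 1e-12)
        return a * dt ** beta - drho

    sol = least_squares(resid, x0=[a0, tc0],
                        bounds=([0.0, t_max + 1e-9], [np.inf, np.inf]))
    a, tc = sol.x
    return CriticalFit(Tc=float(tc), A=float(a), beta=beta,
                       residuals=resid(sol.x), points=list(pts))


def export_coexistence_table(points: Sequence[CoexistencePoint],
                             fit: Optional[CriticalFit], path) -> None:
    """Columnar text table of (T, rho_L, rho_H) plus the fitted Tc/A."""
    import pandas as pd
    df = pd.DataFrame([{"T_K": p.temperature, "rho_dilute_mg_mL": p.rho_dilute,
                        "rho_dense_mg_mL": p.rho_dense} for p in points])
    with open(path, "w") as fh:
        if fit is not None:
            fh.write(f"# Tc_K={fit.Tc:.4f} A={fit.A:.6g} beta={fit.beta}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.4f")


# ---------------------------------------------------------------------------
# persistence length
# ---------------------------------------------------------------------------

def bond_vector_correlation(frames: Sequence[np.ndarray],
                            chain_indices: Sequence[int],
                            max_sep: Optional[int] = None,
                            ) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean bond length b and C(n) = <u_i . u_{i+n}> over i and frames."""
    idx = np.asarray(chain_indices)
    if len(idx) < 3:
        raise AnalysisError("chain needs at least 3 beads")
    n_bonds = len(idx) - 1
    if max_sep is None:
        max_sep = n_bonds - 1
    max_sep = min(max_sep, n_bonds - 1)
    acc = np.zeros(max_sep + 1)
    cnt = np.zeros(max_sep + 1)
    try:  # fast path: equal-length frames stacked into (F, n, 3)
        stack = np.asarray(frames, dtype=float)[:, idx, :]
        assert stack.ndim == 3
    except (ValueError, AssertionError):
        stack = None
    if stack is not None:
        bonds = np.diff(stack, axis=1)
        norms = np.linalg.norm(bonds, axis=2)
        b_mean = float(norms.mean())
        u = bonds / norms[..., None]
        for n in range(max_sep + 1):
            dots = np.sum(u[:, : n_bonds - n] * u[:, n:], axis=2)
            acc[n] = dots.sum()
            cnt[n] = dots.size
    else:
        b_sum, b_n = 0.0, 0
        for pos in frames:
            bonds = np.diff(pos[idx], axis=0)
            norms = np.linalg.norm(bonds, axis=1)
            b_sum += norms.sum()
            b_n += len(norms)
            u = bonds / norms[:, None]
            for n in range(max_sep + 1):
                dots = np.sum(u[: n_bonds - n] * u[n:], axis=1)
                acc[n] += dots.sum()
                cnt[n] += len(dots)
        b_mean = b_sum / b_n
    corr = acc / cnt
    return b_mean, np.arange(max_sep + 1), corr


def persistence_length(frames: Sequence[np.ndarray],
                       chain_indices: Sequence[int],
                       fit_range: tuple[int, int] = (2, 20),
                       ) -> PersistenceFit:
    """Persistence length from the exponential decay of C(n).

    log C(n) is fit linearly over n in ``fit_range`` (inclusive) and
    lp = -b / slope with b the mean bond length. A rigid straight chain
    has C(n) = 1 everywhere and lp = inf. Non-positive C(n) inside the
    range shrink it with a warning.
    """
    b, seps, corr = bond_vector_correlation(frames, chain_indices,
                                            max_sep=fit_range[1])
    lo, hi = fit_range
    hi = min(hi, seps.max())
    sel = (seps >= lo) & (seps <= hi)
    bad = sel & (corr <= 0)
    if bad.any():
        first_bad = seps[bad].min()
        warnings.warn(f"C(n) <= 0 at n={first_bad}; shrinking fit range")
        sel &= seps < first_bad
    if sel.sum() < 2:
        raise AnalysisError("fewer than 2 usable C(n) values in fit range")
    x = seps[sel]
    y = np.log(corr[sel])
    # weight by C(n)*sqrt(samples): Var[log C] ~ Var[C]/C^2 and Var[C]
    # shrinks with the number of (i, i+n) pairs entering the average
    n_bonds = len(idx_arr) - 1 if (idx_arr := np.asarray(chain_indices)) is not None else 0
    w = corr[sel] * np.sqrt(np.maximum(n_bonds - x, 1))
    slope, _ = np.polyfit(x, y, 1, w=w)
    lp = np.inf if slope >= 0 else -b / slope
    return PersistenceFit(mean_bond_length=b, separations=seps,
                          correlation=corr, lp=float(lp),
                          fit_range=(int(lo), int(hi)), slope=float(slope))


def freely_rotating_chain(n_bonds: int, bond_length: float, theta_deg: float,
                          n_frames: int, seed: int) -> list[np.ndarray]:
    """Synthetic freely rotating chain: fixed bend angle, uniform azimuth.

    Closed form: C(n) = cos(theta)^n, lp = -b / ln(cos theta); used as the
    independent oracle for :func:`persistence_length`.
    """
    rng = np.random.default_rng(seed)
    ct = np.cos(np.deg2rad(theta_deg))
    st = np.sin(np.deg2rad(theta_deg))
    u = np.zeros((n_frames, n_bonds, 3))
    u[:, 0, 2] = 1.0
    for k in range(1, n_bonds):
        prev = u[:, k - 1]
        # orthonormal frame transverse to prev, vectorized over frames
        a = np.where(np.abs(prev[:, [0]]) > 0.9,
                     np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0]))
        e1 = np.cross(prev, a)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(prev, e1)
        phi = rng.uniform(0, 2 * np.pi, size=(n_frames, 1))
        u[:, k] = ct * prev + st * (np.cos(phi) * e1 + np.sin(phi) * e2)
    pos = np.concatenate([np.zeros((n_frames, 1, 3)),
                          np.cumsum(bond_length * u, axis=1)], axis=1)
    return list(pos)
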