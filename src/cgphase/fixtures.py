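"""Deterministic toy systems for tests, demos and the acceptance script.

Everything is generated programmatically from a seed -- no external files.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import AMU_PER_NM3_TO_MG_PER_ML
from . import topology as topo
from . import forcefields as ff
from .energetics import Box, SystemState
from .dynamics import draw_maxwell_boltzmann

FIXTURE_KINDS = ("harmonic_dimer", "toy_idp", "dsdna",
                 "slab_step_profile", "lj_cluster")

#: 30-residue mixed charge/hydropathy toy IDP used by energy/force tests.
TOY_IDP_SEQUENCE = "MKVLAEDRFGHQWYSTNCPIGKEDRAVLSF"


@dataclass(frozen=True)
class FixtureSpec:
    kind: str
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; "
                             f"choose from {FIXTURE_KINDS}")


def generate_fixture(spec: FixtureSpec):
    """(topology, assignment, state) for the requested toy system."""
    return _BUILDERS[spec.kind](spec.seed, **spec.params)


def _harmonic_dimer(seed: int, temperature: float = 300.0):
    top = topo.chain_topology("GG", "HPS")
    assignment = ff.load_hps("KR")
    rng = np.random.default_rng(seed)
    pos = np.array([[5.0, 5.0, 5.0], [5.0, 5.0, 5.0 + ff.BACKBONE_R0]])
    vel = draw_maxwell_boltzmann(top.masses, temperature, rng)
    return top, assignment, SystemState(pos, vel, Box.cubic(10.0))


def _toy_idp(seed: int, n_res: int = 30, box_length: float = 25.0):
    seq = (TOY_IDP_SEQUENCE * (n_res // len(TOY_IDP_SEQUENCE) + 1))[:n_res]
    top = topo.chain_topology(seq, "HPS")
    assignment = ff.load_hps("Urry")
    rng = np.random.default_rng(seed)
    # collapsed-ish random walk so that nonbonded terms are exercised
    steps = rng.normal(size=(n_res - 1, 3))
    steps /= np.linalg.norm(steps, axis=1)[:, None]
    pos = np.vstack([[0.0, 0.0, 0.0], np.cumsum(0.38 * steps, axis=0)])
    pos += box_length / 2.0
    vel = np.zeros_like(pos)
    return top, assignment, SystemState(pos, vel, Box.cubic(box_length))


def _dsdna(seed: int, n_bp: int = 20, rescaled: bool = False):
    top = topo.build_dsdna_topology(n_bp)
    assignment = ff.load_mrg_dna(rescaled=rescaled)
    pos = topo.ideal_dsdna_coordinates(n_bp)
    box_len = max(16.0, 2.2 * (0.34 * n_bp + 4.0))
    pos = pos - pos.mean(axis=0) + box_len / 2.0
    vel = np.zeros_like(pos)
    return top, assignment, SystemState(pos, vel, Box.cubic(box_len))


def _slab_step_profile(seed: int, rho_dense: float = 300.0,
                       rho_dilute: float = 10.0,
                       box_xy: float = 10.0, box_z: float = 120.0,
                       dense_halfwidth: float = 10.0):
    """Single-bead molecules placed to realize an exact two-density step.

    Densities are in mg/mL; the dense slab occupies |z - Lz/2| <
    dense_halfwidth. Bead counts are rounded, so the realized densities
    (recomputed from the counts) are stored in the assignment metadata.
    """
    mol = topo.chain_topology("A", "HPS")
    assignment = ff.load_hps("KR")
    mass = mol.masses[0]
    rng = np.random.default_rng(seed)
    v_dense = box_xy * box_xy * 2.0 * dense_halfwidth
    v_total = box_xy * box_xy * box_z
    v_dilute = v_total - v_dense
    n_dense = int(round(rho_dense / AMU_PER_NM3_TO_MG_PER_ML / mass * v_dense))
    n_dilute = int(round(rho_dilute / AMU_PER_NM3_TO_MG_PER_ML / mass * v_dilute))
    zc = box_z / 2.0
    pd = np.column_stack([
        rng.uniform(0, box_xy, n_dense), rng.uniform(0, box_xy, n_dense),
        rng.uniform(zc - dense_halfwidth, zc + dense_halfwidth, n_dense)])
    zlo = rng.uniform(0, v_dilute / (box_xy * box_xy), n_dilute)
    z_dil = np.where(zlo < zc - dense_halfwidth, zlo,
                     zlo + 2.0 * dense_halfwidth)
    pl = np.column_stack([
        rng.uniform(0, box_xy, n_dilute), rng.uniform(0, box_xy, n_dilute),
        z_dil])
    pos = np.vstack([pd, pl])
    system = topo.SystemTopology(entries=[(mol, n_dense + n_dilute)])
    assignment.metadata["realized_rho_dense"] = (
        n_dense * mass * AMU_PER_NM3_TO_MG_PER_ML / v_dense)
    assignment.metadata["realized_rho_dilute"] = (
        n_dilute * mass * AMU_PER_NM3_TO_MG_PER_ML / v_dilute)
    assignment.metadata["dense_halfwidth"] = dense_halfwidth
    state = SystemState(pos, np.zeros_like(pos),
                        Box((box_xy, box_xy, box_z)))
    return system, assignment, state


def _lj_cluster(seed: int, n: int = 8, temperature: float = 50.0):
    """Small alanine cluster near its lattice minimum, for NVE checks."""
    mol = topo.chain_topology("A", "HPS")
    system = topo.SystemTopology(entries=[(mol, n)])
    assignment = ff.load_hps("KR")
    rng = np.random.default_rng(seed)
    side = int(np.ceil(n ** (1 / 3)))
    spacing = 2 ** (1 / 6) * 0.504
    grid = np.array([(i, j, k) for i in range(side)
                     for j in range(side) for k in range(side)][:n], dtype=float)
    pos = grid * spacing + 5.0 + rng.normal(0, 0.01, (n, 3))
    vel = draw_maxwell_boltzmann(system.masses, temperature, rng)
    vel -= vel.mean(axis=0)  # no net drift
    return system, assignment, SystemState(pos, vel, Box.cubic(12.0))


def make_ideal_gas(n: int, box_length: float, temperature: float, seed: int):
    """Non-interacting single-bead molecules (MC-barostat closed-form oracle)."""
    mol = topo.chain_topology("A", "HPS")
    system = topo.SystemTopology(entries=[(mol, n)])
    assignment = ff.ForceFieldAssignment(
        provenance="ideal-gas",
        pair_tables=[ff.PairPotentialTable(
            form="excluded_volume", scope=frozenset("pdr"),
            sigma_by_type={"p:A": 0.5}, epsilon=0.0)],
        bonded=ff.BondedCoefficients({}),
        electrostatics=ff.ElectrostaticsSpec(temperature_K=temperature))
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, box_length, (n, 3))
    vel = draw_maxwell_boltzmann(system.masses, temperature, rng)
    return system, assignment, SystemState(pos, vel, Box.cubic(box_length))


_BUILDERS = {
    "harmonic_dimer": _harmonic_dimer,
    "toy_idp": _toy_idp,
    "dsdna": _dsdna,
    "slab_step_profile": _slab_step_profile,
    "lj_cluster": _lj_cluster,
}
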