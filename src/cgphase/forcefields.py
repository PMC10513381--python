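"""Force-field parameter sets for residue-level condensate models.

Four families are provided behind one :class:`ForceFieldAssignment`
surface:

* **HPS** -- one bead per amino acid, Ashbaugh-Hatch pair potential whose
  attraction scales with a per-residue hydropathy ``lambda``. Two scales
  are shipped (KR and Urry); the effective hydropathy of residue *i* is
  ``mu * lambda_i - delta`` with global scale ``mu`` and shift ``delta``
  (Urry optimum: mu = 1, delta = 0.08).
* **Mpipi** -- Wang-Frenkel pair potential with per-pair (epsilon, sigma)
  tables covering the 20 amino acids and the 4 RNA nucleotides.
* **MOFF** -- C-alpha model with a 20x20 contact-strength matrix
  ``epsilon_ij`` entering a soft tanh-switched contact potential on top of
  an r^-12 repulsion.
* **MRG-CG DNA** -- one bead per nucleotide with quartic polynomial bonds,
  angles and inter-strand "fan bonds", plus excluded volume.

All families share Debye-Hueckel implicit-ion electrostatics. Parameter
tables are shipped as plain-text CSV under ``cgphase/data``; the residue
registry and hydropathy scales are published constants, while the MOFF,
Mpipi and MRG-CG tables are synthetic stand-ins (see the ``_synthetic``
suffix and docs/methods.md) that preserve structure, units and symmetry
but not the published numbers.

Internal units: nm, ps, amu, kJ/mol, e, K. kcal-quoted tables are
converted exactly once on load.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .units import KB, COULOMB_KE, KCAL_TO_KJ

_DATA_DIR = Path(__file__).parent / "data"

#: Generic short-range repulsion/attraction energy scale, kJ/mol (0.2 kcal/mol).
HPS_EPSILON = 0.2 * KCAL_TO_KJ
#: Harmonic backbone bond constant, kJ/mol/nm^2, and rest length, nm.
BACKBONE_K = 8368.0
BACKBONE_R0 = 0.38

DEFAULT_DIELECTRIC = 80.0
DEFAULT_SALT_MM = 100.0
DEFAULT_TEMPERATURE = 300.0
DEFAULT_DH_CUTOFF = 3.5   # nm
DEFAULT_PAIR_CUTOFF = 2.0 # nm

#: Default rescaling applied to the DNA bonded strengths under implicit ions.
MRG_BONDED_RESCALE = 0.9

# MOFF contact-form shape parameters (package convention, see methods note)
MOFF_ETA = 10.0       # nm^-1, switching steepness
MOFF_R0_OFFSET = 0.25 # nm, switching midpoint = sigma_ij + offset

# Wang-Frenkel exponents and range
WF_NU = 1
WF_MU = 2
WF_RANGE_FACTOR = 3.0  # R = 3 sigma


class ForceFieldError(ValueError):
    pass


def _read(name: str, **kw) -> pd.DataFrame:
    return pd.read_csv(_DATA_DIR / name, comment="#", **kw)


def data_file_checksums() -> dict[str, str]:
    """sha256 of every shipped parameter file, for provenance logs."""
    out = {}
    for p in sorted(_DATA_DIR.glob("*.csv")):
        out[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


def debye_length(salt_mM: float, temperature_K: float = DEFAULT_TEMPERATURE,
                 dielectric: float = DEFAULT_DIELECTRIC) -> float:
    """Debye screening length kappa^-1 in nm for a 1:1 electrolyte.

    kappa^2 = 8 pi ke I / (eps_r kB T) with ke the Coulomb prefactor in
    kJ/mol nm and I the ion number density of one species in nm^-3.
    """
    if salt_mM <= 0 or temperature_K <= 0 or dielectric <= 0:
        raise ForceFieldError("salt, temperature and dielectric must be positive")
    ions_per_nm3 = salt_mM * 1e-3 * 0.602214076
    kappa_sq = 8.0 * np.pi * COULOMB_KE * ions_per_nm3 / (
        dielectric * KB * temperature_K)
    return float(1.0 / np.sqrt(kappa_sq))


@dataclass(frozen=True)
class ElectrostaticsSpec:
    """Debye-Hueckel implicit-ion electrostatics."""

    dielectric: float = DEFAULT_DIELECTRIC
    salt_mM: float = DEFAULT_SALT_MM
    temperature_K: float = DEFAULT_TEMPERATURE
    cutoff: float = DEFAULT_DH_CUTOFF

    @property
    def debye_length(self) -> float:
        return debye_length(self.salt_mM, self.temperature_K, self.dielectric)


@dataclass
class PairPotentialTable:
    """Per-type-pair nonbonded parameters for one functional form.

    ``scope`` is a set of bead-type prefixes (``p``, ``d``, ``r``) the
    table covers; ``cross_only`` restricts it to pairs whose two beads
    come from *different* prefixes (used by force-field combinations).
    """

    form: str  # ashbaugh_hatch | wang_frenkel | moff_contact | excluded_volume
    scope: frozenset[str]
    sigma_by_type: dict[str, float]
    epsilon: float = HPS_EPSILON               # scalar scale (AH / EV / MOFF rep)
    lambda_by_type: Optional[dict[str, float]] = None   # AH only (effective)
    epsilon_table: Optional[pd.DataFrame] = None        # WF / MOFF, type-keyed
    sigma_table: Optional[pd.DataFrame] = None          # WF, type-keyed
    cross_only: bool = False
    mu: float = 1.0     # AH global scale (bookkeeping)
    delta: float = 0.0  # AH global shift (bookkeeping)

    def covers(self, type_a: str, type_b: str) -> bool:
        pa, pb = type_a.split(":")[0], type_b.split(":")[0]
        if pa not in self.scope or pb not in self.scope:
            return False
        if self.cross_only and pa == pb:
            return False
        for t in (type_a, type_b):
            if self.form == "moff_contact":
                if t.split(":")[1] not in self.epsilon_table.index:
                    return False
            elif self.epsilon_table is not None:
                if t not in self.epsilon_table.index:
                    return False
            elif t not in self.sigma_by_type:
                return False
        return True

    def params(self, type_a: str, type_b: str) -> dict:
        """Scalar parameter record for one pair (used by the reference path)."""
        if not self.covers(type_a, type_b):
            raise ForceFieldError(f"pair ({type_a}, {type_b}) not covered")
        if self.form == "ashbaugh_hatch":
            sig = 0.5 * (self.sigma_by_type[type_a] + self.sigma_by_type[type_b])
            lam = 0.5 * (self.lambda_by_type[type_a] + self.lambda_by_type[type_b])
            return {"epsilon": self.epsilon, "sigma": sig, "lambda": lam}
        if self.form == "wang_frenkel":
            return {"epsilon": float(self.epsilon_table.loc[type_a, type_b]),
                    "sigma": float(self.sigma_table.loc[type_a, type_b])}
        if self.form == "moff_contact":
            ca, cb = type_a.split(":")[1], type_b.split(":")[1]
            sig = 0.5 * (self.sigma_by_type[type_a] + self.sigma_by_type[type_b])
            return {"epsilon_rep": self.epsilon, "sigma": sig,
                    "epsilon_ij": float(self.epsilon_table.loc[ca, cb]),
                    "eta": MOFF_ETA, "r0": sig + MOFF_R0_OFFSET}
        if self.form == "excluded_volume":
            sig = 0.5 * (self.sigma_by_type[type_a] + self.sigma_by_type[type_b])
            return {"epsilon": self.epsilon, "sigma": sig}
        raise ForceFieldError(f"unknown form {self.form!r}")


@dataclass
class BondedCoefficients:
    """coefficient_key -> record; energies already in kJ/mol."""

    records: dict[str, dict]

    def __getitem__(self, key: str) -> dict:
        try:
            return self.records[key]
        except KeyError:
            raise ForceFieldError(f"no bonded coefficients for key {key!r}") from None

    def __contains__(self, key: str) -> bool:
        return key in self.records


@dataclass
class ForceFieldAssignment:
    """A complete interaction specification for a topology."""

    provenance: str
    pair_tables: list[PairPotentialTable]
    bonded: BondedCoefficients
    electrostatics: ElectrostaticsSpec
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF
    exclusion_rule: str = "bonded-1-2-1-3"
    metadata: dict = field(default_factory=dict)

    def pair_table_for(self, type_a: str, type_b: str) -> Optional[PairPotentialTable]:
        for table in self.pair_tables:
            if table.covers(type_a, type_b):
                return table
        return None

    def validate_coverage(self, topology) -> None:
        """Every distinct bead-type pair of the topology must resolve."""
        types = sorted(set(topology.bead_types))
        for i, ta in enumerate(types):
            for tb in types[i:]:
                if self.pair_table_for(ta, tb) is None:
                    raise ForceFieldError(
                        f"no pair table covers ({ta}, {tb}) in {self.provenance}")
        for t in topology.bonded_terms if hasattr(topology, "bonded_terms") else []:
            if t.coefficient_key not in self.bonded:
                raise ForceFieldError(
                    f"unresolved coefficient key {t.coefficient_key!r}")

    @property
    def max_cutoff(self) -> float:
        return max(self.pair_cutoff, self.electrostatics.cutoff)


# ---------------------------------------------------------------------------
# loaders
# ---------------------------------------------------------------------------

def _aa_sigmas(prefix: str = "p") -> dict[str, float]:
    aa = _read("amino_acids.csv").set_index("code")
    return {f"{prefix}:{c}": float(aa.loc[c, "sigma_nm"]) for c in aa.index}


def _symmetrize_check(df: pd.DataFrame, name: str) -> pd.DataFrame:
    if not np.allclose(df.values, df.values.T):
        raise ForceFieldError(f"{name} table is not symmetric")
    return df


def load_hps(scale: str = "Urry", mu: float = 1.0,
             delta: Optional[float] = None,
             electrostatics: Optional[ElectrostaticsSpec] = None,
             ) -> ForceFieldAssignment:
    """HPS model with the KR or Urry hydropathy scale.

    The effective hydropathy of residue i is ``mu * lambda_i - delta``;
    ``delta`` defaults to the Urry-scale optimum 0.08 (0 for KR).
    """
    scale = scale.capitalize() if scale.lower() == "urry" else scale.upper()
    if scale not in ("KR", "Urry"):
        raise ForceFieldError(f"unknown hydropathy scale {scale!r}")
    if delta is None:
        delta = 0.08 if scale == "Urry" else 0.0
    col = "lambda_kr" if scale == "KR" else "lambda_urry"
    scales = _read("hydropathy_scales.csv").set_index("code")
    if scales[col].isna().any():
        raise ForceFieldError(f"incomplete lambda table for scale {scale}")
    lam = {f"p:{c}": mu * float(scales.loc[c, col]) - delta for c in scales.index}
    table = PairPotentialTable(
        form="ashbaugh_hatch", scope=frozenset("p"),
        sigma_by_type=_aa_sigmas(), epsilon=HPS_EPSILON,
        lambda_by_type=lam, mu=mu, delta=delta)
    bonded = BondedCoefficients({"backbone": {
        "style": "harmonic", "k": BACKBONE_K, "r0": BACKBONE_R0}})
    tag = f"HPS-{scale}(mu={mu:g},delta={delta:g})"
    return ForceFieldAssignment(
        provenance=tag, pair_tables=[table], bonded=bonded,
        electrostatics=electrostatics or ElectrostaticsSpec(),
        metadata={"scale": scale, "mu": mu, "delta": delta,
                  "checksums": data_file_checksums()})


def load_mpipi(electrostatics: Optional[ElectrostaticsSpec] = None,
               ) -> ForceFieldAssignment:
    """Mpipi-style Wang-Frenkel model for proteins and RNA.

    The shipped epsilon/sigma tables are synthetic stand-ins preserving
    the published tables' structure (24 types, symmetry, units).
    """
    eps = _symmetrize_check(_read("mpipi_epsilon_synthetic.csv", index_col=0),
                            "mpipi epsilon")
    sig = _symmetrize_check(_read("mpipi_sigma_synthetic.csv", index_col=0),
                            "mpipi sigma")
    if (sig.values <= 0).any():
        raise ForceFieldError("mpipi sigma table must be positive")
    sig_by_type = {t: float(sig.loc[t, t]) for t in sig.index}
    table = PairPotentialTable(
        form="wang_frenkel", scope=frozenset("pr"),
        sigma_by_type=sig_by_type, epsilon_table=eps, sigma_table=sig)
    bonded = BondedCoefficients({"backbone": {
        "style": "harmonic", "k": BACKBONE_K, "r0": BACKBONE_R0}})
    return ForceFieldAssignment(
        provenance="Mpipi(synthetic tables)", pair_tables=[table], bonded=bonded,
        electrostatics=electrostatics or ElectrostaticsSpec(),
        metadata={"checksums": data_file_checksums()})


def load_moff(electrostatics: Optional[ElectrostaticsSpec] = None,
              ) -> ForceFieldAssignment:
    """MOFF-style contact model (synthetic 20x20 epsilon_ij stand-in)."""
    eps = _symmetrize_check(_read("moff_contact_epsilon_synthetic.csv",
                                  index_col=0), "moff epsilon")
    table = PairPotentialTable(
        form="moff_contact", scope=frozenset("p"),
        sigma_by_type=_aa_sigmas(), epsilon=HPS_EPSILON, epsilon_table=eps)
    bonded = BondedCoefficients({"backbone": {
        "style": "harmonic", "k": BACKBONE_K, "r0": BACKBONE_R0}})
    return ForceFieldAssignment(
        provenance="MOFF(synthetic tables)", pair_tables=[table], bonded=bonded,
        electrostatics=electrostatics or ElectrostaticsSpec(),
        metadata={"checksums": data_file_checksums()})


def load_mrg_dna(rescaled: bool = False,
                 bonded_rescale: float = MRG_BONDED_RESCALE,
                 electrostatics: Optional[ElectrostaticsSpec] = None,
                 ) -> ForceFieldAssignment:
    """MRG-CG style one-bead DNA model with polynomial bonded terms.

    Tables are stored in kcal/mol and converted to kJ/mol exactly once
    here. With ``rescaled=True`` every bonded stiffness is multiplied by
    ``bonded_rescale`` (the implicit-ion correction); electrostatics are
    untouched.
    """
    factor = KCAL_TO_KJ * (bonded_rescale if rescaled else 1.0)
    bonds = _read("mrg_dna_bonds_synthetic.csv").set_index("key")
    angles = _read("mrg_dna_angles_synthetic.csv").set_index("key")
    fans = _read("mrg_dna_fan_bonds_synthetic.csv").set_index("key")
    records: dict[str, dict] = {}
    for key, row in bonds.iterrows():
        records[key] = {"style": "poly_bond", "r0": float(row["r0_nm"]),
                        "k": [factor * float(row[f"k{n}"]) for n in (2, 3, 4)]}
    for key, row in angles.iterrows():
        records[key] = {"style": "poly_angle",
                        "theta0_deg": float(row["theta0_deg"]),
                        "k": [factor * float(row[f"k{n}"]) for n in (2, 3, 4)]}
    for key, row in fans.iterrows():
        records[key] = {"style": "poly_bond", "r0": float(row["r0_nm"]),
                        "delta": int(row["delta"]),
                        "k": [factor * float(row[f"k{n}"]) for n in (2, 3, 4)]}
    nt = _read("nucleotides.csv").set_index(["kind", "code"])
    sig = {f"d:{c}": float(nt.loc[("dna", c), "sigma_nm"]) for c in "ACGT"}
    table = PairPotentialTable(form="excluded_volume", scope=frozenset("d"),
                               sigma_by_type=sig, epsilon=HPS_EPSILON)
    return ForceFieldAssignment(
        provenance=f"MRG-CG(synthetic tables, rescaled={rescaled})",
        pair_tables=[table], bonded=BondedCoefficients(records),
        electrostatics=electrostatics or ElectrostaticsSpec(),
        metadata={"rescaled": rescaled,
                  "bonded_rescale": bonded_rescale if rescaled else 1.0,
                  "fan_deltas": sorted(int(d) for d in fans["delta"]),
                  "checksums": data_file_checksums()})


def combine_cross(protein_ff: ForceFieldAssignment,
                  na_ff: ForceFieldAssignment) -> ForceFieldAssignment:
    """Merge a protein and a nucleic-acid assignment.

    Cross protein/nucleic-acid pairs not already covered by either input
    interact through excluded volume plus the shared Debye-Hueckel term
    only. Both inputs must agree on the electrostatics spec.
    """
    if protein_ff.electrostatics != na_ff.electrostatics:
        raise ForceFieldError("conflicting electrostatics specs in cross merge")
    sigmas: dict[str, float] = {}
    for ff in (protein_ff, na_ff):
        for t in ff.pair_tables:
            sigmas.update(t.sigma_by_type)
    cross = PairPotentialTable(
        form="excluded_volume", scope=frozenset("pdr"),
        sigma_by_type=sigmas, epsilon=HPS_EPSILON, cross_only=True)
    records = dict(protein_ff.bonded.records)
    records.update(na_ff.bonded.records)
    return ForceFieldAssignment(
        provenance=f"{protein_ff.provenance}+{na_ff.provenance}",
        pair_tables=protein_ff.pair_tables + na_ff.pair_tables + [cross],
        bonded=BondedCoefficients(records),
        electrostatics=protein_ff.electrostatics,
        pair_cutoff=max(protein_ff.pair_cutoff, na_ff.pair_cutoff),
        metadata={"cross": "excluded_volume+debye_hueckel",
                  "checksums": data_file_checksums()})
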