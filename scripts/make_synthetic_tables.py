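"""Generate the synthetic pair/bonded parameter tables shipped in
src/cgphase/data/*_synthetic.csv.

The published residue-pair matrices of the MOFF contact model and the
Mpipi model, and the MRG-CG DNA polynomial coefficients, are not freely
redistributable as machine-readable tables; the package therefore ships
deterministic, physically motivated stand-ins, clearly labelled
``_synthetic``. They preserve the structure the code relies on (symmetry,
coverage, units, sign conventions, equilibrium geometry of the ideal
B-form builder) but are NOT the published numbers; quantitative results
obtained with them are illustrative only. This script regenerates the
files verbatim.
"""

from pathlib import Path

import numpy as np
import pandas as pd

HERE = Path(__file__).resolve().parent
DATA = HERE.parent / "src" / "cgphase" / "data"

AA = list("ARNDCQEGHILKMFPSTWYV")
RNA = list("ACGU")

aa = pd.read_csv(DATA / "amino_acids.csv", comment="#").set_index("code")
scales = pd.read_csv(DATA / "hydropathy_scales.csv", comment="#").set_index("code")
nt = pd.read_csv(DATA / "nucleotides.csv", comment="#").set_index(["kind", "code"])

AROMATIC = set("FWY")
CATIONIC = set("RK")


def moff_epsilon():
    """20x20 contact strengths, kJ/mol: hydrophobic pairs attract (eps>0),
    like-charge pairs are made repulsive, everything clipped to O(1)."""
    rows = {}
    for a in AA:
        rows[a] = {}
        for b in AA:
            la, lb = scales.loc[a, "lambda_kr"], scales.loc[b, "lambda_kr"]
            qa, qb = aa.loc[a, "charge_moff_e"], aa.loc[b, "charge_moff_e"]
            eps = 2.5 * (la - 0.45) * (lb - 0.45) - 0.3 * qa * qb
            rows[a][b] = round(float(np.clip(eps, -1.5, 1.5)), 3)
    return pd.DataFrame(rows).loc[AA, AA].T


def mpipi_tables():
    """24x24 Wang-Frenkel (epsilon kJ/mol, sigma nm) for amino acids + RNA.

    Depths scale with the product of Urry hydropathies, boosted for
    aromatic-aromatic, cation-aromatic and nucleotide-involving pairs to
    mimic the pi-driven interaction hierarchy; sigmas are arithmetic means
    of the bead diameters.
    """
    types = [("p", c) for c in AA] + [("r", c) for c in RNA]

    def sigma_of(kind, c):
        return aa.loc[c, "sigma_nm"] if kind == "p" else nt.loc[("rna", c), "sigma_nm"]

    def lam_of(kind, c):
        return scales.loc[c, "lambda_urry"] if kind == "p" else 0.80

    eps = pd.DataFrame(index=[f"{k}:{c}" for k, c in types],
                       columns=[f"{k}:{c}" for k, c in types], dtype=float)
    sig = eps.copy()
    for ka, ca in types:
        for kb, cb in types:
            e = 0.15 + 0.9 * lam_of(ka, ca) * lam_of(kb, cb)
            if ka == "p" and kb == "p":
                if ca in AROMATIC and cb in AROMATIC:
                    e += 0.60
                elif (ca in CATIONIC and cb in AROMATIC) or \
                     (cb in CATIONIC and ca in AROMATIC):
                    e += 0.45
            elif ka == "r" and kb == "r":
                e += 0.30
            else:  # protein-RNA cross
                pc = ca if ka == "p" else cb
                if pc in AROMATIC:
                    e += 0.50
                elif pc in CATIONIC:
                    e += 0.40
            eps.loc[f"{ka}:{ca}", f"{kb}:{cb}"] = round(e, 3)
            sig.loc[f"{ka}:{ca}", f"{kb}:{cb}"] = round(
                0.5 * (sigma_of(ka, ca) + sigma_of(kb, cb)), 3)
    return eps, sig


def mrg_tables():
    """Polynomial bonded coefficients for the one-bead DNA model.

    U(x) = sum_n K_n (x - x0)^n, n = 2..4; bonds/fan bonds in
    kcal/mol/nm^n with x in nm, angles in kcal/mol/deg^n with x in
    degrees. Equilibrium values are taken from the ideal B-form geometry
    of the coordinate builder so that the minimized duplex stays helical;
    stiffnesses are chosen to give a bending persistence length of order
    tens of nm at physiological salt.
    """
    from cgphase.topology import (BDNA_RISE, BDNA_TWIST, BDNA_RADIUS,
                                  BDNA_STRAND_PHASE,
                                  ideal_dsdna_coordinates)

    coords = ideal_dsdna_coordinates(12)
    s1 = coords[:12]
    b0 = float(np.linalg.norm(s1[1] - s1[0]))
    v1, v2 = s1[0] - s1[1], s1[2] - s1[1]
    theta0 = float(np.degrees(np.arccos(
        np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))))

    bonds = pd.DataFrame([{"key": "mrg_bond", "r0_nm": round(b0, 6),
                           "k2": 60.0, "k3": -120.0, "k4": 600.0}])
    angles = pd.DataFrame([{"key": "mrg_angle", "theta0_deg": round(theta0, 4),
                            "k2": 0.015, "k3": 0.0, "k4": 2e-5}])

    # fan-bond equilibrium distances measured on the ideal helix
    n = 12
    s2 = coords[12:]
    rows = []
    k2_by_abs = {0: 8.0, 1: 4.0, 2: 2.0}
    i = 5  # interior nucleotide
    p = n - 1 - i
    for d in (-2, -1, 0, 1, 2):
        r = float(np.linalg.norm(s1[i] - s2[p + d]))
        rows.append({"key": f"fan_{d}", "delta": d, "r0_nm": round(r, 6),
                     "k2": k2_by_abs[abs(d)], "k3": 0.0, "k4": 30.0})
    fans = pd.DataFrame(rows)
    return bonds, angles, fans


HEADER = ("# SYNTHETIC stand-in parameter table generated by "
          "scripts/make_synthetic_tables.py -- not published force-field "
          "values; see docs/methods.md.\n")


def write(df: pd.DataFrame, name: str, index_label=None):
    path = DATA / name
    with open(path, "w") as fh:
        fh.write(HEADER)
        df.to_csv(fh, index=index_label is not None, index_label=index_label)
    print("wrote", path)


if __name__ == "__main__":
    write(moff_epsilon(), "moff_contact_epsilon_synthetic.csv", index_label="code")
    eps, sig = mpipi_tables()
    write(eps, "mpipi_epsilon_synthetic.csv", index_label="type")
    write(sig, "mpipi_sigma_synthetic.csv", index_label="type")
    bonds, angles, fans = mrg_tables()
    write(bonds, "mrg_dna_bonds_synthetic.csv")
    write(angles, "mrg_dna_angles_synthetic.csv")
    write(fans, "mrg_dna_fan_bonds_synthetic.csv")
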