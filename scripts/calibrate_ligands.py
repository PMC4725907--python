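"""Calibration of the ligand hydrophobicity ladder.

Runs pure-ligand self-assembly boxes (16 molecules, 127.3 A edge) for each
species and prints the steady-state monomer probability, which must order
aspirin > resveratrol > curcumin (the solubility ordering).  The shipped
``eps_scale`` values in the species library were chosen with this script;
re-run it after changing depths to confirm the ordering still holds.

Usage: python scripts/calibrate_ligands.py [--seeds 5] [--t-prod 8000]
"""

import argparse

import numpy as np

from dmdnano import analysis as an
from dmdnano import engine
from dmdnano import system_builder as sb
from dmdnano.system_builder import LIGAND_EPS_SCALE


def monomer_probability(ligand: str, seed: int, t_prod: float) -> float:
    state = sb.assemble_system(sb.SystemConfig(
        n_peptides=0, ligand_species=ligand, n_ligands=16,
        box_override=127.3, seed=seed))
    eq = engine.run(state, config=engine.RunConfig(
        t_max=1000.0, frame_dt=500.0, thermostat_rate=0.05, seed=seed))
    prod = engine.run(eq.final_state, config=engine.RunConfig(
        t_max=t_prod, frame_dt=500.0, thermostat_rate=1e-4,
        rescale_dt=25.0, seed=seed + 13))
    window = an.steady_state_window(prod)
    n_mono = 0
    n_frames = 0
    for fv in an.iter_frames(prod, window):
        labels = an.cluster_frame(an.contacts(fv)).labels
        sizes = np.bincount(labels)
        n_mono += int((sizes == 1).sum())
        n_frames += 1
    return n_mono / n_frames / 16


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=5)
    ap.add_argument("--t-prod", type=float, default=8000.0)
    args = ap.parse_args()
    results = {}
    for ligand in ("aspirin", "resveratrol", "curcumin"):
        probs = [monomer_probability(ligand, 61 + k, args.t_prod)
                 for k in range(args.seeds)]
        results[ligand] = float(np.mean(probs))
        print(f"{ligand:12s} eps_scale={LIGAND_EPS_SCALE[ligand]:.2f} "
              f"P(monomer) = {results[ligand]:.3f}  (per seed: "
              f"{np.round(probs, 2)})")
    ok = (results["aspirin"] > results["resveratrol"] > results["curcumin"])
    print("ordering aspirin > resveratrol > curcumin:",
          "OK" if ok else "VIOLATED")


if __name__ == "__main__":
    main()
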