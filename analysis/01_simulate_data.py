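"""Simulate the study's raw inputs: two quadruplicate pulldown datasets (CAA
and NEM analogues) sharing one planted interactor truth, an expected-binder
annotation list, and triplicate SPR equilibrium series at the measured
affinities of the branched-chain binding domain.

Writes MaxQuant-style protein tables, design tables, the truth table and SPR
series under results/data/.
"""

import argparse
from pathlib import Path

import numpy as np

from ubichain.io import write_design, write_protein_table
from ubichain.simulate import (
    SimConfig,
    simulate_steady_state,
    simulate_study,
    truth_to_frame,
)
from ubichain.spr import write_steady_state

#: steady-state affinities (uM) reported for the HIP1 ANTH domain against
#: each chain type; K48 chains sit above the 250 uM injection ceiling
PLANTED_KD_UM = {
    "Br_Ub3": 0.07,
    "K63_Ub3": 1.55,
    "K63_Ub2": 1.89,
    "mono_Ub": 196.73,
    "K48_Ub3": 66.2,
    "K48_Ub2": 137.47,
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    out = args.out_dir
    out.mkdir(parents=True, exist_ok=True)

    config = SimConfig(seed=args.seed)
    data, truth = simulate_study(config, ("CAA", "NEM"))
    for ds, (matrix, design, records) in data.items():
        write_protein_table(matrix, records, out / f"{ds}_proteinGroups.tsv")
        write_design(design, out / f"{ds}_design.tsv")
        n_missing = int(matrix.missing.sum())
        print(
            f"{ds}: {matrix.n_proteins} rows x {matrix.n_samples} samples, "
            f"{n_missing} missing cells "
            f"({n_missing / matrix.missing.size:.1%})"
        )
    truth_to_frame(truth).to_csv(out / "truth.tsv", sep="\t")

    planted = [
        p for p, c in zip(truth.protein_ids, truth.classes)
        if c not in ("background", "bead_binder")
    ]
    (out / "expected_ubbp.txt").write_text(
        "".join(f"{p}\tplanted\n" for p in planted)
    )
    print(f"annotation list: {len(planted)} planted interactors")

    spr_seeds = np.random.SeedSequence(args.seed).spawn(len(PLANTED_KD_UM))
    for (chain, kd), sub in zip(PLANTED_KD_UM.items(), spr_seeds):
        series = simulate_steady_state(kd, 100.0, noise_sd=0.5, n_rep=3, seed=sub)
        write_steady_state(series, out / f"spr_{chain}.tsv")
    print(f"SPR: triplicate series for {len(PLANTED_KD_UM)} chain types")


if __name__ == "__main__":
    main()
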