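"""Score the classification output of stage 02 against the planted truth from
stage 01: per-class sensitivity of the headline call and the overall
false-discovery proportion among linkage/length/branch calls.

Writes results/recovery.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from ubichain.pipeline import score_recovery
from ubichain.simulate import truth_from_frame


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
    parser.add_argument(
        "--interactome-dir", type=Path, default=Path("results/interactome")
    )
    parser.add_argument("--out", type=Path, default=Path("results/recovery.tsv"))
    args = parser.parse_args()

    truth = truth_from_frame(
        pd.read_csv(args.data_dir / "truth.tsv", sep="\t", index_col="protein_id")
    )
    calls = pd.read_csv(args.interactome_dir / "specificity_calls.tsv", sep="\t")
    sensitivity, fdp = score_recovery(calls, truth)

    rows = [
        {"metric": f"sensitivity_{cls}", "value": v} for cls, v in sensitivity.items()
    ]
    rows.append({"metric": "false_discovery_proportion", "value": fdp})
    table = pd.DataFrame(rows)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, sep="\t", index=False)
    for _, row in table.iterrows():
        print(f"{row['metric']:40s} {row['value']:.3f}")


if __name__ == "__main__":
    main()
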