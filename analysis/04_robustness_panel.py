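"""Knock-in / knock-down / knock-out robustness panel for the AI clone.

Scales seven signaling proteins by 10 / 0.1 / 0, re-equilibrates each
perturbed system, applies the hormone stimulus and reports the ratio of
the 72 h integrated marker concentration to the unperturbed run,
averaged over the ensemble (f > 1: perturbation raises the marker).
"""

import argparse

import pandas as pd

from kinens import workflow


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/workflow")
    args = ap.parse_args()

    workflow.robustness(args.outdir, args.seed)
    panel = pd.read_csv(f"{args.outdir}/robustness_panel.csv")
    wide = panel.pivot_table(index=["target", "label"], columns="marker", values="f_mean")
    print(wide.round(3))
    e4f = panel[(panel.target == "E4F") & (panel.factor == 10.0)]
    for row in e4f.itertuples():
        print(f"E4F knock-in: {row.marker} integrated level x{row.f_mean:.2f} wild type")


if __name__ == "__main__":
    main()
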