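#!/usr/bin/env python
"""Female-versus-male reaction-norm slopes (scatter against equality).

Computes mean-standardised slopes against temperature per experiment and
sex on a synthetic dataset and plots females against males; points on
the diagonal have sexually monomorphic plasticity.
"""

import argparse
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from sexplas.norms import slopes_table
from sexplas.synth import SynthConfig, generate

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    res = generate(SynthConfig(), seed=args.seed)
    tab, excluded = slopes_table(res.data)
    wide = tab.pivot_table(index=["study_id", "experiment_id"],
                           columns="sex", values="slope").reset_index()

    OUT.mkdir(exist_ok=True)
    tab.to_csv(OUT / "norm_slopes.csv", index=False)

    fig, ax = plt.subplots(figsize=(5, 5))
    lim = float(np.abs(wide[["F", "M"]]).max().max()) * 1.1
    ax.plot([-lim, lim], [-lim, lim], "k--", lw=0.8, label="equality")
    ax.scatter(wide["F"], wide["M"], s=18, alpha=0.7)
    ax.set_xlabel("female slope (per °C, mean-standardised)")
    ax.set_ylabel("male slope (per °C, mean-standardised)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "norm_slopes.png", dpi=150)

    r = np.corrcoef(wide["F"], wide["M"])[0, 1]
    print(f"{len(wide)} experiments, {len(excluded)} excluded")
    print(f"female-male slope correlation r = {r:.2f} "
          "(slopes cluster near the equality line, with male deficits "
          "reflecting the generating sex deviation)")
    print("wrote results/norm_slopes.csv and results/norm_slopes.png")


if __name__ == "__main__":
    main()
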