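#!/usr/bin/env python
"""Growth versus sexual dimorphism in plasticity, four-panel sweep.

Sweeps the three standard curve parameterisations (symmetric sexes;
female optimum faster + male variance higher; the mirror case) over
b_SD under both demographic modes, writes the tidy curve table and the
closed-form optima, and reports where female-biased plasticity helps.
"""

import argparse
from pathlib import Path

import pandas as pd

from sexplas.theory import figure1_curves, optimal_bsd, sweep_figure1

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--eta", type=float, default=0.05)
    args = ap.parse_args()

    curves = figure1_curves()
    tables, optima = [], []
    for dem in ("female_dominance", "codominance"):
        tab = sweep_figure1(curves, args.eta, dem)
        tab["demography"] = dem
        tables.append(tab)
        for cid, p in curves.items():
            optima.append({
                "demography": dem, "curve_id": cid,
                "b_sd_hat": optimal_bsd(p, args.eta, dem),
            })
    tab = pd.concat(tables, ignore_index=True)
    opt = pd.DataFrame(optima)

    OUT.mkdir(exist_ok=True)
    tab.to_csv(OUT / "fig1_curves.csv", index=False)
    opt.to_csv(OUT / "fig1_optima.csv", index=False)

    print(f"wrote {len(tab)} curve points -> results/fig1_curves.csv")
    print("\nClosed-form optimal b_SD by curve and demography:")
    print(opt.pivot(index="curve_id", columns="demography",
                    values="b_sd_hat").round(4).to_string())
    fd = opt[opt.demography == "female_dominance"]
    print(
        "\nUnder female demographic dominance every curve peaks at "
        f"female-biased plasticity (all optima > 0: {(fd.b_sd_hat > 0).all()}); "
        "under co-dominance the symmetric curve peaks at exactly 0 and only "
        "asymmetries in B or V_A move the optimum off zero."
    )


if __name__ == "__main__":
    main()
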