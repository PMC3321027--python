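"""Stage 4: life-history associations.

Regresses the seven life-history responses jointly on each composite FA index
(with education, cohort and area as covariates), reports per-response FA
coefficients and Pillai block tests, and tests whether the FA association
differs across cohorts or education levels.
"""

import argparse
from pathlib import Path

import pandas as pd

from handfa.associations import fit_multivariate_lm, interaction_tests


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=str, default="results")
    ap.add_argument("--bmi-squared", action="store_true",
                    help="add BMI^2 as an eighth response")
    args = ap.parse_args()

    out = Path(args.results)
    life = pd.read_csv(out / "life_history.csv")
    composites = pd.read_csv(out / "composites.csv", index_col="individual")

    per_resp, blocks = [], []
    for label in composites.columns:
        comp = composites[label]
        res = fit_multivariate_lm(life, comp, bmi_squared=args.bmi_squared)
        pr = res.per_response.copy()
        pr.insert(0, "index_type", label)
        per_resp.append(pr)
        bt = res.block_tests.copy()
        bt.insert(0, "index_type", label)
        bt["n_complete"] = res.n_complete
        blocks.append(bt)
        fa = res.block_tests.set_index("block").loc["fa"]
        print(f"{label}: FA block F_{int(fa.df1)},{int(fa.df2)} = {fa.F:.2f}, "
              f"p = {fa.p:.3f} (n = {res.n_complete})")
        for factor in ("cohort", "education"):
            it = interaction_tests(life, comp, factor)
            blocks.append(pd.DataFrame([{
                "index_type": label, "block": it.block, "pillai": it.pillai,
                "F": it.F, "df1": it.df1, "df2": it.df2, "p": it.p,
                "n_complete": res.n_complete,
            }]))
            print(f"  FA x {factor} interaction: p = {it.p:.3f}")

    pd.concat(per_resp, ignore_index=True).to_csv(
        out / "association_per_response.csv", index=False, float_format="%.10g")
    pd.concat(blocks, ignore_index=True).to_csv(
        out / "association_blocks.csv", index=False, float_format="%.10g")
    print(f"wrote {out / 'association_per_response.csv'} and "
          f"{out / 'association_blocks.csv'}")


if __name__ == "__main__":
    main()
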