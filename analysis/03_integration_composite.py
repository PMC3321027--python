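"""Stage 3: developmental integration and composite FA indices.

Correlates signed FA across the main length traits (digit lengths and palm
width), then builds the two per-individual composite indices: all 21 traits,
and only traits without significant directional asymmetry.
"""

import argparse
from pathlib import Path

import pandas as pd

from handfa.composite import composite_fa, select_non_da_traits
from handfa.fa_model import DATest, SignedFAEstimates
from handfa.integration import signed_fa_correlations
from handfa.pipeline import INTEGRATION_SUBSET


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results", type=str, default="results")
    ap.add_argument("--da-alpha", type=float, default=0.05)
    args = ap.parse_args()

    out = Path(args.results)
    signed_table = pd.read_csv(out / "signed_fa.csv")
    summary = pd.read_csv(out / "trait_summary.csv")
    estimates = SignedFAEstimates(table=signed_table)

    corr = signed_fa_correlations(estimates.values()[INTEGRATION_SUBSET])
    corr.r.to_csv(out / "integration_correlations.csv", float_format="%.10g")
    corr.p.to_csv(out / "integration_pvalues.csv", float_format="%.10g")
    print("signed-FA correlations (lower triangle):")
    print(corr.lower_triangle())

    da_map = {
        row.trait: DATest(chi2=row.da_chi2, p=row.da_p)
        for row in summary.itertuples()
    }
    non_da = select_non_da_traits(da_map, alpha=args.da_alpha)
    comp_all = composite_fa(estimates)
    composites = pd.DataFrame({"composite_all": comp_all.scores})
    if non_da:
        composites["composite_non_da"] = composite_fa(estimates, subset=non_da).scores
    composites.index.name = "individual"
    composites.to_csv(out / "composites.csv", float_format="%.10g")

    print(f"\n{len(non_da)} traits without significant DA: {non_da}")
    print(f"wrote {out / 'integration_correlations.csv'} and {out / 'composites.csv'}")


if __name__ == "__main__":
    main()
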