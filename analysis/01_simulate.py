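"""Stage 1: simulate the study cohort.

Generates a synthetic cohort matching the study design -- 209 post-menopausal
women, 21 hand distances per side, two digitization sessions -- plus the
questionnaire-style life-history table, and writes both to the results
directory for the downstream stages.
"""

import argparse
from pathlib import Path

from handfa.simulate import default_config, simulate_life_history, simulate_measurements


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=20120403)
    ap.add_argument("--n", type=int, default=209)
    ap.add_argument("--sessions", type=int, default=2)
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    cfg = default_config(n_individuals=args.n, n_sessions=args.sessions)
    measurements, truth = simulate_measurements(cfg, seed=args.seed)
    life = simulate_life_history(cfg, truth, seed=args.seed + 1)

    measurements.to_csv(out / "measurements.csv", index=False, float_format="%.10g")
    life.to_csv(out / "life_history.csv", index=False, float_format="%.10g")

    n_rows = len(measurements)
    print(f"simulated {args.n} individuals x {len(cfg.trait_ids)} traits x "
          f"2 sides x {args.sessions} sessions = {n_rows} measurements")
    print(f"wrote {out / 'measurements.csv'} and {out / 'life_history.csv'}")


if __name__ == "__main__":
    main()
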