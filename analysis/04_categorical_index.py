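"""Nonparametric check: categorical classification-error index per cell.

Classifies every response into one of the three prototype categories,
computes the baseline-subtracted attraction index toward the inducer's
category with a BCa bootstrap CI, and reports classification accuracy.
Confirms the parametric pattern without assuming the DoG shape. Writes
results/exp{1,2}/categorical.csv.
"""

import argparse
from pathlib import Path

from sdfaces import AnalysisConfig, read_trials, run_analysis

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-boot", type=int, default=2000)
    ap.add_argument("--seed", type=int, default=3)
    args = ap.parse_args()

    for exp in (1, 2):
        trials = read_trials(ROOT / "results" / "data" / f"exp{exp}_trials.csv")
        cfg = AnalysisConfig(n_boot=args.n_boot, seed=args.seed, variants=())
        rep = run_analysis(trials, exp, cfg, out_dir=ROOT / "results" / f"exp{exp}_categorical")
        c = rep.categorical
        print(f"\nexperiment {exp}:")
        cols = ["condition", "n", "index_pct", "ci_low", "ci_high",
                "significant", "accuracy_pct", "accuracy_sd"]
        print(c.loc[c["estimable"], cols].round(2).to_string(index=False))


if __name__ == "__main__":
    main()
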