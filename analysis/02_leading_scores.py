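"""Compute per-stimulus leading scores from the simulated motion-energy series.

Each 5-minute dyad recording is outlier-filtered (10 x SD rule), scaled to
unit SD, sliced into the two 10-s excerpts (90–100 s and 240–250 s), and
summarized by windowed lagged cross-correlations into green-leading,
white-leading and zero-lag synchrony.  Writes leading_scores.csv and prints
the group contrast that the generator built in: stronger green leading for
the strongly coupled (non-autistic-target) dyads.
"""

import argparse

import pandas as pd

from leadsync.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/run")
    args = ap.parse_args()

    cfg = PipelineConfig(out_dir=args.out_dir, seed=args.seed)
    run_pipeline(cfg, stages=("sync",))
    df = pd.read_csv(f"{args.out_dir}/leading_scores.csv")
    by_diag = df.groupby("diagnosis")[["green_leading", "white_leading", "zero_lag"]].mean()
    print(f"{len(df)} stimuli (2 excerpts x {df.dyad_id.nunique()} dyads)")
    print(by_diag.round(3).to_string())
    diff = by_diag.loc["non-autistic", "green_leading"] - by_diag.loc["autistic", "green_leading"]
    print(f"green-leading difference (non-autistic - autistic targets): {diff:.3f}")


if __name__ == "__main__":
    main()
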