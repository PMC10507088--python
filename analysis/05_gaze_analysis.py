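"""Preprocess the simulated webcam-gaze streams and compare groups.

Applies the quality filters (face-tracking > 50%, fixations >= 50 ms,
>= 400 valid samples per trial, > 50% of trials retained per participant),
computes fixation proportion on the target half and switches per 100 valid
samples, and runs Bayesian t-tests: target-half preference against 0.5 and
the autistic vs non-autistic target contrast on both metrics.
"""

import argparse
import json

from leadsync.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/run")
    args = ap.parse_args()

    cfg = PipelineConfig(out_dir=args.out_dir, seed=args.seed)
    run_pipeline(cfg, stages=("gaze",))
    with open(f"{args.out_dir}/gaze_report.json") as fh:
        r = json.load(fh)
    print(
        f"{r['n_participants']} participants retained "
        f"({r['n_excluded_participants']} excluded by the trial-retention rule)\n"
        f"  mean fixation proportion on target = {r['mean_fixation_proportion_target']:.3f}\n"
        f"  BF10 (proportion vs 0.5)           = {r['bf10_proportion_vs_half']:.3g}\n"
        f"  BF10 (diagnosis, fixation)         = {r['bf10_diagnosis_fixation_proportion_target']:.3g}\n"
        f"  BF10 (diagnosis, switches)         = {r['bf10_diagnosis_switches_per_100']:.3g}"
    )


if __name__ == "__main__":
    main()
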