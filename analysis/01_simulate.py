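"""Generate the synthetic study inputs.

Simulates 22 dyads of coupled motion-energy streams (5 min at 25 fps, the
autistic-target dyads with weaker green->white coupling), a 247-row
participant screening table with the study's exclusion composition in
expectation, and webcam-gaze streams for 40 raters, then writes them under
results/run/ for the downstream steps.
"""

import argparse

from leadsync.pipeline import PipelineConfig, run_pipeline


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", default="results/run")
    args = ap.parse_args()

    cfg = PipelineConfig(out_dir=args.out_dir, seed=args.seed)
    manifest = run_pipeline(cfg, stages=("simulate",))
    c = manifest["counts"]
    print(
        f"simulated {c['n_dyads']} dyads, {c['n_participants']} participants, "
        f"{c['n_gaze_trials']} gaze trials -> {args.out_dir}"
    )


if __name__ == "__main__":
    main()
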