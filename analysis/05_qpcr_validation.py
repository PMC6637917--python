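"""Quantify the simulated qPCR validation arm by the comparative ddCt method.

Uses the endogenous-control gene (hrdB) and the untreated condition as the
calibrator; reports per-condition relative transcript levels with the
across-replicate standard deviation.
"""

import argparse
from pathlib import Path

import pandas as pd

from topoclust import io, pipeline, qpcr


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--demo", type=Path, default=Path("results/demo"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = pipeline.PipelineConfig.from_yaml(args.demo / "config.yaml")
    ct = pd.read_csv(cfg.ct_table, sep="\t", comment="#")

    frames = []
    for target in cfg.qpcr_targets:
        levels = qpcr.ddct(ct, target, cfg.qpcr_reference, cfg.qpcr_calibrator)
        frames.append(levels)
        for row in levels.itertuples():
            print(f"{target} in {row.condition}: relative level "
                  f"{row.relative_level:.3f} (sd {row.sd_relative_level:.3f})")
    args.outdir.mkdir(parents=True, exist_ok=True)
    io.write_table(pd.concat(frames, ignore_index=True),
                   args.outdir / "qpcr_levels.tsv")


if __name__ == "__main__":
    main()
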