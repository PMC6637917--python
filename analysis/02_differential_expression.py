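"""Classify supercoiling-sensitive genes for every contrast.

Upper-quartile normalization, log2 fold changes (treatment over control),
Welch tests on log2(normalized+1), and the |log2FC| > 1.5 & p < 0.05 rule
with the exemption list applied — then a per-contrast summary of affected
counts, genome percentages, and condition specificity.
"""

import argparse
from pathlib import Path

import pandas as pd

from topoclust import diffexpr, io, pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--demo", type=Path, default=Path("results/demo"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    cfg = pipeline.PipelineConfig.from_yaml(args.demo / "config.yaml")
    cm = io.read_counts(cfg.counts, cfg.samples)
    exempt = pipeline._read_list(cfg.exempt_genes)
    genes = io.read_gff3(cfg.gff)

    args.outdir.mkdir(parents=True, exist_ok=True)
    classified = {}
    for treatment, control in cfg.contrasts:
        name = f"{treatment}_vs_{control}"
        diff = diffexpr.run_contrast(cm, (treatment, control), exempt)
        classified[name] = diff
        out = args.outdir / f"diff_{name}.tsv"
        io.write_table(diff.reset_index(), out)
        n_up = (diff["ssg_class"] == "up").sum()
        n_down = (diff["ssg_class"] == "down").sum()
        print(f"{name}: {n_up} up, {n_down} down of {len(diff)} genes -> {out}")

    summary = diffexpr.summarize_affected(classified, total_genes=len(genes))
    io.write_table(summary, args.outdir / "summary.tsv")
    print("\nper-contrast summary (counts, % of genome, % condition-specific):")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
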