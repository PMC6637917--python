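"""Call supercoiling-sensitive clusters and the hypersensitive region.

Maps each affected gene to its transcription unit's start position, scans
the chromosome in sliding windows, merges windows where more than 5% of
units are affected into cluster calls (per direction), scores recovery of
the planted clusters against the truth table, and locates the densest
30-kb interval of affected genes.
"""

import argparse
from pathlib import Path

import pandas as pd

from topoclust import clusters, io, pipeline


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--demo", type=Path, default=Path("results/demo"))
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    ap.add_argument("--contrast", default="topA_down_vs_control")
    args = ap.parse_args()
    cfg = pipeline.PipelineConfig.from_yaml(args.demo / "config.yaml")
    genes = io.read_gff3(cfg.gff)
    tus = io.read_operons(cfg.operons, genes)
    genome = io.read_fasta(cfg.genome)[0]
    diff = pd.read_csv(args.outdir / f"diff_{args.contrast}.tsv", sep="\t",
                       comment="#").set_index("locus_tag")
    affected = {t: c for t, c in diff["ssg_class"].items() if c in ("up", "down")}
    mapped = clusters.map_tss(affected, genes, tus)
    all_pos = clusters.tu_positions(genes, tus)

    scans, frames = [], []
    for direction in ("up", "down"):
        sub = mapped[mapped["direction"] == direction]
        scan = clusters.window_scan(sub["tss_position"].to_numpy(), all_pos,
                                    genome.length, cfg.window_size, cfg.window_step)
        scan.insert(0, "direction", direction)
        scans.append(scan)
        calls = clusters.call_clusters(
            scan, sub["tss_position"].to_numpy(), all_pos, direction,
            chrom_id=genome.chrom_id,
            threshold_percent=cfg.cluster_threshold_percent,
            member_ids=sub["tu_id"].tolist(),
        )
        frames.append(clusters.clusters_to_frame(calls))
        print(f"{direction}: {len(calls)} clusters above "
              f"{cfg.cluster_threshold_percent}% in {cfg.window_size // 1000}-kb windows")

    calls_df = pd.concat([f for f in frames if not f.empty], ignore_index=True)
    io.write_table(calls_df, args.outdir / "clusters.tsv")
    io.write_table(pd.concat(scans, ignore_index=True),
                   args.outdir / "window_scan.tsv")

    truth = pd.read_csv(args.demo / "truth_clusters.tsv", sep="\t", comment="#")
    up_calls = calls_df[calls_df["direction"] == "up"]
    recovered = 0
    for t in truth[truth["direction"] == "up"].itertuples():
        span = t.end - t.start + 1
        if any(min(t.end, c.end) - max(t.start, c.start) + 1 >= 0.5 * span
               for c in up_calls.itertuples()):
            recovered += 1
    print(f"planted up-cluster recovery: {recovered} of "
          f"{(truth['direction'] == 'up').sum()}")

    (lo, hi), n_aff, n_tot = clusters.densest_region(
        genes, list(affected), cfg.densest_width)
    print(f"densest {cfg.densest_width // 1000}-kb region {lo}..{hi}: "
          f"{n_aff} of {n_tot} genes supercoiling-sensitive")
    io.write_table(
        pd.DataFrame([{"start": lo, "end": hi, "n_affected": n_aff,
                       "n_total": n_tot}]),
        args.outdir / "densest_region.tsv")


if __name__ == "__main__":
    main()
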