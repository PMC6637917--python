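"""End-to-end orchestration: config, demo dataset, and the full run.

``make_demo`` writes a complete desk-scale synthetic dataset (genome,
annotation, operon table, counts, sample sheet, Ct table, truth tables and
a ready-to-run YAML config); ``run_all`` executes differential expression,
cluster scanning, promoter profiling and ddCt quantification in dependency
order and writes one TSV per stage. Runs are pure functions of
(config, seed): identical inputs give byte-identical outputs, which is why
output metadata headers carry parameters and content checksums but never
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__, clusters, diffexpr, io, promoters, qpcr, simulate

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclasses.dataclass
class PipelineConfig:
    """All paths, contrasts and thresholds for one pipeline run."""

    genome: str
    gff: str
    counts: str
    samples: str
    outdir: str
    operons: str | None = None
    exempt_genes: str | None = None
    induced_genes: str | None = None
    ct_table: str | None = None
    contrasts: Sequence[Sequence[str]] = ()  # (treatment, control) pairs
    log2fc_threshold: float = diffexpr.LOG2FC_THRESHOLD
    p_threshold: float = diffexpr.P_THRESHOLD
    cluster_threshold_percent: float = clusters.CLUSTER_THRESHOLD_PERCENT
    window_size: int = clusters.WINDOW_SIZE
    window_step: int = clusters.WINDOW_STEP
    denominator: str = "tu"  # "tu" or "gene"
    densest_width: int = 30_000
    upstream: int = promoters.UPSTREAM
    downstream: int = promoters.DOWNSTREAM
    at_window: int = promoters.AT_WINDOW
    at_step: int = 1
    positions: Sequence[int] = promoters.DEFAULT_POSITIONS
    n_controls: int = 66
    qpcr_targets: Sequence[str] = ()
    qpcr_reference: str = qpcr.REFERENCE_GENE
    qpcr_calibrator: str = "control"
    seed: int = 1

    def validate(self) -> None:
        if self.window_step > self.window_size:
            raise ConfigError("window step must not exceed window size")
        if self.window_step <= 0 or self.window_size <= 0:
            raise ConfigError("window geometry must be positive")
        if self.log2fc_threshold <= 0 or not 0 < self.p_threshold < 1:
            raise ConfigError("thresholds must be positive (p in (0,1))")
        if self.denominator not in ("tu", "gene"):
            raise ConfigError("denominator must be 'tu' or 'gene'")
        if not self.contrasts:
            raise ConfigError("at least one contrast is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:12]


def _header(seed: int, **params) -> list[str]:
    lines = [f"topoclust {__version__}", f"seed={seed}"]
    lines += [f"{k}={v}" for k, v in sorted(params.items())]
    return lines


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------


def make_demo(
    seed: int,
    outdir: str | Path,
    design: simulate.SyntheticDesign | None = None,
) -> dict[str, Path]:
    """Generate and write the desk-scale synthetic dataset plus its config.

    The demo plants: spatially clustered log2 effects under long-term
    topoisomerase perturbation (6 up-, 2 down-clusters on the 1 Mb
    chromosome), 66 'induced' genes carrying both an expression effect
    under the brief gyrase-inhibition condition and the AT/GC promoter
    architecture, a small set of exempted regulator-like genes with
    sub-threshold effects, and a zero/known-level Ct table. Truth tables
    for all planted effects are written alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if design is None:
        design = simulate.SyntheticDesign(seed=seed)
    genome = simulate.simulate_genome(design)
    genes, tus = simulate.simulate_annotation(design, genome)
    induced = simulate.choose_induced_genes(design, genes, genome)
    genome = simulate.plant_promoter_architecture(genome, genes, design, induced)

    # exempted regulator-like genes: significant but inside the +-1.5 band
    non_induced = [g.locus_tag for g in genes if g.locus_tag not in induced]
    exempt = sorted(
        np.random.default_rng(np.random.SeedSequence([design.seed, 97])).choice(
            non_induced, size=8, replace=False
        )
    )
    extra = {(t, design.induced_condition): design.induced_log2_effect for t in induced}
    for i, tag in enumerate(exempt):
        extra[(tag, "topA_down")] = 0.7 if i % 2 == 0 else -0.7

    cm, truth_genes = simulate.simulate_counts(design, genes, extra_effects=extra)
    truth_clusters = simulate.cluster_truth_table(design)

    levels = {
        "shc_like_gene": {"control": 1.0, "topA_down": 4.0, "topA_up": 1.5},
        "nap_like_gene": {"control": 1.0, "topA_down": 0.5, "topA_up": 0.9},
    }
    ct = simulate.simulate_ct_table(
        levels, n_replicates=3, noise_sd=design.ct_noise_sd, seed=design.seed
    )

    paths = {
        "genome": outdir / "genome.fa",
        "gff": outdir / "genes.gff3",
        "operons": outdir / "operons.tsv",
        "counts": outdir / "counts.tsv",
        "samples": outdir / "samples.tsv",
        "truth_genes": outdir / "truth_genes.tsv",
        "truth_clusters": outdir / "truth_clusters.tsv",
        "induced_genes": outdir / "induced_genes.txt",
        "exempt_genes": outdir / "exempt_genes.txt",
        "ct_table": outdir / "ct.tsv",
        "config": outdir / "config.yaml",
    }
    io.write_fasta([genome], paths["genome"])
    io.write_gff3(genes, paths["gff"])
    io.write_operons(tus, paths["operons"])
    io.write_counts(cm, paths["counts"], paths["samples"])
    io.write_table(truth_genes, paths["truth_genes"])
    io.write_table(truth_clusters, paths["truth_clusters"])
    paths["induced_genes"].write_text("\n".join(induced) + "\n")
    paths["exempt_genes"].write_text("\n".join(exempt) + "\n")
    io.write_table(ct, paths["ct_table"])

    # demo window geometry: the chromosome-scale 250/125 kb scan scaled by
    # the genome-length ratio so planted clusters stay separable at 1 Mb
    cfg = PipelineConfig(
        genome=str(paths["genome"]),
        gff=str(paths["gff"]),
        counts=str(paths["counts"]),
        samples=str(paths["samples"]),
        operons=str(paths["operons"]),
        exempt_genes=str(paths["exempt_genes"]),
        induced_genes=str(paths["induced_genes"]),
        ct_table=str(paths["ct_table"]),
        outdir=str(outdir / "results"),
        contrasts=[
            ["novobiocin", "control"],
            ["topA_down", "control"],
            ["topA_up", "control"],
        ],
        window_size=50_000,
        window_step=25_000,
        qpcr_targets=list(levels),
        seed=seed,
    )
    cfg.to_yaml(paths["config"])
    return paths


# ---------------------------------------------------------------------------
# full run
# ---------------------------------------------------------------------------


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage in dependency order; abort naming the failing stage."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    log_lines: list[str] = [f"topoclust {__version__} run, seed={config.seed}"]

    def stage(name):
        log_lines.append(f"[stage] {name}")
        log.info("stage: %s", name)

    try:
        stage("load-inputs")
        genome = io.read_fasta(config.genome)[0]
        genes = io.read_gff3(config.gff)
        tus = io.read_operons(config.operons, genes) if config.operons else []
        cm = io.read_counts(config.counts, config.samples)
        exempt = _read_list(config.exempt_genes)
        for key in ("genome", "gff", "counts", "samples"):
            log_lines.append(f"  input {key} sha256={_checksum(Path(getattr(config, key)))}")
        log_lines.append(f"  {len(genes)} genes, {len(tus)} operon TUs, "
                         f"{cm.counts.shape[1]} samples")
    except Exception as exc:  # noqa: BLE001 - stage-named abort
        raise RuntimeError(f"stage load-inputs failed: {exc}") from exc

    classified: dict[str, pd.DataFrame] = {}
    try:
        stage("diffexpr")
        for treatment, control in config.contrasts:
            name = f"{treatment}_vs_{control}"
            diff = diffexpr.run_contrast(
                cm, (treatment, control), exempt,
                log2fc_threshold=config.log2fc_threshold,
                p_threshold=config.p_threshold,
            )
            classified[name] = diff
            path = outdir / f"diff_{name}.tsv"
            io.write_table(
                diff.reset_index(), path,
                header=_header(config.seed, contrast=name,
                               method=diffexpr.SIGNIFICANCE_METHOD,
                               log2fc_threshold=config.log2fc_threshold,
                               p_threshold=config.p_threshold),
            )
            outputs[f"diff_{name}"] = path
            n_aff = int(diff["ssg_class"].isin(["up", "down"]).sum())
            log_lines.append(f"  {name}: {len(diff)} genes in, {n_aff} affected")
    except Exception as exc:
        raise RuntimeError(f"stage diffexpr failed: {exc}") from exc

    try:
        stage("cluster-scan")
        if config.denominator == "tu":
            all_pos = clusters.tu_positions(genes, tus)
        else:
            all_pos = clusters.gene_positions(genes)
        scan_frames, call_frames = [], []
        for name, diff in classified.items():
            affected = {
                t: c for t, c in diff["ssg_class"].items() if c in ("up", "down")
            }
            if not affected:
                continue
            mapped = clusters.map_tss(affected, genes, tus)
            for direction in ("up", "down"):
                sub = mapped[mapped["direction"] == direction]
                scan = clusters.window_scan(
                    sub["tss_position"].to_numpy(), all_pos, genome.length,
                    config.window_size, config.window_step,
                )
                scan.insert(0, "direction", direction)
                scan.insert(0, "contrast", name)
                scan_frames.append(scan)
                calls = clusters.call_clusters(
                    scan, sub["tss_position"].to_numpy(), all_pos, direction,
                    chrom_id=genome.chrom_id,
                    threshold_percent=config.cluster_threshold_percent,
                    member_ids=sub["tu_id"].tolist(),
                )
                cf = clusters.clusters_to_frame(calls)
                cf.insert(0, "contrast", name)
                call_frames.append(cf)
                log_lines.append(f"  {name}/{direction}: {len(calls)} clusters")
        call_frames = [f for f in call_frames if not f.empty]
        scan_all = pd.concat(scan_frames, ignore_index=True) if scan_frames else pd.DataFrame()
        calls_all = pd.concat(call_frames, ignore_index=True) if call_frames else pd.DataFrame()
        hdr = _header(config.seed, window_size=config.window_size,
                      step=config.window_step,
                      threshold=config.cluster_threshold_percent,
                      denominator=config.denominator)
        outputs["window_scan"] = outdir / "window_scan.tsv"
        io.write_table(scan_all, outputs["window_scan"], header=hdr)
        outputs["clusters"] = outdir / "clusters.tsv"
        io.write_table(calls_all, outputs["clusters"], header=hdr)

        # densest (hypersensitive) region over the union of affected genes
        union = sorted(
            {t for diff in classified.values()
             for t, c in diff["ssg_class"].items() if c in ("up", "down")}
        )
        if union:
            (lo, hi), n_aff, n_tot = clusters.densest_region(
                genes, union, config.densest_width
            )
            dense = pd.DataFrame(
                [{"start": lo, "end": hi, "n_affected": n_aff, "n_total": n_tot,
                  "width": config.densest_width}]
            )
            outputs["densest_region"] = outdir / "densest_region.tsv"
            io.write_table(dense, outputs["densest_region"], header=hdr)
            log_lines.append(f"  densest {config.densest_width}-bp region "
                             f"{lo}..{hi}: {n_aff}/{n_tot} genes affected")
    except Exception as exc:
        raise RuntimeError(f"stage cluster-scan failed: {exc}") from exc

    try:
        stage("promoter-composition")
        by_tag = {g.locus_tag: g for g in genes}
        induced_tags = _read_list(config.induced_genes)
        if not induced_tags:
            first = next(iter(classified))
            induced_tags = [
                t for t, c in classified[first]["ssg_class"].items() if c == "up"
            ]
        windows = promoters.extract_many(
            genome, [by_tag[t] for t in induced_tags if t in by_tag]
        )
        prof_ind = promoters.at_profile(windows, "induced")
        rnd_prom = promoters.sample_random_promoters(
            genes, genome, n=config.n_controls, seed=config.seed,
            exclude=induced_tags,
        )
        prof_rnd = promoters.at_profile(rnd_prom, "random_promoters")
        rnd_gen = promoters.sample_random_genomic(
            genome, n=config.n_controls, seed=config.seed
        )
        prof_gen = promoters.at_profile(rnd_gen, "random_genomic")
        profile_df = pd.DataFrame(
            {
                "position": prof_ind.positions,
                "induced": prof_ind.values,
                "random_promoters": prof_rnd.values,
                "random_genomic": prof_gen.values,
            }
        )
        hdr = _header(config.seed, upstream=config.upstream,
                      downstream=config.downstream, at_window=config.at_window,
                      n_controls=config.n_controls)
        outputs["at_profile"] = outdir / "at_profile.tsv"
        io.write_table(profile_df, outputs["at_profile"], header=hdr)
        tests = pd.concat(
            [
                promoters.compare_positions(prof_ind, prof_rnd, config.positions),
                promoters.compare_positions(prof_ind, prof_gen, config.positions),
            ],
            ignore_index=True,
        )
        outputs["position_tests"] = outdir / "position_tests.tsv"
        io.write_table(tests, outputs["position_tests"], header=hdr)
        log_lines.append(f"  {len(windows)} induced promoter windows profiled")
    except Exception as exc:
        raise RuntimeError(f"stage promoter-composition failed: {exc}") from exc

    try:
        stage("qpcr")
        if config.ct_table and config.qpcr_targets:
            ct = pd.read_csv(config.ct_table, sep="\t", comment="#")
            frames = [
                qpcr.ddct(ct, target, config.qpcr_reference, config.qpcr_calibrator)
                for target in config.qpcr_targets
            ]
            levels = pd.concat(frames, ignore_index=True)
            outputs["qpcr_levels"] = outdir / "qpcr_levels.tsv"
            io.write_table(
                levels, outputs["qpcr_levels"],
                header=_header(config.seed, reference=config.qpcr_reference,
                               calibrator=config.qpcr_calibrator),
            )
            log_lines.append(f"  {len(frames)} qPCR targets quantified")
    except Exception as exc:
        raise RuntimeError(f"stage qpcr failed: {exc}") from exc

    try:
        stage("summary")
        summary = diffexpr.summarize_affected(classified, total_genes=len(genes))
        outputs["summary"] = outdir / "summary.tsv"
        io.write_table(summary, outputs["summary"], header=_header(config.seed))
    except Exception as exc:
        raise RuntimeError(f"stage summary failed: {exc}") from exc

    outputs["run_log"] = outdir / "run_log.txt"
    outputs["run_log"].write_text("\n".join(log_lines) + "\n")
    return outputs


def _read_list(path: str | None) -> list[str]:
    if not path:
        return []
    return [
        line.strip() for line in Path(path).read_text().splitlines() if line.strip()
    ]
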