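"""Synthetic genomes, annotations, count matrices and Ct tables.

The generator emulates the data structure of a supercoiling-perturbation
transcriptome study on a GC-rich linear bacterial chromosome: one
chromosome at 72% GC; genes partly grouped into operons; replicated
negative-binomial counts per condition (untreated control, brief gyrase
inhibition, long-term topoisomerase-I depletion or mild induction);
spatially clustered planted log2 effects; and promoters of "induced" genes
carrying an AT-rich patch near the start codon plus a GC-rich block
100-200 bp further upstream. Truth tables of every planted effect are
always produced so downstream recovery can be scored.

Every generator is a pure function of its design; per-stage substreams are
derived from the single design seed so each stage reproduces independently.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneModel,
    GenomeSequence,
    ParameterError,
    TranscriptionUnit,
)

_BASES = np.array(["A", "C", "G", "T"])
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# substream labels, hashed into the SeedSequence so stages are independent
_STREAMS = {"genome": 0, "annotation": 1, "counts": 2, "promoters": 3, "ct": 4,
            "induced": 5}


@dataclasses.dataclass(frozen=True)
class PlantedCluster:
    """A chromosomal interval carrying a planted expression effect.

    Only a sampled ``fraction`` of the genes inside the interval receive the
    effect: real supercoiling-sensitive clusters mix affected and unaffected
    genes, and the >5% window rule must fire well below 100% penetrance.
    """

    start: int
    end: int
    direction: str  # "up" | "down"
    log2_effect: float = 3.0
    fraction: float = 0.5
    condition: str = "topA_down"

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ParameterError("cluster direction must be 'up' or 'down'")
        if not 0 < self.fraction <= 1:
            raise ParameterError("cluster fraction must be in (0, 1]")


@dataclasses.dataclass(frozen=True)
class PromoterArchitecture:
    """Composition planted on the 960-bp promoter window of induced genes.

    Positions are 1-based on the promoter window (750 bp upstream of the
    start codon + 210 bp downstream; the start codon begins at 751).
    Defaults put the AT boost just upstream of the start codon and the GC
    block ~300-450 bp upstream, so 100-bp profile windows starting at
    positions 660 and 340 fall entirely inside the planted intervals.
    """

    at_boost_percent: float = 3.0
    at_interval: tuple[int, int] = (610, 809)
    gc_block_boost_percent: float = 5.0
    gc_block_interval: tuple[int, int] = (290, 489)


_DEFAULT_CLUSTERS = (
    PlantedCluster(50_000, 110_000, "up"),
    PlantedCluster(180_000, 240_000, "up"),
    PlantedCluster(330_000, 390_000, "up"),
    PlantedCluster(520_000, 580_000, "up"),
    PlantedCluster(700_000, 760_000, "up"),
    PlantedCluster(860_000, 920_000, "up"),
    PlantedCluster(120_000, 160_000, "down", log2_effect=-3.0),
    PlantedCluster(620_000, 660_000, "down", log2_effect=-3.0),
)


@dataclasses.dataclass(frozen=True)
class SyntheticDesign:
    """Study-shaped defaults at desk scale: a 1 Mb chromosome, 900 genes.

    Full chromosome scale (8.7 Mb, ~7,900 genes) is reached by overriding
    ``genome_length`` and ``n_genes``; nothing else changes.
    """

    seed: int = 1
    genome_length: int = 1_000_000
    gc_fraction: float = 0.72
    n_genes: int = 900
    gene_length: int = 600
    operon_fraction: float = 0.4
    mean_operon_size: int = 3
    promoter_gap_fraction: float = 0.35  # fraction of genes with a >=960 bp upstream gap
    conditions: tuple[tuple[str, int], ...] = (
        ("control", 4),
        ("novobiocin", 3),
        ("topA_down", 4),
        ("topA_up", 3),
    )
    baseline_mean: float = 200.0
    nb_dispersion: float = 0.05
    planted_clusters: tuple[PlantedCluster, ...] = _DEFAULT_CLUSTERS
    n_induced_promoters: int = 66
    induced_log2_effect: float = 3.0
    induced_condition: str = "novobiocin"
    promoter_architecture: PromoterArchitecture = PromoterArchitecture()
    ct_noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ParameterError("gc_fraction must lie in [0, 1]")
        if self.baseline_mean < 0:
            raise ParameterError("baseline_mean must be non-negative")
        if self.nb_dispersion < 0:
            raise ParameterError("nb_dispersion must be non-negative")
        for name, n in self.conditions:
            if n < 2:
                raise ParameterError(
                    f"condition {name!r}: at least 2 replicates required"
                )
        for c in self.planted_clusters:
            if not (1 <= c.start <= c.end <= self.genome_length):
                raise ParameterError(
                    f"planted cluster {c.start}..{c.end} outside the genome"
                )

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, _STREAMS[stream]])
        )


# ---------------------------------------------------------------------------
# genome
# ---------------------------------------------------------------------------


def simulate_genome(design: SyntheticDesign, chrom_id: str = "chr") -> GenomeSequence:
    """I.i.d. bases with P(G)+P(C) = gc_fraction, G/C and A/T split equally."""
    gc, at = design.gc_fraction, 1.0 - design.gc_fraction
    p = np.array([at / 2, gc / 2, gc / 2, at / 2])
    rng = design.rng("genome")
    seq = rng.choice(_BASES, size=design.genome_length, p=p)
    return GenomeSequence(chrom_id, "".join(seq))


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------


def simulate_annotation(
    design: SyntheticDesign, genome: GenomeSequence
) -> tuple[list[GeneModel], list[TranscriptionUnit]]:
    """Tile non-overlapping genes with mixed gap sizes; group runs into TUs.

    A configurable fraction of inter-genic gaps is at least 960 bp so that
    promoter windows are extractable for enough genes; operons are runs of
    adjacent same-strand genes in transcription order.
    """
    rng = design.rng("annotation")
    n, L = design.n_genes, design.gene_length
    big_gap = 1000
    n_big = int(round(design.promoter_gap_fraction * n))
    n_small = n - n_big
    budget = genome.length - n * L - n_big * big_gap
    small_gap = budget // max(n_small, 1) if n_small else 0
    if budget < 0 or (n_small and small_gap < 20):
        raise ParameterError(
            f"genome of {genome.length} bp too short for {n} genes of {L} bp"
        )
    gaps = np.full(n, small_gap)
    big_idx = rng.choice(n, size=n_big, replace=False)
    gaps[big_idx] = big_gap

    # TU sizes first, strands per TU, then tile genes left to right
    sizes: list[int] = []
    total = 0
    while total < n:
        if design.operon_fraction > 0 and rng.random() < design.operon_fraction:
            size = 2 + rng.poisson(max(design.mean_operon_size - 2, 0))
        else:
            size = 1
        size = min(size, n - total)
        sizes.append(size)
        total += size
    strands = rng.choice(["+", "-"], size=len(sizes))

    genes: list[GeneModel] = []
    tus: list[TranscriptionUnit] = []
    pos = 1
    gi = 0
    for ti, (size, strand) in enumerate(zip(sizes, strands)):
        block: list[GeneModel] = []
        for _ in range(size):
            pos += gaps[gi]
            start = pos
            end = start + L - 1
            if end > genome.length:
                raise ParameterError("genome too short for requested genes")
            block.append(
                GeneModel(f"g{gi + 1:04d}", genome.chrom_id, start, end, strand)
            )
            pos = end + 1
            gi += 1
        genes.extend(block)
        order = block if strand == "+" else block[::-1]
        first = order[0]
        tss = first.start if strand == "+" else first.end
        tus.append(
            TranscriptionUnit(
                f"tu{ti + 1:04d}", tuple(g.locus_tag for g in order), strand, tss
            )
        )
    return genes, tus


def eligible_promoter_genes(
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
    upstream: int = 750,
    downstream: int = 210,
) -> list[str]:
    """Genes whose promoter window fits without running into a neighbour.

    The window needs ``upstream`` gene-free bases 5' of the start codon (so
    planted promoter composition never rewrites a neighbouring gene) plus
    ``downstream`` bases within the chromosome.
    """
    ordered = sorted(genes, key=lambda g: g.start)
    out = []
    for i, g in enumerate(ordered):
        if g.strand == "+":
            prev_end = ordered[i - 1].end if i > 0 else 0
            free = g.start - prev_end - 1
            ok = free >= upstream and g.start - upstream >= 1
            ok = ok and g.start + downstream - 1 <= genome.length
        else:
            next_start = ordered[i + 1].start if i + 1 < len(ordered) else genome.length + 1
            free = next_start - g.end - 1
            ok = free >= upstream and g.end + upstream <= genome.length
            ok = ok and g.end - downstream + 1 >= 1
        if ok:
            out.append(g.locus_tag)
    return out


def choose_induced_genes(
    design: SyntheticDesign,
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
) -> list[str]:
    """Sample the designated 'induced' genes among promoter-eligible ones."""
    eligible = eligible_promoter_genes(genes, genome)
    if len(eligible) < design.n_induced_promoters:
        raise ParameterError(
            f"only {len(eligible)} promoter-eligible genes; "
            f"{design.n_induced_promoters} induced genes requested"
        )
    rng = design.rng("induced")
    picked = rng.choice(len(eligible), size=design.n_induced_promoters, replace=False)
    return [eligible[i] for i in sorted(picked)]


# ---------------------------------------------------------------------------
# counts
# ---------------------------------------------------------------------------


def simulate_counts(
    design: SyntheticDesign,
    genes: Sequence[GeneModel],
    extra_effects: Mapping[tuple[str, str], float] | None = None,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Negative-binomial counts with planted, spatially clustered effects.

    Counts ~ NB(mean = baseline * 2**effect, dispersion = nb_dispersion);
    dispersion 0 degenerates to Poisson. ``extra_effects`` maps
    (locus_tag, condition) to additional planted log2 effects (used for the
    designated induced-promoter genes). Returns the matrix and a truth
    table with one row per planted (gene, condition) effect.
    """
    rng = design.rng("counts")
    tags = [g.locus_tag for g in genes]
    tag_index = {t: i for i, t in enumerate(tags)}
    conditions = [c for c, _ in design.conditions]
    effects = {c: np.zeros(len(genes)) for c in conditions}
    truth_rows: list[dict] = []

    for ci, cluster in enumerate(design.planted_clusters):
        if cluster.condition not in effects:
            raise ParameterError(
                f"planted cluster condition {cluster.condition!r} not in design"
            )
        inside = [
            g.locus_tag for g in genes if cluster.start <= g.start <= cluster.end
        ]
        k = int(round(cluster.fraction * len(inside)))
        hit = rng.choice(len(inside), size=k, replace=False) if inside else []
        for j in sorted(hit):
            tag = inside[j]
            effects[cluster.condition][tag_index[tag]] += cluster.log2_effect
            truth_rows.append(
                {
                    "locus_tag": tag,
                    "condition": cluster.condition,
                    "log2_effect": cluster.log2_effect,
                    "direction": cluster.direction,
                    "source": f"cluster_{ci + 1}",
                }
            )
    for (tag, cond), eff in (extra_effects or {}).items():
        if tag not in tag_index:
            raise ParameterError(f"extra effect on unknown gene {tag!r}")
        effects[cond][tag_index[tag]] += eff
        truth_rows.append(
            {
                "locus_tag": tag,
                "condition": cond,
                "log2_effect": eff,
                "direction": "up" if eff > 0 else "down",
                "source": "extra",
            }
        )

    cols, data, meta = [], [], []
    for cond, n_rep in design.conditions:
        mu = design.baseline_mean * np.exp2(effects[cond])
        for rep in range(1, n_rep + 1):
            if design.nb_dispersion == 0:
                draw = rng.poisson(mu)
            else:
                r = 1.0 / design.nb_dispersion
                p = r / (r + mu)
                draw = rng.negative_binomial(r, p)
            cols.append(f"{cond}_r{rep}")
            data.append(draw)
            meta.append({"sample": f"{cond}_r{rep}", "condition": cond, "replicate": rep})

    counts = pd.DataFrame(
        np.column_stack(data), index=pd.Index(tags, name="gene"), columns=cols
    )
    samples = pd.DataFrame(meta).set_index("sample")
    truth = pd.DataFrame(
        truth_rows,
        columns=["locus_tag", "condition", "log2_effect", "direction", "source"],
    )
    return CountMatrix(counts, samples), truth


def cluster_truth_table(design: SyntheticDesign) -> pd.DataFrame:
    """The planted cluster intervals, one row per cluster."""
    return pd.DataFrame(
        [
            {
                "cluster_id": f"cluster_{i + 1}",
                "start": c.start,
                "end": c.end,
                "direction": c.direction,
                "condition": c.condition,
                "log2_effect": c.log2_effect,
                "fraction": c.fraction,
            }
            for i, c in enumerate(design.planted_clusters)
        ]
    )


# ---------------------------------------------------------------------------
# promoter architecture
# ---------------------------------------------------------------------------


def _window_to_genomic(gene: GeneModel, w: int, upstream: int = 750) -> int:
    """Map a 1-based promoter-window position to a chromosome coordinate."""
    if gene.strand == "+":
        return gene.start - (upstream + 1) + w
    return gene.end + (upstream + 1) - w


def plant_promoter_architecture(
    genome: GenomeSequence,
    genes: Sequence[GeneModel],
    design: SyntheticDesign,
    induced: Sequence[str],
) -> GenomeSequence:
    """Rewrite the upstream windows of induced genes with boosted AT / GC.

    Bases inside the architecture's AT interval are redrawn with the AT
    probability raised by ``at_boost_percent`` points over the genome
    background; the GC block is raised likewise. Intervals with a zero
    boost are left untouched, so a zero/zero architecture is the identity.
    Everything outside the designated genes' windows is unchanged.
    """
    arch = design.promoter_architecture
    window_len = 960
    for lo, hi in (arch.at_interval, arch.gc_block_interval):
        if not (1 <= lo <= hi <= window_len):
            raise ParameterError(
                f"architecture interval {lo}..{hi} outside the {window_len}-bp window"
            )
    by_tag = {g.locus_tag: g for g in genes}
    seq = np.array(list(genome.sequence))
    rng = design.rng("promoters")
    at_bg = 1.0 - design.gc_fraction

    jobs = []
    if arch.at_boost_percent != 0:
        at_frac = min(1.0, at_bg + arch.at_boost_percent / 100.0)
        jobs.append((arch.at_interval, at_frac))
    if arch.gc_block_boost_percent != 0:
        gc_frac = min(1.0, design.gc_fraction + arch.gc_block_boost_percent / 100.0)
        jobs.append((arch.gc_block_interval, 1.0 - gc_frac))

    for tag in induced:
        gene = by_tag[tag]
        for (lo, hi), at_frac in jobs:
            p = np.array(
                [at_frac / 2, (1 - at_frac) / 2, (1 - at_frac) / 2, at_frac / 2]
            )
            draw = rng.choice(_BASES, size=hi - lo + 1, p=p)
            for k, w in enumerate(range(lo, hi + 1)):
                pos = _window_to_genomic(gene, w)
                if not (1 <= pos <= genome.length):
                    raise ParameterError(
                        f"promoter window of {tag} leaves the chromosome"
                    )
                base = draw[k]
                seq[pos - 1] = base if gene.strand == "+" else _COMPLEMENT[base]
    return GenomeSequence(genome.chrom_id, "".join(seq), topology=genome.topology)


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def simulate_ct_table(
    true_levels: Mapping[str, Mapping[str, float]],
    n_replicates: int = 3,
    reference_gene: str = "hrdB",
    reference_ct: float = 20.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct records for targets with known relative transcript levels.

    ``true_levels[target][condition]`` is the level relative to the
    calibrator condition (level 1). Ct_target = Ct_ref - log2(level) +
    Gaussian noise; the reference gene's Ct is constant within a sample, so
    an ideal ddCt analysis recovers the planted levels exactly at zero
    noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, _STREAMS["ct"]]))
    rows = []
    conditions = sorted({c for levels in true_levels.values() for c in levels})
    for cond in conditions:
        for rep in range(1, n_replicates + 1):
            sample = f"{cond}_r{rep}"
            rows.append(
                {"sample": sample, "condition": cond, "gene": reference_gene,
                 "replicate": rep, "ct": reference_ct}
            )
            for target, levels in true_levels.items():
                level = levels[cond]
                if level <= 0:
                    raise ParameterError(
                        f"true level for {target} in {cond} must be positive"
                    )
                ct = reference_ct - math.log2(level) + rng.normal(0.0, noise_sd)
                rows.append(
                    {"sample": sample, "condition": cond, "gene": target,
                     "replicate": rep, "ct": ct}
                )
    return pd.DataFrame(rows, columns=["sample", "condition", "gene", "replicate", "ct"])
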