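"""Readers, writers and shared containers for the formats the pipeline touches.

Every genomic interval in this package is 1-based and inclusive, matching
GFF3. Conversions to other conventions happen only at explicit output
boundaries, never inside analysis code.

Standard formats are parsed with established libraries (Biopython for
FASTA, gffutils for GFF3, pandas for TSV); the thin writers here exist so
that every reader/writer pair round-trips exactly.
"""

from __future__ import annotations

import dataclasses
import logging
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file violates the format contract (not merely a warning)."""


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class GenomeSequence:
    """One chromosome: id, uppercase A/C/G/T/N sequence, topology.

    The organisms this pipeline targets carry linear chromosomes, so
    topology defaults to "linear".
    """

    chrom_id: str
    sequence: str
    topology: str = "linear"

    def __post_init__(self) -> None:
        if self.topology not in ("linear", "circular"):
            raise ParameterError(f"unknown topology {self.topology!r}")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.chrom_id!r} contains invalid bases {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, end: int) -> str:
        """1-based inclusive substring."""
        if not (1 <= start <= end <= self.length):
            raise ParameterError(
                f"slice {start}..{end} outside 1..{self.length} of {self.chrom_id}"
            )
        return self.sequence[start - 1 : end]


@dataclasses.dataclass(frozen=True)
class GeneModel:
    """An annotated gene interval (1-based inclusive, never strand-swapped)."""

    locus_tag: str
    chrom_id: str
    start: int
    end: int
    strand: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise FormatError(
                f"gene {self.locus_tag}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.locus_tag}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Transcription/translation start coordinate on the chromosome."""
        return self.start if self.strand == "+" else self.end


@dataclasses.dataclass(frozen=True)
class TranscriptionUnit:
    """A run of co-transcribed genes; members are in transcription order.

    tss_position is the start of the first transcribed gene: its `start` on
    the plus strand, its `end` on the minus strand.
    """

    tu_id: str
    members: tuple[str, ...]
    strand: str
    tss_position: int

    def __post_init__(self) -> None:
        if not self.members:
            raise ParameterError(f"TU {self.tu_id} has no members")
        if self.strand not in ("+", "-"):
            raise ParameterError(f"TU {self.tu_id}: strand must be + or -")


@dataclasses.dataclass
class CountMatrix:
    """Raw integer counts, genes x samples, with sample metadata.

    ``counts`` is indexed by locus_tag with one column per sample id;
    ``samples`` is indexed by sample id with columns ``condition`` and
    ``replicate``.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene row {dup!r} in count matrix")
        if self.counts.isna().any().any():
            r, c = next(
                (r, c)
                for r in self.counts.index
                for c in self.counts.columns
                if pd.isna(self.counts.at[r, c])
            )
            raise FormatError(f"missing count at gene {r!r}, sample {c!r}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.round().astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.samples.index)
        if missing:
            raise FormatError(f"samples sheet lacks metadata for {sorted(missing)}")

    def condition_columns(self, condition: str) -> list[str]:
        cols = [
            s for s in self.counts.columns
            if self.samples.at[s, "condition"] == condition
        ]
        if not cols:
            raise ParameterError(f"no samples for condition {condition!r}")
        return cols


@dataclasses.dataclass
class ExpressionMatrix:
    """Normalized expression, same shape and metadata as a CountMatrix."""

    values: pd.DataFrame
    samples: pd.DataFrame
    normalization: str = "upper-quartile"

    def condition_columns(self, condition: str) -> list[str]:
        cols = [
            s for s in self.values.columns
            if self.samples.at[s, "condition"] == condition
        ]
        if not cols:
            raise ParameterError(f"no samples for condition {condition!r}")
        return cols


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path, topology: str = "linear") -> list[GenomeSequence]:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: empty or not FASTA")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"{path}: duplicate FASTA headers")
    return [
        GenomeSequence(r.id, str(r.seq).upper(), topology=topology) for r in records
    ]


def write_fasta(genomes: Iterable[GenomeSequence], path: str | Path) -> None:
    recs = [
        SeqRecord(Seq(g.sequence), id=g.chrom_id, description="") for g in genomes
    ]
    SeqIO.write(recs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene/CDS features carrying locus_tag attributes, sorted by start.

    Features without a locus_tag are skipped with a logged warning; an
    interval with end < start is a format error.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    seen: set[str] = set()
    for feat in db.all_features():
        if feat.featuretype not in ("gene", "CDS"):
            continue
        tags = feat.attributes.get("locus_tag")
        if not tags:
            log.warning("%s: %s feature at %s:%d-%d lacks locus_tag; skipped",
                        path, feat.featuretype, feat.seqid, feat.start, feat.end)
            continue
        tag = tags[0]
        if tag in seen:
            continue  # gene + its CDS: keep first occurrence
        if feat.end < feat.start:
            raise FormatError(f"{path}: feature {tag} has end < start")
        product = feat.attributes.get("product", [""])[0]
        genes.append(
            GeneModel(tag, feat.seqid, feat.start, feat.end, feat.strand, product)
        )
        seen.add(tag)
    genes.sort(key=lambda g: (g.chrom_id, g.start))
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.chrom_id}\ttopoclust\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# TSV: counts, sample sheet, operon table
# ---------------------------------------------------------------------------


def read_counts(counts_path: str | Path, samples_path: str | Path) -> CountMatrix:
    """Read a gene x sample count TSV plus its sample-sheet sidecar."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0, comment="#")
    samples = read_sample_sheet(samples_path)
    if counts.isna().any().any():
        na = counts.isna()
        r = counts.index[na.any(axis=1)][0]
        c = counts.columns[na.loc[r]][0]
        raise FormatError(f"{counts_path}: missing count at gene {r!r}, sample {c!r}")
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.number) or not np.allclose(arr, np.round(arr)):
        raise FormatError(f"{counts_path}: counts must be integers")
    if (arr < 0).any():
        raise FormatError(f"{counts_path}: counts must be non-negative")
    return CountMatrix(counts.astype(np.int64), samples)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "condition", "replicate"}
    if not required.issubset(samples.columns):
        raise FormatError(f"{path}: sample sheet needs columns {sorted(required)}")
    return samples.set_index("sample")


def write_counts(
    cm: CountMatrix, counts_path: str | Path, samples_path: str | Path,
    header: Sequence[str] = (),
) -> None:
    _write_tsv(cm.counts, counts_path, index_label="gene", header=header)
    _write_tsv(cm.samples.reset_index(), samples_path, index=False, header=header)


def read_operons(path: str | Path, genes: Sequence[GeneModel]) -> list[TranscriptionUnit]:
    """Read a TU table (tu_id, locus_tag, order) and derive TSS positions."""
    table = pd.read_csv(path, sep="\t", comment="#")
    required = {"tu_id", "locus_tag", "order"}
    if not required.issubset(table.columns):
        raise FormatError(f"{path}: operon table needs columns {sorted(required)}")
    by_tag = {g.locus_tag: g for g in genes}
    tus = []
    for tu_id, grp in table.groupby("tu_id", sort=False):
        members = tuple(grp.sort_values("order")["locus_tag"])
        missing = [m for m in members if m not in by_tag]
        if missing:
            raise FormatError(f"{path}: TU {tu_id} members absent from annotation: {missing}")
        strands = {by_tag[m].strand for m in members}
        if len(strands) != 1:
            raise FormatError(f"{path}: TU {tu_id} mixes strands")
        strand = strands.pop()
        first = by_tag[members[0]]
        tss = first.start if strand == "+" else first.end
        tus.append(TranscriptionUnit(str(tu_id), members, strand, tss))
    return tus


def write_operons(tus: Iterable[TranscriptionUnit], path: str | Path) -> None:
    rows = [
        {"tu_id": tu.tu_id, "locus_tag": m, "order": i + 1}
        for tu in tus
        for i, m in enumerate(tu.members)
    ]
    _write_tsv(pd.DataFrame(rows), path, index=False)


def complete_tus(
    genes: Sequence[GeneModel], tus: Sequence[TranscriptionUnit]
) -> list[TranscriptionUnit]:
    """Add a singleton TU for every gene not covered by the given TUs."""
    covered = {m for tu in tus for m in tu.members}
    out = list(tus)
    for g in genes:
        if g.locus_tag not in covered:
            out.append(
                TranscriptionUnit(f"tu_{g.locus_tag}", (g.locus_tag,), g.strand, g.tss)
            )
    return out


# ---------------------------------------------------------------------------
# generic TSV with metadata header
# ---------------------------------------------------------------------------


def _write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    index: bool = True,
    index_label: str | None = None,
    header: Sequence[str] = (),
) -> None:
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label,
                  float_format="%.6g", lineterminator="\n")


def write_table(df: pd.DataFrame, path: str | Path, header: Sequence[str] = (),
                index: bool = False) -> None:
    """Write a result table as TSV with '#'-prefixed metadata lines."""
    _write_tsv(df, path, index=index, header=header)
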