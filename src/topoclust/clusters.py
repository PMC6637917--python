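"""Sliding-window detection of supercoiling-sensitive gene clusters.

Affected genes are mapped to the transcription start position of their
transcription unit (the first gene of a regulated operon), the percentage
of affected units is computed in windows of 250 kbp moved in 125 kbp steps
along the chromosome, and runs of windows above a 5% threshold are merged
into cluster calls, separately for up- and down-regulated genes. A
companion operation locates the densest fixed-width interval of affected
genes — the supercoiling-hypersensitive region.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneModel, ParameterError, TranscriptionUnit, complete_tus

log = logging.getLogger(__name__)

WINDOW_SIZE = 250_000
WINDOW_STEP = 125_000
CLUSTER_THRESHOLD_PERCENT = 5.0


@dataclasses.dataclass(frozen=True)
class ClusterCall:
    """A merged run of qualifying windows, with its member affected TUs."""

    chrom_id: str
    start: int
    end: int
    direction: str
    peak_window_percent: float
    n_affected: int
    n_total: int
    members: tuple[str, ...]


# ---------------------------------------------------------------------------
# TSS mapping
# ---------------------------------------------------------------------------


def map_tss(
    affected: Mapping[str, str],
    genes: Sequence[GeneModel],
    tus: Sequence[TranscriptionUnit] = (),
) -> pd.DataFrame:
    """One TSS position per affected transcription unit, per direction.

    ``affected`` maps locus_tag -> direction ("up"/"down"). A TU is
    affected in a direction if any member gene is; two affected members of
    one TU yield a single position. Genes without a TU assignment are
    treated as singleton TUs.
    """
    known = {g.locus_tag for g in genes}
    missing = sorted(set(affected) - known)
    if missing:
        raise ParameterError(f"affected genes absent from annotation: {missing}")
    full = complete_tus(genes, tus)
    rows = []
    for tu in full:
        dirs = {affected[m] for m in tu.members if m in affected}
        for d in sorted(dirs):
            rows.append(
                {"tu_id": tu.tu_id, "tss_position": tu.tss_position, "direction": d}
            )
    return pd.DataFrame(rows, columns=["tu_id", "tss_position", "direction"])


def tu_positions(
    genes: Sequence[GeneModel], tus: Sequence[TranscriptionUnit] = ()
) -> np.ndarray:
    """TSS positions of all transcription units (singletons included)."""
    return np.array([tu.tss_position for tu in complete_tus(genes, tus)])


def gene_positions(genes: Sequence[GeneModel]) -> np.ndarray:
    """Per-gene start positions (strand-aware), the per-gene denominator."""
    return np.array([g.tss for g in genes])


# ---------------------------------------------------------------------------
# window scan
# ---------------------------------------------------------------------------


def window_scan(
    affected_positions: Sequence[int] | np.ndarray,
    all_positions: Sequence[int] | np.ndarray,
    genome_length: int,
    window_size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
) -> pd.DataFrame:
    """Percent of affected units per sliding window along the chromosome.

    Windows start at 1, 1+step, 1+2*step, ...; the last windows are clipped
    at the chromosome end. A window with no unit at all has an undefined
    percent (NaN). The ``midpoint`` column is the plotting coordinate.
    """
    if not (0 < step <= window_size):
        raise ParameterError("need window_size >= step > 0")
    if genome_length < window_size:
        log.warning(
            "genome (%d bp) shorter than the window (%d bp): single clipped window",
            genome_length, window_size,
        )
    aff = np.sort(np.asarray(affected_positions, dtype=np.int64))
    tot = np.sort(np.asarray(all_positions, dtype=np.int64))
    starts = np.arange(1, genome_length + 1, step, dtype=np.int64)
    rows = []
    for w in starts:
        end = min(w + window_size - 1, genome_length)
        n_tot = int(np.searchsorted(tot, end, "right") - np.searchsorted(tot, w, "left"))
        n_aff = int(np.searchsorted(aff, end, "right") - np.searchsorted(aff, w, "left"))
        rows.append(
            {
                "window_start": int(w),
                "window_end": int(end),
                "midpoint": (int(w) + int(end)) / 2.0,
                "n_total": n_tot,
                "n_affected": n_aff,
                "percent": 100.0 * n_aff / n_tot if n_tot > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def call_clusters(
    scan: pd.DataFrame,
    affected_positions: Sequence[int] | np.ndarray,
    all_positions: Sequence[int] | np.ndarray,
    direction: str,
    chrom_id: str = "chr",
    threshold_percent: float = CLUSTER_THRESHOLD_PERCENT,
    member_ids: Sequence[str] | None = None,
) -> list[ClusterCall]:
    """Merge qualifying windows (percent strictly above threshold).

    Overlapping or abutting qualifying windows become one call spanning
    their union; members are the affected units whose TSS falls in the
    span; the peak is the highest merged window percent. Windows whose
    percent is undefined never qualify.
    """
    aff = np.asarray(affected_positions, dtype=np.int64)
    tot = np.asarray(all_positions, dtype=np.int64)
    ids = list(member_ids) if member_ids is not None else [str(p) for p in aff]
    if len(ids) != len(aff):
        raise ParameterError("member_ids must align with affected_positions")
    qual = scan[scan["percent"].notna() & (scan["percent"] > threshold_percent)]
    calls: list[ClusterCall] = []
    current: dict | None = None
    for _, row in qual.sort_values("window_start").iterrows():
        w, e, pct = int(row["window_start"]), int(row["window_end"]), row["percent"]
        if current is not None and w <= current["end"] + 1:
            current["end"] = max(current["end"], e)
            current["peak"] = max(current["peak"], pct)
        else:
            if current is not None:
                calls.append(_finalize(current, aff, tot, ids, chrom_id, direction))
            current = {"start": w, "end": e, "peak": pct}
    if current is not None:
        calls.append(_finalize(current, aff, tot, ids, chrom_id, direction))
    return calls


def _finalize(span, aff, tot, ids, chrom_id, direction) -> ClusterCall:
    inside = (aff >= span["start"]) & (aff <= span["end"])
    n_total = int(((tot >= span["start"]) & (tot <= span["end"])).sum())
    members = tuple(i for i, m in zip(ids, inside) if m)
    return ClusterCall(
        chrom_id=chrom_id,
        start=span["start"],
        end=span["end"],
        direction=direction,
        peak_window_percent=float(span["peak"]),
        n_affected=int(inside.sum()),
        n_total=n_total,
        members=members,
    )


def clusters_to_frame(calls: Iterable[ClusterCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom_id": c.chrom_id,
                "start": c.start,
                "end": c.end,
                "direction": c.direction,
                "peak_window_percent": round(c.peak_window_percent, 3),
                "n_affected": c.n_affected,
                "n_total": c.n_total,
                "members": ",".join(c.members),
            }
            for c in calls
        ],
        columns=[
            "chrom_id", "start", "end", "direction", "peak_window_percent",
            "n_affected", "n_total", "members",
        ],
    )


# ---------------------------------------------------------------------------
# densest region
# ---------------------------------------------------------------------------


def densest_region(
    genes: Sequence[GeneModel],
    affected: Iterable[str],
    width: int = 30_000,
) -> tuple[tuple[int, int], int, int]:
    """The width-bp interval, anchored at gene starts, with most affected genes.

    Genes are assigned by start coordinate. Ties are broken by the larger
    affected/total ratio inside the interval, then by the leftmost start.
    Returns ((start, end), n_affected, n_total).
    """
    flagged = set(affected)
    if not flagged:
        raise ParameterError("densest_region needs at least one affected gene")
    ordered = sorted(genes, key=lambda g: g.start)
    starts = np.array([g.start for g in ordered])
    is_aff = np.array([g.locus_tag in flagged for g in ordered])
    best = None
    for anchor in starts:
        lo, hi = anchor, anchor + width - 1
        sel = (starts >= lo) & (starts <= hi)
        n_tot = int(sel.sum())
        n_aff = int(is_aff[sel].sum())
        ratio = n_aff / n_tot if n_tot else 0.0
        key = (n_aff, ratio, -anchor)
        if best is None or key > best[0]:
            best = (key, (int(lo), int(hi)), n_aff, n_tot)
    return best[1], best[2], best[3]
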