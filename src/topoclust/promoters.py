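"""Promoter AT-content profiling against random controls.

For each gene a 960-bp window is extracted — 750 bp upstream of the
translation start codon and 210 bp downstream, read 5'->3' on the coding
strand — and AT% is computed in 100-bp windows slid 1 bp at a time, each
value plotted at the window's first base. The mean profile of a gene set
(e.g. relaxation-induced genes) is compared against randomly sampled
promoters or random genomic sequence, and the difference at named
positions is tested with Shapiro-Wilk normality checks and a two-sample
t-test. Unknown bases (N) count as non-AT so every window's denominator
stays exactly 100.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

from .io import FormatError, GeneModel, GenomeSequence, ParameterError
from .simulate import eligible_promoter_genes

log = logging.getLogger(__name__)

UPSTREAM = 750
DOWNSTREAM = 210
WINDOW_LENGTH = UPSTREAM + DOWNSTREAM  # 960
AT_WINDOW = 100
DEFAULT_POSITIONS = (340, 660)


@dataclasses.dataclass(frozen=True)
class PromoterWindow:
    """A 960-bp promoter sequence; the start codon begins at position 751."""

    locus_tag: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != WINDOW_LENGTH:
            raise FormatError(
                f"{self.locus_tag}: promoter window must be {WINDOW_LENGTH} bp, "
                f"got {len(self.sequence)}"
            )


@dataclasses.dataclass
class ATProfile:
    """Windowed AT% profile of a sequence set.

    ``values`` is the across-sequence mean at each window start (length
    861 for 960-bp inputs); ``per_sequence`` retains the full matrix
    (n_sequences x positions) so positions can be tested statistically.
    """

    set_label: str
    n_sequences: int
    positions: np.ndarray  # 1-based window-start indices
    values: np.ndarray
    per_sequence: np.ndarray

    def at_position(self, position: int) -> np.ndarray:
        """Per-sequence AT% of the window starting at ``position`` (1-based)."""
        idx = np.nonzero(self.positions == position)[0]
        if idx.size == 0:
            raise ParameterError(f"position {position} not in profile")
        return self.per_sequence[:, idx[0]]


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------


def extract_promoter_window(
    genome: GenomeSequence, gene: GeneModel,
    upstream: int = UPSTREAM, downstream: int = DOWNSTREAM,
) -> PromoterWindow:
    """Strand-aware extraction: the returned string reads 5'->3'.

    Plus strand: bases [start-upstream, start+downstream-1]. Minus strand:
    the reverse complement of [end-downstream+1, end+upstream]. In both
    cases the start codon begins at position upstream+1 (751 by default).
    """
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.start + downstream - 1
        if lo < 1 or hi > genome.length:
            raise ParameterError(f"{gene.locus_tag}: insufficient flank")
        seq = genome.slice(lo, hi)
    else:
        lo, hi = gene.end - downstream + 1, gene.end + upstream
        if lo < 1 or hi > genome.length:
            raise ParameterError(f"{gene.locus_tag}: insufficient flank")
        seq = str(Seq(genome.slice(lo, hi)).reverse_complement())
    return PromoterWindow(gene.locus_tag, seq)


def extract_many(
    genome: GenomeSequence, genes: Iterable[GeneModel]
) -> list[PromoterWindow]:
    """Extract windows for all genes with sufficient flank; skip the rest."""
    out = []
    for g in genes:
        try:
            out.append(extract_promoter_window(genome, g))
        except ParameterError:
            log.warning("%s: insufficient flank for a promoter window; skipped",
                        g.locus_tag)
    return out


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------


def at_profile(
    windows: Sequence[PromoterWindow],
    set_label: str = "",
    window: int = AT_WINDOW,
    step: int = 1,
) -> ATProfile:
    """Sliding-window AT% averaged across a sequence set.

    Window i (1-based) covers bases i..i+window-1 of each sequence;
    its AT% is 100 * (#A + #T) / window. N counts as non-AT.
    """
    if not windows:
        raise ParameterError("at_profile needs at least one sequence")
    lengths = {len(w.sequence) for w in windows}
    if len(lengths) != 1:
        bad = next(w for w in windows if len(w.sequence) != min(lengths))
        raise ParameterError(f"unequal sequence lengths (e.g. {bad.locus_tag})")
    L = lengths.pop()
    if window > L:
        raise ParameterError("window longer than the sequences")
    mat = np.zeros((len(windows), L), dtype=np.float64)
    for i, w in enumerate(windows):
        arr = np.frombuffer(w.sequence.encode(), dtype=np.uint8)
        mat[i] = (arr == ord("A")) | (arr == ord("T"))
    csum = np.concatenate(
        [np.zeros((len(windows), 1)), np.cumsum(mat, axis=1)], axis=1
    )
    starts = np.arange(1, L - window + 2, step)
    per_seq = (csum[:, starts - 1 + window] - csum[:, starts - 1]) / window * 100.0
    return ATProfile(
        set_label=set_label,
        n_sequences=len(windows),
        positions=starts,
        values=per_seq.mean(axis=0),
        per_sequence=per_seq,
    )


# ---------------------------------------------------------------------------
# controls
# ---------------------------------------------------------------------------


def sample_random_promoters(
    genes: Sequence[GeneModel],
    genome: GenomeSequence,
    n: int = 66,
    seed: int = 0,
    exclude: Iterable[str] = (),
) -> list[PromoterWindow]:
    """Uniform sample (without replacement) of eligible genes' promoters."""
    banned = set(exclude)
    eligible = [t for t in eligible_promoter_genes(genes, genome) if t not in banned]
    if len(eligible) < n:
        raise ParameterError(
            f"only {len(eligible)} eligible genes for {n} random promoters"
        )
    rng = np.random.default_rng(seed)
    picked = sorted(rng.choice(len(eligible), size=n, replace=False))
    by_tag = {g.locus_tag: g for g in genes}
    return [extract_promoter_window(genome, by_tag[eligible[i]]) for i in picked]


def sample_random_genomic(
    genome: GenomeSequence, n: int = 66, length: int = WINDOW_LENGTH, seed: int = 0
) -> list[PromoterWindow]:
    """n random fixed-length sequences, uniform start, either strand."""
    if genome.length < length:
        raise ParameterError("genome shorter than the requested sequence length")
    rng = np.random.default_rng(seed)
    starts = rng.integers(1, genome.length - length + 2, size=n)
    strands = rng.choice(["+", "-"], size=n)
    out = []
    for i, (s, strand) in enumerate(zip(starts, strands)):
        seq = genome.slice(int(s), int(s) + length - 1)
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        out.append(PromoterWindow(f"random_{i + 1}", seq))
    return out


# ---------------------------------------------------------------------------
# position tests
# ---------------------------------------------------------------------------


def compare_positions(
    profile_a: ATProfile,
    profile_b: ATProfile,
    positions: Sequence[int] = DEFAULT_POSITIONS,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Shapiro-Wilk per set plus a two-sample t-test at each named position.

    The t-test is Welch by default (``equal_var=True`` gives Student). A
    Mann-Whitney p is reported additionally whenever either set fails the
    normality check at 0.05; the t-test remains the primary statistic.
    """
    rows = []
    for pos in positions:
        a = profile_a.at_position(pos)
        b = profile_b.at_position(pos)
        sw_a = float(stats.shapiro(a).pvalue) if a.size >= 3 and np.ptp(a) > 0 else np.nan
        sw_b = float(stats.shapiro(b).pvalue) if b.size >= 3 and np.ptp(b) > 0 else np.nan
        if a.size >= 2 and b.size >= 2:
            if np.ptp(np.concatenate([a, b])) == 0:
                t_p = 1.0
            else:
                t_p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        else:
            t_p = np.nan
        mw_p = np.nan
        if (sw_a < 0.05 or sw_b < 0.05) and a.size >= 2 and b.size >= 2:
            mw_p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        rows.append(
            {
                "position": pos,
                "set_a": profile_a.set_label,
                "set_b": profile_b.set_label,
                "mean_a": float(a.mean()),
                "mean_b": float(b.mean()),
                "normality_p_a": sw_a,
                "normality_p_b": sw_b,
                "test_p": t_p,
                "mannwhitney_p": mw_p,
            }
        )
    return pd.DataFrame(rows)


def plot_profiles(profiles: Sequence[ATProfile], path) -> None:
    """Mean AT% curves for several sets, one figure."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for p in profiles:
        ax.plot(p.positions, p.values, label=f"{p.set_label} (n={p.n_sequences})")
    ax.axvline(UPSTREAM + 1, color="grey", ls="--", lw=0.8)
    ax.set_xlabel("window start position on the 960-bp promoter sequence (bp)")
    ax.set_ylabel("mean AT content in 100-bp window (%)")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
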