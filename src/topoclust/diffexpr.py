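"""Upper-quartile normalization, fold changes and SSG classification.

A supercoiling-sensitive gene (SSG) is one whose transcript level changes
at least 2.83-fold (|log2 fold change| > 1.5) with p < 0.05 between a
supercoiling-perturbed condition and its control. Genes encoding
nucleoid-associated proteins or topoisomerases may be exempted from the
fold-change band and classified on the p-value alone, because their
regulatory role makes even modest level changes meaningful.

Significance is assessed with a two-sided Welch t-test on
log2(normalized + 1) across biological replicates; Benjamini-Hochberg
q-values are reported alongside, but classification uses the raw p-value
threshold. The test choice is recorded in every output's metadata.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CountMatrix, ExpressionMatrix, ParameterError

LOG2FC_THRESHOLD = 1.5
P_THRESHOLD = 0.05

SIGNIFICANCE_METHOD = "welch-t on log2(normalized+1); BH q-values reported"


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def upper_quartile(values: Sequence[float] | np.ndarray) -> float:
    """75th percentile of the nonzero entries, by sort-and-index.

    The empirical (right-continuous, no-interpolation) quantile: sort the
    nonzero values and take the element at 0-based index floor(0.75 * n).
    For [10, 20, 30, 40] this is 40.
    """
    x = np.asarray(values, dtype=float)
    x = np.sort(x[x > 0])
    if x.size == 0:
        raise ParameterError("upper quartile undefined: no nonzero values")
    return float(x[int(math.floor(0.75 * x.size))])


def normalize_upper_quartile(
    cm: CountMatrix, reference_scale: float | str = "median-of-uqs"
) -> ExpressionMatrix:
    """Scale each sample by the upper quartile of its nonzero gene counts.

    value(g, s) = count(g, s) / UQ_s * S with S the reference scale
    (default: the median of the per-sample upper quartiles, so the output
    stays on a count-like scale). Zero counts stay zero; a sample with no
    nonzero count is an error.
    """
    uqs = {}
    for s in cm.counts.columns:
        col = cm.counts[s].to_numpy()
        if not (col > 0).any():
            raise ParameterError(f"sample {s!r} has all-zero counts")
        uqs[s] = upper_quartile(col)
    if reference_scale == "median-of-uqs":
        scale = float(np.median(list(uqs.values())))
    else:
        scale = float(reference_scale)
        if scale <= 0:
            raise ParameterError("reference_scale must be positive")
    values = cm.counts.astype(float).copy()
    for s in values.columns:
        values[s] = values[s] / uqs[s] * scale
    return ExpressionMatrix(values, cm.samples.copy())


# ---------------------------------------------------------------------------
# fold change
# ---------------------------------------------------------------------------


def log2_fold_change(
    expr: ExpressionMatrix,
    contrast: tuple[str, str],
    pseudocount: float = 0.0,
    zero_mean_pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-gene log2(mean treatment / mean control); induction is positive.

    With the default pseudocount of 0, genes with exactly one zero
    condition mean fall back to ``zero_mean_pseudocount`` and are flagged;
    genes with both means zero get a missing log2fc.
    """
    if pseudocount < 0:
        raise ParameterError("pseudocount must be non-negative")
    treatment, control = contrast
    mt = expr.values[expr.condition_columns(treatment)].mean(axis=1)
    mc = expr.values[expr.condition_columns(control)].mean(axis=1)
    lfc = np.full(len(mt), np.nan)
    flags = np.array([""] * len(mt), dtype=object)
    for i, (a, b) in enumerate(zip(mt.to_numpy(), mc.to_numpy())):
        pa, pb = a + pseudocount, b + pseudocount
        if pa > 0 and pb > 0:
            lfc[i] = math.log2(pa / pb)
        elif a == 0 and b == 0:
            flags[i] = "both_zero"
        else:
            lfc[i] = math.log2(
                (a + zero_mean_pseudocount) / (b + zero_mean_pseudocount)
            )
            flags[i] = "zero_mean_pseudocount"
    return pd.DataFrame(
        {
            "mean_treatment": mt,
            "mean_control": mc,
            "log2fc": lfc,
            "fc_flag": flags,
        },
        index=mt.index,
    )


# ---------------------------------------------------------------------------
# significance
# ---------------------------------------------------------------------------


def test_significance(
    expr: ExpressionMatrix, contrast: tuple[str, str]
) -> pd.DataFrame:
    """Welch t on log2(value+1) per gene, with BH q-values over all genes."""
    treatment, control = contrast
    a_cols = expr.condition_columns(treatment)
    b_cols = expr.condition_columns(control)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ParameterError("each condition needs at least 2 replicates")
    a = np.log2(expr.values[a_cols].to_numpy() + 1.0)
    b = np.log2(expr.values[b_cols].to_numpy() + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    # degenerate genes: zero variance in both groups
    var0 = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    same = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p[var0 & same] = 1.0
    p[var0 & ~same] = 0.0
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"p_value": p, "q_value": q}, index=expr.values.index)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def classify_ssg(
    diff: pd.DataFrame,
    exemption_list: Iterable[str] = (),
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Attach the SSG class to a table with log2fc and p_value columns.

    up if log2fc > threshold and p < p_threshold; down symmetric; genes on
    the exemption list are classified on p alone with the direction taken
    from the sign of log2fc. Everything else (including missing log2fc) is
    not_significant.
    """
    exempt = set(exemption_list)
    classes = []
    for tag, row in diff.iterrows():
        lfc, p = row["log2fc"], row["p_value"]
        cls = "not_significant"
        if not (pd.isna(lfc) or pd.isna(p)) and p < p_threshold:
            if tag in exempt:
                cls = "up" if lfc > 0 else "down" if lfc < 0 else "not_significant"
            elif lfc > log2fc_threshold:
                cls = "up"
            elif lfc < -log2fc_threshold:
                cls = "down"
        classes.append(cls)
    out = diff.copy()
    out["ssg_class"] = classes
    return out


def run_contrast(
    cm: CountMatrix,
    contrast: tuple[str, str],
    exemption_list: Iterable[str] = (),
    reference_scale: float | str = "median-of-uqs",
    log2fc_threshold: float = LOG2FC_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Normalize, compute log2FC and p/q, classify: the full per-contrast table."""
    expr = normalize_upper_quartile(cm, reference_scale)
    fc = log2_fold_change(expr, contrast)
    sig = test_significance(expr, contrast)
    diff = fc.join(sig)
    out = classify_ssg(diff, exemption_list, log2fc_threshold, p_threshold)
    out.index.name = "locus_tag"
    return out


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------


def summarize_affected(
    classified: Mapping[str, pd.DataFrame], total_genes: int, decimals: int = 1
) -> pd.DataFrame:
    """Per-contrast affected counts, genome percentages and specificity.

    ``pct_of_genome`` is rounded to ``decimals``; ``pct_specific_floor``
    truncates to a whole percent, matching how such specificities are
    usually printed. Specificity of a contrast counts its affected genes
    found in no other contrast.
    """
    if total_genes <= 0:
        raise ParameterError("total_genes must be positive")
    affected = {
        name: set(df.index[df["ssg_class"].isin(["up", "down"])])
        for name, df in classified.items()
    }
    rows = []
    for name, df in classified.items():
        genes = affected[name]
        others = set().union(
            *(affected[o] for o in affected if o != name)
        ) if len(affected) > 1 else set()
        specific = genes - others
        n = len(genes)
        rows.append(
            {
                "contrast": name,
                "n_up": int((df["ssg_class"] == "up").sum()),
                "n_down": int((df["ssg_class"] == "down").sum()),
                "n_affected": n,
                "pct_of_genome": round(100.0 * n / total_genes, decimals),
                "n_specific": len(specific),
                "pct_specific": round(100.0 * len(specific) / n, decimals) if n else 0.0,
                "pct_specific_floor": int(100 * len(specific) // n) if n else 0,
            }
        )
    return pd.DataFrame(rows)
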