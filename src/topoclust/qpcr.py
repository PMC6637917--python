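"""Comparative ddCt relative quantification with an endogenous control.

Relative transcript level = 2**(-ddCt), where dCt(condition) is the mean
target Ct minus the mean reference-gene Ct over that condition's samples
(technical replicates averaged at the Ct level first), and ddCt subtracts
the calibrator condition's dCt. Amplification efficiency is fixed at 2,
the classic comparative method. The calibrator's own relative level is 1
by construction; any constant per-sample Ct offset (a plate effect)
cancels out.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ParameterError

REFERENCE_GENE = "hrdB"

_COLUMNS = ("sample", "condition", "gene", "replicate", "ct")


def _check(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COLUMNS) - set(records.columns)
    if missing:
        raise ParameterError(f"Ct table lacks columns {sorted(missing)}")
    if (records["ct"] <= 0).any():
        raise ParameterError("Ct values must be positive")
    # average technical replicates within a sample at the Ct level
    return (
        records.groupby(["condition", "sample", "gene"], as_index=False)["ct"].mean()
    )


def ddct(
    records: pd.DataFrame,
    target: str,
    reference_gene: str = REFERENCE_GENE,
    calibrator_condition: str = "control",
) -> pd.DataFrame:
    """Per-condition ddCt and relative level for one target gene."""
    tech = _check(records)
    conditions = sorted(tech["condition"].unique())
    if calibrator_condition not in conditions:
        raise ParameterError(f"calibrator condition {calibrator_condition!r} absent")
    dct = {}
    for cond in conditions:
        sub = tech[tech["condition"] == cond]
        t = sub.loc[sub["gene"] == target, "ct"]
        r = sub.loc[sub["gene"] == reference_gene, "ct"]
        if r.empty:
            raise ParameterError(f"reference gene {reference_gene!r} missing in {cond!r}")
        if t.empty:
            raise ParameterError(f"target {target!r} missing in {cond!r}")
        dct[cond] = float(t.mean() - r.mean())
    rows = []
    for cond in conditions:
        ddct_val = dct[cond] - dct[calibrator_condition]
        rows.append(
            {
                "target_gene": target,
                "condition": cond,
                "calibrator_condition": calibrator_condition,
                "delta_ct": dct[cond],
                "delta_delta_ct": ddct_val,
                "relative_level": float(2.0 ** (-ddct_val)),
                "sd_relative_level": replicate_dispersion(
                    records, target, cond, reference_gene, calibrator_condition
                ),
            }
        )
    return pd.DataFrame(rows)


def replicate_dispersion(
    records: pd.DataFrame,
    target: str,
    condition: str,
    reference_gene: str = REFERENCE_GENE,
    calibrator_condition: str = "control",
) -> float:
    """Standard deviation of per-replicate relative levels (NaN if <2).

    Each biological sample gets its own dCt from replicate-matched target
    and reference Cts; ddCt uses the calibrator's mean dCt; the sd (ddof=1)
    of the resulting 2**(-ddCt) values is returned.
    """
    tech = _check(records)
    cal = tech[tech["condition"] == calibrator_condition]
    cal_t = cal.loc[cal["gene"] == target, "ct"]
    cal_r = cal.loc[cal["gene"] == reference_gene, "ct"]
    if cal_t.empty or cal_r.empty:
        raise ParameterError("calibrator condition lacks target or reference Cts")
    cal_dct = float(cal_t.mean() - cal_r.mean())
    sub = tech[tech["condition"] == condition]
    wide = sub.pivot_table(index="sample", columns="gene", values="ct")
    if target not in wide.columns or reference_gene not in wide.columns:
        raise ParameterError(f"{condition!r} lacks target or reference Cts")
    per_sample = wide[target] - wide[reference_gene]
    per_sample = per_sample.dropna()
    if len(per_sample) < 2:
        return float("nan")
    levels = 2.0 ** (-(per_sample - cal_dct))
    return float(np.std(levels, ddof=1))
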