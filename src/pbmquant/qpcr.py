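"""Relative expression quantification by the 2^−ΔΔCt method.

Per sample, technical replicate Cts are averaged first; then

    ΔCt   = Ct(target) − Ct(reference gene)
    ΔΔCt  = ΔCt(sample) − mean ΔCt over calibrator samples
    fold  = 2^−ΔΔCt

with a fixed amplification efficiency of 2 (no efficiency correction) and
a single reference gene. Condition-level summaries report mean ± SEM over
biological samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CtTable


@dataclass(frozen=True)
class FoldChangeResult:
    """Per-sample fold changes plus per-condition summary.

    ``per_sample``: one row per (sample, gene) with delta_ct,
    delta_delta_ct and fold_change (= 2^−ΔΔCt; log2(fold) == −ΔΔCt by
    construction). ``by_condition``: mean/SEM of fold over samples.
    """

    reference_gene: str
    calibrator_condition: str
    per_sample: pd.DataFrame
    by_condition: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        return self.per_sample

    def fold(self, gene: str, condition: str) -> float:
        """Condition-mean fold change of one gene."""
        m = self.by_condition
        row = m[(m["gene"] == gene) & (m["condition"] == condition)]
        if row.empty:
            raise KeyError((gene, condition))
        return float(row["fold_mean"].iloc[0])


def fold_changes(
    table: CtTable,
    reference_gene: str,
    calibrator_condition: str,
) -> FoldChangeResult:
    """Compute 2^−ΔΔCt fold changes for every (sample, gene).

    ``calibrator_condition`` names the baseline the ΔΔCt is taken against —
    typically the untreated control for in vitro data, or the day-0
    baseline for an in vivo time course; both are just labels here.
    """
    df = table.df
    table.require_reference(reference_gene)
    if calibrator_condition not in set(df["condition"]):
        raise ValidationError(
            f"calibrator condition {calibrator_condition!r} not present"
        )
    # replicate Cts averaged at the Ct level before any differencing
    mean_ct = (
        df.groupby(["sample", "condition", "gene"], sort=False)["ct"]
        .mean()
        .reset_index()
    )
    ref = mean_ct[mean_ct["gene"] == reference_gene][
        ["sample", "ct"]
    ].rename(columns={"ct": "ref_ct"})
    merged = mean_ct.merge(ref, on="sample")
    merged["delta_ct"] = merged["ct"] - merged["ref_ct"]

    calib = merged[merged["condition"] == calibrator_condition]
    missing = set(merged["gene"]) - set(calib["gene"])
    if missing:
        raise ValidationError(
            f"genes missing from calibrator condition: {sorted(missing)}"
        )
    calib_mean = (
        calib.groupby("gene")["delta_ct"].mean().rename("calib_delta_ct")
    )
    merged = merged.merge(calib_mean, on="gene")
    merged["delta_delta_ct"] = merged["delta_ct"] - merged["calib_delta_ct"]
    merged["fold_change"] = 2.0 ** (-merged["delta_delta_ct"])

    rows = []
    for (gene, cond), g in merged.groupby(["gene", "condition"], sort=False):
        folds = g["fold_change"].to_numpy(dtype=float)
        rows.append(
            {
                "gene": gene,
                "condition": cond,
                "n_samples": len(folds),
                "fold_mean": folds.mean(),
                "fold_sem": (
                    folds.std(ddof=1) / math.sqrt(len(folds))
                    if len(folds) > 1
                    else float("nan")
                ),
                "delta_delta_ct_mean": float(g["delta_delta_ct"].mean()),
            }
        )
    per_sample = merged[
        ["sample", "condition", "gene", "delta_ct", "delta_delta_ct", "fold_change"]
    ].reset_index(drop=True)
    return FoldChangeResult(
        reference_gene=reference_gene,
        calibrator_condition=calibrator_condition,
        per_sample=per_sample,
        by_condition=pd.DataFrame(rows),
    )
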