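"""Relative qPCR quantification by the 2^(-ddCt) method.

Each sample's target Ct is first normalized to a housekeeping gene
(dCt = Ct_target - Ct_housekeeping), then to the control condition
(ddCt = dCt - mean dCt of controls), and expressed as a fold change
2^(-ddCt). The control group is aggregated by the arithmetic mean of dCt,
which makes the geometric mean of the control fold changes exactly 1.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = ["validate_ct_table", "ddct_fold_change"]

REQUIRED_COLUMNS = ("sample_id", "condition", "gene", "ct")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format Ct table (sample_id, condition, gene, ct)."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    ct = pd.to_numeric(table["ct"], errors="coerce")
    if ct.isna().any() or (ct <= 0).any() or np.isinf(ct).any():
        raise ValueError("Ct values must be finite and positive")
    return table.assign(ct=ct)


def ddct_fold_change(
    table: pd.DataFrame,
    target_gene: str,
    control_condition: str,
    housekeeping_gene: str = "GAPDH",
) -> pd.DataFrame:
    """Per-sample 2^(-ddCt) fold changes of ``target_gene`` relative to the
    control condition.

    Samples lacking a housekeeping measurement are rejected with a warning
    and excluded. Returns a frame with sample_id, condition, delta_ct,
    ddct, fold_change.
    """
    table = validate_ct_table(table)
    tgt = table[table["gene"] == target_gene]
    hk = table[table["gene"] == housekeeping_gene]
    if tgt.empty:
        raise ValueError(f"no rows for target gene {target_gene!r}")
    if hk.empty:
        raise ValueError(f"no rows for housekeeping gene {housekeeping_gene!r}")
    merged = tgt.merge(
        hk[["sample_id", "condition", "ct"]],
        on=["sample_id", "condition"],
        how="left",
        suffixes=("", "_hk"),
    )
    dropped = merged[merged["ct_hk"].isna()]
    if len(dropped):
        warnings.warn(
            "samples without a housekeeping Ct were rejected: "
            + ", ".join(map(str, dropped["sample_id"].tolist())),
            stacklevel=2,
        )
        merged = merged.dropna(subset=["ct_hk"])
    if merged.empty:
        raise ValueError("no sample has both target and housekeeping Ct")
    merged = merged.assign(delta_ct=merged["ct"] - merged["ct_hk"])
    control = merged[merged["condition"] == control_condition]
    if control.empty:
        raise ValueError(f"control condition {control_condition!r} not present")
    control_mean = control["delta_ct"].mean()
    merged = merged.assign(ddct=merged["delta_ct"] - control_mean)
    merged = merged.assign(fold_change=2.0 ** (-merged["ddct"]))
    return merged[["sample_id", "condition", "delta_ct", "ddct", "fold_change"]]
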