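"""Relative gene-expression quantification from qPCR Ct tables.

Classical 2^-ddCt quantification: technical replicates are averaged on
the Ct scale, each target gene is referenced to a housekeeping gene
(ACTB by default), and fold changes are expressed against an explicitly
named control condition.  Amplification efficiency is fixed at 2.0 per
cycle; no efficiency correction is applied.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("sample", "condition", "gene", "replicate", "ct")
CT_PLAUSIBLE_RANGE = (5.0, 40.0)


@dataclass
class FoldChange:
    """Fold change of one gene in one condition vs. the control condition."""

    gene: Optional[str]
    condition: Optional[str]
    delta_delta_ct: float
    fc: float

    @property
    def log2_fc(self) -> float:
        return -self.delta_delta_ct


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the tidy Ct-table contract; warns on implausible Ct values."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.all(np.isfinite(ct)):
        raise ValueError("all Ct values must be finite")
    lo, hi = CT_PLAUSIBLE_RANGE
    n_odd = int(np.count_nonzero((ct < lo) | (ct > hi)))
    if n_odd:
        warnings.warn(
            f"{n_odd} Ct values outside the plausible {lo}-{hi} cycle range",
            stacklevel=2,
        )
    return table


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Average technical replicates on the Ct scale.

    Returns one row per (sample, condition, gene) with the arithmetic
    mean Ct; genes with different replicate counts average independently.
    """
    validate_ct_table(table)
    return (
        table.groupby(["sample", "condition", "gene"], as_index=False)["ct"]
        .mean()
    )


def delta_delta_ct(
    ct_target: float,
    ct_ref: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
    gene: Optional[str] = None,
    condition: Optional[str] = None,
) -> FoldChange:
    """ddCt = (Ct_target - Ct_ref) - (Ct_target_ctrl - Ct_ref_ctrl);
    fold change = 2^-ddCt.

    Invariant under adding a constant to all Cts of a sample (plate
    offset), and equals 1 when all four Cts agree.
    """
    for name, v in (
        ("ct_target", ct_target),
        ("ct_ref", ct_ref),
        ("ct_target_ctrl", ct_target_ctrl),
        ("ct_ref_ctrl", ct_ref_ctrl),
    ):
        if not np.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v}")
    ddct = (ct_target - ct_ref) - (ct_target_ctrl - ct_ref_ctrl)
    return FoldChange(
        gene=gene, condition=condition, delta_delta_ct=ddct, fc=2.0 ** (-ddct)
    )


def fold_changes(
    table: pd.DataFrame,
    control_condition: str,
    reference_gene: str = "ACTB",
) -> pd.DataFrame:
    """Fold change of every target gene in every condition vs. control.

    Replicates are averaged first; when a condition has several samples,
    their averaged Cts are averaged again (per gene) before differencing.
    Raises if the reference gene is missing for any sample or if the
    control condition is absent, naming the offender.

    Returns a frame with columns gene, condition, delta_delta_ct, fc,
    log2_fc.  The reference gene itself always reports fc = 1.
    """
    averaged = average_replicates(table)
    for sample, group in averaged.groupby("sample"):
        if reference_gene not in set(group["gene"]):
            raise ValueError(
                f"reference gene {reference_gene!r} missing for sample {sample!r}"
            )
    if control_condition not in set(averaged["condition"]):
        raise ValueError(f"control condition {control_condition!r} not in table")
    # condition-level mean Ct per gene
    cond_ct = averaged.groupby(["condition", "gene"])["ct"].mean()
    ref_ct = cond_ct.xs(reference_gene, level="gene")
    out = []
    for (condition, gene), ct in cond_ct.items():
        if gene == reference_gene and condition == control_condition:
            pass  # still reported: fc is 1 by construction
        try:
            ct_target_ctrl = cond_ct[(control_condition, gene)]
        except KeyError:
            raise ValueError(
                f"gene {gene!r} missing in control condition {control_condition!r}"
            ) from None
        result = delta_delta_ct(
            ct,
            ref_ct[condition],
            ct_target_ctrl,
            ref_ct[control_condition],
            gene=gene,
            condition=condition,
        )
        out.append(
            {
                "gene": gene,
                "condition": condition,
                "delta_delta_ct": result.delta_delta_ct,
                "fc": result.fc,
                "log2_fc": result.log2_fc,
            }
        )
    return pd.DataFrame(out).sort_values(["gene", "condition"]).reset_index(drop=True)


def primer_table() -> pd.DataFrame:
    """Bundled primer reference for the murine genes the pipeline targets
    (ACTB reference; MDM2, CDKN1A, BBC3 as stress-response readouts)."""
    with resources.files("tissuedyn.data").joinpath("primers.csv").open() as fh:
        return pd.read_csv(fh)
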