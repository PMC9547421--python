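"""Expression-matrix processing and qPCR relative expression.

Group semantics follow the family-survey convention: Group 1/2 are genes
constitutively high/low across developmental stages (TPM above/below fixed
thresholds in at least a fraction of stage columns); Group 3/4 are genes
induced/repressed under stress treatments relative to a control column
(ratio with a pseudocount).  Heatmap support: log2(TPM+1) row z-scaling
and average-linkage hierarchical ordering on correlation distance.  qPCR
fold changes use the standard double-delta Ct:

    ddCt = (Ct_target,cond - Ct_ref,cond) - (Ct_target,ctrl - Ct_ref,ctrl)
    fold = 2 ** (-ddCt)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import dendrogram, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

DEFAULT_HIGH_TPM = 10.0
DEFAULT_LOW_TPM = 1.0
DEFAULT_STAGE_FRACTION = 0.8  # "nearly all" stages
DEFAULT_INDUCED_RATIO = 2.0
DEFAULT_STRESS_FRACTION = 0.5
PSEUDOCOUNT = 0.5


@dataclass
class GroupAssignment:
    """Gene -> group labels plus the parameters that produced them."""

    labels: pd.Series
    parameters: dict = field(default_factory=dict)

    def counts(self) -> dict:
        return self.labels.value_counts().to_dict()


def _validate_matrix(m: pd.DataFrame) -> None:
    if (m.values < 0).any():
        raise ValueError("TPM values must be nonnegative")
    if m.index.duplicated().any() or m.columns.duplicated().any():
        raise ValueError("duplicate row or column ids")


def assign_development_groups(
    m: pd.DataFrame,
    stage_columns,
    high_tpm: float = DEFAULT_HIGH_TPM,
    low_tpm: float = DEFAULT_LOW_TPM,
    fraction: float = DEFAULT_STAGE_FRACTION,
) -> GroupAssignment:
    """Constitutive expression groups over developmental stages.

    Group1: TPM >= high_tpm in at least *fraction* of stage columns.
    Group2: TPM < low_tpm in at least *fraction* of stage columns (and not
    Group1).  Everything else is ungrouped.
    """
    stage_columns = list(stage_columns)
    if not stage_columns:
        raise ValueError("no stage columns")
    if not high_tpm > low_tpm >= 0:
        raise ValueError("need high_tpm > low_tpm >= 0")
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    sub = m[stage_columns]
    _validate_matrix(sub)
    frac_high = (sub >= high_tpm).mean(axis=1)
    frac_low = (sub < low_tpm).mean(axis=1)
    labels = pd.Series("ungrouped", index=m.index, dtype=object)
    labels[frac_low >= fraction] = "Group2"
    labels[frac_high >= fraction] = "Group1"  # Group1 wins by definition
    return GroupAssignment(
        labels,
        {"high_tpm": high_tpm, "low_tpm": low_tpm, "fraction": fraction,
         "stage_columns": stage_columns},
    )


def assign_stress_groups(
    m: pd.DataFrame,
    treatment_columns,
    control_column: str,
    induced_ratio: float = DEFAULT_INDUCED_RATIO,
    fraction: float = DEFAULT_STRESS_FRACTION,
    pseudocount: float = PSEUDOCOUNT,
) -> GroupAssignment:
    """Stress-responsive groups relative to the control column.

    Group3: treatment/control ratio >= induced_ratio in at least *fraction*
    of treatment columns; Group4: ratio <= 1/induced_ratio likewise.  A
    gene meeting both is set to ungrouped and logged.
    """
    treatment_columns = list(treatment_columns)
    if control_column not in m.columns:
        raise ValueError(f"control column {control_column!r} missing")
    if induced_ratio <= 1:
        raise ValueError("induced_ratio must exceed 1")
    sub = m[treatment_columns + [control_column]]
    _validate_matrix(sub)
    ratio = (m[treatment_columns].add(pseudocount)).div(
        m[control_column] + pseudocount, axis=0
    )
    frac_up = (ratio >= induced_ratio).mean(axis=1)
    frac_down = (ratio <= 1.0 / induced_ratio).mean(axis=1)
    up = frac_up >= fraction
    down = frac_down >= fraction
    both = up & down
    if both.any():
        logger.warning(
            "%d gene(s) met both induction and repression criteria; "
            "set to ungrouped", int(both.sum()),
        )
    labels = pd.Series("ungrouped", index=m.index, dtype=object)
    labels[up & ~both] = "Group3"
    labels[down & ~both] = "Group4"
    return GroupAssignment(
        labels,
        {"induced_ratio": induced_ratio, "fraction": fraction,
         "pseudocount": pseudocount, "control_column": control_column,
         "treatment_columns": treatment_columns},
    )


def zscore_rows(m: pd.DataFrame) -> tuple:
    """Per-row z-scores of log2(TPM+1); constant rows become all-zero.

    Returns ``(scaled, constant_flags)``.
    """
    _validate_matrix(m)
    logm = np.log2(m + 1.0)
    mean = logm.mean(axis=1)
    sd = logm.std(axis=1, ddof=0)
    constant = sd == 0
    sd_safe = sd.replace(0, 1.0)
    scaled = logm.sub(mean, axis=0).div(sd_safe, axis=0)
    scaled.loc[constant, :] = 0.0
    return scaled, constant


def hierarchical_order(m: pd.DataFrame):
    """Average-linkage ordering on 1 - Pearson correlation of scaled rows.

    Constant rows (undefined correlation) sit at distance 1 from everything
    and are flagged.  Returns ``(ordered_ids, linkage_matrix,
    constant_flags)``.
    """
    if len(m) < 2:
        raise ValueError("need at least 2 rows")
    scaled, constant = zscore_rows(m)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(scaled.values)
    corr = np.nan_to_num(corr, nan=0.0)
    for i, flag in enumerate(constant.values):
        if flag:
            corr[i, :] = 0.0
            corr[:, i] = 0.0
            corr[i, i] = 1.0
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    order = dendrogram(z, no_plot=True)["leaves"]
    return [m.index[i] for i in order], z, constant


def ddct_fold_change(
    q: pd.DataFrame, control: str = "control"
) -> pd.DataFrame:
    """2^-ddCt fold changes per (gene, condition).

    *q* has columns gene, condition, ct_target, ct_reference, with a
    control row per gene.  The control condition maps to fold 1 exactly.
    """
    required = {"gene", "condition", "ct_target", "ct_reference"}
    if not required <= set(q.columns):
        raise ValueError(f"qPCR table needs columns {sorted(required)}")
    if q[["ct_target", "ct_reference"]].isna().any().any():
        bad = q[q[["ct_target", "ct_reference"]].isna().any(axis=1)].iloc[0]
        raise ValueError(
            f"missing CT for gene {bad['gene']} condition {bad['condition']}"
        )
    ctrl = q[q["condition"] == control].set_index("gene")
    rows = []
    for _, row in q.iterrows():
        gene = row["gene"]
        if gene not in ctrl.index:
            raise ValueError(f"gene {gene} has no control row")
        dct_cond = row["ct_target"] - row["ct_reference"]
        dct_ctrl = ctrl.loc[gene, "ct_target"] - ctrl.loc[gene, "ct_reference"]
        ddct = dct_cond - dct_ctrl
        rows.append(
            {"gene": gene, "condition": row["condition"],
             "ddct": ddct, "fold_change": 2.0 ** (-ddct)}
        )
    return pd.DataFrame(rows)
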