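"""Relative expression by the 2^-ddCt method and group comparison.

Technical replicates are averaged per sample; dCt = Ct(target) -
Ct(reference) per sample; ddCt subtracts the calibrator group's mean dCt;
the relative quantity is RQ = 2^-ddCt (so the calibrator group's RQ has
geometric mean 1). Groups are compared with an independent-samples
t-test, flagged ``*`` below 0.05 and ``**`` below 0.01.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CT_COLUMNS = ("sample", "group", "gene", "replicate", "ct")


class CtValidationError(ValueError):
    pass


class InsufficientReplicationError(ValueError):
    pass


@dataclass
class CtTable:
    """Long-form qPCR cycle-threshold measurements plus the reference gene."""

    data: pd.DataFrame  # columns per CT_COLUMNS
    reference_gene: str

    def __post_init__(self) -> None:
        missing = set(CT_COLUMNS) - set(self.data.columns)
        if missing:
            raise CtValidationError(f"Ct table missing columns: {sorted(missing)}")
        samples = set(self.data["sample"].unique())
        with_ref = set(
            self.data.loc[self.data["gene"] == self.reference_gene, "sample"]
        )
        if samples - with_ref:
            raise CtValidationError(
                f"reference gene {self.reference_gene!r} not measured in "
                f"sample(s) {sorted(samples - with_ref)}"
            )

    @classmethod
    def from_tsv(
        cls, path: str | os.PathLike, reference_gene: str
    ) -> "CtTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df, reference_gene)


@dataclass
class DdctResult:
    per_sample: pd.DataFrame  # sample, group, delta_ct, ddct, rq
    group_summary: pd.DataFrame  # group, mean_rq, sem_rq, n


def ddct(table: CtTable, target_gene: str, calibrator_group: str) -> DdctResult:
    """Per-sample 2^-ddCt relative quantities for *target_gene*.

    ddCt is taken against the arithmetic mean dCt of *calibrator_group*,
    so calibrator ddCt values average to exactly 0.
    """
    df = table.data
    if target_gene not in set(df["gene"]):
        raise CtValidationError(f"target gene {target_gene!r} not in table")
    # average technical replicates per sample x gene
    mean_ct = (
        df.groupby(["sample", "group", "gene"], as_index=False)["ct"].mean()
    )
    tgt = mean_ct[mean_ct["gene"] == target_gene].set_index("sample")
    ref = mean_ct[mean_ct["gene"] == table.reference_gene].set_index("sample")
    missing = set(tgt.index) - set(ref.index)
    if missing:
        raise CtValidationError(
            f"sample(s) {sorted(missing)} lack reference-gene Ct"
        )
    per = pd.DataFrame(
        {
            "sample": tgt.index,
            "group": tgt["group"].to_numpy(),
            "delta_ct": tgt["ct"].to_numpy()
            - ref.loc[tgt.index, "ct"].to_numpy(),
        }
    )
    cal = per[per["group"] == calibrator_group]
    if cal.empty:
        raise CtValidationError(
            f"calibrator group {calibrator_group!r} has no samples"
        )
    per["ddct"] = per["delta_ct"] - cal["delta_ct"].mean()
    per["rq"] = 2.0 ** (-per["ddct"])
    summary = (
        per.groupby("group")["rq"]
        .agg(mean_rq="mean", sem_rq="sem", n="size")
        .reset_index()
    )
    return DdctResult(per_sample=per.reset_index(drop=True),
                      group_summary=summary)


@dataclass
class GroupComparison:
    t_statistic: float
    p_value: float
    significance: str  # '', '*', or '**'


def group_compare(
    values_a: np.ndarray | list,
    values_b: np.ndarray | list,
    equal_var: bool = True,
) -> GroupComparison:
    """Independent-samples t-test between two groups of RQ values.

    Equal-variance (Student) by default; *equal_var=False* selects Welch.
    Identical groups give t = 0, p = 1. Two constant, different groups
    are degenerate (zero pooled variance); they come back with p = 0 and
    an infinite t, which is reported rather than raised.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientReplicationError("each group needs n >= 2")
    if np.array_equal(a, b):
        t, p = 0.0, 1.0
    elif np.var(a) == 0 and np.var(b) == 0:
        # constant but different groups: difference is certain
        t = np.inf if a.mean() > b.mean() else -np.inf
        p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    if p < 0.01:
        flag = "**"
    elif p < 0.05:
        flag = "*"
    else:
        flag = ""
    return GroupComparison(t_statistic=t, p_value=p, significance=flag)


def direction_concordance(
    dmr_table: pd.DataFrame,
    expression: pd.DataFrame,
    inverse: bool = True,
) -> pd.DataFrame:
    """Compare methylation and expression directions per gene.

    *dmr_table* needs columns ``gene_id`` and ``meth_diff``; *expression*
    needs ``gene`` and ``log2_rq_diff`` (log2 of the mean-RQ ratio between
    the same two groups, in the same orientation). A gene whose DMRs
    disagree in sign is flagged ``mixed``. With the default *inverse*
    convention, hypermethylation paired with lower expression counts as
    concordant.
    """
    rows = []
    expr = expression.set_index("gene")["log2_rq_diff"]
    for gene_id, sub in dmr_table.groupby("gene_id"):
        if gene_id not in expr.index:
            continue
        signs = set(np.sign(sub["meth_diff"]).astype(int)) - {0}
        if len(signs) > 1:
            meth_dir = "mixed"
        elif signs == {1}:
            meth_dir = "up"
        elif signs == {-1}:
            meth_dir = "down"
        else:
            meth_dir = "flat"
        e = float(expr.loc[gene_id])
        expr_dir = "up" if e > 0 else ("down" if e < 0 else "flat")
        if meth_dir in ("mixed", "flat") or expr_dir == "flat":
            concordant = None
        elif inverse:
            concordant = meth_dir != expr_dir
        else:
            concordant = meth_dir == expr_dir
        rows.append(
            {
                "gene": gene_id,
                "meth_direction": meth_dir,
                "expr_direction": expr_dir,
                "concordant": concordant,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "meth_direction",
                                       "expr_direction", "concordant"])
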