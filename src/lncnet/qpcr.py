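"""Relative quantification of qPCR validation genes by the 2^-ddCt method.

Each sample's target Ct is normalised against a housekeeping reference gene
(dCt = Ct_target - Ct_reference), baselined on the control-group mean dCt
(ddCt), and expressed as fold change 2^-ddCt. Group comparisons are run on
the dCt scale (log-scale, closer to normal), with direction reported on
folds; concordance checks whether the qPCR direction for each gene matches
the array's DE direction.
"""

from __future__ import annotations

import warnings

import pandas as pd
from scipy import stats

from .containers import CONTROL, ValidationError
from .diffexpr import DesignError, mann_whitney


def delta_delta_ct(
    records: pd.DataFrame,
    reference_gene: str,
    control_label: str = CONTROL,
) -> pd.DataFrame:
    """Per-sample dCt, ddCt and fold change for every non-reference gene.

    ``records`` must have columns sample_id, group, gene, ct (one row per
    sample x gene). Samples lacking a reference-gene Ct are dropped with a
    warning; absence of control samples is a design error. The control-group
    mean ddCt is 0 by construction for every gene.
    """
    required = {"sample_id", "group", "gene", "ct"}
    missing = required - set(records.columns)
    if missing:
        raise ValidationError(f"qPCR records missing column(s) {sorted(missing)}")
    ref = records[records["gene"] == reference_gene].set_index("sample_id")["ct"]
    if ref.empty:
        raise ValidationError(f"no Ct records for reference gene {reference_gene!r}")
    targets = records[records["gene"] != reference_gene].copy()
    no_ref = ~targets["sample_id"].isin(ref.index)
    if no_ref.any():
        dropped = sorted(targets.loc[no_ref, "sample_id"].unique())
        warnings.warn(
            f"dropping sample(s) without reference Ct: {dropped[:5]}", stacklevel=2
        )
        targets = targets[~no_ref]
    targets["delta_ct"] = targets["ct"].to_numpy() - ref.reindex(
        targets["sample_id"]
    ).to_numpy()
    is_control = targets["group"] == control_label
    if targets.loc[is_control, "sample_id"].nunique() < 2:
        raise DesignError("need >= 2 control samples for the ddCt baseline")
    baseline = (
        targets[is_control].groupby("gene")["delta_ct"].mean().rename("baseline")
    )
    unmatched = set(targets["gene"]) - set(baseline.index)
    if unmatched:
        warnings.warn(
            f"gene(s) without control samples skipped: {sorted(unmatched)[:5]}",
            stacklevel=2,
        )
        targets = targets[targets["gene"].isin(baseline.index)]
    targets["delta_delta_ct"] = (
        targets["delta_ct"] - baseline.reindex(targets["gene"]).to_numpy()
    )
    targets["fold"] = 2.0 ** (-targets["delta_delta_ct"])
    out = targets[
        ["sample_id", "group", "gene", "delta_ct", "delta_delta_ct", "fold"]
    ].rename(columns={"gene": "gene_id"})
    return out.reset_index(drop=True)


def group_compare(
    rel: pd.DataFrame,
    method: str = "t",
    control_label: str = CONTROL,
) -> pd.DataFrame:
    """Case-vs-control test per gene on dCt values.

    ``method`` is ``"t"`` (Welch) or ``"mann-whitney"``. Direction is the
    sign of the case-vs-control mean fold difference (+1 up in cases, -1
    down); genes present in only one group are skipped with a warning.
    """
    if method not in ("t", "mann-whitney"):
        raise ValueError(f"method must be 't' or 'mann-whitney', got {method!r}")
    rows = []
    for gene, sub in rel.groupby("gene_id", sort=True):
        is_control = sub["group"] == control_label
        ctrl = sub.loc[is_control, "delta_ct"].to_numpy(float)
        case = sub.loc[~is_control, "delta_ct"].to_numpy(float)
        if len(ctrl) < 2 or len(case) < 2:
            warnings.warn(
                f"gene {gene!r} lacks >= 2 samples in both groups; skipped",
                stacklevel=2,
            )
            continue
        if method == "t":
            with warnings.catch_warnings():
                # noise-free validation data has ~zero within-group variance;
                # the p-value is degenerate there but direction is still valid
                warnings.simplefilter("ignore", RuntimeWarning)
                res = stats.ttest_ind(case, ctrl, equal_var=False)
            statistic, p = float(res.statistic), float(res.pvalue)
        else:
            statistic, p = mann_whitney(case, ctrl)
        fold_case = float(sub.loc[~is_control, "fold"].mean())
        fold_ctrl = float(sub.loc[is_control, "fold"].mean())
        # lower dCt in cases = higher abundance = upregulated
        direction = 1 if case.mean() < ctrl.mean() else -1
        rows.append((gene, statistic, p, direction, fold_case, fold_ctrl))
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "statistic",
            "p_value",
            "direction",
            "mean_fold_case",
            "mean_fold_control",
        ],
    )


def concordance(
    qpcr_directions: pd.Series | dict,
    array_directions: pd.Series | dict,
    genes=None,
) -> tuple[float, pd.DataFrame]:
    """Fraction of genes whose qPCR direction matches the array DE direction.

    Directions are +1/-1 per gene. Returns (fraction, per-gene table); an
    empty shared gene list is an error.
    """
    qp = pd.Series(qpcr_directions)
    ar = pd.Series(array_directions)
    shared = qp.index.intersection(ar.index)
    if genes is not None:
        shared = shared.intersection(pd.Index(genes))
    if len(shared) == 0:
        raise ValidationError("no shared genes between qPCR and array directions")
    table = pd.DataFrame(
        {
            "gene_id": shared,
            "qpcr_direction": qp.loc[shared].astype(int).to_numpy(),
            "array_direction": ar.loc[shared].astype(int).to_numpy(),
        }
    )
    table["concordant"] = table["qpcr_direction"] == table["array_direction"]
    return float(table["concordant"].mean()), table.reset_index(drop=True)
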