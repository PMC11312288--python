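"""Relative qPCR quantification by the comparative Ct (Livak) method.

Technical replicates are averaged per (gene, animal); each animal's
``dCt = Ct_target - Ct_reference`` normalises against the reference gene
(18S rRNA in the study design); ``ddCt`` subtracts the calibrator-group
mean dCt, and the group fold change is ``2**-mean(ddCt)`` under perfect
doubling efficiency. Significance is an unpaired two-sided t test on the
per-animal dCt values, following standard Livak practice (dCt, not folds,
is the approximately normal quantity at these sample sizes).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ("gene", "group", "animal", "replicate", "ct")


@dataclass
class RelativeExpressionResult:
    """Per-gene fold changes plus the per-animal dCt/ddCt table."""

    per_gene: pd.DataFrame  # index gene; fold_change, p, n_calibrator, n_test
    delta_ct: pd.DataFrame  # gene, group, animal, delta_ct, delta_delta_ct
    reference_gene: str
    calibrator_group: str
    test_group: str


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the CtTable layout and finiteness; returns the table."""
    missing = [c for c in CT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"CtTable missing columns: {missing}")
    ct = table["ct"].to_numpy(dtype=float)
    if not np.isfinite(ct).all():
        raise ValueError("CtTable contains non-finite Ct values")
    return table


def collapse_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct over technical replicates per (gene, group, animal).

    Every gene must be measured for every animal; a missing (gene, animal)
    combination is an error, since dCt needs both target and reference.
    """
    validate_ct_table(table)
    out = (
        table.groupby(["gene", "group", "animal"], sort=True)["ct"]
        .mean()
        .reset_index()
    )
    animals = out[["group", "animal"]].drop_duplicates()
    genes = out["gene"].unique()
    counts = out.groupby("gene")[["group"]].size()
    bad = counts[counts != len(animals)]
    if len(bad):
        raise ValueError(f"gene(s) missing for some animal: {sorted(bad.index)}; "
                         f"expected {len(animals)} animals per gene, n genes={len(genes)}")
    return out


def ddct_fold_change(
    mean_ct: pd.DataFrame,
    reference_gene: str,
    calibrator_group: str = "WT",
    test_group: str | None = None,
    equal_var: bool = True,
) -> RelativeExpressionResult:
    """ddCt fold changes of ``test_group`` relative to ``calibrator_group``.

    ``mean_ct`` is the output of :func:`collapse_replicates`. The fold for
    each target gene is ``2**-mean(ddCt over test-group animals)``; by
    construction the calibrator group's geometric-mean fold is 1.
    """
    groups = sorted(mean_ct["group"].unique())
    if calibrator_group not in groups:
        raise ValueError(f"calibrator group {calibrator_group!r} absent (groups: {groups})")
    if test_group is None:
        others = [g for g in groups if g != calibrator_group]
        if len(others) != 1:
            raise ValueError(f"cannot infer test group from {groups}; pass test_group")
        test_group = others[0]

    wide = mean_ct.pivot_table(index=["group", "animal"], columns="gene", values="ct")
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    if wide[reference_gene].isna().any():
        raise ValueError(f"reference gene {reference_gene!r} missing for some animal")

    dct = wide.sub(wide[reference_gene], axis=0)
    cal = dct.loc[calibrator_group]
    tst = dct.loc[test_group]
    if len(cal) == 0:
        raise ValueError(f"calibrator group {calibrator_group!r} has no animals")
    ddct = dct.sub(cal.mean(axis=0), axis=1)

    rows = {}
    for gene in wide.columns:
        fold = float(2.0 ** (-ddct.loc[test_group, gene].mean()))
        a, b = tst[gene].to_numpy(dtype=float), cal[gene].to_numpy(dtype=float)
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
        else:
            p = float(stats.ttest_ind(a, b, equal_var=equal_var).pvalue)
        rows[gene] = {
            "fold_change": fold,
            "p": p,
            "n_calibrator": int(len(b)),
            "n_test": int(len(a)),
        }
    per_gene = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    per_gene.index.name = "gene"

    long = (
        pd.concat({"delta_ct": dct.stack(), "delta_delta_ct": ddct.stack()}, axis=1)
        .reset_index()
        .rename(columns={"level_0": "group", "level_1": "animal"})
    )
    return RelativeExpressionResult(
        per_gene=per_gene,
        delta_ct=long,
        reference_gene=reference_gene,
        calibrator_group=calibrator_group,
        test_group=test_group,
    )
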