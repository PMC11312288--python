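"""Two-group differential expression on log2 expression matrices.

Implements the study's gene filter — per-gene two-sample t test,
Benjamini–Hochberg q-values, and a significance call at q < 0.05 with
signed linear fold change > 1.5 — plus the signed ``-log10(p)`` ranking
metric that feeds pre-ranked gene-set enrichment.

The fold-change convention is the signed one used by array software:
``fold = 2**log2fc`` for up-regulation and ``-2**(-log2fc)`` for
down-regulation, so "fold change > 1.5" means ``|fold| > 1.5`` on either
side of zero.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

#: Columns of a fully populated DEG table.
DEG_COLUMNS = ("log2fc", "fold", "statistic", "p", "q", "significant", "direction")


@dataclass
class ExpressionMatrix:
    """Log2-scale expression values, genes in rows, with sample conditions.

    Parameters
    ----------
    values
        genes x samples DataFrame of finite log2 intensities; gene index
        must be unique.
    condition
        Map sample name -> condition label (e.g. ``"WT"`` / ``"KO"``);
        every column of ``values`` must be present and every condition
        must have at least two samples.
    """

    values: pd.DataFrame
    condition: Mapping[str, str]

    def __post_init__(self) -> None:
        dup = self.values.index[self.values.index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene names: {sorted(set(dup))}")
        missing = [s for s in self.values.columns if s not in self.condition]
        if missing:
            raise ValueError(f"samples without a condition label: {missing}")
        counts = pd.Series([self.condition[s] for s in self.values.columns]).value_counts()
        small = counts[counts < 2]
        if len(small):
            raise ValueError(f"conditions with fewer than 2 samples: {dict(small)}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def samples_for(self, label: str) -> list[str]:
        """Sample names assigned to condition ``label``, in column order."""
        return [s for s in self.values.columns if self.condition[s] == label]


@dataclass(frozen=True)
class DESummary:
    """Counts of significant genes after the q/fold filter."""

    n_total: int
    n_up: int
    n_down: int


def signed_fold(log2fc: np.ndarray | float) -> np.ndarray | float:
    """Signed linear fold change: 2**x for x >= 0, -(2**-x) for x < 0."""
    x = np.asarray(log2fc, dtype=float)
    out = np.where(x >= 0, np.exp2(x), -np.exp2(-x))
    return out if out.ndim else float(out)


def welch_t_per_gene(
    mat: ExpressionMatrix,
    reference: str = "WT",
    test: str = "KO",
    equal_var: bool = False,
) -> pd.DataFrame:
    """Per-gene two-sided two-sample t test (Welch by default).

    The statistic's sign follows ``mean(test) - mean(reference)``.
    Degenerate genes (zero variance in both groups) get p = 1 when the
    group means are equal and p = 0 (logged) otherwise.

    Returns
    -------
    DataFrame indexed by gene with columns ``statistic`` and ``p``.
    """
    ref = [s for s in (mat.samples_for(reference))]
    tst = [s for s in (mat.samples_for(test))]
    if len(ref) < 2 or len(tst) < 2:
        raise ValueError(f"need >= 2 samples per condition ({reference}: {len(ref)}, {test}: {len(tst)})")
    a = mat.values[tst].to_numpy(dtype=float)
    b = mat.values[ref].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    stat = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    diff = a.mean(axis=1) - b.mean(axis=1)
    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    flat = degenerate & (diff == 0)
    stat[flat] = 0.0
    p[flat] = 1.0
    sep = degenerate & (diff != 0)
    if sep.any():
        log.warning("%d gene(s) with zero variance in both groups but unequal means; p set to 0", int(sep.sum()))
        stat[sep] = np.sign(diff[sep]) * np.inf
        p[sep] = 0.0
    return pd.DataFrame({"statistic": stat, "p": p}, index=mat.genes)


def _trigamma_inverse(x: float) -> float:
    """Solve psi'(y) = x for y by Newton iteration (x > 0)."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        step = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + step
        if abs(step) < 1e-10 * y:
            break
    return float(y)


def moderated_t_per_gene(
    mat: ExpressionMatrix,
    reference: str = "WT",
    test: str = "KO",
) -> pd.DataFrame:
    """Empirical-Bayes moderated t: per-gene variances shrunk to a prior.

    Per-gene pooled residual variances ``s_g^2`` (df ``d = n1 + n2 - 2``)
    are modelled as scaled inverse-chi-square draws around a prior
    ``(d0, s0^2)`` estimated by matching the moments of ``log s_g^2``;
    the posterior variance ``(d0 s0^2 + d s_g^2) / (d0 + d)`` then enters
    an ordinary two-sample t with ``d + d0`` degrees of freedom. This is
    the standard remedy for the heavy-tailed per-gene t at 3-vs-3 array
    designs, where the unmoderated test cannot separate large planted
    effects from variance noise.

    Returns a DataFrame with ``statistic``, ``p``, and the estimated
    prior df in ``df_prior`` (``inf`` for homoscedastic data).
    """
    ref = mat.samples_for(reference)
    tst = mat.samples_for(test)
    if len(ref) < 2 or len(tst) < 2:
        raise ValueError(f"need >= 2 samples per condition ({reference}: {len(ref)}, {test}: {len(tst)})")
    a = mat.values[tst].to_numpy(dtype=float)
    b = mat.values[ref].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    d = n1 + n2 - 2
    diff = a.mean(axis=1) - b.mean(axis=1)
    ss = ((a - a.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (b - b.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s2 = ss / d

    pos = s2 > 0
    if pos.sum() < 2:  # no variance information: fall back to unmoderated
        log.warning("too few positive per-gene variances for moderation")
        return welch_t_per_gene(mat, reference, test, equal_var=True)
    z = np.log(s2[pos])
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))

    if np.isfinite(d0):
        s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
        df_total = d + d0
    else:
        s2_post = np.full_like(s2, s0_sq)
        df_total = 1e6  # numerically normal
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    stat = np.where(se > 0, diff / np.where(se == 0, 1.0, se), np.sign(diff) * np.inf)
    p = 2.0 * stats.t.sf(np.abs(stat), min(df_total, 1e6))
    flat = (se == 0) & (diff == 0)
    stat[flat] = 0.0
    p[flat] = 1.0
    return pd.DataFrame({"statistic": stat, "p": p, "df_prior": d0}, index=mat.genes)


def bh_adjust(p_values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, capped at 1."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_expression(
    mat: ExpressionMatrix,
    reference: str = "WT",
    test: str = "KO",
    q_threshold: float = 0.05,
    fc_threshold: float = 1.5,
    method: str = "moderated",
) -> tuple[pd.DataFrame, DESummary]:
    """Full DE table for ``test`` vs ``reference`` plus the filter summary.

    ``method`` selects the per-gene test: ``moderated`` (empirical-Bayes
    variance shrinkage, the default and the appropriate choice at the
    study's 3-vs-3 design), ``welch`` or ``student``.
    """
    if method == "moderated":
        tt = moderated_t_per_gene(mat, reference=reference, test=test)
    elif method in ("welch", "student"):
        tt = welch_t_per_gene(mat, reference=reference, test=test, equal_var=method == "student")
    else:
        raise ValueError(f"unknown method {method!r}")
    log2fc = (
        mat.values[mat.samples_for(test)].mean(axis=1)
        - mat.values[mat.samples_for(reference)].mean(axis=1)
    )
    table = pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold": signed_fold(log2fc.to_numpy()),
            "statistic": tt["statistic"],
            "p": tt["p"],
            "q": bh_adjust(tt["p"].to_numpy()),
        },
        index=mat.genes,
    )
    return apply_deg_filter(table, q_threshold=q_threshold, fc_threshold=fc_threshold)


def apply_deg_filter(
    table: pd.DataFrame,
    q_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> tuple[pd.DataFrame, DESummary]:
    """Apply the strict ``q < q_threshold`` and ``|fold| > fc_threshold`` filter.

    Adds/overwrites ``significant`` and ``direction`` columns; direction is
    ``up`` / ``down`` for significant genes and ``none`` otherwise.
    """
    out = table.copy()
    if len(out) == 0:
        out["significant"] = pd.Series(dtype=bool)
        out["direction"] = pd.Series(dtype=object)
        return out, DESummary(0, 0, 0)
    sig = (out["q"].to_numpy() < q_threshold) & (np.abs(out["fold"].to_numpy()) > fc_threshold)
    up = sig & (out["log2fc"].to_numpy() > 0)
    down = sig & (out["log2fc"].to_numpy() < 0)
    out["significant"] = sig
    out["direction"] = np.where(up, "up", np.where(down, "down", "none"))
    return out, DESummary(int(sig.sum()), int(up.sum()), int(down.sum()))


def rank_metric(table: pd.DataFrame, max_score: float = 320.0) -> pd.Series:
    """Signed ``-log10(p)`` ranking scores, sorted for pre-ranked enrichment.

    Score sign follows the sign of ``log2fc``; p = 1 gives score 0 and
    p = 0 is clipped to ``max_score`` (logged). Order is descending score
    with deterministic ties broken by gene name.
    """
    p = table["p"].to_numpy(dtype=float)
    sgn = np.sign(table["log2fc"].to_numpy(dtype=float))
    zero_p = p == 0
    if zero_p.any():
        log.warning("%d gene(s) with p = 0; rank score clipped to %g", int(zero_p.sum()), max_score)
    with np.errstate(divide="ignore"):
        mag = np.where(zero_p, max_score, -np.log10(p))
    mag = np.minimum(mag, max_score)
    scores = pd.Series(sgn * mag, index=table.index, name="score")
    order = np.lexsort((scores.index.to_numpy(), -scores.to_numpy()))
    return scores.iloc[order]
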