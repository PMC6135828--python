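"""Enrichment calling: bait purifications versus tag-only controls.

A prey is called significantly enriched for a bait when all three filters
hold (strict inequalities, as printed in the source filters):

* ``log2FC > 2`` — fold change of total-count-normalized mean dSpC, with a
  half-count pseudocount;
* ``FDR < 0.05`` — Benjamini–Hochberg adjusted p-value from a one-sided
  exact conditional binomial test on aggregated counts;
* detection in more than 50% of bait replicates.

The count test conditions on the total x_bait + x_ctrl: under the null of
equal relative abundance, x_bait ~ Binomial(x_bait + x_ctrl, N_b/(N_b+N_c))
where N are the aggregate run totals, and the p-value is the upper tail.
This is a deterministic, assumption-light stand-in for Bayesian
spectral-count tools; it shares their inputs (counts and totals) but not
their posterior machinery.
"""

from __future__ import annotations

from collections.abc import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

#: Default filter thresholds (log2FC strictly above, FDR strictly below,
#: detection fraction strictly above).
DEFAULT_THRESHOLDS = {"log2fc_min": 2.0, "fdr_max": 0.05, "detect_min": 0.5}
DEFAULT_PSEUDOCOUNT = 0.5

ENRICHMENT_COLUMNS = (
    "bait_id",
    "condition",
    "protein_id",
    "log2FC",
    "p_value",
    "fdr",
    "detection_fraction",
    "significant",
)


def _count_matrix(quant_long: pd.DataFrame, run_ids: list[str]) -> pd.DataFrame:
    """Runs × proteins dSpC matrix for the given runs (absent → 0)."""
    sub = quant_long[quant_long["run_id"].isin(run_ids)]
    mat = sub.pivot_table(
        index="run_id", columns="protein_id", values="dSpC", fill_value=0.0
    )
    return mat.reindex(run_ids, fill_value=0.0)


def compute_log2fc(
    bait_counts: pd.DataFrame,
    control_counts: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.Series:
    """log2 fold change of normalized mean dSpC, bait over control.

    Each run's counts are rescaled to the mean run total over all compared
    runs (so means stay on the spectral-count scale), then
    ``log2((mean_bait + eps) / (mean_ctrl + eps))``.  Swapping bait and
    control negates the result exactly.
    """
    if pseudocount <= 0:
        raise ConfigurationError("pseudocount must be positive")
    if bait_counts.shape[0] < 1 or control_counts.shape[0] < 1:
        raise ConfigurationError("need at least one bait run and one control run")
    proteins = bait_counts.columns.union(control_counts.columns)
    b = bait_counts.reindex(columns=proteins, fill_value=0.0)
    c = control_counts.reindex(columns=proteins, fill_value=0.0)
    totals = pd.concat([b.sum(axis=1), c.sum(axis=1)])
    ref = totals.mean()
    b_norm = b.mul(ref / b.sum(axis=1), axis=0)
    c_norm = c.mul(ref / c.sum(axis=1), axis=0)
    fc = (b_norm.mean(axis=0) + pseudocount) / (c_norm.mean(axis=0) + pseudocount)
    out = np.log2(fc)
    out.name = "log2FC"
    return out


def test_enrichment(
    bait_sum: pd.Series | np.ndarray,
    control_sum: pd.Series | np.ndarray,
    n_bait_total: float,
    n_control_total: float,
) -> pd.Series | np.ndarray:
    """One-sided exact conditional binomial p-value per protein.

    ``bait_sum`` / ``control_sum`` are integer counts aggregated across the
    replicates of each arm; ``n_*_total`` the aggregate run totals.  Returns
    P(X >= x_bait) for X ~ Binomial(x_bait + x_ctrl, N_b / (N_b + N_c));
    p = 1 when both counts are zero.
    """
    xb = np.asarray(bait_sum, dtype=np.int64)
    xc = np.asarray(control_sum, dtype=np.int64)
    if (xb < 0).any() or (xc < 0).any():
        raise ConfigurationError("spectral counts must be non-negative")
    if n_bait_total <= 0 or n_control_total <= 0:
        raise ConfigurationError("aggregate run totals must be positive")
    n = xb + xc
    q = n_bait_total / (n_bait_total + n_control_total)
    # upper tail P(X >= xb); sf(k-1) = P(X >= k).  n = 0 → p = 1.
    p = np.where(n > 0, stats.binom.sf(xb - 1, np.maximum(n, 1), q), 1.0)
    p = np.clip(p, 0.0, 1.0)
    if isinstance(bait_sum, pd.Series):
        return pd.Series(p, index=bait_sum.index, name="p_value")
    return p


def adjust_fdr(p_values: pd.Series | np.ndarray) -> pd.Series | np.ndarray:
    """Benjamini–Hochberg step-up adjustment (monotone, order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p_values
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ConfigurationError("p-values must lie in [0, 1]")
    adj = multipletests(p, method="fdr_bh")[1]
    if isinstance(p_values, pd.Series):
        return pd.Series(adj, index=p_values.index, name="fdr")
    return adj


def apply_significance_filters(
    records: pd.DataFrame, thresholds: Mapping[str, float] | None = None
) -> pd.DataFrame:
    """Flag records passing all three strict filters.

    Returns a copy with a boolean ``significant`` column; thresholds default
    to log2FC > 2, FDR < 0.05, detection fraction > 0.5.
    """
    th = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        th.update(thresholds)
    out = records.copy()
    out["significant"] = (
        (out["log2FC"] > th["log2fc_min"])
        & (out["fdr"] < th["fdr_max"])
        & (out["detection_fraction"] > th["detect_min"])
    )
    return out


def call_enrichment(
    quant_long: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    thresholds: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Run the full enrichment stage for every non-control bait group.

    Each (bait_id, condition) group's replicates are compared with all
    control runs.  The bait protein itself and the control's tag protein are
    retained in the table (the bait will trivially be called enriched).
    Returns a long frame with :data:`ENRICHMENT_COLUMNS`.
    """
    controls = sample_sheet[sample_sheet["condition"] == "control"]
    if controls.empty:
        raise ConfigurationError("enrichment requires at least one control run")
    ctrl_mat = _count_matrix(quant_long, controls["run_id"].tolist())
    results = []
    groups = sample_sheet[sample_sheet["condition"] != "control"]
    for (bait, cond), grp in groups.groupby(["bait_id", "condition"], sort=True):
        bait_mat = _count_matrix(quant_long, grp["run_id"].tolist())
        proteins = bait_mat.columns.union(ctrl_mat.columns)
        b = bait_mat.reindex(columns=proteins, fill_value=0.0)
        c = ctrl_mat.reindex(columns=proteins, fill_value=0.0)
        log2fc = compute_log2fc(b, c, pseudocount=pseudocount)
        xb = b.sum(axis=0).round().astype(np.int64)
        xc = c.sum(axis=0).round().astype(np.int64)
        p = test_enrichment(xb, xc, float(b.to_numpy().sum()), float(c.to_numpy().sum()))
        fdr = adjust_fdr(p)
        detection = (b > 0).mean(axis=0)
        rec = pd.DataFrame(
            {
                "bait_id": bait,
                "condition": cond,
                "protein_id": proteins,
                "log2FC": log2fc.to_numpy(),
                "p_value": np.asarray(p),
                "fdr": np.asarray(fdr),
                "detection_fraction": detection.to_numpy(),
            }
        )
        results.append(apply_significance_filters(rec, thresholds))
    return pd.concat(results, ignore_index=True)[list(ENRICHMENT_COLUMNS)]


def significant_sets(records: pd.DataFrame) -> dict[tuple[str, str], set[str]]:
    """Map (bait_id, condition) → set of significant prey IDs."""
    out: dict[tuple[str, str], set[str]] = {}
    for (bait, cond), grp in records.groupby(["bait_id", "condition"]):
        out[(bait, cond)] = set(grp.loc[grp["significant"], "protein_id"])
    return out
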