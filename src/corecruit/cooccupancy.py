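"""Co-occupancy of co-repressor targets with candidate DNA-binding cofactors.

Classifies targets by which cofactors are bound, quantifies how co-repressor
occupancy scales with the number of bound recruiters, compares wild-type and
recruiter-deletion binding after cross-experiment scaling, and tests
derepression of genes downstream of bound versus unbound regions.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateRegressorError,
    EmptyGroupError,
    EmptyJoinError,
    InsufficientGenesError,
    UnscalableProfileError,
)


def classify_targets(target_ids: Iterable[str], cofactor_pvals: pd.DataFrame,
                     p_bind: float = 0.001) -> pd.DataFrame:
    """Classify each target as co-occupied / not-co-occupied / no-data.

    A target is co-occupied iff at least one cofactor has binding p < p_bind
    there; targets absent from the p-table or with all entries missing are
    flagged no-data.  Returns one row per target with the set of bound
    cofactors (comma-joined, empty unless co-occupied).
    """
    target_ids = list(target_ids)
    present = [t for t in target_ids if t in cofactor_pvals.index]
    if not present:
        raise EmptyJoinError("no target overlaps the cofactor p-table")
    rows = []
    for t in target_ids:
        if t not in cofactor_pvals.index:
            rows.append((t, "no-data", ""))
            continue
        p = cofactor_pvals.loc[t]
        if p.isna().all():
            rows.append((t, "no-data", ""))
        elif (p < p_bind).any():
            bound = sorted(p.index[(p < p_bind).fillna(False)])
            rows.append((t, "co-occupied", ",".join(bound)))
        else:
            rows.append((t, "not-co-occupied", ""))
    return pd.DataFrame(rows, columns=["region_id", "status",
                                       "cofactors_bound"])


def count_bound_recruiters(cofactor_pvals: pd.DataFrame,
                           recruiters: Iterable[str],
                           p_bind: float = 0.001) -> pd.Series:
    """Number of recruiters bound (p < p_bind) per region; missing entries
    do not contribute to the count."""
    recruiters = list(recruiters)
    return (cofactor_pvals[recruiters] < p_bind).sum(axis=1)


def bin_by_recruiter_count(corepressor_z: pd.Series,
                           cofactor_pvals: pd.DataFrame,
                           recruiters: Iterable[str],
                           p_bind: float = 0.001) -> pd.DataFrame:
    """Mean and SE of co-repressor Z per recruiter-count bin.

    Single-member bins report se_z = 0 and are flagged ``single_member``.
    """
    recruiters = list(recruiters)
    if not recruiters:
        raise EmptyJoinError("recruiter set is empty")
    counts = count_bound_recruiters(
        cofactor_pvals.loc[corepressor_z.index], recruiters, p_bind)
    df = pd.DataFrame({"z": corepressor_z, "k": counts})
    rows = []
    for k, grp in df.groupby("k", sort=True):
        n = len(grp)
        se = float(grp["z"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        rows.append((int(k), n, float(grp["z"].mean()), se, n == 1))
    return pd.DataFrame(rows, columns=["k", "n_targets", "mean_z", "se_z",
                                       "single_member"])


def regress_on_count(occupancy_z, counts):
    """OLS of occupancy on recruiter count: (slope, intercept, r2, p)."""
    y = np.asarray(occupancy_z, dtype=float)
    x = np.asarray(counts, dtype=float)
    if len(y) < 3:
        raise DegenerateRegressorError("need at least 3 points")
    if np.ptp(x) == 0:
        raise DegenerateRegressorError("counts are constant")
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue ** 2, res.pvalue


def scale_to_reference(profiles: Mapping[str, pd.Series],
                       bound_region_ids: Iterable[str],
                       reference: str) -> dict[str, pd.Series]:
    """Scale each profile so its mean over bound regions matches the
    reference's, cancelling IP-efficiency differences between experiments."""
    bound = list(bound_region_ids)
    if not bound:
        raise EmptyJoinError("bound region set is empty")
    ref_mean = float(profiles[reference].loc[bound].mean())
    out = {}
    for name, prof in profiles.items():
        own = float(prof.loc[bound].mean())
        if own == 0:
            raise UnscalableProfileError(
                f"profile {name} has zero mean over bound regions")
        out[name] = prof * (ref_mean / own)
    return out


def group_comparison(wt_z: pd.Series, del_z: pd.Series,
                     groups: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Per-group wild-type vs deletion means, SEs, and paired t-test p.

    Profiles should be scaled with :func:`scale_to_reference` first.  For a
    group with fewer than 2 members means are reported and p is NaN; when
    the paired differences are identically zero the test reports p = 1.
    """
    rows = []
    for name, ids in groups.items():
        ids = list(ids)
        w = wt_z.loc[ids].to_numpy(dtype=float)
        d = del_z.loc[ids].to_numpy(dtype=float)
        n = len(ids)
        se_w = float(w.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        se_d = float(d.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        if n < 2:
            p = np.nan
        else:
            diff = w - d
            if np.allclose(diff.std(ddof=1), 0.0):
                p = 1.0 if np.allclose(diff, 0.0) else 0.0
            else:
                p = float(stats.ttest_rel(w, d).pvalue)
        rows.append((name, n, float(w.mean()), float(d.mean()),
                     se_w, se_d, p))
    return pd.DataFrame(rows, columns=["group", "n", "mean_wt", "mean_del",
                                       "se_wt", "se_del", "p_value"])


def _map_genes(expression: pd.Series, gene_map: pd.DataFrame) -> pd.DataFrame:
    gm = gene_map.dropna(subset=["region_id"])
    df = gm[["gene_id", "region_id"]].copy()
    df["change"] = expression.reindex(df["gene_id"]).to_numpy()
    return df.dropna(subset=["change"])


def derepression_test(expression: pd.Series, bound_ids: Iterable[str],
                      unbound_ids: Iterable[str],
                      gene_map: pd.DataFrame):
    """Welch t-test of downstream-gene expression change, bound vs unbound.

    Bound regions are those with binding p < 0.001, unbound those with
    p > 0.05 (callers make the selection); genes are mapped to regions via
    ``gene_map``.  Returns (mean_bound, mean_unbound, se_bound,
    se_unbound, p_value).
    """
    df = _map_genes(expression, gene_map)
    bound = df[df["region_id"].isin(set(bound_ids))]["change"].to_numpy()
    unbound = df[df["region_id"].isin(set(unbound_ids))]["change"].to_numpy()
    if len(bound) < 2 or len(unbound) < 2:
        raise EmptyGroupError("both groups need >= 2 mapped genes")
    t = stats.ttest_ind(bound, unbound, equal_var=False)
    return (float(bound.mean()), float(unbound.mean()),
            float(bound.std(ddof=1) / np.sqrt(len(bound))),
            float(unbound.std(ddof=1) / np.sqrt(len(unbound))),
            float(t.pvalue))


def decile_binning(expression: pd.Series, chip_z: pd.Series,
                   gene_map: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Mean ChIP signal per expression-change bin.

    Mapped genes are ranked by expression change (ascending; ties broken by
    stable gene order) and split into ``n_bins`` equal-count bins; the mean
    ChIP Z of each bin's regions is reported.
    """
    df = _map_genes(expression, gene_map)
    if len(df) < n_bins:
        raise InsufficientGenesError(
            f"{len(df)} mapped genes < {n_bins} bins")
    order = np.argsort(df["change"].to_numpy(), kind="stable")
    chunks = np.array_split(order, n_bins)
    z = chip_z.reindex(df["region_id"]).to_numpy()
    rows = []
    for b, idx in enumerate(chunks):
        rows.append((b, len(idx), float(np.nanmean(z[idx]))))
    return pd.DataFrame(rows, columns=["bin", "n_genes", "mean_chip_z"])
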