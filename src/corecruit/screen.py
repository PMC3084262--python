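"""Composite five-test screen ranking transcription factors as candidate
co-repressor recruiters.

For every factor in the panel the screen computes: (a) over-representation
of the factor's DNA-binding motif among co-repressor targets versus the
rest of the genome (one-sided binomial test on the fraction of regions
containing at least one PWM hit); (b) sensitivity — the fraction of
co-repressor targets bound by the factor; (c) specificity — the fraction of
the factor's targets bound by the co-repressor; (d) the Pearson correlation
of factor and co-repressor occupancy over the union of their top binding
quartiles; and (e) the same top-quartile correlation against downstream-gene
derepression in the co-repressor deletion strain.  Each factor receives a
percentile rank per test (ties mid-ranked) and the average percentile rank
over the tests for which it could be evaluated; factors are sorted by the
average.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegeneratePanelError,
    EmptyDenominatorError,
    EmptyInputError,
)
from .pwm import PWM, encode, window_scores, SCORE_BIN

TEST_NAMES = ["motif", "sensitivity", "specificity",
              "binding_corr", "expression_corr"]


@dataclass(frozen=True)
class MotifHit:
    region_id: str
    offset: int
    strand: str
    score: float
    p_value: float


def pwm_scan(sequence: str, pwm: PWM, p_threshold: float = 0.005,
             region_id: str = "") -> list[MotifHit]:
    """Scan both strands; a position is a hit iff the exact null p-value
    of its log-odds score is below ``p_threshold``.

    The p-value of a score is the upper-tail probability of the discretized
    score under the background base distribution, computed exactly by
    dynamic programming; it is a per-site call (no multiple-testing
    correction across positions).  Windows containing N never hit.
    """
    codes = encode(sequence)
    hits: list[MotifHit] = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        scores = window_scores(codes, mat)
        thr = mat.score_threshold(p_threshold)
        for off in np.nonzero(scores >= thr)[0]:
            s = int(scores[off])
            hits.append(MotifHit(region_id, int(off), strand,
                                 s * SCORE_BIN, mat.pvalue_of_score(s)))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def regions_with_hits(sequences: Mapping[str, str], pwm: PWM,
                      p_threshold: float = 0.005) -> set[str]:
    """Region ids containing at least one hit on either strand.

    Equivalent to running :func:`pwm_scan` per region but vectorized over a
    concatenation of all sequences (regions separated by N runs so windows
    never straddle a boundary).
    """
    ids = list(sequences)
    if not ids:
        return set()
    L = len(pwm)
    sep = np.full(L, 4, dtype=np.int8)
    parts, bounds, pos = [], [], 0
    for rid in ids:
        c = encode(sequences[rid])
        bounds.append(pos)
        parts.extend([c, sep])
        pos += len(c) + L
    concat = np.concatenate(parts)
    bounds = np.asarray(bounds)
    hit_regions: set[str] = set()
    for mat in (pwm, pwm.reverse_complement()):
        scores = window_scores(concat, mat)
        thr = mat.score_threshold(p_threshold)
        hit_pos = np.nonzero(scores >= thr)[0]
        if len(hit_pos):
            idx = np.searchsorted(bounds, hit_pos, side="right") - 1
            hit_regions.update(ids[i] for i in np.unique(idx))
    return hit_regions


def motif_overrepresentation(target_hit_count: int, n_targets: int,
                             background_hit_count: int, n_background: int
                             ) -> float:
    """One-sided binomial p for motif enrichment among targets.

    The null success probability is the background hit fraction, floored at
    ``1/(2*n_background)`` so an empty background cannot produce p = 0.
    """
    if n_targets == 0 or n_background == 0:
        raise EmptyInputError("both region sets must be non-empty")
    rate = max(background_hit_count / n_background, 1.0 / (2 * n_background))
    rate = min(rate, 1.0)
    return float(stats.binom.sf(target_hit_count - 1, n_targets, rate))


def motif_test(sequences: Mapping[str, str], pwm: PWM,
               target_ids: Iterable[str], p_threshold: float = 0.005
               ) -> float:
    """Enrichment p-value of a motif among targets vs. the rest."""
    targets = set(target_ids) & set(sequences)
    background = set(sequences) - targets
    if not targets or not background:
        raise EmptyInputError("both region sets must be non-empty")
    hits = regions_with_hits(sequences, pwm, p_threshold)
    return motif_overrepresentation(len(hits & targets), len(targets),
                                    len(hits & background), len(background))


def sensitivity(tf_bound_ids: Iterable[str],
                tup1_target_ids: Iterable[str]) -> float:
    """Fraction of co-repressor targets bound by the factor."""
    targets = set(tup1_target_ids)
    if not targets:
        raise EmptyDenominatorError("co-repressor target set is empty")
    return len(set(tf_bound_ids) & targets) / len(targets)


def specificity(tf_bound_ids: Iterable[str],
                tup1_target_ids: Iterable[str]) -> float:
    """Fraction of the factor's targets bound by the co-repressor.

    Returns NaN (test missing) when the factor has no targets.
    """
    bound = set(tf_bound_ids)
    if not bound:
        return float("nan")
    return len(bound & set(tup1_target_ids)) / len(bound)


def _top_quartile_idx(v: np.ndarray) -> np.ndarray:
    k = int(np.ceil(len(v) / 4))
    return np.argsort(-v, kind="stable")[:k]


def quartile_correlation(x, y, min_pairs: int = 8,
                         subset: str = "union") -> float:
    """Pearson r over the union (or intersection) of the top quartiles.

    Complete pairs only; quartile membership is by rank with ties broken by
    stable index order.  Returns NaN when fewer than ``min_pairs`` complete
    pairs exist or the selected subset has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < min_pairs:
        return float("nan")
    ix, iy = _top_quartile_idx(x), _top_quartile_idx(y)
    if subset == "union":
        sel = np.union1d(ix, iy)
    elif subset == "intersection":
        sel = np.intersect1d(ix, iy)
    else:
        raise ValueError(f"unknown subset rule {subset!r}")
    if len(sel) < 2 or np.ptp(x[sel]) == 0 or np.ptp(y[sel]) == 0:
        return float("nan")
    return float(stats.pearsonr(x[sel], y[sel])[0])


def percent_ranks(scores: Mapping[str, float]) -> dict[str, float]:
    """Ascending mid-rank percentiles over the non-missing scores.

    Percent rank = 100 * rank / n_nonmissing, ties averaged; an untied best
    score gets 100.  Missing (NaN) scores stay missing.
    """
    names = list(scores)
    vals = np.array([scores[n] for n in names], dtype=float)
    ok = np.isfinite(vals)
    if ok.sum() < 2:
        raise DegeneratePanelError("need >= 2 non-missing scores")
    ranks = stats.rankdata(vals[ok]) * 100.0 / ok.sum()
    out = {n: float("nan") for n in names}
    for n, r in zip(np.array(names)[ok], ranks):
        out[n] = float(r)
    return out


def aggregate_ranks(rank_table: pd.DataFrame) -> pd.DataFrame:
    """Average the available percentile ranks and sort the panel.

    ``rank_table`` holds one row per factor and one column per test (NaN =
    test unavailable).  The average uses only available tests; factors with
    no available test are excluded.  Sort order: average rank descending,
    then number of tests used descending, then factor name.
    """
    n_used = rank_table.notna().sum(axis=1)
    out = rank_table.copy()
    out["average_rank"] = rank_table.mean(axis=1, skipna=True)
    out["n_tests_used"] = n_used
    out = out[n_used > 0]
    out = out.sort_index()  # name tie-break, then stable sorts below
    out = out.sort_values("n_tests_used", ascending=False, kind="stable")
    out = out.sort_values("average_rank", ascending=False, kind="stable")
    return out


def run_screen(occupancy, tup1_target_ids: Iterable[str],
               expression: pd.Series | None = None,
               gene_map: pd.DataFrame | None = None,
               sequences: Mapping[str, str] | None = None,
               pwms: Mapping[str, PWM] | None = None,
               p_bind: float = 0.001, motif_p: float = 0.005,
               quartile_subset: str = "union") -> pd.DataFrame:
    """Score every factor on the five tests and rank the panel.

    Tests that cannot be computed for a factor (no PWM, no targets, too few
    complete pairs) are left missing and excluded from its average, as the
    composite screen prescribes.  Returns the scorecard sorted by average
    percentile rank (columns: raw_<test>, rank_<test>, average_rank,
    n_tests_used).
    """
    targets = set(tup1_target_ids)
    tup1_z = occupancy.corepressor_values
    raw = {t: {} for t in TEST_NAMES}

    expr_by_region = None
    if expression is not None and gene_map is not None:
        gm = gene_map.dropna(subset=["region_id"])
        expr_by_region = pd.Series(
            expression.reindex(gm["gene_id"]).to_numpy(),
            index=gm["region_id"].to_numpy())

    for f in occupancy.factors:
        pvals = occupancy.pvalues[f]
        ratios = occupancy.ratios[f]
        tf_bound = set(pvals.index[(pvals < p_bind).fillna(False)])

        if sequences is not None and pwms is not None and f in pwms:
            p_enr = motif_test(sequences, pwms[f], targets, motif_p)
            raw["motif"][f] = -np.log10(max(p_enr, 1e-300))
        else:
            raw["motif"][f] = float("nan")
        raw["sensitivity"][f] = sensitivity(tf_bound, targets)
        raw["specificity"][f] = specificity(tf_bound, targets)
        raw["binding_corr"][f] = quartile_correlation(
            tup1_z, ratios, subset=quartile_subset)
        if expr_by_region is not None:
            common = expr_by_region.index.intersection(ratios.index)
            raw["expression_corr"][f] = quartile_correlation(
                expr_by_region.loc[common], ratios.loc[common],
                subset=quartile_subset)
        else:
            raw["expression_corr"][f] = float("nan")

    card = pd.DataFrame(index=list(occupancy.factors))
    rank_cols = {}
    for t in TEST_NAMES:
        card[f"raw_{t}"] = pd.Series(raw[t])
        col = pd.Series(raw[t])
        if np.isfinite(col).sum() >= 2:
            rank_cols[f"rank_{t}"] = pd.Series(percent_ranks(raw[t]))
        else:
            rank_cols[f"rank_{t}"] = pd.Series(float("nan"),
                                               index=card.index)
    ranks = pd.DataFrame(rank_cols, index=card.index)
    agg = aggregate_ranks(ranks)
    return card.join(agg, how="right")
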