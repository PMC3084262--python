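"""Reference study designs on synthetic data.

Each function assembles one complete in-silico experiment — generation,
analysis, and a summary measurement — so that the pipeline's statistical
behaviour (parameter recovery, screen recovery, peak-caller calibration and
recall, count monotonicity, model improvement) can be measured end to end
from a single seed.  Problem sizes default to scales where each study runs
in seconds to a couple of minutes on one CPU; they are configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import peaks as pk
from . import regression as rg
from .cooccupancy import (bin_by_recruiter_count, count_bound_recruiters,
                          regress_on_count)
from .pwm import PWM
from .screen import run_screen
from .simulate import (
    DEFAULT_WEIGHTS,
    GeneratorConfig,
    default_gene_map,
    generate_dataset,
    generate_expression,
    generate_sequences,
)

NEW_RECRUITERS = ["YAP6", "CIN5", "PHD1", "SKN7"]
KNOWN_RECRUITERS = [f for f in DEFAULT_WEIGHTS if f not in NEW_RECRUITERS]


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 7919 + k) % (2 ** 31)


# --- regression parameter recovery -----------------------------------------


def parameter_recovery_study(seed: int, n_regions: int = 6000,
                             n_decoys: int = 3):
    """Full regression pipeline against the planted truth.

    Generates a dataset at the default study conditions plus ``n_decoys``
    zero-weight decoy factors, runs impute -> univariate screen -> CV fit ->
    drop-nonsignificant, and reports the recovered model together with the
    maximal absolute weight error and whether the planted active set was
    recovered exactly.
    """
    recruiters = list(DEFAULT_WEIGHTS)
    decoys = [f"DEC{i:02d}" for i in range(n_decoys)]
    cfg = GeneratorConfig(n_regions=n_regions,
                          factors=recruiters + decoys, seed=seed)
    _, occ, truth = generate_dataset(cfg)
    model = rg.full_pipeline(occ.corepressor_values, occ.recruiter_ratios,
                             seed=seed)
    errors = {f: abs(model.weights.get(f, 0.0) - beta)
              for f, beta in truth.planted_weights.items()}
    exact_set = sorted(model.included) == sorted(recruiters)
    return {
        "model": model,
        "truth": truth,
        "max_weight_error": max(errors.values()),
        "active_set_recovered": exact_set,
    }


# --- recruiter screen recovery ----------------------------------------------


def make_pwm_panel(factors, length: int = 8, seed: int = 0,
                   consensus_weight: float = 0.85) -> dict[str, PWM]:
    """One informative random PWM per factor (shared uniform background)."""
    rng = np.random.default_rng(seed)
    panel = {}
    off = (1.0 - consensus_weight) / 3.0
    for f in factors:
        cons = rng.integers(0, 4, length)
        matrix = np.full((length, 4), off)
        matrix[np.arange(length), cons] = consensus_weight
        panel[f] = PWM(f, matrix)
    return panel


def screen_recovery_study(seed: int, n_regions: int = 2000,
                          n_decoys: int = 50, top_n: int = 15,
                          min_weight: float = 0.19):
    """Five-test screen over planted recruiters plus rate-matched decoys.

    Decoy factors share the recruiters' binding rate but have zero weight in
    the co-repressor model.  Each factor's motif is planted at its bound
    regions (binding p < 0.001), so the motif test sees realistic planted
    signal.  Reports the scorecard and whether every planted recruiter with
    weight >= ``min_weight`` lands in the top ``top_n``.
    """
    recruiters = list(DEFAULT_WEIGHTS)
    decoys = [f"DEC{i:02d}" for i in range(n_decoys)]
    factors = recruiters + decoys
    cfg = GeneratorConfig(n_regions=n_regions, factors=factors,
                          region_min_bp=200, region_max_bp=500, seed=seed)
    regions, occ, truth = generate_dataset(cfg)

    pwms = make_pwm_panel(factors, seed=_sub_seed(seed, 1))
    planting = {
        f: [str(r) for r in
            occ.pvalues.index[(occ.pvalues[f] < 0.001).fillna(False)]]
        for f in factors
    }
    records, _ = generate_sequences(regions, pwms, planting,
                                    seed=_sub_seed(seed, 2))
    sequences = {rec.id: str(rec.seq) for rec in records}

    gene_map = default_gene_map(regions)
    expression = generate_expression(occ, truth, gene_map,
                                     seed=_sub_seed(seed, 3))

    card = run_screen(occ, truth.planted_target_ids,
                      expression=expression, gene_map=gene_map,
                      sequences=sequences, pwms=pwms)
    top = set(card.index[:top_n])
    wanted = [f for f, b in truth.planted_weights.items() if b >= min_weight]
    recovered = [f for f in wanted if f in top]
    return {
        "scorecard": card,
        "wanted": wanted,
        "recovered": recovered,
        "all_recovered": len(recovered) == len(wanted),
    }


# --- peak caller calibration and recall -------------------------------------


def _element_profile(values, element_bp=800, chrom="chr1"):
    n = len(values)
    return pd.DataFrame({
        "region_id": [f"{chrom}_e{i}" for i in range(n)],
        "chrom": chrom,
        "start": np.arange(n) * element_bp,
        "end": (np.arange(n) + 1) * element_bp,
        "value": values,
    })


def peak_null_calibration_study(seed: int, n_chroms: int = 1000,
                                n_elements: int = 100, fdr: float = 0.001):
    """Realized window false-positive rate on pure-null chromosomes."""
    rng = np.random.default_rng(seed)
    n_sig = n_win = 0
    for _ in range(n_chroms):
        prof = _element_profile(rng.normal(0.0, 1.0, n_elements))
        windows = pk.call_windows(prof)
        n_win += len(windows)
        n_sig += len(pk.fdr_filter(windows, fdr=fdr))
    return {"false_positive_rate": n_sig / n_win, "n_windows": n_win}


def peak_recovery_study(seed: int, n_chroms: int = 100,
                        n_elements: int = 100, amplitude: float = 4.0,
                        span_elements: int = 3, element_bp: int = 800,
                        fdr: float = 0.001):
    """Recall of planted rectangular peaks (>= 4 sigma, >= 1 kb wide).

    The default plants 4-sigma blocks spanning three 800 bp elements
    (2.4 kb).  Recall falls off for blocks much narrower than two window
    widths because the Benjamini-Hochberg cut at FDR 0.001 is extremely
    strict for a window mean over few elements.
    """
    rng = np.random.default_rng(seed)
    recovered = inside = 0
    for _ in range(n_chroms):
        values = rng.normal(0.0, 1.0, n_elements)
        start_el = int(rng.integers(5, n_elements - 5 - span_elements))
        values[start_el:start_el + span_elements] += amplitude
        prof = _element_profile(values, element_bp=element_bp)
        found = pk.call_peaks(prof, fdr=fdr)
        span = (start_el * element_bp, (start_el + span_elements) * element_bp)
        hit = found[(found["window_start"] < span[1])
                    & (found["window_end"] > span[0])]
        if len(hit):
            recovered += 1
            rep = prof.set_index("region_id").loc[
                hit.iloc[0]["representative_element"]]
            if span[0] <= rep["start"] and rep["end"] <= span[1]:
                inside += 1
    return {
        "recall": recovered / n_chroms,
        "representative_inside_rate": inside / max(recovered, 1),
    }


# --- co-occupancy monotonicity and model improvement ------------------------


def count_monotonicity_study(seed: int, n_regions: int = 20000,
                             max_k: int = 4):
    """Mean co-repressor Z per recruiter-count bin at genome scale."""
    cfg = GeneratorConfig(n_regions=n_regions, seed=seed)
    _, occ, _ = generate_dataset(cfg)
    bins = bin_by_recruiter_count(occ.corepressor_values, occ.pvalues,
                                  occ.factors)
    bins = bins[bins["k"] <= max_k].reset_index(drop=True)
    means = bins["mean_z"].to_numpy()
    counts = count_bound_recruiters(occ.pvalues, occ.factors)
    _, _, r2, _ = regress_on_count(occ.corepressor_values, counts)
    return {
        "bins": bins,
        "non_decreasing": bool((np.diff(means) >= 0).all()),
        "count_regression_r2": r2,
    }


def model_improvement_study(seed: int, n_regions: int = 2000):
    """Does adding the four new recruiters improve the five-recruiter base
    model?  Partial F-test on the full data."""
    base_set = [f for f in KNOWN_RECRUITERS]
    cfg = GeneratorConfig(n_regions=n_regions, seed=seed)
    _, occ, _ = generate_dataset(cfg)
    y = occ.corepressor_values
    filled = rg.impute_missing(occ.recruiter_ratios, n_draws=1,
                               seed=seed).draws[0]
    base = rg.fit_with_cv(y, filled[base_set], n_imputations=1, seed=seed)
    ext = rg.fit_with_cv(y, filled[base_set + NEW_RECRUITERS],
                         n_imputations=1, seed=seed)
    delta_r2, p = rg.compare_models(base, ext, y, filled)
    return {"delta_r2": delta_r2, "p_value": p,
            "r2_base": base.r2_heldout, "r2_extended": ext.r2_heldout}
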