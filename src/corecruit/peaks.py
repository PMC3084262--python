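"""Sliding-window peak calling on standardized array profiles.

The workflow mirrors classic ChIP-chip peak finding on spotted arrays:
replicates are standardized and combined by the per-element median, windows
of 1 kb are slid in 250 bp steps along each chromosome, window means are
tested against a Gaussian background null fitted robustly from the
sub-median half of the data, window p-values are corrected by
Benjamini-Hochberg FDR, artifactual peaks are removed with a mock-IP
filter, and neighbouring peaks within 1 kb are collapsed.  The highest
scoring array element within each collapsed peak is its representative.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (
    DegenerateProfileError,
    DegenerateReplicateError,
    EmptyInputError,
    MissingMockCoverageError,
)

PROFILE_COLUMNS = ["region_id", "chrom", "start", "end", "value"]


def make_profile(regions: pd.DataFrame, values) -> pd.DataFrame:
    """Assemble a signal profile (region coordinates + standardized values).

    Output is sorted by (chrom, start); values must be finite.
    """
    prof = regions[["region_id", "chrom", "start", "end"]].copy()
    prof["value"] = np.asarray(values, dtype=float)
    if not np.isfinite(prof["value"]).all():
        raise EmptyInputError("profile values must be finite")
    return prof.sort_values(["chrom", "start"], kind="stable") \
               .reset_index(drop=True)


def standardize_replicates(replicates) -> np.ndarray:
    """Z-transform each replicate and take the per-element median.

    Each replicate is standardized to mean 0, sd 1 across its elements
    (so IP-efficiency differences between arrays cancel), and the combined
    profile is the element-wise median across the standardized replicates.
    """
    reps = [np.asarray(r, dtype=float) for r in replicates]
    if not reps:
        raise EmptyInputError("at least one replicate is required")
    n = len(reps[0])
    if any(len(r) != n for r in reps):
        raise EmptyInputError("replicates must have equal lengths")
    z = []
    for i, r in enumerate(reps):
        sd = r.std(ddof=0)
        if sd == 0:
            raise DegenerateReplicateError(f"replicate {i} has zero variance")
        z.append((r - r.mean()) / sd)
    return np.median(np.vstack(z), axis=0)


def estimate_background(values) -> tuple[float, float]:
    """Fit the null Gaussian by reflecting the sub-median tail.

    Enrichment is assumed one-sided (signal only inflates the upper tail),
    so mu is the median and sigma is estimated from deviations of the
    lower half about the median — equivalent to fitting a Gaussian to the
    lower half reflected about the median.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise DegenerateProfileError("need at least 2 elements")
    mu = float(np.median(v))
    lower = v[v <= mu]
    sigma = float(np.sqrt(np.mean((lower - mu) ** 2)))
    if sigma == 0:
        raise DegenerateProfileError("profile is constant")
    return mu, sigma


def call_windows(profile: pd.DataFrame, window_bp: int = 1000,
                 step_bp: int = 250,
                 background: tuple[float, float] | None = None
                 ) -> pd.DataFrame:
    """Score sliding windows and attach Gaussian-null p-values.

    Per chromosome, candidate windows start at multiples of ``step_bp``
    and must fit within the span of the array elements; on chromosomes
    shorter than one window a single overhanging window anchored at 0 is
    allowed.  A window is scored by the mean standardized value of the
    elements it overlaps; windows covering no element are skipped.  The
    p-value of a window with ``n`` elements and mean ``m`` is the upper
    tail of Normal(mu, sigma/sqrt(n)) for the fitted background (mu, sigma).
    """
    if window_bp < step_bp or step_bp <= 0:
        raise EmptyInputError("need window_bp >= step_bp > 0")
    if len(profile) == 0:
        raise EmptyInputError("empty profile")
    if background is None:
        background = estimate_background(profile["value"])
    mu, sigma = background

    out = []
    for chrom, grp in profile.groupby("chrom", sort=True):
        grp = grp.sort_values("start", kind="stable")
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        values = grp["value"].to_numpy()
        span = int(ends.max())
        if span >= window_bp:
            w_starts = np.arange(0, span - window_bp + 1, step_bp)
        else:
            w_starts = np.array([0])
        w_ends = w_starts + window_bp
        # elements overlap [ws, we) iff start < we and end > ws;
        # elements on a chromosome are non-overlapping and sorted
        i0 = np.searchsorted(ends, w_starts, side="right")
        i1 = np.searchsorted(starts, w_ends, side="left")
        for ws, we, a, b in zip(w_starts, w_ends, i0, i1):
            if b > a:
                out.append((chrom, int(ws), int(we),
                            float(np.mean(values[a:b])), int(b - a)))
    windows = pd.DataFrame(
        out, columns=["chrom", "window_start", "window_end",
                      "mean_z", "n_elements"])
    se = sigma / np.sqrt(windows["n_elements"])
    windows["p_value"] = stats.norm.sf(windows["mean_z"], loc=mu, scale=se)
    return windows


def fdr_filter(windows: pd.DataFrame, fdr: float = 0.001) -> pd.DataFrame:
    """Benjamini-Hochberg over all tested windows; retain q < fdr."""
    windows = windows.copy()
    if len(windows) == 0:
        windows["q_value"] = pd.Series(dtype=float)
        return windows
    _, q, _, _ = multipletests(windows["p_value"], method="fdr_bh")
    windows["q_value"] = q
    return windows[windows["q_value"] < fdr].reset_index(drop=True)


def attach_representatives(peaks: pd.DataFrame,
                           profile: pd.DataFrame) -> pd.DataFrame:
    """Attach the highest-valued overlapping element to each peak."""
    peaks = peaks.copy()
    rep_id, rep_z = [], []
    for _, pk in peaks.iterrows():
        sel = profile[(profile["chrom"] == pk["chrom"])
                      & (profile["start"] < pk["window_end"])
                      & (profile["end"] > pk["window_start"])]
        if len(sel) == 0:
            raise EmptyInputError("peak covers no element")
        best = sel.loc[sel["value"].idxmax()]
        rep_id.append(best["region_id"])
        rep_z.append(float(best["value"]))
    peaks["representative_element"] = rep_id
    peaks["representative_z"] = rep_z
    return peaks


def mock_filter(peaks: pd.DataFrame, mock_profile: pd.DataFrame,
                min_diff: float = 1.0, max_mock_z: float = 2.0
                ) -> pd.DataFrame:
    """Drop peaks explained by the mock IP.

    A peak is retained iff, at its representative element, the signal Z
    exceeds the mock Z by more than ``min_diff`` and the mock Z itself is
    below ``max_mock_z``.
    """
    mock = mock_profile.set_index("region_id")["value"]
    missing = set(peaks["representative_element"]) - set(mock.index)
    if missing:
        raise MissingMockCoverageError(
            f"mock profile missing elements: {sorted(missing)[:5]}")
    mock_z = mock.loc[peaks["representative_element"]].to_numpy()
    keep = ((peaks["representative_z"].to_numpy() - mock_z) > min_diff) \
        & (mock_z < max_mock_z)
    return peaks[keep].reset_index(drop=True)


def collapse_peaks(peaks: pd.DataFrame, gap_bp: int = 1000) -> pd.DataFrame:
    """Merge neighbouring peaks within ``gap_bp`` on the same chromosome.

    The merged span is the union of windows; p/q are the best (minimum)
    over the merged windows, mean_z is taken from the minimum-p window, and
    the representative element is the highest-valued representative across
    the merged peaks.  The operation is idempotent and independent of the
    input row order.
    """
    if len(peaks) == 0:
        return peaks.copy()
    peaks = peaks.sort_values(["chrom", "window_start"], kind="stable")
    merged = []
    cur = None
    for _, pk in peaks.iterrows():
        if cur is not None and pk["chrom"] == cur["chrom"] \
                and pk["window_start"] - cur["window_end"] <= gap_bp:
            cur["window_end"] = max(cur["window_end"], pk["window_end"])
            if pk["p_value"] < cur["p_value"]:
                cur["p_value"] = pk["p_value"]
                cur["mean_z"] = pk["mean_z"]
            if "q_value" in pk.index:
                cur["q_value"] = min(cur["q_value"], pk["q_value"])
            if pk["representative_z"] > cur["representative_z"]:
                cur["representative_z"] = pk["representative_z"]
                cur["representative_element"] = pk["representative_element"]
        else:
            if cur is not None:
                merged.append(cur)
            cur = pk.copy()
    merged.append(cur)
    return pd.DataFrame(merged).reset_index(drop=True)


def call_peaks(profile: pd.DataFrame, mock_profile: pd.DataFrame | None = None,
               window_bp: int = 1000, step_bp: int = 250, fdr: float = 0.001,
               gap_bp: int = 1000,
               background: tuple[float, float] | None = None) -> pd.DataFrame:
    """Full pipeline: windows -> FDR -> mock filter -> collapse."""
    windows = call_windows(profile, window_bp=window_bp, step_bp=step_bp,
                           background=background)
    sig = fdr_filter(windows, fdr=fdr)
    sig = attach_representatives(sig, profile)
    if mock_profile is not None and len(sig):
        sig = mock_filter(sig, mock_profile)
    return collapse_peaks(sig, gap_bp=gap_bp)


def peaks_to_bed(peaks: pd.DataFrame) -> pd.DataFrame:
    """BED6 view of a peak table (score = representative Z x 100)."""
    return pd.DataFrame({
        "chrom": peaks["chrom"],
        "start": peaks["window_start"].astype(int),
        "end": peaks["window_end"].astype(int),
        "name": peaks["representative_element"],
        "score": np.rint(peaks["representative_z"] * 100).astype(int),
        "strand": ".",
    })
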