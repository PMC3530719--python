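"""Differentially methylated region (DMR) detection via Hotelling's T².

Each fragment contributes a triplet (n_plus, n_zero, n_minus): how many
samples called it +1, 0, -1. The null hypothesis is the genome-wide triplet
distribution with mean ``mu0`` and covariance ``B`` estimated over all
fragments. Within each genome-partition window holding n >= 4 fragments the
statistic

    T2 = n * (mean_X - mu0)^T S^{-1} (mean_X - mu0)

uses the window's own sample covariance S (divisor n - 1), and

    F = (n - p) / (p * (n - 1)) * T2

follows an F distribution with (p, n - p) degrees of freedom under the null.

When the call matrix is complete, each triplet sums to the sample count, the
three components are linearly dependent and S has rank at most 2; S is
therefore inverted by Moore-Penrose pseudo-inverse and p is taken as the
effective rank of S (<= 3), which keeps the statistic well defined for both
complete and missing-data inputs. p-values are Benjamini-Hochberg adjusted
across windows; a window is a DMR when its adjusted p-value is below 0.01
(a flag allows thresholding the raw p-value instead). Hyper/hypo direction
is the signed excess of the +1 versus -1 mean frequency relative to
baseline, and the reported score is -log10(p) for hyper-methylated windows
and +log10(p) (negative) for hypo-methylated ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from bedmr.core import MethylCallSet, WindowPartition

DEFAULT_ALPHA = 1e-2
MIN_FRAGMENTS = 4  # n - 1 >= 3 with three states
_P_FLOOR = 1e-300  # keeps log10(p) finite for astronomically small p

RESULT_COLUMNS = [
    "window", "chrom", "start", "end", "n", "T2", "F", "rank", "p", "q",
    "mean_plus", "mean_zero", "mean_minus", "direction", "score",
]


@dataclass
class Baseline:
    """Genome-wide triplet mean ``mu0`` and covariance ``B``."""

    mu0: np.ndarray
    B: np.ndarray
    n_fragments: int = 0

    def __post_init__(self):
        self.mu0 = np.asarray(self.mu0, dtype=float).reshape(3)
        self.B = np.asarray(self.B, dtype=float).reshape(3, 3)
        if (self.mu0 < 0).any():
            raise ValueError("baseline mean components must be non-negative")
        if not np.allclose(self.B, self.B.T):
            raise ValueError("baseline covariance must be symmetric")


@dataclass
class HotellingResult:
    n: int
    T2: float
    F: float
    p: float
    rank: int
    mean: np.ndarray


def estimate_baseline(triplets) -> Baseline:
    """Mean and sample covariance (divisor n-1) of all fragments' triplets."""
    X = np.asarray(triplets, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("triplets must be an (n, 3) array")
    if X.shape[0] < 4:
        raise ValueError(f"need at least 4 fragments to estimate a baseline, got {X.shape[0]}")
    mu0 = X.mean(axis=0)
    B = np.cov(X.T, ddof=1)
    return Baseline(mu0, B, n_fragments=X.shape[0])


def hotelling_test(window_triplets, baseline: Baseline) -> HotellingResult:
    """Hotelling T² of one window's triplets against the baseline mean.

    Requires n >= 4 fragments. Uses the pseudo-inverse of the window
    covariance and sets the dimension parameter to its effective rank.
    """
    X = np.asarray(window_triplets, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("window triplets must be an (n, 3) array")
    n = X.shape[0]
    if n < MIN_FRAGMENTS:
        raise ValueError(f"Hotelling test needs n >= {MIN_FRAGMENTS} fragments, got {n}")
    mu_x = X.mean(axis=0)
    d = mu_x - baseline.mu0
    S = np.cov(X.T, ddof=1)
    rank = int(np.linalg.matrix_rank(S, hermitian=True))
    if rank == 0:
        # zero within-window variance: either exactly at baseline or
        # deterministically off it
        if np.allclose(d, 0.0):
            return HotellingResult(n, 0.0, 0.0, 1.0, 0, mu_x)
        return HotellingResult(n, np.inf, np.inf, 0.0, 0, mu_x)
    if np.allclose(d, 0.0):
        return HotellingResult(n, 0.0, 0.0, 1.0, rank, mu_x)
    T2 = float(n * d @ np.linalg.pinv(S, hermitian=True) @ d)
    T2 = max(T2, 0.0)
    p_dim = min(rank, n - 1)
    F = (n - p_dim) / (p_dim * (n - 1)) * T2
    p = float(stats.f.sf(F, p_dim, n - p_dim))
    return HotellingResult(n, T2, float(F), p, p_dim, mu_x)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([])
    if ((p <= 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _direction(mean: np.ndarray, mu0: np.ndarray) -> str:
    d_plus = mean[0] - mu0[0]
    d_minus = mean[2] - mu0[2]
    excess = d_plus - d_minus
    if excess > 0:
        return "hyper"
    if excess < 0:
        return "hypo"
    # tie: side of the larger absolute component deviation
    return "hyper" if d_plus >= 0 else "hypo"


def scan_windows(
    callset: MethylCallSet,
    partition: WindowPartition,
    baseline: Baseline | None = None,
    min_fragments: int = MIN_FRAGMENTS,
) -> pd.DataFrame:
    """Run the Hotelling test in every window with enough fragments.

    Fragments are assigned to windows by midpoint. The baseline defaults to
    the genome-wide estimate over this call set's own fragments. Windows
    with fewer than ``min_fragments`` fragments are skipped (not rows).
    BH adjustment runs across all tested windows.
    """
    triplets = callset.triplets()
    if baseline is None:
        baseline = estimate_baseline(triplets)
    mid = callset.midpoints()
    frag_window = np.full(len(mid), -1, dtype=np.int64)
    for chrom, grp in callset.fragments.groupby("chrom", sort=False):
        rows = grp.index.to_numpy()
        frag_window[rows] = partition.locate(chrom, mid[rows])

    win = partition.windows
    records = []
    for w in np.unique(frag_window):
        if w < 0:
            continue
        idx = np.nonzero(frag_window == w)[0]
        if len(idx) < min_fragments:
            continue
        res = hotelling_test(triplets[idx], baseline)
        direction = _direction(res.mean, baseline.mu0)
        p_safe = max(res.p, _P_FLOOR)
        score = -np.log10(p_safe) if direction == "hyper" else np.log10(p_safe)
        records.append(
            (
                int(w), win.at[w, "chrom"], int(win.at[w, "start"]), int(win.at[w, "end"]),
                res.n, res.T2, res.F, res.rank, p_safe, np.nan,
                res.mean[0], res.mean[1], res.mean[2], direction, score,
            )
        )
    out = pd.DataFrame(records, columns=RESULT_COLUMNS)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def call_dmrs(
    results: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    use_adjusted: bool = True,
) -> pd.DataFrame:
    """Windows whose (adjusted, by default) p-value falls below ``alpha``."""
    if len(results) == 0:
        return results.copy()
    col = "q" if use_adjusted else "p"
    return results[results[col] < alpha].reset_index(drop=True)


def dmr_midpoints(dmrs: pd.DataFrame) -> pd.DataFrame:
    """Point representation (chrom, pos) of DMR windows for distance work."""
    return pd.DataFrame(
        {"chrom": dmrs["chrom"], "pos": (dmrs["start"] + dmrs["end"]) // 2}
    )
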