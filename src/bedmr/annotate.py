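"""Interval annotation and cohort recurrence summaries for DMRs/BEDMRs.

``overlap_annotate`` relates each region to a feature track (genes, fragile
sites): exact / contains / contained / partial overlap, or proximal within a
distance limit. ``recurrence_table`` reports, per region, the fraction of
samples with a remarkable copy state (amplified/deleted) and methylation
state (+1/-1), flagging regions where either fraction reaches a cutoff
(20% of patients by default).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bedmr.core import MethylCallSet, WindowPartition

ANNOT_COLUMNS = [
    "region", "chrom", "start", "end", "feature", "overlap_type", "distance",
]


def _classify(rs, re_, fs, fe) -> str:
    if rs == fs and re_ == fe:
        return "exact"
    if rs <= fs and re_ >= fe:
        return "contains"
    if fs <= rs and fe >= re_:
        return "contained"
    return "partial"


def overlap_annotate(
    regions: pd.DataFrame,
    features: pd.DataFrame,
    proximal_limit: float = 1_000_000.0,
) -> pd.DataFrame:
    """Relate regions (chrom/start/end) to features (chrom/start/end[,name]).

    Emits one row per overlapping feature; for regions with no overlap, one
    row for the nearest feature within ``proximal_limit`` (overlap type
    ``proximal``, with the gap distance), else a single row with feature
    ``NA`` and type ``none``.
    """
    feats = features.copy()
    if "name" not in feats.columns:
        feats["name"] = [f"feature_{i + 1}" for i in range(len(feats))]
    by_chrom = {c: g.sort_values("start") for c, g in feats.groupby("chrom", sort=False)}
    rows = []
    for r, reg in enumerate(regions.itertuples(index=False)):
        chrom, rs, re_ = reg.chrom, int(reg.start), int(reg.end)
        sub = by_chrom.get(chrom)
        hit = False
        best_gap, best_name = np.inf, None
        if sub is not None:
            for f in sub.itertuples(index=False):
                fs, fe = int(f.start), int(f.end)
                if fs < re_ and fe > rs:  # overlap
                    rows.append(
                        (r, chrom, rs, re_, f.name, _classify(rs, re_, fs, fe), 0.0)
                    )
                    hit = True
                else:
                    gap = fs - re_ if fs >= re_ else rs - fe
                    if gap < best_gap:
                        best_gap, best_name = gap, f.name
        if not hit:
            if best_name is not None and best_gap <= proximal_limit:
                rows.append((r, chrom, rs, re_, best_name, "proximal", float(best_gap)))
            else:
                rows.append((r, chrom, rs, re_, None, "none", np.nan))
    return pd.DataFrame(rows, columns=ANNOT_COLUMNS)


def _sample_region_methylation(callset: MethylCallSet, rows: np.ndarray) -> np.ndarray:
    """Per-sample region methylation state from its fragments' calls.

    A sample is +1/-1 in a region when the mean of its non-missing fragment
    calls there is >= +0.5 / <= -0.5, else 0; NaN if it has no calls.
    """
    sub = callset.calls[rows]
    with np.errstate(invalid="ignore"):
        m = np.nanmean(sub, axis=0)
    state = np.zeros(m.shape)
    state[m >= 0.5] = 1.0
    state[m <= -0.5] = -1.0
    state[~np.isfinite(m)] = np.nan
    return state


def recurrence_table(
    regions: pd.DataFrame,
    state_matrix: np.ndarray,
    partition: WindowPartition,
    callset: MethylCallSet | None = None,
    min_fraction: float = 0.2,
) -> pd.DataFrame:
    """Per-region cohort recurrence of copy and methylation states.

    ``regions`` must carry a ``window`` column indexing the partition (the
    DMR result frame does); the copy fractions come from ``state_matrix``
    (windows x samples codes from :func:`bedmr.cnv.copy_state_matrix`), the
    methylation fractions from per-sample region states over the call set.
    """
    frag_window = None
    if callset is not None:
        mid = callset.midpoints()
        frag_window = np.full(len(mid), -1, dtype=np.int64)
        for chrom, grp in callset.fragments.groupby("chrom", sort=False):
            rows = grp.index.to_numpy()
            frag_window[rows] = partition.locate(chrom, mid[rows])
    out_rows = []
    for reg in regions.itertuples(index=False):
        w = int(reg.window)
        states = state_matrix[w]
        n = len(states)
        frac_amp = float((states == 1).sum() / n) if n else np.nan
        frac_del = float((states == -1).sum() / n) if n else np.nan
        frac_plus = frac_minus = np.nan
        if callset is not None:
            rows = np.nonzero(frag_window == w)[0]
            if len(rows):
                meth = _sample_region_methylation(callset, rows)
                ok = np.isfinite(meth)
                if ok.any():
                    frac_plus = float((meth[ok] == 1).sum() / ok.sum())
                    frac_minus = float((meth[ok] == -1).sum() / ok.sum())
        flagged = bool(
            max(frac_amp or 0, frac_del or 0) >= min_fraction
            or (np.isfinite(frac_plus) and max(frac_plus, frac_minus) >= min_fraction)
        )
        out_rows.append(
            (w, reg.chrom, int(reg.start), int(reg.end),
             frac_amp, frac_del, frac_plus, frac_minus, flagged)
        )
    return pd.DataFrame(
        out_rows,
        columns=[
            "window", "chrom", "start", "end",
            "frac_amplified", "frac_deleted", "frac_plus", "frac_minus", "flagged",
        ],
    )
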