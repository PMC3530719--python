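"""Breakpoint extraction, genome partitioning and per-window copy-state calls.

Every internal boundary between two adjacent segments of one sample is a
breakpoint. Pooling the breakpoints of all samples and cutting every
chromosome at each of them yields a partition into variable-width windows
inside which no sample changes copy state: long windows are quiet regions,
short windows are rearrangement-dense. Within a window each sample is called
amplified (ratio > 1.1), deleted (ratio < 0.9) or normal; the thresholds are
empirical allowances for measurement noise around 1 and are configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bedmr.core import BP_COLUMNS, GenomeSpec, SegmentedProfile, WindowPartition

AMPLIFIED_THRESHOLD = 1.1
DELETED_THRESHOLD = 0.9

# copy-state codes
AMPLIFIED, NORMAL, DELETED = 1, 0, -1


def extract_breakpoints(profiles: list[SegmentedProfile]) -> pd.DataFrame:
    """One record per internal segment boundary per sample.

    Chromosome start/end are not breakpoints; shared boundaries across
    samples are kept with multiplicity.
    """
    rows = []
    for prof in profiles:
        for chrom, grp in prof.segments.groupby("chrom", sort=False):
            starts = grp.sort_values("start")["start"].to_numpy()
            for pos in starts[1:]:
                rows.append((prof.sample_id, chrom, int(pos)))
    return pd.DataFrame(rows, columns=BP_COLUMNS)


def partition_genome(breakpoints: pd.DataFrame, genome: GenomeSpec) -> WindowPartition:
    """Cut each chromosome at every (unique) breakpoint position."""
    rows = []
    by_chrom = (
        {c: g["pos"].to_numpy() for c, g in breakpoints.groupby("chrom", sort=False)}
        if len(breakpoints)
        else {}
    )
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        pos = np.unique(by_chrom.get(chrom, np.array([], dtype=np.int64)))
        if ((pos <= 0) | (pos >= length)).any():
            raise ValueError(f"breakpoint outside (0, {length}) on {chrom}")
        bounds = np.concatenate([[0], pos, [length]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(s), int(e)))
    return WindowPartition(pd.DataFrame(rows, columns=["chrom", "start", "end"]), genome)


def call_copy_state(
    ratio,
    amplified_threshold: float = AMPLIFIED_THRESHOLD,
    deleted_threshold: float = DELETED_THRESHOLD,
):
    """Trinary copy-state call: +1 amplified, -1 deleted, 0 normal.

    Strict inequalities: a ratio exactly at a threshold is normal.
    """
    arr = np.asarray(ratio, dtype=float)
    if (arr <= 0).any():
        raise ValueError("copy ratios must be positive")
    out = np.zeros(arr.shape, dtype=np.int8)
    out[arr > amplified_threshold] = AMPLIFIED
    out[arr < deleted_threshold] = DELETED
    if np.isscalar(ratio) or arr.ndim == 0:
        return int(out)
    return out


def window_ratios(profile: SegmentedProfile, partition: WindowPartition) -> np.ndarray:
    """Ratio of the (unique) segment covering each window for one sample.

    Requires the partition to refine the profile's segmentation (it does by
    construction when built from all samples' breakpoints).
    """
    out = np.full(len(partition), np.nan)
    win = partition.windows
    for chrom, grp in profile.segments.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        seg_starts = grp["start"].to_numpy()
        ratios = grp["ratio"].to_numpy()
        mask = win["chrom"] == chrom
        wstart = win.loc[mask, "start"].to_numpy()
        j = np.searchsorted(seg_starts, wstart, side="right") - 1
        out[mask.to_numpy()] = ratios[np.clip(j, 0, len(ratios) - 1)]
    return out


def copy_state_matrix(
    profiles: list[SegmentedProfile],
    partition: WindowPartition,
    amplified_threshold: float = AMPLIFIED_THRESHOLD,
    deleted_threshold: float = DELETED_THRESHOLD,
) -> tuple[np.ndarray, list[str]]:
    """(windows x samples) matrix of copy-state codes and the sample order."""
    samples = [p.sample_id for p in profiles]
    mat = np.zeros((len(partition), len(profiles)), dtype=np.int8)
    for j, prof in enumerate(profiles):
        ratios = window_ratios(prof, partition)
        covered = np.isfinite(ratios)
        mat[covered, j] = call_copy_state(
            ratios[covered], amplified_threshold, deleted_threshold
        )
    return mat, samples


def cnv_frequency(
    profiles: list[SegmentedProfile],
    partition: WindowPartition,
    amplified_threshold: float = AMPLIFIED_THRESHOLD,
    deleted_threshold: float = DELETED_THRESHOLD,
) -> pd.DataFrame:
    """Per-window fraction of samples amplified / deleted (cohort CNV track)."""
    mat, samples = copy_state_matrix(profiles, partition, amplified_threshold, deleted_threshold)
    n = max(len(samples), 1)
    out = partition.windows.copy()
    out["frac_amplified"] = (mat == AMPLIFIED).sum(axis=1) / n
    out["frac_deleted"] = (mat == DELETED).sum(axis=1) / n
    return out
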