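"""Alu-repeat enrichment around BEDMRs.

The genome is tiled with non-overlapping 100 kb windows and each repeat
element is counted in the window containing its start coordinate. For a
region of interest (a BEDMR, padded symmetrically so it spans at least a
minimum number of whole windows) the per-window counts of one Alu family
are compared with the genome-wide window counts (region windows excluded)
by a one-sided rank-sum test; BH adjustment runs across regions x families
and a region is enriched when its adjusted p falls below 0.001. Finally,
each BEDMR is flagged when an enriched region midpoint lies within 3 Mb.

Family matching is by prefix, so RepeatMasker subfamilies (AluJb, AluSx,
AluYa5, ...) roll up to the three major classes AluJ / AluS / AluY.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from bedmr.core import GenomeSpec
from bedmr.dmr import bh_fdr

ALU_FAMILIES = ("AluJ", "AluS", "AluY")
DEFAULT_WINDOW_SIZE = 100_000
DEFAULT_ALPHA = 1e-3
DEFAULT_MIN_WINDOWS = 3
DEFAULT_COLOC_THRESHOLD = 3_000_000.0

ENRICH_COLUMNS = [
    "region", "chrom", "start", "end", "family",
    "n_windows", "region_mean", "background_mean", "p", "q", "enriched", "untestable",
]


def genome_windows(genome: GenomeSpec, window_size: int = DEFAULT_WINDOW_SIZE) -> pd.DataFrame:
    """Non-overlapping tiling of the genome (last window may be short)."""
    rows = []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        starts = np.arange(0, length, window_size, dtype=np.int64)
        ends = np.minimum(starts + window_size, length)
        for s, e in zip(starts, ends):
            rows.append((chrom, int(s), int(e)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _family_mask(families: pd.Series, family: str | None) -> np.ndarray:
    if family is None:
        return np.ones(len(families), dtype=bool)
    return families.str.startswith(family).to_numpy()


def window_counts(
    repeats: pd.DataFrame,
    genome: GenomeSpec,
    window_size: int = DEFAULT_WINDOW_SIZE,
    family: str | None = None,
) -> pd.DataFrame:
    """Per-window element counts for one family (prefix match) or all.

    An element belongs to the window containing its start coordinate, so
    boundary-spanning elements are counted exactly once.
    """
    win = genome_windows(genome, window_size)
    counts = np.zeros(len(win), dtype=np.int64)
    sel = repeats[_family_mask(repeats["family"], family)]
    offsets = {}
    pos = 0
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        n_win = int(np.ceil(length / window_size))
        offsets[chrom] = (pos, n_win)
        pos += n_win
    for chrom, grp in sel.groupby("chrom", sort=False):
        if chrom not in offsets:
            continue
        off, n_win = offsets[chrom]
        idx = (grp["start"].to_numpy(dtype=np.int64) // window_size)
        idx = idx[(idx >= 0) & (idx < n_win)]
        np.add.at(counts, off + idx, 1)
    out = win.copy()
    out["count"] = counts
    return out


def _region_window_span(
    start: int, end: int, chrom_length: int, window_size: int, min_windows: int
) -> tuple[int, int]:
    """Window index range [i0, i1) covering the region, padded symmetrically
    to at least ``min_windows`` windows (clipped at the chromosome)."""
    i0 = int(start // window_size)
    i1 = int(np.ceil(end / window_size))
    n_chrom = int(np.ceil(chrom_length / window_size))
    while i1 - i0 < min_windows:
        if i0 > 0:
            i0 -= 1
        if i1 - i0 < min_windows and i1 < n_chrom:
            i1 += 1
        if i0 == 0 and i1 == n_chrom:
            break
    return i0, i1


@dataclass
class EnrichmentResult:
    chrom: str
    start: int
    end: int
    family: str
    n_windows: int
    region_mean: float
    background_mean: float
    p: float
    untestable: bool = False


def enrichment_test(
    region: tuple[str, int, int],
    counts: pd.DataFrame,
    genome: GenomeSpec,
    family: str,
    window_size: int = DEFAULT_WINDOW_SIZE,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> EnrichmentResult:
    """One-sided rank-sum test of a region's window counts vs the genome.

    ``counts`` must be the output of :func:`window_counts` for ``family``.
    The region's own windows are excluded from the background. Regions that
    cannot span ``min_windows`` windows are flagged untestable (p = 1).
    """
    chrom, start, end = region
    chrom_length = genome.length_of(chrom)
    i0, i1 = _region_window_span(start, end, chrom_length, window_size, min_windows)
    on_chrom = counts["chrom"] == chrom
    chrom_counts = counts.loc[on_chrom, "count"].to_numpy()
    region_counts = chrom_counts[i0:i1]
    bg_mask = np.ones(len(counts), dtype=bool)
    chrom_rows = np.nonzero(on_chrom.to_numpy())[0]
    bg_mask[chrom_rows[i0:i1]] = False
    background = counts.loc[bg_mask, "count"].to_numpy()
    if len(region_counts) < min_windows or len(background) < min_windows:
        return EnrichmentResult(
            chrom, start, end, family, len(region_counts),
            float(region_counts.mean()) if len(region_counts) else np.nan,
            float(background.mean()) if len(background) else np.nan,
            1.0, untestable=True,
        )
    p = float(
        stats.mannwhitneyu(region_counts, background, alternative="greater").pvalue
    )
    return EnrichmentResult(
        chrom, start, end, family, len(region_counts),
        float(region_counts.mean()), float(background.mean()), p,
    )


def score_regions(
    regions: pd.DataFrame,
    repeats: pd.DataFrame,
    genome: GenomeSpec,
    families: tuple[str, ...] = ALU_FAMILIES,
    window_size: int = DEFAULT_WINDOW_SIZE,
    alpha: float = DEFAULT_ALPHA,
    min_windows: int = DEFAULT_MIN_WINDOWS,
) -> pd.DataFrame:
    """Enrichment of every region x family pair, BH-adjusted jointly."""
    results = []
    for family in families:
        counts = window_counts(repeats, genome, window_size, family)
        for r, row in enumerate(regions.itertuples(index=False)):
            res = enrichment_test(
                (row.chrom, int(row.start), int(row.end)), counts, genome, family,
                window_size, min_windows,
            )
            results.append(
                (r, res.chrom, res.start, res.end, family, res.n_windows,
                 res.region_mean, res.background_mean, res.p, np.nan, False,
                 res.untestable)
            )
    out = pd.DataFrame(results, columns=ENRICH_COLUMNS)
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out["enriched"] = (out["q"] < alpha) & ~out["untestable"]
    return out


def alu_bedmr_coloc(
    enrichment: pd.DataFrame,
    bedmrs: pd.DataFrame,
    threshold: float = DEFAULT_COLOC_THRESHOLD,
) -> tuple[pd.DataFrame, float]:
    """Flag each BEDMR lying within ``threshold`` of an enriched region.

    Returns the BEDMR frame with an ``alu_enriched`` column and the flagged
    fraction.
    """
    if len(bedmrs) == 0 or len(enrichment) == 0:
        out = bedmrs.copy()
        out["alu_enriched"] = pd.Series(dtype=bool)
        return out, float("nan")
    enr = enrichment[enrichment["enriched"]]
    mids = {
        c: ((g["start"] + g["end"]) // 2).to_numpy(dtype=float)
        for c, g in enr.groupby("chrom", sort=False)
    }
    flags = np.zeros(len(bedmrs), dtype=bool)
    bed_mid = ((bedmrs["start"] + bedmrs["end"]) // 2).to_numpy(dtype=float)
    for i, (chrom, m) in enumerate(zip(bedmrs["chrom"], bed_mid)):
        centers = mids.get(chrom)
        if centers is not None and len(centers):
            flags[i] = bool(np.min(np.abs(centers - m)) <= threshold)
    out = bedmrs.reset_index(drop=True).copy()
    out["alu_enriched"] = flags
    return out, float(flags.mean())
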