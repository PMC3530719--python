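"""Core genomic data model shared by every analysis stage.

Coordinates are 0-based, half-open (BED convention) throughout. A genome is
a fixed ordered set of chromosomes (autosomes suffice; copy-number reference
material from a male donor restricts the analysis to autosomes anyway). A
sample's copy-number profile is a set of segments tiling each chromosome;
the boundary between two adjacent segments of one sample is a breakpoint.
The union of all samples' breakpoints partitions the genome into windows in
which no sample changes copy state.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "ratio"]
BP_COLUMNS = ["sample_id", "chrom", "pos"]

#: Counts of methylation states (+1, 0, -1) for one fragment across samples.
TripletCount = namedtuple("TripletCount", ["n_plus", "n_zero", "n_minus"])


class ProfileValidationError(ValueError):
    """A segmented profile violates the tiling/ordering invariants."""

    def __init__(self, message: str, sample_id=None, chrom=None, position=None):
        self.sample_id = sample_id
        self.chrom = chrom
        self.position = position
        where = []
        if sample_id is not None:
            where.append(f"sample={sample_id}")
        if chrom is not None:
            where.append(f"chrom={chrom}")
        if position is not None:
            where.append(f"position={position}")
        suffix = f" [{', '.join(where)}]" if where else ""
        super().__init__(message + suffix)


@dataclass(frozen=True)
class GenomeSpec:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self):
        names = tuple(str(c) for c in self.chrom_names)
        lengths = tuple(int(x) for x in self.chrom_lengths)
        if len(names) != len(lengths):
            raise ValueError("chrom_names and chrom_lengths differ in length")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(x <= 0 for x in lengths):
            raise ValueError("chromosome lengths must be positive")
        object.__setattr__(self, "chrom_names", names)
        object.__setattr__(self, "chrom_lengths", lengths)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def chrom_order(self, chroms) -> np.ndarray:
        """Map chromosome labels to their genome rank (for stable sorting)."""
        index = {c: i for i, c in enumerate(self.chrom_names)}
        return np.asarray([index[c] for c in chroms], dtype=int)

    @classmethod
    def uniform(cls, n_chroms: int, chrom_length: int, prefix: str = "chr") -> "GenomeSpec":
        names = tuple(f"{prefix}{i + 1}" for i in range(n_chroms))
        return cls(names, tuple(int(chrom_length) for _ in names))


@dataclass
class SegmentedProfile:
    """One sample's genome as copy-ratio segments (chrom, start, end, ratio)."""

    sample_id: str
    segments: pd.DataFrame  # columns chrom, start, end, ratio

    def __post_init__(self):
        seg = pd.DataFrame(self.segments)
        missing = [c for c in ("chrom", "start", "end", "ratio") if c not in seg.columns]
        if missing:
            raise ValueError(f"segments missing columns {missing}")
        seg = seg[["chrom", "start", "end", "ratio"]].copy()
        seg["start"] = seg["start"].astype(np.int64)
        seg["end"] = seg["end"].astype(np.int64)
        seg["ratio"] = seg["ratio"].astype(float)
        self.segments = seg.reset_index(drop=True)

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.segments["chrom"]))

    def n_breakpoints(self) -> int:
        """Internal boundaries only: segments minus covered chromosomes."""
        n_chroms = self.segments["chrom"].nunique()
        return len(self.segments) - n_chroms

    def to_seg_frame(self) -> pd.DataFrame:
        out = self.segments.copy()
        out.insert(0, "sample_id", self.sample_id)
        return out[SEG_COLUMNS]


def merge_equal_ratio(segments: pd.DataFrame, rtol: float = 0.0) -> pd.DataFrame:
    """Merge adjacent same-chromosome segments whose ratios are equal.

    Ensures every remaining internal boundary marks an actual copy-state
    transition; segmentation output normally has this property already, but
    synthetic or foreign input may not.
    """
    rows = []
    for chrom, grp in segments.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur = None
        for row in grp.itertuples(index=False):
            if cur is not None and cur["end"] == row.start and (
                cur["ratio"] == row.ratio
                or (rtol > 0 and abs(cur["ratio"] - row.ratio) <= rtol * cur["ratio"])
            ):
                cur["end"] = row.end
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": row.start, "end": row.end, "ratio": row.ratio}
        if cur is not None:
            rows.append(cur)
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio"])


def validate_profiles(
    profiles: list[SegmentedProfile],
    genome: GenomeSpec,
    merge: bool = True,
) -> list[SegmentedProfile]:
    """Check tiling invariants and normalize each profile.

    Per chromosome the segments must be sorted, non-overlapping and tile
    [0, chrom_length) without gaps; ratios must be positive. Adjacent
    equal-ratio segments are merged when *merge* is true (the default).

    Raises
    ------
    ProfileValidationError
        naming the offending sample, chromosome and position.
    """
    out = []
    for prof in profiles:
        seg = prof.segments
        if (seg["ratio"] <= 0).any():
            bad = seg[seg["ratio"] <= 0].iloc[0]
            raise ProfileValidationError(
                "non-positive copy ratio", prof.sample_id, bad["chrom"], int(bad["start"])
            )
        for chrom in seg["chrom"].unique():
            if chrom not in genome.lengths:
                raise ProfileValidationError(
                    "chromosome not in genome", prof.sample_id, chrom
                )
            length = genome.length_of(chrom)
            sub = seg[seg["chrom"] == chrom].sort_values("start")
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            if (starts >= ends).any():
                i = int(np.argmax(starts >= ends))
                raise ProfileValidationError(
                    "empty or inverted segment", prof.sample_id, chrom, int(starts[i])
                )
            if starts[0] != 0:
                raise ProfileValidationError(
                    "gap at chromosome start", prof.sample_id, chrom, 0
                )
            if ends[-1] != length:
                raise ProfileValidationError(
                    f"last segment ends at {int(ends[-1])}, chromosome length {length}",
                    prof.sample_id,
                    chrom,
                    int(ends[-1]),
                )
            gaps = starts[1:] - ends[:-1]
            if (gaps > 0).any():
                i = int(np.argmax(gaps > 0))
                raise ProfileValidationError(
                    "gap between segments", prof.sample_id, chrom, int(ends[i])
                )
            if (gaps < 0).any():
                i = int(np.argmax(gaps < 0))
                raise ProfileValidationError(
                    "overlapping segments", prof.sample_id, chrom, int(starts[i + 1])
                )
        seg = seg.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
        if merge:
            seg = merge_equal_ratio(seg)
        out.append(SegmentedProfile(prof.sample_id, seg))
    return out


@dataclass
class WindowPartition:
    """Genome intervals delimited by the union of all samples' breakpoints."""

    windows: pd.DataFrame  # columns chrom, start, end; sorted, tiling
    genome: GenomeSpec | None = None

    def __post_init__(self):
        win = pd.DataFrame(self.windows)[["chrom", "start", "end"]].copy()
        win["start"] = win["start"].astype(np.int64)
        win["end"] = win["end"].astype(np.int64)
        if (win["start"] >= win["end"]).any():
            raise ValueError("windows must have start < end")
        self.windows = win.reset_index(drop=True)
        # per-chromosome start arrays for O(log n) point location
        self._starts = {
            chrom: (grp.index.to_numpy(), grp["start"].to_numpy(), grp["end"].to_numpy())
            for chrom, grp in self.windows.groupby("chrom", sort=False)
        }

    def __len__(self) -> int:
        return len(self.windows)

    @property
    def lengths(self) -> np.ndarray:
        return (self.windows["end"] - self.windows["start"]).to_numpy()

    def locate(self, chrom, positions) -> np.ndarray:
        """Window index for each position (-1 if outside all windows)."""
        positions = np.atleast_1d(np.asarray(positions, dtype=np.int64))
        if chrom not in self._starts:
            return np.full(positions.shape, -1, dtype=np.int64)
        idx, starts, ends = self._starts[chrom]
        j = np.searchsorted(starts, positions, side="right") - 1
        out = np.full(positions.shape, -1, dtype=np.int64)
        ok = (j >= 0) & (positions < ends[np.clip(j, 0, len(ends) - 1)])
        out[ok] = idx[j[ok]]
        return out

    def midpoints(self) -> np.ndarray:
        return ((self.windows["start"] + self.windows["end"]) // 2).to_numpy()


@dataclass
class MethylCallSet:
    """Fragment-level trinary methylation calls for a set of samples.

    ``calls`` is a float matrix (fragments x samples) holding -1.0, 0.0, +1.0
    or NaN for missing; float so that missingness needs no sentinel.
    """

    fragments: pd.DataFrame  # columns fragment_id, chrom, start, end
    samples: list[str]
    calls: np.ndarray

    def __post_init__(self):
        frag = pd.DataFrame(self.fragments)[["fragment_id", "chrom", "start", "end"]].copy()
        frag["start"] = frag["start"].astype(np.int64)
        frag["end"] = frag["end"].astype(np.int64)
        self.fragments = frag.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.shape != (len(self.fragments), len(self.samples)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.fragments)} fragments x {len(self.samples)} samples"
            )
        finite = self.calls[np.isfinite(self.calls)]
        if finite.size and not np.isin(finite, (-1.0, 0.0, 1.0)).all():
            raise ValueError("calls must be -1, 0, +1 or NaN")

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)

    def midpoints(self) -> np.ndarray:
        return ((self.fragments["start"] + self.fragments["end"]) // 2).to_numpy()

    def triplets(self) -> np.ndarray:
        """Per-fragment counts (n_plus, n_zero, n_minus) over non-missing calls."""
        c = self.calls
        n_plus = np.nansum(c == 1.0, axis=1)
        n_zero = np.nansum(c == 0.0, axis=1)
        n_minus = np.nansum(c == -1.0, axis=1)
        return np.stack([n_plus, n_zero, n_minus], axis=1).astype(np.int64)

    def subset_samples(self, keep: list[str]) -> "MethylCallSet":
        cols = [self.samples.index(s) for s in keep]
        return MethylCallSet(self.fragments, list(keep), self.calls[:, cols])
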