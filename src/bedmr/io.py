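"""Readers and writers for the plain-text genomic formats the pipeline uses.

SEG-like TSV for segmented copy-number profiles, BED3/BED6 for intervals,
BedGraph for per-position tracks, a wide TSV for fragment x sample
methylation matrices, and the RepeatMasker ``.out`` dialect for repeats.
All writers accept an optional header line (e.g. a run's config hash) that
is emitted as a leading ``#`` comment; all readers skip ``#`` lines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from bedmr.core import SEG_COLUMNS, MethylCallSet, SegmentedProfile

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def _open_text(path, mode="r"):
    return open(path, mode, encoding="utf-8", newline="\n")


def write_table(df: pd.DataFrame, path, header_line: str | None = None, sep="\t",
                index=False, float_format="%.10g"):
    """Write a DataFrame as TSV with an optional leading # comment line."""
    with _open_text(path, "w") as fh:
        if header_line:
            fh.write(f"# {header_line}\n")
        df.to_csv(fh, sep=sep, index=index, float_format=float_format, lineterminator="\n")


_write_frame = write_table


# ---------------------------------------------------------------- SEG files

def read_seg(path, one_based: bool = False, log2: bool = False) -> list[SegmentedProfile]:
    """Read a SEG-like TSV (sample, chrom, start, end, ratio) into profiles.

    ``one_based`` shifts starts down by 1 (1-based inclusive input);
    ``log2`` exponentiates the ratio column (log2-scale input).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"SEG file {path} missing columns {missing}")
    if one_based:
        df["start"] = df["start"] - 1
    if log2:
        df["ratio"] = np.exp2(df["ratio"])
    return [
        SegmentedProfile(sample, grp.drop(columns="sample_id"))
        for sample, grp in df.groupby("sample_id", sort=False)
    ]


def write_seg(profiles: list[SegmentedProfile], path, header_line: str | None = None):
    frames = [p.to_seg_frame() for p in profiles]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SEG_COLUMNS)
    _write_frame(df, path, header_line)


# ---------------------------------------------------------------- BED files

def read_bed(path) -> pd.DataFrame:
    """Read BED3/BED6; returns columns chrom,start,end[,name,score,strand]."""
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has {len(parts)} fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer BED coordinates") from None
            extra = parts[3:6] + [None] * (3 - len(parts[3:6]))
            rows.append([parts[0], start, end] + extra)
    df = pd.DataFrame(rows, columns=BED6_COLUMNS)
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    keep = ["chrom", "start", "end"] + [c for c in ("name", "score", "strand")
                                         if df[c].notna().any()]
    return df[keep]


def write_bed(df: pd.DataFrame, path, header_line: str | None = None):
    cols = [c for c in BED6_COLUMNS if c in df.columns]
    with _open_text(path, "w") as fh:
        if header_line:
            fh.write(f"# {header_line}\n")
        df[cols].to_csv(fh, sep="\t", index=False, header=False,
                        float_format="%.10g", lineterminator="\n")


def write_bedgraph(df: pd.DataFrame, value_col: str, path, header_line: str | None = None):
    """Write chrom/start/end/<value_col> as 4-column BedGraph."""
    with _open_text(path, "w") as fh:
        if header_line:
            fh.write(f"# {header_line}\n")
        df[["chrom", "start", "end", value_col]].to_csv(
            fh, sep="\t", index=False, header=False, float_format="%.10g",
            lineterminator="\n")


# ------------------------------------------------- methylation call matrices

META_COLS = ["fragment_id", "chrom", "start", "end"]


def write_methylation(callset: MethylCallSet, path, header_line: str | None = None):
    df = callset.fragments.copy()
    for j, s in enumerate(callset.samples):
        col = callset.calls[:, j]
        df[s] = pd.array(
            [None if not np.isfinite(v) else int(v) for v in col], dtype="Int64"
        )
    _write_frame(df, path, header_line)


def read_methylation(path) -> MethylCallSet:
    """Read a fragment-metadata + per-sample trinary call TSV."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "fragment_id": str})
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"methylation file {path} missing columns {missing}")
    samples = [c for c in df.columns if c not in META_COLS]
    calls = df[samples].to_numpy(dtype=float)
    return MethylCallSet(df[META_COLS], samples, calls)


def read_logratios(path) -> tuple[pd.DataFrame, list[str], np.ndarray]:
    """Read fragment metadata + per-sample log-ratio columns (floats)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "fragment_id": str})
    missing = [c for c in META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"log-ratio file {path} missing columns {missing}")
    samples = [c for c in df.columns if c not in META_COLS]
    return df[META_COLS].copy(), samples, df[samples].to_numpy(dtype=float)


# ------------------------------------------------------------------ repeats

def read_repeats_bed(path) -> pd.DataFrame:
    """Repeat annotations as BED with the family in the name column."""
    df = read_bed(path)
    if "name" not in df.columns:
        raise ValueError(f"repeat BED {path} lacks a name (family) column")
    return df.rename(columns={"name": "family"})[["chrom", "start", "end", "family"]]


def read_repeatmasker_out(path) -> pd.DataFrame:
    """Read the RepeatMasker ``.out`` fixed layout (3 header lines).

    Coordinates are 1-based inclusive in the file and converted to 0-based
    half-open. The repeat name column supplies the family label.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if lineno <= 3 or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 11:
                raise ValueError(f"{path}:{lineno}: truncated RepeatMasker line")
            chrom, begin, end, name = parts[4], parts[5], parts[6], parts[9]
            rows.append((chrom, int(begin) - 1, int(end), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])


def write_repeats_bed(df: pd.DataFrame, path, header_line: str | None = None):
    out = df.rename(columns={"family": "name"})
    write_bed(out, path, header_line=header_line)
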