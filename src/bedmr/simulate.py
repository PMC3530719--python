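"""Synthetic cohorts with planted, recorded truth.

The generator emulates the study conditions the pipeline was designed for:
a tumor-heavy cohort (defaults 100 tumors / 10 normals, mirroring the
108/11 imbalance of metastatic breast-cancer array studies) profiled on an
array-CGH-like platform whose segmentation emits ~dozens of segments per
sample, and a fragment-level methylation platform with trinary calls.

Segmented profiles are emitted directly (no probe-level noise model):
per sample, breakpoint positions are a mixture of a uniform background and
Gaussian clusters around planted hotspot centers; segment ratios alternate
between normal (1.0 +/- 0.03), amplified (1.3 +/- 0.05) and deleted
(0.7 +/- 0.05) regimes so the 1.1/0.9 call thresholds separate them.
Methylation calls are i.i.d. trinary draws per fragment and sample from a
baseline probability vector, replaced in planted DMR windows (tumors only)
by a shifted vector; the defaults reproduce the canonical illustrative
triplet (30, 3, 7) out of 40 samples against a (10, 20, 10) baseline.
Repeat elements are a homogeneous Poisson process per family, multiplied by
a fold factor inside planted clusters (background about one insertion per
3 kb, as for genomic Alu).

All stages draw from per-stage substreams of one seed, so identical
configs give byte-identical outputs and partial re-runs are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from bedmr._seeds import stage_rng
from bedmr.core import GenomeSpec, MethylCallSet, SegmentedProfile, WindowPartition

RATIO_REGIMES = {
    "normal": (1.0, 0.03),
    "amplified": (1.3, 0.05),
    "deleted": (0.7, 0.05),
}
#: cycle of copy regimes along each chromosome; returns to normal between events
REGIME_CYCLE = ("normal", "amplified", "normal", "deleted")


@dataclass
class SimConfig:
    """Generator parameters; defaults are the package's reference conditions."""

    n_samples: int = 100          # tumors
    n_normals: int = 10
    n_chroms: int = 2
    chrom_length: int = 50_000_000
    background_bp_rate: float = 1.0   # expected breakpoints / sample / Mb (total)
    n_hotspots: int = 3
    hotspot_sd: float = 200_000.0     # bp spread of clustered breakpoints
    hotspot_weight: float = 0.7       # fraction of breakpoints from hotspots
    hotspot_min_separation: float = 5_000_000.0
    hotspot_margin: float = 3_000_000.0
    baseline_probs: tuple = (0.25, 0.5, 0.25)     # P(+1), P(0), P(-1)
    dmr_shift: tuple = (0.75, 0.075, 0.175)       # planted tumor probabilities
    dmr_fraction: float = 0.05                    # fraction of eligible windows
    fragment_spacing: int = 20_000                # bp between fragment midpoints
    alu_background_rate: float = 1.0 / 3.0        # elements / kb / family-pool
    alu_family_weights: tuple = (0.25, 0.55, 0.20)  # AluJ, AluS, AluY
    n_alu_clusters: int = 2
    alu_cluster_length: float = 1_000_000.0
    alu_cluster_fold: float = 3.0
    seed: int = 0

    def __post_init__(self):
        for name in ("baseline_probs", "dmr_shift"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or (v < 0).any() or abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must be 3 non-negative values summing to 1")
            setattr(self, name, tuple(float(x) for x in v))
        if self.background_bp_rate < 0 or self.alu_background_rate < 0:
            raise ValueError("rates must be non-negative")
        if not (0.0 <= self.hotspot_weight <= 1.0):
            raise ValueError("hotspot_weight must be in [0, 1]")
        if self.n_hotspots > 0 and self.hotspot_sd >= self.chrom_length:
            raise ValueError("hotspot_sd must be smaller than chrom_length")

    def genome(self) -> GenomeSpec:
        return GenomeSpec.uniform(self.n_chroms, self.chrom_length)


@dataclass
class SimTruth:
    """Planted signal: hotspot centers, DMR windows, Alu clusters."""

    hotspot_centers: list = field(default_factory=list)   # (chrom, pos)
    dmr_windows: list = field(default_factory=list)       # (window_index, shift...)
    alu_clusters: list = field(default_factory=list)      # (chrom, start, end, fold)

    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8", newline="\n") as fh:
                fh.write(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, text_or_path) -> "SimTruth":
        text = str(text_or_path)
        if "\n" not in text and text.endswith(".json"):
            with open(text, encoding="utf-8") as fh:
                text = fh.read()
        data = json.loads(text)
        return cls(
            hotspot_centers=[tuple(x) for x in data.get("hotspot_centers", [])],
            dmr_windows=[tuple(x) for x in data.get("dmr_windows", [])],
            alu_clusters=[tuple(x) for x in data.get("alu_clusters", [])],
        )

    def merged(self, other: "SimTruth") -> "SimTruth":
        return SimTruth(
            hotspot_centers=self.hotspot_centers + other.hotspot_centers,
            dmr_windows=self.dmr_windows + other.dmr_windows,
            alu_clusters=self.alu_clusters + other.alu_clusters,
        )


def _place_clusters(
    rng: np.random.Generator,
    genome: GenomeSpec,
    n: int,
    margin: float,
    min_separation: float,
    max_tries: int = 10_000,
) -> list[tuple[str, float]]:
    """Random cluster centers with an end margin and a minimum separation."""
    lengths = np.asarray(genome.chrom_lengths, dtype=float)
    usable = np.maximum(lengths - 2 * margin, 0.0)
    if usable.sum() <= 0:
        raise ValueError("margins leave no room for clusters")
    weights = usable / usable.sum()
    centers: list[tuple[str, float]] = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        ci = rng.choice(len(lengths), p=weights)
        chrom = genome.chrom_names[ci]
        pos = rng.uniform(margin, lengths[ci] - margin)
        if all(c != chrom or abs(p - pos) >= min_separation for c, p in centers):
            centers.append((chrom, float(pos)))
    else:
        raise ValueError(
            f"could not place {n} clusters with separation {min_separation:g} "
            f"in {max_tries} tries"
        )
    return centers


def simulate_cnv(
    config: SimConfig, genome: GenomeSpec | None = None
) -> tuple[list[SegmentedProfile], SimTruth]:
    """Segmented copy-number profiles with hotspot-clustered breakpoints."""
    if genome is None:
        genome = config.genome()
    rng = stage_rng(config.seed, "cnv")
    if config.n_hotspots > 0:
        hotspots = _place_clusters(
            rng, genome, config.n_hotspots, config.hotspot_margin,
            config.hotspot_min_separation,
        )
    else:
        hotspots = []
    by_chrom: dict[str, list[float]] = {}
    for chrom, pos in hotspots:
        by_chrom.setdefault(chrom, []).append(pos)

    profiles = []
    for s in range(config.n_samples):
        rows = []
        for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
            rate = config.background_bp_rate * (length / 1e6)
            n_bp = rng.poisson(rate)
            centers = by_chrom.get(chrom, [])
            positions = []
            for _ in range(n_bp):
                if centers and rng.uniform() < config.hotspot_weight:
                    c = centers[rng.integers(len(centers))]
                    for _ in range(100):
                        p = rng.normal(c, config.hotspot_sd)
                        if 0 < p < length:
                            break
                    else:
                        p = rng.uniform(1, length - 1)
                else:
                    p = rng.uniform(1, length - 1)
                positions.append(int(round(p)))
            positions = sorted(set(p for p in positions if 0 < p < length))
            bounds = [0] + positions + [length]
            for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
                regime = REGIME_CYCLE[i % len(REGIME_CYCLE)]
                mean, sd = RATIO_REGIMES[regime]
                ratio = max(rng.normal(mean, sd), 0.05)
                rows.append((chrom, a, b, ratio))
        profiles.append(
            SegmentedProfile(
                f"tumor_{s + 1:03d}",
                pd.DataFrame(rows, columns=["chrom", "start", "end", "ratio"]),
            )
        )
    truth = SimTruth(hotspot_centers=[(c, float(p)) for c, p in hotspots])
    return profiles, truth


def _draw_calls(rng, probs, shape) -> np.ndarray:
    """i.i.d. trinary draws coded +1/0/-1 from (p_plus, p_zero, p_minus)."""
    u = rng.uniform(size=shape)
    out = np.full(shape, -1.0)
    out[u < probs[0] + probs[1]] = 0.0
    out[u < probs[0]] = 1.0
    return out


def simulate_methylation(
    config: SimConfig,
    partition: WindowPartition,
    tumor_n: int | None = None,
    normal_n: int | None = None,
) -> tuple[MethylCallSet, MethylCallSet, SimTruth]:
    """Fragment call matrices for tumors and normals with planted DMR windows.

    Fragments sit every ``fragment_spacing`` bp. Windows eligible for
    planting must hold at least 4 fragments (smaller windows are untestable
    downstream and planting there would silently discard signal).
    """
    if len(partition) == 0:
        raise ValueError("partition is empty")
    tumor_n = config.n_samples if tumor_n is None else tumor_n
    normal_n = config.n_normals if normal_n is None else normal_n
    rng = stage_rng(config.seed, "methylation")

    win = partition.windows
    frag_rows = []
    frag_window = []
    fid = 0
    for chrom, grp in win.groupby("chrom", sort=False):
        chrom_end = int(grp["end"].max())
        spacing = int(config.fragment_spacing)
        mids = np.arange(spacing // 2, chrom_end, spacing, dtype=np.int64)
        widx = partition.locate(chrom, mids)
        for m, w in zip(mids, widx):
            fid += 1
            frag_rows.append(
                (f"frag_{fid:06d}", chrom, int(m - spacing // 4), int(m + spacing // 4))
            )
            frag_window.append(int(w))
    fragments = pd.DataFrame(frag_rows, columns=["fragment_id", "chrom", "start", "end"])
    frag_window = np.asarray(frag_window)

    counts = pd.Series(frag_window[frag_window >= 0]).value_counts()
    eligible = sorted(int(w) for w, c in counts.items() if c >= 4)
    n_plant = int(round(config.dmr_fraction * len(eligible)))
    planted = sorted(
        int(w) for w in rng.choice(eligible, size=min(n_plant, len(eligible)), replace=False)
    ) if n_plant else []
    planted_set = set(planted)

    is_planted = np.isin(frag_window, planted)
    tumor_calls = _draw_calls(rng, config.baseline_probs, (len(fragments), tumor_n))
    if is_planted.any():
        tumor_calls[is_planted] = _draw_calls(
            rng, config.dmr_shift, (int(is_planted.sum()), tumor_n)
        )
    normal_calls = _draw_calls(rng, config.baseline_probs, (len(fragments), normal_n))

    tumors = MethylCallSet(
        fragments, [f"tumor_{i + 1:03d}" for i in range(tumor_n)], tumor_calls
    )
    normals = MethylCallSet(
        fragments, [f"normal_{i + 1:03d}" for i in range(normal_n)], normal_calls
    )
    truth = SimTruth(
        dmr_windows=[(int(w), list(config.dmr_shift)) for w in planted]
    )
    return tumors, normals, truth


def simulate_repeats(
    config: SimConfig, genome: GenomeSpec | None = None
) -> tuple[pd.DataFrame, SimTruth]:
    """Poisson repeat positions with planted fold-enriched clusters.

    Background intensity is ``alu_background_rate`` elements per kb overall,
    split across families by ``alu_family_weights``; inside each planted
    cluster the intensity is multiplied by ``alu_cluster_fold``.
    """
    if genome is None:
        genome = config.genome()
    rng = stage_rng(config.seed, "repeats")
    clusters = []
    if config.n_alu_clusters > 0:
        centers = _place_clusters(
            rng, genome, config.n_alu_clusters,
            margin=max(config.alu_cluster_length, 1.0),
            min_separation=max(config.hotspot_min_separation, 2 * config.alu_cluster_length),
        )
        half = config.alu_cluster_length / 2
        clusters = [
            (c, float(p - half), float(p + half), float(config.alu_cluster_fold))
            for c, p in centers
        ]

    families = ("AluJ", "AluS", "AluY")
    weights = np.asarray(config.alu_family_weights, dtype=float)
    weights = weights / weights.sum()
    rate_bp = config.alu_background_rate / 1000.0
    rows = []
    for chrom, length in zip(genome.chrom_names, genome.chrom_lengths):
        n_bg = rng.poisson(rate_bp * length)
        pos = rng.uniform(0, length, n_bg)
        extra = []
        for c, cs, ce, fold in clusters:
            if c != chrom:
                continue
            n_extra = rng.poisson((fold - 1.0) * rate_bp * (ce - cs))
            if n_extra > 0:
                extra.append(rng.uniform(cs, ce, n_extra))
        if extra:
            pos = np.concatenate([pos] + extra)
        pos = np.sort(pos).astype(np.int64)
        fam = rng.choice(len(families), size=len(pos), p=weights)
        lengths = np.maximum(rng.normal(300, 30, len(pos)).astype(np.int64), 50)
        for p, f, ln in zip(pos, fam, lengths):
            rows.append((chrom, int(p), int(min(p + ln, length)), families[f]))
    repeats = pd.DataFrame(rows, columns=["chrom", "start", "end", "family"])
    repeats = repeats[repeats["start"] < repeats["end"]].reset_index(drop=True)
    truth = SimTruth(alu_clusters=clusters)
    return repeats, truth
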