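"""End-to-end pipeline: CNV -> BER -> (calls) -> DMR -> coloc -> repeats -> annotate.

A single :class:`RunConfig` holds every stage's parameters plus input paths
(or the synthetic-mode flag). Every output file starts with a header comment
recording the config hash and seed, so two runs with the same config are
byte-identical and runs with different parameters are distinguishable from
their outputs alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from bedmr import annotate as annotate_mod
from bedmr import ber as ber_mod
from bedmr import cnv as cnv_mod
from bedmr import coloc as coloc_mod
from bedmr import dmr as dmr_mod
from bedmr import io as io_mod
from bedmr import methylation as meth_mod
from bedmr import repeats as repeats_mod
from bedmr.core import GenomeSpec, validate_profiles
from bedmr.simulate import SimConfig, SimTruth, simulate_cnv, simulate_methylation, simulate_repeats


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """All pipeline parameters; serializable, hashable, YAML-loadable."""

    # input mode
    synthetic: bool = True
    sim: SimConfig = field(default_factory=SimConfig)
    seg_path: str | None = None
    seg_one_based: bool = False
    seg_log2: bool = False
    methylation_path: str | None = None      # trinary call matrix TSV
    logratio_path: str | None = None         # raw log-ratio TSV (EM calling)
    repeats_path: str | None = None          # BED with family names
    repeats_format: str = "bed"              # or "repeatmasker"
    features_path: str | None = None         # annotation BED (genes, fragile sites)
    genome_lengths: dict = field(default_factory=dict)  # chrom -> bp (real mode)
    # cnv
    amplified_threshold: float = cnv_mod.AMPLIFIED_THRESHOLD
    deleted_threshold: float = cnv_mod.DELETED_THRESHOLD
    # ber
    bandwidth: float = ber_mod.DEFAULT_BANDWIDTH
    grid_step: float = ber_mod.DEFAULT_GRID_STEP
    min_prominence: float = 0.0
    # methylation calling
    posterior_cutoff: float = meth_mod.DEFAULT_POSTERIOR_CUTOFF
    # dmr
    dmr_alpha: float = dmr_mod.DEFAULT_ALPHA
    dmr_use_adjusted: bool = True
    min_fragments: int = dmr_mod.MIN_FRAGMENTS
    # coloc
    null_family: str = "gamma"
    n_rand: int = coloc_mod.DEFAULT_N_RAND
    coloc_grid_max: float = coloc_mod.DEFAULT_GRID_MAX
    coloc_grid_step: float = coloc_mod.DEFAULT_GRID_STEP
    coloc_mode: str = "rank"
    bedmr_threshold: float = coloc_mod.DEFAULT_BEDMR_THRESHOLD
    use_dstar_threshold: bool = False
    # repeats
    repeat_window_size: int = repeats_mod.DEFAULT_WINDOW_SIZE
    repeat_alpha: float = repeats_mod.DEFAULT_ALPHA
    repeat_min_windows: int = repeats_mod.DEFAULT_MIN_WINDOWS
    alu_coloc_threshold: float = repeats_mod.DEFAULT_COLOC_THRESHOLD
    # annotation
    proximal_limit: float = 1_000_000.0
    recurrence_min_fraction: float = 0.2
    # global
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        # the one seed drives the synthetic stage too
        self.sim = dataclasses.replace(self.sim, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def _json_dump(obj, path):
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        json.dump(obj, fh, sort_keys=True, indent=2)
        fh.write("\n")


def run_pipeline(config: RunConfig, outdir) -> dict:
    """Execute every stage in order, writing all declared outputs to *outdir*.

    Returns a dict of the in-memory stage products for programmatic use.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"bedmr config_hash={config.config_hash()} seed={config.seed}"
    log_lines = [header]

    def log(msg):
        log_lines.append(msg)

    # ------------------------------------------------------------- inputs
    truth = SimTruth()
    if config.synthetic:
        genome = config.sim.genome()
        profiles, cnv_truth = simulate_cnv(config.sim, genome)
        truth = truth.merged(cnv_truth)
        repeats_df, rep_truth = simulate_repeats(config.sim, genome)
        truth = truth.merged(rep_truth)
        callset = None  # generated after partitioning (needs windows)
    else:
        if not config.seg_path:
            raise PipelineError("cnv", "no SEG input configured")
        if not config.genome_lengths:
            raise PipelineError("cnv", "real-data mode requires genome_lengths")
        genome = GenomeSpec(
            tuple(config.genome_lengths), tuple(config.genome_lengths.values())
        )
        profiles = io_mod.read_seg(
            config.seg_path, one_based=config.seg_one_based, log2=config.seg_log2
        )
        if config.repeats_path:
            repeats_df = (
                io_mod.read_repeatmasker_out(config.repeats_path)
                if config.repeats_format == "repeatmasker"
                else io_mod.read_repeats_bed(config.repeats_path)
            )
        else:
            repeats_df = None
        callset = None

    # ---------------------------------------------------------------- cnv
    profiles = validate_profiles(profiles, genome)
    breakpoints = cnv_mod.extract_breakpoints(profiles)
    partition = cnv_mod.partition_genome(breakpoints, genome)
    freq = cnv_mod.cnv_frequency(
        profiles, partition, config.amplified_threshold, config.deleted_threshold
    )
    state_matrix, sample_order = cnv_mod.copy_state_matrix(
        profiles, partition, config.amplified_threshold, config.deleted_threshold
    )
    io_mod.write_seg(profiles, outdir / "profiles.seg", header)
    io_mod.write_bed(partition.windows.assign(name="window"), outdir / "windows.bed", header)
    io_mod.write_bedgraph(freq, "frac_amplified", outdir / "cnv_amplified.bedgraph", header)
    io_mod.write_bedgraph(freq, "frac_deleted", outdir / "cnv_deleted.bedgraph", header)
    log(f"cnv: {len(profiles)} samples, {len(breakpoints)} breakpoints, "
        f"{len(partition)} windows")

    # ---------------------------------------------------------------- ber
    track = ber_mod.breakpoint_density(
        breakpoints, genome, config.bandwidth, config.grid_step
    )
    bers = ber_mod.find_bers(track, config.min_prominence)
    io_mod.write_bedgraph(track.to_bedgraph_frame(), "value",
                          outdir / "breakpoint_density.bedgraph", header)
    io_mod.write_bed(ber_mod.bers_to_bed_frame(bers), outdir / "bers.bed", header)
    log(f"ber: {len(bers)} regions (min_prominence={config.min_prominence})")

    # --------------------------------------------------- methylation calls
    if config.synthetic:
        callset, normals, meth_truth = simulate_methylation(config.sim, partition)
        truth = truth.merged(meth_truth)
        io_mod.write_methylation(callset, outdir / "methylation_tumors.tsv", header)
        io_mod.write_methylation(normals, outdir / "methylation_normals.tsv", header)
        truth.to_json(outdir / "truth.json")
    elif config.methylation_path:
        callset = io_mod.read_methylation(config.methylation_path)
    elif config.logratio_path:
        meta, samples, logratios = io_mod.read_logratios(config.logratio_path)
        model = meth_mod.fit_trinary_em(
            logratios, seed=config.seed, posterior_cutoff=config.posterior_cutoff
        )
        calls = meth_mod.call_matrix(model, logratios)
        from bedmr.core import MethylCallSet

        callset = MethylCallSet(meta, samples, calls)
        io_mod.write_methylation(callset, outdir / "methylation_calls.tsv", header)
        log(f"methcall: EM means={np.round(model.means, 4).tolist()} "
            f"converged={model.converged}")
    else:
        raise PipelineError("dmr", "no methylation calls or log-ratios configured")

    # ---------------------------------------------------------------- dmr
    results = dmr_mod.scan_windows(callset, partition, min_fragments=config.min_fragments)
    if len(results) == 0:
        raise PipelineError("dmr", "no window had enough fragments to test")
    dmrs = dmr_mod.call_dmrs(results, config.dmr_alpha, config.dmr_use_adjusted)
    io_mod.write_table(results, outdir / "dmr_results.tsv", header)
    io_mod.write_bedgraph(results, "score", outdir / "dmr_score.bedgraph", header)
    dmr_bed = dmrs.assign(
        name=[f"DMR_{i + 1}" for i in range(len(dmrs))], strand="."
    )[["chrom", "start", "end", "name", "score", "strand"]]
    io_mod.write_bed(dmr_bed, outdir / "dmrs.bed", header)
    log(f"dmr: {len(results)} windows tested, {len(dmrs)} DMRs "
        f"(alpha={config.dmr_alpha}, adjusted={config.dmr_use_adjusted})")

    # -------------------------------------------------------------- coloc
    coloc_result = None
    bedmrs = dmrs.iloc[0:0].copy()
    if len(dmrs) and len(bers):
        points = dmr_mod.dmr_midpoints(dmrs)
        spacings = coloc_mod.inter_dmr_spacings(points)
        threshold = config.bedmr_threshold
        if len(spacings) >= 10:
            models = coloc_mod.fit_null_models(spacings)
            grid = np.arange(
                0.0, config.coloc_grid_max + config.coloc_grid_step, config.coloc_grid_step
            )
            coloc_result = coloc_mod.coloc_test(
                points, bers, genome, models[config.null_family],
                n_rand=config.n_rand, grid=grid, seed=config.seed + 1,
                mode=config.coloc_mode,
            )
            io_mod.write_table(coloc_result.to_frame(), outdir / "coloc_curves.tsv", header)
            _json_dump(
                {"config_hash": config.config_hash(), "seed": config.seed,
                 **coloc_result.summary()},
                outdir / "coloc_summary.json",
            )
            if config.use_dstar_threshold:
                threshold = coloc_result.d_star
            log(f"coloc: d_star={coloc_result.d_star:.0f} "
                f"q_at_dstar={coloc_result.q_at_dstar:.4g} ({config.null_family} null)")
        else:
            log(f"coloc: skipped ({len(spacings)} spacings < 10)")
        bedmrs = coloc_mod.call_bedmrs(dmrs, bers, threshold)
        bed = bedmrs.assign(
            name=[f"BEDMR_{i + 1}" for i in range(len(bedmrs))], strand="."
        )[["chrom", "start", "end", "name", "score", "strand",
           "ber_center", "ber_distance"]]
        with open(outdir / "bedmrs.bed", "w", encoding="utf-8", newline="\n") as fh:
            fh.write(f"# {header}\n")
            bed.to_csv(fh, sep="\t", index=False, header=False,
                       float_format="%.10g", lineterminator="\n")
        log(f"bedmr: {len(bedmrs)} of {len(dmrs)} DMRs within {threshold:.0f} bp of a BER")
    else:
        log("coloc: skipped (no DMRs or no BERs)")

    # ------------------------------------------------------------ repeats
    enrichment = None
    if repeats_df is not None and len(bedmrs):
        enrichment = repeats_mod.score_regions(
            bedmrs, repeats_df, genome,
            window_size=config.repeat_window_size,
            alpha=config.repeat_alpha,
            min_windows=config.repeat_min_windows,
        )
        flagged, fraction = repeats_mod.alu_bedmr_coloc(
            enrichment, bedmrs, config.alu_coloc_threshold
        )
        io_mod.write_table(enrichment, outdir / "repeat_enrichment.tsv", header)
        io_mod.write_table(flagged, outdir / "bedmr_alu_flags.tsv", header)
        if config.synthetic:
            io_mod.write_repeats_bed(repeats_df, outdir / "repeats.bed", header)
        log(f"repeats: {int(enrichment['enriched'].sum())} enriched region-family "
            f"pairs; {fraction:.3f} of BEDMRs Alu-flagged")
    else:
        log("repeats: skipped (no repeat annotations or no BEDMRs)")

    # ----------------------------------------------------------- annotate
    annotation = None
    if config.features_path and len(bedmrs):
        features = io_mod.read_bed(config.features_path)
        annotation = annotate_mod.overlap_annotate(bedmrs, features, config.proximal_limit)
        io_mod.write_table(annotation, outdir / "annotation.tsv", header)
    recurrence = None
    if len(dmrs):
        recurrence = annotate_mod.recurrence_table(
            dmrs, state_matrix, partition, callset, config.recurrence_min_fraction
        )
        io_mod.write_table(recurrence, outdir / "recurrence.tsv", header)

    with open(outdir / "run_log.txt", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\n".join(log_lines) + "\n")
    _json_dump(
        {"config_hash": config.config_hash(), "seed": config.seed,
         "config": config.to_dict()},
        outdir / "run_config.json",
    )

    return {
        "genome": genome,
        "profiles": profiles,
        "breakpoints": breakpoints,
        "partition": partition,
        "frequency": freq,
        "state_matrix": state_matrix,
        "density": track,
        "bers": bers,
        "callset": callset,
        "dmr_results": results,
        "dmrs": dmrs,
        "coloc": coloc_result,
        "bedmrs": bedmrs,
        "enrichment": enrichment,
        "annotation": annotation,
        "recurrence": recurrence,
        "truth": truth,
    }
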