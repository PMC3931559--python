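"""End-to-end orchestration: build -> mappability -> signal -> subtract
-> peaks -> normalized tag density -> bins -> correlate.

The pipeline is a pure function of (inputs, configuration, seed); every
run writes a manifest recording the stages executed, their parameters
and outputs, so a rerun with the same YAML configuration reproduces the
deterministic artifacts byte-identically.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .binstats import BinnedProfile, bin_median, correlation_matrix, pairwise_regression
from .genome_build import (
    GenomeBuild,
    default_annotation,
    read_fasta,
    write_annotation_tsv,
    write_fasta,
)
from .io import read_reads, write_bedgraph, write_peaks, write_reads_bed, write_tsv
from .mappability import MappabilityParams, classify_and_summarize, mappability_track
from .signal import SignalTrack, call_peaks, dedup, kde_track, subtract_input
from .synthetic import (
    SyntheticGenomeSpec,
    SyntheticReadSpec,
    EnrichmentSite,
    simulate_genome,
    simulate_reads,
    standard_sites,
)
from .tagdensity import TagDensityUndefinedError, normalized_tag_density

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

STAGES = [
    "build",
    "mappability",
    "signal",
    "subtract",
    "peaks",
    "ntd",
    "bins",
    "correlate",
]

# per-config-seed substreams for the pipeline's own randomness
_STREAM_GENOME = 10
_STREAM_INPUT = 11
_STREAM_SAMPLE0 = 100


@dataclass
class SampleConfig:
    name: str
    reads: Optional[str] = None  # path to BED/SAM/BAM; None -> simulate
    n_reads: int = 50_000
    enriched_fraction: float = 0.3
    dup_rate: float = 0.1
    sites: str = "standard"  # or list of [center, weight, sd]


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "out"
    # genome: simulated by default, or an existing build FASTA
    genome_mode: str = "simulate"
    genome_fasta: Optional[str] = None
    repeat_chrom: Optional[str] = None
    repeat_start: int = 0
    repeat_end: int = 0
    host_length: int = 150_000
    repeat_length: int = 45_309
    n_pseudogenes: int = 5
    pseudogene_fraction: float = 0.1
    gc: float = 0.42
    samples: List[SampleConfig] = field(default_factory=list)
    input_reads: Optional[str] = None
    input_n_reads: int = 50_000
    # mappability
    k: int = 36
    ext: int = 200
    poor_threshold: float = 0.25
    # signal
    frag_size: int = 200
    read_length: int = 36
    bandwidth: float = 50.0
    threshold_sd: float = 4.0
    background: str = "analytic"
    subtract_for_peaks: bool = True
    # binning / correlation
    bin_size: int = 100
    score: str = "adjusted_r2"


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    samples = [SampleConfig(**s) for s in raw.pop("samples", [])]
    cfg = PipelineConfig(samples=samples, **raw)
    return cfg


def _sites_for(sample: SampleConfig, repeat_length: int):
    if sample.sites == "standard":
        return standard_sites(repeat_length)
    return tuple(EnrichmentSite(int(c), float(w), float(sd)) for c, w, sd in sample.sites)


def run_pipeline(config: PipelineConfig) -> Dict:
    """Execute all stages, write every artifact under ``config.outdir``,
    and return the manifest (also written as ``manifest.json``).

    Any stage failure aborts with the stage name attached to the error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: Dict = {
        "version": __version__,
        "seed": config.seed,
        "config": {**asdict(config)},
        "stages": [],
    }
    state: Dict = {}
    for stage in STAGES:
        t0 = time.perf_counter()
        try:
            outputs = _STAGE_FUNCS[stage](config, state, outdir)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"].append(
            {
                "name": stage,
                "outputs": outputs,
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
        )
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def _stage_build(config: PipelineConfig, state: Dict, outdir: Path) -> List[str]:
    if config.genome_mode == "simulate":
        spec = SyntheticGenomeSpec(
            host_length=config.host_length,
            repeat_length=config.repeat_length,
            n_pseudogenes=config.n_pseudogenes,
            pseudogene_fraction=config.pseudogene_fraction,
            gc=config.gc,
            seed=config.seed * 1000 + _STREAM_GENOME,
        )
        build, truth = simulate_genome(spec)
        state["truth"] = truth
    elif config.genome_mode == "fasta":
        seqs = read_fasta(config.genome_fasta)
        from .genome_build import Insertion

        build = GenomeBuild(
            name=Path(config.genome_fasta).stem,
            sequences=seqs,
            insertion=Insertion(
                config.repeat_chrom,
                config.repeat_start,
                config.repeat_end - config.repeat_start,
            ),
        )
        build.validate()
    else:
        raise ValueError(f"unknown genome mode {config.genome_mode!r}")
    state["build"] = build
    state["annotation"] = default_annotation(build.repeat_length)
    fasta = outdir / "build.fa"
    ann = outdir / "annotation.tsv"
    write_fasta(build.sequences, fasta)
    write_annotation_tsv(state["annotation"], ann)
    return [str(fasta), str(ann)]


def _stage_mappability(config: PipelineConfig, state: Dict, outdir: Path) -> List[str]:
    params = MappabilityParams(
        k=config.k, ext=config.ext, poor_threshold=config.poor_threshold
    )
    track = mappability_track(state["build"], params)
    state["mappability"] = track
    summaries = classify_and_summarize(track, state["annotation"], params)
    bg = outdir / "mappability.bedgraph"
    ins = state["build"].insertion
    mapp_track = SignalTrack(
        chrom=ins.chrom,
        start=ins.offset,
        values=track.counts.astype(float),
        total_fragments=0,
        bandwidth=0.0,
    )
    write_bedgraph(mapp_track, bg)
    summary = outdir / "mappability_summary.tsv"
    write_tsv(
        [
            (s.region, s.bases_total, s.bases_above_threshold, s.fraction_above_threshold)
            for s in summaries
        ],
        ["region", "bases_total", "bases_above_threshold", "fraction_above_threshold"],
        summary,
    )
    return [str(bg), str(summary)]


def _simulate_sample_reads(
    config: PipelineConfig, state: Dict, sample: SampleConfig, stream: int
):
    spec = SyntheticReadSpec(
        n_reads=sample.n_reads,
        read_length=config.read_length,
        frag_size=config.frag_size,
        enrichment_sites=_sites_for(sample, state["build"].repeat_length),
        enriched_fraction=sample.enriched_fraction,
        dup_rate=sample.dup_rate,
        seed=config.seed * 1000 + stream,
    )
    return simulate_reads(state["build"], spec, mode="chip").reads


def _stage_signal(config: PipelineConfig, state: Dict, outdir: Path) -> List[str]:
    build: GenomeBuild = state["build"]
    ins = build.insertion
    region = (ins.chrom, 0, len(build.sequences[ins.chrom]))
    state["region"] = region
    outputs = []

    # input library
    if config.input_reads:
        input_reads = read_reads(config.input_reads)
    else:
        spec = SyntheticReadSpec(
            n_reads=config.input_n_reads,
            read_length=config.read_length,
            frag_size=config.frag_size,
            enrichment_sites=(),
            enriched_fraction=0.0,
            dup_rate=0.0,
            seed=config.seed * 1000 + _STREAM_INPUT,
        )
        input_reads = simulate_reads(build, spec, mode="input").reads
    input_frags = dedup(input_reads, frag_size=config.frag_size)
    state["input_track"] = kde_track(input_frags, region, config.bandwidth)
    path = outdir / "input.bedgraph"
    write_bedgraph(state["input_track"], path)
    outputs.append(str(path))

    state["chip_tracks"] = {}
    for i, sample in enumerate(config.samples):
        if sample.reads:
            reads = read_reads(sample.reads)
        else:
            reads = _simulate_sample_reads(config, state, sample, _STREAM_SAMPLE0 + i)
        bed = outdir / f"{sample.name}.reads.bed"
        write_reads_bed(reads, bed)
        frags = dedup(reads, frag_size=config.frag_size)
        track = kde_track(frags, region, config.bandwidth)
        state["chip_tracks"][sample.name] = track
        path = outdir / f"{sample.name}.bedgraph"
        write_bedgraph(track, path)
        outputs.extend([str(bed), str(path)])
    return outputs


def _stage_subtract(config: PipelineConfig, state: Dict, outdir: Path) -> List[str]:
    outputs = []
    state["subtracted"] = {}
    for name, track in state["chip_tracks"].items():
        sub = subtract_input(track, state["input_track"])
        state["subtracted"][name] = sub
        path = outdir / f"{name}.subtracted.bedgraph"
        write_bedgraph(sub, path)
        outputs.append(str(path))
    return outputs


def _stage_peaks(config: PipelineConfig, state: Dict, outdir: Path) -> List[str]:
    outputs = []
    state["peaks"] = {}
    source = state["subtracted"] if config.subtract_for_peaks else state["chip_tracks"]
    for name, track in source.items():
        peaks = call_peaks(
            track,
            threshold_sd=config.threshold_sd,
            background=config.background,
            seed=config.seed,
        )
        state["peaks"][name] = peaks
        path = outdir / f"{name}.peaks.bed"
        write_peaks(peaks, path)
        outputs.append(str(path))
    return outputs


def _stage_ntd(config: PipelineConfig, state: Dict, outdir: Path) -> List[str]:
    ins = state["build"].insertion
    interval = (ins.chrom, ins.offset, ins.end)
    rows = []
    for name, peaks in state["peaks"].items():
        try:
            ntd = normalized_tag_density(peaks, interval)
            rows.append(
                (
                    name,
                    ntd.value,
                    ntd.mean_inside,
                    ntd.mean_outside,
                    ntd.n_peaks_inside,
                    ntd.n_peaks_outside,
                )
            )
        except TagDensityUndefinedError:
            n_in = sum(1 for p in peaks if ins.offset <= p.summit < ins.end)
            rows.append((name, "NA", "NA", "NA", n_in, len(peaks) - n_in))
    path = outdir / "ntd.tsv"
    write_tsv(
        rows,
        ["sample", "value", "mean_inside", "mean_outside", "n_inside", "n_outside"],
        path,
    )
    return [str(path)]


def _stage_bins(config: PipelineConfig, state: Dict, outdir: Path) -> List[str]:
    build: GenomeBuild = state["build"]
    ins = build.insertion
    profiles = []
    for name, sub in state["subtracted"].items():
        # restrict the track to the repeat interval before binning
        repeat_track = SignalTrack(
            chrom=sub.chrom,
            start=ins.offset,
            values=sub.values[ins.offset - sub.start : ins.end - sub.start],
            total_fragments=sub.total_fragments,
            bandwidth=sub.bandwidth,
        )
        profiles.append(bin_median(repeat_track, config.bin_size, name=name))
    state["profiles"] = profiles
    path = outdir / "bins.tsv"
    n_bins = len(profiles[0]) if profiles else 0
    rows = [
        [j * config.bin_size] + [p.medians[j] for p in profiles] for j in range(n_bins)
    ]
    write_tsv(rows, ["bin_start"] + [p.name for p in profiles], path)
    return [str(path)]


def _stage_correlate(config: PipelineConfig, state: Dict, outdir: Path) -> List[str]:
    profiles = state["profiles"]
    if len(profiles) < 2:
        return []  # stage recorded in manifest; nothing to correlate
    cm = correlation_matrix(profiles, score=config.score)
    path = outdir / "matrix.tsv"
    rows = [
        [cm.names[i]] + [cm.scores[i, j] for j in range(len(cm.names))]
        for i in range(len(cm.names))
    ]
    write_tsv(rows, ["sample"] + cm.names, path)
    order_path = outdir / "dendrogram_order.tsv"
    write_tsv(
        [(rank, i, cm.names[i]) for rank, i in enumerate(cm.order)],
        ["rank", "index", "sample"],
        order_path,
    )
    reg_path = outdir / "regressions.tsv"
    reg_rows = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            r = pairwise_regression(profiles[i], profiles[j])
            reg_rows.append(
                (
                    f"{profiles[i].name}~{profiles[j].name}",
                    r.slope,
                    r.intercept,
                    r.r_squared,
                    r.r_squared_adjusted,
                    r.f_test_p,
                )
            )
    write_tsv(
        reg_rows,
        ["pair", "slope", "intercept", "r_squared", "adj_r_squared", "f_test_p"],
        reg_path,
    )
    return [str(path), str(order_path), str(reg_path)]


_STAGE_FUNCS = {
    "build": _stage_build,
    "mappability": _stage_mappability,
    "signal": _stage_signal,
    "subtract": _stage_subtract,
    "peaks": _stage_peaks,
    "ntd": _stage_ntd,
    "bins": _stage_bins,
    "correlate": _stage_correlate,
}
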