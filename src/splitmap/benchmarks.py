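"""Simulation benchmark protocol: dataset recipes and one-call runs.

Each benchmark simulates a dataset under a named protocol, maps the
reads with default mapping parameters, calls junctions with a split-read
support filter of two (singleton calls are dominated by error-shifted
breakpoints), and scores the predictions against the witnessed truth
junction catalog at exact breakpoint tolerance.

Two size presets are provided: ``full`` (multi-megabase genome, ~200
isoforms) and ``small`` (the same protocol at the lower end of the
desk-scale range, for fast test runs).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Optional, Tuple

from .evaluate import EvalReport, match_junctions, truth_from_frame
from .index import build_index
from .junctions import JunctionParams
from .pipeline import MapParams, MapResult, map_reads
from .simulate import (
    SimConfig,
    simulate_genome,
    simulate_isoforms,
    simulate_reads,
    truth_junction_catalog,
)

#: split-read support required for a junction call in benchmark runs
BENCHMARK_MIN_SUPPORT = 2

_FULL = {
    "regular400": SimConfig(
        genome_size=4_000_000, n_isoforms=200, read_length=400,
        coverage=10, error_model="454", irregular_fraction=0.0,
    ),
    "mixed400": SimConfig(
        genome_size=4_000_000, n_isoforms=200, read_length=400,
        coverage=10, error_model="454", irregular_fraction=0.20,
    ),
    "regular100": SimConfig(
        genome_size=4_000_000, n_isoforms=200, read_length=100,
        coverage=10, error_model="illumina", irregular_fraction=0.0,
    ),
    "mixed100": SimConfig(
        genome_size=4_000_000, n_isoforms=200, read_length=100,
        coverage=10, error_model="illumina", irregular_fraction=0.20,
    ),
    "circular100": SimConfig(
        genome_size=2_000_000, n_isoforms=100, exons_per_isoform=(1, 3),
        exon_length=(150, 300), circular=True, read_length=100,
        coverage=10, error_model="illumina", irregular_fraction=0.0,
    ),
    "long454_linear": SimConfig(
        genome_size=2_000_000, n_isoforms=50, exons_per_isoform=(3, 12),
        exon_length=(150, 450), full_length_reads=True, coverage=4,
        error_model="454", irregular_fraction=0.0,
    ),
    "long454_circular": SimConfig(
        genome_size=2_000_000, n_isoforms=50, exons_per_isoform=(3, 12),
        exon_length=(150, 450), circular=True, full_length_reads=True,
        coverage=4, error_model="454", irregular_fraction=0.0,
    ),
}


def _shrink(cfg: SimConfig) -> SimConfig:
    return replace(
        cfg,
        genome_size=max(1_000_000, cfg.genome_size // 4),
        n_isoforms=max(25, cfg.n_isoforms // 2),
    )


def benchmark_config(kind: str, preset: str = "full", seed: int = 0) -> SimConfig:
    if kind not in _FULL:
        raise ValueError(f"unknown benchmark kind {kind!r}")
    cfg = _FULL[kind]
    if preset == "small":
        cfg = _shrink(cfg)
    elif preset != "full":
        raise ValueError(f"unknown preset {preset!r}")
    return replace(cfg, seed=seed)


@dataclass
class BenchmarkRun:
    kind: str
    config: SimConfig
    n_reads: int
    n_truth: int
    result: MapResult
    report: EvalReport


def run_benchmark(
    kind: str,
    seed: int = 0,
    preset: str = "full",
    params: Optional[MapParams] = None,
) -> BenchmarkRun:
    """Simulate, map and evaluate one benchmark dataset."""
    cfg = benchmark_config(kind, preset, seed)
    genome = simulate_genome(cfg)
    isoforms, _ = simulate_isoforms(genome, cfg)
    reads, read_truth = simulate_reads(isoforms, cfg)
    index = build_index(genome)
    if params is None:
        params = MapParams(
            junction=JunctionParams(min_support=BENCHMARK_MIN_SUPPORT)
        )
    result = map_reads(((r.name, r.sequence) for r in reads), index, params)
    catalog = truth_junction_catalog(read_truth)
    report = match_junctions(result.junctions, truth_from_frame(catalog))
    return BenchmarkRun(
        kind=kind,
        config=cfg,
        n_reads=len(reads),
        n_truth=report.n_truth,
        result=result,
        report=report,
    )
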