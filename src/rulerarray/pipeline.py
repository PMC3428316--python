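"""Library-level orchestration of the simulate / call / evaluate stages.

These functions are the programmatic interface behind the CLI commands and
the benchmark drivers; each stage logs its counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .calling import EvalReport, IndelCall, call_indels, evaluate_calls
from .config import RunConfig
from .preprocess import NormalizedTrack, build_track
from .segmentation import IntervalFit, fit_genome
from .synthetic_data import (
    SimResult,
    hotspot_repeat_variants,
    random_indel_variants,
    restriction_map,
    simulate_experiment,
)

logger = logging.getLogger(__name__)

__all__ = ["run_call", "simulate_benchmark", "simulate_hotspot_benchmark",
           "benchmark_sensitivity", "hotspot_detection"]


def run_call(probes: pd.DataFrame, intensities: pd.DataFrame,
             sites: np.ndarray, cfg: RunConfig):
    """filter -> normalize -> per-interval joint fit -> classify boundaries.

    Returns ``(track, fits, calls)``.
    """
    track = build_track(probes, intensities, sites, cfg.preprocess)
    fits = fit_genome(track, cfg.segmentation)
    spacing = int(np.median(np.diff(track.position))) if len(track) > 1 else None
    calls = call_indels(fits, track, cfg.calling, probe_spacing=spacing)
    return track, fits, calls


def simulate_benchmark(cfg: RunConfig, n_variants: int = 40,
                       size_range=(100, 2000)) -> tuple[SimResult, list]:
    """Default indel benchmark: mixed insertions/deletions, 10% of variants
    are recognition-site-carrying insertions."""
    rng = np.random.default_rng(cfg.sim.seed + 7_001)  # placement stream
    variants = random_indel_variants(cfg.sim, rng, n=n_variants, size_range=size_range)
    return simulate_experiment(cfg.sim, variants), variants


def simulate_hotspot_benchmark(cfg: RunConfig, deltas=(2,), n_per_delta: int = 20):
    """Hotspot benchmark: AT tracts with elevated termination whose length
    differs between channels by each value in ``deltas``."""
    rng = np.random.default_rng(cfg.sim.seed + 7_002)
    variants = hotspot_repeat_variants(cfg.sim, rng, deltas, n_per_delta=n_per_delta)
    return simulate_experiment(cfg.sim, variants), variants


def benchmark_sensitivity(cfg: RunConfig) -> tuple[EvalReport, SimResult, list[IndelCall]]:
    """End-to-end run of the default benchmark at cfg.sim.seed."""
    sim, _ = simulate_benchmark(cfg)
    _, _, calls = run_call(sim.probes, sim.intensities, sim.sites_ref, cfg)
    report = evaluate_calls(calls, sim.truth, cfg.calling.tolerance, cfg.calling.min_size)
    logger.info("benchmark seed %d: %s", cfg.sim.seed, report.summary())
    return report, sim, calls


def hotspot_detection(cfg: RunConfig, deltas=(2,), n_per_delta: int = 20):
    """Per-tract detection of hotspot repeat-length changes.

    Returns a DataFrame with one row per simulated tract (size, detected).
    """
    sim, _ = simulate_hotspot_benchmark(cfg, deltas, n_per_delta)
    _, _, calls = run_call(sim.probes, sim.intensities, sim.sites_ref, cfg)
    report = evaluate_calls(calls, sim.truth, cfg.calling.tolerance, min_size=0)
    t = report.truth_matched
    return pd.DataFrame({"size": t["size"].abs(), "detected": t["matched"]}), calls
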