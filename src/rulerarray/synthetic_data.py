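"""Paired-genome, two-channel ruler-array simulator.

Emulates a two-strain comparison experiment: a reference genome (channel A)
and a variant genome (channel B) differing by insertions, deletions and
repeat-length changes are digested in silico with a restriction enzyme, and
per-probe hybridization intensities are generated from the extension-
coverage model of :mod:`rulerarray.ruler_model`.

Probes are designed on the reference genome; channel-B signal is evaluated
at each probe's coordinate mapped through the variants.  AT-repeat hotspot
tracts carry an elevated per-base termination probability in both genomes,
so that even a 2 bp tract-length difference between the genomes produces a
persistent intensity step in one channel.

Noise model: a per-probe lognormal affinity shared by both channels
(sequence-dependent hybridization efficiency) plus independent per-channel
Gaussian noise on the log2 scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import SimulationConfig
from .ruler_model import (
    ExtensionModel,
    cumulative_log2_survival,
    expected_log_profile_varp,
)

logger = logging.getLogger(__name__)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

__all__ = [
    "Variant",
    "SimResult",
    "generate_genome",
    "restriction_map",
    "apply_variants",
    "CoordinateMap",
    "plant_hotspot_tracts",
    "simulate_experiment",
    "random_indel_variants",
    "hotspot_repeat_variants",
]


@dataclass
class Variant:
    """A structural difference between the reference and channel-B genome.

    ``size`` is the signed change in channel-B genome length (positive =
    insertion, negative = deletion).  For hotspot repeat changes the
    elevated-termination tract occupies ``[ref_position - tract_len,
    ref_position)`` on the reference and the length change is applied at
    ``ref_position`` (the tract's right edge); ``tract_len`` comes from
    :class:`SimulationConfig`.
    """

    kind: str  # insertion | deletion | repeat_change
    ref_position: int
    size: int
    carries_site: bool = False
    hotspot: bool = False
    seq: str | None = None  # inserted bases; synthesized if None

    def __post_init__(self) -> None:
        if self.kind not in ("insertion", "deletion", "repeat_change"):
            raise ValueError(f"unknown variant kind {self.kind!r}")
        if self.size == 0:
            raise ValueError("variant size must be nonzero")
        if self.kind == "deletion" and self.size > 0:
            raise ValueError("deletion size must be negative")
        if self.kind == "insertion" and self.size < 0:
            raise ValueError("insertion size must be positive")

    @property
    def del_span(self) -> tuple[int, int]:
        """Reference interval removed by this variant (empty for insertions)."""
        if self.size < 0:
            if self.hotspot:
                # length change applied at the tract's right edge
                return (self.ref_position + self.size, self.ref_position)
            return (self.ref_position, self.ref_position - self.size)
        return (self.ref_position, self.ref_position)


class CoordinateMap:
    """Monotone map from reference to alternate coordinates.

    Built from the unchanged blocks between variants; positions falling in
    a deleted interval map to -1.
    """

    def __init__(self, ref_starts: np.ndarray, ref_ends: np.ndarray,
                 alt_starts: np.ndarray, alt_length: int):
        self.ref_starts = ref_starts
        self.ref_ends = ref_ends
        self.alt_starts = alt_starts
        self.alt_length = alt_length

    def map(self, positions) -> np.ndarray:
        pos = np.asarray(positions, dtype=np.int64)
        idx = np.searchsorted(self.ref_starts, pos, side="right") - 1
        idx = np.clip(idx, 0, len(self.ref_starts) - 1)
        inside = (pos >= self.ref_starts[idx]) & (pos < self.ref_ends[idx])
        out = np.where(inside, self.alt_starts[idx] + (pos - self.ref_starts[idx]), -1)
        return out


def generate_genome(config: SimulationConfig, rng: np.random.Generator | None = None) -> str:
    """I.i.d. uniform-base genome of ``config.genome_length`` bp."""
    if config.genome_length < 1:
        raise ValueError("genome_length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    codes = rng.integers(0, 4, size=config.genome_length)
    return bytes(_BASES[codes]).decode("ascii")


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def restriction_map(sequence: str, recognition_seq: str) -> np.ndarray:
    """Sorted unique 0-based start positions of the recognition sequence.

    Both orientations are searched (for a palindromic site such as EcoRI
    GAATTC they coincide); overlapping occurrences are each reported.
    """
    if not sequence or not recognition_seq:
        raise ValueError("sequence and recognition_seq must be non-empty")
    hits: set[int] = set()
    for motif in {recognition_seq, _revcomp(recognition_seq)}:
        start = sequence.find(motif)
        while start != -1:
            hits.add(start)
            start = sequence.find(motif, start + 1)
    return np.array(sorted(hits), dtype=np.int64)


def _scrub_motif(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Remove accidental recognition-site occurrences from an insert."""
    for m in {motif, _revcomp(motif)}:
        while m in seq:
            i = seq.index(m)
            repl = "ACGT"[(("ACGT".index(seq[i]) + 1 + int(rng.integers(3))) % 4)]
            seq = seq[:i] + repl + seq[i + 1:]
    return seq


def _random_insert(n: int, recognition_seq: str, carries_site: bool,
                   rng: np.random.Generator) -> str:
    codes = rng.integers(0, 4, size=n)
    seq = bytes(_BASES[codes]).decode("ascii")
    seq = _scrub_motif(seq, recognition_seq, rng)
    if carries_site:
        if n < len(recognition_seq):
            raise ValueError("carries_site insertion shorter than recognition sequence")
        mid = (n - len(recognition_seq)) // 2
        seq = seq[:mid] + recognition_seq + seq[mid + len(recognition_seq):]
    return seq


def _realize_insert_seqs(variants: Sequence[Variant], config: SimulationConfig,
                         rng: np.random.Generator) -> list[Variant]:
    out = []
    for v in variants:
        if v.size > 0 and v.seq is None:
            if v.hotspot:
                seq = ("AT" * (v.size // 2 + 1))[: v.size]  # continue tract alternation
            else:
                seq = _random_insert(v.size, config.recognition_seq, v.carries_site, rng)
            v = replace(v, seq=seq)
        out.append(v)
    return out


def apply_variants(ref_sequence: str, variants: Sequence[Variant]):
    """Apply sorted, non-overlapping variants; return ``(alt, CoordinateMap)``.

    Insertions must carry their inserted sequence (``Variant.seq``); use
    :func:`simulate_experiment` or ``_realize_insert_seqs`` to synthesize
    them reproducibly.
    """
    n = len(ref_sequence)
    vs = sorted(variants, key=lambda v: v.del_span[0])
    prev_end = 0
    for v in vs:
        a, b = v.del_span
        if a < 0 or b > n:
            raise ValueError(f"variant at {v.ref_position} outside the sequence")
        if a < prev_end:
            raise ValueError(f"overlapping variants at ref position {a}")
        prev_end = max(b, a + 1)  # two insertions at one position also collide
        if v.size > 0 and v.seq is None:
            raise ValueError("insertion variant lacks an inserted sequence")
        if v.size > 0 and len(v.seq) != v.size:
            raise ValueError("inserted sequence length must equal variant size")

    pieces: list[str] = []
    ref_starts, ref_ends, alt_starts = [], [], []
    cur = 0
    alt_pos = 0
    for v in vs:
        a, b = v.del_span
        ins = v.seq if v.size > 0 else ""
        ref_starts.append(cur)
        ref_ends.append(a)
        alt_starts.append(alt_pos)
        pieces.append(ref_sequence[cur:a])
        alt_pos += a - cur
        if ins:
            pieces.append(ins)
            alt_pos += len(ins)
        cur = b
    ref_starts.append(cur)
    ref_ends.append(n)
    alt_starts.append(alt_pos)
    pieces.append(ref_sequence[cur:])
    alt_pos += n - cur

    alt = "".join(pieces)
    cmap = CoordinateMap(
        np.array(ref_starts, dtype=np.int64),
        np.array(ref_ends, dtype=np.int64),
        np.array(alt_starts, dtype=np.int64),
        alt_length=alt_pos,
    )
    assert len(alt) == cmap.alt_length == n + sum(v.size for v in vs)
    return alt, cmap


def plant_hotspot_tracts(ref_sequence: str, variants: Sequence[Variant],
                         tract_len: int) -> str:
    """Overwrite the reference with an AT-alternation repeat at every
    hotspot tract ``[ref_position - tract_len, ref_position)``."""
    seq = ref_sequence
    for v in variants:
        if not v.hotspot:
            continue
        a = v.ref_position - tract_len
        if a < 0 or v.ref_position > len(seq):
            raise ValueError("hotspot tract outside the sequence")
        tract = ("AT" * (tract_len // 2 + 1))[:tract_len]
        seq = seq[:a] + tract + seq[v.ref_position:]
    return seq


def _tract_spans_ref(variants: Sequence[Variant], tract_len: int):
    return [(v.ref_position - tract_len, v.ref_position)
            for v in variants if v.hotspot]


def _tract_spans_alt(variants: Sequence[Variant], tract_len: int, cmap: CoordinateMap):
    spans = []
    for v in variants:
        if not v.hotspot:
            continue
        a = int(cmap.map([v.ref_position - tract_len])[0])
        spans.append((a, a + tract_len + v.size))
    return spans


def _pmap(length: int, p: float, hot_p: float, tracts) -> np.ndarray:
    pm = np.full(length, p)
    for a, b in tracts:
        pm[a:b] = hot_p
    return pm


@dataclass
class SimResult:
    """Everything a simulated experiment produced."""

    probes: pd.DataFrame       # probe_id, chrom, start, end, hit_count, hit_length
    intensities: pd.DataFrame  # probe_id, intensity_A, intensity_B (linear)
    truth: pd.DataFrame        # chrom, ref_start, ref_end, kind, size, carries_site, hotspot, hard
    ref_sequence: str
    alt_sequence: str
    sites_ref: np.ndarray
    sites_alt: np.ndarray
    log2_expected_a: np.ndarray = field(repr=False, default=None)
    log2_expected_b: np.ndarray = field(repr=False, default=None)
    coordinate_map: CoordinateMap | None = None


def _expected_profiles(config: SimulationConfig, ref: str, alt: str,
                       variants: Sequence[Variant], cmap: CoordinateMap,
                       starts: np.ndarray):
    """Noiseless expected log2 profiles for both channels at reference-designed
    probe start coordinates."""
    model = ExtensionModel(config.p_term, config.end_mode, config.background)
    sites_ref = restriction_map(ref, config.recognition_seq)
    sites_alt = restriction_map(alt, config.recognition_seq)
    tl = config.hotspot_tract_len
    p_ref = _pmap(len(ref), config.p_term, config.hotspot_p_term,
                  _tract_spans_ref(variants, tl))
    p_alt = _pmap(len(alt), config.p_term, config.hotspot_p_term,
                  _tract_spans_alt(variants, tl, cmap))
    floor = np.log2(config.background) if config.background > 0 \
        else np.log2(np.finfo(float).tiny)
    if sites_ref.size == 0:  # no anchors: background everywhere
        logger.warning("reference genome contains no recognition sites")
        prof_a = np.full(starts.size, floor)
    else:
        prof_a = expected_log_profile_varp(starts, sites_ref,
                                           cumulative_log2_survival(p_ref), model,
                                           gain=config.gain_a)
    mapped = cmap.map(starts)
    prof_b = np.full(starts.size, floor)
    ok = mapped >= 0
    if sites_alt.size:
        prof_b[ok] = expected_log_profile_varp(mapped[ok], sites_alt,
                                               cumulative_log2_survival(p_alt), model,
                                               gain=config.gain_b)
    return prof_a, prof_b, sites_ref, sites_alt


def simulate_experiment(config: SimulationConfig,
                        variants: Sequence[Variant] = (),
                        ref_sequence: str | None = None) -> SimResult:
    """Run the full in-silico experiment; see module docstring.

    All randomness derives from ``config.seed``.  Passing an explicit
    ``ref_sequence`` bypasses genome generation (hotspot tracts are still
    planted on it).
    """
    rng = np.random.default_rng(config.seed)
    ref = ref_sequence if ref_sequence is not None else generate_genome(config, rng)
    ref = plant_hotspot_tracts(ref, variants, config.hotspot_tract_len)
    variants = _realize_insert_seqs(variants, config, rng)
    alt, cmap = apply_variants(ref, variants)

    starts = np.arange(0, len(ref) - config.probe_length + 1, config.probe_spacing,
                       dtype=np.int64)
    prof_a, prof_b, sites_ref, sites_alt = _expected_profiles(
        config, ref, alt, variants, cmap, starts)

    n = starts.size
    affinity = rng.normal(0.0, config.affinity_sd_log2, n)
    noise_a = rng.normal(0.0, config.noise_sd_log2, n)
    noise_b = rng.normal(0.0, config.noise_sd_log2, n)
    int_a = np.power(2.0, prof_a + affinity + noise_a)
    int_b = np.power(2.0, prof_b + affinity + noise_b)

    probe_ids = [f"P{i:07d}" for i in range(n)]
    hit_count = np.ones(n, dtype=np.int64)
    hit_length = np.full(n, config.probe_length, dtype=np.int64)
    if config.multi_hit_fraction > 0:
        bad = rng.random(n) < config.multi_hit_fraction
        half = rng.random(n) < 0.5
        hit_count[bad & half] = 2          # multi-mappers
        hit_length[bad & ~half] = 50       # marginal partial hits
    probes = pd.DataFrame({
        "probe_id": probe_ids,
        "chrom": config.chrom,
        "start": starts,
        "end": starts + config.probe_length,
        "hit_count": hit_count,
        "hit_length": hit_length,
    })
    intensities = pd.DataFrame({
        "probe_id": probe_ids,
        "intensity_A": int_a,
        "intensity_B": int_b,
    })
    truth = _truth_table(config, variants, sites_ref, starts, prof_a, prof_b)
    return SimResult(probes, intensities, truth, ref, alt, sites_ref, sites_alt,
                     prof_a, prof_b, cmap)


def _truth_table(config: SimulationConfig, variants: Sequence[Variant],
                 sites_ref: np.ndarray, starts: np.ndarray,
                 prof_a: np.ndarray, prof_b: np.ndarray) -> pd.DataFrame:
    """One truth record per variant, with the `hard` flag for the two
    failure geometries: within 200 bp of a restriction site, or a predicted
    noiseless difference-track step below 0.1 log2 (signal cancellation far
    from both sites)."""
    diff = prof_b - prof_a
    rows = []
    for v in variants:
        a, b = v.del_span
        if a == b:  # insertion point
            ref_start, ref_end = v.ref_position, v.ref_position + 1
        else:
            ref_start, ref_end = a, b
        near_site = False
        if sites_ref.size:
            i = np.searchsorted(sites_ref, (ref_start + ref_end) // 2)
            for j in (i - 1, i):
                if 0 <= j < sites_ref.size:
                    s = sites_ref[j]
                    if ref_start - 200 <= s <= ref_end + 200:
                        near_site = True
        lo = np.searchsorted(starts, ref_start - 2 * config.probe_spacing)
        hi = np.searchsorted(starts, ref_end + 2 * config.probe_spacing)
        window = diff[max(lo - 1, 0):hi + 1]
        signal = float(np.max(np.abs(np.diff(window)))) if window.size >= 2 else 0.0
        rows.append({
            "chrom": config.chrom, "ref_start": int(ref_start), "ref_end": int(ref_end),
            "kind": v.kind, "size": int(v.size), "carries_site": bool(v.carries_site),
            "hotspot": bool(v.hotspot), "hard": bool(near_site or signal < 0.1),
            "signal": round(signal, 4),
        })
    return pd.DataFrame(rows, columns=["chrom", "ref_start", "ref_end", "kind", "size",
                                       "carries_site", "hotspot", "hard", "signal"])


def _spaced_positions(rng: np.random.Generator, n: int, lo: int, hi: int,
                      min_gap: int) -> np.ndarray:
    """n sorted positions in [lo, hi) at least min_gap apart."""
    span = hi - lo - (n - 1) * min_gap
    if span <= 0:
        raise ValueError("genome too small for requested variant count/spacing")
    raw = np.sort(rng.integers(0, span, size=n))
    return lo + raw + min_gap * np.arange(n)


def random_indel_variants(config: SimulationConfig, rng: np.random.Generator,
                          n: int = 40, size_range: tuple[int, int] = (100, 2000),
                          carries_site_frac: float = 0.1,
                          min_gap: int = 10_000) -> list[Variant]:
    """Benchmark variant set: ``n`` mixed insertions/deletions with sizes
    uniform in ``size_range``, a fraction of insertions carrying the
    recognition site, placed uniformly with a minimum separation."""
    margin = max(min_gap, 5000)
    pos = _spaced_positions(rng, n, margin, config.genome_length - margin, min_gap)
    sizes = rng.integers(size_range[0], size_range[1] + 1, size=n)
    u = rng.random(n)
    variants = []
    for p, s, ui in zip(pos, sizes, u):
        if ui < carries_site_frac:
            variants.append(Variant("insertion", int(p), int(s), carries_site=True))
        elif ui < carries_site_frac + (1 - carries_site_frac) / 2:
            variants.append(Variant("insertion", int(p), int(s)))
        else:
            variants.append(Variant("deletion", int(p), -int(s)))
    return variants


def hotspot_repeat_variants(config: SimulationConfig, rng: np.random.Generator,
                            deltas: Iterable[int], n_per_delta: int = 5,
                            min_gap: int = 20_000) -> list[Variant]:
    """Hotspot repeat-change set: for each length difference in ``deltas``,
    ``n_per_delta`` AT tracts whose channel-B length differs by that many bp."""
    deltas = list(deltas)
    n = len(deltas) * n_per_delta
    margin = max(min_gap, 5000)
    pos = _spaced_positions(rng, n, margin, config.genome_length - margin, min_gap)
    order = rng.permutation(n)
    variants = []
    for k, p in enumerate(pos):
        d = deltas[order[k] % len(deltas)]
        variants.append(Variant("repeat_change", int(p), int(d), hotspot=True))
    return variants
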