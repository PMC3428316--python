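"""Readers and writers for the pipeline's plain-text formats.

Coordinates are 0-based half-open everywhere (including BED).  TSV files
carry mandatory headers; '.' marks missing values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

PROBE_COLUMNS = ["probe_id", "chrom", "start", "end", "hit_count", "hit_length"]
INTENSITY_COLUMNS = ["probe_id", "intensity_A", "intensity_B"]
TRUTH_COLUMNS = ["chrom", "ref_start", "ref_end", "kind", "size",
                 "carries_site", "hotspot", "hard", "signal"]
SITES_COLUMNS = ["chrom", "position"]


class InputFormatError(ValueError):
    pass


def _read_tsv(path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:  # pandas reports the offending line
        raise InputFormatError(f"{path}: {exc}") from exc
    missing = set(required) - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def read_probes(path) -> pd.DataFrame:
    return _read_tsv(path, PROBE_COLUMNS)


def read_intensities(path) -> pd.DataFrame:
    df = _read_tsv(path, INTENSITY_COLUMNS)
    bad = df.index[(df["intensity_A"] <= 0) | (df["intensity_B"] <= 0)
                   | df["intensity_A"].isna() | df["intensity_B"].isna()]
    if len(bad):
        raise InputFormatError(
            f"{path}: nonpositive or missing intensity at data line(s) "
            f"{[int(i) + 2 for i in bad[:5]]}")  # +2: header + 1-based
    return df


def read_truth(path) -> pd.DataFrame:
    return _read_tsv(path, TRUTH_COLUMNS[:8])


def read_sites(path) -> pd.DataFrame:
    return _read_tsv(path, SITES_COLUMNS)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def write_fasta(path, name: str, sequence: str) -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=name, description="")], str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_calls_bed(calls, path) -> None:
    """BED6: chrom, start, end, name=case, score=round(100*score) clipped
    to [0, 1000], strand='.'."""
    with open(path, "w") as fh:
        for c in calls:
            score = int(np.clip(round(100 * c.score), 0, 1000))
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.case}\t{score}\t.\n")


def read_calls_bed(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputFormatError(f"{path}: malformed BED at line {ln}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise InputFormatError(f"{path}: malformed BED at line {ln}") from exc
            rows.append({"chrom": parts[0], "start": start, "end": end,
                         "name": parts[3] if len(parts) > 3 else ".",
                         "score": int(parts[4]) if len(parts) > 4 else 0})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score"])


def calls_table(calls) -> pd.DataFrame:
    """Detailed per-call TSV payload."""
    return pd.DataFrame(
        [{"chrom": c.chrom, "start": c.start, "end": c.end, "case": c.case,
          "magnitude": round(c.magnitude, 4), "score": round(c.score, 3),
          "step_A": round(c.step_a, 4), "step_B": round(c.step_b, 4),
          "boundary_probe": c.boundary_probe} for c in calls],
        columns=["chrom", "start", "end", "case", "magnitude", "score",
                 "step_A", "step_B", "boundary_probe"])


def sites_table(chrom: str, sites: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"chrom": chrom, "position": np.asarray(sites, dtype=np.int64)})


def report_table(report) -> pd.DataFrame:
    return pd.DataFrame([{
        "sensitivity": round(report.sensitivity, 4),
        "n_true_positives": report.n_true_positives,
        "n_false_positives": report.n_false_positives,
        "n_truth": report.n_truth,
        "n_truth_scored": report.n_truth_scored,
    }])


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
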