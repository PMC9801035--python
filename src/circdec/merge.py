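"""Collect and harmonize circular junction counts from detector outputs.

Supported dialects:

* ``ciri2`` — tab-delimited with a header line; columns include circRNA_ID,
  chr, circRNA_start, circRNA_end, #junction_reads, strand. Coordinates are
  1-based inclusive and are converted to 0-based half-open (start - 1).
* ``circexplorer2`` — BED-like (annotate output): chrom, start, end, name,
  score, strand, ..., readNumber in column 13. A truncated BED6+1 form with
  the count in column 7 is also accepted. Already 0-based half-open.
* ``dcc`` — CircRNACount-style: chr, start, end, then one count column per
  sample (header row names the samples). BED convention, 0-based half-open.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .types import CircLocus, CjcTable, ConfigError, FormatError, GroupDesign

logger = logging.getLogger(__name__)

DIALECTS = ("ciri2", "circexplorer2", "dcc")


def _norm_strand(s: str) -> str:
    return s if s in ("+", "-") else "."


def _parse_int(text: str, what: str, path: str, lineno: int) -> int:
    try:
        value = int(float(text)) if "." in text else int(text)
    except ValueError:
        raise FormatError(f"{path}:{lineno}: unparseable {what} {text!r}") from None
    if value < 0:
        raise FormatError(f"{path}:{lineno}: negative {what} {text!r}")
    return value


def _data_lines(path: str) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


def _parse_ciri2(path: str) -> list[tuple[CircLocus, int]]:
    out: list[tuple[CircLocus, int]] = []
    header: list[str] | None = None
    for lineno, fields in _data_lines(path):
        if header is None and fields[0].lower().lstrip("#") == "circrna_id":
            header = fields
            continue
        if len(fields) < 11:
            raise FormatError(f"{path}:{lineno}: expected >= 11 columns, got {len(fields)}")
        chrom = fields[1]
        start1 = _parse_int(fields[2], "circRNA_start", path, lineno)
        end1 = _parse_int(fields[3], "circRNA_end", path, lineno)
        cjc = _parse_int(fields[4], "junction_reads", path, lineno)
        strand = _norm_strand(fields[10])
        if start1 < 1 or end1 < start1:
            raise FormatError(f"{path}:{lineno}: malformed coordinates {start1}..{end1}")
        # 1-based inclusive -> 0-based half-open
        out.append((CircLocus(chrom, start1 - 1, end1, strand), cjc))
    return out


def _parse_circexplorer2(path: str) -> list[tuple[CircLocus, int]]:
    out: list[tuple[CircLocus, int]] = []
    for lineno, fields in _data_lines(path):
        if len(fields) < 7:
            raise FormatError(f"{path}:{lineno}: expected >= 7 columns, got {len(fields)}")
        chrom = fields[0]
        start = _parse_int(fields[1], "start", path, lineno)
        end = _parse_int(fields[2], "end", path, lineno)
        strand = _norm_strand(fields[5])
        count_col = 12 if len(fields) >= 13 else 6
        cjc = _parse_int(fields[count_col], "readNumber", path, lineno)
        if start >= end:
            raise FormatError(f"{path}:{lineno}: malformed interval {start}..{end}")
        out.append((CircLocus(chrom, start, end, strand), cjc))
    return out


def _read_dcc_frame(path: str, what: str) -> pd.DataFrame:
    """DCC count-matrix file: chr/start/end header then per-sample columns."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 4:
        raise FormatError(f"{path}: DCC {what} needs chr, start, end and >=1 sample column")
    return df


def _parse_dcc(
    path: str, sample: str | None, coordinates: str | None
) -> list[tuple[CircLocus, int]]:
    counts = _read_dcc_frame(path, "CircRNACount")
    sample_cols = list(counts.columns[3:])
    if sample is None:
        if len(sample_cols) != 1:
            raise ConfigError(
                f"{path}: multiple sample columns {sample_cols}; specify which"
            )
        sample = sample_cols[0]
    if sample not in sample_cols:
        raise ConfigError(f"{path}: no sample column {sample!r} (have {sample_cols})")
    strands: dict[tuple[str, int, int], str] = {}
    if coordinates is not None:
        coords = pd.read_csv(coordinates, sep="\t", comment="#")
        strand_col = "Strand" if "Strand" in coords.columns else coords.columns[5]
        for _, row in coords.iterrows():
            strands[(str(row.iloc[0]), int(row.iloc[1]), int(row.iloc[2]))] = _norm_strand(
                str(row[strand_col])
            )
    out: list[tuple[CircLocus, int]] = []
    for i, row in counts.iterrows():
        chrom, start, end = str(row.iloc[0]), int(row.iloc[1]), int(row.iloc[2])
        if start >= end or start < 0:
            raise FormatError(f"{path}:{i + 2}: malformed interval {start}..{end}")
        strand = strands.get((chrom, start, end), ".")
        out.append((CircLocus(chrom, start, end, strand), int(row[sample])))
    return out


def parse_detector_output(
    path: str,
    dialect: str,
    *,
    sample: str | None = None,
    coordinates: str | None = None,
) -> list[tuple[CircLocus, int]]:
    """Parse one detector output file into (locus, CJC) pairs.

    Coordinates are harmonized to canonical 0-based half-open. For the
    ``dcc`` dialect ``path`` is the CircRNACount matrix, ``sample`` selects
    its count column, and ``coordinates`` (the CircCoordinates file) supplies
    strands when given.
    """
    if dialect not in DIALECTS:
        raise ConfigError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not Path(path).exists():
        raise FileNotFoundError(path)
    if dialect == "ciri2":
        parsed = _parse_ciri2(path)
    elif dialect == "circexplorer2":
        parsed = _parse_circexplorer2(path)
    else:
        parsed = _parse_dcc(path, sample, coordinates)
    if not parsed:
        logger.warning("%s: no circRNA records parsed", path)
    return parsed


def parse_dcc_linear(path: str, sample: str | None = None) -> list[tuple[CircLocus, int]]:
    """Read host-gene linear counts from a DCC LinearCount matrix."""
    return _parse_dcc(path, sample, None)


def merge_counts(
    parsed: Mapping[str, list[tuple[CircLocus, int]]], design: GroupDesign
) -> CjcTable:
    """Union per-sample (locus, CJC) lists into one loci x samples table.

    Missing (locus, sample) entries are 0. Duplicate rows for one locus
    within a sample are summed with a warning. Row order is deterministic:
    sorted by (chrom, start, end, strand).
    """
    missing = [s for s in design.samples if s not in parsed]
    if missing:
        raise ConfigError(f"samples in design but not parsed: {missing}")
    samples = design.samples
    per_sample: list[dict[CircLocus, int]] = []
    for s in samples:
        counts: dict[CircLocus, int] = defaultdict(int)
        seen: set[CircLocus] = set()
        for locus, cjc in parsed[s]:
            if locus in seen:
                logger.warning(
                    "sample %s: duplicate rows for %s; summing counts", s, locus.locus_id
                )
            seen.add(locus)
            counts[locus] += int(cjc)
        per_sample.append(dict(counts))
    loci = sorted(set().union(*[set(d) for d in per_sample]))
    mat = np.zeros((len(loci), len(samples)), dtype=np.int64)
    index = {loc: i for i, loc in enumerate(loci)}
    for j, d in enumerate(per_sample):
        for locus, cjc in d.items():
            mat[index[locus], j] = cjc
    return CjcTable(loci, list(samples), mat)


def filter_mean_cjc(table: CjcTable, min_mean: float = 2.0) -> CjcTable:
    """Keep loci whose mean CJC across all samples is >= ``min_mean``."""
    if min_mean < 0:
        raise ConfigError(f"min_mean must be non-negative, got {min_mean}")
    keep = table.cjc.mean(axis=1) >= min_mean
    return CjcTable(
        [loc for loc, k in zip(table.loci, keep) if k],
        list(table.samples),
        table.cjc[keep],
    )


def read_manifest(path: str) -> pd.DataFrame:
    """Read a sample manifest: columns sample, group, file, dialect[, pair_id]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"sample", "group", "file", "dialect"}
    if not required.issubset(df.columns):
        raise ConfigError(
            f"{path}: manifest needs columns {sorted(required)}, has {list(df.columns)}"
        )
    if df["sample"].duplicated().any():
        raise ConfigError(f"{path}: duplicate sample names in manifest")
    groups = df["group"].unique()
    if len(groups) != 2:
        raise ConfigError(f"{path}: manifest must declare exactly 2 groups, has {list(groups)}")
    return df


def design_from_manifest(df: pd.DataFrame, paired: bool = False) -> GroupDesign:
    groups = list(df["group"].unique())
    g1 = df[df["group"] == groups[0]]
    g2 = df[df["group"] == groups[1]]
    if paired:
        if "pair_id" not in df.columns or df["pair_id"].isna().any():
            raise ConfigError("paired design requires a pair_id manifest column")
        g1 = g1.sort_values("pair_id")
        g2 = g2.sort_values("pair_id")
        if list(g1["pair_id"]) != list(g2["pair_id"]):
            raise ConfigError("pair_id values do not match 1:1 across groups")
    return GroupDesign(list(g1["sample"]), list(g2["sample"]), paired=paired)
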