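"""Estimate circRNA lengths from gene annotation and derive effective lengths.

The circle's sequence length ``e`` matters for effective-length correction:
small circles (e < 2L) expose fewer start positions for junction-spanning
reads. ``e`` is estimated from a GTF by picking, among transcripts whose
exon boundaries hit both back-splice coordinates exactly, the one with the
most exons inside the circle, and summing its exon lengths clipped to the
circle; loci without a matching transcript fall back to the genomic span.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import CircLocus, EffectiveLengths

logger = logging.getLogger(__name__)

# tolerate transcript_id "X";, transcript_id X; and key=value styles
_TX_ID = re.compile(r'transcript_id[ =]+"?([^";]+)"?')


@dataclass
class TranscriptModel:
    """Exon structure of one transcript: 0-based half-open exon intervals."""

    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]


class ExonIndex:
    """Transcript exon models grouped by chromosome for boundary lookup."""

    def __init__(self, transcripts: Iterable[TranscriptModel]):
        self.by_chrom: dict[str, list[TranscriptModel]] = defaultdict(list)
        for tx in transcripts:
            tx.exons.sort()
            self.by_chrom[tx.chrom].append(tx)

    @classmethod
    def from_gtf(cls, path: str) -> "ExonIndex":
        """Read exon features from a GTF; requires a transcript_id attribute."""
        exons: dict[tuple[str, str, str], list[tuple[int, int]]] = defaultdict(list)
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 9:
                    continue
                if fields[2] != "exon":
                    continue
                m = _TX_ID.search(fields[8])
                if m is None:
                    logger.warning("%s:%d: exon without transcript_id; skipped", path, lineno)
                    continue
                chrom, strand = fields[0], fields[6]
                start1, end1 = int(fields[3]), int(fields[4])
                # GTF is 1-based inclusive
                exons[(m.group(1), chrom, strand)].append((start1 - 1, end1))
        return cls(
            TranscriptModel(tid, chrom, strand, ivs)
            for (tid, chrom, strand), ivs in exons.items()
        )


def estimate_circ_length(
    locus: CircLocus, annotation: ExonIndex | None
) -> tuple[int, str]:
    """Estimate the circRNA length ``e`` for one back-spliced site.

    Returns ``(e, source)`` with source ``"annotation"`` when a transcript
    matched both boundaries, else ``"span"`` (e = end - start). Boundary
    matching requires exact exon-edge equality; when strand is unknown both
    strands are candidates. Ties on exon count break to the longest clipped
    exonic sum.
    """
    span = locus.end - locus.start
    if annotation is None:
        return span, "span"
    best: tuple[int, int] | None = None  # (n_exons_inside, exonic_sum)
    for tx in annotation.by_chrom.get(locus.chrom, ()):
        if locus.strand != "." and tx.strand in ("+", "-") and tx.strand != locus.strand:
            continue
        edges = {b for iv in tx.exons for b in iv}
        if locus.start not in edges or locus.end not in edges:
            continue
        inside = [
            (max(s, locus.start), min(e, locus.end))
            for s, e in tx.exons
            if s < locus.end and e > locus.start
        ]
        n_exons = len(inside)
        exonic = sum(e - s for s, e in inside)
        if best is None or (n_exons, exonic) > best:
            best = (n_exons, exonic)
    if best is None or best[1] <= 0:  # degenerate: no exonic bases inside
        return span, "span"
    return best[1], "annotation"


def annotate_lengths(
    loci: Sequence[CircLocus],
    annotation: ExonIndex | None,
    read_len: int,
    min_overhang: int,
    *,
    overrides: Mapping[str, int] | None = None,
    force_span: bool = False,
) -> tuple[list[EffectiveLengths], pd.DataFrame]:
    """Effective lengths for every locus, plus a provenance table.

    Without any annotation (and no ``force_span``), every locus takes the
    large-circle limit e >= 2L, under which psi reduces to the plain ratio
    CJC/(LJC/2 + CJC). ``overrides`` maps locus_id to an externally measured
    length (e.g. from full-length isoform reconstruction) and wins over all
    other sources.
    """
    L = read_len - min_overhang
    rows = []
    lengths = []
    for locus in loci:
        if overrides and locus.locus_id in overrides:
            e, source = int(overrides[locus.locus_id]), "override"
        elif annotation is not None:
            e, source = estimate_circ_length(locus, annotation)
        elif force_span:
            e, source = locus.end - locus.start, "span"
        else:
            e, source = 2 * L, "large-limit"
        lengths.append(EffectiveLengths(read_len, min_overhang, e))
        rows.append((locus.locus_id, e, source))
    table = pd.DataFrame(rows, columns=["locus_id", "e", "source"]).set_index("locus_id")
    return lengths, table


def effective_lengths(
    e: int, read_len: int, min_overhang: int
) -> EffectiveLengths:
    """Effective linear/circular lengths for a circle of length ``e``."""
    return EffectiveLengths(read_len=read_len, min_overhang=min_overhang, e=e)
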