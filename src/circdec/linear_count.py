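"""Count linear splice junctions at back-spliced sites from alignments.

A read supports the *upstream* linear junction of a circle when one of its
splice gaps (CIGAR N) ends exactly at ``locus.start`` — a linear splice from
an upstream exon into the circle's first boundary exon. It supports the
*downstream* junction when a gap starts exactly at ``locus.end``. Gaps
internal to the circle (exon skipping within it) never count. Only spliced,
primary, non-duplicate, non-supplementary alignments with mapping quality
>= ``min_mapq`` and >= ``min_overhang`` aligned bases on each side of the
gap are counted; a read contributes at most 1 to each of ljc_up/ljc_down
per locus. Counting is strand-agnostic.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Sequence

import numpy as np
import pysam

from .types import CircLocus, ConfigError, FormatError, LjcTable

logger = logging.getLogger(__name__)

DEFAULT_MIN_OVERHANG = 6
DEFAULT_MIN_MAPQ = 10

_CONSUME_REF = {0, 2, 3, 7, 8}  # M, D, N, =, X
_ALIGNED = {0, 7, 8}  # M, =, X


def _gaps_with_overhangs(
    cigartuples: Sequence[tuple[int, int]], pos: int
) -> list[tuple[int, int, int, int]]:
    """All splice gaps of one alignment as (gap_start, gap_end, left, right).

    ``left``/``right`` are the aligned (M/=/X) base counts between the gap
    and the adjacent gap or read end on each side.
    """
    segments: list[int] = [0]  # aligned bases per inter-gap segment
    gaps: list[tuple[int, int]] = []
    ref = pos
    for op, length in cigartuples:
        if op == 3:  # N
            gaps.append((ref, ref + length))
            segments.append(0)
        elif op in _ALIGNED:
            segments[-1] += length
        if op in _CONSUME_REF:
            ref += length
    return [
        (gs, ge, segments[i], segments[i + 1]) for i, (gs, ge) in enumerate(gaps)
    ]


def count_linear_junctions(
    alignments: str | pysam.AlignmentFile,
    loci: Sequence[CircLocus],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> tuple[np.ndarray, np.ndarray]:
    """Count (ljc_up, ljc_down) for each locus in one sample's alignments.

    ``alignments`` is a SAM/BAM path or an open AlignmentFile. Indexed BAMs
    are queried per chromosome; SAM text is scanned sequentially. Returns two
    int arrays aligned with ``loci``.
    """
    if min_overhang <= 0:
        raise ConfigError("min_overhang must be positive")
    if min_mapq < 0:
        raise ConfigError("min_mapq must be non-negative")

    own = isinstance(alignments, str)
    af = pysam.AlignmentFile(alignments) if own else alignments
    try:
        # edge -> locus indices, per chromosome
        up_edges: dict[str, dict[int, list[int]]] = defaultdict(lambda: defaultdict(list))
        down_edges: dict[str, dict[int, list[int]]] = defaultdict(lambda: defaultdict(list))
        for i, locus in enumerate(loci):
            up_edges[locus.chrom][locus.start].append(i)
            down_edges[locus.chrom][locus.end].append(i)

        refs = set(af.references)
        wanted = {loc.chrom for loc in loci}
        for chrom in sorted(wanted - refs):
            logger.warning("chromosome %s absent from alignment header; zero counts", chrom)

        ljc_up = np.zeros(len(loci), dtype=np.int64)
        ljc_down = np.zeros(len(loci), dtype=np.int64)

        def process(read: pysam.AlignedSegment) -> None:
            if (
                read.is_unmapped
                or read.is_secondary
                or read.is_supplementary
                or read.is_duplicate
                or read.mapping_quality < min_mapq
                or read.cigartuples is None
            ):
                return
            chrom = read.reference_name
            ups = up_edges.get(chrom)
            downs = down_edges.get(chrom)
            if ups is None and downs is None:
                return
            hit_up: set[int] = set()
            hit_down: set[int] = set()
            for gs, ge, left, right in _gaps_with_overhangs(
                read.cigartuples, read.reference_start
            ):
                if left < min_overhang or right < min_overhang:
                    continue
                if ups is not None and ge in ups:
                    hit_up.update(ups[ge])
                if downs is not None and gs in downs:
                    hit_down.update(downs[gs])
            for i in hit_up:
                ljc_up[i] += 1
            for i in hit_down:
                ljc_down[i] += 1

        if af.has_index():
            for chrom in sorted(wanted & refs):
                for read in af.fetch(chrom):
                    process(read)
        else:
            for read in af.fetch(until_eof=True):
                process(read)
        return ljc_up, ljc_down
    finally:
        if own:
            af.close()


def count_from_sj_table(
    sj_file: str,
    loci: Sequence[CircLocus],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
) -> tuple[np.ndarray, np.ndarray]:
    """Count (ljc_up, ljc_down) from a STAR SJ.out.tab splice-junction file.

    STAR reports 1-based inclusive intron coordinates with unique-read
    counts (column 7) and the maximal spliced overhang (column 9). An intron
    ending at 1-based position ``E`` splices into the exonic base at 0-based
    ``E`` — matched to ``locus.start``; an intron starting at 1-based ``S``
    leaves an exon whose 0-based half-open end is ``S - 1`` — matched to
    ``locus.end``. Junctions with max overhang < ``min_overhang`` are
    excluded.
    """
    if min_overhang <= 0:
        raise ConfigError("min_overhang must be positive")
    up_edges: dict[tuple[str, int], list[int]] = defaultdict(list)
    down_edges: dict[tuple[str, int], list[int]] = defaultdict(list)
    for i, locus in enumerate(loci):
        up_edges[(locus.chrom, locus.start)].append(i)
        down_edges[(locus.chrom, locus.end)].append(i)

    ljc_up = np.zeros(len(loci), dtype=np.int64)
    ljc_down = np.zeros(len(loci), dtype=np.int64)
    with open(sj_file) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise FormatError(
                    f"{sj_file}:{lineno}: expected 9 columns, got {len(fields)}"
                )
            try:
                chrom = fields[0]
                intron_start = int(fields[1])
                intron_end = int(fields[2])
                unique = int(fields[6])
                max_overhang = int(fields[8])
            except ValueError:
                raise FormatError(f"{sj_file}:{lineno}: unparseable row") from None
            if intron_start < 1 or intron_end < intron_start or unique < 0:
                raise FormatError(f"{sj_file}:{lineno}: malformed junction row")
            if max_overhang < min_overhang or unique == 0:
                continue
            for i in up_edges.get((chrom, intron_end), ()):
                ljc_up[i] += unique
            for i in down_edges.get((chrom, intron_start - 1), ()):
                ljc_down[i] += unique
    return ljc_up, ljc_down


def build_ljc_table(
    loci: Sequence[CircLocus],
    sample_sources: dict[str, str],
    min_overhang: int = DEFAULT_MIN_OVERHANG,
    min_mapq: int = DEFAULT_MIN_MAPQ,
) -> LjcTable:
    """Count linear junctions for several samples into one LjcTable.

    ``sample_sources`` maps sample name to a SAM/BAM path or a STAR
    ``SJ.out.tab`` path (detected by the ``.tab``/``.sj`` suffix).
    """
    samples = list(sample_sources)
    up = np.zeros((len(loci), len(samples)), dtype=np.int64)
    down = np.zeros((len(loci), len(samples)), dtype=np.int64)
    for j, s in enumerate(samples):
        src = sample_sources[s]
        if src.endswith((".tab", ".sj")):
            up[:, j], down[:, j] = count_from_sj_table(src, loci, min_overhang)
        else:
            up[:, j], down[:, j] = count_linear_junctions(src, loci, min_overhang, min_mapq)
    return LjcTable(list(loci), samples, up, down)
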