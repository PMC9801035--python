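"""Shared fixture generators: synthetic alignments, detector files, GTFs.

Everything is generated programmatically at test time; the brute-force
CIGAR oracle here is deliberately independent of the package's counting
code (it re-parses CIGAR strings with a regex and compares every gap to
every locus).
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pytest

from circdec import CircLocus

# ------------------------------------------------------------ SAM fixtures

SAM_CHROMS = {"chr1": 2_000_000, "chr2": 2_000_000}


def write_sam(path: Path, records: list[tuple], chroms: dict[str, int] = None) -> Path:
    """Write SAM text from (qname, flag, chrom, pos0, mapq, cigar) records."""
    chroms = chroms or SAM_CHROMS
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    for name, length in chroms.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{length}")
    records = sorted(records, key=lambda r: (r[2], r[3]))
    for qname, flag, chrom, pos0, mapq, cigar in records:
        read_len = sum(
            int(n) for n, op in re.findall(r"(\d+)([MIS=X])", cigar)
        )
        seq = "A" * read_len
        lines.append(
            f"{qname}\t{flag}\t{chrom}\t{pos0 + 1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


_CIG = re.compile(r"(\d+)([MIDNSHP=X])")


def cigar_oracle_counts(
    records: list[tuple],
    loci: list[CircLocus],
    min_overhang: int,
    min_mapq: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Brute-force linear-junction counts, independent of the package.

    Enumerates every alignment's splice gaps straight from its CIGAR string
    and compares each gap edge to every locus boundary.
    """
    up = np.zeros(len(loci), dtype=np.int64)
    down = np.zeros(len(loci), dtype=np.int64)
    for qname, flag, chrom, pos0, mapq, cigar in records:
        if flag & (4 | 256 | 1024 | 2048):
            continue
        if mapq < min_mapq:
            continue
        # walk the CIGAR: record (gap_start, gap_end, left_M, right_M)
        segs = [0]
        gaps = []
        ref = pos0
        for n_str, op in _CIG.findall(cigar):
            n = int(n_str)
            if op == "N":
                gaps.append((ref, ref + n))
                segs.append(0)
            elif op in "M=X":
                segs[-1] += n
            if op in "MDN=X":
                ref += n
        for i, locus in enumerate(loci):
            if locus.chrom != chrom:
                continue
            hit_up = False
            hit_down = False
            for gi, (gs, ge) in enumerate(gaps):
                if segs[gi] < min_overhang or segs[gi + 1] < min_overhang:
                    continue
                if ge == locus.start:
                    hit_up = True
                if gs == locus.end:
                    hit_down = True
            up[i] += hit_up
            down[i] += hit_down
    return up, down


def random_spliced_records(
    rng: np.random.Generator,
    loci: list[CircLocus],
    n_reads: int,
    min_overhang: int = 6,
) -> list[tuple]:
    """Random spliced reads, many with gap edges at locus boundaries.

    Mixes reads whose gaps hit a boundary exactly, near-miss reads (edge
    off by 1-3 bp), multi-gap reads, low-MAPQ and flagged reads, and plain
    unspliced reads.
    """
    records = []
    for r in range(n_reads):
        kind = rng.integers(0, 5)
        chrom = rng.choice(list(SAM_CHROMS))
        mapq = int(rng.choice([0, 5, 10, 30, 60]))
        flag = int(rng.choice([0, 16, 256, 1024], p=[0.55, 0.35, 0.05, 0.05]))
        left = int(rng.integers(1, 40))
        right = int(rng.integers(1, 40))
        if kind <= 1 and len(loci):  # aim a gap at a locus boundary
            locus = loci[rng.integers(0, len(loci))]
            chrom = locus.chrom
            gap_len = int(rng.integers(30, 5000))
            if kind == 0:  # gap ends at locus.start (upstream junction)
                ge = locus.start
            else:  # gap starts at locus.end (downstream junction)
                ge = locus.end + gap_len
            gs = ge - gap_len
            pos0 = gs - left
            if pos0 < 0:
                continue
            cigar = f"{left}M{gap_len}N{right}M"
        elif kind == 2 and len(loci):  # near miss
            locus = loci[rng.integers(0, len(loci))]
            chrom = locus.chrom
            gap_len = int(rng.integers(30, 2000))
            off = int(rng.choice([-3, -2, -1, 1, 2, 3]))
            ge = locus.start + off
            gs = ge - gap_len
            pos0 = gs - left
            if pos0 < 0:
                continue
            cigar = f"{left}M{gap_len}N{right}M"
        elif kind == 3:  # two-gap read, second gap may hit a boundary
            pos0 = int(rng.integers(0, 500_000))
            g1 = int(rng.integers(50, 500))
            g2 = int(rng.integers(50, 500))
            mid = int(rng.integers(5, 30))
            cigar = f"{left}M{g1}N{mid}M{g2}N{right}M"
        else:  # unspliced
            pos0 = int(rng.integers(0, 500_000))
            cigar = f"{left + right}M"
        records.append((f"r{r}", flag, chrom, pos0, mapq, cigar))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_901)


@pytest.fixture
def random_loci():
    rng = np.random.default_rng(7)
    loci = []
    for i in range(24):
        chrom = "chr1" if i % 2 else "chr2"
        start = int(rng.integers(10_000, 900_000))
        end = start + int(rng.integers(300, 20_000))
        loci.append(CircLocus(chrom, start, end, "+" if i % 3 else "-"))
    return loci


# ------------------------------------------------------ detector fixtures

CIRI2_HEADER = (
    "circRNA_ID\tchr\tcircRNA_start\tcircRNA_end\t#junction_reads\tSM_MS_SMS\t"
    "#non_junction_reads\tjunction_reads_ratio\tcircRNA_type\tgene_id\tstrand\t"
    "junction_reads_ID"
)


def write_ciri2(path: Path, rows: list[tuple[CircLocus, int]]) -> Path:
    """CIRI2 dialect: 1-based inclusive coordinates."""
    lines = [CIRI2_HEADER]
    for locus, cjc in rows:
        start1 = locus.start + 1
        end1 = locus.end
        lines.append(
            f"{locus.chrom}:{start1}|{end1}\t{locus.chrom}\t{start1}\t{end1}\t{cjc}\t"
            f"{cjc}_0_0\t100\t0.5\texon\tgene_x\t{locus.strand}\tids"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def write_circexplorer2(path: Path, rows: list[tuple[CircLocus, int]], full: bool = True) -> Path:
    """CIRCexplorer2 annotate dialect: BED-like, readNumber in column 13."""
    lines = []
    for locus, cjc in rows:
        base = [
            locus.chrom, str(locus.start), str(locus.end), "circular_RNA/1",
            "0", locus.strand,
        ]
        if full:
            base += [
                str(locus.start), str(locus.end), "0,0,0", "2", "100,100", "0,900",
                str(cjc), "circRNA", "GENE", "TX1", "1", "intron|intron",
            ]
        else:
            base.append(str(cjc))
        lines.append("\t".join(base))
    path.write_text("\n".join(lines) + "\n")
    return path


def write_dcc(
    dirpath: Path, rows: list[tuple[CircLocus, dict[str, int]]], samples: list[str]
) -> tuple[Path, Path]:
    """DCC dialect pair: CircRNACount + CircCoordinates (BED convention)."""
    count_lines = ["Chr\tStart\tEnd\t" + "\t".join(samples)]
    coord_lines = ["Chr\tStart\tEnd\tGene\tJunctionType\tStrand"]
    for locus, counts in rows:
        vals = "\t".join(str(counts.get(s, 0)) for s in samples)
        count_lines.append(f"{locus.chrom}\t{locus.start}\t{locus.end}\t{vals}")
        coord_lines.append(
            f"{locus.chrom}\t{locus.start}\t{locus.end}\tGENE\t1\t{locus.strand}"
        )
    count_path = dirpath / "CircRNACount"
    coord_path = dirpath / "CircCoordinates"
    count_path.write_text("\n".join(count_lines) + "\n")
    coord_path.write_text("\n".join(coord_lines) + "\n")
    return count_path, coord_path


# ----------------------------------------------------- toy pipeline fixture


def build_toy_pipeline(root: Path) -> dict:
    """A tiny but complete analysis input set with one planted DEC.

    Three circles on chr1; group 1 detector files are CIRI2 dialect, group 2
    CIRCexplorer2 (exercising cross-dialect harmonization). Linear junction
    reads are emitted as spliced SAM records with gap edges at the circle
    boundaries. The first locus has psi ~0.5 in group 1 vs ~0.05 in group 2
    at deep counts; the other two are matched between groups.
    """
    root.mkdir(exist_ok=True)
    loci = [
        CircLocus("chr1", 10_000, 12_000, "+"),  # planted DEC
        CircLocus("chr1", 20_000, 21_000, "+"),
        CircLocus("chr1", 30_000, 30_500, "-"),
    ]
    # per-locus (cjc, ljc) by group, with mild per-sample jitter
    plan = {
        "g1": [(100, 200), (20, 80), (30, 70)],
        "g2": [(10, 380), (20, 80), (30, 70)],
    }
    jitter = {"s1": 0, "s2": 3, "s3": -2}
    manifest_rows = []
    for group, dialect in (("g1", "ciri2"), ("g2", "circexplorer2")):
        for s in ("s1", "s2", "s3"):
            sample = f"{group}_{s}"
            rows = [
                (loc, max(1, cjc + jitter[s]))
                for loc, (cjc, _) in zip(loci, plan[group])
            ]
            det = root / f"{sample}.{dialect}"
            if dialect == "ciri2":
                write_ciri2(det, rows)
            else:
                write_circexplorer2(det, rows)
            records = []
            for li, (loc, (_, ljc)) in enumerate(zip(loci, plan[group])):
                n = max(1, ljc + jitter[s])
                n_up = n // 2
                for k in range(n):
                    if k < n_up:  # gap [start-100, start)
                        pos0 = loc.start - 100 - 30
                        cigar = "30M100N30M"
                    else:  # gap [end, end+100)
                        pos0 = loc.end - 30
                        cigar = "30M100N30M"
                    records.append((f"{sample}_l{li}_r{k}", 0, "chr1", pos0, 60, cigar))
            sam = write_sam(root / f"{sample}.sam", records)
            manifest_rows.append((sample, group, str(det), dialect, s))
    manifest = root / "manifest.tsv"
    manifest.write_text(
        "sample\tgroup\tfile\tdialect\tpair_id\n"
        + "\n".join("\t".join(r) for r in manifest_rows)
        + "\n"
    )
    gtf = write_gtf(
        root / "anno.gtf",
        [
            (
                f"tx{i}",
                loc.chrom,
                loc.strand,
                [
                    (loc.start, loc.start + min(300, (loc.end - loc.start) // 2)),
                    (loc.end - min(300, (loc.end - loc.start) // 2), loc.end),
                ],
            )
            for i, loc in enumerate(loci)
        ],
    )
    return {
        "loci": loci,
        "manifest": manifest,
        "gtf": gtf,
        "sams": {f"{g}_{s}": root / f"{g}_{s}.sam" for g in ("g1", "g2") for s in ("s1", "s2", "s3")},
        "planted": loci[0].locus_id,
    }


# ------------------------------------------------------------ GTF fixture


def write_gtf(path: Path, transcripts: list[tuple[str, str, str, list[tuple[int, int]]]]) -> Path:
    """GTF from (transcript_id, chrom, strand, [(start0, end0), ...]) exons."""
    lines = []
    for tid, chrom, strand, exons in transcripts:
        for s0, e0 in exons:
            attrs = f'gene_id "g_{tid}"; transcript_id "{tid}";'
            lines.append(
                f"{chrom}\tfixture\texon\t{s0 + 1}\t{e0}\t.\t{strand}\t.\t{attrs}"
            )
    path.write_text("\n".join(lines) + "\n")
    return path
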