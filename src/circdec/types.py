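"""Core domain containers shared by all stages of the pipeline.

Coordinates are canonical 0-based half-open throughout: ``start`` is the
back-splice acceptor (first base inside the circle), ``end`` is one past the
back-splice donor (first base after the circle).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = ("+", "-", ".")


class ConfigError(ValueError):
    """A user-supplied parameter or design is invalid."""


class FormatError(ValueError):
    """An input file does not match its declared dialect."""


@dataclass(frozen=True, order=True)
class CircLocus:
    """A back-spliced site: one genomic interval with optional strand.

    ``start < end`` always; strand is ``+``, ``-`` or ``.`` (unknown).
    Loci that differ only in strand are distinct (antisense circles).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def from_id(cls, locus_id: str) -> "CircLocus":
        chrom, span, strand = locus_id.rsplit(":", 2)
        start, end = span.split("-")
        return cls(chrom, int(start), int(end), strand)


@dataclass
class GroupDesign:
    """Two-group comparison design; when paired, group1[i] pairs group2[i]."""

    group1: list[str]
    group2: list[str]
    paired: bool = False

    def __post_init__(self) -> None:
        if not self.group1 or not self.group2:
            raise ConfigError("both groups must be non-empty")
        if set(self.group1) & set(self.group2):
            raise ConfigError(
                f"samples in both groups: {sorted(set(self.group1) & set(self.group2))}"
            )
        if len(set(self.group1)) != len(self.group1) or len(set(self.group2)) != len(
            self.group2
        ):
            raise ConfigError("duplicate sample names within a group")
        if self.paired and len(self.group1) != len(self.group2):
            raise ConfigError("paired design requires equal group sizes")

    @property
    def samples(self) -> list[str]:
        return list(self.group1) + list(self.group2)


@dataclass
class CjcTable:
    """Circular junction counts: loci x samples integer matrix."""

    loci: list[CircLocus]
    samples: list[str]
    cjc: np.ndarray  # (n_loci, n_samples) non-negative ints

    def __post_init__(self) -> None:
        self.cjc = np.asarray(self.cjc, dtype=np.int64)
        n, m = len(self.loci), len(self.samples)
        if self.cjc.shape != (n, m):
            raise ValueError(f"cjc shape {self.cjc.shape} != ({n}, {m})")
        if (self.cjc < 0).any():
            raise ValueError("negative circular junction count")
        if len(set(self.samples)) != m:
            raise ValueError("duplicate sample names")
        if len({loc.locus_id for loc in self.loci}) != n:
            raise ValueError("duplicate loci")

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cjc, index=self.locus_ids, columns=self.samples)

    def write_tsv(self, path: str) -> None:
        df = self.to_frame()
        df.index.name = "locus_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str) -> "CjcTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        loci = [CircLocus.from_id(i) for i in df.index]
        return cls(loci, list(df.columns), df.to_numpy())


@dataclass
class LjcTable:
    """Linear junction counts at each back-spliced site.

    ``ljc_up`` counts linear splices into the circle's first exon (gap 3'
    edge at ``locus.start``); ``ljc_down`` counts splices out of its last
    exon (gap 5' edge at ``locus.end``). ``ljc`` is their elementwise sum.
    """

    loci: list[CircLocus]
    samples: list[str]
    ljc_up: np.ndarray
    ljc_down: np.ndarray

    def __post_init__(self) -> None:
        self.ljc_up = np.asarray(self.ljc_up, dtype=np.int64)
        self.ljc_down = np.asarray(self.ljc_down, dtype=np.int64)
        n, m = len(self.loci), len(self.samples)
        for name, mat in (("ljc_up", self.ljc_up), ("ljc_down", self.ljc_down)):
            if mat.shape != (n, m):
                raise ValueError(f"{name} shape {mat.shape} != ({n}, {m})")
            if (mat < 0).any():
                raise ValueError(f"negative entry in {name}")

    @property
    def ljc(self) -> np.ndarray:
        return self.ljc_up + self.ljc_down

    @property
    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def write_tsv(self, path: str) -> None:
        cols: dict[str, np.ndarray] = {}
        for j, s in enumerate(self.samples):
            cols[f"{s}.ljc_up"] = self.ljc_up[:, j]
            cols[f"{s}.ljc_down"] = self.ljc_down[:, j]
            cols[f"{s}.ljc"] = self.ljc[:, j]
        df = pd.DataFrame(cols, index=self.locus_ids)
        df.index.name = "locus_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def read_tsv(cls, path: str) -> "LjcTable":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
        samples = [c[: -len(".ljc_up")] for c in df.columns if c.endswith(".ljc_up")]
        loci = [CircLocus.from_id(i) for i in df.index]
        up = df[[f"{s}.ljc_up" for s in samples]].to_numpy()
        down = df[[f"{s}.ljc_down" for s in samples]].to_numpy()
        return cls(loci, samples, up, down)


@dataclass(frozen=True)
class EffectiveLengths:
    """Effective junction lengths for the linear and circular products.

    ``L = read_len - min_overhang`` is the number of read start positions
    that place a junction-spanning read over one splice junction. The linear
    product exposes two boundary junctions (``Il``); the circular product one
    back-splice junction, capped by the circle size ``e`` (``Ic``):

        Il = 4L           if e >= 2L
           = 2L + e       if e <  2L
        Ic = min(2L, e)
    """

    read_len: int
    min_overhang: int
    e: int

    def __post_init__(self) -> None:
        if self.read_len <= self.min_overhang:
            raise ConfigError(
                f"read_len ({self.read_len}) must exceed min_overhang "
                f"({self.min_overhang})"
            )
        if self.min_overhang < 0:
            raise ConfigError("min_overhang must be non-negative")
        if self.e <= 0:
            raise ConfigError("circRNA length e must be positive")

    @property
    def L(self) -> int:
        return self.read_len - self.min_overhang

    @property
    def Il(self) -> int:
        L = self.L
        return 4 * L if self.e >= 2 * L else 2 * L + self.e

    @property
    def Ic(self) -> int:
        return min(2 * self.L, self.e)


@dataclass
class ModelFit:
    """Fitted hierarchical-model parameters for one locus."""

    mu1: float
    mu2: float
    sigma1: float
    sigma2: float
    rho: float | None  # paired mode only
    loglik: float
    converged: bool = True


@dataclass
class DecTest:
    """Per-locus differential back-splicing test result."""

    locus_id: str
    psi_per_sample: list[float]  # NaN where undefined
    psi1_avg: float
    psi2_avg: float
    delta_psi: float
    llr: float
    pvalue: float
    fdr: float = float("nan")
    is_dec: bool = False
    fit: ModelFit | None = None


@dataclass
class SimTruth:
    """Ground truth for one simulated back-spliced locus."""

    locus_id: str
    stratum: str  # "null-beta" or "alt-beta"
    r1: float
    r2: float
    is_dec: bool
    cjc: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    ljc: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    isoform_fraction: float | None = None


def truth_frame(truths: Sequence[SimTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus_id": [t.locus_id for t in truths],
            "stratum": [t.stratum for t in truths],
            "r1": [t.r1 for t in truths],
            "r2": [t.r2 for t in truths],
            "is_dec": [t.is_dec for t in truths],
        }
    ).set_index("locus_id")
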