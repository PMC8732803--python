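"""Genomic coordinate model: chromosome arms, fixed bin tilings, named loci.

All coordinates are 0-based half-open (BED convention). A :class:`BinGrid`
tiles each chromosome arm with fixed-size bins; terminal partial bins shorter
than half the bin size are kept in the grid but flagged *excluded* so that
downstream per-bin statistics operate on a stable index space.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_BIN_SIZE = 200_000

#: TP53 gene body, hg19 (chr17p13.1).
TP53_HG19 = ("TP53", "chr17", 7_571_720, 7_590_868)

AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))


class AnnotationError(ValueError):
    """Raised when an arm table is malformed (overlaps, bad coordinates)."""


class LookupError_(KeyError):
    """Raised when a contig is absent from a grid."""


@dataclass(frozen=True)
class ChromosomeArm:
    """One chromosome arm as a half-open genomic interval."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"arm {self.name}: start {self.start} !< end {self.end}"
            )

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6


@dataclass(frozen=True)
class Locus:
    """A named genomic interval (e.g. the TP53 gene body)."""

    name: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise AnnotationError(
                f"locus {self.name}: start {self.start} !< end {self.end}"
            )


@dataclass
class BinGrid:
    """Fixed tiling of a set of chromosome arms into equal-size bins.

    Attributes
    ----------
    bin_size:
        Nominal bin width in bp.
    arms:
        The arm table the grid was built from, in input order.
    chrom, start, end:
        Per-bin coordinate arrays (half-open intervals).
    arm_name:
        Per-bin arm assignment.
    excluded:
        Boolean mask; True for terminal partial bins shorter than
        ``bin_size / 2`` (these never carry coverage statistics).
    """

    bin_size: int
    arms: tuple[ChromosomeArm, ...]
    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    arm_name: np.ndarray
    excluded: np.ndarray
    _chrom_slices: dict[str, slice] = field(default_factory=dict, repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.start)

    @property
    def usable(self) -> np.ndarray:
        return ~self.excluded

    def arm_by_name(self, name: str) -> ChromosomeArm:
        for arm in self.arms:
            if arm.name == name:
                return arm
        raise LookupError_(f"unknown arm {name!r}")

    def bins_of_arm(self, name: str) -> np.ndarray:
        """Indices of all (included and excluded) bins of one arm."""
        return np.flatnonzero(self.arm_name == name)

    def locate(self, chrom: str, pos: int) -> int | None:
        """Map a genomic position to its bin index, or None if uncovered.

        Raises :class:`LookupError_` for contigs absent from the grid.
        """
        if pos < 0:
            raise ValueError(f"negative position {pos}")
        if chrom not in self._chrom_slices:
            raise LookupError_(f"unknown chromosome {chrom!r}")
        sl = self._chrom_slices[chrom]
        starts = self.start[sl]
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        if i < 0:
            return None
        idx = sl.start + i
        if pos >= self.end[idx]:
            return None
        return idx

    def locus_bins(self, locus: Locus, include_excluded: bool = False) -> np.ndarray:
        """Indices of grid bins overlapping ``locus``."""
        if locus.chrom not in self._chrom_slices:
            raise LookupError_(f"unknown chromosome {locus.chrom!r}")
        sl = self._chrom_slices[locus.chrom]
        hit = (self.start[sl] < locus.end) & (self.end[sl] > locus.start)
        idx = np.flatnonzero(hit) + sl.start
        if not include_excluded:
            idx = idx[~self.excluded[idx]]
        return idx

    def to_bed(self) -> pd.DataFrame:
        """Grid as a BED4 frame (name column = arm, or 'excluded')."""
        name = np.where(self.excluded, "excluded", self.arm_name)
        return pd.DataFrame(
            {"chrom": self.chrom, "start": self.start, "end": self.end, "name": name}
        )


def _validate_arm_table(arms: Sequence[ChromosomeArm]) -> None:
    by_chrom: dict[str, list[ChromosomeArm]] = {}
    for arm in arms:
        by_chrom.setdefault(arm.chrom, []).append(arm)
    for chrom, group in by_chrom.items():
        group = sorted(group, key=lambda a: a.start)
        for a, b in zip(group, group[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"arms {a.name} and {b.name} overlap on {chrom}"
                )


def build_bin_grid(
    arm_table: Iterable[ChromosomeArm], bin_size: int = DEFAULT_BIN_SIZE
) -> BinGrid:
    """Tile each arm from its start in steps of ``bin_size``.

    The terminal bin of an arm is truncated at the arm end; if its width is
    below ``bin_size / 2`` it is flagged excluded. Deterministic for fixed
    inputs.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    arms = tuple(arm_table)
    if not arms:
        raise AnnotationError("empty arm table")
    _validate_arm_table(arms)

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    names: list[str] = []
    excl: list[bool] = []
    for arm in arms:
        for s in range(arm.start, arm.end, bin_size):
            e = min(s + bin_size, arm.end)
            chroms.append(arm.chrom)
            starts.append(s)
            ends.append(e)
            names.append(arm.name)
            excl.append((e - s) * 2 <= bin_size)  # half-size partials excluded too

    chrom_a = np.asarray(chroms, dtype=object)
    start_a = np.asarray(starts, dtype=np.int64)
    grid = BinGrid(
        bin_size=bin_size,
        arms=arms,
        chrom=chrom_a,
        start=start_a,
        end=np.asarray(ends, dtype=np.int64),
        arm_name=np.asarray(names, dtype=object),
        excluded=np.asarray(excl, dtype=bool),
    )
    slices: dict[str, slice] = {}
    i = 0
    while i < grid.n_bins:
        c = chrom_a[i]
        j = i
        while j < grid.n_bins and chrom_a[j] == c:
            j += 1
        if c in slices:  # arms of one chromosome must be contiguous in input
            raise AnnotationError(f"arms of {c} are not contiguous in the table")
        slices[c] = slice(i, j)
        i = j
    grid._chrom_slices = slices
    return grid


def load_arm_table(path=None, include_sex_chromosomes: bool = False) -> list[ChromosomeArm]:
    """Load an arm table TSV (name, chrom, start, end).

    With no ``path``, the packaged hg19 cytoband-derived table is used.
    Sex chromosomes are dropped unless requested: mixed-sex control panels
    make chrX/chrY Z-scores uninterpretable.
    """
    if path is None:
        ref = importlib.resources.files("cinwgs.data") / "hg19_arms.tsv"
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    arms = [
        ChromosomeArm(r["name"], r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in df.iterrows()
    ]
    if not include_sex_chromosomes:
        arms = [a for a in arms if a.chrom not in ("chrX", "chrY")]
    return arms


def tp53_locus() -> Locus:
    return Locus(*TP53_HG19)


def hg19_grid(
    bin_size: int = DEFAULT_BIN_SIZE, include_sex_chromosomes: bool = False
) -> BinGrid:
    """Convenience constructor: packaged hg19 arm table tiled at ``bin_size``."""
    return build_bin_grid(load_arm_table(None, include_sex_chromosomes), bin_size)
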