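"""Genome coordinate model: chromosome geometry, arm scaling and windowing.

All positions are 1-based inclusive base pairs.  Windows are half-open
``[start, start + window_bp)`` so that tiling arithmetic is unambiguous.
Pericentromere intervals are *inputs* (closed intervals), never inferred:
in real data they come from methylation profiles, in synthetic genomes
they are placed as a configurable central fraction of each chromosome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ARM = "arm"
PERICENTROMERE = "pericentromere"


@dataclass(frozen=True)
class Chromosome:
    """Geometry of one chromosome.

    Parameters
    ----------
    name : str
        Unique chromosome label.
    length : int
        Chromosome length in base pairs.
    centromere_midpoint : int
        Centromere midpoint in base pairs; splits the chromosome into a
        left arm ``[1, centromere]`` and a right arm ``[centromere, length]``.
    peri_start, peri_end : int
        Closed pericentromere interval ``[peri_start, peri_end]``.
    """

    name: str
    length: int
    centromere_midpoint: int
    peri_start: int
    peri_end: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be positive")
        if not (1 <= self.peri_start < self.peri_end <= self.length):
            raise ValueError(
                f"{self.name}: pericentromere [{self.peri_start}, {self.peri_end}] "
                f"must satisfy 1 <= start < end <= length ({self.length})"
            )
        if not (self.peri_start <= self.centromere_midpoint <= self.peri_end):
            raise ValueError(
                f"{self.name}: centromere midpoint {self.centromere_midpoint} outside "
                f"pericentromere [{self.peri_start}, {self.peri_end}]"
            )
        if self.centromere_midpoint in (1, self.length):
            logger.warning(
                "%s: centromere midpoint at chromosome end; degenerates to a single arm",
                self.name,
            )


class GenomeMap:
    """Ordered collection of :class:`Chromosome` records.

    The coordinate authority for every pipeline stage: region
    classification, arm scaling and window partitioning all live here.
    """

    def __init__(self, chromosomes: Iterable[Chromosome]):
        self._chroms: dict[str, Chromosome] = {}
        for c in chromosomes:
            if c.name in self._chroms:
                raise ValueError(f"duplicate chromosome name {c.name!r}")
            self._chroms[c.name] = c
        if not self._chroms:
            raise ValueError("genome map needs at least one chromosome")

    # -- container protocol -------------------------------------------------
    def __getitem__(self, name: str) -> Chromosome:
        try:
            return self._chroms[name]
        except KeyError:
            raise KeyError(f"unknown chromosome {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._chroms

    def __iter__(self):
        return iter(self._chroms.values())

    def __len__(self) -> int:
        return len(self._chroms)

    @property
    def names(self) -> list[str]:
        return list(self._chroms)

    def length(self, name: str) -> int:
        return self[name].length

    # -- construction / serialization ---------------------------------------
    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenomeMap":
        required = ["chrom", "length", "centromere", "peri_start", "peri_end"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"genome map missing columns: {missing}")
        return cls(
            Chromosome(
                name=str(r.chrom),
                length=int(r.length),
                centromere_midpoint=int(r.centromere),
                peri_start=int(r.peri_start),
                peri_end=int(r.peri_end),
            )
            for r in df.itertuples()
        )

    @classmethod
    def from_tsv(cls, path) -> "GenomeMap":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_dict(cls, spec: Mapping) -> "GenomeMap":
        """Build from a config block ``{name: {length, centromere, peri_start, peri_end}}``."""
        return cls(
            Chromosome(
                name=str(name),
                length=int(v["length"]),
                centromere_midpoint=int(v["centromere"]),
                peri_start=int(v["peri_start"]),
                peri_end=int(v["peri_end"]),
            )
            for name, v in spec.items()
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.names,
                "length": [c.length for c in self],
                "centromere": [c.centromere_midpoint for c in self],
                "peri_start": [c.peri_start for c in self],
                "peri_end": [c.peri_end for c in self],
            }
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    # -- coordinate operations ----------------------------------------------
    def classify_region(self, chrom: str, position: int) -> str:
        """Return ``"pericentromere"`` iff *position* lies inside the closed
        pericentromere interval, ``"arm"`` otherwise."""
        c = self[chrom]
        if not (1 <= position <= c.length):
            raise ValueError(f"position {position} outside {chrom} [1, {c.length}]")
        return PERICENTROMERE if c.peri_start <= position <= c.peri_end else ARM

    def classify_regions(self, chrom: str, positions) -> np.ndarray:
        """Vectorized :meth:`classify_region` over an array of positions."""
        c = self[chrom]
        pos = np.asarray(positions, dtype=float)
        if pos.size and (pos.min() < 1 or pos.max() > c.length):
            raise ValueError(f"positions outside {chrom} [1, {c.length}]")
        inside = (pos >= c.peri_start) & (pos <= c.peri_end)
        return np.where(inside, PERICENTROMERE, ARM)

    def arm_scaled_coordinate(self, chrom: str, position: float) -> tuple[float, str]:
        """Map a position onto its arm's telomere(0) -> centromere(1) scale.

        The left arm ``[1, centromere]`` and right arm ``[centromere, length]``
        are each linearly rescaled so 0 is the telomeric end and 1 the
        centromere midpoint.  Returns ``(scaled, arm)`` with
        ``arm in {"left", "right"}``.
        """
        c = self[chrom]
        if not (1 <= position <= c.length):
            raise ValueError(f"position {position} outside {chrom} [1, {c.length}]")
        cen = c.centromere_midpoint
        if cen <= 1:  # degenerate: no left arm
            return (c.length - position) / (c.length - cen), "right"
        if cen >= c.length:  # degenerate: no right arm
            return (position - 1) / (cen - 1), "left"
        if position <= cen:
            return (position - 1) / (cen - 1), "left"
        return (c.length - position) / (c.length - cen), "right"

    def partition_windows(self, window_bp: int, chrom: str | None = None) -> pd.DataFrame:
        """Tile chromosomes with half-open windows ``[start, start + window_bp)``.

        The last window of each chromosome is truncated at the chromosome end,
        so the windows partition ``[1, length]`` with no gaps or overlaps.
        Returns a frame with columns ``chrom, start, end`` (``end`` exclusive).
        """
        if window_bp <= 0:
            raise ValueError(f"window_bp must be positive, got {window_bp}")
        chroms = [self[chrom]] if chrom is not None else list(self)
        rows = []
        for c in chroms:
            starts = np.arange(1, c.length + 1, window_bp, dtype=np.int64)
            ends = np.minimum(starts + window_bp, c.length + 1)
            rows.append(
                pd.DataFrame({"chrom": c.name, "start": starts, "end": ends})
            )
        return pd.concat(rows, ignore_index=True)

    def n_windows(self, window_bp: int, chrom: str) -> int:
        return int(np.ceil(self[chrom].length / window_bp))


def window_index(positions, window_bp: int) -> np.ndarray:
    """0-based window index for 1-based positions under half-open tiling."""
    pos = np.asarray(positions)
    return ((pos - 1) // window_bp).astype(np.int64)


def uniform_genome(
    n_chromosomes: int = 5,
    chrom_length: int = 30_000_000,
    peri_fraction: float = 0.2,
    prefix: str = "chr",
) -> GenomeMap:
    """Synthetic genome: equal-length metacentric chromosomes with the
    pericentromere as the central *peri_fraction* of each chromosome."""
    if not (0 < peri_fraction < 1):
        raise ValueError("peri_fraction must be in (0, 1)")
    half = peri_fraction / 2.0
    chroms = []
    for i in range(n_chromosomes):
        cen = chrom_length // 2
        chroms.append(
            Chromosome(
                name=f"{prefix}{i + 1}",
                length=chrom_length,
                centromere_midpoint=cen,
                peri_start=int(round(chrom_length * (0.5 - half))),
                peri_end=int(round(chrom_length * (0.5 + half))),
            )
        )
    return GenomeMap(chroms)


def arabidopsis_like_genome() -> GenomeMap:
    """Approximate A. thaliana (TAIR10-scale) geometry for realistic examples.

    Lengths and centromere midpoints are rounded public reference values;
    pericentromeres are placed as +/-2.5 Mb around each centromere midpoint
    (a coarse stand-in for the methylation-defined intervals used on real
    data, which are supplied by the user, not computed here).
    """
    geometry = [  # name, length, centromere midpoint
        ("Chr1", 30_427_671, 15_086_000),
        ("Chr2", 19_698_289, 3_607_000),
        ("Chr3", 23_459_830, 13_587_000),
        ("Chr4", 18_585_056, 3_956_000),
        ("Chr5", 26_975_502, 11_725_000),
    ]
    flank = 2_500_000
    return GenomeMap(
        Chromosome(
            name=n,
            length=ln,
            centromere_midpoint=cen,
            peri_start=max(1, cen - flank),
            peri_end=min(ln, cen + flank),
        )
        for n, ln, cen in geometry
    )
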