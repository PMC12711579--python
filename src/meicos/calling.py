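"""Crossover calling from marker genotype tracks.

A transparent support-threshold caller: maximal runs of identical genotype
become segments, runs supported by fewer than ``min_support`` markers are
dissolved (their markers ignored) and flanking same-genotype segments
merge; the pass repeats until stable.  One CO event is emitted per
adjacent segment pair, positioned at the midpoint of the transition
interval (last marker of the left segment, first marker of the right).

An AA<->BB adjacency — possible after dissolution removed the intervening
heterozygous stretch — implies two allele changes and is emitted as two
stacked events sharing the same bounds, flagged ``stacked``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeMap

logger = logging.getLogger(__name__)

GENOTYPES = ("AA", "AB", "BB")
_CODE = {"AA": 0, "AB": 1, "BB": 2}
_NAME = {v: k for k, v in _CODE.items()}

EVENT_COLUMNS = ["individual", "chrom", "left", "right", "midpoint", "transition", "stacked"]
SEGMENT_COLUMNS = ["individual", "chrom", "genotype", "first", "last", "support"]


@dataclass(frozen=True)
class GenotypeSegment:
    individual: str
    chromosome: str
    genotype: str  # AA | AB | BB
    first: float  # first supporting marker position
    last: float   # last supporting marker position
    support: int


@dataclass(frozen=True)
class COEvent:
    individual: str
    chromosome: str
    left: float      # last marker of the preceding segment
    right: float     # first marker of the following segment
    midpoint: float  # (left + right) / 2
    transition: str  # e.g. "AA>AB"
    stacked: bool = False


def _genotype_codes(series: pd.Series) -> np.ndarray:
    """Genotype column -> int8 codes (0/1/2; -1 for NA), categorical-aware."""
    if isinstance(series.dtype, pd.CategoricalDtype):
        lut = np.array(
            [_CODE.get(str(c), -1) for c in series.cat.categories], dtype=np.int8
        )
        raw = series.cat.codes.to_numpy()
        out = np.full(raw.size, -1, dtype=np.int8)
        valid = raw >= 0
        out[valid] = lut[raw[valid]]
        return out
    return series.astype(str).map(lambda g: _CODE.get(g, -1)).to_numpy(dtype=np.int8)


def _runs(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start/end (half-open) indices of maximal equal-value runs."""
    change = np.flatnonzero(codes[1:] != codes[:-1]) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [codes.size]))
    return starts, ends


def segment_genotypes(
    positions,
    genotypes,
    min_support: int = 3,
    individual: str = "",
    chromosome: str = "",
) -> list[GenotypeSegment]:
    """Collapse a marker track into alternating genotype segments.

    ``genotypes`` may be genotype strings or integer codes (0/1/2); missing
    calls must already be dropped.  Runs shorter than ``min_support`` are
    dissolved simultaneously each pass, then runs are recomputed (merging
    flanking same-genotype runs) until every surviving run meets the
    threshold.  An empty track yields an empty list.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 0:
        logger.debug("empty track %s/%s", individual, chromosome)
        return []
    if np.any(np.diff(pos) < 0):
        raise ValueError("marker positions must be sorted")
    g = np.asarray(genotypes)
    codes = (
        np.array([_CODE[x] for x in g], dtype=np.int8)
        if g.dtype.kind in ("U", "S", "O")
        else g.astype(np.int8)
    )
    if codes.size != pos.size:
        raise ValueError("positions and genotypes differ in length")

    while codes.size:
        starts, ends = _runs(codes)
        short = (ends - starts) < min_support
        if not short.any():
            break
        keep = np.ones(codes.size, dtype=bool)
        for s, e in zip(starts[short], ends[short]):
            keep[s:e] = False
        codes = codes[keep]
        pos = pos[keep]
    if codes.size == 0:
        return []

    starts, ends = _runs(codes)
    return [
        GenotypeSegment(
            individual=individual,
            chromosome=chromosome,
            genotype=_NAME[int(codes[s])],
            first=float(pos[s]),
            last=float(pos[e - 1]),
            support=int(e - s),
        )
        for s, e in zip(starts, ends)
    ]


def call_crossovers(segments: list[GenotypeSegment]) -> list[COEvent]:
    """One CO event per adjacent segment pair of a single track.

    AA<->BB adjacencies yield two stacked events (AA>AB then AB>BB, in the
    direction of travel) sharing the same marker-interval bounds.
    """
    events: list[COEvent] = []
    for a, b in zip(segments, segments[1:]):
        left, right = a.last, b.first
        mid = 0.5 * (left + right)
        ca, cb = _CODE[a.genotype], _CODE[b.genotype]
        if abs(ca - cb) == 2:  # parental-to-parental: two allele changes
            step = 1 if cb > ca else -1
            for c0 in (ca, ca + step):
                events.append(
                    COEvent(
                        a.individual, a.chromosome, left, right, mid,
                        f"{_NAME[c0]}>{_NAME[c0 + step]}", stacked=True,
                    )
                )
            logger.warning(
                "stacked %s>%s transition at %s/%s:%.0f-%.0f counted as two COs",
                a.genotype, b.genotype, a.individual, a.chromosome, left, right,
            )
        else:
            events.append(
                COEvent(
                    a.individual, a.chromosome, left, right, mid,
                    f"{a.genotype}>{b.genotype}",
                )
            )
    return events


def segments_to_frame(segments: list[GenotypeSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.individual, s.chromosome, s.genotype, s.first, s.last, s.support) for s in segments],
        columns=SEGMENT_COLUMNS,
    )


def events_to_frame(events: list[COEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.individual, e.chromosome, e.left, e.right, e.midpoint, e.transition, e.stacked) for e in events],
        columns=EVENT_COLUMNS,
    )


def call_population(
    genotype_table: pd.DataFrame, min_support: int = 3
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment and call every (individual, chromosome) track of a genotype
    table (columns ``individual, chrom, position, genotype``; "NA" dropped).

    Returns ``(segments, events)`` frames with columns
    ``SEGMENT_COLUMNS`` / ``EVENT_COLUMNS``.
    """
    df = genotype_table
    codes = _genotype_codes(df["genotype"])  # -1 marks missing
    keep = codes >= 0
    all_segments: list[GenotypeSegment] = []
    all_events: list[COEvent] = []
    work = pd.DataFrame(
        {
            "individual": df["individual"].array[keep],
            "chrom": df["chrom"].array[keep],
            "position": df["position"].to_numpy(dtype=float)[keep],
            "code": codes[keep],
        }
    ).sort_values(["individual", "chrom", "position"], kind="stable")
    for (ind, chrom), track in work.groupby(["individual", "chrom"], sort=True, observed=True):
        segs = segment_genotypes(
            track["position"].to_numpy(),
            track["code"].to_numpy(),
            min_support=min_support,
            individual=str(ind),
            chromosome=str(chrom),
        )
        all_segments.extend(segs)
        all_events.extend(call_crossovers(segs))
    return segments_to_frame(all_segments), events_to_frame(all_events)


def per_individual_counts(
    events: pd.DataFrame,
    individuals,
    genome: GenomeMap | None = None,
) -> pd.DataFrame:
    """Per-individual CO counts: one column per chromosome plus ``total``.

    Individuals without any event appear with zero counts; the chromosome
    column set comes from *genome* when given, else from the events.
    """
    individuals = list(individuals)
    if not individuals:
        raise ValueError("individuals list must not be empty")
    chroms = genome.names if genome is not None else sorted(set(events["chrom"]))
    if len(events):
        pivot = (
            events.groupby(["individual", "chrom"], observed=True)
            .size()
            .unstack(fill_value=0)
        )
    else:
        pivot = pd.DataFrame(index=pd.Index([], name="individual"))
    pivot = pivot.reindex(index=individuals, columns=chroms, fill_value=0).fillna(0).astype(int)
    pivot["total"] = pivot.sum(axis=1)
    pivot.index.name = "individual"
    return pivot
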