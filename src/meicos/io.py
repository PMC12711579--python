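"""File formats: TSV interchange dialect, truth archives and configs.

All tables are tab-delimited UTF-8 with a header row and ``NA`` as the
missing-genotype token.  Internal coordinates are 1-based; the optional
BED export of CO intervals is 0-based half-open.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import MeiosisTruth

logger = logging.getLogger(__name__)

GENOTYPE_TOKENS = {"AA", "AB", "BB", "NA"}
GENOTYPE_COLUMNS = ["individual", "chrom", "position", "genotype"]


def read_genotype_table(path) -> pd.DataFrame:
    """Read and validate a marker genotype table.

    Requires columns ``individual, chrom, position, genotype`` with
    genotype in {AA, AB, BB, NA}; rows are returned sorted by
    (individual, chrom, position).  Duplicate marker rows or unknown
    genotype tokens raise ``ValueError`` naming the offending line
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(
        path, sep="\t", keep_default_na=False,
        dtype={"individual": str, "chrom": str, "genotype": str},
    )
    missing = [c for c in GENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["genotype"].astype(str).isin(GENOTYPE_TOKENS)
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(
            f"{path}: unknown genotype token {df.loc[df.index[bad][0], 'genotype']!r} at line {line}"
        )
    dup = df.duplicated(subset=["individual", "chrom", "position"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise ValueError(f"{path}: duplicate (individual, chrom, position) row at line {line}")
    df["position"] = df["position"].astype(np.int64)
    return df.sort_values(["individual", "chrom", "position"], kind="stable").reset_index(
        drop=True
    )


def write_genotype_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_events(events: pd.DataFrame, path) -> None:
    out = events.rename(columns={"stacked": "flags"}).copy()
    out["flags"] = np.where(out["flags"].astype(bool), "stacked", ".")
    out.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "chrom": str})
    df["stacked"] = df.pop("flags").astype(str) == "stacked"
    return df


def write_events_bed(events: pd.DataFrame, path) -> None:
    """CO uncertainty intervals as BED (0-based half-open) for browsers."""
    bed = pd.DataFrame(
        {
            "chrom": events["chrom"],
            "start": events["left"].astype(np.int64) - 1,
            "end": events["right"].astype(np.int64),
            "name": events["individual"].astype(str) + ":" + events["transition"],
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def write_truth(truths: list[MeiosisTruth], path) -> None:
    rows = [
        {
            "individual": t.individual,
            "parent": t.parent,
            "chrom": t.chromosome,
            "founder": t.founder,
            "co_positions": ",".join(f"{p:.1f}" for p in t.co_positions),
        }
        for t in truths
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_truth(path) -> list[MeiosisTruth]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples():
        pos = (
            np.array([float(x) for x in r.co_positions.split(",")])
            if r.co_positions
            else np.empty(0)
        )
        out.append(
            MeiosisTruth(
                individual=r.individual,
                parent=r.parent,
                chromosome=r.chrom,
                founder=r.founder,
                co_positions=pos,
            )
        )
    return out


def load_config_file(path) -> dict:
    """Load a YAML (or JSON, a YAML subset) configuration mapping."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def file_checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
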