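"""Readers/writers for external formats and circular-coordinate arithmetic.

All replicons handled here are circular. Internal coordinates are 0-based
half-open; every file format read or written uses the convention native to
that format (1-based inclusive for GFF3 and depth TSVs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class Replicon:
    """A named circular replicon.

    Parameters
    ----------
    id : str
        Non-empty sequence identifier.
    length : int
        Length in bp.
    sequence : str, optional
        Uppercase DNA. Non-ACGT letters are preserved; downstream G/C
        counting treats them as neither G nor C.
    sites : dict, optional
        Known site annotations, keys among {"ori", "ter", "dif"},
        values 0-based positions in [0, length).
    """

    id: str
    length: int
    sequence: str | None = None
    circular: bool = True
    sites: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("replicon id must be non-empty")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"replicon {self.id!r}: length {self.length} != "
                    f"sequence length {len(self.sequence)}"
                )
        if self.length <= 0:
            raise ValueError(f"replicon {self.id!r}: length must be positive")
        for name, pos in self.sites.items():
            if not 0 <= pos < self.length:
                raise ValueError(
                    f"replicon {self.id!r}: site {name} at {pos} outside [0, {self.length})"
                )


@dataclass(frozen=True)
class CircularInterval:
    """Arc [start, end) on a circle of given length; may wrap past the end.

    ``span == (end - start) mod length``, with span == length meaning the
    whole circle (encoded as end == start + length).
    """

    start: int
    end: int
    length: int

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.length:
            raise ValueError(f"start {self.start} outside [0, {self.length})")
        if not 0 < self.span <= self.length:
            raise ValueError("interval span must be in (0, length]")

    @property
    def span(self) -> int:
        s = (self.end - self.start) % self.length
        return self.length if s == 0 and self.end != self.start else s

    def contains(self, pos: int) -> bool:
        if self.span == self.length:
            return True
        return (pos - self.start) % self.length < self.span


def circular_distance(p: int, q: int, length: int, oriented: bool = False) -> int:
    """Distance between positions on a circle of ``length`` bp.

    oriented=False: minimum arc distance, in [0, length/2].
    oriented=True: clockwise (coordinate-increasing) distance (q - p) mod length.
    """
    if not (0 <= p < length and 0 <= q < length):
        raise ValueError(f"positions must be in [0, {length}); got {p}, {q}")
    cw = (q - p) % length
    if oriented:
        return cw
    return min(cw, length - cw)


def read_fasta(path: str | Path) -> list[Replicon]:
    """Read a FASTA file into a list of circular Replicons (file order)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    replicons = []
    for rec in records:
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate replicon id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        replicons.append(Replicon(id=rec.id, length=len(seq), sequence=seq))
    return replicons


def write_fasta(replicons: Iterable[Replicon], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rep in replicons:
            if rep.sequence is None:
                raise ValueError(f"replicon {rep.id!r} has no sequence")
            fh.write(f">{rep.id}\n")
            for i in range(0, rep.length, width):
                fh.write(rep.sequence[i : i + width] + "\n")


def read_depth_tsv(
    path: str | Path, replicons: Iterable[Replicon]
) -> dict[str, np.ndarray]:
    """Read a 3-column depth TSV (seqid, 1-based position, depth).

    Positions absent from the file get depth 0 (depth tools omit
    zero-coverage positions); the number of absent positions is logged.
    """
    lengths = {rep.id: rep.length for rep in replicons}
    arrays = {rid: np.zeros(L, dtype=np.int64) for rid, L in lengths.items()}
    try:
        df = pd.read_csv(
            path, sep="\t", header=None, names=["id", "pos", "depth"],
            dtype={"id": str, "pos": np.int64, "depth": np.int64}, comment="#",
        )
    except pd.errors.EmptyDataError:
        df = pd.DataFrame(columns=["id", "pos", "depth"])
    if df.empty:
        logger.warning("%s: empty depth file; all depths set to 0", path)
        return arrays

    unknown = set(df["id"]) - set(lengths)
    if unknown:
        raise FormatError(f"{path}: unknown replicon id(s): {sorted(unknown)}")
    if (df["depth"] < 0).any():
        raise FormatError(f"{path}: negative depth values")
    n_absent = 0
    for rid, sub in df.groupby("id", sort=False):
        L = lengths[rid]
        pos = sub["pos"].to_numpy()
        if pos.min() < 1 or pos.max() > L:
            bad = pos[(pos < 1) | (pos > L)][0]
            raise FormatError(
                f"{path}: position {bad} outside [1, {L}] for replicon {rid!r}"
            )
        arrays[rid][pos - 1] = sub["depth"].to_numpy()
        n_absent += L - len(np.unique(pos))
    for rid in set(lengths) - set(df["id"]):
        n_absent += lengths[rid]
    if n_absent:
        logger.warning("%s: %d positions absent; assigned depth 0", path, n_absent)
    return arrays


def write_depth_tsv(arrays: Mapping[str, np.ndarray], path: str | Path) -> None:
    """Write per-base depth arrays as a 3-column TSV (all positions, 1-based)."""
    with open(path, "w") as fh:
        for rid, arr in arrays.items():
            for i, d in enumerate(arr):
                fh.write(f"{rid}\t{i + 1}\t{int(d)}\n")


GFF_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase", "attributes",
]


def read_gff3(path: str | Path, feature_types: tuple[str, ...] | None = ("CDS", "gene")) -> pd.DataFrame:
    """Read GFF3 features into a DataFrame (1-based inclusive start/end).

    Only the columns this package consumes are validated (seqid, type,
    start, end, strand). ``feature_types=None`` keeps every feature.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"{path}: expected 9 tab-separated columns, got {len(parts)}")
            rows.append(parts)
    df = pd.DataFrame(rows, columns=GFF_COLUMNS)
    if not df.empty:
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if feature_types is not None:
            df = df[df["type"].isin(feature_types)].reset_index(drop=True)
    return df


def write_gff3(df: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, row in df.iterrows():
            fh.write("\t".join(str(row[c]) for c in GFF_COLUMNS) + "\n")


def read_traits_tsv(path: str | Path) -> dict[str, str]:
    """Read a 2-column tip-trait table (tip_name <tab> state)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["tip", "state"], dtype=str,
                     comment="#")
    if df["tip"].duplicated().any():
        dup = df["tip"][df["tip"].duplicated()].iloc[0]
        raise FormatError(f"{path}: duplicate tip name {dup!r}")
    return dict(zip(df["tip"], df["state"]))
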