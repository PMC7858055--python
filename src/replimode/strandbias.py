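"""Leading/lagging strand gene counts per replichore.

ori and ter split a bidirectionally replicating circle into two
replichores. On the right replichore (the clockwise fork, ori -> ter in
increasing-coordinate direction) the leading strand is the forward/plus
strand; on the left replichore (counterclockwise fork) it is the
reverse/minus strand. Gene orientation is biased toward the leading
strand, and the leading/lagging count ratio per replichore quantifies
that bias. A unidirectionally replicating replicon has a single
replichore (the clockwise arc ori -> ter covering essentially the whole
circle) on which forward is leading.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genomeio import CircularInterval, circular_distance


@dataclass
class ReplichoreLayout:
    """ori/ter geometry of one replicon."""

    ori: int
    ter: int
    length: int
    mode: str = "bidirectional"

    def __post_init__(self) -> None:
        if self.mode not in ("bidirectional", "unidirectional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.ori == self.ter:
            raise ValueError("ori and ter must differ")

    @property
    def right_replichore(self) -> CircularInterval:
        return CircularInterval(self.ori, self.ter % self.length, self.length)

    @property
    def left_replichore(self) -> CircularInterval | None:
        if self.mode == "unidirectional":
            return None
        return CircularInterval(self.ter, self.ori, self.length)


@dataclass
class ReplichoreBias:
    leading_count: int
    lagging_count: int

    @property
    def ratio(self) -> float | None:
        """leading/lagging; None when undefined (no lagging genes)."""
        if self.lagging_count == 0:
            return None
        return self.leading_count / self.lagging_count


@dataclass
class StrandBiasResult:
    right: ReplichoreBias
    left: ReplichoreBias | None
    boundary_genes: int
    total_genes: int


def leading_lagging_ratio(
    genes_gff: pd.DataFrame,
    layout: ReplichoreLayout,
    replicon_id: str | None = None,
    boundary_halfwidth: int = 1000,
) -> StrandBiasResult:
    """Count leading- vs lagging-strand genes on each replichore.

    Genes are assigned to the replichore containing their midpoint; genes
    whose midpoint falls within ``boundary_halfwidth`` of ori or ter are
    excluded as boundary genes. Requires strand information in the GFF.
    """
    genes = genes_gff
    if replicon_id is not None:
        genes = genes[genes["seqid"] == replicon_id]
    if genes.empty:
        empty = ReplichoreBias(0, 0)
        left = None if layout.mode == "unidirectional" else ReplichoreBias(0, 0)
        return StrandBiasResult(empty, left, 0, 0)
    if (~genes["strand"].isin(["+", "-"])).any():
        raise ValueError("GFF features must carry +/- strand information")

    L = layout.length
    right = layout.right_replichore
    counts = {"right": [0, 0], "left": [0, 0]}
    boundary = 0
    for _, row in genes.iterrows():
        mid = int((int(row["start"]) - 1 + int(row["end"])) // 2) % L
        if (
            circular_distance(mid, layout.ori % L, L) <= boundary_halfwidth
            or circular_distance(mid, layout.ter % L, L) <= boundary_halfwidth
        ):
            boundary += 1
            continue
        on_right = layout.mode == "unidirectional" or right.contains(mid)
        leading_strand = "+" if on_right else "-"
        side = "right" if on_right else "left"
        if row["strand"] == leading_strand:
            counts[side][0] += 1
        else:
            counts[side][1] += 1

    right_bias = ReplichoreBias(*counts["right"])
    left_bias = (
        None if layout.mode == "unidirectional" else ReplichoreBias(*counts["left"])
    )
    return StrandBiasResult(
        right=right_bias, left=left_bias,
        boundary_genes=boundary, total_genes=int(len(genes)),
    )
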