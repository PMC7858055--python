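"""Motif/structure-based localization of candidate ori and dif sites.

The dif site is the 28-bp XerC/XerD-bound chromosome-dimer-resolution
locus found near the replication terminus: an imperfect palindrome whose
two 11-bp arms bind XerC and XerD around a 6-bp central region. Candidate
dif sites are found by an exhaustive mismatch-counting scan against a
reference 28-mer (deterministic, no external aligner), then filtered on
the canonical structural criteria: intergenic location, arm palindromy,
and a conserved XerD half-site.

Origins are located by their internal structure: clusters of DnaA boxes
(9-mer consensus TTATCCACA) and an excess of GATC Dam-methylation sites
within a short window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genomeio import Replicon, circular_distance

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

# Synthetic 28-bp reference dif with the canonical XerC-arm / 6-bp central
# region / XerD-arm architecture: the XerD half-site is the conserved
# E. coli XerD box, and the XerC arm is its inverted repeat with two
# mismatches (dif sites are imperfect palindromes). A synthetic stand-in:
# the real reference sites used for any particular study are supplied by
# the caller via DifSearchParams.reference_dif.
SYNTHETIC_REFERENCE_DIF = "GGTTAACATAA" + "TGTATA" + "TTATGTTAAAT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class DifSearchParams:
    reference_dif: tuple[str, ...] = (SYNTHETIC_REFERENCE_DIF,)
    max_mismatches: int = 8
    palindrome_min_arm: int = 7
    palindrome_max_mismatch: int = 2
    xerd_arm: str = "right"  # which reference half carries the XerD box
    xerd_max_mismatch: int = 1

    def __post_init__(self) -> None:
        for ref in self.reference_dif:
            if len(ref) != 28:
                raise ValueError(f"reference dif must be 28 bp, got {len(ref)}")
        if not self.reference_dif:
            raise ValueError("at least one reference dif sequence required")


@dataclass
class OriSearchParams:
    dnaA_box: str = "TTATCCACA"
    box_max_mismatch: int = 1
    cluster_window: int = 500
    min_boxes: int = 3
    min_gatc: int = 8

    def __post_init__(self) -> None:
        if len(self.dnaA_box) != 9:
            raise ValueError("DnaA box consensus must be 9 bp")


@dataclass
class SiteCandidate:
    position: int
    score: float
    kind: str
    strand: str = "+"
    in_coding: bool = False
    distance_to_expected: int | None = None
    detail: str = ""


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _mismatch_scan(seq_arr: np.ndarray, motif: str) -> np.ndarray:
    """Mismatch count of ``motif`` at every circular start position."""
    k = len(motif)
    n = len(seq_arr)
    ext = np.concatenate([seq_arr, seq_arr[: k - 1]])
    mm = np.zeros(n, dtype=np.int32)
    for j, base in enumerate(motif.encode("ascii")):
        mm += ext[j : j + n] != base
    return mm


def _coding_intervals(genes_gff: pd.DataFrame, replicon_id: str, length: int):
    sub = genes_gff[
        (genes_gff["seqid"] == replicon_id) & (genes_gff["type"] == "CDS")
    ]
    return [(int(s) - 1, int(e)) for s, e in zip(sub["start"], sub["end"])]


def _overlaps_coding(start: int, end: int, intervals, length: int) -> bool:
    for s, e in intervals:
        # linear overlap plus the wrap case for hits crossing the origin
        for off in (0, -length, length):
            if start + off < e and end + off > s:
                return True
    return False


def _is_arm_palindrome(site: str, min_arm: int, max_mm: int) -> bool:
    """True when the site's outer arms form an inverted repeat of at least
    ``min_arm`` bp with at most ``max_mm`` mismatches."""
    n = len(site)
    for arm in range(n // 2, min_arm - 1, -1):
        left = site[:arm]
        right_rc = reverse_complement(site[n - arm:])
        mm = sum(a != b for a, b in zip(left, right_rc))
        if mm <= max_mm:
            return True
    return False


def find_dif(
    replicon: Replicon,
    genes_gff: pd.DataFrame | None = None,
    params: DifSearchParams | None = None,
    expected_ter: int | None = None,
) -> list[SiteCandidate]:
    """Scan both strands for dif candidates and apply the structural filters.

    Candidates within ``max_mismatches`` of any reference 28-mer are kept
    when they (a) lie outside annotated CDS features, (b) contain an arm
    palindrome, and (c) carry the conserved XerD half-site (exact or one
    mismatch). Ranked by (mismatches, distance to ``expected_ter``).
    """
    params = params or DifSearchParams()
    if replicon.sequence is None:
        raise ValueError(f"replicon {replicon.id!r} has no sequence")
    L = replicon.length
    seq_arr = _encode(replicon.sequence)
    ext_seq = replicon.sequence + replicon.sequence[:27]

    coding = (
        _coding_intervals(genes_gff, replicon.id, L)
        if genes_gff is not None else []
    )
    if genes_gff is None:
        logger.warning(
            "%s: no gene annotations supplied; noncoding filter skipped",
            replicon.id,
        )

    candidates: list[SiteCandidate] = []
    for ref in params.reference_dif:
        xerd_box = ref[17:28] if params.xerd_arm == "right" else ref[0:11]
        for strand, motif in (("+", ref), ("-", reverse_complement(ref))):
            mm = _mismatch_scan(seq_arr, motif)
            for pos in np.flatnonzero(mm <= params.max_mismatches):
                pos = int(pos)
                site = ext_seq[pos : pos + 28]
                site_fwd = site if strand == "+" else reverse_complement(site)
                in_coding = _overlaps_coding(pos, pos + 28, coding, L)
                if coding and in_coding:
                    continue
                if not _is_arm_palindrome(
                    site_fwd, params.palindrome_min_arm,
                    params.palindrome_max_mismatch,
                ):
                    continue
                arm = (
                    site_fwd[17:28] if params.xerd_arm == "right"
                    else site_fwd[0:11]
                )
                xerd_mm = sum(a != b for a, b in zip(arm, xerd_box))
                if xerd_mm > params.xerd_max_mismatch:
                    continue
                dist = (
                    circular_distance(pos, expected_ter, L, oriented=False)
                    if expected_ter is not None else None
                )
                candidates.append(SiteCandidate(
                    position=pos, score=float(mm[pos]), kind="dif",
                    strand=strand, in_coding=in_coding,
                    distance_to_expected=dist,
                    detail=f"{int(mm[pos])} mismatches vs reference",
                ))
    # deduplicate positions found by several references/strands: keep best
    by_pos: dict[int, SiteCandidate] = {}
    for c in candidates:
        if c.position not in by_pos or c.score < by_pos[c.position].score:
            by_pos[c.position] = c
    ranked = sorted(
        by_pos.values(),
        key=lambda c: (c.score, c.distance_to_expected
                       if c.distance_to_expected is not None else 0,
                       c.position),
    )
    return ranked


def find_ori(
    replicon: Replicon,
    params: OriSearchParams | None = None,
    skew_call=None,
) -> list[SiteCandidate]:
    """Slide a window across the circle scoring DnaA boxes and GATC sites.

    Windows with at least ``min_boxes`` DnaA boxes (either strand, up to
    ``box_max_mismatch`` mismatches) and ``min_gatc`` GATC sites are
    candidates, reported at the window midpoint. Ranked by distance to a
    skew-predicted ori when available, else by (boxes, gatc) descending;
    ties broken by coordinate.
    """
    params = params or OriSearchParams()
    if replicon.sequence is None:
        raise ValueError(f"replicon {replicon.id!r} has no sequence")
    L = replicon.length
    seq_arr = _encode(replicon.sequence)

    box_hit = np.zeros(L, dtype=bool)
    for motif in (params.dnaA_box, reverse_complement(params.dnaA_box)):
        box_hit |= _mismatch_scan(seq_arr, motif) <= params.box_max_mismatch
    gatc_hit = _mismatch_scan(seq_arr, "GATC") == 0

    w = params.cluster_window
    step = max(1, w // 5)
    box_cum = np.concatenate([[0], np.cumsum(np.concatenate([box_hit, box_hit]))])
    gatc_cum = np.concatenate([[0], np.cumsum(np.concatenate([gatc_hit, gatc_hit]))])
    starts = np.arange(0, L, step)
    boxes = box_cum[starts + w] - box_cum[starts]
    gatcs = gatc_cum[starts + w] - gatc_cum[starts]
    ok = (boxes >= params.min_boxes) & (gatcs >= params.min_gatc)

    candidates = []
    last_end = -1
    # merge overlapping qualifying windows into one candidate (best window)
    for i in np.flatnonzero(ok):
        s = int(starts[i])
        cand = SiteCandidate(
            position=int((s + w // 2) % L),
            score=float(boxes[i] * 1000 + gatcs[i]),
            kind="ori",
            detail=f"{int(boxes[i])} DnaA boxes, {int(gatcs[i])} GATC",
        )
        if candidates and s <= last_end:
            if cand.score > candidates[-1].score:
                candidates[-1] = cand
            last_end = max(last_end, s + w)
        else:
            candidates.append(cand)
            last_end = s + w
    if skew_call is not None and getattr(skew_call, "predicted_ori", None) is not None:
        for c in candidates:
            c.distance_to_expected = circular_distance(
                c.position, skew_call.predicted_ori, L, oriented=False
            )
        candidates.sort(key=lambda c: (c.distance_to_expected, c.position))
    else:
        candidates.sort(key=lambda c: (-c.score, c.position))
    return candidates
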