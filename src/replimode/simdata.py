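"""Synthetic-data generators with planted ground truth.

Every analysis stage in this package gets a generator that emulates the
relevant feature of real data and records the truth it planted:

* circular sequences whose leading strand is G-enriched, switching sign at
  planted ori/ter (bidirectional) or constant around the circle
  (unidirectional);
* read-depth profiles of exponentially growing populations under a
  fork-progression model — relative copy number 2^(-t(x)/tau), where t(x)
  is the time from the population-wide earliest initiation to replication
  of locus x — with a multiplicative per-bin bias field shared between
  growth phases and Poisson read noise;
* gene annotations with a planted leading-strand bias; and
* trees with a single monophyletic clade of bidirectional tips.

All generators are deterministic under their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

from .genomeio import GFF_COLUMNS, Replicon

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class GrowthModel:
    """Population growth and inter-replicon replication timing.

    tau : doubling time (arbitrary units).
    synchrony : how secondary replicons are timed against the first
        ("termination": all replicons finish together; "initiation": all
        start together; "none": all start together, uncoordinated).
    phase : "exponential" (copy-number gradients present) or "stationary"
        (flat expected coverage).
    """

    tau: float = 1.0
    synchrony: str = "termination"
    phase: str = "exponential"

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.synchrony not in ("initiation", "termination", "none"):
            raise ValueError(f"unknown synchrony {self.synchrony!r}")
        if self.phase not in ("exponential", "stationary"):
            raise ValueError(f"unknown phase {self.phase!r}")


@dataclass
class SimReplicon:
    """Configuration for one synthetic replicon.

    C is the replication period in the GrowthModel's time units (the time a
    fork system needs to copy the whole replicon). ter defaults to the
    antipode of ori (bidirectional) or 20 kb counterclockwise of ori
    (unidirectional, so the single clockwise fork traverses nearly the
    whole circle before terminating adjacent to ori, as in real
    unidirectionally replicating chromids).
    """

    id: str = "sim"
    length: int = 1_000_000
    mode: str = "bidirectional"
    ori: int = 0
    ter: int | None = None
    C: float = 1.0
    skew_amplitude: float = 0.08
    gc_content: float = 0.45
    bias_sigma: float = 0.1
    ter_offset: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("bidirectional", "unidirectional"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 <= self.skew_amplitude <= 0.5:
            raise ValueError("skew_amplitude must be in [0, 0.5]")
        if not 0 < self.gc_content < 1:
            raise ValueError("gc_content must be in (0, 1)")
        if self.ter is None:
            if self.mode == "bidirectional":
                self.ter = (self.ori + self.length // 2) % self.length
            else:
                self.ter = (self.ori - self.ter_offset) % self.length
        if not 0 <= self.ori < self.length:
            raise ValueError("ori out of range")


def _leading_sign(cfg: SimReplicon) -> np.ndarray:
    """+1 where the forward strand is the leading strand, -1 elsewhere."""
    pos = np.arange(cfg.length)
    if cfg.mode == "unidirectional":
        return np.ones(cfg.length)
    d_cw = (pos - cfg.ori) % cfg.length
    arc1 = (cfg.ter - cfg.ori) % cfg.length
    return np.where(d_cw < arc1, 1.0, -1.0)


def generate_replicon(cfg: SimReplicon) -> tuple[Replicon, dict]:
    """Draw an i.i.d. circular sequence with strand-dependent GC skew.

    Per position, P(G) - P(C) = +/- skew_amplitude * gc_content with the
    sign set by which strand is leading there; P(G) + P(C) = gc_content.
    Returns the Replicon and a truth record of the planted parameters.
    """
    a = cfg.skew_amplitude
    gc = cfg.gc_content
    if gc * (1 + a) / 2 > 1 or gc * (1 - a) < 0:
        raise ValueError("skew_amplitude and gc_content imply invalid probabilities")
    rng = np.random.default_rng(cfg.seed)
    sign = _leading_sign(cfg)
    p_g = gc * (1 + a * sign) / 2
    p_c = gc - p_g
    p_at = (1 - gc) / 2
    # cumulative thresholds per position: A | C | G | T
    u = rng.random(cfg.length)
    codes = np.empty(cfg.length, dtype=np.uint8)
    codes[:] = 3  # T
    codes[u < p_at + p_c + p_g] = 2  # G
    codes[u < p_at + p_c] = 1  # C
    codes[u < p_at] = 0  # A
    seq = _BASES[codes].tobytes().decode("ascii")
    rep = Replicon(
        id=cfg.id, length=cfg.length, sequence=seq,
        sites={"ori": cfg.ori, "ter": cfg.ter},
    )
    truth = {
        "id": cfg.id, "mode": cfg.mode, "ori": cfg.ori, "ter": cfg.ter,
        "skew_amplitude": a, "gc_content": gc, "seed": cfg.seed,
    }
    return rep, truth


def plant_motif(replicon: Replicon, motif: str, position: int) -> Replicon:
    """Return a copy of the replicon with ``motif`` written at ``position``
    (wrapping across the coordinate origin if needed)."""
    if replicon.sequence is None:
        raise ValueError("replicon has no sequence")
    L = replicon.length
    seq = list(replicon.sequence)
    for i, base in enumerate(motif.upper()):
        seq[(position + i) % L] = base
    return Replicon(
        id=replicon.id, length=L, sequence="".join(seq),
        sites=dict(replicon.sites),
    )


def replication_time(position, cfg: SimReplicon, growth: GrowthModel | None = None):
    """Time from this replicon's own initiation until locus replication.

    Bidirectional: two forks leave ori at t=0 and meet at ter at t=C; each
    fork covers its replichore linearly in time. Unidirectional: one fork
    proceeds clockwise from ori, reaching ter (clockwise distance d_ot) at
    t=C; the short remaining arc extrapolates linearly past C. Accepts a
    scalar or array of positions.
    """
    pos = np.asarray(position)
    L = cfg.length
    d_cw = (pos - cfg.ori) % L
    if cfg.mode == "unidirectional":
        d_ot = (cfg.ter - cfg.ori) % L
        t = cfg.C * d_cw / d_ot
    else:
        arc1 = (cfg.ter - cfg.ori) % L
        arc2 = L - arc1
        t = np.where(d_cw <= arc1, cfg.C * d_cw / arc1, cfg.C * (L - d_cw) / arc2)
    return t if t.shape else float(t)


@dataclass
class SimulatedCoverage:
    """Per-base depth arrays and the planted truth behind them."""

    exponential: dict[str, np.ndarray]
    stationary: dict[str, np.ndarray]
    expected_exponential: dict[str, np.ndarray]
    bias_fields: dict[str, np.ndarray]
    initiation_offsets: dict[str, float]
    bin_size: int


def simulate_coverage(
    replicons: list[SimReplicon],
    growth: GrowthModel,
    mean_depth: float = 200.0,
    bin_size: int = 1000,
    seed: int = 0,
    bias_fields: dict[str, np.ndarray] | None = None,
) -> SimulatedCoverage:
    """Simulate exponential- and stationary-phase read depth.

    Relative copy number n(x) = 2^(-t_abs(x)/tau), with t_abs measured from
    the population-wide earliest initiation: under termination synchrony a
    replicon with period C_r initiates (C_max - C_r) after the slowest one
    so that all termini finish together; under initiation synchrony (and
    "none") all initiate together. Expected depth is
    mean_depth * n(x)/<n> * bias(bin(x)) with <n> the mean copy number over
    all replicons jointly — a sequencing run has a single depth scale, so
    cross-replicon ratios are preserved. Observed depth is Poisson; the
    stationary phase has n(x) = 1 and shares the bias field.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(seed)
    c_max = max(r.C for r in replicons)
    offsets = {}
    for r in replicons:
        if growth.synchrony == "termination":
            offsets[r.id] = c_max - r.C
        else:
            offsets[r.id] = 0.0

    copy_number: dict[str, np.ndarray] = {}
    for r in replicons:
        pos = np.arange(r.length)
        t_abs = offsets[r.id] + replication_time(pos, r, growth)
        copy_number[r.id] = 2.0 ** (-t_abs / growth.tau)
    total_len = sum(r.length for r in replicons)
    mean_n = sum(cn.sum() for cn in copy_number.values()) / total_len

    if bias_fields is None:
        bias_fields = {}
        for r in replicons:
            n_bins = -(-r.length // bin_size)
            bias_fields[r.id] = np.exp(
                rng.normal(0.0, r.bias_sigma, size=n_bins)
            ) if r.bias_sigma > 0 else np.ones(n_bins)

    exp_depth, stat_depth, expected_exp = {}, {}, {}
    for r in replicons:
        bias_per_base = np.repeat(bias_fields[r.id], bin_size)[: r.length]
        mu_exp = mean_depth * (copy_number[r.id] / mean_n) * bias_per_base
        mu_stat = mean_depth * bias_per_base
        expected_exp[r.id] = mu_exp
        exp_depth[r.id] = rng.poisson(mu_exp).astype(np.int64)
        stat_depth[r.id] = rng.poisson(mu_stat).astype(np.int64)

    return SimulatedCoverage(
        exponential=exp_depth, stationary=stat_depth,
        expected_exponential=expected_exp, bias_fields=bias_fields,
        initiation_offsets=offsets, bin_size=bin_size,
    )


def plant_spikes(
    depth: np.ndarray, n_spikes: int, factor: float = 5.0,
    width: int = 1000, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Multiply ``n_spikes`` non-overlapping width-bp stretches by ``factor``.

    Returns (modified copy, array of spike start positions).
    """
    rng = np.random.default_rng(seed)
    n_slots = len(depth) // width
    starts = rng.choice(n_slots, size=n_spikes, replace=False) * width
    out = depth.astype(float).copy()
    for s in starts:
        out[s : s + width] = out[s : s + width] * factor
    return np.round(out).astype(np.int64), np.sort(starts)


def generate_genes(
    cfg: SimReplicon,
    n_genes: int = 1000,
    leading_fraction: float = 0.6,
    seed: int = 0,
    mean_length: float = 900.0,
    length_sigma: float = 0.3,
) -> pd.DataFrame:
    """Random gene annotations with a planted leading-strand bias.

    Gene midpoints are uniform on the circle; each gene sits on the local
    leading strand with probability ``leading_fraction``. Lengths are
    lognormal; overlaps are not prevented. Returns a GFF3-shaped DataFrame
    (1-based inclusive coordinates; wrap-spanning genes are clipped at the
    coordinate origin).
    """
    if not 0 <= leading_fraction <= 1:
        raise ValueError("leading_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    L = cfg.length
    sign = _leading_sign(cfg)
    rows = []
    mids = rng.integers(0, L, size=n_genes)
    lengths = np.maximum(
        60, rng.lognormal(np.log(mean_length), length_sigma, size=n_genes).astype(int)
    )
    on_leading = rng.random(n_genes) < leading_fraction
    for i in range(n_genes):
        mid = int(mids[i])
        half = int(lengths[i]) // 2
        start = max(1, mid - half + 1)
        end = min(L, mid + half + 1)
        fwd_leading = sign[mid] > 0
        if on_leading[i]:
            strand = "+" if fwd_leading else "-"
        else:
            strand = "-" if fwd_leading else "+"
        rows.append([
            cfg.id, "simdata", "CDS", start, end, ".", strand, "0",
            f"ID=gene{i:05d}",
        ])
    return pd.DataFrame(rows, columns=GFF_COLUMNS)


def generate_trait_tree(
    n_tips: int = 12,
    topology_seed: int = 0,
    bi_clade_size: int = 3,
) -> tuple[dendropy.Tree, dict[str, str], dict]:
    """Random rooted tree with one monophyletic bidirectional clade.

    All other tips are unidirectional. Returns (tree, tip states, truth);
    the planted minimum change count is 1 under a uni-constrained root
    (0 when the clade is empty).
    """
    if not 0 <= bi_clade_size < n_tips:
        raise ValueError("need 0 <= bi_clade_size < n_tips")
    rng = np.random.default_rng(topology_seed)

    def random_topology(labels: list[str]) -> str:
        parts = list(labels)
        while len(parts) > 1:
            i, j = sorted(rng.choice(len(parts), size=2, replace=False))
            b = parts.pop(j)
            a = parts.pop(i)
            parts.append(f"({a},{b})")
        return parts[0]

    uni_tips = [f"uni{i:02d}" for i in range(n_tips - bi_clade_size)]
    bi_tips = [f"bi{i:02d}" for i in range(bi_clade_size)]
    if bi_clade_size == 0:
        newick = random_topology(uni_tips) + ";"
    else:
        bi_sub = random_topology(bi_tips)
        newick = random_topology(uni_tips + [f"@BI@"]).replace("@BI@", bi_sub) + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    states = {t: "uni" for t in uni_tips}
    states.update({t: "bi" for t in bi_tips})
    truth = {
        "n_tips": n_tips,
        "bi_clade": bi_tips,
        "min_changes_uni_root": 0 if bi_clade_size == 0 else 1,
        "newick": newick,
    }
    return tree, states, truth
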