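"""Marker-frequency analysis of sequencing depth.

In an exponentially growing population, loci replicated early (near ori)
are present in more copies than loci replicated late (near ter): relative
copy number follows 2^(-t(x)/tau), so log2 read depth declines linearly
with replication time along each replichore. This module bins per-base
depth, corrects exponential-phase coverage with a stationary-phase sample,
removes outlier bins with a neighbor-IQR rule, fits circular gradient
models (flat / one-slope / two-slope) to infer the replication direction,
and classifies initiation- vs termination-synchrony of replicon pairs from
ori/ori and dif/dif coverage ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genomeio import circular_distance

logger = logging.getLogger(__name__)


@dataclass
class CoverageProfile:
    """Binned depth for one replicon in one growth phase.

    mask[i] is True when bin i has been removed (outlier, or undefined
    correction factor) and must be excluded from downstream fits.
    """

    replicon_id: str
    length: int
    bin_size: int
    bin_values: np.ndarray
    phase: str = "exponential"
    corrected: bool = False
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = -(-self.length // self.bin_size)  # ceil
        if len(self.bin_values) != expected:
            raise ValueError(
                f"{self.replicon_id!r}: {len(self.bin_values)} bins != "
                f"ceil({self.length}/{self.bin_size}) = {expected}"
            )
        if self.phase not in ("exponential", "stationary"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.mask is None:
            self.mask = np.zeros(len(self.bin_values), dtype=bool)

    @property
    def n_bins(self) -> int:
        return len(self.bin_values)

    def bin_centers(self) -> np.ndarray:
        starts = np.arange(self.n_bins) * self.bin_size
        ends = np.minimum(starts + self.bin_size, self.length)
        return (starts + ends) / 2.0


@dataclass
class OutlierParams:
    """Neighbor-IQR outlier rule: a bin is removed when its distance from
    the median of its ``neighbors`` flanking bins (half per side,
    circularly) exceeds ``multiplier`` times their interquartile range."""

    neighbors: int = 50
    multiplier: float = 2.0

    def __post_init__(self) -> None:
        if self.neighbors < 2 or self.neighbors % 2:
            raise ValueError("neighbors must be even and >= 2")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


@dataclass
class GradientFit:
    """Selected circular coverage-gradient model.

    slopes are in log2-coverage units per Mb, one per replichore
    (two for bidirectional, one for unidirectional, none for flat).
    fit_quality is the residual-variance ratio of the chosen model to the
    flat model (smaller is a stronger gradient).
    """

    replicon_id: str
    model: str
    ori_est: int | None
    ter_est: int | None
    slopes: tuple[float, ...]
    fit_quality: float
    log2_drop: float = 0.0


@dataclass
class SynchronyResult:
    R_ori: float
    R_dif: float
    mode: str
    region_halfwidth: int = 5000
    tolerance: float = 0.15


def bin_coverage(
    depth_array: np.ndarray,
    bin_size: int = 1000,
    replicon_id: str = "",
    phase: str = "exponential",
) -> CoverageProfile:
    """Group per-base depth into bins of ``bin_size`` bp (mean per bin).

    The final partial bin is averaged over its actual width.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    depth = np.asarray(depth_array, dtype=float)
    L = len(depth)
    n_bins = -(-L // bin_size)
    sums = np.add.reduceat(depth, np.arange(0, L, bin_size))
    widths = np.full(n_bins, bin_size, dtype=float)
    if L % bin_size:
        widths[-1] = L % bin_size
    return CoverageProfile(
        replicon_id=replicon_id, length=L, bin_size=bin_size,
        bin_values=sums / widths, phase=phase,
    )


def correct_coverage(
    exp_profile: CoverageProfile, stat_profile: CoverageProfile
) -> CoverageProfile:
    """Remove shared coverage bias using a stationary-phase profile.

    Per bin: factor = stationary bin / stationary replicon mean;
    corrected exponential = exponential bin / factor. A stationary sample
    has flat true copy number, so its bin-to-bin variation estimates the
    (library/mapping) bias field shared by both phases. Bins with zero
    stationary coverage are masked rather than divided.
    """
    if (
        exp_profile.bin_size != stat_profile.bin_size
        or exp_profile.n_bins != stat_profile.n_bins
        or exp_profile.replicon_id != stat_profile.replicon_id
    ):
        raise ValueError("exponential and stationary profiles must share binning")
    stat = stat_profile.bin_values
    mean_stat = stat.mean()
    if mean_stat <= 0:
        raise ValueError("stationary profile has zero average coverage")
    factors = stat / mean_stat
    zero = factors == 0
    corrected = np.where(zero, 0.0, exp_profile.bin_values / np.where(zero, 1.0, factors))
    mask = exp_profile.mask | stat_profile.mask | zero
    return CoverageProfile(
        replicon_id=exp_profile.replicon_id, length=exp_profile.length,
        bin_size=exp_profile.bin_size, bin_values=corrected,
        phase=exp_profile.phase, corrected=True, mask=mask,
    )


def remove_outliers(
    profile: CoverageProfile, params: OutlierParams | None = None
) -> CoverageProfile:
    """Mask bins far from their circular neighborhood.

    For each bin, the ``neighbors/2`` bins on each side (circular, the bin
    itself excluded) define Q1, Q3 and a median; the bin is masked when
    |value - median| > multiplier * (Q3 - Q1), strictly. Already-masked
    bins keep their mask and are excluded from every neighborhood. The
    rule is iterated to a fixpoint (each round re-evaluates with the
    freshly masked bins excluded), which makes the operation idempotent.
    """
    params = params or OutlierParams()
    n = profile.n_bins
    half = params.neighbors // 2
    if n < params.neighbors + 1:
        raise ValueError(f"profile has {n} bins; need > {params.neighbors}")

    values = profile.bin_values
    offsets = np.concatenate([np.arange(-half, 0), np.arange(1, half + 1)])
    idx = (np.arange(n)[:, None] + offsets[None, :]) % n  # (n, neighbors)
    mask = profile.mask.copy()
    for _ in range(100):
        neigh = values[idx].astype(float)
        neigh[mask[idx]] = np.nan
        with np.errstate(invalid="ignore"):
            q1 = np.nanpercentile(neigh, 25, axis=1)
            q3 = np.nanpercentile(neigh, 75, axis=1)
            med = np.nanmedian(neigh, axis=1)
        iqr = q3 - q1
        new_outliers = np.abs(values - med) > params.multiplier * iqr
        new_outliers &= ~np.isnan(med) & ~mask
        if not new_outliers.any():
            break
        if (mask | new_outliers).sum() > 0.5 * n:
            break  # downstream fits reject such profiles anyway
        mask = mask | new_outliers
    return CoverageProfile(
        replicon_id=profile.replicon_id, length=profile.length,
        bin_size=profile.bin_size, bin_values=values.copy(),
        phase=profile.phase, corrected=profile.corrected, mask=mask,
    )


def _cw_dist(a: np.ndarray, b: float, n: int) -> np.ndarray:
    return (a - b) % n


def _fit_two_slope(y: np.ndarray, x: np.ndarray, ori: int, ter: int, n: int):
    """LS fit of the circular tent model: peak value p at ori, trough q at
    ter, linear in position along both arcs. Returns (sse, p, q)."""
    arc1 = (ter - ori) % n  # clockwise ori -> ter
    arc2 = n - arc1
    if arc1 == 0 or arc2 == 0:
        return np.inf, 0.0, 0.0
    d = _cw_dist(x, ori, n)
    on_arc1 = d <= arc1
    frac = np.where(on_arc1, d / arc1, (n - d) / arc2)  # 0 at ori, 1 at ter
    # y ~ p*(1-frac) + q*frac
    a = 1 - frac
    b = frac
    g = np.array([[a @ a, a @ b], [a @ b, b @ b]])
    rhs = np.array([a @ y, b @ y])
    try:
        p, q = np.linalg.solve(g, rhs)
    except np.linalg.LinAlgError:
        return np.inf, 0.0, 0.0
    resid = y - (p * a + q * b)
    return float(resid @ resid), float(p), float(q)


def _fit_one_slope(y: np.ndarray, x: np.ndarray, ori: int, n: int):
    """LS fit of the single-fork model: value declines linearly with
    clockwise distance from ori over the whole circle."""
    d = _cw_dist(x, ori, n) / n  # 0 at ori -> 1 just before ori
    a = np.ones_like(y)
    g = np.array([[a @ a, a @ d], [a @ d, d @ d]])
    rhs = np.array([a @ y, d @ y])
    try:
        c0, c1 = np.linalg.solve(g, rhs)
    except np.linalg.LinAlgError:
        return np.inf, 0.0, 0.0
    resid = y - (c0 + c1 * d)
    return float(resid @ resid), float(c0), float(c1)


def infer_replication_direction(
    profile: CoverageProfile, ori: int | None = None,
    ori_constraint_bp: int = 10_000,
) -> GradientFit:
    """Fit circular gradient models to log2 binned coverage and pick one.

    Candidate models: flat; one-slope (single fork, monotone log2 decline
    clockwise from ori); two-slope (peak at ori, trough at ter, linear
    decline along both replichores). Selection minimizes a BIC-style score
    with one degree of freedom charged per breakpoint. If ``ori`` is given,
    ori_est is constrained to within ``ori_constraint_bp`` of it.
    """
    if profile.phase == "stationary":
        logger.warning(
            "%s: stationary-phase profile carries no replication gradient",
            profile.replicon_id,
        )
        return GradientFit(profile.replicon_id, "flat", None, None, (), 1.0)
    n = profile.n_bins
    keep = ~profile.mask & (profile.bin_values > 0)
    if keep.sum() < 0.5 * n:
        raise ValueError(
            f"{profile.replicon_id!r}: more than 50% of bins masked or zero"
        )
    x = np.flatnonzero(keep).astype(float)
    y = np.log2(profile.bin_values[keep])
    m = len(y)

    sse_flat = float(((y - y.mean()) ** 2).sum())

    # candidate breakpoints on a coarse grid, refined around the best
    if ori is not None:
        ori_bin = ori / profile.bin_size
        w = max(1, int(round(ori_constraint_bp / profile.bin_size)))
        cand_ori = np.arange(int(ori_bin) - w, int(ori_bin) + w + 1) % n
        cand_ori = np.unique(cand_ori)
    else:
        stride = max(1, n // 64)
        cand_ori = np.arange(0, n, stride)
    stride_t = max(1, n // 64)
    cand_ter = np.arange(0, n, stride_t)

    def best_uni(cands):
        best = (np.inf, 0.0, 0.0, 0)
        for o in cands:
            sse, c0, c1 = _fit_one_slope(y, x, int(o), n)
            if sse < best[0]:
                best = (sse, c0, c1, int(o))
        return best

    def best_bi(cands_o, cands_t):
        best = (np.inf, 0.0, 0.0, 0, 0)
        for o in cands_o:
            for t in cands_t:
                if o == t:
                    continue
                sse, p, q = _fit_two_slope(y, x, int(o), int(t), n)
                if sse < best[0]:
                    best = (sse, p, q, int(o), int(t))
        return best

    sse_u, c0, c1, ori_u = best_uni(cand_ori)
    # refine unidirectional ori locally
    refine = np.arange(ori_u - max(1, n // 64), ori_u + max(1, n // 64) + 1) % n
    if ori is not None:
        refine = cand_ori
    sse_u, c0, c1, ori_u = min(
        (best_uni(refine), (sse_u, c0, c1, ori_u)), key=lambda t: t[0]
    )

    sse_b, p, q, ori_b, ter_b = best_bi(cand_ori, cand_ter)
    r = max(1, n // 64)
    ref_o = np.arange(ori_b - r, ori_b + r + 1) % n if ori is None else cand_ori
    ref_t = np.arange(ter_b - r, ter_b + r + 1) % n
    sse_b, p, q, ori_b, ter_b = min(
        (best_bi(ref_o, ref_t), (sse_b, p, q, ori_b, ter_b)), key=lambda t: t[0]
    )

    # BIC-style: m*ln(SSE/m) + k*ln(m); one df per breakpoint beyond flat's
    # mean, plus the linear coefficients each model estimates.
    eps = 1e-12
    bic = {
        "flat": m * np.log(sse_flat / m + eps) + 1 * np.log(m),
        "unidirectional": m * np.log(sse_u / m + eps) + 3 * np.log(m),
        "bidirectional": m * np.log(sse_b / m + eps) + 4 * np.log(m),
    }
    model = min(bic, key=bic.get)

    bs = profile.bin_size
    if model == "flat":
        return GradientFit(profile.replicon_id, "flat", None, None, (),
                           1.0, 0.0)
    if model == "unidirectional":
        # c1 is the log2 change over the full circle (negative: decline)
        per_mb = c1 / (n * bs / 1e6)
        ter_est = int(((ori_u - 1) % n) * bs)
        return GradientFit(
            profile.replicon_id, "unidirectional", int(ori_u * bs), ter_est,
            (float(per_mb),), sse_u / sse_flat, float(-c1),
        )
    if p < q:
        # the tent model is symmetric in (ori, p) <-> (ter, q); canonical
        # orientation puts the coverage peak at ori
        ori_b, ter_b = ter_b, ori_b
        p, q = q, p
    arc1 = (ter_b - ori_b) % n * bs / 1e6
    arc2 = (n - (ter_b - ori_b) % n) * bs / 1e6
    drop = p - q
    return GradientFit(
        profile.replicon_id, "bidirectional", int(ori_b * bs), int(ter_b * bs),
        (float(-drop / arc1), float(drop / arc2)), sse_b / sse_flat, float(drop),
    )


def region_coverage(profile: CoverageProfile, site: int, halfwidth: int) -> float:
    """Mean of unmasked bins whose centers lie within ±halfwidth of site."""
    centers = profile.bin_centers()
    dist = np.minimum(
        (centers - site) % profile.length, (site - centers) % profile.length
    )
    sel = (dist <= halfwidth) & ~profile.mask
    if not sel.any():
        raise ValueError(
            f"{profile.replicon_id!r}: all bins within {halfwidth} bp of "
            f"{site} are masked"
        )
    return float(profile.bin_values[sel].mean())


def synchrony_ratios(
    profile_chr1: CoverageProfile,
    profile_chr2: CoverageProfile,
    sites1: dict[str, int],
    sites2: dict[str, int],
    region_halfwidth: int = 5000,
    tolerance: float = 0.15,
) -> SynchronyResult:
    """ori/ori and dif/dif coverage ratios between two replicons.

    Termination synchrony (replicons timed to finish together) leaves the
    terminus regions at equal copy number (R_dif ≈ 1) while the larger
    replicon, initiating earlier, is enriched at its origin (R_ori > 1).
    Initiation synchrony is the mirror image: R_ori ≈ 1 and R_dif < 1.
    """
    for name, sites in (("main", sites1), ("chromid", sites2)):
        for key in ("ori", "dif"):
            if key not in sites:
                raise ValueError(f"{name} replicon lacks a {key!r} site")
    r_ori = region_coverage(profile_chr1, sites1["ori"], region_halfwidth) / \
        region_coverage(profile_chr2, sites2["ori"], region_halfwidth)
    r_dif = region_coverage(profile_chr1, sites1["dif"], region_halfwidth) / \
        region_coverage(profile_chr2, sites2["dif"], region_halfwidth)
    if abs(r_dif - 1) <= tolerance and r_ori > 1 + tolerance:
        mode = "termination_synchrony"
    elif abs(r_ori - 1) <= tolerance and r_dif < 1 - tolerance:
        mode = "initiation_synchrony"
    else:
        mode = "indeterminate"
    return SynchronyResult(
        R_ori=float(r_ori), R_dif=float(r_dif), mode=mode,
        region_halfwidth=region_halfwidth, tolerance=tolerance,
    )
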