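"""ROSE-style super-enhancer calling from H3K27ac peaks and coverage.

The procedure: drop peaks whose midpoint falls within a window of any
annotated TSS, stitch the remaining peaks when their gaps are at most the
stitching distance, score every stitched region by its input-subtracted
H3K27ac load (coverage summed over the region), rank the regions, and
separate super-enhancers (SE) from typical enhancers (TE) at the point
where the min-max-scaled rank curve has slope 1 (the "hockey-stick"
tangent cutoff).  Regions in user-declared amplified intervals (e.g. an
MYCN amplicon) can be masked out of the cutoff fit so a single amplified
locus does not drag the scaled curve, then re-flagged against the fitted
cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CoverageMap, GenomicInterval, GeneRecord, Peak


@dataclass
class StitchedEnhancer:
    """A stitched enhancer region with its load, rank and SE/TE flag."""

    interval: GenomicInterval
    constituents: list[Peak]
    load: float = 0.0
    rank: int = 0
    is_super: bool = False
    se_id: str = ""


@dataclass
class SECallConfig:
    """Tunable distances for SE calling (defaults follow common practice:
    12.5 kb stitching, +/-2 kb promoter exclusion, 50 kb gene window)."""

    stitch_distance: int = 12_500
    tss_exclusion: int = 2_000
    gene_window: int = 50_000
    amplified_regions: list[GenomicInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("stitch_distance", "tss_exclusion", "gene_window"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def exclude_promoter_peaks(
    peaks: list[Peak], genes: list[GeneRecord], window: int = 2_000
) -> list[Peak]:
    """Drop peaks whose midpoint lies within ``window`` of any TSS.

    The bound is closed: a midpoint at exactly tss +/- window is excluded.
    Order of the surviving peaks is preserved.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    if not genes:
        return list(peaks)
    tss_by_chrom: dict[str, np.ndarray] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.tss.chrom, []).append(g.tss.start)  # type: ignore[attr-defined]
    tss_by_chrom = {c: np.sort(np.array(v)) for c, v in tss_by_chrom.items()}

    kept = []
    for p in peaks:
        tss = tss_by_chrom.get(p.interval.chrom)
        if tss is None:
            kept.append(p)
            continue
        mid = p.interval.midpoint
        i = int(np.searchsorted(tss, mid))
        near = min(
            abs(mid - tss[i - 1]) if i > 0 else np.inf,
            abs(tss[i] - mid) if i < len(tss) else np.inf,
        )
        if near > window:
            kept.append(p)
    return kept


def stitch_peaks(peaks: list[Peak], distance: int = 12_500) -> list[StitchedEnhancer]:
    """Merge peaks on a chromosome whenever their gap is <= ``distance``.

    This is the transitive closure of the gap relation; every input peak
    becomes a constituent of exactly one stitched region. Output is sorted
    by (chrom, start).
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    ordered = sorted(peaks, key=lambda p: (p.interval.chrom, p.interval.start, p.interval.end))
    out: list[StitchedEnhancer] = []
    group: list[Peak] = []

    def _close() -> None:
        if not group:
            return
        iv = GenomicInterval(
            group[0].interval.chrom,
            min(p.interval.start for p in group),
            max(p.interval.end for p in group),
        )
        out.append(StitchedEnhancer(interval=iv, constituents=list(group)))
        group.clear()

    cur_chrom, cur_end = None, None
    for p in ordered:
        iv = p.interval
        if cur_chrom == iv.chrom and iv.start - cur_end <= distance:
            group.append(p)
            cur_end = max(cur_end, iv.end)
        else:
            _close()
            group.append(p)
            cur_chrom, cur_end = iv.chrom, iv.end
    _close()
    return out


def score_stitched(
    regions: list[StitchedEnhancer],
    treat: CoverageMap,
    input_ctrl: CoverageMap | None = None,
) -> list[StitchedEnhancer]:
    """Score regions by input-subtracted load and rank them descending.

    load = max(0, treat_sum - input_sum); negative loads are floored at 0
    because a negative enhancer load is meaningless for ranking and breaks
    the scaled rank curve. Ties in load are broken by (chrom, start).
    """
    for r in regions:
        t = treat.query(r.interval)
        i = input_ctrl.query(r.interval) if input_ctrl is not None else 0.0
        r.load = max(0.0, t - i)
    ranked = sorted(regions, key=lambda r: (-r.load, r.interval.chrom, r.interval.start))
    for rank, r in enumerate(ranked, start=1):
        r.rank = rank
    return ranked


def find_se_cutoff(loads: "np.ndarray | list[float]") -> tuple[float, np.ndarray]:
    """Tangent cutoff on the rank-ordered load curve.

    Loads are sorted ascending and min-max scaled to the unit square
    (x = i/(n-1), y = load/max). The cutoff index maximizes x - y, which
    for a convex hockey-stick curve is the point where the slope-1 line is
    tangent to the curve. Ties go to the largest index (fewest SEs).
    Returns the unscaled cutoff load and, for the loads in their *input*
    order, the boolean SE flags (load strictly above the cutoff).
    """
    loads = np.asarray(loads, dtype=float)
    if loads.size < 3:
        raise ValueError("need at least 3 loads to fit a cutoff")
    if np.any(loads < 0):
        raise ValueError("loads must be non-negative")
    if loads.max() == 0:
        raise ValueError("all loads are zero; no curve to fit")
    y = np.sort(loads)
    x = np.arange(y.size) / (y.size - 1)
    diff = x - y / y.max()
    # argmax with ties resolved to the largest index
    idx = y.size - 1 - int(np.argmax(diff[::-1]))
    cutoff = float(y[idx])
    return cutoff, loads > cutoff


def mask_amplified(
    regions: list[StitchedEnhancer],
    amplified: list[GenomicInterval],
) -> tuple[float, list[StitchedEnhancer], list[StitchedEnhancer]]:
    """Fit the SE cutoff with amplified regions excluded, then flag all.

    Regions overlapping any amplified interval are removed before cutoff
    fitting so one amplicon cannot compress the scaled curve; they are
    still flagged afterwards by comparing their load to the fitted cutoff.
    Returns (cutoff, fit set, masked set); flags are set on every region.
    """
    masked = [
        r for r in regions if any(r.interval.overlaps(a) for a in amplified)
    ]
    masked_ids = {id(r) for r in masked}
    fit = [r for r in regions if id(r) not in masked_ids]
    if amplified and not fit:
        raise ValueError("no regions left to fit after amplification masking")
    cutoff, _ = find_se_cutoff([r.load for r in fit])
    for r in regions:
        r.is_super = r.load > cutoff
    return cutoff, fit, masked


def assign_genes(
    ses: list[StitchedEnhancer],
    genes: list[GeneRecord],
    window: int = 50_000,
) -> list[tuple[StitchedEnhancer, GeneRecord, int]]:
    """Associate every enhancer with every gene that overlaps it or whose
    TSS lies within ``window`` of its boundaries (not nearest-only).

    distance = 0 for a TSS inside the region, else the distance from the
    TSS to the nearer boundary; a pair qualifies when distance <= window.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    genes_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_chrom.setdefault(g.tss.chrom, []).append(g)
    for glist in genes_by_chrom.values():
        glist.sort(key=lambda g: g.tss.start)

    pairs = []
    for se in ses:
        iv = se.interval
        for g in genes_by_chrom.get(iv.chrom, []):
            tss = g.tss.start
            if iv.start <= tss < iv.end:
                dist = 0
            else:
                dist = min(abs(tss - iv.start), abs(tss - iv.end))
            if dist <= window:
                pairs.append((se, g, dist))
    return pairs


def rpm_normalize(counts, total_mapped: float):
    """Reads per million mapped reads: count x 1e6 / total."""
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / total_mapped


def rpmpr_normalize(counts, reads_in_peaks: float):
    """Reads per million peak reads: count x 1e6 / reads falling in peaks."""
    if reads_in_peaks <= 0:
        raise ValueError("reads_in_peaks must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / reads_in_peaks


def call_super_enhancers(
    peaks: list[Peak],
    genes: list[GeneRecord],
    treat: CoverageMap,
    input_ctrl: CoverageMap | None = None,
    config: SECallConfig | None = None,
) -> tuple[list[StitchedEnhancer], float]:
    """Full SE call for one sample: exclude, stitch, score, cutoff, flag.

    Returns the ranked stitched regions (SE flags set) and the cutoff.
    """
    cfg = config or SECallConfig()
    kept = exclude_promoter_peaks(peaks, genes, cfg.tss_exclusion)
    regions = stitch_peaks(kept, cfg.stitch_distance)
    ranked = score_stitched(regions, treat, input_ctrl)
    if cfg.amplified_regions:
        cutoff, _, _ = mask_amplified(ranked, cfg.amplified_regions)
    else:
        cutoff, _ = find_se_cutoff([r.load for r in ranked])
        for r in ranked:
            r.is_super = r.load > cutoff
    return ranked, cutoff
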