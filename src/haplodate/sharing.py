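"""Shared-haplotype (IBD-style) segment detection and breed-pair summaries.

Between two phased samples there are four haplotype combinations; for
each, shared segments are maximal runs of marker-wise allele identity,
detected in overlapping marker windows (default 1,000 markers with a
25-marker overlap between consecutive windows) and merged across window
boundaries, which makes the result independent of the window step.
Missing sites are wildcards: they neither break a run nor count toward
the minimum-marker threshold. A run is kept when it spans at least
``min_markers`` informative markers and ``min_cm`` centimorgans.

Breed-pair sharing is summarised by the median, over all cross-breed
sample pairs, of the total shared length in bp (all four haplotype
combinations, all chromosomes). A breed pair shares significantly when
its median exceeds the 95th percentile of the medians of all pairs of
breeds from *different* clades.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import MISSING, HaplotypePanel

__all__ = [
    "SharingParams", "SharedSegment", "PairSharingSummary", "SignificanceResult",
    "window_partition", "detect_segments", "pair_total", "breed_pair_summary",
    "significance_call",
]


@dataclass
class SharingParams:
    window_markers: int = 1000
    window_overlap: int = 25
    min_markers: int = 25
    min_cm: float = 1.0
    combine: str = "sum"           # "sum" or "max" over the 4 haplotype pairs
    scan: str = "windowed"         # "windowed" or "genome" (must agree; tested)

    def __post_init__(self) -> None:
        if self.window_overlap >= self.window_markers:
            raise ValueError("window overlap must be smaller than the window")
        if self.min_markers < 1 or self.min_cm < 0:
            raise ValueError("segment minima must be >= 1 marker and >= 0 cM")
        if self.combine not in ("sum", "max") or self.scan not in ("windowed", "genome"):
            raise ValueError("unknown combine/scan mode")


@dataclass
class SharedSegment:
    sample1: str
    sample2: str
    hap1: int
    hap2: int
    chrom: str
    start: int            # chromosome-local marker index, half-open
    end: int
    bp_length: int
    cm_length: float
    n_markers: int        # informative (non-missing) matching markers


@dataclass
class PairSharingSummary:
    breed_a: str
    breed_b: str
    totals: np.ndarray    # total shared bp per cross-breed sample pair
    median_bp: float
    n_pairs: int
    within_breed: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return tuple(sorted((self.breed_a, self.breed_b)))


@dataclass
class SignificanceResult:
    threshold_bp: float
    percentile: float
    flagged: dict         # breed-pair key -> bool (median > threshold)
    across_clade_pairs: list = field(default_factory=list)


def window_partition(n_markers: int, params: SharingParams | None = None):
    """Half-open marker windows covering [0, n); consecutive windows share
    ``window_overlap`` markers and the final window is clipped."""
    params = params or SharingParams()
    if n_markers < 2:
        raise ValueError("need at least 2 markers")
    step = params.window_markers - params.window_overlap
    out = []
    start = 0
    while True:
        end = min(start + params.window_markers, n_markers)
        out.append((start, end))
        if end >= n_markers:
            return out
        start += step


def _match_runs(eq: np.ndarray, windows, min_len: int = 1) -> list[tuple[int, int]]:
    """Maximal True-runs of ``eq`` found per window and merged.

    Runs shorter than ``min_len`` markers are pruned early unless they
    touch a window edge (only those can grow by merging with a run from
    the overlapping neighbour window); the caller re-applies the full
    thresholds after merging, so the pruning is lossless.
    """
    runs: list[tuple[int, int]] = []
    for a, b in windows:
        mis = np.flatnonzero(~eq[a:b])
        bounds = np.concatenate(([-1], mis, [b - a]))
        s, e = bounds[:-1] + 1, bounds[1:]
        keep = (e > s) & ((e - s >= min_len) | (s == 0) | (e == b - a))
        for k in np.flatnonzero(keep):
            runs.append((int(s[k]) + a, int(e[k]) + a))
    runs.sort()
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_segments(panel: HaplotypePanel, pair, params: SharingParams | None = None):
    """Shared segments between two samples, all 4 haplotype combinations.

    ``pair`` is a pair of sample ids or integer sample indices. Runs are
    trimmed to their first/last informative marker; thresholds are applied
    after cross-window merging so the windowing is invisible in the output.
    """
    params = params or SharingParams()
    ids = panel.sample_ids
    i, j = (ids.index(p) if isinstance(p, str) else int(p) for p in pair)
    m = panel.markers
    out: list[SharedSegment] = []
    for chrom, idx in m.chromosome_indices().items():
        a, b = int(idx[0]), int(idx[-1]) + 1
        cm = m.cm[a:b]
        bp = m.bp[a:b]
        n = b - a
        windows = ([(0, n)] if params.scan == "genome"
                   else window_partition(n, params))
        for h1 in (0, 1):
            x = panel.haplotypes[2 * i + h1, a:b]
            for h2 in (0, 1):
                y = panel.haplotypes[2 * j + h2, a:b]
                wild = (x == MISSING) | (y == MISSING)
                eq = (x == y) | wild
                for s, e in _match_runs(eq, windows, params.min_markers):
                    info = ~wild[s:e]
                    nz = np.flatnonzero(info)
                    if nz.size == 0:
                        continue
                    s2, e2 = s + int(nz[0]), s + int(nz[-1]) + 1
                    n_info = int(nz.size)
                    cm_len = float(cm[e2 - 1] - cm[s2])
                    if n_info < params.min_markers or cm_len < params.min_cm:
                        continue
                    out.append(SharedSegment(
                        ids[i], ids[j], h1, h2, chrom, s2, e2,
                        int(bp[e2 - 1] - bp[s2] + 1), cm_len, n_info))
    return out


def pair_total(segments, combine: str = "sum") -> int:
    """Total shared bp for one sample pair.

    ``sum`` adds all four haplotype combinations (an unphased diploid
    sharing statistic); ``max`` keeps the best combination only.
    """
    if combine == "sum":
        return int(sum(s.bp_length for s in segments))
    totals: dict[tuple[int, int], int] = {}
    for s in segments:
        totals[(s.hap1, s.hap2)] = totals.get((s.hap1, s.hap2), 0) + s.bp_length
    return int(max(totals.values(), default=0))


def breed_pair_summary(panel: HaplotypePanel, breed_a: str, breed_b: str,
                       params: SharingParams | None = None) -> PairSharingSummary:
    """Median total shared length over all cross-breed sample pairs.

    With ``breed_a == breed_b`` the summary runs in within-breed mode over
    the n(n-1)/2 unordered sample pairs.
    """
    params = params or SharingParams()
    breeds = panel.samples["breed"].to_numpy()
    ia = np.flatnonzero(breeds == breed_a)
    ib = np.flatnonzero(breeds == breed_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both breeds need at least one sample")
    within = breed_a == breed_b
    pairs = ([(int(x), int(y)) for k, x in enumerate(ia) for y in ia[k + 1:]]
             if within else [(int(x), int(y)) for x in ia for y in ib])
    if not pairs:
        raise ValueError(f"within-breed mode needs >= 2 samples of {breed_a!r}")
    totals = np.array([pair_total(detect_segments(panel, p, params), params.combine)
                       for p in pairs], dtype=float)
    return PairSharingSummary(breed_a, breed_b, totals, float(np.median(totals)),
                              len(pairs), within)


def significance_call(summaries, clade_map: dict, percentile: float = 95.0,
                      threshold_basis: str = "pair-medians") -> SignificanceResult:
    """Flag breed pairs whose median sharing exceeds the across-clade
    percentile threshold (linear interpolation between order statistics).

    ``threshold_basis`` selects the across-clade distribution the
    percentile is taken over: ``"pair-medians"`` (default) uses one
    median per across-clade breed pair, which by construction leaves the
    top ~5% of across-clade pairs above the threshold whenever their
    medians differ; ``"pair-totals"`` pools the individual sample-pair
    totals of all across-clade breed pairs, so a breed pair is flagged
    only when its median exceeds the bulk of cross-clade sharing.
    """
    if threshold_basis not in ("pair-medians", "pair-totals"):
        raise ValueError("unknown threshold basis")
    across = []
    clades_seen = set()
    for s in summaries:
        ca, cb = clade_map.get(s.breed_a), clade_map.get(s.breed_b)
        if ca is not None:
            clades_seen.add(ca)
        if cb is not None:
            clades_seen.add(cb)
        if ca is not None and cb is not None and ca != cb:
            across.append(s)
    if not across or len(clades_seen) < 2:
        raise ValueError("no across-clade breed pairs to set the threshold")
    if threshold_basis == "pair-medians":
        pool = [s.median_bp for s in across]
    else:
        pool = np.concatenate([np.asarray(s.totals, dtype=float) for s in across])
    threshold = float(np.percentile(pool, percentile))
    flagged = {s.key: bool(s.median_bp > threshold) for s in summaries}
    return SignificanceResult(threshold, percentile, flagged,
                              [s.key for s in across])
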