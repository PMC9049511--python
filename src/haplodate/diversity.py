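"""Diversity and gene-flow statistics: F, windowed pi, LD-based Ne, D.

* Inbreeding F per sample by the method-of-moments homozygosity excess
  (O - E)/(N - E), with expected homozygosity from cohort allele
  frequencies under the 2n/(2n-1) small-sample correction.
* Nucleotide diversity per 500-kb non-overlapping window: sum of per-SNP
  unbiased heterozygosity divided by the full window span in bp.
* Effective population size from linkage disequilibrium via Sved's
  relation E(r²) = 1/(1 + 4Nc): marker pairs are binned by genetic
  distance c (Morgans), r² of genotype dosages is adjusted by the 1/n
  sampling term, and each bin dates Ne at t = 1/(2c) generations ago.
* ABBA-BABA D-statistic on population allele frequencies, with a
  leave-one-block-out jackknife over contiguous physical blocks for the
  standard error and Z score.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeDataset, HaplotypePanel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Inbreeding
# ---------------------------------------------------------------------------

@dataclass
class InbreedingResult:
    sample_id: str
    breed: str
    observed_hom: int     # O
    expected_hom: float   # E
    n_typed: int          # N
    f: float              # (O - E)/(N - E)


def inbreeding_f(ds: GenotypeDataset, cohort=None):
    """Per-sample F and per-breed mean/min/max.

    ``cohort`` selects the samples whose allele frequencies define the
    expectation (default: all samples). Monomorphic markers are excluded.
    Returns ``(results, breed_summary)`` with the summary as a DataFrame
    (breed, n, mean_f, min_f, max_f).
    """
    g = ds.genotypes
    cohort = np.arange(ds.n_samples) if cohort is None else np.asarray(cohort)
    gc = g[cohort]
    typed_c = gc != MISSING
    n_typed_c = typed_c.sum(axis=0)
    alt = np.where(typed_c, gc, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / (2.0 * n_typed_c)
    poly = (n_typed_c >= 2) & (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers in the cohort")
    p = p[poly]
    a = 2.0 * n_typed_c[poly]                       # typed allele count per marker
    exp_het = 2.0 * p * (1.0 - p) * a / (a - 1.0)   # small-sample corrected

    gp = g[:, poly]
    typed = gp != MISSING
    results = []
    n_undefined = 0
    for i in range(ds.n_samples):
        t = typed[i]
        n = int(t.sum())
        o = int(np.sum((gp[i] == 0) | (gp[i] == 2)))
        e = float(np.sum(1.0 - exp_het[t]))
        if n == 0 or np.isclose(n, e):
            f = float("nan")
            n_undefined += 1
        else:
            f = (o - e) / (n - e)
        results.append(InbreedingResult(ds.sample_ids[i],
                                        ds.samples["breed"].iloc[i], o, e, n, f))
    if n_undefined:
        warnings.warn(f"F undefined for {n_undefined} sample(s) (N = E)",
                      stacklevel=2)
    df = pd.DataFrame([(r.breed, r.f) for r in results], columns=["breed", "f"])
    summary = (df.groupby("breed")["f"]
               .agg(n="count", mean_f="mean", min_f="min", max_f="max")
               .reset_index())
    return results, summary


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

@dataclass
class PiWindow:
    chrom: str
    start_bp: int         # 0-based half-open window on a fixed grid
    end_bp: int
    n_snps: int
    pi: float


def nucleotide_pi(data, window_bp: int = 500_000) -> list[PiWindow]:
    """Per-site nucleotide diversity in non-overlapping windows.

    Accepts a :class:`HaplotypePanel` (allele counts from haplotypes) or a
    :class:`GenotypeDataset` (from dosages). Per SNP,
    pi = (2n/(2n-1)) * 2p(1-p) with 2n the typed allele count; a window's
    pi is the per-SNP sum divided by the full window span in bp, so
    SNP-free stretches dilute diversity exactly as invariant sites do.
    """
    if isinstance(data, HaplotypePanel):
        h = data.haplotypes
        typed = h != MISSING
        a = typed.sum(axis=0).astype(float)
        k = np.where(typed, h, 0).sum(axis=0).astype(float)
        markers = data.markers
    else:
        g = data.genotypes
        typed = g != MISSING
        a = 2.0 * typed.sum(axis=0)
        k = np.where(typed, g, 0).sum(axis=0).astype(float)
        markers = data.markers
    if (a >= 2).sum() == 0:
        raise ValueError("need at least two typed alleles somewhere")
    with np.errstate(invalid="ignore", divide="ignore"):
        pfreq = k / a
        site_pi = np.where(a >= 2, a / (a - 1.0) * 2.0 * pfreq * (1.0 - pfreq), 0.0)
    site_pi = np.nan_to_num(site_pi)

    out = []
    for chrom, idx in markers.chromosome_indices().items():
        bp = markers.bp[idx]
        win = (bp - 1) // window_bp
        for w in range(int(win.max()) + 1):
            sel = idx[win == w]
            out.append(PiWindow(chrom, w * window_bp, (w + 1) * window_bp,
                                int(sel.size),
                                float(site_pi[sel].sum()) / window_bp))
    return out


# ---------------------------------------------------------------------------
# Ne from LD
# ---------------------------------------------------------------------------

@dataclass
class NeEstimate:
    t_generations: int    # 1/(2c), rounded
    c_morgans: float      # mean pair distance in the bin
    mean_r2_adj: float
    ne: float
    n_pairs: int


def ne_point(mean_r2_adj: float, c_morgans: float,
             alpha: float = 1.0) -> tuple[float, int]:
    """Sved inversion for one bin: Ne = (1/(4c)) (1/r²_adj - α), t = 1/(2c).

    ``alpha`` = 1 is the mutation-free drift form; 2.2 is the
    mutation-adjusted variant.
    """
    if mean_r2_adj <= 0:
        raise ValueError("adjusted r² must be positive")
    ne = (1.0 / (4.0 * c_morgans)) * (1.0 / mean_r2_adj - alpha)
    return ne, int(round(1.0 / (2.0 * c_morgans)))


def default_c_bins(t_values=(150, 100, 70, 45, 30, 20, 13)) -> list[tuple[float, float]]:
    """Genetic-distance bins whose centres date the given generations ago
    (t = 1/(2c)); the default spans the 13-150 generation regime."""
    edges = sorted(1.0 / (2.0 * t) for t in t_values)
    return list(zip(edges[:-1], edges[1:]))


def ne_from_ld(ds: GenotypeDataset, c_bins=None, maf: float = 0.05,
               n: int | None = None, min_pairs: int = 30,
               alpha: float = 1.0) -> list[NeEstimate]:
    """LD-decay effective population size per genetic-distance bin.

    r² is the squared correlation of genotype dosages (missing dosages
    mean-imputed), adjusted by the 1/n sampling term. Bins with fewer
    than ``min_pairs`` marker pairs are suppressed with a warning.
    """
    if ds.n_samples < 2:
        raise ValueError("need at least two samples")
    n = ds.n_samples if n is None else n
    c_bins = default_c_bins() if c_bins is None else list(c_bins)
    g = ds.genotypes.astype(float)
    g[ds.genotypes == MISSING] = np.nan
    mean = np.nanmean(g, axis=0)
    pfreq = mean / 2.0
    keep = np.isfinite(pfreq) & (np.minimum(pfreq, 1 - pfreq) >= maf)
    inds = np.where(np.isnan(g), mean[None, :], g)
    std = inds.std(axis=0)
    keep &= std > 0

    sums = np.zeros(len(c_bins))
    csums = np.zeros(len(c_bins))
    counts = np.zeros(len(c_bins), dtype=np.int64)
    for idx in ds.markers.chromosome_indices().values():
        sel = idx[keep[idx]]
        if sel.size < 2:
            continue
        z = (inds[:, sel] - mean[sel]) / std[sel]
        morg = ds.markers.cm[sel] / 100.0
        ns = z.shape[0]
        for bi, (lo, hi) in enumerate(c_bins):
            for i in range(sel.size):
                j0 = np.searchsorted(morg, morg[i] + lo, side="left")
                j1 = np.searchsorted(morg, morg[i] + hi, side="left")
                if j1 <= j0:
                    continue
                r = z[:, i] @ z[:, j0:j1] / ns
                sums[bi] += np.sum(r * r)
                csums[bi] += np.sum(morg[j0:j1] - morg[i])
                counts[bi] += j1 - j0
    out = []
    for bi in range(len(c_bins)):
        if counts[bi] < min_pairs:
            warnings.warn(f"bin {c_bins[bi]}: only {counts[bi]} pairs; "
                          "estimate suppressed", stacklevel=2)
            continue
        cbar = csums[bi] / counts[bi]
        r2_adj = sums[bi] / counts[bi] - 1.0 / n
        if r2_adj <= 0:
            warnings.warn(f"bin {c_bins[bi]}: adjusted r² <= 0; "
                          "estimate suppressed", stacklevel=2)
            continue
        ne, t = ne_point(r2_adj, cbar, alpha)
        out.append(NeEstimate(t, float(cbar), float(r2_adj), float(ne),
                              int(counts[bi])))
    return out


# ---------------------------------------------------------------------------
# D-statistics
# ---------------------------------------------------------------------------

@dataclass
class DStatResult:
    populations: tuple    # (P1, P2, P3, Outgroup)
    abba: float
    baba: float
    d: float
    se: float
    z: float
    n_blocks: int
    n_sites: int


def population_frequencies(ds: GenotypeDataset, breed: str) -> np.ndarray:
    """Per-marker allele2 frequency in one breed (nan where untyped)."""
    idx = np.flatnonzero((ds.samples["breed"] == breed).to_numpy())
    if idx.size == 0:
        raise ValueError(f"no samples of breed {breed!r}")
    g = ds.genotypes[idx]
    typed = g != MISSING
    nt = typed.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(nt > 0, np.where(typed, g, 0).sum(axis=0) / (2.0 * nt),
                        np.nan)


def d_statistic(p1, p2, p3, p4, chrom, bp, block_bp: float = 5e6,
                labels=("P1", "P2", "P3", "O")) -> DStatResult:
    """ABBA-BABA D with block-jackknife standard error.

    Per site, abba = (1-p1) p2 p3 (1-p4) and baba = p1 (1-p2) p3 (1-p4);
    D = Σ(abba-baba) / Σ(abba+baba). The jackknife leaves out contiguous
    ``block_bp`` physical blocks in turn.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    chrom = np.asarray(chrom)
    bp = np.asarray(bp)
    ok = np.isfinite(p1) & np.isfinite(p2) & np.isfinite(p3) & np.isfinite(p4)
    p1, p2, p3, p4, chrom, bp = (a[ok] for a in (p1, p2, p3, p4, chrom, bp))
    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)
    num, den = float(np.sum(abba - baba)), float(np.sum(abba + baba))
    if den == 0:
        warnings.warn("D undefined: no informative sites", stacklevel=2)
        return DStatResult(tuple(labels), 0.0, 0.0, float("nan"), float("nan"),
                           float("nan"), 0, 0)
    d = num / den

    site_block = np.array([f"{c}:{int((b - 1) // block_bp)}"
                           for c, b in zip(chrom, bp)])
    block_ids = pd.unique(site_block)
    d_jack = []
    for blk in block_ids:
        m = site_block != blk
        den_j = float(np.sum(abba[m] + baba[m]))
        if den_j == 0:
            continue
        d_jack.append(float(np.sum(abba[m] - baba[m])) / den_j)
    nb = len(d_jack)
    if nb >= 2:
        d_jack = np.asarray(d_jack)
        se = float(np.sqrt((nb - 1) / nb * np.sum((d_jack - d_jack.mean()) ** 2)))
    else:
        se = float("nan")
    z = d / se if se and np.isfinite(se) and se > 0 else float("nan")
    return DStatResult(tuple(labels), float(np.sum(abba)), float(np.sum(baba)),
                       d, se, z, nb, int(p1.size))
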