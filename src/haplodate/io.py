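"""Genotype dataset containers and PLINK/VCF readers and writers.

The in-memory model mirrors what an array-genotyping study works with: a
marker map (chromosome, bp position, cM position, two alleles), a sample
table (id, breed, clade, region), and a samples x markers matrix of
allele2 dosages in {0, 1, 2} with ``MISSING`` (-1) for no-calls. Phased
data additionally carries two haplotype rows per sample with entries in
{0, 1, MISSING}.

Coordinates are 1-based on disk (PED/MAP and VCF convention); all internal
interval arithmetic is 0-based half-open, converted at the boundary.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype / allele call, distinct from 0/1/2.
MISSING = -1

SAMPLE_COLUMNS = ["sample_id", "breed", "clade", "region"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "1": "1", "2": "2", "0": "0"}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class MarkerMap:
    """Per-marker metadata: positions, genetic map, and the two alleles.

    Within each chromosome, bp positions must be strictly increasing and
    cM positions non-decreasing; every marker is biallelic.
    """

    chrom: np.ndarray       # object/str, per marker
    ids: np.ndarray         # marker ids
    bp: np.ndarray          # int64, 1-based physical position
    cm: np.ndarray          # float64, genetic position in cM
    allele1: np.ndarray     # single-character allele codes
    allele2: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        self.validate()

    def validate(self) -> None:
        n = len(self.ids)
        for name in ("chrom", "bp", "cm", "allele1", "allele2"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"marker field {name!r} has wrong length")
        if np.any(self.bp < 1):
            raise ValueError("bp positions must be >= 1")
        if np.any(self.cm < 0):
            raise ValueError("cM positions must be >= 0")
        for idx in self.chromosome_indices().values():
            if np.any(np.diff(self.bp[idx]) <= 0):
                raise ValueError("bp positions must be strictly increasing per chromosome")
            if np.any(np.diff(self.cm[idx]) < 0):
                raise ValueError("cM positions must be non-decreasing per chromosome")
        same = [i for i in range(n) if self.allele1[i] == self.allele2[i]]
        if same:
            raise ValueError(f"marker {self.ids[same[0]]!r} does not have two distinct alleles")

    @property
    def n_markers(self) -> int:
        return len(self.ids)

    def chromosome_indices(self) -> dict[str, np.ndarray]:
        """Marker index array per chromosome, preserving map order."""
        out: dict[str, np.ndarray] = {}
        for c in pd.unique(self.chrom):
            out[c] = np.flatnonzero(self.chrom == c)
        return out

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        return MarkerMap(self.chrom[idx], self.ids[idx], self.bp[idx],
                         self.cm[idx], self.allele1[idx], self.allele2[idx])


def make_sample_table(sample_ids, breeds, clades=None, regions=None) -> pd.DataFrame:
    n = len(sample_ids)
    df = pd.DataFrame({
        "sample_id": list(sample_ids),
        "breed": list(breeds),
        "clade": list(clades) if clades is not None else [None] * n,
        "region": list(regions) if regions is not None else [None] * n,
    })
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample id {dup!r}")
    return df


@dataclass
class GenotypeDataset:
    """Diploid genotypes: samples x markers matrix of allele2 counts."""

    markers: MarkerMap
    samples: pd.DataFrame          # columns: sample_id, breed, clade, region
    genotypes: np.ndarray          # int8, entries in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if list(self.samples.columns[:4]) != SAMPLE_COLUMNS:
            self.samples = self.samples.reindex(columns=SAMPLE_COLUMNS)
        if self.samples["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids")
        if self.genotypes.shape != (len(self.samples), self.markers.n_markers):
            raise ValueError(
                f"genotype matrix shape {self.genotypes.shape} does not match "
                f"{len(self.samples)} samples x {self.markers.n_markers} markers")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(f"genotype entry {self.genotypes[i, j]} at sample "
                             f"{self.samples['sample_id'].iloc[i]!r}, marker "
                             f"{self.markers.ids[j]!r} is not in {{0,1,2,missing}}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def subset_samples(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return GenotypeDataset(self.markers,
                               self.samples.iloc[idx].reset_index(drop=True),
                               self.genotypes[idx])

    def subset_markers(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return GenotypeDataset(self.markers.subset(idx), self.samples.copy(),
                               self.genotypes[:, idx])


@dataclass
class HaplotypePanel:
    """Phased haplotypes, two rows per sample (rows 2i and 2i+1)."""

    markers: MarkerMap
    samples: pd.DataFrame
    haplotypes: np.ndarray         # int8 (2*n_samples, n_markers), {0,1,MISSING}

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if list(self.samples.columns[:4]) != SAMPLE_COLUMNS:
            self.samples = self.samples.reindex(columns=SAMPLE_COLUMNS)
        if self.haplotypes.shape != (2 * len(self.samples), self.markers.n_markers):
            raise ValueError("haplotype matrix must be 2*n_samples x n_markers")
        if not np.isin(self.haplotypes, (0, 1, MISSING)).all():
            raise ValueError("haplotype entries must be in {0,1,missing}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return self.samples["sample_id"].tolist()

    def sample_haplotypes(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.haplotypes[2 * i], self.haplotypes[2 * i + 1]

    def to_genotypes(self) -> GenotypeDataset:
        """Collapse phase: diploid dosage = sum of the two haplotypes."""
        h0 = self.haplotypes[0::2]
        h1 = self.haplotypes[1::2]
        g = (h0 + h1).astype(np.int8)
        g[(h0 == MISSING) | (h1 == MISSING)] = MISSING
        return GenotypeDataset(self.markers, self.samples.copy(), g)

    def subset_samples(self, idx) -> "HaplotypePanel":
        idx = np.asarray(idx)
        rows = np.empty(2 * len(idx), dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        return HaplotypePanel(self.markers,
                              self.samples.iloc[idx].reset_index(drop=True),
                              self.haplotypes[rows])


# ---------------------------------------------------------------------------
# PED/MAP
# ---------------------------------------------------------------------------

def read_ped_map(ped_path, map_path, sidecar_path=None) -> GenotypeDataset:
    """Read whitespace-delimited PLINK PED + MAP into a :class:`GenotypeDataset`.

    The PED family-id column is taken as the breed code. Allele pairs
    ``0 0`` (and the token ``-9``) are missing. Per marker the two observed
    allele characters are assigned to allele1/allele2 in lexicographic
    order and genotypes recoded to allele2 dosage (markers monomorphic in
    the file load as dosage 0 with a placeholder second allele, since PED
    carries no allele order); a third allele at any marker is a
    :class:`FormatError`. An optional sidecar TSV
    (sample_id, breed, clade, region) supplies clade/region labels.
    """
    map_rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{map_path}: line {lineno}: expected 4 columns")
            map_rows.append((parts[0], parts[1], float(parts[2]), int(parts[3])))
    n_markers = len(map_rows)

    fams, sids = [], []
    geno_rows = []
    allele_sets: list[list[str]] = [[] for _ in range(n_markers)]
    raw_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{ped_path}: line {lineno}: expected {6 + 2 * n_markers} "
                    f"fields, found {len(parts)}")
            fams.append(parts[0])
            sids.append(parts[1])
            raw_rows.append(parts[6:])
            for j in range(n_markers):
                for a in parts[6 + 2 * j: 8 + 2 * j]:
                    if a in ("0", "-9"):
                        continue
                    if a not in allele_sets[j]:
                        allele_sets[j].append(a)
                        if len(allele_sets[j]) > 2:
                            raise FormatError(
                                f"{ped_path}: marker {map_rows[j][1]!r} has more "
                                f"than two alleles: {sorted(allele_sets[j])}")

    a1 = np.empty(n_markers, dtype=object)
    a2 = np.empty(n_markers, dtype=object)
    for j, alleles in enumerate(allele_sets):
        alleles = sorted(alleles)
        if len(alleles) == 0:
            alleles = ["A", "z"]       # fully missing marker: placeholders
        elif len(alleles) == 1:
            # monomorphic: observed allele becomes allele1 (dosage 0),
            # with a placeholder second allele ("z" sorts after ACGT/1/2)
            alleles = [alleles[0], "z"]
        a1[j], a2[j] = alleles

    geno = np.full((len(sids), n_markers), MISSING, dtype=np.int8)
    for i, row in enumerate(raw_rows):
        for j in range(n_markers):
            x, y = row[2 * j], row[2 * j + 1]
            if x in ("0", "-9") or y in ("0", "-9"):
                continue
            geno[i, j] = (x == a2[j]) + (y == a2[j])
    geno_rows = geno

    markers = MarkerMap(
        chrom=[r[0] for r in map_rows],
        ids=[r[1] for r in map_rows],
        bp=[r[3] for r in map_rows],
        cm=[r[2] for r in map_rows],
        allele1=a1, allele2=a2,
    )
    samples = make_sample_table(sids, fams)
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, sep="\t", dtype=str)
        samples = samples.drop(columns=["clade", "region"]).merge(
            side[["sample_id", "clade", "region"]], on="sample_id", how="left")
        samples = samples.reindex(columns=SAMPLE_COLUMNS)
    return GenotypeDataset(markers, samples, geno_rows)


def write_ped_map(ds: GenotypeDataset, ped_path, map_path, sidecar_path=None) -> None:
    """Write PED/MAP (and optionally the clade/region sidecar TSV)."""
    m = ds.markers
    with open(map_path, "w") as fh:
        for j in range(m.n_markers):
            fh.write(f"{m.chrom[j]} {m.ids[j]} {m.cm[j]:g} {m.bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i in range(ds.n_samples):
            row = ds.samples.iloc[i]
            fields = [str(row["breed"]), str(row["sample_id"]), "0", "0", "0", "-9"]
            g = ds.genotypes[i]
            for j in range(m.n_markers):
                if g[j] == MISSING:
                    fields += ["0", "0"]
                else:
                    fields += [str(m.allele2[j]) if k < g[j] else str(m.allele1[j])
                               for k in (0, 1)]
            fh.write(" ".join(fields) + "\n")
    if sidecar_path is not None:
        ds.samples.to_csv(sidecar_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(vcf_path, require_phased: bool = False, sidecar_path=None):
    """Read biallelic SNPs from a VCF (GT field only).

    Returns a :class:`HaplotypePanel` when ``require_phased`` is set (any
    unphased heterozygote raises), else a :class:`GenotypeDataset`.
    Multiallelic records are skipped with a logged warning count. Genetic
    positions are taken from an ``CM`` INFO tag when present, else 0.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sids = list(vcf.samples)
    chroms, ids, bps, cms, a1s, a2s = [], [], [], [], [], []
    hap_cols = []
    geno_cols = []
    n_skipped = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_skipped += 1
            continue
        gts = v.genotypes       # [allele0, allele1, phased] per sample
        hap = np.full(2 * len(sids), MISSING, dtype=np.int8)
        gen = np.full(len(sids), MISSING, dtype=np.int8)
        for i, gt in enumerate(gts):
            al = gt[:-1]
            phased = bool(gt[-1])
            if require_phased and len(al) == 2 and al[0] != al[1] and not phased:
                raise FormatError(
                    f"unphased heterozygote at {v.CHROM}:{v.POS} in sample {sids[i]}")
            if len(al) == 2:
                if al[0] >= 0:
                    hap[2 * i] = al[0]
                if al[1] >= 0:
                    hap[2 * i + 1] = al[1]
                if al[0] >= 0 and al[1] >= 0:
                    gen[i] = al[0] + al[1]
        cm = v.INFO.get("CM", 0.0)
        chroms.append(v.CHROM)
        ids.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        bps.append(v.POS)
        cms.append(float(cm))
        a1s.append(v.REF)
        a2s.append(v.ALT[0])
        hap_cols.append(hap)
        geno_cols.append(gen)
    vcf.close()
    if n_skipped:
        logger.warning("read_vcf: skipped %d multiallelic record(s)", n_skipped)
        warnings.warn(f"skipped {n_skipped} multiallelic record(s)", stacklevel=2)

    markers = MarkerMap(chroms, ids, bps, cms, a1s, a2s)
    samples = make_sample_table(sids, [s.split("_")[0] for s in sids])
    if sidecar_path is not None:
        side = pd.read_csv(sidecar_path, sep="\t", dtype=str)
        samples = samples.drop(columns=["breed", "clade", "region"]).merge(
            side, on="sample_id", how="left").reindex(columns=SAMPLE_COLUMNS)
    if require_phased:
        return HaplotypePanel(markers, samples, np.array(hap_cols, dtype=np.int8).T)
    return GenotypeDataset(markers, samples, np.array(geno_cols, dtype=np.int8).T)


def write_vcf(panel: HaplotypePanel, vcf_path) -> None:
    """Write a phased panel as minimal VCF 4.2 with a CM INFO tag."""
    m = panel.markers
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CM,Number=1,Type=Float,Description="Genetic map position (cM)">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(m.chrom):
            idx = np.flatnonzero(m.chrom == c)
            fh.write(f"##contig=<ID={c},length={int(m.bp[idx].max()) + 1}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        H = panel.haplotypes
        for j in range(m.n_markers):
            ref, alt = m.allele1[j], m.allele2[j]
            if str(ref) not in "ACGT":
                ref, alt = "A", "C"    # numeric allele codes: emit placeholder bases
            gts = []
            for i in range(panel.n_samples):
                a, b = H[2 * i, j], H[2 * i + 1, j]
                gts.append(("." if a == MISSING else str(a)) + "|" +
                           ("." if b == MISSING else str(b)))
            fh.write(f"{m.chrom[j]}\t{m.bp[j]}\t{m.ids[j]}\t{ref}\t{alt}\t.\tPASS\t"
                     f"CM={m.cm[j]:.6g}\tGT\t" + "\t".join(gts) + "\n")


# ---------------------------------------------------------------------------
# Filtering / subsetting / merging
# ---------------------------------------------------------------------------

def call_rate_filter(ds: GenotypeDataset, sample_min: float = 0.9,
                     marker_min: float = 0.9) -> GenotypeDataset:
    """Drop low call-rate samples, then low call-rate markers.

    Samples are filtered first (against the full marker set), then markers
    against the retained samples, mirroring common array-QC practice.
    """
    if not (0 <= sample_min <= 1 and 0 <= marker_min <= 1):
        raise ValueError("call-rate thresholds must be in [0, 1]")
    typed = ds.genotypes != MISSING
    keep_s = np.flatnonzero(typed.mean(axis=1) >= sample_min)
    if len(keep_s) == 0:
        raise ValueError("call_rate_filter removed all samples")
    n_drop_s = ds.n_samples - len(keep_s)
    out = ds.subset_samples(keep_s)
    typed = out.genotypes != MISSING
    keep_m = np.flatnonzero(typed.mean(axis=0) >= marker_min)
    n_drop_m = out.markers.n_markers - len(keep_m)
    out = out.subset_markers(keep_m)
    logger.info("call_rate_filter: removed %d sample(s), then %d marker(s)",
                n_drop_s, n_drop_m)
    return out


def subsample_group(ds: GenotypeDataset, breed: str, k: int, seed: int) -> GenotypeDataset:
    """Keep a seeded random subset of ``k`` samples of one breed (others dropped)."""
    idx = np.flatnonzero((ds.samples["breed"] == breed).to_numpy())
    if len(idx) < k:
        raise ValueError(f"breed {breed!r} has {len(idx)} samples, fewer than k={k}")
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(idx, size=k, replace=False))
    return ds.subset_samples(chosen)


def merge_datasets(a: GenotypeDataset, b: GenotypeDataset) -> GenotypeDataset:
    """Merge two datasets on the intersection of (chromosome, bp) markers.

    Allele encodings are reconciled per marker: same pair (possibly
    swapped) or a strand flip of it; strand-ambiguous A/T and C/G markers
    and irreconcilable markers are dropped with a logged count. Sample
    tables are concatenated; duplicate sample ids are an error.
    """
    ids_a = set(a.samples["sample_id"])
    dup = ids_a.intersection(b.samples["sample_id"])
    if dup:
        raise ValueError(f"duplicate sample ids across datasets: {sorted(dup)[:5]}")

    key_a = {(a.markers.chrom[j], int(a.markers.bp[j])): j
             for j in range(a.markers.n_markers)}
    keep_a, keep_b, flip_b = [], [], []
    n_ambig = n_bad = 0
    for jb in range(b.markers.n_markers):
        key = (b.markers.chrom[jb], int(b.markers.bp[jb]))
        if key not in key_a:
            continue
        ja = key_a[key]
        pa = (str(a.markers.allele1[ja]), str(a.markers.allele2[ja]))
        pb = (str(b.markers.allele1[jb]), str(b.markers.allele2[jb]))
        if frozenset(pa) in ({"A", "T"}, {"C", "G"}):
            n_ambig += 1
            continue
        flip = None
        if pb == pa:
            flip = False
        elif pb == pa[::-1]:
            flip = True
        else:
            pc = (_COMPLEMENT.get(pb[0]), _COMPLEMENT.get(pb[1]))
            if pc == pa:
                flip = False
            elif pc == pa[::-1]:
                flip = True
        if flip is None:
            n_bad += 1
            continue
        keep_a.append(ja)
        keep_b.append(jb)
        flip_b.append(flip)
    if n_ambig or n_bad:
        logger.warning("merge_datasets: dropped %d strand-ambiguous and %d "
                       "irreconcilable marker(s)", n_ambig, n_bad)
        warnings.warn(f"merge dropped {n_ambig} ambiguous + {n_bad} "
                      f"irreconcilable marker(s)", stacklevel=2)

    order = np.argsort(keep_a, kind="stable")
    keep_a = np.asarray(keep_a, dtype=np.int64)[order]
    keep_b = np.asarray(keep_b, dtype=np.int64)[order]
    flip_b = np.asarray(flip_b, dtype=bool)[order]

    ga = a.genotypes[:, keep_a]
    gb = b.genotypes[:, keep_b].copy()
    if flip_b.any():
        cols = gb[:, flip_b]
        typed = cols != MISSING
        cols[typed] = 2 - cols[typed]
        gb[:, flip_b] = cols
    samples = pd.concat([a.samples, b.samples], ignore_index=True)
    return GenotypeDataset(a.markers.subset(keep_a), samples,
                           np.vstack([ga, gb]))
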