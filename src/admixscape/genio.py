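"""Genotype and metadata I/O plus the SNP/sample filter cascade.

The central container is :class:`GenotypeMatrix`: an N×L matrix of diploid
genotype codes (0/1/2 copies of the alternate allele, ``-1`` for missing)
with a sample registry and a locus table.  Reduced-representation (RAD-type)
datasets are ingested from VCF; sample coordinates, sex and age class from a
TSV.  The filter cascade mirrors standard practice for such data: per-site
missingness, minor-allele count, an excess-heterozygosity paralog screen,
per-sample completeness, and thinning to one SNP per locus.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "SampleMetadata",
    "FilterReport",
    "read_vcf",
    "write_vcf",
    "read_metadata",
    "write_metadata",
    "intersect_samples",
    "filter_sites",
    "filter_samples",
    "thin_one_snp_per_locus",
    "select_geolocation_panel",
    "read_qmatrix",
    "write_qmatrix",
    "lonlat_to_km",
]

logger = logging.getLogger(__name__)

#: Genotype code for a missing call.
MISSING: int = -1

SEX_VALUES = ("M", "F", "unknown")
AGE_CLASSES = ("Y0-1", "Y1-1.5", "Y2-2.5", "Y3-4.5", "Y5+", "unknown")


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class GenotypeMatrix:
    """N×L diploid genotype codes with sample and locus registries.

    ``genotypes[i, j]`` counts alternate-allele copies for sample ``i`` at
    site ``j`` (0, 1, 2) with :data:`MISSING` (-1) for no-calls.  ``loci`` is
    a DataFrame with columns ``tag`` (locus label, e.g. the RAD locus), ``pos``,
    ``ref`` and ``alt``.
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    loci: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (samples × sites)")
        n, l = self.genotypes.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.loci) != l:
            raise ValueError(f"{len(self.loci)} locus records for {l} columns")
        if len(set(self.sample_ids)) != n:
            raise ValueError("sample ids must be unique")
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype codes must be in {0, 1, 2, -1}")
        self.loci = self.loci.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    @property
    def observed(self) -> np.ndarray:
        """Boolean N×L mask of non-missing calls."""
        return self.genotypes != MISSING

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[:, idx], list(self.sample_ids), self.loci.iloc[idx]
        )

    def take_samples(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            self.genotypes[idx], [self.sample_ids[i] for i in idx], self.loci
        )

    def alt_freqs(self) -> np.ndarray:
        """Per-site alternate-allele frequency over observed alleles (NaN if none)."""
        obs = self.observed
        g = np.where(obs, self.genotypes, 0)
        n_alleles = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, g.sum(axis=0) / n_alleles, np.nan)

    def minor_allele_counts(self) -> np.ndarray:
        obs = self.observed
        g = np.where(obs, self.genotypes, 0)
        alt = g.sum(axis=0)
        total = 2 * obs.sum(axis=0)
        return np.minimum(alt, total - alt)


@dataclass
class SampleMetadata:
    """Per-sample coordinates (planar km), sex, age class and status."""

    table: pd.DataFrame

    REQUIRED = ("id", "x", "y")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise FormatError(f"metadata missing required column {col!r}")
        if t["id"].duplicated().any():
            dups = t.loc[t["id"].duplicated(), "id"].tolist()
            raise FormatError(f"duplicate sample id(s): {dups}")
        for col in ("x", "y"):
            if not np.issubdtype(t[col].dtype, np.number):
                bad = t.index[pd.to_numeric(t[col], errors="coerce").isna()].tolist()
                raise FormatError(f"non-numeric {col!r} in row(s) {bad}")
        for col, allowed in (("sex", SEX_VALUES), ("age_class", AGE_CLASSES)):
            if col not in t.columns:
                t[col] = "unknown"
            t[col] = t[col].fillna("unknown").replace("", "unknown")
            bad = set(t[col]) - set(allowed)
            if bad:
                raise FormatError(f"unrecognized {col} value(s): {sorted(bad)}")
        if "status" not in t.columns:
            t["status"] = ""
        self.table = t.reset_index(drop=True)

    @property
    def ids(self) -> list[str]:
        return self.table["id"].tolist()

    def coords(self, sample_ids: list[str] | None = None) -> np.ndarray:
        """(n, 2) array of x/y in km, optionally ordered by ``sample_ids``."""
        t = self.table.set_index("id")
        if sample_ids is not None:
            t = t.loc[sample_ids]
        return t[["x", "y"]].to_numpy(dtype=float)


@dataclass
class FilterReport:
    """Per-rule removal counts for one pass of the filter cascade."""

    n_in: int
    n_out: int
    removed: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:
        rules = ", ".join(f"{k}={v}" for k, v in self.removed.items())
        return f"{self.n_in} -> {self.n_out} ({rules})"


# ---------------------------------------------------------------------------
# VCF and TSV I/O


def read_vcf(path: str) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records and indels are skipped (a count is logged); the
    locus tag is taken from CHROM, so RAD-style VCFs with one "chromosome"
    per locus group naturally.  Phasing is ignored; ``./.`` becomes missing.
    """
    vcf = VCF(path, gts012=True)
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    loci: list[tuple[str, int, str, str]] = []
    n_skipped = 0
    for rec in vcf:
        if len(rec.ALT) != 1 or not rec.is_snp:
            n_skipped += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = unknown
        g = np.asarray(rec.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        rows.append(g)
        loci.append((rec.CHROM, rec.POS, rec.REF, rec.ALT[0]))
    vcf.close()
    if n_skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", n_skipped)
    genotypes = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((len(sample_ids), 0), dtype=np.int8)
    )
    table = pd.DataFrame(loci, columns=["tag", "pos", "ref", "alt"])
    gm = GenotypeMatrix(genotypes, sample_ids, table)
    gm.n_skipped_records = n_skipped  # type: ignore[attr-defined]
    return gm


def write_vcf(gm: GenotypeMatrix, path: str) -> None:
    """Write a minimal VCF v4.2 with GT-only FORMAT."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for tag in gm.loci["tag"].unique():
            fh.write(f"##contig=<ID={tag}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j, locus in gm.loci.iterrows():
            calls = "\t".join(code[int(g)] for g in gm.genotypes[:, j])
            fh.write(
                f"{locus.tag}\t{int(locus.pos)}\t{locus.tag}_pos{int(locus.pos)}\t"
                f"{locus.ref}\t{locus.alt}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_metadata(path: str) -> SampleMetadata:
    """Read the sample metadata TSV (id, x, y, sex, age_class, status)."""
    table = pd.read_csv(path, sep="\t", dtype={"id": str})
    return SampleMetadata(table)


def write_metadata(md: SampleMetadata, path: str) -> None:
    md.table.to_csv(path, sep="\t", index=False)


def intersect_samples(
    gm: GenotypeMatrix, md: SampleMetadata
) -> tuple[GenotypeMatrix, SampleMetadata]:
    """Restrict both containers to their shared samples, in genotype order.

    Mismatches on either side are reported via the logger rather than
    silently dropped.
    """
    shared = [s for s in gm.sample_ids if s in set(md.ids)]
    geno_only = sorted(set(gm.sample_ids) - set(shared))
    meta_only = sorted(set(md.ids) - set(shared))
    if geno_only:
        logger.warning("samples with genotypes but no metadata: %s", geno_only)
    if meta_only:
        logger.warning("samples with metadata but no genotypes: %s", meta_only)
    idx = [gm.sample_ids.index(s) for s in shared]
    sub = md.table.set_index("id").loc[shared].reset_index()
    return gm.take_samples(np.array(idx, dtype=int)), SampleMetadata(sub)


# ---------------------------------------------------------------------------
# Filter cascade


def filter_sites(
    gm: GenotypeMatrix,
    min_mac: int = 2,
    max_site_missing: float = 0.5,
    max_het: float = 0.70,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove sites by missingness, minor-allele count, and excess heterozygosity.

    Rules are applied in a fixed order (missingness → MAC → heterozygosity)
    and each site is charged to the first rule it fails, so the per-rule
    counts in the report sum to the total removed.  MAC is computed over
    observed alleles only; the heterozygosity screen (fraction of observed
    genotypes that are heterozygous at a polymorphic site exceeding
    ``max_het``) flags likely collapsed paralogs.
    """
    if not (0 <= max_site_missing <= 1 and 0 <= max_het <= 1 and min_mac >= 0):
        raise ValueError("filter thresholds out of range")
    obs = gm.observed
    n_obs = obs.sum(axis=0)
    miss_frac = 1.0 - n_obs / gm.n_samples
    fail_miss = miss_frac > max_site_missing

    mac = gm.minor_allele_counts()
    fail_mac = (mac < min_mac) & ~fail_miss

    with np.errstate(invalid="ignore", divide="ignore"):
        het_frac = np.where(
            n_obs > 0, (gm.genotypes == 1).sum(axis=0) / np.maximum(n_obs, 1), 0.0
        )
    polymorphic = mac > 0
    fail_het = (het_frac > max_het) & polymorphic & ~fail_miss & ~fail_mac

    keep = ~(fail_miss | fail_mac | fail_het)
    report = FilterReport(
        n_in=gm.n_sites,
        n_out=int(keep.sum()),
        removed={
            "site_missingness": int(fail_miss.sum()),
            "mac": int(fail_mac.sum()),
            "excess_het": int(fail_het.sum()),
        },
    )
    if report.n_out == 0:
        logger.warning("filter_sites removed every site")
    return gm.take_sites(np.flatnonzero(keep)), report


def filter_samples(
    gm: GenotypeMatrix, min_completeness: float = 0.5
) -> tuple[GenotypeMatrix, FilterReport]:
    """Remove samples whose fraction of non-missing sites is below threshold."""
    if not 0 <= min_completeness <= 1:
        raise ValueError("min_completeness out of range")
    if gm.n_sites == 0:
        return gm, FilterReport(gm.n_samples, gm.n_samples, {"completeness": 0})
    completeness = gm.observed.sum(axis=1) / gm.n_sites
    keep = completeness >= min_completeness
    report = FilterReport(
        n_in=gm.n_samples,
        n_out=int(keep.sum()),
        removed={"completeness": int((~keep).sum())},
    )
    if report.n_out == 0:
        logger.warning("filter_samples removed every sample")
    return gm.take_samples(np.flatnonzero(keep)), report


def thin_one_snp_per_locus(
    gm: GenotypeMatrix, rule: str = "first", seed: int | None = None
) -> GenotypeMatrix:
    """Keep exactly one SNP per locus tag.

    ``rule='first'`` keeps the lowest position in each tag group;
    ``rule='random'`` draws one uniformly (seeded).  Mitigates
    non-independence of SNPs on the same RAD locus.
    """
    if rule not in ("first", "random"):
        raise ValueError("rule must be 'first' or 'random'")
    tags = gm.loci["tag"]
    if tags.isna().any() or (tags == "").any():
        raise FormatError(
            "loci lack tags; populate the 'tag' column (e.g. from CHROM) first"
        )
    rng = np.random.default_rng(seed)
    keep: list[int] = []
    order = gm.loci.sort_values(["tag", "pos"], kind="stable")
    for _, grp in order.groupby("tag", sort=True):
        if rule == "first":
            keep.append(int(grp.index[0]))
        else:
            keep.append(int(rng.choice(grp.index.to_numpy())))
    return gm.take_sites(np.sort(np.array(keep, dtype=int)))


def select_geolocation_panel(
    gm: GenotypeMatrix, min_maf: float = 0.10, n: int = 5000, seed: int | None = None
) -> GenotypeMatrix:
    """Seeded subsample of ``n`` sites with minor-allele frequency above ``min_maf``.

    Common variants carry most of the spatial assignment signal; if fewer
    than ``n`` qualify, all are returned (logged).
    """
    freqs = gm.alt_freqs()
    with np.errstate(invalid="ignore"):
        maf = np.fmin(freqs, 1.0 - freqs)
    qualifying = np.flatnonzero(maf > min_maf)
    if len(qualifying) <= n:
        if len(qualifying) < n:
            logger.info(
                "select_geolocation_panel: only %d sites exceed MAF %.2f (requested %d)",
                len(qualifying), min_maf, n,
            )
        return gm.take_sites(qualifying)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(qualifying, size=n, replace=False)
    return gm.take_sites(np.sort(chosen))


# ---------------------------------------------------------------------------
# Q-matrix dialect and coordinate helper


def read_qmatrix(path: str) -> np.ndarray:
    """Read a whitespace-delimited Q matrix (one row per individual, K columns)."""
    q = np.loadtxt(path, ndmin=2)
    if q.ndim != 2 or np.any(q < -1e-9) or np.any(np.abs(q.sum(axis=1) - 1) > 1e-3):
        raise FormatError("not a Q matrix: rows must be simplex vectors")
    return q


def write_qmatrix(q: np.ndarray, path: str) -> None:
    np.savetxt(path, np.asarray(q, dtype=float), fmt="%.6f")


def lonlat_to_km(
    lon: np.ndarray, lat: np.ndarray, lon0: float | None = None, lat0: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Project lon/lat (degrees) to planar km by a local equirectangular map.

    Adequate for study extents up to a few hundred km (distance error below
    ~0.5% at 45° latitude over a 300 km span); for larger extents use a
    proper projected CRS upstream.
    """
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    lon0 = float(np.mean(lon)) if lon0 is None else lon0
    lat0 = float(np.mean(lat)) if lat0 is None else lat0
    r_earth = 6371.0088
    x = np.radians(lon - lon0) * r_earth * math.cos(math.radians(lat0))
    y = np.radians(lat - lat0) * r_earth
    return x, y
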