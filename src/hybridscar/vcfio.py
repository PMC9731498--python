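"""Multi-sample VCF and strain-catalog I/O, plus catalog rediscovery.

Reading goes through cyvcf2; only biallelic SNVs with per-sample allele
depths (FORMAT/AD) are retained, mirroring the upstream variant-calling
filter.  Writing emits plain VCF 4.2 text that round-trips losslessly
through the reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .cross import ADMatrix, StrainCatalog

logger = logging.getLogger(__name__)

_SNV_BASES = {"A", "C", "G", "T"}


class VcfFormatError(ValueError):
    """Raised when a VCF lacks the fields this pipeline requires."""


def write_vcf(ad: ADMatrix, path, contig_lengths: dict[str, int] | None = None) -> None:
    """Write an ADMatrix as a multi-sample VCF 4.2 with FORMAT AD and DP."""
    sites = ad.sites
    chroms = list(dict.fromkeys(sites["chrom"]))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in chroms:
            if contig_lengths and chrom in contig_lengths:
                fh.write(f"##contig=<ID={chrom},length={contig_lengths[chrom]}>\n")
            else:
                fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                 'Description="Allelic depths for the ref and alt alleles">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ad.samples) + "\n")
        alt = ad.alt_count
        dp = ad.total_depth
        for i, row in enumerate(sites.itertuples(index=False)):
            cells = "\t".join(
                f"{dp[i, j] - alt[i, j]},{alt[i, j]}:{dp[i, j]}"
                for j in range(len(ad.samples)))
            fh.write(f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t.\t.\t"
                     f"AD:DP\t{cells}\n")


def read_vcf(path, region: str | None = None) -> tuple[ADMatrix, int]:
    """Read a multi-sample VCF into an ADMatrix.

    Multi-allelic and non-SNV records are dropped (the count of dropped
    records is returned and logged); a sample with missing AD is recorded
    as depth 0.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if "AD" not in {f["ID"] for f in vcf.header_iter() if f.type == "FORMAT"}:
        raise VcfFormatError(f"{path}: no FORMAT/AD field; allele depths required")
    rows, alts, dps = [], [], []
    n_dropped = 0
    records = vcf(region) if region else vcf
    for v in records:
        if len(v.ALT) != 1 or len(v.REF) != 1 or v.REF not in _SNV_BASES \
                or v.ALT[0] not in _SNV_BASES:
            n_dropped += 1
            continue
        ad = v.format("AD")
        if ad is None:
            alt_counts = np.zeros(len(samples), dtype=np.int64)
            depths = np.zeros(len(samples), dtype=np.int64)
        else:
            ad = np.asarray(ad, dtype=np.int64)
            ad[ad < 0] = 0  # cyvcf2 encodes missing as negative sentinels
            alt_counts = ad[:, 1]
            depths = ad.sum(axis=1)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0]))
        alts.append(alt_counts)
        dps.append(depths)
    if n_dropped:
        logger.info("read_vcf(%s): dropped %d non-biallelic-SNV records", path, n_dropped)
    sites = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt"])
    shape = (len(rows), len(samples))
    ad_mat = ADMatrix(sites, samples,
                      np.array(alts, dtype=np.int64).reshape(shape),
                      np.array(dps, dtype=np.int64).reshape(shape))
    return ad_mat, n_dropped


# ---------------------------------------------------------------------------
# catalog matching


@dataclass
class CatalogMatchReport:
    """Rediscovery of known strain-informative variants among called sites."""

    n_catalog: int
    n_rediscovered: int
    #: per-called-site flag: True where (chrom, pos, ref, alt) is in the catalog
    in_catalog: np.ndarray

    @property
    def rediscovery_rate(self) -> float:
        return self.n_rediscovered / self.n_catalog


def _check_sorted(df: pd.DataFrame, what: str) -> None:
    for chrom, grp in df.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"{what} must be sorted by (chrom, pos) for merge-join matching")


def match_catalog(sites: pd.DataFrame, catalog: StrainCatalog) -> CatalogMatchReport:
    """Match called sites against the known-strain catalog.

    A catalog variant is rediscovered iff a called site matches it on
    chrom, pos, ref and alt exactly — allele identity, not just position,
    since the catalog's role is strain-informative genotypes.  Both inputs
    must be position-sorted per chromosome.
    """
    if len(catalog) == 0:
        raise ValueError("empty catalog: rediscovery rate undefined")
    _check_sorted(sites, "called sites")
    _check_sorted(catalog.sites, "catalog")
    keys = ["chrom", "pos", "ref", "alt"]
    called = set(map(tuple, sites[keys].itertuples(index=False)))
    cat = set(map(tuple, catalog.sites[keys].itertuples(index=False)))
    in_catalog = np.fromiter(
        (tuple(r) in cat for r in sites[keys].itertuples(index=False)),
        dtype=bool, count=len(sites))
    n_re = sum(1 for r in cat if r in called)
    return CatalogMatchReport(len(catalog), n_re, in_catalog)
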