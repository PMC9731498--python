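"""Germline/somatic variant triage from cross-sample VAF ranking.

The rule operates on one site's variant allele fractions across all
embryos: let v1 >= v2 be the two largest VAFs.  If v1 <= 0.05 the site
is excluded (too little evidence anywhere); if v2 exceeds 40% of v1 the
variant is shared across embryos and is germline or a recurrent artifact;
otherwise it is private to one embryo and called somatic.  A follow-up
pass removes genomic clusters of "somatic" calls that all sit in the same
single embryo — such runs are almost always residual germline haplotype
blocks rather than independent somatic hits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cross import ADMatrix

EXCLUDED = "EXCLUDED"
GERMLINE_OR_FALSE = "GERMLINE_OR_FALSE"
SOMATIC = "SOMATIC"
CLUSTER_REMOVED = "CLUSTER_REMOVED"
LABELS = (EXCLUDED, GERMLINE_OR_FALSE, SOMATIC, CLUSTER_REMOVED)


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the triage rule.

    ``vaf_min`` and ``second_to_max_ratio`` are the published rule's
    boundaries ("above 0.05" and "more than 40%", both strict, applied
    literally).  The cluster parameters formalize the manual removal of
    single-embryo germline clusters as a windowed same-carrier run rule.
    """

    vaf_min: float = 0.05
    second_to_max_ratio: float = 0.40
    cluster_window_bp: int = 1_000_000
    cluster_min_count: int = 3

    def __post_init__(self):
        if not 0 < self.vaf_min < 1:
            raise ValueError("vaf_min must be in (0, 1)")
        if not 0 < self.second_to_max_ratio < 1:
            raise ValueError("second_to_max_ratio must be in (0, 1)")
        if self.cluster_window_bp <= 0:
            raise ValueError("cluster_window_bp must be > 0")
        if self.cluster_min_count < 2:
            raise ValueError("cluster_min_count must be >= 2")


def vaf_matrix(ad: ADMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Sites x samples VAFs and a mask of missing (zero-depth) cells.

    Zero-depth cells contribute VAF 0 to the ranking: the rule is stated
    purely on VAFs and absence of reads is treated as absence of the allele.
    """
    return ad.vaf(), ad.total_depth == 0


def classify_site(vafs: np.ndarray, cfg: ClassifierConfig = ClassifierConfig()) -> str:
    """Label one site from its VAFs across embryos (EXCLUDED / GERMLINE_OR_FALSE
    / SOMATIC).  Requires at least two samples; with one the rule is undefined."""
    vafs = np.asarray(vafs, dtype=float)
    if vafs.size < 2:
        raise ValueError("classify_site needs VAFs from at least 2 samples")
    v1, v2 = np.sort(vafs)[-2:][::-1]
    if v1 <= cfg.vaf_min:
        return EXCLUDED
    if v2 > cfg.second_to_max_ratio * v1:
        return GERMLINE_OR_FALSE
    return SOMATIC


def _classify_bulk(vaf: np.ndarray, cfg: ClassifierConfig) -> np.ndarray:
    """Vectorized version of classify_site over a sites x samples matrix."""
    part = np.partition(vaf, vaf.shape[1] - 2, axis=1)
    v1 = part[:, -1]
    v2 = part[:, -2]
    labels = np.full(vaf.shape[0], SOMATIC, dtype=object)
    labels[v2 > cfg.second_to_max_ratio * v1] = GERMLINE_OR_FALSE
    labels[v1 <= cfg.vaf_min] = EXCLUDED
    return labels


def remove_single_embryo_clusters(table: pd.DataFrame,
                                  cfg: ClassifierConfig = ClassifierConfig()
                                  ) -> pd.DataFrame:
    """Relabel clustered single-embryo somatic calls as CLUSTER_REMOVED.

    ``table`` must hold chrom, pos, label and carrier (the sample with the
    highest VAF, or None on a tie) sorted by (chrom, pos).  Within any
    window of ``cluster_window_bp``, if at least ``cluster_min_count``
    somatic sites share the same single carrier, every somatic site of that
    carrier inside the window is relabeled.  Tied-carrier sites are not
    "in only one embryo" and are never removed.
    """
    out = table.copy()
    somatic = out[(out["label"] == SOMATIC) & out["carrier"].notna()]
    for (chrom, carrier), grp in somatic.groupby(["chrom", "carrier"], sort=False):
        pos = grp["pos"].to_numpy()
        idx = grp.index.to_numpy()
        mark = np.zeros(len(pos), dtype=bool)
        j = 0
        for i in range(len(pos)):
            if j < i:
                j = i
            while j + 1 < len(pos) and pos[j + 1] - pos[i] <= cfg.cluster_window_bp:
                j += 1
            if j - i + 1 >= cfg.cluster_min_count:
                mark[i:j + 1] = True
        out.loc[idx[mark], "label"] = CLUSTER_REMOVED
    return out


def classify_all(ad: ADMatrix, cfg: ClassifierConfig = ClassifierConfig(),
                 catalog_flags: np.ndarray | None = None
                 ) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify every site of an ADMatrix and summarize label counts.

    Sites flagged as members of the known-strain catalog are pre-labeled
    GERMLINE_OR_FALSE and bypass the VAF rule.  Remaining sites get the
    two-top-VAF rule, then the single-embryo cluster filter.  Returns the
    per-site table (chrom, pos, ref, alt, label, v1, v2, carrier) and a
    counts-per-label summary.
    """
    if len(ad.samples) < 2:
        raise ValueError("classification requires at least 2 samples")
    vaf, _ = vaf_matrix(ad)
    table = ad.sites.copy()
    if len(table) == 0:
        return table.assign(label=[], v1=[], v2=[], carrier=[]), dict.fromkeys(LABELS, 0)
    part = np.sort(vaf, axis=1)
    table["v1"] = part[:, -1]
    table["v2"] = part[:, -2]
    top_hits = vaf == part[:, -1:]
    tied = top_hits.sum(axis=1) > 1
    carrier_idx = np.argmax(vaf, axis=1)
    sample_arr = np.array(ad.samples, dtype=object)
    table["carrier"] = sample_arr[carrier_idx]
    table.loc[tied, "carrier"] = None
    table["label"] = _classify_bulk(vaf, cfg)
    if catalog_flags is not None:
        table.loc[np.asarray(catalog_flags, bool), "label"] = GERMLINE_OR_FALSE
    table = remove_single_embryo_clusters(table, cfg)
    summary = {lab: int((table["label"] == lab).sum()) for lab in LABELS}
    return table, summary
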