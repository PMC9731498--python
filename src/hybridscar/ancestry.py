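"""Strain-origin state segmentation and allelic-imbalance scoring.

At catalog sites the VAF of a euploid embryo reads out local ancestry:
~0 in homozygous-reference segments, ~0.5 in heterozygous segments, ~1 in
homozygous-alternate segments.  A three-state model with binomial
emissions and distance-scaled switch probabilities segments each
chromosome into these states; genomic instability is then quantified as
the deviation of heterozygous-site VAFs from 0.5 (copy-neutral LOH and
aneuploidy push them toward 0 or 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

HOM_REF = "HOM_REF"
HET = "HET"
HOM_ALT = "HOM_ALT"
STATES = (HOM_REF, HET, HOM_ALT)


@dataclass(frozen=True)
class StateModel:
    """Three ancestry states with binomial read emissions.

    ``error_rate`` is the expected VAF in a homozygous-reference segment
    (and 1 - error_rate in homozygous-alternate); heterozygous segments
    emit at 0.5.  ``switch_rate`` is the per-base probability of a state
    change; over a gap of g bases the switch probability is 1-(1-t)^g.
    """

    error_rate: float = 0.005
    switch_rate: float = 1e-7

    def __post_init__(self):
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        if not 0 < self.switch_rate < 1:
            raise ValueError("switch_rate must be in (0, 1)")

    @property
    def emission_p(self) -> np.ndarray:
        return np.array([self.error_rate, 0.5, 1.0 - self.error_rate])


@dataclass
class StateTrack:
    """Per-site ancestry states and derived per-chromosome segments."""

    #: chrom, pos, state for every covered catalog site (site order preserved)
    site_states: pd.DataFrame
    #: chrom, start, end, state half-open segments tiling the covered span
    segments: pd.DataFrame


def _viterbi_path(alt: np.ndarray, depth: np.ndarray, pos: np.ndarray,
                  model: StateModel) -> np.ndarray:
    """Most probable state path for one chromosome (log-space DP)."""
    n = len(pos)
    emis = np.stack([binom.logpmf(alt, depth, p) for p in model.emission_p], axis=1)
    score = emis[0].copy()
    back = np.zeros((n, 3), dtype=np.int8)
    log1m_t = np.log1p(-model.switch_rate)
    for i in range(1, n):
        gap = max(int(pos[i] - pos[i - 1]), 1)
        p_switch = -np.expm1(gap * log1m_t)
        p_switch = min(max(p_switch, 1e-300), 1 - 1e-12)
        trans = np.full((3, 3), np.log(p_switch / 2.0))
        np.fill_diagonal(trans, np.log1p(-p_switch))
        cand = score[:, None] + trans
        back[i] = np.argmax(cand, axis=0)
        score = cand[back[i], np.arange(3)] + emis[i]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = int(np.argmax(score))
    for i in range(n - 1, 0, -1):
        path[i - 1] = back[i, path[i]]
    return path


def assign_states(sites: pd.DataFrame, alt: np.ndarray, depth: np.ndarray,
                  model: StateModel = StateModel()) -> StateTrack:
    """Segment one sample's catalog sites into ancestry states.

    ``sites`` holds chrom and pos (sorted per chromosome); ``alt`` and
    ``depth`` are that sample's allele counts at those sites.  Sites with
    zero depth are uncovered and excluded.  Segment boundaries are placed
    midway between adjacent differing-state sites.
    """
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    covered = depth > 0
    state_rows = []
    seg_rows = []
    for chrom, grp in sites.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        m = covered[idx]
        if m.sum() == 0:
            warnings.warn(f"{chrom}: no covered catalog sites; skipped")
            continue
        pos = grp["pos"].to_numpy()[m]
        a = alt[idx][m]
        d = depth[idx][m]
        if len(pos) < 2:
            warnings.warn(f"{chrom}: fewer than 2 covered catalog sites; "
                          "single-site states, no segments")
            p = a[0] / d[0]
            st = HOM_REF if p < 0.25 else (HET if p < 0.75 else HOM_ALT)
            state_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "state": [st]}))
            continue
        path = _viterbi_path(a, d, pos, model)
        states = np.array(STATES, dtype=object)[path]
        state_rows.append(pd.DataFrame({"chrom": chrom, "pos": pos, "state": states}))
        change = np.flatnonzero(path[1:] != path[:-1])
        bounds = [(int(pos[i]) + int(pos[i + 1])) // 2 + 1 for i in change]
        edges = [int(pos[0])] + bounds + [int(pos[-1]) + 1]
        seg_states = states[np.concatenate(([0], change + 1))]
        for (s, e), st in zip(zip(edges[:-1], edges[1:]), seg_states):
            seg_rows.append((chrom, s, e, st))
    site_states = (pd.concat(state_rows, ignore_index=True) if state_rows
                   else pd.DataFrame(columns=["chrom", "pos", "state"]))
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start", "end", "state"])
    return StateTrack(site_states, segments)


@dataclass
class InstabilityReport:
    """Allelic-imbalance summary over heterozygous-assigned catalog sites.

    ``mad_score`` is the mean absolute deviation of VAF from 0.5 (0 for a
    perfectly balanced diploid, 0.5 at full LOH); ``outlier_fraction`` is
    the share of sites with VAF outside [0.5 - delta, 0.5 + delta].  Both
    are None when no site qualifies.
    """

    sample: str
    n_het_sites: int
    mad_score: float | None
    outlier_fraction: float | None
    per_chromosome: pd.DataFrame


def instability_score(track: StateTrack, sites: pd.DataFrame, alt: np.ndarray,
                      depth: np.ndarray, sample: str = "",
                      min_depth: int = 10, delta: float = 0.15) -> InstabilityReport:
    """Score one sample's deviation from balanced heterozygosity.

    Only catalog sites the state model assigned HET and with depth >=
    ``min_depth`` enter the score; below that, binomial sampling noise
    swamps the imbalance signal.
    """
    if min_depth < 1:
        raise ValueError("min_depth must be >= 1")
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    merged = sites[["chrom", "pos"]].copy()
    merged["alt"] = alt
    merged["depth"] = depth
    het = track.site_states[track.site_states["state"] == HET]
    merged = merged.merge(het[["chrom", "pos"]], on=["chrom", "pos"], how="inner")
    merged = merged[merged["depth"] >= min_depth]
    if len(merged) == 0:
        warnings.warn(f"sample {sample}: no qualifying heterozygous sites; "
                      "instability score undefined")
        return InstabilityReport(sample, 0, None, None,
                                 pd.DataFrame(columns=["chrom", "n_sites",
                                                       "mad_score", "outlier_fraction"]))
    vaf = merged["alt"] / merged["depth"]
    dev = (vaf - 0.5).abs()
    merged = merged.assign(dev=dev, outlier=dev > delta)
    per_chrom = (merged.groupby("chrom", sort=False)
                 .agg(n_sites=("dev", "size"), mad_score=("dev", "mean"),
                      outlier_fraction=("outlier", "mean"))
                 .reset_index())
    return InstabilityReport(sample, len(merged), float(dev.mean()),
                             float(merged["outlier"].mean()), per_chrom)


def vaf_density(vafs: np.ndarray, n_bins: int = 50) -> tuple[np.ndarray, np.ndarray]:
    """Normalized VAF histogram density on [0, 1]: (bin_edges, densities)."""
    vafs = np.asarray(vafs, dtype=float)
    if vafs.size == 0:
        raise ValueError("vaf_density needs at least one value")
    if ((vafs < 0) | (vafs > 1)).any():
        raise ValueError("VAFs must lie in [0, 1]")
    dens, edges = np.histogram(vafs, bins=n_bins, range=(0.0, 1.0), density=True)
    return edges, dens
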