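"""Synthetic F2 inter-strain cross simulator.

Generates recombinant F2 embryos from two inbred mouse strains (a
reference strain "B", e.g. C57BL/6, and an alternate strain "9", e.g.
129/Sv), injects genomic-instability events (copy-neutral LOH, segmental
deletions/duplications, whole-chromosome gains/losses), and samples
sequencing read counts at strain-informative catalog SNVs.  The output
data structures are exactly what the downstream analysis stages consume,
so the whole pipeline can be exercised without external sequencing data.

Coordinates are 1-based positions; internal segments are half-open
``[start, end)``.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

REF_STRAIN = "B"
ALT_STRAIN = "9"

LOCI = ("Fancd2", "Smad3")
GENOTYPES = ("+/+", "+/-", "-/-")
#: Mendelian single-locus genotype probabilities in a het x het cross.
GENOTYPE_PROBS = {"+/+": 0.25, "+/-": 0.5, "-/-": 0.25}

EVENT_KINDS = ("CN_LOH", "DELETION", "DUPLICATION", "CHR_GAIN", "CHR_LOSS")


def substream(seed: int, *names: str) -> np.random.Generator:
    """Derive a named, reproducible random substream from one master seed.

    Stages (gametes, litters, reads, ...) each pull their own substream so
    that re-running one stage does not perturb the others.
    """
    keys = [zlib.crc32(n.encode()) for n in names]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


# ---------------------------------------------------------------------------
# genome & catalog


@dataclass(frozen=True)
class Chromosome:
    name: str
    length_bp: int
    map_length_morgans: float

    def __post_init__(self):
        if self.length_bp <= 0:
            raise ValueError(f"chromosome {self.name}: length_bp must be > 0")
        if self.map_length_morgans < 0:
            raise ValueError(f"chromosome {self.name}: map length must be >= 0")


@dataclass(frozen=True)
class GenomeModel:
    """A parameterized genome: chromosome names, physical and genetic lengths."""

    chromosomes: tuple[Chromosome, ...]

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")

    def __getitem__(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    @classmethod
    def example(cls, n_chromosomes: int = 3, length_bp: int = 100_000_000,
                map_length_morgans: float = 1.0) -> "GenomeModel":
        """A small uniform genome, convenient for simulations and tests."""
        return cls(tuple(
            Chromosome(f"chr{i + 1}", length_bp, map_length_morgans)
            for i in range(n_chromosomes)
        ))


_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class StrainCatalog:
    """Known inter-strain informative biallelic SNVs.

    At every catalog site the reference strain is fixed for ``ref`` and the
    alternate strain is fixed for ``alt``, so the variant allele fraction
    reports local ancestry and copy state.
    """

    sites: pd.DataFrame  # columns: chrom, pos, ref, alt
    strain_name: str = "129S1"

    def __post_init__(self):
        s = self.sites
        required = ["chrom", "pos", "ref", "alt"]
        if list(s.columns[:4]) != required:
            s = s[required]
        for chrom, grp in s.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError(f"catalog positions on {chrom} must be strictly increasing")
        if (s["ref"] == s["alt"]).any():
            raise ValueError("catalog ref and alt alleles must differ")
        bad = ~(s["ref"].isin(_BASES) & s["alt"].isin(_BASES)
                & (s["ref"].str.len() == 1) & (s["alt"].str.len() == 1))
        if bad.any():
            raise ValueError("catalog sites must be biallelic SNVs (single A/C/G/T alleles)")
        self.sites = s.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def random(cls, genome: GenomeModel, n_sites: int,
               rng: np.random.Generator, strain_name: str = "129S1") -> "StrainCatalog":
        """Uniformly placed informative SNVs, proportional to chromosome length."""
        lengths = np.array([c.length_bp for c in genome.chromosomes], float)
        per_chrom = rng.multinomial(n_sites, lengths / lengths.sum())
        frames = []
        for c, n in zip(genome.chromosomes, per_chrom):
            if n == 0:
                continue
            pos = np.sort(rng.choice(c.length_bp, size=n, replace=False)) + 1
            ref = rng.integers(0, 4, size=n)
            alt = (ref + rng.integers(1, 4, size=n)) % 4
            frames.append(pd.DataFrame({
                "chrom": c.name, "pos": pos.astype(np.int64),
                "ref": _BASES[ref], "alt": _BASES[alt],
            }))
        return cls(pd.concat(frames, ignore_index=True), strain_name=strain_name)

    def to_tsv(self, path) -> None:
        self.sites.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, strain_name: str = "129S1") -> "StrainCatalog":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df, strain_name=strain_name)


# ---------------------------------------------------------------------------
# haplotype mosaics & gametes


@dataclass
class HaplotypeMosaic:
    """One gamete's ancestry: per chromosome, alternating strain segments.

    ``segments[chrom]`` is a list of ``(start, end, strain)`` half-open
    intervals covering ``[1, length_bp + 1)``.
    """

    segments: dict[str, list[tuple[int, int, str]]]

    def strain_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Strain label for each (1-based) position; vectorized."""
        segs = self.segments[chrom]
        starts = np.array([s for s, _, _ in segs])
        strains = np.array([st for _, _, st in segs])
        idx = np.searchsorted(starts, np.asarray(pos), side="right") - 1
        return strains[idx]


def simulate_f1_gamete(genome: GenomeModel, rng: np.random.Generator) -> HaplotypeMosaic:
    """Draw one recombinant F1 gamete.

    Per chromosome the number of crossovers is Poisson(map length in
    Morgans), crossover positions are uniform, and the starting strain is a
    fair coin; no crossover interference is modeled.
    """
    segments: dict[str, list[tuple[int, int, str]]] = {}
    for c in genome.chromosomes:
        n_break = rng.poisson(c.map_length_morgans)
        breaks = np.sort(rng.integers(2, c.length_bp + 1, size=n_break))
        breaks = np.unique(breaks)  # coincident crossovers collapse
        strain = REF_STRAIN if rng.random() < 0.5 else ALT_STRAIN
        bounds = np.concatenate(([1], breaks, [c.length_bp + 1]))
        segs = []
        for i in range(len(bounds) - 1):
            segs.append((int(bounds[i]), int(bounds[i + 1]), strain))
            strain = ALT_STRAIN if strain == REF_STRAIN else REF_STRAIN
        segments[c.name] = segs
    return HaplotypeMosaic(segments)


def diplotype_segments(genome: GenomeModel, hap1: HaplotypeMosaic,
                       hap2: HaplotypeMosaic) -> pd.DataFrame:
    """Intersect two haplotype mosaics into diplotype segments (BB/B9/99)."""
    rows = []
    for c in genome.chromosomes:
        cuts = sorted({s for s, _, _ in hap1.segments[c.name]}
                      | {s for s, _, _ in hap2.segments[c.name]}
                      | {c.length_bp + 1})
        for a, b in zip(cuts[:-1], cuts[1:]):
            s1 = hap1.strain_at(c.name, np.array([a]))[0]
            s2 = hap2.strain_at(c.name, np.array([a]))[0]
            n_alt = (s1 == ALT_STRAIN) + (s2 == ALT_STRAIN)
            dip = ("BB", "B9", "99")[n_alt]
            if rows and rows[-1][0] == c.name and rows[-1][3] == dip and rows[-1][2] == a:
                rows[-1] = (c.name, rows[-1][1], b, dip)  # merge equal-state neighbours
            else:
                rows.append((c.name, a, b, dip))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "diplotype"])


# ---------------------------------------------------------------------------
# instability events


@dataclass(frozen=True)
class InstabilityEvent:
    """A mosaic genomic-instability event present in ``cell_fraction`` of cells.

    ``haplotype`` names the strain of the haplotype acted on: the retained
    haplotype for CN_LOH / DELETION / CHR_LOSS, the gained haplotype for
    DUPLICATION / CHR_GAIN.  At sites homozygous for the other strain the
    event acts on one of the two identical copies.
    """

    kind: str
    chrom: str
    start: int
    end: int
    haplotype: str = ALT_STRAIN
    cell_fraction: float = 1.0

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.end <= self.start:
            raise ValueError("event interval must satisfy end > start")
        if not 0 < self.cell_fraction <= 1:
            raise ValueError("cell_fraction must be in (0, 1]")
        if self.haplotype not in (REF_STRAIN, ALT_STRAIN):
            raise ValueError(f"haplotype must be {REF_STRAIN!r} or {ALT_STRAIN!r}")


def whole_chromosome_event(kind: str, genome: GenomeModel, chrom: str,
                           haplotype: str = ALT_STRAIN,
                           cell_fraction: float = 1.0) -> InstabilityEvent:
    """Convenience constructor spanning an entire chromosome."""
    return InstabilityEvent(kind, chrom, 1, genome[chrom].length_bp + 1,
                            haplotype, cell_fraction)


def _event_copies(kind: str, haplotype: str, alt_copies: np.ndarray
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(alt, ref) copy numbers inside the event, per site, given the normal
    diplotype's alt copy count (0 = hom ref, 1 = het, 2 = hom alt)."""
    alt = np.asarray(alt_copies, dtype=float)
    het = alt == 1
    gain_is_alt = haplotype == ALT_STRAIN
    if kind == "CN_LOH":
        # het sites collapse to two copies of the retained strain;
        # homozygous sites are unchanged (copy-neutral, alleles identical)
        alt_e = np.where(het, 2.0 if gain_is_alt else 0.0, alt)
        total = np.full_like(alt, 2.0)
    elif kind in ("DELETION", "CHR_LOSS"):
        alt_e = np.where(het, 1.0 if gain_is_alt else 0.0, alt / 2.0)
        total = np.full_like(alt, 1.0)
    elif kind in ("DUPLICATION", "CHR_GAIN"):
        alt_e = np.where(het, 2.0 if gain_is_alt else 1.0, alt * 1.5)
        total = np.full_like(alt, 3.0)
    else:  # pragma: no cover - guarded by InstabilityEvent
        raise ValueError(kind)
    return alt_e, total - alt_e


def expected_vaf(diplotype: str, events: list[InstabilityEvent],
                 base_error_rate: float = 0.0) -> float:
    """Expected variant allele fraction at one site.

    Mixes the normal and event-carrying cell populations linearly, weighting
    each allele's read contribution by its copy number (the standard bulk
    sequencing assumption).  Sequencing error flips a read's allele with
    probability ``base_error_rate``.  Returns ``nan`` when every copy is
    deleted (no coverage).
    """
    alt0 = {"BB": 0, "B9": 1, "99": 2}[diplotype]
    vaf, copies = _site_mixture(np.array([alt0]), events, base_error_rate)
    return float(vaf[0]) if copies[0] > 0 else float("nan")


def _site_mixture(alt_copies: np.ndarray, events: list[InstabilityEvent],
                  e: float, pos: np.ndarray | None = None, chrom: str | None = None
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized expected VAF and total copy number under mosaic events.

    When ``pos``/``chrom`` are given, each event applies only to the sites it
    overlaps; otherwise every event is taken to cover all sites.
    """
    alt0 = np.asarray(alt_copies, dtype=float)
    ref0 = 2.0 - alt0
    alt_w = alt0.copy()
    ref_w = ref0.copy()
    copies = np.full_like(alt0, 2.0)
    for ev in events:
        if pos is None:
            mask = np.ones(alt0.shape, bool)
        else:
            if ev.chrom != chrom:
                continue
            mask = (pos >= ev.start) & (pos < ev.end)
        if not mask.any():
            continue
        cf = ev.cell_fraction
        alt_e, ref_e = _event_copies(ev.kind, ev.haplotype, alt0[mask])
        alt_w[mask] += cf * (alt_e - alt0[mask])
        ref_w[mask] += cf * (ref_e - ref0[mask])
        copies[mask] += cf * (alt_e + ref_e - 2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = (alt_w * (1 - e) + ref_w * e) / (alt_w + ref_w)
    return vaf, copies


def events_over_het_fraction(genome: GenomeModel, embryo: "SimEmbryo",
                             fraction: float, kind: str = "CN_LOH",
                             haplotype: str = ALT_STRAIN,
                             cell_fraction: float = 1.0) -> list[InstabilityEvent]:
    """Events covering about ``fraction`` of the embryo's heterozygous territory.

    Walks the embryo's heterozygous (B9) diplotype segments in genome order
    and emits one event per segment until the cumulative covered length
    reaches the requested fraction of the total heterozygous span; the last
    segment is truncated to hit the target exactly.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    segs = diplotype_segments(genome, embryo.hap1, embryo.hap2)
    het = segs[segs["diplotype"] == "B9"]
    total = int((het["end"] - het["start"]).sum())
    if total == 0:
        raise ValueError("embryo has no heterozygous territory")
    target = fraction * total
    events, covered = [], 0
    for row in het.itertuples(index=False):
        span = row.end - row.start
        take = min(span, int(np.ceil(target - covered)))
        if take <= 0:
            break
        events.append(InstabilityEvent(kind, row.chrom, row.start,
                                       row.start + take, haplotype, cell_fraction))
        covered += take
    return events


def _check_events(events: list[InstabilityEvent]) -> None:
    by_chrom: dict[str, list[InstabilityEvent]] = {}
    for ev in events:
        by_chrom.setdefault(ev.chrom, []).append(ev)
    for chrom, evs in by_chrom.items():
        evs = sorted(evs, key=lambda e: e.start)
        for a, b in zip(evs[:-1], evs[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping events on {chrom} are not supported")


# ---------------------------------------------------------------------------
# embryos & litters


@dataclass
class SimEmbryo:
    """One simulated F2 embryo: ancestry mosaics, targeted-locus genotypes,
    instability events, and survival status per developmental stage."""

    id: str
    locus_genotypes: dict[str, str]
    hap1: HaplotypeMosaic
    hap2: HaplotypeMosaic
    events: list[InstabilityEvent] = field(default_factory=list)
    alive_at: dict[str, bool] = field(default_factory=lambda: {"E12.5": True})

    def __post_init__(self):
        _check_events(self.events)

    @property
    def is_dko(self) -> bool:
        return all(self.locus_genotypes[l] == "-/-" for l in LOCI)

    def genotype_class(self) -> tuple[str, ...]:
        return tuple(self.locus_genotypes[l] for l in LOCI)

    def with_events(self, events: list[InstabilityEvent]) -> "SimEmbryo":
        _check_events(events)
        return replace(self, events=list(events))

    def alt_copies_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Number of alternate-strain haplotypes (0/1/2) at each position."""
        s1 = self.hap1.strain_at(chrom, pos)
        s2 = self.hap2.strain_at(chrom, pos)
        return (s1 == ALT_STRAIN).astype(int) + (s2 == ALT_STRAIN).astype(int)


#: Default post-E12.5 lethality: double knockouts die at ~50% (their weaned
#: frequency is about half the Mendelian expectation); all other genotype
#: classes survive.
DEFAULT_LETHALITY = {("-/-", "-/-"): 0.5}


@dataclass
class SimConfig:
    """Study conditions for read sampling and litter simulation.

    mean_depth
        Mean sequencing depth at a diploid site (exome-scale default 80x).
    depth_dispersion
        Negative-binomial overdispersion alpha (variance = m + alpha * m^2);
        0 means pure Poisson depth.
    base_error_rate
        Per-read probability that the observed allele is flipped.
    n_catalog_sites
        Number of strain-informative catalog SNVs to place on the genome.
    lethality
        Map from (Fancd2, Smad3) genotype pair to probability of death
        after E12.5; classes absent from the map survive.
    """

    mean_depth: float = 80.0
    depth_dispersion: float = 0.0
    base_error_rate: float = 0.001
    n_catalog_sites: int = 20_000
    lethality: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_LETHALITY))
    seed: int = 0

    def __post_init__(self):
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.depth_dispersion < 0:
            raise ValueError("depth_dispersion must be >= 0")
        if not 0 <= self.base_error_rate < 0.5:
            raise ValueError("base_error_rate must be in [0, 0.5)")
        for k, v in self.lethality.items():
            if not 0 <= v <= 1:
                raise ValueError(f"lethality[{k}] must be a probability")


def simulate_embryo(genome: GenomeModel, rng: np.random.Generator,
                    embryo_id: str = "embryo",
                    locus_genotypes: dict[str, str] | None = None,
                    events: list[InstabilityEvent] | None = None) -> SimEmbryo:
    """One embryo from two independent F1 gametes."""
    hap1 = simulate_f1_gamete(genome, rng)
    hap2 = simulate_f1_gamete(genome, rng)
    if locus_genotypes is None:
        locus_genotypes = {
            l: rng.choice(GENOTYPES, p=[GENOTYPE_PROBS[g] for g in GENOTYPES])
            for l in LOCI
        }
    return SimEmbryo(embryo_id, dict(locus_genotypes), hap1, hap2,
                     list(events or []))


def simulate_litter(genome: GenomeModel, config: SimConfig, n_embryos: int,
                    rng: np.random.Generator | None = None) -> list[SimEmbryo]:
    """A litter of F2 embryos from a double-heterozygote intercross.

    Each embryo draws two independent F1 gametes; the two targeted loci
    segregate independently (P(-/-) = 1/4 each, so 1/16 double knockouts);
    survival past E12.5 is Bernoulli(1 - lethality[genotype class]).
    """
    if n_embryos <= 0:
        raise ValueError("n_embryos must be > 0")
    if rng is None:
        rng = substream(config.seed, "litters")
    embryos = []
    for i in range(n_embryos):
        emb = simulate_embryo(genome, rng, embryo_id=f"emb{i:04d}")
        death_p = config.lethality.get(emb.genotype_class(), 0.0)
        emb.alive_at = {"E12.5": True, "E14.5": bool(rng.random() >= death_p)}
        embryos.append(emb)
    return embryos


# ---------------------------------------------------------------------------
# read sampling


@dataclass
class ADMatrix:
    """Sites x samples allele-depth matrix: the substrate of VAF analysis."""

    sites: pd.DataFrame  # columns: chrom, pos, ref, alt
    samples: list[str]
    alt_count: np.ndarray  # int, shape (n_sites, n_samples)
    total_depth: np.ndarray

    def __post_init__(self):
        self.alt_count = np.asarray(self.alt_count, dtype=np.int64)
        self.total_depth = np.asarray(self.total_depth, dtype=np.int64)
        shape = (len(self.sites), len(self.samples))
        if self.alt_count.shape != shape or self.total_depth.shape != shape:
            raise ValueError("alt_count/total_depth shape must be (n_sites, n_samples)")
        if (self.alt_count < 0).any() or (self.total_depth < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.alt_count > self.total_depth).any():
            raise ValueError("alt_count must not exceed total_depth")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def vaf(self) -> np.ndarray:
        """alt / depth with zero-depth cells reported as 0 (flagged by depth)."""
        with np.errstate(invalid="ignore", divide="ignore"):
            v = self.alt_count / self.total_depth
        return np.where(self.total_depth > 0, v, 0.0)

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def equals(self, other: "ADMatrix") -> bool:
        return (self.samples == other.samples
                and self.sites.reset_index(drop=True).equals(
                    other.sites.reset_index(drop=True))
                and np.array_equal(self.alt_count, other.alt_count)
                and np.array_equal(self.total_depth, other.total_depth))


def sample_reads(embryos: list[SimEmbryo], catalog: StrainCatalog,
                 config: SimConfig, rng: np.random.Generator | None = None,
                 stage: str = "E12.5") -> ADMatrix:
    """Sample allele depths at every catalog site for each live embryo.

    Per site and embryo, total depth is Poisson (negative-binomial when
    ``depth_dispersion > 0``) with mean ``mean_depth * copies / 2``, and the
    alt count is Binomial(depth, expected VAF).  Dead embryos carry no reads.
    """
    if rng is None:
        rng = substream(config.seed, "reads")
    live = [e for e in embryos if e.alive_at.get(stage, True)]
    if not live:
        raise ValueError(f"no embryos alive at stage {stage}")
    n_sites = len(catalog)
    alt = np.zeros((n_sites, len(live)), dtype=np.int64)
    dp = np.zeros_like(alt)
    for j, emb in enumerate(live):
        for chrom, grp in catalog.sites.groupby("chrom", sort=False):
            idx = grp.index.to_numpy()
            pos = grp["pos"].to_numpy()
            alt_copies = emb.alt_copies_at(chrom, pos)
            evaf, copies = _site_mixture(alt_copies, emb.events,
                                         config.base_error_rate, pos, chrom)
            mean = config.mean_depth * copies / 2.0
            if config.depth_dispersion > 0:
                a = config.depth_dispersion
                depth = np.where(mean > 0,
                                 rng.negative_binomial(1.0 / a, 1.0 / (1.0 + a * mean)),
                                 0)
            else:
                depth = rng.poisson(mean)
            covered = (depth > 0) & (copies > 0)
            k = np.zeros_like(depth)
            k[covered] = rng.binomial(depth[covered], evaf[covered])
            dp[idx, j] = np.where(copies > 0, depth, 0)
            alt[idx, j] = np.where(copies > 0, k, 0)
    return ADMatrix(catalog.sites.copy(), [e.id for e in live], alt, dp)


# ---------------------------------------------------------------------------
# target-depth simulation for copy-ratio analysis


def simulate_depth_matrix(genome: GenomeModel, n_targets: int,
                          sample_events: dict[str, list[InstabilityEvent]],
                          config: SimConfig,
                          rng: np.random.Generator | None = None,
                          efficiency_sd: float = 0.5):
    """Per-target mean read depths for copy-ratio analysis.

    Targets are evenly spaced along the genome.  Each target carries a
    shared log-normal capture efficiency (what a panel of normals corrects
    for); a sample's depth at a target is Poisson with mean
    ``mean_depth * efficiency * copies / 2`` where copies comes from that
    sample's copy-number events.

    Returns ``(targets, depth)``: a (chrom, start, end) DataFrame and a
    targets x samples depth array; sample order follows ``sample_events``.
    """
    from .cnv import DepthMatrix

    if rng is None:
        rng = substream(config.seed, "targets")
    lengths = np.array([c.length_bp for c in genome.chromosomes], float)
    per_chrom = np.maximum(1, np.round(n_targets * lengths / lengths.sum()).astype(int))
    rows = []
    for c, n in zip(genome.chromosomes, per_chrom):
        width = c.length_bp // (2 * n)
        starts = np.linspace(1, c.length_bp - width, n).astype(np.int64)
        for s in starts:
            rows.append((c.name, int(s), int(s + width)))
    targets = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    eff = rng.lognormal(0.0, efficiency_sd, size=len(targets))
    depth = np.zeros((len(targets), len(sample_events)), dtype=np.int64)
    mid = ((targets["start"] + targets["end"]) // 2).to_numpy()
    chroms = targets["chrom"].to_numpy()
    for j, (sample, events) in enumerate(sample_events.items()):
        copies = np.full(len(targets), 2.0)
        for ev in events:
            mask = (chroms == ev.chrom) & (mid >= ev.start) & (mid < ev.end)
            alt_e, ref_e = _event_copies(ev.kind, ev.haplotype, np.ones(mask.sum()))
            total = alt_e + ref_e
            copies[mask] += ev.cell_fraction * (total - 2.0)
        depth[:, j] = rng.poisson(config.mean_depth * eff * copies / 2.0)
    return DepthMatrix(targets, list(sample_events), depth)


# ---------------------------------------------------------------------------
# truth-table export (for the CLI and for debugging simulations)


def ancestry_truth_table(genome: GenomeModel, embryos: list[SimEmbryo]) -> pd.DataFrame:
    frames = []
    for emb in embryos:
        df = diplotype_segments(genome, emb.hap1, emb.hap2)
        df.insert(0, "embryo", emb.id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def events_table(embryos: list[SimEmbryo]) -> pd.DataFrame:
    rows = [(e.id, ev.kind, ev.chrom, ev.start, ev.end, ev.haplotype, ev.cell_fraction)
            for e in embryos for ev in e.events]
    return pd.DataFrame(rows, columns=["embryo", "kind", "chrom", "start", "end",
                                       "haplotype", "cell_fraction"])


def litter_table(embryos: list[SimEmbryo]) -> pd.DataFrame:
    rows = [(e.id, e.locus_genotypes[LOCI[0]], e.locus_genotypes[LOCI[1]],
             *(e.alive_at.get(s, True) for s in ("E12.5", "E14.5")))
            for e in embryos]
    return pd.DataFrame(rows, columns=["embryo", "Fancd2", "Smad3",
                                       "alive_E12.5", "alive_E14.5"])
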