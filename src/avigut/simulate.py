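"""Synthetic datasets with the statistical structure of the study design.

The design is 4 intestine segments (duodenum, jejunum, ileum, caecum) x
4 ages (11, 25, 34, 46 days) x 3 pens = 48 pooled samples.  Each
(segment, age) cell carries a mean genus composition; counts are drawn
Dirichlet-multinomial around it, which is the standard overdispersed model
for 16S amplicon counts.  The default template encodes the major known
features of the broiler gut: Lactobacillus dominating the proximal
segments and rising with age (to ~0.99 of the duodenum by day 46),
Escherichia/Shigella expanding in the ileum (to ~0.40), Enterococcus as an
early colonizer that disappears after day 11, and a caecum that is far
richer than the other segments, anchored by Lachnoclostridium (~0.20) with
Bacteroides, Alistipes and Faecalibacterium waxing and waning.

``segment_effect`` and ``age_effect`` scale the between-cell compositional
differences on the log scale: at (1, 1) the template is reproduced
exactly, at (0, 0) every cell shares the global mean composition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (AGES, SEGMENTS, BlastHitTable, CountMatrix, FormatError,
                 SampleMetadata, TaxonomyTable)

_SEG_LETTER = {"duodenum": "D", "jejunum": "J", "ileum": "I", "caecum": "C"}

# genus -> phylum for the named pool (narrative anchors of the study system)
_GENUS_PHYLUM = {
    "Lactobacillus": "Firmicutes",
    "Enterococcus": "Firmicutes",
    "Escherichia/Shigella": "Proteobacteria",
    "Bacteroides": "Bacteroidetes",
    "Lachnoclostridium": "Firmicutes",
    "Alistipes": "Bacteroidetes",
    "Faecalibacterium": "Firmicutes",
    "Romboutsia": "Firmicutes",
    "Flavonifractor": "Firmicutes",
    "Clostridium": "Firmicutes",
    "Streptococcus": "Firmicutes",
    "Ruminococcus": "Firmicutes",
}
_N_CAECAL_FILLER = 26  # extra low-abundance caecal genera -> caecal richness


@dataclass
class CommunityTemplate:
    """Per-(segment, age) mean genus compositions plus dispersion.

    `means[(segment, age)]` is a simplex vector over `genus_pool`;
    `theta` is the Dirichlet concentration (larger = less overdispersion).
    The caecum must have strictly more non-zero genera than any other
    segment (its hallmark richness), unless `require_caecal_richness` is
    switched off.
    """

    genus_pool: list[str]
    genus_phylum: dict[str, str]
    means: dict[tuple[str, int], np.ndarray]
    theta: float = 75.0
    segments: tuple[str, ...] = SEGMENTS
    ages: tuple[int, ...] = AGES
    require_caecal_richness: bool = True

    def __post_init__(self) -> None:
        if len(self.genus_pool) == 0:
            raise FormatError("zero-taxon template")
        if self.theta <= 0:
            raise FormatError("theta must be positive")
        for key, vec in self.means.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (len(self.genus_pool),):
                raise FormatError(f"template mean for {key} has wrong length")
            if vec.min() < 0 or not np.isclose(vec.sum(), 1.0, atol=1e-9):
                raise FormatError(f"template mean for {key} is not a composition")
            self.means[key] = vec
        for seg in self.segments:
            for age in self.ages:
                if (seg, age) not in self.means:
                    raise FormatError(f"template missing cell ({seg}, {age})")
        if self.require_caecal_richness:
            support = {
                seg: int((self.segment_mean(seg) > 0).sum())
                for seg in self.segments
            }
            others = [v for s, v in support.items() if s != "caecum"]
            if support.get("caecum", 0) <= max(others):
                raise FormatError(
                    "caecum template must have strictly more non-zero genera "
                    f"than other segments (support sizes: {support})"
                )

    def segment_mean(self, segment: str) -> np.ndarray:
        vecs = [self.means[(segment, a)] for a in self.ages]
        m = np.mean(vecs, axis=0)
        return m / m.sum()

    def global_mean(self) -> np.ndarray:
        vecs = [self.means[k] for k in self.means]
        m = np.mean(vecs, axis=0)
        return m / m.sum()


def _fill(anchors: dict[str, float], support: list[str],
          pool: list[str]) -> np.ndarray:
    """Composition: anchor abundances, remainder spread evenly over support."""
    vec = np.zeros(len(pool))
    idx = {g: i for i, g in enumerate(pool)}
    for g, v in anchors.items():
        vec[idx[g]] = v
    rest = [g for g in support if g not in anchors]
    remainder = 1.0 - vec.sum()
    if remainder < 0:
        raise FormatError(f"anchor abundances exceed 1: {anchors}")
    if rest:
        vec[[idx[g] for g in rest]] = remainder / len(rest)
    elif remainder > 1e-12:
        vec[[idx[g] for g in anchors]] += remainder * vec[[idx[g] for g in anchors]] / vec.sum()
    return vec / vec.sum()


def default_template(theta: float = 75.0) -> CommunityTemplate:
    """The package's default community template for the broiler gut design."""
    filler = [f"CaecalGenus{i:02d}" for i in range(1, _N_CAECAL_FILLER + 1)]
    pool = list(_GENUS_PHYLUM) + filler
    phylum = dict(_GENUS_PHYLUM)
    for i, g in enumerate(filler):
        phylum[g] = ("Firmicutes", "Bacteroidetes", "Proteobacteria",
                     "Actinobacteriota")[i % 4]

    duo_support = ["Lactobacillus", "Enterococcus", "Streptococcus",
                   "Clostridium", "Escherichia/Shigella", "Romboutsia",
                   "Ruminococcus", "Flavonifractor"]
    jej_support = duo_support + ["Faecalibacterium"]
    ile_support = ["Lactobacillus", "Enterococcus", "Escherichia/Shigella",
                   "Bacteroides", "Lachnoclostridium", "Clostridium",
                   "Streptococcus", "Romboutsia", "Flavonifractor",
                   "Alistipes", "Faecalibacterium", "Ruminococcus"]
    cae_support = pool  # every genus occurs in the caecum

    duo = {
        11: {"Lactobacillus": 0.47, "Enterococcus": 0.40},
        25: {"Lactobacillus": 0.85, "Enterococcus": 0.01},
        34: {"Lactobacillus": 0.93, "Enterococcus": 0.005},
        46: {"Lactobacillus": 0.97, "Enterococcus": 0.002},
    }
    jej = {
        11: {"Lactobacillus": 0.30, "Enterococcus": 0.23,
             "Escherichia/Shigella": 0.02},
        25: {"Lactobacillus": 0.75, "Enterococcus": 0.02,
             "Escherichia/Shigella": 0.04},
        34: {"Lactobacillus": 0.85, "Escherichia/Shigella": 0.05},
        46: {"Lactobacillus": 0.90, "Escherichia/Shigella": 0.06},
    }
    ile = {
        11: {"Enterococcus": 0.72, "Escherichia/Shigella": 0.04,
             "Lactobacillus": 0.12},
        25: {"Escherichia/Shigella": 0.20, "Bacteroides": 0.16,
             "Lachnoclostridium": 0.096, "Lactobacillus": 0.25},
        34: {"Escherichia/Shigella": 0.30, "Bacteroides": 0.05,
             "Lactobacillus": 0.30},
        46: {"Escherichia/Shigella": 0.40, "Lactobacillus": 0.35},
    }
    cae = {
        11: {"Lachnoclostridium": 0.205, "Lactobacillus": 0.052,
             "Escherichia/Shigella": 0.024, "Clostridium": 0.10,
             "Bacteroides": 0.05},
        25: {"Lachnoclostridium": 0.20, "Bacteroides": 0.28,
             "Lactobacillus": 0.058, "Alistipes": 0.071},
        34: {"Lachnoclostridium": 0.20, "Bacteroides": 0.065,
             "Lactobacillus": 0.21, "Alistipes": 0.05},
        46: {"Lachnoclostridium": 0.20, "Bacteroides": 0.011,
             "Faecalibacterium": 0.12, "Alistipes": 0.028,
             "Lactobacillus": 0.10},
    }

    means: dict[tuple[str, int], np.ndarray] = {}
    for age in AGES:
        means[("duodenum", age)] = _fill(duo[age], duo_support, pool)
        means[("jejunum", age)] = _fill(jej[age], jej_support, pool)
        means[("ileum", age)] = _fill(ile[age], ile_support, pool)
        means[("caecum", age)] = _fill(cae[age], cae_support, pool)
    return CommunityTemplate(genus_pool=pool, genus_phylum=phylum,
                             means=means, theta=theta)


@dataclass
class GeneratorConfig:
    """Knobs of the dataset generator (defaults = the study conditions)."""

    seed: int = 0
    n_pens: int = 3
    depth_log_mean: float = float(np.log(60_000.0))  # log-normal library size
    depth_log_sigma: float = 0.25
    depth_floor: int = 45_000  # keeps every library above the rarefaction depth
    segment_effect: float = 1.0
    age_effect: float = 1.0
    species_missing_fraction: float = 0.3
    asvs_per_genus: int = 2

    def __post_init__(self) -> None:
        if self.segment_effect < 0 or self.age_effect < 0:
            raise FormatError("effects must be non-negative")
        if not 0 <= self.species_missing_fraction <= 1:
            raise FormatError("species_missing_fraction must be within [0, 1]")
        if self.n_pens < 1 or self.asvs_per_genus < 1:
            raise FormatError("n_pens and asvs_per_genus must be >= 1")


_FLOOR = 1e-12


def cell_mean(template: CommunityTemplate, segment: str, age: int,
              segment_effect: float, age_effect: float) -> np.ndarray:
    """Effective cell mean with scaled between-group differences.

    Log-linear interpolation: global mean + segment_effect x (segment
    deviation) + age_effect x (within-segment age deviation), renormalized.
    """
    g = np.maximum(template.global_mean(), _FLOOR)
    p_seg = np.maximum(template.segment_mean(segment), _FLOOR)
    p_cell = np.maximum(template.means[(segment, age)], _FLOOR)
    logm = (np.log(g)
            + segment_effect * (np.log(p_seg) - np.log(g))
            + age_effect * (np.log(p_cell) - np.log(p_seg)))
    m = np.exp(logm - logm.max())
    m[m < _FLOOR] = 0.0
    return m / m.sum()


def generate_dataset(template: CommunityTemplate | None = None,
                     config: GeneratorConfig = GeneratorConfig()
                     ) -> tuple[CountMatrix, TaxonomyTable, SampleMetadata]:
    """Simulate the full design: ASV counts, taxonomy and metadata.

    Each genus contributes `asvs_per_genus` ASVs whose within-genus split
    is a fixed Dirichlet draw per dataset; per-sample compositions are
    Dirichlet(theta x cell mean) and counts multinomial at a log-normal
    library size (floored so rarefaction at the default depth never fails).
    Deterministic for a fixed config.seed.
    """
    if template is None:
        template = default_template()
    rng = np.random.default_rng(config.seed)
    pool = template.genus_pool
    n_genera = len(pool)

    # ASV layer
    asv_ids, asv_genus = [], []
    for g in pool:
        for k in range(config.asvs_per_genus):
            asv_ids.append(f"ASV_{len(asv_ids) + 1:04d}")
            asv_genus.append(g)
    split = rng.dirichlet(np.full(config.asvs_per_genus, 5.0), size=n_genera)

    # taxonomy
    tax_rows = []
    for i, (aid, genus) in enumerate(zip(asv_ids, asv_genus)):
        phylum = template.genus_phylum[genus]
        missing = rng.random() < config.species_missing_fraction
        species = None if missing else f"{genus} simsp{i % config.asvs_per_genus + 1}"
        tax_rows.append((aid, "Bacteria", phylum, f"{phylum}_c", f"{phylum}_o",
                         f"{genus}aceae", genus, species))
    taxonomy = TaxonomyTable(pd.DataFrame(
        [r[1:] for r in tax_rows],
        index=[r[0] for r in tax_rows],
        columns=["kingdom", "phylum", "class", "order", "family",
                 "genus", "species"],
    ))

    # samples
    meta_rows, columns = [], {}
    for segment in template.segments:
        for age in template.ages:
            mean_g = cell_mean(template, segment, age,
                               config.segment_effect, config.age_effect)
            support = np.flatnonzero(mean_g > 0)
            for pen in range(1, config.n_pens + 1):
                sid = f"S{age}{_SEG_LETTER.get(segment, segment[0].upper())}{pen}"
                p_g = np.zeros(n_genera)
                p_g[support] = rng.dirichlet(template.theta * mean_g[support])
                # expand genus proportions to the ASV layer
                p_asv = (p_g[:, None] * split).ravel()
                depth = int(np.exp(rng.normal(config.depth_log_mean,
                                              config.depth_log_sigma)))
                depth = max(depth, config.depth_floor)
                columns[sid] = rng.multinomial(depth, p_asv / p_asv.sum())
                meta_rows.append((sid, segment, age, pen))

    counts = CountMatrix(pd.DataFrame(columns, index=asv_ids))
    meta = SampleMetadata(
        pd.DataFrame(
            [r[1:] for r in meta_rows],
            index=[r[0] for r in meta_rows],
            columns=["segment", "age_days", "pen"],
        ),
        segments=template.segments, ages=template.ages,
    )
    return counts, taxonomy, meta


# ---------------------------------------------------------------------------
# BLAST hit fixture generator

BRANCHES = ("assignable", "ambiguous", "low_identity", "coverage_filtered")


def generate_blast_hits(taxonomy: TaxonomyTable, config: GeneratorConfig,
                        rng: np.random.Generator
                        ) -> tuple[BlastHitTable, pd.Series]:
    """Hit sets for every genus-only ASV, spanning the rule's branches.

    Each candidate is assigned a ground-truth branch (cycled through
    `BRANCHES`) and gets hits constructed to land in it:

    - assignable: best species >= 97 identity, clear > 2-point gap
    - ambiguous: two species within 2 identity points of each other
    - low_identity: every passing hit below 97
    - coverage_filtered: hits with high identity but < 100% coverage

    Returns the hit table plus the truth label per candidate.
    """
    candidates = taxonomy.candidates_for_species_refinement()
    rows, truth = [], {}
    ref = 0
    for i, taxon in enumerate(candidates):
        genus = taxonomy.df.loc[taxon, "genus"]
        branch = BRANCHES[i % len(BRANCHES)]
        truth[taxon] = branch
        sp1 = f"{genus}_refsp1".replace(" ", "_")
        sp2 = f"{genus}_refsp2".replace(" ", "_")
        jitter = rng.uniform(0, 0.3)
        if branch == "assignable":
            pairs = [(sp1, 98.2 + jitter, 100.0), (sp2, 95.4, 100.0)]
        elif branch == "ambiguous":
            pairs = [(sp1, 98.0 + jitter, 100.0), (sp2, 97.1 + jitter, 100.0)]
        elif branch == "low_identity":
            pairs = [(sp1, 96.2 + jitter, 100.0), (sp2, 95.1, 100.0)]
        else:  # coverage_filtered
            pairs = [(sp1, 99.0, 97.5), (sp2, 98.0, 95.0)]
        for sp, ident, cov in pairs:
            ref += 1
            rows.append((taxon, f"REF{ref:05d}|{sp}", sp.replace("_", " "),
                         round(ident, 2), cov, round(400 + 4 * ident, 1)))
    hits = BlastHitTable(pd.DataFrame(
        rows, columns=["query_id", "subject_id", "subject_species",
                       "percent_identity", "percent_query_coverage",
                       "bitscore"],
    ))
    return hits, pd.Series(truth, dtype=object)


# ---------------------------------------------------------------------------
# qPCR simulation


@dataclass
class QpcrSimConfig:
    """Generating model for dilution series and unknown samples."""

    slope: float = -3.4          # Ct per log10 copies
    intercept: float = 38.0      # Ct at 1 copy
    noise_sd: float = 0.2        # Gaussian Ct noise
    dilution_levels: tuple[float, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    replicates: int = 2
    n_unknowns: int = 48
    unknown_log10_range: tuple[float, float] = (4.0, 7.5)

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise FormatError("qPCR slope must be negative")
        if len(set(self.dilution_levels)) < 3:
            raise FormatError("need >= 3 distinct dilution levels")
        if self.noise_sd < 0:
            raise FormatError("noise_sd must be non-negative")


def generate_qpcr(qconfig: QpcrSimConfig, rng: np.random.Generator
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate (standards, unknowns) under Ct = intercept + slope*log10(copies).

    Standards: columns log10_copies, ct (replicated per level).  Unknowns:
    columns sample_id, true_copies, ct (duplicate Ct rows per sample).
    """
    std_rows = []
    for level in qconfig.dilution_levels:
        for _ in range(qconfig.replicates):
            ct = (qconfig.intercept + qconfig.slope * level
                  + rng.normal(0.0, qconfig.noise_sd))
            std_rows.append((float(level), ct))
    standards = pd.DataFrame(std_rows, columns=["log10_copies", "ct"])

    unk_rows = []
    lo, hi = qconfig.unknown_log10_range
    for i in range(qconfig.n_unknowns):
        log10_true = rng.uniform(lo, hi)
        for _ in range(2):  # analyzed in duplicate
            ct = (qconfig.intercept + qconfig.slope * log10_true
                  + rng.normal(0.0, qconfig.noise_sd))
            unk_rows.append((f"U{i + 1:03d}", 10.0 ** log10_true, ct))
    unknowns = pd.DataFrame(unk_rows, columns=["sample_id", "true_copies", "ct"])
    return standards, unknowns
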