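"""Synthetic populations with known genetic truth.

Generates discrete-generation pedigrees with a small sire pool (so a few
sires accumulate many progeny, as in beef AI schemes), gene-drops founder
haplotypes through the pedigree with Haldane recombination at 1 cM/Mb, and
produces categorical phenotypes by thresholding a latent liability

    l = cg + u + e,   e ~ N(0, 1),   Var(u) = sigma2_a = h2/(1 - h2)

so the liability-scale heritability (excluding the contemporary-group
variance, which the fitted model absorbs as fixed effects) is exactly
``h2_true``. QTL are a subset of the typed markers, which keeps the true
signal visible to a window scan. Editing covariates (calving ages, calving
interval) are drawn so a configurable fraction of records violates the
data-edit rules, giving the QC stage something real to remove.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import GenotypePanel, Pedigree

#: quality score below which a genotype fails the GC-score rule
GC_CUTOFF = 0.15

# mixed-radix decomposition of a contemporary-group index into its five
# components (herd, birth year, season, weaning group, yearling group)
_CG_RADIX = (8, 8, 2, 4, 4)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic population.

    Defaults emulate the study population at desk scale: a five-generation
    pedigree, ~2,000 phenotyped non-founders, ~300 genotyped animals, an AI
    sire pool averaging ~73.6 progeny, liability heritability 0.19 and
    thousands of SNP spread over a bovine-scale genome (25 autosomes of
    100 Mb at 1 cM/Mb, i.e. ~25 Morgans and ~2,500 one-Mb windows; a short
    genome would grossly overdisperse realized relationships around their
    pedigree expectations).
    """

    n_founders: int = 400
    n_generations: int = 5
    offspring_per_mating: int = 2
    progeny_per_sire: float = 73.6
    ai_fraction: float = 0.48
    natural_progeny_per_sire: float = 8.0
    n_chromosomes: int = 25
    chrom_length_bp: int = 100_000_000
    n_markers: int = 2000
    n_qtl: int = 100
    h2_true: float = 0.19
    trait_kind: str = "binary"  # "binary" or "ordinal3"
    thresholds: tuple = (0.0,)
    n_contemporary_groups: int = 20
    cg_effect_sd: float = 0.3
    genotyped_fraction: float = 0.125
    missing_rate: float = 0.01
    low_quality_rate: float = 0.01
    edit_violation_rate: float = 0.02
    major_qtl_share: float = 0.0  # >0: one QTL holds this share of Var(u)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.h2_true < 1.0:
            raise ValueError("h2_true must be in [0, 1)")
        if self.trait_kind not in ("binary", "ordinal3"):
            raise ValueError(f"unknown trait_kind {self.trait_kind!r}")
        arity = 1 if self.trait_kind == "binary" else 2
        if len(self.thresholds) != arity:
            raise ValueError(
                f"{self.trait_kind} requires {arity} threshold(s), got {len(self.thresholds)}"
            )
        if list(self.thresholds) != sorted(self.thresholds) or len(
            set(self.thresholds)
        ) != len(self.thresholds):
            raise ValueError("thresholds must be strictly increasing")
        for name in ("genotyped_fraction", "missing_rate", "low_quality_rate",
                     "edit_violation_rate", "major_qtl_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_qtl > self.n_markers:
            raise ValueError("n_qtl cannot exceed n_markers")
        if self.n_founders < 2:
            raise ValueError("need at least 2 founders")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")

    @property
    def n_categories(self) -> int:
        return len(self.thresholds) + 1

    @property
    def sigma2_a_true(self) -> float:
        """Additive variance implied by h2 with residual variance fixed at 1."""
        return self.h2_true / (1.0 - self.h2_true)

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TrueGeneticModel:
    """Ground truth of the generator: QTL, effects, and true breeding values."""

    qtl_indices: np.ndarray       # positions into the marker panel
    qtl_effects: np.ndarray       # allele-substitution effects, liability units
    sigma2_a_true: float
    true_breeding_values: np.ndarray  # per animal, pedigree order


def simulate_pedigree(config: SimConfig) -> Pedigree:
    """Discrete-generation pedigree mixing heavy AI sires with many
    lightly-used natural-service sires.

    Founders (generation 0) have unknown parents and alternating sexes.
    In each later generation every dam of the previous generation produces
    ``offspring_per_mating`` offspring; an ``ai_fraction`` of the dams are
    inseminated from a small elite pool sized so those sires average
    ``progeny_per_sire`` progeny over the whole pedigree (the animals that
    would be the densely genotyped bulls of a real scheme), while the rest
    are served by a broad pool averaging ``natural_progeny_per_sire``
    progeny. The output carries an ``ai_sire`` boolean column marking
    animals that served in the elite pool.
    """
    rng = np.random.default_rng(config.seed)
    rows = []
    for i in range(config.n_founders):
        rows.append((f"A{i + 1:06d}", "0", "0", 0, "M" if i % 2 == 0 else "F"))
    next_id = config.n_founders + 1
    prev = rows
    elite_used: set[str] = set()
    ai_allocated = 0
    ai_exact = 0.0
    for gen in range(1, config.n_generations + 1):
        males = [r[0] for r in prev if r[4] == "M"]
        dams = [r[0] for r in prev if r[4] == "F"]
        if not males or not dams:
            raise ValueError(f"generation {gen - 1} lacks one sex; cannot mate")
        dams = list(rng.permutation(dams))
        n_ai_dams = int(round(config.ai_fraction * len(dams)))
        ai_off = n_ai_dams * config.offspring_per_mating
        # carry fractional sire counts across generations so the pooled
        # mean progeny per elite sire stays near the target
        ai_exact += ai_off / config.progeny_per_sire
        n_elite = max(1 if n_ai_dams else 0, round(ai_exact) - ai_allocated)
        n_elite = min(n_elite, len(males))
        ai_allocated += n_elite
        nat_off = (len(dams) - n_ai_dams) * config.offspring_per_mating
        n_nat = min(max(1, round(nat_off / config.natural_progeny_per_sire)),
                    max(1, len(males) - n_elite))
        pool = list(rng.choice(males, size=n_elite + n_nat, replace=False))
        elite_pool, nat_pool = pool[:n_elite], pool[n_elite:]
        elite_used.update(elite_pool)
        cur = []
        k = 0
        for j, dam in enumerate(dams):
            if j < n_ai_dams:
                sire = elite_pool[rng.integers(len(elite_pool))]
            else:
                sire = nat_pool[rng.integers(len(nat_pool))]
            for _ in range(config.offspring_per_mating):
                cur.append((f"A{next_id:06d}", sire, dam, gen,
                            "M" if k % 2 == 0 else "F"))
                next_id += 1
                k += 1
        rows.extend(cur)
        prev = cur
    df = pd.DataFrame(rows, columns=["animal", "sire", "dam", "generation", "sex"])
    df["ai_sire"] = df["animal"].isin(elite_used)
    return Pedigree(df)


def _marker_map(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Uniformly scattered markers, sorted within chromosome, no duplicates."""
    per_chrom = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    per_chrom[: config.n_markers % config.n_chromosomes] += 1
    frames = []
    offset = 0
    for c, m in enumerate(per_chrom, start=1):
        # rejection draw of m distinct positions (collisions are vanishingly
        # rare at typical densities; avoids materializing the whole range)
        bp = np.unique(rng.integers(1, config.chrom_length_bp + 1, size=2 * m))
        while len(bp) < m:
            extra = rng.integers(1, config.chrom_length_bp + 1, size=2 * m)
            bp = np.unique(np.concatenate([bp, extra]))
        bp = np.sort(rng.choice(bp, size=m, replace=False))
        frames.append(pd.DataFrame({
            "chrom": str(c),
            "marker_id": [f"M{offset + j + 1:06d}" for j in range(m)],
            "bp": bp.astype(np.int64),
        }))
        offset += m
    return pd.concat(frames, ignore_index=True)


def _recomb_fractions(marker_map: pd.DataFrame) -> np.ndarray:
    """Per-marker probability of switching parental haplotype.

    Entry 0 of each chromosome is 0.5 (random gamete start; chromosomes
    assort independently); within a chromosome, Haldane's map at 1 cM/Mb:
    r = (1 - exp(-2 d_Morgan)) / 2 with d_Morgan = delta_bp * 1e-8.
    """
    bp = marker_map["bp"].to_numpy(float)
    chrom = marker_map["chrom"].to_numpy()
    r = np.empty(len(bp))
    r[0] = 0.5
    d = (bp[1:] - bp[:-1]) * 1e-8
    r[1:] = 0.5 * (1.0 - np.exp(-2.0 * d))
    r[np.r_[False, chrom[1:] != chrom[:-1]]] = 0.5
    return r


def gene_drop(pedigree: Pedigree, config: SimConfig,
              rng: np.random.Generator) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop founder alleles through the pedigree.

    Returns the complete (no missingness) dosage matrix, markers x animals,
    plus the marker map. Founder allele frequencies ~ Uniform(0.05, 0.5).
    """
    marker_map = _marker_map(config, rng)
    m, n = config.n_markers, pedigree.n_animals
    freq = rng.uniform(0.05, 0.5, size=m)
    hap = np.zeros((2, n, m), dtype=np.uint8)
    sires, dams = pedigree.parent_indices()
    switch_p = _recomb_fractions(marker_map)
    generation = pedigree.df["generation"].to_numpy()

    def gametes(parents: np.ndarray) -> np.ndarray:
        """One recombinant gamete per listed parent (vectorized)."""
        state = np.cumsum(rng.random((len(parents), m)) < switch_p, axis=1) % 2
        return np.where(state == 0, hap[0, parents], hap[1, parents])

    for g in np.unique(generation):
        idx = np.flatnonzero(generation == g)
        s, d = sires[idx], dams[idx]
        both = (s >= 0) & (d >= 0)
        none = (s < 0) & (d < 0)
        one = ~both & ~none
        if none.any():
            k = idx[none]
            hap[0, k] = rng.random((len(k), m)) < freq
            hap[1, k] = rng.random((len(k), m)) < freq
        if both.any():
            k = idx[both]
            hap[0, k] = gametes(s[both])
            hap[1, k] = gametes(d[both])
        if one.any():  # one known parent: other gamete from the base population
            k = idx[one]
            known = np.where(s[one] >= 0, s[one], d[one])
            hap[0, k] = gametes(known)
            hap[1, k] = rng.random((len(k), m)) < freq
    dosages = (hap[0] + hap[1]).T.astype(np.float64)  # markers x animals
    return dosages, marker_map


def simulate_genotypes(pedigree: Pedigree, config: SimConfig,
                       rng: np.random.Generator | None = None,
                       complete: np.ndarray | None = None,
                       marker_map: pd.DataFrame | None = None) -> GenotypePanel:
    """Observed panel: gene-dropped dosages plus missingness and low-quality
    artifacts at the configured rates.

    ``complete``/``marker_map`` may carry a pre-computed gene drop (used by
    :func:`simulate_dataset` so true breeding values come from the same
    realization the panel observes).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if complete is None:
        complete, marker_map = gene_drop(pedigree, config, rng)
    dosages = complete.copy()
    shape = dosages.shape
    quality = GC_CUTOFF + (1.0 - GC_CUTOFF) * rng.random(shape)
    low = rng.random(shape) < config.low_quality_rate
    quality[low] = rng.random(int(low.sum())) * GC_CUTOFF
    dosages[rng.random(shape) < config.missing_rate] = np.nan
    return GenotypePanel(dosages, quality, marker_map, pedigree.animal_ids)


def make_genetic_model(complete_dosages: np.ndarray, pedigree: Pedigree,
                       config: SimConfig,
                       rng: np.random.Generator) -> TrueGeneticModel:
    """Pick QTL among the typed markers and scale effects so the founder
    true-breeding-value variance equals sigma2_a = h2/(1-h2) exactly."""
    m = complete_dosages.shape[0]
    qtl = np.sort(rng.choice(m, size=config.n_qtl, replace=False))
    effects = rng.standard_normal(config.n_qtl)
    if config.major_qtl_share > 0 and config.n_qtl > 1:
        p = complete_dosages[qtl].mean(axis=1) / 2.0
        v = 2.0 * p * (1.0 - p) * effects**2
        s = config.major_qtl_share
        big = int(np.argmax(2.0 * p * (1.0 - p)))  # a common variant can carry it
        rest = v.sum() - v[big]
        effects[big] = np.sqrt(s / (1.0 - s) * rest / (2.0 * p[big] * (1.0 - p[big])))
    tbv = complete_dosages[qtl].T @ effects
    founders = (pedigree.df["generation"] == 0).to_numpy()
    base = tbv[founders] if founders.any() else tbv
    sd = base.std()
    if config.h2_true == 0.0 or sd == 0.0:
        effects = np.zeros_like(effects)
        tbv = np.zeros_like(tbv)
    else:
        scale = np.sqrt(config.sigma2_a_true) / sd
        effects = effects * scale
        tbv = tbv * scale
        tbv = tbv - (tbv[founders].mean() if founders.any() else tbv.mean())
    return TrueGeneticModel(qtl, effects, config.sigma2_a_true, tbv)


def _decode_cg(cg: np.ndarray) -> dict[str, np.ndarray]:
    """Five contemporary-group components whose concatenation identifies cg."""
    herd = cg % _CG_RADIX[0]
    year = (cg // 8) % _CG_RADIX[1] + 2002
    season = (cg // 64) % _CG_RADIX[2] + 1
    wean = (cg // 128) % _CG_RADIX[3] + 1
    yearl = (cg // 512) % _CG_RADIX[4] + 1
    return {
        "herd": np.char.add("H", herd.astype(str)),
        "birth_year": year,
        "birth_season": season,
        "weaning_group": wean,
        "yearling_group": yearl,
    }


def simulate_phenotypes(pedigree: Pedigree, model: TrueGeneticModel,
                        config: SimConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Categorical records for every non-founder.

    Liability = CG effect + true breeding value + N(0,1) residual; the
    category is the index of the interval the liability falls in (category 0
    below t1, the top category above the last threshold). Calving-age
    covariates are drawn inside the edit windows except for a
    ``edit_violation_rate`` fraction pushed outside one rule each.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    gen = pedigree.df["generation"].to_numpy()
    pheno_idx = np.flatnonzero(gen >= 1) if config.n_generations > 0 else np.arange(
        pedigree.n_animals)
    n = len(pheno_idx)
    cg = rng.integers(config.n_contemporary_groups, size=n)
    cg_effects = rng.normal(0.0, config.cg_effect_sd,
                            size=config.n_contemporary_groups)
    liab = cg_effects[cg] + model.true_breeding_values[pheno_idx] + rng.standard_normal(n)
    cat = np.searchsorted(np.asarray(config.thresholds), liab)

    afc = rng.normal(30.0, 3.0, size=n).clip(21.5, 39.5)
    ci = rng.normal(14.0, 1.5, size=n).clip(11.5, 20.0)
    asc = (afc + ci).clip(32.5, 52.5)
    ci = asc - afc
    bad = np.flatnonzero(rng.random(n) < config.edit_violation_rate)
    which = rng.integers(3, size=len(bad))
    afc[bad[which == 0]] = rng.uniform(16.0, 20.9, size=int((which == 0).sum()))
    asc[bad[which == 1]] = rng.uniform(53.1, 58.0, size=int((which == 1).sum()))
    ci[bad[which == 2]] = rng.uniform(7.0, 10.9, size=int((which == 2).sum()))

    return pd.DataFrame({
        "animal": [pedigree.animal_ids[i] for i in pheno_idx],
        "trait": cat.astype(np.int64),
        **_decode_cg(cg),
        "age_first_calving": np.round(afc, 1),
        "age_second_calving": np.round(asc, 1),
        "calving_interval": np.round(ci, 1),
    })


@dataclass
class SimulatedData:
    """One complete synthetic study: pedigree, panel, truth, and records."""

    config: SimConfig
    pedigree: Pedigree
    panel: GenotypePanel
    model: TrueGeneticModel
    phenotypes: pd.DataFrame
    genotyped_ids: list[str]

    @property
    def genotyped_panel(self) -> GenotypePanel:
        mask = np.isin(np.array(self.panel.animal_ids), self.genotyped_ids)
        return self.panel.subset(animal_mask=mask)


def simulate_dataset(config: SimConfig) -> SimulatedData:
    """End-to-end draw of a study population from a single seed.

    The genotyped subset always contains the sires actually used (they are
    the best-connected animals, as in real dense-panel data) topped up with
    random animals to reach ``genotyped_fraction``.
    """
    rng = np.random.default_rng(config.seed)
    pedigree = simulate_pedigree(config)
    complete, marker_map = gene_drop(pedigree, config, rng)
    model = make_genetic_model(complete, pedigree, config, rng)
    panel = simulate_genotypes(pedigree, config, rng, complete, marker_map)
    phenotypes = simulate_phenotypes(pedigree, model, config, rng)

    elite = set(pedigree.df.loc[pedigree.df.get("ai_sire", False), "animal"]) \
        if "ai_sire" in pedigree.df.columns else set()
    n_target = int(round(config.genotyped_fraction * pedigree.n_animals))
    ids = np.array(pedigree.animal_ids)
    genotyped = [a for a in ids if a in elite][:n_target]
    others = [a for a in ids if a not in elite]
    extra = n_target - len(genotyped)
    if extra > 0:
        genotyped += list(rng.choice(others, size=min(extra, len(others)),
                                     replace=False))
    order = {a: i for i, a in enumerate(pedigree.animal_ids)}
    genotyped = sorted(genotyped, key=order.__getitem__)
    return SimulatedData(config, pedigree, panel, model, phenotypes, genotyped)
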