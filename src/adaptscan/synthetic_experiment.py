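"""Forward-time simulator of a replicated two-soil evolve-and-resequence experiment.

The generator emulates a greenhouse selection experiment with outcrossing,
self-incompatible annual plants: a full factorial of two soil types
(limestone / tuff), aphid herbivory present or absent, and bumblebee- versus
hand-pollination — eight treatment groups, each with two replicate lines of 49
plants evolving independently for eight generations of selection followed by
two hand-pollinated generations without selection (maternal-effect wash-out).
Generations 1 and 10 are the sampled time points, so nine transmission events
separate them.

Selection acts on fecundity: a plant's expected seed set is multiplied by
``exp(sum_l dosage_l * s_l[soil])``, a log-additive fitness map that keeps
fitness positive. Under bee pollination only a visitation-limited subset of
plants (the configured effective number of seed parents, 21-28 depending on
treatment) sets seed at all, which is the dominant source of drift in the
design; hand-pollination assigns 28 randomly chosen mothers equal base seed
set. Each plant's contribution to the next generation is proportional to its
share of the replicate seed pool, rescaled to 49 plants (largest-remainder
rounding keeps the census exact). Fathers are drawn fitness-proportionally
from the replicate, never equal to the mother (self-incompatibility), and
transmission is Mendelian with free recombination between loci.

Ground truth is known by construction: each locus is antagonistically
pleiotropic (opposite-sign selection in the two soils), conditionally neutral
(selection in one soil only), or neutral, so every downstream stage of the
pipeline can be validated without external data.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, make_marker_frame
from .exceptions import ConfigurationError, ExtinctionError

SOILS = ("limestone", "tuff")
SOIL_CODE = {"limestone": "L", "tuff": "T"}

#: Effective sizes (mean number of seed parents across generations, rounded up)
#: used for the drift-aware CMH test, per treatment line.
DEFAULT_NE = {
    "LNHH": 28, "LHH": 26, "LNHB": 22, "LHB": 22,
    "TNHH": 28, "THH": 27, "TNHB": 23, "THB": 21,
}

LOCUS_CLASSES = ("AP", "CN_limestone", "CN_tuff", "NEUTRAL")


def treatment_label(soil: str, herbivory: bool, pollination: str) -> str:
    """Treatment code, e.g. ``LHB`` = limestone, herbivory, bee-pollination."""
    h = "H" if herbivory else "NH"
    p = "B" if pollination == "bee" else "H"
    return SOIL_CODE[soil] + h + p


def biotic_label(herbivory: bool, pollination: str) -> str:
    """Pollination x herbivory group code (HB, HH, NHB, NHH)."""
    return ("H" if herbivory else "NH") + ("B" if pollination == "bee" else "H")


@dataclass(frozen=True)
class Treatment:
    soil: str
    herbivory: bool
    pollination: str

    @property
    def label(self) -> str:
        return treatment_label(self.soil, self.herbivory, self.pollination)

    @property
    def biotic(self) -> str:
        return biotic_label(self.herbivory, self.pollination)


@dataclass
class ExperimentConfig:
    """Design parameters of the evolution experiment."""

    soils: tuple = SOILS
    herbivory_levels: tuple = (True, False)
    pollination_modes: tuple = ("bee", "hand")
    n_replicates: int = 2
    n_plants: int = 49
    n_selection_generations: int = 8
    n_neutral_generations: int = 2
    ne_per_treatment: dict = field(default_factory=lambda: dict(DEFAULT_NE))
    n_hand_mothers: int = 28
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_plants < 2:
            raise ConfigurationError("n_plants must be >= 2")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if len(self.soils) != 2:
            raise ConfigurationError("exactly two soils are required")
        for label, ne in self.ne_per_treatment.items():
            if ne < 2:
                raise ConfigurationError(f"Ne for {label} must be >= 2 (got {ne})")
        for trt in self.treatments:
            if trt.label not in self.ne_per_treatment:
                raise ConfigurationError(f"no Ne configured for treatment {trt.label}")

    @property
    def treatments(self) -> list:
        return [
            Treatment(s, h, p)
            for s, h, p in itertools.product(
                self.soils, self.herbivory_levels, self.pollination_modes
            )
        ]

    @property
    def plants_per_generation(self) -> int:
        return len(self.treatments) * self.n_replicates * self.n_plants

    @property
    def n_neutral_transmissions(self) -> int:
        """Hand-pollinated wash-out transmissions.

        ``n_neutral_generations`` counts the grown wash-out generations (9
        and 10 by default); the last of them is the sampled endpoint, so it
        contributes no further transmission.
        """
        return max(self.n_neutral_generations - 1, 0)

    @property
    def n_transmissions(self) -> int:
        """Transmission events between the sampled generations (9 by default)."""
        return self.n_selection_generations + self.n_neutral_transmissions

    @property
    def final_generation(self) -> int:
        """Label of the last sampled generation (10 by default)."""
        return 1 + self.n_transmissions

    def ne(self, treatment: Treatment) -> int:
        return int(self.ne_per_treatment[treatment.label])


@dataclass(frozen=True)
class Locus:
    """One simulated biallelic locus with its selective role."""

    chrom: str
    pos: int
    founder_freq: float
    locus_class: str
    s: Mapping[str, float]
    trait_effect: float = 0.0


@dataclass
class GeneticArchitecture:
    """Set of loci with known selection coefficients and trait effects."""

    loci: Sequence[Locus]

    def __post_init__(self):
        if len(self.loci) == 0:
            raise ConfigurationError("architecture must contain at least one locus")
        last = {}
        for loc in self.loci:
            if not (0.0 < loc.founder_freq < 1.0):
                raise ConfigurationError(
                    f"founder frequency must lie in (0,1), got {loc.founder_freq}"
                )
            if loc.locus_class not in LOCUS_CLASSES:
                raise ConfigurationError(f"unknown locus class {loc.locus_class!r}")
            sA, sB = loc.s.get(SOILS[0], 0.0), loc.s.get(SOILS[1], 0.0)
            if loc.locus_class == "AP" and sA * sB >= 0:
                raise ConfigurationError("AP loci need opposite-sign coefficients")
            if loc.locus_class == "CN_limestone" and not (sA != 0 and sB == 0):
                raise ConfigurationError("CN_limestone loci select in limestone only")
            if loc.locus_class == "CN_tuff" and not (sB != 0 and sA == 0):
                raise ConfigurationError("CN_tuff loci select in tuff only")
            if loc.locus_class == "NEUTRAL" and (sA != 0 or sB != 0):
                raise ConfigurationError("NEUTRAL loci must have zero coefficients")
            if loc.chrom in last and loc.pos <= last[loc.chrom]:
                raise ConfigurationError(
                    f"positions must strictly increase within {loc.chrom}"
                )
            last[loc.chrom] = loc.pos

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def founder_freqs(self) -> np.ndarray:
        return np.array([l.founder_freq for l in self.loci])

    @property
    def trait_effects(self) -> np.ndarray:
        return np.array([l.trait_effect for l in self.loci])

    @property
    def classes(self) -> np.ndarray:
        return np.array([l.locus_class for l in self.loci], dtype=object)

    def selection(self, soil: str) -> np.ndarray:
        return np.array([l.s.get(soil, 0.0) for l in self.loci])

    def marker_frame(self) -> pd.DataFrame:
        return make_marker_frame(
            [l.chrom for l in self.loci], [l.pos for l in self.loci]
        )

    def truth_frame(self) -> pd.DataFrame:
        mk = self.marker_frame()
        mk["locus_class"] = self.classes
        mk["s_limestone"] = self.selection("limestone")
        mk["s_tuff"] = self.selection("tuff")
        mk["trait_effect"] = self.trait_effects
        return mk.drop(columns=["ref", "alt"])


def standard_architecture(
    n_ap: int = 12,
    n_cn_per_soil: int = 12,
    n_neutral: int = 120,
    s_ap: float = 0.35,
    s_cn: float = 0.35,
    founder_freq: float = 0.5,
    trait_effect: float = 0.3,
    spacing_bp: int = 5000,
    n_chromosomes: int = 10,
) -> GeneticArchitecture:
    """Default architecture: AP, per-soil CN and neutral loci spread over the genome.

    Loci are assigned round-robin to ``n_chromosomes`` chromosomes (A01..A10,
    matching a 10-chromosome Brassica karyotype) at ``spacing_bp`` intervals so
    unlinked loci fall in distinct pruning windows. Selected loci carry a
    nonzero additive effect on the fitness-proxy trait.
    """
    specs = (
        [("AP", {"limestone": s_ap, "tuff": -s_ap}, trait_effect)] * n_ap
        + [("CN_limestone", {"limestone": s_cn, "tuff": 0.0}, trait_effect)]
        * n_cn_per_soil
        + [("CN_tuff", {"limestone": 0.0, "tuff": s_cn}, trait_effect)]
        * n_cn_per_soil
        + [("NEUTRAL", {"limestone": 0.0, "tuff": 0.0}, 0.0)] * n_neutral
    )
    chroms = [f"A{i + 1:02d}" for i in range(n_chromosomes)]
    counters = {c: 0 for c in chroms}
    loci = []
    for i, (cls, s, beta) in enumerate(specs):
        chrom = chroms[i % n_chromosomes]
        counters[chrom] += 1
        loci.append(
            Locus(
                chrom=chrom,
                pos=counters[chrom] * spacing_bp,
                founder_freq=founder_freq,
                locus_class=cls,
                s=s,
                trait_effect=beta,
            )
        )
    loci.sort(key=lambda l: (l.chrom, l.pos))
    return GeneticArchitecture(loci)


@dataclass
class TraitModel:
    """Generative model for the fitness-proxy trait (number of open flowers).

    trait = intercept + soil_main_effect[soil grown]
          + sum_l dosage_l * trait_effect_l
          + gxe_effect * 1[soil grown == soil line]   (local advantage)
          + Normal(0, residual_sd)
    """

    intercept: float = 30.0
    soil_main_effect: Mapping[str, float] = field(
        default_factory=lambda: {"limestone": -2.0, "tuff": 2.0}
    )
    gxe_effect: float = 0.0
    residual_sd: float = 1.0

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ConfigurationError("residual_sd must be >= 0")


def residual_sd_for_h2(arch: GeneticArchitecture, h2: float) -> float:
    """Residual s.d. giving narrow-sense heritability ``h2`` at founder frequencies.

    Additive genetic variance at Hardy-Weinberg is ``sum_l 2 p_l q_l beta_l^2``.
    """
    if not (0 < h2 < 1):
        raise ConfigurationError("h2 must lie in (0,1)")
    p = arch.founder_freqs
    var_g = float(np.sum(2 * p * (1 - p) * arch.trait_effects**2))
    if var_g == 0:
        raise ConfigurationError("architecture has no trait-effect variance")
    return float(np.sqrt(var_g * (1 - h2) / h2))


@dataclass
class ReproductionPlan:
    """Per-plant seed set, fractional contribution quota and offspring counts."""

    seed_set: np.ndarray
    contribution_quota: np.ndarray
    offspring_count: np.ndarray


def contributions(seed_sets, n_plants: int) -> ReproductionPlan:
    """Normalize seed sets to next-generation contributions.

    quota_i = seed_i / sum(seed) * n_plants; integer offspring counts by
    largest-remainder rounding so they sum exactly to ``n_plants``. Plants
    with zero seed set get zero offspring.
    """
    seed = np.asarray(seed_sets, dtype=float)
    if (seed < 0).any():
        raise ConfigurationError("seed sets must be non-negative")
    total = seed.sum()
    if total <= 0:
        raise ExtinctionError("all seed sets are zero: replicate cannot continue")
    quota = seed / total * n_plants
    counts = np.floor(quota).astype(int)
    short = n_plants - counts.sum()
    if short > 0:
        remainder = quota - np.floor(quota)
        # stable: largest remainder first, ties to the lower index
        order = np.lexsort((np.arange(len(seed)), -remainder))
        counts[order[:short]] += 1
    assert counts.sum() == n_plants
    assert not np.any((seed == 0) & (counts > 0))
    return ReproductionPlan(seed, quota, counts)


def _founder_dosages(n_plants, freqs, rng) -> np.ndarray:
    return rng.binomial(2, freqs[None, :], size=(n_plants, len(freqs))).astype(float)


def simulate_founders(config: ExperimentConfig, arch: GeneticArchitecture):
    """Draw generation-1 plants for every treatment x replicate.

    Genotypes are Hardy-Weinberg draws at the founder frequencies, independent
    across loci and replicates (each replicate is an independent realization of
    the same founder distribution, seeded from the config root seed).
    Returns a :class:`GenotypeMatrix` over all plants and the sample table.
    """
    if len(arch) == 0 or config.n_plants == 0:
        raise ConfigurationError("need at least one locus and one plant")
    freqs = arch.founder_freqs
    rows, blocks = [], []
    for trt in config.treatments:
        for rep in range(config.n_replicates):
            rng = _child_rng(config.rng_seed, trt.label, rep, "founders")
            blocks.append(_founder_dosages(config.n_plants, freqs, rng))
            rows.append(_sample_rows(config, trt, rep, generation=1))
    samples = pd.concat(rows, ignore_index=True)
    geno = GenotypeMatrix(
        np.vstack(blocks), arch.marker_frame(), list(samples["plant_id"])
    )
    return geno, samples


def _child_rng(root_seed: int, *path) -> np.random.Generator:
    """Deterministic per-(treatment, replicate, stage) generator."""
    key = [zlib.crc32(str(p).encode()) % (2**31) for p in path]
    return np.random.default_rng(np.random.SeedSequence([int(root_seed)] + key))


def _sample_rows(config, trt, rep, generation, soil_grown=None, suffix=""):
    n = config.n_plants
    replicate = "AB"[rep] if rep < 2 else f"R{rep + 1}"
    families = np.arange(1, n + 1) + rep * n
    return pd.DataFrame(
        {
            "plant_id": [
                f"{trt.label}_{replicate}_g{generation}_p{i + 1}{suffix}"
                for i in range(n)
            ],
            "treatment": trt.label,
            "biotic_group": trt.biotic,
            "soil_line": trt.soil,
            "soil_grown": soil_grown or trt.soil,
            "herbivory": trt.herbivory,
            "pollination": trt.pollination,
            "replicate": replicate,
            "generation": generation,
            "family": families,
            "plant_index": np.arange(n),
        }
    )


def simulate_phenotype(
    genotypes: GenotypeMatrix,
    samples: pd.DataFrame,
    arch: GeneticArchitecture,
    trait: TraitModel,
    rng: np.random.Generator,
    trait_name: str = "open_flowers",
) -> pd.DataFrame:
    """Attach the fitness-proxy trait to a sample table (returns a copy)."""
    if len(samples) != genotypes.n_samples:
        raise ConfigurationError("sample table does not match genotype matrix")
    missing = set(samples["soil_grown"]) - set(trait.soil_main_effect)
    if missing:
        raise ConfigurationError(f"no soil main effect for {sorted(missing)}")
    genetic = genotypes.dosages @ arch.trait_effects
    soil_part = samples["soil_grown"].map(trait.soil_main_effect).to_numpy(float)
    local = (samples["soil_grown"] == samples["soil_line"]).to_numpy()
    noise = rng.normal(0.0, trait.residual_sd, size=len(samples))
    out = samples.copy()
    out[trait_name] = (
        trait.intercept + soil_part + genetic + trait.gxe_effect * local + noise
    )
    return out


def select_and_mate(
    dosages: np.ndarray,
    selection: np.ndarray,
    pollination: str,
    config: ExperimentConfig,
    ne: int,
    rng: np.random.Generator,
    return_parents: bool = False,
):
    """One transmission event for one replicate; returns offspring dosages.

    Fecundity selection multiplies each plant's expected seed set by
    ``exp(dosage . selection)``. Under bee pollination only ``ne`` randomly
    visited plants (the pollen-limitation cap) receive nonzero base seed set;
    under hand pollination ``n_hand_mothers`` random mothers get equal base
    seed set. Fathers are drawn per offspring proportionally to fitness,
    excluding the mother (self-incompatibility). Transmission is Mendelian
    with free recombination.
    """
    n, m = dosages.shape
    fitness = np.exp(dosages @ selection)
    n_mothers = min(ne if pollination == "bee" else config.n_hand_mothers, n)
    mothers = rng.choice(n, size=n_mothers, replace=False)
    base = np.zeros(n)
    base[mothers] = 1.0
    seed_set = base * fitness
    if (seed_set > 0).sum() < 1 or n < 2:
        raise ExtinctionError("fewer than 2 potential parents with nonzero seed set")
    plan = contributions(seed_set, config.n_plants)

    mother_idx = np.repeat(np.arange(n), plan.offspring_count)
    father_idx = np.empty(config.n_plants, dtype=int)
    for j, mom in enumerate(mother_idx):
        w = fitness.copy()
        w[mom] = 0.0
        father_idx[j] = rng.choice(n, p=w / w.sum())
    half_m = dosages[mother_idx] / 2.0
    half_f = dosages[father_idx] / 2.0
    offspring = (
        (rng.random((config.n_plants, m)) < half_m).astype(float)
        + (rng.random((config.n_plants, m)) < half_f)
    ).astype(float)
    if return_parents:
        return offspring, mother_idx, father_idx
    return offspring


@dataclass
class ExperimentResult:
    """Bundle returned by :func:`run_experiment`."""

    config: ExperimentConfig
    arch: GeneticArchitecture
    markers: pd.DataFrame
    #: (treatment label, replicate label, generation) -> dosage matrix
    genotypes: dict
    #: generation-1 and generation-10 plants grown in local soil, with trait
    samples: pd.DataFrame
    #: reciprocal transplant: generation-10 (and resurrected generation-1)
    #: lines phenotyped in both soils
    transplant: pd.DataFrame
    truth: pd.DataFrame

    def dosages(self, treatment: str, replicate: str, generation: int) -> np.ndarray:
        return self.genotypes[(treatment, replicate, generation)]


def run_experiment(
    config: ExperimentConfig,
    arch: GeneticArchitecture,
    trait: TraitModel | None = None,
) -> ExperimentResult:
    """Run the full replicated design and phenotype the sampled generations.

    Evolves every treatment x replicate from generation 1 through
    ``n_selection_generations`` selective transmissions plus
    ``n_neutral_generations`` neutral hand-pollinated transmissions, storing
    generation-1 and generation-10 genotypes, local-soil phenotypes of both
    sampled generations (trait-evolution assay) and a reciprocal-transplant
    phenotype table in which every sampled line is grown in both soils.
    """
    trait = trait or TraitModel()
    markers = arch.marker_frame()
    final_gen = config.final_generation
    genotypes: dict = {}
    sample_rows, transplant_rows = [], []
    for trt in config.treatments:
        sel = arch.selection(trt.soil)
        for rep in range(config.n_replicates):
            rep_label = "AB"[rep] if rep < 2 else f"R{rep + 1}"
            rng = _child_rng(config.rng_seed, trt.label, rep, "evolve")
            current = _founder_dosages(
                config.n_plants, arch.founder_freqs,
                _child_rng(config.rng_seed, trt.label, rep, "founders"),
            )
            genotypes[(trt.label, rep_label, 1)] = current
            try:
                for _ in range(config.n_selection_generations):
                    current = select_and_mate(
                        current, sel, trt.pollination, config, config.ne(trt), rng
                    )
                for _ in range(config.n_neutral_transmissions):
                    current = select_and_mate(
                        current, np.zeros_like(sel), "hand", config,
                        config.ne(trt), rng,
                    )
            except ExtinctionError as err:
                raise ExtinctionError(
                    f"treatment {trt.label} replicate {rep_label}: {err}"
                ) from err
            genotypes[(trt.label, rep_label, final_gen)] = current

            prng = _child_rng(config.rng_seed, trt.label, rep, "phenotype")
            for gen in {1, final_gen}:
                dos = genotypes[(trt.label, rep_label, gen)]
                geno = GenotypeMatrix(dos, markers)
                local_tab = _sample_rows(config, trt, rep, gen)
                sample_rows.append(
                    simulate_phenotype(geno, local_tab, arch, trait, prng)
                )
                for soil in config.soils:
                    tab = _sample_rows(
                        config, trt, rep, gen, soil_grown=soil,
                        suffix=f"_{SOIL_CODE[soil]}",
                    )
                    transplant_rows.append(
                        simulate_phenotype(geno, tab, arch, trait, prng)
                    )
    return ExperimentResult(
        config=config,
        arch=arch,
        markers=markers,
        genotypes=genotypes,
        samples=pd.concat(sample_rows, ignore_index=True),
        transplant=pd.concat(transplant_rows, ignore_index=True),
        truth=arch.truth_frame(),
    )


def strong_selection_architecture(
    n_ap: int = 20,
    n_cn_per_soil: int = 15,
    n_neutral: int = 300,
    s: float = 0.8,
    **kwargs,
) -> GeneticArchitecture:
    """Strong-selection scenario for ground-truth recovery checks.

    Per-copy selection of 0.8 drives antagonistic loci close to fixation in
    opposite directions within eight selective generations, so most of them
    survive the conservative drift-aware significance filter and the
    classification thresholds despite Ne ~ 21-28 drift.
    """
    return standard_architecture(
        n_ap=n_ap, n_cn_per_soil=n_cn_per_soil, n_neutral=n_neutral,
        s_ap=s, s_cn=s, **kwargs,
    )


def simulate_neutral_panel(
    n_markers: int,
    ne: int = 25,
    n_diploids: int = 49,
    t_generations: int = 9,
    n_replicates: int = 2,
    rng: np.random.Generator | None = None,
    p0_range: tuple = (0.1, 0.9),
) -> np.ndarray:
    """Neutral Wright-Fisher count tables for null calibration of the CMH test.

    Per marker and replicate: founders are ``n_diploids`` plants drawn from a
    pool at a uniform random frequency, the population frequency then drifts
    for ``t_generations`` binomial Wright-Fisher generations at effective
    size ``ne``, and ``n_diploids`` plants are sampled at the end. Returns
    stratified count tables of shape (n_markers, n_replicates, 2, 2) with
    rows (generation 1, generation 10) and columns (alt, ref).
    """
    rng = rng or np.random.default_rng(0)
    n_alleles = 2 * n_diploids
    p0 = rng.uniform(*p0_range, size=n_markers)
    tables = np.empty((n_markers, n_replicates, 2, 2), dtype=np.int64)
    for r in range(n_replicates):
        c1 = rng.binomial(n_alleles, p0)
        p = c1 / n_alleles
        for _ in range(t_generations):
            p = rng.binomial(2 * ne, p) / (2 * ne)
        c10 = rng.binomial(n_alleles, p)
        tables[:, r, 0, 0] = c1
        tables[:, r, 0, 1] = n_alleles - c1
        tables[:, r, 1, 0] = c10
        tables[:, r, 1, 1] = n_alleles - c10
    return tables


def simulate_blup_panel(
    n_samples: int = 150,
    n_markers: int = 200,
    h2: float = 0.5,
    n_causal: int = 20,
    rng: np.random.Generator | None = None,
):
    """Genotype/trait panel with known marker effects for BLUP validation.

    Marker minor-allele frequencies follow a neutral-like spectrum (density
    proportional to 1/x, truncated to [0.01, 0.5] as after a maf filter);
    the ``n_causal`` trait loci are drawn from the commonest markers, since
    loci that respond visibly to selection must segregate at intermediate
    frequency. Causal effects are unit magnitude with random sign; residual
    noise is scaled to the realized genetic variance so heritability is
    ``h2``. Returns (dosages, trait values, true effect vector).
    """
    rng = rng or np.random.default_rng(0)
    maf = np.exp(rng.uniform(np.log(0.01), np.log(0.5), size=n_markers))
    dosages = rng.binomial(2, np.broadcast_to(maf, (n_samples, n_markers))).astype(
        float
    )
    n_common = max(3 * n_causal, n_causal)
    common = np.argsort(-maf)[:n_common]
    causal = rng.choice(common, size=n_causal, replace=False)
    beta = np.zeros(n_markers)
    beta[causal] = rng.choice([-1.0, 1.0], size=n_causal)
    genetic = (dosages - 1.0) @ beta
    sd_g = genetic.std()
    if sd_g == 0:
        raise ConfigurationError("degenerate panel: no genetic variance")
    noise_sd = sd_g * np.sqrt((1 - h2) / h2)
    trait = genetic + rng.normal(0.0, noise_sd, size=n_samples)
    return dosages, trait, beta


def make_transplant_phenotypes(
    n_per_cell: int,
    local_advantage: float = 0.0,
    residual_sd: float = 1.0,
    replicate_sd: float = 0.0,
    soil_main: float = 0.0,
    line_main: float = 0.0,
    intercept: float = 30.0,
    n_replicates: int = 2,
    rng: np.random.Generator | None = None,
    trait_name: str = "open_flowers",
) -> pd.DataFrame:
    """Direct generator of a balanced reciprocal-transplant phenotype table.

    Produces ``n_per_cell`` plants in each of the four soil_line x soil_grown
    cells (split evenly over replicates) with an additive local-advantage
    shift of ``local_advantage`` trait units in the two matched cells. Used
    for calibrating and power-testing the GxE local-adaptation model without
    running the genomic simulator.
    """
    rng = rng or np.random.default_rng(0)
    rows = []
    rep_effects = rng.normal(0.0, replicate_sd, size=n_replicates)
    for line in SOILS:
        for soil in SOILS:
            for rep in range(n_replicates):
                n = n_per_cell // n_replicates + (
                    1 if rep < n_per_cell % n_replicates else 0
                )
                mean = (
                    intercept
                    + (soil_main if soil == "tuff" else 0.0)
                    + (line_main if line == "tuff" else 0.0)
                    + (local_advantage if line == soil else 0.0)
                    + rep_effects[rep]
                )
                rows.append(
                    pd.DataFrame(
                        {
                            "soil_line": line,
                            "soil_grown": soil,
                            "replicate": "AB"[rep] if rep < 2 else f"R{rep + 1}",
                            trait_name: rng.normal(mean, residual_sd, size=n),
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)
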