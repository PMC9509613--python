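"""Synthetic multi-line pedigreed populations with dense genotypes and traits.

The simulator produces the structures the downstream analysis assumes:
closed lines with multi-generation pedigrees and full-sib litters, a dense
variant panel with distance-decaying founder LD, a nested "chip" subset,
and additive traits with a configurable heritability and QTN count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from wgspred.errors import (
    ConfigurationError,
    InfeasibleDesignError,
    IntegrityError,
)

MISSING_PARENT = "0"

PEDIGREE_COLUMNS = ["id", "sire", "dam", "line", "generation", "birth_order"]


@dataclass
class Pedigree:
    """Pedigree records: one row per individual.

    ``table`` columns: id, sire, dam, line, generation, birth_order and an
    auxiliary ``sex`` column ('M'/'F') used only by the simulator. Missing
    parents are coded as ``"0"``. Rows are stored parents-before-children
    (ascending generation).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in PEDIGREE_COLUMNS if c not in self.table.columns]
        if missing:
            raise IntegrityError(f"pedigree table lacks columns: {missing}")

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def n(self) -> int:
        return len(self.table)

    def validate(self) -> None:
        """Raise :class:`IntegrityError` on any violated invariant."""
        t = self.table
        if t["id"].duplicated().any():
            raise IntegrityError("duplicate individual ids")
        gen = dict(zip(t["id"], t["generation"]))
        for _, row in t.iterrows():
            for parent in (row["sire"], row["dam"]):
                if parent == MISSING_PARENT:
                    continue
                if parent not in gen:
                    raise IntegrityError(f"unknown parent {parent!r}")
                if gen[parent] >= row["generation"]:
                    raise IntegrityError(
                        f"parent {parent!r} does not precede {row['id']!r}"
                    )
        founders = t[t["generation"] == 0]
        if not (
            (founders["sire"] == MISSING_PARENT)
            & (founders["dam"] == MISSING_PARENT)
        ).all():
            raise IntegrityError("founders must have both parents missing")
        # litter members (same sire+dam, both known) share one generation
        known = t[(t["sire"] != MISSING_PARENT) & (t["dam"] != MISSING_PARENT)]
        per_litter = known.groupby(["sire", "dam"])["generation"].nunique()
        if (per_litter > 1).any():
            raise IntegrityError("full-sib litter spans multiple generations")

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of sire/dam per individual (-1 when missing).

        Rows are assumed parent-before-child ordered (guaranteed by the
        simulator and by :meth:`validate` via the generation check).
        """
        pos = {iid: k for k, iid in enumerate(self.table["id"])}
        sire = np.array(
            [pos.get(s, -1) for s in self.table["sire"]], dtype=np.int64
        )
        dam = np.array(
            [pos.get(d, -1) for d in self.table["dam"]], dtype=np.int64
        )
        return sire, dam


@dataclass(frozen=True)
class LineDesign:
    """Per-line pedigree design."""

    name: str
    n_founders: int
    n_generations: int
    n_sires: int
    n_dams: int
    litter_size: int

    def validate(self) -> None:
        for attr in ("n_founders", "n_sires", "n_dams", "litter_size"):
            if getattr(self, attr) <= 0:
                raise ConfigurationError(f"{attr} must be positive")
        if self.n_generations < 0:
            raise ConfigurationError("n_generations must be non-negative")


@dataclass(frozen=True)
class GenomeConfig:
    """Stand-in genome coordinates for the simulated panel."""

    n_chromosomes: int
    chromosome_length_bp: int
    variants_per_chromosome: int
    recombination_rate: float  # Morgans per bp
    founder_ld_decay: float  # bp scale of adjacent-allele correlation decay

    def validate(self) -> None:
        if min(
            self.n_chromosomes,
            self.chromosome_length_bp,
            self.variants_per_chromosome,
        ) <= 0:
            raise ConfigurationError("genome dimensions must be positive")
        if self.recombination_rate < 0 or self.founder_ld_decay <= 0:
            raise ConfigurationError(
                "recombination_rate must be >=0 and founder_ld_decay positive"
            )
        if self.chromosome_length_bp <= self.variants_per_chromosome:
            raise ConfigurationError(
                "chromosome too short for the requested variant count"
            )

    @property
    def n_variants(self) -> int:
        return self.n_chromosomes * self.variants_per_chromosome


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosage matrix with variant metadata.

    ``dosages`` holds values in {0,1,2} (float32; NaN marks missing, which
    only occurs after noise injection). ``haplotypes`` (n, 2, m, int8) is
    retained by the simulator for validation and is not serialised.
    """

    individual_ids: np.ndarray
    variants: pd.DataFrame  # variant_id, chrom, pos, is_chip
    dosages: np.ndarray
    haplotypes: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.dosages.shape != (len(self.individual_ids), len(self.variants)):
            raise IntegrityError("dosage matrix shape mismatch")

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> np.ndarray:
        return self.variants["variant_id"].to_numpy()

    @property
    def chip_mask(self) -> np.ndarray:
        return self.variants["is_chip"].to_numpy(dtype=bool)

    def allele_frequencies(self, rows: np.ndarray | None = None) -> np.ndarray:
        d = self.dosages if rows is None else self.dosages[rows]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def minor_allele_frequencies(
        self, rows: np.ndarray | None = None
    ) -> np.ndarray:
        p = self.allele_frequencies(rows)
        return np.minimum(p, 1.0 - p)

    def row_indices(self, ids) -> np.ndarray:
        pos = {iid: k for k, iid in enumerate(self.individual_ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=np.int64)
        except KeyError as exc:  # pragma: no cover - message path
            raise IntegrityError(f"unknown individual id {exc}") from exc

    def subset(self, rows=None, cols=None) -> "GenotypeMatrix":
        rows = np.arange(self.n_individuals) if rows is None else np.asarray(rows)
        cols = np.arange(self.n_variants) if cols is None else np.asarray(cols)
        return GenotypeMatrix(
            individual_ids=self.individual_ids[rows],
            variants=self.variants.iloc[cols].reset_index(drop=True),
            dosages=self.dosages[np.ix_(rows, cols)],
            haplotypes=None
            if self.haplotypes is None
            else self.haplotypes[rows][:, :, cols],
        )


@dataclass
class TraitSimulation:
    """A simulated additive trait and its ground truth."""

    qtn_ids: np.ndarray
    qtn_effects: np.ndarray
    true_breeding_values: np.ndarray
    phenotypes: np.ndarray
    target_h2: float
    realized_h2: float


# ---------------------------------------------------------------------------
# pedigree simulation
# ---------------------------------------------------------------------------


def simulate_pedigree(
    designs: LineDesign | list[LineDesign], seed: int
) -> Pedigree:
    """Simulate closed lines of discrete generations with full-sib litters.

    Each generation, ``n_sires`` males and ``n_dams`` females are sampled
    from the previous generation; every dam produces one litter of
    ``litter_size`` full sibs by a randomly assigned sire. Deterministic
    given ``seed``.
    """
    if isinstance(designs, LineDesign):
        designs = [designs]
    rows: list[tuple] = []
    for design in designs:
        design.validate()
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, _stable_hash(design.name)])
        )
        birth_order = 0
        prev: list[tuple[str, str]] = []  # (id, sex) of previous generation
        for i in range(design.n_founders):
            iid = f"{design.name}-G0-{i:05d}"
            sex = "M" if i < design.n_founders // 2 else "F"
            rows.append(
                (iid, MISSING_PARENT, MISSING_PARENT, design.name, 0, birth_order, sex)
            )
            birth_order += 1
            prev.append((iid, sex))
        for g in range(1, design.n_generations + 1):
            males = [i for i, s in prev if s == "M"]
            females = [i for i, s in prev if s == "F"]
            if len(males) < design.n_sires or len(females) < design.n_dams:
                raise InfeasibleDesignError(
                    f"line {design.name}: generation {g} needs "
                    f"{design.n_sires} sires/{design.n_dams} dams but only "
                    f"{len(males)}/{len(females)} candidates exist"
                )
            sires = list(rng.choice(males, size=design.n_sires, replace=False))
            dams = list(rng.choice(females, size=design.n_dams, replace=False))
            current: list[tuple[str, str]] = []
            for dam in dams:
                sire = sires[int(rng.integers(len(sires)))]
                for _ in range(design.litter_size):
                    iid = f"{design.name}-G{g}-{len(current):05d}"
                    sex = "M" if rng.random() < 0.5 else "F"
                    rows.append(
                        (iid, sire, dam, design.name, g, birth_order, sex)
                    )
                    birth_order += 1
                    current.append((iid, sex))
            prev = current
    table = pd.DataFrame(
        rows, columns=PEDIGREE_COLUMNS + ["sex"]
    ).sort_values(["generation", "line", "birth_order"], kind="stable")
    ped = Pedigree(table.reset_index(drop=True))
    ped.validate()
    return ped


def _stable_hash(text: str) -> int:
    """Deterministic non-negative hash of a short string (seed derivation)."""
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


# ---------------------------------------------------------------------------
# genotype simulation
# ---------------------------------------------------------------------------


def _variant_table(genome: GenomeConfig) -> pd.DataFrame:
    spacing = genome.chromosome_length_bp // (genome.variants_per_chromosome + 1)
    pos = (np.arange(genome.variants_per_chromosome) + 1) * spacing
    frames = []
    for c in range(1, genome.n_chromosomes + 1):
        frames.append(
            pd.DataFrame(
                {
                    "variant_id": [f"{c}_{p}" for p in pos],
                    "chrom": str(c),
                    "pos": pos,
                    "is_chip": False,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _founder_haplotypes(
    n_haplotypes: int,
    variants: pd.DataFrame,
    genome: GenomeConfig,
    freqs: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Binary haplotypes with AR(1) latent-Gaussian LD along each chromosome.

    The latent process gives each variant its marginal frequency exactly
    while adjacent-allele correlation decays as exp(-distance/decay).
    """
    m = len(variants)
    thresholds = norm.ppf(freqs)
    chrom = variants["chrom"].to_numpy()
    pos = variants["pos"].to_numpy()
    haps = np.empty((n_haplotypes, m), dtype=np.int8)
    z = rng.standard_normal(n_haplotypes)
    for k in range(m):
        if k == 0 or chrom[k] != chrom[k - 1]:
            z = rng.standard_normal(n_haplotypes)
        else:
            rho = np.exp(-(pos[k] - pos[k - 1]) / genome.founder_ld_decay)
            z = rho * z + np.sqrt(1.0 - rho * rho) * rng.standard_normal(
                n_haplotypes
            )
        haps[:, k] = z < thresholds[k]
    return haps


def _meiosis(
    parent: np.ndarray,
    chrom_slices: list[slice],
    pos_by_chrom: list[np.ndarray],
    genome: GenomeConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete from a (2, m) parent haplotype pair.

    Haldane model: crossover count per chromosome is Poisson with mean
    equal to the map length in Morgans; crossover positions are uniform
    (no interference).
    """
    gamete = np.empty(parent.shape[1], dtype=np.int8)
    for sl, pos in zip(chrom_slices, pos_by_chrom):
        morgans = genome.chromosome_length_bp * genome.recombination_rate
        n_xo = rng.poisson(morgans) if morgans > 0 else 0
        start = int(rng.integers(2))
        if n_xo == 0:
            gamete[sl] = parent[start, sl]
            continue
        xo = np.sort(rng.uniform(0, genome.chromosome_length_bp, n_xo))
        which = (start + np.searchsorted(xo, pos)) % 2
        gamete[sl] = np.where(which == 0, parent[0, sl], parent[1, sl])
    return gamete


def simulate_founders_and_drop(
    pedigree: Pedigree,
    genome: GenomeConfig,
    seed: int,
    founder_freq_range: tuple[float, float] = (0.05, 0.95),
) -> GenotypeMatrix:
    """Draw founder haplotypes per line and gene-drop through the pedigree.

    Founders of each line are drawn from line-specific allele frequencies
    (shared variant coordinates produce the cross-line variant universe);
    descendants inherit one recombinant gamete from each parent.
    """
    pedigree.validate()
    genome.validate()
    variants = _variant_table(genome)
    m = len(variants)
    n = pedigree.n
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7919]))
    haplotypes = np.zeros((n, 2, m), dtype=np.int8)
    sire_idx, dam_idx = pedigree.parent_indices()

    chrom_slices = []
    pos_by_chrom = []
    chrom_arr = variants["chrom"].to_numpy()
    pos_arr = variants["pos"].to_numpy()
    start = 0
    for c in range(1, genome.n_chromosomes + 1):
        stop = start + genome.variants_per_chromosome
        assert (chrom_arr[start:stop] == str(c)).all()
        chrom_slices.append(slice(start, stop))
        pos_by_chrom.append(pos_arr[start:stop])
        start = stop

    lines = pedigree.table["line"].to_numpy()
    generation = pedigree.table["generation"].to_numpy()
    for line in pd.unique(lines):
        founder_rows = np.flatnonzero((lines == line) & (generation == 0))
        line_rng = np.random.default_rng(
            np.random.SeedSequence([seed, 104729, _stable_hash(str(line))])
        )
        lo, hi = founder_freq_range
        freqs = line_rng.uniform(lo, hi, size=m)
        founder_haps = _founder_haplotypes(
            2 * len(founder_rows), variants, genome, freqs, line_rng
        )
        haplotypes[founder_rows] = founder_haps.reshape(
            len(founder_rows), 2, m
        )

    order = np.argsort(generation, kind="stable")
    for i in order:
        if sire_idx[i] < 0 and dam_idx[i] < 0:
            continue
        if sire_idx[i] < 0 or dam_idx[i] < 0:
            raise IntegrityError(
                f"individual {pedigree.table['id'].iloc[i]!r} has exactly one "
                "known parent; gene dropping requires both or none"
            )
        haplotypes[i, 0] = _meiosis(
            haplotypes[sire_idx[i]], chrom_slices, pos_by_chrom, genome, rng
        )
        haplotypes[i, 1] = _meiosis(
            haplotypes[dam_idx[i]], chrom_slices, pos_by_chrom, genome, rng
        )

    dosages = haplotypes.sum(axis=1).astype(np.float32)
    return GenotypeMatrix(
        individual_ids=pedigree.ids.copy(),
        variants=variants,
        dosages=dosages,
        haplotypes=haplotypes,
    )


def designate_chip(
    genotypes: GenotypeMatrix,
    n_chip: int,
    maf_min: float = 0.01,
    seed: int | None = None,
) -> GenotypeMatrix:
    """Flag ``n_chip`` variants as the nested marker array.

    Chip members are chosen evenly spaced along the genome among variants
    with MAF >= ``maf_min`` (low-MAF variants never make the array).
    ``seed`` is accepted for interface symmetry; the spacing is
    deterministic.
    """
    maf = genotypes.minor_allele_frequencies()
    eligible = np.flatnonzero(maf >= maf_min)
    if n_chip > len(eligible):
        raise InfeasibleDesignError(
            f"requested {n_chip} chip variants but only {len(eligible)} have "
            f"MAF >= {maf_min}"
        )
    pick = eligible[
        (np.arange(n_chip, dtype=np.int64) * len(eligible)) // n_chip
    ]
    variants = genotypes.variants.copy()
    variants["is_chip"] = False
    variants.loc[variants.index[pick], "is_chip"] = True
    return replace(genotypes, variants=variants)


# ---------------------------------------------------------------------------
# trait simulation
# ---------------------------------------------------------------------------


def simulate_trait(
    genotypes: GenotypeMatrix,
    n_qtn: int,
    h2: float,
    qtn_panel: str = "any",
    effect_distribution=None,
    seed: int = 0,
) -> TraitSimulation:
    """Sample QTN, draw effects, and scale residual noise to hit ``h2``.

    ``qtn_panel='wgs_only'`` restricts causal variants to off-chip
    positions, mirroring the premise that the dense panel (not the array)
    carries the causal variants. ``effect_distribution`` is a callable
    ``f(rng, size) -> array`` (default standard normal).
    """
    if not (0.0 < h2 <= 1.0):
        raise ConfigurationError("h2 must be in (0, 1]")
    if n_qtn < 1:
        raise ConfigurationError("n_qtn must be >= 1")
    if qtn_panel not in ("any", "wgs_only"):
        raise ConfigurationError(f"unknown qtn_panel {qtn_panel!r}")
    maf = genotypes.minor_allele_frequencies()
    eligible = maf > 0
    if qtn_panel == "wgs_only":
        eligible &= ~genotypes.chip_mask
    eligible_idx = np.flatnonzero(eligible)
    if n_qtn > len(eligible_idx):
        raise InfeasibleDesignError(
            f"{n_qtn} QTN requested but only {len(eligible_idx)} eligible "
            "variants"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 15485863]))
    qtn = np.sort(rng.choice(eligible_idx, size=n_qtn, replace=False))
    if effect_distribution is None:
        effects = rng.standard_normal(n_qtn)
    else:
        effects = np.asarray(effect_distribution(rng, n_qtn), dtype=float)
    dose = genotypes.dosages[:, qtn].astype(np.float64)
    dose -= dose.mean(axis=0)
    tbv = dose @ effects
    tbv -= tbv.mean()
    var_tbv = float(tbv.var())
    if h2 == 1.0:
        residual = np.zeros_like(tbv)
    else:
        resid_sd = np.sqrt(var_tbv * (1.0 - h2) / h2)
        residual = rng.normal(0.0, resid_sd, size=tbv.shape)
    phenotypes = tbv + residual
    var_phen = float(phenotypes.var())
    realized = var_tbv / var_phen if var_phen > 0 else float("nan")
    return TraitSimulation(
        qtn_ids=genotypes.variant_ids[qtn],
        qtn_effects=effects,
        true_breeding_values=tbv,
        phenotypes=phenotypes,
        target_h2=h2,
        realized_h2=realized,
    )


def inject_genotype_noise(
    genotypes: GenotypeMatrix,
    error_rate: float,
    missing_rate: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Random dosage perturbation standing in for imputation error.

    Each entry is independently replaced by a random dosage in {0,1,2}
    with probability ``error_rate`` and set missing (NaN) with probability
    ``missing_rate``. Off by default in every pipeline.
    """
    if not (0.0 <= error_rate <= 1.0 and 0.0 <= missing_rate <= 1.0):
        raise ConfigurationError("rates must be in [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 32452843]))
    dosages = genotypes.dosages.astype(np.float32).copy()
    flip = rng.random(dosages.shape) < error_rate
    dosages[flip] = rng.integers(0, 3, size=int(flip.sum())).astype(np.float32)
    drop = rng.random(dosages.shape) < missing_rate
    dosages[drop] = np.nan
    return replace(genotypes, dosages=dosages, haplotypes=None)
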