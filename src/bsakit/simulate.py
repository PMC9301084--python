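"""Forward simulation of an EMS-mutagenised F2 mapping population.

The generative model mirrors a classical mapping-by-sequencing design: a
mutant line carrying EMS-induced point mutations (one of them causal and
recessive) is crossed to its progenitor wild type, the F1 is selfed, and the
segregating F2 is phenotyped, pooled by phenotype and sequenced as bulks.

Meiosis follows the Haldane model: crossover counts per chromosome are
Poisson with mean equal to the genetic length in Morgans, crossover
positions are uniform in genetic distance, and there is no interference.
Read sampling at a site is Poisson depth with binomial allele draws at the
pool's true allele frequency, perturbed by a symmetric per-read error rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .genmap import GeneticMap
from .phenotype import AbsorbanceReading, FluorescenceTrace, PigmentContents

__all__ = [
    "CausalLocusSpec",
    "EMSVariantSet",
    "F2Individual",
    "F2Population",
    "PoolSpec",
    "Pool",
    "simulate_f2_population",
    "build_pools",
    "simulate_pool_read_counts",
    "simulate_marker_genotypes",
    "simulate_absorbance_readings",
    "simulate_fluorescence_traces",
]

GREEN = "green"
PALE = "pale-green"

#: purine/pyrimidine transitions characteristic of EMS mutagenesis
EMS_TRANSITIONS = [("G", "A"), ("C", "T")]
_OTHER_CHANGES = [
    (r, a)
    for r in "ACGT"
    for a in "ACGT"
    if r != a and (r, a) not in EMS_TRANSITIONS
]


@dataclass(frozen=True)
class CausalLocusSpec:
    """The single recessive causal locus.

    ``lethal_when_homozygous`` models an allele whose homozygotes die before
    phenotyping (e.g. an albino-lethal insertion allele): such individuals
    are removed from the simulated population before pooling.
    """

    chromosome: str
    position: int
    mode: str = "recessive"
    lethal_when_homozygous: bool = False

    def __post_init__(self) -> None:
        if self.mode != "recessive":
            raise ValueError("only the recessive mode is supported")


@dataclass
class EMSVariantSet:
    """Biallelic SNPs segregating between the two parental lines.

    ``sites`` is a DataFrame with columns ``chrom``, ``pos`` (1-based bp),
    ``ref``, ``alt``, ``origin`` (``mutant-line`` or ``wild-type-line``:
    which parent carries the alt allele).
    """

    sites: pd.DataFrame
    ems_bias: float = 0.7

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "ref", "alt", "origin"}
        missing = required - set(self.sites.columns)
        if missing:
            raise ValueError(f"variant table missing columns {sorted(missing)}")
        df = self.sites.sort_values(["chrom", "pos"], kind="stable")
        df = df.reset_index(drop=True)
        if df.duplicated(["chrom", "pos"]).any():
            raise ValueError("duplicate variant positions within a chromosome")
        if (df["ref"] == df["alt"]).any():
            raise ValueError("alt allele equals ref at some site")
        if len(df):
            is_ts = [
                (r, a) in EMS_TRANSITIONS
                for r, a in zip(df["ref"], df["alt"])
            ]
            frac = float(np.mean(is_ts))
            if frac < self.ems_bias - 1e-9:
                raise ValueError(
                    f"G>A/C>T fraction {frac:.3f} below configured EMS bias "
                    f"{self.ems_bias:.3f}"
                )
        self.sites = df

    def __len__(self) -> int:
        return len(self.sites)

    def site_index(self, chromosome: str, position: int) -> int:
        hit = self.sites.index[
            (self.sites["chrom"] == chromosome)
            & (self.sites["pos"] == position)
        ]
        if len(hit) != 1:
            raise KeyError(
                f"site {chromosome}:{position} not in the variant set"
            )
        return int(hit[0])

    @classmethod
    def random(
        cls,
        gmap: GeneticMap,
        n_sites: int,
        *,
        ems_fraction: float = 0.7,
        mutant_line_fraction: float = 1.0,
        rng: np.random.Generator | None = None,
        seed: int | None = None,
    ) -> "EMSVariantSet":
        """Scatter ``n_sites`` EMS-style SNPs uniformly over the map.

        ``ems_fraction`` of sites are G>A or C>T transitions (the canonical
        EMS signature); ``mutant_line_fraction`` of sites carry the alt
        allele on the mutant line (the rest segregate from the wild-type
        parent, as with residual background polymorphism).
        """
        if rng is None:
            rng = np.random.default_rng(seed)
        lens = np.array([c.length_bp for c in gmap.chromosomes], dtype=float)
        probs = lens / lens.sum()
        rows: list[tuple[str, int, str, str, str]] = []
        seen: set[tuple[str, int]] = set()
        while len(rows) < n_sites:
            ci = int(rng.choice(len(gmap.chromosomes), p=probs))
            chrom = gmap.chromosomes[ci]
            pos = int(rng.integers(1, chrom.length_bp + 1))
            if (chrom.name, pos) in seen:
                continue
            seen.add((chrom.name, pos))
            if rng.random() < ems_fraction:
                ref, alt = EMS_TRANSITIONS[int(rng.integers(2))]
            else:
                ref, alt = _OTHER_CHANGES[int(rng.integers(len(_OTHER_CHANGES)))]
            origin = (
                "mutant-line"
                if rng.random() < mutant_line_fraction
                else "wild-type-line"
            )
            rows.append((chrom.name, pos, ref, alt, origin))
        df = pd.DataFrame(
            rows, columns=["chrom", "pos", "ref", "alt", "origin"]
        )
        # the realised transition fraction can dip below the target by chance
        return cls(df, ems_bias=0.0 if n_sites < 50 else ems_fraction - 0.15)


@dataclass(frozen=True)
class F2Individual:
    """One F2 plant: per-site alt-allele dosage (0/1/2) and phenotype."""

    genotype: np.ndarray
    phenotype: str

    def __post_init__(self) -> None:
        if self.phenotype not in (GREEN, PALE):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")


class F2Population:
    """A simulated F2 cohort; behaves as a sequence of :class:`F2Individual`.

    Internally genotypes are a single ``(n, n_sites)`` uint8 matrix (alt
    dosage) aligned with ``variants.sites``.
    """

    def __init__(
        self,
        genotypes: np.ndarray,
        phenotypes: np.ndarray,
        variants: EMSVariantSet,
        causal: CausalLocusSpec,
    ) -> None:
        self.genotypes = genotypes
        self.phenotypes = phenotypes
        self.variants = variants
        self.causal = causal
        self.causal_index = variants.site_index(
            causal.chromosome, causal.position
        )

    def __len__(self) -> int:
        return self.genotypes.shape[0]

    def __getitem__(self, i: int) -> F2Individual:
        return F2Individual(self.genotypes[i], str(self.phenotypes[i]))

    def subset(self, idx: np.ndarray) -> "F2Population":
        return F2Population(
            self.genotypes[idx], self.phenotypes[idx], self.variants, self.causal
        )

    @property
    def phenotype_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.phenotypes, return_counts=True)
        out = {GREEN: 0, PALE: 0}
        out.update(dict(zip(vals.tolist(), counts.tolist())))
        return out


@dataclass(frozen=True)
class PoolSpec:
    """How one phenotype bulk is assembled and sequenced."""

    phenotype_class: str  # "WP" (green) or "MP" (pale-green)
    size: int = 200
    mean_depth: float = 50.0
    error_rate: float = 0.005

    def __post_init__(self) -> None:
        if self.phenotype_class not in ("WP", "MP"):
            raise ValueError("phenotype_class must be 'WP' or 'MP'")
        if self.size <= 0:
            raise ValueError("pool size must be positive")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error rate must be in [0, 0.5)")
        if self.mean_depth <= 0:
            raise ValueError("mean depth must be positive")


@dataclass
class Pool:
    """A phenotype bulk: the sampled individuals plus its spec."""

    spec: PoolSpec
    members: F2Population

    @property
    def allele_frequencies(self) -> np.ndarray:
        """True alt-allele frequency per site within the pool."""
        return self.members.genotypes.mean(axis=0) / 2.0


def _simulate_gametes(
    gmap: GeneticMap,
    variants: EMSVariantSet,
    n_gametes: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Parental origin (0 = mutant-line haplotype) per gamete per site.

    Crossovers: count ~ Poisson(genetic length in Morgans) per chromosome,
    positions uniform in cM; origin at a site flips at each crossover left
    of it. Returns a (n_gametes, n_sites) uint8 matrix aligned with
    ``variants.sites``.
    """
    n_sites = len(variants)
    origin = np.zeros((n_gametes, n_sites), dtype=np.uint8)
    sites = variants.sites
    for chrom in gmap.chromosomes:
        cols = np.flatnonzero(sites["chrom"].to_numpy() == chrom.name)
        start = rng.integers(0, 2, size=n_gametes).astype(np.uint8)
        if len(cols) == 0:
            continue
        g_cm = gmap.bp_to_cm(chrom.name, sites["pos"].to_numpy()[cols])
        g_cm = np.atleast_1d(g_cm)
        if chrom.length_cm == 0:
            origin[:, cols] = start[:, None]
            continue
        k = rng.poisson(chrom.length_cm / 100.0, size=n_gametes)
        kmax = int(k.max(initial=0))
        if kmax == 0:
            origin[:, cols] = start[:, None]
            continue
        xo = rng.uniform(0.0, chrom.length_cm, size=(n_gametes, kmax))
        live = np.arange(kmax)[None, :] < k[:, None]
        # crossovers left of each site, modulo 2, give the origin parity
        parity = (
            ((xo[:, :, None] < g_cm[None, None, :]) & live[:, :, None])
            .sum(axis=1)
            .astype(np.uint8)
            & 1
        )
        origin[:, cols] = (start[:, None] + parity) & 1
    return origin


def simulate_f2_population(
    gmap: GeneticMap,
    variants: EMSVariantSet,
    causal: CausalLocusSpec,
    n: int,
    seed: int | np.random.Generator | None = None,
    *,
    penetrance: float = 1.0,
) -> F2Population:
    """Simulate ``n`` F2 individuals from a mutant x wild-type cross.

    Each individual is the union of two independent recombinant F1 gametes.
    The phenotype is pale-green iff the causal genotype is homozygous
    mutant, thinned by ``penetrance``. With
    ``causal.lethal_when_homozygous`` set, homozygous-mutant individuals
    are removed (so fewer than ``n`` plants may be returned).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    try:
        causal_idx = variants.site_index(causal.chromosome, causal.position)
    except KeyError:
        raise ValueError(
            f"causal site {causal.chromosome}:{causal.position} is not in "
            "the variant set"
        ) from None
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    gam1 = _simulate_gametes(gmap, variants, n, rng)
    gam2 = _simulate_gametes(gmap, variants, n, rng)
    # dosage of the mutant-line haplotype at each site
    mut_copies = (gam1 == 0).astype(np.uint8) + (gam2 == 0).astype(np.uint8)
    from_mutant = (
        variants.sites["origin"].to_numpy() == "mutant-line"
    )
    genotypes = np.where(from_mutant[None, :], mut_copies, 2 - mut_copies)
    genotypes = genotypes.astype(np.uint8)

    homozygous = genotypes[:, causal_idx] == 2
    expressed = homozygous & (rng.random(n) < penetrance)
    phenotypes = np.where(expressed, PALE, GREEN)

    if causal.lethal_when_homozygous:
        keep = ~homozygous
        genotypes, phenotypes = genotypes[keep], phenotypes[keep]
    return F2Population(genotypes, phenotypes, variants, causal)


def build_pools(
    pop: F2Population,
    wp: PoolSpec,
    mp: PoolSpec,
    seed: int | np.random.Generator | None = None,
) -> tuple[Pool, Pool]:
    """Sample the wild-type and mutant bulks from the population.

    Sampling is without replacement within each phenotype class; raises if a
    class has fewer individuals than the requested pool size.
    """
    if wp.phenotype_class != "WP" or mp.phenotype_class != "MP":
        raise ValueError("pass the WP spec first and the MP spec second")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pools = []
    for spec, phenotype in ((wp, GREEN), (mp, PALE)):
        idx = np.flatnonzero(pop.phenotypes == phenotype)
        if len(idx) < spec.size:
            raise ValueError(
                f"{spec.phenotype_class} pool needs {spec.size} "
                f"{phenotype} individuals but only {len(idx)} are available "
                f"(shortfall {spec.size - len(idx)})"
            )
        chosen = rng.choice(idx, size=spec.size, replace=False)
        pools.append(Pool(spec, pop.subset(np.sort(chosen))))
    return pools[0], pools[1]


def simulate_pool_read_counts(
    wp_pool: Pool,
    mp_pool: Pool,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw pooled sequencing read counts at every variant site.

    Per site and pool: total depth ~ Poisson(mean depth); alt reads ~
    Binomial(depth, f(1-e) + (1-f)e) where f is the pool's true alt-allele
    frequency and e the per-read error rate.

    Returns a coordinate-sorted DataFrame with columns ``chrom, pos, ref,
    alt, wp_alt, wp_dp, mp_alt, mp_dp``.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    sites = wp_pool.members.variants.sites
    out = sites[["chrom", "pos", "ref", "alt"]].copy()
    for label, pool in (("wp", wp_pool), ("mp", mp_pool)):
        if len(pool.members) == 0:
            raise ValueError(f"{label.upper()} pool is empty")
        f = pool.allele_frequencies
        eps = pool.spec.error_rate
        p = f * (1 - eps) + (1 - f) * eps
        depth = rng.poisson(pool.spec.mean_depth, size=len(sites))
        alt = rng.binomial(depth, p)
        out[f"{label}_alt"] = alt
        out[f"{label}_dp"] = depth
    return out


def simulate_marker_genotypes(
    pop: F2Population,
    markers: pd.DataFrame,
    *,
    miscall_rate: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Genotype every individual at the given markers.

    ``markers`` needs columns ``id, chrom, pos``; each must be a site of the
    population's variant set. Calls are exact dosages (0/1/2) unless
    ``miscall_rate`` > 0, in which case each call is replaced by a uniformly
    chosen different code with that probability — a crude model of
    melt-curve misclassification.

    Returns a DataFrame indexed by individual (``ind_0001``, ...) with one
    column per marker id.
    """
    idx = [
        pop.variants.site_index(c, p)
        for c, p in zip(markers["chrom"], markers["pos"])
    ]
    calls = pop.genotypes[:, idx].astype(np.int64)
    if miscall_rate > 0:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        flip = rng.random(calls.shape) < miscall_rate
        shift = rng.integers(1, 3, size=calls.shape)
        calls = np.where(flip, (calls + shift) % 3, calls)
    ids = [f"ind_{i + 1:04d}" for i in range(len(pop))]
    return pd.DataFrame(calls, index=ids, columns=list(markers["id"]))


# ---------------------------------------------------------------------------
# phenotyping-record generators (inverse of the printed formulas)

_PIGMENT_MATRIX = np.array([[12.72, -2.69], [-4.68, 22.88]])


def simulate_absorbance_readings(
    truth: PigmentContents,
    *,
    volume_ml: float = 30.0,
    dilution: float = 1.0,
    weight_g: float = 1.0,
    noise_sd: float = 0.0,
    n: int = 1,
    seed: int | np.random.Generator | None = None,
) -> list[AbsorbanceReading]:
    """Generate absorbance readings consistent with true pigment contents.

    The 663/645 nm pair is the solution of the linear chlorophyll system,
    and the 470 nm value inverts the carotenoid formula; Gaussian noise of
    ``noise_sd`` is then added to each OD. With zero noise, running the
    pigment calculator on a generated reading reproduces ``truth`` exactly.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    scale = volume_ml * dilution / weight_g
    od663, od645 = np.linalg.solve(
        _PIGMENT_MATRIX, np.array([truth.chl_a, truth.chl_b]) / scale
    )
    od470 = (198.0 * truth.car + 3.27 * truth.chl_a + 104.0 * truth.chl_b) / (
        volume_ml / weight_g
    )
    ods = np.array([od663, od645, od470])
    if np.any(ods < -1e-12):
        raise ValueError(
            "pigment contents have no non-negative absorbance solution: "
            f"OD663={od663:.4g}, OD645={od645:.4g}, OD470={od470:.4g}"
        )
    ods = np.clip(ods, 0.0, None)
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    readings = []
    for _ in range(n):
        noisy = ods + rng.normal(0.0, noise_sd, size=3)
        readings.append(
            AbsorbanceReading(
                od663=float(noisy[0]),
                od645=float(noisy[1]),
                od470=float(noisy[2]),
                volume_ml=volume_ml,
                dilution=dilution,
                weight_g=weight_g,
            )
        )
    return readings


def simulate_fluorescence_traces(
    truth: FluorescenceTrace,
    *,
    noise_sd: float = 0.0,
    n: int = 1,
    seed: int | np.random.Generator | None = None,
) -> list[FluorescenceTrace]:
    """Replicate a fluorescence trace with multiplicative Gaussian noise.

    Each raw quantity x becomes x * (1 + N(0, noise_sd)); the instrument
    constant k is left untouched. Zero noise returns exact copies, so the
    derived parameters round-trip.
    """
    if noise_sd < 0:
        raise ValueError("noise sd must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    fields = [
        "fo", "fm", "fs", "fm_prime", "fo_prime", "tau", "p_m", "p_0",
        "abs940", "abs650", "ref_abs940", "ref_abs650",
    ]
    out = []
    for _ in range(n):
        noisy = {
            name: getattr(truth, name) * (1.0 + rng.normal(0.0, noise_sd))
            for name in fields
        }
        out.append(replace(truth, **noisy))
    return out
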