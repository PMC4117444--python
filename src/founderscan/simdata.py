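"""Synthetic founder/outbred cohorts.

Generates the data structures every downstream stage consumes: allele
frequency trajectories through a population bottleneck under class-specific
selection, genotype matrices sampled with optional substructure (the
Balding-Nichols model, so the F estimated downstream has a known truth), and
phenotypes with a genotype -> biomarker -> disease mediation structure that
exercises the Mendelian-randomization stage.

The demographic model is deliberately minimal: two populations share an
ancestral allele frequency; the founder population passes through a single
instantaneous bottleneck ``bottleneck_start`` generations before present and
regrows exponentially, while the outbred population keeps a constant size.
There is no migration, recombination or new mutation -- the model tracks
existing variants, which is all the site-level statistics downstream need.

Selection acts on viability with genotype fitnesses 1, 1-hs, 1-s for the
reference homozygote, heterozygote and alternate homozygote. The
deterministic recursion for the alternate-allele frequency q is

    q' = [q^2 (1-s) + q(1-q)(1-hs)] / [1 - s q^2 - 2hs q(1-q)]

which for a completely recessive lethal (s=1, h=0) reduces to
q' = q/(1+q), with closed form q_t = q0 / (1 + t*q0). Stochastic mode
follows the same recursion and then resamples 2N gametes binomially each
generation (Wright-Fisher drift), so 0 and 1 are absorbing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._rng import stage_rng

logger = logging.getLogger(__name__)

__all__ = [
    "VariantClassSpec",
    "SimConfig",
    "AlleleTrajectory",
    "EffectSpec",
    "SyntheticCohort",
    "recessive_lethal_closed_form",
    "simulate_trajectories",
    "sample_genotypes",
    "simulate_phenotypes",
    "simulate_cohorts",
]

#: canonical functional classes and their default selection parameters
CLASS_DEFAULTS = {
    "synonymous": dict(s=0.0, h=0.5),
    "missense": dict(s=0.01, h=0.5),
    "lof": dict(s=0.01, h=0.5),
    "recessive_lethal": dict(s=1.0, h=0.0),
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass(frozen=True)
class VariantClassSpec:
    """Selection regime for one functional class of variants.

    Parameters
    ----------
    label:
        One of ``synonymous``, ``missense``, ``lof``, ``recessive_lethal``.
    s:
        Selection coefficient against the alternate-homozygote genotype,
        in [0, 1].
    h:
        Dominance of the alternate allele, in [0, 1].
    q0:
        Initial alternate-allele frequency: a float (point mass) or a
        ``(low, high)`` interval sampled per site.
    q0_shape:
        How an interval is sampled: ``"uniform"``; ``"log"`` for a
        density proportional to 1/q (the constant-size neutral
        site-frequency spectrum); or ``"growth"`` for a density
        proportional to q^(-3/2), the steeper spectrum of a recently
        expanded population, which concentrates mass at the ultra-rare
        frequencies that dominate real exome data.
    """

    label: str
    s: float
    h: float
    q0: float | tuple[float, float] = 0.01
    q0_shape: str = "log"

    def __post_init__(self):
        if not np.isfinite(self.s) or not np.isfinite(self.h):
            raise ConfigurationError("selection parameters must be finite")
        if not (0.0 <= self.s <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ConfigurationError(f"s, h must lie in [0,1]; got s={self.s}, h={self.h}")
        if self.label == "recessive_lethal" and not (self.s == 1.0 and self.h == 0.0):
            raise ConfigurationError("recessive_lethal requires s=1, h=0")
        if self.label == "synonymous" and self.s != 0.0:
            raise ConfigurationError("synonymous requires s=0")
        if self.q0_shape not in ("uniform", "log", "growth"):
            raise ConfigurationError(f"unknown q0_shape {self.q0_shape!r}")
        lo, hi = self._q0_interval()
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(f"initial frequency must lie in [0,1]; got {self.q0}")
        if self.q0_shape in ("log", "growth") and lo != hi and lo <= 0.0:
            raise ConfigurationError(f"{self.q0_shape}-shaped initial interval needs a positive lower bound")

    def _q0_interval(self) -> tuple[float, float]:
        if isinstance(self.q0, (tuple, list)):
            return float(self.q0[0]), float(self.q0[1])
        return float(self.q0), float(self.q0)

    @classmethod
    def default(cls, label: str, q0=0.01) -> "VariantClassSpec":
        return cls(label=label, q0=q0, **CLASS_DEFAULTS[label])


@dataclass(frozen=True)
class SimConfig:
    """Full description of a two-population simulation.

    The founder population contracts from ``ancestral_size`` to
    ``bottleneck_size`` diploids ``bottleneck_start`` generations before
    present, then regrows exponentially to ``present_size`` over
    ``generations_post_bottleneck`` generations. The outbred population
    stays at ``ancestral_size``.
    """

    ancestral_size: int = 500_000
    bottleneck_size: int = 1_000
    present_size: int = 500_000
    bottleneck_start: int = 100
    generations_post_bottleneck: int = 100
    class_specs: tuple[VariantClassSpec, ...] = (
        VariantClassSpec("synonymous", s=0.0, h=0.5, q0=(1e-6, 0.05), q0_shape="growth"),
        VariantClassSpec("lof", s=0.01, h=0.5, q0=(1e-6, 0.01), q0_shape="growth"),
    )
    n_sites_per_class: int = 8_000
    sample_sizes: dict = field(default_factory=lambda: {"founder": 3000, "outbred": 3000})
    substructure_F: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0
    mode: str = "stochastic"

    def __post_init__(self):
        for name in ("ancestral_size", "bottleneck_size", "present_size"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if self.generations_post_bottleneck < 0 or self.bottleneck_start < 0:
            raise ConfigurationError("generation counts must be >= 0")
        if not 0.0 <= self.substructure_F <= 1.0:
            raise ConfigurationError("substructure_F must lie in [0,1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ConfigurationError("missing_rate must lie in [0,1]")
        if self.mode not in ("stochastic", "deterministic"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        for sz in self.sample_sizes.values():
            if sz < 1:
                raise ConfigurationError("sample sizes must be >= 1")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


@dataclass
class AlleleTrajectory:
    """Per-generation alternate-allele frequencies for one class in one population.

    ``freqs`` has shape (generations+1, n_sites); row 0 is the initial state.
    """

    population: str
    class_label: str
    freqs: np.ndarray

    @property
    def final(self) -> np.ndarray:
        return self.freqs[-1]

    @property
    def n_generations(self) -> int:
        return self.freqs.shape[0] - 1


@dataclass(frozen=True)
class EffectSpec:
    """Causal structure for one variant: trait effect and disease effects.

    ``beta`` is the per-allele effect on the (standardized) quantitative
    trait in SD units; ``trait_loghr`` the log-hazard of disease per SD of
    the trait; ``direct_loghr`` a direct variant -> disease log-hazard
    (default 0, the exclusion-restriction condition under which Mendelian
    randomization is valid).
    """

    variant: str
    trait: str
    beta: float = 0.0
    trait_loghr: float = 0.0
    direct_loghr: float = 0.0

    def __post_init__(self):
        for v in (self.beta, self.trait_loghr, self.direct_loghr):
            if not np.isfinite(v):
                raise ConfigurationError("effect sizes must be finite")


@dataclass
class SyntheticCohort:
    """One sampled population: samples, genotype dosages, variants, phenotypes.

    ``dosages`` is an (n_samples x n_variants) int8 matrix with entries
    0/1/2 and -1 for missing.
    """

    population: str
    samples: pd.DataFrame
    dosages: np.ndarray
    variants: pd.DataFrame
    phenotypes: pd.DataFrame | None = None

    MISSING = -1

    def __post_init__(self):
        n, m = self.dosages.shape
        if n != len(self.samples) or m != len(self.variants):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def allele_counts(self) -> np.ndarray:
        d = self.dosages
        return np.where(d == self.MISSING, 0, d).sum(axis=0)

    def called_genotypes(self) -> np.ndarray:
        return (self.dosages != self.MISSING).sum(axis=0)

    def allele_freqs(self) -> np.ndarray:
        an = 2 * self.called_genotypes()
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(an > 0, self.allele_counts() / an, 0.0)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(hom_ref, het, hom_alt) counts among called genotypes at column j."""
        col = self.dosages[:, j]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())


def recessive_lethal_closed_form(q0, t):
    """q_t = q0 / (1 + t*q0): the deterministic recursion's closed form."""
    q0 = np.asarray(q0, dtype=float)
    return q0 / (1.0 + t * q0)


def _selection_step(q: np.ndarray, s: float, h: float) -> np.ndarray:
    """One generation of deterministic viability selection on q."""
    if s == 0.0:
        return q
    num = q * q * (1.0 - s) + q * (1.0 - q) * (1.0 - h * s)
    den = 1.0 - s * q * q - 2.0 * h * s * q * (1.0 - q)
    out = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(out, 0.0, 1.0)


def _founder_sizes(config: SimConfig) -> np.ndarray:
    """Diploid size per generation for the founder population (post-bottleneck)."""
    T = config.generations_post_bottleneck
    if T == 0:
        return np.array([], dtype=int)
    g = np.arange(1, T + 1)
    ratio = config.present_size / config.bottleneck_size
    sizes = config.bottleneck_size * ratio ** (g / T)
    return np.maximum(np.round(sizes).astype(int), 1)


def simulate_trajectories(config: SimConfig) -> dict[str, list[AlleleTrajectory]]:
    """Simulate allele-frequency trajectories for both populations.

    Returns a mapping ``population -> [AlleleTrajectory per class]``. Both
    populations start from the same per-site initial frequency (shared
    ancestry at the split). In deterministic mode drift is ignored and the
    two populations evolve identically except that population sizes are
    irrelevant; in stochastic mode each generation resamples 2N gametes
    binomially with N following each population's demography.
    """
    rng = stage_rng(config.seed, "trajectories")
    T = config.generations_post_bottleneck
    founder_sizes = _founder_sizes(config)
    out: dict[str, list[AlleleTrajectory]] = {"founder": [], "outbred": []}

    for spec in config.class_specs:
        lo, hi = spec._q0_interval()
        if lo == hi:
            q0 = np.full(config.n_sites_per_class, lo)
        elif spec.q0_shape == "log":
            # density proportional to 1/q on [lo, hi]
            q0 = lo * (hi / lo) ** rng.random(config.n_sites_per_class)
        elif spec.q0_shape == "growth":
            # density proportional to q**-1.5 on [lo, hi] (inverse CDF)
            u = rng.random(config.n_sites_per_class)
            q0 = (lo**-0.5 + u * (hi**-0.5 - lo**-0.5)) ** -2.0
        else:
            q0 = rng.uniform(lo, hi, size=config.n_sites_per_class)

        for pop in ("founder", "outbred"):
            q = q0.copy()
            if pop == "founder" and config.mode == "stochastic":
                # the bottleneck itself: founders drawn from the ancestral pool
                n_b = 2 * config.bottleneck_size
                q = rng.binomial(n_b, q) / n_b
            freqs = np.empty((T + 1, config.n_sites_per_class))
            freqs[0] = q
            for t in range(1, T + 1):
                q = _selection_step(q, spec.s, spec.h)
                if config.mode == "stochastic":
                    n2 = 2 * (founder_sizes[t - 1] if pop == "founder" else config.ancestral_size)
                    q = rng.binomial(n2, q) / n2
                freqs[t] = q
            out[pop].append(AlleleTrajectory(pop, spec.label, freqs))
    return out


def sample_genotypes(freqs, n: int, F: float = 0.0, rng=None, seed: int | None = None) -> np.ndarray:
    """Sample an (n x n_sites) dosage matrix under the Balding-Nichols model.

    Per site with alternate frequency q the genotype probabilities are

        hom-alt: q^2 + F q(1-q)
        het:     2 q(1-q) (1-F)
        hom-ref: (1-q)^2 + F q(1-q)

    F = 0 recovers Hardy-Weinberg proportions; F = 1 eliminates
    heterozygotes entirely.
    """
    if not 0.0 <= F <= 1.0:
        raise ConfigurationError("F must lie in [0,1]")
    q = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any((q < 0) | (q > 1)):
        raise ConfigurationError("allele frequencies must lie in [0,1]")
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    if rng is None:
        rng = stage_rng(0 if seed is None else seed, "genotypes")
    p2 = q * q + F * q * (1.0 - q)
    p1 = 2.0 * q * (1.0 - q) * (1.0 - F)
    u = rng.random((n, q.size))
    dos = np.zeros((n, q.size), dtype=np.int8)
    dos[u < p2[None, :]] = 2
    dos[(u >= p2[None, :]) & (u < (p2 + p1)[None, :])] = 1
    return dos


def _make_samples(population: str, n: int, rng) -> pd.DataFrame:
    sex = rng.integers(0, 2, size=n)  # 0 = male, 1 = female
    age = np.round(rng.uniform(25, 74, size=n), 1)
    return pd.DataFrame(
        {
            "sample_id": [f"{population[:3].upper()}{i:06d}" for i in range(n)],
            "sex": np.where(sex == 1, "female", "male"),
            "age": age,
            "population": population,
        }
    )


def _variant_table(trajectories: dict[str, list[AlleleTrajectory]]) -> pd.DataFrame:
    """Variant metadata with final frequencies of both populations, one row per site."""
    rows = []
    pos = 1000
    founder = {t.class_label: t for t in trajectories["founder"]}
    outbred = {t.class_label: t for t in trajectories["outbred"]}
    for label, traj_f in founder.items():
        traj_o = outbred[label]
        for j in range(traj_f.freqs.shape[1]):
            rows.append(
                {
                    "variant_id": f"{label}_{j}",
                    "chrom": "1",
                    "pos": pos,
                    "ref": "A",
                    "alt": "T",
                    "var_class": label,
                    "lof_hc": label in ("lof", "recessive_lethal"),
                    "q_founder": traj_f.final[j],
                    "q_outbred": traj_o.final[j],
                }
            )
            pos += 100
    return pd.DataFrame(rows)


def simulate_cohorts(config: SimConfig) -> dict[str, SyntheticCohort]:
    """Full generation pass: trajectories -> genotypes -> sample tables.

    Returns one SyntheticCohort per population, with per-population observed
    allele frequencies written back into the shared variant table
    (``af_founder`` / ``af_outbred`` columns). Phenotypes are attached
    separately by :func:`simulate_phenotypes`.
    """
    trajectories = simulate_trajectories(config)
    variants = _variant_table(trajectories)
    g_rng = stage_rng(config.seed, "genotypes")
    s_rng = stage_rng(config.seed, "samples")
    cohorts = {}
    for pop, n in config.sample_sizes.items():
        q = variants[f"q_{pop}"].to_numpy()
        dos = sample_genotypes(q, n, F=config.substructure_F, rng=g_rng)
        if config.missing_rate > 0:
            mask = g_rng.random(dos.shape) < config.missing_rate
            dos = np.where(mask, SyntheticCohort.MISSING, dos).astype(np.int8)
        cohort = SyntheticCohort(
            population=pop,
            samples=_make_samples(pop, n, s_rng),
            dosages=dos,
            variants=variants.copy(),
        )
        cohorts[pop] = cohort
    for pop, cohort in cohorts.items():
        af = cohort.allele_freqs()
        for c in cohorts.values():
            c.variants[f"af_{pop}"] = af
    return cohorts


def simulate_phenotypes(
    cohort: SyntheticCohort,
    effect_specs: list[EffectSpec],
    noise_sd: float = 1.0,
    age_beta: float = 0.01,
    sex_beta: float = 0.1,
    event_rate: float = 0.1,
    followup_years: float = 10.0,
    rng=None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Attach quantitative traits and a time-to-event outcome to a cohort.

    Each named trait is built as

        y = sum_v beta_v * dosage_v + age_beta*age + sex_beta*1[female] + N(0, noise_sd^2)

    so per-allele effects are in units of the residual SD. The disease is an
    exponential time-to-event whose log-hazard is the standardized trait
    value times ``trait_loghr`` plus any direct variant effects; the
    baseline hazard is calibrated so the marginal event probability within
    ``followup_years`` equals ``event_rate``, and censoring is
    administrative at ``followup_years``.
    """
    if rng is None:
        rng = stage_rng(cohort_seed_default(cohort) if seed is None else seed, "phenotypes")
    vid_to_col = {v: j for j, v in enumerate(cohort.variants["variant_id"])}
    traits = sorted({e.trait for e in effect_specs}) or ["trait_null"]
    for e in effect_specs:
        if e.variant not in vid_to_col:
            raise ConfigurationError(f"effect references unknown variant {e.variant!r}")

    n = cohort.n_samples
    age = cohort.samples["age"].to_numpy(dtype=float)
    female = (cohort.samples["sex"] == "female").to_numpy(dtype=float)
    pheno = cohort.samples[["sample_id", "sex", "age"]].copy()

    loghaz = np.zeros(n)
    for trait in traits:
        y = age_beta * age + sex_beta * female + rng.normal(0.0, noise_sd, size=n)
        for e in effect_specs:
            if e.trait != trait or e.beta == 0.0:
                continue
            d = cohort.dosages[:, vid_to_col[e.variant]].astype(float)
            d[d == SyntheticCohort.MISSING] = 0.0
            y = y + e.beta * d
        pheno[trait] = y
        z = (y - y.mean()) / y.std(ddof=0)
        for e in effect_specs:
            if e.trait == trait and e.trait_loghr != 0.0:
                loghaz = loghaz + e.trait_loghr * z
    for e in effect_specs:
        if e.direct_loghr != 0.0:
            d = cohort.dosages[:, vid_to_col[e.variant]].astype(float)
            d[d == SyntheticCohort.MISSING] = 0.0
            loghaz = loghaz + e.direct_loghr * d

    # calibrate baseline hazard: mean P(T < followup) over samples = event_rate
    rel = np.exp(loghaz)
    from scipy.optimize import brentq

    def event_frac(log_lam0):
        return np.mean(1.0 - np.exp(-np.exp(log_lam0) * rel * followup_years)) - event_rate

    log_lam0 = brentq(event_frac, -30, 5)
    lam = np.exp(log_lam0) * rel
    t_event = rng.exponential(1.0 / lam)
    event = t_event <= followup_years
    pheno["event"] = event.astype(int)
    pheno["time"] = np.where(event, t_event, followup_years)
    cohort.phenotypes = pheno
    return pheno


def cohort_seed_default(cohort: SyntheticCohort) -> int:
    # stable fallback when no explicit phenotype seed is given
    return int(cohort.n_samples + 7 * cohort.n_variants) % (2**31)
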