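"""Synthetic two-line + F1 data generator with exact theoretical truth.

Emulates the data structure of a crossbreeding study on litter size in
pigs: two unrelated pure lines in Hardy-Weinberg equilibrium with
line-specific allele frequencies, an F1 population receiving one gamete
from each line, biological additive and dominance SNP effects correlated
across the three populations, repeated records with permanent-environment
and residual noise, and a population-specific regression of the phenotype
on genomic homozygosity (directional dominance / inbreeding depression).

Markers are in linkage equilibrium within lines (independent loci) and
effects are uncorrelated across loci with Cov(a, d) = 0 within a
population — the assumptions of the multi-locus variance formulas — so
the theoretical variance components of every population are available in
closed form alongside the data.

Default parameter values mirror the litter-size application: phenotypic
means near 13 piglets, within-line additive variance near 0.9, dominance
a modest fraction of it, permanent-environment variances 0.4-0.9,
residual variance near 7, additive effects correlated ~0.8 across
populations and dominance effects ~0.5, inbreeding depression near -12
piglets per unit homozygosity, and 2-5 litter records per sow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix, homozygosity
from .locus import MultiLocusVariances, multilocus_f1_variances, pureline_variances

__all__ = ["SimConfig", "SimulationTruth", "simulate_population",
           "simulate_phenotypes", "simulate"]

POPULATIONS = ("P1", "P2", "F1")


def _corr(off: float) -> tuple:
    return ((1.0, off, off), (off, 1.0, off), (off, off, 1.0))


@dataclass
class SimConfig:
    """Generator settings; ``seed`` is mandatory for reproducibility."""

    seed: int
    m: int = 1000
    n1: int = 500
    n2: int = 500
    n12: int = 500
    beta_freq_1: tuple = (2.0, 2.0)
    beta_freq_2: tuple = (2.0, 2.0)
    freqs1: tuple | None = None  # explicit per-marker frequencies override the Beta draw
    freqs2: tuple | None = None
    sigma2_a: tuple = (2.25e-3, 2.25e-3, 2.25e-3)
    sigma2_d: tuple = (1.0e-3, 1.0e-3, 1.0e-3)
    corr_a: tuple = field(default_factory=lambda: _corr(0.8))
    corr_d: tuple = field(default_factory=lambda: _corr(0.5))
    mu: tuple = (12.7, 13.2, 13.6)
    beta_fho: tuple = (-12.9, -10.7, -11.8)
    perm_env: tuple = (0.63, 0.37, 0.94)
    residual: tuple = (7.0, 7.4, 6.8)
    records_min: int = 2
    records_max: int = 5
    parity_effects: tuple = (0.0, 0.4, 0.7, 0.9, 1.0)
    n_groups: int = 5
    group_sd: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("sigma2_a", "sigma2_d", "perm_env", "residual"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be non-negative")
        for name in ("corr_a", "corr_d"):
            C = np.asarray(getattr(self, name), float)
            if C.shape != (3, 3) or not np.allclose(np.diag(C), 1.0):
                raise ValueError(f"{name} must be 3x3 with unit diagonal")
            if np.linalg.eigvalsh(C).min() < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


@dataclass
class SimulationTruth:
    """True frequencies, effects and closed-form variance components."""

    p1: np.ndarray
    p2: np.ndarray
    a_effects: np.ndarray  # (3, m) per-population biological additive effects
    d_effects: np.ndarray
    sigma2_a: np.ndarray
    sigma2_d: np.ndarray
    f1: MultiLocusVariances
    var_A_pure1: float
    var_D_pure1: float
    var_A_pure2: float
    var_D_pure2: float

    def to_json(self, path) -> None:
        payload = {
            "p1": self.p1.tolist(),
            "p2": self.p2.tolist(),
            "a_effects": self.a_effects.tolist(),
            "d_effects": self.d_effects.tolist(),
            "sigma2_a": self.sigma2_a.tolist(),
            "sigma2_d": self.sigma2_d.tolist(),
            "f1": asdict(self.f1),
            "var_A_pure1": self.var_A_pure1,
            "var_D_pure1": self.var_D_pure1,
            "var_A_pure2": self.var_A_pure2,
            "var_D_pure2": self.var_D_pure2,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            p1=np.array(raw["p1"]), p2=np.array(raw["p2"]),
            a_effects=np.array(raw["a_effects"]),
            d_effects=np.array(raw["d_effects"]),
            sigma2_a=np.array(raw["sigma2_a"]),
            sigma2_d=np.array(raw["sigma2_d"]),
            f1=MultiLocusVariances(**raw["f1"]),
            var_A_pure1=raw["var_A_pure1"], var_D_pure1=raw["var_D_pure1"],
            var_A_pure2=raw["var_A_pure2"], var_D_pure2=raw["var_D_pure2"],
        )


def _theoretical_truth(p1, p2, a_eff, d_eff, s2a, s2d) -> SimulationTruth:
    f1 = multilocus_f1_variances(p1, p2, s2a[2], s2d[2])
    vA1, vD1 = pureline_variances(p1, s2a[0], s2d[0])
    vA2, vD2 = pureline_variances(p2, s2a[1], s2d[1])
    return SimulationTruth(
        p1=p1, p2=p2, a_effects=a_eff, d_effects=d_eff,
        sigma2_a=s2a, sigma2_d=s2d, f1=f1,
        var_A_pure1=vA1, var_D_pure1=vD1, var_A_pure2=vA2, var_D_pure2=vD2,
    )


def simulate_population(config: SimConfig, rng=None):
    """Draw genotypes for the two Hardy-Weinberg lines and the F1.

    Pure-line dosages are Binomial(2, p) per line; each F1 individual is
    Bernoulli(p) + Bernoulli(p'), one gamete from each line.  Returns the
    GenotypeMatrix and the SimulationTruth (frequencies, per-population
    SNP effects, and closed-form variance components).
    """
    rng = np.random.default_rng([config.seed, 0]) if rng is None else rng
    m = config.m
    p1 = rng.beta(*config.beta_freq_1, size=m)
    p2 = rng.beta(*config.beta_freq_2, size=m)
    if config.freqs1 is not None:
        p1 = np.broadcast_to(np.asarray(config.freqs1, float), (m,)).copy()
    if config.freqs2 is not None:
        p2 = np.broadcast_to(np.asarray(config.freqs2, float), (m,)).copy()
    if np.any((p1 < 0) | (p1 > 1)) or np.any((p2 < 0) | (p2 > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")

    g1 = rng.binomial(2, p1, size=(config.n1, m)).astype(float)
    g2 = rng.binomial(2, p2, size=(config.n2, m)).astype(float)
    g12 = (
        rng.binomial(1, p1, size=(config.n12, m))
        + rng.binomial(1, p2, size=(config.n12, m))
    ).astype(float)

    s2a = np.asarray(config.sigma2_a, float)
    s2d = np.asarray(config.sigma2_d, float)
    La = np.linalg.cholesky(np.asarray(config.corr_a) + 1e-12 * np.eye(3))
    Ld = np.linalg.cholesky(np.asarray(config.corr_d) + 1e-12 * np.eye(3))
    a_eff = np.sqrt(s2a)[:, None] * (La @ rng.standard_normal((3, m)))
    d_eff = np.sqrt(s2d)[:, None] * (Ld @ rng.standard_normal((3, m)))

    ns = (config.n1, config.n2, config.n12)
    ids = np.concatenate([
        np.array([f"{pop}_{i + 1:05d}" for i in range(n)], dtype=object)
        for pop, n in zip(POPULATIONS, ns)
    ])
    pops = np.concatenate([np.full(n, pop, dtype=object)
                           for pop, n in zip(POPULATIONS, ns)])
    geno = GenotypeMatrix(
        dosages=np.vstack([g1, g2, g12]),
        pop_labels=pops,
        individual_ids=ids,
        marker_ids=np.array([f"snp{j + 1:05d}" for j in range(m)], dtype=object),
    )
    return geno, _theoretical_truth(p1, p2, a_eff, d_eff, s2a, s2d)


def simulate_phenotypes(geno: GenotypeMatrix, truth: SimulationTruth,
                        config: SimConfig, rng=None) -> pd.DataFrame:
    """Repeated-record phenotypes from the biological-effect model.

    y = mu_pop + parity + group + beta_pop * F_Ho + Z a_pop + W d_pop
        + perm_env + residual,

    where Z, W are the {1,0,-1} and {0,1,0} codings of the individual's
    own genotypes and (a_pop, d_pop) its population's effect vectors;
    repeated records share the individual's permanent-environment draw.
    """
    rng = np.random.default_rng([config.seed, 1]) if rng is None else rng
    if geno.n_markers != truth.a_effects.shape[1]:
        raise ValueError("genotypes and truth have mismatched marker counts")
    pop_code = {p: k for k, p in enumerate(POPULATIONS)}
    popi = np.array([pop_code[p] for p in geno.pop_labels])

    Z = geno.dosages - 1.0
    W = (geno.dosages == 1.0).astype(float)
    if np.isnan(geno.dosages).any():
        raise ValueError("simulated genotypes must be complete")
    g = np.einsum("ij,ij->i", Z, truth.a_effects[popi]) + np.einsum(
        "ij,ij->i", W, truth.d_effects[popi])
    fho = homozygosity(geno)

    n = geno.n_individuals
    sp = np.asarray(config.perm_env, float)
    se = np.asarray(config.residual, float)
    pe = rng.normal(0.0, np.sqrt(sp[popi]))
    n_rec = rng.integers(config.records_min, config.records_max + 1, size=n)
    group_eff = rng.normal(0.0, config.group_sd, size=config.n_groups)

    rows = []
    mu = np.asarray(config.mu, float)
    bf = np.asarray(config.beta_fho, float)
    par_eff = np.asarray(config.parity_effects, float)
    for i in range(n):
        k = popi[i]
        for rec in range(n_rec[i]):
            parity = min(rec, len(par_eff) - 1)
            grp = rng.integers(config.n_groups)
            y = (mu[k] + par_eff[parity] + group_eff[grp] + bf[k] * fho[i]
                 + g[i] + pe[i] + rng.normal(0.0, np.sqrt(se[k])))
            rows.append((geno.individual_ids[i], geno.pop_labels[i],
                         parity + 1, f"g{grp + 1}", y))
    return pd.DataFrame(
        rows, columns=["individual_id", "population", "parity", "group", "phenotype"]
    )


def simulate(config: SimConfig):
    """Genotypes, truth and phenotypes from one seeded generator."""
    geno, truth = simulate_population(config)
    phen = simulate_phenotypes(geno, truth, config)
    return geno, truth, phen
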