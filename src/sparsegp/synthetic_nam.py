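"""Synthetic NAM population and phenotype generator.

Emulates the structure of a nested-association-mapping (NAM) soybean panel:
many bi-parental families sharing one hub parent, founders drawn from three
ancestry groups of increasing divergence from the hub, fully inbred RILs
(dosages in {0, 2}), and multi-environment yield phenotypes built from an
additive variance-component model with genomic main effects, genomic x
environment and family x environment interactions.

The simulator is deliberately simple: founders differ from the hub by
independent per-marker allele flips (group-specific probability), and each
RIL chromosome is a two-state hub/founder mosaic generated by a Markov chain
with a fixed per-adjacent-marker switch probability (no interference, no
genetic-map units). This is adequate to create family structure, ancestry
gradients and LD at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

VAR_KEYS = ("E", "L", "F", "g", "gE", "FE", "resid")

ANCESTRY_GROUPS = ("G1", "G2", "G3")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Parameters of one synthetic NAM population + phenotype draw."""

    n_families_g1: int = 16
    n_families_g2: int = 15
    n_families_g3: int = 8
    rils_per_family: int = 45
    n_markers: int = 1000
    n_chromosomes: int = 20
    recomb_prob: float = 0.1
    founder_divergence_g1: float = 0.15
    founder_divergence_g2: float = 0.30
    founder_divergence_g3: float = 0.45
    n_env: int = 9
    mu: float = 3500.0
    var_components: Mapping[str, float] = field(
        default_factory=lambda: {
            "E": 1.0, "L": 0.5, "F": 0.5, "g": 1.0,
            "gE": 0.5, "FE": 0.5, "resid": 1.0,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rils_per_family < 1:
            raise ConfigError("rils_per_family must be >= 1")
        if not 0.0 <= self.recomb_prob <= 0.5:
            raise ConfigError("recomb_prob must be in [0, 0.5]")
        for g in ("g1", "g2", "g3"):
            d = getattr(self, f"founder_divergence_{g}")
            if not 0.0 <= d <= 1.0:
                raise ConfigError(f"founder_divergence_{g} must be in [0, 1]")
        missing = [k for k in VAR_KEYS if k not in self.var_components]
        if missing:
            raise ConfigError(f"var_components missing keys: {missing}")
        for k in VAR_KEYS:
            if self.var_components[k] < 0:
                raise ConfigError(f"variance component {k!r} must be >= 0")
        if self.n_env < 1:
            raise ConfigError("n_env must be >= 1")
        if self.n_markers < 0:
            raise ConfigError("n_markers must be >= 0")

    @property
    def n_families(self) -> int:
        return self.n_families_g1 + self.n_families_g2 + self.n_families_g3

    @property
    def divergences(self) -> dict[str, float]:
        return {
            "G1": self.founder_divergence_g1,
            "G2": self.founder_divergence_g2,
            "G3": self.founder_divergence_g3,
        }


@dataclass
class NamPopulation:
    """Simulated RIL panel: genotypes plus family/ancestry provenance."""

    genotypes: np.ndarray          # (n_rils, p) dosages, {0, 2} when inbred
    ril_ids: list[str]
    family_ids: list[str]          # per RIL, parallel to ril_ids
    ancestry_of_family: dict[str, str]
    marker_map: pd.DataFrame       # columns: marker, chromosome, order
    hub: np.ndarray                # (p,) hub haplotype, alleles {0, 1}

    @property
    def n_rils(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.family_ids:
            seen.setdefault(f)
        return list(seen)

    def ancestry_of_ril(self) -> list[str]:
        return [self.ancestry_of_family[f] for f in self.family_ids]

    def family_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ril_id": self.ril_ids,
                "family_id": self.family_ids,
                "ancestry_group": self.ancestry_of_ril(),
            }
        )


@dataclass
class TrueEffects:
    """Realized random effects underlying one phenotype draw."""

    E: np.ndarray        # (J,)
    L: np.ndarray        # (n,)
    F: np.ndarray        # (m,) indexed by family order
    g: np.ndarray        # (n,)
    gE: np.ndarray       # (n, J)
    FE: np.ndarray       # (m, J)
    beta: np.ndarray     # (p_used,) marker effects behind g
    beta_env: np.ndarray  # (p_used, J) per-environment marker deviations
    family_order: list[str]


def chromosome_assignment(n_markers: int, n_chromosomes: int) -> np.ndarray:
    """Near-equal split of marker indices into chromosome labels (1-based)."""
    if n_markers == 0:
        return np.zeros(0, dtype=int)
    n_chromosomes = max(1, min(n_chromosomes, n_markers))
    return 1 + (np.arange(n_markers) * n_chromosomes) // n_markers


def make_marker_map(n_markers: int, n_chromosomes: int) -> pd.DataFrame:
    chrom = chromosome_assignment(n_markers, n_chromosomes)
    order = np.zeros(n_markers, dtype=int)
    for c in np.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        order[idx] = np.arange(len(idx))
    return pd.DataFrame(
        {
            "marker": [f"M{i + 1:05d}" for i in range(n_markers)],
            "chromosome": chrom,
            "order": order,
        }
    )


def simulate_founders(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Draw the hub haplotype and one founder haplotype per family.

    Returns ``(hub, founders, groups)`` where ``hub`` has shape ``(p,)`` with
    alleles in {0, 1}, ``founders`` has shape ``(n_families, p)`` and
    ``groups`` gives each founder's ancestry group. A founder in group ``Gx``
    carries the hub allele flipped independently per marker with probability
    ``founder_divergence_gx``, so expected hub-founder mismatch equals the
    divergence parameter.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.n_markers
    hub = rng.integers(0, 2, size=p, dtype=np.int8)
    counts = {
        "G1": config.n_families_g1,
        "G2": config.n_families_g2,
        "G3": config.n_families_g3,
    }
    founders = np.empty((config.n_families, p), dtype=np.int8)
    groups: list[str] = []
    row = 0
    for grp in ANCESTRY_GROUPS:
        div = config.divergences[grp]
        for _ in range(counts[grp]):
            flip = rng.random(p) < div
            founders[row] = np.where(flip, 1 - hub, hub)
            groups.append(grp)
            row += 1
    return hub, founders, groups


def simulate_ril_family(
    hub: np.ndarray,
    founder: np.ndarray,
    n_rils: int,
    chromosome: np.ndarray,
    recomb_prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate one family of inbred RILs as hub/founder chromosome mosaics.

    Per RIL and chromosome, a two-state Markov chain over marker positions
    chooses the parental origin: the state at the first marker is uniform,
    and the state switches between adjacent markers with probability
    ``recomb_prob``. Output dosages are ``2 * allele`` (fully inbred).
    """
    if not 0.0 <= recomb_prob <= 0.5:
        raise ConfigError("recomb_prob must be in [0, 0.5]")
    hub = np.asarray(hub, dtype=np.int8)
    founder = np.asarray(founder, dtype=np.int8)
    if hub.shape != founder.shape:
        raise ConfigError("hub and founder must cover the same markers")
    p = hub.shape[0]
    if p == 0:
        return np.zeros((n_rils, 0), dtype=np.int8)
    chromosome = np.asarray(chromosome)
    # event[i, j] toggles parental origin at marker j; chromosome starts get
    # a fresh uniform initial state instead of a recombination draw.
    is_start = np.ones(p, dtype=bool)
    is_start[1:] = chromosome[1:] != chromosome[:-1]
    event = rng.random((n_rils, p)) < recomb_prob
    event[:, is_start] = rng.random((n_rils, int(is_start.sum()))) < 0.5
    bounds = np.append(np.flatnonzero(is_start), p)
    state = np.empty((n_rils, p), dtype=bool)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        state[:, lo:hi] = np.logical_xor.accumulate(event[:, lo:hi], axis=1)
    allele = np.where(state, founder, hub)
    return (2 * allele).astype(np.int8)


def simulate_population(config: SimConfig) -> NamPopulation:
    """Full NAM panel: founders + per-family RIL mosaics, one call."""
    rng = np.random.default_rng(config.seed)
    hub, founders, groups = simulate_founders(config, rng)
    marker_map = make_marker_map(config.n_markers, config.n_chromosomes)
    chrom = marker_map["chromosome"].to_numpy()
    blocks, ril_ids, family_ids = [], [], []
    ancestry: dict[str, str] = {}
    for k in range(config.n_families):
        fam = f"F{k + 1:02d}"
        ancestry[fam] = groups[k]
        block = simulate_ril_family(
            hub, founders[k], config.rils_per_family, chrom, config.recomb_prob, rng
        )
        blocks.append(block)
        ril_ids.extend(f"{fam}_R{i + 1:03d}" for i in range(config.rils_per_family))
        family_ids.extend([fam] * config.rils_per_family)
    genotypes = (
        np.vstack(blocks)
        if blocks
        else np.zeros((0, config.n_markers), dtype=np.int8)
    )
    return NamPopulation(genotypes, ril_ids, family_ids, ancestry, marker_map, hub)


def _standardize_columns(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale columns (divisor n); returns (X, kept_column_indices)."""
    X = np.asarray(dosages, dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = np.flatnonzero(sd > 0)
    Xs = (X[:, keep] - mean[keep]) / sd[keep]
    return Xs, keep


def simulate_phenotypes(
    pop: NamPopulation, config: SimConfig
) -> tuple[pd.DataFrame, TrueEffects]:
    """Draw one fully balanced phenotype table under the additive model.

    y[i, j] = mu + E_j + L_i + F_k(i) + g_i + gE_ij + FE_k(i)j + eps_ij with
    every component drawn independently at its configured variance. The
    genomic main effect is g = X beta with X the centered/standardized
    dosage matrix and beta ~ N(0, var_g / p); gE stacks environment-specific
    marker-effect deviations built the same way at variance var_gE.
    """
    if pop.n_rils == 0:
        raise ConfigError("population is empty")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(config.seed), 0x9E3779B9])
    )
    v = config.var_components
    n, J = pop.n_rils, config.n_env
    families = pop.families
    m = len(families)
    fam_index = {f: k for k, f in enumerate(families)}
    fam_of_ril = np.array([fam_index[f] for f in pop.family_ids])

    Xs, kept = _standardize_columns(pop.genotypes)
    p_used = max(1, Xs.shape[1])

    E = rng.normal(0.0, np.sqrt(v["E"]), size=J)
    L = rng.normal(0.0, np.sqrt(v["L"]), size=n)
    F = rng.normal(0.0, np.sqrt(v["F"]), size=m)
    beta = rng.normal(0.0, np.sqrt(v["g"] / p_used), size=Xs.shape[1])
    g = Xs @ beta if Xs.shape[1] else np.zeros(n)
    beta_env = rng.normal(0.0, np.sqrt(v["gE"] / p_used), size=(Xs.shape[1], J))
    gE = Xs @ beta_env if Xs.shape[1] else np.zeros((n, J))
    FE = rng.normal(0.0, np.sqrt(v["FE"]), size=(m, J))
    eps = rng.normal(0.0, np.sqrt(v["resid"]), size=(n, J))

    y = (
        config.mu
        + E[None, :]
        + L[:, None]
        + F[fam_of_ril, None]
        + g[:, None]
        + gE
        + FE[fam_of_ril, :]
        + eps
    )

    ancestry = pop.ancestry_of_ril()
    records = pd.DataFrame(
        {
            "ril_id": np.repeat(pop.ril_ids, J),
            "family_id": np.repeat(pop.family_ids, J),
            "ancestry_group": np.repeat(ancestry, J),
            "env_id": np.tile([f"env{j + 1}" for j in range(J)], n),
            "value": y.ravel(),
            "observed": True,
        }
    )
    effects = TrueEffects(
        E=E, L=L, F=F, g=g, gE=gE, FE=FE,
        beta=beta, beta_env=beta_env, family_order=families,
    )
    return records, effects


def simulate_dataset(config: SimConfig) -> tuple[NamPopulation, pd.DataFrame, TrueEffects]:
    """Convenience wrapper: population + phenotypes in one call."""
    pop = simulate_population(config)
    pheno, effects = simulate_phenotypes(pop, config)
    return pop, pheno, effects
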