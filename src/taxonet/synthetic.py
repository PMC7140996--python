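"""Synthetic plant-pollinator networks with a taxonomic hierarchy.

The generator emulates the statistical shape of literature plant-pollinator
studies: between 7 and 135 plant and 12 and 144 pollinator taxa per
network, roughly a quarter of networks binary and the rest count-weighted,
heterogeneous nested-leaning degree distributions, and a species -> genus
-> family hierarchy with at least two families per guild.

Interactions follow an abundance-rank model: plant i and pollinator j
carry abundance ranks a_i, b_j in (0, 1) ordered generalist-first, and the
presence probability is the mixture

    p_ij = (1 - s) * rho + s * sigmoid(kappa * (a_i + b_j - theta))

where ``s`` is the nestedness-strength knob, ``rho`` a per-network target
connectance, and ``theta`` is set so both mixture components have expected
fill rho.  ``kappa`` grows without bound as s -> 1, hence strength 1
yields a nested staircase while strength 0 yields independent
Bernoulli(rho) cells.
Counts, where the network is weighted, are drawn conditional on presence
from a shifted negative binomial so binarization is well defined and
weights are over-dispersed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import BipartiteNetwork, NetworkError, TaxonomyTable, TaxonRecord


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-level knobs; defaults emulate the 41-network literature corpus."""

    n_networks: int = 41
    plants_range: tuple[int, int] = (7, 135)
    pollinators_range: tuple[int, int] = (12, 144)
    fraction_binary: float = 10 / 41
    families_range: tuple[int, int] = (3, 10)
    mean_genera_per_family: float = 2.5
    mean_species_per_genus: float = 2.0
    nestedness_strength: float = 0.6
    connectance_range: tuple[float, float] = (0.07, 0.30)
    count_mean: float = 5.0
    count_dispersion: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.plants_range, self.pollinators_range,
                       self.families_range):
            if not (0 < lo <= hi):
                raise NetworkError("invalid range in generator config")
        if not 0 <= self.fraction_binary <= 1:
            raise NetworkError("fraction_binary must be in [0, 1]")
        if not 0 <= self.nestedness_strength <= 1:
            raise NetworkError("nestedness_strength must be in [0, 1]")
        if self.families_range[0] < 2:
            raise NetworkError("each guild needs at least 2 families")


def _truncated_geometric_sizes(rng, total: int, mean: float) -> list[int]:
    """Right-skewed group sizes >= 1 summing exactly to ``total``."""
    p = 1.0 / max(mean, 1.0)
    sizes: list[int] = []
    left = total
    while left > 0:
        s = min(int(rng.geometric(p)), left)
        sizes.append(s)
        left -= s
    return sizes


def _build_guild_taxonomy(rng, n_species: int, prefix: str,
                          cfg: GeneratorConfig) -> dict[str, TaxonRecord]:
    fmin, fmax = cfg.families_range
    if n_species < fmin:
        raise NetworkError(
            f"cannot place {n_species} species into at least {fmin} families"
        )
    n_fam = int(rng.integers(fmin, min(fmax, n_species) + 1))
    genus_sizes = _truncated_geometric_sizes(rng, n_species,
                                             cfg.mean_species_per_genus)
    while len(genus_sizes) < n_fam:  # need >= one genus per family
        big = int(np.argmax(genus_sizes))
        genus_sizes[big] -= 1
        genus_sizes.append(1)
    # every family gets one genus, the rest are assigned at random
    n_gen = len(genus_sizes)
    fam_of_genus = np.concatenate(
        [np.arange(n_fam), rng.integers(0, n_fam, size=n_gen - n_fam)]
    )
    rng.shuffle(fam_of_genus)
    mapping: dict[str, TaxonRecord] = {}
    sp = 0
    for g, size in enumerate(genus_sizes):
        genus = f"{prefix}gen{g:03d}"
        family = f"{prefix}fam{fam_of_genus[g]:02d}"
        for _ in range(size):
            mapping[f"{prefix}sp{sp:03d}"] = TaxonRecord(
                genus=genus, family=family, species_resolved=True
            )
            sp += 1
    return mapping


def _log_uniform_int(rng, lo: int, hi: int) -> int:
    return int(round(np.exp(rng.uniform(np.log(lo), np.log(hi)))))


def _presence_matrix(rng, r: int, c: int, strength: float, rho: float) -> np.ndarray:
    from scipy.special import expit

    # abundance ranks, generalists first; the nested component thresholds
    # a_i + b_j, so its support is a linear staircase with expected fill rho
    a = (r - np.arange(r) - 0.5) / r
    b = (c - np.arange(c) - 0.5) / c
    theta = 2.0 - np.sqrt(2.0 * min(rho, 0.5))
    kappa = 6.0 / (1.0 - 0.999 * strength)
    nested = expit(kappa * (a[:, None] + b[None, :] - theta))
    p = (1.0 - strength) * rho + strength * nested
    m = (rng.random((r, c)) < p).astype(float)
    # no all-zero lines: give empty taxa their single most plausible partner
    for i in np.flatnonzero(m.sum(axis=1) == 0):
        m[i, int(np.argmax(p[i]))] = 1.0
    for j in np.flatnonzero(m.sum(axis=0) == 0):
        m[int(np.argmax(p[:, j])), j] = 1.0
    return m


def generate_network(
    cfg: GeneratorConfig, index: int, weighted: bool | None = None
) -> tuple[BipartiteNetwork, TaxonomyTable]:
    """Generate one species-level network plus its taxonomy.

    ``index`` selects an independent, reproducible random substream of the
    config seed.  ``weighted`` overrides the per-network coin flip on
    matrix kind (the study driver uses it to pin the binary/weighted mix).
    """
    rng = np.random.default_rng([cfg.seed, index])
    r = _log_uniform_int(rng, *cfg.plants_range)
    c = _log_uniform_int(rng, *cfg.pollinators_range)
    if weighted is None:
        weighted = rng.random() >= cfg.fraction_binary
    rho = float(
        np.exp(rng.uniform(*np.log(np.array(cfg.connectance_range))))
    )
    m = _presence_matrix(rng, r, c, cfg.nestedness_strength, rho)
    if weighted:
        mu = max(cfg.count_mean - 1.0, 0.1)
        size = cfg.count_dispersion
        counts = 1 + rng.negative_binomial(size, size / (size + mu), m.shape)
        m = m * counts

    plants = _build_guild_taxonomy(rng, r, "P", cfg)
    polls = _build_guild_taxonomy(rng, c, "A", cfg)
    net = BipartiteNetwork(
        matrix=m,
        row_labels=tuple(plants),
        col_labels=tuple(polls),
        weighted=weighted,
        level="species",
        name=f"synthetic_{index:03d}",
    )
    return net, TaxonomyTable(plants=plants, pollinators=polls)


def generate_study(
    cfg: GeneratorConfig,
) -> list[tuple[BipartiteNetwork, TaxonomyTable]]:
    """Generate the full study corpus with an exact binary/weighted split."""
    n_binary = int(round(cfg.fraction_binary * cfg.n_networks))
    rng = np.random.default_rng([cfg.seed, 10**6])
    kinds = np.array([False] * n_binary + [True] * (cfg.n_networks - n_binary))
    rng.shuffle(kinds)
    return [
        generate_network(cfg, i, weighted=bool(kinds[i]))
        for i in range(cfg.n_networks)
    ]
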