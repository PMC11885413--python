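"""Two-locus genetics of the underdominance drive.

The drive consists of two unlinked constructs: each carries a toxin
targeting the other locus and an antidote rescuing its own, so offspring
are viable only if they carry at least one drive allele at *both* loci —
or none at all (wild type). With drive alleles A, B and wild-type alleles
a, b this yields nine genotypes, ordered AABB .. aabb. Genotypes AAbb,
Aabb, aaBB and aaBb are killed by an unsuppressed toxin and have fitness
zero; the remaining genotypes combine per-locus fitness factors
multiplicatively.

Mating is panmictic: offspring genotype frequencies follow from random
union of gametes drawn from a common, density-weighted gamete pool, with
free recombination between the loci.

All array operations accept a trailing genotype axis of length 9 and
broadcast over any leading axes, so a whole batch of populations can be
advanced at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "GENOTYPE_LABELS",
    "GAMETE_LABELS",
    "GENOTYPES",
    "Genotype",
    "FitnessParams",
    "N_GENOTYPES",
    "WILD_TYPE",
    "LETHAL",
    "LOCUS_SWAP",
    "gamete_distribution",
    "population_gamete_pool",
    "offspring_densities",
    "fitness_table",
    "partition",
]

N_GENOTYPES = 9

#: Genotype labels in canonical order (index 0 = AABB drive homozygote,
#: index 8 = aabb wild type).
GENOTYPE_LABELS = (
    "AABB", "AABb", "AAbb",
    "AaBB", "AaBb", "Aabb",
    "aaBB", "aaBb", "aabb",
)

#: Gamete types in canonical order.
GAMETE_LABELS = ("AB", "Ab", "aB", "ab")

#: Index of the wild-type genotype aabb.
WILD_TYPE = 8

#: Indices of the four genotypes killed by an unsuppressed toxin
#: (AAbb, Aabb, aaBB, aaBb).
LETHAL = (2, 5, 6, 7)

#: Permutation of genotype indices induced by exchanging the roles of the
#: two loci (A<->B, a<->b).
LOCUS_SWAP = (0, 3, 6, 1, 4, 7, 2, 5, 8)


class Genotype(NamedTuple):
    """One of the nine genotypes.

    Attributes
    ----------
    index : 0-based position in the canonical ordering.
    locus_a, locus_b : number of drive alleles (0, 1 or 2) at each locus.
    label : four-letter genotype string, e.g. ``"AaBb"``.
    """

    index: int
    locus_a: int
    locus_b: int
    label: str


GENOTYPES = tuple(
    Genotype(i, 2 - i // 3, 2 - i % 3, GENOTYPE_LABELS[i]) for i in range(N_GENOTYPES)
)

# Drive-allele count of each gamete type, matching GAMETE_LABELS.
_GAMETE_A = np.array([1, 1, 0, 0])
_GAMETE_B = np.array([1, 0, 1, 0])


def _gamete_shares() -> np.ndarray:
    """(9, 4) matrix of gamete frequencies emitted by each genotype."""
    shares = np.empty((N_GENOTYPES, 4))
    for g in GENOTYPES:
        pa = g.locus_a / 2.0  # probability a gamete carries A
        pb = g.locus_b / 2.0
        shares[g.index] = (
            np.where(_GAMETE_A == 1, pa, 1.0 - pa)
            * np.where(_GAMETE_B == 1, pb, 1.0 - pb)
        )
    return shares


#: (9, 4): row i is the gamete distribution of genotype i.
_SHARES = _gamete_shares()


def _union_map() -> np.ndarray:
    """(9, 16) map from ordered gamete pairs to offspring genotypes."""
    m = np.zeros((N_GENOTYPES, 16))
    for j in range(4):
        for k in range(4):
            ca = _GAMETE_A[j] + _GAMETE_A[k]
            cb = _GAMETE_B[j] + _GAMETE_B[k]
            m[(2 - ca) * 3 + (2 - cb), j * 4 + k] = 1.0
    return m


_UNION = _union_map()


def gamete_distribution(genotype: Genotype | int | str) -> np.ndarray:
    """Gamete frequencies (AB, Ab, aB, ab) produced by one genotype.

    Each locus contributes its drive allele with probability 1, 1/2 or 0
    for allele counts 2, 1 and 0; the loci assort independently, so the
    two-locus gamete frequency is the product of per-locus contributions.
    """
    if isinstance(genotype, str):
        idx = GENOTYPE_LABELS.index(genotype)
    elif isinstance(genotype, Genotype):
        idx = genotype.index
    else:
        idx = int(genotype)
    return _SHARES[idx].copy()


def population_gamete_pool(densities: np.ndarray) -> np.ndarray:
    """Density-weighted gamete pool of a panmictic population.

    Parameters
    ----------
    densities : array of 9 genotype densities.

    Returns
    -------
    (4,) gamete frequencies summing to one.

    Raises
    ------
    ValueError : if the population is empty (no parents) or any density
        is negative.
    """
    n = np.asarray(densities, dtype=float)
    _check_densities(n)
    total = n.sum()
    if total <= 0.0:
        raise ValueError("empty population: no parents to form a gamete pool")
    return (n @ _SHARES) / total


def offspring_densities(densities: np.ndarray) -> np.ndarray:
    """Offspring densities nu_i from random union of pooled gametes.

    The offspring genotype frequencies are the random-union products of
    the population gamete pool (e.g. the double heterozygote arises as
    ``2*g_AB*g_ab + 2*g_Ab*g_aB``) and are scaled so that total offspring
    density equals total parental density exactly — lethal genotypes are
    produced here and only removed by their zero fitness at birth.

    Accepts a batch with the genotype axis last; an empty population maps
    to all-zero offspring.
    """
    n = np.asarray(densities, dtype=float)
    _check_densities(n)
    total = n.sum(axis=-1, keepdims=True)
    safe = np.where(total > 0.0, total, 1.0)
    pool = (n @ _SHARES) / safe  # (..., 4)
    pairs = (pool[..., :, None] * pool[..., None, :]).reshape(*pool.shape[:-1], 16)
    freq = pairs @ _UNION.T  # (..., 9)
    return np.where(total > 0.0, total * freq, 0.0)


def _check_densities(n: np.ndarray) -> None:
    if n.shape[-1] != N_GENOTYPES:
        raise ValueError(f"expected {N_GENOTYPES} genotype densities, got shape {n.shape}")
    if np.any(n < 0.0):
        raise ValueError("genotype densities must be non-negative")


@dataclass(frozen=True)
class FitnessParams:
    """Fitness costs and dominance of the two drive constructs.

    s_a, s_b : homozygous fitness cost of the construct at each locus,
        in [0, 1] (0 = as fit as wild type, 1 = lethal).
    h_a, h_b : dominance of the cost in heterozygotes, in [0, 1]
        (0 = recessive, 1 = dominant).
    """

    s_a: float = 0.0
    s_b: float = 0.0
    h_a: float = 0.5
    h_b: float = 0.5

    def __post_init__(self) -> None:
        for name in ("s_a", "s_b", "h_a", "h_b"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    @classmethod
    def symmetric(cls, s: float, h: float) -> "FitnessParams":
        """Equal cost and dominance at both loci."""
        return cls(s_a=s, s_b=s, h_a=h, h_b=h)

    def swapped(self) -> "FitnessParams":
        """Parameters with the roles of the two loci exchanged."""
        return FitnessParams(s_a=self.s_b, s_b=self.s_a, h_a=self.h_b, h_b=self.h_a)


def fitness_table(params: FitnessParams) -> np.ndarray:
    """Relative fitness psi_i of the nine genotypes.

    Per-locus factors are 1, (1 - h*s) and (1 - s) for 0, 1 and 2 drive
    alleles; a genotype's fitness is the product across the two loci.
    The four toxin-killed genotypes get fitness zero regardless of the
    parameters; the wild type has fitness one.
    """
    wa = np.array([1.0 - params.s_a, 1.0 - params.h_a * params.s_a, 1.0])
    wb = np.array([1.0 - params.s_b, 1.0 - params.h_b * params.s_b, 1.0])
    psi = np.array([wa[2 - g.locus_a] * wb[2 - g.locus_b] for g in GENOTYPES])
    psi[list(LETHAL)] = 0.0
    return psi


def partition(densities: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split a state into (wild-type, drive-carrying, total) densities.

    Wild type is the aabb class; everything else carries at least one
    drive allele. The three values satisfy wild + drive == total exactly.
    """
    n = np.asarray(densities, dtype=float)
    total = n.sum(axis=-1)
    wild = n[..., WILD_TYPE]
    return wild, total - wild, total
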