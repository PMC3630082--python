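"""Model parameters and genotype fitness tables.

The model follows two X-linked (or X + autosomal) biallelic loci.  Locus A
(the "fitness locus") carries alleles A1/A2 that affect male and female
fitness directly.  Locus B (the "modifier locus") is phenotypically silent
except that the female modifier genotype sets the probability ``xi`` with
which each somatic cell lineage silences the paternally inherited X.

Female fitness declines with the fraction ``x`` of cells expressing the
female-deleterious allele A1 through a power function ``w(x) = 1 - x**k * s_f``.
Evaluated at the silencing probabilities this induces parent-of-origin
dominance coefficients ``h_mat = xi**k`` (A1 maternally inherited) and
``h_pat = (1 - xi)**k`` (A1 paternally inherited).  Under unbiased random
X inactivation (xi = 1/2) both collapse to the ordinary dominance
coefficient ``h = (1/2)**k``; ``h`` is the user-facing parameter and
``k = -ln(h)/ln(2)``.

Haplotype index convention, used package-wide::

    0 = A1 B1,  1 = A2 B1,  2 = A1 B2,  3 = A2 B2

In every female genotype ordering the maternally inherited haplotype is
listed first.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

__all__ = [
    "VariationMode",
    "SelectionScheme",
    "InactivationPolicy",
    "DominancePair",
    "FitnessTables",
    "power_fitness",
    "k_from_h",
    "dominance_pair",
    "build_fitness_tables",
    "HAPLOTYPES",
    "MODIFIER_GENOTYPES",
]

#: haplotype labels in index order (A allele, B allele)
HAPLOTYPES = ("A1B1", "A2B1", "A1B2", "A2B2")

#: female modifier genotypes in index order
MODIFIER_GENOTYPES = ("B1B1", "B1B2", "B2B2")

# A allele carried by each haplotype: True where the haplotype carries A1
_CARRIES_A1 = np.array([True, False, True, False])
# B allele carried by each haplotype: 0 for B1, 1 for B2
_B_ALLELE = np.array([0, 0, 1, 1])


class VariationMode(str, Enum):
    """How fitness variation is maintained at the A locus."""

    DELETERIOUS = "deleterious"  # mutation-selection balance, A1 costly to both sexes
    SEXUALLY_ANTAGONISTIC = "sexually_antagonistic"  # A1 costly to females, A2 to males


@dataclass(frozen=True)
class SelectionScheme:
    """Selection, dominance and mutation parameters at the A locus.

    Parameters
    ----------
    mode
        ``deleterious`` (A1 deleterious to both sexes, maintained at
        mutation-selection balance) or ``sexually_antagonistic`` (A1
        deleterious to females, A2 deleterious to males, maintained as a
        balanced polymorphism).
    s_f
        Fitness cost to females homozygous or effectively haploid for A1.
    s_m
        Fitness cost to males carrying A1 (deleterious mode only).
    t_m
        Fitness cost to males carrying A2 (sexually antagonistic mode only).
    h
        Dominance (masking) coefficient of A1 in females practicing
        unbiased random X inactivation.
    u_f, u_m
        Per-gamete mutation rates A2 -> A1 in eggs and sperm.  Ignored
        (forced to zero) in sexually antagonistic mode, where recurrent
        mutation only marginally perturbs the balanced polymorphism.
    """

    mode: VariationMode
    s_f: float
    h: float
    s_m: float | None = None
    t_m: float | None = None
    u_f: float = 0.0
    u_m: float = 0.0

    def __post_init__(self) -> None:
        mode = VariationMode(self.mode)
        object.__setattr__(self, "mode", mode)
        if not 0.0 < self.s_f < 1.0:
            raise ValueError(f"s_f must lie in (0, 1); got {self.s_f}")
        if not 0.0 < self.h < 1.0:
            raise ValueError(f"h must lie in (0, 1); got {self.h}")
        if mode is VariationMode.DELETERIOUS:
            if self.s_m is None or self.t_m is not None:
                raise ValueError("deleterious mode requires s_m and forbids t_m")
            if not 0.0 <= self.s_m < 1.0:
                raise ValueError(f"s_m must lie in [0, 1); got {self.s_m}")
            if self.u_f < 0 or self.u_m < 0:
                raise ValueError("mutation rates must be nonnegative")
            u_max = max(self.u_f, self.u_m)
            if u_max > 0 and u_max >= self.s_f * self.h / 10.0:
                warnings.warn(
                    "mutation rate is not small relative to selection "
                    f"(u={u_max:g} vs s_f*h/10={self.s_f * self.h / 10:g}); "
                    "weak-mutation approximations may degrade",
                    stacklevel=2,
                )
        else:
            if self.t_m is None or self.s_m is not None:
                raise ValueError(
                    "sexually antagonistic mode requires t_m and forbids s_m"
                )
            if not 0.0 < self.t_m < 1.0:
                raise ValueError(f"t_m must lie in (0, 1); got {self.t_m}")
            if self.u_f != 0.0 or self.u_m != 0.0:
                warnings.warn(
                    "mutation is ignored in sexually antagonistic mode; "
                    "forcing u_f = u_m = 0",
                    stacklevel=2,
                )
                object.__setattr__(self, "u_f", 0.0)
                object.__setattr__(self, "u_m", 0.0)

    @property
    def k(self) -> float:
        """Fitness-shape exponent implied by ``h``."""
        return k_from_h(self.h)

    def male_fitness(self) -> np.ndarray:
        """Length-4 male fitness vector ``m_i`` over haplotypes.

        Male fitness depends only on the A allele of the (maternally
        inherited) X haplotype.
        """
        if self.mode is VariationMode.DELETERIOUS:
            cost = np.where(_CARRIES_A1, 1.0 - self.s_m, 1.0)
        else:
            cost = np.where(_CARRIES_A1, 1.0, 1.0 - self.t_m)
        return cost.astype(float)


def k_from_h(h: float) -> float:
    """Exponent ``k`` of the power fitness function such that ``(1/2)**k = h``.

    ``k > 1`` iff ``h < 1/2`` (partial recessivity of A1).
    """
    if not 0.0 < h < 1.0:
        raise ValueError(f"h must lie in (0, 1); got {h}")
    return -math.log(h) / math.log(2.0)


def power_fitness(x_expr: float, scheme: SelectionScheme, k: float | None = None) -> float:
    """Female fitness ``1 - x_expr**k * s_f`` for A1 expressed in a fraction
    ``x_expr`` of cells.

    ``k`` defaults to the exponent implied by ``scheme.h``.
    """
    if not 0.0 <= x_expr <= 1.0:
        raise ValueError(f"x_expr must lie in [0, 1]; got {x_expr}")
    if k is None:
        k = scheme.k
    return 1.0 - _pow(x_expr, k) * scheme.s_f


def _pow(base: float, exponent: float) -> float:
    # explicit branch so that 0**0 == 1 and 0**k == 0 without relying on
    # float pow conventions at the boundary
    if base == 0.0:
        return 1.0 if exponent == 0.0 else 0.0
    return base ** exponent


@dataclass(frozen=True)
class DominancePair:
    """Effective parent-of-origin dominance coefficients of A1."""

    h_mat: float
    h_pat: float


def dominance_pair(xi: float, k: float) -> DominancePair:
    """Dominance coefficients induced by silencing the paternal X with
    probability ``xi``: ``h_mat = xi**k``, ``h_pat = (1-xi)**k``."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"xi must lie in [0, 1]; got {xi}")
    if k < 0:
        raise ValueError(f"k must be nonnegative; got {k}")
    return DominancePair(h_mat=_pow(xi, k), h_pat=_pow(1.0 - xi, k))


def _default_xi22(xi_11: float, xi_12: float) -> float:
    # additive-on-xi extrapolation for the B2 homozygote, clipped to [0, 1];
    # invasion analysis never touches it but forward simulation past rarity does
    return float(np.clip(2.0 * xi_12 - xi_11, 0.0, 1.0))


@dataclass(frozen=True)
class InactivationPolicy:
    """Paternal-X silencing probabilities per female modifier genotype.

    ``xi = 1`` encodes strict paternal X inactivation (PXI); ``xi = 1/2``
    unbiased random X inactivation (RXI).  ``k`` is the fitness-shape
    exponent, normally derived from a scheme's ``h``.
    """

    xi_11: float
    xi_12: float
    k: float
    xi_22: float | None = None

    def __post_init__(self) -> None:
        for name in ("xi_11", "xi_12"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")
        if self.k <= 0:
            raise ValueError(f"k must be positive; got {self.k}")
        if self.xi_22 is None:
            object.__setattr__(self, "xi_22", _default_xi22(self.xi_11, self.xi_12))
        elif not 0.0 <= self.xi_22 <= 1.0:
            raise ValueError(f"xi_22 must lie in [0, 1]; got {self.xi_22}")

    @classmethod
    def from_scheme(
        cls,
        scheme: SelectionScheme,
        xi_11: float,
        xi_12: float | None = None,
        xi_22: float | None = None,
    ) -> "InactivationPolicy":
        """Build a policy with ``k`` derived from ``scheme.h``.

        ``xi_12`` defaults to ``xi_11`` (a phenotypically silent modifier).
        """
        if xi_12 is None:
            xi_12 = xi_11
        return cls(xi_11=xi_11, xi_12=xi_12, k=scheme.k, xi_22=xi_22)

    def xi_for(self, genotype: str | int) -> float:
        """Silencing probability of a female modifier genotype.

        Accepts ``"B1B1"``/``"B1B2"``/``"B2B2"`` or the index 0/1/2.
        """
        if isinstance(genotype, str):
            genotype = MODIFIER_GENOTYPES.index(genotype)
        return (self.xi_11, self.xi_12, self.xi_22)[genotype]

    def dominance(self, genotype: str | int) -> DominancePair:
        return dominance_pair(self.xi_for(genotype), self.k)


@dataclass(frozen=True)
class FitnessTables:
    """Genotype fitness lookup used by the recursions.

    ``f[i, j]`` is the fitness of a female with maternal haplotype ``i`` and
    paternal haplotype ``j``; ``m[i]`` the fitness of a male carrying
    haplotype ``i``.  The female entry depends on the A alleles of the two
    haplotypes (with parent of origin) and, through the silencing
    probability, on the modifier genotype implied by the B alleles.
    """

    f: np.ndarray = field(repr=False)
    m: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        f = np.asarray(self.f, dtype=float)
        m = np.asarray(self.m, dtype=float)
        if f.shape != (4, 4) or m.shape != (4,):
            raise ValueError("f must be 4x4 and m length 4")
        if np.any(f <= 0) or np.any(f > 1) or np.any(m <= 0) or np.any(m > 1):
            raise ValueError("all fitnesses must lie in (0, 1]")
        object.__setattr__(self, "f", f)
        object.__setattr__(self, "m", m)


def _female_fitness(scheme: SelectionScheme, xi: float, mat_is_a1: bool, pat_is_a1: bool) -> float:
    k = scheme.k
    if mat_is_a1 and pat_is_a1:
        return 1.0 - scheme.s_f
    if mat_is_a1:  # A1 expressed in cells keeping the maternal X active
        return 1.0 - _pow(xi, k) * scheme.s_f
    if pat_is_a1:
        return 1.0 - _pow(1.0 - xi, k) * scheme.s_f
    return 1.0


def build_fitness_tables(
    scheme: SelectionScheme, policy: InactivationPolicy
) -> FitnessTables:
    """Full two-locus fitness tables ``f_ij`` (females) and ``m_i`` (males).

    The female modifier genotype is read off the B alleles of the two
    haplotypes; its silencing probability sets the parent-of-origin
    dominance of A1 through the power fitness function.
    """
    f = np.empty((4, 4), dtype=float)
    for i in range(4):
        for j in range(4):
            genotype = _B_ALLELE[i] + _B_ALLELE[j]  # 0, 1 or 2 copies of B2
            xi = policy.xi_for(genotype)
            f[i, j] = _female_fitness(scheme, xi, _CARRIES_A1[i], _CARRIES_A1[j])
    return FitnessTables(f=f, m=scheme.male_fitness())
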