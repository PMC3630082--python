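"""Evolutionarily stable inactivation ratios and mean-fitness accounting.

An inactivation strategy ``xi`` (probability of silencing the paternal
X) is evolutionarily stable when no rare modifier that shifts the ratio
can invade.  Operationally the selection gradient at a resident ``xi``
is ``lambda(xi_11=xi, xi_12=xi+delta) - 1`` with a small strategy
perturbation ``delta`` (default 1e-3); the ESS is its zero.

Closed forms (valid for partially recessive variation, ``h < 1/2``,
writing ``e = -ln(2)/ln(2h) > 0``):

* **Sexually antagonistic polymorphism**: at the interior equilibrium
  the odds that a deleterious A1 arrives paternally rather than
  maternally are ``q_m (1-q_f) / (q_f (1-q_m)) = 1/(1-t_m)`` exactly,
  giving::

      xi* = 1 / (1 + (1 - t_m)**e)

  which always exceeds 1/2: selection favors preferential silencing of
  the paternally inherited X, increasingly so for larger ``t_m`` or ``h``.

* **Mutation-selection balance**: the ESS solves the self-consistency
  condition ``xi/(1-xi) = R(xi)**e`` where
  ``R(xi) = q_m (1-q_f) / (q_f (1-q_m))`` is evaluated at the balance
  frequencies under resident ``xi``.  Assuming ``s_f h << 1`` the ratio
  simplifies to ``R ~= 1 - (2/3)(s_m - s_f h)`` (with ``u_f = u_m``), so
  the maternal X is preferentially silenced (``xi* < 1/2``) exactly when
  ``s_m > s_f h``: deleterious alleles then arrive disproportionately
  via eggs.

Mean-fitness bookkeeping across the PXI -> unbiased-RXI transition
compares the two monomorphic-strategy equilibria (``xi = 1`` vs
``xi = 1/2``).  Under mutation-selection balance female mean fitness
rises and male mean fitness falls (for ``s_m > 0``) throughout the
region where RXI can evolve; under sexual antagonism male fitness rises
exactly when ``s_f > t_m`` (the female-deleterious allele becomes rarer
in eggs) and female fitness rises under broader conditions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

from .equilibria import (
    AlleleFreqPair,
    NoInteriorEquilibriumError,
    msb_equilibrium,
    sa_equilibrium,
    sa_polymorphism_region,
)
from .params import InactivationPolicy, SelectionScheme, VariationMode, dominance_pair
from .stability import h_crit_msb, h_crit_sa, invasion

__all__ = [
    "ESSResult",
    "FitnessChange",
    "UnsupportedRegimeError",
    "selection_gradient",
    "ess_numeric",
    "ess_msb",
    "ess_sa",
    "ess_convergence_walk",
    "mean_fitness_at",
    "mean_fitness_change_msb",
    "mean_fitness_change_sa",
    "mutation_bias_condition",
    "sa_region_classification",
]

_BIAS_TOL = 1e-9


class UnsupportedRegimeError(ValueError):
    """Raised for ``h >= 1/2``: with partial dominance the exponent
    ``-ln(2)/ln(2h)`` flips sign and the ESS analysis does not apply."""


@dataclass(frozen=True)
class ESSResult:
    """An evolutionarily stable paternal-silencing probability."""

    xi_star: float
    source: Literal["analytic", "numeric"]
    gradient_residual: float
    bias_direction: Literal["paternal", "maternal", "unbiased"]


def _bias_direction(xi_star: float, tol: float = _BIAS_TOL) -> str:
    if xi_star > 0.5 + tol:
        return "paternal"
    if xi_star < 0.5 - tol:
        return "maternal"
    return "unbiased"


def _exponent(h: float) -> float:
    """``e = -ln(2)/ln(2h)``, positive for h < 1/2."""
    if h >= 0.5:
        raise UnsupportedRegimeError(
            f"ESS analysis assumes partial recessivity (h < 1/2); got h={h}"
        )
    return -math.log(2.0) / math.log(2.0 * h)


def selection_gradient(
    scheme: SelectionScheme,
    xi: float,
    delta: float = 1e-3,
    symmetric: bool = False,
    r: float = 0.5,
    linkage: Literal["X", "autosome"] = "X",
) -> float:
    """Selection gradient on the inactivation ratio at resident ``xi``.

    Default is the one-sided construction ``lambda(xi, xi + delta) - 1``.
    ``symmetric=True`` uses ``[lambda(xi, xi+delta) - lambda(xi, xi-delta)]/2``,
    which removes the O(delta) bias of the one-sided form near the ESS.
    """
    pol_up = InactivationPolicy.from_scheme(scheme, xi_11=xi, xi_12=min(xi + delta, 1.0))
    lam_up = invasion(scheme, pol_up, r=r, linkage=linkage, cross_check=False).lambda_lead
    if not symmetric:
        return lam_up - 1.0
    pol_dn = InactivationPolicy.from_scheme(scheme, xi_11=xi, xi_12=max(xi - delta, 0.0))
    lam_dn = invasion(scheme, pol_dn, r=r, linkage=linkage, cross_check=False).lambda_lead
    return 0.5 * (lam_up - lam_dn)


def ess_numeric(
    scheme: SelectionScheme,
    bracket: tuple[float, float] = (0.02, 0.98),
    delta: float = 1e-3,
    symmetric: bool = True,
    xtol: float = 1e-9,
    r: float = 0.5,
    linkage: Literal["X", "autosome"] = "X",
) -> ESSResult:
    """ESS located as the zero of the numeric selection gradient.

    If a bracket endpoint falls outside the strategy range over which the
    resident polymorphism exists (possible in the sexually antagonistic
    mode, where the protected region depends on the resident ``xi``), the
    endpoint is moved toward the bracket midpoint until the gradient is
    defined there.
    """

    def g(xi: float) -> float:
        return selection_gradient(scheme, xi, delta=delta, symmetric=symmetric, r=r, linkage=linkage)

    lo, hi = bracket
    mid = 0.5 * (lo + hi)
    for _ in range(60):
        try:
            g(lo)
            break
        except NoInteriorEquilibriumError:
            lo = lo + 0.25 * (mid - lo)
    else:
        raise NoInteriorEquilibriumError(
            "no resident polymorphism anywhere near the lower bracket endpoint"
        )
    for _ in range(60):
        try:
            g(hi)
            break
        except NoInteriorEquilibriumError:
            hi = hi - 0.25 * (hi - mid)
    else:
        raise NoInteriorEquilibriumError(
            "no resident polymorphism anywhere near the upper bracket endpoint"
        )
    xi_star = float(brentq(g, lo, hi, xtol=xtol))
    return ESSResult(
        xi_star=xi_star,
        source="numeric",
        gradient_residual=abs(g(xi_star)),
        bias_direction=_bias_direction(xi_star),
    )


def ess_msb(scheme: SelectionScheme, approx: bool = False) -> ESSResult:
    """Analytic ESS under mutation-selection balance.

    The exact form solves ``xi/(1-xi) = R(xi)**e`` with the transmission
    odds ratio ``R`` taken at the balance equilibrium for resident
    ``xi``; ``approx=True`` uses the weak-selection simplification
    ``R = 1 - (2/3)(s_m - s_f h)`` evaluated once (requires
    ``u_f == u_m``; the bias direction rule is then ``xi* < 1/2`` iff
    ``s_m > s_f h``).
    """
    if scheme.mode is not VariationMode.DELETERIOUS:
        raise ValueError("ess_msb requires deleterious mode")
    if scheme.u_f <= 0 and scheme.u_m <= 0:
        raise ValueError("mutation-selection balance requires a positive mutation rate")
    e = _exponent(scheme.h)
    if approx:
        R = 1.0 - (2.0 / 3.0) * (scheme.s_m - scheme.s_f * scheme.h)
        xi_star = R**e / (1.0 + R**e)
        return ESSResult(
            xi_star=float(xi_star),
            source="analytic",
            gradient_residual=np.nan,
            bias_direction=_bias_direction(xi_star, tol=1e-12),
        )

    def phi(xi: float) -> float:
        pol = InactivationPolicy.from_scheme(scheme, xi_11=xi)
        eq = msb_equilibrium(scheme, pol, refine=True)
        R = eq.q_m * (1.0 - eq.q_f) / (eq.q_f * (1.0 - eq.q_m))
        return math.log(xi / (1.0 - xi)) - e * math.log(R)

    xi_star = float(brentq(phi, 1e-6, 1.0 - 1e-6, xtol=1e-12))
    return ESSResult(
        xi_star=xi_star,
        source="analytic",
        gradient_residual=abs(phi(xi_star)),
        bias_direction=_bias_direction(xi_star, tol=1e-12),
    )


def ess_sa(scheme: SelectionScheme) -> ESSResult:
    """Analytic ESS under sexually antagonistic balancing selection:
    ``xi* = 1/(1 + (1 - t_m)**e)``, always paternally biased."""
    if scheme.mode is not VariationMode.SEXUALLY_ANTAGONISTIC:
        raise ValueError("ess_sa requires sexually antagonistic mode")
    e = _exponent(scheme.h)
    xi_star = 1.0 / (1.0 + (1.0 - scheme.t_m) ** e)
    return ESSResult(
        xi_star=float(xi_star),
        source="analytic",
        gradient_residual=np.nan,
        bias_direction=_bias_direction(xi_star, tol=1e-12),
    )


def ess_convergence_walk(
    scheme: SelectionScheme,
    xi0: float,
    delta: float = 1e-3,
    step0: float = 0.1,
    min_step: float = 1e-4,
    max_substitutions: int = 400,
    r: float = 0.5,
    linkage: Literal["X", "autosome"] = "X",
) -> tuple[float, int]:
    """Iterated invasion-substitution walk toward the ESS.

    From resident ``xi0``, a mutant strategy one step up or down replaces
    the resident whenever it invades; the step halves when neither
    neighbor invades.  Convergence stability of the ESS means the walk
    approaches it from either extreme.  Returns (final resident,
    substitutions performed).
    """
    xi = float(xi0)
    step = step0
    subs = 0
    while step >= min_step and subs < max_substitutions:
        moved = False
        for direction in (+1.0, -1.0):
            cand = float(np.clip(xi + direction * step, 1e-6, 1.0 - 1e-6))
            if cand == xi:
                continue
            pol = InactivationPolicy.from_scheme(scheme, xi_11=xi, xi_12=cand)
            try:
                res = invasion(scheme, pol, r=r, linkage=linkage, cross_check=False)
            except NoInteriorEquilibriumError:
                continue
            if res.invades:
                xi = cand
                subs += 1
                moved = True
                break
        if not moved:
            step *= 0.5
    return xi, subs


@dataclass(frozen=True)
class FitnessChange:
    """Per-sex equilibrium mean fitness before (PXI) and after (RXI)."""

    mean_w_f_before: float
    mean_w_m_before: float
    mean_w_f_after: float
    mean_w_m_after: float
    region_label: str = "interior"

    @property
    def female_up(self) -> bool:
        return self.mean_w_f_after > self.mean_w_f_before + 1e-12

    @property
    def male_up(self) -> bool:
        return self.mean_w_m_after > self.mean_w_m_before + 1e-12

    @property
    def male_unchanged(self) -> bool:
        return abs(self.mean_w_m_after - self.mean_w_m_before) <= 1e-12


def mean_fitness_at(
    scheme: SelectionScheme, xi: float, eq: AlleleFreqPair
) -> tuple[float, float]:
    """Population mean female and male fitness at gamete frequencies
    ``eq`` under a monomorphic strategy ``xi``, from the genotype
    frequency table (random union of gametes)."""
    dom = dominance_pair(xi, scheme.k)
    q_f, q_m = eq.q_f, eq.q_m
    s_f = scheme.s_f
    w_f = 1.0 - s_f * (
        q_f * q_m + dom.h_mat * q_f * (1.0 - q_m) + dom.h_pat * q_m * (1.0 - q_f)
    )
    m = scheme.male_fitness()
    w_m = q_f * m[0] + (1.0 - q_f) * m[1]
    return float(w_f), float(w_m)


def _msb_mean_fitness_closed(scheme: SelectionScheme, xi: float) -> tuple[float, float]:
    """O(u)-accurate closed-form mean fitnesses under strategy ``xi``.

    Writing the balance frequencies to first order in the mutation rate,
    the female load is ``s_f (h_mat q_f + h_pat q_m)`` and the male load
    ``s_m q_f`` (male zygotes carry the maternally transmitted X);
    O(u^2) genotype terms are dropped.
    """
    dom = dominance_pair(xi, scheme.k)
    pol = InactivationPolicy.from_scheme(scheme, xi_11=xi)
    eq = msb_equilibrium(scheme, pol, refine=False)
    w_f = 1.0 - scheme.s_f * (dom.h_mat * eq.q_f + dom.h_pat * eq.q_m)
    w_m = 1.0 - scheme.s_m * eq.q_f
    return float(w_f), float(w_m)


def mean_fitness_change_msb(
    scheme: SelectionScheme, closed_form: bool = True
) -> FitnessChange:
    """Mean-fitness change across the PXI -> unbiased-RXI transition under
    mutation-selection balance.

    With ``closed_form=True`` the O(u) expressions are used; otherwise
    the means are assembled from refined balance equilibria and the full
    genotype table.  Within the region where RXI can evolve
    (``h < h_crit``) female fitness rises and male fitness falls
    whenever ``s_m > 0`` (and is unchanged when ``s_m = 0``).
    """
    if scheme.mode is not VariationMode.DELETERIOUS:
        raise ValueError("mean_fitness_change_msb requires deleterious mode")
    if closed_form:
        wf1, wm1 = _msb_mean_fitness_closed(scheme, 1.0)
        wf2, wm2 = _msb_mean_fitness_closed(scheme, 0.5)
    else:
        for_xi = {}
        for xi in (1.0, 0.5):
            pol = InactivationPolicy.from_scheme(scheme, xi_11=xi)
            eq = msb_equilibrium(scheme, pol, refine=True)
            for_xi[xi] = mean_fitness_at(scheme, xi, eq)
        (wf1, wm1), (wf2, wm2) = for_xi[1.0], for_xi[0.5]
    return FitnessChange(
        mean_w_f_before=wf1,
        mean_w_m_before=wm1,
        mean_w_f_after=wf2,
        mean_w_m_after=wm2,
    )


def mean_fitness_change_sa(scheme: SelectionScheme) -> FitnessChange:
    """Mean-fitness change across the PXI -> unbiased-RXI transition under
    sexually antagonistic balancing selection.

    Uses the exact interior equilibria at ``xi = 1`` and ``xi = 1/2``.
    If either strategy leaves the protected-polymorphism region the
    outcome is labeled (an A allele fixes) rather than raised, with the
    fixed-boundary mean fitness reported.
    """
    if scheme.mode is not VariationMode.SEXUALLY_ANTAGONISTIC:
        raise ValueError("mean_fitness_change_sa requires sexually antagonistic mode")
    labels = []
    means = {}
    for tag, xi in (("before", 1.0), ("after", 0.5)):
        pol = InactivationPolicy.from_scheme(scheme, xi_11=xi)
        try:
            eq = sa_equilibrium(scheme, pol)
            label = "interior"
        except NoInteriorEquilibriumError:
            _, diag = sa_polymorphism_region(scheme, pol)
            # the allele whose rare-invasion growth factor is below one fixes out
            if diag["growth_A1_when_rare"] <= 1.0:
                eq = AlleleFreqPair(q_f=0.0, q_m=0.0)
                label = "A2_fixes"
            else:
                eq = AlleleFreqPair(q_f=1.0, q_m=1.0)
                label = "A1_fixes"
        means[tag] = mean_fitness_at(scheme, xi, eq)
        labels.append(label)
    region_label = labels[0] if labels[0] == labels[1] else f"{labels[0]}->{labels[1]}"
    (wf1, wm1), (wf2, wm2) = means["before"], means["after"]
    return FitnessChange(
        mean_w_f_before=wf1,
        mean_w_m_before=wm1,
        mean_w_f_after=wf2,
        mean_w_m_after=wm2,
        region_label=region_label,
    )


def mutation_bias_condition(scheme: SelectionScheme) -> tuple[bool, float]:
    """Whether sex-biased mutation still favors reduced maternal-X expression.

    Preferential silencing of the maternally inherited X is favored iff
    ``(u_m/u_f) * s_f * h < s_m``; male-biased mutation (``u_m > u_f``)
    shrinks this parameter space because fathers transmit more de-novo
    mutations to daughters.  Returns (condition holds, signed margin
    ``s_m - (u_m/u_f) s_f h``).
    """
    if scheme.mode is not VariationMode.DELETERIOUS:
        raise ValueError("mutation_bias_condition requires deleterious mode")
    if scheme.u_f <= 0:
        raise ValueError("u_f must be positive (the ratio u_m/u_f is undefined)")
    lhs = (scheme.u_m / scheme.u_f) * scheme.s_f * scheme.h
    margin = scheme.s_m - lhs
    return margin > 0.0, float(margin)


def sa_region_classification(
    n_grid: int = 200,
    h_fraction: float = 0.5,
    margin: float = 1e-3,
) -> "pandas.DataFrame":
    """Classify the per-sex mean-fitness change over a (t_m, s_f) grid.

    At each grid point the dominance coefficient is set to
    ``h_fraction`` of the RXI-evolvability threshold
    ``(1 - t_m)/(2 - t_m)`` so that the transition is always favored,
    and the PXI and RXI equilibria are computed exactly.  Points where
    either strategy lacks an interior polymorphism are labeled and
    excluded from interior statistics.
    """
    import pandas as pd

    grid = np.linspace(margin, 1.0 - margin, n_grid)
    rows = []
    for t_m in grid:
        h = h_fraction * h_crit_sa(t_m)
        for s_f in grid:
            scheme = SelectionScheme(
                mode=VariationMode.SEXUALLY_ANTAGONISTIC, s_f=s_f, t_m=t_m, h=h
            )
            fc = mean_fitness_change_sa(scheme)
            rows.append(
                {
                    "t_m": t_m,
                    "s_f": s_f,
                    "h": h,
                    "region_label": fc.region_label,
                    "female_up": fc.female_up,
                    "male_up": fc.male_up,
                    "male_unchanged": fc.male_unchanged,
                    "d_w_f": fc.mean_w_f_after - fc.mean_w_f_before,
                    "d_w_m": fc.mean_w_m_after - fc.mean_w_m_before,
                }
            )
    return pd.DataFrame(rows)
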