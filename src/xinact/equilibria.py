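"""Single-locus equilibria at the fitness locus with the modifier monomorphic.

With B2 absent the two-locus system collapses to a sex-specific
single-locus recursion for the frequency of A1 in eggs (``q_f``) and in
sperm (``q_m``), under the resident silencing probability ``xi_11``:

* eggs:  ``q_f' = [q_f q_m (1-s_f) + q_f(1-q_m)(1-s_f h_mat)/2
  + q_m(1-q_f)(1-s_f h_pat)/2] / W_f`` followed by mutation
  ``q_f'' = q_f' + u_f (1-q_f')``;
* sperm: ``q_m' = q_f m(A1) / [q_f m(A1) + (1-q_f) m(A2)]`` followed by
  ``q_m'' = q_m' + u_m (1-q_m')``.

Two closed forms are implemented:

* **Mutation-selection balance** (deleterious mode).  Linearizing the
  recursion in the rare-allele frequencies gives, accurate to O(u^2)::

      q_f = (2 u_f + u_m (1 - s_f h_pat)) / D
      q_m = q_f (1 - s_m) + u_m
      D   = s_f h_mat + s_m + s_f h_pat (1 - s_m)

  which with ``u_f = u_m`` and unbiased inactivation reduces to the
  familiar X-linked balance ``q_f = 3u / (2 s_f h + s_m (1 - s_f h))``.

* **Sexually antagonistic balanced polymorphism**.  The interior fixed
  point of the exact recursion is linear in ``q_f``::

      q_f = (t_m - s_f (h_mat (1 - t_m) + h_pat))
            / (2 s_f (1 - h_mat (1 - t_m) - h_pat))
      q_m = q_f / (q_f + (1 - q_f)(1 - t_m))

  valid exactly (no weak-selection assumption) whenever the protected-
  polymorphism conditions hold.

Both are cross-checkable against long-run iteration of the full
two-locus recursion with B2 absent, and a Newton polish on the
single-locus map is available to refine the mutation-selection balance
to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import InactivationPolicy, SelectionScheme, VariationMode

__all__ = [
    "AlleleFreqPair",
    "NoInteriorEquilibriumError",
    "msb_equilibrium",
    "sa_equilibrium",
    "sa_polymorphism_region",
    "resident_equilibrium",
    "single_locus_map",
]


class NoInteriorEquilibriumError(ValueError):
    """Raised when a balanced polymorphism is requested outside the
    protected-polymorphism parameter region."""


@dataclass(frozen=True)
class AlleleFreqPair:
    """Frequency of A1 in eggs (``q_f``) and in sperm (``q_m``).

    Zygotic genotype frequencies follow from random union of gametes:
    A1A1 females with probability ``q_m * q_f`` and so on.
    """

    q_f: float
    q_m: float
    converged: bool = True
    residual: float = 0.0

    def __post_init__(self) -> None:
        for name in ("q_f", "q_m"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1.0 + 1e-12:
                raise ValueError(f"{name} must lie in [0, 1]; got {v}")


def _male_fitness_pair(scheme: SelectionScheme) -> tuple[float, float]:
    """(fitness of A1 males, fitness of A2 males)."""
    m = scheme.male_fitness()
    return float(m[0]), float(m[1])


def single_locus_map(q_f, q_m, scheme: SelectionScheme, h_mat: float, h_pat: float):
    """One generation of the B1-fixed sex-specific recursion.

    Accepts floats or complex numbers (the latter for complex-step
    derivatives used by the Newton polish).
    """
    s_f = scheme.s_f
    m1, m2 = _male_fitness_pair(scheme)
    num = (
        q_f * q_m * (1 - s_f)
        + 0.5 * q_f * (1 - q_m) * (1 - s_f * h_mat)
        + 0.5 * q_m * (1 - q_f) * (1 - s_f * h_pat)
    )
    w_f = (
        q_f * q_m * (1 - s_f)
        + q_f * (1 - q_m) * (1 - s_f * h_mat)
        + q_m * (1 - q_f) * (1 - s_f * h_pat)
        + (1 - q_f) * (1 - q_m)
    )
    qf1 = num / w_f
    qf1 = qf1 + scheme.u_f * (1 - qf1)
    w_m = q_f * m1 + (1 - q_f) * m2
    qm1 = q_f * m1 / w_m
    qm1 = qm1 + scheme.u_m * (1 - qm1)
    return qf1, qm1


def _newton_polish(
    q_f: float,
    q_m: float,
    scheme: SelectionScheme,
    h_mat: float,
    h_pat: float,
    tol: float = 1e-14,
    max_iter: int = 50,
) -> tuple[float, float, bool, float]:
    """Refine a fixed-point seed of the single-locus map by Newton's method.

    The 2x2 Jacobian is obtained by complex-step differentiation of the
    same map used for iteration, so the polish targets the exact
    recursion, not a re-derivation of it.
    """
    hstep = 1e-60
    q = np.array([q_f, q_m], dtype=float)
    resid = np.inf
    for _ in range(max_iter):
        f0 = np.array(single_locus_map(q[0], q[1], scheme, h_mat, h_pat))
        g = f0 - q
        resid = float(np.max(np.abs(g)))
        if resid < tol:
            return float(q[0]), float(q[1]), True, resid
        jac = np.empty((2, 2))
        for b in range(2):
            qq = q.astype(complex)
            qq[b] += 1j * hstep
            fb = single_locus_map(qq[0], qq[1], scheme, h_mat, h_pat)
            jac[0, b] = fb[0].imag / hstep
            jac[1, b] = fb[1].imag / hstep
        try:
            step = np.linalg.solve(jac - np.eye(2), -g)
        except np.linalg.LinAlgError:
            break
        q = np.clip(q + step, 0.0, 1.0)
    return float(q[0]), float(q[1]), resid < tol, resid


def msb_equilibrium(
    scheme: SelectionScheme,
    policy: InactivationPolicy,
    refine: bool = False,
) -> AlleleFreqPair:
    """Mutation-selection balance of the deleterious allele under the
    resident strategy ``policy.xi_11``.

    Returns the O(u^2)-accurate closed form; with ``refine=True`` the
    result is Newton-polished on the exact recursion to ~1e-14.
    """
    if scheme.mode is not VariationMode.DELETERIOUS:
        raise ValueError("msb_equilibrium requires deleterious mode")
    dom = policy.dominance("B1B1")
    h_mat, h_pat = dom.h_mat, dom.h_pat
    if scheme.u_f == 0.0 and scheme.u_m == 0.0:
        return AlleleFreqPair(q_f=0.0, q_m=0.0)
    s_f, s_m = scheme.s_f, scheme.s_m
    denom = s_f * h_mat + s_m + s_f * h_pat * (1.0 - s_m)
    q_f = (2.0 * scheme.u_f + scheme.u_m * (1.0 - s_f * h_pat)) / denom
    q_m = q_f * (1.0 - s_m) + scheme.u_m
    if refine:
        q_f, q_m, ok, resid = _newton_polish(q_f, q_m, scheme, h_mat, h_pat)
        return AlleleFreqPair(q_f=q_f, q_m=q_m, converged=ok, residual=resid)
    return AlleleFreqPair(q_f=min(q_f, 1.0), q_m=min(q_m, 1.0))


def sa_polymorphism_region(
    scheme: SelectionScheme, policy: InactivationPolicy
) -> tuple[bool, dict]:
    """Protected-polymorphism test for the sexually antagonistic locus.

    Both alleles must invade when rare under the B1-fixed dynamics.  The
    rare-allele growth factor at each monomorphic boundary is the leading
    eigenvalue of the explicit 2x2 (eggs, sperm) linearization; the
    polymorphism is protected iff both exceed one.
    """
    if scheme.mode is not VariationMode.SEXUALLY_ANTAGONISTIC:
        raise ValueError("sa_polymorphism_region requires sexually antagonistic mode")
    dom = policy.dominance("B1B1")
    h_mat, h_pat = dom.h_mat, dom.h_pat
    s_f = scheme.s_f
    m1, m2 = _male_fitness_pair(scheme)
    # A1 rare at the A2-fixed boundary
    j1 = np.array(
        [
            [0.5 * (1 - s_f * h_mat), 0.5 * (1 - s_f * h_pat)],
            [m1 / m2, 0.0],
        ]
    )
    # A2 rare at the A1-fixed boundary (fitness relative to A1 residents)
    j2 = np.array(
        [
            [0.5 * (1 - s_f * h_pat) / (1 - s_f), 0.5 * (1 - s_f * h_mat) / (1 - s_f)],
            [m2 / m1, 0.0],
        ]
    )
    lam1 = float(np.max(np.abs(np.linalg.eigvals(j1))))
    lam2 = float(np.max(np.abs(np.linalg.eigvals(j2))))
    protected = lam1 > 1.0 and lam2 > 1.0
    return protected, {
        "growth_A1_when_rare": lam1,
        "growth_A2_when_rare": lam2,
        "margin": min(lam1, lam2) - 1.0,
    }


def sa_equilibrium(
    scheme: SelectionScheme,
    policy: InactivationPolicy,
    refine: bool = False,
    check_region: bool = True,
) -> AlleleFreqPair:
    """Interior equilibrium of the sexually antagonistic polymorphism
    under the resident strategy ``policy.xi_11``.

    The closed form is exact for the deterministic recursion.  Outside
    the protected-polymorphism region a
    :class:`NoInteriorEquilibriumError` is raised (one allele fixes).
    """
    if scheme.mode is not VariationMode.SEXUALLY_ANTAGONISTIC:
        raise ValueError("sa_equilibrium requires sexually antagonistic mode")
    if check_region:
        protected, diag = sa_polymorphism_region(scheme, policy)
        if not protected:
            raise NoInteriorEquilibriumError(
                "no protected polymorphism at the A locus: "
                f"boundary growth factors {diag['growth_A1_when_rare']:.6g}, "
                f"{diag['growth_A2_when_rare']:.6g}"
            )
    dom = policy.dominance("B1B1")
    h_mat, h_pat = dom.h_mat, dom.h_pat
    s_f, t_m = scheme.s_f, scheme.t_m
    denom = 2.0 * s_f * (1.0 - h_mat * (1.0 - t_m) - h_pat)
    if denom == 0.0:
        raise NoInteriorEquilibriumError("degenerate parameters: denominator vanishes")
    q_f = (t_m - s_f * (h_mat * (1.0 - t_m) + h_pat)) / denom
    if not 0.0 < q_f < 1.0:
        raise NoInteriorEquilibriumError(
            f"closed-form equilibrium q_f={q_f:.6g} is not interior"
        )
    q_m = q_f / (q_f + (1.0 - q_f) * (1.0 - t_m))
    if refine:
        q_f, q_m, ok, resid = _newton_polish(q_f, q_m, scheme, h_mat, h_pat)
        return AlleleFreqPair(q_f=q_f, q_m=q_m, converged=ok, residual=resid)
    return AlleleFreqPair(q_f=q_f, q_m=q_m)


def resident_equilibrium(
    scheme: SelectionScheme, policy: InactivationPolicy, refine: bool = True
) -> AlleleFreqPair:
    """Equilibrium of the A locus for a population fixed for B1, under the
    resident strategy, dispatched on the variation mode."""
    if scheme.mode is VariationMode.DELETERIOUS:
        return msb_equilibrium(scheme, policy, refine=refine)
    return sa_equilibrium(scheme, policy, refine=refine)
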