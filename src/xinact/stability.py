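"""Linear stability analysis of a rare X-inactivation modifier allele.

A population fixed for B1, with the A locus at its resident equilibrium,
is perturbed by a rare B2 allele whose carriers silence the paternal X
with probability ``xi_12`` (heterozygotes).  Because B2-bearing
haplotypes are rare, the full Jacobian of the recursion is block
triangular; invasion is decided by the leading eigenvalue of the rare
block ``J = d(x3', x4', y3', y4') / d(x3, x4, y3, y4)`` evaluated at
``x3 = x4 = y3 = y4 = 0``.  B2 invades iff that eigenvalue exceeds one.

``J`` is obtained by complex-step differentiation of the same
one-generation map used for forward simulation (a single source of
truth; the step is machine-precision exact), and can be cross-checked
entrywise against central finite differences.  The leading eigenvalue
comes from a dense eigensolve, cross-validated by Newton-Raphson on the
characteristic polynomial.

Closed-form invasion thresholds for the PXI -> unbiased-RXI transition:

* mutation-selection balance: ``h_crit = 3 / (6 - 2 s_m + s_f)``;
* sexually antagonistic polymorphism: ``h_crit = (1 - t_m) / (2 - t_m)``.

Both are independent of the recombination rate and of whether the
modifier is X-linked or autosomal, which the numeric machinery can
verify directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.optimize import brentq

from .equilibria import AlleleFreqPair, resident_equilibrium, single_locus_map
from .params import InactivationPolicy, SelectionScheme, build_fitness_tables
from .recursions import step_arrays

__all__ = [
    "InvasionResult",
    "ResidentUnstableError",
    "jacobian_submatrix",
    "leading_eigenvalue",
    "invasion",
    "h_crit_msb",
    "h_crit_sa",
    "numeric_invasion_boundary",
    "invasion_boundary_h",
    "multilocus_modifier_selection",
]

#: indices of the rare B2-bearing coordinates within (x, y)
_RARE = ((0, 2), (0, 3), (1, 2), (1, 3))  # (pool, haplotype)

NEUTRAL_TOL = 1e-10


class ResidentUnstableError(RuntimeError):
    """Raised when the B1-fixed resident equilibrium is not locally stable,
    so that a rare-modifier linearization around it is meaningless."""


@dataclass(frozen=True)
class InvasionResult:
    """Leading eigenvalue and verdict for a rare modifier allele."""

    lambda_lead: float
    invades: bool
    char_poly_residual: float
    method: str
    equilibrium: AlleleFreqPair
    eigenvalues: np.ndarray = field(repr=False, default=None)

    @property
    def selection_strength(self) -> float:
        """Per-generation selection coefficient on the rare modifier."""
        return self.lambda_lead - 1.0


def _resident_stability(scheme: SelectionScheme, policy: InactivationPolicy, eq) -> float:
    """Spectral radius of the single-locus Jacobian at the resident equilibrium."""
    dom = policy.dominance("B1B1")
    hstep = 1e-60
    jac = np.empty((2, 2))
    q = np.array([eq.q_f, eq.q_m])
    for b in range(2):
        qq = q.astype(complex)
        qq[b] += 1j * hstep
        fb = single_locus_map(qq[0], qq[1], scheme, dom.h_mat, dom.h_pat)
        jac[0, b] = fb[0].imag / hstep
        jac[1, b] = fb[1].imag / hstep
    return float(np.max(np.abs(np.linalg.eigvals(jac))))


def jacobian_submatrix(
    scheme: SelectionScheme,
    policy: InactivationPolicy,
    r: float = 0.5,
    linkage: Literal["X", "autosome"] = "X",
    equilibrium: AlleleFreqPair | None = None,
    method: Literal["complex_step", "finite_difference"] = "complex_step",
    check_resident: bool = True,
) -> tuple[np.ndarray, AlleleFreqPair]:
    """Rare-B2 Jacobian block at the B1-fixed resident equilibrium.

    Differentiates the implemented one-generation map with respect to the
    four B2-bearing haplotype frequencies, holding the resident
    haplotypes at equilibrium.  ``method='finite_difference'`` uses
    central differences (step 1e-7) as an independent cross-check of the
    default complex-step derivative.
    """
    if equilibrium is None:
        equilibrium = resident_equilibrium(scheme, policy, refine=True)
    if check_resident:
        rho = _resident_stability(scheme, policy, equilibrium)
        if rho > 1.0 + 1e-9:
            raise ResidentUnstableError(
                f"resident A-locus equilibrium is unstable (spectral radius {rho:.6g})"
            )
    tables = build_fitness_tables(scheme, policy)
    x0 = np.array([equilibrium.q_f, 1.0 - equilibrium.q_f, 0.0, 0.0])
    y0 = np.array([equilibrium.q_m, 1.0 - equilibrium.q_m, 0.0, 0.0])
    jac = np.empty((4, 4))
    if method == "complex_step":
        h = 1e-60
        for b, (pool, hap) in enumerate(_RARE):
            x = x0.astype(complex)
            y = y0.astype(complex)
            (x, y)[pool][hap] += 1j * h
            xn, yn = step_arrays(x, y, tables, r, scheme, linkage=linkage)
            out = (xn, yn)
            for a, (pa, ha) in enumerate(_RARE):
                jac[a, b] = out[pa][ha].imag / h
    elif method == "finite_difference":
        h = 1e-7
        for b, (pool, hap) in enumerate(_RARE):
            cols = []
            for sign in (+1.0, -1.0):
                x = x0.copy()
                y = y0.copy()
                (x, y)[pool][hap] += sign * h
                xn, yn = step_arrays(x, y, tables, r, scheme, linkage=linkage)
                out = (xn, yn)
                cols.append(np.array([out[pa][ha] for pa, ha in _RARE]))
            jac[:, b] = (cols[0] - cols[1]) / (2.0 * h)
    else:
        raise ValueError(f"unknown differentiation method {method!r}")
    return jac, equilibrium


def _newton_char_poly(J: np.ndarray, lam0: float) -> tuple[float, float]:
    """Newton-Raphson refinement of the leading characteristic-polynomial root."""
    coeffs = np.poly(J)
    dcoeffs = np.polyder(coeffs)
    lam = lam0
    for _ in range(100):
        p = np.polyval(coeffs, lam)
        dp = np.polyval(dcoeffs, lam)
        if dp == 0:
            break
        step = p / dp
        lam -= step
        if abs(step) < 1e-14 * max(1.0, abs(lam)):
            break
    resid = abs(np.polyval(coeffs, lam))
    return float(lam), float(resid)


def leading_eigenvalue(
    J: np.ndarray, cross_check: bool = True
) -> tuple[float, dict]:
    """Leading (largest-modulus) eigenvalue of the rare-modifier block.

    For this model the block is (essentially) nonnegative, so the
    dominant eigenvalue is real; a dominant complex pair flags a
    transcription bug and triggers a warning.  Newton-Raphson on the
    characteristic polynomial cross-validates the dense eigensolve.
    """
    J = np.asarray(J, dtype=float)
    eigs = np.linalg.eigvals(J)
    idx = int(np.argmax(np.abs(eigs)))
    lam = eigs[idx]
    diagnostics: dict = {"eigenvalues": eigs, "method": "eigen_solve"}
    if abs(lam.imag) > 1e-9 * max(1.0, abs(lam)):
        warnings.warn(
            f"dominant eigenvalue has nontrivial imaginary part ({lam:.6g}); "
            "reporting its modulus",
            stacklevel=2,
        )
        lam_lead = float(abs(lam))
        diagnostics["char_poly_residual"] = np.nan
        return lam_lead, diagnostics
    lam_lead = float(lam.real)
    if cross_check:
        lam_nr, resid = _newton_char_poly(J, lam_lead)
        scale = max(1.0, float(np.max(np.abs(np.poly(J)))))
        diagnostics["char_poly_residual"] = resid / scale
        diagnostics["newton_raphson_root"] = lam_nr
        if abs(lam_nr - lam_lead) > 1e-8 * max(1.0, abs(lam_lead)):
            raise RuntimeError(
                "eigensolve and characteristic-polynomial root disagree: "
                f"{lam_lead!r} vs {lam_nr!r}"
            )
    else:
        diagnostics["char_poly_residual"] = np.nan
    return lam_lead, diagnostics


def invasion(
    scheme: SelectionScheme,
    policy: InactivationPolicy,
    r: float = 0.5,
    linkage: Literal["X", "autosome"] = "X",
    cross_check: bool = True,
    neutral_tol: float = NEUTRAL_TOL,
) -> InvasionResult:
    """Invasion analysis of a rare B2 allele with strategy ``policy.xi_12``
    against a resident fixed for ``policy.xi_11``."""
    J, eq = jacobian_submatrix(scheme, policy, r=r, linkage=linkage)
    lam, diag = leading_eigenvalue(J, cross_check=cross_check)
    return InvasionResult(
        lambda_lead=lam,
        invades=lam > 1.0 + neutral_tol,
        char_poly_residual=float(diag.get("char_poly_residual", np.nan)),
        method=diag["method"],
        equilibrium=eq,
        eigenvalues=diag["eigenvalues"],
    )


def h_crit_msb(s_f: float, s_m: float) -> float:
    """Critical dominance below which unbiased RXI invades strict PXI when
    variation is deleterious (mutation-selection balance): ``3/(6 - 2 s_m + s_f)``.

    Increasing in ``s_m`` (stronger purifying selection in males lowers
    the deleterious load of paternal X's) and decreasing in ``s_f``;
    tends to 1/2 as both selection coefficients vanish.
    """
    if not 0.0 < s_f < 1.0 or not 0.0 < s_m < 1.0:
        raise ValueError("s_f and s_m must lie in (0, 1)")
    return 3.0 / (6.0 - 2.0 * s_m + s_f)


def h_crit_sa(t_m: float) -> float:
    """Critical dominance below which unbiased RXI invades strict PXI when
    variation is sexually antagonistic: ``(1 - t_m)/(2 - t_m)``.

    Decreasing in ``t_m`` and tending to 1/2 as ``t_m`` vanishes; strong
    male-beneficial selection severely restricts the RXI-favoring space.
    """
    if not 0.0 < t_m < 1.0:
        raise ValueError("t_m must lie in (0, 1)")
    return (1.0 - t_m) / (2.0 - t_m)


def numeric_invasion_boundary(
    make_problem: Callable[[float], tuple[SelectionScheme, InactivationPolicy]],
    bracket: tuple[float, float],
    r: float = 0.5,
    linkage: Literal["X", "autosome"] = "X",
    xtol: float = 1e-8,
) -> float:
    """Bisection of ``lambda_lead - 1`` over a swept scalar parameter.

    ``make_problem`` maps the swept value to a (scheme, policy) pair.
    Raises if ``lambda_lead - 1`` does not change sign across the
    bracket (as happens, correctly, on both sides of an interior ESS).
    """

    def objective(v: float) -> float:
        scheme, policy = make_problem(v)
        return invasion(scheme, policy, r=r, linkage=linkage, cross_check=False).lambda_lead - 1.0

    f_lo, f_hi = objective(bracket[0]), objective(bracket[1])
    if np.sign(f_lo) == np.sign(f_hi):
        raise ValueError(
            f"lambda - 1 does not change sign over bracket {bracket}: "
            f"({f_lo:.3g}, {f_hi:.3g})"
        )
    return float(brentq(objective, bracket[0], bracket[1], xtol=xtol))


def invasion_boundary_h(
    scheme_factory: Callable[[float], SelectionScheme],
    xi_11: float,
    xi_12: float,
    bracket: tuple[float, float],
    r: float = 0.5,
    linkage: Literal["X", "autosome"] = "X",
    xtol: float = 1e-8,
) -> float:
    """Numeric invasion boundary in the dominance coefficient ``h``.

    ``scheme_factory(h)`` builds the selection scheme at a trial ``h``;
    the policy is rebuilt at each trial so that ``k`` tracks ``h``.
    """

    def make_problem(h: float):
        scheme = scheme_factory(h)
        policy = InactivationPolicy.from_scheme(scheme, xi_11=xi_11, xi_12=xi_12)
        return scheme, policy

    return numeric_invasion_boundary(make_problem, bracket, r=r, linkage=linkage, xtol=xtol)


def multilocus_modifier_selection(lambdas, n: int) -> float:
    """Aggregate selection on a modifier from ``n`` independent fitness loci.

    With weak per-locus effects (``lambda_i`` near 1) the modifier's
    selection coefficient is ``s_mod = n * mean(lambda_i - 1)``; invasion
    is predicted when ``s_mod > 0``.
    """
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("need at least one per-locus eigenvalue")
    if n <= 0:
        raise ValueError("n must be positive")
    if np.any(np.abs(lambdas - 1.0) > 0.01):
        warnings.warn(
            "per-locus eigenvalues deviate from 1 by more than 1%; the "
            "weak-effect aggregation may be inaccurate",
            stacklevel=2,
        )
    return float(n * np.mean(lambdas - 1.0))
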