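"""Exact one-generation haplotype-frequency recursions.

State is a :class:`GametePool`: four haplotype frequencies in eggs
(``x``) and four in sperm (``y``) over the haplotypes
``A1B1, A2B1, A1B2, A2B2``.  Each generation follows the life cycle
birth, selection, recombination, mutation, random mating and syngamy:

* Females of the next generation carry maternal haplotype ``i`` and
  paternal haplotype ``j`` with probability ``x_i * y_j`` and survive with
  relative fitness ``f_ij``; their eggs are parental haplotypes with
  probability ``(1-r)/2`` each and recombinant haplotypes with
  probability ``r/2`` each.
* Males inherit their single X maternally (haplotype ``i`` with
  probability ``x_i``) and survive with fitness ``m_i``.  With an
  X-linked modifier their sperm transmit the maternal haplotype intact;
  with an autosomal modifier the B allele in sperm is drawn equally from
  the father's two autosomal copies, and the female map uses effective
  free recombination (``r = 1/2``) since A and B then assort
  independently.
* Mutation ``A2 -> A1`` occurs per gamete at rate ``u_f`` in eggs and
  ``u_m`` in sperm, after recombination; back-mutation is neglected.

The same arithmetic core serves three purposes: forward simulation,
long-run equilibration (numba-compiled driver), and linearization around
boundary equilibria via complex-step differentiation (the core is written
dtype-generically, so complex perturbations flow through unchanged).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from numba import njit

from .params import FitnessTables, SelectionScheme

__all__ = ["GametePool", "IterationResult", "step_xlinked", "step_autosomal", "iterate"]

# A allele index (0 = A1, 1 = A2) and B allele index (0 = B1, 1 = B2) per haplotype
_A_OF = np.array([0, 1, 0, 1], dtype=np.int64)
_B_OF = np.array([0, 0, 1, 1], dtype=np.int64)
# haplotype index from (A allele, B allele)
_HAP = np.array([[0, 2], [1, 3]], dtype=np.int64)

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class GametePool:
    """Haplotype frequencies in eggs (``x``) and sperm (``y``).

    Each vector must be nonnegative and sum to one within 1e-12; the
    recursions preserve this exactly up to rounding, so a violation
    signals an upstream error rather than something to renormalize away.
    """

    x: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        for name, v in (("x", x), ("y", y)):
            if v.shape != (4,):
                raise ValueError(f"{name} must have length 4")
            if np.any(v < -_SUM_TOL):
                raise ValueError(f"{name} has negative entries: {v}")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1; got {v.sum()!r}")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    @classmethod
    def monomorphic_b1(cls, q_f: float, q_m: float) -> "GametePool":
        """Pool with B2 absent and A1 at frequency ``q_f`` in eggs, ``q_m`` in sperm."""
        return cls(
            x=np.array([q_f, 1.0 - q_f, 0.0, 0.0]),
            y=np.array([q_m, 1.0 - q_m, 0.0, 0.0]),
        )

    @property
    def q_f(self) -> float:
        """Frequency of A1 in eggs."""
        return float(self.x[0] + self.x[2])

    @property
    def q_m(self) -> float:
        """Frequency of A1 in sperm."""
        return float(self.y[0] + self.y[2])

    @property
    def b2_eggs(self) -> float:
        """Frequency of B2 in eggs."""
        return float(self.x[2] + self.x[3])

    @property
    def b2_sperm(self) -> float:
        """Frequency of B2 in sperm."""
        return float(self.y[2] + self.y[3])

    def mean_fitness(self, tables: FitnessTables) -> tuple[float, float]:
        """Population mean female and male fitness for the given tables."""
        wf = float(self.x @ tables.f @ self.y)
        wm = float(self.x @ tables.m)
        return wf, wm


@njit(cache=True)
def _step_core(x, y, f, m, r, u_f, u_m, autosomal):
    """One generation of selection, recombination and mutation.

    Written with explicit loops and no dtype assumptions so numba can
    specialize it for float64 (simulation) and complex128 (complex-step
    Jacobians) alike.
    """
    xp = np.zeros_like(x)
    F = x[0] * 0.0
    for i in range(4):
        for j in range(4):
            w = x[i] * y[j] * f[i, j]
            F = F + w
            xp[i] = xp[i] + w * (1.0 - r) * 0.5
            xp[j] = xp[j] + w * (1.0 - r) * 0.5
            xp[_HAP[_A_OF[i], _B_OF[j]]] = xp[_HAP[_A_OF[i], _B_OF[j]]] + w * r * 0.5
            xp[_HAP[_A_OF[j], _B_OF[i]]] = xp[_HAP[_A_OF[j], _B_OF[i]]] + w * r * 0.5
    for c in range(4):
        xp[c] = xp[c] / F

    yp = np.zeros_like(y)
    if not autosomal:
        M = x[0] * m[0] + x[1] * m[1] + x[2] * m[2] + x[3] * m[3]
        for c in range(4):
            yp[c] = x[c] * m[c] / M
    else:
        # males carry the X-linked A maternally and an autosomal B pair;
        # fitness is independent of B (m[0] == m[2], m[1] == m[3]), and each
        # sperm carries either parental B copy with probability 1/2
        xA = np.zeros_like(x[:2])
        pB = np.zeros_like(y[:2])
        xA[0] = x[0] + x[2]
        xA[1] = x[1] + x[3]
        pB[0] = y[0] + y[1]
        pB[1] = y[2] + y[3]
        M = xA[0] * m[0] + xA[1] * m[1]
        for c in range(4):
            yp[c] = m[c] * 0.5 * (x[c] + xA[_A_OF[c]] * pB[_B_OF[c]]) / M

    # mutation A2 -> A1, per gamete, applied after recombination
    xq = np.zeros_like(xp)
    yq = np.zeros_like(yp)
    xq[0] = xp[0] + u_f * xp[1]
    xq[1] = (1.0 - u_f) * xp[1]
    xq[2] = xp[2] + u_f * xp[3]
    xq[3] = (1.0 - u_f) * xp[3]
    yq[0] = yp[0] + u_m * yp[1]
    yq[1] = (1.0 - u_m) * yp[1]
    yq[2] = yp[2] + u_m * yp[3]
    yq[3] = (1.0 - u_m) * yp[3]
    return xq, yq


@njit(cache=True)
def _iterate_core(x, y, f, m, r, u_f, u_m, autosomal, max_gen, tol):
    delta = 1.0
    gens = 0
    for g in range(max_gen):
        xn, yn = _step_core(x, y, f, m, r, u_f, u_m, autosomal)
        delta = 0.0
        for c in range(4):
            dx = abs(xn[c] - x[c])
            dy = abs(yn[c] - y[c])
            if dx > delta:
                delta = dx
            if dy > delta:
                delta = dy
        x, y = xn, yn
        gens = g + 1
        if delta < tol:
            break
    return x, y, gens, delta, delta < tol


def step_arrays(
    x: np.ndarray,
    y: np.ndarray,
    tables: FitnessTables,
    r: float,
    scheme: SelectionScheme,
    linkage: Literal["X", "autosome"] = "X",
):
    """Low-level one-generation map on raw frequency arrays.

    Accepts float or complex arrays (the latter for complex-step
    linearization).  ``r`` is forced to 1/2 for an autosomal modifier.
    """
    autosomal = linkage == "autosome"
    if autosomal:
        r = 0.5
    elif not 0.0 <= r <= 0.5:
        raise ValueError(f"r must lie in [0, 1/2]; got {r}")
    x = np.asarray(x)
    y = np.asarray(y)
    if x.dtype.kind == "c" or y.dtype.kind == "c":
        x = x.astype(np.complex128)
        y = y.astype(np.complex128)
    else:
        x = x.astype(np.float64)
        y = y.astype(np.float64)
    xn, yn = _step_core(
        x, y, tables.f, tables.m, float(r), float(scheme.u_f), float(scheme.u_m), autosomal
    )
    if x.dtype.kind != "c":
        F = float(np.real(x @ tables.f @ y))
        M = float(np.real(x @ tables.m)) if not autosomal else 1.0
        if F <= 0 or M <= 0:
            raise ValueError("post-selection normalizer is nonpositive; check fitnesses")
    return xn, yn


def step_xlinked(
    pool: GametePool, tables: FitnessTables, r: float, scheme: SelectionScheme
) -> GametePool:
    """One generation with an X-linked modifier recombining at rate ``r``."""
    xn, yn = step_arrays(pool.x, pool.y, tables, r, scheme, linkage="X")
    return GametePool(x=xn, y=yn)


def step_autosomal(
    pool: GametePool, tables: FitnessTables, scheme: SelectionScheme
) -> GametePool:
    """One generation with the modifier on an autosome."""
    xn, yn = step_arrays(pool.x, pool.y, tables, 0.5, scheme, linkage="autosome")
    return GametePool(x=xn, y=yn)


@dataclass(frozen=True)
class IterationResult:
    """Outcome of repeated application of a one-generation map."""

    pool: GametePool
    generations: int
    converged: bool
    max_delta: float
    trajectory: np.ndarray | None = None  # (gens+1, 8) if recorded


def iterate(
    pool0: GametePool,
    tables: FitnessTables,
    scheme: SelectionScheme,
    r: float = 0.5,
    linkage: Literal["X", "autosome"] = "X",
    max_gen: int = 1_000_000,
    tol: float = 1e-12,
    record: bool = False,
) -> IterationResult:
    """Iterate the map to (numerical) fixed point.

    Convergence is declared when the per-generation max absolute change in
    any haplotype frequency falls below ``tol``; non-convergence within
    ``max_gen`` generations is flagged, never silently truncated.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    autosomal = linkage == "autosome"
    r_eff = 0.5 if autosomal else float(r)
    if not 0.0 <= r_eff <= 0.5:
        raise ValueError(f"r must lie in [0, 1/2]; got {r}")
    if record:
        traj = [np.concatenate([pool0.x, pool0.y])]
        x, y = pool0.x.copy(), pool0.y.copy()
        delta = np.inf
        converged = False
        gens = 0
        for g in range(max_gen):
            xn, yn = _step_core(
                x, y, tables.f, tables.m, r_eff, scheme.u_f, scheme.u_m, autosomal
            )
            delta = max(np.max(np.abs(xn - x)), np.max(np.abs(yn - y)))
            x, y = xn, yn
            traj.append(np.concatenate([x, y]))
            gens = g + 1
            if delta < tol:
                converged = True
                break
        return IterationResult(
            pool=GametePool(x=x, y=y),
            generations=gens,
            converged=converged,
            max_delta=float(delta),
            trajectory=np.asarray(traj),
        )
    x, y, gens, delta, conv = _iterate_core(
        pool0.x.astype(np.float64),
        pool0.y.astype(np.float64),
        tables.f,
        tables.m,
        float(r_eff),
        float(scheme.u_f),
        float(scheme.u_m),
        autosomal,
        int(max_gen),
        float(tol),
    )
    return IterationResult(
        pool=GametePool(x=x, y=y),
        generations=int(gens),
        converged=bool(conv),
        max_delta=float(delta),
    )


StepFunction = Callable[[GametePool], GametePool]
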