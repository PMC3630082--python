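"""Resident A-locus equilibria under different inactivation strategies.

The frequency of an X-linked allele at equilibrium depends on the
population's inactivation strategy, because the strategy sets the
parent-of-origin dominance coefficients experienced in females.  This
script compares the closed-form equilibria with long-run iteration of
the full recursion, for both variation modes.
"""

from xinact import (
    GametePool,
    InactivationPolicy,
    SelectionScheme,
    build_fitness_tables,
    iterate,
    msb_equilibrium,
    sa_equilibrium,
)

# --- deleterious variation at mutation-selection balance -------------------
scheme = SelectionScheme(
    mode="deleterious", s_f=0.2, s_m=0.2, h=0.25, u_f=1e-5, u_m=1e-5
)
print("mutation-selection balance, s_f = s_m = 0.2, h = 0.25, u = 1e-5")
for xi, label in ((1.0, "strict paternal inactivation"), (0.5, "unbiased random")):
    policy = InactivationPolicy.from_scheme(scheme, xi_11=xi)
    eq = msb_equilibrium(scheme, policy, refine=True)
    tables = build_fitness_tables(scheme, policy)
    sim = iterate(GametePool.monomorphic_b1(0.01, 0.01), tables, scheme, tol=1e-14)
    print(
        f"  {label:32s} q_f = {eq.q_f:.3e}  q_m = {eq.q_m:.3e}  "
        f"(iterated: {sim.pool.q_f:.3e}, {sim.generations} generations)"
    )

# --- sexually antagonistic balancing selection ------------------------------
sa = SelectionScheme(mode="sexually_antagonistic", s_f=0.22, t_m=0.2, h=0.25)
print("\nsexually antagonistic polymorphism, s_f = 0.22, t_m = 0.2, h = 0.25")
for xi, label in ((1.0, "strict paternal inactivation"), (0.5, "unbiased random")):
    policy = InactivationPolicy.from_scheme(sa, xi_11=xi)
    eq = sa_equilibrium(sa, policy)
    print(f"  {label:32s} q_f = {eq.q_f:.6f}  q_m = {eq.q_m:.6f}")
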