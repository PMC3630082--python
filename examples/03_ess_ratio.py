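"""The evolutionarily stable inactivation ratio.

When the critical dominance condition holds, partial silencing biases
can keep evolving until no modifier of the ratio can invade.  The ESS
silencing probability depends on which parent contributes deleterious
alleles more often: sexually antagonistic variation always favors
silencing the paternal X more than half the time, while deleterious
variation favors the maternal X whenever purifying selection in males
(s_m) exceeds the female heterozygous effect (s_f * h).
"""

from xinact import SelectionScheme, ess_msb, ess_numeric, ess_sa, ess_convergence_walk

sa = SelectionScheme(mode="sexually_antagonistic", s_f=0.25, t_m=0.2, h=0.2)
res = ess_sa(sa)
num = ess_numeric(sa)
print("sexually antagonistic, s_f = 0.25, t_m = 0.2, h = 0.2")
print(f"  closed-form ESS xi* = {res.xi_star:.6f} ({res.bias_direction} bias)")
print(f"  numeric gradient zero = {num.xi_star:.6f}")

msb = SelectionScheme(mode="deleterious", s_f=0.1, s_m=0.15, h=0.3, u_f=1e-5, u_m=1e-5)
res = ess_msb(msb)
print("\ndeleterious, s_f = 0.1, s_m = 0.15, h = 0.3 (s_m > s_f h)")
print(f"  closed-form ESS xi* = {res.xi_star:.6f} ({res.bias_direction} bias)")

xi_final, subs = ess_convergence_walk(msb, xi0=0.99)
print(
    f"  invasion-substitution walk from xi = 0.99 reaches {xi_final:.4f} "
    f"after {subs} substitutions"
)
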