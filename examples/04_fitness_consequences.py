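"""Who gains when random X inactivation replaces paternal silencing?

Switching the population from strict paternal inactivation to the
unbiased rule moves the A-locus equilibrium, so mean fitness changes in
both sexes even though males never inactivate an X.  Under deleterious
variation females gain and males lose; under sexually antagonistic
variation the male outcome flips sign across the s_f = t_m diagonal.
"""

from xinact import (
    SelectionScheme,
    mean_fitness_change_msb,
    mean_fitness_change_sa,
    sa_region_classification,
)

scheme = SelectionScheme(
    mode="deleterious", s_f=0.2, s_m=0.2, h=0.25, u_f=1e-5, u_m=1e-5
)
fc = mean_fitness_change_msb(scheme)
print("deleterious variation, s_f = s_m = 0.2, h = 0.25, u = 1e-5")
print(f"  female mean fitness: {fc.mean_w_f_before:.8f} -> {fc.mean_w_f_after:.8f}"
      f"  (up: {fc.female_up})")
print(f"  male mean fitness:   {fc.mean_w_m_before:.8f} -> {fc.mean_w_m_after:.8f}"
      f"  (up: {fc.male_up})")

for s_f, t_m in ((0.3, 0.2), (0.2, 0.3)):
    fc = mean_fitness_change_sa(
        SelectionScheme(mode="sexually_antagonistic", s_f=s_f, t_m=t_m, h=0.2)
    )
    print(f"\nsexually antagonistic, s_f = {s_f}, t_m = {t_m}, h = 0.2")
    print(f"  female up: {fc.female_up}   male up: {fc.male_up}")

df = sa_region_classification(n_grid=60)
interior = df[df.region_label == "interior"]
changed = interior[~interior.male_unchanged]
print(
    f"\n60 x 60 grid: {len(interior)} interior points, male fitness rises in "
    f"{changed.male_up.mean():.3f} of the {len(changed)} points where it changes"
)
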