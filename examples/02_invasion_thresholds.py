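"""When can random X inactivation displace strict paternal inactivation?

A rare modifier switching heterozygous carriers from strict paternal
silencing (xi = 1) to the unbiased rule (xi = 1/2) invades whenever the
leading eigenvalue of its rare-carrier dynamics exceeds one.  The
invasion condition reduces to a critical dominance threshold that is
independent of the recombination rate and of autosomal versus X-linked
placement of the modifier, which this script verifies numerically.
"""

from xinact import (
    InactivationPolicy,
    SelectionScheme,
    h_crit_msb,
    invasion,
    invasion_boundary_h,
)

s_f = s_m = 0.2
closed = h_crit_msb(s_f, s_m)
print(f"closed-form critical dominance (deleterious mode): h_crit = {closed:.6f}")


def factory(h):
    return SelectionScheme(
        mode="deleterious", s_f=s_f, s_m=s_m, h=h, u_f=1e-5, u_m=1e-5
    )


numeric = invasion_boundary_h(factory, xi_11=1.0, xi_12=0.5, bracket=(0.3, 0.7))
print(f"numeric eigenvalue-bisection boundary:             h     = {numeric:.6f}")

scheme = factory(0.25)  # well below the threshold: RXI should invade
policy = InactivationPolicy.from_scheme(scheme, xi_11=1.0, xi_12=0.5)
print(f"\nleading eigenvalues at h = 0.25 (RXI mutant in a PXI resident):")
for linkage, r in (("X", 0.0), ("X", 0.1), ("X", 0.5), ("autosome", 0.5)):
    res = invasion(scheme, policy, r=r, linkage=linkage)
    tag = f"{linkage}-linked, r = {r}" if linkage == "X" else "autosomal"
    print(f"  {tag:22s} lambda = {res.lambda_lead:.8f}  invades = {res.invades}")
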