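# xinact

Deterministic population genetics of X-inactivation strategy evolution.

Female mammals silence one X chromosome per somatic cell. Whether the
silenced copy is always the paternal one (paternal X inactivation, PXI)
or chosen at random (random X inactivation, RXI) changes the effective
dominance of X-linked alleles in females, and therefore feeds back on
allele frequencies and on selection on the inactivation rule itself.
`xinact` implements a two-locus modifier model of this feedback: an
X-linked fitness locus **A** under sex-specific selection, and a
modifier locus **B** (X-linked at recombination distance *r*, or
autosomal) whose alleles set the probability ξ that a female silences
her paternally inherited X.

The package provides:

- exact one-generation haplotype recursions for both sexes, usable for
  forward simulation and (via complex-step differentiation of the same
  map) for linear stability analysis;
- closed-form resident equilibria for two variation regimes —
  recurrent deleterious mutation at mutation–selection balance, and a
  sexually antagonistic balanced polymorphism — validated against the
  iterated recursions;
- invasion analysis of rare modifier alleles: leading eigenvalues,
  critical dominance thresholds for the PXI → RXI transition, and
  numeric invasion boundaries by eigenvalue bisection;
- evolutionarily stable inactivation ratios (closed-form and numeric),
  invasion-substitution walks, and mean-fitness accounting for each sex
  across strategy transitions;
- parameter sweeps, preset figure tables, and a thin `xinact` CLI.

## Worked example

When is random inactivation favored over strict paternal inactivation?
For deleterious variation the answer is a dominance threshold
`h_crit = 3/(6 − 2 s_m + s_f)`:

```python
from xinact import (
    InactivationPolicy, SelectionScheme, h_crit_msb, invasion,
)

scheme = SelectionScheme(
    mode="deleterious", s_f=0.2, s_m=0.2, h=0.25, u_f=1e-5, u_m=1e-5
)
print(h_crit_msb(scheme.s_f, scheme.s_m))

# rare modifier switching carriers from PXI (xi = 1) to unbiased RXI (xi = 1/2)
policy = InactivationPolicy.from_scheme(scheme, xi_11=1.0, xi_12=0.5)
res = invasion(scheme, policy, r=0.1)
print(res.lambda_lead, res.invades)
```

```
0.5172413793103449
1.0000035414961188 True
```

Here `h = 0.25 < h_crit ≈ 0.517`, so the RXI modifier invades
(leading eigenvalue above one). The verdict — though not the
eigenvalue's magnitude — is independent of `r` and of autosomal
placement. Once RXI is established, the stable silencing ratio under
sexually antagonistic variation is paternally biased:

```python
from xinact import ess_sa
print(ess_sa(SelectionScheme(
    mode="sexually_antagonistic", s_f=0.25, t_m=0.2, h=0.2
)).xi_star)
```

```
0.5421004750049282
```

The same analyses are available from the command line:

```
$ xinact ess --mode sexually_antagonistic --sf 0.25 --tm 0.2 --h 0.2
{
  "xi_star": 0.5421004750049282,
  "source": "analytic",
  "bias_direction": "paternal",
  ...
}
```

The `examples/` directory contains short narrative scripts, one per
capability: resident equilibria, invasion thresholds, ESS ratios,
per-sex fitness consequences, and sweeps/CLI usage. Each runs in
seconds with `python examples/<name>.py`.

## Model summary

Haplotypes are ordered `A1B1, A2B1, A1B2, A2B2`; state is the pair of
haplotype frequency vectors in eggs and sperm. Female fitness follows
the power family `w(x) = 1 − x^k s_f`, where `x` is the fraction of
cells expressing `A1` and `k = −ln(h)/ln(2)` calibrates the family so
that unbiased RXI reproduces an ordinary dominance coefficient `h`. A
strategy ξ then induces parent-of-origin dominance `h_mat = ξ^k`,
`h_pat = (1 − ξ)^k`. Males are hemizygous; selection on them is either
purifying (`s_m`, deleterious mode) or favoring the female-deleterious
allele (`t_m`, sexually antagonistic mode). See `docs/methods.md` for
the full model description, derivations, and numerical methods.
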