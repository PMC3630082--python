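# Methods

## Model

### Loci, haplotypes and life cycle

Two loci are tracked. The **A locus** is X-linked with alleles `A1`
and `A2` and is the target of selection. The **B locus** is a modifier
of the X-inactivation strategy, either X-linked at recombination
fraction `r` from A, or autosomal. Haplotypes are indexed in the fixed
order `A1B1, A2B1, A1B2, A2B2`; the population state is the pair of
haplotype frequency vectors `x` (eggs) and `y` (sperm).

Generations are discrete and non-overlapping, the population effectively
infinite, and mating random. Each generation applies, in order:
random union of gametes; viability selection (sex-specific); meiosis
with recombination; mutation; gamete production. Females of the next
generation form from egg haplotype `i` and sperm haplotype `j` with
probability `x_i y_j` and survive with relative fitness `f_ij` (maternal
haplotype listed first, because parental origin matters in females).
Their eggs carry each parental haplotype with probability `(1 − r)/2`
and each recombinant with probability `r/2`. Males carry a single,
maternally inherited X (haplotype `i` with probability `x_i`) and
survive with fitness `m_i`. With an X-linked modifier, sperm transmit
the male's haplotype intact; with an autosomal modifier, the female map
uses effective free recombination (`r = 1/2`, since A and B then assort
independently) and each sperm carries either of the father's autosomal B
copies with probability 1/2, the male's B pair being one maternal and
one "paternal-pool" copy. Mutation `A2 → A1` occurs per gamete at rate
`u_f` in eggs and `u_m` in sperm; back-mutation is neglected.

Recombination enters the female update only through the four
double-heterozygous mating classes: writing `F` for mean female fitness,

```
x'(r) = x'(0) + (r / 2F) · D · (−1, +1, +1, −1),
D = x1 y4 f14 + x4 y1 f41 − x2 y3 f23 − x3 y2 f32
```

(1-indexed), an identity the test suite checks directly.

### Inactivation strategies and fitness

A female's B genotype sets ξ, the probability that each somatic cell
silences the **paternally** inherited X. Strict paternal inactivation
(PXI) is ξ = 1; unbiased random inactivation (RXI) is ξ = 1/2.
Silencing decisions are independent across the (effectively infinite)
cell population, so a heterozygous female expresses `A1` in a fraction
ξ or 1 − ξ of cells according to the parental origin of `A1`.

Female fitness follows the one-parameter power family

```
w(x) = 1 − x^k · s_f,
```

where `x` is the fraction of cells expressing the deleterious (female-
perspective) allele `A1`. The exponent is calibrated so that unbiased
RXI reproduces a conventional dominance coefficient `h`:
`w(1/2) = 1 − h s_f` requires `(1/2)^k = h`, i.e. `k = −ln(h)/ln(2)`.
`k > 1` (`h < 1/2`) means partial recessivity with synergy between
expressing cells; `k = 1` (`h = 1/2`) is the cell-autonomous
(multiplicative) special case, recovered in the tests by curve-fitting.
A strategy ξ then induces **parent-of-origin dominance**

```
h_mat = ξ^k    (A1 inherited maternally),
h_pat = (1 − ξ)^k  (A1 inherited paternally),
```

so PXI fully exposes maternal alleles (`h_mat = 1`) and fully masks
paternal ones (`h_pat = 0`). Males do not inactivate; their fitness is
`1 − s_m` for `A1` carriers in the **deleterious** mode and `1 − t_m`
for `A2` carriers in the **sexually antagonistic** mode (where `A1`
harms females but benefits males).

### Variation regimes

- **Deleterious mode** (mutation–selection balance): `A1` is
  unconditionally deleterious (`s_f`, `s_m > 0`) and recurrently
  produced by mutation. To first order in the mutation rates the
  balance frequencies in eggs and sperm are

  ```
  q_f = (2 u_f + u_m (1 − s_f h_pat)) / D,
  D   = s_f h_mat + s_m + s_f h_pat (1 − s_m),
  q_m = q_f (1 − s_m) + u_m .
  ```

  The neglected terms are O(u²) with a coefficient that grows like
  `1/D`; the tests bound the error by `3 q_f² / D` against deep
  iteration of the recursion, and a Newton polish (complex-step
  Jacobian) is available to refine the closed form to machine
  precision.

- **Sexually antagonistic mode**: `A1` benefits males (`t_m`) and harms
  females (`s_f`); mutation is set to zero. When both alleles invade
  when rare (protected polymorphism; checked from the exact boundary
  linearizations), the interior equilibrium is, exactly,

  ```
  q_f = (t_m − s_f (h_mat (1 − t_m) + h_pat))
        / (2 s_f (1 − h_mat (1 − t_m) − h_pat)),
  q_m = q_f / (q_f + (1 − q_f)(1 − t_m)).
  ```

  Under strict PXI the protected region reduces to the band
  `t_m/(1 + t_m) < s_f < t_m/(1 − t_m)`, symmetric under `s_f ↔ t_m`.

## Invasion analysis

A resident population fixed for `B1` (strategy `ξ_11`) sits at its
single-locus equilibrium. A rare `B2` (carriers use `ξ_12`) perturbs
the four `B2`-bearing haplotype frequencies; because those are rare, the
full 8×8 Jacobian is block-triangular and invasion is decided by the
leading eigenvalue λ of the 4×4 rare block. `B2` invades iff λ > 1
(with a 1e−10 neutrality band).

The block is obtained by **complex-step differentiation** (step 1e−60)
of the same one-generation map used for simulation — a single source of
truth, exact to machine precision — and can be cross-checked against
central finite differences (step 1e−7). The dense eigensolve is
cross-validated by Newton–Raphson on the characteristic polynomial, and
the resident equilibrium's own stability is verified before
linearizing. A modifier with `ξ_12 = ξ_11` is exactly neutral (λ = 1),
which the machinery reproduces to ~1e−15 — a strong end-to-end check of
the transcription of the recursions.

For the PXI → unbiased-RXI comparison the invasion condition reduces to
closed-form critical dominance thresholds:

```
deleterious:              h_crit = 3 / (6 − 2 s_m + s_f)
sexually antagonistic:    h_crit = (1 − t_m) / (2 − t_m)
```

Both tend to 1/2 under vanishing selection and are independent of `r`
and of modifier linkage; the tests confirm this by eigenvalue bisection
and by verdict comparison across `r ∈ {0, 0.1, 0.25, 0.5}` and
autosomal placement on random scenarios. Selection on a modifier
affected by `n` independent fitness loci aggregates, for weak per-locus
effects, as `s_mod = n · mean(λ_i − 1)`.

## Evolutionarily stable inactivation ratios

For partially recessive variation (`h < 1/2`), define
`e = −ln 2 / ln(2h) = 1/(k − 1) > 0`. The ESS balances the marginal
exposure of maternally versus paternally inherited deleterious alleles,
yielding the self-consistency condition `ξ/(1 − ξ) = R^e` with
`R = q_m (1 − q_f) / (q_f (1 − q_m))`, the odds that a deleterious
allele arrives paternally rather than maternally.

- **Sexually antagonistic**: at the interior equilibrium
  `R = 1/(1 − t_m)` exactly, so `ξ* = 1/(1 + (1 − t_m)^e) > 1/2`
  always — selection favors preferential silencing of the paternal X.
- **Deleterious**: `R` depends on ξ through the balance frequencies;
  the exact ESS is found by a bracketed root solve of the
  self-consistency condition. Under weak selection (and `u_f = u_m`)
  `R ≈ 1 − (2/3)(s_m − s_f h)`, giving the bias rule: the maternal X is
  preferentially silenced (`ξ* < 1/2`) exactly when `s_m > s_f h`. The
  exact solve obeys the same rule away from the knife edge but carries
  higher-order corrections on it. With sex-biased mutation the rule
  generalizes to `(u_m/u_f) s_f h < s_m`.

Numerically, the ESS is located as the zero of the invasion gradient
`[λ(ξ, ξ+δ) − λ(ξ, ξ−δ)]/2` (δ = 1e−3; the symmetric form removes the
O(δ) bias of the one-sided gradient near the ESS). Convergence
stability is demonstrated by invasion-substitution walks with halving
step size. In the antagonistic mode the polymorphism itself exists
only over part of the strategy range, so numeric brackets and walk
starting points are confined (automatically, for the gradient solver)
to the strategy range with a protected polymorphism.

## Mean-fitness accounting

Replacing PXI with unbiased RXI moves the A-locus equilibrium, changing
mean fitness in both sexes. Female mean fitness is assembled from the
genotype table (random union of gametes); male mean fitness is
`1 − s q_f`, because male zygotes carry the maternally transmitted X.
In the deleterious mode, O(u)-accurate closed forms
(`w_f = 1 − s_f (h_mat q_f + h_pat q_m)`, `w_m = 1 − s_m q_f`) agree
with the full table to O(u²); within the RXI-evolvable region female
fitness rises and male fitness falls whenever `s_m > 0` (PXI purges
deleterious variation harder, so RXI raises the frequency males
inherit). In the antagonistic mode male fitness rises exactly when
`s_f > t_m`; on the `s_f = t_m` diagonal `q_f = 1/2` under every
strategy and male fitness is unchanged, so over the evolvable region
male fitness rises in exactly half of the points where it changes at
all. Points where a strategy loses the protected polymorphism are
labeled with the fixing allele and assessed at the boundary.

## Numerical choices

- **Single arithmetic core**: the one-generation map is written once,
  dtype-generically, and compiled with numba for float64 (simulation)
  and complex128 (complex-step linearization) alike.
- **Equilibration**: fixed-point iteration with per-generation max
  change tolerance (default 1e−12, down to 1e−14 in validation runs)
  and explicit non-convergence flags; long runs use a compiled driver.
- **Root finding**: Brent bracketing for invasion boundaries and ESS
  solves; Newton with complex-step Jacobians for equilibrium polishing.
- **Tolerances**: neutrality band 1e−10 on λ; closed-form vs iterated
  equilibria `3 q_f²/D` (deleterious, with a 1e−8 floor) and 1e−8
  (antagonistic); ESS closed vs numeric 1e−3.

## Limitations

- Deterministic, infinite-population dynamics: no drift, so "invasion"
  means deterministic increase from rarity.
- The A locus carries exactly two alleles; multilocus genomes are
  treated only through the weak-effect aggregation of per-locus
  eigenvalues.
- The power fitness family ties the dominance coefficient to the
  silencing ratio with a single shape parameter `k`; the ESS analysis
  additionally assumes partial recessivity (`h < 1/2`).
- Imprinting, cell-lineage effects, escape from inactivation and
  tissue-specific silencing are outside the model.
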