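"""Parameter sweeps, scenario generation and tabular output.

Sweeps evaluate invasion eigenvalues, critical dominance thresholds, ESS
inactivation ratios, fitness changes or equilibria over parameter grids
and return long-format :class:`pandas.DataFrame` tables (one row per
grid point per quantity).  Named presets regenerate the package's
standard figures as tables:

* ``fig2``  - critical dominance curves for RXI invasion, deleterious
  (several ``s_m/s_f`` ratios) and sexually antagonistic variation;
* ``fig3``  - per-sex mean-fitness change classification over the
  (t_m, s_f) square;
* ``fig4``  - ESS inactivation ratio versus selection strength for both
  variation modes;
* ``figs1`` - relative strength of selection on an autosomal modifier
  from a deleterious versus a sexually antagonistic locus.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .equilibria import (
    NoInteriorEquilibriumError,
    resident_equilibrium,
    sa_polymorphism_region,
)
from .ess import (
    ess_msb,
    ess_numeric,
    ess_sa,
    mean_fitness_change_msb,
    mean_fitness_change_sa,
    sa_region_classification,
)
from .params import InactivationPolicy, SelectionScheme, VariationMode
from .stability import h_crit_msb, h_crit_sa, invasion

__all__ = [
    "SweepSpec",
    "run_sweep",
    "random_scenarios",
    "run_preset",
    "load_scenario",
    "PRESETS",
]

_SCENARIO_KEYS = {
    "mode",
    "s_f",
    "s_m",
    "t_m",
    "h",
    "u_f",
    "u_m",
    "u",
    "r",
    "linkage",
    "xi_11",
    "xi_12",
    "xi_22",
}

_QUANTITIES = ("lambda", "h_crit", "xi_star", "fitness_change", "equilibria")


def load_scenario(source: str | Path | dict) -> dict:
    """Read a scenario config (YAML mapping or flat ``key=value`` lines).

    Returns a plain dict restricted to the documented scenario schema;
    ``u`` expands to ``u_f = u_m = u``.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
        try:
            raw = yaml.safe_load(text)
        except yaml.YAMLError:
            raw = None
        if not isinstance(raw, dict):
            raw = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                raw[key.strip()] = yaml.safe_load(value.strip())
    else:
        raw = dict(source)
    unknown = set(raw) - _SCENARIO_KEYS
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    if "u" in raw:
        u = raw.pop("u")
        raw.setdefault("u_f", u)
        raw.setdefault("u_m", u)
    return raw


def scheme_from_scenario(scenario: dict) -> SelectionScheme:
    keys = ("mode", "s_f", "s_m", "t_m", "h", "u_f", "u_m")
    kwargs = {k: scenario[k] for k in keys if k in scenario}
    if "u" in scenario:
        kwargs.setdefault("u_f", scenario["u"])
        kwargs.setdefault("u_m", scenario["u"])
    return SelectionScheme(**kwargs)


def policy_from_scenario(scenario: dict, scheme: SelectionScheme) -> InactivationPolicy:
    return InactivationPolicy.from_scheme(
        scheme,
        xi_11=scenario.get("xi_11", 1.0),
        xi_12=scenario.get("xi_12"),
        xi_22=scenario.get("xi_22"),
    )


@dataclass(frozen=True)
class SweepSpec:
    """A grid sweep: fixed scenario defaults plus varied parameters.

    ``varied`` maps parameter names (scenario schema) to grids;
    ``outputs`` lists requested quantities among
    ``lambda, h_crit, xi_star, fitness_change, equilibria``.
    """

    fixed: dict = field(default_factory=dict)
    varied: dict = field(default_factory=dict)
    outputs: tuple = ("lambda",)
    seed: int = 0

    def __post_init__(self) -> None:
        unknown = (set(self.fixed) | set(self.varied)) - _SCENARIO_KEYS
        if unknown:
            raise ValueError(f"unknown scenario parameters: {sorted(unknown)}")
        for q in self.outputs:
            if q not in _QUANTITIES:
                raise ValueError(f"unknown output quantity {q!r}")
        for name, grid in self.varied.items():
            arr = np.asarray(grid, dtype=float)
            if arr.ndim != 1 or arr.size == 0 or not np.all(np.isfinite(arr)):
                raise ValueError(f"grid for {name!r} must be a finite 1-D sequence")

    def grid_points(self) -> Iterable[dict]:
        names = list(self.varied)
        if not names:
            yield dict(self.fixed)
            return
        grids = [np.asarray(self.varied[n], dtype=float) for n in names]
        mesh = np.meshgrid(*grids, indexing="ij")
        for idx in np.ndindex(mesh[0].shape):
            point = dict(self.fixed)
            point.update({n: float(m[idx]) for n, m in zip(names, mesh)})
            yield point


def _evaluate_point(scenario: dict, quantity: str) -> dict:
    scheme = scheme_from_scenario(scenario)
    out: dict[str, Any] = {}
    r = scenario.get("r", 0.5)
    linkage = scenario.get("linkage", "X")
    if quantity == "lambda":
        policy = policy_from_scenario(scenario, scheme)
        res = invasion(scheme, policy, r=r, linkage=linkage)
        out.update(
            {
                "lambda": res.lambda_lead,
                "invades": res.invades,
                "char_poly_residual": res.char_poly_residual,
            }
        )
    elif quantity == "h_crit":
        if scheme.mode is VariationMode.DELETERIOUS:
            out["h_crit"] = h_crit_msb(scheme.s_f, scheme.s_m)
        else:
            out["h_crit"] = h_crit_sa(scheme.t_m)
    elif quantity == "xi_star":
        if scheme.mode is VariationMode.DELETERIOUS:
            out["xi_star"] = ess_msb(scheme).xi_star
        else:
            out["xi_star"] = ess_sa(scheme).xi_star
    elif quantity == "fitness_change":
        if scheme.mode is VariationMode.DELETERIOUS:
            fc = mean_fitness_change_msb(scheme)
        else:
            fc = mean_fitness_change_sa(scheme)
        out.update(
            {
                "mean_w_f_before": fc.mean_w_f_before,
                "mean_w_m_before": fc.mean_w_m_before,
                "mean_w_f_after": fc.mean_w_f_after,
                "mean_w_m_after": fc.mean_w_m_after,
                "female_up": fc.female_up,
                "male_up": fc.male_up,
                "region_label": fc.region_label,
            }
        )
    elif quantity == "equilibria":
        policy = policy_from_scenario(scenario, scheme)
        eq = resident_equilibrium(scheme, policy)
        out.update({"q_f": eq.q_f, "q_m": eq.q_m})
    return out


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate the requested quantities over the sweep grid.

    One row per grid point per quantity; failures at individual points
    are recorded in the ``error`` column, never aborting the sweep.
    """
    rows = []
    for point in spec.grid_points():
        for quantity in spec.outputs:
            row = dict(point)
            row["quantity"] = quantity
            try:
                row.update(_evaluate_point(point, quantity))
                row["error"] = ""
            except Exception as exc:  # per-row error capture by design
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    df = pd.DataFrame(rows)
    df["package_version"] = __version__
    return df


def write_sweep(df: pd.DataFrame, spec: SweepSpec, out: str | Path) -> None:
    """Write a sweep as CSV with a JSON sidecar describing the spec."""
    out = Path(out)
    df.to_csv(out, index=False)
    sidecar = out.with_suffix(out.suffix + ".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(spec), indent=2, default=list))


def random_scenarios(
    n: int,
    seed: int,
    mode: str = "deleterious",
    require_polymorphism: bool = True,
    max_tries: int = 10_000,
) -> list[tuple[SelectionScheme, InactivationPolicy]]:
    """Reproducible random scenario draws for property testing.

    Selection coefficients are log-uniform on (1e-3, 0.9), dominance
    uniform on (0.01, 0.49), mutation rates log-uniform on (1e-8, 1e-4),
    silencing probabilities uniform.  Sexually antagonistic draws are
    rejection-resampled into the protected-polymorphism region of the
    resident strategy when requested.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    mode = VariationMode(mode)
    rng = np.random.default_rng(seed)
    out: list[tuple[SelectionScheme, InactivationPolicy]] = []
    tries = 0
    while len(out) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("rejection sampling failed to fill the request")
        s_f = float(10 ** rng.uniform(-3, np.log10(0.9)))
        h = float(rng.uniform(0.01, 0.49))
        xi_11 = float(rng.uniform(0.01, 0.99))
        xi_12 = float(rng.uniform(0.0, 1.0))
        if mode is VariationMode.DELETERIOUS:
            s_m = float(10 ** rng.uniform(-3, np.log10(0.9)))
            u = float(10 ** rng.uniform(-8, -4))
            u = min(u, s_f * h / 20.0)  # keep mutation weak relative to selection
            scheme = SelectionScheme(
                mode=mode, s_f=s_f, s_m=s_m, h=h, u_f=u, u_m=u
            )
        else:
            t_m = float(10 ** rng.uniform(-3, np.log10(0.9)))
            scheme = SelectionScheme(mode=mode, s_f=s_f, t_m=t_m, h=h)
        policy = InactivationPolicy.from_scheme(scheme, xi_11=xi_11, xi_12=xi_12)
        if mode is VariationMode.SEXUALLY_ANTAGONISTIC and require_polymorphism:
            protected, _ = sa_polymorphism_region(scheme, policy)
            if not protected:
                continue
        out.append((scheme, policy))
    return out


def _preset_fig2(n_points: int = 101) -> pd.DataFrame:
    """Critical dominance curves: deleterious mode for several s_m/s_f
    ratios versus s_f, and the sexually antagonistic curve versus t_m."""
    s = np.linspace(0.005, 0.895, n_points)
    rows = []
    for ratio in (0.5, 1.0, 2.0):
        for s_f in s:
            s_m = min(ratio * s_f, 0.99)
            rows.append(
                {
                    "curve": f"msb_sm/sf={ratio}",
                    "x": s_f,
                    "h_crit": h_crit_msb(s_f, s_m),
                }
            )
    for t_m in s:
        rows.append({"curve": "sa", "x": t_m, "h_crit": h_crit_sa(t_m)})
    return pd.DataFrame(rows)


def _preset_fig3(n_grid: int = 200) -> pd.DataFrame:
    return sa_region_classification(n_grid=n_grid)


def _preset_fig4(n_points: int = 41) -> pd.DataFrame:
    """ESS inactivation ratio versus selection strength, s_m = s_f for
    the deleterious case, at two dominance values."""
    s = np.linspace(0.01, 0.6, n_points)
    rows = []
    for h in (0.1, 0.25, 0.4):
        for v in s:
            scheme = SelectionScheme(
                mode=VariationMode.DELETERIOUS, s_f=v, s_m=v, h=h, u_f=1e-5, u_m=1e-5
            )
            rows.append(
                {"curve": f"msb_h={h}", "x": v, "xi_star": ess_msb(scheme).xi_star}
            )
            sa = SelectionScheme(
                mode=VariationMode.SEXUALLY_ANTAGONISTIC, s_f=v, t_m=v, h=h
            )
            rows.append({"curve": f"sa_h={h}", "x": v, "xi_star": ess_sa(sa).xi_star})
    return pd.DataFrame(rows)


def _preset_figs1(n_points: int = 13) -> pd.DataFrame:
    """Relative selection strength on an autosomal modifier: deleterious
    locus (xi_12 = 1/2 - 1e-3) versus sexually antagonistic locus
    (xi_12 = 1/2 + 1e-3), h = 0.25, u = 1e-5, s_m = t_m = s_f."""
    rows = []
    for s_f in np.linspace(0.05, 0.65, n_points):
        del_scheme = SelectionScheme(
            mode=VariationMode.DELETERIOUS, s_f=s_f, s_m=s_f, h=0.25, u_f=1e-5, u_m=1e-5
        )
        del_pol = InactivationPolicy.from_scheme(del_scheme, xi_11=0.5, xi_12=0.5 - 1e-3)
        s_del = invasion(del_scheme, del_pol, linkage="autosome").selection_strength
        sa_scheme = SelectionScheme(
            mode=VariationMode.SEXUALLY_ANTAGONISTIC, s_f=s_f, t_m=s_f, h=0.25
        )
        sa_pol = InactivationPolicy.from_scheme(sa_scheme, xi_11=0.5, xi_12=0.5 + 1e-3)
        try:
            s_sa = invasion(sa_scheme, sa_pol, linkage="autosome").selection_strength
            ratio = s_del / s_sa if s_sa != 0 else np.nan
            err = ""
        except NoInteriorEquilibriumError as exc:
            s_sa, ratio, err = np.nan, np.nan, str(exc)
        rows.append(
            {
                "s_f": s_f,
                "s_del": s_del,
                "s_sa": s_sa,
                "ratio_del_over_sa": ratio,
                "error": err,
            }
        )
    return pd.DataFrame(rows)


PRESETS = {
    "fig2": _preset_fig2,
    "fig3": _preset_fig3,
    "fig4": _preset_fig4,
    "figs1": _preset_figs1,
}


def run_preset(name: str, **kwargs) -> pd.DataFrame:
    """Run a named preset sweep and return its table."""
    try:
        fn = PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None
    df = fn(**kwargs)
    df["package_version"] = __version__
    return df
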