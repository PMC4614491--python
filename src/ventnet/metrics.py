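"""Derived quantities and repeated-run statistics.

Damage proxy: the maximal liquid pressure gradient across the advancing tip
recorded for each airway (``G_max``, dyn cm^-2 per um).  An airway counts as
*damaged* when its ``G_max`` exceeds a threshold (default ``10**3.5``, an
arbitrary cut that illuminates spatial trends).  *Relative damage* is an
airway's ``G_max`` divided by the mean over the recruited airways of its
generation, so it averages to one per fully recruited generation.  Because
recruitment-time and stress distributions are strongly non-Gaussian at high
heterogeneity, summaries report medians and 5/95% quantiles alongside
mean +/- s.d.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .engine import Numerics, SimResult, VentilatorProtocol, simulate
from .errors import DomainError
from .network import build_network
from .reopening import FluidParams
from .tube_law import stiffness

DAMAGE_THRESHOLD_DEFAULT = 10.0**3.5  # dyn cm^-2 um^-1


@dataclass
class DamageReport:
    per_airway: pd.DataFrame  # id, generation, G_max, assessed, relative, damaged
    G_net: float
    per_generation: pd.DataFrame  # generation, n, n_assessed, n_damaged, proportion
    threshold: float


def damage_report(
    result: SimResult, threshold: float = DAMAGE_THRESHOLD_DEFAULT
) -> DamageReport:
    """Classify per-airway damage from a simulation's recorded tip stresses.

    Airways whose tip never advanced are excluded from generation means and
    flagged not-assessed; damaged proportions are per generation, out of all
    airways in the generation.
    """
    df = result.airways[["id", "generation", "G_max"]].copy()
    df["assessed"] = result.airways["t_start_s"].notna().to_numpy()
    gen_mean = (
        df[df["assessed"]].groupby("generation")["G_max"].mean().rename("gen_mean")
    )
    df = df.join(gen_mean, on="generation")
    with np.errstate(invalid="ignore", divide="ignore"):
        df["relative"] = np.where(
            df["assessed"] & (df["gen_mean"] > 0), df["G_max"] / df["gen_mean"], np.nan
        )
    df["damaged"] = df["assessed"] & (df["G_max"] > threshold)
    per_gen = (
        df.groupby("generation")
        .agg(
            n=("id", "size"),
            n_assessed=("assessed", "sum"),
            n_damaged=("damaged", "sum"),
        )
        .reset_index()
    )
    per_gen["proportion"] = per_gen["n_damaged"] / per_gen["n"]
    g_net = float(df.loc[df["assessed"], "G_max"].max()) if df["assessed"].any() else 0.0
    return DamageReport(
        per_airway=df.drop(columns="gen_mean"),
        G_net=g_net,
        per_generation=per_gen,
        threshold=threshold,
    )


def stiffness_damage_correlation(
    result: SimResult, network=None, at: str = "a_init"
) -> float:
    """Pearson correlation between per-airway wall stiffness and relative
    damage over the assessed airways; NaN when undefined (fewer than three
    assessed airways or degenerate variance).

    Stiffness is evaluated at the initial collapsed area (the wall state at
    recruitment onset) by default, or at the equilibrium area (``at="a_eq"``).
    """
    rep = damage_report(result)
    df = rep.per_airway[rep.per_airway["assessed"]]
    if network is None:
        raise DomainError("network is required to evaluate airway stiffness")
    gammas = []
    for i in df["id"]:
        airway = network.airways[int(i)]
        area = airway.reopening.a_init if at == "a_init" else airway.elastica.a_eq
        gammas.append(stiffness(area, airway.elastica))
    x = np.asarray(gammas)
    y = df["relative"].to_numpy()
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y)[0])


def stall_intervals(result: SimResult) -> list[tuple[float, float]]:
    """Maximal time intervals (before full recruitment) during which no tip
    advanced: the airway pressure sits below every frontier yield pressure and
    rises by compliance filling alone.  Includes the initial stall, if any."""
    tr = result.trace
    end = result.t_recruit_all if result.t_recruit_all is not None else np.inf
    active = tr["n_peeling"].to_numpy() > 0
    t = tr["t_s"].to_numpy()
    intervals: list[tuple[float, float]] = []
    start = None
    for i in range(len(t)):
        if t[i] >= end:
            break
        if not active[i]:
            if start is None:
                start = t[i]
        else:
            if start is not None and t[i] > start:
                intervals.append((start, t[i]))
            start = None
    if start is not None and end > start and np.isfinite(end):
        intervals.append((start, float(end)))
    return [(a, b) for a, b in intervals if b > a]


@dataclass
class EnsembleSummary:
    """Statistics over repeated seeded simulations of one condition."""

    runs: pd.DataFrame  # one row per run
    summary: pd.DataFrame  # mean/sd/median/quantiles per quantity
    n_runs: int
    seeds: list[int]
    condition: dict
    envelopes: pd.DataFrame | None = None  # common-grid mean +/- s.d. traces


_SUMMARY_QUANTITIES = ("t_R", "t_first_passage", "G_net", "n_acini_open",
                       "n_recruited")


def _summarise(runs: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for q in _SUMMARY_QUANTITIES:
        x = runs[q].to_numpy(dtype=float)
        x = x[np.isfinite(x)]
        if len(x) == 0:
            rows.append({"quantity": q, "n": 0})
            continue
        rows.append(
            {
                "quantity": q,
                "n": len(x),
                "mean": x.mean(),
                "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                "median": np.median(x),
                "q05": np.quantile(x, 0.05),
                "q95": np.quantile(x, 0.95),
            }
        )
    return pd.DataFrame(rows)


def run_ensemble(
    n: int,
    seed_base: int,
    collapse_C: float,
    heterogeneity_d: float,
    protocol: VentilatorProtocol | None = None,
    fluid: FluidParams | None = None,
    numerics: Numerics | None = None,
    damage_threshold: float = DAMAGE_THRESHOLD_DEFAULT,
    envelopes: bool = False,
    envelope_points: int = 200,
) -> EnsembleSummary:
    """Simulate ``n`` independently sampled networks (seeds ``seed_base`` ...
    ``seed_base + n - 1``) under one protocol and summarise the outcomes."""
    if n < 1:
        raise DomainError("ensemble size must be at least 1")
    protocol = protocol or VentilatorProtocol()
    fluid = fluid or FluidParams()
    seeds = list(range(seed_base, seed_base + n))
    rows = []
    traces = []
    for seed in seeds:
        net = build_network(heterogeneity_d, collapse_C, seed, fluid)
        res = simulate(net, protocol, fluid, numerics)
        rep = damage_report(res, damage_threshold)
        row = {
            "seed": seed,
            "t_R": res.t_recruit_all if res.t_recruit_all is not None else np.nan,
            "t_first_passage": (
                res.t_first_passage if res.t_first_passage is not None else np.nan
            ),
            "G_net": rep.G_net,
            "n_recruited": int(res.airways["recruited"].sum()),
            "n_acini_open": int(res.acini["opened"].sum()),
            "complete": res.complete,
            "termination": res.termination,
            "residual_max": res.residual_max,
        }
        for _, g in rep.per_generation.iterrows():
            row[f"damaged_prop_gen{int(g['generation'])}"] = g["proportion"]
        rows.append(row)
        if envelopes:
            traces.append(res.trace[["t_s", "P_cmH2O", "n_recruited"]])
    runs = pd.DataFrame(rows)
    env = None
    if envelopes:
        t_max = max(tr["t_s"].iloc[-1] for tr in traces)
        grid = np.linspace(0.0, t_max, envelope_points)
        P = np.stack(
            [np.interp(grid, tr["t_s"], tr["P_cmH2O"]) for tr in traces]
        )
        nr = np.stack(
            [np.interp(grid, tr["t_s"], tr["n_recruited"]) for tr in traces]
        )
        env = pd.DataFrame(
            {
                "t_s": grid,
                "P_mean": P.mean(axis=0),
                "P_sd": P.std(axis=0, ddof=1) if n > 1 else np.zeros_like(grid),
                "n_recruited_mean": nr.mean(axis=0),
                "n_recruited_sd": (
                    nr.std(axis=0, ddof=1) if n > 1 else np.zeros_like(grid)
                ),
            }
        )
    condition = {
        "collapse_C": collapse_C,
        "heterogeneity_d": heterogeneity_d,
        "v_t_per_kg": protocol.v_t_per_kg,
        "peep": protocol.peep,
        "t_q": protocol.t_q,
    }
    return EnsembleSummary(
        runs=runs,
        summary=_summarise(runs),
        n_runs=n,
        seeds=seeds,
        condition=condition,
        envelopes=env,
    )


def sweep(
    v_t_values,
    collapse_values,
    d_values,
    peep_values=(None,),
    n: int = 100,
    seed_base: int = 0,
    protocol: VentilatorProtocol | None = None,
    fluid: FluidParams | None = None,
    numerics: Numerics | None = None,
) -> pd.DataFrame:
    """Protocol sweep: a tidy frame with one row per run per condition.

    All conditions share the same seed list (matched grids), so ratios across
    conditions compare identical network ensembles.
    """
    base = protocol or VentilatorProtocol()
    out = []
    for vt in v_t_values:
        for c in collapse_values:
            for d in d_values:
                for peep in peep_values:
                    proto = VentilatorProtocol(
                        v_t_per_kg=vt,
                        body_mass=base.body_mass,
                        t_q=base.t_q,
                        peep=peep,
                        subtree_count=base.subtree_count,
                        reference_c=base.reference_c,
                    )
                    ens = run_ensemble(
                        n, seed_base, c, d, proto, fluid, numerics
                    )
                    block = ens.runs.copy()
                    block.insert(0, "v_t_per_kg", vt)
                    block.insert(1, "collapse_C", c)
                    block.insert(2, "heterogeneity_d", d)
                    block.insert(3, "peep", np.nan if peep is None else peep)
                    out.append(block)
    return pd.concat(out, ignore_index=True)


def summarise_sweep(tidy: pd.DataFrame) -> pd.DataFrame:
    """Condition-level means/s.d. of recruitment time and damage metrics."""
    keys = ["v_t_per_kg", "collapse_C", "heterogeneity_d", "peep"]
    g = tidy.groupby(keys, dropna=False)
    return g.agg(
        n=("seed", "size"),
        t_R_mean=("t_R", "mean"),
        t_R_sd=("t_R", "std"),
        G_net_mean=("G_net", "mean"),
        G_net_sd=("G_net", "std"),
        complete_frac=("complete", "mean"),
        n_acini_open_mean=("n_acini_open", "mean"),
    ).reset_index()
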