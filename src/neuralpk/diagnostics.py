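"""Diagnostics for trained neural ODEs.

Two evaluation tools quantify what a trained model learned:

* the derivative-versus-state profile — pairs (x_C, dx_C/dt) sampled along
  a trajectory. For a one-compartment system this is the line
  ``-kel * x_C``; for a two-compartment system a steep distribution-phase
  slope flattening into the terminal phase. Comparing the profile of a
  trained model against the generating mechanism shows how well (and over
  which concentration range) the elimination/distribution mechanism was
  learned — and how badly it degrades outside the trained range.
* simulation reports for held-out regimens — relative RMSE of the model
  curve against the mechanistic oracle. "Relative" means RMSE divided by
  the oracle's mean over the horizon. For data spanning decades (TMDD) the
  comparison is done on log10 concentrations above a floor of 1e-3, the
  smallest observed magnitude, excluding the initial rapid-binding
  transient that sparse sampling cannot resolve.

Reports are evaluated on a geometric time grid at four times the
scenario's sampling density, starting at the first sampling time. Sparse
sampling only constrains the trajectory at that resolution: between
measurements a trained model may wander while still predicting every
observed time point well, so judging the interpolation claim on a grid
much denser than the design would measure behavior the data never
constrained (most visibly inside the steep TMDD transition).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .odeint import SolverConfig, derivative_along_trajectory, solve
from .pk import DoseRegimen, PKParams, ScenarioSpec, central_index, \
    initial_condition, mechanistic_rhs, simulate_reference
from .structures import NODEModel

__all__ = [
    "DerivativeStateProfile",
    "SimulationReport",
    "node_profile",
    "reference_profile",
    "compare_profiles",
    "simulate_node",
    "interpolation_report",
    "LOG_FLOOR",
]

LOG_FLOOR = 1e-3          # smallest observed concentration magnitude
DEFAULT_REL_TOL = 0.15    # "coincides well" threshold on relative RMSE

EVAL_SOLVER = SolverConfig(rtol=1e-6, atol=1e-8)


@dataclass
class DerivativeStateProfile:
    """Paired (concentration, derivative) samples along a trajectory."""

    conc: np.ndarray
    deriv: np.ndarray
    time: np.ndarray
    dose_group: str = ""
    source: str = "node"      # "node" | "reference"


@dataclass
class SimulationReport:
    """Agreement of a model curve with the mechanistic oracle for one
    held-out regimen."""

    regimen: DoseRegimen
    times: np.ndarray
    predicted: np.ndarray
    oracle: np.ndarray
    rel_rmse: float
    max_abs_err: float
    negative_prediction: bool
    log_space: bool = False

    def to_dict(self) -> dict:
        return {
            "regimen": {
                "route": self.regimen.route,
                "dose": self.regimen.d,
                "kin": self.regimen.kin,
                "tinf": self.regimen.tinf,
            },
            "rel_rmse": self.rel_rmse,
            "max_abs_err": self.max_abs_err,
            "negative_flag": self.negative_prediction,
            "log_space": self.log_space,
        }


def _dense_times(horizon: float, n: int = 200, start: float = 0.0) -> np.ndarray:
    return np.linspace(start, horizon, n)


def simulate_node(model: NODEModel, regimen: DoseRegimen, times,
                  cfg: SolverConfig | None = None) -> np.ndarray:
    """Central-compartment curve of a neural-ODE model at ``times``
    (adaptive solver at evaluation tolerances)."""
    model.validate_regimen(regimen)
    cfg = cfg or EVAL_SOLVER
    if regimen.route == "iv_infusion" and regimen.tinf not in cfg.breakpoints:
        cfg = SolverConfig(method=cfg.method, rtol=cfg.rtol, atol=cfg.atol,
                           breakpoints=tuple(cfg.breakpoints) + (regimen.tinf,))
    times = np.asarray(times, dtype=float)
    t_solve = times if times[0] == 0 else np.concatenate([[0.0], times])
    traj = solve(lambda x, t: model.rhs(x, t, regimen),
                 model.initial_state(regimen), t_solve, cfg)
    if times[0] != 0:
        traj = traj[1:]
    return traj[:, model.central_index]


def node_profile(model: NODEModel, regimen: DoseRegimen, horizon: float,
                 n: int = 200, dose_group: str = "") -> DerivativeStateProfile:
    """Derivative-vs-state profile of a model on a dense time grid."""
    times = _dense_times(horizon, n)
    cfg = EVAL_SOLVER
    if regimen.route == "iv_infusion":
        cfg = SolverConfig(rtol=cfg.rtol, atol=cfg.atol,
                           breakpoints=(regimen.tinf,))
    rhs = lambda x, t: model.rhs(x, t, regimen)
    traj = solve(rhs, model.initial_state(regimen), times, cfg)
    conc, deriv = derivative_along_trajectory(rhs, traj, times,
                                              central_index=model.central_index)
    return DerivativeStateProfile(conc=conc, deriv=deriv, time=times,
                                  dose_group=dose_group, source="node")


def reference_profile(model_id: str, params: PKParams, regimen: DoseRegimen,
                      horizon: float, n: int = 200,
                      dose_group: str = "") -> DerivativeStateProfile:
    """Derivative-vs-state profile of a mechanistic model."""
    times = _dense_times(horizon, n)
    cfg = SolverConfig(rtol=1e-8, atol=1e-10,
                       breakpoints=(regimen.tinf,)
                       if regimen.route == "iv_infusion" else ())
    rhs = lambda x, t: mechanistic_rhs(model_id, params, regimen, x, t)
    traj = solve(rhs, initial_condition(model_id, params, regimen), times, cfg)
    conc, deriv = derivative_along_trajectory(
        rhs, traj, times, central_index=central_index(model_id, params)
    )
    return DerivativeStateProfile(conc=conc, deriv=deriv, time=times,
                                  dose_group=dose_group, source="reference")


def compare_profiles(node_prof: DerivativeStateProfile,
                     ref_prof: DerivativeStateProfile,
                     conc_range: tuple, n_grid: int = 100) -> dict:
    """Mean/max absolute derivative discrepancy on a common concentration
    grid inside ``conc_range`` (restricted to where both profiles have
    support)."""
    lo = max(conc_range[0], node_prof.conc.min(), ref_prof.conc.min())
    hi = min(conc_range[1], node_prof.conc.max(), ref_prof.conc.max())
    if not hi > lo:
        raise ValueError(
            f"profiles do not overlap on the requested range {conc_range}"
        )
    grid = np.linspace(lo, hi, n_grid)

    def interp(prof):
        order = np.argsort(prof.conc)
        return np.interp(grid, prof.conc[order], prof.deriv[order])

    diff = np.abs(interp(node_prof) - interp(ref_prof))
    return {
        "mean_abs": float(diff.mean()),
        "max_abs": float(diff.max()),
        "conc_lo": float(lo),
        "conc_hi": float(hi),
    }


def _rel_rmse(pred, oracle, log_space: bool) -> float:
    pred = np.asarray(pred, dtype=float)
    oracle = np.asarray(oracle, dtype=float)
    if log_space:
        # decades above the observation floor; negative predictions clip to 0
        yp = np.log10(np.clip(pred, LOG_FLOOR, None) / LOG_FLOOR)
        yo = np.log10(np.clip(oracle, LOG_FLOOR, None) / LOG_FLOOR)
        return float(np.sqrt(np.mean((yp - yo) ** 2)) / np.mean(yo))
    return float(np.sqrt(np.mean((pred - oracle) ** 2)) / np.mean(oracle))


def plot_report(reports, path, log_scale: bool = False) -> None:
    """Render predicted-vs-oracle curves for a list of SimulationReports
    to a PNG (convenience; CSV/JSON outputs are the contract)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for rep in reports:
        label = (f"kin={rep.regimen.kin:g}, tinf={rep.regimen.tinf:g}"
                 if rep.regimen.route == "iv_infusion"
                 else f"d={rep.regimen.d:g}")
        (line,) = ax.plot(rep.times, rep.oracle, lw=1.5,
                          label=f"{label} (reference)")
        ax.plot(rep.times, rep.predicted, "--", lw=1.5,
                color=line.get_color(), label=f"{label} (model)")
    if log_scale:
        ax.set_yscale("log")
    ax.set_xlabel("time")
    ax.set_ylabel("concentration")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_profile(profiles, path) -> None:
    """Render derivative-versus-state profiles to a PNG."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4.5))
    for prof in profiles:
        style = "-" if prof.source == "reference" else "--"
        label = f"{prof.source} {prof.dose_group}".strip()
        ax.plot(prof.conc, prof.deriv, style, lw=1.5, label=label)
    ax.set_xlabel("concentration $x_C$")
    ax.set_ylabel("derivative $dx_C/dt$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def interpolation_report(model: NODEModel, spec: ScenarioSpec,
                         regimens=None) -> list:
    """Simulate the model and the mechanistic oracle for each held-out
    regimen of a scenario and report the agreement.

    ``regimens`` defaults to the scenario's in-range test regimens.
    Curves are compared on a geometric grid at 4x the sampling density
    (see module docstring for why density is matched to the design).
    """
    regimens = list(regimens) if regimens is not None else list(spec.test_regimens)
    start = max(float(spec.sampling_times()[0]), spec.eval_start)
    times = np.geomspace(start, spec.horizon, 4 * spec.n_times)
    reports = []
    for reg in regimens:
        oracle = simulate_reference(spec.model_id, spec.params, reg, times)
        pred = simulate_node(model, reg, times)
        reports.append(
            SimulationReport(
                regimen=reg,
                times=times,
                predicted=pred,
                oracle=oracle,
                rel_rmse=_rel_rmse(pred, oracle, spec.log_space_eval),
                max_abs_err=float(np.max(np.abs(pred - oracle))),
                negative_prediction=bool(np.any(pred < 0)),
                log_space=spec.log_space_eval,
            )
        )
    return reports
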