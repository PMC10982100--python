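"""Mechanistic compartmental PK models, noise model and scenario registry.

These ordinary mass-action models generate all training data and act as
ground-truth oracles when judging trained neural ODEs:

* one- and two-compartment IV bolus,
* oral first-order absorption with 0/4/8 transit compartments,
* one-compartment IV infusion (zero-order input up to ``tinf``),
* target-mediated drug disposition (TMDD) after IV bolus or oral dosing.

Observations carry multiplicative proportional residual error,
``c_obs = c * (1 + cv * eps)`` with standard-normal ``eps``.

The scenario registry reproduces the study conditions of the experiments
this package is built around: two training dose levels per scenario, fixed
numbers of geometrically spaced sampling times, and held-out regimens used
to probe interpolation.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .odeint import SolverConfig, solve

__all__ = [
    "PKParams",
    "DoseRegimen",
    "PooledDataset",
    "ScenarioSpec",
    "mechanistic_rhs",
    "central_index",
    "state_dim",
    "initial_condition",
    "simulate_reference",
    "add_proportional_error",
    "make_scenario",
    "SCENARIO_NAMES",
]

DATA_SOLVER = SolverConfig(rtol=1e-8, atol=1e-10)


@dataclass
class PKParams:
    """Mechanistic rate constants (1/time unless noted) and volume.

    Only the parameters a given model uses need to be set. ``ksyn`` is in
    amount/volume/time (receptor synthesis); ``V`` is a volume.
    """

    kel: float = 0.0
    V: float = 1.0
    k12: float = 0.0
    k21: float = 0.0
    ka: float = 0.0
    ktr: float = 0.0
    ntr: int = 0
    kon: float = 0.0
    koff: float = 0.0
    ksyn: float = 0.0
    kdeg: float = 0.0
    kint: float = 0.0
    kabs: float = 0.0

    def __post_init__(self):
        for name in ("kel", "k12", "k21", "ka", "ktr", "kon", "koff",
                     "ksyn", "kdeg", "kint", "kabs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.V <= 0:
            raise ValueError("V must be positive")
        if self.ntr < 0:
            raise ValueError("ntr must be a nonnegative integer")


@dataclass(frozen=True)
class DoseRegimen:
    """Single-dose administration: IV bolus, oral, or IV infusion.

    For an infusion the total dose satisfies ``d = kin * tinf``.
    """

    route: str
    d: float = 0.0
    kin: float = 0.0
    tinf: float = 0.0

    def __post_init__(self):
        if self.route not in ("iv_bolus", "oral", "iv_infusion"):
            raise ValueError(f"unknown route {self.route!r}")
        if self.d < 0:
            raise ValueError("dose must be >= 0")
        if self.route == "iv_infusion":
            if self.kin <= 0 or self.tinf <= 0:
                raise ValueError("infusion requires kin > 0 and tinf > 0")
            if not np.isclose(self.d, self.kin * self.tinf):
                raise ValueError(
                    f"infusion dose d={self.d} must equal kin*tinf="
                    f"{self.kin * self.tinf}"
                )

    @classmethod
    def infusion(cls, kin: float, tinf: float) -> "DoseRegimen":
        return cls(route="iv_infusion", d=kin * tinf, kin=kin, tinf=tinf)


MODEL_IDS = (
    "onecomp_iv",
    "twocomp_iv",
    "onecomp_po_transit",
    "onecomp_infusion",
    "tmdd_iv",
    "tmdd_po",
)


def state_dim(model_id: str, params: PKParams) -> int:
    return {
        "onecomp_iv": 1,
        "twocomp_iv": 2,
        "onecomp_po_transit": 2 + params.ntr,
        "onecomp_infusion": 1,
        "tmdd_iv": 3,
        "tmdd_po": 4,
    }[model_id]


def central_index(model_id: str, params: PKParams) -> int:
    """Index of the state component matched to measured concentration."""
    return {
        "onecomp_iv": 0,
        "twocomp_iv": 0,
        "onecomp_po_transit": 1 + params.ntr,
        "onecomp_infusion": 0,
        "tmdd_iv": 0,
        "tmdd_po": 1,
    }[model_id]


def mechanistic_rhs(model_id, params: PKParams, regimen: DoseRegimen, state, t):
    """Time derivative of ``state`` under the requested mass-action model.

    State layouts (concentrations unless noted):
      onecomp_iv          [xC]
      twocomp_iv          [xC, xP]
      onecomp_po_transit  [depot(amount), transit_1..ntr(amount), xC]
      onecomp_infusion    [xC]
      tmdd_iv             [L, R, C]      ligand / free receptor / complex
      tmdd_po             [A(amount), L, R, C]
    """
    if model_id not in MODEL_IDS:
        raise ValueError(f"unknown model_id {model_id!r}")
    x = np.asarray(state, dtype=float)
    expected = state_dim(model_id, params)
    if x.shape != (expected,):
        raise ValueError(
            f"{model_id} expects state length {expected}, got {x.shape}"
        )
    p = params
    if model_id == "onecomp_iv":
        return np.array([-p.kel * x[0]])
    if model_id == "twocomp_iv":
        xc, xp = x
        return np.array(
            [-p.kel * xc - p.k12 * xc + p.k21 * xp, p.k12 * xc - p.k21 * xp]
        )
    if model_id == "onecomp_po_transit":
        # depot -> transit chain (rate ktr) -> central absorption at ka
        dx = np.empty_like(x)
        amounts = x[:-1]
        rate_out = np.empty_like(amounts)
        rate_out[:-1] = p.ktr * amounts[:-1]
        rate_out[-1] = p.ka * amounts[-1]
        dx[0] = -rate_out[0]
        for i in range(1, len(amounts)):
            dx[i] = rate_out[i - 1] - rate_out[i]
        dx[-1] = p.ka * amounts[-1] / p.V - p.kel * x[-1]
        return dx
    if model_id == "onecomp_infusion":
        inp = regimen.kin / p.V if t <= regimen.tinf else 0.0
        return np.array([inp - p.kel * x[0]])
    if model_id == "tmdd_iv":
        L, R, C = x
        bind = p.kon * L * R
        return np.array(
            [
                -p.kel * L - bind + p.koff * C,
                p.ksyn - p.kdeg * R - bind + p.koff * C,
                bind - p.koff * C - p.kint * C,
            ]
        )
    # tmdd_po
    A, L, R, C = x
    bind = p.kon * L * R
    return np.array(
        [
            -p.kabs * A,
            p.kabs * A / p.V - p.kel * L - bind + p.koff * C,
            p.ksyn - p.kdeg * R - bind + p.koff * C,
            bind - p.koff * C - p.kint * C,
        ]
    )


def initial_condition(model_id, params: PKParams, regimen: DoseRegimen) -> np.ndarray:
    """Route-appropriate initial state (bolus dose as d/V in the central or
    ligand compartment; oral dose as an amount in the depot)."""
    y0 = np.zeros(state_dim(model_id, params))
    if model_id in ("tmdd_iv", "tmdd_po"):
        # free receptor starts at its turnover baseline ksyn/kdeg
        ridx = 1 if model_id == "tmdd_iv" else 2
        y0[ridx] = params.ksyn / params.kdeg if params.kdeg > 0 else 0.0
    if regimen.route == "iv_bolus":
        if model_id == "onecomp_infusion":
            raise ValueError("infusion model requires an iv_infusion regimen")
        y0[central_index(model_id, params)] = regimen.d / params.V
    elif regimen.route == "oral":
        y0[0] = regimen.d  # depot amount
    elif regimen.route == "iv_infusion":
        pass  # all compartments empty; input enters through the rhs
    return y0


def simulate_reference(model_id, params, regimen, times,
                       cfg: SolverConfig | None = None) -> np.ndarray:
    """Integrate the mechanistic model and return central concentration at
    the requested (sorted, nonnegative) times."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be nonnegative")
    if cfg is None:
        cfg = DATA_SOLVER
    if model_id == "onecomp_infusion" and regimen.tinf not in cfg.breakpoints:
        cfg = SolverConfig(
            method=cfg.method, rtol=cfg.rtol, atol=cfg.atol,
            breakpoints=tuple(cfg.breakpoints) + (regimen.tinf,),
            max_steps=cfg.max_steps,
        )
    y0 = initial_condition(model_id, params, regimen)
    t_solve = times if times[0] == 0 else np.concatenate([[0.0], times])
    try:
        traj = solve(
            lambda x, t: mechanistic_rhs(model_id, params, regimen, x, t),
            y0, t_solve, cfg,
        )
    except Exception as exc:  # re-raise with model context
        raise RuntimeError(
            f"reference simulation failed for {model_id} ({params}): {exc}"
        ) from exc
    if times[0] != 0:
        traj = traj[1:]
    return traj[:, central_index(model_id, params)]


def add_proportional_error(conc, cv: float, seed) -> np.ndarray:
    """Apply multiplicative proportional error ``c*(1 + cv*eps)``.

    ``seed`` may be an integer or a ``numpy.random.Generator``. Outputs are
    clipped at zero from below; identical seed gives identical output.
    """
    if cv < 0:
        raise ValueError("cv must be nonnegative")
    conc = np.asarray(conc, dtype=float)
    if cv == 0:
        return conc.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    eps = rng.standard_normal(conc.shape)
    return np.clip(conc * (1.0 + cv * eps), 0.0, None)


# ---------------------------------------------------------------------------
# Pooled dataset container + CSV round trip
# ---------------------------------------------------------------------------

CSV_COLUMNS = ["group_id", "route", "dose", "kin", "tinf", "time", "replicate", "conc"]


@dataclass
class PooledDataset:
    """Dose-grouped, replicated concentration–time observations.

    ``df`` holds one row per observation with columns ``group_id, route,
    dose, kin, tinf, time, replicate, conc``; all rows of one group share a
    regimen. ``metadata`` records provenance (generating model, parameters,
    noise cv, seed).
    """

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in CSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        if (self.df["dose"] < 0).any():
            raise ValueError("negative dose in dataset")
        for gid, sub in self.df.groupby("group_id"):
            regs = sub[["route", "dose", "kin", "tinf"]].drop_duplicates()
            if len(regs) != 1:
                raise ValueError(f"group {gid!r} mixes multiple regimens")

    @property
    def group_ids(self):
        return list(dict.fromkeys(self.df["group_id"]))

    def regimen(self, group_id) -> DoseRegimen:
        row = self.df[self.df["group_id"] == group_id].iloc[0]
        kin = float(row["kin"]) if pd.notna(row["kin"]) else 0.0
        tinf = float(row["tinf"]) if pd.notna(row["tinf"]) else 0.0
        return DoseRegimen(route=row["route"], d=float(row["dose"]), kin=kin, tinf=tinf)

    def group(self, group_id) -> pd.DataFrame:
        return self.df[self.df["group_id"] == group_id]

    def subset(self, group_ids) -> "PooledDataset":
        """New dataset restricted to the given dose groups."""
        keep = self.df[self.df["group_id"].isin(list(group_ids))]
        if keep.empty:
            raise ValueError(f"no observations left for groups {group_ids}")
        return PooledDataset(df=keep.reset_index(drop=True),
                             metadata={**self.metadata, "subset": list(group_ids)})

    # -- CSV I/O ----------------------------------------------------------
    def to_csv(self, path_or_buf) -> None:
        self.df.to_csv(path_or_buf, index=False, columns=CSV_COLUMNS)

    @classmethod
    def from_csv(cls, path_or_buf, metadata: dict | None = None) -> "PooledDataset":
        df = pd.read_csv(path_or_buf, float_precision="round_trip")
        missing = [c for c in CSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"malformed dataset CSV: missing fields {missing}")
        if (df["conc"] < 0).any():
            import warnings

            warnings.warn("dataset contains negative concentrations (noisy data?)")
        return cls(df=df.reset_index(drop=True), metadata=metadata or {})

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def build_dataset(groups, metadata=None) -> PooledDataset:
    """Assemble a PooledDataset from (group_id, regimen, times, conc-matrix)
    tuples, where the concentration matrix is (replicates, len(times))."""
    rows = []
    for gid, reg, times, concs in groups:
        concs = np.atleast_2d(concs)
        for j in range(concs.shape[0]):
            for i, t in enumerate(times):
                rows.append(
                    {
                        "group_id": gid,
                        "route": reg.route,
                        "dose": reg.d,
                        "kin": reg.kin if reg.route == "iv_infusion" else np.nan,
                        "tinf": reg.tinf if reg.route == "iv_infusion" else np.nan,
                        "time": t,
                        "replicate": j,
                        "conc": concs[j, i],
                    }
                )
    return PooledDataset(df=pd.DataFrame(rows, columns=CSV_COLUMNS),
                         metadata=metadata or {})


# ---------------------------------------------------------------------------
# Scenario registry
# ---------------------------------------------------------------------------


@dataclass
class ScenarioSpec:
    """Study conditions of one experiment: generating model, parameters,
    training regimens/sampling, and held-out regimens for evaluation."""

    name: str
    model_id: str
    params: PKParams
    train_regimens: list
    n_times: int
    horizon: float
    replicates: int
    structure: str                   # recommended neural-ODE structure
    loss: str = "mse"
    test_regimens: list = field(default_factory=list)       # in training range
    out_of_range_regimens: list = field(default_factory=list)
    log_space_eval: bool = False     # compare on log10 concentrations
    eval_start: float = 0.0          # exclude early transient from evaluation
    t_first: float = 1.0             # first sampling time

    def sampling_times(self) -> np.ndarray:
        """Geometric spacing from the first sampling time to the horizon.

        For the delayed-absorption (transit) scenarios the first sample is
        placed at the end of the lag phase rather than t = 1: samples taken
        while the concentration is still essentially zero measure nothing,
        and the rise/peak/decline is what the design must cover.
        """
        return np.geomspace(self.t_first, self.horizon, self.n_times)


def _iv(d):
    return DoseRegimen(route="iv_bolus", d=d)


def _po(d):
    return DoseRegimen(route="oral", d=d)


_BASE = dict(kel=0.1, V=2.0)
_TMDD = dict(kel=0.1, kon=0.25, koff=0.01, ksyn=0.5, kdeg=0.25, kint=0.1, V=2.0)


def _registry() -> dict:
    sc = {}
    sc["overfit_onecomp"] = ScenarioSpec(
        name="overfit_onecomp", model_id="onecomp_iv",
        params=PKParams(**_BASE), train_regimens=[_iv(1.0)],
        n_times=5, horizon=50.0, replicates=1, structure="separated",
    )
    sc["interp_onecomp"] = ScenarioSpec(
        name="interp_onecomp", model_id="onecomp_iv",
        params=PKParams(**_BASE), train_regimens=[_iv(1.0), _iv(50.0)],
        n_times=5, horizon=50.0, replicates=8, structure="separated",
        test_regimens=[_iv(5.0), _iv(10.0), _iv(20.0), _iv(35.0)],
        out_of_range_regimens=[_iv(20.0)],  # for the single-dose (d=1) variant
    )
    sc["twocomp_iv"] = ScenarioSpec(
        name="twocomp_iv", model_id="twocomp_iv",
        params=PKParams(k12=0.2, k21=0.2, **_BASE),
        train_regimens=[_iv(1.0), _iv(10.0)],
        n_times=5, horizon=50.0, replicates=8, structure="separated",
        test_regimens=[_iv(5.0)],
    )
    sc["po_plain"] = ScenarioSpec(
        name="po_plain", model_id="onecomp_po_transit",
        params=PKParams(ka=0.2, **_BASE),
        train_regimens=[_po(5.0), _po(15.0)],
        n_times=7, horizon=50.0, replicates=8, structure="absorption",
        test_regimens=[_po(10.0)],
    )
    sc["po_transit4"] = ScenarioSpec(
        name="po_transit4", model_id="onecomp_po_transit",
        params=PKParams(ka=0.2, ktr=0.1, ntr=4, **_BASE),
        train_regimens=[_po(5.0), _po(15.0)],
        n_times=10, horizon=100.0, replicates=8, structure="absorption",
        test_regimens=[_po(10.0)], t_first=10.0,
    )
    sc["po_transit8"] = ScenarioSpec(
        name="po_transit8", model_id="onecomp_po_transit",
        params=PKParams(ka=0.2, ktr=0.1, ntr=8, **_BASE),
        train_regimens=[_po(5.0), _po(15.0)],
        n_times=10, horizon=150.0, replicates=8, structure="absorption",
        test_regimens=[_po(10.0)], t_first=10.0,
    )
    sc["infusion"] = ScenarioSpec(
        name="infusion", model_id="onecomp_infusion",
        params=PKParams(**_BASE),
        train_regimens=[DoseRegimen.infusion(1.0, 6.0),
                        DoseRegimen.infusion(10.0, 6.0)],
        n_times=7, horizon=50.0, replicates=8, structure="infusion",
        test_regimens=[DoseRegimen.infusion(7.0, 4.0),
                       DoseRegimen.infusion(5.0, 8.0)],
    )
    sc["tmdd_iv"] = ScenarioSpec(
        name="tmdd_iv", model_id="tmdd_iv",
        params=PKParams(**_TMDD),
        train_regimens=[_iv(50.0), _iv(200.0)],
        n_times=7, horizon=60.0, replicates=8, structure="separated",
        loss="wmse", test_regimens=[_iv(100.0)],
        log_space_eval=True, eval_start=1.0,
    )
    sc["tmdd_po"] = ScenarioSpec(
        name="tmdd_po", model_id="tmdd_po",
        params=PKParams(kabs=0.15, **_TMDD),
        train_regimens=[_po(50.0), _po(200.0)],
        n_times=10, horizon=60.0, replicates=8, structure="mech_abs",
        loss="wmse", test_regimens=[_po(100.0)],
        log_space_eval=True, eval_start=1.0,
    )
    return sc


SCENARIOS = _registry()
SCENARIO_NAMES = tuple(SCENARIOS.keys())


def get_scenario(name: str) -> ScenarioSpec:
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    return SCENARIOS[name]


def make_scenario(name: str, seed: int, cv: float = 0.10) -> tuple:
    """Generate the pooled noisy training dataset for a named scenario.

    Returns ``(dataset, spec)`` where ``spec`` describes the generating
    model and the held-out test regimens. Identical ``(name, seed, cv)``
    reproduce the dataset exactly.
    """
    spec = get_scenario(name)
    times = spec.sampling_times()
    name_key = zlib.crc32(name.encode()) & 0x7FFFFFFF  # stable across runs
    root = np.random.SeedSequence((seed, name_key))
    streams = root.spawn(len(spec.train_regimens))
    groups = []
    for g, (reg, ss) in enumerate(zip(spec.train_regimens, streams)):
        clean = simulate_reference(spec.model_id, spec.params, reg, times)
        rng = np.random.default_rng(ss)
        concs = np.stack(
            [add_proportional_error(clean, cv, rng) for _ in range(spec.replicates)]
        )
        groups.append((f"g{g}", reg, times, concs))
    meta = {
        "scenario": name,
        "model_id": spec.model_id,
        "params": asdict(spec.params),
        "cv": cv,
        "seed": seed,
        "n_times": spec.n_times,
        "horizon": spec.horizon,
        "replicates": spec.replicates,
    }
    return build_dataset(groups, metadata=meta), spec


def refit_onecomp_iv(data: PooledDataset) -> dict:
    """Refit the classical one-compartment IV model to a dataset.

    Least-squares fit of ``c(t) = (d/V) exp(-kel t)`` over all groups and
    replicates (two parameters). Returns the estimates and the mean squared
    error of the fit — the classical-model baseline that the far more
    flexible neural ODE undercuts when it overfits noise.
    """
    from scipy.optimize import curve_fit

    t = data.df["time"].to_numpy(dtype=float)
    d = data.df["dose"].to_numpy(dtype=float)
    c = data.df["conc"].to_numpy(dtype=float)

    def model(x, kel, V):
        tt, dd = x
        return (dd / V) * np.exp(-kel * tt)

    (kel, V), _ = curve_fit(model, (t, d), c, p0=(0.2, 1.0),
                            bounds=([1e-6, 1e-6], [10.0, 1e3]), maxfev=10000)
    resid = model((t, d), kel, V) - c
    return {"kel": float(kel), "V": float(V),
            "mse": float(np.mean(resid**2))}


def save_metadata(dataset: PooledDataset, path) -> None:
    with open(path, "w") as fh:
        json.dump(dataset.metadata, fh, indent=1)
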