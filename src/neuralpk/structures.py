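"""Neural-ODE model structures built from PK principles.

Six structures are available; each composes small one-hidden-layer networks
(:class:`~neuralpk.mlp.MLPSpec`) with known mechanistic terms. ``x_C`` is
the central (measured) state, ``x_A`` an absorption state, ``d`` the dose
and ``V`` the volume of distribution (estimated on the log scale where the
structure contains ``d/V`` or ``kin/V``):

========== ===========================================================
basic      dx_C/dt = f^C(x_C, t),                       x_C(0) = d/V
separated  dx_C/dt = f^C1(x_C) + (d/V) f^C2(t),         x_C(0) = d/V
absorption dx_A/dt = d f^A1(t) - f^A2(x_A),             x_A(0) = 0
           dx_C/dt = f^A2(x_A) - f^C1(x_C) - d f^C2(t), x_C(0) = 0
infusion   dx_C/dt = (kin/V) 1(t<=tinf) + f^C1(x_C) + (d/V) f^C2(t),
                                                        x_C(0) = 0
mech_elim  dx_A/dt = d f^A1(t) - f^A2(x_A),             x_A(0) = 0
           dx_C/dt = f^A2(x_A) - kel x_C,               x_C(0) = 0
mech_abs   dx_A/dt = -ka x_A,                           x_A(0) = d/V
           dx_C/dt = ka x_A - f^C1(x_C) - (d/V) f^C2(t), x_C(0) = 0
========== ===========================================================

Time-input networks (A1, C2) carry the ``-(w**2)`` input-weight restriction
so their explicit time-dependence vanishes beyond a finite onset;
concentration-input networks (C1, A2) are unrestricted. Signs are exactly
as written above (note the absorption structure scales its time term by the
raw dose ``d``, without ``V``: the amount scale can be absorbed by f^A2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .mlp import MLPSpec, mlp_forward, random_mlp
from .pk import DoseRegimen

__all__ = ["NODEModel", "build_node", "STRUCTURES", "count_parameters"]

# structure -> (net names in parameter order, {restricted time nets},
#               state dim, has V, route)
STRUCTURES = {
    "basic": (("C",), frozenset(), 1, True, "iv_bolus"),
    "separated": (("C1", "C2"), frozenset({"C2"}), 1, True, "iv_bolus"),
    "absorption": (("A1", "A2", "C1", "C2"), frozenset({"A1", "C2"}), 2, False, "oral"),
    "infusion": (("C1", "C2"), frozenset({"C2"}), 1, True, "iv_infusion"),
    "mech_elim": (("A1", "A2"), frozenset({"A1"}), 2, False, "oral"),
    "mech_abs": (("C1", "C2"), frozenset({"C2"}), 2, True, "oral"),
}


@dataclass
class NODEModel:
    """One neural-ODE structure with its component networks.

    Parameters
    ----------
    structure
        One of :data:`STRUCTURES`.
    nets
        Map of component name -> :class:`MLPSpec` as the structure requires.
    logV
        log volume of distribution (estimated), or ``None`` for structures
        without ``V``.
    mech_params
        Fixed mechanistic constants (``kel`` for mech_elim, ``ka`` for
        mech_abs); not trainable.
    """

    structure: str
    nets: dict
    logV: float | None = None
    mech_params: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        names, restricted, _, has_v, _ = STRUCTURES[self.structure]
        missing = [n for n in names if n not in self.nets]
        if missing:
            raise ValueError(f"{self.structure} structure requires nets {missing}")
        for n in names:
            want = n in restricted
            if self.nets[n].restrict_input_weights != want:
                raise ValueError(
                    f"net {n!r} must have restrict_input_weights={want} "
                    f"in the {self.structure} structure"
                )
        if has_v and self.logV is None:
            raise ValueError(f"{self.structure} structure estimates V; set logV")
        if self.structure == "mech_elim" and "kel" not in self.mech_params:
            raise ValueError("mech_elim requires mech_params['kel']")
        if self.structure == "mech_abs" and "ka" not in self.mech_params:
            raise ValueError("mech_abs requires mech_params['ka']")

    # -- basic descriptors -------------------------------------------------
    @property
    def net_names(self):
        return STRUCTURES[self.structure][0]

    @property
    def state_dim(self) -> int:
        return STRUCTURES[self.structure][2]

    @property
    def central_index(self) -> int:
        return self.state_dim - 1  # x_C is the last component

    @property
    def has_V(self) -> bool:
        return STRUCTURES[self.structure][3]

    @property
    def V(self) -> float:
        if self.logV is None:
            raise AttributeError(f"{self.structure} structure has no V")
        return float(np.exp(self.logV))

    @property
    def route(self) -> str:
        return STRUCTURES[self.structure][4]

    def validate_regimen(self, regimen: DoseRegimen) -> None:
        if regimen.route != self.route:
            raise ValueError(
                f"the {self.structure} structure requires a {self.route} "
                f"regimen, got {regimen.route}"
            )

    # -- initial conditions ------------------------------------------------
    def initial_state(self, regimen: DoseRegimen) -> np.ndarray:
        self.validate_regimen(regimen)
        s = self.structure
        if s in ("basic", "separated"):
            return np.array([regimen.d / self.V])
        if s == "infusion":
            return np.array([0.0])
        if s in ("absorption", "mech_elim"):
            return np.array([0.0, 0.0])
        # mech_abs: drug starts in the absorption state at d/V
        return np.array([regimen.d / self.V, 0.0])

    # -- right-hand side ---------------------------------------------------
    def rhs(self, state, t, regimen: DoseRegimen) -> np.ndarray:
        """Structure right-hand side at (state, t); signs as documented."""
        state = np.asarray(state, dtype=float)
        if state.shape != (self.state_dim,):
            raise ValueError(
                f"{self.structure} expects state length {self.state_dim}, "
                f"got {state.shape}"
            )
        s, d = self.structure, regimen.d
        f = lambda name, u: float(mlp_forward(self.nets[name], np.atleast_1d(u))[0])
        if s == "basic":
            return np.array([f("C", np.array([state[0], t]))])
        if s == "separated":
            return np.array([f("C1", state[0]) + (d / self.V) * f("C2", t)])
        if s == "infusion":
            inp = regimen.kin / self.V if t <= regimen.tinf else 0.0
            return np.array([inp + f("C1", state[0]) + (d / self.V) * f("C2", t)])
        if s == "absorption":
            xa, xc = state
            a2 = f("A2", xa)
            return np.array(
                [d * f("A1", t) - a2, a2 - f("C1", xc) - d * f("C2", t)]
            )
        if s == "mech_elim":
            xa, xc = state
            a2 = f("A2", xa)
            return np.array(
                [d * f("A1", t) - a2, a2 - self.mech_params["kel"] * xc]
            )
        # mech_abs
        xa, xc = state
        ka = self.mech_params["ka"]
        return np.array(
            [-ka * xa, ka * xa - f("C1", xc) - (d / self.V) * f("C2", t)]
        )

    # -- flat trainable-parameter vector ------------------------------------
    @property
    def n_params(self) -> int:
        return sum(self.nets[n].n_params for n in self.net_names) + (
            1 if self.has_V else 0
        )

    def pack(self) -> np.ndarray:
        parts = [self.nets[n].pack() for n in self.net_names]
        if self.has_V:
            parts.append(np.array([self.logV]))
        return np.concatenate(parts)

    def set_params(self, theta: np.ndarray) -> None:
        theta = np.asarray(theta, dtype=float)
        if theta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {theta.size}")
        k = 0
        for n in self.net_names:
            p = self.nets[n].n_params
            self.nets[n] = self.nets[n].unpack(theta[k : k + p])
            k += p
        if self.has_V:
            self.logV = float(theta[k])

    def net_slices(self) -> dict:
        out, k = {}, 0
        for n in self.net_names:
            p = self.nets[n].n_params
            out[n] = slice(k, k + p)
            k += p
        if self.has_V:
            out["logV"] = k
        return out

    # -- sensitivity machinery (used by the training engine) ----------------
    def initial_state_sensitivity(self, regimen: DoseRegimen) -> np.ndarray:
        """d(initial state)/d(theta); nonzero only in the logV column for
        structures whose initial condition is d/V."""
        S0 = np.zeros((self.state_dim, self.n_params))
        if self.has_V:
            col = self.n_params - 1
            if self.structure in ("basic", "separated"):
                S0[0, col] = -regimen.d / self.V
            elif self.structure == "mech_abs":
                S0[0, col] = -regimen.d / self.V
        return S0

    def rhs_jac(self, regimen: DoseRegimen):
        """Compile ``(y, t) -> (f, J_y, J_theta)`` for the current params.

        Recompile after every ``set_params``; the closure captures weights.
        """
        self.validate_regimen(regimen)
        s, d = self.structure, regimen.d
        sl = self.net_slices()
        P, dim = self.n_params, self.state_dim

        def grab(name):
            n = self.nets[name]
            w1raw = n.W1[:, 0].copy()
            w1eff = -(w1raw**2) if n.restrict_input_weights else w1raw
            return (w1raw, w1eff, n.b1.copy(), n.W2[0].copy(), float(n.b2[0]),
                    n.restrict_input_weights)

        def sng(net, u):
            """Scalar-input net: value, d/du, grad wrt packed params."""
            w1raw, w1eff, b1, w2, b2, restr = net
            z = w1eff * u + b1
            m = z > 0
            a = np.where(m, z, 0.0)
            y = w2 @ a + b2
            wm = w2 * m
            dy_du = wm @ w1eff
            gw1 = wm * (-2.0 * w1raw * u) if restr else wm * u
            grad = np.concatenate([gw1, wm, a, [1.0]])
            return y, dy_du, grad

        if s in ("separated", "infusion"):
            c1, c2 = grab("C1"), grab("C2")
            slc1, slc2, iv = sl["C1"], sl["C2"], sl["logV"]
            kin = regimen.kin if s == "infusion" else 0.0
            tinf = regimen.tinf if s == "infusion" else 0.0

            def rj(y, t):
                V = np.exp(self.logV)
                y1, d1, g1 = sng(c1, y[0])
                y2, _, g2 = sng(c2, t)
                scale = d / V
                f = y1 + scale * y2
                dlogV = -scale * y2
                if s == "infusion" and t <= tinf:
                    f = f + kin / V
                    dlogV = dlogV - kin / V
                Jt = np.zeros((1, P))
                Jt[0, slc1] = g1
                Jt[0, slc2] = scale * g2
                Jt[0, iv] = dlogV
                return np.array([f]), np.array([[d1]]), Jt

            return rj

        if s == "basic":
            n = self.nets["C"]
            W1 = n.W1.copy()
            b1, w2, b2 = n.b1.copy(), n.W2[0].copy(), float(n.b2[0])
            slc, iv = sl["C"], sl["logV"]

            def rj(y, t):
                u = np.array([y[0], t])
                z = W1 @ u + b1
                m = z > 0
                a = np.where(m, z, 0.0)
                fval = w2 @ a + b2
                wm = w2 * m
                dy_dx = wm @ W1[:, 0]
                gW1 = (wm[:, None] * u[None, :]).ravel()
                Jt = np.zeros((1, P))
                Jt[0, slc] = np.concatenate([gW1, wm, a, [1.0]])
                return np.array([fval]), np.array([[dy_dx]]), Jt

            return rj

        if s in ("absorption", "mech_elim"):
            a1, a2n = grab("A1"), grab("A2")
            sla1, sla2 = sl["A1"], sl["A2"]
            if s == "absorption":
                c1, c2 = grab("C1"), grab("C2")
                slc1, slc2 = sl["C1"], sl["C2"]
            else:
                kel = float(self.mech_params["kel"])

            def rj(y, t):
                xa, xc = y
                ya1, _, ga1 = sng(a1, t)
                ya2, da2, ga2 = sng(a2n, xa)
                Jt = np.zeros((2, P))
                Jy = np.zeros((2, 2))
                fa = d * ya1 - ya2
                Jy[0, 0] = -da2
                Jt[0, sla1] = d * ga1
                Jt[0, sla2] = -ga2
                if s == "absorption":
                    yc1, dc1, gc1 = sng(c1, xc)
                    yc2, _, gc2 = sng(c2, t)
                    fc = ya2 - yc1 - d * yc2
                    Jy[1, 0] = da2
                    Jy[1, 1] = -dc1
                    Jt[1, sla2] = ga2
                    Jt[1, slc1] = -gc1
                    Jt[1, slc2] = -d * gc2
                else:
                    fc = ya2 - kel * xc
                    Jy[1, 0] = da2
                    Jy[1, 1] = -kel
                    Jt[1, sla2] = ga2
                return np.array([fa, fc]), Jy, Jt

            return rj

        # mech_abs
        c1, c2 = grab("C1"), grab("C2")
        slc1, slc2, iv = sl["C1"], sl["C2"], sl["logV"]
        ka = float(self.mech_params["ka"])

        def rj(y, t):
            V = np.exp(self.logV)
            xa, xc = y
            yc1, dc1, gc1 = sng(c1, xc)
            yc2, _, gc2 = sng(c2, t)
            scale = d / V
            fa = -ka * xa
            fc = ka * xa - yc1 - scale * yc2
            Jy = np.array([[-ka, 0.0], [ka, -dc1]])
            Jt = np.zeros((2, P))
            Jt[1, slc1] = -gc1
            Jt[1, slc2] = -scale * gc2
            Jt[1, iv] = scale * yc2
            return np.array([fa, fc]), Jy, Jt

        return rj

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "structure": self.structure,
            "nets": {n: s.to_dict() for n, s in self.nets.items()},
            "logV": self.logV,
            "mech_params": dict(self.mech_params),
            "metadata": dict(self.metadata),
        }

    @classmethod
    def from_dict(cls, dd: dict) -> "NODEModel":
        return cls(
            structure=dd["structure"],
            nets={n: MLPSpec.from_dict(s) for n, s in dd["nets"].items()},
            logV=dd.get("logV"),
            mech_params=dd.get("mech_params", {}),
            metadata=dd.get("metadata", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "NODEModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def count_parameters(model: NODEModel) -> int:
    """Total trainable scalar count: per net ``n_hid*(n_in+n_out+1)+n_out``,
    plus one for logV where V is estimated. Mechanistic constants excluded."""
    return model.n_params


def build_node(
    structure: str,
    n_hid=20,
    seed: int = 0,
    *,
    mech_params: dict | None = None,
    logV: float = 0.0,
    out_scale: float = 0.1,
) -> NODEModel:
    """Create a structure with seeded initialization.

    ``n_hid`` is a single width for every component net, or a mapping
    ``{net name: width}`` (width 0 degenerates a net to its output bias).
    Hidden-layer weights/biases use the standard uniform fan-in scheme;
    the output layer is scaled down by ``out_scale`` (default 0.1) so the
    initial right-hand side is close to zero. Starting near the identity
    flow keeps early trajectories bounded — a large random rhs can put
    positive feedback on the concentration state and blow the solution up
    exponentially before training has any signal to work with. The seed is
    recorded in the model metadata.
    """
    from dataclasses import replace

    names, restricted, _, has_v, _ = STRUCTURES[structure]
    widths = dict(n_hid) if isinstance(n_hid, dict) else {n: n_hid for n in names}
    rng = np.random.default_rng(seed)
    nets = {}
    for n in names:
        n_in = 2 if (structure == "basic" and n == "C") else 1
        spec = random_mlp(
            n_in, widths[n], 1, rng=rng, restrict_input_weights=(n in restricted)
        )
        if out_scale != 1.0:
            spec = replace(spec, W2=spec.W2 * out_scale, b2=spec.b2 * out_scale)
        nets[n] = spec
    return NODEModel(
        structure=structure,
        nets=nets,
        logV=logV if has_v else None,
        mech_params=mech_params or {},
        metadata={"seed": seed, "n_hid": widths},
    )
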