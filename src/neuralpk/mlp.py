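"""One-hidden-layer perceptrons used as ODE right-hand-side components.

A network maps an input vector x (usually the scalar concentration or the
scalar time) through one hidden layer to an output vector:

    f(x) = sigma2(W2 @ sigma1(W1_eff @ x + b1) + b2)

with ReLU as the default hidden activation and the identity on the output.
Time-input networks may carry a sign restriction on the input weights,
``w_eff = -(w**2)``, which forces every hidden ReLU argument to decrease in
time so that the network output becomes exactly constant (= b2) beyond a
finite onset time: explicit time-dependence in the dynamics vanishes and
the solution cannot grow without bound as t -> infinity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np

__all__ = [
    "MLPSpec",
    "mlp_forward",
    "restricted_weight",
    "constancy_onset",
    "random_mlp",
    "ACTIVATIONS",
    "register_activation",
]

# Activation registry: name -> (function, derivative). Derivatives are used
# by the sensitivity machinery in the ODE training engine.
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "relu": (lambda z: np.maximum(0.0, z), lambda z: (z > 0).astype(float)),
    "identity": (lambda z: z, lambda z: np.ones_like(z)),
}


def register_activation(name: str, fn: Callable, deriv: Callable) -> None:
    """Register a custom activation under ``name`` (with its derivative)."""
    ACTIVATIONS[name] = (fn, deriv)


def restricted_weight(w):
    """Sign-restricted input weight: ``-(w**2)``, always <= 0.

    The raw weight ``w`` remains the trainable quantity; the restriction is
    applied at evaluation time so gradient updates act on ``w`` itself.
    """
    w = np.asarray(w, dtype=float)
    return -(w**2)


@dataclass
class MLPSpec:
    """Weights, biases and activations of a one-hidden-layer network.

    Parameters
    ----------
    n_in, n_hid, n_out
        Layer widths. All applications in this package use ``n_in = n_out
        = 1`` except the basic two-input structure.
    W1, b1, W2, b2
        Raw parameters; shapes ``(n_hid, n_in)``, ``(n_hid,)``,
        ``(n_out, n_hid)``, ``(n_out,)``.
    act_hidden, act_out
        Activation names from the registry (default relu / identity).
    restrict_input_weights
        When true the effective input weight used in evaluation is
        ``-(W1**2)`` elementwise; used for time-input networks.
    """

    n_in: int
    n_hid: int
    n_out: int
    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    act_hidden: str = "relu"
    act_out: str = "identity"
    restrict_input_weights: bool = False

    def __post_init__(self):
        for name in ("n_in", "n_hid", "n_out"):
            if getattr(self, name) < (1 if name != "n_hid" else 0):
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        self.W1 = np.atleast_2d(np.asarray(self.W1, dtype=float))
        self.b1 = np.asarray(self.b1, dtype=float).ravel()
        self.W2 = np.atleast_2d(np.asarray(self.W2, dtype=float))
        self.b2 = np.asarray(self.b2, dtype=float).ravel()
        if self.W1.shape != (self.n_hid, self.n_in):
            raise ValueError(
                f"W1 shape {self.W1.shape} inconsistent with (n_hid, n_in)="
                f"({self.n_hid}, {self.n_in})"
            )
        if self.b1.shape != (self.n_hid,):
            raise ValueError(f"b1 length {self.b1.shape[0]} != n_hid {self.n_hid}")
        if self.W2.shape != (self.n_out, self.n_hid):
            raise ValueError(
                f"W2 shape {self.W2.shape} inconsistent with (n_out, n_hid)="
                f"({self.n_out}, {self.n_hid})"
            )
        if self.b2.shape != (self.n_out,):
            raise ValueError(f"b2 length {self.b2.shape[0]} != n_out {self.n_out}")
        for act in (self.act_hidden, self.act_out):
            if act not in ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")

    @property
    def effective_W1(self) -> np.ndarray:
        return restricted_weight(self.W1) if self.restrict_input_weights else self.W1

    @property
    def n_params(self) -> int:
        return self.n_hid * (self.n_in + self.n_out + 1) + self.n_out

    # --- flat parameter vector (layout: W1, b1, W2, b2) -------------------
    def pack(self) -> np.ndarray:
        return np.concatenate(
            [self.W1.ravel(), self.b1, self.W2.ravel(), self.b2]
        )

    def unpack(self, theta: np.ndarray) -> "MLPSpec":
        h, i, o = self.n_hid, self.n_in, self.n_out
        if theta.size != self.n_params:
            raise ValueError(f"expected {self.n_params} parameters, got {theta.size}")
        k = 0
        W1 = theta[k : k + h * i].reshape(h, i); k += h * i
        b1 = theta[k : k + h]; k += h
        W2 = theta[k : k + o * h].reshape(o, h); k += o * h
        b2 = theta[k : k + o]
        return replace(self, W1=W1.copy(), b1=b1.copy(), W2=W2.copy(), b2=b2.copy())

    # --- JSON round trip --------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_hid": self.n_hid,
            "n_out": self.n_out,
            "W1": self.W1.tolist(),
            "b1": self.b1.tolist(),
            "W2": self.W2.tolist(),
            "b2": self.b2.tolist(),
            "act_hidden": self.act_hidden,
            "act_out": self.act_out,
            "restrict_input_weights": self.restrict_input_weights,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPSpec":
        return cls(**{**d, "W1": np.array(d["W1"]), "b1": np.array(d["b1"]),
                      "W2": np.array(d["W2"]), "b2": np.array(d["b2"])})

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "MLPSpec":
        return cls.from_dict(json.loads(s))


def mlp_forward(spec: MLPSpec, x, input_scale=None) -> np.ndarray:
    """Evaluate the network at input ``x`` (length ``n_in`` vector).

    Returns a vector of length ``n_out``. Deterministic and continuous in
    x. Inputs are fed in natural units by default; ``input_scale`` is an
    optional affine hook ``(a, b)`` applying ``a*x + b`` before the first
    layer (defaults to the identity).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape != (spec.n_in,):
        raise ValueError(f"input length {x.shape[0]} does not match n_in={spec.n_in}")
    if input_scale is not None:
        a, b = input_scale
        x = a * x + b
    act1 = ACTIVATIONS[spec.act_hidden][0]
    act2 = ACTIVATIONS[spec.act_out][0]
    hidden = act1(spec.effective_W1 @ x + spec.b1)
    return act2(spec.W2 @ hidden + spec.b2)


def constancy_onset(spec: MLPSpec) -> float:
    """Smallest t* >= 0 beyond which a restricted time-network equals b2.

    Each hidden ReLU argument is ``w_eff * t + b1`` with ``w_eff <= 0``; it
    is clamped to zero for all ``t >= b1 / (-w_eff)``. The onset is the max
    of these crossing times over active neurons (0 if every bias is already
    nonpositive); ``inf`` if a neuron with positive bias has zero effective
    weight, since that neuron contributes a constant the output never sheds.
    """
    if not spec.restrict_input_weights:
        raise ValueError("constancy_onset requires a weight-restricted network")
    if spec.n_in != 1 or spec.act_hidden != "relu":
        raise ValueError("constancy_onset requires a scalar-input ReLU network")
    w_eff = spec.effective_W1[:, 0]
    b = spec.b1
    onset = 0.0
    for wi, bi in zip(w_eff, b):
        if bi > 0:
            if wi == 0.0:
                return float("inf")
            onset = max(onset, bi / (-wi))
    return onset


def random_mlp(
    n_in: int,
    n_hid: int,
    n_out: int = 1,
    *,
    rng: np.random.Generator,
    restrict_input_weights: bool = False,
    act_hidden: str = "relu",
    act_out: str = "identity",
) -> MLPSpec:
    """Initialize a network with the standard uniform fan-in scheme.

    Weights and biases of each layer are drawn from U(-k, k) with
    ``k = 1/sqrt(fan_in)`` — the usual default of mainstream NN frameworks.
    """
    k1 = 1.0 / np.sqrt(n_in)
    k2 = 1.0 / np.sqrt(max(n_hid, 1))
    return MLPSpec(
        n_in=n_in,
        n_hid=n_hid,
        n_out=n_out,
        W1=rng.uniform(-k1, k1, size=(n_hid, n_in)),
        b1=rng.uniform(-k1, k1, size=n_hid),
        W2=rng.uniform(-k2, k2, size=(n_out, n_hid)),
        b2=rng.uniform(-k2, k2, size=n_out),
        act_hidden=act_hidden,
        act_out=act_out,
        restrict_input_weights=restrict_input_weights,
    )
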