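"""JIT-compiled inner loop for training (optional fast path).

The numpy implementation in :mod:`neuralpk.odeint` / :mod:`neuralpk.structures`
is the reference; this module re-implements the fixed-grid RK4 solve with
forward parameter sensitivities as a single numba kernel operating directly
on the packed parameter vector. Both paths compute the same discrete
solution (tested against each other); the kernel exists because full-batch
training takes tens of thousands of epochs and the per-epoch solve is the
hot loop.

Supported structure codes (net parameter layout per net: W1, b1, W2, b2,
each hidden width H, so 3H+1 scalars; nets in canonical order; logV last
where V is estimated):

====  ==========  ======================  =================
code  structure   nets (inputs)           extras
====  ==========  ======================  =================
0     separated   C1(x_C), C2(t)          logV
1     infusion    C1(x_C), C2(t)          logV, kin, tinf
2     absorption  A1(t), A2(x_A),
                  C1(x_C), C2(t)          —
3     mech_elim   A1(t), A2(x_A)          kel
4     mech_abs    C1(x_C), C2(t)          logV, ka
====  ==========  ======================  =================
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap(args[0]) if args and callable(args[0]) else wrap


STRUCT_CODES = {
    "separated": 0,
    "infusion": 1,
    "absorption": 2,
    "mech_elim": 3,
    "mech_abs": 4,
}

# restricted (-(w^2)) input-weight flag per net, canonical order
_RESTR = {
    0: np.array([0, 1], dtype=np.int8),
    1: np.array([0, 1], dtype=np.int8),
    2: np.array([1, 0, 0, 1], dtype=np.int8),
    3: np.array([1, 0], dtype=np.int8),
    4: np.array([0, 1], dtype=np.int8),
}


def restricted_flags(code: int) -> np.ndarray:
    return _RESTR[code]


@njit(cache=True)
def _netg(theta, off, H, restricted, u, g):
    """Scalar-input one-hidden-layer net: value, d/du; grads into g."""
    y = theta[off + 3 * H]
    dy = 0.0
    g[3 * H] = 1.0
    for i in range(H):
        w = theta[off + i]
        we = -(w * w) if restricted else w
        z = we * u + theta[off + H + i]
        if z > 0.0:
            w2 = theta[off + 2 * H + i]
            y += w2 * z
            dy += w2 * we
            g[H + i] = w2
            g[2 * H + i] = z
            g[i] = w2 * (-2.0 * w * u) if restricted else w2 * u
        else:
            g[i] = 0.0
            g[H + i] = 0.0
            g[2 * H + i] = 0.0
    return y, dy


@njit(cache=True)
def _eval(code, offs, Hs, theta, restr, mech, d, kin, tinf, y, t, f, Jy, Jt, g):
    """Fill f, Jy, Jt (rows fully overwritten in a fixed sparsity pattern).

    ``offs[k]``/``Hs[k]`` give the packed offset and hidden width of net k.
    """
    P = theta.shape[0]
    if code == 0 or code == 1:
        V = np.exp(theta[P - 1])
        scale = d / V
        y0, dy0 = _netg(theta, offs[0], Hs[0], restr[0], y[0], g[0])
        y1, _ = _netg(theta, offs[1], Hs[1], restr[1], t, g[1])
        fv = y0 + scale * y1
        dlogV = -scale * y1
        if code == 1 and t <= tinf:
            fv += kin / V
            dlogV -= kin / V
        f[0] = fv
        Jy[0, 0] = dy0
        for i in range(3 * Hs[0] + 1):
            Jt[0, offs[0] + i] = g[0, i]
        for i in range(3 * Hs[1] + 1):
            Jt[0, offs[1] + i] = scale * g[1, i]
        Jt[0, P - 1] = dlogV
    elif code == 2:
        ya1, _ = _netg(theta, offs[0], Hs[0], restr[0], t, g[0])
        ya2, da2 = _netg(theta, offs[1], Hs[1], restr[1], y[0], g[1])
        yc1, dc1 = _netg(theta, offs[2], Hs[2], restr[2], y[1], g[2])
        yc2, _ = _netg(theta, offs[3], Hs[3], restr[3], t, g[3])
        f[0] = d * ya1 - ya2
        f[1] = ya2 - yc1 - d * yc2
        Jy[0, 0] = -da2
        Jy[0, 1] = 0.0
        Jy[1, 0] = da2
        Jy[1, 1] = -dc1
        for i in range(3 * Hs[0] + 1):
            Jt[0, offs[0] + i] = d * g[0, i]
        for i in range(3 * Hs[1] + 1):
            Jt[0, offs[1] + i] = -g[1, i]
            Jt[1, offs[1] + i] = g[1, i]
        for i in range(3 * Hs[2] + 1):
            Jt[1, offs[2] + i] = -g[2, i]
        for i in range(3 * Hs[3] + 1):
            Jt[1, offs[3] + i] = -d * g[3, i]
    elif code == 3:
        kel = mech
        ya1, _ = _netg(theta, offs[0], Hs[0], restr[0], t, g[0])
        ya2, da2 = _netg(theta, offs[1], Hs[1], restr[1], y[0], g[1])
        f[0] = d * ya1 - ya2
        f[1] = ya2 - kel * y[1]
        Jy[0, 0] = -da2
        Jy[0, 1] = 0.0
        Jy[1, 0] = da2
        Jy[1, 1] = -kel
        for i in range(3 * Hs[0] + 1):
            Jt[0, offs[0] + i] = d * g[0, i]
        for i in range(3 * Hs[1] + 1):
            Jt[0, offs[1] + i] = -g[1, i]
            Jt[1, offs[1] + i] = g[1, i]
    else:  # code 4, mech_abs
        ka = mech
        V = np.exp(theta[P - 1])
        scale = d / V
        yc1, dc1 = _netg(theta, offs[0], Hs[0], restr[0], y[1], g[0])
        yc2, _ = _netg(theta, offs[1], Hs[1], restr[1], t, g[1])
        f[0] = -ka * y[0]
        f[1] = ka * y[0] - yc1 - scale * yc2
        Jy[0, 0] = -ka
        Jy[0, 1] = 0.0
        Jy[1, 0] = ka
        Jy[1, 1] = -dc1
        for i in range(3 * Hs[0] + 1):
            Jt[1, offs[0] + i] = -g[0, i]
        for i in range(3 * Hs[1] + 1):
            Jt[1, offs[1] + i] = -scale * g[1, i]
        Jt[1, P - 1] = scale * yc2


@njit(cache=True)
def rk4_sens_kernel(code, offs, Hs, theta, restr, mech, d, kin, tinf, grid, y0, S0):
    """Fixed-grid RK4 with forward sensitivities; returns (Y, S)."""
    P = theta.shape[0]
    dim = y0.shape[0]
    n = grid.shape[0]
    nnets = restr.shape[0]
    Hmax = 0
    for k in range(nnets):
        if Hs[k] > Hmax:
            Hmax = Hs[k]
    Y = np.empty((n, dim))
    Sout = np.empty((n, dim, P))
    y = y0.copy()
    S = S0.copy()
    f1 = np.empty(dim)
    f2 = np.empty(dim)
    f3 = np.empty(dim)
    f4 = np.empty(dim)
    Jy = np.empty((dim, dim))
    Jt = np.zeros((dim, P))
    g = np.empty((nnets, 3 * Hmax + 1))
    yk = np.empty(dim)
    dS1 = np.empty((dim, P))
    dS2 = np.empty((dim, P))
    dS3 = np.empty((dim, P))
    dS4 = np.empty((dim, P))
    Sk = np.empty((dim, P))
    for i in range(dim):
        Y[0, i] = y[i]
        for p in range(P):
            Sout[0, i, p] = S[i, p]
    for k in range(n - 1):
        t = grid[k]
        h = grid[k + 1] - grid[k]
        # stage 1
        _eval(code, offs, Hs, theta, restr, mech, d, kin, tinf, y, t, f1, Jy, Jt, g)
        for i in range(dim):
            for p in range(P):
                acc = Jt[i, p]
                for j in range(dim):
                    acc += Jy[i, j] * S[j, p]
                dS1[i, p] = acc
        # stage 2
        for i in range(dim):
            yk[i] = y[i] + 0.5 * h * f1[i]
            for p in range(P):
                Sk[i, p] = S[i, p] + 0.5 * h * dS1[i, p]
        _eval(code, offs, Hs, theta, restr, mech, d, kin, tinf, yk, t + 0.5 * h,
              f2, Jy, Jt, g)
        for i in range(dim):
            for p in range(P):
                acc = Jt[i, p]
                for j in range(dim):
                    acc += Jy[i, j] * Sk[j, p]
                dS2[i, p] = acc
        # stage 3
        for i in range(dim):
            yk[i] = y[i] + 0.5 * h * f2[i]
            for p in range(P):
                Sk[i, p] = S[i, p] + 0.5 * h * dS2[i, p]
        _eval(code, offs, Hs, theta, restr, mech, d, kin, tinf, yk, t + 0.5 * h,
              f3, Jy, Jt, g)
        for i in range(dim):
            for p in range(P):
                acc = Jt[i, p]
                for j in range(dim):
                    acc += Jy[i, j] * Sk[j, p]
                dS3[i, p] = acc
        # stage 4
        for i in range(dim):
            yk[i] = y[i] + h * f3[i]
            for p in range(P):
                Sk[i, p] = S[i, p] + h * dS3[i, p]
        _eval(code, offs, Hs, theta, restr, mech, d, kin, tinf, yk, t + h,
              f4, Jy, Jt, g)
        for i in range(dim):
            for p in range(P):
                acc = Jt[i, p]
                for j in range(dim):
                    acc += Jy[i, j] * Sk[j, p]
                dS4[i, p] = acc
        # combine
        for i in range(dim):
            y[i] = y[i] + (h / 6.0) * (f1[i] + 2.0 * f2[i] + 2.0 * f3[i] + f4[i])
            for p in range(P):
                S[i, p] = S[i, p] + (h / 6.0) * (
                    dS1[i, p] + 2.0 * dS2[i, p] + 2.0 * dS3[i, p] + dS4[i, p]
                )
        if not np.isfinite(y[0]):
            # signal divergence by poisoning the remaining output
            for kk in range(k + 1, n):
                for i in range(dim):
                    Y[kk, i] = np.nan
            for i in range(dim):
                Y[k + 1, i] = np.nan
            return Y, Sout
        for i in range(dim):
            Y[k + 1, i] = y[i]
            for p in range(P):
                Sout[k + 1, i, p] = S[i, p]
    return Y, Sout


def kernel_solve(model, theta, regimen, grid):
    """Dispatch a packed-parameter RK4+sensitivity solve to the kernel.

    Returns (Y, S) like :func:`neuralpk.odeint.solve_rk4_sens`. Raises
    ``KeyError`` for unsupported structures (caller falls back to numpy).
    """
    code = STRUCT_CODES[model.structure]
    names = model.net_names
    Hs = np.array([model.nets[n].n_hid for n in names], dtype=np.int64)
    offs = np.zeros(len(names), dtype=np.int64)
    for k in range(1, len(names)):
        offs[k] = offs[k - 1] + 3 * Hs[k - 1] + 1
    theta = np.ascontiguousarray(theta, dtype=np.float64)
    mech = 0.0
    if model.structure == "mech_elim":
        mech = float(model.mech_params["kel"])
    elif model.structure == "mech_abs":
        mech = float(model.mech_params["ka"])
    # initial state/sensitivity from theta (logV is the last entry where
    # V is estimated), matching NODEModel.initial_state*
    dim = 1 if code <= 1 else 2
    P = theta.size
    y0 = np.zeros(dim)
    S0 = np.zeros((dim, P))
    if code == 0:
        V = np.exp(theta[-1])
        y0[0] = regimen.d / V
        S0[0, P - 1] = -regimen.d / V
    elif code == 4:
        V = np.exp(theta[-1])
        y0[0] = regimen.d / V
        S0[0, P - 1] = -regimen.d / V
    return rk4_sens_kernel(
        code, offs, Hs, theta,
        restricted_flags(code), mech, float(regimen.d),
        float(regimen.kin), float(regimen.tinf),
        np.ascontiguousarray(grid, dtype=np.float64), y0, S0,
    )
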