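"""Numba-compiled adaptive Dormand-Prince 5(4) integrator.

The network ODEs are stiff-free but are driven by a noise current held
piecewise-constant on a fixed 1 ms grid (the same grid used for
recording).  The stepper therefore never crosses a grid boundary: within
each 1 ms cell the right-hand side is smooth and the adaptive embedded
error control is valid; the state is recorded at every boundary.

The arithmetic mirrors :mod:`quadgait.dynamics` exactly (a test asserts
agreement to machine precision); this module only exists for speed.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# indices into the packed constants array (CellConstants.as_array order)
_GSYNE, _GSYNI, _ESYNE, _ESYNI, _ENA = 0, 1, 2, 3, 4
_VTHR, _VMAX, _GNAP, _V12M, _KM = 5, 6, 7, 8, 9
_V12H, _KH, _V12T, _KT, _TAU0, _TAUMAX = 10, 11, 12, 13, 14, 15

OK = 0
FAIL_STEP_UNDERFLOW = 1
FAIL_NONFINITE = 2


@njit(cache=True)
def _rhs(y, dy, inz, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
         exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w, f, se, si):
    n_pop = gL.shape[0]
    n_rg = rg_idx.shape[0]
    vthr = cp[_VTHR]
    vmax = cp[_VMAX]
    inv_span = 1.0 / (vmax - vthr)
    for i in range(n_pop):
        v = y[i]
        if v <= vthr:
            f[i] = 0.0
        elif v >= vmax:
            f[i] = out_mask[i]
        else:
            f[i] = (v - vthr) * inv_span * out_mask[i]
        se[i] = DE[i]
        si[i] = DI[i]
    for e in range(exc_w.shape[0]):
        se[exc_tgt[e]] += exc_w[e] * f[exc_src[e]]
    for e in range(inh_w.shape[0]):
        si[inh_tgt[e]] += inh_w[e] * f[inh_src[e]]
    for i in range(n_pop):
        v = y[i]
        I = (gL[i] * (v - EL[i])
             + cp[_GSYNE] * se[i] * (v - cp[_ESYNE])
             + cp[_GSYNI] * si[i] * (v - cp[_ESYNI])
             + inz[i])
        dy[i] = -I / C
    for k in range(n_rg):
        i = rg_idx[k]
        v = y[i]
        h = y[n_pop + k]
        minf = 1.0 / (1.0 + np.exp((v - cp[_V12M]) / cp[_KM]))
        dy[i] -= cp[_GNAP] * minf * h * (v - cp[_ENA]) / C
        hinf = 1.0 / (1.0 + np.exp((v - cp[_V12H]) / cp[_KH]))
        tauh = cp[_TAU0] + (cp[_TAUMAX] - cp[_TAU0]) / np.cosh(
            (v - cp[_V12T]) / cp[_KT])
        dy[n_pop + k] = (hinf - h) / tauh


@njit(cache=True)
def integrate_grid(y0, noise, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
                   exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w,
                   rec_idx, rtol, atol):
    """Integrate over ``noise.shape[0]`` cells of 1 ms each.

    Returns (status, t_fail, out_V, out_h, y_final, nfev) where out_V
    holds V of the populations in ``rec_idx`` and out_h all h variables,
    both sampled at every cell boundary (n_ms+1 samples incl. t=0).
    """
    n_ms = noise.shape[0]
    n_pop = gL.shape[0]
    n_rg = rg_idx.shape[0]
    ny = n_pop + n_rg
    n_rec = rec_idx.shape[0]

    out_V = np.empty((n_ms + 1, n_rec))
    out_h = np.empty((n_ms + 1, n_rg))

    y = y0.copy()
    ynew = np.empty(ny)
    yerr = np.empty(ny)
    k1 = np.empty(ny); k2 = np.empty(ny); k3 = np.empty(ny)
    k4 = np.empty(ny); k5 = np.empty(ny); k6 = np.empty(ny)
    k7 = np.empty(ny)
    f = np.empty(n_pop); se = np.empty(n_pop); si = np.empty(n_pop)

    for r in range(n_rec):
        out_V[0, r] = y[rec_idx[r]]
    for k in range(n_rg):
        out_h[0, k] = y[n_pop + k]

    hstep = 0.1          # ms, initial guess; adapted and carried over
    hmin = 1e-10
    nfev = 0

    for cell in range(n_ms):
        inz = noise[cell]
        t = 0.0
        _rhs(y, k1, inz, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
             exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w, f, se, si)
        nfev += 1
        while t < 1.0:
            h_ = hstep
            if t + h_ > 1.0:
                h_ = 1.0 - t
            # Dormand-Prince 5(4) stages
            for i in range(ny):
                ynew[i] = y[i] + h_ * (0.2 * k1[i])
            _rhs(ynew, k2, inz, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
                 exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w, f, se, si)
            for i in range(ny):
                ynew[i] = y[i] + h_ * (3.0 / 40.0 * k1[i] + 9.0 / 40.0 * k2[i])
            _rhs(ynew, k3, inz, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
                 exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w, f, se, si)
            for i in range(ny):
                ynew[i] = y[i] + h_ * (44.0 / 45.0 * k1[i]
                                       - 56.0 / 15.0 * k2[i]
                                       + 32.0 / 9.0 * k3[i])
            _rhs(ynew, k4, inz, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
                 exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w, f, se, si)
            for i in range(ny):
                ynew[i] = y[i] + h_ * (19372.0 / 6561.0 * k1[i]
                                       - 25360.0 / 2187.0 * k2[i]
                                       + 64448.0 / 6561.0 * k3[i]
                                       - 212.0 / 729.0 * k4[i])
            _rhs(ynew, k5, inz, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
                 exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w, f, se, si)
            for i in range(ny):
                ynew[i] = y[i] + h_ * (9017.0 / 3168.0 * k1[i]
                                       - 355.0 / 33.0 * k2[i]
                                       + 46732.0 / 5247.0 * k3[i]
                                       + 49.0 / 176.0 * k4[i]
                                       - 5103.0 / 18656.0 * k5[i])
            _rhs(ynew, k6, inz, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
                 exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w, f, se, si)
            for i in range(ny):
                ynew[i] = y[i] + h_ * (35.0 / 384.0 * k1[i]
                                       + 500.0 / 1113.0 * k3[i]
                                       + 125.0 / 192.0 * k4[i]
                                       - 2187.0 / 6784.0 * k5[i]
                                       + 11.0 / 84.0 * k6[i])
            _rhs(ynew, k7, inz, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
                 exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w, f, se, si)
            nfev += 6
            # embedded 4th-order error estimate
            errnorm = 0.0
            for i in range(ny):
                ei = h_ * (71.0 / 57600.0 * k1[i]
                           - 71.0 / 16695.0 * k3[i]
                           + 71.0 / 1920.0 * k4[i]
                           - 17253.0 / 339200.0 * k5[i]
                           + 22.0 / 525.0 * k6[i]
                           - 1.0 / 40.0 * k7[i])
                ay = abs(y[i])
                ayn = abs(ynew[i])
                sc = atol + rtol * (ay if ay > ayn else ayn)
                q = ei / sc
                errnorm += q * q
            errnorm = np.sqrt(errnorm / ny)
            if not np.isfinite(errnorm):
                return FAIL_NONFINITE, float(cell) + t, out_V, out_h, y, nfev
            if errnorm <= 1.0:
                t += h_
                for i in range(ny):
                    y[i] = ynew[i]
                    k1[i] = k7[i]       # FSAL
                if errnorm == 0.0:
                    fac = 5.0
                else:
                    fac = 0.9 * errnorm ** -0.2
                    if fac > 5.0:
                        fac = 5.0
                    elif fac < 0.2:
                        fac = 0.2
                hstep = h_ * fac
            else:
                fac = 0.9 * errnorm ** -0.2
                if fac < 0.1:
                    fac = 0.1
                hstep = h_ * fac
                _rhs(y, k1, inz, cp, C, gL, EL, DE, DI, out_mask, rg_idx,
                     exc_src, exc_tgt, exc_w, inh_src, inh_tgt, inh_w,
                     f, se, si)
                nfev += 1
            if hstep < hmin:
                return (FAIL_STEP_UNDERFLOW, float(cell) + t,
                        out_V, out_h, y, nfev)
        for r in range(n_rec):
            out_V[cell + 1, r] = y[rec_idx[r]]
        for k in range(n_rg):
            out_h[cell + 1, k] = y[n_pop + k]

    return OK, -1.0, out_V, out_h, y, nfev
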