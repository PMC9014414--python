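"""JIT-compiled inner loops for overdamped Langevin propagation.

The state is a point on the torus [-pi, pi)^2; the force is the sum of
an analytic well-based potential (rows (cphi, cpsi, depth, conc)), an
optional explicit Fourier potential part, and an optional Fourier bias,
both given as (2N+1)x(2N+1) coefficient matrices in the ordering of
:mod:`torves.basis`.  A 1x1 zero matrix means "absent".
"""

import numpy as np
from numba import njit

TWO_PI = 2.0 * np.pi


@njit(cache=True)
def _fill_axis(x, f, df):
    """Per-axis basis values and derivatives via trig recurrences."""
    m = f.shape[0]
    f[0] = 1.0
    df[0] = 0.0
    if m == 1:
        return
    c1 = np.cos(x)
    s1 = np.sin(x)
    ck = c1
    sk = s1
    n = (m - 1) // 2
    for k in range(1, n + 1):
        if k > 1:
            ck_new = ck * c1 - sk * s1
            sk_new = sk * c1 + ck * s1
            ck = ck_new
            sk = sk_new
        f[2 * k - 1] = ck
        f[2 * k] = sk
        df[2 * k - 1] = -k * sk
        df[2 * k] = k * ck


@njit(cache=True)
def _matrix_eval(c, fp, fq, dfp, dfq):
    """(value, d/dphi, d/dpsi) of fp^T C fq."""
    m = c.shape[0]
    v = 0.0
    gp = 0.0
    gq = 0.0
    for i in range(m):
        row_f = 0.0
        row_d = 0.0
        for j in range(m):
            row_f += c[i, j] * fq[j]
            row_d += c[i, j] * dfq[j]
        v += fp[i] * row_f
        gp += dfp[i] * row_f
        gq += fp[i] * row_d
    return v, gp, gq


@njit(cache=True)
def propagate(
    phi,
    psi,
    wells,
    pot_c,
    bias_c,
    beta,
    diffusion,
    dt,
    noise,
    step0,
    record_stride,
    rec_t,
    rec_phi,
    rec_psi,
    rec_bias,
    rec_start,
    fsum,
    accumulate,
):
    """Advance ``noise.shape[0]`` Euler-Maruyama steps; record every
    ``record_stride``-th visited state (global step counting from 1).

    Returns (phi, psi, number_of_records_written).  When ``accumulate``
    is true, the bias-basis outer product of every visited state is
    added into ``fsum`` (the VES gradient batch statistic).
    """
    n_steps = noise.shape[0]
    mb = bias_c.shape[0]
    mp = pot_c.shape[0]
    fpb = np.empty(mb)
    fqb = np.empty(mb)
    dfpb = np.empty(mb)
    dfqb = np.empty(mb)
    fpp = np.empty(mp)
    fqp = np.empty(mp)
    dfpp = np.empty(mp)
    dfqp = np.empty(mp)
    amp = beta * diffusion * dt
    nrec = 0
    has_pot_fourier = mp > 1
    has_bias = mb > 1
    for i in range(n_steps):
        gp = 0.0
        gq = 0.0
        for w in range(wells.shape[0]):
            dphi = phi - wells[w, 0]
            dpsi = psi - wells[w, 1]
            depth = wells[w, 2]
            conc = wells[w, 3]
            e = depth * np.exp(conc * (np.cos(dphi) + np.cos(dpsi) - 2.0))
            gp += conc * np.sin(dphi) * e
            gq += conc * np.sin(dpsi) * e
        if has_pot_fourier:
            _fill_axis(phi, fpp, dfpp)
            _fill_axis(psi, fqp, dfqp)
            _, gpp, gqp = _matrix_eval(pot_c, fpp, fqp, dfpp, dfqp)
            gp += gpp
            gq += gqp
        vbias = 0.0
        if has_bias or accumulate:
            _fill_axis(phi, fpb, dfpb)
            _fill_axis(psi, fqb, dfqb)
        if has_bias:
            vbias, gbp, gbq = _matrix_eval(bias_c, fpb, fqb, dfpb, dfqb)
            gp += gbp
            gq += gbq
        phi = phi - amp * gp + noise[i, 0]
        psi = psi - amp * gq + noise[i, 1]
        # wrap to [-pi, pi)
        phi = phi - TWO_PI * np.floor((phi + np.pi) / TWO_PI)
        psi = psi - TWO_PI * np.floor((psi + np.pi) / TWO_PI)
        if accumulate:
            _fill_axis(phi, fpb, dfpb)
            _fill_axis(psi, fqb, dfqb)
            for a in range(mb):
                fa = fpb[a]
                for b in range(mb):
                    fsum[a, b] += fa * fqb[b]
            if has_bias:
                vbias, _, _ = _matrix_eval(bias_c, fpb, fqb, dfpb, dfqb)
        gstep = step0 + i + 1
        if gstep % record_stride == 0:
            if has_bias and not accumulate:
                _fill_axis(phi, fpb, dfpb)
                _fill_axis(psi, fqb, dfqb)
                vbias, _, _ = _matrix_eval(bias_c, fpb, fqb, dfpb, dfqb)
            rec_t[rec_start + nrec] = gstep * dt
            rec_phi[rec_start + nrec] = phi
            rec_psi[rec_start + nrec] = psi
            rec_bias[rec_start + nrec] = vbias
            nrec += 1
    return phi, psi, nrec
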