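"""Numba kernels for the single-site Gauss-Seidel Gibbs sweeps.

The design matrix W is held in CSC so each coefficient owns its records.
Fixed effects are sampled one scalar at a time under a flat prior; random
regression effects are sampled per level as 2x2 (intercept, slope) blocks
whose prior precision couples levels through K^-1 (H^-1 for the additive
effect, identity for permanent-environment and litter effects).

With ``noise = 0`` the same sweeps perform plain Gauss-Seidel iteration on
the mixed-model equations, whose fixed point is the BLUP/posterior-mean
solution for fixed variance components.
"""
import numba as nb
import numpy as np


@nb.njit(cache=True)
def sweep_scalar(w_data, w_indices, w_indptr, e, theta, diag_wtw,
                 start, stop, s2e, z, noise):
    """One pass over scalar coefficients [start, stop) with flat priors."""
    for j in range(start, stop):
        xtx = diag_wtw[j]
        if xtx <= 0.0:
            continue
        lo, hi = w_indptr[j], w_indptr[j + 1]
        num = 0.0
        for k in range(lo, hi):
            num += w_data[k] * e[w_indices[k]]
        num += xtx * theta[j]
        new = num / xtx + noise * z[j] * np.sqrt(s2e / xtx)
        d = new - theta[j]
        theta[j] = new
        for k in range(lo, hi):
            e[w_indices[k]] -= d * w_data[k]


@nb.njit(cache=True)
def sweep_block2(w_data, w_indices, w_indptr, e, theta, diag_wtw, cross,
                 offset, n_lev, kinv_data, kinv_indices, kinv_indptr,
                 ginv, s2e, z, noise):
    """One pass over the 2-vector (intercept, slope) blocks of one effect.

    Coefficients of level l live at columns offset+2l and offset+2l+1;
    ``cross[l]`` caches the within-level cross product of the two design
    columns; ``z`` supplies 2 standard normals per level.
    """
    g00 = ginv[0, 0]
    g01 = ginv[0, 1]
    g11 = ginv[1, 1]
    for l in range(n_lev):
        c0 = offset + 2 * l
        c1 = c0 + 1
        r0 = 0.0
        r1 = 0.0
        for k in range(w_indptr[c0], w_indptr[c0 + 1]):
            r0 += w_data[k] * e[w_indices[k]]
        for k in range(w_indptr[c1], w_indptr[c1 + 1]):
            r1 += w_data[k] * e[w_indices[k]]
        t0 = theta[c0]
        t1 = theta[c1]
        r0 += diag_wtw[c0] * t0 + cross[l] * t1
        r1 += cross[l] * t0 + diag_wtw[c1] * t1
        r0 /= s2e
        r1 /= s2e
        kll = 0.0
        for k in range(kinv_indptr[l], kinv_indptr[l + 1]):
            m = kinv_indices[k]
            v = kinv_data[k]
            if m == l:
                kll = v
            else:
                u0 = theta[offset + 2 * m]
                u1 = theta[offset + 2 * m + 1]
                r0 -= v * (g00 * u0 + g01 * u1)
                r1 -= v * (g01 * u0 + g11 * u1)
        p00 = diag_wtw[c0] / s2e + kll * g00
        p01 = cross[l] / s2e + kll * g01
        p11 = diag_wtw[c1] / s2e + kll * g11
        det = p00 * p11 - p01 * p01
        m0 = (p11 * r0 - p01 * r1) / det
        m1 = (p00 * r1 - p01 * r0) / det
        if noise != 0.0:
            # lower Cholesky of the conditional covariance P^-1
            c00 = p11 / det
            c01 = -p01 / det
            c11 = p00 / det
            l00 = np.sqrt(c00)
            l10 = c01 / l00
            l11 = np.sqrt(c11 - l10 * l10)
            n0 = m0 + l00 * z[2 * l]
            n1 = m1 + l10 * z[2 * l] + l11 * z[2 * l + 1]
        else:
            n0 = m0
            n1 = m1
        d0 = n0 - t0
        d1 = n1 - t1
        theta[c0] = n0
        theta[c1] = n1
        for k in range(w_indptr[c0], w_indptr[c0 + 1]):
            e[w_indices[k]] -= d0 * w_data[k]
        for k in range(w_indptr[c1], w_indptr[c1 + 1]):
            e[w_indices[k]] -= d1 * w_data[k]


@nb.njit(cache=True)
def sweep_joint_a_pe(w_data, w_indices, w_indptr, e, theta, diag_wtw, cross_a,
                     off_a, n_lev_a, pe_of_a, off_pe,
                     kinv_data, kinv_indices, kinv_indptr,
                     ga_inv, gpe_inv, s2e, z, noise):
    """Jointly sample (a0, a1, pe0, pe1) per animal.

    The additive and permanent-environment effects of a recorded sow load on
    the same records with identical design columns, which makes their
    single-site conditionals nearly degenerate; blocking the 4-vector removes
    that ridge.  Animals without a pe level fall back to the 2x2 additive
    block.  ``pe_of_a[l]`` maps additive level l to its pe level (-1 = none).
    """
    ga00 = ga_inv[0, 0]
    ga01 = ga_inv[0, 1]
    ga11 = ga_inv[1, 1]
    gp00 = gpe_inv[0, 0]
    gp01 = gpe_inv[0, 1]
    gp11 = gpe_inv[1, 1]
    P = np.empty((4, 4))
    L = np.empty((4, 4))
    rhs = np.empty(4)
    mean = np.empty(4)
    zz = np.empty(4)
    for l in range(n_lev_a):
        ca0 = off_a + 2 * l
        ca1 = ca0 + 1
        r0 = 0.0
        r1 = 0.0
        for k in range(w_indptr[ca0], w_indptr[ca0 + 1]):
            r0 += w_data[k] * e[w_indices[k]]
        for k in range(w_indptr[ca1], w_indptr[ca1 + 1]):
            r1 += w_data[k] * e[w_indices[k]]
        b00 = diag_wtw[ca0]
        b01 = cross_a[l]
        b11 = diag_wtw[ca1]
        a0 = theta[ca0]
        a1 = theta[ca1]
        # prior coupling of the additive block across relatives
        kll = 0.0
        c0 = 0.0
        c1 = 0.0
        for k in range(kinv_indptr[l], kinv_indptr[l + 1]):
            m = kinv_indices[k]
            v = kinv_data[k]
            if m == l:
                kll = v
            else:
                u0 = theta[off_a + 2 * m]
                u1 = theta[off_a + 2 * m + 1]
                c0 += v * (ga00 * u0 + ga01 * u1)
                c1 += v * (ga01 * u0 + ga11 * u1)
        pl = pe_of_a[l]
        if pl < 0:
            # additive-only 2x2 block
            ra0 = (r0 + b00 * a0 + b01 * a1) / s2e - c0
            ra1 = (r1 + b01 * a0 + b11 * a1) / s2e - c1
            p00 = b00 / s2e + kll * ga00
            p01 = b01 / s2e + kll * ga01
            p11 = b11 / s2e + kll * ga11
            det = p00 * p11 - p01 * p01
            m0 = (p11 * ra0 - p01 * ra1) / det
            m1 = (p00 * ra1 - p01 * ra0) / det
            if noise != 0.0:
                cc00 = p11 / det
                cc01 = -p01 / det
                cc11 = p00 / det
                l00 = np.sqrt(cc00)
                l10 = cc01 / l00
                l11 = np.sqrt(cc11 - l10 * l10)
                n0 = m0 + l00 * z[2 * l]
                n1 = m1 + l10 * z[2 * l] + l11 * z[2 * l + 1]
            else:
                n0 = m0
                n1 = m1
            d0 = n0 - a0
            d1 = n1 - a1
            theta[ca0] = n0
            theta[ca1] = n1
            for k in range(w_indptr[ca0], w_indptr[ca0 + 1]):
                e[w_indices[k]] -= d0 * w_data[k]
            for k in range(w_indptr[ca1], w_indptr[ca1 + 1]):
                e[w_indices[k]] -= d1 * w_data[k]
            continue
        cp0 = off_pe + 2 * pl
        cp1 = cp0 + 1
        p0 = theta[cp0]
        p1 = theta[cp1]
        s0 = a0 + p0
        s1 = a1 + p1
        rhs[0] = (r0 + b00 * s0 + b01 * s1) / s2e - c0
        rhs[1] = (r1 + b01 * s0 + b11 * s1) / s2e - c1
        rhs[2] = (r0 + b00 * s0 + b01 * s1) / s2e
        rhs[3] = (r1 + b01 * s0 + b11 * s1) / s2e
        P[0, 0] = b00 / s2e + kll * ga00
        P[0, 1] = b01 / s2e + kll * ga01
        P[0, 2] = b00 / s2e
        P[0, 3] = b01 / s2e
        P[1, 1] = b11 / s2e + kll * ga11
        P[1, 2] = b01 / s2e
        P[1, 3] = b11 / s2e
        P[2, 2] = b00 / s2e + gp00
        P[2, 3] = b01 / s2e + gp01
        P[3, 3] = b11 / s2e + gp11
        for i in range(4):
            for j in range(i):
                P[i, j] = P[j, i]
        # 4x4 Cholesky P = L L'
        for i in range(4):
            for j in range(i + 1):
                s = P[i, j]
                for k in range(j):
                    s -= L[i, k] * L[j, k]
                if i == j:
                    L[i, i] = np.sqrt(s)
                else:
                    L[i, j] = s / L[j, j]
        # mean = P^-1 rhs via forward/back substitution
        for i in range(4):
            s = rhs[i]
            for k in range(i):
                s -= L[i, k] * zz[k]
            zz[i] = s / L[i, i]
        for i in range(3, -1, -1):
            s = zz[i]
            for k in range(i + 1, 4):
                s -= L[k, i] * mean[k]
            mean[i] = s / L[i, i]
        if noise != 0.0:
            # add L'^-1 z for a N(mean, P^-1) draw
            zz[0] = z[2 * l]
            zz[1] = z[2 * l + 1]
            zz[2] = z[2 * n_lev_a + 2 * pl]
            zz[3] = z[2 * n_lev_a + 2 * pl + 1]
            for i in range(3, -1, -1):
                s = zz[i]
                for k in range(i + 1, 4):
                    s -= L[k, i] * zz[k]
                zz[i] = s / L[i, i]
            for i in range(4):
                mean[i] += zz[i]
        da0 = mean[0] - a0
        da1 = mean[1] - a1
        dp0 = mean[2] - p0
        dp1 = mean[3] - p1
        theta[ca0] = mean[0]
        theta[ca1] = mean[1]
        theta[cp0] = mean[2]
        theta[cp1] = mean[3]
        d0 = da0 + dp0
        d1 = da1 + dp1
        for k in range(w_indptr[ca0], w_indptr[ca0 + 1]):
            e[w_indices[k]] -= d0 * w_data[k]
        for k in range(w_indptr[ca1], w_indptr[ca1 + 1]):
            e[w_indices[k]] -= d1 * w_data[k]
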