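"""Numba-compiled inner kernels.

The numerically hot primitives shared by the public modules: internal-coordinate
chain extension (NeRF), radius of gyration, backbone hydrogen-bond detection and
Markov-bridge state resampling. Public modules wrap these with validation and
typed containers; the test suite cross-checks kernel output against independent
pure-python formulations.
"""

import math

import numpy as np
from numba import njit

# Layout of the geometry parameter vector passed to build_chain.
G_B_N_CA = 0
G_B_CA_C = 1
G_B_C_N = 2
G_B_C_O = 3
G_B_CA_CB = 4
G_A_N_CA_C = 5
G_A_CA_C_N = 6
G_A_C_N_CA = 7
G_A_CA_C_O = 8
G_A_N_CA_CB = 9
G_T_CB = 10
G_OMEGA = 11
G_NPARAMS = 12


@njit(cache=True, inline="always")
def _place_cs(ax, ay, az, bx, by, bz, cx, cy, cz, bond, ct, st, cchi, schi):
    """Coordinates of atom D bonded to c with bond length, angle b-c-D and
    torsion a-b-c-D, taking the angle/torsion as (cos, sin) pairs."""
    # frame at c
    bcx = cx - bx
    bcy = cy - by
    bcz = cz - bz
    r = math.sqrt(bcx * bcx + bcy * bcy + bcz * bcz)
    bcx /= r
    bcy /= r
    bcz /= r
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    # n = ab x bc (normal of the a-b-c plane)
    nx = aby * bcz - abz * bcy
    ny = abz * bcx - abx * bcz
    nz = abx * bcy - aby * bcx
    r = math.sqrt(nx * nx + ny * ny + nz * nz)
    nx /= r
    ny /= r
    nz /= r
    # m = n x bc completes the right-handed frame (bc, m, n)
    mx = ny * bcz - nz * bcy
    my = nz * bcx - nx * bcz
    mz = nx * bcy - ny * bcx
    # out-of-plane component signed so the resulting dihedral a-b-c-D equals
    # chi under the IUPAC (right-hand rule about b->c) sign convention
    d0 = -bond * ct
    d1 = bond * st * cchi
    d2 = bond * st * schi
    return (cx + d0 * bcx + d1 * mx + d2 * nx,
            cy + d0 * bcy + d1 * my + d2 * ny,
            cz + d0 * bcz + d1 * mz + d2 * nz)


@njit(cache=True, inline="always")
def _place_s(ax, ay, az, bx, by, bz, cx, cy, cz, bond, theta_deg, chi_deg):
    theta = theta_deg * math.pi / 180.0
    chi = chi_deg * math.pi / 180.0
    return _place_cs(ax, ay, az, bx, by, bz, cx, cy, cz, bond,
                     math.cos(theta), math.sin(theta),
                     math.cos(chi), math.sin(chi))


@njit(cache=True)
def build_chain(phi, psi, sc_mask, geom):
    """Sequential backbone construction from dihedrals with ideal geometry.

    phi[0] and psi[L-1] are never read (undefined terminal angles). Returns
    (n, ca, c, o, sc) arrays of shape (L, 3); sc rows are NaN where sc_mask is
    False. The carbonyl O of residue i is placed trans to N(i+1) (torsion
    psi_i + 180 about N-CA-C); the C-terminal O uses torsion 180 by convention.
    """
    L = phi.shape[0]
    n = np.empty((L, 3))
    ca = np.empty((L, 3))
    c = np.empty((L, 3))
    o = np.empty((L, 3))
    sc = np.full((L, 3), np.nan)

    rad = math.pi / 180.0
    ct_cacn = math.cos(geom[G_A_CA_C_N] * rad)
    st_cacn = math.sin(geom[G_A_CA_C_N] * rad)
    ct_cnca = math.cos(geom[G_A_C_N_CA] * rad)
    st_cnca = math.sin(geom[G_A_C_N_CA] * rad)
    ct_ncac = math.cos(geom[G_A_N_CA_C] * rad)
    st_ncac = math.sin(geom[G_A_N_CA_C] * rad)
    ct_caco = math.cos(geom[G_A_CA_C_O] * rad)
    st_caco = math.sin(geom[G_A_CA_C_O] * rad)
    ct_ncacb = math.cos(geom[G_A_N_CA_CB] * rad)
    st_ncacb = math.sin(geom[G_A_N_CA_CB] * rad)
    c_om = math.cos(geom[G_OMEGA] * rad)
    s_om = math.sin(geom[G_OMEGA] * rad)
    c_cb = math.cos(geom[G_T_CB] * rad)
    s_cb = math.sin(geom[G_T_CB] * rad)

    # seed residue 1 in the z=0 plane
    nx, ny, nz = 0.0, 0.0, 0.0
    cax, cay, caz = geom[G_B_N_CA], 0.0, 0.0
    ccx = cax - geom[G_B_CA_C] * ct_ncac
    ccy = geom[G_B_CA_C] * st_ncac
    ccz = 0.0
    n[0, 0], n[0, 1], n[0, 2] = nx, ny, nz
    ca[0, 0], ca[0, 1], ca[0, 2] = cax, cay, caz
    c[0, 0], c[0, 1], c[0, 2] = ccx, ccy, ccz

    for i in range(1, L):
        cpsi = math.cos(psi[i - 1] * rad)
        spsi = math.sin(psi[i - 1] * rad)
        cphi = math.cos(phi[i] * rad)
        sphi = math.sin(phi[i] * rad)
        px, py, pz = _place_cs(nx, ny, nz, cax, cay, caz, ccx, ccy, ccz,
                               geom[G_B_C_N], ct_cacn, st_cacn, cpsi, spsi)
        qx, qy, qz = _place_cs(cax, cay, caz, ccx, ccy, ccz, px, py, pz,
                               geom[G_B_N_CA], ct_cnca, st_cnca, c_om, s_om)
        rx, ry, rz = _place_cs(ccx, ccy, ccz, px, py, pz, qx, qy, qz,
                               geom[G_B_CA_C], ct_ncac, st_ncac, cphi, sphi)
        nx, ny, nz = px, py, pz
        cax, cay, caz = qx, qy, qz
        ccx, ccy, ccz = rx, ry, rz
        n[i, 0], n[i, 1], n[i, 2] = nx, ny, nz
        ca[i, 0], ca[i, 1], ca[i, 2] = cax, cay, caz
        c[i, 0], c[i, 1], c[i, 2] = ccx, ccy, ccz

    for i in range(L):
        if i < L - 1:
            # torsion psi + 180: cos/sin are the negated psi trig
            c_o = -math.cos(psi[i] * rad)
            s_o = -math.sin(psi[i] * rad)
        else:
            c_o = -1.0
            s_o = 0.0
        ox, oy, oz = _place_cs(n[i, 0], n[i, 1], n[i, 2],
                               ca[i, 0], ca[i, 1], ca[i, 2],
                               c[i, 0], c[i, 1], c[i, 2],
                               geom[G_B_C_O], ct_caco, st_caco, c_o, s_o)
        o[i, 0], o[i, 1], o[i, 2] = ox, oy, oz
        if sc_mask[i]:
            sx, sy, sz = _place_cs(c[i, 0], c[i, 1], c[i, 2],
                                   n[i, 0], n[i, 1], n[i, 2],
                                   ca[i, 0], ca[i, 1], ca[i, 2],
                                   geom[G_B_CA_CB], ct_ncacb, st_ncacb,
                                   c_cb, s_cb)
            sc[i, 0], sc[i, 1], sc[i, 2] = sx, sy, sz
    return n, ca, c, o, sc


@njit(cache=True)
def rg_of(coords):
    """Root-mean-square distance of rows of coords to their centroid."""
    m = coords.shape[0]
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(m):
        cx += coords[i, 0]
        cy += coords[i, 1]
        cz += coords[i, 2]
    cx /= m
    cy /= m
    cz /= m
    s = 0.0
    for i in range(m):
        dx = coords[i, 0] - cx
        dy = coords[i, 1] - cy
        dz = coords[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
    return math.sqrt(s / m)


@njit(cache=True)
def rg_all_atoms(n, ca, c, o, sc, sc_mask):
    """Radius of gyration over every emitted atom (N, CA, C, O, SC where present)."""
    L = n.shape[0]
    m = 4 * L
    for i in range(L):
        if sc_mask[i]:
            m += 1
    cx = 0.0
    cy = 0.0
    cz = 0.0
    for i in range(L):
        cx += n[i, 0] + ca[i, 0] + c[i, 0] + o[i, 0]
        cy += n[i, 1] + ca[i, 1] + c[i, 1] + o[i, 1]
        cz += n[i, 2] + ca[i, 2] + c[i, 2] + o[i, 2]
        if sc_mask[i]:
            cx += sc[i, 0]
            cy += sc[i, 1]
            cz += sc[i, 2]
    cx /= m
    cy /= m
    cz /= m
    s = 0.0
    for i in range(L):
        dx = n[i, 0] - cx
        dy = n[i, 1] - cy
        dz = n[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
        dx = ca[i, 0] - cx
        dy = ca[i, 1] - cy
        dz = ca[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
        dx = c[i, 0] - cx
        dy = c[i, 1] - cy
        dz = c[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
        dx = o[i, 0] - cx
        dy = o[i, 1] - cy
        dz = o[i, 2] - cz
        s += dx * dx + dy * dy + dz * dz
        if sc_mask[i]:
            dx = sc[i, 0] - cx
            dy = sc[i, 1] - cy
            dz = sc[i, 2] - cz
            s += dx * dx + dy * dy + dz * dz
    return math.sqrt(s / m)


@njit(cache=True, inline="always")
def _dist3(p, q):
    dx = p[0] - q[0]
    dy = p[1] - q[1]
    dz = p[2] - q[2]
    return math.sqrt(dx * dx + dy * dy + dz * dz)


@njit(cache=True, inline="always")
def _angle3(p, q, r):
    """Angle p-q-r in degrees."""
    ax = p[0] - q[0]
    ay = p[1] - q[1]
    az = p[2] - q[2]
    bx = r[0] - q[0]
    by = r[1] - q[1]
    bz = r[2] - q[2]
    na = math.sqrt(ax * ax + ay * ay + az * az)
    nb = math.sqrt(bx * bx + by * by + bz * bz)
    co = (ax * bx + ay * by + az * bz) / (na * nb)
    if co > 1.0:
        co = 1.0
    elif co < -1.0:
        co = -1.0
    return math.acos(co) * 180.0 / math.pi


@njit(cache=True)
def assign_hbonds(n, ca, c, o, cutoff, min_angle, min_sep):
    """Best donor N(i) per acceptor carbonyl O(j), or -1.

    A candidate requires N(i)..O(j) < cutoff, angle C(j)-O(j)..N(i) > min_angle,
    angle O(j)..N(i)-CA(i) > min_angle and |i - j| >= min_sep. Among candidates
    the smallest N..O distance wins; each carbonyl forms at most one bond.
    Returns (donor_of, dist_of) arrays of length L.
    """
    L = n.shape[0]
    donor_of = np.full(L, -1, dtype=np.int64)
    dist_of = np.full(L, np.inf)
    for j in range(L):
        for i in range(L):
            sep = i - j
            if sep < 0:
                sep = -sep
            if sep < min_sep:
                continue
            d = _dist3(n[i], o[j])
            if d >= cutoff:
                continue
            if _angle3(c[j], o[j], n[i]) <= min_angle:
                continue
            if _angle3(o[j], n[i], ca[i]) <= min_angle:
                continue
            if d < dist_of[j]:
                dist_of[j] = d
                donor_of[j] = i
    return donor_of, dist_of


@njit(cache=True)
def hbond_descriptor_from_assignment(donor_of, labels):
    """8-category residue partition from a carbonyl bond assignment.

    labels: int8 per residue, 0=H, 1=E, 2=C. Order of the output:
    (s1, s2, s3, b1, b2, b3, b4, b5) = (H unbonded, E unbonded, C unbonded,
    H-H, E-E, C-C, H-C, E-C bonded); an H-E partner pair is tallied under b5.
    """
    out = np.zeros(8, dtype=np.int64)
    L = donor_of.shape[0]
    for j in range(L):
        i = donor_of[j]
        if i < 0:
            out[labels[j]] += 1
        else:
            la = labels[j]
            lb = labels[i]
            if la > lb:
                la, lb = lb, la
            if la == lb:
                out[3 + la] += 1
            elif la == 0 and lb == 2:
                out[6] += 1
            else:  # E-C and the unnamed H-E pair
                out[7] += 1
    return out


@njit(cache=True)
def rg_mh_block(phi, psi, states, sc_mask, geom, tsteps, init,
                mean_phi, mean_psi, spread,
                lo, width, ref_ld, floor_ld, use_ref, tmean, tsd,
                wlen, wpos, u_bridge, z_phi, z_psi, u_acc, c_hist):
    """One block of Metropolis-Hastings steps for the radius-of-gyration
    pipeline with a Gaussian target and a uniform-bin histogram reference.

    Mutates phi/psi/states in place, writes the post-step coarse value of
    every step into c_hist and returns the number of accepted steps. All
    randomness is pre-drawn (wlen/wpos window draws, u_bridge bridge
    uniforms, z_phi/z_psi emission normals, u_acc acceptance uniforms), so
    the block is a pure function of its inputs.
    """
    L = phi.shape[0]
    nb = ref_ld.shape[0]
    steps = wlen.shape[0]

    def _lr(c):
        g = -0.5 * ((c - tmean) / tsd) ** 2
        if not use_ref:
            return g
        idx = int((c - lo) / width)
        if c < lo or idx >= nb:
            return g - floor_ld
        return g - ref_ld[idx]

    n, ca, cc, o, sc = build_chain(phi, psi, sc_mask, geom)
    c = rg_all_atoms(n, ca, cc, o, sc, sc_mask)
    lr = _lr(c)
    accepted = 0
    for s in range(steps):
        w = wlen[s]
        a = wpos[s]
        b = a + w - 1
        new_states = bridge_resample(tsteps, init, states, a, b, u_bridge[s, :w])
        nphi = phi.copy()
        npsi = psi.copy()
        for t in range(w):
            i = a + t
            st = new_states[i]
            x = mean_phi[st] + z_phi[s, t] * spread[st]
            x = (x + 180.0) % 360.0 - 180.0
            if x == -180.0:
                x = 180.0
            nphi[i] = x
            x = mean_psi[st] + z_psi[s, t] * spread[st]
            x = (x + 180.0) % 360.0 - 180.0
            if x == -180.0:
                x = 180.0
            npsi[i] = x
        if a == 0:
            nphi[0] = np.nan
        if b == L - 1:
            npsi[L - 1] = np.nan
        n, ca, cc, o, sc = build_chain(nphi, npsi, sc_mask, geom)
        c_new = rg_all_atoms(n, ca, cc, o, sc, sc_mask)
        lr_new = _lr(c_new)
        d = lr_new - lr
        if d >= 0.0 or u_acc[s] < math.exp(d):
            phi[:] = nphi
            psi[:] = npsi
            states[:] = new_states
            c = c_new
            lr = lr_new
            accepted += 1
        c_hist[s] = c
    return accepted


@njit(cache=True)
def bridge_resample(tsteps, init, states, a, b, u):
    """Resample states[a..b] (inclusive, 0-based) from the Markov chain
    conditional on the flanking states, using pre-drawn uniforms u (len b-a+1).

    tsteps[i] is the transition matrix for the step residue i -> i+1. Exact
    conditional (forward-filtering backward-smoothing) sampling, so the move
    has unit Hastings ratio with respect to the chain distribution.
    """
    K = init.shape[0]
    L = states.shape[0]
    m = b - a + 1
    beta = np.empty((m, K))
    if b == L - 1:
        for k in range(K):
            beta[m - 1, k] = 1.0
    else:
        r = states[b + 1]
        for k in range(K):
            beta[m - 1, k] = tsteps[b, k, r]
    for t in range(m - 2, -1, -1):
        i = a + t
        for k in range(K):
            s = 0.0
            for kk in range(K):
                s += tsteps[i, k, kk] * beta[t + 1, kk]
            beta[t, k] = s
    out = states.copy()
    p = np.empty(K)
    for t in range(m):
        i = a + t
        tot = 0.0
        if i == 0:
            for k in range(K):
                p[k] = init[k] * beta[t, k]
                tot += p[k]
        else:
            prev = out[i - 1]
            for k in range(K):
                p[k] = tsteps[i - 1, prev, k] * beta[t, k]
                tot += p[k]
        x = u[t] * tot
        cum = 0.0
        ch = K - 1
        for k in range(K):
            cum += p[k]
            if x < cum:
                ch = k
                break
        out[i] = ch
    return out
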