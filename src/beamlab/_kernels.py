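"""Numba kernels for analog neutron/photon transport with track-length tallies.

All state is passed as flat arrays prepared by :mod:`beamlab.transport`.
Conventions inside the kernels:

* energies in eV; a neutron "speed" is sqrt(E) (mass-2 units, E = v^2),
  which is all the collision kinematics need;
* the scene is a prioritized region list plus an optional voxel lattice that
  overrides it; material index -1 means escape;
* tallies are per batch; the engine accumulates batch sums and square sums.
"""

from __future__ import annotations

import numpy as np
from numba import njit

E0_EV = 0.0253
TINY = 1e-12
NUDGE = 1e-6
E_FLOOR = 1e-5      # eV, terminate neutrons below this
MAX_STEPS = 200000


@njit(cache=True, inline="always")
def _in_bbox(x, y, z, bbox):
    return (
        bbox[0, 0] <= x <= bbox[0, 1]
        and bbox[1, 0] <= y <= bbox[1, 1]
        and bbox[2, 0] <= z <= bbox[2, 1]
    )


@njit(cache=True)
def _locate(x, y, z, rtype, params, rmat, prio, bbox,
            has_lat, lat_origin, lat_spacing, lat_mat):
    if not _in_bbox(x, y, z, bbox):
        return np.int64(-1)
    if has_lat:
        if (lat_origin[0] <= x <= lat_origin[0] + lat_spacing[0] * lat_mat.shape[0]
                and lat_origin[1] <= y <= lat_origin[1] + lat_spacing[1] * lat_mat.shape[1]
                and lat_origin[2] <= z <= lat_origin[2] + lat_spacing[2] * lat_mat.shape[2]):
            ix = int((x - lat_origin[0]) / lat_spacing[0])
            iy = int((y - lat_origin[1]) / lat_spacing[1])
            iz = int((z - lat_origin[2]) / lat_spacing[2])
            if ix == lat_mat.shape[0]:
                ix -= 1
            if iy == lat_mat.shape[1]:
                iy -= 1
            if iz == lat_mat.shape[2]:
                iz -= 1
            return np.int64(lat_mat[ix, iy, iz])
    best = np.int64(-1)
    best_prio = -1
    for i in range(rtype.shape[0]):
        if prio[i] <= best_prio:
            continue
        p = params[i]
        if rtype[i] == 0:
            inside = (p[0] <= x <= p[1] and p[2] <= y <= p[3] and p[4] <= z <= p[5])
        elif rtype[i] == 1:
            inside = (x * x + y * y <= p[0] * p[0] and p[1] <= z <= p[2])
        else:
            r2 = x * x + y * y
            inside = (p[0] * p[0] <= r2 <= p[1] * p[1] and p[2] <= z <= p[3])
        if inside:
            best = np.int64(rmat[i])
            best_prio = prio[i]
    return best


@njit(cache=True)
def _dist_boundary(x, y, z, dx, dy, dz, rtype, params, bbox,
                   has_lat, lat_origin, lat_spacing, lat_mat):
    """Distance to the nearest potential material-change surface."""
    best = 1e30
    # lattice voxel faces (when inside the lattice box)
    if has_lat:
        ux = lat_origin[0] + lat_spacing[0] * lat_mat.shape[0]
        uy = lat_origin[1] + lat_spacing[1] * lat_mat.shape[1]
        uz = lat_origin[2] + lat_spacing[2] * lat_mat.shape[2]
        inside = (lat_origin[0] <= x <= ux and lat_origin[1] <= y <= uy
                  and lat_origin[2] <= z <= uz)
        if inside:
            for axis in range(3):
                d = dx if axis == 0 else (dy if axis == 1 else dz)
                if d == 0.0:
                    continue
                c = x if axis == 0 else (y if axis == 1 else z)
                idx = int((c - lat_origin[axis]) / lat_spacing[axis])
                if d > 0:
                    plane = lat_origin[axis] + (idx + 1) * lat_spacing[axis]
                else:
                    plane = lat_origin[axis] + idx * lat_spacing[axis]
                t = (plane - c) / d
                if t <= TINY:
                    t = t + lat_spacing[axis] / abs(d)
                if t < best:
                    best = t
        else:
            for axis in range(3):
                d = dx if axis == 0 else (dy if axis == 1 else dz)
                if d == 0.0:
                    continue
                c = x if axis == 0 else (y if axis == 1 else z)
                lo = lat_origin[axis]
                hi = lo + lat_spacing[axis] * lat_mat.shape[axis]
                for plane in (lo, hi):
                    t = (plane - c) / d
                    if TINY < t < best:
                        best = t
    for i in range(rtype.shape[0]):
        p = params[i]
        if rtype[i] == 0:
            if dx != 0.0:
                for k in range(2):
                    t = (p[k] - x) / dx
                    if TINY < t < best:
                        best = t
            if dy != 0.0:
                for k in range(2):
                    t = (p[2 + k] - y) / dy
                    if TINY < t < best:
                        best = t
            if dz != 0.0:
                for k in range(2):
                    t = (p[4 + k] - z) / dz
                    if TINY < t < best:
                        best = t
        else:
            if rtype[i] == 1:
                r_in = -1.0
                r_out = p[0]
                z0 = p[1]
                z1 = p[2]
            else:
                r_in = p[0]
                r_out = p[1]
                z0 = p[2]
                z1 = p[3]
            if dz != 0.0:
                t = (z0 - z) / dz
                if TINY < t < best:
                    best = t
                t = (z1 - z) / dz
                if TINY < t < best:
                    best = t
            a = dx * dx + dy * dy
            if a > 0.0:
                b = x * dx + y * dy
                c0 = x * x + y * y
                for m in range(2):
                    R = r_out if m == 0 else r_in
                    if R <= 0.0:
                        continue
                    disc = b * b - a * (c0 - R * R)
                    if disc >= 0.0:
                        sq = np.sqrt(disc)
                        t = (-b - sq) / a
                        if TINY < t < best:
                            best = t
                        t = (-b + sq) / a
                        if TINY < t < best:
                            best = t
    if best >= 1e29:
        for axis in range(3):
            d = dx if axis == 0 else (dy if axis == 1 else dz)
            if d == 0.0:
                continue
            c = x if axis == 0 else (y if axis == 1 else z)
            for k in range(2):
                t = (bbox[axis, k] - c) / d
                if TINY < t < best:
                    best = t
    if best < NUDGE:
        best = NUDGE
    return best


@njit(cache=True)
def _group_index(e, edges):
    """Index of e in ascending edges, -1 if outside."""
    if e < edges[0] or e >= edges[edges.shape[0] - 1]:
        return -1
    lo = 0
    hi = edges.shape[0] - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if e >= edges[mid]:
            lo = mid
        else:
            hi = mid
    return lo


@njit(cache=True)
def _macro_xs(mat, e, mat_start, nuc_N, nuc_sig0c, nuc_sigs):
    sigc = 0.0
    sigs = 0.0
    inv_v = np.sqrt(E0_EV / e)
    for k in range(mat_start[mat], mat_start[mat + 1]):
        sigc += nuc_N[k] * nuc_sig0c[k] * inv_v
        sigs += nuc_N[k] * nuc_sigs[k]
    return sigc, sigs


@njit(cache=True)
def _voxel_index(x, y, z, t_origin, t_spacing, shape0, shape1, shape2):
    ix = int((x - t_origin[0]) / t_spacing[0])
    iy = int((y - t_origin[1]) / t_spacing[1])
    iz = int((z - t_origin[2]) / t_spacing[2])
    if ix < 0 or iy < 0 or iz < 0 or ix >= shape0 or iy >= shape1 or iz >= shape2:
        return -1, -1, -1
    return ix, iy, iz


@njit(cache=True)
def _score_track(x, y, z, dx, dy, dz, length, w, e, is_neutron,
                 t_origin, t_spacing, edges, cd_cut,
                 flux, one_v_tot, one_v_sub, pflux, gamma_edep,
                 muen_lin):
    """Amanatides-Woo traversal scoring w*len (and folded variants) per voxel."""
    n0 = flux.shape[1]
    n1 = flux.shape[2]
    n2 = flux.shape[3]
    # clip [0, length] to the mesh box
    t0 = 0.0
    t1 = length
    for axis in range(3):
        d = dx if axis == 0 else (dy if axis == 1 else dz)
        c = x if axis == 0 else (y if axis == 1 else z)
        lo = t_origin[axis]
        n_ax = n0 if axis == 0 else (n1 if axis == 1 else n2)
        hi = lo + t_spacing[axis] * n_ax
        if d == 0.0:
            if c < lo or c > hi:
                return
        else:
            ta = (lo - c) / d
            tb = (hi - c) / d
            if ta > tb:
                ta, tb = tb, ta
            if ta > t0:
                t0 = ta
            if tb < t1:
                t1 = tb
    if t1 <= t0:
        return
    g = _group_index(e, edges) if is_neutron else -1
    f1v = np.sqrt(E0_EV / e) if is_neutron else 0.0
    sub = is_neutron and e < cd_cut
    e_mev = e * 1e-6

    eps = (t1 - t0) * 1e-12 + 1e-15
    t = t0 + eps
    cx = x + dx * t
    cy = y + dy * t
    cz = z + dz * t
    ix = int((cx - t_origin[0]) / t_spacing[0])
    iy = int((cy - t_origin[1]) / t_spacing[1])
    iz = int((cz - t_origin[2]) / t_spacing[2])
    if ix < 0:
        ix = 0
    if iy < 0:
        iy = 0
    if iz < 0:
        iz = 0
    if ix >= n0:
        ix = n0 - 1
    if iy >= n1:
        iy = n1 - 1
    if iz >= n2:
        iz = n2 - 1

    # per-axis step setup
    if dx > 0:
        stepx = 1
        tnx = t0 + ((t_origin[0] + (ix + 1) * t_spacing[0]) - (x + dx * t0)) / dx
        tdx = t_spacing[0] / dx
    elif dx < 0:
        stepx = -1
        tnx = t0 + ((t_origin[0] + ix * t_spacing[0]) - (x + dx * t0)) / dx
        tdx = -t_spacing[0] / dx
    else:
        stepx = 0
        tnx = 1e30
        tdx = 1e30
    if dy > 0:
        stepy = 1
        tny = t0 + ((t_origin[1] + (iy + 1) * t_spacing[1]) - (y + dy * t0)) / dy
        tdy = t_spacing[1] / dy
    elif dy < 0:
        stepy = -1
        tny = t0 + ((t_origin[1] + iy * t_spacing[1]) - (y + dy * t0)) / dy
        tdy = -t_spacing[1] / dy
    else:
        stepy = 0
        tny = 1e30
        tdy = 1e30
    if dz > 0:
        stepz = 1
        tnz = t0 + ((t_origin[2] + (iz + 1) * t_spacing[2]) - (z + dz * t0)) / dz
        tdz = t_spacing[2] / dz
    elif dz < 0:
        stepz = -1
        tnz = t0 + ((t_origin[2] + iz * t_spacing[2]) - (z + dz * t0)) / dz
        tdz = -t_spacing[2] / dz
    else:
        stepz = 0
        tnz = 1e30
        tdz = 1e30

    t = t0
    while t < t1 - 1e-15:
        tn = tnx
        if tny < tn:
            tn = tny
        if tnz < tn:
            tn = tnz
        seg_end = tn if tn < t1 else t1
        seg = seg_end - t
        if seg > 0.0:
            wl = w * seg
            if is_neutron:
                if g >= 0:
                    flux[g, ix, iy, iz] += wl
                one_v_tot[ix, iy, iz] += wl * f1v
                if sub:
                    one_v_sub[ix, iy, iz] += wl * f1v
            else:
                pflux[ix, iy, iz] += wl
                gamma_edep[ix, iy, iz] += wl * e_mev * muen_lin
        t = seg_end
        if tn >= t1:
            break
        if tnx <= tny and tnx <= tnz:
            ix += stepx
            tnx += tdx
            if ix < 0 or ix >= n0:
                break
        elif tny <= tnz:
            iy += stepy
            tny += tdy
            if iy < 0 or iy >= n1:
                break
        else:
            iz += stepz
            tnz += tdz
            if iz < 0 or iz >= n2:
                break


@njit(cache=True)
def _photon_mu(e, pg_loge, pg_mu, pg_muen):
    """Water mass coefficients (cm2/g) interpolated linearly in log E."""
    le = np.log10(e)
    n = pg_loge.shape[0]
    if le <= pg_loge[0]:
        return pg_mu[0], pg_muen[0]
    if le >= pg_loge[n - 1]:
        return pg_mu[n - 1], pg_muen[n - 1]
    lo = 0
    hi = n - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if le >= pg_loge[mid]:
            lo = mid
        else:
            hi = mid
    f = (le - pg_loge[lo]) / (pg_loge[lo + 1] - pg_loge[lo])
    return (pg_mu[lo] * (1 - f) + pg_mu[lo + 1] * f,
            pg_muen[lo] * (1 - f) + pg_muen[lo + 1] * f)


@njit(cache=True)
def _transport_photon(x, y, z, dx, dy, dz, e, w,
                      rtype, params, rmat, prio, bbox,
                      has_lat, lat_origin, lat_spacing, lat_mat, lat_density,
                      mat_mu_scale,
                      pg_loge, pg_mu, pg_muen,
                      t_origin, t_spacing, edges, cd_cut,
                      flux, one_v_tot, one_v_sub, pflux, gamma_edep):
    """Straight-line photon transport: attenuation and local deposition both
    use the energy-absorption coefficient (forward-scatter approximation)."""
    for _ in range(MAX_STEPS):
        mat = _locate(x, y, z, rtype, params, rmat, prio, bbox,
                      has_lat, lat_origin, lat_spacing, lat_mat)
        if mat < 0:
            return 0
        mu_rho, muen_rho = _photon_mu(e, pg_loge, pg_mu, pg_muen)
        scale = mat_mu_scale[mat]
        if has_lat:
            ux = lat_origin[0] + lat_spacing[0] * lat_mat.shape[0]
            uy = lat_origin[1] + lat_spacing[1] * lat_mat.shape[1]
            uz = lat_origin[2] + lat_spacing[2] * lat_mat.shape[2]
            if lat_origin[0] <= x <= ux and lat_origin[1] <= y <= uy and lat_origin[2] <= z <= uz:
                ix = min(int((x - lat_origin[0]) / lat_spacing[0]), lat_mat.shape[0] - 1)
                iy = min(int((y - lat_origin[1]) / lat_spacing[1]), lat_mat.shape[1] - 1)
                iz = min(int((z - lat_origin[2]) / lat_spacing[2]), lat_mat.shape[2] - 1)
                scale *= lat_density[ix, iy, iz]
        muen_lin = muen_rho * scale  # 1/cm (mass coeff x water-equivalent density)
        d_b = _dist_boundary(x, y, z, dx, dy, dz, rtype, params, bbox,
                             has_lat, lat_origin, lat_spacing, lat_mat)
        if muen_lin <= TINY:
            fly = d_b
            absorbed = False
        else:
            s = -np.log(np.random.random()) / muen_lin
            if s < d_b:
                fly = s
                absorbed = True
            else:
                fly = d_b
                absorbed = False
        _score_track(x, y, z, dx, dy, dz, fly, w, e, False,
                     t_origin, t_spacing, edges, cd_cut,
                     flux, one_v_tot, one_v_sub, pflux, gamma_edep, muen_lin)
        if absorbed:
            return 1
        x += (fly + NUDGE) * dx
        y += (fly + NUDGE) * dy
        z += (fly + NUDGE) * dz
    return 0


@njit(cache=True)
def run_batch(pos, dirs, en, is_n, seed,
              rtype, params, rmat, prio, bbox,
              has_lat, lat_origin, lat_spacing, lat_mat, lat_density,
              mat_start, nuc_N, nuc_sig0c, nuc_sigs, nuc_A, nuc_channel,
              h_channel, mat_mu_scale,
              pg_loge, pg_mu, pg_muen,
              t_origin, t_spacing, edges, cd_cut,
              flux, one_v_tot, one_v_sub, capture, recoil, pflux, gamma_edep,
              implicit_capture, photon_on, recoil_cut, freegas_cut, kT):
    """Transport one batch of source particles.  Returns (absorbed, escaped)
    neutron history counts (exact partition in analog mode)."""
    np.random.seed(seed)
    absorbed = 0
    escaped = 0
    n = pos.shape[0]
    for ip in range(n):
        x = pos[ip, 0]
        y = pos[ip, 1]
        z = pos[ip, 2]
        dx = dirs[ip, 0]
        dy = dirs[ip, 1]
        dz = dirs[ip, 2]
        e = en[ip]
        w = 1.0
        if not is_n[ip]:
            if photon_on:
                st = _transport_photon(x, y, z, dx, dy, dz, e, w,
                                       rtype, params, rmat, prio, bbox,
                                       has_lat, lat_origin, lat_spacing, lat_mat, lat_density,
                                       mat_mu_scale, pg_loge, pg_mu, pg_muen,
                                       t_origin, t_spacing, edges, cd_cut,
                                       flux, one_v_tot, one_v_sub, pflux, gamma_edep)
                if st == 1:
                    absorbed += 1
                else:
                    escaped += 1
            else:
                escaped += 1
            continue
        alive = True
        for _ in range(MAX_STEPS):
            if not alive:
                break
            mat = _locate(x, y, z, rtype, params, rmat, prio, bbox,
                          has_lat, lat_origin, lat_spacing, lat_mat)
            if mat < 0:
                escaped += 1
                alive = False
                break
            dens = 1.0
            if has_lat:
                ux = lat_origin[0] + lat_spacing[0] * lat_mat.shape[0]
                uy = lat_origin[1] + lat_spacing[1] * lat_mat.shape[1]
                uz = lat_origin[2] + lat_spacing[2] * lat_mat.shape[2]
                if (lat_origin[0] <= x <= ux and lat_origin[1] <= y <= uy
                        and lat_origin[2] <= z <= uz):
                    ix = min(int((x - lat_origin[0]) / lat_spacing[0]), lat_mat.shape[0] - 1)
                    iy = min(int((y - lat_origin[1]) / lat_spacing[1]), lat_mat.shape[1] - 1)
                    iz = min(int((z - lat_origin[2]) / lat_spacing[2]), lat_mat.shape[2] - 1)
                    dens = lat_density[ix, iy, iz]
            sigc, sigs = _macro_xs(mat, e, mat_start, nuc_N, nuc_sig0c, nuc_sigs)
            sigc *= dens
            sigs *= dens
            sigt = sigc + sigs
            d_b = _dist_boundary(x, y, z, dx, dy, dz, rtype, params, bbox,
                                 has_lat, lat_origin, lat_spacing, lat_mat)
            if sigt <= TINY:
                _score_track(x, y, z, dx, dy, dz, d_b, w, e, True,
                             t_origin, t_spacing, edges, cd_cut,
                             flux, one_v_tot, one_v_sub, pflux, gamma_edep, 0.0)
                x += (d_b + NUDGE) * dx
                y += (d_b + NUDGE) * dy
                z += (d_b + NUDGE) * dz
                continue
            s = -np.log(np.random.random()) / sigt
            if s >= d_b:
                _score_track(x, y, z, dx, dy, dz, d_b, w, e, True,
                             t_origin, t_spacing, edges, cd_cut,
                             flux, one_v_tot, one_v_sub, pflux, gamma_edep, 0.0)
                x += (d_b + NUDGE) * dx
                y += (d_b + NUDGE) * dy
                z += (d_b + NUDGE) * dz
                continue
            _score_track(x, y, z, dx, dy, dz, s, w, e, True,
                         t_origin, t_spacing, edges, cd_cut,
                         flux, one_v_tot, one_v_sub, pflux, gamma_edep, 0.0)
            x += s * dx
            y += s * dy
            z += s * dz
            vx, vy, vz = _voxel_index(x, y, z, t_origin, t_spacing,
                                      flux.shape[1], flux.shape[2], flux.shape[3])
            inv_v = np.sqrt(E0_EV / e)

            if implicit_capture:
                # expected-value capture scoring, then forced scatter
                if vx >= 0:
                    for k in range(mat_start[mat], mat_start[mat + 1]):
                        pc = dens * nuc_N[k] * nuc_sig0c[k] * inv_v / sigt
                        if pc > 0.0:
                            capture[nuc_channel[k], vx, vy, vz] += w * pc
                            if photon_on and nuc_channel[k] == h_channel:
                                phi_ = np.random.random() * 2.0 * np.pi
                                mu_ = 2.0 * np.random.random() - 1.0
                                st_ = np.sqrt(1.0 - mu_ * mu_)
                                _transport_photon(
                                    x, y, z, st_ * np.cos(phi_), st_ * np.sin(phi_),
                                    mu_, 2.22e6, w * pc,
                                    rtype, params, rmat, prio, bbox,
                                    has_lat, lat_origin, lat_spacing, lat_mat, lat_density,
                                    mat_mu_scale, pg_loge, pg_mu, pg_muen,
                                    t_origin, t_spacing, edges, cd_cut,
                                    flux, one_v_tot, one_v_sub, pflux, gamma_edep)
                w *= sigs / sigt
                if w < 0.01:
                    if np.random.random() < w / 0.1:
                        w = 0.1
                    else:
                        absorbed += 1
                        alive = False
                        break
                do_scatter = True
            else:
                if np.random.random() < sigc / sigt:
                    # analog capture: pick nuclide proportional to N*sigma_c
                    xi = np.random.random() * sigc
                    acc = 0.0
                    kk = mat_start[mat]
                    for k in range(mat_start[mat], mat_start[mat + 1]):
                        acc += dens * nuc_N[k] * nuc_sig0c[k] * inv_v
                        kk = k
                        if acc >= xi:
                            break
                    if vx >= 0:
                        capture[nuc_channel[kk], vx, vy, vz] += w
                    if photon_on and nuc_channel[kk] == h_channel:
                        phi_ = np.random.random() * 2.0 * np.pi
                        mu_ = 2.0 * np.random.random() - 1.0
                        st_ = np.sqrt(1.0 - mu_ * mu_)
                        _transport_photon(
                            x, y, z, st_ * np.cos(phi_), st_ * np.sin(phi_), mu_,
                            2.22e6, w,
                            rtype, params, rmat, prio, bbox,
                            has_lat, lat_origin, lat_spacing, lat_mat, lat_density,
                            mat_mu_scale, pg_loge, pg_mu, pg_muen,
                            t_origin, t_spacing, edges, cd_cut,
                            flux, one_v_tot, one_v_sub, pflux, gamma_edep)
                    absorbed += 1
                    alive = False
                    break
                do_scatter = True

            if do_scatter:
                # pick scattering nuclide proportional to N*sigma_s
                xi = np.random.random() * sigs
                acc = 0.0
                kk = mat_start[mat]
                for k in range(mat_start[mat], mat_start[mat + 1]):
                    acc += dens * nuc_N[k] * nuc_sigs[k]
                    kk = k
                    if acc >= xi:
                        break
                A = nuc_A[kk]
                vmag = np.sqrt(e)
                vnx = vmag * dx
                vny = vmag * dy
                vnz = vmag * dz
                # free-gas target below the thermal-motion cutoff (SVT rejection)
                tx = 0.0
                ty = 0.0
                tz = 0.0
                if e < freegas_cut:
                    sig_v = np.sqrt(kT / (2.0 * A))
                    for _try in range(1000):
                        tx = sig_v * np.random.normal()
                        ty = sig_v * np.random.normal()
                        tz = sig_v * np.random.normal()
                        vt = np.sqrt(tx * tx + ty * ty + tz * tz)
                        rx = vnx - tx
                        ry = vny - ty
                        rz = vnz - tz
                        vrel = np.sqrt(rx * rx + ry * ry + rz * rz)
                        if np.random.random() * (vmag + vt) < vrel:
                            break
                # centre-of-mass frame, isotropic scattering
                cmx = (vnx + A * tx) / (1.0 + A)
                cmy = (vny + A * ty) / (1.0 + A)
                cmz = (vnz + A * tz) / (1.0 + A)
                gx = vnx - cmx
                gy = vny - cmy
                gz = vnz - cmz
                gmag = np.sqrt(gx * gx + gy * gy + gz * gz)
                phi_ = np.random.random() * 2.0 * np.pi
                mu_ = 2.0 * np.random.random() - 1.0
                st_ = np.sqrt(1.0 - mu_ * mu_)
                nx_ = gmag * st_ * np.cos(phi_)
                ny_ = gmag * st_ * np.sin(phi_)
                nz_ = gmag * mu_
                vpx = cmx + nx_
                vpy = cmy + ny_
                vpz = cmz + nz_
                e_new = vpx * vpx + vpy * vpy + vpz * vpz
                if e_new < E_FLOOR:
                    e_new = E_FLOOR
                vmag_new = np.sqrt(e_new)
                if e > recoil_cut and nuc_channel[kk] == h_channel and vx >= 0:
                    de = e - e_new
                    if de > 0.0:
                        recoil[vx, vy, vz] += w * de * 1e-6  # MeV
                dx = vpx / vmag_new
                dy = vpy / vmag_new
                dz = vpz / vmag_new
                e = e_new
        else:
            # ran out of steps: treat as absorbed (should not happen)
            absorbed += 1
    return absorbed, escaped
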