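"""Numba transport kernel: photon histories from emission to crystal deposit.

Geometry convention: z axis points from the patient toward the camera.  The
collimator entrance face is at z = 0, the source at z = -D.  Phantom slabs
live at z < 0; the camera stack (collimator, Al entrance window, NaI
crystal, crown-glass backscatter slab) at z >= 0.

Collimator transport uses Woodcock (delta) tracking against the lead
majorant inside the hexagonal-lattice region, which is exact for arbitrary
hole geometry without boundary ray tracing.  The septal-penetration flag
for undisturbed rays is evaluated exactly from the distance to the exit of
the entry hexagon: the holes are completely separated by septal lead, so
leaving the entry hole prism before the collimator back plane implies lead
contact.
"""

import numpy as np
from numba import njit

# flag bits
F_SCAT_PHANTOM = 1
F_SCAT_CAMERA = 2
F_PENETRATED = 4
F_LEAD_XRAY = 8

_MEC2 = 511.0
_SQRT3_2 = 0.8660254037844386
_FWHM2SIG = 0.42466090014400953

# Pb K shell: edge 88 keV, K-alpha 75 keV, (K fraction)*(fluorescence yield)
_PB_K_EDGE = 88.0
_PB_KA_KEV = 75.0
_PB_KXRAY_PROB = 0.75


@njit(cache=False)
def seed_numba(seed):
    np.random.seed(seed)


@njit(cache=False, inline="always")
def _mu_channels(mat, e_kev, log_e, mu_tab, out4):
    """Linear attenuation per channel [1/mm]; returns total."""
    x = np.log(e_kev)
    n = log_e.shape[0]
    if x <= log_e[0]:
        i = 0
        f = 0.0
    elif x >= log_e[n - 1]:
        i = n - 2
        f = 1.0
    else:
        i = np.searchsorted(log_e, x) - 1
        f = (x - log_e[i]) / (log_e[i + 1] - log_e[i])
    tot = 0.0
    for c in range(4):
        v = mu_tab[mat, c, i] * (1.0 - f) + mu_tab[mat, c, i + 1] * f
        out4[c] = v
        tot += v
    return tot


@njit(cache=False)
def sample_compton(e_kev):
    """Klein-Nishina sampling; returns (e_out_kev, cos_theta)."""
    k = e_kev / _MEC2
    eps0 = 1.0 / (1.0 + 2.0 * k)
    a1 = -np.log(eps0)
    a2 = 0.5 * (1.0 - eps0 * eps0)
    while True:
        if np.random.random() * (a1 + a2) < a1:
            eps = eps0 * np.exp(a1 * np.random.random())
        else:
            eps = np.sqrt(eps0 * eps0 + (1.0 - eps0 * eps0) * np.random.random())
        t = (1.0 - eps) / (k * eps)
        sin2 = t * (2.0 - t)
        if np.random.random() <= 1.0 - eps * sin2 / (1.0 + eps * eps):
            return e_kev * eps, 1.0 - t


@njit(cache=False)
def sample_thomson():
    """Coherent-scatter polar angle from the Thomson shape (1+cos^2)."""
    while True:
        mu = 2.0 * np.random.random() - 1.0
        if np.random.random() <= 0.5 * (1.0 + mu * mu):
            return mu


_HC_KEV_ANGSTROM = 12.398


@njit(cache=False, inline="always")
def _compton_accept(e_kev, cos_t, q0):
    """Incoherent scattering-function acceptance S(x,Z)/Z.

    x = sin(theta/2)/lambda [1/Angstrom]; the universal shape
    S/Z = x^2/(q0^2+x^2) suppresses the small-angle scattering that the
    free-electron Klein-Nishina shape overestimates.  q0 <= 0 disables the
    correction (free-electron detector response)."""
    if q0 <= 0.0:
        return True
    x2 = (e_kev / _HC_KEV_ANGSTROM) ** 2 * 0.5 * (1.0 - cos_t)
    return np.random.random() < x2 / (q0 * q0 + x2)


@njit(cache=False)
def sample_coherent(e_kev, fb):
    """Coherent polar angle from a dipole form factor times Thomson shape.

    F(x)^2 ~ 1/(1+(x/fb)^2)^2 concentrates coherent scattering at small
    angles, unlike the bare Thomson shape.  fb <= 0 falls back to Thomson.
    """
    if fb <= 0.0:
        return sample_thomson()
    s_max = (e_kev / _HC_KEV_ANGSTROM) ** 2  # x^2 at 180 degrees
    b2 = fb * fb
    a = s_max / (b2 + s_max)
    while True:
        v = np.random.random() * a
        s = b2 * v / (1.0 - v)
        mu = 1.0 - 2.0 * s / s_max
        if np.random.random() <= 0.5 * (1.0 + mu * mu):
            return mu


@njit(cache=False, inline="always")
def _rotate(ux, uy, uz, cos_t, phi):
    """Rotate unit vector by polar angle (cos_t) about itself, azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    if abs(uz) > 0.999999:
        sign = 1.0 if uz > 0 else -1.0
        return sin_t * cp, sin_t * sp, sign * cos_t
    s = np.sqrt(1.0 - uz * uz)
    vx = sin_t * (cp * uz * ux - sp * uy) / s + cos_t * ux
    vy = sin_t * (cp * uz * uy + sp * ux) / s + cos_t * uy
    vz = -sin_t * cp * s + cos_t * uz
    n = np.sqrt(vx * vx + vy * vy + vz * vz)
    return vx / n, vy / n, vz / n


@njit(cache=False, inline="always")
def _nearest_hex_center(x, y, pitch):
    h = pitch * _SQRT3_2
    jr = int(np.floor(y / h + 0.5))
    best = 1.0e30
    bx = 0.0
    by = 0.0
    for dj in range(-1, 2):
        j = jr + dj
        cy = j * h
        xoff = 0.5 * pitch if (j % 2 != 0) else 0.0
        ir = int(np.floor((x - xoff) / pitch + 0.5))
        for di in range(-1, 2):
            cx = (ir + di) * pitch + xoff
            d2 = (x - cx) ** 2 + (y - cy) ** 2
            if d2 < best:
                best = d2
                bx = cx
                by = cy
    return bx, by


@njit(cache=False, inline="always")
def _in_hole(x, y, pitch, flat):
    cx, cy = _nearest_hex_center(x, y, pitch)
    dx = x - cx
    dy = y - cy
    half = 0.5 * flat
    if abs(dx) > half:
        return False
    if abs(0.5 * dx + _SQRT3_2 * dy) > half:
        return False
    if abs(-0.5 * dx + _SQRT3_2 * dy) > half:
        return False
    return True


@njit(cache=False)
def hex_exit_path(x, y, ux, uy, pitch, flat):
    """Path length (3D units per unit |u_lateral| embedded) to leave the
    current hexagonal hole along lateral velocity (ux, uy).

    Returns a large number if the ray never leaves the hexagon (vertical).
    The caller scales by total/z velocity as needed.
    """
    cx, cy = _nearest_hex_center(x, y, pitch)
    dx = x - cx
    dy = y - cy
    half = 0.5 * flat
    t_exit = 1.0e30
    # the three flat-normal axes
    for ax in range(3):
        if ax == 0:
            ex = 1.0
            ey = 0.0
        elif ax == 1:
            ex = 0.5
            ey = _SQRT3_2
        else:
            ex = -0.5
            ey = _SQRT3_2
        u0 = dx * ex + dy * ey
        v = ux * ex + uy * ey
        if abs(v) > 1.0e-12:
            t = ((half if v > 0 else -half) - u0) / v
            if 0.0 <= t < t_exit:
                t_exit = t
    return t_exit


@njit(cache=False, inline="always")
def _box_exit(x, y, z, ux, uy, uz, hx, hy, z0, z1):
    """Distance to exit the box [-hx,hx]x[-hy,hy]x[z0,z1] from inside."""
    t = 1.0e30
    if uz > 1e-12:
        t = min(t, (z1 - z) / uz)
    elif uz < -1e-12:
        t = min(t, (z0 - z) / uz)
    if ux > 1e-12:
        t = min(t, (hx - x) / ux)
    elif ux < -1e-12:
        t = min(t, (-hx - x) / ux)
    if uy > 1e-12:
        t = min(t, (hy - y) / uy)
    elif uy < -1e-12:
        t = min(t, (-hy - y) / uy)
    return t


@njit(cache=False, inline="always")
def _box_enter(x, y, z, ux, uy, uz, hx, hy, z0, z1):
    """Distance to enter the box from outside; negative if missed."""
    tmin = 0.0
    tmax = 1.0e30
    for axis in range(3):
        if axis == 0:
            p = z
            u = uz
            lo = z0
            hi = z1
        elif axis == 1:
            p = x
            u = ux
            lo = -hx
            hi = hx
        else:
            p = y
            u = uy
            lo = -hy
            hi = hy
        if abs(u) < 1e-12:
            if p < lo or p > hi:
                return -1.0
        else:
            t1 = (lo - p) / u
            t2 = (hi - p) / u
            if t1 > t2:
                t1, t2 = t2, t1
            if t1 > tmin:
                tmin = t1
            if t2 < tmax:
                tmax = t2
    if tmax <= tmin or tmax <= 1e-9:
        return -1.0
    return tmin if tmin > 1e-9 else 1e-9


@njit(cache=False)
def trace_kernel(
    n_emitted,
    seed,
    # source: 0 point, 1 line along y, 2 disk
    src_kind,
    src_half_len,
    src_radius,
    src_z,
    pencil,
    # emission tables
    line_e,
    line_cum,
    cont_icdf,
    # direction biasing (nested cones about +z)
    b1,
    b2,
    cos1,
    cos2,
    # phantom slabs
    slab_z0,
    slab_z1,
    slab_mat,
    slab_hx,
    slab_hy,
    # collimator
    has_coll,
    hole_flat,
    pitch,
    coll_len,
    pb_id,
    # binding corrections per material (<=0 disables)
    mat_q0,
    mat_fb,
    # camera stack
    cam_z0,
    cam_z1,
    cam_mat,
    nai_id,
    det_hx,
    det_hy,
    # blur / cuts
    intr_fwhm,
    eres_frac,
    e_cut,
    # cross sections
    log_e,
    mu_tab,
    # outputs: columns weight, birth_e, e_dep, e_meas, x, y
    out,
    out_flags,
):
    np.random.seed(seed)
    ch = np.zeros(4)
    n_det = 0
    cam_top = cam_z1[cam_z1.shape[0] - 1]
    omega1 = 2.0 * np.pi * (1.0 - cos1)
    omega2 = 2.0 * np.pi * (1.0 - cos2)
    four_pi = 4.0 * np.pi

    for _ in range(n_emitted):
        # --- emission position
        if src_kind == 1:
            x = 0.0
            y = (2.0 * np.random.random() - 1.0) * src_half_len
        elif src_kind == 2:
            r = src_radius * np.sqrt(np.random.random())
            a = 2.0 * np.pi * np.random.random()
            x = r * np.cos(a)
            y = r * np.sin(a)
        else:
            x = 0.0
            y = 0.0
        z = src_z

        # --- emission energy
        e = 0.0
        u = np.random.random()
        picked = False
        for i in range(line_cum.shape[0]):
            if u < line_cum[i]:
                e = line_e[i]
                picked = True
                break
        if not picked:
            uc = np.random.random() * (cont_icdf.shape[0] - 1)
            i0 = int(uc)
            if i0 >= cont_icdf.shape[0] - 1:
                i0 = cont_icdf.shape[0] - 2
            f = uc - i0
            e = cont_icdf[i0] * (1.0 - f) + cont_icdf[i0 + 1] * f
        e_birth = e

        # --- emission direction and statistical weight
        if pencil == 1:
            ux = 0.0
            uy = 0.0
            uz = 1.0
            w = 1.0
        else:
            us = np.random.random()
            if us < b1:
                mu = cos1 + (1.0 - cos1) * np.random.random()
            elif us < b1 + b2:
                mu = cos2 + (1.0 - cos2) * np.random.random()
            else:
                mu = 2.0 * np.random.random() - 1.0
            phi = 2.0 * np.pi * np.random.random()
            s = np.sqrt(max(0.0, 1.0 - mu * mu))
            ux = s * np.cos(phi)
            uy = s * np.sin(phi)
            uz = mu
            q = (1.0 - b1 - b2) / four_pi
            if mu > cos2:
                q += b2 / omega2
            if mu > cos1:
                q += b1 / omega1
            w = (1.0 / four_pi) / q

        flags = 0
        alive = True

        # --- phantom region (z < 0)
        n_slab = slab_z0.shape[0]
        for _step in range(400):
            if not alive:
                break
            if z >= -1e-9 and uz > 0.0:
                break  # reached the camera plane
            # locate current slab
            cur = -1
            for i in range(n_slab):
                if slab_z0[i] - 1e-9 <= z <= slab_z1[i] + 1e-9:
                    if abs(x) <= slab_hx and abs(y) <= slab_hy:
                        if slab_z0[i] <= z < slab_z1[i] or (
                            z == slab_z1[i] and uz < 0.0
                        ):
                            cur = i
                            break
            if cur >= 0:
                mat = slab_mat[cur]
                mu_tot = _mu_channels(mat, e, log_e, mu_tab, ch)
                s_int = -np.log(np.random.random()) / mu_tot
                t_exit = _box_exit(
                    x, y, z, ux, uy, uz, slab_hx, slab_hy, slab_z0[cur], slab_z1[cur]
                )
                if s_int < t_exit:
                    x += ux * s_int
                    y += uy * s_int
                    z += uz * s_int
                    # choose channel
                    uch = np.random.random() * mu_tot
                    if uch < ch[0]:
                        alive = False  # photoelectric
                    elif uch < ch[0] + ch[1]:
                        e_new, ct = sample_compton(e)
                        if _compton_accept(e, ct, mat_q0[mat]):
                            phi = 2.0 * np.pi * np.random.random()
                            ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
                            e = e_new
                            flags |= F_SCAT_PHANTOM
                            if e < e_cut:
                                alive = False
                    elif uch < ch[0] + ch[1] + ch[2]:
                        ct = sample_coherent(e, mat_fb[mat])
                        phi = 2.0 * np.pi * np.random.random()
                        ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
                        flags |= F_SCAT_PHANTOM
                    else:
                        alive = False  # pair: local absorption
                else:
                    x += ux * (t_exit + 1e-6)
                    y += uy * (t_exit + 1e-6)
                    z += uz * (t_exit + 1e-6)
            else:
                # vacuum: jump to nearest slab entry or the z=0 plane
                t_best = 1.0e30
                for i in range(n_slab):
                    t = _box_enter(
                        x, y, z, ux, uy, uz, slab_hx, slab_hy, slab_z0[i], slab_z1[i]
                    )
                    if 0.0 < t < t_best:
                        t_best = t
                t_plane = 1.0e30
                if uz > 1e-12 and z < 0.0:
                    t_plane = -z / uz
                if t_plane < t_best:
                    x += ux * t_plane
                    y += uy * t_plane
                    z = 0.0
                    break
                if t_best > 0.9e30:
                    alive = False
                    break
                x += ux * (t_best + 1e-6)
                y += uy * (t_best + 1e-6)
                z += uz * (t_best + 1e-6)
        if not alive or uz <= 0.0 or z < -1e-6:
            continue
        if abs(x) > det_hx or abs(y) > det_hy:
            continue

        # --- collimator (Woodcock tracking in the hex lattice)
        if has_coll == 1:
            offx = np.random.random() * pitch
            offy = np.random.random() * pitch * _SQRT3_2 * 2.0
            entry_x = x + offx
            entry_y = y + offy
            entry_z = z
            straight = True
            exited = False
            for _step in range(100000):
                mu_tot = _mu_channels(pb_id, e, log_e, mu_tab, ch)
                s = -np.log(np.random.random()) / mu_tot
                dz_left = coll_len - z
                if uz <= 1e-9:
                    alive = False
                    break
                t_plane = dz_left / uz
                if s >= t_plane:
                    x += ux * t_plane
                    y += uy * t_plane
                    z = coll_len
                    exited = True
                    break
                x += ux * s
                y += uy * s
                z += uz * s
                if abs(x) > det_hx or abs(y) > det_hy:
                    alive = False
                    break
                if not _in_hole(x + offx, y + offy, pitch, hole_flat):
                    # real interaction in lead
                    uch = np.random.random() * mu_tot
                    if uch < ch[0]:
                        if e > _PB_K_EDGE and np.random.random() < _PB_KXRAY_PROB:
                            e = _PB_KA_KEV
                            ct = 2.0 * np.random.random() - 1.0
                            phi = 2.0 * np.pi * np.random.random()
                            sn = np.sqrt(max(0.0, 1.0 - ct * ct))
                            ux = sn * np.cos(phi)
                            uy = sn * np.sin(phi)
                            uz = ct
                            flags |= F_LEAD_XRAY
                            straight = False
                            if uz <= 1e-9:
                                alive = False
                                break
                        else:
                            alive = False
                            break
                    elif uch < ch[0] + ch[1]:
                        e_new, ct = sample_compton(e)
                        if _compton_accept(e, ct, mat_q0[pb_id]):
                            phi = 2.0 * np.pi * np.random.random()
                            ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
                            e = e_new
                            if flags & F_LEAD_XRAY == 0:
                                flags |= F_PENETRATED
                            straight = False
                            if e < e_cut or uz <= 1e-9:
                                alive = False
                                break
                    elif uch < ch[0] + ch[1] + ch[2]:
                        ct = sample_coherent(e, mat_fb[pb_id])
                        phi = 2.0 * np.pi * np.random.random()
                        ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
                        if flags & F_LEAD_XRAY == 0:
                            flags |= F_PENETRATED
                        straight = False
                        if uz <= 1e-9:
                            alive = False
                            break
                    else:
                        alive = False  # pair in lead
                        break
            if not alive or not exited:
                continue
            if straight and (flags & F_LEAD_XRAY) == 0:
                # exact septal-contact test for the undisturbed chord
                if not _in_hole(entry_x, entry_y, pitch, hole_flat):
                    flags |= F_PENETRATED
                else:
                    t_hex = hex_exit_path(entry_x, entry_y, ux, uy, pitch, hole_flat)
                    if t_hex * uz < coll_len - entry_z - 1e-9:
                        flags |= F_PENETRATED
        else:
            z = 0.0

        # --- camera stack (Al window, air gap, NaI, crown glass)
        e_dep = 0.0
        cx_sum = 0.0
        cy_sum = 0.0
        n_cam = cam_z0.shape[0]
        for _step in range(200):
            if not alive:
                break
            cur = -1
            for i in range(n_cam):
                if cam_z0[i] - 1e-9 <= z <= cam_z1[i] + 1e-9:
                    if cam_z0[i] <= z < cam_z1[i] or (z == cam_z1[i] and uz < 0.0):
                        cur = i
                        break
            if cur < 0:
                # in a gap: advance to the next layer along the ray
                t_best = 1.0e30
                for i in range(n_cam):
                    t = _box_enter(
                        x, y, z, ux, uy, uz, det_hx, det_hy, cam_z0[i], cam_z1[i]
                    )
                    if 0.0 < t < t_best:
                        t_best = t
                if t_best > 0.9e30:
                    break  # escaped the camera
                x += ux * (t_best + 1e-6)
                y += uy * (t_best + 1e-6)
                z += uz * (t_best + 1e-6)
                if abs(x) > det_hx or abs(y) > det_hy:
                    break
                continue
            mat = cam_mat[cur]
            if mat == 0:
                t_exit = _box_exit(
                    x, y, z, ux, uy, uz, det_hx, det_hy, cam_z0[cur], cam_z1[cur]
                )
                x += ux * (t_exit + 1e-6)
                y += uy * (t_exit + 1e-6)
                z += uz * (t_exit + 1e-6)
                if z <= coll_len or abs(x) > det_hx or abs(y) > det_hy or z >= cam_top:
                    if z <= coll_len or z >= cam_top:
                        break
                    break
                continue
            mu_tot = _mu_channels(mat, e, log_e, mu_tab, ch)
            s_int = -np.log(np.random.random()) / mu_tot
            t_exit = _box_exit(
                x, y, z, ux, uy, uz, det_hx, det_hy, cam_z0[cur], cam_z1[cur]
            )
            if s_int >= t_exit:
                x += ux * (t_exit + 1e-6)
                y += uy * (t_exit + 1e-6)
                z += uz * (t_exit + 1e-6)
                if z < coll_len - 1e-6 or abs(x) > det_hx or abs(y) > det_hy:
                    break
                if z >= cam_top - 1e-6 and uz > 0.0:
                    break
                continue
            x += ux * s_int
            y += uy * s_int
            z += uz * s_int
            uch = np.random.random() * mu_tot
            if mat == nai_id:
                if uch < ch[0]:
                    e_dep += e
                    cx_sum += e * x
                    cy_sum += e * y
                    alive = False
                elif uch < ch[0] + ch[1]:
                    # Compton inside the crystal is part of the detection
                    # cascade, not camera scatter: the deposit centroid moves
                    # but the photon history stays 'primary' unless it was
                    # disturbed before reaching the crystal.
                    e_new, ct = sample_compton(e)
                    if _compton_accept(e, ct, mat_q0[mat]):
                        de = e - e_new
                        e_dep += de
                        cx_sum += de * x
                        cy_sum += de * y
                        phi = 2.0 * np.pi * np.random.random()
                        ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
                        e = e_new
                        if e < e_cut:
                            alive = False
                else:
                    # pair: e+/e- deposit E - 1022, annihilation photons escape
                    de = e - 2.0 * _MEC2
                    if de > 0:
                        e_dep += de
                        cx_sum += de * x
                        cy_sum += de * y
                    alive = False
            else:
                if uch < ch[0]:
                    alive = False
                elif uch < ch[0] + ch[1]:
                    e_new, ct = sample_compton(e)
                    if _compton_accept(e, ct, mat_q0[mat]):
                        phi = 2.0 * np.pi * np.random.random()
                        ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
                        e = e_new
                        flags |= F_SCAT_CAMERA
                        if e < e_cut:
                            alive = False
                elif uch < ch[0] + ch[1] + ch[2]:
                    ct = sample_coherent(e, mat_fb[mat])
                    phi = 2.0 * np.pi * np.random.random()
                    ux, uy, uz = _rotate(ux, uy, uz, ct, phi)
                    flags |= F_SCAT_CAMERA
                else:
                    alive = False

        if e_dep <= 1e-9:
            continue

        cx = cx_sum / e_dep
        cy = cy_sum / e_dep
        if intr_fwhm > 0.0:
            sig = intr_fwhm * np.sqrt(140.0 / e_dep) * _FWHM2SIG
            cx += sig * np.random.normal()
            cy += sig * np.random.normal()
        e_meas = e_dep
        if eres_frac > 0.0:
            sig_e = eres_frac * 140.0 * np.sqrt(e_dep / 140.0) * _FWHM2SIG
            e_meas = max(0.0, e_dep + sig_e * np.random.normal())

        out[n_det, 0] = w
        out[n_det, 1] = e_birth
        out[n_det, 2] = e_dep
        out[n_det, 3] = e_meas
        out[n_det, 4] = cx
        out[n_det, 5] = cy
        out_flags[n_det] = flags
        n_det += 1
        if n_det >= out.shape[0]:
            break
    return n_det
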