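"""Numba kernels for the particle reaction-diffusion simulation (nm / us units).

Glutamate molecules take Gaussian Brownian steps with a region-dependent
diffusion coefficient (cleft vs tortuous extracellular space) and reflect
specularly off every solid surface (terminal hemispheres, glial sheets,
world walls).  Transporters live on sheet faces, diffuse laterally, and bind
free glutamate entering a small interaction shell with a per-step
probability calibrated to mass action.  Unimolecular transitions use
per-step probabilities ``1 - exp(-k dt)``.

Glutamate states: 0 free, 1 bound to a ToG transporter, 2 translocated
(absorbed), 3 escaped (open world boundary only).
Transporter states: 0 To, 1 ToG, 2 TiG.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

GLU_FREE, GLU_BOUND, GLU_TRANSLOC, GLU_ESCAPED = 0, 1, 2, 3
T_TO, T_TOG, T_TIG = 0, 1, 2


@njit(cache=True)
def _wrap_angle(a):
    while a > math.pi:
        a -= 2.0 * math.pi
    while a < -math.pi:
        a += 2.0 * math.pi
    return a


@njit(cache=True)
def _in_cleft(x, y, z, centers, R, hc):
    if abs(z) >= hc:
        return False
    for k in range(centers.shape[0]):
        dx = x - centers[k, 0]
        dy = y - centers[k, 1]
        if dx * dx + dy * dy < R * R:
            return True
    return False


@njit(cache=True)
def _inside_any_solid(x, y, z, centers, R, hc,
                      sheet_syn, sheet_phi0, half_angle, r_in, r_out, hh):
    R2 = R * R
    for k in range(centers.shape[0]):
        dx = x - centers[k, 0]
        dy = y - centers[k, 1]
        r2 = dx * dx + dy * dy
        if z > hc:
            dz = z - hc
            if r2 + dz * dz < R2:
                return True
        elif z < -hc:
            dz = z + hc
            if r2 + dz * dz < R2:
                return True
    if abs(z) < hh:
        for s in range(sheet_syn.shape[0]):
            k = sheet_syn[s]
            dx = x - centers[k, 0]
            dy = y - centers[k, 1]
            rho = math.sqrt(dx * dx + dy * dy)
            if r_in < rho < r_out:
                dth = _wrap_angle(math.atan2(dy, dx) - sheet_phi0[s])
                if abs(dth) < half_angle:
                    return True
    return False


@njit(cache=True)
def _reflect(x, y, z, centers, R, hc,
             sheet_syn, sheet_phi0, half_angle, r_in, r_out, hh,
             world_half, reflective):
    """Resolve a proposed position against all surfaces; returns (x, y, z, ok)."""
    R2 = R * R
    for _ in range(12):
        moved = False
        if reflective:
            if x > world_half:
                x = 2.0 * world_half - x
                moved = True
            elif x < -world_half:
                x = -2.0 * world_half - x
                moved = True
            if y > world_half:
                y = 2.0 * world_half - y
                moved = True
            elif y < -world_half:
                y = -2.0 * world_half - y
                moved = True
            if z > world_half:
                z = 2.0 * world_half - z
                moved = True
            elif z < -world_half:
                z = -2.0 * world_half - z
                moved = True
        # terminal hemispheres (domes above/below the cleft slab)
        for k in range(centers.shape[0]):
            dx = x - centers[k, 0]
            dy = y - centers[k, 1]
            r2 = dx * dx + dy * dy
            if z > hc:
                dz = z - hc
            elif z < -hc:
                dz = z + hc
            else:
                continue
            d2 = r2 + dz * dz
            if d2 < R2:
                d = math.sqrt(d2)
                pen_sphere = R - d
                pen_plane = abs(z) - hc
                if pen_plane < pen_sphere:
                    z = (2.0 * hc - z) if z > 0.0 else (-2.0 * hc - z)
                else:
                    if d < 1e-9:
                        x = centers[k, 0] + R
                    else:
                        scale = (2.0 * R - d) / d
                        x = centers[k, 0] + dx * scale
                        y = centers[k, 1] + dy * scale
                        z = (hc + dz * scale) if z > 0.0 else (-hc + dz * scale)
                moved = True
        # glial sheets (cylindrical shell sections)
        if abs(z) < hh:
            for s in range(sheet_syn.shape[0]):
                k = sheet_syn[s]
                dx = x - centers[k, 0]
                dy = y - centers[k, 1]
                rho = math.sqrt(dx * dx + dy * dy)
                if rho <= r_in or rho >= r_out:
                    continue
                dth = _wrap_angle(math.atan2(dy, dx) - sheet_phi0[s])
                if abs(dth) >= half_angle:
                    continue
                pen_in = rho - r_in
                pen_out = r_out - rho
                pen_z = hh - abs(z)
                pen_th = (half_angle - abs(dth)) * rho
                m = min(min(pen_in, pen_out), min(pen_z, pen_th))
                if m == pen_in:
                    scale = (2.0 * r_in - rho) / rho
                    x = centers[k, 0] + dx * scale
                    y = centers[k, 1] + dy * scale
                elif m == pen_out:
                    scale = (2.0 * r_out - rho) / rho
                    x = centers[k, 0] + dx * scale
                    y = centers[k, 1] + dy * scale
                elif m == pen_z:
                    z = (2.0 * hh - z) if z > 0.0 else (-2.0 * hh - z)
                else:
                    edge = sheet_phi0[s] + (half_angle if dth > 0.0 else -half_angle)
                    th_new = 2.0 * edge - math.atan2(dy, dx)
                    x = centers[k, 0] + rho * math.cos(th_new)
                    y = centers[k, 1] + rho * math.sin(th_new)
                moved = True
        if not moved:
            return x, y, z, True
    return x, y, z, False


@njit(cache=True)
def _tr_position(s, face, theta, zz, centers, sheet_syn, sheet_phi0, r_in, r_out):
    k = sheet_syn[s]
    rho = r_in if face == 0 else r_out
    return (centers[k, 0] + rho * math.cos(theta),
            centers[k, 1] + rho * math.sin(theta), zz)


@njit(cache=True)
def simulate(seed, n_steps, sample_every, dt,
             glu_pos, glu_state,
             centers, R, hc,
             sheet_syn, sheet_phi0, half_angle, r_in, r_out, hh,
             tr_sheet, tr_face, tr_theta, tr_z, tr_state, tr_glu,
             D_cleft, D_out, D_T,
             p_bind, rho_int, p_unbind, p_transloc, p_reset,
             world_half, reflective,
             out_counts, out_tr, record_positions, out_pos):
    """Advance the full scene; fills per-sample count tables.

    out_counts columns: PSD, perisynaptic, extracellular, bound,
    translocated, escaped.  out_tr columns: To, ToG, TiG.
    """
    np.random.seed(seed)
    n = glu_pos.shape[0]
    m = tr_sheet.shape[0]
    sd_cleft = math.sqrt(2.0 * D_cleft * dt)
    sd_out = math.sqrt(2.0 * D_out * dt)
    sd_tr = math.sqrt(2.0 * D_T * dt)
    rho_int2 = rho_int * rho_int
    r_psd = R / 2.0

    # --- binding grid over (theta, z) per sheet, both faces together
    n_sheets = sheet_syn.shape[0]
    cell = max(2.0 * rho_int, 8.0)
    n_th = max(1, int(2.0 * half_angle * r_out / cell))
    n_z = max(1, int(2.0 * hh / cell))
    n_cells = n_sheets * n_th * n_z
    cell_count = np.zeros(n_cells + 1, dtype=np.int64)
    cell_start = np.zeros(n_cells + 1, dtype=np.int64)
    sorted_tr = np.zeros(m, dtype=np.int64)
    tr_cell = np.zeros(m, dtype=np.int64)

    sample_idx = 0

    for step in range(n_steps + 1):
        if step > 0:
            # 1. transporter unimolecular transitions
            for it in range(m):
                st = tr_state[it]
                if st == T_TOG:
                    u = np.random.random()
                    if u < p_unbind:
                        tr_state[it] = T_TO
                        ig = tr_glu[it]
                        tr_glu[it] = -1
                        x, y, zz = _tr_position(tr_sheet[it], tr_face[it],
                                                tr_theta[it], tr_z[it],
                                                centers, sheet_syn, sheet_phi0,
                                                r_in, r_out)
                        # re-release just off the reactive face
                        k = sheet_syn[tr_sheet[it]]
                        dx = x - centers[k, 0]
                        dy = y - centers[k, 1]
                        rho = math.sqrt(dx * dx + dy * dy)
                        off = (rho - rho_int - 1.0) / rho if tr_face[it] == 0 \
                            else (rho + rho_int + 1.0) / rho
                        glu_pos[ig, 0] = centers[k, 0] + dx * off
                        glu_pos[ig, 1] = centers[k, 1] + dy * off
                        glu_pos[ig, 2] = zz
                        glu_state[ig] = GLU_FREE
                    elif u < p_unbind + p_transloc:
                        tr_state[it] = T_TIG
                        glu_state[tr_glu[it]] = GLU_TRANSLOC
                        tr_glu[it] = -1
                elif st == T_TIG:
                    if np.random.random() < p_reset:
                        tr_state[it] = T_TO

            # 2. transporter lateral diffusion, confined to the sheet face
            if D_T > 0.0:
                for it in range(m):
                    rho = r_in if tr_face[it] == 0 else r_out
                    th = tr_theta[it] + np.random.normal() * sd_tr / rho
                    zz = tr_z[it] + np.random.normal() * sd_tr
                    phi0 = sheet_phi0[tr_sheet[it]]
                    lo = phi0 - half_angle
                    hi = phi0 + half_angle
                    if th > hi:
                        th = 2.0 * hi - th
                    elif th < lo:
                        th = 2.0 * lo - th
                    if zz > hh:
                        zz = 2.0 * hh - zz
                    elif zz < -hh:
                        zz = -2.0 * hh - zz
                    tr_theta[it] = th
                    tr_z[it] = zz

            # 3. glutamate Brownian step with reflection
            for ig in range(n):
                if glu_state[ig] != GLU_FREE:
                    continue
                x = glu_pos[ig, 0]
                y = glu_pos[ig, 1]
                z = glu_pos[ig, 2]
                sd = sd_cleft if _in_cleft(x, y, z, centers, R, hc) else sd_out
                nx = x + np.random.normal() * sd
                ny = y + np.random.normal() * sd
                nz = z + np.random.normal() * sd
                nx, ny, nz, ok = _reflect(nx, ny, nz, centers, R, hc,
                                          sheet_syn, sheet_phi0, half_angle,
                                          r_in, r_out, hh, world_half, reflective)
                if not ok or _inside_any_solid(nx, ny, nz, centers, R, hc,
                                               sheet_syn, sheet_phi0, half_angle,
                                               r_in, r_out, hh):
                    continue   # reject the move, keep the old position
                if not reflective and (abs(nx) > world_half or abs(ny) > world_half
                                       or abs(nz) > world_half):
                    glu_state[ig] = GLU_ESCAPED
                    continue
                glu_pos[ig, 0] = nx
                glu_pos[ig, 1] = ny
                glu_pos[ig, 2] = nz

            # 4. binding: rebuild transporter grid, then test free glu near sheets
            if m > 0 and p_bind > 0.0:
                for i in range(n_cells + 1):
                    cell_count[i] = 0
                for it in range(m):
                    s = tr_sheet[it]
                    dth = _wrap_angle(tr_theta[it] - sheet_phi0[s]) + half_angle
                    ith = int(dth / (2.0 * half_angle) * n_th)
                    if ith < 0:
                        ith = 0
                    elif ith >= n_th:
                        ith = n_th - 1
                    iz = int((tr_z[it] + hh) / (2.0 * hh) * n_z)
                    if iz < 0:
                        iz = 0
                    elif iz >= n_z:
                        iz = n_z - 1
                    c = (s * n_th + ith) * n_z + iz
                    tr_cell[it] = c
                    cell_count[c] += 1
                cell_start[0] = 0
                for c in range(n_cells):
                    cell_start[c + 1] = cell_start[c] + cell_count[c]
                    cell_count[c] = 0
                for it in range(m):
                    c = tr_cell[it]
                    sorted_tr[cell_start[c] + cell_count[c]] = it
                    cell_count[c] += 1

                for ig in range(n):
                    if glu_state[ig] != GLU_FREE:
                        continue
                    x = glu_pos[ig, 0]
                    y = glu_pos[ig, 1]
                    z = glu_pos[ig, 2]
                    if abs(z) > hh + rho_int:
                        continue
                    for s in range(n_sheets):
                        k = sheet_syn[s]
                        dx = x - centers[k, 0]
                        dy = y - centers[k, 1]
                        rho = math.sqrt(dx * dx + dy * dy)
                        if rho < r_in - rho_int or rho > r_out + rho_int:
                            continue
                        dth = _wrap_angle(math.atan2(dy, dx) - sheet_phi0[s])
                        if abs(dth) > half_angle + (rho_int + cell) / rho:
                            continue
                        ith0 = int((dth + half_angle) / (2.0 * half_angle) * n_th)
                        iz0 = int((z + hh) / (2.0 * hh) * n_z)
                        bound = False
                        for dith in range(-1, 2):
                            ith = ith0 + dith
                            if ith < 0 or ith >= n_th:
                                continue
                            for diz in range(-1, 2):
                                iz = iz0 + diz
                                if iz < 0 or iz >= n_z:
                                    continue
                                c = (s * n_th + ith) * n_z + iz
                                for q in range(cell_start[c], cell_start[c + 1]):
                                    it = sorted_tr[q]
                                    if tr_state[it] != T_TO:
                                        continue
                                    tx, ty, tz = _tr_position(
                                        tr_sheet[it], tr_face[it], tr_theta[it],
                                        tr_z[it], centers, sheet_syn, sheet_phi0,
                                        r_in, r_out)
                                    ddx = x - tx
                                    ddy = y - ty
                                    ddz = z - tz
                                    if ddx * ddx + ddy * ddy + ddz * ddz > rho_int2:
                                        continue
                                    if np.random.random() < p_bind:
                                        tr_state[it] = T_TOG
                                        tr_glu[it] = ig
                                        glu_state[ig] = GLU_BOUND
                                        bound = True
                                        break
                                if bound:
                                    break
                            if bound:
                                break
                        if bound:
                            break

        # 5. sampling
        if step % sample_every == 0:
            psd = 0
            peri = 0
            ecs = 0
            bound_n = 0
            transloc = 0
            escaped = 0
            for ig in range(n):
                st = glu_state[ig]
                if st == GLU_BOUND:
                    bound_n += 1
                elif st == GLU_TRANSLOC:
                    transloc += 1
                elif st == GLU_ESCAPED:
                    escaped += 1
                else:
                    x = glu_pos[ig, 0]
                    y = glu_pos[ig, 1]
                    z = glu_pos[ig, 2]
                    if abs(z) <= hc and x * x + y * y < R * R:
                        if x * x + y * y < r_psd * r_psd:
                            psd += 1
                        else:
                            peri += 1
                    else:
                        ecs += 1
            out_counts[sample_idx, 0] = psd
            out_counts[sample_idx, 1] = peri
            out_counts[sample_idx, 2] = ecs
            out_counts[sample_idx, 3] = bound_n
            out_counts[sample_idx, 4] = transloc
            out_counts[sample_idx, 5] = escaped
            n_to = 0
            n_tog = 0
            n_tig = 0
            for it in range(m):
                if tr_state[it] == T_TO:
                    n_to += 1
                elif tr_state[it] == T_TOG:
                    n_tog += 1
                else:
                    n_tig += 1
            out_tr[sample_idx, 0] = n_to
            out_tr[sample_idx, 1] = n_tog
            out_tr[sample_idx, 2] = n_tig
            if record_positions:
                for ig in range(n):
                    for d in range(3):
                        out_pos[sample_idx, ig, d] = glu_pos[ig, d]
            sample_idx += 1


@njit(cache=True)
def well_mixed(seed, n_steps, sample_every, dt, box_half,
               glu_pos, glu_state, tr_pos, tr_state, tr_glu,
               D, p_bind, rho_int, p_unbind, p_transloc, p_reset,
               out_counts, out_tr):
    """Closed empty box with volume-distributed static transporters.

    Validation geometry for the binding rule: occupancies must follow the
    3-state mass-action ODE when the box stays well mixed.  Full-sphere
    interaction shells (no walls near transporters).
    """
    np.random.seed(seed)
    n = glu_pos.shape[0]
    m = tr_pos.shape[0]
    sd = math.sqrt(2.0 * D * dt)
    rho_int2 = rho_int * rho_int

    cell = max(2.0 * rho_int, 10.0)
    n_side = max(1, int(2.0 * box_half / cell))
    n_cells = n_side ** 3
    cell_count = np.zeros(n_cells + 1, dtype=np.int64)
    cell_start = np.zeros(n_cells + 1, dtype=np.int64)
    sorted_tr = np.zeros(m, dtype=np.int64)
    tr_cell = np.zeros(m, dtype=np.int64)

    # static transporters: build the grid once
    for i in range(n_cells + 1):
        cell_count[i] = 0
    for it in range(m):
        c = 0
        for d in range(3):
            idx = int((tr_pos[it, d] + box_half) / (2.0 * box_half) * n_side)
            if idx < 0:
                idx = 0
            elif idx >= n_side:
                idx = n_side - 1
            c = c * n_side + idx
        tr_cell[it] = c
        cell_count[c] += 1
    cell_start[0] = 0
    for c in range(n_cells):
        cell_start[c + 1] = cell_start[c] + cell_count[c]
        cell_count[c] = 0
    for it in range(m):
        c = tr_cell[it]
        sorted_tr[cell_start[c] + cell_count[c]] = it
        cell_count[c] += 1

    sample_idx = 0
    for step in range(n_steps + 1):
        if step > 0:
            for it in range(m):
                st = tr_state[it]
                if st == T_TOG:
                    u = np.random.random()
                    if u < p_unbind:
                        tr_state[it] = T_TO
                        ig = tr_glu[it]
                        tr_glu[it] = -1
                        off = rho_int + 1.0
                        glu_pos[ig, 0] = min(max(tr_pos[it, 0] + off, -box_half), box_half)
                        glu_pos[ig, 1] = tr_pos[it, 1]
                        glu_pos[ig, 2] = tr_pos[it, 2]
                        glu_state[ig] = GLU_FREE
                    elif u < p_unbind + p_transloc:
                        tr_state[it] = T_TIG
                        glu_state[tr_glu[it]] = GLU_TRANSLOC
                        tr_glu[it] = -1
                elif st == T_TIG:
                    if np.random.random() < p_reset:
                        tr_state[it] = T_TO

            for ig in range(n):
                if glu_state[ig] != GLU_FREE:
                    continue
                for d in range(3):
                    v = glu_pos[ig, d] + np.random.normal() * sd
                    if v > box_half:
                        v = 2.0 * box_half - v
                    elif v < -box_half:
                        v = -2.0 * box_half - v
                    glu_pos[ig, d] = v

                x = glu_pos[ig, 0]
                y = glu_pos[ig, 1]
                z = glu_pos[ig, 2]
                ix = int((x + box_half) / (2.0 * box_half) * n_side)
                iy = int((y + box_half) / (2.0 * box_half) * n_side)
                iz = int((z + box_half) / (2.0 * box_half) * n_side)
                bound = False
                for di in range(-1, 2):
                    jx = ix + di
                    if jx < 0 or jx >= n_side:
                        continue
                    for dj in range(-1, 2):
                        jy = iy + dj
                        if jy < 0 or jy >= n_side:
                            continue
                        for dk in range(-1, 2):
                            jz = iz + dk
                            if jz < 0 or jz >= n_side:
                                continue
                            c = (jx * n_side + jy) * n_side + jz
                            for q in range(cell_start[c], cell_start[c + 1]):
                                it = sorted_tr[q]
                                if tr_state[it] != T_TO:
                                    continue
                                ddx = x - tr_pos[it, 0]
                                ddy = y - tr_pos[it, 1]
                                ddz = z - tr_pos[it, 2]
                                if ddx * ddx + ddy * ddy + ddz * ddz > rho_int2:
                                    continue
                                if np.random.random() < p_bind:
                                    tr_state[it] = T_TOG
                                    tr_glu[it] = ig
                                    glu_state[ig] = GLU_BOUND
                                    bound = True
                                    break
                            if bound:
                                break
                        if bound:
                            break
                    if bound:
                        break

        if step % sample_every == 0:
            free = 0
            bound_n = 0
            transloc = 0
            for ig in range(n):
                if glu_state[ig] == GLU_FREE:
                    free += 1
                elif glu_state[ig] == GLU_BOUND:
                    bound_n += 1
                elif glu_state[ig] == GLU_TRANSLOC:
                    transloc += 1
            out_counts[sample_idx, 0] = free
            out_counts[sample_idx, 1] = bound_n
            out_counts[sample_idx, 2] = transloc
            n_to = 0
            n_tog = 0
            n_tig = 0
            for it in range(m):
                if tr_state[it] == T_TO:
                    n_to += 1
                elif tr_state[it] == T_TOG:
                    n_tog += 1
                else:
                    n_tig += 1
            out_tr[sample_idx, 0] = n_to
            out_tr[sample_idx, 1] = n_tog
            out_tr[sample_idx, 2] = n_tig
            sample_idx += 1
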