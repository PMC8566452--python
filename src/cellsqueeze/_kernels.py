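"""Numba inner kernels.

Everything that runs once per time step over edges, triangles or lattice
sites lives here as an ``@njit`` function operating on plain arrays. The
public modules wrap these with validated, documented APIs.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# triangle / edge geometry
# ---------------------------------------------------------------------------


@njit(cache=False)
def triangle_geometry(pos, faces):
    """Per-triangle area, unit outward normal, centroid and t_a²+t_b²+t_c².

    Returns (areas, normals, centroids, tsq). Degenerate triangles get a
    zero normal and zero area; callers must check the area.
    """
    nf = faces.shape[0]
    areas = np.empty(nf)
    normals = np.zeros((nf, 3))
    centroids = np.empty((nf, 3))
    tsq = np.empty(nf)
    for t in range(nf):
        a, b, c = faces[t, 0], faces[t, 1], faces[t, 2]
        e1x = pos[b, 0] - pos[a, 0]
        e1y = pos[b, 1] - pos[a, 1]
        e1z = pos[b, 2] - pos[a, 2]
        e2x = pos[c, 0] - pos[a, 0]
        e2y = pos[c, 1] - pos[a, 1]
        e2z = pos[c, 2] - pos[a, 2]
        nx = e1y * e2z - e1z * e2y
        ny = e1z * e2x - e1x * e2z
        nz = e1x * e2y - e1y * e2x
        nn = np.sqrt(nx * nx + ny * ny + nz * nz)
        areas[t] = 0.5 * nn
        if nn > 0.0:
            normals[t, 0] = nx / nn
            normals[t, 1] = ny / nn
            normals[t, 2] = nz / nn
        cx = (pos[a, 0] + pos[b, 0] + pos[c, 0]) / 3.0
        cy = (pos[a, 1] + pos[b, 1] + pos[c, 1]) / 3.0
        cz = (pos[a, 2] + pos[b, 2] + pos[c, 2]) / 3.0
        centroids[t, 0] = cx
        centroids[t, 1] = cy
        centroids[t, 2] = cz
        s = 0.0
        for v in (a, b, c):
            dx = pos[v, 0] - cx
            dy = pos[v, 1] - cy
            dz = pos[v, 2] - cz
            s += dx * dx + dy * dy + dz * dz
        tsq[t] = s
    return areas, normals, centroids, tsq


@njit(cache=False)
def signed_volume(pos, faces):
    """Signed enclosed volume via the divergence theorem (tetrahedra to origin)."""
    vol = 0.0
    for t in range(faces.shape[0]):
        a, b, c = faces[t, 0], faces[t, 1], faces[t, 2]
        ax, ay, az = pos[a, 0], pos[a, 1], pos[a, 2]
        bx, by, bz = pos[b, 0], pos[b, 1], pos[b, 2]
        cx, cy, cz = pos[c, 0], pos[c, 1], pos[c, 2]
        vol += (
            ax * (by * cz - bz * cy)
            - ay * (bx * cz - bz * cx)
            + az * (bx * cy - by * cx)
        )
    return vol / 6.0


@njit(cache=False)
def edge_lengths(pos, edges):
    ne = edges.shape[0]
    out = np.empty(ne)
    for e in range(ne):
        a, b = edges[e, 0], edges[e, 1]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        out[e] = np.sqrt(dx * dx + dy * dy + dz * dz)
    return out


@njit(cache=False)
def dihedral_angles(pos, edges, edge_apex):
    """Dihedral angle per edge, measured between the two incident triangles.

    For edge (A, B) with apexes C1 (triangle containing the directed edge
    A→B in its winding) and C2, the angle is the interior angle between the
    triangle planes: π minus the signed angle between outward normals. A
    convex closed mesh gives angles in (0, π); reflex (concave) folds give
    angles in (π, 2π).
    """
    ne = edges.shape[0]
    theta = np.empty(ne)
    for e in range(ne):
        a, b = edges[e, 0], edges[e, 1]
        c1, c2 = edge_apex[e, 0], edge_apex[e, 1]
        ex = pos[b, 0] - pos[a, 0]
        ey = pos[b, 1] - pos[a, 1]
        ez = pos[b, 2] - pos[a, 2]
        # n1 from triangle (a, b, c1); n2 from triangle (b, a, c2)
        u1x = pos[c1, 0] - pos[a, 0]
        u1y = pos[c1, 1] - pos[a, 1]
        u1z = pos[c1, 2] - pos[a, 2]
        n1x = ey * u1z - ez * u1y
        n1y = ez * u1x - ex * u1z
        n1z = ex * u1y - ey * u1x
        u2x = pos[c2, 0] - pos[b, 0]
        u2y = pos[c2, 1] - pos[b, 1]
        u2z = pos[c2, 2] - pos[b, 2]
        n2x = -(ey * u2z - ez * u2y)
        n2y = -(ez * u2x - ex * u2z)
        n2z = -(ex * u2y - ey * u2x)
        cxx = n1y * n2z - n1z * n2y
        cxy = n1z * n2x - n1x * n2z
        cxz = n1x * n2y - n1y * n2x
        sin_num = cxx * ex + cxy * ey + cxz * ez
        en = np.sqrt(ex * ex + ey * ey + ez * ez)
        if en > 0.0:
            sin_num /= en
        cos_num = n1x * n2x + n1y * n2y + n1z * n2z
        phi = np.arctan2(sin_num, cos_num)
        theta[e] = np.pi - phi
    return theta


# ---------------------------------------------------------------------------
# membrane force laws
# ---------------------------------------------------------------------------


@njit(cache=False)
def stretch_forces(pos, edges, rest_len, k_s, out):
    """Neo-Hookean edge springs: F(A) = k_s κ(λ) (L−L0)/L0 p̂_AB, opposite on B."""
    for e in range(edges.shape[0]):
        a, b = edges[e, 0], edges[e, 1]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        L0 = rest_len[e]
        lam = L / L0
        kappa = (lam**0.5 + lam**-2.5) / (lam + lam**-3.0)
        mag = k_s * kappa * (L - L0) / L0
        fx = mag * dx / L
        fy = mag * dy / L
        fz = mag * dz / L
        out[a, 0] += fx
        out[a, 1] += fy
        out[a, 2] += fz
        out[b, 0] -= fx
        out[b, 1] -= fy
        out[b, 2] -= fz


@njit(cache=False)
def bending_forces(pos, edges, edge_apex, rest_theta, k_b, out):
    """Dihedral restoring loads.

    Per edge pair, a load of magnitude k_b (θ−θ0)/θ0 acts along each
    triangle's outward normal on its apex vertex (sign chosen to restore the
    rest angle) and −½ of the apex-load sum on each shared vertex, so the
    four-vertex group carries zero net force.
    """
    theta = dihedral_angles(pos, edges, edge_apex)
    for e in range(edges.shape[0]):
        a, b = edges[e, 0], edges[e, 1]
        c1, c2 = edge_apex[e, 0], edge_apex[e, 1]
        dev = (theta[e] - rest_theta[e]) / rest_theta[e]
        if dev == 0.0:
            continue
        ex = pos[b, 0] - pos[a, 0]
        ey = pos[b, 1] - pos[a, 1]
        ez = pos[b, 2] - pos[a, 2]
        u1x = pos[c1, 0] - pos[a, 0]
        u1y = pos[c1, 1] - pos[a, 1]
        u1z = pos[c1, 2] - pos[a, 2]
        n1x = ey * u1z - ez * u1y
        n1y = ez * u1x - ex * u1z
        n1z = ex * u1y - ey * u1x
        n1n = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
        u2x = pos[c2, 0] - pos[b, 0]
        u2y = pos[c2, 1] - pos[b, 1]
        u2z = pos[c2, 2] - pos[b, 2]
        n2x = -(ey * u2z - ez * u2y)
        n2y = -(ez * u2x - ex * u2z)
        n2z = -(ex * u2y - ey * u2x)
        n2n = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
        if n1n == 0.0 or n2n == 0.0:
            continue
        # moving the apexes outward (along outward normals) opens the fold
        # (θ → π), so a deficit θ < θ0 needs a +normal push: magnitude -dev.
        m = -k_b * dev
        f1x = m * n1x / n1n
        f1y = m * n1y / n1n
        f1z = m * n1z / n1n
        f2x = m * n2x / n2n
        f2y = m * n2y / n2n
        f2z = m * n2z / n2n
        out[c1, 0] += f1x
        out[c1, 1] += f1y
        out[c1, 2] += f1z
        out[c2, 0] += f2x
        out[c2, 1] += f2y
        out[c2, 2] += f2z
        sx = -0.5 * (f1x + f2x)
        sy = -0.5 * (f1y + f2y)
        sz = -0.5 * (f1z + f2z)
        out[a, 0] += sx
        out[a, 1] += sy
        out[a, 2] += sz
        out[b, 0] += sx
        out[b, 1] += sy
        out[b, 2] += sz


@njit(cache=False)
def area_volume_forces(
    pos, faces, rest_tri_area, rest_area, rest_volume, k_al, k_ag, k_V, out
):
    """Local-area, global-area and global-volume constraint forces.

    Local area pulls each vertex toward (away from) the triangle centroid
    when the triangle area exceeds (falls short of) rest; global area does
    the same weighted by the triangle area and the whole-cell area strain;
    the volume force acts along outward triangle normals.
    """
    areas, normals, centroids, tsq = triangle_geometry(pos, faces)
    S = areas.sum()
    V = signed_volume(pos, faces)
    ga = k_ag * (S - rest_area) / rest_area
    gv = k_V * (V - rest_volume) / rest_volume
    for t in range(faces.shape[0]):
        if tsq[t] == 0.0:
            continue
        dS = areas[t] - rest_tri_area[t]
        cl = -k_al * dS / tsq[t]
        cg = -ga * areas[t] / tsq[t]
        fvx = -gv * areas[t] * normals[t, 0]
        fvy = -gv * areas[t] * normals[t, 1]
        fvz = -gv * areas[t] * normals[t, 2]
        for k in range(3):
            v = faces[t, k]
            tx = pos[v, 0] - centroids[t, 0]
            ty = pos[v, 1] - centroids[t, 1]
            tz = pos[v, 2] - centroids[t, 2]
            out[v, 0] += (cl + cg) * tx + fvx
            out[v, 1] += (cl + cg) * ty + fvy
            out[v, 2] += (cl + cg) * tz + fvz


@njit(cache=False)
def viscous_forces(pos, vel, edges, k_visc, relative, out):
    """Edge dashpots: project nodal (or edge-relative) velocity on the edge.

    relative=True uses v_A − v_B with equal-and-opposite loads (Galilean
    invariant); relative=False is the literal per-node form.
    """
    for e in range(edges.shape[0]):
        a, b = edges[e, 0], edges[e, 1]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L == 0.0:
            continue
        px, py, pz = dx / L, dy / L, dz / L
        if relative:
            rvx = vel[a, 0] - vel[b, 0]
            rvy = vel[a, 1] - vel[b, 1]
            rvz = vel[a, 2] - vel[b, 2]
            proj = rvx * px + rvy * py + rvz * pz
            fx = -k_visc * proj * px
            fy = -k_visc * proj * py
            fz = -k_visc * proj * pz
            out[a, 0] += fx
            out[a, 1] += fy
            out[a, 2] += fz
            out[b, 0] -= fx
            out[b, 1] -= fy
            out[b, 2] -= fz
        else:
            pa = vel[a, 0] * px + vel[a, 1] * py + vel[a, 2] * pz
            out[a, 0] += -k_visc * pa * px
            out[a, 1] += -k_visc * pa * py
            out[a, 2] += -k_visc * pa * pz
            pb = vel[b, 0] * px + vel[b, 1] * py + vel[b, 2] * pz
            out[b, 0] += -k_visc * pb * px
            out[b, 1] += -k_visc * pb * py
            out[b, 2] += -k_visc * pb * pz


@njit(cache=False)
def pairwise_damping_impulses(pos, vel, edges, k_visc, mass, dt):
    """Apply the edge dashpots as pairwise-implicit impulse updates.

    For each edge the relative velocity component along the edge is relaxed
    by the exact implicit factor 1/(1 + k_visc dt (1/m_A + 1/m_B)), with
    equal-and-opposite impulses, so momentum is conserved exactly and the
    update is unconditionally stable for any k_visc. Edges are processed in
    storage order (Gauss–Seidel); the result is deterministic.
    """
    for e in range(edges.shape[0]):
        a, b = edges[e, 0], edges[e, 1]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        dz = pos[b, 2] - pos[a, 2]
        L = np.sqrt(dx * dx + dy * dy + dz * dz)
        if L == 0.0:
            continue
        px, py, pz = dx / L, dy / L, dz / L
        rvx = vel[a, 0] - vel[b, 0]
        rvy = vel[a, 1] - vel[b, 1]
        rvz = vel[a, 2] - vel[b, 2]
        proj = rvx * px + rvy * py + rvz * pz
        w = 1.0 / mass[a] + 1.0 / mass[b]
        # impulse J along p̂ such that the post-update relative projection is
        # proj / (1 + k_visc dt w)
        J = k_visc * dt * proj / (1.0 + k_visc * dt * w)
        vel[a, 0] -= J * px / mass[a]
        vel[a, 1] -= J * py / mass[a]
        vel[a, 2] -= J * pz / mass[a]
        vel[b, 0] += J * px / mass[b]
        vel[b, 1] += J * py / mass[b]
        vel[b, 2] += J * pz / mass[b]


# ---------------------------------------------------------------------------
# channel wall distance
# ---------------------------------------------------------------------------


@njit(cache=False)
def wall_distance(x, y, z, seg, depth):
    """Distance and outward (wall→fluid) unit normal for a channel point.

    ``seg`` is an (n, 4) array of (x0, y0, x1, y1) segments describing the
    +y half-width polyline of the channel in the x–y plane; the −y wall is
    its mirror image and the floor/ceiling are the planes z = 0 and
    z = depth. Patch order (side segments first, then floor, then ceiling)
    breaks exact ties deterministically. A point beyond the side polyline or
    the z planes reports a negative distance (penetration).
    """
    ya = abs(y)
    best = 1e300
    bmx = 0.0
    bmy = 0.0
    bmz = 0.0
    # side-wall polyline (work on |y|, restore sign afterwards)
    for s in range(seg.shape[0]):
        x0, y0, x1, y1 = seg[s, 0], seg[s, 1], seg[s, 2], seg[s, 3]
        vx = x1 - x0
        vy = y1 - y0
        vv = vx * vx + vy * vy
        if vv == 0.0:
            continue
        t = ((x - x0) * vx + (ya - y0) * vy) / vv
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        fx = x0 + t * vx
        fy = y0 + t * vy
        ddx = x - fx
        ddy = ya - fy
        d = np.sqrt(ddx * ddx + ddy * ddy)
        if d < best:
            best = d
            if d > 0.0:
                bmx = ddx / d
                bmy = ddy / d
            else:
                bmx = 0.0
                bmy = -1.0
            bmz = 0.0
    # sign: solid if |y| exceeds the local half-width
    hw = 1e300
    for s in range(seg.shape[0]):
        x0, y0, x1, y1 = seg[s, 0], seg[s, 1], seg[s, 2], seg[s, 3]
        if x1 - x0 == 0.0:
            continue
        if x >= min(x0, x1) and x <= max(x0, x1):
            t = (x - x0) / (x1 - x0)
            h = y0 + t * (y1 - y0)
            if h < hw:
                hw = h
        # also handle points outside the polyline x-range: clamp
    if hw == 1e300:
        hw = seg[0, 1]
    side_sign = 1.0 if ya <= hw else -1.0
    best *= side_sign
    if side_sign < 0.0:
        bmx = -bmx
        bmy = -bmy
    if y < 0.0:
        bmy = -bmy
    # floor z = 0
    if z < best:
        best = z
        bmx, bmy, bmz = 0.0, 0.0, 1.0
    # ceiling z = depth
    if depth - z < best:
        best = depth - z
        bmx, bmy, bmz = 0.0, 0.0, -1.0
    return best, bmx, bmy, bmz


@njit(cache=False)
def wall_forces(pos, vel, seg, depth, a_rep, n_exp, d_cut, mu_f, d_min, eps_v, out):
    """Accumulate wall repulsion and sliding friction; return penetration count.

    Repulsion: a n / d^(n+1) along the wall normal for d < d_cut (d clamped
    at d_min when penetrating). Friction: μ_f times the repulsive magnitude,
    opposing the full nodal velocity, dead-banded below eps_v.
    """
    npen = 0
    for j in range(pos.shape[0]):
        d, mx, my, mz = wall_distance(pos[j, 0], pos[j, 1], pos[j, 2], seg, depth)
        if d <= 0.0:
            npen += 1
            d = d_min
        if d >= d_cut:
            continue
        mag = a_rep * n_exp / d ** (n_exp + 1.0)
        out[j, 0] += mag * mx
        out[j, 1] += mag * my
        out[j, 2] += mag * mz
        if mu_f > 0.0:
            vx, vy, vz = vel[j, 0], vel[j, 1], vel[j, 2]
            vn = np.sqrt(vx * vx + vy * vy + vz * vz)
            if vn > eps_v:
                fmag = mu_f * mag
                out[j, 0] -= fmag * vx / vn
                out[j, 1] -= fmag * vy / vn
                out[j, 2] -= fmag * vz / vn
    return npen


@njit(cache=False)
def friction_impulses(pos, vel, seg, depth, a_rep, n_exp, d_cut, mu_f, d_min, eps_v, mass, dt):
    """Kinetic wall friction applied as a velocity-clipped impulse.

    The impulse magnitude is min(μ_f F_rep dt, m |v|): friction can stop a
    node within a step but never reverse its velocity, which keeps the
    near-wall dynamics stable at desk-scale time steps.
    """
    for j in range(pos.shape[0]):
        d, mx, my, mz = wall_distance(pos[j, 0], pos[j, 1], pos[j, 2], seg, depth)
        if d <= 0.0:
            d = d_min
        if d >= d_cut:
            continue
        vx, vy, vz = vel[j, 0], vel[j, 1], vel[j, 2]
        vn = np.sqrt(vx * vx + vy * vy + vz * vz)
        if vn <= eps_v:
            continue
        mag = mu_f * a_rep * n_exp / d ** (n_exp + 1.0)
        J = mag * dt
        if J > mass[j] * vn:
            J = mass[j] * vn
        vel[j, 0] -= J * vx / (vn * mass[j])
        vel[j, 1] -= J * vy / (vn * mass[j])
        vel[j, 2] -= J * vz / (vn * mass[j])


# ---------------------------------------------------------------------------
# D3Q19 lattice Boltzmann
# ---------------------------------------------------------------------------


@njit(cache=False)
def lbm_collide_stream(f, fpost, fnew, solid, tau, force, EX, EY, EZ, W, OPP):
    """One BGK step with Guo forcing and half-way bounce-back, periodic box.

    ``force`` is the lattice body-force density field (3, nx, ny, nz).
    Populations at solid sites are untouched. Works in lattice units
    (δx = δt = 1, c_s² = 1/3).
    """
    nq, nx, ny, nz = f.shape
    pref = 1.0 - 0.5 / tau
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if solid[ix, iy, iz]:
                    for i in range(nq):
                        fpost[i, ix, iy, iz] = f[i, ix, iy, iz]
                    continue
                rho = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(nq):
                    fi = f[i, ix, iy, iz]
                    rho += fi
                    mx += fi * EX[i]
                    my += fi * EY[i]
                    mz += fi * EZ[i]
                Fx = force[0, ix, iy, iz]
                Fy = force[1, ix, iy, iz]
                Fz = force[2, ix, iy, iz]
                ux = (mx + 0.5 * Fx) / rho
                uy = (my + 0.5 * Fy) / rho
                uz = (mz + 0.5 * Fz) / rho
                usq = ux * ux + uy * uy + uz * uz
                for i in range(nq):
                    eu = EX[i] * ux + EY[i] * uy + EZ[i] * uz
                    feq = (
                        W[i]
                        * rho
                        * (1.0 + 3.0 * eu + 4.5 * eu * eu - 1.5 * usq)
                    )
                    # Guo forcing source term
                    gx = 3.0 * (EX[i] - ux) + 9.0 * eu * EX[i]
                    gy = 3.0 * (EY[i] - uy) + 9.0 * eu * EY[i]
                    gz = 3.0 * (EZ[i] - uz) + 9.0 * eu * EZ[i]
                    Si = pref * W[i] * (gx * Fx + gy * Fy + gz * Fz)
                    fpost[i, ix, iy, iz] = (
                        f[i, ix, iy, iz]
                        - (f[i, ix, iy, iz] - feq) / tau
                        + Si
                    )
    # streaming (pull) with half-way bounce-back
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if solid[ix, iy, iz]:
                    for i in range(nq):
                        fnew[i, ix, iy, iz] = fpost[i, ix, iy, iz]
                    continue
                for i in range(nq):
                    sx = (ix - int(EX[i])) % nx
                    sy = (iy - int(EY[i])) % ny
                    sz = (iz - int(EZ[i])) % nz
                    if solid[sx, sy, sz]:
                        fnew[i, ix, iy, iz] = fpost[OPP[i], ix, iy, iz]
                    else:
                        fnew[i, ix, iy, iz] = fpost[i, sx, sy, sz]


@njit(cache=False)
def lbm_moments(f, solid, force, EX, EY, EZ):
    """Density and velocity fields (with the Guo half-force correction)."""
    nq, nx, ny, nz = f.shape
    rho = np.zeros((nx, ny, nz))
    u = np.zeros((3, nx, ny, nz))
    for ix in range(nx):
        for iy in range(ny):
            for iz in range(nz):
                if solid[ix, iy, iz]:
                    rho[ix, iy, iz] = 0.0
                    continue
                r = 0.0
                mx = 0.0
                my = 0.0
                mz = 0.0
                for i in range(nq):
                    fi = f[i, ix, iy, iz]
                    r += fi
                    mx += fi * EX[i]
                    my += fi * EY[i]
                    mz += fi * EZ[i]
                rho[ix, iy, iz] = r
                u[0, ix, iy, iz] = (mx + 0.5 * force[0, ix, iy, iz]) / r
                u[1, ix, iy, iz] = (my + 0.5 * force[1, ix, iy, iz]) / r
                u[2, ix, iy, iz] = (mz + 0.5 * force[2, ix, iy, iz]) / r
    return rho, u


@njit(cache=False)
def interpolate_velocity_kernel(u, solid, px, py, pz, out):
    """Trilinear interpolation of the velocity field at physical-lattice
    coordinates (site centers at integer coordinates). Solid stencil sites
    contribute zero velocity (no-slip wall). Periodic in x, clamped in y, z.
    Returns the number of queries whose *nearest* site was solid."""
    nx, ny, nz = solid.shape
    nsolid = 0
    for j in range(px.shape[0]):
        x = px[j] % nx
        y = min(max(py[j], 0.0), ny - 1.0)
        z = min(max(pz[j], 0.0), nz - 1.0)
        i0 = int(np.floor(x))
        j0 = int(np.floor(y))
        k0 = int(np.floor(z))
        fx = x - i0
        fy = y - j0
        fz = z - k0
        i1 = (i0 + 1) % nx
        j1 = min(j0 + 1, ny - 1)
        k1 = min(k0 + 1, nz - 1)
        ux = 0.0
        uy = 0.0
        uz = 0.0
        for a in range(2):
            ii = i0 if a == 0 else i1
            wa = 1.0 - fx if a == 0 else fx
            for b in range(2):
                jj = j0 if b == 0 else j1
                wb = 1.0 - fy if b == 0 else fy
                for c in range(2):
                    kk = k0 if c == 0 else k1
                    wc = 1.0 - fz if c == 0 else fz
                    w = wa * wb * wc
                    if not solid[ii, jj, kk]:
                        ux += w * u[0, ii, jj, kk]
                        uy += w * u[1, ii, jj, kk]
                        uz += w * u[2, ii, jj, kk]
        ni = int(np.floor(x + 0.5)) % nx
        nj = min(int(np.floor(y + 0.5)), ny - 1)
        nk = min(int(np.floor(z + 0.5)), nz - 1)
        if solid[ni, nj, nk]:
            nsolid += 1
        out[j, 0] = ux
        out[j, 1] = uy
        out[j, 2] = uz
    return nsolid


@njit(cache=False)
def deposit_forces_kernel(force, solid, px, py, pz, fx, fy, fz):
    """Spread per-node forces onto the lattice force field with the same
    trilinear stencil used for interpolation (adjoint-consistent)."""
    nx, ny, nz = solid.shape
    for j in range(px.shape[0]):
        x = px[j] % nx
        y = min(max(py[j], 0.0), ny - 1.0)
        z = min(max(pz[j], 0.0), nz - 1.0)
        i0 = int(np.floor(x))
        j0 = int(np.floor(y))
        k0 = int(np.floor(z))
        gx = x - i0
        gy = y - j0
        gz = z - k0
        i1 = (i0 + 1) % nx
        j1 = min(j0 + 1, ny - 1)
        k1 = min(k0 + 1, nz - 1)
        for a in range(2):
            ii = i0 if a == 0 else i1
            wa = 1.0 - gx if a == 0 else gx
            for b in range(2):
                jj = j0 if b == 0 else j1
                wb = 1.0 - gy if b == 0 else gy
                for c in range(2):
                    kk = k0 if c == 0 else k1
                    wc = 1.0 - gz if c == 0 else gz
                    w = wa * wb * wc
                    if not solid[ii, jj, kk]:
                        force[0, ii, jj, kk] += w * fx[j]
                        force[1, ii, jj, kk] += w * fy[j]
                        force[2, ii, jj, kk] += w * fz[j]


# ---------------------------------------------------------------------------
# fused passage inner loop
# ---------------------------------------------------------------------------


@njit(cache=False)
def elastic_and_wall_forces(
    pos, vel, edges, edge_apex, faces, L0, theta0, S0_tri, S0, V0,
    ks, kb, kal, kag, kV, seg, depth, a_rep, n_exp, d_cut, d_min, eps_v, out,
):
    out[:, :] = 0.0
    stretch_forces(pos, edges, L0, ks, out)
    bending_forces(pos, edges, edge_apex, theta0, kb, out)
    area_volume_forces(pos, faces, S0_tri, S0, V0, kal, kag, kV, out)
    return wall_forces(
        pos, vel, seg, depth, a_rep, n_exp, d_cut, 0.0, d_min, eps_v, out
    )


@njit(cache=False)
def membrane_substeps(
    pos, vel, mass, f_prev, n_sub, dt,
    edges, edge_apex, faces, L0, theta0, S0_tri, S0, V0,
    ks, kb, kal, kag, kV, kvisc,
    seg, depth, a_rep, n_exp, d_cut, mu_f, d_min, eps_v,
    u_field, solid, ox, oy, oz, dx, vel_scale, xi, imp_grid,
):
    """``n_sub`` velocity-Verlet membrane steps between two fluid steps.

    The fluid field ``u_field`` (lattice units; ``vel_scale`` converts to
    µm/µs) is frozen during the substeps. Drag impulses are accumulated
    (negated) onto ``imp_grid`` in physical units for later conversion
    into the lattice body-force deposit. Returns the number of
    wall-penetration events seen.
    """
    n = pos.shape[0]
    npen = 0
    u_node = np.empty((n, 3))
    px = np.empty(n)
    py = np.empty(n)
    pz = np.empty(n)
    for _ in range(n_sub):
        # velocity Verlet, position forces
        for j in range(n):
            h = 0.5 * dt / mass[j]
            vel[j, 0] += h * f_prev[j, 0]
            vel[j, 1] += h * f_prev[j, 1]
            vel[j, 2] += h * f_prev[j, 2]
            pos[j, 0] += dt * vel[j, 0]
            pos[j, 1] += dt * vel[j, 1]
            pos[j, 2] += dt * vel[j, 2]
        npen += elastic_and_wall_forces(
            pos, vel, edges, edge_apex, faces, L0, theta0, S0_tri, S0, V0,
            ks, kb, kal, kag, kV, seg, depth, a_rep, n_exp, d_cut, d_min,
            eps_v, f_prev,
        )
        for j in range(n):
            h = 0.5 * dt / mass[j]
            vel[j, 0] += h * f_prev[j, 0]
            vel[j, 1] += h * f_prev[j, 1]
            vel[j, 2] += h * f_prev[j, 2]
        # impulse updates
        if kvisc > 0.0:
            pairwise_damping_impulses(pos, vel, edges, kvisc, mass, dt)
        if mu_f > 0.0:
            friction_impulses(
                pos, vel, seg, depth, a_rep, n_exp, d_cut, mu_f, d_min,
                eps_v, mass, dt,
            )
        # drag toward interpolated fluid velocity (exact relaxation)
        for j in range(n):
            px[j] = (pos[j, 0] - ox) / dx
            py[j] = (pos[j, 1] - oy) / dx
            pz[j] = (pos[j, 2] - oz) / dx
        interpolate_velocity_kernel(u_field, solid, px, py, pz, u_node)
        for j in range(n):
            alpha = 1.0 - np.exp(-xi * dt / mass[j])
            jx = mass[j] * alpha * (u_node[j, 0] * vel_scale - vel[j, 0])
            jy = mass[j] * alpha * (u_node[j, 1] * vel_scale - vel[j, 1])
            jz = mass[j] * alpha * (u_node[j, 2] * vel_scale - vel[j, 2])
            vel[j, 0] += jx / mass[j]
            vel[j, 1] += jy / mass[j]
            vel[j, 2] += jz / mass[j]
            u_node[j, 0] = -jx
            u_node[j, 1] = -jy
            u_node[j, 2] = -jz
        deposit_forces_kernel(
            imp_grid, solid, px, py, pz,
            u_node[:, 0].copy(), u_node[:, 1].copy(), u_node[:, 2].copy(),
        )
    return npen
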