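"""Numba kernels for photon transport through a voxel grid.

Delta (Woodcock) tracking with a per-energy global majorant: photons take
exponential free paths against the majorant attenuation and accept real
interactions with probability mu_voxel/mu_majorant, which is unbiased in
heterogeneous voxel media without per-voxel boundary crossings. Interactions
are photoelectric absorption (local deposition) and incoherent scattering
with the Klein-Nishina free-electron law; the energy transferred to the
electron is deposited locally (kerma approximation). Photons are terminated
below 10 keV with the residual energy deposited locally. Coherent
(Rayleigh) scattering is excluded from the transported cross section.

Energies are handled on 1 keV bins from 10 to 150 keV; the bin index of a
photon of energy E keV is floor(E) - 10.
"""
import numpy as np
from numba import njit

E_MIN_KEV = 10.0
E_MAX_KEV = 150.0
N_EBINS = 141  # 10..150 inclusive
KEV_PER_G_TO_MGY = 1.602176634e-10


@njit(cache=True, inline="always")
def _ebin(e):
    i = int(e - 10.0)
    if i < 0:
        i = 0
    elif i > N_EBINS - 1:
        i = N_EBINS - 1
    return i


@njit(cache=True)
def _sample_kn_cos(k):
    """Kahn's rejection method for the Klein-Nishina scattering angle.

    k is the photon energy in electron rest-mass units; returns cos(theta).
    """
    while True:
        r1 = np.random.random()
        r2 = np.random.random()
        r3 = np.random.random()
        if r1 <= (2.0 * k + 1.0) / (2.0 * k + 9.0):
            x = 1.0 + 2.0 * k * r2  # x = E/E'
            if r3 <= 4.0 * (1.0 / x - 1.0 / (x * x)):
                return 1.0 - (x - 1.0) / k
        else:
            x = (2.0 * k + 1.0) / (2.0 * k * r2 + 1.0)
            c = 1.0 - (x - 1.0) / k
            if r3 <= 0.5 * (c * c + 1.0 / x):
                return c


@njit(cache=True)
def sample_kn_cosines(energy_kev, n, seed):
    """Sample n Klein-Nishina scattering cosines at one energy (for tests)."""
    np.random.seed(seed)
    k = energy_kev / 511.0
    out = np.empty(n)
    for i in range(n):
        out[i] = _sample_kn_cos(k)
    return out


@njit(cache=True, inline="always")
def _rotate(dx, dy, dz, cos_t, phi):
    """Rotate unit vector (dx,dy,dz) by polar angle acos(cos_t), azimuth phi."""
    sin_t = np.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cp = np.cos(phi)
    sp = np.sin(phi)
    # build an orthonormal basis around the direction
    if abs(dz) < 0.99999:
        ux = -dy
        uy = dx
        uz = 0.0
    else:
        ux = 1.0
        uy = 0.0
        uz = 0.0
    norm = np.sqrt(ux * ux + uy * uy + uz * uz)
    ux /= norm
    uy /= norm
    uz /= norm
    vx = dy * uz - dz * uy
    vy = dz * ux - dx * uz
    vz = dx * uy - dy * ux
    nx = cos_t * dx + sin_t * (cp * ux + sp * vx)
    ny = cos_t * dy + sin_t * (cp * uy + sp * vy)
    nz = cos_t * dz + sin_t * (cp * uz + sp * vz)
    norm = np.sqrt(nx * nx + ny * ny + nz * nz)
    return nx / norm, ny / norm, nz / norm


@njit(cache=True)
def run_transport(seed, n_photons,
                  density, material,
                  dz, dy, dx,
                  axis_x, axis_y, theta_t, src_z, t_cdf, randomize_phase,
                  gamma_max, coll_half_mm, sid_mm,
                  spec_e, spec_cdf,
                  bowtie_trans,
                  mu_pe, mu_in, majorant,
                  scatter_on,
                  edep):
    """Transport n_photons; tally weighted deposited energy (keV) into edep.

    Returns (emitted_weighted_kev, deposited_kev): total post-bowtie
    expected emitted energy and total deposited energy.
    """
    np.random.seed(seed)
    nz, ny, nx = density.shape
    lx = nx * dx
    ly = ny * dy
    lz = nz * dz
    n_gamma = bowtie_trans.shape[0]
    emitted = 0.0
    deposited = 0.0

    for _ in range(n_photons):
        # --- emission time / source position
        r = np.random.random()
        it = np.searchsorted(t_cdf, r)
        if it >= len(t_cdf):
            it = len(t_cdf) - 1
        theta = theta_t[it]
        if randomize_phase:
            # arbitrary gantry start phase: ensemble average over scans
            theta += 2.0 * np.pi * np.random.random()
        sx = axis_x + sid_mm * np.sin(theta)
        sy = axis_y - sid_mm * np.cos(theta)
        sz = src_z[it]
        cux = (axis_x - sx) / sid_mm
        cuy = (axis_y - sy) / sid_mm

        # --- energy
        r = np.random.random()
        ie_s = np.searchsorted(spec_cdf, r)
        if ie_s >= len(spec_e):
            ie_s = len(spec_e) - 1
        e = spec_e[ie_s]
        ie = _ebin(e)

        # --- direction: fan angle + cone slope
        gamma = (2.0 * np.random.random() - 1.0) * gamma_max
        zeta = (2.0 * np.random.random() - 1.0) * coll_half_mm
        cg = np.cos(gamma)
        sg = np.sin(gamma)
        dxy_x = cux * cg - cuy * sg
        dxy_y = cux * sg + cuy * cg
        slope = zeta / sid_mm
        norm = np.sqrt(1.0 + slope * slope)
        dirx = dxy_x / norm
        diry = dxy_y / norm
        dirz = slope / norm

        # --- bowtie survival weight
        g = abs(gamma) / gamma_max * (n_gamma - 1)
        gi = int(g)
        if gi >= n_gamma - 1:
            w = bowtie_trans[n_gamma - 1, ie]
        else:
            f = g - gi
            w = bowtie_trans[gi, ie] * (1.0 - f) + bowtie_trans[gi + 1, ie] * f
        emitted += w * e

        # --- advance to the grid bounding box
        tmin = 0.0
        tmax = 1.0e30
        ok = True
        for axis in range(3):
            if axis == 0:
                p = sx
                d = dirx
                hi = lx
            elif axis == 1:
                p = sy
                d = diry
                hi = ly
            else:
                p = sz
                d = dirz
                hi = lz
            if abs(d) < 1.0e-12:
                if p < 0.0 or p > hi:
                    ok = False
                    break
            else:
                t1 = (0.0 - p) / d
                t2 = (hi - p) / d
                if t1 > t2:
                    t1, t2 = t2, t1
                if t1 > tmin:
                    tmin = t1
                if t2 < tmax:
                    tmax = t2
        if (not ok) or tmax <= tmin:
            continue
        px = sx + (tmin + 1.0e-9) * dirx
        py = sy + (tmin + 1.0e-9) * diry
        pz = sz + (tmin + 1.0e-9) * dirz

        # --- Woodcock tracking
        alive = True
        while alive:
            maj = majorant[ie]
            if maj <= 1.0e-12:
                break
            s = -np.log(np.random.random()) / maj
            px += s * dirx
            py += s * diry
            pz += s * dirz
            if px < 0.0 or px >= lx or py < 0.0 or py >= ly \
                    or pz < 0.0 or pz >= lz:
                break  # escaped (grid box is convex)
            iix = int(px / dx)
            iiy = int(py / dy)
            iiz = int(pz / dz)
            m = material[iiz, iiy, iix]
            rho = density[iiz, iiy, iix]
            mpe = mu_pe[m, ie] * rho * 0.1  # cm^2/g * g/cm^3 -> 1/cm -> 1/mm
            min_ = mu_in[m, ie] * rho * 0.1
            mu = mpe + min_
            if np.random.random() * maj >= mu:
                continue  # virtual collision
            # real interaction
            if np.random.random() * mu < mpe:
                edep[iiz, iiy, iix] += w * e
                deposited += w * e
                alive = False
            else:
                k = e / 511.0
                cos_t = _sample_kn_cos(k)
                e_new = e / (1.0 + k * (1.0 - cos_t))
                edep[iiz, iiy, iix] += w * (e - e_new)
                deposited += w * (e - e_new)
                if (not scatter_on):
                    alive = False  # scattered photon abandoned (escapes)
                elif e_new < E_MIN_KEV:
                    edep[iiz, iiy, iix] += w * e_new
                    deposited += w * e_new
                    alive = False
                else:
                    phi = 2.0 * np.pi * np.random.random()
                    dirx, diry, dirz = _rotate(dirx, diry, dirz, cos_t, phi)
                    e = e_new
                    ie = _ebin(e)
    return emitted, deposited
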