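"""Numba kernels for overdamped (Brownian) bead-spring dynamics.

All lengths are in monomer diameters, energies in kT, times in units of
``friction * d^2 / kT``.  The pair repulsion is soft-core with a bounded
overlap energy, ``E(r) = eps * (1 - (r/sigma)^2)^2`` for ``r < sigma``, so the
chain can cross itself (no topological locking).

Numerical choices: Euler-Maruyama updates with uniform random increments of
matched variance (weak order-1 convergence needs only the first two moments of
the noise, and uniform draws are several times cheaper than Gaussians); pair
repulsion through a Verlet neighbour list with a 1-diameter skin, rebuilt
every ``REBUILD_EVERY`` steps by a full O(n^2) sweep.
"""

import numpy as np
from numba import njit

REBUILD_EVERY = 10
SKIN = 1.0


@njit(cache=True, fastmath=True)
def brownian_dynamics(
    x,
    bonds,
    bond_k,
    bond_r0,
    rep_eps,
    rep_sigma,
    conf_radius,
    conf_k,
    kT,
    friction,
    dt,
    n_steps,
    seed,
):
    """Integrate ``n_steps`` of overdamped Langevin dynamics in place.

    Returns -1 on success, or the (0-based) step index at which a non-finite
    coordinate was first detected.
    """
    np.random.seed(seed)
    n = x.shape[0]
    nb = bonds.shape[0]
    mob = dt / friction
    # uniform increment on [-a, a] with variance 2 kT dt / friction
    a = np.sqrt(6.0 * kT * dt / friction)

    use_rep = rep_eps > 0.0
    sig2 = rep_sigma * rep_sigma
    cut2 = (rep_sigma + SKIN) * (rep_sigma + SKIN)
    cap = n * (n - 1) // 2
    pi = np.empty(cap, dtype=np.int32)
    pj = np.empty(cap, dtype=np.int32)
    npairs = 0

    f = np.zeros((n, 3))
    for step in range(n_steps):
        for i in range(n):
            f[i, 0] = 0.0
            f[i, 1] = 0.0
            f[i, 2] = 0.0
        # harmonic bonds (backbone + loops)
        for b in range(nb):
            i = bonds[b, 0]
            j = bonds[b, 1]
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dz = x[j, 2] - x[i, 2]
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 1e-12:
                c = bond_k * (r - bond_r0) / r
                f[i, 0] += c * dx
                f[i, 1] += c * dy
                f[i, 2] += c * dz
                f[j, 0] -= c * dx
                f[j, 1] -= c * dy
                f[j, 2] -= c * dz
        # soft-core repulsion via Verlet list
        if use_rep:
            if step % REBUILD_EVERY == 0:
                npairs = 0
                for i in range(n):
                    for j in range(i + 1, n):
                        dx = x[j, 0] - x[i, 0]
                        dy = x[j, 1] - x[i, 1]
                        dz = x[j, 2] - x[i, 2]
                        if dx * dx + dy * dy + dz * dz < cut2:
                            pi[npairs] = i
                            pj[npairs] = j
                            npairs += 1
            for p in range(npairs):
                i = pi[p]
                j = pj[p]
                dx = x[j, 0] - x[i, 0]
                dy = x[j, 1] - x[i, 1]
                dz = x[j, 2] - x[i, 2]
                r2 = dx * dx + dy * dy + dz * dz
                if r2 < sig2 and r2 > 1e-24:
                    q = 1.0 - r2 / sig2
                    c = -4.0 * rep_eps * q / sig2
                    f[i, 0] += c * dx
                    f[i, 1] += c * dy
                    f[i, 2] += c * dz
                    f[j, 0] -= c * dx
                    f[j, 1] -= c * dy
                    f[j, 2] -= c * dz
        # spherical confinement (harmonic wall)
        if conf_radius > 0.0:
            for i in range(n):
                r = np.sqrt(x[i, 0] ** 2 + x[i, 1] ** 2 + x[i, 2] ** 2)
                if r > conf_radius:
                    c = -conf_k * (r - conf_radius) / r
                    f[i, 0] += c * x[i, 0]
                    f[i, 1] += c * x[i, 1]
                    f[i, 2] += c * x[i, 2]
        # Euler-Maruyama update
        if a > 0.0:
            for i in range(n):
                x[i, 0] += mob * f[i, 0] + a * (2.0 * np.random.random() - 1.0)
                x[i, 1] += mob * f[i, 1] + a * (2.0 * np.random.random() - 1.0)
                x[i, 2] += mob * f[i, 2] + a * (2.0 * np.random.random() - 1.0)
        else:
            for i in range(n):
                x[i, 0] += mob * f[i, 0]
                x[i, 1] += mob * f[i, 1]
                x[i, 2] += mob * f[i, 2]
        if step % 200 == 0 or step == n_steps - 1:
            for i in range(n):
                v = x[i, 0] + x[i, 1] + x[i, 2]
                if not np.isfinite(v):
                    return step
    return -1


@njit(cache=True)
def count_contacts_by_separation(x, radius, out):
    """Accumulate contact counts per backbone separation |i-j| into ``out``."""
    n = x.shape[0]
    r2max = radius * radius
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[j, 0] - x[i, 0]
            dy = x[j, 1] - x[i, 1]
            dz = x[j, 2] - x[i, 2]
            if dx * dx + dy * dy + dz * dz <= r2max:
                out[j - i] += 1
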