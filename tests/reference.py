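"""Independent naive reference implementations used as oracles.

Everything here is deliberately unvectorized (explicit loops, explicit window
gathering) and shares no code with the production estimators beyond numpy
primitives.
"""

from __future__ import annotations

import numpy as np


def ref_jones_to_stokes(e1: complex, e2: complex) -> tuple[float, float, float, float]:
    """Stokes vector of one pixel via amplitudes and explicit phase difference."""
    a1, a2 = abs(e1), abs(e2)
    dphi = np.angle(e1 * np.conj(e2))
    return (a1**2 + a2**2, a1**2 - a2**2,
            2 * a1 * a2 * np.cos(dphi), 2 * a1 * a2 * np.sin(dphi))


def _norm_state(i, q, u, v):
    return np.array([q / i, u / i, v / i])


def ref_spatial_dopu(i, q, u, v, valid, kernel_x, kernel_z):
    """Double-loop spatial DOPU; window spans z-(kz-1)//2 .. z+kz//2 inclusive."""
    nz, nx = i.shape
    out = np.full((nz, nx), np.nan)
    for z in range(nz):
        for x in range(nx):
            if not (valid[z, x] and i[z, x] > 0):
                continue
            states = []
            for zz in range(max(0, z - (kernel_z - 1) // 2),
                            min(nz, z + kernel_z // 2 + 1)):
                for xx in range(max(0, x - (kernel_x - 1) // 2),
                                min(nx, x + kernel_x // 2 + 1)):
                    if valid[zz, xx] and i[zz, xx] > 0:
                        states.append(_norm_state(i[zz, xx], q[zz, xx],
                                                  u[zz, xx], v[zz, xx]))
            if len(states) < 2:
                out[z, x] = 1.0
            else:
                out[z, x] = np.linalg.norm(np.mean(states, axis=0))
    return out


def ref_temporal_dopu(i, q, u, v, shifts, masks):
    """Per-pixel loop over the aligned frame stack; <2 contributing frames -> NaN."""
    nf, nz, nx = i.shape
    ai = np.empty_like(i)
    aq = np.empty_like(q)
    au = np.empty_like(u)
    av = np.empty_like(v)
    am = np.empty_like(masks)
    for f in range(nf):
        roll = (-int(shifts[f, 0]), -int(shifts[f, 1]))
        ai[f] = np.roll(i[f], roll, axis=(0, 1))
        aq[f] = np.roll(q[f], roll, axis=(0, 1))
        au[f] = np.roll(u[f], roll, axis=(0, 1))
        av[f] = np.roll(v[f], roll, axis=(0, 1))
        am[f] = np.roll(masks[f], roll, axis=(0, 1))
    out = np.full((nz, nx), np.nan)
    for z in range(nz):
        for x in range(nx):
            states = [_norm_state(ai[f, z, x], aq[f, z, x], au[f, z, x], av[f, z, x])
                      for f in range(nf) if am[f, z, x] and ai[f, z, x] > 0]
            if len(states) >= 2:
                out[z, x] = np.linalg.norm(np.mean(states, axis=0))
    return out


def ref_spectral_dopu(i, q, u, v, mask):
    """Per-pixel loop over the band axis of the unnormalized Stokes parameters."""
    nb, nz, nx = i.shape
    out = np.full((nz, nx), np.nan)
    for z in range(nz):
        for x in range(nx):
            if not mask[z, x]:
                continue
            im = np.mean([i[b, z, x] for b in range(nb)])
            if im <= 0:
                continue
            qm = np.mean([q[b, z, x] for b in range(nb)])
            um = np.mean([u[b, z, x] for b in range(nb)])
            vm = np.mean([v[b, z, x] for b in range(nb)])
            out[z, x] = np.sqrt(qm**2 + um**2 + vm**2) / im
    return out


def resultant_length_null(n_vectors: int, n_replicates: int,
                          rng: np.random.Generator) -> np.ndarray:
    """Monte-Carlo null: lengths of the mean of n isotropic unit vectors."""
    out = np.empty(n_replicates)
    chunk = max(1, int(2e7) // (3 * n_vectors))
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        vecs = rng.normal(size=(m, n_vectors, 3))
        vecs /= np.linalg.norm(vecs, axis=2, keepdims=True)
        out[done:done + m] = np.linalg.norm(vecs.mean(axis=1), axis=1)
        done += m
    return out
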