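"""Analytic test primitives: structured tube and sphere surfaces.

Used by the verification suite (Lamé thick-walled cylinder, offset checks)
and handy for quick experiments; not part of the patient pipeline.
"""

from __future__ import annotations

import numpy as np
import trimesh

from .surface import TriSurface

__all__ = ["tube_surface", "sphere_surface"]


def tube_surface(
    radius: float,
    length: float,
    n_circ: int = 48,
    n_axial: int = 40,
    z0: float = 0.0,
) -> TriSurface:
    """Open cylindrical tube along z, outward-oriented, structured triangles."""
    theta = 2 * np.pi * np.arange(n_circ) / n_circ
    z = z0 + np.linspace(0.0, length, n_axial + 1)
    verts = np.empty(((n_axial + 1) * n_circ, 3))
    for k, zz in enumerate(z):
        sl = slice(k * n_circ, (k + 1) * n_circ)
        verts[sl, 0] = radius * np.cos(theta)
        verts[sl, 1] = radius * np.sin(theta)
        verts[sl, 2] = zz
    tris = []
    for k in range(n_axial):
        b = k * n_circ
        t = (k + 1) * n_circ
        for i in range(n_circ):
            j = (i + 1) % n_circ
            # outward orientation (CCW seen from outside)
            tris.append((b + i, b + j, t + i))
            tris.append((b + j, t + j, t + i))
    return TriSurface(verts, np.asarray(tris, dtype=np.int64))


def sphere_surface(radius: float, subdivisions: int = 3) -> TriSurface:
    """Closed icosphere, outward-oriented."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface.from_trimesh(m)
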