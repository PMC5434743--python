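"""Source-space construction: cortical mesh, surface Laplacian, lead field.

The source space is a triangulated sphere (subdivided icosahedron) scaled to
the brain radius, with one current dipole per vertex oriented along the
outward surface normal.  Volume conduction uses a three-shell concentric
sphere head model (brain / skull / scalp) with the standard conductivities
0.33 / 0.022 / 0.33 S/m.  The scalp potential of a dipole inside a
multilayer sphere is evaluated by the classical Legendre series expansion,
with the layer structure entering through per-degree 2x2 transfer-matrix
products.  For equal conductivities the series collapses to the homogeneous
single-sphere potential, which serves as an independent closed-form check
in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = [
    "HeadModel",
    "build_source_mesh",
    "surface_laplacian",
    "spherical_lead_field",
    "define_roi_gridpoints",
    "standard_electrodes",
    "default_roi_specs",
    "build_default_head_model",
]

#: default shell radii in meters: brain (source space bound), skull, scalp
DEFAULT_RADII = (0.087, 0.092, 0.100)
#: conductivities in S/m ordered innermost -> outermost (brain, skull, scalp)
DEFAULT_CONDUCTIVITIES = (0.33, 0.022, 0.33)
#: sources sit slightly inside the brain shell
SOURCE_RADIUS_FRACTION = 0.92


@dataclass
class Mesh:
    vertices: np.ndarray  # (G, 3) meters
    triangles: np.ndarray  # (F, 3) vertex indices
    normals: np.ndarray  # (G, 3) outward unit normals

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]


@dataclass
class HeadModel:
    """Everything the inverse problem needs about geometry and conduction."""

    mesh: Mesh
    K: np.ndarray        # lead field (C, G)
    H_lap: np.ndarray    # discrete surface Laplacian (G, G)
    conductivities: tuple[float, float, float]
    radii: tuple[float, float, float]
    electrode_names: list[str]
    electrode_pos: np.ndarray  # (C, 3)
    roi_map: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.K.shape[0]

    @property
    def n_gridpoints(self) -> int:
        return self.K.shape[1]

    @property
    def roi_names(self) -> list[str]:
        return list(self.roi_map)


# ---------------------------------------------------------------------------
# icosphere mesh
# ---------------------------------------------------------------------------


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return verts, faces


def build_source_mesh(subdivisions: int = 3, radius: float | None = None) -> Mesh:
    """Triangulated sphere by icosahedron subdivision.

    Vertex count follows the icosphere formula ``V(s) = 10 * 4**s + 2``
    (12, 42, 162, 642, 2562, ...).  The mesh is scaled so that vertices lie
    at ``SOURCE_RADIUS_FRACTION`` of the brain-shell radius, keeping all
    dipoles strictly inside the innermost conductor.
    """
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    if radius is None:
        radius = SOURCE_RADIUS_FRACTION * DEFAULT_RADII[0]
    verts, faces = _icosahedron()
    for _ in range(subdivisions):
        edge_mid: dict[tuple[int, int], int] = {}
        new_faces = []
        verts_list = [v for v in verts]

        def midpoint(a: int, b: int) -> int:
            key = (a, b) if a < b else (b, a)
            if key not in edge_mid:
                m = verts_list[a] + verts_list[b]
                m /= np.linalg.norm(m)
                edge_mid[key] = len(verts_list)
                verts_list.append(m)
            return edge_mid[key]

        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.asarray(verts_list)
        faces = np.asarray(new_faces, dtype=int)
    normals = verts.copy()  # unit sphere: outward normal is the position itself
    return Mesh(vertices=verts * radius, triangles=faces, normals=normals)


# ---------------------------------------------------------------------------
# surface Laplacian
# ---------------------------------------------------------------------------


def surface_laplacian(mesh: Mesh, kind: str = "graph") -> np.ndarray:
    """Discrete surface Laplacian of the mesh.

    ``graph`` (default): degree-minus-adjacency over mesh edges.  ``cotan``:
    cotangent weights.  Both are symmetric with rows summing to zero and the
    constant vector in the null space; the quadratic form penalizes spatial
    roughness of a field sampled at the vertices.
    """
    G = mesh.n_vertices
    tri = mesh.triangles
    areas = np.linalg.norm(
        np.cross(
            mesh.vertices[tri[:, 1]] - mesh.vertices[tri[:, 0]],
            mesh.vertices[tri[:, 2]] - mesh.vertices[tri[:, 0]],
        ),
        axis=1,
    )
    if np.any(areas <= 1e-300):
        bad = int(np.argmin(areas))
        raise ValueError(f"degenerate triangle at face index {bad}")
    W = sp.lil_matrix((G, G))
    if kind == "graph":
        for k in range(3):
            a, b = tri[:, k], tri[:, (k + 1) % 3]
            W[a, b] = 1.0
            W[b, a] = 1.0
    elif kind == "cotan":
        v = mesh.vertices
        for k in range(3):
            i, j, o = tri[:, k], tri[:, (k + 1) % 3], tri[:, (k + 2) % 3]
            u1, u2 = v[i] - v[o], v[j] - v[o]
            cos = np.sum(u1 * u2, axis=1)
            sin = np.linalg.norm(np.cross(u1, u2), axis=1)
            cot = 0.5 * cos / np.maximum(sin, 1e-12)
            for a, b, w in zip(i, j, cot):
                W[a, b] += w
                W[b, a] += w
    else:
        raise ValueError(f"unknown Laplacian kind: {kind}")
    W = W.tocsr()
    deg = np.asarray(W.sum(axis=1)).ravel()
    L = sp.diags(deg) - W
    L = np.asarray(L.todense())
    return 0.5 * (L + L.T)  # enforce exact symmetry


# ---------------------------------------------------------------------------
# multilayer-sphere lead field
# ---------------------------------------------------------------------------


def _multilayer_fn(n_terms: int, radii: np.ndarray, cond: np.ndarray) -> np.ndarray:
    """Per-degree shape factors f_n of the concentric-sphere head model.

    For each spherical-harmonic degree n the layered structure contributes a
    factor obtained from a product of 2x2 boundary matrices over the
    interior interfaces; for equal conductivities every factor is exactly 1
    and the model reduces to a homogeneous sphere.
    """
    n_layers = len(radii)
    R = radii[-1]
    ns = np.arange(1, n_terms + 1, dtype=float)
    f = np.empty(n_terms)
    for idx, n in enumerate(ns):
        m = np.eye(2)
        for k in range(n_layers - 1):
            s = cond[k] / cond[k + 1]
            rk = radii[k] / R
            mk = np.array(
                [
                    [n + (n + 1) * s, (n + 1) * (s - 1) * rk ** -(2 * n + 1)],
                    [n * (s - 1) * rk ** (2 * n + 1), (n + 1) + n * s],
                ]
            ) / (2 * n + 1)
            m = m @ mk  # innermost boundary applied last
        f[idx] = n / (n * m[1, 1] + (1 + n) * m[1, 0])
    return f


def _legendre_terms(x: np.ndarray, n_terms: int):
    """Yield (n, P_n(x), P_n^1(x)) for n = 1..n_terms via stable recursions.

    P_n^1 uses the Ferrers definition without the Condon-Shortley phase:
    P_n^1(cos t) = sin t * dP_n/dx |_{x=cos t}.
    """
    p_prev = np.ones_like(x)      # P_0
    p_cur = x.copy()              # P_1
    dp_prev = np.zeros_like(x)    # P_0'
    dp_cur = np.ones_like(x)      # P_1'
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    for n in range(1, n_terms + 1):
        yield n, p_cur, s * dp_cur
        p_next = ((2 * n + 1) * x * p_cur - n * p_prev) / (n + 1)
        dp_next = dp_prev + (2 * n + 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next


def multilayer_potential(
    electrode_pos: np.ndarray,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    radii=DEFAULT_RADII,
    conductivities=DEFAULT_CONDUCTIVITIES,
    n_terms: int = 200,
) -> np.ndarray:
    """Scalp potentials (C,) of point current dipoles in a layered sphere.

    Parameters
    ----------
    electrode_pos : (C, 3), on the outer shell surface.
    dipole_pos, dipole_moment : (G, 3) positions (inside the innermost
        shell) and moments in A*m.

    Returns
    -------
    ndarray, shape (C, G)
        Potential in volts of each unit dipole at each electrode, before any
        referencing.
    """
    radii = np.asarray(radii, dtype=float)
    cond = np.asarray(conductivities, dtype=float)
    R = radii[-1]
    elec = np.atleast_2d(np.asarray(electrode_pos, dtype=float))
    dip = np.atleast_2d(np.asarray(dipole_pos, dtype=float))
    mom = np.atleast_2d(np.asarray(dipole_moment, dtype=float))
    b = np.linalg.norm(dip, axis=1)
    if np.any(b >= radii[0]):
        raise ValueError("dipole outside the innermost shell")
    C, G = elec.shape[0], dip.shape[0]
    e_hat = elec / np.linalg.norm(elec, axis=1, keepdims=True)

    # decompose each moment into radial and tangential parts
    with np.errstate(invalid="ignore", divide="ignore"):
        b_hat = np.where(b[:, None] > 0, dip / np.where(b[:, None] == 0, 1, b[:, None]), 0.0)
    q_r = np.sum(mom * b_hat, axis=1)
    t_vec = mom - q_r[:, None] * b_hat
    q_t = np.linalg.norm(t_vec, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_hat = np.where(q_t[:, None] > 1e-300, t_vec / np.where(q_t[:, None] == 0, 1, q_t[:, None]), 0.0)

    cosg = np.clip(e_hat @ b_hat.T, -1.0, 1.0)  # (C, G) angle dipole-electrode
    # azimuth of the electrode about the dipole axis, measured from t_hat
    e_perp = e_hat[:, None, :] - cosg[:, :, None] * b_hat[None, :, :]
    cosphi_num = np.einsum("cgk,gk->cg", e_perp, t_hat)
    sing = np.sqrt(np.clip(1.0 - cosg**2, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosphi = np.where(sing > 1e-12, cosphi_num / np.where(sing == 0, 1, sing), 0.0)

    f = b / R  # (G,) eccentricities
    fn = _multilayer_fn(n_terms, radii, cond)
    V = np.zeros((C, G))
    f_pow = np.ones(G)  # f**(n-1)
    for n, Pn, Pn1 in _legendre_terms(cosg, n_terms):
        coeff = (2 * n + 1) / n * fn[n - 1]
        term = coeff * f_pow * (n * q_r * Pn + q_t * Pn1 * cosphi)
        V += term
        f_pow = f_pow * f
    V /= 4.0 * np.pi * cond[-1] * R**2
    return V


def spherical_lead_field(
    mesh: Mesh,
    electrode_pos: np.ndarray,
    conductivities=DEFAULT_CONDUCTIVITIES,
    radii=DEFAULT_RADII,
    n_terms: int = 200,
) -> np.ndarray:
    """Lead field K (C, G): average-referenced scalp potential per unit
    normal-oriented dipole at each mesh vertex."""
    elec = np.asarray(electrode_pos, dtype=float)
    r_e = np.linalg.norm(elec, axis=1)
    R = radii[-1]
    if np.any(np.abs(r_e - R) > 1e-6):
        raise ValueError("electrodes must lie on the outer shell surface")
    K = multilayer_potential(
        elec, mesh.vertices, mesh.normals, radii=radii,
        conductivities=conductivities, n_terms=n_terms,
    )
    K = K - K.mean(axis=0, keepdims=True)  # average reference per source
    return K


def single_sphere_potential(
    electrode_pos: np.ndarray,
    dipole_pos: np.ndarray,
    dipole_moment: np.ndarray,
    radius: float = DEFAULT_RADII[-1],
    conductivity: float = DEFAULT_CONDUCTIVITIES[-1],
) -> np.ndarray:
    """Closed-form surface potential of a dipole in a homogeneous sphere.

    Obtained by summing the Legendre series in closed form with the
    generating-function identities; used as the independent oracle for the
    equal-conductivity limit of :func:`multilayer_potential`.
    """
    elec = np.atleast_2d(np.asarray(electrode_pos, dtype=float))
    dip = np.atleast_2d(np.asarray(dipole_pos, dtype=float))
    mom = np.atleast_2d(np.asarray(dipole_moment, dtype=float))
    R = radius
    b = np.linalg.norm(dip, axis=1)
    e_hat = elec / np.linalg.norm(elec, axis=1, keepdims=True)
    b_hat = np.where(b[:, None] > 0, dip / np.where(b[:, None] == 0, 1, b[:, None]), 0.0)
    q_r = np.sum(mom * b_hat, axis=1)
    t_vec = mom - q_r[:, None] * b_hat
    q_t = np.linalg.norm(t_vec, axis=1)
    t_hat = np.where(q_t[:, None] > 1e-300, t_vec / np.where(q_t[:, None] == 0, 1, q_t[:, None]), 0.0)
    x = np.clip(e_hat @ b_hat.T, -1.0, 1.0)
    e_perp = e_hat[:, None, :] - x[:, :, None] * b_hat[None, :, :]
    s = np.sqrt(np.clip(1.0 - x * x, 0.0, None))
    with np.errstate(invalid="ignore", divide="ignore"):
        cosphi = np.where(s > 1e-12, np.einsum("cgk,gk->cg", e_perp, t_hat) / np.where(s == 0, 1, s), 0.0)
    fr = (b / R)[None, :]
    g = np.sqrt(1.0 - 2.0 * fr * x + fr * fr)
    # radial part: sum (2n+1) f^(n-1) P_n = 2 (x - f)/g^3 + (1/f)(1/g - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rad = 2.0 * (x - fr) / g**3 + np.where(fr > 0, (1.0 / g - 1.0) / np.where(fr == 0, 1, fr), x)
    # tangential part: sum ((2n+1)/n) f^(n-1) P_n^1 cosphi
    #   = s [ 2/g^3 + (1+g) / (g (1 - f x + g)) ] cosphi
    tan = s * (2.0 / g**3 + (1.0 + g) / (g * (1.0 - fr * x + g))) * cosphi
    V = (q_r[None, :] * rad + q_t[None, :] * tan) / (4.0 * np.pi * conductivity * R**2)
    return V


# ---------------------------------------------------------------------------
# electrodes and ROIs
# ---------------------------------------------------------------------------


def standard_electrodes(n: int = 64, radius: float = DEFAULT_RADII[-1]) -> tuple[list[str], np.ndarray]:
    """Deterministic quasi-uniform electrode montage on the upper scalp.

    Electrodes are placed by a Fibonacci spiral restricted to the upper
    portion of the sphere (z above -0.25 R), approximating an extended
    10-20-style whole-head coverage without ear/cheek positions.
    """
    golden = np.pi * (3.0 - np.sqrt(5.0))
    zmin = -0.25
    z = np.linspace(zmin, 0.995, n)
    theta = golden * np.arange(n)
    rho = np.sqrt(1.0 - z * z)
    pos = np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z]) * radius
    names = [f"E{i + 1:02d}" for i in range(n)]
    return names, pos


def default_roi_specs(radius: float | None = None) -> list[dict]:
    """Nine named cortical regions on the spherical source space.

    Mirrors the standard reach-task network: bilateral inferior occipital
    (Occ), superior parietal (Par) and precentral motor (Mot) cortices plus
    three midline regions -- anterior cingulate (ACC), supplementary motor
    area (SMA) and precuneus (Prec) -- whose left/right gridpoint sets are
    merged and treated as single regions.
    """
    if radius is None:
        radius = SOURCE_RADIUS_FRACTION * DEFAULT_RADII[0]

    def ang(az_deg: float, el_deg: float) -> list[float]:
        az, el = np.deg2rad(az_deg), np.deg2rad(el_deg)
        return [
            radius * np.cos(el) * np.cos(az),
            radius * np.cos(el) * np.sin(az),
            radius * np.sin(el),
        ]

    # +x anterior, +y left, +z superior
    r = 0.35 * radius
    return [
        {"name": "L Occ", "seed": ang(170, 0), "radius": r},
        {"name": "R Occ", "seed": ang(-170, 0), "radius": r},
        {"name": "L Par", "seed": ang(140, 45), "radius": r},
        {"name": "R Par", "seed": ang(-140, 45), "radius": r},
        {"name": "L Mot", "seed": ang(60, 45), "radius": r},
        {"name": "R Mot", "seed": ang(-60, 45), "radius": r},
        {"name": "ACC", "seed": [ang(25, 25), ang(-25, 25)], "radius": r, "merge": True},
        {"name": "SMA", "seed": [ang(75, 70), ang(-75, 70)], "radius": r, "merge": True},
        {"name": "Prec", "seed": [ang(160, 60), ang(-160, 60)], "radius": r, "merge": True},
    ]


def define_roi_gridpoints(mesh: Mesh, roi_specs: list[dict]) -> dict[str, np.ndarray]:
    """Map named regions to mesh vertex sets.

    Each region is the set of vertices within ``radius`` (Euclidean) of its
    seed coordinate; regions with ``merge`` set union the vertex sets of
    their (bilateral) seed list.  Vertices claimed by several regions go to
    the nearest seed.
    """
    G = mesh.n_vertices
    best_dist = np.full(G, np.inf)
    owner = np.full(G, -1)
    names = []
    for ri, spec in enumerate(roi_specs):
        names.append(spec["name"])
        seeds = np.atleast_2d(np.asarray(spec["seed"], dtype=float))
        if not spec.get("merge", False) and seeds.shape[0] > 1:
            raise ValueError(f"ROI {spec['name']} lists multiple seeds without merge flag")
        rad = float(spec["radius"])
        for seed in seeds:
            d = np.linalg.norm(mesh.vertices - seed[None, :], axis=1)
            inside = d <= rad
            claim = inside & (d < best_dist)
            best_dist[claim] = d[claim]
            owner[claim] = ri
    roi_map = {}
    for ri, name in enumerate(names):
        idx = np.flatnonzero(owner == ri)
        if idx.size == 0:
            raise ValueError(f"ROI {name} contains no gridpoints; increase its radius")
        roi_map[name] = idx
    return roi_map


def write_mesh_off(mesh: Mesh, path) -> None:
    """Serialize the mesh in the OFF text format."""
    from pathlib import Path

    lines = ["OFF", f"{mesh.n_vertices} {len(mesh.triangles)} 0"]
    lines += [f"{x:.17g} {y:.17g} {z:.17g}" for x, y, z in mesh.vertices]
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    Path(path).write_text("\n".join(lines) + "\n")


def read_mesh_off(path) -> Mesh:
    from pathlib import Path

    tokens = Path(path).read_text().split()
    if tokens[0] != "OFF":
        raise ValueError("not an OFF file")
    nv, nf = int(tokens[1]), int(tokens[2])
    body = tokens[4:]
    verts = np.array(body[: 3 * nv], dtype=float).reshape(nv, 3)
    rest = body[3 * nv :]
    faces = []
    i = 0
    for _ in range(nf):
        k = int(rest[i])
        faces.append([int(v) for v in rest[i + 1 : i + 1 + k]])
        i += k + 1
    normals = verts / np.linalg.norm(verts, axis=1, keepdims=True)
    return Mesh(vertices=verts, triangles=np.asarray(faces, dtype=int), normals=normals)


def save_head_model(model: HeadModel, directory) -> None:
    """Write a head model as plain text: OFF mesh, TSV matrices, JSON header."""
    import json
    from pathlib import Path

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_mesh_off(model.mesh, d / "mesh.off")
    np.savetxt(d / "leadfield.tsv", model.K, delimiter="\t", fmt="%.17g")
    np.savetxt(d / "laplacian.tsv", model.H_lap, delimiter="\t", fmt="%.17g")
    header = {
        "conductivities": list(model.conductivities),
        "radii": list(model.radii),
        "electrode_names": model.electrode_names,
        "electrode_pos": model.electrode_pos.tolist(),
        "roi_map": {k: v.tolist() for k, v in model.roi_map.items()},
    }
    (d / "head_model.json").write_text(json.dumps(header, indent=1))


def load_head_model(directory) -> HeadModel:
    import json
    from pathlib import Path

    d = Path(directory)
    header = json.loads((d / "head_model.json").read_text())
    mesh = read_mesh_off(d / "mesh.off")
    return HeadModel(
        mesh=mesh,
        K=np.loadtxt(d / "leadfield.tsv", delimiter="\t"),
        H_lap=np.loadtxt(d / "laplacian.tsv", delimiter="\t"),
        conductivities=tuple(header["conductivities"]),
        radii=tuple(header["radii"]),
        electrode_names=list(header["electrode_names"]),
        electrode_pos=np.asarray(header["electrode_pos"], dtype=float),
        roi_map={k: np.asarray(v, dtype=int) for k, v in header["roi_map"].items()},
    )


def build_default_head_model(
    subdivisions: int = 3,
    n_electrodes: int = 64,
    conductivities=DEFAULT_CONDUCTIVITIES,
    radii=DEFAULT_RADII,
    laplacian: str = "graph",
    roi_specs: list[dict] | None = None,
) -> HeadModel:
    """Convenience constructor: mesh + Laplacian + lead field + ROI map."""
    mesh = build_source_mesh(subdivisions, radius=SOURCE_RADIUS_FRACTION * radii[0])
    names, pos = standard_electrodes(n_electrodes, radius=radii[-1])
    K = spherical_lead_field(mesh, pos, conductivities=conductivities, radii=radii)
    H = surface_laplacian(mesh, kind=laplacian)
    if roi_specs is None:
        roi_specs = default_roi_specs(radius=SOURCE_RADIUS_FRACTION * radii[0])
    roi_map = define_roi_gridpoints(mesh, roi_specs)
    return HeadModel(
        mesh=mesh,
        K=K,
        H_lap=H,
        conductivities=tuple(conductivities),
        radii=tuple(radii),
        electrode_names=names,
        electrode_pos=pos,
        roi_map=roi_map,
    )
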