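"""Synthetic ensembles with known ground truth.

Two layers:

* a discrete worm-like chain (Kratky-Porod) sampler producing per-frame
  vertex chains and tangents with a prescribed persistence length, optional
  intrinsic curvature and an optional softened joint;
* a pseudo-atomic builder that wraps a two-chain coiled-coil backbone
  around each sampled centerline, producing a :class:`ConformationEnsemble`
  that the whole analysis pipeline (axis, persistence, H-bonds, distances)
  can consume.

The joint bending angle is sampled from the exact discrete Kratky-Porod
equilibrium density ``p(theta) ~ exp(-(Lp/b)(1 - cos theta)) sin theta``
via the closed-form inverse CDF in ``cos theta`` — no small-angle
approximation, so softened (large-angle) joints are sampled correctly.
The first tangent is clamped to +z in every frame, which defines the body
frame and makes time-average tangents meaningful without superposition.

The builder emulates the shape of the analysed system — two parallel
α-helices, author-numbered residues 106-216, ~0.49 nm from the shared axis
— not any real sequence, side chains or force-field physics.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axis import AxisPolyline, SegmentScheme
from .ensembles import ConformationEnsemble, Frame

__all__ = [
    "WLCParams",
    "WLCEnsemble",
    "CoiledCoilBuildParams",
    "sample_wlc_ensemble",
    "build_coiled_coil_ensemble",
    "rigid_rod_ensemble",
    "ideal_helix_frame",
    "mean_cos_kratky_porod",
]


# ---------------------------------------------------------------------------
# Worm-like chain sampler
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WLCParams:
    """Parameters of the discrete worm-like-chain ensemble.

    ``soft_joint`` is an optional ``(joint_index, softness)`` pair: joint
    ``k`` (the bend between tangents ``k-1`` and ``k``, ``1 <= k <=
    n_vertices-2``) is sampled with persistence length ``lp_nm/softness``.
    ``intrinsic_bend_deg`` adds a deterministic rotation about ``bend_axis``
    at every joint, turning the mean shape into a circular arc.
    """

    n_vertices: int = 11
    segment_length_nm: float = 1.5
    lp_nm: float = 100.0
    intrinsic_bend_deg: float = 0.0
    bend_axis: tuple[float, float, float] = (1.0, 0.0, 0.0)
    n_frames: int = 8000
    seed: int = 0
    soft_joint: tuple[int, float] | None = None

    def __post_init__(self) -> None:
        if self.segment_length_nm <= 0:
            raise ValueError("segment length must be positive")
        if self.lp_nm <= 0:
            raise ValueError("persistence length must be positive")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")
        if self.n_vertices < 3:
            raise ValueError("need at least 3 vertices (2 tangents)")
        if self.soft_joint is not None:
            k, soft = self.soft_joint
            if not 1 <= k <= self.n_vertices - 2:
                raise ValueError(
                    f"soft joint index {k} outside 1..{self.n_vertices - 2}"
                )
            if soft < 1:
                raise ValueError("softness factor must be >= 1")


@dataclass
class WLCEnsemble:
    """Sampled vertex chains and tangents: the generator's ground truth."""

    vertices: np.ndarray  # (n_frames, n_vertices, 3), nm
    tangents: np.ndarray  # (n_frames, n_vertices-1, 3), unit
    params: WLCParams

    def to_axis_polyline(self, scheme: SegmentScheme | None = None) -> AxisPolyline:
        """View the sampled chain as an axis polyline for the estimators."""
        lengths = np.linalg.norm(np.diff(self.vertices, axis=1), axis=-1)
        mean_len = lengths.mean(axis=0)
        arc_s = np.concatenate([[0.0], np.cumsum(mean_len[:-1])])
        return AxisPolyline(
            vertices=self.vertices,
            tangents=self.tangents,
            mean_segment_lengths=mean_len,
            arc_s=arc_s,
            scheme=scheme,
        )


def mean_cos_kratky_porod(kappa: float) -> float:
    """Exact mean of cos(theta) under the discrete Kratky-Porod density.

    For ``p(u) ~ exp(kappa u)`` on ``u = cos theta in [-1, 1]`` the mean is
    the Langevin function shifted to this interval: ``coth(kappa) -
    1/kappa``.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    if kappa > 20:
        # coth(kappa) -> 1 to double precision
        return 1.0 - 1.0 / kappa
    return 1.0 / math.tanh(kappa) - 1.0 / kappa


def _sample_cos_theta(kappa: float, n: int,
                      generator: np.random.Generator) -> np.ndarray:
    """Inverse-CDF draw of cos(theta) from p(u) ~ exp(kappa u), u in [-1,1].

    Written as ``1 + log(U + (1-U) exp(-2 kappa)) / kappa`` which is stable
    for stiff joints (large kappa).
    """
    u = generator.random(n)
    u = np.clip(u, 1e-300, 1.0)
    return 1.0 + np.log(u + (1.0 - u) * math.exp(-2.0 * min(kappa, 400.0))) / kappa


def _perpendicular_frame(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal vectors e1, e2 perpendicular to each row of unit t."""
    ref = np.zeros_like(t)
    smallest = np.argmin(np.abs(t), axis=1)
    ref[np.arange(len(t)), smallest] = 1.0
    e1 = np.cross(t, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(t, e1)
    return e1, e2


def _rotation_about(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    from scipy.spatial.transform import Rotation

    return Rotation.from_rotvec(axis * angle_rad).as_matrix()


def sample_wlc_ensemble(params: WLCParams) -> WLCEnsemble:
    """Monte-Carlo sample of clamped discrete worm-like chains.

    Every frame is an independent equilibrium conformation: tangent 0 is
    +z; each subsequent tangent is the previous one bent by a Kratky-Porod
    polar angle with uniform azimuth, then rotated by the deterministic
    intrinsic bend.  Identical seeds give bit-identical ensembles.
    """
    rng = np.random.default_rng(params.seed)
    F, V = params.n_frames, params.n_vertices
    b = params.segment_length_nm
    kappa0 = params.lp_nm / b
    alpha = math.radians(params.intrinsic_bend_deg)
    R = _rotation_about(params.bend_axis, alpha) if alpha != 0.0 else None
    t = np.empty((F, V - 1, 3))
    t[:, 0] = (0.0, 0.0, 1.0)
    for k in range(1, V - 1):
        kappa = kappa0
        if params.soft_joint is not None and params.soft_joint[0] == k:
            kappa = kappa0 / params.soft_joint[1]
        cos_t = _sample_cos_theta(kappa, F, rng)
        sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 0.0, None))
        phi = rng.uniform(0.0, 2.0 * math.pi, F)
        prev = t[:, k - 1]
        e1, e2 = _perpendicular_frame(prev)
        new = (
            cos_t[:, None] * prev
            + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        if R is not None:
            new = new @ R.T
        new /= np.linalg.norm(new, axis=1, keepdims=True)
        t[:, k] = new
    vertices = np.concatenate(
        [np.zeros((F, 1, 3)), np.cumsum(b * t, axis=1)], axis=1
    )
    return WLCEnsemble(vertices=vertices, tangents=t, params=params)


# ---------------------------------------------------------------------------
# Ideal alpha-helix backbone template
# ---------------------------------------------------------------------------

def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame atom placement (angles in rad)."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d = np.array(
        [
            -bond * math.cos(angle),
            bond * math.sin(angle) * math.cos(torsion),
            bond * math.sin(angle) * math.sin(torsion),
        ]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


# standard backbone geometry, nm / degrees
_B_NCA, _B_CAC, _B_CN, _B_CO, _B_NH = 0.1458, 0.1525, 0.1329, 0.1231, 0.101
_A_NCAC, _A_CACN, _A_CNCA, _A_CACO = 111.2, 116.2, 121.7, 120.8
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0

_template_cache: dict = {}


def _ideal_helix_template(n_res: int, with_hydrogens: bool) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Ideal alpha-helix backbone, axis on +z through the origin.

    Returns (atom table without chain ids, coords (n_atoms, 3) nm, rise per
    residue nm).  Residue indices run 0..n_res-1; callers renumber.
    """
    key = (n_res, with_hydrogens)
    if key in _template_cache:
        return _template_cache[key]
    phi, psi, omega = (math.radians(x) for x in (_PHI, _PSI, _OMEGA))
    aNCAC, aCACN, aCNCA, aCACO = (
        math.radians(x) for x in (_A_NCAC, _A_CACN, _A_CNCA, _A_CACO)
    )
    pos: dict[tuple[int, str], np.ndarray] = {}
    N = np.zeros(3)
    CA = N + np.array([_B_NCA, 0.0, 0.0])
    C = _nerf(N + np.array([0.0, 1.0, 0.0]), N, CA, _B_CAC, aNCAC, 0.0)
    pos[(0, "N")], pos[(0, "CA")], pos[(0, "C")] = N, CA, C
    for i in range(n_res):
        N, CA, C = pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")]
        pos[(i, "O")] = _nerf(N, CA, C, _B_CO, aCACO, psi + math.pi)
        if i + 1 < n_res:
            N1 = _nerf(N, CA, C, _B_CN, aCACN, psi)
            CA1 = _nerf(CA, C, N1, _B_NCA, aCNCA, omega)
            C1 = _nerf(C, N1, CA1, _B_CAC, aNCAC, phi)
            pos[(i + 1, "N")], pos[(i + 1, "CA")], pos[(i + 1, "C")] = N1, CA1, C1
            if with_hydrogens:
                u = (C - N1) / np.linalg.norm(C - N1)
                v = (CA1 - N1) / np.linalg.norm(CA1 - N1)
                h_dir = -(u + v)
                pos[(i + 1, "H")] = N1 + _B_NH * h_dir / np.linalg.norm(h_dir)
    # axis from second differences of CA positions (exact for an ideal helix)
    ca = np.array([pos[(i, "CA")] for i in range(n_res)])
    d2 = ca[2:] - 2 * ca[1:-1] + ca[:-2]
    _, _, vt = np.linalg.svd(d2)
    axis = vt[-1]
    if np.dot(ca[-1] - ca[0], axis) < 0:
        axis = -axis
    rise = float(np.mean(np.dot(ca[1:] - ca[:-1], axis)))
    # rotate axis onto +z, put the axis through the origin, CA0 at z=0
    ref = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, ref)
    s = np.linalg.norm(v)
    if s < 1e-12:
        Rm = np.eye(3)
    else:
        vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
        Rm = np.eye(3) + vx + vx @ vx * ((1 - np.dot(axis, ref)) / s**2)
    order = ["N", "H", "CA", "C", "O"] if with_hydrogens else ["N", "CA", "C", "O"]
    rows, coords = [], []
    for i in range(n_res):
        for name in order:
            if (i, name) in pos:
                rows.append((i, "ALA", name))
                coords.append(Rm @ pos[(i, name)])
    coords = np.array(coords)
    ca_t = coords[[j for j, r in enumerate(rows) if r[2] == "CA"]]
    # center the axis: remove mean transverse position of the CA ring and
    # shift z so CA of residue 0 projects to z=0
    center_xy = ca_t[:, :2].mean(axis=0)
    coords[:, :2] -= center_xy
    coords[:, 2] -= ca_t[0, 2]
    atoms = pd.DataFrame(rows, columns=["residue_offset", "residue_name", "atom_name"])
    _template_cache[key] = (atoms, coords, rise)
    return atoms, coords, rise


def ideal_helix_frame(n_res: int = 20, chain_id: str = "A") -> Frame:
    """Single ideal alpha-helix (backbone + amide H) as one Frame.

    Residues are numbered 1..n_res.  With the default H-bond criterion this
    helix carries exactly ``n_res - 4`` backbone i -> i-4 hydrogen bonds.
    """
    atoms, coords, _ = _ideal_helix_template(n_res, with_hydrogens=True)
    table = pd.DataFrame(
        {
            "chain_id": chain_id,
            "residue_index": atoms["residue_offset"] + 1,
            "residue_name": atoms["residue_name"],
            "atom_name": atoms["atom_name"],
        }
    )
    return Frame(atoms=table, coords=coords.copy(), time=0.0)


# ---------------------------------------------------------------------------
# Coiled-coil builder
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CoiledCoilBuildParams:
    """Geometry of the pseudo-atomic two-chain build.

    Defaults emulate the analysed fragment: residues 106-216 on two chains
    whose helix axes run 0.49 nm from the shared coiled-coil axis (so the
    inter-helix distance is ~0.98 nm), with ~0.1485 nm of axial rise per
    residue.  ``place_backbone="CA"`` places Cα atoms only;
    ``"backbone"`` adds N, H, C, O so the H-bond stage can run.
    """

    chain_ids: tuple[str, str] = ("A", "B")
    first_residue: int = 106
    last_residue: int = 216
    inter_axis_radius: float = 0.49  # nm
    rise_per_residue: float = 0.1485  # nm
    place_backbone: str = "CA"  # "CA" | "backbone"
    temperature: float = 300.0  # K
    frame_spacing: float = 10.0  # ps

    def __post_init__(self) -> None:
        if self.inter_axis_radius <= 0:
            raise ValueError("inter-axis radius must be positive")
        if self.last_residue <= self.first_residue:
            raise ValueError("empty residue span")
        if self.place_backbone not in ("CA", "backbone"):
            raise ValueError("place_backbone must be 'CA' or 'backbone'")


def _transport_frames(tang: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Parallel-transport a normal frame along tangent fields.

    ``tang``: (F, G, 3) unit tangents on an arc-length grid.  Returns
    (n1, n2) of the same shape.
    """
    F, G, _ = tang.shape
    n1 = np.empty_like(tang)
    t0 = tang[:, 0]
    ref = np.tile(np.array([1.0, 0.0, 0.0]), (F, 1))
    proj = ref - t0 * np.sum(ref * t0, axis=1, keepdims=True)
    bad = np.linalg.norm(proj, axis=1) < 1e-8
    if bad.any():
        alt = np.tile(np.array([0.0, 1.0, 0.0]), (bad.sum(), 1))
        proj[bad] = alt - t0[bad] * np.sum(alt * t0[bad], axis=1, keepdims=True)
    n1[:, 0] = proj / np.linalg.norm(proj, axis=1, keepdims=True)
    for g in range(1, G):
        a, b = tang[:, g - 1], tang[:, g]
        k = np.cross(a, b)
        s = np.linalg.norm(k, axis=1)
        c = np.sum(a * b, axis=1)
        v = n1[:, g - 1]
        with np.errstate(invalid="ignore", divide="ignore"):
            ku = k / s[:, None]
        rotated = (
            v * c[:, None]
            + np.cross(ku, v) * s[:, None]
            + ku * np.sum(ku * v, axis=1, keepdims=True) * (1 - c[:, None])
        )
        rotated = np.where(s[:, None] < 1e-12, v, rotated)
        # re-orthogonalise against the new tangent to stop drift
        rotated = rotated - b * np.sum(rotated * b, axis=1, keepdims=True)
        n1[:, g] = rotated / np.linalg.norm(rotated, axis=1, keepdims=True)
    n2 = np.cross(tang, n1)
    return n1, n2


def build_coiled_coil_ensemble(
    wlc: WLCEnsemble, params: CoiledCoilBuildParams | None = None
) -> ConformationEnsemble:
    """Wrap a two-chain coiled-coil backbone around each sampled centerline.

    A straight ideal two-helix template (chain B is chain A rotated 180
    degrees about the shared axis, so segment-centroid midpoints fall
    exactly on the axis) is bent along a cubic-spline interpolation of the
    worm-like-chain vertices using a parallel-transported normal frame.
    Vertex ``i`` of the chain corresponds to the centre of analysis segment
    ``i``; with the default segment scheme, ``build_axis`` on the result
    recovers the sampled centerline to within a few hundredths of a nm.
    """
    from scipy.interpolate import CubicSpline

    if params is None:
        params = CoiledCoilBuildParams()
    b = wlc.params.segment_length_nm
    V = wlc.params.n_vertices
    step_res = round(b / params.rise_per_residue)
    if step_res < 1 or abs(b - step_res * params.rise_per_residue) > 0.1 * b:
        raise ValueError(
            f"span/rise inconsistency: segment length {b} nm is not close to "
            f"an integer multiple of rise {params.rise_per_residue} nm/residue"
        )
    n_res = params.last_residue - params.first_residue + 1
    centers_span = (V - 1) * step_res
    if centers_span > n_res - 1:
        raise ValueError(
            f"span/rise inconsistency: {V} vertices need {centers_span + 1} "
            f"residues of coverage but the chain has only {n_res}"
        )
    # residue index whose segment centre sits on vertex 0
    c0_res = params.first_residue + (n_res - 1 - centers_span) // 2
    s_per_res = b / step_res

    with_h = params.place_backbone == "backbone"
    atoms_t, coords_t, rise_nat = _ideal_helix_template(n_res, with_h)
    # template z -> arc length, axial compression to the requested rise
    z_ca0 = 0.0  # template already has CA of residue 0 at z=0
    s_atom_chain = (coords_t[:, 2] - z_ca0) / rise_nat * s_per_res \
        - (c0_res - params.first_residue) * s_per_res
    xy_a = coords_t[:, :2] + np.array([params.inter_axis_radius, 0.0])
    xy_b = -xy_a  # 180-degree rotation about the shared axis
    s_atom = np.concatenate([s_atom_chain, s_atom_chain])
    xy = np.vstack([xy_a, xy_b])

    # centerline and transported frame on an arc-length grid
    F = wlc.vertices.shape[0]
    knots = np.arange(V) * b
    spline = CubicSpline(knots, np.moveaxis(wlc.vertices, 1, 0),
                         axis=0, bc_type="natural")
    pad = 0.05
    s_lo, s_hi = s_atom.min() - pad, s_atom.max() + pad
    grid_in = np.arange(max(s_lo, 0.0), min(s_hi, knots[-1]) + 0.025, 0.05)
    C_in = np.moveaxis(spline(grid_in), 0, 1) if len(grid_in) else np.empty((F, 0, 3))
    T_in = np.moveaxis(spline(grid_in, 1), 0, 1)
    pieces_s, pieces_C, pieces_T = [], [], []
    if s_lo < 0:
        g = np.arange(s_lo, 0.0, 0.05)
        t0 = wlc.tangents[:, 0]
        pieces_s.append(g)
        pieces_C.append(wlc.vertices[:, :1] + t0[:, None, :] * g[None, :, None])
        pieces_T.append(np.repeat(t0[:, None, :], len(g), axis=1))
    pieces_s.append(grid_in)
    pieces_C.append(C_in)
    pieces_T.append(T_in)
    if s_hi > knots[-1]:
        g = np.arange(knots[-1] + 0.05, s_hi + 0.05, 0.05)
        t1 = wlc.tangents[:, -1]
        pieces_s.append(g)
        pieces_C.append(wlc.vertices[:, -1:] + t1[:, None, :] * (g - knots[-1])[None, :, None])
        pieces_T.append(np.repeat(t1[:, None, :], len(g), axis=1))
    s_grid = np.concatenate(pieces_s)
    C_grid = np.concatenate(pieces_C, axis=1)
    T_grid = np.concatenate(pieces_T, axis=1)
    T_grid /= np.linalg.norm(T_grid, axis=-1, keepdims=True)
    n1, n2 = _transport_frames(T_grid)

    # linear interpolation of centerline and frame at every atom's arc length
    gi = np.clip(np.searchsorted(s_grid, s_atom) - 1, 0, len(s_grid) - 2)
    w = ((s_atom - s_grid[gi]) / (s_grid[gi + 1] - s_grid[gi]))[None, :, None]

    def interp(arr: np.ndarray) -> np.ndarray:
        return arr[:, gi] * (1 - w) + arr[:, gi + 1] * w

    Cc, N1, N2 = interp(C_grid), interp(n1), interp(n2)
    coords = Cc + xy[None, :, 0:1] * N1 + xy[None, :, 1:2] * N2

    res_idx = atoms_t["residue_offset"].to_numpy() + params.first_residue
    table = pd.concat(
        [
            pd.DataFrame(
                {
                    "chain_id": cid,
                    "residue_index": res_idx,
                    "residue_name": atoms_t["residue_name"],
                    "atom_name": atoms_t["atom_name"],
                }
            )
            for cid in params.chain_ids
        ],
        ignore_index=True,
    )
    times = np.arange(F, dtype=float) * params.frame_spacing
    return ConformationEnsemble(
        atoms=table,
        coords=coords,
        times=times,
        chain_ids=params.chain_ids,
        temperature=params.temperature,
    )


def rigid_rod_ensemble(
    n_frames: int = 10,
    jitter: float = 0.0,
    seed: int = 0,
    params: CoiledCoilBuildParams | None = None,
    n_vertices: int = 11,
    segment_length_nm: float = 1.5,
) -> ConformationEnsemble:
    """Identical straight coiled-coil frames, plus optional Gaussian jitter.

    The degenerate fixture: with ``jitter=0`` the persistence pipeline
    reports an infinite Lp and every H-bond count has zero SD.
    """
    if jitter < 0:
        raise ValueError("jitter must be non-negative")
    if params is None:
        params = CoiledCoilBuildParams()
    F, V = n_frames, n_vertices
    t = np.tile(np.array([0.0, 0.0, 1.0]), (F, V - 1, 1))
    vertices = np.concatenate(
        [np.zeros((F, 1, 3)), np.cumsum(segment_length_nm * t, axis=1)], axis=1
    )
    wlc = WLCEnsemble(
        vertices=vertices,
        tangents=t,
        params=WLCParams(
            n_vertices=V,
            segment_length_nm=segment_length_nm,
            lp_nm=1e12,
            n_frames=F,
            seed=seed,
        ),
    )
    ens = build_coiled_coil_ensemble(wlc, params)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        ens = ens.with_coords(ens.coords + rng.normal(0.0, jitter, ens.coords.shape))
    return ens
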