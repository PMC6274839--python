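"""Polygonal molecular axis of a two-chain coiled-coil.

The coiled-coil axis is approximated per frame by a polygonal line: Cα atoms
of consecutive, endpoint-sharing segments (11 residues by default, terminal
residues down-weighted to 0.5 so each segment covers about three α-helical
turns) are averaged per chain into centroids; the midpoint of the two chain
centroids is a polygon vertex; unit vectors between consecutive vertices are
the local tangents of the axis.  The profile of distances between the two
per-chain segment centroids measures how tightly the helices wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensembles import ConformationEnsemble

__all__ = [
    "SegmentScheme",
    "AxisPolyline",
    "HelixDistanceProfile",
    "weighted_centroid",
    "build_axis",
    "helix_distance_profile",
]


@dataclass(frozen=True)
class SegmentScheme:
    """Partition of the analysed span into endpoint-sharing segments.

    Segment ``i`` (0-based) covers residues
    ``first_residue + i*(segment_length-1)`` through
    ``first_residue + (i+1)*(segment_length-1)`` inclusive, so consecutive
    segments share exactly one residue.  The default scheme — 11 segments of
    11 residues starting at 106 — spans residues 106..216: segments 106-116,
    116-126, ..., 206-216.
    """

    first_residue: int = 106
    segment_length: int = 11
    n_segments: int = 11
    endpoint_weight: float = 0.5

    def __post_init__(self) -> None:
        if self.segment_length < 2:
            raise ValueError("segments need at least 2 residues")
        if self.n_segments < 2:
            raise ValueError("need at least 2 segments to define a tangent")
        if not 0 < self.endpoint_weight <= 1:
            raise ValueError("endpoint_weight must be in (0, 1]")

    @property
    def stride(self) -> int:
        return self.segment_length - 1

    @property
    def last_residue(self) -> int:
        return self.first_residue + self.n_segments * self.stride

    def segment_residues(self, i: int) -> np.ndarray:
        start = self.first_residue + i * self.stride
        return np.arange(start, start + self.segment_length)

    def weights(self) -> np.ndarray:
        w = np.ones(self.segment_length)
        w[0] = w[-1] = self.endpoint_weight
        return w

    def segment_center_residue(self, i: int) -> float:
        """Residue coordinate of the centre of segment ``i`` (may be x.5)."""
        return self.first_residue + i * self.stride + self.stride / 2.0


def weighted_centroid(positions: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Weighted mean position, sum(w p) / sum(w)."""
    positions = np.asarray(positions, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if positions.shape[0] != weights.shape[0]:
        raise ValueError("positions and weights differ in length")
    total = weights.sum()
    if total <= 0:
        raise ValueError("weights sum to zero")
    return (positions * weights[:, None]).sum(axis=0) / total


@dataclass
class AxisPolyline:
    """Per-frame polygon vertices and unit tangents of the coiled-coil axis.

    ``vertices`` has shape (n_frames, n_segments, 3); ``tangents``
    (n_frames, n_segments-1, 3) with unit rows.  ``arc_s[i]`` is the
    arc-length coordinate of tangent ``i``: the cumulative time-mean
    vertex-to-vertex distance from tangent 0 (``arc_s[0] = 0``), so the
    correlation profile has a single fixed abscissa for the whole ensemble.
    """

    vertices: np.ndarray
    tangents: np.ndarray
    mean_segment_lengths: np.ndarray  # (n_segments-1,), nm
    arc_s: np.ndarray  # (n_segments-1,), nm
    scheme: SegmentScheme | None = None

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.tangents, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("tangents must be unit vectors")
        if self.tangents.shape[1] != self.vertices.shape[1] - 1:
            raise ValueError("tangent count must be vertex count - 1")

    @property
    def n_frames(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_tangents(self) -> int:
        return self.tangents.shape[1]

    def tangent_residue_span(self, i: int) -> tuple[int, int]:
        """Residue interval spanned by tangent ``i`` (segment centres)."""
        if self.scheme is None:
            raise ValueError("axis has no segment scheme attached")
        lo = self.scheme.segment_center_residue(i)
        hi = self.scheme.segment_center_residue(i + 1)
        return int(np.floor(lo)), int(np.ceil(hi))


@dataclass
class HelixDistanceProfile:
    """Time-mean inter-helix distance per segment, with SD over frames."""

    segment_index: np.ndarray
    center_residue: np.ndarray
    d_mean: np.ndarray  # nm
    d_sd: np.ndarray  # nm

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment_index": self.segment_index,
                "center_residue": self.center_residue,
                "d_nm": self.d_mean,
                "sd_nm": self.d_sd,
            }
        )


def _chain_segment_centroids(
    ens: ConformationEnsemble, scheme: SegmentScheme
) -> np.ndarray:
    """Centroids of every segment of each chain: (n_frames, 2, n_segments, 3)."""
    w = scheme.weights()
    out = np.empty((ens.n_frames, 2, scheme.n_segments, 3))
    res = ens.atoms["residue_index"].to_numpy()
    names = ens.atoms["atom_name"].to_numpy()
    chains = ens.atoms["chain_id"].to_numpy()
    for c, cid in enumerate(ens.chain_ids):
        for i in range(scheme.n_segments):
            seg_res = scheme.segment_residues(i)
            idx = []
            for r in seg_res:
                hit = np.flatnonzero((chains == cid) & (res == r) & (names == "CA"))
                if len(hit) != 1:
                    raise ValueError(
                        f"chain {cid} residue {r}: expected exactly one CA atom, "
                        f"found {len(hit)}"
                    )
                idx.append(hit[0])
            pos = ens.coords[:, idx, :]  # (F, L, 3)
            out[:, c, i, :] = np.einsum("flk,l->fk", pos, w) / w.sum()
    return out


def build_axis(ens: ConformationEnsemble, scheme: SegmentScheme | None = None) -> AxisPolyline:
    """Construct the polygonal axis of the coiled-coil for every frame."""
    if scheme is None:
        scheme = SegmentScheme()
    cents = _chain_segment_centroids(ens, scheme)
    vertices = cents.mean(axis=1)  # midpoint of the two chain centroids
    steps = np.diff(vertices, axis=1)
    lengths = np.linalg.norm(steps, axis=-1)
    if np.any(lengths < 1e-12):
        raise ValueError("coincident consecutive vertices; tangent undefined")
    tangents = steps / lengths[..., None]
    mean_len = lengths.mean(axis=0)
    arc_s = np.concatenate([[0.0], np.cumsum(mean_len[:-1])])
    return AxisPolyline(
        vertices=vertices,
        tangents=tangents,
        mean_segment_lengths=mean_len,
        arc_s=arc_s,
        scheme=scheme,
    )


def helix_distance_profile(
    ens: ConformationEnsemble, scheme: SegmentScheme | None = None
) -> HelixDistanceProfile:
    """Distance between the two chains' segment centroids, averaged over time."""
    if scheme is None:
        scheme = SegmentScheme()
    cents = _chain_segment_centroids(ens, scheme)
    d = np.linalg.norm(cents[:, 0] - cents[:, 1], axis=-1)  # (F, n_segments)
    return HelixDistanceProfile(
        segment_index=np.arange(scheme.n_segments),
        center_residue=np.array(
            [scheme.segment_center_residue(i) for i in range(scheme.n_segments)]
        ),
        d_mean=d.mean(axis=0),
        d_sd=d.std(axis=0, ddof=1) if len(d) > 1 else np.zeros(d.shape[1]),
    )
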