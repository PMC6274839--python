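"""Main-chain hydrogen-bond detection and regional occupancy statistics.

Only backbone amide-to-carbonyl bonds (N-H...O=C) are considered.  A donor
nitrogen and acceptor carbonyl oxygen form a bond when their distance is
within a cutoff (default 0.35 nm) and, when an amide hydrogen is present,
the H-N...O angle is within an angular cutoff (default 30 degrees) — the
common geometric convention of MD trajectory analysis.  Pairs closer than
two residues apart within one chain are excluded; inter-chain backbone bonds
are counted.  Without hydrogens the criterion degrades to distance-only
unless ``require_hydrogen`` is set.

Counts are aggregated over user-defined residue regions (possibly disjoint
intervals); a bond belongs to the region containing its *donor* residue, and
both chains contribute to each region's count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensembles import ConformationEnsemble, Frame

__all__ = [
    "HBondCriterion",
    "RegionSpec",
    "RegionHBondStats",
    "detect_mainchain_hbonds",
    "region_hbond_stats",
]


@dataclass(frozen=True)
class HBondCriterion:
    max_donor_acceptor_distance: float = 0.35  # nm, N...O
    max_hydrogen_donor_acceptor_angle: float = 30.0  # degrees, H-N...O
    require_hydrogen: bool = False

    def __post_init__(self) -> None:
        if self.max_donor_acceptor_distance <= 0:
            raise ValueError("distance cutoff must be positive")
        if not 0 < self.max_hydrogen_donor_acceptor_angle <= 90:
            raise ValueError("angle cutoff must be in (0, 90] degrees")


@dataclass(frozen=True)
class RegionSpec:
    """Named set of inclusive residue intervals, applied to both chains."""

    name: str
    residue_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        ivs = sorted(self.residue_intervals)
        for (a_lo, a_hi), (b_lo, b_hi) in zip(ivs[:-1], ivs[1:]):
            if b_lo <= a_hi:
                raise ValueError(
                    f"region {self.name!r}: intervals overlap "
                    f"({a_lo}-{a_hi} and {b_lo}-{b_hi})"
                )
        for lo, hi in ivs:
            if hi < lo:
                raise ValueError(f"region {self.name!r}: empty interval {lo}-{hi}")

    def contains(self, residues: np.ndarray) -> np.ndarray:
        mask = np.zeros(len(residues), dtype=bool)
        for lo, hi in self.residue_intervals:
            mask |= (residues >= lo) & (residues <= hi)
        return mask


@dataclass
class RegionHBondStats:
    region: RegionSpec
    counts: np.ndarray  # per-frame bond counts, both chains
    mean: float
    sd: float

    @classmethod
    def from_counts(cls, region: RegionSpec, counts: np.ndarray) -> "RegionHBondStats":
        counts = np.asarray(counts)
        sd = float(counts.std(ddof=1)) if len(counts) > 1 else 0.0
        return cls(region=region, counts=counts, mean=float(counts.mean()), sd=sd)


@dataclass
class _BackboneIndex:
    """Pre-resolved donor/acceptor atom indices for one atom table."""

    donor_n: np.ndarray  # indices of backbone N atoms (the donors)
    donor_h: np.ndarray  # matching H index or -1
    donor_chain: np.ndarray
    donor_res: np.ndarray
    acc_o: np.ndarray  # indices of backbone O atoms (the acceptors)
    acc_chain: np.ndarray
    acc_res: np.ndarray


def _index_backbone(atoms: pd.DataFrame) -> _BackboneIndex:
    names = atoms["atom_name"].to_numpy()
    chains = atoms["chain_id"].to_numpy()
    res = atoms["residue_index"].to_numpy()
    n_idx = np.flatnonzero(names == "N")
    o_idx = np.flatnonzero(names == "O")
    if len(n_idx) == 0 or len(o_idx) == 0:
        raise ValueError("backbone N and O atoms are required for H-bond analysis")
    h_lookup = {
        (chains[i], res[i]): i for i in np.flatnonzero((names == "H") | (names == "HN"))
    }
    donor_h = np.array(
        [h_lookup.get((chains[i], res[i]), -1) for i in n_idx], dtype=int
    )
    return _BackboneIndex(
        donor_n=n_idx,
        donor_h=donor_h,
        donor_chain=chains[n_idx],
        donor_res=res[n_idx],
        acc_o=o_idx,
        acc_chain=chains[o_idx],
        acc_res=res[o_idx],
    )


def _pair_mask(bb: _BackboneIndex) -> np.ndarray:
    """Static admissibility mask (n_donors, n_acceptors): excludes pairs
    closer than 2 residues within one chain."""
    same_chain = bb.donor_chain[:, None] == bb.acc_chain[None, :]
    near = np.abs(bb.donor_res[:, None] - bb.acc_res[None, :]) < 2
    return ~(same_chain & near)


def _bond_matrix(
    coords: np.ndarray, bb: _BackboneIndex, criterion: HBondCriterion,
    admissible: np.ndarray,
) -> np.ndarray:
    """Boolean bond matrix (n_donors, n_acceptors) for one frame."""
    dn = coords[bb.donor_n]
    ao = coords[bb.acc_o]
    diff = dn[:, None, :] - ao[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    bonds = admissible & (dist <= criterion.max_donor_acceptor_distance)
    have_h = bb.donor_h >= 0
    if criterion.require_hydrogen and not have_h.all():
        missing = bb.donor_res[~have_h]
        raise ValueError(
            "amide hydrogens missing for donor residues "
            f"{missing[:5].tolist()}...: add hydrogens or use the "
            "distance-only criterion (require_hydrogen=False)"
        )
    if have_h.any():
        # H-N...O angle for donors that carry a hydrogen
        hi = np.where(have_h, bb.donor_h, 0)
        nh = coords[hi] - dn  # N->H
        no = -diff  # N->O, (D, A, 3)
        cosang = np.einsum("dk,dak->da", nh, no)
        cosang /= np.maximum(np.linalg.norm(nh, axis=-1)[:, None], 1e-12) * np.maximum(
            dist, 1e-12
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        angle_ok = ang <= criterion.max_hydrogen_donor_acceptor_angle
        bonds &= angle_ok | ~have_h[:, None]
    return bonds


def detect_mainchain_hbonds(
    frame: Frame, criterion: HBondCriterion | None = None
) -> list[tuple[tuple[str, int], tuple[str, int]]]:
    """Backbone hydrogen bonds in one frame.

    Returns ``((donor_chain, donor_residue), (acceptor_chain,
    acceptor_residue))`` pairs, donors being amide nitrogens and acceptors
    carbonyl oxygens.
    """
    if criterion is None:
        criterion = HBondCriterion()
    bb = _index_backbone(frame.atoms)
    bonds = _bond_matrix(frame.coords, bb, criterion, _pair_mask(bb))
    d_ix, a_ix = np.nonzero(bonds)
    return [
        (
            (str(bb.donor_chain[d]), int(bb.donor_res[d])),
            (str(bb.acc_chain[a]), int(bb.acc_res[a])),
        )
        for d, a in zip(d_ix, a_ix)
    ]


def region_hbond_stats(
    ens: ConformationEnsemble,
    regions: list[RegionSpec],
    criterion: HBondCriterion | None = None,
    frame_chunk: int = 200,
) -> list[RegionHBondStats]:
    """Per-region backbone H-bond counts over all frames (mean +/- SD).

    A bond is assigned to every region containing its donor residue,
    summed over both chains.
    """
    if criterion is None:
        criterion = HBondCriterion()
    if not regions:
        raise ValueError("no regions given")
    bb = _index_backbone(ens.atoms)
    admissible = _pair_mask(bb)
    ens_res = set(ens.atoms["residue_index"])
    region_masks = []
    for reg in regions:
        mask = reg.contains(bb.donor_res)
        covered = {int(r) for lo, hi in reg.residue_intervals for r in range(lo, hi + 1)}
        if not covered & ens_res:
            raise ValueError(f"region {reg.name!r} lies outside the ensemble residues")
        region_masks.append(mask)
    counts = np.zeros((len(regions), ens.n_frames), dtype=int)
    for f in range(ens.n_frames):
        bonds = _bond_matrix(ens.coords[f], bb, criterion, admissible)
        per_donor = bonds.sum(axis=1)
        for r, mask in enumerate(region_masks):
            counts[r, f] = int(per_donor[mask].sum())
    return [
        RegionHBondStats.from_counts(reg, counts[r])
        for r, reg in enumerate(regions)
    ]


def stats_table(stats: list[RegionHBondStats]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region": [s.region.name for s in stats],
            "mean": [s.mean for s in stats],
            "sd": [s.sd for s in stats],
            "n_frames": [len(s.counts) for s in stats],
        }
    )
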