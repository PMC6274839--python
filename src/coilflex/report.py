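"""End-to-end analysis orchestration and cross-condition comparison.

``run_analysis`` executes the whole pipeline on one condition — trim the
equilibration phase, superpose, build the polygonal axis, correlation
profile, persistence-length fits (least squares and secant), flexibility
profile, inter-helix distances and regional H-bond statistics — and writes
TSV/JSON artifacts.  ``compare_conditions`` turns several condition
summaries into a comparison table: persistence-length ratios against a
named reference (least squares, with the secant ratio in brackets),
per-region percent changes in mean H-bond counts, and Student's t-tests on
block-wise persistence-length estimates.

Display rounding follows the conventional table format: ratios to two
decimals, percent changes to the nearest percent, Lp to one decimal; full
precision is kept in the JSON artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .axis import SegmentScheme, build_axis, helix_distance_profile
from .ensembles import (
    ConformationEnsemble,
    SelectionSpec,
    read_ensemble,
    superpose,
    trim_equilibration,
)
from .hbonds import HBondCriterion, RegionSpec, RegionHBondStats, region_hbond_stats
from .persistence import (
    PersistenceEstimate,
    blockwise_lp,
    compare_lp,
    correlation_profile,
    fit_lp_least_squares,
    fit_lp_secant,
    flexibility_profile,
)

logger = logging.getLogger("coilflex")

__all__ = [
    "AnalysisConfig",
    "ConditionResult",
    "ConditionSummary",
    "ComparisonReport",
    "default_regions",
    "run_analysis",
    "compare_conditions",
    "format_ratio",
    "percent_change",
]


def default_regions() -> list[RegionSpec]:
    """The three reporting regions of the analysed fragment: the flanks of
    the most labile stretch, the stretch around the protease-sensitive
    133/134 bond, and the C-terminal half."""
    return [
        RegionSpec("res_106-129_138-160", ((106, 129), (138, 160))),
        RegionSpec("res_129-138", ((129, 138),)),
        RegionSpec("res_161-215", ((161, 215),)),
    ]


@dataclass
class AnalysisConfig:
    """Everything one condition's analysis depends on."""

    name: str = "condition"
    input_path: str | None = None
    input_format: str = "pdb"
    chain_ids: tuple[str, str] = ("A", "B")
    temperature: float = 300.0  # K
    t_start_ps: float = 0.0  # equilibration trim
    scheme: SegmentScheme = field(default_factory=SegmentScheme)
    align: bool = True
    hbond_criterion: HBondCriterion = field(default_factory=HBondCriterion)
    regions: list[RegionSpec] = field(default_factory=default_regions)
    n_blocks: int = 8
    output_dir: str | None = None

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            if isinstance(o, frozenset):
                return sorted(o)
            return o

        payload = json.dumps(enc(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ConditionSummary:
    """The numbers a cross-condition comparison needs.

    Constructible from a full pipeline run or directly from reported
    values (e.g. to re-run the ratio arithmetic of a published table).
    """

    name: str
    lp_lsq_nm: float
    lp_secant_nm: float
    temperature: float = 300.0
    hbond_means: dict[str, float] = field(default_factory=dict)
    blockwise_lp_nm: list[float] = field(default_factory=list)
    region_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.region_names:
            self.region_names = tuple(self.hbond_means)


@dataclass
class ConditionResult:
    """Full output of one condition's pipeline run."""

    config: AnalysisConfig
    n_frames: int
    lp_lsq: PersistenceEstimate
    lp_secant: PersistenceEstimate
    blockwise_lp_nm: list[float]
    correlation: pd.DataFrame
    flexibility: pd.DataFrame
    most_flexible: tuple[int, int]
    distances: pd.DataFrame
    hbond_stats: list[RegionHBondStats]

    def summary(self) -> ConditionSummary:
        return ConditionSummary(
            name=self.config.name,
            lp_lsq_nm=self.lp_lsq.lp_nm,
            lp_secant_nm=self.lp_secant.lp_nm,
            temperature=self.config.temperature,
            hbond_means={s.region.name: s.mean for s in self.hbond_stats},
            blockwise_lp_nm=list(self.blockwise_lp_nm),
        )

    def lp_display(self) -> str:
        """Lp formatted as ``98.4 ± 3.9 (110.8)`` (least squares, secant)."""
        return (
            f"{self.lp_lsq.lp_nm:.1f} ± {self.lp_lsq.lp_se_nm:.1f} "
            f"({self.lp_secant.lp_nm:.1f})"
        )


def run_analysis(
    config: AnalysisConfig, ens: ConformationEnsemble | None = None
) -> ConditionResult:
    """Run the full single-condition pipeline; optionally write artifacts.

    ``ens`` may be passed directly (e.g. from the synthetic generator);
    otherwise it is read from ``config.input_path``.
    """

    current_stage = {"name": "setup"}

    def stage(name: str):
        current_stage["name"] = name
        logger.info("[%s] stage: %s", config.name, name)

    try:
        if ens is None:
            stage("read_ensemble")
            if config.input_path is None:
                raise ValueError("no input ensemble and no input_path configured")
            ens = read_ensemble(
                config.input_path,
                format=config.input_format,
                chain_ids=config.chain_ids,
                temperature=config.temperature,
            )
        stage("trim_equilibration")
        ens = trim_equilibration(ens, config.t_start_ps)
        logger.info("[%s] %d frames after trimming", config.name, ens.n_frames)
        if config.align:
            stage("superpose")
            sel = SelectionSpec(
                chain_ids=config.chain_ids,
                residue_range=(config.scheme.first_residue, config.scheme.last_residue),
            )
            ens = superpose(ens, sel)
        stage("build_axis")
        axis = build_axis(ens, config.scheme)
        stage("correlation_profile")
        # after mean-structure superposition the body frame must be
        # re-anchored at the chain start for the profile to decay with s
        prof = correlation_profile(axis, n_blocks=config.n_blocks,
                                   anchor_first=config.align)
        stage("persistence_fits")
        lsq = fit_lp_least_squares(prof, config.temperature)
        sec = fit_lp_secant(prof, config.temperature)
        try:
            blocks = blockwise_lp(
                axis, config.temperature, n_blocks=config.n_blocks,
                anchor_first=config.align,
            )
        except ValueError:
            blocks = []
        stage("flexibility_profile")
        flex = flexibility_profile(prof, config.scheme)
        stage("helix_distance_profile")
        dist = helix_distance_profile(ens, config.scheme)
        stage("region_hbond_stats")
        try:
            hb = region_hbond_stats(ens, config.regions, config.hbond_criterion)
        except ValueError as exc:
            if "backbone N and O" in str(exc):
                logger.warning("[%s] no backbone N/O atoms; H-bond stage skipped",
                               config.name)
                hb = []
            else:
                raise
    except Exception as exc:
        raise type(exc)(
            f"[condition {config.name}, stage {current_stage['name']}] {exc}"
        ) from exc

    result = ConditionResult(
        config=config,
        n_frames=ens.n_frames,
        lp_lsq=lsq,
        lp_secant=sec,
        blockwise_lp_nm=blocks,
        correlation=prof.to_frame(),
        flexibility=flex.to_frame(),
        most_flexible=flex.most_flexible_region(),
        distances=dist.to_frame(),
        hbond_stats=hb,
    )
    if config.output_dir is not None:
        _write_artifacts(result)
    return result


def _write_artifacts(result: ConditionResult) -> None:
    out = Path(result.config.output_dir) / result.config.name
    out.mkdir(parents=True, exist_ok=True)
    chash = result.config.config_hash()
    result.correlation.to_csv(out / "correlation.tsv", sep="\t", index=False)
    result.flexibility.to_csv(out / "flexibility.tsv", sep="\t", index=False)
    result.distances.to_csv(out / "distances.tsv", sep="\t", index=False)
    if result.hbond_stats:
        from .hbonds import stats_table

        stats_table(result.hbond_stats).to_csv(out / "hbonds.tsv", sep="\t", index=False)
    payload = {
        "config_hash": chash,
        "condition": result.config.name,
        "n_frames": result.n_frames,
        "estimates": [result.lp_lsq.to_dict(), result.lp_secant.to_dict()],
        "blockwise_Lp_nm": result.blockwise_lp_nm,
        "most_flexible_region": list(result.most_flexible),
    }
    (out / "estimates.json").write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Cross-condition comparison
# ---------------------------------------------------------------------------

def format_ratio(a: float, b: float) -> str:
    return f"{a / b:.2f}"


def percent_change(reference: float, value: float) -> int:
    """Percent decrease from reference to value, nearest percent.

    ``percent_change(9.7, 6.1)`` is 37 (a 37% decrease); increases come out
    negative.
    """
    if reference == 0:
        raise ValueError("reference mean is zero")
    return round((reference - value) / reference * 100.0)


@dataclass
class ComparisonReport:
    reference: str
    table: pd.DataFrame  # one row per condition
    hbond_changes: pd.DataFrame  # percent change per region vs reference
    p_values: dict[str, float]

    def self_consistent(self, tol: float = 5e-3) -> bool:
        """Check the displayed ratios against the stored Lp columns."""
        ref = self.table[self.table["condition"] == self.reference].iloc[0]
        for _, row in self.table.iterrows():
            want = (
                f"{row['Lp_lsq_nm'] / ref['Lp_lsq_nm']:.2f}"
                f"({row['Lp_secant_nm'] / ref['Lp_secant_nm']:.2f})"
            )
            if row["Lp_ratio"] != want:
                return False
        return True


def compare_conditions(
    summaries: list[ConditionSummary], reference: str
) -> ComparisonReport:
    """Compare several conditions against a named reference condition.

    The ratio column is formatted ``lsq(secant)`` to two decimals, e.g.
    ``1.44(1.37)``.  H-bond percent changes are reported per region,
    relative to the reference condition's mean.  When both conditions carry
    block-wise Lp estimates, a two-tailed equal-variance t-test p-value is
    reported.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 conditions to compare")
    by_name = {s.name: s for s in summaries}
    if reference not in by_name:
        raise ValueError(f"reference condition {reference!r} not among summaries")
    ref = by_name[reference]
    region_sets = {tuple(sorted(s.hbond_means)) for s in summaries if s.hbond_means}
    if len(region_sets) > 1:
        raise ValueError("conditions carry mismatched H-bond region sets")
    rows, p_values, hb_rows = [], {}, []
    for s in summaries:
        ratio = (
            f"{s.lp_lsq_nm / ref.lp_lsq_nm:.2f}"
            f"({s.lp_secant_nm / ref.lp_secant_nm:.2f})"
        )
        rows.append(
            {
                "condition": s.name,
                "T_K": s.temperature,
                "Lp_lsq_nm": s.lp_lsq_nm,
                "Lp_secant_nm": s.lp_secant_nm,
                "Lp_ratio": ratio,
            }
        )
        if s.name != reference and len(s.blockwise_lp_nm) >= 2 and len(ref.blockwise_lp_nm) >= 2:
            a = PersistenceEstimate(s.lp_lsq_nm, float("nan"), "least_squares",
                                    s.temperature, 1.0)
            b = PersistenceEstimate(ref.lp_lsq_nm, float("nan"), "least_squares",
                                    ref.temperature, 1.0)
            _, p = compare_lp(a, b, s.blockwise_lp_nm, ref.blockwise_lp_nm)
            p_values[s.name] = p
        for region, mean in s.hbond_means.items():
            hb_rows.append(
                {
                    "condition": s.name,
                    "region": region,
                    "mean": mean,
                    "percent_change_vs_ref": percent_change(
                        ref.hbond_means[region], mean
                    ),
                }
            )
    report = ComparisonReport(
        reference=reference,
        table=pd.DataFrame(rows),
        hbond_changes=pd.DataFrame(hb_rows),
        p_values=p_values,
    )
    assert report.self_consistent(), "ratio column inconsistent with Lp columns"
    return report
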