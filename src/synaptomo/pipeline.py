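"""Config-driven end-to-end orchestration.

One run reproduces the two analyses of the study design on a cohort of
mice: synapse density (total and GFP-positive presynapses, % GFP-positive)
and tau spread (% postsynapses tau-positive, % synaptic pairs tau-positive),
followed by per-mouse aggregation and group statistics.

Stages per mouse: read or generate the serial-section series → align →
crop ROIs → binarize each channel → label 3D components → single-section
filter → densities and classifications → pooled per-mouse statistics.
All randomness flows from the single run seed; identical config + seed
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc_pairing, group_stats, puncta3d, registration, segmentation
from .errors import ConfigError
from .stack_io import (
    ROLE_GFP,
    ROLE_POSTSYNAPSE,
    ROLE_PRESYNAPSE,
    ROLE_TAU,
    SectionSeries,
    crop_roi,
    read_series,
    series_to_stacks,
)
from .synthetic_data import GroundTruth, SceneConfig, generate_scene

AGE_GROUPS = ("3-6", "9", "18")
GENOTYPE_TG = "rTgTauEC"
GENOTYPE_CTRL = "control"

# statistic → (aggregation rule, group-test branch mirroring the original
# analysis: ANOVA for the normally distributed density family, Kruskal–Wallis
# for the colocalization percentages).  Branches are overridable per run.
STATISTICS = {
    "density_total_pre": ("mean", "anova"),
    "density_gfp_pre": ("mean", "anova"),
    "pct_gfp_pre": ("sum_ratio", "anova"),
    "pct_post_tau": ("sum_ratio", "kruskal_wallis"),
    "pct_pairs_tau": ("sum_ratio", "kruskal_wallis"),
}


@dataclass(frozen=True)
class MouseSpec:
    mouse_id: str
    genotype: str
    age_group: str


@dataclass
class RunConfig:
    """Full description of one cohort analysis run."""

    mice: list[MouseSpec]
    scene: SceneConfig = field(default_factory=SceneConfig)
    mode: str = "synthetic"                     # "synthetic" | "tiff"
    # ordered (match, set) pairs: scene-field overrides for matching mice
    scene_overrides: list[tuple[dict, dict]] = field(default_factory=list)
    channel_paths: dict[str, dict[str, str]] = field(default_factory=dict)  # tiff mode
    pixel_size_um: float = 0.1
    section_thickness_um: float = 0.07
    crops: list[tuple[tuple[float, float], tuple[float, float]]] | None = None
    analyses: dict[str, bool] = field(
        default_factory=lambda: dict(density=True, gfp_percent=True,
                                     tau_coloc=True, pairs=True)
    )
    min_overlap: float = 0.5
    max_pair_dist_um: float = 0.5
    threshold_method: str = "combined"
    exclude_border: bool = False
    reference_channel: str = ROLE_PRESYNAPSE
    search_radius: int = 10
    branch_override: dict[str, str | None] = field(default_factory=dict)
    out_dir: str | None = None
    write_masks: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in ("synthetic", "tiff"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not self.mice:
            raise ConfigError("at least one mouse is required")
        if not 0 <= self.min_overlap <= 1:
            raise ConfigError("min_overlap must be in [0, 1]")
        if self.max_pair_dist_um < 0:
            raise ConfigError("max_pair_dist_um must be nonnegative")
        if self.mode == "tiff":
            for m in self.mice:
                if m.mouse_id not in self.channel_paths:
                    raise ConfigError(f"no channel files for mouse {m.mouse_id!r}")


def scene_for_mouse(config: RunConfig, mouse: MouseSpec, index: int) -> SceneConfig:
    """Per-mouse scene: base config + matching overrides + derived seed."""
    fields = dataclasses.asdict(config.scene)
    for match, settings in config.scene_overrides:
        ok = all(
            getattr(mouse, key) == value for key, value in match.items()
        )
        if ok:
            fields.update(settings)
    fields["footprint_um"] = tuple(fields["footprint_um"])
    fields["punctum_radius_um"] = tuple(fields["punctum_radius_um"])
    fields["punctum_span_sections"] = tuple(fields["punctum_span_sections"])
    fields["amplitude_dim"] = tuple(fields["amplitude_dim"])
    fields["amplitude_bright"] = tuple(fields["amplitude_bright"])
    seed = int(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(100 + index,))
        .generate_state(1)[0] % (2**31)
    )
    fields["seed"] = seed
    return SceneConfig(**fields)


@dataclass
class CropMeasurements:
    """Raw counts and densities for one image crop of one mouse."""

    volume_um3: float
    n_total_pre: int = 0
    n_gfp_pre: int = 0
    n_post: int = 0
    n_post_tau: int = 0
    n_pairs: int = 0
    n_pairs_tau: int = 0
    density_total_pre: float | None = None
    density_gfp_pre: float | None = None


@dataclass
class MouseResult:
    spec: MouseSpec
    crops: list[CropMeasurements]
    transform: registration.AlignmentTransform | None
    ground_truth: GroundTruth | None
    puncta_tables: dict[str, pd.DataFrame] = field(default_factory=dict)


@dataclass
class RunResult:
    config: RunConfig
    mice: list[MouseResult]
    summary: pd.DataFrame
    stats: dict[str, dict]
    log: list[str]


def _measure_crop(
    stacks: dict,
    config: RunConfig,
    log: list[str],
) -> tuple[CropMeasurements, dict[str, pd.DataFrame]]:
    """Run segmentation → labelling → filtering → measurements on one crop."""
    masks = {
        role: segmentation.binarize_stack(stack, method=config.threshold_method)
        for role, stack in stacks.items()
    }
    collections = {}
    for role in (ROLE_PRESYNAPSE, ROLE_POSTSYNAPSE):
        if role in masks:
            pc = puncta3d.label_components(masks[role], exclude_border=config.exclude_border)
            collections[role] = puncta3d.filter_single_section(pc)

    any_stack = next(iter(stacks.values()))
    meas = CropMeasurements(volume_um3=any_stack.physical_volume_um3)
    tables: dict[str, pd.DataFrame] = {}
    toggles = config.analyses

    pre = collections.get(ROLE_PRESYNAPSE)
    post = collections.get(ROLE_POSTSYNAPSE)
    if pre is not None:
        tables[ROLE_PRESYNAPSE] = puncta3d.to_dataframe(pre)
        meas.n_total_pre = len(pre)
        if toggles.get("density", True):
            meas.density_total_pre = puncta3d.density(pre)
    if post is not None:
        tables[ROLE_POSTSYNAPSE] = puncta3d.to_dataframe(post)
        meas.n_post = len(post)

    gfp_pre_ids: set[int] = set()
    if pre is not None and ROLE_GFP in masks and (
        toggles.get("gfp_percent", True) or toggles.get("pairs", True)
        or toggles.get("density", True)
    ):
        gfp_records = coloc_pairing.classify_overlap(
            pre, masks[ROLE_GFP], config.min_overlap
        )
        gfp_pre_ids = {r.punctum_id for r in gfp_records if r.positive}
        meas.n_gfp_pre = len(gfp_pre_ids)
        if toggles.get("density", True):
            meas.density_gfp_pre = meas.n_gfp_pre / meas.volume_um3

    post_tau_records = []
    if post is not None and ROLE_TAU in masks and toggles.get("tau_coloc", True):
        post_tau_records = coloc_pairing.classify_overlap(
            post, masks[ROLE_TAU], config.min_overlap
        )
        meas.n_post_tau = sum(r.positive for r in post_tau_records)

    if (
        pre is not None and post is not None and ROLE_TAU in masks
        and toggles.get("pairs", True)
    ):
        gfp_pre_coll = replace(
            pre, puncta=[p for p in pre if p.id in gfp_pre_ids]
        )
        pairs = coloc_pairing.find_pairs(
            gfp_pre_coll, post, config.max_pair_dist_um
        )
        meas.n_pairs = len(pairs)
        pre_tau_records = coloc_pairing.classify_overlap(
            gfp_pre_coll, masks[ROLE_TAU], config.min_overlap
        )
        if not post_tau_records:
            post_tau_records = coloc_pairing.classify_overlap(
                post, masks[ROLE_TAU], config.min_overlap
            )
        pre_pos = {r.punctum_id: r.positive for r in pre_tau_records}
        post_pos = {r.punctum_id: r.positive for r in post_tau_records}
        meas.n_pairs_tau = sum(
            pre_pos.get(p.pre_id, False) and post_pos.get(p.post_id, False)
            for p in pairs
        )
    return meas, tables


def _load_series(config: RunConfig, mouse: MouseSpec, index: int):
    if config.mode == "synthetic":
        scene = scene_for_mouse(config, mouse, index)
        gt, series = generate_scene(scene)
        return series, gt
    series = read_series(
        config.channel_paths[mouse.mouse_id],
        config.pixel_size_um,
        config.section_thickness_um,
    )
    return series, None


def process_mouse(config: RunConfig, mouse: MouseSpec, index: int) -> MouseResult:
    series, gt = _load_series(config, mouse, index)
    stacks, transform = registration.align_series(
        series, config.reference_channel, config.search_radius
    )
    log: list[str] = []
    crops = config.crops
    if crops is None:
        any_stack = next(iter(stacks.values()))
        crops = [((0.0, 0.0), any_stack.footprint_um())]
    crop_results, tables = [], {}
    for ci, (origin, size) in enumerate(crops):
        cropped = {role: crop_roi(s, origin, size) for role, s in stacks.items()}
        meas, crop_tables = _measure_crop(cropped, config, log)
        crop_results.append(meas)
        for role, table in crop_tables.items():
            tables[f"crop{ci}_{role}"] = table
    return MouseResult(
        spec=mouse, crops=crop_results, transform=transform,
        ground_truth=gt, puncta_tables=tables,
    )


def _summarise_mouse(mr: MouseResult, config: RunConfig) -> dict:
    row: dict = dict(
        mouse=mr.spec.mouse_id,
        genotype=mr.spec.genotype,
        age_months=mr.spec.age_group,
    )
    toggles = config.analyses
    if toggles.get("density", True):
        row["density_total_pre"] = group_stats.aggregate_mouse(
            [c.density_total_pre for c in mr.crops], "mean"
        )
        row["density_gfp_pre"] = group_stats.aggregate_mouse(
            [c.density_gfp_pre for c in mr.crops], "mean"
        )
    if toggles.get("gfp_percent", True):
        row["pct_gfp_pre"] = group_stats.aggregate_mouse(
            [(c.n_gfp_pre, c.n_total_pre) for c in mr.crops], "sum_ratio"
        )
    if toggles.get("tau_coloc", True):
        row["pct_post_tau"] = group_stats.aggregate_mouse(
            [(c.n_post_tau, c.n_post) for c in mr.crops], "sum_ratio"
        )
    if toggles.get("pairs", True):
        row["pct_pairs_tau"] = group_stats.aggregate_mouse(
            [(c.n_pairs_tau, c.n_pairs) for c in mr.crops], "sum_ratio"
        )
    return row


def _group_statistics(summary: pd.DataFrame, config: RunConfig, log: list[str]) -> dict:
    """Run the per-statistic omnibus tests over the cohort design."""
    stats: dict[str, dict] = {}
    genotypes = sorted(summary["genotype"].unique())
    for stat, (_, default_branch) in STATISTICS.items():
        if stat not in summary.columns:
            continue
        values = summary[stat].dropna()
        if values.nunique() < 2 or len(values) < 3:
            log.append(f"{stat}: too few distinct values for a group test; skipped")
            continue
        branch = config.branch_override.get(stat, default_branch)
        if branch is None:
            branch = group_stats.choose_branch(values.tolist())
            log.append(f"{stat}: Shapiro–Wilk gate chose {branch}")
        else:
            log.append(f"{stat}: branch fixed to {branch} by config")
        entry: dict = {"branch": branch}
        if branch == "anova":
            sub = summary.dropna(subset=[stat])
            if sub["genotype"].nunique() >= 2 and sub["age_months"].nunique() >= 2:
                try:
                    entry["anova"] = group_stats.two_way_anova(
                        sub[stat].tolist(),
                        sub["genotype"].tolist(),
                        sub["age_months"].tolist(),
                    )
                except ConfigError as exc:
                    log.append(f"{stat}: ANOVA not estimable ({exc}); skipped")
            else:
                log.append(f"{stat}: design has a single factor level; ANOVA skipped")
        else:
            # rank test across age groups within each genotype (tau statistics
            # are structurally zero in controls, where H degenerates to 0)
            kw: dict[str, group_stats.GroupResult] = {}
            for g in genotypes:
                sub = summary[summary["genotype"] == g].dropna(subset=[stat])
                groups = [
                    sub[sub["age_months"] == a][stat].tolist()
                    for a in sorted(sub["age_months"].unique())
                ]
                groups = [g_ for g_ in groups if g_]
                if len(groups) >= 2:
                    kw[g] = group_stats.kruskal_wallis(groups)
            if kw:
                entry["kruskal_wallis"] = kw
        stats[stat] = entry
    return stats


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute the full cohort analysis; see module docstring for stages."""
    config.validate()
    log: list[str] = [f"run seed: {config.seed}", f"mode: {config.mode}"]
    log.append(f"parameters: min_overlap={config.min_overlap}, "
               f"max_pair_dist_um={config.max_pair_dist_um}, "
               f"threshold={config.threshold_method}, "
               f"exclude_border={config.exclude_border}")
    mice_results = []
    for index, mouse in enumerate(config.mice):
        try:
            mice_results.append(process_mouse(config, mouse, index))
        except Exception as exc:
            raise ConfigError(
                f"pipeline failed for mouse {mouse.mouse_id!r} "
                f"({mouse.genotype}, {mouse.age_group} months): {exc}. "
                f"Check the channel sources and search radius for this mouse."
            ) from exc
        log.append(f"mouse {mouse.mouse_id}: {len(mice_results[-1].crops)} crop(s)")

    summary = pd.DataFrame([_summarise_mouse(mr, config) for mr in mice_results])
    stats = _group_statistics(summary, config, log)

    result = RunResult(config=config, mice=mice_results, summary=summary,
                       stats=stats, log=log)
    if config.out_dir is not None:
        write_outputs(result, Path(config.out_dir))
    return result


# --------------------------------------------------------------------------
# reporting

def _stats_rows(stats: dict) -> list[dict]:
    rows = []
    for stat, entry in stats.items():
        if "anova" in entry:
            res = entry["anova"]
            for term, tr in res.terms.items():
                if term == "residual":
                    continue
                rows.append(dict(statistic=stat, test="two_way_anova", term=term,
                                 value=tr.statistic, df=tr.df, p=tr.p_value))
        if "kruskal_wallis" in entry:
            for genotype, res in entry["kruskal_wallis"].items():
                rows.append(dict(statistic=stat, test="kruskal_wallis",
                                 term=f"age within {genotype}",
                                 value=res.statistic, df=res.df, p=res.p_value))
    return rows


def make_report(result: RunResult) -> str:
    """Human-readable summary: group descriptives plus omnibus tests.

    Density-family statistics are reported as mean ± SEM, colocalization
    percentages as median and interquartile range, matching the reporting
    conventions of the two analysis families.
    """
    if result.summary.empty:
        raise ConfigError("cannot report on an empty result bundle")
    lines = ["Synapse quantification report", "=" * 31, ""]
    summary = result.summary
    mean_sem_stats = [s for s in ("density_total_pre", "density_gfp_pre", "pct_gfp_pre")
                      if s in summary.columns]
    med_iqr_stats = [s for s in ("pct_post_tau", "pct_pairs_tau")
                     if s in summary.columns]
    grouped = summary.groupby(["genotype", "age_months"], sort=True)

    if mean_sem_stats:
        lines.append("Density family (mean ± SEM per group):")
        for (gen, age), sub in grouped:
            parts = []
            for s in mean_sem_stats:
                vals = sub[s].dropna()
                if len(vals) == 0:
                    continue
                sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                parts.append(f"{s}={vals.mean():.4g}±{sem:.3g}")
            lines.append(f"  {gen} / {age} mo (n={len(sub)}): " + ", ".join(parts))
        lines.append("")
    if med_iqr_stats:
        lines.append("Colocalization family (median [IQR] per group):")
        for (gen, age), sub in grouped:
            parts = []
            for s in med_iqr_stats:
                vals = sub[s].dropna()
                if len(vals) == 0:
                    continue
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                parts.append(f"{s}={med:.4g} [{q1:.4g}, {q3:.4g}]")
            lines.append(f"  {gen} / {age} mo (n={len(sub)}): " + ", ".join(parts))
        lines.append("")

    rows = _stats_rows(result.stats)
    if rows:
        lines.append("Group tests:")
        for r in rows:
            lines.append(
                f"  {r['statistic']}: {r['test']} [{r['term']}] "
                f"stat={r['value']:.4g}, df={r['df']}, p={r['p']:.4g}"
            )
    else:
        lines.append("Group tests: none (single group or missing statistics).")
    return "\n".join(lines) + "\n"


def write_outputs(result: RunResult, out_dir: Path) -> None:
    """Write summary CSV, statistics CSV, report, log and puncta tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out_dir / "summary.csv", index=False)
    pd.DataFrame(_stats_rows(result.stats)).to_csv(out_dir / "group_stats.csv", index=False)
    (out_dir / "report.txt").write_text(make_report(result))
    (out_dir / "run_log.txt").write_text("\n".join(result.log) + "\n")
    puncta_dir = out_dir / "puncta"
    puncta_dir.mkdir(exist_ok=True)
    for mr in result.mice:
        if mr.transform is not None:
            mr.transform.write_csv(puncta_dir / f"{mr.spec.mouse_id}_alignment.csv")
        for name, table in mr.puncta_tables.items():
            table.to_csv(puncta_dir / f"{mr.spec.mouse_id}_{name}.csv", index=False)


# --------------------------------------------------------------------------
# default cohort: the study design

def default_cohort(
    seed: int = 0,
    mice_per_group: dict[str, list[int]] | None = None,
    out_dir: str | None = None,
    **scene_kwargs,
) -> RunConfig:
    """The default synthetic cohort mirroring the study design.

    Transgenic (tau-expressing) mice n = 4 per age group and littermate
    controls n = 3, 3, 6 at ages 3–6, 9 and 18 months.  Tau is planted only
    in the transgenic genotype, at postsynaptic fractions of 0.10, 0.08 and
    0.09 per age group; controls carry no tau.  The GFP-positive presynapse
    fraction differs by genotype (0.35 vs 0.25) so a genotype effect exists
    to detect.
    """
    counts = mice_per_group or {GENOTYPE_TG: [4, 4, 4], GENOTYPE_CTRL: [3, 3, 6]}
    mice = []
    for genotype, ns in counts.items():
        for age, n in zip(AGE_GROUPS, ns):
            for i in range(n):
                mice.append(MouseSpec(f"{genotype}_{age}m_{i + 1}", genotype, age))
    post_tau_by_age = {"3-6": 0.10, "9": 0.08, "18": 0.09}
    overrides: list[tuple[dict, dict]] = [
        ({"genotype": GENOTYPE_TG}, {"frac_pre_gfp_positive": 0.35}),
        (
            {"genotype": GENOTYPE_CTRL},
            {
                "frac_pre_gfp_positive": 0.25,
                "frac_post_tau_positive": 0.0,
                "frac_pre_tau_positive": 0.0,
            },
        ),
    ]
    for age, frac in post_tau_by_age.items():
        overrides.append(
            ({"genotype": GENOTYPE_TG, "age_group": age},
             {"frac_post_tau_positive": frac})
        )
    scene = SceneConfig(**scene_kwargs) if scene_kwargs else SceneConfig()
    return RunConfig(
        mice=mice, scene=scene, scene_overrides=overrides,
        out_dir=out_dir, seed=seed,
    )


# --------------------------------------------------------------------------
# YAML config round-trip (CLI surface)

def config_from_yaml(path) -> RunConfig:
    """Load a RunConfig from a YAML file (see docs for the schema)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    mice = [MouseSpec(**m) for m in raw.pop("mice")]
    scene_raw = raw.pop("scene", {})
    for key in ("footprint_um", "punctum_radius_um", "punctum_span_sections",
                "amplitude_dim", "amplitude_bright"):
        if key in scene_raw:
            scene_raw[key] = tuple(scene_raw[key])
    scene = SceneConfig(**scene_raw)
    overrides = [
        (entry["match"], entry["set"]) for entry in raw.pop("scene_overrides", [])
    ]
    crops = raw.pop("crops", None)
    if crops is not None:
        crops = [(tuple(c["origin_um"]), tuple(c["size_um"])) for c in crops]
    return RunConfig(mice=mice, scene=scene, scene_overrides=overrides,
                     crops=crops, **raw)
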