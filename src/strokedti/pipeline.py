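"""Study orchestration: simulate → fit → ROI stats → voxelwise contrast →
IHC → behavior → report.

A study is described by a declarative config (YAML on disk, a plain dict in
memory); :func:`run_study` executes the stages in order into one run
directory, writing a manifest that records parameters, seeds and per-stage
status.  Each stage is also callable on its own against a run directory, so
chaining the CLI subcommands reproduces ``run_study`` exactly.

All volumes are written as uncompressed NIfTI (*.nii), all tables as TSV
with a fixed float format, so repeated runs under one seed are
byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .group_stats import student_t, tukey_hsd
from .ihc_quant import field_report
from .image_io import (
    ImageGrid,
    default_gradient_table,
    read_gradient_table,
    read_volume,
    render_scalar_map,
    write_volume,
)
from .roi_analysis import cohort_roi_table, roi_summary
from .synthetic_data import (
    PhantomSpec,
    simulate_behavior,
    simulate_cohort,
    simulate_ihc_cohort,
)
from .tensor_fit import eigensystem, fa_map, fit_volume, md_map
from .voxel_stats import critical_t, threshold_contrast, voxelwise_t

__all__ = ["StudyConfig", "StageError", "run_study"]

log = logging.getLogger("strokedti")

FLOAT_FMT = "%.10g"

#: groups treated as the reference arm when choosing the contrast direction
CONTROL_GROUPS = ("intact", "sham", "KO_sham")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class StudyConfig:
    """Validated study definition.

    ``cohort`` maps condition name to subject count.  ``vbm`` needs a
    two-group design; by default the control-like group is contrast side A
    (A_greater means the control exceeds the stroke group, i.e. an MD
    decrease after stroke).  An absent ``ihc``/``behavior`` section skips
    that stage.
    """

    output_dir: str = "study_run"
    seed: int = 0
    grid: tuple[int, int, int] = (64, 64, 5)
    snr: float | None = 30.0
    s0: float = 1000.0
    ca23_multiplier: float = 0.90
    infarct_multiplier: float = 1.5
    between_subject_cv: float = 0.03
    b_value: float = 1496.0
    bval_file: str | None = None
    bvec_file: str | None = None
    cohort: dict = field(default_factory=lambda: {"sham": 6, "MCAO": 6})
    weighting: str = "ols"
    roi_alpha: float = 0.05
    vbm_alpha: float = 0.001
    vbm_group_a: str | None = None
    vbm_group_b: str | None = None
    roi_region: str = "hippocampus_CA23_ipsi"
    ihc: dict | None = field(default_factory=lambda: {"n_per_group": {"sham": 4, "MCAO": 4}})
    behavior: dict | None = None

    def __post_init__(self) -> None:
        for name, a in (("roi_alpha", self.roi_alpha), ("vbm_alpha", self.vbm_alpha)):
            if not 0.0 < a < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {a}")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        for p in (self.bval_file, self.bvec_file):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"referenced file {p} does not exist")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid" in raw:
            raw["grid"] = tuple(raw["grid"])
        return cls(**raw)

    def gradient_table(self):
        if self.bval_file and self.bvec_file:
            return read_gradient_table(self.bval_file, self.bvec_file)
        return default_gradient_table(self.b_value)

    def phantom_template(self) -> PhantomSpec:
        return PhantomSpec(
            grid=ImageGrid(self.grid),
            table=self.gradient_table(),
            s0=self.s0,
            snr=self.snr,
            ca23_multiplier=self.ca23_multiplier,
            infarct_multiplier=self.infarct_multiplier,
            seed=self.seed,
        )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=FLOAT_FMT)


def _subjects_index(outdir: Path) -> pd.DataFrame:
    p = outdir / "subjects.tsv"
    if not p.exists():
        raise FileNotFoundError(f"missing {p}; run the simulate stage first")
    return pd.read_csv(p, sep="\t")


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: StudyConfig, outdir: Path) -> None:
    """Generate the cohort and write raw data plus ground truth."""
    subjects = simulate_cohort(
        dict(cfg.cohort),
        template=cfg.phantom_template(),
        base_seed=cfg.seed,
        between_subject_cv=cfg.between_subject_cv,
    )
    rows = []
    for s in subjects:
        write_volume(s.stack, outdir / f"{s.subject_id}_dwi.nii")
        write_volume(s.labels, outdir / f"{s.subject_id}_labels.nii")
        write_volume(s.truth_md, outdir / f"{s.subject_id}_truth_md.nii")
        rows.append((s.subject_id, s.condition))
        log.info("simulate: wrote subject %s (%s)", s.subject_id, s.condition)
    _write_tsv(pd.DataFrame(rows, columns=["subject_id", "group"]), outdir / "subjects.tsv")


def stage_fit(cfg: StudyConfig, outdir: Path) -> None:
    """Tensor-fit every subject; write MD/FA maps and rendered MD PNGs."""
    idx = _subjects_index(outdir)
    report_rows = []
    for sid in idx["subject_id"]:
        stack = read_volume(outdir / f"{sid}_dwi.nii", kind="dwi")
        labels = read_volume(outdir / f"{sid}_labels.nii", kind="labels")
        tv, rep = fit_volume(stack, mask=labels.labels > 0, weighting=cfg.weighting)
        es = eigensystem(tv)
        md = md_map(es)
        write_volume(md, outdir / f"{sid}_md.nii")
        write_volume(fa_map(es), outdir / f"{sid}_fa.nii")
        render_scalar_map(md, outdir / f"{sid}_md.png", slice_index=md.grid.shape[2] // 2)
        report_rows.append((sid, rep.n_attempted, rep.n_fit, rep.n_masked_out))
        log.info("fit: %s — %d/%d voxels fit", sid, rep.n_fit, rep.n_attempted)
    _write_tsv(
        pd.DataFrame(
            report_rows,
            columns=["subject_id", "voxels_attempted", "voxels_fit", "voxels_masked_out"],
        ),
        outdir / "fit_report.tsv",
    )


def stage_roi(cfg: StudyConfig, outdir: Path) -> None:
    """ROI summaries per subject and group statistics on the target region."""
    idx = _subjects_index(outdir)
    subjects = []
    common: set | None = None
    for sid, group in zip(idx["subject_id"], idx["group"]):
        md = read_volume(outdir / f"{sid}_md.nii", kind="scalar")
        labels = read_volume(outdir / f"{sid}_labels.nii", kind="labels")
        common = set(labels.legend) if common is None else common & set(labels.legend)
        subjects.append((sid, group, md, labels))
    # regions outside the common legend (e.g. the infarct, absent from
    # control brains) cannot enter a cohort table
    table = cohort_roi_table(subjects, sorted(common or []))
    _write_tsv(table, outdir / "roi_table.tsv")

    base, _, side = cfg.roi_region.rpartition("_")
    sel = table[(table.region == base) & (table.hemisphere == side)]
    groups = {g: sub.value.to_numpy() for g, sub in sel.groupby("group")}
    results = []
    if len(groups) == 2:
        (ga, va), (gb, vb) = groups.items()
        results.append(student_t(va, vb, cfg.roi_alpha, comparison=f"{ga} vs {gb}"))
    elif len(groups) > 2:
        results.extend(tukey_hsd(groups, cfg.roi_alpha))
    stats_df = pd.DataFrame(
        [(r.comparison, r.statistic, r.df, r.p, r.significant) for r in results],
        columns=["comparison", "statistic", "df", "p", "significant"],
    )
    _write_tsv(stats_df, outdir / "roi_stats.tsv")
    log.info("roi: %d comparisons on %s", len(results), cfg.roi_region)


def _vbm_groups(cfg: StudyConfig, groups: "list[str]") -> tuple[str, str]:
    if cfg.vbm_group_a and cfg.vbm_group_b:
        return cfg.vbm_group_a, cfg.vbm_group_b
    if len(groups) != 2:
        raise ValueError("vbm needs exactly two groups (or explicit vbm_group_a/b)")
    control = [g for g in groups if g in CONTROL_GROUPS]
    if len(control) == 1:
        a = control[0]
        b = [g for g in groups if g != a][0]
        return a, b
    return groups[0], groups[1]


def stage_vbm(cfg: StudyConfig, outdir: Path) -> None:
    """Voxelwise t-contrast with an uncorrected height threshold."""
    idx = _subjects_index(outdir)
    ga, gb = _vbm_groups(cfg, list(dict.fromkeys(idx["group"])))
    maps = {ga: [], gb: []}
    labels = None
    for sid, group in zip(idx["subject_id"], idx["group"]):
        if group in maps:
            maps[group].append(read_volume(outdir / f"{sid}_md.nii", kind="scalar"))
            if labels is None:
                labels = read_volume(outdir / f"{sid}_labels.nii", kind="labels")
    if len(maps[ga]) < 2 or len(maps[gb]) < 2:
        raise ValueError(f"vbm needs >= 2 subjects in each of {ga!r} and {gb!r}")
    tmap = voxelwise_t(maps[ga], maps[gb], direction="A_greater")
    sig = threshold_contrast(tmap, cfg.vbm_alpha)
    write_volume(
        # store t map as a ScalarMap volume
        type(maps[ga][0])(tmap.grid, tmap.t, name="t", units="dimensionless"),
        outdir / "vbm_t.nii",
    )
    write_volume(sig, outdir / "vbm_sig.nii")
    thr = critical_t(cfg.vbm_alpha, tmap.df, "one")
    counts = []
    for region, lid in sorted(labels.legend.items()):
        counts.append((region, int((sig.labels.astype(bool) & (labels.labels == lid)).sum())))
    summary = pd.DataFrame(
        [
            ("contrast", f"{ga} > {gb}"),
            ("df", tmap.df),
            ("alpha", cfg.vbm_alpha),
            ("height_threshold_t", round(thr, 3)),
            ("n_significant_voxels", int(sig.labels.sum())),
        ]
        + [(f"n_significant_{r}", c) for r, c in counts],
        columns=["key", "value"],
    )
    _write_tsv(summary, outdir / "vbm_summary.tsv")
    log.info("vbm: df=%d threshold=%.3f significant=%d", tmap.df, thr, int(sig.labels.sum()))


def stage_ihc(cfg: StudyConfig, outdir: Path) -> None:
    """Simulate fluorescence fields, quantify coverage, test group effects."""
    if not cfg.ihc:
        raise ValueError("no ihc section in config")
    n_per_group = dict(cfg.ihc["n_per_group"])
    fields, truth = simulate_ihc_cohort(n_per_group, base_seed=cfg.seed + 1)
    table, excluded = field_report(fields)
    _write_tsv(table, outdir / "ihc_table.tsv")
    _write_tsv(truth, outdir / "ihc_truth.tsv")
    results = []
    for (region, marker), sub in table.groupby(["region", "marker"]):
        groups = {g: s.value.to_numpy() for g, s in sub.groupby("group")}
        if len(groups) == 2:
            (ga, va), (gb, vb) = groups.items()
            r = student_t(va, vb, comparison=f"{region}/{marker}: {ga} vs {gb}")
            results.append(r)
        elif len(groups) > 2:
            for r in tukey_hsd(groups):
                results.append(
                    replace(r, comparison=f"{region}/{marker}: {r.comparison}")
                )
    _write_tsv(
        pd.DataFrame(
            [(r.comparison, r.statistic, r.df, r.p, r.significant) for r in results],
            columns=["comparison", "statistic", "df", "p", "significant"],
        ),
        outdir / "ihc_stats.tsv",
    )
    if excluded:
        (outdir / "ihc_excluded.txt").write_text("\n".join(excluded) + "\n")
    log.info("ihc: %d fields, %d comparisons", len(fields), len(results))


def stage_behavior(cfg: StudyConfig, outdir: Path) -> None:
    """Simulate and summarize behavioral scores."""
    if not cfg.behavior:
        raise ValueError("no behavior section in config")
    effects = {g: tuple(v) for g, v in cfg.behavior["group_effects"].items()}
    n_per_group = dict(cfg.behavior["n_per_group"])
    table = simulate_behavior(effects, n_per_group, seed=cfg.seed + 2)
    _write_tsv(table, outdir / "behavior.tsv")
    groups = {g: s.freezing_percent.to_numpy() for g, s in table.groupby("group")}
    if len(groups) == 2:
        (ga, va), (gb, vb) = groups.items()
        results = [student_t(va, vb, comparison=f"freezing: {ga} vs {gb}")]
    else:
        results = [
            replace(r, comparison=f"freezing: {r.comparison}") for r in tukey_hsd(groups)
        ]
    _write_tsv(
        pd.DataFrame(
            [(r.comparison, r.statistic, r.df, r.p, r.significant) for r in results],
            columns=["comparison", "statistic", "df", "p", "significant"],
        ),
        outdir / "behavior_stats.tsv",
    )


def stage_report(cfg: StudyConfig, outdir: Path) -> None:
    """Aggregate existing stage TSVs into one text report (no
    recomputation; idempotent)."""
    lines = [f"strokedti {__version__} study report", ""]
    for name in (
        "subjects.tsv",
        "fit_report.tsv",
        "roi_stats.tsv",
        "vbm_summary.tsv",
        "ihc_stats.tsv",
        "behavior_stats.tsv",
    ):
        p = outdir / name
        if p.exists():
            lines.append(f"== {name} ==")
            lines.append(p.read_text().rstrip())
            lines.append("")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


STAGES = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "roi": stage_roi,
    "vbm": stage_vbm,
    "ihc": stage_ihc,
    "behavior": stage_behavior,
    "report": stage_report,
}


def run_study(cfg: StudyConfig) -> Path:
    """Run all applicable stages into ``cfg.output_dir``.

    Skips the IHC/behavior stages when their config sections are absent
    (noted in the manifest).  Any stage failure aborts with a
    :class:`StageError` naming the stage; partial outputs are retained.
    Returns the run directory.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in cfg.__dict__.items()
        },
        "stages": {},
    }
    for name, fn in STAGES.items():
        if name == "ihc" and not cfg.ihc:
            manifest["stages"][name] = "skipped (no ihc section)"
            log.info("ihc: skipped (no config section)")
            continue
        if name == "behavior" and not cfg.behavior:
            manifest["stages"][name] = "skipped (no behavior section)"
            continue
        try:
            fn(cfg, outdir)
            manifest["stages"][name] = "ok"
        except Exception as exc:
            manifest["stages"][name] = f"failed: {exc}"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise StageError(name, exc) from exc
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return outdir
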