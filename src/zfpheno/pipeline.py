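"""End-to-end orchestration and the ``zfpheno`` command-line interface.

A YAML config is the single source of parameters (CLI flags override it);
every effective value is echoed into the machine-readable run report so a
run can be audited and reproduced exactly. Tables are UTF-8 TSV; logs go
to stderr; nothing depends on wall-clock or hidden state, so re-running
the same config on the same inputs yields byte-identical outputs.

Exit codes: 0 success, 2 configuration error, 3 validation/format error,
4 I/O error.
"""

from __future__ import annotations

import json
import shutil
import sys
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import behavior_metrics as bm
from . import proteomics_de as de
from . import stats_core as sc
from . import synthetic_data as synth
from . import trajectory_io as tio
from .errors import ConfigurationError, FormatError, ValidationError, ZfphenoError

EXIT_CONFIG, EXIT_VALIDATION, EXIT_IO = 2, 3, 4


@dataclass
class RunConfig:
    """Effective settings for a run; every field lands in the run report."""

    output_dir: Path
    tracks: Path | None = None
    lfq: Path | None = None
    annotations: Path | None = None
    annotation_names: Path | None = None
    schedule: tio.LightSchedule = field(default_factory=tio.standard_schedule)
    rate_hz: float = tio.DEFAULT_RATE_HZ
    theta_active: float = 0.1
    theta_abrupt: float = 1.2
    min_duration_s: float = 0.2
    merge_gap_s: float = 0.1
    smooth_window: int | None = None
    alpha: float = 0.05
    fc_min: float = 1.0
    q_max: float = 0.01
    detection_rule: str = "both_replicates"
    normalization: str = "median_center"
    sample_groups: dict = field(default_factory=dict)
    subset: list[str] | None = None
    seed: int = 0

    def settings(self) -> dict:
        out = {}
        for k, v in self.__dict__.items():
            if isinstance(v, Path):
                out[k] = str(v)
            elif isinstance(v, tio.LightSchedule):
                out[k] = [list(e) for e in v.epochs]
            else:
                out[k] = v
        return out


@dataclass
class RunReport:
    """Per-stage record of inputs, parameters and in/out counts."""

    settings: dict
    stages: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def add(self, stage: str, **counts) -> None:
        if any(s["stage"] == stage for s in self.stages):
            raise ValidationError(f"stage {stage!r} recorded twice")
        self.stages.append({"stage": stage, **counts})

    def stage(self, name: str) -> dict:
        for s in self.stages:
            if s["stage"] == name:
                return s
        raise KeyError(name)

    def write(self, path: Path) -> None:
        payload = {"settings": self.settings, "stages": self.stages, "warnings": self.warnings}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def load_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    base = path.parent

    def _path(section: dict, key: str) -> Path | None:
        v = section.get(key)
        return (base / v) if v is not None else None

    paths = raw.get("paths", {})
    sched_spec = raw.get("schedule", {})
    if "epochs" in sched_spec:
        schedule = tio.LightSchedule(
            tuple((e["start_s"], e["end_s"], e["condition"]) for e in sched_spec["epochs"])
        )
    else:
        schedule = tio.standard_schedule(
            sched_spec.get("n_cycles", 3), sched_spec.get("light_s", 30.0), sched_spec.get("dark_s", 30.0)
        )
    thr = raw.get("thresholds", {})
    cfg = RunConfig(
        output_dir=_path(paths, "output_dir") or (base / "out"),
        tracks=_path(paths, "tracks"),
        lfq=_path(paths, "lfq"),
        annotations=_path(paths, "annotations"),
        annotation_names=_path(paths, "annotation_names"),
        schedule=schedule,
        rate_hz=float(raw.get("rate_hz", tio.DEFAULT_RATE_HZ)),
        theta_active=float(thr.get("theta_active", 0.1)),
        theta_abrupt=float(thr.get("theta_abrupt", 1.2)),
        min_duration_s=float(thr.get("min_duration_s", 0.2)),
        merge_gap_s=float(thr.get("merge_gap_s", 0.1)),
        smooth_window=raw.get("smooth_window"),
        alpha=float(thr.get("alpha", 0.05)),
        fc_min=float(thr.get("fc_min", 1.0)),
        q_max=float(thr.get("q_max", 0.01)),
        detection_rule=raw.get("detection_rule", "both_replicates"),
        normalization=raw.get("normalization", "median_center"),
        sample_groups=raw.get("sample_groups", {}),
        subset=raw.get("subset"),
        seed=int(raw.get("seed", 0)),
    )
    return cfg


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def run_behavior(cfg: RunConfig) -> RunReport:
    """Behavioral half: per-larva summaries, condition table, profiles, stats."""
    if cfg.tracks is None:
        raise ConfigurationError("behavior analysis requires paths.tracks")
    if not Path(cfg.tracks).exists():
        raise ConfigurationError(f"tracks file not found: {cfg.tracks}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(settings=cfg.settings())

    cohort = tio.read_tracks(cfg.tracks, rate_hz=cfg.rate_hz, schedule=cfg.schedule)
    report.add("read_tracks", n_larvae=len(cohort.larvae),
               n_samples=int(sum(tr.n_samples for tr in cohort.larvae)))

    thr = bm.ActivityThresholds(cfg.theta_active, cfg.theta_abrupt)
    bp = bm.BoltParams(cfg.min_duration_s, cfg.merge_gap_s)
    summaries = [
        bm.summarize_larva(tr, cohort.schedule, thr, bp, smooth_window=cfg.smooth_window)
        for tr in cohort.larvae
    ]
    per_larva = bm.summaries_table(summaries)
    _write_tsv(per_larva, out / "behavior_summaries.tsv")
    if (per_larva["n_bolts"] == 0).all():
        report.warnings.append("no bolts detected in any larva; bolt statistics are all NA")
    report.add("summaries", n_rows=len(per_larva))

    long = bm.epoch_metrics(summaries)
    _write_tsv(long, out / "behavior_conditions.tsv")
    report.add("condition_table", n_rows=len(long))

    profiles = []
    for group in tio.GROUPS:
        if not cohort.by_group(group):
            continue
        prof = bm.locomotor_profile(cohort, group)
        profiles.append(
            pd.DataFrame(
                {
                    "group": group,
                    "bin_start_s": prof.bin_edges[:-1],
                    "mean_distance_mm": prof.mean_distance_mm,
                    "sem": prof.sem,
                }
            )
        )
    prof_df = pd.concat(profiles, ignore_index=True) if profiles else pd.DataFrame(
        columns=["group", "bin_start_s", "mean_distance_mm", "sem"]
    )
    _write_tsv(prof_df, out / "behavior_profile.tsv")
    report.add("profile", n_rows=len(prof_df))

    _behavior_stats(cfg, long, per_larva, out, report)
    report.write(out / "behavior_report.json")
    return report


def _behavior_stats(cfg: RunConfig, long: pd.DataFrame, per_larva: pd.DataFrame,
                    out: Path, report: RunReport) -> None:
    """Group x condition ANOVA + Tukey on per-condition distance, and
    per-metric Welch comparisons between groups on the overall summaries."""
    dist = long[long["metric"] == "total_distance_mm"]
    anova_rows, tukey_df = [], pd.DataFrame(columns=["cell_1", "cell_2", "mean_diff", "p_adj"])
    groups_present = sorted(dist["group"].unique())
    if len(groups_present) == 2 and not dist.empty:
        try:
            aov = sc.two_way_anova(
                dist["value"].to_numpy(), dist["group"].to_numpy(), dist["condition"].to_numpy()
            )
            anova_rows = aov.table.reset_index().rename(columns={"index": "effect"}).to_dict("records")
            cells = dist["group"].astype(str) + ":" + dist["condition"].astype(str)
            tukey_df = sc.tukey_hsd(dist["value"].to_numpy(), cells.to_numpy())
        except ValidationError as exc:
            report.warnings.append(f"ANOVA skipped: {exc}")
    pd.DataFrame(anova_rows).to_csv(out / "behavior_anova.tsv", sep="\t", index=False, na_rep="NA")
    _write_tsv(tukey_df, out / "behavior_tukey.tsv")

    welch_rows = []
    if len(groups_present) == 2:
        for metric in (
            "total_distance_mm", "mean_velocity_mms", "n_bolts", "bolt_interval_s",
            "bolt_duration_s", "bolt_distance_mm", "distance_per_bolt_mm", "active_fraction",
        ):
            a = per_larva.loc[per_larva["group"] == "control", metric].dropna().to_numpy(float)
            b = per_larva.loc[per_larva["group"] == "treated", metric].dropna().to_numpy(float)
            if len(a) < 2 or len(b) < 2:
                report.warnings.append(f"Welch comparison skipped for {metric}: too few values")
                continue
            try:
                res = sc.welch_t(a, b)
            except ValidationError as exc:
                report.warnings.append(f"Welch comparison skipped for {metric}: {exc}")
                continue
            welch_rows.append(
                {"metric": metric, "t": res.statistic, "df": res.df, "p": res.p,
                 "mean_control": float(np.mean(a)), "mean_treated": float(np.mean(b))}
            )
    _write_tsv(pd.DataFrame(welch_rows), out / "behavior_welch.tsv")
    report.add("stats", n_anova_effects=len(anova_rows), n_welch_metrics=len(welch_rows),
               n_tukey_pairs=len(tukey_df))


def run_proteomics(cfg: RunConfig) -> RunReport:
    """Proteomics half: detection sets, filtering, DE, regulation table, enrichment."""
    if cfg.lfq is None:
        raise ConfigurationError("proteomics analysis requires paths.lfq")
    if not Path(cfg.lfq).exists():
        raise ConfigurationError(f"LFQ file not found: {cfg.lfq}")
    if not cfg.sample_groups:
        raise ConfigurationError("proteomics analysis requires a sample_groups map")
    # Fail fast: if enrichment was requested the annotation file must exist
    # before any computation starts.
    if cfg.annotations is not None and not Path(cfg.annotations).exists():
        raise ConfigurationError(f"annotation file not found: {cfg.annotations}")
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(settings=cfg.settings())

    matrix = de.read_lfq(cfg.lfq, cfg.sample_groups)
    report.add("read_lfq", n_proteins=matrix.n_proteins, n_samples=len(matrix.samples))

    sets = de.detection_sets(matrix, rule=cfg.detection_rule)
    counts = sets.counts()
    _write_tsv(counts, out / "detection_counts.tsv")
    report.add("detection_sets", **{r["set"]: int(r["n"]) for _, r in counts.iterrows()})

    filtered = de.filter_consistent(matrix)
    report.add("filter_consistent", n_in=matrix.n_proteins, n_out=filtered.n_proteins)

    normalized = de.log2_normalize(filtered, normalization=cfg.normalization)
    result = de.differential_expression(normalized, alpha=cfg.alpha, fc_min=cfg.fc_min)
    de_table = result.table.reset_index()
    _write_tsv(de_table, out / "de_table.tsv")
    _write_tsv(result.degenerate.reset_index(), out / "de_degenerate.tsv")
    status_counts = result.table["status"].value_counts().to_dict()
    report.add(
        "differential_expression",
        n_tested=len(result.table),
        n_degenerate=len(result.degenerate),
        n_up=int(status_counts.get(de.UP, 0)),
        n_down=int(status_counts.get(de.DOWN, 0)),
        n_ns=int(status_counts.get(de.NS, 0)),
    )

    subset = cfg.subset or de.load_neurodegeneration_table()["gene_symbol"].tolist()
    reg, unresolved = de.regulation_table(result.table, subset)
    _write_tsv(reg, out / "regulation_table.tsv")
    if unresolved:
        report.warnings.append(f"regulation subset symbols not found: {unresolved}")
    report.add("regulation_table", n_rows=len(reg), n_unresolved=len(unresolved))

    if cfg.annotations is not None:
        terms, names = de.read_annotation(cfg.annotations, cfg.annotation_names)
        background = set(result.table["gene_symbol"])
        query = set(result.table.loc[result.table["status"] != de.NS, "gene_symbol"])
        enr = de.enrich(query, terms, background, q_max=cfg.q_max, term_names=names)
        _write_tsv(enr, out / "enrichment.tsv")
        report.add("enrichment", n_terms_tested=len(terms), n_terms_passing=len(enr),
                   n_query=len(query), n_background=len(background))
    report.write(out / "proteomics_report.json")
    return report


def run_all(cfg: RunConfig) -> RunReport:
    """Both halves on one config; equivalent to running them separately."""
    behavior = run_behavior(cfg)
    proteomics = run_proteomics(cfg)
    combined = RunReport(settings=cfg.settings())
    for rep, prefix in ((behavior, "behavior"), (proteomics, "proteomics")):
        for stage in rep.stages:
            combined.stages.append({**stage, "stage": f"{prefix}:{stage['stage']}"})
        combined.warnings.extend(rep.warnings)
    combined.write(Path(cfg.output_dir) / "combined_report.json")
    return combined


def write_fixture_bundle(out_dir: str | Path, seed: int = 0, n_per_group: int = 12,
                         rate_hz: float = 25.0) -> Path:
    """Write a complete, self-consistent demo bundle.

    Contents: synthetic trajectory CSV + schedule YAML (control vs
    hypokinetic cohort), synthetic LFQ CSV + ground-truth TSV, a small
    annotation TSV with two genuinely enriched terms, the packaged curated
    protein tables, and a ready-to-run config.yaml.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedule = tio.standard_schedule()
    cohort = synth.simulate_cohort(n_per_group=n_per_group, schedule=schedule,
                                   rate_hz=rate_hz, seed=seed)
    tio.write_tracks(cohort, out / "tracks.csv")
    tio.write_schedule(schedule, out / "schedule.yaml")

    # The demo uses 4 replicates/group: a duplicate design has essentially no
    # BH-adjusted power at ~2k proteins, which would make the DE stage of the
    # walk-through trivially empty (see docs/methods.md).
    lfq_params = synth.LFQSimParams(seed=seed, n_replicates=4)
    matrix, truth = synth.simulate_lfq(lfq_params)
    de.write_lfq(matrix, out / "lfq.csv")
    truth.to_csv(out / "lfq_truth.tsv", sep="\t", index=False)

    # Annotation: two terms enriched for true up-/down-regulated genes plus
    # background terms of random genes.
    rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(9,)))
    genes = truth["gene_symbol"].to_numpy()
    up = truth.loc[truth["true_log2fc"] > 0, "gene_symbol"].to_numpy()
    down = truth.loc[truth["true_log2fc"] < 0, "gene_symbol"].to_numpy()
    ann_rows: list[tuple[str, str]] = []
    names_rows = [
        ("T0001", "synthetic term enriched for upregulated proteins"),
        ("T0002", "synthetic term enriched for downregulated proteins"),
    ]
    for term, pool in (("T0001", up), ("T0002", down)):
        members = set(pool) | set(rng.choice(genes, size=30, replace=False))
        ann_rows += [(term, g) for g in sorted(members)]
    for i in range(3, 13):
        term = f"T{i:04d}"
        names_rows.append((term, f"synthetic background term {i}"))
        ann_rows += [(term, g) for g in sorted(rng.choice(genes, size=50, replace=False))]
    pd.DataFrame(ann_rows).to_csv(out / "annotation.tsv", sep="\t", index=False, header=False)
    pd.DataFrame(names_rows).to_csv(out / "annotation_names.tsv", sep="\t", index=False, header=False)

    for name in ("neurodegeneration_deps.tsv", "parkinsonism_subset.tsv"):
        with resources.as_file(resources.files("zfpheno.data").joinpath(name)) as p:
            shutil.copy(p, out / name)

    # A demo regulation subset of synthetic genes with known true effects.
    spiked = truth.loc[truth["true_log2fc"] != 0, "gene_symbol"].head(10).tolist()

    cols = list(matrix.intensities.columns)
    config = {
        "paths": {
            "tracks": "tracks.csv",
            "lfq": "lfq.csv",
            "annotations": "annotation.tsv",
            "annotation_names": "annotation_names.tsv",
            "output_dir": "out",
        },
        "schedule": {"n_cycles": 3, "light_s": 30.0, "dark_s": 30.0},
        "rate_hz": rate_hz,
        "thresholds": {
            "theta_active": 0.1, "theta_abrupt": 1.2, "min_duration_s": 0.2,
            "merge_gap_s": 0.1, "alpha": 0.05, "fc_min": 1.0, "q_max": 0.01,
        },
        "detection_rule": "both_replicates",
        "normalization": "median_center",
        "sample_groups": {c: ("control" if c.startswith("ctrl") else "treated") for c in cols},
        "subset": spiked,
        "seed": seed,
    }
    with open(out / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
    return out


def _run_cli(fn, config_path: str, output_dir: str | None, seed: int | None) -> None:
    try:
        cfg = load_config(config_path)
        if output_dir is not None:
            cfg.output_dir = Path(output_dir)
        if seed is not None:
            cfg.seed = seed
        fn(cfg)
    except ConfigurationError as exc:
        click.echo(f"configuration error: {exc}", err=True)
        sys.exit(EXIT_CONFIG)
    except (ValidationError, FormatError) as exc:
        click.echo(f"validation error: {exc}", err=True)
        sys.exit(EXIT_VALIDATION)
    except OSError as exc:
        click.echo(f"I/O error: {exc}", err=True)
        sys.exit(EXIT_IO)
    except ZfphenoError as exc:  # anything else from the package
        click.echo(f"error: {exc}", err=True)
        sys.exit(EXIT_VALIDATION)


@click.group()
def main() -> None:
    """Larval swim phenotyping and LFQ differential expression."""


@main.command()
@click.option("--out", "out_dir", required=True, type=click.Path(), help="Bundle directory.")
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--n-per-group", default=12, show_default=True, type=int)
def fixtures(out_dir: str, seed: int, n_per_group: int) -> None:
    """Write a synthetic demo bundle (tracks, LFQ, annotation, config)."""
    try:
        path = write_fixture_bundle(out_dir, seed=seed, n_per_group=n_per_group)
    except ValidationError as exc:
        click.echo(f"validation error: {exc}", err=True)
        sys.exit(EXIT_VALIDATION)
    click.echo(f"fixture bundle written to {path}", err=True)


@main.command("score-behavior")
@click.option("--config", "config_path", required=True, type=click.Path())
@click.option("--out", "output_dir", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def score_behavior(config_path: str, output_dir: str | None, seed: int | None) -> None:
    """Run the behavioral analysis half."""
    _run_cli(run_behavior, config_path, output_dir, seed)


@main.command("de")
@click.option("--config", "config_path", required=True, type=click.Path())
@click.option("--out", "output_dir", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def de_cmd(config_path: str, output_dir: str | None, seed: int | None) -> None:
    """Run the proteomics differential-expression half (includes enrichment
    when an annotation path is configured)."""
    _run_cli(run_proteomics, config_path, output_dir, seed)


@main.command("enrich")
@click.option("--config", "config_path", required=True, type=click.Path())
@click.option("--out", "output_dir", default=None, type=click.Path())
def enrich_cmd(config_path: str, output_dir: str | None) -> None:
    """Run the proteomics half with enrichment required."""
    def _fn(cfg: RunConfig):
        if cfg.annotations is None:
            raise ConfigurationError("enrich requires paths.annotations in the config")
        return run_proteomics(cfg)
    _run_cli(_fn, config_path, output_dir, None)


@main.command("run-all")
@click.option("--config", "config_path", required=True, type=click.Path())
@click.option("--out", "output_dir", default=None, type=click.Path())
@click.option("--seed", default=None, type=int)
def run_all_cmd(config_path: str, output_dir: str | None, seed: int | None) -> None:
    """Run both halves and write a combined report."""
    _run_cli(run_all, config_path, output_dir, seed)


if __name__ == "__main__":
    main()
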