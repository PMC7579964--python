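"""Resumable driver chaining refinement, counting and aggregation.

The driver executes the stage graph

    refine → count → merge → aggregate orthologs → normalize
           → aggregate modules/pathways → summaries → master table

per the declarative YAML configuration.  Every parameter that can change a
step's output is encoded into that step's output folder name
(``filter.evalue_cutoff_0.001.strategy_best/...``), so a changed parameter
automatically relocates the step's outputs and everything downstream of
them, while untouched stages keep their files.  Planning is demand-driven:
starting from the final outputs, a step is scheduled only when a file
somebody needs is missing.  A re-run under an unchanged configuration
therefore schedules nothing, and changing one parameter re-executes exactly
that step's dependency closure — including when intermediate files were
deleted after a successful run, since nothing demands them anymore.

Samples are processed independently: one sample's malformed input leaves
the other samples' completed outputs valid, and a repaired re-run touches
only the failed sample before resuming the cross-sample stages.
"""

from __future__ import annotations

import logging
import os
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import yaml

from . import abundance_profiling as ap
from . import functional_aggregation as fa
from . import summary_statistics as ss
from .alignment_io import read_alignment_table, write_alignment_table
from .hit_filtering import FilterConfig, refine_hits

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class PipelineFailure(RuntimeError):
    """One or more samples failed (CLI exit code 1)."""

    def __init__(self, failed_samples: dict[str, str]):
        self.failed_samples = failed_samples
        details = "; ".join(f"{s}: {m}" for s, m in failed_samples.items())
        super().__init__(f"sample(s) failed: {details}")


# ---------------------------------------------------------------------------
# parameter-encoded output names


def encode_output_name(step: str, params: dict[str, object]) -> str:
    """Render a step plus its output-determining parameters as a name.

    ``("filter", {"strategy": "best", "evalue_cutoff": 0.001})`` becomes
    ``"filter.evalue_cutoff_0.001.strategy_best"``: parameters joined in
    sorted key order, so the fragment is insertion-order invariant and
    injective for distinct parameter values.  Values are rendered with
    ``str`` exactly as they were spelled in the configuration.
    """
    for key, value in params.items():
        if not key or not all(c.islower() or c == "_" for c in key):
            raise ConfigError(f"parameter key {key!r} must match [a-z_]+")
        rendered = str(value)
        if os.sep in rendered or "/" in rendered:
            raise ConfigError(
                f"parameter value {rendered!r} for {key!r} contains a path "
                "separator"
            )
    parts = [step]
    for key in sorted(params):
        parts.append(f"{key}_{params[key]}")
    return ".".join(parts)


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SampleInputs:
    """Input files of one sample: one or more read-set alignment tables
    (forward / reverse / singleton, each counted independently) and an
    optional FASTQ for quality statistics."""

    alignments: list[Path] = field(default_factory=list)
    fastq: Path | None = None


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run."""

    samples: dict[str, SampleInputs]
    output_dir: Path
    filter: FilterConfig = field(default_factory=FilterConfig)
    unmapped: fa.UnmappedPolicy = field(default_factory=fa.UnmappedPolicy)
    split: str = "even"
    relative_abundance: bool = False
    gene_to_ortholog: Path | None = None
    ortholog_to_module: Path | None = None
    ortholog_to_pathway: Path | None = None
    keep_intermediates: bool = False
    #: user-supplied ortholog profile; skips every upstream stage
    ortholog_profile_input: Path | None = None
    #: raw parameter spellings from the config file, for name encoding
    raw_filter_params: dict[str, object] = field(default_factory=dict)
    raw_aggregate_params: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.samples) != len({s for s in self.samples}):
            raise ConfigError("sample ids must be unique")
        if not self.raw_filter_params:
            self.raw_filter_params = _filter_params(self.filter)
        if not self.raw_aggregate_params:
            self.raw_aggregate_params = {
                "split": self.split,
                "unmapped": self.unmapped.mode,
            }

    def validate_inputs(self) -> None:
        """Referenced files must exist at run start."""
        missing: list[str] = []
        for sid, inputs in self.samples.items():
            for p in inputs.alignments:
                if not p.exists():
                    missing.append(f"{sid}: alignment {p}")
            if inputs.fastq is not None and not inputs.fastq.exists():
                missing.append(f"{sid}: fastq {inputs.fastq}")
        for label in ("gene_to_ortholog", "ortholog_to_module",
                      "ortholog_to_pathway", "ortholog_profile_input"):
            p = getattr(self, label)
            if p is not None and not p.exists():
                missing.append(f"{label}: {p}")
        if self.ortholog_profile_input is None:
            for label in ("gene_to_ortholog", "ortholog_to_module",
                          "ortholog_to_pathway"):
                if getattr(self, label) is None:
                    raise ConfigError(f"mapping table {label!r} is required")
            if not self.samples:
                raise ConfigError("no samples configured")
        else:
            for label in ("ortholog_to_module", "ortholog_to_pathway"):
                if getattr(self, label) is None:
                    raise ConfigError(f"mapping table {label!r} is required")
        if missing:
            raise ConfigError(
                "missing input file(s): " + "; ".join(missing)
            )


def _filter_params(cfg: FilterConfig) -> dict[str, object]:
    params: dict[str, object] = {
        "strategy": cfg.strategy,
        "evalue_cutoff": cfg.evalue_cutoff,
    }
    if cfg.n is not None:
        params["n"] = cfg.n
    if cfg.top_percentage is not None:
        params["top_percentage"] = cfg.top_percentage
    return params


def load_config(path: str | Path) -> PipelineConfig:
    """Parse a YAML configuration file into a :class:`PipelineConfig`."""
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    base = path.parent

    def _resolve(p: object) -> Path:
        return (base / str(p)).resolve() if not os.path.isabs(str(p)) else Path(str(p))

    samples: dict[str, SampleInputs] = {}
    for sid, entry in (raw.get("samples") or {}).items():
        entry = entry or {}
        aligns = entry.get("alignments", [])
        if isinstance(aligns, (str, os.PathLike)):
            aligns = [aligns]
        samples[str(sid)] = SampleInputs(
            alignments=[_resolve(a) for a in aligns],
            fastq=_resolve(entry["fastq"]) if entry.get("fastq") else None,
        )
    fraw = raw.get("filter") or {}
    try:
        fcfg = FilterConfig(
            strategy=fraw.get("strategy", "best"),
            n=fraw.get("n"),
            evalue_cutoff=float(fraw.get("evalue_cutoff", 0.001)),
            top_percentage=(
                float(fraw["top_percentage"])
                if fraw.get("top_percentage") is not None else None
            ),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    araw = raw.get("aggregation") or {}
    try:
        policy = fa.UnmappedPolicy(mode=araw.get("unmapped", "collect"))
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    split = araw.get("split", "even")
    if split not in fa.SPLIT_MODES:
        raise ConfigError(f"aggregation.split must be one of {fa.SPLIT_MODES}")
    mappings = raw.get("mappings") or {}
    if "output_dir" not in raw:
        raise ConfigError(f"{path}: 'output_dir' is required")
    # preserve the config file's own spelling of values in encoded names
    raw_filter_params: dict[str, object] = {
        "strategy": fraw.get("strategy", "best"),
        "evalue_cutoff": fraw.get("evalue_cutoff", 0.001),
    }
    if fraw.get("n") is not None:
        raw_filter_params["n"] = fraw["n"]
    if fraw.get("top_percentage") is not None:
        raw_filter_params["top_percentage"] = fraw["top_percentage"]
    return PipelineConfig(
        samples=samples,
        output_dir=_resolve(raw["output_dir"]),
        filter=fcfg,
        unmapped=policy,
        split=split,
        relative_abundance=bool(raw.get("relative_abundance", False)),
        gene_to_ortholog=(
            _resolve(mappings["gene_to_ortholog"])
            if mappings.get("gene_to_ortholog") else None
        ),
        ortholog_to_module=(
            _resolve(mappings["ortholog_to_module"])
            if mappings.get("ortholog_to_module") else None
        ),
        ortholog_to_pathway=(
            _resolve(mappings["ortholog_to_pathway"])
            if mappings.get("ortholog_to_pathway") else None
        ),
        keep_intermediates=bool(raw.get("keep_intermediates", False)),
        ortholog_profile_input=(
            _resolve(raw["ortholog_profile_input"])
            if raw.get("ortholog_profile_input") else None
        ),
        raw_filter_params=raw_filter_params,
        raw_aggregate_params={
            "split": araw.get("split", "even"),
            "unmapped": araw.get("unmapped", "collect"),
        },
    )


# ---------------------------------------------------------------------------
# stage graph


@dataclass
class Step:
    """One schedulable unit of work in the stage graph."""

    name: str
    inputs: list[Path]
    outputs: list[Path]
    run: Callable[[], None]
    sample: str | None = None  # None for cross-sample steps
    is_final: bool = False
    deletable_outputs: list[Path] = field(default_factory=list)


def _layout(config: PipelineConfig) -> dict[str, Path]:
    root = config.output_dir
    filter_dir = root / encode_output_name("filter", config.raw_filter_params)
    agg_dir = filter_dir / encode_output_name(
        "aggregate", config.raw_aggregate_params
    )
    norm_dir = agg_dir / encode_output_name(
        "normalize", {"relative_abundance": config.relative_abundance}
    )
    if config.ortholog_profile_input is not None:
        # user-provided entry point: only the aggregation tail runs
        agg_dir = root / encode_output_name(
            "aggregate", config.raw_aggregate_params
        )
        norm_dir = agg_dir / encode_output_name(
            "normalize", {"relative_abundance": config.relative_abundance}
        )
    return {
        "root": root,
        "fastq_stats": root / "fastq_stats",
        "alignment_stats": root / "alignment_stats",
        "filter": filter_dir,
        "aggregate": agg_dir,
        "normalize": norm_dir,
    }


def build_steps(config: PipelineConfig) -> list[Step]:
    """Construct the stage graph for a configuration, in topological order."""
    lay = _layout(config)
    steps: list[Step] = []
    per_sample_gene_profiles: list[Path] = []
    stats_inputs: list[tuple[str, Path]] = []  # (step_name, path) for master

    upstream_enabled = config.ortholog_profile_input is None

    for sid, inputs in config.samples.items():
        if inputs.fastq is not None:
            out = lay["fastq_stats"] / f"{sid}.tab"
            steps.append(Step(
                name=f"fastq_stats[{sid}]",
                inputs=[inputs.fastq],
                outputs=[out],
                run=_fastq_stats_runner(inputs.fastq, sid, out),
                sample=sid,
            ))
            stats_inputs.append(("fastq_stats", out))

    if upstream_enabled:
        for sid, inputs in config.samples.items():
            astat = lay["alignment_stats"] / f"{sid}.tab"
            steps.append(Step(
                name=f"alignment_stats[{sid}]",
                inputs=list(inputs.alignments),
                outputs=[astat],
                run=_alignment_stats_runner(inputs.alignments, sid, astat),
                sample=sid,
            ))
            stats_inputs.append(("alignment", astat))

            refined = [
                lay["filter"] / f"{sid}.set{k}.refined.tab"
                for k in range(len(inputs.alignments))
            ]
            fstat = lay["filter"] / f"{sid}.filter_stats.tab"
            steps.append(Step(
                name=f"refine[{sid}]",
                inputs=list(inputs.alignments),
                outputs=refined + [fstat],
                run=_refine_runner(inputs.alignments, config.filter, sid,
                                   refined, fstat),
                sample=sid,
                deletable_outputs=list(refined),
            ))
            stats_inputs.append(("filter", fstat))

            gprof = lay["filter"] / f"{sid}.gene_profile.tab"
            steps.append(Step(
                name=f"count[{sid}]",
                inputs=list(refined),
                outputs=[gprof],
                run=_count_runner(refined, sid, gprof),
                sample=sid,
                deletable_outputs=[gprof],
            ))
            per_sample_gene_profiles.append(gprof)

        merged = lay["filter"] / "gene_profile.tab"
        steps.append(Step(
            name="merge_samples",
            inputs=list(per_sample_gene_profiles),
            outputs=[merged],
            run=_merge_runner(per_sample_gene_profiles, merged),
        ))

        orth_raw = lay["aggregate"] / "ortholog_profile.tab"
        orth_stats = lay["aggregate"] / "aggregate_ortholog_stats.tab"
        steps.append(Step(
            name="aggregate_ortholog",
            inputs=[merged, config.gene_to_ortholog],
            outputs=[orth_raw, orth_stats],
            run=_aggregate_runner(
                merged, "gene", config.gene_to_ortholog, "ortholog",
                config, orth_raw, orth_stats,
            ),
        ))
        stats_inputs.append(("aggregate_ortholog", orth_stats))
    else:
        orth_raw = config.ortholog_profile_input

    orth_final = lay["normalize"] / "ortholog_profile.tab"
    steps.append(Step(
        name="normalize",
        inputs=[orth_raw],
        outputs=[orth_final],
        run=_normalize_runner(orth_raw, config.relative_abundance, orth_final),
        is_final=True,
    ))

    module_out = lay["normalize"] / "module_profile.tab"
    module_stats = lay["normalize"] / "aggregate_module_stats.tab"
    steps.append(Step(
        name="aggregate_module",
        inputs=[orth_final, config.ortholog_to_module],
        outputs=[module_out, module_stats],
        run=_aggregate_runner(
            orth_final, "ortholog", config.ortholog_to_module, "module",
            config, module_out, module_stats,
        ),
        is_final=True,
    ))
    pathway_out = lay["normalize"] / "pathway_profile.tab"
    pathway_stats = lay["normalize"] / "aggregate_pathway_stats.tab"
    steps.append(Step(
        name="aggregate_pathway",
        inputs=[orth_final, config.ortholog_to_pathway],
        outputs=[pathway_out, pathway_stats],
        run=_aggregate_runner(
            orth_final, "ortholog", config.ortholog_to_pathway, "pathway",
            config, pathway_out, pathway_stats,
        ),
        is_final=True,
    ))

    master_out = lay["normalize"] / "summary.master.tab"
    profile_paths = {
        "ortholog": orth_final, "module": module_out, "pathway": pathway_out,
    }
    steps.append(Step(
        name="master_summary",
        inputs=[p for _, p in stats_inputs] + list(profile_paths.values()),
        outputs=[master_out],
        run=_master_runner(stats_inputs, profile_paths, master_out),
        is_final=True,
    ))
    return steps


def plan(config: PipelineConfig, steps: list[Step] | None = None) -> list[Step]:
    """Demand-driven schedule: which steps must run, in execution order.

    Walking the stage graph backwards from the final outputs, a step is
    scheduled when one of its demanded outputs (a final output, or an input
    of an already-scheduled consumer) does not exist on disk.  Existing
    files are trusted — resume detection is by encoded-name existence, not
    timestamps or checksums.
    """
    if steps is None:
        steps = build_steps(config)
    needed: set[Path] = set()
    scheduled: list[Step] = []
    for step in reversed(steps):
        demanded = [
            o for o in step.outputs if step.is_final or o in needed
        ]
        if demanded and any(not Path(o).exists() for o in demanded):
            scheduled.append(step)
            needed.update(step.inputs)
    return list(reversed(scheduled))


def run(config: PipelineConfig) -> dict[str, Path]:
    """Execute the planned steps; returns the final output paths.

    Per-sample steps run inside a failure boundary: an error in one sample
    is recorded, that sample's downstream work is abandoned, and the other
    samples continue.  Cross-sample stages only run when every sample
    succeeded, so partial runs never produce merged outputs built from a
    subset.  With ``keep_intermediates`` unset, intermediate files flagged
    deletable are removed once the whole run has succeeded.
    """
    config.validate_inputs()
    steps = build_steps(config)
    todo = plan(config, steps)
    lay = _layout(config)
    lay["root"].mkdir(parents=True, exist_ok=True)
    log_path = lay["root"] / "run.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    failed: dict[str, str] = {}
    executed: list[Step] = []
    try:
        logger.info("planned %d of %d steps", len(todo), len(steps))
        for step in todo:
            if step.sample is not None and step.sample in failed:
                logger.warning("skipping %s: sample already failed", step.name)
                continue
            if step.sample is None and failed:
                logger.warning(
                    "skipping cross-sample step %s: %d sample(s) failed",
                    step.name, len(failed),
                )
                continue
            for out in step.outputs:
                Path(out).parent.mkdir(parents=True, exist_ok=True)
            try:
                step.run()
            except Exception as exc:  # per-sample isolation boundary
                if step.sample is None:
                    raise
                failed[step.sample] = f"{step.name}: {exc}"
                logger.error("step %s failed: %s", step.name, exc)
                # leave no partial outputs behind
                for out in step.outputs:
                    Path(out).unlink(missing_ok=True)
                continue
            executed.append(step)
            logger.info(
                "completed %s -> %s", step.name,
                ", ".join(str(o) for o in step.outputs),
            )
        if not failed and not config.keep_intermediates:
            for step in steps:
                for out in step.deletable_outputs:
                    if Path(out).exists():
                        Path(out).unlink()
                        logger.info("removed intermediate %s", out)
    finally:
        logger.removeHandler(handler)
        handler.close()
    if failed:
        raise PipelineFailure(failed)
    return {
        "ortholog_profile": lay["normalize"] / "ortholog_profile.tab",
        "module_profile": lay["normalize"] / "module_profile.tab",
        "pathway_profile": lay["normalize"] / "pathway_profile.tab",
        "master_summary": lay["normalize"] / "summary.master.tab",
    }


# ---------------------------------------------------------------------------
# step runners (closures capturing their inputs)


def _fastq_stats_runner(fastq: Path, sid: str, out: Path):
    def _run() -> None:
        ss.fastq_summary(fastq, sid).write(out)
    return _run


def _alignment_stats_runner(alignments: list[Path], sid: str, out: Path):
    def _run() -> None:
        def _all_groups():
            for path in alignments:
                yield from read_alignment_table(path)
        ss.alignment_summary(_all_groups(), sid).write(out)
    return _run


def _refine_runner(
    alignments: list[Path],
    fcfg: FilterConfig,
    sid: str,
    refined_paths: list[Path],
    stats_out: Path,
):
    def _run() -> None:
        reads_in = 0
        reads_out = 0
        matches_out = 0
        for src, dst in zip(alignments, refined_paths):
            refined, summary = refine_hits(
                read_alignment_table(src), fcfg, sample_id=sid
            )
            write_alignment_table(refined, dst)
            row = summary.rows[sid]
            reads_in += row["reads_in"]
            reads_out += row["reads_out"]
            matches_out += row["matches_post_filter"]
        total = ss.StepSummary(step_name="filter")
        total.add_row(sid, {
            "reads_in": reads_in,
            "reads_out": reads_out,
            "matches_post_filter": matches_out,
        })
        total.write(stats_out)
    return _run


def _count_runner(refined_paths: list[Path], sid: str, out: Path):
    def _run() -> None:
        parts = [
            ap.count_gene_abundances(read_alignment_table(p), sid)
            for p in refined_paths
        ]
        ap.write_profile(ap.sum_profiles(parts), out)
    return _run


def _merge_runner(per_sample: list[Path], out: Path):
    def _run() -> None:
        profiles = [ap.read_profile(p, "gene") for p in per_sample]
        ap.write_profile(ap.merge_samples(profiles), out)
    return _run


def _aggregate_runner(
    profile_path: Path,
    source_level: str,
    mapping_path: Path,
    target_level: str,
    config: PipelineConfig,
    out: Path,
    stats_out: Path,
):
    def _run() -> None:
        profile = ap.read_profile(profile_path, source_level)
        mapping = fa.read_mapping_table(mapping_path, source_level, target_level)
        result, summary = fa.aggregate(
            profile, mapping, config.unmapped, config.split
        )
        ap.write_profile(result, out)
        summary.write(stats_out)
    return _run


def _normalize_runner(src: Path, relative: bool, out: Path):
    def _run() -> None:
        if relative:
            profile = ap.read_profile(src, "ortholog")
            ap.write_profile(ap.normalize_relative(profile), out)
        else:
            shutil.copyfile(src, out)
    return _run


def _master_runner(
    stats_inputs: list[tuple[str, Path]],
    profile_paths: dict[str, Path],
    out: Path,
):
    def _run() -> None:
        # per-sample step files of one stage combine into one summary
        by_step: dict[str, ss.StepSummary] = {}
        for step_name, path in stats_inputs:
            part = ss.StepSummary.read(path, step_name)
            bucket = by_step.setdefault(step_name, ss.StepSummary(step_name))
            for sample, row in part.rows.items():
                bucket.add_row(sample, row)
        summaries = list(by_step.values())
        for level, path in profile_paths.items():
            profile = ap.read_profile(path, level)
            summaries.append(
                ss.profile_summary(profile, step_name=f"{level}_profile")
            )
        ss.write_master_table(ss.merge_summaries(summaries), out)
    return _run
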