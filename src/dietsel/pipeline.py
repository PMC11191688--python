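"""End-to-end pipeline: config in, audit-complete report bundle out.

Stage order mirrors the study's statistical analysis: (optional) Ct-to-
relative-expression conversion, univariate screen, preprocessing, consensus
selection per comparison, then per-scenario integration (Venn, fold-change
heatmap, Spearman correlation map).  Every stage writes its artifact (CSV or
JSON) into the bundle directory; a manifest records the config hash, master
seed and library versions so a bundle can be reproduced byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .consensus import SelectionConfig, SelectionResult, select_variables
from .containers import Comparison, CtTable, DEFAULT_COMPARISONS, SampleTable
from .errors import ConfigurationError, DataError, DietselError
from .expression import relative_expression
from .integration import correlation_heatmap, foldchange_heatmap, venn
from .preprocess import PreprocessReport, drop_redundant, impute_median, pca_outliers, scale
from .synthetic import CtConfig, PlantedEffect, StudyConfig, generate_ct_table, generate_study

log = logging.getLogger("dietsel")


@dataclass(frozen=True)
class PreprocessConfig:
    rho_threshold: float = 0.95
    n_components: int = 2
    z_cut: float = 3.0
    exclude_outliers: bool = False


@dataclass
class PipelineConfig:
    """Everything one run needs; exactly one input source must be set."""

    output_dir: str
    master_seed: int = 0
    synthetic: StudyConfig | None = None
    data_path: str | None = None
    annotations_path: str | None = None
    ct_path: str | None = None
    ct_reference_gene: str = "PPIA"
    ct_control_group: str = "Control"
    synthetic_ct: CtConfig | None = None
    comparisons: tuple[Comparison, ...] = DEFAULT_COMPARISONS
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    receptor_block: str = "tasr_expression"

    def __post_init__(self) -> None:
        has_files = self.data_path is not None
        has_synth = self.synthetic is not None
        if has_files == has_synth:
            raise ConfigurationError(
                "exactly one of {data_path+annotations_path, synthetic} must be set"
            )
        if has_files and self.annotations_path is None:
            raise ConfigurationError("data_path requires annotations_path")

    # ---- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["comparisons"] = [dataclasses.asdict(c) for c in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "synthetic" in raw and raw["synthetic"] is not None:
            syn = dict(raw["synthetic"])
            planted = tuple(
                PlantedEffect(
                    variable=p["variable"],
                    groups=tuple(p["groups"]),
                    d=float(p["d"]),
                    direction=p.get("direction", "up"),
                )
                for p in syn.pop("planted", [])
            )
            if "groups" in syn:
                syn["groups"] = tuple(syn["groups"])
            raw["synthetic"] = StudyConfig(planted=planted, **syn)
        if "synthetic_ct" in raw and raw["synthetic_ct"] is not None:
            ct = dict(raw["synthetic_ct"])
            for key in ("genes", "groups"):
                if key in ct:
                    ct[key] = tuple(ct[key])
            raw["synthetic_ct"] = CtConfig(**ct)
        if "comparisons" in raw and raw["comparisons"] is not None:
            raw["comparisons"] = tuple(
                Comparison(**c) if isinstance(c, dict) else c
                for c in raw["comparisons"]
            )
        if "preprocess" in raw and isinstance(raw["preprocess"], dict):
            raw["preprocess"] = PreprocessConfig(**raw["preprocess"])
        if "selection" in raw and isinstance(raw["selection"], dict):
            raw["selection"] = SelectionConfig(**raw["selection"])
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


@dataclass
class ReportBundle:
    """Paths of every artifact one run produced, plus the run manifest."""

    output_dir: Path
    artifacts: dict[str, str] = field(default_factory=dict)
    selections: dict[str, SelectionResult] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def register(self, name: str, path: Path) -> Path:
        self.artifacts[name] = str(path)
        return path


class StageError(DietselError):
    """A pipeline stage failed; carries the partial bundle."""

    def __init__(self, stage: str, cause: Exception, bundle: ReportBundle):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause
        self.bundle = bundle


def _write_csv(frame: pd.DataFrame, path: Path, **kw) -> None:
    frame.to_csv(path, **kw)


def validate_inputs(
    data_path: str | Path,
    annotations_path: str | Path,
    ct_path: str | Path | None = None,
) -> list[dict]:
    """Machine-readable diagnostics for input files; empty list = clean."""
    diagnostics: list[dict] = []

    def diag(level: str, message: str, **ctx) -> None:
        diagnostics.append({"level": level, "message": message, **ctx})

    try:
        raw = pd.read_csv(data_path)
    except Exception as exc:  # unreadable file is a hard diagnostic
        diag("error", f"cannot read data table: {exc}", file=str(data_path))
        return diagnostics
    if "sample" not in raw.columns:
        diag("error", "data table lacks 'sample' column", file=str(data_path))
    if "group" not in raw.columns:
        diag("error", "data table lacks 'group' column", file=str(data_path))
        return diagnostics
    value_cols = [c for c in raw.columns if c not in ("sample", "group")]
    for col in value_cols:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = raw.index[coerced.isna() & raw[col].notna()]
        for i in bad:
            diag(
                "error",
                "non-numeric cell",
                file=str(data_path),
                row=int(i) + 2,  # 1-based, after header
                column=col,
                value=str(raw.loc[i, col]),
            )
    try:
        ann = pd.read_csv(annotations_path)
    except Exception as exc:
        diag("error", f"cannot read annotations: {exc}", file=str(annotations_path))
        return diagnostics
    for col in ("variable", "block", "segment"):
        if col not in ann.columns:
            diag("error", f"annotations lack {col!r} column", file=str(annotations_path))
            return diagnostics
    annotated = set(ann["variable"])
    for col in value_cols:
        if col not in annotated:
            diag("error", "variable missing from annotations", variable=col)
    for var in annotated - set(value_cols):
        diag("warning", "annotated variable absent from data table", variable=var)
    if ct_path is not None:
        try:
            ct = pd.read_csv(ct_path)
        except Exception as exc:
            diag("error", f"cannot read Ct table: {exc}", file=str(ct_path))
            return diagnostics
        if "group" not in ct.columns:
            diag("error", "Ct table lacks 'group' column", file=str(ct_path))
    return diagnostics


def _load_table(config: PipelineConfig) -> SampleTable:
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, master_seed=config.master_seed)
        return generate_study(syn)
    return SampleTable.from_csv(config.data_path, config.annotations_path)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and write the report bundle.

    Raises :class:`StageError` (carrying the partial bundle of completed
    artifacts) if any stage fails.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(output_dir=outdir)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    stage = "load"
    try:
        table = _load_table(config)
        log.info("loaded table: %d samples x %d variables", *table.data.shape)
        table.to_csv(
            bundle.register("samples", outdir / "samples.csv"),
            bundle.register("annotations", outdir / "annotations.csv"),
        )

        # -- expression (optional Ct input) -----------------------------
        ct: CtTable | None = None
        if config.ct_path is not None:
            stage = "expression"
            ct = CtTable.from_csv(
                config.ct_path, config.ct_reference_gene, config.ct_control_group
            )
        elif config.synthetic_ct is not None:
            stage = "expression"
            ct = generate_ct_table(config.synthetic_ct, seed=config.master_seed)
            ct.to_csv(bundle.register("ct", outdir / "ct.csv"))
        if ct is not None:
            expr = relative_expression(ct)
            expr.to_csv(bundle.register("expression", outdir / "expression.csv"))
            log.info("expression: %d genes converted to relative expression", len(expr.genes))

        # -- univariate screen (on imputed, unscaled data) ---------------
        stage = "univariate"
        report = PreprocessReport()
        imputed, report = impute_median(table, report)
        from .univariate import pairwise_screen

        screen = pairwise_screen(imputed, config.comparisons)
        _write_csv(screen, bundle.register("univariate", outdir / "univariate.csv"), index=False)
        log.info("univariate: %d tests, %d flagged '*'", len(screen), int((screen["flag"] == "*").sum()))

        # -- preprocess ---------------------------------------------------
        stage = "preprocess"
        pruned, report = drop_redundant(imputed, config.preprocess.rho_threshold, report)
        scaled, report = scale(pruned, report)
        report = pca_outliers(
            scaled,
            n_components=config.preprocess.n_components,
            z_cut=config.preprocess.z_cut,
            report=report,
        )
        processed = scaled
        if config.preprocess.exclude_outliers and report.outlier_samples:
            processed = scaled.subset_groups(scaled.group_labels)  # copy
            keep = ~processed.data.index.isin(report.outlier_samples)
            processed = SampleTable(
                data=processed.data.loc[keep],
                groups=processed.groups.loc[keep],
                annotations=processed.annotations,
            )
        report.to_json(bundle.register("preprocess_report", outdir / "preprocess_report.json"))
        processed.to_csv(
            bundle.register("processed", outdir / "processed.csv"),
            bundle.register("processed_annotations", outdir / "processed_annotations.csv"),
        )
        log.info(
            "preprocess: %d cells imputed, %d variables dropped, %d outliers flagged",
            report.imputed_cells, len(report.dropped), len(report.outlier_samples),
        )

        # -- consensus selection per comparison ---------------------------
        stage = "selection"
        for cmp_ in config.comparisons:
            sel_cfg = dataclasses.replace(config.selection, seed=config.master_seed)
            result = select_variables(processed, cmp_, sel_cfg)
            bundle.selections[cmp_.label] = result
            _write_csv(
                result.to_frame(),
                bundle.register(f"selection_{cmp_.label}", outdir / f"selection_{cmp_.label}.csv"),
            )
            log.info(
                "selection %s: knee at %d of %d variables",
                cmp_.label, result.knee_index, len(result.ranking.variables),
            )

        # -- integration per scenario -------------------------------------
        stage = "integration"
        scenarios: dict[str, list[Comparison]] = {}
        for cmp_ in config.comparisons:
            scenarios.setdefault(cmp_.scenario, []).append(cmp_)
        for scenario, cmps in scenarios.items():
            if len(cmps) != 2:
                log.info("scenario %s has %d comparison(s); Venn skipped", scenario, len(cmps))
                continue
            sel_a, sel_b = (bundle.selections[c.label] for c in cmps)
            vres = venn(sel_a, sel_b)
            vres.to_json(bundle.register(f"venn_{scenario}", outdir / f"venn_{scenario}.json"))
            common = sorted(vres.intersection)
            fch = foldchange_heatmap(imputed, common, cmps, screen=screen)
            _write_csv(
                fch,
                bundle.register(f"fc_heatmap_{scenario}", outdir / f"fc_heatmap_{scenario}.csv"),
                index=False,
            )
            scenario_groups = sorted({g for c in cmps for g in (c.test, c.reference)})
            corr = correlation_heatmap(imputed, scenario_groups, config.receptor_block)
            prefix = outdir / f"corr_{scenario}"
            corr.to_csv(prefix)
            for suffix in ("rho", "p", "stars", "bh05"):
                bundle.register(f"corr_{scenario}_{suffix}", Path(f"{prefix}_{suffix}.csv"))
            log.info(
                "integration %s: |A|=%d |B|=%d |A&B|=%d",
                scenario, *(vres.counts[k] for k in ("A", "B", "intersection")),
            )

        # -- manifest -----------------------------------------------------
        stage = "manifest"
        import numpy as np_
        import sklearn

        bundle.manifest = {
            "config": config.to_dict(),
            "config_hash": config.config_hash(),
            "master_seed": config.master_seed,
            "versions": {
                "dietsel": __version__,
                "numpy": np_.__version__,
                "pandas": pd.__version__,
                "scikit-learn": sklearn.__version__,
            },
            "elapsed_seconds": round(time.time() - t0, 3),
            "artifacts": dict(bundle.artifacts),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(bundle.manifest, fh, indent=2, default=str)
        bundle.artifacts["manifest"] = str(outdir / "manifest.json")
        log.info("pipeline complete in %.1fs", time.time() - t0)
        return bundle
    except DietselError as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc, bundle) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
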