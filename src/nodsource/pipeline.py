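"""End-to-end orchestration: validate -> preprocess -> diversity -> venn ->
source tracking -> statistics, with provenance headers and a MANIFEST.

Every stage writes plain TSVs so that any stage can be re-run from the
previous stage's outputs.  Output files carry ``#``-prefixed header lines
recording the package version, the seed and a hash of the configuration;
the MANIFEST aggregates per-stage status and all warnings raised, so no
stage silently swallows them.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

import nodsource
from nodsource.core_io import (
    COMPARTMENTS,
    CountTable,
    PhenotypeTable,
    ValidationError,
    read_count_table,
    read_metadata,
    read_phenotypes,
    read_taxonomy,
    validate_mock_community,
    write_count_table,
)
from nodsource.preprocess import css_normalize, remove_organelles, replicate_presence_filter
from nodsource.community import (
    bray_curtis,
    nmds_embed,
    observed_richness,
    permanova,
    venn_partition,
)
from nodsource.source_tracking import (
    attribution_percentages,
    chord_matrix,
    recruited_family_summary,
)
from nodsource.stats_models import anova_tukey_cld, recruitment_model

log = logging.getLogger("nodsource")


class PipelineError(RuntimeError):
    """A stage failed; partial outputs and the MANIFEST are retained."""


@dataclass
class PipelineConfig:
    """Paths, filter settings and analysis toggles for a full run."""

    counts_path: str
    metadata_path: str
    taxonomy_path: str
    out_dir: str
    phenotype_path: str | None = None
    count_format: str = "tsv"
    samples_as_rows: bool = False
    min_reps: int = 2
    css_quantile: float = 0.5
    css_scale: float = 1000.0
    permanova_terms: list = field(
        default_factory=lambda: ["compartment", "treatment", "compartment:treatment"]
    )
    n_perm: int = 999
    nmds_restarts: int = 20
    seed: int = 0
    alpha: float = 0.05
    log_offset: float = 1.0
    weights: str = "asv_count"
    collapse_bulk_roots: bool = False
    presence_on_normalized: bool = False
    venn_compartments: list = field(default_factory=lambda: list(COMPARTMENTS))
    mock_sample_id: str | None = None
    mock_expected: list = field(default_factory=list)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls(**doc)

    def validate_paths(self) -> None:
        paths = [self.counts_path, self.metadata_path, self.taxonomy_path]
        if self.phenotype_path:
            paths.append(self.phenotype_path)
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise ValidationError(f"configured paths do not exist: {missing}")

    def digest(self) -> str:
        """Hash of the analysis settings (paths excluded, so runs of the same
        configuration in different locations are comparable)."""
        doc = {k: v for k, v in asdict(self).items() if not k.endswith(("_path", "_dir"))}
        blob = json.dumps(doc, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _header(config: PipelineConfig) -> list[str]:
    return [
        f"nodsource {nodsource.__version__}",
        f"seed={config.seed}",
        f"config={config.digest()}",
    ]


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, index=True, index_label=None) -> None:
    with open(path, "w") as fh:
        for line in _header(config):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label)


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage; returns the output directory.

    On a stage failure the MANIFEST marks the stage ``failed`` (subsequent
    stages ``skipped``) and :class:`PipelineError` is raised; outputs of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_names = ["validate", "preprocess", "diversity", "venn", "sourcetrack", "stats"]
    manifest = {
        "stages": {s: "pending" for s in stage_names},
        "warnings": {},
        "seed": config.seed,
        "config": config.digest(),
        "version": nodsource.__version__,
    }
    state: dict = {}

    def finish() -> None:
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)

    for stage in stage_names:
        func = _STAGES[stage]
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                func(config, out, state)
            manifest["warnings"][stage] = [str(w.message) for w in caught]
            manifest["stages"][stage] = "ok"
            log.info("stage %s: ok", stage)
        except Exception as exc:
            manifest["stages"][stage] = "failed"
            for later in stage_names[stage_names.index(stage) + 1 :]:
                manifest["stages"][later] = "skipped"
            manifest["warnings"][stage] = [f"error: {exc}"]
            finish()
            raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    finish()
    return out


def _stage_validate(config: PipelineConfig, out: Path, state: dict) -> None:
    config.validate_paths()
    counts = read_count_table(
        config.counts_path, format=config.count_format, samples_as_rows=config.samples_as_rows
    )
    meta = read_metadata(config.metadata_path)
    taxonomy = read_taxonomy(config.taxonomy_path)
    ignore = [config.mock_sample_id] if config.mock_sample_id else []
    meta.check_covers(counts, ignore=ignore)
    if config.mock_sample_id and config.mock_expected:
        report = validate_mock_community(
            counts, taxonomy, config.mock_expected, config.mock_sample_id
        )
        with open(out / "mock_report.json", "w") as fh:
            json.dump(
                {
                    "summary": report.summary,
                    "missing": report.missing,
                    "never_observed": report.never_observed,
                    "relative_abundance": report.relative_abundance,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
    if config.mock_sample_id and config.mock_sample_id in counts.data.columns:
        counts = counts.drop_samples([config.mock_sample_id]).drop_empty_asvs()
    state["counts"] = counts
    state["meta"] = meta
    state["taxonomy"] = taxonomy
    if config.phenotype_path:
        state["phenotypes"] = read_phenotypes(config.phenotype_path)


def _stage_preprocess(config: PipelineConfig, out: Path, state: dict) -> None:
    counts, taxonomy = state["counts"], state["taxonomy"]
    cleaned, org_log = remove_organelles(counts, taxonomy)
    _write_tsv(org_log.to_frame(), out / "organelle_removal.tsv", config)
    filtered = replicate_presence_filter(cleaned, state["meta"], min_reps=config.min_reps)
    write_count_table(filtered, out / "counts_filtered.tsv", header_lines=_header(config))
    normalized = css_normalize(
        filtered, quantile_level=config.css_quantile, output_scale=config.css_scale
    )
    _write_tsv(normalized.data, out / "css_normalized.tsv", config, index_label="asv_id")
    _write_tsv(
        normalized.scaling_factors.to_frame(), out / "css_factors.tsv", config,
        index_label="sample_id",
    )
    state["filtered"] = filtered
    state["normalized"] = normalized


def _stage_diversity(config: PipelineConfig, out: Path, state: dict) -> None:
    filtered, meta = state["filtered"], state["meta"]
    rich = observed_richness(filtered).to_frame()
    rich = rich.join(meta.data[["compartment", "treatment", "block", "replicate"]])
    _write_tsv(rich, out / "richness.tsv", config, index_label="sample_id")
    state["richness"] = rich

    dmat = bray_curtis(state["normalized"])
    _write_tsv(dmat.to_frame(), out / "bray_curtis.tsv", config, index_label="sample_id")
    ord_res = nmds_embed(dmat, n_restarts=config.nmds_restarts, seed=config.seed)
    nm = ord_res.to_frame()
    nm["stress"] = ord_res.stress
    _write_tsv(nm, out / "nmds.tsv", config, index_label="sample_id")
    perm = permanova(dmat, meta, config.permanova_terms, n_perm=config.n_perm, seed=config.seed)
    _write_tsv(perm.table, out / "permanova.tsv", config, index_label="term")
    state["permanova"] = perm


def _stage_venn(config: PipelineConfig, out: Path, state: dict) -> None:
    table = state["normalized"] if config.presence_on_normalized else state["filtered"]
    meta = state["meta"]
    present = set(meta.data["compartment"])
    for comp in [c for c in config.venn_compartments if c in present]:
        part = venn_partition(table, meta, group_factor="treatment", within=comp)
        _write_tsv(part.to_frame(), out / f"venn_{comp}_summary.tsv", config, index=False)
        _write_tsv(part.to_long_frame(), out / f"venn_{comp}_cells.tsv", config, index=False)


def _stage_sourcetrack(config: PipelineConfig, out: Path, state: dict) -> None:
    table = state["normalized"] if config.presence_on_normalized else state["filtered"]
    if config.presence_on_normalized:
        table = CountTable((table.data > 0).astype(int))
    result = attribution_percentages(
        table,
        state["meta"],
        weights=config.weights,
        collapse_bulk_roots=config.collapse_bulk_roots,
    )
    _write_tsv(result.per_block, out / "attribution_blocks.tsv", config, index=False)
    _write_tsv(result.treatment_means, out / "attribution_means.tsv", config, index=False)
    _write_tsv(chord_matrix(result), out / "chord.tsv", config, index=False)
    fam = recruited_family_summary(result, state["taxonomy"])
    _write_tsv(fam, out / "family_summary.tsv", config, index=False)
    state["attribution"] = result


def _stage_stats(config: PipelineConfig, out: Path, state: dict) -> None:
    result = state["attribution"]
    response = "percent" if config.weights == "asv_count" else "read_percent"
    model = recruitment_model(result, response=response, offset=config.log_offset, alpha=config.alpha)
    _write_tsv(model.anova, out / "recruitment_anova.tsv", config, index_label="term")
    _write_tsv(model.pairwise, out / "recruitment_pairwise.tsv", config, index=False)

    rich = state["richness"]
    for comp in ("root", "nodule"):
        sub = rich[rich["compartment"] == comp]
        if sub.empty or sub["treatment"].nunique() < 2:
            continue
        anova, cld = anova_tukey_cld(sub, "observed_asvs", ["treatment"], alpha=config.alpha)
        _write_tsv(anova, out / f"richness_anova_{comp}.tsv", config, index_label="term")
        if cld is not None:
            summary = cld.means.to_frame("mean")
            summary["letters"] = pd.Series(cld.letters)
            _write_tsv(summary, out / f"richness_cld_{comp}.tsv", config, index_label="treatment")

    if "phenotypes" in state:
        pheno: PhenotypeTable = state["phenotypes"]
        rows = []
        for var in pheno.variables:
            anova, cld = anova_tukey_cld(pheno.data, var, ["treatment"], alpha=config.alpha)
            for trt, letters in (cld.letters if cld else {}).items():
                rows.append(
                    {"variable": var, "treatment": trt,
                     "mean": cld.means[trt], "letters": letters}
                )
        if rows:
            _write_tsv(pd.DataFrame(rows), out / "phenotype_cld.tsv", config, index=False)


_STAGES = {
    "validate": _stage_validate,
    "preprocess": _stage_preprocess,
    "diversity": _stage_diversity,
    "venn": _stage_venn,
    "sourcetrack": _stage_sourcetrack,
    "stats": _stage_stats,
}
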