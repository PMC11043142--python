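"""Orchestration: simulate -> filter -> enrich -> burden -> density -> ld -> report.

A :class:`PipelineConfig` (typically loaded from YAML) names the enabled
stages, their parameters and the working directory.  Stages communicate
only through files, so any stage can be rerun in isolation; a run writes
a ``manifest.json`` with the full configuration, input checksums and
output paths.  Outputs carry no timestamps, so a rerun with an identical
configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import burden as burden_mod
from . import density as density_mod
from .datamodel import filter_rare_missense, single_interval_gene
from .enrichment import enrich_variants
from .io import (
    load_fmd_cohort_fixture,
    read_control_table,
    read_genotype_matrix,
    read_variant_table,
    write_results,
)
from .ld import ld_matrix
from .populations import GNOMAD_V21_EXOMES, make_panel
from .simulate import (
    SimulationConfig,
    simulate_cohort,
    simulate_control_panel,
    simulate_frequency_table,
    simulate_genotypes,
)

logger = logging.getLogger("varburden")

ALL_STAGES = ("simulate", "filter", "enrich", "burden", "density", "ld", "report")


class ConfigError(ValueError):
    """Raised for invalid pipeline configuration (exit code 2 in the CLI)."""


@dataclass
class PipelineConfig:
    out_dir: str = "varburden_run"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    variants_path: str | None = None  # external variant table; else simulated
    controls_path: str | None = None
    genotypes_path: str | None = None
    simulate: dict = field(default_factory=dict)  # SimulationConfig overrides
    reference_population: str = "NFE"
    af_threshold: float = 0.01
    alpha: float = 0.05
    ci_method: str = "woolf"
    zero_policy: str = "none"
    comparison_populations: tuple[str, ...] = ("AFR", "EAS", "SAS", "AMR")
    burden_populations: tuple[str, ...] = ("NFE", "GLOBAL")
    control_tolerance: int = 439
    halfwidth: int = 100
    step: int = 1
    expected_overall: float | None = None  # expected missense count, whole release
    density_populations: tuple[str, ...] = ("NFE", "AFR", "EAS", "SAS", "AMR")

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigError(f"unknown stages {unknown}; known: {list(ALL_STAGES)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("pipeline config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"unknown config keys {sorted(unknown)}; known: {sorted(known)}"
            )
        for key in ("stages", "comparison_populations", "burden_populations",
                    "density_populations"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulation_config(config: PipelineConfig) -> SimulationConfig:
    params = dict(config.simulate)
    known = {f.name for f in dataclasses.fields(SimulationConfig)}
    unknown = set(params) - known
    if unknown:
        raise ConfigError(f"unknown simulate keys {sorted(unknown)}")
    params.setdefault("seed", config.seed)
    if "gene" in params and isinstance(params["gene"], dict):
        g = params["gene"]
        params["gene"] = single_interval_gene(
            g.get("gene_symbol", "GENE1"), int(g["cds_length"]),
            contig=g.get("contig", "chr11"), start=int(g.get("start", 0)),
        )
    for key in ("planted_enrichments", "ldr_segments", "planted_cohort_ac", "ld_blocks"):
        if key in params:
            params[key] = tuple(
                tuple(tuple(x) if isinstance(x, list) else x for x in item)
                for item in params[key]
            )
    return SimulationConfig(**params)


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in fixed order; returns the manifest.

    A failing stage aborts the run with :class:`StageError` naming the
    stage, after removing any files it had partially written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": [],
        "outputs": {},
        "input_checksums": {},
    }
    staged: dict[str, str] = {}
    for path_key in ("variants_path", "controls_path", "genotypes_path"):
        p = getattr(config, path_key)
        if p is not None:
            manifest["input_checksums"][path_key] = _checksum(Path(p))

    def record_outputs(stage: str, outputs: dict[str, str]) -> None:
        manifest["stages"].append(stage)
        for name, path in outputs.items():
            manifest["outputs"][name] = {
                "path": path,
                "sha256": _checksum(Path(path)),
            }
        staged.update(outputs)

    sim_cfg = _simulation_config(config) if "simulate" in config.stages else None
    panel = GNOMAD_V21_EXOMES

    def run_stage(name, fn) -> None:
        before = {p for p in out.rglob("*") if p.is_file()}
        try:
            fn()
        except ConfigError:
            raise
        except Exception as exc:
            for path in {p for p in out.rglob("*") if p.is_file()} - before:
                path.unlink(missing_ok=True)
            logger.error("stage %s failed: %s", name, exc)
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    def gene_model():
        return sim_cfg.gene if sim_cfg is not None else single_interval_gene(
            "GENE1", 8778
        )

    def load_variants():
        variants_path = config.variants_path or staged.get("variants")
        if variants_path is None:
            return load_fmd_cohort_fixture(), GNOMAD_V21_EXOMES
        fmt = "vcf-sites" if str(variants_path).endswith(".vcf") else "tsv"
        return read_variant_table(variants_path, format=fmt, panel=panel), panel

    def load_cohort_records():
        path = staged.get("filtered_variants") or config.variants_path or staged.get("variants")
        if path is None:
            return load_fmd_cohort_fixture(), GNOMAD_V21_EXOMES
        return read_variant_table(path, panel=panel), panel

    def stage_simulate():
        nonlocal panel
        logger.info("stage simulate: seed=%d", sim_cfg.seed)
        records, truth = simulate_frequency_table(sim_cfg)
        cohort = simulate_cohort(sim_cfg, records)
        controls = simulate_control_panel(sim_cfg)
        sim_panel = make_panel(
            {**sim_cfg.populations, "GLOBAL": sum(sim_cfg.populations.values())}
        )
        tables = {
            "variants": list(cohort.variants),
            "panel": sim_panel,
            "controls": controls,
        }
        if sim_cfg.ld_blocks:
            tables["genotypes"] = simulate_genotypes(
                sim_cfg, n_variants=max(i for (p, _, _) in sim_cfg.ld_blocks for i in p) + 1
            )
        outputs = write_results(tables, out)
        truth_path = out / "truth.json"
        truth.to_json(truth_path)
        outputs["truth"] = str(truth_path)
        record_outputs("simulate", outputs)
        panel = sim_panel

    def stage_filter():
        records, pnl = load_variants()
        cohort = filter_rare_missense(
            records, config.reference_population, config.af_threshold
        )
        logger.info("stage filter: %d records kept", len(cohort.variants))
        outputs = write_results(
            {"variants": list(cohort.variants), "panel": pnl}, out / "filtered"
        )
        record_outputs("filter", {"filtered_variants": outputs["variants"]})

    def stage_enrich():
        records, pnl = load_cohort_records()
        pairs = [
            (config.reference_population, other)
            for other in config.comparison_populations
        ]
        df = enrich_variants(
            records, pairs, panel=pnl, alpha=config.alpha,
            ci_method=config.ci_method, zero_policy=config.zero_policy,
        )
        record_outputs("enrich", write_results({"enrichment": df}, out))

    def stage_burden():
        records, pnl = load_cohort_records()
        cohort = filter_rare_missense(
            records, config.reference_population, config.af_threshold
        )
        # Burden aggregates the variants actually observed in the cohort
        # (the cohort-vs-population comparison is defined on that set).
        carried = [v for v in cohort.variants if v.cohort_ac]
        if carried:
            cohort = dataclasses.replace(cohort, variants=tuple(carried))
        results = [
            burden_mod.gene_burden_or(cohort, population=code, panel=pnl,
                                      gene_symbol=gene_model().gene_symbol)
            for code in config.burden_populations
            if code in pnl
        ]
        results = burden_mod.attach_qvalues(results)
        tables = {"burden": pd.DataFrame([r.__dict__ for r in results])}
        controls_path = config.controls_path or staged.get("controls")
        if controls_path:
            controls = read_control_table(controls_path)
            gene = gene_model()
            selected = burden_mod.select_controls(
                controls, gene, config.control_tolerance
            )
            if selected:
                pct = []
                for code in sorted(selected[0].rare_missense_count):
                    focal_count = sum(1 for v in cohort.variants if v.af(code) > 0)
                    pct.append(
                        burden_mod.percentile_rank(
                            selected, focal_count, code,
                            gene_symbol=gene.gene_symbol,
                        ).__dict__
                    )
                tables["percentile"] = pd.DataFrame(pct)
        record_outputs("burden", write_results(tables, out))

    def stage_density():
        records, pnl = load_variants()
        gene = gene_model()
        overall = (config.expected_overall
                   if config.expected_overall is not None else float(len(records)))
        expected = density_mod.ExpectedCounts(
            overall=overall,
            scale=density_mod.an_share_scales(pnl)
            if "GLOBAL" in pnl
            else {c: 1.0 for c in pnl},
        )
        profiles, regions = {}, {}
        for code in config.density_populations:
            if code not in pnl:
                continue
            profile = density_mod.density_profile(
                records, gene, code, config.halfwidth, config.step
            ).with_threshold(density_mod.population_threshold(expected, gene, code))
            profiles[code] = profile
            regions[code] = (density_mod.call_regions(profile), profile)
        sim_rows = []
        codes = list(profiles)
        for i, a in enumerate(codes):
            for b in codes[i + 1:]:
                sim_rows.append(
                    {"pop1": a, "pop2": b,
                     "similarity_pct": density_mod.profile_similarity(
                         regions[a][0], regions[b][0])}
                )
        record_outputs(
            "density",
            write_results(
                {"density": profiles, "regions": regions,
                 "similarity": pd.DataFrame(sim_rows),
                 "chrom": gene.transcript_id},
                out,
            ),
        )

    def stage_ld():
        genotypes_path = config.genotypes_path or staged.get("genotypes")
        if genotypes_path is None:
            raise ConfigError("ld stage needs genotypes (simulate or genotypes_path)")
        genotypes = read_genotype_matrix(genotypes_path)
        record_outputs("ld", write_results({"ld": ld_matrix(genotypes)}, out))

    def stage_report():
        path = out / "report.md"
        path.write_text(report(manifest))
        record_outputs("report", {"report": str(path)})

    stage_fns = {
        "simulate": stage_simulate,
        "filter": stage_filter,
        "enrich": stage_enrich,
        "burden": stage_burden,
        "density": stage_density,
        "ld": stage_ld,
        "report": stage_report,
    }
    for name in ALL_STAGES:
        if name in config.stages:
            run_stage(name, stage_fns[name])

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return manifest


def report(manifest: dict) -> str:
    """Human-readable per-stage summary of a run's outputs."""
    out = ["# varburden run report", ""]
    outputs = manifest.get("outputs", {})

    def path_of(name):
        entry = outputs.get(name)
        return None if entry is None else entry["path"]

    enrich_path = path_of("enrichment")
    out.append("## Enrichment")
    if enrich_path and Path(enrich_path).exists():
        df = pd.read_csv(enrich_path, sep="\t")
        n_var = df["variant"].nunique() if len(df) else 0
        out.append(f"- variants compared: {n_var}")
        if len(df) == 0 or not df["enriched"].any():
            out.append("- 0 enriched comparisons")
        else:
            per_pair = (
                df[df["enriched"]].groupby(["pop1", "pop2"]).size().sort_index()
            )
            for (p1, p2), n in per_pair.items():
                out.append(f"- enriched in {p1} vs {p2}: {n}")
        n_dep = int(df["depleted"].sum()) if len(df) else 0
        out.append(f"- depleted comparisons: {n_dep}")
    else:
        out.append("- absent")
    out.append("")

    out.append("## Gene burden")
    burden_path = path_of("burden")
    if burden_path and Path(burden_path).exists():
        df = pd.read_csv(burden_path, sep="\t")
        for _, row in df.iterrows():
            out.append(
                f"- vs {row['population']}: OR {row['or_point']:.2f} "
                f"[{row['ci_low']:.2f}-{row['ci_high']:.2f}], "
                f"q = {row['q_value']:.3g}"
            )
    else:
        out.append("- absent")
    out.append("")

    out.append("## Density")
    density_outputs = sorted(k for k in outputs if k.startswith("density_"))
    if density_outputs:
        for key in density_outputs:
            df = pd.read_csv(outputs[key]["path"], sep="\t")
            ldr_frac = float((df["label"] == "LDR").mean())
            out.append(
                f"- {key.removeprefix('density_')}: LDR fraction of CDS "
                f"{100 * ldr_frac:.1f}%"
            )
    else:
        out.append("- absent")
    out.append("")

    out.append("## Linkage disequilibrium")
    ld_path = path_of("ld")
    if ld_path and Path(ld_path).exists():
        df = pd.read_csv(ld_path, sep="\t", index_col=0)
        r2 = df.to_numpy()
        ids = list(df.columns)
        pairs = [
            (r2[i, j], ids[i], ids[j])
            for i in range(len(ids))
            for j in range(i + 1, len(ids))
            if r2[i, j] == r2[i, j]
        ]
        for value, a, b in sorted(pairs, reverse=True)[:5]:
            out.append(f"- {a} x {b}: r2 = {value:.3f}")
        if not pairs:
            out.append("- no informative pair")
    else:
        out.append("- absent")
    out.append("")
    return "\n".join(out) + "\n"
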