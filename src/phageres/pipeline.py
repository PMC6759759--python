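"""End-to-end orchestration: simulate -> growth -> RBG -> fitness -> variants -> stats.

Every stage writes a TSV/CSV with a metadata header (package version,
stage, seed, config hash) into a run directory, and a manifest records the
files, so a fixed seed reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .design import ExperimentDesign, Phage, RegimeKind
from .fitness import fitness_by_mutation_burden, fitness_frame, fitness_table
from .growth import NO_PHAGE, extract_metrics, metrics_frame, read_plate_csv
from .resistance import rbg_table, resistance_matrix
from .stats import blocked_anova, tukey_frame, tukey_hsd
from .synthetic import (
    SimulationConfig,
    make_true_params,
    simulate_coverage_track,
    simulate_curves,
    simulate_variant_table,
    write_truth_json,
)
from .variants import (
    GeneCategoryTable,
    call_svs,
    classify_and_count,
    flag_ancestral_background,
    lineage_filename,
    packaged_gene_categories,
    quality_filter,
    read_depth_tsv,
    read_vcf_dir,
    remove_shared_variants,
    sv_frame,
    write_depth_tsv,
    write_vcf,
)
from .synthetic import PAO1_CHROM


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run, loadable from YAML."""

    design: ExperimentDesign
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    growth_window: int = 5
    growth_min_rate: float = 0.005
    rbg_clip: bool = False
    rbg_min_denominator: float = 0.02
    variant_min_depth: int = 20
    variant_min_alt_fraction: float = 0.8
    sv_del_ratio: float = 0.25
    sv_dup_ratio: float = 1.75
    sv_min_deletion_bp: int = 100
    category_table: str | None = None  # None -> packaged table
    stats_interaction: bool = False
    coverage_scope: str = "with_sv"  # or "all"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        d = raw.get("design", {})
        design = ExperimentDesign(
            ancestors=d.get("ancestors", ["PAO1_FT1", "PAO1_FT2", "PAO1_FT3"]),
            phages=[Phage(p["name"], p["receptor"]) for p in d.get("phages", [])]
            or [
                Phage("PA5P2", "TYPE_IV_PILUS"),
                Phage("PT7", "TYPE_IV_PILUS"),
                Phage("PA10P2", "LPS"),
                Phage("14/1", "LPS"),
            ],
            excluded_phages=d.get("excluded_phages", ["PT7"]),
        )
        sim = SimulationConfig(**raw.get("simulation", {}))
        kwargs = {k: v for k, v in raw.items() if k not in ("design", "simulation")}
        return cls(design=design, simulation=sim, **kwargs)

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "design": {
                    "ancestors": self.design.ancestors,
                    "phages": [(p.name, p.receptor.value) for p in self.design.phages],
                    "excluded": self.design.excluded_phages,
                },
                "simulation": {
                    k: getattr(self.simulation, k)
                    for k in sorted(vars(self.simulation))
                },
                "options": {
                    k: v
                    for k, v in sorted(vars(self).items())
                    if k not in ("design", "simulation")
                },
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write_table(df: pd.DataFrame, path: Path, stage: str, config: PipelineConfig,
                 sep: str = "\t") -> None:
    with open(path, "w") as fh:
        fh.write(f"# phageres {__version__}\n")
        fh.write(f"# stage: {stage}\n")
        fh.write(f"# seed: {config.simulation.seed}\n")
        fh.write(f"# config_hash: {config.config_hash()}\n")
        df.to_csv(fh, sep=sep, index=False)


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage on synthetic data; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.simulation.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    # --- simulate -----------------------------------------------------------
    stage = "simulate"
    try:
        truth = make_true_params(config.design, config.simulation)
        curves_df = simulate_curves(truth, config.simulation)
        curves_path = outdir / "curves.csv"
        _write_table(curves_df, curves_path, stage, config, sep=",")
        write_truth_json(truth, outdir / "truth.json")
        vcf_dir = outdir / "vcf"
        vcf_dir.mkdir(exist_ok=True)
        variant_records = simulate_variant_table(truth, config.simulation)
        by_lin: dict[str, list] = {}
        for r in variant_records:
            by_lin.setdefault(r.lineage, []).append(r)
        for lin, recs in sorted(by_lin.items()):
            write_vcf(recs, vcf_dir / f"{lineage_filename(lin)}.vcf",
                      PAO1_CHROM, config.simulation.genome_length_bp)
        cov_dir = outdir / "coverage"
        cov_dir.mkdir(exist_ok=True)
        sequenced = [p for p in truth if p.lineage.regime is not None]
        if config.coverage_scope == "with_sv":
            tracked = [p for p in sequenced if p.sv_events] + sequenced[:1]
        else:
            tracked = sequenced
        for p in tracked:
            path = cov_dir / f"{lineage_filename(p.lineage.label)}.depth.tsv"
            write_depth_tsv(simulate_coverage_track(p, config.simulation), path)
        manifest["stages"][stage] = {
            "curves": curves_path.name,
            "truth": "truth.json",
            "vcf_dir": "vcf",
            "coverage_dir": "coverage",
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- growth metrics -----------------------------------------------------
    stage = "growth"
    try:
        curves = read_plate_csv(curves_path)
        metrics = [
            extract_metrics(c, window=config.growth_window, min_rate=config.growth_min_rate)
            for c in curves
        ]
        mdf = metrics_frame(metrics)
        _write_table(mdf, outdir / "metrics.tsv", stage, config)
        manifest["stages"][stage] = {"metrics": "metrics.tsv"}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- resistance ---------------------------------------------------------
    stage = "resistance"
    try:
        mutant_curves = [c for c in curves if "|ancestor|" not in c.lineage]
        records = rbg_table(
            mutant_curves,
            min_denominator=config.rbg_min_denominator,
            clip=config.rbg_clip,
        )
        rbg_df = pd.DataFrame(
            [
                {
                    "lineage": r.lineage,
                    "assay_phage": r.assay_phage,
                    "endpoint_h": r.endpoint_h,
                    "replicate": r.replicate,
                    "rbg": r.rbg,
                    "clipped": r.clipped,
                    "undefined_reason": r.undefined_reason or "",
                }
                for r in records
            ]
        )
        _write_table(rbg_df, outdir / "rbg.tsv", stage, config)
        matrix = resistance_matrix(records)
        _write_table(matrix, outdir / "rbg_matrix.tsv", stage, config)
        manifest["stages"][stage] = {"rbg": "rbg.tsv", "matrix": "rbg_matrix.tsv"}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- fitness ------------------------------------------------------------
    stage = "fitness"
    try:
        ancestor_labels = {
            m.lineage for m in metrics if "|ancestor|" in m.lineage
        }
        fit_records = fitness_table(metrics, ancestor_labels)
        fdf = fitness_frame(fit_records)
        _write_table(fdf, outdir / "fitness.tsv", stage, config)
        manifest["stages"][stage] = {"fitness": "fitness.tsv"}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- variants + SV ------------------------------------------------------
    stage = "variants"
    try:
        if config.category_table is not None:
            table_path = Path(config.category_table)
            if not table_path.exists():
                raise FileNotFoundError(f"category table not found: {table_path}")
            table = GeneCategoryTable.from_tsv(table_path)
        else:
            table = packaged_gene_categories()
        raw_records = read_vcf_dir(vcf_dir)
        kept = quality_filter(
            raw_records,
            min_depth=config.variant_min_depth,
            min_alt_fraction=config.variant_min_alt_fraction,
        )
        kept, discarded = remove_shared_variants(kept)
        pedigree = {
            lin: lin.split("|", 1)[0] for lin in {r.lineage for r in kept}
        }
        flagged = flag_ancestral_background(kept, pedigree)
        annotated, counts = classify_and_count(flagged, table)
        vdf = pd.DataFrame(
            [
                {
                    "lineage": r.lineage,
                    "chrom": r.chrom,
                    "pos": r.pos,
                    "ref": r.ref,
                    "alt": r.alt,
                    "depth": r.depth,
                    "alt_count": r.alt_count,
                    "gene": r.gene or "",
                    "category": r.category.value if r.category else "",
                    "background": r.background,
                }
                for r in annotated
            ]
        )
        _write_table(vdf, outdir / "mutations.tsv", stage, config)
        _write_table(counts, outdir / "mutation_counts.tsv", stage, config)
        sv_calls = []
        for path in sorted(cov_dir.glob("*.depth.tsv")):
            lin = path.name[: -len(".depth.tsv")].replace("%2F", "/").replace("%7C", "|")
            track = read_depth_tsv(path)
            sv_calls.extend(
                call_svs(
                    track,
                    config.simulation.genome_length_bp,
                    lineage=lin,
                    del_ratio=config.sv_del_ratio,
                    dup_ratio=config.sv_dup_ratio,
                    min_deletion_bp=config.sv_min_deletion_bp,
                )
            )
        _write_table(sv_frame(sv_calls), outdir / "sv_calls.tsv", stage, config)
        manifest["stages"][stage] = {
            "mutations": "mutations.tsv",
            "counts": "mutation_counts.tsv",
            "sv_calls": "sv_calls.tsv",
            "n_shared_discarded": len(discarded),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- stats --------------------------------------------------------------
    stage = "stats"
    try:
        stats_files = {}
        # RBG: treatment = regime kind, blocked by ancestor, phage pair, endpoint
        rbg_obs = rbg_df[rbg_df["undefined_reason"] == ""].copy()
        parts = rbg_obs["lineage"].str.split("|", expand=True)
        rbg_obs["ancestor"] = parts[0]
        rbg_obs["regime"] = parts[1].str.split(":").str[0]
        rbg_obs["phage_pair"] = (
            parts[1].str.split(":").str[1].str.replace(">", "+", regex=False)
            .map(lambda s: "+".join(sorted(s.split("+"))))
        )
        terms = ["ancestor", "phage_pair"]
        if rbg_obs["endpoint_h"].nunique() > 1:
            terms.append("endpoint_h")
        terms.append("regime")
        if config.stats_interaction:
            terms.append("regime:phage_pair")
        anova = blocked_anova(rbg_obs, "rbg", terms)
        _write_table(anova.to_frame(), outdir / "anova_rbg.tsv", stage, config)
        tuk = tukey_hsd(anova, "regime", rbg_obs, "rbg")
        _write_table(tukey_frame(tuk), outdir / "tukey_rbg.tsv", stage, config)
        stats_files["anova_rbg"] = "anova_rbg.tsv"
        stats_files["tukey_rbg"] = "tukey_rbg.tsv"

        # fitness: same blocking minus endpoint
        fit_obs = fdf.copy()
        parts = fit_obs["lineage"].str.split("|", expand=True)
        fit_obs["ancestor"] = parts[0]
        fit_obs["regime"] = parts[1].str.split(":").str[0]
        fit_obs["phage_pair"] = (
            parts[1].str.split(":").str[1].str.replace(">", "+", regex=False)
            .map(lambda s: "+".join(sorted(s.split("+"))))
        )
        anova_fit = blocked_anova(fit_obs, "relative_fitness",
                                  ["ancestor", "phage_pair", "regime"])
        _write_table(anova_fit.to_frame(), outdir / "anova_fitness.tsv", stage, config)
        tuk_fit = tukey_hsd(anova_fit, "regime", fit_obs, "relative_fitness")
        _write_table(tukey_frame(tuk_fit), outdir / "tukey_fitness.tsv", stage, config)
        stats_files["anova_fitness"] = "anova_fitness.tsv"
        stats_files["tukey_fitness"] = "tukey_fitness.tsv"

        # mutation counts: blocked by ancestor
        cnt = counts.copy()
        parts = cnt["lineage"].str.split("|", expand=True)
        cnt["ancestor"] = parts[0]
        cnt["regime"] = parts[1].str.split(":").str[0]
        anova_cnt = blocked_anova(cnt, "total", ["ancestor", "regime"])
        _write_table(anova_cnt.to_frame(), outdir / "anova_mutation_count.tsv",
                     stage, config)
        tuk_cnt = tukey_hsd(anova_cnt, "regime", cnt, "total")
        _write_table(tukey_frame(tuk_cnt), outdir / "tukey_mutation_count.tsv",
                     stage, config)
        stats_files["anova_mutation_count"] = "anova_mutation_count.tsv"
        stats_files["tukey_mutation_count"] = "tukey_mutation_count.tsv"

        # single- vs multi-mutation fitness (Welch)
        count_map = dict(zip(counts["lineage"], counts["total"]))
        try:
            burden = fitness_by_mutation_burden(fit_records, count_map)
            burden_df = pd.DataFrame(
                [
                    {
                        "n_single": burden.n_single,
                        "n_multiple": burden.n_multiple,
                        "mean_single": burden.mean_single,
                        "mean_multiple": burden.mean_multiple,
                        "t": burden.welch.t,
                        "df": burden.welch.df,
                        "p": burden.welch.p,
                    }
                ]
            )
            _write_table(burden_df, outdir / "fitness_by_burden.tsv", stage, config)
            stats_files["fitness_by_burden"] = "fitness_by_burden.tsv"
        except ValueError:
            pass  # too few lineages in one burden group; comparison skipped
        manifest["stages"][stage] = stats_files
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


REQUIRED_OUTPUTS = [
    "rbg_matrix.tsv",
    "fitness.tsv",
    "mutation_counts.tsv",
    "mutations.tsv",
]


def summarize(run_dir) -> dict[str, pd.DataFrame]:
    """Assemble presentation tables from a completed run directory.

    Produces per-regime resistance matrices, fitness per regime with the
    simultaneous-selection mean as a reference value, mutation counts by
    category, and observed mean relative fitness per mutated genotype with
    the additive-cost prediction.  No statistics are recomputed here.
    """
    run_dir = Path(run_dir)
    missing = [f for f in REQUIRED_OUTPUTS if not (run_dir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"incomplete run at {run_dir}: missing {', '.join(missing)}"
        )
    out_dir = run_dir / "summary"
    out_dir.mkdir(exist_ok=True)
    read = lambda name: pd.read_csv(run_dir / name, sep="\t", comment="#")  # noqa: E731

    tables: dict[str, pd.DataFrame] = {}
    matrix = read("rbg_matrix.tsv")
    parts = matrix["lineage"].str.split("|", expand=True)
    matrix["regime"] = parts[1].str.split(":").str[0]
    for regime, grp in matrix.groupby("regime"):
        tab = grp.pivot_table(index="lineage", columns="assay_phage",
                              values="rbg_mean").reset_index()
        tables[f"resistance_{regime}"] = tab
        tab.to_csv(out_dir / f"resistance_{regime}.tsv", sep="\t", index=False)

    fit = read("fitness.tsv")
    parts = fit["lineage"].str.split("|", expand=True)
    fit["regime"] = parts[1].str.split(":").str[0]
    sim = fit.loc[fit["regime"] == RegimeKind.SIMULTANEOUS.value, "relative_fitness"]
    fit["simultaneous_mean_rf"] = sim.mean() if len(sim) else np.nan
    tables["fitness_by_regime"] = fit
    fit.to_csv(out_dir / "fitness_by_regime.tsv", sep="\t", index=False)
    present = set(fit["regime"])
    notes = [
        f"note: no {k.value} lineages in this run"
        for k in RegimeKind
        if k.value not in present
    ]
    if notes:
        (out_dir / "notes.txt").write_text("\n".join(notes) + "\n")

    counts = read("mutation_counts.tsv")
    parts = counts["lineage"].str.split("|", expand=True)
    counts["regime"] = parts[1].str.split(":").str[0]
    by_cat = counts.groupby("regime")[
        [c for c in counts.columns if c not in ("lineage", "regime")]
    ].mean().reset_index()
    tables["mutation_counts_by_regime"] = by_cat
    by_cat.to_csv(out_dir / "mutation_counts_by_regime.tsv", sep="\t", index=False)

    # cost vs genotype: observed mean RF per mutated gene combination
    muts = read("mutations.tsv")
    muts = muts[~muts["background"]]
    genotype = (
        muts.sort_values("gene")
        .groupby("lineage")["gene"]
        .agg(lambda g: "+".join(g))
        .rename("genotype")
    )
    fit2 = fit.merge(genotype, on="lineage", how="left")
    cost_tab = (
        fit2.groupby("genotype")["relative_fitness"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "mean_rf", "count": "n"})
    )
    singles = muts.merge(counts[["lineage", "total"]], on="lineage")
    singles = singles[singles["total"] == 1]
    single_rf = singles.merge(fit, on="lineage")
    add_pred = np.nan
    by_receptor = single_rf[single_rf["category"].isin(["LPS", "TYPE_IV_PILUS"])]
    if by_receptor["category"].nunique() == 2:
        from .fitness import additive_cost_prediction

        means = by_receptor.groupby("category")["relative_fitness"].mean().to_dict()
        add_pred = additive_cost_prediction(means).value
    cost_tab["additive_prediction_two_receptors"] = add_pred
    tables["cost_vs_genotype"] = cost_tab
    cost_tab.to_csv(out_dir / "cost_vs_genotype.tsv", sep="\t", index=False)
    return tables
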