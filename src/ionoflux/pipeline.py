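"""One-command orchestration: simulate -> phenotype -> ionome -> deg ->
patterns -> pca, with a provenance report.

Every stage writes its outputs as TSV under ``config.out_dir``; rerunning
with the same configuration and seed reproduces every output byte for
byte. Input tables can be supplied via the config paths instead of being
simulated.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .deg import DEModel
from .io import (
    PipelineConfig,
    read_count_matrix,
    read_ionome_table,
    write_count_matrix,
    write_ionome_table,
)
from .ionome import ELEMENTS, IonomeModel
from .multivariate import cumulative_variance, log_normalized_counts, pca
from .patterns import (
    element_direction_counts,
    element_patterns,
    log2fc_matrix,
    upset_exclusive_intersections,
)
from .phenotyping import convex_hull_area, excess_green, projected_area
from .simulate import (
    CountSimConfig,
    IonomeSimConfig,
    gen_annotation,
    gen_count_matrix,
    gen_ionome_dataset,
    gen_plant_image,
)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run report."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            "alpha": config.alpha, "nu_test": config.nu_test,
            "trim_m": config.trim_m, "trim_a": config.trim_a,
            "cpm_threshold": config.cpm_threshold,
            "min_samples": config.min_samples, "dominance": config.dominance,
            "noise_cv": config.noise_cv,
        },
        "stages": {},
    }

    def _stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(f"stage {name!r} failed: {exc}") from exc

    # --- simulate / load inputs -------------------------------------------
    def _inputs():
        if config.ionome_table:
            samples = read_ionome_table(config.ionome_table)
            phenotypes = None
        else:
            sim = IonomeSimConfig(
                species=config.species, n_replicates=config.n_replicates,
                noise_cv=config.noise_cv, seed=config.seed,
            )
            samples, phenotypes, _ = gen_ionome_dataset(sim)
            write_ionome_table(samples, out / "ionome_samples.tsv")
            phenotypes.to_csv(out / "phenotypes.tsv", sep="\t", index=False)
        if config.count_matrix:
            counts = read_count_matrix(config.count_matrix)
            sheet = pd.read_csv(config.sample_sheet, sep="\t")
        else:
            csim = CountSimConfig(
                n_genes=config.n_genes,
                n_samples_per_group=config.n_samples_per_group,
                de_fraction=config.de_fraction,
                planted_log2fc=config.planted_log2fc,
                dispersion=config.count_dispersion, seed=config.seed,
            )
            counts, sheet, truth = gen_count_matrix(csim)
            write_count_matrix(counts, out / "counts.tsv")
            sheet.to_csv(out / "sample_sheet.tsv", sep="\t", index=False)
            truth.to_csv(out / "de_truth.tsv", sep="\t")
        if config.annotation_table:
            annotation = pd.read_csv(config.annotation_table, sep="\t")
        else:
            per_el = {el: 12 for el in ELEMENTS[:10]}
            annotation = gen_annotation(
                n_genes=len(counts), elements=ELEMENTS,
                per_element_counts=per_el, kig_fraction=0.5, seed=config.seed,
            )
            annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
        return samples, phenotypes, counts, sheet, annotation

    samples, phenotypes, counts, sheet, annotation = _stage("simulate", _inputs)
    report["stages"]["simulate"] = {
        "ionome_rows": len(samples),
        "count_genes": len(counts),
        "count_samples": counts.shape[1],
        "annotation_rows": len(annotation),
    }

    # --- phenotyping demo image -------------------------------------------
    def _pheno():
        record, truth = gen_plant_image(
            [{"type": "disk", "cx": 32, "cy": 32, "r": 14},
             {"type": "rect", "x": 28, "y": 8, "w": 8, "h": 24}],
            seed=config.seed,
        )
        tab = pd.DataFrame([{
            "ExG": excess_green(record),
            "side_area": projected_area(record.mask, record.pixel_scale),
            "convex_hull_area": convex_hull_area(record.mask, record.pixel_scale),
            "true_projected_area": truth["projected_area"],
        }])
        tab.to_csv(out / "image_indices.tsv", sep="\t", index=False)
        return tab

    image_tab = _stage("phenotype", _pheno)
    report["stages"]["phenotype"] = {"images": len(image_tab)}

    # --- ionome ------------------------------------------------------------
    def _ionome():
        model = IonomeModel.from_dataframe(samples)
        res = model.fit(alpha=config.alpha, nu_test=config.nu_test,
                        seed=config.seed)
        res.net_uptake_table.to_csv(out / "net_uptake.tsv", sep="\t", index=False)
        res.relative_nu.to_csv(out / "relative_nu.tsv", sep="\t", index=False)
        res.relative_concentration.to_csv(
            out / "relative_concentration.tsv", sep="\t", index=False
        )
        return res

    ion_res = _stage("ionome", _ionome)
    report["stages"]["ionome"] = {
        "nu_estimates": len(ion_res.net_uptake_table),
        "significant_nu_ratios": int(ion_res.relative_nu["significant"].sum()),
    }

    # --- differential expression -------------------------------------------
    def _deg():
        model = DEModel(counts, sheet)
        res = model.fit(
            alpha=config.alpha, cpm_threshold=config.cpm_threshold,
            min_samples=config.min_samples,
            trim_m=config.trim_m, trim_a=config.trim_a,
        )
        for name, tab in res.tables.items():
            tab.to_csv(out / f"deg_{name}.tsv", sep="\t")
        return res

    deg_res = _stage("deg", _deg)
    report["stages"]["deg"] = {
        name: int(tab["deg"].sum()) for name, tab in deg_res.tables.items()
    }
    report["stages"]["deg"]["dispersion"] = {
        k: float(v) for k, v in deg_res.dispersions.items()
    }

    # --- gene patterns ------------------------------------------------------
    def _patterns():
        counts_dir = element_direction_counts(deg_res.tables, annotation)
        pats = element_patterns(counts_dir, dominance=config.dominance)
        named = {}
        for direction in ("up", "down"):
            for name, genes in deg_res.deg_sets(direction).items():
                named[f"{name}_{direction}"] = genes
        profile = upset_exclusive_intersections(named)
        profile_out = profile.copy()
        profile_out["sets"] = profile_out["sets"].map(lambda t: "|".join(t))
        counts_dir.to_csv(out / "element_direction_counts.tsv", sep="\t", index=False)
        pats.to_csv(out / "element_patterns.tsv", sep="\t", index=False)
        profile_out.to_csv(out / "upset_profile.tsv", sep="\t", index=False)
        log2fc_matrix(deg_res.tables, annotation).to_csv(
            out / "log2fc_matrix.tsv", sep="\t"
        )
        return pats, profile

    pats, profile = _stage("patterns", _patterns)
    report["stages"]["patterns"] = {
        "elements_classified": len(pats),
        "upset_subsets": len(profile),
    }

    # --- PCA ----------------------------------------------------------------
    def _pca():
        # elemental content of young leaf blades, one row per plant
        ylb = samples[samples["tissue"] == "YLB"]
        elements = [c for c in ylb.columns if c in ELEMENTS]
        mat = ylb.set_index(["treatment", "harvest", "replicate"])[elements]
        ion_pca = pca(mat, center=True, scale=True)
        expr = log_normalized_counts(
            deg_res.model.counts.loc[deg_res.tables[next(iter(deg_res.tables))].index],
            deg_res.normalization.effective_library_sizes,
        )
        expr = expr.loc[:, expr.std(axis=0) > 0]
        expr_pca = pca(expr, center=True, scale=False)
        rows = []
        for label, res in (("ionome", ion_pca), ("expression", expr_pca)):
            for k in (1, 2):
                rows.append((label, k, cumulative_variance(
                    res.explained_variance_ratio, k)))
        var = pd.DataFrame(rows, columns=["matrix", "k", "cumulative_variance"])
        var.to_csv(out / "pca_variance.tsv", sep="\t", index=False)
        ion_pca.scores.to_csv(out / "pca_ionome_scores.tsv", sep="\t")
        return var

    var = _stage("pca", _pca)
    report["stages"]["pca"] = {
        row["matrix"] + f"_pc{row['k']}": float(row["cumulative_variance"])
        for _, row in var.iterrows()
    }

    (out / "run_report.yaml").write_text(yaml.safe_dump(report, sort_keys=False))
    return report
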