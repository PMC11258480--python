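"""End-to-end orchestration of the analysis stages with a run manifest.

Stage order: simulate (optional) -> differential expression -> epistasis ->
integration (controls, RUV correction, MDS, correlation, overlaps) -> gene-set
enrichment -> RNA-element statistics -> consensus network.  Every stage writes
TSV/JSON outputs into the run directory and registers itself in a manifest
carrying the package version, seed, thresholds and input checksums, so that a
run is reproducible and auditable.  A stage failure raises an error naming the
stage.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .diffexpr import ContrastResult, DispersionModel, test_contrast
from .enrichment import GeneSetCollection, gsea_prerank, read_gmt, results_frame
from .epistasis import EpistasisAnalysis
from .integrate import (
    correlation_panel,
    empirical_controls,
    mds_embed,
    overlap_counts,
    remove_unwanted_variation,
)
from .network import consensus, edge_scores, threshold_edges
from .rna_elements import aggregate_categories, welch_t
from .simulate import CountMatrix, InteractionModel, simulate_counts, simulate_effects


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run every stage on the configured (or simulated) inputs.

    Returns the manifest dict, which is also written to ``manifest.json`` in
    the run directory.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    for field in ("counts", "metadata", "gmt", "annotation"):
        path = getattr(config, field)
        if path is not None and not Path(path).exists():
            raise FileNotFoundError(f"configured input {field!r} not found: {path}")

    manifest: dict = {
        "package": "epistax",
        "version": __version__,
        "python": platform.python_version(),
        "seed": seed,
        "thresholds": {
            "fc": config.fc, "deg_q": config.deg_q, "episel_q": config.episel_q,
            "control_p": config.control_p, "nes": config.nes, "link": config.link,
            "splice_p": config.splice_p, "bcv": config.bcv,
        },
        "inputs": {},
        "stages": [],
    }

    # ---- stage 1: simulate (or load) -------------------------------------
    stage = "simulate"
    try:
        if config.counts is not None:
            cm = CountMatrix.read_tsv(config.counts, config.metadata)
            manifest["inputs"]["counts"] = _checksum(Path(config.counts))
            manifest["inputs"]["metadata"] = _checksum(Path(config.metadata))
        else:
            sim = config.simulate
            model = InteractionModel.preset(sim["model"], noise_sd=sim["noise_sd"])
            effects = simulate_effects(
                model, sim["n_features"], sim["effect_sd"],
                frac_nonnull=sim["frac_nonnull"], seed=seed,
            )
            cm = simulate_counts(
                effects, n_reps=sim["n_reps"], depth_mean=sim["depth_mean"],
                bcv=config.bcv, batch_sd=sim["batch_sd"], seed=seed + 1,
            )
            effects.write_tsv(out / "true_effects.tsv")
            cm.write_tsv(out / "counts.tsv", out / "sample_meta.tsv")
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 2: differential expression --------------------------------
    stage = "de"
    try:
        wt = cm.samples_for("WT")
        disp = DispersionModel(bcv=config.bcv)
        contrasts: dict[str, ContrastResult] = {}
        for genotype in ("A", "B", "AB"):
            res = test_contrast(
                cm, wt, cm.samples_for(genotype), dispersion=disp,
                fc_threshold=config.fc, q_threshold=config.deg_q,
            )
            res.write_tsv(out / f"de_{genotype}_vs_WT.tsv")
            contrasts[genotype] = res
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 3: epistasis ----------------------------------------------
    stage = "epistasis"
    try:
        est = EpistasisAnalysis(
            q_threshold=config.episel_q, n_boot=config.n_boot, seed=seed
        ).fit((contrasts["A"], contrasts["B"], contrasts["AB"]))
        res = est.result_
        report = {
            "s_hat": res.s_hat,
            "boot_mean": res.boot_mean,
            "ci": list(res.ci),
            "n_features": res.n_features,
            "best_model": est.best_model_,
            "model_ranking": [[m, s] for m, s in res.model_ranking],
            "model_overlap": res.model_overlap,
        }
        (out / "epistasis.json").write_text(json.dumps(report, indent=2))
        pd.DataFrame({"boot_s": res.boot}).to_csv(out / "epistasis_boot.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 4: integrate ----------------------------------------------
    stage = "integrate"
    try:
        controls = empirical_controls(list(contrasts.values()), p_threshold=config.control_p)
        panel = remove_unwanted_variation(cm, controls, k=config.ruv_k)
        coords = mds_embed(panel, n_top=config.n_top)
        coords.to_csv(out / "mds_coordinates.tsv", sep="\t")
        profiles = pd.DataFrame({g: c.beta for g, c in contrasts.items()},
                                index=cm.feature_ids)
        comparison = correlation_panel(profiles)
        comparison.r.to_csv(out / "correlation_matrix.tsv", sep="\t")
        deg_sets = {
            g: {f for f, d in zip(c.feature_ids, c.is_deg) if d}
            for g, c in contrasts.items()
        }
        deg_sets = {g: s for g, s in deg_sets.items() if s}
        if len(deg_sets) >= 2:
            overlap_counts(deg_sets).to_csv(out / "overlap_counts.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 5: gene-set enrichment ------------------------------------
    stage = "gsea"
    try:
        if config.gmt is not None:
            collection = read_gmt(config.gmt)
            manifest["inputs"]["gmt"] = _checksum(Path(config.gmt))
        else:
            collection = _synthetic_collection(cm.feature_ids, contrasts["AB"], seed)
        for genotype, res in contrasts.items():
            results = gsea_prerank(
                res, collection, n_perm=config.n_perm, seed=seed
            )
            results_frame(results).to_csv(out / f"gsea_{genotype}.tsv", sep="\t")
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 6: RNA elements -------------------------------------------
    stage = "rna_elements"
    try:
        if config.annotation is not None:
            ann_df = pd.read_csv(config.annotation, sep="\t", index_col=0)
            annotation = ann_df.iloc[:, 0].to_dict()
            manifest["inputs"]["annotation"] = _checksum(Path(config.annotation))
        else:
            cats = ("exonic", "intron_derived", "intergenic", "lincRNA")
            annotation = {f: cats[i % 4] for i, f in enumerate(cm.feature_ids)}
        panel_values = panel.values
        table = aggregate_categories(panel_values, annotation)
        table.to_csv(out / "category_aggregates.tsv", sep="\t")
        rows = []
        wt_samples = cm.samples_for("WT")
        for genotype in ("A", "B", "AB"):
            gsamples = cm.samples_for(genotype)
            if len(wt_samples) < 2 or len(gsamples) < 2:
                continue
            for cat in table.index:
                t, df_, p = welch_t(table.loc[cat, wt_samples], table.loc[cat, gsamples])
                rows.append({"genotype": genotype, "category": cat, "t": t, "df": df_, "p": p})
        if rows:
            pd.DataFrame(rows).to_csv(out / "category_tests.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    # ---- stage 7: network -------------------------------------------------
    stage = "network"
    try:
        scores = edge_scores(profiles)
        net = consensus(scores)
        edges = threshold_edges(net, threshold=config.link, out_dir=out)
        pd.DataFrame(edges, columns=["node_a", "node_b", "intensity"]).to_csv(
            out / "edges.tsv", sep="\t", index=False
        )
        manifest["stages"].append(stage)
    except Exception as exc:  # noqa: BLE001
        raise StageError(stage, exc) from exc

    manifest["outputs"] = {p.name: _checksum(p) for p in sorted(out.glob("*.tsv"))}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _synthetic_collection(feature_ids, contrast: ContrastResult, seed: int) -> GeneSetCollection:
    """Small synthetic gene-set collection for runs without a GMT input:
    random sets plus one set planted on the strongest positive effects."""
    rng = np.random.default_rng(seed)
    ids = list(feature_ids)
    sets = {
        f"random_{i}": list(rng.choice(ids, size=20, replace=False)) for i in range(5)
    }
    order = np.argsort(contrast.beta)[::-1]
    sets["planted_top"] = [ids[j] for j in order[:20]]
    return GeneSetCollection(sets=sets)
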