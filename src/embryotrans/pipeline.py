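"""End-to-end synthetic pipeline orchestration.

One config (YAML or dict) drives the full run: simulate a barnyard mixture
and demultiplex it, simulate structured counts, apply QC and normalization,
annotate cell type and sex, compute the three gene-set scores, run the
within- and cross-generation hurdle DE comparisons, build and apply the
control-generation confounder blacklist, classify cross-generation
directionality, match the conserved mitochondrial catalog and compute
pathway fold enrichment.  Every stage's outputs land as CSV under the
output directory and a JSON manifest records parameters, counts and file
hashes so the run is reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .de import ComparisonSpec, DEThresholds, run_de
from .demux import DemuxConfig, demux_batch
from .generational import (
    apply_confounder_filter,
    build_confounder_blacklist,
    classify_directionality,
    fold_enrichment_test,
    mito_categorize,
)
from .qc import (
    QCThresholds,
    annotate_cell_type,
    classify_sex,
    compute_qc_metrics,
    filter_cells,
    normalize,
)
from .scores import GENE_SETS, compare_score_groups, gene_set_score
from .simulate import (
    RIBO_GENES,
    PlantedEffect,
    SimDesign,
    generate_barnyard,
    generate_counts,
    make_mito_catalog,
    make_pathways,
)

logger = logging.getLogger("embryotrans")

__all__ = ["PipelineConfig", "run_pipeline", "render_report"]


@dataclass
class PipelineConfig:
    """All pipeline parameters, round-trippable through YAML."""

    seed: int = 0
    output_dir: str = "embryotrans_run"
    n_cells_per_group: int = 150
    n_genes: int = 800
    frac_te: float = 0.7
    frac_male: float = 0.3
    dispersion: float = 2.0
    dropout_rate: float = 0.2
    planted_effects: list = field(default_factory=list)  # dicts mirroring PlantedEffect
    n_barnyard_rat: int = 300
    n_barnyard_human: int = 100
    barnyard_separation: float = 0.8
    barnyard_noise_sd: float = 0.02
    demux_min_rate: float = 0.5
    demux_margin: float = 0.1
    max_mito_fraction: float = 0.25
    min_genes: int = 10  # synthetic matrices are far smaller than real runs
    max_genes: int = 8000
    lfc_cut: float = 1.0
    p_cut: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def design(self) -> SimDesign:
        effects = tuple(
            PlantedEffect(
                label=e["label"],
                genes=tuple(e["genes"]),
                group=e["group"],
                generation=e["generation"],
                log2_effect=float(e["log2_effect"]),
            )
            for e in self.planted_effects
        )
        return SimDesign(
            n_cells_per_group=self.n_cells_per_group,
            n_genes=self.n_genes,
            frac_te=self.frac_te,
            frac_male=self.frac_male,
            planted_effects=effects,
            dispersion=self.dispersion,
            dropout_rate=self.dropout_rate,
            seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in dependency order and return the manifest.

    Rerunning with an identical config reproduces byte-identical outputs
    (all randomness flows from ``config.seed``).  A stage failure aborts
    the run with the failing stage named.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "stages": {},
    }
    files: dict[str, Path] = {}

    def stage(name):
        logger.info("stage %s", name)
        manifest["stages"][name] = {}
        return manifest["stages"][name]

    try:
        # --- demux ---------------------------------------------------
        st = stage("demux")
        barnyard = generate_barnyard(
            config.n_barnyard_rat,
            config.n_barnyard_human,
            config.barnyard_separation,
            config.barnyard_noise_sd,
            seed=config.seed,
        )
        called, summary = demux_batch(
            barnyard, DemuxConfig(config.demux_min_rate, config.demux_margin)
        )
        _write_csv(called, outdir / "demux.csv")
        files["demux"] = outdir / "demux.csv"
        st.update(summary)
        st["recovery"] = float(
            (called["call"] == called["species_true"]).mean()
        )

        # --- counts + QC ---------------------------------------------
        st = stage("qc")
        adata, truth = generate_counts(config.design())
        compute_qc_metrics(adata, ribo_genes=RIBO_GENES)
        thresholds = QCThresholds(
            config.max_mito_fraction, config.min_genes, config.max_genes
        )
        adata, report = filter_cells(adata, thresholds)
        report.to_csv(outdir / "qc_report.csv")
        files["qc_report"] = outdir / "qc_report.csv"
        st["n_cells_in"] = int(len(report))
        st["n_cells_retained"] = int(report["retained"].sum())
        st["thresholds"] = asdict(thresholds)

        # --- normalize + annotate ------------------------------------
        st = stage("annotate")
        normalize(adata)
        annotate_cell_type(adata)
        classify_sex(adata)
        adata.obs.to_csv(outdir / "cells.csv")
        files["cells"] = outdir / "cells.csv"
        st["n_te"] = int((adata.obs["cell_type"] == "TE").sum())
        st["n_icm"] = int((adata.obs["cell_type"] == "ICM").sum())
        st["n_male"] = int((adata.obs["sex_class"] == "male").sum())

        # --- gene-set scores -----------------------------------------
        st = stage("scores")
        score_rows = []
        labels = (
            adata.obs["group"].astype(str) + "-" + adata.obs["generation"].astype(str)
        )
        for name, gene_set in GENE_SETS.items():
            result = gene_set_score(adata, gene_set)
            comparison = compare_score_groups(result, labels)
            st[name] = {
                "p_value": comparison.p_value,
                "test": comparison.test,
                "medians": {k: v[1] for k, v in comparison.groups.items()},
            }
            frame = result.scores.rename("score").to_frame()
            frame.insert(0, "set", name)
            frame["group"] = adata.obs["group"].values
            frame["generation"] = adata.obs["generation"].values
            score_rows.append(frame.reset_index(names="cell"))
        _write_csv(pd.concat(score_rows, ignore_index=True), outdir / "scores.csv")
        files["scores"] = outdir / "scores.csv"

        # --- differential expression ---------------------------------
        st = stage("de")
        de_thresholds = DEThresholds(config.lfc_cut, config.p_cut)
        comparisons = {
            "F2_HFDM_vs_CON": ComparisonSpec(
                "F2_HFDM_vs_CON",
                {"group": "HFDM", "generation": "F2"},
                {"group": "CON", "generation": "F2"},
            ),
            "F3_HFDM_vs_CON": ComparisonSpec(
                "F3_HFDM_vs_CON",
                {"group": "HFDM", "generation": "F3"},
                {"group": "CON", "generation": "F3"},
            ),
            "HFDM_F3_vs_F2": ComparisonSpec(
                "HFDM_F3_vs_F2",
                {"group": "HFDM", "generation": "F3"},
                {"group": "HFDM", "generation": "F2"},
            ),
        }
        de_results = {}
        for name, spec in comparisons.items():
            res = run_de(adata, spec, de_thresholds)
            de_results[name] = res
            _write_csv(res, outdir / f"de_{name}.csv")
            files[f"de_{name}"] = outdir / f"de_{name}.csv"

        # --- confounder filter ---------------------------------------
        blacklist = build_confounder_blacklist(adata, de_thresholds)
        pd.Series(sorted(blacklist), name="gene").to_csv(
            outdir / "blacklist.csv", index=False
        )
        files["blacklist"] = outdir / "blacklist.csv"
        filtered = {
            name: apply_confounder_filter(res, blacklist)
            for name, res in de_results.items()
        }
        for name, res in filtered.items():
            _write_csv(res, outdir / f"de_{name}_filtered.csv")
            files[f"de_{name}_filtered"] = outdir / f"de_{name}_filtered.csv"
        st["blacklist_size"] = len(blacklist)
        for name, res in filtered.items():
            sig = res[res["significant"]]
            st[name] = {
                "n_tested": int(len(res)),
                "n_significant": int(len(sig)),
                "n_up": int((sig["direction"] == "up").sum()),
                "n_down": int((sig["direction"] == "down").sum()),
            }

        # --- generational analysis -----------------------------------
        st = stage("generational")
        directionality = classify_directionality(
            filtered["F2_HFDM_vs_CON"], filtered["F3_HFDM_vs_CON"], de_thresholds
        )
        _write_csv(directionality, outdir / "directionality.csv")
        files["directionality"] = outdir / "directionality.csv"
        st["directionality_counts"] = (
            directionality["category"].value_counts().to_dict()
        )

        catalog = make_mito_catalog(seed=config.seed)
        mito = mito_categorize(
            filtered["F2_HFDM_vs_CON"][filtered["F2_HFDM_vs_CON"]["significant"]],
            catalog,
        )
        _write_csv(mito, outdir / "mito_matches.csv")
        files["mito_matches"] = outdir / "mito_matches.csv"
        st["n_mito_matches"] = int(len(mito))

        universe = list(filtered["F2_HFDM_vs_CON"]["gene"])
        degs = list(
            filtered["F2_HFDM_vs_CON"].loc[
                filtered["F2_HFDM_vs_CON"]["significant"], "gene"
            ]
        )
        if degs:
            pathways = make_pathways(universe, seed=config.seed)
            enrichment = fold_enrichment_test(degs, pathways, universe)
            _write_csv(enrichment, outdir / "enrichment.csv")
            files["enrichment"] = outdir / "enrichment.csv"
            st["n_pathways_tested"] = int(len(enrichment))
        else:
            st["n_pathways_tested"] = 0
    except Exception as exc:  # name the failing stage, then re-raise
        failed = list(manifest["stages"])[-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest["files"] = {name: _sha256(path) for name, path in files.items()}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def render_report(output_dir, top_n: int = 20) -> str:
    """Human-readable summary of a completed run.

    Per comparison, the top DEGs sorted by p-value (at most ``top_n``),
    directionality counts, enrichment and score summaries drawn from the
    manifest and result files.

    Raises
    ------
    FileNotFoundError
        If the manifest or a referenced stage output is missing.
    """
    outdir = Path(output_dir)
    manifest_path = outdir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest at {manifest_path}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines = [
        f"embryotrans run (version {manifest['version']}, seed {manifest['seed']})",
        "",
    ]
    de_stage = manifest["stages"].get("de", {})
    for name, info in de_stage.items():
        if not isinstance(info, dict) or "n_significant" not in info:
            continue
        path = outdir / f"de_{name}_filtered.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing stage output {path}")
        res = pd.read_csv(path)
        sig = res[res["significant"]]
        lines.append(
            f"== {name}: {info['n_significant']} DEGs "
            f"({info['n_down']} down, {info['n_up']} up) =="
        )
        top = sig.head(top_n)
        for _, row in top.iterrows():
            lines.append(
                f"  {row['gene']:<12} p={row['p_value']:.3g} "
                f"log2FC={row['log2_fc']:+.3f} adj.p={row['p_adjusted']:.3g}"
            )
        lines.append("")
    gen_stage = manifest["stages"].get("generational", {})
    if gen_stage.get("directionality_counts"):
        lines.append("== cross-generation directionality ==")
        for cat, n in sorted(gen_stage["directionality_counts"].items()):
            lines.append(f"  {cat:<12} {n}")
        lines.append("")
    score_stage = manifest["stages"].get("scores", {})
    for name, info in score_stage.items():
        if isinstance(info, dict) and "p_value" in info:
            lines.append(
                f"score {name}: {info['test']} p={info['p_value']:.3g} "
                f"medians={info['medians']}"
            )
    report = "\n".join(lines)
    (outdir / "report.txt").write_text(report)
    return report
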