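"""End-to-end orchestration of the analysis stages with a machine-readable report."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import audiogram_phenotype as ap
from . import cohort_sim, io, threshold_scan, variant_consensus_qc
from . import variant_load_outliers as vlo
from ._utils import config_hash
from .summary import overall_mean_age, summarize_cohort
from .variants import MultiCallerVariantTable

log = logging.getLogger(__name__)

STAGES = ("simulate", "classify", "qc", "outliers", "scan")


@dataclass
class RunConfig:
    out_dir: str = "presbyscan_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    simulate: dict = field(default_factory=dict)
    paths: dict = field(default_factory=dict)  # audiograms/metadata/variants/basis/overrides
    outliers: dict = field(default_factory=dict)  # comparisons, genesets, mode
    scan: dict = field(default_factory=dict)  # criteria overrides, pooled

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: v for k, v in raw.items() if k in cls.__dataclass_fields__})
        stages = {s: True for s in STAGES}
        stages.update(raw.get("stages", {}))
        cfg.stages = stages
        return cfg

    def to_plain(self) -> dict:
        return {
            "out_dir": self.out_dir, "seed": self.seed, "stages": self.stages,
            "simulate": self.simulate, "paths": self.paths,
            "outliers": self.outliers, "scan": self.scan,
        }


def _criteria_from(overrides: dict) -> threshold_scan.ScanCriteria:
    kwargs = {k: v for k, v in overrides.items()
              if k in threshold_scan.ScanCriteria.__dataclass_fields__}
    if "sd_caps" in kwargs:
        kwargs["sd_caps"] = tuple((float(b), float(c)) for b, c in kwargs["sd_caps"])
    return threshold_scan.ScanCriteria(**kwargs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write outputs plus a run report.

    Stage order mirrors the analysis: simulate (optional) -> classify -> QC ->
    outliers -> threshold scan.  Every output file is stamped with the run
    id, seed and config hash; the report records counts at each filter so
    conservation can be checked.  Deterministic stages reproduce
    byte-identical outputs for identical config + seed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config.to_plain())
    run_id = f"presbyscan-{chash}"
    header = f"run_id={run_id} seed={config.seed} config_hash={chash}"
    report = {"run_id": run_id, "seed": config.seed, "config_hash": chash,
              "stages": {}}

    # ----- inputs (simulated or loaded) -----
    if config.stages.get("simulate", False):
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        effects = [
            cohort_sim.PlantedEffect(**e) for e in sim_kwargs.pop("planted_effects", [])
        ]
        sim_cfg = cohort_sim.SimConfig(planted_effects=effects, **sim_kwargs)
        cohort = cohort_sim.simulate_cohort(sim_cfg)
        fixture_dir = out / "cohort"
        cohort_sim.write_fixture(cohort, fixture_dir)
        audiograms, metadata, table = (
            cohort.audiograms, cohort.participants, cohort.genotypes
        )
        report["stages"]["simulate"] = {
            "n_participants": len(metadata), "n_variants": len(table.variants),
            "fixture_dir": str(fixture_dir),
        }
    else:
        audiograms = io.read_audiograms(config.paths["audiograms"])
        metadata = io.read_metadata(config.paths["metadata"])
        table = MultiCallerVariantTable.from_tsv(config.paths["variants"]) \
            if "variants" in config.paths else None

    basis = (io.read_basis(config.paths["basis"]) if "basis" in config.paths
             else ap.default_basis([float(c) for c in audiograms.columns]))

    classification = None
    if config.stages.get("classify", True):
        overrides = (io.read_overrides(config.paths["overrides"])
                     if "overrides" in config.paths else None)
        classification = ap.classify_cohort(audiograms, basis, overrides=overrides)
        io.write_classification(classification, out / "classification.csv", header)
        summary = summarize_cohort(classification, metadata)
        summary.reset_index().to_csv(out / "summary.csv", index=False)
        counts = classification["category"].value_counts().to_dict()
        report["stages"]["classify"] = {
            "n_classified": int(len(classification)),
            "n_excluded": int(len(metadata) - len(classification)),
            "category_counts": {k: int(v) for k, v in counts.items()},
            "overall_mean_age": overall_mean_age(summary)
            if len(classification) else None,
        }

    qc_result = None
    if config.stages.get("qc", True) and table is not None:
        qc_result = variant_consensus_qc.apply_qc(table)
        kept = qc_result.kept.copy()
        kept.insert(0, "variant_id", kept.index)
        with open(out / "consensus_variants.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            kept.to_csv(fh, sep="\t", index=False)
        report["stages"]["qc"] = dict(qc_result.drop_log)

    if config.stages.get("outliers", True) and qc_result is not None \
            and classification is not None:
        comparisons = config.outliers.get("comparisons") or _default_comparisons(
            classification
        )
        matrix = vlo.count_variants_per_gene(
            qc_result.consensus, qc_result.kept,
            classification["category"], table.samples,
            mode=config.outliers.get("mode", "alleles"),
        )
        matrix.to_csv(out / "gene_load_matrix.csv")
        outlier_report = {}
        all_lists = {}
        for predictor, response in comparisons:
            if predictor not in matrix.columns or response not in matrix.columns:
                log.warning("skipping comparison %s~%s: group absent",
                            response, predictor)
                continue
            try:
                fit = vlo.fit_outliers(matrix, predictor, response)
            except ValueError as exc:
                log.warning("skipping comparison %s~%s: %s", response, predictor, exc)
                continue
            tag = f"{predictor}_vs_{response}"
            fit.scatter_frame(matrix).to_csv(out / f"outliers_{tag}.csv")
            all_lists[tag] = set(fit.high_in_response) | set(fit.high_in_predictor)
            outlier_report[tag] = {
                "high_in_response": len(fit.high_in_response),
                "high_in_predictor": len(fit.high_in_predictor),
            }
        combined = vlo.combine_and_intersect(all_lists) if all_lists else None
        if combined:
            io.write_gene_set(combined["combined"], out / "outlier_genes_combined.txt")
            outlier_report["combined"] = len(combined["combined"])
        report["stages"]["outliers"] = outlier_report

    if config.stages.get("scan", True) and qc_result is not None:
        criteria = _criteria_from(config.scan.get("criteria", {}))
        scan_df = threshold_scan.scan_cohort(
            qc_result.consensus, qc_result.kept, audiograms, metadata,
            criteria=criteria, seed=config.seed,
            pooled=bool(config.scan.get("pooled", False)),
        )
        with open(out / "scan_results.tsv", "w") as fh:
            fh.write(f"# {header}\n")
            scan_df.to_csv(fh, sep="\t", index=False)
        report["stages"]["scan"] = {
            "n_variants_scanned": int(scan_df["variant_id"].nunique()),
            "n_groups": int(len(scan_df)),
            "n_candidates": int(scan_df["candidate"].sum()),
            "n_detected": int((scan_df["decision"] == "detected").sum()),
            "n_rejected": int((scan_df["decision"] == "candidate_rejected").sum()),
        }

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return report


def _default_comparisons(classification: pd.DataFrame) -> list:
    present = set(classification["category"])
    wanted = [
        ("OlderNormal", "Metabolic"),
        ("OlderNormal", "Sensory"),
        ("Metabolic", "Sensory"),
    ]
    return [(a, b) for a, b in wanted if a in present and b in present]
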