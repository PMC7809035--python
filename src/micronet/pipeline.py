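"""End-to-end orchestration of the analysis stages behind one config.

Stage order: preprocess -> signatures -> association -> network ->
mediation, with morphology and snRNA-seq validation independent of the
bulk chain. In synthetic mode every input is generated from one root seed;
in real mode expression/module/phenotype tables are read from disk.
Every output is a tidy CSV, an edge list, or a JSON summary, and is
reproducible from the config plus the seed alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association as assoc
from . import mediation as med
from . import morphology as morph
from . import network as net
from . import preprocess as prep
from . import signatures as sig
from . import snrna
from . import synthetic as synth

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "preprocess",
    "signatures",
    "association",
    "network",
    "mediation",
    "morphology",
    "snrna",
)

#: every headline analysis threshold, overridable per run
DEFAULT_PARAMS = {
    "fold": 4.0,  # signature fold-enrichment rule
    "min_expr": 1.0,  # signature expression floor (FPKM)
    "fpkm_floor": 1.0,  # bulk gene filter: mean FPKM must exceed this
    "residualize": ["rin", "pmi"],  # technical covariates removed per gene
    "alpha": 0.05,
    "gwas_window": 50_000,
    "folds": 10,
    "repeats": 10,
    "grid": None,  # None -> network.DEFAULT_GRID
    "positive_fraction": 0.10,
    "traits": ["amyloid_sqrt", "tau_sqrt", "np", "nft", "dp", "decline_slope"],
    "network_traits": ["amyloid_sqrt", "tau_sqrt", "decline_slope", "sex", "age_death"],
    "hidden_covariates": ["rin", "pmi"],
    "modules": list(synth.IMMUNE_MODULES),
    "visits": 8,
    "longitudinal_resid_sd": 0.25,
    "cells_per_subject": 80,
    "imaging_subjects": 6,
    "imaging_effect": -0.3,
    "sn_cells": 600,
    "subset": None,  # e.g. {"study": 0} restricts rows before modeling
}


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    stages: tuple = ALL_STAGES
    synthetic: dict | None = field(default_factory=dict)  # kwargs for default_truth
    inputs: dict | None = None  # expression/modules/phenotypes paths
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.stages:
            raise ValueError("no stages enabled")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' and 'inputs' must be given")
        if self.inputs is not None:
            for key in ("expression", "modules", "phenotypes"):
                if key not in self.inputs:
                    raise ValueError(f"inputs block missing {key!r}")
                if not Path(self.inputs[key]).exists():
                    raise ValueError(f"input path does not exist: {self.inputs[key]}")
        unknown_params = set(self.params) - set(DEFAULT_PARAMS)
        if unknown_params:
            raise ValueError(f"unknown params: {sorted(unknown_params)}")

    def param(self, key: str):
        return self.params.get(key, DEFAULT_PARAMS[key])

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)


def _load_inputs(config: PipelineConfig):
    if config.inputs is not None:
        expr = prep.ExpressionMatrix.from_tsv(config.inputs["expression"], unit="fpkm")
        assignment = prep.ModuleAssignment.from_tsv(config.inputs["modules"])
        phen = pd.read_csv(config.inputs["phenotypes"], index_col="subject_id")
        truth = None
    else:
        truth = synth.default_truth(seed=config.seed, **(config.synthetic or {}))
        expr, assignment, phen = synth.generate_cohort(truth)
    assoc.validate_phenotypes(phen)
    return truth, expr, assignment, phen


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages and write the report bundle to outdir.

    Returns the summary dict (also written as summary.json). Partial
    outputs are left in place if a stage raises.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    p = config.param
    truth, expr, assignment, phen = _load_inputs(config)
    if truth is not None:
        truth.to_json(outdir / "truth.json")
    phen.to_csv(outdir / "phenotypes.csv")

    scores = None
    if "preprocess" in config.stages:
        normalized = prep.quantile_normalize(expr)
        filtered = prep.filter_genes(normalized, min_mean=p("fpkm_floor"))
        logged = prep.log2_transform(filtered)
        if phen["study"].nunique() > 1:
            logged = prep.adjust_batch(logged, phen.loc[logged.sample_ids, "study"])
        resid_cols = [c for c in p("residualize") if c in phen.columns]
        if resid_cols:
            logged = prep.ExpressionMatrix(
                prep.residualize(logged, phen.loc[logged.sample_ids, resid_cols]).values,
                unit="log2",
            )
        modules = [m for m in p("modules") if m in assignment.module_ids]
        scores = prep.module_scores(logged, assignment, modules)
        scores.to_csv(outdir / "meta_features.csv", index_label="subject_id")
        summary["preprocess"] = {
            "genes_kept": int(filtered.shape[0]),
            "genes_total": int(expr.shape[0]),
            "modules_scored": modules,
        }

    if "signatures" in config.stages:
        if truth is None:
            raise ValueError("signature stage requires synthetic mode or reference profiles")
        profiles = synth.generate_reference_profiles(truth)
        bulk_mean = profiles["bulk"].values.mean(axis=1)
        gene_sets = {}
        for cell_type in truth.signature_spec:
            target_mean = profiles[cell_type].values.mean(axis=1)
            gene_sets[cell_type] = sig.derive_enriched_set(
                target_mean, [bulk_mean], fold=p("fold"), min_expr=p("min_expr"), name=cell_type
            )
        sig.write_gmt(gene_sets.values(), outdir / "signatures.gmt")
        background = prep.filter_genes(
            prep.quantile_normalize(expr), p("fpkm_floor")
        ).gene_ids
        enrichment = sig.enrich_modules(assignment, gene_sets["microglia"], background)
        enrichment.to_csv(outdir / "enrichment.csv", index=False)
        probes, intervals, ad_genes = synth.generate_gwas_summary(truth, window=p("gwas_window"))
        flags = sig.gwas_gene_flags(intervals, probes, window=p("gwas_window"), alpha=p("alpha"))
        summary["signatures"] = {
            "signature_sizes": {k: len(v) for k, v in gene_sets.items()},
            "enriched_modules": enrichment.loc[enrichment["significant"], "module_id"].tolist(),
            "bonferroni_threshold": enrichment.attrs["bonferroni_threshold"],
            "gwas_flagged": len(flags),
            "gwas_planted_recovered": len(set(ad_genes) & flags.genes),
        }

    if "association" in config.stages:
        if truth is not None:
            lc = synth.generate_longitudinal(
                truth, visits=p("visits"), resid_sd=p("longitudinal_resid_sd")
            )
            est = assoc.fit_decline_slopes(lc.observations)
            phen = phen.copy()
            phen["decline_slope"] = est.reindex(phen.index)
            summary["decline_slope_truth_corr"] = float(
                est.corr(lc.true_slopes.reindex(est.index))
            )
        work = phen
        subset = p("subset")
        if subset:
            for col, val in subset.items():
                work = work[work[col] == val]
        if scores is None:
            raise ValueError("association stage requires preprocess outputs")
        grid_df = assoc.association_grid(
            scores.loc[scores.index.intersection(work.index)], p("traits"), work
        )
        reject, threshold = assoc.adjust_multiplicity(grid_df["p"], method="bh", alpha=p("alpha"))
        grid_df["bh_significant"] = reject
        grid_df.to_csv(outdir / "associations.csv", index=False)
        summary["association"] = {
            "n_tests": len(grid_df),
            "bh_threshold": threshold,
            "n_significant": int(reject.sum()),
        }

    network_obj = None
    if "network" in config.stages:
        network_obj = net.build_network(
            scores,
            phen,
            p("network_traits"),
            hidden_covariates=p("hidden_covariates"),
            folds=p("folds"),
            repeats=p("repeats"),
            grid=p("grid") or net.DEFAULT_GRID,
            seed=config.seed,
        )
        edges = network_obj.edges()
        edges.to_csv(outdir / "network_edges.csv", index=False)
        network_obj.to_graphml(outdir / "network.graphml")
        summary["network"] = {
            "lambda": network_obj.lam,
            "n_edges": len(edges),
            "n_samples": network_obj.n,
        }

    if "mediation" in config.stages:
        covs = phen[["rin", "pmi"]]
        triples = {
            "m5_tau_cogdec": ("m5", "tau_sqrt", "decline_slope"),
            "m114_amyloid_cogdec": ("m114", "amyloid_sqrt", "decline_slope"),
        }
        all_rows = []
        med_summary = {}
        for label, (module, trait_mid, trait_out) in triples.items():
            if module not in scores.columns:
                continue
            results = med.order_triple(
                scores[module],
                phen[trait_out],
                phen[trait_mid],
                covs,
                alpha=p("alpha"),
                names=(module, trait_out, trait_mid),
            )
            table = med.orderings_table(results)
            table.insert(0, "triple", label)
            all_rows.append(table)
            med_summary[label] = {
                "supported": [
                    "->".join(r.ordering) for r in results if r.supported
                ]
            }
        if all_rows:
            pd.concat(all_rows).to_csv(outdir / "mediation.csv", index=False)
        if "m114" in scores.columns:
            frac = assoc.mediated_variance_fraction(
                "amyloid_sqrt", "sex", scores["m114"], phen
            )
            med_summary["sex_via_m114"] = {
                "attenuation": frac.attenuation,
                "variance_ratio": frac.variance_ratio,
                "defined": frac.defined,
            }
        summary["mediation"] = med_summary

    if "morphology" in config.stages:
        if truth is None:
            raise ValueError("morphology stage requires synthetic mode or image inputs")
        images = synth.generate_cell_images(
            truth,
            cells_per_subject=p("cells_per_subject"),
            n_subjects=p("imaging_subjects"),
            effect=p("imaging_effect"),
        )
        pan, sub = "TMEM119", "VASP"
        cells = []
        for i, sid in enumerate(images.subject_ids):
            subject_cells = morph.segment_cells(images.masks[i], subject_id=sid)
            morph.call_positivity(
                subject_cells, images.channels[pan][i], pan, p("positive_fraction")
            )
            morph.call_positivity(
                subject_cells, images.channels[sub][i], sub, p("positive_fraction")
            )
            cells.extend(subject_cells)
        frame = morph.cells_to_frame(cells)
        frame.to_csv(outdir / "cells.csv", index=False)
        double = frame[frame[f"{pan}_positive"]]
        beta, se, pval = morph.compare_compactness(
            double["compactness"], double[f"{sub}_positive"], double["subject_id"]
        )
        fractions = double.groupby("subject_id")[f"{sub}_positive"].mean()
        if len(fractions) >= 4:
            stage_beta, stage_p = morph.positivity_vs_stage(
                fractions, images.stages.reindex(fractions.index)
            )
        else:
            logger.info("fewer than 4 imaging subjects: skipping stage regression")
            stage_beta = stage_p = None
        summary["morphology"] = {
            "n_cells": len(frame),
            "group_beta": beta,
            "group_se": se,
            "group_p": pval,
            "stage_beta": stage_beta,
            "stage_p": stage_p,
        }

    if "snrna" in config.stages:
        if truth is None:
            raise ValueError("snRNA stage requires synthetic mode or count inputs")
        counts = synth.generate_sn_counts(
            truth, cells=max(p("sn_cells"), 4 * truth.n_subjects)
        )
        cpm_matrix = snrna.cpm(counts)
        score = snrna.cell_module_score(cpm_matrix, assignment, "m5")
        by_cluster = score.groupby(counts.metadata["cluster"]).mean()
        proportions = snrna.cluster_proportions(
            counts.metadata, sorted(counts.metadata["cluster"].unique())
        )
        proportions.to_csv(outdir / "cluster_proportions.csv")
        res = snrna.proportion_trait_assoc(proportions["Mic1"], "tau_sqrt", phen)
        summary["snrna"] = {
            "m5_score_by_cluster": by_cluster.to_dict(),
            "mic1_highest_m5": bool(by_cluster.idxmax() == "Mic1"),
            "mic1_tau_beta": res.beta,
            "mic1_tau_p": res.p,
            "n_subjects": res.n,
        }

    summary["versions"] = {
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    summary["params"] = {k: config.params.get(k, v) for k, v in DEFAULT_PARAMS.items()}
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray,)):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
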