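"""End-to-end orchestration: one config, staged artifacts, a run manifest,
and truth-based evaluation for synthetic cohorts.

Stage order: recurrent peaks -> enhancer/gene copy status -> enhancer
activity -> target links -> cooperative models -> motifs -> triplets ->
networks -> core module -> survival. Every stage writes its artifact before
the next starts; all randomness derives from the single config seed through
named substreams, so adding a stage never perturbs earlier draws.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import pandas as pd
import yaml

from . import circuits as tc
from . import peaks as pk
from . import regulation as reg
from . import survival as surv
from .genome import filter_enhancer_context, write_bed
from .simulate import Cohort, generate_cohort, read_cohort, write_cohort

logger = logging.getLogger("cnacircuits")

__version__ = "0.1.0"

__all__ = ["PipelineConfig", "run_pipeline", "simulate_and_evaluate", "evaluate_run"]


@dataclasses.dataclass
class PipelineConfig:
    """All thresholds of the pipeline; defaults are the study's values."""

    seed: int = 0
    bin_size: int = 100_000
    amp_thresh: float = 0.3
    del_thresh: float = -0.3
    peak_qmax: float = 0.25
    n_perm: int = 1000
    promoter_halfwidth: int = 2000
    min_expressed_frac: float = 0.1
    min_group: int = 3
    activity_fdr: float = 0.05
    target_fdr: float = 0.05
    target_min_dist: float = 1e3
    target_max_dist: float = 1e7
    target_mode: str = "window"   # or "nearest"
    motif_score_frac: float = 0.8
    motif_alpha: float = 0.005
    de_fdr: float = 0.1
    de_fc: float = 1.2
    scc_min: float = 0.3
    scc_fdr: float = 0.01
    tf_min_out: int = 20
    gene_min_in: int = 7
    cox_alpha: float = 0.05
    permutation_B: int = 10000
    joint_refit: bool = False     # refit screen genes jointly for the risk score
    record_timestamps: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _chrom_lengths(cohort: Cohort) -> dict:
    if cohort.config is not None:
        return dict(cohort.config.chrom_lengths)
    lengths: dict = {}
    for segs in cohort.segments.values():
        for iv, _ in segs:
            lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    return lengths


def _direction_of(region, called_peaks):
    mid = region.midpoint
    best = None
    for p in called_peaks:
        if p.region.chrom == region.chrom and p.region.start <= mid < p.region.end:
            ov = region.overlap_length(p.region)
            if best is None or ov > best[1]:
                best = (p.direction, ov)
    return None if best is None else best[0]


def run_pipeline(cohort: Cohort, config: PipelineConfig, out_dir) -> dict:
    """Execute all stages on a cohort; returns in-memory results plus the
    manifest (also written to ``out_dir/manifest.json``)."""
    os.makedirs(out_dir, exist_ok=True)
    counts: dict = {}
    results: dict = {}

    def stage(name, n):
        counts[name] = int(n)
        logger.info("stage %-22s %6d records", name, n)

    tumors = cohort.erna.tumor_samples()
    normals = cohort.erna.normal_samples()
    if not cohort.genes:
        raise ValueError("pre-flight: cohort has no gene annotation")
    if not cohort.enhancers:
        raise ValueError("pre-flight: cohort has no enhancer annotation")

    # -- enhancer context filter -----------------------------------------
    kept_enh = filter_enhancer_context(
        cohort.enhancers, cohort.genes, config.promoter_halfwidth
    )
    stage("enhancers_kept", len(kept_enh))

    # -- recurrent peaks ---------------------------------------------------
    tumor_segments = {s: cohort.segments[s] for s in tumors if s in cohort.segments}
    called = pk.call_recurrent_peaks(
        tumor_segments,
        _chrom_lengths(cohort),
        bin_size=config.bin_size,
        amp_thresh=config.amp_thresh,
        del_thresh=config.del_thresh,
        qmax=config.peak_qmax,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    stage("peaks", len(called))
    write_bed(
        os.path.join(out_dir, "peaks.bed"),
        [(p.region, p.direction) for p in called],
        extra_cols=[[f"{p.qvalue:.6g}", "+", f"{p.gscore:.4f}"] for p in called],
    )
    results["peaks"] = called

    # -- copy status -------------------------------------------------------
    enh_status = pk.assign_copy_status(
        [(e.id, e.region) for e in kept_enh], called, tumor_segments,
        config.amp_thresh, config.del_thresh,
    )
    gene_status = pk.assign_copy_status(
        [(g.id, g.region) for g in cohort.genes], called, tumor_segments,
        config.amp_thresh, config.del_thresh,
    )
    enh_status.to_csv(os.path.join(out_dir, "enhancer_status.tsv"), sep="\t")
    gene_status.to_csv(os.path.join(out_dir, "gene_status.tsv"), sep="\t")
    stage("enhancers_in_peaks", len(enh_status))
    stage("genes_in_peaks", len(gene_status))
    results["enh_status"] = enh_status
    results["gene_status"] = gene_status

    enh_dir = {
        e.id: _direction_of(e.region, called)
        for e in kept_enh
        if e.id in enh_status.index
    }

    # -- enhancer activity --------------------------------------------------
    activity = pd.concat(
        [
            reg.test_enhancer_activity(
                cohort.erna, enh_status, d, config.min_expressed_frac, config.min_group
            )
            for d in ("amplified", "deleted")
        ],
        ignore_index=True,
    )
    activity.to_csv(os.path.join(out_dir, "activity.tsv"), sep="\t", index=False)
    stage("activity_tests", len(activity))
    results["activity"] = activity

    # -- target links --------------------------------------------------------
    candidates = {
        e.id: reg.candidate_targets(
            e, cohort.genes, config.target_min_dist, config.target_max_dist
        )
        for e in kept_enh
        if e.id in enh_status.index
    }
    link_parts, n_tested = [], 0
    for d in ("amplified", "deleted"):
        ids = [e for e, dd in enh_dir.items() if dd == d]
        part = reg.call_target_genes(
            cohort.gene_expr,
            enh_status.loc[[i for i in enh_status.index if i in ids]],
            candidates,
            d,
            fdr=config.target_fdr,
            min_group=config.min_group,
            mode=config.target_mode,
        )
        n_tested += part.attrs.get("n_tested", 0)
        link_parts.append(part)
    links = pd.concat(link_parts, ignore_index=True)
    links.attrs["n_tested"] = n_tested
    links.to_csv(os.path.join(out_dir, "links.tsv"), sep="\t", index=False)
    stage("links", len(links))
    stage("link_pairs_tested", n_tested)
    results["links"] = links

    epg_counts, epg_frac = reg.enhancers_per_gene(links)
    epg_counts.rename("n_enhancers").to_csv(
        os.path.join(out_dir, "enhancers_per_gene.tsv"), sep="\t"
    )
    results["enhancers_per_gene_frac2"] = epg_frac

    # -- cooperative regulatory models ---------------------------------------
    label_rows = []
    for row in links.itertuples():
        if row.gene not in gene_status.index and row.enhancer not in enh_status.index:
            continue
        for s in tumors:
            e_st = int(enh_status.loc[row.enhancer, s]) if row.enhancer in enh_status.index else 0
            g_st = int(gene_status.loc[row.gene, s]) if row.gene in gene_status.index else 0
            lab = reg.classify_regulatory_model(e_st, g_st, row.direction)
            if lab is not None:
                label_rows.append(
                    {
                        "sample": s,
                        "enhancer": row.enhancer,
                        "gene": row.gene,
                        "direction": row.direction,
                        "label": lab,
                    }
                )
    labels = pd.DataFrame(
        label_rows, columns=["sample", "enhancer", "gene", "direction", "label"]
    )
    labels.to_csv(os.path.join(out_dir, "model_labels.tsv"), sep="\t", index=False)
    stage("model_labels", len(labels))
    results["model_labels"] = labels

    model_cmp = reg.compare_model_expression(cohort.gene_expr, labels, config.min_group)
    model_cmp.to_csv(os.path.join(out_dir, "model_comparisons.tsv"), sep="\t", index=False)
    stage("model_comparisons", len(model_cmp))
    results["model_comparisons"] = model_cmp

    # -- motif scan and enrichment --------------------------------------------
    kept_ids = [e.id for e in kept_enh if e.id in cohort.sequences]
    seqs = {i: cohort.sequences[i] for i in kept_ids}
    hits = tc.scan_motifs(cohort.pwms, seqs, score_frac=config.motif_score_frac)
    pd.DataFrame(
        [dataclasses.asdict(h) for h in hits],
        columns=["motif_id", "seq_id", "pos", "strand", "score"],
    ).to_csv(os.path.join(out_dir, "motif_hits.tsv"), sep="\t", index=False)
    stage("motif_hits", len(hits))
    results["motif_hits"] = hits

    motif_ids = [p.motif_id for p in cohort.pwms]
    enrich_parts = []
    for d in ("amplified", "deleted"):
        altered = sorted(e for e, dd in enh_dir.items() if dd == d)
        if not altered:
            continue
        part = tc.motif_enrichment(hits, altered, kept_ids, config.motif_alpha, motif_ids)
        part["direction"] = d
        enrich_parts.append(part)
    enrichment = (
        pd.concat(enrich_parts, ignore_index=True)
        if enrich_parts
        else pd.DataFrame(
            columns=["motif_id", "hits_altered", "n_altered", "hits_background",
                     "n_background", "p", "significant", "direction"]
        )
    )
    enrichment.to_csv(os.path.join(out_dir, "motif_enrichment.tsv"), sep="\t", index=False)
    stage("motifs_enriched", int(enrichment["significant"].sum()) if len(enrichment) else 0)
    results["motif_enrichment"] = enrichment

    # -- DE, co-expression, triplets -------------------------------------------
    de = tc.differential_expression(
        cohort.gene_expr.data, tumors, normals, config.de_fdr, config.de_fc
    )
    de.to_csv(os.path.join(out_dir, "differential_expression.tsv"), sep="\t")
    stage("de_features", int((de["status"] != "ns").sum()))
    results["de"] = de

    motif_tf = {p.motif_id: p.tf for p in cohort.pwms}
    pairs = tc.candidate_tf_gene_pairs(links, hits, enrichment, motif_tf)
    coexpr = (
        tc.spearman_coexpression(cohort.gene_expr.data[tumors], pairs)
        if pairs
        else pd.DataFrame(columns=["tf", "gene", "scc", "p", "tested", "q"])
    )
    coexpr.to_csv(os.path.join(out_dir, "coexpression.tsv"), sep="\t", index=False)
    stage("coexpression_pairs", len(coexpr))
    results["coexpression"] = coexpr

    triplets = tc.assemble_triplets(
        links, hits, enrichment, de, coexpr, motif_tf,
        scc_min=config.scc_min, scc_fdr=config.scc_fdr,
    )
    triplets.to_csv(os.path.join(out_dir, "triplets.tsv"), sep="\t", index=False)
    stage("triplets", len(triplets))
    results["triplets"] = triplets

    # -- networks and core module -----------------------------------------------
    networks, core_stats = {}, {}
    for d in ("amplified", "deleted"):
        net = tc.build_network(triplets[triplets["direction"] == d])
        networks[d] = net
        with open(os.path.join(out_dir, f"network_{d}.sif"), "w") as fh:
            for u, v, data in net.edges(data=True):
                fh.write(f"{u}\t{data['sign']}\t{v}\n")
        module, mstats = tc.extract_core_module(net, config.tf_min_out, config.gene_min_in)
        core_stats[d] = mstats
        stage(f"network_{d}_edges", net.number_of_edges())
        stage(f"core_{d}_interactions", mstats["n_interactions"])
    with open(os.path.join(out_dir, "core_module.json"), "w") as fh:
        json.dump(core_stats, fh, indent=1, sort_keys=True)
    results["networks"] = networks
    results["core_stats"] = core_stats

    # -- survival ------------------------------------------------------------------
    module_genes = sorted(
        set(triplets["gene"]).union(triplets["tf"])
        if len(triplets)
        else set(links["gene"])
    )
    surv_out: dict = {"screened": 0}
    if module_genes and len(cohort.clinical):
        train, test = surv.split_cohort(cohort.clinical, seed=config.seed)
        expr = cohort.gene_expr.data
        screened = surv.cox_screen(
            expr[train], cohort.clinical.loc[train], module_genes, config.cox_alpha
        )
        screened.to_csv(os.path.join(out_dir, "cox_screen.tsv"), sep="\t", index=False)
        surv_out["screened"] = len(screened)
        if len(screened):
            betas = screened.set_index("gene")["beta"]
            if config.joint_refit and len(betas) > 1:
                betas = _joint_refit(expr[train], cohort.clinical.loc[train], betas)
            model_scores_tr = surv.risk_scores(betas, expr, train)
            model_scores_te = surv.risk_scores(betas, expr, test)
            grp, threshold = surv.dichotomize(model_scores_tr, model_scores_te)
            model = surv.RiskModel(betas, threshold)
            with open(os.path.join(out_dir, "risk_model.json"), "w") as fh:
                json.dump(model.to_dict(), fh, indent=1, sort_keys=True)
            scores = pd.concat([model_scores_tr, model_scores_te]).rename("risk")
            out = pd.DataFrame({"risk": scores, "group": grp})
            out["split"] = ["train" if s in set(train) else "test" for s in out.index]
            out.to_csv(os.path.join(out_dir, "risk_scores.tsv"), sep="\t", index_label="sample")
            try:
                stat_tr, p_tr = surv.logrank(grp.loc[train], cohort.clinical)
                stat_te, p_te = surv.logrank(grp.loc[test], cohort.clinical)
            except ValueError as exc:
                logger.warning("logrank skipped: %s", exc)
                stat_tr = p_tr = stat_te = p_te = float("nan")
            surv_out.update(
                {
                    "threshold": threshold,
                    "logrank_train": {"statistic": stat_tr, "p": p_tr},
                    "logrank_test": {"statistic": stat_te, "p": p_te},
                }
            )
            try:
                adj = surv.adjusted_cox(
                    grp, cohort.clinical,
                    cohort.clinical[["age", "grade", "gender", "idh"]],
                )
                surv_out["adjusted_cox"] = adj
            except ValueError as exc:
                logger.warning("adjusted Cox skipped: %s", exc)
            _write_km(os.path.join(out_dir, "km_coordinates.tsv"), grp, cohort.clinical)
    with open(os.path.join(out_dir, "survival.json"), "w") as fh:
        json.dump(surv_out, fh, indent=1, sort_keys=True, default=float)
    stage("survival_screened", surv_out["screened"])
    results["survival"] = surv_out

    # -- manifest --------------------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "counts": counts,
    }
    if config.record_timestamps:
        import datetime

        manifest["timestamps"] = {"finished": datetime.datetime.now().isoformat()}
    tmp = os.path.join(out_dir, "manifest.json.tmp")
    with open(tmp, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    os.replace(tmp, os.path.join(out_dir, "manifest.json"))
    results["manifest"] = manifest
    return results


def _joint_refit(expr, clinical, betas):
    from lifelines import CoxPHFitter

    df = clinical[["time", "event"]].astype(float).copy()
    for g in betas.index:
        df[g] = np.log2(expr.loc[g].to_numpy(dtype=float) + 1.0)
    cph = CoxPHFitter(penalizer=0.1)
    cph.fit(df, duration_col="time", event_col="event")
    return cph.params_.loc[list(betas.index)]


def _write_km(path, groups, clinical):
    from lifelines import KaplanMeierFitter

    rows = []
    for label in sorted(set(groups)):
        ids = groups.index[groups == label]
        km = KaplanMeierFitter()
        km.fit(clinical.loc[ids, "time"], clinical.loc[ids, "event"])
        sf = km.survival_function_
        for t, p in zip(sf.index, sf.iloc[:, 0]):
            rows.append({"group": label, "time": float(t), "survival": float(p)})
    pd.DataFrame(rows, columns=["group", "time", "survival"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Truth evaluation
# ---------------------------------------------------------------------------

def _safe_div(a, b):
    return float(a) / b if b else None


def evaluate_run(cohort: Cohort, results: dict, permutation_B: int = 10000,
                 seed: int = 0) -> dict:
    """Compare pipeline output against the cohort's planted truth.

    Reports precision/recall per stage (None where truth is empty), the
    planted-motif detection rate, survival statistics, and a cancer-gene
    style permutation enrichment using the planted link targets as the
    curated list.
    """
    truth = cohort.truth
    report: dict = {}

    called = results["peaks"]
    true_peaks = truth.peaks
    rec = sum(
        any(
            p.direction == t["direction"] and p.region.overlaps(t["region"])
            for p in called
        )
        for t in true_peaks
    )
    prec = sum(
        any(
            p.direction == t["direction"] and p.region.overlaps(t["region"])
            for t in true_peaks
        )
        for p in called
    )
    report["peaks"] = {
        "n_true": len(true_peaks),
        "n_called": len(called),
        "recall": _safe_div(rec, len(true_peaks)),
        "precision": _safe_div(prec, len(called)),
    }

    true_links = {(l["enhancer"], l["gene"]) for l in truth.links}
    called_links = {
        (r.enhancer, r.gene) for r in results["links"].itertuples()
    }
    report["links"] = {
        "n_true": len(true_links),
        "n_called": len(called_links),
        "recall": _safe_div(len(true_links & called_links), len(true_links)),
        "precision": _safe_div(len(true_links & called_links), len(called_links)),
        "n_tested": results["links"].attrs.get("n_tested", 0),
    }

    true_trip = {(c["tf"], c["enhancer"], c["gene"]) for c in truth.circuits}
    called_trip = {
        (r.tf, r.enhancer, r.gene) for r in results["triplets"].itertuples()
    }
    report["triplets"] = {
        "n_true": len(true_trip),
        "n_called": len(called_trip),
        "recall": _safe_div(len(true_trip & called_trip), len(true_trip)),
        "precision": _safe_div(len(true_trip & called_trip), len(called_trip)),
    }

    enrich = results["motif_enrichment"]
    planted = {(c["motif_id"], c["direction"]) for c in truth.circuits}
    if len(enrich):
        flagged = {
            (r.motif_id, r.direction) for r in enrich.itertuples() if r.significant
        }
        non_planted = [
            (r.motif_id, r.direction)
            for r in enrich.itertuples()
            if (r.motif_id, r.direction) not in planted
        ]
        report["motifs"] = {
            "n_planted": len(planted),
            "planted_flagged": len(planted & flagged),
            "detection_rate": _safe_div(len(planted & flagged), len(planted)),
            "false_flag_rate": _safe_div(
                len(set(non_planted) & flagged), len(non_planted)
            ),
        }
    else:
        report["motifs"] = {"n_planted": len(planted), "detection_rate": None}

    surv_out = results.get("survival", {})
    report["survival"] = {
        "n_prognostic_true": len(truth.prognostic),
        "screened": surv_out.get("screened", 0),
        "logrank_train_p": surv_out.get("logrank_train", {}).get("p"),
        "logrank_test_p": surv_out.get("logrank_test", {}).get("p"),
        "adjusted_hr": surv_out.get("adjusted_cox", {}).get("hr"),
    }

    universe = [g.id for g in cohort.genes]
    link_targets = sorted({l["gene"] for l in truth.links})
    called_targets = sorted({g for _, g in called_links})
    if called_targets and link_targets:
        obs, p = tc.cancer_gene_permutation(
            called_targets, link_targets, universe, B=permutation_B, seed=seed
        )
        report["cancer_gene_permutation"] = {"observed_proportion": obs, "p": p}
    else:
        report["cancer_gene_permutation"] = {"observed_proportion": None, "p": None}
    return report


def simulate_and_evaluate(cohort_config, pipeline_config: PipelineConfig, out_dir) -> dict:
    """One-command synthetic demo: generate, write, run, evaluate.

    Writes the cohort under ``out_dir/cohort``, pipeline artifacts under
    ``out_dir/run`` and the recovery report to ``out_dir/report.json``.
    """
    cohort = generate_cohort(cohort_config)
    write_cohort(cohort, os.path.join(out_dir, "cohort"))
    results = run_pipeline(cohort, pipeline_config, os.path.join(out_dir, "run"))
    report = evaluate_run(
        cohort, results, permutation_B=pipeline_config.permutation_B,
        seed=pipeline_config.seed,
    )
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=float)
    return report
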