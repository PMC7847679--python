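"""Enhancer activity shifts under CNV, enhancer-to-target-gene calling, and
the six cooperative CNA/enhancer regulatory models.

Expression comparisons are Welch t-tests on log2(x+1); FDR is BH, applied
globally per CNV direction. Target calls must pass both the FDR gate and a
direction-consistency gate: amplification must raise, deletion must lower,
expression in enhancer-altered samples.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genome import EnhancerRecord, ExpressionMatrix, GeneRecord, bh_adjust

logger = logging.getLogger("cnacircuits")

__all__ = [
    "test_enhancer_activity",
    "candidate_targets",
    "call_target_genes",
    "enhancers_per_gene",
    "classify_regulatory_model",
    "compare_model_expression",
    "REGULATORY_MODELS",
]

_ALTERED = {"amplified": 1, "deleted": -1}


def _welch_rows(mat_a: np.ndarray, mat_b: np.ndarray):
    """Row-wise Welch t on log2(x+1); rows that are constant in both groups
    with equal means give t=0, p=1 (scipy's cancellation artifacts guarded)."""
    a = np.log2(mat_a + 1.0)
    b = np.log2(mat_b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    delta = a.mean(axis=1) - b.mean(axis=1)
    both_const = (np.ptp(a, axis=1) == 0) & (np.ptp(b, axis=1) == 0)
    same = both_const & np.isclose(delta, 0.0, atol=1e-12)
    flat = np.isnan(p) | same
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    delta = np.where(same, 0.0, delta)
    return t, p, delta


def test_enhancer_activity(
    erna: ExpressionMatrix,
    copy_status: pd.DataFrame,
    direction: str,
    min_expressed_frac: float = 0.1,
    min_group: int = 3,
) -> pd.DataFrame:
    """Compare eRNA of CNV-altered versus unaltered tumor samples per enhancer.

    Enhancers expressed in fewer than ``min_expressed_frac`` of samples, or
    with fewer than ``min_group`` samples in either group, are skipped
    (logged). ``delta`` is the mean log2(x+1) difference altered - unaltered;
    q-values are BH across the enhancers tested for this direction.
    """
    want = _ALTERED[direction]
    tumors = [s for s in erna.tumor_samples() if s in copy_status.columns]
    rows = []
    skipped = {"not_in_matrix": 0, "low_expression": 0, "small_group": 0}
    for eid in copy_status.index:
        if eid not in erna.data.index:
            skipped["not_in_matrix"] += 1
            continue
        x = erna.data.loc[eid, tumors].to_numpy(dtype=float)
        if (x > 0).mean() < min_expressed_frac:
            skipped["low_expression"] += 1
            continue
        st = copy_status.loc[eid, tumors].to_numpy()
        altered, unaltered = x[st == want], x[st == 0]
        if len(altered) < min_group or len(unaltered) < min_group:
            skipped["small_group"] += 1
            continue
        t, p, delta = _welch_rows(altered[None, :], unaltered[None, :])
        rows.append(
            {
                "enhancer": eid,
                "direction": direction,
                "n_altered": len(altered),
                "n_unaltered": len(unaltered),
                "delta": float(delta[0]),
                "t": float(t[0]),
                "p": float(p[0]),
            }
        )
    if any(skipped.values()):
        logger.info("test_enhancer_activity[%s]: skipped %s", direction, skipped)
    df = pd.DataFrame(
        rows,
        columns=["enhancer", "direction", "n_altered", "n_unaltered", "delta", "t", "p"],
    )
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df


def candidate_targets(
    enhancer: EnhancerRecord,
    genes,
    min_dist: float = 1e3,
    max_dist: float = 1e7,
) -> pd.DataFrame:
    """Genes whose TSS lies within [min_dist, max_dist] of the enhancer
    midpoint, the single nearest flagged (distance ties break on gene id)."""
    mid = enhancer.region.midpoint
    rows = []
    for g in genes:
        if g.region.chrom != enhancer.region.chrom:
            continue
        dist = abs(g.tss - mid)
        if min_dist <= dist <= max_dist:
            rows.append({"gene": g.id, "distance": int(dist)})
    df = pd.DataFrame(rows, columns=["gene", "distance"])
    df["nearest"] = False
    if len(df):
        df = df.sort_values(["distance", "gene"]).reset_index(drop=True)
        df.loc[0, "nearest"] = True
    return df


def call_target_genes(
    gene_expr: ExpressionMatrix,
    enh_status: pd.DataFrame,
    candidates: dict,
    direction: str,
    fdr: float = 0.05,
    min_group: int = 3,
    mode: str = "window",
) -> pd.DataFrame:
    """Call enhancer target genes by directional differential expression.

    For each enhancer with >= ``min_group`` altered samples, every candidate
    gene (``mode='window'``) or only the nearest (``mode='nearest'``) is
    tested altered-vs-unaltered; BH runs globally over all tested pairs of
    this direction, and a link is kept when q < ``fdr`` and the mean
    difference matches the CNV direction (+ amplified, - deleted).
    """
    if mode not in ("window", "nearest"):
        raise ValueError("mode must be 'window' or 'nearest'")
    want = _ALTERED[direction]
    tumors = [s for s in gene_expr.tumor_samples() if s in enh_status.columns]
    gdata = gene_expr.data[tumors]
    records = []
    for eid in enh_status.index:
        cand = candidates.get(eid)
        if cand is None or not len(cand):
            continue
        cand = cand[cand["nearest"]] if mode == "nearest" else cand
        st = enh_status.loc[eid, tumors].to_numpy()
        alt_mask, un_mask = st == want, st == 0
        if alt_mask.sum() < min_group or un_mask.sum() < min_group:
            continue
        genes = [g for g in cand["gene"] if g in gdata.index]
        if not genes:
            continue
        sub = gdata.loc[genes].to_numpy(dtype=float)
        keep = ~np.all(sub == 0, axis=1)
        if not keep.all():
            logger.info(
                "call_target_genes[%s]: %d all-zero genes skipped for %s",
                direction, int((~keep).sum()), eid,
            )
        sub = sub[keep]
        genes = [g for g, k in zip(genes, keep) if k]
        dist = dict(zip(cand["gene"], cand["distance"]))
        t, p, delta = _welch_rows(sub[:, alt_mask], sub[:, un_mask])
        for g, ti, pi, di in zip(genes, t, p, delta):
            records.append(
                {
                    "enhancer": eid,
                    "gene": g,
                    "direction": direction,
                    "distance": dist[g],
                    "delta": float(di),
                    "t": float(ti),
                    "p": float(pi),
                }
            )
    tested = pd.DataFrame(
        records,
        columns=["enhancer", "gene", "direction", "distance", "delta", "t", "p"],
    )
    if not len(tested):
        tested["q"] = []
        return tested
    tested["q"] = bh_adjust(tested["p"].to_numpy())
    sign_ok = tested["delta"] > 0 if direction == "amplified" else tested["delta"] < 0
    links = tested[(tested["q"] < fdr) & sign_ok].reset_index(drop=True)
    logger.info(
        "call_target_genes[%s]: %d links from %d tested pairs",
        direction, len(links), len(tested),
    )
    links.attrs["n_tested"] = len(tested)
    return links


def enhancers_per_gene(links: pd.DataFrame) -> tuple:
    """Per-gene count of distinct regulating enhancers and the fraction of
    genes with two or more."""
    if not len(links):
        return pd.Series(dtype=int), float("nan")
    dedup = links.drop_duplicates(subset=["enhancer", "gene"])
    counts = dedup.groupby("gene")["enhancer"].nunique().sort_index()
    frac = float((counts >= 2).mean())
    return counts, frac


REGULATORY_MODELS = {
    ("amplified", 1, 0): "enh_only_amp",
    ("amplified", 0, 1): "gene_only_amp",
    ("amplified", 1, 1): "both_amp",
    ("deleted", -1, 0): "enh_only_del",
    ("deleted", 0, -1): "gene_only_del",
    ("deleted", -1, -1): "both_del",
}


def classify_regulatory_model(enh_status: int, gene_status: int, direction: str):
    """Map an (enhancer, gene) copy-status pair to one of the six
    cooperative regulatory models, or None for neutral/mixed pairs."""
    if enh_status not in (-1, 0, 1) or gene_status not in (-1, 0, 1):
        raise ValueError("statuses must be in {-1, 0, +1}")
    if direction not in _ALTERED:
        raise ValueError(f"bad direction {direction!r}")
    return REGULATORY_MODELS.get((direction, enh_status, gene_status))


def compare_model_expression(
    gene_expr: ExpressionMatrix,
    labels: pd.DataFrame,
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-gene comparison of expression across cooperative models.

    ``labels``: long format (sample, enhancer, gene, label). For each gene
    and direction, tests both-altered vs enhancer-only and both-altered vs
    gene-only (Welch on log2(x+1)); BH across all comparisons.
    """
    rows = []
    for (gene, direction), sub in labels.groupby(["gene", "direction"]):
        if gene not in gene_expr.data.index:
            continue
        suffix = "amp" if direction == "amplified" else "del"
        by_label = {
            lab: sorted(set(s.loc[:, "sample"]))
            for lab, s in sub.groupby("label")
        }
        both = by_label.get(f"both_{suffix}", [])
        for other_key in (f"enh_only_{suffix}", f"gene_only_{suffix}"):
            other = by_label.get(other_key, [])
            if len(both) < min_group or len(other) < min_group:
                logger.info(
                    "compare_model_expression: %s %s vs %s skipped (group sizes %d, %d)",
                    gene, f"both_{suffix}", other_key, len(both), len(other),
                )
                continue
            a = gene_expr.data.loc[gene, both].to_numpy(dtype=float)
            b = gene_expr.data.loc[gene, other].to_numpy(dtype=float)
            t, p, delta = _welch_rows(a[None, :], b[None, :])
            rows.append(
                {
                    "gene": gene,
                    "direction": direction,
                    "comparison": f"both_vs_{other_key}",
                    "mean_both": float(np.log2(a + 1).mean()),
                    "mean_other": float(np.log2(b + 1).mean()),
                    "delta": float(delta[0]),
                    "p": float(p[0]),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["gene", "direction", "comparison", "mean_both", "mean_other",
                 "delta", "p"],
    )
    df["q"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df
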