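"""TF-enhancer-gene regulatory circuits.

PWM motif scanning of enhancer sequences, count-based motif enrichment in
CNV-altered enhancers, tumor-vs-normal differential expression, TF-gene
co-expression, triplet assembly, the signed regulatory network, its core
module, and the cancer-gene permutation test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .genome import bh_adjust

logger = logging.getLogger("cnacircuits")

__all__ = [
    "PWM",
    "MotifHit",
    "read_meme",
    "write_meme",
    "scan_motifs",
    "motif_enrichment",
    "differential_expression",
    "spearman_coexpression",
    "candidate_tf_gene_pairs",
    "assemble_triplets",
    "build_network",
    "extract_core_module",
    "cancer_gene_permutation",
]

_ALPHABET = "ACGT"
_CODE = {b: i for i, b in enumerate(_ALPHABET)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


# ---------------------------------------------------------------------------
# Motif model and MEME I/O
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PWM:
    """Position weight matrix: ``matrix[j, b]`` = P(base b at position j)."""

    motif_id: str
    tf: str
    matrix: np.ndarray  # shape (L, 4), rows sum to 1
    background: np.ndarray = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        bg = self.background
        bg = np.full(4, 0.25) if bg is None else np.asarray(bg, dtype=float)
        object.__setattr__(self, "background", bg)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"{self.motif_id}: matrix must be L x 4")
        if m.shape[0] < 4:
            raise ValueError(f"{self.motif_id}: motif length must be >= 4")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: PWM columns must each sum to 1")
        if not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{self.motif_id}: background must sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """log2(p/bg) per position and base, floored at p=1e-9."""
        p = np.maximum(self.matrix, 1e-9)
        return np.log2(p / self.background[None, :])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join(_ALPHABET[i] for i in self.matrix.argmax(axis=1))


def write_meme(path, pwms: Sequence[PWM]) -> None:
    """Write motifs in MEME minimal motif format (version 4)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = pwms[0].background if pwms else np.full(4, 0.25)
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {f:.6f}" for b, f in zip(_ALPHABET, bg)) + "\n\n")
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.motif_id} {pwm.tf}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" " + " ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")


def read_meme(path) -> list:
    """Parse a MEME minimal motif file into a list of :class:`PWM`."""
    pwms = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freqs.get(b, 0.25) for b in _ALPHABET])
        elif line.startswith("MOTIF"):
            toks = line.split()
            motif_id = toks[1]
            tf = toks[2] if len(toks) > 2 else motif_id
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                "letter-probability matrix"
            ):
                i += 1
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for j in range(1, w + 1):
                rows.append([float(x) for x in lines[i + j].split()])
            i += w
            pwms.append(PWM(motif_id, tf, np.array(rows), background))
        i += 1
    return pwms


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    seq_id: str
    pos: int  # 0-based start on the forward strand
    strand: str
    score: float


def _encode(seq: str) -> np.ndarray:
    # A=0 C=1 G=2 T=3, anything else (N) = 4 -> scores 0 bits
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    code = np.full(arr.size, 4, dtype=np.int8)
    for base, idx in _CODE.items():
        code[arr == ord(base)] = idx
    return code


def _window_scores(code: np.ndarray, lo5: np.ndarray) -> np.ndarray:
    L = lo5.shape[0]
    n = code.size - L + 1
    if n <= 0:
        return np.empty(0)
    scores = np.zeros(n)
    for j in range(L):
        scores += lo5[j, code[j : j + n]]
    return scores


def scan_motifs(
    pwms: Sequence[PWM],
    sequences: Mapping[str, str],
    score_thresh_bits: float = None,
    score_frac: float = 0.8,
) -> list:
    """Scan both strands of each sequence with each PWM.

    A hit is reported where the summed log-odds score (bits) reaches the
    threshold: ``score_thresh_bits`` if given, else ``score_frac`` times the
    PWM's maximum attainable score. Positions are 0-based starts on the
    forward strand; N bases contribute 0 bits.
    """
    hits: list = []
    for pwm in pwms:
        lo = pwm.log_odds()
        lo5 = np.hstack([lo, np.zeros((lo.shape[0], 1))])
        thresh = (
            score_thresh_bits
            if score_thresh_bits is not None
            else score_frac * pwm.max_score()
        )
        L = len(pwm)
        for seq_id, seq in sequences.items():
            code = _encode(seq)
            fwd = _window_scores(code, lo5)
            for pos in np.nonzero(fwd >= thresh)[0]:
                hits.append(MotifHit(pwm.motif_id, seq_id, int(pos), "+", float(fwd[pos])))
            rc = _encode(seq.upper().translate(_COMPLEMENT)[::-1])
            rev = _window_scores(rc, lo5)
            n = code.size
            for pos in np.nonzero(rev >= thresh)[0]:
                hits.append(
                    MotifHit(pwm.motif_id, seq_id, int(n - pos - L), "-", float(rev[pos]))
                )
    return hits


# ---------------------------------------------------------------------------
# Motif enrichment in CNV-altered enhancers
# ---------------------------------------------------------------------------

def motif_enrichment(
    hits: Sequence[MotifHit],
    altered_ids: Iterable[str],
    background_ids: Iterable[str],
    alpha: float = 0.005,
    motif_ids: Sequence[str] = None,
) -> pd.DataFrame:
    """One-sided Fisher count enrichment of motif-bearing enhancers in the
    CNV-altered set versus the rest of the background universe.

    Each enhancer counts once per motif regardless of hit multiplicity.
    Motifs with p < ``alpha`` are flagged significant.
    """
    altered = set(altered_ids)
    universe = set(background_ids)
    if not altered:
        raise ValueError("altered enhancer set is empty")
    if not altered <= universe:
        raise ValueError("altered enhancers must be a subset of the background")
    seq_with_hit: dict = {}
    for h in hits:
        seq_with_hit.setdefault(h.motif_id, set()).add(h.seq_id)
    if motif_ids is None:
        motif_ids = sorted(seq_with_hit)
    rows = []
    n_alt, n_uni = len(altered), len(universe)
    for m in motif_ids:
        with_hit = seq_with_hit.get(m, set()) & universe
        a = len(with_hit & altered)
        c = len(with_hit) - a
        table = [[a, n_alt - a], [c, (n_uni - n_alt) - c]]
        p = stats.fisher_exact(table, alternative="greater")[1]
        rows.append(
            {
                "motif_id": m,
                "hits_altered": a,
                "n_altered": n_alt,
                "hits_background": len(with_hit),
                "n_background": n_uni,
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "motif_id", "hits_altered", "n_altered", "hits_background",
            "n_background", "p", "significant",
        ],
    )


# ---------------------------------------------------------------------------
# Differential expression and co-expression
# ---------------------------------------------------------------------------

def differential_expression(
    data: pd.DataFrame,
    tumor_ids: Sequence[str],
    normal_ids: Sequence[str],
    fdr: float = 0.1,
    fc: float = 1.2,
) -> pd.DataFrame:
    """Tumor-vs-normal DE call per feature: ``up``, ``down`` or ``ns``.

    Welch t-test on log2(x+1); BH across features; ``up`` requires q < fdr
    and a linear-scale mean ratio > fc, ``down`` the reciprocal.
    """
    if len(tumor_ids) < 2 or len(normal_ids) < 2:
        raise ValueError("need >= 2 samples per group")
    t_lin = data[list(tumor_ids)].to_numpy()
    n_lin = data[list(normal_ids)].to_numpy()
    t_log = np.log2(t_lin + 1.0)
    n_log = np.log2(n_lin + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat, p = stats.ttest_ind(t_log, n_log, axis=1, equal_var=False)
    flat = np.isnan(p)
    if flat.any():
        logger.info("differential_expression: %d zero-variance features set ns", flat.sum())
    p = np.where(flat, 1.0, p)
    q = bh_adjust(p)
    mean_t, mean_n = t_lin.mean(axis=1), n_lin.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean_n > 0, mean_t / mean_n, np.where(mean_t > 0, np.inf, 1.0))
    status = np.where(
        (q < fdr) & (ratio > fc), "up",
        np.where((q < fdr) & (ratio < 1.0 / fc), "down", "ns"),
    )
    status = np.where(flat, "ns", status)
    return pd.DataFrame(
        {"feature": data.index, "fold": ratio, "p": p, "q": q, "status": status}
    ).set_index("feature")


def spearman_coexpression(
    data: pd.DataFrame, pairs: Sequence, min_n: int = 5
) -> pd.DataFrame:
    """Spearman rank correlation per (tf, gene) pair with BH across pairs.

    Average ranks on ties. Pairs with a constant vector are skipped (logged)
    and reported with NaN statistics and ``tested=False``.
    """
    rows = []
    tested_p = []
    for tf, gene in pairs:
        x = data.loc[tf].to_numpy(dtype=float)
        y = data.loc[gene].to_numpy(dtype=float)
        if x.size < min_n:
            raise ValueError(f"pair ({tf}, {gene}): need >= {min_n} paired samples")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.info("spearman_coexpression: constant vector for (%s, %s), skipped", tf, gene)
            rows.append({"tf": tf, "gene": gene, "scc": np.nan, "p": np.nan, "tested": False})
            continue
        rho, p = stats.spearmanr(x, y)
        rows.append({"tf": tf, "gene": gene, "scc": float(rho), "p": float(p), "tested": True})
        tested_p.append(p)
    df = pd.DataFrame(rows, columns=["tf", "gene", "scc", "p", "tested"])
    df["q"] = np.nan
    if tested_p:
        df.loc[df["tested"], "q"] = bh_adjust(np.array(tested_p))
    return df


# ---------------------------------------------------------------------------
# Triplet assembly and network
# ---------------------------------------------------------------------------

def candidate_tf_gene_pairs(
    links: pd.DataFrame,
    hits: Sequence[MotifHit],
    enrichment: pd.DataFrame,
    motif_tf: Mapping[str, str],
) -> list:
    """Distinct (tf, gene) pairs eligible for a triplet: the TF's motif is
    enriched for the link's CNV direction and hits the link's enhancer."""
    enriched = {
        (row.motif_id, row.direction)
        for row in enrichment.itertuples()
        if row.significant
    }
    hit_map: dict = {}
    for h in hits:
        hit_map.setdefault(h.seq_id, set()).add(h.motif_id)
    pairs = set()
    for row in links.itertuples():
        for m in hit_map.get(row.enhancer, ()):
            if (m, row.direction) in enriched:
                pairs.add((motif_tf[m], row.gene))
    return sorted(pairs)


def assemble_triplets(
    links: pd.DataFrame,
    hits: Sequence[MotifHit],
    enrichment: pd.DataFrame,
    de: pd.DataFrame,
    coexpr: pd.DataFrame,
    motif_tf: Mapping[str, str],
    scc_min: float = 0.3,
    scc_fdr: float = 0.01,
) -> pd.DataFrame:
    """Emit TF-enhancer-gene triplets passing all four evidence filters.

    A triplet requires: (a) the TF's motif enriched for the CNV direction and
    present in the enhancer, (b) an enhancer-gene link, (c) both TF and gene
    differentially expressed, (d) |SCC| > ``scc_min`` at q < ``scc_fdr``.
    The edge sign is + when TF and gene are dysregulated in the same
    direction, - otherwise.
    """
    enriched = {
        (row.motif_id, row.direction)
        for row in enrichment.itertuples()
        if row.significant
    }
    hit_map: dict = {}
    for h in hits:
        hit_map.setdefault(h.seq_id, set()).add(h.motif_id)
    co = {
        (row.tf, row.gene): (row.scc, row.q)
        for row in coexpr.itertuples()
        if row.tested
    }
    rows = []
    for row in links.itertuples():
        for m in sorted(hit_map.get(row.enhancer, ())):
            if (m, row.direction) not in enriched:
                continue
            tf = motif_tf[m]
            if tf not in de.index or row.gene not in de.index:
                continue
            tf_de = de.loc[tf, "status"]
            gene_de = de.loc[row.gene, "status"]
            if tf_de == "ns" or gene_de == "ns":
                continue
            if (tf, row.gene) not in co:
                continue
            scc, scc_q = co[(tf, row.gene)]
            if not (abs(scc) > scc_min and scc_q < scc_fdr):
                continue
            rows.append(
                {
                    "tf": tf,
                    "enhancer": row.enhancer,
                    "gene": row.gene,
                    "direction": row.direction,
                    "scc": scc,
                    "scc_q": scc_q,
                    "tf_de": tf_de,
                    "gene_de": gene_de,
                    "sign": "+" if tf_de == gene_de else "-",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["tf", "enhancer", "gene", "direction", "scc", "scc_q",
                 "tf_de", "gene_de", "sign"],
    )


def build_network(triplets: pd.DataFrame) -> nx.MultiDiGraph:
    """Aggregate triplets into a signed TF->gene network.

    One edge per distinct (TF, gene, sign); supporting enhancers kept as an
    edge attribute. Conflicting signs for a pair become parallel edges.
    """
    g = nx.MultiDiGraph()
    grouped: dict = {}
    for row in triplets.itertuples():
        grouped.setdefault((row.tf, row.gene, row.sign), []).append(row.enhancer)
    conflicts = {
        (tf, gene)
        for tf, gene, _ in grouped
        if (tf, gene, "+") in grouped and (tf, gene, "-") in grouped
    }
    if conflicts:
        logger.info("build_network: %d TF-gene pairs carry both signs", len(conflicts))
    for (tf, gene, sign), enhancers in sorted(grouped.items()):
        if tf not in g:
            g.add_node(tf, kind="TF")
        else:
            g.nodes[tf]["kind"] = "TF"
        if gene not in g:
            g.add_node(gene, kind="gene")
        g.add_edge(tf, gene, key=sign, sign=sign, enhancers=sorted(set(enhancers)))
    return g


def extract_core_module(
    network: nx.MultiDiGraph, tf_min_out: int = 20, gene_min_in: int = 7
) -> tuple:
    """High-connectivity core: TFs regulating more than ``tf_min_out``
    distinct genes and genes regulated by more than ``gene_min_in`` distinct
    TFs, with the interactions between them.

    Returns ``(module, stats)`` where stats counts interactions, TFs and
    genes. An empty module is returned with a warning when the thresholds
    prune everything.
    """
    out_deg = {
        n: len(set(network.successors(n)))
        for n, d in network.nodes(data=True)
        if d.get("kind") == "TF"
    }
    in_deg = {n: len(set(network.predecessors(n))) for n in network.nodes}
    keep_tfs = {n for n, d in out_deg.items() if d > tf_min_out}
    keep_genes = {n for n, d in in_deg.items() if d > gene_min_in}
    module = nx.MultiDiGraph()
    interactions = set()
    for u, v, key, data in network.edges(keys=True, data=True):
        if u in keep_tfs and v in keep_genes:
            module.add_node(u, **network.nodes[u])
            module.add_node(v, **network.nodes[v])
            module.add_edge(u, v, key=key, **data)
            interactions.add((u, v))
    stats_out = {
        "n_interactions": len(interactions),
        "n_tfs": len({u for u, _ in interactions}),
        "n_genes": len({v for _, v in interactions}),
    }
    if not interactions:
        logger.warning("extract_core_module: thresholds pruned every interaction")
    return module, stats_out


# ---------------------------------------------------------------------------
# Cancer-gene permutation test
# ---------------------------------------------------------------------------

def cancer_gene_permutation(
    targets: Iterable[str],
    cancer_genes: Iterable[str],
    universe: Iterable[str],
    B: int = 10000,
    seed: int = 0,
) -> tuple:
    """Empirical enrichment of known cancer genes among target genes.

    Draws ``B`` random gene sets of the same size from the universe (without
    replacement) and counts draws whose cancer-gene proportion reaches the
    observed one; p = (1 + hits) / (B + 1).
    """
    targets = set(targets)
    cancer = set(cancer_genes)
    uni = sorted(set(universe))
    if not targets <= set(uni) or not cancer <= set(uni):
        raise ValueError("targets and cancer genes must be subsets of the universe")
    n, N = len(targets), len(uni)
    if n == 0 or n > N:
        raise ValueError(f"invalid target set size {n} for universe {N}")
    obs_count = len(targets & cancer)
    observed = obs_count / n
    is_cancer = np.array([g in cancer for g in uni])
    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(B, int(2e7) // max(N, 1)))
    done = 0
    while done < B:
        b = min(chunk, B - done)
        keys = rng.random((b, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        counts = is_cancer[idx].sum(axis=1)
        hits += int((counts >= obs_count).sum())
        done += b
    p = (1 + hits) / (B + 1)
    return observed, float(p)
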