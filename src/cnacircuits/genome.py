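"""Genomic interval arithmetic, annotation filtering, standard-format I/O,
and the shared statistical primitives used by every pipeline stage.

All coordinates are 0-based half-open (BED convention) everywhere in the
package; 1-based inputs must be converted at the boundary by the caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("cnacircuits")

__all__ = [
    "GenomicInterval",
    "EnhancerRecord",
    "GeneRecord",
    "ExpressionMatrix",
    "read_bed",
    "write_bed",
    "overlap_assign",
    "filter_enhancer_context",
    "bh_adjust",
    "hypergeom_enrichment",
]

VALID_GRADES = ("II", "III", "IV", "normal")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open span [start, end) on one chromosome."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and max(self.start, other.start) < min(self.end, other.end)
        )

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class EnhancerRecord:
    """An enhancer with its genomic span and annotation context.

    ``context`` is one of ``intronic``, ``intergenic`` (retained classes) or
    ``excluded`` (overlapping a promoter window or an exon). ``unassigned``
    is allowed before :func:`filter_enhancer_context` has run.
    """

    id: str
    region: GenomicInterval
    context: str = "unassigned"

    def __post_init__(self) -> None:
        if self.context not in ("intronic", "intergenic", "excluded", "unassigned"):
            raise ValueError(f"invalid enhancer context {self.context!r}")


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene with TSS, strand and exon structure."""

    id: str
    symbol: str
    region: GenomicInterval
    strand: str
    exons: tuple = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        for ex in self.exons:
            if ex.chrom != self.region.chrom or ex.start < self.region.start or ex.end > self.region.end:
                raise ValueError(f"exon {ex} outside gene body of {self.id}")

    @property
    def tss(self) -> int:
        # transcription start: left edge on +, last base on -
        return self.region.start if self.strand == "+" else self.region.end - 1


class ExpressionMatrix:
    """Feature x sample matrix of non-negative expression values plus grade labels.

    Enhancer activity is TPM-like, gene expression FPKM-like; the container
    does not care which, it only enforces non-negativity and unique ids.
    """

    def __init__(self, data: pd.DataFrame, grades: pd.Series):
        if data.index.has_duplicates:
            raise ValueError("duplicate feature ids")
        if data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (data.values < 0).any():
            raise ValueError("expression values must be non-negative")
        grades = grades.reindex(data.columns)
        if grades.isna().any():
            missing = list(grades.index[grades.isna()])
            raise ValueError(f"samples missing grade labels: {missing[:5]}")
        bad = set(grades.unique()) - set(VALID_GRADES)
        if bad:
            raise ValueError(f"invalid grade labels: {sorted(bad)}")
        self.data = data
        self.grades = grades

    @property
    def features(self) -> pd.Index:
        return self.data.index

    @property
    def samples(self) -> pd.Index:
        return self.data.columns

    def tumor_samples(self) -> list:
        return list(self.grades.index[self.grades != "normal"])

    def normal_samples(self) -> list:
        return list(self.grades.index[self.grades == "normal"])

    def subset(self, features=None, samples=None) -> "ExpressionMatrix":
        data = self.data
        if features is not None:
            data = data.loc[list(features)]
        if samples is not None:
            data = data[list(samples)]
        return ExpressionMatrix(data, self.grades.reindex(data.columns))


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

class BedParseError(ValueError):
    pass


def read_bed(path) -> list:
    """Read a BED3+ file into ``[(GenomicInterval, name), ...]`` in file order.

    Column 4 (name) defaults to ``""`` for BED3 lines. Raises
    :class:`BedParseError` naming the offending line on malformed input.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: non-integer coordinates") from exc
            try:
                iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
            name = fields[3] if len(fields) > 3 else ""
            out.append((iv, name))
    return out


def write_bed(path, records: Iterable, extra_cols=None) -> None:
    """Write ``(GenomicInterval, name)`` pairs as BED; ``extra_cols`` maps
    row index -> list of additional columns (score, strand, ...)."""
    with open(path, "w") as fh:
        for i, (iv, name) in enumerate(records):
            row = [iv.chrom, str(iv.start), str(iv.end), name]
            if extra_cols is not None:
                row.extend(str(c) for c in extra_cols[i])
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Interval operations
# ---------------------------------------------------------------------------

def overlap_assign(
    queries: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> list:
    """All (query_index, target_index) pairs with >=1 bp overlap.

    Half-open semantics: abutting intervals ([100,200) vs [200,300)) do not
    overlap. Uses a per-chromosome sorted sweep, O((n+m) log(n+m) + k).
    """
    pairs: list = []
    if not queries or not targets:
        return pairs
    by_chrom: dict = {}
    for j, t in enumerate(targets):
        by_chrom.setdefault(t.chrom, []).append((t.start, t.end, j))
    for starts in by_chrom.values():
        starts.sort()
    for i, q in enumerate(queries):
        entries = by_chrom.get(q.chrom)
        if not entries:
            continue
        # scan entries whose start < q.end; early exit is fine because
        # entries are sorted by start
        for t_start, t_end, j in entries:
            if t_start >= q.end:
                break
            if t_end > q.start:
                pairs.append((i, j))
    return pairs


def filter_enhancer_context(
    enhancers: Sequence[EnhancerRecord],
    genes: Sequence[GeneRecord],
    promoter_halfwidth: int = 2000,
) -> list:
    """Keep enhancers in intronic or intergenic space.

    An enhancer is excluded if it overlaps any promoter window
    [tss - halfwidth, tss + halfwidth) or any exon. Retained enhancers are
    labeled ``intronic`` when inside a gene body, else ``intergenic``.
    Idempotent: running it on its own output returns the same records.
    """
    for g in genes:
        if g.exons is None:
            raise ValueError(f"gene {g.id} lacks exon annotation")

    forbidden: list = []
    bodies: list = []
    for g in genes:
        p_start = max(0, g.tss - promoter_halfwidth)
        p_end = g.tss + promoter_halfwidth
        forbidden.append(GenomicInterval(g.region.chrom, p_start, p_end))
        forbidden.extend(g.exons)
        bodies.append(g.region)

    enh_regions = [e.region for e in enhancers]
    bad = {i for i, _ in overlap_assign(enh_regions, forbidden)}
    in_body = {i for i, _ in overlap_assign(enh_regions, bodies)}

    kept = []
    for i, e in enumerate(enhancers):
        if i in bad:
            continue
        context = "intronic" if i in in_body else "intergenic"
        kept.append(EnhancerRecord(e.id, e.region, context))
    return kept


# ---------------------------------------------------------------------------
# Statistical primitives
# ---------------------------------------------------------------------------

def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, same order as input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k).

    ``k`` successes observed among ``n`` draws without replacement from a
    universe of ``N`` items of which ``K`` are in the category.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"k={k} outside [0, min(K={K}, n={n})]")
    return float(stats.hypergeom.sf(k - 1, N, K, n))
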