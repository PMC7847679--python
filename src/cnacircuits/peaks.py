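"""Recurrent copy-number peak calling and per-sample copy-status assignment.

A simplified frequency-times-amplitude caller: the genome is tiled into
fixed bins, each bin scores the summed above-threshold amplitude across
samples (G-score), and significance comes from a circular-shift permutation
null that preserves each sample's per-chromosome segment structure.
Amplifications and deletions are scored separately; maximal runs of
contiguous significant bins are reported as peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomicInterval, bh_adjust, hypergeom_enrichment, overlap_assign

logger = logging.getLogger("cnacircuits")

__all__ = ["RecurrentPeak", "call_recurrent_peaks", "assign_copy_status",
           "peak_overlap_validation"]


@dataclass(frozen=True)
class RecurrentPeak:
    """A direction-tagged recurrent CNV region.

    ``region`` spans the full contiguous significant run; ``summit`` is the
    bin with the maximal G-score inside it.
    """

    region: GenomicInterval
    direction: str
    gscore: float
    qvalue: float
    summit: GenomicInterval = None

    def __post_init__(self):
        if self.direction not in ("amplified", "deleted"):
            raise ValueError(f"bad direction {self.direction!r}")
        if not 0.0 <= self.qvalue <= 1.0:
            raise ValueError("qvalue outside [0, 1]")
        if self.gscore <= 0:
            raise ValueError("gscore must be positive")


def _bin_matrix(segments, samples, chrom, length, bin_size):
    """Length-weighted mean log2 ratio per (sample, bin) for one chromosome."""
    n_bins = int(np.ceil(length / bin_size))
    mat = np.zeros((len(samples), n_bins))
    cov = np.zeros((len(samples), n_bins))
    for si, s in enumerate(samples):
        for iv, ratio in segments[s]:
            if iv.chrom != chrom:
                continue
            b0 = iv.start // bin_size
            b1 = (iv.end - 1) // bin_size
            for b in range(b0, b1 + 1):
                lo = max(iv.start, b * bin_size)
                hi = min(iv.end, (b + 1) * bin_size)
                mat[si, b] += ratio * (hi - lo)
                cov[si, b] += hi - lo
    with np.errstate(invalid="ignore"):
        mat = np.where(cov > 0, mat / np.maximum(cov, 1), 0.0)
    return mat


def call_recurrent_peaks(
    segments: dict,
    chrom_lengths: dict,
    bin_size: int = 100_000,
    amp_thresh: float = 0.3,
    del_thresh: float = -0.3,
    qmax: float = 0.25,
    n_perm: int = 1000,
    seed: int = 0,
) -> list:
    """Call recurrent amplified and deleted regions from per-sample segments.

    Per direction: bin G-score = sum over samples of the ratio excess beyond
    the calling threshold; the null pools G-scores from ``n_perm``
    per-sample, per-chromosome circular shifts of the binned profiles;
    empirical p-values are BH-adjusted over all genome bins and maximal runs
    of bins with q <= ``qmax`` become peaks.
    """
    if not segments:
        raise ValueError("no samples provided")
    samples = sorted(segments)
    for chrom, L in chrom_lengths.items():
        if bin_size > L:
            raise ValueError(f"bin_size {bin_size} exceeds {chrom} length {L}")

    rng = np.random.default_rng(seed)
    chroms = sorted(chrom_lengths)
    binned = {
        c: _bin_matrix(segments, samples, c, chrom_lengths[c], bin_size)
        for c in chroms
    }

    def excess(mat, direction):
        if direction == "amplified":
            return np.maximum(mat - amp_thresh, 0.0)
        return np.maximum(del_thresh - mat, 0.0)

    peaks = []
    for direction in ("amplified", "deleted"):
        obs_parts, null_parts = [], []
        for c in chroms:
            contrib = excess(binned[c], direction)  # samples x bins
            obs_parts.append(contrib.sum(axis=0))
            n_s, n_b = contrib.shape
            cols = np.arange(n_b)
            null = np.empty((n_perm, n_b))
            for p in range(n_perm):
                offsets = rng.integers(0, n_b, size=n_s)
                shifted = contrib[np.arange(n_s)[:, None], (cols[None, :] - offsets[:, None]) % n_b]
                null[p] = shifted.sum(axis=0)
            null_parts.append(null.ravel())
        obs = np.concatenate(obs_parts)
        null_pool = np.sort(np.concatenate(null_parts))
        n_null = null_pool.size
        # upper-tail empirical p with +1 smoothing
        ge = n_null - np.searchsorted(null_pool, obs, side="left")
        pvals = (1.0 + ge) / (n_null + 1.0)
        qvals = bh_adjust(pvals)

        # decompose the genome-wide vectors back into chromosomes
        offset = 0
        for c in chroms:
            n_b = binned[c].shape[1]
            q_c = qvals[offset : offset + n_b]
            g_c = obs[offset : offset + n_b]
            offset += n_b
            sig = (q_c <= qmax) & (g_c > 0)
            b = 0
            while b < n_b:
                if not sig[b]:
                    b += 1
                    continue
                run_start = b
                while b < n_b and sig[b]:
                    b += 1
                run_end = b  # exclusive bin index
                top = run_start + int(np.argmax(g_c[run_start:run_end]))
                region = GenomicInterval(
                    c,
                    run_start * bin_size,
                    min(run_end * bin_size, chrom_lengths[c]),
                )
                summit = GenomicInterval(
                    c, top * bin_size, min((top + 1) * bin_size, chrom_lengths[c])
                )
                peaks.append(
                    RecurrentPeak(
                        region=region,
                        direction=direction,
                        gscore=float(g_c[run_start:run_end].max()),
                        qvalue=float(q_c[run_start:run_end].min()),
                        summit=summit,
                    )
                )
    logger.info(
        "call_recurrent_peaks: %d peaks (%d amplified, %d deleted)",
        len(peaks),
        sum(p.direction == "amplified" for p in peaks),
        sum(p.direction == "deleted" for p in peaks),
    )
    return peaks


def assign_copy_status(
    features,
    peaks,
    segments: dict,
    amp_thresh: float = 0.3,
    del_thresh: float = -0.3,
) -> pd.DataFrame:
    """Per-sample copy status {-1, 0, +1} for features inside recurrent peaks.

    ``features``: iterable of ``(id, GenomicInterval)``. A feature inside an
    amplified peak is +1 in exactly those samples whose covering segment
    (largest overlap on ties/spans) reaches ``amp_thresh``; mirrored for
    deletions. Features overlapping no peak are dropped. A feature touching
    peaks of both directions follows the peak with the larger overlap.
    """
    features = list(features)
    regions = [iv for _, iv in features]
    peak_regions = [p.region for p in peaks]
    pairs = overlap_assign(regions, peak_regions)
    best: dict = {}
    for fi, pi in pairs:
        ov = regions[fi].overlap_length(peak_regions[pi])
        if fi not in best or ov > best[fi][1]:
            best[fi] = (pi, ov)

    samples = sorted(segments)
    by_chrom = {
        s: {} for s in samples
    }
    for s in samples:
        for iv, r in segments[s]:
            by_chrom[s].setdefault(iv.chrom, []).append((iv, r))
    kept = sorted(best, key=lambda fi: features[fi][0])
    status = np.zeros((len(kept), len(samples)), dtype=int)
    for row, fi in enumerate(kept):
        fid, region = features[fi]
        direction = peaks[best[fi][0]].direction
        for col, s in enumerate(samples):
            ratio, cover = None, 0
            for iv, r in by_chrom[s].get(region.chrom, ()):
                ov = region.overlap_length(iv)
                if ov > cover:
                    cover, ratio = ov, r
            if ratio is None:
                continue
            if direction == "amplified" and ratio >= amp_thresh:
                status[row, col] = 1
            elif direction == "deleted" and ratio <= del_thresh:
                status[row, col] = -1
    return pd.DataFrame(status, index=[features[fi][0] for fi in kept], columns=samples)


def peak_overlap_validation(enhancers_a, enhancers_b, universe) -> float:
    """Hypergeometric p for the overlap of two peak-resident enhancer sets
    over a common enhancer universe (cohort-vs-cohort validation)."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty enhancer universe")
    a = set(enhancers_a) & uni
    b = set(enhancers_b) & uni
    k = len(a & b)
    return hypergeom_enrichment(k, len(a), len(b), len(uni))
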