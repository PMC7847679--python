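"""Synthetic glioma-like cohort generator with planted ground truth.

Emulates the data model of a multi-grade CNV + expression study: three tumor
grades plus a handful of normals; recurrent amplified/deleted regions whose
prevalence rises with grade; multiplicative dosage coupling of enhancer
(eRNA, TPM-like) and gene (FPKM-like) expression to copy state; TF-driven
target-gene expression through motif-bearing enhancer sequences; and
survival hazards tied to a planted prognostic gene subset.

Every planted effect is recorded in a :class:`TruthRecord` so downstream
stages have a recoverable answer. Generation is fully deterministic given
the config seed; all randomness flows through spawned substreams so that
adding a component never perturbs earlier draws.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import brentq

from .circuits import PWM, read_meme, write_meme
from .genome import (
    EnhancerRecord,
    ExpressionMatrix,
    GeneRecord,
    GenomicInterval,
    read_bed,
    write_bed,
)

logger = logging.getLogger("cnacircuits")

__all__ = [
    "PlantedPeak",
    "PlantedLink",
    "PlantedCircuit",
    "CohortConfig",
    "TruthRecord",
    "Cohort",
    "default_config",
    "null_config",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

TUMOR_GRADES = ("II", "III", "IV")
_ALPHABET = "ACGT"


# ---------------------------------------------------------------------------
# Config and truth types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedPeak:
    """A recurrent CNV region to plant: carriers of each grade are drawn
    with the grade's prevalence and receive ``mean_log2`` copy ratio."""

    name: str
    region: GenomicInterval
    direction: str  # amplified | deleted
    prevalence: Mapping[str, float]  # grade -> carrier probability
    mean_log2: float

    def __post_init__(self):
        if self.direction not in ("amplified", "deleted"):
            raise ValueError(f"bad direction {self.direction!r}")
        for g, p in self.prevalence.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence for grade {g} outside [0,1]: {p}")
        if self.direction == "amplified" and self.mean_log2 <= 0:
            raise ValueError("amplified peak needs positive mean_log2")
        if self.direction == "deleted" and self.mean_log2 >= 0:
            raise ValueError("deleted peak needs negative mean_log2")

    @property
    def copy_state(self) -> int:
        # discrete state whose log2(c/2) is closest to the planted ratio
        return int(np.clip(round(2 * 2 ** self.mean_log2), 0, 4))


@dataclass(frozen=True)
class PlantedLink:
    enhancer: str
    gene: str
    peak: str


@dataclass(frozen=True)
class PlantedCircuit:
    tf: str
    enhancer: str
    gene: str
    sign: int  # +1: gene follows TF; -1: gene opposes TF

    def __post_init__(self):
        if self.sign not in (+1, -1):
            raise ValueError("circuit sign must be +1 or -1")


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic study.

    The annotation (enhancers, genes including TF gene records) is explicit
    so planted peaks, links and circuits can reference stable ids.
    """

    seed: int
    n_per_grade: Mapping[str, int]
    n_normal: int
    chrom_lengths: Mapping[str, int]
    enhancers: Sequence[EnhancerRecord]
    genes: Sequence[GeneRecord]
    tf_ids: Sequence[str]
    peaks: Sequence[PlantedPeak] = ()
    links: Sequence[PlantedLink] = ()
    circuits: Sequence[PlantedCircuit] = ()
    prognostic: Mapping[str, float] = field(default_factory=dict)
    dosage_factor: float = 2.0
    noise_sd: float = 0.25          # log-normal sd (natural log) on expression
    tf_noise_sd: float = 0.4        # TFs get more biological variance
    tf_tumor_fold: float = 4.0      # tumor-vs-normal fold for circuit TFs
    tf_coupling: float = 1.0        # exponent of TF deviation on target genes
    ratio_jitter_sd: float = 0.05   # per-segment log2-ratio jitter
    background_cnv_rate: float = 3.0      # mean passenger events per sample
    background_cnv_mean_len: float = 2e6
    silent_enhancer_frac: float = 0.05
    de_background_frac: float = 0.3     # ordinary genes dysregulated in tumors
    de_background_log2_sd: float = 1.0  # sd of their log2 tumor fold
    motif_length: int = 10
    extra_motif_sites: int = 5      # circuit motif copies in other altered enhancers
    baseline_hazard: float = np.log(2) / 800.0  # per day
    censoring_rate: float = 0.3

    def validate(self) -> None:
        enh_ids = {e.id for e in self.enhancers}
        gene_ids = {g.id for g in self.genes}
        if len(enh_ids) != len(self.enhancers):
            raise ValueError("duplicate enhancer ids")
        if len(gene_ids) != len(self.genes):
            raise ValueError("duplicate gene ids")
        if not set(self.tf_ids) <= gene_ids:
            raise ValueError("tf_ids must reference gene records")
        for rec in list(self.enhancers) + list(self.genes):
            L = self.chrom_lengths.get(rec.region.chrom)
            if L is None or rec.region.end > L:
                raise ValueError(f"{rec.id} outside chromosome bounds")
        for pk in self.peaks:
            L = self.chrom_lengths.get(pk.region.chrom)
            if L is None or pk.region.end > L:
                raise ValueError(f"planted peak {pk.name} outside chromosome bounds")
        for ln in self.links:
            if ln.enhancer not in enh_ids or ln.gene not in gene_ids:
                raise ValueError(f"link {ln} references unknown id")
        for c in self.circuits:
            if c.tf not in self.tf_ids or c.enhancer not in enh_ids or c.gene not in gene_ids:
                raise ValueError(f"circuit {c} references unknown id")
        for g in self.prognostic:
            if g not in gene_ids:
                raise ValueError(f"prognostic gene {g} unknown")
        if self.peaks:
            # at least one planted peak must have prevalence non-decreasing
            # with grade (higher-grade tumors carry more CNAs)
            def nondec(pk):
                vals = [pk.prevalence.get(g, 0.0) for g in TUMOR_GRADES]
                return all(a <= b for a, b in zip(vals, vals[1:]))

            if not any(nondec(pk) for pk in self.peaks):
                raise ValueError("no planted peak has grade-non-decreasing prevalence")


@dataclass
class TruthRecord:
    """Everything the generator planted, keyed by stable ids."""

    peaks: list                 # dicts: name, region, direction, copy_state, carriers
    copy_states: dict           # feature id -> {sample: state} for altered cells only
    links: list                 # dicts: enhancer, gene, peak, direction
    circuits: list              # dicts: tf, enhancer, gene, sign, motif_id, direction
    motif_placements: list      # dicts: motif_id, enhancer, pos
    prognostic: dict            # gene -> log-hazard per SD
    peak_enhancers: dict        # peak name -> enhancer ids inside

    def to_json(self) -> dict:
        def iv(r):
            return [r.chrom, r.start, r.end]

        peaks = [dict(p, region=iv(p["region"])) for p in self.peaks]
        return {
            "peaks": peaks,
            "copy_states": self.copy_states,
            "links": self.links,
            "circuits": self.circuits,
            "motif_placements": self.motif_placements,
            "prognostic": self.prognostic,
            "peak_enhancers": self.peak_enhancers,
        }

    @classmethod
    def from_json(cls, d: dict) -> "TruthRecord":
        peaks = [
            dict(p, region=GenomicInterval(*p["region"])) for p in d["peaks"]
        ]
        return cls(
            peaks=peaks,
            copy_states=d["copy_states"],
            links=d["links"],
            circuits=d["circuits"],
            motif_placements=d["motif_placements"],
            prognostic=d["prognostic"],
            peak_enhancers=d["peak_enhancers"],
        )


@dataclass
class Cohort:
    config: CohortConfig
    enhancers: list
    genes: list
    tf_ids: list
    segments: dict              # sample -> list of (GenomicInterval, log2 ratio)
    erna: ExpressionMatrix
    gene_expr: ExpressionMatrix
    sequences: dict             # enhancer id -> sequence
    pwms: list
    clinical: pd.DataFrame
    truth: TruthRecord


# ---------------------------------------------------------------------------
# Default study layout
# ---------------------------------------------------------------------------

_PEAK_BLOCK = 200_000
_SLOT = 400_000


def _exons_for(chrom, start, end):
    return (
        GenomicInterval(chrom, start, start + 300),
        GenomicInterval(chrom, end - 300, end),
    )


def default_config(
    seed: int = 0,
    n_per_grade: Mapping[str, int] = None,
    n_normal: int = 5,
    n_chrom: int = 5,
    chrom_len: int = 42_000_000,
    n_enhancers: int = 300,
    n_genes: int = 500,
    n_tfs: int = 12,
    n_peaks: int = 20,
    n_circuits: int = 10,
    prevalence: Sequence[float] = (0.6, 0.7, 0.8),
    mean_log2: float = 1.0,
    n_prognostic: int = 6,
    prognostic_loghr: float = 0.8,
    **overrides,
) -> CohortConfig:
    """The default strong-effect study: planted peaks each carry one target
    gene regulated by two enhancers plus two motif-carrier fillers.

    20 peaks (amp/del alternating) yield 40 enhancer-gene links; the first
    ``n_circuits`` peaks get a TF circuit each. Layout is deterministic; the
    seed only drives the stochastic draws in :func:`generate_cohort`.
    """
    if n_per_grade is None:
        n_per_grade = {"II": 50, "III": 50, "IV": 50}
    chroms = {f"chr{i + 1}": chrom_len for i in range(n_chrom)}
    per_chrom = int(np.ceil(n_peaks / n_chrom))
    if 2_000_000 + per_chrom * 10_000_000 > chrom_len + 9_800_000:
        raise ValueError("chromosomes too short for the requested peak count")

    enhancers, genes, peaks, links, circuits = [], [], [], [], []
    peak_positions = []
    k = 0
    for ci in range(n_chrom):
        for pi in range(per_chrom):
            if k >= n_peaks:
                break
            chrom = f"chr{ci + 1}"
            base = 2_000_000 + pi * 10_000_000
            peak_positions.append((chrom, base))
            k += 1

    for idx, (chrom, base) in enumerate(peak_positions):
        pk_name = f"PK{idx + 1:02d}"
        direction = "amplified" if idx % 2 == 0 else "deleted"
        gid = f"GT{idx + 1:03d}"
        g_start, g_end = base + 20_000, base + 30_000
        genes.append(
            GeneRecord(gid, gid, GenomicInterval(chrom, g_start, g_end), "+",
                       _exons_for(chrom, g_start, g_end))
        )
        enh_ids = []
        for j, off in enumerate((60_000, 140_000)):
            eid = f"EP{idx + 1:03d}{'ab'[j]}"
            enhancers.append(
                EnhancerRecord(eid, GenomicInterval(chrom, base + off, base + off + 1000))
            )
            enh_ids.append(eid)
        peaks.append(
            PlantedPeak(
                pk_name,
                GenomicInterval(chrom, base, base + _PEAK_BLOCK),
                direction,
                dict(zip(TUMOR_GRADES, prevalence)),
                mean_log2 if direction == "amplified" else -mean_log2,
            )
        )
        links.append(PlantedLink(enh_ids[0], gid, pk_name))
        links.append(PlantedLink(enh_ids[1], gid, pk_name))
        if idx < n_circuits:
            tf_id = f"TF{idx + 1:02d}"
            circuits.append(
                PlantedCircuit(tf_id, enh_ids[0], gid,
                               +1 if direction == "amplified" else -1)
            )

    # ordinary gene/enhancer slots outside the peak blocks, genome order
    blocked = {(c, b) for c, b in peak_positions}
    free_slots = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1}"
        for s in range(0, chrom_len - _SLOT + 1, _SLOT):
            if any(c == chrom and s < b + _PEAK_BLOCK and b < s + _SLOT
                   for c, b in peak_positions):
                continue
            free_slots.append((chrom, s))

    n_ordinary = n_genes - n_peaks
    if n_ordinary + n_tfs > len(free_slots):
        raise ValueError("not enough slots for the requested gene count")
    tf_ids = [f"TF{i + 1:02d}" for i in range(n_tfs)]
    for i in range(n_ordinary + n_tfs):
        chrom, s = free_slots[i]
        strand = "+" if i % 2 == 0 else "-"
        g_start, g_end = s + 150_000, s + 160_000
        gid = f"G{i + 1:04d}" if i < n_ordinary else tf_ids[i - n_ordinary]
        genes.append(
            GeneRecord(gid, gid, GenomicInterval(chrom, g_start, g_end), strand,
                       _exons_for(chrom, g_start, g_end))
        )
    n_ord_enh = n_enhancers - 2 * n_peaks
    if n_ord_enh < 0:
        raise ValueError("n_enhancers smaller than the peak-resident count")
    for i in range(n_ord_enh):
        chrom, s = free_slots[i]
        enhancers.append(
            EnhancerRecord(f"E{i + 1:04d}", GenomicInterval(chrom, s + 50_000, s + 51_000))
        )

    prognostic = {}
    circuit_genes = [c.gene for c in circuits]
    for i, g in enumerate(circuit_genes[:n_prognostic]):
        prognostic[g] = prognostic_loghr if i % 2 == 0 else -prognostic_loghr

    cfg = CohortConfig(
        seed=seed,
        n_per_grade=dict(n_per_grade),
        n_normal=n_normal,
        chrom_lengths=chroms,
        enhancers=tuple(enhancers),
        genes=tuple(genes),
        tf_ids=tuple(tf_ids),
        peaks=tuple(peaks),
        links=tuple(links),
        circuits=tuple(circuits),
        prognostic=prognostic,
        **overrides,
    )
    cfg.validate()
    return cfg


def null_config(seed: int = 0, **kwargs) -> CohortConfig:
    """Global-null variant: planted CNV peaks remain (so enhancers enter the
    copy-status matrix and tests actually run) but expression is decoupled
    from dosage and no circuits or prognostic effects exist."""
    kwargs.setdefault("n_circuits", 0)
    kwargs.setdefault("n_prognostic", 0)
    cfg = default_config(seed=seed, **kwargs)
    return replace(cfg, dosage_factor=1.0, circuits=(), prognostic={})


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _sample_ids(config) -> tuple:
    samples, grades = [], []
    for g in TUMOR_GRADES:
        for i in range(config.n_per_grade.get(g, 0)):
            samples.append(f"{g}_{i + 1:03d}")
            grades.append(g)
    for i in range(config.n_normal):
        samples.append(f"N_{i + 1:03d}")
        grades.append("normal")
    return samples, pd.Series(grades, index=samples, name="grade")


def _segments_for_sample(config, chrom, carried, rng):
    """Non-overlapping segments tiling one chromosome of one sample.

    ``carried``: list of (PlantedPeak, state) the sample carries on this
    chromosome. Passenger background CNVs are carved into neutral gaps only.
    """
    L = config.chrom_lengths[chrom]
    blocks = sorted(
        (pk.region.start, pk.region.end, pk, state) for pk, state in carried
    )
    segs = []  # (start, end, ratio, planted?)
    cursor = 0
    jit = config.ratio_jitter_sd
    for s, e, pk, state in blocks:
        if s > cursor:
            segs.append([cursor, s, rng.normal(0.0, jit), False])
        ratio = np.log2(max(state, 0.5) / 2.0) + rng.normal(0.0, jit)
        segs.append([s, e, ratio, True])
        cursor = e
    if cursor < L:
        segs.append([cursor, L, rng.normal(0.0, jit), False])

    n_events = rng.poisson(config.background_cnv_rate * L / sum(config.chrom_lengths.values()))
    for _ in range(n_events):
        length = int(np.clip(rng.exponential(config.background_cnv_mean_len), 2e5, 5e6))
        start = int(rng.integers(0, L))
        ratio = rng.choice([-1.0, 1.0]) * rng.uniform(0.4, 1.0)
        # place within the neutral gap containing start, if any
        for i, (s, e, _, planted) in enumerate(segs):
            if planted or not (s <= start < e):
                continue
            ev_s, ev_e = start, min(start + length, e)
            if ev_e - ev_s < 50_000:
                break
            tail = [ev_e, e, segs[i][2], False]
            segs[i][1] = ev_s
            pieces = [[ev_s, ev_e, ratio + rng.normal(0.0, jit), False]]
            if tail[0] < tail[1]:
                pieces.append(tail)
            if segs[i][0] == segs[i][1]:
                segs[i : i + 1] = pieces
            else:
                segs[i + 1 : i + 1] = pieces
            break
    return [
        (GenomicInterval(chrom, s, e), float(r)) for s, e, r, _ in segs if e > s
    ]


def _solve_censor_horizon(lam: np.ndarray, target: float) -> float:
    """Horizon c of Uniform(0, c) censoring giving the target mean censored
    fraction under per-sample exponential event rates ``lam``."""

    def frac(c):
        x = lam * c
        return float(np.mean((1.0 - np.exp(-x)) / x)) - target

    lo, hi = 1e-9, 1e12
    if frac(lo) < 0:  # target above attainable range
        return lo
    return brentq(frac, lo, hi, xtol=1e-6, rtol=1e-10)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full cohort from the config; deterministic given the seed."""
    config.validate()
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_carrier = np.random.default_rng(streams[0])
    rng_seg = np.random.default_rng(streams[1])
    rng_expr = np.random.default_rng(streams[2])
    rng_seq = np.random.default_rng(streams[3])
    rng_surv = np.random.default_rng(streams[4])
    rng_clin = np.random.default_rng(streams[5])

    samples, grades = _sample_ids(config)
    tumors = [s for s in samples if grades[s] != "normal"]

    # --- carriers per planted peak -------------------------------------
    carriers = {}
    for pk in config.peaks:
        carried = []
        for s in tumors:
            if rng_carrier.random() < pk.prevalence.get(grades[s], 0.0):
                carried.append(s)
        carriers[pk.name] = carried

    # --- per-sample segments -------------------------------------------
    peaks_by_chrom: dict = {}
    for pk in config.peaks:
        peaks_by_chrom.setdefault(pk.region.chrom, []).append(pk)
    segments = {}
    for s in samples:
        segs = []
        is_tumor = grades[s] != "normal"
        for chrom in config.chrom_lengths:
            carried = [
                (pk, pk.copy_state)
                for pk in peaks_by_chrom.get(chrom, [])
                if is_tumor and s in carriers[pk.name]
            ]
            segs.extend(_segments_for_sample(config, chrom, carried, rng_seg))
        segments[s] = segs

    # --- copy states of features (planted peaks only) -------------------
    def state_of(region) -> tuple:
        mid = region.midpoint
        for pk in peaks_by_chrom.get(region.chrom, []):
            if pk.region.start <= mid < pk.region.end:
                return pk
        return None

    copy_states: dict = {}
    feature_peak: dict = {}
    for rec in list(config.enhancers) + list(config.genes):
        pk = state_of(rec.region)
        if pk is None:
            continue
        feature_peak[rec.id] = pk
        copy_states[rec.id] = {s: pk.copy_state for s in carriers[pk.name]}

    def c_of(fid, sample):
        return copy_states.get(fid, {}).get(sample, 2)

    # --- expression ------------------------------------------------------
    n_s = len(samples)
    circuit_by_gene = {c.gene: c for c in config.circuits}
    circuit_tfs = {c.tf for c in config.circuits}

    enh_base = np.exp(rng_expr.normal(np.log(5.0), 0.5, size=len(config.enhancers)))
    silent = rng_expr.random(len(config.enhancers)) < config.silent_enhancer_frac
    for i, e in enumerate(config.enhancers):
        if silent[i] and e.id not in feature_peak:
            enh_base[i] = 0.0
    erna = np.empty((len(config.enhancers), n_s))
    d = config.dosage_factor
    for i, e in enumerate(config.enhancers):
        noise = np.exp(rng_expr.normal(0.0, config.noise_sd, size=n_s))
        dose = np.array([d ** (c_of(e.id, s) - 2) for s in samples])
        erna[i] = enh_base[i] * dose * noise

    gene_order = [g.id for g in config.genes]
    gene_base = np.exp(rng_expr.normal(np.log(10.0), 0.5, size=len(gene_order)))
    base_of = dict(zip(gene_order, gene_base))
    is_tumor_vec = np.array([grades[s] != "normal" for s in samples])

    gexpr = np.empty((len(gene_order), n_s))
    tf_dev: dict = {}  # tf id -> multiplicative deviation from baseline
    # TFs first so targets can couple to their realized expression
    for i, gid in enumerate(gene_order):
        if gid not in config.tf_ids:
            continue
        sd = config.tf_noise_sd
        noise = np.exp(rng_expr.normal(0.0, sd, size=n_s))
        fold = np.where(
            is_tumor_vec, config.tf_tumor_fold if gid in circuit_tfs else 1.0, 1.0
        )
        dev = fold * noise
        tf_dev[gid] = dev
        gexpr[i] = base_of[gid] * dev
    # background tumor dysregulation: a realistic fraction of ordinary genes
    # shifts between tumor and normal so the DE screen sees a full landscape
    for i, gid in enumerate(gene_order):
        if gid in config.tf_ids:
            continue
        noise = np.exp(rng_expr.normal(0.0, config.noise_sd, size=n_s))
        dose = np.array([d ** (c_of(gid, s) - 2) for s in samples])
        coupling = 1.0
        circ = circuit_by_gene.get(gid)
        if circ is not None:
            coupling = tf_dev[circ.tf] ** (config.tf_coupling * circ.sign)
        bg_fold = 1.0
        if (
            circ is None
            and gid not in copy_states
            and rng_expr.random() < config.de_background_frac
        ):
            bg_fold = 2.0 ** rng_expr.normal(0.0, config.de_background_log2_sd)
        tumor_shift = np.where(is_tumor_vec, bg_fold, 1.0)
        gexpr[i] = base_of[gid] * dose * coupling * tumor_shift * noise

    erna_mat = ExpressionMatrix(
        pd.DataFrame(erna, index=[e.id for e in config.enhancers], columns=samples),
        grades,
    )
    gene_mat = ExpressionMatrix(
        pd.DataFrame(gexpr, index=gene_order, columns=samples), grades
    )

    # --- enhancer sequences and motifs -----------------------------------
    consensi: dict = {}
    used = set()
    for tf in config.tf_ids:
        while True:
            cons = "".join(rng_seq.choice(list(_ALPHABET), size=config.motif_length))
            if cons not in used:
                used.add(cons)
                break
        consensi[tf] = cons
    pwms = []
    for tf, cons in consensi.items():
        m = np.full((len(cons), 4), 0.01)
        for j, b in enumerate(cons):
            m[j, _ALPHABET.index(b)] = 0.97
        pwms.append(PWM(f"M_{tf}", tf, m))

    sequences = {
        e.id: "".join(rng_seq.choice(list(_ALPHABET), size=e.region.length))
        for e in config.enhancers
    }

    def plant(eid, cons):
        seq = sequences[eid]
        pos = int(rng_seq.integers(0, len(seq) - len(cons) + 1))
        sequences[eid] = seq[:pos] + cons + seq[pos + len(cons):]
        return pos

    # TF binding is pervasive: each circuit motif also lands in altered
    # enhancers of other peaks of the same direction, so enrichment against
    # the full enhancer universe is detectable. The circuit's own peak is
    # excluded to keep its planted triplet unambiguous.
    placements = []
    for c in config.circuits:
        cons = consensi[c.tf]
        pos = plant(c.enhancer, cons)
        placements.append({"motif_id": f"M_{c.tf}", "enhancer": c.enhancer, "pos": pos})
        own_peak = feature_peak[c.enhancer]
        pool = sorted(
            ln.enhancer
            for ln in config.links
            if ln.peak != own_peak.name
            and feature_peak.get(ln.enhancer) is not None
            and feature_peak[ln.enhancer].direction == own_peak.direction
        )
        n_extra = min(config.extra_motif_sites, len(pool))
        for eid in rng_seq.choice(pool, size=n_extra, replace=False):
            pos = plant(eid, cons)
            placements.append({"motif_id": f"M_{c.tf}", "enhancer": eid, "pos": pos})

    # --- clinical and survival -------------------------------------------
    n_t = len(tumors)
    age = np.clip(np.round(rng_clin.normal(50, 12, size=n_t)), 20, 85).astype(int)
    gender = np.where(rng_clin.random(n_t) < 0.5, "male", "female")
    idh = np.where(rng_clin.random(n_t) < 0.45, "mutant", "wildtype")

    loghr = np.zeros(n_t)
    if config.prognostic:
        tumor_expr = gene_mat.data[tumors]
        for gid, beta in config.prognostic.items():
            x = np.log2(tumor_expr.loc[gid].to_numpy() + 1.0)
            sd = x.std(ddof=0)
            z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
            loghr += beta * z
    lam = config.baseline_hazard * np.exp(loghr)
    event_t = rng_surv.exponential(1.0 / lam)
    horizon = _solve_censor_horizon(lam, config.censoring_rate)
    censor_t = rng_surv.uniform(0.0, horizon, size=n_t)
    time = np.minimum(event_t, censor_t)
    event = (event_t <= censor_t).astype(int)
    time = np.maximum(time, 1e-3)

    clinical = pd.DataFrame(
        {
            "sample": tumors,
            "time": time,
            "event": event,
            "age": age,
            "grade": [grades[s] for s in tumors],
            "gender": gender,
            "idh": idh,
        }
    ).set_index("sample")

    truth = TruthRecord(
        peaks=[
            {
                "name": pk.name,
                "region": pk.region,
                "direction": pk.direction,
                "copy_state": pk.copy_state,
                "carriers": carriers[pk.name],
            }
            for pk in config.peaks
        ],
        copy_states={k: dict(v) for k, v in copy_states.items()},
        links=[
            {
                "enhancer": ln.enhancer,
                "gene": ln.gene,
                "peak": ln.peak,
                "direction": next(
                    pk.direction for pk in config.peaks if pk.name == ln.peak
                ),
            }
            for ln in config.links
        ],
        circuits=[
            {
                "tf": c.tf,
                "enhancer": c.enhancer,
                "gene": c.gene,
                "sign": c.sign,
                "motif_id": f"M_{c.tf}",
                "direction": feature_peak[c.enhancer].direction,
            }
            for c in config.circuits
        ],
        motif_placements=placements,
        prognostic=dict(config.prognostic),
        peak_enhancers={
            pk.name: [
                e.id
                for e in config.enhancers
                if feature_peak.get(e.id) is pk
            ]
            for pk in config.peaks
        },
    )

    return Cohort(
        config=config,
        enhancers=list(config.enhancers),
        genes=list(config.genes),
        tf_ids=list(config.tf_ids),
        segments=segments,
        erna=erna_mat,
        gene_expr=gene_mat,
        sequences=sequences,
        pwms=pwms,
        clinical=clinical,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# On-disk round trip
# ---------------------------------------------------------------------------

_FILES = {
    "enhancers": "enhancers.bed",
    "genes": "genes.tsv",
    "segments": "segments.seg",
    "erna": "erna.tsv",
    "gene_expr": "gene_expression.tsv",
    "samples": "samples.tsv",
    "fasta": "enhancers.fa",
    "motifs": "motifs.meme",
    "clinical": "clinical.tsv",
    "truth": "truth.json",
}


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write all cohort artifacts; returns the path map."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {k: os.path.join(out_dir, v) for k, v in _FILES.items()}

    write_bed(paths["enhancers"], [(e.region, e.id) for e in cohort.enhancers])

    with open(paths["genes"], "w") as fh:
        fh.write("id\tsymbol\tchrom\tstart\tend\tstrand\texons\tis_tf\n")
        tfset = set(cohort.tf_ids)
        for g in cohort.genes:
            ex = ";".join(f"{e.start}-{e.end}" for e in g.exons)
            fh.write(
                f"{g.id}\t{g.symbol}\t{g.region.chrom}\t{g.region.start}\t"
                f"{g.region.end}\t{g.strand}\t{ex}\t{int(g.id in tfset)}\n"
            )

    with open(paths["segments"], "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tlog2ratio\n")
        for s, segs in cohort.segments.items():
            for iv, ratio in segs:
                fh.write(f"{s}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{ratio:.6f}\n")

    cohort.erna.data.round(6).to_csv(paths["erna"], sep="\t", index_label="feature")
    cohort.gene_expr.data.round(6).to_csv(
        paths["gene_expr"], sep="\t", index_label="feature"
    )
    cohort.erna.grades.rename("grade").to_csv(
        paths["samples"], sep="\t", index_label="sample"
    )

    records = [
        SeqRecord(Seq(seq), id=eid, description="")
        for eid, seq in cohort.sequences.items()
    ]
    SeqIO.write(records, paths["fasta"], "fasta")

    write_meme(paths["motifs"], cohort.pwms)
    cohort.clinical.round(6).to_csv(paths["clinical"], sep="\t", index_label="sample")

    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth.to_json(), fh, indent=1, sort_keys=True)
    return paths


def read_cohort(out_dir, config: CohortConfig = None) -> Cohort:
    """Read a cohort directory back into memory.

    ``config`` is optional metadata; files on disk are authoritative.
    """
    paths = {k: os.path.join(out_dir, v) for k, v in _FILES.items()}

    enhancers = [EnhancerRecord(name, iv) for iv, name in read_bed(paths["enhancers"])]

    genes, tf_ids = [], []
    gtab = pd.read_csv(paths["genes"], sep="\t", dtype={"exons": str})
    for row in gtab.itertuples():
        exons = tuple(
            GenomicInterval(row.chrom, int(a), int(b))
            for a, b in (p.split("-") for p in str(row.exons).split(";") if p and p != "nan")
        )
        genes.append(
            GeneRecord(row.id, row.symbol,
                       GenomicInterval(row.chrom, row.start, row.end),
                       row.strand, exons)
        )
        if row.is_tf:
            tf_ids.append(row.id)

    seg_tab = pd.read_csv(paths["segments"], sep="\t")
    segments: dict = {}
    for row in seg_tab.itertuples():
        segments.setdefault(row.sample, []).append(
            (GenomicInterval(row.chrom, row.start, row.end), float(row.log2ratio))
        )

    grades = pd.read_csv(paths["samples"], sep="\t", index_col="sample")["grade"]
    erna = ExpressionMatrix(
        pd.read_csv(paths["erna"], sep="\t", index_col="feature"), grades
    )
    gene_expr = ExpressionMatrix(
        pd.read_csv(paths["gene_expr"], sep="\t", index_col="feature"), grades
    )

    sequences = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(paths["fasta"], "fasta")
    }
    pwms = read_meme(paths["motifs"])
    clinical = pd.read_csv(paths["clinical"], sep="\t", index_col="sample")
    with open(paths["truth"]) as fh:
        truth = TruthRecord.from_json(json.load(fh))

    return Cohort(
        config=config,
        enhancers=enhancers,
        genes=genes,
        tf_ids=tf_ids,
        segments=segments,
        erna=erna,
        gene_expr=gene_expr,
        sequences=sequences,
        pwms=pwms,
        clinical=clinical,
        truth=truth,
    )
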