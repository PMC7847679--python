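"""Motif scanning, enrichment, triplet assembly, networks, permutation test."""

import itertools
import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cnacircuits.circuits import (
    PWM,
    MotifHit,
    assemble_triplets,
    build_network,
    cancer_gene_permutation,
    differential_expression,
    extract_core_module,
    motif_enrichment,
    read_meme,
    scan_motifs,
    spearman_coexpression,
    write_meme,
)

_B = "ACGT"


def point_mass_pwm(consensus, motif_id="M1", tf="TF1"):
    m = np.zeros((len(consensus), 4))
    for j, b in enumerate(consensus):
        m[j, _B.index(b)] = 1.0
    return PWM(motif_id, tf, m)


def soft_pwm(consensus, motif_id="M1", tf="TF1"):
    m = np.full((len(consensus), 4), 0.01)
    for j, b in enumerate(consensus):
        m[j, _B.index(b)] = 0.97
    return PWM(motif_id, tf, m)


def brute_force_hits(pwm, sequences, threshold):
    """Independent per-position scoring oracle."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    lo = np.log2(np.maximum(pwm.matrix, 1e-9) / pwm.background[None, :])
    L = len(pwm)
    hits = set()
    for sid, seq in sequences.items():
        seq = seq.upper()
        for strand in "+-":
            s = seq if strand == "+" else "".join(comp[b] for b in reversed(seq))
            for p in range(len(s) - L + 1):
                score = sum(
                    lo[j, _B.index(s[p + j])] if s[p + j] in _B else 0.0
                    for j in range(L)
                )
                if score >= threshold:
                    fwd = p if strand == "+" else len(s) - p - L
                    hits.add((pwm.motif_id, sid, fwd, strand, round(score, 6)))
    return hits


class TestPWM:
    def test_bad_column_sum_rejected(self):
        m = np.full((5, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            PWM("M", "T", m)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="length"):
            point_mass_pwm("ACG")

    def test_meme_round_trip(self, tmp_path):
        pwms = [soft_pwm("ACGTAC", "M1", "TFA"), soft_pwm("TTGACA", "M2", "TFB")]
        path = tmp_path / "m.meme"
        write_meme(path, pwms)
        back = read_meme(path)
        assert [p.motif_id for p in back] == ["M1", "M2"]
        assert [p.tf for p in back] == ["TFA", "TFB"]
        for a, b in zip(back, pwms):
            assert np.allclose(a.matrix, b.matrix, atol=1e-6)
            assert np.allclose(a.background, b.background)


class TestScanMotifs:
    def test_point_mass_on_own_consensus_scores_8_bits(self):
        pwm = point_mass_pwm("ACGT")
        hits = scan_motifs([pwm], {"s": "ACGT"})
        fwd = [h for h in hits if h.strand == "+"]
        assert len(fwd) == 1
        assert fwd[0].pos == 0
        assert fwd[0].score == pytest.approx(8.0)  # 4 * log2(1/0.25)
        # ACGT is its own reverse complement; all hits share the full score
        assert all(h.score == pytest.approx(8.0) for h in hits)

    def test_no_hit_on_mismatched_sequence(self):
        assert scan_motifs([point_mass_pwm("ACGT")], {"s": "TTTT"}) == []

    def test_n_bases_score_zero_bits(self):
        pwm = point_mass_pwm("ACGT")
        hits = scan_motifs([pwm], {"s": "ACGN"}, score_thresh_bits=5.9)
        # ACGT is palindromic, so the N-discounted 6-bit hit shows on both strands
        assert len(hits) == 2
        assert all(h.score == pytest.approx(6.0) and h.pos == 0 for h in hits)

    def test_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(12)
        pwms = [
            soft_pwm("".join(rng.choice(list(_B), size=6)), f"M{i}", f"TF{i}")
            for i in range(3)
        ]
        seqs = {
            f"s{i}": "".join(rng.choice(list(_B), size=60)) for i in range(20)
        }
        for pwm in pwms:
            thresh = 0.8 * pwm.max_score()
            got = {
                (h.motif_id, h.seq_id, h.pos, h.strand, round(h.score, 6))
                for h in scan_motifs([pwm], seqs)
            }
            assert got == brute_force_hits(pwm, seqs, thresh)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(3)
        pwm = soft_pwm("GATTACA")
        seqs = {f"s{i}": "".join(rng.choice(list(_B), size=50)) for i in range(10)}
        comp = str.maketrans("ACGT", "TGCA")
        rc = {k: v.translate(comp)[::-1] for k, v in seqs.items()}
        a = scan_motifs([pwm], seqs)
        b = scan_motifs([pwm], rc)
        flip = {"+": "-", "-": "+"}
        mapped = {
            (h.seq_id, len(seqs[h.seq_id]) - h.pos - len(pwm), flip[h.strand],
             round(h.score, 9))
            for h in b
        }
        assert mapped == {
            (h.seq_id, h.pos, h.strand, round(h.score, 9)) for h in a
        }


class TestMotifEnrichment:
    def hits_for(self, motif, seq_ids):
        return [MotifHit(motif, s, 0, "+", 10.0) for s in seq_ids]

    def test_perfect_enrichment_matches_exact_tail(self):
        altered = [f"a{i}" for i in range(5)]
        rest = [f"b{i}" for i in range(15)]
        res = motif_enrichment(self.hits_for("M", altered), altered, altered + rest)
        # Fisher one-sided for table [[5,0],[0,15]] = 1/C(20,5)
        expected = 1 / math.comb(20, 5)
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-9)
        assert bool(res.loc[0, "significant"])

    def test_equal_rates_not_enriched(self):
        altered = [f"a{i}" for i in range(10)]
        rest = [f"b{i}" for i in range(10)]
        hits = self.hits_for("M", altered[:5] + rest[:5])
        res = motif_enrichment(hits, altered, altered + rest)
        assert res.loc[0, "p"] > 0.5

    def test_zero_hit_motif_reported_when_listed(self):
        altered = ["a0", "a1"]
        res = motif_enrichment([], altered, altered + ["b0"], motif_ids=["M"])
        assert res.loc[0, "hits_altered"] == 0 and res.loc[0, "p"] == 1.0

    def test_empty_altered_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            motif_enrichment([], [], ["a"])
        with pytest.raises(ValueError, match="subset"):
            motif_enrichment([], ["x"], ["a"])


class TestDifferentialExpression:
    def build(self, tumor_fold, seed=0, n_t=30, n_n=10):
        rng = np.random.default_rng(seed)
        tumors = [f"T{i}" for i in range(n_t)]
        normals = [f"N{i}" for i in range(n_n)]
        base = 50.0
        t_vals = base * tumor_fold * rng.lognormal(0, 0.05, n_t)
        n_vals = base * rng.lognormal(0, 0.05, n_n)
        data = pd.DataFrame(
            [np.concatenate([t_vals, n_vals])], index=["g"], columns=tumors + normals
        )
        return data, tumors, normals

    def test_fold_above_gate_called_up(self):
        data, t, n = self.build(1.5)
        de = differential_expression(data, t, n)
        assert de.loc["g", "status"] == "up"

    def test_significant_but_small_fold_is_ns(self):
        data, t, n = self.build(1.1, seed=1)
        de = differential_expression(data, t, n)
        assert de.loc["g", "q"] < 0.1  # highly significant shift
        assert de.loc["g", "status"] == "ns"  # but below the 1.2-fold gate

    def test_down_direction(self):
        data, t, n = self.build(0.5, seed=2)
        assert differential_expression(data, t, n).loc["g", "status"] == "down"

    def test_equal_means_ns(self):
        data = pd.DataFrame(
            [[5.0] * 8], index=["g"], columns=[f"S{i}" for i in range(8)]
        )
        de = differential_expression(data, [f"S{i}" for i in range(4)],
                                     [f"S{i}" for i in range(4, 8)])
        assert de.loc["g", "status"] == "ns" and de.loc["g", "p"] == 1.0

    def test_too_few_samples_rejected(self):
        data, t, n = self.build(2.0)
        with pytest.raises(ValueError):
            differential_expression(data, t[:1], n)


class TestSpearman:
    def test_perfect_monotone(self):
        data = pd.DataFrame(
            [[1, 2, 3, 4, 5], [10, 20, 30, 40, 50], [50, 40, 30, 20, 10]],
            index=["tf", "up", "down"], columns=list("abcde"),
        )
        res = spearman_coexpression(data, [("tf", "up"), ("tf", "down")])
        assert res.loc[0, "scc"] == pytest.approx(1.0)
        assert res.loc[1, "scc"] == pytest.approx(-1.0)

    def test_matches_rank_pearson_oracle(self):
        from scipy.stats import rankdata

        rng = np.random.default_rng(8)
        n = 20
        feats = {f"f{i}": rng.normal(size=n) ** 2 for i in range(12)}
        data = pd.DataFrame(feats).T
        data.columns = [f"s{i}" for i in range(n)]
        pairs = [(f"f{i}", f"f{i + 6}") for i in range(6)]
        res = spearman_coexpression(data, pairs)
        for row in res.itertuples():
            rx = rankdata(data.loc[row.tf])
            ry = rankdata(data.loc[row.gene])
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert row.scc == pytest.approx(oracle, abs=1e-12)

    def test_constant_vector_skipped(self):
        data = pd.DataFrame(
            [[1, 1, 1, 1, 1], [1, 2, 3, 4, 5]], index=["flat", "var"],
            columns=list("abcde"),
        )
        res = spearman_coexpression(data, [("flat", "var")])
        assert not res.loc[0, "tested"] and np.isnan(res.loc[0, "scc"])

    def test_too_few_samples_rejected(self):
        data = pd.DataFrame([[1, 2], [3, 4]], index=["a", "b"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="paired samples"):
            spearman_coexpression(data, [("a", "b")])


def triplet_inputs(tf_de="up", gene_de="up", scc=0.8, scc_q=0.001,
                   enriched=True, hit=True):
    links = pd.DataFrame(
        [{"enhancer": "e1", "gene": "g1", "direction": "amplified"}]
    )
    hits = [MotifHit("M1", "e1", 5, "+", 9.0)] if hit else []
    enrichment = pd.DataFrame(
        [{"motif_id": "M1", "significant": enriched, "direction": "amplified"}]
    )
    de = pd.DataFrame(
        {"status": [tf_de, gene_de]}, index=["TF1", "g1"]
    )
    coexpr = pd.DataFrame(
        [{"tf": "TF1", "gene": "g1", "scc": scc, "q": scc_q, "tested": True}]
    )
    return links, hits, enrichment, de, coexpr, {"M1": "TF1"}


class TestAssembleTriplets:
    def test_concordant_de_gives_positive_sign(self):
        trips = assemble_triplets(*triplet_inputs("up", "up"))
        assert len(trips) == 1 and trips.loc[0, "sign"] == "+"

    def test_discordant_de_gives_negative_sign(self):
        trips = assemble_triplets(*triplet_inputs("up", "down", scc=-0.8))
        assert trips.loc[0, "sign"] == "-"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"tf_de": "ns"},
            {"gene_de": "ns"},
            {"scc": 0.2},
            {"scc_q": 0.05},
            {"enriched": False},
            {"hit": False},
        ],
    )
    def test_each_filter_blocks(self, kwargs):
        assert len(assemble_triplets(*triplet_inputs(**kwargs))) == 0

    def test_output_ids_subset_of_inputs(self, strong_results):
        results, _ = strong_results
        trips = results["triplets"]
        links = results["links"]
        assert set(trips["enhancer"]) <= set(links["enhancer"])
        assert set(trips["gene"]) <= set(links["gene"])
        assert set(zip(trips["enhancer"], trips["gene"])) <= set(
            zip(links["enhancer"], links["gene"])
        )

    def test_planted_circuits_recovered(self, strong_results):
        _, report = strong_results
        assert report["triplets"]["recall"] >= 0.8


def star_triplets(tf, genes, sign="+"):
    return pd.DataFrame(
        [
            {"tf": tf, "enhancer": f"e_{g}", "gene": g, "direction": "amplified",
             "scc": 0.5, "scc_q": 0.001, "tf_de": "up", "gene_de": "up",
             "sign": sign}
            for g in genes
        ]
    )


class TestNetwork:
    def test_multi_enhancer_support_collapses_to_one_edge(self):
        trips = pd.DataFrame(
            [
                {"tf": "T", "enhancer": e, "gene": "g", "direction": "amplified",
                 "scc": 0.5, "scc_q": 0.001, "tf_de": "up", "gene_de": "up",
                 "sign": "+"}
                for e in ("e1", "e2", "e3")
            ]
        )
        net = build_network(trips)
        assert net.number_of_edges() == 1
        (_, _, data), = net.edges(data=True)
        assert data["enhancers"] == ["e1", "e2", "e3"]

    def test_empty_triplets_give_empty_network(self):
        net = build_network(star_triplets("T", []))
        assert net.number_of_nodes() == 0

    def test_degree_sequence_on_fixture(self):
        # 5 triplets: T1->(g1,g2) via two enhancers on g1; T2->(g1,g3)
        rows = [
            ("T1", "ea", "g1"), ("T1", "eb", "g1"), ("T1", "ec", "g2"),
            ("T2", "ed", "g1"), ("T2", "ee", "g3"),
        ]
        trips = pd.DataFrame(
            [
                {"tf": t, "enhancer": e, "gene": g, "direction": "amplified",
                 "scc": 0.5, "scc_q": 0.001, "tf_de": "up", "gene_de": "up",
                 "sign": "+"}
                for t, e, g in rows
            ]
        )
        net = build_network(trips)
        out = {n: len(set(net.successors(n))) for n in ("T1", "T2")}
        indeg = {n: len(set(net.predecessors(n))) for n in ("g1", "g2", "g3")}
        assert out == {"T1": 2, "T2": 2}
        assert indeg == {"g1": 2, "g2": 1, "g3": 1}

    def test_conflicting_signs_kept_as_parallel_edges(self):
        trips = pd.concat(
            [star_triplets("T", ["g"], "+"), star_triplets("T", ["g"], "-")]
        )
        net = build_network(trips)
        assert net.number_of_edges() == 2
        assert {d["sign"] for _, _, d in net.edges(data=True)} == {"+", "-"}


class TestCoreModule:
    def test_zero_thresholds_keep_full_network(self):
        net = build_network(star_triplets("T", [f"g{i}" for i in range(5)]))
        module, stats = extract_core_module(net, 0, 0)
        assert stats["n_interactions"] == 5
        assert module.number_of_edges() == net.number_of_edges()

    def test_star_above_threshold_kept(self):
        net = build_network(star_triplets("T", [f"g{i}" for i in range(25)]))
        module, stats = extract_core_module(net, 20, 0)
        assert stats["n_tfs"] == 1 and stats["n_genes"] == 25

    def test_planted_hub_community_extracted_exactly(self):
        hub_tfs = [f"H{i}" for i in range(3)]
        hub_genes = [f"hg{i}" for i in range(4)]
        parts = [star_triplets(t, hub_genes) for t in hub_tfs]
        # background: low-degree TFs and genes
        parts.append(star_triplets("bgT", ["bg1", "bg2"]))
        net = build_network(pd.concat(parts, ignore_index=True))
        module, stats = extract_core_module(net, tf_min_out=3, gene_min_in=2)
        assert set(module.nodes) == set(hub_tfs) | set(hub_genes)
        assert stats["n_interactions"] == 12

    def test_overpruning_returns_empty_module(self):
        net = build_network(star_triplets("T", ["g1"]))
        module, stats = extract_core_module(net, 20, 7)
        assert stats["n_interactions"] == 0 and module.number_of_edges() == 0


class TestCancerGenePermutation:
    def test_targets_all_cancer_gives_proportion_one(self):
        uni = [f"g{i}" for i in range(20)]
        obs, p = cancer_gene_permutation(uni[:5], uni[:5], uni, B=200, seed=1)
        assert obs == 1.0 and 0 < p <= 1

    def test_cancer_equals_universe_gives_p_one(self):
        uni = [f"g{i}" for i in range(10)]
        obs, p = cancer_gene_permutation(uni[:4], uni, uni, B=200, seed=1)
        assert obs == 1.0 and p == pytest.approx(1.0)

    def test_matches_hypergeometric_tail(self):
        # universe 10, targets 4, cancer 5: P(X >= overlap) exactly
        uni = [f"g{i}" for i in range(10)]
        targets, cancer = uni[:4], uni[3:8]
        obs_count = len(set(targets) & set(cancer))  # 1
        B = 4000
        obs, p = cancer_gene_permutation(targets, cancer, uni, B=B, seed=5)
        exact = sum(
            math.comb(5, j) * math.comb(5, 4 - j) / math.comb(10, 4)
            for j in range(obs_count, 5)
        )
        se = math.sqrt(exact * (1 - exact) / B)
        assert abs(p - exact) <= 3 * se + 2 / B

    def test_reproducible_and_in_range(self):
        uni = [f"g{i}" for i in range(50)]
        a = cancer_gene_permutation(uni[:10], uni[5:20], uni, B=500, seed=7)
        b = cancer_gene_permutation(uni[:10], uni[5:20], uni, B=500, seed=7)
        assert a == b and 0 < a[1] <= 1

    def test_invalid_inputs_rejected(self):
        uni = ["a", "b"]
        with pytest.raises(ValueError):
            cancer_gene_permutation(["z"], ["a"], uni)
        with pytest.raises(ValueError):
            cancer_gene_permutation([], ["a"], uni)
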