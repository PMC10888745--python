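"""Signed-rank profiles, query construction and the normalized
connectivity score, checked against independent brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sigconn.connectivity import (
    ORDERED,
    UNORDERED,
    QuerySignature,
    build_query,
    build_reference_ranks,
    max_raw_score,
    score_library,
    zhang_score,
)
from sigconn.differential import contrast
from sigconn.errors import EmptyQueryError, UndefinedScoreError

from conftest import make_expression, make_library


def brute_force_max(n: int, m: int, mode: str) -> int:
    """Independent oracle: maximum of C = sum_i sr_ref(g_i) * sr_q(g_i)
    over every placement of m query genes onto distinct reference rank
    magnitudes 1..n and every sign assignment."""
    best = -(10**9)
    q_ranks = list(range(1, m + 1)) if mode == ORDERED else [1] * m
    for placement in itertools.permutations(range(1, n + 1), m):
        for signs in itertools.product((-1, 1), repeat=m):
            c = sum(s * r * q for s, r, q in zip(signs, placement, q_ranks))
            best = max(best, c)
    return best


def naive_score(ref_ranks: dict[str, int], n: int, q: QuerySignature) -> float:
    """Independent plain-python route to the normalized score."""
    eff = [(g, s) for g, s in zip(q.genes, q.signs) if ref_ranks.get(g, 0) != 0]
    total = 0
    for i, (g, s) in enumerate(eff):
        srq = s * (i + 1) if q.mode == ORDERED else s
        total += ref_ranks[g] * srq
    m = len(eff)
    if q.mode == ORDERED:
        cmax = sum((m - k) * (n - k) for k in range(m))
    else:
        cmax = sum(n - k for k in range(m))
    return total / cmax


class TestReferenceRanks:
    def test_definition(self):
        lib = make_library({"S": np.array([2.0, -1.0, 0.5])}, genes=["A", "B", "C"])
        ref = build_reference_ranks(lib, "S")
        assert ref.signed_ranks == {"A": 3, "B": -2, "C": 1}

    def test_tie_broken_by_gene_id(self):
        lib = make_library({"S": np.array([1.0, -1.0])}, genes=["A", "B"])
        ref = build_reference_ranks(lib, "S")
        assert ref.signed_ranks == {"A": 1, "B": -2}

    def test_zero_amplitude_gets_rank_zero(self):
        lib = make_library({"S": np.array([2.0, 0.0, -1.0])}, genes=["A", "B", "C"])
        ref = build_reference_ranks(lib, "S")
        assert ref.signed_ranks["B"] == 0
        assert {abs(r) for r in ref.signed_ranks.values() if r != 0} == {2, 3}

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        amps = rng.standard_normal(50)
        genes = [f"G{i:02d}" for i in range(50)]
        a = build_reference_ranks(make_library({"S": amps}, genes=genes), "S")
        transformed = np.sign(amps) * (np.abs(amps) ** 3 + 1.0)
        b = build_reference_ranks(make_library({"S": transformed}, genes=genes), "S")
        assert a.signed_ranks == b.signed_ranks


class TestBuildQuery:
    @pytest.fixture
    def ct(self):
        # 5 genes: strong up, mild up, strong down, mild down, null
        ctrl = np.array([10.0, 10.0, 40.0, 16.0, 20.0])
        trt = np.array([40.0, 16.0, 10.0, 10.0, 20.0])
        offsets = np.array([-1e-6, 0.0, 1e-6])
        vals = np.hstack([ctrl[:, None] * (1 + offsets), trt[:, None] * (1 + offsets)])
        return contrast(make_expression(vals, genes=["U1", "U2", "D1", "D2", "N"]))

    def test_order_and_signs(self, ct):
        q = build_query(ct, ["U1", "U2", "D1", "D2", "N"])
        assert q.genes == ["U2", "D2", "D1", "U1"] or q.genes == ["D2", "U2", "D1", "U1"]
        sr = q.signed_ranks()
        assert sr["U1"] == 4 and sr["D1"] == -3

    def test_landmark_intersection_drops_outsiders(self, ct):
        q = build_query(ct, ["U1", "D1"])
        assert set(q.genes) == {"U1", "D1"}

    def test_empty_intersection_raises(self, ct):
        with pytest.raises(EmptyQueryError):
            build_query(ct, ["NOT_A_GENE"])

    def test_m_max_keeps_strongest(self, ct):
        q = build_query(ct, ["U1", "U2", "D1", "D2"], m_max=2)
        assert q.genes == ["D1", "U1"]

    def test_unordered_mode_signs_only(self, ct):
        q = build_query(ct, ["U1", "U2", "D1", "D2"], mode=UNORDERED)
        assert set(q.signed_ranks().values()) <= {-1, 1}


class TestZhangScore:
    def test_worked_example(self, five_gene_ref):
        # ref sr {A:+5, B:-4, C:+3, D:-2, E:+1}; query (C weakest +, B strongest +)
        ref = build_reference_ranks(five_gene_ref, "REF")
        q = QuerySignature(["C", "B"], [1, 1])
        rec = zhang_score(ref, q)
        assert rec.c == pytest.approx(-5 / 14)
        assert rec.m_eff == 2

    def test_self_query_scores_one(self):
        rng = np.random.default_rng(1)
        genes = [f"G{i:03d}" for i in range(100)]
        lib = make_library({"S": rng.standard_normal(100)}, genes=genes)
        ref = build_reference_ranks(lib, "S")
        top = sorted(ref.signed_ranks.items(), key=lambda kv: abs(kv[1]))[-20:]
        q = QuerySignature([g for g, _ in top], [1 if r > 0 else -1 for _, r in top])
        assert zhang_score(ref, q).c == 1.0
        assert zhang_score(ref, q.flipped()).c == -1.0

    def test_antisymmetry_under_sign_flip(self):
        rng = np.random.default_rng(2)
        genes = [f"G{i:03d}" for i in range(60)]
        lib = make_library({"S": rng.standard_normal(60)}, genes=genes)
        ref = build_reference_ranks(lib, "S")
        picks = rng.choice(genes, size=10, replace=False).tolist()
        q = QuerySignature(picks, rng.choice([-1, 1], size=10).tolist())
        assert zhang_score(ref, q.flipped()).c == -zhang_score(ref, q).c

    def test_bounded_over_random_draws(self):
        rng = np.random.default_rng(3)
        genes = [f"G{i:03d}" for i in range(40)]
        for _ in range(300):
            lib = make_library({"S": rng.standard_normal(40)}, genes=genes)
            ref = build_reference_ranks(lib, "S")
            m = int(rng.integers(1, 15))
            picks = rng.choice(genes, size=m, replace=False).tolist()
            mode = ORDERED if rng.random() < 0.5 else UNORDERED
            q = QuerySignature(picks, rng.choice([-1, 1], size=m).tolist(), mode)
            rec = zhang_score(ref, q)
            assert -1.0 <= rec.c <= 1.0

    def test_matches_naive_oracle_on_random_instances(self):
        rng = np.random.default_rng(4)
        genes = [f"G{i:03d}" for i in range(30)]
        for _ in range(100):
            amps = rng.standard_normal(30)
            amps[rng.random(30) < 0.2] = 0.0  # some zero amplitudes
            lib = make_library({"S": amps}, genes=genes)
            ref = build_reference_ranks(lib, "S")
            m = int(rng.integers(1, 10))
            picks = rng.choice(genes, size=m, replace=False).tolist()
            q = QuerySignature(picks, rng.choice([-1, 1], size=m).tolist())
            try:
                rec = zhang_score(ref, q)
            except UndefinedScoreError:
                assert all(ref.signed_ranks[g] == 0 for g in picks)
                continue
            assert rec.c == pytest.approx(naive_score(ref.signed_ranks, ref.n, q), abs=1e-12)

    @pytest.mark.parametrize("mode", [ORDERED, UNORDERED])
    def test_closed_form_max_equals_brute_force(self, mode):
        for n in range(1, 7):
            for m in range(1, min(n, 3) + 1):
                assert max_raw_score(n, m, mode) == brute_force_max(n, m, mode)

    def test_missing_gene_consistency(self, five_gene_ref):
        ref = build_reference_ranks(five_gene_ref, "REF")
        with_absent = QuerySignature(["C", "ZZZ", "B"], [1, 1, 1])
        without = QuerySignature(["C", "B"], [1, 1])
        a, b = zhang_score(ref, with_absent), zhang_score(ref, without)
        assert a.c == b.c and a.m_eff == b.m_eff == 2

    def test_all_zero_reference_undefined(self):
        lib = make_library({"S": np.zeros(4)}, genes=list("ABCD"))
        ref = build_reference_ranks(lib, "S")
        with pytest.raises(UndefinedScoreError):
            zhang_score(ref, QuerySignature(["A"], [1]))

    def test_empty_query_rejected_at_construction(self):
        with pytest.raises(EmptyQueryError):
            QuerySignature([], [])


class TestScoreLibrary:
    def test_planted_best_among_decoys(self):
        rng = np.random.default_rng(5)
        genes = [f"G{i:03d}" for i in range(50)]
        target = rng.standard_normal(50)
        amps = {"TARGET": target}
        for i in range(3):
            amps[f"DECOY{i}"] = rng.standard_normal(50)
        lib = make_library(amps, genes=genes)
        ref = build_reference_ranks(lib, "TARGET")
        top = sorted(ref.signed_ranks.items(), key=lambda kv: abs(kv[1]))[-10:]
        q = QuerySignature([g for g, _ in top], [1 if r > 0 else -1 for _, r in top])
        records = {r.signature_id: r.c for r in score_library(lib, q)}
        assert records["TARGET"] == 1.0
        assert all(records["TARGET"] > v for k, v in records.items() if k != "TARGET")

    def test_duplicated_signature_scores_identically(self):
        rng = np.random.default_rng(6)
        genes = [f"G{i:03d}" for i in range(20)]
        amps = rng.standard_normal(20)
        lib = make_library({"S1": amps, "S2": amps.copy()}, genes=genes)
        q = QuerySignature(genes[:5], [1, -1, 1, 1, -1])
        recs = {r.signature_id: r.c for r in score_library(lib, q)}
        assert recs["S1"] == recs["S2"]

    def test_records_sorted_and_complete_at_scale(self):
        rng = np.random.default_rng(7)
        genes = [f"G{i:04d}" for i in range(978)]
        lib = make_library(
            {f"SIG{i:03d}": rng.standard_normal(978) for i in range(200)}, genes=genes
        )
        picks = rng.choice(genes, size=30, replace=False).tolist()
        q = QuerySignature(picks, rng.choice([-1, 1], size=30).tolist())
        records = score_library(lib, q)
        assert len(records) == 200
        assert [r.signature_id for r in records] == sorted(r.signature_id for r in records)

    def test_all_zero_signature_flagged_not_crash(self):
        genes = list("ABCD")
        lib = make_library({"OK": np.array([1.0, -2.0, 3.0, 0.5]), "ZERO": np.zeros(4)}, genes=genes)
        q = QuerySignature(["A", "B"], [1, -1])
        recs = {r.signature_id: r for r in score_library(lib, q)}
        assert recs["OK"].ok
        assert not recs["ZERO"].ok and np.isnan(recs["ZERO"].c)
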