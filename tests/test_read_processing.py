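"""Adapter trimming, mapping, counting and normalization."""

import math

import numpy as np
import pandas as pd
import pytest

from mirconsensus import (
    CountTable,
    MiRNAReference,
    ReadRecord,
    count_unambiguous,
    map_reads,
    normalize_counts,
    trim_adapter,
    trim_adapters,
)
from mirconsensus.read_processing import AMBIGUOUS, ASSIGNED, UNMAPPED, end_weights

from conftest import ADAPTER, random_seq


def read(seq, rid="r1"):
    return ReadRecord(rid, seq, "I" * len(seq))


# ---------------------------------------------------------------------------
# oracle: transparently slow re-scorer of every offset
# ---------------------------------------------------------------------------


def brute_trim(seq, adapter, min_overlap, max_penalty):
    n = len(seq)
    weights = [1 + (n - 1 - i) / (n - 1) if n > 1 else 1.0 for i in range(n)]
    candidates = []
    for s in range(n):
        L = min(len(adapter), n - s)
        if L < min_overlap:
            continue
        pen = sum(weights[s + j] for j in range(L) if seq[s + j] != adapter[j])
        if pen <= max_penalty:
            candidates.append((pen, s))
    if not candidates:
        return None
    return min(candidates)


class TestTrimAdapter:
    def test_exact_adapter_found(self):
        insert = random_seq(np.random.default_rng(0), 20)
        res = trim_adapter(read(insert + ADAPTER[: 36 - 20]), ADAPTER)
        assert res.adapter_found and res.adapter_start == 20
        assert res.insert == insert and res.score == 0.0

    def test_no_adapter_cut_to_22(self):
        rng = np.random.default_rng(5)
        checked = 0
        for _ in range(50):
            seq = random_seq(rng, 36)
            res = trim_adapter(read(seq), ADAPTER)
            if not res.adapter_found:
                assert len(res.insert) == 22
                checked += 1
        assert checked > 0

    def test_short_read_passes_through_unchanged(self):
        # fallback is truncation only
        seq = "ACGTACGTACGTACG"  # 15 nt, no adapter
        res = trim_adapter(read(seq), ADAPTER, max_penalty=0.0)
        assert not res.adapter_found and res.insert == seq

    def test_end_mismatch_scores_lower_penalty(self):
        # same adapter occurrence, one mismatch near the 5' end vs near the
        # 3' end: the end mismatch must cost less
        rng = np.random.default_rng(7)
        insert = random_seq(rng, 14)
        tail = (insert + ADAPTER)[:36]
        pos_early, pos_late = 16, 34  # both inside the adapter region
        for pos in (pos_early, pos_late):
            assert pos >= len(insert)
        r_early = list(tail)
        r_early[pos_early] = "A" if r_early[pos_early] != "A" else "C"
        r_late = list(tail)
        r_late[pos_late] = "A" if r_late[pos_late] != "A" else "C"
        res_early = trim_adapter(read("".join(r_early)), ADAPTER)
        res_late = trim_adapter(read("".join(r_late)), ADAPTER)
        assert res_early.adapter_start == res_late.adapter_start == len(insert)
        assert res_late.score < res_early.score
        w = end_weights(36)
        assert res_early.score == pytest.approx(w[pos_early])
        assert res_late.score == pytest.approx(w[pos_late])

    def test_agrees_with_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        reads = []
        for i in range(200):
            if i % 2 == 0:
                ins = random_seq(rng, int(rng.integers(10, 26)))
                seq = (ins + ADAPTER + random_seq(rng, 36))[:36]
            else:
                seq = random_seq(rng, 36)
            reads.append(read(seq, f"r{i}"))
        batch = trim_adapters(reads, ADAPTER)
        for r, res in zip(reads, batch):
            single = trim_adapter(r, ADAPTER)
            assert (single.insert, single.adapter_found, single.adapter_start) == (
                res.insert,
                res.adapter_found,
                res.adapter_start,
            )
            oracle = brute_trim(r.sequence, ADAPTER, 5, 2.5)
            if oracle is None:
                assert not res.adapter_found
                assert len(res.insert) == min(22, len(r.sequence))
            else:
                pen, s = oracle
                assert res.adapter_found and res.adapter_start == s
                assert res.score == pytest.approx(pen)

    def test_zero_penalty_is_exact_substring_search(self):
        rng = np.random.default_rng(99)
        for i in range(100):
            seq = random_seq(rng, 36)
            if i % 3 == 0:
                s0 = int(rng.integers(0, 30))
                seq = seq[:s0] + ADAPTER[: 36 - s0]
            res = trim_adapter(read(seq), ADAPTER, max_penalty=0.0)
            # oracle: earliest exact occurrence of the adapter prefix
            hit = None
            for s in range(36 - 5 + 1):
                L = min(len(ADAPTER), 36 - s)
                if L >= 5 and seq[s : s + L] == ADAPTER[:L]:
                    hit = s
                    break
            assert res.adapter_found == (hit is not None)
            if hit is not None:
                assert res.adapter_start == hit

    def test_errors(self):
        with pytest.raises(ValueError):
            trim_adapter(read("", "x"), ADAPTER)
        with pytest.raises(ValueError):
            trim_adapter(read("ACGT" * 9), "ACGTN")


# ---------------------------------------------------------------------------
# mapping
# ---------------------------------------------------------------------------


def tiny_reference():
    pre_a = "AAAAA" + "ACGTACGTACGTACGTACGTAC" + "GGGGG"
    pre_b = "TTTTT" + "TGCATGCATGCATGCATGCATG" + "CCCCC"
    pre_c = "CCCCC" + "ACGTACGTACGTACGTACGTAC" + "AAAAA"  # same mature as A
    return MiRNAReference(
        precursors={"preA": pre_a, "preB": pre_b, "preC": pre_c},
        matures={
            "mirA": ("preA", 5, 27),
            "mirB": ("preB", 5, 27),
            "mirC": ("preC", 5, 27),
        },
    )


class TestMapReads:
    def test_exact_unique_mature(self, reference):
        locus = sorted(reference.matures)[0]
        [res] = map_reads([reference.mature_sequence(locus)], reference)
        assert res.status == ASSIGNED and res.locus == locus and res.mismatches == 0

    def test_shared_mature_is_ambiguous(self):
        ref = tiny_reference()
        [res] = map_reads([ref.mature_sequence("mirA")], ref)
        assert res.status == AMBIGUOUS

    def test_mismatch_threshold(self, reference):
        locus = sorted(reference.matures)[0]
        mature = reference.mature_sequence(locus)

        def mutate(seq, positions):
            chars = list(seq)
            for p in positions:
                chars[p] = "A" if chars[p] != "A" else "C"
            return "".join(chars)

        [two] = map_reads([mutate(mature, [3, 8])], reference)
        assert two.status == ASSIGNED and two.mismatches == 2
        [three] = map_reads([mutate(mature, [3, 8, 13])], reference)
        assert three.status == UNMAPPED

    def test_below_floor_unmapped(self, reference):
        [res] = map_reads(["ACGTACGT"], reference)
        assert res.status == UNMAPPED

    def test_agrees_with_exhaustive_oracle(self, reference):
        """Slow all-loci all-offsets Hamming scan with length iteration."""

        def oracle(insert, max_mm=2, pad=5, floor=16):
            if len(insert) < floor:
                return (UNMAPPED, None)
            for L in range(len(insert), floor - 1, -1):
                query = insert[:L]
                hits = {}
                for locus, (pre, ms, me) in reference.matures.items():
                    P = reference.precursors[pre]
                    lo, hi = max(0, ms - pad), min(len(P), me + pad)
                    for o in range(lo, hi - L + 1):
                        d = sum(a != b for a, b in zip(query, P[o : o + L]))
                        if d <= max_mm:
                            hits[locus] = min(hits.get(locus, d), d)
                if hits:
                    best = min(hits.values())
                    loci = [l for l, d in hits.items() if d == best]
                    if len(loci) == 1:
                        return (ASSIGNED, loci[0])
                    return (AMBIGUOUS, None)
            return (UNMAPPED, None)

        rng = np.random.default_rng(77)
        inserts = []
        loci = sorted(reference.matures)
        for i in range(300):
            locus = loci[int(rng.integers(len(loci)))]
            m = reference.mature_sequence(locus)
            kind = i % 4
            if kind == 0:
                ins = m
            elif kind == 1:
                ins = m[: len(m) - int(rng.integers(1, 4))]
            elif kind == 2:
                chars = list(m)
                p = int(rng.integers(len(m)))
                chars[p] = "A" if chars[p] != "A" else "G"
                ins = "".join(chars)
            else:
                ins = random_seq(rng, 22)
            inserts.append(ins)
        results = map_reads(inserts, reference)
        for ins, res in zip(inserts, results):
            status, locus = oracle(ins)
            assert res.status == status
            if status == ASSIGNED:
                assert res.locus == locus

    def test_conservation(self, reference):
        rng = np.random.default_rng(3)
        inserts = [random_seq(rng, 22) for _ in range(50)] + [
            reference.mature_sequence(l) for l in sorted(reference.matures)[:5]
        ]
        results = map_reads(inserts, reference)
        by_status = {s: sum(r.status == s for r in results) for s in (ASSIGNED, AMBIGUOUS, UNMAPPED)}
        assert sum(by_status.values()) == len(inserts)


class TestCounting:
    def test_tally_and_exclusions(self, reference):
        loci = sorted(reference.matures)[:2]
        assignments = (
            map_reads([reference.mature_sequence(loci[0])] * 10, reference)
            + map_reads([reference.mature_sequence(loci[1])] * 5, reference)
        )
        col = count_unambiguous(assignments, "s1")
        assert col[loci[0]] == 10 and col[loci[1]] == 5
        assert col.sum() <= len(assignments)

    def test_all_ambiguous_zero_column(self):
        ref = tiny_reference()
        assignments = map_reads([ref.mature_sequence("mirA")] * 4, ref)
        col = count_unambiguous(assignments, "s1", loci=list(ref.matures))
        assert (col == 0).all()


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def brute_tmm(counts: pd.DataFrame, trim_m=0.30, trim_a=0.05):
    """Independent trimmed-mean-of-M computation (plain python loops)."""
    lib = counts.sum(axis=0).astype(float)
    f75 = {s: float(np.quantile(counts[s] / lib[s], 0.75)) for s in counts.columns}
    mean75 = sum(f75.values()) / len(f75)
    ref = min(sorted(counts.columns), key=lambda s: (abs(f75[s] - mean75), s))
    factors = {}
    for s in counts.columns:
        rows = [
            (math.log2((counts.at[g, s] / lib[s]) / (counts.at[g, ref] / lib[ref])),
             0.5 * math.log2((counts.at[g, s] / lib[s]) * (counts.at[g, ref] / lib[ref])))
            for g in counts.index
            if counts.at[g, s] > 0 and counts.at[g, ref] > 0
        ]
        n = len(rows)
        Ms = [m for m, _ in rows]
        As = [a for _, a in rows]
        keep = [True] * n
        for vals, frac in ((Ms, trim_m), (As, trim_a)):
            cut = int(math.floor(n * frac / 2))
            if cut:
                order = sorted(range(n), key=lambda i: vals[i])
                for i in order[:cut] + order[n - cut:]:
                    keep[i] = False
        kept = [Ms[i] for i in range(n) if keep[i]]
        factors[s] = 2 ** (sum(kept) / len(kept)) if kept else 1.0
    log_gm = sum(math.log(f) for f in factors.values()) / len(factors)
    return {s: f / math.exp(log_gm) for s, f in factors.items()}


def random_counts(rng, n_loci=50, samples=("s1", "s2", "s3")):
    base = rng.poisson(100, size=n_loci) + 1
    data = {
        s: rng.poisson(base * rng.uniform(0.5, 2.0)) + (1 if i == 0 else 0)
        for i, s in enumerate(samples)
    }
    df = pd.DataFrame(data, index=[f"L{i:03d}" for i in range(n_loci)])
    df.iloc[0] += 1  # at least one locus positive everywhere
    return df


class TestNormalize:
    def test_identical_samples_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        table = normalize_counts(CountTable(counts))
        assert np.allclose(table.norm_factors, 1.0)

    def test_pure_depth_scaling(self):
        a = np.array([10, 25, 40, 5, 100])
        counts = pd.DataFrame({"a": a, "b": 2 * a})
        table = normalize_counts(CountTable(counts))
        eff = counts.sum(axis=0) * table.norm_factors
        assert eff["b"] / eff["a"] == pytest.approx(2.0)
        assert np.allclose(table.normalized["a"], table.normalized["b"])

    def test_matches_brute_force_oracle(self, rng):
        counts = random_counts(rng)
        table = normalize_counts(CountTable(counts))
        oracle = brute_tmm(counts)
        for s in counts.columns:
            assert table.norm_factors[s] == pytest.approx(oracle[s], abs=1e-10)

    def test_relabel_and_scale_invariance(self, rng):
        counts = random_counts(rng)
        t1 = normalize_counts(CountTable(counts))
        shuffled = counts[["s3", "s1", "s2"]]
        t2 = normalize_counts(CountTable(shuffled))
        for s in counts.columns:
            assert t1.norm_factors[s] == pytest.approx(t2.norm_factors[s])
        t3 = normalize_counts(CountTable(counts * 7))
        for s in counts.columns:
            assert t1.norm_factors[s] == pytest.approx(t3.norm_factors[s])
        ratio = t3.normalized / t1.normalized
        assert np.allclose(ratio, 7.0)

    def test_all_zero_sample_errors(self):
        counts = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            normalize_counts(CountTable(counts))
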