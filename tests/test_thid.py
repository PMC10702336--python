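"""Pairwise identity, top-hit search, dense ranks, cross-coverage."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barcodedb import (
    Scoring,
    dense_ranks,
    pairwise_identity,
    subsample_cross_coverage,
    top_hit_search,
)
from barcodedb.thid import round_half_up

SCORING = Scoring()


def nw_oracle(a: str, b: str, sc: Scoring = SCORING) -> float:
    """Quadratic-space affine-gap NW in plain Python.

    Same objective as the production kernel (max score, ties toward more
    matches, then prefer an aligned column over opening or extending a gap)
    but written independently: dict-of-tuples DP over (score, matches) pairs
    with explicit path reconstruction.
    """

    def best(cands):
        # first candidate wins ties on (score, matches): D before V before H
        top = None
        for s, q, name in cands:
            if top is None or s > top[0] or (s == top[0] and q > top[1]):
                top = (s, q, name)
        return top

    NEG = float("-inf")
    n, m = len(a), len(b)
    # cell value: (score, matches); one table per state
    D = {}  # diagonal
    V = {}  # gap consuming a (vertical)
    H = {}  # gap consuming b (horizontal)
    ptr = {}
    D[0, 0] = (0, 0)
    for i in range(1, n + 1):
        V[i, 0] = (sc.gap_open + sc.gap_extend * i, 0)
        ptr["V", i, 0] = "V" if i > 1 else "D"
    for j in range(1, m + 1):
        H[0, j] = (sc.gap_open + sc.gap_extend * j, 0)
        ptr["H", 0, j] = "H" if j > 1 else "D"
    tables = {"D": D, "V": V, "H": H}
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eq = a[i - 1] == b[j - 1]
            sub = sc.match if eq else sc.mismatch
            cands = [
                (t[i - 1, j - 1][0] + sub, t[i - 1, j - 1][1] + eq, name)
                for name, t in tables.items()
                if (i - 1, j - 1) in t
            ]
            if cands:
                s, q, p = best(cands)
                D[i, j] = (s, q)
                ptr["D", i, j] = p
            cands = [
                (
                    t[i - 1, j][0]
                    + (sc.gap_extend if name == "V" else sc.gap_open + sc.gap_extend),
                    t[i - 1, j][1],
                    name,
                )
                for name, t in tables.items()
                if (i - 1, j) in t
            ]
            if cands:
                s, q, p = best(cands)
                V[i, j] = (s, q)
                ptr["V", i, j] = p
            cands = [
                (
                    t[i, j - 1][0]
                    + (sc.gap_extend if name == "H" else sc.gap_open + sc.gap_extend),
                    t[i, j - 1][1],
                    name,
                )
                for name, t in tables.items()
                if (i, j - 1) in t
            ]
            if cands:
                s, q, p = best(cands)
                H[i, j] = (s, q)
                ptr["H", i, j] = p
    state = best(
        [(t[n, m][0], t[n, m][1], name) for name, t in tables.items() if (n, m) in t]
    )[2]
    cols = []
    i, j = n, m
    while i > 0 or j > 0:
        cols.append(state)
        prev = ptr[state, i, j]
        if state == "D":
            i, j = i - 1, j - 1
        elif state == "V":
            i -= 1
        else:
            j -= 1
        state = prev
    cols.reverse()
    lo, hi = 0, len(cols)
    while lo < hi and cols[lo] != "D":
        lo += 1
    while hi > lo and cols[hi - 1] != "D":
        hi -= 1
    internal = cols[lo:hi]
    if not internal:
        return 0.0
    # matches: replay the diagonal columns
    matches = 0
    ai = bi = 0
    for k, c in enumerate(cols):
        if c == "D":
            if a[ai] == b[bi]:
                matches += 1
            ai += 1
            bi += 1
        elif c == "V":
            ai += 1
        else:
            bi += 1
    return 100.0 * matches / len(internal)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        seq = "ACGT" * 25
        assert pairwise_identity(seq, seq) == 100.0

    def test_three_substitutions_in_hundred(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 100))
        mutated = list(seq)
        for pos in (10, 50, 90):
            mutated[pos] = next(b for b in "ACGT" if b != seq[pos])
        assert pairwise_identity(seq, "".join(mutated)) == pytest.approx(97.0)

    def test_matches_python_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = int(rng.integers(30, 61))
            a = "".join(rng.choice(list("ACGT"), n))
            b = "".join(rng.choice(list("ACGT"), int(rng.integers(30, 61))))
            assert pairwise_identity(a, b) == pytest.approx(nw_oracle(a, b))

    def test_matches_oracle_with_planted_indels(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), 60))
            cut = int(rng.integers(10, 50))
            b = a[:cut] + a[cut + 3 :]  # 3-base internal deletion
            assert pairwise_identity(a, b) == pytest.approx(nw_oracle(a, b))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        a=st.text(alphabet="ACGT", min_size=5, max_size=40),
        b=st.text(alphabet="ACGT", min_size=5, max_size=40),
    )
    def test_symmetric(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_terminal_gaps_excluded_from_columns(self):
        # b is a with an extra tail; the tail is a terminal gap run
        a = "ACGTACGTAC"
        b = a + "GGGG"
        assert pairwise_identity(a, b) == 100.0


class TestTopHitSearch:
    def test_exact_copy_hits_its_reference_at_100(self):
        refs = [("r1", "ACGT" * 30), ("r2", "TTAA" * 30)]
        table = top_hit_search([("q1", "ACGT" * 30)], refs)
        (row,) = table.rows
        assert (row.target_id, row.identity) == ("r1", 100.0)

    def test_below_threshold_records_no_hit(self):
        rng = np.random.default_rng(3)
        refs = [("r1", "".join(rng.choice(list("ACGT"), 120)))]
        query = [("q1", "".join(rng.choice(list("ACGT"), 120)))]
        table = top_hit_search(query, refs, threshold=0.9)
        assert table.rows[0].target_id is None
        assert table.n_hits() == 0

    def test_ties_go_to_lowest_reference_id(self):
        seq = "ACGT" * 30
        refs = [("zzz", seq), ("aaa", seq)]
        table = top_hit_search([("q", seq)], refs)
        assert table.rows[0].target_id == "aaa"

    def test_matches_all_pairs_bruteforce_selection(self):
        rng = np.random.default_rng(17)
        refs = [
            (f"r{i:03d}", "".join(rng.choice(list("ACGT"), 80))) for i in range(20)
        ]
        queries = []
        for i in range(50):
            rid, rseq = refs[int(rng.integers(len(refs)))]
            k = int(rng.integers(0, 20))
            seq = list(rseq)
            for pos in rng.choice(80, size=k, replace=False):
                seq[pos] = next(
                    b for b in "ACGT" if b != rseq[pos]
                )
            queries.append((f"q{i:03d}", "".join(seq)))
        table = top_hit_search(queries, refs, threshold=0.7)
        # brute force: full identity matrix, best per query, same tie rule
        for qid, qseq in queries:
            ids = [pairwise_identity(qseq, rseq) for rid, rseq in sorted(refs)]
            best_pct = max(ids)
            best_rid = sorted(refs)[ids.index(best_pct)][0]
            row = next(r for r in table.rows if r.query_id == qid)
            if best_pct >= 70.0:
                assert row.target_id == best_rid
                assert row.identity == pytest.approx(best_pct)
            else:
                assert row.target_id is None

    def test_histogram_mass_equals_queries_with_hits(self):
        rng = np.random.default_rng(23)
        refs = [(f"r{i}", "".join(rng.choice(list("ACGT"), 60))) for i in range(10)]
        queries = [(f"q{i}", "".join(rng.choice(list("ACGT"), 60))) for i in range(30)]
        queries += [("qcopy", refs[0][1])]
        table = top_hit_search(queries, refs, threshold=0.7)
        assert sum(table.histogram().values()) == table.n_hits()

    def test_fasta_inputs_accepted(self, small_truth, tmp_path):
        ref_fasta = tmp_path / "refs.fasta"
        rows = small_truth.records.head(5)
        with open(ref_fasta, "w") as fh:
            for _, row in rows.iterrows():
                fh.write(f">{row['record_id']}\n{row['sequence']}\n")
        table = top_hit_search(str(small_truth.query_fasta), str(ref_fasta))
        assert len(table.rows) == len(small_truth.queries)


class TestRounding:
    def test_half_up(self):
        assert round_half_up(99.5) == 100
        assert round_half_up(98.49) == 98
        assert round_half_up(97.0) == 97


class TestDenseRanks:
    def test_tied_top_pair_shares_rank_three(self):
        assert dense_ranks([5, 10, 20, 20]) == [1, 2, 3, 3]

    def test_all_equal(self):
        assert dense_ranks([7, 7, 7]) == [1, 1, 1]

    def test_strictly_increasing(self):
        assert dense_ranks([1, 2, 3, 4]) == [1, 2, 3, 4]

    def test_permutation_invariant_up_to_labels(self):
        counts = [4, 9, 9, 2, 11]
        ranks = dense_ranks(counts)
        perm = [2, 0, 4, 1, 3]
        permuted = dense_ranks([counts[i] for i in perm])
        assert permuted == [ranks[i] for i in perm]


class TestCrossCoverage:
    def test_identical_databases_hit_at_100(self):
        rng = np.random.default_rng(9)
        seqs = [(f"s{i}", "".join(rng.choice(list("ACGT"), 80))) for i in range(12)]
        db_a = [(f"a{i}", s) for i, (_, s) in enumerate(seqs)]
        db_b = [(f"b{i}", s) for i, (_, s) in enumerate(seqs)]
        df = subsample_cross_coverage({"A": db_a, "B": db_b}, n=5, reps=2, seed=0)
        at_100 = df[df.identity == 100]
        assert (at_100.mean_hits == 5.0).all()

    def test_unrelated_databases_hit_nothing(self):
        rng = np.random.default_rng(10)
        db_a = [(f"a{i}", "".join(rng.choice(list("ACGT"), 100))) for i in range(8)]
        db_b = [(f"b{i}", "".join(rng.choice(list("ACGT"), 100))) for i in range(8)]
        df = subsample_cross_coverage({"A": db_a, "B": db_b}, n=4, reps=2, seed=1)
        assert (df.mean_hits == 0.0).all()

    def test_single_substitution_copies_concentrate_at_99(self):
        rng = np.random.default_rng(11)
        base = [(f"s{i}", "".join(rng.choice(list("ACGT"), 150))) for i in range(10)]
        mutated = []
        for i, (_, s) in enumerate(base):
            pos = int(rng.integers(150))
            s2 = s[:pos] + next(b for b in "ACGT" if b != s[pos]) + s[pos + 1 :]
            mutated.append((f"m{i}", s2))  # 149/150 = 99.33 -> bin 99
        df = subsample_cross_coverage(
            {"orig": base, "mut": mutated}, n=6, reps=2, seed=2
        )
        at_99 = df[df.identity == 99]
        assert (at_99.mean_hits == 6.0).all()
        assert (df[df.identity != 99].mean_hits == 0.0).all()

    def test_n_too_large_is_fatal(self):
        db = [("a", "ACGT" * 20)]
        with pytest.raises(ValueError, match="fewer than"):
            subsample_cross_coverage({"A": db, "B": db}, n=5, reps=1, seed=0)

    def test_seed_reproducible(self):
        rng = np.random.default_rng(13)
        db_a = [(f"a{i}", "".join(rng.choice(list("ACGT"), 60))) for i in range(8)]
        db_b = [(f"b{i}", "".join(rng.choice(list("ACGT"), 60))) for i in range(8)]
        kw = dict(n=4, reps=2, seed=99)
        df1 = subsample_cross_coverage({"A": db_a, "B": db_b}, **kw)
        df2 = subsample_cross_coverage({"A": db_a, "B": db_b}, **kw)
        assert df1.equals(df2)
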