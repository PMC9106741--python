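import numpy as np
import pytest
import scipy.sparse as sp

from hashladder.hash_io import (
    AMBIGUOUS,
    NO_MATCH,
    HashCountMatrix,
    count_hashes,
    has_trailing_polyA,
    knee_threshold,
    match_barcode,
    read_mtx,
    write_mtx,
)


def levenshtein_dp(a: str, b: str) -> int:
    """Independent dynamic-programming Levenshtein oracle."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


class TestMatchBarcode:
    WL = {"AAAAAAAAAA": "s1", "CCCCCCCCCC": "s2"}

    def test_exact_match(self):
        assert match_barcode("AAAAAAAAAA", self.WL) == "s1"

    def test_distance_two_match(self):
        assert match_barcode("AAAAAAAAGG", self.WL) == "s1"

    def test_symmetric_tie_is_ambiguous(self):
        wl = {"AAAAAAAAAA": "s1", "AAAAAAAAAC": "s2"}
        assert match_barcode("AAAAAAAAAG", wl) == AMBIGUOUS

    def test_out_of_range_is_no_match(self):
        assert match_barcode("GGGGGTTTTT", self.WL) == NO_MATCH

    def test_empty_whitelist_rejected(self):
        with pytest.raises(ValueError):
            match_barcode("AAAAAAAAAA", {})

    def test_agrees_with_dp_oracle_on_random_instances(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            wl_codes = ["".join(rng.choice(bases, 10)) for _ in range(5)]
            wl = {bc: f"s{i}" for i, bc in enumerate(wl_codes)}
            q = "".join(rng.choice(bases, 10))
            dists = {sid: levenshtein_dp(q, bc) for bc, sid in wl.items()}
            dmin = min(dists.values())
            winners = [s for s, d in dists.items() if d == dmin]
            got = match_barcode(q, wl, max_dist=2)
            if dmin > 2:
                assert got == NO_MATCH
            elif len(winners) > 1:
                assert got == AMBIGUOUS
            else:
                assert got == winners[0]


class TestPolyA:
    def test_polya_window_present(self):
        # barcode (10) + spacer base (position 11) + poly(A) at 12-16
        assert has_trailing_polyA("ACGTACGTAC" + "G" + "AAAAA")

    def test_one_mismatch_rejected_by_default(self):
        assert has_trailing_polyA("ACGTACGTACGCAAAAT") is False

    def test_one_mismatch_allowed_when_configured(self):
        assert has_trailing_polyA("ACGTACGTACGCAAAAT", max_mismatch=1) is True

    def test_short_read_is_false(self):
        assert has_trailing_polyA("ACGTACGTACGT") is False


class TestCountHashes:
    WL = {"AAAAAAAAAA": "s1", "CCCCCCCCCC": "s2"}

    @staticmethod
    def read(bc):
        return bc + "C" + "AAAAA"

    def test_umi_collapse(self):
        recs = [
            ("cell1", "UMI1", self.read("AAAAAAAAAA")),
            ("cell1", "UMI1", self.read("AAAAAAAAAA")),
        ]
        m, tally = count_hashes(recs, self.WL)
        assert m.row("cell1").sum() == 1
        assert tally.retained == 2

    def test_distinct_umis_count_separately(self):
        recs = [
            ("cell1", "UMI1", self.read("AAAAAAAAAA")),
            ("cell1", "UMI2", self.read("AAAAAAAAAA")),
        ]
        m, _ = count_hashes(recs, self.WL)
        assert m.row("cell1").sum() == 2

    def test_duplication_rate_ten(self, rng):
        # 100 reads = 10 distinct UMIs x 10 duplicates over 2 cells x 5 UMIs each
        recs = []
        for cell in ("c1", "c2"):
            for u in range(5):
                for _ in range(10):
                    recs.append((cell, f"U{u}", self.read("AAAAAAAAAA")))
        order = rng.permutation(len(recs))
        m, tally = count_hashes([recs[i] for i in order], self.WL)
        assert tally.retained == 100
        assert m.dense().sum() == 10

    def test_rejection_tally(self):
        recs = [
            ("c", "U1", self.read("AAAAAAAAAA")),      # kept
            ("c", "U2", self.read("GGGGGTTTTT")),      # no_match
            ("c", "U3", "AAAAAAAAAA" + "C" + "TTTTT"),  # no polyA
            ("c",),                                     # malformed
        ]
        m, tally = count_hashes(recs, self.WL)
        assert (tally.retained, tally.no_match, tally.no_polyA, tally.malformed) == (
            1, 1, 1, 1,
        )
        assert m.dense().sum() <= len(recs)

    def test_mostly_malformed_raises(self):
        recs = [("c",)] * 3 + [("c", "U1", self.read("AAAAAAAAAA"))]
        with pytest.raises(ValueError, match="malformed"):
            count_hashes(recs, self.WL)

    def test_output_total_bounded_by_input(self, rng):
        bases = np.array(list("ACGT"))
        recs = [
            (f"c{rng.integers(3)}", "".join(rng.choice(bases, 4)), self.read("AAAAAAAAAA"))
            for _ in range(50)
        ]
        m, tally = count_hashes(recs, self.WL)
        assert m.dense().sum() <= 50


class TestKnee:
    def test_bimodal_separation(self, rng):
        cells = rng.poisson(5000, 1000)
        debris = rng.poisson(20, 10000)
        totals = np.concatenate([cells, debris])
        cut = knee_threshold(totals)
        assert 20 < cut < 5000
        assert (cells >= cut).mean() >= 0.99
        assert (debris < cut).mean() >= 0.99

    def test_all_equal_warns_and_returns_total(self):
        with pytest.warns(UserWarning):
            assert knee_threshold([7.0] * 20) == 7.0

    def test_override_respected(self):
        assert knee_threshold([1, 10, 100] * 5, override=42.0) == 42.0

    def test_chord_distance_hand_checked(self):
        # totals 100, 10, 1 -> log10 curve (0,2),(~0.301,1),(~0.477,0);
        # chord from (0,2) to (0.477,0); middle point is farthest
        totals = [100.0, 10.0, 1.0] + [1.0] * 0
        # need >= 10 barcodes: pad with more extreme points keeping shape
        totals = [100.0] * 1 + [10.0] * 1 + [1.0] * 8
        cut = knee_threshold(np.array(totals))
        # the knee must sit at one of the distinct totals
        assert cut in (100.0, 10.0, 1.0)
        # hand check on the 3-point curve: middle point maximizes distance
        x = np.log10(np.arange(1, 11))
        y = np.log10(np.sort(totals)[::-1])
        dx, dy = x[-1] - x[0], y[-1] - y[0]
        dist = np.abs(dy * (x - x[0]) - dx * (y - y[0])) / np.hypot(dx, dy)
        assert cut == np.sort(totals)[::-1][np.argmax(dist)]

    def test_too_few_barcodes_rejected(self):
        with pytest.raises(ValueError):
            knee_threshold([5, 6, 7])


class TestMatrixIO:
    def test_round_trip(self, tmp_path, rng):
        m = sp.random(7, 5, density=0.4, random_state=1, dtype=float).tocsr()
        m.data = np.round(m.data * 10) + 1.0
        m = m.astype(np.int64)
        rows = [f"r{i}" for i in range(7)]
        cols = [f"c{j}" for j in range(5)]
        write_mtx(tmp_path / "t", m, rows, cols)
        back, r2, c2 = read_mtx(tmp_path / "t")
        assert (back != m).nnz == 0
        assert r2 == rows and c2 == cols

    def test_empty_matrix_round_trip(self, tmp_path):
        m = sp.csr_matrix((3, 4), dtype=np.int64)
        write_mtx(tmp_path / "e", m, list("abc"), list("wxyz"))
        back, r, c = read_mtx(tmp_path / "e")
        assert back.shape == (3, 4) and back.nnz == 0

    def test_dims_mismatch_with_names_rejected(self, tmp_path):
        m = sp.csr_matrix(np.eye(3, dtype=np.int64))
        write_mtx(tmp_path / "m", m, list("abc"), list("xyz"))
        with open(tmp_path / "m.rows.txt", "w") as fh:
            fh.write("a\nb\n")
        with pytest.raises(ValueError):
            read_mtx(tmp_path / "m")

    def test_shape_name_mismatch_on_write(self, tmp_path):
        with pytest.raises(ValueError):
            write_mtx(tmp_path / "x", sp.eye(3), list("ab"), list("abc"))


class TestHashCountMatrix:
    def test_duplicate_cells_rejected(self):
        with pytest.raises(ValueError):
            HashCountMatrix(["a", "a"], ["s"], np.zeros((2, 1)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            HashCountMatrix(["a"], ["s"], np.array([[-1]]))

    def test_from_triplets_and_nonzeros(self):
        m = HashCountMatrix.from_triplets([("a", "s1", 2), ("b", "s2", 3)])
        assert set(m.nonzeros()) == {("a", "s1", 2), ("b", "s2", 3)}
        assert m.total_per_cell().tolist() == [2, 3]
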