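import numpy as np
import pandas as pd
import pytest

from lishlnr import codebook as cb, decode as dc
from lishlnr.imgproc import BitVectorTable


def make_records(bits, xy=None):
    n = len(bits)
    if xy is None:
        xy = np.zeros((n, 2))
    pos = pd.DataFrame({"x_um": xy[:, 0], "y_um": xy[:, 1], "n_spots": 4})
    return BitVectorTable(positions=pos, bits=np.asarray(bits, dtype=np.uint8),
                          intensities=np.zeros((n, bits.shape[1] if n else 0)))


class TestDecodeBitvector:
    def test_exact_codeword_distance_zero(self, book24):
        idx, d = dc.decode_bitvector(book24.words[5], book24)
        assert (idx, d) == (5, 0)

    def test_all_zero_vector_unassigned(self, book24):
        idx, d = dc.decode_bitvector(np.zeros(24, dtype=np.uint8), book24)
        assert idx is None and d is None

    def test_length_mismatch_raises(self, book24):
        with pytest.raises(ValueError, match="length"):
            dc.decode_bitvector(np.zeros(16, dtype=np.uint8), book24)

    def test_distance_two_tie_never_assigned(self):
        words = np.array([[1, 1, 0, 0], [0, 0, 1, 1]], dtype=np.uint8)
        book = cb.Codebook(4, 2, 4, words)
        idx, _ = dc.decode_bitvector(np.array([1, 0, 1, 0]), book, max_correctable=2)
        assert idx is None

    def test_single_error_correction_exhaustive(self, book24):
        """Every single-bit flip of every codeword decodes back to it, and
        never to a different codeword (MHD4 guarantee, checked exhaustively)."""
        words = book24.words
        n, nbits = words.shape
        perturbed = np.repeat(words, nbits, axis=0)
        flip = np.tile(np.eye(nbits, dtype=np.uint8), (n, 1))
        perturbed ^= flip
        d = dc._distance_matrix(perturbed, book24)
        dmin = d.min(axis=1)
        unique = (d == dmin[:, None]).sum(axis=1) == 1
        decoded = d.argmin(axis=1)
        expected = np.repeat(np.arange(n), nbits)
        assert dmin.max() == 1
        assert unique.all()
        assert np.array_equal(decoded, expected)


class TestDecodeTable:
    def test_noiseless_identity(self, book24, panel24, standard_run):
        table = standard_run["table"]
        truth = standard_run["truth"]
        assert (table["status"] == "assigned").all()
        got = table["gene"].value_counts().sort_index()
        want = truth["target"].value_counts().sort_index()
        assert got.equals(want)

    def test_empty_records(self, book24, panel24):
        out = dc.decode_table(make_records(np.zeros((0, 24), dtype=np.uint8)),
                              book24, panel24)
        assert out.empty

    def test_permutation_invariance(self, book24, panel24):
        rng = np.random.default_rng(0)
        idx = rng.integers(0, len(book24), size=50)
        bits = book24.words[idx].copy()
        perm = rng.permutation(50)
        t1 = dc.decode_table(make_records(bits), book24, panel24)
        t2 = dc.decode_table(make_records(bits[perm]), book24, panel24)
        assert sorted(t1["gene"]) == sorted(t2["gene"])

    def test_dropout_records_still_decode(self, book24, panel24):
        cw = panel24.target_to_codeword[panel24.target_names[0]]
        bits = book24.words[[cw]].copy()
        bits[0, book24.on_bits(cw)[0]] = 0  # one on-bit dropped
        out = dc.decode_table(make_records(bits), book24, panel24)
        assert out["gene"].iloc[0] == panel24.target_names[0]
        assert out["distance"].iloc[0] == 1


def synthetic_table(genes, statuses):
    return pd.DataFrame({
        "x_um": np.zeros(len(genes)), "y_um": np.zeros(len(genes)),
        "gene": genes, "distance": 0, "status": statuses,
    })


class TestMisID:
    @pytest.fixture()
    def small_book_panel(self):
        book = cb.generate_codebook(10, 4, 4, seed=4)
        panel = cb.assign_targets(book, ["A", "B"], 0.4, seed=5)
        return book, panel

    def test_zero_negative_decodes(self, small_book_panel):
        book, panel = small_book_panel
        table = synthetic_table(["A"] * 10 + ["B"] * 10, ["assigned"] * 20)
        report = dc.estimate_misid(table, book, panel)
        assert report.global_pct == 0.0
        assert report.flagged_genes == []

    def test_equal_rates_give_100_percent(self, small_book_panel):
        book, panel = small_book_panel
        neg_ids = sorted(book.negative_ids)
        genes = ["A"] * 5 + ["B"] * 5 + [f"neg_{i}" for i in neg_ids for _ in range(5)]
        statuses = ["assigned"] * 10 + ["negative"] * (5 * len(neg_ids))
        report = dc.estimate_misid(synthetic_table(genes, statuses), book, panel)
        assert report.global_pct == pytest.approx(100.0)

    def test_misid_rises_with_spurious_rate(self, book24, panel24):
        rng = np.random.default_rng(6)
        cw_ids = np.array([panel24.target_to_codeword[t] for t in panel24.target_names])
        misids = []
        for p_spur in [0.0, 0.01, 0.03]:
            idx = rng.choice(cw_ids, size=3000)
            bits = book24.words[idx].copy()
            flips = (bits == 0) & (rng.random(bits.shape) < p_spur)
            bits ^= flips.astype(np.uint8)
            table = dc.decode_table(make_records(bits), book24, panel24)
            report = dc.estimate_misid(table, book24, panel24)
            misids.append(report.global_pct)
        assert misids[0] <= misids[1] <= misids[2]

    def test_undefined_without_assigned_decodes(self, small_book_panel):
        book, panel = small_book_panel
        table = synthetic_table([], [])
        report = dc.estimate_misid(table, book, panel)
        assert report.global_pct is None
        assert "undefined" in report.summary()


class TestLowPlexColocalization:
    def spec(self, radius=2.0, cells=10):
        return dc.LowPlexPairSpec(
            matched_pairs=[(0, 1, "GAPDH")], mismatched_pairs=[(0, 2, "MM1")],
            coloc_radius_px=radius, cell_count=cells)

    def test_identical_coordinates_all_pair(self):
        xy = np.random.default_rng(0).uniform(0, 100, size=(30, 2))
        spots = {c: pd.DataFrame({"x_px": xy[:, 0], "y_px": xy[:, 1]})
                 for c in (0, 1)}
        out = dc.colocalize_lowplex(spots, self.spec())
        matched = out[out["label"] == "GAPDH"].iloc[0]
        assert matched["count"] == 30
        assert matched["per_cell"] == 3.0

    def test_lone_channel_spot_never_pairs(self):
        spots = {0: pd.DataFrame({"x_px": [10.0], "y_px": [10.0]}),
                 1: pd.DataFrame(columns=["x_px", "y_px"])}
        out = dc.colocalize_lowplex(spots, self.spec())
        assert (out["count"] == 0).all()

    def test_mismatched_pairs_median_zero_on_separated_rcps(self):
        # matched channels colocalize; the mismatch channel is far away
        rng = np.random.default_rng(1)
        per_cell_mm = []
        for s in range(11):
            xy = rng.uniform(0, 500, size=(40, 2))
            far = rng.uniform(1000, 1500, size=(40, 2))
            spots = {0: pd.DataFrame({"x_px": xy[:, 0], "y_px": xy[:, 1]}),
                     1: pd.DataFrame({"x_px": xy[:, 0], "y_px": xy[:, 1]}),
                     2: pd.DataFrame({"x_px": far[:, 0], "y_px": far[:, 1]})}
            out = dc.colocalize_lowplex(spots, self.spec())
            per_cell_mm.append(out[out["kind"] == "mismatched"]["per_cell"].iloc[0])
        assert np.median(per_cell_mm) == 0.0

    def test_chance_pairs_match_poisson_expectation(self):
        # independent uniform channels: E[pairs] ~ lambda1*lambda2*pi*r^2*A
        rng = np.random.default_rng(2)
        area = 500.0 * 500.0
        n1, n2, r = 300, 300, 2.0
        expected = (n1 / area) * (n2 / area) * np.pi * r**2 * area
        counts = []
        for _ in range(30):
            a = rng.uniform(0, 500, size=(n1, 2))
            b = rng.uniform(0, 500, size=(n2, 2))
            spots = {0: pd.DataFrame({"x_px": a[:, 0], "y_px": a[:, 1]}),
                     1: pd.DataFrame({"x_px": b[:, 0], "y_px": b[:, 1]})}
            out = dc.colocalize_lowplex(spots, self.spec(radius=r))
            counts.append(out[out["label"] == "GAPDH"]["count"].iloc[0])
        se = np.std(counts, ddof=1) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - expected) < max(4 * se, 0.5)
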