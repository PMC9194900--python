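"""Loss-run spectra, geometric fits, retention windows and the P-index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import p_index_spreadsheet
from wgdkit import fractionation as fr
from wgdkit.depth_align import ABSENT, AlignmentTable


def table_from_columns(columns: dict[str, list[str]], chrom="c1") -> AlignmentTable:
    """Build a minimal alignment table from raw column cell lists."""
    n = len(next(iter(columns.values())))
    index = [f"r{i}" for i in range(n)]
    data = pd.DataFrame({"chrom": chrom}, index=index)
    data["R.1"] = index
    for name, cells in columns.items():
        data[name] = cells
    return AlignmentTable(ref_name="R", expected=[("R", 1), ("Q", len(columns))],
                         data=data)


def windows_table(a_rates, b_rates):
    rw = fr.RetentionWindows("A", "B", window=100, step=1)
    rw.windows["c1"] = np.column_stack([a_rates, b_rates])
    return rw


class TestLossRuns:
    def test_no_absences_empty_spectrum(self):
        t = table_from_columns({"Q.1": ["g"] * 6})
        assert fr.loss_runs(t, "Q.1").counts == {}

    def test_pattern_counting(self):
        # G . . G . G -> runs {2: 1, 1: 1}
        t = table_from_columns({"Q.1": ["g", ABSENT, ABSENT, "g", ABSENT, "g"]})
        assert fr.loss_runs(t, "Q.1").counts == {2: 1, 1: 1}

    def test_runs_do_not_span_chromosomes(self):
        n = 4
        index = [f"r{i}" for i in range(2 * n)]
        data = pd.DataFrame({"chrom": ["c1"] * n + ["c2"] * n}, index=index)
        data["R.1"] = index
        data["Q.1"] = ["g", "g", ABSENT, ABSENT, ABSENT, "g", "g", "g"]
        t = AlignmentTable("R", [("R", 1), ("Q", 1)], data)
        assert fr.loss_runs(t, "Q.1").counts == {2: 1, 1: 1}


class TestFitGeometric:
    def test_all_singletons_p_one(self):
        sp = fr.RunLengthSpectrum(counts={1: 50})
        fr.fit_geometric(sp)
        assert sp.p_hat == 1.0

    def test_closed_form_mle(self):
        # runs 1,1,2,4: mean 2 -> p_hat = 0.5
        sp = fr.RunLengthSpectrum(counts={1: 2, 2: 1, 4: 1})
        sp.counts = {1: 2 * 5, 2: 1 * 5, 4: 1 * 5}  # n >= 10
        fr.fit_geometric(sp)
        assert sp.p_hat == pytest.approx(0.5)

    def test_insufficient_runs(self):
        with pytest.raises(fr.InsufficientDataError):
            fr.fit_geometric(fr.RunLengthSpectrum(counts={1: 3}))

    def test_recovers_run_p_within_3se(self):
        """MLE over 10,000 simulated geometric runs recovers p within 3 SE."""
        rng = np.random.default_rng(8)
        p = 0.6
        lengths = rng.geometric(p, size=10000)
        counts = dict(zip(*np.unique(lengths, return_counts=True)))
        sp = fr.RunLengthSpectrum(counts={int(k): int(v) for k, v in counts.items()})
        fr.fit_geometric(sp)
        se = p * np.sqrt(1 - p) / np.sqrt(10000)  # asymptotic SE of the MLE
        assert abs(sp.p_hat - p) <= 3 * se
        assert sp.pvalue > 0.01

    def test_deviation_grows_with_run_length_under_mixture(self):
        """Non-geometric (mixture) loss shows residuals growing with length."""
        rng = np.random.default_rng(9)
        lengths = np.concatenate([
            rng.geometric(0.8, size=8000), rng.geometric(0.25, size=2000)
        ])
        counts = dict(zip(*np.unique(lengths, return_counts=True)))
        sp = fr.RunLengthSpectrum(counts={int(k): int(v) for k, v in counts.items()})
        fr.fit_geometric(sp)
        n, p = sp.n_runs, sp.p_hat
        ls = np.array(sorted(sp.counts))
        obs = np.array([sp.counts[int(l)] for l in ls], dtype=float)
        exp = n * p * (1 - p) ** (ls - 1)
        resid = np.abs(obs - exp) / np.sqrt(np.maximum(exp, 1e-9))
        keep = exp >= 1
        slope = np.polyfit(ls[keep], resid[keep], 1)[0]
        assert slope > 0


class TestRetentionWindows:
    def test_fully_retained(self):
        t = table_from_columns({"Q.1": ["g"] * 150, "Q.2": ["g"] * 150})
        rw = fr.retention_windows(t, "Q.1", "Q.2", window=100)
        assert np.all(rw.windows["c1"] == 1.0)
        assert rw.windows["c1"].shape == (51, 2)  # N = span - M + 1

    def test_alternating_half(self):
        cells = ["g", ABSENT] * 100
        t = table_from_columns({"Q.1": cells, "Q.2": cells})
        rw = fr.retention_windows(t, "Q.1", "Q.2", window=100)
        assert np.allclose(rw.windows["c1"], 0.5)

    def test_short_chromosome_skipped(self):
        t = table_from_columns({"Q.1": ["g"] * 50, "Q.2": ["g"] * 50})
        rw = fr.retention_windows(t, "Q.1", "Q.2", window=100)
        assert rw.windows == {} and rw.skipped == ["c1"]

    def test_plot_smoke(self, tmp_path):
        t = table_from_columns({"Q.1": ["g"] * 150, "Q.2": (["g", ABSENT] * 75)})
        rw = fr.retention_windows(t, "Q.1", "Q.2", window=100)
        out = tmp_path / "ret.png"
        fr.retention_plot(rw, str(out))
        assert out.exists()


class TestWindowDifferenceTest:
    def test_identical_columns_fraction_one(self):
        rw = windows_table([0.6] * 50, [0.6] * 50)
        frame = fr.window_difference_test(rw)
        assert frame[frame["chrom"] == "overall"]["fraction_not_different"].iloc[0] == 1.0

    def test_extreme_difference_fraction_zero(self):
        rw = windows_table([1.0] * 50, [0.0] * 50)
        frame = fr.window_difference_test(rw)
        assert frame[frame["chrom"] == "overall"]["fraction_not_different"].iloc[0] == 0.0


class TestPIndex:
    def test_equal_windows_zero(self):
        rw = windows_table([0.5] * 20, [0.5] * 20)
        assert fr.p_index(rw).p_index == 0.0

    def test_uniform_bias_one(self):
        rw = windows_table([0.8] * 20, [0.4] * 20)
        assert fr.p_index(rw).p_index == 1.0

    def test_worked_four_window_example(self):
        a = [0.8, 0.5, 0.6, 0.6]
        b = [0.4, 0.5, 0.7, 0.3]
        rw = windows_table(a, b)
        result = fr.p_index(rw)
        # d = (0.667, 0, 0.154, 0.667); delta = (1, 0, 1, 1)
        # contribution = |+1 - 1 + 1| / 3 = 1/3
        assert result.p_index == pytest.approx(1 / 3)
        assert result.p_index == pytest.approx(
            p_index_spreadsheet({"c1": list(zip(a, b))})
        )

    def test_chromosome_weighting(self):
        rw = fr.RetentionWindows("A", "B", 100, 1)
        rw.windows["c1"] = np.column_stack([[0.8] * 30, [0.4] * 30])  # contributes 1
        rw.windows["c2"] = np.column_stack([[0.5] * 10, [0.5] * 10])  # contributes 0
        result = fr.p_index(rw)
        assert result.p_index == pytest.approx(30 / 40)
        assert result.per_chromosome["weight"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_excluded_flag(self):
        rw = windows_table([0.5] * 15, [0.5] * 15)
        result = fr.p_index(rw)
        assert result.all_excluded and result.p_index == 0.0

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(st.floats(0, 1, allow_nan=False),
                      st.floats(0, 1, allow_nan=False)),
            min_size=1, max_size=60,
        )
    )
    def test_bounded_and_label_symmetric(self, pairs):
        """P-index stays in [0, 1] and is invariant to swapping A and B."""
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        r1 = fr.p_index(windows_table(a, b))
        assert 0.0 <= r1.p_index <= 1.0
        r2 = fr.p_index(windows_table(b, a))
        assert r1.p_index == pytest.approx(r2.p_index, abs=1e-12)
        assert r1.per_chromosome["signed_sum"].iloc[0] == pytest.approx(
            -r2.per_chromosome["signed_sum"].iloc[0], abs=1e-12
        )

    @settings(max_examples=100, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_spreadsheet_oracle_on_random_windows(self, seed):
        rng = np.random.default_rng(seed)
        by_chrom = {}
        raw = {}
        for c in range(rng.integers(1, 4)):
            n = int(rng.integers(1, 40))
            a = rng.random(n)
            b = rng.random(n)
            by_chrom[f"c{c}"] = np.column_stack([a, b])
            raw[f"c{c}"] = list(zip(a, b))
        rw = fr.RetentionWindows("A", "B", 100, 1)
        rw.windows = by_chrom
        assert fr.p_index(rw).p_index == pytest.approx(p_index_spreadsheet(raw))

    def test_plot_smoke(self, tmp_path):
        sp = fr.RunLengthSpectrum(counts={1: 60, 2: 25, 3: 10, 4: 5})
        fr.fit_geometric(sp)
        out = tmp_path / "runs.png"
        fr.loss_run_plot({"q": sp}, str(out))
        assert out.exists()
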