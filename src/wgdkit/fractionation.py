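"""Post-WGD gene loss and retention statistics, and the P-index.

Fractionation - the loss of duplicated genes after polyploidy - proceeds in
runs of consecutive genes whose lengths are approximately geometric.  This
module extracts loss-run spectra from alignment-table columns, fits the
geometric law by maximum likelihood with a chi-square goodness of fit,
computes sliding-window gene retention rates along the reference order for a
pair of homoeologous subgenome columns, tests windows for retention
differences, and aggregates them into the P-index: a [0, 1] statistic of
fractionation asymmetry between subgenomes.  Values above 0.3 diagnose
allopolyploidy (divergent parental subgenomes fractionate unequally); values
near 0 indicate autopolyploid-like balanced loss.

P-index definition (per homoeologous chromosome pair C of the reference, with
window retention rates A_i, B_i):

    d_i     = |A_i - B_i| / (0.5 (A_i + B_i))      (0 when A_i = B_i = 0)
    delta_i = 1 if 0.1 < d_i < 3 else 0            (inclusion coefficient)
    contribution_C = | sum_i sign(A_i - B_i) delta_i | / (number included)
    W_C     = N_C / sum_c N_c
    P-index = sum_C W_C * contribution_C

The denominator of a chromosome's contribution is the count of included
windows, which makes each contribution a mean sign in [-1, 1] and bounds the
P-index in [0, 1]; windows with A_i = B_i are always excluded, so the sign is
always defined.  Note d_i <= 2 by construction, so the printed upper cutoff
of 3 never binds; it is kept as stated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from wgdkit.depth_align import ABSENT, AlignmentTable

DEFAULT_WINDOW = 100
DEFAULT_STEP = 1
DELTA_LOW = 0.1
DELTA_HIGH = 3.0
P_INDEX_THRESHOLD = 0.3


class InsufficientDataError(ValueError):
    pass


# ---------------------------------------------------------------------------
# loss runs and geometric fits
# ---------------------------------------------------------------------------


@dataclass
class RunLengthSpectrum:
    """Counts of maximal loss runs by length, with an optional geometric fit."""

    counts: dict[int, int]
    p_hat: float | None = None
    chi2: float | None = None
    pvalue: float | None = None
    dof: int | None = None

    @property
    def n_runs(self) -> int:
        return sum(self.counts.values())

    @property
    def n_lost(self) -> int:
        return sum(length * c for length, c in self.counts.items())

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.counts.items())
        return pd.DataFrame(rows, columns=["run_length", "n_runs"])


def loss_runs(table: AlignmentTable, column: str) -> RunLengthSpectrum:
    """Maximal runs of absence marks in one table column, along ref order.

    Runs do not span reference chromosome boundaries.
    """
    counts: dict[int, int] = {}
    col = table.data[column]
    for _, sub in table.data.groupby("chrom", sort=True):
        absent = (col.loc[sub.index] == ABSENT).to_numpy()
        run = 0
        for a in absent:
            if a:
                run += 1
            elif run:
                counts[run] = counts.get(run, 0) + 1
                run = 0
        if run:
            counts[run] = counts.get(run, 0) + 1
    return RunLengthSpectrum(counts=counts)


def fit_geometric(spectrum: RunLengthSpectrum, min_expected: float = 5.0) -> RunLengthSpectrum:
    """Geometric MLE and chi-square goodness of fit on a run-length spectrum.

    Support starts at L = 1 (a single lost gene is a run), so the MLE is
    p_hat = n_runs / total lost genes (1 / mean run length).  Expected counts
    n * p * (1-p)^(L-1) are pooled from the tail until each cell has
    ``min_expected``; dof = cells - 2 (one estimated parameter).
    """
    n = spectrum.n_runs
    if n < 10:
        raise InsufficientDataError(f"need >= 10 runs to fit, got {n}")
    total = spectrum.n_lost
    p_hat = n / total
    spectrum.p_hat = float(p_hat)
    if p_hat >= 1.0:  # all runs length 1: perfect fit, nothing to test
        spectrum.chi2, spectrum.pvalue, spectrum.dof = 0.0, 1.0, 0
        return spectrum

    max_len = max(spectrum.counts)
    observed = np.array([spectrum.counts.get(length, 0) for length in range(1, max_len + 1)],
                        dtype=float)
    expected = n * p_hat * (1 - p_hat) ** np.arange(max_len)
    expected[-1] += n * (1 - p_hat) ** max_len  # fold the infinite tail in

    # pool cells from the tail until every cell has min_expected
    obs_cells, exp_cells = [], []
    acc_o = acc_e = 0.0
    for o, e in zip(observed, expected):
        acc_o += o
        acc_e += e
        if acc_e >= min_expected:
            obs_cells.append(acc_o)
            exp_cells.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and exp_cells:
        obs_cells[-1] += acc_o
        exp_cells[-1] += acc_e
    if len(exp_cells) < 3:
        spectrum.chi2, spectrum.pvalue, spectrum.dof = 0.0, 1.0, 0
        return spectrum
    obs_arr, exp_arr = np.array(obs_cells), np.array(exp_cells)
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    chi2, _ = stats.chisquare(obs_arr, exp_arr)
    dof = len(obs_cells) - 2
    spectrum.chi2 = float(chi2)
    spectrum.dof = dof
    spectrum.pvalue = float(stats.chi2.sf(chi2, dof))
    return spectrum


# ---------------------------------------------------------------------------
# retention windows
# ---------------------------------------------------------------------------


@dataclass
class RetentionWindows:
    """Sliding-window retention rates of two homoeologous columns vs reference.

    ``windows[chrom]`` is an (N_C, 2) array of per-window retention rates
    (columns A and B) with windows of ``window`` genes sliding by ``step``
    along the reference gene order of that chromosome.
    """

    column_a: str
    column_b: str
    window: int
    step: int
    windows: dict[str, np.ndarray] = field(default_factory=dict)
    skipped: list[str] = field(default_factory=list)

    @property
    def n_windows(self) -> int:
        return sum(len(w) for w in self.windows.values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, arr in self.windows.items():
            for i, (a, b) in enumerate(arr):
                rows.append((chrom, i * self.step, a, b))
        return pd.DataFrame(rows, columns=["chrom", "window_start", "A", "B"])


def retention_windows(
    table: AlignmentTable,
    column_a: str,
    column_b: str,
    window: int = DEFAULT_WINDOW,
    step: int = DEFAULT_STEP,
) -> RetentionWindows:
    """Per-window retention of two subgenome columns along the reference.

    A window covers ``window`` consecutive reference genes; its retention is
    the fraction of those positions whose cell is not the absence mark.
    Chromosomes shorter than one window are skipped with a warning.
    """
    import logging

    out = RetentionWindows(column_a, column_b, window, step)
    for chrom, sub in table.data.groupby("chrom", sort=True):
        present = np.stack(
            [(sub[column_a] != ABSENT).to_numpy(), (sub[column_b] != ABSENT).to_numpy()],
            axis=1,
        ).astype(float)
        n = len(present)
        if n < window:
            out.skipped.append(chrom)
            logging.getLogger(__name__).warning(
                "chromosome %s span %d < window %d: skipped", chrom, n, window
            )
            continue
        csum = np.vstack([np.zeros((1, 2)), np.cumsum(present, axis=0)])
        starts = np.arange(0, n - window + 1, step)
        rates = (csum[starts + window] - csum[starts]) / window
        out.windows[chrom] = rates
    return out


def window_difference_test(
    rw: RetentionWindows, delta: float = 0.05, alpha: float = 0.05
) -> pd.DataFrame:
    """Fraction of windows with no significant retention difference.

    A window is "not significantly different" when |A - B| < delta OR a
    two-proportion chi-square test on the retained counts (window * A vs
    window * B successes out of window) is not significant at ``alpha``.
    Returns one row per chromosome plus an 'overall' row.
    """
    rows = []
    tot_same = tot_n = 0
    for chrom, arr in sorted(rw.windows.items()):
        a, b = arr[:, 0], arr[:, 1]
        small = np.abs(a - b) < delta
        ka = np.round(a * rw.window).astype(int)
        kb = np.round(b * rw.window).astype(int)
        pvals = np.array([_two_proportion_p(x, y, rw.window) for x, y in zip(ka, kb)])
        same = small | (pvals >= alpha)
        rows.append((chrom, len(arr), float(same.mean())))
        tot_same += int(same.sum())
        tot_n += len(arr)
    rows.append(("overall", tot_n, tot_same / tot_n if tot_n else float("nan")))
    return pd.DataFrame(rows, columns=["chrom", "n_windows", "fraction_not_different"])


def _two_proportion_p(k1: int, k2: int, n: int) -> float:
    if k1 == k2:
        return 1.0
    tbl = np.array([[k1, n - k1], [k2, n - k2]])
    if (tbl.sum(axis=0) == 0).any():
        return 1.0
    _, p, _, _ = stats.chi2_contingency(tbl, correction=True)
    return float(p)


# ---------------------------------------------------------------------------
# P-index
# ---------------------------------------------------------------------------


@dataclass
class PIndexResult:
    """The P-index with its per-chromosome decomposition."""

    p_index: float
    per_chromosome: pd.DataFrame  # chrom, n_windows, weight, included, signed_sum, contribution
    low: float = DELTA_LOW
    high: float = DELTA_HIGH
    all_excluded: bool = False

    def is_allopolyploid(self, threshold: float = P_INDEX_THRESHOLD) -> bool:
        return self.p_index > threshold


def p_index(
    rw: RetentionWindows, low: float = DELTA_LOW, high: float = DELTA_HIGH
) -> PIndexResult:
    """The polyploidy index over all homoeologous chromosome pairs.

    See the module docstring for the formula.  Returns 0 (with a flag) when
    every window is excluded by the d_i thresholds.
    """
    if rw.n_windows == 0:
        raise InsufficientDataError("no retention windows")
    total_windows = rw.n_windows
    rows = []
    p = 0.0
    any_included = False
    for chrom, arr in sorted(rw.windows.items()):
        a, b = arr[:, 0], arr[:, 1]
        mean = 0.5 * (a + b)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(mean > 0, np.abs(a - b) / mean, 0.0)
        delta = (d > low) & (d < high)
        n_inc = int(delta.sum())
        signed = float(np.sign(a - b)[delta].sum())
        contribution = abs(signed) / n_inc if n_inc else 0.0
        weight = len(arr) / total_windows
        p += weight * contribution
        any_included = any_included or n_inc > 0
        rows.append((chrom, len(arr), weight, n_inc, signed, contribution))
    frame = pd.DataFrame(
        rows, columns=["chrom", "n_windows", "weight", "included", "signed_sum",
                       "contribution"],
    )
    result = PIndexResult(p_index=float(p), per_chromosome=frame, low=low, high=high,
                          all_excluded=not any_included)
    if result.all_excluded:
        import logging

        logging.getLogger(__name__).warning("all windows excluded by d thresholds")
    return result


def p_index_report(result: PIndexResult) -> pd.DataFrame:
    frame = result.per_chromosome.copy()
    frame.loc[len(frame)] = ["P-index", result.per_chromosome["n_windows"].sum(),
                             1.0, result.per_chromosome["included"].sum(),
                             float("nan"), result.p_index]
    return frame


def loss_run_plot(spectra: dict[str, RunLengthSpectrum], path: str) -> None:
    """Observed run-length counts with fitted geometric curves."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, sp in spectra.items():
        frame = sp.to_frame()
        (line,) = ax.plot(frame["run_length"], frame["n_runs"], "o", ms=3, label=label)
        if sp.p_hat:
            lengths = np.arange(1, max(sp.counts) + 1)
            ax.plot(lengths, sp.n_runs * sp.p_hat * (1 - sp.p_hat) ** (lengths - 1),
                    "-", lw=1, color=line.get_color())
    ax.set_yscale("log")
    ax.set_xlabel("continuously missing genes")
    ax.set_ylabel("runs")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def retention_plot(rw: RetentionWindows, path: str) -> None:
    """Two retention lines per chromosome along the reference order."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    chroms = sorted(rw.windows)
    fig, axes = plt.subplots(len(chroms), 1, figsize=(8, 2 * max(len(chroms), 1)),
                             squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        arr = rw.windows[chrom]
        x = np.arange(len(arr)) * rw.step
        ax.plot(x, arr[:, 0], c="crimson", lw=0.8, label=rw.column_a)
        ax.plot(x, arr[:, 1], c="navy", lw=0.8, label=rw.column_b)
        ax.set_ylim(0, 1)
        ax.set_ylabel(chrom, fontsize=7)
        ax.legend(fontsize=6)
    axes[-1, 0].set_xlabel("window start (genes)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
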