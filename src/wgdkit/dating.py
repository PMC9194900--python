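"""Ks-peak decomposition, lineage-rate correction and event dating.

A Ks sample (anchor-pair Ks values of colinear blocks) is decomposed into a
weighted sum of normal components by EM; component means are the Ks peaks of
polyploidization or speciation events, with the component sigma reported as
the "+/-" spread.  Because lineages evolve at divergent rates, peaks of one
shared (same-age) event observed in different lineages differ; multiplicative
per-lineage coefficients anchored to a shared benchmark event rescale every
peak to the reference lineage's clock.  A corrected peak is converted to an
age interval by linear scaling against a single calibrated event (e.g. the
core-eudicot hexaploidy at 115-130 Mya).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_FIT_DOMAIN = (0.02, 2.0)


class InsufficientDataError(ValueError):
    pass


class ConvergenceError(RuntimeError):
    pass


@dataclass(frozen=True)
class MixtureComponent:
    weight: float
    mean: float
    sd: float


@dataclass
class KsMixtureModel:
    """Weighted normal components fitted to a Ks sample; peaks = events."""

    components: list[MixtureComponent]
    domain: tuple[float, float]
    n: int
    bandwidth: float
    log_likelihood: float
    bic: float

    @property
    def peaks(self) -> list[float]:
        """Component means sorted ascending."""
        return sorted(c.mean for c in self.components)

    def summary_frame(self):
        import pandas as pd

        comps = sorted(self.components, key=lambda c: c.mean)
        return pd.DataFrame(
            [(i + 1, c.weight, c.mean, c.sd, self.n) for i, c in enumerate(comps)],
            columns=["component", "weight", "mean", "sd", "n"],
        )


@dataclass
class RateCorrection:
    """Per-lineage multiplicative clock coefficients, anchored to a benchmark.

    ``coefficients[lineage]`` rescales that lineage's Ks onto the reference
    lineage's clock; the reference has coefficient exactly 1.
    """

    reference: str
    benchmark: str
    coefficients: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients[self.reference] = 1.0
        if any(v <= 0 for v in self.coefficients.values()):
            raise ValueError("rate coefficients must be positive")


@dataclass(frozen=True)
class EventCalibration:
    """A calibrated event: its corrected Ks peak and age interval in Mya."""

    event: str
    ks_peak: float
    age_lo: float
    age_hi: float

    def __post_init__(self):
        if self.ks_peak <= 0:
            raise ValueError("calibration Ks peak must be positive")
        if not (0 < self.age_lo <= self.age_hi):
            raise ValueError("need 0 < age_lo <= age_hi")


# ---------------------------------------------------------------------------
# peak finding and mixture fitting
# ---------------------------------------------------------------------------


def _clean_sample(ks_sample, domain) -> np.ndarray:
    x = np.asarray(ks_sample, dtype=float)
    x = x[np.isfinite(x)]
    if (x < 0).any():
        raise ValueError("Ks values must be >= 0")
    return x[(x > domain[0]) & (x <= domain[1])]


def kde_peaks(
    ks_sample,
    bandwidth="auto",
    domain: tuple[float, float] = DEFAULT_FIT_DOMAIN,
    grid_size: int = 1024,
) -> list[float]:
    """Modes of a Gaussian kernel density of the Ks sample, sorted ascending.

    ``bandwidth='auto'`` uses Silverman's rule.  Requires n >= 30 values in
    the fit domain; a degenerate (constant) sample is rejected.
    """
    from scipy.stats import gaussian_kde

    x = _clean_sample(ks_sample, domain)
    if len(x) < 30:
        raise InsufficientDataError(f"need >= 30 Ks values in domain, got {len(x)}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all Ks values identical")
    bw = None if bandwidth == "auto" else bandwidth / x.std(ddof=1)
    kde = gaussian_kde(x, bw_method=bw)
    grid = np.linspace(domain[0], domain[1], grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    return [float(g) for g in grid[1:-1][interior]]


def fit_mixture(
    ks_sample,
    k="auto",
    seed: int = 0,
    domain: tuple[float, float] = DEFAULT_FIT_DOMAIN,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> KsMixtureModel:
    """EM fit of a k-component normal mixture to the Ks sample.

    The sample is restricted to the fit domain (defaults exclude allelic
    noise below 0.02 and saturation above 2.0).  ``k='auto'`` selects the
    component count by BIC over 1..5.  Initial means come from the kernel
    density modes, so the fit is deterministic given the seed.
    """
    from sklearn.mixture import GaussianMixture

    x = _clean_sample(ks_sample, domain)
    if len(x) < 50:
        raise InsufficientDataError(f"need >= 50 Ks values in domain, got {len(x)}")
    try:
        modes = kde_peaks(x, domain=domain)
    except (InsufficientDataError, ValueError):
        modes = []
    sil = 1.06 * x.std(ddof=1) * len(x) ** (-1 / 5)

    ks_to_try = range(1, 6) if k == "auto" else [int(k)]
    best = None
    X = x.reshape(-1, 1)
    for kk in ks_to_try:
        if kk < 1:
            raise ValueError("k must be >= 1")
        if modes and len(modes) >= kk:
            init = np.array(sorted(modes, key=lambda m: -_mode_height(x, m, sil))[:kk])
            init = np.sort(init).reshape(-1, 1)
        else:
            init = np.quantile(x, np.linspace(0.1, 0.9, kk)).reshape(-1, 1)
        gm = GaussianMixture(
            n_components=kk,
            covariance_type="full",
            means_init=init,
            max_iter=max_iter,
            tol=tol,
            random_state=seed,
            n_init=1,
        )
        gm.fit(X)
        if not gm.converged_:
            if k != "auto":
                raise ConvergenceError(
                    f"EM did not converge in {max_iter} iterations "
                    f"(k={kk}, n={len(x)}, ll={gm.lower_bound_:.4f})"
                )
            continue
        bic = gm.bic(X)
        if best is None or bic < best[0]:
            best = (bic, gm)
    if best is None:
        raise ConvergenceError("EM did not converge for any component count")
    bic, gm = best
    comps = [
        MixtureComponent(float(w), float(m[0]), float(np.sqrt(c[0, 0])))
        for w, m, c in zip(gm.weights_, gm.means_, gm.covariances_)
    ]
    comps.sort(key=lambda c: c.mean)
    return KsMixtureModel(
        components=comps,
        domain=domain,
        n=len(x),
        bandwidth=float(sil),
        log_likelihood=float(gm.lower_bound_ * len(x)),
        bic=float(bic),
    )


def _mode_height(x: np.ndarray, mode: float, bw: float) -> float:
    return float(np.exp(-0.5 * ((x - mode) / max(bw, 1e-9)) ** 2).sum())


# ---------------------------------------------------------------------------
# rate correction and dating
# ---------------------------------------------------------------------------


def estimate_correction(
    peaks: dict[str, float], reference: str, benchmark: str = "shared"
) -> RateCorrection:
    """Estimate lineage coefficients from one shared event's observed peaks.

    ``peaks[lineage]`` is the Ks peak the shared (same-age) benchmark event
    shows in that lineage; the coefficient is mu_ref / mu_lineage, so slower
    lineages (smaller observed peak) get coefficients > 1.
    """
    if reference not in peaks:
        raise ValueError(f"reference lineage {reference!r} not among peaks")
    if any(p <= 0 for p in peaks.values()):
        raise ValueError("peaks must be positive")
    mu_ref = peaks[reference]
    coeff = {lin: mu_ref / mu for lin, mu in peaks.items()}
    return RateCorrection(reference=reference, benchmark=benchmark, coefficients=coeff)


def apply_correction(ks: float, lineages, corr: RateCorrection) -> float:
    """Rescale a Ks value onto the reference clock.

    For a within-genome peak pass one lineage (ks' = lambda_i * ks); for a
    cross-genome peak pass both (ks' = ks * (lambda_i + lambda_j) / 2 - each
    lineage contributes half of the divergence path).
    """
    if isinstance(lineages, str):
        lineages = [lineages]
    lams = []
    for lin in lineages:
        if lin not in corr.coefficients:
            raise ValueError(f"no rate coefficient for lineage {lin!r}")
        lams.append(corr.coefficients[lin])
    if len(lams) == 1:
        return ks * lams[0]
    if len(lams) == 2:
        return ks * (lams[0] + lams[1]) / 2.0
    raise ValueError("pass one or two lineages")


def date_event(ks_corrected: float, cal: EventCalibration) -> tuple[int, int]:
    """Convert a corrected Ks peak to an age interval in Mya.

    Linear scaling against the calibration: t = ks / ks_cal * [T_lo, T_hi],
    bounds rounded to the nearest integer Myr.
    """
    if ks_corrected <= 0:
        raise ValueError("corrected Ks must be positive")
    lo = int(round(ks_corrected / cal.ks_peak * cal.age_lo))
    hi = int(round(ks_corrected / cal.ks_peak * cal.age_hi))
    return lo, hi


def dating_report(events: dict[str, float], cal: EventCalibration):
    """Dating TSV frame: event, corrected ks, age bounds."""
    import pandas as pd

    rows = []
    for name, ks in events.items():
        lo, hi = date_event(ks, cal)
        rows.append((name, ks, lo, hi))
    return pd.DataFrame(rows, columns=["event", "ks_corrected", "age_lo_mya", "age_hi_mya"])


def ks_density_plot(samples: dict[str, list], path: str, mixtures=None, domain=DEFAULT_FIT_DOMAIN):
    """Overlaid Ks kernel densities per comparison, with fitted peak markers."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    fig, ax = plt.subplots(figsize=(7, 4))
    for label, sample in samples.items():
        x = _clean_sample(sample, domain)
        if len(x) < 30:
            continue
        grid = np.linspace(domain[0], domain[1], 512)
        ax.plot(grid, gaussian_kde(x)(grid), label=label, lw=1.2)
        if mixtures and label in mixtures:
            for peak in mixtures[label].peaks:
                ax.axvline(peak, ls="--", lw=0.6, c="0.5")
    ax.set_xlabel("Ks")
    ax.set_ylabel("density")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
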