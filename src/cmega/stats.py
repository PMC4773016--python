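"""Ensemble summaries, hybrid-vs-exact comparison metrics, and recovery of
the hidden-species mean from the simulated sub-network.

The comparison convention: for each recorded species and grid time the two
ensembles' means are compared through the z-score
``(mean_A - mean_B) / sqrt(SE_A^2 + SE_B^2)`` with ``SE = std/sqrt(N)``;
standard deviations are compared the same way with the standard error of
the sample standard deviation obtained from the fourth central moment
(delta method), which stays honest for the strongly non-normal indicator
and copy-number distributions produced here.  Histograms of integer counts
use unit bins and a two-sample chi-square with small-expectation bins
pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import expm
from scipy.stats import chi2 as chi2_dist


@dataclass
class EnsembleResult:
    """Raw ensemble recording: array (n_runs, n_times, n_columns)."""

    grid: np.ndarray
    states: np.ndarray
    columns: List[str]
    model: str = ""
    method: str = ""
    seed: object = None
    counters: Optional[Dict[str, int]] = None

    def column(self, name: str) -> np.ndarray:
        return self.states[:, :, self.columns.index(name)]

    @property
    def n_runs(self) -> int:
        return self.states.shape[0]


@dataclass
class EnsembleSummary:
    """Pointwise moments of an ensemble plus optional count histograms.

    ``std`` uses the population convention (ddof=0), recorded in
    ``meta['std_convention']``.  ``m4`` is the fourth central moment,
    carried so that comparisons can attach a standard error to ``std``.
    Histograms are unit-bin probability tables at named times.
    """

    grid: np.ndarray
    columns: List[str]
    mean: np.ndarray  # (T, C)
    std: np.ndarray
    m4: np.ndarray
    n_runs: int
    seed: object = None
    histograms: Dict[float, Dict[str, np.ndarray]] = field(default_factory=dict)
    meta: Dict[str, str] = field(default_factory=dict)
    binary: List[bool] = field(default_factory=list)

    def series(self, name: str, which: str = "mean") -> np.ndarray:
        return getattr(self, which)[:, self.columns.index(name)]

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.grid}
        for j, c in enumerate(self.columns):
            data[f"mean_{c}"] = self.mean[:, j]
            data[f"std_{c}"] = self.std[:, j]
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def write_histograms(self, path_pattern: str) -> None:
        """Write one TSV per (time, column): columns value, probability."""
        for t, hists in self.histograms.items():
            for col, (values, probs) in hists.items():
                frame = pd.DataFrame({"value": values, "probability": probs})
                frame.to_csv(
                    path_pattern.format(time=f"{t:g}", column=col),
                    sep="\t",
                    index=False,
                )


def summarize(
    ensemble: EnsembleResult,
    histogram_times: Sequence[float] = (),
    histogram_columns: Sequence[str] | None = None,
) -> EnsembleSummary:
    """Pointwise mean/std (population convention) and unit-bin histograms."""
    x = ensemble.states
    if x.shape[0] < 2:
        raise ValueError("an ensemble needs at least two realizations")
    mean = x.mean(axis=0)
    centred = x - mean
    std = np.sqrt((centred**2).mean(axis=0))
    m4 = (centred**4).mean(axis=0)
    hists: Dict[float, Dict[str, np.ndarray]] = {}
    cols = list(histogram_columns or [])
    for t in histogram_times:
        ti = int(np.argmin(np.abs(ensemble.grid - t)))
        at_t: Dict[str, np.ndarray] = {}
        for c in cols:
            vals = ensemble.column(c)[:, ti]
            lo, hi = int(vals.min()), int(vals.max())
            edges = np.arange(lo, hi + 2)
            counts, _ = np.histogram(vals, bins=edges)
            at_t[c] = (edges[:-1], counts / counts.sum())
        hists[float(ensemble.grid[ti])] = at_t
    binary = [
        bool(np.isin(x[:, :, j], (0.0, 1.0)).all()) for j in range(x.shape[2])
    ]
    return EnsembleSummary(
        grid=ensemble.grid.copy(),
        columns=list(ensemble.columns),
        mean=mean,
        std=std,
        m4=m4,
        n_runs=x.shape[0],
        seed=ensemble.seed,
        histograms=hists,
        meta={"std_convention": "population (ddof=0)"},
        binary=binary,
    )


def _std_se(std: np.ndarray, m4: np.ndarray, n: int) -> np.ndarray:
    """Delta-method standard error of the sample std from the fourth
    central moment; zero-variance points get SE 0."""
    var_s2 = np.clip(m4 - std**4 * (n - 3) / max(n - 1, 1), 0.0, None) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(std > 0, np.sqrt(var_s2) / (2 * np.maximum(std, 1e-300)), 0.0)
    return se


def _zscores(a, se_a, b, se_b):
    denom = np.sqrt(se_a**2 + se_b**2)
    diff = a - b
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(denom > 0, diff / np.maximum(denom, 1e-300), np.where(diff == 0, 0.0, np.inf))
    return z


def two_sample_chi2(counts_a: np.ndarray, counts_b: np.ndarray, min_expected: float = 5.0):
    """Two-sample chi-square on unit-bin count histograms.

    Adjacent bins are pooled until every pooled bin has at least
    ``min_expected`` combined counts.  Returns (statistic, dof, p).
    """
    counts_a = np.asarray(counts_a, dtype=float)
    counts_b = np.asarray(counts_b, dtype=float)
    pooled_a, pooled_b = [], []
    acc_a = acc_b = 0.0
    for ca, cb in zip(counts_a, counts_b):
        acc_a += ca
        acc_b += cb
        if acc_a + acc_b >= min_expected:
            pooled_a.append(acc_a)
            pooled_b.append(acc_b)
            acc_a = acc_b = 0.0
    if acc_a + acc_b > 0:
        if pooled_a:
            pooled_a[-1] += acc_a
            pooled_b[-1] += acc_b
        else:
            pooled_a, pooled_b = [acc_a], [acc_b]
    oa = np.asarray(pooled_a)
    ob = np.asarray(pooled_b)
    na, nb = oa.sum(), ob.sum()
    k1 = np.sqrt(nb / na)
    k2 = np.sqrt(na / nb)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = (k1 * oa - k2 * ob) ** 2 / (oa + ob)
    stat = float(np.nansum(terms))
    dof = max(len(oa) - 1, 1)
    return stat, dof, float(chi2_dist.sf(stat, dof))


@dataclass
class ComparisonReport:
    """Deterministic report of an A-vs-B ensemble comparison."""

    columns: List[str]
    grid: np.ndarray
    z_mean: np.ndarray  # (T, C)
    z_std: np.ndarray
    chi2: pd.DataFrame
    n_a: int
    n_b: int

    @property
    def max_abs_z(self) -> float:
        worst = float(np.nanmax(np.abs(self.z_mean)))
        if not np.isnan(self.z_std).all():
            worst = max(worst, float(np.nanmax(np.abs(self.z_std))))
        return worst

    def to_frame(self) -> pd.DataFrame:
        data = {"time": self.grid}
        for j, c in enumerate(self.columns):
            data[f"z_mean_{c}"] = self.z_mean[:, j]
            data[f"z_std_{c}"] = self.z_std[:, j]
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compare_ensembles(
    a: EnsembleSummary,
    b: EnsembleSummary,
    columns: Sequence[str] | None = None,
    min_count_for_std: int = 10,
) -> ComparisonReport:
    """Per-time z-scores of means and stds plus chi-square on shared
    histograms.

    For 0/1-valued columns (promoter indicators) the std is a deterministic
    function of the occupancy fraction and its delta-method standard error
    is only trustworthy when both occupancy counts are away from the
    boundary; std comparisons with fewer than ``min_count_for_std``
    occupied or unoccupied runs in either ensemble are masked to NaN (a
    calibration rule: two independent exact-SSA ensembles routinely breach
    any fixed band at such points).

    The z-band interpretation also carries a multiplicity caveat: with many
    correlated grid points a rare |z| slightly above 3 is expected even for
    identical processes.
    """
    if len(a.grid) != len(b.grid) or not np.allclose(a.grid, b.grid):
        raise ValueError("ensembles must share the recording grid")
    cols = list(columns) if columns else [c for c in a.columns if c in b.columns]
    ja = [a.columns.index(c) for c in cols]
    jb = [b.columns.index(c) for c in cols]
    mean_a, mean_b = a.mean[:, ja], b.mean[:, jb]
    std_a, std_b = a.std[:, ja], b.std[:, jb]
    se_ma = std_a / np.sqrt(a.n_runs)
    se_mb = std_b / np.sqrt(b.n_runs)
    z_mean = _zscores(mean_a, se_ma, mean_b, se_mb)
    z_std = _zscores(
        std_a,
        _std_se(std_a, a.m4[:, ja], a.n_runs),
        std_b,
        _std_se(std_b, b.m4[:, jb], b.n_runs),
    )
    for c_idx, (ca, cb) in enumerate(zip(ja, jb)):
        if a.binary and a.binary[ca] and b.binary and b.binary[cb]:
            occ_a = mean_a[:, c_idx] * a.n_runs
            occ_b = mean_b[:, c_idx] * b.n_runs
            ok = (
                (np.minimum(occ_a, a.n_runs - occ_a) >= min_count_for_std)
                & (np.minimum(occ_b, b.n_runs - occ_b) >= min_count_for_std)
            )
            z_std[~ok, c_idx] = np.nan
    rows = []
    for t in sorted(set(a.histograms) & set(b.histograms)):
        for c in set(a.histograms[t]) & set(b.histograms[t]):
            va, pa = a.histograms[t][c]
            vb, pb = b.histograms[t][c]
            lo = int(min(va.min(), vb.min()))
            hi = int(max(va.max(), vb.max()))
            grid_vals = np.arange(lo, hi + 1)
            ca = np.zeros(len(grid_vals))
            cb = np.zeros(len(grid_vals))
            ca[np.searchsorted(grid_vals, va)] = pa * a.n_runs
            cb[np.searchsorted(grid_vals, vb)] = pb * b.n_runs
            stat, dof, p = two_sample_chi2(ca, cb)
            rows.append({"time": t, "column": c, "chi2": stat, "dof": dof, "p": p})
    chi2_frame = pd.DataFrame(rows, columns=["time", "column", "chi2", "dof", "p"])
    return ComparisonReport(cols, a.grid.copy(), z_mean, z_std, chi2_frame,
                            a.n_runs, b.n_runs)


# ---------------------------------------------------------------------------
# Hidden-species mean recovery
# ---------------------------------------------------------------------------


def recover_hidden_mean(
    t_grid: np.ndarray,
    m_mean: np.ndarray,
    params: Dict[str, float],
    model: str = "switch",
    n0: Sequence[float] | float = 0.0,
    d: int | None = None,
) -> np.ndarray:
    """Mean trajectory of the hidden species driven by the recovered mRNA
    mean.

    Solves ``dn/dt = K*m(t) - q*n`` (switch) or the conversion-cascade
    chain (Griffith) with ``m(t)`` piecewise linear between grid points;
    each step is advanced exactly with an augmented matrix exponential, so
    the map from ``m_mean`` to the result is linear (superposition holds
    to rounding).

    Returns shape (T,) for the switch and (T, d) for the cascade.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    m_mean = np.asarray(m_mean, dtype=float)
    if t_grid.shape != m_mean.shape:
        raise ValueError("t_grid and m_mean must align")
    K, q = params["K"], params["q"]
    if model == "switch":
        A = np.array([[-q]])
        drive = np.array([K])
        dim = 1
    elif model == "griffith":
        dim = int(d if d is not None else params.get("d", 10))
        a = params["a"]
        A = np.zeros((dim, dim))
        A[0, 0] = -a
        for i in range(1, dim):
            A[i, i - 1] = a
            A[i, i] = -a if i < dim - 1 else A[i, i]
        A[dim - 1, dim - 1] = -q
        drive = np.zeros(dim)
        drive[0] = K
    else:
        raise ValueError(f"unknown model {model!r}")
    n = np.zeros(dim) + np.asarray(n0, dtype=float)
    out = np.empty((len(t_grid), dim))
    out[0] = n
    aug = np.zeros((dim + 2, dim + 2))
    aug[:dim, :dim] = A
    for k in range(1, len(t_grid)):
        dt = t_grid[k] - t_grid[k - 1]
        m0 = m_mean[k - 1]
        slope = (m_mean[k] - m_mean[k - 1]) / dt if dt > 0 else 0.0
        # components dim / dim+1 carry (t - t_{k-1}) and the constant 1
        aug[:dim, dim] = drive * slope
        aug[:dim, dim + 1] = drive * m0
        aug[dim, dim + 1] = 1.0
        vec = np.concatenate([n, [0.0, 1.0]])
        n = (expm(aug * dt) @ vec)[:dim]
        out[k] = n
    return out if dim > 1 else out[:, 0]
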