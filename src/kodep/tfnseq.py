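"""TFNseq trajectory classification.

A transposon knockout library is propagated on selective media and timed
fractions are sequenced; mapping insertion junctions yields a
relative-abundance trajectory for each mutant.  Each trajectory is
explained by one of three growth models for the log relative abundance
y(t):

* no-effect      M0: y = c                       (wild-type growth)
* sufficiency    M1: y = c - s*t,  s in [0, 2k0] (immediate growth deficit)
* overabundance  M2: y = c            for t <= T
                     y = c - k0*(t-T) for t >  T

In M2 the mutant grows at the wild-type rate until its target protein is
diluted to the functional threshold at the arrest time T, then stops while
the library continues at k0 — hence the fixed post-breakpoint slope -k0,
which makes the overabundance conversion o = exp(k0*T) self-consistent.

Model selection uses two successive null-hypothesis tests: test 1 rejects
the no-effect null against the overabundance alternative (F statistic on
the weighted residual sum of squares), and, when rejected, test 2 rejects
the sufficiency null against the overabundance alternative.  Across a
library, Benjamini-Hochberg correction is applied within each stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "InsertionTrajectory",
    "ModelFits",
    "TrajectoryFit",
    "log_relative_abundance",
    "fit_trajectory_models",
    "classify_trajectory",
    "classify_library",
    "overabundance_from_arrest",
    "estimate_k0",
    "aggregate_insertions",
]

MODELS = ("no_effect", "sufficient", "overabundant")
#: minimum fractions with nonzero counts for a trajectory to be classifiable
MIN_NONZERO_FRACTIONS = 4


def informative_fractions(counts: np.ndarray) -> np.ndarray:
    """Mask of fractions carrying information about a declining mutant.

    Once a mutant's reads fall to zero, the log relative abundance
    saturates at the pseudocount detection limit and later fractions say
    nothing about how far the true abundance has fallen; fitting them as
    Gaussian data would penalize the very decline being measured.  All
    trailing zero-count fractions except the first (which records that the
    mutant vanished) are therefore right-censored.
    """
    counts = np.asarray(counts)
    nz = np.nonzero(counts)[0]
    mask = np.ones(counts.size, dtype=bool)
    if nz.size == 0:
        return mask
    last = int(nz[-1])
    mask[last + 2:] = False
    return mask


@dataclass
class InsertionTrajectory:
    """Read counts of one mutant (or one gene's summed insertions) over fractions."""

    gene_id: str
    times: np.ndarray
    counts: np.ndarray
    totals: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.totals = np.asarray(self.totals, dtype=float)
        if not (self.times.shape == self.counts.shape == self.totals.shape):
            raise ValueError("times, counts and totals must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.counts > self.totals):
            raise ValueError("counts cannot exceed per-fraction totals")

    @property
    def classifiable(self) -> bool:
        return int(np.count_nonzero(self.counts)) >= MIN_NONZERO_FRACTIONS


@dataclass
class ModelFits:
    """Weighted least-squares fits of the three trajectory models."""

    rss: dict[str, float]
    intercepts: dict[str, float]
    slope: float            # M1 decline rate s (1/h)
    arrest_time: float      # M2 breakpoint T (h)
    n: int

    def curvature_se_T(self, k0: float, times, y, weights) -> float:
        """Breakpoint standard error from the local curvature of rss(T)."""
        h = max(1e-3, float(np.median(np.diff(times))) / 20.0)
        T = self.arrest_time
        r0 = _rss_breakpoint(times, y, weights, k0, T)
        rp = _rss_breakpoint(times, y, weights, k0, T + h)
        rm = _rss_breakpoint(times, y, weights, k0, max(0.0, T - h))
        curv = (rp + rm - 2 * r0) / h**2
        dof = self.n - 3
        if curv <= 0 or dof <= 0:
            return float("nan")
        sigma2 = max(self.rss["overabundant"], 1e-12) / dof
        return float(np.sqrt(2 * sigma2 / curv))


@dataclass
class TrajectoryFit:
    """Classification outcome for one trajectory."""

    gene_id: str
    model: str
    p_no_effect: float
    p_sufficiency: float
    slope: float
    arrest_time: float
    log10_o: float
    se_log10_o: float
    rss: dict[str, float]
    classifiable: bool = True


# ---------------------------------------------------------------------------
# log relative abundance
# ---------------------------------------------------------------------------

def log_relative_abundance(
    traj: InsertionTrajectory, pseudocount: float = 0.5
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Anchored log relative abundance with delta-method weights.

    y_t = ln((counts_t + pc) / (totals_t + pc)) - y_0; weights are inverse
    variances of the log ratio under binomial sampling,
    Var(y_t) ~ (1 - p_t) / (counts_t + pc).  Because every model carries a
    free intercept, anchoring at the first fraction shifts the intercept
    only and leaves all residual sums of squares unchanged.
    """
    if np.any(traj.totals <= 0):
        raise ValueError("per-fraction totals must be positive")
    pc = pseudocount
    p_hat = (traj.counts + pc) / (traj.totals + pc)
    y = np.log(p_hat)
    y = y - y[0]
    var = (1.0 - p_hat) / (traj.counts + pc)
    return traj.times, y, 1.0 / var


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

def _wls_rss(resid: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Profile out the intercept: c = weighted mean of resid, return (c, rss)."""
    c = float(np.dot(w, resid) / w.sum())
    r = resid - c
    return c, float(np.dot(w, r * r))


def _rss_breakpoint(times, y, w, k0: float, T: float) -> float:
    x = -k0 * np.clip(times - T, 0.0, None)
    return _wls_rss(y - x, w)[1]


def fit_trajectory_models(
    times: np.ndarray,
    y: np.ndarray,
    k0: float,
    weights: np.ndarray | None = None,
    grid_step: float | None = None,
    refine: bool = True,
) -> ModelFits:
    """Weighted least-squares fits of M0, M1 and M2 to one trajectory.

    The M2 breakpoint T is located on a grid over [0, t_last] (default
    resolution one-tenth of the fraction interval) and refined by bounded
    scalar minimization between the neighbouring grid points.  The grid
    includes T = t_last, where M2 degenerates to M0, so
    rss(M2) <= rss(M0); likewise s = 0 makes rss(M1) <= rss(M0).
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    n = times.size
    if n < 4:
        raise ValueError("need at least 4 fractions for model selection")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)

    # M0
    c0, rss0 = _wls_rss(y, w)

    # M1: free decline slope in [0, 2 k0]
    tbar = np.dot(w, times) / w.sum()
    ybar = np.dot(w, y) / w.sum()
    tc = times - tbar
    denom = np.dot(w, tc * tc)
    b = float(np.dot(w, tc * (y - ybar)) / denom) if denom > 0 else 0.0
    s = float(np.clip(-b, 0.0, 2 * k0))
    c1, rss1 = _wls_rss(y + s * times, w)

    # M2: breakpoint grid + refinement
    if grid_step is None:
        grid_step = float(np.median(np.diff(times))) / 10.0
    t_last = times[-1]
    grid = np.arange(0.0, t_last + grid_step / 2, grid_step)
    if grid[-1] < t_last:
        grid = np.append(grid, t_last)
    X = -k0 * np.clip(times[None, :] - grid[:, None], 0.0, None)
    resid = y[None, :] - X
    c_grid = resid @ w / w.sum()
    r = resid - c_grid[:, None]
    rss_grid = (r * r) @ w
    j = int(np.argmin(rss_grid))
    T_hat, rss2 = float(grid[j]), float(rss_grid[j])
    if refine:
        lo = grid[max(0, j - 1)]
        hi = grid[min(grid.size - 1, j + 1)]
        if hi > lo:
            res = optimize.minimize_scalar(
                lambda T: _rss_breakpoint(times, y, w, k0, T),
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-6},
            )
            if res.fun <= rss2:
                T_hat, rss2 = float(res.x), float(res.fun)
    c2, _ = _wls_rss(y + k0 * np.clip(times - T_hat, 0.0, None), w)

    return ModelFits(
        rss={"no_effect": rss0, "sufficient": rss1, "overabundant": rss2},
        intercepts={"no_effect": c0, "sufficient": c1, "overabundant": c2},
        slope=s,
        arrest_time=T_hat,
        n=n,
    )


# ---------------------------------------------------------------------------
# sequential tests
# ---------------------------------------------------------------------------

def _f_pvalue(rss_null: float, rss_alt: float, q: int, dof: int) -> float:
    """P-value of the F statistic on the rss reduction; negative F -> 1."""
    if dof <= 0:
        return float("nan")
    if rss_alt <= 1e-14:
        return 0.0 if rss_null > 1e-12 else 1.0
    F = ((rss_null - rss_alt) / q) / (rss_alt / dof)
    if F <= 0:
        return 1.0
    return float(stats.f.sf(F, q, dof))


def stage_pvalues(fits: ModelFits) -> tuple[float, float]:
    """(p_no_effect, p_sufficiency) for the two successive tests.

    Test 1: no-effect null against the better-fitting of the two
    alternatives (2 extra parameters).  Testing against the best
    alternative rather than against M2 alone keeps the residual variance
    estimate honest when the true decline is gentle (s << k0), where the
    fixed-slope breakpoint model misfits.
    Test 2: sufficiency null vs overabundance (1 extra parameter; the
    models touch at the T = 0 / s = k0 boundary).
    """
    dof = fits.n - 3
    rss_alt = min(fits.rss["sufficient"], fits.rss["overabundant"])
    p1 = _f_pvalue(fits.rss["no_effect"], rss_alt, 2, dof)
    p2 = _f_pvalue(fits.rss["sufficient"], fits.rss["overabundant"], 1, dof)
    return p1, p2


def classify_trajectory(
    fits: ModelFits,
    k0: float,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    gene_id: str = "",
    times: np.ndarray | None = None,
    y: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> TrajectoryFit:
    """Classify a single trajectory with raw (per-gene) test levels.

    The breakpoint standard error (hence se of log10 o) is computed from
    the local curvature of rss(T) when the trajectory data are provided.
    """
    if fits.n - 3 < 1:
        return TrajectoryFit(
            gene_id=gene_id, model="unclassifiable", p_no_effect=np.nan,
            p_sufficiency=np.nan, slope=np.nan, arrest_time=np.nan,
            log10_o=np.nan, se_log10_o=np.nan, rss=fits.rss, classifiable=False,
        )
    p1, p2 = stage_pvalues(fits)
    se = float("nan")
    if p1 < alpha1 and p2 < alpha2:
        model = "overabundant"
        log10_o = float(np.log10(overabundance_from_arrest(k0, fits.arrest_time)))
        if times is not None and y is not None:
            w = np.ones(fits.n) if weights is None else weights
            se_T = fits.curvature_se_T(k0, times, y, w)
            se = k0 * se_T / np.log(10)
        T = fits.arrest_time
        slope = k0
    elif p1 < alpha1:
        model, log10_o, T, slope = "sufficient", 0.0, np.nan, fits.slope
    else:
        model, log10_o, T, slope = "no_effect", np.nan, np.nan, np.nan
    return TrajectoryFit(
        gene_id=gene_id, model=model, p_no_effect=p1, p_sufficiency=p2,
        slope=slope, arrest_time=T, log10_o=log10_o, se_log10_o=se, rss=fits.rss,
    )


# ---------------------------------------------------------------------------
# library-level classification
# ---------------------------------------------------------------------------

def _bh_reject(pvals: np.ndarray, alpha: float) -> np.ndarray:
    from statsmodels.stats.multitest import multipletests

    if pvals.size == 0:
        return np.zeros(0, dtype=bool)
    return multipletests(pvals, alpha=alpha, method="fdr_bh")[0]


def _time_columns(counts: pd.DataFrame) -> tuple[list[str], np.ndarray]:
    cols = [c for c in counts.columns if c.startswith("t_")]
    if len(cols) < 4:
        raise ValueError("count matrix needs >= 4 t_<hours> fraction columns")
    times = np.array([float(c[2:]) for c in cols])
    order = np.argsort(times)
    return [cols[i] for i in order], times[order]


def classify_library(
    counts: pd.DataFrame,
    k0: float,
    alpha1: float = 0.05,
    alpha2: float = 0.05,
    pseudocount: float = 0.5,
    multiple_testing: str = "bh",
    normalization: str = "self",
    reference_genes: list[str] | None = None,
) -> pd.DataFrame:
    """Classify every gene of a count matrix (gene_id × t_<hours> columns).

    ``normalization`` handles library-composition drift (as perturbed
    mutants leave the pool, every relative-abundance trajectory acquires a
    shared offset):

    * ``"none"`` — trajectories are used as measured;
    * ``"reference"`` — the aggregate trajectory of ``reference_genes``
      (e.g. annotated neutral loci) is subtracted from every gene;
    * ``"self"`` (default) — two passes: genes classified no-effect in a
      first pass serve as the reference set for a second pass.

    ``multiple_testing``: "bh" applies Benjamini-Hochberg within each test
    stage across genes; "none" uses raw per-gene levels.
    """
    if normalization not in ("none", "reference", "self"):
        raise ValueError(f"unknown normalization {normalization!r}")
    cols, times = _time_columns(counts)
    mat = counts[cols].to_numpy(dtype=float)
    totals = mat.sum(axis=0)
    gene_ids = counts["gene_id"].astype(str).to_numpy()

    def run_pass(offset: np.ndarray) -> pd.DataFrame:
        rows = []
        store: dict[str, tuple] = {}
        for i, gid in enumerate(gene_ids):
            traj = InsertionTrajectory(gid, times, mat[i], totals)
            keep = informative_fractions(mat[i])
            if not traj.classifiable or keep.sum() < 4:
                rows.append((gid, False, np.nan, np.nan, None))
                continue
            t, y, w = log_relative_abundance(traj, pseudocount)
            y = y - offset
            t, y, w = t[keep], y[keep], w[keep]
            fits = fit_trajectory_models(t, y, k0, weights=w)
            p1, p2 = stage_pvalues(fits)
            store[gid] = (fits, t, y, w)
            rows.append((gid, True, p1, p2, fits))
        df = pd.DataFrame(rows, columns=["gene_id", "classifiable", "p1", "p2", "fits"])
        df.attrs["store"] = store
        return df

    def decide(df: pd.DataFrame) -> pd.DataFrame:
        ok = df["classifiable"].to_numpy()
        p1 = df["p1"].to_numpy(dtype=float)
        if multiple_testing == "bh":
            rej1 = np.zeros(len(df), dtype=bool)
            rej1[ok] = _bh_reject(p1[ok], alpha1)
            p2 = df["p2"].to_numpy(dtype=float)
            rej2 = np.zeros(len(df), dtype=bool)
            rej2[rej1] = _bh_reject(p2[rej1], alpha2)
        else:
            rej1 = ok & (p1 < alpha1)
            rej2 = rej1 & (df["p2"].to_numpy(dtype=float) < alpha2)
        out = []
        store = df.attrs["store"]
        for i, row in df.iterrows():
            gid = row["gene_id"]
            if not row["classifiable"]:
                out.append((gid, "unclassifiable", np.nan, np.nan, np.nan,
                            np.nan, np.nan, np.nan))
                continue
            fits = row["fits"]
            if rej2[i]:
                log10_o = float(np.log10(overabundance_from_arrest(k0, fits.arrest_time)))
                _, t, y, w = (fits, *store[gid][1:])
                se_T = fits.curvature_se_T(k0, t, y, w)
                out.append((gid, "overabundant", row["p1"], row["p2"], k0,
                            fits.arrest_time, log10_o, k0 * se_T / np.log(10)))
            elif rej1[i]:
                out.append((gid, "sufficient", row["p1"], row["p2"], fits.slope,
                            np.nan, 0.0, np.nan))
            else:
                out.append((gid, "no_effect", row["p1"], row["p2"], np.nan,
                            np.nan, np.nan, np.nan))
        return pd.DataFrame(out, columns=[
            "gene_id", "class", "p_no_effect", "p_sufficiency", "slope",
            "arrest_time_h", "log10_o", "se_log10_o",
        ])

    zero = np.zeros(times.size)
    result = decide(run_pass(zero))

    ref: np.ndarray | None = None
    if normalization == "reference":
        if not reference_genes:
            raise ValueError("normalization='reference' needs reference_genes")
        ref = np.isin(gene_ids, np.asarray(reference_genes, dtype=str))
    elif normalization == "self":
        neutral = result.loc[result["class"] == "no_effect", "gene_id"]
        ref = np.isin(gene_ids, neutral.to_numpy())
        if ref.sum() == 0:
            ref = None
    if ref is not None and ref.any():
        pooled = mat[ref].sum(axis=0)
        y_ref = np.log((pooled + pseudocount) / (totals + pseudocount))
        offset = y_ref - y_ref[0]
        result = decide(run_pass(offset))
    return result


# ---------------------------------------------------------------------------
# conversions and helpers
# ---------------------------------------------------------------------------

def overabundance_from_arrest(k0: float, T: float) -> float:
    """Overabundance from an arrest time: o = exp(k0 * T)."""
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    if T < 0:
        raise ValueError("arrest time must be non-negative")
    return float(np.exp(k0 * T))


def estimate_k0(
    k0: float | None = None,
    times: np.ndarray | None = None,
    absolute_totals: np.ndarray | None = None,
) -> tuple[float, str]:
    """Wild-type growth rate for the o = exp(k0*T) conversion, with provenance.

    Relative abundances alone cannot determine k0.  When spike-in absolute
    library sizes are available, an exponential is fit to total library
    growth; otherwise a configured k0 is passed through.  Returns
    ``(k0, source)`` with source in {"config", "spike-in"}.
    """
    if absolute_totals is not None:
        if times is None:
            raise ValueError("absolute totals need matching times")
        t = np.asarray(times, dtype=float)
        y = np.log(np.asarray(absolute_totals, dtype=float))
        slope = float(np.polyfit(t, y, 1)[0])
        if slope <= 0:
            raise ValueError("library is not growing; cannot estimate k0")
        return slope, "spike-in"
    if k0 is not None:
        if k0 <= 0:
            raise ValueError("k0 must be positive")
        return float(k0), "config"
    raise ValueError("supply either k0 or spike-in absolute totals")


def aggregate_insertions(insertions: pd.DataFrame) -> pd.DataFrame:
    """Sum insertion-level counts to per-gene trajectories.

    Expects a gene_id column plus t_<hours> count columns; position/strand
    columns, if present, are dropped (they are carried in the input for
    bookkeeping but play no role in fitting).
    """
    cols, _ = _time_columns(insertions)
    return insertions.groupby("gene_id", as_index=False)[cols].sum()
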