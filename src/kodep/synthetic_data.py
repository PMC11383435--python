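"""Synthetic data generators for knockout-depletion experiments.

Three generators emulate the statistical structure of the raw data the
downstream analyses consume, so the whole pipeline is testable without any
experimental download:

* :func:`simulate_lineage` — single-cell time-lapse of a knockout lineage:
  exponential areal growth, conserved protein partitioned by dilution at
  division, and threshold growth arrest once a cell's concentration falls
  below ``C0 / o_true``.
* :func:`simulate_tfnseq_library` — relative-abundance time courses of a
  transposon knockout library sampled as timed culture fractions, with
  multinomial sequencing noise at a fixed per-fraction read depth.
* :func:`simulate_rnaseq` — RNA-seq read counts drawn multinomially from
  per-gene message numbers (transcripts per gene per cell cycle).

:func:`simulate_genome` composes the library and RNA-seq generators into a
genome-scale scenario in which essential-gene overabundance follows the
robustness-load trade-off prediction, for end-to-end pipeline tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .lineage import ROOT_SENTINEL, CellTrack, LineageTree

__all__ = [
    "LineageSimConfig",
    "TfnseqSimConfig",
    "simulate_lineage",
    "simulate_tfnseq_library",
    "simulate_library_from_truth",
    "simulate_rnaseq",
    "simulate_genome",
]

CLASSES = ("no_effect", "sufficient", "overabundant")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class LineageSimConfig:
    """Parameters of the single-cell knockout-depletion simulation.

    The progenitor is born at half the doubling area with concentration
    ``C0``; protein synthesis stops at t = 0 (knockout) and the pool is
    thereafter conserved and partitioned in proportion to area at division.
    A cell arrests (growth rate drops to ``arrest_rate``) from the first
    sample at which its concentration falls below ``C0 / o_true``.
    """

    k0: float = float(np.log(2))          # wild-type growth rate (1/h)
    doubling_area: float = 2.0            # division area (µm²)
    o_true: float = 10.0                  # true overabundance (>= 1; np.inf = no arrest)
    C0: float = 1.0                       # initial concentration (a.u./µm²)
    dt: float = 0.1                       # sampling interval (h)
    t_max: float = 8.0                    # simulated duration (h)
    growth_noise_cv: float = 0.0          # CV of per-cell growth rate
    division_asymmetry_cv: float = 0.0    # CV of daughter area fraction about 0.5
    n_progenitors: int = 1
    arrest_rate: float = 0.0              # growth rate after arrest (1/h)
    hill_exponent: float | None = None    # smooth Hill-type arrest when set
    synthesis_rate: float = 0.0           # protein synthesis per µm² per h (control)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ValueError("k0 must be positive")
        if self.o_true < 1:
            raise ValueError("o_true must be >= 1")
        if self.dt <= 0 or self.t_max <= 0:
            raise ValueError("dt and t_max must be positive")
        if not 0 <= self.growth_noise_cv < 1:
            raise ValueError("growth_noise_cv must be in [0, 1)")
        if self.doubling_area <= 0 or self.C0 <= 0:
            raise ValueError("doubling_area and C0 must be positive")
        if self.n_progenitors < 1:
            raise ValueError("need at least one progenitor")


@dataclass
class TfnseqSimConfig:
    """Parameters of the transposon knockout-library simulation.

    Fractions are collected every two hours by default.  The expected
    relative abundance of mutant i at time t is proportional to
    ``exp(g_i(t))`` with ``g_i`` = 0 (no_effect), ``-s_i t`` (sufficient,
    immediate growth deficit ``s_i``) or 0 until the arrest time ``T_i``
    and ``-k0 (t - T_i)`` after it (overabundant: the mutant stops growing
    while the library continues at ``k0``).
    """

    n_genes_per_class: dict[str, int] = field(
        default_factory=lambda: {"no_effect": 100, "sufficient": 100, "overabundant": 100}
    )
    sample_times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 24.0 + 1e-9, 2.0)
    )
    depth: int = 100_000
    k0: float = float(np.log(2))
    sufficiency_slope_range: tuple[float, float] = (0.2 * np.log(2), np.log(2))
    overabundance_range: tuple[float, float] = (0.5, 2.5)   # log10 o
    seed: int = 0

    def __post_init__(self) -> None:
        self.sample_times = np.asarray(self.sample_times, dtype=float)
        if np.any(np.diff(self.sample_times) <= 0):
            raise ValueError("sample_times must be strictly increasing")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if any(v < 0 for v in self.n_genes_per_class.values()):
            raise ValueError("gene counts must be non-negative")
        if sum(self.n_genes_per_class.values()) == 0:
            raise ValueError("empty library: all class counts are zero")
        if min(self.overabundance_range) <= 0:
            raise ValueError("overabundance_range values must be positive")


# ---------------------------------------------------------------------------
# single-cell lineage simulation
# ---------------------------------------------------------------------------

def _sample_rate(rng: np.random.Generator, k0: float, cv: float) -> float:
    if cv == 0:
        return k0
    return k0 * max(0.05, 1.0 + cv * rng.standard_normal())


def _daughter_fraction(rng: np.random.Generator, cv: float) -> float:
    if cv == 0:
        return 0.5
    # symmetric Beta(a, a): sd = 0.5*cv  =>  a = (1/cv^2 - 1)/2
    a = max((1.0 / cv**2 - 1.0) / 2.0, 1.0)
    return float(rng.beta(a, a))


def simulate_lineage(config: LineageSimConfig) -> LineageTree:
    """Simulate a knockout-depletion lineage forest on a regular time grid.

    Returns a :class:`~kodep.lineage.LineageTree` whose fluorescence channel
    carries the conserved protein amount, so that concentration = fluor/area.
    The internally accumulated total-area series is stored under
    ``tree.meta["internal_totals"]`` for bookkeeping cross-checks.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    grid = np.arange(0.0, cfg.t_max + cfg.dt / 2, cfg.dt)
    c_thresh = 0.0 if np.isinf(cfg.o_true) else cfg.C0 / cfg.o_true

    tracks: dict[int, CellTrack] = {}
    progenitors: list[int] = []
    internal_totals = np.zeros(grid.size)
    next_id = 0
    a_birth0 = cfg.doubling_area / 2.0

    # stack entries: (cell_id, parent_id, t_birth, first_grid_index, area, protein)
    stack: list[tuple[int, int, float, int, float, float]] = []
    for _ in range(cfg.n_progenitors):
        stack.append((next_id, ROOT_SENTINEL, 0.0, 0, a_birth0, cfg.C0 * a_birth0))
        progenitors.append(next_id)
        next_id += 1

    while stack:
        cell_id, parent_id, t_birth, i0, a_birth, protein = stack.pop()
        k = _sample_rate(rng, cfg.k0, cfg.growth_noise_cv)
        times: list[float] = []
        areas: list[float] = []
        fluors: list[float] = []
        arrested = False

        if cfg.hill_exponent is None:
            # analytic exponential growth; division at a continuous time
            t_div = t_birth + np.log(cfg.doubling_area / a_birth) / k
            a_curr, t_curr = a_birth, t_birth
            divided = False
            for gi in range(i0, grid.size):
                t = grid[gi]
                if not arrested and t > t_div + 1e-9:
                    divided = True
                    break
                if arrested:
                    a = a_curr * np.exp(cfg.arrest_rate * (t - t_curr))
                else:
                    a = a_birth * np.exp(k * (t - t_birth))
                if cfg.synthesis_rate > 0:
                    protein += cfg.synthesis_rate * a * cfg.dt
                if not arrested and c_thresh > 0 and protein / a < c_thresh:
                    arrested = True
                    a_curr, t_curr = a, t
                times.append(t)
                areas.append(a)
                fluors.append(protein)
                internal_totals[gi] += a
            if divided:
                f = _daughter_fraction(rng, cfg.division_asymmetry_cv)
                a_div = cfg.doubling_area
                # daughters sample strictly after the division time so each
                # grid point carries either the mother or both daughters
                j0 = int(np.searchsorted(grid, t_div + 1e-9))
                stack.append((next_id, cell_id, t_div, j0, f * a_div, f * protein))
                next_id += 1
                stack.append((next_id, cell_id, t_div, j0, (1 - f) * a_div, (1 - f) * protein))
                next_id += 1
        else:
            # smooth Hill-type arrest: stepwise integration on the grid
            n = cfg.hill_exponent
            a = a_birth
            for gi in range(i0, grid.size):
                t = grid[gi]
                times.append(t)
                areas.append(a)
                fluors.append(protein)
                internal_totals[gi] += a
                conc = protein / a
                k_eff = k * conc**n / (conc**n + c_thresh**n) if c_thresh > 0 else k
                a = a * np.exp(k_eff * cfg.dt)
                if a >= cfg.doubling_area and k_eff > 0.5 * k:
                    f = _daughter_fraction(rng, cfg.division_asymmetry_cv)
                    stack.append((next_id, cell_id, t + cfg.dt, gi + 1, f * a, f * protein))
                    next_id += 1
                    stack.append((next_id, cell_id, t + cfg.dt, gi + 1, (1 - f) * a, (1 - f) * protein))
                    next_id += 1
                    break

        tracks[cell_id] = CellTrack(
            cell_id=cell_id,
            parent_id=parent_id,
            times=np.array(times),
            areas=np.array(areas),
            fluor=np.array(fluors),
        )

    # daughters born within the final sampling interval have no samples; drop
    # such childless leaves so every retained track carries data
    parents = {t.parent_id for t in tracks.values()}
    for cid in [c for c, t in tracks.items() if t.n_samples == 0 and c not in parents]:
        del tracks[cid]

    tree = LineageTree(tracks=tracks, progenitor_ids=progenitors)
    tree.meta["internal_totals"] = (grid, internal_totals)
    tree.meta["config"] = cfg
    return tree


# ---------------------------------------------------------------------------
# TFNseq library simulation
# ---------------------------------------------------------------------------

def _log_growth_offsets(
    truth: pd.DataFrame, times: np.ndarray, k0: float
) -> np.ndarray:
    """g_i(t) per gene: log abundance relative to an unperturbed mutant."""
    g = np.zeros((len(truth), times.size))
    cls = truth["class"].to_numpy()
    slope = truth["slope"].to_numpy()
    T = truth["arrest_time_h"].to_numpy()
    suf = cls == "sufficient"
    g[suf] = -slope[suf, None] * times[None, :]
    ov = cls == "overabundant"
    g[ov] = -k0 * np.clip(times[None, :] - T[ov, None], 0.0, None)
    return g


def simulate_library_from_truth(
    truth: pd.DataFrame,
    sample_times: np.ndarray,
    depth: int,
    k0: float,
    seed: int,
    initial_abundance: np.ndarray | None = None,
) -> pd.DataFrame:
    """Draw a multinomial count matrix from a per-gene truth table.

    ``truth`` needs columns gene_id, class, slope, arrest_time_h.  Returns a
    frame with gene_id and one ``t_<hours>`` column per fraction; column
    sums equal ``depth`` exactly.
    """
    rng = np.random.default_rng(seed)
    times = np.asarray(sample_times, dtype=float)
    g = _log_growth_offsets(truth, times, k0)
    if initial_abundance is None:
        initial_abundance = np.ones(len(truth))
    weights = initial_abundance[:, None] * np.exp(g)
    counts = np.empty_like(weights, dtype=np.int64)
    for j in range(times.size):
        p = weights[:, j] / weights[:, j].sum()
        counts[:, j] = rng.multinomial(depth, p)
    out = pd.DataFrame(counts, columns=[f"t_{t:g}" for t in times])
    out.insert(0, "gene_id", truth["gene_id"].to_numpy())
    return out


def simulate_tfnseq_library(
    config: TfnseqSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a knockout-library time course under the three growth classes.

    Returns ``(counts, truth)``: the count matrix (gene_id × t_<hours>) and
    the per-gene ground truth (class, slope, arrest_time_h, log10_o).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    rows = []
    gi = 0
    for cls in CLASSES:
        for _ in range(cfg.n_genes_per_class.get(cls, 0)):
            slope = np.nan
            T = np.nan
            log10_o = np.nan
            if cls == "sufficient":
                slope = rng.uniform(*cfg.sufficiency_slope_range)
                log10_o = 0.0
            elif cls == "overabundant":
                log10_o = rng.uniform(*cfg.overabundance_range)
                T = log10_o * np.log(10) / cfg.k0
            rows.append((f"gene_{gi:05d}", cls, slope, T, log10_o))
            gi += 1
    truth = pd.DataFrame(
        rows, columns=["gene_id", "class", "slope", "arrest_time_h", "log10_o"]
    )
    counts = simulate_library_from_truth(
        truth, cfg.sample_times, cfg.depth, cfg.k0, seed=int(rng.integers(2**31))
    )
    return counts, truth


# ---------------------------------------------------------------------------
# RNA-seq simulation
# ---------------------------------------------------------------------------

def simulate_rnaseq(
    message_numbers: pd.Series | dict[str, float],
    depth: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Multinomial RNA-seq counts with read probabilities ∝ message number.

    ``message_numbers`` maps gene_id to µ_m (transcripts per gene per cell
    cycle).  Inverse of message-number estimation up to sampling error.
    """
    mu = pd.Series(message_numbers, dtype=float)
    if depth <= 0:
        raise ValueError("depth must be positive")
    if np.any(mu < 0):
        raise ValueError("message numbers must be non-negative")
    total = mu.sum()
    if total == 0:
        raise ValueError("all message numbers are zero")
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(depth, (mu / total).to_numpy())
    return pd.DataFrame({"gene_id": mu.index, "count": counts})


# ---------------------------------------------------------------------------
# genome-scale composition
# ---------------------------------------------------------------------------

def simulate_genome(
    n_essential: int = 150,
    n_nonessential: int = 350,
    frac_sufficient_essential: float = 0.31,
    frac_defect_nonessential: float = 0.10,
    epsilon: float = 1e-3,
    tfnseq_depth: int = 100_000,
    rnaseq_depth: int = 1_000_000,
    sample_times: np.ndarray | None = None,
    k0: float = float(np.log(2)),
    overabundance_scatter: float = 0.15,
    sufficient_boundary_log10_o: float = 0.15,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Simulate a genome-scale knockout-depletion experiment.

    Per-gene message numbers µ_m are drawn log-normally; essential genes
    receive a true overabundance scattered around the robustness-load
    trade-off optimum o*(µ_m) at the given expression load ``epsilon``, so
    low-expression genes are highly overabundant and high-expression genes
    are close to sufficient.  Drawn genes whose log10 o falls below
    ``sufficient_boundary_log10_o`` are labelled sufficient (immediate
    arrest); non-essential genes are mostly no-effect with a minority
    carrying partial growth defects.

    Returns a dict with ``tfnseq_counts``, ``rnaseq_counts``, ``annotation``
    (gene_id, essential) and ``truth`` (class, slope, arrest_time_h,
    log10_o, mu_m) frames.
    """
    from .rlto import RltoParams, optimal_overabundance

    rng = np.random.default_rng(seed)
    if sample_times is None:
        sample_times = np.arange(0.0, 24.0 + 1e-9, 2.0)
    n_total = n_essential + n_nonessential
    gene_ids = [f"gene_{i:05d}" for i in range(n_total)]
    essential = np.zeros(n_total, dtype=int)
    essential[:n_essential] = 1
    log10_mu = rng.normal(0.9, 0.55, size=n_total)
    mu_m = 10.0**log10_mu

    cls = np.empty(n_total, dtype=object)
    slope = np.full(n_total, np.nan)
    T = np.full(n_total, np.nan)
    log10_o = np.full(n_total, np.nan)

    for i in range(n_essential):
        o_star = optimal_overabundance(
            RltoParams(mu_m=mu_m[i], epsilon=epsilon)
        ).o_star
        # a fraction of essential genes is forced sufficient irrespective of µ
        if rng.random() < frac_sufficient_essential:
            drawn = 0.0
        else:
            drawn = np.log10(o_star) + overabundance_scatter * rng.standard_normal()
        if drawn < sufficient_boundary_log10_o:
            cls[i] = "sufficient"
            slope[i] = k0
            log10_o[i] = 0.0
        else:
            cls[i] = "overabundant"
            log10_o[i] = drawn
            T[i] = drawn * np.log(10) / k0
    for i in range(n_essential, n_total):
        if rng.random() < frac_defect_nonessential:
            cls[i] = "sufficient"   # partial growth defect, immediate onset
            slope[i] = rng.uniform(0.1 * k0, 0.5 * k0)
            log10_o[i] = 0.0
        else:
            cls[i] = "no_effect"

    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "essential": essential,
            "class": cls,
            "slope": slope,
            "arrest_time_h": T,
            "log10_o": log10_o,
            "mu_m": mu_m,
        }
    )
    counts = simulate_library_from_truth(
        truth, sample_times, tfnseq_depth, k0, seed=int(rng.integers(2**31))
    )
    rnaseq = simulate_rnaseq(
        pd.Series(mu_m, index=gene_ids), rnaseq_depth, seed=int(rng.integers(2**31))
    )
    annotation = pd.DataFrame({"gene_id": gene_ids, "essential": essential})
    return {
        "tfnseq_counts": counts,
        "rnaseq_counts": rnaseq,
        "annotation": annotation,
        "truth": truth,
    }
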