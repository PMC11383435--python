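"""Single-cell knockout-depletion analysis.

After an essential gene is deleted, the pre-existing protein pool is no
longer replenished and is diluted by growth: the mean concentration over
the progeny of a progenitor cell follows

    C(t) = C0 * V0 / V(t),

where ``V(t)`` is the total volume of the progeny (segmented area is used
as the volume proxy throughout).  Growth continues until the concentration
falls below the functional threshold ``C_A``, at which point the lineage
arrests.  The overabundance of the targeted protein is

    o = C0 / C_A = V(T) / V0 = exp(k0 * T),

with ``T`` the arrest time and ``k0`` the wild-type growth rate.  This
module reconstructs growth rates, arrest times, the growth-rate-versus-
depletion fitness landscape and the resulting overabundance estimates from
cell-tracking tables (cell id, parent id, time, segmented area, optional
integrated fluorescence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ROOT_SENTINEL = -1
#: sentinel written to the fluorescence column when no fluorescence was measured
FLUOR_MISSING = -1.0

__all__ = [
    "CellTrack",
    "LineageTree",
    "FitnessLandscape",
    "LineageResult",
    "DilutionCheck",
    "dilution_concentration",
    "areal_growth_rate",
    "total_area_series",
    "detect_arrest",
    "overabundance_from_lineage",
    "fitness_landscape",
    "fluorescence_dilution_check",
    "analyze_lineage",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class CellTrack:
    """Time series of one segmented cell between birth and division/arrest.

    Parameters
    ----------
    cell_id : int
        Unique identifier of the cell.
    parent_id : int
        Identifier of the mother cell, or ``ROOT_SENTINEL`` (-1) for a
        progenitor present at the moment of knockout (t = 0).
    times : ndarray
        Sample times in hours, strictly increasing.
    areas : ndarray
        Segmented areas in µm², positive, same length as ``times``.
    fluor : ndarray, optional
        Integrated fluorescence (a.u.); proxy for protein *amount*.
    """

    cell_id: int
    parent_id: int
    times: np.ndarray
    areas: np.ndarray
    fluor: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.fluor is not None:
            self.fluor = np.asarray(self.fluor, dtype=float)
            if self.fluor.shape != self.times.shape:
                raise ValueError("fluor and times must have equal length")
        if self.times.shape != self.areas.shape:
            raise ValueError("times and areas must have equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.areas <= 0):
            raise ValueError("areas must be positive")

    @property
    def n_samples(self) -> int:
        return self.times.size

    def concentration(self) -> np.ndarray:
        """Fluorescence concentration (amount / area)."""
        if self.fluor is None:
            raise ValueError("track carries no fluorescence")
        return self.fluor / self.areas


@dataclass
class LineageTree:
    """A forest of cell tracks linked by parentage."""

    tracks: dict[int, CellTrack]
    progenitor_ids: list[int]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for track in self.tracks.values():
            if track.parent_id != ROOT_SENTINEL and track.parent_id not in self.tracks:
                raise ValueError(
                    f"cell {track.cell_id} references unknown parent {track.parent_id}"
                )
        for pid in self.progenitor_ids:
            if pid not in self.tracks:
                raise ValueError(f"progenitor {pid} not in tracks")

    def __len__(self) -> int:
        return len(self.tracks)

    def children(self, cell_id: int) -> list[int]:
        return [t.cell_id for t in self.tracks.values() if t.parent_id == cell_id]

    @property
    def has_fluorescence(self) -> bool:
        return any(t.fluor is not None for t in self.tracks.values())

    # -- table round trip ---------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.tracks.values():
            fluor = t.fluor if t.fluor is not None else np.full(t.n_samples, FLUOR_MISSING)
            for i in range(t.n_samples):
                rows.append((t.cell_id, t.parent_id, t.times[i], t.areas[i], fluor[i]))
        return pd.DataFrame(
            rows, columns=["cell_id", "parent_id", "time_h", "area_um2", "fluor_au"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LineageTree":
        tracks: dict[int, CellTrack] = {}
        progenitors: list[int] = []
        for cell_id, sub in df.groupby("cell_id", sort=True):
            sub = sub.sort_values("time_h")
            parent = int(sub["parent_id"].iloc[0])
            fluor = sub["fluor_au"].to_numpy()
            tracks[int(cell_id)] = CellTrack(
                cell_id=int(cell_id),
                parent_id=parent,
                times=sub["time_h"].to_numpy(),
                areas=sub["area_um2"].to_numpy(),
                fluor=None if np.all(fluor == FLUOR_MISSING) else fluor,
            )
            if parent == ROOT_SENTINEL:
                progenitors.append(int(cell_id))
        return cls(tracks=tracks, progenitor_ids=progenitors)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path) -> "LineageTree":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class FitnessLandscape:
    """Growth rate as a function of relative protein abundance C/C0."""

    rel_abundance: np.ndarray
    growth_rate: np.ndarray
    arrest_rel_abundance: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rel_abundance": self.rel_abundance, "growth_rate": self.growth_rate}
        )


@dataclass
class LineageResult:
    """Overabundance estimates for one lineage (forest of progenitors)."""

    arrest_time: float | None
    o_elongation: float
    o_septation: float
    n_cells: int
    n_progenitors: int

    @property
    def log10_o_elongation(self) -> float:
        return float(np.log10(self.o_elongation))

    @property
    def log10_o_septation(self) -> float:
        return float(np.log10(self.o_septation))


@dataclass
class DilutionCheck:
    """Goodness of fit of the dilution prediction C(t) = C0 V0 / V(t)."""

    rel_rms: float
    arrested_max_drift: float
    n_arrested: int


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def dilution_concentration(C0: float, V0: float, V_t) -> np.ndarray:
    """Predicted mean progeny concentration ``C0 * V0 / V(t)``."""
    V_t = np.asarray(V_t, dtype=float)
    if V0 <= 0 or np.any(V_t <= 0):
        raise ValueError("volumes must be positive")
    if np.any(V_t < V0 * (1 - 1e-12)):
        raise ValueError("progeny volume cannot shrink below the progenitor volume")
    return C0 * V0 / V_t


def _window_slopes(times: np.ndarray, y: np.ndarray, window: int) -> np.ndarray:
    """Centered sliding-window least-squares slopes; truncated at endpoints."""
    n = times.size
    half = window // 2
    slopes = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        t = times[lo:hi]
        v = y[lo:hi]
        if t.size < 2:
            slopes[i] = 0.0
            continue
        tc = t - t.mean()
        denom = np.dot(tc, tc)
        slopes[i] = np.dot(tc, v - v.mean()) / denom if denom > 0 else 0.0
    return slopes


def areal_growth_rate(track: CellTrack, window: int = 5) -> np.ndarray:
    """Single-cell areal growth rate k(t) = d ln A / dt.

    A centered sliding window of ``window`` samples is least-squares fit to
    ln A versus t; windows are truncated at the track endpoints so short
    post-division tracks remain usable.
    """
    if window < 3:
        raise ValueError("window must be >= 3 samples")
    if track.n_samples < window:
        raise ValueError(
            f"track {track.cell_id} has {track.n_samples} samples < window {window}"
        )
    return _window_slopes(track.times, np.log(track.areas), window)


def total_area_series(tree: LineageTree) -> tuple[np.ndarray, np.ndarray]:
    """Total live segmented area over the whole forest at each sample time."""
    if not tree.tracks:
        raise ValueError("empty lineage tree")
    acc: dict[float, float] = {}
    for t in tree.tracks.values():
        for ti, ai in zip(np.round(t.times, 9), t.areas):
            acc[ti] = acc.get(ti, 0.0) + ai
    times = np.array(sorted(acc))
    return times, np.array([acc[t] for t in times])


def detect_arrest(
    times: np.ndarray,
    k_series: np.ndarray,
    k0: float,
    frac: float = 0.5,
    min_consecutive: int = 2,
) -> float | None:
    """Earliest time after which the smoothed growth rate stays below frac*k0.

    The threshold crossing is linearly interpolated between the last sample
    above and the first sample below the threshold; ``None`` when growth
    never drops durably below the threshold.
    """
    if k0 <= 0:
        raise ValueError("k0 must be positive")
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    times = np.asarray(times, dtype=float)
    k = np.asarray(k_series, dtype=float)
    thr = frac * k0
    below = k < thr
    # smallest i with all samples below threshold from i onward
    idx = None
    for i in range(k.size):
        if below[i:].all() and (k.size - i) >= min_consecutive:
            idx = i
            break
    if idx is None:
        return None
    if idx == 0:
        return float(times[0])
    k_hi, k_lo = k[idx - 1], k[idx]
    if k_hi <= thr:
        # the previous sample already sits at the threshold: idx is minimal,
        # so k_hi >= thr and equality means the crossing is exactly there
        return float(times[idx - 1])
    if k_hi == k_lo:
        return float(times[idx])
    w = (k_hi - thr) / (k_hi - k_lo)
    return float(times[idx - 1] + w * (times[idx] - times[idx - 1]))


def _log_interp(times: np.ndarray, totals: np.ndarray, t: float) -> float:
    """Interpolate the total-area series in log space at time t."""
    return float(np.exp(np.interp(t, times, np.log(totals))))


def overabundance_from_lineage(tree: LineageTree, T: float | None) -> LineageResult:
    """Overabundance from total progeny growth and from cell counts.

    ``o_elongation`` is the fold-growth of total live area between knockout
    and arrest, V(T)/V0 = C0/C_A; ``o_septation`` is the ratio of final
    live-cell count to progenitor count.
    """
    times, totals = total_area_series(tree)
    A0 = totals[0]
    if A0 <= 0:
        raise ValueError("zero progenitor area")
    if T is not None:
        if not (times[0] <= T <= times[-1] + 1e-9):
            raise ValueError("arrest time outside the observed range")
        o_elong = _log_interp(times, totals, min(T, times[-1])) / A0
    else:
        o_elong = float("nan")
    t_final = times[-1]
    n_final = sum(
        1 for tr in tree.tracks.values()
        if tr.n_samples and np.isclose(tr.times[-1], t_final)
    )
    n_prog = len(tree.progenitor_ids)
    return LineageResult(
        arrest_time=T,
        o_elongation=float(o_elong),
        o_septation=n_final / n_prog,
        n_cells=n_final,
        n_progenitors=n_prog,
    )


def aggregate_growth_rate(
    tree: LineageTree, window: int = 7
) -> tuple[np.ndarray, np.ndarray]:
    """Growth rate of the total live area (robust to division events)."""
    times, totals = total_area_series(tree)
    if times.size < 3:
        raise ValueError("lineage too short for growth-rate estimation")
    return times, _window_slopes(times, np.log(totals), window)


def fitness_landscape(
    tree: LineageTree, k0: float, frac: float = 0.5, window: int = 7
) -> FitnessLandscape:
    """Growth rate as a function of relative protein abundance.

    By the dilution model, C/C0 = V0/V(t): each time point of a single
    knockout-depletion lineage samples the fitness landscape at one
    abundance, between wild type (C/C0 = 1) and the value reached at arrest.
    """
    times, totals = total_area_series(tree)
    t_k, k = aggregate_growth_rate(tree, window=window)
    rel = totals[0] / totals
    T = detect_arrest(t_k, k, k0=k0, frac=frac)
    arrest_rel = totals[0] / _log_interp(times, totals, T) if T is not None else None
    order = np.argsort(rel)[::-1]
    return FitnessLandscape(
        rel_abundance=rel[order],
        growth_rate=k[order],
        arrest_rel_abundance=arrest_rel,
    )


def fluorescence_dilution_check(
    tree: LineageTree,
    C0: float | None = None,
    arrest_growth_tol: float = 1e-3,
) -> DilutionCheck:
    """Test the dilution prediction against measured fluorescence.

    Compares the amount-weighted mean concentration over all progeny with
    C0*V0/V(t) (relative RMS deviation), and checks that arrested cells
    (area drift below ``arrest_growth_tol`` over their final samples) hold
    their concentration.
    """
    if not tree.has_fluorescence:
        raise ValueError("lineage carries no fluorescence")
    acc_area: dict[float, float] = {}
    acc_fluor: dict[float, float] = {}
    for tr in tree.tracks.values():
        if tr.fluor is None:
            continue
        for ti, ai, fi in zip(np.round(tr.times, 9), tr.areas, tr.fluor):
            acc_area[ti] = acc_area.get(ti, 0.0) + ai
            acc_fluor[ti] = acc_fluor.get(ti, 0.0) + fi
    times = np.array(sorted(acc_area))
    areas = np.array([acc_area[t] for t in times])
    fluor = np.array([acc_fluor[t] for t in times])
    mean_conc = fluor / areas
    if C0 is None:
        C0 = mean_conc[0]
    pred = dilution_concentration(C0, areas[0], np.maximum(areas, areas[0]))
    rel_rms = float(np.sqrt(np.mean(((mean_conc - pred) / pred) ** 2)))

    drifts = []
    for tr in tree.tracks.values():
        if tr.fluor is None or tr.n_samples < 3:
            continue
        # arrested tail: final samples with negligible area growth
        rel_growth = np.abs(np.diff(np.log(tr.areas)))
        tail = rel_growth[-2:]
        if np.all(tail < arrest_growth_tol):
            conc = tr.concentration()[-3:]
            drifts.append(np.abs(conc / conc[0] - 1).max())
    return DilutionCheck(
        rel_rms=rel_rms,
        arrested_max_drift=float(max(drifts)) if drifts else 0.0,
        n_arrested=len(drifts),
    )


def analyze_lineage(
    tree: LineageTree,
    k0: float,
    frac: float = 0.5,
    window: int = 7,
) -> tuple[LineageResult, FitnessLandscape]:
    """End-to-end single-lineage analysis: arrest, overabundance, landscape."""
    t_k, k = aggregate_growth_rate(tree, window=window)
    T = detect_arrest(t_k, k, k0=k0, frac=frac)
    result = overabundance_from_lineage(tree, T)
    landscape = fitness_landscape(tree, k0=k0, frac=frac, window=window)
    return result, landscape
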