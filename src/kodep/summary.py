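"""Genome-scale summaries of overabundance versus expression.

Joins per-gene classifications, overabundances and message numbers into
the headline statistics of a knockout-depletion screen — class fractions
by essentiality, the median essential overabundance, the
expression-weighted mean overabundance — and the windowed
expression-overabundance trend compared against the parameter-free RLTO
prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSummary",
    "class_fractions",
    "overabundance_statistics",
    "trend_curve",
    "compare_to_rlto",
    "summarize",
]


@dataclass
class GenomeSummary:
    per_gene: pd.DataFrame
    frac_no_effect_noness: float
    frac_sufficient_ess: float
    frac_overabundant_ess: float
    median_o_ess: float
    weighted_mean_o: float
    trend: pd.DataFrame
    n_unclassifiable: int = 0
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "frac_no_effect_nonessential": self.frac_no_effect_noness,
            "frac_sufficient_essential": self.frac_sufficient_ess,
            "frac_overabundant_essential": self.frac_overabundant_ess,
            "median_o_essential": self.median_o_ess,
            "weighted_mean_o_essential": self.weighted_mean_o,
            "n_unclassifiable": self.n_unclassifiable,
        }


def class_fractions(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Fraction of genes per (essentiality × class) cell.

    Unclassifiable genes are excluded from the denominators and reported
    in the returned frame's ``attrs["n_unclassifiable"]``.
    """
    if per_gene.empty:
        raise ValueError("empty per-gene table")
    df = per_gene[["essential", "class"]].copy()
    n_unclass = int((df["class"] == "unclassifiable").sum())
    df = df[df["class"] != "unclassifiable"]
    out = (
        df.groupby(["essential", "class"]).size().rename("n").reset_index()
    )
    out["fraction"] = out["n"] / out.groupby("essential")["n"].transform("sum")
    out.attrs["n_unclassifiable"] = n_unclass
    return out


def overabundance_statistics(
    per_gene: pd.DataFrame,
    essential_only: bool = True,
    include_sufficient: bool = True,
    weight: str = "mu_m",
) -> tuple[float, float]:
    """(median o, expression-weighted mean o) over classified genes.

    Sufficient genes enter with their measured o = 1 unless
    ``include_sufficient`` is off (then the median is over overabundant
    genes only).  The weighted mean is Σ(w·o)/Σw with w the message number
    by default — message number is the expression proxy available in this
    pipeline; pass another column name to weight by protein abundance.
    """
    df = per_gene
    if essential_only:
        df = df[df["essential"] == 1]
    df = df[df["class"].isin(["sufficient", "overabundant"])]
    if not include_sufficient:
        df = df[df["class"] == "overabundant"]
    if df.empty:
        raise ValueError("no classified essential genes")
    o = 10.0 ** df["log10_o"].to_numpy(dtype=float)
    w = df[weight].to_numpy(dtype=float)
    if np.any(w < 0) or w.sum() == 0:
        raise ValueError("weights must be non-negative with positive sum")
    return float(np.median(o)), float(np.sum(w * o) / np.sum(w))


def trend_curve(
    per_gene: pd.DataFrame,
    window_width: float = 0.25,
    window_step: float = 0.125,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Windowed mean log10 o versus log10 message number.

    Sliding windows of ``window_width`` in log10 mu_m advance by
    ``window_step``; windows with fewer than ``min_genes`` genes are merged
    with the next window until populated.  Returns window centers (mean
    log10 mu_m of members), widths, means and standard errors.
    """
    df = per_gene[np.isfinite(per_gene["log10_o"]) & (per_gene["mu_m"] > 0)]
    if df.empty:
        raise ValueError("no genes with finite overabundance and expression")
    lmu = np.log10(df["mu_m"].to_numpy(dtype=float))
    lo = df["log10_o"].to_numpy(dtype=float)
    if np.ptp(lmu) == 0:
        starts = [lmu.min() - window_width / 2]
    else:
        starts = list(np.arange(lmu.min(), lmu.max() - window_width / 2 + 1e-9,
                                window_step))
        if not starts:
            starts = [lmu.min()]
    rows = []
    i = 0
    while i < len(starts):
        left = starts[i]
        right = left + window_width
        j = i
        mask = (lmu >= left) & (lmu < right)
        # grow the window rightward until it holds enough genes
        while mask.sum() < min_genes and j + 1 < len(starts):
            j += 1
            right = starts[j] + window_width
            mask = (lmu >= left) & (lmu < right)
        if mask.sum() == 0:
            i = j + 1
            continue
        vals = lo[mask]
        rows.append((
            float(lmu[mask].mean()), float(right - left), int(mask.sum()),
            float(vals.mean()),
            float(vals.std(ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan,
        ))
        i = j + 1
    return pd.DataFrame(rows, columns=[
        "center_log10_mu", "width_log10_mu", "n_genes", "mean_log10_o",
        "se_log10_o",
    ])


def compare_to_rlto(trend: pd.DataFrame, rlto_curve: pd.DataFrame) -> pd.DataFrame:
    """Per-window difference between the measured trend and the RLTO curve.

    The model curve (columns mu_m, log10_o_star) is interpolated in
    log10 mu at each window center and subtracted from the window mean; no
    fitting is performed — the model is evaluated at its defaults,
    honouring its parameter-free character.  The frame's attrs carry the
    mean difference and the fraction of positive windows.
    """
    lmu_model = np.log10(rlto_curve["mu_m"].to_numpy(dtype=float))
    lo_model = rlto_curve["log10_o_star"].to_numpy(dtype=float)
    order = np.argsort(lmu_model)
    lmu_model, lo_model = lmu_model[order], lo_model[order]
    centers = trend["center_log10_mu"].to_numpy(dtype=float)
    inside = (centers >= lmu_model[0]) & (centers <= lmu_model[-1])
    if not inside.any():
        raise ValueError("trend and model curves do not overlap in mu_m")
    out = trend.loc[inside].copy()
    model_at = np.interp(out["center_log10_mu"], lmu_model, lo_model)
    out["model_log10_o_star"] = model_at
    out["difference"] = out["mean_log10_o"] - model_at
    out.attrs["mean_difference"] = float(out["difference"].mean())
    out.attrs["frac_positive"] = float((out["difference"] > 0).mean())
    return out


def summarize(
    per_gene: pd.DataFrame,
    rlto_curve: pd.DataFrame | None = None,
    **trend_kwargs,
) -> GenomeSummary:
    """Full genome summary from a joined per-gene table.

    ``per_gene`` needs gene_id, essential, class, log10_o and mu_m columns
    (the output of the classifier joined with the expression table).
    """
    fracs = class_fractions(per_gene)

    def frac(essential: int, cls: str) -> float:
        m = (fracs["essential"] == essential) & (fracs["class"] == cls)
        return float(fracs.loc[m, "fraction"].iloc[0]) if m.any() else 0.0

    median_o, weighted_o = overabundance_statistics(per_gene)
    ess = per_gene[(per_gene["essential"] == 1)
                   & per_gene["class"].isin(["sufficient", "overabundant"])]
    trend = trend_curve(ess, **trend_kwargs)
    extras = {}
    if rlto_curve is not None:
        extras["rlto_comparison"] = compare_to_rlto(trend, rlto_curve)
    return GenomeSummary(
        per_gene=per_gene,
        frac_no_effect_noness=frac(0, "no_effect"),
        frac_sufficient_ess=frac(1, "sufficient"),
        frac_overabundant_ess=frac(1, "overabundant"),
        median_o_ess=median_o,
        weighted_mean_o=weighted_o,
        trend=trend,
        n_unclassifiable=fracs.attrs["n_unclassifiable"],
        extras=extras,
    )
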