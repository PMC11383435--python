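"""Message numbers (transcripts per gene per cell cycle) from RNA-seq counts.

RNA-seq yields relative transcript abundances only; converting them to
message numbers requires an absolute scale — the total number of
transcripts a cell produces per cell cycle — which must be supplied (the
default is a bacterial order-of-magnitude figure).  Counts are optionally
length-normalized to transcript shares before scaling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .rlto import ONE_MESSAGE_THRESHOLD

__all__ = [
    "DEFAULT_TOTAL_MESSAGES",
    "message_number_from_counts",
    "join_overabundance_expression",
]

#: default total transcript productions per cell cycle (order of magnitude
#: for an exponentially growing bacterium); the absolute scale cannot be
#: inferred from relative RNA-seq and should be set from culture data
DEFAULT_TOTAL_MESSAGES = 30_000.0


def message_number_from_counts(
    counts: pd.DataFrame,
    total_messages_per_cell_cycle: float = DEFAULT_TOTAL_MESSAGES,
    length_normalize: bool = True,
) -> pd.DataFrame:
    """Per-gene message numbers from a count table.

    ``counts`` needs gene_id and count columns, plus length_bp when
    ``length_normalize`` is on (reads are converted to transcript shares by
    dividing by gene length; disable for 3'-counting protocols).  Shares
    sum to one before scaling, so Σ mu_m equals the configured total.
    Genes below the one-message-rule threshold (mu_m < 1) are flagged.
    """
    scale = total_messages_per_cell_cycle
    if scale <= 0:
        raise ValueError("total messages per cell cycle must be positive")
    if counts["count"].lt(0).any():
        raise ValueError("counts must be non-negative")
    total = counts["count"].sum()
    if total <= 0:
        raise ValueError("count table is empty")
    if length_normalize:
        if "length_bp" not in counts.columns:
            raise ValueError("length normalization requested but length_bp missing")
        if counts["length_bp"].le(0).any():
            raise ValueError("gene lengths must be positive")
        share = counts["count"] / counts["length_bp"]
    else:
        share = counts["count"].astype(float)
    share = share / share.sum()
    out = pd.DataFrame(
        {"gene_id": counts["gene_id"], "mu_m": scale * share.to_numpy()}
    )
    out["below_one_message"] = out["mu_m"] < ONE_MESSAGE_THRESHOLD
    return out


def join_overabundance_expression(
    classification: pd.DataFrame,
    expression: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Inner join of the per-gene classification and expression tables.

    Returns ``(joined, reconciliation)`` where the reconciliation log lists
    gene ids present on only one side.  Duplicate gene ids on either side
    are an error.
    """
    for name, df in (("classification", classification), ("expression", expression)):
        dup = df["gene_id"][df["gene_id"].duplicated()].unique()
        if len(dup):
            raise ValueError(f"duplicate gene_ids in {name} table: {sorted(dup)[:10]}")
    joined = classification.merge(expression, on="gene_id", how="inner")
    left = set(classification["gene_id"])
    right = set(expression["gene_id"])
    reconciliation = {
        "classification_only": sorted(left - right),
        "expression_only": sorted(right - left),
    }
    return joined, reconciliation
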