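"""Newly-synthesized-protein calling against an untreated control.

Affinity enrichment of analog-labeled proteins always co-purifies bead and
resin binders, so an untreated control is run alongside.  Proteins that are
not significantly enriched over the control (FC > 1.5, BH-adjusted p <
0.05) among those detected in the control are background binders and are
removed.  A protein is then called newly synthesized (NSP) when it is
detected in every treated replicate and is either absent from all control
replicates or significantly enriched over the control at the same
thresholds.  "Detected" means a non-missing LFQ value; upstream search-
engine identification FDR is assumed already applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_tables import QuantMatrix
from .stats import MinProbConfig, ModTConfig, bh_adjust, minprob_impute, moderated_t_test

__all__ = [
    "identify_background",
    "call_nsps",
    "replicate_reproducibility",
    "set_overlap",
    "STATUS_NSP",
    "STATUS_BACKGROUND",
    "STATUS_NOT_IDENTIFIED",
    "STATUS_NOT_ENRICHED",
]

STATUS_NSP = "NSP"
STATUS_BACKGROUND = "background"
STATUS_NOT_IDENTIFIED = "not-identified"
STATUS_NOT_ENRICHED = "identified-not-enriched"


def _enrichment_table(
    matrix: QuantMatrix,
    treated: str,
    control: str,
    minprob: MinProbConfig | None,
    seed: int,
) -> pd.DataFrame:
    """Moderated-t enrichment of treated over control on imputed values."""
    filled = minprob_impute(matrix, minprob, seed=seed)
    return moderated_t_test(filled, treated, control, ModTConfig())


def _check_conditions(matrix: QuantMatrix, treated: str, control: str) -> None:
    for cond in (treated, control):
        if cond not in matrix.conditions:
            raise KeyError(f"unknown condition label {cond!r}")
        if len(matrix.samples_for(cond)) < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 replicates")


def identify_background(
    matrix: QuantMatrix,
    treated: str,
    control: str,
    fc: float = 1.5,
    alpha: float = 0.05,
    minprob: MinProbConfig | None = None,
    seed: int = 0,
) -> set[str]:
    """Background binders: control-detected proteins not enriched in treated.

    Every protein with at least one observed control value is tested
    (moderated t on MinProb-imputed log2 values, BH-adjusted across the
    tested proteins); those failing ``FC > fc`` and ``p.adj < alpha`` are
    returned.  Proteins entirely absent from the control are never
    classified as background.
    """
    if fc <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    _check_conditions(matrix, treated, control)
    control_cols = matrix.samples_for(control)
    detected_in_control = matrix.values[control_cols].notna().any(axis=1)
    tested = matrix.values.index[detected_in_control]
    if len(tested) == 0:
        return set()

    table = _enrichment_table(matrix, treated, control, minprob, seed).loc[tested]
    p_adj = bh_adjust(table["p"].to_numpy())
    enriched = (table["log2fc"].to_numpy() > np.log2(fc)) & (p_adj < alpha)
    return set(tested[~enriched])


def call_nsps(
    matrix: QuantMatrix,
    treated: str,
    control: str,
    background: set[str],
    fc: float = 1.5,
    alpha: float = 0.05,
    minprob: MinProbConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Call NSPs; one row per protein with status, evidence and statistics.

    Candidates are proteins detected in all treated replicates and not in
    the background set.  A candidate is an NSP if it is missing in every
    control replicate (evidence ``absent-in-control``) or significantly
    enriched over the control (moderated t on imputed values, ``FC > fc``,
    BH ``p.adj < alpha``; evidence ``enriched``).  Statuses are mutually
    exclusive: ``NSP``, ``background``, ``not-identified`` (not present in
    all treated replicates), ``identified-not-enriched``.
    """
    if fc <= 0 or alpha <= 0:
        raise ValueError("thresholds must be positive")
    _check_conditions(matrix, treated, control)
    treated_cols = matrix.samples_for(treated)
    control_cols = matrix.samples_for(control)
    observed = matrix.values.notna()
    in_all_treated = observed[treated_cols].all(axis=1)
    absent_in_control = ~observed[control_cols].any(axis=1)

    ids = matrix.values.index
    out = pd.DataFrame(
        {
            "status": STATUS_NOT_IDENTIFIED,
            "evidence": "",
            "log2fc": np.nan,
            "p": np.nan,
            "p_adj": np.nan,
        },
        index=ids,
    )
    is_background = ids.isin(background)
    out.loc[is_background, "status"] = STATUS_BACKGROUND

    candidates = in_all_treated & ~is_background
    # Absence branch: never seen in the control.
    absent = candidates & absent_in_control
    out.loc[absent, "status"] = STATUS_NSP
    out.loc[absent, "evidence"] = "absent-in-control"

    # Enrichment branch for candidates with some control signal.
    to_test = ids[candidates & ~absent_in_control]
    if len(to_test) > 0:
        table = _enrichment_table(matrix, treated, control, minprob, seed).loc[to_test]
        p_adj = bh_adjust(table["p"].to_numpy())
        enriched = (table["log2fc"].to_numpy() > np.log2(fc)) & (p_adj < alpha)
        out.loc[to_test, "log2fc"] = table["log2fc"].to_numpy()
        out.loc[to_test, "p"] = table["p"].to_numpy()
        out.loc[to_test, "p_adj"] = p_adj
        hit = to_test[enriched]
        miss = to_test[~enriched]
        out.loc[hit, "status"] = STATUS_NSP
        out.loc[hit, "evidence"] = "enriched"
        out.loc[miss, "status"] = STATUS_NOT_ENRICHED
    return out


def replicate_reproducibility(presence: pd.DataFrame) -> tuple[float, float]:
    """Reproducibility fractions over the union of detected proteins.

    ``presence`` is a boolean protein x replicate table.  Returns the
    percentage of union proteins detected in all replicates and in at
    least two replicates.
    """
    if presence.shape[1] < 2:
        raise ValueError("need at least 2 replicates")
    counts = presence.astype(bool).sum(axis=1)
    union = counts > 0
    n_union = int(union.sum())
    if n_union == 0:
        raise ValueError("no protein detected in any replicate")
    pct_all = 100.0 * float((counts == presence.shape[1]).sum()) / n_union
    pct_two = 100.0 * float((counts >= 2).sum()) / n_union
    return pct_all, pct_two


def set_overlap(a: set, b: set) -> tuple[float, float, float]:
    """Shared / a-only / b-only percentages of the union of two id sets."""
    a, b = set(a), set(b)
    union = a | b
    if not union:
        raise ValueError("both sets are empty")
    n = len(union)
    return (
        100.0 * len(a & b) / n,
        100.0 * len(a - b) / n,
        100.0 * len(b - a) / n,
    )
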