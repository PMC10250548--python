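"""Pulse-labeling time-course analytics.

A pulse design labels cells during consecutive time windows after a
stimulus (plus a pre-stimulation steady-state window), with the heavy-
lysine channel as an internal marker for nascent protein.  The operations
here quantify label specificity, the presence dynamics of proteins across
windows (lost after stimulation, regained later), z-scored abundance
profiles at window granularity, and a per-protein one-way ANOVA across
windows with Bonferroni-corrected consecutive pairwise comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io_tables import PeptideRecord, QuantMatrix

__all__ = [
    "PresenceDynamics",
    "ProfileAnova",
    "label_specificity",
    "presence_dynamics",
    "zscore_profiles",
    "profile_anova",
]

HEAVY_LYSINE = "Lys8"


def label_specificity(
    peptides: list[PeptideRecord], heavy_label: str = HEAVY_LYSINE
) -> float:
    """Percentage of peptides carrying at least one heavy label."""
    if not peptides:
        raise ValueError("empty peptide list")
    n_heavy = sum(1 for p in peptides if p.has_modification(heavy_label))
    return 100.0 * n_heavy / len(peptides)


@dataclass
class PresenceDynamics:
    """Window-wise detection flags and the derived dynamics counts.

    ``detected`` is a protein x window boolean frame (a protein counts as
    detected in a window when present in all of that window's replicates,
    or any replicate under ``rule="any"``).  ``n_lost`` counts steady-state
    proteins undetected in the first post-stimulation window, ``n_regained``
    those of them detected again in a later window.
    """

    detected: pd.DataFrame
    windows: list[str]
    rule: str
    n_total: int
    n_steady: int
    n_lost: int
    n_regained: int

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "windows": list(self.windows),
            "n_total": self.n_total,
            "n_steady": self.n_steady,
            "n_lost": self.n_lost,
            "n_regained": self.n_regained,
        }


def presence_dynamics(matrix: QuantMatrix, rule: str = "all") -> PresenceDynamics:
    """Presence dynamics across time windows; the first window is steady state."""
    if rule not in ("all", "any"):
        raise ValueError(f"rule must be 'all' or 'any', got {rule!r}")
    windows = matrix.windows
    if windows is None or len(windows) < 2:
        raise ValueError("need a design with at least 2 time windows")

    observed = matrix.values.notna()
    cols = {}
    for w in windows:
        samples = list(matrix.design.index[matrix.design["window"] == w])
        flags = observed[samples]
        cols[w] = flags.all(axis=1) if rule == "all" else flags.any(axis=1)
    detected = pd.DataFrame(cols)[windows]

    any_window = detected.any(axis=1)
    steady = detected[windows[0]]
    lost = steady & ~detected[windows[1]]
    regained = lost & detected[windows[2:]].any(axis=1) if len(windows) > 2 else lost & False
    return PresenceDynamics(
        detected=detected,
        windows=list(windows),
        rule=rule,
        n_total=int(any_window.sum()),
        n_steady=int(steady.sum()),
        n_lost=int(lost.sum()),
        n_regained=int(regained.sum()),
    )


def zscore_profiles(
    matrix: QuantMatrix, level: str = "window_means"
) -> tuple[pd.DataFrame, list[str]]:
    """Per-protein z-scored abundance profiles over time windows.

    Only rows complete across all windows and replicates are profiled.
    With ``level="window_means"`` (heatmap granularity) each protein's
    replicate-mean window values are standardized to zero mean and unit
    sample s.d. (n-1 denominator); ``level="replicates"`` standardizes the
    individual replicate values instead.  Returns the z frame and the ids
    of constant rows whose z-score is undefined (flagged, left NaN).
    """
    if level not in ("window_means", "replicates"):
        raise ValueError(f"unknown level {level!r}")
    windows = matrix.windows
    if windows is None:
        raise ValueError("matrix carries no time windows")
    complete = matrix.values.notna().all(axis=1)
    values = matrix.values[complete]

    if level == "window_means":
        profile = pd.DataFrame(
            {
                w: values[
                    list(matrix.design.index[matrix.design["window"] == w])
                ].mean(axis=1)
                for w in windows
            }
        )[windows]
    else:
        profile = values

    mean = profile.mean(axis=1)
    sd = profile.std(axis=1, ddof=1)
    flagged = list(profile.index[sd == 0])
    z = profile.sub(mean, axis=0).div(sd.where(sd > 0), axis=0)
    return z, flagged


@dataclass
class ProfileAnova:
    """One-way ANOVA of a protein's abundance across time windows."""

    protein: str
    f_statistic: float
    p_value: float
    pairwise_p: dict[tuple[str, str], float]


def profile_anova(matrix: QuantMatrix, protein: str) -> ProfileAnova:
    """One-way fixed-effects ANOVA across windows for one protein.

    Consecutive-window pairwise two-sample t p-values are Bonferroni
    corrected (multiplied by the number of comparisons, capped at 1).
    Requires complete data: replicate values for every window.
    """
    windows = matrix.windows
    if windows is None or len(windows) < 2:
        raise ValueError("need a design with at least 2 time windows")
    if protein not in matrix.values.index:
        raise KeyError(f"unknown protein {protein!r}")
    row = matrix.values.loc[protein]
    if row.isna().any():
        raise ValueError(
            f"protein {protein!r} has missing values; ANOVA assumes completeness"
        )
    groups = []
    for w in windows:
        samples = list(matrix.design.index[matrix.design["window"] == w])
        if len(samples) < 2:
            raise ValueError(f"window {w!r} has fewer than 2 replicates")
        groups.append(row[samples].to_numpy(float))

    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = sps.f_oneway(*groups)
    n_pairs = len(windows) - 1
    pairwise = {}
    for w1, w2, g1, g2 in zip(windows, windows[1:], groups, groups[1:]):
        if np.allclose(np.concatenate([g1, g2]), g1[0]):
            p_pair = 1.0
        else:
            p_pair = float(sps.ttest_ind(g1, g2).pvalue)
        pairwise[(w1, w2)] = min(1.0, p_pair * n_pairs)
    return ProfileAnova(
        protein=protein,
        f_statistic=float(f_stat),
        p_value=float(p),
        pairwise_p=pairwise,
    )
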