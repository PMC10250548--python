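"""Amino-acid composition statistics and modification mass arithmetic.

Metabolic labeling with a threonine analog only reaches proteins that contain
threonine, so composition statistics over a proteome (mean residue content,
share of proteins lacking the residue, share with a single N-terminal
methionine that may be cleaved) quantify the theoretical coverage of the
method.  Modification specifications pair a residue substitution with its
elemental-composition delta, from which the monoisotopic mass shift used by
the search engine is derived.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd
from pyteomics import mass as _pmass

__all__ = [
    "ModificationSpec",
    "ContentSummary",
    "BUILTIN_MODIFICATIONS",
    "mod_mass_delta",
    "residue_content",
    "content_summary",
    "UnknownElementError",
]

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

_SYMBOL_RE = re.compile(r"^(?P<iso>\d+)?(?P<el>[A-Z][a-z]?)$")


class UnknownElementError(ValueError):
    """Raised when an elemental delta names an unknown element or isotope."""


def _monoisotopic_mass(symbol: str) -> float:
    """Monoisotopic mass of an element, or exact mass of a named isotope.

    ``"C"`` gives the mass of the principal isotope (12.0); ``"13C"`` gives
    the exact mass of carbon-13.  Masses come from the NIST table shipped
    with pyteomics.
    """
    m = _SYMBOL_RE.match(symbol)
    if m is None:
        raise UnknownElementError(f"unparsable element symbol: {symbol!r}")
    el = m.group("el")
    try:
        table = _pmass.nist_mass[el]
    except KeyError:
        raise UnknownElementError(f"unknown element: {el!r}") from None
    iso = m.group("iso")
    key = int(iso) if iso else 0
    try:
        return table[key][0]
    except KeyError:
        raise UnknownElementError(f"unknown isotope {iso} of {el}") from None


@dataclass(frozen=True)
class ModificationSpec:
    """A named residue substitution with its elemental-composition delta.

    Parameters
    ----------
    name : str
        Modification name as it appears in peptide tables, e.g. ``"Thr->bES"``.
    target : str or None
        Single-letter code of the residue the modification applies to, or
        ``None`` for modifications without a residue target (e.g. N-terminal
        acetylation).
    elemental_delta : dict
        Map from element (or isotope, e.g. ``"13C"``) symbol to a signed
        integer count of atoms gained or lost.
    """

    name: str
    target: str | None
    elemental_delta: dict = field(default_factory=dict)

    @property
    def monoisotopic_delta(self) -> float:
        """Signed monoisotopic mass shift in Da."""
        return mod_mass_delta(self)


def mod_mass_delta(spec: ModificationSpec) -> float:
    """Monoisotopic mass delta (Da) of a modification, to 4 decimals.

    The delta is the signed sum of monoisotopic element masses over the
    elemental-composition delta; isotope swaps (e.g. ``{"13C": 4, "C": -4}``)
    use the exact isotope mass difference.
    """
    total = 0.0
    for symbol, count in spec.elemental_delta.items():
        total += count * _monoisotopic_mass(symbol)
    return round(total, 4)


#: Substitutions and modifications this package knows by name.  The analog
#: substitution Thr->bES (C+1, H-2 relative to threonine) and the heavy
#: amino acids Thr5 (13C4,15N) and Lys8 (13C6,15N2) drive the labeling
#: analytics; the remaining entries are the common search-engine variable
#: modifications encountered in the peptide tables.
BUILTIN_MODIFICATIONS: dict[str, ModificationSpec] = {
    spec.name: spec
    for spec in (
        ModificationSpec("Thr->bES", "T", {"C": 1, "H": -2}),
        ModificationSpec("Thr->Thr5", "T", {"13C": 4, "C": -4, "15N": 1, "N": -1}),
        ModificationSpec("Lys8", "K", {"13C": 6, "C": -6, "15N": 2, "N": -2}),
        ModificationSpec("Oxidation (M)", "M", {"O": 1}),
        ModificationSpec("Acetyl (N-term)", None, {"C": 2, "H": 2, "O": 1}),
    )
}


def residue_content(sequence: str, residue: str) -> float:
    """Percentage of a sequence's residues equal to ``residue``.

    Nonstandard letters (U, X, B, Z, ...) are excluded from both numerator
    and denominator.

    Raises
    ------
    ValueError
        If the sequence is empty, contains no standard residues, or
        ``residue`` is not a single standard amino-acid letter.
    """
    if residue not in STANDARD_RESIDUES:
        raise ValueError(f"residue must be one standard amino-acid letter, got {residue!r}")
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    n_std = sum(1 for c in seq if c in STANDARD_RESIDUES)
    if n_std == 0:
        raise ValueError("sequence contains no standard residues")
    return 100.0 * seq.count(residue) / n_std


@dataclass
class ContentSummary:
    """Residue-content statistics over a protein set.

    ``mean_pct`` is the unweighted mean of per-protein residue percentages
    (each protein counts once regardless of length); ``length_weighted_pct``
    is the residue frequency of the concatenated sequences.  The two agree
    only when all sequences have equal length.
    """

    residue: str
    per_protein: pd.Series
    mean_pct: float
    length_weighted_pct: float
    lacking_pct: float
    containing_pct: float
    single_nterm_met_pct: float | None
    n_proteins: int
    n_nonstandard_excluded: int


def content_summary(
    proteome: dict[str, str],
    residue: str,
    subset: set[str] | None = None,
) -> ContentSummary:
    """Summarize residue content over a proteome or a subset of it.

    Parameters
    ----------
    proteome : dict
        Map of protein id to amino-acid sequence.
    residue : str
        Single-letter residue to profile.
    subset : set of str, optional
        Restrict the summary to these ids (e.g. the identified nascent
        proteins); all must exist in ``proteome``.
    """
    if not proteome:
        raise ValueError("empty proteome")
    if subset is not None:
        missing = sorted(set(subset) - set(proteome))
        if missing:
            raise KeyError(f"subset ids not in proteome: {missing}")
        ids = sorted(subset)
    else:
        ids = list(proteome)
    if not ids:
        raise ValueError("empty protein subset")

    fractions = {}
    total_count = 0
    total_len = 0
    n_nonstd = 0
    n_lacking = 0
    n_single_nterm_met = 0
    for pid in ids:
        seq = proteome[pid].upper()
        n_nonstd += sum(1 for c in seq if c not in STANDARD_RESIDUES)
        frac = residue_content(seq, residue)
        fractions[pid] = frac
        std = [c for c in seq if c in STANDARD_RESIDUES]
        total_count += std.count(residue)
        total_len += len(std)
        if frac == 0.0:
            n_lacking += 1
        if seq.count("M") == 1 and seq.startswith("M"):
            n_single_nterm_met += 1

    per_protein = pd.Series(fractions, name=f"{residue}_pct")
    n = len(ids)
    return ContentSummary(
        residue=residue,
        per_protein=per_protein,
        mean_pct=float(per_protein.mean()),
        length_weighted_pct=100.0 * total_count / total_len,
        lacking_pct=100.0 * n_lacking / n,
        containing_pct=100.0 * (n - n_lacking) / n,
        single_nterm_met_pct=(100.0 * n_single_nterm_met / n) if residue == "M" else None,
        n_proteins=n,
        n_nonstandard_excluded=n_nonstd,
    )
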