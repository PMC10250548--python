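"""Tab-separated quantification tables, FASTA input and run configuration.

The pipeline consumes two search-engine export dialects:

``peptides``
    One row per modified peptide: ``Sequence``, ``Modifications``,
    ``Proteins``, ``Charge`` and one ``Intensity <sample>`` column per
    sample.  ``Modifications`` is a semicolon-separated list of
    ``name@position`` tokens (1-based position, or ``any``); the literal
    ``Unmodified`` or an empty cell means no modification.

``proteins``
    One row per protein group: ``Majority protein IDs``, optional
    ``Gene names`` and one ``LFQ intensity <sample>`` column per sample.

Sample columns encode the experimental design in their names:
``<condition>_<replicate>`` or, for pulse-labeling time courses,
``<condition>@<window>_<replicate>``.  Condition and window labels must not
contain ``_`` or ``@``.  A raw intensity of 0, an empty cell or ``NaN``
marks a non-detection; protein intensities are log2-transformed exactly
once at read time.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .composition import BUILTIN_MODIFICATIONS, STANDARD_RESIDUES

__all__ = [
    "PeptideRecord",
    "QuantMatrix",
    "ExperimentDesign",
    "SchemaError",
    "TableParseError",
    "read_peptide_table",
    "peptide_records_from_frame",
    "read_protein_matrix",
    "quant_matrix_from_frame",
    "write_protein_matrix",
    "read_results_table",
    "write_results_table",
    "read_fasta",
    "load_config",
]


class SchemaError(ValueError):
    """A table is missing a mandatory column or violates the dialect."""


class TableParseError(ValueError):
    """A cell could not be parsed; carries the offending row number."""


_SAMPLE_RE = re.compile(r"^(?P<cond>[^@_]+)(?:@(?P<win>[^@_]+))?_(?P<rep>\d+)$")

_MISSING_TOKENS = {"", "nan", "na", "0", "0.0"}


def parse_sample_name(name: str) -> tuple[str, str | None, int]:
    """Split ``cond_2`` / ``cond@window_2`` into (condition, window, replicate)."""
    m = _SAMPLE_RE.match(name.strip())
    if m is None:
        raise SchemaError(
            f"sample column {name!r} does not follow the "
            "'<condition>[@<window>]_<replicate>' naming convention"
        )
    return m.group("cond"), m.group("win"), int(m.group("rep"))


@dataclass
class PeptideRecord:
    """One modified-peptide row of the ``peptides`` dialect.

    ``intensities`` maps sample id to a positive linear intensity or
    ``None`` for a non-detection.
    """

    sequence: str
    charge: int
    modifications: list[tuple[str, int | str]]
    protein_id: str
    intensities: dict[str, float | None]

    def __post_init__(self) -> None:
        if not self.sequence or any(c not in STANDARD_RESIDUES for c in self.sequence):
            raise ValueError(
                f"sequence {self.sequence!r} contains non-standard residues"
            )
        if self.charge < 1:
            raise ValueError(f"charge must be positive, got {self.charge}")
        for name, pos in self.modifications:
            if pos == "any":
                continue
            if not isinstance(pos, int) or pos < 1 or pos > len(self.sequence):
                raise ValueError(
                    f"modification {name!r} position {pos!r} outside sequence "
                    f"of length {len(self.sequence)}"
                )
            spec = BUILTIN_MODIFICATIONS.get(name)
            if spec is not None and spec.target is not None:
                if self.sequence[pos - 1] != spec.target:
                    raise ValueError(
                        f"modification {name!r} targets {spec.target} but position "
                        f"{pos} of {self.sequence} is {self.sequence[pos - 1]}"
                    )

    def has_modification(self, name: str) -> bool:
        return any(n == name for n, _ in self.modifications)


@dataclass
class ExperimentDesign:
    """Condition / replicate / time-window layout of an experiment."""

    conditions: list[str]
    replicates: dict[str, int]
    time_windows: list[str] | None = None

    def __post_init__(self) -> None:
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be unique")
        if self.time_windows is not None and len(set(self.time_windows)) != len(
            self.time_windows
        ):
            raise ValueError("time-window labels must be unique")
        for cond, n in self.replicates.items():
            if n < 1:
                raise ValueError(f"condition {cond!r} has no replicates")


@dataclass
class QuantMatrix:
    """Protein (or peptide) x sample log2-intensity matrix with design.

    ``values`` holds log2 intensities with ``NaN`` marking missing cells;
    ``design`` is indexed by sample id with columns ``condition``,
    ``replicate`` and ``window`` (``None`` outside time courses).  Window
    order in ``design`` is the experimental order and is preserved.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.values.columns) != list(self.design.index):
            raise ValueError("values columns and design index disagree")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dups}")
        key = self.design[["condition", "window"]].astype(object).apply(tuple, axis=1)
        for grp, sub in self.design.groupby(key, sort=False):
            if sub["replicate"].duplicated().any():
                raise ValueError(f"duplicate replicate indices within {grp}")

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where a cell is missing."""
        return self.values.isna()

    @property
    def row_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def conditions(self) -> list[str]:
        return list(dict.fromkeys(self.design["condition"]))

    @property
    def windows(self) -> list[str] | None:
        wins = [w for w in dict.fromkeys(self.design["window"]) if w is not None]
        return wins or None

    def samples_for(self, condition: str, window: str | None = None) -> list[str]:
        sel = self.design["condition"] == condition
        if window is not None:
            sel &= self.design["window"] == window
        samples = list(self.design.index[sel])
        if not samples:
            raise KeyError(
                f"no samples for condition {condition!r}"
                + (f", window {window!r}" if window is not None else "")
            )
        return samples

    def experiment_design(self) -> ExperimentDesign:
        conds = self.conditions
        reps = {
            c: int((self.design["condition"] == c).sum() // max(1, len(self.windows or [None])))
            for c in conds
        }
        return ExperimentDesign(conds, reps, self.windows)

    def copy_with(self, values: pd.DataFrame) -> "QuantMatrix":
        return QuantMatrix(values=values, design=self.design.copy())


def _design_from_samples(samples: list[str]) -> pd.DataFrame:
    rows = []
    for s in samples:
        cond, win, rep = parse_sample_name(s)
        rows.append({"condition": cond, "window": win, "replicate": rep})
    return pd.DataFrame(rows, index=pd.Index(samples, name="sample"))


def _parse_intensity(cell, row_number: int) -> float | None:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return None
    text = str(cell).strip()
    if text.lower() in _MISSING_TOKENS:
        return None
    try:
        value = float(text)
    except ValueError:
        raise TableParseError(
            f"row {row_number}: malformed intensity cell {cell!r}"
        ) from None
    if value < 0:
        raise TableParseError(f"row {row_number}: negative intensity {value}")
    return None if value == 0 else value


def _parse_modifications(cell) -> list[tuple[str, int | str]]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)):
        return []
    text = str(cell).strip()
    if not text or text == "Unmodified":
        return []
    mods: list[tuple[str, int | str]] = []
    for token in text.split(";"):
        token = token.strip()
        if not token:
            continue
        if "@" in token:
            name, _, pos = token.rpartition("@")
            mods.append((name, "any" if pos == "any" else int(pos)))
        else:
            mods.append((token, "any"))
    return mods


_DIALECTS = {
    "peptides": {
        "mandatory": ["Sequence", "Modifications", "Proteins", "Charge"],
        "intensity_prefix": "Intensity ",
    },
    "proteins": {
        "mandatory": ["Majority protein IDs"],
        "intensity_prefix": "LFQ intensity ",
    },
}


def read_peptide_table(path, dialect: str = "peptides") -> list[PeptideRecord]:
    """Read a modified-peptide TSV into :class:`PeptideRecord` objects.

    Column order is irrelevant; an intensity cell of 0 or an empty cell
    marks the sample as missing for that peptide form.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return peptide_records_from_frame(frame, dialect=dialect)


def peptide_records_from_frame(
    frame: pd.DataFrame, dialect: str = "peptides"
) -> list[PeptideRecord]:
    """As :func:`read_peptide_table` but from an in-memory frame."""
    spec = _DIALECTS[dialect]
    for col in spec["mandatory"]:
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    prefix = spec["intensity_prefix"]
    intensity_cols = [c for c in frame.columns if c.startswith(prefix)]
    if not intensity_cols:
        raise SchemaError(f"no {prefix!r} sample columns found")
    samples = [c[len(prefix):] for c in intensity_cols]

    records = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        row = dict(zip(frame.columns, row))
        try:
            charge = int(float(row["Charge"]))
        except (TypeError, ValueError):
            raise TableParseError(f"row {i}: malformed Charge {row['Charge']!r}") from None
        intensities = {
            s: _parse_intensity(row[prefix + s], i) for s in samples
        }
        records.append(
            PeptideRecord(
                sequence=str(row["Sequence"]).strip().upper(),
                charge=charge,
                modifications=_parse_modifications(row["Modifications"]),
                protein_id=str(row["Proteins"]).strip(),
                intensities=intensities,
            )
        )
    return records


def read_protein_matrix(path) -> tuple[QuantMatrix, ExperimentDesign]:
    """Read a protein-group LFQ table into a log2 :class:`QuantMatrix`.

    Zeros and blanks become missing; intensities are log2-transformed
    exactly once; the design is inferred from the sample column names.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return quant_matrix_from_frame(frame)


def quant_matrix_from_frame(frame: pd.DataFrame) -> tuple[QuantMatrix, ExperimentDesign]:
    """As :func:`read_protein_matrix` but from an in-memory frame."""
    spec = _DIALECTS["proteins"]
    for col in spec["mandatory"]:
        if col not in frame.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    prefix = spec["intensity_prefix"]
    intensity_cols = [c for c in frame.columns if c.startswith(prefix)]
    if not intensity_cols:
        raise SchemaError(f"no {prefix!r} sample columns found")
    samples = [c[len(prefix):] for c in intensity_cols]
    design = _design_from_samples(samples)

    ids = frame["Majority protein IDs"].astype(str).str.strip()
    if ids.duplicated().any():
        dups = sorted(ids[ids.duplicated()].unique())
        raise ValueError(f"duplicate row ids: {dups}")

    raw = np.full((len(frame), len(samples)), np.nan)
    for j, s in enumerate(samples):
        col = frame[prefix + s]
        for i, cell in enumerate(col):
            v = _parse_intensity(cell, i + 2)
            if v is not None:
                raw[i, j] = np.log2(v)
    values = pd.DataFrame(raw, index=pd.Index(ids, name="protein"), columns=samples)
    qm = QuantMatrix(values=values, design=design)
    return qm, qm.experiment_design()


def write_protein_matrix(matrix: QuantMatrix, path) -> None:
    """Write a QuantMatrix back to the ``proteins`` dialect (linear scale,

    0 for missing), inverting the log2 transform applied at read time."""
    linear = np.power(2.0, matrix.values).fillna(0.0)
    out = pd.DataFrame({"Majority protein IDs": matrix.values.index})
    for s in matrix.values.columns:
        out[f"LFQ intensity {s}"] = linear[s].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def write_results_table(frame: pd.DataFrame, path) -> None:
    """Write a results frame as TSV; missing cells become empty fields."""
    frame.to_csv(path, sep="\t", index=True, index_label=frame.index.name or "id")


def read_results_table(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA proteome into an id -> sequence map.

    Ids come from the first header token; when the token is UniProt
    pipe-delimited (``sp|P12345|NAME``) the accession is extracted.
    Sequences are uppercased and trailing stop characters stripped.
    """
    proteome: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        token = rec.id
        if "|" in token:
            parts = token.split("|")
            token = parts[1] if len(parts) >= 2 and parts[1] else parts[0]
        seq = str(rec.seq).upper().rstrip("*")
        proteome[token] = seq
    if not proteome:
        raise ValueError(f"no FASTA records in {path}")
    return proteome


def load_config(path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a YAML mapping")
    return cfg
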