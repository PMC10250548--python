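"""Synthetic quantification tables with known ground truth.

Every downstream stage of the pipeline is exercisable without external
downloads by generating search-engine-style tables that emulate the three
study designs:

* an incorporation experiment — cells fed both the clickable analog and a
  heavy isotopologue of the same amino acid, so each single-threonine
  peptide appears as an analog form (expected intensity ``A * p``), a heavy
  form (``A * (1 - p)``) and a residual unlabeled form, where ``A`` is the
  peptide's latent log-normal abundance and ``p`` the true per-threonine
  substitution probability;
* an enrichment experiment — true newly synthesized proteins present in the
  treated condition and absent-or-low in the untreated control, on top of a
  background of bead binders present in both at equal expectation;
* a pulse-labeling time course — per-window protein abundance profiles with
  replicates, plus a peptide-level companion table whose peptides carry the
  heavy-lysine label with a configurable probability.

Missingness is modeled as left censoring: each cell is observed with a
probability that follows a logistic curve rising in the latent log2
intensity, the standard surrogate for the LC-MS detection limit and the
mechanism MinProb-style imputation presumes.  A single global seed is split
into per-stage substreams so stages can be re-run independently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

from .io_tables import QuantMatrix, _design_from_samples

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_incorporation_dataset",
    "simulate_nsp_experiment",
    "simulate_timecourse",
    "midpoint_for_missing_fraction",
    "DEFAULT_WINDOWS",
]

DEFAULT_WINDOWS = ("steady", "0-1h", "1-2h", "3-4h")

AA_POOL = "ACDEFGHILMNPQSVWY"  # no T (inserted explicitly), no K/R (C-terminal)


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic generator.

    Defaults mirror the labeling experiments the pipeline targets: three
    biological replicates, a per-threonine analog substitution probability
    of 1/40.8, ~20% replicate-to-replicate coefficient of variation on the
    linear intensity scale, log2 LFQ intensities around 25, and a logistic
    detection curve whose midpoint sits well below the bulk of the
    intensity distribution.
    """

    n_proteins: int = 200
    peptides_per_protein: tuple[int, int] = (1, 3)
    incorporation_p: float = 1.0 / 40.8
    base_log2_mu: float = 25.0
    base_log2_sigma: float = 1.5
    replicate_cv: float = 0.2
    n_replicates: int = 3
    nsp_fraction: float = 0.2
    nsp_delta_log2: float = 5.0
    de_effects: tuple[tuple[int, float, int], ...] = ()
    missing_curve: tuple[float, float] | None = (20.0, 1.0)
    thr0_level: float = 0.5
    multi_thr_fraction: float = 0.1
    thr_free_fraction: float = 0.1
    split_mod_fraction: float = 0.2
    lys8_fraction: float = 0.97
    time_windows: tuple[str, ...] = DEFAULT_WINDOWS
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.incorporation_p < 1:
            raise ValueError("incorporation_p must be in (0, 1)")
        for name in ("nsp_fraction", "lys8_fraction", "multi_thr_fraction",
                     "thr_free_fraction", "split_mod_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.base_log2_sigma <= 0 or self.replicate_cv < 0:
            raise ValueError("base_log2_sigma must be > 0 and replicate_cv >= 0")
        if self.n_replicates < 1 or self.n_proteins < 1:
            raise ValueError("n_replicates and n_proteins must be positive")
        lo, hi = self.peptides_per_protein
        if lo < 1 or hi < lo:
            raise ValueError("peptides_per_protein must be a non-empty range")
        if self.thr0_level < 0:
            raise ValueError("thr0_level must be >= 0")


@dataclass
class GroundTruth:
    """What the generator actually planted, serialized next to each dataset."""

    true_incorporation_p: float | None = None
    true_nsp_ids: list[str] = field(default_factory=list)
    true_background_ids: list[str] = field(default_factory=list)
    true_de: dict[str, list[float]] = field(default_factory=dict)
    censored_cells: list[tuple[str, str]] = field(default_factory=list)
    latent_log2: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        data = asdict(self)
        data["censored_cells"] = [list(c) for c in self.censored_cells]
        with open(path, "w") as fh:
            json.dump(data, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            data = json.load(fh)
        data["censored_cells"] = [tuple(c) for c in data.get("censored_cells", [])]
        return cls(**data)


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _noise(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-one multiplicative log-normal noise with the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _detect_prob(log2_intensity: np.ndarray, curve: tuple[float, float] | None) -> np.ndarray:
    """Logistic detection probability, rising in log2 intensity."""
    x = np.asarray(log2_intensity, dtype=float)
    if curve is None:
        return np.ones_like(x)
    midpoint, slope = curve
    return 1.0 / (1.0 + np.exp(-slope * (x - midpoint)))


def midpoint_for_missing_fraction(
    fraction: float, mu: float, sigma: float, slope: float = 1.0
) -> float:
    """Detection-curve midpoint yielding a target marginal missing fraction.

    Solves ``E[1 - logistic(slope * (X - m))] = fraction`` for ``m`` with
    ``X ~ N(mu, sigma^2)``, so a simulation can be pinned to a stated
    censoring level (e.g. 25% missing) rather than to an ad-hoc midpoint.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    grid = mu + sigma * np.linspace(-6, 6, 2001)
    weights = sps.norm.pdf(grid, mu, sigma)
    weights /= weights.sum()

    def marginal_missing(m: float) -> float:
        return float(np.sum(weights * (1.0 - 1.0 / (1.0 + np.exp(-slope * (grid - m))))))

    lo, hi = mu - 20 * sigma, mu + 20 * sigma
    return float(optimize.brentq(lambda m: marginal_missing(m) - fraction, lo, hi))


def _random_sequence(rng: np.random.Generator, n_thr: int, length: int = 10) -> str:
    """Random tryptic-looking sequence with exactly ``n_thr`` threonines."""
    body = list(rng.choice(list(AA_POOL), size=length - 1 - n_thr))
    for _ in range(n_thr):
        body.insert(int(rng.integers(0, len(body) + 1)), "T")
    return "".join(body) + ("K" if rng.random() < 0.5 else "R")


def _unique_sequences(rng: np.random.Generator, n: int, n_thr: int) -> list[str]:
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n:
        s = _random_sequence(rng, n_thr)
        if s not in seen:
            seen.add(s)
            seqs.append(s)
    return seqs


def _censor(
    rng: np.random.Generator,
    intensity: np.ndarray,
    curve: tuple[float, float] | None,
) -> np.ndarray:
    """Return a copy with left-censored cells set to NaN (linear scale in)."""
    out = np.asarray(intensity, dtype=float).copy()
    positive = out > 0
    with np.errstate(divide="ignore"):
        log2 = np.where(positive, np.log2(np.where(positive, out, 1.0)), -np.inf)
    p_detect = _detect_prob(log2, curve)
    dropped = rng.random(out.shape) >= p_detect
    out[dropped | ~positive] = np.nan
    return out


def simulate_incorporation_dataset(
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Peptide table for the analog-vs-heavy incorporation design.

    Each single-threonine peptide is emitted in three modification states:
    the heavy form at expectation ``A * (1 - p)``, the analog form at
    ``A * p`` and a residual unlabeled form at ``A * thr0_level`` (protein
    made before labeling started), each perturbed by replicate noise and
    left-censored by the detection curve.  Multi-threonine and
    threonine-free peptides are emitted to exercise the selection filters,
    and a fraction of analog rows is split over two modification states
    (with and without an extra acetylation) to exercise intensity summing.
    """
    cfg.validate()
    rng_seq, rng_ab, rng_noise, rng_cens, rng_misc = _spawn(cfg.seed, 5)
    p = cfg.incorporation_p
    samples = [f"lab_{r + 1}" for r in range(cfg.n_replicates)]

    n_pep = cfg.n_proteins
    n_multi = int(round(cfg.multi_thr_fraction * n_pep))
    n_free = int(round(cfg.thr_free_fraction * n_pep))
    singles = _unique_sequences(rng_seq, n_pep, n_thr=1)
    multis = _unique_sequences(rng_seq, n_multi, n_thr=2)
    frees = _unique_sequences(rng_seq, n_free, n_thr=0)

    rows: list[dict] = []
    truth = GroundTruth(true_incorporation_p=p)

    def emit(seq: str, mods: str, protein: str, expected: float) -> None:
        reps = expected * _noise(rng_noise, cfg.replicate_cv, cfg.n_replicates)
        observed = _censor(rng_cens, reps, cfg.missing_curve)
        row = {
            "Sequence": seq,
            "Modifications": mods,
            "Proteins": protein,
            "Charge": 2,
        }
        for s, v in zip(samples, observed):
            row[f"Intensity {s}"] = 0.0 if np.isnan(v) else v
        rows.append(row)

    for i, seq in enumerate(singles):
        protein = f"P{i + 1:05d}"
        abundance = float(2.0 ** rng_ab.normal(cfg.base_log2_mu, cfg.base_log2_sigma))
        truth.latent_log2[seq] = float(np.log2(abundance))
        t_pos = seq.index("T") + 1
        emit(seq, f"Thr->Thr5@{t_pos}", protein, abundance * (1.0 - p))
        bes_total = abundance * p
        if rng_misc.random() < cfg.split_mod_fraction:
            share = 0.3 + 0.4 * rng_misc.random()
            emit(seq, f"Thr->bES@{t_pos}", protein, bes_total * share)
            emit(
                seq,
                f"Thr->bES@{t_pos};Acetyl (N-term)@any",
                protein,
                bes_total * (1.0 - share),
            )
        else:
            emit(seq, f"Thr->bES@{t_pos}", protein, bes_total)
        if cfg.thr0_level > 0:
            emit(seq, "Unmodified", protein, abundance * cfg.thr0_level)

    for j, seq in enumerate(multis + frees):
        protein = f"X{j + 1:05d}"
        abundance = float(2.0 ** rng_ab.normal(cfg.base_log2_mu, cfg.base_log2_sigma))
        emit(seq, "Unmodified", protein, abundance)

    return pd.DataFrame(rows), truth


def simulate_nsp_experiment(cfg: SimulationConfig) -> tuple[QuantMatrix, GroundTruth]:
    """Protein LFQ matrix for the treated-vs-untreated enrichment design.

    True newly synthesized proteins carry their full abundance in the
    treated condition and sit ``nsp_delta_log2`` lower in the control,
    where the detection curve censors most of them; background binders
    have equal expectation in both conditions.  Entries of
    ``cfg.de_effects`` (set size, |log2FC|, direction) plant differential
    effects on background proteins, recorded in ``GroundTruth.true_de``.
    """
    cfg.validate()
    rng_ab, rng_noise, rng_cens = _spawn(cfg.seed, 3)
    n = cfg.n_proteins
    n_nsp = int(round(cfg.nsp_fraction * n))
    ids = [f"P{i + 1:05d}" for i in range(n)]
    nsp_ids = ids[:n_nsp]
    bg_ids = ids[n_nsp:]

    samples = [f"treated_{r + 1}" for r in range(cfg.n_replicates)] + [
        f"control_{r + 1}" for r in range(cfg.n_replicates)
    ]
    base = rng_ab.normal(cfg.base_log2_mu, cfg.base_log2_sigma, size=n)

    treated_mu = base.copy()
    control_mu = base.copy()
    control_mu[:n_nsp] -= cfg.nsp_delta_log2

    truth = GroundTruth(
        true_nsp_ids=list(nsp_ids),
        true_background_ids=list(bg_ids),
        latent_log2={pid: float(b) for pid, b in zip(ids, base)},
    )
    cursor = n_nsp  # DE effects are planted on background proteins
    for size, lfc, direction in cfg.de_effects:
        if cursor + size > n:
            raise ValueError("de_effects exceed the number of background proteins")
        for k in range(cursor, cursor + size):
            treated_mu[k] += direction * abs(lfc)
            truth.true_de[ids[k]] = [direction * abs(lfc)]
        cursor += size

    sd_log2 = np.sqrt(np.log1p(cfg.replicate_cv**2)) / np.log(2.0)
    cols = {}
    for r in range(cfg.n_replicates):
        cols[f"treated_{r + 1}"] = treated_mu + rng_noise.normal(0, sd_log2, n)
    for r in range(cfg.n_replicates):
        cols[f"control_{r + 1}"] = control_mu + rng_noise.normal(0, sd_log2, n)
    latent = pd.DataFrame(cols, index=pd.Index(ids, name="protein"))[samples]

    p_detect = _detect_prob(latent.to_numpy(), cfg.missing_curve)
    dropped = rng_cens.random(latent.shape) >= p_detect
    values = latent.mask(dropped)
    truth.censored_cells = [
        (ids[i], samples[j]) for i, j in zip(*np.nonzero(dropped))
    ]
    qm = QuantMatrix(values=values, design=_design_from_samples(samples))
    return qm, truth


def simulate_timecourse(
    cfg: SimulationConfig,
    profiles: dict[str, list[float]] | None = None,
    condition: str = "pulse",
) -> tuple[QuantMatrix, pd.DataFrame, GroundTruth]:
    """Pulse-labeling time-course matrix plus a heavy-label peptide table.

    ``profiles`` maps protein id to per-window log2 means for proteins with
    planted dynamics; all other proteins are flat at their latent baseline.
    The companion peptide table assigns each peptide the heavy-lysine label
    with probability ``cfg.lys8_fraction``.
    """
    cfg.validate()
    windows = list(cfg.time_windows)
    if len(windows) < 2:
        raise ValueError("need at least 2 time windows")
    rng_ab, rng_noise, rng_cens, rng_pep = _spawn(cfg.seed, 4)
    n = cfg.n_proteins
    ids = [f"P{i + 1:05d}" for i in range(n)]
    if profiles:
        unknown = sorted(set(profiles) - set(ids))
        if unknown:
            raise ValueError(f"profiles reference unknown proteins: {unknown}")
        for pid, prof in profiles.items():
            if len(prof) != len(windows):
                raise ValueError(
                    f"profile for {pid} has {len(prof)} values for {len(windows)} windows"
                )

    base = rng_ab.normal(cfg.base_log2_mu, cfg.base_log2_sigma, size=n)
    samples = [
        f"{condition}@{w}_{r + 1}" for w in windows for r in range(cfg.n_replicates)
    ]
    sd_log2 = np.sqrt(np.log1p(cfg.replicate_cv**2)) / np.log(2.0)

    means = np.tile(base[:, None], (1, len(windows)))
    truth = GroundTruth(latent_log2={pid: float(b) for pid, b in zip(ids, base)})
    if profiles:
        for pid, prof in profiles.items():
            means[ids.index(pid), :] = prof
            truth.true_de[pid] = [float(v) for v in prof]

    cols = {}
    for wi, w in enumerate(windows):
        for r in range(cfg.n_replicates):
            cols[f"{condition}@{w}_{r + 1}"] = means[:, wi] + rng_noise.normal(
                0, sd_log2, n
            )
    latent = pd.DataFrame(cols, index=pd.Index(ids, name="protein"))[samples]
    p_detect = _detect_prob(latent.to_numpy(), cfg.missing_curve)
    dropped = rng_cens.random(latent.shape) >= p_detect
    values = latent.mask(dropped)
    truth.censored_cells = [(ids[i], samples[j]) for i, j in zip(*np.nonzero(dropped))]
    qm = QuantMatrix(values=values, design=_design_from_samples(samples))

    # Peptide-level companion: heavy-lysine labeling specificity.
    lo, hi = cfg.peptides_per_protein
    pep_rows = []
    seen: set[str] = set()
    for pid in ids:
        for _ in range(int(rng_pep.integers(lo, hi + 1))):
            seq = None
            while seq is None or seq in seen:
                seq = _random_sequence(rng_pep, n_thr=1)[:-1] + "K"
            seen.add(seq)
            heavy = rng_pep.random() < cfg.lys8_fraction
            mods = f"Lys8@{len(seq)}" if heavy else "Unmodified"
            intensity = float(
                2.0 ** rng_pep.normal(cfg.base_log2_mu, cfg.base_log2_sigma)
            )
            row = {
                "Sequence": seq,
                "Modifications": mods,
                "Proteins": pid,
                "Charge": 2,
            }
            for r in range(cfg.n_replicates):
                row[f"Intensity {condition}@{windows[0]}_{r + 1}"] = intensity * float(
                    _noise(rng_pep, cfg.replicate_cv, 1)[0]
                )
            pep_rows.append(row)
    peptides = pd.DataFrame(pep_rows)
    return qm, peptides, truth
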