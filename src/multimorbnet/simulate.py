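"""Synthetic inpatient cohorts with known marginals and planted odds ratios.

The generator draws, per stratum (sex × age band), one baseline record per
synthetic patient.  A record's disease set is assembled from:

* planted disease pairs, each sampled exactly from the 2×2 joint
  distribution that matches the two marginal prevalences and a target odds
  ratio (the Plackett construction, :func:`joint_from_or`) — planted pairs
  are pairwise disjoint in their disease support, which is what makes the
  exact sampling possible;
* background diseases, independent Bernoulli draws at their marginals, so
  every non-planted pair is independent by construction.

Pairs can be planted in both sexes or in one sex only, emulating shared
versus sex-specific multimorbidity patterns.  Records that come out with
no disease at all are redrawn (the ingest stage rejects empty code sets);
the redraw count is kept in the ground-truth manifest because redraws bias
marginals slightly upward.

A :class:`GroundTruth` manifest records the exact joint cells of every
planted pair per stratum and which pairs should exceed odds ratio 1, so
recovery of the planted structure can be scored without re-deriving it.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from .icd10 import chapter_of
from .ingest import AdmissionRecord, Dialect, write_records

__all__ = [
    "PlantedPair",
    "SyntheticConfig",
    "GroundTruth",
    "joint_from_or",
    "generate_records",
    "write_fixture",
    "make_catalog",
    "study_config",
    "recovery_config",
    "decomposition_config",
]

Scope = Literal["both_sexes", "male_only", "female_only"]


@dataclass(frozen=True, slots=True)
class PlantedPair:
    """A disease pair planted with a target odds ratio in some sex scope."""

    x: str
    y: str
    target_or: float
    scope: Scope = "both_sexes"

    def applies_to(self, sex: str) -> bool:
        return self.scope == "both_sexes" or self.scope == f"{sex}_only"


@dataclass(frozen=True)
class SyntheticConfig:
    """Full generative specification of a synthetic multi-stratum cohort."""

    seed: int
    #: (sex, (age_lo, age_hi), n_records) per stratum
    strata: tuple[tuple[str, tuple[int, int], int], ...]
    #: code3 -> marginal prevalence, planted-pair diseases included
    catalog: dict[str, float]
    planted_pairs: tuple[PlantedPair, ...] = ()

    def __post_init__(self) -> None:
        support: set[str] = set()
        for p in self.planted_pairs:
            if p.x == p.y:
                raise ValueError(f"planted pair {p.x}-{p.y} is degenerate")
            if p.x in support or p.y in support:
                raise ValueError(
                    f"planted pairs must be disease-disjoint; {p.x} or {p.y} reused"
                )
            if p.target_or <= 0:
                raise ValueError("target odds ratio must be positive")
            support |= {p.x, p.y}
        for code, m in self.catalog.items():
            if not 0 < m < 1:
                raise ValueError(f"marginal of {code} must lie in (0,1), got {m}")
            chapter_of(code)  # must be a valid category
        missing = support - set(self.catalog)
        if missing:
            raise ValueError(f"planted diseases missing from catalog: {sorted(missing)}")


@dataclass
class GroundTruth:
    """What was actually planted, per stratum."""

    #: stratum label -> pair "X|Y" -> {cells, target_or, scope}
    planted: dict[str, dict[str, dict]] = field(default_factory=dict)
    #: stratum label -> pair keys expected to have OR > 1
    positive_pairs: dict[str, list[str]] = field(default_factory=dict)
    redraws: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def pair_key(x: str, y: str) -> str:
        return "|".join(sorted((x, y)))

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted": self.planted,
                "positive_pairs": self.positive_pairs,
                "redraws": self.redraws,
            },
            indent=2,
            sort_keys=True,
        )


def joint_from_or(p_x: float, p_y: float, psi: float) -> tuple[float, float, float, float]:
    """2×2 cell probabilities (p11, p10, p01, p00) with given marginals and OR.

    Solves the Plackett equation psi·(p_x−p11)(p_y−p11) = p11·(1−p_x−p_y+p11)
    for the joint cell p11; the admissible root lies in the Fréchet interval
    [max(0, p_x+p_y−1), min(p_x, p_y)].  The returned cells reproduce psi as
    their cross-product ratio.
    """
    if not (0 < p_x < 1 and 0 < p_y < 1):
        raise ValueError(f"marginals must lie in (0,1): {p_x}, {p_y}")
    if psi <= 0:
        raise ValueError(f"odds ratio must be positive: {psi}")
    if psi == 1.0:
        p11 = p_x * p_y
    else:
        a = psi - 1.0
        b = 1.0 + (p_x + p_y) * a
        c = psi * p_x * p_y
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError(f"no admissible joint for p_x={p_x}, p_y={p_y}, psi={psi}")
        p11 = (b - np.sqrt(disc)) / (2.0 * a)
    lo, hi = max(0.0, p_x + p_y - 1.0), min(p_x, p_y)
    if not (lo - 1e-12 <= p11 <= hi + 1e-12):
        raise ValueError(
            f"root {p11} outside Fréchet bounds [{lo}, {hi}] for p_x={p_x}, p_y={p_y}, psi={psi}"
        )
    p11 = min(max(p11, lo), hi)
    cells = (p11, p_x - p11, p_y - p11, 1.0 - p_x - p_y + p11)
    if any(v < -1e-12 for v in cells):
        raise ValueError(f"negative cell for p_x={p_x}, p_y={p_y}, psi={psi}: {cells}")
    return tuple(max(v, 0.0) for v in cells)  # type: ignore[return-value]


def _stratum_label(sex: str, band: tuple[int, int]) -> str:
    return f"{sex}_{band[0]}-{band[1]}"


def _sample_stratum(
    rng: np.random.Generator,
    n: int,
    pair_cells: list[tuple[str, str, tuple[float, float, float, float]]],
    background: list[tuple[str, float]],
) -> tuple[np.ndarray, list[str], int]:
    """Boolean disease matrix for one stratum; empty rows redrawn."""
    codes = [c for x, y, _ in pair_cells for c in (x, y)] + [c for c, _ in background]
    bg_p = np.array([m for _, m in background])

    def draw(k: int) -> np.ndarray:
        cols = []
        for _, _, (p11, p10, p01, _) in pair_cells:
            u = rng.random(k)
            has_x = u < p11 + p10
            has_y = (u < p11) | ((u >= p11 + p10) & (u < p11 + p10 + p01))
            cols.append(has_x)
            cols.append(has_y)
        if len(bg_p):
            bg = rng.random((k, len(bg_p))) < bg_p
        else:
            bg = np.zeros((k, 0), dtype=bool)
        planted = np.column_stack(cols) if cols else np.zeros((k, 0), dtype=bool)
        return np.hstack([planted, bg])

    mat = draw(n)
    redraws = 0
    for _ in range(1000):  # practically unreachable cap
        empty = ~mat.any(axis=1)
        k = int(empty.sum())
        if k == 0:
            break
        redraws += k
        mat[empty] = draw(k)
    return mat, codes, redraws


def generate_records(
    config: SyntheticConfig,
) -> tuple[list[AdmissionRecord], GroundTruth]:
    """Draw the full multi-stratum cohort; byte-identical for a fixed seed.

    One record per synthetic patient; ages uniform within the band,
    admission dates constant (baseline selection is exercised by dedicated
    multi-admission fixtures, not here).
    """
    truth = GroundTruth()
    records: list[AdmissionRecord] = []
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.strata))
    planted_support = {c for p in config.planted_pairs for c in (p.x, p.y)}
    background = sorted(
        (c, m) for c, m in config.catalog.items() if c not in planted_support
    )
    counter = 0
    for (sex, band, n), ss in zip(config.strata, streams):
        rng = np.random.default_rng(ss)
        label = _stratum_label(sex, band)
        active = [p for p in config.planted_pairs if p.applies_to(sex)]
        pair_cells = [
            (p.x, p.y, joint_from_or(config.catalog[p.x], config.catalog[p.y], p.target_or))
            for p in active
        ]
        # diseases of pairs not planted in this sex still appear, independently
        inactive_bg = sorted(
            (c, config.catalog[c])
            for p in config.planted_pairs
            if not p.applies_to(sex)
            for c in (p.x, p.y)
        )
        mat, codes, redraws = _sample_stratum(rng, n, pair_cells, background + inactive_bg)
        ages = rng.integers(band[0], band[1] + 1, size=n)
        truth.redraws[label] = redraws
        truth.planted[label] = {
            GroundTruth.pair_key(x, y): {
                "cells": list(cells),
                "target_or": p.target_or,
                "scope": p.scope,
            }
            for (x, y, cells), p in zip(pair_cells, active)
        }
        truth.positive_pairs[label] = sorted(
            GroundTruth.pair_key(p.x, p.y) for p in active if p.target_or > 1
        )
        code_arr = np.array(codes)
        for i in range(n):
            counter += 1
            records.append(
                AdmissionRecord(
                    record_id=f"r{counter:07d}",
                    patient_id=f"p{counter:07d}",
                    sex=sex,  # type: ignore[arg-type]
                    age_years=int(ages[i]),
                    admission_date=_dt.date(2010, 1, 1),
                    codes=frozenset(code_arr[mat[i]].tolist()),
                )
            )
    return records, truth


def write_fixture(
    records: Sequence[AdmissionRecord],
    truth: GroundTruth,
    out_dir: str | Path,
    dialect: Dialect | None = None,
) -> tuple[Path, Path]:
    """Emit the cohort table plus the ground-truth manifest under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort_path = out / "cohort.csv"
    truth_path = out / "ground_truth.json"
    write_records(records, cohort_path, dialect)
    truth_path.write_text(truth.to_json())
    return cohort_path, truth_path


# ---------------------------------------------------------------------------
# Ready-made configurations

# per-chapter (letter, lo, hi) blocks of valid 3-character categories
_CHAPTER_BLOCKS = {
    1: ("A", 0, 99), 2: ("C", 0, 97), 3: ("D", 50, 89), 4: ("E", 0, 90),
    5: ("F", 0, 99), 6: ("G", 0, 99), 7: ("H", 0, 59), 8: ("H", 60, 95),
    9: ("I", 0, 99), 10: ("J", 0, 99), 11: ("K", 0, 93), 12: ("L", 0, 99),
    13: ("M", 0, 99), 14: ("N", 0, 99),
}


def make_catalog(
    n_diseases: int,
    seed: int,
    marginal_range: tuple[float, float] = (0.002, 0.03),
) -> dict[str, float]:
    """A disease catalog spread across Chapters 1–14, log-uniform marginals."""
    rng = np.random.default_rng(seed)
    codes: list[str] = []
    i = 0
    while len(codes) < n_diseases:
        chapter = (i % 14) + 1
        letter, lo, hi = _CHAPTER_BLOCKS[chapter]
        offset = i // 14
        if lo + offset > hi:
            i += 1
            continue
        codes.append(f"{letter}{lo + offset:02d}")
        i += 1
    lo_m, hi_m = marginal_range
    marg = np.exp(rng.uniform(np.log(lo_m), np.log(hi_m), size=n_diseases))
    return dict(zip(codes, marg.round(6).tolist()))


def study_config(seed: int, scale: float = 0.1) -> SyntheticConfig:
    """A cohort emulating the study's structure at a reduced size.

    Eight sex × age strata with record counts proportional to the Chinese
    inpatient cohort (scaled by ``scale``), a 260-disease catalog over
    Chapters 1–14, and planted pattern sets: shared pairs in both sexes
    plus male-only and female-only pairs, odds ratios 2–8.
    """
    male_n = [30167, 31655, 25402, 16110]
    female_n = [20956, 24751, 21550, 13542]
    bands = [(40, 44), (45, 49), (50, 54), (55, 59)]
    strata = tuple(
        [("male", b, max(200, int(n * scale))) for b, n in zip(bands, male_n)]
        + [("female", b, max(200, int(n * scale))) for b, n in zip(bands, female_n)]
    )
    catalog = make_catalog(260, seed=seed)
    rng = np.random.default_rng(seed + 1)
    codes = sorted(catalog)
    chosen = rng.choice(len(codes), size=36, replace=False)
    # planted diseases get marginals in a band where detection is realistic
    pair_codes = [codes[i] for i in chosen]
    for c in pair_codes:
        catalog[c] = float(np.round(np.exp(rng.uniform(np.log(0.03), np.log(0.10))), 6))
    scopes = ["both_sexes"] * 8 + ["male_only"] * 5 + ["female_only"] * 5
    ors = [2.0, 4.0, 8.0, 2.0, 4.0, 8.0, 4.0, 8.0, 4.0, 8.0, 2.0, 4.0, 8.0, 4.0, 8.0, 2.0, 4.0, 8.0]
    pairs = tuple(
        PlantedPair(x=pair_codes[2 * i], y=pair_codes[2 * i + 1], target_or=ors[i], scope=s)
        for i, s in enumerate(scopes)
    )
    return SyntheticConfig(seed=seed, strata=strata, catalog=catalog, planted_pairs=pairs)


def decomposition_config(
    seed: int,
    n_per_sex: int = 25_000,
    n_background: int = 200,
) -> SyntheticConfig:
    """The sex-decomposition benchmark: one male and one female stratum.

    Plants 8 shared pairs, 5 male-only pairs and 5 female-only pairs with
    odds ratios in {4, 8} — strong, structural effects, since the question
    here is which derived network a pattern lands in, not dose-response.
    Marginals of planted diseases are drawn in 0.03–0.10.
    """
    n_pairs = 18
    catalog = make_catalog(n_background + 2 * n_pairs, seed=seed)
    rng = np.random.default_rng(seed + 1)
    codes = sorted(catalog)
    chosen = rng.choice(len(codes), size=2 * n_pairs, replace=False)
    pair_codes = [codes[i] for i in chosen]
    for c in pair_codes:
        catalog[c] = float(np.round(rng.uniform(0.03, 0.10), 6))
    scopes: list[Scope] = ["both_sexes"] * 8 + ["male_only"] * 5 + ["female_only"] * 5
    ors = [4.0, 8.0] * 9
    pairs = tuple(
        PlantedPair(x=pair_codes[2 * i], y=pair_codes[2 * i + 1], target_or=ors[i], scope=s)
        for i, s in enumerate(scopes)
    )
    return SyntheticConfig(
        seed=seed,
        strata=(("male", (40, 59), n_per_sex), ("female", (40, 59), n_per_sex)),
        catalog=catalog,
        planted_pairs=pairs,
    )


def recovery_config(
    seed: int,
    n_records: int = 50_000,
    n_pairs: int = 30,
    n_background: int = 200,
    psis: Sequence[float] = (2.0, 4.0, 8.0),
) -> SyntheticConfig:
    """The parameter-recovery benchmark: one stratum, 30 planted pairs.

    All disease marginals are drawn in 0.03–0.10 — planted and background
    alike, so every pair sits in the regime where the Wald test is well
    calibrated; the planted odds ratios cycle through ``psis``; the 200
    background diseases are independent of everything.
    """
    catalog = make_catalog(n_background + 2 * n_pairs, seed=seed, marginal_range=(0.03, 0.10))
    rng = np.random.default_rng(seed + 1)
    codes = sorted(catalog)
    chosen = rng.choice(len(codes), size=2 * n_pairs, replace=False)
    pair_codes = [codes[i] for i in chosen]
    for c in pair_codes:
        catalog[c] = float(np.round(rng.uniform(0.03, 0.10), 6))
    pairs = tuple(
        PlantedPair(
            x=pair_codes[2 * i],
            y=pair_codes[2 * i + 1],
            target_or=float(psis[i % len(psis)]),
        )
        for i in range(n_pairs)
    )
    return SyntheticConfig(
        seed=seed,
        strata=(("male", (40, 59), n_records),),
        catalog=catalog,
        planted_pairs=pairs,
    )
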