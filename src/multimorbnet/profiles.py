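"""Descriptive multimorbidity profiles per cohort stratum.

A stratum profile counts distinct diseases, total diagnoses, and the
single / multimorbidity (>=2 diseases) / complex multimorbidity (>=4
diseases) decomposition of inpatients, with percentages of the stratum
size.  Percentages are kept at full precision internally and rounded
half-up to 2 decimals only for presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .ingest import CohortStratum

__all__ = ["MultimorbidityProfile", "profile", "prevalence_ratio", "round_half_up", "pct"]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round with ties away from zero (presentation convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def pct(part: int | float, whole: int | float) -> float:
    """100·part/whole at full precision; NaN for an empty denominator."""
    if whole == 0:
        return float("nan")
    return 100.0 * part / whole


@dataclass(frozen=True)
class MultimorbidityProfile:
    """Stratum-level counts and percentages of multimorbidity burden."""

    label: str
    n_records: int
    n_diseases: int
    n_diagnoses: int
    n_single: int
    n_multi: int
    n_complex: int

    @property
    def pct_single(self) -> float:
        return pct(self.n_single, self.n_records)

    @property
    def pct_multi(self) -> float:
        return pct(self.n_multi, self.n_records)

    @property
    def pct_complex(self) -> float:
        return pct(self.n_complex, self.n_records)

    @property
    def diagnoses_per_capita(self) -> float:
        if self.n_records == 0:
            return float("nan")
        return self.n_diagnoses / self.n_records

    @classmethod
    def from_counts(
        cls,
        n_records: int,
        n_multi: int,
        n_complex: int = 0,
        n_diseases: int = 0,
        n_diagnoses: int = 0,
        label: str = "",
    ) -> "MultimorbidityProfile":
        """Build a profile from already-tabulated counts (e.g. a published table)."""
        return cls(
            label=label,
            n_records=n_records,
            n_diseases=n_diseases,
            n_diagnoses=n_diagnoses,
            n_single=n_records - n_multi,
            n_multi=n_multi,
            n_complex=n_complex,
        )

    def as_row(self) -> dict:
        return {
            "stratum": self.label,
            "n_records": self.n_records,
            "n_diseases": self.n_diseases,
            "n_diagnoses": self.n_diagnoses,
            "diagnoses_per_capita": round_half_up(self.diagnoses_per_capita)
            if self.n_records
            else float("nan"),
            "n_single": self.n_single,
            "pct_single": round_half_up(self.pct_single) if self.n_records else float("nan"),
            "n_multi": self.n_multi,
            "pct_multi": round_half_up(self.pct_multi) if self.n_records else float("nan"),
            "n_complex": self.n_complex,
            "pct_complex": round_half_up(self.pct_complex) if self.n_records else float("nan"),
        }


def profile(stratum: CohortStratum) -> MultimorbidityProfile:
    """Count the stratum's disease burden.

    ``n_diagnoses`` sums distinct 3-character categories over records (a
    record with {I10, E11} contributes 2); ``n_diseases`` counts distinct
    categories observed anywhere in the stratum.
    """
    sizes = [len(r.codes) for r in stratum.records]
    return MultimorbidityProfile(
        label=stratum.label,
        n_records=stratum.n_records,
        n_diseases=len(stratum.observed_codes()),
        n_diagnoses=sum(sizes),
        n_single=sum(1 for s in sizes if s == 1),
        n_multi=sum(1 for s in sizes if s >= 2),
        n_complex=sum(1 for s in sizes if s >= 4),
    )


def prevalence_ratio(p_a: float, p_b: float) -> float:
    """Fold difference between two prevalences (presented as e.g. ``1.06×``).

    Raises ``ZeroDivisionError`` on a zero reference prevalence.
    """
    if p_b == 0:
        raise ZeroDivisionError("reference prevalence is zero; fold undefined")
    return p_a / p_b
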