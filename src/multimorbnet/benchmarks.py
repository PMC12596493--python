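"""Seeded validation benchmarks on synthetic cohorts.

These run the full generate → ingest → network path against the
ground-truth manifest of the generator:

* :func:`run_recovery` — can the network construction find pairs planted
  with a known odds ratio, how accurately does it estimate them, and does
  the Bonferroni correction keep false background edges out?
* :func:`run_decomposition` — do sex-scoped planted patterns land in the
  sex-specific network and shared patterns in the sex-overlapped network?
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .ingest import stratify
from .netalgebra import overlapped, specific
from .netbuild import build_network
from .simulate import (
    GroundTruth,
    decomposition_config,
    generate_records,
    recovery_config,
)

__all__ = ["RecoveryResult", "DecompositionResult", "run_recovery", "run_decomposition"]


@dataclass(frozen=True)
class RecoveryResult:
    n_records: int
    n_planted: int
    n_strong: int            # planted pairs with target OR >= 4
    strong_recovered: int
    planted_recovered: int
    false_edges: int         # accepted edges not planted
    n_null_pairs: int        # candidate pairs with no planted association
    max_abs_log_or_error: float  # over recovered planted pairs
    mean_abs_log_or_error: float

    @property
    def strong_recovery_rate(self) -> float:
        return self.strong_recovered / self.n_strong


def run_recovery(seed: int, n_records: int = 50_000) -> RecoveryResult:
    """One parameter-recovery run at the benchmark's study conditions."""
    cfg = recovery_config(seed=seed, n_records=n_records)
    records, truth = generate_records(cfg)
    stratum = stratify(records, "all")["all_40-59"]
    net = build_network(stratum)

    planted = truth.planted["male_40-59"]
    strong = {k for k, v in planted.items() if v["target_or"] >= 4}
    accepted = {"|".join(e.key): e for e in net.edges}

    errors = [
        abs(math.log(accepted[k].odds_ratio) - math.log(planted[k]["target_or"]))
        for k in planted
        if k in accepted
    ]
    n_diseases = len(cfg.catalog)
    return RecoveryResult(
        n_records=n_records,
        n_planted=len(planted),
        n_strong=len(strong),
        strong_recovered=len(strong & set(accepted)),
        planted_recovered=len(set(planted) & set(accepted)),
        false_edges=len(set(accepted) - set(planted)),
        n_null_pairs=n_diseases * (n_diseases - 1) // 2 - len(planted),
        max_abs_log_or_error=max(errors) if errors else float("nan"),
        mean_abs_log_or_error=sum(errors) / len(errors) if errors else float("nan"),
    )


@dataclass(frozen=True)
class DecompositionResult:
    n_male_only: int
    male_only_in_specific: int
    male_only_in_overlapped: int
    n_shared: int
    shared_in_overlapped: int
    identity_holds: bool


def run_decomposition(seed: int, n_per_sex: int = 25_000) -> DecompositionResult:
    """One sex-decomposition run: where do scoped planted patterns land?"""
    cfg = decomposition_config(seed=seed, n_per_sex=n_per_sex)
    records, truth = generate_records(cfg)
    strata = stratify(records, "sex")
    male = build_network(strata["male_40-59"])
    female = build_network(strata["female_40-59"])
    shared_net = overlapped(male, female)
    male_spec = specific(male, female)

    def keys(net):
        return {"|".join(e.key) for e in net.edges}

    male_planted = truth.planted["male_40-59"]
    male_only = {k for k, v in male_planted.items() if v["scope"] == "male_only"}
    shared = {k for k, v in male_planted.items() if v["scope"] == "both_sexes"}
    return DecompositionResult(
        n_male_only=len(male_only),
        male_only_in_specific=len(male_only & keys(male_spec)),
        male_only_in_overlapped=len(male_only & keys(shared_net)),
        n_shared=len(shared),
        shared_in_overlapped=len(shared & keys(shared_net)),
        identity_holds=male.n_edges == male_spec.n_edges + shared_net.n_edges,
    )
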