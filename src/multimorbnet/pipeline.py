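"""End-to-end orchestration: cohort in, three-level networks and summary out.

``run_pipeline`` executes the full analysis from one configuration:

1. ingest (or simulate) the cohort and apply the record-level filters;
2. profile every stratum (overall, per sex, per sex × age band);
3. build the complete multimorbidity network per stratum;
4. derive sex-specific and sex-overlapped networks and check the
   decomposition identity |complete| = |specific| + |overlapped|;
5. compute node metrics, hubs, hub and hub-associated networks, coverage;
6. aggregate pattern frequencies to ICD-10 chapters and rank them.

All artifacts land under the output directory: a master summary TSV with
one row per stratum (record counts, multimorbidity split, network sizes,
hub coverage), edge TSV + GraphML per network, per-node metrics TSV,
chapter tables, and a JSON log of every criterion value including the
realized Bonferroni N per network.  Runs are deterministic for a fixed
configuration and seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from . import netalgebra, netmetrics
from .chapters import chapter_frequencies, rank_trajectories
from .ingest import CohortStratum, Dialect, FilterReport, read_records
from .netbuild import MultimorbidityNetwork, NetworkCriteria, build_network
from .netio import criteria_provenance, metrics_to_frame, write_edge_tsv, write_graphml
from .profiles import MultimorbidityProfile, profile, round_half_up
from .simulate import SyntheticConfig, generate_records

__all__ = ["RunConfig", "RunResult", "run_pipeline", "export_network"]


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: input, thresholds, attribution mode, output directory."""

    out_dir: str | Path
    input_path: str | Path | None = None
    simulate: SyntheticConfig | None = None
    dialect: Dialect = field(default_factory=Dialect)
    criteria: NetworkCriteria = field(default_factory=NetworkCriteria)
    hub_k: int = 10
    attribution: Literal["dual", "half"] = "dual"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("provide exactly one of input_path or simulate")
        if not (0 < self.criteria.alpha < 1) or self.criteria.prevalence_floor < 0:
            raise ValueError("criteria out of range")
        if self.hub_k < 1:
            raise ValueError("hub_k must be positive")


@dataclass
class RunResult:
    """In-memory handles to everything a run produced."""

    profiles: dict[str, MultimorbidityProfile]
    networks: dict[str, MultimorbidityNetwork]
    hubs: dict[str, netmetrics.HubSet]
    coverage: dict[str, dict[str, netmetrics.CoverageStats]]
    summary: pd.DataFrame
    filter_report: FilterReport
    identity_checks: dict[str, dict]


def export_network(
    net: MultimorbidityNetwork,
    out_dir: str | Path,
    fmt: Literal["graphml", "tsv"] = "tsv",
    metrics: dict | None = None,
    hubs: netmetrics.HubSet | None = None,
) -> Path:
    """Write one network (plus provenance) in the requested format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = f"{net.stratum_label}_{net.operation}"
    if fmt == "tsv":
        path = out / f"{stem}.edges.tsv"
        write_edge_tsv(path, net)
    elif fmt == "graphml":
        path = out / f"{stem}.graphml"
        write_graphml(path, net, metrics=metrics, hubs=hubs)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    (out / f"{stem}.provenance.json").write_text(criteria_provenance(net))
    return path


def _hub_block(
    net: MultimorbidityNetwork, k: int
) -> tuple[netmetrics.HubSet | None, dict[str, netmetrics.CoverageStats], dict]:
    if net.n_edges == 0:
        return None, {}, {}
    metrics = netmetrics.compute_metrics(net)
    hubs = netmetrics.top_hubs(net, k=k, metrics=metrics)
    hub_net = netmetrics.hub_network(net, hubs)
    assoc = netmetrics.hub_associated_network(net, hubs)
    cov = {
        "hub": netmetrics.coverage(hub_net, net),
        "hub_associated": netmetrics.coverage(assoc, net),
    }
    return hubs, cov, metrics


def _summary_row(
    prof: MultimorbidityProfile,
    net: MultimorbidityNetwork,
    hubs: netmetrics.HubSet | None,
    cov: Mapping[str, netmetrics.CoverageStats],
) -> dict:
    row = prof.as_row()
    row.update(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        bonferroni_n=net.criteria.n_bonferroni,
        total_pattern_frequency=net.total_pattern_frequency,
    )
    if hubs is not None and "hub_associated" in cov:
        ha = cov["hub_associated"]
        row.update(
            n_hubs=len(tuple(hubs)),
            hub_assoc_nodes=ha.node_count,
            hub_assoc_node_pct=round_half_up(ha.node_pct),
            hub_assoc_edges=ha.edge_count,
            hub_assoc_edge_pct=round_half_up(ha.edge_pct),
            hub_assoc_freq=ha.freq_total,
            hub_assoc_freq_pct=round_half_up(ha.freq_pct),
        )
    return row


def _audit_summary(df: pd.DataFrame) -> None:
    """Recompute every derived percentage from the summary's own counts."""
    for row in df.itertuples(index=False):
        if row.n_records:
            assert row.pct_multi == round_half_up(100 * row.n_multi / row.n_records)
            assert row.n_single + row.n_multi == row.n_records


def run_pipeline(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    report = FilterReport()
    if config.simulate is not None:
        records, truth = generate_records(config.simulate)
        (out / "ground_truth.json").write_text(truth.to_json())
    else:
        records, report = read_records(config.input_path, config.dialect)

    # filter once, stratify three ways (labels of the schemes never collide)
    from .ingest import filter_scope, normalize_records, select_baseline, stratify

    normed = normalize_records(records, report)
    scoped = [r for r in (filter_scope(rec, report) for rec in normed) if r is not None]
    baseline = select_baseline(scoped, report)
    aged = [r for r in baseline if 40 <= r.age_years <= 59]
    report.age_out_of_range += len(baseline) - len(aged)
    strata: dict[str, CohortStratum] = {}
    for scheme in ("all", "sex", "sex_age"):
        strata.update(stratify(aged, scheme))
    (out / "filter_report.json").write_text(report.to_json())

    profiles: dict[str, MultimorbidityProfile] = {}
    networks: dict[str, MultimorbidityNetwork] = {}
    hubs: dict[str, netmetrics.HubSet] = {}
    coverage: dict[str, dict[str, netmetrics.CoverageStats]] = {}
    rows = []
    for label, stratum in strata.items():
        prof = profile(stratum)
        net = build_network(stratum, config.criteria)
        profiles[label] = prof
        networks[label] = net
        hub_set, cov, metrics = _hub_block(net, config.hub_k)
        if hub_set is not None:
            hubs[label] = hub_set
            coverage[label] = cov
            metrics_to_frame(metrics, hub_set).to_csv(
                out / f"{label}_metrics.tsv", sep="\t", index=False
            )
        export_network(net, out, "tsv")
        export_network(net, out, "graphml", metrics=metrics or None, hubs=hub_set)
        rows.append(_summary_row(prof, net, hub_set, cov))

    # second level: sex-specific and sex-overlapped, with the identity check
    identity: dict[str, dict] = {}
    male_label, female_label = "male_40-59", "female_40-59"
    if male_label in networks and female_label in networks:
        male, female = networks[male_label], networks[female_label]
        shared = netalgebra.overlapped(male, female)
        male_spec = netalgebra.specific(male, female)
        female_spec = netalgebra.specific(female, male)
        for net in (shared, male_spec, female_spec):
            networks[net.stratum_label] = net
            export_network(net, out, "tsv")
        for sex_net, spec in ((male, male_spec), (female, female_spec)):
            identity[sex_net.stratum_label] = {
                "complete": sex_net.n_edges,
                "specific": spec.n_edges,
                "overlapped": shared.n_edges,
                "holds": sex_net.n_edges == spec.n_edges + shared.n_edges,
            }
        assert all(v["holds"] for v in identity.values())
    (out / "identity_checks.json").write_text(json.dumps(identity, indent=2))

    # chapter surfaces: per sex network and rank trajectories across bands
    chapter_rows = []
    for label in (male_label, female_label):
        if label in networks:
            for cf in chapter_frequencies(networks[label], config.attribution):
                chapter_rows.append({"stratum": label, **dataclasses.asdict(cf)})
    if chapter_rows:
        pd.DataFrame(chapter_rows).to_csv(out / "chapter_frequencies.tsv", sep="\t", index=False)
    for sex in ("male", "female"):
        bands = {
            lbl: net
            for lbl, net in networks.items()
            if lbl.startswith(f"{sex}_") and net.operation == "complete" and not lbl.endswith("40-59")
        }
        if len(bands) >= 2:
            pd.DataFrame(rank_trajectories(bands, config.attribution)).to_csv(
                out / f"{sex}_chapter_ranks.tsv", sep="\t", index=False
            )

    summary = pd.DataFrame(rows)
    _audit_summary(summary)
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return RunResult(
        profiles=profiles,
        networks=networks,
        hubs=hubs,
        coverage=coverage,
        summary=summary,
        filter_report=report,
        identity_checks=identity,
    )
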