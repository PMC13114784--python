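"""Composite pipeline: detect -> classify -> stats, with a run report.

The run report mirrors the headline statistics of a detection run
(prevalence, event and family counts, role categories, cross-H-group
fraction, paired sizes, position distribution, top rankings); every
number in it is recomputable from the emitted tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

from . import __version__
from .detect import DEFAULT_MIN_GAP, detect_all
from .families import (
    DEFAULT_MIN_EVENTS,
    HOST_CONSISTENT,
    INSERTION_CONSISTENT,
    VERSATILE,
    aggregate_roles,
    classify_h_groups,
    partnership_counts,
    rank_families,
)
from .io import (
    read_domain_table,
    write_event_table,
    write_partnership_table,
    write_profile_table,
)
from .stats import paired_size_analysis, position_distribution

__all__ = ["run_pipeline", "build_report"]


def build_report(
    proteins, events, summary, profiles, partnerships, cross_fraction,
    *, min_gap: int, min_events: int, seed: int | None = None,
) -> dict:
    """Assemble the run-report dictionary from computed stage outputs."""
    sizes = paired_size_analysis(events)
    role_counts: dict[str, int] = {}
    for p in profiles:
        role_counts[p.role] = role_counts.get(p.role, 0) + 1
    rankings = {
        role: [
            {"f_id": p.family.f_id, "host_events": p.host_events,
             "insert_events": p.insert_events}
            for p in rank_families(profiles, role, 5)
        ]
        for role in (HOST_CONSISTENT, INSERTION_CONSISTENT, VERSATILE)
    }
    return {
        "tool": {"name": "domainsert", "version": __version__},
        "parameters": {"min_gap": min_gap, "min_events": min_events, "seed": seed},
        "input": {
            "n_proteins": summary.n_proteins,
            "n_multidomain": summary.n_multidomain,
        },
        "detection": {
            "n_proteins_with_insertion": summary.n_proteins_with_insertion,
            "prevalence": summary.prevalence,
            "prevalence_undefined": summary.prevalence_undefined,
            "n_events": summary.n_events,
            "n_unique_families_in_events": summary.n_unique_families_in_events,
            "mean_domains_per_insertion_protein": summary.mean_domains_per_insertion_protein,
            "depth_histogram": {str(k): v for k, v in summary.depth_histogram.items()},
        },
        "roles": {
            "category_counts": role_counts,
            "n_family_role_instances": sum(
                (p.host_events > 0) + (p.insert_events > 0) for p in profiles
            ),
        },
        "partnerships": {
            "n_records": len(partnerships),
            "cross_h_group_fraction": cross_fraction,
        },
        "paired_sizes": asdict(sizes),
        "position_distribution": position_distribution(events),
        "h_group_categories": None,  # filled by run_pipeline
        "rankings": rankings,
    }


def run_pipeline(
    domains_path,
    out_dir,
    min_gap: int = DEFAULT_MIN_GAP,
    min_events: int = DEFAULT_MIN_EVENTS,
    strict: bool = False,
    seed: int | None = None,
) -> dict:
    """Run detect -> classify -> stats on a domain table; write all outputs.

    Writes ``events.tsv``, ``profiles.tsv``, ``partnerships.tsv`` and
    ``report.json`` under ``out_dir`` and returns the report dict.
    Deterministic given the input table and parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    proteins, read_report = read_domain_table(domains_path, strict=strict)
    events, summary = detect_all(proteins, min_gap)
    profiles = aggregate_roles(events, min_events)
    partnerships, cross_fraction = partnership_counts(events)
    h_cats = classify_h_groups(profiles, min_events=min_events)

    write_event_table(events, out / "events.tsv")
    write_profile_table(profiles, out / "profiles.tsv")
    write_partnership_table(partnerships, out / "partnerships.tsv")

    report = build_report(
        proteins, events, summary, profiles, partnerships, cross_fraction,
        min_gap=min_gap, min_events=min_events, seed=seed,
    )
    report["input"]["n_rows_rejected"] = len(read_report.rejected)
    cat_counts: dict[str, int] = {}
    for v in h_cats.values():
        cat_counts[v] = cat_counts.get(v, 0) + 1
    report["h_group_categories"] = cat_counts
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
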