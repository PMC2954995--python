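"""End-to-end analysis: selection -> endpoints -> index -> summary tables.

`run_analysis` wires the modules together and returns every output table;
`write_outputs` exports them (CSV per table plus one JSON mirror).  The
severity scale analysed for a sample follows its defining diagnosis: the
bipolar samples are summarised on the bipolar scale (the comorbid
sub-sample additionally on the ADHD scale), the ADHD-only sample on the
ADHD scale.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from . import io as nio
from .endpoints import baseline_days_used, compute_endpoints_frame, endpoints_to_frame
from .io import round_half_away
from .medication import client_medication_index, medication_summary
from .model import ClientProfile, SeverityEndpoints
from .selection import select_samples, selection_report
from .stats import dropout_analysis, split_analyses, summarize_group

__all__ = ["run_analysis", "write_outputs"]

#: (sample label, scale) combinations summarised, mirroring the report tables
SAMPLE_SCALES = (
    ("primary_bipolar", "bipolar"),
    ("bipolar_not_adhd", "bipolar"),
    ("bipolar_and_adhd", "bipolar"),
    ("bipolar_and_adhd", "adhd"),
    ("adhd_not_bipolar", "adhd"),
)


def _ensure_frames(clients, reports, medications):
    cdf = clients if isinstance(clients, pd.DataFrame) else nio.clients_to_frame(list(clients))
    rdf = reports if isinstance(reports, pd.DataFrame) else nio.reports_to_frame(list(reports))
    mdf = (
        medications
        if isinstance(medications, pd.DataFrame)
        else nio.medications_to_frame(list(medications))
    )
    return cdf, rdf, mdf


def _profiles(cdf: pd.DataFrame) -> dict[str, ClientProfile]:
    return {
        str(r.client_id): ClientProfile(
            str(r.client_id),
            int(r.age_years),
            str(r.sex),
            bool(r.dx_bipolar),
            bool(r.dx_adhd),
            int(getattr(r, "treatment_start_day", 0)),
        )
        for r in cdf.itertuples(index=False)
    }


def run_analysis(
    clients,
    reports,
    medications,
    min_days: int = 60,
    window: int = 180,
    welch: bool = True,
) -> dict:
    """Run the full pipeline; inputs may be record lists or DataFrames.

    Returns a dict with the sample definitions, per-client endpoints, and all
    summary tables (severity, responders, medication, dropout, splits,
    selection report).
    """
    cdf, rdf, mdf = _ensure_frames(clients, reports, medications)
    profiles = _profiles(cdf)

    samples = select_samples(profiles.values(), rdf, min_days=min_days, window=window)
    samples_by_label = {s.label: s for s in samples}

    all_endpoints, undefined = compute_endpoints_frame(rdf)
    ep_index: dict[tuple, SeverityEndpoints] = {
        (e.client_id, e.scale): e for e in all_endpoints
    }

    def sample_endpoints(label: str, scale: str) -> list[SeverityEndpoints]:
        ids = sorted(samples_by_label[label].member_ids)
        return [ep_index[(cid, scale)] for cid in ids if (cid, scale) in ep_index]

    severity_rows = []
    responder_rows = []
    for label, scale in SAMPLE_SCALES:
        eps = sample_endpoints(label, scale)
        if len(eps) < 2:
            continue
        s = summarize_group(eps, f"{label}[{scale}]")
        severity_rows.append(s)
        n_def = s.n - s.n_pct_undefined
        responder_rows.append(
            {
                "sample": label,
                "scale": scale,
                "n": n_def,
                "pct_reduction_gt_30": int(round_half_away(100.0 * s.frac_reduction_gt_30)),
                "pct_reduction_gt_50": int(round_half_away(100.0 * s.frac_reduction_gt_50)),
            }
        )

    primary_eps = sample_endpoints("primary_bipolar", "bipolar")
    splits = (
        split_analyses(primary_eps, profiles, label_prefix="primary_bipolar:", welch=welch)
        if len(primary_eps) >= 4
        else {}
    )
    dropout = dropout_analysis(primary_eps, welch=welch) if len(primary_eps) >= 2 else None

    # medication indices, per sample, on the sample's defining scale
    med_summaries = []
    indices_by_sample: dict[str, list] = {}
    by_scale_reports = {sc: g for sc, g in rdf.groupby("scale")}
    med_by_client = {cid: g for cid, g in mdf.groupby("client_id")} if len(mdf) else {}
    for label, scale in SAMPLE_SCALES:
        if (label, scale) == ("bipolar_and_adhd", "adhd"):
            continue  # indices are per client, already computed on bipolar scale
        members = sorted(samples_by_label[label].member_ids)
        results = []
        for cid in members:
            ep = ep_index.get((cid, scale))
            if ep is None:
                continue
            creports = by_scale_reports[scale]
            creports = creports[creports["client_id"] == cid]
            bdays = baseline_days_used(creports)
            cmeds = med_by_client.get(cid, pd.DataFrame(columns=mdf.columns))
            results.append(client_medication_index(cmeds, cid, bdays, ep.locf_month))
        indices_by_sample[label] = results
        if results:
            med_summaries.append(medication_summary(label, results))

    return {
        "samples": samples_by_label,
        "selection_report": selection_report(samples),
        "endpoints": all_endpoints,
        "endpoints_frame": endpoints_to_frame(all_endpoints),
        "endpoints_undefined": undefined,
        "summary_severity": severity_rows,
        "summary_responders": pd.DataFrame(responder_rows),
        "summary_medication": pd.concat(med_summaries, ignore_index=True)
        if med_summaries
        else pd.DataFrame(columns=["sample", "measure", "baseline", "locf", "pct_change"]),
        "medication_indices": indices_by_sample,
        "splits": splits,
        "dropout": dropout,
        "metadata": {
            "min_days": min_days,
            "window": window,
            "welch": welch,
            "multiple_testing_correction": "none",
        },
    }


def _split_summaries(splits: Mapping) -> list:
    rows = []
    for spec in splits.values():
        for summary in spec["sides"].values():
            if summary is not None:
                rows.append(summary)
    return rows


def write_outputs(results: dict, outdir) -> dict[str, Path]:
    """Export all tables to ``outdir``; returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    paths["selection_report"] = outdir / "selection_report.csv"
    results["selection_report"].to_csv(paths["selection_report"], index=False)

    paths["endpoints"] = outdir / "endpoints.csv"
    results["endpoints_frame"].to_csv(paths["endpoints"], index=False)

    severity = list(results["summary_severity"]) + _split_summaries(results.get("splits", {}))
    if severity:
        paths["summary_severity"] = outdir / "summary_severity.csv"
        severity_df = nio.write_summary(severity, paths["summary_severity"])
    else:
        severity_df = pd.DataFrame()

    paths["summary_responders"] = outdir / "summary_responders.csv"
    results["summary_responders"].to_csv(paths["summary_responders"], index=False)

    paths["summary_medication"] = outdir / "summary_medication.csv"
    results["summary_medication"].to_csv(paths["summary_medication"], index=False)

    if results.get("dropout") is not None:
        paths["dropout"] = outdir / "dropout.csv"
        results["dropout"]["table"].to_csv(paths["dropout"], index=False)

    paths["tables_json"] = outdir / "tables.json"
    nio.write_tables_json(
        {
            "selection_report": results["selection_report"],
            "summary_severity": severity_df,
            "summary_responders": results["summary_responders"],
            "summary_medication": results["summary_medication"],
            "dropout": results["dropout"]["table"] if results.get("dropout") else None,
            "metadata": results["metadata"],
        },
        paths["tables_json"],
    )
    return paths
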