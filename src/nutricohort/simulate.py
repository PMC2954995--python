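"""Synthetic longitudinal cohorts with the structure the analysis assumes.

The original monitoring database is proprietary, so pipeline testing and
parameter-recovery checks run on generated cohorts calibrated to the printed
cohort moments: bipolar baseline severity ~ mean 17.8, SD 10.1 on the 0-48
scale; a heterogeneous response in which a ~19% minority worsens; last
reported month distributed over months 3/4/5/6 at roughly 18/17/16/49%; 79%
of bipolar clients (41% of ADHD-only clients) medicated at baseline, with
medication tapering coupled to realised improvement.

Per-client model
----------------
Each client draws a latent baseline severity, an effect ``c`` (proportional
reduction; negative for worseners) from a two-component mixture, and a last
reported month.  The latent severity trajectory decays exponentially from
baseline toward ``baseline * (1 - c)`` with a configurable half-life.  On
each reported day the latent level plus Gaussian day-to-day noise is turned
into item scores by independent Binomial(3, p) draws whose expected total
equals the latent level, then clipped to the scale bounds.  Medication doses
start at each medication's personal maximum and step down by a fixed
fraction of that maximum at month boundaries, with a taper probability that
increases logistically with the client's realised improvement.

Everything is driven by one ``numpy.random.default_rng`` seed: identical
seed and config give a byte-identical cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .endpoints import MONTH_DAYS, N_MONTHS
from .io import ITEM_COLUMNS, write_cohort
from .model import SCALE_N_ITEMS, SEVERITY_MAX, SEVERITY_N_ITEMS

__all__ = ["SyntheticCohortConfig", "CohortData", "generate_cohort", "truth_compare"]

#: common psychiatric medications with a typical daily dose (arbitrary units);
#: the index itself is unit-free, these only make the CSVs look realistic
_MED_DOSES = {
    "lithium": 900.0,
    "divalproex": 750.0,
    "risperidone": 2.0,
    "aripiprazole": 10.0,
    "olanzapine": 10.0,
    "quetiapine": 300.0,
    "lamotrigine": 100.0,
    "oxcarbazepine": 600.0,
    "carbamazepine": 400.0,
    "topiramate": 100.0,
    "sertraline": 100.0,
    "escitalopram": 10.0,
    "fluoxetine": 20.0,
    "atomoxetine": 40.0,
    "bupropion": 150.0,
    "venlafaxine": 75.0,
    "paroxetine": 20.0,
    "fluvoxamine": 100.0,
    "buspirone": 15.0,
    "clonazepam": 0.5,
}
_MED_NAMES = tuple(_MED_DOSES)


@dataclass
class SyntheticCohortConfig:
    """Generator settings; the defaults are the study conditions.

    ``improver_mean_reduction`` is the mean proportional reduction among
    improvers before truncation to ``improver_bounds``; ``worsener_frac`` of
    clients instead worsen by a folded-normal proportional increase.
    ``dropout_probs`` is the distribution of the last reported month.
    """

    n_clients: int = 200
    seed: int = 0
    # diagnosis mix: 91 bipolar-only / 29 bipolar+ADHD / 41 ADHD-only
    diag_mix: dict = field(
        default_factory=lambda: {
            "bipolar_only": 91 / 161,
            "bipolar_adhd": 29 / 161,
            "adhd_only": 41 / 161,
        }
    )
    age_range: tuple = (7, 17)  # inclusive, uniform integer years
    frac_female: float = 49 / 120
    bipolar_baseline_mean: float = 17.8
    bipolar_baseline_sd: float = 10.1
    adhd_only_baseline_mean: float = 6.0
    adhd_only_baseline_sd: float = 2.5
    adhd_comorbid_baseline_mean: float = 5.0
    adhd_comorbid_baseline_sd: float = 2.9
    improver_mean_reduction: float = 0.60
    improver_sd: float = 0.25
    improver_bounds: tuple = (0.02, 0.95)
    worsener_frac: float = 0.19
    worsener_mean_increase: float = 0.15
    worsener_sd: float = 0.10
    trajectory_halflife_days: float = 21.0
    daily_noise_sd: float = 2.0
    reporting_rate: float = 0.8
    pre_treatment_days: int = 7
    dropout_probs: dict = field(
        default_factory=lambda: {3: 0.18, 4: 0.17, 5: 0.16, 6: 0.49}
    )
    med_p_any_bipolar: float = 0.79
    med_p_any_adhd_only: float = 0.41
    med_extra_mean: float = 1.06  # medication count = 1 + Poisson(this)
    taper_logit_intercept: float = -1.0
    taper_logit_slope: float = 3.0
    taper_step_frac: float = 0.25

    def validate(self) -> None:
        probs = list(self.diag_mix.values()) + list(self.dropout_probs.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(sum(self.diag_mix.values()) - 1) > 1e-9:
            raise ValueError("diag_mix must sum to 1")
        if abs(sum(self.dropout_probs.values()) - 1) > 1e-9:
            raise ValueError("dropout_probs must sum to 1")
        if set(self.dropout_probs) != {3, 4, 5, 6}:
            raise ValueError("dropout_probs must cover months 3..6")
        if not 0 <= self.worsener_frac <= 1:
            raise ValueError("worsener_frac must lie in [0, 1]")
        if not 0 < self.bipolar_baseline_mean < SEVERITY_MAX["bipolar"]:
            raise ValueError("bipolar baseline mean outside scale bounds")
        if not 0 < self.adhd_only_baseline_mean < SEVERITY_MAX["adhd"]:
            raise ValueError("adhd baseline mean outside scale bounds")
        if not 0 < self.reporting_rate <= 1:
            raise ValueError("reporting_rate must lie in (0, 1]")

    # ---- analytic moments implied by the effect mixture -------------------

    def _improver_mean(self) -> float:
        lo, hi = self.improver_bounds
        mu, sd = self.improver_mean_reduction, self.improver_sd
        if sd == 0:
            return float(min(max(mu, lo), hi))
        return float(sps.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd).mean())

    def _improver_sf(self, threshold: float) -> float:
        lo, hi = self.improver_bounds
        mu, sd = self.improver_mean_reduction, self.improver_sd
        if sd == 0:
            return float(min(max(mu, lo), hi) > threshold)
        return float(sps.truncnorm((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd).sf(threshold))

    def _worsener_mean(self) -> float:
        mu, sd = self.worsener_mean_increase, self.worsener_sd
        if sd == 0:
            return abs(mu)
        return float(sps.foldnorm(abs(mu) / sd, scale=sd).mean())

    def expected_mean_reduction(self) -> float:
        """Population mean proportional reduction implied by the mixture."""
        w = self.worsener_frac
        return float((1 - w) * self._improver_mean() - w * self._worsener_mean())

    def expected_responder_frac(self, threshold: float = 0.5) -> float:
        """Population fraction with true reduction beyond ``threshold``."""
        return float((1 - self.worsener_frac) * self._improver_sf(threshold))

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "dropout_probs" in raw:
            raw["dropout_probs"] = {int(k): float(v) for k, v in raw["dropout_probs"].items()}
        for key in ("age_range", "improver_bounds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        cfg.validate()
        return cfg


class CohortData(NamedTuple):
    """Generated cohort: the three input tables plus the latent truth record."""

    clients: pd.DataFrame
    reports: pd.DataFrame
    medications: pd.DataFrame
    truth: dict

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.clients.to_csv(outdir / "clients.csv", index=False)
        rep = self.reports.drop(columns=["severity"])
        rep = rep.astype({c: "Int64" for c in ITEM_COLUMNS})
        rep.to_csv(outdir / "symptom_reports.csv", index=False)
        self.medications.to_csv(outdir / "medications.csv", index=False)
        (outdir / "truth.json").write_text(json.dumps(self.truth, indent=2))


def _draw_effect(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> float:
    """Proportional reduction; negative values are worsening."""
    if rng.random() < cfg.worsener_frac:
        return -abs(rng.normal(cfg.worsener_mean_increase, cfg.worsener_sd))
    lo, hi = cfg.improver_bounds
    if cfg.improver_sd == 0:
        return float(min(max(cfg.improver_mean_reduction, lo), hi))
    while True:  # truncated normal by rejection; acceptance ~0.95 at defaults
        c = rng.normal(cfg.improver_mean_reduction, cfg.improver_sd)
        if lo <= c <= hi:
            return c


def _latent_level(base: float, c: float, days: np.ndarray, halflife: float) -> np.ndarray:
    """Exponential approach from baseline toward base*(1-c); flat pre-treatment."""
    frac = np.where(days >= 0, 1.0 - np.power(2.0, -np.maximum(days, 0) / halflife), 0.0)
    return base * (1.0 - c * frac)


def _item_block(
    rng: np.random.Generator, level: np.ndarray, scale: str, noise_sd: float
) -> np.ndarray:
    """Integer item scores whose severity total tracks the latent level.

    With ``noise_sd == 0`` the scores are deterministic: the rounded latent
    level is distributed greedily across the severity items (and filler items
    are constant), so a zero-noise configuration reproduces the latent
    trajectory exactly up to integer rounding and scale clipping.
    """
    n_days = level.size
    n_items = SCALE_N_ITEMS[scale]
    n_sev = SEVERITY_N_ITEMS[scale]
    items = np.empty((n_days, n_items), dtype=int)
    if noise_sd == 0:
        target = np.rint(np.clip(level, 0.0, SEVERITY_MAX[scale])).astype(int)
        full, rem = np.divmod(target, 3)
        for k in range(n_sev):
            items[:, k] = np.where(k < full, 3, np.where(k == full, rem, 0))
        if n_items > n_sev:
            items[:, n_sev:] = 1
        return items
    noisy = np.clip(level + rng.normal(0.0, noise_sd, size=n_days), 0.0, SEVERITY_MAX[scale])
    p = noisy / SEVERITY_MAX[scale]
    items[:, :n_sev] = rng.binomial(3, p[:, None], size=(n_days, n_sev))
    if n_items > n_sev:  # filler items outside the severity total (audit only)
        items[:, n_sev:] = rng.binomial(3, 0.3, size=(n_days, n_items - n_sev))
    return items


def generate_cohort(
    config: SyntheticCohortConfig | None = None, seed: int | None = None
) -> CohortData:
    """Generate clients, daily reports and medication records, plus truth.

    ``seed`` overrides ``config.seed``.  The truth record stores every
    client's latent baseline, assigned effect, last reported month and
    medication schedule summary, alongside the analytic moments implied by
    the configuration.
    """
    cfg = config or SyntheticCohortConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    groups = list(cfg.diag_mix)
    group_p = np.array([cfg.diag_mix[g] for g in groups], dtype=float)
    months = np.array(sorted(cfg.dropout_probs), dtype=int)
    month_p = np.array([cfg.dropout_probs[m] for m in months], dtype=float)

    client_rows = []
    report_blocks: list[pd.DataFrame] = []
    med_rows = []
    truth_clients = []

    width = len(str(max(cfg.n_clients, 1)))
    for i in range(cfg.n_clients):
        cid = f"C{i + 1:0{width}d}"
        diag = groups[rng.choice(len(groups), p=group_p)]
        dx_bip = diag != "adhd_only"
        dx_adhd = diag != "bipolar_only"
        age = int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1))
        sex = "female" if rng.random() < cfg.frac_female else "male"
        last_month = int(months[rng.choice(len(months), p=month_p)])
        effect = _draw_effect(rng, cfg)

        base_bip = (
            float(np.clip(rng.normal(cfg.bipolar_baseline_mean, cfg.bipolar_baseline_sd), 1.0, 46.0))
            if dx_bip
            else None
        )
        if diag == "adhd_only":
            base_adhd = float(
                np.clip(rng.normal(cfg.adhd_only_baseline_mean, cfg.adhd_only_baseline_sd), 0.5, 8.5)
            )
        elif diag == "bipolar_adhd":
            base_adhd = float(
                np.clip(
                    rng.normal(cfg.adhd_comorbid_baseline_mean, cfg.adhd_comorbid_baseline_sd),
                    0.5,
                    8.5,
                )
            )
        else:
            base_adhd = None

        # reporting calendar: shared across the client's scales
        pre = np.arange(-cfg.pre_treatment_days, 0)
        post = np.arange(0, MONTH_DAYS * last_month)
        all_days = np.concatenate([pre, post])
        reported = all_days[rng.random(all_days.size) < cfg.reporting_rate]

        for scale, base in (("bipolar", base_bip), ("adhd", base_adhd)):
            if base is None or reported.size == 0:
                continue
            level = _latent_level(base, effect, reported, cfg.trajectory_halflife_days)
            # noise scales with the checklist length so both scales are
            # comparably noisy relative to their range
            noise = cfg.daily_noise_sd * SEVERITY_MAX[scale] / SEVERITY_MAX["bipolar"]
            items = _item_block(rng, level, scale, noise)
            block = pd.DataFrame(items, columns=[f"item_{k+1}" for k in range(items.shape[1])])
            block.insert(0, "scale", scale)
            block.insert(0, "day", reported)
            block.insert(0, "client_id", cid)
            block["severity"] = items[:, : SEVERITY_N_ITEMS[scale]].sum(axis=1)
            report_blocks.append(block)

        # medications: count, names, initial (maximum) doses, monthly taper
        p_any = cfg.med_p_any_bipolar if dx_bip else cfg.med_p_any_adhd_only
        n_meds = 1 + int(rng.poisson(cfg.med_extra_mean)) if rng.random() < p_any else 0
        n_meds = min(n_meds, len(_MED_NAMES))
        true_locf_index = 0.0
        if n_meds:
            names = [_MED_NAMES[k] for k in rng.choice(len(_MED_NAMES), n_meds, replace=False)]
            p_taper = 1.0 / (1.0 + np.exp(-(cfg.taper_logit_intercept + cfg.taper_logit_slope * effect)))
            for med in names:
                initial = _MED_DOSES[med] * float(rng.choice([0.5, 1.0, 1.5, 2.0]))
                med_rows.append((cid, -cfg.pre_treatment_days, med, initial))
                dose = initial
                for m in range(1, last_month + 1):
                    if dose > 0 and rng.random() < p_taper:
                        dose = max(0.0, dose - cfg.taper_step_frac * initial)
                        med_rows.append((cid, MONTH_DAYS * (m - 1), med, round(dose, 4)))
                true_locf_index += dose / initial

        client_rows.append(
            {
                "client_id": cid,
                "age_years": age,
                "sex": sex,
                "dx_bipolar": dx_bip,
                "dx_adhd": dx_adhd,
                "treatment_start_day": 0,
            }
        )
        truth_clients.append(
            {
                "client_id": cid,
                "diag_group": diag,
                "age_years": age,
                "sex": sex,
                "effect": effect,
                "last_month": last_month,
                "base_bipolar": base_bip,
                "base_adhd": base_adhd,
                "n_meds_baseline": n_meds,
                "true_med_index_baseline": float(n_meds),
                "true_med_index_locf": true_locf_index,
            }
        )

    clients = pd.DataFrame(client_rows)
    if report_blocks:
        reports = pd.concat(report_blocks, ignore_index=True)
        for col in ITEM_COLUMNS:
            if col not in reports.columns:
                reports[col] = np.nan
        reports = reports[["client_id", "day", "scale", *ITEM_COLUMNS, "severity"]]
    else:
        reports = pd.DataFrame(columns=["client_id", "day", "scale", *ITEM_COLUMNS, "severity"])
    medications = pd.DataFrame(med_rows, columns=["client_id", "day", "medication", "dose"])

    truth = {
        "config": _config_dict(cfg),
        "configured": {
            "mean_proportional_reduction": cfg.expected_mean_reduction(),
            "worsened_fraction": cfg.worsener_frac,
            "responder_50_fraction": cfg.expected_responder_frac(0.5),
            "dropout_probs": {str(k): v for k, v in cfg.dropout_probs.items()},
        },
        "clients": truth_clients,
    }
    return CohortData(clients, reports, medications, truth)


def _config_dict(cfg: SyntheticCohortConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["age_range"] = list(d["age_range"])
    d["improver_bounds"] = list(d["improver_bounds"])
    d["dropout_probs"] = {str(k): v for k, v in d["dropout_probs"].items()}
    return d


def truth_compare(
    truth: dict,
    endpoints: Sequence,
    med_summary: pd.DataFrame | None = None,
    member_ids: set | None = None,
) -> dict:
    """Recovery report: pipeline estimates vs configured and realised truth.

    ``endpoints`` are SeverityEndpoints from the pipeline; bipolar-scale
    endpoints (restricted to ``member_ids`` when given) drive the severity
    comparisons.  Returns, for the mean proportional reduction, the worsened
    fraction and the responder(>50%) fraction: the pipeline estimate, the
    configured (analytic) value, the realised truth in this cohort, and the
    estimate-minus-configured bias; plus the per-client RMSE of measured vs
    assigned proportional reduction, and the medication percent-change
    comparison when ``med_summary`` is provided.
    """
    truth_by_id = {t["client_id"]: t for t in truth["clients"]}
    eps = [
        e
        for e in endpoints
        if e.scale == "bipolar" and (member_ids is None or e.client_id in member_ids)
    ]
    unknown = {e.client_id for e in eps} - set(truth_by_id)
    if unknown:
        raise ValueError(f"endpoints for clients not in truth record: {sorted(unknown)[:5]}")
    if not eps:
        raise ValueError("no bipolar endpoints to compare")

    base = np.array([e.baseline_severity for e in eps])
    locf = np.array([e.locf_severity for e in eps])
    est_reduction = 1.0 - locf.mean() / base.mean()
    est_worsened = float(np.mean([e.worsened for e in eps]))
    est_resp50 = float(np.mean([e.responder_50 for e in eps]))

    effects = np.array([truth_by_id[e.client_id]["effect"] for e in eps])
    measured = np.array(
        [np.nan if e.pct_change is None else -e.pct_change / 100.0 for e in eps]
    )
    ok = ~np.isnan(measured)

    cfgd = truth["configured"]
    report = {
        "n": len(eps),
        "mean_proportional_reduction": {
            "estimate": float(est_reduction),
            "configured": cfgd["mean_proportional_reduction"],
            "realized": float(effects.mean()),
            "bias": float(est_reduction - cfgd["mean_proportional_reduction"]),
        },
        "worsened_fraction": {
            "estimate": est_worsened,
            "configured": cfgd["worsened_fraction"],
            "realized": float((effects < 0).mean()),
            "bias": float(est_worsened - cfgd["worsened_fraction"]),
        },
        "responder_50_fraction": {
            "estimate": est_resp50,
            "configured": cfgd["responder_50_fraction"],
            "realized": float((effects > 0.5).mean()),
            "bias": float(est_resp50 - cfgd["responder_50_fraction"]),
        },
        "per_client_reduction_rmse": float(
            np.sqrt(np.mean((measured[ok] - effects[ok]) ** 2))
        ),
    }
    if med_summary is not None:
        row = med_summary[med_summary["measure"] == "mean_index_all_clients"].iloc[0]
        ids = {e.client_id for e in eps}
        tb = np.array([truth_by_id[c]["true_med_index_baseline"] for c in ids])
        tl = np.array([truth_by_id[c]["true_med_index_locf"] for c in ids])
        true_pct = 100.0 * (tl.mean() - tb.mean()) / tb.mean() if tb.mean() > 0 else None
        est_pct = row["pct_change"]
        report["medication_pct_change"] = {
            "estimate": None if est_pct is None else float(est_pct),
            "truth": true_pct,
            "bias": None
            if est_pct is None or true_pct is None
            else float(est_pct - true_pct),
        }
    return report
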