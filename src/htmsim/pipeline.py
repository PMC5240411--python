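"""End-to-end experiment runner.

Binds the five computational stages into one reproducible experiment:

1. simulate a synthetic HF telemonitoring cohort;
2. run the three alert algorithms on every patient;
3. build 28-day episodes, prune consecutive-alert duplicates, label outcomes,
   and assemble 15 virtual caseloads per algorithm arm;
4. simulate clinician panels reviewing the caseloads — the *simple* arm (A)
   reviews weight rule-of-thumb alerts with 8 raters, the *advanced* arm (P)
   splits 4 + 4 raters over the weight-MACD and impedance-CUSUM sub-arms;
5. compute agreement (raw pairwise, Fleiss kappa with bootstrap CIs) and
   workload statistics (capped/imputed review times, Mann-Whitney arm
   comparison, action-by-outcome rates, detection-weighted action rates).

Every stage draws its randomness from a sub-seed derived from the master seed
and a fixed per-stage code, so adding a stage never perturbs the randomness of
earlier stages, and a full run is byte-identical for a fixed master seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .agreement import AgreementResult, bootstrap_ci, collapse_to_action, fleiss_kappa, raw_agreement
from .alerts import AlertConfig, AlertSeries, run_algorithm
from .cohort import (
    CohortConfig,
    CohortData,
    events_to_json,
    profiles_to_json,
    simulate_cohort,
    vitals_to_csv,
)
from .episodes import (
    Caseload,
    Episode,
    assemble_caseloads,
    build_episodes,
    build_filler_pool,
    label_all,
    prune_consecutive,
)
from .raters import RaterPolicy, RaterResponse, make_panel, responses_to_frame, simulate_responses
from .workload import ArmSummary, cap_and_impute_times, mann_whitney_u, summarize_arm, total_review_time, algorithm_sensitivity, detection_weighted_action_rate

__all__ = ["ExperimentConfig", "ArmResult", "ExperimentResult", "RunManifest", "run_experiment"]

# fixed per-stage seed codes; appending new stages must use fresh codes
_STAGE_COHORT = 0
_STAGE_CASELOADS = 10  # + arm index
_STAGE_PANEL = 20  # + arm index
_STAGE_RESPONSES = 30  # + arm index
_STAGE_BOOTSTRAP = 40  # + arm index

#: (arm key, algorithm, rater prefix, default panel size)
ARMS = (
    ("A", "rot", "A", 8),
    ("M", "macd", "M", 4),
    ("C", "cusum", "C", 4),
)


@dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    alerts: AlertConfig = field(default_factory=AlertConfig)
    n_caseloads: int = 15
    filler_fraction: float = 0.5
    n_raters_simple: int = 8
    n_raters_advanced: int = 4  # per advanced sub-arm
    policy_spread: float = 0.3
    missing_response_rate: float = 0.02
    cap_s: float = 300.0
    n_boot: int = 2000
    master_seed: int = 0

    def sub_seed(self, code: int) -> int:
        """Derived sub-seed: stable per stage code under the master seed."""
        return int(
            np.random.SeedSequence([self.master_seed, code]).generate_state(1)[0]
            % (2**31)
        )


@dataclass
class ArmResult:
    arm: str
    algorithm: str
    alerts: dict[str, AlertSeries]
    episodes_raw: list[Episode]
    episodes: list[Episode]  # pruned + labeled
    caseloads: list[Caseload]
    panel: list[RaterPolicy]
    responses: list[RaterResponse]
    summary: ArmSummary
    raw_agreement_binary: float
    kappa_binary: AgreementResult
    sensitivity: float
    concern_rate_decomp: float
    detection_weighted_action_rate: float


@dataclass
class ExperimentResult:
    config: ExperimentConfig
    cohort: CohortData
    arms: dict[str, ArmResult]
    pooled_kappa: AgreementResult
    pooled_raw_agreement: float
    total_minutes_arm_a: list[float]
    total_minutes_arm_p: list[float]
    mann_whitney_u_stat: float
    mann_whitney_p: float


@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    sub_seeds: dict[str, int]
    outputs: dict[str, str]
    record_counts: dict[str, int]
    version: str


def _config_hash(config: ExperimentConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _run_arm(
    arm: str,
    algorithm: str,
    prefix: str,
    n_raters: int,
    idx: int,
    cohort: CohortData,
    config: ExperimentConfig,
) -> ArmResult:
    alerts = {
        pid: run_algorithm(algorithm, series, config.alerts)
        for pid, series in cohort.vitals.items()
    }
    raw: list[Episode] = []
    for pid in sorted(alerts):
        raw.extend(build_episodes(alerts[pid], cohort.vitals[pid]))
    pruned = prune_consecutive(raw)
    labeled = label_all(pruned, cohort.events)
    filler = label_all(build_filler_pool(cohort.vitals, alerts), cohort.events)
    caseloads = assemble_caseloads(
        labeled,
        filler,
        n_caseloads=config.n_caseloads,
        filler_fraction=config.filler_fraction,
        seed=config.sub_seed(_STAGE_CASELOADS + idx),
        arm=arm,
    )
    panel = make_panel(
        n_raters,
        policy_spread=config.policy_spread,
        seed=config.sub_seed(_STAGE_PANEL + idx),
        prefix=prefix,
    )
    responses = simulate_responses(
        panel,
        caseloads,
        seed=config.sub_seed(_STAGE_RESPONSES + idx),
        missing_rate=config.missing_response_rate,
    )
    summary = summarize_arm(arm, responses, labeled, panel, cap_s=config.cap_s)
    matrix = collapse_to_action(responses, panel_size=n_raters)
    kappa_res = bootstrap_ci(
        matrix,
        fleiss_kappa,
        n_boot=config.n_boot,
        seed=config.sub_seed(_STAGE_BOOTSTRAP + idx),
    )
    sens = algorithm_sensitivity(alerts, cohort.events)
    concern = summary.outcome_split.concern_rate_decomp
    composite = (
        detection_weighted_action_rate(sens, concern)
        if not (np.isnan(sens) or np.isnan(concern))
        else float("nan")
    )
    return ArmResult(
        arm=arm,
        algorithm=algorithm,
        alerts=alerts,
        episodes_raw=raw,
        episodes=labeled,
        caseloads=caseloads,
        panel=panel,
        responses=responses,
        summary=summary,
        raw_agreement_binary=raw_agreement(matrix),
        kappa_binary=kappa_res,
        sensitivity=sens,
        concern_rate_decomp=concern,
        detection_weighted_action_rate=composite,
    )


def run_experiment(
    config: ExperimentConfig | None = None,
    out_dir: str | Path | None = None,
) -> tuple[ExperimentResult, RunManifest]:
    """Run the full simulated experiment; optionally write all stage outputs.

    Returns the in-memory result plus a manifest of sub-seeds, output paths
    and record counts.  Byte-identical outputs for identical configs.
    """
    config = config or ExperimentConfig()
    cohort_cfg = replace(config.cohort, seed=config.sub_seed(_STAGE_COHORT))
    cohort = simulate_cohort(cohort_cfg)

    arms: dict[str, ArmResult] = {}
    for idx, (arm, algorithm, prefix, default_n) in enumerate(ARMS):
        n_raters = config.n_raters_simple if arm == "A" else config.n_raters_advanced
        arms[arm] = _run_arm(arm, algorithm, prefix, n_raters, idx, cohort, config)

    # pooled advanced arm P: stack the two 4-rater sub-arm matrices
    m_matrix = collapse_to_action(arms["M"].responses, panel_size=config.n_raters_advanced)
    c_matrix = collapse_to_action(arms["C"].responses, panel_size=config.n_raters_advanced)
    from .agreement import RatingMatrix

    pooled = RatingMatrix(
        case_ids=m_matrix.case_ids + c_matrix.case_ids,
        categories=m_matrix.categories,
        counts=np.vstack([m_matrix.counts, c_matrix.counts]),
        panel_size=config.n_raters_advanced,
    )
    pooled_kappa = bootstrap_ci(
        pooled, fleiss_kappa, n_boot=config.n_boot,
        seed=config.sub_seed(_STAGE_BOOTSTRAP + 9),
    )
    pooled_raw = raw_agreement(pooled)

    minutes_a = list(arms["A"].summary.total_minutes_per_rater.values())
    minutes_p = list(arms["M"].summary.total_minutes_per_rater.values()) + list(
        arms["C"].summary.total_minutes_per_rater.values()
    )
    u_stat, p_value = mann_whitney_u(minutes_a, minutes_p)

    result = ExperimentResult(
        config=config,
        cohort=cohort,
        arms=arms,
        pooled_kappa=pooled_kappa,
        pooled_raw_agreement=pooled_raw,
        total_minutes_arm_a=minutes_a,
        total_minutes_arm_p=minutes_p,
        mann_whitney_u_stat=u_stat,
        mann_whitney_p=p_value,
    )

    sub_seeds = {
        "cohort": config.sub_seed(_STAGE_COHORT),
        **{
            f"{stage}_{arm}": config.sub_seed(code + idx)
            for idx, (arm, _, _, _) in enumerate(ARMS)
            for stage, code in (
                ("caseloads", _STAGE_CASELOADS),
                ("panel", _STAGE_PANEL),
                ("responses", _STAGE_RESPONSES),
                ("bootstrap", _STAGE_BOOTSTRAP),
            )
        },
        "bootstrap_pooled": config.sub_seed(_STAGE_BOOTSTRAP + 9),
    }
    manifest = RunManifest(
        config_hash=_config_hash(config),
        master_seed=config.master_seed,
        sub_seeds=sub_seeds,
        outputs={},
        record_counts={
            "patients": len(cohort.profiles),
            "events": len(cohort.events),
            **{
                f"episodes_raw_{a.algorithm}": len(a.episodes_raw) for a in arms.values()
            },
            **{f"episodes_{a.algorithm}": len(a.episodes) for a in arms.values()},
            **{f"responses_{a.arm}": len(a.responses) for a in arms.values()},
        },
        version=__version__,
    )
    if out_dir is not None:
        _write_outputs(result, manifest, Path(out_dir))
    return result, manifest


def _episode_record(ep: Episode) -> dict[str, Any]:
    return {
        "episode_id": ep.episode_id,
        "patient_id": ep.patient_id,
        "start_day": ep.start_day,
        "end_day": ep.end_day,
        "window": ep.window,
        "is_alert_episode": ep.is_alert_episode,
        "algorithm": ep.algorithm,
        "decompensated": ep.decompensated,
        "display_name": ep.display_name,
    }


def _write_outputs(result: ExperimentResult, manifest: RunManifest, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def record(key: str, path: Path) -> Path:
        paths[key] = str(path.relative_to(out))
        return path

    vitals_to_csv(
        [result.cohort.vitals[pid] for pid in sorted(result.cohort.vitals)],
        record("vitals", out / "vitals.csv"),
    )
    profiles_to_json(result.cohort.profiles, record("profiles", out / "profiles.json"))
    events_to_json(result.cohort.events, record("events", out / "events.json"))

    for arm, a in result.arms.items():
        import pandas as pd

        alert_rows = []
        for pid in sorted(a.alerts):
            s = a.alerts[pid]
            for d, v in zip(s.stat_days.tolist(), s.statistic.tolist()):
                alert_rows.append(
                    {
                        "patient_id": pid,
                        "day": d,
                        "algorithm": s.algorithm,
                        "statistic": round(v, 6),
                        "alert": d in set(s.alert_days.tolist()),
                    }
                )
        pd.DataFrame(alert_rows).to_csv(
            record(f"alerts_{arm}", out / f"alerts_{arm}.csv"), index=False
        )
        (record(f"episodes_{arm}", out / f"episodes_{arm}.json")).write_text(
            json.dumps([_episode_record(e) for e in a.episodes], indent=1, sort_keys=True)
        )
        (record(f"caseloads_{arm}", out / f"caseloads_{arm}.json")).write_text(
            json.dumps(
                [
                    {
                        "caseload_id": cl.caseload_id,
                        "arm": cl.arm,
                        "episodes": [_episode_record(e) for e in cl.episodes],
                    }
                    for cl in a.caseloads
                ],
                indent=1,
                sort_keys=True,
            )
        )
        responses_to_frame(a.responses).to_csv(
            record(f"responses_{arm}", out / f"responses_{arm}.csv"),
            index=False,
            float_format="%.6g",
        )

    summary = {
        "arms": {
            arm: {
                "algorithm": a.algorithm,
                "n_alert_days": int(sum(len(s.alert_days) for s in a.alerts.values())),
                "episodes_raw": len(a.episodes_raw),
                "episodes_pruned": len(a.episodes),
                "sensitivity": a.sensitivity,
                "raw_agreement_binary": a.raw_agreement_binary,
                "kappa": a.kappa_binary.statistic,
                "kappa_ci": [a.kappa_binary.ci_low, a.kappa_binary.ci_high],
                "total_minutes_mean": a.summary.total_minutes_mean,
                "total_minutes_sd": a.summary.total_minutes_sd,
                "per_alert_seconds_mean": a.summary.per_alert_seconds_mean,
                "action_proportion": a.summary.action_proportion,
                "concern_rate_decomp": a.concern_rate_decomp,
                "detection_weighted_action_rate": a.detection_weighted_action_rate,
            }
            for arm, a in result.arms.items()
        },
        "pooled_arm_p": {
            "raw_agreement_binary": result.pooled_raw_agreement,
            "kappa": result.pooled_kappa.statistic,
            "kappa_ci": [result.pooled_kappa.ci_low, result.pooled_kappa.ci_high],
        },
        "mann_whitney": {
            "U": result.mann_whitney_u_stat,
            "p_two_sided": result.mann_whitney_p,
            "total_minutes_arm_a": result.total_minutes_arm_a,
            "total_minutes_arm_p": result.total_minutes_arm_p,
        },
    }
    record("summary", out / "summary.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True)
    )

    manifest.outputs = paths
    (out / "manifest.json").write_text(
        json.dumps(
            {
                "config_hash": manifest.config_hash,
                "master_seed": manifest.master_seed,
                "sub_seeds": manifest.sub_seeds,
                "outputs": manifest.outputs,
                "record_counts": manifest.record_counts,
                "version": manifest.version,
            },
            indent=1,
            sort_keys=True,
        )
    )
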