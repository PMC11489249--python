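"""End-to-end orchestration: from inputs to per-community risk and profiles.

Stages compose through the shared CSV schemas: survey -> validation ->
social indicators; traits + consumption + climate hazard -> ecological
risk (SH1); indicators -> dimension indices -> vulnerability -> CFSR
with propagated confidence -> risk-profile labels.  Outputs are a
group-score table, a community table mirroring the published layout, a
profile table and a JSON run manifest sufficient to reproduce the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from cfsr import __version__
from cfsr._rounding import round_half_up
from cfsr.aggregate import propagate_confidence, risk_index, vulnerability
from cfsr.climate import hazard_scores, read_climate_csv
from cfsr.ecology import (
    GROUPS,
    community_resource_component,
    ecological_risk_to_resource,
    load_consumption_csv,
    load_traits_csv,
    score_groups,
)
from cfsr.profiles import ProfileRule, classify_profile
from cfsr.registry import Registry, default_registry, load_registry
from cfsr.social import IndicatorScore, score_social_indicators
from cfsr.survey import load_survey, validate_survey
from cfsr.synthetic import (
    DEFAULT_CONSUMPTION,
    default_scenarios,
    generate_survey,
    generate_trait_fixture,
    nutrition_group_means,
)

log = logging.getLogger("cfsr")

#: published hazard scores used when no raw climate series are supplied
FIXTURE_HAZARD_SCORES = {"sst": 0.350, "chl_a": 0.550}


@dataclass(frozen=True)
class CommunityRisk:
    """Final per-community results: dimension indices and composites."""

    community: str
    SH: float
    SE: float
    SS: float
    SAC: float
    vulnerability: float
    ERR: float
    CFSR: float
    confidence: float
    profile: str


@dataclass
class RunConfig:
    """Everything a run needs; round-trips losslessly through the manifest."""

    survey_path: str | None = None       # None -> synthetic survey
    traits_path: str | None = None       # None -> shipped trait fixture
    consumption_path: str | None = None  # None -> shipped demo shares
    climate_path: str | None = None      # None -> fixture hazard scores
    registry_path: str | None = None     # None -> default registry
    ref_window: tuple[int, int] = (2001, 2011)
    fut_window: tuple[int, int] = (2011, 2021)
    equation_mode: str = "table_consistent"  # or "literal"
    profile_thresholds: tuple[float, float] = (0.5, 0.5)
    seed: int = 0
    precision: str = "3dp"  # or "full"
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if self.equation_mode not in {"table_consistent", "literal"}:
            raise ValueError(f"unknown equation mode {self.equation_mode!r}")
        if self.precision not in {"3dp", "full"}:
            raise ValueError(f"unknown precision {self.precision!r}")
        for name in ("survey_path", "traits_path", "consumption_path",
                     "climate_path", "registry_path"):
            path = getattr(self, name)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{name} does not exist: {path}")


@dataclass
class PipelineResult:
    config: RunConfig
    group_scores: pd.DataFrame
    community_table: pd.DataFrame
    profile_table: pd.DataFrame
    risks: list[CommunityRisk]
    indicator_scores: list[IndicatorScore]
    warnings: list[str] = field(default_factory=list)


def _fmt(x: float, precision: str) -> float:
    return round_half_up(x, 3) if precision == "3dp" else x


def _group_mean(values: Mapping[str, float]) -> float:
    return sum(values.values()) / len(values)


def _dimension_index(
    registry: Registry,
    dimension: str,
    values: Mapping[str, float],
    confidences: Mapping[str, float],
) -> tuple[float, float]:
    """(value, confidence) of a dimension: mean over groups of member means."""
    group_vals, group_confs = [], []
    for _, codes in registry.groups(dimension).items():
        member_vals = [values[c] for c in codes if c in values]
        member_confs = [confidences[c] for c in codes if c in confidences]
        if not member_vals:
            continue
        group_vals.append(sum(member_vals) / len(member_vals))
        group_confs.append(propagate_confidence(member_confs))
    if not group_vals:
        raise ValueError(f"no scored indicators in dimension {dimension!r}")
    return sum(group_vals) / len(group_vals), propagate_confidence(group_confs)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage and assemble the per-community risk table."""
    warnings_log: list[str] = []
    registry = (
        load_registry(config.registry_path) if config.registry_path
        else default_registry()
    )

    # --- survey ---
    if config.survey_path:
        raw = load_survey(config.survey_path)
    else:
        raw = generate_survey(default_scenarios(), seed=config.seed, registry=registry)
    table, report = validate_survey(raw, registry)
    if report.n_issues:
        warnings_log.append(f"{report.n_issues} survey answers flagged as invalid")
        log.warning("survey validation flagged %d answers", report.n_issues)

    # --- climate hazard ---
    if config.climate_path:
        series = read_climate_csv(config.climate_path)
        hz = hazard_scores(series, config.ref_window, config.fut_window)
    else:
        hz = hazard_scores(None, config.ref_window, config.fut_window,
                           fixture_scores=FIXTURE_HAZARD_SCORES)
        warnings_log.append("no climate series supplied; using fixture hazard scores")
    eh1 = hz.get("sst")
    eh2 = hz.get("chl_a")
    if eh1 is None or eh2 is None:
        raise ValueError("climate stage must yield both 'sst' and 'chl_a' scores")
    rh = (eh1 + eh2) / 2.0

    # --- ecological risk ---
    families = (
        load_traits_csv(config.traits_path) if config.traits_path
        else generate_trait_fixture()
    )
    groups = score_groups(families)
    if config.consumption_path:
        consumption = load_consumption_csv(config.consumption_path)
    else:
        consumption = {c: DEFAULT_CONSUMPTION[c] for c in registry.communities}
    err_by_community: dict[str, dict[str, float]] = {}
    for community in registry.communities:
        props = consumption[community]
        re_ = community_resource_component(groups["RE"].to_dict(), props)
        rs = community_resource_component(groups["RS"].to_dict(), props)
        rac = community_resource_component(groups["RAC"].to_dict(), props)
        v, err = ecological_risk_to_resource(rh, re_, rs, rac,
                                             mode=config.equation_mode)
        err_by_community[community] = {
            "RH": rh, "RE": re_, "RS": rs, "RAC": rac,
            "resource_vulnerability": v, "ERR": err,
        }

    # --- social indicators ---
    nutrition = nutrition_group_means()
    indicator_scores = score_social_indicators(
        table, registry, nutrition_means=nutrition, consumption=consumption
    )

    # --- aggregation ---
    resource_conf = {
        c: registry[c].resolved_confidence
        for c in ("EH1", "EH2", "EE1", "EE2", "ES1", "ES2", "EA1", "EA2")
    }
    err_confidence = propagate_confidence([
        propagate_confidence([resource_conf["EH1"], resource_conf["EH2"]]),
        propagate_confidence([resource_conf["EE1"], resource_conf["EE2"]]),
        propagate_confidence([resource_conf["ES1"], resource_conf["ES2"]]),
        propagate_confidence([resource_conf["EA1"], resource_conf["EA2"]]),
    ])

    rule = ProfileRule(*config.profile_thresholds)
    risks: list[CommunityRisk] = []
    for community in registry.communities:
        values = {s.code: s.value for s in indicator_scores if s.community == community}
        confs = {s.code: s.confidence for s in indicator_scores
                 if s.community == community}
        err = err_by_community[community]["ERR"]
        # literal mode may leave ERR outside [0,1]; clip only for nesting
        values["SH1"] = min(max(err, 0.0), 1.0)
        confs["SH1"] = err_confidence
        sh, sh_conf = _dimension_index(registry, "social_hazard", values, confs)
        se, se_conf = _dimension_index(registry, "social_exposure", values, confs)
        ss, ss_conf = _dimension_index(registry, "social_sensitivity", values, confs)
        sac, sac_conf = _dimension_index(
            registry, "social_adaptive_capacity", values, confs
        )
        v = vulnerability(ss, sac, mode=config.equation_mode)
        if config.equation_mode == "literal":
            cfsr_value = (sh + se) / 2.0 + v
        else:
            cfsr_value = risk_index(sh, se, v)
        confidence = propagate_confidence([sh_conf, se_conf, ss_conf, sac_conf])
        profile = classify_profile(
            (sh + se) / 2.0,
            min(max(v, 0.0), 1.0),
            rule,
        )
        risks.append(CommunityRisk(
            community=community, SH=sh, SE=se, SS=ss, SAC=sac,
            vulnerability=v, ERR=err, CFSR=cfsr_value,
            confidence=confidence, profile=profile,
        ))

    # --- output tables ---
    p = config.precision
    group_rows = []
    for trait, comp in (("EE1", "RE"), ("EE2", "RE"), ("ES1", "RS"),
                        ("ES2", "RS"), ("EA1", "RAC"), ("EA2", "RAC")):
        group_rows.append(
            {"indicator": trait, "component": comp,
             **{g: _fmt(groups.loc[g, trait], p) for g in groups.index}}
        )
    for comp in ("RE", "RS", "RAC"):
        a, b = {"RE": ("EE1", "EE2"), "RS": ("ES1", "ES2"),
                "RAC": ("EA1", "EA2")}[comp]
        group_rows.append(
            {"indicator": f"{comp}_average", "component": comp,
             # published tables average the two already-rounded rows
             **{g: _fmt((round_half_up(groups.loc[g, a], 3)
                         + round_half_up(groups.loc[g, b], 3)) / 2.0, p)
                for g in groups.index}}
        )
    group_table = pd.DataFrame(group_rows)

    community_rows = []
    for s in indicator_scores:
        community_rows.append({"community": s.community, "code": s.code,
                               "value": _fmt(s.value, p),
                               "confidence": _fmt(s.confidence, p),
                               "n_respondents": s.n_respondents})
    for community, comp in err_by_community.items():
        for key, val in comp.items():
            community_rows.append({"community": community, "code": key,
                                   "value": _fmt(val, p),
                                   "confidence": _fmt(err_confidence, p),
                                   "n_respondents": 0})
    for r in risks:
        for key in ("SH", "SE", "SS", "SAC", "vulnerability", "CFSR"):
            community_rows.append({"community": r.community, "code": key,
                                   "value": _fmt(getattr(r, key), p),
                                   "confidence": _fmt(r.confidence, p),
                                   "n_respondents": 0})
    community_table = pd.DataFrame(community_rows)

    profile_table = pd.DataFrame(
        [{"community": r.community,
          "exposure_hazard": _fmt((r.SH + r.SE) / 2.0, p),
          "vulnerability": _fmt(r.vulnerability, p),
          "profile": r.profile} for r in risks]
    )

    return PipelineResult(
        config=config,
        group_scores=group_table,
        community_table=community_table,
        profile_table=profile_table,
        risks=risks,
        indicator_scores=indicator_scores,
        warnings=warnings_log,
    )


def write_outputs(result: PipelineResult) -> dict[str, str]:
    """Write the three CSV tables and the JSON manifest; returns the paths."""
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "group_scores": str(out / "group_scores.csv"),
        "community_risk": str(out / "community_risk.csv"),
        "profiles": str(out / "profiles.csv"),
        "manifest": str(out / "manifest.json"),
    }
    fmt = "%.3f" if result.config.precision == "3dp" else "%.12g"
    result.group_scores.to_csv(paths["group_scores"], index=False, float_format=fmt)
    result.community_table.to_csv(paths["community_risk"], index=False, float_format=fmt)
    result.profile_table.to_csv(paths["profiles"], index=False, float_format=fmt)
    manifest = {
        "version": __version__,
        "config": asdict(result.config),
        "seed": result.config.seed,
        "warnings": result.warnings,
        "communities": [asdict(r) for r in result.risks],
    }
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def config_from_manifest(path) -> RunConfig:
    """Rebuild a RunConfig from a run manifest (lossless round-trip)."""
    with open(path) as fh:
        manifest = json.load(fh)
    cfg = dict(manifest["config"])
    cfg["ref_window"] = tuple(cfg["ref_window"])
    cfg["fut_window"] = tuple(cfg["fut_window"])
    cfg["profile_thresholds"] = tuple(cfg["profile_thresholds"])
    return RunConfig(**cfg)
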