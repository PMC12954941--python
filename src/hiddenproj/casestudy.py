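"""Config-driven reproduction of the screening-design case studies.

A case study pits a baseline design (usually a regular fraction) against a
proposed non-regular design, compares strength, projection coverage, and
run counts, and self-checks every declared expectation.  Expectations live
in the YAML config so the same runner can express new comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import yaml

from .analysis import (
    Comparison,
    compare_designs,
    projection_coverage,
    run_reduction_pct,
    verify_strength,
)
from .design import Design, read_design
from .hadamard import hadamard_to_oa, paley_type1, paley_type2, sylvester
from .regular import GeneratorSet, build_regular

__all__ = [
    "ConfigError",
    "CaseStudyConfig",
    "CaseStudyResult",
    "resolve_design",
    "load_config",
    "bundled_config_path",
    "run_case_study",
    "render_report",
]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """A case-study config cannot be resolved."""


def resolve_design(spec: Mapping[str, Any], base_dir: Path | None = None) -> Design:
    """Build a Design from a config spec.

    Supported kinds::

        {kind: regular, k: 4, generators: "E=ABC,F=ACD"}
        {kind: paley1,  q: 11, cols: 6}
        {kind: paley2,  q: 13, cols: 6}
        {kind: sylvester, m: 4, cols: 6}
        {kind: file, path: design.csv, format: csv}
    """
    try:
        kind = spec["kind"]
    except (KeyError, TypeError):
        raise ConfigError(f"design spec must have a 'kind': {spec!r}")
    try:
        if kind == "regular":
            gen = GeneratorSet.from_strings(
                int(spec["k"]), spec.get("generators", ""), spec.get("base_labels")
            )
            return build_regular(gen)
        if kind in ("paley1", "paley2"):
            builder = paley_type1 if kind == "paley1" else paley_type2
            return hadamard_to_oa(builder(int(spec["q"])), int(spec["cols"]))
        if kind == "sylvester":
            return hadamard_to_oa(sylvester(int(spec["m"])), int(spec["cols"]))
        if kind == "file":
            path = Path(spec["path"])
            if base_dir is not None and not path.is_absolute():
                path = base_dir / path
            return read_design(path, spec.get("format", "csv"))
    except ConfigError:
        raise
    except (KeyError, ValueError) as exc:
        raise ConfigError(f"cannot resolve design spec {spec!r}: {exc}") from exc
    raise ConfigError(f"unknown design kind {kind!r}")


@dataclass(frozen=True)
class CaseStudyConfig:
    name: str
    baseline: Mapping[str, Any]
    proposal: Mapping[str, Any]
    k_values: tuple[int, ...]
    expectations: Mapping[str, Any] = field(default_factory=dict)
    base_dir: Path | None = None

    def __post_init__(self):
        if not self.k_values:
            raise ConfigError("k_values must be non-empty")


def load_config(path) -> CaseStudyConfig:
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot load {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} does not contain a mapping")
    missing = {"name", "baseline", "proposal", "k_values"} - raw.keys()
    if missing:
        raise ConfigError(f"{path} is missing keys {sorted(missing)}")
    return CaseStudyConfig(
        name=str(raw["name"]),
        baseline=raw["baseline"],
        proposal=raw["proposal"],
        k_values=tuple(int(k) for k in raw["k_values"]),
        expectations=raw.get("expectations", {}) or {},
        base_dir=path.parent,
    )


def bundled_config_path(name: str) -> Path:
    """Path of a config shipped with the package (quit, hsv1, npi)."""
    ref = resources.files("hiddenproj") / "configs" / f"{name}.yaml"
    if not ref.is_file():
        raise ConfigError(f"no bundled config named {name!r}")
    return Path(str(ref))


@dataclass(frozen=True)
class CaseStudyResult:
    config: CaseStudyConfig
    comparison: Comparison
    report: str
    failures: tuple[str, ...]

    @property
    def passed(self) -> bool:
        return not self.failures


def _check_expectations(cfg: CaseStudyConfig, comparison: Comparison) -> list[str]:
    exp = cfg.expectations
    base, prop = comparison.designs
    failures = []

    def check(label, expected, actual):
        if expected != actual:
            failures.append(f"{label}: expected {expected}, got {actual}")

    for role, summary in (("baseline", base), ("proposal", prop)):
        if f"{role}_runs" in exp:
            check(f"{role}_runs", int(exp[f"{role}_runs"]), summary.runs)
        if f"{role}_strength" in exp:
            check(f"{role}_strength", int(exp[f"{role}_strength"]), summary.strength)
        cov_exp = exp.get(f"{role}_coverage") or {}
        for k, pct in cov_exp.items():
            k = int(k)
            if k not in summary.coverage:
                failures.append(f"{role}_coverage[{k}]: k={k} not computed")
                continue
            actual = summary.coverage[k].coverage  # exact rational in [0, 1]
            check(f"{role}_coverage[{k}]%", Fraction(str(pct)), 100 * actual)
    if "run_reduction_pct" in exp:
        check(
            "run_reduction_pct",
            int(exp["run_reduction_pct"]),
            run_reduction_pct(base.runs, prop.runs),
        )
    if "runs_saved" in exp:
        check("runs_saved", int(exp["runs_saved"]), base.runs - prop.runs)
    return failures


def run_case_study(cfg: CaseStudyConfig) -> CaseStudyResult:
    """Build both designs, compare them, and self-check the expectations."""
    baseline = resolve_design(cfg.baseline, cfg.base_dir)
    proposal = resolve_design(cfg.proposal, cfg.base_dir)
    log.info(
        "case study %s: baseline %d runs x %d factors, proposal %d runs x %d factors",
        cfg.name, baseline.runs, baseline.n_factors, proposal.runs, proposal.n_factors,
    )
    comparison = compare_designs(
        [("baseline", baseline), ("proposal", proposal)],
        cfg.k_values,
        baseline="baseline",
    )
    for summary in comparison.designs:
        log.info("%s: strength %d", summary.name, summary.strength)
        for k, report in summary.coverage.items():
            log.info("%s: %s", summary.name, report)
            for subset in report.deficient_subsets:
                log.debug("%s deficient subset: %s", summary.name, subset)
    failures = _check_expectations(cfg, comparison)
    report = render_report(comparison, title=cfg.name)
    return CaseStudyResult(cfg, comparison, report, tuple(failures))


def _fmt_pct(frac: Fraction) -> str:
    return f"{round(float(100 * frac), 1)}%"


def render_report(comparison: Comparison, title: str | None = None) -> str:
    """Deterministic markdown report: identical inputs, identical bytes."""
    lines = []
    if title:
        lines += [f"# Case study: {title}", ""]
    names = [s.name for s in comparison.designs]
    lines.append("| Subset size | " + " | ".join(names) + " |")
    lines.append("|---" * (len(names) + 1) + "|")
    for k in comparison.k_values:
        cells = [_fmt_pct(s.coverage[k].coverage) for s in comparison.designs]
        lines.append(f"| {k} factors | " + " | ".join(cells) + " |")
    lines.append("")
    for s in comparison.designs:
        extra = ""
        if comparison.baseline is not None and s.name != comparison.baseline:
            extra = f", {s.reduction_vs_baseline_pct}% fewer runs than {comparison.baseline}"
        lines.append(
            f"- {s.name}: {s.runs} runs x {s.n_factors} factors, strength {s.strength}{extra}"
        )
        for k in comparison.k_values:
            rep = s.coverage[k]
            if rep.deficient_subsets:
                shown = ", ".join("{" + ",".join(sub) + "}" for sub in rep.deficient_subsets)
                lines.append(
                    f"  - k={k}: {rep.full_rank_count}/{rep.total_subsets} full rank; "
                    f"deficient: {shown}"
                )
    return "\n".join(lines) + "\n"
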