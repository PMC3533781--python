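"""Analysis pipeline and standardized report.

A complete population analysis runs: validation -> (optional) abbreviation
code expansion -> (optional) transliteration onto an allele pool -> EM
frequency estimation -> Hardy-Weinberg assessment -> Ewens-Watterson
neutrality test -> sample-size significance thresholds -> report.
Assessment of HWE is mandatory for any use of allele frequencies: a report
carrying frequencies but no HWE result is flagged incomplete.  Every stage
is logged with its parameters so the run is fully reproducible from the
report alone.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import yaml

from hlapop import __version__
from hlapop.frequency_inference import (
    FrequencyEstimate,
    em_allele_frequencies,
    flag_nonsignificant,
)
from hlapop.genotype_io import MacTable, read_sample, validate_sample
from hlapop.nomenclature import AlleleMapping, transliterate_sample
from hlapop.popgen_tests import ewens_watterson_test, hwe_test
from hlapop.sample_size import ThresholdQuery, frequency_threshold

logger = logging.getLogger("hlapop")

MANDATORY_HWE = (
    "assessment of Hardy-Weinberg equilibrium is mandatory for any use of "
    "allele frequencies describing the genetic profile of a population"
)


@dataclass
class AnalysisReport:
    """Full provenance record of one analysis run."""

    metadata: dict = field(default_factory=dict)
    frequencies: dict = field(default_factory=dict)
    flags: dict = field(default_factory=dict)
    em_diagnostics: dict = field(default_factory=dict)
    hwe: dict | None = None
    neutrality: dict | None = None
    threshold: dict | None = None
    ethics_statement: str = ""
    software: str = f"hlapop {__version__}"
    seed: int | None = None
    config_echo: dict = field(default_factory=dict)
    violations: list = field(default_factory=list)
    stage_log: list = field(default_factory=list)

    @property
    def complete(self) -> bool:
        return not (self.frequencies and self.hwe is None)

    def to_dict(self) -> dict:
        return {
            "software": self.software,
            "seed": self.seed,
            "complete": self.complete,
            "metadata": self.metadata,
            "frequencies": self.frequencies,
            "flags": {str(k): sorted(v) for k, v in self.flags.items()},
            "em_diagnostics": self.em_diagnostics,
            "hwe": self.hwe,
            "neutrality": self.neutrality,
            "threshold": self.threshold,
            "ethics_statement": self.ethics_statement,
            "violations": self.violations,
            "config_echo": self.config_echo,
            "stage_log": self.stage_log,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, default=str)


DEFAULT_CONFIG = {
    "dialect": "glstring",
    "strict": False,
    "mac_table": None,
    "transliterate": None,
    "run_hwe": True,
    "run_neutrality": True,
    "hwe_alternative": "inbreeding",
    "significance_model": "I",
    "em": {"n_starts": 5, "seed": 0},
    "neutrality": {"replicates": 10000, "seed": 0},
    "barchart": None,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a key-value mapping")
    return cfg


class StageError(RuntimeError):
    """Pipeline stage failure with stage name and remediation hint."""

    def __init__(self, stage: str, cause: Exception, hint: str = ""):
        self.stage = stage
        self.cause = cause
        msg = f"stage {stage!r} failed: {cause}"
        if hint:
            msg += f" (hint: {hint})"
        super().__init__(msg)


def run_pipeline(config: dict | str | Path) -> AnalysisReport:
    """Execute the full analysis chain described by a configuration mapping
    (or a YAML file path).  All defaults are echoed into the report."""
    if not isinstance(config, dict):
        config = load_config(config)
    cfg = {**DEFAULT_CONFIG, **config}
    for key in ("em", "neutrality"):
        cfg[key] = {**DEFAULT_CONFIG[key], **(config.get(key) or {})}
    report = AnalysisReport(config_echo=cfg, seed=cfg["em"].get("seed"))

    def log_stage(name, **params):
        logger.info("stage %s: %s", name, params)
        report.stage_log.append({"stage": name, **params})

    if "input" not in cfg:
        raise StageError("read", ValueError("config must name an 'input' file"))
    try:
        mac = MacTable.from_tsv(cfg["mac_table"]) if cfg["mac_table"] else None
        sample = read_sample(cfg["input"], cfg["dialect"], mac_table=mac)
        log_stage("read", input=str(cfg["input"]), dialect=cfg["dialect"],
                  n_individuals=sample.n_individuals,
                  mac_table=str(cfg["mac_table"]) if cfg["mac_table"] else None)
    except Exception as exc:
        raise StageError("read", exc, "check the input path and dialect") from exc

    validation = validate_sample(sample, strict=False)
    report.violations.extend(validation.violations)
    log_stage("validate", n_violations=len(validation.violations))
    if cfg["strict"] and not validation.ok:
        raise StageError(
            "validate", ValueError(validation.to_text().strip()),
            "provide explicit pair lists and complete metadata")

    if cfg["transliterate"]:
        try:
            mapping = AlleleMapping.from_tsv(cfg["transliterate"])
            sample = transliterate_sample(sample, mapping)
            log_stage("transliterate", mapping=str(cfg["transliterate"]),
                      n_classes=len(set(mapping.entries.values())))
        except Exception as exc:
            raise StageError("transliterate", exc,
                             "the mapping must cover every allele in the data") from exc

    report.metadata = {
        "population_name": sample.metadata.population_name,
        "study_type": sample.metadata.study_type,
        "n_individuals": sample.n_individuals,
        "loci": sample.locus_set,
        "ambiguity_fraction": sample.ambiguity_fraction(),
    }
    report.ethics_statement = sample.metadata.ethics_statement

    try:
        est = em_allele_frequencies(sample, **cfg["em"])
        est = flag_nonsignificant(est, model=cfg["significance_model"])
        log_stage("em", **cfg["em"])
    except Exception as exc:
        raise StageError("em", exc, "check for empty candidate sets") from exc
    report.frequencies = {str(k): v for k, v in est.sorted_items()}
    report.flags = est.flags
    report.em_diagnostics = est.em_diagnostics

    if cfg["run_hwe"]:
        try:
            hwe = hwe_test(sample, alternative=cfg["hwe_alternative"])
            report.hwe = hwe.to_dict()
            log_stage("hwe", alternative=cfg["hwe_alternative"],
                      p_value=hwe.p_value)
        except Exception as exc:
            raise StageError("hwe", exc) from exc
    else:
        report.violations.append(f"HWE assessment skipped: {MANDATORY_HWE}")
        log_stage("hwe", skipped=True)

    if cfg["run_neutrality"]:
        try:
            ew = ewens_watterson_test(est, **cfg["neutrality"])
            report.neutrality = ew.to_dict()
            log_stage("neutrality", **cfg["neutrality"])
        except Exception as exc:
            raise StageError("neutrality", exc) from exc
    else:
        log_stage("neutrality", skipped=True)

    thr = frequency_threshold(
        ThresholdQuery(N=sample.n_individuals, model=cfg["significance_model"]))
    report.threshold = {
        "N": sample.n_individuals,
        "model": thr.query.model,
        "threshold_percent": thr.percent,
    }
    log_stage("thresholds", N=sample.n_individuals, model=thr.query.model)

    if cfg["barchart"]:
        render_barchart(est, cfg["barchart"])
        log_stage("barchart", path=str(cfg["barchart"]))
    return report


def render_barchart(est: FrequencyEstimate, path, fmt: str | None = None):
    """Bar chart of allele frequencies, sorted descending, with +-2 SE
    whiskers (SE = sqrt(p(1-p)/2N)) and nonsignificant alleles hatched.
    Bar charts, not pie charts: angular areas are error-prone to compare.
    SVG output is deterministic for fixed input (no timestamp)."""
    if not est.frequencies:
        raise ValueError("cannot plot an empty frequency estimate")
    items = est.sorted_items()
    labels = [str(k) for k, _ in items]
    values = [v for _, v in items]
    two_n = est.n_gene_copies
    errors = [2.0 * math.sqrt(v * (1.0 - v) / two_n) for v in values]
    nonsig = ["nonsignificant" in est.flags.get(k, set()) for k, _ in items]

    fig, ax = plt.subplots(figsize=(max(4.0, 0.6 * len(items) + 1.5), 3.5))
    bars = ax.bar(range(len(items)), values, yerr=errors, capsize=3,
                  color="#4878a8", edgecolor="black", linewidth=0.5)
    for bar, ns in zip(bars, nonsig):
        if ns:
            bar.set_hatch("///")
            bar.set_facecolor("#c8d8e8")
    ax.set_xticks(range(len(items)))
    ax.set_xticklabels(labels, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("frequency")
    locus = "~".join(est.loci)
    ax.set_title(f"{locus} allele frequencies (2N = {two_n})", fontsize=10)
    fig.tight_layout()
    path = Path(path)
    fmt = fmt or (path.suffix.lstrip(".") or "svg")
    if fmt not in ("svg", "png"):
        raise ValueError(f"unsupported format {fmt!r}; use svg or png")
    if fmt == "svg":
        # fixed hash salt + no date: byte-stable output for fixed input
        with plt.rc_context({"svg.hashsalt": "hlapop"}):
            fig.savefig(path, format=fmt, metadata={"Date": None})
    else:
        fig.savefig(path, format=fmt)
    plt.close(fig)
    return path
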