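"""Configured end-to-end pipeline: validate -> filter -> fit -> diagnose ->
summarize -> trend -> four-path, with reproducibility metadata.

Every run is driven by a :class:`RunConfig` (flat YAML on disk); all
outputs carry a metadata sidecar with the config hash and seed so results
are attributable to an exact configuration.  Summaries are refused when
the convergence diagnostics fail, unless the run is forced — in which case
the metadata carries a warning banner instead.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import diagnostics, summaries
from .model import (ChainConfig, ModelSpec, N_CATEGORIES, PosteriorChain,
                    add_eval_year, extract_ebv, filter_records, gibbs_fit,
                    load_records, posterior_summary)
from .pedigree import Pedigree, PedigreeError, load_pedigree

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; partial outputs are flagged."""


@dataclass
class RunConfig:
    pedigree: str = ""
    records: str = ""
    outdir: str = "out"
    traits: tuple = ("hip", "elbow")
    iterations: int = 100_000
    burn_in: int = 20_000
    thin: int = 20
    seed: int = 0
    min_age_months: int = 24
    loess_span: float = 0.75
    force: bool = False
    log_level: str = "INFO"

    def __post_init__(self):
        if isinstance(self.traits, str):
            self.traits = tuple(s.strip() for s in self.traits.split(",") if s.strip())
        else:
            self.traits = tuple(self.traits)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["traits"] = list(self.traits)
        return d

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_inputs(pedigree_file, records_file) -> list[dict]:
    """Cross-check a pedigree/records file pair; returns machine-readable
    issues (empty list = clean)."""
    issues: list[dict] = []
    ped = None
    try:
        ped = load_pedigree(pedigree_file)
    except (PedigreeError, OSError, ValueError) as exc:
        issues.append({"file": str(pedigree_file), "row": None,
                       "field": "pedigree", "issue": str(exc)})
    try:
        rec = load_records(records_file)
    except (OSError, ValueError) as exc:
        issues.append({"file": str(records_file), "row": None,
                       "field": "records", "issue": str(exc)})
        return issues
    score_range = {t: k for t, k in N_CATEGORIES.items()}
    for i, row in rec.iterrows():
        if ped is not None and str(row.get("animal")) not in ped:
            issues.append({"file": str(records_file), "row": int(i),
                           "field": "animal",
                           "issue": f"animal {row.get('animal')!r} not in pedigree"})
        sex = str(row.get("sex", "")).upper()
        if sex not in ("M", "F"):
            issues.append({"file": str(records_file), "row": int(i),
                           "field": "sex", "issue": f"invalid sex {row.get('sex')!r}"})
        age = pd.to_numeric(pd.Series([row.get("age_months")]), errors="coerce")[0]
        if pd.isna(age) or age < 0:
            issues.append({"file": str(records_file), "row": int(i),
                           "field": "age_months", "issue": "missing or negative age"})
        n_scores = 0
        for t, k in score_range.items():
            v = row.get(f"{t}_score")
            if pd.isna(v):
                continue
            n_scores += 1
            if not (float(v).is_integer() and 1 <= float(v) <= k):
                issues.append({"file": str(records_file), "row": int(i),
                               "field": f"{t}_score",
                               "issue": f"score {v!r} outside 1..{k}"})
        if n_scores == 0:
            issues.append({"file": str(records_file), "row": int(i),
                           "field": "scores", "issue": "no score recorded"})
        if pd.isna(row.get("eval_year", float("nan"))) and \
                not str(row.get("birth_date", "") or "").strip():
            issues.append({"file": str(records_file), "row": int(i),
                           "field": "birth_date",
                           "issue": "neither eval_year nor birth_date present"})
    return issues


def _sidecar(outdir: Path, config: RunConfig, extra: dict | None = None) -> None:
    meta = {"config": config.to_dict(), "config_hash": config.hash(),
            "seed": config.seed}
    meta.update(extra or {})
    (outdir / "run_metadata.json").write_text(json.dumps(meta, indent=2))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns a map of artifact paths.

    Raises :class:`PipelineError` (and leaves a flag in the metadata) when
    validation or diagnostics fail without ``force``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    issues = validate_inputs(config.pedigree, config.records)
    (outdir / "validation.json").write_text(json.dumps(issues, indent=2))
    artifacts["validation"] = str(outdir / "validation.json")
    if issues:
        _sidecar(outdir, config, {"failed_stage": "validate",
                                  "n_issues": len(issues)})
        raise PipelineError(
            f"input validation found {len(issues)} issue(s); first: "
            f"{issues[0]['issue']}")

    ped = load_pedigree(config.pedigree)
    records = add_eval_year(load_records(config.records))
    records = filter_records(records, config.min_age_months)

    spec = ModelSpec(traits=config.traits,
                     n_categories={t: N_CATEGORIES[t] for t in config.traits})
    chain = gibbs_fit(ped, records, spec=spec,
                      chain=ChainConfig(total_iterations=config.iterations,
                                        burn_in=config.burn_in,
                                        thin=config.thin, seed=config.seed))
    chain_dir = outdir / "chain"
    chain.save(chain_dir)
    artifacts["chain"] = str(chain_dir)

    report = diagnostics.convergence_report(chain)
    (outdir / "diagnostics.json").write_text(report.to_json())
    artifacts["diagnostics"] = str(outdir / "diagnostics.json")
    warning = None
    if not report.passed:
        if not config.force:
            _sidecar(outdir, config, {"failed_stage": "diagnose"})
            raise PipelineError(
                "convergence diagnostics failed (autocorrelation/trend); "
                "rerun longer or pass force=True to emit summaries anyway")
        warning = "diagnostics failed; summaries emitted under force"
        logger.warning(warning)

    gsum = summaries.summarize_genetics(chain)
    sa = summaries.sex_age_report(chain)
    summary = {
        "genetics": gsum.to_dict(),
        "sex_age_effects": sa.to_dict(orient="records"),
        "prevalence": {t: summaries.prevalence(records, t)
                       for t in config.traits if records[f"{t}_score"].notna().any()},
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))
    posterior_summary(chain).to_csv(outdir / "posterior_summary.csv", index=False)
    artifacts["summary"] = str(outdir / "summary.json")

    ebv = extract_ebv(chain)
    trend_frames = []
    for t in config.traits:
        ts = summaries.genetic_trend(ebv, ped, trait=t, span=config.loess_span)
        tab = ts.table.copy()
        tab.insert(0, "trait", t)
        trend_frames.append(tab)
    pd.concat(trend_frames, ignore_index=True).to_csv(
        outdir / "trend.csv", index=False)
    artifacts["trend"] = str(outdir / "trend.csv")

    fp_frames = []
    fits = {}
    for t in config.traits:
        fp = summaries.four_path(ebv, ped, trait=t)
        tab = fp.table.copy()
        tab.insert(0, "trait", t)
        fp_frames.append(tab)
        fits[t] = fp.fits
    pd.concat(fp_frames, ignore_index=True).to_csv(
        outdir / "fourpath.csv", index=False)
    (outdir / "fourpath_fits.json").write_text(json.dumps(fits, indent=2))
    artifacts["fourpath"] = str(outdir / "fourpath.csv")

    _sidecar(outdir, config, {"diagnostics_passed": report.passed,
                              "warning": warning})
    artifacts["metadata"] = str(outdir / "run_metadata.json")
    return artifacts
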