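"""End-to-end orchestration: simulate/load -> harmonize -> MR -> MVMR.

A run is described by a :class:`RunConfig` (usually loaded from YAML) and
produces a deterministic report bundle: a method-by-method estimate table
laid out like the study's summary tables (median variants, IVW variants,
Egger variants with intercept rows, MR-horse, and total/direct mediation
rows when mediators are present), heterogeneity statistics, exclusion
logs, and a machine-readable YAML carrying every reported number.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .horse import MCMCConfig, mr_horse
from .mr import egger, heterogeneity, ivw, median_estimators, radial_outliers
from .mvmr import mediation_decompose
from .sumstats import harmonize, read_sumstats, subset_by_annotation
from .synthetic import MediatorSpec, SumstatsScenario, gen_twosample_sumstats

logger = logging.getLogger(__name__)

DEFAULT_METHODS = ("median", "ivw", "egger", "horse")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """One analysis run: exactly one of a simulation scenario or real inputs."""

    out_dir: str
    seed: int = 0
    simulate: dict | None = None
    inputs: dict | None = None
    methods: tuple = DEFAULT_METHODS
    penalized: bool = True
    robust: bool = True
    outlier_removal: bool = False
    outlier_alpha: float = 0.05
    palindrome_eaf_window: float = 0.08
    annotation: str | None = None
    n_boot: int = 1000
    horse: dict = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("config must set exactly one of 'simulate' or 'inputs'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def canonical(self) -> str:
        # analysis identity: exclude where the report goes and how chatty it is
        d = {k: v for k, v in self.__dict__.items() if k not in ("out_dir", "log_level")}
        d["methods"] = list(self.methods)
        return yaml.safe_dump(d, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


def _build_instrument_set(config: RunConfig):
    if config.simulate is not None:
        spec = dict(config.simulate)
        med = spec.pop("mediator_spec", None)
        if med is not None:
            med = MediatorSpec(**med)
        scenario = SumstatsScenario(**spec, mediator_spec=med, seed=config.seed)
        exposure, outcome, mediator, truth = gen_twosample_sumstats(scenario)
        mediators = {scenario.mediator_spec.label: mediator} if mediator is not None else {}
    else:
        exposure = read_sumstats(config.inputs["exposure"])
        outcome = read_sumstats(config.inputs["outcome"])
        mediators = {
            label: read_sumstats(path)
            for label, path in (config.inputs.get("mediators") or {}).items()
        }
        truth = None
    iset = harmonize(
        exposure, outcome, mediators,
        palindrome_eaf_window=config.palindrome_eaf_window,
    )
    return iset, truth


def _estimate_rows(iset, config: RunConfig, rng_seeds):
    rows = []
    het = None

    def add(est):
        rows.append(est.as_dict())

    if "median" in config.methods:
        add(median_estimators(iset, "simple", n_boot=config.n_boot, seed=rng_seeds["median"]))
        add(median_estimators(iset, "weighted", n_boot=config.n_boot, seed=rng_seeds["median"]))
        if config.penalized:
            add(median_estimators(iset, "penalized_weighted", n_boot=config.n_boot,
                                  seed=rng_seeds["median"]))
    if "ivw" in config.methods:
        est, het = ivw(iset)
        add(est)
        if config.penalized:
            add(ivw(iset, penalized=True)[0])
        if config.robust:
            add(ivw(iset, robust=True)[0])
        if config.penalized and config.robust:
            add(ivw(iset, penalized=True, robust=True)[0])
    if "egger" in config.methods:
        add(egger(iset))
        if config.penalized:
            add(egger(iset, penalized=True))
        if config.robust:
            add(egger(iset, robust=True))
        if config.penalized and config.robust:
            add(egger(iset, penalized=True, robust=True))
    if "horse" in config.methods:
        horse_cfg = MCMCConfig(seed=rng_seeds["horse"], **config.horse)
        rows.append(mr_horse(iset, mcmc_config=horse_cfg).as_dict())
    if het is None and iset.n_snps >= 2:
        w = 1.0 / iset.se_outcome**2
        theta = float(np.sum(w * iset.beta_exposure * iset.beta_outcome)
                      / np.sum(w * iset.beta_exposure**2))
        het = heterogeneity(iset, theta)
    return rows, het


def run_analysis(config: RunConfig) -> dict:
    """Run the configured analysis and write the report bundle.

    Deterministic given the config seed. Returns the report dict that is
    also written as ``results.yaml``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    base = np.random.SeedSequence(config.seed)
    child = base.spawn(4)
    rng_seeds = {
        "median": child[0],
        "horse": int(child[1].generate_state(1)[0] % (2**31)),
        "mediation": child[2],
    }

    try:
        iset, truth = _build_instrument_set(config)
    except Exception as e:  # noqa: BLE001
        raise PipelineError("harmonize", str(e)) from e
    if iset.n_snps < 3:
        raise PipelineError("harmonize", f"only {iset.n_snps} SNPs retained")
    logger.info("instrument set: %d SNPs retained, %d excluded",
                iset.n_snps, len(iset.exclusions))

    strata = {"all": iset}
    if config.annotation:
        ann = pd.read_csv(config.annotation, sep="\t")
        try:
            strata = subset_by_annotation(iset, ann)
        except Exception as e:  # noqa: BLE001
            raise PipelineError("annotation", str(e)) from e

    report = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_snps": iset.n_snps,
        "strata": {},
        "exclusions": iset.exclusions.to_dict("records"),
    }
    estimate_frames = []
    for label, sub in strata.items():
        try:
            rows, het = _estimate_rows(sub, config, rng_seeds)
        except Exception as e:  # noqa: BLE001
            raise PipelineError(f"mr:{label}", str(e)) from e
        stratum = {"n_snps": sub.n_snps, "estimates": rows,
                   "heterogeneity": het.as_dict() if het else None}

        if config.outlier_removal:
            try:
                outliers, trimmed = radial_outliers(sub, alpha_level=config.outlier_alpha)
                est_trim, het_trim = ivw(trimmed)
                stratum["outliers_removed"] = outliers
                stratum["ivw_outliers_removed"] = est_trim.as_dict()
                stratum["heterogeneity_outliers_removed"] = het_trim.as_dict()
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"outliers:{label}", str(e)) from e

        if sub.mediators:
            try:
                med = mediation_decompose(sub, n_boot=config.n_boot,
                                          seed=rng_seeds["mediation"])
            except Exception as e:  # noqa: BLE001
                raise PipelineError(f"mvmr:{label}", str(e)) from e
            stratum["mediation"] = med.as_dict()
            rows = [med.total.as_dict(), med.direct.as_dict()] + rows

        report["strata"][label] = stratum
        frame = pd.DataFrame(rows)
        frame.insert(0, "stratum", label)
        estimate_frames.append(frame)

    if truth is not None:
        report["truth"] = {
            "theta": truth["theta"],
            "theta_total": truth["theta_total"],
            "n_invalid": int((~truth["snps"]["valid"]).sum()),
        }

    estimates = pd.concat(estimate_frames, ignore_index=True)
    estimates.to_csv(out / "estimates.tsv", sep="\t", index=False, float_format="%.10g")
    iset.write_exclusions(out / "exclusions.tsv")
    het_rows = [
        {"stratum": label, **s["heterogeneity"]}
        for label, s in report["strata"].items() if s["heterogeneity"]
    ]
    pd.DataFrame(het_rows).to_csv(out / "heterogeneity.tsv", sep="\t", index=False,
                                  float_format="%.10g")
    med_rows = []
    for label, s in report["strata"].items():
        if "mediation" in s:
            m = s["mediation"]
            med_rows.append({"stratum": label, "effect": "Total effect",
                             **{k: v for k, v in m["total"].items() if k != "method"}})
            med_rows.append({"stratum": label, "effect": "Direct effects",
                             **{k: v for k, v in m["direct"].items() if k != "method"}})
    if med_rows:
        pd.DataFrame(med_rows).to_csv(out / "mediation.tsv", sep="\t", index=False,
                                      float_format="%.10g")

    with open(out / "results.yaml", "w") as fh:
        yaml.safe_dump(_to_plain(report), fh, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write(f"carriermr {__version__}\n")
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"config_hash: {config.config_hash()}\n")
        fh.write(f"n_snps_retained: {iset.n_snps}\n")
        fh.write(f"n_excluded: {len(iset.exclusions)}\n")
    return report


def _to_plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialization."""
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj
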