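"""End-to-end orchestration: simulate/load -> QC -> scan -> cocktail -> report.

A run is described by one YAML config (exactly one of a simulation block or
input paths), executes with a single master seed, and writes tab-delimited
tables whose header comments record the config hash and seed so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cocktail import cocktail_scan
from .exposures import harmonize_alcohol
from .genio import read_genotypes
from .meta import genomic_lambda, qq_points
from .models import DEFAULT_COVARIATES
from .qc import QCThresholds, qc_filter
from .scan import interaction_scan
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["RunConfig", "run_scan", "load_config", "genomewide_flags"]

GENOMEWIDE_ALPHA = 5e-8


@dataclass
class RunConfig:
    simulation: SimulationConfig | None = None
    genotype_path: str | None = None
    genotype_format: str = "vcf"
    phenotype_path: str | None = None
    exposure_col: str = "alcohol_cat"
    scheme: str = "study_sex"
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    qc: QCThresholds = field(default_factory=QCThresholds)
    alpha: float = GENOMEWIDE_ALPHA
    n_exposures: int = 2            # Bonferroni-across-exposures divisor
    cocktail_alpha: float = 0.05
    cocktail_base_group_size: int = 5
    out_dir: str = "results/run"
    seed: int = 0

    def __post_init__(self) -> None:
        sim = self.simulation is not None
        paths = self.genotype_path is not None or self.phenotype_path is not None
        if sim == paths:
            raise ValueError("exactly one of simulation config or input paths must be given")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = raw.pop("simulation", None)
    if sim is not None:
        for key in ("exposure_probs", "null_maf_range", "imputation_r2_range"):
            if key in sim:
                sim[key] = tuple(sim[key])
        sim = SimulationConfig(**sim)
    qc = raw.pop("qc", None)
    kwargs = dict(raw)
    if "covariates" in kwargs:
        kwargs["covariates"] = tuple(kwargs["covariates"])
    cfg = RunConfig(simulation=sim, qc=QCThresholds(**qc) if qc else QCThresholds(), **kwargs)
    return cfg


def _config_hash(cfg: RunConfig) -> str:
    def enc(o):
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        return str(o)

    blob = json.dumps(dataclasses.asdict(cfg), default=enc, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _write_table(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def genomewide_flags(p_values, alpha: float = GENOMEWIDE_ALPHA, n_exposures: int = 2):
    """Genome-wide and Bonferroni-across-exposures significance flags.

    The across-exposure flag divides alpha by the number of exposures
    scanned (e.g. 5e-8 / 2 = 2.5e-8 for alcohol + smoking); it is a
    reporting flag, not a hard filter.
    """
    p = np.asarray(p_values, dtype=float)
    with np.errstate(invalid="ignore"):
        gw = p < alpha
        bonf = p < alpha / n_exposures
    return gw & np.isfinite(p), bonf & np.isfinite(p)


def _load_inputs(cfg: RunConfig):
    if cfg.simulation is not None:
        sim = dataclasses.replace(cfg.simulation, seed=cfg.seed)
        return simulate_cohort(sim)
    cohort = pd.read_csv(cfg.phenotype_path, sep="\t")
    gm = read_genotypes(cfg.genotype_path, format=cfg.genotype_format)
    ids = list(cohort["subject_id"].astype(str))
    if gm.samples and list(gm.samples) != ids:
        lookup = {s: i for i, s in enumerate(gm.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise ValueError(f"phenotype subjects missing from genotypes: {missing[:5]}...")
        gm = dataclasses.replace(gm, dosage=gm.dosage[:, [lookup[s] for s in ids]], samples=ids)
    if "alcohol_cat" not in cohort.columns and "alcohol_gday" in cohort.columns:
        cohort["alcohol_cat"] = harmonize_alcohol(cohort["alcohol_gday"].to_numpy())
    return cohort, gm


def run_scan(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the results bundle.

    Bundle keys: cohort, genotypes (post-QC), qc_report, scan (one row per
    QC-passing variant), cocktail, lambda (per interaction term), qq (per
    term), flags.  Tables are also written under cfg.out_dir.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tag = _config_hash(cfg)
    hdr = [f"gxescan {__version__}", f"config_hash={tag}", f"seed={cfg.seed}"]
    log: list[str] = []

    def stage(name, **kv):
        log.append(" ".join([f"stage={name}"] + [f"{k}={v}" for k, v in kv.items()]))

    cohort, gm = _load_inputs(cfg)
    stage("input", subjects=len(cohort), variants=gm.n_variants,
          cases=int((cohort["status"] == 1).sum()), controls=int((cohort["status"] == 0).sum()))

    gm_pass, qc_report = qc_filter(gm, cohort, cfg.qc)
    stage("qc", kept=gm_pass.n_variants, dropped=gm.n_variants - gm_pass.n_variants)

    scan = interaction_scan(cohort, gm_pass, covariates=cfg.covariates,
                            exposure_col=cfg.exposure_col, scheme=cfg.scheme)
    lambdas, qq = {}, {}
    for term in ("GxE1", "GxE2"):
        col = f"p_{term}"
        if col in scan.columns:
            p = scan[col].to_numpy(dtype=float)
            p = p[np.isfinite(p)]
            if p.size:
                lambdas[term] = genomic_lambda(p)
                exp_q, obs_q = qq_points(p)
                qq[term] = pd.DataFrame({"expected": exp_q, "observed": obs_q})
    gw, bonf = genomewide_flags(scan.get("p_GxE1", pd.Series(dtype=float)),
                                alpha=cfg.alpha, n_exposures=cfg.n_exposures)
    scan["genomewide_sig"] = gw
    scan["bonferroni_exposures_sig"] = bonf
    stage("scan", variants=len(scan), genomewide_hits=int(gw.sum()),
          **{f"lambda_{k}": f"{v:.4f}" for k, v in lambdas.items()})

    cocktail = cocktail_scan(cohort, gm_pass, exposure_col=cfg.exposure_col,
                             alpha=cfg.cocktail_alpha,
                             base_group_size=cfg.cocktail_base_group_size)
    stage("cocktail", significant=int(cocktail["significant"].sum()))

    _write_table(qc_report, out_dir / "qc_report.tsv", hdr)
    _write_table(scan, out_dir / "scan.tsv", hdr)
    _write_table(cocktail, out_dir / "cocktail.tsv", hdr)
    for term, df in qq.items():
        _write_table(df, out_dir / f"qq_{term}.tsv", hdr)
    with open(out_dir / "lambda.json", "w") as fh:
        json.dump({k: round(v, 6) for k, v in lambdas.items()}, fh, indent=1, sort_keys=True)
    with open(out_dir / "run.log", "w") as fh:
        fh.write("\n".join(hdr + log) + "\n")

    return {
        "cohort": cohort,
        "genotypes": gm_pass,
        "qc_report": qc_report,
        "scan": scan,
        "cocktail": cocktail,
        "lambda": lambdas,
        "qq": qq,
        "config_hash": tag,
    }
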