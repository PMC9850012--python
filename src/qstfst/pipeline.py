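"""Orchestration: simulate -> QC -> FST -> per-ring model battery -> QST ->
divergence verdicts, as a configured, logged, reproducible run.

Stages communicate only through their serialized outputs in the run
directory; a manifest records the configuration hash, the seed, package
version and a checksum per output file, so a rerun with the same
configuration and seed reproduces every output bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import bonferroni_threshold, verdict_table
from .fst import pairwise_fst_distribution
from .genotypes import (
    filter_genotype_class_count,
    filter_missingness,
    pca_genotypes,
    read_vcf,
)
from .quantgen import (
    filter_families,
    normalize_traits,
    per_ring_battery,
    prepare_rings,
    qst_per_trait,
)
from .simdata import SimConfig, simulate_dataset

log = logging.getLogger("qstfst")

__all__ = ["RunConfig", "run_pipeline", "StageError", "ConfigError"]


class ConfigError(ValueError):
    """Invalid run configuration (exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (exit code 3)."""


@dataclass
class RunConfig:
    """Parsed YAML configuration for one run."""

    outdir: Path
    seed: int
    vcf: Path | None = None
    popfile: Path | None = None
    phenotypes: Path | None = None
    simulate: dict | None = None
    min_per_class: int = 5
    max_sample_missing: float = 0.7
    max_locus_missing: float = 0.7
    min_offspring_per_site: int = 4
    max_ring: int = 13
    drop_innermost: int = 2
    last_calendar_year: int = 2008
    alpha: float = 0.05
    n_perm: int = 1000
    battery_model: int = 2
    pca_components: int = 2
    family_var_scale: float = 2.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "seed" not in raw:
            raise ConfigError("config must set an explicit seed")
        if "outdir" not in raw:
            raise ConfigError("config must set outdir")
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{**raw, "outdir": Path(raw["outdir"])})
        has_inputs = cfg.vcf and cfg.popfile and cfg.phenotypes
        if not has_inputs and cfg.simulate is None:
            raise ConfigError(
                "config needs either input paths (vcf, popfile, phenotypes) "
                "or a simulate block"
            )
        if has_inputs:
            for p in (cfg.vcf, cfg.popfile, cfg.phenotypes):
                if not Path(p).exists():
                    raise ConfigError(f"input not found: {p}")
        return cfg

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in self.__dict__.items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class _Run:
    cfg: RunConfig
    outputs: dict = field(default_factory=dict)

    def record(self, name: str, path: Path):
        self.outputs[name] = {"path": str(path), "sha256": _sha256(path)}

    def write_manifest(self):
        manifest = {
            "version": __version__,
            "seed": self.cfg.seed,
            "config_hash": self.cfg.config_hash(),
            "outputs": self.outputs,
        }
        path = self.cfg.outdir / "manifest.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage_simulate(run: _Run):
    cfg = run.cfg
    sim_cfg = SimConfig(**{**(cfg.simulate or {}), "seed": cfg.seed})
    out = simulate_dataset(sim_cfg)
    paths = out.write(cfg.outdir / "simulated")
    for k, v in paths.items():
        run.record(f"simulate/{k}", Path(v))
    cfg.vcf = Path(paths["vcf"])
    cfg.popfile = Path(paths["popfile"])
    cfg.phenotypes = Path(paths["phenotypes"])


def _stage_qc(run: _Run):
    cfg = run.cfg
    G = read_vcf(cfg.vcf, cfg.popfile)
    G1, rep1 = filter_missingness(G, cfg.max_sample_missing, cfg.max_locus_missing)
    G2, rep2 = filter_genotype_class_count(G1, cfg.min_per_class)
    report = pd.concat([rep1.to_frame(), rep2.to_frame()])
    qcdir = cfg.outdir / "qc"
    qcdir.mkdir(parents=True, exist_ok=True)
    report.to_csv(qcdir / "filter_report.tsv", sep="\t", index=False)
    run.record("qc/filter_report", qcdir / "filter_report.tsv")
    from .genotypes import write_vcf

    write_vcf(G2, qcdir / "filtered.vcf", popfile=qcdir / "populations.tsv")
    run.record("qc/filtered_vcf", qcdir / "filtered.vcf")
    run.record("qc/populations", qcdir / "populations.tsv")
    scores, pve = pca_genotypes(G2, n_components=cfg.pca_components)
    scores.to_csv(qcdir / "pca_scores.tsv", sep="\t")
    (qcdir / "pca_pve.json").write_text(json.dumps({"percent_variance": pve.tolist()}))
    run.record("qc/pca_scores", qcdir / "pca_scores.tsv")
    run.record("qc/pca_pve", qcdir / "pca_pve.json")
    log.info("QC: %d -> %d samples, %d -> %d loci",
             G.n_samples, G2.n_samples, G.n_loci, G2.n_loci)


def _stage_fst(run: _Run):
    cfg = run.cfg
    qcdir = cfg.outdir / "qc"
    G = read_vcf(qcdir / "filtered.vcf", qcdir / "populations.tsv")
    dist = pairwise_fst_distribution(G)
    fstdir = cfg.outdir / "fst"
    fstdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"chrom": G.loci["chrom"], "pos": G.loci["pos"], "fst": dist.per_snp}
    ).to_csv(fstdir / "per_snp.tsv", sep="\t", index=False)
    (fstdir / "summary.json").write_text(json.dumps(dist.summary(), indent=2))
    np.savetxt(fstdir / "positive_part.txt", dist.positive_part)
    for name in ("per_snp.tsv", "summary.json", "positive_part.txt"):
        run.record(f"fst/{name}", fstdir / name)
    log.info("FST: mean=%.4f q95=%.4f", dist.mean_fst, dist.q95)


def _load_prepared_phenotypes(cfg: RunConfig):
    raw = pd.read_csv(cfg.phenotypes, sep="\t")
    tab, _ = prepare_rings(raw, cfg.max_ring, cfg.drop_innermost, cfg.last_calendar_year)
    tab, _ = filter_families(tab, cfg.min_offspring_per_site)
    return normalize_traits(tab)


def _stage_battery(run: _Run):
    cfg = run.cfg
    tab = _load_prepared_phenotypes(cfg)
    _, summary = per_ring_battery(tab, model_id=cfg.battery_model, alpha=cfg.alpha)
    outdir = cfg.outdir / "battery"
    outdir.mkdir(parents=True, exist_ok=True)
    summary.to_csv(outdir / "wald_tests.tsv", sep="\t", index=False)
    meta = {
        "model": cfg.battery_model,
        "n_tests": summary.attrs["n_tests"],
        "bonferroni_cutoff": bonferroni_threshold(cfg.alpha, summary.attrs["n_tests"]),
    }
    (outdir / "battery.json").write_text(json.dumps(meta, indent=2))
    run.record("battery/wald_tests", outdir / "wald_tests.tsv")
    run.record("battery/meta", outdir / "battery.json")


def _stage_qst(run: _Run):
    cfg = run.cfg
    tab = _load_prepared_phenotypes(cfg)
    results = qst_per_trait(tab, family_var_scale=cfg.family_var_scale)
    outdir = cfg.outdir / "qst"
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for trait, res in results.items():
        for ring, v in res.per_ring_qst.items():
            rows.append({"trait": trait, "ring": ring, "qst": v})
        rows.append({"trait": trait, "ring": "mean", "qst": res.mean_qst})
    pd.DataFrame(rows).to_csv(outdir / "qst.tsv", sep="\t", index=False)
    run.record("qst/qst", outdir / "qst.tsv")


def _stage_compare(run: _Run):
    cfg = run.cfg
    qst_tab = pd.read_csv(cfg.outdir / "qst" / "qst.tsv", sep="\t")
    means = qst_tab[qst_tab["ring"] == "mean"].set_index("trait")["qst"]
    pos = np.loadtxt(cfg.outdir / "fst" / "positive_part.txt")
    summary = json.loads((cfg.outdir / "fst" / "summary.json").read_text())
    from .fst import FstDistribution

    dist = FstDistribution(
        per_snp=pos, n_pairs_used=np.ones_like(pos), mean_method=summary["mean_method"],
        mean_fst=summary["mean_fst"], ratio_of_sums=summary["ratio_of_sums"],
        positive_part=np.sort(pos), q95=summary["q95"],
    )

    class _R:
        def __init__(self, m):
            self.mean_qst = m

    table = verdict_table({t: _R(m) for t, m in means.items()}, dist)
    outdir = cfg.outdir / "compare"
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "verdicts.tsv", sep="\t", index=False)
    (outdir / "summary.json").write_text(
        json.dumps({"fst": summary, "verdicts": table.to_dict(orient="records")},
                   indent=2)
    )
    run.record("compare/verdicts", outdir / "verdicts.tsv")
    run.record("compare/summary", outdir / "summary.json")


_STAGES = {
    "simulate": _stage_simulate,
    "qc": _stage_qc,
    "fst": _stage_fst,
    "fitbattery": _stage_battery,
    "qst": _stage_qst,
    "compare": _stage_compare,
}


def run_pipeline(cfg: RunConfig, stages=None):
    """Run the requested stages (default: all that apply) in order."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        stages = list(_STAGES)
        if cfg.simulate is None:
            stages.remove("simulate")
    run = _Run(cfg)
    for name in stages:
        log.info("stage: %s", name)
        try:
            _STAGES[name](run)
        except Exception as exc:
            run.write_manifest()
            raise StageError(f"stage {name!r} failed: {exc}") from exc
        run.write_manifest()
    return run
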