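"""End-to-end pipeline stages with reproducible configs and manifests.

Stages: ``simulate`` (synthetic study), ``fit`` (hierarchical MCMC +
convergence table + population posterior summary), ``validate``
(posterior-predictive check of the 16 movement statistics), ``syndromes``
(residual matrix, PCA, k-means, silhouette, biplot) and ``report`` (one
summary document).  Every stage writes its fully-resolved configuration
and a manifest of content hashes next to its outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .hierarchy import MCMCConfig, PosteriorChains, gelman_rubin, run_mcmc, trait_summaries
from .likelihood import IndividualParams
from .simulate import posterior_predictive
from .stats import residual_stats, stats_table
from .syndromes import biplot, centroid_table, detect_syndromes

log = logging.getLogger("movesynd")

STAGES = ("simulate", "fit", "validate", "syndromes", "report")


class MissingInputError(FileNotFoundError):
    pass


@dataclass
class PipelineConfig:
    seed: int = 1
    study: synthetic.StudyConfig = field(default_factory=synthetic.small_study_config)
    mcmc_n_adapt: int = 1000
    mcmc_n_iter: int = 3000
    mcmc_n_chains: int = 2
    mcmc_thin: int = 5
    n_rep: int = 250
    k_min: int = 2
    k_max: int = 8
    min_detections: int = 1

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        study = synthetic.StudyConfig(**raw.pop("study", {}))
        return cls(study=study, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _write_manifest(outdir: Path) -> None:
    entries = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            entries[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    (outdir / "manifest.json").write_text(json.dumps(entries, indent=1))


def _dump_config(config: PipelineConfig, outdir: Path) -> None:
    (outdir / "config_resolved.yaml").write_text(yaml.safe_dump(config.to_dict()))


def _require(path: Path, hint: str) -> Path:
    if not path.exists():
        raise MissingInputError(f"missing input {path} -- run the {hint} stage first")
    return path


def run_simulate(config: PipelineConfig, outdir) -> synthetic.SyntheticStudy:
    out = Path(outdir) / "study"
    study = synthetic.make_dataset(config.study, seed=config.seed)
    study.save(out)
    n_empty = sum(1 for h in study.histories if h.n_detections == 0)
    if n_empty:
        log.warning("%d individuals were never detected after release", n_empty)
    _dump_config(config, out)
    _write_manifest(out)
    return study


def _load_study(outdir) -> synthetic.SyntheticStudy:
    return synthetic.SyntheticStudy.load(_require(Path(outdir) / "study", "simulate"))


def run_fit(config: PipelineConfig, outdir) -> PosteriorChains:
    out = Path(outdir) / "fit"
    out.mkdir(parents=True, exist_ok=True)
    study = _load_study(outdir)
    data = study.study_data(min_detections=config.min_detections)
    mcmc = MCMCConfig(
        n_adapt=config.mcmc_n_adapt,
        n_iter=config.mcmc_n_iter,
        n_chains=config.mcmc_n_chains,
        thin=config.mcmc_thin,
        seed=config.seed,
    )
    chains = run_mcmc(data, mcmc)
    for c in range(chains.n_chains):
        log.info(
            "chain %d acceptance rates per individual: %s",
            c,
            np.round(chains.acceptance[c], 3).tolist(),
        )
    summary = chains.summary_table()
    summary.to_csv(out / "posterior_summary.csv", float_format="%.6g")
    psrf = gelman_rubin(chains)
    psrf.rename("psrf").to_csv(out / "gelman_rubin.csv")
    bad = psrf[psrf > 1.1].dropna()
    if len(bad):
        log.warning("unconverged scalars (PSRF > 1.1): %s", bad.index.tolist())
        (out / "convergence_warnings.txt").write_text("\n".join(bad.index))
    pd.DataFrame(
        chains.theta_posterior_mean(),
        index=data.traits.ids,
        columns=list(IndividualParams.NAMES),
    ).to_csv(out / "theta_posterior_mean.csv", float_format="%.8g")
    trait_summaries(chains, data.traits).to_csv(out / "trait_summaries.csv", float_format="%.4g")
    chains.to_frame().to_csv(out / "chains.csv", index=False, float_format="%.8g")
    _dump_config(config, out)
    _write_manifest(out)
    return chains


def _reload_chains(outdir, data) -> PosteriorChains:
    """Rebuild a PosteriorChains object from the tidy chains.csv."""
    path = _require(Path(outdir) / "fit" / "chains.csv", "fit")
    df = pd.read_csv(path)
    ids = data.traits.ids
    n_chains = df["chain"].nunique()
    n_draws = df["iter"].nunique()
    n_i = len(ids)
    theta = np.empty((n_chains, n_draws, n_i, 7))
    zeta = np.empty((n_chains, n_draws, 3, 7))
    sigma = np.zeros((n_chains, n_draws, 7, 7))
    names = list(IndividualParams.NAMES)
    piv = df.pivot_table(index=["chain", "iter"], columns="parameter", values="value")
    for i, ind in enumerate(ids):
        for p, nm in enumerate(names):
            col = piv[f"theta[{ind},{nm}]"].to_numpy().reshape(n_chains, n_draws)
            theta[:, :, i, p] = col
    for a, tr in enumerate(("intercept", "sex", "logweight")):
        for p, nm in enumerate(names):
            zeta[:, :, a, p] = piv[f"zeta[{tr},{nm}]"].to_numpy().reshape(n_chains, n_draws)
    for p, nm in enumerate(names):
        sigma[:, :, p, p] = piv[f"sigma[{nm},{nm}]"].to_numpy().reshape(n_chains, n_draws)
    cfg = MCMCConfig(seed=0)
    return PosteriorChains(
        theta=theta,
        zeta=zeta,
        sigma=sigma,
        acceptance=np.full((n_chains, n_i), np.nan),
        config=cfg,
        individual_ids=ids,
    )


def run_validate(config: PipelineConfig, outdir, chains: PosteriorChains | None = None):
    out = Path(outdir) / "validate"
    out.mkdir(parents=True, exist_ok=True)
    study = _load_study(outdir)
    data = study.study_data(min_detections=config.min_detections)
    fit_study = _predictive_view(study, config.min_detections)
    if chains is None:
        chains = _reload_chains(outdir, data)
    population, per_individual = posterior_predictive(
        chains, fit_study, n_rep=config.n_rep, seed=config.seed
    )
    population.to_csv(out / "predictive_population.csv", index=False, float_format="%.6g")
    per_individual.to_csv(out / "predictive_individual_mean.csv", float_format="%.6g")
    observed = stats_table(data.histories, study.loggers, study.logger_habitat)
    observed.to_csv(out / "observed_stats.csv", float_format="%.6g")
    obs_pop = observed.mean(axis=0, skipna=True)
    lo = population.quantile(0.025)
    hi = population.quantile(0.975)
    report = pd.DataFrame(
        {
            "observed": obs_pop,
            "replicate_mean": population.mean(),
            "q0.025": lo,
            "q0.975": hi,
            "inside_95": (obs_pop >= lo) & (obs_pop <= hi),
        }
    )
    report.to_csv(out / "predictive_check.csv", float_format="%.6g")
    _dump_config(config, out)
    _write_manifest(out)
    return report


def _predictive_view(study: synthetic.SyntheticStudy, min_detections: int):
    """Study restricted to fitted individuals (chains align with these)."""
    keep = [i for i, h in enumerate(study.histories) if h.n_detections >= min_detections]
    import copy

    view = copy.copy(study)
    view.histories = [study.histories[i] for i in keep]
    from .hierarchy import TraitMatrix

    view.traits = TraitMatrix(
        ids=[study.traits.ids[i] for i in keep], matrix=study.traits.matrix[keep]
    )
    return view


def run_syndromes(config: PipelineConfig, outdir, chains: PosteriorChains | None = None):
    out = Path(outdir) / "syndromes"
    out.mkdir(parents=True, exist_ok=True)
    study = _load_study(outdir)
    data = study.study_data(min_detections=config.min_detections)
    observed = pd.read_csv(
        _require(Path(outdir) / "validate" / "observed_stats.csv", "validate"), index_col=0
    )
    predictive = pd.read_csv(
        Path(outdir) / "validate" / "predictive_individual_mean.csv", index_col=0
    )
    theta_mean = pd.read_csv(
        _require(Path(outdir) / "fit" / "theta_posterior_mean.csv", "fit"), index_col=0
    )
    common = observed.index
    matrix = residual_stats(
        observed.loc[common],
        predictive.loc[common],
        theta_mean.loc[common].to_numpy(),
    )
    matrix.to_csv(out / "residual_matrix.csv", float_format="%.6g")
    result = detect_syndromes(
        matrix, k_range=range(config.k_min, config.k_max + 1), seed=config.seed
    )
    pd.DataFrame(
        {
            "individual_id": matrix.index,
            "cluster": result.assignments,
            "PC1": result.scores[:, 0],
            "PC2": result.scores[:, 1],
        }
    ).to_csv(out / "assignments.csv", index=False, float_format="%.6g")
    centroid_table(result).to_csv(out / "centroids.csv", float_format="%.4g")
    result.silhouette.rename("mean_silhouette").to_csv(out / "silhouette.csv")
    pd.Series(result.variance_fraction, name="variance_fraction").to_csv(
        out / "pca_variance.csv", index_label="component"
    )
    biplot(result, out / "biplot.png")
    _dump_config(config, out)
    _write_manifest(out)
    return result


def run_report(config: PipelineConfig, outdir) -> str:
    out = Path(outdir)
    lines = ["# Movement-syndrome pipeline report", ""]
    summary = _require(out / "fit" / "posterior_summary.csv", "fit")
    lines += ["## Population posterior summary", "", pd.read_csv(summary).to_string(index=False), ""]
    psrf = pd.read_csv(out / "fit" / "gelman_rubin.csv", index_col=0)["psrf"]
    lines += [
        "## Convergence",
        "",
        f"max PSRF = {psrf.max():.3f} over {len(psrf)} scalars "
        f"({int((psrf > 1.1).sum())} above 1.1)",
        "",
    ]
    check = pd.read_csv(_require(out / "validate" / "predictive_check.csv", "validate"), index_col=0)
    inside = int(check["inside_95"].sum())
    lines += [
        "## Posterior-predictive check",
        "",
        f"{inside} of {len(check)} population-mean statistics inside the central 95 % band",
        "",
        check.to_string(),
        "",
    ]
    sil = pd.read_csv(_require(out / "syndromes" / "silhouette.csv", "syndromes"), index_col=0)
    best_k = int(sil["mean_silhouette"].idxmax())
    lines += [
        "## Movement syndromes",
        "",
        f"Average Silhouette Method selects k = {best_k}",
        "",
        sil.to_string(),
        "",
    ]
    text = "\n".join(lines)
    (out / "report.md").write_text(text)
    _write_manifest(out)
    return text


def run_stage(stage: str, config: PipelineConfig, outdir):
    """Dispatch one pipeline stage; see module docstring for the contract."""
    if stage == "simulate":
        return run_simulate(config, outdir)
    if stage == "fit":
        return run_fit(config, outdir)
    if stage == "validate":
        return run_validate(config, outdir)
    if stage == "syndromes":
        return run_syndromes(config, outdir)
    if stage == "report":
        return run_report(config, outdir)
    raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")


def run_all(config: PipelineConfig, outdir):
    """The scaled-down full pipeline: all five stages in sequence."""
    run_simulate(config, outdir)
    chains = run_fit(config, outdir)
    run_validate(config, outdir, chains=chains)
    run_syndromes(config, outdir, chains=chains)
    return run_report(config, outdir)
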