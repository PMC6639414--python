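"""End-to-end orchestration: simulate -> fitness -> qc -> landscapes ->
metrics -> topologies -> evolution, with YAML configuration and a manifest
recording seeds and parameter hashes. Stage outputs are pure functions of
(inputs, config, seeds); a rerun with the same config is bit-identical.
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

from . import evolution, fitness, landscape, metrics, preprocess, synthetic, topology

PACKAGE_VERSION = "0.1.0"


# -- configuration ---------------------------------------------------------

@dataclass
class SimulateParams:
    enabled: bool = True
    n_promoters: int = 120
    mean_range: tuple[float, float] = (2.0, 6.0)
    noise_coupling_slope: float = -0.4
    noise_scatter_sd: float = 0.15
    error_sds: tuple[float, float, float] = (0.1, 0.1, 0.02)
    n_genes: int = 30
    wt_mu_range: tuple[float, float] = (2.5, 5.5)
    depth: float = 1e6
    generation_rate: float = 10.0 / 23.0


@dataclass
class FitnessParams:
    weights: str = "inverse_sd"


@dataclass
class QcParams:
    fitness_error_threshold: float = 0.1
    expression_window: tuple[float, float] = (2.0, 6.0)
    gene_window: tuple[float, float] = (3.0, 5.0)
    motif_exclusions: list = field(default_factory=list)


@dataclass
class LandscapeParams:
    mean_halfwidth: float = 1.5
    mean_step: float = 0.05
    noise_lo: float = -3.0
    noise_hi: float = -1.0
    noise_step: float = 0.025
    scale_mu: float = 0.602
    scale_eta: float = 0.361
    optimize_kernel: bool = False
    cv_folds: int = 10
    method: str = "auxiliary"


@dataclass
class MetricsParams:
    n_permutations: int = 10_000
    curvature_drop: float = 0.05


@dataclass
class TopologyParams:
    n_components: int = 2
    pt1_threshold: float = 0.0
    pt2_threshold: float = 0.0


@dataclass
class EvolutionParams:
    enabled: bool = True
    n_walks: int = 100
    max_steps: int = 500
    likelihood_weights: dict = field(
        default_factory=lambda: {"s+": 1.0, "s-": 1.0, "f+": 1.0, "f-": 1.0})


@dataclass
class PipelineConfig:
    """Every stage's parameters, with the study defaults.

    Unknown keys are rejected when loading from YAML. One top-level seed
    fans out into independent per-stage child seeds.
    """

    seed: int = 0
    counts_path: str | None = None
    panel_path: str | None = None
    genes_path: str | None = None
    simulate: SimulateParams = field(default_factory=SimulateParams)
    fitness: FitnessParams = field(default_factory=FitnessParams)
    qc: QcParams = field(default_factory=QcParams)
    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    metrics: MetricsParams = field(default_factory=MetricsParams)
    topology: TopologyParams = field(default_factory=TopologyParams)
    evolution: EvolutionParams = field(default_factory=EvolutionParams)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(dc_type, data, path):
            fields = {f.name: f for f in dataclasses.fields(dc_type)}
            unknown = set(data) - set(fields)
            if unknown:
                raise ValueError(f"unknown config key(s) at {path or 'top '}"
                                 f"level: {sorted(unknown)}")
            kwargs = {}
            for name, value in data.items():
                ftype = fields[name].type
                sub = {"simulate": SimulateParams, "fitness": FitnessParams,
                       "qc": QcParams, "landscape": LandscapeParams,
                       "metrics": MetricsParams, "topology": TopologyParams,
                       "evolution": EvolutionParams}.get(name)
                if sub is not None and isinstance(value, dict):
                    kwargs[name] = build(sub, value, f"{path}{name}.")
                elif isinstance(value, list) and name != "motif_exclusions":
                    kwargs[name] = tuple(value)
                else:
                    kwargs[name] = value
            return dc_type(**kwargs)

        return build(cls, raw, "")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def param_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def stage_seeds(seed: int) -> dict[str, int]:
    """Stable, independent child seeds (< 2**31) for each stochastic stage."""
    names = ["simulate", "kernel_cv", "metrics", "evolution"]
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    return {n: int(c.generate_state(1)[0] % (2 ** 31))
            for n, c in zip(names, children)}


# -- stages ----------------------------------------------------------------

def _simulate_stage(cfg: PipelineConfig, outdir: Path, seed: int
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    p = cfg.simulate
    panel = synthetic.generate_promoter_panel(synthetic.SyntheticPanelConfig(
        n_promoters=p.n_promoters, mean_range=tuple(p.mean_range),
        noise_coupling_slope=p.noise_coupling_slope,
        noise_scatter_sd=p.noise_scatter_sd,
        error_sds=tuple(p.error_sds), seed=seed))
    rng = np.random.default_rng(seed + 1)
    archetypes = [synthetic.shortage_truth, synthetic.surplus_truth,
                  synthetic.peaked_truth]
    truths = {}
    for i in range(p.n_genes):
        wt = float(rng.uniform(*p.wt_mu_range))
        truths[f"G{i + 1:02d}"] = archetypes[i % 3](wt)
    counts = synthetic.generate_read_counts(
        panel, truths, depth=p.depth, generation_rate=p.generation_rate,
        seed=seed + 2)
    genes = pd.DataFrame({"gene": list(truths),
                          "wt_log2_mean": [t.wt_log2_mean
                                           for t in truths.values()]})
    synthetic.write_panel(panel, outdir / "panel.tsv")
    synthetic.write_read_counts(counts, outdir / "counts.tsv")
    genes.to_csv(outdir / "genes.tsv", sep="\t", index=False)
    return panel, counts, genes


def _snap_wt(wt: float, step: float) -> float:
    # landscape grids are built around the wild-type anchor; keep the
    # anchor itself on the global expression lattice so grid columns align
    # with multiples of the step
    return round(wt / step) * step


def run_all(config: PipelineConfig, outdir) -> dict:
    """Execute every enabled stage; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = stage_seeds(config.seed)
    manifest = {"version": PACKAGE_VERSION, "seed": config.seed,
                "stage_seeds": seeds, "param_hash": config.param_hash(),
                "stages": []}

    # inputs ---------------------------------------------------------------
    if config.simulate.enabled:
        panel, counts, genes = _simulate_stage(config, outdir,
                                               seeds["simulate"])
        manifest["stages"].append("simulate")
    else:
        for attr in ("counts_path", "panel_path", "genes_path"):
            path = getattr(config, attr)
            if path is None or not Path(path).exists():
                raise FileNotFoundError(
                    f"simulate disabled and {attr} missing: {path!r}")
        counts = pd.read_csv(config.counts_path, sep="\t")
        panel = pd.read_csv(config.panel_path, sep="\t")
        genes = pd.read_csv(config.genes_path, sep="\t")

    # fitness --------------------------------------------------------------
    fit = fitness.strain_fitness_table(counts, weights=config.fitness.weights)
    fitness.write_fitness(fit, outdir / "fitness.tsv")
    manifest["stages"].append("fitness")
    manifest["normalization"] = fit.attrs["normalization"]

    # qc -------------------------------------------------------------------
    wt_mu = dict(zip(genes["gene"], genes["wt_log2_mean"]))
    strains_only = fit[fit["gene"] != fitness.WILDTYPE_GENE]
    panel_q, strains_q, report = preprocess.qc_panel(
        panel, strains_only, wt_mu,
        fitness_error_threshold=config.qc.fitness_error_threshold,
        expression_window=tuple(config.qc.expression_window),
        gene_window=tuple(config.qc.gene_window),
        motif_exclusions=[tuple(x) for x in config.qc.motif_exclusions])
    report.to_json(outdir / "qc_report.json")
    manifest["stages"].append("qc")

    # landscapes -----------------------------------------------------------
    lp = config.landscape
    merged = strains_q.merge(panel_q, on="promoter_id")
    kernel = landscape.SmoothingKernel(lp.scale_mu, lp.scale_eta)
    if lp.optimize_kernel and len(merged) >= lp.cv_folds:
        g0 = merged["gene"].iloc[0]
        sub = merged[merged["gene"] == g0]
        grid0 = landscape.make_grid(
            _snap_wt(wt_mu[g0], lp.mean_step), lp.mean_halfwidth,
            lp.mean_step, lp.noise_lo, lp.noise_hi, lp.noise_step)
        kernel, _ = landscape.optimize_kernel(
            sub["log2_mean"], sub["log2_cv"], sub["err_mean"], sub["err_cv"],
            sub["sigma_f"], sub["fitness"], grid0, folds=lp.cv_folds,
            seed=seeds["kernel_cv"])
    manifest["kernel"] = {"scale_mu": kernel.scale_mu,
                          "scale_eta": kernel.scale_eta}

    landscapes: dict[str, landscape.FitnessLandscape] = {}
    land_dir = outdir / "landscapes"
    land_dir.mkdir(exist_ok=True)
    for gene, sub in merged.groupby("gene", sort=True):
        grid = landscape.make_grid(
            _snap_wt(wt_mu[gene], lp.mean_step), lp.mean_halfwidth,
            lp.mean_step, lp.noise_lo, lp.noise_hi, lp.noise_step)
        ls = landscape.smooth_landscape(
            sub["log2_mean"], sub["log2_cv"], sub["err_mean"], sub["err_cv"],
            sub["sigma_f"], sub["fitness"], grid, kernel,
            method=lp.method, gene=gene, with_uncertainty=True)
        landscapes[gene] = ls
        ls.to_frame().to_csv(land_dir / f"{gene}.tsv", sep="\t", index=False)
    with open(land_dir / "grid.json", "w") as fh:
        json.dump({"mean_halfwidth": lp.mean_halfwidth,
                   "mean_step": lp.mean_step, "noise_lo": lp.noise_lo,
                   "noise_hi": lp.noise_hi, "noise_step": lp.noise_step,
                   "kernel": manifest["kernel"]}, fh, indent=2)
    manifest["stages"].append("landscape")

    # metrics --------------------------------------------------------------
    mp = config.metrics
    per_gene, perm_sens, perm_intol = {}, [], []
    rng_seed = seeds["metrics"]
    for k, (gene, sub) in enumerate(merged.groupby("gene", sort=True)):
        lw = metrics.LineWeights.build(
            sub["log2_mean"].to_numpy(), sub["log2_cv"].to_numpy(),
            sub["err_mean"].to_numpy(), sub["err_cv"].to_numpy(),
            sub["sigma_f"].to_numpy(), landscapes[gene].grid, kernel)
        res = metrics.permutation_null(sub["fitness"].to_numpy(), lw,
                                       n=mp.n_permutations,
                                       seed=(rng_seed + k) % (2 ** 31))
        pc = metrics.partial_correlation_metrics(
            sub["log2_mean"], sub["log2_cv"], sub["fitness"])
        curve = landscapes[gene].f[:, 0]
        res["curvature"] = metrics.expression_curvature(
            landscapes[gene].grid.mu, curve, landscapes[gene].grid.wt_mu,
            drop=mp.curvature_drop)
        res["partial_r_mean"] = pc["r_mean"]
        res["partial_r_noise"] = pc["r_noise"]
        per_gene[gene] = res
        perm_sens.append(res.pop("perm_sens"))
        perm_intol.append(res.pop("perm_noise"))
    table = metrics.gene_metrics_table(per_gene)
    if len(table) >= 3:
        r_obs, p_corr = metrics.metric_correlation_test(
            table["sensitivity"], table["intolerance"],
            np.vstack(perm_sens), np.vstack(perm_intol))
        manifest["metric_correlation"] = {"r": r_obs, "p": p_corr}
    table.to_csv(outdir / "metrics.tsv", sep="\t", index=False)
    manifest["stages"].append("metrics")

    # topology -------------------------------------------------------------
    decomp = None
    if len(landscapes) >= 2:
        normed = {g: topology.normalize_landscape(ls)
                  for g, ls in landscapes.items()}
        decomp = topology.pca_landscapes(
            normed, n_components=config.topology.n_components)
        surfaces, loadings, meta = topology.decomposition_frames(decomp)
        topo_dir = outdir / "topology"
        topo_dir.mkdir(exist_ok=True)
        surfaces.to_csv(topo_dir / "topologies.tsv", sep="\t", index=False)
        labels = topology.classify_peaked(
            decomp.loadings, config.topology.pt1_threshold,
            config.topology.pt2_threshold)
        loadings["topology_class"] = labels.to_numpy()
        loadings.to_csv(topo_dir / "loadings.tsv", sep="\t", index=False)
        with open(topo_dir / "metadata.json", "w") as fh:
            json.dump(meta, fh, indent=2)
        manifest["stages"].append("topology")

    # evolution ------------------------------------------------------------
    if config.evolution.enabled and decomp is not None:
        ep = config.evolution
        weights = {evolution.Move(k): float(v)
                   for k, v in ep.likelihood_weights.items()}
        evo_dir = outdir / "evolution"
        evo_dir.mkdir(exist_ok=True)
        rng = np.random.default_rng(seeds["evolution"])
        grid = decomp.grid
        panels = {"pt1": decomp.topologies[0]}
        if decomp.n_components > 1:
            panels["pt2"] = decomp.topologies[1]
            panels["pt1+pt2"] = decomp.topologies[0] + decomp.topologies[1]
        for name, surf in panels.items():
            ls = landscape.FitnessLandscape(
                grid=grid, f=surf, total_weight=np.ones(grid.shape),
                gene=name)
            evolution.funnel_mask_frame(ls).to_csv(
                evo_dir / f"{name}_funnel.tsv", sep="\t", index=False)
            frames = []
            for w in range(ep.n_walks):
                start = (int(rng.integers(0, grid.shape[0])),
                         int(rng.integers(0, grid.shape[1])))
                traj = evolution.simulate_walk(start, ls, weights,
                                               max_steps=ep.max_steps,
                                               rng=rng)
                df = traj.to_frame(ls)
                df.insert(0, "walk", w)
                frames.append(df)
            pd.concat(frames, ignore_index=True).to_csv(
                evo_dir / f"{name}_walks.tsv", sep="\t", index=False)
        manifest["stages"].append("evolution")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
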