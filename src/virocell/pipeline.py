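"""Pipeline orchestration: config, run functions, reports with checksums.

Every run writes TSV/JSON outputs plus a ``run_report.json`` listing each
output file with its SHA-256 checksum, the full parameter echo and any
warnings — identical config and seed must give identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import complementarity, expression, genome_io, synthetic, trends
from .codons import CODONS, genetic_code


@dataclass
class RunConfig:
    """Parameters for a pipeline run; flags override config-file values."""

    out_dir: str = "virocell_out"
    seed: int = 0
    log_level: str = "INFO"
    # complementarity
    pair_manifest: str | None = None
    t_test_welch: bool = True
    # expression
    counts_path: str | None = None
    sample_meta_path: str | None = None
    annotation_path: str | None = None
    n_clusters: int = 3
    b_resamples: int = 100
    subsample_fraction: float = 0.75
    epsilon: float = 1.0
    infected_fraction: dict = field(default_factory=dict)  # time -> f
    # trends
    trend_design_path: str | None = None
    reference_treatment: str = "uninfected"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate_inputs(self, *paths: str | None) -> None:
        missing = [p for p in paths if p and not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


@dataclass
class RunReport:
    stage: str
    status: str = "ok"
    parameters: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)  # path -> checksum
    outputs: dict = field(default_factory=dict)  # path -> checksum
    warnings: list[str] = field(default_factory=list)
    metrics: dict = field(default_factory=dict)

    def write(self, out_dir: Path) -> Path:
        path = out_dir / "run_report.json"
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
        return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, header_comment: str = "") -> Path:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t")
    return path


def _finish(report: RunReport, out_dir: Path, caught) -> RunReport:
    report.warnings.extend(str(w.message) for w in caught)
    report.write(out_dir)
    return report


# ---------------------------------------------------------------------------
# complementarity
# ---------------------------------------------------------------------------


def run_complementarity(config: RunConfig) -> RunReport:
    """Pair manifest (phage_path, host_path, family TSV) -> D_c/impact tables."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.validate_inputs(config.pair_manifest)
    report = RunReport(stage="complementarity", parameters=asdict(config))
    manifest = pd.read_csv(config.pair_manifest, sep="\t")
    report.inputs[config.pair_manifest] = _sha256(Path(config.pair_manifest))
    pairs = [
        (row.phage_path, row.host_path, getattr(row, "family", "unknown"))
        for row in manifest.itertuples()
    ]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        results, failures = complementarity.batch_pair_analysis(pairs)

        rows = [
            (r.phage_id, r.host_id, r.family, r.d_c, r.gc_phage, r.gc_host)
            for r in results
        ]
        pair_tsv = _write_tsv(
            pd.DataFrame(
                rows,
                columns=["phage_id", "host_id", "family", "d_c", "gc_phage", "gc_host"],
            ).set_index("phage_id"),
            out_dir / "pairs.tsv",
            f"seed={config.seed} codon_order=alphabetical",
        )
        report.outputs[str(pair_tsv)] = _sha256(pair_tsv)

        code = genetic_code()
        for r in results:
            imp = pd.DataFrame(
                {
                    "amino_acid": [code[c] for c in CODONS],
                    "freq_phage": [r.profile.phage_freqs[c] for c in CODONS],
                    "delta": [r.profile.impact[c] for c in CODONS],
                },
                index=pd.Index(CODONS, name="codon"),
            )
            p = _write_tsv(
                imp,
                out_dir / f"impact_{r.phage_id}_{r.host_id}.tsv",
                f"seed={config.seed} D_c={r.d_c:.6f}",
            )
            report.outputs[str(p)] = _sha256(p)

        if failures:
            fr = pd.DataFrame(failures, columns=["pair", "reason"]).set_index("pair")
            p = _write_tsv(fr, out_dir / "failures.tsv")
            report.outputs[str(p)] = _sha256(p)

        groups: dict[str, list[float]] = {}
        for r in results:
            groups.setdefault(r.family, []).extend(r.profile.impact.values())
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        if len(groups) >= 2:
            comps = complementarity.compare_groups(
                groups, method="t_test", welch=config.t_test_welch
            )
            gt = pd.DataFrame(
                [
                    (c.group_a, c.group_b, c.method, c.statistic, c.p_raw, c.p_adjusted)
                    for c in comps
                ],
                columns=["group_a", "group_b", "method", "statistic", "p_raw", "p_adj"],
            )
            p = _write_tsv(gt.set_index("group_a"), out_dir / "group_tests.tsv")
            report.outputs[str(p)] = _sha256(p)
        else:
            warnings.warn("fewer than 2 family groups of sufficient size; group tests skipped")

        report.metrics = {"n_pairs": len(results), "n_failures": len(failures)}
        if failures:
            report.status = "completed_with_failures"
    return _finish(report, out_dir, caught)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------


def _load_counts(config: RunConfig) -> tuple[expression.CountMatrix, pd.DataFrame]:
    values = pd.read_csv(config.counts_path, sep="\t", index_col=0, comment="#")
    samples = pd.read_csv(config.sample_meta_path, sep="\t", index_col=0, comment="#")
    ann = pd.read_csv(config.annotation_path, sep="\t", index_col=0, comment="#")
    if values.empty:
        raise ValueError("empty gene set in counts matrix")
    return expression.CountMatrix(values=values, samples=samples), ann


def run_expression(config: RunConfig) -> RunReport:
    """Counts + metadata + annotation -> FPKM/z matrices, clusters, fold changes."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.validate_inputs(
        config.counts_path, config.sample_meta_path, config.annotation_path
    )
    report = RunReport(stage="expression", parameters=asdict(config))
    for p in (config.counts_path, config.sample_meta_path, config.annotation_path):
        report.inputs[p] = _sha256(Path(p))

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        counts, ann = _load_counts(config)
        fpkm_m = expression.fpkm(counts, ann)
        log_m = expression.log2_transform(fpkm_m)
        z_m = expression.zscore_rows(log_m)
        echo = f"seed={config.seed} epsilon={config.epsilon}"
        for name, m in (("fpkm", fpkm_m), ("log2fpkm", log_m), ("zscore", z_m)):
            p = _write_tsv(m.values, out_dir / f"{name}.tsv", f"provenance={m.provenance} {echo}")
            report.outputs[str(p)] = _sha256(p)

        meta = counts.samples
        infected_trts = [t for t in meta["treatment"].unique() if t != "uninfected"]
        phage_genes = ann.index[ann["stratum"] == "phage"]

        # temporal clustering of phage genes within each infection
        cluster_rows = []
        for trt in infected_trts:
            cols = meta.index[meta["treatment"] == trt]
            pg = [g for g in phage_genes if g in z_m.values.index]
            if len(pg) < config.n_clusters:
                continue
            sub = expression.ExpressionMatrix(z_m.values.loc[pg, cols], "zscore")
            times = meta.loc[cols, "time_min"]
            tc = expression.temporal_cluster(
                sub,
                n_clusters=config.n_clusters,
                b_resamples=config.b_resamples,
                subsample_fraction=config.subsample_fraction,
                seed=config.seed,
                times=times,
            )
            profiles = expression.mean_time_profiles(sub, times)
            profiles = profiles.loc[tc.labels.index]
            if config.n_clusters == 3:
                tc = expression.assign_stages(tc, profiles)
            for g in tc.labels.index:
                cid = int(tc.labels[g])
                cluster_rows.append(
                    (trt, g, cid, tc.stages.get(cid, ""), float(tc.stability[g]))
                )
        if cluster_rows:
            ct = pd.DataFrame(
                cluster_rows,
                columns=["treatment", "gene_id", "cluster", "stage", "stability"],
            ).set_index("gene_id")
            p = _write_tsv(ct, out_dir / "clusters.tsv", echo)
            report.outputs[str(p)] = _sha256(p)

        # infected-fraction-adjusted fold change per virocell (host genes, FPKM)
        host_genes = [g for g in ann.index[ann["stratum"] == "host"] if g in fpkm_m.values.index]
        times_sorted = sorted(meta["time_min"].unique())
        f_map = {int(k): float(v) for k, v in (config.infected_fraction or {}).items()}
        f = pd.Series({t: f_map.get(int(t), 1.0) for t in times_sorted})
        fc_tables = {}
        for trt in infected_trts:
            inf_mean = pd.DataFrame(
                {
                    t: fpkm_m.values.loc[
                        host_genes, meta.index[(meta["treatment"] == trt) & (meta["time_min"] == t)]
                    ].mean(axis=1)
                    for t in times_sorted
                }
            )
            ctl_mean = pd.DataFrame(
                {
                    t: fpkm_m.values.loc[
                        host_genes,
                        meta.index[(meta["treatment"] == "uninfected") & (meta["time_min"] == t)],
                    ].mean(axis=1)
                    for t in times_sorted
                }
            )
            fc = expression.adjusted_fold_change(inf_mean, ctl_mean, f, epsilon=config.epsilon)
            fc_tables[trt] = fc
            p = _write_tsv(fc.log2fc, out_dir / f"log2fc_{trt}.tsv", f"{echo} f={dict(f)}")
            report.outputs[str(p)] = _sha256(p)

        if len(fc_tables) >= 2:
            panel = expression.classify_de_panel(fc_tables)
            report.metrics.update(panel.counts())

        # trend model on per-sample total host counts
        totals = counts.values.loc[host_genes].sum(axis=0)
        design = pd.DataFrame(
            {
                "response": totals,
                "treatment": meta["treatment"],
                "time_min": meta["time_min"],
                "replicate": meta["replicate"],
            }
        )
        fit = trends.fit_trend_model(design, reference=config.reference_treatment)
        eff = fit.anova_effects()
        p = _write_tsv(eff, out_dir / "trend_effects.tsv", echo)
        report.outputs[str(p)] = _sha256(p)
        grid = np.linspace(min(times_sorted), max(times_sorted), 25)
        cis = fit.simultaneous_cis(grid)
        p = _write_tsv(cis.set_index("treatment"), out_dir / "trend_curves.tsv", echo)
        report.outputs[str(p)] = _sha256(p)
        if len(fit.treatments_) >= 2:
            comps = fit.tukey_pairwise("level") + fit.tukey_pairwise("slope")
            tk = pd.DataFrame(
                [(c.pair, c.quantity, c.estimate, c.se, c.p_adjusted) for c in comps],
                columns=["pair", "quantity", "estimate", "se", "p_adj"],
            ).set_index("pair")
            p = _write_tsv(tk, out_dir / "trend_tukey.tsv", echo)
            report.outputs[str(p)] = _sha256(p)
    return _finish(report, out_dir, caught)


# ---------------------------------------------------------------------------
# one-command synthetic validation
# ---------------------------------------------------------------------------


def run_synthetic_validation(seed: int = 0, out_dir: str | Path = "virocell_validate") -> RunReport:
    """Generate synthetic data, run both pipelines, verify recovery metrics.

    Checks (all must pass; any failure flips the status to "failed"):
    codon-impact brute-force agreement, top-k shifted-codon recovery,
    noiseless fold-change inversion, noiseless cluster recovery, and
    trend-coefficient agreement with a normal-equations solution.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(stage="synthetic_validation", parameters={"seed": seed})
    rng = np.random.default_rng(seed)
    checks: dict[str, bool] = {}
    metrics: dict[str, float] = {}

    # codon impact vs literal brute force on random vectors
    def brute_impact(a, b):
        base = 1 - a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        out = np.empty(64)
        for i in range(64):
            s = a.copy()
            s[i] = b[i]
            out[i] = abs(1 - s @ b / (np.linalg.norm(s) * np.linalg.norm(b)) - base)
        return out

    max_diff = 0.0
    for _ in range(200):
        a = rng.dirichlet(np.ones(64))
        b = rng.dirichlet(np.ones(64))
        prof = complementarity.codon_impact(a, b)
        mine = np.array([prof.impact[c] for c in CODONS])
        max_diff = max(max_diff, float(np.abs(mine - brute_impact(a, b)).max()))
    metrics["impact_oracle_max_diff"] = max_diff
    checks["impact_matches_brute_force"] = max_diff < 1e-12

    # shifted-codon recovery: mean top-k precision over seeded replicates
    precisions, dcs = [], []
    for rep in range(50):
        host_spec = synthetic.GenomeSimSpec(seed=seed + rep)
        host = synthetic.synth_host(host_spec)[:2]
        phage, phage_cds, truth = synthetic.synth_phage_from_host(
            host_spec, delta=0.3, seed=seed + rep + 50_000, host=host
        )
        res = complementarity.pair_analysis((phage, phage_cds), host)
        ranked = sorted(
            res.profile.impact, key=lambda c: (-res.profile.impact[c], c)
        )
        k = len(truth.shifted_codons)
        precisions.append(len(set(ranked[:k]) & set(truth.shifted_codons)) / k)
        dcs.append(float(truth.realized_dc))
    precision = float(np.mean(precisions))
    metrics["impact_recovery_precision"] = precision
    metrics["realized_dc"] = float(np.mean(dcs))
    checks["shifted_codons_recovered"] = precision >= 0.9

    # noiseless fold-change inversion and cluster recovery
    spec = synthetic.ExpressionSimSpec(seed=seed, dispersion=0.0)
    counts, ann, etruth = synthetic.synth_expression(spec)
    meta = counts.samples
    host_genes = ann.index[ann["stratum"] == "host"]
    inf_mean = pd.DataFrame(
        {
            t: counts.values.loc[
                host_genes, meta.index[(meta["treatment"] == "HP1") & (meta["time_min"] == t)]
            ].mean(axis=1)
            for t in spec.time_points
        }
    )
    ctl_mean = pd.DataFrame(
        {
            t: counts.values.loc[
                host_genes,
                meta.index[(meta["treatment"] == "uninfected") & (meta["time_min"] == t)],
            ].mean(axis=1)
            for t in spec.time_points
        }
    )
    fc = expression.adjusted_fold_change(inf_mean, ctl_mean, etruth.infected_fraction)
    err = float((fc.log2fc - etruth.true_log2fc).abs().max().max())
    metrics["fc_recovery_max_error"] = err
    checks["fold_change_inverts_mixture"] = err < 0.05

    from sklearn.metrics import adjusted_rand_score

    phage_genes = ann.index[ann["stratum"] == "phage"]
    cols = meta.index[meta["treatment"] == "HP1"]
    fpkm_m = expression.fpkm(counts, ann)
    z = expression.zscore_rows(
        expression.log2_transform(
            expression.ExpressionMatrix(fpkm_m.values.loc[phage_genes, cols], "fpkm")
        )
    )
    tc = expression.temporal_cluster(z, seed=seed, times=meta.loc[cols, "time_min"])
    ari = adjusted_rand_score(
        etruth.cluster_ids.loc[tc.labels.index], tc.labels
    )
    metrics["cluster_recovery_ari_noiseless"] = float(ari)
    checks["clusters_recovered_noiseless"] = ari == 1.0

    # trend model vs normal equations
    design = synthetic.synth_trend_design(
        effect_sizes={"HP1": 2.0}, slope=0.5, sigma=1.0, seed=seed
    )
    fit = trends.fit_trend_model(design)
    X = fit.X_.to_numpy()
    y = design["response"].to_numpy()
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    coef_diff = float(np.abs(beta - fit.coef_.to_numpy()).max())
    metrics["trend_coef_max_diff"] = coef_diff
    checks["trend_matches_normal_equations"] = coef_diff < 1e-9

    report.metrics = {**metrics, **{f"pass_{k}": bool(v) for k, v in checks.items()}}
    report.status = "ok" if all(checks.values()) else "failed"
    summary = pd.DataFrame(
        {"value": pd.Series(metrics), "passed": pd.Series(checks).reindex(metrics.keys())}
    )
    _write_tsv(summary, out / "validation_summary.tsv", f"seed={seed}")
    report.outputs[str(out / "validation_summary.tsv")] = _sha256(
        out / "validation_summary.tsv"
    )
    report.write(out)
    return report
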