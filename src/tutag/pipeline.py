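"""End-to-end orchestration: simulate/load -> DE -> overlap -> rank model -> report.

A run is described by a YAML config naming either input files (counts,
sample sheet, gene sets) or a simulation block, plus the pairwise
comparisons to perform. Every stage's output is written to the run
directory; the report aggregates enriched counts, a per-marker-set overlap
table (the published table analog), the Venn partition of the first two
comparisons, logistic-fit summaries and MDS coordinates. All randomness
flows from the single config seed, so a run is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .diffexp import DEResult, filter_low_counts, run_comparison
from .overlap import OverlapTestResult, VennPartition, overlap_test, venn_partition
from .rankmodel import fit_logistic, mds_leading_foldchange, rank_by_fold_enrichment
from .simulate import (
    SimulationConfig,
    generate_catalog,
    marker_gene_sets,
    simulate_counts,
    write_simulation,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "ConfigError", "validate_config", "run_pipeline"]


class ConfigError(ValueError):
    """Aggregated configuration problems."""


@dataclass
class RunConfig:
    comparisons: list[tuple[str, str]]
    counts: str | None = None
    samples: str | None = None
    gene_sets: str | None = None
    simulation: SimulationConfig | None = None
    alpha: float = 0.1
    n_resamples: int = 1000
    seed: int = 0
    outdir: str = "tutag_run"
    l23_set: str = "L2/3"
    mds_top: int = 500

    def to_dict(self) -> dict:
        return {
            "comparisons": [list(c) for c in self.comparisons],
            "counts": self.counts,
            "samples": self.samples,
            "gene_sets": self.gene_sets,
            "simulation": None if self.simulation is None else self.simulation.to_dict(),
            "alpha": self.alpha,
            "n_resamples": self.n_resamples,
            "seed": self.seed,
            "outdir": self.outdir,
            "l23_set": self.l23_set,
            "mds_top": self.mds_top,
        }


@dataclass
class RunReport:
    """Aggregated, serializable run results with provenance."""

    comparisons: dict = field(default_factory=dict)
    venn: dict | None = None
    mds: dict | None = None
    provenance: dict = field(default_factory=dict)


def _as_run_config(data: dict) -> RunConfig:
    problems: list[str] = []
    comparisons = [tuple(c) for c in data.get("comparisons", [])]
    if not comparisons:
        problems.append("comparisons: at least one (type_A, type_B) pair required")
    for c in comparisons:
        if len(c) != 2:
            problems.append(f"comparisons: {c!r} is not a pair")
    has_paths = any(data.get(k) for k in ("counts", "samples"))
    has_sim = data.get("simulation") is not None
    if has_paths == has_sim:
        problems.append("exactly one of (counts+samples paths) or a simulation block is required")
    if has_paths and not (data.get("counts") and data.get("samples")):
        problems.append("both counts and samples paths are required in file mode")
    sim = None
    if has_sim:
        try:
            sim = SimulationConfig.from_dict(data["simulation"])
        except (TypeError, ValueError) as exc:
            problems.append(f"simulation: {exc}")
    alpha = data.get("alpha", 0.1)
    if not 0 < alpha < 1:
        problems.append("alpha must be in (0, 1)")
    n_resamples = data.get("n_resamples", data.get("B", 1000))
    if n_resamples < 1:
        problems.append("n_resamples must be >= 1")
    if sim is not None:
        known = set(sim.population_profiles)
        for c in comparisons:
            for t in c:
                if t not in known:
                    problems.append(
                        f"comparisons: unknown sample type {t!r} (known: {sorted(known)})"
                    )
    if problems:
        raise ConfigError("invalid run config:\n  - " + "\n  - ".join(problems))
    return RunConfig(
        comparisons=comparisons,
        counts=data.get("counts"),
        samples=data.get("samples"),
        gene_sets=data.get("gene_sets"),
        simulation=sim,
        alpha=alpha,
        n_resamples=int(n_resamples),
        seed=int(data.get("seed", 0)),
        outdir=str(data.get("outdir", "tutag_run")),
        l23_set=str(data.get("l23_set", "L2/3")),
        mds_top=int(data.get("mds_top", 500)),
    )


def validate_config(path: str | Path) -> RunConfig:
    """Parse, default and cross-check a YAML run config."""
    data = tio.read_yaml(path)
    return _as_run_config(data)


def _derived_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([seed, *key]).generate_state(1)[0] % (2**31))


def _safe(name: str) -> str:
    return name.replace("/", "").replace(" ", "_")


def _overlap_row(r: OverlapTestResult) -> dict:
    return {
        "set": r.set_name,
        "db_in_universe": r.db_in_universe,
        "observed_overlap": r.observed_overlap,
        "resample_mean": r.resample_mean,
        "resample_sd": r.resample_sd,
        "ci95_low": r.ci95[0],
        "ci95_high": r.ci95[1],
        "p_resample": r.p_resample,
        "p_resample_corrected": r.p_resample_corrected,
        "significant": r.significant,
        "direction": r.direction,
        "hypergeom_p": r.hypergeom_p,
    }


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute a full run and write all artifacts under ``config.outdir``."""
    t0 = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = config.to_dict()
    tio.write_yaml(cfg_dict, outdir / "config_echo.yaml")
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]

    # --- inputs -----------------------------------------------------------
    truth = None
    if config.simulation is not None:
        sim = config.simulation
        catalog = generate_catalog(sim)
        matrix, sheet, truth = simulate_counts(catalog, sim)
        gene_sets = marker_gene_sets(catalog)
        write_simulation(outdir / "simulated", matrix, sheet, truth, sim)
        tio.write_gene_sets(gene_sets, outdir / "simulated" / "marker_sets.gmt")
        logger.info("simulated %d genes x %d samples", *matrix.shape)
    else:
        matrix = tio.read_counts(config.counts)
        sheet = tio.read_sample_sheet(config.samples)
        sheet.validate_against(matrix)
        gene_sets = tio.read_gene_sets(config.gene_sets) if config.gene_sets else None
        logger.info("loaded %d genes x %d samples", *matrix.shape)
        known = set(sheet.sample_types)
        unknown = [t for c in config.comparisons for t in c if t not in known]
        if unknown:
            raise ConfigError(
                f"comparisons name unknown sample types {sorted(set(unknown))}; "
                f"sample sheet has {sorted(known)}"
            )

    report = RunReport()
    de_results: dict[tuple[str, str], DEResult] = {}

    # --- per-comparison DE + overlap + rank model -------------------------
    for ci, (type_a, type_b) in enumerate(config.comparisons):
        tstage = time.time()
        de = run_comparison(matrix, sheet, type_a, type_b, alpha=config.alpha)
        de_results[(type_a, type_b)] = de
        tag = f"{_safe(type_a)}_vs_{_safe(type_b)}"
        tio.write_de_table(de, outdir / f"de_{tag}.tsv")
        entry: dict = {
            "type_a": type_a,
            "type_b": type_b,
            "n_genes_prefilter": de.n_genes_prefilter,
            "n_genes_filtered": len(de.universe),
            "n_enriched": len(de.enriched_genes),
            "dispersion_trend": list(de.dispersion_trend),
        }

        if gene_sets is not None:
            rows = []
            for si, name in enumerate(gene_sets.names()):
                res = overlap_test(
                    de.enriched_genes,
                    de.universe,
                    gene_sets[name],
                    set_name=name,
                    B=config.n_resamples,
                    seed=_derived_seed(config.seed, 1, ci, si),
                )
                rows.append(_overlap_row(res))
            entry["overlap"] = rows

            if config.l23_set in gene_sets.names():
                ranked = rank_by_fold_enrichment(de, gene_sets[config.l23_set])
                fit = fit_logistic(ranked)
                entry["logistic"] = {
                    "intercept": fit.intercept,
                    "slope": fit.slope,
                    "se_slope": fit.se_slope,
                    "z_slope": fit.z_slope,
                    "p_slope": fit.p_slope,
                    "converged": fit.converged,
                    "n_obs": fit.n_obs,
                }
        logger.info("comparison %s vs %s done in %.1fs", type_a, type_b, time.time() - tstage)
        report.comparisons[tag] = entry

    # --- Venn partition of the first two comparisons ----------------------
    if len(config.comparisons) >= 2 and gene_sets is not None and config.l23_set in gene_sets.names():
        (a1, b1), (a2, b2) = config.comparisons[0], config.comparisons[1]
        de1, de2 = de_results[(a1, b1)], de_results[(a2, b2)]
        vp = venn_partition(
            de1.enriched_genes, de2.enriched_genes, gene_sets[config.l23_set]
        )
        report.venn = {
            "comparison_a": f"{a1}_vs_{b1}",
            "comparison_b": f"{a2}_vs_{b2}",
            "sizes": vp.sizes,
            "pct_l23": vp.pct_in_set,
            "empty_partitions": vp.empty_partitions,
        }

    # --- MDS over all samples --------------------------------------------
    if matrix.shape[1] >= 3:
        filtered_all = filter_low_counts(matrix, matrix.sample_ids)
        coords = mds_leading_foldchange(filtered_all, top=config.mds_top)
        coords.to_csv(outdir / "mds_coordinates.tsv", sep="\t", index_label="sample_id")
        report.mds = {
            "coordinates": {s: [float(x) for x in coords.loc[s]] for s in coords.index},
            "top": config.mds_top,
        }

    from . import __version__

    report.provenance = {
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "tutag_version": __version__,
    }
    logger.info("pipeline finished in %.1fs", time.time() - t0)
    tio.write_json(report, outdir / "report.json")
    (outdir / "report.txt").write_text(render_report(report))
    return report


def render_report(report: RunReport) -> str:
    """Human-readable text table mirroring the published overlap table."""
    lines: list[str] = []
    for tag, entry in report.comparisons.items():
        lines.append(f"Comparison: {entry['type_a']} vs {entry['type_b']}")
        lines.append(
            f"  genes: {entry['n_genes_prefilter']} -> {entry['n_genes_filtered']} after filter; "
            f"enriched (padj < alpha, FC > 1): {entry['n_enriched']}"
        )
        if "overlap" in entry:
            lines.append(
                f"  {'set':<14}{'K':>6}{'obs':>6}{'mean':>9}{'sd':>7}"
                f"{'ci95':>18}{'p':>9}  significance"
            )
            for row in entry["overlap"]:
                sig = (
                    f"significant {row['direction']} CI" if row["significant"] else "inside CI"
                )
                ci = f"[{row['ci95_low']:.1f}, {row['ci95_high']:.1f}]"
                lines.append(
                    f"  {row['set']:<14}{row['db_in_universe']:>6}"
                    f"{row['observed_overlap']:>6}{row['resample_mean']:>9.2f}"
                    f"{row['resample_sd']:>7.2f}{ci:>18}{row['p_resample']:>9.4f}  {sig}"
                )
        if "logistic" in entry:
            lg = entry["logistic"]
            lines.append(
                f"  logistic membership~rank: slope={lg['slope']:.3e} "
                f"(z={lg['z_slope']:.2f}, p={lg['p_slope']:.3e}, converged={lg['converged']})"
            )
        lines.append("")
    if report.venn:
        v = report.venn
        lines.append(
            f"Venn {v['comparison_a']} | {v['comparison_b']}: "
            f"only_a={v['sizes']['only_a']} both={v['sizes']['both']} only_b={v['sizes']['only_b']}"
        )
        lines.append(
            "  % layer 2/3 members: "
            + ", ".join(f"{k}={v['pct_l23'][k]:.1f}%" for k in ("only_a", "both", "only_b"))
        )
        lines.append("")
    return "\n".join(lines) + "\n"
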