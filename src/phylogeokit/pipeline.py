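"""Config-driven orchestration of the analysis stages over a dataset bundle.

A run configuration (YAML or dict) names the input files and enables
stages; stages run in dependency order (sequence summaries feed the
network; the other stages are independent), each writing its own tabular
outputs plus a machine-readable JSON summary and a plain-text report.
Identical configs and seeds produce byte-identical summaries.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import clusterpost, colourindex, demography, hapnet, nichetest, seqstats

log = logging.getLogger("phylogeokit")

SUMMARY_SCHEMA_VERSION = 1

STAGES = ("seqstats", "network", "demography", "deltak", "pca", "niche",
          "plumage")


@dataclass
class RunConfig:
    """Paths, stage toggles and per-stage parameters for a pipeline run."""

    outdir: str = "phylogeokit_out"
    alignment: str | None = None
    popmap: str | None = None
    genotypes: str | None = None
    lnp_table: str | None = None
    occurrences: str | None = None
    backgrounds: str | None = None
    traits: str | None = None
    contemporary_migration: str | None = None
    historical_migration: str | None = None
    stages: list[str] = field(default_factory=list)
    seed: int = 0
    params: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(open(path)) or {}
        known = {k: data[k] for k in data if k in cls.__dataclass_fields__}
        return cls(**known)

    def validate(self) -> list[str]:
        problems = []
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            problems.append(f"unknown stages: {sorted(unknown)}")
        needs = {
            "seqstats": ["alignment", "popmap"],
            "network": ["alignment"],
            "demography": ["contemporary_migration", "historical_migration"],
            "deltak": ["lnp_table"],
            "pca": ["genotypes"],
            "niche": ["occurrences"],
            "plumage": ["traits"],
        }
        for stage in self.stages:
            for attr in needs.get(stage, []):
                path = getattr(self, attr)
                if path is None:
                    problems.append(f"stage {stage!r} needs input {attr!r}")
                elif not Path(path).exists():
                    problems.append(f"stage {stage!r}: missing file {path}")
        return problems


def _load_alignment(config: RunConfig) -> seqstats.Alignment:
    popmap = seqstats.read_popmap(config.popmap) if config.popmap else None
    return seqstats.Alignment.from_fasta(config.alignment, popmap)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the JSON-serialisable summary.

    Raises ``ValueError`` listing every pre-flight problem at once.
    """
    problems = config.validate()
    if problems:
        raise ValueError("pre-flight check failed:\n  " + "\n  ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = config.params
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION,
                     "seed": config.seed, "stages": {}, "warnings": []}
    for stage in [s for s in STAGES if s in config.stages]:
        t0 = time.monotonic()
        log.info("stage %s: starting", stage)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            stage_out = _run_stage(stage, config, outdir, p)
        for w in caught:
            message = f"{stage}: {w.message}"
            summary["warnings"].append(message)
            log.warning("%s", message)
        summary["stages"][stage] = stage_out
        # timings go to the log only, so the summary stays byte-reproducible
        log.info("stage %s: done in %.2fs", stage, time.monotonic() - t0)
    (outdir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=float) + "\n")
    report = ["phylogeokit run report", "=" * 22]
    for stage, out in summary["stages"].items():
        report.append(f"[{stage}] {out.get('headline', 'done')}")
    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    return summary


def _run_stage(stage: str, config: RunConfig, outdir: Path, p: dict) -> dict:
    if stage == "seqstats":
        aln = _load_alignment(config)
        table = seqstats.population_summary(
            aln, n_replicates=p.get("n_replicates", 1000),
            n_bootstrap=p.get("n_bootstrap", 1000), seed=config.seed)
        table.to_csv(outdir / "seqstats.tsv", sep="\t", index=False)
        return {"headline": f"{len(table)} populations summarised",
                "populations": table["population"].tolist(),
                "output": "seqstats.tsv"}
    if stage == "network":
        aln = _load_alignment(config)
        table = seqstats.collapse_haplotypes(aln)
        net = hapnet.median_joining(table, epsilon=p.get("epsilon", 0))
        hapnet.write_gml(net, outdir / "network.gml")
        hapnet.write_edge_tsv(net, outdir / "network_edges.tsv")
        return {"headline": (f"{table.H} haplotypes, "
                             f"{len(net.medians)} median vectors, "
                             f"cost {net.total_cost}"),
                "H": table.H, "medians": len(net.medians),
                "total_cost": net.total_cost,
                "output": "network.gml"}
    if stage == "demography":
        pops_c, cm = demography.read_migration_matrix(
            config.contemporary_migration)
        _, hm = demography.read_migration_matrix(config.historical_migration)
        np.fill_diagonal(cm, 1.0 - np.nansum(
            np.where(np.eye(len(pops_c), dtype=bool), 0.0, cm), axis=1))
        tables = demography.MigrationTables(
            pops_c, cm, hm, mu=p.get("microsat_mu", 5e-4))
        out = demography.compare_migration_eras(
            tables, n_perm=p.get("n_perm", 5000), seed=config.seed)
        res = out["mantel"]
        pd.DataFrame(out["historical_m"], index=pops_c,
                     columns=pops_c).to_csv(outdir / "historical_m.csv")
        return {"headline": f"Mantel r = {res.r:.3f}, p = {res.p:.3f}",
                "mantel_r": res.r, "mantel_p": res.p, "exact": res.exact,
                "era_ratios": out["era_ratios"]}
    if stage == "deltak":
        df = pd.read_csv(config.lnp_table, sep=None, engine="python")
        res = clusterpost.evanno_delta_k(clusterpost.LnPTable(df))
        res.per_k.to_csv(outdir / "delta_k.tsv", sep="\t", index=False)
        return {"headline": f"best K = {res.best_k}", "best_k": res.best_k,
                "output": "delta_k.tsv"}
    if stage == "pca":
        gm = clusterpost.read_genotype_table(config.genotypes)
        res = clusterpost.genotype_pca(gm)
        coords = pd.DataFrame(res.coordinates[:, :4],
                              columns=[f"PC{i+1}" for i in
                                       range(min(4, res.coordinates.shape[1]))])
        coords.insert(0, "id", res.ids)
        coords.insert(1, "population", res.populations)
        coords.to_csv(outdir / "genotype_pca.csv", index=False)
        return {"headline": (f"PC1 explains "
                             f"{100 * res.explained_variance_ratio[0]:.1f}%"),
                "explained": res.explained_variance_ratio[:4].tolist(),
                "output": "genotype_pca.csv"}
    if stage == "niche":
        occ = nichetest.ClimateTable.from_csv(config.occurrences)
        bg = (nichetest.ClimateTable.from_csv(config.backgrounds)
              if config.backgrounds else None)
        groups = occ.groups
        frames = []
        out: dict = {"pairs": {}}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                a, b = groups[i], groups[j]
                results = nichetest.niche_divergence_test(
                    occ.for_group(a), occ.for_group(b),
                    bg.for_group(a) if bg else None,
                    bg.for_group(b) if bg else None,
                    n_axes=p.get("n_axes", 4),
                    n_rep=p.get("n_rep", 1000),
                    fraction=p.get("fraction", 0.75),
                    alpha=p.get("alpha", 0.05),
                    n_background=p.get("n_background", 1000),
                    seed=config.seed)
                frames.append(nichetest.results_table(results, f"{a} vs {b}"))
                out["pairs"][f"{a} vs {b}"] = [
                    r.classification for r in results]
        table = pd.concat(frames, ignore_index=True)
        table.to_csv(outdir / "niche_divergence.tsv", sep="\t", index=False)
        out["headline"] = f"{len(out['pairs'])} pairs tested"
        out["output"] = "niche_divergence.tsv"
        return out
    if stage == "plumage":
        df = pd.read_csv(config.traits)
        scored = colourindex.score_table(df)
        scored.to_csv(outdir / "plumage_scored.csv", index=False)
        profile = colourindex.cline_profile(
            scored, n_bins=p.get("n_bins", 10), per_character=True)
        profile.to_csv(outdir / "plumage_cline.tsv", sep="\t", index=False)
        return {"headline": (f"index range "
                             f"{scored['index'].min()}-{scored['index'].max()}"),
                "mean_index": float(scored["index"].mean()),
                "output": "plumage_scored.csv"}
    raise AssertionError(f"unhandled stage {stage}")
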