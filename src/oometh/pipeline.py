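"""End-to-end orchestration: simulate → WGBS → ChIP → clusters → allelic.

A single :class:`RunConfig` (loadable from YAML) carries the simulation
settings, the genotype list, and every analysis threshold with its
default.  :func:`run_full_pipeline` executes the stages, writes track
files stamped with the config hash and seed, and returns a
machine-readable summary.  Identical configs yield identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import chip as chipmod
from . import clusters as clustermod
from . import io as oio
from . import wgbs as wgbsmod
from .allelic import allelic_gene_counts, assign_reads, filter_informative_snps
from .simulate import (
    GENOTYPES,
    SimulationConfig,
    SyntheticCohort,
    generate_cohort,
    simulate_allelic_reads,
)

log = logging.getLogger("oometh")


@dataclass
class Thresholds:
    """Every cutoff of the analysis in one auditable place."""

    informative_min: int = 4
    informative_max: int = 100
    min_informative_sites: int = 6
    hmr_min: float = 80.0
    lmr_max: float = 20.0
    me2_enrichment: float = 1.4
    me3_enrichment: float = 1.5
    gene_loss_control_min: float = 1.0
    gene_loss_ratio: float = 0.67
    affected_delta: float = -20.0
    affected_control_min: float = 40.0
    unaffected_delta_low: float = -10.0
    unaffected_delta_high: float = 10.0
    unaffected_control_min: float = 40.0


@dataclass
class RunConfig:
    seed: int = 0
    genotypes: tuple[str, ...] = GENOTYPES
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_clusters: int = 5
    allelic_genes: int = 30  # genes carried through the allelic stage
    out_dir: str | None = None

    def __post_init__(self) -> None:
        unknown = [g for g in self.genotypes if g not in GENOTYPES]
        if unknown:
            raise ValueError(f"unknown genotypes {unknown}; expected {GENOTYPES}")
        self.simulation.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimulationConfig(**{
            **raw.get("simulation", {}),
            "autosome_lengths": tuple(
                raw.get("simulation", {}).get("autosome_lengths", SimulationConfig().autosome_lengths)
            ),
        })
        thr = Thresholds(**raw.get("thresholds", {}))
        kwargs = {k: v for k, v in raw.items() if k not in ("simulation", "thresholds")}
        if "genotypes" in kwargs:
            kwargs["genotypes"] = tuple(kwargs["genotypes"])
        return cls(simulation=sim, thresholds=thr, **kwargs)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "seed": self.seed,
                "genotypes": list(self.genotypes),
                "simulation": asdict(self.simulation),
                "thresholds": asdict(self.thresholds),
                "n_clusters": self.n_clusters,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def wgbs_stage(cohort: SyntheticCohort, thr: Thresholds) -> dict[str, wgbsmod.BinMethylation]:
    """Informative filter + bin pooling per genotype, with filter logging."""
    binmeth = {}
    for g, calls in cohort.wgbs.items():
        kept = wgbsmod.filter_informative_calls(
            calls, thr.informative_min, thr.informative_max
        )
        log.info("wgbs[%s]: %d CpGs in, %d informative", g, len(calls), len(kept))
        binmeth[g] = wgbsmod.compute_bin_methylation(
            kept, cohort.grid, thr.min_informative_sites
        )
    return binmeth


def chip_stage(cohort: SyntheticCohort, thr: Thresholds) -> dict:
    """Enrichment ratios, spike QC, occupancies and the gene-loss call."""
    out: dict = {"ratios": {}, "occupancy": {}, "specificity": {}, "scale_factors": {}}
    layout = cohort.grid.layout
    for (mark, g), exp in cohort.chip.items():
        track = chipmod.bin_enrichment_ratio(exp.chip, exp.input, mark=mark)
        out["ratios"][(mark, g)] = track
        if exp.spike_in is not None:
            out["specificity"][(mark, g)] = chipmod.antibody_specificity(
                exp.spike_in, f"K36{mark}"
            )
    for mark, threshold in (("me2", thr.me2_enrichment), ("me3", thr.me3_enrichment)):
        key = (mark, "control")
        if key in out["ratios"]:
            out["occupancy"][mark] = chipmod.enriched_occupancy(
                out["ratios"][key], layout, threshold
            )
    me2_panel = {
        exp.sample_id: exp.spike_in
        for (mark, g), exp in cohort.chip.items()
        if mark == "me2" and exp.spike_in is not None
    }
    if len(me2_panel) >= 2 and ("me2", "control") in cohort.chip:
        ref = cohort.chip[("me2", "control")].sample_id
        out["scale_factors"] = chipmod.spike_in_scale_factors(me2_panel, ref)
    # gene-level H3K36me2 loss: control vs K36M
    if ("me2", "control") in cohort.chip and ("me2", "K36M") in cohort.chip:
        ctl, mut = cohort.chip[("me2", "control")], cohort.chip[("me2", "K36M")]
        ctl_r = {
            g.gene_id: chipmod.gene_body_ratio(ctl.chip, ctl.input, g)
            for g in cohort.genes
        }
        mut_r = {
            g.gene_id: chipmod.gene_body_ratio(mut.chip, mut.input, g)
            for g in cohort.genes
        }
        out["gene_ratios"] = {"control": ctl_r, "K36M": mut_r}
        out["loss_genes"] = chipmod.call_h3k36me2_loss_genes(
            ctl_r, mut_r, thr.gene_loss_control_min, thr.gene_loss_ratio
        )
    return out


def run_full_pipeline(config: RunConfig) -> dict:
    """Execute all stages; write tracks if ``out_dir`` is set; return summary."""
    thr = config.thresholds
    header = {"config_hash": config.config_hash(), "seed": config.seed}
    cohort = generate_cohort(config.simulation, genotypes=config.genotypes)
    binmeth = wgbs_stage(cohort, thr)

    summary: dict = {
        "seed": config.seed,
        "config_hash": header["config_hash"],
        "global_mean": {},
        "per_class": {},
        "category_fractions": {},
    }
    for g, bm in binmeth.items():
        s = wgbsmod.methylome_summary(bm)
        summary["global_mean"][g] = s.global_mean
        summary["per_class"][g] = s.per_class
        summary["category_fractions"][g] = s.category_fractions

    deltas = {}
    affected_counts = {}
    if "control" in binmeth:
        for g, bm in binmeth.items():
            if g == "control":
                continue
            d = wgbsmod.delta_methylation(bm, binmeth["control"])
            deltas[g] = d
            labels = wgbsmod.classify_affected_bins(
                d, binmeth["control"],
                thr.affected_delta, thr.affected_control_min,
                thr.unaffected_delta_low, thr.unaffected_delta_high,
                thr.unaffected_control_min,
            )
            affected_counts[g] = {
                "affected": int(np.sum(labels == wgbsmod.AFFECTED)),
                "unaffected": int(np.sum(labels == wgbsmod.UNAFFECTED)),
            }
    summary["affected_bins"] = affected_counts

    chip_out = chip_stage(cohort, thr)
    summary["occupancy"] = {
        mark: {kl: 100.0 * f for kl, f in occ.items()}
        for mark, occ in chip_out["occupancy"].items()
    }
    summary["antibody_specificity"] = {
        f"{m}:{g}": v for (m, g), v in chip_out["specificity"].items()
    }
    if "loss_genes" in chip_out:
        summary["n_h3k36me2_loss_genes"] = len(chip_out["loss_genes"])

    assignment = None
    ratios = chip_out["ratios"]
    if ("me2", "control") in ratios and ("me3", "control") in ratios:
        assignment = clustermod.cluster_bins(
            ratios[("me2", "control")], ratios[("me3", "control")],
            k=config.n_clusters, seed=config.seed,
        )
        tracks = {
            "me2_control": ratios[("me2", "control")].ratio,
            "me3_control": ratios[("me3", "control")].ratio,
        }
        for g, bm in binmeth.items():
            tracks[f"meth_{g}"] = bm.level
        for g, d in deltas.items():
            tracks[f"delta_{g}"] = d.values
        csum = clustermod.cluster_summary(assignment, tracks)
        summary["cluster_sizes"] = assignment.sizes()
        summary["cluster_summary"] = csum.to_dict(orient="records")

    # allelic stage on a subset of genes
    if config.allelic_genes > 0:
        genes = cohort.genes[: config.allelic_genes]
        snps = filter_informative_snps(cohort.snps)
        reads = simulate_allelic_reads(genes, snps, config.simulation)
        assignments = assign_reads(reads)
        gene_counts = allelic_gene_counts(assignments)
        mat, pat = gene_counts["maternal"].sum(), gene_counts["paternal"].sum()
        summary["allelic"] = {
            "n_reads": len(assignments),
            "maternal_fraction": float(mat / (mat + pat)) if mat + pat else float("nan"),
            "conflicting": int(gene_counts["conflicting"].sum()),
            "unassigned": int(gene_counts["unassigned"].sum()),
        }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for g, bm in binmeth.items():
            oio.write_bin_methylation(bm, out / f"meth_{g}.bedgraph", header=header)
        for (mark, g), track in chip_out["ratios"].items():
            oio.write_bedgraph(track.grid, track.ratio, out / f"ratio_{mark}_{g}.bedgraph", header=header)
        for g, d in deltas.items():
            oio.write_bedgraph(d.grid, d.values, out / f"delta_{g}.bedgraph", header=header)
        if assignment is not None:
            clustermod.export_heatmap_matrix(assignment, tracks, out / "heatmap_matrix.tsv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
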