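"""End-to-end synthetic-study pipeline.

``run_pipeline`` executes, in dependency order, the five stages of the
analysis on a generated rhizobox study: (1) simulate an untreated and a
biochar-treated arm of one site × compartment condition (community
counts, traits coupled to planted modules, a zymogram image with known
root footprint); (2) zymogram calibration, hotspot detection and
compartment statistics; (3) community statistics (rare-taxon filter,
Shannon + Kruskal–Wallis, Bray–Curtis + PERMANOVA, differential
abundance); (4) per-arm co-occurrence networks with topology, null-model
comparison and hub shifts; (5) module detection, module–trait
associations, Mantel confirmation and the new/maintained/missed shift
classification.

Everything is driven by one :class:`PipelineConfig` (constructible from a
YAML file) and a single seed; identical config + seed gives byte-identical
numeric outputs. Every stage writes plain TSV/JSON artifacts into the run
directory, and ``manifest.json`` records the stage list, seeds and the
defaults/tie-break conventions in force.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import community as comm
from . import io as rio
from . import modules as mods
from . import network as net
from . import simulate as sim
from . import zymography as zym
from .datatypes import AbundanceTable, Condition, ValidationError
from .plotting import association_heatmap

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

STAGES = ("simulate", "zymography", "community", "network", "associate")


@dataclass
class PipelineConfig:
    """All knobs of the pipeline, with the field-standard defaults.

    Thresholds: edge screen p < 0.01, module–trait significance p < 0.01,
    null-model verdict p < 0.05, top-10 hubs, top-4 modules, 0.005%
    rare-taxon filter. Simulation sizes are a desk-scale demonstration
    (see docs/methods.md).
    """

    seed: int = 0
    # thresholds
    edge_alpha: float = 0.01
    association_alpha: float = 0.01
    null_alpha: float = 0.05
    k_hubs: int = 10
    top_modules: int = 4
    rare_threshold_percent: float = 0.005
    n_perm: int = 199
    n_null_graphs: int = 199
    null_metrics: tuple[str, ...] = ("clustering_coefficient", "modularity")
    # simulated study
    site: str = "non_urban"
    compartment: str = "rhizosphere"
    n_samples: int = 24
    n_taxa: int = 60
    n_modules: int = 4
    coupling: float = 2.0
    dispersion: float = 0.3
    trait_effect: float = 2.0
    trait_noise_sd: float = 0.5
    trait_names: tuple[str, ...] = ("TOC", "NN", "pH")
    untreated_links: tuple[int, ...] = (1, 0, 0)
    treated_links: tuple[int, ...] = (1, 2, 0)
    image_shape: tuple[int, int] = (96, 96)
    band_width_px: int = 3
    background_mean: float = 100.0
    background_sd: float = 5.0
    hotspot_gain: float = 50.0
    threshold_mode: str = "local"

    def validate(self) -> None:
        for name in ("edge_alpha", "association_alpha", "null_alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.k_hubs < 1:
            raise ValidationError("k_hubs must be ≥ 1")
        if self.top_modules < 1:
            raise ValidationError("top_modules must be ≥ 1")
        if not (0 <= self.rare_threshold_percent <= 100):
            raise ValidationError("rare_threshold_percent must be in [0, 100]")
        if self.n_perm < 99 or self.n_null_graphs < 99:
            raise ValidationError("n_perm and n_null_graphs must be ≥ 99")
        if self.n_samples < 4:
            raise ValidationError("n_samples must be ≥ 4 (correlation screen)")
        if len(self.trait_names) != len(self.untreated_links) or \
                len(self.trait_names) != len(self.treated_links):
            raise ValidationError("trait_names and link lists must have equal length")
        Condition(self.site, self.compartment, "untreated")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config key(s) {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def _json_dump(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all five stages; returns the manifest (also written to disk)."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    # one deterministic seed per consumer, all derived from config.seed
    seeds = np.random.default_rng(config.seed).integers(0, 2**31 - 1, size=12)
    (s_com_u, s_com_t, s_tr_u, s_tr_t, s_zym, s_perm, s_null_u, s_null_t,
     s_lou, s_div, s_mantel, _spare) = map(int, seeds)
    manifest: dict = {"stages": [], "seed": config.seed,
                      "config": config.to_dict(),
                      "conventions": {
                          "sd": "sample (ddof=1)",
                          "hotspot_rule": "grey strictly > mean + 2*SD",
                          "hub_tie_break": "degree desc, betweenness desc, label",
                          "module_ranking": "size desc, summed degree desc, label",
                          "p_values": "permutation tests use the add-one convention",
                      }}

    # ---- stage 1: simulate --------------------------------------------------
    table_u, truth_u = sim.generate_community(
        n_samples=config.n_samples, n_taxa=config.n_taxa,
        n_modules=config.n_modules, coupling=config.coupling,
        dispersion=config.dispersion, seed=s_com_u,
        condition=(config.site, config.compartment, "untreated"),
        sample_prefix="U")
    table_t, truth_t = sim.generate_community(
        n_samples=config.n_samples, n_taxa=config.n_taxa,
        n_modules=config.n_modules, coupling=config.coupling,
        dispersion=config.dispersion, seed=s_com_t,
        condition=(config.site, config.compartment, "biochar"),
        sample_prefix="T")
    traits_u = sim.generate_traits(truth_u, list(config.untreated_links),
                                   effect=config.trait_effect,
                                   noise_sd=config.trait_noise_sd, seed=s_tr_u,
                                   trait_names=list(config.trait_names))
    traits_t = sim.generate_traits(truth_t, list(config.treated_links),
                                   effect=config.trait_effect,
                                   noise_sd=config.trait_noise_sd, seed=s_tr_t,
                                   trait_names=list(config.trait_names))
    zymogram, ztruth = sim.generate_zymogram(
        shape=config.image_shape, seed=s_zym,
        background_mean=config.background_mean,
        background_sd=config.background_sd,
        hotspot_gain=config.hotspot_gain, band_width_px=config.band_width_px)

    rio.write_abundance_table(table_u, out / "counts_untreated.tsv",
                              out / "metadata_untreated.tsv")
    rio.write_abundance_table(table_t, out / "counts_biochar.tsv",
                              out / "metadata_biochar.tsv")
    rio.write_trait_table(traits_u, out / "traits_untreated.tsv")
    rio.write_trait_table(traits_t, out / "traits_biochar.tsv")
    rio.write_zymogram(zymogram, out / "zymogram.tif")
    rio.write_mask(ztruth.root_mask, out / "root_mask.tif")
    _json_dump({"module_of": truth_u.module_of,
                "untreated_links": list(config.untreated_links),
                "treated_links": list(config.treated_links)},
               out / "simulation_truth.json")
    manifest["stages"].append("simulate")

    # ---- stage 2: zymography ------------------------------------------------
    bg = config.background_mean
    curve = zym.fit_calibration([(0.0, bg), (100.0, bg + 100.0), (200.0, bg + 200.0)])
    activity = zym.grey_to_activity(zymogram, curve)
    roi = np.ones(zymogram.image.shape, dtype=bool)
    whole = zym.detect_hotspots(zymogram, roi)
    masks = zym.segment_compartments(ztruth.root_mask, config.band_width_px, roi)
    stats_by_comp = zym.compartment_stats(activity, masks, zymogram,
                                          threshold_mode=config.threshold_mode)
    _json_dump({"whole_roi": {"threshold": whole.threshold,
                              "percent_hotspot": whole.percent_area,
                              "n_hotspot_px": whole.n_hotspot_px,
                              "n_background_px": whole.n_background_px},
                "threshold_mode": config.threshold_mode,
                "compartments": stats_by_comp},
               out / "zymography.json")
    pd.DataFrame(stats_by_comp).T.to_csv(out / "zymography_compartments.tsv", sep="\t")
    manifest["stages"].append("zymography")

    # ---- stage 3: community -------------------------------------------------
    combined = AbundanceTable(
        counts=pd.concat([table_u.counts, table_t.counts]),
        metadata=pd.concat([table_u.metadata, table_t.metadata]),
        taxonomy=table_u.taxonomy)
    filtered = comm.filter_rare(combined, config.rare_threshold_percent)
    rio.write_abundance_table(filtered, out / "counts_filtered.tsv",
                              out / "metadata_filtered.tsv")
    div = comm.diversity_test(filtered, "treatment")
    div["shannon"].to_csv(out / "shannon.tsv", sep="\t")
    bc = comm.bray_curtis(filtered)
    bc.to_csv(out / "bray_curtis.tsv", sep="\t")
    perma = comm.permanova(bc, filtered.metadata["treatment"],
                           n_perm=config.n_perm, seed=s_perm)
    diff = comm.differential_abundance(filtered, "treatment")
    diff.to_csv(out / "differential_abundance.tsv", sep="\t")
    _json_dump({"kruskal_wallis": {"factor": "treatment", "H": div["H"],
                                   "p_value": div["p_value"]},
                "permanova": {"pseudo_F": perma.pseudo_F, "p_value": perma.p_value,
                              "n_permutations": perma.n_permutations}},
               out / "community_tests.json")
    manifest["stages"].append("community")

    # ---- stage 4: networks + hubs -------------------------------------------
    arms = {"untreated": (table_u, s_null_u), "biochar": (table_t, s_null_t)}
    networks = {}
    hubs = {}
    for arm, (table, null_seed) in arms.items():
        filt = comm.filter_rare(table, config.rare_threshold_percent)
        rho, p, dropped = net.correlation_screen(filt)
        network = net.build_network(
            rho, p, edge_alpha=config.edge_alpha,
            condition=Condition(config.site, config.compartment,
                                "untreated" if arm == "untreated" else "biochar"))
        networks[arm] = network
        topo = net.topology(network, seed=s_lou)
        null = net.null_ensemble(network, n_graphs=config.n_null_graphs,
                                 seed=null_seed, metrics=config.null_metrics,
                                 alpha=config.null_alpha)
        k = min(config.k_hubs, network.n_nodes)
        if k < config.k_hubs:
            log.warning("network %s has only %d nodes; hub list shortened",
                        arm, network.n_nodes)
        hubs[arm] = net.top_hubs(network, k=k)
        rio.write_network(network, out / f"network_{arm}.tsv", "edge_list")
        rio.write_network(network, out / f"network_{arm}.graphml", "graphml")
        _json_dump({"topology": topo.as_dict(),
                    "zero_variance_taxa_excluded": dropped,
                    "null_comparison": {"observed": null.observed,
                                        "null_mean": null.null_mean,
                                        "null_sd": null.null_sd,
                                        "p_values": null.p_values,
                                        "non_random": null.non_random,
                                        "n_graphs": null.n_graphs},
                    "hubs": hubs[arm]},
               out / f"network_{arm}.json")
    shift = net.hub_shift(hubs["untreated"], hubs["biochar"])
    _json_dump({"maintained": sorted(shift.maintained),
                "lost": sorted(shift.lost), "gained": sorted(shift.gained),
                "counts": shift.counts()},
               out / "hub_shift.json")
    manifest["stages"].append("network")

    # ---- stage 5: modules + associations ------------------------------------
    part_u = mods.detect_modules(networks["untreated"], seed=s_lou)
    part_t = mods.detect_modules(networks["biochar"], seed=s_lou)
    mapping, jaccard = mods.match_modules(part_u, part_t)
    part_u.as_series().to_csv(out / "modules_untreated.tsv", sep="\t")
    part_t.as_series().to_csv(out / "modules_biochar.tsv", sep="\t")

    top_u = part_u.top(config.top_modules)
    prof_u = mods.module_profiles(comm.filter_rare(table_u, config.rare_threshold_percent),
                                  part_u, top_u)
    top_t = part_t.top(config.top_modules)
    prof_t = mods.module_profiles(comm.filter_rare(table_t, config.rare_threshold_percent),
                                  part_t, top_t)
    prof_t.columns = [f"M{mapping[int(c[1:])]}" for c in prof_t.columns]

    exp_u = mods.expand_traits_to_units(traits_u, table_u.metadata)
    exp_t = mods.expand_traits_to_units(traits_t, table_t.metadata)
    am_u = mods.associate(prof_u, exp_u, alpha=config.association_alpha)
    am_t = mods.associate(prof_t, exp_t, alpha=config.association_alpha)
    am_u.rho.to_csv(out / "associations_untreated_rho.tsv", sep="\t")
    am_u.p.to_csv(out / "associations_untreated_p.tsv", sep="\t")
    am_t.rho.to_csv(out / "associations_biochar_rho.tsv", sep="\t")
    am_t.p.to_csv(out / "associations_biochar_p.tsv", sep="\t")
    association_heatmap(am_u, out / "associations_untreated.png",
                        title="Untreated module-trait associations")
    association_heatmap(am_t, out / "associations_biochar.png",
                        title="Biochar module-trait associations")

    mantel_out = {}
    from scipy.spatial.distance import pdist, squareform
    for arm, (prof, exp, mseed) in {
        "untreated": (prof_u, exp_u, s_mantel),
        "biochar": (prof_t, exp_t, s_mantel + 1),
    }.items():
        d_prof = squareform(pdist(prof.to_numpy()))
        d_trait = squareform(pdist(exp.to_numpy()))
        r, pv = mods.mantel(d_prof, d_trait, n_perm=config.n_perm, seed=mseed)
        mantel_out[arm] = {"mantel_r": r, "p_value": pv}

    assoc_shift = mods.classify_shift(am_u, am_t)
    _json_dump({"module_matching": {"mapping": {f"M{k}": f"M{v}" for k, v in mapping.items()},
                                    "jaccard": {f"M{k}": v for k, v in jaccard.items()}},
                "mantel": mantel_out,
                "shift": {"new": sorted(map(list, assoc_shift.new)),
                          "maintained": sorted(map(list, assoc_shift.maintained)),
                          "missed": sorted(map(list, assoc_shift.missed)),
                          "counts": assoc_shift.counts()}},
               out / "associations.json")
    manifest["stages"].append("associate")

    _json_dump(manifest, out / "manifest.json")
    return manifest
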