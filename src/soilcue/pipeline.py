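"""Full-study orchestration: rates, chemistry, diversity, four group networks,
topology comparison and statistics from a config file.

The analysis splits samples into the four ecological niches — AM
non-rhizosphere, AM rhizosphere, ECM non-rhizosphere, ECM rhizosphere — and
builds one bacterial–fungal co-occurrence network per niche from that niche's
samples only (bacteria and fungi prevalence-filtered separately, then merged
and renormalised jointly per sample). Per-stage seeds derive deterministically
from the master seed, so a bundle is reproducible from its manifest alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._util import derive_seed
from .chemistry import process_chemistry_table
from .community import (
    DEFAULT_PREVALENCE_FRACTIONS,
    DEFAULT_RAREFACTION_DEPTHS,
    OtuTable,
    alpha_diversity_table,
    prevalence_filter,
    rarefy,
)
from .isotope import IncubationConfig, process_incubation_table
from .network import (
    TOPOLOGY_FIELDS,
    build_network,
    degree_distribution_ks,
    module_composition,
    network_edge_table,
    topology,
)
from .sparcc import bootstrap_pseudo_p, sparcc
from .stats import factorial_test, spearman_screen, wilcoxon_pair

logger = logging.getLogger(__name__)

GROUPS = [
    ("AM", "non_rhizosphere"),
    ("AM", "rhizosphere"),
    ("ECM", "non_rhizosphere"),
    ("ECM", "rhizosphere"),
]

RESPONSES = [
    "growth",
    "respiration",
    "uptake",
    "cue",
    "q_growth",
    "q_co2",
    "q_uptake",
    "turnover",
    "MBC",
    "MBN",
    "r_cn",
    "b_cn",
    "imbalance",
]

SCREEN_RESPONSES = [
    "growth",
    "respiration",
    "uptake",
    "q_growth",
    "q_co2",
    "q_uptake",
    "cue",
    "turnover",
]


@dataclass
class RunConfig:
    """Everything needed to reproduce one full analysis run."""

    metadata_path: str
    incubation_path: str
    fumigation_path: str
    otu_bacteria_path: str
    otu_fungi_path: str
    out_dir: str = "results"
    seed: int = 0
    incubation: IncubationConfig = field(default_factory=IncubationConfig)
    rarefaction_depths: dict = field(
        default_factory=lambda: dict(DEFAULT_RAREFACTION_DEPTHS)
    )
    prevalence_fractions: dict = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_FRACTIONS)
    )
    r_min: float = 0.65
    alpha: float = 0.05
    n_iterations: int = 20
    n_bootstraps: int = 100

    def __post_init__(self) -> None:
        if not 0 < self.r_min < 1 or not 0 < self.alpha < 1:
            raise ValueError("network thresholds out of range")
        if self.n_iterations < 1 or self.n_bootstraps < 1:
            raise ValueError("iteration and bootstrap counts must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        inc = IncubationConfig(**raw.pop("incubation", {}))
        return cls(incubation=inc, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class GroupNetworkResult:
    """Network, topology and module composition for one niche."""

    mycorrhizal_type: str
    position: str
    network: nx.Graph
    summary: pd.Series
    modules: pd.DataFrame
    n_samples: int
    n_taxa: int


@dataclass
class ResultBundle:
    """All outputs of one run, keyed the way the study reports them."""

    rates: pd.DataFrame
    chemistry: pd.DataFrame
    diversity: pd.DataFrame
    networks: dict[tuple[str, str], GroupNetworkResult]
    network_comparisons: pd.DataFrame
    statistics: pd.DataFrame
    wilcoxon: pd.DataFrame
    correlation_screen: pd.DataFrame
    exclusion_log: pd.DataFrame
    manifest: dict

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.rates.to_csv(out / "rates.tsv", sep="\t", index=False)
        self.chemistry.to_csv(out / "chemistry.tsv", sep="\t", index=False)
        self.diversity.to_csv(out / "diversity.tsv", sep="\t", index=False)
        self.statistics.to_csv(out / "statistics.tsv", sep="\t", index=False)
        self.wilcoxon.to_csv(out / "wilcoxon.tsv", sep="\t", index=False)
        self.correlation_screen.to_csv(out / "correlation_screen.tsv", sep="\t", index=False)
        self.network_comparisons.to_csv(out / "network_ks.tsv", sep="\t", index=False)
        self.exclusion_log.to_csv(out / "exclusions.tsv", sep="\t", index=False)
        topo = pd.DataFrame(
            {f"{g.mycorrhizal_type}_{g.position}": g.summary for g in self.networks.values()}
        )
        topo.to_csv(out / "topology.tsv", sep="\t")
        for (m, p), g in self.networks.items():
            stem = f"network_{m}_{p}"
            nx.write_graphml(g.network, out / f"{stem}.graphml")
            network_edge_table(g.network).to_csv(out / f"{stem}_edges.csv", index=False)
            g.modules.to_csv(out / f"{stem}_modules.tsv", sep="\t", index=False)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(self.manifest, fh, sort_keys=False)


def validate_inputs(
    metadata: pd.DataFrame,
    incubation: pd.DataFrame,
    fumigation: pd.DataFrame,
    bacteria: OtuTable,
    fungi: OtuTable,
) -> list[str]:
    """Cross-reference and integrity checks; returns a list of issues (empty = pristine)."""
    issues: list[str] = []
    meta_ids = set(metadata["sample_id"])
    for name, ids in [
        ("incubation", set(incubation["sample_id"])),
        ("fumigation", set(fumigation["sample_id"])),
        ("otu_bacteria", set(bacteria.sample_ids)),
        ("otu_fungi", set(fungi.sample_ids)),
    ]:
        for sid in sorted(ids - meta_ids):
            issues.append(f"{name}: sample {sid!r} absent from metadata")
        for sid in sorted(meta_ids - ids):
            issues.append(f"{name}: metadata sample {sid!r} missing")
    for col in ("mycorrhizal_type", "position"):
        bad = set(metadata[col]) - (
            {"AM", "ECM"} if col == "mycorrhizal_type" else {"rhizosphere", "non_rhizosphere"}
        )
        if bad:
            issues.append(f"metadata: unknown {col} level(s) {sorted(bad)}")
    for name, tab in [("otu_bacteria", bacteria), ("otu_fungi", fungi)]:
        vals = tab.counts.values
        if not np.allclose(vals, np.round(vals)):
            issues.append(f"{name}: non-integer counts")
        if (vals < 0).any():
            taxa, samples = np.where(vals < 0)
            issues.append(
                f"{name}: negative count at taxon {tab.taxon_ids[taxa[0]]!r}, "
                f"sample {tab.sample_ids[samples[0]]!r}"
            )
    for name, frame in [("incubation", incubation), ("fumigation", fumigation)]:
        dup = frame["sample_id"][frame["sample_id"].duplicated()]
        if len(dup):
            issues.append(f"{name}: duplicate sample_id {sorted(set(dup))}")
    return issues


def group_network(
    bacteria: OtuTable,
    fungi: OtuTable,
    sample_ids: list[str],
    prevalence_fractions: dict,
    r_min: float,
    alpha: float,
    n_iterations: int,
    n_bootstraps: int,
    seed: int,
) -> tuple[nx.Graph, pd.Series, pd.DataFrame, int]:
    """SparCC network for one niche from its samples only.

    The two domains are prevalence-filtered separately at their own
    thresholds, then the count tables are concatenated; the correlation
    estimator renormalises jointly per sample via its Dirichlet fraction
    draws.
    """
    b = prevalence_filter(
        bacteria.subset_samples(sample_ids), prevalence_fractions["bacteria"]
    )
    f = prevalence_filter(fungi.subset_samples(sample_ids), prevalence_fractions["fungi"])
    merged = pd.concat([b.counts, f.counts])
    domains = {t: "bacteria" for t in b.taxon_ids}
    domains.update({t: "fungi" for t in f.taxon_ids})
    est = sparcc(merged.values, n_iter=n_iterations, seed=derive_seed(seed, "sparcc"),
                 taxon_ids=list(merged.index))
    est.pseudo_p_matrix = bootstrap_pseudo_p(
        merged.values,
        est.r_matrix,
        n_bootstraps=n_bootstraps,
        n_iter=n_iterations,
        seed=derive_seed(seed, "bootstrap"),
    )
    est.n_bootstraps = n_bootstraps
    net = build_network(est, r_min=r_min, alpha=alpha, domains=domains)
    summary = topology(net).to_series()
    modules = module_composition(net)
    return net, summary, modules, len(merged)


def run_all(
    config: RunConfig,
    metadata: pd.DataFrame | None = None,
    incubation: pd.DataFrame | None = None,
    fumigation: pd.DataFrame | None = None,
    bacteria: OtuTable | None = None,
    fungi: OtuTable | None = None,
) -> ResultBundle:
    """Run the complete analysis. Tables may be passed in-memory; otherwise
    they are read from the paths in ``config``.

    Raises on validation failure. Deterministic given config + seed.
    """
    if metadata is None:
        metadata = pd.read_csv(config.metadata_path, sep="\t")
    if incubation is None:
        incubation = pd.read_csv(config.incubation_path, sep="\t")
    if fumigation is None:
        fumigation = pd.read_csv(config.fumigation_path, sep="\t")
    if bacteria is None:
        bacteria = OtuTable.from_tsv(config.otu_bacteria_path, "bacteria")
    if fungi is None:
        fungi = OtuTable.from_tsv(config.otu_fungi_path, "fungi")

    issues = validate_inputs(metadata, incubation, fumigation, bacteria, fungi)
    if issues:
        raise ValueError("input validation failed:\n" + "\n".join(issues))

    meta = metadata.set_index("sample_id")
    seed = config.seed

    rates = process_incubation_table(incubation, config.incubation)
    chem = process_chemistry_table(fumigation)
    logger.info("rates: %d rows; chemistry: %d rows", len(rates), len(chem))

    excluded = rates[rates["reason"] != ""][["sample_id", "reason"]].assign(stage="rates")
    chem_exc = chem[chem["reason"] != ""][["sample_id", "reason"]].assign(stage="chemistry")
    exclusion_log = pd.concat([excluded, chem_exc], ignore_index=True)

    bact_r = rarefy(bacteria, config.rarefaction_depths["bacteria"], derive_seed(seed, "rarefy-bacteria"))
    fung_r = rarefy(fungi, config.rarefaction_depths["fungi"], derive_seed(seed, "rarefy-fungi"))
    diversity = pd.concat(
        [alpha_diversity_table(bact_r), alpha_diversity_table(fung_r)], ignore_index=True
    )
    logger.info("diversity: %d rows", len(diversity))

    networks: dict[tuple[str, str], GroupNetworkResult] = {}
    for myc, pos in GROUPS:
        sids = list(meta.index[(meta["mycorrhizal_type"] == myc) & (meta["position"] == pos)])
        net, summary, modules, n_taxa = group_network(
            bact_r,
            fung_r,
            sids,
            config.prevalence_fractions,
            config.r_min,
            config.alpha,
            config.n_iterations,
            config.n_bootstraps,
            derive_seed(seed, f"network-{myc}-{pos}"),
        )
        networks[(myc, pos)] = GroupNetworkResult(myc, pos, net, summary, modules, len(sids), n_taxa)
        logger.info(
            "network %s/%s: %d samples, %d taxa -> %d nodes, %d links",
            myc, pos, len(sids), n_taxa, summary["n_nodes"], summary["n_links"],
        )

    ks_rows = []
    keys = list(networks)
    for a in range(len(keys)):
        for b_ in range(a + 1, len(keys)):
            ga, gb = networks[keys[a]], networks[keys[b_]]
            if ga.network.number_of_nodes() and gb.network.number_of_nodes():
                d, p = degree_distribution_ks(ga.network, gb.network)
            else:
                d, p = float("nan"), float("nan")
            ks_rows.append(
                {
                    "network_a": f"{keys[a][0]}_{keys[a][1]}",
                    "network_b": f"{keys[b_][0]}_{keys[b_][1]}",
                    "ks_statistic": d,
                    "ks_p": p,
                }
            )
    network_comparisons = pd.DataFrame(ks_rows)

    per_sample = (
        rates.set_index("sample_id")
        .join(chem.set_index("sample_id"), rsuffix="_chem")
        .join(meta[["species", "mycorrhizal_type", "position"]])
        .reset_index()
    )

    stat_rows = []
    for response in RESPONSES:
        sub = per_sample[[response, "mycorrhizal_type", "position", "species"]].rename(
            columns={response: "response", "mycorrhizal_type": "factor_m", "position": "factor_p"}
        )
        try:
            res = factorial_test(sub)
        except ValueError as exc:
            logger.warning("factorial test skipped for %s: %s", response, exc)
            continue
        res.insert(0, "response", response)
        stat_rows.append(res)
    statistics = pd.concat(stat_rows, ignore_index=True)

    wil_rows = []
    for response in RESPONSES:
        for myc in ("AM", "ECM"):
            sub = per_sample[per_sample["mycorrhizal_type"] == myc]
            a = sub.loc[sub["position"] == "non_rhizosphere", response].dropna()
            b_vals = sub.loc[sub["position"] == "rhizosphere", response].dropna()
            if len(a) >= 3 and len(b_vals) >= 3:
                stat, p = wilcoxon_pair(a, b_vals)
                wil_rows.append(
                    {"response": response, "contrast": f"{myc}: non_rhizosphere vs rhizosphere",
                     "statistic": stat, "p": p}
                )
        for pos in ("non_rhizosphere", "rhizosphere"):
            sub = per_sample[per_sample["position"] == pos]
            a = sub.loc[sub["mycorrhizal_type"] == "ECM", response].dropna()
            b_vals = sub.loc[sub["mycorrhizal_type"] == "AM", response].dropna()
            if len(a) >= 3 and len(b_vals) >= 3:
                stat, p = wilcoxon_pair(a, b_vals)
                wil_rows.append(
                    {"response": response, "contrast": f"{pos}: ECM vs AM",
                     "statistic": stat, "p": p}
                )
    wilcoxon = pd.DataFrame(wil_rows)

    screen = _correlation_screen(per_sample, diversity, networks, meta)

    manifest = {
        "soilcue_version": __version__,
        "seed": seed,
        "config": _manifest_config(config),
        "row_counts": {
            "rates": len(rates),
            "chemistry": len(chem),
            "diversity": len(diversity),
            "statistics": len(statistics),
            "exclusions": len(exclusion_log),
        },
        "notes": {
            "path_metrics": "diameter and average path length computed on the largest connected component",
            "turnover_definition": "growth_rate / MBC",
        },
    }

    return ResultBundle(
        rates=rates,
        chemistry=chem,
        diversity=diversity,
        networks=networks,
        network_comparisons=network_comparisons,
        statistics=statistics,
        wilcoxon=wilcoxon,
        correlation_screen=screen,
        exclusion_log=exclusion_log,
        manifest=manifest,
    )


def _manifest_config(config: RunConfig) -> dict:
    d = config.to_dict()
    d["incubation"] = asdict(config.incubation)
    return d


def _correlation_screen(
    per_sample: pd.DataFrame,
    diversity: pd.DataFrame,
    networks: dict[tuple[str, str], GroupNetworkResult],
    meta: pd.DataFrame,
) -> pd.DataFrame:
    """Spearman screen of CUE predictors, run separately per mycorrhizal type.

    Per-sample predictors are the diversity indices and soil chemistry
    ratios; the four network topology metrics exist once per niche and are
    broadcast to that niche's samples (so within one mycorrhizal type they
    take two values, rhizosphere and non-rhizosphere).
    """
    div = diversity.pivot(index="sample_id", columns="domain", values=["richness", "shannon"])
    div.columns = [f"{dom[0].upper()}_{metric}" for metric, dom in div.columns]

    topo_cols = ["avgK", "density", "clustering_coefficient", "centralization_of_degree"]
    topo_per_sample = pd.DataFrame(index=meta.index, columns=topo_cols, dtype=float)
    for (myc, pos), g in networks.items():
        mask = (meta["mycorrhizal_type"] == myc) & (meta["position"] == pos)
        for c in topo_cols:
            topo_per_sample.loc[mask, c] = g.summary[c]

    frames = []
    indexed = per_sample.set_index("sample_id")
    for myc in ("AM", "ECM"):
        ids = meta.index[meta["mycorrhizal_type"] == myc]
        predictors = pd.concat(
            [
                div.reindex(ids),
                topo_per_sample.reindex(ids),
                indexed.reindex(ids)[["pH", "b_cn", "r_cn", "imbalance"]],
            ],
            axis=1,
        )
        responses = indexed.reindex(ids)[SCREEN_RESPONSES]
        res = spearman_screen(predictors, responses)
        res.insert(0, "mycorrhizal_type", myc)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)
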