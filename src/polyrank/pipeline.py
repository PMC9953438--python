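"""End-to-end orchestration: synthesis, the analysis stages in dependency
order (morphometrics -> distances -> consensus clustering; niche ->
geography; parentage scan; integration), and report output.

Analysis parameters default to the study protocol this pipeline
implements: 20 EFA harmonics, 15 shape PCs, 5000/100 shape-test
permutations, WKM with 5000 runs and k in [2, 14] at feature/sample
fractions 0.60/0.80, 200 niche-equivalency replicates, 400 sympatry
simulations at threshold 0.25, and alpha = 0.01 with Bonferroni
correction throughout.  Synthetic-dataset sizes are configurable so smoke
runs finish quickly; every random step derives its seed from the run
seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import (
    consensus,
    formats_io,
    geography,
    morphometrics,
    niche,
    popgen,
    ranking,
    sniploid,
    synthetic,
)

__all__ = ["RunConfig", "SyntheticDataset", "synthesize_dataset", "run_pipeline"]


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "polyrank_run"
    # synthetic-world sizes
    n_diploid_taxa: int = 3
    samples_per_taxon: int = 6
    n_sites: int = 600
    divergence_F: float = 0.2
    missing_rate: float = 0.02
    leaves_per_taxon: int = 20
    grid_shape: tuple[int, int] = (30, 45)
    n_occ_per_taxon: int = 30
    scenario: str = "allopatric"
    # analysis parameters (protocol defaults)
    n_harmonics: int = 20
    n_pc: int = 15
    n_perm_shape: int = 5000
    n_perm_npmanova: int = 100
    wkm_runs: int = 5000
    k_min: int = 2
    k_max: int = 14
    feature_fraction: float = 0.60
    sample_fraction: float = 0.80
    niche_reps: int = 200
    sympatry_sims: int = 400
    range_threshold: float = 0.25
    alpha: float = 0.01

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in data:
            data = {**data, "grid_shape": tuple(data["grid_shape"])}
        return cls(**data)


@dataclass
class SyntheticDataset:
    genotypes: formats_io.GenotypeMatrix
    leaf_annotations: dict[str, list]
    env: formats_io.EnvStack
    occurrences: formats_io.OccurrenceSet
    truth: synthetic.SimTruth
    allotetraploid: str
    autotetraploid: str
    taxa: list[str] = field(default_factory=list)


def synthesize_dataset(cfg: RunConfig) -> SyntheticDataset:
    """One coherent synthetic world: diploid taxa plus one allotetraploid
    (child of the first two diploids) and one autotetraploid, each taxon
    with its own leaf-dissection level and environmental niche."""
    rng = np.random.default_rng(cfg.seed)
    allo, auto = "allotetraploid", "autotetraploid"
    g, truth = synthetic.simulate_genotypes(
        n_taxa=cfg.n_diploid_taxa,
        samples_per_taxon=cfg.samples_per_taxon,
        n_sites=cfg.n_sites,
        divergence_F=cfg.divergence_F,
        polyploid_specs={
            allo: ("taxon00", "taxon01"),
            auto: f"auto:taxon{cfg.n_diploid_taxa - 1:02d}",
        },
        missing_rate=cfg.missing_rate,
        seed=int(rng.integers(2**31 - 1)),
    )
    taxa = sorted(set(g.taxon_of.values()))
    leaf_annots: dict[str, list] = {}
    for i, t in enumerate(taxa):
        annots, _, leaf_truth = synthetic.simulate_leaves(
            n_per_taxon=cfg.leaves_per_taxon,
            elongation=2.0 + 0.4 * i,
            dissection_amplitude=0.05 + 0.08 * i,
            lobe_count=6 + (i % 3) * 2,
            bend_curvature=0.002,
            seed=int(rng.integers(2**31 - 1)),
            taxon=t,
        )
        leaf_annots[t] = annots
        truth.dissection_of[t] = leaf_truth.dissection_of[t]
    env_seed = int(rng.integers(2**31 - 1))
    niche_rng = np.random.default_rng(env_seed)
    niches = {t: (niche_rng.standard_normal(3) * 0.8, 0.7) for t in taxa}
    env, occ, land_truth = synthetic.simulate_landscape(
        grid_shape=cfg.grid_shape,
        n_env=3,
        taxa_niches=niches,
        n_occ_per_taxon=cfg.n_occ_per_taxon,
        scenario=cfg.scenario,
        seed=env_seed,
    )
    truth.niche_centers = land_truth.niche_centers
    truth.niche_widths = land_truth.niche_widths
    truth.params["landscape"] = land_truth.params
    return SyntheticDataset(
        genotypes=g, leaf_annotations=leaf_annots, env=env, occurrences=occ,
        truth=truth, allotetraploid=allo, autotetraploid=auto, taxa=taxa,
    )


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    formats_io.write_vcf_genotypes(ds.genotypes, out / "genotypes.vcf")
    formats_io.write_occurrence_table(ds.occurrences, out / "occurrences.csv")
    for name, arr in ds.env.layers.items():
        formats_io.write_esri_ascii(arr, ds.env.extent, ds.env.resolution,
                                    out / f"{name}.asc")
    for t, annots in ds.leaf_annotations.items():
        formats_io.write_leaf_annotations_json(annots, out / f"leaves_{t}.json")
    ds.truth.to_json(out / "sim_truth.json")
    meta = {
        "taxon_of": ds.genotypes.taxon_of,
        "ploidy_of": ds.genotypes.ploidy_of,
        "taxa": ds.taxa,
        "allotetraploid": ds.allotetraploid,
        "autotetraploid": ds.autotetraploid,
    }
    (out / "dataset.json").write_text(json.dumps(meta, indent=1))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_morphometrics(ds: SyntheticDataset, cfg: RunConfig) -> morphometrics.PairwiseTestTable:
    metrics = []
    for taxon, annots in ds.leaf_annotations.items():
        for ann in annots:
            mask = morphometrics.straighten_leaf(ann)
            contour = morphometrics.mask_to_contour(mask)
            ldi = morphometrics.leaf_dissection_index(contour)
            coeffs, feats = morphometrics.elliptic_fourier_descriptors(
                contour, n_harmonics=cfg.n_harmonics
            )
            metrics.append(
                morphometrics.LeafMetrics(ann.specimen_id, taxon, ldi, coeffs, feats)
            )
    return morphometrics.pairwise_morphology_tests(
        metrics, n_pc=cfg.n_pc, n_perm_shape=cfg.n_perm_shape,
        n_perm_npmanova=cfg.n_perm_npmanova, seed=cfg.seed,
    )


def stage_distances(ds: SyntheticDataset, cfg: RunConfig, out: Path | None = None):
    nd = popgen.nei_distance_matrix(ds.genotypes)
    pcoa = popgen.pcoa_lingoes(nd.D)
    if out is not None:
        formats_io.write_distance_nexus(nd.labels, nd.D, out / "nei_distances.nex")
        formats_io.write_distance_phylip(nd.labels, nd.D, out / "nei_distances.phy")
    return nd, pcoa


def stage_wkm(ds: SyntheticDataset, cfg: RunConfig, nd, pcoa):
    X = pcoa.scores_for_variance(0.5)
    labels = [ds.genotypes.taxon_of[s] for s in nd.labels]
    constraints = consensus.ConstraintSet.from_taxon_map(
        nd.labels, ds.genotypes.taxon_of,
        must_link_taxa=ds.taxa,
    )
    wcfg = consensus.WkmConfig(
        n_runs=cfg.wkm_runs, feature_fraction=cfg.feature_fraction,
        sample_fraction=cfg.sample_fraction, k_min=cfg.k_min,
        k_max=min(cfg.k_max, len(nd.labels) - 1), seed=cfg.seed,
    )
    model = consensus.run_wkm_ensemble(X, constraints, wcfg)
    model = consensus.consensus_partition(model, X)
    cluster_of_taxon = {}
    best = model.labels_at(model.k_best_bic)
    for t in ds.taxa:
        idx = [i for i, lab in enumerate(labels) if lab == t]
        vals, counts = np.unique(best[idx], return_counts=True)
        cluster_of_taxon[t] = int(vals[np.argmax(counts)])
    return model, cluster_of_taxon


def stage_sniploid(ds: SyntheticDataset, cfg: RunConfig) -> pd.DataFrame:
    diploids = [t for t in ds.taxa
                if ds.genotypes.ploidy_of[ds.genotypes.samples_of_taxon(t)[0]] == 2]
    return sniploid.parent_scan(ds.genotypes, diploids, ds.allotetraploid)


def _pairwise_permutation_tables(ds: SyntheticDataset, cfg: RunConfig):
    env_pc = niche.env_pca_rasters(ds.env, n_components=3)
    rng = np.random.default_rng(cfg.seed)
    taxa = ds.taxa
    pairs = list(itertools.combinations(sorted(taxa), 2))
    m = len(pairs)
    niche_p: dict[frozenset, tuple[float | None, float | None]] = {}
    symp_p: dict[frozenset, float | None] = {}
    for a, b in pairs:
        xa, xb = ds.occurrences.for_taxon(a), ds.occurrences.for_taxon(b)
        key = frozenset((a, b))
        try:
            _, _, p_d, p_i = niche.niche_equivalency_test(
                xa, xb, env_pc, n_reps=cfg.niche_reps,
                seed=int(rng.integers(2**31 - 1)),
            )
            niche_p[key] = (
                float(morphometrics.bonferroni_adjust(p_d, m)),
                float(morphometrics.bonferroni_adjust(p_i, m)),
            )
        except niche.NicheUndefinedError:
            niche_p[key] = (None, None)
        try:
            _, p_s = geography.sympatry_test(
                xa, xb, env_pc, n_sim=cfg.sympatry_sims,
                threshold=cfg.range_threshold,
                seed=int(rng.integers(2**31 - 1)),
            )
            symp_p[key] = float(morphometrics.bonferroni_adjust(p_s, m))
        except niche.NicheUndefinedError:
            symp_p[key] = None
    return niche_p, symp_p


def run_pipeline(cfg: RunConfig, ds: SyntheticDataset | None = None) -> dict:
    """Execute all stages and write CSV outputs plus a Markdown report.

    Returns a summary dict (cluster model optima, parentage ranking,
    evidence matrix and decisions) for programmatic use.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(asdict(cfg), indent=1))
    if ds is None:
        ds = synthesize_dataset(cfg)
        write_dataset(ds, out / "data")

    morpho = stage_morphometrics(ds, cfg)
    morpho.to_frame().to_csv(out / "morphology_pairwise.csv")
    nd, pcoa = stage_distances(ds, cfg, out)
    model, cluster_of_taxon = stage_wkm(ds, cfg, nd, pcoa)
    pd.DataFrame(model.C, index=nd.labels, columns=nd.labels).to_csv(
        out / "consensus_matrix.csv"
    )
    pd.DataFrame(
        [(k, v[1], v[2]) for k, v in sorted(model.per_k.items())],
        columns=["k", "BIC", "CH"],
    ).to_csv(out / "cluster_scores.csv", index=False)
    scan = stage_sniploid(ds, cfg)
    scan.to_csv(out / "parent_scan.csv", index=False)
    niche_p, symp_p = _pairwise_permutation_tables(ds, cfg)

    taxa_idx = {t: i for i, t in enumerate(morpho.taxa)}
    morpho_p = {
        frozenset((a, b)): (
            float(morpho.p_ldi[taxa_idx[a], taxa_idx[b]]),
            float(morpho.p_perm[taxa_idx[a], taxa_idx[b]]),
            float(morpho.p_npmanova[taxa_idx[a], taxa_idx[b]]),
        )
        for a, b in itertools.combinations(sorted(ds.taxa), 2)
    }
    evidence = ranking.build_evidence_matrix(
        cluster_of_taxon, symp_p, niche_p, morpho_p, alpha=cfg.alpha
    )
    decisions = ranking.rank_decisions(evidence)
    evidence.to_frame().to_csv(out / "evidence_matrix.csv", index=False)
    ranking.decisions_to_frame(decisions).to_csv(out / "rank_decisions.csv", index=False)
    arrangement = ranking.species_arrangement(decisions)
    _write_figures(out, model, nd, scan)
    _write_report(out, cfg, ds, model, scan, evidence, decisions, arrangement)
    return {
        "k_best_bic": model.k_best_bic,
        "k_best_ch": model.k_best_ch,
        "cluster_of_taxon": cluster_of_taxon,
        "parent_scan": scan,
        "evidence": evidence,
        "decisions": decisions,
        "arrangement": arrangement,
    }


def _write_figures(out: Path, model, nd, scan) -> None:
    """Consensus-matrix heatmap (ordered by consensus clusters), per-k
    score curves, and the parentage stacked bars."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = np.argsort(model.labels_at(model.k_best_bic), kind="stable")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(model.C[np.ix_(order, order)], cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(order)))
    ax.set_yticks(range(len(order)))
    labels = [nd.labels[i] for i in order]
    ax.set_xticklabels(labels, rotation=90, fontsize=5)
    ax.set_yticklabels(labels, fontsize=5)
    fig.colorbar(im, label="co-association")
    fig.tight_layout()
    fig.savefig(out / "consensus_heatmap.png", dpi=150)
    plt.close(fig)

    ks = sorted(model.per_k)
    fig, ax1 = plt.subplots(figsize=(5, 3.5))
    ax1.plot(ks, [model.per_k[k][1] for k in ks], "o-", color="tab:blue")
    ax1.set_xlabel("number of clusters k")
    ax1.set_ylabel("BIC (lower is better)", color="tab:blue")
    ax2 = ax1.twinx()
    ax2.plot(ks, [model.per_k[k][2] for k in ks], "s--", color="tab:orange")
    ax2.set_ylabel("CH (higher is better)", color="tab:orange")
    fig.tight_layout()
    fig.savefig(out / "cluster_scores.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 3.5))
    pair_labels = [f"{r.parent1}\nx {r.parent2}" for r in scan.itertuples()]
    bottom = np.zeros(len(scan))
    for cat, color in [("cat1", "#4477aa"), ("cat2", "#66ccee"),
                       ("cat34", "#ccbb44"), ("cat5", "#ee6677")]:
        vals = scan[cat].to_numpy()
        ax.bar(pair_labels, vals, bottom=bottom, label=cat, color=color)
        bottom += vals
    ax.set_ylabel("mean category proportion")
    ax.legend(fontsize=7)
    ax.tick_params(axis="x", labelsize=6)
    fig.tight_layout()
    fig.savefig(out / "parent_scan.png", dpi=150)
    plt.close(fig)


def _write_report(out, cfg, ds, model, scan, evidence, decisions, arrangement) -> None:
    lines = ["# Integrative delimitation report", ""]
    lines.append(f"Seed: {cfg.seed}; taxa: {', '.join(ds.taxa)}")
    lines.append(f"BIC-optimal k: {model.k_best_bic}; CH-optimal k: {model.k_best_ch}")
    lines.append("")
    lines.append("## Parentage scan (mean homeo-SNP proportion, descending)")
    lines.append(scan.to_string(index=False))
    lines.append("")
    lines.append("## Evidence matrix")
    lines.append(evidence.to_frame().to_string(index=False))
    lines.append("")
    lines.append("## Rank recommendations")
    for d in decisions:
        lines.append(f"- {d.pair[0]} / {d.pair[1]}: {d.recommendation} ({d.rule_id})")
    lines.append("")
    groups = ["{" + ", ".join(sorted(g)) + "}" for g in arrangement]
    lines.append(f"Species arrangement: {', '.join(groups)}")
    (Path(out) / "report.md").write_text("\n".join(lines) + "\n")
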