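"""End-to-end orchestration: simulate -> QC -> ancestry -> statistics ->
clustering -> classification, with every intermediate written to disk."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import ancestry, classify, clustering, popstats
from .genotype_io import (
    FilterConfig,
    GenotypeMatrix,
    apply_site_filters,
    filter_individuals,
    ld_thin,
    read_vcf,
    write_filter_report,
    write_vcf,
)
from .simulate import ScenarioConfig, generate_scenario

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    scenario: ScenarioConfig | None = None
    vcf_path: str | None = None
    metadata_path: str | None = None
    filters: FilterConfig = field(default_factory=FilterConfig)
    K: int | None = None  # None -> select by cross-validation over k_range
    k_range: tuple[int, ...] = (1, 2, 3, 4, 5)
    restarts: int = 3
    folds: int = 5
    em_max_iter: int = 500
    em_tol: float = 1e-4
    tau_admixture: float = 0.10
    threshold_km: float = 100.0
    theta_fst: float = 0.02
    theta_mix: float = 0.5
    thin_window_bp: int = 5000
    min_overlap: int = 50
    fst_estimator: str = "weir_cockerham"
    rng_seed: int = 0
    out_dir: str = "seedtrace_out"


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _label_clusters(fit: ancestry.AncestryFit) -> list[str]:
    """Cluster labels are arbitrary identifiers; natural populations anchor
    them to the region through the inferred catalogue."""
    return [f"ESU{k + 1}" for k in range(fit.K)]


def _catalog_from_metadata(
    metadata: pd.DataFrame,
    assignments: list[ancestry.EsuAssignment],
    all_labels: list[str] | None = None,
) -> classify.EsuCatalog:
    """Regional catalogue inferred from metadata: natural populations anchor
    their majority-assigned ESU; clusters without a non-admixed natural
    population are allochthonous by definition."""
    pop_of = dict(zip(metadata["individual_id"], metadata["pop_id"]))
    coords = {
        r.pop_id: (float(r.latitude), float(r.longitude)) for r in metadata.itertuples()
    }
    status_of = dict(zip(metadata["pop_id"], metadata["status"]))
    esus = sorted(set(all_labels or []) | {a.esu for a in assignments})
    refs: dict[str, list[tuple[str, float, float]]] = {}
    by_pop: dict[str, list[ancestry.EsuAssignment]] = {}
    for a in assignments:
        by_pop.setdefault(pop_of[a.individual_id], []).append(a)
    for pop, members in by_pop.items():
        if status_of.get(pop) != "natural":
            continue
        # Natural references must be non-admixed; a population is treated as
        # admixed here only when at least half its members are, so a single
        # noisy individual cannot disqualify an ESU's only reference.
        if sum(m.admixed for m in members) >= 0.5 * len(members):
            continue
        counts: dict[str, int] = {}
        for m in members:
            counts[m.esu] = counts.get(m.esu, 0) + 1
        esu = max(sorted(counts), key=lambda e: counts[e])
        refs.setdefault(esu, []).append((pop, *coords[pop]))
    return classify.EsuCatalog(
        esus=esus, autochthonous=set(refs), reference_pops=refs
    )


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns a report bundle of paths and key results."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out), "rng_seed": cfg.rng_seed}

    stage = "simulate/load"
    try:
        if cfg.scenario is not None:
            G, truth, paths = generate_scenario(cfg.scenario, out / "scenario")
            metadata = pd.read_csv(paths["metadata"], sep="\t")
            bundle["truth"] = truth
        elif cfg.vcf_path and cfg.metadata_path:
            if not Path(cfg.vcf_path).exists():
                raise FileNotFoundError(cfg.vcf_path)
            if not Path(cfg.metadata_path).exists():
                raise FileNotFoundError(cfg.metadata_path)
            G = read_vcf(cfg.vcf_path)
            metadata = pd.read_csv(cfg.metadata_path, sep="\t")
        else:
            raise ValueError("need either a scenario or vcf_path + metadata_path")
    except Exception as exc:
        raise StageError(stage, exc) from exc
    metadata["pop_id"] = metadata["pop_id"].astype(str)

    stage = "qc"
    try:
        G, report = apply_site_filters(G, cfg.filters)
        G = filter_individuals(G, cfg.filters.max_individual_missingness)
        G = ld_thin(G, cfg.thin_window_bp)
        write_filter_report(report, out / "filter_report.tsv")
        write_vcf(G, out / "filtered.vcf")
        log.info("QC kept %d individuals x %d sites", G.n_individuals, G.n_loci)
        bundle["n_sites"] = G.n_loci
        bundle["n_individuals"] = G.n_individuals
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "ancestry"
    try:
        if cfg.K is not None:
            K = cfg.K
        else:
            cv = ancestry.cv_scan(
                G, cfg.k_range, folds=cfg.folds, rng_seed=cfg.rng_seed,
                n_restarts=1,
            )
            K = ancestry.select_K(cv, rule="min")
            bundle["cv_errors"] = cv.errors
        fit = ancestry.fit_admixture(
            G, K, n_restarts=cfg.restarts, max_iter=cfg.em_max_iter,
            tol=cfg.em_tol, rng_seed=cfg.rng_seed,
        )
        labels = _label_clusters(fit)
        assignments = ancestry.assign_esu(
            fit.Q, labels, tau=cfg.tau_admixture, individual_ids=G.individual_ids
        )
        ancestry.write_q_matrix(fit, G.individual_ids, labels, out / "Q.tsv")
        pd.DataFrame(fit.P, index=labels).to_csv(
            out / "P.tsv", sep="\t", float_format="%.6f"
        )
        bundle["K"] = K
        bundle["fit"] = fit
        bundle["esu_labels"] = labels
        bundle["assignments"] = assignments
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "statistics"
    try:
        pop_of = dict(zip(metadata["individual_id"], metadata["pop_id"]))
        esu_of_ind = {a.individual_id: a.esu for a in assignments}
        freqs = popstats.group_allele_freqs(G, esu_of_ind)
        diversity = popstats.inbreeding_F(G, freqs, esu_of_ind)
        diversity.to_csv(out / "diversity.tsv", sep="\t", float_format="%.6f")
        pop_labels = {i: pop_of[i] for i in G.individual_ids}
        counts: dict[str, int] = {}
        for i in G.individual_ids:
            counts[pop_labels[i]] = counts.get(pop_labels[i], 0) + 1
        usable = {i: p for i, p in pop_labels.items() if counts[p] >= 2}
        fst = popstats.pairwise_fst(G, usable, estimator=cfg.fst_estimator)
        fst.to_csv(out / "fst_populations.tsv", sep="\t", float_format="%.6f")
        D = popstats.ibs_dissimilarity(G, min_overlap=cfg.min_overlap)
        D.to_csv(out / "ibs_dissimilarity.tsv", sep="\t", float_format="%.6f")
        bundle["fst"] = fst
        bundle["diversity"] = diversity
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "clustering"
    try:
        if D.shape[0] >= 3:
            tree = clustering.neighbor_joining(D)
            (out / "tree.nwk").write_text(tree.newick + "\n")
        esu_of_pop: dict[str, str] = {}
        for pop in sorted(set(pop_labels.values())):
            members = [a for a in assignments if pop_of[a.individual_id] == pop]
            counts2: dict[str, int] = {}
            for m in members:
                counts2[m.esu] = counts2.get(m.esu, 0) + 1
            esu_of_pop[pop] = max(sorted(counts2), key=lambda e: counts2[e])
        nat = {
            str(r.pop_id) for r in metadata.itertuples() if r.status == "natural"
        }
        source_groups = clustering.detect_homogeneous_source(
            fst, D, pop_labels, esu_of_pop,
            natural_pops=nat, theta_fst=cfg.theta_fst, theta_mix=cfg.theta_mix,
        )
        clustering.write_source_report(source_groups, out / "source_groups.tsv")
        bundle["source_groups"] = source_groups
    except Exception as exc:
        raise StageError(stage, exc) from exc

    stage = "classification"
    try:
        catalog = _catalog_from_metadata(metadata, assignments, labels)
        pop_mean_q: dict[str, dict[str, float]] = {}
        for pop in esu_of_pop:
            idx = [i for i, ind in enumerate(G.individual_ids) if pop_of[ind] == pop]
            means = fit.Q[idx].mean(axis=0)
            pop_mean_q[pop] = {labels[k]: float(means[k]) for k in range(fit.K)}
        evidence = classify.build_evidence(
            assignments, source_groups, catalog,
            metadata, pop_mean_q,
            tau=cfg.tau_admixture, threshold_km=cfg.threshold_km,
        )
        results = [classify.classify_population(e) for e in evidence]
        summary = classify.summarize(results, evidence)
        classify.write_summary(summary, out / "summary.tsv")
        with open(out / "classification.tsv", "w") as fh:
            fh.write("pop_id\tcategory\tdirect_seeding\trationale\n")
            for r in results:
                fh.write(
                    f"{r.pop_id}\t{r.category}\t{'yes' if r.direct_seeding else 'no'}\t"
                    f"{';'.join(r.rationale)}\n"
                )
        bundle["evidence"] = evidence
        bundle["results"] = results
        bundle["summary"] = summary
    except Exception as exc:
        raise StageError(stage, exc) from exc

    (out / "run_config.json").write_text(
        json.dumps(
            {
                "rng_seed": cfg.rng_seed,
                "K": bundle.get("K"),
                "tau_admixture": cfg.tau_admixture,
                "threshold_km": cfg.threshold_km,
                "theta_fst": cfg.theta_fst,
                "theta_mix": cfg.theta_mix,
                "thin_window_bp": cfg.thin_window_bp,
                "n_sites": bundle.get("n_sites"),
                "n_individuals": bundle.get("n_individuals"),
            },
            indent=1,
        )
    )
    return bundle
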