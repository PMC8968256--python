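"""End-to-end curation workflow over a genotype matrix and passport table.

Stage order: read -> Fisher disassociation filter -> site/accession QC ->
split by passport taxon -> per-group single-het cleanup -> per-group
duplicate detection -> structure (NJ tree, PCA, mislabel proposals on
duplicate-collapsed accessions) -> diversity and pairwise F_ST tables ->
selection scan for a named group pair -> per-group and combined greedy
cores.  Every artifact, parameter and count is recorded in a manifest so
each reported number is recomputable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coreset, dedup, geno_io, popstats, structure, sweep_scan, variant_qc
from .geno_io import GenotypeMatrix, PassportRecord, passport_frame, subset

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genotypes: str  # VCF or HapMap path
    passports: str
    outdir: str
    seed: int = 0
    # QC
    fisher_alpha: float = 0.001
    maf_min: float = 0.01
    missing_max: float = 0.30
    het_max: float = 0.10
    accession_missing_max: float = 0.55
    single_het_min_population: int = 100
    # dedup (its own site filter, looser MAF / tighter missingness)
    dedup_maf_min: float = 0.05
    dedup_missing_max: float = 0.50
    dedup_het_max: float = 0.10
    ibs_threshold: float | None = None  # None = auto-detect, fallback 0.99
    min_compared: int = 500
    # structure
    k_neighbors: int = 10
    agreement: float = 0.8
    pca_components: int = 10
    # scan
    scan_pair: tuple[str, str] | None = None
    lowess_f: float = 0.1
    k_sigma: float = 3.0
    # core
    cv: float = 0.99
    d: float = 0.0001


def _read_genotypes(path: str) -> GenotypeMatrix:
    if str(path).endswith((".hmp", ".hmp.txt", ".hapmap")):
        return geno_io.read_hapmap(path)
    return geno_io.read_vcf(path)


def run_curation(config: PipelineConfig) -> dict:
    """Run the whole workflow; returns the manifest (also written to disk)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": asdict(config), "stages": {}, "artifacts": {}}
    log_path = out / "filter_log.jsonl"
    log_path.write_text("")

    def record(stage: str, report: variant_qc.FilterReport) -> None:
        report.append_to_log(log_path)
        manifest["stages"][stage] = {
            "sites_in": report.sites_in, "sites_out": report.sites_out,
            "accessions_in": report.accessions_in,
            "accessions_out": report.accessions_out,
            "parameters": report.parameters}

    G = _read_genotypes(config.genotypes)
    passports = geno_io.read_passport(config.passports)
    pf = passport_frame(passports)
    manifest["stages"]["input"] = {"n_accessions": G.n_accessions,
                                   "n_sites": G.n_sites}

    # --- QC cascade ------------------------------------------------------
    kept, rep = variant_qc.fisher_disassociation_filter(G, alpha=config.fisher_alpha)
    record("fisher", rep)
    G = subset(G, site_indices=kept)

    kept, rep = variant_qc.filter_sites(G, maf_min=config.maf_min,
                                        missing_max=config.missing_max,
                                        het_max=config.het_max)
    record("site_filters", rep)
    G = subset(G, site_indices=kept)

    kept_ids, rep = variant_qc.filter_accessions(
        G, missing_max=config.accession_missing_max)
    record("accession_filter", rep)
    G = subset(G, accessions=kept_ids)

    geno_io.write_vcf(G, out / "filtered.vcf")
    manifest["artifacts"]["filtered_vcf"] = "filtered.vcf"

    groups = {a: str(pf.loc[a, "taxon"]) for a in G.accession_ids if a in pf.index}
    labels = list(dict.fromkeys(groups.values()))

    # --- per-group duplicate detection -----------------------------------
    dedup_out: dict[str, dict] = {}
    all_groups: list[set[str]] = []
    for label in labels:
        members = [a for a in G.accession_ids if groups.get(a) == label]
        if len(members) < 2:
            continue
        G_grp = subset(G, accessions=members)
        kept, _ = variant_qc.filter_sites(G_grp, maf_min=config.dedup_maf_min,
                                          missing_max=config.dedup_missing_max,
                                          het_max=config.dedup_het_max)
        if len(kept) == 0:
            continue
        res = dedup.ibs_matrix(subset(G_grp, site_indices=kept),
                               min_compared=min(config.min_compared, len(kept)))
        vals = dedup.offdiagonal_identities(res)
        if config.ibs_threshold is not None:
            thr, note = config.ibs_threshold, "fixed by config"
        elif len(vals) >= 100:
            det = dedup.detect_identity_threshold(vals)
            thr, note = det.threshold, det.note
        else:
            thr, note = 0.99, "too few pairs for auto-detection; default used"
        grp_set = dedup.duplicate_groups(res, threshold=thr)
        pheno = dedup.phenotype_consistency(grp_set, passports)
        dedup_out[label] = {"n": len(members), "loci_compared": len(kept),
                            "threshold": thr, "threshold_note": note,
                            "n_groups": len(grp_set.groups),
                            "unique_count": grp_set.unique_count,
                            "redundant": grp_set.n_redundant,
                            "groups": grp_set.to_json_dict()["groups"],
                            "phenotype_flags": int(pheno["flagged"].sum())
                            if len(pheno) else 0}
        all_groups.extend(grp_set.groups)
    (out / "duplicates.json").write_text(json.dumps(dedup_out, indent=2))
    manifest["artifacts"]["duplicates"] = "duplicates.json"
    rep_rows = [{"representative": sorted(grp)[0], "member": m, "group_label": label}
                for label, d in dedup_out.items()
                for grp in (set(g) for g in d["groups"])
                for m in sorted(grp)]
    pd.DataFrame(rep_rows, columns=["representative", "member", "group_label"]) \
        .to_csv(out / "duplicate_members.csv", index=False)
    manifest["artifacts"]["duplicate_members"] = "duplicate_members.csv"
    manifest["stages"]["dedup"] = {
        l: {k: v for k, v in d.items() if k != "groups"} for l, d in dedup_out.items()}

    # --- structure on duplicate-collapsed accessions ----------------------
    combined = dedup.DuplicateGroupSet(0.0, all_groups,
                                       G.n_accessions - sum(len(g) - 1
                                                            for g in all_groups),
                                       G.n_accessions)
    reps = dedup.representatives(combined, G.accession_ids)
    G_reps = subset(G, accessions=reps)
    kept, _ = variant_qc.filter_sites(G_reps, maf_min=config.dedup_maf_min,
                                      missing_max=config.dedup_missing_max,
                                      het_max=config.dedup_het_max)
    D = structure.distance_matrix(subset(G_reps, site_indices=kept),
                                  min_compared=1)
    tree = structure.nj_tree(D)
    structure.to_newick(tree, out / "nj_tree.nwk")
    manifest["artifacts"]["nj_tree"] = "nj_tree.nwk"

    pca = structure.grm_pca(G_reps, k=min(config.pca_components, len(reps)))
    pca_df = pca.to_frame()
    pca_df.loc["variance_explained"] = pca.variance_explained
    pca_df.to_csv(out / "pca.tsv", sep="\t")
    manifest["artifacts"]["pca"] = "pca.tsv"

    rep_labels = {a: groups[a] for a in reps}
    proposals = structure.flag_misclassified(
        D, rep_labels, k_neighbors=min(config.k_neighbors, len(reps) - 1),
        agreement=config.agreement)
    structure.proposals_frame(proposals).to_csv(out / "mislabel_proposals.csv",
                                                index=False)
    manifest["artifacts"]["mislabel_proposals"] = "mislabel_proposals.csv"
    manifest["stages"]["structure"] = {
        "n_representatives": len(reps), "n_proposals": len(proposals),
        "pc1_variance": float(pca.variance_explained[0])}

    # --- diversity and pairwise F_ST --------------------------------------
    div = popstats.diversity_table(G, groups)
    div.to_csv(out / "diversity.tsv", sep="\t", index=False)
    fst = popstats.pairwise_fst_table(G, groups)
    fst.to_csv(out / "pairwise_fst.tsv", sep="\t")
    manifest["artifacts"]["diversity"] = "diversity.tsv"
    manifest["artifacts"]["pairwise_fst"] = "pairwise_fst.tsv"
    manifest["stages"]["diversity"] = div.to_dict(orient="records")

    # --- selection scan ----------------------------------------------------
    if config.scan_pair is not None:
        pair = tuple(config.scan_pair)
        members = [a for a in G.accession_ids if groups.get(a) in pair]
        G_pair = subset(G, accessions=members)
        kept, rep = variant_qc.drop_single_het_fixed(
            G_pair, min_population=config.single_het_min_population)
        G_pair = subset(G_pair, site_indices=kept)
        seg = popstats.segregating_mask(G_pair)
        G_pair = variant_qc.mode_impute(
            subset(G_pair, site_indices=np.flatnonzero(seg)))
        profile = sweep_scan.run_scan(
            G_pair, groups, pair,
            sweep_scan.ScanConfig(f=config.lowess_f, k_sigma=config.k_sigma,
                                  seed=config.seed))
        profile.write_tsv(out / "fst_scan.tsv")
        profile.write_bed(out / "fst_regions.bed")
        profile.write_config(out / "fst_scan_config.json")
        manifest["artifacts"]["fst_scan"] = "fst_scan.tsv"
        manifest["artifacts"]["fst_regions"] = "fst_regions.bed"
        manifest["stages"]["scan"] = {
            "pair": list(pair), "n_sites": profile.metadata["n_sites"],
            "genome_mean": profile.genome_mean, "genome_sd": profile.genome_sd,
            "threshold": profile.threshold,
            "regions": [asdict(r) for r in profile.regions]}

    # --- core collections --------------------------------------------------
    cores: dict[str, list[str]] = {}
    core_stage: dict[str, dict] = {}
    for label in labels:
        members = [a for a in G.accession_ids if groups.get(a) == label]
        if len(members) < 2:
            continue
        G_grp = subset(G, accessions=members)
        seg = popstats.segregating_mask(G_grp)
        sel = coreset.greedy_core(subset(G_grp, site_indices=np.flatnonzero(seg)),
                                  cv=config.cv, d=config.d)
        cores[label] = sel.selected
        sel.write_csv(out / f"core_{label}.csv")
        core_stage[label] = {"core_size": len(sel.selected),
                             "final_coverage": sel.final_coverage,
                             "stop_reason": sel.stop_reason}
    combined_core = sorted({a for ids in cores.values() for a in ids})
    report = coreset.core_report(cores, G, pf, groups)
    report.to_csv(out / "core_report.csv", index=False)
    manifest["artifacts"]["core_report"] = "core_report.csv"
    manifest["stages"]["core"] = {"per_group": core_stage,
                                  "combined_core_size": len(combined_core)}

    manifest["consistency"] = {
        "dedup_unique_plus_redundant_equals_n":
            combined.unique_count + combined.n_redundant == G.n_accessions}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
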