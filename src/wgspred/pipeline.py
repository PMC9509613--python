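"""One-command pipeline: simulate -> QC -> GWAS -> preselect -> fit -> evaluate.

Every intermediate result is persisted as TSV with the config hash and
seed in a header comment; a manifest records stage seeds and content
hashes. Re-running with the same config and seed reproduces all outputs
bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from wgspred import bayesr, evaluate, gwas, preselect, relmat, simpop, traitprep
from wgspred.io import (
    config_hash,
    write_dosage_tsv,
    write_pedigree_tsv,
    write_table,
    write_vcf,
)
from wgspred.simpop import GenomeConfig, LineDesign, _stable_hash


def _scenario_seed(seed: int, *parts: str) -> int:
    return (seed * 2654435761 + _stable_hash("|".join(parts))) % (2**31 - 1)


def _bayesr_config(analysis: dict, seed: int) -> dict:
    b = dict(analysis.get("bayesr", {}))
    b.setdefault("n_iterations", 2000)
    b.setdefault("burn_in", 1000)
    b.setdefault("thin", 5)
    return b


def _fit_and_score(
    geno,
    variant_set,
    response,
    train_ids,
    test_ids,
    cfg: bayesr.BayesRConfig,
    line_labels=None,
):
    cols = pd.Index(geno.variant_ids).get_indexer(variant_set.variant_ids)
    rows_train = geno.row_indices(train_ids)
    rows_test = geno.row_indices(test_ids)
    X_train = geno.dosages[np.ix_(rows_train, cols)]
    X_test = geno.dosages[np.ix_(rows_test, cols)]
    labels_train = labels_test = None
    if line_labels is not None:
        labels_train = line_labels.loc[list(train_ids)].to_numpy()
        labels_test = line_labels.loc[list(test_ids)].to_numpy()
    fit = bayesr.fit_bayesr(
        response.loc[list(train_ids)].to_numpy(),
        X_train,
        line_labels=labels_train,
        config=cfg,
        variant_ids=variant_set.variant_ids,
    )
    gebv = bayesr.predict_gebv(fit, X_test, line_labels=labels_test)
    return fit, gebv


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the full study design described by ``config``.

    Returns the output directory; the main artifacts are ``report.tsv``
    (one row per scenario) and, when enough scenarios exist,
    ``comparison.tsv`` (accuracy-difference regression).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["seed"])
    meta = {"config_hash": config_hash(config), "seed": seed}
    sim = config["simulation"]
    analysis = config["analysis"]

    genome = GenomeConfig(**sim["genome"])
    designs = [LineDesign(**d) for d in sim["lines"]]
    ped = simpop.simulate_pedigree(designs, seed)
    geno = simpop.simulate_founders_and_drop(ped, genome, seed)
    noise = sim.get("noise")
    if noise:
        geno = simpop.inject_genotype_noise(
            geno,
            error_rate=noise.get("error_rate", 0.0),
            missing_rate=noise.get("missing_rate", 0.0),
            seed=seed,
        )
    geno = simpop.designate_chip(
        geno, sim["chip"]["n_variants"], sim["chip"].get("maf_min", 0.01)
    )
    write_pedigree_tsv(ped, out / "pedigree.tsv", meta)
    write_dosage_tsv(geno, out / "dosages.tsv", meta)
    if sim.get("write_vcf"):
        line_of = dict(zip(ped.table["id"], ped.table["line"]))
        write_vcf(geno, out / "genotypes.vcf", line_labels=line_of)

    line_labels = pd.Series(
        ped.table["line"].to_numpy(), index=ped.table["id"].to_numpy()
    )
    lines = [d.name for d in designs]

    traits = {}
    for t_i, tspec in enumerate(sim["traits"]):
        trait = simpop.simulate_trait(
            geno,
            n_qtn=tspec["n_qtn"],
            h2=tspec["h2"],
            qtn_panel=tspec.get("qtn_panel", "any"),
            seed=_scenario_seed(seed, "trait", tspec["name"]),
        )
        traits[tspec["name"]] = trait
        write_table(
            pd.DataFrame(
                {
                    "id": geno.individual_ids,
                    "tbv": trait.true_breeding_values,
                    "phenotype": trait.phenotypes,
                }
            ),
            out / f"trait_{tspec['name']}_truth.tsv",
            meta,
        )
        write_table(
            pd.DataFrame(
                {"variant_id": trait.qtn_ids, "effect": trait.qtn_effects}
            ),
            out / f"trait_{tspec['name']}_qtn.tsv",
            meta,
        )

    A = relmat.pedigree_A(ped)

    responses = {}
    use_phen = analysis.get("use_phenotypes", True)
    for name, trait in traits.items():
        phen = pd.Series(trait.phenotypes, index=geno.individual_ids)
        if use_phen:
            table = traitprep.bypass_deregression(phen, line_labels)
        else:
            parts = []
            for line in lines:
                ids = line_labels.index[line_labels == line]
                sub = relmat.RelationshipMatrix(
                    np.asarray(ids, dtype=object),
                    A.submatrix(ids),
                    kind="pedigree_A",
                )
                ebvs = traitprep.animal_model_blup(
                    phen.loc[ids], sub, h2=analysis.get("blup_h2", 0.3),
                    pedigree=ped,
                )
                parts.append(
                    traitprep.deregress(
                        ebvs,
                        ped,
                        min_reliability=analysis.get("min_reliability", 0.0),
                        line_labels=line_labels,
                        phenotyped_ids=set(ids),
                    )
                )
            table = pd.concat(parts, ignore_index=True)
        write_table(table, out / f"response_{name}.tsv", meta)
        responses[name] = table.set_index("id")["debv"]

    bcfg = _bayesr_config(analysis, seed)
    window_bp = analysis.get("window_bp", preselect.DEFAULT_WINDOW_BP)
    p_threshold = analysis.get("p_threshold", preselect.DEFAULT_P_THRESHOLD)
    set_names = analysis.get("variant_sets", ["chip", "top", "chipplussign"])
    report_rows = []

    def run_scenario(line, trait_name, train_ids, test_ids, tag=""):
        response = responses[trait_name]
        rows_line = np.flatnonzero(line_labels.to_numpy() == line)
        rows_train = geno.row_indices(train_ids)
        chip_qc = preselect.qc_filter(geno, "chip", rows=rows_line)
        wgs_qc = preselect.qc_filter(geno, "wgs", rows=rows_line)
        chipset = preselect.chip_set(geno, chip_qc)

        K = relmat.genomic_K(geno.subset(rows=rows_train), chip_qc)
        spectral = gwas.SpectralDecomposition.from_K(K.values)
        y_train = response.loc[list(train_ids)].to_numpy()
        vc = gwas.estimate_null_vc(y_train, spectral)
        scan_cols = np.flatnonzero(wgs_qc)
        scan = gwas.association_scan(
            y_train,
            geno.dosages[np.ix_(rows_train, scan_cols)],
            geno.variant_ids[scan_cols],
            spectral,
            vc,
            variant_meta=geno.variants.iloc[scan_cols],
        )
        write_table(
            scan,
            out / f"gwas_{line}_{trait_name}{tag}.tsv",
            meta,
        )

        sets = []
        for sname in set_names:
            if sname == "chip":
                sets.append(chipset)
            elif sname == "top":
                for target in analysis.get("top_targets", [None]):
                    sets.append(
                        preselect.select_top_per_window(
                            scan, window_bp, target_count=target
                        )
                    )
            elif sname == "chipplussign":
                sets.append(
                    preselect.select_chip_plus_sign(
                        scan,
                        chipset.variant_ids,
                        window_bp,
                        p_threshold,
                    )
                )
            else:
                raise ValueError(f"unknown variant set {sname!r}")

        for vset in sets:
            cfg = bayesr.BayesRConfig(
                seed=_scenario_seed(seed, line, trait_name, vset.name, tag),
                **bcfg,
            )
            fit, gebv = _fit_and_score(
                geno, vset, response, train_ids, test_ids, cfg
            )
            scores = evaluate.evaluate_scenario(
                gebv, response.loc[list(test_ids)].to_numpy()
            )
            report_rows.append(
                {
                    "line": line,
                    "trait": trait_name,
                    "variant_set": "chip" if vset.name == "chip" else vset.name,
                    "n_variants": len(vset),
                    "n_train": len(train_ids),
                    "n_test": scores["n_test"],
                    "accuracy": scores["accuracy"],
                    "bias": scores["bias"],
                }
            )

    min_fam = analysis.get("min_family_size", 5)
    rel_thr = analysis.get("rel_threshold", 0.5)
    splits = {}  # (line, trait) -> (train_ids, test_ids)
    for line in lines:
        families = evaluate.define_test_set(ped, min_fam, line=line)
        test_ids = [i for fam in families.values() for i in fam]
        for trait_name, response in responses.items():
            phenotyped = [
                i
                for i in response.index
                if line_labels.get(i) == line and i not in set(test_ids)
            ]
            train_ids = evaluate.define_training_set(
                A, test_ids, phenotyped, rel_thr
            )
            splits[(line, trait_name)] = (train_ids, test_ids)
            run_scenario(line, trait_name, train_ids, test_ids)
            for target_n in analysis.get("reduced_training", []):
                reduced = evaluate.reduce_training(train_ids, ped, target_n)
                run_scenario(
                    line, trait_name, reduced, test_ids, tag=f"_n{target_n}"
                )

    if analysis.get("multi_line") and len(lines) > 1:
        inter_mask, union_mask = preselect.ml_variant_universe(
            geno, line_labels.loc[list(geno.individual_ids)].to_numpy()
        )
        ml_chip = preselect.VariantSet(
            name="ml_chip",
            variant_ids=geno.variant_ids[geno.chip_mask & union_mask],
        )
        for trait_name, response in responses.items():
            train_ids = [
                i for line in lines for i in splits[(line, trait_name)][0]
            ]
            rows_train = geno.row_indices(train_ids)
            K = relmat.genomic_K(
                geno.subset(rows=rows_train), geno.chip_mask & union_mask
            )
            spectral = gwas.SpectralDecomposition.from_K(K.values)
            y_train = response.loc[train_ids].to_numpy()
            cov = gwas.line_design_matrix(
                line_labels.loc[train_ids].to_numpy()
            )
            vc = gwas.estimate_null_vc(y_train, spectral, covariates=cov)
            scan_cols = np.flatnonzero(inter_mask)
            scan = gwas.association_scan(
                y_train,
                geno.dosages[np.ix_(rows_train, scan_cols)],
                geno.variant_ids[scan_cols],
                spectral,
                vc,
                covariates=cov,
                variant_meta=geno.variants.iloc[scan_cols],
            )
            write_table(scan, out / f"gwas_ml_{trait_name}.tsv", meta)
            sets = [ml_chip]
            if "top" in set_names:
                for target in analysis.get("top_targets", [None]):
                    vset = preselect.select_top_per_window(
                        scan, window_bp, target_count=target
                    )
                    vset.name = "ml_" + vset.name
                    sets.append(vset)
            if "chipplussign" in set_names:
                vset = preselect.select_chip_plus_sign(
                    scan, ml_chip.variant_ids, window_bp, p_threshold
                )
                vset.name = "ml_chip_plus_sign"
                sets.append(vset)
            for vset in sets:
                cfg = bayesr.BayesRConfig(
                    seed=_scenario_seed(seed, "multi", trait_name, vset.name),
                    **bcfg,
                )
                cols = pd.Index(geno.variant_ids).get_indexer(
                    vset.variant_ids
                )
                fit = bayesr.fit_bayesr(
                    y_train,
                    geno.dosages[np.ix_(rows_train, cols)],
                    line_labels=line_labels.loc[train_ids].to_numpy(),
                    config=cfg,
                    variant_ids=vset.variant_ids,
                )
                for line in lines:  # evaluated separately per line
                    test_ids = splits[(line, trait_name)][1]
                    rows_test = geno.row_indices(test_ids)
                    gebv = bayesr.predict_gebv(
                        fit,
                        geno.dosages[np.ix_(rows_test, cols)],
                        line_labels=line_labels.loc[test_ids].to_numpy(),
                    )
                    scores = evaluate.evaluate_scenario(
                        gebv, response.loc[test_ids].to_numpy()
                    )
                    report_rows.append(
                        {
                            "line": line,
                            "trait": trait_name,
                            "variant_set": vset.name,
                            "n_variants": len(vset),
                            "n_train": len(train_ids),
                            "n_test": scores["n_test"],
                            "accuracy": scores["accuracy"],
                            "bias": scores["bias"],
                        }
                    )

    report = pd.DataFrame(report_rows)
    write_table(report, out / "report.tsv", meta)
    try:
        cmp = evaluate.compare_scenarios(report)
        write_table(
            pd.DataFrame(
                [
                    {
                        "b": cmp["b"],
                        "p_value": cmp["p_value"],
                        "r_squared": cmp["r_squared"],
                        "n_scenarios": cmp["n_scenarios"],
                    }
                ]
            ),
            out / "comparison.tsv",
            meta,
        )
    except Exception:
        pass  # too few scenarios for the difference regression

    manifest = {
        "config_hash": meta["config_hash"],
        "seed": seed,
        "files": {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(out.glob("*.tsv"))
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out
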