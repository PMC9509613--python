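"""Shared fixtures.

The two expensive populations are session-scoped and lazy, so running a
single module only builds what it needs.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from wgspred import evaluate, gwas, relmat, simpop


@pytest.fixture(scope="session")
def toy_pedigree() -> simpop.Pedigree:
    """Hand-written 8-individual pedigree: founders, full sibs, inbred child.

    f1 x f2 -> s1, s2 (full sibs); s1 x s2 -> c1 (inbred, F=0.25);
    f3 x f4 -> u1 (unrelated branch).
    """
    rows = [
        ("f1", "0", "0", "A", 0, 0, "M"),
        ("f2", "0", "0", "A", 0, 1, "F"),
        ("f3", "0", "0", "A", 0, 2, "M"),
        ("f4", "0", "0", "A", 0, 3, "F"),
        ("s1", "f1", "f2", "A", 1, 4, "M"),
        ("s2", "f1", "f2", "A", 1, 5, "F"),
        ("u1", "f3", "f4", "A", 1, 6, "M"),
        ("c1", "s1", "s2", "A", 2, 7, "F"),
    ]
    return simpop.Pedigree(
        pd.DataFrame(
            rows,
            columns=simpop.PEDIGREE_COLUMNS + ["sex"],
        )
    )


@pytest.fixture(scope="session")
def founder_pop():
    """2,000 unrelated founders x 5,000 near-LD-free variants, 500 on chip.

    Used for calibration-style tests where Hardy-Weinberg structure and
    independent tests matter more than pedigree structure.
    """
    ped = simpop.simulate_pedigree(
        simpop.LineDesign("F", 2000, 0, 1, 1, 5), seed=1301
    )
    genome = simpop.GenomeConfig(
        n_chromosomes=5,
        chromosome_length_bp=20_000_000,
        variants_per_chromosome=1000,
        recombination_rate=1e-8,
        founder_ld_decay=2_000.0,  # ~20 kb spacing: adjacent r ~ 0
    )
    geno = simpop.simulate_founders_and_drop(ped, genome, seed=1301)
    geno = simpop.designate_chip(geno, 500)
    return ped, geno


@pytest.fixture(scope="session")
def founder_spectral(founder_pop):
    """Eigendecomposition of the chip-panel K for the founder population."""
    _, geno = founder_pop
    K = relmat.genomic_K(geno, geno.chip_mask)
    return K, gwas.SpectralDecomposition.from_K(K.values)


@pytest.fixture(scope="session")
def study_pop():
    """A realistic single-line study population for end-to-end experiments.

    ~4,700 individuals over 4 generations (last generation = full-sib
    litters of 7), 10,000 variants with moderate short-range LD, 1,000 of
    them on the chip. Returns the pedigree, genotypes, and the train/test
    design (relationship-pruned training set, full-sib test families).
    """
    design = simpop.LineDesign(
        name="A",
        n_founders=500,
        n_generations=3,
        n_sires=50,
        n_dams=200,
        litter_size=7,
    )
    genome = simpop.GenomeConfig(
        n_chromosomes=5,
        chromosome_length_bp=20_000_000,
        variants_per_chromosome=2000,
        recombination_rate=1e-8,
        founder_ld_decay=5_000.0,
    )
    ped = simpop.simulate_pedigree(design, seed=11)
    geno = simpop.simulate_founders_and_drop(ped, genome, seed=11)
    geno = simpop.designate_chip(geno, 1000)
    A = relmat.pedigree_A(ped)
    families = evaluate.define_test_set(ped, min_family_size=5)
    test_ids = [i for fam in families.values() for i in fam]
    train_ids = evaluate.define_training_set(
        A, test_ids, [i for i in ped.ids if i not in set(test_ids)]
    )
    return {
        "pedigree": ped,
        "genotypes": geno,
        "A": A,
        "families": families,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }


@pytest.fixture(scope="session")
def study_gwas_cache(study_pop):
    """Chip-K spectral decomposition and rotated dense genotypes for the
    study population's training set (shared across GWAS-heavy tests)."""
    geno = study_pop["genotypes"]
    train_rows = geno.row_indices(study_pop["train_ids"])
    K = relmat.genomic_K(geno.subset(rows=train_rows), geno.chip_mask)
    spectral = gwas.SpectralDecomposition.from_K(K.values)
    rotated = spectral.rotate(
        np.asarray(geno.dosages[train_rows], dtype=np.float64)
    )
    return {"train_rows": train_rows, "spectral": spectral, "rotated": rotated}
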