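"""File formats and run configuration.

TSV is the canonical interchange format (tab-separated, ``%.10g`` floats,
optional ``#`` header comments carrying the config hash and seed). VCF
(GT-coded, biallelic, diploid) is supported for genotype exchange.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wgspred.errors import ConfigurationError, ParseError
from wgspred.simpop import (
    PEDIGREE_COLUMNS,
    GenotypeMatrix,
    Pedigree,
)

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# generic TSV
# ---------------------------------------------------------------------------


def write_table(
    df: pd.DataFrame, path, meta: dict | None = None
) -> None:
    """Write a TSV with fixed float formatting and ``# key=value`` header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if meta:
            pairs = " ".join(f"{k}={v}" for k, v in sorted(meta.items()))
            fh.write(f"# wgspred {pairs}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------


def write_pedigree_tsv(pedigree: Pedigree, path, meta=None) -> None:
    cols = PEDIGREE_COLUMNS + (
        ["sex"] if "sex" in pedigree.table.columns else []
    )
    write_table(pedigree.table[cols], path, meta)


def read_pedigree_tsv(path) -> Pedigree:
    t = read_table(path, dtype={c: str for c in ("id", "sire", "dam", "line")})
    ped = Pedigree(t)
    ped.validate()
    return ped


# ---------------------------------------------------------------------------
# genotypes: dosage TSV
# ---------------------------------------------------------------------------


def write_dosage_tsv(genotypes: GenotypeMatrix, path, meta=None) -> None:
    """Rows = individuals, columns = variant ids; companion variants file
    written alongside as ``<stem>.variants.tsv`` (chrom/pos/is_chip)."""
    path = Path(path)
    df = pd.DataFrame(
        genotypes.dosages, columns=genotypes.variant_ids
    )
    df.insert(0, "id", genotypes.individual_ids)
    write_table(df, path, meta)
    write_table(
        genotypes.variants, path.with_suffix(".variants.tsv"), meta
    )


def read_dosage_tsv(path, variants_path=None) -> GenotypeMatrix:
    path = Path(path)
    df = read_table(path, dtype={"id": str})
    ids = df["id"].to_numpy(dtype=object)
    dosages = df.drop(columns="id").to_numpy(dtype=np.float32)
    finite = dosages[np.isfinite(dosages)]
    if not np.isin(finite, [0.0, 1.0, 2.0]).all():
        raise ParseError(f"{path}: dosages must be 0, 1, or 2")
    if variants_path is None:
        variants_path = path.with_suffix(".variants.tsv")
    if Path(variants_path).exists():
        variants = read_table(
            variants_path, dtype={"variant_id": str, "chrom": str}
        )
        variants["is_chip"] = variants["is_chip"].astype(bool)
    else:  # reconstruct coordinates from "<chrom>_<pos>" ids
        vids = [str(c) for c in df.columns if c != "id"]
        try:
            chrom = [v.rsplit("_", 1)[0] for v in vids]
            pos = [int(v.rsplit("_", 1)[1]) for v in vids]
        except (IndexError, ValueError) as exc:
            raise ParseError(
                f"{path}: variant ids are not '<chrom>_<pos>' and no "
                "variants table was found"
            ) from exc
        variants = pd.DataFrame(
            {"variant_id": vids, "chrom": chrom, "pos": pos, "is_chip": False}
        )
    return GenotypeMatrix(
        individual_ids=ids, variants=variants, dosages=dosages
    )


# ---------------------------------------------------------------------------
# genotypes: VCF
# ---------------------------------------------------------------------------

_GT_CODES = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_vcf(
    genotypes: GenotypeMatrix, path, line_labels=None
) -> None:
    """Minimal biallelic VCFv4.2 with GT; chip membership in INFO/CHIP."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(genotypes.individual_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##INFO=<ID=CHIP,Number=0,Type=Flag,'
            'Description="Variant is on the marker array">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        for chrom in pd.unique(genotypes.variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        if line_labels is not None:
            for s in samples:
                fh.write(f"##SAMPLE=<ID={s},Line={line_labels[s]}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        variants = genotypes.variants
        for j in range(genotypes.n_variants):
            info = "CHIP" if variants["is_chip"].iloc[j] else "."
            gts = "\t".join(
                _GT_CODES.get(float(d), "./.")
                if np.isfinite(d)
                else "./."
                for d in genotypes.dosages[:, j]
            )
            fh.write(
                f"{variants['chrom'].iloc[j]}\t{variants['pos'].iloc[j]}\t"
                f"{variants['variant_id'].iloc[j]}\tA\tC\t.\tPASS\t{info}\t"
                f"GT\t{gts}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a diploid biallelic VCF into dosages (0/1/2, NaN missing)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    rows = []
    dosage_rows = []
    for k, rec in enumerate(vcf, start=1):
        if len(rec.ALT) != 1:
            raise ParseError(
                f"{path} record {k} ({rec.CHROM}:{rec.POS}): multi-allelic "
                "sites are not supported"
            )
        dos = np.empty(len(samples), dtype=np.float32)
        for s, gt in enumerate(rec.genotypes):
            alleles = gt[:-1]
            if len(alleles) != 2:
                raise ParseError(
                    f"{path} record {k} ({rec.CHROM}:{rec.POS}): ploidy "
                    f"{len(alleles)} is not supported"
                )
            if alleles[0] < 0 or alleles[1] < 0:
                dos[s] = np.nan
            else:
                dos[s] = alleles[0] + alleles[1]
        rows.append(
            {
                "variant_id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "is_chip": bool(rec.INFO.get("CHIP", False)),
            }
        )
        dosage_rows.append(dos)
    variants = pd.DataFrame(rows)
    dosages = (
        np.vstack(dosage_rows).T
        if dosage_rows
        else np.zeros((len(samples), 0), dtype=np.float32)
    )
    return GenotypeMatrix(
        individual_ids=samples, variants=variants, dosages=dosages
    )


def read_genotypes(path, fmt: str | None = None) -> GenotypeMatrix:
    """Dispatch on ``fmt`` ('vcf' | 'dosage_tsv'; inferred from suffix)."""
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if path.suffix == ".vcf" else "dosage_tsv"
    if fmt == "vcf":
        return read_vcf(path)
    if fmt == "dosage_tsv":
        return read_dosage_tsv(path)
    raise ConfigurationError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

REQUIRED_KEYS = (
    "seed",
    "simulation",
    "simulation.genome",
    "simulation.lines",
    "simulation.chip",
    "simulation.traits",
    "analysis",
)


def load_config(path) -> dict:
    with open(path) as fh:
        config = yaml.safe_load(fh)
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if not isinstance(config, dict):
        raise ConfigurationError("config must be a mapping")
    for dotted in REQUIRED_KEYS:
        node = config
        for part in dotted.split("."):
            if not isinstance(node, dict) or part not in node:
                raise ConfigurationError(f"config missing required key: {dotted}")
            node = node[part]


def config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
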