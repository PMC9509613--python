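"""Predictor variant-set construction from GWAS results.

Implements the marker-QC filters, the window index used for proxy
selection, Top-k-per-window sets, ChipPlusSign (array augmented with one
significant variant per window), and the multi-line variant universes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from wgspred.errors import ConfigurationError
from wgspred.simpop import GenotypeMatrix

DEFAULT_WINDOW_BP = 55_000
#: window-count anchor: the default window size is tuned to emit ~40k
#: variants on the reference genome, so target densities rescale against it
BASE_TARGET = 40_000
DEFAULT_P_THRESHOLD = 1e-6


@dataclass
class VariantSet:
    """An ordered, duplicate-free predictor variant set with provenance."""

    name: str
    variant_ids: np.ndarray
    provenance: dict = field(default_factory=dict)  # id -> origin tag
    window_size_bp: int | None = None
    p_threshold: float | None = None

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        if len(set(self.variant_ids)) != len(self.variant_ids):
            raise ConfigurationError("variant set contains duplicates")

    def __len__(self) -> int:
        return len(self.variant_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "provenance": [
                    self.provenance.get(v, "") for v in self.variant_ids
                ],
            }
        )


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def qc_filter(
    genotypes: GenotypeMatrix,
    panel: str = "chip",
    maf_min: float | None = None,
    call_rate_min: float = 0.80,
    hwe_alpha: float = 1e-6,
    rows: np.ndarray | None = None,
) -> np.ndarray:
    """Boolean mask of variants passing MAF, call-rate, and HWE filters.

    Defaults follow the marker-array rules (MAF >= 0.01, call rate >= 0.80,
    HWE chi-square with 1 df at ``hwe_alpha``); the dense-panel default is
    the stricter post-imputation MAF >= 0.023. ``rows`` restricts the
    computation to one line's individuals.
    """
    if maf_min is None:
        maf_min = 0.01 if panel == "chip" else 0.023
    if not (0.0 <= maf_min <= 1.0 and 0.0 <= call_rate_min <= 1.0):
        raise ConfigurationError("maf_min and call_rate_min must be in [0,1]")
    d = genotypes.dosages if rows is None else genotypes.dosages[rows]
    n = d.shape[0]
    observed = ~np.isnan(d)
    call_rate = observed.mean(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)

    n_obs = observed.sum(axis=0)
    n_het = np.nansum(d == 1, axis=0)
    n_hom_alt = np.nansum(d == 2, axis=0)
    n_hom_ref = n_obs - n_het - n_hom_alt
    exp = np.stack(
        [
            n_obs * (1.0 - p) ** 2,
            n_obs * 2.0 * p * (1.0 - p),
            n_obs * p**2,
        ]
    )
    obs = np.stack([n_hom_ref, n_het, n_hom_alt]).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.nansum(
            np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0), axis=0
        )
    hwe_p = chi2.sf(stat, df=1)
    hwe_ok = np.where(maf > 0, hwe_p >= hwe_alpha, True)

    mask = (
        np.nan_to_num(maf) >= maf_min
    ) & (call_rate >= call_rate_min) & hwe_ok
    if panel == "chip":
        mask &= genotypes.chip_mask
    return mask


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def window_index(
    variants: pd.DataFrame, window_size_bp: int = DEFAULT_WINDOW_BP
) -> pd.DataFrame:
    """Map each variant to its (chromosome, window ordinal).

    Windows are consecutive, non-overlapping, 1-based-inclusive
    [w*size + 1, (w+1)*size] per chromosome, anchored at position 1.
    """
    if window_size_bp <= 0:
        raise ConfigurationError("window size must be positive")
    pos = variants["pos"].to_numpy()
    if (pos < 1).any():
        raise ConfigurationError("positions must be >= 1")
    return pd.DataFrame(
        {
            "variant_id": variants["variant_id"].to_numpy(),
            "chrom": variants["chrom"].to_numpy(),
            "window": (pos - 1) // window_size_bp,
        }
    )


def _ranked(gwas: pd.DataFrame) -> pd.DataFrame:
    """Tested variants sorted by (p, pos, id) for deterministic argmin."""
    g = gwas[gwas["tested"]].copy()
    return g.sort_values(
        ["p", "pos", "variant_id"], kind="stable"
    )


def select_top_per_window(
    gwas: pd.DataFrame,
    window_size_bp: int = DEFAULT_WINDOW_BP,
    target_count: int | None = None,
) -> VariantSet:
    """One lowest-p variant per non-empty window (Top40k-style set).

    When ``target_count`` is given the window size is rescaled as
    size * BASE_TARGET / target so the expected number of non-empty
    windows tracks the requested density. Ties in p break by smaller
    position, then id. Windows with no tested variant contribute nothing.
    """
    if target_count is not None:
        window_size_bp = max(1, round(window_size_bp * BASE_TARGET / target_count))
    g = _ranked(gwas)
    win = (g["pos"].to_numpy() - 1) // window_size_bp
    g = g.assign(window=win)
    top = g.groupby(["chrom", "window"], sort=False).head(1)
    top = top.sort_values(["chrom", "pos"], kind="stable")
    ids = top["variant_id"].to_numpy(dtype=object)
    return VariantSet(
        name=f"top_w{window_size_bp}",
        variant_ids=ids,
        provenance={v: "wgs_topwindow" for v in ids},
        window_size_bp=window_size_bp,
    )


def select_chip_plus_sign(
    gwas: pd.DataFrame,
    chip_ids: np.ndarray,
    window_size_bp: int = DEFAULT_WINDOW_BP,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> VariantSet:
    """Chip augmented with one significant (p <= threshold) proxy per window.

    Among the significant dense-panel variants of each window only the
    lowest-p one is retained; the result is the union with the chip set
    (a significant variant already on the array is counted once). With no
    significant variants the output equals the chip set.
    """
    chip_ids = np.asarray(chip_ids, dtype=object)
    g = _ranked(gwas)
    g = g[g["p"] <= p_threshold]
    win = (g["pos"].to_numpy() - 1) // window_size_bp
    proxies = (
        g.assign(window=win).groupby(["chrom", "window"], sort=False).head(1)
    )
    chip_set = set(chip_ids)
    added = [
        v for v in proxies["variant_id"] if v not in chip_set
    ]
    provenance = {v: "chip" for v in chip_ids}
    provenance.update({v: "wgs_significant" for v in added})
    ids = np.concatenate([chip_ids, np.asarray(added, dtype=object)])
    return VariantSet(
        name="chip_plus_sign",
        variant_ids=ids,
        provenance=provenance,
        window_size_bp=window_size_bp,
        p_threshold=p_threshold,
    )


def chip_set(genotypes: GenotypeMatrix, qc_mask: np.ndarray | None = None) -> VariantSet:
    """The marker-array benchmark set (optionally QC-filtered)."""
    mask = genotypes.chip_mask
    if qc_mask is not None:
        mask = mask & qc_mask
    ids = genotypes.variant_ids[mask]
    return VariantSet(
        name="chip",
        variant_ids=ids,
        provenance={v: "chip" for v in ids},
    )


def ml_variant_universe(
    genotypes: GenotypeMatrix,
    line_labels: np.ndarray,
    chip_qc_kwargs: dict | None = None,
    wgs_qc_kwargs: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Multi-line variant masks.

    Returns ``(intersection, union)``: the intersection mask keeps dense
    variants segregating and passing QC in every line (ML-Top/ML-ChipPlusSign
    candidates); the union mask keeps chip variants passing QC in at least
    one line (ML-Chip).
    """
    labels = np.asarray(line_labels, dtype=str)
    lines = sorted(set(labels))
    if len(lines) < 2:
        rows = np.flatnonzero(labels == lines[0])
        wgs = qc_filter(genotypes, panel="wgs", rows=rows, **(wgs_qc_kwargs or {}))
        chip = qc_filter(genotypes, panel="chip", rows=rows, **(chip_qc_kwargs or {}))
        return wgs, chip
    inter = np.ones(genotypes.n_variants, dtype=bool)
    union = np.zeros(genotypes.n_variants, dtype=bool)
    for line in lines:
        rows = np.flatnonzero(labels == line)
        maf = genotypes.minor_allele_frequencies(rows)
        segregating = np.nan_to_num(maf) > 0
        wgs_ok = qc_filter(
            genotypes, panel="wgs", rows=rows, **(wgs_qc_kwargs or {})
        )
        chip_ok = qc_filter(
            genotypes, panel="chip", rows=rows, **(chip_qc_kwargs or {})
        )
        inter &= segregating & wgs_ok
        union |= chip_ok
    return inter, union
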