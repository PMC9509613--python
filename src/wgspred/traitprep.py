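"""Animal-model BLUP and deregression of estimated breeding values.

The response used downstream (``y``) is a deregressed EBV: the parent
average is removed and the Mendelian-sampling part is unshrunk by its
reliability. A bypass that feeds simulated phenotypes straight through is
provided so experiments can isolate prediction-method behaviour from
deregression choices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from wgspred.errors import ConfigurationError, SchemaError
from wgspred.relmat import RelationshipMatrix
from wgspred.simpop import MISSING_PARENT, Pedigree

#: reliability floor for the Mendelian-sampling term (never divide by ~0)
MS_RELIABILITY_FLOOR = 0.01


@dataclass
class EbvTable:
    """Estimated breeding values with reliabilities and parent averages.

    ``table`` columns: id, ebv, reliability, parent_average.
    """

    table: pd.DataFrame
    sigma_u2: float
    sigma_e2: float


def animal_model_blup(
    phenotypes: pd.Series,
    A: RelationshipMatrix,
    h2: float,
    fixed_effects: pd.Series | None = None,
    pedigree: Pedigree | None = None,
) -> EbvTable:
    """Solve Henderson's mixed-model equations for a single-record animal model.

    ``phenotypes`` maps individual id -> record; every phenotyped id must be
    in ``A``. Fixed effects are an overall mean plus an optional categorical
    batch (``fixed_effects``: id -> level). The variance ratio is
    lambda = (1 - h2) / h2; sigma_u2 is anchored at ``h2 * var(y)``.
    Reliability is 1 - PEV / sigma_u2 from the inverse coefficient matrix.
    """
    if not (0.0 < h2 < 1.0):
        raise ConfigurationError("h2 must be in (0, 1) for BLUP")
    ids = list(A.individual_ids)
    pos = {iid: k for k, iid in enumerate(ids)}
    rec_ids = [i for i in phenotypes.index if i in pos]
    if len(rec_ids) != len(phenotypes):
        raise SchemaError("phenotyped individuals missing from A")
    y = phenotypes.loc[rec_ids].to_numpy(dtype=float)
    n_rec, n_ind = len(rec_ids), len(ids)

    # fixed-effect design: mean plus optional batch dummies (first level
    # absorbed into the mean to keep X full rank)
    X = np.ones((n_rec, 1))
    if fixed_effects is not None:
        levels = sorted(set(fixed_effects.loc[rec_ids]))
        for level in levels[1:]:
            X = np.hstack(
                [X, (fixed_effects.loc[rec_ids] == level).to_numpy()[:, None]]
            )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("singular fixed-effect design")

    Z = np.zeros((n_rec, n_ind))
    for r, iid in enumerate(rec_ids):
        Z[r, pos[iid]] = 1.0
    lam = (1.0 - h2) / h2
    Ainv = np.linalg.inv(A.values)
    p = X.shape[1]
    C = np.zeros((p + n_ind, p + n_ind))
    C[:p, :p] = X.T @ X
    C[:p, p:] = X.T @ Z
    C[p:, :p] = Z.T @ X
    C[p:, p:] = Z.T @ Z + lam * Ainv
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    Cinv = np.linalg.inv(C)
    sol = Cinv @ rhs
    ebv = sol[p:]

    var_y = float(y.var(ddof=1)) if n_rec > 1 else 1.0
    sigma_u2 = h2 * var_y
    sigma_e2 = lam * sigma_u2
    # PEV_i = Cinv_uu[i,i] * sigma_e2  =>  rel = 1 - lambda * Cinv_uu[i,i]
    rel = 1.0 - lam * np.diag(Cinv)[p:]
    rel = np.clip(rel, 0.0, 1.0 - 1e-12)

    # individuals with no record and no relatives carry no information
    phenotyped = np.zeros(n_ind, dtype=bool)
    phenotyped[[pos[i] for i in rec_ids]] = True

    parent_average = np.zeros(n_ind)
    if pedigree is not None:
        ped = pedigree.table.set_index("id")
        for k, iid in enumerate(ids):
            if iid not in ped.index:
                continue
            s, d = ped.loc[iid, "sire"], ped.loc[iid, "dam"]
            es = ebv[pos[s]] if s != MISSING_PARENT and s in pos else 0.0
            ed = ebv[pos[d]] if d != MISSING_PARENT and d in pos else 0.0
            parent_average[k] = (es + ed) / 2.0

    table = pd.DataFrame(
        {
            "id": ids,
            "ebv": ebv,
            "reliability": rel,
            "parent_average": parent_average,
        }
    )
    return EbvTable(table=table, sigma_u2=sigma_u2, sigma_e2=sigma_e2)


def deregress(
    ebvs: EbvTable,
    pedigree: Pedigree,
    min_reliability: float = 0.0,
    line_labels: pd.Series | None = None,
    phenotyped_ids=None,
) -> pd.DataFrame:
    """Deregress EBV by removing the parent average and unshrinking.

    dEBV = PA + (EBV - PA) / r2_MS with r2_MS = max(floor, r2_ind - r2_PA)
    and r2_PA = (r2_sire + r2_dam) / 4 (missing parents contribute 0).
    Individuals with r2_MS < ``min_reliability`` are dropped, as are
    individuals without an own phenotype when ``phenotyped_ids`` is given.

    Returns a TraitTable frame: id, line, debv, weight, r2_ms.
    """
    tab = ebvs.table.set_index("id")
    ped = pedigree.table.set_index("id")
    rows = []
    for iid in tab.index:
        if phenotyped_ids is not None and iid not in phenotyped_ids:
            continue
        r2 = float(tab.loc[iid, "reliability"])
        if iid in ped.index:
            s, d = ped.loc[iid, "sire"], ped.loc[iid, "dam"]
        else:
            s = d = MISSING_PARENT
        r2_s = float(tab.loc[s, "reliability"]) if s in tab.index else 0.0
        r2_d = float(tab.loc[d, "reliability"]) if d in tab.index else 0.0
        ebv_s = float(tab.loc[s, "ebv"]) if s in tab.index else 0.0
        ebv_d = float(tab.loc[d, "ebv"]) if d in tab.index else 0.0
        pa = (ebv_s + ebv_d) / 2.0
        r2_pa = (r2_s + r2_d) / 4.0
        r2_ms = max(MS_RELIABILITY_FLOOR, r2 - r2_pa)
        if r2_ms < min_reliability or r2 <= 0.0:
            continue
        debv = pa + (float(tab.loc[iid, "ebv"]) - pa) / r2_ms
        line = "" if line_labels is None else str(line_labels.get(iid, ""))
        # VanRaden-style record weight; stored but unused by default
        weight = r2_ms / max(1.0 - r2_ms, 1e-12)
        rows.append((iid, line, debv, weight, r2_ms))
    return pd.DataFrame(
        rows, columns=["id", "line", "debv", "weight", "r2_ms"]
    )


def bypass_deregression(
    phenotypes: pd.Series, line_labels: pd.Series | None = None
) -> pd.DataFrame:
    """Use phenotypes directly as the response (TraitTable schema)."""
    return pd.DataFrame(
        {
            "id": phenotypes.index,
            "line": ""
            if line_labels is None
            else line_labels.loc[phenotypes.index].astype(str).to_numpy(),
            "debv": phenotypes.to_numpy(dtype=float),
            "weight": 1.0,
            "r2_ms": 1.0,
        }
    )
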