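"""Study design: train/test construction, metrics, and scenario comparison.

The testing set consists of full-sib families (>= 5 sibs) from the last
generation with no progeny of their own; the training set keeps phenotyped
individuals whose pedigree relationship with every test individual is
below 0.5 (excluding parents and full/"closer" relatives of the test
candidates). Accuracy is the test-set correlation between GEBV and the
response; bias is the regression slope of the response on GEBV.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from wgspred.errors import (
    ConfigurationError,
    InfeasibleDesignError,
)
from wgspred.relmat import RelationshipMatrix
from wgspred.simpop import MISSING_PARENT, Pedigree


@dataclass
class Scenario:
    line: str
    trait: str
    variant_set_name: str
    train_ids: np.ndarray
    test_ids: np.ndarray

    @property
    def n_train(self) -> int:
        return len(self.train_ids)

    def validate(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ConfigurationError("train and test sets overlap")


def define_test_set(
    pedigree: Pedigree, min_family_size: int = 5, line: str | None = None
) -> dict[tuple[str, str], list[str]]:
    """Full-sib test families from the last generation.

    Returns a mapping (sire, dam) -> member ids for every family of
    childless last-generation individuals with >= ``min_family_size``
    full sibs. "Last generation" is the maximum generation index (per the
    requested line when given).
    """
    t = pedigree.table
    if line is not None:
        t = t[t["line"] == line]
    if t.empty:
        raise InfeasibleDesignError(f"no individuals in line {line!r}")
    last = t["generation"].max()
    parents = set(pedigree.table["sire"]) | set(pedigree.table["dam"])
    parents.discard(MISSING_PARENT)
    cand = t[(t["generation"] == last) & ~t["id"].isin(parents)]
    cand = cand[
        (cand["sire"] != MISSING_PARENT) & (cand["dam"] != MISSING_PARENT)
    ]
    families: dict[tuple[str, str], list[str]] = {}
    for (s, d), grp in cand.groupby(["sire", "dam"], sort=True):
        if len(grp) >= min_family_size:
            families[(s, d)] = list(grp["id"])
    if not families:
        raise InfeasibleDesignError(
            f"no full-sib family of size >= {min_family_size} in the last "
            "generation"
        )
    return families


def define_training_set(
    A: RelationshipMatrix,
    test_ids,
    phenotyped_ids,
    rel_threshold: float = 0.5,
) -> list[str]:
    """Phenotyped individuals with max relationship to the test set < threshold."""
    test_ids = list(test_ids)
    test_idx = A.index_of(test_ids)
    pos = {iid: k for k, iid in enumerate(A.individual_ids)}
    train = []
    for iid in phenotyped_ids:
        k = pos.get(iid)
        if k is None:
            continue
        if float(A.values[k, test_idx].max()) < rel_threshold:
            train.append(iid)
    if not train:
        raise InfeasibleDesignError("training set is empty after pruning")
    return train


def reduce_training(
    train_ids, pedigree: Pedigree, target_n: int
) -> list[str]:
    """Keep the ``target_n`` most recent training individuals.

    Recency is largest ``birth_order`` (ties broken by id); a no-op when
    ``target_n`` >= the current size.
    """
    if target_n < 1:
        raise ConfigurationError("target_n must be >= 1")
    order = dict(
        zip(pedigree.table["id"], pedigree.table["birth_order"])
    )
    ranked = sorted(train_ids, key=lambda i: (-order[i], i))
    return sorted(ranked[:target_n], key=lambda i: (order[i], i))


def replicate_split(
    families: dict, k: int = 5, seed: int = 0
) -> list[list[str]]:
    """Randomly partition test families into ``k`` family-exclusive subsets.

    Subset sizes are balanced to within one family; every family lands in
    exactly one subset. Deterministic given ``seed``.
    """
    keys = sorted(families)
    if len(keys) < k:
        raise ConfigurationError(
            f"{len(keys)} families cannot fill {k} replicates"
        )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2147483629]))
    perm = rng.permutation(len(keys))
    subsets: list[list[str]] = [[] for _ in range(k)]
    for rank, fam_pos in enumerate(perm):
        subsets[rank % k].extend(families[keys[fam_pos]])
    return subsets


def accuracy(gebv: np.ndarray, response: np.ndarray) -> float | None:
    """Pearson correlation; None (undefined) when either vector is constant."""
    gebv = np.asarray(gebv, dtype=float)
    response = np.asarray(response, dtype=float)
    if len(gebv) < 3:
        raise ConfigurationError("need at least 3 pairs")
    if gebv.std() == 0 or response.std() == 0:
        return None
    return float(np.corrcoef(gebv, response)[0, 1])


def bias(gebv: np.ndarray, response: np.ndarray) -> float | None:
    """OLS slope of the response on GEBV (1 = unbiased); None if undefined."""
    gebv = np.asarray(gebv, dtype=float)
    response = np.asarray(response, dtype=float)
    var = gebv.var()
    if var == 0:
        return None
    cov = np.mean((gebv - gebv.mean()) * (response - response.mean()))
    return float(cov / var)


def compare_scenarios(
    reports: pd.DataFrame, weight_by_n_test: bool = False
) -> dict:
    """Regress (WGS-set accuracy - chip accuracy) on training-set size.

    ``reports`` columns: line, trait, variant_set, accuracy, n_train
    [, n_test]; each (line, trait, n_train) group must contain a ``chip``
    benchmark row. Trait and line enter as categorical effects when they
    vary. Returns slope ``b``, its p-value, and the model R^2.
    """
    chip = reports[reports["variant_set"] == "chip"].set_index(
        ["line", "trait", "n_train"]
    )["accuracy"]
    rows = []
    for _, r in reports[reports["variant_set"] != "chip"].iterrows():
        key = (r["line"], r["trait"], r["n_train"])
        if key not in chip.index:
            continue
        if pd.isna(r["accuracy"]) or pd.isna(chip.loc[key]):
            continue
        rows.append(
            {
                "line": r["line"],
                "trait": r["trait"],
                "n_train": float(r["n_train"]),
                "difference": float(r["accuracy"]) - float(chip.loc[key]),
                "n_test": float(r.get("n_test", 1.0)),
            }
        )
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ConfigurationError(
            "need >= 3 scenarios with a chip benchmark"
        )
    formula = "difference ~ n_train"
    if table["trait"].nunique() > 1:
        formula += " + C(trait)"
    if table["line"].nunique() > 1:
        formula += " + C(line)"
    if weight_by_n_test:
        model = smf.wls(formula, data=table, weights=table["n_test"])
    else:
        model = smf.ols(formula, data=table)
    with np.errstate(divide="ignore", invalid="ignore"):
        fit = model.fit()
    return {
        "b": float(fit.params["n_train"]),
        "p_value": float(fit.pvalues["n_train"]),
        "r_squared": float(fit.rsquared),
        "n_scenarios": int(len(table)),
        "table": table,
    }


def evaluate_scenario(
    gebv: np.ndarray, response: np.ndarray
) -> dict:
    """Accuracy and bias for one scenario (missing metrics stay None)."""
    return {
        "accuracy": accuracy(gebv, response),
        "bias": bias(gebv, response),
        "n_test": int(len(gebv)),
    }
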