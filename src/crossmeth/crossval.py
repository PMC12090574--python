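"""Grouped cross-validation over species-tissue combinations.

Folds partition the *eligible* combinations (species seen in >1 tissue and
tissue seen in >1 species).  Within each fold the remaining observed
combinations are split into training and validation sets for hyperparameter
selection; a validation combination must keep at least one same-species and
one same-tissue combination in training, and the validation set must retain
at least 10% of the non-test combinations or the split is redrawn.  All
individual samples of a test combination are excluded from training, and a
test combination is scored only if both same-species different-tissue and
same-tissue different-species data remain in the training set — the filter
is applied identically to every method.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import baselines as bl
from .cvae import Hyperparameters, build_model, fit, grid_search_hyperparameters
from .data import (CombinationMeanMatrix, ConditionLabels, SampleMatrix,
                   compute_combination_means, enumerate_combinations)
from .imputation import impute_keys


@dataclass
class FoldPlan:
    k: int
    seed: int
    test: list = field(default_factory=list)        # per-fold combination lists
    train: list = field(default_factory=list)
    validation: list = field(default_factory=list)
    evaluable: list = field(default_factory=list)

    def to_json(self, path) -> None:
        def enc(sets):
            return [[list(key) for key in sorted(s)] for s in sets]
        with open(path, "w") as fh:
            json.dump({"k": self.k, "seed": self.seed, "test": enc(self.test),
                       "train": enc(self.train), "validation": enc(self.validation),
                       "evaluable": enc(self.evaluable)}, fh, indent=1)


def make_outer_folds(eligible, k: int = 5, seed: int = 0) -> list[set]:
    """Seeded uniform partition of the eligible set into k near-equal test sets."""
    if k < 2:
        raise ValueError("k must be >= 2")
    eligible = sorted(eligible)
    if len(eligible) < k:
        raise ValueError("fewer eligible combinations than folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(eligible))
    return [set(eligible[i] for i in chunk)
            for chunk in np.array_split(order, k)]


def split_train_validation(non_test, seed: int, val_frac: float = 0.2,
                           min_frac: float = 0.1, max_retries: int = 50):
    """Draw a validation subset that keeps same-species/same-tissue support in train.

    A candidate validation combination lacking at least one same-species and
    at least one same-tissue combination in the candidate training set is
    moved back to training; if the surviving validation set is below
    ``min_frac`` of the non-test combinations the whole draw is retried with
    the next seed.
    """
    non_test = sorted(non_test)
    if not non_test:
        raise ValueError("non_test set is empty")
    best = None
    for attempt in range(max_retries):
        rng = np.random.default_rng(seed + attempt)
        n_val = max(1, int(round(val_frac * len(non_test))))
        chosen = rng.choice(len(non_test), size=n_val, replace=False)
        val = {non_test[i] for i in chosen}
        train = set(non_test) - val
        moved = True
        while moved:
            moved = False
            for key in sorted(val):
                s, t = key
                has_species = any(ks == s for ks, _ in train)
                has_tissue = any(kt == t for _, kt in train)
                if not (has_species and has_tissue):
                    val.discard(key)
                    train.add(key)
                    moved = True
        if best is None or len(val) > len(best[1]):
            best = (train, val)
        if len(val) >= min_frac * len(non_test):
            return train, val
    raise ValueError(
        f"could not find a valid train/validation split in {max_retries} attempts; "
        f"best attempt kept {len(best[1])}/{len(non_test)} in validation")


def _samples_for(matrix: SampleMatrix, labels: ConditionLabels, combos) -> list[int]:
    combos = set(combos)
    return [i for i, key in enumerate(labels.pairs()) if key in combos]


def _subset(matrix: SampleMatrix, labels: ConditionLabels, idx):
    sub = SampleMatrix(matrix.values[idx], [matrix.sample_ids[i] for i in idx],
                       list(matrix.probe_ids))
    return sub, labels.subset(idx)


def _score(imputed: CombinationMeanMatrix, observed: CombinationMeanMatrix,
           fold: int, method: str) -> pd.DataFrame:
    rows = []
    for i, key in enumerate(imputed.keys):
        obs = observed.row(key)
        imp = imputed.values[i]
        r = float("nan")
        if obs.std() > 0 and imp.std() > 0:
            r = float(np.corrcoef(imp, obs)[0, 1])
        rows.append({"species": key[0], "tissue": key[1], "fold": fold,
                     "method": method, "r": r,
                     "mse": float(np.mean((imp - obs) ** 2))})
    return pd.DataFrame(rows)


def run_cross_validation(matrix: SampleMatrix, labels: ConditionLabels,
                         grid, k: int = 5, seed: int = 0,
                         methods=("cmimpute", "species", "tissue", "global", "logistic"),
                         val_rejoin: bool = False, logistic_lam: float = 2.0):
    """Full grouped CV: grid search per fold, then score every method per test key.

    Returns ``(results, plan, imputations)`` where results maps method name to
    a per-key score table concatenated across folds, plan is the FoldPlan, and
    imputations maps method name to a list of per-fold CombinationMeanMatrix.
    """
    observed, _, eligible = enumerate_combinations(labels)
    if not eligible:
        raise ValueError("no eligible combinations for cross-validation")
    grid = [g if isinstance(g, Hyperparameters) else Hyperparameters(**g) for g in grid]
    folds = make_outer_folds(eligible, k=k, seed=seed)
    all_means = compute_combination_means(matrix, labels)
    plan = FoldPlan(k=k, seed=seed)
    results: dict[str, list] = {m: [] for m in methods}
    imputations: dict[str, list] = {m: [] for m in methods}

    for fold_i, test in enumerate(folds):
        non_test = observed - test
        train_c, val_c = split_train_validation(non_test, seed=seed * 101 + fold_i)
        train_idx = _samples_for(matrix, labels, train_c)
        tm, tl = _subset(matrix, labels, train_idx)
        val_means_full = compute_combination_means(
            *_subset(matrix, labels, _samples_for(matrix, labels, val_c)))

        best_hyper, _table = grid_search_hyperparameters(
            grid, tm, tl, val_means_full, seed=seed * 977 + fold_i)

        final_c = train_c | val_c if val_rejoin else train_c
        fm, fl = _subset(matrix, labels, _samples_for(matrix, labels, final_c))

        # a test key counts only with two-sided support in the final training set
        evaluable = sorted(
            (s, t) for s, t in test
            if any(ks == s and kt != t for ks, kt in final_c)
            and any(kt == t and ks != s for ks, kt in final_c))
        plan.test.append(set(test))
        plan.train.append(set(train_c))
        plan.validation.append(set(val_c))
        plan.evaluable.append(set(evaluable))
        if not evaluable:
            continue
        observed_test = CombinationMeanMatrix(
            np.vstack([all_means.row(key) for key in evaluable]),
            keys=evaluable, probe_ids=list(matrix.probe_ids))

        for method in methods:
            if method == "cmimpute":
                model = build_model(best_hyper, fm.n_probes, fl, seed=seed * 977 + fold_i)
                fit(model, fm, fl, seed=seed * 977 + fold_i)
                imputed = impute_keys(model, evaluable, base_seed=seed * 31 + fold_i)
                imputed.probe_ids = list(matrix.probe_ids)
            elif method in bl.MEAN_KINDS:
                imputed = bl.mean_baseline_matrix(fm, fl, evaluable, method)
            elif method == "logistic":
                models = bl.fit_logistic_baseline(fm, fl, logistic_lam)
                imputed = bl.logistic_impute_matrix(models, fl, evaluable,
                                                    fm.probe_ids)
            else:
                raise ValueError(f"unknown method {method!r}")
            results[method].append(_score(imputed, observed_test, fold_i, method))
            imputations[method].append(imputed)

    tables = {m: (pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame())
              for m, chunks in results.items()}
    return tables, plan, imputations


def final_model_hyperparameters(matrix: SampleMatrix, labels: ConditionLabels,
                                grid, n_splits: int = 4, seed: int = 0,
                                test_frac: float = 0.2) -> Hyperparameters:
    """Pick hyperparameters for the final all-data model.

    Draws ``n_splits`` random 80-20 train/test splits over the eligible
    combinations, grid-searches each, then among the per-split winners picks
    the one with the highest mean held-out score across all splits.
    """
    observed, _, eligible = enumerate_combinations(labels)
    grid = [g if isinstance(g, Hyperparameters) else Hyperparameters(**g) for g in grid]
    eligible = sorted(eligible)
    winners = []
    split_data = []
    for si in range(n_splits):
        rng = np.random.default_rng(seed + si)
        n_test = max(1, int(round(test_frac * len(eligible))))
        test = {eligible[i] for i in rng.choice(len(eligible), n_test, replace=False)}
        train_c = observed - test
        tm, tl = _subset(matrix, labels, _samples_for(matrix, labels, train_c))
        test_means = compute_combination_means(
            *_subset(matrix, labels, _samples_for(matrix, labels, test)))
        best, table = grid_search_hyperparameters(grid, tm, tl, test_means,
                                                  seed=seed + si)
        winners.append(best)
        split_data.append({h_repr(h): s for h, s, _ in table})
    # average each winner's score across every split's table
    avg = []
    for w in winners:
        scores = [d.get(h_repr(w), float("nan")) for d in split_data]
        avg.append(float(np.nanmean(scores)))
    return winners[int(np.nanargmax(avg))]


def h_repr(h: Hyperparameters) -> str:
    return json.dumps(asdict(h), sort_keys=True)
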