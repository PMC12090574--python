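"""Leave-one-species-out regression of log maximum lifespan on methylation.

Combination mean samples (observed or imputed) predict the natural logarithm
of a species' maximum recorded lifespan with ordinary linear least squares.
With more probes than species the system is underdetermined and the
minimum-norm solution is used.  Two settings:

tissue_agnostic -- rows are averaged within species to one sample per
species; each LOSO iteration holds out one species-average row.

tissue_specific -- rows stay intact and share their species' lifespan; each
LOSO iteration holds out all rows of one species and predicts each row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CombinationMeanMatrix


@dataclass
class LifespanTable:
    species: list
    max_lifespan: np.ndarray

    def __post_init__(self) -> None:
        self.species = [str(s) for s in self.species]
        self.max_lifespan = np.asarray(self.max_lifespan, dtype=float)
        if len(self.species) != len(set(self.species)):
            raise ValueError("duplicate species in lifespan table")
        if (self.max_lifespan <= 0).any() or not np.isfinite(self.max_lifespan).all():
            raise ValueError("lifespans must be positive and finite")

    def lookup(self) -> dict:
        return dict(zip(self.species, self.max_lifespan))

    @classmethod
    def from_tsv(cls, path) -> "LifespanTable":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df["species"]), df["max_lifespan_years"].to_numpy())

    def to_tsv(self, path) -> None:
        pd.DataFrame({"species": self.species,
                      "max_lifespan_years": self.max_lifespan}).to_csv(
            path, sep="\t", index=False)


@dataclass
class LifespanPredictionReport:
    mode: str
    per_unit: pd.DataFrame
    r: float
    mse: float
    log_base: str = "natural"
    warnings: list = field(default_factory=list)


def _lstsq_fit_predict(X_train, y_train, X_test):
    """Least squares with intercept; minimum-norm when underdetermined."""
    A = np.column_stack([np.ones(len(X_train)), X_train])
    coef, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    return np.column_stack([np.ones(len(X_test)), X_test]) @ coef


def loso_lifespan_regression(samples: CombinationMeanMatrix,
                             lifespans: LifespanTable,
                             mode: str = "tissue_agnostic") -> LifespanPredictionReport:
    if mode not in ("tissue_agnostic", "tissue_specific"):
        raise ValueError("mode must be 'tissue_agnostic' or 'tissue_specific'")
    table = lifespans.lookup()
    warnings = []
    keep = [i for i, (s, _t) in enumerate(samples.keys) if s in table]
    dropped = sorted({samples.keys[i][0] for i in range(len(samples.keys))
                      if i not in set(keep)})
    if dropped:
        warnings.append(f"species without lifespan excluded: {dropped}")
    keys = [samples.keys[i] for i in keep]
    vals = samples.values[keep]
    species_list = sorted({s for s, _ in keys})
    if len(species_list) < 3:
        raise ValueError("need at least 3 species with lifespan entries")

    if mode == "tissue_agnostic":
        X = np.vstack([vals[[i for i, (s, _) in enumerate(keys) if s == sp]].mean(axis=0)
                       for sp in species_list])
        y = np.log(np.array([table[sp] for sp in species_list]))
        rows = []
        for i, sp in enumerate(species_list):
            mask = np.arange(len(species_list)) != i
            pred = _lstsq_fit_predict(X[mask], y[mask], X[i][None, :])[0]
            rows.append({"species": sp, "tissue": "", "predicted": float(pred),
                         "reported": float(y[i])})
    else:
        X = vals
        y = np.log(np.array([table[s] for s, _ in keys]))
        rows = []
        sp_arr = np.array([s for s, _ in keys])
        for sp in species_list:
            held = sp_arr == sp
            preds = _lstsq_fit_predict(X[~held], y[~held], X[held])
            for (s, t), p, rep in zip(np.array(keys, dtype=object)[held], preds, y[held]):
                rows.append({"species": s, "tissue": t, "predicted": float(p),
                             "reported": float(rep)})

    df = pd.DataFrame(rows)
    pred, rep = df["predicted"].to_numpy(), df["reported"].to_numpy()
    if rep.std() == 0 or pred.std() <= 1e-12 * max(1.0, np.abs(pred).max()):
        r = float("nan")
        warnings.append("Pearson r undefined (constant predictions or targets)")
    else:
        r = float(np.corrcoef(pred, rep)[0, 1])
    mse = float(np.mean((pred - rep) ** 2))
    return LifespanPredictionReport(mode=mode, per_unit=df, r=r, mse=mse,
                                    warnings=warnings)


def tissue_specific_lifespan_eval(report: LifespanPredictionReport,
                                  min_species: int = 3) -> dict:
    """Per-tissue r and MSE for tissues predicted in at least ``min_species`` species."""
    if report.mode != "tissue_specific":
        raise ValueError("requires a tissue_specific report")
    per_tissue = []
    for tissue, grp in report.per_unit.groupby("tissue"):
        if grp["species"].nunique() < min_species:
            continue
        pred, rep = grp["predicted"].to_numpy(), grp["reported"].to_numpy()
        r = float("nan")
        if pred.std() > 0 and rep.std() > 0:
            r = float(np.corrcoef(pred, rep)[0, 1])
        per_tissue.append({"tissue": tissue, "n_species": int(grp["species"].nunique()),
                           "r": r, "mse": float(np.mean((pred - rep) ** 2))})
    if not per_tissue:
        raise ValueError(f"no tissue observed in >= {min_species} species")
    df = pd.DataFrame(per_tissue)
    finite_r = df["r"].to_numpy()
    finite_r = finite_r[np.isfinite(finite_r)]
    return {"per_tissue": df,
            "mean_r": float(finite_r.mean()) if finite_r.size else float("nan"),
            "median_mse": float(df["mse"].median())}


def cross_prediction_correlation(report_a: LifespanPredictionReport,
                                 report_b: LifespanPredictionReport) -> float:
    """Correlation between two reports' predictions over their shared species.

    Used to compare, e.g., predictions from observed vs imputed inputs.
    """
    a = report_a.per_unit.groupby("species")["predicted"].mean()
    b = report_b.per_unit.groupby("species")["predicted"].mean()
    shared = sorted(set(a.index) & set(b.index))
    if len(shared) < 3:
        raise ValueError("need at least 3 shared species")
    return float(np.corrcoef(a.loc[shared], b.loc[shared])[0, 1])
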