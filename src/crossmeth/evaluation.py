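"""Agreement metrics, probe-variance stratification, and signal quantification.

Sample-wise metrics compare an imputed combination mean sample with its
observed counterpart across probes; probe-wise metrics compare a probe's
imputed values with its observed values across combinations.  Pearson r is
undefined for constant vectors; such entries are flagged and excluded from r
summaries while their squared errors still count.  All variances are
population variances (divide by n).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .data import CombinationMeanMatrix, ConditionLabels, SampleMatrix


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson r, NaN when either vector is constant."""
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def _summary(values: np.ndarray) -> dict:
    finite = values[np.isfinite(values)]
    return {
        "mean": float(finite.mean()) if finite.size else float("nan"),
        "median": float(np.median(finite)) if finite.size else float("nan"),
        "n": int(finite.size),
        "n_undefined": int(values.size - finite.size),
    }


@dataclass
class AgreementReport:
    per_sample: pd.DataFrame | None = None
    per_probe: pd.DataFrame | None = None
    summary: dict = field(default_factory=dict)


def _align(imputed: CombinationMeanMatrix, observed: CombinationMeanMatrix,
           probes=None):
    keys = [k for k in imputed.keys if k in set(observed.keys)]
    if len(keys) != len(imputed.keys) or len(keys) != len(observed.keys):
        if not keys:
            raise ValueError("no shared combination keys")
    if probes is None:
        probes = [p for p in imputed.probe_ids if p in set(observed.probe_ids)]
    else:
        probes = list(probes)
        for p in probes:
            if p not in imputed.probe_ids or p not in observed.probe_ids:
                raise ValueError(f"probe {p!r} not shared by both matrices")
    ii = [imputed.probe_ids.index(p) for p in probes]
    oi = [observed.probe_ids.index(p) for p in probes]
    a = np.vstack([imputed.row(k)[ii] for k in keys])
    b = np.vstack([observed.row(k)[oi] for k in keys])
    return keys, probes, a, b


def sample_wise_agreement(imputed: CombinationMeanMatrix,
                          observed: CombinationMeanMatrix,
                          probes=None) -> AgreementReport:
    """Per-combination Pearson r and MSE between imputed and observed rows."""
    keys, probes, a, b = _align(imputed, observed, probes)
    if len(probes) < 2:
        raise ValueError("need at least 2 probes for sample-wise agreement")
    rows = []
    for i, key in enumerate(keys):
        rows.append({
            "species": key[0], "tissue": key[1],
            "r": _pearson(a[i], b[i]),
            "mse": float(np.mean((a[i] - b[i]) ** 2)),
        })
    df = pd.DataFrame(rows)
    return AgreementReport(per_sample=df, summary={
        "sample_r": _summary(df["r"].to_numpy()),
        "sample_mse": _summary(df["mse"].to_numpy()),
    })


def probe_wise_agreement(imputed: CombinationMeanMatrix,
                         observed: CombinationMeanMatrix,
                         probes=None) -> AgreementReport:
    """Per-probe Pearson r and MSE across combinations."""
    keys, probes, a, b = _align(imputed, observed, probes)
    if len(keys) < 2:
        raise ValueError("need at least 2 shared combinations for probe-wise agreement")
    rows = []
    for j, p in enumerate(probes):
        rows.append({
            "probe": p,
            "r": _pearson(a[:, j], b[:, j]),
            "mse": float(np.mean((a[:, j] - b[:, j]) ** 2)),
        })
    df = pd.DataFrame(rows)
    return AgreementReport(per_probe=df, summary={
        "probe_r": _summary(df["r"].to_numpy()),
        "probe_mse": _summary(df["mse"].to_numpy()),
    })


# ---------------------------------------------------------------------------
# Probe variance profile
# ---------------------------------------------------------------------------

@dataclass
class VarianceProfile:
    probe_ids: list
    inter_combination: np.ndarray | None
    mean_inter_tissue: np.ndarray | None
    mean_inter_species: np.ndarray | None
    warnings: list = field(default_factory=list)

    def metric(self, name: str) -> np.ndarray:
        out = getattr(self, name)
        if out is None:
            raise ValueError(f"variance metric {name!r} was not computable")
        return out


def probe_variance_profile(matrix: SampleMatrix,
                           labels: ConditionLabels) -> VarianceProfile:
    """Three staged per-probe variances over combination means.

    inter-combination: variance across all observed combination means.
    mean inter-tissue: within each species with >1 tissue, the variance of its
    per-tissue means, averaged over those species.
    mean inter-species: symmetric, over tissues with >1 species.
    """
    from .data import compute_combination_means

    combos = compute_combination_means(matrix, labels)
    warnings: list[str] = []
    inter_comb = combos.values.var(axis=0, ddof=0) if len(combos.keys) >= 2 else None
    if inter_comb is None:
        warnings.append("fewer than 2 combinations: inter-combination variance absent")

    by_species: dict[str, list[int]] = {}
    by_tissue: dict[str, list[int]] = {}
    for i, (s, t) in enumerate(combos.keys):
        by_species.setdefault(s, []).append(i)
        by_tissue.setdefault(t, []).append(i)

    multi_s = [s for s, idx in sorted(by_species.items()) if len(idx) > 1]
    if multi_s:
        mit = np.mean([combos.values[by_species[s]].var(axis=0, ddof=0)
                       for s in multi_s], axis=0)
    else:
        mit = None
        warnings.append("no species with >1 tissue: mean inter-tissue variance absent")

    multi_t = [t for t, idx in sorted(by_tissue.items()) if len(idx) > 1]
    if multi_t:
        mis = np.mean([combos.values[by_tissue[t]].var(axis=0, ddof=0)
                       for t in multi_t], axis=0)
    else:
        mis = None
        warnings.append("no tissue with >1 species: mean inter-species variance absent")

    return VarianceProfile(list(matrix.probe_ids), inter_comb, mit, mis, warnings)


def assign_variance_quartiles(profile: VarianceProfile, metric: str,
                              probes=None) -> dict:
    """Rank-based quartile labels Q1..Q4 over a probe subset.

    Probes are ordered by (variance, probe id) for stable ties; group sizes
    differ by at most one, with remainders going to the lowest quartiles.
    """
    values = profile.metric(metric)
    if probes is None:
        probes = list(profile.probe_ids)
    idx = [profile.probe_ids.index(p) for p in probes]
    if len(idx) < 4:
        raise ValueError("need at least 4 probes to form quartiles")
    order = sorted(range(len(idx)), key=lambda i: (values[idx[i]], probes[i]))
    labels = {}
    for q, chunk in enumerate(np.array_split(np.array(order), 4), start=1):
        for i in chunk:
            labels[probes[int(i)]] = f"Q{q}"
    return labels


# ---------------------------------------------------------------------------
# Signal analyses
# ---------------------------------------------------------------------------

def remove_species_signal(samples: CombinationMeanMatrix,
                          training: SampleMatrix,
                          labels: ConditionLabels) -> np.ndarray:
    """Subtract each row's same-species training mean; deltas lie in [-1, 1]."""
    out = np.empty_like(samples.values)
    sp = np.array(labels.species)
    for i, (species, _tissue) in enumerate(samples.keys):
        mask = sp == species
        if not mask.any():
            raise ValueError(f"species {species!r} absent from training data")
        out[i] = samples.values[i] - training.values[mask].mean(axis=0)
    return out


def pairwise_label_scores(samples: CombinationMeanMatrix, mode: str, probes=None):
    """Pair correlation scores and same-label indicators over unordered pairs."""
    if mode not in ("species", "tissue"):
        raise ValueError("mode must be 'species' or 'tissue'")
    if probes is not None:
        idx = [samples.probe_ids.index(p) for p in probes]
        vals = samples.values[:, idx]
    else:
        vals = samples.values
    labels = samples.species if mode == "species" else samples.tissue
    n = vals.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples")
    scores, positive = [], []
    for i in range(n):
        for j in range(i + 1, n):
            scores.append(_pearson(vals[i], vals[j]))
            positive.append(labels[i] == labels[j])
    return np.array(scores), np.array(positive, dtype=bool)


def label_signal_auc(samples: CombinationMeanMatrix, mode: str,
                     probes=None) -> float:
    """AUC for classifying same-species (or same-tissue) pairs by correlation.

    Ties contribute 1/2 (Mann-Whitney convention); undefined pair correlations
    (constant rows) are dropped.
    """
    scores, positive = pairwise_label_scores(samples, mode, probes)
    ok = np.isfinite(scores)
    scores, positive = scores[ok], positive[ok]
    if positive.all() or not positive.any():
        raise ValueError("need both same-label and different-label pairs")
    return float(roc_auc_score(positive, scores))


def paired_method_comparison(scores_a, scores_b) -> dict:
    """Fraction of keys where method a beats b, plus Wilcoxon signed-rank p.

    Zero differences are dropped before the test; if every difference is zero
    the p-value is flagged undefined.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must align")
    if a.size < 5:
        raise ValueError("need at least 5 paired scores")
    fraction = float(np.mean(a > b))
    diffs = a - b
    nonzero = diffs[diffs != 0]
    if nonzero.size == 0:
        return {"fraction_a_better": fraction, "p_value": float("nan"),
                "flag": "all differences zero"}
    stat, p = stats.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided")
    return {"fraction_a_better": fraction, "p_value": float(p), "statistic": float(stat)}


def individual_to_individual_variability(matrix: SampleMatrix,
                                         labels: ConditionLabels,
                                         probes=None) -> pd.DataFrame:
    """Mean pairwise Pearson r between individuals within each combination.

    Combinations with fewer than two individuals are omitted.
    """
    if probes is not None:
        idx = [matrix.probe_ids.index(p) for p in probes]
        vals = matrix.values[:, idx]
    else:
        vals = matrix.values
    groups: dict = {}
    for i, key in enumerate(labels.pairs()):
        groups.setdefault(key, []).append(i)
    rows = []
    for key in sorted(groups):
        members = groups[key]
        if len(members) < 2:
            continue
        rs = []
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                rs.append(_pearson(vals[members[x]], vals[members[y]]))
        rs = np.array(rs)
        rows.append({"species": key[0], "tissue": key[1],
                     "mean_pairwise_r": float(np.nanmean(rs)),
                     "n_individuals": len(members)})
    return pd.DataFrame(rows)
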