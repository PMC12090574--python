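"""Combination mean imputation from a trained conditional VAE.

Imputation is individual-agnostic: the latent representation is drawn from
the standard normal prior (never from encoding an existing sample), the
target (species, tissue) two-hot label is fed to the decoder, and the
sigmoid-mapped decoder output is the imputed combination mean sample.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from .cvae import CVAEModel
from .data import (CombinationKey, CombinationMeanMatrix, ConditionLabels,
                   encode_condition_labels, enumerate_combinations)


@dataclass
class ImputedSample:
    key: CombinationKey
    values: np.ndarray
    latent_seed: int


def _key_seed(base_seed: int, key: CombinationKey) -> int:
    """Stable per-key seed so grid imputation is order-independent."""
    h = zlib.crc32(f"{key[0]}\t{key[1]}".encode())
    return int((int(base_seed) * 2654435761 + h) % (2 ** 31))


def impute_combination_mean(model: CVAEModel, key: CombinationKey,
                            seed: int) -> ImputedSample:
    """Impute one combination mean sample: z ~ N(0, I_Z), decode with the label."""
    species, tissue = key
    if species not in model.vocab.species_vocab:
        raise ValueError(f"species {species!r} not in model vocabulary")
    if tissue not in model.vocab.tissue_vocab:
        raise ValueError(f"tissue {tissue!r} not in model vocabulary")
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((1, model.latent_dim))
    y = encode_condition_labels(model.vocab, [(species, tissue)])
    values = model.decode(z, y)[0]
    return ImputedSample(key=(species, tissue), values=values, latent_seed=int(seed))


def impute_keys(model: CVAEModel, keys, base_seed: int) -> CombinationMeanMatrix:
    """Impute an explicit list of combinations; counts are 0 (no observed data)."""
    keys = [tuple(k) for k in keys]
    rows = [impute_combination_mean(model, k, _key_seed(base_seed, k)).values
            for k in keys]
    probe_ids = [f"p{i}" for i in range(model.n_probes)]
    return CombinationMeanMatrix(np.vstack(rows) if rows else
                                 np.zeros((0, model.n_probes)),
                                 keys=keys, probe_ids=probe_ids)


def impute_missing_grid(model: CVAEModel, labels: ConditionLabels,
                        base_seed: int, probe_ids=None) -> CombinationMeanMatrix:
    """Impute every (species, tissue) grid cell without observed samples.

    Per-key seeds are derived by stable hashing from ``base_seed``, so the
    result is deterministic and independent of iteration order.
    """
    _, missing, _ = enumerate_combinations(labels)
    keys = sorted(missing)
    out = impute_keys(model, keys, base_seed)
    if probe_ids is not None:
        if len(probe_ids) != model.n_probes:
            raise ValueError("probe_ids length must equal model probe count")
        out.probe_ids = list(probe_ids)
    return out


@dataclass
class LatentStabilityReport:
    """Variability of imputed samples across latent draws vs across combinations.

    ``median_within_key_variance`` is the median (over probes and keys) of the
    per-probe variance across replicate draws of the same combination.
    ``median_between_key_variance`` is the median per-probe variance across
    the per-combination mean imputations.  A well-behaved model shows
    within << between: the label, not the latent draw, determines the output.
    """

    median_within_key_variance: float
    median_between_key_variance: float
    per_key_within: dict


def latent_stability_report(model: CVAEModel, keys, n_draws: int = 20,
                            seed: int = 0) -> LatentStabilityReport:
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    keys = [tuple(k) for k in keys]
    per_key_within = {}
    key_means = []
    within_medians = []
    for key in keys:
        base = _key_seed(seed, key)
        draws = np.vstack([
            impute_combination_mean(model, key, seed=(base + 7919 * d) % (2 ** 31)).values
            for d in range(n_draws)
        ])
        var = draws.var(axis=0)
        per_key_within[key] = float(np.median(var))
        within_medians.append(var)
        key_means.append(draws.mean(axis=0))
    within = float(np.median(np.concatenate(within_medians)))
    between = float(np.median(np.vstack(key_means).var(axis=0))) if len(keys) > 1 else float("nan")
    return LatentStabilityReport(median_within_key_variance=within,
                                 median_between_key_variance=between,
                                 per_key_within=per_key_within)
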