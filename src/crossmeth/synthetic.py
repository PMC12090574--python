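"""Seeded synthetic methylation compendia with known species/tissue structure.

The generator mimics the structure of real cross-mammal methylation-array
compendia: per-probe baseline methylation, additive per-species and
per-tissue effects on the logit scale, a small species-by-tissue interaction,
individual-level noise, and an incomplete, imbalanced observed grid (only a
fraction of species-tissue cells carry samples, with a skewed number of
individuals per cell).  Because every effect is known, downstream modules can
be tested against exact ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import (CombinationMeanMatrix, ConditionLabels, MappabilityTable,
                   SampleMatrix)
from .lifespan import LifespanTable


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class EffectSizes:
    """Logit-scale standard deviations of the generative effects."""

    species: float = 0.6
    tissue: float = 0.6
    interaction: float = 0.1
    noise: float = 0.4
    baseline: float = 1.2


@dataclass
class SyntheticTruth:
    species_names: list
    tissue_names: list
    probe_ids: list
    baseline: np.ndarray          # (M,) logit-scale probe baselines
    species_effects: np.ndarray   # (S, M)
    tissue_effects: np.ndarray    # (T, M)
    interaction: np.ndarray       # (S, T, M)
    effect_sds: EffectSizes
    observed_mask: np.ndarray     # (S, T) bool
    counts: np.ndarray            # (S, T) individuals per observed cell
    seed: int

    def logit_means(self) -> np.ndarray:
        return (self.baseline[None, None, :] + self.species_effects[:, None, :]
                + self.tissue_effects[None, :, :] + self.interaction)

    def true_means(self) -> np.ndarray:
        """(S, T, M) array of noiseless combination mean beta values."""
        return _sigmoid(self.logit_means())

    def true_mean_matrix(self, keys=None) -> CombinationMeanMatrix:
        means = self.true_means()
        if keys is None:
            keys = [(s, t) for s in self.species_names for t in self.tissue_names]
        si = {s: i for i, s in enumerate(self.species_names)}
        ti = {t: i for i, t in enumerate(self.tissue_names)}
        rows = np.vstack([means[si[s], ti[t]] for s, t in keys])
        return CombinationMeanMatrix(rows, keys=[tuple(k) for k in keys],
                                     probe_ids=list(self.probe_ids))

    def species_average_means(self) -> np.ndarray:
        """(S, M) species-level average of the true means over all tissues."""
        return self.true_means().mean(axis=1)


def _draw_observed_mask(rng, S, T, observed_fraction, max_tries=200):
    n_obs = int(round(observed_fraction * S * T))
    if n_obs < max(S, T):
        raise ValueError("observed_fraction too small to cover every species and tissue")
    for _ in range(max_tries):
        flat = rng.choice(S * T, size=n_obs, replace=False)
        mask = np.zeros(S * T, dtype=bool)
        mask[flat] = True
        mask = mask.reshape(S, T)
        if mask.any(axis=1).all() and mask.any(axis=0).all():
            return mask
    raise ValueError("could not draw a connected observed mask at this fraction")


def generate_compendium(S: int = 20, T: int = 6, M: int = 300,
                        mean_samples_per_combo: float = 3.0,
                        observed_fraction: float = 0.8,
                        effect_sds: EffectSizes | None = None,
                        seed: int = 0):
    """Generate (SampleMatrix, ConditionLabels, SyntheticTruth).

    Probe p in species s and tissue t has logit-scale mean
    b_p + u_{s,p} + v_{t,p} + w_{s,t,p}; an individual's beta value is the
    sigmoid of that mean plus Gaussian noise.  The observed mask keeps every
    species in >= 1 tissue and every tissue in >= 1 species; per-cell
    individual counts are geometric (mean ``mean_samples_per_combo``) to
    mimic opportunistic, imbalanced collection.
    """
    if S < 2 or T < 2 or M < 2:
        raise ValueError("S, T, M must all be >= 2")
    if not 0 < observed_fraction <= 1:
        raise ValueError("observed_fraction must be in (0, 1]")
    sds = effect_sds or EffectSizes()
    rng = np.random.default_rng(seed)
    species_names = [f"species{i:03d}" for i in range(S)]
    tissue_names = [f"tissue{i:02d}" for i in range(T)]
    probe_ids = [f"cg{i:05d}" for i in range(M)]

    baseline = rng.normal(0.0, sds.baseline, size=M)
    species_eff = rng.normal(0.0, sds.species, size=(S, M))
    tissue_eff = rng.normal(0.0, sds.tissue, size=(T, M))
    interaction = rng.normal(0.0, sds.interaction, size=(S, T, M))
    mask = _draw_observed_mask(rng, S, T, observed_fraction)

    counts = np.zeros((S, T), dtype=int)
    p_geom = min(1.0, 1.0 / max(mean_samples_per_combo, 1.0))
    counts[mask] = rng.geometric(p_geom, size=int(mask.sum()))

    truth = SyntheticTruth(species_names, tissue_names, probe_ids, baseline,
                           species_eff, tissue_eff, interaction, sds, mask,
                           counts, int(seed))
    logit = truth.logit_means()
    rows, sp, ti = [], [], []
    for i in range(S):
        for j in range(T):
            for _ in range(counts[i, j]):
                noise = rng.normal(0.0, sds.noise, size=M) if sds.noise > 0 else 0.0
                rows.append(_sigmoid(logit[i, j] + noise))
                sp.append(species_names[i])
                ti.append(tissue_names[j])
    values = np.clip(np.vstack(rows), 0.0, 1.0)
    sample_ids = [f"s{i:05d}" for i in range(len(rows))]
    matrix = SampleMatrix(values, sample_ids, probe_ids)
    labels = ConditionLabels(sp, ti)
    return matrix, labels, truth


def generate_lifespans(truth: SyntheticTruth, signal_probes: int = 3,
                       noise_sd: float = 0.0, seed: int = 0,
                       base_log_lifespan: float = 3.0) -> LifespanTable:
    """Species lifespans whose log is linear in species-average methylation.

    ``signal_probes`` probes carry the signal; with 0 the log-lifespan is pure
    noise around the base value.  The linear combination is standardized to
    unit spread before adding noise, so r-based recovery tests are
    scale-free.  Lifespans are exponentiated, hence strictly positive.
    """
    if signal_probes > len(truth.probe_ids):
        raise ValueError("signal_probes exceeds probe count")
    rng = np.random.default_rng(seed)
    features = truth.species_average_means()
    S = features.shape[0]
    if signal_probes > 0:
        idx = rng.choice(features.shape[1], size=signal_probes, replace=False)
        coeffs = rng.normal(1.0, 0.5, size=signal_probes)
        raw = features[:, idx] @ coeffs
        sd = raw.std()
        signal = (raw - raw.mean()) / sd if sd > 0 else np.zeros(S)
    else:
        signal = np.zeros(S)
    log_life = base_log_lifespan + signal + rng.normal(0.0, noise_sd, size=S)
    return LifespanTable(list(truth.species_names), np.exp(log_life))


def generate_mappability(probe_ids, species_ids, mappable_prob: float = 0.95,
                         seed: int = 0) -> MappabilityTable:
    """Random mappability mask, for interface testing only (no biology)."""
    rng = np.random.default_rng(seed)
    mat = rng.random((len(probe_ids), len(species_ids))) < mappable_prob
    return MappabilityTable(list(probe_ids), list(species_ids), mat)
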