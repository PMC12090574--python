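"""Core data model for methylation compendia.

A compendium is a samples-by-probes matrix of beta values (fraction of
methylated copies at a CpG, in [0, 1]) together with a species and tissue
label for every individual sample.  The unit of imputation downstream is the
*combination mean sample*: a species' average methylation profile within one
tissue type.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

CombinationKey = tuple[str, str]
"""(species, tissue) pair identifying one combination mean sample."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what} id: {i!r}")
        seen.add(i)


@dataclass
class SampleMatrix:
    """N x M matrix of beta values with sample and probe identifiers.

    Values must be finite and in [0, 1]; missing values are rejected rather
    than silently imputed (the pipeline assumes a complete normalized matrix).
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.probe_ids = [str(p) for p in self.probe_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d array")
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValueError("matrix must have at least one sample and one probe")
        if len(self.sample_ids) != n or len(self.probe_ids) != m:
            raise ValueError("id lists do not match matrix shape")
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.probe_ids, "probe")
        bad = ~np.isfinite(self.values) | (self.values < 0) | (self.values > 1)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"beta value out of [0, 1] at sample {self.sample_ids[i]!r}, "
                f"probe {self.probe_ids[j]!r}: {self.values[i, j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def subset_probes(self, probe_ids) -> "SampleMatrix":
        idx = [self.probe_ids.index(p) for p in probe_ids]
        return SampleMatrix(self.values[:, idx], list(self.sample_ids), list(probe_ids))


@dataclass
class ConditionLabels:
    """Per-sample species/tissue assignments plus deterministic vocabularies.

    Vocabularies are the lexicographically sorted unique species and tissues;
    one-hot column order is fixed by them.
    """

    species: list[str]
    tissue: list[str]
    species_vocab: list[str] = field(default_factory=list)
    tissue_vocab: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.species = [str(s) for s in self.species]
        self.tissue = [str(t) for t in self.tissue]
        if len(self.species) != len(self.tissue):
            raise ValueError("species and tissue lists differ in length")
        if not self.species_vocab:
            self.species_vocab = sorted(set(self.species))
        if not self.tissue_vocab:
            self.tissue_vocab = sorted(set(self.tissue))
        sv, tv = set(self.species_vocab), set(self.tissue_vocab)
        for s in self.species:
            if s not in sv:
                raise ValueError(f"species {s!r} not in vocabulary")
        for t in self.tissue:
            if t not in tv:
                raise ValueError(f"tissue {t!r} not in vocabulary")

    @property
    def n_samples(self) -> int:
        return len(self.species)

    @property
    def n_species(self) -> int:
        return len(self.species_vocab)

    @property
    def n_tissues(self) -> int:
        return len(self.tissue_vocab)

    def pairs(self) -> list[CombinationKey]:
        return list(zip(self.species, self.tissue))

    def subset(self, idx) -> "ConditionLabels":
        return ConditionLabels(
            [self.species[i] for i in idx],
            [self.tissue[i] for i in idx],
            list(self.species_vocab),
            list(self.tissue_vocab),
        )


@dataclass
class CombinationMeanMatrix:
    """One row per (species, tissue) combination of mean probe values.

    ``counts`` records how many individual samples contributed to each row;
    imputed rows carry count 0.
    """

    values: np.ndarray
    keys: list[CombinationKey]
    probe_ids: list[str]
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.keys = [(str(s), str(t)) for s, t in self.keys]
        if self.values.ndim != 2 or self.values.shape[0] != len(self.keys):
            raise ValueError("values rows must align with keys")
        if self.values.shape[1] != len(self.probe_ids):
            raise ValueError("values columns must align with probe_ids")
        if self.counts is None:
            self.counts = np.zeros(len(self.keys), dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if not np.isfinite(self.values).all():
            raise ValueError("non-finite combination mean values")
        if (self.values < -1e-12).any() or (self.values > 1 + 1e-12).any():
            raise ValueError("combination mean values outside [0, 1]")
        _check_unique(self.keys, "combination")

    def row(self, key: CombinationKey) -> np.ndarray:
        return self.values[self.keys.index(tuple(key))]

    @property
    def species(self) -> list[str]:
        return [k[0] for k in self.keys]

    @property
    def tissue(self) -> list[str]:
        return [k[1] for k in self.keys]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.probe_ids)
        df.insert(0, "tissue", self.tissue)
        df.insert(0, "species", self.species)
        return df

    def as_labels(self) -> ConditionLabels:
        return ConditionLabels(self.species, self.tissue)


@dataclass
class MappabilityTable:
    """Probe x species boolean table: does the probe map to a unique locus?"""

    probe_ids: list[str]
    species_ids: list[str]
    mappable: np.ndarray

    def __post_init__(self) -> None:
        self.mappable = np.asarray(self.mappable, dtype=bool)
        if self.mappable.shape != (len(self.probe_ids), len(self.species_ids)):
            raise ValueError("mappability matrix shape inconsistent with ids")


# ---------------------------------------------------------------------------
# File I/O (TSV + HDF5)
# ---------------------------------------------------------------------------

def load_sample_matrix(path, labels_path) -> tuple[SampleMatrix, ConditionLabels]:
    """Read a samples-by-probes TSV (or HDF5) and its sample label table.

    The matrix header row holds probe ids, the first column sample ids.  The
    labels file is TSV with columns ``sample_id``, ``species``, ``tissue``;
    label rows are reordered to the matrix's sample order.
    """
    if str(path).endswith((".h5", ".hdf5")):
        matrix = load_matrix_h5(path)
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"non-numeric value in matrix {path}: {exc}") from exc
        matrix = SampleMatrix(values, [str(i) for i in df.index], [str(c) for c in df.columns])

    lab = pd.read_csv(labels_path, sep="\t", dtype=str)
    required = {"sample_id", "species", "tissue"}
    if not required.issubset(lab.columns):
        raise ValueError(f"labels file must have columns {sorted(required)}")
    _check_unique(list(lab["sample_id"]), "label sample")
    by_id = lab.set_index("sample_id")
    missing = [s for s in matrix.sample_ids if s not in by_id.index]
    if missing:
        raise ValueError(f"labels file missing sample_id(s): {missing}")
    ordered = by_id.loc[matrix.sample_ids]
    labels = ConditionLabels(list(ordered["species"]), list(ordered["tissue"]))
    return matrix, labels


def save_sample_matrix(matrix: SampleMatrix, path, labels: ConditionLabels | None = None,
                       labels_path=None) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.sample_ids, columns=matrix.probe_ids)
    df.to_csv(path, sep="\t", index_label="sample_id")
    if labels is not None and labels_path is not None:
        save_labels(labels, matrix.sample_ids, labels_path)


def save_labels(labels: ConditionLabels, sample_ids, path) -> None:
    pd.DataFrame(
        {"sample_id": sample_ids, "species": labels.species, "tissue": labels.tissue}
    ).to_csv(path, sep="\t", index=False)


def save_matrix_h5(matrix: SampleMatrix, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=matrix.values)
        f.create_dataset("sample_ids", data=np.array(matrix.sample_ids, dtype="S"))
        f.create_dataset("probe_ids", data=np.array(matrix.probe_ids, dtype="S"))


def load_matrix_h5(path) -> SampleMatrix:
    with h5py.File(path, "r") as f:
        return SampleMatrix(
            f["values"][...],
            [s.decode() for s in f["sample_ids"][...]],
            [p.decode() for p in f["probe_ids"][...]],
        )


def load_mappability(path) -> MappabilityTable:
    """TSV with rows = probes (first column ids), columns = species, cells in {0,1}."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("mappability cells must be 0 or 1")
    return MappabilityTable([str(i) for i in df.index], [str(c) for c in df.columns],
                            vals.astype(bool))


def save_combination_means(combos: CombinationMeanMatrix, path, metadata: dict | None = None) -> None:
    with open(path, "w") as fh:
        if metadata:
            meta = " ".join(f"{k}={v}" for k, v in sorted(metadata.items()))
            fh.write(f"# {meta}\n")
        combos.to_frame().assign(n_samples=combos.counts).to_csv(fh, sep="\t", index=False)


def load_combination_means(path) -> CombinationMeanMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    counts = df.pop("n_samples").to_numpy() if "n_samples" in df.columns else None
    keys = list(zip(df.pop("species"), df.pop("tissue")))
    return CombinationMeanMatrix(df.to_numpy(dtype=float), keys=keys,
                                 probe_ids=[str(c) for c in df.columns], counts=counts)


# ---------------------------------------------------------------------------
# Label encoding and combination bookkeeping
# ---------------------------------------------------------------------------

def encode_condition_labels(labels: ConditionLabels,
                            pairs: list[CombinationKey] | None = None) -> np.ndarray:
    """Two-hot encode (species, tissue) pairs into an N x (S + T) matrix.

    Columns are the species block (vocab order) followed by the tissue block;
    every row has exactly two ones.
    """
    if pairs is None:
        pairs = labels.pairs()
    s_index = {s: i for i, s in enumerate(labels.species_vocab)}
    t_index = {t: i for i, t in enumerate(labels.tissue_vocab)}
    S, T = len(s_index), len(t_index)
    out = np.zeros((len(pairs), S + T))
    for i, (s, t) in enumerate(pairs):
        if s not in s_index:
            raise ValueError(f"species {s!r} not in vocabulary")
        if t not in t_index:
            raise ValueError(f"tissue {t!r} not in vocabulary")
        out[i, s_index[s]] = 1.0
        out[i, S + t_index[t]] = 1.0
    return out


def compute_combination_means(matrix: SampleMatrix,
                              labels: ConditionLabels) -> CombinationMeanMatrix:
    """Average individual samples within each observed (species, tissue) pair."""
    if matrix.n_samples != labels.n_samples:
        raise ValueError("matrix and labels disagree on sample count")
    groups: dict[CombinationKey, list[int]] = {}
    for i, key in enumerate(labels.pairs()):
        groups.setdefault(key, []).append(i)
    keys = sorted(groups)
    values = np.vstack([matrix.values[groups[k]].mean(axis=0) for k in keys])
    counts = np.array([len(groups[k]) for k in keys])
    return CombinationMeanMatrix(values, keys=keys, probe_ids=list(matrix.probe_ids),
                                 counts=counts)


def enumerate_combinations(labels: ConditionLabels):
    """Partition the S x T grid into observed / missing, and find eligible pairs.

    An observed pair is *eligible* (can be meaningfully held out) when its
    species occurs with more than one distinct tissue and its tissue occurs
    with more than one distinct species.
    """
    observed = set(labels.pairs())
    grid = {(s, t) for s in labels.species_vocab for t in labels.tissue_vocab}
    missing = grid - observed
    tissues_of: dict[str, set] = {}
    species_of: dict[str, set] = {}
    for s, t in observed:
        tissues_of.setdefault(s, set()).add(t)
        species_of.setdefault(t, set()).add(s)
    eligible = {
        (s, t) for s, t in observed
        if len(tissues_of[s]) > 1 and len(species_of[t]) > 1
    }
    return observed, missing, eligible


def select_highest_coverage_probes(table: MappabilityTable, fraction: float = 0.9) -> set:
    """Probes mappable in at least ``fraction`` of the table's species (inclusive)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if len(table.species_ids) == 0:
        raise ValueError("mappability table has no species")
    frac = table.mappable.mean(axis=1)
    return {p for p, f in zip(table.probe_ids, frac) if f >= fraction - 1e-12}
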